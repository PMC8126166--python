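"""Endosomal compartment model and receptor-fate prediction.

Internalized ApoE-LDLR complexes travel through progressively more
acidic compartments: extracellular medium (pH ~7.5), very early
endosome (VEE, pH 7.0-7.5), early endosome (EE, pH 6-7) and late
endosome (LE, pH 5.0-6.0).  At each station the mean charge product
between the isoform's R112C domain and the LDL-A repeats decides the
receptor's fate: repulsion lets ApoE dissociate so the receptor
recycles to the plasma membrane; a neutral interaction leaves the
complex bound; attraction in the late endosome traps the complex,
which is then routed to lysosomal degradation.  Attraction anywhere
earlier merely keeps the complex bound, since degradation is only
assigned from the late endosome.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .interaction import InteractionProfile, classify_value
from .protonation import TitrationError

FATE_BY_LABEL = {
    "repulsive": "dissociates_recycles",
    "neutral": "remains_bound",
}


@dataclass(frozen=True)
class Compartment:
    """A station of the endocytic pathway with its intraluminal pH range."""

    name: str
    ph_lo: float
    ph_hi: float

    def __post_init__(self) -> None:
        if self.ph_lo > self.ph_hi:
            raise TitrationError(f"{self.name}: ph_lo > ph_hi")

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.ph_lo + self.ph_hi)


#: Compartment sets.  ``figure4`` uses the pathway pH ranges
#: (VEE 7.0-7.5, EE 6-7, LE 5.0-6.0); ``midpoint_legacy`` uses the
#: single representative values quoted alongside the charge analysis
#: (EE 6.5, LE 5.5).  Both appear in the source narrative, so neither
#: is silently treated as the correct one: the set is always an
#: explicit argument or config entry.
COMPARTMENT_SETS: dict[str, tuple[Compartment, ...]] = {
    "figure4": (
        Compartment("extracellular", 7.5, 7.5),
        Compartment("VEE", 7.0, 7.5),
        Compartment("EE", 6.0, 7.0),
        Compartment("LE", 5.0, 6.0),
    ),
    "midpoint_legacy": (
        Compartment("extracellular", 7.5, 7.5),
        Compartment("VEE", 7.25, 7.25),
        Compartment("EE", 6.5, 6.5),
        Compartment("LE", 5.5, 5.5),
    ),
}


def default_compartments(set_name: str = "figure4") -> list[Compartment]:
    """Compartments of the endocytic pathway, ordered by decreasing pH."""
    try:
        return list(COMPARTMENT_SETS[set_name])
    except KeyError:
        raise TitrationError(
            f"unknown compartment set {set_name!r}; "
            f"available: {', '.join(COMPARTMENT_SETS)}"
        ) from None


def _fate(label: str, compartment: str) -> str:
    if label == "attractive":
        return "trapped_degraded" if compartment == "LE" else "remains_bound"
    return FATE_BY_LABEL[label]


def fate_report(
    profiles: Sequence[InteractionProfile],
    compartments: Sequence[Compartment] | None = None,
    eps: float = 0.5,
    *,
    worst_case: bool = False,
) -> pd.DataFrame:
    """Predict the receptor fate per (isoform, compartment).

    Each profile's mean alpha is evaluated at the compartment midpoint
    (with ``worst_case=True``, additionally at both interval endpoints,
    keeping the evaluation whose classification is most attractive),
    classified against the neutrality threshold ``eps``, and mapped to a
    fate.  Returns a tidy DataFrame with one row per isoform and
    compartment, columns (isoform, compartment, ph, mean_alpha, label,
    fate).
    """
    if eps <= 0:
        raise TitrationError("eps must be positive")
    compartments = (
        default_compartments() if compartments is None else list(compartments)
    )
    severity = {"repulsive": 0, "neutral": 1, "attractive": 2}
    rows = []
    for prof in profiles:
        grid = np.asarray(prof.ph_grid, dtype=float)
        for comp in compartments:
            phs = [comp.midpoint]
            if worst_case:
                phs += [comp.ph_lo, comp.ph_hi]
            picked = None
            for ph in phs:
                if not grid[0] <= ph <= grid[-1]:
                    raise TitrationError(
                        f"compartment {comp.name} pH {ph} outside the "
                        f"profile grid [{grid[0]}, {grid[-1]}]"
                    )
                alpha = float(np.interp(ph, grid, prof.mean_alpha))
                label = classify_value(alpha, eps)
                cand = (severity[label], ph, alpha, label)
                if picked is None or cand[0] > picked[0]:
                    picked = cand
            _, ph, alpha, label = picked
            rows.append(
                {
                    "isoform": prof.isoform_id,
                    "compartment": comp.name,
                    "ph": ph,
                    "mean_alpha": alpha,
                    "label": label,
                    "fate": _fate(label, comp.name),
                }
            )
    return pd.DataFrame(rows)
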