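"""Synthetic peptides and independent oracles for the titration engine.

The generator produces random peptides with a controlled ionizable
composition so that every stage of the pipeline (counting, titration,
charge products, interval extraction) can be exercised on inputs that
are independent of the packaged domain fixtures.  The charge oracle
re-implements the titration sum as a deliberately naive per-residue
loop — no precomputed counts, no vectorization — so that agreement
with the engine is a meaningful cross-check rather than a tautology.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .domains import CANONICAL_AA, PeptideSequence, SequenceError
from .protonation import TitrationOptions, default_table

ACIDIC_RESIDUES = "DE"
BASIC_RESIDUES = "KRH"
NEUTRAL_RESIDUES = "GAVLIPFMWSTNQ"  # no titratable side chain

_CLASS_POOLS: Mapping[str, str] = {
    "acidic": ACIDIC_RESIDUES,
    "basic": BASIC_RESIDUES,
    "neutral": NEUTRAL_RESIDUES,
}


@dataclass(frozen=True)
class CompositionSpec:
    """Recipe for a random peptide of controlled composition.

    ``group_fractions`` maps residue classes ("acidic", "basic",
    "neutral") or specific one-letter codes to target fractions; the
    remainder of the length is filled with glycine.
    """

    length: int
    group_fractions: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise SequenceError("length must be >= 1")
        total = 0.0
        for key, frac in self.group_fractions.items():
            if key not in _CLASS_POOLS and key not in CANONICAL_AA:
                raise SequenceError(f"unknown residue class {key!r}")
            if frac < 0:
                raise SequenceError(f"negative fraction for {key!r}")
            total += frac
        if total > 1 + 1e-9:
            raise SequenceError(f"fractions sum to {total} > 1")


def random_peptide(spec: CompositionSpec) -> PeptideSequence:
    """Draw a peptide matching ``spec``; deterministic given the seed.

    Each class receives round(fraction * length) residues (within one
    residue of the exact target), drawn uniformly from the class pool;
    positions are then shuffled.
    """
    rng = np.random.default_rng(spec.seed)
    residues: list[str] = []
    for key in sorted(spec.group_fractions):
        count = round(spec.group_fractions[key] * spec.length)
        count = min(count, spec.length - len(residues))
        pool = _CLASS_POOLS.get(key, key)
        residues.extend(rng.choice(list(pool), size=count))
    residues.extend("G" * (spec.length - len(residues)))
    perm = rng.permutation(len(residues))
    seq = "".join(residues[i] for i in perm)
    return PeptideSequence(id=f"synthetic_seed{spec.seed}", residues=seq)


def oracle_net_charge(
    seq: PeptideSequence, ph: float, opts: TitrationOptions | None = None
) -> float:
    """Reference net charge by an unvectorized per-residue walk.

    Structurally independent of the engine: iterates the residue string
    directly, re-resolving each group's pKa and protonated fraction on
    the spot, and handles the termini as two extra pseudo-residues.
    """
    opts = opts or TitrationOptions()
    if not 0.0 < ph < 14.0:
        raise ValueError(f"pH {ph} outside (0, 14)")
    table = opts.pka_table
    total = 0.0
    for index, residue in enumerate(seq.residues):
        position = seq.numbering_offset + index
        if residue in "KRH":
            total += 1.0 / (1.0 + 10.0 ** (ph - table[residue]))
        elif residue in "DEY":
            total -= 1.0 / (1.0 + 10.0 ** (table[residue] - ph))
        elif residue == "C":
            bridged = position in seq.disulfide_cys
            if opts.titrate_disulfide_cys or not bridged:
                total -= 1.0 / (1.0 + 10.0 ** (table["C"] - ph))
    if opts.include_termini and seq.has_free_n_terminus:
        total += 1.0 / (1.0 + 10.0 ** (ph - table["N_TERM"]))
    if opts.include_termini and seq.has_free_c_terminus:
        total -= 1.0 / (1.0 + 10.0 ** (table["C_TERM"] - ph))
    return total


def mutate(
    seq: PeptideSequence, position: int, new_residue: str
) -> PeptideSequence:
    """Single-residue substitution at a mature-protein position.

    All annotations are preserved, except that destroying a cysteine
    removes the position from the disulfide set (a newly created
    cysteine is a free thiol, never auto-bridged).
    """
    if new_residue not in CANONICAL_AA:
        raise SequenceError(f"illegal residue {new_residue!r}")
    old = seq.residue_at(position)  # raises on out-of-range
    i = position - seq.numbering_offset
    ss = set(seq.disulfide_cys)
    if old == "C" and new_residue != "C":
        ss.discard(position)
    return replace(
        seq,
        residues=seq.residues[:i] + new_residue + seq.residues[i + 1:],
        disulfide_cys=frozenset(ss),
    )


def run_selftest(
    n_peptides: int = 500,
    n_ph: int = 20,
    master_seed: int = 20210510,
    tol: float = 1e-9,
) -> tuple[int, int, float]:
    """Oracle-equivalence sweep: engine vs per-residue oracle.

    Draws ``n_peptides`` random mixed-composition peptides, compares
    :func:`endocharge.protonation.net_charge` with
    :func:`oracle_net_charge` at ``n_ph`` pH values each, and returns
    (passed, failed, max_abs_deviation).
    """
    from .protonation import net_charge

    rng = np.random.default_rng(master_seed)
    opts = TitrationOptions(pka_table=default_table())
    passed = failed = 0
    worst = 0.0
    for k in range(n_peptides):
        spec = CompositionSpec(
            length=int(rng.integers(5, 60)),
            group_fractions={
                "acidic": float(rng.uniform(0, 0.4)),
                "basic": float(rng.uniform(0, 0.4)),
                "C": float(rng.uniform(0, 0.1)),
                "Y": float(rng.uniform(0, 0.1)),
            },
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        pep = random_peptide(spec)
        for ph in rng.uniform(0.5, 13.5, size=n_ph):
            dev = abs(net_charge(pep, ph, opts) - oracle_net_charge(pep, ph, opts))
            worst = max(worst, dev)
            if dev < tol:
                passed += 1
            else:
                failed += 1
    return passed, failed, worst
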