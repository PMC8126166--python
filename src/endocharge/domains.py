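"""Peptide sequence registry, FASTA I/O and subsequence extraction.

All coordinates are 1-based inclusive positions in the mature protein
(signal peptide removed), because the allele-defining ApoE positions
112/158 are universally quoted in mature numbering.

The built-in registry holds the two ApoE "R112C domain" variants (the
segment of the third amphipathic helix that carries the E3/E4
polymorphic position 112) and the seven ~40-residue LDL-A repeats from
the LDL receptor ectodomain.  The registry FASTA is shipped with the
package; it is re-derivable from the full-length reference sequences
plus the window coordinates recorded in ``data/config.yaml`` (see
:func:`derive_builtins`).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = set("ACDEFGHIKLMNPQRSTVWY")

#: Registry keys, in canonical order.
BUILTIN_NAMES = (
    "R112C_E3",
    "R112C_E4",
    "RP1",
    "RP2",
    "RP3",
    "RP4",
    "RP5",
    "RP6",
    "RP7",
)


class SequenceError(ValueError):
    """Invalid peptide sequence or coordinates."""


@dataclass(frozen=True)
class PeptideSequence:
    """An annotated one-letter peptide sequence.

    Parameters
    ----------
    id:
        Short label, e.g. ``"R112C_E3"`` or ``"RP1"``.
    residues:
        Uppercase string over the 20 canonical one-letter codes.
    numbering_offset:
        Mature-protein position of the first residue (1-based).
    disulfide_cys:
        Mature positions of cysteines engaged in disulfide bridges.
    has_free_n_terminus, has_free_c_terminus:
        Whether the alpha-amino / alpha-carboxyl group is present and
        free to titrate.  Internal fragments of a larger chain may have
        both switched off.
    """

    id: str
    residues: str
    numbering_offset: int = 1
    disulfide_cys: frozenset[int] = field(default_factory=frozenset)
    has_free_n_terminus: bool = True
    has_free_c_terminus: bool = True

    def __post_init__(self) -> None:
        if not self.residues:
            raise SequenceError(f"{self.id!r}: empty sequence")
        for i, aa in enumerate(self.residues):
            if aa not in CANONICAL_AA:
                raise SequenceError(
                    f"{self.id!r}: illegal residue {aa!r} at position "
                    f"{self.numbering_offset + i}"
                )
        if self.numbering_offset < 1:
            raise SequenceError(f"{self.id!r}: numbering_offset must be >= 1")
        object.__setattr__(self, "disulfide_cys", frozenset(self.disulfide_cys))
        for pos in self.disulfide_cys:
            if self.residue_at(pos) != "C":
                raise SequenceError(
                    f"{self.id!r}: disulfide annotation at {pos} is not a Cys"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def start(self) -> int:
        return self.numbering_offset

    @property
    def end(self) -> int:
        return self.numbering_offset + len(self.residues) - 1

    def residue_at(self, position: int) -> str:
        """Residue at a mature-protein position (1-based)."""
        if not self.start <= position <= self.end:
            raise SequenceError(
                f"{self.id!r}: position {position} outside "
                f"[{self.start}, {self.end}]"
            )
        return self.residues[position - self.numbering_offset]


def _header_of(seq: PeptideSequence) -> str:
    parts = []
    if seq.numbering_offset != 1:
        parts.append(f"offset={seq.numbering_offset}")
    if seq.disulfide_cys:
        parts.append("ss=" + ",".join(str(p) for p in sorted(seq.disulfide_cys)))
    if not seq.has_free_n_terminus:
        parts.append("nterm=blocked")
    if not seq.has_free_c_terminus:
        parts.append("cterm=blocked")
    return " ".join(parts)


def _parse_description(seq_id: str, description: str) -> dict:
    """Parse ``key=value`` tokens from a FASTA description line.

    The first whitespace-delimited token is the id; everything after is
    free description except the recognized keys below.
    """
    kwargs: dict = {}
    for token in description.split()[1:]:
        if token.startswith("offset="):
            kwargs["numbering_offset"] = int(token[len("offset="):])
        elif token.startswith("ss="):
            payload = token[len("ss="):]
            if payload:
                kwargs["disulfide_cys"] = frozenset(
                    int(p) for p in payload.split(",")
                )
        elif token == "nterm=blocked":
            kwargs["has_free_n_terminus"] = False
        elif token == "cterm=blocked":
            kwargs["has_free_c_terminus"] = False
    return kwargs


def read_fasta(path: str | Path) -> list[PeptideSequence]:
    """Read peptides from a FASTA file.

    Annotations are taken from ``offset=``, ``ss=`` (comma-separated
    mature positions of disulfide-bonded cysteines), ``nterm=blocked``
    and ``cterm=blocked`` tokens in the header; the defaults are
    offset 1, no disulfides and free termini.
    """
    path = Path(path)
    out: list[PeptideSequence] = []
    with path.open() as handle:
        # Reject non-FASTA leading content with a line number; SeqIO
        # silently returns nothing for some malformed inputs.
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise SequenceError(
                    f"{path}: line {lineno} is not FASTA (expected '>')"
                )
            break
    for record in SeqIO.parse(str(path), "fasta"):
        kwargs = _parse_description(record.id, record.description)
        out.append(PeptideSequence(record.id, str(record.seq).upper(), **kwargs))
    return out


def write_fasta(seqs: Iterable[PeptideSequence], path: str | Path) -> None:
    """Write peptides as FASTA, 60 residues per line, annotations in header."""
    seqs = list(seqs)
    if not seqs:
        raise SequenceError("refusing to write an empty FASTA file")
    records = [
        SeqRecord(Seq(s.residues), id=s.id, description=_header_of(s))
        for s in seqs
    ]
    with Path(path).open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
        writer.write_file(records)


def extract_subsequence(
    seq: PeptideSequence,
    start: int,
    end: int,
    *,
    free_termini: bool = True,
    new_id: str | None = None,
) -> PeptideSequence:
    """Extract [start, end] (mature coordinates, 1-based inclusive).

    The fragment keeps mature numbering (``numbering_offset = start``)
    and the disulfide annotations that fall inside the window.  By
    default the fragment is treated as a free peptide with both termini
    titratable, mirroring how a pasted subsequence is handled by naive
    charge calculators; ``free_termini=False`` marks both ends as
    blocked (an internal fragment of a longer chain).
    """
    if start > end:
        raise SequenceError(f"start {start} > end {end}")
    if start < seq.start or end > seq.end:
        raise SequenceError(
            f"window [{start}, {end}] outside {seq.id!r} range "
            f"[{seq.start}, {seq.end}]"
        )
    i = start - seq.numbering_offset
    return PeptideSequence(
        id=new_id or f"{seq.id}[{start}-{end}]",
        residues=seq.residues[i : i + (end - start + 1)],
        numbering_offset=start,
        disulfide_cys=frozenset(p for p in seq.disulfide_cys if start <= p <= end),
        has_free_n_terminus=free_termini,
        has_free_c_terminus=free_termini,
    )


def _data_path(name: str) -> Path:
    return Path(importlib.resources.files("endocharge") / "data" / name)


def load_config() -> dict:
    """Load the packaged configuration (windows, defaults, thresholds)."""
    with _data_path("config.yaml").open() as fh:
        return yaml.safe_load(fh)


_REGISTRY: dict[str, PeptideSequence] | None = None


def _registry() -> dict[str, PeptideSequence]:
    global _REGISTRY
    if _REGISTRY is None:
        seqs = read_fasta(_data_path("builtins.fasta"))
        _REGISTRY = {s.id: s for s in seqs}
    return _REGISTRY


def get_builtin(name: str) -> PeptideSequence:
    """Return a registry sequence by name (``R112C_E3``, ``R112C_E4``, ``RP1``..``RP7``)."""
    reg = _registry()
    if name not in reg:
        raise KeyError(
            f"unknown built-in {name!r}; valid keys: {', '.join(BUILTIN_NAMES)}"
        )
    return reg[name]


def repeats() -> list[PeptideSequence]:
    """The seven LDL-A repeats RP1..RP7, in order."""
    return [get_builtin(f"RP{i}") for i in range(1, 8)]


def derive_builtins() -> dict[str, PeptideSequence]:
    """Re-derive the registry from reference sequences and config windows.

    The ApoE4 R112C domain is the E3 window with the single C112R
    substitution; each LDL-A repeat is a window of the LDLR ectodomain
    fragment with its six conserved cysteines marked disulfide-bonded.
    Used by the test suite to prove the shipped registry is regenerable.
    """
    cfg = load_config()
    refs = {s.id: s for s in read_fasta(_data_path("reference.fasta"))}
    apoe = refs["APOE3_MATURE"]
    ldlr = refs["LDLR_MATURE_N"]
    out: dict[str, PeptideSequence] = {}

    w = cfg["r112c_window"]
    e3 = extract_subsequence(apoe, w["start"], w["end"], new_id="R112C_E3")
    out["R112C_E3"] = e3
    i112 = 112 - e3.numbering_offset
    out["R112C_E4"] = replace(
        e3, id="R112C_E4",
        residues=e3.residues[:i112] + "R" + e3.residues[i112 + 1:],
    )

    for name, w in cfg["repeat_windows"].items():
        rp = extract_subsequence(ldlr, w["start"], w["end"], new_id=name)
        cys = frozenset(
            rp.numbering_offset + i
            for i, aa in enumerate(rp.residues) if aa == "C"
        )
        out[name] = replace(rp, disulfide_cys=cys)
    return out
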