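"""Sequence-level metrics: glycosylation sequons, alignment conservation,
and pairwise identity.

The Ig1 isoform repertoire carries a constant N-glycosylation sequon
(N-X-S/T, X ≠ P) on the F strand, which blocks the CFG face and steers
homodimerization to the variable ABED face — so sequon scanning and
per-column conservation of an isoform alignment are first-class analyses
here rather than generic utilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

_AA20 = set("ACDEFGHIKLMNPQRSTVWY")
_GAP = "-"


def scan_sequons(
    sequence: str, exclude_proline: bool = True
) -> list[int]:
    """1-based positions of N-glycosylation sequons N-X-S/T in ``sequence``.

    ``X`` may be any residue except proline (standard sequon biology);
    ``exclude_proline=False`` disables that rule. ``X`` characters and gaps
    in the sequence are tolerated but never match N/S/T.
    """
    seq = sequence.upper()
    bad = sorted(set(seq) - _AA20 - {"X", _GAP})
    if bad:
        raise ValueError(f"non-protein characters in sequence: {bad}")
    hits = []
    for i in range(len(seq) - 2):
        if seq[i] != "N":
            continue
        if exclude_proline and seq[i + 1] == "P":
            continue
        if seq[i + 2] in ("S", "T"):
            hits.append(i + 1)
    return hits


@dataclass
class MSAProfile:
    """Aligned sequences with per-column composition and annotations."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)
    #: per-column annotation: "inner", "outer", or "" (unannotated); used to
    #: contrast the buried alignment positions with the solvent-facing ones
    column_annotations: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.sequences) < 2:
            raise ValueError("an alignment needs at least 2 sequences")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) != 1:
            raise ValueError("aligned sequences must have equal length")
        self.sequences = [s.upper() for s in self.sequences]
        if not self.ids:
            self.ids = [f"seq{i+1}" for i in range(len(self.sequences))]
        if not self.column_annotations:
            self.column_annotations = [""] * self.width

    @property
    def width(self) -> int:
        return len(self.sequences[0])

    def column(self, i: int) -> str:
        return "".join(s[i] for s in self.sequences)

    def frequencies(self, i: int) -> dict[str, float]:
        """Residue + gap frequencies of column ``i`` (sum to 1)."""
        col = self.column(i)
        n = len(col)
        out: dict[str, float] = {}
        for c in col:
            out[c] = out.get(c, 0.0) + 1.0 / n
        return out


def read_fasta_alignment(path: str | Path) -> MSAProfile:
    """Load an aligned FASTA file into an :class:`MSAProfile`."""
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if current:
                seqs.append("".join(current))
                current = []
            ids.append(line[1:].split()[0])
        else:
            current.append(line)
    if current:
        seqs.append("".join(current))
    return MSAProfile(seqs, ids)


def column_information_content(
    profile: MSAProfile, gap_flag_fraction: float = 0.5
) -> tuple[np.ndarray, np.ndarray]:
    """Per-column information content in bits, sequence-logo style.

    IC_i = log2(20) − H_i, with H_i the Shannon entropy of the non-gap
    residue frequencies of column i. Columns whose gap fraction exceeds
    ``gap_flag_fraction`` (or that are all-gap, where IC is undefined and
    reported as NaN) are flagged in the returned boolean array.
    """
    ic = np.zeros(profile.width)
    flagged = np.zeros(profile.width, dtype=bool)
    for i in range(profile.width):
        col = [c for c in profile.column(i) if c != _GAP]
        gap_frac = 1.0 - len(col) / len(profile.sequences)
        if not col:
            ic[i] = np.nan
            flagged[i] = True
            continue
        if gap_frac > gap_flag_fraction:
            flagged[i] = True
        _, counts = np.unique(np.array(col), return_counts=True)
        p = counts / counts.sum()
        entropy = float(-(p * np.log2(p)).sum())
        ic[i] = np.log2(20.0) - entropy
    return ic, flagged


def mean_ic_by_annotation(profile: MSAProfile) -> dict[str, float]:
    """Mean information content per column-annotation group.

    For an Ig-domain isoform alignment the expected pattern is low mean IC
    for the outer-facing (interface-forming, variable) columns and high
    mean IC for the inner-facing (core, conserved) columns.
    """
    ic, _ = column_information_content(profile)
    out: dict[str, list[float]] = {}
    for value, ann in zip(ic, profile.column_annotations):
        label = ann or "unannotated"
        if np.isfinite(value):
            out.setdefault(label, []).append(float(value))
    return {k: float(np.mean(v)) for k, v in out.items()}


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Percent identity between two aligned sequences.

    A position counts toward the denominator when at most one member is a
    gap; it counts as identical when both residues match and neither is a
    gap. Positions where both are gaps are ignored.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("aligned sequences must have equal length")
    a, b = seq_a.upper(), seq_b.upper()
    denom = ident = 0
    for x, y in zip(a, b):
        if x == _GAP and y == _GAP:
            continue
        denom += 1
        if x == y and x != _GAP:
            ident += 1
    if denom == 0:
        raise ValueError("no aligned positions")
    return 100.0 * ident / denom
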