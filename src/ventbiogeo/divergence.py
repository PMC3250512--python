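"""Tamura-Nei (TN93) pairwise distances, gap coding, and rate-based dating.

Distances are computed after pairwise deletion of alignment columns
containing a gap or ambiguity in either sequence; alignment gaps can
separately be recoded as binary indel characters appended to the matrix
(simple indel coding, one character per distinct gap extent).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log

import numpy as np

__all__ = [
    "AlignedSeqSet",
    "IndelCharacterBlock",
    "PairwiseDistance",
    "DivergenceEstimate",
    "SaturatedPairError",
    "read_fasta",
    "write_fasta",
    "gap_code",
    "append_gap_characters",
    "tamura_nei",
    "pairwise_distances",
    "tn93_from_proportions",
    "date_divergence",
    "RATE_PRESETS",
]

_IUPAC = set("ACGTURYSWKMBDHVN-")
_PURINES = {"A", "G"}
_PYRIMIDINES = {"C", "T"}

# Published crustacean mitochondrial substitution-rate presets (% per My)
RATE_PRESETS: dict[str, float] = {
    "anomuran_16s": 0.53,
    "jamaican_crab": 0.65,
    "fiddler_crab": 0.90,
    "barnacle": 0.67,
}


class SaturatedPairError(ValueError):
    """Distance undefined: a logarithm argument fell to zero or below."""


@dataclass
class AlignedSeqSet:
    """Equal-length nucleotide rows keyed by unique ids."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate sequence ids")
        if not self.rows or not self.rows[0]:
            raise ValueError("alignment is empty")
        length = len(self.rows[0])
        self.rows = [r.upper() for r in self.rows]
        for sid, row in zip(self.ids, self.rows):
            if len(row) != length:
                raise ValueError(f"sequence {sid!r} has length {len(row)} != {length}")
            bad = set(row) - _IUPAC
            if bad:
                raise ValueError(f"sequence {sid!r} has invalid symbols {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def pair(self, id_a: str, id_b: str) -> tuple[str, str]:
        return self.rows[self.ids.index(id_a)], self.rows[self.ids.index(id_b)]


def read_fasta(path) -> AlignedSeqSet:
    ids: list[str] = []
    rows: list[str] = []
    current: list[str] | None = None
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                ids.append(line[1:].split()[0])
                current = []
                rows.append(current)  # type: ignore[arg-type]
            elif current is None:
                raise ValueError(f"{path}: sequence data before first header")
            else:
                current.append(line)
    if not ids:
        raise ValueError(f"{path}: no sequences found")
    return AlignedSeqSet(ids=ids, rows=["".join(r) for r in rows])


def write_fasta(seqs: AlignedSeqSet, path, width: int = 70) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sid, row in zip(seqs.ids, seqs.rows):
            fh.write(f">{sid}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Gap coding


@dataclass
class IndelCharacterBlock:
    """Binary indel characters, one per distinct maximal gap extent.

    ``extents`` are half-open column ranges (start, end) ordered by
    (start, end); ``scores[i, k] == 1`` iff sequence i has a gap exactly
    spanning extent k.
    """

    ids: list[str]
    extents: list[tuple[int, int]]
    scores: np.ndarray


def _gap_extents(row: str) -> list[tuple[int, int]]:
    extents = []
    start = None
    for i, c in enumerate(row):
        if c == "-" and start is None:
            start = i
        elif c != "-" and start is not None:
            extents.append((start, i))
            start = None
    if start is not None:
        extents.append((start, len(row)))
    return extents


def gap_code(alignment: AlignedSeqSet) -> IndelCharacterBlock:
    """Simple indel coding: each distinct maximal gap extent becomes a character."""
    per_seq = [set(_gap_extents(r)) for r in alignment.rows]
    extents = sorted(set().union(*per_seq)) if per_seq else []
    scores = np.zeros((len(alignment.ids), len(extents)), dtype=int)
    for i, seen in enumerate(per_seq):
        for k, ext in enumerate(extents):
            if ext in seen:
                scores[i, k] = 1
    return IndelCharacterBlock(ids=list(alignment.ids), extents=extents, scores=scores)


def append_gap_characters(alignment: AlignedSeqSet) -> AlignedSeqSet:
    """Return the alignment with 0/1 indel characters appended to each row."""
    block = gap_code(alignment)
    rows = [
        row + "".join(str(v) for v in block.scores[i])
        for i, row in enumerate(alignment.rows)
    ]
    out = AlignedSeqSet.__new__(AlignedSeqSet)  # rows now contain 0/1 symbols
    out.ids = list(alignment.ids)
    out.rows = rows
    return out


# ---------------------------------------------------------------------------
# Tamura-Nei distance


@dataclass
class PairwiseDistance:
    value: float  # substitutions per site
    p1: float  # purine-transition proportion
    p2: float  # pyrimidine-transition proportion
    q: float  # transversion proportion
    freqs: dict[str, float]  # base frequencies pooled over the pair
    n_sites: int

    @property
    def percent(self) -> float:
        return 100.0 * self.value


def tn93_from_proportions(
    p1: float, p2: float, q: float, freqs: dict[str, float], n_sites: int = 0
) -> PairwiseDistance:
    """Evaluate the TN93 closed form from observed proportions and frequencies."""
    gA, gC, gG, gT = (freqs[b] for b in "ACGT")
    if abs(gA + gC + gG + gT - 1.0) > 1e-9:
        raise ValueError("base frequencies must sum to 1")
    gR, gY = gA + gG, gC + gT
    for base, g in zip("ACGT", (gA, gC, gG, gT)):
        needed = p1 if base in "AG" else p2
        if g == 0.0 and needed > 0:
            raise ValueError(
                f"zero frequency for {base} with nonzero transition proportion"
            )
    k1 = 2.0 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2.0 * gT * gC / gY if gY > 0 else 0.0
    arg1 = 1.0 - (gR * p1 / (2.0 * gA * gG) if gA * gG > 0 else 0.0) - q / (2.0 * gR)
    arg2 = 1.0 - (gY * p2 / (2.0 * gT * gC) if gT * gC > 0 else 0.0) - q / (2.0 * gY)
    arg3 = 1.0 - q / (2.0 * gR * gY)
    if min(arg1, arg2, arg3) <= 0.0:
        raise SaturatedPairError(
            f"saturated pair: log arguments ({arg1:.4g}, {arg2:.4g}, {arg3:.4g})"
        )
    d = (
        -k1 * log(arg1)
        - k2 * log(arg2)
        - 2.0
        * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
           - (gT * gC * gR / gY if gY > 0 else 0.0))
        * log(arg3)
    )
    return PairwiseDistance(
        value=max(d, 0.0),
        p1=p1,
        p2=p2,
        q=q,
        freqs={"A": gA, "C": gC, "G": gG, "T": gT},
        n_sites=n_sites,
    )


def tamura_nei(seq_a: str, seq_b: str) -> PairwiseDistance:
    """TN93 distance for an aligned pair with pairwise deletion.

    Columns with a gap or any non-ACGT symbol in either sequence are
    dropped; base frequencies are pooled over both remaining sequences.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences differ in length")
    pairs = [
        (x, y)
        for x, y in zip(seq_a.upper(), seq_b.upper())
        if x in "ACGT" and y in "ACGT"
    ]
    n = len(pairs)
    if n == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    counts = {b: 0 for b in "ACGT"}
    n_p1 = n_p2 = n_q = 0
    for x, y in pairs:
        counts[x] += 1
        counts[y] += 1
        if x != y:
            if {x, y} <= _PURINES:
                n_p1 += 1
            elif {x, y} <= _PYRIMIDINES:
                n_p2 += 1
            else:
                n_q += 1
    freqs = {b: counts[b] / (2 * n) for b in "ACGT"}
    return tn93_from_proportions(n_p1 / n, n_p2 / n, n_q / n, freqs, n_sites=n)


def pairwise_distances(seqs: AlignedSeqSet) -> list[tuple[str, str, PairwiseDistance | None]]:
    """All pairwise TN93 distances; saturated pairs yield None, not an error."""
    out = []
    for i in range(len(seqs.ids)):
        for j in range(i + 1, len(seqs.ids)):
            try:
                d = tamura_nei(seqs.rows[i], seqs.rows[j])
            except SaturatedPairError:
                d = None
            out.append((seqs.ids[i], seqs.ids[j], d))
    return out


# ---------------------------------------------------------------------------
# Rate-based dating


@dataclass
class DivergenceEstimate:
    distance_percent: float
    rate_percent_per_my: float
    time_my: float

    @property
    def time_my_rounded(self) -> float:
        return round(self.time_my, 1)


def date_divergence(
    distance_percent: float, rate_percent_per_my: float
) -> DivergenceEstimate:
    """Divergence time in My: percent distance over percent-per-My rate."""
    if rate_percent_per_my <= 0:
        raise ValueError("rate must be positive")
    if distance_percent < 0:
        raise ValueError("distance must be nonnegative")
    return DivergenceEstimate(
        distance_percent=distance_percent,
        rate_percent_per_my=rate_percent_per_my,
        time_my=distance_percent / rate_percent_per_my,
    )
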