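"""Nucleotide composition: pooled content, positional occupancy, P/P richness.

Positional matrices are 1-based and can be anchored at either end: position
p from the 5' end is the p-th base of the sequence, position p from the 3'
end is the p-th base counting backwards.  Sequences shorter than p simply
do not contribute at p, so per-position coverage is non-increasing.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import pandas as pd

from mirchar._util import PURINES, PYRIMIDINES, round_half_away
from mirchar.library import MirnaLibrary, MirnaRecord

BASES = ("A", "C", "G", "U")


class Anchor(str, Enum):
    FIVE_PRIME = "five_prime"
    THREE_PRIME = "three_prime"


@dataclass
class CompositionProfile:
    counts: dict[str, int]
    n_nucleotides: int

    @property
    def fractions(self) -> dict[str, float]:
        return {b: self.counts.get(b, 0) / self.n_nucleotides for b in BASES}

    @property
    def rounded_percentages(self) -> dict[str, int]:
        return {b: int(round_half_away(100.0 * f)) for b, f in self.fractions.items()}


@dataclass
class PositionalFrequencyMatrix:
    anchor: Anchor
    counts: pd.DataFrame  # index: 1-based position, columns: A,C,G,U

    @property
    def n_covering(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def fractions(self) -> pd.DataFrame:
        return self.counts.div(self.n_covering, axis=0)


@dataclass
class PPClassification:
    id: str
    purine_fraction: float
    pyrimidine_fraction: float
    call: str  # purine_rich | pyrimidine_rich | neither
    highly_rich: bool
    threshold: float

    @property
    def purine_pct(self) -> int:
        return int(round_half_away(100.0 * self.purine_fraction))

    @property
    def pyrimidine_pct(self) -> int:
        return int(round_half_away(100.0 * self.pyrimidine_fraction))

    @property
    def reported_pct(self) -> int:
        """The printed percentage: that of the dominant base class."""
        if self.purine_fraction >= self.pyrimidine_fraction:
            return self.purine_pct
        return self.pyrimidine_pct


def base_content(library: MirnaLibrary) -> CompositionProfile:
    """Pooled base counts over every nucleotide of every sequence."""
    if not library.records:
        raise ValueError("base content undefined for an empty library")
    counts = Counter()
    for rec in library.records:
        counts.update(rec.sequence)
    total = sum(counts.values())
    return CompositionProfile(counts={b: counts.get(b, 0) for b in BASES}, n_nucleotides=total)


def positional_frequency(
    library: MirnaLibrary, anchor: Anchor | str = Anchor.FIVE_PRIME
) -> PositionalFrequencyMatrix:
    """Per-position base counts, anchored at the 5' or 3' end."""
    anchor = Anchor(anchor)
    if not library.records:
        raise ValueError("positional frequencies undefined for an empty library")
    max_len = max(r.length for r in library.records)
    counts = pd.DataFrame(0, index=range(1, max_len + 1), columns=list(BASES))
    for rec in library.records:
        seq = rec.sequence if anchor is Anchor.FIVE_PRIME else rec.sequence[::-1]
        for pos, base in enumerate(seq, start=1):
            counts.at[pos, base] += 1
    counts.index.name = "position"
    return PositionalFrequencyMatrix(anchor=anchor, counts=counts)


def terminal_bases(library: MirnaLibrary) -> pd.DataFrame:
    """Counts of each base at the first (5') and last (3') position.

    Tidy frame with columns base, end ("five_prime"/"three_prime"), length
    (sequence-length stratum) and count; strata are the observed lengths.
    Sum over lengths for the overall census.
    """
    if not library.records:
        raise ValueError("terminal bases undefined for an empty library")
    tallies: Counter = Counter()
    for rec in library.records:
        tallies[(rec.sequence[0], "five_prime", rec.length)] += 1
        tallies[(rec.sequence[-1], "three_prime", rec.length)] += 1
    rows = [
        {"base": b, "end": e, "length": ln, "count": c}
        for (b, e, ln), c in sorted(tallies.items())
    ]
    return pd.DataFrame(rows, columns=["base", "end", "length", "count"])


def classify_pp(
    record: MirnaRecord,
    threshold: float = 0.70,
    highly_rich_threshold: float = 0.90,
) -> PPClassification:
    """Purine/pyrimidine-richness call for one sequence.

    A sequence is purine-rich when its A+G fraction strictly exceeds
    ``threshold`` (default 0.70), pyrimidine-rich symmetrically for C+U;
    ``highly_rich`` flags the dominant fraction reaching
    ``highly_rich_threshold`` (>= 0.90, the table-report band).
    """
    n = record.length
    pur = sum(1 for b in record.sequence if b in PURINES) / n
    pyr = sum(1 for b in record.sequence if b in PYRIMIDINES) / n
    if pur > threshold:
        call = "purine_rich"
    elif pyr > threshold:
        call = "pyrimidine_rich"
    else:
        call = "neither"
    highly = max(pur, pyr) >= highly_rich_threshold
    return PPClassification(
        id=record.id,
        purine_fraction=pur,
        pyrimidine_fraction=pyr,
        call=call,
        highly_rich=highly,
        threshold=threshold,
    )


def classify_pp_library(
    library: MirnaLibrary,
    threshold: float = 0.70,
    highly_rich_threshold: float = 0.90,
) -> pd.DataFrame:
    rows = []
    for rec in library.records:
        c = classify_pp(rec, threshold, highly_rich_threshold)
        rows.append(
            {
                "id": c.id,
                "sequence": rec.sequence,
                "purine_pct": c.purine_pct,
                "pyrimidine_pct": c.pyrimidine_pct,
                "call": c.call,
                "highly_rich": c.highly_rich,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "sequence", "purine_pct", "pyrimidine_pct", "call", "highly_rich"]
    )


def write_composition_tsv(profile: CompositionProfile, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("base\tcount\tfraction\n")
        for b in BASES:
            out.write(f"{b}\t{profile.counts.get(b, 0)}\t{profile.fractions[b]:.6f}\n")


def write_pfm_tsv(pfm: PositionalFrequencyMatrix, path: str | Path) -> None:
    pfm.counts.to_csv(path, sep="\t")
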