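"""Simple-sequence-repeat (microsatellite) detection in short RNA sequences.

A valid SSR tract is at least ``min_repeats`` (default 3) complete copies
of a primitive unit of 1-5 nt, maximal in complete units: no additional
full unit immediately before or after, and a trailing partial unit never
extends the tract ("GUGUGUG" is (GU)3, the final G excluded).  Each unit
length is censused independently — a mononucleotide run and a dinucleotide
tract may overlap — but within one unit length scanning is leftmost-greedy
and non-overlapping.  The library-level relative count is tracts per miRNA
on average: total tracts divided by library size.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

from mirchar._util import RNA_ALPHABET, format_relative
from mirchar.library import MirnaLibrary, MirnaRecord


def is_primitive(unit: str) -> bool:
    """True if the unit is not itself a repetition of a shorter string."""
    n = len(unit)
    for d in range(1, n):
        if n % d == 0 and unit[:d] * (n // d) == unit:
            return False
    return True


def canonical_class(unit: str) -> str:
    """Grouping label for report rows.

    Dinucleotides group as unordered pairs ("GU/UG"); other unit lengths
    use the lexicographically smallest rotation.
    """
    if len(unit) == 2:
        a, b = sorted(unit)
        return f"{a}{b}/{b}{a}"
    rotations = [unit[i:] + unit[:i] for i in range(len(unit))]
    return min(rotations)


@dataclass(frozen=True)
class SSRRecord:
    """One maximal SSR tract; coordinates 1-based inclusive."""

    id: str
    unit: str
    repeat_count: int
    start: int
    end: int

    @property
    def unit_length(self) -> int:
        return len(self.unit)

    @property
    def tract_length(self) -> int:
        return self.unit_length * self.repeat_count

    @property
    def canonical_class(self) -> str:
        return canonical_class(self.unit)


@dataclass
class SSRSummary:
    totals: dict[int, int]  # unit_length -> tract count
    class_totals: dict[str, int]  # canonical class -> tract count
    n_mirnas: int

    @property
    def grand_total(self) -> int:
        return sum(self.totals.values())

    @property
    def relative_counts(self) -> dict[int, float]:
        return {k: v / self.n_mirnas for k, v in self.totals.items()}

    @property
    def grand_relative(self) -> float:
        return self.grand_total / self.n_mirnas

    def formatted_relative(self, unit_length: int) -> str:
        return format_relative(self.totals.get(unit_length, 0), self.n_mirnas)


def find_ssrs(
    record: MirnaRecord, min_repeats: int = 3, max_unit: int = 5
) -> list[SSRRecord]:
    """All maximal primitive-unit SSR tracts, sorted by (unit_length, start).

    Minimum three complete repeats by default, so mono tracts need runs of
    >= 3 nt, di >= 6 nt, ..., penta >= 15 nt.
    """
    if min_repeats < 2:
        raise ValueError("min_repeats must be >= 2")
    if not 1 <= max_unit <= 5:
        raise ValueError("max_unit must be in 1..5")
    seq = record.sequence
    n = len(seq)
    tracts: list[SSRRecord] = []
    for k in range(1, max_unit + 1):
        i = 0
        while i + k * min_repeats <= n:
            unit = seq[i : i + k]
            if not is_primitive(unit):
                i += 1
                continue
            m = 1
            while seq[i + k * m : i + k * (m + 1)] == unit:
                m += 1
            if m >= min_repeats:
                tracts.append(
                    SSRRecord(
                        id=record.id,
                        unit=unit,
                        repeat_count=m,
                        start=i + 1,
                        end=i + k * m,
                    )
                )
                i += k * m  # leftmost-greedy, non-overlapping within a unit length
            else:
                i += 1
    tracts.sort(key=lambda t: (t.unit_length, t.start))
    return tracts


def ssr_summary(library: MirnaLibrary, min_repeats: int = 3, max_unit: int = 5) -> SSRSummary:
    """Library-level tract totals and per-miRNA relative counts."""
    if not library.records:
        raise ValueError("SSR summary undefined for an empty library")
    totals: Counter = Counter()
    class_totals: Counter = Counter()
    for rec in library.records:
        for tract in find_ssrs(rec, min_repeats=min_repeats, max_unit=max_unit):
            totals[tract.unit_length] += 1
            class_totals[tract.canonical_class] += 1
    return SSRSummary(
        totals={k: totals.get(k, 0) for k in range(1, max_unit + 1)},
        class_totals=dict(class_totals),
        n_mirnas=len(library),
    )


def longest_mono_run(library: MirnaLibrary, base: str) -> tuple[int, list[str]]:
    """Longest run of a single base over the library, with the ids achieving it.

    Runs of any length count (not only >= min_repeats), so the maximum is
    well-defined even on libraries with no qualifying SSR.
    """
    if base not in RNA_ALPHABET:
        raise ValueError(f"base must be one of A,C,G,U, got {base!r}")
    if not library.records:
        raise ValueError("longest run undefined for an empty library")
    best = 0
    ids: list[str] = []
    for rec in library.records:
        run = 0
        rec_best = 0
        for ch in rec.sequence:
            run = run + 1 if ch == base else 0
            rec_best = max(rec_best, run)
        if rec_best > best:
            best, ids = rec_best, [rec.id]
        elif rec_best == best and best > 0:
            ids.append(rec.id)
    return best, ids


def write_tracts_tsv(tracts: list[SSRRecord], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("id\tunit\tclass\tunit_length\trepeat_count\tstart\tend\n")
        for t in tracts:
            out.write(
                f"{t.id}\t{t.unit}\t{t.canonical_class}\t{t.unit_length}\t"
                f"{t.repeat_count}\t{t.start}\t{t.end}\n"
            )


def write_summary_tsv(summary: SSRSummary, path: str | Path) -> None:
    """Unit-length totals with relative counts in parentheses, then class rows."""
    names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta"}
    with open(path, "w") as out:
        out.write("row\tvalue\n")
        for k in sorted(summary.totals):
            out.write(
                f"{names.get(k, k)}\t{summary.totals[k]} ({summary.formatted_relative(k)})\n"
            )
        out.write(
            f"total\t{summary.grand_total} "
            f"({format_relative(summary.grand_total, summary.n_mirnas)})\n"
        )
        for cls in sorted(summary.class_totals):
            out.write(
                f"class:{cls}\t{summary.class_totals[cls]} "
                f"({format_relative(summary.class_totals[cls], summary.n_mirnas)})\n"
            )
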