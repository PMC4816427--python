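"""Hairpin (stem-loop) enumeration and tetraloop classification.

Mature miRNAs, although canonically single-stranded, are short enough
(16-27 nt) to fold back on themselves.  The enumerator considers every
loop placement within a configurable size range and grows a contiguous
stem outward from the closing pair while bases pair (Watson-Crick A:U and
G:C plus, by default, the G:U wobble).  Stems have no bulges or internal
loops — with molecules this short, contiguous pairing keeps the enumerator
exactly checkable against brute force; this deliberately diverges from
thermodynamic folders.

The tetraloop filter cascade mirrors the report layout: (1) loop is one of
the configured stable tetraloop motifs, (2) additionally the stem has at
least 3 base pairs, (3) additionally the closing pair (innermost, adjacent
to the loop) is C-G.

``stability_score`` is a simple stacked-pair surrogate (GC=3, AU=2, GU=1,
minus 0.5 per loop nucleotide beyond 3).  It is NOT a free energy in
kcal/mol; it only orders hairpins by rough stability.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from mirchar.library import MirnaLibrary, MirnaRecord

# The eight stable tetraloop motifs singled out in the loop census, plus
# UUUU which the cascade table tabulates alongside them.
DEFAULT_TETRALOOP_SET = frozenset(
    {"UUCG", "GAAA", "GCAA", "GAGA", "GUGA", "GGAA", "CUUG", "UUUG", "UUUU"}
)

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def can_pair(a: str, b: str, allow_wobble: bool = True) -> bool:
    return (a, b) in _WC or (allow_wobble and (a, b) in _WOBBLE)


_PAIR_WEIGHT = {frozenset("GC"): 3.0, frozenset("AU"): 2.0, frozenset("GU"): 1.0}


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop: nested contiguous pairs enclosing an unpaired loop.

    ``pairs`` is outermost first; positions are 1-based.  The closing pair
    is the innermost pair, adjacent to the loop.
    """

    id: str
    pairs: tuple[tuple[int, int], ...]
    loop_start: int
    loop_end: int
    loop_seq: str

    @property
    def stem_length(self) -> int:
        return len(self.pairs)

    @property
    def loop_length(self) -> int:
        return self.loop_end - self.loop_start + 1

    @property
    def closing_pair_positions(self) -> tuple[int, int]:
        return self.pairs[-1]


def closing_pair_bases(hairpin: Hairpin, sequence: str) -> tuple[str, str]:
    i, j = hairpin.closing_pair_positions
    return sequence[i - 1], sequence[j - 1]


@dataclass(frozen=True)
class TetraloopRecord:
    hairpin: Hairpin
    loop_in_motif_set: bool
    stem_ge_3: bool
    closing_pair_cg: bool


def enumerate_hairpins(
    record: MirnaRecord,
    min_stem: int = 3,
    loop_min: int = 3,
    loop_max: int = 8,
    allow_wobble: bool = True,
) -> list[Hairpin]:
    """All maximal-stem hairpins, one per viable loop placement.

    For each loop window the stem grows outward from the closing pair as
    far as bases pair; the result is kept when the (maximal) stem reaches
    ``min_stem``.  Sorted by (stem_length desc, loop_length asc,
    loop_start asc).  Dangling ends are unconstrained.
    """
    if not 3 <= loop_min <= loop_max:
        raise ValueError("need 3 <= loop_min <= loop_max")
    if min_stem < 1:
        raise ValueError("min_stem must be >= 1")
    seq = record.sequence
    n = len(seq)
    found: list[Hairpin] = []
    for loop_len in range(loop_min, loop_max + 1):
        for ls in range(1, n - loop_len + 2):  # 1-based loop start
            le = ls + loop_len - 1
            # grow stem outward from the closing pair (ls-1, le+1)
            k = 0
            while (
                ls - k - 1 >= 1
                and le + k + 1 <= n
                and can_pair(seq[ls - k - 2], seq[le + k], allow_wobble)
            ):
                k += 1
            if k >= min_stem:
                pairs = tuple(
                    (ls - k + d, le + k - d) for d in range(k)
                )  # outermost first
                found.append(
                    Hairpin(
                        id=record.id,
                        pairs=pairs,
                        loop_start=ls,
                        loop_end=le,
                        loop_seq=seq[ls - 1 : le],
                    )
                )
    found.sort(key=lambda h: (-h.stem_length, h.loop_length, h.loop_start))
    return found


def best_hairpin(
    record: MirnaRecord,
    min_stem: int = 3,
    loop_min: int = 3,
    loop_max: int = 8,
    allow_wobble: bool = True,
) -> Hairpin | None:
    """The top-ranked hairpin (longest stem, then smallest/leftmost loop)."""
    hairpins = enumerate_hairpins(record, min_stem, loop_min, loop_max, allow_wobble)
    return hairpins[0] if hairpins else None


def classify_tetraloop(
    hairpin: Hairpin,
    sequence: str,
    motif_set: Iterable[str] = DEFAULT_TETRALOOP_SET,
    strict_orientation: bool = False,
    min_stem: int = 3,
) -> TetraloopRecord:
    """Flags for the three-stage tetraloop filter cascade.

    ``strict_orientation`` requires the closing pair to read 5'-C, 3'-G;
    the default accepts the unordered pair {C, G}.
    """
    motif_set = set(motif_set)
    loop_ok = hairpin.loop_length == 4 and hairpin.loop_seq in motif_set
    stem_ok = hairpin.stem_length >= min_stem
    a, b = closing_pair_bases(hairpin, sequence)
    if strict_orientation:
        cg_ok = (a, b) == ("C", "G")
    else:
        cg_ok = {a, b} == {"C", "G"}
    return TetraloopRecord(
        hairpin=hairpin,
        loop_in_motif_set=loop_ok,
        stem_ge_3=stem_ok,
        closing_pair_cg=cg_ok,
    )


def stability_score(hairpin: Hairpin, sequence: str) -> float:
    """Stacked-pair surrogate score; higher = more stable.  Not kcal/mol."""
    total = 0.0
    for i, j in hairpin.pairs:
        total += _PAIR_WEIGHT[frozenset((sequence[i - 1], sequence[j - 1]))]
    return total - 0.5 * (hairpin.loop_length - 3)


def dot_bracket(hairpin: Hairpin | None, sequence: str) -> str:
    """Dot-bracket string for one hairpin over the full sequence."""
    marks = ["."] * len(sequence)
    if hairpin is not None:
        for i, j in hairpin.pairs:
            marks[i - 1] = "("
            marks[j - 1] = ")"
    return "".join(marks)


def tetraloop_cascade(
    library: MirnaLibrary,
    motif_set: Iterable[str] = DEFAULT_TETRALOOP_SET,
    min_stem: int = 3,
    loop_min: int = 3,
    loop_max: int = 8,
    allow_wobble: bool = True,
    strict_orientation: bool = False,
    count_mode: str = "best",
) -> dict[str, dict[str, int]]:
    """Per-motif counts across the three cascade stages.

    ``count_mode='best'`` counts each sequence once, by its best hairpin
    whose loop is a motif tetraloop (preferring hairpins that survive
    deeper stages); ``'all'`` counts every qualifying hairpin.  Stage keys:
    ``hairpin`` (motif loop), ``stem3`` (+ stem >= 3), ``stem3_cg``
    (+ C-G closing pair).  Counts are non-increasing across stages.
    """
    if count_mode not in ("best", "all"):
        raise ValueError("count_mode must be 'best' or 'all'")
    motif_set = set(motif_set)
    cascade = {m: {"hairpin": 0, "stem3": 0, "stem3_cg": 0} for m in sorted(motif_set)}
    # stage counting requires seeing sub-min_stem stems for stage 1, so
    # enumerate with min_stem=1 and apply the stem filter as a cascade stage
    for rec in library.records:
        hairpins = enumerate_hairpins(
            rec, min_stem=1, loop_min=loop_min, loop_max=loop_max, allow_wobble=allow_wobble
        )
        classified = [
            classify_tetraloop(h, rec.sequence, motif_set, strict_orientation, min_stem)
            for h in hairpins
            if h.loop_length == 4 and h.loop_seq in motif_set
        ]
        if not classified:
            continue
        if count_mode == "all":
            chosen = classified
        else:
            chosen = [
                max(
                    classified,
                    key=lambda c: (
                        c.stem_ge_3 and c.closing_pair_cg,
                        c.stem_ge_3,
                        c.hairpin.stem_length,
                    ),
                )
            ]
        for c in chosen:
            row = cascade[c.hairpin.loop_seq]
            row["hairpin"] += 1
            if c.stem_ge_3:
                row["stem3"] += 1
                if c.closing_pair_cg:
                    row["stem3_cg"] += 1
    return cascade


def write_hairpins_tsv(
    items: Sequence[tuple[MirnaRecord, Hairpin]], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write(
            "id\tstem_length\tloop_start\tloop_end\tloop_seq\tclosing_pair\tscore\tdot_bracket\n"
        )
        for rec, h in items:
            a, b = closing_pair_bases(h, rec.sequence)
            out.write(
                f"{rec.id}\t{h.stem_length}\t{h.loop_start}\t{h.loop_end}\t{h.loop_seq}\t"
                f"{a}{b}\t{stability_score(h, rec.sequence):.1f}\t{dot_bracket(h, rec.sequence)}\n"
            )


def write_cascade_tsv(cascade: dict[str, dict[str, int]], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("motif\thairpin_formation\tstem_ge_3\tstem_ge_3_and_cg_closing\n")
        totals = [0, 0, 0]
        for motif, row in cascade.items():
            out.write(f"{motif}\t{row['hairpin']}\t{row['stem3']}\t{row['stem3_cg']}\n")
            totals[0] += row["hairpin"]
            totals[1] += row["stem3"]
            totals[2] += row["stem3_cg"]
        out.write(f"Total\t{totals[0]}\t{totals[1]}\t{totals[2]}\n")
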