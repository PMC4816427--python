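"""Fixed-motif scanning and alternating-GU tract detection.

The motif of primary interest is the 5'-UGUGU-3' pentamer (interferon
induction motif, IIM): small RNAs carrying it can stimulate the innate
immune response.  GU-rich tracts — maximal runs of strictly alternating G
and U in either phase — are censused separately.  Only the given strand is
scanned: mature miRNAs are single-stranded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from mirchar._util import RNA_ALPHABET
from mirchar.library import MirnaLibrary, MirnaRecord


@dataclass(frozen=True)
class MotifHit:
    """One motif occurrence; coordinates are 1-based inclusive."""

    id: str
    motif: str
    start: int
    end: int
    overlapping: bool


@dataclass(frozen=True)
class GuTract:
    """A maximal strictly-alternating G/U run (either phase), 1-based."""

    id: str
    start: int
    end: int
    tract: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def scan_motif(
    record: MirnaRecord, motif: str, overlapping: bool = True
) -> list[MotifHit]:
    """All occurrences of an exact motif, in ascending start order.

    Overlapping mode (default) reports every occurrence; non-overlapping
    mode is leftmost-greedy, resuming after each hit.  Overlap matters
    here: UGUGU copies in GU-repeat regions overlap each other.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    bad = set(motif) - RNA_ALPHABET
    if bad:
        raise ValueError(f"motif {motif!r}: invalid characters {sorted(bad)}")
    seq, m = record.sequence, len(motif)
    hits: list[MotifHit] = []
    i = 0
    while i + m <= len(seq):
        if seq[i : i + m] == motif:
            hits.append(
                MotifHit(
                    id=record.id,
                    motif=motif,
                    start=i + 1,
                    end=i + m,
                    overlapping=overlapping,
                )
            )
            i += 1 if overlapping else m
        else:
            i += 1
    return hits


def find_iim(
    library: MirnaLibrary, motif: str = "UGUGU"
) -> list[tuple[MirnaRecord, list[MotifHit]]]:
    """Records carrying at least one occurrence of the motif, with their hits."""
    out = []
    for rec in library.records:
        hits = scan_motif(rec, motif, overlapping=True)
        if hits:
            out.append((rec, hits))
    return out


def gu_tracts(record: MirnaRecord, min_length: int = 5) -> list[GuTract]:
    """Maximal alternating-G/U tracts of length >= ``min_length``.

    A tract contains only G and U, never two equal adjacent characters,
    and cannot be extended in either direction while staying alternating
    (so reported tracts never overlap).
    """
    if min_length < 2:
        raise ValueError("min_length must be >= 2")
    seq = record.sequence
    tracts: list[GuTract] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] not in "GU":
            i += 1
            continue
        j = i
        while j + 1 < n and seq[j + 1] in "GU" and seq[j + 1] != seq[j]:
            j += 1
        if j - i + 1 >= min_length:
            tracts.append(GuTract(id=record.id, start=i + 1, end=j + 1, tract=seq[i : j + 1]))
        i = j + 1
    return tracts


def is_gu_rich(record: MirnaRecord, min_length: int = 5) -> bool:
    """GU-richness: presence of a maximal alternating G/U tract >= min_length.

    The weakest rule satisfied by every sequence in the published GU-rich
    list; no exclusive definition exists, so this is a necessary-condition
    classifier.
    """
    return bool(gu_tracts(record, min_length))


def write_motif_hits_tsv(hits: list[MotifHit], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("id\tmotif\tstart\tend\n")
        for h in hits:
            out.write(f"{h.id}\t{h.motif}\t{h.start}\t{h.end}\n")


def write_iim_census_tsv(
    census: list[tuple[MirnaRecord, list[MotifHit]]], path: str | Path
) -> None:
    with open(path, "w") as out:
        out.write("id\tsequence\tn_hits\n")
        for rec, hits in census:
            out.write(f"{rec.id}\t{rec.sequence}\t{len(hits)}\n")


def write_gu_tracts_tsv(tracts: list[GuTract], path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("id\tstart\tend\ttract\tlength\n")
        for t in tracts:
            out.write(f"{t.id}\t{t.start}\t{t.end}\t{t.tract}\t{t.length}\n")
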