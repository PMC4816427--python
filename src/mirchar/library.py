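"""Reading, normalizing and deduplicating mature-miRNA FASTA libraries.

A mature miRNA library (miRBase ``mature.fa`` dialect) routinely annotates
the same mature sequence under several names (paralogous loci, historic
renames).  All censuses here are over *unique sequences*, so deduplication
keeps one record per distinct sequence and remembers every name that
carried it.
"""

from __future__ import annotations

import gzip
import json
from collections import Counter, OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

from mirchar._util import normalize_sequence, round_half_away, validate_sequence


@dataclass(frozen=True)
class MirnaRecord:
    """One identified mature miRNA sequence over {A,C,G,U}."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        validate_sequence(self.sequence, self.id)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class MirnaLibrary:
    """An ordered collection of miRNA records plus dedup bookkeeping.

    ``alias_map`` maps each retained sequence to every id that carried it;
    it is populated by :func:`deduplicate` (singletons before that).
    """

    records: list[MirnaRecord]
    alias_map: dict[str, list[str]] = field(default_factory=dict)
    source: str = "unknown"

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def sequences(self) -> list[str]:
        return [r.sequence for r in self.records]


@dataclass
class LengthDistribution:
    counts: dict[int, int]
    n_total: int

    @property
    def percentages(self) -> dict[int, float]:
        """Unrounded percentages; sum to 100."""
        return {k: 100.0 * v / self.n_total for k, v in self.counts.items()}

    @property
    def rounded_percentages(self) -> dict[int, int]:
        """Integer percentages, half away from zero (report convention)."""
        return {k: int(round_half_away(p)) for k, p in self.percentages.items()}


def _make_record(ident: str, description: str, raw_seq: str) -> MirnaRecord:
    seq = normalize_sequence(raw_seq)
    validate_sequence(seq, ident)
    return MirnaRecord(id=ident, sequence=seq, description=description)


def _build_alias_map(records: Iterable[MirnaRecord]) -> dict[str, list[str]]:
    aliases: dict[str, list[str]] = {}
    for rec in records:
        aliases.setdefault(rec.sequence, []).append(rec.id)
    return aliases


def read_fasta(path: str | Path, species_prefix: str | None = None) -> MirnaLibrary:
    """Read a (possibly gzipped) mature-miRNA FASTA file.

    Sequences are normalized (T->U, uppercased); a record whose sequence
    contains anything outside {A,C,G,U,T} aborts the read with the
    offending id.  ``species_prefix`` filters on the first header token
    (miRBase human ids start ``hsa-``).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    records: list[MirnaRecord] = []
    with opener(path, "rt") as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if species_prefix is not None and not entry.id.startswith(species_prefix):
                continue
            desc = entry.description
            if desc.startswith(entry.id):
                desc = desc[len(entry.id) :].strip()
            records.append(_make_record(entry.id, desc, str(entry.seq)))
    return MirnaLibrary(
        records=records, alias_map=_build_alias_map(records), source=str(path)
    )


def library_from_pairs(
    pairs: Iterable[tuple[str, str]], source: str = "in-memory"
) -> MirnaLibrary:
    """Build a library from (id, sequence) pairs, normalizing as read_fasta does."""
    records = [_make_record(ident, "", seq) for ident, seq in pairs]
    return MirnaLibrary(
        records=records, alias_map=_build_alias_map(records), source=source
    )


def write_fasta(library: MirnaLibrary, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as out:
        for rec in library.records:
            header = f">{rec.id} {rec.description}".rstrip()
            out.write(f"{header}\n{rec.sequence}\n")


def deduplicate(library: MirnaLibrary) -> MirnaLibrary:
    """Collapse records with identical sequences, keeping the first-seen id.

    Idempotent; ``alias_map`` lists every id per retained sequence in file
    order.
    """
    kept: "OrderedDict[str, MirnaRecord]" = OrderedDict()
    aliases: dict[str, list[str]] = {}
    for rec in library.records:
        if rec.sequence not in kept:
            kept[rec.sequence] = rec
            aliases[rec.sequence] = []
        ids = aliases[rec.sequence]
        # merge ids already collapsed into this record by an earlier pass
        for ident in library.alias_map.get(rec.sequence, [rec.id]) or [rec.id]:
            if ident not in ids:
                ids.append(ident)
        if rec.id not in ids:
            ids.append(rec.id)
    return MirnaLibrary(
        records=list(kept.values()), alias_map=aliases, source=library.source
    )


def length_distribution(library: MirnaLibrary) -> LengthDistribution:
    if not library.records:
        raise ValueError("length distribution undefined for an empty library")
    counts = Counter(r.length for r in library.records)
    return LengthDistribution(counts=dict(sorted(counts.items())), n_total=len(library))


def library_summary(library: MirnaLibrary) -> Mapping[str, object]:
    """JSON-ready summary: record counts and the length histogram."""
    dist = length_distribution(library) if library.records else None
    return {
        "source": library.source,
        "n_records": len(library.records),
        "n_unique": len(set(library.sequences())),
        "length_histogram": dist.counts if dist else {},
    }


def write_summary_json(library: MirnaLibrary, path: str | Path) -> None:
    Path(path).write_text(json.dumps(library_summary(library), indent=2) + "\n")


def write_summary_tsv(library: MirnaLibrary, path: str | Path) -> None:
    with open(path, "w") as out:
        out.write("id\tsequence\tlength\n")
        for rec in library.records:
            out.write(f"{rec.id}\t{rec.sequence}\t{rec.length}\n")
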