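#!/usr/bin/env python
"""Build the working libraries and report their length structure.

Writes the three embedded reference tables as FASTA, generates the
2042-sequence synthetic stand-in for the full deduplicated human mature
miRNA library (seeded, so every later script sees the same library), and
tabulates the length distribution.
"""

from pathlib import Path

from mirchar.fixtures import write_fixture_tables
from mirchar.library import deduplicate, length_distribution, write_fasta
from mirchar.synthetic import SyntheticSpec, generate_library

RESULTS = Path(__file__).resolve().parent.parent / "results"
SYNTH_SEED = 19
SYNTH_N = 2042


def synthetic_library():
    """The shared synthetic full-scale library (deterministic)."""
    lib, _ = generate_library(SyntheticSpec(n_sequences=SYNTH_N, seed=SYNTH_SEED))
    return deduplicate(lib)


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    paths = write_fixture_tables(RESULTS / "fixtures")
    for name, path in paths.items():
        print(f"wrote reference set {name} -> {path}")

    lib = synthetic_library()
    write_fasta(lib, RESULTS / "synthetic_library.fasta")
    dist = length_distribution(lib)
    with open(RESULTS / "length_distribution.tsv", "w") as out:
        out.write("length\tcount\tpercent\n")
        for length, count in dist.counts.items():
            out.write(f"{length}\t{count}\t{dist.rounded_percentages[length]}\n")
    mode = max(dist.counts, key=dist.counts.get)
    print(
        f"synthetic library: {len(lib)} unique sequences, lengths "
        f"{min(dist.counts)}-{max(dist.counts)} nt, mode {mode} nt "
        f"({dist.rounded_percentages[mode]}%)"
    )


if __name__ == "__main__":
    main()
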