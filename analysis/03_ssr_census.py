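#!/usr/bin/env python
"""Simple-sequence-repeat census with per-miRNA relative counts.

Scans the synthetic full-scale library for SSR tracts (unit sizes 1-5,
minimum three complete repeats), writes the per-tract table and the
unit-length summary, and reports the longest mononucleotide runs.  Also
confirms the 18-nt poly(G) run in the purine-rich reference set.
"""

import importlib
from pathlib import Path

from mirchar.fixtures import table1_library
from mirchar.ssr import find_ssrs, longest_mono_run, ssr_summary, write_summary_tsv, write_tracts_tsv

build = importlib.import_module("01_build_library")
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lib = build.synthetic_library()
    tracts = [t for rec in lib.records for t in find_ssrs(rec)]
    write_tracts_tsv(tracts, RESULTS / "ssr_tracts.tsv")
    summary = ssr_summary(lib)
    write_summary_tsv(summary, RESULTS / "ssr_summary.tsv")
    names = {1: "mono", 2: "di", 3: "tri", 4: "tetra", 5: "penta"}
    print(f"SSR census over {summary.n_mirnas} sequences:")
    for k in sorted(summary.totals):
        print(
            f"  {names[k]:5s} {summary.totals[k]:5d} tracts "
            f"({summary.formatted_relative(k)} per miRNA)"
        )
    print(f"  total {summary.grand_total:5d} ({summary.grand_relative:.2f} per miRNA)")
    for base in "AUGC":
        length, ids = longest_mono_run(lib, base)
        print(f"longest poly({base}) run: {length} nt ({len(ids)} sequence(s))")

    length, ids = longest_mono_run(table1_library(), "G")
    print(f"\nreference set: longest poly(G) run {length} nt in {ids[0]}")


if __name__ == "__main__":
    main()
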