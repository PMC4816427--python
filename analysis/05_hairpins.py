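#!/usr/bin/env python
"""Hairpin folding propensity and the tetraloop filter cascade.

Enumerates stem-loops (>= 3 bp contiguous stem, loop 3-8 nt, wobble pairs
allowed) over the synthetic full-scale library, reports how many sequences
can fold, the loop-size breakdown of the best hairpins, and the
three-stage tetraloop cascade (motif loop / >= 3 bp stem / C-G closing
pair).
"""

import importlib
from collections import Counter
from pathlib import Path

from mirchar.hairpin import (
    best_hairpin,
    tetraloop_cascade,
    write_cascade_tsv,
    write_hairpins_tsv,
)

build = importlib.import_module("01_build_library")
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lib = build.synthetic_library()
    best = [
        (rec, h) for rec in lib.records if (h := best_hairpin(rec)) is not None
    ]
    write_hairpins_tsv(best, RESULTS / "hairpins_synthetic.tsv")
    frac = 100 * len(best) / len(lib)
    print(f"{len(best)}/{len(lib)} sequences ({frac:.0f}%) fold into a hairpin")
    loop_sizes = Counter(h.loop_length for _, h in best)
    print(
        "loop sizes of best hairpins: "
        + ", ".join(f"{k} nt: {loop_sizes[k]}" for k in sorted(loop_sizes))
    )

    cascade = tetraloop_cascade(lib)
    write_cascade_tsv(cascade, RESULTS / "tetraloop_cascade_synthetic.tsv")
    totals = {
        stage: sum(row[stage] for row in cascade.values())
        for stage in ("hairpin", "stem3", "stem3_cg")
    }
    print(
        f"tetraloop cascade: {totals['hairpin']} motif loops -> "
        f"{totals['stem3']} with >=3 bp stems -> {totals['stem3_cg']} with C-G "
        f"closing pairs"
    )


if __name__ == "__main__":
    main()
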