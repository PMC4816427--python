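#!/usr/bin/env python
"""Nucleotide composition and purine/pyrimidine richness.

Reports pooled base content and 5'/3'-anchored positional occupancy for
the synthetic full-scale library, and reproduces the purine/pyrimidine
percentages of the highly-rich reference set from its printed sequences.
"""

import importlib
from pathlib import Path

from mirchar.composition import (
    Anchor,
    base_content,
    classify_pp_library,
    positional_frequency,
    write_composition_tsv,
    write_pfm_tsv,
)
from mirchar.fixtures import table1_library

build = importlib.import_module("01_build_library")
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    lib = build.synthetic_library()
    profile = base_content(lib)
    write_composition_tsv(profile, RESULTS / "composition.tsv")
    pcts = profile.rounded_percentages
    print(
        "pooled base content (synthetic library): "
        + ", ".join(f"{b} {pcts[b]}%" for b in "GUAC")
    )
    for anchor, name in ((Anchor.FIVE_PRIME, "five"), (Anchor.THREE_PRIME, "three")):
        pfm = positional_frequency(lib, anchor)
        write_pfm_tsv(pfm, RESULTS / f"pfm_{name}_prime.tsv")
    pfm5 = positional_frequency(lib, Anchor.FIVE_PRIME)
    first = pfm5.fractions.loc[1]
    print(
        "position 1 (5') occupancy: "
        + ", ".join(f"{b} {100 * first[b]:.0f}%" for b in "UAGC")
    )

    t1 = classify_pp_library(table1_library())
    t1.to_csv(RESULTS / "pp_reference_set.tsv", sep="\t", index=False)
    print("\nhighly purine/pyrimidine-rich reference set:")
    for _, row in t1.iterrows():
        pct = max(row.purine_pct, row.pyrimidine_pct)
        print(f"  {row.id:18s} {row.call:16s} {pct:3d}%")


if __name__ == "__main__":
    main()
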