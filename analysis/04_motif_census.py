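#!/usr/bin/env python
"""UGUGU (interferon induction motif) and GU-tract censuses.

Verifies that every sequence in the published IIM set carries the motif,
that every published GU-rich sequence has an alternating tract of >= 5 nt,
and reports the same censuses over the synthetic full-scale library.
"""

import importlib
from pathlib import Path

from mirchar.fixtures import table3_library, table4_library
from mirchar.motifs import (
    find_iim,
    gu_tracts,
    is_gu_rich,
    write_gu_tracts_tsv,
    write_iim_census_tsv,
)

build = importlib.import_module("01_build_library")
RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    t4 = table4_library()
    census = find_iim(t4)
    write_iim_census_tsv(census, RESULTS / "iim_reference_set.tsv")
    print(f"IIM reference set: {len(census)}/{len(t4)} sequences carry UGUGU")

    t3 = table3_library()
    rich = [rec for rec in t3.records if is_gu_rich(rec)]
    all_tracts = [t for rec in t3.records for t in gu_tracts(rec)]
    write_gu_tracts_tsv(all_tracts, RESULTS / "gu_tracts_reference_set.tsv")
    longest = max(all_tracts, key=lambda t: t.length)
    print(
        f"GU-rich reference set: {len(rich)}/{len(t3)} qualify; longest tract "
        f"{longest.length} nt ({longest.tract}) in {longest.id}"
    )

    lib = build.synthetic_library()
    synth_census = find_iim(lib)
    write_iim_census_tsv(synth_census, RESULTS / "iim_synthetic.tsv")
    synth_rich = sum(is_gu_rich(rec) for rec in lib.records)
    print(
        f"synthetic library: {len(synth_census)}/{len(lib)} carry UGUGU by "
        f"chance, {synth_rich} are GU-rich"
    )


if __name__ == "__main__":
    main()
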