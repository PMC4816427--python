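"""Published reference sequences, embedded verbatim for regression tests.

Three small sets of mature human miRNA sequences printed in the source
tables of the characterization study this package re-implements:

* ``TABLE1`` — highly purine/pyrimidine-rich sequences with their printed
  integer percentages and lengths,
* ``TABLE3`` — the GU-rich list,
* ``TABLE4`` — the 50 sequences carrying the UGUGU interferon induction
  motif.

Names and sequences are stored exactly as printed, including two printed
oddities that are preserved rather than corrected: ``hsa-miR-4271`` is
listed with length 22 but prints a 19-nt sequence (flagged via
``TABLE1_LENGTH_DISCREPANCIES``), and one Table-4 name prints as
``iR-642a-5p``.
"""

from __future__ import annotations

from pathlib import Path

from mirchar.library import MirnaLibrary, library_from_pairs, write_fasta

# (name, sequence, printed percentage, printed length, richness group)
TABLE1: tuple[tuple[str, str, int, int, str], ...] = (
    ("hsa-miR-4290", "UGCCCUCCUUUCUUCCCUC", 95, 19, "pyrimidine"),
    ("hsa-miR-1281", "UCGCCUCCUCCUCUCCC", 94, 17, "pyrimidine"),
    ("hsa-miR-4716-5p", "UCCAUGUUUCCUUCCCCCUUCU", 91, 22, "pyrimidine"),
    ("hsa-miR-483-3p", "UCACUCCUCUCCUCCCGUCUU", 90, 21, "pyrimidine"),
    ("hsa-miR-877-3p", "UCCUCUUCUCCCUCCUCCCAG", 90, 21, "pyrimidine"),
    ("hsa-miR-6124", "GGGAAAAGGAAGGGGGAGGA", 100, 20, "purine"),
    ("hsa-miR-4271", "GGGGGAAGAAAAGGUGGGG", 95, 22, "purine"),
    ("hsa-miR-483-5p", "AAGACGGGAGGAAAGAAGGGAG", 95, 22, "purine"),
    ("hsa-miR-4644", "UGGAGAGAGAAAAGAGACAGAAG", 91, 23, "purine"),
    ("hsa-miR-4716-3p", "AAGGGGGAAGGAAACAUGGAGA", 91, 22, "purine"),
    ("hsa-miR-1234-5p", "GGGGGGGGGGGGGGGGGGCCG", 90, 21, "purine"),
)

#: names whose printed sequence length disagrees with the printed length
#: column (printed 19-mer vs claimed 22); stored as printed, never "fixed".
TABLE1_LENGTH_DISCREPANCIES: dict[str, tuple[int, int]] = {
    "hsa-miR-4271": (19, 22)  # (actual printed sequence length, printed length column)
}

TABLE3: tuple[tuple[str, str], ...] = (
    ("miR-574-5p", "UGAGUGUGUGUGUGUGAGUGUGU"),
    ("miR-941", "CACCCGGCUGUGUGCACAUGUGC"),
    ("miR-3149", "UUUGUAUGGAUAUGUGUGUGUAU"),
    ("miR-1238-5p", "GUGAGUGGGAGCCCCAGUGUGUG"),
    ("miR-545-3p", "UCAGCAAACAUUUAUUGUGUGC"),
    ("miR-2278", "GAGAGCAGUGUGUGUUGCCUGG"),
    ("miR-3148", "UGGAAAAAACUGGUGUGUGCUU"),
    ("let-7b-5p", "UGAGGUAGUAGGUUGUGUGGUU"),
    ("miR-493-3p", "UGAAGGUCUACUGUGUGCCAGG"),
    ("miR-1180", "UUUCCGGCUCGCGUGGGUGUGU"),
    ("miR-539-5p", "GGAGAAAUUAUCCUUGGUGUGU"),
    ("miR-32-3p", "CAAUUUAGUGUGUGUGAUAUUU"),
    ("miR-206", "UGGAAUGUAAGGAAGUGUGUGG"),
    ("miR-1299", "UUCUGGAAUUCUGUGUGAGGGA"),
    ("miR-3911", "UGUGUGGAUCCUGGAGGAGGCA"),
    ("miR-297", "AUGUAUGUGUGCAUGUGCAUG"),
    ("miR-610", "UGAGCUAAAUGUGUGCUGGGA"),
    ("miR-1228-5p", "GUGGGCGGGGGCAGGUGUGUG"),
    ("miR-595", "GAAGUGUGCCGUGGUGUGUCU"),
    ("miR-4455", "AGGGUGUGUGUGUUUUU"),
    ("miR-3650", "AGGUGUGUCUGUAGAGUCC"),
    ("miR-147a", "GUGUGUGGAAAUGCUUCUGC"),
    ("miR-660-3p", "ACCUCCUGUGUGCAUGGAUUA"),
)

TABLE4: tuple[tuple[str, str], ...] = (
    ("miR-3682-5p", "CUACUUCUACCUGUGUUAUCAU"),
    ("miR-2278", "GAGAGCAGUGUGUGUUGCCUGG"),
    ("miR-1238-5p", "GUGAGUGGGAGCCCCAGUGUGUG"),
    ("miR-3149", "UUGUAUGGAUAUGUGUGUGUAU"),
    ("let-7b-5p", "UGAGGUAGUAGGUUGUGUGGUU"),
    ("miR-4455", "AGGGUGUGUGUGUUUUU"),
    ("miR-4717-5p", "UAGGCCACAGCCACCCAUGUGU"),
    ("miR-573", "CUGAAGUGAUGUGUAACUGAUCAG"),
    ("miR-660-3p", "ACCUCCUGUGUGCAUGGAUUA"),
    ("miR-378a-5p", "CUCCUGACUCCAGGUCCUGUGU"),
    ("miR-599", "GUUGUGUCAGUUUAUCAAAC"),
    ("miR-1226-3p", "UCACCAGCCCUGUGUUCCCUAG"),
    ("miR-1270", "CUGGAGAUAUGGAAGAGCUGUGU"),
    ("miR-610", "UGAGCUAAAUGUGUGCUGGGA"),
    ("miR-3911", "UGUGUGGAUCCUGGAGGAGGCA"),
    ("miR-3650", "AGGUGUGUCUGUAGAGUCC"),
    ("miR-4789-5p", "GUAUACACCUGAUAUGUGUAUG"),
    ("miR-330-5p", "UCUCUGGGCCUGUGUCUUAGGC"),
    ("miR-941", "CACCCGGCUGUGUGCACAUGUGC"),
    ("miR-597", "UGUGUCACUCGAUGACCACUGU"),
    ("miR-5580-5p", "UGCUGGCUCAUUUCAUAUGUGU"),
    ("miR-4700-5p", "UCUGGGGAUGAGGACAGUGUGU"),
    ("miR-892a", "CACUGUGUCCUUUCUGCGUAG"),
    ("miR-206", "UGGAAUGUAAGGAAGUGUGUGG"),
    ("miR-595", "GAAGUGUGCCGUGGUGUGUC"),
    ("miR-539-5p", "GGAGAAAUUAUCCUUGGUGUGU"),
    ("miR-1180-3p", "UUUCCGGCUCGCGUGGGUGUGU"),
    ("miR-450a-5p", "UUUUGCGAUGUGUUCCUAAUAU"),
    ("miR-493-3p", "UGAAGGUCUACUGUGUGCCAGG"),
    ("miR-4669", "UGUGUCCGGGAAGUGGAGGAGG"),
    ("miR-4753-3p", "UUCUCUUUCUUUAGCCUUGUGU"),
    ("miR-624-5p", "UAGUACCAGUACCUUGUGUUCA"),
    ("miR-3657", "UGUGUCCCAUUAUUGGUGAUU"),
    ("miR-3148", "UGGAAAAAACUGGUGUGUGCUU"),
    ("miR-3177-5p", "UGUGUACACACGUGCCAGGCGCU"),
    ("miR-581", "UCUUGUGUUCUCUAGAUCAGU"),
    ("miR-642b-5p", "GGUUCCCUCUCCAAAUGUGUCU"),
    ("miR-147a", "GUGUGUGGAAAUGCUUCUGC"),
    ("miR-592", "UUGUGUCAAUAUGCGAUGAUGU"),
    ("miR-545-3p", "UCAGCAAACAUUUAUUGUGUGC"),
    ("miR-1228-5p", "GUGGGCGGGGGCAGGUGUGUG"),
    ("iR-642a-5p", "GUCCCUCUCCAAAUGUGUCUUG"),
    ("miR-3152-3p", "UGUGUUAGAAUAGGGGCAAUAA"),
    ("miR-32-3p", "CAAUUUAGUGUGUGUGAUAUUU"),
    ("miR-1299", "UUCUGGAAUUCUGUGUGAGGGA"),
    ("miR-297", "AUGUAUGUGUGCAUGUGCAUG"),
    ("miR-187-3p", "UCGUGUCUUGUGUUGCAGCCGG"),
    ("miR-5010-3p", "UUUUGUGUCUCCCAUUCCCCAG"),
    ("miR-574-5p", "UGAGUGUGUGUGUGUGAGUGUGU"),
    ("miR-649", "AAACCUGUGUUGUUCAAGAGUC"),
)


def table1_library() -> MirnaLibrary:
    """The 11 highly purine/pyrimidine-rich sequences (5 pyrimidine, 6 purine)."""
    return library_from_pairs(
        [(name, seq) for name, seq, _, _, _ in TABLE1], source="table1"
    )


def table3_library() -> MirnaLibrary:
    """The 23 GU-rich sequences."""
    return library_from_pairs(TABLE3, source="table3")


def table4_library() -> MirnaLibrary:
    """The 50 UGUGU (interferon induction motif) sequences."""
    return library_from_pairs(TABLE4, source="table4")


def write_fixture_tables(out_dir: str | Path) -> dict[str, Path]:
    """Write the three reference sets as FASTA files; returns name -> path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, lib in (
        ("table1", table1_library()),
        ("table3", table3_library()),
        ("table4", table4_library()),
    ):
        path = out_dir / f"{name}.fasta"
        write_fasta(lib, path)
        paths[name] = path
    return paths
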