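"""Hairpin enumeration, tetraloop cascade, stability surrogate, dot-bracket."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import oracle_hairpins, random_rna
from mirchar.hairpin import (
    Hairpin,
    best_hairpin,
    can_pair,
    classify_tetraloop,
    dot_bracket,
    enumerate_hairpins,
    stability_score,
    tetraloop_cascade,
)
from mirchar.library import MirnaRecord, library_from_pairs

LET7B = "UGAGGUAGUAGGUUGUGUGGUU"


def rec(seq: str, ident: str = "x") -> MirnaRecord:
    return MirnaRecord(id=ident, sequence=seq)


def as_keys(hairpins):
    return {(h.pairs, h.loop_start, h.loop_end) for h in hairpins}


def test_forced_hairpin():
    hs = enumerate_hairpins(rec("GGGAAAACCC"))
    assert len(hs) == 1
    h = hs[0]
    assert h.pairs == ((1, 10), (2, 9), (3, 8))
    assert (h.loop_start, h.loop_end, h.loop_seq) == (4, 7, "AAAA")
    assert h.stem_length == 3
    assert h.closing_pair_positions == (3, 8)


def test_no_hairpin_in_homopolymer():
    assert enumerate_hairpins(rec("AAAAAA")) == []
    assert best_hairpin(rec("ACGU")) is None


def test_let7b_matches_brute_force():
    got = as_keys(enumerate_hairpins(rec(LET7B)))
    assert got == oracle_hairpins(LET7B)


def test_best_hairpin_prefers_longer_stem():
    # two disjoint candidates: stem 4 (GGGG/CCCC around GAAA) and stem 3
    seq = "GGGGGAAACCCCAAGGGUUCGCCC"
    best = best_hairpin(rec(seq), min_stem=3)
    oracle = oracle_hairpins(seq, min_stem=3)
    assert best is not None
    assert best.stem_length == max(len(p) for p, _, _ in oracle)
    assert best.stem_length >= 4


def test_sort_order_is_stem_then_loop():
    hs = enumerate_hairpins(rec(LET7B), min_stem=1)
    keys = [(-h.stem_length, h.loop_length, h.loop_start) for h in hs]
    assert keys == sorted(keys)


@settings(derandomize=True, max_examples=150)
@given(
    st.text(alphabet="ACGU", min_size=1, max_size=30),
    st.integers(1, 4),
    st.booleans(),
)
def test_enumeration_agrees_with_brute_force(seq, min_stem, wobble):
    got = as_keys(enumerate_hairpins(rec(seq), min_stem=min_stem, allow_wobble=wobble))
    assert got == oracle_hairpins(seq, min_stem=min_stem, allow_wobble=wobble)


def test_enumeration_brute_force_random_trials():
    rng = random.Random(1234)
    for _ in range(1000):
        seq = random_rna(rng, 8, 30)
        assert as_keys(enumerate_hairpins(rec(seq))) == oracle_hairpins(seq)


@settings(derandomize=True, max_examples=80)
@given(st.text(alphabet="ACGU", min_size=4, max_size=28))
def test_relaxing_parameters_never_removes_hairpins(seq):
    base = as_keys(enumerate_hairpins(rec(seq), min_stem=3, loop_min=4, loop_max=6))
    relaxed = as_keys(enumerate_hairpins(rec(seq), min_stem=2, loop_min=3, loop_max=8))
    assert base <= relaxed


@settings(derandomize=True, max_examples=80)
@given(st.text(alphabet="ACGU", min_size=4, max_size=28))
def test_pairing_and_nesting_invariants(seq):
    for h in enumerate_hairpins(rec(seq), min_stem=1):
        i0, j0 = h.pairs[0]
        for k, (i, j) in enumerate(h.pairs):
            assert (i, j) == (i0 + k, j0 - k)
            assert 1 <= i < j <= len(seq)
            assert can_pair(seq[i - 1], seq[j - 1], allow_wobble=True)
        assert h.pairs[-1] == (h.loop_start - 1, h.loop_end + 1)
        assert h.loop_length >= 3


def test_wobble_toggle():
    # stem is all G:U pairs, so it vanishes without wobble
    seq = "GGGAAAAUUU"
    assert enumerate_hairpins(rec(seq), allow_wobble=True)
    assert enumerate_hairpins(rec(seq), allow_wobble=False) == []


def test_classify_tetraloop_all_flags():
    seq = "GCCGAAAGGC"
    h = enumerate_hairpins(rec(seq))[0]
    assert h.loop_seq == "GAAA"
    c = classify_tetraloop(h, seq)
    assert c.loop_in_motif_set and c.stem_ge_3 and c.closing_pair_cg


def test_classify_tetraloop_non_cg_closing():
    seq = "AUUCGU"
    h = enumerate_hairpins(rec(seq), min_stem=1, loop_min=4, loop_max=4)[0]
    assert h.loop_seq == "UUCG"
    c = classify_tetraloop(h, seq)
    assert c.loop_in_motif_set
    assert not c.stem_ge_3
    assert not c.closing_pair_cg


def test_closing_pair_orientation_modes():
    seq = "GCCGAAAGGC"  # closing pair reads 5'-C, 3'-G
    h = enumerate_hairpins(rec(seq))[0]
    assert classify_tetraloop(h, seq, strict_orientation=True).closing_pair_cg
    rev = "CCGGAAACGG"  # closing pair reads 5'-G, 3'-C
    h2 = enumerate_hairpins(rec(rev))[0]
    assert classify_tetraloop(h2, rev).closing_pair_cg
    assert not classify_tetraloop(h2, rev, strict_orientation=True).closing_pair_cg


def test_stability_score_example():
    seq = "GGGAAAACCC"
    h = enumerate_hairpins(rec(seq))[0]
    assert stability_score(h, seq) == pytest.approx(8.5)  # 3 GC pairs, loop 4


def test_stability_strictly_increases_with_gc_pair():
    rng = random.Random(7)
    for _ in range(50):
        loop_len = rng.randint(3, 8)
        stem = rng.randint(1, 5)
        # build a hairpin directly: a stem of random pair types around a loop
        bases = [rng.choice(["GC", "CG", "AU", "UA", "GU", "UG"]) for _ in range(stem)]
        left = "".join(b[0] for b in bases)
        loop = "".join(rng.choice("ACGU") for _ in range(loop_len))
        right = "".join(b[1] for b in reversed(bases))
        seq = left + loop + right
        h = Hairpin(
            id="x",
            pairs=tuple((k + 1, len(seq) - k) for k in range(stem)),
            loop_start=stem + 1,
            loop_end=stem + loop_len,
            loop_seq=loop,
        )
        bigger_seq = "G" + seq + "C"
        h_bigger = Hairpin(
            id="x",
            pairs=tuple((k + 1, len(bigger_seq) - k) for k in range(stem + 1)),
            loop_start=stem + 2,
            loop_end=stem + 1 + loop_len,
            loop_seq=loop,
        )
        assert stability_score(h_bigger, bigger_seq) > stability_score(h, seq)


def test_dot_bracket():
    seq = "GGGAAAACCC"
    h = enumerate_hairpins(rec(seq))[0]
    assert dot_bracket(h, seq) == "(((....)))"
    assert dot_bracket(None, seq) == "." * 10


def test_cascade_counts_constructed():
    """20 motif-tetraloop hairpins, 8 with C-G closing pairs -> 20/20/8."""
    cg = "AAAGGCGAAAGCCAAA"  # stem GGC/GCC, closing C-G, loop GAAA
    au = "AAAGGAGAAAUCCAAA"  # stem GGA/UCC, closing A-U, loop GAAA
    lib = library_from_pairs(
        [(f"cg{i}", cg) for i in range(8)] + [(f"au{i}", au) for i in range(12)]
    )
    cascade = tetraloop_cascade(lib)
    row = cascade["GAAA"]
    assert (row["hairpin"], row["stem3"], row["stem3_cg"]) == (20, 20, 8)
    total = {k: sum(r[k] for r in cascade.values()) for k in ("hairpin", "stem3", "stem3_cg")}
    assert total["hairpin"] >= total["stem3"] >= total["stem3_cg"]


def test_cascade_monotonic_on_fixture(table4):
    cascade = tetraloop_cascade(table4)
    for row in cascade.values():
        assert row["hairpin"] >= row["stem3"] >= row["stem3_cg"]


def test_count_mode_all_geq_best(table3):
    best = tetraloop_cascade(table3, count_mode="best")
    everything = tetraloop_cascade(table3, count_mode="all")
    for motif in best:
        for stage in ("hairpin", "stem3", "stem3_cg"):
            assert everything[motif][stage] >= best[motif][stage]


def test_parameter_validation():
    with pytest.raises(ValueError):
        enumerate_hairpins(rec("ACGU"), loop_min=2)
    with pytest.raises(ValueError):
        enumerate_hairpins(rec("ACGU"), min_stem=0)
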