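"""Synthetic library generation: determinism, planting, certification."""

import math

import numpy as np
import pytest

from mirchar.fixtures import write_fixture_tables
from mirchar.library import write_fasta
from mirchar.motifs import scan_motif
from mirchar.ssr import find_ssrs
from mirchar.synthetic import (
    DEFAULT_BASE_FREQUENCIES,
    GenerationError,
    HairpinFeature,
    MotifFeature,
    SSRFeature,
    SyntheticSpec,
    TerminalBaseFeature,
    generate_library,
    verify_planted_hairpin,
)


def test_empty_spec():
    lib, truth = generate_library(SyntheticSpec(n_sequences=0, seed=1))
    assert len(lib) == 0
    assert not truth.motifs and not truth.ssrs and not truth.hairpins


def test_determinism_byte_identical_fasta(tmp_path):
    spec = SyntheticSpec(
        n_sequences=50,
        planted_features=[MotifFeature("UGUGU", 0.3), SSRFeature("GU", 4, 0.2)],
        seed=99,
    )
    paths = []
    for name in ("a.fa", "b.fa"):
        lib, _ = generate_library(spec)
        path = tmp_path / name
        write_fasta(lib, path)
        paths.append(path)
    assert paths[0].read_bytes() == paths[1].read_bytes()


def test_exact_fraction_planted_and_certified_free():
    spec = SyntheticSpec(
        n_sequences=100, planted_features=[MotifFeature("UGUGU", 0.3)], seed=7
    )
    lib, truth = generate_library(spec)
    assert len(truth.motifs) == 30
    carriers = {r.id for r in lib.records if "UGUGU" in r.sequence}
    assert carriers == set(truth.motifs)
    assert set(truth.certified_free["motif:UGUGU"]) == {
        r.id for r in lib.records
    } - carriers
    # planted coordinates index the planted pattern exactly
    by_id = {r.id: r for r in lib.records}
    for ident, instances in truth.motifs.items():
        for inst in instances:
            seq = by_id[ident].sequence
            assert seq[inst["start"] - 1 : inst["end"]] == inst["motif"]
            assert any(
                h.start == inst["start"]
                for h in scan_motif(by_id[ident], inst["motif"])
            )


def test_planted_ssr_is_maximal_and_unique():
    spec = SyntheticSpec(
        n_sequences=40, planted_features=[SSRFeature("AG", 4, 0.5)], seed=3
    )
    lib, truth = generate_library(spec)
    by_id = {r.id: r for r in lib.records}
    assert len(truth.ssrs) == 20
    for ident, instances in truth.ssrs.items():
        inst = instances[0]
        tracts = find_ssrs(by_id[ident])
        assert [
            (t.unit, t.repeat_count, t.start, t.end) for t in tracts
        ] == [(inst["unit"], inst["repeat_count"], inst["start"], inst["end"])]
    for ident in truth.certified_free["ssr"]:
        assert find_ssrs(by_id[ident]) == []


def test_planted_hairpin_recovered_exactly():
    spec = SyntheticSpec(
        n_sequences=30,
        planted_features=[HairpinFeature(4, "GAAA", ("C", "G"), 0.5)],
        seed=13,
    )
    lib, truth = generate_library(spec)
    by_id = {r.id: r for r in lib.records}
    assert len(truth.hairpins) == 15
    for ident, instances in truth.hairpins.items():
        assert verify_planted_hairpin(by_id[ident], instances[0])


def test_terminal_base_planting():
    spec = SyntheticSpec(
        n_sequences=25,
        planted_features=[TerminalBaseFeature("U", "five_prime", 1.0)],
        seed=2,
    )
    lib, _ = generate_library(spec)
    assert all(r.sequence.startswith("U") for r in lib.records)


def test_base_frequencies_within_three_standard_errors():
    """A ~1e5-nt featureless corpus matches the spec composition."""
    spec = SyntheticSpec(n_sequences=5000, seed=17)
    lib, _ = generate_library(spec)
    pooled = "".join(lib.sequences())
    n = len(pooled)
    assert n > 90_000
    for base, p in DEFAULT_BASE_FREQUENCIES.items():
        observed = pooled.count(base) / n
        se = math.sqrt(p * (1 - p) / n)
        assert abs(observed - p) <= 3 * se, (base, observed, p)


def test_length_distribution_respected():
    spec = SyntheticSpec(n_sequences=2000, seed=23)
    lib, _ = generate_library(spec)
    lengths = np.array([r.length for r in lib.records])
    assert lengths.min() >= 16 and lengths.max() <= 27
    mode_frac = (lengths == 22).mean()
    assert 0.40 < mode_frac < 0.54  # nominal 47%


def test_infeasible_feature_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(
            n_sequences=5,
            planted_features=[SSRFeature("UGGGC", 10, 0.5)],  # 50 nt > max length
            seed=1,
        ).validate()


def test_overcommitted_fractions_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(
            n_sequences=5,
            planted_features=[MotifFeature("UGUGU", 0.7), SSRFeature("GU", 3, 0.6)],
            seed=1,
        ).validate()


def test_bad_probability_vectors_rejected():
    with pytest.raises(ValueError):
        SyntheticSpec(n_sequences=1, length_distribution={22: 0.5}, seed=1).validate()


def test_nested_tracts_inside_planted_span_tolerated():
    # (AAAG)3 necessarily contains mono (A)3 runs; they sit inside the
    # planted span, so certification accepts them and the scanner reports
    # both the planted tetra tract and the nested mono runs
    lib, truth = generate_library(
        SyntheticSpec(
            n_sequences=2, planted_features=[SSRFeature("AAAG", 3, 1.0)], seed=1
        )
    )
    by_id = {r.id: r for r in lib.records}
    for ident, instances in truth.ssrs.items():
        inst = instances[0]
        tracts = find_ssrs(by_id[ident])
        assert any(
            t.unit == "AAAG" and t.start == inst["start"] and t.end == inst["end"]
            for t in tracts
        )
        mono = [t for t in tracts if t.unit_length == 1]
        assert mono and all(
            inst["start"] <= t.start and t.end <= inst["end"] for t in mono
        )


def test_write_fixture_tables(tmp_path):
    paths = write_fixture_tables(tmp_path)
    from mirchar.library import read_fasta

    assert len(read_fasta(paths["table1"])) == 11
    assert len(read_fasta(paths["table3"])) == 23
    assert len(read_fasta(paths["table4"])) == 50
    t1 = read_fasta(paths["table1"])
    from mirchar.composition import classify_pp

    calls = [classify_pp(r).call for r in t1.records]
    assert calls.count("pyrimidine_rich") == 5
    assert calls.count("purine_rich") == 6
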