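"""Seeded synthetic miRNA libraries with plantable features and ground truth.

The generator emulates a mature human miRNA library: ~2000 short sequences
of 16-27 nt with the mode at 22 nt (about 47% of sequences, with 21 nt and
23 nt the next most common), background bases i.i.d. with the pooled
composition observed in the real library (G 29%, U 26%, A 23%, C 22%).

Features — exact motif copies, SSR tracts, stem-loop hairpins, fixed
terminal bases — are planted in a chosen fraction of records by
overwriting background positions at a uniformly drawn admissible
placement.  Each record carries at most one planted feature directive, so
plantings never interfere.  Ground truth records exact 1-based coordinates
for every planted instance, and the generator *certifies* feature absence
where the recovery tests need it: records free of a planted feature type
are resampled until the corresponding scanner finds nothing, and flanks of
planted SSR tracts are constrained so the planted boundaries are the
maximal tract.  Certification of "no spurious SSR elsewhere" uses the
package's own scanners; coordinate bookkeeping is independent of them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np

from mirchar.hairpin import can_pair, enumerate_hairpins
from mirchar.library import MirnaLibrary, MirnaRecord, _build_alias_map
from mirchar.ssr import find_ssrs

BASES = ("A", "C", "G", "U")

#: qualitative mimic of the real length profile: mode 22 (~47%), shoulders
#: at 21 (~12%) and 23 (~14%), remainder spread over 16-27.
DEFAULT_LENGTH_DISTRIBUTION: dict[int, float] = {
    16: 0.01,
    17: 0.01,
    18: 0.02,
    19: 0.04,
    20: 0.06,
    21: 0.12,
    22: 0.47,
    23: 0.14,
    24: 0.05,
    25: 0.04,
    26: 0.02,
    27: 0.02,
}

#: pooled base content of the real deduplicated library.
DEFAULT_BASE_FREQUENCIES: dict[str, float] = {"A": 0.23, "C": 0.22, "G": 0.29, "U": 0.26}

_PAIRABLE = {
    "A": ("U",),
    "U": ("A", "G"),
    "G": ("C", "U"),
    "C": ("G",),
}
_ALL_PAIRS = (("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G"))


@dataclass(frozen=True)
class MotifFeature:
    motif: str
    fraction: float


@dataclass(frozen=True)
class SSRFeature:
    unit: str
    repeat_count: int
    fraction: float


@dataclass(frozen=True)
class HairpinFeature:
    stem_length: int
    loop_seq: str
    closing_pair: tuple[str, str]  # (5' base, 3' base) of the innermost pair
    fraction: float


@dataclass(frozen=True)
class TerminalBaseFeature:
    base: str
    end: str  # "five_prime" | "three_prime"
    fraction: float


Feature = Union[MotifFeature, SSRFeature, HairpinFeature, TerminalBaseFeature]


@dataclass
class SyntheticSpec:
    n_sequences: int
    length_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_LENGTH_DISTRIBUTION)
    )
    base_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_FREQUENCIES)
    )
    planted_features: list[Feature] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be >= 0")
        for name, dist in (
            ("length_distribution", self.length_distribution),
            ("base_frequencies", self.base_frequencies),
        ):
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities sum to {total}, not 1")
            if any(p < 0 for p in dist.values()):
                raise ValueError(f"{name} has negative probabilities")
        frac_sum = sum(f.fraction for f in self.planted_features)
        if any(not 0 <= f.fraction <= 1 for f in self.planted_features):
            raise ValueError("feature fractions must lie in [0, 1]")
        if frac_sum > 1 + 1e-9:
            raise ValueError(
                "feature fractions sum to more than 1; each record carries at "
                "most one planted feature"
            )
        max_len = max(k for k, p in self.length_distribution.items() if p > 0)
        for feat in self.planted_features:
            if _feature_span(feat) > max_len:
                raise ValueError(f"feature {feat} cannot fit any drawable length")


def _feature_span(feature: Feature) -> int:
    if isinstance(feature, MotifFeature):
        return len(feature.motif)
    if isinstance(feature, SSRFeature):
        return len(feature.unit) * feature.repeat_count
    if isinstance(feature, HairpinFeature):
        return 2 * feature.stem_length + len(feature.loop_seq)
    return 1


@dataclass
class GroundTruth:
    """Exact coordinates of every planted feature instance, per record id.

    ``certified_free`` maps a feature key (e.g. ``"motif:UGUGU"`` or
    ``"ssr"``) to the ids the generator guarantees carry no such feature.
    """

    motifs: dict[str, list[dict]] = field(default_factory=dict)
    ssrs: dict[str, list[dict]] = field(default_factory=dict)
    hairpins: dict[str, list[dict]] = field(default_factory=dict)
    terminal: dict[str, list[dict]] = field(default_factory=dict)
    certified_free: dict[str, list[str]] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "motifs": self.motifs,
                    "ssrs": self.ssrs,
                    "hairpins": self.hairpins,
                    "terminal": self.terminal,
                    "certified_free": self.certified_free,
                },
                indent=2,
            )
            + "\n"
        )


class GenerationError(RuntimeError):
    pass


_MAX_TRIES = 2000


def _draw_length(rng: np.random.Generator, lengths, probs, min_len: int) -> int:
    """Draw a sequence length, rejecting draws shorter than ``min_len``."""
    if max(lengths) < min_len:
        raise GenerationError(f"no drawable length can hold a span of {min_len} nt")
    for _ in range(_MAX_TRIES):
        ln = int(rng.choice(lengths, p=probs))
        if ln >= min_len:
            return ln
    raise GenerationError("length rejection sampling failed")


def _plant_ssr(seq: list[str], rng: np.random.Generator, feat: SSRFeature) -> dict:
    k = len(feat.unit)
    span = k * feat.repeat_count
    start0 = int(rng.integers(0, len(seq) - span + 1))
    seq[start0 : start0 + span] = list(feat.unit * feat.repeat_count)
    # resample flanking bases so the planted tract is maximal: the base
    # before must not complete a unit copy ending there, the base after
    # must not begin one
    if start0 > 0 and seq[start0 - 1] == feat.unit[-1]:
        choices = [b for b in BASES if b != feat.unit[-1]]
        seq[start0 - 1] = str(rng.choice(choices))
    end0 = start0 + span - 1
    if end0 + 1 < len(seq) and seq[end0 + 1] == feat.unit[0]:
        choices = [b for b in BASES if b != feat.unit[0]]
        seq[end0 + 1] = str(rng.choice(choices))
    return {
        "unit": feat.unit,
        "repeat_count": feat.repeat_count,
        "start": start0 + 1,
        "end": end0 + 1,
    }


def _plant_hairpin(seq: list[str], rng: np.random.Generator, feat: HairpinFeature) -> dict:
    stem, loop = feat.stem_length, feat.loop_seq
    span = 2 * stem + len(loop)
    start0 = int(rng.integers(0, len(seq) - span + 1))
    # stem pairs, innermost (closing) fixed, the rest random valid pairs
    pairs_bases = [feat.closing_pair] + [
        _ALL_PAIRS[int(rng.integers(0, len(_ALL_PAIRS)))] for _ in range(stem - 1)
    ]  # innermost first
    left = [p[0] for p in reversed(pairs_bases)]  # outermost first on the 5' arm
    right = [p[1] for p in pairs_bases]  # innermost first on the 3' arm
    seq[start0 : start0 + span] = left + list(loop) + right
    # flanks must not pair, or the planted stem would extend outward
    i_flank, j_flank = start0 - 1, start0 + span
    if i_flank >= 0 and j_flank < len(seq):
        while can_pair(seq[i_flank], seq[j_flank], allow_wobble=True):
            seq[j_flank] = str(rng.choice(BASES))
    loop_start = start0 + stem + 1  # 1-based
    pairs = [
        (start0 + 1 + d, start0 + span - d) for d in range(stem)
    ]  # outermost first
    return {
        "pairs": pairs,
        "loop_start": loop_start,
        "loop_end": loop_start + len(loop) - 1,
        "loop_seq": loop,
        "closing_pair": list(feat.closing_pair),
    }


def _has_spurious_ssr(record: MirnaRecord, planted: dict | None) -> bool:
    for tract in find_ssrs(record):
        if planted is None:
            return True
        if not (tract.start >= planted["start"] and tract.end <= planted["end"]):
            return True
    return False


def generate_library(spec: SyntheticSpec) -> tuple[MirnaLibrary, GroundTruth]:
    """Deterministically generate a library and its ground truth.

    Identical spec + seed gives identical output.  Exactly
    ``round(fraction * n)`` records receive each feature directive.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_sequences
    lengths = sorted(spec.length_distribution)
    len_probs = np.array([spec.length_distribution[k] for k in lengths], dtype=float)
    len_probs /= len_probs.sum()
    base_probs = np.array([spec.base_frequencies[b] for b in BASES], dtype=float)
    base_probs /= base_probs.sum()

    # assign each record at most one feature directive
    assignment: list[Feature | None] = [None] * n
    order = rng.permutation(n)
    cursor = 0
    for feat in spec.planted_features:
        count = int(round(feat.fraction * n))
        for idx in order[cursor : cursor + count]:
            assignment[idx] = feat
        cursor += count

    motif_directives = [f for f in spec.planted_features if isinstance(f, MotifFeature)]
    ssr_planted = any(isinstance(f, SSRFeature) for f in spec.planted_features)

    truth = GroundTruth()
    records: list[MirnaRecord] = []
    width = max(4, len(str(max(n, 1))))
    for i in range(n):
        ident = f"syn-{i:0{width}d}"
        feat = assignment[i]
        min_len = _feature_span(feat) if feat is not None else min(lengths)
        length = _draw_length(rng, lengths, len_probs, min_len)
        for attempt in range(_MAX_TRIES):
            seq = [str(b) for b in rng.choice(BASES, size=length, p=base_probs)]
            instance: dict | None = None
            if isinstance(feat, MotifFeature):
                start0 = int(rng.integers(0, length - len(feat.motif) + 1))
                seq[start0 : start0 + len(feat.motif)] = list(feat.motif)
                instance = {
                    "motif": feat.motif,
                    "start": start0 + 1,
                    "end": start0 + len(feat.motif),
                }
            elif isinstance(feat, SSRFeature):
                instance = _plant_ssr(seq, rng, feat)
            elif isinstance(feat, HairpinFeature):
                instance = _plant_hairpin(seq, rng, feat)
            elif isinstance(feat, TerminalBaseFeature):
                pos = 0 if feat.end == "five_prime" else length - 1
                seq[pos] = feat.base
                instance = {"base": feat.base, "end": feat.end}
            record = MirnaRecord(id=ident, sequence="".join(seq))

            # certification: scanners must find nothing they should not
            ok = True
            for mdir in motif_directives:
                if feat is None and mdir.motif in record.sequence:
                    ok = False  # certified-free record must lack the motif
            if ok and ssr_planted and feat is None and _has_spurious_ssr(record, None):
                ok = False
            if ok and isinstance(feat, SSRFeature) and _has_spurious_ssr(record, instance):
                ok = False
            if ok:
                break
        else:
            raise GenerationError(
                f"could not certify record {ident} after {_MAX_TRIES} attempts; "
                f"feature {feat} may be self-conflicting"
            )

        records.append(record)
        if isinstance(feat, MotifFeature):
            truth.motifs.setdefault(ident, []).append(instance)
        elif isinstance(feat, SSRFeature):
            truth.ssrs.setdefault(ident, []).append(instance)
        elif isinstance(feat, HairpinFeature):
            truth.hairpins.setdefault(ident, []).append(instance)
        elif isinstance(feat, TerminalBaseFeature):
            truth.terminal.setdefault(ident, []).append(instance)

    # certified-free sets: records with no planted feature at all
    unplanted = [r.id for r, a in zip(records, assignment) if a is None]
    for mdir in motif_directives:
        truth.certified_free[f"motif:{mdir.motif}"] = list(unplanted)
    if ssr_planted:
        truth.certified_free["ssr"] = list(unplanted)

    library = MirnaLibrary(
        records=records, alias_map=_build_alias_map(records), source="synthetic"
    )
    return library, truth


def verify_planted_hairpin(record: MirnaRecord, instance: dict) -> bool:
    """True if the enumerator reports the planted hairpin exactly."""
    want_pairs = tuple(tuple(p) for p in instance["pairs"])
    for h in enumerate_hairpins(
        record,
        min_stem=min(3, len(want_pairs)),
        loop_min=3,
        loop_max=max(8, len(instance["loop_seq"])),
    ):
        if h.pairs == want_pairs and h.loop_start == instance["loop_start"]:
            return True
    return False
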