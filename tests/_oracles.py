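"""Independent brute-force oracles used to cross-check the scanners.

Each oracle enumerates candidate substructures exhaustively and filters by
the definitions directly; none shares code or scanning strategy with the
implementation under test.
"""

from __future__ import annotations

import random


def naive_motif_starts(seq: str, motif: str) -> list[int]:
    """Every occurrence start (1-based), by checking all substrings."""
    m = len(motif)
    return [i + 1 for i in range(len(seq) - m + 1) if seq[i : i + m] == motif]


def oracle_gu_tracts(seq: str, min_length: int) -> list[tuple[int, int, str]]:
    """All maximal alternating-G/U substrings >= min_length, as (start, end, tract)."""

    def alternating(sub: str) -> bool:
        return (
            set(sub) <= {"G", "U"}
            and all(a != b for a, b in zip(sub, sub[1:]))
        )

    n = len(seq)
    out = []
    for i in range(n):
        for j in range(i, n):
            sub = seq[i : j + 1]
            if not alternating(sub):
                continue
            left_ext = i > 0 and alternating(seq[i - 1 : j + 1])
            right_ext = j + 1 < n and alternating(seq[i : j + 2])
            if not left_ext and not right_ext and len(sub) >= min_length:
                out.append((i + 1, j + 1, sub))
    return sorted(out)


def _primitive(unit: str) -> bool:
    # a string is primitive iff it is not a nontrivial rotation of itself
    return (unit + unit).find(unit, 1) == len(unit)


def oracle_ssrs(
    seq: str, min_repeats: int = 3, max_unit: int = 5
) -> list[tuple[str, int, int, int]]:
    """Maximal primitive-unit tracts as (unit, repeat_count, start, end), 1-based.

    Enumerates every (start, unit length) placement, keeps complete-unit
    maximal tracts with enough repeats, then resolves overlaps within each
    unit length leftmost-greedily.
    """
    n = len(seq)
    chosen: list[tuple[str, int, int, int]] = []
    for k in range(1, max_unit + 1):
        candidates = []
        for i in range(n - k * min_repeats + 1):
            unit = seq[i : i + k]
            if not _primitive(unit):
                continue
            m = 0
            while seq[i + k * m : i + k * (m + 1)] == unit:
                m += 1
            if m < min_repeats:
                continue
            if i - k >= 0 and seq[i - k : i] == unit:
                continue  # not left-maximal
            candidates.append((unit, m, i + 1, i + k * m))
        candidates.sort(key=lambda c: c[2])
        last_end = 0
        for cand in candidates:
            if cand[2] > last_end:
                chosen.append(cand)
                last_end = cand[3]
    return sorted(chosen, key=lambda c: (len(c[0]), c[2]))


_WC_AND_WOBBLE = {"AU", "UA", "GC", "CG", "GU", "UG"}
_WC_ONLY = {"AU", "UA", "GC", "CG"}


def oracle_hairpins(
    seq: str,
    min_stem: int = 3,
    loop_min: int = 3,
    loop_max: int = 8,
    allow_wobble: bool = True,
) -> set[tuple[tuple[tuple[int, int], ...], int, int]]:
    """Every (pairs, loop_start, loop_end) with a maximal contiguous stem.

    Tests each (loop placement, stem length) combination independently.
    """
    ok = _WC_AND_WOBBLE if allow_wobble else _WC_ONLY
    n = len(seq)
    found = set()
    for ls in range(1, n + 1):
        for le in range(ls + loop_min - 1, min(n, ls + loop_max - 1) + 1):
            for stem in range(min_stem, n // 2 + 1):
                i0, j0 = ls - stem, le + stem
                if i0 < 1 or j0 > n:
                    continue
                pairs = tuple((i0 + d, j0 - d) for d in range(stem))
                if any(seq[i - 1] + seq[j - 1] not in ok for i, j in pairs):
                    continue
                # maximal: one more outward pair must be impossible
                if i0 - 1 >= 1 and j0 + 1 <= n and seq[i0 - 2] + seq[j0] in ok:
                    continue
                # inner extension check: pair adjacent to the loop must exist
                # (by construction stem >= 1 and innermost is (ls-1, le+1))
                found.add((pairs, ls, le))
    return found


def random_rna(rng: random.Random, min_len: int = 5, max_len: int = 30) -> str:
    return "".join(rng.choice("ACGU") for _ in range(rng.randint(min_len, max_len)))
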