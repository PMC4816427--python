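"""Shared helpers: alphabet validation and the reporting rounding convention."""

from __future__ import annotations

import math

RNA_ALPHABET = frozenset("ACGU")
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CU")


def normalize_sequence(raw: str) -> str:
    """Uppercase and map T->U (DNA-alphabet FASTA files are common)."""
    return raw.strip().upper().replace("T", "U")


def validate_sequence(seq: str, ident: str = "?") -> None:
    bad = set(seq) - RNA_ALPHABET
    if bad:
        raise ValueError(
            f"record {ident!r}: invalid characters {sorted(bad)} after T->U normalization"
        )
    if not seq:
        raise ValueError(f"record {ident!r}: empty sequence")


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (school rounding, not banker's).

    This is the convention that reproduces the printed integer percentages
    of the purine/pyrimidine table (e.g. 18/19 = 94.74 -> 95, 19/21 = 90.48
    -> 90).
    """
    factor = 10**ndigits
    scaled = x * factor
    rounded = math.floor(abs(scaled) + 0.5) * (1 if scaled >= 0 else -1)
    return rounded / factor if ndigits else float(rounded)


def format_relative(total: int, n: int) -> str:
    """Relative count (tracts per miRNA) formatted for reports.

    Two decimals normally (2326/2042 -> "1.14"); three when the value would
    otherwise print as 0.00 (3/2042 -> "0.001"), matching how very rare
    repeat classes are tabulated.
    """
    if n <= 0:
        raise ValueError("library size must be positive")
    value = total / n
    two = round_half_away(value, 2)
    if two == 0.0 and total > 0:
        return f"{round_half_away(value, 3):.3f}"
    return f"{two:.2f}"
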