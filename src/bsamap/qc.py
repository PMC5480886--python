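"""Sequencing QC arithmetic: run totals, filtering yield, fold coverage."""

from __future__ import annotations

import math


def _round2(x: float, mode: str) -> float:
    if mode == "half_even":
        # float repr noise would defeat round-half-even on e.g. 99.085
        from decimal import Decimal, ROUND_HALF_EVEN

        return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_EVEN))
    if mode == "truncate":
        return math.floor(x * 100) / 100
    raise ValueError(f"unknown rounding mode {mode!r}")


def seq_totals(read_pairs: float, read_length: int) -> float:
    """Total sequenced bases in Gbp (2 decimals): pairs x 2 x read length."""
    if read_pairs < 0 or read_length < 0:
        raise ValueError("negative input")
    return _round2(read_pairs * 2 * read_length / 1e9, "half_even")


def pct_passed(raw: float, passed: float, mode: str = "half_even") -> float:
    """Percentage of raw reads surviving quality filtering, 2 decimals.

    ``mode='truncate'`` chops instead of rounding — published QC tables mix
    the two conventions across rows.
    """
    if passed > raw:
        raise ValueError(f"passed reads ({passed}) exceed raw reads ({raw})")
    if raw <= 0:
        raise ValueError("raw read count must be positive")
    return _round2(100.0 * passed / raw, mode)


def coverage(total_bases: float, genome_size: float) -> int:
    """Fold genome coverage at integer precision (the 'NX' of a run table)."""
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if total_bases < 0:
        raise ValueError("negative base count")
    return int(round(total_bases / genome_size))


def format_coverage(total_bases: float, genome_size: float) -> str:
    return f"{coverage(total_bases, genome_size)}X"
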