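"""Amplicon length-window filtering and retention accounting.

Full-length 16S rRNA amplicons (V1–V9, ~1.5 kb) outside the expected size
window are discarded before clustering; the window is inclusive at both
ends, so reads of exactly ``min_len`` or ``max_len`` are retained.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_EVEN, Decimal

import numpy as np

from .errors import ConfigError, InputError


@dataclass(frozen=True)
class QcConfig:
    min_len: int = 1200
    max_len: int = 1600

    def __post_init__(self):
        if not 0 < self.min_len <= self.max_len:
            raise ConfigError("require 0 < min_len <= max_len")


@dataclass(frozen=True)
class QcSummary:
    raw_count: int
    retained_count: int
    retention_pct: float  # 100*retained/raw, half-even to 2 decimals


def length_filter(lengths, cfg: QcConfig = QcConfig()) -> np.ndarray:
    """Boolean keep-mask: True where ``min_len <= length <= max_len``."""
    arr = np.asarray(lengths)
    if arr.size and arr.min() < 0:
        raise InputError("negative read length")
    return (arr >= cfg.min_len) & (arr <= cfg.max_len) if arr.size else np.zeros(0, dtype=bool)


def qc_retention_summary(raw_count: int, retained_count: int) -> QcSummary:
    """Retention summary with the percentage rounded half-even to 2 dp."""
    if raw_count < 0 or retained_count < 0:
        raise InputError("counts must be nonnegative")
    if retained_count > raw_count:
        raise InputError("retained_count exceeds raw_count")
    if raw_count == 0:
        raise InputError("retention percentage undefined for raw_count = 0")
    pct = (Decimal(retained_count) * 100 / Decimal(raw_count)).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_EVEN
    )
    return QcSummary(raw_count, retained_count, float(pct))


def run_qc(lengths, cfg: QcConfig = QcConfig()) -> QcSummary:
    """Filter *lengths* and summarise retention in one step."""
    mask = length_filter(lengths, cfg)
    return qc_retention_summary(int(np.size(lengths)), int(mask.sum()))
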