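"""Community profiling over a sample × OPU count table.

Relative abundance, per-OPU prevalence, prevalence-threshold core-microbiota
detection, per-category abundance summaries and per-sample richness.  The
core criterion defaults to strict "present in more than 90% of samples",
with a toggle for the >=-flavoured convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError
from .opu import Opu


@dataclass
class AbundanceTable:
    """Sample × OPU nonnegative integer counts (samples are rows)."""

    counts: pd.DataFrame

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise InputError("duplicate sample or OPU labels")
        vals = df.to_numpy()
        if vals.size == 0:
            raise InputError("empty abundance table")
        if (vals < 0).any():
            raise InputError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise InputError("counts must be integers")
        if (vals.sum(axis=1) == 0).any():
            bad = df.index[vals.sum(axis=1) == 0].tolist()
            raise InputError(f"all-zero sample rows: {bad[:5]}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def opus(self) -> list[str]:
        return list(self.counts.columns)

    @classmethod
    def from_tsv(cls, path) -> "AbundanceTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def to_tsv(self, path) -> None:
        self.counts.astype(int).to_csv(path, sep="\t")


@dataclass(frozen=True)
class CoreConfig:
    prevalence_threshold: float = 0.90
    strict: bool = True  # strict: prevalence > threshold; else >=

    def __post_init__(self):
        if not 0 < self.prevalence_threshold <= 1:
            raise ConfigError("prevalence_threshold must be in (0, 1]")


@dataclass(frozen=True)
class CoreResult:
    core_opus: tuple[str, ...]
    mean_abundance_pct: float  # across-sample mean of the core set's summed rel. abundance
    sd_abundance_pct: float


@dataclass(frozen=True)
class CategorySummary:
    n_opus: int
    mean_abundance_pct: float


def relative_abundance(table: AbundanceTable) -> pd.DataFrame:
    """Row-normalised fractions; every row sums to 1."""
    counts = table.counts.astype(float)
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        raise InputError("all-zero sample row")
    return counts.div(totals, axis=0)


def prevalence_table(table: AbundanceTable) -> pd.Series:
    """Per-OPU fraction of samples in which the OPU has count > 0."""
    return (table.counts > 0).mean(axis=0)


def detect_core(table: AbundanceTable, cfg: CoreConfig = CoreConfig()) -> CoreResult:
    """Core OPUs by prevalence plus the mean ± sd of their summed abundance.

    The abundance summary is computed per sample (sum of the core OPUs'
    relative abundances) and then averaged across samples; sd uses n−1.
    """
    prev = prevalence_table(table)
    if cfg.strict:
        core = prev.index[prev > cfg.prevalence_threshold]
    else:
        core = prev.index[prev >= cfg.prevalence_threshold]
    core = tuple(sorted(core))
    if not core:
        return CoreResult(core, 0.0, 0.0)
    per_sample = relative_abundance(table)[list(core)].sum(axis=1) * 100.0
    sd = float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0
    return CoreResult(core, float(per_sample.mean()), sd)


def summarize_categories(
    opus: Union[Sequence[Opu], Mapping[str, str]],
    table: AbundanceTable,
) -> dict[str, CategorySummary]:
    """Per-category OPU counts and mean relative-abundance shares (percent).

    Accepts either classified :class:`Opu` objects or an ``opu_id -> category``
    mapping.  The share of a category is the across-sample mean of its
    per-sample summed relative abundance; shares total 100% up to rounding.
    """
    if isinstance(opus, Mapping):
        cat_of = dict(opus)
    else:
        cat_of = {}
        for o in opus:
            if o.category is None:
                raise InputError(f"{o.opu_id} has no category")
            cat_of[o.opu_id] = o.category.value
    missing = [c for c in table.opus if c not in cat_of]
    if missing:
        raise InputError(f"OPUs without a category: {missing[:5]}")

    rel = relative_abundance(table)
    out: dict[str, CategorySummary] = {}
    for cat in sorted(set(cat_of[c] for c in table.opus)):
        cols = [c for c in table.opus if cat_of[c] == cat]
        share = float(rel[cols].sum(axis=1).mean() * 100.0)
        out[cat] = CategorySummary(n_opus=len(cols), mean_abundance_pct=share)
    return out


def richness_stats(table: AbundanceTable) -> tuple[float, float]:
    """Mean ± sd (n−1) of the per-sample number of OPUs with count > 0."""
    per_sample = (table.counts > 0).sum(axis=1)
    sd = float(per_sample.std(ddof=1)) if len(per_sample) > 1 else 0.0
    return float(per_sample.mean()), sd
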