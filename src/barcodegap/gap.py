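"""Distribution summaries and the barcode-gap quantile stress test.

The barcode gap is the separation between the intra-specific and
inter-specific pairwise distance distributions of a marker.  Real
datasets routinely contain outliers that drive the minimum
inter-specific distance to zero, so the naive gap (min(inter) −
max(intra)) is uninformative.  The stress test instead tightens
quantiles around both distributions: at level p it compares the upper
p-quantile of the intra pool with the lower (1−p)-quantile of the inter
pool,

    gap(p) = Q_inter(1 − p) − Q_intra(p),       p ∈ {0.85, 0.90, 0.95}.

A positive value is the size of the gap; a negative value means the
distributions overlap at that stringency.  As p rises toward 1 the
quantiles approach the raw extremes and the gap shrinks or vanishes.

Quantiles are type-7 (linear interpolation of order statistics,
h = (n−1)p + 1) and variances are sample variances (n−1 denominator),
matching the defaults of the R environment in which this style of
analysis is conventionally run.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from barcodegap.partition import DistancePools

logger = logging.getLogger(__name__)

#: Stress-test levels used throughout: 85%, 90% and 95%.
DEFAULT_LEVELS = (0.85, 0.90, 0.95)

#: Quantile grid reported by :func:`summarize`; includes the lower tails
#: used for inter pools and the upper tails used for intra pools.
DEFAULT_QUANTILE_GRID = (0.05, 0.075, 0.10, 0.15, 0.85, 0.90, 0.925, 0.95)


def quantile(values: Sequence[float], p: float) -> float:
    """Type-7 sample quantile: linear interpolation, h = (n−1)·p + 1.

    Raises ``ValueError`` for an empty list or p outside [0, 1].
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("quantile of an empty list")
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"probability {p} outside [0, 1]")
    return float(np.quantile(vals, p, method="linear"))


@dataclass(frozen=True)
class SummaryStats:
    """n, mean, median, sample variance and a quantile grid for one pool."""

    n: int
    mean: float
    median: float
    variance: float
    quantiles: Mapping[float, float]

    def __post_init__(self) -> None:
        if self.variance < 0:
            raise ValueError("variance must be non-negative")
        probs = sorted(self.quantiles)
        vals = [self.quantiles[p] for p in probs]
        if any(b < a - 1e-12 for a, b in zip(vals, vals[1:])):
            raise ValueError("quantiles must be non-decreasing in probability")


def summarize(
    pool: Sequence[float],
    quantile_grid: Sequence[float] = DEFAULT_QUANTILE_GRID,
) -> SummaryStats:
    """Summarise one distance pool.

    Sample variance uses the n−1 denominator; a single-value pool gets
    variance 0 with a warning (singleton species are deliberately kept in
    datasets, so one-pair pools occur).
    """
    vals = np.asarray(pool, dtype=float)
    if vals.size == 0:
        raise ValueError("cannot summarise an empty pool")
    if vals.size == 1:
        logger.warning("pool of size 1: variance reported as 0")
        var = 0.0
    else:
        var = float(np.var(vals, ddof=1))
    return SummaryStats(
        n=int(vals.size),
        mean=float(np.mean(vals)),
        median=float(np.median(vals)),
        variance=var,
        quantiles={p: quantile(vals, p) for p in quantile_grid},
    )


@dataclass(frozen=True)
class GapAssessment:
    """The gap verdict at one quantile level.

    ``intra_upper`` is the intra pool's p-quantile and ``inter_lower``
    the inter pool's (1−p)-quantile (one-sided convention) or the
    corresponding central-interval endpoints (two-sided).  The gap is
    their difference; it is "present" iff strictly positive.  The
    midpoint is reported regardless of presence — it is the natural
    clustering-cutoff candidate when a gap exists.
    """

    level: float
    intra_upper: float
    inter_lower: float

    @property
    def gap_size(self) -> float:
        return self.inter_lower - self.intra_upper

    @property
    def present(self) -> bool:
        return self.gap_size > 0.0

    @property
    def midpoint(self) -> float:
        return (self.intra_upper + self.inter_lower) / 2.0


def stress_test(
    pools: DistancePools,
    levels: Iterable[float] = DEFAULT_LEVELS,
    two_sided: bool = False,
) -> list[GapAssessment]:
    """Assess the barcode gap at each quantile level.

    One-sided (default): intra at p vs inter at 1−p.  Two-sided reads
    "quantiles around the distribution" as central intervals: intra at
    (1+p)/2 vs inter at (1−p)/2.  Both conventions shrink the gap as p
    grows.  Raises ``ValueError`` if either pool is empty.
    """
    if not pools.intra:
        raise ValueError(
            f"empty intra pool ({pools.dataset_name}/{pools.region}): "
            "no same-species pairs with defined distances"
        )
    if not pools.inter:
        raise ValueError(
            f"empty inter pool ({pools.dataset_name}/{pools.region}): "
            "no between-species pairs with defined distances"
        )
    out = []
    for p in levels:
        if not 0.5 < p < 1.0:
            raise ValueError(f"stress-test level {p} must lie in (0.5, 1)")
        if two_sided:
            hi, lo = (1.0 + p) / 2.0, (1.0 - p) / 2.0
        else:
            hi, lo = p, 1.0 - p
        out.append(
            GapAssessment(
                level=p,
                intra_upper=quantile(pools.intra, hi),
                inter_lower=quantile(pools.inter, lo),
            )
        )
    return out


def gap_midpoint(assessment: GapAssessment) -> float:
    """Midpoint of the gap interval, (intra_upper + inter_lower) / 2.

    Defined regardless of gap presence; multiplied by 100 it is the
    percent sequence-divergence cutoff a clustering workflow would use.
    """
    return assessment.midpoint


def build_report(
    pools_by_dataset: Mapping[str, Mapping[str, DistancePools]],
    levels: Iterable[float] = DEFAULT_LEVELS,
    two_sided: bool = False,
    ntaxa: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Stress-test table: one row per dataset, Gap?/Size per region × level.

    *pools_by_dataset* maps dataset name → region → pools.  The footer row
    (``dataset == "__footer__"``) carries, per region × level, the count of
    gap-positive datasets and the mean gap size among those only.  Sizes
    are rounded to 4 decimals, so a tiny positive gap may display 0.0.
    """
    levels = list(levels)
    datasets = list(pools_by_dataset)
    if not datasets:
        raise ValueError("no datasets to report")
    regions: list[str] = []
    for ds in datasets:
        for r in pools_by_dataset[ds]:
            if r not in regions:
                regions.append(r)

    rows = []
    for ds in datasets:
        pools_by_region = pools_by_dataset[ds]
        any_pool = next(iter(pools_by_region.values()))
        row: dict[str, object] = {
            "dataset": ds,
            "ntaxa": (ntaxa or {}).get(ds, any_pool.n_species),
            "nseq": any_pool.n_sequences,
        }
        for region in regions:
            if region not in pools_by_region:
                continue
            for a in stress_test(pools_by_region[region], levels, two_sided):
                key = f"{region}_{int(round(a.level * 100))}"
                row[f"{key}_gap"] = a.present
                row[f"{key}_size"] = round(a.gap_size, 4)
        rows.append(row)

    footer: dict[str, object] = {"dataset": "__footer__", "ntaxa": "", "nseq": ""}
    for region in regions:
        for p in levels:
            key = f"{region}_{int(round(p * 100))}"
            flags = [r.get(f"{key}_gap") for r in rows]
            sizes = [
                r[f"{key}_size"]
                for r, f in zip(rows, flags)
                if f is True
            ]
            footer[f"{key}_gap"] = sum(1 for f in flags if f is True)
            footer[f"{key}_size"] = (
                round(float(np.mean(sizes)), 4) if sizes else math.nan
            )
    rows.append(footer)
    return pd.DataFrame(rows)


def build_cutoff_table(
    pools_by_dataset: Mapping[str, Mapping[str, DistancePools]],
    level: float = 0.95,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Cutoff table: gap presence and midpoint (in percent) per region.

    The midpoint of the gap interval at the given level — conventionally
    95% on raw distances — approximates the centre of the proposed
    barcode gap and hence a candidate clustering cutoff.
    """
    rows = []
    for ds, pools_by_region in pools_by_dataset.items():
        row: dict[str, object] = {"dataset": ds}
        for region, pools in pools_by_region.items():
            (a,) = stress_test(pools, [level], two_sided)
            row[f"{region}_gap"] = a.present
            row[f"{region}_midpoint_pct"] = round(a.midpoint * 100.0, 1)
        rows.append(row)
    return pd.DataFrame(rows)
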