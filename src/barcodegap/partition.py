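"""Pooling pairwise distances into intra- and inter-specific distributions.

Each unordered pair of distinct sequences contributes exactly one value:
to the intra pool when both members carry the same species label, to the
inter pool otherwise.  Undefined (NaN) distances are excluded but
counted, so pool sizes always reconcile with C(N, 2).

`relabel` re-partitions the same sequences under an alternative species
hypothesis — merging labels ("lumping") or renaming toward a finer
scheme ("splitting") — so the pools of competing taxonomies can be
compared on identical pair sets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd

from barcodegap.alignment_io import SpeciesPartition
from barcodegap.distance import DistanceMatrix


@dataclass(frozen=True)
class DistancePools:
    """Flattened intra/inter distance values for one dataset/region/model.

    Invariant: ``len(intra) + len(inter) + n_undefined_excluded`` equals
    C(N, 2) over the N sequences in the source matrix.
    """

    dataset_name: str
    region: str
    model: str
    partition_name: str
    intra: tuple[float, ...]
    inter: tuple[float, ...]
    n_undefined_excluded: int = 0
    n_sequences: int = 0
    n_species: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences:
            expected = math.comb(self.n_sequences, 2)
            total = len(self.intra) + len(self.inter) + self.n_undefined_excluded
            if total != expected:
                raise ValueError(
                    f"pool sizes {total} do not reconcile with "
                    f"C({self.n_sequences},2) = {expected}"
                )
        if any(v < 0 for v in self.intra) or any(v < 0 for v in self.inter):
            raise ValueError("pooled distances must be non-negative")

    def to_dataframe(self) -> pd.DataFrame:
        """Long format: dataset, region, model, partition, type, distance."""
        rows = [
            (self.dataset_name, self.region, self.model, self.partition_name,
             kind, v)
            for kind, pool in (("intra", self.intra), ("inter", self.inter))
            for v in pool
        ]
        return pd.DataFrame(
            rows,
            columns=["dataset", "region", "model", "partition", "type",
                     "distance"],
        )


def split_pools(
    matrix: DistanceMatrix,
    partition: SpeciesPartition,
    dataset_name: str | None = None,
    region: str = "custom",
) -> DistancePools:
    """Split a distance matrix into intra- and inter-specific pools.

    Every matrix id must be labelled in *partition*; unordered pairs are
    counted once, self-pairs never.
    """
    missing = [i for i in matrix.ids if i not in partition.assignments]
    if missing:
        raise KeyError(
            f"partition {partition.name!r} lacks labels for: {missing}"
        )
    labels = [partition.assignments[i] for i in matrix.ids]
    intra, inter = [], []
    n_undef = 0
    for i, j in combinations(range(matrix.n), 2):
        d = matrix.values[i, j]
        if np.isnan(d):
            n_undef += 1
        elif labels[i] == labels[j]:
            intra.append(float(d))
        else:
            inter.append(float(d))
    return DistancePools(
        dataset_name=dataset_name or "dataset",
        region=region,
        model=matrix.model,
        partition_name=partition.name,
        intra=tuple(intra),
        inter=tuple(inter),
        n_undefined_excluded=n_undef,
        n_sequences=matrix.n,
        n_species=len(set(labels)),
    )


def relabel(
    partition: SpeciesPartition,
    merge_map: Mapping[str, str],
    name: str,
    allow_partial: bool = True,
) -> SpeciesPartition:
    """Apply a label → label map to produce an alternative partition.

    A many-to-one map lumps species; with ``allow_partial`` (default)
    labels absent from the map pass through unchanged, otherwise every
    label present in *partition* must be mapped.
    """
    present = set(partition.assignments.values())
    unmapped = present - set(merge_map)
    if unmapped and not allow_partial:
        raise KeyError(f"merge map does not cover labels: {sorted(unmapped)}")
    assignments = {
        sid: merge_map.get(lab, lab) for sid, lab in partition.assignments.items()
    }
    return SpeciesPartition(name=name, assignments=assignments)


def merge_closest_species(
    matrix: DistanceMatrix,
    partition: SpeciesPartition,
    n_merges: int = 2,
    name: str = "lumping",
) -> SpeciesPartition:
    """Lump the *n_merges* closest disjoint species pairs into joint taxa.

    Distance between species is the mean of their defined between-member
    pairwise distances.  This mimics how distance-based partitioners merge
    sister taxa when "lumping": the merged pairs are the most similar ones,
    so their former inter-specific distances — the low tail of the inter
    pool — become intra-specific.
    """
    labels = [partition.assignments[i] for i in matrix.ids]
    species = sorted(set(labels))
    means: dict[tuple[str, str], float] = {}
    for a, b in combinations(species, 2):
        idx_a = [i for i, l in enumerate(labels) if l == a]
        idx_b = [i for i, l in enumerate(labels) if l == b]
        vals = matrix.values[np.ix_(idx_a, idx_b)]
        if np.all(np.isnan(vals)):
            continue
        means[(a, b)] = float(np.nanmean(vals))
    merge_map: dict[str, str] = {}
    used: set[str] = set()
    for (a, b), _ in sorted(means.items(), key=lambda kv: kv[1]):
        if a in used or b in used:
            continue
        merge_map[a] = merge_map[b] = f"{name}_{a}"
        used |= {a, b}
        if len(used) >= 2 * n_merges:
            break
    return relabel(partition, merge_map, name)


def concatenate_pools(pools: list[DistancePools], name: str = "overall") -> DistancePools:
    """Pair-weighted pooling across datasets: concatenate the value lists.

    Datasets with more sequence pairs dominate the overall distributions
    in proportion to their pair counts; per-dataset averaging is the
    caller's alternative (average the per-pool summaries instead).
    """
    if not pools:
        raise ValueError("no pools to concatenate")
    regions = {p.region for p in pools}
    models = {p.model for p in pools}
    if len(models) > 1:
        raise ValueError(f"cannot pool across models: {sorted(models)}")
    return DistancePools(
        dataset_name=name,
        region=regions.pop() if len(regions) == 1 else "custom",
        model=models.pop(),
        partition_name=name,
        intra=tuple(v for p in pools for v in p.intra),
        inter=tuple(v for p in pools for v in p.inter),
        n_undefined_excluded=sum(p.n_undefined_excluded for p in pools),
    )
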