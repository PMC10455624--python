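"""Pairwise genetic distances with pairwise deletion.

Implements the raw proportion of differing sites (p-distance) and the
Kimura two-parameter (K80) correction, which distinguishes transitions
(A↔G, C↔T) from transversions:

    d = -(1/2) * ln((1 - 2P - Q) * sqrt(1 - 2Q))

where, per pair of sequences, P and Q are the proportions of comparable
sites showing a transition and a transversion respectively.  "Pairwise
deletion" means a site is dropped only for the pairs in which either
member carries a gap or an ambiguous base; the column still contributes
to every other pair.

A site is comparable for a pair iff both characters are unambiguous
bases (A, C, G, T).  IUPAC partial ambiguities (R, Y, ...) are treated as
missing for that pair; this strict rule keeps P and Q well defined and
is a documented divergence from distance routines that weight partial
ambiguities fractionally.

Distances that cannot be computed — zero comparable overlap, or a K80
log-domain violation under saturation — are carried as NaN ("undefined"),
never silently dropped: downstream pooling counts them.

Patristic (cophenetic) distances between the tips of a phylogram are the
third model: the sum of branch lengths along the unique tip-to-tip path.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from barcodegap.alignment_io import AlignedSequenceSet

logger = logging.getLogger(__name__)

MODELS = ("raw", "k80", "cophenetic")

# A,G are purines (even codes), C,T pyrimidines (odd codes): a mismatch is a
# transition iff the codes share parity.
_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


class DistanceError(ValueError):
    """Raised for inputs on which no distance matrix can be built."""


@dataclass(frozen=True)
class PairSiteCounts:
    """Per-pair site classification under pairwise deletion.

    ``n_comparable`` counts sites where both sequences have an unambiguous
    base; of those, ``n_transition`` differ by A↔G or C↔T and
    ``n_transversion`` by any other substitution.
    """

    n_comparable: int
    n_transition: int
    n_transversion: int

    def __post_init__(self) -> None:
        if min(self.n_comparable, self.n_transition, self.n_transversion) < 0:
            raise ValueError("site counts must be non-negative")
        if self.n_transition + self.n_transversion > self.n_comparable:
            raise ValueError("more mismatches than comparable sites")

    @property
    def P(self) -> float:
        """Transition proportion; 0.0 when there is no overlap."""
        return self.n_transition / self.n_comparable if self.n_comparable else 0.0

    @property
    def Q(self) -> float:
        """Transversion proportion; 0.0 when there is no overlap."""
        return self.n_transversion / self.n_comparable if self.n_comparable else 0.0


def _encode(rows: tuple[str, ...]) -> np.ndarray:
    mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
    return _CODE[mat].reshape(len(rows), -1)


def classify_pair_sites(row_a: str, row_b: str) -> PairSiteCounts:
    """Classify the aligned sites of one sequence pair.

    Raises ``ValueError`` if the rows have different lengths.
    """
    if len(row_a) != len(row_b):
        raise ValueError(
            f"aligned rows differ in length: {len(row_a)} vs {len(row_b)}"
        )
    a = _CODE[np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)]
    comparable = (a < 4) & (b < 4)
    mismatch = comparable & (a != b)
    transition = mismatch & ((a & 1) == (b & 1))
    return PairSiteCounts(
        n_comparable=int(comparable.sum()),
        n_transition=int(transition.sum()),
        n_transversion=int(mismatch.sum() - transition.sum()),
    )


def p_distance(counts: PairSiteCounts) -> Optional[float]:
    """Raw proportion of differing comparable sites.

    Returns ``None`` (undefined) when the pair shares no comparable sites.
    """
    if counts.n_comparable == 0:
        return None
    return (counts.n_transition + counts.n_transversion) / counts.n_comparable


def k80_distance(counts: PairSiteCounts) -> Optional[float]:
    """Kimura two-parameter distance, d = -½·ln((1-2P-Q)·√(1-2Q)).

    Returns ``None`` when undefined: no comparable sites, or saturation
    driving either log argument to zero or below.
    """
    if counts.n_comparable == 0:
        return None
    p, q = counts.P, counts.Q
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


@dataclass(frozen=True)
class DistanceMatrix:
    """A symmetric pairwise distance matrix tagged with its model.

    ``values`` holds substitutions/site (sequence models) or tip-to-tip
    path length (cophenetic); undefined entries are NaN.
    ``comparable_sites`` (sequence models only) holds the per-pair count
    of sites surviving pairwise deletion.
    """

    model: str
    ids: tuple[str, ...]
    values: np.ndarray
    comparable_sites: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("values must be square over ids")
        if not np.all(np.diag(self.values) == 0.0):
            raise ValueError("diagonal must be exactly zero")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("matrix must be symmetric")
        finite = ~np.isnan(self.values)
        if np.any(self.values[finite] < 0):
            raise ValueError("distances must be non-negative")
        self.values.setflags(write=False)
        if self.comparable_sites is not None:
            self.comparable_sites.setflags(write=False)

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def n_undefined_pairs(self) -> int:
        """Count of unordered pairs whose distance is undefined (NaN)."""
        iu = np.triu_indices(self.n, k=1)
        return int(np.isnan(self.values[iu]).sum())

    def get(self, id_a: str, id_b: str) -> float:
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        """Square matrix as a DataFrame with ids on both axes."""
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_long_dataframe(self) -> pd.DataFrame:
        """One row per unordered pair: id1, id2, model, distance, comparable_sites."""
        recs = []
        for i, j in combinations(range(self.n), 2):
            recs.append(
                {
                    "id1": self.ids[i],
                    "id2": self.ids[j],
                    "model": self.model,
                    "distance": self.values[i, j],
                    "comparable_sites": (
                        int(self.comparable_sites[i, j])
                        if self.comparable_sites is not None
                        else pd.NA
                    ),
                }
            )
        return pd.DataFrame.from_records(recs)


def filter_by_coverage(
    alignment: AlignedSequenceSet, min_fraction: float = 0.5
) -> tuple[AlignedSequenceSet, tuple[str, ...]]:
    """Drop sequences covering less than *min_fraction* of the region.

    Coverage is the fraction of columns that are not gaps ('-') or fully
    missing ('N').  Returns the filtered alignment and the dropped ids;
    mirrors the practice of excluding sequences spanning under half of a
    region before distance analysis.
    """
    kept, rows, dropped = [], [], []
    for sid, row in zip(alignment.ids, alignment.rows):
        informative = sum(c not in "-N" for c in row)
        if informative / alignment.width >= min_fraction:
            kept.append(sid)
            rows.append(row)
        else:
            dropped.append(sid)
    if dropped:
        logger.info(
            "coverage filter (%s/%s): dropped %d of %d sequences",
            alignment.dataset_name, alignment.region, len(dropped),
            alignment.n_sequences,
        )
    if not kept:
        raise DistanceError(
            f"coverage filter removed every sequence in {alignment.dataset_name}"
        )
    return (
        AlignedSequenceSet(
            alignment.dataset_name, alignment.region, tuple(kept), tuple(rows)
        ),
        tuple(dropped),
    )


def pairwise_matrix(
    alignment: AlignedSequenceSet,
    model: str = "k80",
    min_comparable_sites: int = 1,
) -> DistanceMatrix:
    """All-pairs distance matrix under ``raw`` or ``k80`` with pairwise deletion.

    Pairs with fewer than *min_comparable_sites* overlapping unambiguous
    sites are undefined (NaN).  Undefined entries are counted and logged,
    never dropped silently.
    """
    if model not in ("raw", "k80"):
        raise ValueError(f"pairwise_matrix supports raw|k80, got {model!r}")
    if alignment.n_sequences < 2:
        raise DistanceError("need at least 2 sequences for a distance matrix")
    if min_comparable_sites < 1:
        raise ValueError("min_comparable_sites must be >= 1")

    codes = _encode(alignment.rows)
    n = alignment.n_sequences
    values = np.zeros((n, n), dtype=float)
    comp = np.zeros((n, n), dtype=int)
    good = codes < 4
    parity = codes & 1

    for i in range(n - 1):
        # vectorised across all partners j > i
        both = good[i] & good[i + 1 :]
        mismatch = both & (codes[i] != codes[i + 1 :])
        transition = mismatch & (parity[i] == parity[i + 1 :])
        nc = both.sum(axis=1)
        nts = transition.sum(axis=1)
        ntv = mismatch.sum(axis=1) - nts
        with np.errstate(divide="ignore", invalid="ignore"):
            if model == "raw":
                d = (nts + ntv) / nc
            else:
                p = nts / nc
                q = ntv / nc
                w1 = 1.0 - 2.0 * p - q
                w2 = 1.0 - 2.0 * q
                d = np.where(
                    (w1 > 0) & (w2 > 0),
                    -0.5 * np.log(np.clip(w1, 1e-300, None)
                                  * np.sqrt(np.clip(w2, 1e-300, None))),
                    np.nan,
                )
        d = np.where(nc >= min_comparable_sites, d, np.nan)
        values[i, i + 1 :] = d
        values[i + 1 :, i] = d
        comp[i, i + 1 :] = nc
        comp[i + 1 :, i] = nc

    matrix = DistanceMatrix(
        model=model, ids=alignment.ids, values=values, comparable_sites=comp
    )
    if matrix.n_undefined_pairs:
        logger.info(
            "%s/%s %s matrix: %d of %d pairs undefined",
            alignment.dataset_name, alignment.region, model,
            matrix.n_undefined_pairs, n * (n - 1) // 2,
        )
    return matrix


def cophenetic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Patristic distances: branch-length path sums between every tip pair.

    The tree must carry branch lengths on all non-root edges (enforced by
    :func:`barcodegap.alignment_io.read_tree`).
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise DistanceError("need at least 2 tips for a cophenetic matrix")
    for leaf in leaves:
        if leaf.edge.length is None:
            raise DistanceError(
                f"tip {leaf.taxon.label!r} has no branch length"
            )
    pdm = tree.phylogenetic_distance_matrix()
    ids = tuple(leaf.taxon.label for leaf in leaves)
    taxa = {leaf.taxon.label: leaf.taxon for leaf in leaves}
    n = len(ids)
    values = np.zeros((n, n), dtype=float)
    for i, j in combinations(range(n), 2):
        d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
        values[i, j] = values[j, i] = d
    return DistanceMatrix(model="cophenetic", ids=ids, values=values)
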