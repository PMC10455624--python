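"""Synthetic multi-species ITS alignment generator with known truth.

Emulates the structure of expertly curated fungal barcode datasets so
that every pipeline stage — distance models, pooling, the stress test —
can be exercised against analytically known expectations:

* several species per dataset, each with a configurable number of
  sequences (singletons allowed);
* within-species divergence well below between-species divergence;
* a transition/transversion bias (K80 process with ratio κ);
* region rate structure: a fast ITS1, a nearly frozen 5.8S and an
  intermediate ITS2, concatenated into the full barcode region;
* alignment gaps, either scattered or as ragged terminal ends.

Sequences evolve along an explicit individual-level tree.  Each species
hangs off the root by a stem of length ``inter_divergence / 2`` (star
species tree, the default, keeps expected pool means analytic; a
Yule-shaped species tree is available for more realistic topologies) and
each individual hangs off its species ancestor by a branch of
``intra_divergence / 2``.  Branch lengths are expected substitutions per
site at relative rate 1; per-region rates scale them.

Mutation uses the exact K80 transition probabilities for a branch of
length d (matrix-exponential endpoint sampling, not a Bernoulli
approximation), so the K80 distance estimator is the matched inverse of
the generator:

    P(transition)        = 1/4 + 1/4·e^(−4d/(κ+2)) − 1/2·e^(−2d(κ+1)/(κ+2))
    P(each transversion) = 1/4 − 1/4·e^(−4d/(κ+2))
"""

from __future__ import annotations

import io
import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from barcodegap.alignment_io import AlignedSequenceSet, SpeciesPartition, read_tree

_BASES = np.array(list("ACGT"))

#: Default aligned region lengths (columns), close to the mean aligned
#: lengths of curated macrofungal barcode matrices: ITS1 ≈ 333, 5.8S ≈ 175,
#: ITS2 ≈ 312, totalling ≈ 820 for the full region.
DEFAULT_REGION_LENGTHS = (333, 175, 312)

#: Relative substitution-rate multipliers (ITS1, 5.8S, ITS2): the ITS1
#: spacer evolves fastest, the 5.8S gene is conserved, ITS2 intermediate.
DEFAULT_REGION_RATES = (1.5, 0.1, 1.0)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic dataset.

    ``intra_divergence`` is the expected substitutions/site (at relative
    rate 1) separating two individuals of the same species;
    ``inter_divergence`` the expected divergence between two species
    ancestors.  A pair from different species is therefore expected at
    ``inter_divergence + intra_divergence``.  Defaults put within-species
    divergence well below between-species divergence, in the range
    typical of congeneric macrofungal barcode data.
    """

    n_species: int = 10
    seqs_per_species: int | Sequence[int] = 5
    region_lengths: tuple[int, int, int] = DEFAULT_REGION_LENGTHS
    region_rates: tuple[float, float, float] = DEFAULT_REGION_RATES
    inter_divergence: float = 0.055
    intra_divergence: float = 0.006
    kappa: float = 2.0
    gap_fraction: float = 0.02
    terminal_gaps: bool = False
    tree_shape: str = "star"
    seed: int = 0
    dataset_name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")
        counts = self.per_species_counts()
        if any(c < 1 for c in counts):
            raise ValueError("every species needs at least one sequence")
        if any(l <= 0 for l in self.region_lengths):
            raise ValueError("region lengths must be positive")
        if any(r < 0 for r in self.region_rates):
            raise ValueError("region rates must be non-negative")
        if not 0.0 <= self.gap_fraction < 0.5:
            raise ValueError("gap_fraction must lie in [0, 0.5)")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if self.inter_divergence < 0 or self.intra_divergence < 0:
            raise ValueError("divergences must be non-negative")
        if self.tree_shape not in ("star", "yule"):
            raise ValueError("tree_shape must be 'star' or 'yule'")
        if self.intra_divergence >= self.inter_divergence:
            warnings.warn(
                "intra_divergence >= inter_divergence: species will not be "
                "separated in distance space",
                stacklevel=2,
            )

    def per_species_counts(self) -> tuple[int, ...]:
        if isinstance(self.seqs_per_species, int):
            return (self.seqs_per_species,) * self.n_species
        counts = tuple(int(c) for c in self.seqs_per_species)
        if len(counts) != self.n_species:
            raise ValueError(
                f"seqs_per_species lists {len(counts)} species, "
                f"config says {self.n_species}"
            )
        return counts

    @property
    def n_sequences(self) -> int:
        return sum(self.per_species_counts())

    @property
    def total_length(self) -> int:
        return sum(self.region_lengths)

    def nrits_rate(self) -> float:
        """Length-weighted mean rate of the concatenated region."""
        l = np.asarray(self.region_lengths, dtype=float)
        r = np.asarray(self.region_rates, dtype=float)
        return float((l * r).sum() / l.sum())

    def region_rate(self, region: str) -> float:
        rates = {"ITS1": self.region_rates[0], "5.8S": self.region_rates[1],
                 "ITS2": self.region_rates[2], "nrITS": self.nrits_rate()}
        try:
            return rates[region]
        except KeyError:
            raise ValueError(f"unknown region {region!r}") from None


@dataclass(frozen=True)
class SimulatedDataset:
    """Alignments per region plus the generating truth."""

    config: SimulationConfig
    alignments: dict[str, AlignedSequenceSet]  # nrITS, ITS1, 5.8S, ITS2
    partition: SpeciesPartition
    tree_newick: str

    @property
    def tree(self):
        return read_tree(self.tree_newick)


def _k80_step(codes: np.ndarray, d: float, kappa: float,
              rng: np.random.Generator) -> np.ndarray:
    """Evolve base codes (0..3 = ACGT) along a branch of length *d*."""
    if d <= 0:
        return codes.copy()
    e1 = math.exp(-4.0 * d / (kappa + 2.0))
    e2 = math.exp(-2.0 * d * (kappa + 1.0) / (kappa + 2.0))
    p_ti = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv = 0.25 - 0.25 * e1  # each of the two transversion targets
    u = rng.random(codes.shape)
    out = codes.copy()
    # transition partner: A<->G, C<->T  (xor 2); transversion partners:
    # opposite parity (xor 1, xor 3)
    out = np.where(u < p_ti, codes ^ 2, out)
    out = np.where((u >= p_ti) & (u < p_ti + p_tv), codes ^ 1, out)
    out = np.where((u >= p_ti + p_tv) & (u < p_ti + 2 * p_tv), codes ^ 3, out)
    return out


def _species_stems(config: SimulationConfig,
                   rng: np.random.Generator) -> list[float]:
    """Root-to-ancestor distances per species.

    Star shape: every stem is inter_divergence / 2, so any two ancestors
    sit exactly inter_divergence apart.  Yule shape: stems are drawn from
    a pure-birth depth profile and rescaled to the same mean, so ancestor
    pair distances vary around inter_divergence.
    """
    half = config.inter_divergence / 2.0
    if config.tree_shape == "star":
        return [half] * config.n_species
    depths = rng.exponential(1.0, size=config.n_species)
    depths *= half / depths.mean()
    return list(depths)


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset: alignments, true partition and true tree.

    Deterministic for a fixed ``config.seed``.  Gap masking is applied to
    the concatenated matrix before slicing, so the per-region alignments
    are exact column slices of the emitted full-region alignment, as with
    real curated matrices.
    """
    rng = np.random.default_rng(config.seed)
    counts = config.per_species_counts()
    lengths = config.region_lengths
    rates = config.region_rates
    stems = _species_stems(config, rng)
    tip_len = config.intra_divergence / 2.0

    species_labels = [f"sp{s + 1:02d}" for s in range(config.n_species)]
    ids: list[str] = []
    assignments: dict[str, str] = {}
    seqs: list[np.ndarray] = []

    # root sequence per region, evolved down stems then tips
    roots = [rng.integers(0, 4, size=l).astype(np.int64) for l in lengths]
    for sp, stem, n_ind in zip(species_labels, stems, counts):
        ancestors = [
            _k80_step(root, stem * rate, config.kappa, rng)
            for root, rate in zip(roots, rates)
        ]
        for k in range(n_ind):
            sid = f"{sp}_{k + 1}"
            ids.append(sid)
            assignments[sid] = sp
            tips = [
                _k80_step(anc, tip_len * rate, config.kappa, rng)
                for anc, rate in zip(ancestors, rates)
            ]
            seqs.append(np.concatenate(tips))

    matrix = np.stack(seqs)  # (N, total_length) base codes
    chars = _BASES[matrix].astype("<U1")

    if config.gap_fraction > 0:
        total = config.total_length
        if config.terminal_gaps:
            for row in chars:
                n_mask = rng.binomial(total, config.gap_fraction)
                n_prefix = rng.integers(0, n_mask + 1)
                row[:n_prefix] = "-"
                if n_mask - n_prefix:
                    row[total - (n_mask - n_prefix):] = "-"
        else:
            mask = rng.random(chars.shape) < config.gap_fraction
            chars[mask] = "-"

    rows = tuple("".join(row) for row in chars)
    full = AlignedSequenceSet(config.dataset_name, "nrITS", tuple(ids), rows)

    bounds = np.concatenate([[0], np.cumsum(lengths)])
    alignments = {"nrITS": full}
    for name, lo, hi in zip(("ITS1", "5.8S", "ITS2"), bounds[:-1], bounds[1:]):
        alignments[name] = AlignedSequenceSet(
            config.dataset_name, name, tuple(ids),
            tuple(r[lo:hi] for r in rows),
        )

    partition = SpeciesPartition(name="true", assignments=assignments)
    tree_newick = _build_newick(species_labels, stems, counts, tip_len)
    return SimulatedDataset(config, alignments, partition, tree_newick)


def _build_newick(species: list[str], stems: list[float],
                  counts: Sequence[int], tip_len: float) -> str:
    clades = []
    for sp, stem, n in zip(species, stems, counts):
        tips = ",".join(f"{sp}_{k + 1}:{tip_len:.10g}" for k in range(n))
        if n == 1:
            clades.append(f"{sp}_1:{stem + tip_len:.10g}")
        else:
            clades.append(f"({tips}):{stem:.10g}")
    return f"({','.join(clades)});"


def expected_pool_means(
    config: SimulationConfig, region: str = "nrITS"
) -> tuple[float, float]:
    """Analytic expected (intra, inter) divergences for a star species tree.

    By additivity of expected path length, two conspecific individuals
    are separated by twice the tip branch and two heterospecific ones by
    the two tips plus both stems, all scaled by the region's relative
    rate.  The K80 distance estimator recovers these path lengths in
    expectation, so pipeline pool means should match within sampling
    error.
    """
    rate = config.region_rate(region)
    intra = config.intra_divergence * rate
    inter = (config.inter_divergence + config.intra_divergence) * rate
    return intra, inter


def write_bundle(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA per region, species map TSV, true newick and YAML metadata."""
    from barcodegap.alignment_io import write_alignment

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for region, aln in dataset.alignments.items():
        p = outdir / f"{dataset.config.dataset_name}_{region.replace('.', '')}.fasta"
        write_alignment(aln, p)
        paths[region] = p

    map_path = outdir / f"{dataset.config.dataset_name}_species.tsv"
    with open(map_path, "w") as fh:
        fh.write("# sequence id\tspecies\n")
        for sid in dataset.alignments["nrITS"].ids:
            fh.write(f"{sid}\t{dataset.partition.assignments[sid]}\n")
    paths["species_map"] = map_path

    tree_path = outdir / f"{dataset.config.dataset_name}_true.nwk"
    tree_path.write_text(dataset.tree_newick + "\n")
    paths["tree"] = tree_path

    meta = {
        "dataset_name": dataset.config.dataset_name,
        "seed": dataset.config.seed,
        "n_species": dataset.config.n_species,
        "seqs_per_species": list(dataset.config.per_species_counts()),
        "region_lengths": list(dataset.config.region_lengths),
        "region_rates": list(dataset.config.region_rates),
        "inter_divergence": dataset.config.inter_divergence,
        "intra_divergence": dataset.config.intra_divergence,
        "kappa": dataset.config.kappa,
        "gap_fraction": dataset.config.gap_fraction,
        "terminal_gaps": dataset.config.terminal_gaps,
        "tree_shape": dataset.config.tree_shape,
    }
    meta_path = outdir / f"{dataset.config.dataset_name}_meta.yaml"
    with open(meta_path, "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)
    paths["metadata"] = meta_path
    return paths
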