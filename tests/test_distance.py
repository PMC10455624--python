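import math
import shutil
import subprocess

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from barcodegap.alignment_io import AlignedSequenceSet
from barcodegap.distance import (
    DistanceError,
    DistanceMatrix,
    PairSiteCounts,
    classify_pair_sites,
    cophenetic_matrix,
    filter_by_coverage,
    k80_distance,
    p_distance,
    pairwise_matrix,
)
from barcodegap.alignment_io import read_tree
from conftest import random_alignment

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


def naive_pair_counts(a: str, b: str) -> PairSiteCounts:
    """Independent per-site loop oracle for site classification."""
    nc = nts = ntv = 0
    for x, y in zip(a, b):
        if x in "ACGT" and y in "ACGT":
            nc += 1
            if x != y:
                if (x, y) in TRANSITIONS:
                    nts += 1
                else:
                    ntv += 1
    return PairSiteCounts(nc, nts, ntv)


class TestClassifyPairSites:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("ACGT", "ACGT", (4, 0, 0)),
            ("ACGT", "GCGT", (4, 1, 0)),
            ("AC-TN", "ACGTA", (3, 0, 0)),
            ("ACGT", "TGCA", (4, 0, 4)),
            ("ACGT", "AGGT", (4, 0, 1)),  # C↔G is a transversion
        ],
    )
    def test_examples(self, a, b, expected):
        c = classify_pair_sites(a, b)
        assert (c.n_comparable, c.n_transition, c.n_transversion) == expected

    def test_iupac_ambiguity_excluded(self):
        c = classify_pair_sites("ARGT", "AAGT")
        assert c.n_comparable == 3

    def test_unequal_lengths(self):
        with pytest.raises(ValueError, match="length"):
            classify_pair_sites("ACG", "ACGT")

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_loop(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 40))
        a = "".join(rng.choice(list("ACGTN-RY"), size=n))
        b = "".join(rng.choice(list("ACGTN-RY"), size=n))
        assert classify_pair_sites(a, b) == naive_pair_counts(a, b)


class TestScalarDistances:
    def test_p_distance(self):
        assert p_distance(PairSiteCounts(4, 0, 0)) == 0.0
        assert p_distance(PairSiteCounts(4, 1, 0)) == 0.25
        assert p_distance(PairSiteCounts(0, 0, 0)) is None

    def test_k80_closed_form(self):
        # d = -0.5 * ln((1-2P-Q) * sqrt(1-2Q))
        assert k80_distance(PairSiteCounts(10, 0, 0)) == 0.0
        assert k80_distance(PairSiteCounts(10, 1, 0)) == pytest.approx(
            -0.5 * math.log(0.8), abs=1e-12
        )
        assert k80_distance(PairSiteCounts(10, 1, 0)) == pytest.approx(
            0.111572, abs=5e-7
        )
        assert k80_distance(PairSiteCounts(10, 0, 1)) == pytest.approx(
            -0.5 * math.log(0.9 * math.sqrt(0.8)), abs=1e-12
        )
        assert k80_distance(PairSiteCounts(10, 0, 1)) == pytest.approx(
            0.1084661, abs=5e-7
        )

    def test_k80_saturation_undefined(self):
        assert k80_distance(PairSiteCounts(10, 5, 0)) is None
        assert k80_distance(PairSiteCounts(10, 0, 5)) is None
        assert k80_distance(PairSiteCounts(0, 0, 0)) is None

    @given(st.integers(1, 200), st.integers(0, 200), st.integers(0, 200))
    @settings(max_examples=200, deadline=None)
    def test_k80_inflates_p(self, nc, nts, ntv):
        """Model correction never deflates: d_K80 >= d_raw when both defined."""
        if nts + ntv > nc:
            return
        c = PairSiteCounts(nc, nts, ntv)
        d_raw, d_k80 = p_distance(c), k80_distance(c)
        if d_raw is not None and d_k80 is not None:
            assert d_k80 >= d_raw - 1e-12


class TestPairwiseMatrix:
    def test_identical_sequences_zero(self):
        aln = AlignedSequenceSet.from_records(
            [("a", "ACGTAC"), ("b", "ACGTAC"), ("c", "ACGTAC")]
        )
        m = pairwise_matrix(aln, "k80")
        assert np.all(m.values == 0.0)
        assert m.ids == ("a", "b", "c")

    def test_requires_two_sequences(self):
        aln = AlignedSequenceSet.from_records([("a", "ACGT")])
        with pytest.raises(DistanceError):
            pairwise_matrix(aln)

    @pytest.mark.parametrize("model", ["raw", "k80"])
    def test_matches_per_pair_oracle(self, model):
        """Matrix equals independent per-pair, per-site recomputation."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            aln = random_alignment(rng)
            m = pairwise_matrix(aln, model)
            for i in range(aln.n_sequences):
                for j in range(i + 1, aln.n_sequences):
                    c = naive_pair_counts(aln.rows[i], aln.rows[j])
                    exp = p_distance(c) if model == "raw" else k80_distance(c)
                    got = m.values[i, j]
                    if exp is None:
                        assert math.isnan(got)
                    else:
                        assert got == pytest.approx(exp, abs=1e-12)
                    assert m.comparable_sites[i, j] == c.n_comparable

    def test_matrix_invariants(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            aln = random_alignment(rng)
            m = pairwise_matrix(aln, "k80")
            assert np.all(np.diag(m.values) == 0.0)
            assert np.allclose(m.values, m.values.T, equal_nan=True)
            finite = ~np.isnan(m.values)
            assert np.all(m.values[finite] >= 0)
            assert np.all(m.comparable_sites <= aln.width)

    def test_pairwise_deletion_locality(self):
        """Gapping a column in two sequences only perturbs pairs involving
        those sequences; entries among the untouched sequences are
        identical (unlike complete deletion, which would drop the column
        for everyone)."""
        rng = np.random.default_rng(3)
        aln = random_alignment(rng, n_seqs=6, n_cols=40, gap_prob=0.0)
        before = pairwise_matrix(aln, "raw")
        rows = list(aln.rows)
        rows[0] = "-" + rows[0][1:]
        rows[1] = "-" + rows[1][1:]
        after = pairwise_matrix(
            AlignedSequenceSet.from_records(list(zip(aln.ids, rows))), "raw"
        )
        untouched = np.ix_(range(2, 6), range(2, 6))
        assert np.array_equal(before.values[untouched], after.values[untouched])
        assert np.array_equal(before.comparable_sites[untouched],
                              after.comparable_sites[untouched])
        assert after.comparable_sites[0, 1] == before.comparable_sites[0, 1] - 1

    def test_min_comparable_sites(self):
        aln = AlignedSequenceSet.from_records(
            [("a", "AC--"), ("b", "A--T"), ("c", "ACGT")]
        )
        m = pairwise_matrix(aln, "raw", min_comparable_sites=2)
        assert math.isnan(m.get("a", "b"))  # only 1 shared site
        assert not math.isnan(m.get("a", "c"))
        assert m.n_undefined_pairs == 1

    def test_k80_at_least_raw_on_matrix(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, n_seqs=8, n_cols=50)
        raw = pairwise_matrix(aln, "raw").values
        k80 = pairwise_matrix(aln, "k80").values
        both = ~np.isnan(raw) & ~np.isnan(k80)
        assert np.all(k80[both] >= raw[both] - 1e-12)


class TestCoverageFilter:
    def test_drops_sparse_sequences(self):
        aln = AlignedSequenceSet.from_records(
            [("full", "ACGTACGTAC"), ("half", "ACGT------"),
             ("sparse", "AC--------")]
        )
        kept, dropped = filter_by_coverage(aln, 0.5)
        assert kept.ids == ("full",)
        assert set(dropped) == {"half", "sparse"}

    def test_boundary_is_inclusive(self):
        aln = AlignedSequenceSet.from_records(
            [("a", "ACGTA-----"), ("b", "ACGTACGTAC")]
        )
        kept, dropped = filter_by_coverage(aln, 0.5)
        assert "a" in kept.ids


@pytest.mark.skipif(shutil.which("Rscript") is None,
                    reason="Rscript not available")
class TestAgainstApe:
    """Cross-check against the independent reference distance routine in R."""

    def run_ape(self, fasta, model):
        script = (
            'suppressMessages(library(ape));'
            f'a <- read.dna("{fasta}", format="fasta");'
            f'd <- dist.dna(a, model="{model}", pairwise.deletion=TRUE);'
            'cat(as.vector(d), sep=",")'
        )
        out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        return [float(x) for x in out.stdout.strip().split(",")]

    @pytest.mark.parametrize("model,ape_model", [("raw", "raw"), ("k80", "K80")])
    def test_agreement_on_fixture(self, tmp_path, model, ape_model):
        rng = np.random.default_rng(99)
        aln = random_alignment(rng, n_seqs=6, n_cols=60, gap_prob=0.05)
        fasta = tmp_path / "x.fa"
        fasta.write_text(
            "".join(f">{i}\n{s}\n" for i, s in zip(aln.ids, aln.rows))
        )
        ours = pairwise_matrix(aln, model)
        theirs = self.run_ape(fasta, ape_model)
        # ape's dist object is column-major lower triangle
        k = 0
        for j in range(aln.n_sequences):
            for i in range(j + 1, aln.n_sequences):
                assert ours.values[i, j] == pytest.approx(
                    theirs[k], abs=1e-6, nan_ok=True
                )
                k += 1


def naive_patristic(tree):
    """All-pairs shortest path on the tree graph, via networkx."""
    import networkx as nx

    g = nx.Graph()
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue
        g.add_edge(id(edge.tail_node), id(edge.head_node), weight=edge.length)
    leaves = {leaf.taxon.label: id(leaf) for leaf in tree.leaf_node_iter()}
    lengths = dict(nx.all_pairs_dijkstra_path_length(g))
    return {
        (a, b): lengths[na][nb]
        for a, na in leaves.items()
        for b, nb in leaves.items()
    }


def random_tree(rng, n_tips):
    """Random binary newick with random branch lengths."""
    nodes = [f"T{i}:{rng.uniform(0.01, 1.0):.4f}" for i in range(n_tips)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.01, 1.0):.4f}")
    return nodes[0].rsplit(":", 1)[0] + ";"


class TestCophenetic:
    def test_manual_path_sums(self):
        m = cophenetic_matrix(read_tree("((A:0.1,B:0.2):0.05,C:0.3);"))
        assert m.get("A", "B") == pytest.approx(0.30)
        assert m.get("A", "C") == pytest.approx(0.45)
        assert m.get("B", "C") == pytest.approx(0.55)
        assert all(m.get(x, x) == 0.0 for x in "ABC")

    def test_star_tree(self):
        m = cophenetic_matrix(read_tree("(A:1,B:1,C:1);"))
        iu = np.triu_indices(3, 1)
        assert np.allclose(m.values[iu], 2.0)

    def test_matches_graph_shortest_path(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            n = int(rng.integers(3, 13))
            tree = read_tree(random_tree(rng, n))
            m = cophenetic_matrix(tree)
            oracle = naive_patristic(tree)
            for i, a in enumerate(m.ids):
                for j, b in enumerate(m.ids):
                    assert m.values[i, j] == pytest.approx(
                        oracle[(a, b)], abs=1e-9
                    )

    def test_four_point_condition(self):
        """Patristic matrices are additive: every quadruple satisfies the
        four-point condition."""
        from itertools import combinations

        rng = np.random.default_rng(23)
        tree = read_tree(random_tree(rng, 8))
        m = cophenetic_matrix(tree)
        d = m.values
        for i, j, k, l in combinations(range(8), 4):
            sums = sorted(
                [d[i, j] + d[k, l], d[i, k] + d[j, l], d[i, l] + d[j, k]]
            )
            assert sums[1] == pytest.approx(sums[2], abs=1e-9)
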