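"""Alignment, distances, NJ, reconciliation, contrasts, regression —
each against an independent oracle (brute-force DP, generating tree,
exhaustive reconciliation maps, closed forms, R's ape, normal equations)."""

import shutil
import subprocess
import textwrap

import dendropy
import numpy as np
import pytest

from spidrokit.phylo import (
    cluster_divergence,
    global_align,
    neighbor_joining,
    p_distance,
    pic,
    reconcile,
    regress,
)
from spidrokit.seqio import SequenceRecord


def _tree(nwk, rooted=True):
    t = dendropy.Tree.get(data=nwk, schema="newick", preserve_underscores=True)
    t.is_rooted = rooted
    return t


# ---------------------------------------------------------------------------
# alignment


def _nw_linear(a, b, match=1, mismatch=-1, gap=-1):
    """Textbook Needleman-Wunsch with linear gap cost (oracle)."""
    n, m = len(a), len(b)
    dp = np.zeros((n + 1, m + 1))
    dp[:, 0] = np.arange(n + 1) * gap
    dp[0, :] = np.arange(m + 1) * gap
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            dp[i, j] = max(dp[i - 1, j - 1] + s, dp[i - 1, j] + gap, dp[i, j - 1] + gap)
    return dp[n, m]


class TestGlobalAlign:
    def test_identical_sequences(self):
        aln = global_align("ACGTACGT", "ACGTACGT")
        assert "-" not in aln.gapped_a and aln.score == 8

    def test_single_gap(self):
        aln = global_align("ACGT", "ACT")
        assert aln.gapped_a.count("-") + aln.gapped_b.count("-") == 1

    def test_degapping_recovers_inputs(self):
        aln = global_align("GGAGAS", "GGAS")
        assert aln.gapped_a.replace("-", "") == "GGAGAS"
        assert aln.gapped_b.replace("-", "") == "GGAS"

    def test_score_matches_linear_gap_oracle(self, rng):
        for _ in range(25):
            a = "".join(rng.choice(list("ACGT"), size=12))
            b = "".join(rng.choice(list("ACGT"), size=12))
            got = global_align(a, b, gap_open=-1, gap_extend=-1).score
            assert got == pytest.approx(_nw_linear(a, b))


class TestPDistance:
    def test_identical_and_single_difference(self):
        assert p_distance(global_align("A" * 100, "A" * 100)) == 0.0
        b = "C" + "A" * 99
        assert p_distance(global_align("A" * 100, b)) == pytest.approx(0.01)

    def test_symmetry(self, rng):
        a = "".join(rng.choice(list("ACGT"), size=60))
        b = "".join(rng.choice(list("ACGT"), size=55))
        assert p_distance(global_align(a, b)) == pytest.approx(p_distance(global_align(b, a)))

    def test_gap_columns_excluded(self):
        from spidrokit.phylo import PairwiseAlignment

        aln = PairwiseAlignment("AC-GT", "ACCGA", 0)
        assert p_distance(aln) == pytest.approx(1 / 4)


class TestClusterDivergence:
    def test_identical_sequences(self):
        recs = [SequenceRecord(f"s{i}", "nucleotide", "ACGT" * 20) for i in range(4)]
        labels = {"s0": "x", "s1": "x", "s2": "y", "s3": "y"}
        within, between = cluster_divergence(recs, labels)
        assert within == {"x": 0.0, "y": 0.0} and between == 0.0

    def test_between_exceeds_within_for_diverged_clusters(self, rng):
        base = "".join(rng.choice(list("ACGT"), size=300))
        far = list(base)
        for i in rng.choice(300, size=30, replace=False):
            far[i] = "ACGT".replace(far[i], "")[rng.integers(3)]
        far = "".join(far)

        def noisy(seq, k):
            s = list(seq)
            for i in rng.choice(len(s), size=k, replace=False):
                s[i] = "ACGT".replace(s[i], "")[rng.integers(3)]
            return "".join(s)

        recs = [
            SequenceRecord("a1", "nucleotide", noisy(base, 2)),
            SequenceRecord("a2", "nucleotide", noisy(base, 2)),
            SequenceRecord("b1", "nucleotide", noisy(far, 2)),
            SequenceRecord("b2", "nucleotide", noisy(far, 2)),
        ]
        within, between = cluster_divergence(recs, {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
        assert between > max(within.values())

    def test_singleton_cluster_not_applicable(self):
        recs = [
            SequenceRecord("a", "nucleotide", "ACGT" * 10),
            SequenceRecord("b", "nucleotide", "ACGT" * 10),
        ]
        within, _ = cluster_divergence(recs, {"a": "x", "b": "y"})
        assert within == {"x": None, "y": None}


# ---------------------------------------------------------------------------
# neighbor joining


def _additive_matrix(nwk, labels):
    t = dendropy.Tree.get(data=nwk, schema="newick")
    pdm = t.phylogenetic_distance_matrix()
    tx = {l: t.taxon_namespace.get_taxon(l) for l in labels}
    return np.array([[pdm.distance(tx[a], tx[b]) for b in labels] for a in labels])


def _topology(tree):
    tree = tree.clone(depth=1)
    tree.update_bipartitions(suppress_unifurcations=True)
    return {frozenset(b.leafset_taxa(tree.taxon_namespace)[i].label
                      for i in range(len(b.leafset_taxa(tree.taxon_namespace))))
            for b in tree.bipartition_encoding}


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        labels = ["a", "b", "c"]
        dm = np.array([[0, 3, 5], [3, 0, 6], [5, 6, 0]], dtype=float)
        tree = neighbor_joining(labels, dm)
        # closed form: la = (dab+dac-dbc)/2 = 1, lb = 2, lc = 4
        edge = {t.taxon.label: t.edge.length for t in tree.leaf_node_iter()}
        assert edge == pytest.approx({"a": 1.0, "b": 2.0, "c": 4.0})

    def test_additive_five_taxon_exact_recovery(self):
        nwk = "((A:2,B:3):1,((C:4,D:1):2,E:6):1);"
        labels = ["A", "B", "C", "D", "E"]
        dm = _additive_matrix(nwk, labels)
        tree = neighbor_joining(labels, dm)
        # every pairwise tree distance must equal the input (additivity)
        pdm = tree.phylogenetic_distance_matrix()
        tx = {l: tree.taxon_namespace.get_taxon(l) for l in labels}
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                assert pdm.distance(tx[a], tx[b]) == pytest.approx(dm[i, j])

    def test_invalid_matrices_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            neighbor_joining(["a", "b", "c"], np.array([[0, 1, 2], [1, 0, 3], [9, 3, 0.0]]))
        with pytest.raises(ValueError):
            neighbor_joining(["a", "b"], np.array([[1.0, 1], [1, 0]]))


# ---------------------------------------------------------------------------
# reconciliation


def _brute_force_min_duplications(gene_tree, species_tree, leaf_species):
    """Minimum duplications over all consistent reconciliation maps."""
    sp_nodes = list(species_tree.preorder_node_iter())
    ancestors = {nd: set() for nd in sp_nodes}
    for nd in sp_nodes:
        a = nd
        while a is not None:
            ancestors[nd].add(a)
            a = a.parent_node
    sp_leaf = {nd.taxon.label: nd for nd in species_tree.leaf_node_iter()}
    gene_nodes = list(gene_tree.postorder_node_iter())

    lca_map = {}
    for g in gene_nodes:
        if g.is_leaf():
            lca_map[g] = sp_leaf[leaf_species[g.taxon.label]]
        else:
            c1, c2 = g.child_nodes()
            common = ancestors[lca_map[c1]] & ancestors[lca_map[c2]]
            lca_map[g] = min(common, key=lambda nd: -len(ancestors[nd]))

    internal = [g for g in gene_nodes if not g.is_leaf()]
    candidates = {g: sorted(ancestors[lca_map[g]], key=lambda nd: len(ancestors[nd]))
                  for g in internal}
    best = [None]

    def is_dup(mg, mc1, mc2):
        # speciation only if the children map into distinct child
        # subtrees of M(g); anything else is a duplication
        if mg is mc1 or mg is mc2:
            return True
        sides = []
        for mc in (mc1, mc2):
            for child in mg.child_nodes():
                if child in ancestors[mc]:
                    sides.append(child)
                    break
        return len(sides) < 2 or sides[0] is sides[1]

    def rec(idx, assign):
        if idx == len(internal):
            dups = 0
            for g in internal:
                mg = assign.get(g, lca_map[g])
                c1, c2 = g.child_nodes()
                if is_dup(mg, assign.get(c1, lca_map[c1]), assign.get(c2, lca_map[c2])):
                    dups += 1
            if best[0] is None or dups < best[0]:
                best[0] = dups
            return
        g = internal[idx]
        for cand in candidates[g]:
            ok = True
            for c in g.child_nodes():
                mc = assign.get(c, lca_map[c])
                if cand not in ancestors[mc]:
                    ok = False
                    break
            parent = g.parent_node
            if ok and parent is not None and parent in assign and assign[parent] not in ancestors[cand]:
                ok = False
            if ok:
                assign[g] = cand
                rec(idx + 1, assign)
                del assign[g]

    # enumerate top-down so the parent constraint is checkable
    internal.reverse()
    rec(0, {})
    return best[0]


class TestReconcile:
    def test_congruent_trees_no_events(self):
        st = _tree("((A,B),C);")
        gt = _tree("((a,b),c);")
        res = reconcile(gt, st, {"a": "A", "b": "B", "c": "C"})
        assert res.n_duplications == 0 and res.n_losses == 0

    def test_within_species_duplication(self):
        st = _tree("(A,B);")
        gt = _tree("((a1,a2),b);")
        res = reconcile(gt, st, {"a1": "A", "a2": "A", "b": "B"})
        assert res.n_duplications == 1

    def test_duplication_count_matches_brute_force(self, rng):
        st = _tree("(((A,B),(C,D)),(E,F));")
        cases = [
            "((((a,b),(c,d)),(e,f)),((a2,b2),c2));",
            "((a,a2),((b,c),(d,(e,f))));",
            "(((a,b),(a2,b2)),((c,d),(e,f)));",
        ]
        for nwk in cases:
            gt = _tree(nwk)
            leaf_map = {l.taxon.label: l.taxon.label[0].upper() for l in gt.leaf_node_iter()}
            res = reconcile(gt, st, leaf_map)
            assert res.n_duplications == _brute_force_min_duplications(gt, st, leaf_map)

    def test_invariant_to_label_permutation_within_species(self):
        st = _tree("((A,B),C);")
        gt1 = _tree("(((a1,a2),b),c);")
        gt2 = _tree("(((a2,a1),b),c);")
        m = {"a1": "A", "a2": "A", "b": "B", "c": "C"}
        assert reconcile(gt1, st, m).n_duplications == reconcile(gt2, st, m).n_duplications

    def test_unmapped_leaf_and_polytomy_errors(self):
        st = _tree("((A,B),C);")
        with pytest.raises(ValueError, match="no species mapping"):
            reconcile(_tree("((a,b),c);"), st, {"a": "A", "b": "B"})
        with pytest.raises(ValueError, match="binary"):
            reconcile(_tree("(a,b,c);"), st, {"a": "A", "b": "B", "c": "C"})


# ---------------------------------------------------------------------------
# contrasts


class TestPic:
    def test_two_tip_closed_form(self):
        t = _tree("(A:2.0,B:2.0);")
        cs = pic(t, {"A": 5.0, "B": 1.0})
        assert cs.contrasts == [(4.0, 4.0)]
        assert cs.standardized == pytest.approx([2.0])

    def test_three_tip_hand_computation(self):
        # ((A:1,B:1):1,C:2); x = 2, 0, 1
        t = _tree("((A:1.0,B:1.0):1.0,C:2.0);")
        cs = pic(t, {"A": 2.0, "B": 0.0, "C": 1.0})
        assert cs.n_tips == 3 and len(cs.contrasts) == 2
        # first contrast A-B: 2, var 2; ancestral value 1, branch 1 + 1/2
        # second contrast anc-C: 0, var 1.5 + 2
        assert cs.contrasts[0] == pytest.approx((2.0, 2.0))
        assert cs.contrasts[1] == pytest.approx((0.0, 3.5))

    def test_matches_r_ape_pic(self, tmp_path):
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the ape cross-check")
        nwk = "((A:1.5,B:0.5):1.0,(C:2.0,D:1.0):0.5);"
        traits = {"A": 3.1, "B": -1.2, "C": 0.7, "D": 2.4}
        script = tmp_path / "pic.R"
        script.write_text(textwrap.dedent("""
            suppressMessages(library(ape))
            t <- read.tree(text="((A:1.5,B:0.5):1.0,(C:2.0,D:1.0):0.5);")
            x <- c(A=3.1, B=-1.2, C=0.7, D=2.4)
            cat(sort(pic(x, t)), sep="\\n")
        """))
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, check=True)
        expected = sorted(abs(float(v)) for v in out.stdout.split())
        cs = pic(_tree(nwk), traits)
        got = sorted(abs(v) for v in cs.standardized)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_bm_simulation_contrast_variance(self):
        from spidrokit.synth import simulate_bm_traits

        taxa = [f"t{i}" for i in range(16)]
        nwk = taxa
        while len(nwk) > 1:
            nwk = [f"({nwk[i]}:1.0,{nwk[i+1]}:1.0)" for i in range(0, len(nwk), 2)]
        tree = _tree(nwk[0] + ";")
        sigma2 = 2.5
        stds = []
        for seed in range(500):
            traits = simulate_bm_traits(tree, sigma2, seed=seed)
            stds.extend(pic(tree, traits).standardized)
        var = np.var(stds)
        se = sigma2 * np.sqrt(2 / len(stds))
        assert abs(var - sigma2) < 2 * se

    def test_missing_trait_errors(self):
        with pytest.raises(ValueError, match="missing trait"):
            pic(_tree("(A:1,B:1);"), {"A": 1.0})


# ---------------------------------------------------------------------------
# regression


class TestRegress:
    def test_exact_line(self):
        x = [0.0, 1, 2, 3]
        r = regress(x, [2 * v for v in x])
        assert r.slope == pytest.approx(2) and r.r_squared == pytest.approx(1)

    def test_normal_equations_oracle(self):
        x = np.array([0.0, 1.0, 2.0, 4.0])
        y = np.array([1.0, 2.0, 2.0, 5.0])
        X = np.column_stack([np.ones(4), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        r = regress(x, y)
        assert r.intercept == pytest.approx(beta[0]) and r.slope == pytest.approx(beta[1])

    def test_through_origin_slope(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([2.1, 3.9, 6.0])
        r = regress(x, y, through_origin=True)
        assert r.intercept is None
        assert r.slope == pytest.approx(float(x @ y / (x @ x)))

    def test_adjusted_r2_below_r2(self, rng):
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(size=10)
        r = regress(x, y)
        assert r.adjusted_r_squared <= r.r_squared
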