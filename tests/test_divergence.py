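import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from codonsel.divergence import (
    _site_counts,
    date_nodes,
    nei_gojobori_ds,
    node_mean_ds,
    pairwise_ds_matrix,
    SynonymousDistanceMatrix,
)
from codonsel.genetic_code import CODON_INDEX, CODON_TO_AA, SENSE_CODONS, STOP_CODONS
from codonsel.seqio import CodonAlignment, LabeledTree
from codonsel.simulate import SimulationSpec, simulate_codon_alignment


def seq(*codons: str) -> np.ndarray:
    return np.array([CODON_INDEX[c] for c in codons], dtype=np.int16)


def oracle_pathway_diffs(a: str, b: str):
    """Independent re-enumeration of minimal stop-free mutational pathways."""
    pos = [k for k in range(3) if a[k] != b[k]]
    results = []
    for order in itertools.permutations(pos):
        cur, sd, nd, ok = a, 0, 0, True
        for p in order:
            nxt = cur[:p] + b[p] + cur[p + 1:]
            if nxt in STOP_CODONS:
                ok = False
                break
            sd += CODON_TO_AA[cur] == CODON_TO_AA[nxt]
            nd += CODON_TO_AA[cur] != CODON_TO_AA[nxt]
            cur = nxt
        if ok:
            results.append((sd, nd))
    return (np.mean([r[0] for r in results]), np.mean([r[1] for r in results]))


class TestNeiGojobori:
    def test_identical_sequences_are_zero(self):
        s = seq("ATG", "TTT", "GGA")
        r = nei_gojobori_ds(s, s)
        assert r.ds == 0.0 and r.dn == 0.0

    def test_fourfold_third_position_single_difference(self):
        # GTT -> GTC: one synonymous difference; GTT/GTC are 4-fold at
        # position 3, so each codon carries exactly 1 synonymous site
        r = nei_gojobori_ds(seq("GTT"), seq("GTC"))
        assert r.syn_diffs == 1.0 and r.nonsyn_diffs == 0.0
        assert r.syn_sites == 1.0
        assert r.dn == 0.0
        # a single codon pair gives pS = 1 >= 3/4: correction undefined
        assert r.saturated_s and np.isinf(r.ds)

    def test_two_difference_pair_matches_pathway_oracle(self):
        for a, b in [("TTT", "GTA"), ("ATG", "TGG"), ("TGT", "TAT"),
                     ("AAA", "ACC"), ("TTA", "CGA")]:
            r = nei_gojobori_ds(seq(a), seq(b))
            sd, nd = oracle_pathway_diffs(a, b)
            assert r.syn_diffs == pytest.approx(sd), (a, b)
            assert r.nonsyn_diffs == pytest.approx(nd), (a, b)

    def test_saturation_is_flagged_infinite(self):
        # a long run of the same maximally synonymous-divergent codon pair
        r = nei_gojobori_ds(seq(*["GTT"] * 50), seq(*["GTC"] * 50))
        assert r.saturated_s and np.isinf(r.ds)

    def test_pairwise_incomplete_codons_dropped(self):
        a = np.array([CODON_INDEX["GTT"], -1, CODON_INDEX["AAA"]], dtype=np.int16)
        b = np.array([CODON_INDEX["GTC"], CODON_INDEX["TTT"], -1], dtype=np.int16)
        r = nei_gojobori_ds(a, b)
        assert r.n_codons == 1 and r.syn_diffs == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(derandomize=True, max_examples=15, deadline=None)
    def test_symmetry_and_column_order_invariance(self, s):
        rng = np.random.default_rng(s)
        a = rng.integers(0, 61, 40).astype(np.int16)
        b = rng.integers(0, 61, 40).astype(np.int16)
        r1, r2 = nei_gojobori_ds(a, b), nei_gojobori_ds(b, a)
        assert (r1.ds, r1.dn) == (r2.ds, r2.dn)
        perm = rng.permutation(40)
        r3 = nei_gojobori_ds(a[perm], b[perm])
        assert r1.ds == pytest.approx(r3.ds, rel=1e-9)
        assert r1.dn == pytest.approx(r3.dn, rel=1e-9)

    def test_neutral_simulation_dn_ds_near_one(self):
        labels = {"a": "social", "b": "subsocial"}
        tree = LabeledTree.from_newick("(a:0.15,b:0.15);", labels)
        spec = SimulationSpec(tree=tree, kappa=1.0, n_codons=30_000, seed=4,
                              omega_by_class={"internal": 1.0,
                                              "external_social": 1.0,
                                              "external_subsocial": 1.0})
        aln, _ = simulate_codon_alignment(spec)
        r = nei_gojobori_ds(aln.codons[0], aln.codons[1])
        assert r.dn / r.ds == pytest.approx(1.0, abs=0.08)


class TestNodeAveraging:
    @pytest.fixture()
    def tree_and_matrix(self, rng):
        labels = {t: "subsocial" for t in "abcdef"}
        labels["a"] = "social"
        nwk = "(((a:1,b:1):1,(c:1,d:1):1):1,(e:1,f:1):2);"
        tree = LabeledTree.from_newick(nwk, labels)
        taxa = tree.taxa
        m = rng.random((6, 6))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        return tree, SynonymousDistanceMatrix(taxa, m, m.copy())

    def test_cherry_equals_pairwise_entry(self, tree_and_matrix):
        tree, ds = tree_and_matrix
        recs = {r["node"]: r for r in node_mean_ds(tree, ds)}
        cherry = next(r for r in recs.values()
                      if r["n_pairs"] == 1 and r["clades"] == [["a"], ["b"]])
        assert cherry["mean_ds"] == pytest.approx(ds.pair("a", "b"))

    def test_pair_counts_partition_all_pairs(self, tree_and_matrix):
        tree, ds = tree_and_matrix
        recs = node_mean_ds(tree, ds)
        assert sum(r["n_pairs"] for r in recs) == 6 * 5 // 2

    def test_root_mean_matches_mrca_oracle(self, tree_and_matrix):
        tree, ds = tree_and_matrix
        recs = node_mean_ds(tree, ds)
        root = recs[0]
        # oracle: dendropy MRCA over all tip pairs
        t = tree.tree
        vals = []
        for a, b in itertools.combinations(tree.taxa, 2):
            mrca = t.mrca(taxon_labels=[a, b])
            if mrca is t.seed_node:
                vals.append(ds.pair(a, b))
        assert root["mean_ds"] == pytest.approx(np.mean(vals))
        assert root["n_pairs"] == len(vals)


class TestDating:
    def test_zero_distance_is_age_zero(self):
        recs = [{"node": "node1", "clades": [["a"], ["b"]], "n_pairs": 1,
                 "mean_ds": 0.0, "finite": True}]
        out = date_nodes(recs, mu=8.4e-8)
        assert out.records[0]["age_my"] == 0.0

    def test_saturated_node_is_undated(self):
        recs = [{"node": "node1", "clades": [["a"], ["b"]], "n_pairs": 1,
                 "mean_ds": float("inf"), "finite": False}]
        out = date_nodes(recs)
        assert out.records[0]["age_my"] is None

    def test_dating_arithmetic(self):
        # dS of 2.184 per synonymous site at the default Drosophila rate
        # corresponds to a 13-My-old split (generation time 1 yr)
        recs = [{"node": "node1", "clades": [["a"], ["b"]], "n_pairs": 1,
                 "mean_ds": 2 * 8.4e-8 * 13e6, "finite": True}]
        out = date_nodes(recs, mu=8.4e-8, generation_time=1.0)
        assert out.records[0]["age_my"] == pytest.approx(13.0)

    def test_invalid_mu_rejected(self):
        with pytest.raises(ValueError):
            date_nodes([], mu=0.0)


def test_site_counts_sane():
    s = _site_counts()
    # every codon has between 0 (ATG/TGG) and 3 synonymous sites
    assert s.min() == 0.0 and s.max() <= 3.0
    assert s[CODON_INDEX["ATG"]] == 0.0
    # 4-fold codon: third position fully synonymous
    assert s[CODON_INDEX["GTT"]] == 1.0
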