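"""FPKM, differential expression, clustering and the candidate funnel."""
from math import comb

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from hexanull.config import ParameterError, SimulationConfig
from hexanull.expression import (deg_test, fpkm, homeolog_specific_genes,
                                 intersect_candidates, kmeans, term_enrichment,
                                 tissue_specific_genes)
from hexanull.synthetic import simulate_dataset


def brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Independent oracle: adjusted p_i = min over the tail of p*m/rank."""
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = np.inf
    for rank_from_end, ix in enumerate(order[::-1]):
        rank = m - rank_from_end
        running = min(running, p[ix] * m / rank)
        adj[ix] = min(running, 1.0)
    return adj


class TestFpkm:
    def test_closed_form(self):
        counts = pd.DataFrame({"s": [100, 0]}, index=["g1", "g2"])
        lengths = pd.Series([1000, 500], index=["g1", "g2"])
        out = fpkm(counts, lengths, pd.Series({"s": 1_000_000}))
        assert out.loc["g1", "s"] == pytest.approx(100.0)
        assert out.loc["g2", "s"] == 0.0

    def test_doubling_library_halves_fpkm(self):
        counts = pd.DataFrame({"s": [50]}, index=["g"])
        lengths = pd.Series([2000], index=["g"])
        one = fpkm(counts, lengths, pd.Series({"s": 1_000_000}))
        two = fpkm(counts, lengths, pd.Series({"s": 2_000_000}))
        assert two.loc["g", "s"] == pytest.approx(one.loc["g", "s"] / 2)

    def test_counts_recoverable(self, rng):
        counts = pd.DataFrame(rng.integers(0, 5000, size=(50, 4)),
                              index=[f"g{i}" for i in range(50)],
                              columns=list("abcd"))
        lengths = pd.Series(rng.integers(200, 4000, size=50), index=counts.index)
        libs = counts.sum(axis=0)
        out = fpkm(counts, lengths, libs)
        back = out * np.outer(lengths, libs) / 1e9
        assert np.allclose(back, counts, rtol=1e-12)

    def test_zero_library_size_rejected(self):
        counts = pd.DataFrame({"s": [1]}, index=["g"])
        with pytest.raises(ParameterError):
            fpkm(counts, pd.Series([100], index=["g"]), pd.Series({"s": 0}))


def test_bh_matches_brute_force(rng):
    for _ in range(20):
        p = rng.random(50) ** rng.uniform(0.5, 3.0)
        _, adj, _, _ = multipletests(p, method="fdr_bh")
        assert np.allclose(adj, brute_force_bh(p), atol=1e-12)


def _nb(rng, mean, disp, size):
    size_param = 1.0 / disp
    return rng.negative_binomial(size_param, size_param / (size_param + mean), size=size)


class TestDegTest:
    def test_null_type_one_error_controlled(self, rng):
        # 100 replicate null datasets of 200 genes, identical group means:
        # the average realized false-discovery proportion stays at or
        # below the nominal FDR
        fdp = []
        lengths = pd.Series(1000, index=[f"g{i}" for i in range(200)])
        for _ in range(100):
            means = rng.lognormal(4.0, 1.0, size=200)
            counts = pd.DataFrame(
                _nb(rng, means[:, None], 0.05, (200, 6)),
                index=lengths.index, columns=list("abcdef"))
            res = deg_test(counts, ["a", "b", "c"], ["d", "e", "f"], lengths,
                           fc_min=2.0, fdr_max=0.01)
            # every discovery is false under the complete null
            fdp.append(1.0 if len(res.significant) else 0.0)
        assert np.mean(fdp) <= 0.01

    def test_planted_fold_change_detected(self, rng):
        lengths = pd.Series(1000, index=[f"g{i}" for i in range(300)])
        means = rng.lognormal(5.0, 0.5, size=300)
        a = _nb(rng, means[:, None] * 1.0, 0.05, (300, 4)).astype(float)
        b = _nb(rng, means[:, None], 0.05, (300, 4)).astype(float)
        planted = lengths.index[:10]
        a[:10] = _nb(rng, means[:10, None] * 8.0, 0.05, (10, 4))
        counts = pd.DataFrame(np.hstack([a, b]).astype(int), index=lengths.index,
                              columns=[f"s{i}" for i in range(8)])
        res = deg_test(counts, [f"s{i}" for i in range(4)],
                       [f"s{i}" for i in range(4, 8)], lengths,
                       fc_min=4.0, fdr_max=0.01)
        found = set(res.up)
        assert len(found & set(planted)) / len(planted) >= 0.9

    def test_direction_partitions_significant_set(self, rng):
        lengths = pd.Series(1000, index=[f"g{i}" for i in range(100)])
        means = rng.lognormal(4, 1, size=100)
        shift = np.where(rng.random(100) < 0.3, 6.0, 1.0)
        a = _nb(rng, (means * shift)[:, None], 0.05, (100, 3))
        b = _nb(rng, means[:, None], 0.05, (100, 3))
        counts = pd.DataFrame(np.hstack([a, b]), index=lengths.index,
                              columns=[f"s{i}" for i in range(6)])
        res = deg_test(counts, [f"s{i}" for i in range(3)],
                       [f"s{i}" for i in range(3, 6)], lengths)
        assert len(res.up) + len(res.down) == len(res.significant)

    def test_all_zero_genes_excluded_and_reported(self):
        lengths = pd.Series(1000, index=["g0", "g1"])
        counts = pd.DataFrame({"a": [0, 5], "b": [0, 6], "c": [0, 4], "d": [0, 5]},
                              index=lengths.index)
        res = deg_test(counts, ["a", "b"], ["c", "d"], lengths)
        assert res.excluded == ["g0"]
        assert "g0" not in res.table.index

    def test_single_replicate_rejected(self):
        lengths = pd.Series(1000, index=["g"])
        counts = pd.DataFrame({"a": [1], "b": [1], "c": [1]}, index=["g"])
        with pytest.raises(ParameterError):
            deg_test(counts, ["a"], ["b", "c"], lengths)


class TestHomeologSpecific:
    table = pd.DataFrame({
        "group_id": ["t1", "t1", "t1", "p1", "p1", "s1"],
        "gene_id": ["a2A", "a2B", "a2D", "b2A", "b2B", "c2A"],
        "chromosome": ["chr2A", "chr2B", "chr2D", "chr2A", "chr2B", "chr2A"],
    })

    def test_triad_member_excluded_pair_excluded_singleton_included(self):
        out = homeolog_specific_genes(["a2A", "b2A", "c2A"], self.table)
        assert out == {"c2A"}

    def test_gene_absent_from_table_treated_as_specific(self):
        out = homeolog_specific_genes(["a2A", "novel"], self.table)
        assert out == {"novel"}

    def test_generator_truth_round_trip(self, default_dataset):
        model = default_dataset.model
        focal = default_dataset.config.focal_chromosome
        focal_genes = model.genes.loc[model.genes["chromosome"] == focal, "gene_id"]
        out = homeolog_specific_genes(focal_genes, model.homeolog_table())
        assert out == model.chromosome_specific_genes(focal)


class TestKmeans:
    def test_objective_non_increasing_and_deterministic(self, rng):
        x = rng.normal(size=(200, 5))
        fit = kmeans(x, k=4, seed=9)
        path = np.array(fit.objective_path)
        assert (np.diff(path) <= 1e-9).all()
        again = kmeans(x, k=4, seed=9)
        assert (fit.labels == again.labels).all()

    def test_k_larger_than_points_rejected(self, rng):
        with pytest.raises(ParameterError):
            kmeans(rng.normal(size=(3, 2)), k=5)

    def test_objective_matches_reference_implementation(self, rng):
        # independent route: scikit-learn's KMeans should reach the same
        # within-cluster sum of squares on well-conditioned data
        from sklearn.cluster import KMeans as SkKMeans
        x = rng.normal(size=(300, 4)) + np.repeat(np.eye(4)[:3] * 6, 100, axis=0)
        ours = kmeans(x, k=3, seed=2)
        ref = SkKMeans(n_clusters=3, n_init=10, random_state=2).fit(x)
        assert ours.inertia == pytest.approx(ref.inertia_, rel=1e-6)

    def test_recovers_well_separated_clusters(self, rng):
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        x = np.vstack([c + rng.normal(scale=0.3, size=(30, 2)) for c in centers])
        fit = kmeans(x, k=3, seed=1)
        truth = np.repeat([0, 1, 2], 30)
        # same partition up to label permutation
        assert len({(t, l) for t, l in zip(truth, fit.labels)}) == 3


class TestTissueSpecific:
    def tissue_fpkm(self, with_noise: bool, rng=None):
        tissues = ["stamen", "root", "leaf", "stem", "pistil"]
        rows, genes = [], []
        for i in range(40):  # planted stamen-specific
            rows.append([100, 2, 2, 2, 2])
            genes.append(f"st{i}")
        for i in range(40):  # root-specific
            rows.append([2, 100, 2, 2, 2])
            genes.append(f"rt{i}")
        for i in range(120):  # constitutive
            rows.append([20, 20, 20, 20, 20])
            genes.append(f"c{i}")
        x = np.array(rows, dtype=float)
        if with_noise:
            x *= rng.lognormal(0, 0.1, size=x.shape)
        return pd.DataFrame(x, index=genes, columns=tissues)

    def test_zero_noise_recovers_planted_set_exactly(self):
        mat = self.tissue_fpkm(with_noise=False)
        spec, _, _ = tissue_specific_genes(mat, "stamen", k=2, seed=0)
        assert spec == {f"st{i}" for i in range(40)}

    def test_constitutive_never_specific(self, rng):
        mat = self.tissue_fpkm(with_noise=True, rng=rng)
        spec, _, _ = tissue_specific_genes(mat, "stamen", k=4, seed=0)
        assert not spec & {f"c{i}" for i in range(120)}

    def test_default_simulation_sensitivity_and_fdr(self, default_dataset):
        ds = default_dataset
        mat = fpkm(ds.tissue_matrix.counts, ds.tissue_matrix.gene_lengths)
        spec, _, _ = tissue_specific_genes(mat, "stamen", k=8, seed=ds.config.seed)
        truth = ds.model.tissue_specific_genes("stamen_specific")
        tp = len(spec & truth)
        assert tp / len(truth) >= 0.9
        assert (len(spec) - tp) / max(len(spec), 1) <= 0.1

    def test_k_exceeding_gene_count_rejected(self):
        mat = self.tissue_fpkm(with_noise=False).iloc[:5]
        with pytest.raises(ParameterError):
            tissue_specific_genes(mat, "stamen", k=50)


class TestFunnel:
    def test_disjoint_sets_intersect_empty(self):
        rep = intersect_candidates({"a", "b"}, {"c"})
        assert rep.candidates == set()

    def test_subset_intersection(self):
        rep = intersect_candidates({"a", "b"}, {"a", "b", "c"})
        assert rep.candidates == {"a", "b"}

    def test_provenance_flags_consistent(self):
        rep = intersect_candidates({"a", "b"}, {"b", "c"}, deg={"b", "d"})
        assert rep.candidates == {"b"}
        prov = rep.provenance
        assert bool(prov.loc["b"].all())
        assert set(prov.index) == {"a", "b", "c", "d"}
        assert (prov["candidate"] == (prov["chromosome_specific"]
                                      & prov["tissue_specific"] & prov["deg"])).all()

    def test_adding_genes_never_removes_candidates(self):
        base = intersect_candidates({"a", "b"}, {"b"}).candidates
        grown = intersect_candidates({"a", "b", "z"}, {"b", "z"}).candidates
        assert base <= grown

    def test_generator_truth_recovered(self, default_dataset):
        ds = default_dataset
        focal = ds.config.focal_chromosome
        chrom_truth = ds.model.chromosome_specific_genes(focal)
        stamen_truth = ds.model.tissue_specific_genes("stamen_specific")
        mat = fpkm(ds.tissue_matrix.counts, ds.tissue_matrix.gene_lengths)
        spec, _, _ = tissue_specific_genes(mat, "stamen", k=8, seed=ds.config.seed)
        rep = intersect_candidates(chrom_truth, spec)
        assert rep.candidates == chrom_truth & stamen_truth


class TestTermEnrichment:
    def test_set_equal_to_universe_gives_p_one(self):
        universe = {f"g{i}" for i in range(10)}
        terms = pd.DataFrame({"gene_id": list(universe)[:4], "term": "T1"})
        out = term_enrichment(universe, universe, terms)
        assert out.loc["T1", "p"] == pytest.approx(1.0)

    def test_term_identical_to_set_matches_combinatorial_oracle(self):
        universe = [f"g{i}" for i in range(12)]
        query = set(universe[:4])
        terms = pd.DataFrame({"gene_id": sorted(query), "term": "T"})
        out = term_enrichment(query, universe, terms)
        assert out.loc["T", "p"] == pytest.approx(1 / comb(12, 4), rel=1e-9)

    def test_term_without_universe_members_skipped(self):
        universe = {"a", "b"}
        terms = pd.DataFrame({"gene_id": ["x", "y"], "term": "T"})
        out = term_enrichment({"a"}, universe, terms)
        assert len(out) == 0

    def test_empty_query_rejected(self):
        with pytest.raises(ParameterError):
            term_enrichment(set(), {"a"}, pd.DataFrame({"gene_id": [], "term": []}))


def test_screen_recovers_candidates_on_fresh_simulation():
    ds = simulate_dataset(SimulationConfig(seed=99, n_genes=1000))
    mat = fpkm(ds.tissue_matrix.counts, ds.tissue_matrix.gene_lengths)
    spec, _, _ = tissue_specific_genes(mat, "stamen", k=8, seed=99)
    focal = ds.config.focal_chromosome
    chrom = homeolog_specific_genes(
        ds.model.genes.loc[ds.model.genes["chromosome"] == focal, "gene_id"],
        ds.model.homeolog_table())
    rep = intersect_candidates(chrom, spec)
    truth = (ds.model.chromosome_specific_genes(focal)
             & ds.model.tissue_specific_genes("stamen_specific"))
    assert rep.candidates == truth
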