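"""Generator correctness: gamete transmission, dosage effects, determinism."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hexanull.config import ParameterError, SimulationConfig
from hexanull.synthetic import (build_genome, chromosome_names, focal_copy_numbers,
                                simulate_bulk_snps, simulate_counts, simulate_dataset,
                                simulate_markers, simulate_progeny,
                                simulate_tissue_matrix)
from hexanull.synthetic import _dosage_factor  # noqa: internal but load-bearing


def class_freqs(copies: np.ndarray) -> tuple[float, float, float]:
    n = len(copies)
    return ((copies == 2).sum() / n, (copies == 1).sum() / n, (copies == 0).sum() / n)


class TestProgeny:
    def test_equal_transmission_is_mendelian_1_2_1(self):
        cfg = SimulationConfig(seed=3, female_null_transmission=1.0,
                               male_null_transmission=1.0)
        copies = focal_copy_numbers(cfg, np.random.default_rng(3), n=100_000)
        counts = [(copies == 2).sum(), (copies == 1).sum(), (copies == 0).sum()]
        p = stats.chisquare(counts, f_exp=[25_000, 50_000, 25_000]).pvalue
        assert p > 0.01

    def test_half_male_transmission_gives_one_sixth_nullisomic(self):
        # analytic enumeration: q_f = 1/2, q_m = 0.5/1.5 = 1/3, P_D = 1/6
        cfg = SimulationConfig(seed=4, female_null_transmission=1.0,
                               male_null_transmission=0.5)
        copies = focal_copy_numbers(cfg, np.random.default_rng(4), n=1_000_000)
        d_freq = (copies == 0).mean()
        assert d_freq == pytest.approx(1 / 6, abs=3 * np.sqrt((1 / 6) * (5 / 6) / 1e6))

    def test_null_pollen_never_transmits_at_zero_rate(self):
        cfg = SimulationConfig(seed=5, male_null_transmission=0.0)
        copies = focal_copy_numbers(cfg, np.random.default_rng(5), n=50_000)
        assert (copies == 0).sum() == 0

    def test_progeny_objects_carry_phenotype_mapping(self):
        cfg = SimulationConfig(seed=6, n_progeny=50)
        progeny = simulate_progeny(cfg)
        for g in progeny:
            focal = g.copy_number[cfg.focal_chromosome]
            assert g.phenotype_class == {2: "T", 1: "M", 0: "D"}[focal]
            assert all(g.copy_number[c] == 2 for c in chromosome_names()
                       if c != cfg.focal_chromosome)

    def test_invalid_rate_rejected(self):
        with pytest.raises(ParameterError):
            SimulationConfig(male_null_transmission=1.5)


class TestGenome:
    def test_weights_sum_to_one_and_triads_span_subgenomes(self):
        cfg = SimulationConfig(seed=11)
        model = build_genome(cfg, np.random.default_rng(11))
        assert model.chromosomes.sum() == pytest.approx(1.0, abs=1e-12)
        groups = model.genes.dropna(subset=["homeolog_group"]).groupby("homeolog_group")
        sizes = groups.size()
        assert sizes.isin([2, 3]).all()
        for _, sub in groups:
            assert sub["chromosome"].nunique() == len(sub)

    def test_focal_specific_truth_has_no_homeolog_group(self):
        cfg = SimulationConfig(seed=11)
        model = build_genome(cfg, np.random.default_rng(11))
        truth = model.chromosome_specific_genes(cfg.focal_chromosome)
        sub = model.genes[model.genes["gene_id"].isin(truth)]
        assert (sub["chromosome"] == cfg.focal_chromosome).all()
        assert sub["homeolog_group"].isna().all()


class TestCounts:
    def test_dosage_factor_closed_form(self):
        # monosomic halves expression without compensation, is restored
        # fully at compensation 1, and a lost chromosome is always silent
        assert _dosage_factor(np.array([1]), 0.0)[0] == 0.5
        assert _dosage_factor(np.array([1]), 1.0)[0] == 1.0
        assert _dosage_factor(np.array([2]), 0.7)[0] == 1.0
        assert _dosage_factor(np.array([0]), 1.0)[0] == 0.0

    def test_lost_chromosome_counts_exactly_zero(self, default_dataset):
        cfg = default_dataset.config
        genes = default_dataset.model.genes
        focal_genes = genes.loc[genes["chromosome"] == cfg.focal_chromosome, "gene_id"]
        d_samples = [g.sample_id for g in default_dataset.genotypes
                     if g.phenotype_class == "D"]
        assert d_samples
        block = default_dataset.counts.counts.loc[focal_genes, d_samples]
        assert (block.to_numpy() == 0).all()

    def test_library_sizes_near_configured_mean(self, default_dataset):
        cfg = default_dataset.config
        totals = default_dataset.counts.library_sizes()
        genes = default_dataset.model.genes
        # conservative bound: per-library SD of the NB total at the mean
        mu = cfg.mean_library_size * genes["base_mean"] / genes["base_mean"].sum()
        sd = np.sqrt((mu + cfg.nb_dispersion * mu**2).sum())
        assert (np.abs(totals - cfg.mean_library_size) < 5 * sd).all()

    def test_monosomic_fraction_ratio_follows_two_minus_f(self):
        # with no compensation the euploid:monosomic focal read-fraction
        # ratio tends to 2 - f (f = focal euploid expression share)
        cfg = SimulationConfig(seed=21, n_progeny=60, mean_library_size=2_000_000)
        ds = simulate_dataset(cfg)
        genes = ds.model.genes.set_index("gene_id")
        focal = genes["chromosome"] == cfg.focal_chromosome
        frac = {}
        for cls in ("T", "M"):
            ids = [g.sample_id for g in ds.genotypes if g.phenotype_class == cls]
            sub = ds.counts.counts[ids].sum(axis=1)
            frac[cls] = sub[focal.to_numpy()].sum() / sub.sum()
        base = genes.loc[:, "base_mean"]
        f = base[focal].sum() / base.sum()
        assert frac["T"] / frac["M"] == pytest.approx(2 - f, rel=0.03)


class TestBulkSnps:
    def test_focal_snps_maximally_divergent(self, default_dataset):
        snps = default_dataset.snps
        cfg = default_dataset.config
        focal = snps[snps["chrom"] == cfg.focal_chromosome]
        f_cols = [f"fertile_{a}" for a in "ACGT"]
        s_cols = [f"sterile_{a}" for a in "ACGT"]
        f = focal[f_cols].to_numpy(float)
        s = focal[s_cols].to_numpy(float)
        ok = (f.sum(1) > 0) & (s.sum(1) > 0)
        f, s = f[ok] / f[ok].sum(1, keepdims=True), s[ok] / s[ok].sum(1, keepdims=True)
        ed = np.sqrt(((f - s) ** 2).sum(1))
        assert np.allclose(ed, np.sqrt(2))

    def test_too_few_snps_rejected(self, default_dataset):
        cfg = SimulationConfig(seed=1)
        cfg.n_snps = 10  # bypass constructor validation to hit the op's own check
        with pytest.raises(ParameterError):
            simulate_bulk_snps(default_dataset.model, default_dataset.genotypes,
                               cfg, np.random.default_rng(0))

    def test_positions_sorted_within_chromosome(self, default_dataset):
        for _, sub in default_dataset.snps.groupby("chrom"):
            assert sub["pos"].is_monotonic_increasing


class TestMarkersAndTissues:
    def test_noiseless_marker_intensities_are_half_copy_number(self):
        cfg = SimulationConfig(seed=31, marker_noise_sd=0.0, n_progeny=40)
        progeny = simulate_progeny(cfg)
        panel = simulate_markers(progeny, cfg, np.random.default_rng(31))
        for g in progeny:
            for mid, chrom in panel.markers.itertuples(index=False):
                assert panel.intensities.loc[g.sample_id, mid] == g.copy_number[chrom] / 2

    def test_planted_stamen_genes_peak_in_stamen(self, default_dataset):
        fpkm_like = default_dataset.tissue_matrix.counts
        truth = default_dataset.model.tissue_specific_genes("stamen_specific")
        peaks = fpkm_like.loc[sorted(truth)].idxmax(axis=1)
        assert (peaks == "stamen").all()

    def test_constitutive_profile_flat_in_expectation(self):
        # with no specific genes competing for library mass, constitutive
        # tissue means agree closely at high depth
        cfg = SimulationConfig(seed=32, n_genes=210, mean_library_size=5_000_000,
                               nb_dispersion=1e-6,
                               stamen_specific_fraction=0.0,
                               other_tissue_specific_fraction=0.0)
        model = build_genome(cfg, np.random.default_rng(32))
        tm = simulate_tissue_matrix(model, cfg, np.random.default_rng(33))
        sub = tm.counts
        ratio = sub.mean(axis=0) / sub.mean(axis=0).mean()
        assert np.allclose(ratio, 1.0, atol=0.02)


class TestDeterminism:
    def test_same_seed_identical_outputs(self, small_config):
        a = simulate_dataset(small_config)
        b = simulate_dataset(small_config)
        assert a.counts.counts.equals(b.counts.counts)
        assert a.snps.equals(b.snps)
        assert a.markers.intensities.equals(b.markers.intensities)
        assert a.tissue_matrix.counts.equals(b.tissue_matrix.counts)
        assert [g.phenotype_class for g in a.genotypes] == \
               [g.phenotype_class for g in b.genotypes]

    def test_different_seeds_differ(self, small_config):
        import dataclasses
        other = dataclasses.replace(small_config, seed=small_config.seed + 1)
        a = simulate_dataset(small_config)
        b = simulate_dataset(other)
        assert not a.counts.counts.equals(b.counts.counts)
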