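import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import tiny_metadata
from ssmi import (
    ExpressionMatrix,
    Platform,
    PresenceFlags,
    Space,
    Unit,
    ValidationError,
    log_transform,
)
from ssmi.metrics import (
    binned_reproducibility,
    foldchange_concordance,
    per_gene_reproducibility,
    presence_summary,
    region_anova,
    replicate_correlations,
    stratified_subsample,
    subsample_stability,
)
from ssmi.probe_qc import QCConfig
from ssmi.simulate import SimulationConfig, simulate

EPS = 2.0 ** -10


def _em(values, ids, samples, space=Space.LOG2, unit=Unit.INTENSITY):
    return ExpressionMatrix(
        pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=samples),
        space,
        Platform.MICROARRAY,
        unit,
    )


class TestReplicateCorrelations:
    def test_duplicate_columns_give_r_1(self, rng):
        meta = tiny_metadata(n_regions=2, donors=("d1",))
        samples = list(meta.sample_ids)
        col = rng.normal(5, 2, size=100)
        values = np.column_stack([col + rng.normal(0, 1e-9, 100) for _ in samples])
        # replicate pairs share region and hemisphere
        mat = _em(values, [f"g{i}" for i in range(100)], samples)
        rep = replicate_correlations(mat, meta)
        assert len(rep) == 2
        np.testing.assert_allclose(rep["r"], 1.0, atol=1e-6)

    def test_independent_columns_give_near_zero(self, rng):
        meta = tiny_metadata(n_regions=1, donors=("d1",))
        samples = list(meta.sample_ids)
        values = rng.normal(size=(10_000, len(samples)))
        mat = _em(values, [f"g{i}" for i in range(10_000)], samples)
        rep = replicate_correlations(mat, meta)
        assert np.abs(rep["r"]).max() < 0.05

    def test_no_pairs_is_an_error(self):
        meta = tiny_metadata(n_regions=2, donors=("d1",), reps=1)
        samples = list(meta.sample_ids)
        mat = _em(np.ones((5, len(samples))), [f"g{i}" for i in range(5)], samples)
        with pytest.raises(ValidationError, match="no replicate pairs"):
            replicate_correlations(mat, meta)

    def test_median_matches_variance_components(self, default_sim):
        # replicate pairs differ only by measurement noise; across genes the
        # expected correlation is var(signal) / (var(signal) + var(noise))
        sim = default_sim
        log2 = log_transform(sim.array, EPS)
        rep = replicate_correlations(log2, sim.metadata)
        truth = sim.truth
        probes = list(log2.feature_ids)
        # signal = noise-free probe values; use one replicate pair's samples
        cfg = truth.config
        between = np.var(
            log2.data.to_numpy() - 0.0, axis=0
        ).mean()  # total spread per sample, proxy for signal+noise
        noise_var = cfg.array_noise_sd ** 2
        expected = 1.0 - noise_var / between
        assert rep["r"].median() == pytest.approx(expected, abs=0.02)


class TestPresenceSummary:
    def _flags(self, values, ids, samples):
        return PresenceFlags(
            pd.DataFrame(values, index=ids, columns=samples), Platform.MICROARRAY
        )

    def test_single_fragment_gene_present_at_5pct_only(self):
        samples = [f"s{j}" for j in range(20)]
        counts = np.zeros((2, 20))
        counts[0, 0] = 1.0  # one fragment in one of 20 samples = 5%
        seq = ExpressionMatrix(
            pd.DataFrame(counts, index=["g1", "g2"], columns=samples),
            Space.LINEAR,
            Platform.RNASEQ,
            Unit.COUNTS,
        )
        flags = self._flags(np.ones((2, 20), dtype=bool), ["g1", "g2"], samples)
        table = presence_summary(flags, seq).set_index("threshold")
        assert table.loc[0.05, "n_seq"] == 1  # g1 at exactly 5%
        assert table.loc[0.50, "n_seq"] == 0
        assert table.loc[0.95, "n_seq"] == 0

    def test_overlap_bounded_by_marginals(self, default_sim):
        sim = default_sim
        gene_of = sim.annotation.gene_of()
        flags = sim.presence_array.flags.copy()
        flags.index = gene_of.loc[flags.index].to_numpy()
        flags = flags[~flags.index.duplicated()]
        table = presence_summary(
            PresenceFlags(flags, Platform.MICROARRAY), sim.seq_counts
        )
        assert (table["n_overlap"] <= table[["n_array", "n_seq"]].min(axis=1)).all()

    def test_expressed_fraction_recovered(self):
        # genes with counts in >=50% of samples should reflect how many
        # genes the generator expresses above one fragment per sample
        sim = simulate(SimulationConfig(seed=41, n_donors=1))
        expected_counts = sim.seq_counts.data.to_numpy()
        frac_true = ((expected_counts >= 1).mean(axis=1) >= 0.5).mean()
        flags = PresenceFlags(
            sim.seq_counts.data >= 1, Platform.RNASEQ
        )
        table = presence_summary(flags, sim.seq_counts).set_index("threshold")
        assert table.loc[0.5, "n_seq"] / len(sim.seq_counts.data) == pytest.approx(
            frac_true, abs=0.02
        )


class TestFoldchangeConcordance:
    def test_identical_matrices_give_exactly_1(self, default_sim):
        sim = default_sim
        log2 = log_transform(sim.seq_tpm, EPS)
        d1 = log2.subset_samples(sim.metadata.samples_of_donor("brain1"))
        _, R = foldchange_concordance(d1, d1, sim.metadata, n_draws=5000, seed=3)
        assert R == 1.0

    def test_seeded_rerun_is_identical(self, default_sim):
        sim = default_sim
        log2 = log_transform(sim.seq_tpm, EPS)
        d1 = log2.subset_samples(sim.metadata.samples_of_donor("brain1"))
        d2 = log2.subset_samples(sim.metadata.samples_of_donor("brain2"))
        draws1, R1 = foldchange_concordance(d1, d2, sim.metadata, 2000, seed=9)
        draws2, R2 = foldchange_concordance(d1, d2, sim.metadata, 2000, seed=9)
        assert R1 == R2
        pd.testing.assert_frame_equal(draws1, draws2)

    def test_permuted_genes_give_near_zero(self, default_sim, rng):
        sim = default_sim
        log2 = log_transform(sim.seq_tpm, EPS)
        d1 = log2.subset_samples(sim.metadata.samples_of_donor("brain1"))
        perm = d1.data.copy()
        perm.index = rng.permutation(perm.index.to_numpy())
        d1p = ExpressionMatrix(
            perm.loc[d1.data.index], Space.LOG2, Platform.RNASEQ, Unit.TPM
        )
        _, R = foldchange_concordance(d1, d1p, sim.metadata, 100_000, seed=3)
        assert abs(R) < 0.02

    def test_regions_distinct_and_filtered(self, default_sim):
        sim = default_sim
        log2 = log_transform(sim.seq_tpm, EPS)
        d1 = log2.subset_samples(sim.metadata.samples_of_donor("brain1"))
        draws, _ = foldchange_concordance(
            d1, d1, sim.metadata, 3000, regions_filter="non_neocortex", seed=1
        )
        assert (draws["region_a"] != draws["region_b"]).all()
        non_neo = set(
            sim.metadata.table.loc[
                sim.metadata.table["region_class"] == "non_neocortex", "region"
            ]
        )
        assert set(draws["region_a"]).issubset(non_neo)

    def test_too_few_regions_is_an_error(self, default_sim):
        sim = default_sim
        log2 = log_transform(sim.seq_tpm, EPS)
        with pytest.raises(ValidationError, match="at least 2 regions"):
            foldchange_concordance(
                log2, log2, sim.metadata, 100, regions_filter=["ctx00"], seed=0
            )


class TestPerGeneReproducibility:
    def _two_donor(self, profile_b):
        meta = tiny_metadata(n_regions=4, donors=("d1", "d2"), reps=1)
        samples = list(meta.sample_ids)
        profile_a = np.array([1.0, 3.0, 2.0, 5.0])
        values = np.empty((1, len(samples)))
        for j, s in enumerate(samples):
            reg = int(meta.table.loc[s, "region"][1])
            values[0, j] = (profile_a if s.startswith("d1") else profile_b)[reg]
        matA = _em(values[:, :4], ["g1"], samples[:4])
        matB = _em(values[:, 4:], ["g1"], samples[4:])
        return matA, matB, meta

    def test_identical_profiles_give_1(self):
        matA, matB, meta = self._two_donor(np.array([1.0, 3.0, 2.0, 5.0]))
        r = per_gene_reproducibility(matA, matB, meta)
        assert r.iloc[0] == pytest.approx(1.0)

    def test_reversed_profile_gives_minus_1(self):
        matA, matB, meta = self._two_donor(np.array([5.0, 2.0, 3.0, 1.0]))
        # reversed rank order with mirrored spacing: exactly anti-linear
        r = per_gene_reproducibility(
            matA, matB, meta
        )
        assert r.iloc[0] < -0.8

    def test_no_region_effect_centers_at_zero(self):
        sim = simulate(
            SimulationConfig(
                seed=51,
                de_fraction=0.0,
                background_region_sd=0.0,
                donor_scale_sd=0.0,
            )
        )
        log2 = log_transform(sim.seq_tpm, EPS)
        d1 = log2.subset_samples(sim.metadata.samples_of_donor("brain1"))
        d2 = log2.subset_samples(sim.metadata.samples_of_donor("brain2"))
        r = per_gene_reproducibility(d1, d2, sim.metadata)
        assert abs(np.nanmean(r)) < 0.03


class TestBinnedReproducibility:
    def test_equal_bins_and_constant_r(self):
        r = pd.Series(0.7, index=[f"g{i}" for i in range(40)])
        v = pd.Series(np.arange(40.0), index=r.index)
        bins = binned_reproducibility(r, v, n_bins=20)
        assert [b.n for b in bins] == [2] * 20
        assert all(b.mean_r == pytest.approx(0.7) for b in bins)
        assert all(b.sem == 0.0 for b in bins)

    def test_remainder_spread_over_leading_bins(self):
        r = pd.Series(0.5, index=[f"g{i}" for i in range(43)])
        v = pd.Series(np.arange(43.0), index=r.index)
        sizes = [b.n for b in binned_reproducibility(r, v, n_bins=20)]
        assert sizes[:3] == [3, 3, 3] and sizes[3:] == [2] * 17
        assert sum(sizes) == 43

    def test_fewer_genes_than_bins_is_an_error(self):
        r = pd.Series(0.5, index=["g1", "g2"])
        with pytest.raises(ValidationError, match="fewer genes"):
            binned_reproducibility(r, r, n_bins=20)

    def test_reproducibility_rises_with_expression_then_plateaus(self, deep_sim):
        # low expressers are Poisson/noise dominated: binned between-donor
        # correlation rises with expression and levels off once counting
        # noise is negligible (deep-coverage regime; at shallow depth the
        # plateau lies beyond the observable expression range)
        sim = deep_sim
        log2 = log_transform(sim.seq_tpm, EPS)
        d1 = log2.subset_samples(sim.metadata.samples_of_donor("brain1"))
        d2 = log2.subset_samples(sim.metadata.samples_of_donor("brain2"))
        r = per_gene_reproducibility(d1, d2, sim.metadata)
        expr = log2.data.mean(axis=1)
        bins = binned_reproducibility(r, expr, n_bins=20, sort_key="expression")
        means = np.array([b.mean_r for b in bins])
        lower = means[:10]
        rho = stats.spearmanr(np.arange(10), lower).statistic
        assert rho > 0.8
        # plateau: the top half varies much less than the overall rise
        assert means[10:].max() - means[10:].min() < 0.5 * (means.max() - means.min())


class TestRegionAnova:
    def test_matches_hand_sum_of_squares_and_scipy(self, rng):
        meta = tiny_metadata(n_regions=3, donors=("d1",), reps=2,
                             region_class=["neocortex"] * 3)
        samples = list(meta.sample_ids)
        values = rng.normal(size=(5, len(samples)))
        mat = _em(values, [f"g{i}" for i in range(5)], samples)
        out = region_anova(mat, meta, "neocortex")
        regions = meta.table.loc[samples, "region"]
        for g in range(5):
            groups = [
                values[g, [i for i, s in enumerate(samples) if regions[s] == reg]]
                for reg in sorted(regions.unique())
            ]
            f, p = stats.f_oneway(*groups)
            assert out["F"].iloc[g] == pytest.approx(f, abs=1e-10)
            assert out["p"].iloc[g] == pytest.approx(p, abs=1e-10)

    def test_constant_gene_gets_p_1(self):
        meta = tiny_metadata(n_regions=2, donors=("d1",), reps=2,
                             region_class=["neocortex"] * 2)
        samples = list(meta.sample_ids)
        mat = _em(np.full((1, len(samples)), 7.0), ["g1"], samples)
        out = region_anova(mat, meta, "neocortex")
        assert out["p"].iloc[0] == 1.0

    def test_separated_means_are_significant(self, rng):
        meta = tiny_metadata(n_regions=3, donors=("d1",), reps=3,
                             region_class=["neocortex"] * 3)
        samples = list(meta.sample_ids)
        values = rng.normal(0, 1, size=(1, len(samples)))
        for j, s in enumerate(samples):
            values[0, j] += 10.0 * int(meta.table.loc[s, "region"][1])
        mat = _em(values, ["g1"], samples)
        out = region_anova(mat, meta, "neocortex")
        assert out["bonferroni_significant"].iloc[0]

    def test_null_simulation_calibration(self):
        # no region effects: uncorrected p uniform, Bonferroni count zero
        sim = simulate(
            SimulationConfig(
                seed=61,
                n_donors=1,
                n_genes=1000,
                de_fraction=0.0,
                background_region_sd=0.0,
                donor_scale_sd=0.0,
                array_noise_sd=0.5,
                background_floor=-np.inf,
                saturation_ceiling=np.inf,
            )
        )
        log2 = log_transform(sim.array, EPS)
        out = region_anova(log2, sim.metadata, "neocortex")
        assert out["bonferroni_significant"].sum() == 0
        ks = stats.kstest(out["p"], "uniform")
        assert ks.pvalue > 0.01


class TestSubsampleStability:
    def test_stratified_subsample_maximizes_diversity(self, default_sim):
        meta = default_sim.metadata
        donor = meta.samples_of_donor("brain2")
        rng = np.random.default_rng(0)
        sub = stratified_subsample(meta, donor, 16, rng)
        classes = meta.table.loc[sub, "region_class"].nunique()
        regions = meta.table.loc[sub, "region"].nunique()
        assert classes == 2 and regions == 16

    def test_full_size_equals_full_fit(self, default_sim):
        sim = default_sim
        arr = log_transform(sim.array, EPS)
        seq = log_transform(sim.seq_tpm, EPS)
        train = sim.metadata.samples_of_donor("brain2")
        out = subsample_stability(
            arr, seq, sim.annotation, sim.metadata, train,
            sizes=[len(train)], n_rep=3, seed=2,
        )
        assert out["pass_rate_sd"].iloc[0] == 0.0
        assert out["m_dev_median"].iloc[0] == 0.0
        assert out["b_dev_median"].iloc[0] == 0.0

    def test_pass_rate_rises_and_levels_off(self, deep_sim):
        sim = deep_sim
        arr = log_transform(sim.array, EPS)
        seq = log_transform(sim.seq_tpm, EPS)
        train = sim.metadata.samples_of_donor("brain2")
        out = subsample_stability(
            arr, seq, sim.annotation, sim.metadata, train,
            sizes=[4, 8, 16, 32, 64, len(train)], n_rep=3, seed=2,
        )
        rates = out["pass_rate_mean"].to_numpy()
        assert rates[-1] >= rates[0]
        gains = np.diff(rates)
        # rises, then consecutive gains shrink monotonically beyond the knee
        knee = int(np.argmax(gains))
        assert knee <= 2  # knee within the small-sample range
        assert all(g1 > g2 for g1, g2 in zip(gains[knee:], gains[knee + 1:]))
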