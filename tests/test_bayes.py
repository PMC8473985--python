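"""Bayesian count model, predictive threshold, and diversity LMM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import orthodiv as od
from orthodiv.bayes import PosteriorSamples, posterior_predictive_threshold


def degenerate_posterior(intensity, sigma2_e=0.0, n_draws=50, n_cells=2000, seed=3):
    """A point-mass posterior for analytic predictive checks."""
    cfg = od.FitConfig(iterations=2000, thin=10, burn_in_samples=100, seed=seed)
    draws = pd.DataFrame(
        {
            "intercept": np.full(n_draws, np.log(intensity)),
            "u_S": np.zeros(n_draws),
            "sigma2_u": np.zeros(n_draws),
            "sigma2_e": np.full(n_draws, sigma2_e),
        }
    )
    design = pd.DataFrame({"species": ["A"] * n_cells, "subfamily": ["S"] * n_cells})
    return PosteriorSamples(
        draws=draws, kind="poisson_glmm", species_levels=["A"],
        subfamily_levels=["S"], reference_species="A", config=cfg, design=design,
    )


class TestFitConfig:
    def test_burn_in_must_leave_samples(self):
        with pytest.raises(ValueError, match="burn_in"):
            od.FitConfig(iterations=1000, thin=10, burn_in_samples=100)

    def test_default_protocol_sample_counts(self):
        cfg = od.FitConfig()
        assert cfg.retained == 10_000 and cfg.kept == 9_000

    def test_quantile_bounds(self):
        with pytest.raises(ValueError, match="q"):
            od.FitConfig(iterations=2000, thin=10, burn_in_samples=10, q=1.5)


class TestPoissonGlmm:
    def test_single_species_intercept_recovery(self):
        obs = od.simulate_glmm_counts(
            1000, ["A"], ["S1", "S2"], beta0=0.4, seed=2, zero_truncated=False
        )
        cfg = od.FitConfig(iterations=20_000, thin=10, burn_in_samples=400, seed=9)
        s = od.fit_poisson_glmm(obs, cfg)
        m, sd = s.draws["intercept"].mean(), s.draws["intercept"].std()
        assert abs(m - 0.4) < 3 * sd

    def test_species_contrast_recovery(self):
        obs = od.simulate_glmm_counts(
            400, ["A", "B"], ["S1", "S2", "S3", "S4"], beta0=0.3,
            species_effects={"B": np.log(2)}, sigma2_e=0.2, seed=4,
            zero_truncated=False,
        )
        cfg = od.FitConfig(iterations=20_000, thin=10, burn_in_samples=400, seed=10)
        s = od.fit_poisson_glmm(obs, cfg)
        m, sd = s.draws["species_B"].mean(), s.draws["species_B"].std()
        assert abs(m - np.log(2)) < 3 * sd

    def test_seed_determinism_bit_exact(self):
        obs = od.simulate_glmm_counts(100, ["A", "B"], ["S1", "S2"], beta0=0.2, seed=5)
        cfg = od.FitConfig(iterations=3000, thin=5, burn_in_samples=100, seed=77)
        a = od.fit_poisson_glmm(obs, cfg)
        b = od.fit_poisson_glmm(obs, cfg)
        assert a.draws.equals(b.draws)

    def test_all_ones_matches_poisson_quantile_oracle(self):
        # all counts 1: fitted intensity ~1 (the MLE of lambda*exp(-lambda)),
        # so the predictive upper limit tracks poisson.ppf(0.95, ~1.0) = 3
        obs = pd.DataFrame(
            {
                "species": ["A"] * 400,
                "subfamily": ["S1", "S2"] * 200,
                "count": 1,
            }
        )
        cfg = od.FitConfig(iterations=10_000, thin=5, burn_in_samples=400, seed=6)
        s = od.fit_poisson_glmm(obs, cfg)
        th = posterior_predictive_threshold(s, seed=1)
        lam_hat = float(np.exp(s.draws["intercept"]).mean())
        oracle = stats.poisson.ppf(0.95, lam_hat)
        assert abs(th.mean_upper - oracle) <= 1.0
        assert th.threshold <= oracle + 1

    def test_empty_observations_rejected(self):
        with pytest.raises(ValueError, match="observations"):
            od.fit_poisson_glmm(
                pd.DataFrame(columns=["species", "subfamily", "count"]),
                od.FitConfig(iterations=1000, thin=10, burn_in_samples=10),
            )


class TestPredictiveThreshold:
    def test_degenerate_posterior_matches_poisson_quantile(self):
        # P(X<=2 | 1.2) ~ 0.879 < 0.95 <= P(X<=3) ~ 0.966: upper limit 3
        s = degenerate_posterior(1.2)
        th = posterior_predictive_threshold(s, q=0.95, seed=1)
        assert stats.poisson.ppf(0.95, 1.2) == 3
        assert np.all(th.per_draw_upper == 3)
        assert th.mean_upper == pytest.approx(3.0)
        assert th.threshold == 4

    def test_vanishing_intensity_gives_threshold_one(self):
        s = degenerate_posterior(1e-6)
        th = posterior_predictive_threshold(s, q=0.95, seed=2)
        assert th.mean_upper == 0.0 and th.threshold == 1

    def test_overdispersion_raises_upper_limit(self):
        base = posterior_predictive_threshold(degenerate_posterior(1.2), seed=3)
        wide = posterior_predictive_threshold(
            degenerate_posterior(1.2, sigma2_e=1.0), seed=3
        )
        assert wide.mean_upper > base.mean_upper

    def test_invalid_quantile_rejected(self):
        with pytest.raises(ValueError, match="q"):
            posterior_predictive_threshold(degenerate_posterior(1.0), q=1.2)


class TestFlagRedundant:
    @pytest.fixture()
    def matrix(self):
        table = pd.DataFrame(
            {"subfamily": ["S", "S"], "A": [5, 2], "B": [1, 2]},
            index=["S:OG0001", "S:OG0002"],
        )
        return od.AbundanceMatrix(table=table, species=["A", "B"])

    def test_threshold_four(self, matrix):
        flags = od.flag_redundant_orthogroups(matrix, 4)
        assert len(flags) == 1
        assert flags.iloc[0].to_dict() == {
            "orthogroup": "S:OG0001", "species": "A", "count": 5,
        }

    def test_threshold_one_flags_every_nonzero(self, matrix):
        assert len(od.flag_redundant_orthogroups(matrix, 1)) == 4

    def test_threshold_above_max_empty(self, matrix):
        assert len(od.flag_redundant_orthogroups(matrix, 6)) == 0


class TestRelatednessMatrix:
    def test_three_species_closed_form(self):
        tree = od.read_species_tree("((B:6,C:6):6,A:12);")
        C = od.relatedness_matrix(tree, ["A", "B", "C"])
        expected = np.array([[1, 0, 0], [0, 1, 0.5], [0, 0.5, 1]], dtype=float)
        np.testing.assert_allclose(C, expected)

    def test_missing_species_rejected(self):
        tree = od.read_species_tree("((B:6,C:6):6,A:12);")
        with pytest.raises(ValueError, match="missing"):
            od.relatedness_matrix(tree, ["A", "Z"])


class TestPhyloLmm:
    def _table(self, rng, species_offsets=None, n_subfam=12, base=2.0, noise=0.25):
        species_offsets = species_offsets or {}
        rows = []
        for k in range(n_subfam):
            for sp in ["A", "B", "C"]:
                rows.append(
                    {
                        "subfamily": f"S{k:02d}",
                        "species": sp,
                        "H": base + species_offsets.get(sp, 0.0) + noise * rng.normal(),
                    }
                )
        return pd.DataFrame(rows)

    @pytest.fixture()
    def tree(self):
        return od.read_species_tree("((B:6,C:6):6,A:12);")

    def test_identity_relatedness_equal_means_overlap(self, rng, tree):
        table = self._table(rng)
        cfg = od.FitConfig(iterations=10_000, thin=5, burn_in_samples=400, seed=8)
        s = od.fit_phylo_lmm(table, tree, cfg, relatedness=np.eye(3))
        comp = od.compare_groups(s, "species", interval=0.5)
        assert not comp["notable"].any()

    def test_injected_species_offset_recovered(self, rng, tree):
        table = self._table(rng, species_offsets={"C": 1.0})
        cfg = od.FitConfig(iterations=15_000, thin=5, burn_in_samples=500, seed=12)
        s = od.fit_phylo_lmm(table, tree, cfg)
        contrast = s.draws["species_C"] - s.draws["species_A"]
        assert abs(contrast.mean() - 1.0) < 3 * contrast.std()

    def test_location_equivariance(self, rng, tree):
        table = self._table(rng)
        cfg = od.FitConfig(iterations=8000, thin=5, burn_in_samples=300, seed=3)
        s1 = od.fit_phylo_lmm(table, tree, cfg)
        doubled = table.assign(H=2 * table["H"])
        s2 = od.fit_phylo_lmm(doubled, tree, cfg)
        m1 = np.mean([s1.draws[f"species_{x}"].mean() for x in "ABC"])
        m2 = np.mean([s2.draws[f"species_{x}"].mean() for x in "ABC"])
        assert m2 == pytest.approx(2 * m1, rel=0.02)

    def test_identity_reduction_matches_independent_sampler(self, rng, tree):
        """With C = I the model is an ordinary two-way random-effects model;
        cross-check posterior means against a separately coded Gibbs sampler."""
        table = self._table(rng, species_offsets={"B": 0.5}, n_subfam=10)
        cfg = od.FitConfig(iterations=20_000, thin=5, burn_in_samples=1000, seed=21)
        s = od.fit_phylo_lmm(table, tree, cfg, relatedness=np.eye(3))
        ref = _reference_two_way_gibbs(table, seed=22, n_iter=20_000, burn=4_000)
        for i, sp in enumerate(["A", "B", "C"]):
            ours = (s.draws["mu"] + s.draws[f"a_{sp}"]).mean()
            assert ours == pytest.approx(ref[i], abs=0.08)

    def test_fewer_than_two_subfamilies_rejected(self, rng, tree):
        table = self._table(rng, n_subfam=1)
        with pytest.raises(ValueError, match="subfamilies"):
            od.fit_phylo_lmm(table, tree, od.FitConfig(iterations=1000, thin=5, burn_in_samples=10))

    def test_singular_relatedness_suggests_jitter(self, rng, tree):
        table = self._table(rng)
        with pytest.raises(ValueError, match="jitter"):
            od.fit_phylo_lmm(
                table, tree,
                od.FitConfig(iterations=1000, thin=5, burn_in_samples=10),
                relatedness=np.ones((3, 3)),
            )


def _reference_two_way_gibbs(table, seed, n_iter, burn):
    """Independent scalar-update Gibbs sampler for y = mu + a_i + b_j + eps
    with iid normal priors; returns posterior mean of mu + a_i per species."""
    rng = np.random.default_rng(seed)
    species = sorted(table["species"].unique())
    subfams = sorted(table["subfamily"].unique())
    y = table["H"].to_numpy()
    si = table["species"].map({s: i for i, s in enumerate(species)}).to_numpy()
    ki = table["subfamily"].map({s: i for i, s in enumerate(subfams)}).to_numpy()
    S, K, n = len(species), len(subfams), len(y)
    mu, a, b = y.mean(), np.zeros(S), np.zeros(K)
    s2a = s2b = s2e = max(y.var(), 1e-3)
    sums = np.zeros(S)
    out = np.zeros(S)
    count = 0
    for it in range(n_iter):
        r = y - a[si] - b[ki]
        prec = n / s2e + 1 / 100.0
        mu = (r.sum() / s2e) / prec + rng.normal() / np.sqrt(prec)
        for i in range(S):
            mask = si == i
            prec = mask.sum() / s2e + 1 / s2a
            mean = ((y[mask] - mu - b[ki[mask]]).sum() / s2e) / prec
            a[i] = mean + rng.normal() / np.sqrt(prec)
        for k in range(K):
            mask = ki == k
            prec = mask.sum() / s2e + 1 / s2b
            mean = ((y[mask] - mu - a[si[mask]]).sum() / s2e) / prec
            b[k] = mean + rng.normal() / np.sqrt(prec)
        s2a = (0.001 + 0.5 * (a @ a)) / rng.gamma(0.001 + S / 2)
        s2b = (0.001 + 0.5 * (b @ b)) / rng.gamma(0.001 + K / 2)
        resid = y - mu - a[si] - b[ki]
        s2e = (0.001 + 0.5 * (resid @ resid)) / rng.gamma(0.001 + n / 2)
        if it >= burn:
            out += mu + a
            count += 1
    return out / count


class TestCompareGroups:
    def _samples(self, cols):
        cfg = od.FitConfig(iterations=2000, thin=10, burn_in_samples=10, seed=0)
        draws = pd.DataFrame(cols)
        return PosteriorSamples(
            draws=draws, kind="phylo_lmm",
            species_levels=[c.replace("species_", "") for c in cols],
            subfamily_levels=[], reference_species=None, config=cfg,
        )

    def test_identical_marginals_not_notable(self):
        x = np.linspace(-1, 1, 500)
        s = self._samples({"species_A": x, "species_B": x})
        assert not od.compare_groups(s)["notable"].any()

    def test_point_masses_notable(self):
        s = self._samples(
            {"species_A": np.zeros(100), "species_B": np.ones(100)}
        )
        assert od.compare_groups(s)["notable"].all()

    def test_widening_interval_never_creates_notability(self):
        rng = np.random.default_rng(0)
        s = self._samples(
            {
                "species_A": rng.normal(0, 1, 2000),
                "species_B": rng.normal(0.8, 1, 2000),
                "species_C": rng.normal(5.0, 1, 2000),
            }
        )
        narrow = od.compare_groups(s, interval=0.5)["notable"]
        wide = od.compare_groups(s, interval=0.9)["notable"]
        assert not (wide & ~narrow).any()
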