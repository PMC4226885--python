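"""Mixture likelihood, EM estimation, LOD profiles and variance partition."""

import itertools

import numpy as np
import pytest

from epiqtl import (
    BackcrossData,
    Locus,
    MIMModel,
    em_fit,
    evaluate_fit,
    genotype_mixture,
    genotypic_values,
    lod_profile,
    model_loglik,
    variance_partition,
)
from epiqtl.genetic_map import conditional_genotype_probability

from conftest import two_qtl_architecture
from epiqtl import simulate_backcross


def brute_force_loglik(model: MIMModel, data: BackcrossData) -> float:
    """Independent oracle: enumerate all 2^m configurations per individual
    directly from the single-locus conditional probabilities."""
    m = model.n_qtl
    total = 0.0
    for i in range(data.n):
        per_qtl = [
            conditional_genotype_probability(data.map, data.genotypes[i], loc)
            for loc in model.qtl
        ]
        lik = 0.0
        for cfg in itertools.product((0, 1), repeat=m):
            pi = 1.0
            mean = model.mu
            x = [0.5 if c == 0 else -0.5 for c in cfg]
            for k in range(m):
                pi *= per_qtl[k][cfg[k]]
                mean += model.a[k] * x[k]
            for (k, l), g in zip(model.interactions, model.gamma):
                mean += g * x[k] * x[l]
            lik += pi * np.exp(
                -0.5 * (data.phenotypes[i] - mean) ** 2 / model.sigma2
            ) / np.sqrt(2 * np.pi * model.sigma2)
        total += np.log(lik)
    return total


@pytest.fixture(scope="module")
def two_qtl_cross():
    return simulate_backcross(two_qtl_architecture(), 40, seed=9)


class TestGenotypeMixture:
    def test_single_qtl_at_marker(self, two_qtl_cross):
        mix = genotype_mixture(two_qtl_cross.data, [Locus("1", 20.0)])
        assert mix.codes.shape[1] == 1
        np.testing.assert_allclose(mix.pi, 1.0)
        assert mix.n_individuals == 40

    def test_two_unlinked_mid_interval_uniform(self, small_map):
        # discordant flanks around both loci -> 4 equiprobable configurations
        geno = np.array([[0, 1, 0, 1, 0, 0, 1, 0, 1, 0]])
        data = BackcrossData(
            phenotypes=np.array([0.0, 0.0]),
            genotypes=np.vstack([geno, geno]),
            map=small_map,
        )
        mix = genotype_mixture(data, [Locus("1", 5.0), Locus("2", 5.0)])
        assert mix.offsets[1] - mix.offsets[0] == 4
        np.testing.assert_allclose(mix.pi[:4], 0.25)

    @pytest.mark.parametrize("tau", [0.0, 1e-6, 1e-3])
    def test_retained_probabilities_sum_to_one(self, two_qtl_cross, tau):
        loci = [Locus("1", 25.0), Locus("2", 35.0)]
        mix = genotype_mixture(two_qtl_cross.data, loci, truncation=tau)
        sums = np.add.reduceat(mix.pi, mix.offsets[:-1])
        np.testing.assert_allclose(sums, 1.0, atol=1e-12)

    def test_two_loci_same_interval_rejected(self, two_qtl_cross):
        with pytest.raises(ValueError, match="interval"):
            genotype_mixture(two_qtl_cross.data, [Locus("1", 23.0), Locus("1", 27.0)])

    def test_qtl_cap(self, two_qtl_cross):
        loci = [Locus("1", p) for p in (5.0, 15.0, 25.0, 35.0, 45.0, 55.0)]
        loci += [Locus("2", p) for p in (5.0, 15.0, 25.0, 35.0, 45.0, 55.0)]
        loci += [Locus("1", 10.0)]  # 13th, on a marker
        with pytest.raises(ValueError, match="at most"):
            genotype_mixture(two_qtl_cross.data, loci)


class TestModelLoglik:
    def test_null_model_exact_normal(self, two_qtl_cross):
        y = two_qtl_cross.data.phenotypes
        model = MIMModel.null(mu=1.3, sigma2=2.1)
        expected = float(
            np.sum(-0.5 * np.log(2 * np.pi * 2.1) - 0.5 * (y - 1.3) ** 2 / 2.1)
        )
        assert model_loglik(model, two_qtl_cross.data) == pytest.approx(expected)

    def test_matches_enumeration_oracle(self, two_qtl_cross):
        model = MIMModel(
            qtl=(Locus("1", 22.0), Locus("2", 38.0)),
            a=np.array([0.8, -0.4]),
            interactions=((0, 1),),
            gamma=np.array([1.1]),
            mu=0.2,
            sigma2=1.4,
        )
        mix = genotype_mixture(two_qtl_cross.data, model.qtl, truncation=0.0)
        ll = model_loglik(model, two_qtl_cross.data, mixture=mix)
        assert ll == pytest.approx(brute_force_loglik(model, two_qtl_cross.data),
                                   rel=1e-10)

    def test_invalid_sigma2(self, two_qtl_cross):
        model = MIMModel.null()
        object.__setattr__(model, "sigma2", -1.0)
        with pytest.raises(ValueError):
            model_loglik(model, two_qtl_cross.data)


class TestEMFit:
    def test_null_model_normal_mle(self, two_qtl_cross):
        fit = em_fit(MIMModel.null(), two_qtl_cross.data)
        y = two_qtl_cross.data.phenotypes
        assert fit.model.mu == pytest.approx(np.mean(y), abs=1e-9)
        assert fit.model.sigma2 == pytest.approx(np.var(y), rel=1e-9)
        assert fit.converged

    def test_qtl_at_observed_marker_equals_ols(self, two_qtl_cross):
        # fully informative genotype -> EM equals closed-form regression
        data = two_qtl_cross.data
        off = data.map.marker_offset("1")
        x = np.where(data.genotypes[:, off + 2] == 0, 0.5, -0.5)  # marker at 20
        X = np.column_stack([np.ones(data.n), x])
        beta, *_ = np.linalg.lstsq(X, data.phenotypes, rcond=None)
        resid = data.phenotypes - X @ beta
        fit = em_fit(
            MIMModel(qtl=(Locus("1", 20.0),), a=np.zeros(1), interactions=(),
                     gamma=np.zeros(0)),
            data,
        )
        assert fit.model.mu == pytest.approx(beta[0], abs=1e-8)
        assert fit.model.a[0] == pytest.approx(beta[1], abs=1e-8)
        assert fit.model.sigma2 == pytest.approx(np.mean(resid**2), rel=1e-8)

    def test_loglik_monotone_every_iteration(self, arch1, arch1_cross):
        fit = em_fit(arch1.true_model(), arch1_cross.data,
                     init=MIMModel(qtl=arch1.qtl, a=np.zeros(8),
                                   interactions=arch1.interactions,
                                   gamma=np.zeros(8), mu=0.0, sigma2=4.0))
        diffs = np.diff(fit.loglik_history)
        assert np.all(diffs >= -1e-8)

    def test_estimates_near_truth_large_n(self, arch1):
        cross = simulate_backcross(arch1, 5000, seed=10)
        fit = em_fit(arch1.true_model(), cross.data, init=arch1.true_model())
        np.testing.assert_allclose(fit.model.a, arch1.main_effects, atol=0.2)
        np.testing.assert_allclose(fit.model.gamma, arch1.interaction_effects,
                                   atol=0.4)

    def test_singular_design_raises(self, small_map):
        # a chromosome that never recombines in-sample and an all-HOM cross
        rng = np.random.default_rng(0)
        geno = np.zeros((30, 10), dtype=np.int8)
        data = BackcrossData(phenotypes=rng.normal(size=30), genotypes=geno,
                             map=small_map)
        from epiqtl import SingularModelError

        model = MIMModel(qtl=(Locus("1", 10.0),), a=np.zeros(1),
                         interactions=(), gamma=np.zeros(0))
        with pytest.raises(SingularModelError):
            em_fit(model, data)


class TestLodProfile:
    def test_zero_effect_model_zero_lod(self, small_map):
        # phenotype exactly orthogonal to the coded marker: the refitted main
        # effect is zero, so the profile LOD vanishes at the QTL position
        geno = np.zeros((8, 10), dtype=np.int8)
        geno[4:, 2] = 1  # marker at 1:20 splits the sample in half
        geno[:, 1] = [0, 1] * 4
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        data = BackcrossData(phenotypes=y, genotypes=geno, map=small_map)
        model = MIMModel(qtl=(Locus("1", 20.0),), a=np.zeros(1),
                         interactions=(), gamma=np.zeros(0), mu=0.0, sigma2=1.0)
        fit = em_fit(model, data)
        assert fit.model.a[0] == pytest.approx(0.0, abs=1e-10)
        grid, lods = lod_profile(fit, data, 0, grid=[20.0])
        assert lods[0] == pytest.approx(0.0, abs=1e-6)

    def test_profile_equals_refit_oracle(self, two_qtl_cross):
        data = two_qtl_cross.data
        fit = em_fit(
            MIMModel(qtl=(Locus("1", 25.0),), a=np.zeros(1), interactions=(),
                     gamma=np.zeros(0)),
            data,
        )
        grid, lods = lod_profile(fit, data, 0, grid=[15.0, 25.0])
        reduced = em_fit(MIMModel.null(), data)
        for pos, lod in zip(grid, lods):
            full = em_fit(
                MIMModel(qtl=(Locus("1", float(pos)),), a=np.zeros(1),
                         interactions=(), gamma=np.zeros(0)),
                data,
            )
            assert lod == pytest.approx(
                (full.loglik - reduced.loglik) / np.log(10.0), abs=1e-5
            )

    def test_empty_grid_rejected(self, two_qtl_cross):
        fit = em_fit(
            MIMModel(qtl=(Locus("1", 25.0),), a=np.zeros(1), interactions=(),
                     gamma=np.zeros(0)),
            two_qtl_cross.data,
        )
        with pytest.raises(ValueError):
            lod_profile(fit, two_qtl_cross.data, 0, grid=[])


class TestVariancePartitionAndGenotypicValues:
    def test_null_model_zero_r2(self, two_qtl_cross):
        fit = em_fit(MIMModel.null(), two_qtl_cross.data)
        part = variance_partition(fit)
        assert part["r_squared"] == 0.0
        assert part["residual_fraction"] == 1.0

    def test_single_marker_qtl_r2_is_squared_correlation(self, two_qtl_cross):
        data = two_qtl_cross.data
        off = data.map.marker_offset("1")
        x = np.where(data.genotypes[:, off + 2] == 0, 0.5, -0.5)
        fit = em_fit(
            MIMModel(qtl=(Locus("1", 20.0),), a=np.zeros(1), interactions=(),
                     gamma=np.zeros(0)),
            data,
        )
        part = variance_partition(fit)
        r2 = np.corrcoef(x, data.phenotypes)[0, 1] ** 2
        assert part["r_squared"] == pytest.approx(r2, rel=1e-6)

    def test_components_sum_to_one(self, arch1, arch1_cross):
        fit = em_fit(arch1.true_model(), arch1_cross.data, init=arch1.true_model())
        part = variance_partition(fit)
        total = (
            sum(part["components"].values())
            + sum(part["covariances"].values())
            + part["residual_fraction"]
        )
        assert total == pytest.approx(1.0, rel=1e-9)

    def test_true_model_r2_near_heritability(self, arch1):
        cross = simulate_backcross(arch1, 20_000, seed=11)
        fit = em_fit(arch1.true_model(), cross.data, init=arch1.true_model())
        part = variance_partition(fit)
        assert part["r_squared"] == pytest.approx(0.80, abs=0.03)

    def test_genotypic_values_zero_effect(self, two_qtl_cross):
        model = MIMModel(
            qtl=(Locus("1", 20.0),), a=np.zeros(1), interactions=(),
            gamma=np.zeros(0), mu=1.5, sigma2=1.0,
        )
        fit = evaluate_fit(model, two_qtl_cross.data)
        np.testing.assert_allclose(genotypic_values(fit), 1.5)

    def test_genotypic_values_fully_informative(self, two_qtl_cross):
        # both QTL on observed markers: value equals the model equation
        data = two_qtl_cross.data
        model = MIMModel(
            qtl=(Locus("1", 20.0), Locus("2", 30.0)),
            a=np.array([1.0, -0.5]),
            interactions=((0, 1),),
            gamma=np.array([2.0]),
            mu=0.3,
            sigma2=1.0,
        )
        fit = evaluate_fit(model, data)
        off1 = data.map.marker_offset("1")
        off2 = data.map.marker_offset("2")
        x1 = np.where(data.genotypes[:, off1 + 2] == 0, 0.5, -0.5)
        x2 = np.where(data.genotypes[:, off2 + 3] == 0, 0.5, -0.5)
        expected = 0.3 + 1.0 * x1 - 0.5 * x2 + 2.0 * x1 * x2
        np.testing.assert_allclose(genotypic_values(fit), expected, atol=1e-9)

    def test_genotypic_value_correlation_near_h2(self, arch1):
        cross = simulate_backcross(arch1, 10_000, seed=12)
        fit = em_fit(arch1.true_model(), cross.data, init=arch1.true_model())
        gv = genotypic_values(fit)
        r2 = np.corrcoef(gv, cross.data.phenotypes)[0, 1] ** 2
        # posterior values use y, so r^2 slightly exceeds h^2; loose band
        assert 0.75 < r2 < 0.9
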