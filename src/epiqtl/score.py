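"""Efficient score tests and normal-multiplier resampling thresholds.

The score statistic approximates the likelihood-ratio test for adding
parameters to a fitted MIM model without refitting the alternative.  Per
individual, the score contribution of a candidate parameter is the
derivative of the mixture log-likelihood at the null estimates; directions
spanned by the null model's own parameters (the nuisance scores) are
projected out, and the statistic is the quadratic form of the summed
efficient contributions in their empirical (outer-product) information.

Because the statistic is a quadratic form in a sum of per-individual terms,
its null distribution can be regenerated by reweighting every term with one
standard-normal multiplier per individual (shared across all positions of a
search space within a resample).  The empirical distribution of the maximum
reweighted statistic over the search space yields genome-wide thresholds;
a single-point space yields pointwise thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genetic_map import GeneticMap, Locus, conditional_genotype_probabilities
from .mim import BackcrossData, FitResult, em_fit, MIMModel

__all__ = [
    "ScoreTest",
    "ThresholdEstimate",
    "CrossWorkspace",
    "ScoreEngine",
    "efficient_score_test",
    "resample_max_distribution",
    "pointwise_threshold",
    "empirical_pvalue",
    "permutation_threshold_interval_mapping",
]

_RIDGE = 1e-10


class CrossWorkspace:
    """Per-dataset cache of conditional genotype probabilities, keyed by
    locus.  Scans evaluate the same grid positions many times across search
    iterations; the probabilities depend only on map and markers."""

    def __init__(self, data: BackcrossData):
        self.data = data
        self._cache: dict[tuple[str, float], np.ndarray] = {}

    def probs(self, locus: Locus) -> np.ndarray:
        key = (locus.chromosome, round(float(locus.position), 6))
        hit = self._cache.get(key)
        if hit is None:
            hit = conditional_genotype_probabilities(
                self.data.map, self.data.genotypes, locus
            )
            self._cache[key] = hit
        return hit

    def zcodes(self, locus: Locus) -> np.ndarray:
        """Marginal expected Cockerham code E[x | markers] per individual."""
        p = self.probs(locus)
        return 0.5 * (p[:, 0] - p[:, 1])

    def zmatrix(self, loci: Sequence[Locus]) -> np.ndarray:
        if not loci:
            return np.zeros((self.data.n, 0))
        return np.column_stack([self.zcodes(loc) for loc in loci])

    def per_qtl_probs(self, loci: Sequence[Locus]) -> np.ndarray:
        return np.array([self.probs(loc) for loc in loci])


@dataclass
class ScoreTest:
    """An efficient score test for one or more added parameters.

    ``contributions`` holds the projected, leverage-corrected per-individual
    scores used for variance estimation and multiplier resampling; the
    observed statistic's numerator is the plain sum of the projected scores.
    """

    statistic: float
    contributions: np.ndarray = field(repr=False)  # n x t corrected scores
    information: np.ndarray = field(repr=False)  # t x t empirical information
    singular: bool = False


@dataclass
class ThresholdEstimate:
    """Empirical resampled distribution of the max statistic over a search
    space."""

    resamples: np.ndarray  # (B,) sorted ascending
    seed: int | None = None

    def __post_init__(self) -> None:
        r = np.sort(np.asarray(self.resamples, dtype=float))
        if r.size < 100:
            raise ValueError("need at least 100 resamples")
        object.__setattr__(self, "resamples", r)

    @property
    def B(self) -> int:
        return int(self.resamples.size)

    def quantile(self, alpha: float) -> float:
        """(1 - alpha) empirical quantile; alpha = 1 gives the minimum."""
        if not (0.0 < alpha <= 1.0):
            raise ValueError("alpha must be in (0, 1]")
        return float(np.quantile(self.resamples, 1.0 - alpha, method="higher"))

    def pvalue(self, observed: float) -> float:
        return empirical_pvalue(observed, self)


def empirical_pvalue(observed: float, thresholds: ThresholdEstimate) -> float:
    """p = (1 + #{resampled >= observed}) / (B + 1)."""
    count = int(np.sum(thresholds.resamples >= observed))
    return (1.0 + count) / (thresholds.B + 1.0)


def _orth_basis(S: np.ndarray) -> np.ndarray:
    """Orthonormal basis of the column space (rank-robust, via SVD)."""
    if S.size == 0:
        return np.zeros((S.shape[0], 0))
    U, s, _ = np.linalg.svd(S, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return np.zeros((S.shape[0], 0))
    return U[:, s > s[0] * 1e-10]


class ScoreEngine:
    """Score machinery bound to one null fit.

    Exposes the per-individual nuisance scores of the fitted model (as an
    orthonormal basis for projection) and builders for raw score columns of
    candidate parameters.  All score columns drop the common 1/sigma^2
    factor — the projected quadratic-form statistic is scale invariant.
    """

    def __init__(self, fit: FitResult, workspace: CrossWorkspace | None = None):
        self.fit = fit
        self.workspace = workspace if workspace is not None else CrossWorkspace(fit.data)
        mix = fit.mixture
        y = fit.data.phenotypes
        beta = np.concatenate(([fit.model.mu], fit.model.a, fit.model.gamma))
        resid = y[mix.indiv] - fit.design @ beta
        wr = fit.weights * resid
        # per-individual score of each mean-structure parameter
        self.param_scores = np.add.reduceat(
            wr[:, None] * fit.design, mix.offsets[:-1], axis=0
        )
        # sigma^2 score: sum_c w [(y-mu_c)^2 / (2 s^4) - 1 / (2 s^2)]
        s2 = fit.model.sigma2
        wr2 = np.add.reduceat(fit.weights * resid**2, mix.offsets[:-1])
        sig_score = wr2 / (2.0 * s2**2) - 1.0 / (2.0 * s2)
        S = np.column_stack([self.param_scores, sig_score])
        self._Q = _orth_basis(S)
        # leverage of the nuisance projection; used for the finite-sample
        # variance correction (the projection overfits heavy-tailed
        # contributions, deflating the empirical information)
        if self._Q.shape[1]:
            self.leverage = np.einsum("ij,ij->i", self._Q, self._Q)
        else:
            self.leverage = np.zeros(fit.data.n)
        # jackknife-style (HC3) correction: heavy-leverage individuals have
        # their projected contributions scaled back up
        self.var_scale = 1.0 / np.clip(1.0 - self.leverage, 0.05, None)

    # -- nuisance projection -------------------------------------------

    def project(self, U: np.ndarray) -> np.ndarray:
        """Project out the null model's nuisance score directions."""
        if self._Q.shape[1] == 0:
            return U
        return U - self._Q @ (self._Q.T @ U)

    def scaled(self, U_proj: np.ndarray, extra_leverage: np.ndarray | None = None) -> np.ndarray:
        """Leverage-corrected contributions for variance estimation and
        resampling: u_i / sqrt(1 - h_i), with per-column extra leverage from
        any additional per-test nuisance directions."""
        if extra_leverage is None:
            if U_proj.ndim == 1:
                return U_proj * self.var_scale
            return U_proj * self.var_scale[:, None]
        h = self.leverage[:, None] + extra_leverage
        return U_proj / np.clip(1.0 - h, 0.05, None)

    # -- raw score columns ---------------------------------------------

    @property
    def posterior_residual(self) -> np.ndarray:
        """sum_c w_ic (y_i - mu_c); equals the intercept score column."""
        return self.param_scores[:, 0]

    def main_score(self, k: int) -> np.ndarray:
        """Score column of main effect a_k of a QTL already in the model."""
        return self.param_scores[:, 1 + k]

    def new_main_columns(self, loci: Sequence[Locus]) -> np.ndarray:
        """Raw scores of new main effects at candidate loci (n x P)."""
        Z = self.workspace.zmatrix(loci)
        return self.posterior_residual[:, None] * Z

    def new_interaction_columns(self, loci: Sequence[Locus], k: int) -> np.ndarray:
        """Raw scores of the interaction between a new QTL at each candidate
        locus and existing QTL ``k``."""
        Z = self.workspace.zmatrix(loci)
        return self.main_score(k)[:, None] * Z

    def existing_interaction_column(self, k: int, l: int) -> np.ndarray:
        """Raw score of a new interaction between model QTL ``k`` and ``l``."""
        mix = self.fit.mixture
        y = self.fit.data.phenotypes
        beta = np.concatenate(
            ([self.fit.model.mu], self.fit.model.a, self.fit.model.gamma)
        )
        resid = y[mix.indiv] - self.fit.design @ beta
        col = self.fit.weights * resid * mix.codes[:, k] * mix.codes[:, l]
        return np.add.reduceat(col, mix.offsets[:-1])

    def pair_interaction_column(self, locus1: Locus, locus2: Locus) -> np.ndarray:
        """Raw score of the interaction between two proposed new QTL."""
        z1 = self.workspace.zcodes(locus1)
        z2 = self.workspace.zcodes(locus2)
        return self.posterior_residual * z1 * z2


def _joint_statistic(
    U_num: np.ndarray, U_var: np.ndarray
) -> tuple[float, np.ndarray, bool]:
    """Quadratic-form statistic: numerator from projected contributions,
    information from the leverage-corrected ones."""
    V = U_var.T @ U_var
    usum = U_num.sum(axis=0)
    t = V.shape[0]
    singular = False
    if t == 1:
        v = float(V[0, 0])
        if v <= _RIDGE:
            return 0.0, V, True
        return float(usum[0] ** 2 / v), V, False
    try:
        stat = float(usum @ np.linalg.solve(V, usum))
        if not np.isfinite(stat) or stat < 0:
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        stat = float(usum @ np.linalg.pinv(V) @ usum)
        singular = True
    return stat, V, singular


def efficient_score_test(
    data: BackcrossData,
    null_fit: FitResult,
    added_terms: Sequence[tuple],
    workspace: CrossWorkspace | None = None,
    engine: ScoreEngine | None = None,
) -> ScoreTest:
    """Score test for adding parameters to ``null_fit``'s model.

    ``added_terms`` descriptors:

    * ``("main", locus)`` — main effect of a new QTL at ``locus``;
    * ``("int_new", locus, k)`` — interaction between a new QTL at ``locus``
      and existing QTL ``k``; the new QTL's main effect is held at zero and
      projected out as a nuisance direction;
    * ``("int_existing", k, l)`` — interaction between two model QTL;
    * ``("int_pair", locus1, locus2)`` — interaction between two new QTL;
      both new main effects are nuisance directions at zero.
    """
    if engine is None:
        engine = ScoreEngine(null_fit, workspace)
    cols: list[np.ndarray] = []
    extra: list[np.ndarray] = []
    for term in added_terms:
        kind = term[0]
        if kind == "main":
            cols.append(engine.new_main_columns([term[1]])[:, 0])
        elif kind == "int_new":
            _, locus, k = term
            cols.append(engine.new_interaction_columns([locus], k)[:, 0])
            extra.append(engine.new_main_columns([locus])[:, 0])
        elif kind == "int_existing":
            _, k, l = term
            cols.append(engine.existing_interaction_column(k, l))
        elif kind == "int_pair":
            _, l1, l2 = term
            cols.append(engine.pair_interaction_column(l1, l2))
            extra.append(engine.new_main_columns([l1])[:, 0])
            extra.append(engine.new_main_columns([l2])[:, 0])
        else:
            raise ValueError(f"unknown term descriptor {term!r}")
    U = engine.project(np.column_stack(cols))
    extra_lev = None
    if extra:
        E = engine.project(np.column_stack(extra))
        Qe = _orth_basis(E)
        if Qe.shape[1]:
            U = U - Qe @ (Qe.T @ U)
            extra_lev = np.einsum("ij,ij->i", Qe, Qe)[:, None]
    Uv = engine.scaled(U, extra_lev)
    stat, V, singular = _joint_statistic(U, Uv)
    return ScoreTest(statistic=stat, contributions=Uv, information=V, singular=singular)


# -- resampling --------------------------------------------------------


def resampled_maxima_1d(
    U: np.ndarray, B: int, rng: np.random.Generator
) -> np.ndarray:
    """Maxima over a search space of single-parameter tests.

    ``U`` is n x P projected contributions; one N(0,1) multiplier per
    individual per resample, shared across positions.  The per-position
    information is held fixed at its observed value.
    """
    if U.ndim != 2 or U.shape[1] == 0:
        raise ValueError("empty search space")
    V = np.einsum("ij,ij->j", U, U)
    ok = V > _RIDGE
    if not np.any(ok):
        return np.zeros(B)
    G = rng.standard_normal((B, U.shape[0]))
    num = G @ U[:, ok]
    stats = num**2 / V[ok][None, :]
    return stats.max(axis=1)


def resample_max_distribution(
    score_tests: Sequence[ScoreTest],
    B: int,
    seed: int | np.random.Generator = 0,
) -> ThresholdEstimate:
    """Resampled distribution of the max statistic over ``score_tests``.

    All tests must share the same individuals.  Within each of the ``B``
    resamples a single standard-normal multiplier vector reweights every
    test's contributions; information matrices stay at their observed values.
    """
    if len(score_tests) == 0:
        raise ValueError("empty search space")
    if B < 100:
        raise ValueError("need at least 100 resamples")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = score_tests[0].contributions.shape[0]
    if any(t.contributions.shape[0] != n for t in score_tests):
        raise ValueError("score tests must share the same individuals")

    if all(t.contributions.shape[1] == 1 for t in score_tests):
        U = np.column_stack([t.contributions[:, 0] for t in score_tests])
        maxima = resampled_maxima_1d(U, B, rng)
    else:
        G = rng.standard_normal((B, n))
        per_test = []
        for t in score_tests:
            Uc = t.contributions
            num = G @ Uc  # B x t
            try:
                sol = np.linalg.solve(t.information, num.T)
            except np.linalg.LinAlgError:
                sol = np.linalg.pinv(t.information) @ num.T
            per_test.append(np.einsum("bt,tb->b", num, sol))
        maxima = np.max(np.column_stack(per_test), axis=1)
    return ThresholdEstimate(resamples=maxima)


def pointwise_threshold(
    score_test: ScoreTest,
    B: int,
    alpha: float,
    seed: int | np.random.Generator = 0,
) -> float:
    """(1 - alpha) quantile of the resampled statistic at a single test."""
    if B < 100:
        raise ValueError("need at least 100 resamples")
    dist = resample_max_distribution([score_test], B, seed)
    return dist.quantile(alpha)


# -- permutation LRT harness (validation only) --------------------------


def permutation_threshold_interval_mapping(
    data: BackcrossData,
    n_perm: int,
    alpha: float,
    seed: int | np.random.Generator = 0,
    grid_cm: float = 1.0,
    em_iters: int = 30,
    em_tol: float = 1e-6,
) -> float:
    """Genome-wide LRT threshold for single-QTL interval mapping under
    phenotype permutation.

    At each grid position a two-component normal mixture (mixing proportions
    from the conditional genotype probabilities) is fitted by EM to every
    permuted phenotype vector simultaneously; the (1 - alpha) quantile of the
    per-permutation genome-wide maximum of 2 * (loglik_1 - loglik_0) is
    returned.  This is the standard empirical-threshold oracle the score
    resampling is compared against.
    """
    if n_perm < 100:
        raise ValueError("need at least 100 permutations")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    y = data.phenotypes
    n = y.shape[0]
    Y = np.empty((n, n_perm))
    for b in range(n_perm):
        Y[:, b] = y[rng.permutation(n)]

    # null log-likelihood is permutation invariant
    var0 = float(np.var(y))
    ll0 = -0.5 * n * (np.log(2.0 * np.pi * var0) + 1.0)

    ws = CrossWorkspace(data)
    grid = data.map.grid(grid_cm)
    max_lrt = np.zeros(n_perm)
    mu = np.full(n_perm, float(np.mean(y)))
    for locus in grid:
        probs = ws.probs(locus)  # n x 2
        p_hom = probs[:, 0][:, None]
        a = np.zeros(n_perm)
        mu_p = mu.copy()
        s2 = np.full(n_perm, var0)
        ll_prev = np.full(n_perm, -np.inf)
        for _ in range(em_iters):
            mu_hom = mu_p[None, :] + 0.5 * a[None, :]
            mu_het = mu_p[None, :] - 0.5 * a[None, :]
            d_hom = Y - mu_hom
            d_het = Y - mu_het
            log_h = np.log(np.clip(p_hom, 1e-300, None)) - 0.5 * d_hom**2 / s2[None, :]
            log_t = np.log(np.clip(1.0 - p_hom, 1e-300, None)) - 0.5 * d_het**2 / s2[None, :]
            mx = np.maximum(log_h, log_t)
            w_h = np.exp(log_h - mx)
            w_t = np.exp(log_t - mx)
            tot = w_h + w_t
            ll = (mx + np.log(tot)).sum(axis=0) - 0.5 * n * np.log(2.0 * np.pi * s2)
            w_h = w_h / tot
            # weighted regression of y on x in {+-1/2}; x^2 = 1/4 identically
            e = w_h - 0.5  # E[x]
            se = e.sum(axis=0)
            sy = Y.sum(axis=0)
            sey = (e * Y).sum(axis=0)
            det = n * (n / 4.0) - se**2
            mu_new = ((n / 4.0) * sy - se * sey) / det
            a_new = (n * sey - se * sy) / det
            r = Y - mu_new[None, :]
            s2_new = (
                (r**2).sum(axis=0) - 2.0 * a_new * (e * r).sum(axis=0) + a_new**2 * n / 4.0
            ) / n
            mu_p, a, s2 = mu_new, a_new, np.clip(s2_new, 1e-12, None)
            if np.all(np.isfinite(ll_prev)) and np.all(
                ll - ll_prev <= em_tol * (np.abs(ll_prev) + 1e-12)
            ):
                break
            ll_prev = ll
        np.maximum(max_lrt, 2.0 * (ll - ll0), out=max_lrt)
    return float(np.quantile(max_lrt, 1.0 - alpha, method="higher"))
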