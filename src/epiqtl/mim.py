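"""Multiple-interval-mapping core: mixture likelihood and EM estimation.

The model for a backcross with ``m`` putative QTL is

    y_i = mu + sum_k a_k x_ik + sum_{(k,l)} gamma_kl x_ik x_il + eps_i,

with Cockerham codes x in {+1/2, -1/2}, eps ~ N(0, sigma^2), and only a
selected subset of unordered pairs (k, l) carrying an interaction effect.
QTL genotypes are unobserved; given marker data the likelihood is a mixture
of (up to) 2^m normals whose mixing proportions are the conditional
probabilities of the multi-locus QTL genotype configurations.  Tiny mixing
proportions are truncated and the remainder renormalized.  Parameters are
estimated by EM: the E-step computes posterior configuration weights, the
M-step solves the weighted least-squares normal equations and updates
sigma^2 from the weighted residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .genetic_map import (
    GeneticMap,
    Locus,
    conditional_genotype_probabilities,
)

MAX_QTL = 12
DEFAULT_TRUNCATION = 1e-6
DEFAULT_EM_TOL = 1e-8
DEFAULT_EM_MAXIT = 1000

__all__ = [
    "BackcrossData",
    "MIMModel",
    "GenotypeMixture",
    "FitResult",
    "SingularModelError",
    "genotype_mixture",
    "model_loglik",
    "em_fit",
    "evaluate_fit",
    "lod_profile",
    "variance_partition",
    "genotypic_values",
]


class SingularModelError(RuntimeError):
    """Raised when the weighted normal equations are (numerically) singular."""


@dataclass(frozen=True)
class BackcrossData:
    """Phenotypes + marker genotypes + map for one backcross population."""

    phenotypes: np.ndarray
    genotypes: np.ndarray  # n x M codes (HOM/HET/MISSING), columns in map order
    map: GeneticMap

    def __post_init__(self) -> None:
        y = np.asarray(self.phenotypes, dtype=float)
        g = np.asarray(self.genotypes)
        if y.ndim != 1 or y.shape[0] < 2:
            raise ValueError("need at least 2 phenotyped individuals")
        if not np.all(np.isfinite(y)):
            raise ValueError("phenotypes must be finite")
        if g.shape != (y.shape[0], self.map.n_markers):
            raise ValueError(
                f"genotype matrix shape {g.shape} does not match "
                f"(n={y.shape[0]}, M={self.map.n_markers})"
            )
        object.__setattr__(self, "phenotypes", y)
        object.__setattr__(self, "genotypes", g)

    @property
    def n(self) -> int:
        return int(self.phenotypes.shape[0])


@dataclass(frozen=True, eq=False)
class MIMModel:
    """An MIM model structure with (possibly estimated) parameters.

    ``interactions`` holds unordered 0-based QTL index pairs (k < l); the
    aligned ``gamma`` vector holds their effects.
    """

    qtl: tuple[Locus, ...]
    a: np.ndarray
    interactions: tuple[tuple[int, int], ...]
    gamma: np.ndarray
    mu: float = 0.0
    sigma2: float = 1.0

    def __post_init__(self) -> None:
        a = np.atleast_1d(np.asarray(self.a, dtype=float))
        g = np.atleast_1d(np.asarray(self.gamma, dtype=float))
        m = len(self.qtl)
        if a.shape != (m,):
            raise ValueError("main-effect vector length must equal number of QTL")
        pairs = tuple(tuple(sorted(p)) for p in self.interactions)
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate interaction pairs")
        for k, l in pairs:
            if not (0 <= k < l < m):
                raise ValueError(f"interaction pair ({k}, {l}) references invalid QTL")
        if g.shape != (len(pairs),):
            raise ValueError("gamma length must equal number of interaction pairs")
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        object.__setattr__(self, "qtl", tuple(self.qtl))
        object.__setattr__(self, "interactions", pairs)
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "gamma", g)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MIMModel):
            return NotImplemented
        return (
            self.qtl == other.qtl
            and self.interactions == other.interactions
            and np.array_equal(self.a, other.a)
            and np.array_equal(self.gamma, other.gamma)
            and self.mu == other.mu
            and self.sigma2 == other.sigma2
        )

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    @property
    def n_params(self) -> int:
        """Mean-structure parameters: mu + mains + interactions."""
        return 1 + self.n_qtl + len(self.interactions)

    def partners(self, k: int) -> list[int]:
        """QTL indices interacting with QTL ``k``."""
        return [l if j == k else j for (j, l) in self.interactions if k in (j, l)]

    @classmethod
    def null(cls, mu: float = 0.0, sigma2: float = 1.0) -> "MIMModel":
        return cls(qtl=(), a=np.zeros(0), interactions=(), gamma=np.zeros(0),
                   mu=mu, sigma2=sigma2)

    # structural edits used by the model search -----------------------

    def with_qtl(self, locus: Locus, effect: float = 0.0) -> "MIMModel":
        return replace(self, qtl=self.qtl + (locus,), a=np.append(self.a, effect))

    def with_interaction(self, k: int, l: int, effect: float = 0.0) -> "MIMModel":
        k, l = sorted((k, l))
        return replace(
            self,
            interactions=self.interactions + ((k, l),),
            gamma=np.append(self.gamma, effect),
        )

    def without_interaction(self, k: int, l: int) -> "MIMModel":
        k, l = sorted((k, l))
        keep = [i for i, p in enumerate(self.interactions) if p != (k, l)]
        return replace(
            self,
            interactions=tuple(self.interactions[i] for i in keep),
            gamma=self.gamma[keep],
        )

    def without_qtl(self, k: int) -> "MIMModel":
        """Remove QTL ``k`` along with all of its interaction terms."""
        keep = [i for i, p in enumerate(self.interactions) if k not in p]

        def shift(j: int) -> int:
            return j - 1 if j > k else j

        pairs = tuple(
            (shift(a_), shift(b_)) for (a_, b_) in (self.interactions[i] for i in keep)
        )
        return replace(
            self,
            qtl=self.qtl[:k] + self.qtl[k + 1 :],
            a=np.delete(self.a, k),
            interactions=pairs,
            gamma=self.gamma[keep],
        )

    def moved(self, k: int, locus: Locus) -> "MIMModel":
        qtl = list(self.qtl)
        qtl[k] = locus
        return replace(self, qtl=tuple(qtl))


@dataclass(frozen=True)
class GenotypeMixture:
    """Retained multi-locus genotype configurations per individual (ragged,
    stored flat).  ``codes`` holds Cockerham ±1/2 codes, one row per retained
    configuration; rows of individual ``i`` are ``offsets[i]:offsets[i+1]``."""

    indiv: np.ndarray  # (N,) individual index per row
    codes: np.ndarray  # (N, m)
    pi: np.ndarray  # (N,) prior mixing proportions, sum to 1 per individual
    offsets: np.ndarray  # (n + 1,)

    @property
    def n_individuals(self) -> int:
        return len(self.offsets) - 1

    @property
    def n_qtl(self) -> int:
        return self.codes.shape[1]


def _per_qtl_probs(data: BackcrossData, loci: Sequence[Locus]) -> np.ndarray:
    """(m, n, 2) conditional genotype probabilities for each locus."""
    return np.array(
        [conditional_genotype_probabilities(data.map, data.genotypes, loc) for loc in loci]
    )


def _check_distinct_intervals(gmap: GeneticMap, loci: Sequence[Locus]) -> None:
    """QTL must occupy distinct marker intervals (else their genotypes are not
    conditionally independent given the flanking markers)."""
    seen: set[tuple[str, int]] = set()
    for loc in loci:
        pos = gmap.chrom_positions(loc.chromosome)
        # interval index: markers[j] <= p < markers[j+1]; a locus exactly on an
        # interior marker sits on the boundary and conflicts with neither side,
        # give it its own pseudo-interval.
        on_marker = np.any(np.abs(pos - loc.position) <= 1e-9)
        if on_marker:
            j = int(np.argmin(np.abs(pos - loc.position)))
            key = (loc.chromosome, -j - 1)
        else:
            j = int(np.searchsorted(pos, loc.position) - 1)
            key = (loc.chromosome, j)
        if key in seen:
            raise ValueError(f"two QTL share marker interval {key} on {loc.chromosome}")
        seen.add(key)


def genotype_mixture(
    data: BackcrossData,
    loci: Sequence[Locus],
    truncation: float = DEFAULT_TRUNCATION,
    per_qtl_probs: np.ndarray | None = None,
) -> GenotypeMixture:
    """Joint genotype-configuration priors given marker data.

    Per-QTL conditional probabilities multiply across QTL (QTL in distinct
    marker intervals are conditionally independent given their flanking
    markers).  Configurations with prior below ``truncation`` are dropped and
    the remainder renormalized; the most probable configuration is always
    retained.
    """
    m = len(loci)
    if m > MAX_QTL:
        raise ValueError(f"at most {MAX_QTL} QTL supported (got {m})")
    n = data.n
    if m == 0:
        return GenotypeMixture(
            indiv=np.arange(n),
            codes=np.zeros((n, 0)),
            pi=np.ones(n),
            offsets=np.arange(n + 1),
        )
    _check_distinct_intervals(data.map, loci)
    probs = per_qtl_probs if per_qtl_probs is not None else _per_qtl_probs(data, loci)

    # dense joint over 2^m configurations: bit k of config index = genotype of QTL k
    joint = np.ones((n, 1))
    for k in range(m):
        joint = (joint[:, :, None] * probs[k][:, None, :]).reshape(n, -1)

    n_cfg = 1 << m
    # configuration index: QTL 0 is the most significant bit (outermost factor
    # in the joint product above); bit value 0=HOM, 1=HET
    bits = (np.arange(n_cfg)[:, None] >> (m - 1 - np.arange(m))[None, :]) & 1
    codes_full = np.where(bits == 0, 0.5, -0.5)

    keep = (joint >= truncation) & (joint > 0.0)
    keep[np.arange(n), joint.argmax(axis=1)] = True
    counts = keep.sum(axis=1)
    offsets = np.concatenate(([0], np.cumsum(counts)))
    indiv = np.repeat(np.arange(n), counts)
    cfg_idx = np.flatnonzero(keep.ravel()) % n_cfg
    pi = joint[keep]
    # renormalize within individuals
    sums = np.add.reduceat(pi, offsets[:-1])
    pi = pi / sums[indiv]
    return GenotypeMixture(indiv=indiv, codes=codes_full[cfg_idx], pi=pi, offsets=offsets)


def design_matrix(model: MIMModel, mixture: GenotypeMixture) -> np.ndarray:
    """Per-configuration design rows: [1, x_1..x_m, x_k x_l per interaction]."""
    N = mixture.codes.shape[0]
    cols = [np.ones(N)]
    for k in range(model.n_qtl):
        cols.append(mixture.codes[:, k])
    for k, l in model.interactions:
        cols.append(mixture.codes[:, k] * mixture.codes[:, l])
    return np.column_stack(cols)


def _beta(model: MIMModel) -> np.ndarray:
    return np.concatenate(([model.mu], model.a, model.gamma))


def _model_with_beta(model: MIMModel, beta: np.ndarray, sigma2: float) -> MIMModel:
    m = model.n_qtl
    return replace(
        model,
        mu=float(beta[0]),
        a=beta[1 : 1 + m].copy(),
        gamma=beta[1 + m :].copy(),
        sigma2=float(sigma2),
    )


def _estep(
    y: np.ndarray,
    mixture: GenotypeMixture,
    D: np.ndarray,
    beta: np.ndarray,
    sigma2: float,
) -> tuple[float, np.ndarray, np.ndarray]:
    """Posterior configuration weights and the observed-data log-likelihood.

    Returns (loglik, posterior weights per row, residual per row at beta).
    """
    resid = y[mixture.indiv] - D @ beta
    logw = np.log(mixture.pi) - 0.5 * resid**2 / sigma2
    # per-individual logsumexp over contiguous row blocks
    mx = np.maximum.reduceat(logw, mixture.offsets[:-1])
    w = np.exp(logw - mx[mixture.indiv])
    sums = np.add.reduceat(w, mixture.offsets[:-1])
    ll_i = mx + np.log(sums)
    n = mixture.n_individuals
    loglik = float(ll_i.sum() - 0.5 * n * np.log(2.0 * np.pi * sigma2))
    w = w / sums[mixture.indiv]
    return loglik, w, resid


def model_loglik(
    model: MIMModel, data: BackcrossData, mixture: GenotypeMixture | None = None
) -> float:
    """Mixture log-likelihood of ``data`` under ``model``."""
    if model.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if mixture is None:
        mixture = genotype_mixture(data, model.qtl)
    D = design_matrix(model, mixture)
    ll, _, _ = _estep(data.phenotypes, mixture, D, _beta(model), model.sigma2)
    return ll


@dataclass
class FitResult:
    """EM estimate of an MIM model, with the internals needed for score tests,
    genotypic values and the R^2 partition."""

    model: MIMModel
    loglik: float
    n_iter: int
    converged: bool
    mixture: GenotypeMixture = field(repr=False)
    design: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)  # posterior configuration weights
    data: BackcrossData = field(repr=False)
    loglik_history: np.ndarray = field(default_factory=lambda: np.zeros(0), repr=False)

    @property
    def posterior_residual(self) -> np.ndarray:
        """Per-individual sum_c w_ic (y_i - mu_c)."""
        resid = self.data.phenotypes[self.mixture.indiv] - self.design @ _beta(self.model)
        return np.add.reduceat(self.weights * resid, self.mixture.offsets[:-1])

    def expected_codes(self) -> np.ndarray:
        """Posterior E[x_ik] (n x m), using phenotype information."""
        w = self.weights[:, None] * self.mixture.codes
        return np.add.reduceat(w, self.mixture.offsets[:-1], axis=0)

    def expected_products(self) -> np.ndarray:
        """Posterior E[x_ik x_il] per interaction pair (n x n_interactions)."""
        cols = [
            self.mixture.codes[:, k] * self.mixture.codes[:, l]
            for k, l in self.model.interactions
        ]
        if not cols:
            return np.zeros((self.data.n, 0))
        w = self.weights[:, None] * np.column_stack(cols)
        return np.add.reduceat(w, self.mixture.offsets[:-1], axis=0)


def em_fit(
    structure: MIMModel,
    data: BackcrossData,
    init: MIMModel | None = None,
    tol: float = DEFAULT_EM_TOL,
    maxit: int = DEFAULT_EM_MAXIT,
    truncation: float = DEFAULT_TRUNCATION,
    mixture: GenotypeMixture | None = None,
) -> FitResult:
    """Fit the MIM model by EM with positions and interaction set fixed.

    ``init`` supplies starting parameter values (defaults to the values stored
    in ``structure``); a model fitted before a small structural edit is a good
    warm start.  The log-likelihood is non-decreasing across iterations;
    convergence is declared when its relative change drops below ``tol``.
    """
    y = data.phenotypes
    n = data.n
    if mixture is None:
        mixture = genotype_mixture(data, structure.qtl, truncation)
    D = design_matrix(structure, mixture)

    start = init if init is not None else structure
    beta = _beta(start if start.n_params == structure.n_params else structure)
    sigma2 = float(start.sigma2)
    if not np.isfinite(sigma2) or sigma2 <= 0:
        sigma2 = float(np.var(y)) or 1.0

    prev_ll = -np.inf
    ll = -np.inf
    converged = False
    it = 0
    history: list[float] = []
    for it in range(1, maxit + 1):
        ll, w, _ = _estep(y, mixture, D, beta, sigma2)
        history.append(ll)
        # M-step: weighted least squares over retained configurations
        Dw = D * w[:, None]
        A = D.T @ Dw
        b = Dw.T @ y[mixture.indiv]
        try:
            new_beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            raise SingularModelError(
                "singular normal equations; a QTL has (numerically) constant "
                "expected genotype codes"
            ) from None
        if not np.all(np.isfinite(new_beta)):
            raise SingularModelError("non-finite parameter update")
        resid_new = y[mixture.indiv] - D @ new_beta
        new_sigma2 = float(np.sum(w * resid_new**2) / n)
        if new_sigma2 <= 0 or not np.isfinite(new_sigma2):
            raise SingularModelError("degenerate residual variance")
        beta, sigma2 = new_beta, new_sigma2
        if np.isfinite(prev_ll) and ll - prev_ll <= tol * (abs(prev_ll) + 1e-12):
            converged = True
            break
        prev_ll = ll

    # report the log-likelihood at the final parameter values
    ll, w, _ = _estep(y, mixture, D, beta, sigma2)
    fitted = _model_with_beta(structure, beta, sigma2)
    return FitResult(
        model=fitted,
        loglik=ll,
        n_iter=it,
        converged=converged,
        mixture=mixture,
        design=D,
        weights=w,
        data=data,
        loglik_history=np.array(history),
    )


def evaluate_fit(
    model: MIMModel,
    data: BackcrossData,
    truncation: float = DEFAULT_TRUNCATION,
    mixture: GenotypeMixture | None = None,
) -> FitResult:
    """A :class:`FitResult` at the given parameter values, without running EM.

    Useful for score tests or genotypic values at externally supplied
    parameters.
    """
    if mixture is None:
        mixture = genotype_mixture(data, model.qtl, truncation)
    D = design_matrix(model, mixture)
    ll, w, _ = _estep(data.phenotypes, mixture, D, _beta(model), model.sigma2)
    return FitResult(
        model=model, loglik=ll, n_iter=0, converged=True, mixture=mixture,
        design=D, weights=w, data=data, loglik_history=np.array([ll]),
    )


def lod_profile(
    fit: FitResult,
    data: BackcrossData,
    qtl_index: int,
    grid: Sequence[float] | np.ndarray | None = None,
    grid_cm: float = 1.0,
    tol: float = DEFAULT_EM_TOL,
    maxit: int = DEFAULT_EM_MAXIT,
    truncation: float = DEFAULT_TRUNCATION,
) -> tuple[np.ndarray, np.ndarray]:
    """LOD profile for one QTL: full model with the QTL moved along a grid
    versus the reduced model with the QTL's main and interaction effects
    removed (refit).  LOD = (loglik_full - loglik_reduced) / ln 10.
    """
    model = fit.model
    if not (0 <= qtl_index < model.n_qtl):
        raise IndexError("qtl_index out of range")
    chrom = model.qtl[qtl_index].chromosome
    if grid is None:
        lo, hi = data.map.chrom_span(chrom)
        grid = np.arange(lo, hi + 1e-9, grid_cm)
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty grid")

    reduced = em_fit(
        model.without_qtl(qtl_index), data, init=model.without_qtl(qtl_index),
        tol=tol, maxit=maxit, truncation=truncation,
    )
    lods = np.empty(grid.shape)
    warm = model
    for j, p in enumerate(grid):
        moved = warm.moved(qtl_index, Locus(chrom, float(p)))
        try:
            full = em_fit(moved, data, init=warm, tol=tol, maxit=maxit,
                          truncation=truncation)
            lods[j] = (full.loglik - reduced.loglik) / np.log(10.0)
            warm = full.model
        except (SingularModelError, ValueError):
            lods[j] = np.nan
    return grid, lods


def variance_partition(fit: FitResult) -> dict:
    """Partition of the model R^2 into per-term variance components and
    pairwise covariance components (linkage disequilibrium), computed from the
    estimated effects and the sample (co)variances of the posterior-expected
    coded genotypes.  Components, covariances and the residual fraction sum
    to 1 of the phenotypic variance."""
    model = fit.model
    y = fit.data.phenotypes
    vy = float(np.var(y))
    terms: list[tuple[str, np.ndarray]] = []
    ex = fit.expected_codes()
    for k in range(model.n_qtl):
        terms.append((f"a[{k}]", model.a[k] * ex[:, k]))
    exx = fit.expected_products()
    for j, (k, l) in enumerate(model.interactions):
        terms.append((f"gamma[{k},{l}]", model.gamma[j] * exx[:, j]))

    if terms:
        T = np.column_stack([t for _, t in terms])
        C = np.cov(T, rowvar=False, ddof=0).reshape(len(terms), len(terms))
        genetic = T.sum(axis=1)
        v_g = float(np.var(genetic))
    else:
        C = np.zeros((0, 0))
        v_g = 0.0

    components = {name: float(C[i, i]) / vy for i, (name, _) in enumerate(terms)}
    covariances = {}
    for i in range(len(terms)):
        for j in range(i + 1, len(terms)):
            if abs(C[i, j]) > 0:
                covariances[f"{terms[i][0]}*{terms[j][0]}"] = 2.0 * float(C[i, j]) / vy
    r2 = v_g / vy if vy > 0 else 0.0
    return {
        "components": components,
        "covariances": covariances,
        "r_squared": r2,
        "residual_fraction": 1.0 - r2,
        "v_genetic": v_g,
        "v_phenotypic": vy,
    }


def genotypic_values(fit: FitResult) -> np.ndarray:
    """Posterior-expected genetic value per individual:
    mu + sum_k a_k E[x_ik | y, markers] + sum gamma_kl E[x_ik x_il | y, markers]."""
    model = fit.model
    value = np.full(fit.data.n, model.mu)
    ex = fit.expected_codes()
    if model.n_qtl:
        value = value + ex @ model.a
    exx = fit.expected_products()
    if len(model.interactions):
        value = value + exx @ model.gamma
    return value
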