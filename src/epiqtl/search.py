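"""Three-stage sequential model selection for epistatic QTL.

Stage 1 scans the genome for main-effect QTL, admitting significant
pairwise interactions among identified QTL as it goes, then prunes and
re-positions the model.  Stage 2 scans for new QTL whose interaction with
an identified main-effect QTL is significant (Bonferroni-adjusted over the
main QTL).  Stage 3 runs a two-dimensional scan for interacting pairs in
which neither member has a detectable main effect.  Every test uses score
statistics with normal-multiplier resampling thresholds: genome-wide for
searches over positions, pointwise for admitting or deleting individual
parameters.

Scans always exclude positions inside the "window" of a QTL already in the
model (up to 10 cM per side, bounded by the nearest flanking markers); the
window is also the region over which a QTL's position is re-optimized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .genetic_map import GeneticMap, Locus
from .mim import (
    BackcrossData,
    FitResult,
    MIMModel,
    SingularModelError,
    em_fit,
)
from .score import (
    CrossWorkspace,
    ScoreEngine,
    ThresholdEstimate,
    resampled_maxima_1d,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SearchConfig",
    "SearchTrace",
    "SearchResult",
    "qtl_window",
    "scan_main_effect",
    "admit_interactions_with",
    "backward_eliminate",
    "optimize_positions",
    "stage1",
    "stage2",
    "stage3",
    "run_search",
]

_EPS = 1e-9


@dataclass(frozen=True)
class SearchConfig:
    """Tuning parameters of the model search."""

    alpha: float = 0.05
    window_cm: float = 10.0
    grid_cm: float = 1.0
    grid2d_cm: float = 5.0
    resamples: int = 1000
    em_tol: float = 1e-8
    em_maxit: int = 1000
    truncation: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.grid_cm <= 0 or self.grid2d_cm <= 0 or self.window_cm <= 0:
            raise ValueError("grids and window must be positive")


@dataclass
class SearchTrace:
    """Chronological record of search decisions and per-stage model
    checkpoints (forward phase and after optimization/elimination)."""

    steps: list[dict] = field(default_factory=list)
    checkpoints: dict[str, MIMModel] = field(default_factory=dict)

    def log(self, **record) -> None:
        self.steps.append(record)

    def checkpoint(self, name: str, model: MIMModel) -> None:
        self.checkpoints[name] = model


@dataclass
class SearchResult:
    model: MIMModel
    trace: SearchTrace
    fit: FitResult
    origins: tuple[str, ...] = ()  # 'main' or 'epistatic' per QTL


CHECKPOINTS = (
    "stage1_forward",
    "stage1_final",
    "stage2_forward",
    "stage2_final",
    "stage3_forward",
    "stage3_final",
)


def qtl_window(gmap: GeneticMap, locus: Locus, half_cm: float = 10.0) -> tuple[float, float]:
    """The window of an identified QTL: up to ``half_cm`` per side, stopping
    at the nearest marker strictly beyond the QTL on that side (a QTL sitting
    exactly on a marker is bounded by the adjacent markers)."""
    pos = gmap.chrom_positions(locus.chromosome)
    p = float(locus.position)
    left_marks = pos[pos < p - _EPS]
    right_marks = pos[pos > p + _EPS]
    lo = p - (min(half_cm, p - left_marks[-1]) if left_marks.size else 0.0)
    hi = p + (min(half_cm, right_marks[0] - p) if right_marks.size else 0.0)
    return lo, hi


def _excluded(grid: list[Locus], model: MIMModel, gmap: GeneticMap,
              half_cm: float) -> list[Locus]:
    """Grid positions outside every model QTL's window."""
    windows: dict[str, list[tuple[float, float]]] = {}
    for q in model.qtl:
        windows.setdefault(q.chromosome, []).append(qtl_window(gmap, q, half_cm))
    out = []
    for loc in grid:
        spans = windows.get(loc.chromosome, ())
        if any(lo - _EPS <= loc.position <= hi + _EPS for lo, hi in spans):
            continue
        out.append(loc)
    return out


class _Searcher:
    """Shared state for one model search over one dataset."""

    def __init__(self, data: BackcrossData, config: SearchConfig,
                 rng: np.random.Generator | None = None):
        self.data = data
        self.config = config
        self.ws = CrossWorkspace(data)
        self.rng = rng if rng is not None else np.random.default_rng(config.seed)
        self.grid1 = data.map.grid(config.grid_cm)
        self.grid2 = data.map.grid(config.grid2d_cm)
        self.origins: list[str] = []

    def fit(self, model: MIMModel, init: MIMModel | None = None) -> FitResult:
        cfg = self.config
        mixture = None
        from .mim import genotype_mixture

        mixture = genotype_mixture(
            self.data, model.qtl, cfg.truncation,
            per_qtl_probs=self.ws.per_qtl_probs(model.qtl) if model.qtl else None,
        )
        return em_fit(model, self.data, init=init, tol=cfg.em_tol,
                      maxit=cfg.em_maxit, truncation=cfg.truncation,
                      mixture=mixture)

    def engine(self, fit: FitResult) -> ScoreEngine:
        return ScoreEngine(fit, self.ws)

    def open_grid(self, grid: list[Locus], model: MIMModel) -> list[Locus]:
        return _excluded(grid, model, self.data.map, self.config.window_cm)


# -- single-operation entry points -------------------------------------


def _stats_1d(U_num: np.ndarray, U_var: np.ndarray) -> np.ndarray:
    """Per-column score statistics: numerator from the projected scores,
    variance from the leverage-corrected ones."""
    V = np.einsum("ij,ij->j", U_var, U_var)
    s = U_num.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        stats = np.where(V > 1e-10, s**2 / np.clip(V, 1e-300, None), 0.0)
    return stats


def scan_main_effect(
    fit: FitResult,
    searcher: _Searcher,
    rng: np.random.Generator,
) -> tuple[Locus | None, float, float, float, np.ndarray]:
    """Genome scan (1 cM grid, model windows excluded) for a new main-effect
    QTL.  Returns (best locus, statistic, genome-wide threshold, empirical p,
    per-position statistics)."""
    cfg = searcher.config
    loci = searcher.open_grid(searcher.grid1, fit.model)
    if not loci:
        raise RuntimeError("no scan positions left outside QTL windows")
    eng = searcher.engine(fit)
    U = eng.project(eng.new_main_columns(loci))
    Uv = eng.scaled(U)
    stats = _stats_1d(U, Uv)
    best = int(np.argmax(stats))
    maxima = resampled_maxima_1d(Uv, cfg.resamples, rng)
    dist = ThresholdEstimate(resamples=maxima)
    thr = dist.quantile(cfg.alpha)
    p = dist.pvalue(float(stats[best]))
    return loci[best], float(stats[best]), thr, p, stats


def _pointwise(U_col: np.ndarray, B: int, alpha: float,
               rng: np.random.Generator) -> float:
    maxima = resampled_maxima_1d(U_col[:, None], B, rng)
    return ThresholdEstimate(resamples=maxima).quantile(alpha)


def admit_interactions_with(
    fit: FitResult,
    new_index: int,
    searcher: _Searcher,
    rng: np.random.Generator,
    trace: SearchTrace | None = None,
) -> FitResult:
    """Repeatedly add the maximal significant pairwise interaction between
    QTL ``new_index`` and the other model QTL (pointwise threshold)."""
    cfg = searcher.config
    while True:
        model = fit.model
        candidates = [
            tuple(sorted((new_index, k)))
            for k in range(model.n_qtl)
            if k != new_index and tuple(sorted((new_index, k))) not in model.interactions
        ]
        if not candidates:
            return fit
        eng = searcher.engine(fit)
        cols = np.column_stack(
            [eng.existing_interaction_column(k, l) for k, l in candidates]
        )
        U = eng.project(cols)
        Uv = eng.scaled(U)
        stats = _stats_1d(U, Uv)
        j = int(np.argmax(stats))
        thr = _pointwise(Uv[:, j], cfg.resamples, cfg.alpha, rng)
        if trace is not None:
            trace.log(action="test_interaction", pair=candidates[j],
                      statistic=float(stats[j]), threshold=thr,
                      accepted=bool(stats[j] > thr))
        if stats[j] <= thr:
            return fit
        k, l = candidates[j]
        model = model.with_interaction(k, l)
        fit = searcher.fit(model, init=replace(model, sigma2=fit.model.sigma2))


def _drop_test_interaction(
    fit: FitResult, pair: tuple[int, int], searcher: _Searcher,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Score test of an interaction already in the model, against the refit
    reduced model without it; pointwise threshold."""
    cfg = searcher.config
    reduced = fit.model.without_interaction(*pair)
    rfit = searcher.fit(reduced, init=reduced)
    eng = searcher.engine(rfit)
    U = eng.project(eng.existing_interaction_column(*pair)[:, None])
    Uv = eng.scaled(U)
    stat = float(_stats_1d(U, Uv)[0])
    thr = _pointwise(Uv[:, 0], cfg.resamples, cfg.alpha, rng)
    return stat, thr


def _drop_test_main(
    fit: FitResult, k: int, searcher: _Searcher, rng: np.random.Generator,
    genome_wide: bool,
) -> tuple[float, float]:
    """Score test of QTL k's main effect.  The reduced model removes the QTL
    (and, in the pointwise stage-1 variant, its interactions with it)."""
    cfg = searcher.config
    locus = fit.model.qtl[k]
    reduced = fit.model.without_qtl(k)
    rfit = searcher.fit(reduced, init=reduced)
    eng = searcher.engine(rfit)
    if genome_wide:
        loci = searcher.open_grid(searcher.grid1, reduced)
        U_scan = eng.scaled(eng.project(eng.new_main_columns(loci)))
        maxima = resampled_maxima_1d(U_scan, cfg.resamples, rng)
        thr = ThresholdEstimate(resamples=maxima).quantile(cfg.alpha)
    u = eng.project(eng.new_main_columns([locus]))
    uv = eng.scaled(u)
    stat = float(_stats_1d(u, uv)[0])
    if not genome_wide:
        thr = _pointwise(uv[:, 0], cfg.resamples, cfg.alpha, rng)
    return stat, thr


def backward_eliminate(
    fit: FitResult,
    searcher: _Searcher,
    rng: np.random.Generator,
    phase: str,
    origins: list[str],
    trace: SearchTrace | None = None,
) -> FitResult:
    """Backward elimination of insignificant effects.

    ``phase='stage1'``: mains and interactions together, both at pointwise
    thresholds; eliminating a main removes the QTL and its interactions.
    ``phase='stage2plus'``: interactions first (pointwise), then main effects
    of interaction-free QTL (genome-wide threshold).
    """
    if phase not in ("stage1", "stage2plus"):
        raise ValueError("phase must be 'stage1' or 'stage2plus'")

    def drop_interaction_round(fit: FitResult) -> tuple[FitResult, bool]:
        model = fit.model
        worst = None
        for pair in model.interactions:
            stat, thr = _drop_test_interaction(fit, pair, searcher, rng)
            ratio = stat / thr if thr > 0 else np.inf
            if stat <= thr and (worst is None or ratio < worst[0]):
                worst = (ratio, pair, stat, thr)
        if worst is None:
            return fit, False
        _, pair, stat, thr = worst
        if trace is not None:
            trace.log(action="drop_interaction", pair=pair, statistic=stat,
                      threshold=thr)
        model = fit.model.without_interaction(*pair)
        return searcher.fit(model, init=model), True

    def drop_main_round(fit: FitResult, genome_wide: bool,
                        only_interaction_free: bool) -> tuple[FitResult, bool]:
        model = fit.model
        worst = None
        for k in range(model.n_qtl):
            if only_interaction_free and model.partners(k):
                continue
            stat, thr = _drop_test_main(fit, k, searcher, rng, genome_wide)
            ratio = stat / thr if thr > 0 else np.inf
            if stat <= thr and (worst is None or ratio < worst[0]):
                worst = (ratio, k, stat, thr)
        if worst is None:
            return fit, False
        _, k, stat, thr = worst
        if trace is not None:
            trace.log(action="drop_qtl", qtl=str(fit.model.qtl[k]), statistic=stat,
                      threshold=thr)
        model = fit.model.without_qtl(k)
        del origins[k]
        return searcher.fit(model, init=model), True

    if phase == "stage1":
        # alternate: drop whichever (main or interaction) is least significant
        changed = True
        while changed:
            changed = False
            fit, ch = drop_interaction_round(fit)
            changed = changed or ch
            if not ch:
                fit, ch2 = drop_main_round(fit, genome_wide=False,
                                           only_interaction_free=False)
                changed = changed or ch2
    else:
        while True:
            fit, ch = drop_interaction_round(fit)
            if not ch:
                break
        while True:
            fit, ch = drop_main_round(fit, genome_wide=True,
                                      only_interaction_free=True)
            if not ch:
                break
    return fit


def optimize_positions(
    fit: FitResult,
    searcher: _Searcher,
    use_interactions: bool,
    trace: SearchTrace | None = None,
) -> FitResult:
    """Move each QTL in turn to the position of its window's 1 cM grid that
    maximizes its score statistic (main effect only, or jointly with its
    interaction effects), refitting after each move."""
    cfg = searcher.config
    model = fit.model
    for k in range(model.n_qtl):
        model = fit.model
        locus = model.qtl[k]
        lo, hi = qtl_window(searcher.data.map, locus, cfg.window_cm)
        grid = np.arange(lo, hi + _EPS, cfg.grid_cm)
        if not np.any(np.abs(grid - locus.position) < _EPS):
            grid = np.sort(np.append(grid, locus.position))
        cand = [Locus(locus.chromosome, round(float(p), 6)) for p in grid]
        # never move into a marker interval occupied by another model QTL
        other_keys = {
            _interval_key(searcher.data.map, q)
            for j, q in enumerate(model.qtl) if j != k
        }
        cand = [
            c for c in cand
            if _interval_key(searcher.data.map, c) not in other_keys
            or abs(c.position - locus.position) < _EPS
        ]

        reduced = model.without_qtl(k)
        rfit = searcher.fit(reduced, init=reduced)
        eng = searcher.engine(rfit)
        main_cols = eng.new_main_columns(cand)
        if use_interactions and model.partners(k):
            partners = model.partners(k)
            shifted = [l - 1 if l > k else l for l in partners]
            stats = np.empty(len(cand))
            for j, loc in enumerate(cand):
                cols = [main_cols[:, j]]
                cols += [eng.new_interaction_columns([loc], l)[:, 0] for l in shifted]
                U = eng.project(np.column_stack(cols))
                Uv = eng.scaled(U)
                V = Uv.T @ Uv
                s = U.sum(axis=0)
                try:
                    stats[j] = float(s @ np.linalg.solve(V, s))
                except np.linalg.LinAlgError:
                    stats[j] = float(s @ np.linalg.pinv(V) @ s)
        else:
            Um = eng.project(main_cols)
            stats = _stats_1d(Um, eng.scaled(Um))
        j = int(np.argmax(stats))
        if abs(cand[j].position - locus.position) > _EPS:
            if trace is not None:
                trace.log(action="move_qtl", qtl=k, frm=locus.position,
                          to=cand[j].position, statistic=float(stats[j]))
            moved = model.moved(k, cand[j])
            fit = searcher.fit(moved, init=moved)
    return fit


# -- stages ------------------------------------------------------------


def stage1(
    data: BackcrossData,
    config: SearchConfig,
    searcher: _Searcher | None = None,
    trace: SearchTrace | None = None,
) -> tuple[FitResult, SearchTrace, _Searcher]:
    """Forward search for main-effect QTL with interaction admission, then
    backward elimination and position optimization."""
    searcher = searcher or _Searcher(data, config)
    trace = trace or SearchTrace()
    rng = searcher.rng
    fit = searcher.fit(MIMModel.null(mu=float(np.mean(data.phenotypes)),
                                     sigma2=float(np.var(data.phenotypes))))
    while fit.model.n_qtl < 12:
        locus, stat, thr, p, _ = scan_main_effect(fit, searcher, rng)
        accepted = stat > thr
        trace.log(stage=1, action="scan_main", locus=str(locus), statistic=stat,
                  threshold=thr, p=p, accepted=accepted)
        if not accepted:
            break
        model = fit.model.with_qtl(locus)
        searcher.origins.append("main")
        fit = searcher.fit(model, init=replace(model, sigma2=fit.model.sigma2))
        fit = admit_interactions_with(fit, fit.model.n_qtl - 1, searcher, rng, trace)
    trace.checkpoint("stage1_forward", fit.model)
    fit = backward_eliminate(fit, searcher, rng, "stage1", searcher.origins, trace)
    fit = optimize_positions(fit, searcher, use_interactions=False, trace=trace)
    trace.checkpoint("stage1_final", fit.model)
    return fit, trace, searcher


def stage2(
    fit: FitResult,
    searcher: _Searcher,
    trace: SearchTrace,
) -> FitResult:
    """Search for epistatic QTL interacting with the main-effect QTL."""
    cfg = searcher.config
    rng = searcher.rng
    while fit.model.n_qtl < 12:
        mains = [k for k, o in enumerate(searcher.origins) if o == "main"]
        if not mains:
            break
        loci = searcher.open_grid(searcher.grid1, fit.model)
        if not loci:
            break
        eng = searcher.engine(fit)
        M = eng.project(eng.new_main_columns(loci))  # nuisance: new main at zero
        m_norm = np.einsum("ij,ij->j", M, M)
        with np.errstate(divide="ignore", invalid="ignore"):
            Mhat = np.where(m_norm > 1e-10, M / np.sqrt(np.clip(m_norm, 1e-300, None)), 0.0)
        lev_extra = Mhat**2
        G = rng.standard_normal((cfg.resamples, searcher.data.n))
        best = None  # (p, k, locus, stat, thr)
        for k in mains:
            T = eng.project(eng.new_interaction_columns(loci, k))
            T = T - Mhat * np.einsum("ij,ij->j", Mhat, T)[None, :]
            Tv = eng.scaled(T, lev_extra)
            stats = _stats_1d(T, Tv)
            j = int(np.argmax(stats))
            V = np.einsum("ij,ij->j", Tv, Tv)
            ok = V > 1e-10
            if not np.any(ok):
                continue
            maxima = ((G @ Tv[:, ok]) ** 2 / V[ok][None, :]).max(axis=1)
            dist = ThresholdEstimate(resamples=maxima)
            pval = dist.pvalue(float(stats[j]))
            thr = dist.quantile(cfg.alpha)
            if best is None or pval < best[0]:
                best = (pval, k, loci[j], float(stats[j]), thr)
        if best is None:
            break
        pval, k, locus, stat, thr = best
        p_adj = min(1.0, pval * len(mains))
        accepted = p_adj < cfg.alpha
        trace.log(stage=2, action="scan_epistatic", partner=k, locus=str(locus),
                  statistic=stat, threshold=thr, p=pval, p_adjusted=p_adj,
                  accepted=accepted)
        if not accepted:
            break
        model = fit.model.with_qtl(locus)
        new_idx = model.n_qtl - 1
        model = model.with_interaction(k, new_idx)
        searcher.origins.append("epistatic")
        fit = searcher.fit(model, init=replace(model, sigma2=fit.model.sigma2))
        fit = admit_interactions_with(fit, new_idx, searcher, rng, trace)
    trace.checkpoint("stage2_forward", fit.model)
    fit = optimize_positions(fit, searcher, use_interactions=True, trace=trace)
    fit = backward_eliminate(fit, searcher, rng, "stage2plus", searcher.origins, trace)
    trace.checkpoint("stage2_final", fit.model)
    return fit


def _pair_scan(
    fit: FitResult, searcher: _Searcher, rng: np.random.Generator
) -> tuple[tuple[Locus, Locus] | None, float, float]:
    """Two-dimensional scan over unordered pairs of open grid positions for a
    purely epistatic pair.  Returns (best pair, statistic, threshold)."""
    cfg = searcher.config
    loci = searcher.open_grid(searcher.grid2, fit.model)
    P = len(loci)
    if P < 2:
        return None, 0.0, np.inf
    eng = searcher.engine(fit)
    Z = searcher.ws.zmatrix(loci)
    R = eng.posterior_residual
    M = eng.project(R[:, None] * Z)  # new-main nuisance columns
    m_norm = np.einsum("ij,ij->j", M, M)
    with np.errstate(divide="ignore", invalid="ignore"):
        Mhat = np.where(m_norm > 1e-10, M / np.sqrt(np.clip(m_norm, 1e-300, None)), 0.0)
    G = rng.standard_normal((cfg.resamples, searcher.data.n))
    run_max = np.zeros(cfg.resamples)
    best_stat = -np.inf
    best_pair: tuple[int, int] | None = None
    interval_key = [_interval_key(searcher.data.map, loc) for loc in loci]
    for p in range(P - 1):
        qs = np.arange(p + 1, P)
        # two proposed QTL may not share a marker interval
        valid = np.array([interval_key[q] != interval_key[p] for q in qs])
        if not valid.any():
            continue
        qs = qs[valid]
        block = (R * Z[:, p])[:, None] * Z[:, qs]
        block = eng.project(block)
        # project out the two new main effects (held at zero under the null)
        mp = Mhat[:, p]
        block -= mp[:, None] * (mp @ block)[None, :]
        Mq = Mhat[:, qs]
        Mq = Mq - mp[:, None] * (mp @ Mq)[None, :]
        mq_n = np.einsum("ij,ij->j", Mq, Mq)
        with np.errstate(divide="ignore", invalid="ignore"):
            Mqhat = np.where(
                mq_n > 1e-10, Mq / np.sqrt(np.clip(mq_n, 1e-300, None)), 0.0
            )
        block = block - Mqhat * np.einsum("ij,ij->j", Mqhat, block)[None, :]
        block_v = eng.scaled(block, mp[:, None] ** 2 + Mqhat**2)
        V = np.einsum("ij,ij->j", block_v, block_v)
        ok = V > 1e-10
        if not ok.any():
            continue
        s = block.sum(axis=0)
        stats = np.where(ok, s**2 / np.clip(V, 1e-300, None), 0.0)
        j = int(np.argmax(stats))
        if stats[j] > best_stat:
            best_stat = float(stats[j])
            best_pair = (p, int(qs[j]))
        bm = ((G @ block_v[:, ok]) ** 2 / V[ok][None, :]).max(axis=1)
        np.maximum(run_max, bm, out=run_max)
    if best_pair is None:
        return None, 0.0, np.inf
    thr = ThresholdEstimate(resamples=run_max).quantile(cfg.alpha)
    return (loci[best_pair[0]], loci[best_pair[1]]), best_stat, thr


def _interval_key(gmap: GeneticMap, loc: Locus) -> tuple:
    pos = gmap.chrom_positions(loc.chromosome)
    if np.any(np.abs(pos - loc.position) <= 1e-9):
        return (loc.chromosome, -int(np.argmin(np.abs(pos - loc.position))) - 1)
    return (loc.chromosome, int(np.searchsorted(pos, loc.position) - 1))


def _optimize_pair_coordinate(
    fit: FitResult, searcher: _Searcher, fixed: Locus, moving_chrom_any: None = None
) -> Locus:
    """Best 1 cM-grid position for one member of a proposed epistatic pair,
    the other member held fixed; tested parameter is the pair interaction with
    both new mains projected out."""
    eng = searcher.engine(fit)
    loci = searcher.open_grid(searcher.grid1, fit.model)
    fixed_key = _interval_key(searcher.data.map, fixed)
    loci = [l for l in loci if _interval_key(searcher.data.map, l) != fixed_key]
    Z = searcher.ws.zmatrix(loci)
    R = eng.posterior_residual
    zf = searcher.ws.zcodes(fixed)
    U = eng.project((R * zf)[:, None] * Z)
    mf = eng.project((R * zf)[:, None])[:, 0]
    M = eng.project(R[:, None] * Z)
    mf_n = float(mf @ mf)
    if mf_n > 1e-10:
        mf = mf / np.sqrt(mf_n)
        U = U - mf[:, None] * (mf @ U)[None, :]
        M = M - mf[:, None] * (mf @ M)[None, :]
    mn = np.einsum("ij,ij->j", M, M)
    with np.errstate(divide="ignore", invalid="ignore"):
        Mhat = np.where(mn > 1e-10, M / np.sqrt(np.clip(mn, 1e-300, None)), 0.0)
    U = U - Mhat * np.einsum("ij,ij->j", Mhat, U)[None, :]
    Uv = eng.scaled(U, mf[:, None] ** 2 + Mhat**2)
    stats = _stats_1d(U, Uv)
    return loci[int(np.argmax(stats))]


def stage3(
    fit: FitResult,
    searcher: _Searcher,
    trace: SearchTrace,
) -> FitResult:
    """Two-dimensional search for interacting pairs with little or no main
    effect, followed by the final optimization and elimination."""
    cfg = searcher.config
    rng = searcher.rng
    while fit.model.n_qtl < 11:
        pair, stat, thr = _pair_scan(fit, searcher, rng)
        accepted = pair is not None and stat > thr
        trace.log(stage=3, action="scan_pair",
                  pair=None if pair is None else (str(pair[0]), str(pair[1])),
                  statistic=stat, threshold=float(thr), accepted=bool(accepted))
        if not accepted:
            break
        l1, l2 = pair
        # coordinate-wise position refinement on the 1 cM grid
        l2 = _optimize_pair_coordinate(fit, searcher, fixed=l1)
        l1 = _optimize_pair_coordinate(fit, searcher, fixed=l2)
        model = fit.model.with_qtl(l1).with_qtl(l2)
        i1, i2 = model.n_qtl - 2, model.n_qtl - 1
        model = model.with_interaction(i1, i2)
        searcher.origins.extend(["epistatic", "epistatic"])
        fit = searcher.fit(model, init=replace(model, sigma2=fit.model.sigma2))
        fit = admit_interactions_with(fit, i1, searcher, rng, trace)
        fit = admit_interactions_with(fit, i2, searcher, rng, trace)
    trace.checkpoint("stage3_forward", fit.model)
    fit = optimize_positions(fit, searcher, use_interactions=True, trace=trace)
    fit = backward_eliminate(fit, searcher, rng, "stage2plus", searcher.origins, trace)
    trace.checkpoint("stage3_final", fit.model)
    return fit


def run_search(
    data: BackcrossData, config: SearchConfig | None = None
) -> SearchResult:
    """Full three-stage search; deterministic given ``config.seed``."""
    config = config or SearchConfig()
    fit, trace, searcher = stage1(data, config)
    fit = stage2(fit, searcher, trace)
    fit = stage3(fit, searcher, trace)
    return SearchResult(model=fit.model, trace=trace, fit=fit,
                        origins=tuple(searcher.origins))
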