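"""Simulation-study evaluation: detection pairing, power/FPR, LOD support
intervals, and the replicate harness.

A simulated QTL counts as *detected* in a fitted model when it is paired,
one-to-one and on the same chromosome, with an identified QTL (greedy
nearest-distance assignment).  Identified QTL left unpaired are
*misidentified*.  An interaction is detected when both endpoints are
correctly identified and the interaction term between them is in the model.
FPR is the fraction of identified QTL (or interactions) over all replicates
that are misidentified.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genetic_map import Locus
from .mim import BackcrossData, FitResult, MIMModel, SingularModelError, lod_profile
from .search import CHECKPOINTS, SearchConfig, run_search
from .simulator import Architecture, simulate_backcross

logger = logging.getLogger(__name__)

__all__ = [
    "Pairing",
    "LODInterval",
    "MetricsTable",
    "pair_identified",
    "detection_metrics",
    "lod_support_interval",
    "replicate_study",
]


@dataclass(frozen=True)
class Pairing:
    """One-to-one nearest-distance assignment of simulated to identified QTL."""

    sim_to_ident: tuple  # per simulated QTL: identified index or None
    ident_correct: tuple  # per identified QTL: True if paired

    def detected(self, k: int) -> bool:
        return self.sim_to_ident[k] is not None


def pair_identified(truth: Architecture, model: MIMModel) -> Pairing:
    """Pair each simulated QTL with the nearest same-chromosome identified
    QTL, greedily by increasing distance, one-to-one."""
    cands = []
    for si, sq in enumerate(truth.qtl):
        for ii, iq in enumerate(model.qtl):
            if iq.chromosome == sq.chromosome:
                cands.append((abs(iq.position - sq.position), si, ii))
    cands.sort()
    sim_to_ident: list = [None] * truth.n_qtl
    ident_used = [False] * model.n_qtl
    for _, si, ii in cands:
        if sim_to_ident[si] is None and not ident_used[ii]:
            sim_to_ident[si] = ii
            ident_used[ii] = True
    return Pairing(tuple(sim_to_ident), tuple(ident_used))


def _interaction_status(
    truth: Architecture, model: MIMModel, pairing: Pairing
) -> tuple[list[bool], int, int]:
    """(per simulated interaction: detected, #identified interactions,
    #misidentified interactions)."""
    ident_of_sim = pairing.sim_to_ident
    sim_of_ident = {v: k for k, v in enumerate(ident_of_sim) if v is not None}
    sim_pairs = set(truth.interactions)
    detected = []
    for k, l in truth.interactions:
        ik, il = ident_of_sim[k], ident_of_sim[l]
        detected.append(
            ik is not None and il is not None
            and tuple(sorted((ik, il))) in model.interactions
        )
    mis = 0
    for ik, il in model.interactions:
        sk, sl = sim_of_ident.get(ik), sim_of_ident.get(il)
        correct = (
            sk is not None and sl is not None
            and tuple(sorted((sk, sl))) in sim_pairs
        )
        mis += 0 if correct else 1
    return detected, len(model.interactions), mis


@dataclass(frozen=True)
class LODInterval:
    """LOD-z support interval around an identified QTL."""

    z: float
    low: float
    high: float
    peak: float  # position of maximum LOD (adjusted QTL position)

    @property
    def width(self) -> float:
        return self.high - self.low

    def contains(self, position: float) -> bool:
        return self.low - 1e-9 <= position <= self.high + 1e-9


def lod_support_interval(
    fit: FitResult,
    data: BackcrossData,
    qtl_index: int,
    z: float = 1.0,
    grid_cm: float = 1.0,
    profile: tuple[np.ndarray, np.ndarray] | None = None,
) -> LODInterval:
    """Longest contiguous interval around the profile maximum where the LOD
    stays within ``z`` of the maximum.

    The profile is evaluated on a 1 cM grid bounded by neighboring identified
    QTL on the same chromosome (or the chromosome ends); the QTL position is
    snapped to the profile argmax.
    """
    if z <= 0:
        raise ValueError("z must be positive")
    model = fit.model
    locus = model.qtl[qtl_index]
    lo, hi = data.map.chrom_span(locus.chromosome)
    for j, q in enumerate(model.qtl):
        if j == qtl_index or q.chromosome != locus.chromosome:
            continue
        if q.position < locus.position:
            lo = max(lo, q.position)
        elif q.position > locus.position:
            hi = min(hi, q.position)
    if profile is None:
        grid = np.arange(lo, hi + 1e-9, grid_cm)
        grid, lods = lod_profile(fit, data, qtl_index, grid=grid)
    else:
        grid, lods = profile
        sel = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
        grid, lods = grid[sel], lods[sel]
    finite = np.isfinite(lods)
    grid, lods = grid[finite], lods[finite]
    if grid.size == 0:
        raise RuntimeError("LOD profile could not be evaluated on the interval")
    imax = int(np.argmax(lods))
    cutoff = lods[imax] - z
    i_lo = imax
    while i_lo > 0 and lods[i_lo - 1] >= cutoff - 1e-12:
        i_lo -= 1
    i_hi = imax
    while i_hi < len(grid) - 1 and lods[i_hi + 1] >= cutoff - 1e-12:
        i_hi += 1
    # the interval is defined on continuous positions: interpolate the
    # LOD = cutoff crossing between the last grid point inside and the first
    # outside (pure grid truncation biases the width low by up to one step)
    low = float(grid[i_lo])
    if i_lo > 0 and lods[i_lo] > lods[i_lo - 1]:
        frac = (lods[i_lo] - cutoff) / (lods[i_lo] - lods[i_lo - 1])
        low -= float(min(1.0, max(0.0, frac)) * (grid[i_lo] - grid[i_lo - 1]))
    high = float(grid[i_hi])
    if i_hi < len(grid) - 1 and lods[i_hi] > lods[i_hi + 1]:
        frac = (lods[i_hi] - cutoff) / (lods[i_hi] - lods[i_hi + 1])
        high += float(min(1.0, max(0.0, frac)) * (grid[i_hi + 1] - grid[i_hi]))
    return LODInterval(z=z, low=low, high=high, peak=float(grid[imax]))


@dataclass
class MetricsTable:
    """Aggregated simulation-study metrics in the layout of the reference
    power tables: per-QTL and per-interaction powers at the six search
    checkpoints, estimates, LOD-1 coverage/width, and per-checkpoint FPR."""

    qtl: pd.DataFrame
    interactions: pd.DataFrame
    fpr: dict = field(default_factory=dict)
    fpr_i: dict = field(default_factory=dict)
    mean_n_qtl: dict = field(default_factory=dict)
    n_replicates: int = 0
    n_failed: int = 0
    model_size_counts: dict = field(default_factory=dict)
    interaction_size_counts: dict = field(default_factory=dict)
    zero_identified: bool = False

    def fraction_with_n_qtl(self, n: int) -> float:
        total = sum(self.model_size_counts.values())
        return self.model_size_counts.get(n, 0) / total if total else 0.0


def detection_metrics(
    replicates: list[dict],
    truth: Architecture,
    checkpoints: tuple[str, ...] = CHECKPOINTS,
) -> MetricsTable:
    """Aggregate per-replicate search outputs into a metrics table.

    Each replicate record is a dict with key ``"checkpoints"`` mapping
    checkpoint names to models and (optionally, final checkpoint only)
    ``"lod"`` mapping simulated-QTL index to an interval record
    ``(peak, low, high, covered)``.
    """
    if not replicates:
        raise ValueError("need at least one replicate")
    reps = [r for r in replicates if not r.get("failed")]
    n_failed = len(replicates) - len(reps)
    R = len(reps)
    m, n_int = truth.n_qtl, len(truth.interactions)

    power = {c: np.zeros(m) for c in checkpoints}
    ipower = {c: np.zeros(n_int) for c in checkpoints}
    mis = {c: 0 for c in checkpoints}
    tot = {c: 0 for c in checkpoints}
    imis = {c: 0 for c in checkpoints}
    itot = {c: 0 for c in checkpoints}
    nq = {c: [] for c in checkpoints}
    eff_est: list[list[float]] = [[] for _ in range(m)]
    pos_est: list[list[float]] = [[] for _ in range(m)]
    ieff_est: list[list[float]] = [[] for _ in range(n_int)]
    cov_cnt = np.zeros(m)
    width_sum = np.zeros(m)
    size_counts: dict[int, int] = {}
    isize_counts: dict[int, int] = {}

    final = checkpoints[-1]
    for rec in reps:
        for c in checkpoints:
            model = rec["checkpoints"].get(c)
            if model is None:
                continue
            pairing = pair_identified(truth, model)
            for k in range(m):
                power[c][k] += pairing.detected(k)
            det_i, n_ident_i, mis_i = _interaction_status(truth, model, pairing)
            for j in range(n_int):
                ipower[c][j] += det_i[j]
            mis[c] += sum(1 for ok in pairing.ident_correct if not ok)
            tot[c] += model.n_qtl
            imis[c] += mis_i
            itot[c] += n_ident_i
            nq[c].append(model.n_qtl)
            if c == final:
                size_counts[model.n_qtl] = size_counts.get(model.n_qtl, 0) + 1
                isize_counts[len(model.interactions)] = (
                    isize_counts.get(len(model.interactions), 0) + 1
                )
                for k in range(m):
                    ii = pairing.sim_to_ident[k]
                    if ii is None:
                        continue
                    eff_est[k].append(float(model.a[ii]))
                    lod = rec.get("lod", {}).get(k)
                    if lod is not None:
                        peak, lo, hi, covered = lod
                        pos_est[k].append(peak)
                        if covered:
                            cov_cnt[k] += 1
                            width_sum[k] += hi - lo
                    else:
                        pos_est[k].append(model.qtl[ii].position)
                ident_of_sim = pairing.sim_to_ident
                for j, (k, l) in enumerate(truth.interactions):
                    if det_i[j]:
                        pr = tuple(sorted((ident_of_sim[k], ident_of_sim[l])))
                        gidx = model.interactions.index(pr)
                        ieff_est[j].append(float(model.gamma[gidx]))

    def mean_sd(vals: list[float]) -> tuple[float, float]:
        if not vals:
            return np.nan, np.nan
        arr = np.asarray(vals)
        return float(arr.mean()), float(arr.std(ddof=1)) if arr.size > 1 else 0.0

    qtl_rows = []
    for k in range(m):
        row = {
            "qtl": k + 1,
            "chrom": truth.qtl[k].chromosome,
            "pos_cM": truth.qtl[k].position,
            "effect": float(truth.main_effects[k]),
        }
        for c in checkpoints:
            row[f"power_{c}"] = 100.0 * power[c][k] / R if R else np.nan
        row["effect_mean"], row["effect_sd"] = mean_sd(eff_est[k])
        row["pos_mean"], row["pos_sd"] = mean_sd(pos_est[k])
        n_det = len(eff_est[k])
        row["lod1_coverage"] = 100.0 * cov_cnt[k] / n_det if n_det else np.nan
        row["lod1_width"] = width_sum[k] / cov_cnt[k] if cov_cnt[k] else np.nan
        qtl_rows.append(row)

    int_rows = []
    for j, (k, l) in enumerate(truth.interactions):
        row = {
            "pair": f"{k + 1}:{l + 1}",
            "effect": float(truth.interaction_effects[j]),
        }
        for c in checkpoints:
            row[f"power_{c}"] = 100.0 * ipower[c][j] / R if R else np.nan
        row["effect_mean"], row["effect_sd"] = mean_sd(ieff_est[j])
        int_rows.append(row)

    zero_ident = all(tot[c] == 0 for c in checkpoints)
    if zero_ident:
        logger.warning("no QTL identified in any replicate; FPR reported as 0")
    return MetricsTable(
        qtl=pd.DataFrame(qtl_rows),
        interactions=pd.DataFrame(int_rows),
        fpr={c: (mis[c] / tot[c] if tot[c] else 0.0) for c in checkpoints},
        fpr_i={c: (imis[c] / itot[c] if itot[c] else 0.0) for c in checkpoints},
        mean_n_qtl={c: float(np.mean(nq[c])) if nq[c] else np.nan for c in checkpoints},
        n_replicates=R,
        n_failed=n_failed,
        model_size_counts=size_counts,
        interaction_size_counts=isize_counts,
        zero_identified=zero_ident,
    )


def run_replicate(
    arch: Architecture,
    n: int,
    config: SearchConfig,
    sim_seed,
    lod_z: float = 1.0,
    compute_lod: bool = True,
) -> dict:
    """Simulate one replicate, run the search, and collect the checkpoint
    models and LOD-1 intervals of the paired identified QTL."""
    cross = simulate_backcross(arch, n, seed=sim_seed)
    data = cross.data
    try:
        result = run_search(data, config)
    except (SingularModelError, ValueError, np.linalg.LinAlgError) as exc:
        logger.warning("replicate failed: %s", exc)
        return {"failed": True, "error": str(exc)}
    rec: dict = {"checkpoints": dict(result.trace.checkpoints), "failed": False,
                 "model": result.model}
    if compute_lod and result.model.n_qtl:
        pairing = pair_identified(arch, result.model)
        lod: dict[int, tuple] = {}
        for k in range(arch.n_qtl):
            ii = pairing.sim_to_ident[k]
            if ii is None:
                continue
            try:
                interval = lod_support_interval(result.fit, data, ii, z=lod_z)
            except (SingularModelError, RuntimeError):
                continue
            lod[k] = (
                interval.peak,
                interval.low,
                interval.high,
                interval.contains(arch.qtl[k].position),
            )
        rec["lod"] = lod
    return rec


def replicate_study(
    arch: Architecture,
    n: int,
    reps: int,
    config: SearchConfig | None = None,
    master_seed: int = 0,
    lod_z: float = 1.0,
    compute_lod: bool = True,
    progress: bool = False,
) -> MetricsTable:
    """Simulate ``reps`` populations, run the full search on each, and
    aggregate power/FPR/estimate metrics.  Reproducible given
    ``master_seed`` (per-replicate seeds derive from it deterministically);
    failed replicates are logged and excluded from denominators."""
    if reps < 1:
        raise ValueError("reps must be at least 1")
    config = config or SearchConfig()
    records = []
    for rep in range(reps):
        sim_seed = np.random.SeedSequence([master_seed, rep, 0])
        search_seed = int(
            np.random.SeedSequence([master_seed, rep, 1]).generate_state(1)[0] % (2**31)
        )
        rep_config = SearchConfig(
            alpha=config.alpha, window_cm=config.window_cm, grid_cm=config.grid_cm,
            grid2d_cm=config.grid2d_cm, resamples=config.resamples,
            em_tol=config.em_tol, em_maxit=config.em_maxit,
            truncation=config.truncation, seed=search_seed,
        )
        rec = run_replicate(arch, n, rep_config, sim_seed, lod_z=lod_z,
                            compute_lod=compute_lod)
        records.append(rec)
        if progress:
            status = "failed" if rec.get("failed") else (
                f"{rec['model'].n_qtl} QTL, {len(rec['model'].interactions)} interactions"
            )
            logger.info("replicate %d/%d: %s", rep + 1, reps, status)
    return detection_metrics(records, arch)
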