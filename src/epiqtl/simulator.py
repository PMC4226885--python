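"""Backcross simulation under an epistatic QTL architecture.

A chromosome is simulated as a first-order Markov chain along its ordered
loci (markers plus any QTL inserted in map order): the first locus is
homozygous/heterozygous with probability 1/2 each, and the genotype switches
between adjacent loci with probability equal to the Haldane recombination
fraction of the inter-locus distance (no interference).  The phenotype is
the Cockerham-coded model equation plus N(0, sigma^2) noise.

Two reference architectures are provided: eight QTL on nine 110 cM
chromosomes (markers every 10 cM), eight interactions, with equal effects
tuned to h^2 = 0.8 (architecture 1) or variable effects near h^2 = 0.6
(architecture 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genetic_map import (
    HET,
    HOM,
    MISSING,
    GeneticMap,
    Locus,
    map_distance_to_recombination,
)
from .mim import BackcrossData, MIMModel

__all__ = [
    "Architecture",
    "SimulatedCross",
    "VarianceDecomposition",
    "architecture_1",
    "architecture_2",
    "simulate_backcross",
    "analytic_variance_components",
]


@dataclass(frozen=True)
class Architecture:
    """Simulation truth: map, QTL loci, main effects, interaction effects,
    residual SD.  Interaction pairs are 0-based QTL indices (k < l)."""

    map: GeneticMap
    qtl: tuple[Locus, ...]
    main_effects: np.ndarray
    interactions: tuple[tuple[int, int], ...]
    interaction_effects: np.ndarray
    sigma: float = 1.0

    def __post_init__(self) -> None:
        a = np.asarray(self.main_effects, dtype=float)
        g = np.asarray(self.interaction_effects, dtype=float)
        m = len(self.qtl)
        if a.shape != (m,):
            raise ValueError("main_effects length must equal number of QTL")
        pairs = tuple(tuple(sorted(p)) for p in self.interactions)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate interaction pairs")
        for k, l in pairs:
            if not (0 <= k < l < m):
                raise ValueError(f"invalid interaction pair ({k}, {l})")
        if g.shape != (len(pairs),):
            raise ValueError("interaction_effects length mismatch")
        if self.sigma <= 0:
            raise ValueError("residual SD must be positive")
        for loc in self.qtl:
            self.map.validate_locus(loc)
        object.__setattr__(self, "qtl", tuple(self.qtl))
        object.__setattr__(self, "interactions", pairs)
        object.__setattr__(self, "main_effects", a)
        object.__setattr__(self, "interaction_effects", g)

    @property
    def n_qtl(self) -> int:
        return len(self.qtl)

    def true_model(self) -> MIMModel:
        return MIMModel(
            qtl=self.qtl,
            a=self.main_effects.copy(),
            interactions=self.interactions,
            gamma=self.interaction_effects.copy(),
            mu=0.0,
            sigma2=self.sigma**2,
        )


@dataclass(frozen=True)
class SimulatedCross:
    data: BackcrossData
    qtl_genotypes: np.ndarray = field(repr=False)  # n x m, HOM/HET
    seed: int = 0


@dataclass(frozen=True)
class VarianceDecomposition:
    v_additive: float
    v_epistatic: float
    sigma2: float

    @property
    def v_genetic(self) -> float:
        return self.v_additive + self.v_epistatic

    @property
    def v_phenotypic(self) -> float:
        return self.v_genetic + self.sigma2

    @property
    def heritability(self) -> float:
        return self.v_genetic / self.v_phenotypic

    @property
    def additive_fraction(self) -> float:
        return self.v_additive / self.v_phenotypic

    @property
    def epistatic_fraction(self) -> float:
        return self.v_epistatic / self.v_phenotypic


# -- reference architectures -------------------------------------------

_ARCH_MAP = dict(n_chrom=9, length_cm=110.0, spacing_cm=10.0)
_ARCH_QTL = (
    ("1", 47.0),
    ("1", 80.0),
    ("2", 49.0),
    ("3", 22.0),
    ("3", 78.0),
    ("6", 5.0),
    ("7", 70.0),
    ("9", 63.0),
)
# unordered QTL pairs carrying epistasis (1-based in reports, 0-based here)
_ARCH_PAIRS = ((0, 1), (1, 3), (1, 6), (2, 5), (3, 4), (3, 7), (4, 6), (6, 7))


def architecture_1() -> Architecture:
    """Equal-effect control architecture: four main-effect QTL (a = 1.41),
    four QTL with zero main effect, eight interactions of |gamma| = 1.77,
    residual SD 1; h^2 = 0.8 (additive 0.5, epistatic 0.3)."""
    gmap = GeneticMap.uniform(**_ARCH_MAP)
    return Architecture(
        map=gmap,
        qtl=tuple(Locus(c, p) for c, p in _ARCH_QTL),
        main_effects=np.array([1.41, 1.41, 0.0, 1.41, 0.0, 0.0, 1.41, 0.0]),
        interactions=_ARCH_PAIRS,
        interaction_effects=np.array(
            [1.77, 1.77, -1.77, 1.77, -1.77, 1.77, 1.77, -1.77]
        ),
        sigma=1.0,
    )


def architecture_2() -> Architecture:
    """Variable-effect architecture at the same positions and interaction
    pairs as architecture 1; h^2 near 0.6 (additive ~0.375)."""
    gmap = GeneticMap.uniform(**_ARCH_MAP)
    return Architecture(
        map=gmap,
        qtl=tuple(Locus(c, p) for c, p in _ARCH_QTL),
        main_effects=np.array([1.42, 0.76, -0.04, -0.46, 0.04, -0.06, 0.83, 0.13]),
        interactions=_ARCH_PAIRS,
        interaction_effects=np.array(
            [0.49, 0.99, -0.82, -1.63, -1.31, 1.14, 0.98, -0.98]
        ),
        sigma=1.0,
    )


# -- simulation --------------------------------------------------------


def simulate_backcross(
    arch: Architecture,
    n: int,
    seed: int | np.random.SeedSequence = 0,
    missing_rate: float = 0.0,
) -> SimulatedCross:
    """Simulate ``n`` backcross individuals under ``arch``.

    Deterministic given ``seed``.  ``missing_rate`` optionally masks marker
    genotypes at random (defaults to fully observed data).
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if isinstance(seed, np.random.SeedSequence):
        rng = np.random.default_rng(seed)
        seed_repr = int(seed.entropy) if isinstance(seed.entropy, int) else 0
    else:
        rng = np.random.default_rng(seed)
        seed_repr = int(seed)

    gmap = arch.map
    marker_geno = np.empty((n, gmap.n_markers), dtype=np.int8)
    qtl_geno = np.empty((n, arch.n_qtl), dtype=np.int8)

    for ci, chrom in enumerate(gmap.chromosomes):
        mpos = gmap.positions[ci]
        q_here = [(j, loc.position) for j, loc in enumerate(arch.qtl) if loc.chromosome == chrom]
        # merged locus list in map order; QTL inserted between markers
        loci = [(p, ("m", mi)) for mi, p in enumerate(mpos)]
        loci += [(p, ("q", j)) for j, p in q_here]
        loci.sort(key=lambda t: (t[0], t[1][0] == "m"))  # QTL before marker at ties
        pos_arr = np.array([p for p, _ in loci])
        r = np.asarray(map_distance_to_recombination(np.diff(pos_arr)))

        u = rng.random((n, len(loci)))
        g = np.empty((n, len(loci)), dtype=np.int8)
        g[:, 0] = (u[:, 0] < 0.5).astype(np.int8)  # HOM=0 with prob 1/2
        for j in range(1, len(loci)):
            switch = u[:, j] < r[j - 1]
            g[:, j] = np.where(switch, 1 - g[:, j - 1], g[:, j - 1])

        off = gmap.marker_offset(chrom)
        for j, (_, tag) in enumerate(loci):
            kind, idx = tag
            if kind == "m":
                marker_geno[:, off + idx] = g[:, j]
            else:
                qtl_geno[:, idx] = g[:, j]

    x = np.where(qtl_geno == HOM, 0.5, -0.5)
    genetic = x @ arch.main_effects
    for (k, l), gam in zip(arch.interactions, arch.interaction_effects):
        genetic = genetic + gam * x[:, k] * x[:, l]
    y = genetic + rng.normal(0.0, arch.sigma, size=n)

    if missing_rate > 0:
        mask = rng.random(marker_geno.shape) < missing_rate
        # keep at least one observed marker per chromosome per individual
        for ci, chrom in enumerate(gmap.chromosomes):
            off = gmap.marker_offset(chrom)
            cols = slice(off, off + len(gmap.positions[ci]))
            all_masked = mask[:, cols].all(axis=1)
            mask[all_masked, off] = False
        marker_geno = np.where(mask, MISSING, marker_geno).astype(np.int8)

    data = BackcrossData(phenotypes=y, genotypes=marker_geno, map=gmap)
    return SimulatedCross(data=data, qtl_genotypes=qtl_geno, seed=seed_repr)


# -- analytic variance decomposition ------------------------------------


def _code_covariance(arch: Architecture, k: int, l: int) -> float:
    """Cov(x_k, x_l): 1/4 on the diagonal, (1 - 2 r) / 4 for linked pairs,
    0 across chromosomes."""
    if k == l:
        return 0.25
    qa, qb = arch.qtl[k], arch.qtl[l]
    if qa.chromosome != qb.chromosome:
        return 0.0
    r = map_distance_to_recombination(abs(qa.position - qb.position))
    return (1.0 - 2.0 * float(r)) / 4.0


def analytic_variance_components(arch: Architecture) -> VarianceDecomposition:
    """Exact backcross variance decomposition.

    With E[x] = 0 and x^2 = 1/4 identically, main terms and product terms are
    exactly uncorrelated, as are product terms for different pairs, so

        V_A = sum_{k,l} a_k a_l Cov(x_k, x_l),
        V_I = sum_pairs gamma^2 (1/16 - Cov(x_k, x_l)^2).
    """
    m = arch.n_qtl
    a = arch.main_effects
    v_add = 0.0
    for k in range(m):
        for l in range(m):
            if a[k] and a[l]:
                v_add += a[k] * a[l] * _code_covariance(arch, k, l)
    v_epi = 0.0
    for (k, l), gam in zip(arch.interactions, arch.interaction_effects):
        c = _code_covariance(arch, k, l)
        v_epi += gam**2 * (1.0 / 16.0 - c**2)
    return VarianceDecomposition(
        v_additive=float(v_add), v_epistatic=float(v_epi), sigma2=arch.sigma**2
    )
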