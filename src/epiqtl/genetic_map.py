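"""Genetic-map arithmetic for a backcross.

Coordinates are centimorgans (cM) on a linkage map.  Genotype codes used
throughout the package:

* ``HOM`` (0) — homozygous (like the recurrent parent),
* ``HET`` (1) — heterozygous,
* ``MISSING`` (-1) — not observed.

A backcross segregates 1:1 at every locus, and each locus has only the two
genotype classes above, which is what makes the Cockerham ±1/2 coding
orthogonal between main and interaction effects even under linkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np

HOM: int = 0
HET: int = 1
MISSING: int = -1

__all__ = [
    "HOM",
    "HET",
    "MISSING",
    "GeneticMap",
    "Locus",
    "map_distance_to_recombination",
    "cockerham_code",
    "conditional_genotype_probability",
    "conditional_genotype_probabilities",
    "expected_codes",
]


def map_distance_to_recombination(d: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: cM distance -> recombination fraction.

    r = (1 - exp(-2 d / 100)) / 2, valid under no crossover interference.
    Monotone increasing, r(0) = 0, r -> 1/2 for large d.
    """
    d_arr = np.asarray(d, dtype=float)
    if np.any(d_arr < 0):
        raise ValueError("map distance must be non-negative")
    r = 0.5 * (1.0 - np.exp(-2.0 * d_arr / 100.0))
    if np.isscalar(d) or d_arr.ndim == 0:
        return float(r)
    return r


def cockerham_code(genotype: int | np.ndarray) -> float | np.ndarray:
    """Cockerham scale for a backcross: homozygous -> +1/2, heterozygous -> -1/2."""
    g = np.asarray(genotype)
    if np.any((g != HOM) & (g != HET)):
        raise ValueError("cockerham_code is defined only for realized genotypes (HOM/HET)")
    x = np.where(g == HOM, 0.5, -0.5)
    if np.isscalar(genotype) or x.ndim == 0:
        return float(x)
    return x


class Locus(NamedTuple):
    """A position on the genetic map: (chromosome id, position in cM)."""

    chromosome: str
    position: float


@dataclass(frozen=True)
class GeneticMap:
    """Ordered marker positions per chromosome.

    Parameters
    ----------
    chromosomes
        Chromosome identifiers in map order.
    marker_names
        Tuple (per chromosome) of marker-name tuples.
    positions
        Tuple (per chromosome) of strictly increasing cM positions.
    """

    chromosomes: tuple[str, ...]
    marker_names: tuple[tuple[str, ...], ...]
    positions: tuple[np.ndarray, ...] = field(repr=False)

    def __post_init__(self) -> None:
        if not (len(self.chromosomes) == len(self.marker_names) == len(self.positions)):
            raise ValueError("chromosomes, marker_names and positions must align")
        if len(set(self.chromosomes)) != len(self.chromosomes):
            raise ValueError("duplicate chromosome ids")
        seen: set[str] = set()
        for chrom, names, pos in zip(self.chromosomes, self.marker_names, self.positions):
            pos = np.asarray(pos, dtype=float)
            if len(names) != len(pos):
                raise ValueError(f"chromosome {chrom}: names/positions length mismatch")
            if len(pos) < 2:
                raise ValueError(f"chromosome {chrom}: needs at least 2 markers")
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {chrom}: positions must be strictly increasing")
            if np.any(pos < 0):
                raise ValueError(f"chromosome {chrom}: negative positions")
            dup = seen.intersection(names)
            if dup:
                raise ValueError(f"duplicate marker names: {sorted(dup)}")
            seen.update(names)
        object.__setattr__(self, "positions", tuple(np.asarray(p, dtype=float) for p in self.positions))

    # -- construction -------------------------------------------------

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, str, float]]) -> "GeneticMap":
        """Build from (marker, chromosome, position_cM) rows, chromosomes ordered
        by first appearance."""
        chrom_order: list[str] = []
        by_chrom: dict[str, list[tuple[str, float]]] = {}
        for name, chrom, pos in records:
            chrom = str(chrom)
            if chrom not in by_chrom:
                chrom_order.append(chrom)
                by_chrom[chrom] = []
            by_chrom[chrom].append((str(name), float(pos)))
        names = tuple(tuple(n for n, _ in by_chrom[c]) for c in chrom_order)
        pos = tuple(np.array([p for _, p in by_chrom[c]], dtype=float) for c in chrom_order)
        return cls(tuple(chrom_order), names, pos)

    @classmethod
    def uniform(cls, n_chrom: int, length_cm: float, spacing_cm: float,
                chrom_prefix: str = "") -> "GeneticMap":
        """Equally spaced markers 0, spacing, ..., length on each chromosome."""
        grid = np.arange(0.0, length_cm + 1e-9, spacing_cm)
        chroms = tuple(f"{chrom_prefix}{i + 1}" for i in range(n_chrom))
        names = tuple(
            tuple(f"m{c}_{j + 1}" for j in range(len(grid))) for c in chroms
        )
        return cls(chroms, names, tuple(grid.copy() for _ in chroms))

    # -- queries ------------------------------------------------------

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def n_markers(self) -> int:
        return int(sum(len(p) for p in self.positions))

    def chrom_index(self, chromosome: str) -> int:
        try:
            return self.chromosomes.index(chromosome)
        except ValueError:
            raise KeyError(f"unknown chromosome {chromosome!r}") from None

    def chrom_positions(self, chromosome: str) -> np.ndarray:
        return self.positions[self.chrom_index(chromosome)]

    def marker_offset(self, chromosome: str) -> int:
        """Column offset of a chromosome's first marker in the genome-wide
        marker order (chromosomes concatenated in map order)."""
        ci = self.chrom_index(chromosome)
        return int(sum(len(p) for p in self.positions[:ci]))

    def all_marker_names(self) -> tuple[str, ...]:
        return tuple(n for names in self.marker_names for n in names)

    def chrom_span(self, chromosome: str) -> tuple[float, float]:
        pos = self.chrom_positions(chromosome)
        return float(pos[0]), float(pos[-1])

    def validate_locus(self, locus: Locus) -> None:
        lo, hi = self.chrom_span(locus.chromosome)
        if not (lo - 1e-9 <= locus.position <= hi + 1e-9):
            raise ValueError(
                f"locus {locus} outside marker span [{lo}, {hi}] of chromosome {locus.chromosome}"
            )

    def grid(self, step_cm: float) -> list[Locus]:
        """Regular grid from first to last marker of each chromosome (inclusive),
        anchored at the first marker."""
        if step_cm <= 0:
            raise ValueError("grid step must be positive")
        out: list[Locus] = []
        for chrom, pos in zip(self.chromosomes, self.positions):
            p = pos[0]
            while p <= pos[-1] + 1e-9:
                out.append(Locus(chrom, round(float(min(p, pos[-1])), 6)))
                p += step_cm
        return out


# -- conditional QTL-genotype probabilities ---------------------------


def conditional_genotype_probabilities(
    gmap: GeneticMap, genotypes: np.ndarray, locus: Locus
) -> np.ndarray:
    """P(QTL genotype | observed marker genotypes) for every individual.

    ``genotypes`` is the full n × M genome-wide marker matrix (HOM/HET/MISSING),
    columns in map order.  Returns an (n, 2) array of (P(HOM), P(HET)).

    Conditioning uses the nearest non-missing flanking markers, skipping
    missing markers outward.  Double recombination within the resulting
    bracket is ignored: concordant flanks give that genotype probability 1;
    discordant flanks at distances d1 (left) and d2 (right) give
    P(left genotype) = r2 / (r1 + r2) with Haldane r's.  Beyond the last
    informative marker the single flank is used with its recombination
    fraction.
    """
    gmap.validate_locus(locus)
    ci = gmap.chrom_index(locus.chromosome)
    pos = gmap.positions[ci]
    off = gmap.marker_offset(locus.chromosome)
    g = np.asarray(genotypes)[:, off : off + len(pos)]
    n = g.shape[0]

    obs = g != MISSING
    if np.any(~obs.any(axis=1)):
        bad = int(np.flatnonzero(~obs.any(axis=1))[0])
        raise ValueError(
            f"individual {bad} has no informative marker on chromosome {locus.chromosome}"
        )

    p = float(locus.position)
    left_cols = pos <= p + 1e-9
    right_cols = pos >= p - 1e-9

    # index of nearest informative marker on each side (-1 when none)
    def _last_true(mask: np.ndarray, cols: np.ndarray) -> np.ndarray:
        sub = mask[:, cols]
        if sub.shape[1] == 0:
            return np.full(n, -1)
        idx = np.where(sub, np.arange(sub.shape[1])[None, :], -1).max(axis=1)
        col_map = np.flatnonzero(cols)
        return np.where(idx >= 0, col_map[np.clip(idx, 0, None)], -1)

    def _first_true(mask: np.ndarray, cols: np.ndarray) -> np.ndarray:
        sub = mask[:, cols]
        if sub.shape[1] == 0:
            return np.full(n, -1)
        big = sub.shape[1]
        idx = np.where(sub, np.arange(sub.shape[1])[None, :], big).min(axis=1)
        col_map = np.flatnonzero(cols)
        return np.where(idx < big, col_map[np.clip(idx, None, big - 1)], -1)

    jl = _last_true(obs, left_cols)
    jr = _first_true(obs, right_cols)

    out = np.empty((n, 2), dtype=float)

    has_l = jl >= 0
    has_r = jr >= 0
    gl = np.where(has_l, g[np.arange(n), np.clip(jl, 0, None)], -1)
    gr = np.where(has_r, g[np.arange(n), np.clip(jr, 0, None)], -1)
    dl = np.where(has_l, p - pos[np.clip(jl, 0, None)], np.inf)
    dr = np.where(has_r, pos[np.clip(jr, 0, None)] - p, np.inf)

    # a flank at zero distance (locus on an informative marker) dominates
    at_marker_l = has_l & (dl <= 1e-9)
    at_marker_r = has_r & (dr <= 1e-9)

    both = has_l & has_r
    concordant = both & (gl == gr)
    discordant = both & (gl != gr)
    only_l = has_l & ~has_r
    only_r = has_r & ~has_l

    p_hom = np.empty(n, dtype=float)

    # two informative flanks, same genotype: no-double-recombination => certain
    p_hom[concordant] = (gl[concordant] == HOM).astype(float)

    # discordant flanks: P(left genotype) = r2 / (r1 + r2)
    if np.any(discordant):
        r1 = np.asarray(map_distance_to_recombination(dl[discordant]))
        r2 = np.asarray(map_distance_to_recombination(dr[discordant]))
        p_left = r2 / (r1 + r2)
        p_hom[discordant] = np.where(gl[discordant] == HOM, p_left, 1.0 - p_left)

    # one-sided: single flank with its recombination fraction
    for mask, gg, dd in ((only_l, gl, dl), (only_r, gr, dr)):
        if np.any(mask):
            r = np.asarray(map_distance_to_recombination(dd[mask]))
            p_same = 1.0 - r
            p_hom[mask] = np.where(gg[mask] == HOM, p_same, 1.0 - p_same)

    # locus exactly at an informative marker overrides interpolation
    for mask, gg in ((at_marker_l, gl), (at_marker_r, gr)):
        if np.any(mask):
            p_hom[mask] = (gg[mask] == HOM).astype(float)

    out[:, 0] = p_hom
    out[:, 1] = 1.0 - p_hom
    return out


def conditional_genotype_probability(
    gmap: GeneticMap, marker_row: Sequence[int] | np.ndarray, locus: Locus
) -> tuple[float, float]:
    """Single-individual wrapper; returns (P(HOM), P(HET))."""
    row = np.asarray(marker_row).reshape(1, -1)
    probs = conditional_genotype_probabilities(gmap, row, locus)
    return float(probs[0, 0]), float(probs[0, 1])


def expected_codes(gmap: GeneticMap, genotypes: np.ndarray, locus: Locus) -> np.ndarray:
    """Posterior-mean Cockerham code E[x] = P(HOM)/2 - P(HET)/2 per individual."""
    probs = conditional_genotype_probabilities(gmap, genotypes, locus)
    return 0.5 * (probs[:, 0] - probs[:, 1])
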