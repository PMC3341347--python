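"""Forward simulation of stands, pedigrees, and error-corrupted genotypes.

Generates data with the statistical structure the inference assumes: a
mapped stand of adult trees (Poisson count at a configured density,
uniform locations, right-skewed fecundities, Hardy-Weinberg genotypes at
Dirichlet allele frequencies), seedlings produced by fecundity-weighted
mothers with 2D-t seed displacements and distance-and-pollen-weighted
fathers, exterior parents in a buffer strip around the plot (so out-of-plot
parentage categories actually occur), and genotyping error applied through
the same dropout/mistyping channels the likelihood models.

Defaults emulate the denser of the two stand structures this package's
methods were developed for: 26.5 adults/ha on a 7.5-ha square plot
(expected 199 adults), per-tree fecundity means averaging ~948 seeds/yr
with maxima near 2,900, 6 microsatellite loci with 14-35 alleles each,
and per-locus dropout rates spanning 0.02-0.08 and mistyping rates
0.02-0.18.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon

from . import kernels
from .genotypes import (
    MISSING,
    AlleleFrequencies,
    ErrorRates,
    GenotypeTable,
    mistype_matrix,
)

__all__ = [
    "SimConfig",
    "default_polygon",
    "simulate_stand",
    "simulate_allele_frequencies",
    "simulate_offspring",
    "apply_genotyping_error",
    "simulate_dataset",
]


def default_polygon(area_ha: float = 7.5) -> Polygon:
    """Square plot of the given area, local coordinates in meters."""
    side = math.sqrt(area_ha * 1e4)
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


@dataclass
class SimConfig:
    """Study conditions for the forward simulator.

    Attributes
    ----------
    polygon : shapely Polygon or None
        Plot boundary (m).  None means a 7.5-ha square.
    adult_density_ha : adults per hectare (Poisson intensity).
    fecundity_mean : mean of per-tree fecundity means, seeds/yr.  Per-tree
        means are Gamma(shape=2) scaled to this mean, giving the observed
        right skew (maxima ~3x the mean at a 200-tree stand).
    fecundity_sd_frac : posterior SD of each tree's fecundity as a
        fraction of its mean (the inference mixes over this uncertainty).
    n_loci, alleles_min, alleles_max : microsatellite panel; alleles per
        locus drawn uniformly from [alleles_min, alleles_max].
    motif : repeat motif length, bp.
    base_size : smallest allele size, bp.
    u_s, u_p : true seed and pollen dispersal parameters, m^2.
    n_seedlings : number of in-plot seedlings to generate.
    e1, e2 : per-locus mistyping / dropout rates.  None means evenly
        spaced across the empirical ranges 0.02-0.18 and 0.02-0.08.
    out_margin : width (m) of the exterior buffer populated with virtual
        parents at the in-plot density.  The inference treats the stand as
        part of continuous forest, so the buffer should comfortably exceed
        the expected seed dispersal distance (several kernel means).
    """

    polygon: Polygon | None = None
    adult_density_ha: float = 26.5
    fecundity_mean: float = 948.0
    fecundity_shape: float = 2.0
    fecundity_sd_frac: float = 0.3
    n_loci: int = 6
    alleles_min: int = 14
    alleles_max: int = 35
    motif: int = 2
    base_size: int = 120
    u_s: float = 92.0
    u_p: float = 8600.0
    n_seedlings: int = 179
    e1: np.ndarray | None = None
    e2: np.ndarray | None = None
    out_margin: float = 200.0
    species: tuple = (("Q_rubra", 0.65), ("Q_coccinea", 0.27), ("Q_velutina", 0.08))

    def __post_init__(self):
        if self.polygon is None:
            self.polygon = default_polygon()
        if self.e1 is None:
            self.e1 = np.linspace(0.02, 0.18, self.n_loci)
        if self.e2 is None:
            self.e2 = np.linspace(0.02, 0.08, self.n_loci)
        if self.adult_density_ha <= 0 or self.n_seedlings < 0:
            raise ValueError("density must be positive and seedling count nonnegative")
        if not (0 < self.alleles_min <= self.alleles_max):
            raise ValueError("allele count range invalid")

    @property
    def error_rates(self) -> ErrorRates:
        return ErrorRates(self.e1, self.e2)


def _uniform_in_polygon(polygon: Polygon, n: int, rng) -> np.ndarray:
    """Rejection-sample n uniform points inside a polygon."""
    minx, miny, maxx, maxy = polygon.bounds
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 16)
        cand = np.column_stack(
            [rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)]
        )
        inside = np.fromiter(
            (polygon.contains(Point(x, y)) for x, y in cand), bool, count=m
        )
        keep = cand[inside][: n - filled]
        pts[filled : filled + len(keep)] = keep
        filled += len(keep)
    return pts


def simulate_allele_frequencies(cfg: SimConfig, rng) -> AlleleFrequencies:
    """Dirichlet(0.5) allele frequencies over a random-width ladder per locus."""
    ladders, freqs = [], []
    for _ in range(cfg.n_loci):
        k = int(rng.integers(cfg.alleles_min, cfg.alleles_max + 1))
        ladders.append(cfg.base_size + cfg.motif * np.arange(k, dtype=np.int64))
        freqs.append(rng.dirichlet(np.full(k, 0.5)))
    return AlleleFrequencies(ladders, freqs)


def _hwe_genotypes(freqs: AlleleFrequencies, n: int, rng) -> np.ndarray:
    """(n, L, 2) Hardy-Weinberg genotype calls from per-locus frequencies."""
    L = len(freqs.ladders)
    calls = np.empty((n, L, 2), dtype=np.int64)
    for l in range(L):
        ladder, f = freqs.ladders[l], freqs.freqs[l]
        calls[:, l, :] = ladder[rng.choice(len(ladder), size=(n, 2), p=f)]
    return calls


def _fecundity_means(n: int, cfg: SimConfig, rng) -> np.ndarray:
    shape = cfg.fecundity_shape
    return rng.gamma(shape, cfg.fecundity_mean / shape, size=n)


def simulate_stand(cfg: SimConfig, rng, freqs: AlleleFrequencies | None = None):
    """Simulate the mapped adult stand.

    Returns ``(adults, genotypes, freqs)``: a DataFrame with columns
    id, x, y, species, dbh_cm, fecundity_mean, fecundity_sd; the true
    GenotypeTable for the adults; and the allele frequencies used.
    Tree count is Poisson(density x area); locations are uniform in the
    polygon; DBH is lognormal (median ~38 cm) so cohort splitting by the
    DBH median is exercised.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if freqs is None:
        freqs = simulate_allele_frequencies(cfg, rng)
    area_ha = cfg.polygon.area / 1e4
    expected = cfg.adult_density_ha * area_ha
    if expected <= 0:
        raise ValueError("expected tree count is zero; enlarge the plot or density")
    n = int(rng.poisson(expected))
    n = max(n, 2)
    xy = _uniform_in_polygon(cfg.polygon, n, rng)
    fec = _fecundity_means(n, cfg, rng)
    names = [s for s, _ in cfg.species]
    probs = np.array([p for _, p in cfg.species], dtype=float)
    probs = probs / probs.sum()
    adults = pd.DataFrame(
        {
            "id": [f"A{i:04d}" for i in range(n)],
            "x": xy[:, 0],
            "y": xy[:, 1],
            "species": rng.choice(names, size=n, p=probs),
            "dbh_cm": np.exp(rng.normal(math.log(38.0), 0.45, size=n)) + 10.0,
            "fecundity_mean": fec,
            "fecundity_sd": cfg.fecundity_sd_frac * fec + 1.0,
        }
    )
    calls = _hwe_genotypes(freqs, n, rng)
    loci = [f"L{l + 1}" for l in range(cfg.n_loci)]
    gt = GenotypeTable(list(adults["id"]), loci, calls, np.full(cfg.n_loci, cfg.motif))
    return adults, gt, freqs


def _exterior_parents(cfg: SimConfig, freqs: AlleleFrequencies, rng):
    """Virtual parents in the buffer strip, at the in-plot density."""
    ring = cfg.polygon.buffer(cfg.out_margin).difference(cfg.polygon)
    n = int(rng.poisson(cfg.adult_density_ha * ring.area / 1e4))
    n = max(n, 1)
    minx, miny, maxx, maxy = ring.bounds
    pts = np.empty((n, 2))
    filled = 0
    while filled < n:
        m = max(4 * (n - filled), 16)
        cand = np.column_stack([rng.uniform(minx, maxx, m), rng.uniform(miny, maxy, m)])
        inside = np.fromiter((ring.contains(Point(x, y)) for x, y in cand), bool, count=m)
        keep = cand[inside][: n - filled]
        pts[filled : filled + len(keep)] = keep
        filled += len(keep)
    fec = _fecundity_means(n, cfg, rng)
    calls = _hwe_genotypes(freqs, n, rng)
    return pts, fec, calls


def simulate_offspring(adults: pd.DataFrame, adult_calls: np.ndarray, freqs, cfg: SimConfig, rng):
    """Simulate seedlings with a recorded true pedigree.

    Mothers are chosen proportional to fecundity among in-plot adults and
    virtual exterior parents; each seed lands at mother + a 2D-t
    displacement (u_s) and is kept only if inside the plot; fathers are
    chosen proportional to pollen output x K(distance to mother; u_p),
    self excluded.  Offspring genotypes take one allele from each parent.

    Returns ``(seedlings, seedling_calls, pedigree)``; the pedigree
    DataFrame records mother_id/father_id as in-plot ids or "OUT", plus
    the realized mother-offspring and father-mother distances.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if len(adults) == 0:
        raise ValueError("stand is empty")
    out_xy, out_fec, out_calls = _exterior_parents(cfg, freqs, rng)
    all_xy = np.vstack([adults[["x", "y"]].to_numpy(float), out_xy])
    all_fec = np.concatenate([adults["fecundity_mean"].to_numpy(float), out_fec])
    all_calls = np.vstack([adult_calls, out_calls])
    n_in = len(adults)
    n_parents = len(all_fec)
    if all_fec.sum() <= 0:
        raise ValueError("all fecundities are zero")
    p_mother = all_fec / all_fec.sum()

    rows, child_calls = [], []
    attempts = 0
    max_attempts = 200 * max(cfg.n_seedlings, 1)
    while len(rows) < cfg.n_seedlings:
        batch = max(2 * (cfg.n_seedlings - len(rows)), 16)
        attempts += batch
        if attempts > max_attempts:
            raise RuntimeError(
                "no seedlings landed inside the plot after the maximum number of attempts"
            )
        mothers = rng.choice(n_parents, size=batch, p=p_mother)
        disp = kernels.sample_displacements(cfg.u_s, batch, rng)
        pos = all_xy[mothers] + disp
        inside = np.fromiter(
            (cfg.polygon.contains(Point(x, y)) for x, y in pos), bool, count=batch
        )
        for m, (x, y) in zip(mothers[inside], pos[inside]):
            if len(rows) >= cfg.n_seedlings:
                break
            d2 = np.sum((all_xy - all_xy[m]) ** 2, axis=1)
            w = all_fec * kernels.kernel_density(np.sqrt(d2), cfg.u_p)
            w[m] = 0.0
            f = rng.choice(n_parents, p=w / w.sum())
            calls = np.empty((cfg.n_loci, 2), dtype=np.int64)
            pick = rng.integers(0, 2, size=(2, cfg.n_loci))
            calls[:, 0] = all_calls[m, np.arange(cfg.n_loci), pick[0]]
            calls[:, 1] = all_calls[f, np.arange(cfg.n_loci), pick[1]]
            child_calls.append(calls)
            rows.append(
                {
                    "id": f"S{len(rows):04d}",
                    "x": x,
                    "y": y,
                    "mother_id": adults["id"].iloc[m] if m < n_in else "OUT",
                    "father_id": adults["id"].iloc[f] if f < n_in else "OUT",
                    "mother_distance": math.hypot(x - all_xy[m, 0], y - all_xy[m, 1]),
                    "father_mother_distance": math.sqrt(d2[f]),
                }
            )
    columns = ["id", "x", "y", "mother_id", "father_id", "mother_distance",
               "father_mother_distance"]
    ped = pd.DataFrame(rows, columns=columns)
    seedlings = ped[["id", "x", "y"]].copy()
    pedigree = ped[["id", "mother_id", "father_id", "mother_distance", "father_mother_distance"]]
    child_arr = (
        np.array(child_calls, dtype=np.int64)
        if child_calls
        else np.zeros((0, cfg.n_loci, 2), dtype=np.int64)
    )
    return seedlings, child_arr, pedigree


def apply_genotyping_error(table: GenotypeTable, err: ErrorRates, rng) -> GenotypeTable:
    """Corrupt true calls through the dropout-then-mistyping channels.

    Shares the channel definitions of :func:`seedshadow.genotypes.
    observation_model`: heterozygotes collapse to one of their alleles
    with probability e2, then each recorded allele independently steps one
    motif along the locus ladder with probability e1 (edge rungs step
    inward).  Missing calls stay missing.  Reproducible under a fixed rng.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if err.n_loci != table.n_loci:
        raise ValueError("error rates must have one entry per locus")
    calls = table.calls.copy()
    for l in range(table.n_loci):
        ladder = table.ladder(l)
        m = mistype_matrix(len(ladder), float(err.e1[l]))
        cl = calls[:, l, :]
        present = ~(cl == MISSING).any(axis=1)
        het = present & (cl[:, 0] != cl[:, 1])
        drop = het & (rng.random(len(cl)) < err.e2[l])
        kept = rng.integers(0, 2, size=len(cl))
        cl[drop, 0] = cl[drop, kept[drop]]
        cl[drop, 1] = cl[drop, 0]
        for a in range(2):
            idx = np.where(present)[0]
            pos = np.searchsorted(ladder, cl[idx, a])
            cdf = np.cumsum(m[pos], axis=1)
            newpos = (cdf < rng.random(len(idx))[:, None]).sum(axis=1)
            cl[idx, a] = ladder[newpos]
        calls[:, l, :] = cl
    return GenotypeTable(list(table.ids), list(table.loci), calls, table.motif.copy())


def simulate_dataset(cfg: SimConfig | None = None, seed: int = 0):
    """Generate a complete, internally consistent dataset plus its truth.

    Returns a dict with keys ``adults``, ``seedlings``, ``genotypes``
    (observed, error-corrupted, adults + seedlings), ``true_genotypes``,
    ``polygon``, ``error_rates``, ``pedigree`` (true), ``freqs`` (true
    simulation frequencies), and ``config``.
    """
    cfg = cfg if cfg is not None else SimConfig()
    rng = np.random.default_rng(seed)
    adults, adult_gt, freqs = simulate_stand(cfg, rng)
    seedlings, seedling_calls, pedigree = simulate_offspring(
        adults, adult_gt.calls, freqs, cfg, rng
    )
    ids = list(adults["id"]) + list(seedlings["id"])
    calls = np.vstack([adult_gt.calls, seedling_calls])
    true_gt = GenotypeTable(ids, adult_gt.loci, calls, adult_gt.motif.copy())
    obs_gt = apply_genotyping_error(true_gt, cfg.error_rates, rng)
    return {
        "adults": adults,
        "seedlings": seedlings,
        "genotypes": obs_gt,
        "true_genotypes": true_gt,
        "polygon": cfg.polygon,
        "error_rates": cfg.error_rates,
        "pedigree": pedigree,
        "freqs": freqs,
        "config": cfg,
    }
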