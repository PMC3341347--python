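"""Hierarchical Bayesian parentage and dispersal inference.

The model assigns each seedling a (mother, father) pair — each slot an
in-plot adult or OUT (an unmapped tree beyond the plot boundary) — jointly
with the seed and pollen dispersal parameters ``u_s`` and ``u_p`` of the
2D-t kernel.  The unnormalized probability of a pair is

    seed term    f_i  * K(d_ik; u_s)          (mother i to seedling k)
  x pollen term  c_i' * K(d_i'i; u_p)         (father i' to mother i)
  x genotype term P(G_obs_k | parents, e1, e2)

with fecundity f and pollen output c proportional, selfing excluded
(mother != father), and OUT slots integrated over a grid of virtual
exterior parents at the in-plot mean density and fecundity.  Priors on u_s
and u_p are truncated normals whose truncation bounds are stated as mean
dispersal distances.  Sampling is Gibbs on pedigrees (each seedling's pair
redrawn from its exact conditional) and random-walk Metropolis on log u,
with per-tree fecundities redrawn each sweep from their (zero-truncated
normal) posteriors so that the chain mixes over fecundity uncertainty.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.special import ndtr
from scipy.stats import truncnorm
from shapely.geometry import Point, Polygon

from . import kernels
from .genotypes import (
    MISSING,
    AlleleFrequencies,
    ErrorRates,
    GenotypeTable,
    allele_frequencies,
    obs_weight_matrix,
)

__all__ = [
    "PriorSpec",
    "DEFAULT_SEED_PRIOR",
    "DEFAULT_POLLEN_PRIOR",
    "McmcConfig",
    "Dataset",
    "ExteriorGrid",
    "build_exterior_grid",
    "ParentageModel",
    "PosteriorSamples",
    "run_mcmc",
    "summarize_posterior",
    "CATEGORIES",
]

logger = logging.getLogger(__name__)


def _kd(d: np.ndarray, u: float) -> np.ndarray:
    """2D-t density on precomputed (validated) distance matrices."""
    return u / (np.pi * (u + d * d) ** 2)

#: Parentage categories, in reporting order.
CATEGORIES = ("in/in", "in-mother/out-father", "in-father/out-mother", "out/out")


@dataclass(frozen=True)
class PriorSpec:
    """Truncated-normal prior for a dispersal parameter.

    ``mean`` and ``sd`` are on the u scale (m^2); the truncation bounds
    are given as mean dispersal distances (m) and converted through
    ``param_from_distance``.
    """

    mean: float
    sd: float
    min_distance: float
    max_distance: float

    def __post_init__(self):
        if self.sd <= 0:
            raise ValueError("prior sd must be positive")
        if not 0 < self.min_distance < self.max_distance:
            raise ValueError("need 0 < min_distance < max_distance")

    @property
    def lower(self) -> float:
        cached = getattr(self, "_lower", None)
        if cached is None:
            cached = kernels.param_from_distance(self.min_distance)
            object.__setattr__(self, "_lower", cached)
        return cached

    @property
    def upper(self) -> float:
        cached = getattr(self, "_upper", None)
        if cached is None:
            cached = kernels.param_from_distance(self.max_distance)
            object.__setattr__(self, "_upper", cached)
        return cached

    def _dist(self):
        # frozen scipy distribution, built once (construction is costly)
        cached = getattr(self, "_frozen", None)
        if cached is None:
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            cached = truncnorm(a, b, loc=self.mean, scale=self.sd)
            object.__setattr__(self, "_frozen", cached)
        return cached

    def logpdf(self, u: float) -> float:
        """Truncated-normal log-density on the u scale (analytic)."""
        if not self.lower <= u <= self.upper:
            return -np.inf
        z = getattr(self, "_log_z", None)
        if z is None:
            a = (self.lower - self.mean) / self.sd
            b = (self.upper - self.mean) / self.sd
            z = float(np.log(ndtr(b) - ndtr(a)) + 0.5 * np.log(2.0 * np.pi) + np.log(self.sd))
            object.__setattr__(self, "_log_z", z)
        return -0.5 * ((u - self.mean) / self.sd) ** 2 - z

    def truncated_mean(self) -> float:
        """Analytic mean of the truncated prior (not the nominal mean)."""
        return float(self._dist().mean())

    def truncated_sd(self) -> float:
        return float(self._dist().std())


#: Seed-kernel prior: mean 253 (mean distance 25 m), SD 1000, truncated to
#: mean distances in (5 m, 157 m).
DEFAULT_SEED_PRIOR = PriorSpec(253.0, 1000.0, 5.0, 157.0)
#: Pollen-kernel prior: mean 2000 (mean distance 70.2 m), SD 1500,
#: truncated to mean distances in (5 m, 192 m).
DEFAULT_POLLEN_PRIOR = PriorSpec(2000.0, 1500.0, 5.0, 192.0)


@dataclass
class McmcConfig:
    """Sampler schedule and numerical settings.

    The reference schedule is 50,000 steps, 30,000 burn-in, thin 20 —
    retaining exactly (50000 - 30000) / 20 = 1000 draws.  ``grid_spacing``
    and ``grid_cutoff`` (m) control the virtual exterior-parent grid;
    coarser grids trade tail accuracy for speed and are appropriate for
    simulation studies.  ``species_mode`` is "pooled" (all adults are one
    interbreeding population) or "separate" (candidate parents and allele
    frequencies restricted to the seedling cohort's species).
    """

    n_steps: int = 50_000
    burn_in: int = 30_000
    thin: int = 20
    prop_scale_s: float = 0.5
    prop_scale_p: float = 0.5
    adapt: bool = True
    grid_spacing: float = 10.0
    grid_cutoff: float = 500.0
    species_mode: str = "pooled"
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.burn_in < self.n_steps:
            raise ValueError("need 0 <= burn_in < n_steps")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.grid_spacing <= 0 or self.grid_cutoff <= 0:
            raise ValueError("grid spacing and cutoff must be positive")
        if self.species_mode not in ("pooled", "separate"):
            raise ValueError("species_mode must be 'pooled' or 'separate'")

    @property
    def n_retained(self) -> int:
        return (self.n_steps - self.burn_in) // self.thin


@dataclass
class Dataset:
    """Validated inputs for one stand.

    adults : DataFrame with id, x, y, species, fecundity_mean,
        fecundity_sd (optionally dbh_cm).
    seedlings : DataFrame with id, x, y.
    genotypes : observed GenotypeTable covering all adults and seedlings.
    polygon : plot boundary (shapely, meters).
    error_rates : per-locus ErrorRates.
    """

    adults: pd.DataFrame
    seedlings: pd.DataFrame
    genotypes: GenotypeTable
    polygon: Polygon
    error_rates: ErrorRates

    def __post_init__(self):
        for col in ("id", "x", "y", "fecundity_mean", "fecundity_sd"):
            if col not in self.adults.columns:
                raise ValueError(f"adults table lacks required column {col!r}")
        for col in ("id", "x", "y"):
            if col not in self.seedlings.columns:
                raise ValueError(f"seedlings table lacks required column {col!r}")
        ids = list(self.adults["id"]) + list(self.seedlings["id"])
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids across adults and seedlings")
        missing = [i for i in ids if i not in self.genotypes._index]
        if missing:
            raise ValueError(f"no genotype row for id(s): {missing[:5]}")
        if self.error_rates.n_loci != self.genotypes.n_loci:
            raise ValueError("error rates must have one entry per genotype locus")
        if np.any(self.adults["fecundity_mean"].to_numpy(float) < 0):
            raise ValueError("fecundity means must be nonnegative")
        if np.any(self.adults["fecundity_sd"].to_numpy(float) < 0):
            raise ValueError("fecundity SDs must be nonnegative")
        boundary = self.polygon.buffer(1e-6)
        for label, df in (("adult", self.adults), ("seedling", self.seedlings)):
            for _, row in df.iterrows():
                if not boundary.contains(Point(row["x"], row["y"])):
                    raise ValueError(
                        f"{label} {row['id']} at ({row['x']:.1f}, {row['y']:.1f}) "
                        "lies outside the plot polygon"
                    )

    @property
    def n_adults(self) -> int:
        return len(self.adults)

    @property
    def n_seedlings(self) -> int:
        return len(self.seedlings)


@dataclass
class ExteriorGrid:
    """Virtual out-of-plot parents on a regular grid outside the polygon.

    Each cell carries ``mass`` = expected tree count (density x cell area)
    and the in-plot mean fecundity; the pollen pool beyond the grid is
    handled by the complement rule in the model, so the cutoff only needs
    to capture the seed/pollen coupling near the boundary.
    """

    xy: np.ndarray
    mass: np.ndarray
    mean_fecundity: float
    spacing: float
    density_m2: float

    @property
    def n_cells(self) -> int:
        return len(self.mass)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())


def build_exterior_grid(
    polygon: Polygon,
    density_ha: float,
    mean_fecundity: float,
    cutoff: float = 500.0,
    spacing: float = 10.0,
    expected_seed_distance: float | None = None,
) -> ExteriorGrid:
    """Tile the annulus between the plot boundary and ``cutoff`` with cells.

    Cells whose centers fall strictly outside the polygon but within
    ``cutoff`` of it each get expected tree count density x spacing^2.
    A zero density yields an empty grid (all out-of-plot weights vanish).
    Warns when the cutoff is less than twice the expected seed dispersal
    distance, since then a noticeable share of the seed-source tail is
    beyond the grid.
    """
    if density_ha < 0:
        raise ValueError("density must be nonnegative")
    if polygon.area <= 0 or not polygon.is_valid:
        raise ValueError("polygon must be simple with positive area")
    if expected_seed_distance is not None and cutoff < 2.0 * expected_seed_distance:
        warnings.warn(
            f"exterior cutoff {cutoff:.0f} m is below twice the expected seed "
            f"distance {expected_seed_distance:.0f} m; the dispersal tail is truncated"
        )
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx - cutoff + spacing / 2, maxx + cutoff, spacing)
    ys = np.arange(miny - cutoff + spacing / 2, maxy + cutoff, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    keep = np.empty(len(pts), dtype=bool)
    for i, (x, y) in enumerate(pts):
        p = Point(x, y)
        keep[i] = (not polygon.contains(p)) and polygon.exterior.distance(p) <= cutoff and (
            not polygon.touches(p)
        )
        if keep[i] and polygon.distance(p) == 0.0 and polygon.contains(p):
            keep[i] = False
    pts = pts[keep]
    density_m2 = density_ha / 1e4
    mass = np.full(len(pts), density_m2 * spacing * spacing)
    return ExteriorGrid(pts, mass, float(mean_fecundity), spacing, density_m2)


def _interior_quadrature(polygon: Polygon, spacing: float):
    """Midpoint quadrature nodes and weights over the plot interior."""
    minx, miny, maxx, maxy = polygon.bounds
    xs = np.arange(minx + spacing / 2, maxx, spacing)
    ys = np.arange(miny + spacing / 2, maxy, spacing)
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    keep = np.fromiter((polygon.contains(Point(x, y)) for x, y in pts), bool, count=len(pts))
    return pts[keep], spacing * spacing


@dataclass
class PedigreeState:
    """Current (mother, father) assignment per seedling.

    ``mothers`` and ``fathers`` are integer arrays indexing the candidate
    adults, with the value ``n_adults`` standing for OUT.  A tree can
    never occupy both slots of the same seedling.
    """

    mothers: np.ndarray
    fathers: np.ndarray
    out_index: int

    def __post_init__(self):
        both_in = (self.mothers != self.out_index) & (self.fathers != self.out_index)
        if np.any(self.mothers[both_in] == self.fathers[both_in]):
            raise ValueError("a tree cannot be both mother and father of one seedling")

    def categories(self) -> np.ndarray:
        """Category label per seedling (see :data:`CATEGORIES`)."""
        m_in = self.mothers != self.out_index
        f_in = self.fathers != self.out_index
        out = np.empty(len(self.mothers), dtype=object)
        out[m_in & f_in] = CATEGORIES[0]
        out[m_in & ~f_in] = CATEGORIES[1]
        out[~m_in & f_in] = CATEGORIES[2]
        out[~m_in & ~f_in] = CATEGORIES[3]
        return out


class ParentageModel:
    """Precomputed likelihood machinery for one dataset.

    Builds, once: pairwise distance matrices, the exterior-parent grid,
    the interior quadrature grid for complement integrals, and the
    genotype-likelihood tensor G[k, m, f] (OUT = last index in each slot),
    which is independent of the dispersal parameters and fecundities.
    """

    def __init__(
        self,
        dataset: Dataset,
        seed_prior: PriorSpec = DEFAULT_SEED_PRIOR,
        pollen_prior: PriorSpec = DEFAULT_POLLEN_PRIOR,
        config: McmcConfig | None = None,
    ):
        self.dataset = dataset
        self.seed_prior = seed_prior
        self.pollen_prior = pollen_prior
        self.config = config if config is not None else McmcConfig()

        ax = dataset.adults[["x", "y"]].to_numpy(float)
        sx = dataset.seedlings[["x", "y"]].to_numpy(float)
        self.n_adults = len(ax)
        self.n_seedlings = len(sx)
        self.OUT = self.n_adults

        self.fec_mean = dataset.adults["fecundity_mean"].to_numpy(float)
        self.fec_sd = dataset.adults["fecundity_sd"].to_numpy(float)
        area_ha = dataset.polygon.area / 1e4
        density_ha = self.n_adults / area_ha
        mean_fec = float(self.fec_mean.mean()) if self.n_adults else 0.0
        self.grid = build_exterior_grid(
            dataset.polygon,
            density_ha,
            mean_fec,
            cutoff=self.config.grid_cutoff,
            spacing=self.config.grid_spacing,
        )
        self._int_pts, self._int_area = _interior_quadrature(
            dataset.polygon, self.config.grid_spacing
        )

        # distance matrices (meters)
        self.d_as = cdist(ax, sx) if self.n_seedlings else np.zeros((self.n_adults, 0))
        self.d_aa = cdist(ax, ax)
        self.d_cs = (
            cdist(self.grid.xy, sx)
            if self.grid.n_cells and self.n_seedlings
            else np.zeros((self.grid.n_cells, self.n_seedlings))
        )
        self.d_ca = (
            cdist(self.grid.xy, ax) if self.grid.n_cells else np.zeros((0, self.n_adults))
        )
        self.d_ci = (
            cdist(self.grid.xy, self._int_pts)
            if self.grid.n_cells and len(self._int_pts)
            else np.zeros((self.grid.n_cells, len(self._int_pts)))
        )

        # per-seedling edge distance (minimum dispersal distance for immigrants)
        self.edge_distance = np.array(
            [dataset.polygon.exterior.distance(Point(x, y)) for x, y in sx]
        )

        self._freqs = allele_frequencies(dataset.genotypes)
        self.G = self._genotype_tensor()

    # -- genotype machinery -------------------------------------------------

    def _species_candidates(self) -> np.ndarray | None:
        if self.config.species_mode == "pooled":
            return None
        if "species" not in self.dataset.adults.columns:
            raise ValueError("species_mode='separate' requires a species column")
        return self.dataset.adults["species"].to_numpy()

    def _genotype_tensor(self) -> np.ndarray:
        """G[k, m, f] = P(G_obs_k | mother m, father f), OUT = last index."""
        ds = self.dataset
        gt = ds.genotypes
        err = ds.error_rates
        A, K = self.n_adults, self.n_seedlings
        freqs = self._freqs
        sp_freqs = None
        seedling_species = None
        if self.config.species_mode == "separate":
            # under no-hybridization, an OUT parent of a seedling transmits
            # from its own species' allele frequencies (subsetted adults)
            sp = ds.adults["species"]
            sp_freqs = {
                s: allele_frequencies(gt, list(ds.adults.loc[sp == s, "id"]))
                for s in sp.unique()
            }
            if "species" in ds.seedlings.columns:
                seedling_species = ds.seedlings["species"].to_numpy()
        adult_rows = np.stack([gt.row(i) for i in ds.adults["id"]]) if A else np.zeros((0, gt.n_loci, 2), int)
        G = np.ones((K, A + 1, A + 1))
        any_locus = np.zeros(K, dtype=bool)
        for l in range(gt.n_loci):
            ladder = gt.ladder(l)
            nL = len(ladder)
            # transmission matrix: one row per adult + the OUT (frequency) row
            M = np.zeros((A + 1, nL))
            for a in range(A):
                pair = adult_rows[a, l]
                if np.all(pair == MISSING):
                    M[a] = freqs.freqs[l]
                else:
                    pos = np.searchsorted(ladder, pair)
                    M[a, pos[0]] += 0.5
                    M[a, pos[1]] += 0.5
            M[A] = freqs.freqs[l]
            for k, sid in enumerate(ds.seedlings["id"]):
                obs = gt.row(sid)[l]
                if np.all(obs == MISSING):
                    continue
                any_locus[k] = True
                W = obs_weight_matrix(obs, ladder, float(err.e1[l]), float(err.e2[l]))
                Mk = M
                if seedling_species is not None and seedling_species[k] in sp_freqs:
                    Mk = M.copy()
                    Mk[A] = sp_freqs[seedling_species[k]].freqs[l]
                G[k] *= Mk @ W @ Mk.T
        for k in np.where(~any_locus)[0]:
            warnings.warn(
                f"seedling {ds.seedlings['id'].iloc[k]} has no genotyped locus; "
                "its genotype term is 1 (no information)"
            )
        return G

    # -- kernel-weighted components -----------------------------------------

    def _components(self, u_s: float, u_p: float, fec: np.ndarray):
        """Memoized wrapper around :meth:`_compute_components`.

        Within one MCMC step the Gibbs sweep and the Metropolis current
        state evaluate the same (u_s, u_p, fecundities); caching the last
        result roughly halves the per-step cost.
        """
        key = (float(u_s), float(u_p), fec.tobytes())
        if getattr(self, "_comp_key", None) == key:
            return self._comp_val
        val = self._compute_components(u_s, u_p, fec)
        self._comp_key, self._comp_val = key, val
        return val

    def _compute_components(self, u_s: float, u_p: float, fec: np.ndarray):
        """All kernel/fecundity ingredients of the pair weights.

        Returns (seed_in, seed_out, pollen_in, pollen_out_in, om, oo):
        seed_in (A, K), seed_out (K,), pollen_in (A, A) with zero diagonal
        [mother, father], pollen_out_in (A,) for an in-plot mother with an
        OUT father, om (K, A) the out-mother/in-father coupling (seed and
        pollen integrated over exterior cells), oo (K,) the out/out term.
        """
        u_s = float(u_s)
        u_p = float(u_p)
        if u_s <= 0 or u_p <= 0:
            raise ValueError("dispersal parameters must be positive")
        g = self.grid
        cellw = g.mass * g.mean_fecundity  # expected seed output per cell
        seed_in = fec[:, None] * _kd(self.d_as, u_s)
        pollen_in = fec[None, :] * _kd(self.d_aa, u_p)
        np.fill_diagonal(pollen_in, 0.0)
        if g.n_cells:
            Ks_cs = _kd(self.d_cs, u_s)  # (C, K)
            Kp_ca = _kd(self.d_ca, u_p)  # (C, A)
            seed_out = cellw @ Ks_cs
            pollen_out_in = cellw @ Kp_ca
            # pollen reaching each exterior cell from the (unbounded) exterior:
            # complement of the in-plot kernel mass
            if len(self._int_pts):
                in_mass = _kd(self.d_ci, u_p) @ np.full(
                    len(self._int_pts), self._int_area
                )
            else:
                in_mass = np.zeros(g.n_cells)
            qp = g.density_m2 * g.mean_fecundity * np.clip(1.0 - in_mass, 0.0, None)
            seed_cells = cellw[:, None] * Ks_cs  # (C, K)
            om = seed_cells.T @ (Kp_ca * fec[None, :])  # (K, A)
            oo = seed_cells.T @ qp
        else:
            seed_out = np.zeros(self.n_seedlings)
            pollen_out_in = np.zeros(self.n_adults)
            om = np.zeros((self.n_seedlings, self.n_adults))
            oo = np.zeros(self.n_seedlings)
        return seed_in, seed_out, pollen_in, pollen_out_in, om, oo

    def pair_weights(self, u_s: float, u_p: float, fec: np.ndarray | None = None) -> np.ndarray:
        """Unnormalized pair-weight tensor W[k, mother, father].

        Index ``n_adults`` in either slot means OUT.  Entries with
        mother == father (both in-plot) are zero; under
        ``species_mode='separate'`` candidates of other species than the
        seedling's are excluded (weight zero) as well.
        """
        fec = self.fec_mean if fec is None else np.asarray(fec, float)
        seed_in, seed_out, pollen_in, pollen_out_in, om, oo = self._components(u_s, u_p, fec)
        A, K = self.n_adults, self.n_seedlings
        W = np.empty((K, A + 1, A + 1))
        W[:, :A, :A] = seed_in.T[:, :, None] * pollen_in[None, :, :]
        W[:, :A, A] = seed_in.T * pollen_out_in[None, :]
        W[:, A, :A] = om
        W[:, A, A] = oo
        W *= self.G
        idx = np.arange(A)
        W[:, idx, idx] = 0.0
        sp = self._species_candidates()
        if sp is not None and "species" in self.dataset.seedlings.columns:
            s_sp = self.dataset.seedlings["species"].to_numpy()
            for k in range(K):
                mask = np.concatenate([sp != s_sp[k], [False]])
                W[k, mask, :] = 0.0
                W[k, :, mask] = 0.0
        return W

    def pair_weight(self, k: int, mother, father, u_s: float, u_p: float, fec=None) -> float:
        """Single unnormalized pair weight; ``mother``/``father`` are adult
        indices or the string "OUT"."""
        m = self.OUT if mother == "OUT" else int(mother)
        f = self.OUT if father == "OUT" else int(father)
        return float(self.pair_weights(u_s, u_p, fec)[k, m, f])

    def pedigree_conditional(self, u_s: float, u_p: float, fec=None) -> np.ndarray:
        """Normalized conditional P[k, mother, father]; rows sum to 1."""
        W = self.pair_weights(u_s, u_p, fec)
        totals = W.reshape(self.n_seedlings, -1).sum(axis=1)
        bad = np.where(totals <= 0.0)[0]
        if len(bad):
            sid = self.dataset.seedlings["id"].iloc[bad[0]]
            raise ValueError(
                f"all parent-pair weights are zero for seedling {sid}; "
                "check genotyping-error rates and the exterior grid"
            )
        return W / totals[:, None, None]

    # -- MCMC updates --------------------------------------------------------

    def gibbs_update_pedigrees(
        self, u_s: float, u_p: float, fec: np.ndarray, rng
    ) -> PedigreeState:
        """Redraw every seedling's (mother, father) from its conditional.

        Samples the exact joint by factorizing it: the mother marginal
        sums the father axis out of the weight tensor without
        materializing it, then the father is drawn from its conditional
        given the sampled mother.  Equivalent to flattening the full
        (A+1) x (A+1) table but linear instead of quadratic in memory.
        """
        seed_in, seed_out, pollen_in, pollen_out_in, om, oo = self._components(u_s, u_p, fec)
        A, K = self.n_adults, self.n_seedlings
        # father-axis weight rows: in-plot fathers then the OUT column
        p_full = np.concatenate([pollen_in, pollen_out_in[:, None]], axis=1)  # (A, A+1)
        om_full = np.concatenate([om, oo[:, None]], axis=1)  # (K, A+1)
        marg = np.empty((K, A + 1))
        marg[:, :A] = seed_in.T * np.einsum("mf,kmf->km", p_full, self.G[:, :A, :], optimize=True)
        marg[:, A] = np.einsum("kf,kf->k", om_full, self.G[:, A, :], optimize=True)
        totals = marg.sum(axis=1)
        bad = np.where(totals <= 0.0)[0]
        if len(bad):
            sid = self.dataset.seedlings["id"].iloc[bad[0]]
            raise ValueError(
                f"all parent-pair weights are zero for seedling {sid}; "
                "check genotyping-error rates and the exterior grid"
            )
        cdf = np.cumsum(marg, axis=1)
        mothers = (cdf < (rng.random(K) * cdf[:, -1])[:, None]).sum(axis=1)
        rows = np.empty((K, A + 1))
        in_m = mothers < A
        rows[in_m] = p_full[mothers[in_m]]
        rows[~in_m] = om_full[~in_m]
        rows = rows * self.G[np.arange(K), mothers, :]
        fcdf = np.cumsum(rows, axis=1)
        fathers = (fcdf < (rng.random(K) * fcdf[:, -1])[:, None]).sum(axis=1)
        return PedigreeState(mothers, fathers, self.OUT)

    def loglik_dispersal(
        self, u_s: float, u_p: float, fec: np.ndarray, state: PedigreeState
    ) -> float:
        """Log of the kernel/fecundity factors of the current pedigree.

        The genotype term does not involve (u_s, u_p) and cancels in the
        Metropolis ratio, so it is omitted here.
        """
        seed_in, seed_out, pollen_in, pollen_out_in, om, oo = self._components(u_s, u_p, fec)
        m, f = state.mothers, state.fathers
        k_idx = np.arange(self.n_seedlings)
        ll = 0.0
        inin = (m != self.OUT) & (f != self.OUT)
        inout = (m != self.OUT) & (f == self.OUT)
        outin = (m == self.OUT) & (f != self.OUT)
        outout = (m == self.OUT) & (f == self.OUT)
        terms = np.empty(self.n_seedlings)
        terms[inin] = seed_in[m[inin], k_idx[inin]] * pollen_in[m[inin], f[inin]]
        terms[inout] = seed_in[m[inout], k_idx[inout]] * pollen_out_in[m[inout]]
        terms[outin] = om[k_idx[outin], f[outin]]
        terms[outout] = oo[outout]
        if np.any(terms <= 0.0):
            return -np.inf
        ll += float(np.sum(np.log(terms)))
        return ll

    def metropolis_update_dispersal(
        self,
        u_s: float,
        u_p: float,
        fec: np.ndarray,
        state: PedigreeState,
        rng,
        scales=(0.5, 0.5),
    ):
        """One random-walk update of (u_s, u_p) on the log scale.

        Proposals outside the prior truncation bounds are auto-rejected.
        Returns (u_s, u_p, accepted_s, accepted_p).
        """
        cur_ll = self.loglik_dispersal(u_s, u_p, fec, state)
        acc = [False, False]
        for which, (prior, scale) in enumerate(
            ((self.seed_prior, scales[0]), (self.pollen_prior, scales[1]))
        ):
            cur = u_s if which == 0 else u_p
            prop = cur * np.exp(scale * rng.standard_normal())
            if not (prior.lower <= prop <= prior.upper):
                continue
            prop_ll = (
                self.loglik_dispersal(prop, u_p, fec, state)
                if which == 0
                else self.loglik_dispersal(u_s, prop, fec, state)
            )
            # log-normal random walk: Jacobian term log(prop/cur)
            log_alpha = (
                prop_ll
                - cur_ll
                + prior.logpdf(prop)
                - prior.logpdf(cur)
                + np.log(prop / cur)
            )
            if np.log(rng.random()) < log_alpha:
                if which == 0:
                    u_s = prop
                else:
                    u_p = prop
                cur_ll = prop_ll
                acc[which] = True
        return u_s, u_p, acc[0], acc[1]

    def draw_fecundities(self, rng) -> np.ndarray:
        """Per-tree fecundity draws from zero-truncated normals.

        Trees with SD 0 return their mean exactly.
        """
        return draw_fecundities(self.fec_mean, self.fec_sd, rng)


def draw_fecundities(means, sds, rng) -> np.ndarray:
    """Independent zero-truncated normal draws, one per tree."""
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    if np.any(sds < 0):
        raise ValueError("fecundity SDs must be nonnegative")
    out = means.copy()
    pos = sds > 0
    if np.any(pos):
        a = (0.0 - means[pos]) / sds[pos]
        out[pos] = truncnorm.rvs(
            a, np.inf, loc=means[pos], scale=sds[pos], random_state=rng
        )
    return out


@dataclass
class PosteriorSamples:
    """Retained MCMC draws plus the full-length trace.

    ``us``/``up`` are the retained dispersal draws; ``mothers``/``fathers``
    (n_retained, n_seedlings) the retained pedigrees (value n_adults =
    OUT); ``fecundities`` the retained fecundity draws; ``trace`` a
    DataFrame over all steps with u_s, u_p and acceptance flags.
    """

    us: np.ndarray
    up: np.ndarray
    mothers: np.ndarray
    fathers: np.ndarray
    fecundities: np.ndarray
    trace: pd.DataFrame
    out_index: int
    config: McmcConfig
    acceptance: dict = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return len(self.us)


def run_mcmc(
    model_or_dataset,
    config: McmcConfig | None = None,
    seed: int | None = None,
    progress_every: int = 1000,
) -> PosteriorSamples:
    """Run the Gibbs-within-Metropolis sampler.

    Each sweep draws fecundities, redraws every pedigree slot from its
    exact conditional, then updates (u_s, u_p) by random-walk Metropolis
    on the log scale.  Proposal scales adapt toward a 0.2-0.5 acceptance
    rate during burn-in only.  The chain is reproducible bit-for-bit
    under a fixed seed.
    """
    if isinstance(model_or_dataset, ParentageModel):
        model = model_or_dataset
        if config is not None:
            model.config = config
    else:
        model = ParentageModel(model_or_dataset, config=config)
    cfg = model.config
    rng = np.random.default_rng(cfg.seed if seed is None else seed)

    u_s = float(np.clip(model.seed_prior.mean, model.seed_prior.lower, model.seed_prior.upper))
    u_p = float(
        np.clip(model.pollen_prior.mean, model.pollen_prior.lower, model.pollen_prior.upper)
    )
    scales = [cfg.prop_scale_s, cfg.prop_scale_p]
    fec = model.draw_fecundities(rng)
    has_seedlings = model.n_seedlings > 0
    state = (
        model.gibbs_update_pedigrees(u_s, u_p, fec, rng)
        if has_seedlings
        else PedigreeState(np.zeros(0, int), np.zeros(0, int), model.OUT)
    )

    n_ret = cfg.n_retained
    us = np.empty(n_ret)
    up = np.empty(n_ret)
    mothers = np.empty((n_ret, model.n_seedlings), dtype=np.int32)
    fathers = np.empty((n_ret, model.n_seedlings), dtype=np.int32)
    fecs = np.empty((n_ret, model.n_adults))
    trace = np.empty((cfg.n_steps, 4))
    acc_window = np.zeros(2)
    window = 0
    kept = 0
    for step in range(cfg.n_steps):
        fec = model.draw_fecundities(rng)
        if has_seedlings:
            state = model.gibbs_update_pedigrees(u_s, u_p, fec, rng)
        u_s, u_p, a_s, a_p = model.metropolis_update_dispersal(
            u_s, u_p, fec, state, rng, scales
        )
        acc_window += (a_s, a_p)
        window += 1
        if cfg.adapt and step < cfg.burn_in and window == 100:
            for j in range(2):
                rate = acc_window[j] / window
                scales[j] = float(np.clip(scales[j] * np.exp(rate - 0.3), 1e-3, 10.0))
            acc_window[:] = 0.0
            window = 0
        trace[step] = (u_s, u_p, a_s, a_p)
        if step >= cfg.burn_in and (step - cfg.burn_in) % cfg.thin == cfg.thin - 1:
            us[kept], up[kept] = u_s, u_p
            mothers[kept] = state.mothers
            fathers[kept] = state.fathers
            fecs[kept] = fec
            kept += 1
        if progress_every and (step + 1) % progress_every == 0:
            logger.info(
                "step %d/%d  u_s=%.1f  u_p=%.1f", step + 1, cfg.n_steps, u_s, u_p
            )
    trace_df = pd.DataFrame(trace, columns=["u_s", "u_p", "accept_s", "accept_p"])
    trace_df.insert(0, "step", np.arange(cfg.n_steps))
    post = trace_df.iloc[cfg.burn_in :]
    return PosteriorSamples(
        us[:kept],
        up[:kept],
        mothers[:kept],
        fathers[:kept],
        fecs[:kept],
        trace_df,
        model.OUT,
        cfg,
        acceptance={
            "u_s": float(post["accept_s"].mean()),
            "u_p": float(post["accept_p"].mean()),
        },
    )


def effective_sample_size(x: np.ndarray) -> float:
    """ESS by the initial-positive-sequence autocorrelation estimator."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for t in range(1, n):
        if acf[t] <= 0:
            break
        s += acf[t]
    return float(n / (1.0 + 2.0 * s))


def summarize_posterior(samples: PosteriorSamples, dataset: Dataset | None = None) -> dict:
    """Posterior summaries: dispersal table, per-seedling parentage, categories.

    Returns a dict with ``dispersal`` (mean/SD/95% CI and the implied mean
    dispersal distance for u_s and u_p), ``parentage`` (per-seedling modal
    pair and its posterior frequency), and ``categories`` (modal parentage
    category counts and percentages over the four in/out combinations).
    """
    if samples.n_retained < 2:
        raise ValueError("need at least two retained samples to summarize")
    rows = []
    for name, draws in (("u_s", samples.us), ("u_p", samples.up)):
        lo, hi = np.percentile(draws, [2.5, 97.5])
        rows.append(
            {
                "parameter": name,
                "posterior_mean": float(draws.mean()),
                "posterior_sd": float(draws.std(ddof=1)),
                "ci_2.5": float(lo),
                "ci_97.5": float(hi),
                "expected_distance_m": kernels.expected_distance(float(draws.mean())),
                "ess": effective_sample_size(draws),
            }
        )
    dispersal = pd.DataFrame(rows)

    n_ret, K = samples.mothers.shape
    OUT = samples.out_index
    adult_ids = (
        list(dataset.adults["id"]) if dataset is not None else [str(i) for i in range(OUT)]
    )
    seedling_ids = (
        list(dataset.seedlings["id"]) if dataset is not None else [str(k) for k in range(K)]
    )

    def _label(idx):
        return "OUT" if idx == OUT else adult_ids[idx]

    parent_rows = []
    modal_cats = []
    for k in range(K):
        pairs = samples.mothers[:, k].astype(np.int64) * (OUT + 1) + samples.fathers[:, k]
        vals, counts = np.unique(pairs, return_counts=True)
        best = vals[np.argmax(counts)]
        m, f = int(best // (OUT + 1)), int(best % (OUT + 1))
        cats = np.where(
            (samples.mothers[:, k] != OUT) & (samples.fathers[:, k] != OUT),
            0,
            np.where(
                samples.mothers[:, k] != OUT,
                1,
                np.where(samples.fathers[:, k] != OUT, 2, 3),
            ),
        )
        modal_cat = CATEGORIES[int(np.bincount(cats, minlength=4).argmax())]
        modal_cats.append(modal_cat)
        parent_rows.append(
            {
                "seedling_id": seedling_ids[k],
                "modal_mother": _label(m),
                "modal_father": _label(f),
                "modal_pair_freq": float(counts.max() / n_ret),
                "p_mother_in": float(np.mean(samples.mothers[:, k] != OUT)),
                "p_father_in": float(np.mean(samples.fathers[:, k] != OUT)),
                "modal_category": modal_cat,
            }
        )
    parentage = pd.DataFrame(parent_rows)
    cat_counts = pd.Series(modal_cats).value_counts().reindex(list(CATEGORIES), fill_value=0)
    categories = pd.DataFrame(
        {
            "category": cat_counts.index,
            "count": cat_counts.to_numpy(),
            "percent": 100.0 * cat_counts.to_numpy() / max(K, 1),
        }
    )
    return {"dispersal": dispersal, "parentage": parentage, "categories": categories}
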