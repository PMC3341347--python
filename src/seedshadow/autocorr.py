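"""Multilocus spatial genetic autocorrelation (the coefficient r).

Implements the Smouse & Peakall (1999) multiallelic, codominant
autocorrelation analysis as popularized by GenAlEx.  Each pair of diploid
genotypes at one locus gets a squared genetic distance equal to half the
squared Euclidean distance between their allele-count vectors (so AA-AA =
0, AA-AB = 1, AB-CD = 2, AA-BC = 3, AA-BB = 4); distances are summed over
loci, converted to a covariance matrix by Gower centering, and the
per-distance-class correlation is

    r(h) = sum over ordered pairs (i, j) in class h of c_ij
           / sum_i (number of class-h pairs involving i) * c_ii.

Significance is assessed by a permutation test (genotypes shuffled across
locations, giving an envelope around r = 0) and uncertainty by
bootstrapping pairs within each distance class.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable

__all__ = [
    "squared_distance_matrix",
    "autocorrelation_r",
    "CohortPartition",
    "partition_cohorts",
]


def _allele_counts(calls_l: np.ndarray, ladder: np.ndarray) -> np.ndarray:
    """(n, n_alleles) allele-count vectors for one locus; NaN rows = missing."""
    n = len(calls_l)
    out = np.zeros((n, len(ladder)))
    missing = (calls_l == MISSING).any(axis=1)
    for a in range(2):
        pos = np.searchsorted(ladder, calls_l[:, a])
        pos = np.clip(pos, 0, len(ladder) - 1)
        ok = ~missing & (ladder[pos] == calls_l[:, a])
        np.add.at(out, (np.where(ok)[0], pos[ok]), 1.0)
    out[missing] = np.nan
    return out


def squared_distance_matrix(table: GenotypeTable) -> np.ndarray:
    """Pairwise squared genetic distance, summed over loci.

    Per locus, d^2 = 0.5 * ||y_i - y_j||^2 on allele-count vectors; a
    locus missing in either member of a pair contributes nothing to that
    pair (pairwise deletion).
    """
    n = table.n_individuals
    D = np.zeros((n, n))
    for l in range(table.n_loci):
        y = _allele_counts(table.calls[:, l, :], table.ladder(l))
        sq = np.nansum(y * y, axis=1)
        with np.errstate(invalid="ignore"):
            cross = np.where(np.isnan(y), 0.0, y) @ np.where(np.isnan(y), 0.0, y).T
            d2 = 0.5 * (sq[:, None] + sq[None, :] - 2.0 * cross)
        pair_missing = np.isnan(y).any(axis=1)
        d2[pair_missing, :] = 0.0
        d2[:, pair_missing] = 0.0
        D += d2
    np.fill_diagonal(D, 0.0)
    return D


def _gower_center(D: np.ndarray) -> np.ndarray:
    rm = D.mean(axis=1, keepdims=True)
    return -0.5 * (D - rm - rm.T + D.mean())


def _r_from_pairs(C: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> float:
    num = 2.0 * C[ii, jj].sum()
    den = (C[ii, ii] + C[jj, jj]).sum()
    return float(num / den) if den > 0 else np.nan


def autocorrelation_r(
    table: GenotypeTable,
    xy,
    class_edges=None,
    n_permutations: int = 999,
    n_bootstrap: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-distance-class genetic correlation r with CIs and a null envelope.

    Parameters
    ----------
    table : GenotypeTable for the cohort (order matches ``xy``).
    xy : (n, 2) coordinates in meters.
    class_edges : distance-class edges in m; default 0-100 m in 10-m bins.
    n_permutations : permutations of genotypes across locations for the
        95% envelope around r = 0.
    n_bootstrap : bootstrap resamples of pairs within each class for the
        95% CI of r.

    Returns a DataFrame with columns class_lo, class_hi, n_pairs, r,
    ci_low, ci_high, perm_low, perm_high.  Classes with < 2 individuals
    (no pairs) get NaN and are flagged with n_pairs = 0.
    """
    xy = np.asarray(xy, float)
    n = table.n_individuals
    if len(xy) != n:
        raise ValueError("coordinate rows must match genotype rows")
    if n < 2 or table.n_loci < 1:
        raise ValueError("need at least two individuals and one locus")
    edges = (
        np.arange(0.0, 110.0, 10.0) if class_edges is None else np.asarray(class_edges, float)
    )
    rng = np.random.default_rng(seed)
    C = _gower_center(squared_distance_matrix(table))
    iu, ju = np.triu_indices(n, k=1)
    d = np.sqrt(((xy[iu] - xy[ju]) ** 2).sum(axis=1))

    rows = []
    for c in range(len(edges) - 1):
        sel = (d >= edges[c]) & (d < edges[c + 1])
        ii, jj = iu[sel], ju[sel]
        row = {
            "class_lo": edges[c],
            "class_hi": edges[c + 1],
            "n_pairs": int(sel.sum()),
            "r": np.nan,
            "ci_low": np.nan,
            "ci_high": np.nan,
            "perm_low": np.nan,
            "perm_high": np.nan,
        }
        if sel.sum() == 0:
            warnings.warn(
                f"distance class [{edges[c]:.0f}, {edges[c + 1]:.0f}) m has no pairs"
            )
            rows.append(row)
            continue
        row["r"] = _r_from_pairs(C, ii, jj)
        if n_bootstrap:
            boots = np.empty(n_bootstrap)
            for b in range(n_bootstrap):
                pick = rng.integers(0, len(ii), len(ii))
                boots[b] = _r_from_pairs(C, ii[pick], jj[pick])
            row["ci_low"], row["ci_high"] = np.nanpercentile(boots, [2.5, 97.5])
        if n_permutations:
            perms = np.empty(n_permutations)
            for p in range(n_permutations):
                perm = rng.permutation(n)
                perms[p] = _r_from_pairs(C, perm[ii], perm[jj])
            row["perm_low"], row["perm_high"] = np.nanpercentile(perms, [2.5, 97.5])
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class CohortPartition:
    """Adults split at the median DBH, plus seedlings as a third cohort.

    ``large`` holds adult ids with DBH strictly above the median,
    ``small`` the rest (ties go to the small cohort), ``seedlings`` the
    seedling ids, and ``median_dbh`` the split point actually used.
    """

    large: list
    small: list
    seedlings: list
    median_dbh: float
    excluded: list


def partition_cohorts(
    adults: pd.DataFrame, seedlings: pd.DataFrame, median_dbh: float | None = None
) -> CohortPartition:
    """Split adults into large/small cohorts at the (or a supplied) median DBH.

    Adults without a DBH are excluded with a warning.  DBH exactly at the
    median is assigned to the small cohort.
    """
    if "dbh_cm" not in adults.columns:
        raise ValueError("adults table lacks a dbh_cm column")
    dbh = adults["dbh_cm"].to_numpy(float)
    ok = np.isfinite(dbh)
    excluded = list(adults.loc[~ok, "id"])
    if excluded:
        warnings.warn(f"{len(excluded)} adult(s) excluded for missing DBH")
    med = float(np.median(dbh[ok])) if median_dbh is None else float(median_dbh)
    ids = adults.loc[ok, "id"].to_numpy()
    vals = dbh[ok]
    return CohortPartition(
        large=list(ids[vals > med]),
        small=list(ids[vals <= med]),
        seedlings=list(seedlings["id"]),
        median_dbh=med,
        excluded=excluded,
    )
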