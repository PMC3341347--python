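"""Microsatellite genotypes, allele frequencies, and the genotyping-error model.

Genotypes are diploid allele-size calls (bp) at a small number of
microsatellite loci.  Two error channels corrupt observed calls:

* **allelic dropout** (rate ``e2`` per locus): one allele of a heterozygote
  fails to amplify, so the genotype is recorded as a homozygote for one of
  its two alleles (equal split between the two);
* **mistyping** (rate ``e1`` per locus): an allele is recorded as one of
  adjacent fragment length (stutter), i.e. shifted by one motif unit up or
  down the locus's size ladder (equal split; edge alleles shift inward).

The channels compose dropout-then-mistyping, and mistyping acts
independently on each recorded allele.  ``observation_model`` gives
P(observed | true); summed over all observable genotypes it is exactly 1.

``offspring_genotype_prob`` combines Mendelian transmission from two
(possibly unknown) parents with this observation model: an unknown parent
transmits an allele drawn from population allele frequencies
(Hardy-Weinberg), so the both-unknown case reduces to an HWE genotype
probability convolved with error.  Loci are treated as independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MISSING",
    "GenotypeTable",
    "ErrorRates",
    "AlleleFrequencies",
    "allele_frequencies",
    "mistype_matrix",
    "obs_weight_matrix",
    "observation_model",
    "transmission_vector",
    "offspring_genotype_prob",
    "estimate_error_rates",
]

#: Sentinel allele size for a missing call (GenAlEx convention).
MISSING = 0


@dataclass
class GenotypeTable:
    """Diploid allele-size calls for a set of individuals.

    Parameters
    ----------
    ids : list of str
        Individual identifiers, unique.
    loci : list of str
        Locus names.
    calls : ndarray of int, shape (n_individuals, n_loci, 2)
        Allele sizes in bp; 0 marks a missing call.  A half-called locus
        (one allele 0) is treated as locus-missing.
    motif : ndarray of int, shape (n_loci,)
        Repeat-motif length per locus (bp); adjacent ladder rungs differ
        by one motif.
    """

    ids: list
    loci: list
    calls: np.ndarray
    motif: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int64)
        self.motif = np.asarray(self.motif, dtype=np.int64)
        n, L = len(self.ids), len(self.loci)
        if self.calls.shape != (n, L, 2):
            raise ValueError(f"calls must have shape ({n}, {L}, 2), got {self.calls.shape}")
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids in genotype table")
        if np.any(self.motif <= 0):
            raise ValueError("motif lengths must be positive")
        if np.any(self.calls < 0):
            raise ValueError("allele sizes must be nonnegative (0 = missing)")
        # half-calls are conservative locus-missing
        half = (self.calls == MISSING).any(axis=2)
        self.calls[half] = MISSING
        for l in range(L):
            sizes = self.calls[:, l, :][self.calls[:, l, :] != MISSING]
            if sizes.size and np.any((sizes - sizes.min()) % self.motif[l] != 0):
                raise ValueError(
                    f"locus {self.loci[l]}: allele sizes are not on a {self.motif[l]}-bp ladder"
                )
        self._index = {sid: i for i, sid in enumerate(self.ids)}

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_loci(self) -> int:
        return len(self.loci)

    def row(self, sample_id) -> np.ndarray:
        return self.calls[self._index[sample_id]]

    def missing_mask(self) -> np.ndarray:
        """Boolean (n, L): True where the locus call is missing."""
        return (self.calls == MISSING).all(axis=2)

    def ladder(self, locus: int) -> np.ndarray:
        """All allele sizes from min to max observed, in motif steps."""
        sizes = self.calls[:, locus, :][self.calls[:, locus, :] != MISSING]
        if sizes.size == 0:
            raise ValueError(f"locus {self.loci[locus]} has no non-missing calls")
        return np.arange(sizes.min(), sizes.max() + 1, self.motif[locus], dtype=np.int64)

    def subset(self, ids) -> "GenotypeTable":
        idx = [self._index[i] for i in ids]
        return GenotypeTable(list(ids), list(self.loci), self.calls[idx].copy(), self.motif.copy())


@dataclass
class ErrorRates:
    """Per-locus mistyping (e1) and allelic-dropout (e2) probabilities."""

    e1: np.ndarray
    e2: np.ndarray

    def __post_init__(self):
        self.e1 = np.atleast_1d(np.asarray(self.e1, dtype=float))
        self.e2 = np.atleast_1d(np.asarray(self.e2, dtype=float))
        if self.e1.shape != self.e2.shape:
            raise ValueError("e1 and e2 must have one entry per locus each")
        for name, arr in (("e1", self.e1), ("e2", self.e2)):
            if np.any(arr < 0) or np.any(arr >= 1):
                raise ValueError(f"{name} rates must lie in [0, 1)")

    @property
    def n_loci(self) -> int:
        return len(self.e1)


@dataclass
class AlleleFrequencies:
    """Per-locus empirical allele frequencies on each locus's size ladder.

    ``ladders[l]`` is the size ladder (ndarray of bp) and ``freqs[l]`` the
    matching frequency vector (sums to 1; zero at unobserved rungs).
    """

    ladders: list = field(default_factory=list)
    freqs: list = field(default_factory=list)

    def __post_init__(self):
        for l, f in enumerate(self.freqs):
            if abs(float(np.sum(f)) - 1.0) > 1e-9:
                raise ValueError(f"locus {l}: frequencies sum to {np.sum(f)}, not 1")

    def frequency(self, locus: int, size: int) -> float:
        ladder = self.ladders[locus]
        pos = np.searchsorted(ladder, size)
        if pos >= len(ladder) or ladder[pos] != size:
            return 0.0
        return float(self.freqs[locus][pos])


def allele_frequencies(table: GenotypeTable, ids=None) -> AlleleFrequencies:
    """Empirical per-locus allele frequencies (missing calls excluded).

    ``ids`` optionally restricts the count to a subset (e.g. a species);
    the ladder is still built from the full table so matrices computed
    against it stay aligned.
    """
    sub = table.calls if ids is None else table.calls[[table._index[i] for i in ids]]
    ladders, freqs = [], []
    for l in range(table.n_loci):
        ladder = table.ladder(l)
        sizes = sub[:, l, :][sub[:, l, :] != MISSING]
        if sizes.size == 0:
            raise ValueError(f"locus {table.loci[l]} has no non-missing calls in the subset")
        counts = np.zeros(len(ladder))
        pos = np.searchsorted(ladder, sizes)
        np.add.at(counts, pos, 1.0)
        ladders.append(ladder)
        freqs.append(counts / counts.sum())
    return AlleleFrequencies(ladders, freqs)


def mistype_matrix(n_rungs: int, e1: float) -> np.ndarray:
    """Single-allele mistyping kernel on a ladder of ``n_rungs`` sizes.

    m[i, j] = P(record rung j | true rung i): stay with prob 1-e1, shift to
    each adjacent rung with prob e1/2.  Edge rungs shift inward only (the
    whole e1 mass goes to the single neighbor), keeping rows normalized.
    """
    if n_rungs == 1:
        return np.ones((1, 1))
    m = np.zeros((n_rungs, n_rungs))
    idx = np.arange(n_rungs)
    m[idx, idx] = 1.0 - e1
    m[idx[1:-1], idx[1:-1] - 1] = e1 / 2.0
    m[idx[1:-1], idx[1:-1] + 1] = e1 / 2.0
    m[0, 1] = e1
    m[-1, -2] = e1
    return m


def obs_weight_matrix(obs_pair: np.ndarray, ladder: np.ndarray, e1: float, e2: float) -> np.ndarray:
    """W[a, b] = P(observed genotype | true genotype {ladder[a], ladder[b]}).

    The workhorse of both the observation model and the pedigree
    likelihood: with the observed (unordered) genotype fixed, W gives the
    observation probability for every possible true genotype, indexed by
    ladder rungs of the two true alleles.  Symmetric in (a, b).
    """
    m = mistype_matrix(len(ladder), e1)
    ci = int(np.searchsorted(ladder, obs_pair[0]))
    di = int(np.searchsorted(ladder, obs_pair[1]))
    for pos, size in ((ci, obs_pair[0]), (di, obs_pair[1])):
        if pos >= len(ladder) or ladder[pos] != size:
            raise ValueError(f"observed allele {size} is outside the locus size ladder")
    if ci == di:
        pp = np.multiply.outer(m[:, ci], m[:, ci])
    else:
        pp = np.multiply.outer(m[:, ci], m[:, di]) + np.multiply.outer(m[:, di], m[:, ci])
    # dropout mixes the heterozygote {a,b} to {a,a} or {b,b} with e2/2 each
    diag = np.diag(pp)
    w = (1.0 - e2) * pp + (e2 / 2.0) * (diag[:, None] + diag[None, :])
    np.fill_diagonal(w, diag)  # true homozygotes cannot drop out
    return w


def observation_model(true_pair, obs_pair, err: ErrorRates, locus: int, ladder) -> float:
    """P(observed genotype | true genotype) at one locus.

    Both genotypes are unordered allele-size pairs on the locus's ladder.
    With e1 = e2 = 0 this is the identity; for any rates the probabilities
    over all observable genotypes sum to 1.
    """
    ladder = np.asarray(ladder)
    true_pair = np.asarray(true_pair)
    for size in true_pair:
        pos = np.searchsorted(ladder, size)
        if pos >= len(ladder) or ladder[pos] != size:
            raise ValueError(f"true allele {size} is outside the locus size ladder")
    w = obs_weight_matrix(np.asarray(obs_pair), ladder, float(err.e1[locus]), float(err.e2[locus]))
    a = int(np.searchsorted(ladder, true_pair[0]))
    b = int(np.searchsorted(ladder, true_pair[1]))
    return float(w[a, b])


def transmission_vector(parent_pair, ladder, freqs=None) -> np.ndarray:
    """P(transmitted allele = each ladder rung) for one parent at one locus.

    A known parent transmits each of its two alleles with probability 1/2
    (its observed genotype is taken at face value for transmission; error
    enters through the offspring's observation model).  An unknown parent
    — ``parent_pair is None`` or a missing call — transmits from population
    allele frequencies (``freqs``, aligned to the ladder).
    """
    ladder = np.asarray(ladder)
    if parent_pair is None or np.all(np.asarray(parent_pair) == MISSING):
        if freqs is None:
            raise ValueError("allele frequencies required for an unknown parent")
        return np.asarray(freqs, dtype=float)
    vec = np.zeros(len(ladder))
    for size in np.asarray(parent_pair):
        pos = np.searchsorted(ladder, size)
        if pos >= len(ladder) or ladder[pos] != size:
            raise ValueError(f"parent allele {size} is outside the locus size ladder")
        vec[pos] += 0.5
    return vec


def offspring_genotype_prob(
    g_mother,
    g_father,
    g_obs,
    err: ErrorRates,
    freqs: AlleleFrequencies,
    mother_known: bool = True,
    father_known: bool = True,
) -> float:
    """P(offspring's observed multilocus genotype | parents).

    Product over non-missing offspring loci of

        sum_true  P_Mendel(true | parents) * P_obs(observed | true),

    where Mendelian transmission draws one allele from each parent's
    transmission vector.  ``g_mother``/``g_father`` are (L, 2) call arrays
    (ignored for a parent flagged unknown, which transmits from ``freqs``).
    If every offspring locus is missing the probability is 1 (no
    information) and a warning is issued.
    """
    g_obs = np.asarray(g_obs)
    n_loci = g_obs.shape[0]
    used = 0
    log_p = 0.0
    for l in range(n_loci):
        obs = g_obs[l]
        if np.all(obs == MISSING):
            continue
        used += 1
        ladder = freqs.ladders[l]
        fvec = freqs.freqs[l]
        mv = transmission_vector(
            np.asarray(g_mother)[l] if (mother_known and g_mother is not None) else None,
            ladder,
            fvec,
        )
        fv = transmission_vector(
            np.asarray(g_father)[l] if (father_known and g_father is not None) else None,
            ladder,
            fvec,
        )
        w = obs_weight_matrix(obs, ladder, float(err.e1[l]), float(err.e2[l]))
        p = float(mv @ w @ fv)
        if p <= 0.0:
            return 0.0
        log_p += np.log(p)
    if used == 0:
        warnings.warn("offspring genotype entirely missing: probability defined as 1")
        return 1.0
    return float(np.exp(log_p))


def estimate_error_rates(
    reference: GenotypeTable,
    retyped: GenotypeTable,
    default: tuple = (0.05, 0.05),
) -> tuple:
    """Estimate per-locus (e1, e2) from re-genotyped individuals.

    ``reference`` holds the accepted (consensus) calls and ``retyped`` the
    independent re-typing of the same individuals.  Counting definitions:

    * e2 = (reference heterozygotes re-typed as a homozygote for one of
      their own alleles) / (reference heterozygote comparisons);
    * e1 = (alleles shifted by exactly one motif between typings) /
      (allele comparisons, 2 per individual-locus pair).

    Estimates are clipped to [0, 0.5).  A locus with no usable repeats is
    left at ``default`` and reported in the returned ``flagged`` list.

    Returns
    -------
    (ErrorRates, flagged) where flagged is a list of locus names that had
    no repeat data.
    """
    if reference.loci != retyped.loci:
        raise ValueError("reference and retyped tables must cover the same loci")
    common = [i for i in reference.ids if i in retyped._index]
    if not common:
        raise ValueError("no shared individuals between reference and retyped tables")
    L = reference.n_loci
    e1 = np.full(L, default[0], dtype=float)
    e2 = np.full(L, default[1], dtype=float)
    flagged = []
    for l in range(L):
        motif = int(reference.motif[l])
        het_comp = drop = allele_comp = adj = 0
        for sid in common:
            ref = np.sort(reference.row(sid)[l])
            new = np.sort(retyped.row(sid)[l])
            if np.any(ref == MISSING) or np.any(new == MISSING):
                continue
            allele_comp += 2
            adj += int(np.sum(np.abs(ref - new) == motif))
            if ref[0] != ref[1]:
                het_comp += 1
                if new[0] == new[1] and new[0] in ref:
                    drop += 1
        if allele_comp == 0:
            flagged.append(reference.loci[l])
            continue
        e1[l] = min(adj / allele_comp, 0.5 - 1e-12)
        if het_comp > 0:
            e2[l] = min(drop / het_comp, 0.5 - 1e-12)
        else:
            flagged.append(reference.loci[l])
    return ErrorRates(e1, e2), flagged
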