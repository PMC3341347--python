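"""Parentage model: pair weights, exterior grid, Gibbs/Metropolis updates.

The key correctness checks are independent-oracle based: pair weights are
recomputed by hand from kernel x fecundity x Mendelian factors, and the
pedigree conditional is compared against exhaustive enumeration over all
(mother, father) combinations on the 4-adult/2-seedling fixture.
"""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import Point, Polygon

from seedshadow import kernels
from seedshadow.genotypes import ErrorRates, GenotypeTable, allele_frequencies, offspring_genotype_prob
from seedshadow.parentage import (
    DEFAULT_POLLEN_PRIOR,
    DEFAULT_SEED_PRIOR,
    Dataset,
    McmcConfig,
    ParentageModel,
    PedigreeState,
    PriorSpec,
    build_exterior_grid,
    draw_fecundities,
    run_mcmc,
    summarize_posterior,
)

SMALL_CFG = McmcConfig(
    n_steps=60, burn_in=20, thin=2, grid_spacing=25.0, grid_cutoff=100.0
)


def enumerate_conditional(model, dataset, u_s, u_p, fec):
    """Brute-force pedigree conditional via direct per-pair products.

    Recomputes every pair weight from first principles (kernel density,
    fecundity, exterior-cell sums, offspring genotype probability) without
    touching the model's vectorized weight code.
    """
    ax = dataset.adults[["x", "y"]].to_numpy(float)
    sx = dataset.seedlings[["x", "y"]].to_numpy(float)
    A, K = len(ax), len(sx)
    gt = dataset.genotypes
    err = dataset.error_rates
    freqs = allele_frequencies(gt)
    grid = model.grid
    cellw = grid.mass * grid.mean_fecundity
    int_pts, int_area = model._int_pts, model._int_area
    fec = np.asarray(fec, float)

    def gprob(k, m, f):
        gm = gt.row(dataset.adults["id"].iloc[m]) if m is not None else None
        gf = gt.row(dataset.adults["id"].iloc[f]) if f is not None else None
        return offspring_genotype_prob(
            gm, gf, gt.row(dataset.seedlings["id"].iloc[k]), err, freqs,
            mother_known=m is not None, father_known=f is not None,
        )

    P = np.zeros((K, A + 1, A + 1))
    for k in range(K):
        for m in range(A + 1):
            for f in range(A + 1):
                if m < A and f < A and m == f:
                    continue
                if m < A:
                    seed = fec[m] * kernels.kernel_density(
                        np.hypot(*(sx[k] - ax[m])), u_s
                    )
                    if f < A:
                        pollen = fec[f] * kernels.kernel_density(
                            np.hypot(*(ax[m] - ax[f])), u_p
                        )
                    else:
                        d = np.hypot(grid.xy[:, 0] - ax[m, 0], grid.xy[:, 1] - ax[m, 1])
                        pollen = float(cellw @ kernels.kernel_density(d, u_p))
                    w = seed * pollen
                else:
                    d_ck = np.hypot(grid.xy[:, 0] - sx[k, 0], grid.xy[:, 1] - sx[k, 1])
                    seed_cells = cellw * kernels.kernel_density(d_ck, u_s)
                    if f < A:
                        d_cf = np.hypot(grid.xy[:, 0] - ax[f, 0], grid.xy[:, 1] - ax[f, 1])
                        w = float(
                            seed_cells @ (fec[f] * kernels.kernel_density(d_cf, u_p))
                        )
                    else:
                        in_mass = np.array(
                            [
                                int_area
                                * kernels.kernel_density(
                                    np.hypot(int_pts[:, 0] - cx, int_pts[:, 1] - cy), u_p
                                ).sum()
                                for cx, cy in grid.xy
                            ]
                        )
                        qp = grid.density_m2 * grid.mean_fecundity * (1.0 - in_mass)
                        w = float(seed_cells @ qp)
                P[k, m, f] = w * gprob(
                    k, m if m < A else None, f if f < A else None
                )
        P[k] /= P[k].sum()
    return P


class TestPriorSpec:
    def test_truncation_bounds_from_distances(self):
        p = DEFAULT_SEED_PRIOR
        assert p.lower == pytest.approx(kernels.param_from_distance(5.0))
        assert p.upper == pytest.approx(kernels.param_from_distance(157.0))

    def test_logpdf_matches_scipy(self):
        from scipy.stats import truncnorm

        p = DEFAULT_POLLEN_PRIOR
        a = (p.lower - p.mean) / p.sd
        b = (p.upper - p.mean) / p.sd
        ref = truncnorm(a, b, loc=p.mean, scale=p.sd)
        for u in (50.0, 2000.0, 12000.0):
            assert p.logpdf(u) == pytest.approx(float(ref.logpdf(u)), abs=1e-10)
        assert p.logpdf(p.upper * 2) == -np.inf

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(100.0, -1.0, 5.0, 100.0)
        with pytest.raises(ValueError):
            PriorSpec(100.0, 10.0, 100.0, 5.0)


class TestExteriorGrid:
    def test_total_mass_matches_annulus_area(self, square_100m):
        g = build_exterior_grid(square_100m, 9.8, 900.0, cutoff=300.0, spacing=10.0)
        annulus_ha = ((100 + 600) ** 2 - 100**2) / 1e4  # bounding square minus plot
        # cells are restricted to within `cutoff` of the boundary, which
        # rounds the corners: mass is slightly below the bounding estimate
        assert 0.8 * 9.8 * annulus_ha < g.total_mass <= 9.8 * annulus_ha
        assert np.all(g.mass > 0)

    def test_zero_density_empty_weights(self, square_100m):
        g = build_exterior_grid(square_100m, 0.0, 900.0, cutoff=100.0, spacing=20.0)
        assert g.total_mass == 0.0

    def test_cells_strictly_outside_polygon(self, square_100m):
        g = build_exterior_grid(square_100m, 10.0, 900.0, cutoff=80.0, spacing=15.0)
        for x, y in g.xy:
            assert not square_100m.contains(Point(x, y))

    def test_short_cutoff_warns(self, square_100m):
        with pytest.warns(UserWarning, match="truncated"):
            build_exterior_grid(
                square_100m, 10.0, 900.0, cutoff=50.0, spacing=20.0,
                expected_seed_distance=44.0,
            )

    def test_out_of_plot_seed_mass_larger_at_edge(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        u_s = 800.0
        cellw = model.grid.mass * model.grid.mean_fecundity
        center = np.array([50.0, 50.0])
        edge = np.array([5.0, 50.0])
        def mass(pt):
            d = np.hypot(model.grid.xy[:, 0] - pt[0], model.grid.xy[:, 1] - pt[1])
            return float(cellw @ kernels.kernel_density(d, u_s))
        assert mass(edge) > mass(center)


class TestPairWeights:
    def test_doubling_fecundity_doubles_in_mother_weight(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        fec = toy_dataset.adults["fecundity_mean"].to_numpy(float)
        w1 = model.pair_weights(300.0, 2000.0, fec)
        fec2 = fec.copy()
        fec2[0] *= 2
        w2 = model.pair_weights(300.0, 2000.0, fec2)
        assert w2[0, 0, 1] == pytest.approx(2 * w1[0, 0, 1])

    def test_selfing_excluded(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        W = model.pair_weights(300.0, 2000.0)
        for m in range(model.n_adults):
            assert np.all(W[:, m, m] == 0.0)

    def test_in_in_weight_matches_hand_product(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        u_s, u_p = 400.0, 3000.0
        fec = toy_dataset.adults["fecundity_mean"].to_numpy(float)
        W = model.pair_weights(u_s, u_p, fec)
        freqs = allele_frequencies(toy_dataset.genotypes)
        k, m, f = 0, 0, 1
        d_mk = np.hypot(35.0 - 20.0, 40.0 - 30.0)
        d_fm = np.hypot(20.0 - 80.0, 30.0 - 30.0)
        g = offspring_genotype_prob(
            toy_dataset.genotypes.row("A0"),
            toy_dataset.genotypes.row("A1"),
            toy_dataset.genotypes.row("S0"),
            toy_dataset.error_rates,
            freqs,
        )
        want = (
            fec[m] * kernels.kernel_density(d_mk, u_s)
            * fec[f] * kernels.kernel_density(d_fm, u_p)
            * g
        )
        assert W[k, m, f] == pytest.approx(want, rel=1e-12)

    def test_conditional_rows_sum_to_one(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        P = model.pedigree_conditional(300.0, 2000.0)
        np.testing.assert_allclose(P.reshape(2, -1).sum(axis=1), 1.0, atol=1e-12)

    def test_conditional_matches_enumeration(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        fec = toy_dataset.adults["fecundity_mean"].to_numpy(float)
        got = model.pedigree_conditional(500.0, 4000.0, fec)
        want = enumerate_conditional(model, toy_dataset, 500.0, 4000.0, fec)
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_single_compatible_pair_gets_probability_one(self, square_100m):
        # two adults whose genotypes force them to be the parents; no
        # exterior (zero-mass grid via a huge empty cutoff trick: density 0)
        adults = pd.DataFrame(
            {
                "id": ["M", "F"],
                "x": [40.0, 60.0],
                "y": [50.0, 50.0],
                "species": ["Q", "Q"],
                "fecundity_mean": [100.0, 100.0],
                "fecundity_sd": [0.0, 0.0],
            }
        )
        seedlings = pd.DataFrame({"id": ["S"], "x": [50.0], "y": [50.0]})
        calls = np.array([[[100, 100]], [[102, 102]], [[100, 102]]])
        gt = GenotypeTable(["M", "F", "S"], ["L1"], calls, np.array([2]))
        ds = Dataset(adults, seedlings, gt, square_100m, ErrorRates([0.0], [0.0]))
        model = ParentageModel(ds, config=SMALL_CFG)
        model.grid.mass[:] = 0.0  # cutoff 0: no exterior mass
        P = model.pedigree_conditional(300.0, 2000.0)
        # both orderings of the pair are compatible; together they carry all mass
        assert P[0, 0, 1] + P[0, 1, 0] == pytest.approx(1.0)

    def test_all_zero_weights_name_the_seedling(self, square_100m):
        adults = pd.DataFrame(
            {
                "id": ["M", "F"],
                "x": [40.0, 60.0],
                "y": [50.0, 50.0],
                "species": ["Q", "Q"],
                "fecundity_mean": [100.0, 100.0],
                "fecundity_sd": [0.0, 0.0],
            }
        )
        seedlings = pd.DataFrame({"id": ["S"], "x": [50.0], "y": [50.0]})
        # seedling carries an allele no parent (nor HWE pool) can deliver
        # at e = 0: alleles 104/106 vs adults 100/102
        calls = np.array([[[100, 100]], [[100, 100]], [[104, 106]]])
        gt = GenotypeTable(["M", "F", "S"], ["L1"], calls, np.array([2]))
        ds = Dataset(adults, seedlings, gt, square_100m, ErrorRates([0.0], [0.0]))
        model = ParentageModel(ds, config=SMALL_CFG)
        model.grid.mass[:] = 0.0
        with pytest.raises(ValueError, match="S"):
            model.pedigree_conditional(300.0, 2000.0)


class TestGibbs:
    def test_empirical_frequencies_match_conditional(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        u_s, u_p = 500.0, 4000.0
        fec = toy_dataset.adults["fecundity_mean"].to_numpy(float)
        P = model.pedigree_conditional(u_s, u_p, fec)
        rng = np.random.default_rng(11)
        n = 20_000
        counts = np.zeros_like(P)
        for _ in range(n):
            st = model.gibbs_update_pedigrees(u_s, u_p, fec, rng)
            counts[np.arange(2), st.mothers, st.fathers] += 1
        freq = counts / n
        se = np.sqrt(P * (1 - P) / n)
        assert np.all(np.abs(freq - P) <= 3 * se + 5e-4)

    def test_mother_never_equals_father(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        rng = np.random.default_rng(3)
        fec = toy_dataset.adults["fecundity_mean"].to_numpy(float)
        for _ in range(200):
            st = model.gibbs_update_pedigrees(400.0, 3000.0, fec, rng)
            in_both = (st.mothers != model.OUT) & (st.fathers != model.OUT)
            assert not np.any(st.mothers[in_both] == st.fathers[in_both])


class TestMetropolisAndFecundity:
    def test_chain_respects_truncation(self, toy_dataset):
        cfg = McmcConfig(n_steps=400, burn_in=100, thin=2, grid_spacing=25.0,
                         grid_cutoff=100.0)
        s = run_mcmc(ParentageModel(toy_dataset, config=cfg), seed=9, progress_every=0)
        assert np.all(s.trace["u_s"] >= DEFAULT_SEED_PRIOR.lower - 1e-9)
        assert np.all(s.trace["u_s"] <= DEFAULT_SEED_PRIOR.upper + 1e-9)
        assert np.all(s.trace["u_p"] >= DEFAULT_POLLEN_PRIOR.lower - 1e-9)
        assert np.all(s.trace["u_p"] <= DEFAULT_POLLEN_PRIOR.upper + 1e-9)

    def test_fecundity_draws_truncated_normal(self, rng):
        means = np.array([948.0, 500.0, 0.0])
        sds = np.array([500.0, 0.0, 0.0])
        draws = np.stack([draw_fecundities(means, sds, rng) for _ in range(20_000)])
        assert np.all(draws >= 0)
        np.testing.assert_allclose(draws[:, 1], 500.0)
        from scipy.stats import truncnorm

        a = (0 - 948.0) / 500.0
        want = truncnorm.mean(a, np.inf, loc=948.0, scale=500.0)
        se = draws[:, 0].std() / np.sqrt(len(draws))
        assert abs(draws[:, 0].mean() - want) < 4 * se

    def test_negative_sd_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_fecundities([100.0], [-1.0], rng)


class TestRunAndSummary:
    def test_retained_count_follows_schedule(self, toy_dataset):
        cfg = McmcConfig(n_steps=200, burn_in=80, thin=6, grid_spacing=25.0,
                         grid_cutoff=100.0)
        s = run_mcmc(ParentageModel(toy_dataset, config=cfg), seed=1, progress_every=0)
        assert s.n_retained == (200 - 80) // 6

    def test_fixed_seed_reproduces_trace(self, toy_dataset):
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        a = run_mcmc(model, seed=5, progress_every=0)
        b = run_mcmc(model, seed=5, progress_every=0)
        pd.testing.assert_frame_equal(a.trace, b.trace)
        np.testing.assert_array_equal(a.mothers, b.mothers)
        np.testing.assert_array_equal(a.fathers, b.fathers)

    def test_summary_structure(self, toy_dataset):
        cfg = McmcConfig(n_steps=300, burn_in=100, thin=2, grid_spacing=25.0,
                         grid_cutoff=100.0)
        s = run_mcmc(ParentageModel(toy_dataset, config=cfg), seed=2, progress_every=0)
        summ = summarize_posterior(s, toy_dataset)
        disp = summ["dispersal"].set_index("parameter")
        assert disp.loc["u_s", "expected_distance_m"] == pytest.approx(
            kernels.expected_distance(disp.loc["u_s", "posterior_mean"])
        )
        assert summ["categories"]["count"].sum() == len(toy_dataset.seedlings)
        assert len(summ["parentage"]) == len(toy_dataset.seedlings)
        assert (summ["parentage"]["modal_pair_freq"] > 0).all()

    def test_pedigree_state_rejects_selfing(self):
        with pytest.raises(ValueError):
            PedigreeState(np.array([1]), np.array([1]), out_index=5)

    def test_species_mode_shifts_mass_toward_out(self, toy_dataset):
        """Restricting candidates to the seedling's species can only
        remove in-plot weight, so the OUT share weakly increases."""
        import copy

        ds = copy.deepcopy(toy_dataset)
        ds.adults["species"] = ["QR", "QV", "QR", "QV"]
        ds.seedlings["species"] = ["QR", "QR"]
        pooled = ParentageModel(ds, config=SMALL_CFG)
        sep_cfg = McmcConfig(n_steps=60, burn_in=20, thin=2, grid_spacing=25.0,
                             grid_cutoff=100.0, species_mode="separate")
        separate = ParentageModel(ds, config=sep_cfg)
        for model_pair in ((pooled, separate),):
            P_pool = model_pair[0].pedigree_conditional(500.0, 4000.0)
            P_sep = model_pair[1].pedigree_conditional(500.0, 4000.0)
        out = pooled.OUT
        for k in range(2):
            out_pool = P_pool[k, out, :].sum() + P_pool[k, :, out].sum() - P_pool[k, out, out]
            out_sep = P_sep[k, out, :].sum() + P_sep[k, :, out].sum() - P_sep[k, out, out]
            assert out_sep >= out_pool - 1e-12

    def test_out_share_increases_toward_edge(self, toy_dataset):
        """Moving a seedling toward the plot edge raises its OUT-mother mass."""
        model = ParentageModel(toy_dataset, config=SMALL_CFG)
        u_s = 800.0
        cellw = model.grid.mass * model.grid.mean_fecundity
        xs = np.linspace(50.0, 2.0, 8)
        masses = []
        for x in xs:
            d = np.hypot(model.grid.xy[:, 0] - x, model.grid.xy[:, 1] - 50.0)
            masses.append(float(cellw @ kernels.kernel_density(d, u_s)))
        assert np.all(np.diff(masses) > 0)
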