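"""Expected spectra, likelihood, the constant-gBGC fit and summaries."""

import numpy as np
import pytest
from scipy import stats
from scipy.special import gammaln

from beegc import gbgc, simulate
from beegc.gbgc import (
    BinSpec,
    ClassSFS,
    GbgcFit,
    b_from_B,
    binned_fits,
    build_class_sfs,
    class_frequency_summaries,
    equilibrium_gc,
    estimate_lambda,
    expected_class_spectrum,
    expected_observed_spectra,
    fit_M1star,
    folded_spectrum_test,
    loglik,
    r_from_rho,
)
from beegc.io import PolarizedRow
from beegc.variants import harmonic_number
from conftest import make_site


class TestExpectedSpectrum:
    def test_neutral_limit_proportional_to_1_over_i(self):
        g = expected_class_spectrum(0.0, 60)
        i = np.arange(1, 60)
        assert np.max(np.abs(g * i - 1.0)) < 1e-8
        assert g[0] / g[1] == pytest.approx(2.0, abs=1e-8)

    def test_mean_frequency_increases_with_b(self):
        means = []
        for B in (-5.0, 0.0, 5.0):
            g = expected_class_spectrum(B, 20)
            i = np.arange(1, 20)
            means.append(np.sum(i * g) / np.sum(g))
        assert means[0] < means[1] < means[2]

    def test_monotone_over_b_grid(self):
        i = np.arange(1, 30)
        prev = -np.inf
        for B in np.arange(-10.0, 10.5, 1.0):
            g = expected_class_spectrum(B, 30)
            assert (g > 0).all()
            mean = np.sum(i * g) / np.sum(g)
            assert mean > prev
            prev = mean

    def test_matches_dense_trapezoid_oracle(self):
        n, B = 10, 2.0
        x = np.linspace(1e-9, 1 - 1e-9, 1_000_001)
        phi = (1 - np.exp(-B * (1 - x))) / ((1 - np.exp(-B)) * x * (1 - x))
        g = expected_class_spectrum(B, n)
        for i in range(1, n):
            oracle = np.trapezoid(stats.binom.pmf(i, n, x) * phi, x)
            assert g[i - 1] == pytest.approx(oracle, abs=1e-7)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            expected_class_spectrum(0.0, 1)
        with pytest.raises(ValueError):
            expected_class_spectrum(np.inf, 10)


def default_params(n, **kw):
    base = dict(B=2.0, theta_ws=100.0, theta_sw=300.0, theta_n=150.0)
    base.update(kw)
    return GbgcFit(**base)


class TestExpectedObserved:
    def test_no_error_reduces_to_theta_g(self):
        n = 10
        p = default_params(n)
        e = expected_observed_spectra(p, n)
        assert np.allclose(e["WS"], 100.0 * expected_class_spectrum(2.0, n))
        assert np.allclose(e["SW"], 300.0 * expected_class_spectrum(-2.0, n))
        assert np.allclose(e["N"], 150.0 * expected_class_spectrum(0.0, n))

    def test_total_invariant_under_error_at_b0(self):
        n = 12
        tot = []
        for e_ws, e_sw in ((0.0, 0.0), (0.2, 0.1), (0.4, 0.3)):
            p = default_params(n, B=0.0, e_ws=e_ws, e_sw=e_sw)
            e = expected_observed_spectra(p, n)
            tot.append(e["WS"].sum() + e["SW"].sum())
        assert np.allclose(tot, tot[0])

    def test_hand_expanded_mixture(self):
        n = 4
        p = default_params(n, e_ws=0.1)
        e = expected_observed_spectra(p, n)
        g_b = expected_class_spectrum(2.0, n)
        g_mb = expected_class_spectrum(-2.0, n)
        for i in (1, 2, 3):
            ws = 0.9 * 100.0 * g_b[i - 1]  # no SW error feeding in
            sw = 1.0 * 300.0 * g_mb[i - 1] + 0.1 * 100.0 * g_b[n - i - 1]
            assert e["WS"][i - 1] == pytest.approx(ws, abs=1e-12)
            assert e["SW"][i - 1] == pytest.approx(sw, abs=1e-12)

    def test_out_of_bounds_rejected(self):
        with pytest.raises(ValueError):
            expected_observed_spectra(default_params(6, e_ws=0.6), 6)
        with pytest.raises(ValueError):
            expected_observed_spectra(default_params(6, theta_ws=-1.0), 6)


class TestLoglik:
    def make_data(self, n, params, exact=True, seed=0):
        e = expected_observed_spectra(params, n)
        rng = np.random.default_rng(seed)
        draw = (lambda v: v) if exact else rng.poisson
        return ClassSFS(
            n=n,
            counts_ws=draw(e["WS"]),
            counts_sw=draw(e["SW"]),
            counts_n=draw(e["N"]),
        )

    def test_maximal_at_truth_on_grid(self):
        n = 8
        p = default_params(n)
        data = self.make_data(n, p)
        ll_true = loglik(p, data)
        for B in (-2.0, 0.0, 1.0, 3.0, 5.0):
            if B == p.B:
                continue
            assert loglik(default_params(n, B=B), data) < ll_true

    def test_doubling_closed_form(self):
        n = 6
        p = default_params(n)
        data = self.make_data(n, p, exact=False, seed=1)
        double = GbgcFit(
            B=p.B, theta_ws=200.0, theta_sw=600.0, theta_n=300.0
        )
        data2 = ClassSFS(
            n=n,
            counts_ws=2 * data.counts_ws,
            counts_sw=2 * data.counts_sw,
            counts_n=2 * data.counts_n,
        )
        e = expected_observed_spectra(p, n)
        delta = 0.0
        for key, c in (("WS", data.counts_ws), ("SW", data.counts_sw),
                       ("N", data.counts_n)):
            mu = e[key]
            delta += np.sum(
                c * np.log(mu) + 2 * c * np.log(2) - mu
                - gammaln(2 * c + 1) + gammaln(c + 1)
            )
        assert loglik(double, data2) - loglik(p, data) == pytest.approx(delta)

    def test_empty_data(self):
        n = 5
        p = default_params(n)
        data = ClassSFS(
            n=n, counts_ws=np.zeros(4), counts_sw=np.zeros(4), counts_n=np.zeros(4)
        )
        e = expected_observed_spectra(p, n)
        assert loglik(p, data) == pytest.approx(-sum(v.sum() for v in e.values()))

    def test_zero_expectation_with_counts_is_minus_inf(self):
        n = 5
        p = default_params(n, e_ws=0.0)
        data = self.make_data(n, p)
        p_bad = default_params(n, r=np.array([1.0, 0.0, 0.0, 0.0]))
        assert loglik(p_bad, data) == -np.inf


class TestFit:
    def test_noise_free_self_consistency(self):
        n = 20
        truth = GbgcFit(
            B=3.0, theta_ws=500.0, theta_sw=1500.0, theta_n=800.0,
            e_ws=0.1, e_sw=0.05, e_n=0.02,
        )
        e = expected_observed_spectra(truth, n)
        data = ClassSFS(
            n=n, counts_ws=e["WS"], counts_sw=e["SW"], counts_n=e["N"]
        )
        fit = fit_M1star(data, seed=0, n_starts=4)
        assert fit.converged
        assert fit.B == pytest.approx(3.0, rel=1e-3)
        assert fit.theta_ws == pytest.approx(500.0, rel=1e-2)
        assert fit.e_ws == pytest.approx(0.1, abs=1e-3)

    def test_neutral_data_gives_small_b(self):
        sfs = simulate.simulate_class_sfs(
            B=0.0, n=60, theta_ws=3000.0, lam=12.0, seed=2
        )
        fit = fit_M1star(sfs, seed=0, n_starts=4)
        assert abs(fit.B) < 0.1

    def test_minimum_count_guard(self):
        tiny = ClassSFS(
            n=5, counts_ws=np.ones(4), counts_sw=np.ones(4), counts_n=np.ones(4)
        )
        with pytest.raises(ValueError):
            fit_M1star(tiny)


class TestLambdaAndScalings:
    def test_lambda_symmetric(self):
        assert estimate_lambda(10.0, 10.0, 0.5) == pytest.approx(1.0)

    def test_lambda_hand_value(self):
        assert estimate_lambda(1.0, 2.0, 0.34) == pytest.approx(2 * 0.66 / 0.34)

    def test_lambda_boundary_rejected(self):
        with pytest.raises(ValueError):
            estimate_lambda(1.0, 2.0, 0.0)

    def test_equilibrium_gc_limits(self):
        assert equilibrium_gc(0.0, 3.0) == pytest.approx(0.25)
        assert equilibrium_gc(200.0, 3.0) == pytest.approx(1.0)
        assert equilibrium_gc(5.71, 11.69) == pytest.approx(0.96, abs=0.005)

    def test_b_from_B_ploidy(self):
        assert b_from_B(0.38, 1e4, "diploid") == pytest.approx(9.5e-6)
        assert b_from_B(5.71, 5e5, "haplodiploid") == pytest.approx(3.8e-6, rel=0.01)

    def test_r_from_rho(self):
        assert r_from_rho(390.0, 5e5, "haplodiploid") == pytest.approx(26.0)
        # diploid scaling is 4 Ne r
        assert r_from_rho(390.0, 5e5, "diploid") == pytest.approx(26.0 * 3 / 4)

    def test_invalid_ne(self):
        with pytest.raises(ValueError):
            b_from_B(1.0, 0.0)


def expand_sfs_to_rows(sfs, start_pos=1):
    """Materialize a ClassSFS as per-SNP rows (for builders that take SNPs)."""
    rows = []
    pos = start_pos
    for cls, counts in (("WS", sfs.counts_ws), ("SW", sfs.counts_sw),
                        ("WW", sfs.counts_n)):
        for i, c in enumerate(counts, start=1):
            for _ in range(int(c)):
                rows.append(
                    PolarizedRow(
                        chrom="c", pos=pos, ancestral="A", derived="G",
                        k=i, n=sfs.n, p_ancestral=1.0, mclass=cls, titv="Ti",
                        context=frozenset(),
                    )
                )
                pos += 1
    return rows


class TestBuildClassSfs:
    def test_counts_land_in_cells(self):
        rows = [
            PolarizedRow("c", p, "A", "G", 1, 10, 1.0, "WS", "Ti", frozenset())
            for p in range(3)
        ]
        sfs = build_class_sfs(rows)
        assert sfs.counts_ws[0] == 3
        assert sfs.counts_ws.sum() == 3 and sfs.total == 3

    def test_totals_conserved_and_stratified(self, small_polarized):
        snps = small_polarized.resolved
        sfs = build_class_sfs(snps)
        assert sfs.total == len(snps)
        strata = build_class_sfs(snps, stratifier=lambda s: s.titv)
        assert sum(s.total for s in strata.values()) == len(snps)

    def test_mixed_n_rejected(self):
        rows = [
            PolarizedRow("c", 1, "A", "G", 1, 10, 1.0, "WS", "Ti", frozenset()),
            PolarizedRow("c", 2, "A", "G", 1, 12, 1.0, "WS", "Ti", frozenset()),
        ]
        with pytest.raises(ValueError):
            build_class_sfs(rows)


class TestBinnedFits:
    def test_single_bin_equals_global_fit(self):
        sfs = simulate.simulate_class_sfs(
            B=3.0, n=12, theta_ws=800.0, lam=10.0, seed=3
        )
        rows = expand_sfs_to_rows(sfs)
        values = np.full(len(rows), 0.5)
        spec = BinSpec(variable="local_GC", edges=(0.0, 1.0))
        fits = binned_fits(rows, values, spec, seed=0, n_starts=3)
        direct = fit_M1star(build_class_sfs(rows), seed=0, n_starts=3)
        assert fits[0].B == pytest.approx(direct.B, abs=1e-6)

    def test_empty_bin_absent_run_continues(self):
        sfs = simulate.simulate_class_sfs(
            B=1.0, n=10, theta_ws=500.0, lam=10.0, seed=4
        )
        rows = expand_sfs_to_rows(sfs)
        values = np.full(len(rows), 0.1)
        spec = BinSpec(variable="local_GC", edges=(0.0, 0.5, 1.0))
        fits = binned_fits(rows, values, spec, seed=0, n_starts=3)
        assert fits[1] is None and fits[0] is not None

    def test_edges_must_ascend(self):
        with pytest.raises(ValueError):
            BinSpec(variable="rho", edges=(1.0, 1.0))


class TestFoldedSpectrumTest:
    def test_null_table(self):
        sites = []
        pos = 1
        for x, y in (("A", "G"), ("G", "A")):
            for k in (2, 20):  # MAF 2/60 < 0.25, 20/60 >= 0.25
                for _ in range(50):
                    sites.append(make_site(k=k, x=x, y=y, pos=pos))
                    pos += 1
        res = folded_spectrum_test(sites)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p == pytest.approx(1.0)

    def test_against_hypergeometric_oracle(self):
        # W: 900 low / 100 mid; S: 700 low / 300 mid
        sites = []
        pos = 1
        for count, k, x, y in (
            (900, 2, "G", "A"),   # minor allele A (weak), low MAF
            (100, 20, "G", "A"),  # minor weak, mid MAF
            (700, 2, "A", "G"),   # minor strong, low
            (300, 20, "A", "G"),  # minor strong, mid
        ):
            for _ in range(count):
                sites.append(make_site(k=k, x=x, y=y, pos=pos))
                pos += 1
        res = folded_spectrum_test(sites)
        assert res.odds_ratio == pytest.approx((900 * 300) / (100 * 700), rel=1e-10)
        # independent exact-test oracle: hypergeometric tail enumeration
        oracle = stats.hypergeom(2000, 1000, 1600)
        p_one = oracle.sf(900 - 1)
        assert res.p < 1e-6
        assert res.p <= 2 * p_one + 1e-12
        assert res.p == pytest.approx(stats.fisher_exact(res.table)[1])

    def test_folding_invariant_under_relabelling(self):
        spec = [("A", "G", 3), ("A", "G", 25), ("G", "A", 5), ("G", "A", 20)]
        sites = [
            make_site(k=k, x=x, y=y, pos=i + 1) for i, (x, y, k) in enumerate(spec)
        ]
        # swapping which allele is 'reference' must not change folded output
        swapped = [
            make_site(k=60 - k, x=y, y=x, pos=i + 1)
            for i, (x, y, k) in enumerate(spec)
        ]
        a = folded_spectrum_test(sites)
        b = folded_spectrum_test(swapped)
        assert np.array_equal(a.spectrum_w, b.spectrum_w)
        assert np.array_equal(a.spectrum_s, b.spectrum_s)
        assert np.array_equal(a.table, b.table)

    def test_same_class_sites_excluded(self):
        sites = [
            make_site(k=5, x="A", y="T", pos=1),  # WW: excluded
            make_site(k=30, x="A", y="G", pos=2),  # exact tie: excluded
            make_site(k=5, x="A", y="G", pos=3),  # S minor, low
            make_site(k=40, x="A", y="G", pos=4),  # W minor, mid
            make_site(k=5, x="G", y="A", pos=5),  # W minor, low
            make_site(k=40, x="G", y="A", pos=6),  # S minor, mid
        ]
        res = folded_spectrum_test(sites)
        assert res.n_excluded == 2
        assert res.table.sum() == 4


class TestClassFrequencySummaries:
    def test_neutral_mean_frequency(self):
        n = 60
        sfs = simulate.simulate_class_sfs(
            B=0.0, n=n, theta_ws=2000.0, lam=1.0, gc=0.5, seed=5
        )
        rows = expand_sfs_to_rows(sfs)
        out = class_frequency_summaries(rows, seed=0)
        cells = out["cells"].set_index("cell")
        expected = (n - 1) / (n * harmonic_number(n - 1))
        ws = cells.loc["WS:Ti"]
        sw = cells.loc["SW:Ti"]
        assert ws["mean_f_d"] == pytest.approx(expected, rel=0.05)
        # B=0: WS and SW mean frequencies equal within CIs
        assert ws["ci_lo"] < sw["mean_f_d"] < ws["ci_hi"]

    def test_transition_specific_bias_pattern(self):
        # B=6 on transitions only: WS/SW ratio elevated for Ti, ~1 for Tv
        rng_seed = 6
        rows = []
        pos = 1
        for titv, B in (("Ti", 6.0), ("Tv", 0.0)):
            sfs = simulate.simulate_class_sfs(
                B=B, n=30, theta_ws=2000.0, lam=2.0, gc=0.5, seed=rng_seed
            )
            for cls, counts in (("WS", sfs.counts_ws), ("SW", sfs.counts_sw)):
                for i, c in enumerate(counts, start=1):
                    for _ in range(int(c)):
                        rows.append(
                            PolarizedRow(
                                "c", pos, "A", "G", i, 30, 1.0, cls, titv,
                                frozenset(),
                            )
                        )
                        pos += 1
        out = class_frequency_summaries(rows, seed=0)
        ratios = out["ratios"].set_index("ratio")["value"]
        assert ratios["WS/SW mean f_d (Ti)"] > 2.0
        assert ratios["WS/SW mean f_d (Tv)"] == pytest.approx(1.0, abs=0.15)

    def test_single_class_leaves_other_cells_absent(self):
        rows = [
            PolarizedRow("c", p, "A", "G", 3, 10, 1.0, "WS", "Ti", frozenset())
            for p in range(30)
        ]
        out = class_frequency_summaries(rows, seed=0)
        assert set(out["cells"]["cell"]) == {"WS:Ti"}
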