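"""Class-specific site frequency spectra and gBGC estimation.

GC-biased gene conversion (gBGC) acts like directional selection of
population-scaled strength B on weak (A/T) vs strong (G/C) alleles.  Under
a constant-B model the density of derived-allele population frequencies at
segregating sites is the sojourn-time density

    phi(x; B) = (1 - exp(-B (1 - x))) / ((1 - exp(-B)) x (1 - x)),

with the neutral limit phi(x; 0) = 1/x.  Binomial sampling of n haplotypes
gives the expected derived allele frequency spectrum G_i(B), i = 1..n-1.

The fitted model describes observed WS (weak-to-strong), SW and neutral
(WW+SS pooled) spectra as independent Poisson counts with expectations
built from per-class mutation-influx scales theta, a shared multiplicative
distortion vector r_i (r_1 = 1) absorbing demography and ascertainment,
and polarization-error probabilities e that convert WS <-> SW with
mirrored frequency:

    E_i[WS] = r_i ((1-e_WS) theta_WS G_i(B)   + e_SW theta_SW G_{n-i}(-B))
    E_i[SW] = r_i ((1-e_SW) theta_SW G_i(-B)  + e_WS theta_WS G_{n-i}(B))
    E_i[N]  = r_i theta_N ((1-e_N) G_i(0) + e_N G_{n-i}(0))

Maximum likelihood uses the closed-form profile of the distortion vector
(given all other parameters the optimal r_i for i >= 2 equals the observed
over modelled total at frequency i), reducing the numerical search to the
seven structural parameters (B, three log-theta, three logit-e).

The AT mutational bias is lambda = (theta_SW / gc) / (theta_WS / (1-gc)),
i.e. the per-site S->W over W->S mutation rate given the base composition,
and the equilibrium GC content under mutation-conversion balance is
GC* = 1 / (1 + lambda exp(-B)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit, gammaln, logit

from beegc.popgen import bootstrap_compare

_N_QUAD = 256
_NEUTRAL_EPS = 1e-6


@dataclass
class ClassSFS:
    """Derived-allele-count spectra for the WS, SW and neutral classes.

    ``counts_*[i-1]`` is the number of SNPs with derived count i, for
    i = 1..n-1; the neutral class pools WW and SS mutations.
    """

    n: int
    counts_ws: np.ndarray
    counts_sw: np.ndarray
    counts_n: np.ndarray
    label: str | None = None

    def __post_init__(self) -> None:
        for name in ("counts_ws", "counts_sw", "counts_n"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.n - 1,):
                raise ValueError(f"{name} must have length n-1 = {self.n - 1}")
            if (arr < 0).any():
                raise ValueError(f"{name} must be non-negative")
            setattr(self, name, arr)

    @property
    def total(self) -> float:
        return float(self.counts_ws.sum() + self.counts_sw.sum() + self.counts_n.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "i": np.arange(1, self.n),
                "count_ws": self.counts_ws,
                "count_sw": self.counts_sw,
                "count_n": self.counts_n,
            }
        )


@dataclass
class GbgcFit:
    """Parameters of the constant-gBGC spectrum model (fitted or fixed)."""

    B: float
    theta_ws: float
    theta_sw: float
    theta_n: float
    e_ws: float = 0.0
    e_sw: float = 0.0
    e_n: float = 0.0
    r: np.ndarray | None = None  # distortion vector, r[0] == 1
    lam: float | None = None
    loglik: float = np.nan
    converged: bool = False
    n_starts_used: int = 0
    ci_b: tuple[float, float] | None = None


def build_class_sfs(
    snps: Iterable,
    stratifier: Callable | None = None,
) -> ClassSFS | dict:
    """Tally polarized SNPs into class spectra, optionally per stratum.

    ``snps`` need ``k``, ``mclass`` and a haploid sample size (``site.n``
    or ``n``); all SNPs must share n.  ``stratifier(snp)`` returns a
    stratum label; with a stratifier a dict of label -> ClassSFS is
    returned.
    """
    strata: dict = {}
    n_seen: set[int] = set()
    for snp in snps:
        n = snp.site.n if hasattr(snp, "site") else snp.n
        n_seen.add(n)
        if len(n_seen) > 1:
            raise ValueError(f"mixed haploid sample sizes: {sorted(n_seen)}")
        label = stratifier(snp) if stratifier is not None else None
        if label not in strata:
            strata[label] = {
                "WS": np.zeros(n - 1),
                "SW": np.zeros(n - 1),
                "N": np.zeros(n - 1),
            }
        cls = snp.mclass if snp.mclass in ("WS", "SW") else "N"
        strata[label][cls][snp.k - 1] += 1
    if not strata:
        raise ValueError("no SNPs provided")
    n = n_seen.pop()
    out = {
        label: ClassSFS(
            n=n,
            counts_ws=d["WS"],
            counts_sw=d["SW"],
            counts_n=d["N"],
            label=None if label is None else str(label),
        )
        for label, d in strata.items()
    }
    if stratifier is None:
        return out[None]
    return out


@lru_cache(maxsize=None)
def _quadrature(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gauss-Legendre nodes/weights on (0,1) and the binomial kernel matrix
    P[i-1, q] = C(n,i) x_q^i (1-x_q)^(n-i)."""
    z, w = np.polynomial.legendre.leggauss(_N_QUAD)
    x = 0.5 * (z + 1.0)
    w = 0.5 * w
    i = np.arange(1, n)
    log_binom = gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
    log_pmf = (
        log_binom[:, None]
        + i[:, None] * np.log(x)[None, :]
        + (n - i)[:, None] * np.log1p(-x)[None, :]
    )
    return x, w, np.exp(log_pmf)


def sojourn_density(x: np.ndarray, B: float) -> np.ndarray:
    """Sojourn-time density phi(x; B) of a derived allele under bias B."""
    x = np.asarray(x, dtype=float)
    if abs(B) < _NEUTRAL_EPS:
        return 1.0 / x
    return -np.expm1(-B * (1.0 - x)) / (-np.expm1(-B) * x * (1.0 - x))


def expected_class_spectrum(B: float, n: int) -> np.ndarray:
    """Expected (unnormalized) spectrum G_i(B), i = 1..n-1, for sample size n.

    G_i(B) = integral_0^1 C(n,i) x^i (1-x)^(n-i) phi(x; B) dx, evaluated
    with 256-node Gauss-Legendre quadrature; the analytic neutral limit
    G_i(0) = 1/i is used for |B| below 1e-6.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not np.isfinite(B):
        raise ValueError("B must be finite")
    if abs(B) < _NEUTRAL_EPS:
        return 1.0 / np.arange(1, n, dtype=float)
    x, w, pmf = _quadrature(n)
    return pmf @ (w * sojourn_density(x, B))


def expected_observed_spectra(params: GbgcFit, n: int) -> dict[str, np.ndarray]:
    """Expected observed counts per class under distortion and
    polarization error (see module docstring for the formulas)."""
    for name in ("theta_ws", "theta_sw", "theta_n"):
        if getattr(params, name) <= 0:
            raise ValueError(f"{name} must be positive")
    for name in ("e_ws", "e_sw", "e_n"):
        if not 0 <= getattr(params, name) <= 0.5:
            raise ValueError(f"{name} must be in [0, 0.5]")
    r = np.ones(n - 1) if params.r is None else np.asarray(params.r, dtype=float)
    if r.shape != (n - 1,):
        raise ValueError("r must have length n-1")
    if (r < 0).any() or abs(r[0] - 1.0) > 1e-12:
        raise ValueError("distortion must be non-negative with r_1 == 1")
    g_b = expected_class_spectrum(params.B, n)
    g_mb = expected_class_spectrum(-params.B, n)
    g_0 = expected_class_spectrum(0.0, n)
    e_ws, e_sw, e_n = params.e_ws, params.e_sw, params.e_n
    t_ws, t_sw, t_n = params.theta_ws, params.theta_sw, params.theta_n
    return {
        "WS": r * ((1 - e_ws) * t_ws * g_b + e_sw * t_sw * g_mb[::-1]),
        "SW": r * ((1 - e_sw) * t_sw * g_mb + e_ws * t_ws * g_b[::-1]),
        "N": r * t_n * ((1 - e_n) * g_0 + e_n * g_0[::-1]),
    }


def loglik(params: GbgcFit, data: ClassSFS) -> float:
    """Independent-Poisson log-likelihood of class spectra under ``params``."""
    expected = expected_observed_spectra(params, data.n)
    total = 0.0
    for key, counts in (
        ("WS", data.counts_ws),
        ("SW", data.counts_sw),
        ("N", data.counts_n),
    ):
        e = expected[key]
        if ((e == 0) & (counts > 0)).any():
            return -np.inf
        pos = e > 0
        total += float(
            np.sum(counts[pos] * np.log(e[pos]) - e[pos] - gammaln(counts[pos] + 1))
            - np.sum(e[~pos])
        )
    return total


# ---------------------------------------------------------------------------
# maximum-likelihood fit


def _unit_spectra(B: float, e: np.ndarray, theta: np.ndarray, n: int):
    """Per-class expected spectra with r == 1."""
    g_b = expected_class_spectrum(B, n)
    g_mb = expected_class_spectrum(-B, n)
    g_0 = expected_class_spectrum(0.0, n)
    e_ws, e_sw, e_n = e
    t_ws, t_sw, t_n = theta
    m_ws = (1 - e_ws) * t_ws * g_b + e_sw * t_sw * g_mb[::-1]
    m_sw = (1 - e_sw) * t_sw * g_mb + e_ws * t_ws * g_b[::-1]
    m_n = t_n * ((1 - e_n) * g_0 + e_n * g_0[::-1])
    return m_ws, m_sw, m_n


def _profiled_negloglik(psi: np.ndarray, data: ClassSFS) -> float:
    """Negative log-likelihood at psi = (B, log theta x3, logit(2e) x3),
    with the distortion vector profiled out in closed form."""
    B = psi[0]
    theta = np.exp(psi[1:4])
    e = 0.5 * expit(psi[4:7])
    m_ws, m_sw, m_n = _unit_spectra(B, e, theta, data.n)
    m_tot = m_ws + m_sw + m_n
    c_tot = data.counts_ws + data.counts_sw + data.counts_n
    r = np.ones_like(m_tot)
    r[1:] = c_tot[1:] / m_tot[1:]
    ll = 0.0
    for m, c in ((m_ws, data.counts_ws), (m_sw, data.counts_sw), (m_n, data.counts_n)):
        mu = r * m
        pos = mu > 0
        if ((~pos) & (c > 0)).any():
            return np.inf
        ll += np.sum(c[pos] * np.log(mu[pos]) - mu[pos]) - np.sum(mu[~pos])
    return -float(ll)


_PSI_BOUNDS_E = (-14.0, 14.0)  # logit scale; e in ~[4e-7, 0.4999996]


def _fit_psi(
    data: ClassSFS,
    psi0: np.ndarray,
    b_bounds: tuple[float, float],
    fixed_b: float | None = None,
) -> optimize.OptimizeResult:
    bounds = [b_bounds] + [(-40.0, 40.0)] * 3 + [_PSI_BOUNDS_E] * 3
    if fixed_b is not None:
        bounds[0] = (fixed_b, fixed_b)
        psi0 = psi0.copy()
        psi0[0] = fixed_b
    return optimize.minimize(
        _profiled_negloglik,
        psi0,
        args=(data,),
        method="L-BFGS-B",
        bounds=bounds,
        options={"maxiter": 500},
    )


def _psi_to_fit(psi: np.ndarray, data: ClassSFS) -> GbgcFit:
    B = float(psi[0])
    theta = np.exp(psi[1:4])
    e = 0.5 * expit(psi[4:7])
    m_ws, m_sw, m_n = _unit_spectra(B, e, theta, data.n)
    m_tot = m_ws + m_sw + m_n
    c_tot = data.counts_ws + data.counts_sw + data.counts_n
    r = np.ones_like(m_tot)
    r[1:] = c_tot[1:] / m_tot[1:]
    fit = GbgcFit(
        B=B,
        theta_ws=float(theta[0]),
        theta_sw=float(theta[1]),
        theta_n=float(theta[2]),
        e_ws=float(e[0]),
        e_sw=float(e[1]),
        e_n=float(e[2]),
        r=r,
    )
    fit.loglik = loglik(fit, data)
    return fit


def _initial_psi(data: ClassSFS, rng: np.random.Generator, jitter: bool) -> np.ndarray:
    g0_sum = expected_class_spectrum(0.0, data.n).sum()
    totals = np.array(
        [data.counts_ws.sum(), data.counts_sw.sum(), data.counts_n.sum()]
    )
    log_theta = np.log(np.maximum(totals, 1.0) / g0_sum)
    if not jitter:
        return np.concatenate(([1.0], log_theta, logit(2 * np.full(3, 0.05))))
    B0 = rng.uniform(-5.0, 15.0)
    log_theta = log_theta + rng.normal(0.0, 0.5, size=3)
    e0 = rng.uniform(0.01, 0.4, size=3)
    return np.concatenate(([B0], log_theta, logit(2 * e0)))


def fit_M1star(
    data: ClassSFS,
    n_starts: int = 8,
    seed: int = 0,
    b_bounds: tuple[float, float] = (-50.0, 50.0),
    min_total: float = 200.0,
    profile_ci: bool = False,
    gc: float | None = None,
) -> GbgcFit:
    """Maximum-likelihood fit of the constant-gBGC spectrum model.

    Maximizes the Poisson likelihood over B, the three theta scales, the
    three polarization-error probabilities (in [0, 0.5]) and the profiled
    distortion vector, using bounded quasi-Newton optimization on log- and
    logit-transformed parameters from ``n_starts`` seeded starts (one
    deterministic moment-based start plus random restarts).  Ties in
    log-likelihood are broken toward smaller ``|B|``.  With ``gc`` the AT
    mutational bias lambda is filled in; with ``profile_ci`` a 95%
    profile-likelihood confidence interval for B is attached.
    """
    if data.total < min_total:
        raise ValueError(
            f"total SNP count {data.total:.0f} below minimum {min_total:.0f}"
        )
    rng = np.random.default_rng(seed)
    best: optimize.OptimizeResult | None = None
    any_converged = False
    for start in range(n_starts):
        psi0 = _initial_psi(data, rng, jitter=start > 0)
        res = _fit_psi(data, psi0, b_bounds)
        any_converged = any_converged or bool(res.success)
        if (
            best is None
            or res.fun < best.fun - 1e-9
            or (abs(res.fun - best.fun) <= 1e-9 and abs(res.x[0]) < abs(best.x[0]))
        ):
            best = res
    fit = _psi_to_fit(best.x, data)
    fit.converged = any_converged
    fit.n_starts_used = n_starts
    if gc is not None:
        fit.lam = estimate_lambda(fit.theta_ws, fit.theta_sw, gc)
    if profile_ci:
        fit.ci_b = profile_ci_b(data, fit, b_bounds=b_bounds)
    return fit


def _fit_to_psi(fit: GbgcFit) -> np.ndarray:
    e = np.clip([fit.e_ws, fit.e_sw, fit.e_n], 1e-6, 0.5 - 1e-9)
    return np.concatenate(
        (
            [fit.B],
            np.log([fit.theta_ws, fit.theta_sw, fit.theta_n]),
            logit(2 * np.asarray(e)),
        )
    )


def profile_ci_b(
    data: ClassSFS,
    fit: GbgcFit,
    level: float = 0.95,
    b_bounds: tuple[float, float] = (-50.0, 50.0),
) -> tuple[float, float]:
    """Profile-likelihood confidence interval for B.

    The nuisance parameters are re-optimized (warm-started from the MLE)
    on a bracketing search in each direction, and the deviance crossing of
    the chi-square(1) critical value is located by root finding.  An
    endpoint that never crosses within ``b_bounds`` is reported at the
    bound.
    """
    crit = stats.chi2.ppf(level, df=1)
    psi_hat = _fit_to_psi(fit)
    ll_max = -_profiled_negloglik(psi_hat, data)

    def deviance(b: float) -> float:
        res = _fit_psi(data, psi_hat, b_bounds, fixed_b=b)
        return 2.0 * (ll_max + res.fun) - crit

    out = []
    for direction in (-1.0, 1.0):
        step = 0.25 * max(1.0, abs(fit.B))
        b_in = fit.B
        b_out = None
        b = fit.B
        for _ in range(60):
            b = b + direction * step
            b = min(max(b, b_bounds[0]), b_bounds[1])
            if deviance(b) > 0:
                b_out = b
                break
            b_in = b
            step *= 1.6
            if b in b_bounds:
                break
        if b_out is None:
            out.append(b_bounds[0] if direction < 0 else b_bounds[1])
        else:
            out.append(
                float(optimize.brentq(deviance, b_in, b_out, xtol=1e-3))
                if b_in != b_out
                else float(b_out)
            )
    return (min(out), max(out))


# ---------------------------------------------------------------------------
# derived quantities and scalings


def estimate_lambda(theta_ws: float, theta_sw: float, gc: float) -> float:
    """AT mutational bias lambda = (theta_SW / gc) / (theta_WS / (1 - gc)).

    theta_SW mutations arise on S (G/C) sites and theta_WS on W (A/T)
    sites; dividing by the base-composition opportunity converts the
    influx scales to per-site rates, whose ratio is lambda.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must be strictly between 0 and 1")
    if theta_ws <= 0 or theta_sw <= 0:
        raise ValueError("theta parameters must be positive")
    return (theta_sw / gc) / (theta_ws / (1.0 - gc))


def equilibrium_gc(B: float, lam: float) -> float:
    """Equilibrium GC content under mutation-conversion balance:
    GC* = 1 / (1 + lambda * exp(-B))."""
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return 1.0 / (1.0 + lam * np.exp(-B))


def _ploidy_factor(ploidy_system: str) -> int:
    try:
        return {"diploid": 4, "haplodiploid": 3}[ploidy_system]
    except KeyError:
        raise ValueError(f"unknown ploidy system {ploidy_system!r}") from None


def b_from_B(B: float, n_e: float, ploidy_system: str = "haplodiploid") -> float:
    """Per-meiosis conversion bias b from the population-scaled B.

    B = 4 N_E b in diploids and 3 N_E b in haplodiploid systems (haploid
    males halve the scaled recombination opportunity).
    """
    if n_e <= 0:
        raise ValueError("N_E must be positive")
    return B / (_ploidy_factor(ploidy_system) * n_e)


def r_from_rho(
    rho_per_kb: float, n_e: float, ploidy_system: str = "haplodiploid"
) -> float:
    """Sex-averaged crossover rate in cM/Mb from a population rate rho/kb.

    rho = 3 N_E r (haplodiploid) or 4 N_E r (diploid) with r the per-bp,
    per-generation crossover probability; 1 crossover per Mb corresponds
    to 100 cM/Mb, so cM/Mb = r_per_bp * 1e8.
    """
    if n_e <= 0:
        raise ValueError("N_E must be positive")
    r_per_bp = (rho_per_kb / 1000.0) / (_ploidy_factor(ploidy_system) * n_e)
    return r_per_bp * 1e8


# ---------------------------------------------------------------------------
# stratified fits and model-free spectrum summaries


@dataclass(frozen=True)
class BinSpec:
    """Stratification of SNPs by a local covariate.

    ``variable`` names the covariate (``local_GC`` measured in 100 bp to
    each side of the SNP, or ``rho`` from the 1 kb window containing it);
    ``edges`` are strictly ascending bin boundaries.
    """

    variable: str
    edges: tuple

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.edges, self.edges[1:])):
            raise ValueError("edges must be strictly ascending")

    def assign(self, values: Sequence[float]) -> np.ndarray:
        """Bin index per value; -1 for values outside the outer edges."""
        idx = np.digitize(np.asarray(values, dtype=float), self.edges) - 1
        idx[(idx < 0) | (idx >= len(self.edges) - 1)] = -1
        return idx


def binned_fits(
    snps: Sequence,
    values: Sequence[float],
    bins: BinSpec,
    min_total: float = 200.0,
    **fit_kwargs,
) -> dict[int, GbgcFit | None]:
    """Independent constant-gBGC fit per covariate bin.

    ``values`` is the per-SNP covariate aligned with ``snps``.  Bins whose
    spectra hold fewer than ``min_total`` SNPs are reported as None.
    """
    idx = bins.assign(values)
    out: dict[int, GbgcFit | None] = {}
    for b in range(len(bins.edges) - 1):
        members = [s for s, i in zip(snps, idx) if i == b]
        if not members:
            out[b] = None
            continue
        sfs = build_class_sfs(members)
        if sfs.total < min_total:
            out[b] = None
            continue
        out[b] = fit_M1star(sfs, min_total=min_total, **fit_kwargs)
    return out


@dataclass
class FoldedTest:
    spectrum_w: np.ndarray
    spectrum_s: np.ndarray
    table: np.ndarray
    odds_ratio: float
    p: float
    n_excluded: int


def folded_spectrum_test(
    sites: Sequence, maf_cut: float = 0.25
) -> FoldedTest:
    """Folded W/S minor-allele spectra and an exact 2x2 frequency test.

    Uses unpolarized sites whose minor allele is unambiguously weak (A/T)
    with a strong major allele or vice versa; WW and SS sites, and exact
    50/50 ties, are excluded.  The 2x2 table crosses minor-allele class
    (W vs S) with frequency stratum (MAF < ``maf_cut`` vs >=) and is
    tested with Fisher's exact test.
    """
    weak = frozenset("AT")
    n = None
    excluded = 0
    spec: dict[str, np.ndarray] = {}
    table = np.zeros((2, 2), dtype=int)
    for s in sites:
        n = s.n
        if spec == {}:
            spec = {"W": np.zeros(n // 2), "S": np.zeros(n // 2)}
        x_weak = s.allele_x in weak
        y_weak = s.allele_y in weak
        if x_weak == y_weak:
            excluded += 1
            continue
        if s.count_y * 2 == s.n:
            excluded += 1
            continue
        minor_is_y = s.count_y * 2 < s.n
        minor_allele_weak = y_weak if minor_is_y else x_weak
        m = min(s.count_y, s.n - s.count_y)
        cls = "W" if minor_allele_weak else "S"
        spec[cls][m - 1] += 1
        table["WS".index(cls), 0 if m / s.n < maf_cut else 1] += 1
    if n is None:
        raise ValueError("no sites provided")
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        raise ValueError("empty stratum in the 2x2 table")
    odds_ratio, p = stats.fisher_exact(table)
    return FoldedTest(
        spectrum_w=spec["W"],
        spectrum_s=spec["S"],
        table=table,
        odds_ratio=float(odds_ratio),
        p=float(p),
        n_excluded=excluded,
    )


def class_frequency_summaries(
    snps: Sequence,
    n_boot: int = 200,
    seed: int = 0,
    n_freq_bins: int = 10,
) -> dict[str, pd.DataFrame]:
    """Mean derived allele frequency per mutation class, Ti/Tv and
    CpG/GpC context, with bootstrap CIs, ratio summaries and relative
    per-frequency-bin class proportions.
    """
    recs = []
    for snp in snps:
        recs.append(
            {
                "mclass": snp.mclass,
                "titv": snp.titv,
                "f_d": snp.f_d,
                "context": snp.context,
            }
        )
    df = pd.DataFrame(recs)
    if df.empty:
        raise ValueError("no SNPs provided")

    def summarize(groups: Mapping[str, np.ndarray]) -> pd.DataFrame:
        groups = {k: v for k, v in groups.items() if len(v) > 0}
        if not groups:
            return pd.DataFrame()
        summaries, _ = bootstrap_compare(groups, n_boot=n_boot, seed=seed)
        return pd.DataFrame(
            [
                {
                    "cell": k,
                    "n": s.n,
                    "mean_f_d": s.mean,
                    "ci_lo": s.ci_lo,
                    "ci_hi": s.ci_hi,
                }
                for k, s in summaries.items()
            ]
        )

    cells = {
        f"{m}:{t}": df.loc[(df.mclass == m) & (df.titv == t), "f_d"].to_numpy()
        for m in ("WS", "SW", "WW", "SS")
        for t in ("Ti", "Tv")
    }
    cells.update(
        {
            f"{m}:{flag}": df.loc[
                (df.mclass == m) & df.context.map(lambda c: flag in c), "f_d"
            ].to_numpy()
            for m in ("WS", "SS")
            for flag in ("CpG-creating", "GpC-creating")
        }
    )
    cells.update(
        {
            f"SW:{flag}": df.loc[
                (df.mclass == "SW") & df.context.map(lambda c: flag in c), "f_d"
            ].to_numpy()
            for flag in ("CpG-destroying", "GpC-destroying")
        }
    )
    cell_df = summarize(cells)

    ratios = []
    means = {r["cell"]: r["mean_f_d"] for _, r in cell_df.iterrows()}
    for t in ("Ti", "Tv"):
        a, b = means.get(f"WS:{t}"), means.get(f"SW:{t}")
        if a is not None and b is not None and b > 0:
            ratios.append({"ratio": f"WS/SW mean f_d ({t})", "value": a / b})
    for m in ("WS", "SS"):
        a = means.get(f"{m}:CpG-creating")
        b = means.get(f"{m}:GpC-creating")
        if a is not None and b is not None and b > 0:
            ratios.append({"ratio": f"{m} CpG-/GpC-creating mean f_d", "value": a / b})

    bins = np.linspace(0.0, 1.0, n_freq_bins + 1)
    df["freq_bin"] = pd.cut(df.f_d, bins, include_lowest=True)
    rel = (
        df.groupby(["freq_bin", "mclass"], observed=False)
        .size()
        .unstack(fill_value=0)
    )
    rel = rel.div(rel.sum(axis=1).replace(0, np.nan), axis=0)

    return {
        "cells": cell_df,
        "ratios": pd.DataFrame(ratios),
        "relative_spectra": rel.reset_index(),
    }
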