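"""Maximum-likelihood estimation of gBGC and codon-usage selection.

The model treats the counts of each derived-frequency class (and the
lineage-specific substitution count) of each mutation category as
independent Poisson draws around expectations from the stationary
diffusion density of a semidominant allele with scaled coefficient gamma:

    f(x; gamma) = (1 - exp(-gamma (1 - x))) / ((1 - exp(-gamma)) x (1 - x))

binomially sampled to n chromosomes.  Directional categories (W->S vs
S->W, U->P vs P->U) feel opposite signs of the coefficient; the joint
nine-category model assumes gBGC (B) and selection on codon usage (S) act
additively.  Substitution expectations use the relative fixation rate
d(gamma) = gamma / (1 - exp(-gamma)), scaled by a divergence parameter tau
and an *ancestral* coefficient (B0/S0) distinct from the *recent* one
(B1/S1) acting on polymorphism.  Nuisance parameters absorb the mutation
bias lambda (ratio of S->W to W->S scaled mutation rates), demographic
spectrum distortion (one multiplier r_i per frequency class, r_1 = 1) and
the polarization-error probability e, which mixes each category's spectrum
with the frequency-mirrored spectrum of its reverse category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from sklearn.base import BaseEstimator

from .alignments import GC_CONS, GC_SW, GC_WS, PREF_NEUTRAL, PREF_PU, PREF_UP
from .spectra import CategorySfsSet, categories_for, reverse_category

NEUTRAL = "NEUTRAL"

_GAMMA_EPS = 1e-6

#: free thetas per set; reverse categories are tied through lambda
BASE_CATEGORIES = {
    "gBGC": (GC_WS, NEUTRAL),
    "SCU": (PREF_UP, NEUTRAL),
    "joint": tuple(
        f"{gc}:{pref}"
        for gc in (GC_WS, GC_CONS)
        for pref in (PREF_UP, PREF_PU, PREF_NEUTRAL)
    ),
}

FORCE_NAMES = {"gBGC": ("B0", "B1"), "SCU": ("S0", "S1"), "joint": ("B0", "B1", "S0", "S1")}


def _gamma_signs(category: str, set_name: str) -> tuple[int, int]:
    """(sign of B, sign of S) entering gamma = sB*B + sS*S for a category."""
    if set_name == "gBGC":
        return {GC_WS: (1, 0), GC_SW: (-1, 0), NEUTRAL: (0, 0)}[category]
    if set_name == "SCU":
        return {PREF_UP: (0, 1), PREF_PU: (0, -1), NEUTRAL: (0, 0)}[category]
    gc, pref = category.split(":")
    sb = {GC_WS: 1, GC_SW: -1, GC_CONS: 0}[gc]
    ss = {PREF_UP: 1, PREF_PU: -1, PREF_NEUTRAL: 0}[pref]
    return sb, ss


# ---------------------------------------------------------------------------
# diffusion primitives


def sfs_density(x: float, gamma: float) -> float:
    """Stationary density of derived-allele frequency under coefficient gamma.

    Neutral limit (|gamma| below 1e-6) switches to the series 1/x to avoid
    cancellation.
    """
    x = float(x)
    if not 0 < x < 1:
        raise ValueError(f"frequency {x} outside (0, 1)")
    if abs(gamma) < _GAMMA_EPS:
        # 4th-order expansion of the gamma-dependence around 0
        u = 1 - x
        corr = 1 + gamma * (1 - u) / 2 + gamma**2 * (1 - u) * (1 - 2 * u) / 12
        return corr / x
    return float(np.expm1(-gamma * (1 - x)) / np.expm1(-gamma) / (x * (1 - x)))


def fixation_factor(gamma) -> float | np.ndarray:
    """Relative fixation rate d(gamma) = gamma / (1 - exp(-gamma)); d(0) = 1."""
    g = np.asarray(gamma, dtype=float)
    out = np.empty_like(g)
    small = np.abs(g) < 1e-8
    gs = g[small]
    out[small] = 1 + gs / 2 + gs**2 / 12
    gl = g[~small]
    out[~small] = gl / (-np.expm1(-gl))
    if np.isscalar(gamma) or np.ndim(gamma) == 0:
        return float(out)
    return out


def _fixation_factor_grad(gamma) -> np.ndarray:
    """d'(gamma) for the fixation-rate factor."""
    g = np.asarray(gamma, dtype=float)
    out = np.empty_like(g)
    small = np.abs(g) < 1e-6
    gs = g[small]
    out[small] = 0.5 + gs / 6
    gl = g[~small]
    em = -np.expm1(-gl)  # 1 - exp(-gl)
    out[~small] = (em - gl * np.exp(-gl)) / em**2
    return out


class _SfsBasis:
    """Cached Gauss-Legendre quadrature basis for binned spectra at fixed n.

    F_i(gamma) = int_0^1 C(n,i) x^i (1-x)^(n-i) f(x; gamma) dx is evaluated
    as A @ h(gamma) with A[i-1, k] = w_k C(n,i) x_k^(i-1) (1-x_k)^(n-i-1)
    and h the smooth part of the density; the integrand is a degree-(n-2)
    polynomial times an entire function, so a fixed 200-point rule is exact
    to near machine precision for the n used here.
    """

    _cache: dict[int, "_SfsBasis"] = {}

    def __init__(self, n: int, n_nodes: int = 200):
        nodes, weights = np.polynomial.legendre.leggauss(n_nodes)
        self.x = 0.5 * (nodes + 1)
        self.w = 0.5 * weights
        self.n = n
        i = np.arange(1, n)
        logC = special.gammaln(n + 1) - special.gammaln(i + 1) - special.gammaln(n - i + 1)
        logA = (
            logC[:, None]
            + (i[:, None] - 1) * np.log(self.x[None, :])
            + (n - i[:, None] - 1) * np.log1p(-self.x[None, :])
        )
        self.A = np.exp(logA) * self.w[None, :]

    @classmethod
    def for_n(cls, n: int) -> "_SfsBasis":
        if n not in cls._cache:
            cls._cache[n] = cls(n)
        return cls._cache[n]

    def h(self, gammas: np.ndarray) -> np.ndarray:
        """Smooth density factor h[g, k] = (1-exp(-g(1-x_k)))/(1-exp(-g))."""
        g = np.asarray(gammas, dtype=float)[:, None]
        u = 1 - self.x[None, :]
        small = np.abs(g) < _GAMMA_EPS
        with np.errstate(divide="ignore", invalid="ignore"):
            exact = np.expm1(-g * u) / np.expm1(-g)
        series = u * (1 + g * (1 - u) / 2 + g**2 * (1 - u) * (1 - 2 * u) / 12)
        return np.where(small, series, exact)

    def binned(self, gammas) -> np.ndarray:
        """F_i(gamma) for each gamma; shape (len(gammas), n-1)."""
        g = np.atleast_1d(np.asarray(gammas, dtype=float))
        return self.h(g) @ self.A.T

    def h_grad(self, gammas: np.ndarray) -> np.ndarray:
        """d h / d gamma at the quadrature nodes."""
        g = np.asarray(gammas, dtype=float)[:, None]
        u = 1 - self.x[None, :]
        small = np.abs(g) < _GAMMA_EPS
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            A1 = np.expm1(-g * u)
            A2 = np.expm1(-g)
            exact = (-u * np.exp(-g * u) * A2 + A1 * np.exp(-g)) / A2**2
        series = u * ((1 - u) / 2 + g * (1 - u) * (1 - 2 * u) / 6)
        return np.where(small, series, exact)

    def binned_with_grad(self, gammas):
        """(F, dF/dgamma) for each gamma; each of shape (len(gammas), n-1)."""
        g = np.atleast_1d(np.asarray(gammas, dtype=float))
        return self.h(g) @ self.A.T, self.h_grad(g) @ self.A.T


def binned_sfs(gamma: float, n: int) -> np.ndarray:
    """Expected per-theta SFS vector F_1..F_(n-1) under coefficient gamma.

    Neutral closed form: F_i(0) = 1/i.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    return _SfsBasis.for_n(n).binned([gamma])[0]


# ---------------------------------------------------------------------------
# expected counts and likelihood


@dataclass
class SpectrumParams:
    """Full parameter vector of the Poisson spectrum model."""

    n: int
    set_name: str
    lam: float = 1.0
    theta: dict = field(default_factory=dict)  # base-category thetas
    b0: float = 0.0
    b1: float = 0.0
    s0: float = 0.0
    s1: float = 0.0
    e: float = 0.0
    r: np.ndarray | None = None  # length n-1, r[0] == 1
    tau: float = 1.0

    def __post_init__(self) -> None:
        if self.r is None:
            self.r = np.ones(self.n - 1)
        self.r = np.asarray(self.r, dtype=float)
        if self.r.shape != (self.n - 1,):
            raise ValueError("r must have length n-1")
        if not math.isclose(self.r[0], 1.0):
            raise ValueError("r_1 must equal 1 (normalization)")
        if not 0 <= self.e < 0.5:
            raise ValueError("polarization error must lie in [0, 0.5)")
        for c in BASE_CATEGORIES[self.set_name]:
            self.theta.setdefault(c, 0.0)

    def category_theta(self, category: str) -> float:
        base = BASE_CATEGORIES[self.set_name]
        if category in base:
            return self.theta[category]
        rev = reverse_category(category, self.set_name)
        return self.lam * self.theta[rev]

    def category_gamma(self, category: str, epoch: str) -> float:
        sb, ss = _gamma_signs(category, self.set_name)
        if epoch == "recent":
            return sb * self.b1 + ss * self.s1
        return sb * self.b0 + ss * self.s0


def expected_counts(params: SpectrumParams):
    """Expected SFS and divergence counts per category.

    Polymorphism:  mu_c(i) = r_i [(1-e) theta_c F_i(g1(c))
                                  + e theta_cbar F_(n-i)(g1(cbar))]
    Divergence:    mu_c(D) = tau [(1-e) theta_c d(g0(c))
                                  + e theta_cbar d(g0(cbar))]
    where cbar is the category with ancestral/derived swapped.
    """
    cats = categories_for(params.set_name)
    basis = _SfsBasis.for_n(params.n)
    g1 = {c: params.category_gamma(c, "recent") for c in cats}
    uniq = sorted(set(g1.values()))
    F = dict(zip(uniq, basis.binned(uniq)))
    e = params.e
    mu_sfs, mu_div = {}, {}
    for c in cats:
        cbar = reverse_category(c, params.set_name)
        th_c, th_b = params.category_theta(c), params.category_theta(cbar)
        mu = (1 - e) * th_c * F[g1[c]] + e * th_b * F[g1[cbar]][::-1]
        mu_sfs[c] = params.r * mu
        d_c = fixation_factor(params.category_gamma(c, "ancestral"))
        d_b = fixation_factor(params.category_gamma(cbar, "ancestral"))
        mu_div[c] = params.tau * ((1 - e) * th_c * d_c + e * th_b * d_b)
    return mu_sfs, mu_div


def loglik(params: SpectrumParams, data: CategorySfsSet) -> float:
    """Independent-Poisson composite log-likelihood over classes + divergence."""
    if data.n != params.n:
        raise ValueError(f"data n={data.n} != model n={params.n}")
    if data.set_name != params.set_name:
        raise ValueError("category set mismatch")
    mu_sfs, mu_div = expected_counts(params)
    total = 0.0
    for c in data.categories:
        k = np.append(data.sfs[c], data.div[c])
        mu = np.append(mu_sfs[c], mu_div[c])
        bad = (mu <= 0) & (k > 0)
        if bad.any():
            raise ValueError(f"zero expectation with nonzero count in {c}")
        mu = np.clip(mu, 1e-300, None)
        total += float(np.sum(k * np.log(mu) - mu - special.gammaln(k + 1)))
    return total


# ---------------------------------------------------------------------------
# fitting


_CHI2_95_HALF = stats.chi2.ppf(0.95, 1) / 2  # 1.9207... logL drop for 95% CI


class _Layout:
    """Mapping between the flat optimizer vector and named parameters."""

    def __init__(self, n, set_name, force_spec, fit_error, fit_demography):
        self.n = n
        self.set_name = set_name
        self.force_spec = dict(force_spec)
        self.names: list[str] = ["log_lam"]
        self.bounds: list[tuple[float, float]] = [(np.log(0.05), np.log(20.0))]
        for c in BASE_CATEGORIES[set_name]:
            self.names.append(f"log_theta:{c}")
            self.bounds.append((np.log(1e-8), np.log(1e12)))
        self.free_forces = [f for f in FORCE_NAMES[set_name] if self.force_spec.get(f) == "free"]
        for f in self.free_forces:
            self.names.append(f)
            self.bounds.append((-50.0, 50.0))
        self.fit_error = fit_error
        if fit_error:
            self.names.append("e")
            self.bounds.append((0.0, 0.49))
        self.fit_demography = fit_demography
        if fit_demography:
            for i in range(2, n):
                self.names.append(f"log_r:{i}")
                self.bounds.append((np.log(1e-3), np.log(1e3)))
        self.names.append("log_tau")
        self.bounds.append((np.log(1e-8), np.log(1e6)))
        self.n_free = len(self.names)
        self.index = {name: k for k, name in enumerate(self.names)}

        # vectorized category metadata for the fast objective
        cats = categories_for(set_name)
        base = BASE_CATEGORIES[set_name]
        self.cats = cats
        self.rev_idx = np.array(
            [cats.index(reverse_category(c, set_name)) for c in cats]
        )
        self.base_idx = np.empty(len(cats), dtype=int)
        self.lam_pow = np.zeros(len(cats))
        for k, c in enumerate(cats):
            if c in base:
                self.base_idx[k] = base.index(c)
            else:
                self.base_idx[k] = base.index(reverse_category(c, set_name))
                self.lam_pow[k] = 1.0
        self.sB = np.array([_gamma_signs(c, set_name)[0] for c in cats], dtype=float)
        self.sS = np.array([_gamma_signs(c, set_name)[1] for c in cats], dtype=float)
        self.i_theta = np.array([self.index[f"log_theta:{c}"] for c in base])
        self.i_r = (
            np.array([self.index[f"log_r:{i}"] for i in range(2, n)])
            if fit_demography
            else np.array([], dtype=int)
        )
        # gradient destination for each logical force (None = not free)
        self.force_dest = {}
        for fam in ("B", "S"):
            anc, rec = fam + "0", fam + "1"
            if anc not in FORCE_NAMES[set_name]:
                continue
            self.force_dest[anc] = self.index.get(anc)
            if self.force_spec.get(rec) == "equal":
                self.force_dest[rec] = self.index.get(anc)
            else:
                self.force_dest[rec] = self.index.get(rec)

    def force_values(self, vec: np.ndarray) -> dict:
        """Values of B0, B1, S0, S1 implied by the flat vector."""
        out = {}
        for fam in ("B", "S"):
            anc, rec = fam + "0", fam + "1"
            if anc not in FORCE_NAMES[self.set_name]:
                out[anc] = out[rec] = 0.0
                continue
            v0 = vec[self.index[anc]] if self.force_spec.get(anc) == "free" else 0.0
            spec1 = self.force_spec.get(rec)
            if spec1 == "free":
                v1 = vec[self.index[rec]]
            elif spec1 == "equal":
                v1 = v0
            else:
                v1 = 0.0
            out[anc], out[rec] = v0, v1
        return out

    def unpack(self, vec: np.ndarray) -> SpectrumParams:
        v = dict(zip(self.names, vec))
        forces = {}
        for f in FORCE_NAMES[self.set_name]:
            spec = self.force_spec.get(f, "zero")
            if spec == "free":
                forces[f] = v[f]
            elif spec == "equal":
                anc = f[0] + "0"
                forces[f] = forces.get(anc, v.get(anc, 0.0))
            else:
                forces[f] = 0.0
        theta = {
            c: np.exp(v[f"log_theta:{c}"]) for c in BASE_CATEGORIES[self.set_name]
        }
        r = np.ones(self.n - 1)
        if self.fit_demography:
            for i in range(2, self.n):
                r[i - 1] = np.exp(v[f"log_r:{i}"])
        return SpectrumParams(
            n=self.n,
            set_name=self.set_name,
            lam=np.exp(v["log_lam"]),
            theta=theta,
            b0=forces.get("B0", 0.0),
            b1=forces.get("B1", 0.0),
            s0=forces.get("S0", 0.0),
            s1=forces.get("S1", 0.0),
            e=v.get("e", 0.0),
            r=r,
            tau=np.exp(v["log_tau"]),
        )


def _start_vector(layout: _Layout, data: CategorySfsSet, rng=None) -> np.ndarray:
    """Data-driven starting point (optionally jittered)."""
    base = BASE_CATEGORIES[layout.set_name]
    H = np.sum(1.0 / np.arange(1, data.n))
    vec = np.zeros(layout.n_free)
    for c in base:
        tot = max(data.sfs[c].sum(), 1.0)
        vec[layout.index[f"log_theta:{c}"]] = np.log(tot / H)
    fwd = base[0]
    rev = reverse_category(fwd, layout.set_name)
    tot_fwd = max(data.sfs[fwd].sum(), 1.0)
    tot_rev = max(data.sfs[rev].sum(), 1.0)
    lam0 = float(np.clip(tot_rev / tot_fwd, 0.06, 19.0))
    vec[layout.index["log_lam"]] = np.log(lam0)
    # tau start: observed divergence over the summed per-category thetas
    theta_sum = 0.0
    for c in categories_for(layout.set_name):
        if c in base:
            theta_sum += np.exp(vec[layout.index[f"log_theta:{c}"]])
        else:
            rc = reverse_category(c, layout.set_name)
            theta_sum += lam0 * np.exp(vec[layout.index[f"log_theta:{rc}"]])
    total_div = max(sum(data.div.values()), 1.0)
    vec[layout.index["log_tau"]] = np.log(total_div / max(theta_sum, 1e-8))
    if layout.fit_error:
        vec[layout.index["e"]] = 0.02
    if rng is not None:
        jitter = rng.normal(0.0, 0.3, size=layout.n_free)
        if layout.fit_error:
            jitter[layout.index["e"]] = 0.0
            vec[layout.index["e"]] = rng.uniform(0.0, 0.2)
        for f in layout.free_forces:
            jitter[layout.index[f]] = rng.normal(0.0, 0.3)
        vec = vec + jitter
        lo = np.array([b[0] for b in layout.bounds])
        hi = np.array([b[1] for b in layout.bounds])
        vec = np.clip(vec, lo + 1e-9, hi - 1e-9)
    return vec


@dataclass
class FitResult:
    """Point estimates, profile CIs and fit diagnostics."""

    params: SpectrumParams
    estimates: dict
    loglik: float
    aic: float
    n_free: int
    conf_int: dict
    converged: bool
    lrt_pvalues: dict = field(default_factory=dict)
    force_spec: dict = field(default_factory=dict)
    named_x: dict = field(default_factory=dict)


class SfsModel(BaseEstimator):
    """Poisson-random-field estimator of gBGC and/or codon-usage selection.

    Fits the spectrum model to a :class:`CategorySfsSet` by bounded
    quasi-Newton maximization with seeded multi-start.  Ancestral and recent
    intensities (B0/B1 for gBGC, S0/S1 for selection) can each be freely
    estimated, fixed to zero, or tied equal ("equal" for the recent one).

    Parameters
    ----------
    set_name : {"gBGC", "SCU", "joint"}
    b0, b1, s0, s1 : {"free", "zero", "equal"}
        Force specification.  For the gBGC set s0/s1 are forced to zero, and
        vice versa for the SCU set.
    fit_error : bool
        Estimate the polarization-error probability e (shared between SNPs
        and substitutions).
    fit_demography : bool
        Estimate the per-class distortion multipliers r_2..r_(n-1).
    n_starts : int
        Number of optimizer starts (first start is data-driven, the rest
        jittered with ``seed``).
    compute_ci : bool
        Profile-likelihood 95% intervals (1.92 logL drop) for lambda and the
        free force parameters.

    Attributes
    ----------
    result_ : FitResult
    params_ : dict of point estimates (lambda, thetas, forces, e, tau)
    loglik_, aic_, n_free_ : float
    conf_int_ : dict name -> (low, high)
    """

    def __init__(
        self,
        set_name: str = "gBGC",
        b0: str = "free",
        b1: str = "free",
        s0: str = "zero",
        s1: str = "zero",
        fit_error: bool = True,
        fit_demography: bool = True,
        n_starts: int = 10,
        seed: int = 0,
        compute_ci: bool = True,
        ci_params=None,
        maxiter: int = 500,
    ):
        self.set_name = set_name
        self.b0 = b0
        self.b1 = b1
        self.s0 = s0
        self.s1 = s1
        self.fit_error = fit_error
        self.fit_demography = fit_demography
        self.n_starts = n_starts
        self.seed = seed
        self.compute_ci = compute_ci
        self.ci_params = ci_params
        self.maxiter = maxiter

    # -- internals ---------------------------------------------------------

    def _force_spec(self) -> dict:
        spec = {"B0": self.b0, "B1": self.b1, "S0": self.s0, "S1": self.s1}
        if self.set_name == "gBGC":
            spec["S0"] = spec["S1"] = "zero"
        elif self.set_name == "SCU":
            spec["B0"] = spec["B1"] = "zero"
        for name, v in spec.items():
            if v not in ("free", "zero", "equal"):
                raise ValueError(f"{name}: invalid force spec {v!r}")
            if v == "equal" and name.endswith("0"):
                raise ValueError("'equal' applies to the recent parameter only")
        return spec

    def _objective(self, layout: _Layout, data: CategorySfsSet):
        """Negative composite log-likelihood with its analytic gradient."""
        k_sfs = np.stack([data.sfs[c] for c in layout.cats])
        k_div = np.array([data.div[c] for c in layout.cats])
        lgam = float(
            np.sum(special.gammaln(k_sfs + 1)) + np.sum(special.gammaln(k_div + 1))
        )
        basis = _SfsBasis.for_n(layout.n)
        rev = layout.rev_idx
        n_free = layout.n_free

        def neg_loglik(vec: np.ndarray):
            lam = np.exp(vec[layout.index["log_lam"]])
            theta_b = np.exp(vec[layout.i_theta])
            forces = layout.force_values(vec)
            e = vec[layout.index["e"]] if layout.fit_error else 0.0
            r = np.ones(layout.n - 1)
            if layout.fit_demography:
                r[1:] = np.exp(vec[layout.i_r])
            tau = np.exp(vec[layout.index["log_tau"]])

            theta = lam**layout.lam_pow * theta_b[layout.base_idx]
            g1 = layout.sB * forces["B1"] + layout.sS * forces["S1"]
            g0 = layout.sB * forces["B0"] + layout.sS * forces["S0"]
            F, dF = basis.binned_with_grad(g1)
            dvec = fixation_factor(g0)
            ddvec = _fixation_factor_grad(g0)

            Pu = theta[:, None] * F
            Qu = (theta[:, None] * F)[rev][:, ::-1]
            mu = r[None, :] * ((1 - e) * Pu + e * Qu)
            Du = theta * dvec
            mud = tau * ((1 - e) * Du + e * Du[rev])

            mu_c = np.clip(mu, 1e-300, None)
            mud_c = np.clip(mud, 1e-300, None)
            ll = (
                float(np.sum(k_sfs * np.log(mu_c) - mu_c))
                + float(np.sum(k_div * np.log(mud_c) - mud_c))
                - lgam
            )

            # gradient
            w = k_sfs / mu_c - 1.0  # dl/dmu
            wD = k_div / mud_c - 1.0
            grad = np.zeros(n_free)

            # per-category split of mu into its theta_c and theta_cbar parts
            T1 = w * r[None, :] * (1 - e) * Pu  # dl/dlog(theta_c-part)
            T2 = w * r[None, :] * e * Qu  # belongs to theta of reverse cat
            D1 = wD * tau * (1 - e) * Du
            D2 = wD * tau * e * Du[rev]
            own = T1.sum(axis=1) + D1
            other = T2.sum(axis=1) + D2  # attributed to theta of rev cat
            per_cat = own.copy()
            np.add.at(per_cat, rev, other)
            np.add.at(grad, layout.i_theta[layout.base_idx], per_cat)
            grad[layout.index["log_lam"]] += float(np.sum(per_cat * layout.lam_pow))

            if layout.fit_error:
                de = np.sum(w * r[None, :] * (Qu - Pu)) + np.sum(
                    wD * tau * (Du[rev] - Du)
                )
                grad[layout.index["e"]] += float(de)
            if layout.fit_demography:
                grad[layout.i_r] += (w * mu).sum(axis=0)[1:]
            grad[layout.index["log_tau"]] += float(np.sum(wD * mud))

            # forces: recent via dF, ancestral via d'
            dPu = theta[:, None] * dF
            dQu = (theta[:, None] * dF)[rev][:, ::-1]
            dDu = theta * ddvec
            for fam, sign in (("B", layout.sB), ("S", layout.sS)):
                dest1 = layout.force_dest.get(fam + "1")
                if dest1 is not None:
                    dmu = r[None, :] * (
                        (1 - e) * sign[:, None] * dPu
                        + e * sign[rev][:, None] * dQu
                    )
                    grad[dest1] += float(np.sum(w * dmu))
                dest0 = layout.force_dest.get(fam + "0")
                if dest0 is not None:
                    dmud = tau * ((1 - e) * sign * dDu + e * (sign * dDu)[rev])
                    grad[dest0] += float(np.sum(wD * dmud))

            return -ll, -grad

        return neg_loglik

    def _optimize(self, fun, x0, bounds):
        return optimize.minimize(
            fun,
            x0,
            method="L-BFGS-B",
            jac=True,
            bounds=bounds,
            options={"maxiter": self.maxiter, "maxfun": 10**6, "ftol": 1e-11},
        )

    def _profile_ci(self, fun, layout, xopt, name, lmax):
        """Profile-likelihood bounds at the 1.92 logL drop (95%, 1 df).

        The profile is close to a parabola near the optimum, so the first
        step is sized from its local curvature; the crossing is then
        bracketed geometrically and polished with Brent's method.
        """
        j = layout.index[name]
        lo_b, hi_b = layout.bounds[j]
        target = lmax - _CHI2_95_HALF
        free = [k for k in range(layout.n_free) if k != j]
        free_bounds = [layout.bounds[k] for k in free]
        warm = xopt[free].copy()

        def profile(value: float) -> float:
            nonlocal warm
            base = xopt.copy()
            base[j] = value

            def inner(sub):
                base[free] = sub
                val, grad = fun(base)
                return val, grad[free]

            res = optimize.minimize(
                inner, warm, method="L-BFGS-B", jac=True, bounds=free_bounds,
                options={"maxiter": 100, "ftol": 1e-9},
            )
            warm = res.x
            return -res.fun

        out = {}
        mle = xopt[j]
        scale = max(0.05, abs(mle) * 0.25)
        for direction, bound in ((-1, lo_b), (+1, hi_b)):
            warm = xopt[free].copy()
            # curvature probe: half-width estimate from one profile point
            probe = mle + direction * scale
            probe = np.clip(probe, lo_b, hi_b)
            drop = lmax - profile(probe)
            if drop <= 1e-9:
                width = 4 * scale
            else:
                width = scale * math.sqrt(_CHI2_95_HALF / drop)
            a, fa = probe, lmax - drop
            b = None
            cand = mle + direction * width * 1.2
            for _ in range(30):
                cand = np.clip(cand, lo_b, hi_b)
                val = profile(cand)
                if val < target:
                    b, fb = cand, val
                    break
                a, fa = cand, val
                if cand in (lo_b, hi_b):
                    break
                cand = mle + direction * (abs(cand - mle) * 1.6)
            if b is None:
                out[direction] = bound
                continue
            if fa < target:  # probe already below the drop: bracket inward
                a, fa = mle, lmax
            try:
                root = optimize.brentq(
                    lambda v: profile(v) - target, min(a, b), max(a, b),
                    xtol=max(1e-3, 0.01 * abs(b - a)), maxiter=30,
                )
            except ValueError:  # pragma: no cover - numerical corner
                root = b
            out[direction] = float(root)
        return out[-1], out[+1]

    # -- API ---------------------------------------------------------------

    def fit(self, data: CategorySfsSet, extra_starts=None):
        """Fit the model; ``extra_starts`` adds warm-start vectors (mappings
        from parameter name to value, e.g. from a nested fit)."""
        if data.set_name != self.set_name:
            raise ValueError(
                f"data set {data.set_name!r} does not match estimator set {self.set_name!r}"
            )
        spec = self._force_spec()
        layout = _Layout(data.n, self.set_name, spec, self.fit_error, self.fit_demography)
        fun = self._objective(layout, data)
        rng = np.random.default_rng(self.seed)
        starts = [
            _start_vector(layout, data, rng=None if k == 0 else rng)
            for k in range(max(1, self.n_starts))
        ]
        for named in extra_starts or ():
            x0 = _start_vector(layout, data)
            for name, value in named.items():
                if name in layout.index:
                    lo, hi = layout.bounds[layout.index[name]]
                    x0[layout.index[name]] = np.clip(value, lo, hi)
            starts.append(x0)
        best = None
        failures = []
        for x0 in starts:
            try:
                res = self._optimize(fun, x0, layout.bounds)
            except (ValueError, FloatingPointError) as exc:  # pragma: no cover
                failures.append(str(exc))
                continue
            if best is None or res.fun < best.fun:
                best = res
        if best is None:
            raise RuntimeError(f"all optimizer starts failed: {failures}")

        params = layout.unpack(best.x)
        lmax = -best.fun
        named_x = dict(zip(layout.names, best.x))
        for f, v in layout.force_values(best.x).items():
            named_x.setdefault(f, v)
        estimates = {"lambda": params.lam, "e": params.e, "tau": params.tau}
        for c in BASE_CATEGORIES[self.set_name]:
            estimates[f"theta:{c}"] = params.theta[c]
        for f, v in (("B0", params.b0), ("B1", params.b1), ("S0", params.s0), ("S1", params.s1)):
            if f in FORCE_NAMES[self.set_name]:
                estimates[f] = v

        conf = {}
        if self.compute_ci:
            targets = ["log_lam"] + layout.free_forces
            if self.ci_params is not None:
                wanted = {"log_lam" if p == "lambda" else p for p in self.ci_params}
                targets = [t for t in targets if t in wanted]
            for name in targets:
                lo, hi = self._profile_ci(fun, layout, best.x, name, lmax)
                if name == "log_lam":
                    conf["lambda"] = (float(np.exp(lo)), float(np.exp(hi)))
                else:
                    conf[name] = (float(lo), float(hi))

        self.layout_ = layout
        self.x_ = best.x
        self.result_ = FitResult(
            params=params,
            estimates=estimates,
            loglik=lmax,
            aic=2 * layout.n_free - 2 * lmax,
            n_free=layout.n_free,
            conf_int=conf,
            converged=bool(best.success),
            force_spec=spec,
            named_x=named_x,
        )
        self.params_ = estimates
        self.loglik_ = lmax
        self.aic_ = self.result_.aic
        self.n_free_ = layout.n_free
        self.conf_int_ = conf
        self.converged_ = self.result_.converged
        return self


def fit_sfs_model(data: CategorySfsSet, **kwargs) -> FitResult:
    """Functional wrapper: fit and return the :class:`FitResult`."""
    return SfsModel(set_name=data.set_name, **kwargs).fit(data).result_


def lrt(fit_null: FitResult, fit_alt: FitResult) -> float:
    """Likelihood-ratio test p-value between nested fits.

    Chi-square with df = difference in free parameters on 2 * delta logL.
    """
    df = fit_alt.n_free - fit_null.n_free
    if df <= 0:
        raise ValueError("alternative must have more free parameters than null")
    delta = fit_alt.loglik - fit_null.loglik
    if delta < -1e-6:
        raise ValueError(
            f"alternative logL below null by {-delta:.3g}: non-nested or failed fit"
        )
    return float(stats.chi2.sf(max(2 * delta, 0.0), df))


def nested_force_tests(data: CategorySfsSet, **kwargs) -> FitResult:
    """Fit the two-epoch model and run the three standard nested tests.

    Returns the full (B0, B1 free) fit with LRT p-values for ancestral = 0,
    recent = 0 and recent = ancestral attached (force names follow the set:
    S0/S1 for the SCU set).
    """
    set_name = data.set_name
    prefix = FORCE_NAMES[set_name][0][0].lower()

    def kw(a, b):
        return {prefix + "0": a, prefix + "1": b}

    ci = kwargs.pop("compute_ci", True)
    no_anc = fit_sfs_model(data, **kw("zero", "free"), compute_ci=False, **kwargs)
    no_rec = fit_sfs_model(data, **kw("free", "zero"), compute_ci=False, **kwargs)
    equal = fit_sfs_model(data, **kw("free", "equal"), compute_ci=False, **kwargs)
    nested = [no_anc, no_rec, equal]
    full = SfsModel(
        set_name=set_name, **kw("free", "free"), compute_ci=ci, **kwargs
    ).fit(data, extra_starts=[f.named_x for f in nested]).result_
    full.lrt_pvalues = {
        "ancestral=0": lrt(no_anc, full),
        "recent=0": lrt(no_rec, full),
        "recent=ancestral": lrt(equal, full),
    }
    return full


class JointModelScan(BaseEstimator):
    """AIC scan over the 16 joint gBGC x SCU models.

    Each of B0, B1, S0, S1 is either fixed to zero or freely estimated.
    Models are ranked by AIC; when the top models are within ``aic_tie`` of
    the minimum the one with the fewest free parameters is selected.  Models
    within 0.01 AIC of the selection are reported as co-best.

    Attributes
    ----------
    scan_ : pandas.DataFrame, one row per model.
    best_ : FitResult of the selected model.
    co_best_ : list of model labels tied with the best.
    """

    def __init__(self, aic_tie: float = 2.0, n_starts: int = 3, seed: int = 0,
                 compute_ci: bool = False, fit_error: bool = True,
                 fit_demography: bool = True, maxiter: int = 500):
        self.aic_tie = aic_tie
        self.n_starts = n_starts
        self.seed = seed
        self.compute_ci = compute_ci
        self.fit_error = fit_error
        self.fit_demography = fit_demography
        self.maxiter = maxiter

    def fit(self, data: CategorySfsSet):
        if data.set_name != "joint":
            raise ValueError("joint model scan requires the 9-category set")
        rows = []
        fits = {}
        warm = []
        for mask in range(16):
            spec = {
                name: ("free" if (mask >> k) & 1 else "zero")
                for k, name in enumerate(("B0", "B1", "S0", "S1"))
            }
            label = "+".join([f for f in ("B0", "B1", "S0", "S1") if spec[f] == "free"]) or "null"
            try:
                fr = SfsModel(
                    set_name="joint",
                    b0=spec["B0"], b1=spec["B1"], s0=spec["S0"], s1=spec["S1"],
                    n_starts=self.n_starts, seed=self.seed,
                    compute_ci=False, fit_error=self.fit_error,
                    fit_demography=self.fit_demography, maxiter=self.maxiter,
                ).fit(data, extra_starts=warm).result_
                if mask == 0:
                    warm = [fr.named_x]  # seed fuller models from the null fit
            except (RuntimeError, ValueError) as exc:
                rows.append({"model": label, "failed": str(exc)})
                continue
            fits[label] = fr
            rows.append(
                {
                    "model": label,
                    "n_free": fr.n_free,
                    "loglik": fr.loglik,
                    "aic": fr.aic,
                    "B0": fr.estimates.get("B0", 0.0),
                    "B1": fr.estimates.get("B1", 0.0),
                    "S0": fr.estimates.get("S0", 0.0),
                    "S1": fr.estimates.get("S1", 0.0),
                    "failed": "",
                }
            )
        scan = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
        ok = scan[scan["failed"] == ""]
        if ok.empty:
            raise RuntimeError("all 16 model fits failed")
        amin = ok["aic"].min()
        near = ok[ok["aic"] - amin < self.aic_tie]
        chosen = near.sort_values(["n_free", "aic"]).iloc[0]
        self.scan_ = scan
        self.best_label_ = str(chosen["model"])
        self.best_ = fits[self.best_label_]
        self.co_best_ = list(
            ok.loc[abs(ok["aic"] - chosen["aic"]) < 0.01, "model"]
        )
        if self.compute_ci:
            spec = self.best_.force_spec
            self.best_ = fit_sfs_model(
                data,
                b0=spec["B0"], b1=spec["B1"], s0=spec["S0"], s1=spec["S1"],
                n_starts=self.n_starts, seed=self.seed, compute_ci=True,
                fit_error=self.fit_error, fit_demography=self.fit_demography,
                maxiter=self.maxiter,
            )
        return self


def joint_model_scan(data: CategorySfsSet, **kwargs) -> JointModelScan:
    return JointModelScan(**kwargs).fit(data)


# ---------------------------------------------------------------------------
# Li-Bulmer equilibrium utilities


def equilibrium_gc(lam: float, B: float) -> float:
    """Stationary GC content under mutation bias lambda and fixation bias B.

    GC* = 1 / (1 + lambda * exp(-B)); reduces to 1/(1 + lambda) at B = 0.
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")
    return 1.0 / (1.0 + lam * math.exp(-B))


def solve_lambda(gc_target: float, B: float) -> float:
    """Mutation bias needed to hold GC content at ``gc_target`` given B."""
    if not 0 < gc_target < 1:
        raise ValueError("GC target must lie in (0, 1)")
    return (1 - gc_target) / gc_target * math.exp(B)
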