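"""Joint model: connectivity simplex, ring-reencounter multinomials,
bivariate-normal isotope mixture, and binomial parasite-prevalence mixing.

All likelihoods are written against the natural-scale parameter containers
defined here; the unconstrained reparameterization used by the sampler lives
in :mod:`migconn.parameterization`.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from scipy.stats import norm, beta as beta_dist

from .config import PriorConfig
from .data_io import (
    IsotopeData,
    ParasiteData,
    ReencounterData,
    POPULATION_INDICES,
)

__all__ = [
    "ConnectivityParams",
    "RecoveryProbs",
    "IsotopeMixtureParams",
    "ParasiteParams",
    "ModelState",
    "DataBundle",
    "cell_probs_known",
    "loglik_known",
    "cond_cell_probs_unknown",
    "loglik_unknown",
    "isotope_loglik",
    "isotope_complete_data_loglik",
    "parasite_loglik",
    "log_prior",
    "log_posterior",
    "ALL_SOURCES",
]

ALL_SOURCES = ("rings", "isotopes", "parasites")


@dataclass
class ConnectivityParams:
    """Row-simplex of wintering proportions, built from auxiliary (0,1) variates.

    ``m[i, k] = m_star[i, k] / sum_v m_star[i, v]``; each of the eight rows
    sums to one.
    """

    m_star: np.ndarray
    m: np.ndarray = field(init=False)

    def __post_init__(self):
        self.m_star = np.asarray(self.m_star, dtype=float)
        if self.m_star.shape != (8, 4):
            raise ValueError(f"m_star must be 8x4, got {self.m_star.shape}")
        if ((self.m_star <= 0) | (self.m_star >= 1)).any():
            raise ValueError("m_star entries must lie in (0, 1)")
        self.m = self.m_star / self.m_star.sum(axis=1, keepdims=True)

    @classmethod
    def from_m(cls, m: np.ndarray) -> "ConnectivityParams":
        """Build from an explicit row-simplex (m_star set to m itself)."""
        m = np.asarray(m, dtype=float)
        if m.shape != (8, 4):
            raise ValueError(f"m must be 8x4, got {m.shape}")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-8) or (m < 0).any():
            raise ValueError("rows of m must be simplexes")
        # m itself lies in (0,1)^4 once strictly positive, so it is a valid m_star
        eps = 1e-12
        return cls(m_star=np.clip(m, eps, 1 - eps))


@dataclass
class RecoveryProbs:
    """Area-specific reencounter probabilities; Eastern is tied to Central."""

    r_ad: np.ndarray
    r_juv: np.ndarray

    def __post_init__(self):
        self.r_ad = self._expand(np.asarray(self.r_ad, dtype=float), "r_ad")
        self.r_juv = self._expand(np.asarray(self.r_juv, dtype=float), "r_juv")

    @staticmethod
    def _expand(r: np.ndarray, name: str) -> np.ndarray:
        if r.shape == (3,):  # free values (Western, Central=Eastern, Southern)
            r = np.array([r[0], r[1], r[1], r[2]])
        if r.shape != (4,):
            raise ValueError(f"{name} must have length 3 (free) or 4, got {r.shape}")
        if r[1] != r[2]:
            raise ValueError(f"{name}: Eastern must equal Central (shared parameter)")
        # closed endpoints admitted for generative edge cases; the sampler
        # itself always stays in the open interval
        if ((r < 0) | (r > 1)).any():
            raise ValueError(f"{name} entries must lie in [0, 1]")
        return r

    @property
    def free_ad(self) -> np.ndarray:
        return self.r_ad[[0, 1, 3]]

    @property
    def free_juv(self) -> np.ndarray:
        return self.r_juv[[0, 1, 3]]


@dataclass
class IsotopeMixtureParams:
    """Two-component bivariate-normal mixture on the standardized isotope scale.

    Component 0 pools Western/Central/Eastern Africa ("WCE"), component 1 is
    Southern Africa. The WCE d13C mean is tied to the Southern one through the
    non-positive offset ``theta``.
    """

    mu_s_d13c: float
    theta: float
    mu_wce_d15n: float
    mu_s_d15n: float
    sigma_c: np.ndarray  # (WCE, Southern) d13C SDs
    sigma_n: np.ndarray  # (WCE, Southern) d15N SDs
    rho: np.ndarray  # (WCE, Southern) correlations

    def __post_init__(self):
        self.sigma_c = np.asarray(self.sigma_c, dtype=float)
        self.sigma_n = np.asarray(self.sigma_n, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        for arr, name in ((self.sigma_c, "sigma_c"), (self.sigma_n, "sigma_n"), (self.rho, "rho")):
            if arr.shape != (2,):
                raise ValueError(f"{name} must have length 2 (WCE, Southern)")
        if self.theta > 0:
            raise ValueError("theta must be non-positive")
        if (self.sigma_c <= 0).any() or (self.sigma_n <= 0).any():
            raise ValueError("component SDs must be positive")
        if ((self.rho <= -1) | (self.rho >= 1)).any():
            raise ValueError("correlations must lie in (-1, 1)")

    @property
    def mu_wce_d13c(self) -> float:
        return self.mu_s_d13c + self.theta

    @property
    def means(self) -> np.ndarray:
        """2x2 matrix of component means, rows (WCE, Southern), cols (d13C, d15N)."""
        return np.array(
            [[self.mu_wce_d13c, self.mu_wce_d15n], [self.mu_s_d13c, self.mu_s_d15n]]
        )

    def covariance(self, component: int) -> np.ndarray:
        sc, sn, r = self.sigma_c[component], self.sigma_n[component], self.rho[component]
        return np.array([[sn * sn, r * sn * sc], [r * sn * sc, sc * sc]])

    @staticmethod
    def rho_from_rho0(rho0: float | np.ndarray) -> np.ndarray:
        """The (0,1) -> (-1,1) transform applied to the auxiliary beta variates."""
        return 2.0 * (np.asarray(rho0, dtype=float) - 0.5)


@dataclass
class ParasiteParams:
    """Wintering-area prevalences plus the breeding/wintering prevalence ratio."""

    f_nb: np.ndarray  # 4 areas x 5 lineages, each in (0,1)
    a: float

    def __post_init__(self):
        self.f_nb = np.asarray(self.f_nb, dtype=float)
        if self.f_nb.shape != (4, 5):
            raise ValueError(f"f_nb must be 4x5, got {self.f_nb.shape}")
        if ((self.f_nb <= 0) | (self.f_nb >= 1)).any():
            raise ValueError("f_nb entries must lie in (0, 1)")
        if self.a <= 0:
            raise ValueError("a must be positive")

    def breeding_prevalence(self, m: np.ndarray) -> np.ndarray:
        """3x5 breeding prevalences ``f_b[i,p] = a * sum_k f_nb[k,p] m[i,k]``."""
        m_pop = np.asarray(m)[list(POPULATION_INDICES), :]
        return self.a * (m_pop @ self.f_nb)


@dataclass
class ModelState:
    connectivity: ConnectivityParams
    recovery: RecoveryProbs
    isotopes: IsotopeMixtureParams
    parasites: ParasiteParams


@dataclass
class DataBundle:
    rings: ReencounterData | None = None
    isotopes: IsotopeData | None = None
    parasites: ParasiteData | None = None


# ---------------------------------------------------------------------------
# Ring-reencounter likelihoods
# ---------------------------------------------------------------------------

def cell_probs_known(m_row: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Five multinomial cell probabilities (four areas + never reencountered)."""
    m_row = np.asarray(m_row, dtype=float)
    r = np.asarray(r, dtype=float)
    p = m_row * r
    return np.append(p, 1.0 - p.sum())


def _multinomial_logpmf(counts: np.ndarray, probs: np.ndarray) -> float:
    counts = np.asarray(counts)
    probs = np.asarray(probs, dtype=float)
    n = counts.sum()
    if ((probs == 0) & (counts > 0)).any():
        return -np.inf
    coef = gammaln(n + 1) - gammaln(counts + 1).sum()
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, counts * np.log(probs), 0.0)
    return float(coef + terms.sum())


def loglik_known(R_row: np.ndarray, N: int, m_row: np.ndarray, r: np.ndarray) -> float:
    """Multinomial log-pmf of a known-total row (size N, five cells)."""
    R_row = np.asarray(R_row)
    if R_row.sum() != N:
        raise ValueError(f"counts sum to {R_row.sum()} but N={N}")
    return _multinomial_logpmf(R_row, cell_probs_known(m_row, r))


def cond_cell_probs_unknown(m_row: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Cell probabilities conditional on reencounter: ``m r`` renormalized."""
    p = np.asarray(m_row, dtype=float) * np.asarray(r, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValueError("all cell probabilities are zero; conditional undefined")
    return p / total


def loglik_unknown(R_row: np.ndarray, m_row: np.ndarray, r: np.ndarray) -> float:
    """Multinomial log-pmf with the observed reencounter total as size.

    An all-zero row carries no information and contributes exactly 0.
    """
    R_row = np.asarray(R_row)
    if R_row.sum() == 0:
        return 0.0
    return _multinomial_logpmf(R_row, cond_cell_probs_unknown(m_row, r))


# ---------------------------------------------------------------------------
# Isotope mixture likelihood
# ---------------------------------------------------------------------------

def _bvn_logpdf(y: np.ndarray, mu_c: float, mu_n: float, sigma_c: float, sigma_n: float, rho: float) -> np.ndarray:
    """Vectorized bivariate-normal log density; y is n x 2 (d13C, d15N)."""
    zc = (y[:, 0] - mu_c) / sigma_c
    zn = (y[:, 1] - mu_n) / sigma_n
    om = 1.0 - rho * rho
    if om <= 0:
        raise ValueError("correlation implies a non-positive-definite covariance")
    quad = (zc * zc - 2.0 * rho * zc * zn + zn * zn) / om
    return -np.log(2.0 * np.pi * sigma_c * sigma_n * np.sqrt(om)) - 0.5 * quad


def _mixture_weights(m: np.ndarray) -> np.ndarray:
    """3x2 matrix of per-population (WCE, Southern) mixture weights."""
    m_pop = np.asarray(m)[list(POPULATION_INDICES), :]
    return np.column_stack([m_pop[:, :3].sum(axis=1), m_pop[:, 3]])


def isotope_loglik(
    data: IsotopeData, params: IsotopeMixtureParams, connectivity: ConnectivityParams
) -> float:
    """Marginalized two-component mixture log-likelihood over all individuals."""
    y = data.standardized
    mu = params.means
    log_wce = _bvn_logpdf(y, mu[0, 0], mu[0, 1], params.sigma_c[0], params.sigma_n[0], params.rho[0])
    log_s = _bvn_logpdf(y, mu[1, 0], mu[1, 1], params.sigma_c[1], params.sigma_n[1], params.rho[1])
    v = _mixture_weights(connectivity.m)[data.pop]  # n x 2
    with np.errstate(divide="ignore"):
        lw = np.log(v)
    return float(np.logaddexp(lw[:, 0] + log_wce, lw[:, 1] + log_s).sum())


def isotope_complete_data_loglik(
    data: IsotopeData,
    params: IsotopeMixtureParams,
    connectivity: ConnectivityParams,
    w: np.ndarray,
) -> float:
    """Joint log density of the data and a latent assignment vector ``w``.

    ``w[j]`` is 0 for the pooled WCE component and 1 for Southern Africa.
    Averaging ``exp(complete - assignment prior)`` over ``w ~ Categorical(v)``
    recovers the marginalized likelihood, which is how the two evaluation
    modes are cross-checked.
    """
    w = np.asarray(w)
    y = data.standardized
    mu = params.means
    out = np.empty(data.n)
    for comp in (0, 1):
        mask = w == comp
        if mask.any():
            out[mask] = _bvn_logpdf(
                y[mask], mu[comp, 0], mu[comp, 1],
                params.sigma_c[comp], params.sigma_n[comp], params.rho[comp],
            )
    v = _mixture_weights(connectivity.m)[data.pop]
    chosen = v[np.arange(data.n), w]
    if (chosen == 0).any():
        return -np.inf
    return float(out.sum() + np.log(chosen).sum())


# ---------------------------------------------------------------------------
# Parasite likelihood
# ---------------------------------------------------------------------------

def _binomial_logpmf_sum(G: np.ndarray, H: np.ndarray, f: np.ndarray) -> float:
    if ((f <= 0) | (f >= 1)).any():
        valid = (f > 0) & (f < 1)
        # cells with no samples are vacuous whatever f is
        if (~valid & (H > 0)).any():
            return -np.inf
        f = np.where(valid, f, 0.5)
    coef = gammaln(H + 1) - gammaln(G + 1) - gammaln(H - G + 1)
    return float((coef + G * np.log(f) + (H - G) * np.log1p(-f)).sum())


def parasite_loglik(
    data: ParasiteData, params: ParasiteParams, connectivity: ConnectivityParams
) -> float:
    """Binomial log-likelihood of wintering and breeding infection tables."""
    f_b = params.breeding_prevalence(connectivity.m)
    ll = _binomial_logpmf_sum(data.G_nb, data.H_nb, params.f_nb)
    ll += _binomial_logpmf_sum(data.G_b, data.H_b, f_b)
    return ll


# ---------------------------------------------------------------------------
# Priors and joint posterior (natural scale)
# ---------------------------------------------------------------------------

def _half_normal_logpdf(x: float | np.ndarray, sd: float) -> np.ndarray:
    return np.log(2.0) + norm.logpdf(x, scale=sd)


def log_prior(state: ModelState, priors: PriorConfig | None = None) -> float:
    """Joint log prior density on the natural scale; -inf outside support.

    Flat Beta(1,1) on every ``m_star`` and Uniform(0,1) on ``r`` and ``f_nb``
    contribute constants; the informative terms are the isotope means, the
    correlation transforms, the SD priors and the half-normal on ``a``.
    """
    pc = priors or PriorConfig()
    c, iso, par = state.connectivity, state.isotopes, state.parasites
    if ((c.m_star <= 0) | (c.m_star >= 1)).any():
        return -np.inf
    for r in (state.recovery.r_ad, state.recovery.r_juv):
        if ((r < 0) | (r > 1)).any():
            return -np.inf
    if iso.theta > 0 or state.parasites.a <= 0:
        return -np.inf
    if ((par.f_nb <= 0) | (par.f_nb >= 1)).any():
        return -np.inf
    rho0 = iso.rho / 2.0 + 0.5
    if ((rho0 <= 0) | (rho0 >= 1)).any():
        return -np.inf

    lp = 0.0
    lp += norm.logpdf(iso.mu_s_d13c, loc=pc.mu_s_d13c_mean, scale=pc.mu_s_d13c_sd)
    lp += _half_normal_logpdf(-iso.theta, pc.theta_sd)
    lp += norm.logpdf(iso.mu_wce_d15n, scale=pc.mu_d15n_sd)
    lp += norm.logpdf(iso.mu_s_d15n, scale=pc.mu_d15n_sd)
    # rho = 2*(rho0 - 0.5): constant Jacobian 1/2 per component
    lp += beta_dist.logpdf(rho0[0], *pc.rho0_wce_beta) + np.log(0.5)
    lp += beta_dist.logpdf(rho0[1], *pc.rho0_southern_beta) + np.log(0.5)
    lp += _half_normal_logpdf(iso.sigma_c, pc.sigma_sd).sum()
    lp += _half_normal_logpdf(iso.sigma_n, pc.sigma_sd).sum()
    lp += _half_normal_logpdf(par.a, pc.a_sd)
    return float(lp)


def log_posterior(
    state: ModelState,
    data: DataBundle,
    active_sources=ALL_SOURCES,
    priors: PriorConfig | None = None,
) -> float:
    """Log prior plus the log-likelihoods of every active data source."""
    active = tuple(active_sources)
    if not active:
        raise ValueError("at least one data source must be active")
    unknown = set(active) - set(ALL_SOURCES)
    if unknown:
        raise ValueError(f"unknown data sources: {sorted(unknown)}")

    lp = log_prior(state, priors)
    if not np.isfinite(lp):
        return -np.inf
    m = state.connectivity.m
    if "rings" in active:
        if data.rings is None:
            raise ValueError("rings active but no reencounter data supplied")
        rd = data.rings
        for i in range(8):
            lp += loglik_known(rd.R_ad_known[i], rd.N_ad[i], m[i], state.recovery.r_ad)
            lp += loglik_known(rd.R_juv_known[i], rd.N_juv[i], m[i], state.recovery.r_juv)
            lp += loglik_unknown(rd.R_ad_unknown[i], m[i], state.recovery.r_ad)
            lp += loglik_unknown(rd.R_juv_unknown[i], m[i], state.recovery.r_juv)
    if "isotopes" in active:
        if data.isotopes is None:
            raise ValueError("isotopes active but no isotope data supplied")
        lp += isotope_loglik(data.isotopes, state.isotopes, state.connectivity)
    if "parasites" in active:
        if data.parasites is None:
            raise ValueError("parasites active but no parasite data supplied")
        f_b = state.parasites.breeding_prevalence(m)
        if ((f_b >= 1) & (data.parasites.H_b > 0)).any():
            return -np.inf
        lp += parasite_loglik(data.parasites, state.parasites, state.connectivity)
    return float(lp)
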