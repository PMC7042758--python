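"""Posterior sampling, convergence diagnostics, and posterior summaries.

The sampler is an adaptive Metropolis-within-Gibbs on unconstrained scales
(logit for probabilities and the correlation auxiliaries, log for SDs and the
prevalence ratio) with Jacobian corrections, run vectorized across chains.
Block updates exploit the separability of the joint density: the eight
connectivity rows are conditionally independent given everything else, as are
the five parasite-lineage columns, so each group is proposed and
accepted/rejected in a single vectorized step.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import betaln, gammaln

from .config import ModelConfig, PriorConfig
from .data_io import AREAS, GROUPS, POPULATION_INDICES
from .model import ALL_SOURCES, DataBundle

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PosteriorDraws",
    "run_mcmc",
    "gelman_rubin",
    "summarize",
    "sample_prior",
    "parameter_names",
]

_R_LABELS = ("Western", "CentralEastern", "Southern")
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass(frozen=True)
class SamplerConfig:
    """Chain protocol; defaults mirror the study's fitting protocol."""

    n_chains: int = 3
    n_iter: int = 120_000
    burn_in: int = 60_000
    thin: int = 6
    seed: int = 0
    init_step: float = 0.3
    adapt_decay: float = 0.6
    max_init_tries: int = 100
    init_candidates: int = 300

    def __post_init__(self):
        if self.burn_in >= self.n_iter:
            raise ValueError("burn_in must be smaller than n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_chains < 2:
            raise ValueError("need at least 2 chains for convergence diagnostics")

    @property
    def n_kept(self) -> int:
        return (self.n_iter - self.burn_in) // self.thin


def parameter_names(lineages=None) -> list[str]:
    """Canonical ordering of the sampled natural-scale parameters."""
    from .data_io import DEFAULT_LINEAGES

    lineages = tuple(lineages) if lineages is not None else DEFAULT_LINEAGES
    names = [f"m[{g.value},{a.value}]" for g in GROUPS for a in AREAS]
    names += [f"r_ad[{lab}]" for lab in _R_LABELS]
    names += [f"r_juv[{lab}]" for lab in _R_LABELS]
    names += ["mu_d13C[Southern]", "theta", "mu_d15N[WCE]", "mu_d15N[Southern]"]
    names += ["sigma_d13C[WCE]", "sigma_d15N[WCE]", "sigma_d13C[Southern]", "sigma_d15N[Southern]"]
    names += ["rho[WCE]", "rho[Southern]"]
    names += [f"f_nb[{a.value},{p}]" for a in AREAS for p in lineages]
    names += ["a"]
    return names


@dataclass
class PosteriorDraws:
    """Chain-structured posterior draws of the named natural-scale parameters."""

    draws: np.ndarray  # (n_chains, n_kept, n_params)
    names: list[str]
    config: SamplerConfig
    acceptance: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.draws.ndim != 3 or self.draws.shape[2] != len(self.names):
            raise ValueError("draws must be (chains, iterations, parameters)")
        self._index = {n: i for i, n in enumerate(self.names)}

    def get(self, name: str) -> np.ndarray:
        """(chains, kept) array for one parameter."""
        if name not in self._index:
            raise KeyError(f"unknown parameter {name!r}")
        return self.draws[:, :, self._index[name]]

    def flat(self, name: str) -> np.ndarray:
        return self.get(name).reshape(-1)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        C, K, P = self.draws.shape
        df = pd.DataFrame(self.draws.reshape(C * K, P), columns=self.names)
        df.insert(0, "iteration", np.tile(np.arange(K), C))
        df.insert(0, "chain", np.repeat(np.arange(C), K))
        return df

    def save(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def load(cls, path, config: SamplerConfig | None = None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        chains = sorted(df["chain"].unique())
        names = [c for c in df.columns if c not in ("chain", "iteration")]
        arrs = [df[df["chain"] == c][names].to_numpy() for c in chains]
        draws = np.stack(arrs)
        cfg = config or SamplerConfig(
            n_chains=len(chains), n_iter=2 * draws.shape[1], burn_in=draws.shape[1], thin=1
        )
        return cls(draws=draws, names=names, config=cfg)


# ---------------------------------------------------------------------------
# Prior sampling (natural scale) — also the diagnostics prior reference
# ---------------------------------------------------------------------------

def sample_prior(
    priors: PriorConfig | None = None,
    n: int = 10_000,
    rng: np.random.Generator | int | None = None,
    lineages=None,
) -> pd.DataFrame:
    """Independent draws of every named parameter from its prior.

    Connectivity rows are drawn through the auxiliary construction
    (iid Uniform(0,1) variates, row-normalized).
    """
    pc = priors or PriorConfig()
    rng = np.random.default_rng(rng)
    m_star = rng.uniform(size=(n, 8, 4))
    m = m_star / m_star.sum(axis=2, keepdims=True)
    cols: dict[str, np.ndarray] = {}
    names = parameter_names(lineages)
    m_flat = m.reshape(n, 32)
    for j, name in enumerate(names[:32]):
        cols[name] = m_flat[:, j]
    for j, lab in enumerate(_R_LABELS):
        cols[f"r_ad[{lab}]"] = rng.uniform(size=n)
        cols[f"r_juv[{lab}]"] = rng.uniform(size=n)
    cols["mu_d13C[Southern]"] = rng.normal(pc.mu_s_d13c_mean, pc.mu_s_d13c_sd, size=n)
    cols["theta"] = -np.abs(rng.normal(0.0, pc.theta_sd, size=n))
    cols["mu_d15N[WCE]"] = rng.normal(0.0, pc.mu_d15n_sd, size=n)
    cols["mu_d15N[Southern]"] = rng.normal(0.0, pc.mu_d15n_sd, size=n)
    for name in names[42:46]:
        cols[name] = np.abs(rng.normal(0.0, pc.sigma_sd, size=n))
    cols["rho[WCE]"] = 2.0 * (rng.beta(*pc.rho0_wce_beta, size=n) - 0.5)
    cols["rho[Southern]"] = 2.0 * (rng.beta(*pc.rho0_southern_beta, size=n) - 0.5)
    for name in names[48:68]:
        cols[name] = rng.uniform(size=n)
    cols["a"] = np.abs(rng.normal(0.0, pc.a_sd, size=n))
    return pd.DataFrame(cols)[names]


# ---------------------------------------------------------------------------
# Vectorized joint sampler
# ---------------------------------------------------------------------------

def _sigmoid(z):
    return 1.0 / (1.0 + np.exp(-z))


def _log_jac_logit(z):
    # log s(z) + log(1 - s(z)), numerically stable
    return -np.logaddexp(0.0, z) - np.logaddexp(0.0, -z)


class _Sampler:
    """Internal vectorized state; one instance per run_mcmc call."""

    POP = list(POPULATION_INDICES)

    def __init__(self, data: DataBundle, model_config: ModelConfig, cfg: SamplerConfig, active):
        self.cfg = cfg
        self.pc = model_config.priors
        self.active = tuple(active)
        self.rng = np.random.default_rng(cfg.seed)
        self.C = cfg.n_chains
        self.rings = data.rings if "rings" in self.active else None
        self.iso = data.isotopes if "isotopes" in self.active else None
        self.par = data.parasites if "parasites" in self.active else None
        if "rings" in self.active and self.rings is None:
            raise ValueError("rings active but no reencounter data supplied")
        if "isotopes" in self.active and self.iso is None:
            raise ValueError("isotopes active but no isotope data supplied")
        if "parasites" in self.active and self.par is None:
            raise ValueError("parasites active but no parasite data supplied")
        self._setup_data()
        self._init_chains()
        self._setup_adaptation()

    # -- data constants -----------------------------------------------------
    def _setup_data(self):
        if self.rings is not None:
            rd = self.rings
            self.RkA, self.RkJ = rd.R_ad_known.astype(float), rd.R_juv_known.astype(float)
            self.RuA, self.RuJ = rd.R_ad_unknown.astype(float), rd.R_juv_unknown.astype(float)
            self.ckA = gammaln(self.RkA.sum(1) + 1) - gammaln(self.RkA + 1).sum(1)
            self.ckJ = gammaln(self.RkJ.sum(1) + 1) - gammaln(self.RkJ + 1).sum(1)
            self.cuA = gammaln(self.RuA.sum(1) + 1) - gammaln(self.RuA + 1).sum(1)
            self.cuJ = gammaln(self.RuJ.sum(1) + 1) - gammaln(self.RuJ + 1).sum(1)
        if self.iso is not None:
            self.Y = self.iso.standardized
            self.pop = self.iso.pop
            self.n_iso = self.Y.shape[0]
        if self.par is not None:
            pr = self.par
            self.Gnb, self.Hnb = pr.G_nb.astype(float), pr.H_nb.astype(float)
            self.Gb, self.Hb = pr.G_b.astype(float), pr.H_b.astype(float)
            self.cnb = gammaln(self.Hnb + 1) - gammaln(self.Gnb + 1) - gammaln(self.Hnb - self.Gnb + 1)
            self.cb = gammaln(self.Hb + 1) - gammaln(self.Gb + 1) - gammaln(self.Hb - self.Gb + 1)
        pc = self.pc
        self.betaln_wce = betaln(*pc.rho0_wce_beta)
        self.betaln_s = betaln(*pc.rho0_southern_beta)

    # -- prior densities on the unconstrained scale -------------------------
    def _prior_m_rows(self, z_m):  # (C,8,4) -> (C,8)
        return _log_jac_logit(z_m).sum(axis=2)

    def _prior_r(self, z_r):  # (C,3) -> (C,)
        return _log_jac_logit(z_r).sum(axis=1)

    def _prior_means(self, mu_sc, u_theta, mu_wn, mu_sn):
        pc = self.pc
        lp = -0.5 * ((mu_sc - pc.mu_s_d13c_mean) / pc.mu_s_d13c_sd) ** 2 - np.log(pc.mu_s_d13c_sd) - _HALF_LOG_2PI
        # theta = -exp(u): half-normal density on |theta| plus log-Jacobian u
        th = np.exp(u_theta)
        lp += np.log(2.0) - 0.5 * (th / pc.theta_sd) ** 2 - np.log(pc.theta_sd) - _HALF_LOG_2PI + u_theta
        lp += -0.5 * (mu_wn / pc.mu_d15n_sd) ** 2 - np.log(pc.mu_d15n_sd) - _HALF_LOG_2PI
        lp += -0.5 * (mu_sn / pc.mu_d15n_sd) ** 2 - np.log(pc.mu_d15n_sd) - _HALF_LOG_2PI
        return lp

    def _prior_scales(self, log_sigma, z_rho0):  # (C,4), (C,2) -> (C,)
        pc = self.pc
        sig = np.exp(log_sigma)
        lp = (
            np.log(2.0)
            - 0.5 * (sig / pc.sigma_sd) ** 2
            - np.log(pc.sigma_sd)
            - _HALF_LOG_2PI
            + log_sigma
        ).sum(axis=1)
        aw, bw = pc.rho0_wce_beta
        as_, bs = pc.rho0_southern_beta
        ls0 = -np.logaddexp(0.0, -z_rho0)  # log sigmoid
        ls1 = -np.logaddexp(0.0, z_rho0)  # log(1 - sigmoid)
        lp += aw * ls0[:, 0] + bw * ls1[:, 0] - self.betaln_wce
        lp += as_ * ls0[:, 1] + bs * ls1[:, 1] - self.betaln_s
        return lp

    def _prior_f_cols(self, z_f):  # (C,4,5) -> (C,5)
        return _log_jac_logit(z_f).sum(axis=1)

    def _prior_a(self, log_a):
        pc = self.pc
        a = np.exp(log_a)
        return np.log(2.0) - 0.5 * (a / pc.a_sd) ** 2 - np.log(pc.a_sd) - _HALF_LOG_2PI + log_a

    # -- likelihood terms ----------------------------------------------------
    def _ring_known_rows(self, m, r4, R, const):
        """(C,8,4) x (C,4) against an (8,5) count matrix -> (C,8)."""
        P = m * r4[:, None, :]
        p5 = 1.0 - P.sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            ll = const[None, :] + (R[None, :, :4] * np.log(P)).sum(axis=2)
            ll = np.where(p5 > 0, ll + R[None, :, 4] * np.log(np.where(p5 > 0, p5, 1.0)), -np.inf)
        return ll

    def _ring_unknown_rows(self, m, r4, R, const):
        P = m * r4[:, None, :]
        Q = P / P.sum(axis=2, keepdims=True)
        return const[None, :] + (R[None, :, :] * np.log(Q)).sum(axis=2)

    def _iso_phis(self, mu_sc, theta, mu_wn, mu_sn, sig, rho):
        """Component log densities for all individuals; sig (C,4), rho (C,2)."""
        Yc, Yn = self.Y[:, 0], self.Y[:, 1]
        out = []
        mus = ((mu_sc + theta, mu_wn, sig[:, 0], sig[:, 1], rho[:, 0]),
               (mu_sc, mu_sn, sig[:, 2], sig[:, 3], rho[:, 1]))
        for mc, mn, sc, sn, rh in mus:
            zc = (Yc[None, :] - mc[:, None]) / sc[:, None]
            zn = (Yn[None, :] - mn[:, None]) / sn[:, None]
            om = 1.0 - rh * rh
            quad = zc * zc - 2.0 * rh[:, None] * zc * zn + zn * zn
            out.append(
                -np.log(2.0 * np.pi * sc * sn * np.sqrt(om))[:, None] - 0.5 * quad / om[:, None]
            )
        return out  # [phi_wce, phi_s], each (C, n)

    def _iso_contrib(self, m, phi_wce, phi_s):
        m_pop = m[:, self.POP, :]
        v1 = m_pop[:, :, :3].sum(axis=2)  # (C,3)
        v2 = m_pop[:, :, 3]
        lw1 = np.log(v1)[:, self.pop_cols]  # advanced-indexed per individual
        lw2 = np.log(v2)[:, self.pop_cols]
        return np.logaddexp(lw1 + phi_wce, lw2 + phi_s)  # (C, n)

    def _par_b_cells(self, m, f_nb, a):
        f_b = a[:, None, None] * np.einsum("cik,ckp->cip", m[:, self.POP, :], f_nb)
        bad = f_b >= 1.0
        f_b = np.clip(f_b, 1e-300, 1.0 - 1e-16)
        ll = self.cb[None] + self.Gb[None] * np.log(f_b) + (self.Hb[None] - self.Gb[None]) * np.log1p(-f_b)
        return np.where(bad & (self.Hb[None] > 0), -np.inf, ll)  # (C,3,5)

    def _par_nb_cells(self, f_nb):
        return self.cnb[None] + self.Gnb[None] * np.log(f_nb) + (self.Hnb[None] - self.Gnb[None]) * np.log1p(-f_nb)

    # -- initialization ------------------------------------------------------
    def _draw_prior_init(self, C):
        """One prior draw of every unconstrained coordinate for C chains."""
        pc, rng = self.pc, self.rng

        def logit_u(shape):
            u = rng.uniform(size=shape)
            return np.log(u) - np.log1p(-u)

        r0 = np.column_stack(
            [rng.beta(*pc.rho0_wce_beta, size=C), rng.beta(*pc.rho0_southern_beta, size=C)]
        )
        return dict(
            z_m=logit_u((C, 8, 4)),
            z_r_ad=logit_u((C, 3)),
            z_r_juv=logit_u((C, 3)),
            mu_sc=rng.normal(pc.mu_s_d13c_mean, pc.mu_s_d13c_sd, size=C),
            u_theta=np.log(np.abs(rng.normal(0, pc.theta_sd, size=C)) + 1e-12),
            mu_wn=rng.normal(0, pc.mu_d15n_sd, size=C),
            mu_sn=rng.normal(0, pc.mu_d15n_sd, size=C),
            log_sigma=np.log(np.abs(rng.normal(0, pc.sigma_sd, size=(C, 4))) + 1e-6),
            z_rho0=np.log(r0) - np.log1p(-r0),
            z_f=logit_u((C, 4, 5)),
            log_a=np.log(np.abs(rng.normal(0, pc.a_sd, size=C)) + 1e-12),
        )

    _INIT_KEYS = (
        "z_m", "z_r_ad", "z_r_juv", "mu_sc", "u_theta", "mu_wn", "mu_sn",
        "log_sigma", "z_rho0", "z_f", "log_a",
    )

    def _init_chains(self):
        C = self.C
        if self.iso is not None:
            self.pop_cols = self.pop  # alias used by advanced indexing
        for key, val in self._draw_prior_init(C).items():
            setattr(self, key, val)
        self._refresh_all()
        # re-draw only the chains whose starting density is not finite (with a
        # half-normal prior on the prevalence ratio, derived breeding
        # prevalences >= 1 are common under prior draws)
        for attempt in range(self.cfg.max_init_tries):
            bad = ~np.isfinite(self._total_loglik())
            if not bad.any():
                break
            fresh = self._draw_prior_init(int(bad.sum()))
            for key in self._INIT_KEYS:
                getattr(self, key)[bad] = fresh[key]
            self._refresh_all()
        else:
            raise RuntimeError("no finite starting point found after bounded retries")
        # among further prior draws, keep the best starting density per chain;
        # this shortens the long walk from a prior draw (r ~ 0.5) to the
        # posterior bulk (r possibly ~ 1e-4) without informing from data
        best = {k: getattr(self, k).copy() for k in self._INIT_KEYS}
        best_lp = self._total_loglik()
        for _ in range(self.cfg.init_candidates):
            fresh = self._draw_prior_init(C)
            for key in self._INIT_KEYS:
                setattr(self, key, fresh[key])
            self._refresh_all()
            lp = self._total_loglik()
            better = np.isfinite(lp) & (lp > best_lp)
            if better.any():
                best_lp = np.where(better, lp, best_lp)
                for key in self._INIT_KEYS:
                    arr = best[key]
                    arr[better] = fresh[key][better]
        for key in self._INIT_KEYS:
            setattr(self, key, best[key])
        self._refresh_all()

    def _refresh_all(self):
        """Recompute every natural-scale cache and likelihood term."""
        ms = _sigmoid(self.z_m)
        self.m = ms / ms.sum(axis=2, keepdims=True)
        r3a, r3j = _sigmoid(self.z_r_ad), _sigmoid(self.z_r_juv)
        self.r_ad4 = r3a[:, [0, 1, 1, 2]]
        self.r_juv4 = r3j[:, [0, 1, 1, 2]]
        self.theta = -np.exp(self.u_theta)
        self.sigma = np.exp(self.log_sigma)
        self.rho = 2.0 * (_sigmoid(self.z_rho0) - 0.5)
        self.f_nb = _sigmoid(self.z_f)
        self.a = np.exp(self.log_a)

        self.prior_m = self._prior_m_rows(self.z_m)
        self.prior_r_ad = self._prior_r(self.z_r_ad)
        self.prior_r_juv = self._prior_r(self.z_r_juv)
        self.prior_means = self._prior_means(self.mu_sc, self.u_theta, self.mu_wn, self.mu_sn)
        self.prior_scales = self._prior_scales(self.log_sigma, self.z_rho0)
        self.prior_f = self._prior_f_cols(self.z_f)
        self.prior_a = self._prior_a(self.log_a)

        if self.rings is not None:
            self.llkA = self._ring_known_rows(self.m, self.r_ad4, self.RkA, self.ckA)
            self.llkJ = self._ring_known_rows(self.m, self.r_juv4, self.RkJ, self.ckJ)
            self.lluA = self._ring_unknown_rows(self.m, self.r_ad4, self.RuA, self.cuA)
            self.lluJ = self._ring_unknown_rows(self.m, self.r_juv4, self.RuJ, self.cuJ)
        if self.iso is not None:
            self.phi_wce, self.phi_s = self._iso_phis(
                self.mu_sc, self.theta, self.mu_wn, self.mu_sn, self.sigma, self.rho
            )
            self.contrib = self._iso_contrib(self.m, self.phi_wce, self.phi_s)
        if self.par is not None:
            self.ll_nb_cells = self._par_nb_cells(self.f_nb)
            self.ll_b_cells = self._par_b_cells(self.m, self.f_nb, self.a)

    def _total_loglik(self):
        tot = np.zeros(self.C)
        if self.rings is not None:
            tot += self.llkA.sum(1) + self.llkJ.sum(1) + self.lluA.sum(1) + self.lluJ.sum(1)
        if self.iso is not None:
            tot += self.contrib.sum(1)
        if self.par is not None:
            tot += self.ll_nb_cells.sum((1, 2)) + self.ll_b_cells.sum((1, 2))
        return tot

    # -- adaptation ----------------------------------------------------------
    def _setup_adaptation(self):
        C, s = self.C, np.log(self.cfg.init_step)
        self.ls = {
            "m": np.full((C, 8), s),
            "r_ad": np.full(C, s),
            "r_juv": np.full(C, s),
            "means": np.full(C, s),
            "scales": np.full(C, s),
            "f": np.full((C, 5), s),
            "a": np.full(C, s + 0.5),
            "ridge": np.full(C, s),
        }
        self.targets = {
            "m": 0.28, "r_ad": 0.3, "r_juv": 0.3, "means": 0.28,
            "scales": 0.25, "f": 0.28, "a": 0.44, "ridge": 0.28,
        }
        self.acc_sums = {k: 0.0 for k in self.ls}
        self.acc_n = {k: 0 for k in self.ls}

    def _adapt(self, key, alpha, t):
        if t < self.cfg.burn_in:
            gamma = (t + 10.0) ** (-self.cfg.adapt_decay)
            self.ls[key] += gamma * (alpha - self.targets[key])
        self.acc_sums[key] += alpha.mean()
        self.acc_n[key] += 1

    # -- block updates -------------------------------------------------------
    def _update_m(self, t):
        C = self.C
        step = np.exp(self.ls["m"])[:, :, None]
        z_new = self.z_m + step * self.rng.normal(size=(C, 8, 4))
        ms = _sigmoid(z_new)
        m_new = ms / ms.sum(axis=2, keepdims=True)
        prior_new = self._prior_m_rows(z_new)
        delta = prior_new - self.prior_m  # (C,8)

        if self.rings is not None:
            llkA_n = self._ring_known_rows(m_new, self.r_ad4, self.RkA, self.ckA)
            llkJ_n = self._ring_known_rows(m_new, self.r_juv4, self.RkJ, self.ckJ)
            lluA_n = self._ring_unknown_rows(m_new, self.r_ad4, self.RuA, self.cuA)
            lluJ_n = self._ring_unknown_rows(m_new, self.r_juv4, self.RuJ, self.cuJ)
            delta = delta + (llkA_n - self.llkA) + (llkJ_n - self.llkJ)
            delta = delta + (lluA_n - self.lluA) + (lluJ_n - self.lluJ)
        if self.iso is not None:
            contrib_n = self._iso_contrib(m_new, self.phi_wce, self.phi_s)
            d_ind = contrib_n - self.contrib  # (C, n)
            # aggregate per population, scatter onto the owning m rows
            for p_idx, g_idx in enumerate(self.POP):
                delta[:, g_idx] += d_ind[:, self.pop == p_idx].sum(axis=1)
        if self.par is not None:
            llb_n = self._par_b_cells(m_new, self.f_nb, self.a)
            d_rows = (llb_n - self.ll_b_cells).sum(axis=2)  # (C,3)
            for p_idx, g_idx in enumerate(self.POP):
                delta[:, g_idx] += d_rows[:, p_idx]

        with np.errstate(invalid="ignore"):
            alpha = np.exp(np.minimum(delta, 0.0))
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
        accept = self.rng.uniform(size=(C, 8)) < alpha  # (C,8)
        acc3 = accept[:, :, None]
        self.z_m = np.where(acc3, z_new, self.z_m)
        self.m = np.where(acc3, m_new, self.m)
        self.prior_m = np.where(accept, prior_new, self.prior_m)
        if self.rings is not None:
            self.llkA = np.where(accept, llkA_n, self.llkA)
            self.llkJ = np.where(accept, llkJ_n, self.llkJ)
            self.lluA = np.where(accept, lluA_n, self.lluA)
            self.lluJ = np.where(accept, lluJ_n, self.lluJ)
        if self.iso is not None:
            acc_pop = accept[:, self.POP]  # (C,3)
            acc_ind = acc_pop[:, self.pop]  # (C,n)
            self.contrib = np.where(acc_ind, contrib_n, self.contrib)
        if self.par is not None:
            acc_pop = accept[:, self.POP]
            self.ll_b_cells = np.where(acc_pop[:, :, None], llb_n, self.ll_b_cells)
        self._adapt("m", alpha, t)

    def _update_r(self, age, t):
        key = f"r_{age}"
        z_old = self.z_r_ad if age == "ad" else self.z_r_juv
        step = np.exp(self.ls[key])[:, None]
        z_new = z_old + step * self.rng.normal(size=z_old.shape)
        r4_new = _sigmoid(z_new)[:, [0, 1, 1, 2]]
        prior_new = self._prior_r(z_new)
        delta = prior_new - (self.prior_r_ad if age == "ad" else self.prior_r_juv)
        if self.rings is not None:
            Rk, ck = (self.RkA, self.ckA) if age == "ad" else (self.RkJ, self.ckJ)
            Ru, cu = (self.RuA, self.cuA) if age == "ad" else (self.RuJ, self.cuJ)
            llk_n = self._ring_known_rows(self.m, r4_new, Rk, ck)
            llu_n = self._ring_unknown_rows(self.m, r4_new, Ru, cu)
            llk_o = self.llkA if age == "ad" else self.llkJ
            llu_o = self.lluA if age == "ad" else self.lluJ
            delta = delta + (llk_n - llk_o).sum(1) + (llu_n - llu_o).sum(1)
        with np.errstate(invalid="ignore"):
            alpha = np.exp(np.minimum(delta, 0.0))
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
        accept = self.rng.uniform(size=self.C) < alpha
        accN = accept[:, None]
        if age == "ad":
            self.z_r_ad = np.where(accN, z_new, self.z_r_ad)
            self.r_ad4 = np.where(accN, r4_new, self.r_ad4)
            self.prior_r_ad = np.where(accept, prior_new, self.prior_r_ad)
            if self.rings is not None:
                self.llkA = np.where(accN, llk_n, self.llkA)
                self.lluA = np.where(accN, llu_n, self.lluA)
        else:
            self.z_r_juv = np.where(accN, z_new, self.z_r_juv)
            self.r_juv4 = np.where(accN, r4_new, self.r_juv4)
            self.prior_r_juv = np.where(accept, prior_new, self.prior_r_juv)
            if self.rings is not None:
                self.llkJ = np.where(accN, llk_n, self.llkJ)
                self.lluJ = np.where(accN, llu_n, self.lluJ)
        self._adapt(key, alpha, t)

    def _update_iso_block(self, which, t):
        C = self.C
        step = np.exp(self.ls[which])
        if which == "means":
            noise = step[:, None] * self.rng.normal(size=(C, 4))
            mu_sc = self.mu_sc + noise[:, 0]
            u_th = self.u_theta + noise[:, 1]
            mu_wn = self.mu_wn + noise[:, 2]
            mu_sn = self.mu_sn + noise[:, 3]
            log_sigma, z_rho0 = self.log_sigma, self.z_rho0
            prior_new = self._prior_means(mu_sc, u_th, mu_wn, mu_sn)
            prior_old = self.prior_means
        else:
            noise = step[:, None] * self.rng.normal(size=(C, 6))
            mu_sc, u_th, mu_wn, mu_sn = self.mu_sc, self.u_theta, self.mu_wn, self.mu_sn
            log_sigma = self.log_sigma + noise[:, :4]
            z_rho0 = self.z_rho0 + noise[:, 4:]
            prior_new = self._prior_scales(log_sigma, z_rho0)
            prior_old = self.prior_scales
        delta = prior_new - prior_old
        if self.iso is not None:
            theta = -np.exp(u_th)
            sigma = np.exp(log_sigma)
            rho = 2.0 * (_sigmoid(z_rho0) - 0.5)
            phi_w, phi_s = self._iso_phis(mu_sc, theta, mu_wn, mu_sn, sigma, rho)
            contrib_n = self._iso_contrib(self.m, phi_w, phi_s)
            delta = delta + (contrib_n - self.contrib).sum(1)
        with np.errstate(invalid="ignore"):
            alpha = np.exp(np.minimum(delta, 0.0))
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
        accept = self.rng.uniform(size=C) < alpha
        accN = accept[:, None]
        if which == "means":
            self.mu_sc = np.where(accept, mu_sc, self.mu_sc)
            self.u_theta = np.where(accept, u_th, self.u_theta)
            self.mu_wn = np.where(accept, mu_wn, self.mu_wn)
            self.mu_sn = np.where(accept, mu_sn, self.mu_sn)
            self.theta = -np.exp(self.u_theta)
            self.prior_means = np.where(accept, prior_new, self.prior_means)
        else:
            self.log_sigma = np.where(accN, log_sigma, self.log_sigma)
            self.z_rho0 = np.where(accN, z_rho0, self.z_rho0)
            self.sigma = np.exp(self.log_sigma)
            self.rho = 2.0 * (_sigmoid(self.z_rho0) - 0.5)
            self.prior_scales = np.where(accept, prior_new, self.prior_scales)
        if self.iso is not None:
            self.phi_wce = np.where(accN, phi_w, self.phi_wce)
            self.phi_s = np.where(accN, phi_s, self.phi_s)
            self.contrib = np.where(accN, contrib_n, self.contrib)
        self._adapt(which, alpha, t)

    def _update_f(self, t):
        C = self.C
        step = np.exp(self.ls["f"])[:, None, :]  # (C,1,5)
        z_new = self.z_f + step * self.rng.normal(size=(C, 4, 5))
        f_new = _sigmoid(z_new)
        prior_new = self._prior_f_cols(z_new)
        delta = prior_new - self.prior_f  # (C,5)
        if self.par is not None:
            llnb_n = self._par_nb_cells(f_new)
            llb_n = self._par_b_cells(self.m, f_new, self.a)
            delta = delta + (llnb_n - self.ll_nb_cells).sum(1) + (llb_n - self.ll_b_cells).sum(1)
        with np.errstate(invalid="ignore"):
            alpha = np.exp(np.minimum(delta, 0.0))
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
        accept = self.rng.uniform(size=(C, 5)) < alpha  # per lineage column
        accCol = accept[:, None, :]
        self.z_f = np.where(accCol, z_new, self.z_f)
        self.f_nb = np.where(accCol, f_new, self.f_nb)
        self.prior_f = np.where(accept, prior_new, self.prior_f)
        if self.par is not None:
            self.ll_nb_cells = np.where(accCol, llnb_n, self.ll_nb_cells)
            self.ll_b_cells = np.where(accCol, llb_n, self.ll_b_cells)
        self._adapt("f", alpha, t)

    def _update_a(self, t):
        C = self.C
        la_new = self.log_a + np.exp(self.ls["a"]) * self.rng.normal(size=C)
        a_new = np.exp(la_new)
        prior_new = self._prior_a(la_new)
        delta = prior_new - self.prior_a
        if self.par is not None:
            llb_n = self._par_b_cells(self.m, self.f_nb, a_new)
            delta = delta + (llb_n - self.ll_b_cells).sum((1, 2))
        with np.errstate(invalid="ignore"):
            alpha = np.exp(np.minimum(delta, 0.0))
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
        accept = self.rng.uniform(size=C) < alpha
        self.log_a = np.where(accept, la_new, self.log_a)
        self.a = np.exp(self.log_a)
        self.prior_a = np.where(accept, prior_new, self.prior_a)
        if self.par is not None:
            self.ll_b_cells = np.where(accept[:, None, None], llb_n, self.ll_b_cells)
        self._adapt("a", alpha, t)

    def _update_ridge(self, t):
        """Joint move along the m-r confounding ridge.

        Reencounter data mainly constrain the products m[i,k] * r_k, leaving a
        slow direction where all of area k's connectivity shares trade off
        against its reencounter probabilities. Proposing a correlated shift of
        (logit r_ad[k], logit r_juv[k]) and the opposing shift of column k of
        the m auxiliaries walks this ridge directly.
        """
        C = self.C
        # 10% heavy-tailed proposals let a chain trapped on the ridge jump out
        boost = np.where(self.rng.uniform(size=C) < 0.1, 5.0, 1.0)
        d = (boost * np.exp(self.ls["ridge"]))[:, None] * self.rng.normal(size=(C, 3))
        z_r_ad = self.z_r_ad + d
        z_r_juv = self.z_r_juv + d
        dcol = -d[:, [0, 1, 1, 2]]
        z_m = self.z_m + dcol[:, None, :]
        ms = _sigmoid(z_m)
        m_new = ms / ms.sum(axis=2, keepdims=True)
        r_ad4 = _sigmoid(z_r_ad)[:, [0, 1, 1, 2]]
        r_juv4 = _sigmoid(z_r_juv)[:, [0, 1, 1, 2]]

        pm, pra, prj = self._prior_m_rows(z_m), self._prior_r(z_r_ad), self._prior_r(z_r_juv)
        delta = (
            pm.sum(1) - self.prior_m.sum(1) + pra - self.prior_r_ad + prj - self.prior_r_juv
        )
        if self.rings is not None:
            llkA = self._ring_known_rows(m_new, r_ad4, self.RkA, self.ckA)
            llkJ = self._ring_known_rows(m_new, r_juv4, self.RkJ, self.ckJ)
            lluA = self._ring_unknown_rows(m_new, r_ad4, self.RuA, self.cuA)
            lluJ = self._ring_unknown_rows(m_new, r_juv4, self.RuJ, self.cuJ)
            delta = delta + (llkA - self.llkA).sum(1) + (llkJ - self.llkJ).sum(1)
            delta = delta + (lluA - self.lluA).sum(1) + (lluJ - self.lluJ).sum(1)
        if self.iso is not None:
            contrib_n = self._iso_contrib(m_new, self.phi_wce, self.phi_s)
            delta = delta + (contrib_n - self.contrib).sum(1)
        if self.par is not None:
            llb_n = self._par_b_cells(m_new, self.f_nb, self.a)
            delta = delta + (llb_n - self.ll_b_cells).sum((1, 2))
        with np.errstate(invalid="ignore"):
            alpha = np.exp(np.minimum(delta, 0.0))
        alpha = np.where(np.isnan(alpha), 0.0, alpha)
        accept = self.rng.uniform(size=C) < alpha
        accN = accept[:, None]
        acc3 = accept[:, None, None]
        self.z_m = np.where(acc3, z_m, self.z_m)
        self.m = np.where(acc3, m_new, self.m)
        self.z_r_ad = np.where(accN, z_r_ad, self.z_r_ad)
        self.z_r_juv = np.where(accN, z_r_juv, self.z_r_juv)
        self.r_ad4 = np.where(accN, r_ad4, self.r_ad4)
        self.r_juv4 = np.where(accN, r_juv4, self.r_juv4)
        self.prior_m = np.where(accN, pm, self.prior_m)
        self.prior_r_ad = np.where(accept, pra, self.prior_r_ad)
        self.prior_r_juv = np.where(accept, prj, self.prior_r_juv)
        if self.rings is not None:
            self.llkA = np.where(accN, llkA, self.llkA)
            self.llkJ = np.where(accN, llkJ, self.llkJ)
            self.lluA = np.where(accN, lluA, self.lluA)
            self.lluJ = np.where(accN, lluJ, self.lluJ)
        if self.iso is not None:
            self.contrib = np.where(accN, contrib_n, self.contrib)
        if self.par is not None:
            self.ll_b_cells = np.where(acc3, llb_n, self.ll_b_cells)
        self._adapt("ridge", alpha, t)

    # -- recording -----------------------------------------------------------
    def _record(self, out, k):
        C = self.C
        out[:, k, 0:32] = self.m.reshape(C, 32)
        out[:, k, 32:35] = self.r_ad4[:, [0, 1, 3]]
        out[:, k, 35:38] = self.r_juv4[:, [0, 1, 3]]
        out[:, k, 38] = self.mu_sc
        out[:, k, 39] = self.theta
        out[:, k, 40] = self.mu_wn
        out[:, k, 41] = self.mu_sn
        out[:, k, 42:46] = self.sigma
        out[:, k, 46:48] = self.rho
        out[:, k, 48:68] = self.f_nb.reshape(C, 20)
        out[:, k, 68] = self.a

    def run(self) -> np.ndarray:
        cfg = self.cfg
        out = np.empty((self.C, cfg.n_kept, 69))
        k = 0
        for t in range(cfg.n_iter):
            self._update_m(t)
            self._update_r("ad", t)
            self._update_r("juv", t)
            self._update_iso_block("means", t)
            self._update_iso_block("scales", t)
            self._update_f(t)
            self._update_a(t)
            self._update_ridge(t)
            if t >= cfg.burn_in and (t - cfg.burn_in) % cfg.thin == cfg.thin - 1 and k < cfg.n_kept:
                self._record(out, k)
                k += 1
        return out[:, :k, :]

    @property
    def acceptance_rates(self) -> dict[str, float]:
        return {k: float(self.acc_sums[k]) / max(self.acc_n[k], 1) for k in self.ls}


def run_mcmc(
    data: DataBundle,
    model_config: ModelConfig | None = None,
    sampler_config: SamplerConfig | None = None,
    active_sources=None,
) -> PosteriorDraws:
    """Sample the joint posterior (or the prior, with no active sources).

    Deterministic given (seed, configuration, data). With ``active_sources``
    empty the chains target the prior alone, which is how prior-only runs for
    identifiability diagnostics are produced.
    """
    model_config = model_config or ModelConfig()
    cfg = sampler_config or SamplerConfig()
    active = tuple(active_sources) if active_sources is not None else tuple(model_config.active_sources)
    unknown = set(active) - set(ALL_SOURCES)
    if unknown:
        raise ValueError(f"unknown data sources: {sorted(unknown)}")
    sampler = _Sampler(data, model_config, cfg, active)
    draws = sampler.run()
    lineages = data.parasites.lineage_names if data.parasites is not None else None
    rates = sampler.acceptance_rates
    logger.info("acceptance rates: %s", {k: round(v, 3) for k, v in rates.items()})
    return PosteriorDraws(
        draws=draws, names=parameter_names(lineages), config=cfg, acceptance=rates
    )


# ---------------------------------------------------------------------------
# Convergence diagnostics and summaries
# ---------------------------------------------------------------------------

def gelman_rubin(draws: PosteriorDraws | np.ndarray, parameter: str | None = None) -> float:
    """Potential scale reduction factor from between/within-chain variances.

    For identical chains (zero between-chain variance) this equals
    ``sqrt((n-1)/n)``.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            raise ValueError("parameter name required with PosteriorDraws input")
        x = draws.get(parameter)
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of draws")
    m, n = x.shape
    if n < 2:
        raise ValueError("need >= 2 draws per chain")
    chain_means = x.mean(axis=1)
    W = x.var(axis=1, ddof=1).mean()
    B_over_n = chain_means.var(ddof=1)
    if W == 0:
        return 1.0 if B_over_n == 0 else np.inf
    var_hat = (n - 1) / n * W + B_over_n
    return float(np.sqrt(var_hat / W))


def max_gelman_rubin(draws: PosteriorDraws) -> tuple[str, float]:
    """Worst R-hat over all parameters (name, value)."""
    worst = ("", -np.inf)
    for name in draws.names:
        r = gelman_rubin(draws, name)
        if r > worst[1]:
            worst = (name, r)
    return worst


def summarize(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior mean, SD, and central 95% credible interval per parameter."""
    flat = draws.draws.reshape(-1, draws.draws.shape[2])
    if flat.shape[0] == 0:
        raise ValueError("no draws to summarize")
    q = np.percentile(flat, [2.5, 50.0, 97.5], axis=0)
    return pd.DataFrame(
        {
            "mean": flat.mean(axis=0),
            "sd": flat.std(axis=0, ddof=1) if flat.shape[0] > 1 else np.zeros(flat.shape[1]),
            "q2.5": q[0],
            "median": q[1],
            "q97.5": q[2],
        },
        index=pd.Index(draws.names, name="parameter"),
    )
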