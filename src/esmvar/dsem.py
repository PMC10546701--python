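"""Bayesian estimation of the two-level bivariate VAR(1) dynamic SEM.

Model (see :mod:`esmvar.params` for the parameter conventions):

    y_it = mu_i + w_it
    w_it = Phi_i w_{i,t-1} + zeta_it,   zeta_it ~ N(0, Sigma_i)
    eta_i = (mu_i, vec(Phi_i), ln diag(Sigma_i), z_i) ~ N(gamma + beta x_i, Omega)

estimated with a Gibbs sampler whose blocks are

1. data augmentation -- missing within-person deviations are drawn from
   their conditional normal given the neighbouring occasions and the
   person's dynamics (single-site sweep over the slot grid; the VAR(1)
   Markov structure makes the neighbour conditional exact);
2. per-person transition parameters (AR and cross-lagged slopes) from their
   4-dimensional conjugate normal conditional;
3. per-person trait means from their 2-dimensional conjugate normal
   conditional;
4. per-person log innovation variances and Fisher-z innovation correlation
   via a jointly proposed random-walk Metropolis step whose scale adapts
   toward 20-40% acceptance during burn-in and is frozen afterwards;
5. fixed effects gamma (and group slopes beta when a covariate is given)
   from their conjugate normal conditional, prior N(0, 1e10);
6. the level-2 covariance Omega from its inverse-Wishart conditional
   (prior: identity scale, dimension + 1 degrees of freedom).

The likelihood is conditioned on the first occasion (standard conditional
VAR likelihood); missing first occasions are augmented under the person's
stationary distribution.  All randomness flows from the config seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from esmvar.params import (
    EFFECT_NAMES,
    LN_VAR_A,
    LN_VAR_S,
    MU_A,
    MU_S,
    N_EFFECTS,
    PHI_A,
    PHI_A_ON_S,
    PHI_S,
    PHI_S_ON_A,
    Z_CORR,
    stationary_cov,
    transition_matrix,
)
from esmvar.preprocess import EsmGrid

logger = logging.getLogger(__name__)

_VAR_BLOCK = np.array([LN_VAR_A, LN_VAR_S, Z_CORR])
_MU_BLOCK = np.array([MU_A, MU_S])
_PHI_BLOCK = np.array([PHI_A, PHI_S, PHI_S_ON_A, PHI_A_ON_S])
# eta indices in transition-matrix row-major order (Phi11, Phi12, Phi21, Phi22)
_PHI_THETA = np.array([PHI_A, PHI_A_ON_S, PHI_S_ON_A, PHI_S])


@dataclass
class McmcConfig:
    """Sampler settings.

    ``n_iterations`` counts post-adaptation draws per chain *including*
    burn-in; ``n_burn_in`` defaults to half of them (discard-first-half
    convention).  ``psr_cutoff`` is the convergence rule applied to the
    Gelman-Rubin potential scale reduction of every stored parameter.
    """

    n_chains: int = 2
    n_iterations: int = 5000
    n_burn_in: int | None = None
    thinning: int = 1
    seed: int = 0
    proposal_scale: float = 0.25
    psr_cutoff: float = 1.10
    fixed_effect_prior_var: float = 1e10
    omega_prior_scale: float = 1.0
    omega_prior_df: int | None = None  # default: dimension + 1
    stationary_init: bool = True
    adapt: bool = True

    def __post_init__(self) -> None:
        if self.n_burn_in is None:
            self.n_burn_in = self.n_iterations // 2
        if self.n_iterations <= self.n_burn_in:
            raise ValueError("n_iterations must exceed n_burn_in")
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")


@dataclass
class PosteriorDraws:
    """MCMC output: ``draws[c, k, p]`` for chain c, kept draw k, parameter p."""

    parameter_names: list[str]
    draws: np.ndarray
    config: McmcConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.draws.shape[0]

    def index_of(self, name: str) -> int:
        return self.parameter_names.index(name)

    def pooled(self, name: str) -> np.ndarray:
        return self.draws[:, :, self.index_of(name)].reshape(-1)

    def to_frame(self) -> pd.DataFrame:
        flat = self.draws.reshape(-1, self.draws.shape[2])
        return pd.DataFrame(flat, columns=self.parameter_names)

    def save(self, path) -> None:
        """Persist chains as a delimited table (chain, iteration, parameters)."""
        df = self.to_frame()
        c, k, _ = self.draws.shape
        df.insert(0, "iteration", np.tile(np.arange(k), c))
        df.insert(0, "chain", np.repeat(np.arange(c), k))
        df.to_csv(path, index=False)

    @classmethod
    def load(cls, path, config: McmcConfig | None = None) -> "PosteriorDraws":
        df = pd.read_csv(path)
        names = [c for c in df.columns if c not in ("chain", "iteration")]
        n_chains = int(df["chain"].max()) + 1
        arr = df[names].to_numpy().reshape(n_chains, -1, len(names))
        cfg = config or McmcConfig(
            n_chains=n_chains, n_iterations=2 * arr.shape[1], seed=0
        )
        return cls(parameter_names=names, draws=arr, config=cfg)


def grids_to_arrays(
    grids: list[EsmGrid], outcome: str = "composite"
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Stack grids into a (n, T, 2) array of (arousal, self-esteem indicator).

    ``outcome`` selects the self-esteem indicator: the two-item
    ``"composite"`` (default), the single ``"se_worth"`` item, or the
    reverse-coded ``"se_worthless"`` item.  Missing stays NaN.
    """
    if not grids:
        raise ValueError("no grids supplied")
    T = grids[0].n_slots
    if any(g.n_slots != T for g in grids):
        raise ValueError("all grids must share one slot count (equidistant design)")
    ys, ids, codes = [], [], []
    for g in grids:
        if outcome == "composite":
            se = g.composite
        elif outcome == "se_worth":
            se = g.se_worth
        elif outcome == "se_worthless":
            se = 10.0 - g.se_worthless  # reverse-coded so "higher = better"
        else:
            raise ValueError(f"unknown outcome {outcome!r}")
        ys.append(np.column_stack([g.arousal, se]))
        ids.append(g.participant_id)
        codes.append(g.group)
    return np.array(ys), ids, np.array(codes, dtype=float)


# ---------------------------------------------------------------------------
# conditional-distribution helpers (unit-testable pieces of the sampler)


def _conditional_gaussian(omega: np.ndarray, block: np.ndarray):
    """Blocks for p(eta[block] | eta[rest]) under eta ~ N(m, omega).

    Returns ``(gain, cond_cov, cond_prec)`` with
    ``mean = m[block] + gain @ (eta[rest] - m[rest])``.
    """
    rest = np.setdiff1d(np.arange(omega.shape[0]), block)
    o_bb = omega[np.ix_(block, block)]
    o_br = omega[np.ix_(block, rest)]
    o_rr = omega[np.ix_(rest, rest)]
    gain = o_br @ np.linalg.inv(o_rr + 1e-12 * np.eye(rest.size))
    cov = o_bb - gain @ o_br.T
    cov = 0.5 * (cov + cov.T) + 1e-10 * np.eye(block.size)
    return gain, cov, np.linalg.inv(cov), rest


def phi_conditional_moments(
    W: np.ndarray,
    siginv: tuple[np.ndarray, np.ndarray, np.ndarray],
    prior_mean: np.ndarray,
    prior_prec: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior mean and precision of theta = (Phi11, Phi12, Phi21, Phi22).

    ``W`` is the complete (augmented) deviation array (n, T, 2); ``siginv``
    holds the components (i11, i12, i22) of each person's innovation
    precision; the prior is the 4-dimensional conditional from Omega in
    theta order.  With a diffuse prior and vanishing innovation variance the
    posterior mean collapses onto the per-person OLS lag-1 solution.
    """
    i11, i12, i22 = siginv
    Wl, Wc = W[:, :-1, :], W[:, 1:, :]
    G = np.einsum("nti,ntj->nij", Wl, Wl)
    H = np.einsum("nti,ntj->nij", Wl, Wc)  # H[:, j, c] = sum_t x_tj y_tc
    n = W.shape[0]
    prec = np.empty((n, 4, 4))
    prec[:, 0:2, 0:2] = i11[:, None, None] * G
    prec[:, 0:2, 2:4] = i12[:, None, None] * G
    prec[:, 2:4, 0:2] = i12[:, None, None] * G
    prec[:, 2:4, 2:4] = i22[:, None, None] * G
    lin = np.empty((n, 4))
    lin[:, 0:2] = i11[:, None] * H[:, :, 0] + i12[:, None] * H[:, :, 1]
    lin[:, 2:4] = i12[:, None] * H[:, :, 0] + i22[:, None] * H[:, :, 1]
    prec_post = prec + prior_prec[None, :, :]
    lin_post = lin + prior_mean @ prior_prec.T
    mean = np.linalg.solve(prec_post, lin_post[:, :, None])[:, :, 0]
    return mean, prec_post


def _draw_mvn_from_precision(
    rng: np.random.Generator, mean: np.ndarray, prec: np.ndarray
) -> np.ndarray:
    """Batched MVN draws given (n, d) means and (n, d, d) precisions."""
    L = np.linalg.cholesky(prec)
    z = rng.standard_normal(mean.shape)
    # solve L^T x = z  =>  x ~ N(0, prec^{-1})
    x = np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
    return mean + x


def _chol2_draw(rng, m1, m2, p11, p12, p22):
    """Sample bivariate normals from precision components (vectorised)."""
    det = p11 * p22 - p12 * p12
    c11 = p22 / det
    c12 = -p12 / det
    c22 = p11 / det
    l11 = np.sqrt(c11)
    l21 = c12 / l11
    l22 = np.sqrt(np.maximum(c22 - l21 * l21, 1e-12))
    z1 = rng.standard_normal(m1.shape)
    z2 = rng.standard_normal(m1.shape)
    return m1 + l11 * z1, m2 + l21 * z1 + l22 * z2


class _Chain:
    """State and update blocks for one MCMC chain (vectorised over persons)."""

    def __init__(
        self,
        Y: np.ndarray,
        covariate: np.ndarray | None,
        config: McmcConfig,
        rng: np.random.Generator,
    ) -> None:
        self.Y = Y
        self.n, self.T, _ = Y.shape
        self.x = covariate
        self.cfg = config
        self.rng = rng
        self.D = (~np.isnan(Y)).astype(float)  # observedness per coordinate
        self.Y0 = np.nan_to_num(Y, nan=0.0)
        self.n_nonstationary = 0
        # slot-wise missingness index lists (static); pos_* are positions of
        # each pattern inside miss_any[t]
        self.miss_any, self.pos_both, self.pos_a, self.pos_s = [], [], [], []
        for t in range(self.T):
            ma = self.D[:, t, 0] == 0
            ms = self.D[:, t, 1] == 0
            u = np.flatnonzero(ma | ms)
            self.miss_any.append(u)
            self.pos_both.append(np.searchsorted(u, np.flatnonzero(ma & ms)))
            self.pos_a.append(np.searchsorted(u, np.flatnonzero(ma & ~ms)))
            self.pos_s.append(np.searchsorted(u, np.flatnonzero(~ma & ms)))
        self._init_state()

    # -- initialisation ----------------------------------------------------
    def _init_state(self) -> None:
        rng = self.rng
        n, T = self.n, self.T
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            mu0 = np.nanmean(self.Y, axis=1)  # (n, 2)
        col_mean = np.nanmean(self.Y.reshape(-1, 2), axis=0)
        mu0 = np.where(np.isnan(mu0), col_mean[None, :], mu0)
        eta = np.zeros((n, N_EFFECTS))
        eta[:, _MU_BLOCK] = mu0 + rng.normal(0.0, 0.2, size=(n, 2))
        eta[:, _PHI_BLOCK[:2]] = rng.normal(0.2, 0.1, size=(n, 2))  # AR slopes
        eta[:, _PHI_BLOCK[2:]] = rng.normal(0.0, 0.05, size=(n, 2))  # cross-lags
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", category=RuntimeWarning)
            v0 = np.nanvar(self.Y, axis=1)
        v0 = np.where(np.isnan(v0) | (v0 <= 1e-4), 1.0, v0)
        eta[:, LN_VAR_A] = np.log(v0[:, 0]) + rng.normal(0.0, 0.2, size=n)
        eta[:, LN_VAR_S] = np.log(v0[:, 1]) + rng.normal(0.0, 0.2, size=n)
        eta[:, Z_CORR] = rng.normal(0.0, 0.1, size=n)
        self.eta = eta
        self.gamma = eta.mean(axis=0)
        self.beta = np.zeros(N_EFFECTS) if self.x is not None else None
        resid = eta - self.gamma
        if self.x is not None:
            resid = resid - np.outer(self.x - self.x.mean(), np.zeros(N_EFFECTS))
        omega0 = np.diag(np.maximum(resid.var(axis=0), 1e-3))
        self.omega = omega0 + 1e-3 * np.eye(N_EFFECTS)
        # latent deviations; missing coordinates start at 0
        self.W = np.where(self.D > 0, self.Y0 - self.eta[:, _MU_BLOCK][:, None, :], 0.0)
        self.prop_scale = np.full(self.n, self.cfg.proposal_scale)
        self.mh_accepts = 0
        self.mh_proposals = 0
        self._refresh_dynamics()

    # -- cached per-person matrices ---------------------------------------
    def _refresh_dynamics(self) -> None:
        e = self.eta
        self.p11, self.p12 = e[:, PHI_A], e[:, PHI_A_ON_S]
        self.p21, self.p22 = e[:, PHI_S_ON_A], e[:, PHI_S]
        v_a = np.exp(np.clip(e[:, LN_VAR_A], -12.0, 12.0))
        v_s = np.exp(np.clip(e[:, LN_VAR_S], -12.0, 12.0))
        rho = np.tanh(e[:, Z_CORR])
        c = rho * np.sqrt(v_a * v_s)
        det = np.maximum(v_a * v_s - c * c, 1e-12)
        self.s11, self.s12, self.s22 = v_a, c, v_s
        self.i11, self.i12, self.i22 = v_s / det, -c / det, v_a / det
        self.logdet_sigma = np.log(det)

    def _phi_mats(self) -> np.ndarray:
        phi = np.empty((self.n, 2, 2))
        phi[:, 0, 0], phi[:, 0, 1] = self.p11, self.p12
        phi[:, 1, 0], phi[:, 1, 1] = self.p21, self.p22
        return phi

    def _sigma_mats(self) -> np.ndarray:
        sig = np.empty((self.n, 2, 2))
        sig[:, 0, 0], sig[:, 1, 1] = self.s11, self.s22
        sig[:, 0, 1] = sig[:, 1, 0] = self.s12
        return sig

    def _stationary_prior_precisions(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Precision components of each person's stationary distribution.

        Nonstationary persons fall back to a diffuse 3*Sigma prior for the
        initial occasion; occurrences are counted.
        """
        phi = self._phi_mats()
        sig = self._sigma_mats()
        s0 = stationary_cov(phi, sig)
        bad = np.isnan(s0[:, 0, 0])
        if np.any(bad):
            self.n_nonstationary += int(bad.sum())
            s0[bad] = 3.0 * sig[bad]
        det = np.maximum(s0[:, 0, 0] * s0[:, 1, 1] - s0[:, 0, 1] ** 2, 1e-12)
        return s0[:, 1, 1] / det, -s0[:, 0, 1] / det, s0[:, 0, 0] / det

    # -- block 1: missing-data augmentation --------------------------------
    def update_missing(self) -> None:
        rng = self.rng
        W = self.W
        # Phi^T Sigma^{-1} Phi components (symmetric)
        b11 = self.i11 * self.p11 + self.i12 * self.p21  # (Sigma^-1 Phi)_11
        b12 = self.i11 * self.p12 + self.i12 * self.p22
        b21 = self.i12 * self.p11 + self.i22 * self.p21
        b22 = self.i12 * self.p12 + self.i22 * self.p22
        a11 = self.p11 * b11 + self.p21 * b21
        a12 = self.p11 * b12 + self.p21 * b22
        a22 = self.p12 * b12 + self.p22 * b22
        q11, q12, q22 = self._stationary_prior_precisions()
        T = self.T
        for t in range(T):
            any_idx = self.miss_any[t]
            if any_idx.size == 0:
                continue
            u = any_idx
            if t == 0:
                p11_, p12_, p22_ = q11[u] + a11[u], q12[u] + a12[u], q22[u] + a22[u]
                wa2, ws2 = W[u, 1, 0], W[u, 1, 1]
                l1 = b11[u] * wa2 + b21[u] * ws2
                l2 = b12[u] * wa2 + b22[u] * ws2
            elif t == T - 1:
                p11_, p12_, p22_ = self.i11[u], self.i12[u], self.i22[u]
                wa0, ws0 = W[u, t - 1, 0], W[u, t - 1, 1]
                fa = self.p11[u] * wa0 + self.p12[u] * ws0
                fs = self.p21[u] * wa0 + self.p22[u] * ws0
                l1 = self.i11[u] * fa + self.i12[u] * fs
                l2 = self.i12[u] * fa + self.i22[u] * fs
            else:
                p11_ = self.i11[u] + a11[u]
                p12_ = self.i12[u] + a12[u]
                p22_ = self.i22[u] + a22[u]
                wa0, ws0 = W[u, t - 1, 0], W[u, t - 1, 1]
                wa2, ws2 = W[u, t + 1, 0], W[u, t + 1, 1]
                fa = self.p11[u] * wa0 + self.p12[u] * ws0
                fs = self.p21[u] * wa0 + self.p22[u] * ws0
                l1 = self.i11[u] * fa + self.i12[u] * fs + b11[u] * wa2 + b21[u] * ws2
                l2 = self.i12[u] * fa + self.i22[u] * fs + b12[u] * wa2 + b22[u] * ws2
            det = p11_ * p22_ - p12_ * p12_
            m1 = (p22_ * l1 - p12_ * l2) / det
            m2 = (p11_ * l2 - p12_ * l1) / det
            both = self.pos_both[t]
            only_a = self.pos_a[t]
            only_s = self.pos_s[t]
            if both.size:
                wa, ws = _chol2_draw(
                    rng, m1[both], m2[both], p11_[both], p12_[both], p22_[both]
                )
                W[u[both], t, 0] = wa
                W[u[both], t, 1] = ws
            if only_a.size:
                ws_obs = W[u[only_a], t, 1]
                cond_mean = m1[only_a] - (p12_[only_a] / p11_[only_a]) * (ws_obs - m2[only_a])
                W[u[only_a], t, 0] = cond_mean + rng.standard_normal(only_a.size) / np.sqrt(
                    p11_[only_a]
                )
            if only_s.size:
                wa_obs = W[u[only_s], t, 0]
                cond_mean = m2[only_s] - (p12_[only_s] / p22_[only_s]) * (wa_obs - m1[only_s])
                W[u[only_s], t, 1] = cond_mean + rng.standard_normal(only_s.size) / np.sqrt(
                    p22_[only_s]
                )

    # -- block 2: transition parameters ------------------------------------
    def update_phi(self) -> None:
        gain, cov, prec, rest = _conditional_gaussian(self.omega, _PHI_BLOCK)
        m_all = self._prior_means()
        m_cond = m_all[:, _PHI_BLOCK] + (self.eta[:, rest] - m_all[:, rest]) @ gain.T
        # reorder (phi_A, phi_S, SonA, AonS) -> theta (phi_A, AonS, SonA, phi_S)
        perm = np.array([0, 3, 2, 1])
        m_theta = m_cond[:, perm]
        prec_theta = prec[np.ix_(perm, perm)]
        mean, prec_post = phi_conditional_moments(
            self.W, (self.i11, self.i12, self.i22), m_theta, prec_theta
        )
        theta = _draw_mvn_from_precision(self.rng, mean, prec_post)
        self.eta[:, _PHI_THETA] = theta
        self._refresh_dynamics()

    # -- block 3: trait means ----------------------------------------------
    def update_mu(self) -> None:
        gain, cov, prec_c, rest = _conditional_gaussian(self.omega, _MU_BLOCK)
        m_all = self._prior_means()
        m_cond = m_all[:, _MU_BLOCK] + (self.eta[:, rest] - m_all[:, rest]) @ gain.T
        D0 = self.D[:, :-1, :]
        D1 = self.D[:, 1:, :]
        Wl, Wc = self.W[:, :-1, :], self.W[:, 1:, :]
        za = Wc[:, :, 0] - (self.p11[:, None] * Wl[:, :, 0] + self.p12[:, None] * Wl[:, :, 1])
        zs = Wc[:, :, 1] - (self.p21[:, None] * Wl[:, :, 0] + self.p22[:, None] * Wl[:, :, 1])
        C11 = D1[:, :, 0] - self.p11[:, None] * D0[:, :, 0]
        C12 = -self.p12[:, None] * D0[:, :, 1]
        C21 = -self.p21[:, None] * D0[:, :, 0]
        C22 = D1[:, :, 1] - self.p22[:, None] * D0[:, :, 1]
        mu_a, mu_s = self.eta[:, MU_A][:, None], self.eta[:, MU_S][:, None]
        ra = za + C11 * mu_a + C12 * mu_s
        rs = zs + C21 * mu_a + C22 * mu_s
        i11, i12, i22 = self.i11[:, None], self.i12[:, None], self.i22[:, None]
        P11 = (C11 * C11 * i11 + 2 * C11 * C21 * i12 + C21 * C21 * i22).sum(axis=1)
        P12 = (C11 * C12 * i11 + (C11 * C22 + C12 * C21) * i12 + C21 * C22 * i22).sum(axis=1)
        P22 = (C12 * C12 * i11 + 2 * C12 * C22 * i12 + C22 * C22 * i22).sum(axis=1)
        q1 = i11 * ra + i12 * rs
        q2 = i12 * ra + i22 * rs
        L1 = (C11 * q1 + C21 * q2).sum(axis=1)
        L2 = (C12 * q1 + C22 * q2).sum(axis=1)
        pc = prec_c
        L1 += pc[0, 0] * m_cond[:, 0] + pc[0, 1] * m_cond[:, 1]
        L2 += pc[1, 0] * m_cond[:, 0] + pc[1, 1] * m_cond[:, 1]
        P11 = P11 + pc[0, 0]
        P12 = P12 + pc[0, 1]
        P22 = P22 + pc[1, 1]
        det = P11 * P22 - P12 * P12
        m1 = (P22 * L1 - P12 * L2) / det
        m2 = (P11 * L2 - P12 * L1) / det
        mu_a_new, mu_s_new = _chol2_draw(self.rng, m1, m2, P11, P12, P22)
        self.eta[:, MU_A] = mu_a_new
        self.eta[:, MU_S] = mu_s_new
        # refresh observed deviations; latent coordinates stay
        mu = self.eta[:, _MU_BLOCK][:, None, :]
        self.W = np.where(self.D > 0, self.Y0 - mu, self.W)

    # -- block 4: innovation variances / correlation ------------------------
    def _innovation_sse(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        Wl, Wc = self.W[:, :-1, :], self.W[:, 1:, :]
        za = Wc[:, :, 0] - (self.p11[:, None] * Wl[:, :, 0] + self.p12[:, None] * Wl[:, :, 1])
        zs = Wc[:, :, 1] - (self.p21[:, None] * Wl[:, :, 0] + self.p22[:, None] * Wl[:, :, 1])
        return (za * za).sum(axis=1), (za * zs).sum(axis=1), (zs * zs).sum(axis=1)

    @staticmethod
    def _loglik_var(x: np.ndarray, m11, m12, m22, n_terms: int) -> np.ndarray:
        v_a = np.exp(np.clip(x[:, 0], -12.0, 12.0))
        v_s = np.exp(np.clip(x[:, 1], -12.0, 12.0))
        rho = np.tanh(x[:, 2])
        c = rho * np.sqrt(v_a * v_s)
        det = np.maximum(v_a * v_s - c * c, 1e-300)
        i11, i12, i22 = v_s / det, -c / det, v_a / det
        return -0.5 * (n_terms * np.log(det) + i11 * m11 + 2 * i12 * m12 + i22 * m22)

    def update_var(self, adapting: bool) -> None:
        rng = self.rng
        gain, cov, prec_c, rest = _conditional_gaussian(self.omega, _VAR_BLOCK)
        m_all = self._prior_means()
        m_cond = m_all[:, _VAR_BLOCK] + (self.eta[:, rest] - m_all[:, rest]) @ gain.T
        m11, m12, m22 = self._innovation_sse()
        n_terms = self.T - 1
        x_cur = self.eta[:, _VAR_BLOCK]
        def log_target(x):
            d = x - m_cond
            lp = -0.5 * np.einsum("ni,ij,nj->n", d, prec_c, d)
            return lp + self._loglik_var(x, m11, m12, m22, n_terms)
        lp_cur = log_target(x_cur)
        x_prop = x_cur + self.prop_scale[:, None] * rng.standard_normal(x_cur.shape)
        lp_prop = log_target(x_prop)
        accept = np.log(rng.random(self.n)) < (lp_prop - lp_cur)
        self.eta[:, _VAR_BLOCK] = np.where(accept[:, None], x_prop, x_cur)
        self.mh_accepts += int(accept.sum())
        self.mh_proposals += self.n
        if adapting and self.cfg.adapt:
            self.prop_scale *= np.exp(0.05 * (accept.astype(float) - 0.3))
            np.clip(self.prop_scale, 1e-3, 5.0, out=self.prop_scale)
        self._refresh_dynamics()

    # -- blocks 5-6: level-2 parameters -------------------------------------
    def _prior_means(self) -> np.ndarray:
        if self.x is None:
            return np.broadcast_to(self.gamma, (self.n, N_EFFECTS))
        return self.gamma[None, :] + np.outer(self.x, self.beta)

    def update_fixed_effects(self) -> None:
        oinv = np.linalg.inv(self.omega)
        tau = 1.0 / self.cfg.fixed_effect_prior_var
        if self.x is None:
            prec = self.n * oinv + tau * np.eye(N_EFFECTS)
            lin = oinv @ self.eta.sum(axis=0)
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, lin)
            z = self.rng.standard_normal(N_EFFECTS)
            self.gamma = mean + np.linalg.solve(L.T, z)
        else:
            sx, sxx = self.x.sum(), (self.x * self.x).sum()
            szz = np.array([[self.n, sx], [sx, sxx]])
            prec = np.kron(szz, oinv) + tau * np.eye(2 * N_EFFECTS)
            lin = np.concatenate([oinv @ self.eta.sum(axis=0), oinv @ (self.x @ self.eta)])
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, lin)
            z = self.rng.standard_normal(2 * N_EFFECTS)
            g = mean + np.linalg.solve(L.T, z)
            self.gamma, self.beta = g[:N_EFFECTS], g[N_EFFECTS:]

    def update_omega(self) -> None:
        resid = self.eta - self._prior_means()
        scatter = resid.T @ resid
        df0 = self.cfg.omega_prior_df or (N_EFFECTS + 1)
        scale = self.cfg.omega_prior_scale * np.eye(N_EFFECTS) + scatter
        self.omega = invwishart.rvs(df=df0 + self.n, scale=scale, random_state=self.rng)
        self.omega = 0.5 * (self.omega + self.omega.T)

    # -- within-level R^2 ----------------------------------------------------
    def within_r2_now(self) -> tuple[float, float, int]:
        phi = self._phi_mats()
        sig = self._sigma_mats()
        s_inf = stationary_cov(phi, sig)
        ok = ~np.isnan(s_inf[:, 0, 0])
        n_bad = int((~ok).sum())
        if not np.any(ok):
            return np.nan, np.nan, n_bad
        r2_a = 1.0 - sig[ok, 0, 0] / s_inf[ok, 0, 0]
        r2_s = 1.0 - sig[ok, 1, 1] / s_inf[ok, 1, 1]
        return float(r2_a.mean()), float(r2_s.mean()), n_bad

    # -- one full sweep ------------------------------------------------------
    def sweep(self, adapting: bool) -> None:
        self.update_missing()
        self.update_phi()
        self.update_mu()
        self.update_var(adapting)
        self.update_fixed_effects()
        self.update_omega()


def _parameter_names(with_covariate: bool) -> list[str]:
    names = [f"gamma_{n}" for n in EFFECT_NAMES]
    if with_covariate:
        names += [f"beta_{n}" for n in EFFECT_NAMES]
    names += [f"omega_{n}" for n in EFFECT_NAMES]
    names += ["r2_arousal", "r2_selfesteem"]
    return names


def fit_dsem(
    grids: list[EsmGrid],
    covariate: np.ndarray | list | None = None,
    config: McmcConfig | None = None,
    outcome: str = "composite",
) -> PosteriorDraws:
    """Fit the two-level dynamic SEM by MCMC.

    Parameters
    ----------
    grids : one :class:`EsmGrid` per person (equal slot counts; missing
        slots allowed, all-missing persons are dropped with a warning).
    covariate : optional per-person numeric predictor of all nine random
        effects (e.g. the raw group code 1/2/3, or a 0/1 dummy).
    config : MCMC settings; two chains of 5000 iterations with first-half
        burn-in by default.
    outcome : self-esteem indicator passed to :func:`grids_to_arrays`.

    Returns
    -------
    PosteriorDraws with chains for the fixed effects (gamma, optionally
    beta), the level-2 random-effect variances (omega diagonal) and the
    within-level R-squared of both outcomes.
    """
    config = config or McmcConfig()
    Y, ids, codes = grids_to_arrays(grids, outcome=outcome)
    if covariate is not None:
        covariate = np.asarray(covariate, dtype=float)
        if covariate.shape[0] != len(grids):
            raise ValueError("covariate must have one value per person")
    keep = ~np.all(np.isnan(Y).all(axis=2), axis=1)
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} person(s) with no observed responses",
            RuntimeWarning,
            stacklevel=2,
        )
        Y = Y[keep]
        ids = [p for p, k in zip(ids, keep) if k]
        if covariate is not None:
            covariate = covariate[keep]
    if Y.shape[0] < 2:
        raise ValueError("need at least two persons with observations")

    names = _parameter_names(covariate is not None)
    n_keep = (config.n_iterations - config.n_burn_in) // config.thinning
    draws = np.empty((config.n_chains, n_keep, len(names)))
    acc_rates, nonstat_counts = [], []
    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), 7001, c)))
        chain = _Chain(Y, covariate, config, rng)
        k = 0
        for it in range(config.n_iterations):
            chain.sweep(adapting=it < config.n_burn_in)
            if it >= config.n_burn_in and (it - config.n_burn_in) % config.thinning == 0:
                if k < n_keep:
                    row = [chain.gamma]
                    if covariate is not None:
                        row.append(chain.beta)
                    row.append(np.diag(chain.omega))
                    r2a, r2s, _ = chain.within_r2_now()
                    row.append(np.array([r2a, r2s]))
                    draws[c, k] = np.concatenate(row)
                    k += 1
        acc_rates.append(chain.mh_accepts / max(chain.mh_proposals, 1))
        nonstat_counts.append(chain.n_nonstationary)
    meta = {
        "person_ids": ids,
        "n_persons": Y.shape[0],
        "n_occasions": Y.shape[1],
        "mh_acceptance": acc_rates,
        "n_nonstationary_draws": nonstat_counts,
        "outcome": outcome,
        "covariate_used": covariate is not None,
    }
    return PosteriorDraws(parameter_names=names, draws=draws, config=config, meta=meta)


# ---------------------------------------------------------------------------
# diagnostics and summaries


def psr(draws: PosteriorDraws | np.ndarray, parameter: str | int | None = None):
    """Gelman-Rubin potential scale reduction factor.

    For chains ``x[c, k]`` with within-chain variance W and between-chain
    variance B (of chain means, times k):

        PSR = sqrt( ( W (k-1)/k + B/k ) / W )

    Accepts a :class:`PosteriorDraws` plus a parameter name/index, or a raw
    (chains, draws) array.  Requires >= 2 chains with >= 10 draws each.
    """
    if isinstance(draws, PosteriorDraws):
        if parameter is None:
            return {name: psr(draws, name) for name in draws.parameter_names}
        idx = draws.index_of(parameter) if isinstance(parameter, str) else int(parameter)
        x = draws.draws[:, :, idx]
    else:
        x = np.asarray(draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("PSR needs at least two chains")
    m, k = x.shape
    if k < 10:
        raise ValueError("PSR needs at least 10 draws per chain")
    chain_means = x.mean(axis=1)
    w = x.var(axis=1, ddof=1).mean()
    b = k * np.var(chain_means, ddof=1)
    if w <= 0:
        return 1.0
    return float(np.sqrt((w * (k - 1) / k + b / k) / w))


def summarize(draws: PosteriorDraws, psr_cutoff: float | None = None) -> pd.DataFrame:
    """Posterior medians, equal-tailed 95% credible intervals, PSR, flags.

    ``significant`` marks parameters whose 95% CI excludes zero -- the
    decision rule used throughout the analysis (no multiplicity
    correction).  The frame's ``attrs['converged']`` records whether every
    parameter's PSR fell below the cutoff (only defined with >= 2 chains).
    """
    if draws.draws.size == 0:
        raise ValueError("no draws to summarise")
    cutoff = psr_cutoff if psr_cutoff is not None else draws.config.psr_cutoff
    rows = []
    can_psr = draws.n_chains >= 2 and draws.draws.shape[1] >= 10
    for i, name in enumerate(draws.parameter_names):
        pooled = draws.draws[:, :, i].reshape(-1)
        pooled = pooled[~np.isnan(pooled)]
        if pooled.size == 0:
            rows.append((name, np.nan, np.nan, np.nan, np.nan, False))
            continue
        med = float(np.median(pooled))
        lo, hi = np.percentile(pooled, [2.5, 97.5])
        r = psr(draws, i) if can_psr else np.nan
        rows.append((name, med, float(lo), float(hi), r, bool(lo > 0 or hi < 0)))
    out = pd.DataFrame(
        rows, columns=["parameter", "median", "ci_low", "ci_high", "psr", "significant"]
    ).set_index("parameter")
    if can_psr:
        out.attrs["converged"] = bool(np.nanmax(out["psr"].to_numpy()) < cutoff)
        out.attrs["psr_cutoff"] = cutoff
    return out


def within_r2(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary of the within-level explained variance per outcome.

    Per draw and person, R^2 = 1 - (innovation variance) / (stationary
    within-person variance from the person's Lyapunov solution), averaged
    over persons; nonstationary person-draws are excluded (counted in
    ``draws.meta['n_nonstationary_draws']``).
    """
    s = summarize(draws)
    return s.loc[["r2_arousal", "r2_selfesteem"], ["median", "ci_low", "ci_high"]]


def r2_from_effects(eta: np.ndarray) -> np.ndarray:
    """Closed-form within-level R^2 per outcome for effect vectors.

    For a diagonal transition matrix with univariate AR slope phi and no
    cross-lags this reduces to phi**2 (stationary variance sigma^2 /
    (1 - phi^2)).
    """
    from esmvar.params import innovation_cov
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    phi = transition_matrix(eta)
    sig = innovation_cov(eta)
    s_inf = stationary_cov(phi, sig)
    r2 = 1.0 - np.stack([sig[:, 0, 0] / s_inf[:, 0, 0], sig[:, 1, 1] / s_inf[:, 1, 1]], axis=1)
    return r2 if r2.shape[0] > 1 else r2[0]
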