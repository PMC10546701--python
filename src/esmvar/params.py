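"""Parameter conventions for the bivariate two-level VAR(1) dynamic SEM.

Each person *i* is characterised by a 9-dimensional random-effect vector

    eta_i = (mu_A, mu_S, phi_A, phi_S, phi_SonA, phi_AonS,
             ln_var_A, ln_var_S, z_AS)

where ``mu`` are latent trait means of arousal (A) and self-esteem (S) on the
0-10 rating scale, ``phi_A``/``phi_S`` are AR(1) slopes, ``phi_SonA`` is the
slope of self-esteem on arousal at the previous occasion (the
arousal -> self-esteem cross-lag), ``phi_AonS`` the reverse cross-lag,
``ln_var`` are log innovation variances, and ``z_AS`` is the Fisher-z
transformed innovation correlation.  The within-person model is

    y_it = mu_i + w_it,      w_it = Phi_i w_{i,t-1} + zeta_it,

with ``Phi_i = [[phi_A, phi_AonS], [phi_SonA, phi_S]]`` acting on the state
``(w_A, w_S)`` and ``zeta_it ~ N(0, Sigma_i)``,
``Sigma_i = [[v_A, rho sqrt(v_A v_S)], [., v_S]]``, ``v = exp(ln_var)``,
``rho = tanh(z_AS)``.  At level 2, ``eta_i ~ N(m_g(i), Omega)`` with a
group-specific mean and a shared covariance ``Omega``.

The Fisher-z parameterisation of the innovation covariance random effect
guarantees a positive-definite ``Sigma_i`` for every real ``z_AS``; a log
transform of the covariance itself would be undefined whenever arousal and
self-esteem innovations are negatively related, as they typically are.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

#: Canonical ordering of the person-effect vector.
EFFECT_NAMES: tuple[str, ...] = (
    "mu_arousal",
    "mu_selfesteem",
    "phi_arousal",
    "phi_selfesteem",
    "phi_se_on_arousal_lag",
    "phi_arousal_on_se_lag",
    "ln_var_arousal",
    "ln_var_selfesteem",
    "z_innov_corr",
)

MU_A, MU_S, PHI_A, PHI_S, PHI_S_ON_A, PHI_A_ON_S, LN_VAR_A, LN_VAR_S, Z_CORR = range(9)

N_EFFECTS = 9

#: index order that maps eta[PHI_A..PHI_A_ON_S] onto the row-major transition
#: matrix [[phi_A, phi_AonS], [phi_SonA, phi_S]].
PHI_ETA_INDEX = (PHI_A, PHI_A_ON_S, PHI_S_ON_A, PHI_S)


def transition_matrix(eta: np.ndarray) -> np.ndarray:
    """Transition matrix Phi for one effect vector or a batch.

    Parameters
    ----------
    eta : array, shape (9,) or (n, 9)

    Returns
    -------
    array, shape (2, 2) or (n, 2, 2)
    """
    eta = np.asarray(eta, dtype=float)
    batched = eta.ndim == 2
    e = np.atleast_2d(eta)
    phi = np.empty((e.shape[0], 2, 2))
    phi[:, 0, 0] = e[:, PHI_A]
    phi[:, 0, 1] = e[:, PHI_A_ON_S]
    phi[:, 1, 0] = e[:, PHI_S_ON_A]
    phi[:, 1, 1] = e[:, PHI_S]
    return phi if batched else phi[0]


def innovation_cov(eta: np.ndarray) -> np.ndarray:
    """Innovation covariance Sigma for one effect vector or a batch."""
    eta = np.asarray(eta, dtype=float)
    batched = eta.ndim == 2
    e = np.atleast_2d(eta)
    v_a = np.exp(e[:, LN_VAR_A])
    v_s = np.exp(e[:, LN_VAR_S])
    rho = np.tanh(e[:, Z_CORR])
    sig = np.empty((e.shape[0], 2, 2))
    sig[:, 0, 0] = v_a
    sig[:, 1, 1] = v_s
    sig[:, 0, 1] = sig[:, 1, 0] = rho * np.sqrt(v_a * v_s)
    return sig if batched else sig[0]


def spectral_radius(phi: np.ndarray) -> np.ndarray:
    """Spectral radius of 2x2 transition matrices (batched).

    Uses the closed form for 2x2 eigenvalues; for complex pairs the modulus
    is sqrt(det).
    """
    phi = np.asarray(phi, dtype=float)
    batched = phi.ndim == 3
    p = phi.reshape(-1, 2, 2)
    tr = p[:, 0, 0] + p[:, 1, 1]
    det = p[:, 0, 0] * p[:, 1, 1] - p[:, 0, 1] * p[:, 1, 0]
    disc = tr * tr - 4.0 * det
    out = np.empty(p.shape[0])
    real = disc >= 0
    sq = np.sqrt(np.abs(disc))
    out[real] = np.maximum(
        np.abs((tr[real] + sq[real]) / 2.0), np.abs((tr[real] - sq[real]) / 2.0)
    )
    out[~real] = np.sqrt(np.abs(det[~real]))
    return out if batched else float(out[0])


def stationary_cov(phi: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Stationary covariance of w_t = Phi w_{t-1} + zeta_t (batched).

    Solves the discrete Lyapunov equation S = Phi S Phi' + Sigma through its
    vectorised linear form ``(I4 - Phi (x) Phi) vec(S) = vec(Sigma)``.
    Nonstationary entries (spectral radius >= 1) come back as NaN.
    """
    phi = np.asarray(phi, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    batched = phi.ndim == 3
    p = phi.reshape(-1, 2, 2)
    s = sigma.reshape(-1, 2, 2)
    kron = np.einsum("nij,nkl->nikjl", p, p).reshape(-1, 4, 4)
    lhs = np.eye(4)[None, :, :] - kron
    out = np.full((p.shape[0], 2, 2), np.nan)
    ok = spectral_radius(p) < 1.0
    if np.any(ok):
        vec = np.linalg.solve(lhs[ok], s[ok].reshape(-1, 4, 1))
        out[ok] = vec.reshape(-1, 2, 2)
        # symmetrise away round-off
        out[ok] = 0.5 * (out[ok] + np.transpose(out[ok], (0, 2, 1)))
    return out if batched else out[0]


def _check_psd(mat: np.ndarray, name: str, tol: float = 1e-10) -> None:
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError(f"{name} must be a square matrix, got shape {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise ValueError(f"{name} must be symmetric")
    eigvals = np.linalg.eigvalsh(mat)
    if eigvals.min() < -tol * max(1.0, eigvals.max()):
        raise ValueError(f"{name} must be positive semi-definite (min eig {eigvals.min():.3g})")


@dataclass
class TrueParams:
    """Generative truth for a synthetic experience-sampling cohort.

    Attributes
    ----------
    group_labels : group names, e.g. ``("BPD", "DD", "NCC")``; the numeric
        group code used downstream is the 1-based position in this tuple.
    group_means : array (G, 9), population means of the person effects per
        group, in :data:`EFFECT_NAMES` order.
    omega : array (9, 9), level-2 covariance of person effects (shared
        across groups, mirroring the estimator's assumption).
    n_per_group : persons per group.
    n_occasions : prompts per person (52 quarter hours from 8 am to 9 pm).
    burn_in : pre-sample occasions simulated and discarded so that series
        start from their stationary regime.
    item_disagreement_sd : occasion-level SD of the two self-esteem items'
        disagreement around the latent composite.
    item_person_sd : person-level SD of stable item-specific offsets.
    """

    group_labels: tuple[str, ...] = ("BPD", "DD", "NCC")
    group_means: np.ndarray = field(default=None)  # type: ignore[assignment]
    omega: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_per_group: tuple[int, ...] = (42, 40, 40)
    n_occasions: int = 52
    burn_in: int = 50
    item_disagreement_sd: float = 0.83
    item_person_sd: float = 0.82

    def __post_init__(self) -> None:
        if self.group_means is None or self.omega is None:
            raise ValueError("group_means and omega are required; see default_true_params()")
        self.group_means = np.asarray(self.group_means, dtype=float)
        self.omega = np.asarray(self.omega, dtype=float)
        if self.group_means.ndim != 2 or self.group_means.shape[1] != N_EFFECTS:
            raise ValueError("group_means must have shape (n_groups, 9)")
        if len(self.group_labels) != self.group_means.shape[0]:
            raise ValueError("group_labels and group_means disagree on the number of groups")
        if np.isscalar(self.n_per_group):
            self.n_per_group = (int(self.n_per_group),) * len(self.group_labels)
        self.n_per_group = tuple(int(n) for n in self.n_per_group)
        if len(self.n_per_group) != len(self.group_labels):
            raise ValueError("n_per_group must give one count per group")
        if any(n <= 0 for n in self.n_per_group):
            raise ValueError("every group must contain at least one person")
        if self.n_occasions < 2:
            raise ValueError("n_occasions must be >= 2")
        _check_psd(self.omega, "omega")
        rad = spectral_radius(transition_matrix(self.group_means))
        if np.any(rad >= 1.0):
            raise ValueError(
                "mean transition matrix is nonstationary for group(s) "
                f"{[self.group_labels[i] for i in np.flatnonzero(rad >= 1.0)]}"
            )

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)

    @property
    def n_persons(self) -> int:
        return int(sum(self.n_per_group))

    def to_dict(self) -> dict:
        return {
            "group_labels": list(self.group_labels),
            "group_means": self.group_means.tolist(),
            "effect_names": list(EFFECT_NAMES),
            "omega": self.omega.tolist(),
            "n_per_group": list(self.n_per_group),
            "n_occasions": self.n_occasions,
            "burn_in": self.burn_in,
            "item_disagreement_sd": self.item_disagreement_sd,
            "item_person_sd": self.item_person_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueParams":
        return cls(
            group_labels=tuple(d["group_labels"]),
            group_means=np.asarray(d["group_means"], dtype=float),
            omega=np.asarray(d["omega"], dtype=float),
            n_per_group=tuple(d["n_per_group"]),
            n_occasions=int(d["n_occasions"]),
            burn_in=int(d["burn_in"]),
            item_disagreement_sd=float(d.get("item_disagreement_sd", 0.83)),
            item_person_sd=float(d.get("item_person_sd", 0.82)),
        )


@dataclass
class MissingnessPattern:
    """Prompt-level non-response model.

    ``mode`` is ``"mcar"`` (uniform deletion) or ``"time_of_day"``
    (slot-dependent deletion propensities).  ``overall_rate`` is the expected
    fraction of prompts deleted; ``slot_weights`` are relative propensities
    per slot (uniform when omitted).  The realised per-slot deletion
    probability is ``overall_rate * w_t / mean(w)``, clipped to [0, 1].
    """

    mode: str = "time_of_day"
    overall_rate: float = 0.5
    slot_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("mcar", "time_of_day"):
            raise ValueError("mode must be 'mcar' or 'time_of_day'")
        if not 0.0 <= self.overall_rate <= 1.0:
            raise ValueError("overall_rate must lie in [0, 1]")
        if self.slot_weights is not None:
            self.slot_weights = np.asarray(self.slot_weights, dtype=float)
            if np.any(self.slot_weights < 0):
                raise ValueError("slot_weights must be nonnegative")

    def deletion_probs(self, n_occasions: int) -> np.ndarray:
        if self.mode == "mcar" or self.slot_weights is None:
            return np.full(n_occasions, self.overall_rate)
        w = self.slot_weights
        if w.shape[0] != n_occasions:
            raise ValueError(
                f"slot_weights has length {w.shape[0]}, expected {n_occasions}"
            )
        if w.sum() == 0:
            return np.zeros(n_occasions)
        return np.clip(self.overall_rate * w / w.mean(), 0.0, 1.0)


def default_true_params(
    scenario: str = "study",
    n_per_group: tuple[int, ...] | None = None,
) -> TrueParams:
    """Built-in generative regimes.

    ``"study"`` places the group means of trait levels, AR(1) slopes and
    cross-lagged slopes at the posterior medians estimated on the original
    cohort (three diagnostic groups, 42/40/40 persons, 52 quarter-hourly
    prompts).  Log innovation variances and the innovation correlation are
    not printed in the source report's running text; the defaults encode
    within-person fluctuation SDs of roughly 1.0-1.3 rating points and a
    moderately negative arousal/self-esteem innovation correlation, which
    reproduce realistic series on the 0-10 scale.

    ``"bpd_only_cross_lag"`` keeps everything else but zeroes every
    cross-lagged mean except the negative arousal -> self-esteem effect in
    the first (BPD) group -- the cleanest regime for detection-rate checks.

    ``"null"`` zeroes all AR and cross-lagged means (white noise around
    traits).
    """
    ln = math.log
    atanh = math.atanh
    means = np.array(
        [
            # mu_A   mu_S   phi_A  phi_S  SonA   AonS   ln vA     ln vS     z
            [5.86, 3.22, 0.52, 0.38, -0.15, -0.04, ln(1.6), ln(1.4), atanh(-0.30)],
            [3.42, 5.18, 0.47, 0.42, -0.03, -0.09, ln(1.3), ln(1.5), atanh(-0.30)],
            [1.91, 8.93, 0.43, 0.36, -0.01, -0.03, ln(1.0), ln(0.7), atanh(-0.20)],
        ]
    )
    if scenario == "bpd_only_cross_lag":
        means[:, [PHI_S_ON_A, PHI_A_ON_S]] = 0.0
        means[0, PHI_S_ON_A] = -0.15
    elif scenario == "null":
        means[:, PHI_A:PHI_A_ON_S + 1] = 0.0
    elif scenario != "study":
        raise ValueError(f"unknown scenario {scenario!r}")
    omega = np.diag(
        np.array([1.0, 1.2, 0.10, 0.10, 0.10, 0.10, 0.40, 0.40, 0.30]) ** 2
    )
    kwargs = {}
    if n_per_group is not None:
        kwargs["n_per_group"] = n_per_group
    return TrueParams(group_means=means, omega=omega, **kwargs)


def default_missingness(n_occasions: int = 52, overall_rate: float = 0.5) -> MissingnessPattern:
    """Time-of-day pattern peaking in the 9-10 AM hour.

    With the standard 8 am schedule at 15-minute spacing, slots 4-7 cover
    9:00-10:00 AM; their deletion propensity is doubled, mirroring the
    morning non-response peak observed in the field, and the remaining slots
    share a mild late-evening upweighting.
    """
    w = np.ones(n_occasions)
    if n_occasions >= 8:
        w[4:8] = 2.0
    if n_occasions >= 52:
        w[-4:] = 1.3
    return MissingnessPattern(mode="time_of_day", overall_rate=overall_rate, slot_weights=w)
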