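"""Multilevel composite reliability for the two-item self-esteem scale.

The two positively-keyed indicators (item 1 and the reverse-coded item 2)
are decomposed into between-person and within-person parts with a Bayesian
two-level bivariate normal model,

    x_it = b_i + e_it,   b_i ~ N(nu, Sigma_B),   e_it ~ N(0, Sigma_W),

sampled by Gibbs (person means conjugate normal, both covariances
inverse-Wishart).  With two indicators a one-factor measurement model is
identified only under equal loadings, in which case the common-factor
variance at a level equals the inter-item covariance c at that level, and
the unit-weight composite (the analysed occasion mean) has reliability

    omega_level   = 4 c / (v1 + v2 + 2 c)
    omega_overall = 4 (c_W + c_B) / (v1W + v2W + 2 c_W + v1B + v2B + 2 c_B)

per draw, summarised as posterior medians with equal-tailed 95% credible
intervals, matching the Bayesian machinery used for the dynamic model.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import invwishart

from esmvar.dsem import McmcConfig
from esmvar.preprocess import EsmGrid

LEVELS = ("within", "between", "overall")


def omega_from_covs(sigma_w: np.ndarray, sigma_b: np.ndarray) -> dict[str, float]:
    """Closed-form unit-weight composite reliabilities from level covariances."""
    sw = np.asarray(sigma_w, dtype=float)
    sb = np.asarray(sigma_b, dtype=float)
    def level(s):
        return 4.0 * s[0, 1] / (s[0, 0] + s[1, 1] + 2.0 * s[0, 1])
    tot = sw + sb
    return {
        "within": level(sw),
        "between": level(sb),
        "overall": 4.0 * (sw[0, 1] + sb[0, 1]) / (tot[0, 0] + tot[1, 1] + 2.0 * (sw[0, 1] + sb[0, 1])),
    }


def _extract_items(grids: list[EsmGrid]) -> list[np.ndarray]:
    """Per-person (T_i, 2) arrays of occasions where both items are observed."""
    out = []
    for g in grids:
        keep = ~np.isnan(g.se_worth) & ~np.isnan(g.se_worthless)
        x = np.column_stack([g.se_worth[keep], 10.0 - g.se_worthless[keep]])
        if x.shape[0] > 0:
            out.append(x)
    return out


def multilevel_omega(
    data: list[EsmGrid] | list[np.ndarray],
    config: McmcConfig | None = None,
) -> pd.DataFrame:
    """Within-, between- and overall reliability of the two-item composite.

    Parameters
    ----------
    data : either preprocessed :class:`EsmGrid` objects (items are taken
        from ``se_worth`` and reverse-coded ``se_worthless``) or a list of
        per-person (T_i, 2) item arrays already positively keyed.
    config : MCMC settings (chains are pooled; defaults to a single chain
        of 2000 iterations, first half burn-in).

    Returns
    -------
    DataFrame indexed by level with columns estimate / ci_low / ci_high,
    estimates clipped to [0, 1].  Raises if fewer than 2 persons or, on
    average, fewer than 2 complete occasions per person are available.
    """
    config = config or McmcConfig(n_chains=1, n_iterations=2000)
    if len(data) and isinstance(data[0], EsmGrid):
        xs = _extract_items(data)  # type: ignore[arg-type]
    else:
        xs = [np.asarray(x, dtype=float) for x in data]  # type: ignore[union-attr]
    n = len(xs)
    if n < 2:
        raise ValueError("need at least two persons with complete item pairs")
    t_i = np.array([x.shape[0] for x in xs], dtype=float)
    if t_i.mean() < 2:
        raise ValueError("need on average >= 2 complete occasions per person")
    sums = np.array([x.sum(axis=0) for x in xs])  # (n, 2)
    sxx_tot = sum(x.T @ x for x in xs)  # (2, 2), pooled raw cross-products

    all_draws = []
    for c in range(config.n_chains):
        rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(config.seed), 7101, c)))
        b = sums / t_i[:, None]
        nu = b.mean(axis=0)
        resid_w = np.concatenate([x - bi for x, bi in zip(xs, b)])
        sw = np.cov(resid_w.T) + 1e-3 * np.eye(2)
        sb = np.cov(b.T) + 1e-3 * np.eye(2)
        draws = []
        for it in range(config.n_iterations):
            swi = np.linalg.inv(sw)
            sbi = np.linalg.inv(sb)
            # person means: prec = T_i SWinv + SBinv
            prec = t_i[:, None, None] * swi[None, :, :] + sbi[None, :, :]
            lin = sums @ swi.T + nu @ sbi.T
            L = np.linalg.cholesky(prec)
            mean = np.linalg.solve(prec, lin[:, :, None])[:, :, 0]
            z = rng.standard_normal((n, 2))
            b = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), z[:, :, None])[:, :, 0]
            # grand mean (flat prior)
            nu = b.mean(axis=0) + np.linalg.cholesky(sb / n) @ rng.standard_normal(2)
            # covariances
            dev_b = b - nu
            sb = invwishart.rvs(df=3 + n, scale=np.eye(2) + dev_b.T @ dev_b, random_state=rng)
            cross = b.T @ sums
            sse_w = sxx_tot - cross - cross.T + (t_i[:, None] * b).T @ b
            sw = invwishart.rvs(df=3 + int(t_i.sum()), scale=np.eye(2) + sse_w, random_state=rng)
            if it >= config.n_burn_in:
                om = omega_from_covs(sw, sb)
                draws.append([om[lv] for lv in LEVELS])
        all_draws.append(np.array(draws))
    d = np.concatenate(all_draws, axis=0)
    d = np.clip(d, 0.0, 1.0)
    if np.median(d[:, 0]) <= 0.0:
        warnings.warn(
            "within-level inter-item covariance is non-positive; within-level "
            "reliability is degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    rows = []
    for j, lv in enumerate(LEVELS):
        lo, hi = np.percentile(d[:, j], [2.5, 97.5])
        rows.append((lv, float(np.median(d[:, j])), float(lo), float(hi)))
    return pd.DataFrame(rows, columns=["level", "estimate", "ci_low", "ci_high"]).set_index("level")
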