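"""Synthetic experience-sampling cohorts from the model the estimator assumes.

Person effects are drawn multivariate-normal around group means, bivariate
within-person series follow the person's VAR(1), and prompts are deleted
according to a missingness pattern.  The two self-esteem items are generated
so that their occasion mean reproduces the latent composite exactly:

    se_worth     = S_it + d_it + u_i
    se_worthless = (10 - S_it) + d_it + u_i

with occasion-level disagreement ``d_it`` and a stable person-level offset
``u_i``.  The disagreement terms cancel in the reverse-coded composite, so
the analysed score *is* the simulated VAR variable (measurement error in the
composite is part of the innovations, exactly as the estimator assumes),
while the item-level covariance structure still yields non-trivial
within- and between-level composite reliabilities.

Everything is a pure function of (parameters, pattern, seed); per-person
randomness is keyed by group and within-group index, so regenerating a
cohort never depends on person ordering.
"""

from __future__ import annotations

import hashlib
import warnings

import numpy as np
import yaml

from esmvar.params import (
    EFFECT_NAMES,
    MissingnessPattern,
    TrueParams,
    innovation_cov,
    spectral_radius,
    stationary_cov,
    transition_matrix,
)
from esmvar.preprocess import EsmGrid


def _person_rng(seed: int, group_index: int, person_index: int, stage: int) -> np.random.Generator:
    """Independent, order-invariant stream for one person and stage."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(int(seed), int(stage), int(group_index), int(person_index)))
    )


def draw_person_effects(
    true_params: TrueParams, seed: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Draw one 9-dimensional effect vector per simulated person.

    Returns ``(eta, group_codes, person_ids)`` where ``eta`` has shape
    (n_persons, 9), group codes are 1-based positions in
    ``true_params.group_labels`` and ids look like ``"BPD_007"``.
    """
    # eigen-based factor handles PSD (including singular) omega exactly
    lam, vec = np.linalg.eigh(true_params.omega)
    chol = vec @ np.diag(np.sqrt(np.clip(lam, 0.0, None)))
    etas, codes, ids = [], [], []
    for g, (label, n_g) in enumerate(zip(true_params.group_labels, true_params.n_per_group)):
        mean = true_params.group_means[g]
        for j in range(n_g):
            rng = _person_rng(seed, g, j, stage=0)
            etas.append(mean + chol @ rng.standard_normal(mean.shape[0]))
            codes.append(g + 1)
            ids.append(f"{label}_{j + 1:03d}")
    return np.array(etas), np.array(codes, dtype=int), ids


def simulate_series(
    effects: np.ndarray,
    n_occasions: int,
    burn_in: int = 50,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Simulate one person's bivariate (arousal, self-esteem) series.

    ``y_t = mu + w_t`` with ``w_t = Phi w_{t-1} + zeta_t``; the first
    ``burn_in`` occasions are discarded so the retained series starts in the
    stationary regime.  Deterministic given the seed (or supplied rng).
    """
    if n_occasions < 0:
        raise ValueError("n_occasions must be nonnegative")
    effects = np.asarray(effects, dtype=float)
    if rng is None:
        rng = np.random.default_rng(seed)
    phi = transition_matrix(effects)
    sigma = innovation_cov(effects)
    mu = effects[:2]
    if spectral_radius(phi) >= 1.0:
        warnings.warn(
            "person transition matrix is nonstationary (spectral radius >= 1); "
            "simulating anyway",
            RuntimeWarning,
            stacklevel=2,
        )
        w = np.zeros(2)
    else:
        s0 = stationary_cov(phi, sigma)
        w = np.linalg.cholesky(s0 + 1e-12 * np.eye(2)) @ rng.standard_normal(2)
    chol = np.linalg.cholesky(sigma + 1e-12 * np.eye(2))
    total = burn_in + n_occasions
    innov = rng.standard_normal((total, 2)) @ chol.T
    out = np.empty((total, 2))
    for t in range(total):
        w = phi @ w + innov[t]
        out[t] = w
    return mu + out[burn_in:]


def generate_dataset(
    true_params: TrueParams,
    pattern: MissingnessPattern | None = None,
    seed: int = 0,
) -> dict:
    """Generate a complete cohort and its observed (missingness-applied) view.

    Returns a dict with keys ``eta`` (n, 9 truth), ``group_codes``,
    ``person_ids``, ``complete_grids`` and ``grids`` (after missingness;
    identical objects when ``pattern`` is None or has rate 0).
    """
    eta, codes, ids = draw_person_effects(true_params, seed)
    T = true_params.n_occasions
    grids: list[EsmGrid] = []
    for i, pid in enumerate(ids):
        g = codes[i] - 1
        j = int(pid.rsplit("_", 1)[1]) - 1
        rng = _person_rng(seed, g, j, stage=1)
        y = simulate_series(eta[i], T, true_params.burn_in, rng=rng)
        d = rng.normal(0.0, true_params.item_disagreement_sd, size=T)
        u = rng.normal(0.0, true_params.item_person_sd)
        worth = y[:, 1] + d + u
        worthless = (10.0 - y[:, 1]) + d + u
        grids.append(
            EsmGrid(
                participant_id=pid,
                group=int(codes[i]),
                arousal=y[:, 0],
                se_worth=worth,
                se_worthless=worthless,
            )
        )
    observed = grids
    if pattern is not None and pattern.overall_rate > 0:
        observed = [
            apply_missingness(
                g,
                pattern,
                seed=None,
                rng=_person_rng(seed, codes[i] - 1, int(g.participant_id.rsplit("_", 1)[1]) - 1, stage=2),
            )
            for i, g in enumerate(grids)
        ]
    return {
        "eta": eta,
        "group_codes": codes,
        "person_ids": ids,
        "complete_grids": grids,
        "grids": observed,
        "true_params": true_params,
        "pattern": pattern,
        "seed": int(seed),
    }


def apply_missingness(
    grid: EsmGrid,
    pattern: MissingnessPattern,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> EsmGrid:
    """Delete prompts from a complete grid according to the pattern.

    Whole prompts are deleted (all three ratings at once), mirroring
    non-response to a prompt.  Expected retained fraction is
    ``1 - overall_rate``; slot-wise deletion probability is proportional to
    the pattern's slot weights.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    probs = pattern.deletion_probs(grid.n_slots)
    drop = rng.random(grid.n_slots) < probs
    def masked(a: np.ndarray) -> np.ndarray:
        out = a.copy()
        out[drop] = np.nan
        return out
    return EsmGrid(
        participant_id=grid.participant_id,
        group=grid.group,
        arousal=masked(grid.arousal),
        se_worth=masked(grid.se_worth),
        se_worthless=masked(grid.se_worthless),
        interval_min=grid.interval_min,
    )


def dataset_hash(grids: list[EsmGrid]) -> str:
    """Stable content hash of a list of grids (order-invariant)."""
    h = hashlib.sha256()
    for g in sorted(grids, key=lambda g: g.participant_id):
        h.update(g.participant_id.encode())
        h.update(np.int64(g.group).tobytes())
        for arr in (g.arousal, g.se_worth, g.se_worthless):
            h.update(np.ascontiguousarray(np.round(arr, 10)).tobytes())
    return h.hexdigest()


def write_manifest(
    true_params: TrueParams,
    seed: int,
    path,
    pattern: MissingnessPattern | None = None,
    data_hash: str | None = None,
) -> dict:
    """Serialise the generative truth next to the data (YAML).

    The manifest is the oracle for parameter-recovery tests: it records the
    group means (both the Fisher-z innovation-correlation parameterisation
    and the implied raw innovation covariance), the level-2 covariance, the
    design sizes, the seed and optionally a content hash of the emitted
    dataset.
    """
    record = {
        "true_params": true_params.to_dict(),
        "seed": int(seed),
        "effect_names": list(EFFECT_NAMES),
    }
    sig = innovation_cov(true_params.group_means)
    record["implied_innovation_cov_per_group"] = {
        label: sig[g].tolist() for g, label in enumerate(true_params.group_labels)
    }
    if pattern is not None:
        record["missingness"] = {
            "mode": pattern.mode,
            "overall_rate": float(pattern.overall_rate),
            "slot_weights": None
            if pattern.slot_weights is None
            else pattern.slot_weights.tolist(),
        }
    if data_hash is not None:
        record["dataset_sha256"] = data_hash
    with open(path, "w") as fh:
        yaml.safe_dump(record, fh, sort_keys=False)
    return record


def read_manifest(path) -> dict:
    """Read a manifest and re-validate the recorded parameters (PSD etc.)."""
    with open(path) as fh:
        record = yaml.safe_load(fh)
    record["true_params_obj"] = TrueParams.from_dict(record["true_params"])
    return record
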