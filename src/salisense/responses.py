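"""Synthetic 36-feature colour-difference matrices.

The generator reconciles the two kinds of information reported for the
device's clinical evaluation (whose raw data are not deposited):

* per-receptor *qualitative* structure — which spots respond for which
  group, and which spots track blood glucose;
* the only *quantitative* distribution — the group-wise Euclidean norm of
  the 36-element response vector, 358.31 (±27.98) for diabetic vs
  328.47 (±31.60) for non-diabetic samples.

Rows are built in three layers.  (1) A hard responsiveness mask: a spot not
listed as responsive for the participant's group carries only |noise|, which
is exactly zero at zero noise.  (2) Responsive magnitudes: group-exclusive
spots follow a logistic activation in FBG (diabetic-linked spots switch on
above the ~126 mg/dL diagnostic cutoff, nondiabetic-linked spots switch off
above ~100 mg/dL), so borderline-glycaemia subjects from either group
produce similar, ambiguous patterns; the two glucose-tracking spots (MR+TBOH
and TMA-AgNPs) are linear in a latent bivariate-normal link to (binned,
resp. raw) FBG with the configured correlations.  (3) Calibration: each row
is rescaled — on the responsive, non-correlated channels only — so its norm
equals a draw from the configured group norm distribution.  This leaves the
FBG correlations and the noise floor untouched while matching the printed
norm statistics exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import expit

from ._util import STREAM_NORMS, STREAM_REPLICATES, STREAM_RESPONSES, stream_rng
from .chemometrics import fbg_bin_midpoints
from .config import GeneratorConfig
from .panel import (DEFAULT_PANEL, DIABETIC, FEATURE_COLUMNS, NONDIABETIC,
                    validate_panel)


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0.0:
        return np.zeros_like(x)
    return (x - x.mean()) / sd


def _activation(fbg: np.ndarray, receptor, config: GeneratorConfig) -> np.ndarray:
    """Saturating (logistic) response fraction of a group-exclusive spot."""
    groups = receptor.responsive_to
    if groups == {DIABETIC}:
        return expit((fbg - config.act_midpoint_diabetic) / config.act_tau)
    if groups == {NONDIABETIC}:
        return expit((config.act_midpoint_nondiabetic - fbg) / config.act_tau)
    return np.ones_like(fbg)


def generate_responses(cohort: pd.DataFrame, panel=DEFAULT_PANEL,
                       config: GeneratorConfig | None = None) -> pd.DataFrame:
    """n x 36 colour-difference matrix for a cohort.

    Returns a DataFrame indexed by participant id with columns S1_R .. S12_B
    on the 0-255 scale; all entries non-negative.  Deterministic for a given
    config + seed.
    """
    config = config or GeneratorConfig()
    validate_panel(panel)
    panel = tuple(sorted(panel, key=lambda r: r.index))
    n = len(cohort)
    if n == 0:
        return pd.DataFrame(np.empty((0, 36)), columns=list(FEATURE_COLUMNS))

    rng = stream_rng(config.seed, STREAM_RESPONSES)
    rng_norm = stream_rng(config.seed, STREAM_NORMS)

    fbg = cohort["fbg"].to_numpy(dtype=float)
    group = cohort["group"].to_numpy()
    z_fbg = _standardize(fbg)
    z_bin = _standardize(fbg_bin_midpoints(fbg, config.fbg_bin_edges,
                                           config.fbg_top_bin_value))

    X = np.zeros((n, 36))
    corr_mask = np.zeros((n, 36), dtype=bool)
    scal_mask = np.zeros((n, 36), dtype=bool)

    for receptor in panel:
        cols = slice(3 * (receptor.index - 1), 3 * receptor.index)
        weights = np.asarray(receptor.max_delta_rgb, dtype=float)
        member = np.isin(group, list(receptor.responsive_to))

        # Draw every stream unconditionally so the generator stays
        # reproducible when masks or the panel's responsiveness change.
        eps = rng.standard_normal(n)
        jit_r = np.clip(rng.normal(0.0, config.receptor_jitter, n), -0.15, 0.15) \
            if config.receptor_jitter > 0 else np.zeros(n)
        jit_c = rng.normal(0.0, config.channel_jitter, (n, 3)) \
            if config.channel_jitter > 0 else np.zeros((n, 3))
        noise = np.abs(rng.normal(0.0, config.noise_sd, (n, 3))) \
            if config.noise_sd > 0 else np.zeros((n, 3))

        if receptor.fbg_rho != 0.0:
            rho = receptor.fbg_rho
            z = z_bin if receptor.fbg_link == "binned" else z_fbg
            latent = rho * z + np.sqrt(1.0 - rho ** 2) * eps
            frac = np.clip(config.corr_base + config.corr_amp * latent, 0.0, 0.95)
            block = frac[:, None] * weights[None, :]
            corr_mask[:, cols] = member[:, None]
        else:
            act = _activation(fbg, receptor, config)
            block = (act * (1.0 + jit_r))[:, None] * weights[None, :] + jit_c
            block = np.clip(block, 0.0, None)
            scal_mask[:, cols] = member[:, None]

        X[:, cols] = np.where(member[:, None], block, noise)

    # --- norm calibration -------------------------------------------------
    target = np.empty(n)
    for g, mean, sd in ((DIABETIC, config.norm_mean_d, config.norm_sd_d),
                        (NONDIABETIC, config.norm_mean_nd, config.norm_sd_nd)):
        sel = group == g
        draws = rng_norm.normal(mean, sd, int(sel.sum()))
        lim = config.norm_truncation * sd
        target[sel] = np.clip(draws, mean - lim, max(mean - lim, 0.0) + 2 * lim)

    fixed_sq = np.sum(np.where(scal_mask, 0.0, X) ** 2, axis=1)
    scal_sq = np.sum(np.where(scal_mask, X, 0.0) ** 2, axis=1)
    scalable = scal_sq > 1e-12
    factor = np.ones(n)
    need = np.maximum(target[scalable] ** 2 - fixed_sq[scalable], 0.0)
    factor[scalable] = np.sqrt(need / scal_sq[scalable])
    X = np.where(scal_mask, X * factor[:, None], X)

    # Cap single-channel shifts and push the excess onto the row's other
    # responsive channels, keeping the row norm intact (a saturating spot
    # cannot shift further than the 8-bit range allows).
    cap = config.delta_cap
    for _ in range(8):
        over = scal_mask & (X > cap)
        if not over.any():
            break
        free = scal_mask & ~over
        fixed2 = np.sum(np.where(free, 0.0, np.minimum(X, cap)) ** 2, axis=1)
        free_sq = np.sum(np.where(free, X, 0.0) ** 2, axis=1)
        rows = over.any(axis=1) & (free_sq > 1e-12)
        f2 = np.ones(n)
        f2[rows] = np.sqrt(np.maximum(target[rows] ** 2 - fixed2[rows], 0.0)
                           / free_sq[rows])
        X = np.where(over, cap, np.where(free, X * f2[:, None], X))

    X = np.clip(X, 0.0, 255.0)
    return pd.DataFrame(X, index=pd.Index(cohort["id"], name="id"),
                        columns=list(FEATURE_COLUMNS))


def generate_replicates(response_row, k: int, config: GeneratorConfig | None = None,
                        group: str = DIABETIC) -> np.ndarray:
    """k noisy re-measurements of one sample on freshly fabricated devices.

    Replicate noise is multiplicative (a device-level gain factor), so the
    RSD% of the replicate norms converges to the configured group RSD for
    large k.  Returns a (k, 36) array.
    """
    if k < 1:
        raise ValueError("need at least one replicate")
    config = config or GeneratorConfig()
    row = np.asarray(response_row, dtype=float)
    if row.ndim != 1:
        raise ValueError("response_row must be 1-D")
    rsd = config.replicate_rsd_d if group == DIABETIC else config.replicate_rsd_nd
    rng = stream_rng(config.seed, STREAM_REPLICATES)
    gain = 1.0 + rng.normal(0.0, rsd / 100.0, k)
    return np.clip(gain[:, None] * row[None, :], 0.0, 255.0)


def write_response_csv(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, index=True, float_format="%.6f")


def read_response_csv(path) -> pd.DataFrame:
    matrix = pd.read_csv(path, index_col=0)
    missing = set(FEATURE_COLUMNS) - set(matrix.columns)
    if missing:
        raise ValueError(f"response CSV missing columns: {sorted(missing)}")
    return matrix[list(FEATURE_COLUMNS)]
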