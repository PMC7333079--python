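"""Evaluation metrics: unit-normalized RMSE, Fisher-averaged Pearson, stance masking.

RMSE conventions follow standard gait-analysis reporting: joint angles in
degrees, joint moments as a percentage of body weight times body height
(%BW*BH), and ground reaction forces as a percentage of body weight (%BW).
GRFs are evaluated over the stance phase only, detected from the reference
vertical GRF.  Correlations are averaged through the Fisher z-transform.
"""

from __future__ import annotations

import warnings

import numpy as np

GRAVITY = 9.81
STANCE_THRESHOLD_BW = 0.05  # vertical GRF threshold (fraction of body weight)

#: metric class of each estimated variable
VARIABLE_CLASSES = {
    "hip_angle_deg": "angle",
    "knee_angle_deg": "angle",
    "ankle_angle_deg": "angle",
    "hip_moment_nm": "moment",
    "knee_moment_nm": "moment",
    "ankle_moment_nm": "moment",
    "grf_ap_bw": "grf",
    "grf_v_bw": "grf",
}

#: unit string of the reported RMSE per class
CLASS_UNITS = {"angle": "deg", "moment": "%BW*BH", "grf": "%BW"}


def rmse(
    est: np.ndarray,
    ref: np.ndarray,
    variable_class: str,
    bw=None,
    bh=None,
    mask: np.ndarray | None = None,
) -> float:
    """Root mean square error over all points of all cycles, in reporting units.

    Parameters
    ----------
    est, ref : (n, 100) trajectory sets in storage units (deg / N m / BW)
    variable_class : 'angle' | 'moment' | 'grf'
    bw, bh : per-cycle body weight (kg) and height (m); required for moments
    mask : optional boolean (n, 100) selecting the evaluated points
    """
    est = np.atleast_2d(np.asarray(est, dtype=float))
    ref = np.atleast_2d(np.asarray(ref, dtype=float))
    if est.shape != ref.shape:
        raise ValueError(f"shape mismatch: est {est.shape} vs ref {ref.shape}")
    err = est - ref
    if variable_class == "angle":
        pass  # already degrees
    elif variable_class == "moment":
        if bw is None or bh is None:
            raise ValueError("moment RMSE needs body weight and height")
        denom = np.asarray(bw, dtype=float) * GRAVITY * np.asarray(bh, dtype=float)
        err = err / np.atleast_1d(denom)[:, None] * 100.0
    elif variable_class == "grf":
        err = err * 100.0  # BW -> %BW
    else:
        raise ValueError(f"unknown variable class {variable_class!r}")
    if mask is not None:
        if mask.shape != est.shape:
            raise ValueError("mask shape mismatch")
        if not mask.any():
            warnings.warn("empty evaluation mask; RMSE undefined, returning nan")
            return float("nan")
        err = err[mask]
    return float(np.sqrt(np.mean(err**2)))


def rmse_relative(est: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None) -> float:
    """RMSE divided by the reference range (max - min over evaluated points)."""
    est = np.atleast_2d(est)
    ref = np.atleast_2d(ref)
    sel = ref[mask] if mask is not None else ref
    rng = float(sel.max() - sel.min())
    raw = rmse(est, ref, "angle", mask=mask)  # unit-free: no scaling applied
    return raw / rng if rng > 0 else float("nan")


def pearson_per_cycle(est: np.ndarray, ref: np.ndarray, mask: np.ndarray | None = None):
    """Pearson r of each cycle (masked points excluded); degenerate cycles -> nan."""
    est = np.atleast_2d(est)
    ref = np.atleast_2d(ref)
    out = np.empty(est.shape[0])
    for i in range(est.shape[0]):
        sel = mask[i] if mask is not None else slice(None)
        a, b = est[i][sel], ref[i][sel]
        if np.size(a) < 2 or a.std() == 0 or b.std() == 0:
            out[i] = np.nan
            continue
        out[i] = np.corrcoef(a, b)[0, 1]
    return out


def pearson_mean(r_values) -> float:
    """Fisher-transform average: tanh(mean(atanh(r))); |r| = 1 clipped with warning."""
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return float("nan")
    if np.any(np.abs(r) >= 1.0):
        warnings.warn("correlations at +-1 clipped before the Fisher transform")
        r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    return float(np.tanh(np.mean(np.arctanh(r))))


def stance_mask(grf_v: np.ndarray, threshold: float = STANCE_THRESHOLD_BW) -> np.ndarray:
    """Contiguous initial stance region of a 100-point cycle.

    Cycles start at initial contact, so stance is the first contiguous run at
    or above the threshold (default 5% BW); the force may still be ramping up
    from zero at point 0.  A mid-swing re-contact is not part of the mask.  An
    all-swing trajectory yields an empty mask with a warning.
    """
    grf_v = np.asarray(grf_v, dtype=float)
    above = grf_v >= threshold
    mask = np.zeros_like(above)
    if not above.any():
        warnings.warn("vertical GRF never reaches the stance threshold; empty stance mask")
        return mask
    start = int(np.argmax(above))
    rest = above[start:]
    end = start + (int(np.argmin(rest)) if not rest.all() else rest.size)
    mask[start:end] = True
    return mask


def stance_masks(grf_v_set: np.ndarray, threshold: float = STANCE_THRESHOLD_BW) -> np.ndarray:
    """Per-cycle stance masks for an (n, 100) set of reference vertical GRFs."""
    return np.stack([stance_mask(g, threshold) for g in np.atleast_2d(grf_v_set)])
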