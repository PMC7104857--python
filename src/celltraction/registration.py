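"""Drift correction by normalized cross-correlation template matching.

Stage drift between frames of a bead time-lapse is estimated by matching
a template (by default the central quarter of the reference frame)
against every frame with the normalized correlation coefficient, located
to sub-pixel precision with a 3-point Gaussian peak fit per axis, and
removed by spline-interpolated translation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.feature import match_template

__all__ = ["DriftTrajectory", "drift_correct", "subpixel_peak"]


@dataclass
class DriftTrajectory:
    """Per-frame drift (dx, dy) in px relative to the reference frame."""

    dx: np.ndarray
    dy: np.ndarray
    correlation: np.ndarray      # peak NCC per frame
    alignable: np.ndarray        # False where the peak fell below the floor


# design matrix for the 9-point log-quadratic fit (1, x, y, x², y², xy)
_OFFS = np.array([(dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1)], dtype=float)
_A9 = np.column_stack(
    [np.ones(9), _OFFS[:, 1], _OFFS[:, 0], _OFFS[:, 1] ** 2, _OFFS[:, 0] ** 2,
     _OFFS[:, 1] * _OFFS[:, 0]]
)
_A9_PINV = np.linalg.pinv(_A9)


def subpixel_peak(corr: np.ndarray, peak: tuple[int, int]) -> tuple[float, float]:
    """Refine an integer correlation peak to sub-pixel precision.

    Fits a 2-D Gaussian through the 3×3 neighbourhood (least-squares
    quadratic in log space), which handles tilted, non-separable peaks:
    a per-axis 3-point fit leaks displacement from one axis into the
    other whenever the peak's principal axes are rotated.  Falls back
    to per-axis 3-point fits (Gaussian, else parabolic) when the
    neighbourhood contains non-positive samples or the quadratic is not
    concave.  Returns the (row, col) offset from the integer peak,
    clamped to (−1, 1) and zero at image borders.
    """
    iy, ix = peak
    ny, nx = corr.shape
    if 0 < iy < ny - 1 and 0 < ix < nx - 1:
        patch = corr[iy - 1:iy + 2, ix - 1:ix + 2]
        if np.all(patch > 0):
            coef = _A9_PINV @ np.log(patch).ravel()
            _, b, c, d, e, f = coef
            det = 4.0 * d * e - f * f
            if d < 0 and det > 0:  # concave quadratic
                dx = (-2.0 * e * b + f * c) / det
                dy = (-2.0 * d * c + f * b) / det
                if abs(dx) < 1.0 and abs(dy) < 1.0:
                    return float(dy), float(dx)
    # fallback: separable 3-point fits
    out = []
    for axis, idx in ((0, iy), (1, ix)):
        if idx <= 0 or idx >= corr.shape[axis] - 1:
            out.append(0.0)
            continue
        if axis == 0:
            cm, c0, cp = corr[idx - 1, ix], corr[idx, ix], corr[idx + 1, ix]
        else:
            cm, c0, cp = corr[iy, idx - 1], corr[iy, idx], corr[iy, idx + 1]
        if cm > 0 and c0 > 0 and cp > 0:
            lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        else:
            lm, l0, lp = cm, c0, cp
        denom = lm + lp - 2.0 * l0
        if denom >= 0 or not np.isfinite(denom):
            out.append(0.0)
        else:
            out.append(float(np.clip(0.5 * (lm - lp) / denom, -0.5, 0.5)))
    return out[0], out[1]


def _default_template_slices(shape: tuple[int, int]) -> tuple[slice, slice]:
    """Central region of the frame, excluding a 1/8 margin per side.

    A large template keeps the correlation anchored on the static
    majority of the bead carpet even when a cell deforms the gel
    locally; the margin leaves room to search for the drift.
    """
    ny, nx = shape
    return slice(ny // 8, ny - ny // 8), slice(nx // 8, nx - nx // 8)


def _locate(frame: np.ndarray, template: np.ndarray) -> tuple[float, float, float]:
    """Sub-pixel template position (row, col) and peak NCC in a frame."""
    ncc = match_template(frame, template, pad_input=False)
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    dy, dx = subpixel_peak(ncc, peak)
    return peak[0] + dy, peak[1] + dx, float(ncc[peak])


def drift_correct(
    stack: np.ndarray,
    template_region: tuple[slice, slice] | None = None,
    reference_index: int = 0,
    min_correlation: float = 0.5,
    interpolation_order: int = 3,
) -> tuple[np.ndarray, DriftTrajectory]:
    """Align a frame stack to its reference frame.

    Parameters
    ----------
    stack : ndarray, shape (n_frames, ny, nx)
        Image sequence (a 2-frame pair is the usual TFM case).
    template_region : pair of slices, optional
        Region of the reference frame used as the matching template;
        default is the central 25% of the frame.
    reference_index : int
        Frame that defines zero drift.
    min_correlation : float
        Frames whose peak NCC falls below this are flagged unalignable
        (returned untranslated).

    Returns
    -------
    aligned, trajectory
    """
    stack = np.asarray(stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, ny, nx)")
    n = stack.shape[0]
    region = template_region or _default_template_slices(stack.shape[1:])
    template = stack[reference_index][region]
    if template.shape[0] >= stack.shape[1] or template.shape[1] >= stack.shape[2]:
        raise ValueError("template region must be strictly inside the frame")

    ry0, rx0, _ = _locate(stack[reference_index], template)
    dx = np.zeros(n)
    dy = np.zeros(n)
    cc = np.zeros(n)
    ok = np.ones(n, dtype=bool)
    aligned = np.empty_like(stack)
    for i in range(n):
        if i == reference_index:
            cc[i] = 1.0
            aligned[i] = stack[i]
            continue
        py, px, c = _locate(stack[i], template)
        cc[i] = c
        if c < min_correlation:
            ok[i] = False
            aligned[i] = stack[i]
            continue
        dy[i] = py - ry0
        dx[i] = px - rx0
        aligned[i] = ndimage.shift(
            stack[i], (-dy[i], -dx[i]), order=interpolation_order, mode="nearest"
        )
    return aligned, DriftTrajectory(dx=dx, dy=dy, correlation=cc, alignable=ok)
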