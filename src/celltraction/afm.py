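"""Hertz-model analysis of AFM nano-indentation curves.

A spherical tip of radius R pressed a depth δ into an elastic sample of
Young's modulus E and Poisson ratio ν exerts the Hertz force

    F(δ) = (4/3) · E / (1 − ν²) · √R · δ^{3/2},

valid for δ ≪ R.  The fitter estimates E and the contact point jointly
by least squares on a curve containing both a pre-contact baseline and
the indentation ramp.  Cantilever spring constants come from the
thermal fluctuation method (equipartition of the thermal deflection
variance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

BOLTZMANN = 1.380649e-23  # J/K

__all__ = [
    "IndentationCurve",
    "HertzFit",
    "hertz_force",
    "hertz_fit",
    "thermal_spring_constant",
    "stiffness_map",
    "read_indentation_table",
]


@dataclass
class IndentationCurve:
    """Force vs indentation samples.

    ``depth`` in µm on the piezo axis (negative before nominal
    contact), ``force`` in N.  ``contact_point`` is the known true
    contact depth for synthetic curves, or the fitted one.
    """

    depth: np.ndarray
    force: np.ndarray
    tip_radius: float            # µm
    contact_point: float | None = None

    def __post_init__(self) -> None:
        self.depth = np.asarray(self.depth, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.depth.shape != self.force.shape or self.depth.ndim != 1:
            raise ValueError("depth and force must be matching 1-D arrays")
        if np.any(np.diff(self.depth) < 0):
            raise ValueError("depth must be non-decreasing")


@dataclass(frozen=True)
class HertzFit:
    """Result of a joint (E, contact point) Hertz fit."""

    youngs_modulus: float        # Pa
    contact_point: float         # µm
    residual_rms: float          # N
    poisson_ratio: float
    converged: bool


def hertz_force(
    depth_um, youngs_modulus: float, tip_radius_um: float, poisson_ratio: float = 0.5
):
    """Closed-form Hertz force (N) at indentation depth (µm, clipped at 0)."""
    delta_m = np.clip(np.asarray(depth_um, dtype=float), 0.0, None) * 1e-6
    r_m = tip_radius_um * 1e-6
    return (
        (4.0 / 3.0)
        * youngs_modulus
        / (1.0 - poisson_ratio ** 2)
        * np.sqrt(r_m)
        * delta_m ** 1.5
    )


def thermal_spring_constant(deflection_variance: float, temperature: float = 298.0) -> float:
    """Cantilever spring constant from thermal fluctuations (N/m).

    Equipartition for a simple harmonic oscillator:
    k = k_B·T / ⟨x²⟩, with the deflection variance in m².
    """
    if deflection_variance <= 0 or temperature <= 0:
        raise ValueError("variance and temperature must be positive")
    return BOLTZMANN * temperature / deflection_variance


def hertz_fit(
    curve: IndentationCurve,
    tip_radius: float | None = None,
    poisson_ratio: float = 0.5,
) -> HertzFit:
    """Joint least-squares fit of Young's modulus and contact point.

    The model is F = A·max(z − z₀, 0)^{3/2} with A carrying E; fitting
    the contact point jointly avoids the bias of threshold-based
    contact detection on noisy curves.  A result with E pinned at the
    parameter bound or a failed solver is flagged ``converged=False``.
    """
    r = tip_radius if tip_radius is not None else curve.tip_radius
    z = curve.depth
    f = curve.force
    if z.size < 8:
        raise ValueError("curve too short to fit")

    f_scale = max(np.abs(f).max(), 1e-15)
    span = z.max() - z.min()

    # initial contact point: first sample rising above the baseline band
    base = f[: max(3, z.size // 10)]
    thr = base.mean() + 3.0 * (base.std() + 1e-3 * f_scale)
    above = np.flatnonzero(f > thr)
    z0_init = z[above[0]] if above.size else z[z.size // 2]
    depth_end = max(z.max() - z0_init, 1e-3 * span)
    e_init = max(
        f[-1] / ((4.0 / 3.0) / (1.0 - poisson_ratio ** 2) * np.sqrt(r * 1e-6) * (depth_end * 1e-6) ** 1.5),
        1.0,
    )

    def resid(params):
        log_e, z0 = params
        return (hertz_force(z - z0, np.exp(log_e), r, poisson_ratio) - f) / f_scale

    lo = [np.log(1e-2), z.min()]
    hi = [np.log(1e9), z.max() - 1e-6 * span]
    sol = least_squares(
        resid,
        x0=[np.log(e_init), z0_init],
        bounds=(lo, hi),
        xtol=1e-12,
        ftol=1e-12,
    )
    e_fit = float(np.exp(sol.x[0]))
    z0_fit = float(sol.x[1])
    rms = float(np.sqrt(np.mean((resid(sol.x) * f_scale) ** 2)))
    at_bound = (
        sol.x[0] <= lo[0] + 1e-6
        or sol.x[0] >= hi[0] - 1e-6
        or sol.x[1] >= hi[1] - 1e-9
    )
    return HertzFit(
        youngs_modulus=e_fit,
        contact_point=z0_fit,
        residual_rms=rms,
        poisson_ratio=poisson_ratio,
        converged=bool(sol.success and not at_bound),
    )


def stiffness_map(
    curves, tip_radius: float | None = None, poisson_ratio: float = 0.5
) -> tuple[np.ndarray, dict]:
    """Per-position Hertz fits over a grid of indentation curves.

    ``curves`` is a 2-D nested sequence (e.g. 10×10) of
    IndentationCurve or None; failed or missing fits become NaN, not
    errors.  Returns the E map (Pa) and a summary dict with the median,
    median absolute deviation, and counts.
    """
    nrow = len(curves)
    ncol = len(curves[0])
    emap = np.full((nrow, ncol), np.nan)
    for i in range(nrow):
        for j in range(ncol):
            c = curves[i][j]
            if c is None:
                continue
            try:
                fit = hertz_fit(c, tip_radius=tip_radius, poisson_ratio=poisson_ratio)
            except (ValueError, RuntimeError):
                continue
            if fit.converged:
                emap[i, j] = fit.youngs_modulus
    good = emap[np.isfinite(emap)]
    summary = {
        "median_pa": float(np.median(good)) if good.size else float("nan"),
        "mad_pa": float(np.median(np.abs(good - np.median(good)))) if good.size else float("nan"),
        "n_fit": int(good.size),
        "n_missing": int(nrow * ncol - good.size),
    }
    return emap, summary


def read_indentation_table(
    path,
    tip_radius: float,
    depth_column: int | str = 0,
    force_column: int | str = 1,
    **read_kwargs,
) -> IndentationCurve:
    """Read a two-column (depth µm, force N) text table into a curve."""
    df = pd.read_csv(path, **read_kwargs)
    depth = df.iloc[:, depth_column] if isinstance(depth_column, int) else df[depth_column]
    force = df.iloc[:, force_column] if isinstance(force_column, int) else df[force_column]
    return IndentationCurve(
        depth=depth.to_numpy(float), force=force.to_numpy(float), tip_radius=tip_radius
    )
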