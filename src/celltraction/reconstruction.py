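"""Regularized Fourier-transform traction cytometry (FTTC).

The substrate is modelled as an isotropic, linearly elastic half-space.
A tangential traction field ``T(x)`` applied at the surface produces a
surface displacement ``u(x)`` through the Boussinesq solution; in Fourier
space the relation is algebraic,

    u(k) = G(k) · T(k),

with the 2×2 symmetric kernel (k in rad/µm, E in Pa)

    G(k) = 2 (1 + ν) / (E k³) · [ (1−ν) k² + ν ky²,   −ν kx ky
                                  −ν kx ky,            (1−ν) k² + ν kx² ].

Reconstruction inverts this relation per wavevector with 0th-order
Tikhonov regularization, T(k) = (GᵀG + λI)⁻¹ Gᵀ u(k).  The zero
wavevector is excluded: a traction field in mechanical equilibrium has no
net force, so the DC term of the traction is zero, and rigid-body mean
displacement carries no traction information.

The default regularization weight λ = 1e-10 is small relative to the
squared kernel entries at the grid scales used here, so it suppresses
only the noise-dominated highest frequencies.  Its effective strength
depends on the units of G (µm/Pa here); it is exposed as a parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fields import DisplacementField, SubstrateSpec, TractionField

__all__ = [
    "greens_tensor_fourier",
    "fttc_reconstruct",
    "estimate_noise_floor",
    "NoiseEstimate",
]


def greens_tensor_fourier(kx, ky, substrate: SubstrateSpec):
    """Boussinesq half-space kernel in Fourier space.

    Parameters
    ----------
    kx, ky : array-like
        Angular wavenumbers in rad/µm.  Must not both be zero anywhere.
    substrate : SubstrateSpec
        Gel elastic constants.

    Returns
    -------
    gxx, gxy, gyy : ndarray
        Components of the symmetric 2×2 tensor, in µm/Pa.
    """
    kx = np.asarray(kx, dtype=float)
    ky = np.asarray(ky, dtype=float)
    k = np.hypot(kx, ky)
    if np.any(k == 0):
        raise ValueError("zero wavevector is singular; handle the DC term separately")
    e = substrate.youngs_modulus
    nu = substrate.poisson_ratio
    pref = 2.0 * (1.0 + nu) / (e * k ** 3)
    gxx = pref * ((1.0 - nu) * k ** 2 + nu * ky ** 2)
    gyy = pref * ((1.0 - nu) * k ** 2 + nu * kx ** 2)
    gxy = pref * (-nu * kx * ky)
    return gxx, gxy, gyy


def _padded_size(n: int, pad_factor: float) -> int:
    """Next power of two at least ``pad_factor * n``."""
    return int(2 ** np.ceil(np.log2(max(2, int(np.ceil(n * pad_factor))))))


def _wavenumbers(ny: int, nx: int, spacing_um: float):
    kx = 2.0 * np.pi * np.fft.fftfreq(nx, d=spacing_um)
    ky = 2.0 * np.pi * np.fft.fftfreq(ny, d=spacing_um)
    return np.meshgrid(kx, ky)


def fttc_reconstruct(
    displacement: DisplacementField,
    substrate: SubstrateSpec,
    lambda_reg: float = 1e-10,
    pad_factor: float = 2.0,
) -> TractionField:
    """Reconstruct the traction field from a validated displacement field.

    The displacement grid is mean-subtracted, zero-padded to the next
    power of two (at least ``pad_factor`` times the grid), transformed,
    inverted per wavevector with Tikhonov damping, and cropped back.

    Raises
    ------
    ValueError
        If the field still contains invalid nodes (run the
        normalized-median validator first) or non-finite values.
    """
    if not displacement.valid.all():
        raise ValueError(
            "displacement field contains invalid nodes; run "
            "normalized_median_validate() before reconstruction"
        )
    u = displacement.u
    v = displacement.v
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))):
        raise ValueError("displacement contains non-finite values")

    ny, nx = u.shape
    npx = _padded_size(nx, pad_factor)
    npy = _padded_size(ny, pad_factor)
    upad = np.zeros((npy, npx))
    vpad = np.zeros((npy, npx))
    upad[:ny, :nx] = u - u.mean()
    vpad[:ny, :nx] = v - v.mean()

    spacing = displacement.spacing_um
    kxg, kyg = _wavenumbers(npy, npx, spacing)
    gxx, gxy, gyy = _greens_safe(kxg, kyg, substrate)

    uh = np.fft.fft2(upad)
    vh = np.fft.fft2(vpad)

    # Tikhonov solve of the symmetric 2x2 system per wavevector:
    # T = (G^T G + lam I)^-1 G^T u, with G symmetric.
    a = gxx * gxx + gxy * gxy + lambda_reg
    b = gxy * (gxx + gyy)
    c = gxy * gxy + gyy * gyy + lambda_reg
    det = a * c - b * b
    rhs_x = gxx * uh + gxy * vh
    rhs_y = gxy * uh + gyy * vh
    txh = (c * rhs_x - b * rhs_y) / det
    tyh = (a * rhs_y - b * rhs_x) / det
    txh[0, 0] = 0.0
    tyh[0, 0] = 0.0

    tx = np.real(np.fft.ifft2(txh))[:ny, :nx]
    ty = np.real(np.fft.ifft2(tyh))[:ny, :nx]
    # cropping the padded grid leaves a residual mean; remove it so the
    # returned field satisfies force balance at machine precision
    tx -= tx.mean()
    ty -= ty.mean()
    return TractionField(
        grid_x=displacement.grid_x,
        grid_y=displacement.grid_y,
        tx=tx,
        ty=ty,
        substrate=substrate,
        lambda_reg=lambda_reg,
    )


def _greens_safe(kxg, kyg, substrate):
    """Kernel on a full FFT grid with the DC entry left as a dummy."""
    kx = kxg.copy()
    ky = kyg.copy()
    kx[0, 0] = 1.0  # dummy; the DC term of the solution is forced to zero
    return greens_tensor_fourier(kx, ky, substrate)


@dataclass(frozen=True)
class NoiseEstimate:
    """Traction noise floor estimated from a cell-free region."""

    noise_floor: float  # Pa
    method: str
    n_nodes: int


def estimate_noise_floor(
    traction: TractionField,
    cell_free_mask: np.ndarray,
    percentile: float = 95.0,
) -> NoiseEstimate:
    """Estimate the traction noise floor from cell-free grid nodes.

    ``cell_free_mask`` is boolean, either on the traction grid directly
    or on the source image pixel grid (sampled at the nearest node).
    The floor is the given percentile (default 95th) of the traction
    magnitude over the masked nodes.
    """
    mask = np.asarray(cell_free_mask, dtype=bool)
    mag = traction.magnitude
    if mask.shape != mag.shape:
        # pixel-space mask: sample at node positions
        iy = np.clip(np.round(traction.grid_y).astype(int), 0, mask.shape[0] - 1)
        ix = np.clip(np.round(traction.grid_x).astype(int), 0, mask.shape[1] - 1)
        mask = mask[np.ix_(iy, ix)]
    if not mask.any():
        raise ValueError("cell-free mask selects no grid nodes")
    values = mag[mask]
    floor = float(np.percentile(values, percentile))
    return NoiseEstimate(noise_floor=floor, method=f"p{percentile:g}", n_nodes=int(mask.sum()))
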