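"""Synthetic ground-truth generators for every pipeline input.

The central piece is a planted traction scene: a handful of oval,
Gaussian-profile force foci (arranged as antiparallel dipole pairs, the
way a contractile cell loads its substrate) pushed through the Boussinesq
forward model to obtain the surface displacement field, which is then
rendered into a pair of fluorescent-bead images (relaxed reference and
deformed, with drift and photon noise).  Because the planted traction is
known exactly, every downstream stage — drift correction, PIV, the FTTC
inversion, focus segmentation — can be scored against ground truth.

Also here: Hertz-law indentation curves for the AFM fitter, striped
fibre textures for the orientation analyzer, and Gaussian force-profile
cohorts with planted subpopulation labels for the clustering stage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .fields import DisplacementField, SubstrateSpec, TractionField
from .reconstruction import _padded_size, _wavenumbers, _greens_safe

__all__ = [
    "PlantedFocusSpec",
    "SceneSpec",
    "CohortSpec",
    "default_scene",
    "default_cohort",
    "plant_traction_field",
    "forward_displacement",
    "render_bead_images",
    "render_cell_image",
    "simulate_indentation_curve",
    "render_fiber_image",
    "simulate_force_profile_cohort",
]


@dataclass(frozen=True)
class PlantedFocusSpec:
    """A single Gaussian traction focus.

    ``center`` in µm from the image origin, ``peak_stress`` in Pa,
    ``sigma`` the Gaussian radius in µm, ``direction`` a unit vector
    giving the traction orientation.
    """

    center: tuple[float, float]
    peak_stress: float
    sigma: float
    direction: tuple[float, float]

    def __post_init__(self) -> None:
        if self.peak_stress < 0:
            raise ValueError("peak_stress must be >= 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        n = float(np.hypot(*self.direction))
        if not np.isclose(n, 1.0, atol=1e-6):
            raise ValueError("direction must be a unit vector")


@dataclass(frozen=True)
class SceneSpec:
    """Full description of a synthetic bead-image scene."""

    substrate: SubstrateSpec
    image_shape: tuple[int, int]          # (ny, nx) px
    foci: tuple[PlantedFocusSpec, ...]
    bead_density: float = 1.0             # beads / µm²
    psf_sigma: float = 0.23               # µm (≈1.5 px at 0.153 µm/px)
    photon_noise_sd: float = 0.10         # intensity units (bead peak = 1)
    drift: tuple[float, float] = (0.0, 0.0)  # px per frame (applied to deformed)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bead_density <= 0:
            raise ValueError("bead_density must be positive")

    @property
    def extent_um(self) -> tuple[float, float]:
        ny, nx = self.image_shape
        p = self.substrate.pixel_size
        return ny * p, nx * p


def _dipole_pair(
    center: tuple[float, float],
    separation: float,
    axis_deg: float,
    peak_stress: float,
    sigma: float,
) -> tuple[PlantedFocusSpec, PlantedFocusSpec]:
    """Two antiparallel foci pulling toward their common centre."""
    th = np.deg2rad(axis_deg)
    ax = np.array([np.cos(th), np.sin(th)])
    c = np.asarray(center, dtype=float)
    c1 = tuple(c - 0.5 * separation * ax)
    c2 = tuple(c + 0.5 * separation * ax)
    return (
        PlantedFocusSpec(c1, peak_stress, sigma, tuple(ax)),
        PlantedFocusSpec(c2, peak_stress, sigma, tuple(-ax)),
    )


def default_scene(seed: int = 0, image_shape: tuple[int, int] = (1024, 1024)) -> SceneSpec:
    """The reference study scene: a contractile cell on soft gel.

    Four foci (two antiparallel dipole pairs) of 600–800 Pa peak stress
    and σ = 4 µm sit at the centre of a 1024×1024 px field (≈157×157 µm
    at 0.153 µm/px) on a 4.5 kPa, ν = 0.5 substrate.  Pairwise focus
    separations are ≥ 6σ so each focus resolves as its own structure,
    and the wide cell-free margin both lets the dipole far field decay
    before the periodic boundary and provides the region for
    noise-floor estimation.  The default photon noise puts the
    reconstructed cell-free traction floor near the 50 Pa design point.
    """
    sub = SubstrateSpec()
    ny, nx = image_shape
    cy = 0.5 * ny * sub.pixel_size
    cx = 0.5 * nx * sub.pixel_size
    foci = _dipole_pair((cx, cy - 15.0), 30.0, 0.0, 800.0, 4.0) + _dipole_pair(
        (cx, cy + 15.0), 30.0, 0.0, 600.0, 4.0
    )
    return SceneSpec(
        substrate=sub,
        image_shape=image_shape,
        foci=foci,
        drift=(2.0, 1.5),
        seed=seed,
    )


def plant_traction_field(scene: SceneSpec) -> TractionField:
    """Sample the planted foci on the pixel grid and balance the scene.

    Each focus contributes ``peak · exp(−r²/2σ²) · direction``.  Any
    residual net force (dipole pairs cancel only up to discretization)
    is removed by subtracting a broad Gaussian-weighted counter-traction
    centred on the field, so the scene satisfies the zero-net-force
    assumption of the half-space inversion to machine precision.
    """
    p = scene.substrate.pixel_size
    ny, nx = scene.image_shape
    hy, wx = scene.extent_um
    x = (np.arange(nx) + 0.5) * p
    y = (np.arange(ny) + 0.5) * p
    xx, yy = np.meshgrid(x, y)

    tx = np.zeros((ny, nx))
    ty = np.zeros((ny, nx))
    for f in scene.foci:
        cx, cy = f.center
        if not (3 * f.sigma <= cx <= wx - 3 * f.sigma and 3 * f.sigma <= cy <= hy - 3 * f.sigma):
            raise ValueError(
                f"focus at {f.center} µm closer than 3σ to the field edge "
                f"({wx:.1f}×{hy:.1f} µm)"
            )
        g = np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * f.sigma ** 2))
        tx += f.peak_stress * f.direction[0] * g
        ty += f.peak_stress * f.direction[1] * g

    # broad-support counter-traction absorbs the discretization residual
    sig_s = 0.2 * min(hy, wx)
    w = np.exp(-((xx - wx / 2) ** 2 + (yy - hy / 2) ** 2) / (2.0 * sig_s ** 2))
    w /= w.sum()
    tx -= tx.sum() * w
    ty -= ty.sum() * w

    return TractionField(
        grid_x=x / p,  # pixel-center coordinates in px
        grid_y=y / p,
        tx=tx,
        ty=ty,
        substrate=scene.substrate,
    )


def forward_displacement(
    traction: TractionField,
    substrate: SubstrateSpec | None = None,
    pad_factor: float = 2.0,
) -> DisplacementField:
    """Boussinesq forward model: traction grid → surface displacement (µm).

    Applies ``u(k) = G(k) · T(k)`` on the zero-padded Fourier grid with
    the zero-frequency term set to zero (the mean displacement of an
    infinite half-space under a balanced load is undetermined and is
    removed by convention).
    """
    if substrate is None:
        substrate = traction.substrate
    tx, ty = traction.tx, traction.ty
    if not (np.all(np.isfinite(tx)) and np.all(np.isfinite(ty))):
        raise ValueError("traction contains non-finite values")
    ny, nx = tx.shape
    npx = _padded_size(nx, pad_factor)
    npy = _padded_size(ny, pad_factor)
    txp = np.zeros((npy, npx))
    typ = np.zeros((npy, npx))
    txp[:ny, :nx] = tx
    typ[:ny, :nx] = ty

    spacing = traction.spacing_um
    kxg, kyg = _wavenumbers(npy, npx, spacing)
    gxx, gxy, gyy = _greens_safe(kxg, kyg, substrate)

    th_x = np.fft.fft2(txp)
    th_y = np.fft.fft2(typ)
    uh = gxx * th_x + gxy * th_y
    vh = gxy * th_x + gyy * th_y
    uh[0, 0] = 0.0
    vh[0, 0] = 0.0
    u = np.real(np.fft.ifft2(uh))[:ny, :nx]
    v = np.real(np.fft.ifft2(vh))[:ny, :nx]
    return DisplacementField(
        grid_x=traction.grid_x,
        grid_y=traction.grid_y,
        u=u,
        v=v,
        pixel_size=substrate.pixel_size,
    )


def _render_spots(shape, positions_px, amplitudes, sigma_px):
    """Accumulate Gaussian PSF spots at sub-pixel positions."""
    ny, nx = shape
    img = np.zeros((ny, nx))
    r = max(2, int(np.ceil(4 * sigma_px)))
    for (px, py), a in zip(positions_px, amplitudes):
        ix, iy = int(np.round(px)), int(np.round(py))
        x0, x1 = max(0, ix - r), min(nx, ix + r + 1)
        y0, y1 = max(0, iy - r), min(ny, iy + r + 1)
        if x0 >= x1 or y0 >= y1:
            continue
        gx = np.exp(-((np.arange(x0, x1) - px) ** 2) / (2 * sigma_px ** 2))
        gy = np.exp(-((np.arange(y0, y1) - py) ** 2) / (2 * sigma_px ** 2))
        img[y0:y1, x0:x1] += a * np.outer(gy, gx)
    return img


def render_bead_images(
    scene: SceneSpec,
    displacement: DisplacementField | None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Render the (reference, deformed) fiducial-bead image pair.

    Beads are placed uniformly at random (seeded), each rendered as a
    Gaussian PSF spot of slightly varying brightness.  In the deformed
    frame each bead moves by the local substrate displacement
    (interpolated bilinearly from the displacement grid) plus the
    per-frame stage drift; Gaussian photon noise is added independently
    to both frames.  Returns ``(reference, deformed, bead_positions_px)``.
    """
    rng = np.random.default_rng(scene.seed)
    ny, nx = scene.image_shape
    p = scene.substrate.pixel_size
    area = ny * nx * p * p
    n_beads = int(round(scene.bead_density * area))

    win_um2 = (32 * p) ** 2
    if scene.bead_density * win_um2 < 10:
        warnings.warn(
            "bead density yields fewer than 10 beads per 32-px PIV window; "
            "displacement estimates will be under-seeded",
            stacklevel=2,
        )

    pos = rng.uniform(low=(0, 0), high=(nx, ny), size=(n_beads, 2))
    amps = rng.uniform(0.7, 1.3, size=n_beads)
    sigma_px = scene.psf_sigma / p

    ref = _render_spots((ny, nx), pos, amps, sigma_px)

    if displacement is None:
        disp = np.zeros((n_beads, 2))
    else:
        interp_u = RegularGridInterpolator(
            (displacement.grid_y, displacement.grid_x),
            displacement.u,
            bounds_error=False,
            fill_value=None,
        )
        interp_v = RegularGridInterpolator(
            (displacement.grid_y, displacement.grid_x),
            displacement.v,
            bounds_error=False,
            fill_value=None,
        )
        pts = pos[:, ::-1]  # (y, x) ordering for the interpolator
        disp = np.column_stack([interp_u(pts), interp_v(pts)]) / p  # µm → px
    moved = pos + disp + np.asarray(scene.drift)

    deformed = _render_spots((ny, nx), moved, amps, sigma_px)

    if scene.photon_noise_sd > 0:
        ref = ref + rng.normal(0.0, scene.photon_noise_sd, ref.shape)
        deformed = deformed + rng.normal(0.0, scene.photon_noise_sd, deformed.shape)
    return ref, deformed, pos


def render_cell_image(
    scene: SceneSpec,
    margin: float = 12.0,
    noise_sd: float = 0.02,
) -> np.ndarray:
    """Render the cell-channel image: a smooth ellipse covering the foci.

    The synthetic cell is the smallest axis-aligned ellipse enclosing
    every planted focus with ``margin`` µm to spare, softened by a
    Gaussian edge and overlaid with seeded Gaussian noise — enough
    structure for threshold-based segmentation, nothing more.
    """
    rng = np.random.default_rng(scene.seed + 1)
    ny, nx = scene.image_shape
    p = scene.substrate.pixel_size
    col, row = np.meshgrid(np.arange(nx), np.arange(ny))
    x = (col + 0.5) * p
    y = (row + 0.5) * p
    if scene.foci:
        cxs = np.array([f.center[0] for f in scene.foci])
        cys = np.array([f.center[1] for f in scene.foci])
        cx, cy = cxs.mean(), cys.mean()
        ax = max(np.abs(cxs - cx).max(), 1.0) + margin
        ay = max(np.abs(cys - cy).max(), 1.0) + margin
    else:
        cx, cy = 0.5 * nx * p, 0.5 * ny * p
        ax = ay = margin
    inside = ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 <= 1.0
    from scipy.ndimage import gaussian_filter

    img = gaussian_filter(inside.astype(float), 2.0 / p * 0.5)
    return img + rng.normal(0.0, noise_sd, img.shape)


def simulate_indentation_curve(
    youngs_modulus: float,
    tip_radius: float,
    poisson_ratio: float = 0.5,
    max_depth: float = 1.0,
    n_points: int = 200,
    noise_sd: float = 0.0,
    seed: int = 0,
    pre_contact_fraction: float = 0.3,
):
    """Hertz-law force–indentation curve for a spherical tip.

    F(δ) = (4/3) · E/(1−ν²) · √R · δ^{3/2} for δ > 0, zero before the
    contact point, plus additive Gaussian force noise.  ``tip_radius``
    and ``max_depth`` in µm, modulus in Pa, force in N.  The returned
    curve includes a pre-contact segment of ``pre_contact_fraction`` of
    the depth range before the (true, zero) contact point.
    """
    from .afm import IndentationCurve  # local import to avoid a cycle

    if youngs_modulus <= 0 or tip_radius <= 0 or max_depth <= 0 or n_points < 4:
        raise ValueError("modulus, tip radius, depth and n_points must be positive")
    rng = np.random.default_rng(seed)
    z = np.linspace(-pre_contact_fraction * max_depth, max_depth, n_points)
    delta_m = np.clip(z, 0.0, None) * 1e-6
    r_m = tip_radius * 1e-6
    force = (4.0 / 3.0) * youngs_modulus / (1.0 - poisson_ratio ** 2) * np.sqrt(r_m) * delta_m ** 1.5
    if noise_sd > 0:
        force = force + rng.normal(0.0, noise_sd, force.shape)
    return IndentationCurve(depth=z, force=force, tip_radius=tip_radius, contact_point=0.0)


def render_fiber_image(
    angle: float,
    period: float = 8.0,
    shape: tuple[int, int] = (256, 256),
    noise_sd: float = 0.05,
    seed: int = 0,
    contrast: float = 1.0,
) -> np.ndarray:
    """Striped texture oriented at ``angle`` (degrees, stripe direction
    counterclockwise from the image x-axis with y pointing up, mod 180).
    """
    if not 0 <= angle < 180:
        raise ValueError("angle must lie in [0, 180)")
    ny, nx = shape
    rng = np.random.default_rng(seed)
    col, row = np.meshgrid(np.arange(nx), np.arange(ny))
    x = col.astype(float)
    y = (ny - 1 - row).astype(float)  # y up
    th = np.deg2rad(angle)
    phase = -x * np.sin(th) + y * np.cos(th)  # coordinate across the stripes
    img = 0.5 + 0.5 * contrast * np.cos(2 * np.pi * phase / period)
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img


@dataclass(frozen=True)
class CohortSpec:
    """Planted-subpopulation cohort of per-cell force profiles.

    Three groups drawn feature-wise from Gaussians with the given means
    and standard deviations, plus iid standard-normal noise features.
    """

    n_per_group: tuple[int, int, int]
    group_means: np.ndarray   # (3, p) signal-feature means
    group_sds: np.ndarray     # (3, p) matching sds
    n_noise_features: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        means = np.atleast_2d(np.asarray(self.group_means, dtype=float))
        sds = np.atleast_2d(np.asarray(self.group_sds, dtype=float))
        object.__setattr__(self, "group_means", means)
        object.__setattr__(self, "group_sds", sds)
        if means.shape != sds.shape or means.shape[0] != 3:
            raise ValueError("group_means and group_sds must both be (3, p)")
        if any(n < 2 for n in self.n_per_group):
            raise ValueError("each group needs at least 2 cells")
        if np.any(sds < 0):
            raise ValueError("group_sds must be non-negative")


def default_cohort(
    seed: int = 0,
    n_per_group: tuple[int, int, int] = (20, 20, 20),
    separation_sds: float = 4.0,
    n_signal_features: int = 12,
    n_noise_features: int = 4,
) -> CohortSpec:
    """Three contractility groups (low / intermediate / high force).

    Per signal feature, neighbouring group means sit ``separation_sds``
    unit standard deviations apart, the way mean and peak traction
    separate weak, intermediate and strongly contractile cells in a
    ~60-cell cohort.  The intermediate group rises on only half the
    features, so the three groups span a two-dimensional signal
    subspace rather than a single line.
    """
    p = n_signal_features
    low = np.zeros(p)
    high = np.full(p, separation_sds)
    mid = np.where(np.arange(p) < p // 2, separation_sds, 0.0)
    means = np.stack([low, mid, high])
    sds = np.ones_like(means)
    return CohortSpec(
        n_per_group=n_per_group,
        group_means=means,
        group_sds=sds,
        n_noise_features=n_noise_features,
        seed=seed,
    )


def simulate_force_profile_cohort(spec: CohortSpec):
    """Draw the cell-by-feature table and its ground-truth labels.

    Returns ``(profiles, labels)`` where ``profiles`` is a pandas
    DataFrame (cells × features, named ``f00..`` and ``noise00..``) and
    ``labels`` the planted group index (0, 1, 2) per cell.
    """
    import pandas as pd

    rng = np.random.default_rng(spec.seed)
    blocks = []
    labels = []
    p = spec.group_means.shape[1]
    for g, n in enumerate(spec.n_per_group):
        x = rng.normal(spec.group_means[g], spec.group_sds[g], size=(n, p))
        blocks.append(x)
        labels.extend([g] * n)
    signal = np.vstack(blocks)
    cols = [f"f{i:02d}" for i in range(p)]
    if spec.n_noise_features > 0:
        noise = rng.normal(0.0, 1.0, size=(signal.shape[0], spec.n_noise_features))
        signal = np.hstack([signal, noise])
        cols += [f"noise{i:02d}" for i in range(spec.n_noise_features)]
    df = pd.DataFrame(signal, columns=cols)
    df.index = [f"cell{i:03d}" for i in range(len(df))]
    return df, np.asarray(labels)
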