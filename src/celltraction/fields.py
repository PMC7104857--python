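"""Grid-based vector field containers shared across the pipeline.

Displacement fields live on a regular grid of interrogation-window centers
(PIV nodes); traction fields are reconstructed on the same grid.  Grid node
coordinates are kept in pixels of the source image, while the physical
vector components are kept in micrometres (displacements) or pascals
(tractions).  ``pixel_size`` (µm/px) ties the two together.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class SubstrateSpec:
    """Elastic properties of the gel substrate and the imaging scale.

    Parameters
    ----------
    youngs_modulus : float
        Young's modulus of the gel in Pa (default 4500 Pa: soft
        polyacrylamide in the stiffness range of fibrotic nodules).
    poisson_ratio : float
        Poisson ratio, in [0, 0.5]; 0.5 models an incompressible gel.
    pixel_size : float
        Image scale in µm per pixel.
    """

    youngs_modulus: float = 4500.0
    poisson_ratio: float = 0.5
    pixel_size: float = 0.153

    def __post_init__(self) -> None:
        if not self.youngs_modulus > 0:
            raise ValueError("youngs_modulus must be positive")
        if not 0.0 <= self.poisson_ratio <= 0.5:
            raise ValueError("poisson_ratio must lie in [0, 0.5]")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")


def _check_grid(grid_x: np.ndarray, grid_y: np.ndarray) -> None:
    for g, name in ((grid_x, "grid_x"), (grid_y, "grid_y")):
        if g.ndim != 1 or g.size < 2:
            raise ValueError(f"{name} must be 1-D with at least 2 nodes")
        steps = np.diff(g)
        if not np.allclose(steps, steps[0]):
            raise ValueError(f"{name} must be regularly spaced")


@dataclass
class DisplacementField:
    """Regular grid of (u, v) displacement vectors.

    ``u[i, j]`` is the x-displacement in µm at pixel position
    ``(grid_x[j], grid_y[i])``.  ``valid`` flags nodes whose correlation
    peak was usable; ``replaced`` flags nodes overwritten by the
    normalized-median validator.
    """

    grid_x: np.ndarray  # px, node centers, shape (nx,)
    grid_y: np.ndarray  # px, shape (ny,)
    u: np.ndarray       # µm, shape (ny, nx)
    v: np.ndarray       # µm
    pixel_size: float   # µm / px
    valid: np.ndarray = None
    replaced: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        _check_grid(self.grid_x, self.grid_y)
        shape = (self.grid_y.size, self.grid_x.size)
        if self.u.shape != shape or self.v.shape != shape:
            raise ValueError("u/v shape must be (len(grid_y), len(grid_x))")
        if self.valid is None:
            self.valid = np.ones(shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != shape:
            raise ValueError("valid flags must match grid shape")
        if self.replaced is None:
            self.replaced = np.zeros(shape, dtype=bool)

    @property
    def spacing_px(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0])

    @property
    def spacing_um(self) -> float:
        return self.spacing_px * self.pixel_size

    @property
    def u_px(self) -> np.ndarray:
        return self.u / self.pixel_size

    @property
    def v_px(self) -> np.ndarray:
        return self.v / self.pixel_size

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "x_px": xx.ravel(),
                "y_px": yy.ravel(),
                "u_um": self.u.ravel(),
                "v_um": self.v.ravel(),
                "valid": self.valid.ravel(),
            }
        )


@dataclass
class TractionField:
    """Traction stress field on a regular grid, components in Pa."""

    grid_x: np.ndarray
    grid_y: np.ndarray
    tx: np.ndarray
    ty: np.ndarray
    substrate: SubstrateSpec
    lambda_reg: float | None = None

    def __post_init__(self) -> None:
        self.grid_x = np.asarray(self.grid_x, dtype=float)
        self.grid_y = np.asarray(self.grid_y, dtype=float)
        self.tx = np.asarray(self.tx, dtype=float)
        self.ty = np.asarray(self.ty, dtype=float)
        _check_grid(self.grid_x, self.grid_y)
        shape = (self.grid_y.size, self.grid_x.size)
        if self.tx.shape != shape or self.ty.shape != shape:
            raise ValueError("tx/ty shape must be (len(grid_y), len(grid_x))")

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.tx, self.ty)

    @property
    def spacing_px(self) -> float:
        return float(self.grid_x[1] - self.grid_x[0])

    @property
    def spacing_um(self) -> float:
        return self.spacing_px * self.substrate.pixel_size

    @property
    def node_area_um2(self) -> float:
        return self.spacing_um ** 2

    def net_force(self) -> tuple[float, float]:
        """Net force (nN-scale check); zero for a balanced field."""
        a = self.node_area_um2
        return float(self.tx.sum() * a), float(self.ty.sum() * a)

    def to_dataframe(self) -> pd.DataFrame:
        xx, yy = np.meshgrid(self.grid_x, self.grid_y)
        return pd.DataFrame(
            {
                "x_px": xx.ravel(),
                "y_px": yy.ravel(),
                "tx_pa": self.tx.ravel(),
                "ty_pa": self.ty.ravel(),
                "magnitude_pa": self.magnitude.ravel(),
            }
        )
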