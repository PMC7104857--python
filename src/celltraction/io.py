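"""File I/O: TIFF image pairs, CSV field tables, YAML configs, manifests."""

from __future__ import annotations

import hashlib
import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .fields import DisplacementField, SubstrateSpec, TractionField


def derive_seed(base_seed: int, stage: str) -> int:
    """Stable per-stage seed fan-out from a single run seed (< 2^31)."""
    return zlib.crc32(f"{stage}:{base_seed}".encode()) & 0x7FFFFFFF


def write_image_pair(path_ref: Path, path_def: Path, reference, deformed) -> None:
    """Write a bead image pair as 16-bit TIFFs on a shared intensity scale."""
    lo = min(reference.min(), deformed.min())
    hi = max(reference.max(), deformed.max())
    scale = 65535.0 / max(hi - lo, 1e-12)
    for path, img in ((path_ref, reference), (path_def, deformed)):
        tifffile.imwrite(path, ((img - lo) * scale).astype(np.uint16))


def read_image(path: Path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def write_displacement_csv(path: Path, field: DisplacementField) -> None:
    df = field.to_dataframe()
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um={field.pixel_size}\n")
        fh.write(f"# spacing_px={field.spacing_px}\n")
        df.to_csv(fh, index=False)


def read_displacement_csv(path: Path) -> DisplacementField:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].strip().split("=")
            meta[key.strip()] = float(val)
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    gx = np.unique(df["x_px"])
    gy = np.unique(df["y_px"])
    shape = (gy.size, gx.size)
    return DisplacementField(
        grid_x=gx,
        grid_y=gy,
        u=df["u_um"].to_numpy().reshape(shape),
        v=df["v_um"].to_numpy().reshape(shape),
        pixel_size=meta["pixel_size_um"],
        valid=df["valid"].to_numpy(bool).reshape(shape),
    )


def write_traction_csv(path: Path, field: TractionField) -> None:
    with open(path, "w") as fh:
        fh.write(f"# pixel_size_um={field.substrate.pixel_size}\n")
        fh.write(f"# youngs_modulus_pa={field.substrate.youngs_modulus}\n")
        fh.write(f"# poisson_ratio={field.substrate.poisson_ratio}\n")
        fh.write(f"# lambda_reg={field.lambda_reg}\n")
        field.to_dataframe().to_csv(fh, index=False)


def read_traction_csv(path: Path) -> TractionField:
    meta = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, val = line[1:].strip().split("=")
            meta[key.strip()] = val
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    gx = np.unique(df["x_px"])
    gy = np.unique(df["y_px"])
    shape = (gy.size, gx.size)
    lam = meta.get("lambda_reg", "None")
    return TractionField(
        grid_x=gx,
        grid_y=gy,
        tx=df["tx_pa"].to_numpy().reshape(shape),
        ty=df["ty_pa"].to_numpy().reshape(shape),
        substrate=SubstrateSpec(
            youngs_modulus=float(meta["youngs_modulus_pa"]),
            poisson_ratio=float(meta["poisson_ratio"]),
            pixel_size=float(meta["pixel_size_um"]),
        ),
        lambda_reg=None if lam == "None" else float(lam),
    )


def save_traction_heatmap(path: Path, field: TractionField) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    extent_um = [
        field.grid_x[0] * field.substrate.pixel_size,
        field.grid_x[-1] * field.substrate.pixel_size,
        field.grid_y[-1] * field.substrate.pixel_size,
        field.grid_y[0] * field.substrate.pixel_size,
    ]
    im = ax.imshow(field.magnitude, extent=extent_um, cmap="inferno")
    fig.colorbar(im, ax=ax, label="|T| (Pa)")
    ax.set_xlabel("x (µm)")
    ax.set_ylabel("y (µm)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def load_yaml(path: Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_yaml(path: Path, data: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class Manifest:
    """Append-only record of stage parameters and output checksums."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.entries = []
        if self.path.exists():
            self.entries = json.loads(self.path.read_text())

    def record(self, stage: str, params: dict, outputs: list[Path]) -> None:
        self.entries.append(
            {
                "stage": stage,
                "params": params,
                "outputs": {str(p): sha256(p) for p in outputs},
                "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
            }
        )
        self.path.write_text(json.dumps(self.entries, indent=2))
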