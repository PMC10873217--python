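"""Manual-style VOI noise measurement.

Reproduces the reference measurement: mean and pixel-wise sample SD of the
SUV values inside a cubic VOI of fixed physical edge length (default 20 mm,
i.e. a 2×2×2 cm cube) at an explicitly supplied center. Inclusion rule:
a voxel belongs to the VOI iff its center falls inside the closed cube.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateVoiError, SchemaError, VoiOutOfBoundsError
from .io import SuvVolume

DEFAULT_EDGE_MM = 20.0

_EPS = 1e-9


@dataclass
class VOIMeasurement:
    center_mm: tuple[float, float, float]
    edge_mm: float
    n_voxels: int
    mean_suv: float
    sd_suv: float
    organ_label: str = ""


def cubic_voi_noise(
    volume: SuvVolume,
    center_mm: tuple[float, float, float],
    edge_mm: float = DEFAULT_EDGE_MM,
    organ_label: str = "",
) -> VOIMeasurement:
    """Mean and sample SD of SUV inside a cubic VOI.

    The cube ``[center − edge/2, center + edge/2]`` per axis must fit inside
    the physical extent of the volume (voxel edges included).
    """
    if edge_mm <= 0:
        raise ValueError("edge_mm must be positive")
    half = edge_mm / 2.0
    slices: list[slice] = []
    for axis in range(3):  # 0=x, 1=y, 2=z
        d = volume.spacing[axis]
        o = volume.origin[axis]
        n = volume.voxels.shape[2 - axis]
        lo_mm = center_mm[axis] - half
        hi_mm = center_mm[axis] + half
        if lo_mm < o - 0.5 * d - _EPS or hi_mm > o + (n - 0.5) * d + _EPS:
            raise VoiOutOfBoundsError(
                f"VOI out of bounds on axis {'xyz'[axis]}: "
                f"[{lo_mm:.2f}, {hi_mm:.2f}] mm outside volume extent"
            )
        lo = int(np.ceil((lo_mm - o) / d - _EPS))
        hi = int(np.floor((hi_mm - o) / d + _EPS))
        lo = max(lo, 0)
        hi = min(hi, n - 1)
        slices.append(slice(lo, hi + 1))
    sub = volume.voxels[slices[2], slices[1], slices[0]]
    if sub.size < 2:
        raise DegenerateVoiError(f"degenerate VOI: only {sub.size} voxel(s) inside the cube")
    return VOIMeasurement(
        center_mm=tuple(float(c) for c in center_mm),
        edge_mm=float(edge_mm),
        n_voxels=int(sub.size),
        mean_suv=float(np.mean(sub)),
        sd_suv=float(np.std(sub, ddof=1)),
        organ_label=organ_label,
    )


BATCH_COLUMNS = ["study_id", "organ", "x_mm", "y_mm", "z_mm"]


def batch_voi(volumes: dict[str, SuvVolume], table: pd.DataFrame) -> pd.DataFrame:
    """Run VOI measurements for a batch table.

    ``table`` needs columns study_id, organ, x_mm, y_mm, z_mm (and optionally
    edge_mm); ``volumes`` maps study_id → volume. Returns the table augmented
    with n_voxels, mean_suv, sd_suv.
    """
    missing = [c for c in BATCH_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"schema error: missing columns {missing}")
    rows = []
    for _, row in table.iterrows():
        vol = volumes[str(row["study_id"])]
        edge = float(row["edge_mm"]) if "edge_mm" in table.columns and pd.notna(row.get("edge_mm")) else DEFAULT_EDGE_MM
        m = cubic_voi_noise(
            vol,
            (float(row["x_mm"]), float(row["y_mm"]), float(row["z_mm"])),
            edge_mm=edge,
            organ_label=str(row["organ"]),
        )
        rows.append(
            {
                **row.to_dict(),
                "edge_mm": m.edge_mm,
                "n_voxels": m.n_voxels,
                "mean_suv": m.mean_suv,
                "sd_suv": m.sd_suv,
            }
        )
    return pd.DataFrame(rows)
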