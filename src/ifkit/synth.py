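"""Synthetic single-molecule displacement datasets.

Generates localization-pair tables with the statistical structure the
diffusivity-mapping analysis assumes: a two-population spatial field
(slow filament-bound molecules on a rasterized filament mask, fast
dispersed molecules elsewhere), short paired-frame displacements drawn
from the local diffusion coefficient, Gaussian localization error in
both frames, and truncation at a capture radius.

Per axis the displacement variance is ``2*D*dt + 2*sigma_loc**2``: the
Brownian term plus localization error from each of the two paired
localizations.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError

CSV_COLUMNS = ["x0_um", "y0_um", "dx_um", "dy_um", "label"]


@dataclass(frozen=True)
class AcquisitionSettings:
    """Timing, precision, and geometry of a paired-frame acquisition."""

    dt: float = 1e-3            # pair interval, s
    sigma_loc: float = 0.02     # per-axis localization precision, um
    capture_radius: float = 0.8  # max recordable displacement magnitude, um
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InputError(f"dt must be > 0, got {self.dt}")
        if self.sigma_loc < 0:
            raise InputError(f"sigma_loc must be >= 0, got {self.sigma_loc}")
        if self.capture_radius <= 0:
            raise InputError(f"capture_radius must be > 0, got {self.capture_radius}")


@dataclass
class DiffusivityField:
    """Ground-truth local diffusion coefficients on a bin lattice.

    The grid is row-major, 0-based, origin at the top-left corner with y
    increasing downward; each cell is ``bin_size`` um on a side.
    """

    D: np.ndarray               # um^2/s, shape (n_rows, n_cols)
    filament_mask: np.ndarray   # bool, same shape
    bound_fraction: float
    bin_size: float = 0.4       # um per grid cell
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        self.filament_mask = np.asarray(self.filament_mask, dtype=bool)
        if self.D.ndim != 2 or self.D.shape != self.filament_mask.shape:
            raise InputError("D grid and filament mask must be congruent 2-D arrays")
        if np.any(self.D < 0):
            raise InputError("diffusion coefficients must be >= 0")
        if not 0.0 <= self.bound_fraction <= 1.0:
            raise InputError(f"bound_fraction out of [0, 1]: {self.bound_fraction}")
        if self.bin_size <= 0:
            raise InputError("bin_size must be > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.D.shape

    @property
    def width_um(self) -> float:
        return self.shape[1] * self.bin_size

    @property
    def height_um(self) -> float:
        return self.shape[0] * self.bin_size

    def local_D(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Field value at positions (um); positions must lie inside the field."""
        col = np.clip(((x - self.origin[0]) / self.bin_size).astype(int), 0, self.shape[1] - 1)
        row = np.clip(((y - self.origin[1]) / self.bin_size).astype(int), 0, self.shape[0] - 1)
        return self.D[row, col]


def make_filament_field(
    grid_shape: tuple[int, int],
    n_filaments: int,
    D_bound: float = 1.5,
    D_free: float = 7.0,
    bound_fraction: float = 0.5,
    seed: int = 0,
    bin_size: float = 0.4,
) -> DiffusivityField:
    """Rasterize random-walk filament polylines onto a grid.

    Cells on a filament get ``D_bound``; all other cells get ``D_free``.
    """
    n_rows, n_cols = grid_shape
    if n_rows <= 0 or n_cols <= 0:
        raise InputError(f"grid dimensions must be positive, got {grid_shape}")
    if n_filaments < 0:
        raise InputError("n_filaments must be >= 0")
    if D_bound < 0 or D_free < 0:
        raise InputError("diffusion coefficients must be >= 0")
    if not 0.0 <= bound_fraction <= 1.0:
        raise InputError(f"bound_fraction out of [0, 1]: {bound_fraction}")

    rng = np.random.default_rng(seed)
    mask = np.zeros(grid_shape, dtype=bool)
    n_steps = 2 * (n_rows + n_cols)
    for _ in range(n_filaments):
        r = rng.integers(0, n_rows)
        c = rng.integers(0, n_cols)
        angle = rng.uniform(0, 2 * np.pi)
        rf, cf = float(r), float(c)
        for _ in range(n_steps):
            mask[int(rf), int(cf)] = True
            angle += rng.normal(0.0, 0.3)  # persistent direction, gentle turns
            rf += np.sin(angle)
            cf += np.cos(angle)
            if not (0 <= rf < n_rows and 0 <= cf < n_cols):
                break

    D = np.where(mask, D_bound, D_free).astype(float)
    return DiffusivityField(D=D, filament_mask=mask,
                            bound_fraction=bound_fraction, bin_size=bin_size)


def simulate_displacements(
    field: DiffusivityField,
    settings: AcquisitionSettings,
    n_molecules: int,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, int]:
    """Draw one displacement per molecule from the local diffusivity field.

    Returns the recorded table and the number of molecules discarded for
    exceeding the capture radius (rows + discards == n_molecules).
    """
    if n_molecules <= 0:
        raise InputError("n_molecules must be > 0")
    if rng is None:
        rng = np.random.default_rng(settings.seed)

    n_bound = int(round(field.bound_fraction * n_molecules))
    n_free = n_molecules - n_bound
    mask_rows, mask_cols = np.nonzero(field.filament_mask)
    if n_bound > 0 and mask_rows.size == 0:
        raise ConfigurationError("bound_fraction > 0 but the filament mask is empty")

    xs, ys, labels = [], [], []
    if n_bound > 0:
        pick = rng.integers(0, mask_rows.size, size=n_bound)
        x = field.origin[0] + (mask_cols[pick] + rng.random(n_bound)) * field.bin_size
        y = field.origin[1] + (mask_rows[pick] + rng.random(n_bound)) * field.bin_size
        xs.append(x); ys.append(y); labels.append(np.full(n_bound, "bound"))
    if n_free > 0:
        x = field.origin[0] + rng.random(n_free) * field.width_um
        y = field.origin[1] + rng.random(n_free) * field.height_um
        xs.append(x); ys.append(y); labels.append(np.full(n_free, "free"))

    x0 = np.concatenate(xs)
    y0 = np.concatenate(ys)
    label = np.concatenate(labels)
    D_local = field.local_D(x0, y0)

    sigma = np.sqrt(2.0 * D_local * settings.dt + 2.0 * settings.sigma_loc**2)
    dx = rng.normal(0.0, 1.0, n_molecules) * sigma
    dy = rng.normal(0.0, 1.0, n_molecules) * sigma

    keep = np.hypot(dx, dy) <= settings.capture_radius
    n_discarded = int(n_molecules - keep.sum())
    table = pd.DataFrame(
        {
            "x0_um": x0[keep],
            "y0_um": y0[keep],
            "dx_um": dx[keep],
            "dy_um": dy[keep],
            "label": label[keep],
        }
    )
    return table, n_discarded


def simulate_timecourse(
    field_start: DiffusivityField,
    field_end: DiffusivityField,
    n_steps: int,
    settings: AcquisitionSettings,
    n_molecules_per_step: int,
) -> list[tuple[pd.DataFrame, int]]:
    """Simulate a sequence of conditions interpolating between two fields.

    Step k uses bound_fraction (and the D grid) linearly interpolated
    between the endpoints; per-step random streams are spawned
    deterministically from the master seed.
    """
    if field_start.shape != field_end.shape:
        raise InputError("endpoint fields must have congruent grids")
    if n_steps < 2:
        raise InputError("n_steps must be >= 2")

    streams = np.random.SeedSequence(settings.seed).spawn(n_steps)
    out = []
    for k in range(n_steps):
        t = k / (n_steps - 1)
        field_k = replace(
            field_start,
            D=(1 - t) * field_start.D + t * field_end.D,
            bound_fraction=(1 - t) * field_start.bound_fraction + t * field_end.bound_fraction,
        )
        rng = np.random.default_rng(streams[k])
        out.append(simulate_displacements(field_k, settings, n_molecules_per_step, rng=rng))
    return out


# ---------------------------------------------------------------------------
# I/O

def write_displacements(
    table: pd.DataFrame,
    path: Union[str, Path],
    settings: AcquisitionSettings | None = None,
    n_discarded: int | None = None,
) -> None:
    """Write the displacement table as CSV plus a JSON metadata sidecar."""
    path = Path(path)
    table.to_csv(path, index=False, columns=CSV_COLUMNS)
    if settings is not None:
        meta = {"settings": asdict(settings), "n_rows": int(len(table))}
        if n_discarded is not None:
            meta["n_discarded"] = int(n_discarded)
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def write_field(field: DiffusivityField, path: Union[str, Path]) -> None:
    """Ground-truth D grid as float32 TIFF plus a JSON lattice descriptor."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, field.D.astype(np.float32))
    descriptor = {
        "origin_x_um": field.origin[0],
        "origin_y_um": field.origin[1],
        "bin_size_um": field.bin_size,
        "n_rows": field.shape[0],
        "n_cols": field.shape[1],
        "order": "row-major",
        "indexing": "0-based",
        "y_axis": "increasing downward",
    }
    path.with_suffix(".json").write_text(json.dumps(descriptor, indent=2))
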