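"""Spatial binning and maximum-likelihood fitting of displacement maps.

Per spatial bin, displacement magnitudes r are fit to a 2-D isotropic
Brownian step distribution

    P(r) = (r / s**2) * exp(-r**2 / (2 s**2)),   s**2 = 2*D*dt + 2*sigma_loc**2

optionally mixed at weight phi with a uniform-in-area background
``P_bg(r) = 2 r / R_cap**2``.  With the background disabled the MLE has
the closed form ``s_hat**2 = mean(r**2) / 2`` (so for sigma_loc = 0,
``D_hat = sum(r**2) / (4 N dt)``); with the background enabled the
(D, phi) likelihood is maximized numerically from the moment start.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import InputError
from .synth import AcquisitionSettings

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BinLattice:
    """Half-open [lo, hi) spatial bins, 0-based row-major, y downward."""

    origin: tuple[float, float]  # (x, y) of the top-left corner, um
    bin_size: float              # um
    n_rows: int
    n_cols: int

    def __post_init__(self) -> None:
        if self.bin_size <= 0:
            raise InputError("bin_size must be > 0")
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise InputError("lattice dimensions must be positive")

    def bin_index(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(row, col, in_field) for each origin position."""
        col = np.floor((np.asarray(x) - self.origin[0]) / self.bin_size).astype(int)
        row = np.floor((np.asarray(y) - self.origin[1]) / self.bin_size).astype(int)
        ok = (row >= 0) & (row < self.n_rows) & (col >= 0) & (col < self.n_cols)
        return row, col, ok


@dataclass(frozen=True)
class FitOptions:
    """Choices for the per-bin likelihood fit."""

    fit_background: bool = False
    n_min: int = 10          # bins with fewer displacements are masked
    D_max: float = 100.0     # upper bound for the optimizer, um^2/s
    tol: float = 1e-10       # optimizer tolerance on D


@dataclass
class FitResult:
    D_hat: float
    background_fraction: float
    n_used: int
    log_likelihood: float
    converged: bool

    def __post_init__(self) -> None:
        if self.n_used < 0:
            raise InputError("n_used must be >= 0")


@dataclass
class DiffusivityMap:
    """Per-bin fit results; masked bins carry no D value."""

    lattice: BinLattice
    D: np.ndarray            # um^2/s, NaN where masked
    phi: np.ndarray
    counts: np.ndarray
    mask: np.ndarray         # True where the bin is below n_min / unfit
    fits: dict[tuple[int, int], FitResult] = dc_field(default_factory=dict)

    @property
    def median_D(self) -> float:
        vals = self.D[~self.mask]
        return float(np.median(vals)) if vals.size else float("nan")


def bin_displacements(
    table: pd.DataFrame, lattice: BinLattice
) -> tuple[dict[tuple[int, int], np.ndarray], int]:
    """Group displacement magnitudes by the bin of their origin.

    Returns {(row, col): magnitudes} for nonempty bins plus the count of
    records whose origin falls outside the lattice.
    """
    if len(table) == 0:
        logger.warning("empty displacement table: empty map")
        return {}, 0
    row, col, ok = lattice.bin_index(table["x0_um"].to_numpy(), table["y0_um"].to_numpy())
    r = np.hypot(table["dx_um"].to_numpy(), table["dy_um"].to_numpy())
    out_of_field = int((~ok).sum())
    flat = row[ok] * lattice.n_cols + col[ok]
    order = np.argsort(flat, kind="stable")
    flat_sorted = flat[order]
    r_sorted = r[ok][order]
    bins: dict[tuple[int, int], np.ndarray] = {}
    if flat_sorted.size:
        starts = np.flatnonzero(np.r_[True, np.diff(flat_sorted) != 0])
        stops = np.r_[starts[1:], flat_sorted.size]
        for a, b in zip(starts, stops):
            key = (int(flat_sorted[a] // lattice.n_cols), int(flat_sorted[a] % lattice.n_cols))
            bins[key] = r_sorted[a:b]
    return bins, out_of_field


def _neg_log_likelihood(
    r: np.ndarray, D: float, phi: float, dt: float, sigma_loc: float, r_cap: float
) -> float:
    s2 = 2.0 * D * dt + 2.0 * sigma_loc**2
    if s2 <= 0:
        return np.inf
    fg = (r / s2) * np.exp(-(r**2) / (2.0 * s2))
    bg = 2.0 * r / r_cap**2
    pdf = (1.0 - phi) * fg + phi * bg
    if np.any(pdf <= 0):
        return np.inf
    return -float(np.sum(np.log(pdf)))


def fit_diffusivity_numeric(
    displacement_magnitudes: np.ndarray,
    settings: AcquisitionSettings,
    options: FitOptions = FitOptions(),
    fix_background: float | None = None,
) -> FitResult:
    """Numerically maximize the likelihood over D (and phi unless fixed).

    Independent of the closed-form path in :func:`fit_diffusivity`; with
    ``fix_background=0.0`` the two must agree to optimizer tolerance.
    """
    r = np.asarray(displacement_magnitudes, dtype=float)
    n = r.size
    dt, sig = settings.dt, settings.sigma_loc
    s2_hat = float(np.mean(r**2)) / 2.0
    D_moment = max(0.0, (s2_hat - 2.0 * sig**2) / (2.0 * dt))

    if fix_background is not None:
        phi = float(fix_background)
        from scipy.optimize import brentq

        r_cap = settings.capture_radius

        def score(D: float) -> float:
            # d/dD of the negative log-likelihood at fixed phi
            s2 = 2.0 * D * dt + 2.0 * sig**2
            if phi == 0.0:
                # log f = log r - log s2 - r^2/(2 s2): stable at tiny s2
                return -2.0 * dt * float(np.sum(r**2 / (2.0 * s2**2) - 1.0 / s2))
            fg = (r / s2) * np.exp(-(r**2) / (2.0 * s2))
            pdf = (1.0 - phi) * fg + phi * 2.0 * r / r_cap**2
            dfg_dD = fg * (r**2 / (2.0 * s2**2) - 1.0 / s2) * (2.0 * dt)
            return -float(np.sum((1.0 - phi) * dfg_dD / pdf))

        lo = 0.0 if sig > 0 else 1e-12
        hi = max(4.0 * D_moment + 1.0, 1.0)
        while score(hi) < 0 and hi < options.D_max:
            hi = min(2.0 * hi, options.D_max)
        if score(lo) >= 0:  # likelihood decreasing from the boundary
            D_hat = 0.0
        else:
            D_hat = float(brentq(score, lo, hi, xtol=1e-15, rtol=8.9e-16))
        ll = -_neg_log_likelihood(r, D_hat, phi, dt, sig, r_cap)
        return FitResult(D_hat, phi, n, ll, converged=True)

    best = None
    for D0, phi0 in ((D_moment, 0.01), (D_moment, 0.3), (max(D_moment, 1.0) * 2, 0.05)):
        res = minimize(
            lambda p: _neg_log_likelihood(r, p[0], p[1], dt, sig, settings.capture_radius),
            x0=[min(max(D0, 1e-6), options.D_max), phi0],
            method="L-BFGS-B",
            bounds=[(0.0, options.D_max), (0.0, 1.0)],
            options={"ftol": options.tol, "gtol": 1e-12},
        )
        if best is None or res.fun < best.fun:
            best = res
    return FitResult(max(0.0, float(best.x[0])), float(best.x[1]), n,
                     -float(best.fun), bool(best.success))


def fit_diffusivity(
    displacement_magnitudes: np.ndarray,
    settings: AcquisitionSettings,
    options: FitOptions = FitOptions(),
) -> FitResult:
    """Maximum-likelihood D (and optionally background weight) for one bin."""
    r = np.asarray(displacement_magnitudes, dtype=float)
    if not np.all(np.isfinite(r)):
        raise InputError("non-finite displacement magnitudes")
    if np.any(r < 0):
        raise InputError("displacement magnitudes must be >= 0")
    n = r.size
    if n < options.n_min:
        return FitResult(float("nan"), float("nan"), n, float("nan"), converged=False)

    dt, sig = settings.dt, settings.sigma_loc
    # moment / closed-form estimate: s2_hat = mean(r^2) / 2
    s2_hat = float(np.mean(r**2)) / 2.0
    D_moment = max(0.0, (s2_hat - 2.0 * sig**2) / (2.0 * dt))

    if not options.fit_background:
        # closed-form MLE (phi = 0); D floored at 0
        ll = -_neg_log_likelihood(r, D_moment, 0.0, dt, sig, settings.capture_radius)
        return FitResult(D_moment, 0.0, n, ll, converged=True)

    return fit_diffusivity_numeric(r, settings, options)


def map_diffusivity(
    table: pd.DataFrame,
    lattice: BinLattice,
    settings: AcquisitionSettings,
    options: FitOptions = FitOptions(),
) -> DiffusivityMap:
    """Fit every bin of the lattice; bins under ``n_min`` are masked."""
    bins, _ = bin_displacements(table, lattice)
    shape = (lattice.n_rows, lattice.n_cols)
    D = np.full(shape, np.nan)
    phi = np.full(shape, np.nan)
    counts = np.zeros(shape, dtype=int)
    mask = np.ones(shape, dtype=bool)
    fits: dict[tuple[int, int], FitResult] = {}
    for key, r in bins.items():
        counts[key] = r.size
        fit = fit_diffusivity(r, settings, options)
        fits[key] = fit
        if fit.converged:
            D[key] = fit.D_hat
            phi[key] = fit.background_fraction
            mask[key] = False
    if mask.all():
        logger.warning("all bins below the minimum-count threshold: fully masked map")
    return DiffusivityMap(lattice, D, phi, counts, mask, fits)


def model_pdf(
    r: np.ndarray, fit: FitResult, settings: AcquisitionSettings
) -> np.ndarray:
    """Fitted displacement-magnitude PDF evaluated at r."""
    s2 = 2.0 * fit.D_hat * settings.dt + 2.0 * settings.sigma_loc**2
    fg = (r / s2) * np.exp(-(r**2) / (2.0 * s2)) if s2 > 0 else np.where(r == 0, np.inf, 0.0)
    bg = 2.0 * r / settings.capture_radius**2
    phi = fit.background_fraction if np.isfinite(fit.background_fraction) else 0.0
    return (1.0 - phi) * fg + phi * bg


def displacement_histogram(
    displacement_magnitudes: np.ndarray,
    fit: FitResult,
    settings: AcquisitionSettings,
    n_bins: int = 50,
    n_curve: int = 400,
) -> dict:
    """Density-normalized histogram plus the fitted curve on a uniform grid."""
    r = np.asarray(displacement_magnitudes, dtype=float)
    if r.size == 0:
        raise InputError("empty displacement set")
    if n_bins < 2:
        raise InputError("n_bins must be >= 2")
    hist, edges = np.histogram(r, bins=n_bins, range=(0.0, settings.capture_radius),
                               density=True)
    counts, _ = np.histogram(r, bins=edges)
    grid = np.linspace(0.0, settings.capture_radius, n_curve)
    return {
        "bin_edges": edges,
        "density": hist,
        "counts": counts,
        "curve_r": grid,
        "curve_pdf": model_pdf(grid, fit, settings),
    }


def save_histogram(result: dict, csv_path, png_path=None, title: str = "") -> None:
    centers = 0.5 * (result["bin_edges"][:-1] + result["bin_edges"][1:])
    pd.DataFrame({"r_um": centers, "density": result["density"],
                  "count": result["counts"]}).to_csv(csv_path, index=False)
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4, 3))
        ax.bar(centers, result["density"], width=np.diff(result["bin_edges"]),
               color="0.8", edgecolor="0.5")
        ax.plot(result["curve_r"], result["curve_pdf"], color="tab:blue")
        ax.set_xlabel("displacement (μm)")
        ax.set_ylabel("probability density")
        if title:
            ax.set_title(title)
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)


def save_map(dmap: DiffusivityMap, tiff_path, png_path=None,
             d_range: tuple[float, float] = (0.0, 10.0)) -> None:
    """D map as float32 TIFF + lattice JSON; optional color-coded PNG."""
    import json

    import tifffile

    from pathlib import Path

    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path, dmap.D.astype(np.float32))
    descriptor = {
        "origin_x_um": dmap.lattice.origin[0],
        "origin_y_um": dmap.lattice.origin[1],
        "bin_size_um": dmap.lattice.bin_size,
        "n_rows": dmap.lattice.n_rows,
        "n_cols": dmap.lattice.n_cols,
        "order": "row-major",
        "indexing": "0-based",
        "y_axis": "increasing downward",
    }
    tiff_path.with_suffix(".json").write_text(json.dumps(descriptor, indent=2))
    if png_path is not None:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(4.5, 4))
        im = ax.imshow(dmap.D, vmin=d_range[0], vmax=d_range[1], cmap="jet")
        fig.colorbar(im, ax=ax, label="D (μm²/s)")
        ax.set_xticks([]); ax.set_yticks([])
        fig.tight_layout()
        fig.savefig(png_path, dpi=150)
        plt.close(fig)


def fits_to_frame(dmap: DiffusivityMap) -> pd.DataFrame:
    rows = [
        {"row": k[0], "col": k[1], "D_um2_s": f.D_hat, "phi": f.background_fraction,
         "n_used": f.n_used, "log_likelihood": f.log_likelihood, "converged": f.converged}
        for k, f in sorted(dmap.fits.items())
    ]
    return pd.DataFrame(rows)
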