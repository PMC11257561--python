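"""End-to-end demo pipeline: simulate -> map -> infer -> report.

Reproduces the inference chain on synthetic data: a filament-state /
dispersed-state / reassembled-state trio of displacement tables, their
diffusivity maps and histograms, an oligomer-size estimate from the
dispersed-state median D, charge curves for the bundled sequences, and
an ionics table for the buffer presets — all linked by one manifest.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import assembly, buffers, charge, smdm, synth
from .errors import InputError

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1
REQUIRED_COLUMNS = ["x0_um", "y0_um", "dx_um", "dy_um"]


@dataclass
class PipelineConfig:
    seed: int = 1
    n_molecules: int = 100_000
    grid_shape: tuple[int, int] = (48, 48)
    n_filaments: int = 12
    bin_size: float = 0.4
    D_bound: float = 1.5
    D_free: float = 7.0
    bound_fraction: float = 0.85
    dt: float = 1e-3
    sigma_loc: float = 0.02
    capture_radius: float = 0.8
    n_min: int = 10
    fit_background: bool = False
    # oligomer assumptions
    D_reference: float = 20.0       # free-FP reference diffusivity, um^2/s
    mw_reference: float = 27.0      # kDa
    mw_construct: float = 81.0      # kDa
    mw_subunit: float = 54.0        # kDa
    composition: str = "all-fusions"
    # sequences and buffers
    sequence_fastas: tuple[str, ...] = ()   # extra FASTA paths; bundled fixtures always run
    buffer_presets: tuple[str, ...] = tuple(sorted(buffers.BUFFER_PRESETS))

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @property
    def run_id(self) -> str:
        digest = hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:8]
        return f"run-{digest}-seed{self.seed}"

    def acquisition(self) -> synth.AcquisitionSettings:
        return synth.AcquisitionSettings(
            dt=self.dt, sigma_loc=self.sigma_loc,
            capture_radius=self.capture_radius, seed=self.seed,
        )


def read_localizations(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a displacement table, rejecting malformed rows."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    table = pd.read_csv(path, dtype=str)
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise InputError(f"{path}: missing required columns {missing}")
    numeric = table[REQUIRED_COLUMNS].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    for idx in table.index[bad]:
        logger.warning("%s: rejecting malformed row at line %d", path, idx + 2)
    # exact float() parsing for the kept rows (pd.to_numeric is lossy in the ulp)
    out = table.loc[~bad, REQUIRED_COLUMNS].astype(float).reset_index(drop=True)
    if "label" in table.columns:
        out["label"] = table.loc[~bad, "label"].reset_index(drop=True)
    logger.info("%s: %d rows loaded, %d rejected", path, len(out), int(bad.sum()))
    return out


def run_demo(config: PipelineConfig, outdir: Union[str, Path]) -> dict:
    """Run every stage on synthetic inputs; returns the manifest."""
    outdir = Path(outdir) / config.run_id
    outdir.mkdir(parents=True, exist_ok=True)
    settings = config.acquisition()
    artifacts: dict[str, str] = {}
    results: dict = {"schema_version": SCHEMA_VERSION, "config": config.to_dict()}

    def register(key: str, path: Path) -> Path:
        artifacts[key] = str(path.relative_to(outdir))
        return path

    # -- stage 1: synthetic fields and displacement tables -----------------
    logger.info("stage synth: grid %s, %d filaments", config.grid_shape, config.n_filaments)
    field_fil = synth.make_filament_field(
        config.grid_shape, config.n_filaments, config.D_bound, config.D_free,
        config.bound_fraction, seed=config.seed, bin_size=config.bin_size,
    )
    field_disp = synth.make_filament_field(
        config.grid_shape, 0, config.D_bound, config.D_free, 0.0,
        seed=config.seed, bin_size=config.bin_size,
    )
    synth.write_field(field_fil, register("field_filament", outdir / "field_filament.tif"))

    states = {"filament": field_fil, "dispersed": field_disp, "reassembled": field_fil}
    streams = np.random.SeedSequence(config.seed).spawn(len(states))
    tables: dict[str, pd.DataFrame] = {}
    lattice = smdm.BinLattice((0.0, 0.0), config.bin_size, *config.grid_shape)
    options = smdm.FitOptions(fit_background=config.fit_background, n_min=config.n_min)
    maps: dict[str, smdm.DiffusivityMap] = {}

    for (name, fld), stream in zip(states.items(), streams):
        rng = np.random.default_rng(stream)
        table, n_disc = synth.simulate_displacements(fld, settings, config.n_molecules, rng=rng)
        tables[name] = table
        synth.write_displacements(
            table, register(f"displacements_{name}", outdir / f"displacements_{name}.csv"),
            settings=settings, n_discarded=n_disc,
        )
        logger.info("stage synth[%s]: %d rows, %d discarded", name, len(table), n_disc)

        # -- stage 2: diffusivity maps + histograms ------------------------
        dmap = smdm.map_diffusivity(table, lattice, settings, options)
        maps[name] = dmap
        smdm.save_map(dmap, register(f"dmap_{name}", outdir / f"dmap_{name}.tif"),
                      png_path=register(f"dmap_{name}_png", outdir / f"dmap_{name}.png"))
        smdm.fits_to_frame(dmap).to_csv(
            register(f"fits_{name}", outdir / f"fits_{name}.csv"), index=False)
        r = np.hypot(table["dx_um"], table["dy_um"]).to_numpy()
        pooled = smdm.fit_diffusivity(r, settings, options)
        hist = smdm.displacement_histogram(r, pooled, settings)
        smdm.save_histogram(
            hist, register(f"hist_{name}", outdir / f"hist_{name}.csv"),
            png_path=register(f"hist_{name}_png", outdir / f"hist_{name}.png"),
            title=f"{name}: D = {pooled.D_hat:.2f} um^2/s",
        )
        logger.info("stage map[%s]: median D = %.3f", name, dmap.median_D)

    results["median_D"] = {name: maps[name].median_D for name in states}

    # -- stage 3: oligomer estimate from the dispersed state ---------------
    est = assembly.oligomer_size_from_D(
        D_measured=maps["dispersed"].median_D,
        D_reference=config.D_reference,
        mw_reference=config.mw_reference,
        mw_construct=config.mw_construct,
        mw_vimentin=config.mw_subunit,
        composition=config.composition,
    )
    results["oligomer"] = est.to_dict()
    register("oligomer", outdir / "oligomer.json").write_text(
        json.dumps(est.to_dict(), indent=2))

    # -- stage 4: charge curves for configured sequences -------------------
    seq_paths = [charge.bundled_fasta("P08670"), charge.bundled_fasta("P14136")]
    seq_paths += [Path(p) for p in config.sequence_fastas]
    charge_report = {}
    for fasta in seq_paths:
        for species in charge.read_fasta(fasta):
            curve = charge.charge_curve(species.sequence)
            stem = species.name.replace("|", "_")
            curve.to_frame().to_csv(
                register(f"curve_{stem}", outdir / f"curve_{stem}.csv"), index=False)
            _plot_curve(curve, register(f"curve_{stem}_png", outdir / f"curve_{stem}.png"),
                        species.name)
            charge_report[species.name] = {
                "molecular_weight_kda": round(species.molecular_weight_kda, 1),
                "net_charge_pH7.3": charge.net_charge(species.sequence, 7.3),
                "pI": curve.pI,
                "pka_preset": charge.DEFAULT_PKA,
            }
    results["charge"] = charge_report

    # -- stage 5: buffer ionics --------------------------------------------
    z_vim = charge_report.get("sp|P08670|VIME_HUMAN", {}).get("net_charge_pH7.3", -18.0)
    buffer_report = {}
    for preset in config.buffer_presets:
        state = buffers.speciate(buffers.get_preset(preset))
        buffer_report[preset] = buffers.ionic_report(state, charge_per_subunit=z_vim)
    results["buffers"] = buffer_report
    register("buffers", outdir / "buffers.json").write_text(
        json.dumps(buffer_report, indent=2))

    manifest = {
        "schema_version": SCHEMA_VERSION,
        "run_id": config.run_id,
        "seed": config.seed,
        "config": config.to_dict(),
        "artifacts": artifacts,
        "results": results,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def write_report(results: dict, path: Union[str, Path]) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **results}
    Path(path).write_text(json.dumps(payload, indent=2))


def _plot_curve(curve: charge.ChargeCurve, path: Path, title: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 3))
    ax.plot(curve.pH, curve.Z, color="tab:red")
    ax.axhline(0.0, color="0.6", lw=0.8)
    if curve.pI is not None:
        ax.axvline(curve.pI, color="0.6", lw=0.8, ls="--")
    ax.set_xlabel("pH")
    ax.set_ylabel("net charge (e)")
    ax.set_title(title, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
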