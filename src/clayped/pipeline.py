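"""Run configuration, stage orchestration, reporting and plots.

A run is described by a YAML/JSON-able :class:`RunConfig`: which stages to
execute, per-stage parameters, input/output paths and a global seed.
``run_pipeline`` executes the requested stages in dependency order (the
adsorption series is computed before anything that consumes it), writes
CSV/JSON reports plus a provenance record (config hash, seed, package
version), and keeps going through independent stages when one fails.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .adsorption_templating import (
    AdsorptionSeries,
    adsorption_fraction,
    orientation_histogram,
    rdf,
    reactive_pairs,
)
from .energetics import BULK_WATER_ENERGY, hydration_energy
from .io import EnergySeries, Role, Trajectory, read_energy_csv, read_trajectory, write_energy_csv, write_trajectory
from .layer_geometry import assign_layers, d_spacing, undulation
from .surface_dynamics import direction_autocorrelation, residence, track_velocities
from .synth_traj import GeneratorConfig, generate
from .wetdry_kinetics import KineticParams, run_cycles

__all__ = ["RunConfig", "run_pipeline", "configure_logging"]

log = logging.getLogger("clayped")

STAGES = (
    "generate",
    "layers",
    "adsorption",
    "rdf",
    "orient",
    "pairs",
    "diffusion",
    "energy",
    "kinetics",
)
# stages that cannot run unless their dependency ran (or an input is provided)
_NEEDS_ADSORPTION = {"pairs", "diffusion", "orient"}
_NEEDS_TRAJ = {"layers", "adsorption", "rdf", "orient", "pairs", "diffusion"}


class _JsonLineFormatter(logging.Formatter):
    def format(self, record: logging.LogRecord) -> str:
        return json.dumps(
            {"level": record.levelname, "stage": record.name, "msg": record.getMessage()}
        )


def configure_logging(level: str = "INFO", json_lines: bool = False) -> None:
    """Logging to stderr, optionally as machine-readable JSON lines."""
    handler = logging.StreamHandler(sys.stderr)
    if json_lines:
        handler.setFormatter(_JsonLineFormatter())
    else:
        handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("clayped")
    root.handlers[:] = [handler]
    root.setLevel(level.upper())


@dataclass
class RunConfig:
    """Validated description of one pipeline run; unknown keys are rejected."""

    stages: list[str] = field(default_factory=lambda: list(STAGES))
    seed: int = 0
    outdir: str = "clayped_out"
    traj_path: str | None = None
    species: list[str] = field(default_factory=lambda: ["ALA"] * 20)
    n_frames: int = 50
    generator: dict[str, Any] = field(default_factory=dict)
    adsorption: dict[str, Any] = field(default_factory=dict)
    rdf: dict[str, Any] = field(default_factory=dict)
    layers: dict[str, Any] = field(default_factory=dict)
    pairs: dict[str, Any] = field(default_factory=dict)
    energy: dict[str, Any] = field(default_factory=dict)
    kinetics: dict[str, Any] = field(default_factory=dict)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages {sorted(unknown)}; valid: {STAGES}")
        if self.traj_path is not None and not Path(self.traj_path).exists():
            raise ValueError(f"trajectory path {self.traj_path!r} does not exist")
        for key in ("hydrated_csv", "dry_csv"):
            p = self.energy.get(key)
            if p is not None and not Path(p).exists():
                raise ValueError(f"energy file {p!r} does not exist")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _resolve_stages(requested: list[str]) -> list[str]:
    """Order stages by the canonical sequence, auto-inserting dependencies."""
    wanted = set(requested)
    if wanted & _NEEDS_ADSORPTION and "adsorption" not in wanted:
        wanted.add("adsorption")
        log.info("adsorption stage auto-inserted (required by %s)",
                 sorted(wanted & _NEEDS_ADSORPTION))
    if wanted & _NEEDS_TRAJ and "generate" not in wanted:
        wanted.add("generate")
    return [s for s in STAGES if s in wanted]


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns a report dict.

    Each stage writes its tables under ``config.outdir``; a failing stage is
    recorded and its dependents are halted while independent stages continue.
    ``report["failed"]`` is empty on a fully successful run.
    """
    configure_logging(config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {"outputs": {}, "failed": {}}

    stages = _resolve_stages(config.stages)
    traj: Trajectory | None = None
    energy_series: EnergySeries | None = None
    ads: AdsorptionSeries | None = None

    if config.traj_path is not None:
        traj = read_trajectory(config.traj_path)
        stages = [s for s in stages if s != "generate"]

    def record(stage: str, **outputs: Any) -> None:
        report["outputs"][stage] = {k: str(v) for k, v in outputs.items()}
        log.info("stage %s done: %s", stage, sorted(outputs))

    for stage in stages:
        if stage in _NEEDS_TRAJ and traj is None:
            report["failed"][stage] = "no trajectory available (generate failed?)"
            continue
        if stage in _NEEDS_ADSORPTION and ads is None and "adsorption" in report["failed"]:
            report["failed"][stage] = "dependency 'adsorption' failed"
            continue
        try:
            if stage == "generate":
                gcfg = GeneratorConfig(**{"rng_seed": config.seed, **config.generator})
                traj, energy_series = generate(gcfg, config.species, config.n_frames)
                tpath = outdir / "trajectory.pdb"
                epath = outdir / "energies.csv"
                write_trajectory(traj, tpath)
                write_energy_csv(energy_series, epath)
                record(stage, trajectory=tpath, energies=epath)
            elif stage == "layers":
                la = assign_layers(traj.first_frame(), **config.layers.get("assign", {}))
                prof = d_spacing(la, traj.first_frame(), **config.layers.get("window", {}))
                und = undulation(la, traj)
                out = outdir / "layers.json"
                out.write_text(json.dumps({
                    "n_layers": la.n_layers,
                    "n_noise": la.n_noise,
                    "mean_z": la.mean_z.tolist(),
                    "d_spacing_mean": prof.mean,
                    "d_spacing_std": prof.std,
                    "pair_mean": prof.pair_mean.tolist(),
                    "undulation_per_layer": und.per_layer_std.tolist(),
                    "undulation_pooled": und.pooled_std,
                }, indent=2))
                record(stage, summary=out)
            elif stage == "adsorption":
                ads = adsorption_fraction(traj, **config.adsorption)
                out = outdir / "adsorption.csv"
                pd.DataFrame({
                    "frame": np.arange(traj.n_frames),
                    "frac_backbone": ads.backbone.mean(axis=1),
                    "frac_sidechain": ads.sidechain.mean(axis=1),
                }).to_csv(out, index=False)
                summ = outdir / "adsorption.json"
                summ.write_text(json.dumps(ads.summary(), indent=2))
                record(stage, series=out, summary=summ)
            elif stage == "rdf":
                kw = dict(config.rdf)
                pair = tuple(kw.pop("pair", (Role.C_TERM_O.value, Role.LDH_METAL_AL.value)))
                r_max = kw.pop("r_max", min(traj.box.min() / 2.0 - 0.5, 12.0))
                res = rdf(traj, pair, r_max, **kw)
                ref = rdf(traj, (Role.LDH_METAL_AL.value, Role.LDH_METAL_AL.value), r_max, **kw)
                out = outdir / "rdf.csv"
                pd.DataFrame({
                    "r": res.r,
                    "g_" + "_".join(res.pair): res.g,
                    "g_AL_AL": ref.g,
                }).to_csv(out, index=False)
                record(stage, table=out)
            elif stage == "orient":
                hist = orientation_histogram(traj, adsorbed_only=ads is not None, adsorption=ads)
                out = outdir / "orientation.csv"
                pd.DataFrame({"theta_deg": hist.bin_centers, "count": hist.counts}).to_csv(
                    out, index=False
                )
                record(stage, histogram=out)
            elif stage == "pairs":
                rp = reactive_pairs(traj, ads, **config.pairs)
                out = outdir / "reactive_pairs.csv"
                pd.DataFrame({
                    "frame": np.arange(traj.n_frames),
                    "n_pairs": rp.counts,
                    "percent_participating": rp.percent_participating,
                }).to_csv(out, index=False)
                record(stage, series=out)
            elif stage == "diffusion":
                stats = track_velocities(traj, ads)
                six = direction_autocorrelation(stats, rng_seed=config.seed)
                res = residence(traj, ads)
                out = outdir / "diffusion.json"
                out.write_text(json.dumps({
                    "n_steps": stats.n_steps,
                    "velocity_mean": float(stats.velocities.mean()) if stats.n_steps else None,
                    "velocity_std": float(stats.velocities.std()) if stats.n_steps else None,
                    "six_fold_score": six.score,
                    "six_fold_p": six.p_value,
                    "residence_mean": res.mean,
                    "residence_std": res.std,
                    "n_never_adsorbed": res.n_never_adsorbed,
                }, indent=2))
                csv_out = outdir / "velocities.csv"
                pd.DataFrame({
                    "velocity_A_per_ns": stats.velocities,
                    "direction_deg": stats.directions,
                }).to_csv(csv_out, index=False)
                record(stage, summary=out, velocities=csv_out)
            elif stage == "energy":
                kw = dict(config.energy)
                if "hydrated_csv" in kw:
                    s_n = read_energy_csv(kw.pop("hydrated_csv"), int(kw.pop("n_water")))
                    s_0 = read_energy_csv(kw.pop("dry_csv"), 0)
                elif energy_series is not None and energy_series.n_water > 0:
                    s_n = energy_series
                    gcfg = GeneratorConfig(
                        **{"rng_seed": config.seed, **config.generator, "hydration": 0}
                    )
                    _, s_0 = generate(gcfg, config.species, config.n_frames)
                else:
                    raise ValueError("energy stage needs CSV inputs or a hydrated generate stage")
                res = hydration_energy(s_n, s_0, kw.pop("reference", BULK_WATER_ENERGY))
                if kw:
                    raise ValueError(f"unknown energy options {sorted(kw)}")
                out = outdir / "energy.json"
                out.write_text(json.dumps(dataclasses.asdict(res), indent=2))
                record(stage, summary=out)
            elif stage == "kinetics":
                kw = dict(config.kinetics)
                n_cycles = kw.pop("n_cycles", 20)
                params = KineticParams(**kw)
                ledger = run_cycles(n_cycles, params)
                out = outdir / "kinetics_surface.csv"
                ledger.to_frame().to_csv(out)
                summ = outdir / "kinetics.json"
                summ.write_text(json.dumps({
                    "first_cycle_at_threshold": {
                        f"X{n + 1}": int(c)
                        for n, c in enumerate(ledger.first_cycle)
                        if c > 0
                    },
                    "threshold": params.threshold,
                    "longest_after_cycle_1": ledger.longest_significant(1),
                }, indent=2))
                record(stage, ledger=out, summary=summ)
        except Exception as exc:  # noqa: BLE001 — stage isolation is the contract
            log.error("stage %s failed: %s", stage, exc)
            report["failed"][stage] = str(exc)
            if stage == "generate":
                traj = None
            if stage == "adsorption":
                ads = None

    prov = {
        "config_sha256": config.config_hash(),
        "seed": config.seed,
        "clayped_version": __version__,
        "numpy_version": np.__version__,
    }
    (outdir / "provenance.json").write_text(json.dumps(prov, indent=2))
    report["provenance"] = prov
    return report
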