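"""Pipeline orchestration: protonate → per-frame geometry → trajectory
metrics → recovery report, from a single config.

Every default the analysis uses (50 Å² SASA threshold, 3.5 Å contact
cutoff, 30° hydrogen-bond angle, 1.4 Å SASA probe, 1.0 Å CCS probe, 0.1
tail fraction, 0.5 occupancy binarization) lives in
:class:`PipelineConfig`, so a config file is a complete provenance record.
Runs are deterministic given the config: all Monte-Carlo seeds derive from
``config.seed``.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core import Phase, ReplicaSet, StructureModel, read_structure, read_trajectory
from .errors import ConfigError, DataError
from .geometry import ccs_projection_approximation, molecular_volume, shrake_rupley_sasa
from .metrics import SeriesStat, contact_occupancy, hydrogen_bond_count, rmsd_series
from .protonation import (
    apply_neighbor_exclusion,
    apply_plan,
    build_protonation_plan,
    per_residue_sasa,
    select_candidates,
)
from .recovery import (
    PhaseGeometry,
    RecoveryReport,
    build_report,
    contact_recovery,
    tail_average,
)
from . import synth

log = logging.getLogger(__name__)

PHASES = (Phase.BULK, Phase.VACUUM, Phase.REHYDRATION)


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; round-trips through YAML."""

    # input: either the built-in synthetic scenario or per-phase file lists
    mode: str = "synthetic"                  # "synthetic" | "files"
    seed: int = 7
    n_res_per_chain: int = 24
    n_replicas: int = 8
    n_frames: int = 50
    phase_files: dict = field(default_factory=dict)  # phase → list of PDB paths
    topology_file: str = ""
    dt_ns: float = 10.0

    # protonation
    target_charge: int = 10
    sasa_threshold: float = 50.0
    neighbor_mode: str = "sequence"
    spatial_cutoff: float | None = None
    symmetric: bool = True
    sasa_frame_stride: int = 5

    # geometry
    sasa_probe: float = 1.4
    ccs_probe: float = 1.0
    ccs_orientations: int = 16
    ccs_pixel: float = 0.5
    volume_voxel: float = 0.3
    geometry_stride: int = 1

    # metrics / recovery
    rmsd_selection: str = "calpha"
    contact_cutoff: float = 3.5
    presence_threshold: float = 0.5
    hbond_distance: float = 3.5
    hbond_angle: float = 30.0
    tail_fraction: float = 0.1

    outdir: str = "vacuform_out"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ConfigError(f"unknown mode {self.mode!r}")
        if not 0 < self.tail_fraction <= 1:
            raise ConfigError("tail_fraction must be in (0, 1]")
        if self.neighbor_mode == "spatial" and self.spatial_cutoff is None:
            raise ConfigError("spatial neighbor mode requires spatial_cutoff")
        if self.mode == "files":
            missing = [p.value for p in PHASES if p.value not in self.phase_files]
            if missing:
                raise ConfigError(f"phase_files missing phases: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        try:
            return cls(**data)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:16]


def _ccs_seed(base: int, phase_idx: int, rep_idx: int, frame_idx: int) -> int:
    ss = np.random.SeedSequence([base, phase_idx, rep_idx, frame_idx])
    return int(ss.generate_state(1)[0] % (2 ** 31))


def load_ensembles(config: PipelineConfig) -> tuple[StructureModel, dict[Phase, ReplicaSet]]:
    """Obtain the three phase ensembles (generate or read from files)."""
    if config.mode == "synthetic":
        ref, specs = synth.default_scenario(seed=config.seed,
                                            n_res_per_chain=config.n_res_per_chain,
                                            n_replicas=config.n_replicas,
                                            n_frames=config.n_frames)
        return ref, {ph: synth.generate_phase_ensemble(ref, sp)
                     for ph, sp in specs.items()}
    topo = read_structure(config.topology_file)
    from .core import assign_solution_charges
    topo = assign_solution_charges(topo)
    out = {}
    for phase in PHASES:
        files = config.phase_files[phase.value]
        reps = [read_trajectory(f, topo, dt=config.dt_ns,
                                replica_id=f"{phase.value}-{i:03d}", phase=phase)
                for i, f in enumerate(files)]
        out[phase] = ReplicaSet(reps)
    return topo, out


def geometry_series(replicas: ReplicaSet, config: PipelineConfig,
                    phase_idx: int) -> tuple[dict[str, SeriesStat], pd.DataFrame]:
    """Per-frame CCS/SASA/volume for every replica, as replica-averaged
    series plus a tidy per-frame table."""
    topo = replicas.topology
    radii = topo.radii
    stride = config.geometry_stride
    times = replicas.replicas[0].frame_times[::stride]
    n_t = len(times)
    vals = {m: np.empty((n_t, replicas.n_replicas)) for m in ("ccs", "sasa", "volume")}
    rows = []
    for j, rep in enumerate(replicas.replicas):
        for k, fi in enumerate(range(0, rep.n_frames, stride)):
            frame = rep.frames[fi]
            ccs = ccs_projection_approximation(
                frame, radii, probe=config.ccs_probe,
                n_orientations=config.ccs_orientations,
                seed=_ccs_seed(config.seed, phase_idx, j, fi),
                pixel=config.ccs_pixel)
            sasa = float(shrake_rupley_sasa(frame, radii, probe=config.sasa_probe).sum())
            vol = molecular_volume(frame, radii, voxel=config.volume_voxel)
            vals["ccs"][k, j] = ccs.ccs
            vals["sasa"][k, j] = sasa
            vals["volume"][k, j] = vol
            rows.append({"replica": rep.replica_id, "frame": fi,
                         "time_ns": rep.frame_times[fi], "ccs": ccs.ccs,
                         "ccs_se": ccs.mc_standard_error, "sasa": sasa,
                         "volume": vol})
    series = {}
    for m, unit in (("ccs", "Å²"), ("sasa", "Å²"), ("volume", "Å³")):
        v = vals[m]
        sd = v.std(axis=1, ddof=1) if replicas.n_replicas > 1 else np.zeros(n_t)
        series[m] = SeriesStat(time=times, mean=v.mean(axis=1), spread=sd,
                               label=f"{m} [{unit}]", samples=v)
    return series, pd.DataFrame(rows)


def run_protonation(config: PipelineConfig, bulk: ReplicaSet):
    """SASA → candidates → exclusion → plan → vacuum-charged structure."""
    topo = bulk.topology
    sasa = per_residue_sasa(bulk.replicas[0], probe=config.sasa_probe,
                            frame_stride=config.sasa_frame_stride)
    candidates = select_candidates(sasa, threshold=config.sasa_threshold)
    candidates = apply_neighbor_exclusion(candidates, topo,
                                          mode=config.neighbor_mode,
                                          spatial_cutoff=config.spatial_cutoff)
    plan = build_protonation_plan(topo, candidates, config.target_charge,
                                  symmetric=config.symmetric,
                                  sasa_threshold=config.sasa_threshold)
    charged = apply_plan(topo, plan)
    return plan, charged


def _tail_window(n_frames: int, tail_fraction: float) -> tuple[int, int]:
    k = max(1, int(round(n_frames * tail_fraction)))
    return n_frames - k, n_frames


def run_pipeline(config: PipelineConfig) -> RecoveryReport:
    """Run the full analysis and write all artifacts under ``config.outdir``.

    Stages: load/generate → protonation → per-frame geometry → RMSD and
    occupancy/H-bond metrics → recovery report. Any stage failure aborts
    with the stage name; outputs written before the failure are flagged
    as partial in the run log.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    run_log: dict = {"config_sha256": config.digest(), "version": __version__,
                     "stages": {}, "partial": True, "warnings": []}
    t_all = time.time()
    config.to_yaml(outdir / "config.yaml")

    def stage(name):
        def wrap(fn, *args, **kw):
            t0 = time.time()
            try:
                result = fn(*args, **kw)
            except Exception as exc:
                run_log["stages"][name] = {"status": "failed", "error": str(exc)}
                _write_log(outdir, run_log)
                raise DataError(f"stage {name!r} failed: {exc}") from exc
            run_log["stages"][name] = {"status": "ok",
                                       "seconds": round(time.time() - t0, 3)}
            return result
        return wrap

    ref, ensembles = stage("load")(load_ensembles, config)

    plan, charged = stage("protonate")(run_protonation, config, ensembles[Phase.BULK])
    (outdir / "protonation_plan.json").write_text(plan.to_json() + "\n")
    (outdir / "protonation_table.txt").write_text(plan.to_table() + "\n")

    series: dict[Phase, dict[str, SeriesStat]] = {}
    for i, phase in enumerate(PHASES):
        s, table = stage(f"geometry:{phase.value}")(
            geometry_series, ensembles[phase], config, i)
        series[phase] = s
        table.to_csv(outdir / f"series_{phase.value}.csv", index=False)

    # RMSD of the rehydration phase against both references
    bulk_ref = ref
    vac_last = ensembles[Phase.VACUUM].replicas[0]
    vacuum_ref = ref.with_coords(vac_last.frames[-1])
    for name, reference in (("bulk", bulk_ref), ("vacuum", vacuum_ref)):
        rs = stage(f"rmsd:vs_{name}")(
            rmsd_series, ensembles[Phase.REHYDRATION], reference,
            config.rmsd_selection)
        pd.DataFrame({"time_ns": rs.time, "mean": rs.mean,
                      "sd": rs.spread}).to_csv(
            outdir / f"rmsd_rehydration_vs_{name}.csv", index=False)

    window = _tail_window(config.n_frames if config.mode == "synthetic"
                          else ensembles[Phase.BULK].replicas[0].n_frames,
                          config.tail_fraction)
    occ = {}
    hbond_mean = {}
    for phase in PHASES:
        occ[phase] = stage(f"occupancy:{phase.value}")(
            contact_occupancy, ensembles[phase], window, config.contact_cutoff)
        np.savetxt(outdir / f"occupancy_{phase.value}.tsv", occ[phase].matrix,
                   delimiter="\t", fmt="%.6f")
        counts = []
        proxy = False
        for rep in ensembles[phase].replicas:
            for fi in range(*window):
                hb = hydrogen_bond_count(rep.frames[fi], ref,
                                         d_cutoff=config.hbond_distance,
                                         angle_cutoff=config.hbond_angle)
                counts.append(hb.count)
                proxy |= hb.proxy_mode
        hbond_mean[phase.value] = float(np.mean(counts))
        if proxy:
            run_log["warnings"].append(
                f"{phase.value}: hydrogen bonds counted in donor-heavy-atom "
                "proxy mode (no hydrogens in topology)")

    def phase_geo(phase: Phase) -> PhaseGeometry:
        return PhaseGeometry(
            ccs=tail_average(series[phase]["ccs"], config.tail_fraction),
            sasa=tail_average(series[phase]["sasa"], config.tail_fraction),
            volume=tail_average(series[phase]["volume"], config.tail_fraction))

    contact = stage("contact_recovery")(
        contact_recovery, occ[Phase.BULK], occ[Phase.VACUUM],
        occ[Phase.REHYDRATION], config.presence_threshold)
    report = stage("report")(
        build_report, phase_geo(Phase.BULK), phase_geo(Phase.VACUUM),
        phase_geo(Phase.REHYDRATION), contact, hbond_mean, config.tail_fraction)

    (outdir / "recovery_report.json").write_text(report.to_json() + "\n")
    (outdir / "recovery_report.md").write_text(report.to_markdown())
    run_log["partial"] = False
    run_log["total_seconds"] = round(time.time() - t_all, 3)
    _write_log(outdir, run_log)
    return report


def _write_log(outdir: Path, run_log: dict) -> None:
    log_copy = dict(run_log)
    log_copy.pop("total_seconds", None)  # timings vary run to run
    timed = {k: {kk: vv for kk, vv in v.items() if kk != "seconds"}
             for k, v in run_log["stages"].items()}
    (outdir / "run_log.json").write_text(
        json.dumps({**log_copy, "stages": timed}, indent=2, sort_keys=True) + "\n")
    (outdir / "run_timings.json").write_text(
        json.dumps(run_log, indent=2, sort_keys=True) + "\n")
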