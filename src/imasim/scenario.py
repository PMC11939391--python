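"""Scenario configuration, batch simulation running and fixture generation.

This is the engineering shell that makes the engine executable end-to-end
without haptic hardware: a YAML scenario describes the anatomy, solver,
coupling, instrument scripts and metrics setup; :func:`run_scenario` builds
the scene, replays the scripted operator trajectory frame by frame (60 Hz
frames, 5 ms solver substeps), performs grasping, cutting, coupling and force
evaluation, and writes machine-checkable artifacts (JSON-lines event log,
force CSV, trajectory CSV, metrics report JSON). Everything is deterministic
given the scenario seed.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from . import anatomy, cardiac, coupling, cutting, haptics, instrument, metrics
from .mesh_core import PolylineMesh, closest_point_on_mesh
from .pbd import SolverConfig, step

__all__ = ["Scenario", "RunResult", "load_scenario", "run_scenario",
           "generate_fixtures", "analyze_trajectory_files", "summary_table",
           "FIXTURE_KINDS"]

FRAME_RATE = 60.0
FIXTURE_KINDS = ("demo_scene", "static_trial_set", "dynamic_trial_set",
                 "table1_trajectories")


@dataclass
class Scenario:
    """Validated scenario: anatomy specs, solver/coupling/force configuration,
    instrument scripts, metrics setup, seed and output directory."""

    seed: int
    output_dir: Path
    label: str = "static"
    fascia: anatomy.FasciaSpec = field(default_factory=anatomy.FasciaSpec)
    fascia_origin: tuple = (0.0, 0.0, 0.02)
    vessel_radius: float = 0.0015
    vessel_centerline: np.ndarray = None  # type: ignore[assignment]
    vessel_sim_segments: int = 6
    vessel_display_segments: int = 12
    strands: anatomy.StrandGenSpec = field(
        default_factory=lambda: anatomy.StrandGenSpec(max_distance=0.012))
    support_radius: float = 0.03
    support_length: float = 0.1
    heart_amplitude: float = 0.0
    heart_period: float = 0.8
    lambda_max: float = 0.005
    cut_width: float = 0.004
    capture_radius: float = 0.002
    scripts: list = field(default_factory=list)
    reference_distance: float = metrics.DEFAULT_REFERENCE_DISTANCE
    cardiac_side_vector: tuple = (1.0, 0.0, 0.0)
    projection_normal: tuple = (0.0, 0.0, 1.0)
    duration: float | None = None

    def __post_init__(self) -> None:
        self.output_dir = Path(self.output_dir)
        if self.vessel_centerline is None:
            self.vessel_centerline = np.column_stack([
                np.full(12, 0.04), np.linspace(0.01, 0.11, 12), np.zeros(12)])
        self.vessel_centerline = np.asarray(self.vessel_centerline,
                                            dtype=float).reshape(-1, 3)
        if self.label not in ("static", "dynamic"):
            raise ValueError("label must be 'static' or 'dynamic'")
        for p in self.scripts:
            if not Path(p).exists():
                raise FileNotFoundError(f"instrument script not found: {p}")


def load_scenario(path) -> Scenario:
    """Load and validate a scenario YAML; errors name the offending key."""
    path = Path(path)
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: scenario must be a mapping")

    def _need(key, typ):
        if key not in raw:
            raise ValueError(f"{path}: missing required key '{key}'")
        if not isinstance(raw[key], typ):
            raise ValueError(f"{path}: key '{key}' must be {typ.__name__}")
        return raw[key]

    seed = _need("seed", int)
    out = Path(_need("output_dir", str))
    kwargs: dict = {"seed": seed, "output_dir": out}
    simple = {"label": str, "vessel_radius": (int, float),
              "heart_amplitude": (int, float), "heart_period": (int, float),
              "lambda_max": (int, float), "cut_width": (int, float),
              "capture_radius": (int, float),
              "reference_distance": (int, float), "duration": (int, float)}
    for key, typ in simple.items():
        if key in raw:
            if not isinstance(raw[key], typ):
                raise ValueError(f"{path}: key '{key}' has wrong type")
            kwargs[key] = raw[key]
    if "fascia" in raw:
        f = raw["fascia"]
        if not isinstance(f, dict):
            raise ValueError(f"{path}: key 'fascia' must be a mapping")
        try:
            kwargs["fascia"] = anatomy.FasciaSpec(
                width=f.get("width", 0.08), height=f.get("height", 0.12),
                resolution=tuple(f.get("resolution", (9, 13))),
                total_mass=f.get("total_mass", 0.05))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: invalid fascia spec: {exc}") from None
    if "strands" in raw:
        s = raw["strands"]
        if not isinstance(s, dict):
            raise ValueError(f"{path}: key 'strands' must be a mapping")
        kwargs["strands"] = anatomy.StrandGenSpec(
            strands_per_face=s.get("strands_per_face", 2),
            segments_per_strand=s.get("segments_per_strand", 3),
            max_distance=s.get("max_distance", 0.012),
            max_angle_deviation=float(np.deg2rad(s.get("max_angle_deg", 15.0))))
    if "scripts" in raw:
        if not isinstance(raw["scripts"], list):
            raise ValueError(f"{path}: key 'scripts' must be a list of paths")
        kwargs["scripts"] = [Path(path).parent / p for p in raw["scripts"]]
    return Scenario(**kwargs)


@dataclass
class RunResult:
    """Artifacts of one scenario run."""

    trajectory: metrics.Trajectory
    sai: float
    report: dict
    report_path: Path
    events_path: Path
    forces_path: Path
    cut_events: int


def _build_scene(sc: Scenario):
    fascia_mesh, fascia_cs, fascia_sys = anatomy.build_fascia(
        sc.fascia, origin=sc.fascia_origin)
    vessel = anatomy.build_vessel(sc.vessel_centerline, sc.vessel_radius,
                                  sc.vessel_sim_segments, sc.vessel_display_segments)
    from .pbd import ParticleSystem
    v_mass = anatomy.assign_uniform_mass(vessel.sim_mesh, 0.01)
    v_inv = 1.0 / v_mass
    # anchor the end rings so the free vessel keeps station (gravity-free)
    nseg = sc.vessel_sim_segments
    v_inv[:nseg] = 0.0
    v_inv[-nseg:] = 0.0
    vessel_sys = ParticleSystem(vessel.sim_mesh.vertices.copy(),
                                inverse_masses=v_inv)
    vessel_cs = anatomy.constraints_from_mesh(vessel.sim_mesh,
                                              vessel.sim_mesh.vertices,
                                              1.0, 0.2)
    cl = sc.vessel_centerline
    axis = cl[-1] - cl[0]
    support = anatomy.build_support_cylinder(
        center=cl.mean(axis=0) - np.array([0.0, 0.0, sc.support_radius + 0.005]),
        axis=axis / np.linalg.norm(axis), radius=sc.support_radius,
        length=sc.support_length, n_circ=10, n_axial=6)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        network = anatomy.generate_strands(support, vessel.sim_mesh, sc.strands,
                                           sc.seed)
    strand_sys = strand_cs = cmap = None
    if network.strands:
        strand_sys, strand_cs = anatomy.attach_strand_constraints(network)
        cmap = coupling.build_coupling_map(network, vessel.sim_mesh, sc.lambda_max)
    heart = cardiac.CardiacCycleSpec(
        period=sc.heart_period,
        amplitude=sc.heart_amplitude if sc.label == "dynamic" else 0.0,
        mesh=cardiac.make_ellipsoid_heart(center=(0.12, 0.06, -0.01)))
    return (fascia_mesh, fascia_cs, fascia_sys, vessel, vessel_sys, vessel_cs,
            support, network, strand_sys, strand_cs, cmap, heart)


def run_scenario(sc: Scenario) -> RunResult:
    """Replay the scenario's instrument scripts through the full engine.

    Raises with a stage-tagged message on any module failure; an empty
    trajectory (no instrument script) is rejected at the metrics stage.
    """
    out = Path(sc.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (fascia_mesh, fascia_cs, fascia_sys, vessel, vessel_sys, vessel_cs,
     support, network, strand_sys, strand_cs, cmap, heart) = _build_scene(sc)

    solver_fascia = SolverConfig()
    solver_zero_g = SolverConfig(external_acceleration=np.zeros(3))
    frame_dt = 1.0 / FRAME_RATE
    substeps = max(1, round(frame_dt / solver_fascia.dt))
    mean_edge = float(np.mean([np.linalg.norm(np.diff(
        fascia_mesh.vertices[e], axis=0)) for e in fascia_mesh.edges()]))
    eps = 0.5 * mean_edge

    scripts = [instrument.load_tool_script(p) if not isinstance(p, instrument.ToolScript)
               else p for p in sc.scripts]
    events_path = out / "events.jsonl"
    forces_path = out / "forces.csv"
    events = open(events_path, "w")
    times: list[float] = []
    tips: list[np.ndarray] = []
    contacts: list[haptics.ContactState] = []
    cut_events = 0
    applied_ima = np.zeros_like(vessel_sys.positions)
    fascia_fixed_rest = None

    try:
        if scripts:
            script = scripts[0]
            t_end = script.times[-1] if sc.duration is None else sc.duration
            n_frames = int(np.floor(t_end * FRAME_RATE)) + 1
            state = instrument.InstrumentState()
            prev_tip = None
            for k in range(n_frames):
                t = k * frame_dt
                pose, jaw_rate, pedal = script.pose_at(t)
                state.t_controller = pose
                state.jaw_rate = jaw_rate
                instrument.update_jaw(state, frame_dt)
                tip = instrument.world_transform(state).translation

                # cardiac pulsation moves the kinematic boundaries
                if heart.amplitude > 0:
                    fixed = fascia_sys.fixed
                    if fascia_fixed_rest is None or len(fascia_fixed_rest) != fixed.sum():
                        fascia_fixed_rest = fascia_sys.rest_positions[fixed].copy()
                    pert = np.array([cardiac.field_perturbation(heart, p, t)
                                     for p in fascia_fixed_rest])
                    fascia_sys.positions[fixed] = fascia_fixed_rest + pert

                # grasp / release drives the coupling state β
                if state.closed and not state.grasping:
                    instrument.grasp(state, fascia_sys, sc.capture_radius)
                    if state.grasping:
                        events.write(json.dumps({"frame": k, "event": "grasp",
                                                 "n": len(state.grasp_set)}) + "\n")
                elif not state.closed and state.grasping:
                    instrument.release(state, fascia_sys)
                    events.write(json.dumps({"frame": k, "event": "release"}) + "\n")

                for _ in range(substeps):
                    instrument.update_grasped_particles(state, fascia_sys)
                    step(fascia_sys, fascia_cs, solver_fascia)
                    step(vessel_sys, vessel_cs, solver_zero_g)

                # contact query against the fascia for forces and β
                dist, q, fi = closest_point_on_mesh(tip, fascia_mesh)
                nrm = fascia_mesh.face_normals()[fi]
                pen = max(0.0, float(-nrm @ (tip - q)))
                vel = np.zeros(3) if prev_tip is None else (tip - prev_tip) / frame_dt
                vn = abs(float(nrm @ vel))
                vt = float(np.linalg.norm(vel - (nrm @ vel) * nrm))
                in_contact = pen > 0 or dist < 1e-3
                contacts.append(haptics.ContactState(pen, vn, vt, "fascia",
                                                     pedal, in_contact))
                times.append(t)
                beta = 1 if (state.grasping or pen > 0) else 0

                # bidirectional coupling (positional offset transfer)
                if cmap is not None and strand_sys is not None:
                    ima_off = vessel_sys.positions - vessel_sys.rest_positions
                    s_off = coupling.propagate_ima_to_strands(
                        ima_off, cmap, n_strand_points=network.n_particles)
                    strand_sys.positions[cmap.strand_indices] = \
                        strand_sys.rest_positions[cmap.strand_indices] + \
                        s_off[cmap.strand_indices]
                    anatomy.update_strand_anchors(
                        network, strand_sys,
                        support.vertices, vessel_sys.positions)
                    step(strand_sys, strand_cs, solver_zero_g)
                    fat_off = strand_sys.positions - strand_sys.rest_positions
                    new_ima = coupling.propagate_fat_to_ima(
                        fat_off, applied_ima, beta, cmap)
                    vessel_sys.positions += new_ima - applied_ima
                    applied_ima = new_ima

                # electrocautery dissection
                if pedal and prev_tip is not None:
                    geom = cutting.CutGeometry(prev_tip, tip, eps)
                    fascia_mesh, fascia_sys, delta = cutting.cut_fascia(
                        fascia_mesh, fascia_sys, fascia_cs, geom)
                    if not delta.empty:
                        cut_events += 1
                        events.write(json.dumps(
                            {"frame": k, "event": "cut_fascia",
                             **delta.summary(),
                             "components": cutting.mesh_components(fascia_mesh)})
                            + "\n")
                    if network.strands:
                        plane = cutting.CutPlane.from_pose(
                            tip, instrument.world_transform(state).rotation,
                            sc.cut_width)
                        marked = cutting.mark_segments_for_removal(network, plane)
                        if marked:
                            removed, orphans = cutting.remove_segments(
                                network, marked, strand_cs)
                            cut_events += 1
                            events.write(json.dumps(
                                {"frame": k, "event": "cut_strands",
                                 "segments": len(marked),
                                 "orphans": len(orphans)}) + "\n")
                cutting.decay_diameters(network, steps=1)
                events.write(json.dumps(
                    {"frame": k, "event": "frame", "beta": beta,
                     "max_offset": float(np.abs(applied_ima).max())}) + "\n")
                prev_tip = tip
                tips.append(tip)
        else:
            # settle only: no instrument, no cuts
            for _ in range(30):
                step(fascia_sys, fascia_cs, solver_fascia)
                step(vessel_sys, vessel_cs, solver_zero_g)
    finally:
        events.close()

    if contacts:
        haptics.force_timeline(haptics.LAYER_DEFAULTS, np.asarray(times),
                               contacts).to_csv(forces_path, index=False)
    else:
        forces_path.write_text("time_s,layer,F_n,F_t,F_th,F_total,"
                               "clamped_n,clamped_t\n")

    if not tips:
        raise ValueError("metrics stage: empty trajectory "
                         "(scenario has no instrument script samples)")
    traj = metrics.Trajectory(np.asarray(times), np.asarray(tips),
                              FRAME_RATE, sc.label)
    cfg = metrics.SAIConfig(
        centerline=PolylineMesh(
            sc.vessel_centerline,
            np.column_stack([np.arange(len(sc.vessel_centerline) - 1),
                             np.arange(1, len(sc.vessel_centerline))]),
            np.full(len(sc.vessel_centerline), 2 * sc.vessel_radius)),
        reference_distance=sc.reference_distance,
        cardiac_side_vector=np.asarray(sc.cardiac_side_vector, dtype=float),
        projection_normal=np.asarray(sc.projection_normal, dtype=float))
    sai = metrics.compute_sai(traj, cfg)
    report = {
        "label": sc.label, "seed": sc.seed, "n_samples": traj.n,
        "sai": sai, "cut_events": cut_events,
        "final_fascia_components": cutting.mesh_components(fascia_mesh),
        "strand_segments_remaining": int(len(network.polyline.segments))
        if network.strands or len(network.polyline.segments) else 0,
    }
    report_path = out / "metrics_report.json"
    report_path.write_text(json.dumps(report, sort_keys=True, indent=2) + "\n")
    # export trajectory for re-analysis
    import pandas as pd
    pd.DataFrame({"time_s": traj.times, "tx": traj.positions[:, 0],
                  "ty": traj.positions[:, 1], "tz": traj.positions[:, 2]}
                 ).to_csv(out / "trajectory.csv", index=False)
    return RunResult(traj, sai, report, report_path, events_path, forces_path,
                     cut_events)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------


def _default_sai_config() -> metrics.SAIConfig:
    n = 12
    cl = np.column_stack([np.full(n, 0.04), np.linspace(0.01, 0.11, n),
                          np.zeros(n)])
    return metrics.SAIConfig(
        centerline=PolylineMesh(cl, np.column_stack([np.arange(n - 1),
                                                     np.arange(1, n)]),
                                np.full(n, 0.003)),
        cardiac_side_vector=np.array([1.0, 0.0, 0.0]),
        projection_normal=np.array([0.0, 0.0, 1.0]))


def _trajectory_to_script(traj: metrics.Trajectory) -> instrument.ToolScript:
    n = traj.n
    return instrument.ToolScript(
        traj.times, traj.positions,
        np.tile([1.0, 0.0, 0.0, 0.0], (n, 1)),
        np.zeros(n), np.zeros(n, dtype=bool))


def _demo_script(out_dir: Path) -> Path:
    """Scripted pass of the cautery tip across the fascia sheet with pedal on."""
    n = 90
    t = np.arange(n) / FRAME_RATE
    x = np.linspace(-0.01, 0.09, n)
    y = np.full(n, 0.055)  # off the fascia grid lines so edges are crossed cleanly
    z = np.full(n, 0.02)
    pedal = np.ones(n, dtype=int)
    pedal[:10] = 0
    script = instrument.ToolScript(t, np.column_stack([x, y, z]),
                                   np.tile([1.0, 0.0, 0.0, 0.0], (n, 1)),
                                   np.zeros(n), pedal.astype(bool))
    path = out_dir / "demo_script.csv"
    instrument.save_tool_script(script, path)
    return path


def generate_fixtures(kind: str, seed: int, out_dir="fixtures") -> list[Path]:
    """Write synthetic fixture files; returns the created paths.

    Kinds: ``demo_scene`` (scenario YAML + scripted cut), ``static_trial_set``
    / ``dynamic_trial_set`` (10 trajectory CSVs regenerating the respective
    reference per-trial SAI values) and ``table1_trajectories`` (all 20).
    """
    if kind not in FIXTURE_KINDS:
        raise ValueError(f"unknown fixture kind {kind!r}; choose from "
                         f"{', '.join(FIXTURE_KINDS)}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _default_sai_config()
    written: list[Path] = []
    if kind == "demo_scene":
        script = _demo_script(out)
        written.append(script)
        ypath = out / "demo_scene.yaml"
        ypath.write_text(yaml.safe_dump({
            "seed": int(seed), "output_dir": str(out / "run"),
            "label": "static",
            "scripts": [script.name]}))
        written.append(ypath)
        return written
    groups = []
    if kind in ("static_trial_set", "table1_trajectories"):
        groups.append(("static", metrics.REFERENCE_SAI_STATIC))
    if kind in ("dynamic_trial_set", "table1_trajectories"):
        groups.append(("dynamic", metrics.REFERENCE_SAI_DYNAMIC))
    label_offset = {"static": 0, "dynamic": 500}
    for label, targets in groups:
        for i, target in enumerate(targets, start=1):
            traj = metrics.sample_tool_positions(
                target, n=1000, seed=(seed * 1000 + label_offset[label] + i) % (2**31),
                config=cfg, exact=True)
            path = out / f"{label}_trial_{i:02d}.csv"
            instrument.save_tool_script(_trajectory_to_script(traj), path)
            written.append(path)
    return written


def analyze_trajectory_files(paths, config: metrics.SAIConfig | None = None,
                             ) -> list[float]:
    """SAI of each trajectory CSV (tool-script format) under ``config``."""
    cfg = config or _default_sai_config()
    out = []
    for p in paths:
        script = instrument.load_tool_script(p)
        traj = metrics.Trajectory(script.times, script.positions)
        out.append(metrics.compute_sai(traj, cfg))
    return out


def summary_table(dynamic_sai, static_sai) -> str:
    """Plain-text per-trial + summary table for a dynamic vs. static comparison."""
    ra, rb = metrics.group_stats(dynamic_sai, static_sai)
    lines = ["Trial\tDynamic SAI\tStatic SAI"]
    for i, (d, s) in enumerate(zip(dynamic_sai, static_sai), start=1):
        lines.append(f"{i}\t{d:.3f}\t{s:.3f}")
    lines.append(f"Mean ± SD\t{ra.mean:.3f} ± {ra.sd:.3f}\t"
                 f"{rb.mean:.3f} ± {rb.sd:.3f}")
    lines.append(f"mean difference = {ra.mean_difference:.3f}, "
                 f"Welch t = {ra.t_statistic:.2f}, p = {ra.p_value:.2e}")
    return "\n".join(lines)
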