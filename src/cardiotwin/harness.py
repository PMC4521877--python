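"""Configuration, orchestration and end-to-end pipeline runs.

A :class:`RunConfig` (YAML-serializable) names the stages to run and the
per-module configurations; :func:`run_pipeline` executes the stages in
dependency order (mesh -> fibers -> ep -> ecg / beat -> personalize;
cohort is independent), writes each stage's artifacts, and records a
manifest with inputs, outputs, seeds, filled-in defaults and wall times.
The single global seed fans out to per-stage seeds by fixed offsets so a
manifest plus the package version reproduces every artifact.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from . import ecg as ecg_mod
from . import ep as ep_mod
from .cohort import CohortPriors, cohort_summary, cohort_to_dataframe, \
    sample_cohort
from .fibers import FiberRule, generate_fibers
from .geometry import AnatomyConfig, build_biventricular_mesh
from .hemodynamics import AtrialModel, HemoParameters, WindkesselParameters
from .mechanics import MechParameters, simulate_beat
from .personalize import ClinicalTargets, EPPersonalization
from ._vtk import write_vtk

log = logging.getLogger("cardiotwin")

STAGE_DEPS = {
    "mesh": (),
    "fibers": ("mesh",),
    "ep": ("fibers",),
    "ecg": ("ep",),
    "beat": ("ep",),
    "personalize": ("ecg",),
    "cohort": (),
}
# fixed per-stage seed offsets from the global seed
SEED_OFFSETS = {"mesh": 1, "ep": 2, "cohort": 3, "personalize": 4}


def _build(cls, data, stage, filled):
    """Instantiate a config dataclass from a dict, logging filled defaults."""
    data = dict(data or {})
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    for f in dataclasses.fields(cls):
        if f.name not in data:
            filled.setdefault(stage, []).append(f.name)
    for f in dataclasses.fields(cls):
        if f.name in data and isinstance(data[f.name], list):
            data[f.name] = tuple(data[f.name])
    return cls(**data)


@dataclass
class RunConfig:
    output_dir: str = "cardiotwin_run"
    seed: int = 0
    stages: tuple = ("mesh", "fibers", "ep", "ecg")
    verbosity: str = "INFO"
    anatomy: dict = field(default_factory=dict)
    fiber_rule: dict = field(default_factory=dict)
    ep: dict = field(default_factory=dict)        # EPParameters fields
    ep_run: dict = field(default_factory=dict)    # duration, dt, protocol
    torso: dict = field(default_factory=dict)
    mechanics: dict = field(default_factory=dict)
    hemodynamics: dict = field(default_factory=dict)  # wk/atrium/cycle_length
    cohort: dict = field(default_factory=dict)    # n, observations
    targets_file: str | None = None

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown RunConfig fields: {sorted(unknown)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def to_dict(self):
        return dataclasses.asdict(self)


def run_pipeline(config):
    """Execute the requested stages; returns the manifest dict."""
    logging.basicConfig(level=getattr(logging, config.verbosity, logging.INFO))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = list(config.stages)
    for s in stages:
        if s not in STAGE_DEPS:
            raise ValueError(f"unknown stage {s!r}")
        for dep in STAGE_DEPS[s]:
            if dep not in stages:
                raise ValueError(
                    f"stage {s!r} requires stage {dep!r}, which is not in "
                    f"the requested stages")
    order = [s for s in STAGE_DEPS if s in stages]

    filled = {}
    manifest = {"version": __version__, "seed": config.seed,
                "config": config.to_dict(), "stages": {}}
    ctx = {}

    for stage in order:
        t0 = time.perf_counter()
        entry = {"status": "ok", "outputs": [],
                 "seed": config.seed + SEED_OFFSETS.get(stage, 0)}
        try:
            outputs = _run_stage(stage, config, ctx, out, entry["seed"],
                                 filled)
            entry["outputs"] = outputs
        except Exception as exc:  # noqa: BLE001 - manifest records failures
            entry["status"] = f"failed: {exc}"
            log.error("stage %s failed: %s", stage, exc)
            entry["wall_time_s"] = time.perf_counter() - t0
            manifest["stages"][stage] = entry
            for later in order[order.index(stage) + 1:]:
                if stage in STAGE_DEPS[later]:
                    manifest["stages"][later] = {"status": "skipped "
                                                 f"(dependency {stage} failed)"}
            break
        entry["wall_time_s"] = time.perf_counter() - t0
        manifest["stages"][stage] = entry

    manifest["defaults_filled"] = filled
    if filled:
        log.info("defaults filled in: %s", filled)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest


def _run_stage(stage, config, ctx, out, seed, filled):
    if stage == "mesh":
        cfg = _build(AnatomyConfig, config.anatomy, "anatomy", filled)
        ctx["mesh"] = build_biventricular_mesh(cfg, seed=seed)
        path = out / "heart.vtk"
        ctx["mesh"].save(path)
        return [str(path)]

    if stage == "fibers":
        rule = _build(FiberRule, config.fiber_rule, "fiber_rule", filled)
        ctx["fibers"] = generate_fibers(ctx["mesh"], rule)
        path = out / "heart_fibers.vtk"
        mesh = ctx["mesh"]
        write_vtk(path, mesh.nodes, mesh.tets,
                  point_data={"transmural_depth": mesh.nodal_depth},
                  cell_data={"fibers": ctx["fibers"].fibers,
                             "elevation_angle_deg": ctx["fibers"].angles,
                             "element_tag": mesh.element_tags},
                  title="cardiotwin fibers; unit vectors, angles deg")
        return [str(path)]

    if stage == "ep":
        params = _build(ep_mod.EPParameters, config.ep, "ep", filled)
        run = dict(config.ep_run)
        duration = run.pop("duration", 170.0 + params.apd_estimate + 80.0)
        dt = run.pop("dt", 0.1)
        protocol_name = run.pop("protocol", "sinus")
        if run:
            raise ValueError(f"unknown ep_run fields: {sorted(run)}")
        mesh = ctx["mesh"]
        if protocol_name == "sinus":
            protocol = ep_mod.sinus_protocol(mesh)
        elif protocol_name == "crt_biv":
            protocol = ep_mod.crt_biv_protocol(
                mesh, mesh.nodes[np.argmax(mesh.nodes[:, 0])],
                mesh.nodes[np.argmin(mesh.nodes[:, 0])])
        else:
            raise ValueError(f"unknown protocol {protocol_name!r}")
        ctx["ep_params"] = params
        ctx["ep_sol"] = ep_mod.simulate_ep(mesh, ctx["fibers"], params,
                                           protocol, duration, dt=dt)
        path = out / "ep_maps.vtk"
        write_vtk(path, mesh.nodes, mesh.tets,
                  point_data={"activation_ms": ctx["ep_sol"].activation,
                              "repolarization_ms":
                                  ctx["ep_sol"].repolarization},
                  title="cardiotwin EP maps; times in ms")
        return [str(path)]

    if stage == "ecg":
        torso = ecg_mod.build_torso(
            ctx["mesh"], _build(ecg_mod.TorsoConfig, config.torso, "torso",
                                filled))
        ctx["torso"] = torso
        trace = ecg_mod.compute_ecg(ctx["ep_sol"], ctx["mesh"], ctx["fibers"],
                                    ctx["ep_params"], torso)
        feats = ecg_mod.extract_features(trace)
        ctx["ecg"] = trace
        p1 = out / "ecg.csv"
        trace.to_csv(p1)
        p2 = out / "ecg_features.json"
        with open(p2, "w") as fh:
            json.dump({"qrsd_ms": feats.qrsd, "qtd_ms": feats.qtd,
                       "ea_deg": feats.ea}, fh, indent=1)
        return [str(p1), str(p2)]

    if stage == "beat":
        mech = _build(MechParameters, config.mechanics, "mechanics", filled)
        hcfg = dict(config.hemodynamics)
        wk = _build(WindkesselParameters, hcfg.pop("wk", {}), "windkessel",
                    filled)
        atrium = _build(AtrialModel, hcfg.pop("atrium", {}), "atrium", filled)
        hemo = HemoParameters(wk=wk, atrium=atrium, **hcfg)
        _, loops = simulate_beat(ctx["mesh"], ctx["fibers"], ctx["ep_sol"],
                                 mech, hemo)
        paths = []
        for name, loop in loops.items():
            p = out / f"pvloop_{name.lower()}.csv"
            loop.to_csv(p)
            paths.append(str(p))
        return paths

    if stage == "personalize":
        if not config.targets_file:
            raise ValueError("personalize stage needs targets_file")
        targets = ClinicalTargets.from_json(config.targets_file)
        model = EPPersonalization(targets, ctx["mesh"], ctx["fibers"],
                                  ctx.get("torso"))
        result = model.fit()
        path = out / "ep_fit.json"
        result.to_json(path)
        return [str(path)]

    if stage == "cohort":
        ccfg = dict(config.cohort)
        n = ccfg.pop("n", 46)
        observations = ccfg.pop("observations", "fast")
        if ccfg:
            raise ValueError(f"unknown cohort fields: {sorted(ccfg)}")
        patients = sample_cohort(CohortPriors(), n=n, seed=seed,
                                 observations=observations)
        df = cohort_to_dataframe(patients)
        p1 = out / "cohort.csv"
        with open(p1, "w") as fh:
            fh.write("# cardiotwin virtual cohort; one row per patient; "
                     "ms/ml/mmHg/kPa/mm2_per_s units\n")
            df.to_csv(fh, index=False)
        p2 = out / "cohort_summary.csv"
        with open(p2, "w") as fh:
            fh.write("# mean (sample SD) per numeric field\n")
            cohort_summary(df).to_csv(fh, index=False)
        return [str(p1), str(p2)]

    raise ValueError(f"unknown stage {stage!r}")
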