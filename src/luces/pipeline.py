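"""End-to-end scenario runs: demand → suitability → CA → valuation → trade-offs.

A single YAML (or dict) config drives one scenario run on synthetic
inputs: generate a landscape with known ground truth, estimate the
Markov transition matrix between the two snapshot dates, project and
scenario-adjust demand, train the suitability network, validate the CA
by hindcasting the second snapshot from the first, allocate the future
map, value it, and report trade-offs/synergies between service
categories.  All randomness derives from one master seed through named
substreams, so a rerun reproduces every artifact byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import accuracy, association, ca, demand as demand_mod, suitability, synth, valuation
from .exceptions import ConfigError
from .grids import (
    CLASS_NAMES,
    CLASSES,
    ConstraintMask,
    DriverStack,
    LandUseMap,
    write_ascii_grid,
    write_drivers,
    write_landuse,
)

#: substream names in derivation order
_STREAMS = ("truth", "drivers", "evolve", "mask", "ann", "ca_validate", "ca", "perm")

DEFAULT_CONFIG = {
    "scenario": "natural_evolution",
    "seed": 0,
    "output_dir": None,
    "synthetic": {
        "shape": [64, 64],
        "n_point_sources": 3,
        "corr_length": 6.0,
        "smoothing_passes": 1,
        "constraint_fraction": 0.5,
    },
    "demand": {"steps": 1},
    "suitability": {"hidden_size": 12, "epochs": 200, "lr": 0.01, "n_samples": None},
    "ca": {"max_iter": 200, "tol": None, "cost_off_diagonal": 0.5},
    "valuation": {"grid_size": 240.0, "levels": 5},
    "association": {"n_perm": 199, "alpha": 0.05, "scheme": "queen"},
}


def derive_seeds(master: int) -> dict[str, int]:
    """Named substream seeds (< 2³¹) from one master seed."""
    out = {}
    for i, name in enumerate(_STREAMS):
        ss = np.random.SeedSequence([int(master), i])
        out[name] = int(ss.generate_state(1)[0] % 2**31)
    return out


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(source: str | Path | dict | None) -> dict:
    if source is None:
        cfg: dict = {}
    elif isinstance(source, dict):
        cfg = source
    else:
        with open(source) as fh:
            cfg = yaml.safe_load(fh) or {}
    merged = _merge(DEFAULT_CONFIG, cfg)
    if merged["scenario"] not in synth.SCENARIOS:
        raise ConfigError(f"unknown scenario {merged['scenario']!r}")
    return merged


def _scenario_cost(scenario: str, off_diagonal: float) -> ca.CostMatrix:
    cost = ca.CostMatrix.uniform(off_diagonal)
    if scenario == "cultivated_protection":
        return cost.forbid_from([1])
    if scenario == "ecological_protection":
        return cost.forbid_from([2, 4])
    return cost


def run_scenario(config: str | Path | dict | None = None) -> dict:
    """Run one scenario end-to-end; returns the artifact bundle as a dict.

    If the config names an ``output_dir``, every artifact is also
    written there (ASCII grids, CSV tables, JSON metrics) together with
    a ``manifest.json`` listing seeds, parameters and artifact hashes.
    """
    cfg = load_config(config)
    seeds = derive_seeds(cfg["seed"])
    scenario = cfg["scenario"]
    syn = cfg["synthetic"]

    drivers = synth.gen_drivers(
        tuple(syn["shape"]),
        n_point_sources=syn["n_point_sources"],
        corr_length=syn["corr_length"],
        seed=seeds["drivers"],
    )
    truth = synth.default_truth(len(drivers.names), seed=seeds["truth"])
    map_t0 = synth.gen_initial_map(drivers, truth, syn["smoothing_passes"])
    map_t1 = synth.evolve_map(map_t0, truth, seed=seeds["evolve"])

    # Markov stage
    tm = demand_mod.estimate_transition(map_t0, map_t1)
    counts_t1 = map_t1.class_counts()
    dv = demand_mod.project_demand(tm, counts_t1, steps=cfg["demand"]["steps"])
    dv = demand_mod.apply_scenario_demand(dv, scenario, counts_t1)

    mask = synth.gen_constraint_masks(
        map_t1, scenario, fraction=syn["constraint_fraction"], seed=seeds["mask"]
    )

    # suitability stage
    sut = cfg["suitability"]
    n_samples = sut["n_samples"] or min(
        20 * len(CLASSES) * len(drivers.names), map_t1.n_active
    )
    ts = suitability.sample_training(
        map_t1, drivers, n=n_samples, strategy="uniform", seed=seeds["ann"]
    )
    model = suitability.train_ann(
        ts,
        hidden_size=sut["hidden_size"],
        epochs=sut["epochs"],
        lr=sut["lr"],
        seed=seeds["ann"],
    )
    cube = suitability.predict_suitability(model, drivers)
    aucs = suitability.roc_auc_per_class(cube, map_t1)

    cost = _scenario_cost(scenario, cfg["ca"]["cost_off_diagonal"])
    weights = ca.NeighborhoodWeights()

    # hindcast validation: allocate t1 from t0 under the observed t1 demand
    val_log: list[dict] = []
    sim_t1 = ca.run_simulation(
        map_t0,
        cube,
        demand_mod.DemandVector(counts_t1),
        cost=ca.CostMatrix.uniform(cfg["ca"]["cost_off_diagonal"]),
        mask=None,
        w=weights,
        max_iter=cfg["ca"]["max_iter"],
        tol=cfg["ca"]["tol"],
        seed=seeds["ca_validate"],
        log=val_log,
    )
    metrics = {
        "overall_accuracy": accuracy.overall_accuracy(sim_t1, map_t1),
        "kappa": accuracy.kappa(sim_t1, map_t1),
        "figure_of_merit": accuracy.figure_of_merit(map_t0, map_t1, sim_t1),
        "mean_roc_auc": suitability.mean_auc(aucs),
        "roc_auc_per_class": {CLASS_NAMES[c]: aucs[c] for c in CLASSES},
    }

    # forward allocation under the scenario demand
    run_log: list[dict] = []
    sim_future = ca.run_simulation(
        map_t1,
        cube,
        dv,
        cost=cost,
        mask=mask,
        w=weights,
        max_iter=cfg["ca"]["max_iter"],
        tol=cfg["ca"]["tol"],
        seed=seeds["ca"],
        log=run_log,
    )

    # valuation stage
    table = valuation.load_coefficients()
    esv = valuation.compute_esv(sim_future, table)
    esv_cat = valuation.esv_by_category(esv, table)
    grid = valuation.compute_uesv_grid(sim_future, table, cfg["valuation"]["grid_size"])
    levels = valuation.classify_levels(grid.uesv, k=cfg["valuation"]["levels"])

    # trade-off / synergy stage
    assoc = cfg["association"]
    report = association.service_pair_report(
        grid,
        alpha=assoc["alpha"],
        n_perm=assoc["n_perm"],
        seed=seeds["perm"],
        scheme=assoc["scheme"],
    )

    bundle = {
        "config": cfg,
        "seeds": seeds,
        "drivers": drivers,
        "truth": truth,
        "map_t0": map_t0,
        "map_t1": map_t1,
        "transition": tm,
        "demand": dv,
        "mask": mask,
        "model": model,
        "cube": cube,
        "sim_t1": sim_t1,
        "sim_future": sim_future,
        "metrics": metrics,
        "esv": esv,
        "esv_by_category": esv_cat,
        "uesv_grid": grid,
        "levels": levels,
        "pair_report": report,
        "validation_log": val_log,
        "iteration_log": run_log,
    }
    if cfg["output_dir"]:
        bundle["manifest"] = write_bundle(Path(cfg["output_dir"]), bundle)
    return bundle


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_bundle(outdir: Path, bundle: dict) -> dict:
    """Write all artifacts of a scenario run and a manifest with hashes."""
    outdir.mkdir(parents=True, exist_ok=True)
    files: list[Path] = []

    def track(path: Path) -> Path:
        files.append(path)
        return path

    write_landuse(track(outdir / "map_t0.asc"), bundle["map_t0"])
    write_landuse(track(outdir / "map_t1.asc"), bundle["map_t1"])
    write_landuse(track(outdir / "sim_t1_validation.asc"), bundle["sim_t1"])
    write_landuse(track(outdir / "sim_future.asc"), bundle["sim_future"])
    files.extend(write_drivers(outdir / "drivers", bundle["drivers"]))
    write_ascii_grid(
        track(outdir / "constraint_mask.asc"),
        bundle["mask"].mask.astype(float),
        bundle["map_t0"].cell_size,
        nodata=-9999,
    )
    bundle["transition"].to_csv(track(outdir / "transition_matrix.csv"))
    bundle["demand"].to_series().to_csv(track(outdir / "demand.csv"), header=["cells"])
    for i, c in enumerate(CLASSES):
        write_ascii_grid(
            track(outdir / f"suitability_{CLASS_NAMES[c]}.asc"),
            bundle["cube"].probs[i],
            bundle["map_t0"].cell_size,
            nodata=-9999,
        )
    (outdir / "metrics.json").write_text(
        json.dumps(bundle["metrics"], indent=2, sort_keys=True)
    )
    track(outdir / "metrics.json")
    bundle["esv"].to_csv(track(outdir / "esv_per_service.csv"), header=["esv_100yuan"])
    bundle["esv_by_category"].to_csv(
        track(outdir / "esv_by_category.csv"), header=["esv_100yuan"]
    )
    bundle["uesv_grid"].to_frame().to_csv(track(outdir / "uesv_grid.csv"), index=False)
    write_ascii_grid(
        track(outdir / "uesv_levels.asc"),
        bundle["levels"].astype(float),
        bundle["uesv_grid"].grid_size,
        nodata=0,
    )
    bundle["pair_report"].to_csv(track(outdir / "pair_report.csv"), index=False)
    ca.iteration_log_frame(bundle["iteration_log"]).to_csv(
        track(outdir / "iteration_log.csv"), index=False
    )
    ca.iteration_log_frame(bundle["validation_log"]).to_csv(
        track(outdir / "validation_log.csv"), index=False
    )

    manifest = {
        "config": bundle["config"],
        "seeds": bundle["seeds"],
        "artifacts": {
            str(p.relative_to(outdir)): _sha256(p) for p in sorted(files)
        },
    }
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str)
    )
    return manifest
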