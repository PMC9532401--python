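"""End-to-end pipeline: surrogates -> eigenbasis -> observations -> MCMC ->
validation, with a manifest recording hashes and seeds of every artifact."""

from __future__ import annotations

import hashlib
import json
import os
import time
from typing import Optional

import numpy as np
import pandas as pd

from .cable.protocols import PacingProtocol
from .cable.table import generate_training_table
from .calibration.likelihood import ERPIntervalObservation
from .config import RunConfig
from .manifold.laplacian import solve_eigenproblem
from .manifold.meshio import read_mesh
from .surrogate.design import latin_hypercube
from .surrogate.polynomial import (
    fit_surrogates,
    load_surrogates,
    save_surrogates,
)
from .synthetic.fixtures import make_fixture_mesh
from .synthetic.observe import observe_erp
from .synthetic.sites import design_observation_sites
from .synthetic.truth import generate_ground_truth
from .synthetic.validate import validate
from .workflow import calibrate

__all__ = ["run_pipeline", "read_observations_csv", "write_observations_csv"]


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def read_observations_csv(path) -> list:
    df = pd.read_csv(path)
    required = {"vertex_id", "protocol", "interval_low_ms", "interval_width_ms"}
    if not required.issubset(df.columns):
        raise ValueError(f"observations CSV must have columns {sorted(required)}")
    return [
        ERPIntervalObservation(
            vertex=int(r.vertex_id),
            protocol=str(r.protocol),
            interval_low=float(r.interval_low_ms),
            interval_width=float(r.interval_width_ms),
        )
        for r in df.itertuples()
    ]


def write_observations_csv(observations, path) -> None:
    pd.DataFrame(
        [
            {
                "vertex_id": o.vertex,
                "protocol": o.protocol,
                "interval_low_ms": o.interval_low,
                "interval_width_ms": o.interval_width,
            }
            for o in observations
        ]
    ).to_csv(path, index=False)


def run_pipeline(cfg: RunConfig, *, progress: bool = True) -> dict:
    """Execute the staged workflow; halts with the stage name on failure and
    persists partial outputs.  Returns the manifest (also written to disk)."""
    os.makedirs(cfg.output_dir, exist_ok=True)
    manifest = {
        "config": json.loads(cfg.to_json()),
        "stages": [],
        "artifacts": {},
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }

    def log(msg):
        if progress:
            print(f"[pipeline] {msg}", flush=True)

    def artifact(name, path):
        manifest["artifacts"][name] = {"path": path, "sha256": _sha256(path)}

    def stage(name):
        manifest["stages"].append(name)
        log(f"stage: {name}")

    def fail(name, exc):
        manifest["failed_stage"] = name
        manifest["error"] = str(exc)
        with open(os.path.join(cfg.output_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # -- surrogates ---------------------------------------------------------
    try:
        stage("fit-surrogates")
        if cfg.surrogates_json:
            f1, f2 = load_surrogates(cfg.surrogates_json)
        else:
            design = latin_hypercube(
                cfg.design_size,
                [[0.1, 1.5], [1.0, 30.0], [120.0, 270.0]],
                seed=cfg.design_seed,
            )
            table = generate_training_table(
                design,
                s1s2=PacingProtocol(kind="S1S2", s1_interval=cfg.s1_interval,
                                    n_s1=cfg.n_s1),
                s1s2s3=PacingProtocol(kind="S1S2S3", s1_interval=cfg.s1_interval,
                                      s2_interval=cfg.s2_interval, n_s1=cfg.n_s1),
            )
            tpath = os.path.join(cfg.output_dir, "training_table.csv")
            table.to_csv(tpath, index=False)
            artifact("training_table", tpath)
            f1, f2 = fit_surrogates(table)
        spath = os.path.join(cfg.output_dir, "surrogates.json")
        save_surrogates(spath, f1, f2)
        artifact("surrogates", spath)
    except Exception as exc:
        fail("fit-surrogates", exc)

    # -- mesh + eigenbasis --------------------------------------------------
    try:
        stage("eigenbasis")
        if cfg.mesh_path:
            mesh = read_mesh(cfg.mesh_path)
        else:
            mesh = make_fixture_mesh(
                cfg.fixture_kind, cfg.fixture_edge_mm, scale=cfg.fixture_scale_mm
            )
        K = min(cfg.n_eigenfunctions, mesh.n_vertices - 2)
        basis = solve_eigenproblem(mesh, K)
        bpath = os.path.join(cfg.output_dir, "eigenbasis.npz")
        basis.save(bpath)
        artifact("eigenbasis", bpath)
    except Exception as exc:
        fail("eigenbasis", exc)

    # -- observations (load or synthesize) ----------------------------------
    scenario = None
    try:
        if cfg.observations_csv:
            stage("load-observations")
            observations = read_observations_csv(cfg.observations_csv)
        else:
            stage("make-truth")
            scenario = generate_ground_truth(
                mesh, cfg.truth_lengthscale, cfg.truth_seed, f1, f2, basis=basis
            )
            stage("observe")
            design = design_observation_sites(
                mesh,
                cfg.n_observation_sites,
                exclusion_radius=cfg.boundary_exclusion_mm,
                seed=cfg.site_seed,
            )
            observations = observe_erp(
                scenario, design, cfg.observation_resolution
            )
        opath = os.path.join(cfg.output_dir, "observations.csv")
        write_observations_csv(observations, opath)
        artifact("observations", opath)
    except Exception as exc:
        fail("observations", exc)

    # -- calibration --------------------------------------------------------
    try:
        stage("calibrate")
        samples, model, fields = calibrate(
            observations,
            basis,
            f1,
            f2,
            cfg.mcmc_config(),
            K=cfg.calibration_K,
            kernel_family=cfg.kernel_family,
            bracket_pad=cfg.bracket_pad,
        )
        draws_path = os.path.join(cfg.output_dir, "posterior_draws.csv")
        cols = (
            ["m1", "m2", "log_alpha1", "log_alpha2", "log_rho1", "log_rho2"]
            + [f"eta1_{k}" for k in range(model.K)]
            + [f"eta2_{k}" for k in range(model.K)]
        )
        dd = pd.DataFrame(samples.draws, columns=cols)
        dd.insert(0, "chain", samples.chain_ids)
        dd.insert(1, "log_posterior", samples.log_posteriors)
        dd.to_csv(draws_path, index=False)
        artifact("posterior_draws", draws_path)

        summ = fields.summaries()
        sdf = pd.DataFrame(
            {
                "tau_out_mean": summ["tau_out"]["mean"],
                "tau_out_sd": summ["tau_out"]["sd"],
                "apd_max_mean": summ["apd_max"]["mean"],
                "apd_max_sd": summ["apd_max"]["sd"],
            }
        )
        spath2 = os.path.join(cfg.output_dir, "field_summaries.csv")
        sdf.to_csv(spath2, index_label="vertex_id")
        artifact("field_summaries", spath2)
        manifest["mcmc"] = {
            "n_retained": int(samples.n_retained),
            "divergences": int(samples.diagnostics["divergences"]),
            "max_split_rhat": float(
                np.nanmax(samples.diagnostics["split_rhat"])
            ),
        }
    except Exception as exc:
        fail("calibrate", exc)

    # -- validation (only when truth is available) ---------------------------
    if scenario is not None:
        try:
            stage("validate")
            metrics = validate(scenario, fields, f1, f2)
            manifest["validation"] = {
                "rmse_map": metrics.rmse_map,
                "rmse_mean": metrics.rmse_mean,
                "ise_below_3": metrics.ise_below_3,
            }
        except Exception as exc:
            fail("validate", exc)

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    mpath = os.path.join(cfg.output_dir, "manifest.json")
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    log(f"manifest written to {mpath}")
    return manifest
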