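"""End-to-end pipeline: trajectories → microstates → validated MSM →
macrostates → unfolding pathways and passage times → per-state reports.

``run_pipeline`` orchestrates the stages in order, persists every stage's
output as plain-text artifacts under an output directory, and writes a run log
(seed, parameters, package versions). The default configuration runs the
packaged toy unfolding simulator, so the whole analysis is reproducible from a
single seed with no external data.
"""

from __future__ import annotations

import json
import sys
from copy import deepcopy
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cluster import RMSDMetric, assign, k_centers, pool_frames
from .discrete import save_discrete_trajectories
from .featurize import (Trajectory, read_structure, read_trajectory,
                        write_structure, write_trajectory)
from .lumping import coarse_grain, coarse_model, pcca_plus, spectral_gap_report
from .msm import (count_transitions, estimate_transition_matrix,
                  implied_timescales, residence_probability)
from .report import export_network, hbonds_to_frame, summaries_to_frame, summarize_states
from .synthetic import ToyLandscape, generate_toy_unfolding_trajectories
from .tpt import committors, mfpt, pathway_edge_times, reactive_flux, top_pathways

__all__ = ["default_config", "run_pipeline", "load_config"]


def default_config() -> dict:
    """Baseline configuration: toy-unfolding input, three macrostates."""
    return {
        "input": {
            "kind": "toy",              # "toy" or "pdb"
            "paths": [],                 # multi-model PDB files when kind == "pdb"
            "frame_interval": 1.0,       # physical time between frames (pdb input)
            "n_traj": 31,
            "n_steps": 150000,
            "save_stride": 750,
            "barrier_height": 12.0,
            "kT": 0.005,
        },
        "cluster": {
            # "all" suits the one-bead-per-residue toy model; use "backbone"
            # for all-atom nucleic-acid input
            "selection": "all",
            "cutoff": None,
            "k": 40,
        },
        "msm": {
            "lag": 2,
            "reversible": True,
            "its_lags": [1, 2, 3, 4, 6, 8],
            "n_timescales": 5,
        },
        "validate": {
            "horizons": [0, 1, 2, 4, 8],
            "n_macro_top": 3,
        },
        "lump": {
            "n_macro": 3,
        },
        "tpt": {
            "source": "auto",            # macrostate indices, or "auto" (folded = most compact)
            "target": "auto",
            "n_pathways": 4,
        },
        "report": {
            "n_samples": 100,
            "rmsd_selections": {"backbone": "all"},
            "distance_pairs": [["G1", "G15"], ["G2", "G14"], ["G6", "G10"], ["G1", "C"]],
            "edge_floor": 1e-4,
        },
    }


def load_config(path: str | Path) -> dict:
    """Read a YAML config and merge it over the defaults (section-wise)."""
    cfg = default_config()
    user = yaml.safe_load(Path(path).read_text()) or {}
    for section, values in user.items():
        cfg.setdefault(section, {}).update(values or {})
    return cfg


def _load_input(cfg: dict, seed: int, outdir: Path) -> list[Trajectory]:
    sec = cfg["input"]
    if sec["kind"] == "pdb":
        if not sec["paths"]:
            raise ValueError("input.paths must list multi-model PDB files")
        return [read_trajectory(p, frame_interval=sec["frame_interval"])
                for p in sec["paths"]]
    landscape = ToyLandscape(barrier_height=sec["barrier_height"], kT=sec["kT"])
    trajs = generate_toy_unfolding_trajectories(
        landscape, n_traj=sec["n_traj"], n_steps=sec["n_steps"],
        save_stride=sec["save_stride"], seed=seed)
    return trajs


def _auto_endpoint_states(summaries, mode: str) -> list[int]:
    """Pick the most compact (folded) or most extended (unfolded) macrostate
    by mean backbone RMSD against the reference."""
    key = lambda s: s.rmsd_stats["backbone"][0]
    ordered = sorted(summaries, key=key)
    return [ordered[0].macrostate] if mode == "folded" else [ordered[-1].macrostate]


def run_pipeline(config: Optional[dict] = None,
                 outdir: str | Path = "quadmsm_run",
                 seed: int = 0) -> dict:
    """Run every stage and persist all artifacts; returns the in-memory
    results keyed by stage.

    Stage failures raise with the stage name and the offending input attached.
    """
    cfg = deepcopy(config) if config else default_config()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    results: dict = {"config": cfg, "seed": seed}
    stage = "input"
    try:
        trajs = _load_input(cfg, seed, outdir)
        results["trajectories"] = trajs
        reference = trajs[0].frame(0) if cfg["input"]["kind"] == "toy" else \
            read_structure(cfg["input"]["paths"][0], model=1)
        # toy input: reference = folded template rendering (frame 0 of walker 0,
        # which starts at the folded end of the seed spread)
        write_structure(reference, outdir / "reference.pdb")

        stage = "cluster"
        frames, origins = pool_frames(trajs)
        metric = RMSDMetric(trajs[0].frame(0), cfg["cluster"]["selection"])
        model_c = k_centers(frames, metric, cutoff=cfg["cluster"]["cutoff"],
                            k=cfg["cluster"]["k"], origins=origins)
        dtrajs = assign(trajs, model_c, metric)
        model_c.save_manifest(outdir / "cluster_manifest.json")
        save_discrete_trajectories(dtrajs, outdir / "dtrajs")
        results["cluster"] = model_c
        results["dtrajs"] = dtrajs

        stage = "msm"
        counts = count_transitions(dtrajs, lag=cfg["msm"]["lag"])
        model = estimate_transition_matrix(counts, reversible=cfg["msm"]["reversible"])
        np.savetxt(outdir / "count_matrix.txt", counts.counts,
                   header=f"lag_frames={counts.lag} lag_time={counts.lag_time}")
        np.savetxt(outdir / "transition_matrix.txt", model.T,
                   header=f"lag_frames={model.lag} lag_time={model.lag_time} "
                          f"active={','.join(map(str, model.active))}")
        np.savetxt(outdir / "stationary.txt", model.pi)
        results["counts"] = counts
        results["model"] = model

        stage = "validate"
        its = implied_timescales(dtrajs, cfg["msm"]["its_lags"],
                                 n_timescales=cfg["msm"]["n_timescales"],
                                 reversible=cfg["msm"]["reversible"])
        its.to_csv(outdir / "implied_timescales.csv")
        results["implied_timescales"] = its

        stage = "lump"
        macro = pcca_plus(model, n_macro=cfg["lump"]["n_macro"])
        P, W, edges = coarse_grain(model, macro, edge_floor=0.0)
        gaps = spectral_gap_report(model)
        gaps.to_csv(outdir / "spectral_gaps.csv")
        np.savetxt(outdir / "membership.txt", macro.chi,
                   header="PCCA+ fuzzy memberships, one row per microstate")
        pd.DataFrame({"microstate": macro.micro_labels,
                      "macrostate": macro.assignment}).to_csv(
            outdir / "macro_assignment.csv", index=False)
        np.savetxt(outdir / "coarse_transition_matrix.txt", W,
                   header=f"lag_time={model.lag_time}")
        results["macro"] = macro
        results["coarse"] = (P, W)

        stage = "validate-residence"
        resid = residence_probability(dtrajs, macro.assignment_by_label(), model,
                                      horizons=cfg["validate"]["horizons"])
        resid.to_csv(outdir / "residence_probability.csv", index=False)
        results["residence"] = resid

        stage = "report"
        rmsd_sel = cfg["report"].get("rmsd_selections", {"backbone": "backbone"})
        pairs = [tuple(p) for p in cfg["report"]["distance_pairs"]]
        summaries = summarize_states(trajs, dtrajs, macro, reference,
                                     rmsd_selections=rmsd_sel,
                                     distance_pairs=pairs,
                                     n_samples=cfg["report"]["n_samples"],
                                     seed=seed)
        summaries_to_frame(summaries).to_csv(outdir / "state_summaries.csv", index=False)
        hb = hbonds_to_frame(summaries)
        hb.to_csv(outdir / "hbond_occupancy.csv", index=False)
        for s in summaries:
            ti, fi = s.representative
            write_structure(trajs[ti].frame(fi),
                            outdir / f"representative_state{s.macrostate}.pdb")
        results["summaries"] = summaries

        stage = "tpt"
        cmodel = coarse_model(model, macro)
        if cfg["tpt"]["source"] == "auto":
            A = _auto_endpoint_states(summaries, "folded")
        else:
            A = list(cfg["tpt"]["source"])
        if cfg["tpt"]["target"] == "auto":
            B = _auto_endpoint_states(summaries, "unfolded")
        else:
            B = list(cfg["tpt"]["target"])
        comm = committors(cmodel, A, B)
        flux = reactive_flux(cmodel, comm)
        paths = top_pathways(flux, K=cfg["tpt"]["n_pathways"])
        mf = mfpt(cmodel, B)
        np.savetxt(outdir / "committors.txt",
                   np.column_stack([comm.q_forward, comm.q_backward]),
                   header="q_forward q_backward (macrostate rows)")
        np.savetxt(outdir / "net_flux.txt", flux.net,
                   header=f"total_flux={flux.total_flux}")
        with open(outdir / "pathways.txt", "w") as fh:
            fh.write("# rank\tpath\tflux\tfraction\n")
            for r, p in enumerate(paths, 1):
                fh.write(f"{r}\t{p.label()}\t{p.flux:.6e}\t{p.fraction:.4f}\n")
        np.savetxt(outdir / "mfpt.txt", mf.times,
                   header=f"MFPT to {list(B)} in units of lag_time={mf.lag_time}")
        results["committors"] = comm
        results["flux"] = flux
        results["pathways"] = paths
        results["mfpt"] = mf
        results["endpoints"] = (A, B)
        if paths:
            results["edge_times"] = pathway_edge_times(cmodel, paths[0])

        stage = "network-export"
        node_attrs = {s.macrostate: {"rmsd": s.rmsd_stats["backbone"][0]}
                      for s in summaries}
        export_network(P, W, node_attrs, outdir / "network.graphml",
                       edge_floor=cfg["report"]["edge_floor"])

        stage = "log"
        log = {
            "package": "quadmsm",
            "version": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "seed": seed,
            "config": cfg,
            "n_microstates": model_c.n_centers,
            "n_active": int(model.n_states),
            "n_macrostates": int(macro.n_macro),
            "endpoints": {"source": list(map(int, A)), "target": list(map(int, B))},
        }
        (outdir / "run_log.yaml").write_text(yaml.safe_dump(log, sort_keys=False))
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    return results
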