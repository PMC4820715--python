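"""Per-macrostate structural summaries and transition-network export.

``summarize_states`` reproduces the shape of per-state characterization
tables: population, mean ± sd backbone and per-loop RMSD against a reference
structure, mean ± sd of configured residue-center distances, hydrogen-bond
occupancies, and a representative conformation (the member closest to the
cluster-average structure) — all over a fixed-seed subsample of member frames
(100 by default). ``export_network`` writes the macrostate transition network
as GraphML (and GEXF) with population / RMSD node attributes and weighted
edges, ready for external graph layout tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx

from .cluster import representative_conformation
from .discrete import DiscreteTrajectory
from .featurize import (HBondRecord, SelectionLike, Structure, Trajectory,
                        centroid_distances, hbond_occupancy, kabsch_superpose)
from .lumping import MacroModel
from .msm import MarkovModel

__all__ = ["StateSummary", "summarize_states", "export_network"]


@dataclass
class StateSummary:
    """Structural characterization of one macrostate."""

    macrostate: int
    population: float
    n_members: int
    n_sampled: int
    rmsd_stats: dict[str, tuple[float, float]]       # name -> (mean, sd) in Å
    distance_stats: dict[str, tuple[float, float]]   # "G1-G15" -> (mean, sd) in Å
    hbonds: list[HBondRecord]
    representative: tuple[int, int]                   # (trajectory, frame)
    used_all_members: bool = False

    def to_row(self) -> dict:
        row = {"macrostate": self.macrostate, "population": self.population,
               "n_members": self.n_members, "n_sampled": self.n_sampled}
        for k, (m, s) in self.rmsd_stats.items():
            row[f"rmsd_{k}_mean"] = m
            row[f"rmsd_{k}_sd"] = s
        for k, (m, s) in self.distance_stats.items():
            row[f"dist_{k}_mean"] = m
            row[f"dist_{k}_sd"] = s
        return row


def _macro_frame_index(dtrajs: Sequence[DiscreteTrajectory],
                       macro: MacroModel) -> dict[int, list[tuple[int, int]]]:
    label_to_macro = macro.assignment_by_label()
    frames: dict[int, list[tuple[int, int]]] = {m: [] for m in range(macro.n_macro)}
    for ti, dt in enumerate(dtrajs):
        for fi, s in enumerate(dt.states):
            m = label_to_macro.get(int(s))
            if m is not None:
                frames[m].append((ti, fi))
    return frames


def summarize_states(trajs: Sequence[Trajectory],
                     dtrajs: Sequence[DiscreteTrajectory],
                     macro: MacroModel,
                     reference: Structure,
                     rmsd_selections: Optional[dict[str, SelectionLike]] = None,
                     distance_pairs: Optional[Sequence[tuple[str, str]]] = None,
                     hbond_params: Optional[dict] = None,
                     n_samples: int = 100,
                     seed: int = 0) -> list[StateSummary]:
    """Structural summary of every non-empty macrostate.

    ``n_samples`` member frames per macrostate are drawn uniformly without
    replacement with a fixed seed (all members if fewer, flagged on the
    summary). Empty macrostates are omitted with a warning on stderr.
    """
    import sys

    rmsd_selections = rmsd_selections or {"backbone": "backbone"}
    distance_pairs = list(distance_pairs or [])
    hbond_params = hbond_params or {}
    rng = np.random.default_rng(seed)
    frames_by_macro = _macro_frame_index(dtrajs, macro)
    out = []
    for m in range(macro.n_macro):
        members = frames_by_macro[m]
        if not members:
            print(f"warning: macrostate {m} has no member frames; omitted",
                  file=sys.stderr)
            continue
        if len(members) > n_samples:
            pick = rng.choice(len(members), size=n_samples, replace=False)
            sample = [members[i] for i in sorted(pick)]
            used_all = False
        else:
            sample = members
            used_all = True
        structures = [trajs[ti].frame(fi) for ti, fi in sample]
        rmsd_stats = {}
        for name, sel in rmsd_selections.items():
            vals = np.array([kabsch_superpose(s, reference, sel)[2] for s in structures])
            rmsd_stats[name] = (float(vals.mean()), float(vals.std(ddof=0)))
        distance_stats = {}
        if distance_pairs:
            tables = [centroid_distances(s, distance_pairs) for s in structures]
            arr = np.array([t["distance"].to_numpy() for t in tables])
            for j, (a, b) in enumerate(distance_pairs):
                distance_stats[f"{a}-{b}"] = (float(arr[:, j].mean()),
                                              float(arr[:, j].std(ddof=0)))
        hbonds = hbond_occupancy(structures, **hbond_params)
        rep_local = representative_conformation(structures)
        rep = sample[next(i for i, s in enumerate(structures) if s is rep_local)]
        out.append(StateSummary(
            macrostate=m, population=float(macro.populations[m]),
            n_members=len(members), n_sampled=len(sample),
            rmsd_stats=rmsd_stats, distance_stats=distance_stats,
            hbonds=hbonds, representative=rep, used_all_members=used_all))
    return out


def export_network(populations: np.ndarray,
                   weights: np.ndarray,
                   node_attrs: Optional[dict[int, dict]] = None,
                   path: str | Path = "network.graphml",
                   edge_floor: float = 0.0,
                   write_gexf: bool = True) -> Path:
    """Write the macrostate transition network as GraphML (and GEXF).

    Nodes carry ``population``, a ``label`` and any extra attributes supplied
    (e.g. mean backbone RMSD); edges carry the coarse transition weight and
    appear only above ``edge_floor``. Attributes must cover every node.
    """
    n = len(populations)
    node_attrs = node_attrs or {}
    missing = [i for i in node_attrs if i not in range(n)]
    if missing:
        raise ValueError(f"attributes given for unknown nodes: {missing}")
    G = nx.DiGraph()
    for i in range(n):
        attrs = {"population": float(populations[i]), "label": str(i)}
        for k, v in node_attrs.get(i, {}).items():
            attrs[k] = float(v) if isinstance(v, (int, float, np.floating)) else str(v)
        G.add_node(str(i), **attrs)
    for i in range(n):
        for j in range(n):
            if i != j and weights[i, j] > edge_floor:
                G.add_edge(str(i), str(j), weight=float(weights[i, j]))
    path = Path(path)
    nx.write_graphml(G, path)
    if write_gexf:
        nx.write_gexf(G, path.with_suffix(".gexf"))
    return path


def summaries_to_frame(summaries: Sequence[StateSummary]) -> pd.DataFrame:
    """Flat per-state table of populations, RMSD and distance statistics."""
    return pd.DataFrame([s.to_row() for s in summaries])


def hbonds_to_frame(summaries: Sequence[StateSummary]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        for hb in s.hbonds:
            rows.append({"macrostate": s.macrostate, "bond": hb.label,
                         "occupancy_percent": hb.occupancy})
    return pd.DataFrame(rows)
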