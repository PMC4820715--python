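"""k-centers microstate clustering under the RMSD metric.

The greedy farthest-point (k-centers) algorithm discretizes a pooled ensemble
of conformational frames into microstates, either down to a distance cutoff
(every frame within ``cutoff`` of its center) or to a fixed number of centers.
The metric is pluggable: the default is backbone Kabsch RMSD, but any symmetric
non-negative pairwise function works, which is how 1-D toy metrics are used in
tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import json
import numpy as np

from .discrete import DiscreteTrajectory
from .featurize import (SelectionLike, Structure, Trajectory, _batch_rmsd,
                        kabsch_superpose, make_selection)

__all__ = [
    "ClusterModel",
    "RMSDMetric",
    "ScalarMetric",
    "pool_frames",
    "k_centers",
    "assign",
    "representative_conformation",
]


class RMSDMetric:
    """Backbone (or custom-selection) superposition RMSD between frames.

    Frames are coordinate arrays of shape ``(n_atoms, 3)``; ``one_to_many``
    computes minimum RMSD of one frame against a stack in a single batched
    Kabsch pass.
    """

    name = "rmsd"

    def __init__(self, template: Structure, selection: SelectionLike = "backbone"):
        self.mask = make_selection(selection)(template)
        if self.mask.sum() < 3:
            raise ValueError("metric selection must keep at least 3 atoms")

    def one_to_many(self, frame: np.ndarray, stack: np.ndarray) -> np.ndarray:
        return _batch_rmsd(frame[self.mask], stack[:, self.mask, :])

    def __call__(self, a: np.ndarray, b: np.ndarray) -> float:
        return float(self.one_to_many(a, b[None])[0])


class ScalarMetric:
    """Absolute difference between scalar frames (toy 1-D metric)."""

    name = "scalar"

    def one_to_many(self, frame, stack) -> np.ndarray:
        return np.abs(np.asarray(stack, dtype=float) - float(frame))

    def __call__(self, a, b) -> float:
        return abs(float(a) - float(b))


def _distances_to(metric, frame, frames) -> np.ndarray:
    if hasattr(metric, "one_to_many"):
        return np.asarray(metric.one_to_many(frame, frames), dtype=float)
    return np.array([metric(frame, f) for f in frames], dtype=float)


@dataclass
class ClusterModel:
    """Result of k-centers clustering over a pooled frame ensemble."""

    center_indices: list[int]               # indices into the pooled ensemble
    center_origin: list[tuple[int, int]]    # (trajectory index, frame index)
    centers: list                            # center frame payloads
    metric_name: str
    cutoff: Optional[float] = None
    k: Optional[int] = None
    max_center_distance: float = 0.0

    @property
    def n_centers(self) -> int:
        return len(self.center_indices)

    def save_manifest(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "metric": self.metric_name,
            "cutoff": self.cutoff,
            "k": self.k,
            "max_center_distance": self.max_center_distance,
            "centers": [{"pooled_index": int(i), "trajectory": int(t), "frame": int(f)}
                        for i, (t, f) in zip(self.center_indices, self.center_origin)],
        }
        path.write_text(json.dumps(payload, indent=2))
        return path


def pool_frames(trajs: Sequence[Trajectory]) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Concatenate trajectory frames in file order then frame order.

    The pooling order fixes center identity, so it is part of the contract.
    Returns the stacked coordinates and the (trajectory, frame) origin of each
    pooled index.
    """
    coords = np.concatenate([t.coords for t in trajs], axis=0)
    origins = [(ti, fi) for ti, t in enumerate(trajs) for fi in range(t.n_frames)]
    return coords, origins


def k_centers(frames: Sequence | np.ndarray,
              metric,
              cutoff: Optional[float] = None,
              k: Optional[int] = None,
              origins: Optional[list[tuple[int, int]]] = None,
              initial: int = 0) -> ClusterModel:
    """Greedy farthest-point clustering of a pooled frame ensemble.

    The first center is the designated initial frame (frame 0 of the pooled
    ensemble by default); each round adds the frame farthest from all existing
    centers, until the maximum distance drops to ``cutoff`` (cutoff mode) or
    ``k`` centers exist (k mode). Exactly one of ``cutoff`` / ``k`` must be
    given. Ties in the farthest-frame search resolve to the lowest pooled
    index, making the procedure fully deterministic.
    """
    n = len(frames)
    if n < 1:
        raise ValueError("need at least one frame")
    if (cutoff is None) == (k is None):
        raise ValueError("give exactly one of cutoff or k")
    if cutoff is not None and cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if k is not None and (k < 1 or k > n):
        raise ValueError("k must lie in [1, number of frames]")
    centers = [initial]
    dmin = _distances_to(metric, frames[initial], frames)
    while True:
        far = int(np.argmax(dmin))  # argmax takes the lowest index on ties
        dmax = float(dmin[far])
        if cutoff is not None and dmax <= cutoff:
            break
        if k is not None and len(centers) >= k:
            break
        if dmax == 0.0:
            break  # all remaining frames coincide with existing centers
        centers.append(far)
        dmin = np.minimum(dmin, _distances_to(metric, frames[far], frames))
    origins = origins or [(0, i) for i in range(n)]
    return ClusterModel(
        center_indices=centers,
        center_origin=[origins[c] for c in centers],
        centers=[frames[c] for c in centers],
        metric_name=getattr(metric, "name", getattr(metric, "__name__", "custom")),
        cutoff=cutoff,
        k=k,
        max_center_distance=float(dmin.max()),
    )


def assign(trajs_or_frames, model: ClusterModel, metric,
           frame_interval: Optional[float] = None) -> list[DiscreteTrajectory]:
    """Map every frame to its nearest center; ties go to the lowest center index.

    Accepts either a list of :class:`Trajectory` (one discrete trajectory per
    input trajectory) or a flat frame sequence (returned as one discrete
    trajectory).
    """
    if len(trajs_or_frames) and isinstance(trajs_or_frames[0], Trajectory):
        groups = [(t.coords, t.frame_interval) for t in trajs_or_frames]
    else:
        groups = [(trajs_or_frames, frame_interval or 1.0)]
    out = []
    for frames, interval in groups:
        nf = len(frames)
        d = np.empty((model.n_centers, nf))
        for ci, c in enumerate(model.centers):
            d[ci] = _distances_to(metric, c, frames)
        labels = np.argmin(d, axis=0)  # argmin resolves ties to the lowest index
        out.append(DiscreteTrajectory(labels, frame_interval=interval))
    return out


def representative_conformation(members: Sequence[Structure]) -> Structure:
    """The member with the lowest RMSD to the cluster-average structure.

    All members are superposed onto the first member, the mean structure is
    taken over the superposed coordinates, and the member minimizing RMSD to
    that mean is returned.
    """
    if len(members) == 0:
        raise ValueError("cluster has no members")
    if len(members) == 1:
        return members[0]
    ref = members[0]
    superposed = [ref.coords]
    for m in members[1:]:
        R, t, _ = kabsch_superpose(m, ref, selection=None)
        superposed.append(m.coords @ R.T + t)
    mean_coords = np.mean(superposed, axis=0)
    mean_struct = ref.with_coords(mean_coords)
    rmsds = [kabsch_superpose(m, mean_struct, selection=None)[2] for m in members]
    return members[int(np.argmin(rmsds))]
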