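"""Discretized (microstate-labelled) trajectories.

A :class:`DiscreteTrajectory` holds the per-frame state labels ``s(t)`` obtained
either by clustering conformational frames or by sampling a ground-truth chain.
Labels are non-negative integers; the frame interval carries the physical time
between consecutive labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["DiscreteTrajectory", "save_discrete_trajectories", "load_discrete_trajectories"]


@dataclass
class DiscreteTrajectory:
    """Per-frame microstate labels for one trajectory.

    Parameters
    ----------
    states
        Integer state label per frame, shape ``(n_frames,)``.
    frame_interval
        Physical time between consecutive frames (same unit across an ensemble;
        nanoseconds for the aptamer data this package models).
    """

    states: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValueError("states must be a 1-D integer sequence")
        if self.states.size and self.states.min() < 0:
            raise ValueError("state labels must be non-negative")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    def __len__(self) -> int:
        return int(self.states.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiscreteTrajectory):
            return NotImplemented
        return (
            self.frame_interval == other.frame_interval
            and np.array_equal(self.states, other.states)
        )


def save_discrete_trajectories(dtrajs: list[DiscreteTrajectory], directory: str | Path,
                               prefix: str = "dtraj") -> list[Path]:
    """Write one plain-text file per trajectory, one integer label per line."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, dt in enumerate(dtrajs):
        p = directory / f"{prefix}_{i:04d}.txt"
        np.savetxt(p, dt.states, fmt="%d", header=f"frame_interval={dt.frame_interval}")
        paths.append(p)
    return paths


def load_discrete_trajectories(paths: list[str | Path]) -> list[DiscreteTrajectory]:
    """Read trajectories written by :func:`save_discrete_trajectories`."""
    out = []
    for p in paths:
        p = Path(p)
        interval = 1.0
        with open(p) as fh:
            first = fh.readline()
        if first.startswith("#") and "frame_interval=" in first:
            interval = float(first.split("frame_interval=")[1])
        states = np.loadtxt(p, dtype=np.int64, ndmin=1)
        out.append(DiscreteTrajectory(states, frame_interval=interval))
    return out
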