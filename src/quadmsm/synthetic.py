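"""Synthetic ground truth for testing the unfolding-analysis pipeline.

Two generators live here:

* :func:`build_metastable_chain` plants a block-structured, reversible Markov
  chain (macrostate blocks joined by weak links) whose transition matrix and
  stationary distribution are known exactly, so estimator, lumping, committor
  and passage-time code can be tested against ground truth.
* :func:`generate_toy_unfolding_trajectories` integrates overdamped Brownian
  walkers on a triple-well reaction-coordinate potential and renders each saved
  position as a 15-bead structure interpolating between a compact (folded) and
  an extended template. The landscape mimics the topology of a quadruplex
  unfolding network: a folded basin and an unfolded basin bridged by a
  low-population connector well.

All randomness flows from explicit per-call seeds; no global state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .discrete import DiscreteTrajectory
from .featurize import Trajectory

__all__ = [
    "GroundTruthChain",
    "ToyLandscape",
    "build_metastable_chain",
    "sample_discrete_trajectories",
    "generate_toy_unfolding_trajectories",
    "simulate_reaction_coordinate",
    "save_chain",
]

#: 5'->3' sequence of the thrombin-binding aptamer, used to label toy beads.
TBA_SEQUENCE = "GGTTGGTGTGGTTGG"


@dataclass
class GroundTruthChain:
    """A planted Markov chain with known macrostate block structure."""

    n_states: int
    transition_matrix: np.ndarray
    stationary: np.ndarray
    block_labels: np.ndarray
    lag_unit: float = 1.0  # physical time per chain step (ns)

    def __post_init__(self) -> None:
        T = np.asarray(self.transition_matrix, dtype=float)
        pi = np.asarray(self.stationary, dtype=float)
        if T.shape != (self.n_states, self.n_states):
            raise ValueError("transition matrix shape mismatch")
        if np.any(T < 0) or np.any(T > 1):
            raise ValueError("transition probabilities must lie in [0, 1]")
        if not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("rows of the transition matrix must sum to 1")
        if not np.allclose(pi @ T, pi, atol=1e-10):
            raise ValueError("stationary vector does not satisfy pi @ T = pi")
        self.transition_matrix = T
        self.stationary = pi
        self.block_labels = np.asarray(self.block_labels, dtype=np.int64)


def build_metastable_chain(n_macro: int,
                           n_micro_per_macro: int,
                           intra_p: float,
                           inter_p: float,
                           seed: int = 0,
                           jitter: float = 0.0,
                           block_sizes: Optional[Sequence[int]] = None,
                           lag_unit: float = 1.0) -> GroundTruthChain:
    """Plant a reversible block chain: dense blocks, weak links between
    adjacent blocks.

    A symmetric weight matrix ``W`` is built with entry ``intra_p`` for every
    pair inside a block (including the diagonal) and ``inter_p`` for every pair
    across adjacent blocks, optionally perturbed by symmetric multiplicative
    jitter, then row-normalized. Row-normalizing a symmetric ``W`` yields a
    reversible chain whose stationary distribution is proportional to the row
    sums — both are attached as ground truth.

    ``block_sizes`` overrides the uniform ``n_macro × n_micro_per_macro``
    layout with explicit block sizes (e.g. ``[11, 10, 11]``).
    """
    if n_macro < 2:
        raise ValueError("need at least 2 macrostate blocks")
    if not (intra_p > inter_p > 0):
        raise ValueError("require intra_p > inter_p > 0")
    if jitter < 0 or jitter >= 1:
        raise ValueError("jitter must lie in [0, 1)")
    sizes = list(block_sizes) if block_sizes is not None else [n_micro_per_macro] * n_macro
    if len(sizes) != n_macro or any(s < 1 for s in sizes):
        raise ValueError("block_sizes must give a positive size per macrostate")
    labels = np.concatenate([np.full(s, b, dtype=np.int64) for b, s in enumerate(sizes)])
    n = labels.size
    same = labels[:, None] == labels[None, :]
    adjacent = np.abs(labels[:, None] - labels[None, :]) == 1
    W = np.where(same, intra_p, 0.0) + np.where(adjacent, inter_p, 0.0)
    if jitter > 0:
        rng = np.random.default_rng(seed)
        U = rng.uniform(-1.0, 1.0, size=(n, n))
        U = (U + U.T) / 2.0
        W = W * (1.0 + jitter * U)
    if np.any(W < 0):
        raise ValueError("jittered weights became negative; parameters infeasible")
    row = W.sum(axis=1)
    T = W / row[:, None]
    if np.any(T > 1.0) or not np.allclose(T.sum(axis=1), 1.0, atol=1e-12):
        raise ValueError("parameter combination yields a non-stochastic matrix")
    pi = row / row.sum()
    return GroundTruthChain(n_states=n, transition_matrix=T, stationary=pi,
                            block_labels=labels, lag_unit=lag_unit)


def sample_discrete_trajectories(chain: GroundTruthChain,
                                 n_traj: int,
                                 n_steps: int,
                                 seed: int = 0) -> list[DiscreteTrajectory]:
    """Sample state sequences of length ``n_steps + 1`` from the chain.

    Initial states are drawn from the stationary distribution; the seed fixes
    the whole stream, so equal seeds give identical output.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if n_traj < 1:
        raise ValueError("n_traj must be >= 1")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(chain.transition_matrix, axis=1)
    cum[:, -1] = 1.0
    states = np.empty((n_traj, n_steps + 1), dtype=np.int64)
    states[:, 0] = rng.choice(chain.n_states, size=n_traj, p=chain.stationary)
    for t in range(n_steps):
        u = rng.random(n_traj)
        states[:, t + 1] = (cum[states[:, t]] < u[:, None]).sum(axis=1)
    return [DiscreteTrajectory(states[i], frame_interval=chain.lag_unit)
            for i in range(n_traj)]


# ---------------------------------------------------------------------------
# Toy continuous unfolding simulator
# ---------------------------------------------------------------------------

def _default_folded_template() -> np.ndarray:
    """Compact helical arrangement of 15 beads (Å); small end-to-end distance."""
    i = np.arange(15)
    theta = i * (2.0 * np.pi / 8.0)
    return np.column_stack([5.0 * np.cos(theta), 5.0 * np.sin(theta), 0.9 * i])


def _default_extended_template() -> np.ndarray:
    """Fully extended 15-bead strand along x (Å); end-to-end 44.8 Å."""
    i = np.arange(15)
    return np.column_stack([3.2 * i, np.zeros(15), np.zeros(15)])


@dataclass
class ToyLandscape:
    """Triple-well reaction-coordinate landscape rendered as 15-bead frames.

    The potential is ``V(r) = barrier_height · [r (r − 0.5) (r − 1)]²`` with
    minima at r = 0 (folded), 0.5 (connector) and 1 (unfolded), plus a narrow
    Gaussian lift of the connector well (``connector_lift``, kT units) that
    keeps the middle basin genuinely low-population, as the intermediate
    between the folded and unfolded regions of a real unfolding network is.
    Energies are in units of kT at kT = 1; ``kT`` sets the actual thermal
    energy of the walker, so the effective barrier is ≈ 0.0023 ·
    barrier_height / kT in thermal units.
    """

    barrier_height: float = 12.0
    connector_lift: float = 2.5      # raise of the middle well, in units of kT
    connector_sigma: float = 0.12    # width of the Gaussian lift on r
    kT: float = 0.005
    dt: float = 0.005
    jitter_sd: float = 0.35          # Å, Gaussian noise added to rendered beads
    folded_template: np.ndarray = field(default_factory=_default_folded_template)
    extended_template: np.ndarray = field(default_factory=_default_extended_template)

    def __post_init__(self) -> None:
        self.folded_template = np.asarray(self.folded_template, dtype=float)
        self.extended_template = np.asarray(self.extended_template, dtype=float)
        if self.folded_template.shape != self.extended_template.shape:
            raise ValueError("templates must have identical bead counts")
        # Euler–Maruyama stability: dt must resolve the stiffest curvature.
        rr = np.linspace(-0.3, 1.3, 2001)
        vv = self.potential(rr)
        interior = (vv[1:-1] < vv[:-2]) & (vv[1:-1] < vv[2:])
        if interior.sum() != 3:
            raise ValueError(
                f"potential must have exactly three local minima, found "
                f"{int(interior.sum())}; adjust connector_lift/connector_sigma")
        vpp = np.gradient(np.gradient(vv, rr), rr)
        self.max_curvature = float(np.abs(vpp).max())
        if self.dt > 1.0 / self.max_curvature:
            raise ValueError(
                f"dt={self.dt} exceeds the stability bound 1/max|V''| = "
                f"{1.0 / self.max_curvature:.4g}"
            )

    def potential(self, r: np.ndarray) -> np.ndarray:
        p = r * (r - 0.5) * (r - 1.0)
        lift = self.connector_lift * self.kT * np.exp(
            -((r - 0.5) ** 2) / (2.0 * self.connector_sigma ** 2))
        return self.barrier_height * p ** 2 + lift

    def force(self, r: np.ndarray) -> np.ndarray:
        p = r * (r - 0.5) * (r - 1.0)
        dp = 3.0 * r ** 2 - 3.0 * r + 0.5
        dlift = self.connector_lift * self.kT * (-(r - 0.5) / self.connector_sigma ** 2) \
            * np.exp(-((r - 0.5) ** 2) / (2.0 * self.connector_sigma ** 2))
        return -(2.0 * self.barrier_height * p * dp + dlift)

    def render(self, r: np.ndarray, rng: Optional[np.random.Generator] = None) -> np.ndarray:
        """Bead coordinates for reaction-coordinate values ``r`` (any shape
        broadcastable to frames): linear interpolation between templates at
        clip(r, 0, 1) plus Gaussian jitter."""
        alpha = np.clip(np.asarray(r, dtype=float), 0.0, 1.0)
        coords = ((1.0 - alpha)[..., None, None] * self.folded_template
                  + alpha[..., None, None] * self.extended_template)
        if rng is not None and self.jitter_sd > 0:
            coords = coords + rng.normal(0.0, self.jitter_sd, size=coords.shape)
        return coords


def simulate_reaction_coordinate(landscape: ToyLandscape,
                                 n_traj: int,
                                 n_steps: int,
                                 seed: int = 0,
                                 start: float | str = "spread") -> np.ndarray:
    """Overdamped Euler–Maruyama walkers on the landscape.

    Returns positions of shape ``(n_traj, n_steps + 1)``. ``start`` is either a
    single reaction-coordinate value for all walkers or ``"spread"`` — initial
    positions evenly spread over [0, 1], emulating unfolding seeds scattered
    across the conformation space. Walkers are reflected at r = −0.25 and
    r = 1.25; divergence aborts with a diagnostic.
    """
    rng = np.random.default_rng(seed)
    if start == "spread":
        r = np.linspace(0.0, 1.0, n_traj)
    else:
        r = np.full(n_traj, float(start))
    lo, hi = -0.25, 1.25
    out = np.empty((n_traj, n_steps + 1))
    out[:, 0] = r
    sigma = np.sqrt(2.0 * landscape.kT * landscape.dt)
    for t in range(n_steps):
        r = r + landscape.force(r) * landscape.dt + sigma * rng.standard_normal(n_traj)
        r = np.where(r < lo, 2 * lo - r, r)
        r = np.where(r > hi, 2 * hi - r, r)
        if not np.all(np.isfinite(r)) or np.any(np.abs(r) > 10.0):
            raise FloatingPointError(
                f"integration diverged at step {t}; reduce dt below the "
                f"stability bound 1/max|V''| = {1.0 / landscape.max_curvature:.4g}"
            )
        out[:, t + 1] = r
    return out


def _bead_atom_table() -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    names = np.array(["C1'"] * 15, dtype=object)
    residues = np.array([f"{b}{i + 1}" for i, b in enumerate(TBA_SEQUENCE)], dtype=object)
    elements = np.array(["C"] * 15, dtype=object)
    return names, residues, elements


def generate_toy_unfolding_trajectories(landscape: ToyLandscape,
                                        n_traj: int = 31,
                                        n_steps: int = 200_000,
                                        save_stride: int = 1000,
                                        seed: int = 0,
                                        start: float | str = "spread",
                                        return_paths: bool = False):
    """Ensemble of toy unfolding trajectories as 15-bead structures.

    Frames are saved every ``save_stride`` integration steps including step 0,
    giving ``n_steps // save_stride + 1`` frames per trajectory. The frame
    interval equals ``landscape.dt * save_stride``. With ``return_paths`` the
    saved reaction-coordinate values are returned alongside.
    """
    paths = simulate_reaction_coordinate(landscape, n_traj, n_steps, seed=seed, start=start)
    saved = paths[:, ::save_stride]
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    names, residues, elements = _bead_atom_table()
    interval = landscape.dt * save_stride
    trajs = [Trajectory(names, residues, elements, landscape.render(saved[i], rng), interval)
             for i in range(n_traj)]
    if return_paths:
        return trajs, saved
    return trajs


def save_chain(chain: GroundTruthChain, path: str | Path) -> Path:
    """Write the ground-truth matrix as delimited text; the header names the
    lag unit and the planted block labels."""
    path = Path(path)
    header = (f"lag_unit={chain.lag_unit}\n"
              f"block_labels={','.join(map(str, chain.block_labels))}\n"
              f"stationary={','.join(f'{x:.17g}' for x in chain.stationary)}")
    np.savetxt(path, chain.transition_matrix, header=header)
    return path
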