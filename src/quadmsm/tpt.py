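"""Transition path theory and mean first passage times.

Given a Markov model, a source set A (e.g. the native, quadruplex-containing
state) and a target set B (the unfolded, extended states), this module
computes

* forward and backward committors q⁺, q⁻ (harmonic linear systems with fixed
  boundary values; the backward system runs on the time-reversed matrix
  T̃_ij = π_j T_ji / π_i);
* reactive gross fluxes f_ij = π_i q⁻_i T_ij q⁺_j, loop-corrected net fluxes
  f⁺_ij = max(f_ij − f_ji, 0), and the total reactive flux F;
* a ranked decomposition of the net-flux network into unfolding pathways by
  iterative widest-path (bottleneck) removal;
* mean first passage times to a target set, MFPT_i = t + Σ_j T_ij · MFPT_j
  with MFPT = 0 on the target, in the physical units of the lag time t.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from heapq import heappush, heappop
from typing import Optional, Sequence

import numpy as np
from scipy.sparse.csgraph import connected_components

from .msm import MarkovModel

__all__ = [
    "CommittorSet",
    "FluxNetwork",
    "Pathway",
    "MFPTResult",
    "forward_committor",
    "backward_committor",
    "committors",
    "reactive_flux",
    "top_pathways",
    "mfpt",
    "pathway_edge_times",
]


@dataclass
class CommittorSet:
    """Forward/backward committors for source set A and target set B.

    Indices refer to rows of the model they were computed on (the active set).
    """

    q_forward: np.ndarray
    q_backward: np.ndarray
    A: tuple[int, ...]
    B: tuple[int, ...]

    def __post_init__(self) -> None:
        qp, qm = self.q_forward, self.q_backward
        for q in (qp, qm):
            if np.any(q < -1e-10) or np.any(q > 1 + 1e-10):
                raise ValueError("committors must lie in [0, 1]")
        if not (np.allclose(qp[list(self.A)], 0) and np.allclose(qp[list(self.B)], 1)):
            raise ValueError("forward committor boundary values violated")
        if not (np.allclose(qm[list(self.A)], 1) and np.allclose(qm[list(self.B)], 0)):
            raise ValueError("backward committor boundary values violated")


@dataclass
class FluxNetwork:
    """Gross and net reactive fluxes between states (per lag step)."""

    gross: np.ndarray
    net: np.ndarray
    total_flux: float
    A: tuple[int, ...]
    B: tuple[int, ...]

    def __post_init__(self) -> None:
        if np.any(self.gross < -1e-15):
            raise ValueError("gross fluxes must be non-negative")
        n = self.gross.shape[0]
        inter = [i for i in range(n) if i not in self.A and i not in self.B]
        imbalance = np.abs(self.net.sum(axis=1) - self.net.sum(axis=0))[inter]
        if imbalance.size and imbalance.max() > 1e-10:
            raise ValueError("net flux is not conserved at intermediate states")


@dataclass
class Pathway:
    """One A→B pathway with the flux it carries."""

    states: tuple[int, ...]
    flux: float
    fraction: float

    def label(self, names: Optional[Sequence[str]] = None) -> str:
        """Hyphen-joined state labels, e.g. ``3-19-5-24-11-6-21``."""
        if names is None:
            return "-".join(str(s) for s in self.states)
        return "-".join(str(names[s]) for s in self.states)


@dataclass
class MFPTResult:
    """Mean first passage times (physical units) to a target set."""

    times: np.ndarray
    target: tuple[int, ...]
    lag_time: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if np.any(t[list(self.target)] != 0):
            raise ValueError("MFPT must vanish on the target set")
        if np.any(t < 0) or not np.all(np.isfinite(t)):
            raise ValueError("MFPTs must be finite and non-negative")
        self.times = t


def _check_sets(model: MarkovModel, A: Sequence[int], B: Sequence[int]) -> tuple[list, list, list]:
    A, B = sorted(set(int(a) for a in A)), sorted(set(int(b) for b in B))
    if not A or not B:
        raise ValueError("A and B must be non-empty")
    if set(A) & set(B):
        raise ValueError("A and B must be disjoint")
    n = model.n_states
    if max(A + B) >= n or min(A + B) < 0:
        raise ValueError("A and B must be indices into the active state set")
    I = [i for i in range(n) if i not in A and i not in B]
    return A, B, I


def _solve_committor(T: np.ndarray, A: list, B: list, I: list) -> np.ndarray:
    q = np.zeros(T.shape[0])
    q[B] = 1.0
    if I:
        M = np.eye(len(I)) - T[np.ix_(I, I)]
        rhs = T[np.ix_(I, B)].sum(axis=1)
        try:
            q[I] = np.linalg.solve(M, rhs)
        except np.linalg.LinAlgError as err:
            raise ValueError("intermediate states cannot reach A ∪ B; "
                             "run on the ergodic active set") from err
    return np.clip(q, 0.0, 1.0)


def forward_committor(model: MarkovModel, A: Sequence[int], B: Sequence[int]) -> np.ndarray:
    """Probability of visiting B before A, per state (0 on A, 1 on B)."""
    A, B, I = _check_sets(model, A, B)
    return _solve_committor(model.T, A, B, I)


def backward_committor(model: MarkovModel, A: Sequence[int], B: Sequence[int]) -> np.ndarray:
    """Probability, looking backward in time, of having come last from A.

    Solves the forward problem on the time-reversed matrix
    T̃_ij = π_j T_ji / π_i with the roles of A and B swapped (1 on A, 0 on B).
    """
    A, B, I = _check_sets(model, A, B)
    Trev = (model.pi[None, :] * model.T.T) / model.pi[:, None]
    return _solve_committor(Trev, B, A, I)


def committors(model: MarkovModel, A: Sequence[int], B: Sequence[int]) -> CommittorSet:
    A2, B2, _ = _check_sets(model, A, B)
    return CommittorSet(q_forward=forward_committor(model, A, B),
                        q_backward=backward_committor(model, A, B),
                        A=tuple(A2), B=tuple(B2))


def reactive_flux(model: MarkovModel, comm: CommittorSet) -> FluxNetwork:
    """Reactive gross and net fluxes and the total A→B flux F.

    f_ij = π_i q⁻_i T_ij q⁺_j for i ≠ j (zero diagonal); the net flux removes
    back-and-forth loops, f⁺_ij = max(f_ij − f_ji, 0); F is the total net flux
    out of A (which equals the flux into B).
    """
    qp, qm = comm.q_forward, comm.q_backward
    f = (model.pi * qm)[:, None] * model.T * qp[None, :]
    np.fill_diagonal(f, 0.0)
    net = np.clip(f - f.T, 0.0, None)
    F = float(net[list(comm.A), :].sum())
    F_in = float(net[:, list(comm.B)].sum())
    if abs(F - F_in) > 1e-10 * max(F, 1.0):
        raise AssertionError("flux out of A does not match flux into B")
    return FluxNetwork(gross=f, net=net, total_flux=F, A=comm.A, B=comm.B)


def _widest_path(net: np.ndarray, A: Sequence[int], B: Sequence[int]
                 ) -> Optional[tuple[list[int], float]]:
    """Maximum-bottleneck path from any state in A to any state in B.

    Dijkstra-style search maximizing the minimum edge capacity; ties resolve
    toward lower state indices (both in the pop order and in parent updates),
    making the decomposition deterministic.
    """
    n = net.shape[0]
    width = np.zeros(n)
    parent = np.full(n, -1, dtype=int)
    heap = []
    for a in sorted(A):
        width[a] = np.inf
        heappush(heap, (-np.inf, a))
    done = np.zeros(n, dtype=bool)
    while heap:
        negw, u = heappop(heap)
        if done[u]:
            continue
        done[u] = True
        for v in range(n):
            cap = net[u, v]
            if cap <= 0 or done[v]:
                continue
            w = min(width[u], cap)
            if w > width[v]:
                width[v] = w
                parent[v] = u
                heappush(heap, (-w, v))
    best, bw = -1, 0.0
    for b in sorted(B):
        if width[b] > bw:
            best, bw = b, width[b]
    if best < 0 or bw <= 0:
        return None
    path = [best]
    while parent[path[-1]] >= 0:
        path.append(parent[path[-1]])
    if path[-1] not in A:
        return None
    return path[::-1], float(bw)


def top_pathways(flux: FluxNetwork, K: int, tol: float = 1e-12) -> list[Pathway]:
    """Decompose the net-flux network into its K strongest pathways.

    Iterative bottleneck decomposition: find the A→B path whose
    minimum-capacity edge is maximal, record it with its bottleneck flux,
    subtract that flux along the path, repeat until K paths are found or the
    residual flux is exhausted (fewer than K paths are then returned).
    """
    if K <= 0:
        raise ValueError("K must be positive")
    if flux.total_flux <= 0:
        raise ValueError("total reactive flux is zero; no pathways to decompose")
    residual = flux.net.copy()
    out: list[Pathway] = []
    for _ in range(K):
        found = _widest_path(residual, flux.A, flux.B)
        if found is None:
            break
        path, w = found
        if w <= tol * flux.total_flux:
            break
        for u, v in zip(path[:-1], path[1:]):
            residual[u, v] -= w
        out.append(Pathway(states=tuple(path), flux=w, fraction=w / flux.total_flux))
    return out


def mfpt(model: MarkovModel, target: Sequence[int],
         lag_time: Optional[float] = None) -> MFPTResult:
    """Mean first passage time from every state to the target set.

    Solves MFPT_i = t + Σ_j T_ij MFPT_j for i outside the target with
    MFPT = 0 on the target; ``t`` defaults to the model's physical lag time.
    States that cannot reach the target make the system singular and are
    reported by name.
    """
    target = sorted(set(int(s) for s in target))
    if not target:
        raise ValueError("target set must be non-empty")
    n = model.n_states
    if max(target) >= n or min(target) < 0:
        raise ValueError("target states outside the active set")
    t = model.lag_time if lag_time is None else float(lag_time)
    rest = [i for i in range(n) if i not in target]
    times = np.zeros(n)
    if rest:
        # reachability check on the directed transition graph
        reach = _reaches(model.T, set(target))
        unreachable = [int(model.active[i]) for i in rest if not reach[i]]
        if unreachable:
            raise ValueError(f"states cannot reach the target: {unreachable}")
        M = np.eye(len(rest)) - model.T[np.ix_(rest, rest)]
        times[rest] = np.linalg.solve(M, np.full(len(rest), t))
    return MFPTResult(times=times, target=tuple(target), lag_time=t)


def _reaches(T: np.ndarray, target: set[int]) -> np.ndarray:
    n = T.shape[0]
    reach = np.zeros(n, dtype=bool)
    stack = list(target)
    reach[list(target)] = True
    incoming = [np.flatnonzero(T[:, j] > 0) for j in range(n)]
    while stack:
        j = stack.pop()
        for i in incoming[j]:
            if not reach[i]:
                reach[i] = True
                stack.append(int(i))
    return reach


def pathway_edge_times(model: MarkovModel, pathway: Pathway,
                       restrict_to_path: bool = False) -> list[tuple[int, int, float]]:
    """Per-edge transition times along a pathway, as pairwise MFPTs.

    For each consecutive pair (u, v) the MFPT from u to {v} is computed either
    on the full transition matrix (default) or on the matrix restricted to the
    pathway's states, row-renormalized (``restrict_to_path=True``); the two
    conventions are labelled by the caller's choice.
    """
    edges = []
    if restrict_to_path:
        idx = list(pathway.states)
        sub = model.T[np.ix_(idx, idx)]
        rowsum = sub.sum(axis=1, keepdims=True)
        if np.any(rowsum == 0):
            raise ValueError("path-restricted matrix has a state with no in-path transitions")
        sub = sub / rowsum
        vals, vecs = np.linalg.eig(sub.T)
        pi = np.abs(vecs[:, int(np.argmax(vals.real))].real)
        pi /= pi.sum()
        sub_model = MarkovModel(T=sub, pi=pi, lag=model.lag, lag_time=model.lag_time,
                                active=np.asarray(idx), reversible=False)
        for a, b in zip(range(len(idx) - 1), range(1, len(idx))):
            res = mfpt(sub_model, [b])
            edges.append((pathway.states[a], pathway.states[b], float(res.times[a])))
        return edges
    for u, v in zip(pathway.states[:-1], pathway.states[1:]):
        res = mfpt(model, [v])
        edges.append((int(u), int(v), float(res.times[u])))
    return edges
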