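"""Markov-state-model estimation and validation.

Transition counting at a lag time, the symmetrize-and-normalize (reversible)
transition-matrix estimator, stationary distributions, implied relaxation
timescales, and the two standard validation checks: the implied-timescale
plateau (lag-independence of t_k indicates Markovian behaviour) and the
residence-probability test (model-propagated versus directly counted
probability of remaining in a macrostate).

Estimator convention: the symmetrized counts C' = (C + Cᵀ)/2 are
row-normalized, which yields a row-stochastic T satisfying detailed balance
with π proportional to the row sums of C'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import connected_components

from .discrete import DiscreteTrajectory

__all__ = [
    "CountMatrix",
    "MarkovModel",
    "count_transitions",
    "ergodic_trim",
    "estimate_transition_matrix",
    "eigen_spectrum",
    "implied_timescales",
    "residence_probability",
]


@dataclass
class CountMatrix:
    """Transition counts at a fixed lag (sliding-window mode)."""

    counts: np.ndarray
    lag: int                       # in frames
    lag_time: float                # physical units (lag * frame interval)
    mode: str = "sliding"
    state_labels: Optional[np.ndarray] = None  # original labels of the rows

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValueError("counts must be square")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.state_labels is None:
            self.state_labels = np.arange(self.counts.shape[0])
        self.state_labels = np.asarray(self.state_labels, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return self.counts.shape[0]


@dataclass
class MarkovModel:
    """Row-stochastic transition matrix with stationary distribution.

    ``active`` maps the rows of ``T`` back to the original microstate labels
    (states outside the largest strongly connected component are trimmed).
    """

    T: np.ndarray
    pi: np.ndarray
    lag: int
    lag_time: float
    active: np.ndarray
    reversible: bool = True

    def __post_init__(self) -> None:
        self.T = np.asarray(self.T, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if not np.allclose(self.T.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("rows of T must sum to 1")
        if np.any(self.pi < -1e-15) or abs(self.pi.sum() - 1.0) > 1e-10:
            raise ValueError("pi must be a probability vector")
        if not np.allclose(self.pi @ self.T, self.pi, atol=1e-8):
            raise ValueError("pi is not stationary for T")
        self.active = np.asarray(self.active, dtype=np.int64)

    @property
    def n_states(self) -> int:
        return self.T.shape[0]

    def index_of(self, labels: Sequence[int]) -> np.ndarray:
        """Active-set row indices for original microstate labels."""
        lookup = {int(s): i for i, s in enumerate(self.active)}
        missing = [s for s in labels if int(s) not in lookup]
        if missing:
            raise ValueError(f"states not in the active set: {missing}")
        return np.array([lookup[int(s)] for s in labels], dtype=int)


def count_transitions(dtrajs: Sequence[DiscreteTrajectory], lag: int,
                      n_states: Optional[int] = None) -> CountMatrix:
    """Sliding-window transition counts at integer lag (in frames).

    Every frame ``t`` with ``t + lag`` inside the same trajectory contributes
    one count; trajectories are never concatenated. Total counts equal
    ``Σ_traj max(len − lag, 0)``; an error is raised if no trajectory is longer
    than the lag.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    usable = [dt for dt in dtrajs if len(dt) > lag]
    if not usable:
        raise ValueError(f"all trajectories are shorter than lag {lag}")
    if n_states is None:
        n_states = int(max(dt.states.max() for dt in dtrajs)) + 1
    C = np.zeros((n_states, n_states))
    for dt in usable:
        s = dt.states
        np.add.at(C, (s[:-lag], s[lag:]), 1.0)
    interval = usable[0].frame_interval
    return CountMatrix(C, lag=lag, lag_time=lag * interval)


def ergodic_trim(counts: CountMatrix) -> tuple[CountMatrix, np.ndarray]:
    """Restrict counts to the largest strongly connected component.

    Returns the trimmed matrix and a mapping ``old index -> new index`` (−1
    for removed states).
    """
    C = counts.counts
    n = C.shape[0]
    n_comp, comp = connected_components(C > 0, directed=True, connection="strong")
    sizes = np.bincount(comp, minlength=n_comp)
    # tie-break toward the component containing the lowest state index
    best = int(np.argmax(sizes))
    keep = np.flatnonzero(comp == best)
    mapping = np.full(n, -1, dtype=np.int64)
    mapping[keep] = np.arange(keep.size)
    trimmed = CountMatrix(C[np.ix_(keep, keep)], lag=counts.lag,
                          lag_time=counts.lag_time, mode=counts.mode,
                          state_labels=counts.state_labels[keep])
    return trimmed, mapping


def estimate_transition_matrix(counts: CountMatrix,
                               reversible: bool = True) -> MarkovModel:
    """Estimate T (and π) from counts after ergodic trimming.

    Reversible mode (the default): C' = (C + Cᵀ)/2 row-normalized;
    π = row sums of C', normalized — the stationary vector of the resulting T,
    which satisfies detailed balance by construction. Non-reversible mode
    row-normalizes C directly and takes π from the leading left eigenvector.
    """
    trimmed, _ = ergodic_trim(counts)
    C = trimmed.counts
    if C.size == 0 or C.sum() == 0:
        raise ValueError("no connected states with counts remain after trimming")
    if reversible:
        Cs = (C + C.T) / 2.0
        row = Cs.sum(axis=1)
        T = Cs / row[:, None]
        pi = row / row.sum()
    else:
        row = C.sum(axis=1)
        if np.any(row == 0):
            raise ValueError("a state in the strongly connected component has no outgoing counts")
        T = C / row[:, None]
        vals, vecs = np.linalg.eig(T.T)
        i = int(np.argmax(vals.real))
        pi = np.abs(vecs[:, i].real)
        pi = pi / pi.sum()
    return MarkovModel(T=T, pi=pi, lag=trimmed.lag, lag_time=trimmed.lag_time,
                       active=trimmed.state_labels, reversible=reversible)


def eigen_spectrum(model: MarkovModel, k: Optional[int] = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues (descending) and right eigenvectors of T.

    For reversible models the π^{1/2}-conjugate symmetric matrix
    D^{1/2} T D^{−1/2} is diagonalized with a symmetric solver for numerical
    stability; the right eigenvectors of T are recovered as D^{−1/2} v. For
    non-reversible models a dense nonsymmetric solver is used.
    """
    n = model.n_states
    k = n if k is None else min(k, n)
    if model.reversible:
        sqrt_pi = np.sqrt(model.pi)
        S = (sqrt_pi[:, None] * model.T) / sqrt_pi[None, :]
        S = (S + S.T) / 2.0
        vals, vecs = np.linalg.eigh(S)
        order = np.argsort(vals)[::-1]
        vals = vals[order][:k]
        right = (vecs[:, order][:, :k]) / sqrt_pi[:, None]
        for j in range(right.shape[1]):
            norm = np.max(np.abs(right[:, j]))
            if norm > 0:
                right[:, j] = right[:, j] / norm
        if k >= 1:
            right[:, 0] = 1.0
        return vals, right
    vals, vecs = np.linalg.eig(model.T)
    order = np.argsort(-vals.real)
    return vals[order][:k], vecs[:, order][:, :k]


def implied_timescales(dtrajs: Sequence[DiscreteTrajectory],
                       lags: Sequence[int],
                       n_timescales: int = 10,
                       reversible: bool = True) -> pd.DataFrame:
    """Implied timescales t_k(τ) = −τ / ln μ_k for a ladder of lag times.

    For each lag, a model is estimated and the ``n_timescales``
    largest-magnitude non-unit eigenvalues with μ in (0, 1) are converted to
    relaxation times in the trajectories' physical time unit. Eigenvalues that
    are non-positive (or, in non-reversible mode, complex) yield NaN; μ ≥ 1
    yields +inf (timescale above any finite cap). Rows are indexed by lag.
    """
    rows = {}
    for lag in lags:
        model = estimate_transition_matrix(count_transitions(dtrajs, lag),
                                           reversible=reversible)
        vals, _ = eigen_spectrum(model, k=n_timescales + 1)
        mus = vals[1:] if len(vals) > 1 else np.array([])
        ts = np.full(n_timescales, np.nan)
        for j, mu in enumerate(mus[:n_timescales]):
            if np.iscomplexobj(mu) and abs(mu.imag) > 1e-12:
                continue
            mu = float(np.real(mu))
            if mu >= 1.0 - 1e-12:
                ts[j] = np.inf
            elif mu > 0.0:
                ts[j] = -model.lag_time / np.log(mu)
        rows[model.lag_time] = ts
    df = pd.DataFrame.from_dict(
        rows, orient="index",
        columns=[f"t{k + 1}" for k in range(n_timescales)])
    df.index.name = "lag_time"
    return df


def residence_probability(dtrajs: Sequence[DiscreteTrajectory],
                          macro_assignment: dict[int, int] | np.ndarray,
                          model: MarkovModel,
                          horizons: Sequence[int]) -> pd.DataFrame:
    """Residence-probability validation curves per macrostate and horizon.

    Empirical: the fraction of frames in macrostate M whose frame at ``t + h``
    is still in M (direct count from the trajectories). Predicted: the
    stationary-weighted model propagation
    ``π_Mᵀ T^h 1_M / Σ π_M``. Horizons are in frames of the discrete
    trajectories; the returned table also carries the binomial standard error
    of each empirical value.
    """
    if isinstance(macro_assignment, dict):
        macro_of = dict(macro_assignment)
    else:
        arr = np.asarray(macro_assignment)
        macro_of = {int(s): int(arr[i]) for i, s in enumerate(model.active)}
    missing = [int(s) for s in model.active if int(s) not in macro_of]
    if missing:
        raise ValueError(f"macro assignment does not cover active microstates: {missing}")
    macros = sorted(set(macro_of.values()))
    # per-state macro lookup over the raw label space
    max_label = max(int(dt.states.max()) for dt in dtrajs)
    lookup = np.full(max_label + 1, -1, dtype=np.int64)
    for s, m in macro_of.items():
        if s <= max_label:
            lookup[s] = m
    in_macro_model = {m: np.array([macro_of[int(s)] == m for s in model.active])
                      for m in macros}
    rows = []
    for m in macros:
        ind = in_macro_model[m].astype(float)
        pi_m = model.pi * ind
        if pi_m.sum() == 0:
            continue
        x0 = pi_m / pi_m.sum()
        for h in horizons:
            num = den = 0
            for dt in dtrajs:
                lab = lookup[dt.states]
                if h == 0:
                    sel = lab == m
                    num += int(np.sum(sel))
                    den += int(np.sum(sel))
                elif len(dt) > h:
                    a, b = lab[:-h], lab[h:]
                    sel = a == m
                    num += int(np.sum(sel & (b == m)))
                    den += int(np.sum(sel))
            x = x0.copy()
            for _ in range(int(h)):
                x = x @ model.T
            predicted = float(x @ ind)
            empirical = num / den if den else np.nan
            se = (np.sqrt(max(empirical * (1 - empirical), 0.0) / den)
                  if den else np.nan)
            rows.append({"macrostate": m, "horizon": int(h),
                         "empirical": empirical, "predicted": predicted,
                         "n_obs": den, "se": se})
    return pd.DataFrame(rows)
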