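"""PCCA+ metastable lumping of microstates into macrostates.

Robust Perron cluster cluster analysis assigns each microstate a fuzzy
membership in each of ``n_macro`` metastable sets, derived from the geometry
of the top right eigenvectors of a reversible transition matrix: rows of the
eigenvector matrix lie (up to noise) in a simplex whose vertices correspond to
the metastable sets. The inner-simplex algorithm locates those vertices by
greedy farthest-point selection in eigenvector space; memberships follow from
the affine transform mapping vertices to unit coordinates, with small
infeasibilities clipped and rows renormalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .msm import MarkovModel, eigen_spectrum

__all__ = ["MacroModel", "pcca_plus", "coarse_grain", "spectral_gap_report"]


@dataclass
class MacroModel:
    """PCCA+ membership of microstates in macrostates.

    ``chi`` is the n_micro × n_macro fuzzy membership matrix (rows sum to 1);
    ``assignment`` is the crisp argmax assignment; ``populations`` are the
    stationary weights aggregated per macrostate. ``micro_labels`` carries the
    original microstate labels of the rows (the model's active set).
    """

    chi: np.ndarray
    assignment: np.ndarray
    populations: np.ndarray
    micro_labels: np.ndarray
    crispness: float
    coarse_T: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        chi = np.asarray(self.chi, dtype=float)
        if np.any(chi < -1e-12) or np.any(chi > 1 + 1e-12):
            raise ValueError("memberships must lie in [0, 1]")
        if not np.allclose(chi.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("membership rows must sum to 1")
        if abs(self.populations.sum() - 1.0) > 1e-8:
            raise ValueError("macrostate populations must sum to 1")
        self.chi = chi

    @property
    def n_macro(self) -> int:
        return self.chi.shape[1]

    def members(self, macro: int) -> np.ndarray:
        """Original microstate labels crisply assigned to ``macro``."""
        return self.micro_labels[self.assignment == macro]

    def assignment_by_label(self) -> dict[int, int]:
        return {int(s): int(m) for s, m in zip(self.micro_labels, self.assignment)}


def _inner_simplex_vertices(psi: np.ndarray) -> list[int]:
    """Greedy farthest-point vertex search in eigenvector space.

    The first vertex is the row of largest norm; each further vertex maximizes
    the residual after projecting out the affine span of those already chosen.
    """
    n, m = psi.shape
    chosen = [int(np.argmax(np.linalg.norm(psi, axis=1)))]
    basis: list[np.ndarray] = []
    for _ in range(m - 1):
        resid = psi - psi[chosen[0]]
        for b in basis:
            resid = resid - np.outer(resid @ b, b)
        norms = np.linalg.norm(resid, axis=1)
        nxt = int(np.argmax(norms))
        if norms[nxt] <= 1e-12:
            raise ValueError("degenerate eigenvector geometry: affinely dependent rows")
        chosen.append(nxt)
        basis.append(resid[nxt] / norms[nxt])
    return chosen


def pcca_plus(model: MarkovModel, n_macro: int) -> MacroModel:
    """Lump a reversible Markov model into ``n_macro`` metastable macrostates.

    Memberships come from the inner-simplex vertex construction on the top
    ``n_macro`` right eigenvectors; the crisp assignment is the maximal
    membership (ties to the lowest macrostate index). The reported crispness
    is trace(S)/n_macro of the crispness matrix
    S = (diag(π·χ))⁻¹ χᵀ diag(π) χ, which equals 1 for a perfectly crisp
    lumping.
    """
    if n_macro < 2:
        raise ValueError("n_macro must be >= 2")
    if n_macro > model.n_states:
        raise ValueError("n_macro exceeds the number of microstates")
    if not model.reversible:
        raise ValueError("PCCA+ requires a reversible model; estimate with reversible=True")
    db = model.pi[:, None] * model.T - model.pi[None, :] * model.T.T
    if np.abs(db).max() > 1e-8:
        raise ValueError("model violates detailed balance; PCCA+ requires reversibility")
    vals, psi = eigen_spectrum(model, k=min(n_macro + 1, model.n_states))
    if len(vals) > n_macro:
        gap = float(vals[n_macro - 1] - vals[n_macro])
        if gap < 1e-12:
            raise ValueError(
                f"degenerate eigenvalue geometry at the cut: λ_{n_macro} = "
                f"{vals[n_macro - 1]:.12g}, λ_{n_macro + 1} = {vals[n_macro]:.12g}")
    if np.any(vals[:n_macro].real <= 0):
        raise ValueError("n_macro exceeds the number of eigenvalues with positive real part")
    psi = np.real(psi[:, :n_macro])
    vertices = _inner_simplex_vertices(psi)
    A = psi[vertices]
    chi = psi @ np.linalg.inv(A)
    chi = np.clip(chi, 0.0, None)
    rowsum = chi.sum(axis=1)
    if np.any(rowsum <= 0):
        raise ValueError("degenerate membership row; eigenvector geometry unusable")
    chi = chi / rowsum[:, None]
    assignment = np.argmax(chi, axis=1)  # ties resolve to the lowest macro index
    if len(np.unique(assignment)) < n_macro:
        raise ValueError("a macrostate is empty under crisp assignment; "
                         "reduce n_macro or inspect the spectral gap report")
    populations = np.array([model.pi[assignment == m].sum() for m in range(n_macro)])
    # crispness matrix S = D_coarse^-1 chi^T D chi with D = diag(pi)
    w = chi.T @ model.pi
    S = (chi.T * model.pi) @ chi / w[:, None]
    crisp = float(np.trace(S) / n_macro)
    return MacroModel(chi=chi, assignment=assignment, populations=populations,
                      micro_labels=model.active.copy(), crispness=crisp)


def coarse_grain(model: MarkovModel, macro: MacroModel,
                 edge_floor: float = 0.0
                 ) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, float]]]:
    """Crisp coarse-grained populations and transition weights.

    ``P_M = Σ_{i∈M} π_i`` and ``W_MN = Σ_{i∈M, j∈N} π_i T_ij / P_M`` (a
    row-stochastic macrostate matrix). The edge list keeps off-diagonal
    weights above ``edge_floor``. The coarse matrix is also stored on the
    macro model.
    """
    m = macro.n_macro
    P = macro.populations
    W = np.zeros((m, m))
    for M in range(m):
        in_M = macro.assignment == M
        flow = (model.pi[in_M, None] * model.T[in_M, :]).sum(axis=0)
        for N in range(m):
            W[M, N] = flow[macro.assignment == N].sum()
        W[M] /= P[M]
    edges = [(M, N, float(W[M, N])) for M in range(m) for N in range(m)
             if M != N and W[M, N] > edge_floor]
    macro.coarse_T = W
    return P, W, edges


def coarse_model(model: MarkovModel, macro: MacroModel) -> MarkovModel:
    """The crisp coarse-grained chain as a MarkovModel (macrostate-level
    committors, fluxes and passage times run on this)."""
    P, W, _ = coarse_grain(model, macro)
    return MarkovModel(T=W, pi=P, lag=model.lag, lag_time=model.lag_time,
                       active=np.arange(macro.n_macro), reversible=model.reversible)


def spectral_gap_report(model: MarkovModel, k: int = 12) -> pd.DataFrame:
    """Leading eigenvalues with gaps, to guide the choice of n_macro."""
    vals, _ = eigen_spectrum(model, k=min(k, model.n_states))
    vals = np.real(vals)
    gaps = np.append(-np.diff(vals), np.nan)
    return pd.DataFrame({"eigenvalue": vals, "gap_to_next": gaps},
                        index=pd.RangeIndex(1, len(vals) + 1, name="rank"))
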