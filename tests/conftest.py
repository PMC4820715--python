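import numpy as np
import pytest

from quadmsm.featurize import Structure, Trajectory
from quadmsm.msm import MarkovModel


def make_structure(coords, names=None, residues=None, elements=None):
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    names = names or [f"C{i + 1}" for i in range(n)]
    residues = residues or [f"G{i + 1}" for i in range(n)]
    elements = elements or ["C"] * n
    return Structure(np.array(names, dtype=object), np.array(residues, dtype=object),
                     np.array(elements, dtype=object), coords)


def make_trajectory(frames, **kw):
    frames = np.asarray(frames, dtype=float)
    s = make_structure(frames[0], **{k: v for k, v in kw.items() if k != "frame_interval"})
    return Trajectory(s.atom_names, s.residues, s.elements, frames,
                      kw.get("frame_interval", 1.0))


def model_from_T(T, lag_time=1.0, reversible=None):
    """Wrap a row-stochastic matrix as a MarkovModel with its exact stationary
    vector (dense eigensolver)."""
    T = np.asarray(T, dtype=float)
    vals, vecs = np.linalg.eig(T.T)
    pi = np.abs(vecs[:, np.argmax(vals.real)].real)
    pi = pi / pi.sum()
    if reversible is None:
        reversible = bool(np.allclose(pi[:, None] * T, pi[None, :] * T.T, atol=1e-12))
    return MarkovModel(T=T, pi=pi, lag=1, lag_time=lag_time,
                       active=np.arange(T.shape[0]), reversible=reversible)


@pytest.fixture
def tetra():
    """Four non-coplanar points, the smallest generic rigid body."""
    return make_structure([[0.0, 0, 0], [1.5, 0, 0], [0, 2.0, 0], [0.3, 0.4, 1.8]])


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
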