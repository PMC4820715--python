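"""Geometric observables for nucleic-acid conformational ensembles.

This module owns trajectory I/O (multi-model PDB) and the structural features
used throughout the unfolding analysis:

* least-squares (Kabsch) superposition and RMSD, whole-backbone or per-loop;
* distances between residue heavy-atom centers, or between a residue and the
  heavy-atom center of the whole molecule;
* hydrogen-bond occupancy over a set of structures, reported in the
  ``N7@G14…N2@G2`` donor–acceptor notation.

Residues are addressed by compact labels combining the one-letter base code
with the 1-based sequence position, e.g. ``G1`` … ``G15`` for the
thrombin-binding aptamer 5'-GGTTGGTGTGGTTGG-3'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

import biotite.structure as bst
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "Structure",
    "Trajectory",
    "HBondRecord",
    "backbone_selection",
    "heavy_selection",
    "make_selection",
    "kabsch_superpose",
    "rmsd_series",
    "centroid_distances",
    "hbond_occupancy",
    "read_structure",
    "read_trajectory",
    "write_trajectory",
]

#: Standard nucleic-acid backbone atom names used for fitting and deviation.
BACKBONE_ATOMS = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")

#: Atomic masses for the optional mass-weighted center convention.
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "P": 30.974}

SelectionLike = Union[None, str, Sequence[str], Callable[["Structure"], np.ndarray]]


@dataclass(eq=False)
class Structure:
    """One conformational frame: labelled atoms with coordinates in Å.

    ``residues`` carries per-atom labels such as ``"G1"``; ``elements`` carries
    the element symbol (``"H"`` flags hydrogens).
    """

    atom_names: np.ndarray
    residues: np.ndarray
    elements: np.ndarray
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residues = np.asarray(self.residues, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.atom_names)
        if not (len(self.residues) == len(self.elements) == self.coords.shape[0] == n):
            raise ValueError("atom table fields must have equal length")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if any(r == "" for r in self.residues):
            raise ValueError("residue labels must be non-empty")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.elements], dtype=bool)

    def atom_labels(self) -> list[str]:
        """Per-atom ``name@residue`` labels, e.g. ``N7@G14``."""
        return [f"{a}@{r}" for a, r in zip(self.atom_names, self.residues)]

    def subset(self, mask: np.ndarray) -> "Structure":
        return Structure(self.atom_names[mask], self.residues[mask],
                         self.elements[mask], self.coords[mask])

    def with_coords(self, coords: np.ndarray) -> "Structure":
        return Structure(self.atom_names, self.residues, self.elements, coords)


@dataclass(eq=False)
class Trajectory:
    """Ordered frames sharing one atom table, saved at a fixed interval.

    ``coords`` has shape ``(n_frames, n_atoms, 3)``; ``frame_interval`` is the
    physical time between saved frames.
    """

    atom_names: np.ndarray
    residues: np.ndarray
    elements: np.ndarray
    coords: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self) -> None:
        self.atom_names = np.asarray(self.atom_names, dtype=object)
        self.residues = np.asarray(self.residues, dtype=object)
        self.elements = np.asarray(self.elements, dtype=object)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[1] != len(self.atom_names):
            raise ValueError("frames are not congruent with the atom table")
        if self.frame_interval <= 0:
            raise ValueError("frame interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def frame(self, i: int) -> Structure:
        return Structure(self.atom_names, self.residues, self.elements, self.coords[i])

    def frames(self) -> list[Structure]:
        return [self.frame(i) for i in range(self.n_frames)]


@dataclass
class HBondRecord:
    """A donor(–H)…acceptor contact with its percentage occupancy."""

    donor: str
    acceptor: str
    occupancy: float
    hydrogen: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.occupancy <= 100.0):
            raise ValueError("occupancy must lie in [0, 100]")

    @property
    def label(self) -> str:
        return f"{self.donor}…{self.acceptor}"


# ---------------------------------------------------------------------------
# Selections
# ---------------------------------------------------------------------------

def backbone_selection(residues: Optional[Sequence[str]] = None) -> Callable[[Structure], np.ndarray]:
    """Select the sugar–phosphate backbone, optionally restricted to residues.

    ``backbone_selection(("T7", "G8", "T9"))`` expresses a per-loop selection
    such as the TGT loop of the aptamer.
    """

    resset = set(residues) if residues is not None else None

    def _sel(s: Structure) -> np.ndarray:
        mask = np.array([a in BACKBONE_ATOMS for a in s.atom_names], dtype=bool)
        if resset is not None:
            mask &= np.array([r in resset for r in s.residues], dtype=bool)
        return mask

    return _sel


def heavy_selection() -> Callable[[Structure], np.ndarray]:
    """Select all non-hydrogen atoms."""
    return lambda s: s.heavy_mask()


def make_selection(spec: SelectionLike) -> Callable[[Structure], np.ndarray]:
    """Normalize a selection specifier to a mask-returning callable.

    Accepts ``None``/``"all"``, ``"heavy"``, ``"backbone"``, a sequence of
    residue labels (backbone of those residues), or a callable.
    """
    if spec is None or spec == "all":
        return lambda s: np.ones(s.n_atoms, dtype=bool)
    if spec == "heavy":
        return heavy_selection()
    if spec == "backbone":
        return backbone_selection()
    if callable(spec):
        return spec
    if isinstance(spec, (list, tuple)):
        return backbone_selection(spec)
    raise ValueError(f"unrecognized selection: {spec!r}")


def _selected_pair(mobile: Structure, reference: Structure,
                   selection: SelectionLike) -> tuple[np.ndarray, np.ndarray]:
    sel = make_selection(selection)
    mmask, rmask = sel(mobile), sel(reference)
    if mmask.sum() != rmask.sum():
        mlab = set(np.array(mobile.atom_labels(), dtype=object)[mmask])
        rlab = set(np.array(reference.atom_labels(), dtype=object)[rmask])
        missing = sorted(mlab.symmetric_difference(rlab))
        raise ValueError(
            "selection resolves to different atom counts in the two structures; "
            f"unmatched atoms: {missing}"
        )
    return mobile.coords[mmask], reference.coords[rmask]


# ---------------------------------------------------------------------------
# Superposition / RMSD
# ---------------------------------------------------------------------------

def _check_noncollinear(x: np.ndarray) -> None:
    if x.shape[0] < 3:
        raise ValueError("selection must resolve to at least 3 atoms")
    centered = x - x.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-8) < 2:
        raise ValueError("selected atoms are collinear; superposition is degenerate")


def kabsch_superpose(mobile: Structure, reference: Structure,
                     selection: SelectionLike = None
                     ) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` where
    ``x' = rotation @ (x - <mobile>) + <reference>`` maps selected mobile atoms
    onto the reference frame, ``translation`` is the net shift so that
    ``x' = rotation @ x + translation``, and ``rmsd`` (Å) is the least-squares
    minimum over all proper rigid transforms.
    """
    xm, xr = _selected_pair(mobile, reference, selection)
    _check_noncollinear(xm)
    _check_noncollinear(xr)
    cm, cr = xm.mean(axis=0), xr.mean(axis=0)
    rot, rssd = Rotation.align_vectors(xr - cr, xm - cm)
    R = rot.as_matrix()
    t = cr - R @ cm
    rmsd = float(rssd / np.sqrt(xm.shape[0]))
    return R, t, rmsd


def _batch_rmsd(ref_xyz: np.ndarray, mob_xyz: np.ndarray) -> np.ndarray:
    """Minimum RMSD of each frame in ``mob_xyz`` (F, N, 3) onto ``ref_xyz`` (N, 3).

    Vectorized Kabsch via batched SVD; proper rotations enforced by sign
    correction of the smallest singular value.
    """
    ref = ref_xyz - ref_xyz.mean(axis=0)
    mob = mob_xyz - mob_xyz.mean(axis=1, keepdims=True)
    n = ref.shape[0]
    # cross-covariance per frame
    H = np.einsum("fni,nj->fij", mob, ref)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U) * np.linalg.det(Vt)
    S_corr = S.copy()
    S_corr[:, -1] *= np.sign(det)
    ssd = (mob ** 2).sum(axis=(1, 2)) + (ref ** 2).sum() - 2.0 * S_corr.sum(axis=1)
    return np.sqrt(np.maximum(ssd, 0.0) / n)


def rmsd_series(traj: Trajectory, reference: Structure,
                selection: SelectionLike = "backbone",
                name: str = "rmsd") -> pd.DataFrame:
    """Per-frame superposition RMSD of a trajectory against a reference.

    The same selection restricts both the fit and the deviation. Returns a
    one-column table (Å) indexed by frame.
    """
    sel = make_selection(selection)
    tmask = sel(traj.frame(0))
    xm, xr = _selected_pair(traj.frame(0), reference, selection)
    _check_noncollinear(xr)
    values = _batch_rmsd(reference.coords[sel(reference)], traj.coords[:, tmask, :])
    return pd.DataFrame({name: values})


# ---------------------------------------------------------------------------
# Residue-center distances
# ---------------------------------------------------------------------------

def _center(structure: Structure, residue: str, mass_weighted: bool) -> np.ndarray:
    heavy = structure.heavy_mask()
    if residue == "C":
        mask = heavy
    else:
        mask = heavy & np.array([r == residue for r in structure.residues], dtype=bool)
        if not mask.any():
            raise ValueError(f"unknown residue label: {residue!r}")
    xyz = structure.coords[mask]
    if mass_weighted:
        w = np.array([_MASSES.get(e, 12.011) for e in structure.elements[mask]])
        return (xyz * w[:, None]).sum(axis=0) / w.sum()
    return xyz.mean(axis=0)


def centroid_distances(structure: Structure,
                       pairs: Sequence[tuple[str, str]],
                       mass_weighted: bool = False) -> pd.DataFrame:
    """Distances (Å) between residue heavy-atom geometric centers.

    Each pair names two residues, or a residue and ``"C"`` — the heavy-atom
    geometric center of the whole molecule (the convention behind per-residue
    "distance to centroid" columns). Set ``mass_weighted`` for mass-weighted
    centers instead of geometric ones.
    """
    rows = []
    for a, b in pairs:
        d = float(np.linalg.norm(_center(structure, a, mass_weighted)
                                 - _center(structure, b, mass_weighted)))
        rows.append({"pair": f"{a}-{b}", "distance": d})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Hydrogen-bond occupancy
# ---------------------------------------------------------------------------

def _donor_acceptor_tables(s: Structure) -> tuple[np.ndarray, np.ndarray, dict[int, list[int]]]:
    """Indices of candidate donors/acceptors (N, O heavy atoms) and, when the
    structure contains hydrogens, the covalently bonded hydrogens of each donor
    (same residue, within 1.25 Å)."""
    is_no = np.array([e in ("N", "O") for e in s.elements], dtype=bool) & s.heavy_mask()
    no_idx = np.flatnonzero(is_no)
    h_idx = np.flatnonzero(np.array([e == "H" for e in s.elements], dtype=bool))
    bonded: dict[int, list[int]] = {}
    if h_idx.size:
        for i in no_idx:
            same_res = [j for j in h_idx if s.residues[j] == s.residues[i]]
            if same_res:
                d = np.linalg.norm(s.coords[same_res] - s.coords[i], axis=1)
                close = [same_res[k] for k in np.flatnonzero(d <= 1.25)]
                if close:
                    bonded[int(i)] = close
    donors = np.array([i for i in no_idx if (not h_idx.size) or i in bonded], dtype=int)
    return donors, no_idx, bonded


def hbond_occupancy(structures: Sequence[Structure],
                    dist_cut: float = 3.5,
                    angle_cut: float = 135.0,
                    min_report: float = 50.0) -> list[HBondRecord]:
    """Percentage occupancy of hydrogen bonds over a structure set.

    Geometric criterion: donor–acceptor distance ≤ ``dist_cut`` Å and, when the
    structures contain hydrogens, donor–H–acceptor angle ≥ ``angle_cut`` degrees
    for at least one hydrogen bonded to the donor. Without hydrogens the
    distance criterion alone applies. Occupancy is the percentage of structures
    in which the criterion holds; contacts within one residue are excluded and
    records below ``min_report`` % are dropped.
    """
    if not structures:
        raise ValueError("structure set is empty")
    first = structures[0]
    donors, acceptors, bonded = _donor_acceptor_tables(first)
    if donors.size == 0 or acceptors.size == 0:
        return []
    labels = first.atom_labels()
    n_frames = len(structures)
    counts = np.zeros((donors.size, acceptors.size), dtype=int)
    same_res = np.array([[first.residues[d] == first.residues[a] for a in acceptors]
                         for d in donors], dtype=bool)
    use_angle = bool(bonded)
    for s in structures:
        dx = s.coords[donors][:, None, :] - s.coords[acceptors][None, :, :]
        dist_ok = (np.linalg.norm(dx, axis=2) <= dist_cut) & ~same_res
        if use_angle:
            ok = np.zeros_like(dist_ok)
            for di, d in enumerate(donors):
                acc_hits = np.flatnonzero(dist_ok[di])
                if acc_hits.size == 0:
                    continue
                for a_i in acc_hits:
                    a = acceptors[a_i]
                    for h in bonded[int(d)]:
                        v1 = s.coords[d] - s.coords[h]
                        v2 = s.coords[a] - s.coords[h]
                        cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
                        ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
                        if ang >= angle_cut:
                            ok[di, a_i] = True
                            break
            dist_ok = ok
        counts += dist_ok
    records = []
    for di, d in enumerate(donors):
        for ai, a in enumerate(acceptors):
            if int(d) == int(a):
                continue
            occ = 100.0 * counts[di, ai] / n_frames
            if occ >= min_report and occ > 0:
                hlab = labels[bonded[int(d)][0]] if use_angle else None
                records.append(HBondRecord(donor=labels[int(d)], acceptor=labels[int(a)],
                                           occupancy=occ, hydrogen=hlab))
    records.sort(key=lambda r: (-r.occupancy, r.donor, r.acceptor))
    return records


# ---------------------------------------------------------------------------
# Multi-model PDB I/O
# ---------------------------------------------------------------------------

def _residue_label(res_name: str, res_id: int) -> str:
    base = res_name.strip()
    if base.startswith("D") and len(base) > 1:
        base = base[1:]
    return f"{base[0]}{res_id}"


def _from_atom_array(arr) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    names = np.array([a.item() if hasattr(a, "item") else a for a in arr.atom_name], dtype=object)
    residues = np.array([_residue_label(rn, ri) for rn, ri in zip(arr.res_name, arr.res_id)],
                        dtype=object)
    elements = np.array([e if e else n[0] for e, n in zip(arr.element, arr.atom_name)],
                        dtype=object)
    return names, residues, elements


def read_structure(path: str | Path, model: int = 1) -> Structure:
    """Read a single model (1-based index) from a PDB file.

    ``model=12`` expresses "the twelfth frame" of a multi-model NMR deposition.
    """
    pdb = PDBFile.read(str(path))
    arr = pdb.get_structure(model=model)
    names, residues, elements = _from_atom_array(arr)
    return Structure(names, residues, elements, np.asarray(arr.coord, dtype=float))


def read_trajectory(path: str | Path, frame_interval: float = 1.0) -> Trajectory:
    """Read a multi-model PDB file as a trajectory (one model per frame)."""
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()  # AtomArrayStack
    arr0 = stack[0]
    names, residues, elements = _from_atom_array(arr0)
    return Trajectory(names, residues, elements,
                      np.asarray(stack.coord, dtype=float), frame_interval)


def _to_atom_array_stack(traj: Trajectory):
    n = traj.n_atoms
    arr = bst.AtomArray(n)
    res_ids, res_names = [], []
    for lab in traj.residues:
        base, idx = lab[0], int(lab[1:])
        res_ids.append(idx)
        res_names.append("D" + base if base in "GATC" else base)
    arr.res_id = np.array(res_ids, dtype=int)
    arr.res_name = np.array(res_names, dtype="U5")
    arr.atom_name = np.array(list(traj.atom_names), dtype="U6")
    arr.element = np.array(list(traj.elements), dtype="U2")
    arr.chain_id = np.array(["A"] * n, dtype="U4")
    arr.hetero = np.zeros(n, dtype=bool)
    stack = bst.stack([arr] * traj.n_frames)
    stack.coord = traj.coords.astype(np.float32)
    return stack


def write_trajectory(traj: Trajectory, path: str | Path) -> Path:
    """Write a trajectory as a multi-model PDB file (MODEL records per frame)."""
    path = Path(path)
    pdb = PDBFile()
    pdb.set_structure(_to_atom_array_stack(traj))
    pdb.write(str(path))
    return path


def write_structure(structure: Structure, path: str | Path) -> Path:
    """Write a single structure as a one-model PDB file."""
    traj = Trajectory(structure.atom_names, structure.residues, structure.elements,
                      structure.coords[None, :, :], 1.0)
    return write_trajectory(traj, path)
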