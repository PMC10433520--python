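"""Ensemble flexibility metrics: superposition, RMSD, B-factors, pairwise RMSF.

All metrics operate on an atom selection (backbone by default elsewhere in the
package) and superpose with the Kabsch algorithm before measuring, so rigid
body motion never registers as flexibility. B-factors use the crystallographic
convention B = (8 pi^2 / 3) * MSF with the mean-square fluctuation taken about
each atom's ensemble-mean position after superposing every frame onto the
first frame's selection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from corrdock.errors import StructureError
from corrdock.structure_io import Ensemble, Structure, select

BFACTOR_PREFACTOR = 8.0 * np.pi**2 / 3.0


@dataclass
class MetricSeries:
    """Labelled metric values: frame indices (RMSD) or residue ids (B, RMSF)."""

    labels: list
    values: np.ndarray
    subset: str
    units: str = "A"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.labels) != len(self.values):
            raise ValueError("labels and values length mismatch")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# subset={self.subset}\tunits={self.units}\n")
            fh.write("label\tvalue\n")
            for lab, val in zip(self.labels, self.values):
                fh.write(f"{lab}\t{val:.6f}\n")


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid superposition of ``mobile`` onto ``reference``.

    Returns ``(rotation, translation, rmsd)`` such that
    ``mobile @ rotation.T + translation`` minimizes the RMSD to the reference;
    the rotation is proper (det +1). Degenerate (collinear or tiny) point sets
    are rejected because the optimal rotation is then underdetermined.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise StructureError("mobile and reference must be matching (N, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise StructureError(f"superposition needs at least 3 points, got {n}")
    mc, rc = mobile.mean(axis=0), reference.mean(axis=0)
    x, y = mobile - mc, reference - rc
    if np.linalg.matrix_rank(x, tol=1e-8) < 2 or np.linalg.matrix_rank(y, tol=1e-8) < 2:
        raise StructureError("degenerate (collinear) point set; rotation underdetermined")
    u, _s, vt = np.linalg.svd(x.T @ y)
    d = np.sign(np.linalg.det(u @ vt))
    rotation = (u @ np.diag([1.0, 1.0, d]) @ vt).T
    translation = rc - rotation @ mc
    residual = (mobile @ rotation.T + translation) - reference
    rmsd = float(np.sqrt(np.mean(np.sum(residual**2, axis=1))))
    return rotation, translation, rmsd


def _subset_coords(structure: Structure, subset: str) -> tuple[np.ndarray, list[int]]:
    idx = select(structure, subset)
    return structure.coords[idx], idx


def rmsd_trace(ensemble: Ensemble, reference: Structure, subset: str = "backbone") -> MetricSeries:
    """Per-frame RMSD to a common reference after per-frame superposition."""
    ref_xyz, ref_idx = _subset_coords(reference, subset)
    values = []
    for k, frame in enumerate(ensemble.frames):
        xyz, idx = _subset_coords(frame, subset)
        if xyz.shape != ref_xyz.shape:
            raise StructureError(
                f"frame {k}: selection yields {xyz.shape[0]} atoms, reference has {ref_xyz.shape[0]}")
        _r, _t, rmsd = kabsch_superpose(xyz, ref_xyz)
        values.append(rmsd)
    return MetricSeries(labels=list(range(len(ensemble))), values=np.array(values), subset=subset)


def _superpose_frames(ensemble: Ensemble, subset: str) -> tuple[np.ndarray, list[int], Structure]:
    """Subset coordinates of every frame superposed onto frame 0's subset."""
    first = ensemble.frames[0]
    ref_xyz, idx = _subset_coords(first, subset)
    out = np.empty((len(ensemble), len(idx), 3))
    out[0] = ref_xyz
    for k, frame in enumerate(ensemble.frames[1:], start=1):
        xyz, fidx = _subset_coords(frame, subset)
        if xyz.shape != ref_xyz.shape:
            raise StructureError(
                f"frame {k}: selection yields {xyz.shape[0]} atoms, frame 0 has {ref_xyz.shape[0]}")
        rot, trans, _ = kabsch_superpose(xyz, ref_xyz)
        out[k] = xyz @ rot.T + trans
    return out, idx, first


def _per_residue(structure: Structure, idx: list[int], per_atom: np.ndarray,
                 reducer) -> tuple[list, np.ndarray]:
    keys: list = []
    groups: dict = {}
    for pos, atom_i in enumerate(idx):
        a = structure.atoms[atom_i]
        key = (a.chain, a.resid)
        if key not in groups:
            groups[key] = []
            keys.append(key)
        groups[key].append(pos)
    values = np.array([reducer(per_atom[groups[k]]) for k in keys])
    labels = [f"{c}/{r}" for c, r in keys]
    return labels, values


def bfactor_per_residue(ensemble: Ensemble, subset: str = "backbone") -> MetricSeries:
    """Computed B-factor per residue, in A^2.

    Per atom, MSF is the mean squared displacement from its mean position over
    the superposed frames; per residue, B = (8 pi^2 / 3) * mean MSF over the
    residue's selected atoms.
    """
    if len(ensemble) < 2:
        raise StructureError("B-factor analysis needs at least 2 frames")
    xyz, idx, first = _superpose_frames(ensemble, subset)
    mean_pos = xyz.mean(axis=0)
    msf = np.mean(np.sum((xyz - mean_pos) ** 2, axis=2), axis=0)
    labels, values = _per_residue(first, idx, BFACTOR_PREFACTOR * msf, np.mean)
    return MetricSeries(labels=labels, values=values, subset=subset, units="A^2")


def pairwise_rmsf(a: Structure, b: Structure, subset: str = "backbone") -> MetricSeries:
    """Per-residue RMSF between two structures (e.g. WT vs mutant endpoints).

    ``b`` is superposed onto ``a`` over the whole subset, so localized
    differences are measured in a common frame; each residue's value is the
    root-mean-square of its atoms' displacements.
    """
    a_xyz, a_idx = _subset_coords(a, subset)
    b_xyz, _b_idx = _subset_coords(b, subset)
    if a_xyz.shape != b_xyz.shape:
        raise StructureError(
            f"selection mismatch: {a_xyz.shape[0]} atoms in a vs {b_xyz.shape[0]} in b")
    rot, trans, _ = kabsch_superpose(b_xyz, a_xyz)
    moved = b_xyz @ rot.T + trans
    sq_disp = np.sum((moved - a_xyz) ** 2, axis=1)
    labels, values = _per_residue(a, a_idx, sq_disp, lambda v: float(np.sqrt(np.mean(v))))
    return MetricSeries(labels=labels, values=values, subset=subset)
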