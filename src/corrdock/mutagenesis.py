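"""Single-residue deletion mutants and peptide-junction regularization.

Deleting an internal residue (the F508del construction) leaves the flanking
backbone carbonyl carbon and amide nitrogen separated by a distorted gap —
3.36 A in the published construction — which must be closed into a plausible
peptide bond. Rather than a full force-field minimization, the junction is
regularized locally: steepest descent on a harmonic energy with a C-N bond
term and the two flanking backbone angle terms, moving only atoms of the two
junction residues. This is a deliberately desk-scale local regularizer, not
a molecular-mechanics minimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Iterable

import numpy as np

from corrdock.errors import StructureError
from corrdock.structure_io import Structure

# Engh-Huber ideal backbone angles at a trans peptide junction (degrees)
IDEAL_CA_C_N = 116.2
IDEAL_C_N_CA = 121.7
#: ideal trans peptide C-N bond length (A)
TARGET_BOND = 1.33


@dataclass
class Junction:
    """A declared new peptide junction after a deletion."""

    chain: str
    deleted_resid: int
    left_resid: int   # donates the carbonyl C
    right_resid: int  # accepts via the amide N

    def __post_init__(self) -> None:
        if not (self.left_resid < self.deleted_resid < self.right_resid):
            raise StructureError("junction residues must bracket the deleted residue in author numbering")


@dataclass
class JunctionReport:
    """Record of a deletion + regularization, serializable to JSON."""

    chain: str
    deleted_resid: int
    left_resid: int
    right_resid: int
    gap_before: float
    bond_after: float | None = None
    steps_run: int = 0
    converged: bool = False
    energy_trace: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)


def _cn_distance(structure: Structure, junction: Junction) -> float:
    c = structure.atoms[structure.atom_index(junction.chain, junction.left_resid, "C")].coords
    n = structure.atoms[structure.atom_index(junction.chain, junction.right_resid, "N")].coords
    return float(np.linalg.norm(c - n))


def delete_residue(structure: Structure, chain: str, resid: int) -> tuple[Structure, JunctionReport]:
    """Excise all atoms of one residue and declare the new junction.

    Both sequence neighbours (``resid - 1`` with a backbone C, ``resid + 1``
    with a backbone N) must exist; terminal residues leave no junction to
    rebuild and raise. ``gap_before`` is the flanking C...N distance.
    """
    if not structure.has_residue(chain, resid):
        raise StructureError(f"residue {chain}/{resid} not present; cannot delete")
    left, right = resid - 1, resid + 1
    for neighbour, atom in ((left, "C"), (right, "N")):
        if not structure.has_residue(chain, neighbour):
            raise StructureError(
                f"no junction possible: residue {chain}/{resid} lacks neighbour {neighbour}")
        try:
            structure.atom_index(chain, neighbour, atom)
        except StructureError:
            raise StructureError(
                f"no junction possible: neighbour {chain}/{neighbour} lacks backbone {atom}") from None
    doomed = set(structure.residue_atoms(chain, resid))
    kept = [a for i, a in enumerate(structure.atoms) if i not in doomed]
    mutant = Structure(kept)
    junction = Junction(chain, resid, left, right)
    report = JunctionReport(chain, resid, left, right, gap_before=_cn_distance(mutant, junction))
    return mutant, report


def _angle_energy(a: np.ndarray, b: np.ndarray, c: np.ndarray, theta0: float, k: float) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = np.arccos(np.clip(cosang, -1.0, 1.0))
    return k * (theta - np.deg2rad(theta0)) ** 2


def _junction_energy(coords: np.ndarray, idx: dict[str, int | None],
                     target_bond: float, k_bond: float, k_angle: float) -> float:
    c, n = coords[idx["C"]], coords[idx["N"]]
    energy = k_bond * (np.linalg.norm(c - n) - target_bond) ** 2
    if idx["CA_left"] is not None:
        energy += _angle_energy(coords[idx["CA_left"]], c, n, IDEAL_CA_C_N, k_angle)
    if idx["CA_right"] is not None:
        energy += _angle_energy(c, n, coords[idx["CA_right"]], IDEAL_C_N_CA, k_angle)
    return float(energy)


def regularize_junction(
    structure: Structure,
    junction: Junction | JunctionReport,
    target_bond: float = TARGET_BOND,
    k_bond: float = 10.0,
    k_angle: float = 2.0,
    step_size: float = 0.05,
    max_steps: int = 2000,
    tol: float = 1e-8,
) -> tuple[Structure, JunctionReport]:
    """Close a peptide junction by local steepest descent.

    The energy is harmonic: a C-N bond term toward ``target_bond`` (1.33 A,
    the ideal trans peptide bond) plus CA-C-N and C-N-CA angle terms toward
    sp2 ideals. Only atoms of the two junction residues move. The step is
    halved whenever it would raise the energy, so the accepted-energy trace
    is non-increasing by construction. Non-convergence within ``max_steps``
    is reported via ``converged=False``, never raised.
    """
    for name, value in (("target_bond", target_bond), ("k_bond", k_bond), ("k_angle", k_angle),
                        ("step_size", step_size), ("max_steps", max_steps), ("tol", tol)):
        if value < 0:
            raise ValueError(f"{name} must be non-negative, got {value}")
    chain = junction.chain
    left, right = junction.left_resid, junction.right_resid
    jun = Junction(chain, getattr(junction, "deleted_resid", (left + right) // 2), left, right)

    moving = structure.residue_atoms(chain, left) + structure.residue_atoms(chain, right)
    if not moving:
        raise StructureError(f"junction residues {left}/{right} have no atoms")
    coords = structure.coords

    def atom_or_none(resid: int, name: str) -> int | None:
        try:
            return structure.atom_index(chain, resid, name)
        except StructureError:
            return None

    idx = {
        "C": structure.atom_index(chain, left, "C"),
        "N": structure.atom_index(chain, right, "N"),
        "CA_left": atom_or_none(left, "CA"),
        "CA_right": atom_or_none(right, "CA"),
    }

    pts = coords[moving]
    dmat = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    np.fill_diagonal(dmat, np.inf)
    if np.any(dmat < 0.1):
        raise StructureError("overlapping atoms (< 0.1 A) at the junction; refusing to regularize")

    energy = _junction_energy(coords, idx, target_bond, k_bond, k_angle)
    trace = [energy]
    step = step_size
    steps_run = 0
    converged = False
    h = 1e-5
    for _ in range(max_steps):
        grad = np.zeros_like(coords)
        for i in moving:
            for ax in range(3):
                orig = coords[i, ax]
                coords[i, ax] = orig + h
                e_plus = _junction_energy(coords, idx, target_bond, k_bond, k_angle)
                coords[i, ax] = orig - h
                e_minus = _junction_energy(coords, idx, target_bond, k_bond, k_angle)
                coords[i, ax] = orig
                grad[i, ax] = (e_plus - e_minus) / (2 * h)
        gnorm = float(np.linalg.norm(grad))
        if gnorm < tol or energy < tol:
            converged = True
            break
        direction = -grad / gnorm
        # backtracking: halve the step until the energy does not increase
        accepted = False
        trial_step = step
        for _half in range(40):
            trial = coords + trial_step * direction
            e_new = _junction_energy(trial, idx, target_bond, k_bond, k_angle)
            if e_new <= energy:
                coords = trial
                energy = e_new
                accepted = True
                break
            trial_step *= 0.5
        steps_run += 1
        if not accepted:
            converged = True  # no descent direction at working precision
            break
        trace.append(energy)
        if len(trace) >= 2 and trace[-2] - trace[-1] < tol:
            converged = True
            break

    result = structure.with_coords(coords)
    report = JunctionReport(
        chain=chain,
        deleted_resid=jun.deleted_resid,
        left_resid=left,
        right_resid=right,
        gap_before=_cn_distance(structure, jun),
        bond_after=_cn_distance(result, jun),
        steps_run=steps_run,
        converged=converged,
        energy_trace=[float(e) for e in trace],
    )
    return result, report
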