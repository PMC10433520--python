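"""Synthetic inputs with the statistical and geometric structure the
analysis assumes.

Every generator is deterministic given its seed and produces data in the same
containers the real pipeline consumes. The default score specification ships
five sites by two systems with mixture shapes qualitatively matching the
study conditions — one narrow negative-mode site in the wild type, a second
one appearing only in the mutant, and wide mixed distributions reaching far
positive scores elsewhere. Synthetic draws are never a stand-in for real
docking output; they exercise the bookkeeping and the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from corrdock.errors import StructureError
from corrdock.mutagenesis import Junction
from corrdock.structure_io import AtomRecord, Ensemble, Structure
from corrdock.docking_adapter import ScoreRecord, ScoreSet
from corrdock.interaction_profile import LigandPose

# idealized backbone offsets (A) within one residue, extended-chain frame
_BACKBONE_OFFSETS = {
    "N": np.array([0.0, 0.0, 0.0]),
    "CA": np.array([1.46, 0.0, 0.0]),
    "C": np.array([2.19, 1.31, 0.0]),
    "O": np.array([1.66, 2.40, 0.2]),
}
_RESIDUE_ADVANCE = np.array([3.52, 0.0, 0.0])  # C(i) -> N(i+1) ~ 1.33 A


def synth_chain(n_res: int, geometry: str = "extended", seed: int = 0,
                chain: str = "A", start_resid: int = 1) -> Structure:
    """Backbone-only poly-alanine-like chain (N, CA, C, O per residue)."""
    if n_res < 1:
        raise ValueError("n_res must be >= 1")
    if geometry not in ("extended", "helix"):
        raise ValueError(f"unknown geometry {geometry!r}")
    atoms = []
    serial = 1
    for r in range(n_res):
        if geometry == "extended":
            # alternate a small zig in y so the chain is never collinear
            base = r * _RESIDUE_ADVANCE + np.array([0.0, 0.6 * (r % 2), 0.0])
        else:
            theta = np.deg2rad(100.0) * r
            base = np.array([2.3 * np.cos(theta), 2.3 * np.sin(theta), 1.5 * r])
        for name in ("N", "CA", "C", "O"):
            atoms.append(AtomRecord(
                serial=serial, name=name, element=name[0], resname="ALA",
                chain=chain, resid=start_resid + r,
                coords=base + _BACKBONE_OFFSETS[name]))
            serial += 1
    return Structure(atoms)


def synth_ensemble(base: Structure, n_frames: int, sigma_profile, seed: int = 0,
                   frame_spacing_ns: float = 10.0) -> Ensemble:
    """Jittered snapshot ensemble around ``base``; frame 0 is the base itself.

    ``sigma_profile`` gives each residue's isotropic per-axis fluctuation in
    A (scalar, or one value per residue in structure order).
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    residues = base.residues()
    sigma = np.broadcast_to(np.asarray(sigma_profile, dtype=float), (len(residues),))
    res_of_atom = {i: residues.index((a.chain, a.resid))
                   for i, a in enumerate(base.atoms)}
    per_atom_sigma = np.array([sigma[res_of_atom[i]] for i in range(len(base))])
    rng = np.random.default_rng(seed)
    frames = [base]
    coords = base.coords
    for _ in range(1, n_frames):
        jitter = rng.normal(0.0, 1.0, coords.shape) * per_atom_sigma[:, None]
        frames.append(base.with_coords(coords + jitter))
    return Ensemble(frames, frame_times=frame_spacing_ns * np.arange(n_frames))


SERIES_NAMES = ("VX-809", "ABBV-2222", "thiazole", "ARN")
#: planted per-series score offsets (kcal/mol): more negative binds better,
#: giving the fraction-negative ranking VX-809 > ABBV-2222 > thiazole > ARN
DEFAULT_SERIES_OFFSETS = {"VX-809": -1.5, "ABBV-2222": -0.5, "thiazole": 0.5, "ARN": 1.5}


@dataclass
class ScoreSpec:
    """Specification for the synthetic docking-score tensor.

    ``mixtures`` maps (site, system) to a list of components
    (mean kcal/mol, sd, weight); weights must sum to 1.
    """

    mixtures: dict[tuple[str, str], list[tuple[float, float, float]]]
    n_ligands: int = 220
    n_snapshots: int = 100
    series_offsets: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_SERIES_OFFSETS))
    seed: int = 0

    def __post_init__(self) -> None:
        for key, comps in self.mixtures.items():
            weights = np.array([w for _m, _s, w in comps])
            if abs(weights.sum() - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {key} must sum to 1")
            if any(s <= 0 for _m, s, _w in comps):
                raise ValueError(f"mixture sds for {key} must be positive")

    def ligand_series(self) -> dict[str, str]:
        names = list(self.series_offsets) or ["unassigned"]
        return {f"lig{i:04d}": names[i % len(names)] for i in range(self.n_ligands)}


def default_score_spec(seed: int = 0, n_ligands: int = 220, n_snapshots: int = 100) -> ScoreSpec:
    """Five sites x two systems, shaped like the study conditions.

    Signs and orderings only: one narrow negative-mode site (MSD1) in both
    systems — broader and weaker in the mutant — a sharp high-probability
    negative site appearing only in the mutant (NBD1_alt), and wide,
    predominantly positive distributions everywhere else.
    """
    mix = {
        ("MSD1", "WT"): [(-4.2, 0.8, 0.8), (6.0, 3.0, 0.2)],
        ("MSD1", "MT"): [(-4.6, 1.6, 0.55), (9.0, 6.0, 0.45)],
        ("MSD1_alt", "WT"): [(-5.0, 1.0, 0.04), (20.0, 9.0, 0.96)],
        ("MSD1_alt", "MT"): [(-5.5, 1.0, 0.03), (29.6, 12.0, 0.97)],
        ("NBD1", "WT"): [(-0.5, 0.6, 0.01), (54.3, 15.0, 0.99)],
        ("NBD1", "MT"): [(119.4, 30.0, 1.0)],
        ("NBD1_alt", "WT"): [(83.1, 22.0, 1.0)],
        ("NBD1_alt", "MT"): [(-5.9, 0.5, 0.85), (3.0, 3.0, 0.15)],
        ("ICL4", "WT"): [(-4.0, 2.0, 0.02), (5.3, 5.0, 0.98)],
        ("ICL4", "MT"): [(-3.5, 1.8, 0.03), (20.1, 10.0, 0.97)],
    }
    return ScoreSpec(mixtures=mix, n_ligands=n_ligands, n_snapshots=n_snapshots, seed=seed)


def synth_scores(spec: ScoreSpec) -> ScoreSet:
    """Draw the full (ligand x snapshot) score tensor for every (site, system)."""
    rng = np.random.default_rng(spec.seed)
    series_of = spec.ligand_series()
    records = []
    for (site, system), comps in spec.mixtures.items():
        means = np.array([m for m, _s, _w in comps])
        sds = np.array([s for _m, s, _w in comps])
        weights = np.array([w for _m, _s, w in comps])
        n = spec.n_ligands * spec.n_snapshots
        choice = rng.choice(len(comps), size=n, p=weights)
        draws = rng.normal(means[choice], sds[choice])
        k = 0
        for lig, series in series_of.items():
            offset = spec.series_offsets.get(series, 0.0)
            for snap in range(spec.n_snapshots):
                records.append(ScoreRecord(lig, series, system, site, snap,
                                           float(draws[k] + offset)))
                k += 1
    sites = sorted({s for s, _ in spec.mixtures})
    systems = sorted({y for _, y in spec.mixtures})
    return ScoreSet(records, dims={"n_ligands": spec.n_ligands,
                                   "n_snapshots": spec.n_snapshots,
                                   "sites": sites, "systems": systems})


def synth_junction(gap: float, chain: str = "A", left_resid: int = 507,
                   right_resid: int = 509) -> tuple[Structure, Junction]:
    """Two flanking backbone residues with the C...N distance exactly ``gap``.

    The residue numbering leaves a hole where the deleted residue sat, as a
    real deletion construct would; the junction geometry is deliberately
    strained (collinear-ish angles) so a regularizer has work to do.
    """
    if gap <= 0:
        raise ValueError("gap must be positive")
    left = synth_chain(1, seed=0, chain=chain, start_resid=left_resid)
    right = synth_chain(1, seed=0, chain=chain, start_resid=right_resid)
    c_pos = left.atoms[left.atom_index(chain, left_resid, "C")].coords
    shift = (c_pos + np.array([gap, 0.0, 0.0])) - right.atoms[right.atom_index(chain, right_resid, "N")].coords
    atoms = list(left.atoms) + [
        AtomRecord(a.serial + 4, a.name, a.element, a.resname, a.chain, a.resid,
                   a.coords + shift)
        for a in right.atoms
    ]
    structure = Structure(atoms)
    measured = np.linalg.norm(
        structure.atoms[structure.atom_index(chain, right_resid, "N")].coords
        - structure.atoms[structure.atom_index(chain, left_resid, "C")].coords)
    if abs(measured - gap) > 1e-6:
        raise StructureError("junction construction failed to hit the requested gap")
    return structure, Junction(chain, (left_resid + right_resid) // 2, left_resid, right_resid)


@dataclass
class PosePlanting:
    """What to plant in a synthetic docked pose."""

    n_hbonds: int = 0
    n_contacts: int = 0
    n_clashes: int = 0
    bridge: bool = False
    bridge_span: float = 11.0


def synth_docked_pose(planting: PosePlanting) -> tuple[Structure, LigandPose]:
    """Protein fragment + ligand pose with each planted interaction strictly
    inside its detection window and everything else far outside.

    Planted units sit 30 A apart so no cross-unit pair can register. A
    planted bridge contributes its own residue with two nitrogen hbond
    partners (backbone-plus-sidechain, lysine-style) to ligand atoms
    ``bridge_span`` apart — so it adds 2 to the hydrogen-bond total.
    """
    atoms: list[AtomRecord] = []
    lig_coords: list[np.ndarray] = []
    lig_elements: list[str] = []
    serial = 1
    resid = 1

    def add_atom(name: str, element: str, pos: np.ndarray, resname: str = "ALA",
                 advance: bool = True) -> None:
        nonlocal serial, resid
        atoms.append(AtomRecord(serial, name, element, resname, "A", resid,
                                np.asarray(pos, dtype=float)))
        serial += 1
        if advance:
            resid += 1

    def add_lig(element: str, pos) -> None:
        lig_coords.append(np.asarray(pos, dtype=float))
        lig_elements.append(element)

    x = 0.0
    for _ in range(planting.n_hbonds):
        add_atom("O", "O", [x, 0.0, 0.0])
        add_lig("N", [x, 2.8, 0.0])
        x += 30.0
    for _ in range(planting.n_contacts):
        add_atom("CB", "C", [x, 0.0, 0.0])
        add_lig("C", [x, 3.5, 0.0])
        x += 30.0
    for _ in range(planting.n_clashes):
        add_atom("CG", "C", [x, 0.0, 0.0])
        add_lig("C", [x, 1.4, 0.0])
        x += 30.0
    if planting.bridge:
        span = planting.bridge_span
        add_atom("N", "N", [x, 0.0, 0.0], resname="LYS", advance=False)
        add_atom("NZ", "N", [x + span, 0.0, 0.0], resname="LYS")
        add_lig("O", [x, 2.8, 0.0])
        add_lig("O", [x + span, 2.8, 0.0])
        x += span + 30.0
    if not atoms:
        # far-apart protein/ligand pair: a well-separated pose, empty report
        add_atom("CA", "C", [0.0, 0.0, 0.0])
        add_lig("C", [50.0, 50.0, 50.0])
    if not lig_coords:
        add_lig("C", [x + 50.0, 50.0, 50.0])
    return Structure(atoms), LigandPose(np.asarray(lig_coords), lig_elements)
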