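"""LIGPLOT-style protein-ligand interaction profiling for a docked pose.

Hydrogen bonds use a hydrogen-free, element-typed donor/acceptor criterion
(protein N/O/S vs ligand N/O/F, donor-acceptor distance <= 3.35 A); fluorine
counts as a weak acceptor because fluorinated corrector ends do hydrogen-bond
in these pockets. Nonbonded contacts are residue-level heavy-atom approaches
within 3.90 A; pairs at covalent distance (<= 1.90 A) are flagged as clash
artifacts of the kind interaction-diagram tools draw as spurious bonds when
docking jams a ligand into a closed pocket. A residue whose atoms hydrogen-
bond to ligand atoms at opposite ends of the molecule (mutual distance >=
8 A) is reported as *bridging* — the K464 backbone-plus-sidechain motif.
All cutoffs are conventional stand-ins for LIGPLOT's defaults and are fully
configurable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.spatial.distance import cdist

from corrdock.errors import StructureError
from corrdock.structure_io import Structure

PROTEIN_POLAR = {"N", "O", "S"}
LIGAND_POLAR = {"N", "O", "F"}


@dataclass
class InteractionParams:
    hbond_da_max: float = 3.35   # donor-acceptor cutoff, A
    contact_max: float = 3.90    # nonbonded contact cutoff, A
    clash_max: float = 1.90      # apparent covalent contact, A
    bridge_span_min: float = 8.0  # "opposite ends" span, A

    def __post_init__(self) -> None:
        if not (self.clash_max < self.hbond_da_max < self.contact_max):
            raise ValueError("require clash_max < hbond_da_max < contact_max")


@dataclass
class LigandPose:
    """Heavy-atom ligand pose: coordinates, element per atom, optional names."""

    coords: np.ndarray
    elements: list[str]
    names: list[str] | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3 or self.coords.shape[0] == 0:
            raise StructureError("pose coords must be a non-empty (N, 3) array")
        if len(self.elements) != len(self.coords):
            raise StructureError("pose elements length mismatch")
        if self.names is None:
            self.names = [f"{el}{i+1}" for i, el in enumerate(self.elements)]


@dataclass
class HBond:
    residue: str          # "chain/resid RESNAME"
    protein_atom: str
    ligand_atom: str
    ligand_index: int
    distance: float


@dataclass
class Contact:
    residue: str
    protein_atom: str
    ligand_atom: str
    distance: float


@dataclass
class Clash:
    residue: str
    protein_atom: str
    ligand_atom: str
    distance: float


@dataclass
class InteractionReport:
    hbonds: list[HBond] = field(default_factory=list)
    contacts: list[Contact] = field(default_factory=list)
    clashes: list[Clash] = field(default_factory=list)
    bridging_residues: list[str] = field(default_factory=list)

    def totals(self) -> tuple[int, int, int]:
        return len(self.hbonds), len(self.contacts), len(self.clashes)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)
            fh.write("\n")

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("type\tresidue\tprotein_atom\tligand_atom\tdistance\n")
            for kind, items in (("hbond", self.hbonds), ("contact", self.contacts),
                                ("clash", self.clashes)):
                for it in items:
                    fh.write(f"{kind}\t{it.residue}\t{it.protein_atom}\t{it.ligand_atom}\t{it.distance:.3f}\n")


def _protein_arrays(protein: Structure):
    idx = [i for i, a in enumerate(protein.atoms)
           if a.element != "H" and not a.hetero]
    coords = protein.coords[idx] if idx else np.empty((0, 3))
    return idx, coords


def _res_label(atom) -> str:
    return f"{atom.chain}/{atom.resid} {atom.resname}"


def _pair_distances(protein: Structure, pose: LigandPose):
    pidx, pxyz = _protein_arrays(protein)
    dists = cdist(pxyz, pose.coords) if len(pidx) else np.empty((0, len(pose.coords)))
    return pidx, dists


def detect_hbonds(protein: Structure, pose: LigandPose,
                  params: InteractionParams | None = None) -> list[HBond]:
    """Element-typed hydrogen bonds: protein N/O/S vs ligand N/O/F within the
    donor-acceptor window (clash_max, hbond_da_max]."""
    params = params or InteractionParams()
    pidx, dists = _pair_distances(protein, pose)
    out = []
    for row, i in enumerate(pidx):
        atom = protein.atoms[i]
        if atom.element not in PROTEIN_POLAR:
            continue
        for j in range(len(pose.coords)):
            if pose.elements[j] not in LIGAND_POLAR:
                continue
            d = dists[row, j]
            if params.clash_max < d <= params.hbond_da_max:
                out.append(HBond(_res_label(atom), atom.name, pose.names[j], j, float(d)))
    return out


def detect_contacts(protein: Structure, pose: LigandPose,
                    params: InteractionParams | None = None) -> list[Contact]:
    """Residue-level nonbonded contacts: closest heavy-atom approach within
    contact_max, excluding atom pairs already reported as hydrogen bonds or
    clashes (the three interaction classes are disjoint)."""
    params = params or InteractionParams()
    hb_pairs = {(h.residue, h.protein_atom, h.ligand_index)
                for h in detect_hbonds(protein, pose, params)}
    pidx, dists = _pair_distances(protein, pose)
    best: dict[str, Contact] = {}
    for row, i in enumerate(pidx):
        atom = protein.atoms[i]
        label = _res_label(atom)
        for j in range(len(pose.coords)):
            d = float(dists[row, j])
            if d > params.contact_max or d <= params.clash_max:
                continue
            if (label, atom.name, j) in hb_pairs:
                continue
            if label not in best or d < best[label].distance:
                best[label] = Contact(label, atom.name, pose.names[j], d)
    return [best[k] for k in best]


def detect_clashes(protein: Structure, pose: LigandPose,
                   params: InteractionParams | None = None) -> list[Clash]:
    """Heavy-atom pairs at apparent covalent distance (<= clash_max) — the
    spurious-bond artifact of poses jammed into closed pockets."""
    params = params or InteractionParams()
    pidx, dists = _pair_distances(protein, pose)
    out = []
    for row, i in enumerate(pidx):
        atom = protein.atoms[i]
        for j in range(len(pose.coords)):
            d = float(dists[row, j])
            if d <= params.clash_max:
                out.append(Clash(_res_label(atom), atom.name, pose.names[j], d))
    return out


def binding_profile(protein: Structure, pose: LigandPose,
                    params: InteractionParams | None = None) -> InteractionReport:
    """Full interaction report: hbonds, contacts, clashes, bridging residues.

    A residue bridges when it donates/accepts >= 2 hydrogen bonds to ligand
    atoms whose mutual distance is at least ``bridge_span_min``.
    """
    params = params or InteractionParams()
    hbonds = detect_hbonds(protein, pose, params)
    contacts = detect_contacts(protein, pose, params)
    clashes = detect_clashes(protein, pose, params)
    by_res: dict[str, list[int]] = {}
    for h in hbonds:
        by_res.setdefault(h.residue, []).append(h.ligand_index)
    bridging = []
    for residue, lig_atoms in by_res.items():
        uniq = sorted(set(lig_atoms))
        if len(uniq) < 2:
            continue
        span = cdist(pose.coords[uniq], pose.coords[uniq]).max()
        if span >= params.bridge_span_min:
            bridging.append(residue)
    return InteractionReport(hbonds=hbonds, contacts=contacts, clashes=clashes,
                             bridging_residues=sorted(bridging))
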