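"""Protein structures and snapshot ensembles in PDB format.

Reading and writing delegate to biotite; this module wraps its arrays behind
ordered :class:`AtomRecord` lists keyed by author residue numbering, which is
never renumbered — residue identifiers like F508 or K464 must mean what they
mean in the deposited structure. Alternate locations are resolved to the
highest-occupancy conformer (ties keep the first listed). HETATM records are
read but excluded from protein selections by default, mirroring the usual
practice of stripping lipids, waters and ions before docking.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import biotite.structure as bst
import biotite.structure.io.pdb as bpdb

from corrdock.errors import ParseError, SelectionError, StructureError

BACKBONE_ATOMS = ("N", "CA", "C", "O")

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "DOD"}


@dataclass
class AtomRecord:
    """One atom: author numbering, element, coordinates in Angstrom."""

    serial: int
    name: str
    element: str
    resname: str
    chain: str
    resid: int
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""
    hetero: bool = False

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise StructureError(f"atom {self.serial} {self.name}: coords must be a finite 3-vector")
        if not self.element:
            self.element = _infer_element(self.name)
        if self.occupancy is not None and not (0.0 <= self.occupancy <= 1.0):
            raise StructureError(f"atom {self.serial} {self.name}: occupancy {self.occupancy} outside [0, 1]")


class Structure:
    """An ordered list of atoms with a (chain, resid) residue index."""

    def __init__(self, atoms: Iterable[AtomRecord]):
        self.atoms: list[AtomRecord] = list(atoms)
        self._residue_index: dict[tuple[str, int], list[int]] = {}
        seen: set[tuple[str, int, str]] = set()
        for i, atom in enumerate(self.atoms):
            key = (atom.chain, atom.resid, atom.name)
            if key in seen:
                raise StructureError(f"duplicate atom {key} after altloc resolution")
            seen.add(key)
            self._residue_index.setdefault((atom.chain, atom.resid), []).append(i)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        """(n_atoms, 3) coordinate array in Angstrom."""
        return np.array([a.coords for a in self.atoms], dtype=float)

    def residues(self) -> list[tuple[str, int]]:
        """(chain, resid) keys in order of first appearance."""
        return list(self._residue_index)

    def residue_atoms(self, chain: str, resid: int) -> list[int]:
        """Atom indices of one residue; empty list if absent."""
        return list(self._residue_index.get((chain, resid), []))

    def has_residue(self, chain: str, resid: int) -> bool:
        return (chain, resid) in self._residue_index

    def atom_index(self, chain: str, resid: int, name: str) -> int:
        for i in self.residue_atoms(chain, resid):
            if self.atoms[i].name == name:
                return i
        raise StructureError(f"atom {name} not found in residue {chain}/{resid}")

    def with_coords(self, coords: np.ndarray) -> "Structure":
        """Copy of the structure with replaced coordinates."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise StructureError("coordinate array shape does not match atom count")
        new = [
            AtomRecord(a.serial, a.name, a.element, a.resname, a.chain, a.resid,
                       coords[i].copy(), a.occupancy, a.altloc, a.hetero)
            for i, a in enumerate(self.atoms)
        ]
        return Structure(new)


@dataclass
class Ensemble:
    """Snapshot ensemble: frames with identical atom ordering, times in ns."""

    frames: list[Structure]
    frame_times: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.frames:
            raise StructureError("ensemble must contain at least one frame")
        ref = [(a.chain, a.resid, a.name) for a in self.frames[0].atoms]
        for k, frame in enumerate(self.frames[1:], start=1):
            keys = [(a.chain, a.resid, a.name) for a in frame.atoms]
            if keys != ref:
                raise StructureError(f"frame {k} atom ordering differs from frame 0")
        if self.frame_times is None:
            self.frame_times = 10.0 * np.arange(len(self.frames))
        self.frame_times = np.asarray(self.frame_times, dtype=float)
        if len(self.frame_times) != len(self.frames):
            raise StructureError("frame_times length does not match frame count")
        if len(self.frame_times) > 1 and not np.all(np.diff(self.frame_times) > 0):
            raise StructureError("frame_times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)

    def coords(self) -> np.ndarray:
        """(n_frames, n_atoms, 3) coordinate tensor."""
        return np.stack([f.coords for f in self.frames])


def _infer_element(name: str) -> str:
    """Element from an atom name, PDB convention (first alphabetic character;
    leading digits as in '1HB' are remoteness markers, not elements)."""
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise StructureError(f"cannot infer element from atom name {name!r}")
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "NA", "MN"}:
        return stripped[:2].capitalize()
    return stripped[0].upper()


def _prevalidate(text: str, path: str) -> None:
    n_atoms = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")):
            n_atoms += 1
            if len(line) < 54:
                raise ParseError(f"{path}, line {lineno}: ATOM/HETATM record shorter than coordinate fields")
            for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
                try:
                    float(line[lo:hi])
                except ValueError:
                    raise ParseError(f"{path}, line {lineno}: unparseable {what} coordinate {line[lo:hi]!r}") from None
    if n_atoms == 0:
        raise ParseError(f"{path}: empty structure (no ATOM/HETATM records)")


def _from_atom_array(arr: bst.AtomArray) -> Structure:
    serials = arr.atom_id if "atom_id" in arr.get_annotation_categories() else np.arange(1, len(arr) + 1)
    occ = arr.occupancy if "occupancy" in arr.get_annotation_categories() else np.ones(len(arr))
    records = [
        AtomRecord(
            serial=int(serials[i]),
            name=str(arr.atom_name[i]),
            element=str(arr.element[i]).capitalize(),
            resname=str(arr.res_name[i]),
            chain=str(arr.chain_id[i]),
            resid=int(arr.res_id[i]),
            coords=arr.coord[i],
            occupancy=float(np.clip(occ[i], 0.0, 1.0)),
            hetero=bool(arr.hetero[i]),
        )
        for i in range(len(arr))
    ]
    return Structure(records)


def read_pdb(path: str | Path) -> Structure:
    """Read a single-model PDB file.

    Altlocs are resolved to the highest-occupancy conformer; blank element
    columns are inferred from atom names; atoms keep file order and author
    residue numbers.
    """
    path = Path(path)
    text = path.read_text()
    _prevalidate(text, str(path))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # element guessing is intended
        pdbfile = bpdb.PDBFile.read(path)
        try:
            arr = pdbfile.get_structure(model=1, altloc="occupancy",
                                        extra_fields=["occupancy", "atom_id"])
        except Exception as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if len(arr) == 0:
        raise ParseError(f"{path}: empty structure (no ATOM/HETATM records)")
    return _from_atom_array(arr)


def _to_atom_array(structure: Structure) -> bst.AtomArray:
    n = len(structure)
    if n == 0:
        raise StructureError("cannot write a structure with no atoms")
    arr = bst.AtomArray(n)
    arr.coord = structure.coords
    arr.chain_id = np.array([a.chain for a in structure.atoms])
    arr.res_id = np.array([a.resid for a in structure.atoms])
    arr.res_name = np.array([a.resname for a in structure.atoms])
    arr.atom_name = np.array([a.name for a in structure.atoms])
    arr.element = np.array([a.element.upper() for a in structure.atoms])
    arr.hetero = np.array([a.hetero for a in structure.atoms])
    arr.set_annotation("occupancy", np.array([a.occupancy for a in structure.atoms]))
    arr.set_annotation("b_factor", np.zeros(n))
    # serials renumbered 1..N on write
    arr.set_annotation("atom_id", np.arange(1, n + 1))
    return arr


def write_pdb(structure: Structure, path: str | Path) -> None:
    """Write fixed-width PDB ATOM/HETATM records, coordinates to 3 decimals.

    Serials are renumbered 1..N; author chain/residue numbering is preserved.
    """
    pdbfile = bpdb.PDBFile()
    pdbfile.set_structure(_to_atom_array(structure))
    pdbfile.write(Path(path))


def read_ensemble(source: str | Path, frame_times: Sequence[float] | None = None) -> Ensemble:
    """Read a snapshot ensemble.

    ``source`` is either a multi-model PDB (MODEL/ENDMDL) or a manifest TSV
    with columns ``path`` and optional ``time_ns`` (paths relative to the
    manifest's directory). Default times are 10 ns apart, the usual snapshot
    spacing for a 1 us trajectory sampled at 100 frames.
    """
    source = Path(source)
    if source.suffix.lower() in {".tsv", ".txt", ".manifest"}:
        frames, times = [], []
        lines = [ln for ln in source.read_text().splitlines() if ln.strip() and not ln.startswith("#")]
        header = lines[0].split("\t")
        if "path" not in header:
            raise ParseError(f"{source}: ensemble manifest needs a 'path' column")
        ipath = header.index("path")
        itime = header.index("time_ns") if "time_ns" in header else None
        for ln in lines[1:]:
            cells = ln.split("\t")
            frames.append(read_pdb(source.parent / cells[ipath]))
            if itime is not None:
                times.append(float(cells[itime]))
        return Ensemble(frames, np.array(times) if times else frame_times)
    text = source.read_text()
    _prevalidate(text, str(source))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pdbfile = bpdb.PDBFile.read(source)
        try:
            stack = pdbfile.get_structure(altloc="occupancy", extra_fields=["occupancy", "atom_id"])
        except Exception as exc:
            raise ParseError(f"{source}: {exc}") from exc
    if stack.array_length() == 0:
        raise ParseError(f"{source}: empty structure (no ATOM/HETATM records)")
    frames = [_from_atom_array(stack[i]) for i in range(stack.stack_depth())]
    return Ensemble(frames, frame_times)


_RESID_RE = re.compile(r"^(-?\d+)(?:-(-?\d+))?$")


def select(structure: Structure, spec: str, include_hetero: bool = False) -> list[int]:
    """Resolve a selection expression to an ordered atom index list.

    Clauses joined by ``and``: ``backbone`` (atom names N, CA, C, O),
    ``protein`` (non-HETATM), ``chain A``, ``resid 507-509`` (comma-separated
    ranges allowed), ``name CA,CB``. An empty result is valid; a malformed
    expression raises :class:`SelectionError`. HETATM atoms and waters are
    excluded unless ``include_hetero`` is set.
    """
    if not isinstance(spec, str) or not spec.strip():
        raise SelectionError("selection expression must be a non-empty string")
    keep = np.ones(len(structure), dtype=bool)
    if not include_hetero:
        keep &= np.array([not a.hetero and a.resname not in _WATER_RESNAMES
                          for a in structure.atoms], dtype=bool)
    for clause in re.split(r"\s+and\s+", spec.strip()):
        tokens = clause.split(None, 1)
        head = tokens[0].lower()
        if head == "backbone" and len(tokens) == 1:
            keep &= np.array([a.name in BACKBONE_ATOMS for a in structure.atoms])
        elif head == "protein" and len(tokens) == 1:
            keep &= np.array([not a.hetero for a in structure.atoms])
        elif head == "chain" and len(tokens) == 2:
            chains = {c.strip() for c in tokens[1].split(",")}
            keep &= np.array([a.chain in chains for a in structure.atoms])
        elif head == "name" and len(tokens) == 2:
            names = {c.strip().upper() for c in tokens[1].split(",")}
            keep &= np.array([a.name.upper() in names for a in structure.atoms])
        elif head == "resid" and len(tokens) == 2:
            wanted: set[int] = set()
            for part in tokens[1].split(","):
                m = _RESID_RE.match(part.strip())
                if not m:
                    raise SelectionError(f"malformed resid term {part!r} in {spec!r}")
                lo = int(m.group(1))
                hi = int(m.group(2)) if m.group(2) is not None else lo
                wanted.update(range(lo, hi + 1))
            keep &= np.array([a.resid in wanted for a in structure.atoms])
        else:
            raise SelectionError(f"malformed selection clause {clause!r}")
    return [int(i) for i in np.flatnonzero(keep)]
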