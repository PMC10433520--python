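"""Residue-defined docking grid boxes.

A binding site is a named residue list; its grid box is a cube (default edge
10 A) centred on the unweighted centroid of the listed residues' heavy atoms.
Centres can be recomputed per snapshot so the box tracks pocket drift across
an ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from corrdock.errors import StructureError
from corrdock.structure_io import Ensemble, Structure

DEFAULT_EDGE = 10.0


@dataclass
class SiteDefinition:
    name: str
    residues: list[tuple[str, int]]
    center: np.ndarray
    edge: float = DEFAULT_EDGE

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.edge <= 0:
            raise ValueError(f"site {self.name}: edge must be positive")
        if not self.residues:
            raise ValueError(f"site {self.name}: residue list is empty")
        if self.center.shape != (3,) or not np.all(np.isfinite(self.center)):
            raise ValueError(f"site {self.name}: center must be a finite 3-vector")


def compute_center(structure: Structure, residues: list[tuple[str, int]]) -> np.ndarray:
    """Unweighted heavy-atom centroid of the listed residues, in A."""
    coords = []
    for chain, resid in residues:
        idx = structure.residue_atoms(chain, resid)
        if not idx:
            raise StructureError(f"site residue {chain}/{resid} missing from structure")
        coords.extend(structure.atoms[i].coords for i in idx
                      if structure.atoms[i].element != "H")
    if not coords:
        raise StructureError("site residues contain no heavy atoms")
    return np.mean(np.asarray(coords), axis=0)


def build_sites(structure: Structure, spec: list[dict] | str | Path) -> list[SiteDefinition]:
    """Build SiteDefinitions from a site spec (list of dicts, or YAML path).

    Each entry: ``{name, chain, resids: [..], edge?}``; the default edge is
    10 A. Duplicate site names raise.
    """
    if isinstance(spec, (str, Path)):
        spec = yaml.safe_load(Path(spec).read_text())
    if not spec:
        raise ValueError("site spec lists no sites")
    seen: set[str] = set()
    sites = []
    for entry in spec:
        name = entry["name"]
        if name in seen:
            raise ValueError(f"duplicate site name {name!r}")
        seen.add(name)
        residues = [(entry.get("chain", "A"), int(r)) for r in entry["resids"]]
        sites.append(SiteDefinition(
            name=name,
            residues=residues,
            center=compute_center(structure, residues),
            edge=float(entry.get("edge", DEFAULT_EDGE)),
        ))
    return sites


def site_centers(ensemble: Ensemble, site: SiteDefinition) -> np.ndarray:
    """(n_frames, 3) per-snapshot grid-box centres for one site."""
    return np.stack([compute_center(frame, site.residues) for frame in ensemble.frames])


def centers_to_tsv(ensemble: Ensemble, sites: list[SiteDefinition], path) -> None:
    with open(path, "w") as fh:
        fh.write("site\tframe\ttime_ns\tx\ty\tz\tedge\n")
        for site in sites:
            for k, c in enumerate(site_centers(ensemble, site)):
                t = ensemble.frame_times[k]
                fh.write(f"{site.name}\t{k}\t{t:g}\t{c[0]:.3f}\t{c[1]:.3f}\t{c[2]:.3f}\t{site.edge:g}\n")
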