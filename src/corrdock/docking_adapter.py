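"""Parse batch AutoDock-Vina outputs into score records.

The scoring function is never re-derived: Vina's reported affinities are
collected verbatim (including implausibly positive ones — pooled ensemble
distributions legitimately extend far above zero when a pocket cannot
accommodate a ligand). Each (ligand, system, site, snapshot) run contributes
one record, the rank-1 (most favourable) pose affinity.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from corrdock.errors import ParseError

COLUMNS = ["ligand_id", "series", "system", "site", "snapshot", "dg", "n_poses"]


@dataclass(frozen=True)
class ScoreRecord:
    """Top-pose binding score for one docking run (kcal/mol)."""

    ligand_id: str
    series: str
    system: str
    site: str
    snapshot: int
    dg: float
    n_poses: int = 1

    def __post_init__(self) -> None:
        if self.snapshot < 0:
            raise ValueError("snapshot index must be >= 0")
        if not np.isfinite(self.dg):
            raise ValueError("binding score must be finite")


class ScoreSet:
    """Pooled collection of score records with declared dimensions.

    Backed by a pandas DataFrame (columns ``ligand_id, series, system, site,
    snapshot, dg, n_poses``); the key (ligand, system, site, snapshot) is
    unique.
    """

    def __init__(self, records: Iterable[ScoreRecord] | pd.DataFrame,
                 dims: dict | None = None):
        if isinstance(records, pd.DataFrame):
            df = records[COLUMNS].copy()
        else:
            df = pd.DataFrame([vars(r) for r in records], columns=COLUMNS)
        df["snapshot"] = df["snapshot"].astype(int)
        key = df[["ligand_id", "system", "site", "snapshot"]]
        dup = key.duplicated()
        if dup.any():
            first = df[dup].iloc[0]
            raise ValueError(
                f"duplicate score record for ligand={first.ligand_id} system={first.system} "
                f"site={first.site} snapshot={first.snapshot}")
        self.df = df.reset_index(drop=True)
        self.dims = dims or {
            "n_ligands": df["ligand_id"].nunique(),
            "n_snapshots": df["snapshot"].nunique(),
            "sites": sorted(df["site"].unique().tolist()),
            "systems": sorted(df["system"].unique().tolist()),
        }

    def __len__(self) -> int:
        return len(self.df)

    def subset(self, site: str | None = None, system: str | None = None) -> pd.DataFrame:
        df = self.df
        if site is not None:
            df = df[df["site"] == site]
        if system is not None:
            df = df[df["system"] == system]
        return df

    def completeness(self) -> pd.DataFrame:
        """Per-(site, system) record counts vs the declared full grid."""
        expected = self.dims.get("n_ligands", 0) * self.dims.get("n_snapshots", 0)
        counts = (self.df.groupby(["site", "system"], sort=True)
                  .size().rename("n_records").reset_index())
        counts["expected"] = expected
        counts["complete"] = counts["n_records"] == expected
        return counts

    def to_tsv(self, path: str | Path) -> None:
        path = Path(path)
        self.df.to_csv(path, sep="\t", index=False)
        sidecar = path.with_suffix(path.suffix + ".json")
        sidecar.write_text(json.dumps(self.dims, indent=2, default=str) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreSet":
        path = Path(path)
        df = pd.read_csv(path, sep="\t")
        sidecar = path.with_suffix(path.suffix + ".json")
        dims = json.loads(sidecar.read_text()) if sidecar.exists() else None
        return cls(df, dims=dims)


_VINA_ROW = re.compile(r"^\s*(\d+)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s+(-?\d+(?:\.\d+)?)\s*$")


def parse_vina_log(text: str) -> list[tuple[int, float, float, float]]:
    """Parse the Vina result table: (rank, affinity kcal/mol, rmsd_lb, rmsd_ub).

    Poses come back in rank order, rank 1 first. Non-monotone affinities get a
    warning but the order is preserved — the table is Vina's, not ours.
    """
    rows = []
    in_table = False
    for line in text.splitlines():
        if set(line.strip()) and set(line.strip()) <= {"-", "+", " "} and "-" in line:
            in_table = True
            continue
        if in_table:
            m = _VINA_ROW.match(line)
            if m:
                rows.append((int(m.group(1)), float(m.group(2)), float(m.group(3)), float(m.group(4))))
            elif rows:
                break
    if not rows:
        raise ParseError("no Vina result table found in log text")
    rows.sort(key=lambda r: r[0])
    affinities = [r[1] for r in rows]
    if any(b < a for a, b in zip(affinities, affinities[1:])):
        warnings.warn("Vina affinities not monotone in rank; order preserved", stacklevel=2)
    return rows


_AD_TYPE_TO_ELEMENT = {
    "A": "C", "C": "C", "N": "N", "NA": "N", "NS": "N", "OA": "O", "OS": "O",
    "SA": "S", "S": "S", "F": "F", "CL": "Cl", "BR": "Br", "I": "I", "P": "P",
    "HD": "H", "H": "H", "HS": "H",
}


def parse_pdbqt_poses(text: str) -> list[dict]:
    """Parse MODEL/ENDMDL-delimited PDBQT docked poses.

    Each pose yields ``{"affinity", "coords", "elements", "names"}`` with
    heavy atoms only (hydrogens dropped); BRANCH/TORSDOF records are ignored
    for geometry. A model without its ``REMARK VINA RESULT`` raises.
    """
    poses = []
    current: dict | None = None
    for line in text.splitlines():
        if line.startswith("MODEL"):
            current = {"affinity": None, "coords": [], "elements": [], "names": []}
        elif line.startswith("REMARK VINA RESULT:") and current is not None:
            current["affinity"] = float(line.split(":", 1)[1].split()[0])
        elif line.startswith(("ATOM", "HETATM")) and current is not None:
            if len(line) < 54:
                raise ParseError(f"short ATOM record in PDBQT pose: {line!r}")
            tail = line[54:].split()
            ad_type = tail[-1].upper() if tail else ""
            element = _AD_TYPE_TO_ELEMENT.get(ad_type) or ad_type.capitalize() or "C"
            if element == "H":
                continue
            current["coords"].append([float(line[30:38]), float(line[38:46]), float(line[46:54])])
            current["elements"].append(element)
            current["names"].append(line[12:16].strip())
        elif line.startswith("ENDMDL") and current is not None:
            if current["affinity"] is None:
                raise ParseError("PDBQT model lacks a REMARK VINA RESULT record")
            current["coords"] = np.asarray(current["coords"], dtype=float)
            poses.append(current)
            current = None
    if not poses:
        raise ParseError("no MODEL/ENDMDL poses found in PDBQT text")
    return poses


@dataclass
class CollectReport:
    """Bookkeeping from a collect() pass."""

    n_records: int
    missing: list[dict] = field(default_factory=list)
    completeness: pd.DataFrame | None = None


def _top_affinity(path: Path) -> tuple[float, int]:
    text = path.read_text()
    if "REMARK VINA RESULT" in text:
        poses = parse_pdbqt_poses(text)
        return min(p["affinity"] for p in poses), len(poses)
    rows = parse_vina_log(text)
    return min(r[1] for r in rows), len(rows)


def collect(manifest: pd.DataFrame | str | Path, root: str | Path | None = None,
            dims: dict | None = None) -> tuple[ScoreSet, CollectReport]:
    """Collect a batch-docking run manifest into a ScoreSet.

    Manifest rows: ``ligand, series, system, site, snapshot, path`` (TSV file
    or DataFrame). Each output file contributes its most favourable affinity.
    Missing files are flagged in the report, never imputed; duplicate keys
    raise. The result is independent of manifest row order.
    """
    if isinstance(manifest, (str, Path)):
        root = root if root is not None else Path(manifest).parent
        manifest = pd.read_csv(manifest, sep="\t")
    root = Path(root) if root is not None else Path(".")
    records, missing = [], []
    cache: dict[Path, tuple[float, int]] = {}  # manifests may reuse output files
    for row in manifest.itertuples(index=False):
        path = root / str(row.path)
        if not path.exists():
            missing.append({"ligand_id": row.ligand, "system": row.system,
                            "site": row.site, "snapshot": int(row.snapshot),
                            "path": str(path)})
            continue
        if path not in cache:
            cache[path] = _top_affinity(path)
        dg, n_poses = cache[path]
        records.append(ScoreRecord(str(row.ligand), str(row.series), str(row.system),
                                   str(row.site), int(row.snapshot), dg, n_poses))
    records.sort(key=lambda r: (r.site, r.system, r.ligand_id, r.snapshot))
    scores = ScoreSet(records, dims=dims)
    report = CollectReport(n_records=len(scores), missing=missing,
                           completeness=scores.completeness())
    return scores, report
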