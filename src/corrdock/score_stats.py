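"""Pooled binding-score distribution statistics and the site-viability rule.

The central statistic of the analysis: for each (site, system) the scores of
every ligand docked to every snapshot are pooled into one distribution, and a
site is judged by the distribution's *mode* — the most probable binding score
— rather than by its single best score. A spectacular best score observed
once in 22,000 runs says nothing about the library; a negative mode says most
of the library binds favourably. Viability is therefore strict ``mode < 0``,
with the fraction of negative scores reported as secondary evidence.

Histograms use bins aligned to multiples of the bin width (default
0.2 kcal/mol); a score on a bin edge belongs to the bin on its right, and
mode ties break toward the lower (more favourable) score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from corrdock.docking_adapter import ScoreSet

DEFAULT_BIN_WIDTH = 0.2


@dataclass
class DistributionSummary:
    """Pooled score distribution for one (site, system)."""

    site: str
    system: str
    n: int
    bin_width: float
    bin_centers: np.ndarray
    probabilities: np.ndarray
    mode: float
    p_mode: float
    best: float
    fraction_negative: float

    def __post_init__(self) -> None:
        self.bin_centers = np.asarray(self.bin_centers, dtype=float)
        self.probabilities = np.asarray(self.probabilities, dtype=float)
        if abs(self.probabilities.sum() - 1.0) > 1e-9:
            raise ValueError("histogram probabilities must sum to 1")
        if not (0.0 <= self.p_mode <= 1.0 and 0.0 <= self.fraction_negative <= 1.0):
            raise ValueError("p_mode and fraction_negative must be in [0, 1]")


def summarize(scores: ScoreSet, site: str, system: str,
              bin_width: float = DEFAULT_BIN_WIDTH) -> DistributionSummary:
    """Pool all (ligand, snapshot) scores for one site/system and summarize.

    mode = centre of the maximum-probability bin (ties -> lower score);
    p_mode = that bin's probability mass; best = minimum pooled score;
    fraction_negative = share of scores strictly below zero.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    pool = scores.subset(site=site, system=system)["dg"].to_numpy(dtype=float)
    if pool.size == 0:
        raise ValueError(f"no score records for site={site!r} system={system!r}")
    idx = np.floor(pool / bin_width).astype(np.int64)
    lo, hi = idx.min(), idx.max()
    counts = np.bincount(idx - lo, minlength=hi - lo + 1)
    probabilities = counts / pool.size
    bin_centers = (np.arange(lo, hi + 1) + 0.5) * bin_width
    imax = int(np.argmax(probabilities))  # argmax takes the first => lowest score on ties
    return DistributionSummary(
        site=site, system=system, n=int(pool.size), bin_width=bin_width,
        bin_centers=bin_centers, probabilities=probabilities,
        mode=float(bin_centers[imax]), p_mode=float(probabilities[imax]),
        best=float(pool.min()), fraction_negative=float(np.mean(pool < 0)),
    )


@dataclass
class SiteTable:
    """Per-(site, system) roll-up: best, mode, p_mode, fraction_negative."""

    df: pd.DataFrame

    COLUMNS = ["site", "system", "best", "mode", "p_mode", "fraction_negative"]

    def __post_init__(self) -> None:
        missing = [c for c in ("site", "system", "best", "mode", "p_mode") if c not in self.df.columns]
        if missing:
            raise ValueError(f"site table missing columns {missing}")
        if "fraction_negative" not in self.df.columns:
            self.df = self.df.assign(fraction_negative=np.nan)
        self.df = self.df[self.COLUMNS].reset_index(drop=True)
        if self.df.duplicated(["site", "system"]).any():
            raise ValueError("duplicate (site, system) row in site table")

    def __len__(self) -> int:
        return len(self.df)

    @classmethod
    def from_records(cls, rows: Iterable[Mapping]) -> "SiteTable":
        return cls(pd.DataFrame(list(rows)))

    def row(self, site: str, system: str) -> pd.Series:
        sel = self.df[(self.df["site"] == site) & (self.df["system"] == system)]
        if sel.empty:
            raise KeyError(f"no row for ({site}, {system})")
        return sel.iloc[0]

    def to_tsv(self, path, header_lines: list[str] | None = None) -> None:
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def make_site_table(summaries: list[DistributionSummary]) -> SiteTable:
    """One row per (site, system), sites in first-seen order."""
    if not summaries:
        raise ValueError("no summaries given")
    site_order: list[str] = []
    for s in summaries:
        if s.site not in site_order:
            site_order.append(s.site)
    rows = [{"site": s.site, "system": s.system, "best": s.best, "mode": s.mode,
             "p_mode": s.p_mode, "fraction_negative": s.fraction_negative}
            for s in summaries]
    df = pd.DataFrame(rows)
    df["__o"] = df["site"].map({s: i for i, s in enumerate(site_order)})
    df = df.sort_values(["__o", "system"], kind="stable").drop(columns="__o")
    return SiteTable(df)


@dataclass
class Viability:
    site: str
    system: str
    viable: bool
    rationale: str


def classify_viable(summary) -> Viability:
    """Mode-based site viability: viable iff the most probable score < 0.

    Accepts a DistributionSummary or any row-like object with ``site``,
    ``system``, ``mode`` and optionally ``fraction_negative`` attributes/keys,
    so published site tables (which print best/mode/p_mode only) can be
    classified directly.
    """
    get = (lambda k, d=None: summary.get(k, d)) if isinstance(summary, Mapping) \
        else (lambda k, d=None: getattr(summary, k, d))
    mode = float(get("mode"))
    frac = get("fraction_negative")
    viable = mode < 0.0
    parts = [f"mode {mode:g} kcal/mol is {'negative (favourable)' if viable else 'non-negative'}"]
    if frac is not None and np.isfinite(frac):
        parts.append(f"fraction of negative scores {float(frac):.3f}")
        if float(frac) >= 0.5:
            parts.append("predominantly favorable")
    return Viability(site=str(get("site")), system=str(get("system")),
                     viable=viable, rationale="; ".join(parts))


def classify_table(table: SiteTable) -> dict[str, list[str]]:
    """Viable site names per system, from a site table."""
    out: dict[str, list[str]] = {}
    for _, row in table.df.iterrows():
        verdict = classify_viable(row.to_dict())
        out.setdefault(verdict.system, [])
        if verdict.viable:
            out[verdict.system].append(verdict.site)
    return out


def _arg_rows(df: pd.DataFrame, column: str, take_max: bool) -> list[tuple[str, str, float]]:
    target = df[column].max() if take_max else df[column].min()
    hit = df[np.isclose(df[column], target)]
    return [(r.site, r.system, float(getattr(r, column))) for r in hit.itertuples(index=False)]


def extremes(table: SiteTable) -> dict[str, list[tuple[str, str, float]]]:
    """Study-wide extremes: most favourable mode and best score, largest p_mode.

    Each entry is a list of (site, system, value); ties are all reported.
    """
    if len(table) == 0:
        raise ValueError("empty site table")
    return {
        "min_mode": _arg_rows(table.df, "mode", take_max=False),
        "min_best": _arg_rows(table.df, "best", take_max=False),
        "max_p_mode": _arg_rows(table.df, "p_mode", take_max=True),
    }


def series_summary(scores: ScoreSet, series_mapping: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-(series, system) fraction of negative scores, pooled over all sites.

    Returns a DataFrame sorted by descending fraction_negative within each
    system — the ranking of ligand series by how often they bind favourably
    anywhere. Ligands without a series raise.
    """
    df = scores.df.copy()
    if series_mapping is not None:
        unmapped = sorted(set(df["ligand_id"]) - set(series_mapping))
        if unmapped:
            raise ValueError(f"ligands without a series: {unmapped[:5]}")
        df["series"] = df["ligand_id"].map(series_mapping)
    if df["series"].isna().any() or (df["series"] == "").any():
        bad = sorted(df.loc[df["series"].isna() | (df["series"] == ""), "ligand_id"].unique())
        raise ValueError(f"ligands without a series: {bad[:5]}")
    out = (df.assign(neg=df["dg"] < 0)
           .groupby(["system", "series"], sort=True)["neg"]
           .agg(fraction_negative="mean", n="size")
           .reset_index()
           .sort_values(["system", "fraction_negative"], ascending=[True, False],
                        kind="stable")
           .reset_index(drop=True))
    out["rank"] = out.groupby("system").cumcount() + 1
    return out
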