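"""Small built-in datasets.

``reference_site_table`` carries the published per-site docking statistics
for wild-type and F508del CFTR — best score, mode, and p(mode) of the pooled
ensemble-docking distribution at each of the five candidate corrector sites.
These ten rows are inputs for the table-level logic (extremes, viability);
they are not produced by this package.
"""

from __future__ import annotations

from corrdock.score_stats import SiteTable

SITES = ("MSD1", "MSD1_alt", "NBD1", "NBD1_alt", "ICL4")

_REFERENCE_ROWS = [
    # site, system, best (kcal/mol), mode (kcal/mol), p_mode
    ("MSD1", "WT", -7.6, -4.2, 0.27),
    ("MSD1_alt", "WT", -7.1, 20.0, 0.026),
    ("NBD1", "WT", -1.5, 54.3, 0.025),
    ("NBD1_alt", "WT", 4.3, 83.1, 0.019),
    ("ICL4", "WT", -8.2, 5.3, 0.031),
    ("MSD1", "MT", -7.8, -4.6, 0.088),
    ("MSD1_alt", "MT", -7.9, 29.6, 0.022),
    ("NBD1", "MT", 39.6, 119.4, 0.017),
    ("NBD1_alt", "MT", -8.7, -5.9, 0.35),
    ("ICL4", "MT", -6.9, 20.1, 0.069),
]


def reference_site_table() -> SiteTable:
    """The published ten-row (site, system) statistics as a SiteTable."""
    return SiteTable.from_records(
        {"site": s, "system": y, "best": b, "mode": m, "p_mode": p}
        for s, y, b, m, p in _REFERENCE_ROWS
    )
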