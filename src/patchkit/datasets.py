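"""Published measurement tables bundled for the counting workflow.

These are the side-by-side yeast measurements the ratio-chain counting
operates on: the pairwise peak-intensity ratio table between endogenously
tagged endocytic proteins in budding (sc) and fission (sp) yeast, the
sfGFP-nanocage-calibrated absolute anchors, and the per-cell copy-number
totals used for the patch-vs-cell occupancy ratios. Ratios are already
brightness-corrected molecule ratios (the mEGFP/GFP 14% brightness
difference was removed during the underlying intensity analysis).
"""

from __future__ import annotations

import pandas as pd

from .counting import RatioGraph

__all__ = [
    "ratio_table",
    "count_anchors",
    "yeast_ratio_graph",
    "cell_totals",
    "MYOSIN_POOL",
]

#: The pooled budding-yeast type-I myosins appear as one node in the ratio
#: table (a single measured ratio against both isoforms together).
MYOSIN_POOL = "scMyo3+scMyo5"

# (numerator, denominator, ratio) with count(num) : count(den) = ratio : 1
_RATIO_ROWS = [
    ("spPan1", "scSla1", 1.30),
    ("spPan1", "scPan1", 1.67),
    ("scEnd3", "spPan1", 0.46),
    ("scSla2", "scLas17", 1.30),
    ("spEnd4", "scSla2", 0.93),
    ("spWsp1", "scLas17", 1.40),
    ("scVrp1", "scSla1", 0.47),
    ("spVrp1", "scVrp1", 1.23),
    ("scMyo3", "scMyo5", 0.51),
    ("spMyo1", MYOSIN_POOL, 0.57),
    ("spArc5", "scSla1", 1.80),
    ("spArc5", "scArc15", 1.03),
    ("spArc3", "scArc15", 1.03),
    ("scAbp1", "scSla1", 4.80),
    ("spFim1", "scAbp1", 0.84),
    ("spFim1", "scSac6", 1.24),
]

#: Nanocage-calibrated absolute peak counts (molecules per endocytic site).
_ANCHORS = {"scSla1": 168.0, "scLas17": 102.0, "scMyo5": 199.0}


def ratio_table() -> pd.DataFrame:
    """Measured peak-intensity ratio table as a DataFrame."""
    return pd.DataFrame(_RATIO_ROWS, columns=["numerator", "denominator", "ratio"])


def count_anchors() -> dict[str, float]:
    """Proteins counted directly against the 120-copy nanocage standard."""
    return dict(_ANCHORS)


def yeast_ratio_graph() -> RatioGraph:
    """The full measured ratio graph, anchored and ready to resolve."""
    return RatioGraph(
        edges=[tuple(row) for row in _RATIO_ROWS],
        anchors=count_anchors(),
        composites={MYOSIN_POOL: ("scMyo3", "scMyo5")},
    )


# per-cell totals and per-patch peaks used for the occupancy ratios,
# exactly as printed (species, protein, total per cell, peak per patch,
# printed 3-decimal ratio)
_CELL_TOTAL_ROWS = [
    ("budding", "Arp2/3 complex subunits", 12784, 294, 0.023),
    ("budding", "WASp/Las17", 3134, 102, 0.033),
    ("budding", "WIP/Vrp1", 3559, 78, 0.021),
    ("budding", "Myo5", 6051, 200, 0.033),
    ("budding", "Myo3", 4222, 100, 0.024),
    ("budding", "Fimbrin/Sac6", 24543, 545, 0.022),
    ("budding", "HIP1R/Sla2", 8879, 133, 0.015),
    ("budding", "Pan1", 9830, 131, 0.013),
    ("budding", "End3", 6064, 100, 0.016),
    ("budding", "Sla1", 8776, 91, 0.010),
    ("budding", "Abp1", 18301, 800, 0.044),
    ("fission", "Arp2/3 complex subunits", 40000, 304, 0.008),
    ("fission", "WASp/Wsp1", 68000, 138, 0.002),
    ("fission", "WIP/Vrp1", 19000, 95, 0.005),
    ("fission", "Myosin-I", 63000, 170, 0.003),
    ("fission", "Fimbrin/Fim1", 87000, 675, 0.008),
    ("fission", "HIP1R/End4", 22000, 124, 0.006),
    ("fission", "Pan1", 27000, 219, 0.008),
]


def cell_totals() -> pd.DataFrame:
    """Per-cell totals vs per-patch peaks, with the printed occupancy ratios."""
    return pd.DataFrame(
        _CELL_TOTAL_ROWS,
        columns=["species", "protein", "total_per_cell", "peak_per_patch", "printed_ratio"],
    )
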