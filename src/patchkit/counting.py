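"""Ratiometric molecule counting against a fluorescent standard.

Absolute copy numbers at endocytic sites are obtained by comparing patch
peak fluorescence to an extracellular standard particle of known copy number
(a 60-subunit protein nanocage carrying 120 sfGFP), after normalizing for
exposure time and fluorophore brightness. Proteins never imaged against the
standard directly are counted through a *ratio chain*: measured pairwise
peak-intensity ratios form a graph whose anchored nodes carry absolute
counts, and counts propagate along the edges.

Brightness convention: mEGFP is 14% brighter than GFP; sfGFP is treated as
equal to GFP (configurable). Measured ratio tables between strains are taken
as already brightness-corrected; raw intensity ratios should pass through
:func:`brightness_correct_ratio` first.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .errors import ConfigurationError, InsufficientDataError, UnresolvableGraphError

__all__ = [
    "CalibrationStandard",
    "BrightnessTable",
    "RatioGraph",
    "ResolvedCounts",
    "fit_intensity_distribution",
    "check_linearity",
    "molecules_from_standard",
    "brightness_correct_ratio",
    "resolve_ratio_chain",
    "patch_to_cell_ratio",
]

logger = logging.getLogger(__name__)

#: Path disagreement (max/min − 1) above which the resolver warns.
CONSISTENCY_TOLERANCE = 0.20


@dataclass(frozen=True)
class CalibrationStandard:
    """A standard particle of known fluorophore copy number."""

    mean_intensity: float
    copies: int = 120
    fluorophore: str = "sfGFP"
    sd_intensity: float = 0.0
    exposure: float = 1.0

    def __post_init__(self) -> None:
        if self.copies < 1:
            raise ValueError("copies must be >= 1")
        if self.mean_intensity <= 0:
            raise ValueError("mean_intensity must be positive")
        if self.exposure <= 0:
            raise ValueError("exposure must be positive")


@dataclass
class BrightnessTable:
    """Relative fluorophore brightness on a common scale (GFP = 1)."""

    factors: dict[str, float] = field(
        default_factory=lambda: {"GFP": 1.0, "mEGFP": 1.14, "sfGFP": 1.0, "EGFP": 1.0}
    )

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.factors.values()):
            raise ValueError("brightness factors must be positive")

    def __getitem__(self, fluorophore: str) -> float:
        try:
            return self.factors[fluorophore]
        except KeyError:
            raise ConfigurationError(
                f"fluorophore {fluorophore!r} not in brightness table "
                f"(known: {sorted(self.factors)})"
            ) from None


@dataclass
class RatioGraph:
    """Measured peak-intensity ratios between proteins, plus absolute anchors.

    ``edges`` are (a, b, r) meaning count(a) : count(b) = r : 1 (ratios
    already brightness-corrected). ``anchors`` map protein → absolute count.
    ``composites`` define sum nodes (e.g. the pooled type-I myosins): a
    composite's count is the sum of its members' counts, and edges may
    reference the composite by name.
    """

    edges: list[tuple[str, str, float]] = field(default_factory=list)
    anchors: dict[str, float] = field(default_factory=dict)
    composites: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a, b, r in self.edges:
            if r <= 0:
                raise ValueError(f"edge {a}:{b} has non-positive ratio {r}")
        for name, count in self.anchors.items():
            if count <= 0:
                raise ValueError(f"anchor {name} has non-positive count {count}")

    def proteins(self) -> set[str]:
        nodes = set(self.anchors)
        for a, b, _ in self.edges:
            nodes.update((a, b))
        for name, members in self.composites.items():
            nodes.add(name)
            nodes.update(members)
        return nodes


@dataclass
class ResolvedCounts:
    """Absolute counts with per-protein path provenance and warnings."""

    counts: dict[str, float]
    provenance: dict[str, dict]
    warnings: list[str] = field(default_factory=list)

    def __getitem__(self, protein: str) -> float:
        return self.counts[protein]


# ---------------------------------------------------------------------------
# calibration QC


def fit_intensity_distribution(intensities) -> tuple[float, float, dict]:
    """Gaussian location/scale of a standard-particle intensity sample.

    Maximum-likelihood fit plus goodness-of-fit diagnostics; the
    ``unimodal_gaussian`` flag goes False when the sample is inconsistent
    with a single Gaussian (e.g. two well-separated modes).
    """
    values = np.asarray(intensities, dtype=float)
    if len(values) < 30:
        raise InsufficientDataError(f"need >= 30 intensities, got {len(values)}")
    mean, sd = stats.norm.fit(values)
    if sd > 0:
        normality = stats.normaltest(values)
        ks = stats.kstest(values, "norm", args=(mean, sd))
        diagnostics = {
            "normaltest_stat": float(normality.statistic),
            "normaltest_p": float(normality.pvalue),
            "ks_stat": float(ks.statistic),
            "ks_p": float(ks.pvalue),
            "unimodal_gaussian": bool(normality.pvalue > 1e-3),
        }
    else:
        diagnostics = {
            "normaltest_stat": 0.0,
            "normaltest_p": 1.0,
            "ks_stat": 0.0,
            "ks_p": 1.0,
            "unimodal_gaussian": True,
        }
    return float(mean), float(sd), diagnostics


def check_linearity(exposures, means) -> dict:
    """Exposure-linearity QC of standard-particle mean intensities.

    OLS fit of mean intensity vs exposure time. QC passes when R² ≥ 0.99
    and the intercept is within 3 standard errors of 0 (intensity must
    extrapolate to zero at zero exposure).
    """
    x = np.asarray(exposures, dtype=float)
    y = np.asarray(means, dtype=float)
    if len(np.unique(x)) < 3:
        raise InsufficientDataError("need at least 3 distinct exposure levels")
    fit = stats.linregress(x, y)
    r_squared = float(fit.rvalue**2)
    intercept_ok = abs(fit.intercept) <= 3.0 * fit.intercept_stderr + 1e-12
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "intercept_stderr": float(fit.intercept_stderr),
        "r_squared": r_squared,
        "passed": bool(r_squared >= 0.99 and intercept_ok),
    }


# ---------------------------------------------------------------------------
# counting


def molecules_from_standard(
    patch_peak_intensity: float,
    standard: CalibrationStandard,
    patch_exposure: float = 1.0,
    brightness: BrightnessTable | None = None,
    patch_fluorophore: str = "sfGFP",
) -> float:
    """Copy number of a patch protein from the intensity ratio to a standard.

    count = copies × (patch rate / standard rate) × brightness correction,
    where rates are intensity per unit exposure and the correction maps the
    patch fluorophore onto the standard's brightness scale.
    """
    if patch_exposure <= 0:
        raise ValueError("patch_exposure must be positive")
    if patch_peak_intensity < 0:
        raise ValueError("patch_peak_intensity must be non-negative")
    brightness = brightness or BrightnessTable()
    patch_rate = patch_peak_intensity / patch_exposure
    standard_rate = standard.mean_intensity / standard.exposure
    correction = brightness[standard.fluorophore] / brightness[patch_fluorophore]
    return standard.copies * (patch_rate / standard_rate) * correction


def brightness_correct_ratio(
    raw_ratio: float,
    fluor_a: str,
    fluor_b: str,
    brightness: BrightnessTable | None = None,
) -> float:
    """Convert a raw intensity ratio A:B into a molecule ratio.

    molecule ratio = raw ratio × brightness(B) / brightness(A). Single-shot:
    apply exactly once to raw intensity data.
    """
    if raw_ratio <= 0:
        raise ValueError("raw_ratio must be positive")
    brightness = brightness or BrightnessTable()
    return raw_ratio * brightness[fluor_b] / brightness[fluor_a]


def _edge_graph(graph: RatioGraph) -> tuple[nx.Graph, list[str]]:
    """Collapse repeated measurements of the same pair into one edge.

    Parallel measurements are combined by geometric mean; a disagreement
    above the consistency tolerance is reported (a plain graph would
    silently overwrite one measurement with the other).
    """
    by_pair: dict[frozenset, list[float]] = {}
    order: dict[frozenset, tuple[str, str]] = {}
    for a, b, r in graph.edges:
        key = frozenset((a, b))
        first_a, _ = order.setdefault(key, (a, b))
        by_pair.setdefault(key, []).append(r if a == first_a else 1.0 / r)
    warnings: list[str] = []
    g = nx.Graph()
    g.add_nodes_from(graph.proteins())
    for key, values in by_pair.items():
        a, b = order[key]
        spread = max(values) / min(values) - 1.0
        if spread > CONSISTENCY_TOLERANCE:
            warnings.append(
                f"repeated measurements of {a}:{b} disagree by {spread:.1%}"
            )
        combined = math.exp(float(np.mean(np.log(values))))
        g.add_edge(a, b, ratio=combined, head=a)  # count(head) = ratio * count(other)
    return g, warnings


def _path_value(g: nx.Graph, path: list[str], anchor_value: float) -> float:
    value = anchor_value
    for src, dst in itertools.pairwise(path):
        data = g.edges[src, dst]
        r, head = data["ratio"], data["head"]
        value = value * r if head == dst else value / r
    return value


def resolve_ratio_chain(graph: RatioGraph) -> ResolvedCounts:
    """Propagate anchored absolute counts through the ratio graph.

    Counts travel from anchors along breadth-first shortest paths,
    multiplying or dividing edge ratios. When several anchors reach a node
    the geometric mean is reported and the max/min disagreement recorded
    (a warning above 20%). Cycle products deviating from 1 by more than 20%
    also warn. Composite (sum) nodes resolve once all members are known and
    then propagate outward like any other node.
    """
    g, warnings = _edge_graph(graph)

    for cycle in nx.cycle_basis(g):
        product = _path_value(g, cycle + [cycle[0]], 1.0)
        deviation = max(product, 1.0 / product) - 1.0  # direction-independent
        if deviation > CONSISTENCY_TOLERANCE:
            warnings.append(
                f"cycle {'-'.join(cycle)} product {product:.3f} deviates from 1 by "
                f"{deviation:.1%}"
            )

    counts: dict[str, float] = {}
    provenance: dict[str, dict] = {}
    for name, value in graph.anchors.items():
        counts[name] = float(value)
        provenance[name] = {"anchor": name, "path": [name], "n_paths": 1}

    # alternate BFS propagation with composite resolution until stable
    changed = True
    while changed:
        changed = False
        sources = [n for n in counts if n in g]
        reachable: dict[str, list[tuple[str, list[str], float]]] = {}
        for src in sources:
            lengths, paths = nx.single_source_dijkstra(g, src, weight=None)
            for node, path in paths.items():
                if node in counts:
                    continue
                reachable.setdefault(node, []).append(
                    (src, path, _path_value(g, path, counts[src]))
                )
        for node, hits in reachable.items():
            values = [v for _, _, v in hits]
            geo = math.exp(float(np.mean(np.log(values))))
            spread = max(values) / min(values) - 1.0
            if spread > CONSISTENCY_TOLERANCE:
                warnings.append(
                    f"{node}: paths from anchors disagree by {spread:.1%} "
                    f"(values {sorted(round(v, 1) for v in values)})"
                )
            counts[node] = geo
            best = min(hits, key=lambda h: len(h[1]))
            provenance[node] = {
                "anchor": best[0],
                "path": best[1],
                "n_paths": len(hits),
                "spread": spread,
            }
            changed = True
        for name, members in graph.composites.items():
            if name not in counts and all(m in counts for m in members):
                counts[name] = sum(counts[m] for m in members)
                provenance[name] = {
                    "anchor": "+".join(members),
                    "path": list(members),
                    "n_paths": 1,
                }
                changed = True

    unresolved = sorted(graph.proteins() - set(counts))
    if unresolved:
        raise UnresolvableGraphError(
            f"no anchor reaches: {unresolved}; every connected component needs an anchor"
        )
    for msg in warnings:
        logger.warning(msg)
    return ResolvedCounts(counts=counts, provenance=provenance, warnings=warnings)


def patch_to_cell_ratio(peak_per_patch: float, total_per_cell: float) -> float:
    """Fraction of a cell's copies present in one patch at peak, to 3 decimals."""
    if total_per_cell <= 0:
        raise ValueError("total_per_cell must be positive")
    if peak_per_patch <= 0:
        raise ValueError("peak_per_patch must be positive")
    return round(peak_per_patch / total_per_cell, 3)
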