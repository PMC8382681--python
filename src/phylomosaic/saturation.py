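"""Per-marker mutational saturation diagnostics.

Multiple substitutions at the same site erode the linear relationship between
the observed pairwise divergence (p-distance) and the divergence implied by
the tree (patristic distance). Regressing observed on inferred distance over
all taxon pairs of a marker gives a slope in (0, 1]: near 1 means essentially
unsaturated, and the slope decreases toward 0 as saturation accumulates. The
slope is the marker's saturation statistic; a marker set can then be ranked
from least to most saturated.

Inferred distances are read from each marker's own gene tree, since saturation
is a per-gene property; using a supermatrix tree instead is possible but is
logged loudly as a deviation.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy import stats as _scipy_stats

from .errors import DegenerateInputError, MissingTaxonError
from .seqio import MarkerStats
from .supermatrix import Alignment
from .treekit import DEFAULT_MIN_OVERLAP, leaf_labels, p_distance, patristic_matrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairPoint:
    """One taxon pair's (observed p-distance, inferred patristic distance)."""

    taxon_a: str
    taxon_b: str
    observed: float
    inferred: float


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of observed on inferred distance; slope = saturation level."""

    slope: float
    intercept: float
    r_squared: float
    n_pairs: int


def pairwise_distance_table(
    aln: Alignment,
    tree: dendropy.Tree,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[list[PairPoint], float, float]:
    """Observed-vs-inferred distance points for every defined taxon pair.

    Returns the points plus the mean observed and mean inferred distance over
    the included pairs. Pairs whose p-distance is undefined (below the overlap
    floor) are excluded from both the table and the means.
    """
    tree_taxa = leaf_labels(tree)
    offenders = sorted(set(aln.taxa) - tree_taxa)
    if offenders:
        raise MissingTaxonError(f"alignment taxa missing from tree: {offenders}")
    patristic = patristic_matrix(tree)
    points = []
    for a, b in itertools.combinations(aln.taxa, 2):
        obs = p_distance(aln.rows[a], aln.rows[b], min_overlap)
        if obs is None:
            continue
        points.append(PairPoint(a, b, obs, patristic.get(a, b)))
    if not points:
        return [], float("nan"), float("nan")
    mean_obs = float(np.mean([p.observed for p in points]))
    mean_inf = float(np.mean([p.inferred for p in points]))
    return points, mean_obs, mean_inf


def fit_saturation(points: Sequence[PairPoint]) -> RegressionFit:
    """Ordinary least squares of observed (response) on inferred (predictor).

    The intercept is estimated, not forced through the origin. The slope is
    the saturation level: lower slope = more saturated.
    """
    if len(points) < 3:
        raise DegenerateInputError(
            f"saturation regression needs >= 3 pairs, got {len(points)}"
        )
    x = np.array([p.inferred for p in points])
    y = np.array([p.observed for p in points])
    if np.ptp(x) == 0.0:
        raise DegenerateInputError(
            "inferred distances all equal; regression slope undefined"
        )
    res = _scipy_stats.linregress(x, y)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n_pairs=len(points),
    )


def saturation_fit(
    aln: Alignment,
    tree: dendropy.Tree,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[RegressionFit, float, float]:
    """Convenience: distance table + regression for one marker."""
    points, mean_obs, mean_inf = pairwise_distance_table(aln, tree, min_overlap)
    return fit_saturation(points), mean_obs, mean_inf


def saturation_report(
    markers: Sequence[tuple[Alignment, dendropy.Tree]],
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    using_supermatrix_tree: bool = False,
) -> list[MarkerStats]:
    """Per-marker saturation slope and mean-distance summaries.

    Markers that cannot support the regression (too few defined pairs, zero
    predictor variance) yield rows with the saturation fields left absent
    rather than failing the whole report. The returned rows are in input
    order; sorting by slope gives the saturation ranking.
    """
    if using_supermatrix_tree:
        logger.warning(
            "saturation computed against a supermatrix tree, not per-marker "
            "gene trees: slopes conflate marker-specific rate variation"
        )
    rows = []
    for aln, tree in markers:
        row = MarkerStats(marker=aln.marker, n_sequences=len(aln.taxa), n_sites=aln.length)
        try:
            fit, mean_obs, mean_inf = saturation_fit(aln, tree, min_overlap)
        except (DegenerateInputError, MissingTaxonError) as exc:
            logger.warning("marker %s: saturation undefined (%s)", aln.marker, exc)
            rows.append(row)
            continue
        row.mean_observed = mean_obs
        row.mean_inferred = mean_inf
        row.saturation = fit.slope
        rows.append(row)
    return rows


def rank_by_saturation(rows: Sequence[MarkerStats]) -> list[MarkerStats]:
    """Markers ordered most-saturated first (ascending slope); undefined last."""
    defined = [r for r in rows if r.saturation is not None]
    undefined = [r for r in rows if r.saturation is None]
    return sorted(defined, key=lambda r: r.saturation) + undefined
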