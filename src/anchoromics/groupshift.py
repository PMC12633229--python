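"""Within-group correlation shifts, centroid geometry, and group-level tests.

Quantifies how a gene's relationship with the anchor changes between
diagnostic groups: per-group Pearson r (pairwise-complete), 95% confidence
ellipses, pooled-covariance Mahalanobis distance between group centroids in
the 2-D (gene, anchor) plane, qualitative decorrelation / separation
classes, and Wilcoxon rank-sum group comparisons with BH correction.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import PairwiseR, bh_adjust, pearson_pairwise

#: stable band for the decorrelation class (|delta r| below this is "stable")
DECORRELATION_BAND = 0.02
#: separation class cuts on Mahalanobis D: little < 0.60 <= moderate < 0.90 <= strong
SEPARATION_CUTS = (0.60, 0.90)

DEFAULT_CONTRAST_GROUPS = ("Control", "MCI", "AD")
EXACT_WILCOXON_MAX_N = 20


def within_group_r(
    x: Sequence[float],
    y: Sequence[float],
    groups: Sequence[str],
    keep: Sequence[str],
) -> dict[str, PairwiseR]:
    """Pairwise-complete Pearson r per kept group.

    Groups with fewer than three complete pairs come back as excluded
    markers (``too_few_pairs``) rather than being dropped silently.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if not (len(x) == len(y) == len(groups)):
        raise ValueError("x, y and groups must be aligned to the same samples")
    present = set(groups)
    for g in keep:
        if g not in present:
            raise ValueError(f"kept group {g!r} absent from labels")
    return {g: pearson_pairwise(x[groups == g], y[groups == g]) for g in keep}


def _complete_points(points: np.ndarray) -> np.ndarray:
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 2:
        raise ValueError("expected an (n, 2) point set")
    return points[np.isfinite(points).all(axis=1)]


def mahalanobis_separation(
    points_a: np.ndarray, points_b: np.ndarray
) -> float:
    """Pooled-covariance Mahalanobis distance between two 2-D group centroids.

    D = sqrt((mu_a - mu_b)' S^-1 (mu_a - mu_b)) with S the (n-1)-weighted
    pooled within-group covariance.
    """
    a = _complete_points(points_a)
    b = _complete_points(points_b)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("each group needs >= 3 complete 2-D points")
    ca = np.cov(a, rowvar=False)
    cb = np.cov(b, rowvar=False)
    na, nb = len(a), len(b)
    S = ((na - 1) * ca + (nb - 1) * cb) / (na + nb - 2)
    delta = a.mean(axis=0) - b.mean(axis=0)
    try:
        sol = np.linalg.solve(S, delta)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled covariance is singular; consider a ridge fallback "
            "(add a small diagonal) if the data are degenerate"
        ) from exc
    d2 = float(delta @ sol)
    return math.sqrt(max(d2, 0.0))


@dataclasses.dataclass
class Ellipse:
    """A bivariate-normal density contour: center, semi-axes, orientation (degrees)."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]  # major, minor
    angle_deg: float
    coverage: float


def confidence_ellipse(points: np.ndarray, coverage: float = 0.95) -> Ellipse:
    """Normal-theory coverage ellipse of a 2-D point set.

    Axes are sqrt(eigenvalue * q) with q the chi-square(2 df) quantile at
    ``coverage``; orientation comes from the leading eigenvector.
    """
    pts = _complete_points(points)
    if len(pts) < 3:
        raise ValueError("need >= 3 complete points")
    if not 0 <= coverage < 1:
        raise ValueError("coverage must be in [0, 1)")
    C = np.cov(pts, rowvar=False)
    evals, evecs = np.linalg.eigh(C)
    if evals[0] <= 0:
        raise np.linalg.LinAlgError("sample covariance is singular; degenerate ellipse")
    q = stats.chi2.ppf(coverage, df=2) if coverage > 0 else 0.0
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    angle = math.degrees(math.atan2(evecs[1, 0], evecs[0, 0]))
    return Ellipse(
        center=tuple(pts.mean(axis=0)),
        semi_axes=(math.sqrt(evals[0] * q), math.sqrt(evals[1] * q)),
        angle_deg=angle,
        coverage=coverage,
    )


def classify_decorrelation(
    r_ref: float, r_alt: float, stable_band: float = DECORRELATION_BAND
) -> str:
    """stable / decorrelated / over_correlated from the r change alt - ref."""
    delta = r_alt - r_ref
    if abs(delta) < stable_band:
        return "stable"
    return "decorrelated" if delta < 0 else "over_correlated"


def classify_separation(
    D: float, cuts: tuple[float, float] = SEPARATION_CUTS
) -> str:
    """little / moderate / strong from the Mahalanobis distance D."""
    if D < 0:
        raise ValueError("D must be >= 0")
    low, high = cuts
    if D < low:
        return "little"
    if D < high:
        return "moderate"
    return "strong"


def _exact_ranksum_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact rank-sum p by enumeration of all group assignments.

    Uses midranks, so ties are handled exactly; identical multisets give
    p = 1. Only called for combined n <= EXACT_WILCOXON_MAX_N.
    """
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    na = len(a)
    w_obs = ranks[:na].sum()
    expect = na * (len(pooled) + 1) / 2.0
    dev = abs(w_obs - expect)
    count = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), na):
        w = ranks[list(combo)].sum()
        if abs(w - expect) >= dev - 1e-9:
            count += 1
        total += 1
    return count / total


@dataclasses.dataclass
class GroupComparison:
    """Wilcoxon rank-sum contrasts for one feature across diagnostic groups."""

    feature_id: str
    table: pd.DataFrame  # columns group_a, group_b, n_a, n_b, statistic, p, fdr


def compare_groups(
    values: Sequence[float],
    groups: Sequence[str],
    feature_id: str = "feature",
    contrast_groups: Sequence[str] = DEFAULT_CONTRAST_GROUPS,
) -> GroupComparison:
    """All pairwise Wilcoxon rank-sum contrasts among the contrast groups.

    Exact enumeration (midrank, tie-exact) when the combined n is at most
    20; tie-corrected normal approximation otherwise. BH correction is
    applied across the contrasts; undefined contrasts (an empty group) get
    NaN and are left out of the BH family.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    rows = []
    for ga, gb in itertools.combinations(contrast_groups, 2):
        a = values[(groups == ga) & np.isfinite(values)]
        b = values[(groups == gb) & np.isfinite(values)]
        if len(a) < 2 or len(b) < 2:
            rows.append((ga, gb, len(a), len(b), np.nan, np.nan))
            continue
        u = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        if len(a) + len(b) <= EXACT_WILCOXON_MAX_N:
            p = _exact_ranksum_pvalue(a, b)
        else:
            p = float(u.pvalue)
        rows.append((ga, gb, len(a), len(b), float(u.statistic), p))
    table = pd.DataFrame(
        rows, columns=["group_a", "group_b", "n_a", "n_b", "statistic", "p"]
    )
    table["fdr"] = np.nan
    defined = table["p"].notna()
    if defined.any():
        table.loc[defined, "fdr"] = bh_adjust(table.loc[defined, "p"].to_numpy())
    return GroupComparison(feature_id=feature_id, table=table)


@dataclasses.dataclass
class GroupShiftResult:
    """Full group-shift record for one (gene, anchor) pair on one layer."""

    gene_id: str
    layer: str  # "rna_rna" or "rna_protein"
    r_by_group: dict[str, PairwiseR]
    centroid_by_group: dict[str, tuple[float, float]]
    D: float
    ellipse_by_group: dict[str, Ellipse]
    decorrelation_class: str
    separation_class: str
    group_pair: tuple[str, str]


def group_shift_analysis(
    x: pd.Series,
    y: pd.Series,
    groups: pd.Series,
    gene_id: str = "gene",
    layer: str = "rna_rna",
    group_pair: tuple[str, str] = ("Control", "AD"),
    keep: Sequence[str] | None = None,
    coverage: float = 0.95,
    stable_band: float = DECORRELATION_BAND,
    separation_cuts: tuple[float, float] = SEPARATION_CUTS,
) -> GroupShiftResult:
    """Assemble the per-gene group-shift record in the (x=gene, y=anchor) plane.

    ``x`` and ``y`` are sample-indexed Series; samples are intersected by id.
    The Mahalanobis distance and the decorrelation class compare the two
    groups of ``group_pair`` (reference first).
    """
    common = x.index.intersection(y.index).intersection(groups.index)
    xv = x.loc[common].to_numpy(float)
    yv = y.loc[common].to_numpy(float)
    gv = groups.loc[common].to_numpy(object)
    keep = list(keep) if keep is not None else list(group_pair)
    r_by_group = within_group_r(xv, yv, gv, keep=keep)

    centroids: dict[str, tuple[float, float]] = {}
    ellipses: dict[str, Ellipse] = {}
    pts_by_group: dict[str, np.ndarray] = {}
    for g in keep:
        pts = _complete_points(np.column_stack([xv[gv == g], yv[gv == g]]))
        pts_by_group[g] = pts
        if len(pts) >= 3:
            centroids[g] = (float(pts[:, 0].mean()), float(pts[:, 1].mean()))
            try:
                ellipses[g] = confidence_ellipse(pts, coverage)
            except np.linalg.LinAlgError:
                pass

    ga, gb = group_pair
    D = mahalanobis_separation(pts_by_group[ga], pts_by_group[gb])
    ra, rb = r_by_group[ga], r_by_group[gb]
    if ra.ok and rb.ok:
        decorr = classify_decorrelation(ra.r, rb.r, stable_band)
    else:
        decorr = "undefined"
    return GroupShiftResult(
        gene_id=gene_id,
        layer=layer,
        r_by_group=r_by_group,
        centroid_by_group=centroids,
        D=D,
        ellipse_by_group=ellipses,
        decorrelation_class=decorr,
        separation_class=classify_separation(D, separation_cuts),
        group_pair=group_pair,
    )
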