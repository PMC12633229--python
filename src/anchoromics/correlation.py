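"""Pairwise-complete Pearson correlation with the pipeline's validity rules.

Correlations use pairwise-complete observations; results with fewer than
three valid samples or zero variance on either restricted vector are
excluded rather than reported. Two p-value routes are provided — the Fisher
z-transformation (used for anchor/volcano profiles) and the t-test on r
(used for the all-pairs table) — plus Benjamini–Hochberg FDR in linear or
log space.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .io import ExpressionMatrix

logger = logging.getLogger("anchoromics")

TIER_MODERATE = 0.50
TIER_WEAK = 0.30
STRONG_PAIR = 0.70

# exclusion markers
EXCL_NONE = "none"
EXCL_TOO_FEW = "too_few_pairs"
EXCL_ZERO_VAR = "zero_variance"


@dataclasses.dataclass
class PairwiseR:
    r: float | None
    n_complete: int
    excluded_reason: str = EXCL_NONE

    @property
    def ok(self) -> bool:
        return self.excluded_reason == EXCL_NONE


def pearson_pairwise(x: Sequence[float], y: Sequence[float]) -> PairwiseR:
    """Pearson r over indices where both vectors are present.

    Returns an excluded marker when fewer than three complete pairs remain
    or either restricted vector has zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    mask = np.isfinite(x) & np.isfinite(y)
    n = int(mask.sum())
    if n < 3:
        return PairwiseR(None, n, EXCL_TOO_FEW)
    xs, ys = x[mask], y[mask]
    if np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return PairwiseR(None, n, EXCL_ZERO_VAR)
    xc = xs - xs.mean()
    yc = ys - ys.mean()
    r = float(xc @ yc / np.sqrt((xc @ xc) * (yc @ yc)))
    return PairwiseR(max(-1.0, min(1.0, r)), n)


def fisher_z_pvalue(r: float, n: int) -> float | None:
    """Two-sided p for r via the Fisher z-transformation (needs n >= 4).

    z = atanh(r) * sqrt(n - 3), referred to the standard normal. Returns
    None (excluded) when n < 4; |r| = 1 gives the p = 0 limit.
    """
    if n < 4:
        return None
    if abs(r) >= 1:
        return 0.0
    z = np.arctanh(r) * np.sqrt(n - 3)
    return float(special.erfc(abs(z) / np.sqrt(2.0)))


def t_pvalue_on_r(r: float, n: int) -> float | None:
    """Two-sided p for r via t = r*sqrt((n-2)/(1-r^2)) with n-2 df (needs n >= 3)."""
    if n < 3:
        return None
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def bh_adjust(p: Sequence[float], log_space: bool = False) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjustment, capped at 1.

    The log-space variant performs the ranking and min-accumulation on
    log p-values so that heavily underflowing p-values keep their order.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranks = np.arange(1, m + 1)
    if log_space:
        with np.errstate(divide="ignore"):
            logp = np.log(p[order])
        adj = logp + np.log(m) - np.log(ranks)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        adj = np.minimum(adj, 0.0)
        out_sorted = np.exp(adj)
    else:
        adj = p[order] * m / ranks
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        out_sorted = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = out_sorted
    return out


def tier_of(r: float, moderate: float = TIER_MODERATE, weak: float = TIER_WEAK) -> str:
    a = abs(r)
    if a >= moderate:
        return "moderate"
    if a >= weak:
        return "weak"
    return "ns"


def corr_with_vector(
    X: np.ndarray, y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized pairwise-complete Pearson r of every row of X against y.

    Returns (r, n_complete, excluded_reason) arrays; excluded rows carry
    r = NaN. This is the hot path shared by anchor profiling and the
    permutation null of the enrichment statistic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = np.isfinite(X) & np.isfinite(y)[None, :]
    n = mask.sum(axis=1)
    X0 = np.where(mask, X, 0.0)
    Y = np.where(mask, y[None, :], 0.0)
    sx = X0.sum(axis=1)
    sy = Y.sum(axis=1)
    sxx = (X0 * X0).sum(axis=1)
    syy = (Y * Y).sum(axis=1)
    sxy = (X0 * Y).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        vx = n * sxx - sx * sx
        vy = n * syy - sy * sy
        r = (n * sxy - sx * sy) / np.sqrt(vx * vy)
    # numerical floor for "zero variance" on the restricted vectors
    scale_x = np.maximum(sxx, 1.0)
    scale_y = np.maximum(syy, 1.0)
    zero_var = (vx <= 1e-12 * n * scale_x) | (vy <= 1e-12 * n * scale_y)
    reason = np.full(X.shape[0], EXCL_NONE, dtype=object)
    reason[zero_var] = EXCL_ZERO_VAR
    reason[n < 3] = EXCL_TOO_FEW
    r = np.clip(r, -1.0, 1.0)
    r[reason != EXCL_NONE] = np.nan
    return r, n.astype(int), reason


@dataclasses.dataclass
class AnchorProfile:
    """Per-feature correlation profile against one anchor feature.

    ``table`` columns: r, n_complete, p, fdr, tier, excluded_reason —
    indexed by feature id. FDR is BH across all non-excluded features.
    """

    anchor_id: str
    anchor_modality: str
    p_method: str
    table: pd.DataFrame

    def scored(self) -> pd.DataFrame:
        return self.table[self.table["excluded_reason"] == EXCL_NONE]


def anchor_profile(
    matrix: ExpressionMatrix,
    anchor: pd.Series,
    p_method: str = "fisher_z",
    anchor_id: str = "anchor",
    anchor_modality: str = "rna",
    tier_moderate: float = TIER_MODERATE,
    tier_weak: float = TIER_WEAK,
) -> AnchorProfile:
    """Correlate every feature of ``matrix`` with the anchor vector.

    The anchor is a sample-indexed Series (e.g. one matrix row, a protein
    abundance vector, or a PCA loading phenotype); samples are intersected
    by id before the pairwise-complete rule applies.
    """
    if p_method not in ("fisher_z", "t_test"):
        raise ValueError(f"unknown p_method {p_method!r}")
    common = [s for s in matrix.sample_ids if s in anchor.index]
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} overlapping samples between matrix and anchor"
        )
    if len(common) < len(matrix.sample_ids):
        logger.info(
            "anchor_profile: intersected to %d/%d samples",
            len(common),
            len(matrix.sample_ids),
        )
    X = matrix.values[common].to_numpy(float)
    y = anchor.loc[common].to_numpy(float)
    r, n, reason = corr_with_vector(X, y)

    pfun = fisher_z_pvalue if p_method == "fisher_z" else t_pvalue_on_r
    min_n = 4 if p_method == "fisher_z" else 3
    p = np.full(r.size, np.nan)
    for i in range(r.size):
        if reason[i] != EXCL_NONE:
            continue
        if n[i] < min_n:
            reason[i] = EXCL_TOO_FEW
            r[i] = np.nan
            continue
        p[i] = pfun(r[i], int(n[i]))

    fdr = np.full(r.size, np.nan)
    ok = reason == EXCL_NONE
    if ok.any():
        fdr[ok] = bh_adjust(p[ok])
    tiers = np.full(r.size, "", dtype=object)
    tiers[ok] = [tier_of(v, tier_moderate, tier_weak) for v in r[ok]]
    table = pd.DataFrame(
        {
            "r": r,
            "n_complete": n,
            "p": p,
            "fdr": fdr,
            "tier": tiers,
            "excluded_reason": reason,
        },
        index=pd.Index(matrix.feature_ids, name="feature"),
    )
    return AnchorProfile(
        anchor_id=anchor_id,
        anchor_modality=anchor_modality,
        p_method=p_method,
        table=table,
    )


def assemble_variables(
    matrices: Iterable[ExpressionMatrix],
    metadata: pd.DataFrame | None = None,
    metadata_cols: Sequence[str] = (),
) -> pd.DataFrame:
    """Stack matrices (and numeric metadata columns) into one variables x samples frame.

    Variable names are prefixed with their modality ("rna:NPTX2",
    "protein:NPTX2", "metadata:pmi") so the same gene can appear in several
    layers; samples are the union, with NaN where a layer lacks a sample.
    """
    blocks: list[pd.DataFrame] = []
    for m in matrices:
        block = m.values.copy()
        block.index = [f"{m.modality}:{f}" for f in block.index]
        blocks.append(block)
    if metadata is not None and metadata_cols:
        meta = metadata[list(metadata_cols)].astype(float).T
        meta.index = [f"metadata:{c}" for c in metadata_cols]
        blocks.append(meta)
    if not blocks:
        raise ValueError("no variables to assemble")
    out = pd.concat(blocks, axis=0, join="outer")
    _dups = out.index[out.index.duplicated()]
    if len(_dups):
        raise ValueError(f"duplicate variable names after assembly: {list(_dups)[:5]}")
    return out


@dataclasses.dataclass
class PairTable:
    """All unordered variable pairs with r, t-based p, log-space BH FDR, strong flag."""

    table: pd.DataFrame  # columns var_a, var_b, r, n_complete, p, fdr, strong
    excluded: pd.DataFrame  # columns var_a, var_b, n_complete, excluded_reason


def all_pairs_table(
    variables: pd.DataFrame,
    strong_threshold: float = STRONG_PAIR,
) -> PairTable:
    """All-pairs correlation table over an assembled variables x samples frame.

    Symmetric duplicates are collapsed (each unordered pair once); p-values
    come from the t-test on r with log-space BH FDR; ``strong`` flags
    |r| >= ``strong_threshold``.
    """
    names = list(variables.index)
    if len(names) < 2:
        raise ValueError("need at least 2 variables")
    X = variables.to_numpy(float)
    rows, excl = [], []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            res = pearson_pairwise(X[i], X[j])
            if res.ok:
                rows.append(
                    (names[i], names[j], res.r, res.n_complete,
                     t_pvalue_on_r(res.r, res.n_complete))
                )
            else:
                excl.append((names[i], names[j], res.n_complete, res.excluded_reason))
    table = pd.DataFrame(rows, columns=["var_a", "var_b", "r", "n_complete", "p"])
    if len(table):
        table["fdr"] = bh_adjust(table["p"].to_numpy(), log_space=True)
        table["strong"] = table["r"].abs() >= strong_threshold
    else:
        table["fdr"] = []
        table["strong"] = []
    excluded = pd.DataFrame(
        excl, columns=["var_a", "var_b", "n_complete", "excluded_reason"]
    )
    return PairTable(table=table, excluded=excluded)
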