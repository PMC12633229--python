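"""Continuous-phenotype enrichment against an anchor correlation ranking.

Features are ranked by their Pearson correlation with an anchor phenotype
(a gene's RNA, a protein abundance vector, or a PCA loading), and each gene
set's enrichment score is the mean tie-averaged rank of its members minus
the mean rank of the universe:

    ES = mean(rank of members) - (N + 1) / 2

Significance comes from a phenotype-permutation null: the anchor vector is
shuffled across samples (one shared shuffle per permutation for every set
and every anchor in a run), correlations and ranks are recomputed, and

    NES = (ES - mean_null) / sd_null

with two-sided p from the standard-normal approximation and BH FDR across
sets. Leading edges (Pos5/Neg5) are the up-to-five positively and
negatively correlated members with the largest |r|. A term is "unique" to
the main anchor when |NES| exceeds every background-category median |NES|
by at least a configurable fold (1.2 by default).
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .correlation import EXCL_NONE, AnchorProfile, bh_adjust, corr_with_vector
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("anchoromics")

UNIQUENESS_FOLD = 1.2
DEFAULT_N_PERM = 5000


@dataclasses.dataclass
class RankedList:
    """Features ordered by ascending anchor correlation, with tie-averaged ranks."""

    feature_ids: list[str]  # ascending r order
    r: np.ndarray  # aligned to feature_ids
    ranks: np.ndarray  # tie-averaged ranks, aligned to feature_ids

    @property
    def N(self) -> int:
        return len(self.feature_ids)

    def rank_of(self) -> dict[str, float]:
        return dict(zip(self.feature_ids, self.ranks))


def rank_by_anchor(profile: AnchorProfile) -> RankedList:
    """Ascending-r ranking of a profile's non-excluded features."""
    scored = profile.scored()
    if len(scored) < 2:
        raise ValueError("need >= 2 non-excluded features to rank")
    order = np.argsort(scored["r"].to_numpy(), kind="mergesort")
    r = scored["r"].to_numpy()[order]
    features = [scored.index[i] for i in order]
    ranks = stats.rankdata(r, method="average")
    return RankedList(feature_ids=features, r=r, ranks=ranks)


def enrichment_score(ranked: RankedList, set_members: Sequence[str]) -> float | None:
    """ES = mean rank of the set's members minus the universe mean (N+1)/2.

    Membership is intersected with the ranked universe; a set with no
    members present is skipped (None) with a warning.
    """
    pos = ranked.rank_of()
    member_ranks = [pos[g] for g in set_members if g in pos]
    if not member_ranks:
        logger.warning("gene set has no members in the ranked universe; skipped")
        return None
    return float(np.mean(member_ranks) - (ranked.N + 1) / 2.0)


def leading_edges(
    ranked: RankedList, set_members: Sequence[str], k: int = 5
) -> tuple[list[str], list[str]]:
    """(Pos-k, Neg-k) leading edges of a set, ordered by |r| descending.

    Pos-k are the up-to-k members with the largest positive r; Neg-k the
    up-to-k with the most negative r. Members with r of the wrong sign are
    not padded in, so a set may report fewer than k contributors per side.
    """
    rmap = dict(zip(ranked.feature_ids, ranked.r))
    present = [(g, rmap[g]) for g in set_members if g in rmap]
    pos = sorted((gr for gr in present if gr[1] > 0), key=lambda t: -t[1])[:k]
    neg = sorted((gr for gr in present if gr[1] < 0), key=lambda t: t[1])[:k]
    return [g for g, _ in pos], [g for g, _ in neg]


def running_sum_curve(
    ranked: RankedList, set_members: Sequence[str]
) -> np.ndarray:
    """Classic hit/miss running sum along the ranked list (for plotting only).

    Hits step +1/|S|, misses step -1/|S^c|; the curve returns to 0 at
    position N. The mean-rank ES remains the statistic of record.
    """
    members = set(set_members) & set(ranked.feature_ids)
    if not members:
        raise ValueError("no set members in the ranked universe")
    n_hit = len(members)
    n_miss = ranked.N - n_hit
    if n_miss == 0:
        return np.zeros(ranked.N)
    steps = np.array(
        [1.0 / n_hit if g in members else -1.0 / n_miss for g in ranked.feature_ids]
    )
    return np.cumsum(steps)


@dataclasses.dataclass
class EnrichmentReport:
    """Per-set enrichment results for one anchor.

    ``table`` columns: n_members, ES, null_mean, null_sd, NES, p, p_empirical,
    fdr, pos5, neg5 (comma-joined), flagged (zero null sd), plus uniqueness
    columns once background anchors are folded in.
    """

    anchor_id: str
    n_perm: int
    seed: int
    table: pd.DataFrame
    ranked: RankedList


def _ranked_from_r(feature_ids: Sequence[str], r: np.ndarray) -> RankedList:
    order = np.argsort(r, kind="mergesort")
    return RankedList(
        feature_ids=[feature_ids[i] for i in order],
        r=r[order],
        ranks=stats.rankdata(r[order], method="average"),
    )


def permutation_nes(
    matrix: ExpressionMatrix,
    anchor: pd.Series,
    sets: GeneSetCollection,
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    anchor_id: str = "anchor",
    exclude_anchor_feature: str | None = None,
) -> EnrichmentReport:
    """Mean-rank ES per set with a phenotype-permutation NES.

    One shared shuffle of the anchor's sample assignment per permutation is
    used for every set (and, via the shared seed, for every anchor of a
    background-comparison run). Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    common = [s for s in matrix.sample_ids if s in anchor.index]
    anchor = anchor.loc[common].astype(float)
    anchor = anchor[np.isfinite(anchor.to_numpy())]
    common = list(anchor.index)
    if len(common) < 3:
        raise ValueError("fewer than 3 usable samples shared by matrix and anchor")
    feature_ids = [
        f for f in matrix.feature_ids if f != exclude_anchor_feature
    ]
    X = matrix.values.loc[feature_ids, common].to_numpy(float)
    y = anchor.to_numpy(float)

    r_obs, _, reason = corr_with_vector(X, y)
    ok = reason == EXCL_NONE
    universe = [f for f, o in zip(feature_ids, ok) if o]
    if len(universe) < 2:
        raise ValueError("fewer than 2 scorable features")
    Xu = X[ok]
    ranked = _ranked_from_r(universe, r_obs[ok])
    N = ranked.N
    rank_pos = ranked.rank_of()

    member_idx: dict[str, np.ndarray] = {}
    es_obs: dict[str, float] = {}
    uidx = {f: i for i, f in enumerate(universe)}
    for name, members in sets.sets.items():
        present = [g for g in members if g in uidx]
        if not present:
            logger.warning("set %s has no members in the universe; skipped", name)
            continue
        member_idx[name] = np.array([uidx[g] for g in present])
        es_obs[name] = float(
            np.mean([rank_pos[g] for g in present]) - (N + 1) / 2.0
        )

    rng = np.random.default_rng(seed)
    null_es = {name: np.empty(n_perm) for name in member_idx}
    ranks_buf = np.empty(len(universe))
    for b in range(n_perm):
        perm = rng.permutation(len(y))
        r_null, _, _ = corr_with_vector(Xu, y[perm])
        ranks_buf = stats.rankdata(r_null, method="average")
        mean_all = (N + 1) / 2.0
        for name, idx in member_idx.items():
            null_es[name][b] = ranks_buf[idx].mean() - mean_all

    rows = []
    for name, idx in member_idx.items():
        nm = float(null_es[name].mean())
        nsd = float(null_es[name].std(ddof=1))
        es = es_obs[name]
        flagged = nsd == 0.0
        if flagged:
            nes = np.nan
            p = np.nan
            logger.warning("set %s: permutation null has zero sd; NES undefined", name)
        else:
            nes = (es - nm) / nsd
            p = float(special.erfc(abs(nes) / np.sqrt(2.0)))
        p_emp = float(
            (1 + np.sum(np.abs(null_es[name] - nm) >= abs(es - nm))) / (n_perm + 1)
        )
        pos5, neg5 = leading_edges(ranked, sets.sets[name])
        rows.append(
            (name, len(idx), es, nm, nsd, nes, p, p_emp,
             ",".join(pos5), ",".join(neg5), flagged)
        )
    table = pd.DataFrame(
        rows,
        columns=["set", "n_members", "ES", "null_mean", "null_sd", "NES", "p",
                 "p_empirical", "pos5", "neg5", "flagged"],
    ).set_index("set")
    defined = table["p"].notna()
    table["fdr"] = np.nan
    if defined.any():
        table.loc[defined, "fdr"] = bh_adjust(table.loc[defined, "p"].to_numpy())
    return EnrichmentReport(
        anchor_id=anchor_id, n_perm=n_perm, seed=seed, table=table, ranked=ranked
    )


def background_uniqueness(
    report: EnrichmentReport,
    background_anchors: Mapping[str, str],
    matrix: ExpressionMatrix,
    sets: GeneSetCollection,
    anchor_source: ExpressionMatrix | None = None,
    n_perm: int | None = None,
    fold: float = UNIQUENESS_FOLD,
) -> EnrichmentReport:
    """Flag sets whose main-anchor |NES| beats all background-category medians.

    Each background gene (mapped gene -> category) is run through the same
    enrichment with the same seed (shared permutation schedule); per set
    and category the median |NES| over the category's anchors is taken, and
    ``unique`` is |NES_main| >= fold x max(category medians). Background NES
    values are appended as ``bg_nes:<gene>`` columns.
    """
    source = anchor_source if anchor_source is not None else matrix
    n_perm = n_perm if n_perm is not None else report.n_perm
    by_cat: dict[str, list[str]] = {}
    for gene, cat in background_anchors.items():
        by_cat.setdefault(cat, []).append(gene)
    bg_reports: dict[str, EnrichmentReport] = {}
    for cat, genes in sorted(by_cat.items()):
        usable = [g for g in genes if g in source.feature_ids]
        if not usable:
            logger.warning("background category %s has no usable anchors; skipped", cat)
            continue
        for gene in usable:
            bg_reports[gene] = permutation_nes(
                matrix,
                source.feature(gene),
                sets,
                n_perm=n_perm,
                seed=report.seed,
                anchor_id=gene,
                exclude_anchor_feature=gene if source is matrix else None,
            )
    table = report.table.copy()
    for gene, rep in bg_reports.items():
        table[f"bg_nes:{gene}"] = rep.table["NES"].reindex(table.index)
    unique = []
    for name in table.index:
        medians = []
        for cat, genes in sorted(by_cat.items()):
            vals = [
                abs(bg_reports[g].table.loc[name, "NES"])
                for g in genes
                if g in bg_reports and name in bg_reports[g].table.index
                and np.isfinite(bg_reports[g].table.loc[name, "NES"])
            ]
            if vals:
                medians.append(float(np.median(vals)))
        nes_main = table.loc[name, "NES"]
        if not medians or not np.isfinite(nes_main):
            unique.append(False)
        else:
            unique.append(bool(abs(nes_main) >= fold * max(medians)))
    table["unique"] = unique
    return EnrichmentReport(
        anchor_id=report.anchor_id,
        n_perm=report.n_perm,
        seed=report.seed,
        table=table,
        ranked=report.ranked,
    )


def is_unique(nes_main: float, category_medians: Sequence[float],
              fold: float = UNIQUENESS_FOLD) -> bool:
    """The bare uniqueness rule: |NES| >= fold x every background-category median."""
    if not category_medians:
        return False
    return abs(nes_main) >= fold * max(category_medians)
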