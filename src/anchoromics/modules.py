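"""Mixed-variable correlation modules and PCA phenotypes.

Builds the correlation-distance matrix (d = 1 - r, pairwise-complete) over
an assembled set of variables (RNA features, protein features, numeric
metadata, component scores), clusters it with average linkage (UPGMA), and
assigns path-style module labels such as ``1/2/1``. Also computes the PCA
sample phenotypes with the +/- 3 SD outlier-exclusion rule.

Path labels are assigned top-down: at each level a cluster is split
multiway at the largest gap in its subtree's sorted merge heights, and a
cluster whose root merge height is already below a coherence threshold
(members correlating above r = 1 - threshold on average) is not split
further. Children are numbered by increasing mean subtree merge height
(ties: smallest leaf index). This makes labels deterministic and lets a
level hold more than two branches, matching the multiway label style.
"""

from __future__ import annotations

import dataclasses
import logging
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .correlation import pearson_pairwise
from .io import ExpressionMatrix

logger = logging.getLogger("anchoromics")

#: do not split clusters whose root merge height (1 - mean between-branch r)
#: is below this; 0.5 means "members already cohere at r > 0.5 on average"
SPLIT_MIN_HEIGHT = 0.5


def correlation_distance_matrix(
    variables: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric distance matrix d = 1 - r over a variables x samples frame.

    Zero-variance variables are dropped with a warning; pairs excluded by
    the pairwise-complete rules are imputed with the maximum observed
    distance and returned in the second frame for the log.
    """
    X = variables.to_numpy(float)
    keep = []
    for i, name in enumerate(variables.index):
        vals = X[i][np.isfinite(X[i])]
        if vals.size == 0 or np.ptp(vals) == 0:
            logger.warning("variable %s has zero variance; dropped", name)
        else:
            keep.append(i)
    if len(keep) < 2:
        raise ValueError("need >= 2 variables with variance")
    names = [variables.index[i] for i in keep]
    X = X[keep]
    m = len(names)
    D = np.zeros((m, m))
    excluded = []
    for i in range(m):
        for j in range(i + 1, m):
            res = pearson_pairwise(X[i], X[j])
            if res.ok:
                D[i, j] = D[j, i] = 1.0 - res.r
            else:
                D[i, j] = D[j, i] = np.nan
                excluded.append((names[i], names[j], res.excluded_reason))
    if excluded:
        dmax = np.nanmax(D)
        logger.warning(
            "%d excluded pairs imputed with max observed distance %.3f",
            len(excluded), dmax,
        )
        D = np.where(np.isnan(D), dmax, D)
        np.fill_diagonal(D, 0.0)
    dist = pd.DataFrame(D, index=names, columns=names)
    excl = pd.DataFrame(excluded, columns=["var_a", "var_b", "excluded_reason"])
    return dist, excl


@dataclasses.dataclass
class ModuleAssignment:
    """UPGMA merge tree plus path-style module labels at a chosen depth."""

    variables: list[str]
    merge_tree: np.ndarray  # scipy linkage matrix (m-1, 4)
    labels: dict[str, str]  # variable -> "a/b/c" path label
    cut_depth: int

    def modules(self) -> dict[str, list[str]]:
        """Module label -> member variables, in input order."""
        out: dict[str, list[str]] = {}
        for v in self.variables:
            out.setdefault(self.labels[v], []).append(v)
        return out


def _children(node: int, Z: np.ndarray, m: int) -> tuple[int, int]:
    row = Z[node - m]
    return int(row[0]), int(row[1])


def _leaves(node: int, Z: np.ndarray, m: int) -> list[int]:
    if node < m:
        return [node]
    a, b = _children(node, Z, m)
    return _leaves(a, Z, m) + _leaves(b, Z, m)


def _subtree_heights(node: int, Z: np.ndarray, m: int) -> list[float]:
    if node < m:
        return []
    a, b = _children(node, Z, m)
    return _subtree_heights(a, Z, m) + _subtree_heights(b, Z, m) + [float(Z[node - m, 2])]


def _gap_split(node: int, Z: np.ndarray, m: int) -> list[int]:
    """Split a cluster at the largest gap in its sorted merge heights.

    Children are the maximal subclusters whose root merge lies strictly
    below the gap. Falls back to the two root children when every merge
    height is identical.
    """
    heights = sorted(_subtree_heights(node, Z, m))
    if not heights:
        return [node]
    hs = np.asarray(heights)
    if len(hs) == 1 or np.all(np.diff(hs) <= 0):  # single or tied merges
        return list(_children(node, Z, m))
    gaps = np.diff(hs)
    span = float(hs[-1] - hs[0])
    if gaps.max() < 0.5 * span:
        # no dominant gap: fall back to the plain binary root split
        return list(_children(node, Z, m))
    k = int(np.flatnonzero(gaps == gaps.max())[-1])  # tie: prefer the higher gap
    threshold = float(hs[k])
    out: list[int] = []

    def descend(nd: int) -> None:
        if nd < m or float(Z[nd - m, 2]) <= threshold:
            out.append(nd)
        else:
            a, b = _children(nd, Z, m)
            descend(a)
            descend(b)

    descend(node)
    return out


def _mean_height(node: int, Z: np.ndarray, m: int) -> float:
    hs = _subtree_heights(node, Z, m)
    return float(np.mean(hs)) if hs else 0.0


def average_linkage_cluster(
    distances: pd.DataFrame,
    cut_depth: int = 3,
    split_min_height: float = SPLIT_MIN_HEIGHT,
) -> ModuleAssignment:
    """UPGMA tree over a distance matrix with top-down path labels.

    ``cut_depth`` is the number of label levels; label paths shorter than
    the requested depth (coherent clusters that stop splitting) are padded
    with 1s so every variable receives a full-depth label.
    """
    names = list(distances.index)
    m = len(names)
    if cut_depth < 1:
        raise ValueError("cut_depth must be >= 1")
    if m == 1:
        return ModuleAssignment(
            variables=names,
            merge_tree=np.empty((0, 4)),
            labels={names[0]: "/".join(["1"] * cut_depth)},
            cut_depth=cut_depth,
        )
    Z = linkage(squareform(distances.to_numpy(float), checks=False), method="average")
    labels: dict[int, list[str]] = {}

    def assign(node: int, prefix: list[str], depth: int) -> None:
        if depth == cut_depth or node < m:
            path = prefix + ["1"] * (cut_depth - depth)
            for leaf in _leaves(node, Z, m):
                labels[leaf] = path
            return
        if node >= m and float(Z[node - m, 2]) < split_min_height:
            # coherent cluster: stop splitting, pad the label
            path = prefix + ["1"] * (cut_depth - depth)
            for leaf in _leaves(node, Z, m):
                labels[leaf] = path
            return
        kids = _gap_split(node, Z, m)
        if kids == [node]:  # no clear substructure: stop, pad the label
            path = prefix + ["1"] * (cut_depth - depth)
            for leaf in _leaves(node, Z, m):
                labels[leaf] = path
            return
        kids.sort(key=lambda nd: (_mean_height(nd, Z, m), min(_leaves(nd, Z, m))))
        for i, kid in enumerate(kids, start=1):
            assign(kid, prefix + [str(i)], depth + 1)

    assign(2 * m - 2, [], 0)
    return ModuleAssignment(
        variables=names,
        merge_tree=Z,
        labels={names[i]: "/".join(labels[i]) for i in range(m)},
        cut_depth=cut_depth,
    )


@dataclasses.dataclass
class PcaPhenotype:
    """Sample-level PCA phenotypes with outlier exclusion.

    ``scores`` holds retained samples only (mean 0 per component after the
    single-pass exclusion); ``outlier`` flags every original sample.
    """

    scores: pd.DataFrame  # retained samples x components
    loadings: pd.DataFrame  # genes x components
    variance_fractions: np.ndarray
    outlier: pd.Series  # bool per original sample

    def loading_phenotype(self, component: str) -> pd.Series:
        """A component's gene loadings as a ranking phenotype for enrichment."""
        return self.loadings[component]


def _pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of samples (columns of the genes x samples matrix X)."""
    Xc = X - X.mean(axis=1, keepdims=True)  # center genes
    # observations = samples: SVD of Xc^T (samples x genes)
    U, s, Vt = np.linalg.svd(Xc.T, full_matrices=False)
    scores = U * s  # samples x comps
    loadings = Vt.T  # genes x comps
    # orient each component so its largest-magnitude loading is positive
    for k in range(loadings.shape[1]):
        j = np.argmax(np.abs(loadings[:, k]))
        if loadings[j, k] < 0:
            loadings[:, k] *= -1
            scores[:, k] *= -1
    var = s**2 / max(X.shape[1] - 1, 1)
    frac = var / var.sum() if var.sum() > 0 else var
    return scores, loadings, frac


def pca_phenotypes(
    matrix: ExpressionMatrix,
    n_components: int = 2,
    outlier_sd: float = 3.0,
) -> PcaPhenotype:
    """Principal components of samples with the +/- outlier_sd SD exclusion rule.

    Samples whose PC1 or PC2 score lies beyond ``outlier_sd`` standard
    deviations from that component's mean are flagged and excluded, and the
    decomposition is recomputed once on the retained samples.
    """
    X = matrix.values.to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("PCA requires a complete matrix (no missing values)")
    n_genes, n_samples = X.shape
    if n_samples < 3:
        raise ValueError("need >= 3 samples")
    if n_components > min(n_genes, n_samples):
        raise ValueError("n_components exceeds matrix rank bound")
    scores, _, _ = _pca(X)
    flagged = np.zeros(n_samples, dtype=bool)
    for k in range(min(2, scores.shape[1])):
        col = scores[:, k]
        sd = col.std(ddof=1)
        if sd > 0:
            flagged |= np.abs(col - col.mean()) > outlier_sd * sd
    retained = ~flagged
    scores2, loadings2, frac2 = _pca(X[:, retained])
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return PcaPhenotype(
        scores=pd.DataFrame(
            scores2[:, :n_components],
            index=[s for s, keep in zip(matrix.sample_ids, retained) if keep],
            columns=comp_names,
        ),
        loadings=pd.DataFrame(
            loadings2[:, :n_components], index=matrix.feature_ids, columns=comp_names
        ),
        variance_fractions=frac2[:n_components],
        outlier=pd.Series(flagged, index=matrix.sample_ids, name="outlier"),
    )
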