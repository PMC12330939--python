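"""Molecular subtype assignment and RBP-driven sample stratification.

The stratification workflow mirrors the common expression-based tumor
subgrouping recipe: (1) keep only RBPs whose expression splits samples
into two well-separated 1-D clusters, (2) drop RBPs whose split merely
recapitulates the known molecular subtypes (chi-square independence
filter), (3) cluster samples by k-means on the retained, standardized RBP
expression with the silhouette index choosing k, and (4) report the RBPs
that discriminate the resulting clusters (one-way ANOVA, BH-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

SUBTYPE_ORDER = ("classical", "mesenchymal", "neural", "proneural")


# ---------------------------------------------------------------------------
# subtype assignment
# ---------------------------------------------------------------------------

def assign_subtypes(gene_expr: pd.DataFrame, signature_sets: dict[str, list[str]]) -> pd.DataFrame:
    """Nearest-centroid-style subtype labels from signature gene z-scores.

    ``gene_expr`` is log-CPM, genes x samples.  Each signature gene is
    z-scored across samples; a sample's score for a subtype is the mean z
    over that subtype's (present) genes, and the label is the argmax with
    ties broken by the documented subtype order (sorted names), flagged
    ambiguous.
    """
    if len(signature_sets) < 2:
        raise ValueError("need >= 2 signature sets")
    scores = {}
    for subtype in sorted(signature_sets):
        genes = signature_sets[subtype]
        present = [g for g in genes if g in gene_expr.index]
        if not present:
            raise ValueError(f"signature {subtype!r}: no genes present in the matrix")
        if len(present) < len(genes):
            import warnings

            missing = sorted(set(genes) - set(present))
            warnings.warn(f"signature {subtype!r}: dropped absent genes {missing}", stacklevel=2)
        sub = gene_expr.loc[present].astype(float)
        sd = sub.std(axis=1, ddof=1).replace(0, np.nan)
        z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
        scores[subtype] = z.mean(axis=0)
    score_df = pd.DataFrame(scores)  # samples x subtypes, columns sorted
    arr = score_df.to_numpy()
    best = arr.argmax(axis=1)  # argmax takes the first (sorted-order) maximum
    labels = score_df.columns.to_numpy()[best]
    is_max = arr == arr.max(axis=1, keepdims=True)
    ambiguous = is_max.sum(axis=1) > 1
    out = score_df.copy()
    out.insert(0, "sample_id", score_df.index)
    out["subtype"] = labels
    out["ambiguous"] = ambiguous
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# per-RBP discretization and independence filter
# ---------------------------------------------------------------------------

@dataclass
class Discretization:
    labels: np.ndarray  # 0 = low cluster, 1 = high cluster
    separation: float  # between-SS / within-SS
    discretizable: bool
    constant: bool = False


def discretize_by_rbp(
    expr_vector: np.ndarray | pd.Series,
    seed: int = 0,
    separation_threshold: float = 3.0,
    n_init: int = 25,
) -> Discretization:
    """Two-cluster 1-D k-means split of one RBP's expression across samples.

    The split is "able to discretize" when the between-/within-cluster
    sum-of-squares ratio exceeds ``separation_threshold``.  The default of
    3.0 is calibrated so a unimodal Gaussian rarely qualifies (its ratio
    concentrates near 2) while a 4-sigma bimodal mixture almost always
    does.  The low-mean cluster is labelled 0.
    """
    x = np.asarray(expr_vector, dtype=float)
    if len(x) < 4:
        raise ValueError("need >= 4 samples")
    if np.all(x == x[0]):
        return Discretization(np.zeros(len(x), dtype=int), 0.0, False, constant=True)
    km = KMeans(n_clusters=2, n_init=n_init, random_state=seed)
    labels = km.fit_predict(x.reshape(-1, 1))
    means = [x[labels == g].mean() for g in (0, 1)]
    if means[0] > means[1]:
        labels = 1 - labels
    within = sum(np.sum((x[labels == g] - x[labels == g].mean()) ** 2) for g in (0, 1))
    grand = x.mean()
    between = sum(np.sum(labels == g) * (x[labels == g].mean() - grand) ** 2 for g in (0, 1))
    sep = between / within if within > 0 else np.inf
    return Discretization(labels, float(sep), bool(sep >= separation_threshold))


def subtype_independence_filter(
    cluster_labels: np.ndarray,
    subtype_labels: np.ndarray,
    alpha: float = 0.01,
) -> dict:
    """Chi-square independence of a 2-cluster split against subtype labels.

    The RBP is kept only when the split shows *no* significant association
    with the known subtypes (p > alpha).  Degenerate labelings (a single
    level on either side) are dropped with a flag; low expected counts are
    recorded as a warning, not an error.
    """
    cluster_labels = np.asarray(cluster_labels)
    subtype_labels = np.asarray(subtype_labels)
    if len(cluster_labels) != len(subtype_labels):
        raise ValueError("labelings must cover the same samples")
    tab = pd.crosstab(cluster_labels, subtype_labels).to_numpy()
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        return {"keep": False, "pvalue": np.nan, "chi2": np.nan, "degenerate": True, "low_expected": False}
    chi2, p, _, expected = stats.chi2_contingency(tab, correction=False)
    return {
        "keep": bool(p > alpha),
        "pvalue": float(p),
        "chi2": float(chi2),
        "degenerate": False,
        "low_expected": bool((expected < 5).any()),
    }


# ---------------------------------------------------------------------------
# k-means stratification with silhouette-selected k
# ---------------------------------------------------------------------------

@dataclass
class StratificationResult:
    rbp_subset: list[str]
    sample_ids: list[str]
    labels: np.ndarray
    chosen_k: int
    silhouette: dict[int, float]
    discriminant: pd.DataFrame | None = None
    weak_structure: bool = False


def cluster_samples(
    rbp_expr: pd.DataFrame,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
    n_init: int = 25,
    weak_silhouette: float = 0.25,
) -> StratificationResult:
    """k-means over samples on per-RBP standardized expression.

    ``rbp_expr`` is RBPs x samples.  Each k in ``k_range`` (skipping k >= n)
    gets a seeded 25-restart k-means; the mean silhouette picks k.  A best
    silhouette below ``weak_silhouette`` flags weak structure.
    """
    if rbp_expr.shape[0] < 2:
        raise ValueError("need >= 2 RBPs")
    X = rbp_expr.to_numpy(dtype=float)
    sd = X.std(axis=1, ddof=1)
    sd[sd == 0] = 1.0
    Xs = ((X - X.mean(axis=1, keepdims=True)) / sd[:, None]).T  # samples x RBPs
    n = Xs.shape[0]
    sil: dict[int, float] = {}
    labels_by_k: dict[int, np.ndarray] = {}
    for k in k_range:
        if n <= k:
            continue
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        lab = km.fit_predict(Xs)
        _, sizes = np.unique(lab, return_counts=True)
        # singleton clusters break the downstream ANOVA; such a k is not a
        # usable stratification and is skipped rather than chosen
        if len(sizes) < 2 or sizes.min() < 2:
            continue
        sil[k] = float(silhouette_score(Xs, lab, metric="euclidean"))
        labels_by_k[k] = lab
    if not sil:
        raise ValueError(f"no k in {k_range} is usable with n={n} samples")
    chosen_k = max(sil, key=lambda k: (sil[k], -k))
    return StratificationResult(
        rbp_subset=list(rbp_expr.index),
        sample_ids=list(rbp_expr.columns),
        labels=labels_by_k[chosen_k],
        chosen_k=chosen_k,
        silhouette=sil,
        weak_structure=max(sil.values()) < weak_silhouette,
    )


def discriminant_rbps(
    rbp_expr: pd.DataFrame,
    cluster_labels: np.ndarray,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-way ANOVA per RBP across clusters, BH-adjusted.

    An RBP is discriminant when its adjusted p-value is <= alpha.  A
    cluster of size 1 invalidates the ANOVA (no within-cluster variance
    contribution) and prompts re-clustering instead of a silent skip.
    """
    labels = np.asarray(cluster_labels)
    uniq, sizes = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need >= 2 clusters")
    if (sizes < 2).any():
        small = uniq[sizes < 2].tolist()
        raise ValueError(f"cluster(s) {small} have < 2 samples; re-cluster before testing")
    rows = []
    for rbp, vec in rbp_expr.iterrows():
        groups = [vec.to_numpy(dtype=float)[labels == g] for g in uniq]
        if all(np.ptp(g) == 0 for g in groups) and len({g[0] for g in groups}) == 1:
            f, p = 0.0, 1.0
        else:
            f, p = stats.f_oneway(*groups)
            if np.isnan(f):
                f, p = 0.0, 1.0
        rows.append({"rbp_name": rbp, "F": float(f), "pvalue": float(p)})
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["pvalue"].to_numpy(), method="fdr_bh")[1]
    df["discriminant"] = df["fdr"] <= alpha
    return df


def stratify(
    rbp_expr: pd.DataFrame,
    subtype_labels: pd.Series | None,
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6),
    seed: int = 0,
    separation_threshold: float = 3.0,
    chi2_alpha: float = 0.01,
    anova_alpha: float = 0.05,
) -> StratificationResult:
    """Full stratification: discretize -> independence filter -> k-means -> ANOVA."""
    kept = []
    for i, (rbp, vec) in enumerate(rbp_expr.iterrows()):
        disc = discretize_by_rbp(vec.to_numpy(), seed=seed + i, separation_threshold=separation_threshold)
        if not disc.discretizable:
            continue
        if subtype_labels is not None:
            res = subtype_independence_filter(
                disc.labels, subtype_labels.reindex(rbp_expr.columns).to_numpy(), alpha=chi2_alpha
            )
            if not res["keep"]:
                continue
        kept.append(rbp)
    if len(kept) < 2:
        raise ValueError(f"only {len(kept)} RBPs survive the discretization/independence filters")
    result = cluster_samples(rbp_expr.loc[kept], k_range=k_range, seed=seed)
    result.discriminant = discriminant_rbps(rbp_expr.loc[kept], result.labels, alpha=anova_alpha)
    return result
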