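"""Detection and removal of environmentally influenced CpG sites.

Water-body structure in percent methylation is assessed with PCA and one-way
PERMANOVA on Euclidean distances; environment-associated sites are located
with discriminant analysis of principal components (DAPC) after K-means
clustering, and the sites contributing most to the first discriminant
function are removed in batches until the focal water bodies are no longer
distinguishable (PERMANOVA p above alpha).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from ._utils import logger


# --------------------------------------------------------------------------
# PCA
# --------------------------------------------------------------------------

def pca_scores(x, scale_unit: bool = True):
    """Centered (optionally unit-scaled) PCA via SVD.

    Returns (scores, loadings, explained_variance_ratio). Component signs are
    fixed so each loading vector's largest-magnitude entry is positive.
    Zero-variance columns are dropped (with a warning) when scaling.
    """
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    xc = x - mu
    keep = np.arange(x.shape[1])
    if scale_unit:
        sd = xc.std(axis=0, ddof=0)
        zero = sd == 0
        if zero.any():
            logger.warning("pca: dropping %d zero-variance sites", int(zero.sum()))
            keep = np.flatnonzero(~zero)
            xc = xc[:, keep]
            sd = sd[keep]
        xc = xc / sd
    u, s, vt = np.linalg.svd(xc, full_matrices=False)
    # deterministic sign: largest-|loading| entry positive per component
    flips = np.sign(vt[np.arange(vt.shape[0]), np.abs(vt).argmax(axis=1)])
    flips[flips == 0] = 1.0
    vt = vt * flips[:, None]
    u = u * flips[None, :]
    scores = u * s
    var = s**2
    evr = var / var.sum() if var.sum() > 0 else var
    loadings = np.zeros((x.shape[1], vt.shape[0]))
    loadings[keep] = vt.T
    return scores, loadings, evr


# --------------------------------------------------------------------------
# PERMANOVA
# --------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    pseudo_f: float
    r2: float
    p_value: float
    n_perm: int
    seed: int | None
    method: str  # "exhaustive" or "monte_carlo"


def _is_distance_matrix(x: np.ndarray) -> bool:
    return (
        x.ndim == 2
        and x.shape[0] == x.shape[1]
        and np.allclose(np.diag(x), 0)
        and np.allclose(x, x.T)
    )


def _ss_stats(d2: np.ndarray, codes: np.ndarray, k: int):
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(idx.size, 1)].sum() / idx.size
    ss_between = ss_total - ss_within
    f = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf
    r2 = ss_between / ss_total if ss_total > 0 else 0.0
    return f, r2


def _distinct_assignment_count(sizes: np.ndarray) -> int:
    n = int(sizes.sum())
    count, rem = 1, n
    for s in sizes:
        count *= comb(rem, int(s))
        rem -= int(s)
    return count


def _exhaustive_f_values(d2: np.ndarray, sizes: np.ndarray):
    """Pseudo-F for every distinct assignment of n items to the group sizes."""
    from itertools import combinations

    n = d2.shape[0]
    k = sizes.size
    fs = []

    def rec(remaining: tuple[int, ...], g: int, codes: np.ndarray):
        if g == k:
            f, _ = _ss_stats(d2, codes, k)
            fs.append(f)
            return
        size = int(sizes[g])
        if g == k - 1:
            codes = codes.copy()
            codes[list(remaining)] = g
            f, _ = _ss_stats(d2, codes, k)
            fs.append(f)
            return
        for chosen in combinations(remaining, size):
            c = codes.copy()
            c[list(chosen)] = g
            rec(tuple(i for i in remaining if i not in chosen), g + 1, c)

    rec(tuple(range(n)), 0, np.full(n, -1))
    return np.array(fs)


def permanova(
    data,
    groups,
    n_perm: int = 9999,
    seed: int | None = None,
    permutations: str = "auto",
) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances.

    ``data`` may be an (n x p) feature matrix or an (n x n) symmetric
    distance matrix (detected automatically). The pseudo-F statistic is
    (SS_between/(k-1)) / (SS_within/(n-k)) on squared distances. The p-value
    comes from random label permutations, ``p = (#{F_perm >= F_obs} + 1) /
    (n_perm + 1)``, or from exhaustive enumeration of all distinct label
    assignments when their number does not exceed ``n_perm`` (or when
    ``permutations="exhaustive"``), in which case ``p = #{F >= F_obs} / N``.
    """
    data = np.asarray(data, dtype=float)
    labels, codes = np.unique(np.asarray(groups), return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least 2 groups")
    sizes = np.bincount(codes)
    if (sizes < 2).any():
        small = labels[sizes < 2]
        raise ValueError(f"every group needs >= 2 members; too small: {list(small)}")
    if _is_distance_matrix(data):
        d2 = data**2
    else:
        diff = data[:, None, :] - data[None, :, :]
        d2 = np.einsum("ijk,ijk->ij", diff, diff)
    n = d2.shape[0]
    if n != codes.size:
        raise ValueError("groups length must match data")

    f_obs, r2 = _ss_stats(d2, codes, k)
    n_distinct = _distinct_assignment_count(sizes)
    exhaustive = permutations == "exhaustive" or (
        permutations == "auto" and n_distinct <= n_perm
    )
    if exhaustive:
        fs = _exhaustive_f_values(d2, sizes)
        p = float(np.mean(fs >= f_obs - 1e-12))
        return PermanovaResult(float(f_obs), float(r2), p, int(fs.size), seed, "exhaustive")

    rng = np.random.default_rng(seed)
    count = 0
    # vectorized permutation of within-group sums in batches
    batch = max(1, min(n_perm, 2000))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        perm_codes = np.empty((b, n), dtype=np.int64)
        for i in range(b):
            perm_codes[i] = codes[rng.permutation(n)]
        ss_within = np.zeros(b)
        for g in range(k):
            mask = (perm_codes == g).astype(float)
            ss_within += 0.5 * np.einsum("bi,ij,bj->b", mask, d2, mask) / sizes[g]
        ss_total = d2[np.triu_indices(n, 1)].sum() / n
        ss_between = ss_total - ss_within
        with np.errstate(divide="ignore"):
            f_perm = (ss_between / (k - 1)) / (ss_within / (n - k))
        count += int(np.sum(f_perm >= f_obs - 1e-12))
        done += b
    p = (count + 1) / (n_perm + 1)
    return PermanovaResult(float(f_obs), float(r2), float(p), n_perm, seed, "monte_carlo")


# --------------------------------------------------------------------------
# DAPC
# --------------------------------------------------------------------------

@dataclass
class DiscriminantResult:
    retained_pcs: int
    discriminant_loadings: np.ndarray  # weights on retained PCs (discriminant 1)
    site_contributions: pd.Series  # per-site, non-negative, sums to 1
    assignment_accuracy: float
    kmeans_labels: np.ndarray | None = None


def kmeans_clusters(pc_scores, k: int = 2, n_start: int = 10, seed: int | None = None) -> np.ndarray:
    """K-means labels (1..k) on PC scores; best of ``n_start`` restarts."""
    pc_scores = np.asarray(pc_scores, dtype=float)
    if k > pc_scores.shape[0]:
        raise ValueError("k cannot exceed the number of fish")
    if k == 1:
        return np.ones(pc_scores.shape[0], dtype=int)
    km = KMeans(n_clusters=k, n_init=n_start, random_state=seed)
    return km.fit_predict(pc_scores) + 1


def _lda_on_pcs(scores_pc: np.ndarray, labels: np.ndarray) -> LinearDiscriminantAnalysis:
    lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=None)
    try:
        lda.fit(scores_pc, labels)
    except np.linalg.LinAlgError:
        logger.warning("singular within-class scatter; ridge-regularised LDA")
        lda = LinearDiscriminantAnalysis(solver="eigen", shrinkage=1e-6)
        lda.fit(scores_pc, labels)
    return lda


def dapc_fit(x, labels, n_pcs: int, scale_unit: bool = False) -> DiscriminantResult:
    """DAPC: linear discriminant analysis on the first ``n_pcs`` PC scores.

    Site contributions are the squared weights of discriminant function 1
    back-projected onto the original sites, normalised to sum to one.
    ``x`` may be a DataFrame (columns = site ids) or an array.
    """
    site_ids = list(x.columns) if isinstance(x, pd.DataFrame) else None
    xa = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    max_pcs = min(xa.shape[0] - 1, xa.shape[1])
    if not 1 <= n_pcs <= max_pcs:
        raise ValueError(f"n_pcs must be in [1, {max_pcs}]")
    scores, loadings, _ = pca_scores(xa, scale_unit=scale_unit)
    sub = scores[:, :n_pcs]
    lda = _lda_on_pcs(sub, labels)
    w = lda.scalings_[:, 0]
    v = loadings[:, :n_pcs] @ w  # discriminant-1 direction in site space
    contrib = v**2
    total = contrib.sum()
    contrib = contrib / total if total > 0 else contrib
    acc = float(np.mean(lda.predict(sub) == labels))
    idx = site_ids if site_ids is not None else np.arange(xa.shape[1])
    return DiscriminantResult(
        retained_pcs=n_pcs,
        discriminant_loadings=w,
        site_contributions=pd.Series(contrib, index=idx),
        assignment_accuracy=acc,
    )


def dapc_crossvalidate(
    x,
    labels,
    max_pcs: int = 300,
    reps: int = 50,
    holdout: float = 0.1,
    seed: int | None = None,
    n_grid: int = 15,
    scale_unit: bool = False,
):
    """Pick the PC count by repeated stratified holdout assignment accuracy.

    Returns (best_n_pcs, table) where ``table`` has columns n_pcs and
    mean_accuracy. Ties resolve to the fewest PCs. ``max_pcs`` beyond the
    matrix rank is truncated with a warning.
    """
    xa = np.asarray(x, dtype=float)
    labels = np.asarray(labels)
    n = xa.shape[0]
    rng = np.random.default_rng(seed)
    rank_cap = min(n - 1 - int(np.ceil(holdout * n)), xa.shape[1])
    if max_pcs > rank_cap:
        logger.warning("max_pcs %d exceeds usable rank; truncated to %d", max_pcs, rank_cap)
        max_pcs = rank_cap
    candidates = np.unique(np.linspace(1, max_pcs, num=min(max_pcs, n_grid)).astype(int))
    scores, _, _ = pca_scores(xa, scale_unit=scale_unit)

    classes, codes = np.unique(labels, return_inverse=True)
    acc = np.zeros((candidates.size, reps))
    for r in range(reps):
        test_idx = []
        for c in range(classes.size):
            members = np.flatnonzero(codes == c)
            n_test = max(1, int(round(holdout * members.size)))
            if n_test >= members.size:
                raise ValueError(f"group {classes[c]!r} too small for holdout {holdout}")
            test_idx.append(rng.choice(members, size=n_test, replace=False))
        test = np.concatenate(test_idx)
        train = np.setdiff1d(np.arange(n), test)
        for ci, npc in enumerate(candidates):
            lda = _lda_on_pcs(scores[train][:, :npc], labels[train])
            acc[ci, r] = np.mean(lda.predict(scores[test][:, :npc]) == labels[test])
    mean_acc = acc.mean(axis=1)
    best = int(candidates[int(np.argmax(mean_acc))])  # argmax takes first = fewest PCs
    table = pd.DataFrame({"n_pcs": candidates, "mean_accuracy": mean_acc})
    return best, table


# --------------------------------------------------------------------------
# Iterative removal
# --------------------------------------------------------------------------

def iterative_env_site_removal(
    x: pd.DataFrame,
    groups,
    removal_fraction: float = 0.5,
    alpha: float = 0.05,
    max_iter: int = 10,
    n_perm: int = 9999,
    max_pcs: int = 300,
    cv_reps: int = 50,
    holdout: float = 0.1,
    seed: int = 0,
):
    """Iteratively remove environment-discriminating sites.

    ``x`` is a complete fish x site DataFrame restricted to the focal water
    bodies; ``groups`` gives each fish's water body. Each iteration
    cross-validates the DAPC PC count, fits the discriminant on the
    water-body labels, removes the top ``removal_fraction`` of sites by
    discriminant-1 contribution (ties broken by site id), and re-tests
    water-body separation with PERMANOVA. Stops when p > alpha or after
    ``max_iter`` iterations. (Discriminating on the known labels rather than
    K-means clusters keeps the procedure aimed at the water-body axis even
    when another gradient, such as age, dominates total variance; with two
    cleanly separated water bodies the K = 2 clusters coincide with the
    labels.)

    Returns (retained_site_ids, removed_site_ids, audit DataFrame).
    """
    if not isinstance(x, pd.DataFrame):
        raise TypeError("x must be a fish x site DataFrame")
    if not 0 < removal_fraction <= 1:
        raise ValueError("removal_fraction must be in (0, 1]")
    groups = np.asarray(groups)
    current = x.copy()
    removed: list[str] = []
    audit_rows = []

    res = permanova(current.to_numpy(), groups, n_perm=n_perm, seed=seed)
    audit_rows.append(
        dict(iteration=0, n_sites=current.shape[1], retained_pcs=np.nan,
             assignment_accuracy=np.nan, pseudo_f=res.pseudo_f, r2=res.r2,
             p_value=res.p_value)
    )
    it = 0
    while res.p_value <= alpha and it < max_iter:
        it += 1
        n_sites = current.shape[1]
        n_remove = max(1, int(round(removal_fraction * n_sites)))
        if n_remove >= n_sites:
            logger.warning(
                "iteration %d would remove all %d remaining sites; stopping with "
                "partial result", it, n_sites,
            )
            removed.extend(current.columns)
            current = current.iloc[:, :0]
            audit_rows.append(
                dict(iteration=it, n_sites=0, retained_pcs=np.nan,
                     assignment_accuracy=np.nan, pseudo_f=np.nan, r2=np.nan,
                     p_value=np.nan)
            )
            break
        best_pcs, _ = dapc_crossvalidate(
            current, groups, max_pcs=max_pcs, reps=cv_reps,
            holdout=holdout, seed=seed + 100 + it,
        )
        fit = dapc_fit(current, groups, n_pcs=best_pcs)
        order = fit.site_contributions.sort_values(
            ascending=False, kind="mergesort"
        )
        # deterministic tie-break: equal contributions ordered by site id
        order = order.iloc[
            np.lexsort((order.index.astype(str), -order.to_numpy()))
        ]
        drop = list(order.index[:n_remove])
        removed.extend(drop)
        current = current.drop(columns=drop)
        res = permanova(current.to_numpy(), groups, n_perm=n_perm, seed=seed + 200 + it)
        audit_rows.append(
            dict(iteration=it, n_sites=current.shape[1], retained_pcs=best_pcs,
                 assignment_accuracy=fit.assignment_accuracy, pseudo_f=res.pseudo_f,
                 r2=res.r2, p_value=res.p_value)
        )
        logger.info(
            "env removal iteration %d: %d sites removed, %d left, PERMANOVA p=%.4f",
            it, len(drop), current.shape[1], res.p_value,
        )
    audit = pd.DataFrame(audit_rows)
    return list(current.columns), removed, audit
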