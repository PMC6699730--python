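"""Survey-profile clustering under missing data.

Each survey is summarized by 16 conditional termination probabilities: for
contraceptive users and non-users, six five-year age groups for women in
union plus two coarse bands (15-24, 25-49) for women not in union.  Cells
estimated from fewer than ``min_n`` unweighted pregnancies are too noisy to
trust and are set missing.  Surveys are then clustered with k-POD — a
k-means variant that alternates full k-means on a completed matrix with
re-imputation of missing cells from the assigned centroid, judging fit only
on observed cells — the number of clusters is chosen with the gap statistic,
and the completed profiles are summarized with a correlation-matrix PCA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from .dialect import AGE_GROUPS, REGROUPED_AGE_BANDS

logger = logging.getLogger(__name__)

#: Fixed feature order: users first, in-union five-year groups then the two
#: not-in-union bands; non-users follow in the same arrangement.
FEATURE_COLUMNS = tuple(
    f"{use}|{union}|{band}"
    for use in ("using", "notusing")
    for union, bands in (("in-union", AGE_GROUPS),
                         ("not-in-union", REGROUPED_AGE_BANDS))
    for band in bands
)


@dataclass
class FeatureMatrix:
    """Per-survey 16-feature termination profiles with a support mask."""

    X: pd.DataFrame            # surveys x 16, NaN = missing
    support: pd.DataFrame      # unweighted pregnancies per cell
    min_n: int = 10

    @property
    def missing_fraction(self) -> float:
        return float(self.X.isna().to_numpy().mean())


@dataclass
class ClusterModel:
    k: int
    centroids: pd.DataFrame          # k x 16, index = labels 1..k
    assignments: pd.Series           # survey -> label (1-based)
    completed: pd.DataFrame          # missing cells imputed to centroid
    objective: float                 # SSE over observed cells
    n_iterations: int
    converged: bool
    restart_count: int
    best_restart: int


@dataclass
class GapResult:
    table: pd.DataFrame              # k, log_w, ref_log_w, gap, s_k
    chosen_k: int


@dataclass
class PCAResult:
    loadings: pd.DataFrame           # components x features
    variance_fractions: np.ndarray
    scores: pd.DataFrame             # surveys x first two dimensions
    dropped_columns: list = field(default_factory=list)


def regrouped_estimates(episodes: pd.DataFrame, conf: float = 0.95
                        ) -> pd.DataFrame:
    """Per-survey cell estimates at the clustering resolution.

    In-union pregnancies keep the six age groups; not-in-union pregnancies
    are pooled into the 15-24 and 25-49 bands where small samples are
    endemic.  Returns columns survey, use, union, band, T, n_unweighted.
    """
    from .estimates import estimate_T

    df = episodes.copy()
    niu = ~df["union_at_pregnancy"].astype(bool)
    df["band"] = df["age_group"]
    df.loc[niu, "band"] = np.where(
        df.loc[niu, "imputed_age"] < 25, "15-24", "25-49")
    est = estimate_T(
        df, by=("survey", "use_at_pregnancy", "union_at_pregnancy", "band"),
        conf=conf)
    return est


def build_features(estimates: pd.DataFrame, min_n: int = 10) -> FeatureMatrix:
    """Assemble the survey x 16 matrix, masking low-support cells.

    ``estimates`` is the output of :func:`regrouped_estimates`.  A cell with
    fewer than ``min_n`` unweighted pregnancies is set missing; surveys with
    all 16 cells missing are excluded with a warning.
    """
    surveys = sorted(estimates["survey"].unique())
    X = pd.DataFrame(np.nan, index=surveys, columns=list(FEATURE_COLUMNS))
    support = pd.DataFrame(0, index=surveys, columns=list(FEATURE_COLUMNS))
    for _, r in estimates.iterrows():
        use = "using" if r["use_at_pregnancy"] else "notusing"
        union = "in-union" if r["union_at_pregnancy"] else "not-in-union"
        col = f"{use}|{union}|{r['band']}"
        if col not in X.columns:
            continue
        support.loc[r["survey"], col] = r["n_unweighted"]
        if r["n_unweighted"] >= min_n:
            X.loc[r["survey"], col] = r["T"]
    empty = X.isna().all(axis=1)
    if empty.any():
        logger.warning("excluding %d survey(s) with all cells missing: %s",
                       int(empty.sum()), list(X.index[empty]))
        X = X[~empty]
        support = support[~empty]
    return FeatureMatrix(X=X, support=support, min_n=min_n)


def _observed_objective(X: np.ndarray, mask: np.ndarray,
                        centers: np.ndarray, labels: np.ndarray) -> float:
    diff = X - centers[labels]
    diff[mask] = 0.0
    return float(np.sum(diff * diff))


def kpod(features: FeatureMatrix | pd.DataFrame, k: int,
         restarts: int = 50, max_iter: int = 200, tol: float = 1e-8,
         seed: int = 0) -> ClusterModel:
    """k-POD clustering of partially observed survey profiles.

    Missing cells start at their column's observed mean; each outer
    iteration runs full k-means on the completed matrix (k-means++ on the
    first pass of a restart, warm-started thereafter) and refills missing
    cells from the assigned centroid, until assignments are a fixpoint or
    the observed-cell objective change drops below ``tol``.  The best of
    ``restarts`` runs by observed-cell objective is kept, and clusters are
    relabelled 1..k in increasing order of centroid mean probability.
    """
    Xdf = features.X if isinstance(features, FeatureMatrix) else features
    empty_cols = Xdf.columns[Xdf.isna().all(axis=0)]
    if len(empty_cols):
        logger.warning("dropping %d feature column(s) with no observed "
                       "values: %s", len(empty_cols), list(empty_cols))
        Xdf = Xdf.drop(columns=empty_cols)
    X = Xdf.to_numpy(dtype=float)
    mask = np.isnan(X)
    n_obs_rows = int((~mask).any(axis=1).sum())
    if k > n_obs_rows:
        raise ValueError(f"k={k} exceeds surveys with observed cells "
                         f"({n_obs_rows})")
    col_means = np.nanmean(X, axis=0)

    best = None
    for r in range(restarts):
        Xc = X.copy()
        Xc[mask] = np.take(col_means, np.nonzero(mask)[1])
        prev_labels = None
        prev_obj = np.inf
        converged = False
        centers = None
        for it in range(max_iter):
            if it == 0:
                km = KMeans(n_clusters=k, init="k-means++", n_init=1,
                            random_state=seed + r)
            else:
                km = KMeans(n_clusters=k, init=centers, n_init=1,
                            random_state=seed + r)
            km.fit(Xc)
            labels = km.labels_
            centers = km.cluster_centers_
            obj = _observed_objective(X, mask, centers, labels)
            Xc[mask] = centers[labels][mask]
            if prev_labels is not None and (
                    np.array_equal(labels, prev_labels)
                    or abs(prev_obj - obj) < tol):
                converged = True
                prev_labels, prev_obj = labels, obj
                break
            prev_labels, prev_obj = labels, obj
        n_it = it + 1
        if best is None or prev_obj < best[0] - 0.0:
            best = (prev_obj, prev_labels, centers, Xc.copy(), n_it,
                    converged, r)

    obj, labels, centers, Xc, n_it, converged, r_best = best
    order = np.argsort(centers.mean(axis=1), kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    new_labels = relabel[labels]
    centroids = pd.DataFrame(centers[order], index=np.arange(1, k + 1),
                             columns=Xdf.columns)
    return ClusterModel(
        k=k, centroids=centroids,
        assignments=pd.Series(new_labels, index=Xdf.index, name="cluster"),
        completed=pd.DataFrame(Xc, index=Xdf.index, columns=Xdf.columns),
        objective=obj, n_iterations=n_it, converged=converged,
        restart_count=restarts, best_restart=r_best,
    )


def gap_select_k(features: FeatureMatrix | pd.DataFrame, kmax: int = 8,
                 B_refs: int = 10, seed: int = 0, restarts: int = 10,
                 max_iter: int = 200, tol: float = 1e-8) -> GapResult:
    """Choose the number of clusters with the gap statistic.

    Reference datasets draw each observed cell uniformly over its column's
    observed range (keeping the missing mask) and are clustered with the
    same k-POD settings.  The chosen k is the smallest with
    ``gap(k) >= gap(k+1) - s_{k+1}`` (the one-standard-error rule), falling
    back to ``kmax``.
    """
    if kmax < 2:
        raise ValueError("kmax must be at least 2")
    Xdf = features.X if isinstance(features, FeatureMatrix) else features
    Xdf = Xdf.drop(columns=Xdf.columns[Xdf.isna().all(axis=0)])
    if kmax > len(Xdf) - 1:
        # k = n surveys would zero the within-dispersion; keep k < n
        new_kmax = max(2, len(Xdf) - 1)
        logger.warning("kmax reduced from %d to %d (number of surveys - 1)",
                       kmax, new_kmax)
        kmax = new_kmax
    X = Xdf.to_numpy(dtype=float)
    mask = np.isnan(X)
    lo = np.nanmin(X, axis=0)
    hi = np.nanmax(X, axis=0)
    degenerate = hi <= lo
    if degenerate.any():
        logger.warning("%d zero-range column(s) held constant in the "
                       "reference distribution", int(degenerate.sum()))
    rng = np.random.default_rng(seed)

    ks = np.arange(1, kmax + 1)
    log_w = np.empty(kmax)
    for i, k in enumerate(ks):
        model = kpod(Xdf, int(k), restarts=restarts, max_iter=max_iter,
                     tol=tol, seed=seed)
        log_w[i] = np.log(model.objective)

    ref_log_w = np.empty((B_refs, kmax))
    for b in range(B_refs):
        R = lo + rng.random(X.shape) * np.where(degenerate, 0.0, hi - lo)
        R[mask] = np.nan
        Rdf = pd.DataFrame(R, index=Xdf.index, columns=Xdf.columns)
        ref_seed = int(rng.integers(0, 2**31 - 1))
        for i, k in enumerate(ks):
            model = kpod(Rdf, int(k), restarts=restarts, max_iter=max_iter,
                         tol=tol, seed=ref_seed)
            ref_log_w[b, i] = np.log(model.objective)

    gap = ref_log_w.mean(axis=0) - log_w
    s_k = ref_log_w.std(axis=0, ddof=0) * np.sqrt(1.0 + 1.0 / B_refs)
    chosen = int(ks[-1])
    for i in range(kmax - 1):
        if gap[i] >= gap[i + 1] - s_k[i + 1]:
            chosen = int(ks[i])
            break
    table = pd.DataFrame({
        "k": ks, "log_w": log_w, "ref_log_w": ref_log_w.mean(axis=0),
        "gap": gap, "s_k": s_k,
    })
    return GapResult(table=table, chosen_k=chosen)


def pca_profiles(completed: pd.DataFrame) -> PCAResult:
    """Correlation-matrix PCA of completed survey profiles.

    Columns are standardized so each probability contributes equally
    regardless of its level.  The first dimension is oriented so its
    loadings sum positive (an overall-level axis giving positive weight to
    every probability); other dimensions pin the sign of their largest
    loading.  Constant columns are dropped with a warning.
    """
    sd = completed.std(axis=0, ddof=1)
    # sd of a constant column carries float residue from the mean; treat
    # anything below 1e-12 (values are probabilities) as constant
    dropped = list(completed.columns[sd < 1e-12])
    if dropped:
        logger.warning("dropping constant column(s): %s", dropped)
    Xd = completed.drop(columns=dropped)
    Z = (Xd - Xd.mean(axis=0)) / Xd.std(axis=0, ddof=1)
    n_comp = min(Z.shape[0] - 1, Z.shape[1]) if Z.shape[0] > 1 else 1
    pca = PCA(n_components=n_comp)
    scores = pca.fit_transform(Z.to_numpy())
    loadings = pca.components_
    signs = np.where(
        np.abs(loadings).argmax(axis=1) >= 0,
        np.sign(loadings[np.arange(len(loadings)),
                         np.abs(loadings).argmax(axis=1)]),
        1.0)
    signs[0] = np.sign(loadings[0].sum()) or 1.0
    signs[signs == 0] = 1.0
    loadings = loadings * signs[:, None]
    scores = scores * signs[None, :]
    return PCAResult(
        loadings=pd.DataFrame(
            loadings, columns=Xd.columns,
            index=[f"dim{i + 1}" for i in range(n_comp)]),
        variance_fractions=pca.explained_variance_ratio_.copy(),
        scores=pd.DataFrame(scores[:, :2], index=completed.index,
                            columns=["dim1", "dim2"]),
        dropped_columns=dropped,
    )
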