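"""Multivariate models: PCA metabotype discovery and two-class OPLS-DA.

OPLS-DA separates class-predictive variation from orthogonal (class-
unrelated) variation.  Per orthogonal round, with X column-centered and y
coded -1/+1:

    w  = X'y / ||X'y||          predictive weight
    t  = Xw,  p = X't / t't     predictive score / loading
    w_o = p - (w'p) w,  normalized
    t_o = X w_o,  p_o = X't_o / t_o't_o
    X  <- X - t_o p_o'          deflation

After ``n_orth`` rounds a single predictive component is fitted on the
deflated matrix.  Orthogonal scores are exactly uncorrelated with y by
construction.  VIP scores are computed over the predictive component(s)
only; their squares average to 1 across bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA as _SkPCA
from sklearn.metrics import silhouette_score

from .preprocessing import BinnedMatrix, ColumnScaler

__all__ = [
    "PcaModel",
    "OplsdaModel",
    "fit_pca",
    "detect_spontaneous_clusters",
    "overlay_covariates",
    "fit_oplsda",
    "predict_oplsda",
    "compute_vip",
]


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PcaModel:
    loadings: np.ndarray  # bins x components, orthonormal
    scores: np.ndarray  # samples x components
    explained_variance_fraction: np.ndarray
    means: np.ndarray
    bin_labels: list[str] = field(default_factory=list)


def fit_pca(m: BinnedMatrix | pd.DataFrame | np.ndarray, n_components: int) -> PcaModel:
    """Column-center and fit PCA; scores are projections on orthonormal loadings."""
    if isinstance(m, BinnedMatrix):
        df = m.values
    elif isinstance(m, pd.DataFrame):
        df = m
    else:
        df = pd.DataFrame(np.asarray(m, dtype=float))
    X = df.to_numpy(dtype=float)
    max_rank = min(X.shape[0] - 1, X.shape[1])
    if not 1 <= n_components <= max_rank:
        raise ValueError(f"n_components must be in [1, {max_rank}]")
    pca = _SkPCA(n_components=n_components, svd_solver="full")
    scores = pca.fit_transform(X)
    return PcaModel(
        loadings=pca.components_.T,
        scores=scores,
        explained_variance_fraction=pca.explained_variance_ratio_,
        means=pca.mean_,
        bin_labels=[str(c) for c in df.columns],
    )


def detect_spontaneous_clusters(
    scores: np.ndarray,
    k_clusters: int = 2,
    n_restarts: int = 50,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Centroid-based partition of the first two PC scores.

    Returns (labels, mean silhouette).  Automates the visual call of a
    spontaneous two-group split in a scores plot.  Silhouette is NaN for a
    single cluster.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    pts = scores[:, : min(2, scores.shape[1])]
    if pts.shape[0] < k_clusters:
        raise ValueError("need at least k_clusters samples")
    if k_clusters == 1:
        return np.zeros(pts.shape[0], dtype=int), float("nan")
    if np.allclose(pts, pts[0]):
        raise ValueError("degenerate scores: all samples identical")
    km = KMeans(n_clusters=k_clusters, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(pts)
    sil = float(silhouette_score(pts, labels)) if len(np.unique(labels)) > 1 else float("nan")
    return labels, sil


DEFAULT_COVARIATES = ("age", "gender", "ethnicity", "episode_type", "disease_duration")


def overlay_covariates(
    labels: np.ndarray,
    meta: pd.DataFrame,
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
) -> pd.DataFrame:
    """Association of a binary cluster labelling with clinical covariates.

    Continuous covariates are compared with Mann-Whitney U; categorical ones
    with Fisher's exact test (multi-level categories are collapsed to the
    most frequent level vs the rest, mirroring the common White-vs-combined
    convention).  Raw and Bonferroni-adjusted p values are returned with
    m = number of covariates actually tested.
    """
    labels = np.asarray(labels)
    if meta.shape[0] == 0:
        raise ValueError("empty metadata")
    if len(np.unique(labels)) != 2:
        raise ValueError("labels must be binary")
    if len(labels) != meta.shape[0]:
        raise ValueError("labels/metadata length mismatch")

    rows = []
    for cov in covariates:
        if cov not in meta.columns:
            rows.append({"covariate": cov, "test": "missing", "p_raw": np.nan, "note": "absent"})
            continue
        col = meta[cov]
        if pd.api.types.is_numeric_dtype(col):
            g0 = col[labels == np.unique(labels)[0]].dropna()
            g1 = col[labels == np.unique(labels)[1]].dropna()
            if g0.nunique() <= 1 and g1.nunique() <= 1 and set(g0) == set(g1):
                rows.append({"covariate": cov, "test": "skipped", "p_raw": np.nan, "note": "constant"})
                continue
            p = stats.mannwhitneyu(g0, g1, alternative="two-sided").pvalue
            rows.append({"covariate": cov, "test": "mann_whitney", "p_raw": float(p), "note": ""})
        else:
            levels = col.astype(str)
            uniq = levels.value_counts()
            if len(uniq) < 2:
                rows.append({"covariate": cov, "test": "skipped", "p_raw": np.nan, "note": "single level"})
                continue
            top = uniq.index[0]
            binary = (levels == top).to_numpy()
            table = np.array(
                [
                    [np.sum(binary & (labels == np.unique(labels)[0])), np.sum(~binary & (labels == np.unique(labels)[0]))],
                    [np.sum(binary & (labels == np.unique(labels)[1])), np.sum(~binary & (labels == np.unique(labels)[1]))],
                ]
            )
            p = stats.fisher_exact(table, alternative="two-sided")[1]
            note = f"collapsed to {top!r} vs rest" if len(uniq) > 2 else ""
            rows.append({"covariate": cov, "test": "fisher_exact", "p_raw": float(p), "note": note})
    out = pd.DataFrame(rows)
    tested = out["p_raw"].notna()
    m = int(tested.sum())
    out["p_adjusted"] = np.where(tested, np.minimum(1.0, out["p_raw"] * m), np.nan)
    out.attrs["bonferroni_m"] = m
    return out


# ---------------------------------------------------------------------------
# OPLS-DA
# ---------------------------------------------------------------------------

@dataclass
class OplsdaModel:
    """Fitted two-class OPLS-DA parameters.

    The predictive weight ``w`` has unit norm; ``orthogonal_*`` arrays hold
    one row per orthogonal component.  ``class_map`` maps the two class
    labels to -1/+1; ``threshold`` is the midpoint of the class-mean
    predictive scores.
    """

    w: np.ndarray
    t: np.ndarray
    p: np.ndarray
    orthogonal_w: np.ndarray  # n_orth x bins
    orthogonal_t: np.ndarray  # samples x n_orth
    orthogonal_p: np.ndarray  # n_orth x bins
    class_map: dict[str, int]
    threshold: float
    vip: np.ndarray
    bin_labels: list[str]
    scaler: ColumnScaler
    y_coded: np.ndarray
    ssy_explained: np.ndarray  # y sum-of-squares explained per predictive comp

    @property
    def n_orth(self) -> int:
        return self.orthogonal_w.shape[0]

    @property
    def positive_label(self) -> str:
        return next(k for k, v in self.class_map.items() if v == +1)

    def to_json(self, path) -> None:
        """Serialize the fitted model (arrays inline) to a JSON file."""
        import json
        from pathlib import Path

        payload = {
            "w": self.w.tolist(),
            "p": self.p.tolist(),
            "orthogonal_w": self.orthogonal_w.tolist(),
            "orthogonal_p": self.orthogonal_p.tolist(),
            "class_map": self.class_map,
            "threshold": self.threshold,
            "vip": self.vip.tolist(),
            "bin_labels": self.bin_labels,
            "scaler": {
                "scaling": self.scaler.scaling,
                "center": self.scaler.center,
                "means": self.scaler.means_.tolist(),
                "scale": self.scaler.scale_.tolist(),
            },
            "t": self.t.tolist(),
            "y_coded": self.y_coded.tolist(),
            "ssy_explained": np.asarray(self.ssy_explained).tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "OplsdaModel":
        import json
        from pathlib import Path

        d = json.loads(Path(path).read_text())
        scaler = ColumnScaler(d["scaler"]["scaling"], d["scaler"]["center"])
        scaler.means_ = np.asarray(d["scaler"]["means"], dtype=float)
        scaler.scale_ = np.asarray(d["scaler"]["scale"], dtype=float)
        n_bins = len(d["w"])
        ow = np.asarray(d["orthogonal_w"], dtype=float).reshape(-1, n_bins)
        op = np.asarray(d["orthogonal_p"], dtype=float).reshape(-1, n_bins)
        return cls(
            w=np.asarray(d["w"], dtype=float),
            t=np.asarray(d["t"], dtype=float),
            p=np.asarray(d["p"], dtype=float),
            orthogonal_w=ow,
            orthogonal_t=np.zeros((len(d["y_coded"]), ow.shape[0])),
            orthogonal_p=op,
            class_map={k: int(v) for k, v in d["class_map"].items()},
            threshold=float(d["threshold"]),
            vip=np.asarray(d["vip"], dtype=float),
            bin_labels=list(d["bin_labels"]),
            scaler=scaler,
            y_coded=np.asarray(d["y_coded"], dtype=float),
            ssy_explained=np.asarray(d["ssy_explained"], dtype=float),
        )


def _code_classes(y: np.ndarray, positive_label: str | None) -> tuple[np.ndarray, dict[str, int]]:
    classes = sorted(map(str, np.unique(y)))
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {classes}")
    if positive_label is None:
        positive_label = classes[1]
    if str(positive_label) not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {classes}")
    negative = next(c for c in classes if c != str(positive_label))
    class_map = {negative: -1, str(positive_label): +1}
    coded = np.array([class_map[str(v)] for v in y], dtype=float)
    return coded, class_map


def fit_oplsda(
    X: np.ndarray | pd.DataFrame,
    y: np.ndarray | list,
    n_orth: int = 1,
    scaling: str = "pareto",
    center: bool = True,
    positive_label: str | None = None,
    bin_labels: list[str] | None = None,
) -> OplsdaModel:
    """Fit a two-class OPLS-DA model with one predictive component.

    Scaling/centering parameters are estimated on the training matrix and
    stored in the model so prediction applies the identical transform.
    """
    if isinstance(X, pd.DataFrame):
        if bin_labels is None:
            bin_labels = [str(c) for c in X.columns]
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X/y length mismatch")
    if n_orth < 0:
        raise ValueError("n_orth must be >= 0")
    coded, class_map = _code_classes(y, positive_label)
    for lbl, code in class_map.items():
        if np.sum(coded == code) < 3:
            raise ValueError(f"class {lbl!r} needs at least 3 samples")
    if np.std(coded) == 0:
        raise ValueError("zero-variance class vector")
    if bin_labels is None:
        bin_labels = [str(j) for j in range(X.shape[1])]

    scaler = ColumnScaler(scaling, center).fit(X)
    Xd = scaler.transform(X)
    yc = coded - coded.mean()

    ortho_w, ortho_t, ortho_p = [], [], []
    for _ in range(n_orth):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw == 0:
            raise ValueError("degenerate fit: all-zero weight vector")
        w /= nw
        t = Xd @ w
        p = Xd.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o == 0:
            break  # no orthogonal variation left
        w_o /= n_o
        t_o = Xd @ w_o
        p_o = Xd.T @ t_o / (t_o @ t_o)
        Xd = Xd - np.outer(t_o, p_o)
        ortho_w.append(w_o)
        ortho_t.append(t_o)
        ortho_p.append(p_o)

    w = Xd.T @ yc
    nw = np.linalg.norm(w)
    if nw == 0:
        raise ValueError("degenerate fit: all-zero weight vector")
    w /= nw
    t = Xd @ w
    p = Xd.T @ t / (t @ t)

    mean_pos = t[coded == +1].mean()
    mean_neg = t[coded == -1].mean()
    threshold = 0.5 * (mean_pos + mean_neg)

    b = (t @ yc) / (t @ t)
    ssy = np.array([b**2 * (t @ t)])

    n_o = len(ortho_w)
    model = OplsdaModel(
        w=w,
        t=t,
        p=p,
        orthogonal_w=np.array(ortho_w).reshape(n_o, X.shape[1]),
        orthogonal_t=np.array(ortho_t).T.reshape(X.shape[0], n_o),
        orthogonal_p=np.array(ortho_p).reshape(n_o, X.shape[1]),
        class_map=class_map,
        threshold=float(threshold),
        vip=np.empty(0),
        bin_labels=list(bin_labels),
        scaler=scaler,
        y_coded=coded,
        ssy_explained=ssy,
    )
    model.vip = compute_vip(model)
    return model


def predict_oplsda(
    model: OplsdaModel,
    X_new: np.ndarray | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray]:
    """Predictive scores and class labels for new samples.

    Applies training centering/scaling, strips each orthogonal component
    (t_o = X w_o; X <- X - t_o p_o'), scores on the predictive weight and
    thresholds at the training midpoint.
    """
    if isinstance(X_new, pd.DataFrame):
        cols = [str(c) for c in X_new.columns]
        if cols != model.bin_labels:
            raise ValueError("column mismatch between model and new data")
        X_new = X_new.to_numpy(dtype=float)
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new[None, :]
    if X_new.shape[1] != model.w.size:
        raise ValueError(
            f"column mismatch: model has {model.w.size} bins, data has {X_new.shape[1]}"
        )
    Xd = model.scaler.transform(X_new)
    for w_o, p_o in zip(model.orthogonal_w, model.orthogonal_p):
        t_o = Xd @ w_o
        Xd = Xd - np.outer(t_o, p_o)
    scores = Xd @ model.w
    # orient: positive class has the higher training mean score
    pos_high = model.t[model.y_coded == +1].mean() > model.t[model.y_coded == -1].mean()
    inv = {v: k for k, v in model.class_map.items()}
    if pos_high:
        labels = np.where(scores > model.threshold, inv[+1], inv[-1])
    else:
        labels = np.where(scores > model.threshold, inv[-1], inv[+1])
    return scores, labels


def compute_vip(model: OplsdaModel) -> np.ndarray:
    """VIP over the predictive component(s) only.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja/||w_a||)^2 / sum_a SSY_a ), so the
    squared scores average to 1 across the p bins.
    """
    W = np.atleast_2d(model.w)  # components x bins
    ssy = np.asarray(model.ssy_explained, dtype=float)
    p_bins = W.shape[1]
    norms = np.linalg.norm(W, axis=1)
    frac = (W / norms[:, None]) ** 2
    return np.sqrt(p_bins * (ssy @ frac) / ssy.sum())
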