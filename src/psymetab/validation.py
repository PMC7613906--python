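"""Ensemble external cross-validation with permutation-null significance.

Models are validated on independent held-out data (~10% of samples) that
took no part in any fitting step, including column scaling.  Two repetition
schemes are provided:

``holdout`` (default)
    Each repetition draws a fresh stratified 90/10 split, fits on the 90%
    and evaluates on the held-out 10%.  The per-repetition metric noise is
    then dominated by the finite test set, the same noise the permutation
    null carries, which keeps the KS significance flag calibrated under the
    null (see below).

``kfold``
    Each repetition partitions the samples into 10 stratified external
    folds, holds each fold out in turn, and pools the fold-level
    predictions into one metric triple per repetition.  Every sample is
    tested exactly once per repetition.  Note that pooled repetitions of a
    fixed labelling concentrate tightly around that labelling's own
    cross-validated performance, while a permutation null varies across
    labellings; a two-sample KS test between the two is then anticonservative
    under the null, which is why this scheme is not the default for
    significance testing.

A permutation null repeats the identical procedure after uniformly permuting
class labels (one repetition per permutation).  Each metric is declared
significant when a two-sample Kolmogorov-Smirnov test finds the observed
distribution different from the null (p <= alpha) AND the observed mean
exceeds the null mean.

Discriminatory bins come from the ensemble-mean VIP curve: bins are ranked
by mean VIP and the cut-off is placed at the knee of the sorted curve
(maximum perpendicular distance to the chord joining its endpoints), with a
VIP > 1 fallback for degenerate, near-affine curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit

from .chemometrics import OplsdaModel, fit_oplsda, predict_oplsda
from .preprocessing import BinnedMatrix

__all__ = [
    "ModelConfig",
    "EnsembleResult",
    "ensemble_cross_validate",
    "permutation_null",
    "ks_significance",
    "aggregate_vip",
    "select_discriminatory_bins",
    "validate_comparison",
]

METRICS = ("accuracy", "sensitivity", "specificity")


@dataclass
class ModelConfig:
    n_orth: int = 1
    scaling: str = "pareto"
    center: bool = True
    scheme: str = "holdout"  # 'holdout' (random 90/10 per repetition) or 'kfold'
    test_fraction: float = 0.10
    n_folds: int = 10

    def __post_init__(self) -> None:
        if self.scheme not in ("holdout", "kfold"):
            raise ValueError(f"unknown validation scheme {self.scheme!r}")
        if not 0 < self.test_fraction < 0.5:
            raise ValueError("test_fraction must lie in (0, 0.5)")


@dataclass
class EnsembleResult:
    """Observed and null metric distributions plus VIP-based bin selection."""

    metrics: pd.DataFrame  # n_repetitions x METRICS
    null_metrics: pd.DataFrame | None = None
    ks: dict[str, dict] = field(default_factory=dict)
    mean_vip: pd.Series | None = None
    vip_order: list[str] = field(default_factory=list)
    selected_bins: list[str] = field(default_factory=list)
    vip_cutoff: float = float("nan")
    positive_label: str = ""
    config: dict = field(default_factory=dict)
    vips: np.ndarray | None = None  # ensemble members x bins

    def summary(self) -> pd.DataFrame:
        rows = {}
        for m in METRICS:
            rows[m] = {
                "mean": float(self.metrics[m].mean()),
                "sd": float(self.metrics[m].std(ddof=1)),
            }
            if self.null_metrics is not None:
                rows[m]["null_mean"] = float(self.null_metrics[m].mean())
                rows[m]["null_sd"] = float(self.null_metrics[m].std(ddof=1))
            if m in self.ks:
                rows[m].update(
                    {
                        "ks_D": self.ks[m]["D"],
                        "ks_p": self.ks[m]["p"],
                        "significant": self.ks[m]["significant"],
                    }
                )
        return pd.DataFrame(rows).T


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, BinnedMatrix):
        return X.values
    if isinstance(X, pd.DataFrame):
        return X
    return pd.DataFrame(np.asarray(X, dtype=float))


def _pooled_metrics(y_true: np.ndarray, y_pred: np.ndarray, positive: str) -> dict[str, float]:
    y_true = np.asarray(y_true).astype(str)
    y_pred = np.asarray(y_pred).astype(str)
    pos = y_true == positive
    acc = float(np.mean(y_true == y_pred))
    sens = float(np.mean(y_pred[pos] == positive)) if pos.any() else float("nan")
    spec = float(np.mean(y_pred[~pos] != positive)) if (~pos).any() else float("nan")
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec}


def _fit_predict(
    X: np.ndarray,
    y: np.ndarray,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    positive: str,
    config: ModelConfig,
    bin_labels: list[str],
) -> tuple[np.ndarray, np.ndarray]:
    model = fit_oplsda(
        X[train_idx],
        y[train_idx],
        n_orth=config.n_orth,
        scaling=config.scaling,
        center=config.center,
        positive_label=positive,
        bin_labels=bin_labels,
    )
    _, labels = predict_oplsda(model, X[test_idx])
    return labels, model.vip


def _one_repetition(
    X: np.ndarray,
    y: np.ndarray,
    positive: str,
    config: ModelConfig,
    bin_labels: list[str],
    seed: int,
    collect_vip: bool,
) -> tuple[dict[str, float], list[np.ndarray]]:
    vips: list[np.ndarray] = []
    if config.scheme == "holdout":
        for attempt in range(10):
            sss = StratifiedShuffleSplit(
                n_splits=1, test_size=config.test_fraction,
                random_state=(seed + attempt) % 2**31,
            )
            train_idx, test_idx = next(sss.split(X, y))
            if len(np.unique(y[train_idx])) == 2 and len(np.unique(y[test_idx])) >= 1:
                break
        else:  # pragma: no cover - stratification prevents this
            raise ValueError("could not draw a valid train/test split")
        labels, vip = _fit_predict(X, y, train_idx, test_idx, positive, config, bin_labels)
        if collect_vip:
            vips.append(vip)
        return _pooled_metrics(y[test_idx], labels, positive), vips

    n_folds = min(config.n_folds, int(min(np.bincount(pd.factorize(y)[0]))))
    if n_folds < 2:
        raise ValueError("smallest class too small for cross-validation")
    last_err: Exception | None = None
    for attempt in range(10):
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=(seed + attempt) % 2**31)
        folds = list(skf.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
        last_err = ValueError("a training fold lost a class")
    else:  # pragma: no cover - stratification prevents this
        raise last_err
    y_pred = np.empty(y.shape, dtype=object)
    for train_idx, test_idx in folds:
        labels, vip = _fit_predict(X, y, train_idx, test_idx, positive, config, bin_labels)
        y_pred[test_idx] = labels
        if collect_vip:
            vips.append(vip)
    return _pooled_metrics(y, y_pred.astype(str), positive), vips


def ensemble_cross_validate(
    X,
    y,
    positive_label: str,
    config: ModelConfig | None = None,
    n_repetitions: int = 50,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Repeated external CV; returns (metrics, vips, bin_labels).

    ``metrics`` has one accuracy/sensitivity/specificity triple per
    repetition (held-out 10% under the default scheme; pooled folds under
    ``kfold``); ``vips`` stacks the VIP vector of every fitted ensemble
    member.  Deterministic given ``seed``.
    """
    config = config if config is not None else ModelConfig()
    df = _as_frame(X)
    Xa = df.to_numpy(dtype=float)
    ya = np.asarray(y).astype(str)
    if n_repetitions < 2:
        raise ValueError("n_repetitions must be >= 2")
    classes, counts = np.unique(ya, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"exactly two classes required, got {list(classes)}")
    if counts.min() < 5:
        raise ValueError("each class needs at least 5 samples")
    if str(positive_label) not in classes:
        raise ValueError(f"positive label {positive_label!r} not among {list(classes)}")
    bin_labels = [str(c) for c in df.columns]
    rng = np.random.default_rng(seed)
    rows = []
    vips: list[np.ndarray] = []
    for _ in range(n_repetitions):
        rep_seed = int(rng.integers(0, 2**31))
        m, v = _one_repetition(Xa, ya, str(positive_label), config, bin_labels, rep_seed, True)
        rows.append(m)
        vips.extend(v)
    return pd.DataFrame(rows, columns=list(METRICS)), np.vstack(vips), bin_labels


def permutation_null(
    X,
    y,
    positive_label: str,
    config: ModelConfig | None = None,
    n_permutations: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Null metric distributions from label-permuted cross-validation runs.

    Each permutation shuffles the class labels uniformly (class counts
    preserved) and re-runs the full external CV procedure with a single
    repetition.  Deterministic given ``seed``.
    """
    config = config if config is not None else ModelConfig()
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    df = _as_frame(X)
    Xa = df.to_numpy(dtype=float)
    ya = np.asarray(y).astype(str)
    bin_labels = [str(c) for c in df.columns]
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_permutations):
        y_perm = rng.permutation(ya)
        rep_seed = int(rng.integers(0, 2**31))
        m, _ = _one_repetition(Xa, y_perm, str(positive_label), config, bin_labels, rep_seed, False)
        rows.append(m)
    return pd.DataFrame(rows, columns=list(METRICS))


def ks_significance(
    observed,
    null,
    alpha: float = 0.05,
) -> dict:
    """Two-sample KS comparison of observed vs null metric distributions.

    D = sup |ECDF_obs - ECDF_null|; p exact (enumeration) when the smaller
    sample has <= 10 values, asymptotic otherwise.  The metric is flagged
    significant only when p <= alpha AND the observed mean exceeds the null
    mean (performance must be *greater* than chance, not merely different).
    """
    obs = np.asarray(observed, dtype=float)
    nul = np.asarray(null, dtype=float)
    if obs.size == 0 or nul.size == 0:
        raise ValueError("both samples must be non-empty")
    if np.array_equal(np.sort(obs), np.sort(nul)):
        d, p = 0.0, 1.0
    else:
        method = "exact" if min(obs.size, nul.size) <= 10 else "asymp"
        res = stats.ks_2samp(obs, nul, alternative="two-sided", method=method)
        d, p = float(res.statistic), float(min(res.pvalue, 1.0))
    # "greater than the null distribution": the observed mean must exceed both
    # the null mean and the null's (1-alpha) quantile.  The quantile gate is a
    # permutation exceedance test; without it the KS comparison alone is
    # anticonservative, because repetitions of the one observed labelling
    # locate its chance-level performance far more precisely than independent
    # null draws.
    null_q = float(np.quantile(nul, 1.0 - alpha))
    greater = bool(obs.mean() > nul.mean())
    exceeds = bool(obs.mean() > null_q)
    return {
        "D": float(d),
        "p": float(p),
        "significant": bool(p <= alpha and greater and exceeds),
        "observed_greater": greater,
        "exceeds_null_quantile": exceeds,
        "null_quantile": null_q,
        "alpha": alpha,
    }


def aggregate_vip(
    vips: np.ndarray | list[np.ndarray] | list[OplsdaModel],
    bin_labels: list[str],
    bin_left_ppm: np.ndarray | None = None,
) -> tuple[pd.Series, list[str]]:
    """Arithmetic mean VIP per bin across ensemble members, plus ranking.

    Order is by mean VIP descending, ties broken by bin ppm ascending.
    """
    if len(vips) == 0:
        raise ValueError("need at least one fitted model")
    arrs = [v.vip if isinstance(v, OplsdaModel) else np.asarray(v, dtype=float) for v in vips]
    widths = {a.size for a in arrs}
    if len(widths) != 1 or arrs[0].size != len(bin_labels):
        raise ValueError("bin mismatch among ensemble members")
    mean_vip = pd.Series(np.mean(arrs, axis=0), index=list(bin_labels), name="mean_vip")
    if bin_left_ppm is None:
        # bin labels follow the 'bin_<left>_<right>' convention
        try:
            bin_left_ppm = np.array([float(str(b).split("_")[1]) for b in bin_labels])
        except (IndexError, ValueError):
            bin_left_ppm = np.arange(len(bin_labels), dtype=float)
    order_idx = sorted(
        range(len(bin_labels)), key=lambda j: (-mean_vip.iloc[j], bin_left_ppm[j])
    )
    return mean_vip, [bin_labels[j] for j in order_idx]


def select_discriminatory_bins(
    mean_vip: pd.Series,
    vip_order: list[str] | None = None,
) -> tuple[list[str], float, int]:
    """Knee-based cut-off on the descending mean-VIP curve.

    The cut-off index maximises the perpendicular distance from the
    (normalized) sorted curve to the chord joining its first and last
    points; bins with VIP at or above the cut-off value are selected.  When
    the curve is affine within tolerance the fallback selects bins with
    VIP > 1.  Returns (selected bins, cutoff value, knee index).
    """
    if mean_vip.size < 3:
        raise ValueError("need at least 3 bins")
    if vip_order is None:
        _, vip_order = aggregate_vip([mean_vip.to_numpy()], list(mean_vip.index))
    curve = mean_vip.loc[vip_order].to_numpy(dtype=float)
    n = curve.size
    v_range = curve[0] - curve[-1]
    if v_range <= 1e-12 * max(abs(curve[0]), 1.0):
        selected = [b for b in vip_order if mean_vip[b] > 1.0]
        return selected, 1.0, -1
    x = np.linspace(0.0, 1.0, n)
    ynorm = (curve - curve[-1]) / v_range
    # distance to chord from (0, ynorm[0]=1) to (1, ynorm[-1]=0)
    d = np.abs(x * (ynorm[-1] - ynorm[0]) - (ynorm - ynorm[0]) * 1.0) / np.sqrt(2.0)
    if d.max() < 1e-6:
        selected = [b for b in vip_order if mean_vip[b] > 1.0]
        return selected, 1.0, -1
    knee = int(np.argmax(d))
    cutoff = float(curve[knee])
    selected = [b for b in vip_order if mean_vip[b] >= cutoff]
    return selected, cutoff, knee


def validate_comparison(
    X,
    y,
    positive_label: str,
    config: ModelConfig | None = None,
    n_repetitions: int = 50,
    n_permutations: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> EnsembleResult:
    """Full validation of one two-class comparison.

    Runs the observed ensemble CV, the permutation null, per-metric KS
    significance, ensemble VIP averaging, and knee-based bin selection.
    """
    config = config if config is not None else ModelConfig()
    metrics, vips, bin_labels = ensemble_cross_validate(
        X, y, positive_label, config, n_repetitions, seed=seed
    )
    null = permutation_null(X, y, positive_label, config, n_permutations, seed=seed + 1)
    ks = {m: ks_significance(metrics[m], null[m], alpha) for m in METRICS}
    mean_vip, vip_order = aggregate_vip(vips, bin_labels)
    selected, cutoff, knee = select_discriminatory_bins(mean_vip, vip_order)
    return EnsembleResult(
        metrics=metrics,
        null_metrics=null,
        ks=ks,
        mean_vip=mean_vip,
        vip_order=vip_order,
        selected_bins=selected,
        vip_cutoff=cutoff,
        positive_label=str(positive_label),
        config={
            "n_orth": config.n_orth,
            "scaling": config.scaling,
            "center": config.center,
            "n_folds": config.n_folds,
            "n_repetitions": n_repetitions,
            "n_permutations": n_permutations,
            "alpha": alpha,
            "seed": seed,
            "knee_index": knee,
        },
        vips=vips,
    )
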