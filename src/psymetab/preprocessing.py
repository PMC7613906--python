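"""Spectral preprocessing: referencing, baseline, binning, normalization.

The pipeline follows the serum NMR convention of referencing each spectrum to
the lactate doublet at 1.33 ppm, removing a fifth-degree polynomial baseline,
and integrating 0.02-ppm bins over 0.80-8.47 ppm with the water resonance
region (4.13-5.22 ppm) excluded, which yields 328 retained bins.

Bin-edge convention: a fixed grid anchored at the region's left edge,
left-closed/right-open bins, a partial final bin dropped, and exclusion of
any bin overlapping the open water interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .spectra import Spectrum

__all__ = [
    "ReferencingError",
    "PreprocessConfig",
    "BinnedMatrix",
    "ColumnScaler",
    "reference_to_lactate",
    "correct_baseline",
    "bin_spectrum",
    "default_bin_edges",
    "bin_label",
    "normalize_and_scale",
    "assemble_matrix",
]

_EPS = 1e-9

DEFAULT_BIN_WIDTH = 0.02
DEFAULT_REGION = (0.80, 8.47)
DEFAULT_EXCLUSION = (4.13, 5.22)


class ReferencingError(RuntimeError):
    pass


def bin_label(left: float, right: float) -> str:
    return f"bin_{left:.2f}_{right:.2f}"


def default_bin_edges(
    width: float = DEFAULT_BIN_WIDTH,
    region: tuple[float, float] = DEFAULT_REGION,
    exclusion: tuple[float, float] | None = DEFAULT_EXCLUSION,
) -> np.ndarray:
    """Retained (left, right) bin edges under the study's edge convention."""
    if width <= 0:
        raise ValueError("bin width must be positive")
    lo, hi = region
    n_total = int(np.floor((hi - lo) / width + _EPS))
    lefts = lo + width * np.arange(n_total)
    rights = lefts + width
    if exclusion is not None:
        ex_lo, ex_hi = exclusion
        keep = ~((rights > ex_lo + _EPS) & (lefts < ex_hi - _EPS))
    else:
        keep = np.ones(n_total, dtype=bool)
    return np.column_stack([lefts[keep], rights[keep]])


def reference_to_lactate(
    s: Spectrum,
    target: float = 1.33,
    search_halfwidth: float = 0.05,
) -> tuple[Spectrum, float]:
    """Shift the ppm axis so the lactate doublet centroid sits at ``target``.

    The centroid is the mean position of the two highest local maxima inside
    ``target +/- search_halfwidth``.  Raises :class:`ReferencingError` naming
    the sample when fewer than two local maxima are found.
    """
    sp = s.sorted()
    lo, hi = target - search_halfwidth, target + search_halfwidth
    if sp.ppm[0] > lo or sp.ppm[-1] < hi:
        raise ValueError("search window extends beyond the spectrum axis")
    mask = (sp.ppm >= lo) & (sp.ppm <= hi)
    window_ppm = sp.ppm[mask]
    window_y = sp.intensity[mask]
    peaks, _ = find_peaks(window_y)
    if peaks.size < 2:
        raise ReferencingError(
            f"sample {s.sample_id!r}: fewer than two local maxima in the "
            f"lactate search window [{lo:.3f}, {hi:.3f}] ppm"
        )
    top2 = peaks[np.argsort(window_y[peaks])[-2:]]
    centroid = float(np.mean(window_ppm[top2]))
    shift = target - centroid
    out = s.shifted(shift)
    out.meta["referencing_shift_ppm"] = shift
    return out, shift


def correct_baseline(
    s: Spectrum,
    degree: int = 5,
    max_iter: int = 20,
    k: float = 3.0,
) -> Spectrum:
    """Subtract an iteratively reweighted polynomial baseline.

    Fits a degree-``degree`` polynomial, then repeatedly drops points lying
    more than ``k`` robust standard deviations above the fit (peaks) and
    refits, until the support set stabilises or ``max_iter`` is reached.
    Non-convergence produces a warning and is flagged in provenance.
    """
    if degree < 0:
        raise ValueError("degree must be >= 0")
    if s.ppm.size < degree + 2:
        raise ValueError("need at least degree + 2 points")
    sp = s.sorted()
    y = sp.intensity
    support = np.ones(y.size, dtype=bool)
    converged = False
    fit_vals = np.zeros_like(y)
    # converged when the support set changes by <= 0.1% of points
    change_tol = max(1, int(0.001 * y.size))
    for _ in range(max_iter):
        poly = np.polynomial.Polynomial.fit(sp.ppm[support], y[support], degree)
        fit_vals = poly(sp.ppm)
        resid = y - fit_vals
        neg = resid[resid <= 0]
        sigma = 1.4826 * float(np.median(np.abs(neg))) if neg.size else 0.0
        sigma = max(sigma, 1e-12 * max(float(np.max(np.abs(y))), 1.0))
        new_support = resid <= k * sigma
        if new_support.sum() < degree + 2:
            break
        if int(np.sum(new_support != support)) <= change_tol:
            converged = True
            support = new_support
            break
        support = new_support
    if not converged:
        warnings.warn(
            f"baseline correction did not converge for sample {s.sample_id!r}",
            RuntimeWarning,
            stacklevel=2,
        )
    corrected = y - fit_vals
    if not s.ascending:
        corrected = corrected[::-1]
    out = Spectrum(s.ppm.copy(), corrected, s.sample_id, dict(s.meta))
    out.meta["baseline_converged"] = converged
    return out


def _cumulative_trapezoid_at(ppm: np.ndarray, y: np.ndarray, points: np.ndarray) -> np.ndarray:
    """Trapezoidal antiderivative of (ppm, y) evaluated at arbitrary points.

    Equivalent to inserting each evaluation point as an interpolated node and
    integrating with the trapezoid rule, so bin values F(b) - F(a) are
    exactly additive over adjacent intervals.
    """
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (y[1:] + y[:-1]) * np.diff(ppm))])
    idx = np.searchsorted(ppm, points, side="right") - 1
    idx = np.clip(idx, 0, ppm.size - 2)
    x0 = ppm[idx]
    y0 = y[idx]
    slope = (y[idx + 1] - y0) / (ppm[idx + 1] - x0)
    dx = points - x0
    y_at = y0 + slope * dx
    return cum[idx] + 0.5 * (y0 + y_at) * dx


def bin_spectrum(
    s: Spectrum,
    width: float = DEFAULT_BIN_WIDTH,
    region: tuple[float, float] = DEFAULT_REGION,
    exclusion: tuple[float, float] | None = DEFAULT_EXCLUSION,
) -> tuple[np.ndarray, np.ndarray]:
    """Integrate the spectrum over the retained bin grid.

    Returns (values, edges) where ``values[i]`` is the trapezoidal integral
    of intensity over ``edges[i]``.  The axis must sample at least four
    points per bin width.
    """
    sp = s.sorted()
    step = float(np.max(np.diff(sp.ppm)))
    if step > width / 4.0 + _EPS:
        raise ValueError(
            f"axis resolution {step:.4g} ppm is coarser than a quarter bin width "
            f"({width / 4.0:.4g} ppm)"
        )
    if sp.ppm[0] > region[0] or sp.ppm[-1] < region[1]:
        raise ValueError("binning region extends beyond the spectrum axis")
    edges = default_bin_edges(width, region, exclusion)
    lefts = _cumulative_trapezoid_at(sp.ppm, sp.intensity, edges[:, 0])
    rights = _cumulative_trapezoid_at(sp.ppm, sp.intensity, edges[:, 1])
    return rights - lefts, edges


@dataclass
class PreprocessConfig:
    reference: bool = True
    reference_target: float = 1.33
    reference_halfwidth: float = 0.05
    baseline: bool = True
    baseline_degree: int = 5
    bin_width: float = DEFAULT_BIN_WIDTH
    region: tuple[float, float] = DEFAULT_REGION
    exclusion: tuple[float, float] | None = DEFAULT_EXCLUSION
    normalization: str = "pqn"
    scaling: str = "pareto"
    center: bool = True


@dataclass
class BinnedMatrix:
    """Samples x retained-bins feature matrix with processing state."""

    values: pd.DataFrame
    bin_edges: np.ndarray
    normalization_state: str = "raw"
    scaling_state: str = "none"
    centered: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        if self.bin_edges.shape != (self.values.shape[1], 2):
            raise ValueError("bin_edges must align with matrix columns")
        lefts, rights = self.bin_edges[:, 0], self.bin_edges[:, 1]
        if np.any(rights <= lefts):
            raise ValueError("bins must have positive width")
        if np.any(lefts[1:] < rights[:-1] - _EPS):
            raise ValueError("bins must be sorted and non-overlapping")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("non-finite values in binned matrix")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def bin_labels(self) -> list[str]:
        return list(self.values.columns)

    def copy(self) -> "BinnedMatrix":
        return replace(self, values=self.values.copy(), provenance=dict(self.provenance))


class ColumnScaler:
    """Column-wise centering/scaling fit on training data only.

    ``scaling``: 'none', 'unit_variance' (divide by SD) or 'pareto' (divide
    by sqrt(SD)).  Constant columns are centered but left unscaled.
    """

    def __init__(self, scaling: str = "pareto", center: bool = True):
        if scaling not in ("none", "unit_variance", "pareto"):
            raise ValueError(f"unknown scaling {scaling!r}")
        self.scaling = scaling
        self.center = center
        self.means_: np.ndarray | None = None
        self.scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray) -> "ColumnScaler":
        X = np.asarray(X, dtype=float)
        self.means_ = X.mean(axis=0) if self.center else np.zeros(X.shape[1])
        sd = X.std(axis=0, ddof=1)
        if self.scaling == "none":
            self.scale_ = np.ones(X.shape[1])
        elif self.scaling == "unit_variance":
            self.scale_ = np.where(sd > 0, sd, 1.0)
        else:
            self.scale_ = np.where(sd > 0, np.sqrt(sd), 1.0)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.means_ is None:
            raise RuntimeError("scaler not fitted")
        return (np.asarray(X, dtype=float) - self.means_) / self.scale_


def normalize_and_scale(
    m: BinnedMatrix,
    normalization: str = "total_area",
    scaling: str = "none",
    center: bool = False,
) -> BinnedMatrix:
    """Row-wise normalization followed by optional column scaling.

    ``total_area`` divides each sample by its bin sum; ``pqn`` applies
    probabilistic quotient normalization (total-area first, then division by
    the median quotient against the cohort median spectrum).  Scaling and
    centering are column-wise and recorded in the matrix state; applying a
    normalization or scaling twice is rejected.
    """
    out = m.copy()
    X = out.values.to_numpy(dtype=float)

    if normalization not in ("none", "total_area", "pqn"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization != "none":
        if m.normalization_state != "raw":
            raise ValueError(
                f"matrix already normalized ({m.normalization_state}); refusing to re-normalize"
            )
        sums = X.sum(axis=1)
        bad = np.where(sums <= 0)[0]
        if bad.size:
            names = [out.sample_ids[i] for i in bad]
            raise ValueError(f"non-positive total area for samples {names}")
        X = X / sums[:, None]
        if normalization == "pqn":
            ref = np.median(X, axis=0)
            if np.all(ref == 0):
                raise ValueError("PQN reference spectrum is identically zero")
            with np.errstate(divide="ignore", invalid="ignore"):
                quot = np.where(ref > 0, X / ref, np.nan)
            factors = np.nanmedian(quot, axis=1)
            if np.any(~np.isfinite(factors)) or np.any(factors <= 0):
                raise ValueError("degenerate PQN quotient factors")
            X = X / factors[:, None]
        out.normalization_state = normalization

    if scaling not in ("none", "unit_variance", "pareto"):
        raise ValueError(f"unknown scaling {scaling!r}")
    if scaling != "none" or center:
        if m.scaling_state != "none" or m.centered:
            raise ValueError("matrix already scaled/centered; refusing to re-scale")
        scaler = ColumnScaler(scaling, center).fit(X)
        X = scaler.transform(X)
        out.scaling_state = scaling
        out.centered = center

    out.values = pd.DataFrame(X, index=m.values.index, columns=m.values.columns)
    return out


def assemble_matrix(
    spectra: list[Spectrum],
    meta: pd.DataFrame,
    config: PreprocessConfig | None = None,
) -> BinnedMatrix:
    """Reference -> baseline-correct -> bin each spectrum; stack by metadata.

    Sample ids must match 1:1 between spectra and metadata.  Samples flagged
    ``multi_positive`` in the metadata (positive for more than one antibody)
    are excluded from the matrix, mirroring their exclusion from model
    training; exclusions are logged in provenance.  The returned matrix is
    raw (unnormalized); apply :func:`normalize_and_scale` downstream.
    """
    config = config if config is not None else PreprocessConfig()
    if not spectra:
        raise ValueError("empty spectrum list")
    by_id = {s.sample_id: s for s in spectra}
    if len(by_id) != len(spectra):
        raise ValueError("duplicate sample ids among spectra")
    meta_ids = list(meta["sample_id"])
    orphans_spec = sorted(set(by_id) - set(meta_ids))
    orphans_meta = sorted(set(meta_ids) - set(by_id))
    if orphans_spec or orphans_meta:
        raise ValueError(
            f"sample id mismatch; spectra without metadata: {orphans_spec}, "
            f"metadata without spectra: {orphans_meta}"
        )

    excluded: list[str] = []
    if "multi_positive" in meta.columns:
        excluded = list(meta.loc[meta["multi_positive"].astype(bool), "sample_id"])
    kept_ids = [sid for sid in meta_ids if sid not in set(excluded)]

    rows = []
    shifts: dict[str, float] = {}
    converged: dict[str, bool] = {}
    edges = None
    for sid in kept_ids:
        s = by_id[sid]
        if config.reference:
            s, shift = reference_to_lactate(
                s, config.reference_target, config.reference_halfwidth
            )
            shifts[sid] = shift
        if config.baseline:
            s = correct_baseline(s, config.baseline_degree)
            converged[sid] = bool(s.meta.get("baseline_converged", True))
        vals, edges = bin_spectrum(s, config.bin_width, config.region, config.exclusion)
        rows.append(vals)

    labels = [bin_label(left, right) for left, right in edges]
    values = pd.DataFrame(np.vstack(rows), index=kept_ids, columns=labels)
    return BinnedMatrix(
        values,
        edges,
        provenance={
            "referencing_shifts_ppm": shifts,
            "baseline_converged": converged,
            "excluded_multi_positive": excluded,
            "config": {
                "bin_width": config.bin_width,
                "region": list(config.region),
                "exclusion": list(config.exclusion) if config.exclusion else None,
                "baseline_degree": config.baseline_degree if config.baseline else None,
            },
        },
    )
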