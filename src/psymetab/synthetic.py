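"""Seeded synthetic serum 1H-NMR cohorts: spectra, clinical metadata, truth.

The generator emulates the statistical structure a serum metabotyping
analysis assumes: per-sample metabolite concentrations drawn log-normally
around class means, Lorentzian multiplet spectra on a fine frequency-domain
grid, a smooth random polynomial baseline, Gaussian noise, and a shared
chemical-shift jitter on sharp resonances.  Clinical metadata carries
antibody groups and 8-item PANSS ratings whose totals are calibrated to
published group medians (12 for antibody-negative and NMDAR/LGI1/CASPR2-like
samples, 19 for the VGKC/GlyR-like class).

Every draw is deterministic given the configured seed; a truth record names
the planted-effect metabolites and the spectral bins their resonances fall
in, so downstream recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .peaks import PeakLibrary, load_default_library
from .spectra import Spectrum, write_csv_spectrum, write_jcamp

__all__ = [
    "EffectConfig",
    "CohortConfig",
    "generate_spectrum",
    "generate_cohort",
    "simulate_clinical",
    "write_cohort",
    "DEFAULT_GROUP_SIZES",
    "LIPOPROTEIN_METABOLITES",
    "INCREASED_METABOLITES",
]

ANALYSIS_GROUPS = ("Control", "VGKC_GlyR", "NMDAR_LGI1_CASPR2")
DEFAULT_GROUP_SIZES = {"Control": 70, "VGKC_GlyR": 20, "NMDAR_LGI1_CASPR2": 53}

# antibody composition of the two case groups (counts at the default sizes)
_ANTIBODY_SPLIT = {
    "Control": [("Control", 1.0)],
    "VGKC_GlyR": [("VGKC", 13 / 20), ("GlyR", 7 / 20)],
    "NMDAR_LGI1_CASPR2": [("NMDAR", 35 / 53), ("LGI1", 9 / 53), ("CASPR2", 9 / 53)],
}

LIPOPROTEIN_METABOLITES = (
    "lipid_ch3",
    "lipid_ch2",
    "lipid_allylic",
    "lipid_unsaturated",
)
INCREASED_METABOLITES = (
    "leucine",
    "isoleucine",
    "valine",
    "lysine",
    "choline",
    "glucose",
)

DEFAULT_BIN_PPM_WIDTH = 0.02  # matches the preprocessing bin convention

PANSS_ITEMS = ("P1", "P2", "P3", "N1", "N4", "N6", "G5", "G9")
_POSITIVE_ITEMS = ("P1", "P2", "P3")
_NEGATIVE_ITEMS = ("N1", "N4", "N6")
_GENERAL_ITEMS = ("G5", "G9")

# Per-item Poisson rates for (item score - 1), mixed over a Gamma(4, 1/4)
# patient-severity multiplier.  Calibrated so the 8-item total has population
# median 12 in the Control / NMDAR_LGI1_CASPR2 classes and 19 in VGKC_GlyR.
_PANSS_RATES = {
    "Control": {"P": 1.12, "N": 0.22, "G": 0.11},
    "NMDAR_LGI1_CASPR2": {"P": 1.12, "N": 0.22, "G": 0.11},
    "VGKC_GlyR": {"P": 2.10, "N": 1.05, "G": 1.45},
}
_SEVERITY_SHAPE = 4.0  # Gamma shape of the patient-level severity multiplier


def default_effects() -> dict[str, dict[str, float]]:
    """Per-class multiplicative fold factors (reference class folds are 1)."""
    vgkc = {m: 0.7 for m in LIPOPROTEIN_METABOLITES}
    vgkc.update({m: 1.4 for m in INCREASED_METABOLITES})
    return {"Control": {}, "NMDAR_LGI1_CASPR2": {}, "VGKC_GlyR": vgkc}


@dataclass
class EffectConfig:
    """Noise/effect structure of a synthetic cohort.

    ``multiplicative_effects[class][metabolite]`` is the fold factor applied
    to that metabolite's mean concentration in that class; omitted entries
    are 1.  ``between_subject_cv`` is the log-normal coefficient of variation
    of per-sample concentrations; ``shift_jitter_sd`` (ppm) is the SD of the
    per-spectrum chemical-shift offset applied to sharp peaks;
    ``baseline_poly_sd`` and ``noise_sd`` are in intensity units.
    """

    class_labels: tuple[str, ...] = ANALYSIS_GROUPS
    multiplicative_effects: dict[str, dict[str, float]] = field(default_factory=default_effects)
    between_subject_cv: float = 0.20
    shift_jitter_sd: float = 0.002
    baseline_poly_sd: float = 0.05
    noise_sd: float = 0.02
    reference_class: str = "Control"

    def __post_init__(self) -> None:
        if self.between_subject_cv < 0:
            raise ValueError("between_subject_cv must be >= 0")
        for v in (self.shift_jitter_sd, self.baseline_poly_sd, self.noise_sd):
            if v < 0:
                raise ValueError("noise standard deviations must be >= 0")
        for cls, folds in self.multiplicative_effects.items():
            if cls not in self.class_labels:
                raise ValueError(f"effect class {cls!r} not in class_labels")
            for met, f in folds.items():
                if f <= 0:
                    raise ValueError(f"fold factor for {met!r} in {cls!r} must be > 0")
        ref_folds = self.multiplicative_effects.get(self.reference_class, {})
        if any(f != 1 for f in ref_folds.values()):
            raise ValueError("reference class must have fold factor 1 for every metabolite")

    def null(self) -> "EffectConfig":
        """Copy with all fold factors 1 (no planted effects)."""
        return replace(self, multiplicative_effects={c: {} for c in self.class_labels})

    def fold(self, cls: str, metabolite: str) -> float:
        return self.multiplicative_effects.get(cls, {}).get(metabolite, 1.0)


@dataclass
class CohortConfig:
    group_sizes: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    effects: EffectConfig = field(default_factory=EffectConfig)
    ppm_min: float = 0.5
    ppm_max: float = 9.0
    ppm_step: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ppm_step <= 0:
            raise ValueError("ppm grid step must be positive")
        if self.ppm_step > 0.001 + 1e-12:
            raise ValueError("ppm grid step must be <= 0.001 ppm")
        for g, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {g!r} needs at least 2 samples")

    def grid(self) -> np.ndarray:
        n = int(round((self.ppm_max - self.ppm_min) / self.ppm_step)) + 1
        return np.linspace(self.ppm_min, self.ppm_max, n)


def _lorentzian_mix(
    ppm: np.ndarray,
    concentrations: dict[str, float],
    library: PeakLibrary,
    jitter: float,
) -> np.ndarray:
    """Sum of metabolite Lorentzian lines; sharp lines shifted by ``jitter``."""
    y = np.zeros_like(ppm)
    for name, conc in concentrations.items():
        if name not in library:
            raise ValueError(f"unknown metabolite {name!r} in concentration table")
        if conc < 0:
            raise ValueError(f"negative concentration for {name!r}")
        if conc == 0:
            continue
        tpl = library[name]
        gamma2 = tpl.linewidth**2
        shift = jitter if tpl.baseline_class == "sharp" else 0.0
        for center, height in tpl.multiplet:
            y += (conc * height) * gamma2 / ((ppm - (center + shift)) ** 2 + gamma2)
    return y


def _random_baseline(ppm: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Random degree-5 polynomial with RMS amplitude ``sd``."""
    if sd == 0:
        return np.zeros_like(ppm)
    x = 2.0 * (ppm - ppm[0]) / (ppm[-1] - ppm[0]) - 1.0
    coeffs = rng.normal(size=6)
    base = np.polynomial.polynomial.polyval(x, coeffs)
    rms = np.sqrt(np.mean(base**2))
    if rms == 0:
        return np.zeros_like(ppm)
    return base * (sd / rms)


def generate_spectrum(
    concentrations: dict[str, float],
    library: PeakLibrary | None = None,
    noise_sd: float = 0.0,
    baseline_poly_sd: float = 0.0,
    shift_jitter_sd: float = 0.0,
    seed: int | np.random.Generator = 0,
    ppm: np.ndarray | None = None,
    sample_id: str = "synthetic",
) -> Spectrum:
    """Synthesize one frequency-domain spectrum.

    Intensities are the sum of Lorentzian multiplets (line height
    proportional to concentration), a random degree-5 polynomial baseline,
    and white Gaussian noise.  One chemical-shift offset per spectrum is
    applied to all sharp templates.  Deterministic given the seed.
    """
    library = library if library is not None else load_default_library()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if ppm is None:
        ppm = CohortConfig().grid()
    ppm = np.asarray(ppm, dtype=float)
    if ppm.size < 2 or np.any(np.diff(ppm) <= 0):
        raise ValueError("ppm grid must be strictly increasing with positive step")
    if ppm[0] > 0.5 or ppm[-1] < 9.0:
        raise ValueError("ppm grid must cover at least 0.5-9.0 ppm")
    if np.max(np.diff(ppm)) > 0.001 + 1e-12:
        raise ValueError("ppm grid resolution must be <= 0.001 ppm")

    jitter = rng.normal(0.0, shift_jitter_sd) if shift_jitter_sd > 0 else 0.0
    y = _lorentzian_mix(ppm, concentrations, library, jitter)
    y += _random_baseline(ppm, baseline_poly_sd, rng)
    if noise_sd > 0:
        y += rng.normal(0.0, noise_sd, size=ppm.size)
    return Spectrum(ppm, y, sample_id=sample_id, meta={"jitter_ppm": float(jitter)})


def simulate_clinical(analysis_group: str, rng: np.random.Generator) -> dict:
    """Draw demographics and 8-item PANSS ratings for one sample.

    Item scores are 1 + a truncated Poisson count whose rate mixes a
    subscale-specific level with a Gamma-distributed patient severity
    multiplier; demographics come from distributions shared across groups.
    """
    if analysis_group not in ANALYSIS_GROUPS:
        raise ValueError(f"unknown analysis group {analysis_group!r}")
    rates = _PANSS_RATES[analysis_group]
    severity = rng.gamma(_SEVERITY_SHAPE, 1.0 / _SEVERITY_SHAPE)
    record: dict = {}
    for item in PANSS_ITEMS:
        lam = rates[item[0]] * severity
        record[item] = int(1 + min(6, rng.poisson(lam)))
    record["panss_positive"] = sum(record[i] for i in _POSITIVE_ITEMS)
    record["panss_negative"] = sum(record[i] for i in _NEGATIVE_ITEMS)
    record["panss_general"] = sum(record[i] for i in _GENERAL_ITEMS)
    record["panss_total"] = sum(record[i] for i in PANSS_ITEMS)

    record["age"] = float(np.clip(16.0 + rng.gamma(2.2, 5.5), 16.0, 70.0))
    record["gender"] = "F" if rng.random() < 0.43 else "M"
    record["ethnicity"] = rng.choice(
        ["White", "Asian", "Black", "Mixed", "Other"], p=[0.70, 0.13, 0.09, 0.05, 0.03]
    )
    record["episode_type"] = rng.choice(["first", "relapse", "unknown"], p=[0.65, 0.33, 0.02])
    record["disease_duration"] = float(np.exp(rng.normal(np.log(100.0), 1.1)))
    return record


def _antibody_labels(group: str, n: int, rng: np.random.Generator) -> list[str]:
    """Assign antibody subgroup labels with the published composition."""
    split = _ANTIBODY_SPLIT[group]
    counts = [int(round(frac * n)) for _, frac in split]
    counts[-1] = n - sum(counts[:-1])
    labels: list[str] = []
    for (ab, _), c in zip(split, counts):
        labels.extend([ab] * max(c, 0))
    rng.shuffle(labels)
    return labels[:n]


def _truth_bins(
    config: "CohortConfig",
    library: PeakLibrary,
    snr_threshold: float = 1.0,
) -> tuple[dict[str, dict[str, list[str]]], dict[str, list[str]]]:
    """Bins where the planted effects are detectable, computed noiselessly.

    Lorentzian tails spread every metabolite's intensity across many bins,
    so "the bins a resonance falls in" is defined operationally: a bin is a
    planted-effect bin for a class when the expected between-class
    difference of its integral exceeds ``snr_threshold`` within-class
    standard deviations.  The within-class SD combines the between-subject
    concentration CV (independent per metabolite) with the integrated
    point-noise; both follow from the generator's own parameters, so the
    truth record is exact for the configured cohort.

    Returns (per-class per-metabolite bins, per-class combined bins).
    """
    from .preprocessing import bin_label, bin_spectrum, default_bin_edges

    effects = config.effects
    grid = config.grid()
    edges = default_bin_edges()
    labels = [bin_label(left, right) for left, right in edges]
    contrib = {}
    for name in library.names():
        clean = generate_spectrum({name: 1.0}, library=library, ppm=grid)
        contrib[name], _ = bin_spectrum(clean)
    b_ref = sum(contrib.values())
    step = config.ppm_step
    npts = DEFAULT_BIN_PPM_WIDTH / step
    noise_bin_sd = effects.noise_sd * step * np.sqrt(max(npts - 1.5, 1.0))
    var_within = (effects.between_subject_cv**2) * sum(c**2 for c in contrib.values())
    sd = np.sqrt(var_within + noise_bin_sd**2)

    by_met: dict[str, dict[str, list[str]]] = {}
    combined: dict[str, list[str]] = {}
    for cls, folds in effects.multiplicative_effects.items():
        planted = {m for m, f in folds.items() if f != 1.0}
        if not planted:
            continue
        b_eff = sum(effects.fold(cls, n) * c for n, c in contrib.items())
        snr_total = np.abs(b_eff - b_ref) / sd
        combined[cls] = [l for l, s in zip(labels, snr_total) if s >= snr_threshold]
        by_met[cls] = {}
        for met in sorted(planted):
            snr_met = np.abs((effects.fold(cls, met) - 1.0) * contrib[met]) / sd
            by_met[cls][met] = [l for l, s in zip(labels, snr_met) if s >= snr_threshold]
    return by_met, combined


def generate_cohort(
    config: CohortConfig | None = None,
    library: PeakLibrary | None = None,
) -> tuple[list[Spectrum], pd.DataFrame, dict]:
    """Generate a full cohort: spectra, clinical metadata table, truth record.

    Per-sample concentrations are log-normal around class means (class mean =
    reference mean x fold factor, with the configured between-subject CV).
    The truth record names planted metabolites, their fold factors, and the
    retained bins their resonances fall in.
    """
    config = config if config is not None else CohortConfig()
    library = library if library is not None else load_default_library()
    effects = config.effects
    rng = np.random.default_rng(config.seed)
    ppm = config.grid()

    sigma = float(np.sqrt(np.log1p(effects.between_subject_cv**2)))
    spectra: list[Spectrum] = []
    rows: list[dict] = []
    seen_ids: set[str] = set()
    for group in config.group_sizes:
        if group not in effects.class_labels:
            raise ValueError(f"group {group!r} has no effect configuration")
    for group, n in config.group_sizes.items():
        antibodies = _antibody_labels(group, n, rng) if group in _ANTIBODY_SPLIT else [group] * n
        for i in range(n):
            sample_id = f"{group}_{i:03d}"
            if sample_id in seen_ids:
                raise ValueError(f"overlapping sample id {sample_id!r}")
            seen_ids.add(sample_id)
            conc = {
                name: effects.fold(group, name) * float(np.exp(rng.normal(-0.5 * sigma**2, sigma)))
                for name in library.names()
            }
            spectrum = generate_spectrum(
                conc,
                library=library,
                noise_sd=effects.noise_sd,
                baseline_poly_sd=effects.baseline_poly_sd,
                shift_jitter_sd=effects.shift_jitter_sd,
                seed=rng,
                ppm=ppm,
                sample_id=sample_id,
            )
            spectra.append(spectrum)
            row = {
                "sample_id": sample_id,
                "antibody_group": antibodies[i],
                "analysis_group": group,
                "multi_positive": False,
            }
            row.update(simulate_clinical(group if group in ANALYSIS_GROUPS else "Control", rng))
            rows.append(row)

    meta = pd.DataFrame(rows)
    by_met, combined = _truth_bins(config, library)
    truth = {
        "effects": {
            cls: dict(folds)
            for cls, folds in effects.multiplicative_effects.items()
            if any(f != 1.0 for f in folds.values())
        },
        "bins_by_metabolite": by_met,
        "planted_bins_by_class": combined,
        "planted_bins": sorted({b for bins in combined.values() for b in bins}),
        "seed": config.seed,
    }
    return spectra, meta, truth


def write_cohort(
    spectra: list[Spectrum],
    meta: pd.DataFrame,
    truth: dict,
    outdir: str | Path,
    spectrum_format: str = "csv",
) -> None:
    """Write spectra (CSV or JCAMP-DX), metadata CSV, and truth JSON."""
    outdir = Path(outdir)
    specdir = outdir / "spectra"
    specdir.mkdir(parents=True, exist_ok=True)
    for s in spectra:
        if spectrum_format == "csv":
            write_csv_spectrum(s, specdir / f"{s.sample_id}.csv")
        elif spectrum_format in ("jcamp", "jdx", "dx"):
            write_jcamp(s, specdir / f"{s.sample_id}.dx")
        else:
            raise ValueError(f"unknown spectrum format {spectrum_format!r}")
    meta.to_csv(outdir / "metadata.csv", index=False)
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
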