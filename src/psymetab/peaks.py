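"""Serum NMR peak library: Lorentzian multiplet templates.

Each metabolite is described by one or more multiplets (center, multiplicity,
scalar coupling in Hz, relative height).  Multiplets are expanded into
individual Lorentzian lines at load time, converting couplings to ppm at the
library's spectrometer frequency.  Line intensities follow the first-order
binomial pattern, scaled so the tallest line of a multiplet carries the
stated height.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from math import comb

import yaml

__all__ = ["PeakTemplate", "PeakLibrary", "load_default_library", "load_library"]


@dataclass(frozen=True)
class PeakTemplate:
    """Expanded line list for one metabolite.

    Parameters
    ----------
    metabolite_name : str
    multiplet : list of (center_ppm, relative_height)
        Individual Lorentzian lines after multiplet expansion.
    linewidth : float
        Lorentzian half-width at half-maximum, ppm.
    baseline_class : {"sharp", "broad"}
        Broad templates model lipoprotein/macromolecule envelopes and are
        exempt from per-spectrum chemical-shift jitter.
    """

    metabolite_name: str
    multiplet: list[tuple[float, float]]
    linewidth: float
    baseline_class: str

    def __post_init__(self) -> None:
        if self.baseline_class not in ("sharp", "broad"):
            raise ValueError(f"unknown baseline_class {self.baseline_class!r}")
        if self.linewidth <= 0:
            raise ValueError(f"{self.metabolite_name}: linewidth must be > 0")
        for center, height in self.multiplet:
            if not 0.5 <= center <= 9.0:
                raise ValueError(
                    f"{self.metabolite_name}: line center {center} ppm outside 0.5-9.0"
                )
            if height <= 0:
                raise ValueError(f"{self.metabolite_name}: relative height must be > 0")


def _expand_multiplet(
    center: float, multiplicity: int, j_hz: float, height: float, freq_mhz: float
) -> list[tuple[float, float]]:
    """First-order multiplet -> list of (position_ppm, height) lines."""
    if multiplicity < 1:
        raise ValueError("multiplicity must be >= 1")
    if multiplicity == 1:
        return [(center, height)]
    j_ppm = j_hz / freq_mhz
    coeffs = [comb(multiplicity - 1, k) for k in range(multiplicity)]
    tallest = max(coeffs)
    lines = []
    for k, c in enumerate(coeffs):
        offset = (k - (multiplicity - 1) / 2.0) * j_ppm
        lines.append((center + offset, height * c / tallest))
    return lines


@dataclass
class PeakLibrary:
    """Collection of :class:`PeakTemplate` keyed by metabolite name."""

    templates: dict[str, PeakTemplate]
    spectrometer_frequency_mhz: float = 700.0
    source: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        sharp = [t.linewidth for t in self.templates.values() if t.baseline_class == "sharp"]
        broad = [t.linewidth for t in self.templates.values() if t.baseline_class == "broad"]
        if sharp and broad and min(broad) < 5.0 * max(sharp):
            raise ValueError(
                "broad templates must have linewidth >= 5x the widest sharp template"
            )

    def __getitem__(self, name: str) -> PeakTemplate:
        return self.templates[name]

    def __contains__(self, name: str) -> bool:
        return name in self.templates

    def names(self) -> list[str]:
        return list(self.templates)


def load_library(spec: dict, source: str = "") -> PeakLibrary:
    """Build a :class:`PeakLibrary` from a parsed YAML mapping."""
    freq = float(spec.get("spectrometer_frequency_mhz", 700.0))
    if freq <= 0:
        raise ValueError("spectrometer frequency must be positive")
    templates: dict[str, PeakTemplate] = {}
    for entry in spec["metabolites"]:
        name = entry["name"]
        if name in templates:
            raise ValueError(f"duplicate metabolite {name!r} in peak library")
        lines: list[tuple[float, float]] = []
        for m in entry["multiplets"]:
            lines.extend(
                _expand_multiplet(
                    float(m["center"]),
                    int(m.get("multiplicity", 1)),
                    float(m.get("j_hz", 0.0)),
                    float(m.get("height", 1.0)),
                    freq,
                )
            )
        templates[name] = PeakTemplate(
            metabolite_name=name,
            multiplet=lines,
            linewidth=float(entry["linewidth"]),
            baseline_class=entry.get("class", "sharp"),
        )
    return PeakLibrary(templates, spectrometer_frequency_mhz=freq, source=source)


def load_default_library() -> PeakLibrary:
    """Load the serum peak library shipped with the package."""
    ref = resources.files("psymetab.data").joinpath("serum_peaks.yaml")
    with ref.open("r") as fh:
        spec = yaml.safe_load(fh)
    return load_library(spec, source="serum_peaks.yaml")
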