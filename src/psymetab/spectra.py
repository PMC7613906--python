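"""Frequency-domain spectrum container and plain-text I/O.

A :class:`Spectrum` is a 1D frequency-domain NMR trace: a strictly monotone
ppm axis and an equal-length intensity vector, plus free-form provenance
metadata.  Readers/writers cover two-column CSV (``ppm,intensity``) and a
minimal JCAMP-DX subset (AFFN ``XYDATA (X++(Y..Y))`` with a linear abscissa),
which is all this pipeline emits and consumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "read_csv_spectrum",
    "write_csv_spectrum",
    "read_jcamp",
    "write_jcamp",
    "read_spectrum",
]


@dataclass
class Spectrum:
    ppm: np.ndarray
    intensity: np.ndarray
    sample_id: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ppm = np.asarray(self.ppm, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.ppm.ndim != 1 or self.intensity.ndim != 1:
            raise ValueError("ppm and intensity must be 1D")
        if self.ppm.shape != self.intensity.shape:
            raise ValueError(
                f"axis/intensity length mismatch: {self.ppm.size} vs {self.intensity.size}"
            )
        if self.ppm.size < 2:
            raise ValueError("spectrum needs at least two points")
        d = np.diff(self.ppm)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("ppm axis must be strictly monotone")
        if not (np.isfinite(self.ppm).all() and np.isfinite(self.intensity).all()):
            raise ValueError("non-finite values in spectrum")

    @property
    def ascending(self) -> bool:
        return bool(self.ppm[1] > self.ppm[0])

    def sorted(self) -> "Spectrum":
        """Return a copy with the ppm axis ascending."""
        if self.ascending:
            return Spectrum(self.ppm.copy(), self.intensity.copy(), self.sample_id, dict(self.meta))
        return Spectrum(self.ppm[::-1].copy(), self.intensity[::-1].copy(), self.sample_id, dict(self.meta))

    def shifted(self, delta: float) -> "Spectrum":
        """Return a copy with ``delta`` added to the ppm axis."""
        return Spectrum(self.ppm + delta, self.intensity.copy(), self.sample_id, dict(self.meta))


def read_csv_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read a two-column ``ppm,intensity`` CSV."""
    path = Path(path)
    df = pd.read_csv(path)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["ppm", "intensity"]:
        raise ValueError(f"{path}: expected header 'ppm,intensity', got {list(df.columns)}")
    return Spectrum(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        sample_id=sample_id if sample_id is not None else path.stem,
    )


def write_csv_spectrum(s: Spectrum, path: str | Path) -> None:
    pd.DataFrame({"ppm": s.ppm, "intensity": s.intensity}).to_csv(path, index=False)


def write_jcamp(s: Spectrum, path: str | Path) -> None:
    """Write a minimal JCAMP-DX file (AFFN XYDATA over a linear ppm axis)."""
    sp = s.sorted()
    step = np.diff(sp.ppm)
    if not np.allclose(step, step[0], rtol=1e-8, atol=1e-12):
        raise ValueError("JCAMP-DX XYDATA writer requires an evenly spaced axis")
    lines = [
        "##TITLE=" + (s.sample_id or "spectrum"),
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
        f"##FIRSTX={sp.ppm[0]:.10g}",
        f"##LASTX={sp.ppm[-1]:.10g}",
        f"##NPOINTS={sp.ppm.size}",
        "##XFACTOR=1.0",
        "##YFACTOR=1.0",
        "##XYDATA=(X++(Y..Y))",
    ]
    y = sp.intensity
    for i in range(0, y.size, 8):
        chunk = y[i : i + 8]
        lines.append(f"{sp.ppm[i]:.10g} " + " ".join(f"{v:.8g}" for v in chunk))
    lines.append("##END=")
    Path(path).write_text("\n".join(lines) + "\n")


def read_jcamp(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Read the JCAMP-DX subset produced by :func:`write_jcamp`.

    Supports AFFN ``(X++(Y..Y))`` tables with FIRSTX/LASTX/NPOINTS and scalar
    X/Y factors; compressed (SQZ/DIF/DUP) forms are not supported.
    """
    path = Path(path)
    fields: dict[str, str] = {}
    ydata: list[float] = []
    in_table = False
    title = ""
    for raw in path.read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            val = val.strip()
            if key == "TITLE":
                title = val
            if key == "XYDATA":
                in_table = True
                continue
            if key == "END":
                in_table = False
            fields[key] = val
            continue
        if in_table:
            parts = line.replace(",", " ").split()
            # first token on each table line is the abscissa; rest are Y
            ydata.extend(float(tok) for tok in parts[1:])
    for req in ("FIRSTX", "LASTX", "NPOINTS"):
        if req not in fields:
            raise ValueError(f"{path}: missing ##{req} record")
    n = int(fields["NPOINTS"])
    if len(ydata) != n:
        raise ValueError(f"{path}: NPOINTS={n} but {len(ydata)} ordinates read")
    xfac = float(fields.get("XFACTOR", "1.0"))
    yfac = float(fields.get("YFACTOR", "1.0"))
    ppm = np.linspace(float(fields["FIRSTX"]), float(fields["LASTX"]), n) * xfac
    return Spectrum(
        ppm,
        np.asarray(ydata) * yfac,
        sample_id=sample_id if sample_id is not None else (title or path.stem),
    )


def read_spectrum(path: str | Path, sample_id: str | None = None) -> Spectrum:
    """Dispatch on extension: ``.csv`` -> CSV reader, ``.dx``/``.jdx`` -> JCAMP."""
    suffix = Path(path).suffix.lower()
    if suffix == ".csv":
        return read_csv_spectrum(path, sample_id)
    if suffix in (".dx", ".jdx", ".jcamp"):
        return read_jcamp(path, sample_id)
    raise ValueError(f"unrecognised spectrum format: {path}")
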