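"""Single-spectrum container and plain-text I/O.

A :class:`Spectrum` is one sample's absorbance trace on a uniform wavenumber
grid (cm^-1), plus label metadata (sample id, patient id, clinical group,
pathological stage).  Spectra are written as two-column delimited text files
with a small ``#``-prefixed header, the cohort interchange format used by the
generator, the preprocessing stages and the CLI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Clinical groups: liver, gastric, colorectal cancer, and healthy controls.
GROUPS = ("LC", "GC", "CC", "Control")

#: Pathological stage vocabulary for the intra-group (staging) task.
STAGE_NAMES = {
    1: "nonspecific symptom",
    2: "cancer",
    3: "postoperative",
    4: "control",
}

_GRID_RTOL = 1e-9


@dataclass
class Spectrum:
    """One sample's wavenumber grid + absorbance values + labels."""

    wavenumbers: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.wavenumbers.ndim != 1 or self.absorbance.ndim != 1:
            raise ValueError("wavenumbers and absorbance must be 1-D")
        if self.wavenumbers.size != self.absorbance.size:
            raise ValueError(
                f"length mismatch: {self.wavenumbers.size} wavenumbers vs "
                f"{self.absorbance.size} absorbance values"
            )
        if self.wavenumbers.size >= 2:
            d = np.diff(self.wavenumbers)
            if np.any(d <= 0):
                raise ValueError("wavenumber grid must be strictly increasing")
            if np.ptp(d) > _GRID_RTOL * max(1.0, abs(d[0])):
                raise ValueError("wavenumber grid must be uniform")

    @property
    def step(self) -> float:
        """Grid spacing in cm^-1."""
        return float(self.wavenumbers[1] - self.wavenumbers[0])

    def with_absorbance(self, values: np.ndarray) -> "Spectrum":
        """Copy carrying new absorbance values on the same grid/labels."""
        return Spectrum(self.wavenumbers, np.asarray(values, dtype=float), dict(self.meta))

    def clip(self, lo: float, hi: float) -> "Spectrum":
        """Restrict to the closed wavenumber range [lo, hi]."""
        mask = (self.wavenumbers >= lo) & (self.wavenumbers <= hi)
        if mask.sum() < 2:
            raise ValueError(f"range [{lo}, {hi}] retains fewer than 2 grid points")
        return Spectrum(self.wavenumbers[mask], self.absorbance[mask], dict(self.meta))

    def to_text(self, path: str | Path) -> None:
        path = Path(path)
        lines = [f"# {k}: {self.meta[k]}" for k in sorted(self.meta)]
        lines.append("# wavenumber_cm-1\tabsorbance_au")
        for w, a in zip(self.wavenumbers, self.absorbance):
            lines.append(f"{w:.6f}\t{a:.10e}")
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def from_text(cls, path: str | Path) -> "Spectrum":
        meta: dict = {}
        wn, ab = [], []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    k, v = k.strip(), v.strip()
                    if k not in ("wavenumber_cm-1",):
                        meta[k] = int(v) if v.lstrip("-").isdigit() else v
                continue
            w, a = line.split("\t")
            wn.append(float(w))
            ab.append(float(a))
        return cls(np.array(wn), np.array(ab), meta)


def common_grid(spectra: list[Spectrum]) -> np.ndarray:
    """Shared grid of a cohort; raises if any spectrum deviates."""
    if not spectra:
        raise ValueError("empty cohort")
    grid = spectra[0].wavenumbers
    for s in spectra[1:]:
        if s.wavenumbers.size != grid.size or not np.allclose(
            s.wavenumbers, grid, rtol=0, atol=1e-9
        ):
            raise ValueError("spectra do not share a common wavenumber grid")
    return grid
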