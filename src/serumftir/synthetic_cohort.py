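"""Synthetic serum ATR-FTIR cohort generator.

Serum mid-infrared spectra are modelled as a sum of Gaussian vibrational
bands (protein amide A/I/II/III, lipid C-H stretches and bends, carboxylate,
nucleic-acid phosphate, carbohydrate-ring modes, and four glycoprotein-linked
marker bands) on a linear baseline with white instrument noise.  Cancer-group
effects enter per band as a signed center shift (blue-shift positive) and a
multiplicative amplitude factor relative to the healthy-control preset;
pathological stage scales both effects through an exponent in [0, 1] so that
"control stage" reproduces the control forward model exactly:

    A(nu) = sum_b  amp_b * factor_b**s * exp(-(nu - c_b - s*delta_b)^2 / (2*sigma_b^2))
            + baseline(nu) [+ water(nu)] + N(0, noise_sigma^2)

The default presets encode the reference band table shipped with the package
(``data/band_table_v1.tsv``); the default cohort reproduces the study head
count of 252 serum samples from 210 patients in four groups (liver, gastric,
colorectal cancer, and 44 controls).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .spectrum import GROUPS, Spectrum

#: Stage effect scales: 1 = nonspecific symptom, 2 = cancer, 3 = postoperative,
#: 4 = control.  Stage 4 must have scale 0 (identical to controls).
DEFAULT_STAGE_SCALES = {1: 0.5, 2: 1.0, 3: 0.3, 4: 0.0}

#: Water background band centers (O-H stretch, H-O-H bend) and widths/weights.
WATER_BANDS = ((3346.0, 120.0, 1.0), (1637.0, 45.0, 0.7))


@dataclass(frozen=True)
class BandSpec:
    """A named vibrational band of the control (reference) serum model."""

    name: str
    assignment: str
    center: float  # cm^-1
    width: float  # Gaussian sigma, cm^-1
    amplitude: float  # absorbance, a.u. (amide I == 1)
    half_window: float = 8.0  # SD-IR search half-window, cm^-1

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError(f"band {self.name!r}: width must be > 0")
        if self.amplitude < 0:
            raise ValueError(f"band {self.name!r}: amplitude must be >= 0")


@dataclass(frozen=True)
class GroupEffect:
    """Per-band disease effect: signed center shift and amplitude multiplier."""

    band: str
    center_delta: float = 0.0  # cm^-1, positive = blue-shift vs Control
    amplitude_factor: float = 1.0  # dimensionless, vs Control

    def __post_init__(self) -> None:
        if self.amplitude_factor <= 0:
            raise ValueError(f"band {self.band!r}: amplitude_factor must be > 0")


@dataclass(frozen=True)
class StageProfile:
    """Pathological stage with the multiplier applied to every group effect."""

    stage: int
    effect_scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.effect_scale <= 1.0:
            raise ValueError("effect_scale must lie in [0, 1]")
        if self.stage == 4 and self.effect_scale != 0.0:
            raise ValueError("stage 4 (control) must have effect_scale 0")


@dataclass
class CohortConfig:
    """Generator parameterization.

    ``group_sizes`` are patient counts.  Every patient contributes one
    specimen; the first ``second_specimens[g]`` patients of group ``g``
    contribute a second specimen at a distinct stage.  The defaults reproduce
    the study head count: 25 LC (+25 second specimens), 68 GC (+17), 73 CC,
    44 controls = 252 spectra.  ``specimens_per_patient`` overrides the plan
    with a fixed count per DTC patient when set.
    """

    group_sizes: dict = field(
        default_factory=lambda: {"LC": 25, "GC": 68, "CC": 73, "Control": 44}
    )
    second_specimens: dict = field(
        default_factory=lambda: {"LC": 25, "GC": 17, "CC": 0}
    )
    specimens_per_patient: int | None = None
    grid: tuple = (900.0, 4000.0, 2.0)  # start, stop, step (cm^-1)
    noise_sigma: float = 0.002  # a.u., white noise per grid point
    baseline: tuple = (0.02, 1e-5)  # intercept (a.u.), slope (a.u. per cm^-1)
    water_amplitude: float = 0.5  # a.u.
    stage_scales: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_SCALES))
    line_shape: str = "gaussian"  # or "pseudo-voigt"
    voigt_eta: float = 0.3  # Lorentzian fraction for pseudo-Voigt
    seed: int = 42

    def __post_init__(self) -> None:
        start, stop, step = self.grid
        if step <= 0:
            raise ValueError("grid step must be > 0")
        if stop <= start:
            raise ValueError("grid stop must exceed start")
        for g, n in self.group_sizes.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}")
            if n < 0:
                raise ValueError(f"group size for {g!r} must be >= 0")
        if self.specimens_per_patient is not None and self.specimens_per_patient < 1:
            raise ValueError("specimens_per_patient must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.stage_scales.get(4, 0.0) != 0.0:
            raise ValueError("stage 4 (control) must have effect scale 0")

    def wavenumbers(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(round((stop - start) / step)) + 1
        return start + step * np.arange(n)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Cohort:
    """Ordered collection of spectra plus the config that produced it."""

    spectra: list
    config: CohortConfig

    def __len__(self) -> int:
        return len(self.spectra)

    def manifest(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": s.meta["sample_id"],
                "patient_id": s.meta["patient_id"],
                "group": s.meta["group"],
                "stage": s.meta["stage"],
            }
            for s in self.spectra
        ]
        return pd.DataFrame(rows)

    def subset(self, predicate) -> "Cohort":
        return Cohort([s for s in self.spectra if predicate(s.meta)], self.config)


def default_band_table(
    path: str | Path | None = None,
) -> tuple[list[BandSpec], dict]:
    """Load the reference band table: control bands + per-group effects.

    Returns ``(bands, effects)`` where ``effects[group]`` is a list of
    :class:`GroupEffect`, one per band.  Control effects are identically
    (0, 1).  Band centers, group shifts, and amide-I-anchored relative
    absorbances follow the reference table shipped with the package.
    """
    if path is None:
        res = importlib.resources.files("serumftir") / "data" / "band_table_v1.tsv"
        df = pd.read_csv(res, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")

    bands: list[BandSpec] = []
    effects: dict = {g: [] for g in GROUPS}
    for _, r in df.iterrows():
        bands.append(
            BandSpec(
                name=r["name"],
                assignment=r["assignment"],
                center=float(r["control_center"]),
                width=float(r["sigma"]),
                amplitude=float(r["control_relabs"]),
                half_window=float(r["half_window"]),
            )
        )
        effects["Control"].append(GroupEffect(r["name"], 0.0, 1.0))
        for g, prefix in (("LC", "lc"), ("GC", "gc"), ("CC", "cc")):
            effects[g].append(
                GroupEffect(
                    r["name"],
                    center_delta=float(r[f"{prefix}_center"]) - float(r["control_center"]),
                    amplitude_factor=float(r[f"{prefix}_relabs"]) / float(r["control_relabs"]),
                )
            )
    return bands, effects


def _profile(nu: np.ndarray, center: float, sigma: float, shape: str, eta: float) -> np.ndarray:
    g = np.exp(-((nu - center) ** 2) / (2.0 * sigma**2))
    if shape == "gaussian":
        return g
    if shape == "pseudo-voigt":
        # Lorentzian HWHM matched to the Gaussian half-width.
        gam = sigma * np.sqrt(2.0 * np.log(2.0))
        lor = gam**2 / ((nu - center) ** 2 + gam**2)
        return (1.0 - eta) * g + eta * lor
    raise ValueError(f"unknown line shape {shape!r}")


def water_background(nu: np.ndarray, amplitude: float) -> np.ndarray:
    """Residual liquid-water background: O-H stretch 3346, H-O-H bend 1637 cm^-1."""
    out = np.zeros_like(nu)
    for c, s, w in WATER_BANDS:
        out += amplitude * w * np.exp(-((nu - c) ** 2) / (2.0 * s**2))
    return out


def generate_spectrum(
    bands: list[BandSpec],
    effects: list[GroupEffect],
    effect_scale: float,
    config: CohortConfig,
    rng: np.random.Generator,
    include_water: bool = False,
    meta: dict | None = None,
) -> Spectrum:
    """Forward-model one spectrum.

    Amplitude factors are applied as ``factor**effect_scale`` and shifts as
    ``effect_scale * delta``, so ``effect_scale == 0`` reproduces the control
    model exactly.  Raises if any shifted band center leaves the grid.
    """
    nu = config.wavenumbers()
    eff = {e.band: e for e in effects}
    a = np.zeros_like(nu)
    for b in bands:
        e = eff.get(b.name, GroupEffect(b.name))
        center = b.center + effect_scale * e.center_delta
        if not (nu[0] <= center <= nu[-1]):
            raise ValueError(
                f"band {b.name!r}: shifted center {center:.1f} cm^-1 leaves the grid"
            )
        amp = b.amplitude * e.amplitude_factor**effect_scale
        a += amp * _profile(nu, center, b.width, config.line_shape, config.voigt_eta)
    intercept, slope = config.baseline
    a += intercept + slope * nu
    if include_water:
        a += water_background(nu, config.water_amplitude)
    if config.noise_sigma > 0:
        a += rng.normal(0.0, config.noise_sigma, size=nu.size)
    return Spectrum(nu, a, dict(meta or {}))


def specimen_plan(config: CohortConfig) -> list[tuple[str, str, int]]:
    """Deterministic (patient_id, group, stage) plan for one cohort.

    DTC patients get one specimen at a stage cycling 1, 2, 3 by patient index;
    patients with a second specimen get the next distinct stage.  Controls
    contribute one stage-4 specimen each.
    """
    plan: list[tuple[str, str, int]] = []
    for g in GROUPS:
        n = config.group_sizes.get(g, 0)
        if g == "Control":
            plan.extend((f"{g}{i:03d}", g, 4) for i in range(n))
            continue
        if config.specimens_per_patient is not None:
            k = config.specimens_per_patient
            for i in range(n):
                for j in range(k):
                    plan.append((f"{g}{i:03d}", g, (i + j) % 3 + 1))
            continue
        extra = config.second_specimens.get(g, 0)
        for i in range(n):
            first = i % 3 + 1
            plan.append((f"{g}{i:03d}", g, first))
            if i < extra:
                plan.append((f"{g}{i:03d}", g, first % 3 + 1))
    return plan


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a labeled cohort; a pure function of the config (incl. seed)."""
    config = config or CohortConfig()
    bands, effects = default_band_table()
    rng = np.random.default_rng(config.seed)
    spectra = []
    for k, (pid, group, stage) in enumerate(specimen_plan(config)):
        scale = float(config.stage_scales[stage])
        meta = {
            "sample_id": f"S{k:04d}",
            "patient_id": pid,
            "group": group,
            "stage": stage,
        }
        spectra.append(
            generate_spectrum(bands, effects[group], scale, config, rng, meta=meta)
        )
    return Cohort(spectra, config)


def generate_wet_dry_pair(
    bands: list[BandSpec],
    config: CohortConfig,
    rng: np.random.Generator,
    effects: list[GroupEffect] | None = None,
) -> tuple[Spectrum, Spectrum]:
    """(wet, dry) pair: wet = dry serum model + residual water background."""
    effects = effects or [GroupEffect(b.name) for b in bands]
    dry = generate_spectrum(bands, effects, 0.0, config, rng, include_water=False)
    # the water term is the only wet/dry difference; instrument noise is shared
    wet = dry.with_absorbance(
        dry.absorbance + water_background(dry.wavenumbers, config.water_amplitude)
    )
    wet.meta.update(state="wet")
    dry.meta.update(state="dry")
    return wet, dry


def write_cohort(cohort: Cohort, outdir: str | Path) -> pd.DataFrame:
    """Write one file per spectrum + manifest + config; returns the manifest."""
    outdir = Path(outdir)
    spec_dir = outdir / "spectra"
    spec_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.manifest()
    paths = []
    for s in cohort.spectra:
        p = spec_dir / f"{s.meta['sample_id']}.tsv"
        s.to_text(p)
        paths.append(str(p.relative_to(outdir)))
    manifest["path"] = paths
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    (outdir / "config.yaml").write_text(yaml.safe_dump(cohort.config.to_dict()))
    return manifest


def read_cohort(indir: str | Path) -> Cohort:
    """Read a cohort written by :func:`write_cohort`."""
    indir = Path(indir)
    manifest = pd.read_csv(indir / "manifest.tsv", sep="\t")
    cfg_raw = yaml.safe_load((indir / "config.yaml").read_text())
    for key in ("grid", "baseline"):
        cfg_raw[key] = tuple(cfg_raw[key])
    for key in ("stage_scales",):
        cfg_raw[key] = {int(k): float(v) for k, v in cfg_raw[key].items()}
    config = CohortConfig(**cfg_raw)
    spectra = [Spectrum.from_text(indir / p) for p in manifest["path"]]
    return Cohort(spectra, config)
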