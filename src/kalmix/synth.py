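"""Synthetic UV-Vis spectra with the statistical structure the filter assumes.

Real calibration spectra for the hydrochlorothiazide (HCT) / losartan
potassium (LSP) system are not publicly deposited, so every other module is
exercised on synthetic spectra built from first principles:

* each component is a sum of Gaussian absorption bands (center, width,
  peak absorptivity) — enough to reproduce the essential feature of the
  system, two strongly overlapping spectra with maxima near 272 nm (HCT)
  and 235 nm (LSP);
* mixtures obey Beer–Lambert additivity exactly;
* the instrument adds i.i.d. Gaussian absorbance noise (default SD
  0.002 AU, a typical photometric noise floor chosen so synthetic errors
  land in the low-percent range a real assay of this kind reports).

The study presets and designs below mirror a two-drug tablet assay:
single-point standards at 5 (HCT-like) and 20 (LSP-like) µg/mL, seven
mixture designs spanning concentration ratios 1:24 to 6:4, tablet samples
at 5 + 20 µg/mL, and a three-level spike plan.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .errors import ConfigError
from .spectra import Spectrum, SpectrumSet, write_spectrum

__all__ = [
    "BandModel",
    "NoiseModel",
    "MixtureDesign",
    "component_spectrum",
    "mixture_spectrum",
    "study_presets",
    "study_grid",
    "STUDY_MIXTURE_DESIGNS",
    "STUDY_SPIKE_LEVELS",
    "generate_study_fixture",
]


@dataclass(frozen=True)
class BandModel:
    """Gaussian-band parameterization of one component's unit spectrum.

    ``bands`` is a tuple of (center nm, width-sigma nm, peak absorptivity
    AU·mL/µg); the unit spectrum is their pointwise sum.
    """

    name: str
    bands: tuple[tuple[float, float, float], ...]

    def __post_init__(self) -> None:
        if not self.bands:
            raise ValueError(f"{self.name!r}: need at least one band")
        for mu, sigma, peak in self.bands:
            if sigma <= 0:
                raise ValueError(f"{self.name!r}: band width must be > 0")
            if peak <= 0:
                raise ValueError(f"{self.name!r}: peak absorptivity must be > 0")
        object.__setattr__(self, "bands", tuple(tuple(b) for b in self.bands))

    def unit_absorbances(self, grid: np.ndarray) -> np.ndarray:
        """Absorbance of a 1 µg/mL solution on ``grid``."""
        grid = np.asarray(grid, dtype=float)
        a = np.zeros_like(grid)
        for mu, sigma, peak in self.bands:
            a += peak * np.exp(-((grid - mu) ** 2) / (2.0 * sigma**2))
        return a


@dataclass(frozen=True)
class NoiseModel:
    """Additive homoscedastic Gaussian absorbance noise."""

    sigma: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("noise sigma must be >= 0")


@dataclass(frozen=True)
class MixtureDesign:
    """Designed true concentrations (µg/mL) and replicate count."""

    concentrations: Mapping[str, float]
    replicates: int = 1
    label: str = ""

    def __post_init__(self) -> None:
        conc = dict(self.concentrations)
        if any(c < 0 for c in conc.values()):
            raise ValueError("concentrations must be >= 0")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        object.__setattr__(self, "concentrations", conc)


def component_spectrum(
    model: BandModel, concentration: float, grid: Sequence[float]
) -> Spectrum:
    """Noiseless Beer–Lambert spectrum of one component at ``concentration``."""
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavelength grid")
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    return Spectrum(
        grid.copy(),
        concentration * model.unit_absorbances(grid),
        f"{model.name}_{concentration:g}",
    )


def mixture_spectrum(
    models: Sequence[BandModel],
    design: MixtureDesign,
    noise: NoiseModel,
    grid: Sequence[float],
) -> SpectrumSet:
    """Replicate mixture spectra: summed component spectra plus noise.

    Replicates draw from consecutive child streams of one seeded generator,
    so the whole set is reproducible from ``noise.seed`` while replicates
    stay statistically independent.
    """
    grid = np.asarray(grid, dtype=float)
    names = {m.name for m in models}
    if names != set(design.concentrations):
        raise ConfigError(
            f"designed components {sorted(design.concentrations)} do not match "
            f"band models {sorted(names)}"
        )
    clean = np.zeros_like(grid)
    for m in models:
        clean = clean + design.concentrations[m.name] * m.unit_absorbances(grid)
    streams = np.random.SeedSequence(noise.seed).spawn(design.replicates)
    spectra = []
    base = design.label or "mix"
    for k, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        noisy = clean + rng.normal(0.0, noise.sigma, size=grid.size) if noise.sigma > 0 else clean.copy()
        spectra.append(Spectrum(grid.copy(), noisy, f"{base}_r{k}"))
    return SpectrumSet(tuple(spectra), grid)


def study_grid() -> np.ndarray:
    """220–300 nm at 1.0 nm steps (81 points)."""
    return np.arange(220.0, 301.0, 1.0)


# Band constants are fixture plumbing chosen to reproduce the overlap
# geometry of the real system (maxima near 272 and 235 nm, standards at
# 5 / 20 µg/mL peaking in a plausible 0.2-0.8 AU window, unit-spectrum
# cosine similarity ~0.47); they are NOT measured absorptivities.
_HCT_BANDS = ((272.0, 9.0, 0.070), (225.0, 6.0, 0.050))
_LSP_BANDS = ((235.0, 10.0, 0.030), (270.0, 14.0, 0.0045))

#: single-point calibration standards, µg/mL
STUDY_STANDARDS = {"HCT": 5.0, "LSP": 20.0}

#: the seven accuracy/repeatability mixture designs (HCT, LSP in µg/mL)
STUDY_MIXTURE_DESIGNS = {
    "M1": {"HCT": 1.0, "LSP": 24.0},
    "M2": {"HCT": 2.0, "LSP": 20.0},
    "M3": {"HCT": 3.0, "LSP": 16.0},
    "M4": {"HCT": 4.0, "LSP": 12.0},
    "M5": {"HCT": 5.0, "LSP": 8.0},
    "M6": {"HCT": 6.0, "LSP": 4.0},
    "M7": {"HCT": 5.0, "LSP": 20.0},
}

#: spike levels added on top of the tablet base solution, µg/mL
STUDY_SPIKE_LEVELS = {
    "HCT": (0.5, 1.0, 1.5),
    "LSP": (2.0, 4.0, 6.0),
}

#: tablet base solution when 3/5 of an average tablet weight is taken
STUDY_SPIKE_BASE = {"HCT": 3.0, "LSP": 12.0}

#: tablet sample solution (full average tablet weight taken)
STUDY_TABLET_TRUTH = {"HCT": 5.0, "LSP": 20.0}


def study_presets() -> tuple[BandModel, BandModel, np.ndarray]:
    """HCT-like and LSP-like band models plus the 220–300 nm grid."""
    return (
        BandModel("HCT", _HCT_BANDS),
        BandModel("LSP", _LSP_BANDS),
        study_grid(),
    )


def generate_study_fixture(
    outdir: str | Path,
    seed: int = 0,
    *,
    sigma: float = 0.002,
    replicates: int = 3,
) -> Path:
    """Write the full synthetic study as CSV spectra plus a YAML manifest.

    Produces calibration standards, the seven accuracy mixtures
    (``replicates`` each), three tablet samples, and a three-level spike
    study (unspiked + three levels, ``replicates`` each, per the combined
    spike plan).  Every spectrum carries fresh noise from a child stream of
    ``seed``; the manifest records file roles and true concentrations so
    downstream accuracy scoring has ground truth.  Returns the manifest
    path.  Regenerating with the same seed is byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    hct, lsp, grid = study_presets()
    models = [hct, lsp]

    manifest: dict = {
        "grid_nm": {"start": 220.0, "stop": 300.0, "step": 1.0},
        "noise_sigma_au": sigma,
        "seed": seed,
        "standards": [],
        "mixtures": [],
        "tablets": [],
        "spikes": [],
    }

    def emit(design: MixtureDesign, sub_seed: int, role: str, extra: dict | None = None):
        sset = mixture_spectrum(models, design, NoiseModel(sigma, sub_seed), grid)
        for spec in sset:
            fname = f"{spec.label}.csv"
            write_spectrum(spec, outdir / fname)
            entry = {
                "path": fname,
                "role": role,
                "true_ugml": {k: float(v) for k, v in design.concentrations.items()},
            }
            if extra:
                entry.update(extra)
            manifest[role + "s" if not role.endswith("s") else role].append(entry)

    # stable sub-seed layout: standards 0-9, mixtures 10-99, tablets 100-109,
    # spikes 110+ — derived from the master seed via SeedSequence spawning
    root = np.random.SeedSequence(seed)
    sub = iter(root.generate_state(200, dtype=np.uint32).tolist())

    for name, conc in STUDY_STANDARDS.items():
        design = MixtureDesign({"HCT": 0.0, "LSP": 0.0} | {name: conc}, 1, f"std_{name}{conc:g}")
        emit(design, next(sub), "standard", {"component": name, "concentration_ugml": conc})

    for label, conc in STUDY_MIXTURE_DESIGNS.items():
        emit(MixtureDesign(conc, replicates, label), next(sub), "mixture", {"design": label})

    emit(
        MixtureDesign(STUDY_TABLET_TRUTH, replicates, "tablet"),
        next(sub),
        "tablet",
        {"design": "tablet"},
    )

    emit(
        MixtureDesign(STUDY_SPIKE_BASE, replicates, "spike_L0"),
        next(sub),
        "spike",
        {"level": 0, "added_ugml": {"HCT": 0.0, "LSP": 0.0}},
    )
    for level in range(1, 4):
        added = {c: STUDY_SPIKE_LEVELS[c][level - 1] for c in ("HCT", "LSP")}
        total = {c: STUDY_SPIKE_BASE[c] + added[c] for c in ("HCT", "LSP")}
        emit(
            MixtureDesign(total, replicates, f"spike_L{level}"),
            next(sub),
            "spike",
            {"level": level, "added_ugml": added},
        )

    manifest_path = outdir / "manifest.yaml"
    manifest_path.write_text(
        yaml.safe_dump(manifest, sort_keys=True), encoding="utf-8"
    )
    return manifest_path
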