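"""End-to-end study harnesses: synthetic spectra → filter → validation stats.

These functions replicate the two simulation studies the synthetic system
supports:

* :func:`accuracy_study` — the seven two-component mixture designs, many
  noisy replicates each, scored as mean |RE%| and RSD% against the
  half-Horwitz repeatability bound;
* :func:`lod_study` — replicate quantifications of a solution near the
  expected detection limit, turned into LOD/LOQ.

Calibration uses noiseless preset standards (ideal single-point
calibration), so the reported errors isolate what measurement noise on the
mixture spectrum does to the filter estimates.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .kalman import FilterConfig, SensitivityMatrix, build_sensitivity_matrix, run_filter
from .spectra import Spectrum, align_to_grid
from .synth import (
    STUDY_MIXTURE_DESIGNS,
    STUDY_STANDARDS,
    MixtureDesign,
    NoiseModel,
    component_spectrum,
    mixture_spectrum,
    study_presets,
)
from .validation import horwitz_half_rsd, relative_error, rsd_percent, ugml_to_fraction

__all__ = ["preset_calibration", "accuracy_study", "lod_study", "predicted_estimate_sd"]


def preset_calibration() -> SensitivityMatrix:
    """Sensitivity matrix from the noiseless 5 / 20 µg/mL preset standards."""
    hct, lsp, grid = study_presets()
    standards = align_to_grid(
        [
            Spectrum(grid, component_spectrum(hct, STUDY_STANDARDS["HCT"], grid).absorbances, "HCT"),
            Spectrum(grid, component_spectrum(lsp, STUDY_STANDARDS["LSP"], grid).absorbances, "LSP"),
        ]
    )
    return build_sensitivity_matrix(standards, dict(STUDY_STANDARDS))


def _sub_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) % (2**31) for s in state]


def accuracy_study(
    seed: int = 0,
    replicates: int = 100,
    sigma: float = 0.002,
    designs: Mapping[str, Mapping[str, float]] | None = None,
    config: FilterConfig | None = None,
) -> pd.DataFrame:
    """Monte-Carlo accuracy/repeatability study over the mixture designs.

    For every design, ``replicates`` independent noisy mixture spectra are
    quantified against the noiseless preset calibration.  Returns one row
    per (design, component) with the true concentration, mean estimate,
    mean absolute RE%, RSD% of the replicate estimates, and the
    half-Horwitz bound at the true concentration.
    """
    designs = dict(designs) if designs is not None else dict(STUDY_MIXTURE_DESIGNS)
    hct, lsp, grid = study_presets()
    H = preset_calibration()
    cfg = config if config is not None else FilterConfig(measurement_variance=max(sigma, 1e-4) ** 2)
    seeds = _sub_seeds(seed, len(designs))
    rows = []
    for (label, conc), sub in zip(designs.items(), seeds):
        sset = mixture_spectrum(
            [hct, lsp],
            MixtureDesign(conc, replicates, label),
            NoiseModel(sigma, sub),
            grid,
        )
        estimates = np.array([run_filter(H, s, cfg).estimate for s in sset])
        for i, comp in enumerate(H.components):
            true_c = conc[comp]
            est = estimates[:, i]
            res = [relative_error(e, true_c) for e in est]
            rows.append(
                {
                    "design": label,
                    "component": comp,
                    "true_ugml": true_c,
                    "mean_ugml": float(np.mean(est)),
                    "mean_abs_re_percent": float(np.mean(np.abs(res))),
                    "rsd_percent": rsd_percent(est.tolist()),
                    "half_horwitz_percent": horwitz_half_rsd(ugml_to_fraction(true_c)),
                }
            )
    return pd.DataFrame(rows)


def predicted_estimate_sd(sigma: float = 0.002) -> dict[str, float]:
    """Noise-propagated SD of each concentration estimate, µg/mL.

    The converged filter equals the batch least-squares solution, whose
    covariance under i.i.d. absorbance noise of SD ``sigma`` is
    σ²·(HᵀH)⁻¹ — the closed-form oracle the LOD harness is checked against.
    """
    H = preset_calibration()
    gram_inv = np.linalg.inv(H.values.T @ H.values)
    sds = sigma * np.sqrt(np.diag(gram_inv))
    return dict(zip(H.components, (float(s) for s in sds)))


def lod_study(
    seed: int = 0,
    n: int = 7,
    sigma: float = 0.002,
    concentrations: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """LOD/LOQ from replicate quantifications near the detection limit.

    The low-level solution defaults to 0.10 µg/mL HCT-like and 0.50 µg/mL
    LSP-like — a few multiples of the noise-propagated estimate SD, i.e.
    "near the expected limit of detection".  Returns one row per component
    with the replicate SD, LOD = 3.3·SD and LOQ = 10·SD.
    """
    from .validation import lod_loq

    conc = dict(concentrations) if concentrations is not None else {"HCT": 0.10, "LSP": 0.50}
    hct, lsp, grid = study_presets()
    H = preset_calibration()
    cfg = FilterConfig(measurement_variance=max(sigma, 1e-4) ** 2)
    sset = mixture_spectrum(
        [hct, lsp],
        MixtureDesign(conc, n, "lod"),
        NoiseModel(sigma, _sub_seeds(seed, 1)[0]),
        grid,
    )
    estimates = np.array([run_filter(H, s, cfg).estimate for s in sset])
    rows = []
    for i, comp in enumerate(H.components):
        lod, loq = lod_loq(estimates[:, i].tolist())
        rows.append(
            {
                "component": comp,
                "true_ugml": conc[comp],
                "n": n,
                "sd_ugml": float(np.std(estimates[:, i], ddof=1)),
                "lod_ugml": lod,
                "loq_ugml": loq,
            }
        )
    return pd.DataFrame(rows)
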