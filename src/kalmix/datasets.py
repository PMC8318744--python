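"""Bundled example validation data for an HCT/LSP combination tablet assay.

Measured values from a single-laboratory validation of a UV-Vis
Kalman-filter assay of tablets nominally containing 12.5 mg
hydrochlorothiazide (HCT) and 50 mg losartan potassium (LSP): accuracy
mixtures, tablet-content replicates, a three-level spike-recovery study,
and a head-to-head comparison against an HPLC reference assay.  These are
measurement results, not raw spectra; they exercise the validation
calculus (relative error, repeatability vs the Horwitz criterion,
recovery, content, and F/t method comparison) on realistic numbers.
"""

from __future__ import annotations

__all__ = [
    "ACCURACY_MIXTURES",
    "TABLET_CONCENTRATIONS_UGML",
    "TABLET_AVG_WEIGHT_MG",
    "TABLET_POWDER_MG",
    "RECOVERY_STUDY",
    "METHOD_COMPARISON_MG",
]

#: seven standard-mixture designs: {label: {component: (true µg/mL, replicate
#: measurements µg/mL)}}
ACCURACY_MIXTURES: dict[str, dict[str, tuple[float, tuple[float, ...]]]] = {
    "M1": {"HCT": (1.0, (1.002, 0.996, 0.999)), "LSP": (24.0, (24.206, 24.238, 24.229))},
    "M2": {"HCT": (2.0, (1.981, 1.981, 1.975)), "LSP": (20.0, (20.115, 20.112, 20.131))},
    "M3": {"HCT": (3.0, (2.982, 2.973, 2.974)), "LSP": (16.0, (15.961, 15.971, 15.979))},
    "M4": {"HCT": (4.0, (3.975, 3.966, 3.965)), "LSP": (12.0, (12.067, 12.071, 12.072))},
    "M5": {"HCT": (5.0, (5.008, 4.991, 4.990)), "LSP": (8.0, (8.019, 8.035, 8.031))},
    "M6": {"HCT": (6.0, (5.921, 5.897, 5.904)), "LSP": (4.0, (4.064, 4.074, 4.077))},
    "M7": {"HCT": (5.0, (4.990, 4.975, 4.980)), "LSP": (20.0, (20.203, 20.224, 20.220))},
}

#: final-solution concentrations of three tablet sample preparations
TABLET_CONCENTRATIONS_UGML: dict[str, tuple[float, ...]] = {
    "HCT": (4.978, 4.975, 4.953),
    "LSP": (20.033, 20.042, 19.942),
}

#: average tablet weight and powder weight taken (mg); here equal, so the
#: M/m correction is unity
TABLET_AVG_WEIGHT_MG = 253.4
TABLET_POWDER_MG = 253.4

#: spike-recovery study: {component: {spike µg/mL: (unspiked replicates C1,
#: spiked replicates C2)}}; replicate k pairs with replicate k
RECOVERY_STUDY: dict[str, dict[float, tuple[tuple[float, ...], tuple[float, ...]]]] = {
    "HCT": {
        0.5: ((3.003, 3.009, 3.013), (3.512, 3.508, 3.508)),
        1.0: ((3.003, 3.009, 3.013), (3.996, 4.004, 4.000)),
        1.5: ((3.003, 3.009, 3.013), (4.515, 4.520, 4.517)),
    },
    "LSP": {
        2.0: ((11.997, 11.991, 11.997), (13.962, 13.964, 13.966)),
        4.0: ((11.997, 11.991, 11.997), (15.887, 15.882, 15.886)),
        6.0: ((11.997, 11.991, 11.997), (17.973, 17.973, 17.970)),
    },
}

#: per-tablet contents (mg) by the filter method vs the HPLC reference
METHOD_COMPARISON_MG: dict[str, tuple[tuple[float, ...], tuple[float, ...]]] = {
    "HCT": ((12.4450, 12.4375, 12.3825), (12.45, 12.38, 12.42)),
    "LSP": ((50.0825, 50.105, 49.855), (49.93, 50.30, 50.45)),
}
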