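"""Assay-validation statistics for multicomponent spectrophotometric methods.

Implements the standard single-laboratory validation calculus used when a
new quantification method (here, Kalman-filter spectral unmixing) is
checked against reference values and against an established method:

* signed relative error RE% of a measured vs. reference concentration,
* repeatability as RSD% of replicates, judged against half the Horwitz
  function value at that concentration,
* detection and quantification limits LOD = 3.3·SD, LOQ = 10·SD from
  replicates near the expected detection limit,
* spike recovery Rev% = (C₂ − C₁)·100/Cs with an 85–110% acceptance window,
* tablet content in mg/tablet from the final-solution concentration and the
  dilution chain,
* two-method equivalence: variance-ratio F-test (larger variance in the
  numerator) and pooled two-sample t-test at significance level α.

All statistics use the sample (n−1) standard deviation.  Computation is
kept at full precision; rounding half-up to a table's printed precision
happens only in the report rendering layer.
"""

from __future__ import annotations

import decimal
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError

__all__ = [
    "ReplicateSet",
    "TabletDesign",
    "SpikeDesign",
    "MethodComparison",
    "ValidationReport",
    "relative_error",
    "rsd_percent",
    "horwitz_half_rsd",
    "ugml_to_fraction",
    "lod_loq",
    "recovery",
    "tablet_content",
    "compare_methods",
    "f_critical",
    "t_critical",
    "round_half_up",
    "build_validation_report",
]

#: acceptable spike-recovery window, percent
RECOVERY_WINDOW = (85.0, 110.0)


@dataclass(frozen=True)
class ReplicateSet:
    """Replicate measurements of one quantity (µg/mL or mg/tablet)."""

    values: tuple[float, ...]
    label: str = ""

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"{self.label!r}: non-finite replicate values")
        object.__setattr__(self, "values", vals)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        """Sample standard deviation (n−1 denominator)."""
        if self.n < 2:
            raise ValueError(f"{self.label!r}: need n >= 2 for an SD, got {self.n}")
        return float(np.std(self.values, ddof=1))


@dataclass(frozen=True)
class TabletDesign:
    """Dilution chain of the tablet assay.

    ``dilution_product`` collapses the fixed preparation factors
    (dissolve in 250 mL, dilute 10 → 100 mL, µg → mg) into one constant,
    2.5 by default; ``M`` is the average tablet weight and ``m`` the powder
    weight actually taken, both in mg.
    """

    M: float
    m: float
    dilution_product: float = 2.5

    def __post_init__(self) -> None:
        if self.M <= 0 or self.m <= 0 or self.dilution_product <= 0:
            raise ValueError("tablet design parameters must all be > 0")


@dataclass(frozen=True)
class SpikeDesign:
    """Spiking plan: added concentrations per level, replicates per level."""

    levels: tuple[float, ...]
    replicates: int = 3

    def __post_init__(self) -> None:
        if 0.0 not in self.levels:
            raise ValueError("spike design must include the unspiked level 0")
        if any(l < 0 for l in self.levels):
            raise ValueError("spike levels must be >= 0")
        if self.replicates < 1:
            raise ValueError("need at least one replicate per level")


@dataclass(frozen=True)
class MethodComparison:
    """F/t equivalence comparison of two replicate sets."""

    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    f_exp: float
    f_crit: float
    sd_pool: float
    t_exp: float
    t_crit: float
    alpha: float
    df: int
    variances_equivalent: bool
    means_equivalent: bool


def relative_error(measured: float, reference: float) -> float:
    """Signed relative error RE% = (C − C₀)·100/C₀."""
    if reference == 0:
        raise ValueError("reference concentration must be nonzero")
    return (measured - reference) * 100.0 / reference


def rsd_percent(replicates: ReplicateSet | Sequence[float]) -> float:
    """Relative standard deviation RSD% = SD·100/mean, sample SD."""
    r = replicates if isinstance(replicates, ReplicateSet) else ReplicateSet(tuple(replicates))
    if r.mean == 0:
        raise ValueError("mean of replicates is zero; RSD undefined")
    return r.sd * 100.0 / r.mean


def ugml_to_fraction(concentration_ugml: float) -> float:
    """Convert µg/mL to the mass fraction the Horwitz function expects."""
    return concentration_ugml * 1e-6


def horwitz_half_rsd(mass_fraction: float) -> float:
    """Half the Horwitz-function RSD, percent.

    The Horwitz function RSD_H = 2^(1 − 0.5·log₁₀ C) predicts the
    between-laboratory RSD at mass fraction C; single-laboratory
    repeatability is commonly accepted when RSD < ½·RSD_H.
    """
    if not (0.0 < mass_fraction < 1.0):
        raise ValueError(
            f"mass fraction must be in (0, 1), got {mass_fraction} "
            "(e.g. 5 µg/mL → 5e-6)"
        )
    return 0.5 * 2.0 ** (1.0 - 0.5 * math.log10(mass_fraction))


def lod_loq(
    replicates: ReplicateSet | Sequence[float],
    *,
    min_n: int = 7,
) -> tuple[float, float]:
    """Detection and quantification limits from low-level replicates.

    LOD = 3.3·SD, LOQ = 10·SD, with SD the sample standard deviation of
    replicate measurements of a solution near the expected detection
    limit.  Fewer than ``min_n`` (default 7) replicates triggers a warning;
    fewer than 2 is an error.
    """
    r = replicates if isinstance(replicates, ReplicateSet) else ReplicateSet(tuple(replicates))
    if r.n < 2:
        raise ValueError(f"need at least 2 replicates, got {r.n}")
    if r.n < min_n:
        warnings.warn(
            f"only {r.n} replicates (recommended >= {min_n}); LOD/LOQ may be unstable",
            stacklevel=2,
        )
    sd = r.sd
    return 3.3 * sd, 10.0 * sd


def recovery(spiked: float, unspiked: float, spike: float) -> float:
    """Spike recovery Rev% = (C₂ − C₁)·100/Cs."""
    if spike <= 0:
        raise ValueError(f"spike concentration must be > 0, got {spike}")
    return (spiked - unspiked) * 100.0 / spike


def tablet_content(concentration_ugml: float, design: TabletDesign) -> float:
    """Content in mg/tablet from the final-solution concentration."""
    return design.dilution_product * concentration_ugml * design.M / design.m


def f_critical(alpha: float, df_num: int, df_den: int) -> float:
    """Critical value of the two-sided variance-ratio test at ``alpha``.

    With the larger variance conventionally placed in the numerator, the
    two-sided test at significance α rejects above the upper α/2 quantile —
    the value analytical-chemistry F-tables list as F(α; df_num; df_den),
    e.g. F(0.05; 2; 2) = 39.00.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df_num < 1 or df_den < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.f.ppf(1.0 - alpha / 2.0, df_num, df_den))


def t_critical(alpha: float, df: int) -> float:
    """Two-sided t quantile (upper 1 − α/2 point) at ``df`` degrees of freedom."""
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError("degrees of freedom must be >= 1")
    return float(stats.t.ppf(1.0 - alpha / 2.0, df))


def compare_methods(
    a: ReplicateSet | Sequence[float],
    b: ReplicateSet | Sequence[float],
    alpha: float = 0.05,
) -> MethodComparison:
    """Two-method equivalence: variance-ratio F-test and pooled t-test.

    The F statistic puts the larger sample variance in the numerator and is
    compared against the two-sided critical value :func:`f_critical`.  The t
    statistic uses the pooled standard deviation

        SD_pool = sqrt(((n_a−1)s_a² + (n_b−1)s_b²) / (n_a+n_b−2))

    and is compared two-sided at n_a+n_b−2 degrees of freedom.  Swapping
    the two sets leaves every statistic unchanged.
    """
    ra = a if isinstance(a, ReplicateSet) else ReplicateSet(tuple(a), "a")
    rb = b if isinstance(b, ReplicateSet) else ReplicateSet(tuple(b), "b")
    if ra.n < 2 or rb.n < 2:
        raise ValueError("both replicate sets need n >= 2")
    sa, sb = ra.sd, rb.sd
    va, vb = sa**2, sb**2
    if va >= vb:
        f_exp = va / vb if vb > 0 else (1.0 if va == 0 else math.inf)
        df_num, df_den = ra.n - 1, rb.n - 1
    else:
        f_exp = vb / va
        df_num, df_den = rb.n - 1, ra.n - 1
    df = ra.n + rb.n - 2
    sd_pool = math.sqrt(((ra.n - 1) * va + (rb.n - 1) * vb) / df)
    if sd_pool == 0.0:
        if ra.mean != rb.mean:
            raise ValueError(
                "zero pooled SD with unequal means: degenerate replicate data"
            )
        t_exp = 0.0
    else:
        t_exp = abs(ra.mean - rb.mean) / (sd_pool * math.sqrt(1.0 / ra.n + 1.0 / rb.n))
    f_crit = f_critical(alpha, df_num, df_den)
    t_crit = t_critical(alpha, df)
    return MethodComparison(
        mean_a=ra.mean,
        mean_b=rb.mean,
        sd_a=sa,
        sd_b=sb,
        f_exp=f_exp,
        f_crit=f_crit,
        sd_pool=sd_pool,
        t_exp=t_exp,
        t_crit=t_crit,
        alpha=alpha,
        df=df,
        variances_equivalent=f_exp < f_crit,
        means_equivalent=t_exp < t_crit,
    )


def round_half_up(x: float, ndigits: int) -> float:
    """Round half away from zero at ``ndigits`` decimals (report rendering)."""
    q = decimal.Decimal(10) ** -ndigits
    return float(
        decimal.Decimal(repr(float(x))).quantize(q, rounding=decimal.ROUND_HALF_UP)
    )


@dataclass
class ValidationReport:
    """Assembled validation tables; sections are None when not requested."""

    accuracy: pd.DataFrame | None = None
    recovery: pd.DataFrame | None = None
    content: pd.DataFrame | None = None
    lod: pd.DataFrame | None = None
    comparison: pd.DataFrame | None = None
    alpha: float = 0.05

    def sections(self) -> dict[str, pd.DataFrame]:
        out = {}
        for name in ("accuracy", "recovery", "content", "lod", "comparison"):
            df = getattr(self, name)
            if df is not None and not df.empty:
                out[name] = df
        return out

    def to_text(self) -> str:
        """Human-readable summary; values rounded half-up per column."""
        titles = {
            "accuracy": "Accuracy and repeatability (RE%, RSD% vs 1/2 Horwitz)",
            "recovery": f"Spike recovery (acceptable {RECOVERY_WINDOW[0]:.0f}-{RECOVERY_WINDOW[1]:.0f}%)",
            "content": "Tablet content (mg/tablet)",
            "lod": "Detection and quantification limits",
            "comparison": f"Two-method comparison (alpha = {self.alpha})",
        }
        decimals = {
            "true_ugml": 3, "mean_ugml": 3, "re_percent": 2, "rsd_percent": 2,
            "half_horwitz_percent": 2, "c1_ugml": 3, "c2_ugml": 3,
            "spike_ugml": 3, "recovery_percent": 2, "conc_ugml": 3,
            "content_mg": 4, "sd_ugml": 4, "lod_ugml": 3, "loq_ugml": 3,
            "mean_a": 4, "mean_b": 4, "sd_pool": 4, "f_exp": 3, "f_crit": 2,
            "t_exp": 3, "t_crit": 3,
        }
        blocks = []
        for name, df in self.sections().items():
            shown = df.copy()
            for col in shown.columns:
                if col in decimals and pd.api.types.is_float_dtype(shown[col]):
                    shown[col] = shown[col].map(
                        lambda v, nd=decimals[col]: round_half_up(v, nd)
                        if pd.notna(v)
                        else v
                    )
            blocks.append(f"== {titles[name]} ==\n{shown.to_string(index=False)}")
        return "\n\n".join(blocks) if blocks else "(empty report)"


def build_validation_report(
    *,
    accuracy: Mapping[str, Mapping[str, tuple[float, Sequence[float]]]] | None = None,
    recovery_data: Mapping[str, Mapping[float, tuple[Sequence[float], Sequence[float]]]] | None = None,
    content_data: Mapping[str, Sequence[float]] | None = None,
    tablet_design: TabletDesign | None = None,
    lod_data: Mapping[str, Sequence[float]] | None = None,
    comparison_data: Mapping[str, tuple[Sequence[float], Sequence[float]]] | None = None,
    alpha: float = 0.05,
) -> ValidationReport:
    """Assemble the full validation report from raw measured values.

    Parameters
    ----------
    accuracy
        ``{mixture_label: {component: (true_ugml, measured_replicates)}}``.
    recovery_data
        ``{component: {spike_ugml: (unspiked_replicates, spiked_replicates)}}``;
        replicate *k* of each spiked level is paired with replicate *k* of
        the unspiked set.
    content_data
        ``{component: final_solution_concentrations_ugml}`` — requires
        ``tablet_design``.
    lod_data
        ``{component: low-level replicate measurements}``.
    comparison_data
        ``{component: (method_a_replicates, method_b_replicates)}``.
    """
    report = ValidationReport(alpha=alpha)

    if accuracy:
        rows = []
        for label, per_comp in accuracy.items():
            for comp, (true_c, measured) in per_comp.items():
                reps = ReplicateSet(tuple(measured), f"{label}/{comp}")
                half_h = horwitz_half_rsd(ugml_to_fraction(true_c))
                rsd = rsd_percent(reps)
                rows.append(
                    {
                        "mixture": label,
                        "component": comp,
                        "n": reps.n,
                        "true_ugml": true_c,
                        "mean_ugml": reps.mean,
                        "re_percent": relative_error(reps.mean, true_c),
                        "rsd_percent": rsd,
                        "half_horwitz_percent": half_h,
                        "repeatability_ok": rsd < half_h,
                    }
                )
        report.accuracy = pd.DataFrame(rows)

    if recovery_data:
        rows = []
        for comp, levels in recovery_data.items():
            for spike, (unspiked, spiked) in sorted(levels.items()):
                if spike <= 0:
                    raise ConfigError(
                        f"recovery level for {comp!r} must have spike > 0"
                    )
                if len(unspiked) != len(spiked):
                    raise ConfigError(
                        f"recovery for {comp!r} at {spike} µg/mL: replicate "
                        "counts of unspiked and spiked sets differ"
                    )
                for k, (c1, c2) in enumerate(zip(unspiked, spiked), start=1):
                    rev = recovery(c2, c1, spike)
                    rows.append(
                        {
                            "component": comp,
                            "spike_ugml": spike,
                            "replicate": k,
                            "c1_ugml": c1,
                            "c2_ugml": c2,
                            "recovery_percent": rev,
                            "within_window": RECOVERY_WINDOW[0] <= rev <= RECOVERY_WINDOW[1],
                        }
                    )
        report.recovery = pd.DataFrame(rows)

    if content_data:
        if tablet_design is None:
            raise ConfigError("content_data requires a tablet_design")
        rows = []
        for comp, concs in content_data.items():
            for k, ci in enumerate(concs, start=1):
                rows.append(
                    {
                        "component": comp,
                        "replicate": k,
                        "conc_ugml": float(ci),
                        "content_mg": tablet_content(float(ci), tablet_design),
                    }
                )
        report.content = pd.DataFrame(rows)

    if lod_data:
        rows = []
        for comp, reps in lod_data.items():
            r = ReplicateSet(tuple(reps), comp)
            lod, loq = lod_loq(r)
            rows.append(
                {
                    "component": comp,
                    "n": r.n,
                    "sd_ugml": r.sd,
                    "lod_ugml": lod,
                    "loq_ugml": loq,
                }
            )
        report.lod = pd.DataFrame(rows)

    if comparison_data:
        rows = []
        for comp, (a, b) in comparison_data.items():
            mc = compare_methods(a, b, alpha=alpha)
            rows.append(
                {
                    "component": comp,
                    "mean_a": mc.mean_a,
                    "mean_b": mc.mean_b,
                    "f_exp": mc.f_exp,
                    "f_crit": mc.f_crit,
                    "sd_pool": mc.sd_pool,
                    "t_exp": mc.t_exp,
                    "t_crit": mc.t_crit,
                    "variances_equivalent": mc.variances_equivalent,
                    "means_equivalent": mc.means_equivalent,
                }
            )
        report.comparison = pd.DataFrame(rows)

    return report
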