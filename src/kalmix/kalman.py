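"""Static-state Kalman filter for multicomponent spectral unmixing.

Under Beer–Lambert additivity a mixture's absorbance at wavelength λ is

    A(λ) = Σ_i h_i(λ) · c_i + ε(λ),

where ``h_i(λ)`` is component *i*'s absorptivity at unit concentration
(AU per µg/mL) and ``c`` is the unknown, wavelength-independent
concentration vector.  The filter treats ``c`` as a static state and each
wavelength as one scalar measurement: starting from a diffuse prior it
sweeps the spectrum in wavelength order, updating the estimate ĉ and its
covariance P at every step via the scalar-measurement Kalman recursion

    e  = A(λ) − h·ĉ                 (innovation)
    g  = P·h / (h·P·h + r)          (gain)
    ĉ' = ĉ + g·e
    P' = P − g·(h·P)                (or the Joseph form, optionally)

Full-spectrum sweeps are repeated, carrying ĉ and P forward, until the
estimate stops moving.  With a diffuse prior the converged estimate equals
the classical-least-squares (CLS) batch solution, which
:func:`cls_oracle` computes independently for verification.

The measurement matrix comes from single-point calibration: one standard
spectrum per component, divided by its known concentration
(:func:`build_sensitivity_matrix`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import (
    GridMismatchError,
    NumericalStabilityError,
    SingularityError,
    UnobservableComponentError,
)
from .spectra import GRID_ATOL, Spectrum, SpectrumSet

__all__ = [
    "SensitivityMatrix",
    "FilterConfig",
    "FilterResult",
    "build_sensitivity_matrix",
    "kalman_step",
    "run_filter",
    "cls_oracle",
    "innovation_diagnostics",
]


@dataclass(frozen=True)
class SensitivityMatrix:
    """Per-wavelength unit-concentration absorptivities of each component.

    ``values[k, i]`` is component ``components[i]``'s absorbance at
    ``grid[k]`` for a 1 µg/mL solution.  This is the filter's measurement
    model; a component whose column is identically zero is unobservable and
    rejected at construction.
    """

    grid: np.ndarray
    components: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        values = np.asarray(self.values, dtype=float)
        components = tuple(self.components)
        if values.shape != (grid.size, len(components)):
            raise ValueError(
                f"values shape {values.shape} does not match "
                f"({grid.size} wavelengths, {len(components)} components)"
            )
        if not np.all(np.isfinite(values)):
            raise ValueError("non-finite absorptivities")
        for i, name in enumerate(components):
            if np.all(values[:, i] == 0.0):
                raise UnobservableComponentError(
                    f"component {name!r} has an all-zero absorptivity column"
                )
        grid = grid.copy()
        values = values.copy()
        grid.flags.writeable = False
        values.flags.writeable = False
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "components", components)
        object.__setattr__(self, "values", values)

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass(frozen=True)
class FilterConfig:
    """Tunables of the sequential filter.

    prior_mean
        Initial concentration guess, µg/mL (scalar broadcast or vector).
    prior_variance
        Diagonal of the initial covariance, (µg/mL)².  The default 1e6 is
        diffuse: it makes the converged filter match the least-squares
        solution to well below any reporting precision.
    measurement_variance
        Scalar absorbance noise variance r (AU²), or a per-wavelength
        vector for heteroscedastic noise.
    passes
        Maximum number of full-spectrum sweeps.
    tolerance
        Convergence threshold on the max component-wise estimate change
        over one sweep, µg/mL.
    joseph
        Use the Joseph-form covariance update.  The plain form is default:
        at a few dozen wavelengths and 2–4 components it is benign, and the
        flag documents the stability trade-off rather than hiding it.
    """

    prior_mean: float | Sequence[float] = 0.0
    prior_variance: float = 1e6
    measurement_variance: float | Sequence[float] = 1e-6
    passes: int = 50
    tolerance: float = 1e-9
    joseph: bool = False

    def __post_init__(self) -> None:
        if self.prior_variance <= 0:
            raise ValueError("prior_variance must be > 0")
        r = np.asarray(self.measurement_variance, dtype=float)
        if np.any(r <= 0):
            raise ValueError("measurement_variance must be > 0")
        if self.passes < 1:
            raise ValueError("passes must be >= 1")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")


@dataclass(frozen=True)
class FilterResult:
    """Converged filter output.

    ``innovations`` and ``trace`` hold one entry per processed wavelength
    (``len(grid) × passes_used`` steps in total); ``trace[k]`` is the
    estimate *after* step ``k``.
    """

    estimate: np.ndarray
    covariance: np.ndarray
    innovations: np.ndarray
    trace: np.ndarray
    passes_used: int
    components: tuple[str, ...]
    converged: bool

    @property
    def posterior_sd(self) -> np.ndarray:
        """Per-component posterior standard deviation, µg/mL."""
        return np.sqrt(np.clip(np.diag(self.covariance), 0.0, None))


def build_sensitivity_matrix(
    standards: SpectrumSet,
    concentrations: Mapping[str, float],
) -> SensitivityMatrix:
    """Single-point Beer–Lambert calibration from one standard per component.

    Each standard spectrum is divided by its known concentration; the label
    of the spectrum names the component.  Mirrors calibrating from a single
    HCT 5 µg/mL and a single LSP 20 µg/mL standard.
    """
    missing = [s.label for s in standards if s.label not in concentrations]
    if missing:
        raise ValueError(f"no concentration given for standards: {missing}")
    columns = []
    names = []
    for s in standards:
        c = float(concentrations[s.label])
        if c <= 0:
            raise ValueError(
                f"standard {s.label!r}: concentration must be > 0, got {c}"
            )
        columns.append(s.absorbances / c)
        names.append(s.label)
    return SensitivityMatrix(standards.grid, tuple(names), np.column_stack(columns))


def kalman_step(
    estimate: np.ndarray,
    covariance: np.ndarray,
    h: np.ndarray,
    absorbance: float,
    r: float,
    *,
    joseph: bool = False,
) -> tuple[np.ndarray, np.ndarray, float]:
    """One scalar-measurement update; returns (ĉ', P', innovation)."""
    c = np.asarray(estimate, dtype=float)
    P = np.asarray(covariance, dtype=float)
    h = np.asarray(h, dtype=float)
    if not (
        np.all(np.isfinite(c))
        and np.all(np.isfinite(P))
        and np.all(np.isfinite(h))
        and np.isfinite(absorbance)
        and np.isfinite(r)
    ):
        raise ValueError("non-finite input to kalman_step")
    if r <= 0:
        raise ValueError("measurement variance r must be > 0")
    if h.shape != c.shape:
        raise ValueError(f"h shape {h.shape} does not match state shape {c.shape}")
    Ph = P @ h
    s = float(h @ Ph) + r  # innovation variance, > 0 since r > 0
    e = float(absorbance) - float(h @ c)
    g = Ph / s
    c_new = c + g * e
    if joseph:
        n = c.size
        ImgH = np.eye(n) - np.outer(g, h)
        P_new = ImgH @ P @ ImgH.T + r * np.outer(g, g)
    else:
        P_new = P - np.outer(g, Ph)
    P_new = 0.5 * (P_new + P_new.T)  # enforce symmetry against round-off
    return c_new, P_new, e


def run_filter(
    H: SensitivityMatrix,
    sample: Spectrum,
    config: FilterConfig | None = None,
    *,
    descending: bool = False,
) -> FilterResult:
    """Estimate component concentrations from one mixture spectrum.

    Wavelengths are processed in ascending order (``descending`` reverses
    each sweep; with a static state the converged estimate is the same).
    Sweeps repeat, carrying ĉ and P forward, until the largest
    component-wise estimate change over a sweep drops below
    ``config.tolerance`` or ``config.passes`` is exhausted.
    """
    cfg = config if config is not None else FilterConfig()
    if len(sample) != H.grid.size or not np.allclose(
        sample.wavelengths, H.grid, rtol=0.0, atol=GRID_ATOL
    ):
        raise GridMismatchError(
            f"sample {sample.label!r} is not on the calibration grid"
        )
    n = H.n_components
    n_wl = H.grid.size
    c = np.broadcast_to(np.asarray(cfg.prior_mean, dtype=float), (n,)).astype(float)
    P = np.eye(n) * float(cfg.prior_variance)
    r = np.broadcast_to(
        np.asarray(cfg.measurement_variance, dtype=float), (n_wl,)
    ).astype(float)

    order = np.arange(n_wl)[::-1] if descending else np.arange(n_wl)
    innovations: list[float] = []
    trace: list[np.ndarray] = []
    psd_floor = -1e-10 * max(float(cfg.prior_variance), 1.0)

    converged = False
    passes_used = 0
    for _ in range(cfg.passes):
        c_before = c.copy()
        for k in order:
            c, P, e = kalman_step(
                c, P, H.values[k], sample.absorbances[k], r[k], joseph=cfg.joseph
            )
            innovations.append(e)
            trace.append(c.copy())
        passes_used += 1
        if np.min(np.linalg.eigvalsh(P)) < psd_floor:
            raise NumericalStabilityError(
                "posterior covariance lost positive semi-definiteness; "
                "increase measurement_variance or enable the Joseph update"
            )
        if np.max(np.abs(c - c_before)) < cfg.tolerance:
            converged = True
            break

    if np.any(c < 0):
        neg = [H.components[i] for i in np.flatnonzero(c < 0)]
        warnings.warn(
            f"negative concentration estimate for {neg}; reported unclipped",
            stacklevel=2,
        )
    return FilterResult(
        estimate=c,
        covariance=P,
        innovations=np.asarray(innovations),
        trace=np.asarray(trace),
        passes_used=passes_used,
        components=H.components,
        converged=converged,
    )


def cls_oracle(
    H: SensitivityMatrix,
    sample: Spectrum,
    r: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch classical-least-squares solution and its covariance.

    Solves the normal equations (HᵀH)ĉ = HᵀA; the covariance is
    r·(HᵀH)⁻¹ for homoscedastic noise variance ``r``.  This is the solution
    the converged sequential filter must reproduce, computed by an
    independent route.
    """
    if len(sample) != H.grid.size or not np.allclose(
        sample.wavelengths, H.grid, rtol=0.0, atol=GRID_ATOL
    ):
        raise GridMismatchError(
            f"sample {sample.label!r} is not on the calibration grid"
        )
    M = H.values
    gram = M.T @ M
    # rank check via SVD before solving; name the collinear pair if found
    sv = np.linalg.svd(M, compute_uv=False)
    if sv[-1] < 1e-10 * sv[0]:
        worst = None
        for i in range(H.n_components):
            for j in range(i + 1, H.n_components):
                ui = M[:, i] / np.linalg.norm(M[:, i])
                uj = M[:, j] / np.linalg.norm(M[:, j])
                cos = abs(float(ui @ uj))
                if worst is None or cos > worst[0]:
                    worst = (cos, H.components[i], H.components[j])
        detail = (
            f" (most collinear pair: {worst[1]!r} and {worst[2]!r})"
            if worst
            else ""
        )
        raise SingularityError("sensitivity matrix is rank-deficient" + detail)
    rhs = M.T @ sample.absorbances
    estimate = np.linalg.solve(gram, rhs)
    covariance = float(r) * np.linalg.inv(gram)
    return estimate, covariance


def innovation_diagnostics(result: FilterResult) -> dict[str, float]:
    """Mean, variance, and lag-1 autocorrelation of the innovation sequence.

    For an adequate measurement model the innovations behave like white
    noise: near-zero mean and near-zero lag-1 autocorrelation.  Structure
    in the innovations (large mean, strong autocorrelation) signals a
    missing absorber or a wrong sensitivity matrix.  The autocorrelation is
    the Pearson correlation between the sequence and its one-step shift;
    it is NaN for constant sequences.
    """
    e = np.asarray(result.innovations, dtype=float)
    if e.size == 0:
        raise ValueError("empty innovation sequence")
    mean = float(np.mean(e))
    variance = float(np.var(e, ddof=0))
    if e.size < 2 or variance == 0.0:
        lag1 = float("nan")
    else:
        a, b = e[:-1], e[1:]
        sa, sb = np.std(a), np.std(b)
        if sa == 0.0 or sb == 0.0:
            lag1 = float("nan")
        else:
            lag1 = float(np.corrcoef(a, b)[0, 1])
    return {"mean": mean, "variance": variance, "lag1_autocorrelation": lag1}
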