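"""Phosphorescence-decay processing: outlier rejection, averaging,
mono-exponential lifetime fitting and Stern-Volmer pO2 conversion.

A location's 20 repetition histograms are screened for motion-corrupted
decays by an iterated two-sided Grubbs test on total photon counts, the
survivors are averaged bin-wise, and the mean decay is fitted over the
window t >= 5 µs with

    y(t) = A * exp(-t / tau) + C

The decay rate tau is the phosphorescence lifetime; collisional quenching by
oxygen shortens it, so pO2 follows from the Stern-Volmer relation
1/tau = 1/tau0 + kq * pO2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import (
    CalibrationError,
    DegenerateInputError,
    FewDecaysWarning,
)
from .protocol import AcquisitionProtocol, CalibrationParams

__all__ = [
    "DecayHistogram",
    "FitResult",
    "GrubbsRejection",
    "total_photons",
    "grubbs_critical_value",
    "reject_outlier_decays",
    "average_decays",
    "fit_lifetime",
    "fit_location",
    "lifetime_to_po2",
    "po2_to_lifetime",
]


@dataclass
class DecayHistogram:
    """Time-binned photon counts from one PLIM repetition.

    ``t`` holds bin-start times in µs relative to the end of the excitation
    gate; ``counts`` the photons per bin (integers for raw acquisitions,
    real-valued for averaged or expected-value decays).
    """

    t: np.ndarray
    counts: np.ndarray
    protocol: AcquisitionProtocol = field(default_factory=AcquisitionProtocol)
    truth: Optional[dict] = None  # generator-side ground truth, if synthetic

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.t.ndim != 1 or self.t.shape != self.counts.shape:
            raise DegenerateInputError("t and counts must be 1-D and congruent")
        if self.t.size == 0:
            raise DegenerateInputError("empty decay histogram")
        if np.any(self.counts < 0):
            raise DegenerateInputError("negative photon counts")
        dt = np.diff(self.t)
        if self.t.size > 1 and (
            np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-9, atol=1e-9)
        ):
            raise DegenerateInputError("bin times must be uniform and increasing")


@dataclass(frozen=True)
class FitResult:
    """Mono-exponential fit of a mean phosphorescence decay."""

    amplitude: float
    tau_us: float
    offset: float
    residual_norm: float
    n_kept: int = 0
    po2_mmhg: Optional[float] = None
    converged: bool = True
    message: str = ""


@dataclass(frozen=True)
class GrubbsRejection:
    """One iteration of the Grubbs screen: which decay fell and why."""

    index: int
    total_photons: float
    g_statistic: float
    g_critical: float


def total_photons(decay: DecayHistogram) -> float:
    """Total photon count of one decay (the Grubbs screening variable)."""
    return float(np.sum(decay.counts))


def grubbs_critical_value(n: int, alpha: float) -> float:
    """Two-sided Grubbs critical value G_crit(n, alpha).

    Derived from the Student-t distribution:
    ``G = (n-1)/sqrt(n) * sqrt(t^2 / (n-2+t^2))`` with
    ``t = t_{alpha/(2n), n-2}`` (upper quantile).
    """
    if n < 3:
        raise ValueError("Grubbs test requires n >= 3")
    t = stats.t.isf(alpha / (2.0 * n), n - 2)
    return (n - 1) / np.sqrt(n) * np.sqrt(t * t / (n - 2 + t * t))


def reject_outlier_decays(
    decays: Sequence[DecayHistogram], alpha: float = 0.05
) -> tuple[list[DecayHistogram], list[GrubbsRejection]]:
    """Iteratively remove decays whose total photons are Grubbs outliers.

    At each iteration the single most extreme total (two-sided) is tested at
    significance ``alpha`` and removed if G exceeds the critical value;
    iteration stops at the first non-rejection or once fewer than 3 decays
    remain.  Input order of the kept decays is preserved.

    Returns the kept decays and a log of rejections (original indices).
    """
    decays = list(decays)
    if len(decays) < 3:
        warnings.warn(
            "Grubbs rejection needs >= 3 decays; passing all through",
            FewDecaysWarning,
            stacklevel=2,
        )
        return decays, []

    totals = np.array([total_photons(d) for d in decays])
    alive = list(range(len(decays)))
    log: list[GrubbsRejection] = []
    while len(alive) >= 3:
        x = totals[alive]
        mean = x.mean()
        sd = x.std(ddof=1)
        if sd == 0:
            break
        dev = np.abs(x - mean)
        j = int(np.argmax(dev))
        g = dev[j] / sd
        g_crit = grubbs_critical_value(len(alive), alpha)
        if g > g_crit:
            log.append(GrubbsRejection(alive[j], float(x[j]), float(g), g_crit))
            del alive[j]
        else:
            break
    return [decays[i] for i in alive], log


def average_decays(decays: Sequence[DecayHistogram]) -> DecayHistogram:
    """Bin-wise arithmetic mean of repetition decays (identical bin grids)."""
    decays = list(decays)
    if not decays:
        raise DegenerateInputError("no decays to average")
    t0 = decays[0].t
    for d in decays[1:]:
        if d.t.shape != t0.shape or not np.allclose(d.t, t0, rtol=0, atol=1e-9):
            raise DegenerateInputError("mismatched bin grids")
    mean = np.mean([d.counts for d in decays], axis=0)
    return DecayHistogram(t=t0.copy(), counts=mean, protocol=decays[0].protocol)


def _monoexp(t: np.ndarray, a: float, tau: float, c: float) -> np.ndarray:
    return a * np.exp(-t / tau) + c


def fit_lifetime(
    mean_decay: DecayHistogram,
    window_start_us: float = 5.0,
    calib: Optional[CalibrationParams] = None,
    weighted: bool = False,
    clamp_negative_po2: bool = False,
) -> FitResult:
    """Fit A*exp(-t/tau)+C to a mean decay over bins with t >= window_start_us.

    The first ``window_start_us`` (default 5 µs) of the decay are discarded,
    leaving 285 µs under the default protocol.  Initialization: C0 from the
    mean of the last 10% of bins, tau0 from the log-slope of the
    background-subtracted first half of the window, A0 from the first window
    bin.  Optionally Poisson-weighted (weights 1/max(counts, 1)); default
    unweighted.  If ``calib`` is given, the fitted tau is also converted to
    pO2.

    A decay with zero dynamic range raises :class:`DegenerateInputError`;
    optimizer failure returns a flagged (``converged=False``) result, never a
    silent value.
    """
    sel = mean_decay.t >= window_start_us
    t = mean_decay.t[sel]
    y = mean_decay.counts[sel]
    if t.size < 4:
        raise DegenerateInputError("fit window contains fewer than 4 bins")
    if np.ptp(y) <= 0:
        raise DegenerateInputError("decay has zero dynamic range in the window")

    n_tail = max(1, int(round(0.1 * y.size)))
    c0 = float(np.mean(y[-n_tail:]))
    a0 = max(float(y[0] - c0), 1e-12)
    half = slice(0, y.size // 2)
    pos = y[half] - c0 > 0
    if pos.sum() >= 2:
        th, yh = t[half][pos], np.log(y[half][pos] - c0)
        slope = np.polyfit(th, yh, 1)[0]
        tau_init = -1.0 / slope if slope < 0 else 0.25 * (t[-1] - t[0])
    else:
        tau_init = 0.25 * (t[-1] - t[0])
    tau_init = float(np.clip(tau_init, 1e-3, 10 * (t[-1] - t[0])))

    sigma = np.sqrt(np.maximum(y, 1.0)) if weighted else None
    try:
        popt, _ = optimize.curve_fit(
            _monoexp,
            t,
            y,
            p0=[a0, tau_init, c0],
            sigma=sigma,
            bounds=([0.0, 1e-6, -np.inf], [np.inf, np.inf, np.inf]),
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
            max_nfev=20000,
        )
    except RuntimeError as exc:  # non-convergence: flagged, never silent
        return FitResult(
            amplitude=np.nan,
            tau_us=np.nan,
            offset=np.nan,
            residual_norm=np.nan,
            converged=False,
            message=str(exc),
        )
    a, tau, c = (float(v) for v in popt)
    resid = float(np.linalg.norm(y - _monoexp(t, a, tau, c)))
    po2 = None
    if calib is not None:
        po2 = lifetime_to_po2(tau, calib, clamp_negative=clamp_negative_po2)
    return FitResult(
        amplitude=a, tau_us=tau, offset=c, residual_norm=resid, po2_mmhg=po2
    )


def fit_location(
    decays: Sequence[DecayHistogram],
    calib: CalibrationParams,
    window_start_us: float = 5.0,
    grubbs_alpha: float = 0.05,
    weighted: bool = False,
    clamp_negative_po2: bool = True,
) -> tuple[FitResult, list[GrubbsRejection]]:
    """Full per-location chain: Grubbs screen -> average -> fit -> pO2.

    Rejection happens strictly before averaging.  Returns the fit (with
    ``n_kept`` filled in) and the rejection log.
    """
    kept, log = reject_outlier_decays(decays, alpha=grubbs_alpha)
    mean = average_decays(kept)
    result = fit_lifetime(
        mean,
        window_start_us=window_start_us,
        calib=calib,
        weighted=weighted,
        clamp_negative_po2=clamp_negative_po2,
    )
    return replace(result, n_kept=len(kept)), log


def lifetime_to_po2(
    tau_us: float,
    calib: CalibrationParams,
    clamp_negative: bool = False,
    rtol: float = 1e-6,
) -> float:
    """Invert the Stern-Volmer relation: pO2 = (1/tau - 1/tau0) / kq.

    A lifetime exceeding tau0 beyond relative tolerance ``rtol`` violates the
    calibration and raises :class:`CalibrationError` unless
    ``clamp_negative`` maps it to 0 mmHg.
    """
    if not np.isfinite(tau_us) or tau_us <= 0:
        raise CalibrationError(f"invalid lifetime {tau_us!r}")
    po2 = (1.0 / tau_us - 1.0 / calib.tau0_us) / calib.kq_per_us_mmhg
    if po2 < 0:
        if tau_us <= calib.tau0_us * (1 + rtol) or clamp_negative:
            return 0.0
        raise CalibrationError(
            f"tau = {tau_us:.4g} us exceeds tau0 = {calib.tau0_us:.4g} us"
        )
    return float(po2)


def po2_to_lifetime(po2_mmhg: float, calib: CalibrationParams) -> float:
    """Stern-Volmer forward model: tau = 1 / (1/tau0 + kq * pO2)."""
    po2 = np.asarray(po2_mmhg, dtype=float)
    if np.any(~np.isfinite(po2)) or np.any(po2 < 0):
        raise CalibrationError("pO2 must be finite and >= 0")
    tau = 1.0 / (1.0 / calib.tau0_us + calib.kq_per_us_mmhg * po2)
    return float(tau) if np.isscalar(po2_mmhg) else tau
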