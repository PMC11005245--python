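"""Acquisition protocol and probe calibration parameters.

The pointwise PLIM protocol interleaves a short excitation gate with a long
photon-collection gate; one excitation/collection pair is a *cycle*.  A
*repetition* accumulates a TCSPC histogram over ``n_cycles`` cycles, and each
intravascular location is measured ``n_repetitions`` times.  The per-cycle
photon sums of a single repetition double as one sample each of the RBC-flux
intensity trace.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigError

__all__ = ["AcquisitionProtocol", "CalibrationParams"]


@dataclass(frozen=True)
class AcquisitionProtocol:
    """Timing of a pointwise PLIM acquisition.

    Defaults follow the standard awake-mouse protocol: a 10 µs excitation
    gate followed by 290 µs of TCSPC collection (300 µs cycle), 2000 cycles
    per repetition (0.6 s) and 20 repetitions per location.

    Parameters
    ----------
    excitation_us : float
        Duration of the excitation gate (µs).
    collection_us : float
        Duration of the photon-collection gate (µs).
    n_cycles : int
        Cycles accumulated into one TCSPC histogram / intensity trace.
    n_repetitions : int
        Repetitions (decays) acquired per intravascular location.
    bin_width_us : float
        TCSPC histogram bin width (µs).  Must divide ``collection_us``.
    """

    excitation_us: float = 10.0
    collection_us: float = 290.0
    n_cycles: int = 2000
    n_repetitions: int = 20
    bin_width_us: float = 1.0

    def __post_init__(self) -> None:
        if self.excitation_us <= 0 or self.collection_us <= 0:
            raise ConfigError("excitation_us and collection_us must be positive")
        if self.n_cycles < 1 or self.n_repetitions < 1:
            raise ConfigError("n_cycles and n_repetitions must be >= 1")
        if self.bin_width_us <= 0:
            raise ConfigError("bin_width_us must be positive")
        ratio = self.collection_us / self.bin_width_us
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigError(
                "collection_us must be an integer multiple of bin_width_us"
            )

    @property
    def cycle_us(self) -> float:
        """Cycle period: excitation + collection (µs)."""
        return self.excitation_us + self.collection_us

    @property
    def trace_duration_s(self) -> float:
        """Duration of one repetition = one intensity trace (s)."""
        return self.n_cycles * self.cycle_us * 1e-6

    @property
    def sample_dt_s(self) -> float:
        """Intensity-trace sampling interval = one cycle (s)."""
        return self.cycle_us * 1e-6

    @property
    def n_bins(self) -> int:
        """Number of TCSPC histogram bins per decay."""
        return int(round(self.collection_us / self.bin_width_us))

    def bin_times_us(self) -> np.ndarray:
        """Bin-start times relative to the end of the excitation gate (µs)."""
        return np.arange(self.n_bins, dtype=float) * self.bin_width_us


@dataclass(frozen=True)
class CalibrationParams:
    """Phosphorescent-probe and hemoglobin calibration constants.

    Lifetime-to-pO2 conversion uses the Stern-Volmer form
    ``1/tau = 1/tau0 + kq * pO2``; pO2-to-SO2 uses the Hill equation with
    murine coefficients (h = 2.59, P50 = 40.2 mmHg).  ``tau0`` and ``kq``
    are probe- and temperature-specific (objective heated to ~36.6 °C);
    the defaults place tau between roughly 40 µs (0 mmHg) and 15 µs
    (150 mmHg).

    Parameters
    ----------
    tau0_us : float
        Phosphorescence lifetime at zero oxygen (µs).
    kq_per_us_mmhg : float
        Collisional quenching rate constant (1/(µs·mmHg)).
    hill_h : float
        Hill exponent (dimensionless).
    hill_p50_mmhg : float
        pO2 at 50% hemoglobin saturation (mmHg).
    temperature_c : float
        Calibration temperature (°C); informational.
    """

    tau0_us: float = 40.0
    kq_per_us_mmhg: float = 2.78e-4
    hill_h: float = 2.59
    hill_p50_mmhg: float = 40.2
    temperature_c: float = 36.6

    def __post_init__(self) -> None:
        if self.tau0_us <= 0 or self.kq_per_us_mmhg <= 0:
            raise ConfigError("tau0_us and kq_per_us_mmhg must be positive")
        if self.hill_h <= 0 or self.hill_p50_mmhg <= 0:
            raise ConfigError("hill_h and hill_p50_mmhg must be positive")
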