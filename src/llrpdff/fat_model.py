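"""Chemical-shift signal model for multi-echo gradient-echo water-fat imaging.

The acquired complex signal of a voxel containing water and fat at echo time
``TE_n`` is modelled as

    M_n = (M_w + C_n * M_f) * exp(-R2* . TE_n) * E_n

where ``C_n`` is the complex fat dephasing coefficient of a pre-calibrated
multi-peak fat spectrum, ``R2*`` a single effective relaxation rate for the
mixture and ``E_n`` a unit-magnitude phasor collecting system phase errors.
Taking magnitudes removes ``E_n``, which is what the magnitude fitting stage
relies on.  The proton density fat fraction is ``PDFF = M_f / (M_f + M_w)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path

import numpy as np

from .constants import (
    GAMMA_MHZ_PER_T,
    REFERENCE_TEMPERATURE_C,
    WATER_SHIFT_PPM_PER_DEGC,
)

__all__ = [
    "FatSpectrum",
    "EchoTrain",
    "VoxelSignalParams",
    "MultiEchoImage",
    "fat_coefficients",
    "forward_signal",
    "pdff",
    "temperature_correct",
    "water_fat_separation_hz",
]

_NORM_TOL = 1e-9


@dataclass(frozen=True)
class FatSpectrum:
    """Multi-peak fat resonance model.

    Parameters
    ----------
    shifts_ppm:
        Chemical shift of each peak relative to water, in ppm.  Peaks upfield
        of water (the bulk of the triglyceride spectrum, e.g. methylene at
        -3.40 ppm) carry negative values.
    amplitudes:
        Relative peak amplitudes; must be non-negative and sum to one.
    reference_temperature:
        Temperature (C) at which the shifts are calibrated.
    """

    shifts_ppm: np.ndarray
    amplitudes: np.ndarray
    reference_temperature: float = REFERENCE_TEMPERATURE_C

    def __post_init__(self) -> None:
        shifts = np.atleast_1d(np.asarray(self.shifts_ppm, dtype=float))
        amps = np.atleast_1d(np.asarray(self.amplitudes, dtype=float))
        object.__setattr__(self, "shifts_ppm", shifts)
        object.__setattr__(self, "amplitudes", amps)
        if shifts.ndim != 1 or amps.shape != shifts.shape or shifts.size < 1:
            raise ValueError("spectrum needs matching 1D shift/amplitude lists")
        if np.any(amps < 0):
            raise ValueError("peak amplitudes must be non-negative")
        if abs(amps.sum() - 1.0) > _NORM_TOL:
            raise ValueError(
                f"peak amplitudes must sum to 1 (got {amps.sum():.12f})"
            )

    @property
    def n_peaks(self) -> int:
        return int(self.shifts_ppm.size)

    @property
    def main_peak_ppm(self) -> float:
        """Shift of the dominant (largest-amplitude) peak, ppm."""
        return float(self.shifts_ppm[int(np.argmax(self.amplitudes))])

    def frequencies_hz(self, field_strength: float) -> np.ndarray:
        """Peak frequency offsets from water in Hz at ``field_strength`` (T)."""
        return self.shifts_ppm * GAMMA_MHZ_PER_T * field_strength

    @classmethod
    def single_peak(cls, shift_ppm: float = -3.40) -> "FatSpectrum":
        """Main-methylene-peak-only model."""
        return cls(np.array([shift_ppm]), np.array([1.0]))

    @classmethod
    def nine_peak_liver(cls) -> "FatSpectrum":
        """The packaged nine-peak liver triglyceride model."""
        ref = resources.files("llrpdff.data").joinpath("nine_peak_liver.tsv")
        with resources.as_file(ref) as path:
            return cls.from_table(path)

    @classmethod
    def from_table(cls, path: str | Path) -> "FatSpectrum":
        """Read a spectrum from a two-column (ppm, amplitude) text table.

        A header comment line ``# reference_temperature_celsius: <T>`` sets
        the calibration temperature (default 37 C).
        """
        ref_t = REFERENCE_TEMPERATURE_C
        rows = []
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "reference_temperature_celsius" in line:
                    ref_t = float(line.split(":")[-1])
                continue
            cols = line.split()
            rows.append((float(cols[0]), float(cols[1])))
        shifts, amps = (np.array(c) for c in zip(*rows))
        return cls(shifts, amps, reference_temperature=ref_t)


@dataclass(frozen=True)
class EchoTrain:
    """Echo times (s) of a multi-echo acquisition plus field strength (T)."""

    echo_times: np.ndarray
    field_strength: float
    repetition_time: float | None = None

    def __post_init__(self) -> None:
        te = np.atleast_1d(np.asarray(self.echo_times, dtype=float))
        object.__setattr__(self, "echo_times", te)
        if te.size < 1 or np.any(te <= 0):
            raise ValueError("echo times must be positive")
        if np.any(np.diff(te) <= 0):
            raise ValueError("echo times must be strictly increasing")
        if self.field_strength <= 0:
            raise ValueError("field strength must be positive")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times.size)

    @classmethod
    def from_ms(
        cls,
        echo_times_ms,
        field_strength: float,
        repetition_time_ms: float | None = None,
    ) -> "EchoTrain":
        tr = None if repetition_time_ms is None else repetition_time_ms * 1e-3
        return cls(np.asarray(echo_times_ms, float) * 1e-3, field_strength, tr)


@dataclass(frozen=True)
class VoxelSignalParams:
    """Water/fat amplitudes, effective relaxation rate and phase errors."""

    water_amplitude: float
    fat_amplitude: float
    relaxation_rate: float = 0.0
    phase_errors: np.ndarray | None = None  # unit-magnitude, one per echo

    def __post_init__(self) -> None:
        if self.water_amplitude < 0 or self.fat_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.relaxation_rate < 0:
            raise ValueError("relaxation rate must be non-negative")
        if self.phase_errors is not None:
            e = np.atleast_1d(np.asarray(self.phase_errors, complex))
            if not np.allclose(np.abs(e), 1.0, atol=1e-9):
                raise ValueError("phase errors must be unit-magnitude phasors")
            object.__setattr__(self, "phase_errors", e)


@dataclass
class MultiEchoImage:
    """Complex echo-image stack shaped (echo, z, y, x) with timing attached."""

    data: np.ndarray
    echoes: EchoTrain

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 4:
            raise ValueError("expected (echo, z, y, x) array")
        if self.data.shape[0] != self.echoes.n_echoes:
            raise ValueError("echo axis does not match the echo train")

    @property
    def shape(self) -> tuple:
        return self.data.shape


def fat_coefficients(spectrum: FatSpectrum, echoes: EchoTrain) -> np.ndarray:
    """Complex fat dephasing coefficient per echo.

    ``C_n = sum_i w_i * exp(2j*pi * df_i * TE_n)`` with ``df_i`` the peak
    offsets from water in Hz.  ``|C_n| <= 1`` always; ``C = 1`` at ``TE = 0``.
    """
    freqs = spectrum.frequencies_hz(echoes.field_strength)  # (m,)
    phase = 2.0j * np.pi * np.outer(echoes.echo_times, freqs)  # (E, m)
    return np.exp(phase) @ spectrum.amplitudes.astype(complex)


def fat_coefficients_at(
    spectrum: FatSpectrum, echo_times_s: np.ndarray, field_strength: float
) -> np.ndarray:
    """``fat_coefficients`` for an arbitrary (possibly dense) TE grid."""
    freqs = spectrum.frequencies_hz(field_strength)
    te = np.atleast_1d(np.asarray(echo_times_s, float))
    return np.exp(2.0j * np.pi * np.outer(te, freqs)) @ spectrum.amplitudes.astype(
        complex
    )


def forward_signal(
    params: VoxelSignalParams,
    coeffs: np.ndarray,
    echoes: EchoTrain,
    magnitude: bool = False,
) -> np.ndarray:
    """Per-echo voxel signal ``(M_w + C_n M_f) exp(-R2* TE_n) E_n``.

    With ``magnitude=True`` returns ``|M_w + C_n M_f| exp(-R2* TE_n)`` (the
    phase-error phasor drops out of the magnitude).
    """
    coeffs = np.asarray(coeffs)
    if coeffs.shape != (echoes.n_echoes,):
        raise ValueError("coefficient count does not match the echo train")
    decay = np.exp(-params.relaxation_rate * echoes.echo_times)
    core = (params.water_amplitude + coeffs * params.fat_amplitude) * decay
    if magnitude:
        return np.abs(core)
    if params.phase_errors is not None:
        if params.phase_errors.shape != coeffs.shape:
            raise ValueError("phase-error count does not match the echo train")
        core = core * params.phase_errors
    return core


def pdff(water_amplitude, fat_amplitude):
    """Proton density fat fraction in percent, ``100 * M_f / (M_f + M_w)``.

    Accepts scalars or arrays.  Voxels where both amplitudes are zero are
    undefined and returned as NaN (a flagged missing value).
    """
    mw = np.asarray(water_amplitude, dtype=float)
    mf = np.asarray(fat_amplitude, dtype=float)
    if np.any(mw < 0) or np.any(mf < 0):
        raise ValueError("amplitudes must be non-negative")
    total = mw + mf
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, 100.0 * mf / np.where(total > 0, total, 1.0), np.nan)
    if out.ndim == 0:
        return float(out) if total > 0 else float("nan")
    return out


def temperature_correct(spectrum: FatSpectrum, temperature: float) -> FatSpectrum:
    """Adjust water-relative shifts for the temperature of the sample.

    Only the water reference moves with temperature (-0.01 ppm/C from 37 C);
    the fat resonances are temperature-stable, so each water-relative shift
    changes by ``-(T - 37) * (-0.01)`` ppm.  Below body temperature the
    apparent water-fat separation therefore increases (e.g. at 22 C the main
    peak moves from -3.40 to -3.55 ppm).  Amplitudes are unchanged.
    """
    if not (0.0 <= temperature <= 45.0):
        raise ValueError("temperature outside the plausible 0-45 C range")
    delta_water = (temperature - spectrum.reference_temperature) * (
        WATER_SHIFT_PPM_PER_DEGC
    )
    return replace(
        spectrum,
        shifts_ppm=spectrum.shifts_ppm - delta_water,
        reference_temperature=temperature,
    )


def water_fat_separation_hz(
    spectrum: FatSpectrum, field_strength: float
) -> float:
    """Absolute water to main-fat-peak frequency separation in Hz."""
    return abs(spectrum.main_peak_ppm) * GAMMA_MHZ_PER_T * field_strength
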