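"""Signal conditioning: log10 + full-scale contrast stretch, SNR-defined noise,
and polar-angle cropping.

The stretch maps ``log10(I)`` affinely onto [0, 255] (floating point, not
quantized); it is invariant to any positive rescaling of the raw intensities.
Noise is zero-mean white Gaussian with variance set from the mean signal power
``S = sum(I_tilde**2) / (181*361)`` and the requested SNR in dB; noisy values
are deliberately left unclipped so the realized SNR matches the definition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DataError, DegenerateSignalError, ParameterError
from .forward_scattering import N_PHI, N_THETA, PHI_DEG, THETA_DEG, ScatteringSignal

__all__ = [
    "ProcessedSignal",
    "log_contrast_stretch",
    "mean_signal_power",
    "add_white_gaussian_noise",
    "crop_polar_range",
    "write_processed",
    "read_processed",
    "export_png",
]

FULL_SCALE = 255.0


@dataclass
class ProcessedSignal:
    """Contrast-stretched, image-like map I_tilde(theta, phi)."""

    values: np.ndarray
    provenance: ScatteringSignal | None = None
    noise_snr_db: float | None = None
    log_min: float | None = None  # affine stretch parameters, for inversion
    log_max: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (N_THETA, N_PHI):
            raise DataError(
                f"processed signal must be {N_THETA}x{N_PHI}, got {self.values.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("processed signal must be finite")

    @property
    def theta_deg(self) -> np.ndarray:
        return THETA_DEG

    @property
    def phi_deg(self) -> np.ndarray:
        return PHI_DEG


def log_contrast_stretch(signal: ScatteringSignal) -> ProcessedSignal:
    """Map ``log10(I)`` onto the full [0, 255] scale.

    Exact zeros are guarded by ``eps = (smallest positive intensity) * 1e-3``
    before the log.  Output minimum is exactly 0 and maximum exactly 255.
    """
    intensity = signal.intensity
    positive = intensity[intensity > 0]
    if positive.size == 0:
        raise DegenerateSignalError("all-zero intensity cannot be stretched")
    eps = positive.min() * 1e-3
    log_i = np.log10(np.maximum(intensity, eps))
    lmin, lmax = log_i.min(), log_i.max()
    if lmax == lmin:
        raise DegenerateSignalError("constant intensity cannot be stretched")
    stretched = FULL_SCALE * (log_i - lmin) / (lmax - lmin)
    return ProcessedSignal(
        values=stretched,
        provenance=signal,
        log_min=float(lmin),
        log_max=float(lmax),
    )


def mean_signal_power(values: np.ndarray | ProcessedSignal) -> float:
    """Average signal power: mean of squared values over all 181x361 samples."""
    if isinstance(values, ProcessedSignal):
        values = values.values
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (N_THETA, N_PHI):
        raise DataError(f"expected {N_THETA}x{N_PHI}, got {values.shape}")
    return float(np.mean(values**2))


def add_white_gaussian_noise(
    processed: ProcessedSignal, snr_db: float, seed: int
) -> ProcessedSignal:
    """Add i.i.d. zero-mean Gaussian noise at the requested SNR (dB).

    Noise variance is ``S * 10**(-snr_db/10)`` where ``S`` is the mean signal
    power.  ``snr_db = inf`` is the noise-disabled sentinel.  Output is not
    clipped to [0, 255].
    """
    if np.isnan(snr_db):
        raise ParameterError("snr_db must not be NaN")
    if np.isposinf(snr_db):
        return ProcessedSignal(
            values=processed.values.copy(),
            provenance=processed.provenance,
            noise_snr_db=None,
            log_min=processed.log_min,
            log_max=processed.log_max,
        )
    s_power = mean_signal_power(processed.values)
    if s_power == 0.0:
        raise DegenerateSignalError("zero-power signal: SNR undefined")
    sigma = np.sqrt(s_power * 10.0 ** (-snr_db / 10.0))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, sigma, size=processed.values.shape)
    return ProcessedSignal(
        values=processed.values + noise,
        provenance=processed.provenance,
        noise_snr_db=float(snr_db),
        log_min=processed.log_min,
        log_max=processed.log_max,
    )


def crop_polar_range(
    values: np.ndarray | ProcessedSignal, theta_min_deg: int, theta_max_deg: int
) -> np.ndarray:
    """Rows ``theta_min..theta_max`` inclusive, all phi columns.

    Bounds must satisfy ``0 <= theta_min < theta_max <= 180``.
    """
    if isinstance(values, ProcessedSignal):
        values = values.values
    values = np.asarray(values)
    if values.ndim != 2 or values.shape[0] != N_THETA:
        raise DataError(f"expected {N_THETA} polar rows, got shape {values.shape}")
    tmin, tmax = int(theta_min_deg), int(theta_max_deg)
    if not (0 <= tmin < tmax <= 180):
        raise ParameterError(
            f"require 0 <= theta_min < theta_max <= 180, got ({theta_min_deg}, {theta_max_deg})"
        )
    return values[tmin : tmax + 1, :]


# ---------------------------------------------------------------------------
# persistence / export
# ---------------------------------------------------------------------------

def write_processed(processed: ProcessedSignal, path) -> None:
    """HDF5 persistence (dataset ``values`` + stretch/noise attributes)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("values", data=processed.values, dtype=np.float64)
        if processed.noise_snr_db is not None:
            f.attrs["noise_snr_db"] = processed.noise_snr_db
        if processed.log_min is not None:
            f.attrs["log_min"] = processed.log_min
            f.attrs["log_max"] = processed.log_max


def read_processed(path) -> ProcessedSignal:
    import h5py

    with h5py.File(path, "r") as f:
        values = np.asarray(f["values"], dtype=np.float64)
        attrs = dict(f.attrs)
    return ProcessedSignal(
        values=values,
        noise_snr_db=float(attrs["noise_snr_db"]) if "noise_snr_db" in attrs else None,
        log_min=float(attrs["log_min"]) if "log_min" in attrs else None,
        log_max=float(attrs["log_max"]) if "log_max" in attrs else None,
    )


def export_png(processed: ProcessedSignal, path) -> None:
    """8-bit grayscale export, row 0 = theta 0 at the top (visualization only:
    values are clipped to [0, 255] and quantized here, nowhere else)."""
    from PIL import Image

    quantized = np.clip(np.round(processed.values), 0, 255).astype(np.uint8)
    Image.fromarray(quantized, mode="L").save(path)
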