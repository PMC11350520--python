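"""First-order Born far-field computation of 181x361 angle-resolved intensity maps.

The forward model is a single-scattering surrogate: the far-field amplitude is
the 3D Fourier transform of the scattering potential
``k0**2 (n(r)**2 - n_cyto**2) / (4 pi)`` evaluated on the Ewald sphere
``q = k (s_hat(theta, phi) - z_hat)`` with ``k = 2 pi n_cyto / lambda``, and the
intensity carries the dipole polarization factor
``P = cos^2(theta) cos^2(phi) + sin^2(phi)`` for incident polarization along
the phi = 0 reference direction.  Amplitudes are obtained by zero-padded FFT
and trilinear interpolation.  Units are arbitrary (downstream conditioning is
scale-invariant).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from scipy import fft as sp_fft
from scipy.ndimage import map_coordinates

from .errors import DataError, FormatError, ParameterError, ResolutionError
from .nucleus_models import NucleusSpec, RIVolume

__all__ = [
    "ScatteringSignal",
    "born_far_field",
    "polarization_factor",
    "write_signal",
    "read_signal",
    "signal_from_matrix",
    "THETA_DEG",
    "PHI_DEG",
]

THETA_DEG = np.arange(181)
PHI_DEG = np.arange(361)

N_THETA = 181
N_PHI = 361

SOURCE_BORN = "born_surrogate"
SOURCE_EXTERNAL = "external"


@dataclass
class ScatteringSignal:
    """Raw far-field intensity map I(theta, phi) on the fixed 181x361 grid."""

    intensity: np.ndarray
    wavelength_nm: float
    source: str = SOURCE_BORN
    spec: NucleusSpec | None = None

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=np.float64)
        if self.intensity.shape != (N_THETA, N_PHI):
            raise DataError(
                f"intensity must be {N_THETA}x{N_PHI}, got {self.intensity.shape}"
            )
        if not np.all(np.isfinite(self.intensity)):
            raise DataError("intensity must be finite")
        if np.any(self.intensity < 0):
            raise DataError("intensity must be non-negative")
        if not np.array_equal(self.intensity[:, 0], self.intensity[:, -1]):
            raise DataError("columns phi=0 and phi=360 must be identical")
        if self.wavelength_nm <= 0:
            raise ParameterError("wavelength_nm must be > 0")
        if self.source not in (SOURCE_BORN, SOURCE_EXTERNAL):
            raise ParameterError(f"unknown source {self.source!r}")

    @property
    def theta_deg(self) -> np.ndarray:
        return THETA_DEG

    @property
    def phi_deg(self) -> np.ndarray:
        return PHI_DEG


def polarization_factor(theta_rad: np.ndarray, phi_rad: np.ndarray) -> np.ndarray:
    """Dipole factor ``cos^2(theta) cos^2(phi) + sin^2(phi)``, broadcast to a map."""
    ct2 = np.cos(theta_rad)[:, None] ** 2
    cp2 = np.cos(phi_rad)[None, :] ** 2
    sp2 = np.sin(phi_rad)[None, :] ** 2
    return ct2 * cp2 + sp2


def _scattering_vectors(k: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Momentum-transfer components q = k (s_hat - z_hat) on the angle grid.

    phi is sampled 0..359 only; column 360 is copied from column 0 afterwards
    so azimuthal periodicity is exact by construction.
    """
    theta = np.deg2rad(THETA_DEG.astype(np.float64))
    phi = np.deg2rad(np.arange(360, dtype=np.float64))
    st = np.sin(theta)[:, None]
    qx = k * st * np.cos(phi)[None, :]
    qy = k * st * np.sin(phi)[None, :]
    qz = k * (np.cos(theta)[:, None] - 1.0) * np.ones_like(phi)[None, :]
    return qx, qy, qz


def born_far_field(
    volume: RIVolume,
    wavelength_nm: float = 800.0,
    pad_factor: int = 2,
    interp_order: int = 3,
) -> ScatteringSignal:
    """Compute the Born-approximation far-field intensity map of a phantom.

    The scattering potential is referenced to the cytoplasm index, so a
    homogeneous nucleus still scatters.  The potential is zero-padded by
    ``pad_factor`` per axis, FFT'd, and the complex amplitude is interpolated
    onto the Ewald sphere before squaring.  ``interp_order=1`` is trilinear;
    the default cubic spline is needed because the amplitude oscillates on a
    scale of only a few k-grid samples for micron-sized bodies.
    """
    if wavelength_nm <= 0:
        raise ParameterError("wavelength_nm must be > 0")
    if pad_factor < 1:
        raise ParameterError("pad_factor must be >= 1")
    if interp_order not in (1, 3):
        raise ParameterError("interp_order must be 1 (trilinear) or 3 (cubic)")
    if not np.all(np.isfinite(volume.values)):
        raise DataError("volume contains non-finite values")
    voxel = volume.voxel_um
    wavelength_um = wavelength_nm * 1e-3
    n_cyto = volume.spec.n_cyto if volume.spec is not None else float(
        np.min(volume.values)
    )
    k = 2.0 * np.pi * n_cyto / wavelength_um
    if 2.0 * k > np.pi / voxel:
        raise ResolutionError(
            f"voxel {voxel} um cannot sample momentum transfer 2k = {2 * k:.3f} "
            f"rad/um (Nyquist limit {np.pi / voxel:.3f} rad/um)"
        )

    k0 = 2.0 * np.pi / wavelength_um  # vacuum wavenumber
    potential = (k0**2 / (4.0 * np.pi)) * (
        volume.values.astype(np.float64) ** 2 - n_cyto**2
    )

    padded_shape = tuple(pad_factor * n for n in potential.shape)
    padded = np.zeros(padded_shape, dtype=np.complex64)
    start = [(p - n) // 2 for p, n in zip(padded_shape, potential.shape)]
    sl = tuple(slice(s, s + n) for s, n in zip(start, potential.shape))
    padded[sl] = potential
    # center the object at the origin (wrapped) so the spectral phase is smooth
    padded = np.fft.ifftshift(padded)
    amplitude = np.fft.fftshift(sp_fft.fftn(padded, overwrite_x=True))
    amplitude *= np.complex64(voxel**3)

    axes = [
        np.fft.fftshift(2.0 * np.pi * np.fft.fftfreq(n, d=voxel))
        for n in padded_shape
    ]
    qx, qy, qz = _scattering_vectors(k)
    # fractional grid indices of the Ewald-sphere points (axes are uniform)
    coords = np.stack(
        [
            (q - ax[0]) / (ax[1] - ax[0])
            for q, ax in zip((qx.ravel(), qy.ravel(), qz.ravel()), axes)
        ]
    )
    a_q = map_coordinates(amplitude, coords, order=interp_order,
                          mode="constant", cval=0.0).reshape(N_THETA, 360)

    theta = np.deg2rad(THETA_DEG.astype(np.float64))
    phi = np.deg2rad(np.arange(360, dtype=np.float64))
    intensity = np.abs(a_q) ** 2 * polarization_factor(theta, phi)

    full = np.empty((N_THETA, N_PHI), dtype=np.float64)
    full[:, :360] = intensity
    full[:, 360] = intensity[:, 0]
    return ScatteringSignal(
        intensity=full,
        wavelength_nm=wavelength_nm,
        source=SOURCE_BORN,
        spec=volume.spec,
    )


# ---------------------------------------------------------------------------
# signal I/O
# ---------------------------------------------------------------------------

def signal_from_matrix(
    matrix: np.ndarray,
    wavelength_nm: float = 800.0,
    source: str = SOURCE_EXTERNAL,
) -> ScatteringSignal:
    """Wrap an externally computed 181x361 intensity matrix (e.g. FDTD output)."""
    matrix = np.asarray(matrix, dtype=np.float64)
    if matrix.shape != (N_THETA, N_PHI):
        raise FormatError(
            f"expected a {N_THETA}x{N_PHI} matrix, got {matrix.shape}"
        )
    if not np.array_equal(matrix[:, 0], matrix[:, -1]):
        matrix = matrix.copy()
        matrix[:, -1] = matrix[:, 0]
    return ScatteringSignal(intensity=matrix, wavelength_nm=wavelength_nm, source=source)


def write_signal(signal: ScatteringSignal, path: str | Path) -> None:
    """Write a signal as HDF5 (``.h5``) or as a CSV matrix (``.csv``).

    HDF5 is lossless for metadata; the CSV dialect is one header row of phi
    values followed by 181 rows x 361 columns of intensities.
    """
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("intensity", data=signal.intensity, dtype=np.float64)
            f.attrs["wavelength_nm"] = signal.wavelength_nm
            f.attrs["source"] = signal.source
            if signal.spec is not None:
                f.attrs["spec_shape"] = signal.spec.shape
                f.attrs["spec_corr_length_um"] = signal.spec.corr_length_um
                f.attrs["spec_fluct_std"] = signal.spec.fluct_std
                f.attrs["spec_seed"] = signal.spec.seed
    elif path.suffix.lower() == ".csv":
        header = ",".join(str(p) for p in PHI_DEG)
        np.savetxt(path, signal.intensity, delimiter=",", header=header, comments="")
    else:
        raise FormatError(f"unsupported signal format: {path.suffix!r}")


def read_signal(path: str | Path, wavelength_nm: float = 800.0) -> ScatteringSignal:
    """Read a signal from HDF5 or CSV; CSV inputs become ``source='external'``."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "intensity" not in f:
                raise FormatError(f"{path}: missing 'intensity' dataset")
            intensity = np.asarray(f["intensity"], dtype=np.float64)
            meta = dict(f.attrs)
        if intensity.shape != (N_THETA, N_PHI):
            raise FormatError(
                f"{path}: expected {N_THETA}x{N_PHI}, got {intensity.shape}"
            )
        return ScatteringSignal(
            intensity=intensity,
            wavelength_nm=float(meta.get("wavelength_nm", wavelength_nm)),
            source=str(meta.get("source", SOURCE_EXTERNAL)),
        )
    if path.suffix.lower() == ".csv":
        matrix = np.loadtxt(path, delimiter=",", skiprows=1)
        if matrix.ndim != 2 or matrix.shape != (N_THETA, N_PHI):
            raise FormatError(
                f"{path}: expected {N_THETA} rows x {N_PHI} columns, got "
                f"{matrix.shape if matrix.ndim == 2 else matrix.ndim}d"
            )
        if np.any(matrix < 0):
            raise DataError(f"{path}: negative intensities")
        return signal_from_matrix(matrix, wavelength_nm=wavelength_nm)
    raise FormatError(f"unsupported signal format: {path.suffix!r}")
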