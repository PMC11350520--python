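"""Voxelated nuclear phantoms with Gaussian-correlated refractive-index fluctuations.

A phantom is a 3D refractive-index field: a geometric nuclear body (sphere or
ellipsoid) embedded in homogeneous cytoplasm, with a zero-mean stationary
Gaussian random field added inside the nucleus.  The fluctuation field has the
Gaussian autocorrelation ``C(r) = fluct_std**2 * exp(-r**2 / corr_length**2)``,
so the correlation drops to ``1/e`` at one correlation length.

The masked sample mean and standard deviation are rescaled to match ``n_mean``
and ``fluct_std`` exactly, which makes both parameters crisp regression labels.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

from .errors import ContainmentError, DataError, ParameterError

__all__ = [
    "NucleusSpec",
    "RIVolume",
    "make_nucleus_mask",
    "sample_correlated_fluctuations",
    "build_ri_volume",
    "enumerate_dataset",
    "disorder_strength",
    "derive_seed",
    "save_volume",
    "load_volume",
    "volume_filename",
    "write_manifest",
]

SPHERE = "sphere"
ELLIPSOID = "ellipsoid"

#: default padding beyond the nuclear body, per axis and side [um]
DEFAULT_PADDING_UM = 1.0


def derive_seed(base_seed: int, *parts) -> int:
    """Derive a stable 63-bit child seed from a base seed and a key tuple.

    Uses SHA-256 over a canonical string representation, so the mapping is
    reproducible across platforms and Python processes (unlike ``hash()``).
    """
    key = "|".join([str(int(base_seed))] + [repr(p) for p in parts])
    digest = hashlib.sha256(key.encode("utf-8")).digest()
    return int.from_bytes(digest[:8], "big") >> 1


@dataclass(frozen=True)
class NucleusSpec:
    """Generative parameters of one nuclear phantom."""

    shape: str
    corr_length_um: float
    fluct_std: float
    radius_um: float | None = None
    semiaxes_um: tuple[float, float, float] | None = None
    n_mean: float = 1.40
    n_cyto: float = 1.36
    voxel_um: float = 0.1
    grid_shape: tuple[int, int, int] | None = None
    seed: int = 0
    padding_um: float = DEFAULT_PADDING_UM

    def __post_init__(self) -> None:
        if self.shape not in (SPHERE, ELLIPSOID):
            raise ParameterError(f"shape must be 'sphere' or 'ellipsoid', got {self.shape!r}")
        if self.shape == SPHERE:
            if self.radius_um is None:
                raise ParameterError("sphere requires radius_um")
            if self.radius_um <= 0:
                raise ParameterError("radius_um must be > 0")
        else:
            if self.semiaxes_um is None:
                raise ParameterError("ellipsoid requires semiaxes_um")
            axes = tuple(float(a) for a in self.semiaxes_um)
            if len(axes) != 3 or any(a <= 0 for a in axes):
                raise ParameterError("semiaxes_um must be three positive lengths")
            object.__setattr__(self, "semiaxes_um", axes)
        if not self.corr_length_um > 0:
            raise ParameterError("corr_length_um must be > 0")
        if self.fluct_std < 0:
            raise ParameterError("fluct_std must be >= 0")
        if not (self.n_mean > self.n_cyto > 1.0):
            raise ParameterError("require n_mean > n_cyto > 1")
        if self.voxel_um <= 0:
            raise ParameterError("voxel_um must be > 0")
        if self.voxel_um > self.corr_length_um / 2.0 + 1e-12:
            raise ParameterError(
                f"voxel_um={self.voxel_um} cannot resolve corr_length_um="
                f"{self.corr_length_um}; need voxel_um <= corr_length_um/2"
            )
        if self.grid_shape is None:
            object.__setattr__(self, "grid_shape", self._default_grid_shape())
        gs = tuple(int(n) for n in self.grid_shape)
        if len(gs) != 3 or any(n < 3 for n in gs):
            raise ParameterError("grid_shape must be three integers >= 3")
        object.__setattr__(self, "grid_shape", gs)
        for n, a in zip(gs, self.semiaxes()):
            if n * self.voxel_um < 2.0 * a + 2.0 * self.voxel_um:
                raise ContainmentError(
                    f"grid extent {n * self.voxel_um:.3f} um cannot contain a body "
                    f"of semiaxis {a} um (need >= {2 * a + 2 * self.voxel_um:.3f} um)"
                )

    def semiaxes(self) -> tuple[float, float, float]:
        """Per-axis semiaxis lengths; all equal to the radius for spheres."""
        if self.shape == SPHERE:
            r = float(self.radius_um)
            return (r, r, r)
        return self.semiaxes_um  # type: ignore[return-value]

    def _default_grid_shape(self) -> tuple[int, int, int]:
        out = []
        for a in self.semiaxes():
            extent = 2.0 * (a + self.padding_um)
            n = int(math.ceil(extent / self.voxel_um))
            out.append(n + (n % 2 == 0))  # odd, so one voxel sits at the center
        return tuple(out)

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinates per axis, centered on the grid [um]."""
        return tuple(
            (np.arange(n) - (n - 1) / 2.0) * self.voxel_um for n in self.grid_shape
        )


@dataclass
class RIVolume:
    """A voxelated 3D refractive-index field plus its nucleus mask."""

    values: np.ndarray
    mask: np.ndarray
    voxel_um: float
    spec: NucleusSpec | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape or self.values.ndim != 3:
            raise DataError("values and mask must be matching 3D arrays")
        if not np.all(np.isfinite(self.values)):
            raise DataError("refractive-index values must be finite")
        if np.any(self.values <= 1.0):
            raise DataError("refractive-index values must exceed 1")


def make_nucleus_mask(spec: NucleusSpec) -> np.ndarray:
    """Boolean mask of voxels whose centers lie inside the nuclear body.

    A voxel center ``c`` is inside iff ``sum(((c_i - center_i)/a_i)**2) <= 1``
    with the grid center as origin.
    """
    x, y, z = spec.axis_coordinates()
    a = spec.semiaxes()
    q = (
        (x[:, None, None] / a[0]) ** 2
        + (y[None, :, None] / a[1]) ** 2
        + (z[None, None, :] / a[2]) ** 2
    )
    return q <= 1.0


def _gaussian_psd(k_sq: np.ndarray, corr_length_um: float, fluct_std: float) -> np.ndarray:
    """Power spectral density of the Gaussian autocorrelation model.

    3D Fourier transform of ``fluct_std**2 * exp(-r**2/lc**2)``:
    ``S(k) = fluct_std**2 * pi**1.5 * lc**3 * exp(-k**2 lc**2 / 4)``.
    """
    lc = corr_length_um
    return fluct_std**2 * math.pi**1.5 * lc**3 * np.exp(-k_sq * lc**2 / 4.0)


def sample_correlated_fluctuations(spec: NucleusSpec) -> np.ndarray:
    """One realization of the zero-mean Gaussian fluctuation field on the full grid.

    Spectral synthesis: white Gaussian noise is filtered in frequency space by
    ``sqrt(S(k))`` (normalized by the voxel volume) and transformed back.
    Because the filter is applied to the transform of a real field, Hermitian
    symmetry holds and the output is real up to floating rounding.
    Deterministic given ``spec.seed``.
    """
    if spec.fluct_std < 0:
        raise ParameterError("fluct_std must be >= 0")
    if spec.fluct_std == 0.0:
        return np.zeros(spec.grid_shape, dtype=np.float64)
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal(spec.grid_shape)
    spectrum = np.fft.rfftn(white)
    freqs = [2.0 * np.pi * np.fft.fftfreq(n, d=spec.voxel_um) for n in spec.grid_shape]
    freqs[-1] = 2.0 * np.pi * np.fft.rfftfreq(spec.grid_shape[-1], d=spec.voxel_um)
    k_sq = (
        freqs[0][:, None, None] ** 2
        + freqs[1][None, :, None] ** 2
        + freqs[2][None, None, :] ** 2
    )
    amplitude = np.sqrt(_gaussian_psd(k_sq, spec.corr_length_um, spec.fluct_std))
    amplitude /= spec.voxel_um**1.5
    field_ = np.fft.irfftn(spectrum * amplitude, s=spec.grid_shape, axes=(0, 1, 2))
    return field_


def build_ri_volume(spec: NucleusSpec) -> RIVolume:
    """Assemble the refractive-index volume for one spec.

    Cytoplasm index everywhere; inside the mask the fluctuation field is added
    to the mean nuclear index and affinely rescaled so the masked sample mean
    equals ``n_mean`` and the masked sample standard deviation equals
    ``fluct_std`` exactly (population convention, ``ddof=0``).
    """
    mask = make_nucleus_mask(spec)
    values = np.full(spec.grid_shape, spec.n_cyto, dtype=np.float64)
    inside = sample_correlated_fluctuations(spec)[mask]
    if spec.fluct_std > 0:
        std = inside.std()
        if std == 0.0:
            raise DataError("degenerate fluctuation field: zero variance inside mask")
        inside = (inside - inside.mean()) * (spec.fluct_std / std)
    else:
        inside = np.zeros_like(inside)
    values[mask] = spec.n_mean + inside
    return RIVolume(values=values, mask=mask, voxel_um=spec.voxel_um, spec=spec)


def disorder_strength(corr_length_um: float, fluct_std: float, alpha: int = 1) -> float:
    """Lumped heterogeneity measure ``corr_length * fluct_std**alpha``."""
    if alpha not in (1, 2):
        raise ParameterError(f"alpha must be 1 or 2, got {alpha}")
    if corr_length_um < 0 or fluct_std < 0:
        raise ParameterError("inputs must be >= 0")
    return corr_length_um * fluct_std**alpha


def enumerate_dataset(
    *,
    shapes: Sequence[str] = (SPHERE, ELLIPSOID),
    corr_lengths_um: Sequence[float] | None = None,
    fluct_stds: Sequence[float] | None = None,
    pairs: Sequence[tuple[float, float]] | None = None,
    replicates: int = 3,
    base_seed: int = 0,
    radius_um: float = 4.0,
    semiaxes_um: tuple[float, float, float] = (3.0, 4.0, 5.0),
    n_mean: float = 1.40,
    n_cyto: float = 1.36,
    voxel_um: float = 0.1,
    padding_um: float = DEFAULT_PADDING_UM,
) -> list[NucleusSpec]:
    """Enumerate one spec per (shape x parameter combination x replicate).

    Either ``pairs`` gives explicit (corr_length, fluct_std) combinations, or
    the full Cartesian grid of ``corr_lengths_um`` x ``fluct_stds`` is used.
    Ordering is deterministic (shapes outermost, replicates innermost) and each
    spec gets a distinct derived seed.
    """
    if pairs is None:
        if not corr_lengths_um or not fluct_stds:
            raise ParameterError("need corr_lengths_um and fluct_stds, or explicit pairs")
        pairs = [(lc, dn) for lc in corr_lengths_um for dn in fluct_stds]
    else:
        pairs = [(float(lc), float(dn)) for lc, dn in pairs]
        if not pairs:
            raise ParameterError("explicit pair list is empty")
    if not shapes:
        raise ParameterError("shapes list is empty")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")
    specs: list[NucleusSpec] = []
    for shape in shapes:
        for lc, dn in pairs:
            for rep in range(replicates):
                seed = derive_seed(base_seed, shape, float(lc), float(dn), rep)
                kwargs = dict(
                    shape=shape,
                    corr_length_um=float(lc),
                    fluct_std=float(dn),
                    n_mean=n_mean,
                    n_cyto=n_cyto,
                    voxel_um=voxel_um,
                    seed=seed,
                    padding_um=padding_um,
                )
                if shape == SPHERE:
                    kwargs["radius_um"] = radius_um
                else:
                    kwargs["semiaxes_um"] = semiaxes_um
                specs.append(NucleusSpec(**kwargs))
    return specs


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def volume_filename(spec: NucleusSpec, replicate: int | None = None) -> str:
    rep = "" if replicate is None else f"_rep{replicate}"
    return (
        f"{spec.shape}_lc{spec.corr_length_um:g}_dn{spec.fluct_std:g}{rep}"
        f"_seed{spec.seed}.h5"
    )


def save_volume(volume: RIVolume, path: str | Path) -> None:
    """Persist a volume as HDF5 (datasets ``ri`` and ``mask`` + spec attributes)."""
    spec = volume.spec
    with h5py.File(path, "w") as f:
        f.create_dataset("ri", data=volume.values, dtype=np.float64)
        f.create_dataset("mask", data=volume.mask.astype(np.uint8))
        f.attrs["voxel_um"] = volume.voxel_um
        if spec is not None:
            f.attrs["shape"] = spec.shape
            f.attrs["corr_length_um"] = spec.corr_length_um
            f.attrs["fluct_std"] = spec.fluct_std
            f.attrs["n_mean"] = spec.n_mean
            f.attrs["n_cyto"] = spec.n_cyto
            f.attrs["seed"] = spec.seed
            f.attrs["padding_um"] = spec.padding_um
            f.attrs["grid_shape"] = np.asarray(spec.grid_shape)
            if spec.shape == SPHERE:
                f.attrs["radius_um"] = spec.radius_um
            else:
                f.attrs["semiaxes_um"] = np.asarray(spec.semiaxes_um)


def load_volume(path: str | Path) -> RIVolume:
    with h5py.File(path, "r") as f:
        values = np.asarray(f["ri"], dtype=np.float64)
        mask = np.asarray(f["mask"], dtype=bool)
        attrs = dict(f.attrs)
    spec = None
    if "shape" in attrs:
        kwargs = dict(
            shape=str(attrs["shape"]),
            corr_length_um=float(attrs["corr_length_um"]),
            fluct_std=float(attrs["fluct_std"]),
            n_mean=float(attrs["n_mean"]),
            n_cyto=float(attrs["n_cyto"]),
            voxel_um=float(attrs["voxel_um"]),
            seed=int(attrs["seed"]),
            padding_um=float(attrs.get("padding_um", DEFAULT_PADDING_UM)),
            grid_shape=tuple(int(n) for n in attrs["grid_shape"]),
        )
        if kwargs["shape"] == SPHERE:
            kwargs["radius_um"] = float(attrs["radius_um"])
        else:
            kwargs["semiaxes_um"] = tuple(float(a) for a in attrs["semiaxes_um"])
        spec = NucleusSpec(**kwargs)
    return RIVolume(values=values, mask=mask, voxel_um=float(attrs["voxel_um"]), spec=spec)


def write_manifest(specs: Iterable[NucleusSpec], paths: Iterable[str | Path],
                   out_csv: str | Path) -> pd.DataFrame:
    """One row per spec (all generative fields + artifact path), written as CSV."""
    rows = []
    for spec, path in zip(specs, paths):
        rows.append(
            dict(
                shape=spec.shape,
                corr_length_um=spec.corr_length_um,
                fluct_std=spec.fluct_std,
                radius_um=spec.radius_um,
                semiaxes_um="" if spec.semiaxes_um is None else
                ";".join(f"{a:g}" for a in spec.semiaxes_um),
                n_mean=spec.n_mean,
                n_cyto=spec.n_cyto,
                voxel_um=spec.voxel_um,
                grid_shape=";".join(str(n) for n in spec.grid_shape),
                seed=spec.seed,
                path=str(path),
            )
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_csv, index=False)
    return df
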