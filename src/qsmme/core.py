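"""Shared constants, containers and Fourier helpers.

All fields are carried internally in Tesla; susceptibility in ppm of B0.
Phase volumes are radians, wrapped to (-pi, pi] unless stated otherwise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import fft as sp_fft

#: Proton gyromagnetic ratio, rad s^-1 T^-1 (angular).
GAMMA = 2.0 * np.pi * 42.577478518e6

FieldRole = Literal["total", "background", "local"]
FieldUnits = Literal["tesla", "radians", "ppm"]


def wrap_phase(phi: np.ndarray) -> np.ndarray:
    """Wrap phase to the principal interval (-pi, pi]."""
    return np.angle(np.exp(1j * np.asarray(phi)))


def fftn(x: np.ndarray) -> np.ndarray:
    return sp_fft.fftn(x)


def ifftn(x: np.ndarray) -> np.ndarray:
    return sp_fft.ifftn(x)


@dataclass
class FieldMap:
    """A 3D field perturbation volume with a role and units tag."""

    values: np.ndarray
    units: FieldUnits = "tesla"
    role: FieldRole = "total"
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("FieldMap values must be 3D")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.values.shape:
                raise ValueError("mask shape mismatch")

    def to_ppm(self, b0_tesla: float) -> np.ndarray:
        """Return the field in ppm of B0 regardless of the stored units."""
        if self.units == "ppm":
            return self.values
        if self.units == "tesla":
            return self.values / (b0_tesla * 1e-6)
        raise ValueError(
            "cannot convert radian-valued field to ppm without an echo time"
        )


@dataclass
class SusceptibilityMap:
    """A susceptibility volume (ppm) on a mask, with inversion metadata."""

    chi: np.ndarray
    mask: np.ndarray | None = None
    b0_tesla: float = 3.0
    alpha_used: float | None = None
    correction_factor: float = 1.0

    def __post_init__(self) -> None:
        self.chi = np.asarray(self.chi, dtype=float)
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)


@dataclass
class MultiEchoGRE:
    """4D multi-echo gradient-recalled-echo acquisition (x, y, z, echo)."""

    magnitude: np.ndarray
    phase: np.ndarray
    echo_times_s: np.ndarray
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_tesla: float = 3.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)

    def __post_init__(self) -> None:
        self.magnitude = np.asarray(self.magnitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        self.echo_times_s = np.asarray(self.echo_times_s, dtype=float)
        if self.magnitude.shape != self.phase.shape:
            raise ValueError("magnitude and phase must share shape")
        if self.magnitude.ndim != 4:
            raise ValueError("expected 4D (x, y, z, echo) volumes")
        if self.magnitude.shape[-1] != self.echo_times_s.size:
            raise ValueError("4th axis length must equal number of echo times")
        if np.any(np.diff(self.echo_times_s) <= 0):
            raise ValueError("echo times must be strictly increasing")

    @property
    def n_echoes(self) -> int:
        return int(self.echo_times_s.size)

    def complex_signal(self) -> np.ndarray:
        return self.magnitude * np.exp(1j * self.phase)


def default_echo_times(n_echoes: int = 5, te1_s: float = 3.0e-3,
                       spacing_s: float = 5.4e-3) -> np.ndarray:
    """Evenly spaced echo train; defaults give {3.0, 8.4, 13.8, 19.2, 24.6} ms."""
    return te1_s + spacing_s * np.arange(n_echoes)


def as_unit_vector(v: Sequence[float]) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("direction vector must be nonzero")
    return v / n
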