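"""Digital head phantom and multi-echo GRE simulation.

A phantom is a piece-wise-regional 3D model: each region carries a geometry
primitive and Gaussian-distributed tissue properties (susceptibility chi in
ppm, proton density M0 in arbitrary units, T2* in ms).  The total field is
the dipole convolution of the chi map; the ground-truth local field is
obtained by the reference-scan method (re-simulating with all sources
outside the brain mask removed and the mask-mean chi subtracted).  Noisy
complex multi-echo data are generated from the field, M0 and T2* maps with
independent Gaussian noise on the real and imaginary channels.
"""
from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np
from scipy import ndimage

from .core import (GAMMA, FieldMap, MultiEchoGRE, as_unit_vector,
                   default_echo_times, fftn, ifftn, wrap_phase)
from .dipole_inversion import dipole_kernel

__all__ = [
    "Ellipsoid", "Cylinder", "Box", "TissueProps", "Region", "PhantomSpec",
    "LabelVolume", "GroundTruth", "build_phantom", "simulate_fields",
    "simulate_gre", "erode_mask", "default_head_phantom", "sphere_phantom",
    "load_label_phantom",
]


# ---------------------------------------------------------------------------
# geometry primitives (voxel coordinates)
# ---------------------------------------------------------------------------

@dataclass
class Ellipsoid:
    center: tuple[float, float, float]
    semiaxes: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        q = sum(((g - c) / a) ** 2
                for g, c, a in zip(grids, self.center, self.semiaxes))
        return q <= 1.0


@dataclass
class Cylinder:
    """Finite cylinder from p0 to p1 with the given radius (voxels)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        p0 = np.asarray(self.p0, float)
        p1 = np.asarray(self.p1, float)
        axis = p1 - p0
        length2 = float(axis @ axis)
        if length2 == 0:
            raise ValueError("degenerate cylinder axis")
        grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                            indexing="ij")
        rel = [g - c for g, c in zip(grids, p0)]
        t = sum(r * a for r, a in zip(rel, axis)) / length2
        d2 = sum((r - t * a) ** 2 for r, a in zip(rel, axis))
        return (d2 <= self.radius ** 2) & (t >= 0.0) & (t <= 1.0)


@dataclass
class Box:
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def mask(self, shape: tuple[int, int, int]) -> np.ndarray:
        grids = np.ogrid[: shape[0], : shape[1], : shape[2]]
        inside = np.ones(shape, dtype=bool)
        for g, lo, hi in zip(grids, self.lo, self.hi):
            inside &= (g >= lo) & (g <= hi)
        return inside


# ---------------------------------------------------------------------------
# spec / outputs
# ---------------------------------------------------------------------------

@dataclass
class TissueProps:
    chi_mean_ppm: float
    chi_sd_ppm: float
    m0_mean: float
    m0_sd: float
    t2star_mean_ms: float
    t2star_sd_ms: float

    def __post_init__(self) -> None:
        if self.t2star_mean_ms <= 0:
            raise ValueError("t2star_mean_ms must be positive")
        if self.m0_mean < 0:
            raise ValueError("m0_mean must be nonnegative")


@dataclass
class Region:
    name: str
    geometry: Ellipsoid | Cylinder | Box
    tissue: TissueProps
    in_brain: bool = True


@dataclass
class PhantomSpec:
    """Full configuration of a synthetic head phantom.

    Regions listed later overwrite earlier ones where geometries overlap.
    ``phi0_poly`` holds coefficients of a smooth polynomial phase offset in
    normalized coordinates (constant, x, y, z, x^2, y^2, z^2); ``None``
    means no offset.
    """

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    b0_tesla: float = 3.0
    b0_direction: tuple[float, float, float] = (0.0, 0.0, 1.0)
    regions: list[Region] = dc_field(default_factory=list)
    phi0_poly: Sequence[float] | None = None
    noise_sd: float = 0.07
    echo_times_s: np.ndarray = dc_field(default_factory=default_echo_times)
    seed: int = 0

    def __post_init__(self) -> None:
        self.echo_times_s = np.asarray(self.echo_times_s, dtype=float)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.echo_times_s.size < 1 or np.any(np.diff(self.echo_times_s) <= 0):
            raise ValueError("echo times must be strictly increasing, length >= 1")
        if any(s <= 0 for s in self.grid_shape):
            raise ValueError("grid_shape must be positive")


@dataclass
class LabelVolume:
    labels: np.ndarray
    name_map: dict[int, str]
    brain_mask: np.ndarray


@dataclass
class GroundTruth:
    chi_true: np.ndarray           # ppm
    m0_true: np.ndarray            # a.u.
    t2star_true: np.ndarray        # ms
    phi0_true: np.ndarray          # radians
    db_total: FieldMap | None = None
    db_background: FieldMap | None = None
    db_local_true: FieldMap | None = None


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_phantom(spec: PhantomSpec) -> tuple[LabelVolume, GroundTruth]:
    """Rasterize the region list into label and property volumes.

    Per-voxel properties are drawn independently as mean + SD * z with z
    standard normal, from a sub-stream of the master seed.  T2* samples are
    clipped at 1 ms so the monoexponential decay model stays valid.
    Background air has chi = 0 (the phantom is self-referenced) and M0 = 0.
    """
    shape = spec.grid_shape
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    labels = np.zeros(shape, dtype=np.int32)
    name_map: dict[int, str] = {}
    brain = np.zeros(shape, dtype=bool)
    chi = np.zeros(shape, dtype=float)
    m0 = np.zeros(shape, dtype=float)
    t2s = np.full(shape, np.inf)

    for idx, region in enumerate(spec.regions, start=1):
        g = region.geometry.mask(shape)
        if not g.any():
            raise ValueError(f"region {region.name!r} lies outside the grid")
        labels[g] = idx
        name_map[idx] = region.name
        if region.in_brain:
            brain |= g
        n = int(g.sum())
        t = region.tissue
        chi[g] = t.chi_mean_ppm + t.chi_sd_ppm * rng.standard_normal(n)
        m0[g] = np.clip(t.m0_mean + t.m0_sd * rng.standard_normal(n), 0, None)
        t2s[g] = np.clip(
            t.t2star_mean_ms + t.t2star_sd_ms * rng.standard_normal(n), 1.0, None)

    phi0 = np.zeros(shape, dtype=float)
    if spec.phi0_poly is not None:
        c = np.zeros(7)
        c[: len(spec.phi0_poly)] = spec.phi0_poly
        grids = np.meshgrid(*[np.linspace(-1, 1, s) for s in shape],
                            indexing="ij")
        phi0 = (c[0] + c[1] * grids[0] + c[2] * grids[1] + c[3] * grids[2]
                + c[4] * grids[0] ** 2 + c[5] * grids[1] ** 2
                + c[6] * grids[2] ** 2)

    lv = LabelVolume(labels=labels, name_map=name_map, brain_mask=brain)
    gt = GroundTruth(chi_true=chi, m0_true=m0, t2star_true=t2s, phi0_true=phi0)
    return lv, gt


def _forward_field(chi_ppm: np.ndarray, voxel_size_mm, b0_direction,
                   b0_tesla: float) -> np.ndarray:
    """Dipole-convolution field (Tesla) of a chi distribution (ppm)."""
    d = dipole_kernel(chi_ppm.shape, voxel_size_mm, b0_direction).d_k
    return b0_tesla * 1e-6 * np.real(ifftn(d * fftn(chi_ppm)))


def simulate_fields(chi_true: np.ndarray, brain_mask: np.ndarray,
                    voxel_size_mm=(1.0, 1.0, 1.0),
                    b0_direction=(0.0, 0.0, 1.0), b0_tesla: float = 3.0,
                    ) -> tuple[FieldMap, FieldMap, FieldMap]:
    """Total, background and local field of a chi map (all Tesla).

    The local field follows the reference-scan decomposition: it is the
    field of the source distribution restricted to the brain mask with the
    mask-mean chi subtracted inside; the background field is the remainder.
    """
    chi_true = np.asarray(chi_true, dtype=float)
    if not np.all(np.isfinite(chi_true)):
        raise ValueError("chi volume must be finite")
    brain_mask = np.asarray(brain_mask, dtype=bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    b0_direction = as_unit_vector(b0_direction)

    total = _forward_field(chi_true, voxel_size_mm, b0_direction, b0_tesla)
    chi_in = np.where(brain_mask, chi_true - chi_true[brain_mask].mean(), 0.0)
    local = _forward_field(chi_in, voxel_size_mm, b0_direction, b0_tesla)
    background = total - local
    return (
        FieldMap(total, units="tesla", role="total", mask=brain_mask),
        FieldMap(background, units="tesla", role="background", mask=brain_mask),
        FieldMap(local, units="tesla", role="local", mask=brain_mask),
    )


def attach_fields(gt: GroundTruth, spec: PhantomSpec, lv: LabelVolume) -> GroundTruth:
    """Convenience: simulate and attach the three field maps to a GroundTruth."""
    tot, bg, loc = simulate_fields(gt.chi_true, lv.brain_mask,
                                   spec.voxel_size_mm, spec.b0_direction,
                                   spec.b0_tesla)
    gt.db_total, gt.db_background, gt.db_local_true = tot, bg, loc
    return gt


def simulate_gre(gt: GroundTruth, spec: PhantomSpec,
                 n_repeats: int = 1) -> list[MultiEchoGRE]:
    """Simulate noisy multi-echo complex GRE acquisitions.

    The noise-free signal is M0 * exp(-TE/T2*) * exp(i(gamma*dBtot*TE + phi0));
    zero-mean Gaussian noise of SD ``spec.noise_sd`` is added independently
    to the real and imaginary parts, regenerated at every echo and repeat.
    Repeats share the ground truth (emulating back-to-back scans of the
    same subject) but use independent noise streams.
    """
    if n_repeats < 1:
        raise ValueError("n_repeats must be >= 1")
    if gt.db_total is None:
        raise ValueError("ground truth has no fields; call attach_fields first")
    te = spec.echo_times_s
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")

    r2star = np.where(gt.t2star_true > 0, 1e3 / gt.t2star_true, 0.0)  # s^-1
    db = gt.db_total.values
    # sub-streams: index 0 is reserved for property sampling in build_phantom
    ss = np.random.SeedSequence(spec.seed)
    streams = ss.spawn(1 + n_repeats * te.size)

    out: list[MultiEchoGRE] = []
    for rep in range(n_repeats):
        mag = np.empty(spec.grid_shape + (te.size,), dtype=float)
        phs = np.empty_like(mag)
        for i, t in enumerate(te):
            signal = (gt.m0_true * np.exp(-t * r2star)
                      * np.exp(1j * (GAMMA * db * t + gt.phi0_true)))
            if spec.noise_sd > 0:
                rng = np.random.default_rng(streams[1 + rep * te.size + i])
                noise = spec.noise_sd * (
                    rng.standard_normal(spec.grid_shape)
                    + 1j * rng.standard_normal(spec.grid_shape))
                signal = signal + noise
            mag[..., i] = np.abs(signal)
            phs[..., i] = np.angle(signal)
        out.append(MultiEchoGRE(mag, phs, te, spec.voxel_size_mm,
                                spec.b0_tesla, tuple(spec.b0_direction)))
    return out


def erode_mask(mask: np.ndarray, radius_voxels: int) -> np.ndarray:
    """Morphological erosion by a 3x3x3 cube applied ``radius_voxels`` times."""
    if radius_voxels < 0:
        raise ValueError("radius must be >= 0")
    mask = np.asarray(mask, dtype=bool)
    if radius_voxels == 0:
        return mask.copy()
    out = ndimage.binary_erosion(mask, structure=np.ones((3, 3, 3), bool),
                                 iterations=radius_voxels)
    if not out.any():
        raise ValueError(f"mask eroded to empty at radius {radius_voxels}")
    return out


# ---------------------------------------------------------------------------
# ready-made phantoms
# ---------------------------------------------------------------------------

#: Default tissue table (configuration, not measured ground truth): chi in
#: ppm relative to surrounding tissue, T2* in ms, M0 normalized to GM = 1.
DEFAULT_TISSUES: dict[str, TissueProps] = {
    "GM":   TissueProps(0.02, 0.010, 1.00, 0.05, 60.0, 5.0),
    "WM":   TissueProps(-0.03, 0.010, 0.80, 0.05, 55.0, 5.0),
    "CSF":  TissueProps(0.00, 0.005, 1.00, 0.05, 500.0, 50.0),
    "TH":   TissueProps(0.02, 0.010, 0.90, 0.05, 60.0, 5.0),
    "CN":   TissueProps(0.06, 0.010, 0.90, 0.05, 55.0, 5.0),
    "PU":   TissueProps(0.09, 0.010, 0.90, 0.05, 50.0, 5.0),
    "GP":   TissueProps(0.18, 0.020, 0.85, 0.05, 35.0, 5.0),
    "vein": TissueProps(0.45, 0.030, 0.80, 0.05, 20.0, 3.0),
}


def default_head_phantom(grid_shape=(96, 96, 96), noise_sd: float = 0.07,
                         seed: int = 0,
                         tissues: dict[str, TissueProps] | None = None,
                         **kwargs) -> PhantomSpec:
    """Piece-wise-regional head phantom with deep-GM nuclei and a vein.

    The geometry scales with the grid: a GM head ellipsoid containing a WM
    core, ventricular CSF, bilateral caudate (CN), putamen (PU), globus
    pallidus (GP) and thalamus (TH) nuclei, and a posterior superior venous
    sinus modelled as a cylinder arc.
    """
    t = dict(DEFAULT_TISSUES)
    if tissues:
        t.update(tissues)
    n = np.asarray(grid_shape, dtype=float)
    c = n / 2.0

    def E(cx, cy, cz, ax, ay, az):
        return Ellipsoid((cx * n[0], cy * n[1], cz * n[2]),
                         (ax * n[0], ay * n[1], az * n[2]))

    regions = [
        Region("GM", E(0.5, 0.5, 0.5, 0.42, 0.42, 0.42), t["GM"]),
        Region("WM", E(0.5, 0.5, 0.5, 0.30, 0.30, 0.28), t["WM"]),
        # lateral-ventricle CSF, two elongated ellipsoids around the midline
        Region("CSF", E(0.42, 0.5, 0.54, 0.04, 0.14, 0.05), t["CSF"]),
        Region("CSF", E(0.58, 0.5, 0.54, 0.04, 0.14, 0.05), t["CSF"]),
        # deep gray matter, bilateral
        Region("TH", E(0.42, 0.55, 0.46, 0.055, 0.07, 0.055), t["TH"]),
        Region("TH", E(0.58, 0.55, 0.46, 0.055, 0.07, 0.055), t["TH"]),
        Region("CN", E(0.40, 0.40, 0.56, 0.04, 0.08, 0.045), t["CN"]),
        Region("CN", E(0.60, 0.40, 0.56, 0.04, 0.08, 0.045), t["CN"]),
        Region("PU", E(0.34, 0.46, 0.48, 0.04, 0.075, 0.05), t["PU"]),
        Region("PU", E(0.66, 0.46, 0.48, 0.04, 0.075, 0.05), t["PU"]),
        Region("GP", E(0.40, 0.49, 0.46, 0.032, 0.05, 0.04), t["GP"]),
        Region("GP", E(0.60, 0.49, 0.46, 0.032, 0.05, 0.04), t["GP"]),
        # superior sagittal / straight sinus stand-in: posterior cylinder
        Region("vein",
               Cylinder((0.5 * n[0], 0.30 * n[1], 0.70 * n[2]),
                        (0.5 * n[0], 0.78 * n[1], 0.70 * n[2]),
                        radius=max(2.0, 0.025 * float(n.min()))),
               t["vein"]),
    ]
    return PhantomSpec(grid_shape=tuple(int(s) for s in grid_shape),
                       regions=regions, noise_sd=noise_sd, seed=seed,
                       **kwargs)


def sphere_phantom(grid_shape=(64, 64, 64), chi_ppm: float = 1.0,
                   radius_frac: float = 0.12, mask_frac: float = 0.38,
                   t2star_ms: float = 50.0, noise_sd: float = 0.0,
                   seed: int = 0, **kwargs) -> PhantomSpec:
    """Single-sphere phantom inside a larger spherical 'brain' mask.

    The inner sphere carries the chi contrast; the surrounding mask sphere
    is chi = 0 tissue.  Used for closed-form field checks and for the
    underestimation-correction calibration.
    """
    n = np.asarray(grid_shape, dtype=float)
    c = tuple(n / 2.0)
    rin = radius_frac * float(n.min())
    rout = mask_frac * float(n.min())
    bg = TissueProps(0.0, 0.0, 1.0, 0.0, t2star_ms, 0.0)
    sph = TissueProps(chi_ppm, 0.0, 1.0, 0.0, t2star_ms, 0.0)
    regions = [
        Region("tissue", Ellipsoid(c, (rout,) * 3), bg),
        Region("sphere", Ellipsoid(c, (rin,) * 3), sph),
    ]
    return PhantomSpec(grid_shape=tuple(int(s) for s in grid_shape),
                       regions=regions, noise_sd=noise_sd, seed=seed, **kwargs)


def load_label_phantom(labels: np.ndarray, name_map: dict[int, str],
                       tissues: dict[str, TissueProps],
                       brain_labels: Sequence[int] | None = None,
                       **spec_kwargs) -> tuple[PhantomSpec, LabelVolume, GroundTruth]:
    """Build a phantom from an externally supplied label volume.

    Accepts any voxelized anatomical model (e.g. a resampled Zubal head)
    plus a tissue table mapping region names to properties.  Labels absent
    from ``name_map`` are treated as air.
    """
    labels = np.asarray(labels)
    spec = PhantomSpec(grid_shape=labels.shape, regions=[], **spec_kwargs)
    ss = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])

    shape = labels.shape
    chi = np.zeros(shape)
    m0 = np.zeros(shape)
    t2s = np.full(shape, np.inf)
    brain = np.zeros(shape, dtype=bool)
    if brain_labels is None:
        brain_labels = list(name_map)
    for lab, name in name_map.items():
        g = labels == lab
        if not g.any():
            continue
        t = tissues[name]
        nvox = int(g.sum())
        chi[g] = t.chi_mean_ppm + t.chi_sd_ppm * rng.standard_normal(nvox)
        m0[g] = np.clip(t.m0_mean + t.m0_sd * rng.standard_normal(nvox), 0, None)
        t2s[g] = np.clip(
            t.t2star_mean_ms + t.t2star_sd_ms * rng.standard_normal(nvox),
            1.0, None)
        if lab in brain_labels:
            brain |= g
    lv = LabelVolume(labels=labels.astype(np.int32), name_map=dict(name_map),
                     brain_mask=brain)
    gt = GroundTruth(chi_true=chi, m0_true=m0, t2star_true=t2s,
                     phi0_true=np.zeros(shape))
    return spec, lv, gt
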