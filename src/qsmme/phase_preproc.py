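"""Phase-domain building blocks shared by every pipeline.

Temporal unwrapping of the echo train, nonlinear complex fitting of the
total field, FFT-based Laplacian spatial unwrapping, and SHARP background
field removal.  The discrete Laplacian throughout is the 7-point stencil
(center -6, six face neighbours +1, scaled by the squared voxel size),
diagonalized by the FFT with periodic boundaries, so the forward and
truncated-inverse operators are exactly consistent.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import GAMMA, FieldMap, MultiEchoGRE, fftn, ifftn, wrap_phase
from .phantom_sim import erode_mask

__all__ = ["PhaseOffsetMap", "temporal_unwrap", "nlfit_complex",
           "laplacian_unwrap", "sharp", "laplacian_eigenvalues"]


@dataclass
class PhaseOffsetMap:
    """TE-independent phase offset phi0 (radians)."""

    values: np.ndarray


def laplacian_eigenvalues(shape, voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """FFT eigenvalues of the periodic 7-point discrete Laplacian.

    lam(k) = sum_axis 2(cos(2 pi n / N) - 1) / h^2; all values are <= 0
    with lam(0) = 0.
    """
    lam = np.zeros(shape)
    for ax, (n, h) in enumerate(zip(shape, voxel_size_mm)):
        theta = 2.0 * np.pi * np.fft.fftfreq(n)
        sh = [1, 1, 1]
        sh[ax] = n
        lam = lam + (2.0 * (np.cos(theta) - 1.0) / h ** 2).reshape(sh)
    return lam


def temporal_unwrap(phase_4d: np.ndarray, echo_times_s=None) -> np.ndarray:
    """Voxel-wise temporal unwrapping of a multi-echo phase series.

    The first echo is left unchanged; every later echo is shifted by the
    integer multiple of 2 pi that brings each successive difference into
    (-pi, pi].  Echo times are accepted for interface symmetry but do not
    enter the computation.
    """
    phase_4d = np.asarray(phase_4d, dtype=float)
    if phase_4d.ndim < 2 or phase_4d.shape[-1] == 1:
        warnings.warn("single echo: temporal unwrapping is the identity")
        return phase_4d.copy()
    out = np.empty_like(phase_4d)
    out[..., 0] = phase_4d[..., 0]
    for i in range(1, phase_4d.shape[-1]):
        step = wrap_phase(phase_4d[..., i] - phase_4d[..., i - 1])
        out[..., i] = out[..., i - 1] + step
    return out


def nlfit_complex(gre: MultiEchoGRE, mask: np.ndarray | None = None,
                  max_iter: int = 30,
                  tol: float = 1e-6) -> tuple[FieldMap, PhaseOffsetMap, np.ndarray]:
    """Voxel-wise nonlinear least-squares fit of the complex echo train.

    Minimizes sum_i |S_i - M_i exp(i(phi0 + gamma dB TE_i))|^2 over the
    total field dB and offset phi0 by Gauss-Newton iterations, initialized
    from a magnitude-squared-weighted linear fit of the temporally
    unwrapped phase.  The measured magnitudes M_i are kept as the model
    amplitudes, so the estimator correctly treats the complex-domain noise
    as Gaussian.  Returns the field (Tesla), the offset (radians) and the
    final residual norm map (NaN where the magnitude vanishes at every
    echo).
    """
    te = gre.echo_times_s
    if te.size < 2:
        raise ValueError("need at least 2 echoes to fit a field")
    mag = gre.magnitude
    sig = gre.complex_signal()
    w = mag ** 2

    valid = w.sum(axis=-1) > 0
    if mask is not None:
        # voxels outside the mask are not fitted (background noise voxels
        # have a multimodal likelihood and would stall the iteration)
        valid = valid & np.asarray(mask, dtype=bool)
        w = w * valid[..., None]

    # weighted linear initialization on the temporally unwrapped phase
    phi_u = temporal_unwrap(gre.phase, te)
    s0 = w.sum(axis=-1)
    s1 = (w * te).sum(axis=-1)
    s2 = (w * te ** 2).sum(axis=-1)
    sy = (w * phi_u).sum(axis=-1)
    sty = (w * te * phi_u).sum(axis=-1)
    det = s0 * s2 - s1 ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        b = np.where(det > 0, (s0 * sty - s1 * sy) / det, 0.0)   # rad/s
        phi0 = np.where(det > 0, (s2 * sy - s1 * sty) / det, 0.0)

    # Gauss-Newton refinement; the normal matrix depends on magnitudes only
    a11 = (w * te ** 2).sum(axis=-1)
    a12 = (w * te).sum(axis=-1)
    a22 = w.sum(axis=-1)
    det_a = a11 * a22 - a12 ** 2
    ok = valid & (det_a > 0)
    for _ in range(max_iter):
        model = mag * np.exp(1j * (phi0[..., None] + b[..., None] * te))
        r = sig - model
        im = np.imag(np.conj(model) * r)
        g1 = (te * im).sum(axis=-1)
        g2 = im.sum(axis=-1)
        with np.errstate(invalid="ignore", divide="ignore"):
            db = np.where(ok, (a22 * g1 - a12 * g2) / det_a, 0.0)
            dphi = np.where(ok, (a11 * g2 - a12 * g1) / det_a, 0.0)
        b = b + db
        phi0 = phi0 + dphi
        scale = np.maximum(np.abs(b), 1.0 / te[-1])
        if np.max(np.abs(db) / scale) < tol and np.max(np.abs(dphi)) < tol:
            break

    model = mag * np.exp(1j * (phi0[..., None] + b[..., None] * te))
    residual = np.sqrt((np.abs(sig - model) ** 2).sum(axis=-1))
    residual = np.where(valid, residual, np.nan)
    b = np.where(valid, b, 0.0)
    phi0 = np.where(valid, phi0, 0.0)
    field = FieldMap(b / GAMMA, units="tesla", role="total")
    return field, PhaseOffsetMap(values=phi0), residual


def _laplacian_of_wrapped(phase: np.ndarray, lam: np.ndarray) -> np.ndarray:
    """Discrete Laplacian of the true phase from its wrapped version.

    Uses cos(p) L[sin(p)] - sin(p) L[cos(p)], which for the 7-point stencil
    equals sum_neighbours sin(p_n - p) and is insensitive to 2 pi wraps.
    """
    sin_p, cos_p = np.sin(phase), np.cos(phase)
    lap_sin = np.real(ifftn(lam * fftn(sin_p)))
    lap_cos = np.real(ifftn(lam * fftn(cos_p)))
    return cos_p * lap_sin - sin_p * lap_cos


def _truncated_inverse(volume: np.ndarray, lam: np.ndarray,
                       threshold: float) -> np.ndarray:
    """Invert the FFT-diagonal operator, zeroing the truncated set."""
    mx = np.abs(lam).max()
    keep = np.abs(lam) > threshold * mx
    vk = fftn(volume)
    out_k = np.where(keep, vk / np.where(keep, lam, 1.0), 0.0)
    return np.real(ifftn(out_k))


def laplacian_unwrap(phase_3d: np.ndarray, mask: np.ndarray | None = None,
                     tsvd_threshold: float = 1e-10,
                     voxel_size_mm=(1.0, 1.0, 1.0)) -> np.ndarray:
    """Laplacian spatial phase unwrapping.

    Estimates the Laplacian of the true phase through the sin/cos identity,
    then applies the truncated inverse Laplacian (k-space values with
    |lam| <= threshold * max|lam| are zeroed, which always includes DC).
    The output is set to zero mean over the mask: the global constant is in
    the operator null space and carries no field information.
    """
    phase_3d = np.asarray(phase_3d, dtype=float)
    if not np.all(np.isfinite(phase_3d)):
        raise ValueError("phase must be finite")
    if tsvd_threshold >= 1.0:
        raise ValueError("threshold >= 1 truncates everything")
    lam = laplacian_eigenvalues(phase_3d.shape, voxel_size_mm)
    lap = _laplacian_of_wrapped(phase_3d, lam)
    out = _truncated_inverse(lap, lam, tsvd_threshold)
    if mask is None:
        mask = np.ones(phase_3d.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    return out - out[mask].mean()


def sharp(phase_like: np.ndarray, mask: np.ndarray,
          tsvd_threshold: float = 0.05, erode_voxels: int = 5,
          voxel_size_mm=(1.0, 1.0, 1.0),
          units: str = "radians") -> tuple[FieldMap, np.ndarray]:
    """SHARP background removal with the 3-voxel Laplacian kernel.

    The forward step applies the discrete Laplacian via the sin/cos
    identity (so wrapped phase input is admissible and the operation
    performs simultaneous spatial unwrapping and background removal),
    restricts the result to the mask eroded by ``erode_voxels``, and
    deconvolves by truncated inversion (relative threshold on the kernel's
    k-space magnitude).  The output is the background-free phase/field on
    the eroded mask, mean-zero over that mask.
    """
    phase_like = np.asarray(phase_like, dtype=float)
    if not np.all(np.isfinite(phase_like)):
        raise ValueError("input must be finite")
    if tsvd_threshold >= 1.0:
        raise ValueError("threshold >= 1 truncates everything")
    mask = np.asarray(mask, dtype=bool)
    em = erode_mask(mask, erode_voxels)
    lam = laplacian_eigenvalues(phase_like.shape, voxel_size_mm)
    lap = _laplacian_of_wrapped(phase_like, lam) * em
    # deconvolution kernel normalized as (delta - face-neighbour mean), i.e.
    # -lam/6 for unit voxels, so its k-space values are O(1) and the
    # truncation threshold is compared against them absolutely
    h2 = np.mean(np.asarray(voxel_size_mm, dtype=float) ** 2)
    lam_norm = -lam * h2 / 6.0
    keep = lam_norm > tsvd_threshold
    lap_k = fftn(lap)
    out_k = np.where(keep, lap_k / np.where(keep, lam, 1.0), 0.0)
    out = np.real(ifftn(out_k))
    out = np.where(em, out - out[em].mean(), 0.0)
    return FieldMap(out, units=units, role="local", mask=em), em
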