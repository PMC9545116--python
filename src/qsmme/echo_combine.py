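"""Weighted-averaging rules for multi-echo combination, and R2* mapping.

Three convex combinations are implemented: TE-weighted averaging of the
unwrapped total-field phase, SNR-weighted averaging of background-free
phase (weights depend on TE and the local R2*), and magnitude-weighted
averaging of per-echo susceptibility maps.  All weight sets sum to one at
every voxel and are returned for audit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .core import GAMMA, FieldMap, SusceptibilityMap

__all__ = ["EchoWeights", "RelaxometryMaps", "te_weights", "snr_weights",
           "susceptibility_weights", "te_weighted_average", "fit_r2star",
           "snr_weighted_average", "susceptibility_weighted_average"]


@dataclass
class EchoWeights:
    weights: np.ndarray            # scalars (n,) or per-voxel (..., n)
    scheme: Literal["te", "snr", "magnitude-susceptibility"]


@dataclass
class RelaxometryMaps:
    r2star: np.ndarray             # s^-1, >= 0
    m0: np.ndarray                 # a.u., >= 0


def te_weights(echo_times_s: np.ndarray) -> EchoWeights:
    """w_i = TE_i / sum_j TE_j (spatially constant)."""
    te = np.asarray(echo_times_s, dtype=float)
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    return EchoWeights(weights=te / te.sum(), scheme="te")


def snr_weights(echo_times_s: np.ndarray, r2star: np.ndarray) -> EchoWeights:
    """w_i(r) = TE_i exp(-TE_i R2*(r)) / sum_j TE_j exp(-TE_j R2*(r))."""
    te = np.asarray(echo_times_s, dtype=float)
    r2 = np.asarray(r2star, dtype=float)
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    if np.any(r2 < 0):
        raise ValueError("R2* must be nonnegative")
    w = te * np.exp(-r2[..., None] * te)
    return EchoWeights(weights=w / w.sum(axis=-1, keepdims=True), scheme="snr")


def susceptibility_weights(magnitude_4d: np.ndarray,
                           echo_times_s: np.ndarray) -> EchoWeights:
    """w_i(r) = M^2(r,TE_i) TE_i^2 / sum_j M^2(r,TE_j) TE_j^2.

    Voxels with zero magnitude at every echo get all-zero weights (the
    combined value there is reported as 0 and flagged by the caller).
    """
    m = np.asarray(magnitude_4d, dtype=float)
    te = np.asarray(echo_times_s, dtype=float)
    w = m ** 2 * te ** 2
    tot = w.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(tot > 0, w / np.where(tot > 0, tot, 1.0), 0.0)
    return EchoWeights(weights=w, scheme="magnitude-susceptibility")


def te_weighted_average(unwrapped_phase_4d: np.ndarray,
                        echo_times_s: np.ndarray,
                        ) -> tuple[FieldMap, EchoWeights]:
    """TE-weighted total-field estimate from unwrapped per-echo phase.

    dB(r) = (1/gamma) sum_i w_i phi_i(r) / TE_i, with w_i = TE_i / sum TE_j,
    which collapses algebraically to (1/gamma) * sum_i phi_i / sum_j TE_j.
    """
    phi = np.asarray(unwrapped_phase_4d, dtype=float)
    te = np.asarray(echo_times_s, dtype=float)
    ew = te_weights(te)
    db = phi.sum(axis=-1) / (GAMMA * te.sum())
    return FieldMap(db, units="tesla", role="total"), ew


def fit_r2star(magnitude_4d: np.ndarray, echo_times_s: np.ndarray,
               mask: np.ndarray | None = None, max_iter: int = 20,
               r2_max: float = 2000.0) -> RelaxometryMaps:
    """Voxel-wise monoexponential fit M = M0 exp(-R2* TE).

    Initialized by ordinary least squares on log(M) versus TE, refined by
    Gauss-Newton on the nonlinear model, with R2* bounded to [0, r2_max]
    s^-1 to stabilize rapidly decaying (venous) voxels.  Voxels with any
    nonpositive magnitude are excluded (R2* = 0, M0 = 0).
    """
    m = np.asarray(magnitude_4d, dtype=float)
    te = np.asarray(echo_times_s, dtype=float)
    if te.size < 2:
        raise ValueError("need at least 2 echoes")
    shape = m.shape[:-1]
    if mask is None:
        mask = np.ones(shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    ok = mask & np.all(m > 0, axis=-1)

    logm = np.log(np.where(m > 0, m, 1.0))
    n = te.size
    st, st2 = te.sum(), (te ** 2).sum()
    sy = logm.sum(axis=-1)
    sty = (logm * te).sum(axis=-1)
    det = n * st2 - st ** 2
    slope = (n * sty - st * sy) / det
    intercept = (st2 * sy - st * sty) / det
    r2 = np.clip(-slope, 0.0, r2_max)
    m0 = np.exp(intercept)

    for _ in range(max_iter):
        model = m0[..., None] * np.exp(-r2[..., None] * te)
        r = m - model
        # Jacobian columns: d/dM0 = model/M0, d/dR2 = -TE*model
        j1 = model / np.where(m0[..., None] > 0, m0[..., None], 1.0)
        j2 = -te * model
        a11 = (j1 * j1).sum(axis=-1)
        a12 = (j1 * j2).sum(axis=-1)
        a22 = (j2 * j2).sum(axis=-1)
        g1 = (j1 * r).sum(axis=-1)
        g2 = (j2 * r).sum(axis=-1)
        det_a = a11 * a22 - a12 ** 2
        good = ok & (det_a > 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            dm0 = np.where(good, (a22 * g1 - a12 * g2) / det_a, 0.0)
            dr2 = np.where(good, (a11 * g2 - a12 * g1) / det_a, 0.0)
        m0 = np.clip(m0 + dm0, 0.0, None)
        r2 = np.clip(r2 + dr2, 0.0, r2_max)
        if max(np.abs(dm0).max(initial=0.0), np.abs(dr2).max(initial=0.0)) \
                < 1e-10 * max(1.0, r2.max(initial=0.0)):
            break

    r2 = np.where(ok, r2, 0.0)
    m0 = np.where(ok, m0, 0.0)
    return RelaxometryMaps(r2star=r2, m0=m0)


def snr_weighted_average(local_phase_4d: np.ndarray,
                         echo_times_s: np.ndarray, r2star: np.ndarray,
                         ) -> tuple[FieldMap, EchoWeights]:
    """SNR-weighted local-field estimate from background-free phase.

    dBLoc(r) = (1/gamma) sum_i w_i(r) phi_i(r) / TE_i with TE- and
    R2*-dependent weights; at R2* = 0 this reduces exactly to the
    TE-weighted average.
    """
    phi = np.asarray(local_phase_4d, dtype=float)
    te = np.asarray(echo_times_s, dtype=float)
    ew = snr_weights(te, r2star)
    db = (ew.weights * phi / te).sum(axis=-1) / GAMMA
    return FieldMap(db, units="tesla", role="local"), ew


def susceptibility_weighted_average(chi_per_echo_4d: np.ndarray,
                                    magnitude_4d: np.ndarray,
                                    echo_times_s: np.ndarray,
                                    b0_tesla: float = 3.0,
                                    ) -> tuple[SusceptibilityMap, EchoWeights]:
    """Magnitude-weighted combination of per-echo susceptibility maps.

    chi(r) = sum_i w_i(r) chi_i(r) with w_i proportional to M^2 TE^2.
    """
    chi = np.asarray(chi_per_echo_4d, dtype=float)
    ew = susceptibility_weights(magnitude_4d, echo_times_s)
    combined = (ew.weights * chi).sum(axis=-1)
    return SusceptibilityMap(chi=combined, b0_tesla=b0_tesla), ew
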