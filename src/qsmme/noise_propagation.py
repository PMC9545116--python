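"""Analytic phase-noise propagation through every combination rule.

Per-echo phase-noise maps follow the reciprocal-SNR law; the two-scan
difference method estimates ROI noise from repeated acquisitions; closed
forms propagate the per-echo noise through nonlinear fitting, TE-weighted
and SNR-weighted averaging; and a linear-response Fourier calculation
carries field noise through the Tikhonov inversion to susceptibility
noise.  A Monte-Carlo driver reruns entire pipelines on independent noise
realizations and is the oracle every analytic map is validated against.

Propagation is derived directly from the combination formulas (first-order
error propagation of independent per-echo noise); variance filtering
through the inversion uses the squared image-domain impulse response of
the regularized inverse kernel, which is exact for voxel-wise independent
field noise.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .core import GAMMA, FieldMap, fftn, ifftn
from .dipole_inversion import DipoleKernelGrid
from .phantom_sim import GroundTruth, LabelVolume, PhantomSpec, simulate_gre

__all__ = ["NoiseMaps", "snr_difference", "phase_noise_map",
           "sigma_field_fit", "sigma_field_tewavg", "sigma_field_snrwavg",
           "sigma_chi_fourier", "sigma_chi_suscwavg", "monte_carlo_sigma"]


@dataclass
class NoiseMaps:
    """Container for the analytic noise products of one pipeline."""

    sigma_phi: np.ndarray              # per-echo, radians (..., n)
    sigma_db: np.ndarray | None = None  # Tesla
    sigma_chi: np.ndarray | None = None  # ppm
    c_of_te: np.ndarray | None = None  # per-echo calibration, 1 for phantoms
    sense_factor_R: float = 1.0
    roi_stats: pd.DataFrame | None = None


def snr_difference(scan1, scan2, rois: dict[str, np.ndarray],
                   sense_factor_R: float = 3.0) -> pd.DataFrame:
    """ROI noise estimation from two back-to-back co-registered scans.

    Per ROI and echo: M_ROI = mean of (M1+M2)/2, sigma(M) = sqrt(R/2) *
    SD(M1-M2) and sigma(phi) = sqrt(R/2) * SD(wrapped phase difference),
    where R is the net parallel-imaging (SENSE) factor.  The sqrt(R/2)
    convention reduces to the textbook difference method at R = 1.
    Rows tagged ``roi='combined'`` average the per-ROI values per echo.
    """
    if scan1.n_echoes != scan2.n_echoes:
        raise ValueError("mismatched echo counts")
    from .core import wrap_phase

    rows = []
    for name, roi in rois.items():
        roi = np.asarray(roi, dtype=bool)
        if not roi.any():
            raise ValueError(f"ROI {name!r} is empty")
        for i, te in enumerate(scan1.echo_times_s):
            m1 = scan1.magnitude[..., i][roi]
            m2 = scan2.magnitude[..., i][roi]
            dphi = wrap_phase(scan1.phase[..., i][roi]
                              - scan2.phase[..., i][roi])
            rows.append({
                "roi": name, "echo": i, "te_s": te,
                "m_roi": 0.5 * (m1 + m2).mean(),
                "sigma_m": np.sqrt(sense_factor_R / 2.0) * (m1 - m2).std(ddof=1),
                "sigma_phi": np.sqrt(sense_factor_R / 2.0) * dphi.std(ddof=1),
            })
    df = pd.DataFrame(rows)
    combined = (df.groupby(["echo", "te_s"], as_index=False)
                [["m_roi", "sigma_m", "sigma_phi"]].mean())
    combined.insert(0, "roi", "combined")
    return pd.concat([df, combined], ignore_index=True)


def c_of_te(roi_stats: pd.DataFrame) -> np.ndarray:
    """Phase-noise calibration constant per echo from two-scan ROI stats.

    c(TE) = sigma_ROI(phi) * M_ROI / sigma_ROI(M); equals 1 by definition
    for simulated data at high SNR.
    """
    comb = roi_stats[roi_stats["roi"] == "combined"].sort_values("echo")
    return (comb["sigma_phi"] * comb["m_roi"] / comb["sigma_m"]).to_numpy()


def phase_noise_map(magnitude: np.ndarray, sigma_m: float,
                    c_te: float = 1.0) -> np.ndarray:
    """Reciprocal-SNR phase noise: sigma(phi) = c * sigma(M) / M (radians).

    Zero-magnitude voxels are flagged with +inf.
    """
    m = np.asarray(magnitude, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(m > 0, c_te * sigma_m / np.where(m > 0, m, 1.0),
                        np.inf)


def _stack(per_echo) -> np.ndarray:
    """Stack a list of per-echo maps on the last axis; pass arrays through
    (echo axis already last)."""
    if isinstance(per_echo, (list, tuple)):
        return np.stack([np.asarray(v, dtype=float) for v in per_echo],
                        axis=-1)
    return np.asarray(per_echo, dtype=float)


def sigma_field_fit(sigma_phi_per_echo, echo_times_s) -> np.ndarray:
    """A-priori noise of the fitted total field (Tesla).

    Weighted-least-squares slope variance of phase versus TE with an
    intercept (the phase offset), evaluated voxel-wise:
    sigma(dB) = (1/gamma) sqrt(S0 / (S0 S2 - S1^2)) with
    S_p = sum TE^p / sigma_phi^2.  Identical for linear and nonlinear
    complex fitting at high SNR.
    """
    s = _stack(sigma_phi_per_echo)
    te = np.asarray(echo_times_s, dtype=float)
    if te.size < 2:
        raise ValueError("need at least 2 echoes")
    if np.any(s <= 0):
        raise ValueError("per-echo sigma_phi must be positive")
    inv = 1.0 / s ** 2
    s0 = inv.sum(axis=-1)
    s1 = (te * inv).sum(axis=-1)
    s2 = (te ** 2 * inv).sum(axis=-1)
    return np.sqrt(s0 / (s0 * s2 - s1 ** 2)) / GAMMA


def sigma_field_tewavg(sigma_phi_per_echo, echo_times_s) -> np.ndarray:
    """Noise of the TE-weighted total field (Tesla), uncorrelated echoes:
    sigma(dB) = sqrt(sum sigma_phi^2) / (gamma * sum TE)."""
    s = _stack(sigma_phi_per_echo)
    te = np.asarray(echo_times_s, dtype=float)
    if np.any(s < 0):
        raise ValueError("sigma_phi must be nonnegative")
    return np.sqrt((s ** 2).sum(axis=-1)) / (GAMMA * te.sum())


def sigma_field_snrwavg(sigma_phi_per_echo, echo_times_s,
                        r2star) -> np.ndarray:
    """Noise of the SNR-weighted local field (Tesla).

    First-order propagation of the weighted average with weights
    TE exp(-TE R2*): the per-echo coefficient on phi_i is
    exp(-TE_i R2*) / sum_j TE_j exp(-TE_j R2*); reduces to the TE-weighted
    expression at R2* = 0.
    """
    s = _stack(sigma_phi_per_echo)
    te = np.asarray(echo_times_s, dtype=float)
    r2 = np.asarray(r2star, dtype=float)[..., None]
    coef = np.exp(-te * r2) / (te * np.exp(-te * r2)).sum(axis=-1,
                                                          keepdims=True)
    return np.sqrt((coef ** 2 * s ** 2).sum(axis=-1)) / GAMMA


def sigma_chi_fourier(sigma_db_local: np.ndarray, kernel: DipoleKernelGrid,
                      b0_tesla: float = 3.0,
                      correction_factor: float = 1.0) -> np.ndarray:
    """Susceptibility noise map from a local-field noise map (ppm).

    The Tikhonov inversion is linear with image-domain impulse response
    h = IFT[D/(D^2+alpha)]; for voxel-wise independent field noise the
    variance map transforms as var(chi) = h^2 (convolved with) var(field),
    evaluated in k-space.  Tiny negative values from the real-part FFT
    round trip are clipped at zero before the square root.
    """
    if kernel.alpha is None:
        raise ValueError("kernel.alpha must be set")
    sig_ppm = np.asarray(sigma_db_local, dtype=float) / (b0_tesla * 1e-6)
    h = np.real(ifftn(kernel.inverse_tikhonov()))
    h2_k = fftn(h ** 2)
    var = np.real(ifftn(h2_k * fftn(sig_ppm ** 2)))
    return correction_factor * np.sqrt(np.clip(var, 0.0, None))


def sigma_chi_suscwavg(chi_per_echo, sigma_chi_per_echo, magnitude_per_echo,
                       sigma_m_per_echo, echo_times_s) -> np.ndarray:
    """Noise of the magnitude-weighted susceptibility combination (ppm).

    First-order propagation of chi = sum w_i chi_i through both the
    per-echo chi uncertainties and the magnitude dependence of the weights
    w_i = M_i^2 TE_i^2 / Q:  d chi / d M_i = (2 M_i TE_i^2 / Q)
    (chi_i - chi_bar), evaluated analytically.
    """
    chi = _stack(chi_per_echo)
    schi = _stack(sigma_chi_per_echo)
    m = _stack(magnitude_per_echo)
    sm = np.asarray(sigma_m_per_echo, dtype=float)
    te = np.asarray(echo_times_s, dtype=float)
    if sm.ndim <= 1:
        sm = np.broadcast_to(sm, chi.shape)
    q = (m ** 2 * te ** 2).sum(axis=-1, keepdims=True)
    ok = q > 0
    qs = np.where(ok, q, 1.0)
    w = np.where(ok, m ** 2 * te ** 2 / qs, 0.0)
    chi_bar = (w * chi).sum(axis=-1, keepdims=True)
    dchi_dm = 2.0 * m * te ** 2 / qs * (chi - chi_bar)
    var = ((dchi_dm ** 2) * sm ** 2 + w ** 2 * schi ** 2).sum(axis=-1)
    return np.where(ok[..., 0], np.sqrt(var), 0.0)


def monte_carlo_sigma(pipeline_name: str, spec: PhantomSpec,
                      lv: LabelVolume, gt: GroundTruth, n_repeats: int,
                      seed: int, alpha: float,
                      correction_factor: float = 1.0,
                      ) -> dict[str, np.ndarray]:
    """Empirical noise maps: rerun a pipeline on independent realizations.

    Returns voxel-wise SD maps of the combined field and of chi, plus the
    eroded mask the pipeline reported them on.  Ground truth is shared;
    only the complex noise stream varies between repeats.
    """
    from .pipelines_io import PipelineConfig, run_pipeline

    if n_repeats < 50:
        raise ValueError("n_repeats must be >= 50 for stable SD maps")
    cfg = PipelineConfig(pipeline=pipeline_name, alpha=alpha,
                         correction_factor=correction_factor)
    sum_f = sumsq_f = None
    sum_c = sumsq_c = None
    em = None
    rng = np.random.default_rng(seed)
    for rep in range(n_repeats):
        rep_spec = replace(spec, seed=int(rng.integers(2 ** 31)))
        gre = simulate_gre(gt, rep_spec, n_repeats=1)[0]
        result = run_pipeline(gre, lv.brain_mask, cfg)
        f = result.db_combined.values
        c = result.chi.chi
        if sum_f is None:
            sum_f = np.zeros_like(f)
            sumsq_f = np.zeros_like(f)
            sum_c = np.zeros_like(c)
            sumsq_c = np.zeros_like(c)
        sum_f += f
        sumsq_f += f ** 2
        sum_c += c
        sumsq_c += c ** 2
        em = result.eroded_mask
    n = float(n_repeats)
    sd_f = np.sqrt(np.clip(sumsq_f / n - (sum_f / n) ** 2, 0.0, None)
                   * n / (n - 1))
    sd_c = np.sqrt(np.clip(sumsq_c / n - (sum_c / n) ** 2, 0.0, None)
                   * n / (n - 1))
    return {"sigma_db": sd_f, "sigma_chi": sd_c, "eroded_mask": em}
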