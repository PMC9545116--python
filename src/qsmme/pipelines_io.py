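"""End-to-end QSM pipelines and NIfTI input/output.

Four processing streams share the same building blocks but combine echoes
at different stages:

* ``nlfit``     - nonlinear complex fit of the echo train, then SHARP,
                  then Tikhonov inversion;
* ``te-wavg``   - per-echo Laplacian unwrapping, TE-weighted averaging of
                  the phase, SHARP, inversion;
* ``snr-wavg``  - per-echo SHARP, R2* mapping, SNR-weighted averaging of
                  the background-free phase, inversion;
* ``susc-wavg`` - per-echo SHARP and per-echo inversion, then
                  magnitude-weighted averaging of the chi maps (per-echo
                  chi maps from an external tool can be supplied instead).

All pipelines report chi on the SHARP-eroded mask; fitted or averaged
fields are passed to SHARP as phase at the echo-spacing time so that any
residual 2 pi ambiguities from temporal unwrapping remain wrapped and are
resolved spatially.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import nibabel as nib
import numpy as np

from .core import GAMMA, FieldMap, MultiEchoGRE, SusceptibilityMap, wrap_phase
from .dipole_inversion import (calibrate_correction, lcurve_alpha,
                               tikhonov_invert)
from .echo_combine import (EchoWeights, RelaxometryMaps, fit_r2star,
                           snr_weighted_average, susceptibility_weighted_average,
                           te_weighted_average)
from .phase_preproc import laplacian_unwrap, nlfit_complex, sharp

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "read_gre",
           "write_volume", "write_gre", "PIPELINES"]

logger = logging.getLogger("qsmme")

PIPELINES = ("nlfit", "te-wavg", "snr-wavg", "susc-wavg")


@dataclass
class PipelineConfig:
    """Configuration shared by the four processing streams."""

    pipeline: str = "nlfit"
    sharp_threshold: float = 0.05
    erode_voxels: int = 5
    unwrap_threshold: float = 1e-10
    alpha: float | None = None            # fixed Tikhonov alpha; None -> L-curve
    alpha_grid: np.ndarray | None = None
    correction_factor: float | None = None  # None -> sphere calibration
    external_chi: np.ndarray | None = None  # (..., n) per-echo chi, susc-wavg hook
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.pipeline not in PIPELINES:
            raise ValueError(f"unknown pipeline {self.pipeline!r}; "
                             f"expected one of {PIPELINES}")
        for thr in (self.sharp_threshold, self.unwrap_threshold):
            if not (0.0 < thr < 1.0):
                raise ValueError("thresholds must lie in (0, 1)")


@dataclass
class PipelineResult:
    chi: SusceptibilityMap
    db_combined: FieldMap
    eroded_mask: np.ndarray
    alpha: float
    correction_factor: float
    db_total: FieldMap | None = None
    phi0: np.ndarray | None = None
    r2star: RelaxometryMaps | None = None
    weights: EchoWeights | None = None
    chi_per_echo: np.ndarray | None = None
    lcurve: np.ndarray | None = None
    intermediates: dict = dc_field(default_factory=dict)


def _choose_alpha(cfg: PipelineConfig, fm: FieldMap, mask: np.ndarray,
                  gre: MultiEchoGRE) -> tuple[float, np.ndarray | None]:
    if cfg.alpha is not None:
        return float(cfg.alpha), None
    alpha, curve = lcurve_alpha(fm, mask, alpha_grid=cfg.alpha_grid,
                                b0_tesla=gre.b0_tesla,
                                voxel_size_mm=gre.voxel_size_mm,
                                b0_direction=gre.b0_direction)
    return alpha, curve


def _choose_correction(cfg: PipelineConfig, shape, alpha: float,
                       gre: MultiEchoGRE) -> float:
    if cfg.correction_factor is not None:
        return float(cfg.correction_factor)
    return calibrate_correction(tuple(shape), alpha, b0_tesla=gre.b0_tesla,
                                sharp_threshold=cfg.sharp_threshold,
                                erode_voxels=cfg.erode_voxels)


def run_pipeline(gre: MultiEchoGRE, mask: np.ndarray,
                 config: PipelineConfig) -> PipelineResult:
    """Run one complete multi-echo QSM processing stream.

    Returns the susceptibility map together with every intermediate (field
    maps, weights, eroded mask, alpha, correction factor).  If
    ``config.out_dir`` is set, volumes are also written as NIfTI.
    """
    mask = np.asarray(mask, dtype=bool)
    te = gre.echo_times_s
    dte = float(te[1] - te[0]) if te.size > 1 else float(te[0])
    name = config.pipeline
    inter: dict = {}
    try:
        if name == "nlfit":
            result = _run_nlfit(gre, mask, config, dte, inter)
        elif name == "te-wavg":
            result = _run_tewavg(gre, mask, config, dte, inter)
        elif name == "snr-wavg":
            result = _run_snrwavg(gre, mask, config, inter)
        else:
            result = _run_suscwavg(gre, mask, config, inter)
    except Exception as exc:
        raise RuntimeError(f"pipeline {name!r} failed: {exc}") from exc
    if config.out_dir is not None:
        _write_result(result, gre, Path(config.out_dir), name)
    return result


def _field_stage(gre, mask, config, dte, phase_ref, inter):
    """SHARP + inversion shared by nlfit and te-wavg (total-field input)."""
    loc, em = sharp(phase_ref, mask, tsvd_threshold=config.sharp_threshold,
                    erode_voxels=config.erode_voxels,
                    voxel_size_mm=gre.voxel_size_mm)
    db_loc = FieldMap(loc.values / (GAMMA * dte), units="tesla",
                      role="local", mask=em)
    alpha, curve = _choose_alpha(config, db_loc, em, gre)
    corr = _choose_correction(config, db_loc.values.shape, alpha, gre)
    chi = tikhonov_invert(db_loc, em, alpha=alpha, b0_tesla=gre.b0_tesla,
                          correction_factor=corr,
                          voxel_size_mm=gre.voxel_size_mm,
                          b0_direction=gre.b0_direction)
    return db_loc, em, alpha, corr, chi, curve


def _run_nlfit(gre, mask, config, dte, inter) -> PipelineResult:
    db_total, phi0, residual = nlfit_complex(gre, mask)
    inter["nlfit_residual"] = residual
    phase_ref = wrap_phase(GAMMA * db_total.values * dte)
    db_loc, em, alpha, corr, chi, curve = _field_stage(
        gre, mask, config, dte, phase_ref, inter)
    return PipelineResult(chi=chi, db_combined=db_loc, eroded_mask=em,
                          alpha=alpha, correction_factor=corr,
                          db_total=db_total, phi0=phi0.values,
                          lcurve=curve, intermediates=inter)


def _run_tewavg(gre, mask, config, dte, inter) -> PipelineResult:
    unwrapped = np.empty_like(gre.phase)
    for i in range(gre.n_echoes):
        unwrapped[..., i] = laplacian_unwrap(
            gre.phase[..., i], mask, tsvd_threshold=config.unwrap_threshold,
            voxel_size_mm=gre.voxel_size_mm)
    inter["unwrapped_phase"] = unwrapped
    db_total, weights = te_weighted_average(unwrapped, gre.echo_times_s)
    phase_ref = GAMMA * db_total.values * dte
    db_loc, em, alpha, corr, chi, curve = _field_stage(
        gre, mask, config, dte, phase_ref, inter)
    return PipelineResult(chi=chi, db_combined=db_loc, eroded_mask=em,
                          alpha=alpha, correction_factor=corr,
                          db_total=db_total, weights=weights,
                          lcurve=curve, intermediates=inter)


def _sharp_per_echo(gre, mask, config):
    loc_phase = np.empty_like(gre.phase)
    em = None
    for i in range(gre.n_echoes):
        loc, em = sharp(gre.phase[..., i], mask,
                        tsvd_threshold=config.sharp_threshold,
                        erode_voxels=config.erode_voxels,
                        voxel_size_mm=gre.voxel_size_mm)
        loc_phase[..., i] = loc.values
    return loc_phase, em


def _run_snrwavg(gre, mask, config, inter) -> PipelineResult:
    loc_phase, em = _sharp_per_echo(gre, mask, config)
    inter["local_phase"] = loc_phase
    relax = fit_r2star(gre.magnitude, gre.echo_times_s, em)
    db_loc, weights = snr_weighted_average(loc_phase, gre.echo_times_s,
                                           relax.r2star)
    db_loc = FieldMap(db_loc.values * em, units="tesla", role="local",
                      mask=em)
    alpha, curve = _choose_alpha(config, db_loc, em, gre)
    corr = _choose_correction(config, db_loc.values.shape, alpha, gre)
    chi = tikhonov_invert(db_loc, em, alpha=alpha, b0_tesla=gre.b0_tesla,
                          correction_factor=corr,
                          voxel_size_mm=gre.voxel_size_mm,
                          b0_direction=gre.b0_direction)
    return PipelineResult(chi=chi, db_combined=db_loc, eroded_mask=em,
                          alpha=alpha, correction_factor=corr,
                          r2star=relax, weights=weights, lcurve=curve,
                          intermediates=inter)


def _run_suscwavg(gre, mask, config, inter) -> PipelineResult:
    te = gre.echo_times_s
    loc_phase, em = _sharp_per_echo(gre, mask, config)
    inter["local_phase"] = loc_phase
    fields = [FieldMap(loc_phase[..., i] / (GAMMA * te[i]), units="tesla",
                       role="local", mask=em) for i in range(te.size)]
    if config.external_chi is not None:
        chi_stack = np.asarray(config.external_chi, dtype=float)
        mid = te.size // 2
        alpha, curve = _choose_alpha(config, fields[mid], em, gre)
        corr = 1.0  # external maps arrive on their own scale
    else:
        # one L-curve on the middle echo; alpha shared across echoes
        mid = te.size // 2
        alpha, curve = _choose_alpha(config, fields[mid], em, gre)
        corr = _choose_correction(config, gre.magnitude.shape[:-1], alpha, gre)
        chi_stack = np.stack([
            tikhonov_invert(fields[i], em, alpha=alpha,
                            b0_tesla=gre.b0_tesla, correction_factor=corr,
                            voxel_size_mm=gre.voxel_size_mm,
                            b0_direction=gre.b0_direction).chi
            for i in range(te.size)], axis=-1)
    inter["chi_per_echo"] = chi_stack
    chi_comb, weights = susceptibility_weighted_average(
        chi_stack, gre.magnitude, te, b0_tesla=gre.b0_tesla)
    chi = SusceptibilityMap(chi=chi_comb.chi * em, mask=em,
                            b0_tesla=gre.b0_tesla, alpha_used=alpha,
                            correction_factor=corr)
    # magnitude-weighted field combination, for noise bookkeeping
    db_comb = (weights.weights * loc_phase / (GAMMA * te)).sum(axis=-1) * em
    db_loc = FieldMap(db_comb, units="tesla", role="local", mask=em)
    return PipelineResult(chi=chi, db_combined=db_loc, eroded_mask=em,
                          alpha=alpha, correction_factor=corr,
                          weights=weights, chi_per_echo=chi_stack,
                          lcurve=curve, intermediates=inter)


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------

def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def write_volume(volume: np.ndarray, path: str | Path,
                 voxel_size_mm=(1.0, 1.0, 1.0)) -> Path:
    """Write a volume as float32 NIfTI with a diagonal affine."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(volume, dtype=np.float32),
                          _affine(voxel_size_mm))
    nib.save(img, str(path))
    return path


def write_gre(gre: MultiEchoGRE, out_dir: str | Path, prefix: str = "gre",
              seed: int | None = None) -> dict[str, Path]:
    """Write magnitude/phase 4D NIfTI pairs plus a JSON sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "magnitude": write_volume(gre.magnitude, out_dir / f"{prefix}_mag.nii.gz",
                                  gre.voxel_size_mm),
        "phase": write_volume(gre.phase, out_dir / f"{prefix}_phase.nii.gz",
                              gre.voxel_size_mm),
    }
    sidecar = {
        "echo_times_s": [float(t) for t in gre.echo_times_s],
        "b0_tesla": gre.b0_tesla,
        "b0_direction": [float(v) for v in gre.b0_direction],
    }
    if seed is not None:
        sidecar["seed"] = int(seed)
    sc = out_dir / f"{prefix}.json"
    sc.write_text(json.dumps(sidecar, indent=2))
    paths["sidecar"] = sc
    return paths


def read_gre(mag_path: str | Path, phase_path: str | Path,
             sidecar_path: str | Path) -> MultiEchoGRE:
    """Read a 4D magnitude/phase pair with its JSON sidecar.

    Phase is expected in radians; a nonnegative scaled-integer dialect
    (e.g. values in [0, 4095]) is auto-detected and rescaled to (-pi, pi]
    with a logged warning.
    """
    mag_img = nib.load(str(mag_path))
    phs_img = nib.load(str(phase_path))
    meta = json.loads(Path(sidecar_path).read_text())
    mag = np.asarray(mag_img.dataobj, dtype=float)
    phs = np.asarray(phs_img.dataobj, dtype=float)
    te = np.asarray(meta["echo_times_s"], dtype=float)
    if mag.ndim == 3:
        mag = mag[..., None]
        phs = phs[..., None]
    if mag.shape[-1] != te.size:
        raise ValueError("echo-count mismatch between volumes and sidecar")
    pmin, pmax = phs.min(), phs.max()
    if pmin >= 0 and pmax > np.pi + 1e-3:
        # scaled-integer dialect (e.g. [0, 4095]); the full range is taken
        # as the next power of two above the observed maximum
        full = 2.0 ** np.ceil(np.log2(np.floor(pmax) + 1.0))
        logger.warning("phase stored in scaled-integer dialect "
                       "[0, %g]; rescaling to (-pi, pi]", full - 1)
        phs = wrap_phase(phs * (2.0 * np.pi / full) - np.pi)
    vox = tuple(float(v) for v in mag_img.header.get_zooms()[:3])
    return MultiEchoGRE(mag, phs, te, voxel_size_mm=vox,
                        b0_tesla=float(meta.get("b0_tesla", 3.0)),
                        b0_direction=tuple(meta.get("b0_direction",
                                                    (0.0, 0.0, 1.0))))


def _write_result(result: PipelineResult, gre: MultiEchoGRE, out: Path,
                  name: str) -> None:
    out.mkdir(parents=True, exist_ok=True)
    v = gre.voxel_size_mm
    write_volume(result.chi.chi, out / f"{name}_chi.nii.gz", v)
    write_volume(result.db_combined.values, out / f"{name}_dbloc.nii.gz", v)
    write_volume(result.eroded_mask.astype(np.float32),
                 out / f"{name}_mask.nii.gz", v)
    if result.db_total is not None:
        write_volume(result.db_total.values, out / f"{name}_dbtot.nii.gz", v)
    meta = {"alpha": result.alpha,
            "correction_factor": result.correction_factor,
            "pipeline": name}
    (out / f"{name}_meta.json").write_text(json.dumps(meta, indent=2))
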