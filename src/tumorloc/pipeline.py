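"""End-to-end experiment orchestration.

``run_localization`` executes the full chain for one (CT, CBCT, GTV) triple:
coarse 5 mm registration, search-region construction, template matching with
the requested enhancement mode, Otsu binarization and centroid estimation.
``run_all`` drives whole experiments (three-station validation phantom, or
the 10-case x 4-fraction clinical-like cohort) and emits error records, the
statistical summary and a reproducibility manifest.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np

from . import __version__
from .config import PipelineConfig
from .evaluation import ErrorRecord, location_error, records_to_frame, summarize
from .matching import LocalizationResult, localize
from .phantom import (
    ClinicalCase,
    DegradationSpec,
    PhantomSpec,
    degrade_to_cbct,
    generate_case,
    make_clinical_like_cases,
    make_phantom_ct,
)
from .preprocess import preprocess_cbct
from .registration import TranslationResult, register_translation
from .volumes import GTVStructure, Volume, resample_isotropic

__all__ = ["run_localization", "run_phantom_experiment", "run_clinical_experiment",
           "run_all"]

log = logging.getLogger("tumorloc")


def coarse_register(ct1: Volume, cbct1: Volume,
                    coarse_spacing_mm: float = 5.0) -> TranslationResult:
    """Resample both volumes to the coarse grid (trilinear) and register."""
    ct5 = resample_isotropic(ct1, coarse_spacing_mm, method="trilinear")
    cbct5 = resample_isotropic(cbct1, coarse_spacing_mm, method="trilinear")
    return register_translation(ct5, cbct5)


def run_localization(ct1: Volume, cbct1: Volume, g: GTVStructure,
                     cfg: PipelineConfig, mode: str,
                     tr: TranslationResult | None = None,
                     cbct_pre: Volume | None = None) -> LocalizationResult:
    """Localize one tumor in one MV-CBCT with one template mode."""
    t0 = time.perf_counter()
    if tr is None:
        tr = coarse_register(ct1, cbct1, cfg.registration.coarse_spacing_mm)
    res = localize(
        ct1, cbct1, g, tr, mode=mode,
        gamma=cfg.enhance.gamma, sigma_mm=cfg.enhance.sigma_mm,
        dilation_px=cfg.registration.dilation_px,
        cbct_pre=cbct_pre,
        median_size=cfg.preprocess.median_size,
        log_sigma_px=cfg.preprocess.log_sigma_px,
        log_mode=cfg.preprocess.log_mode,
    )
    log.info("localize mode=%s box=%s-%s offset=%s score=%.3f (%.2f s)",
             mode, res.region.box_min, res.region.box_max,
             res.matched_offset, res.score, time.perf_counter() - t0)
    return res


def _phantom_shift(cfg: PipelineConfig, rng: np.random.Generator) -> tuple[float, float, float]:
    if cfg.phantom.shift_mm is not None:
        return tuple(float(v) for v in cfg.phantom.shift_mm)
    return tuple(float(v) for v in rng.uniform(-cfg.phantom.max_shift_mm,
                                               cfg.phantom.max_shift_mm, 3))


def run_phantom_experiment(cfg: PipelineConfig) -> list[ErrorRecord]:
    """Three-station validation phantom: one CT, one degraded CBCT with a
    known rigid shift, localization of each station with each mode."""
    rng = np.random.default_rng(cfg.seed)
    spec = PhantomSpec().default_validation_tumors(cfg.phantom.tumor_diameter_mm)
    ct, gtvs, truth = make_phantom_ct(spec)
    dspec = DegradationSpec(
        blur_fwhm_mm=cfg.phantom.blur_fwhm_mm, noise_sd=cfg.phantom.noise_sd,
        contrast_scale=cfg.phantom.contrast_scale, fov_mm=cfg.phantom.fov_mm,
        shift_mm=_phantom_shift(cfg, rng), seed=int(rng.integers(0, 2**31 - 1)),
    )
    cbct, record = degrade_to_cbct(ct, dspec)
    tr = coarse_register(ct, cbct, cfg.registration.coarse_spacing_mm)
    cbct_pre = preprocess_cbct(cbct, median_size=cfg.preprocess.median_size,
                               log_sigma_px=cfg.preprocess.log_sigma_px,
                               log_mode=cfg.preprocess.log_mode)
    shift = np.asarray(record["applied_shift_mm"])
    records: list[ErrorRecord] = []
    for g in gtvs:
        ref = np.asarray(truth[g.name]) + shift
        for mode in cfg.modes:
            res = run_localization(ct, cbct, g, cfg, mode, tr=tr, cbct_pre=cbct_pre)
            records.append(location_error(res.centroid_mm, ref, case=g.name,
                                          fraction=1, mode=mode))
    return records


def run_clinical_experiment(cfg: PipelineConfig) -> list[ErrorRecord]:
    """Clinical-like cohort: n cases x n fractions, every mode."""
    degradation = DegradationSpec(
        blur_fwhm_mm=cfg.phantom.blur_fwhm_mm, noise_sd=cfg.phantom.noise_sd,
        contrast_scale=cfg.phantom.contrast_scale, fov_mm=cfg.phantom.fov_mm,
    )
    cases = make_clinical_like_cases(
        n=cfg.phantom.n_cases, n_fractions=cfg.phantom.n_fractions,
        seed=cfg.seed, degradation=degradation,
        max_shift_mm=cfg.phantom.max_shift_mm,
    )
    records: list[ErrorRecord] = []
    for case in cases:
        ct, g, truth = generate_case(case)
        center = np.asarray(truth[case.tumor.station])
        for j, dspec in enumerate(case.fractions):
            cbct, record = degrade_to_cbct(ct, dspec)
            tr = coarse_register(ct, cbct, cfg.registration.coarse_spacing_mm)
            cbct_pre = preprocess_cbct(cbct, median_size=cfg.preprocess.median_size,
                                       log_sigma_px=cfg.preprocess.log_sigma_px,
                                       log_mode=cfg.preprocess.log_mode)
            ref = center + np.asarray(record["applied_shift_mm"])
            for mode in cfg.modes:
                res = run_localization(ct, cbct, g, cfg, mode, tr=tr, cbct_pre=cbct_pre)
                records.append(location_error(res.centroid_mm, ref,
                                              case=f"case{case.case_id:02d}",
                                              fraction=j + 1, mode=mode))
    return records


def run_all(cfg: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """Run the configured experiment end to end.

    Writes ``errors.csv`` (one row per case x fraction x mode),
    ``summary.json`` (per-mode statistics and pairwise t/F tests) and
    ``manifest.json`` (config hash, seed, versions) when ``outdir`` is given;
    bit-identical outputs for identical config + seed.
    """
    t0 = time.perf_counter()
    if cfg.phantom.experiment == "phantom":
        records = run_phantom_experiment(cfg)
    elif cfg.phantom.experiment == "clinical":
        records = run_clinical_experiment(cfg)
    else:
        raise ValueError(f"unknown experiment {cfg.phantom.experiment!r}")
    summary = summarize(records)
    result = {"records": records, "summary": summary,
              "elapsed_s": time.perf_counter() - t0}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        records_to_frame(records).to_csv(out / "errors.csv", index=False,
                                         float_format="%.6f")
        (out / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
        manifest = {
            "config": cfg.model_dump(),
            "config_hash": cfg.content_hash(),
            "seed": cfg.seed,
            "versions": {"tumorloc": __version__, "numpy": np.__version__},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      sort_keys=True, default=str))
    return result
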