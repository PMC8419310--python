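"""End-to-end driver: simulate -> invert -> masks -> statistics -> report.

Every artifact is written under one output directory with provenance (config
hash, seed, library versions). Re-running with the same configuration
reproduces all numeric outputs bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as nio
from .cohort import AnimalSession, CohortSpec, make_cohort
from .inversion import InversionConfig, ParameterMaps, invert
from .masks import (ATLAS_N_SLICES, LesionMaskSet, build_mask_set,
                    incidence_map, regional_incidence)
from .phantom import ATLAS_LABELS
from .stats import (EmptyRegionError, RegionSample, lesion_vs_rest,
                    percent_change_map, regional_mean, samples_frame,
                    summarize_cohort)

log = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class PipelineConfig:
    cohort: CohortSpec = field(default_factory=CohortSpec)
    inversion: InversionConfig = field(default_factory=InversionConfig)
    gd_threshold_pct: float = 15.0
    vsop_ratio_threshold: float = 0.8
    min_size_px: int = 5
    vsop_dilation_px: int = 2
    alpha_norm: float = 0.05
    render_figures: bool = True

    def config_hash(self) -> str:
        blob = json.dumps(nio._as_plain(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def session_region_masks(session: AnimalSession, mask_set: LesionMaskSet) -> dict:
    """Analysis regions for one animal: lesion classes and their complements.

    The parenchyma (brain minus ventricles) defines 'whole_brain'; the
    complements non_gd / non_vsop are the rest-of-brain references for the
    lesion-vs-rest contrasts.
    """
    parench = session.phantom_eae.brain & ~session.phantom_eae.ventricles
    return {
        "whole_brain": parench,
        "gd": mask_set.gd,
        "vsop": mask_set.vsop,
        "non_gd": parench & ~mask_set.gd,
        "non_vsop": parench & ~mask_set.vsop,
    }


def collect_samples(session: AnimalSession,
                    maps_b: ParameterMaps, maps_e: ParameterMaps,
                    regions: dict) -> list[RegionSample]:
    """Regional means for both metrics and timepoints; empty regions skipped
    with a log entry (that animal simply drops out of the region's pairing)."""
    out = []
    for tag, mask in regions.items():
        for metric in ("c", "phi"):
            for tp, maps in (("baseline", maps_b), ("eae", maps_e)):
                try:
                    out.append(regional_mean(maps, mask, metric,
                                             animal_id=session.animal_id,
                                             region_tag=tag, timepoint=tp))
                except EmptyRegionError as e:
                    log.info("skipped: %s", e)
    return out


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the full analysis; returns a dict of artifact paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"outdir": str(outdir)}
    nio.save_config(config, outdir / "config.yaml")
    provenance = {
        "config_hash": config.config_hash(),
        "seed": config.cohort.seed,
        "versions": {m.__name__: m.__version__ for m in
                     (np, pd, __import__("scipy"), __import__("nibabel"))},
    }
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2))

    # --- stage: simulate ---------------------------------------------------
    try:
        sessions = make_cohort(config.cohort)
    except Exception as e:
        raise PipelineStageError("simulate", e) from e

    # --- stage: invert -----------------------------------------------------
    maps = {}
    try:
        for s in sessions:
            brain_b = s.phantom_baseline.brain & ~s.phantom_baseline.ventricles
            brain_e = s.phantom_eae.brain & ~s.phantom_eae.ventricles
            maps[s.animal_id] = (
                invert(s.wavefield_baseline, config.inversion, brain_mask=brain_b),
                invert(s.wavefield_eae, config.inversion, brain_mask=brain_e),
            )
    except Exception as e:
        raise PipelineStageError("invert", e) from e

    # --- stage: masks ------------------------------------------------------
    try:
        mask_sets = {}
        for s in sessions:
            mask_sets[s.animal_id] = build_mask_set(
                s.gd_pair, s.vsop_pair,
                s.phantom_eae.brain, s.phantom_eae.ventricles,
                gd_threshold_pct=config.gd_threshold_pct,
                vsop_ratio_threshold=config.vsop_ratio_threshold,
                min_size_px=config.min_size_px,
                vsop_dilation_px=config.vsop_dilation_px)
        inc_gd = incidence_map([mask_sets[s.animal_id].gd for s in sessions], "gd")
        inc_vsop = incidence_map([mask_sets[s.animal_id].vsop for s in sessions], "vsop")
        spacing = sessions[0].phantom_eae.pixel_spacing_mm
        paths["incidence_gd"] = str(nio.write_nifti(
            outdir / "incidence_gd.nii.gz", inc_gd.percent, spacing, np.float32))
        paths["incidence_vsop"] = str(nio.write_nifti(
            outdir / "incidence_vsop.nii.gz", inc_vsop.percent, spacing, np.float32))
        atlas = sessions[0].phantom_eae.atlas
        reg_inc = regional_incidence(
            [mask_sets[s.animal_id].gd for s in sessions], atlas, ATLAS_LABELS
        ).rename(columns={"incidence_pct": "gd_mask"})
        reg_inc["vsop_mask"] = regional_incidence(
            [mask_sets[s.animal_id].vsop for s in sessions], atlas, ATLAS_LABELS
        )["incidence_pct"]
        paths["regional_incidence"] = str(outdir / "regional_incidence.csv")
        reg_inc.to_csv(paths["regional_incidence"], index=False)
    except Exception as e:
        raise PipelineStageError("masks", e) from e

    # representative parameter and percent-change maps (first animal)
    s0 = sessions[0]
    m_b, m_e = maps[s0.animal_id]
    paths["example_c_map"] = str(nio.write_nifti(
        outdir / "example_c_map_eae.nii.gz",
        np.where(m_e.valid_mask, m_e.c_map, np.nan), spacing, np.float32))
    paths["example_phi_map"] = str(nio.write_nifti(
        outdir / "example_phi_map_eae.nii.gz",
        np.where(m_e.valid_mask, m_e.phi_map, np.nan), spacing, np.float32))
    for metric in ("c", "phi"):
        paths[f"example_pct_change_{metric}"] = str(nio.write_nifti(
            outdir / f"example_pct_change_{metric}.nii.gz",
            percent_change_map(m_b, m_e, metric), spacing, np.float32))

    # --- stage: stats (degrades gracefully; maps already written) ----------
    stats_errors = {}
    samples: list[RegionSample] = []
    for s in sessions:
        m_b, m_e = maps[s.animal_id]
        samples += collect_samples(s, m_b, m_e,
                                   session_region_masks(s, mask_sets[s.animal_id]))
    df = samples_frame(samples)
    paths["samples"] = str(outdir / "samples.csv")
    df.to_csv(paths["samples"], index=False)
    try:
        summary = summarize_cohort(df, alpha_norm=config.alpha_norm)
        paths["summary"] = str(outdir / "summary.csv")
        summary.to_csv(paths["summary"], index=False)
    except Exception as e:
        stats_errors["summary"] = repr(e)
    contrasts = []
    for tag in ("gd", "vsop"):
        for metric in ("c", "phi"):
            try:
                r = lesion_vs_rest(df, tag, metric, alpha_norm=config.alpha_norm)
                t = r["test"]
                contrasts.append({
                    "region": tag, "metric": metric, "n": t.n,
                    "pct_lesion_mean": float(np.mean(r["pct_lesion"])),
                    "pct_lesion_sd": float(np.std(r["pct_lesion"], ddof=1)),
                    "pct_rest_mean": float(np.mean(r["pct_rest"])),
                    "pct_rest_sd": float(np.std(r["pct_rest"], ddof=1)),
                    "test_used": t.test_used, "p_value": t.p_value,
                })
            except (EmptyRegionError, ValueError) as e:
                stats_errors[f"lesion_vs_rest_{tag}_{metric}"] = repr(e)
    if contrasts:
        paths["lesion_vs_rest"] = str(outdir / "lesion_vs_rest.csv")
        pd.DataFrame(contrasts).to_csv(paths["lesion_vs_rest"], index=False)
    if stats_errors:
        paths["stats_errors"] = str(outdir / "stats_errors.json")
        (outdir / "stats_errors.json").write_text(json.dumps(stats_errors, indent=2))
        log.warning("stats stage reported errors: %s", stats_errors)

    # --- stage: report -----------------------------------------------------
    if config.render_figures:
        try:
            from .report import render_report
            paths.update(render_report(outdir))
        except Exception as e:
            raise PipelineStageError("report", e) from e
    return paths
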