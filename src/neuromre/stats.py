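"""Regional statistics: masked means, percent changes and paired testing.

The testing procedure reproduces the GraphPad-style analysis convention:
normality of each compared group is checked with the D'Agostino-Pearson K^2
omnibus test; if both groups pass (p >= alpha), a two-sided paired t-test is
used, otherwise the Wilcoxon matched-pairs signed-rank test (zero differences
dropped, exact null distribution for n <= 25). Reported p-values are
unadjusted, one test per comparison.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .inversion import ParameterMaps

log = logging.getLogger(__name__)

REGION_TAGS = ("whole_brain", "gd", "vsop", "non_gd", "non_vsop")
METRICS = ("c", "phi")


class EmptyRegionError(ValueError):
    """A mask does not intersect the valid pixels of a parameter map."""


@dataclass
class RegionSample:
    animal_id: str
    region_tag: str
    timepoint: str           # 'baseline' | 'eae'
    metric: str              # 'c' | 'phi'
    value: float
    n_valid_px: int


@dataclass
class PairedTestResult:
    test_used: str           # 'paired_t' | 'wilcoxon_signed_rank'
    statistic: float
    p_value: float
    n: int
    normality_p_group1: float
    normality_p_group2: float
    mean_sd_group1: tuple[float, float]
    mean_sd_group2: tuple[float, float]
    note: str = ""


def regional_mean(maps: ParameterMaps, mask: np.ndarray, metric: str,
                  animal_id: str = "", region_tag: str = "",
                  timepoint: str = "") -> RegionSample:
    """Mean of a parameter map over mask ∩ valid pixels.

    Ventricles never contribute: they are excluded from the validity mask at
    inversion time (no shear-wave propagation in fluid).
    """
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    img = maps.c_map if metric == "c" else maps.phi_map
    sel = np.asarray(mask, dtype=bool) & maps.valid_mask
    n = int(sel.sum())
    if n == 0:
        raise EmptyRegionError(
            f"no valid pixels for animal={animal_id!r} region={region_tag!r} "
            f"timepoint={timepoint!r}")
    return RegionSample(animal_id=animal_id, region_tag=region_tag,
                        timepoint=timepoint, metric=metric,
                        value=float(img[sel].mean()), n_valid_px=n)


def percent_change(baseline: RegionSample, eae: RegionSample) -> float:
    """Relative change in percent, 100 * (eae - baseline) / baseline."""
    for f in ("animal_id", "region_tag", "metric"):
        if getattr(baseline, f) != getattr(eae, f):
            raise ValueError(f"baseline and EAE samples differ in {f}")
    if baseline.value <= 0:
        raise ValueError("percent change undefined for non-positive baseline")
    return 100.0 * (eae.value - baseline.value) / baseline.value


def dagostino_pearson_p(x: np.ndarray) -> float:
    """p-value of the D'Agostino-Pearson K^2 omnibus normality test."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-n kurtosis-test warning
        return float(sps.normaltest(np.asarray(x, dtype=float)).pvalue)


def paired_compare(group1, group2, alpha_norm: float = 0.05) -> PairedTestResult:
    """Normality-gated paired comparison of two matched groups.

    Groups are paired by position (one entry per animal). With n < 8 the
    omnibus normality test is undefined; the gate is skipped with a warning
    and the rank test is used.
    """
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.shape != g2.shape or g1.ndim != 1:
        raise ValueError("groups must be 1D and equally sized (paired)")
    n = g1.size
    if n < 2:
        raise ValueError("paired comparison needs at least 2 pairs")
    note = ""
    if n < 8:
        p1 = p2 = float("nan")
        use_t = False
        note = "n < 8: normality gate skipped, Wilcoxon used"
        log.warning(note)
    else:
        p1 = dagostino_pearson_p(g1)
        p2 = dagostino_pearson_p(g2)
        use_t = (p1 >= alpha_norm) and (p2 >= alpha_norm)

    diffs = g2 - g1
    if np.all(diffs == 0):
        return PairedTestResult(
            test_used="paired_t" if use_t else "wilcoxon_signed_rank",
            statistic=float("nan"), p_value=float("nan"), n=n,
            normality_p_group1=p1, normality_p_group2=p2,
            mean_sd_group1=(float(g1.mean()), float(g1.std(ddof=1))),
            mean_sd_group2=(float(g2.mean()), float(g2.std(ddof=1))),
            note="all paired differences are zero; p undefined")

    if use_t:
        res = sps.ttest_rel(g2, g1)
        test_used = "paired_t"
    else:
        nz = diffs[diffs != 0]  # classical Wilcoxon: drop zero differences
        method = "exact" if nz.size <= 25 else "approx"
        res = sps.wilcoxon(nz, zero_method="wilcox", method=method)
        test_used = "wilcoxon_signed_rank"
    return PairedTestResult(
        test_used=test_used, statistic=float(res.statistic),
        p_value=float(res.pvalue), n=n,
        normality_p_group1=p1, normality_p_group2=p2,
        mean_sd_group1=(float(g1.mean()), float(g1.std(ddof=1))),
        mean_sd_group2=(float(g2.mean()), float(g2.std(ddof=1))),
        note=note)


def percent_change_map(maps_baseline: ParameterMaps, maps_eae: ParameterMaps,
                       metric: str = "c") -> np.ndarray:
    """Voxelwise percent change on the joint valid mask (NaN elsewhere)."""
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    b = maps_baseline.c_map if metric == "c" else maps_baseline.phi_map
    e = maps_eae.c_map if metric == "c" else maps_eae.phi_map
    if b.shape != e.shape:
        raise ValueError("maps are not co-registered")
    ok = maps_baseline.valid_mask & maps_eae.valid_mask & (b > 0)
    out = np.full(b.shape, np.nan)
    out[ok] = 100.0 * (e[ok] - b[ok]) / b[ok]
    return out


def samples_frame(samples: list[RegionSample]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in samples])


def _paired_values(df: pd.DataFrame, region: str, metric: str):
    """Baseline/EAE value arrays paired by animal; animals missing either
    timepoint are dropped with a log entry."""
    sub = df[(df.region_tag == region) & (df.metric == metric)]
    piv = sub.pivot_table(index="animal_id", columns="timepoint",
                          values="value", aggfunc="first")
    if "baseline" not in piv or "eae" not in piv:
        raise EmptyRegionError(f"no paired data for region={region!r} metric={metric!r}")
    full = piv.dropna(subset=["baseline", "eae"])
    dropped = sorted(set(piv.index) - set(full.index))
    if dropped:
        log.info("region %s/%s: dropped animals without both timepoints: %s",
                 region, metric, dropped)
    return full["baseline"].to_numpy(), full["eae"].to_numpy(), list(full.index)


def lesion_vs_rest(df: pd.DataFrame, region_tag: str, metric: str,
                   alpha_norm: float = 0.05) -> dict:
    """Compare per-animal percent changes inside a lesion class vs the rest.

    The complement region is ``non_gd`` / ``non_vsop`` (brain minus that
    lesion class minus ventricles). Animals lacking the lesion region are
    dropped and reported in ``n``.
    """
    rest_tag = "non_gd" if region_tag == "gd" else "non_vsop"
    bl, el, ids_l = _paired_values(df, region_tag, metric)
    br, er, ids_r = _paired_values(df, rest_tag, metric)
    common = sorted(set(ids_l) & set(ids_r))
    if len(common) < 2:
        raise EmptyRegionError(
            f"need >= 2 animals with region {region_tag!r}; have {len(common)}")
    il = [ids_l.index(a) for a in common]
    ir = [ids_r.index(a) for a in common]
    pct_lesion = 100.0 * (el[il] - bl[il]) / bl[il]
    pct_rest = 100.0 * (er[ir] - br[ir]) / br[ir]
    test = paired_compare(pct_rest, pct_lesion, alpha_norm=alpha_norm)
    return {"region": region_tag, "metric": metric, "animals": common,
            "pct_lesion": pct_lesion, "pct_rest": pct_rest, "test": test}


def summarize_cohort(df: pd.DataFrame, regions=REGION_TAGS, metrics=METRICS,
                     alpha_norm: float = 0.05) -> pd.DataFrame:
    """One row per (region, metric): group means +- sd, percent change, test."""
    rows = []
    for region in regions:
        for metric in metrics:
            try:
                b, e, ids = _paired_values(df, region, metric)
            except EmptyRegionError:
                continue
            if len(ids) < 2:
                continue
            test = paired_compare(b, e, alpha_norm=alpha_norm)
            pct = 100.0 * (e - b) / b
            rows.append({
                "region": region, "metric": metric, "n": len(ids),
                "baseline_mean": b.mean(), "baseline_sd": b.std(ddof=1),
                "eae_mean": e.mean(), "eae_sd": e.std(ddof=1),
                "pct_change_mean": pct.mean(), "pct_change_sd": pct.std(ddof=1),
                "test_used": test.test_used, "statistic": test.statistic,
                "p_value": test.p_value,
                "normality_p_baseline": test.normality_p_group1,
                "normality_p_eae": test.normality_p_group2,
            })
    return pd.DataFrame(rows)
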