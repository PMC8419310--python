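"""Figure and markdown report rendering. No analysis logic lives here."""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as nio

DPI = 120


def _mid_slice(vol: np.ndarray) -> np.ndarray:
    return vol[vol.shape[0] // 2]


def render_report(results_dir, out_dir=None) -> dict:
    """Render incidence maps, group box plots and percent-change maps from a
    completed results directory; writes report.md embedding the config hash."""
    results_dir = Path(results_dir)
    out_dir = Path(out_dir) if out_dir else results_dir
    out_dir.mkdir(parents=True, exist_ok=True)
    missing = [f for f in ("incidence_gd.nii.gz", "samples.csv") if
               not (results_dir / f).exists()]
    if missing:
        raise FileNotFoundError(f"report inputs missing from {results_dir}: {missing}")
    paths = {}

    # incidence maps, 0-100% colour scale
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, name in zip(axes, ("gd", "vsop")):
        vol, _ = nio.read_nifti(results_dir / f"incidence_{name}.nii.gz")
        im = ax.imshow(_mid_slice(vol), vmin=0, vmax=100, cmap="hot")
        ax.set_title(f"{name} incidence (% of animals)")
        ax.axis("off")
        fig.colorbar(im, ax=ax, fraction=0.04)
    fig.tight_layout()
    paths["fig_incidence"] = str(out_dir / "fig_incidence.png")
    fig.savefig(paths["fig_incidence"], dpi=DPI)
    plt.close(fig)

    # group comparisons: one panel per (region, metric)
    df = pd.read_csv(results_dir / "samples.csv")
    combos = sorted(set(zip(df.region_tag, df.metric)))
    ncols = 2
    nrows = (len(combos) + 1) // ncols
    fig, axes = plt.subplots(nrows, ncols, figsize=(8, 2.6 * nrows), squeeze=False)
    for ax, (region, metric) in zip(axes.ravel(), combos):
        sub = df[(df.region_tag == region) & (df.metric == metric)]
        data = [sub[sub.timepoint == tp].value.to_numpy()
                for tp in ("baseline", "eae")]
        ax.boxplot(data, tick_labels=["baseline", "EAE"])
        unit = "m/s" if metric == "c" else "rad"
        ax.set_title(f"{region} — {metric} ({unit})", fontsize=9)
    for ax in axes.ravel()[len(combos):]:
        ax.axis("off")
    fig.tight_layout()
    paths["fig_groups"] = str(out_dir / "fig_group_comparisons.png")
    fig.savefig(paths["fig_groups"], dpi=DPI)
    plt.close(fig)

    # percent-change maps
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.2))
    for ax, metric in zip(axes, ("c", "phi")):
        f = results_dir / f"example_pct_change_{metric}.nii.gz"
        if f.exists():
            vol, _ = nio.read_nifti(f)
            im = ax.imshow(_mid_slice(vol), vmin=-30, vmax=30, cmap="RdBu_r")
            fig.colorbar(im, ax=ax, fraction=0.04)
        ax.set_title(f"% change, {metric}-map")
        ax.axis("off")
    fig.tight_layout()
    paths["fig_pct_change"] = str(out_dir / "fig_pct_change_maps.png")
    fig.savefig(paths["fig_pct_change"], dpi=DPI)
    plt.close(fig)

    cfg_hash = "unknown"
    prov = results_dir / "provenance.json"
    if prov.exists():
        cfg_hash = json.loads(prov.read_text()).get("config_hash", "unknown")
    lines = [
        "# Cohort analysis report", "",
        f"Configuration hash: `{cfg_hash}`", "",
        "![incidence](fig_incidence.png)", "",
        "![groups](fig_group_comparisons.png)", "",
        "![pct change](fig_pct_change_maps.png)", "",
    ]
    summary = results_dir / "summary.csv"
    if summary.exists():
        lines += ["## Group summary", "",
                  pd.read_csv(summary).round(4).to_markdown(index=False), ""]
    lvr = results_dir / "lesion_vs_rest.csv"
    if lvr.exists():
        lines += ["## Lesion vs rest-of-brain percent changes", "",
                  pd.read_csv(lvr).round(4).to_markdown(index=False), ""]
    paths["report_md"] = str(out_dir / "report.md")
    Path(paths["report_md"]).write_text("\n".join(lines))
    return paths
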