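"""Render the figure report from the staged results directory.

Produces incidence-map panels, baseline-vs-EAE box plots per region and
metric, and representative percent-change maps, plus a markdown summary. The
rendering step contains no analysis logic; it only draws what stages 01-04
computed.
"""

import hashlib
import json
from pathlib import Path

import numpy as np

from neuromre import io as nio
from neuromre.stats import percent_change_map
from neuromre.report import render_report

ROOT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    manifest = nio.read_manifest(ROOT / "manifest.csv")
    first_id = sorted(manifest.animal_id)[0]
    first = manifest[manifest.animal_id == first_id].set_index("timepoint")

    import importlib.util
    spec = importlib.util.spec_from_file_location(
        "stage04", Path(__file__).parent / "04_regional_stats.py")
    stage04 = importlib.util.module_from_spec(spec)
    spec.loader.exec_module(stage04)
    maps = {tp: stage04.load_maps(first.loc[tp].rename(first.loc[tp].name))
            for tp in ("baseline", "eae")}
    sp = maps["eae"].pixel_spacing_mm
    for metric in ("c", "phi"):
        pct = percent_change_map(maps["baseline"], maps["eae"], metric)
        nio.write_nifti(ROOT / f"example_pct_change_{metric}.nii.gz", pct,
                        sp, np.float32)

    cfg_hash = hashlib.sha256(
        (ROOT / "cohort_spec.yaml").read_bytes()
        + (ROOT / "inversion_config.yaml").read_bytes()).hexdigest()[:16]
    (ROOT / "provenance.json").write_text(json.dumps({"config_hash": cfg_hash}))

    paths = render_report(ROOT)
    for k, p in paths.items():
        print(f"{k}: {p}")


if __name__ == "__main__":
    main()
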