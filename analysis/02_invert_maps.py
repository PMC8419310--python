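"""Invert every session's wave images into stiffness (c) and fluidity (phi)
maps.

Reads the cohort manifest written by 01_simulate_cohort.py, runs the
multifrequency wavenumber inversion and the Laplacian loss-angle inversion
with the default configuration, and writes c/phi/validity volumes next to
each session.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from neuromre import io as nio
from neuromre.inversion import InversionConfig, invert

ROOT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    manifest = nio.read_manifest(ROOT / "manifest.csv")
    cfg = InversionConfig()
    nio.save_config(cfg, ROOT / "inversion_config.yaml")
    for _, row in manifest.iterrows():
        wf = nio.load_wavefield(pd.read_csv(row.wavefield_manifest_path))
        brain, _ = nio.read_nifti(row.brain_path)
        vents, _ = nio.read_nifti(row.ventricles_path)
        pm = invert(wf, cfg, brain_mask=(brain > 0) & ~(vents > 0))
        out = Path(row.wavefield_manifest_path).parent
        sp = wf.pixel_spacing_mm
        nio.write_nifti(out / "c_map.nii.gz", pm.c_map, sp, np.float32)
        nio.write_nifti(out / "phi_map.nii.gz", pm.phi_map, sp, np.float32)
        nio.write_nifti(out / "valid_mask.nii.gz", pm.valid_mask, sp)
        v = pm.valid_mask
        print(f"{row.animal_id}/{row.timepoint}: median c = "
              f"{np.median(pm.c_map[v]):.3f} m/s, median phi = "
              f"{np.median(pm.phi_map[v]):.3f} rad over {int(v.sum())} px")
    print("\nparameter maps written for every session")


if __name__ == "__main__":
    main()
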