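"""Build lesion masks from the contrast images and compute incidence maps.

Per animal (EAE timepoint): threshold the percent-change T1 map into a Gd
mask, threshold the post/pre T2* ratio into a VSOP mask, dilate the VSOP mask
by two pixels, enforce mutual exclusion, remove ventricles. Then cohort-level
voxelwise incidence maps (native grid and resampled to the 215-slice atlas
spacing) and the per-region incidence table.
"""

from pathlib import Path

import numpy as np

from neuromre import io as nio
from neuromre.contrast import ContrastImagePair
from neuromre.masks import build_mask_set, incidence_map, regional_incidence, \
    resample_slices
from neuromre.phantom import ATLAS_LABELS

ROOT = Path(__file__).resolve().parents[1] / "results" / "cohort"


def main():
    manifest = nio.read_manifest(ROOT / "manifest.csv")
    eae = manifest[manifest.timepoint == "eae"]
    gd_masks, vsop_masks = [], []
    spacing = None
    atlas = None
    for _, row in eae.iterrows():
        brain = nio.read_nifti(row.brain_path)[0] > 0
        vents = nio.read_nifti(row.ventricles_path)[0] > 0
        pairs = {}
        for name, modality in (("gd", "t1_gbca"), ("vsop", "t2star_vsop")):
            pre, sp = nio.read_nifti(getattr(row, f"{name}_pre_path"))
            post, _ = nio.read_nifti(getattr(row, f"{name}_post_path"))
            pairs[name] = ContrastImagePair(pre=pre, post=post, modality=modality,
                                            pixel_spacing_mm=sp)
            spacing = sp
        ms = build_mask_set(pairs["gd"], pairs["vsop"], brain, vents)
        adir = Path(row.brain_path).parent
        nio.write_nifti(adir / "gd_mask.nii.gz", ms.gd, spacing)
        nio.write_nifti(adir / "vsop_mask.nii.gz", ms.vsop, spacing)
        gd_masks.append(ms.gd)
        vsop_masks.append(ms.vsop)
        if atlas is None:
            atlas = nio.read_nifti(adir / "atlas.nii.gz")[0].astype(np.int16)
        print(f"{row.animal_id}: gd mask {int(ms.gd.sum())} px, "
              f"vsop mask {int(ms.vsop.sum())} px")

    for name, masks in (("gd", gd_masks), ("vsop", vsop_masks)):
        inc = incidence_map(masks, name)
        nio.write_nifti(ROOT / f"incidence_{name}.nii.gz", inc.percent,
                        spacing, np.float32)
        atlas_grid = resample_slices(inc.percent, spacing[0], method="nearest")
        nio.write_nifti(ROOT / f"incidence_{name}_atlas.nii.gz", atlas_grid,
                        (spacing[0] * inc.percent.shape[0] / atlas_grid.shape[0],
                         spacing[1], spacing[2]), np.float32)
        print(f"{name}: peak incidence {inc.percent.max():.0f}% of animals")

    table = regional_incidence(gd_masks, atlas, ATLAS_LABELS)
    table = table.rename(columns={"incidence_pct": "gd_mask"})
    table["vsop_mask"] = regional_incidence(vsop_masks, atlas,
                                            ATLAS_LABELS)["incidence_pct"]
    table.to_csv(ROOT / "regional_incidence.csv", index=False)
    print("\nregional incidence (% of animals with any mask voxel in region):")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
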