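"""Quantify every image through its label mask into one merged cell
table (mean marker intensity, centroid, area per cell)."""

import sys
from pathlib import Path

import pandas as pd
import tifffile

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import SCRATCH

from imcrecur.quantify import merge_images, quantify_image


def main():
    panel = pd.read_csv(SCRATCH / "panel.csv")["marker_name"].tolist()
    clinical = pd.read_csv(SCRATCH / "clinical.csv")
    tables = []
    for row in clinical.itertuples():
        image = tifffile.imread(SCRATCH / "images" / f"{row.image_id}.tiff")
        mask = tifffile.imread(SCRATCH / "masks" / f"{row.image_id}_mask.tiff")
        tables.append(
            quantify_image(image, mask, panel, row.image_id, row.patient_id, row.batch)
        )
    cells = merge_images(tables)
    cells.to_csv(SCRATCH / "cells_raw.csv", index=False)
    print(f"quantified {len(cells)} cells from {len(tables)} images "
          f"-> {SCRATCH / 'cells_raw.csv'}")


if __name__ == "__main__":
    main()
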