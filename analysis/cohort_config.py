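"""Shared configuration for the analysis drivers.

The simulated study mirrors the cohort design (36 patients, 17
recurrent, 1-3 images each, two acquisition batches with a x1.5
intensity shift, planted vimentin-high epithelial depletion in
recurrent tumors) at desk scale: ~150-230 cells per 384x384 px image so
the full driver chain runs in minutes on one CPU.
"""

from pathlib import Path

from imcrecur.synthetic_cohort import CohortConfig

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "cohort"
RESULTS = ROOT / "results"

SEED = 20260919


def desk_scale_config(seed: int = SEED) -> CohortConfig:
    return CohortConfig(
        n_patients=36,
        n_recurrent=17,
        cells_per_image=(150, 230),
        image_size_px=(384, 384),
        contact_fraction=0.4,
        seed=seed,
    )
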