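"""Synthetic multiplexed-image cohort with planted effects.

Emulates an imaging-mass-cytometry study of low-stage endometrial
tumors: ~36 patients (17 recurrent), 1-3 tissue-core images per patient
acquired in two batches with a multiplicative inter-batch intensity
shift, 21-marker log-normal intensity profiles per cell phenotype, an
enrichment of a vimentin+/ER+/PR+ epithelial phenotype in non-recurrent
patients, and survival times tied to recurrence. Cells are rasterized
as non-overlapping disks on a jittered grid; a configurable fraction of
cells is placed in surface contact to exercise neighborhood analysis.

Two generation paths share the same samplers: ``simulate_cell_table``
draws the single-cell statistical structure only (fast; no images) and
``simulate_cohort`` additionally rasterizes images and label masks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from imcrecur.markers import CLUSTERING_MARKERS

__all__ = [
    "PhenotypeSpec",
    "SurvivalConfig",
    "CohortConfig",
    "SyntheticTruth",
    "SimulatedCohort",
    "default_phenotypes",
    "simulate_cell_table",
    "simulate_cohort",
    "simulate_survival_times",
    "place_cells",
    "write_cohort",
]

# log-intensity levels (natural log of raw counts)
_HI = math.log(30.0)  # strongly expressed marker
_MID = math.log(8.0)  # moderately expressed
_LO = math.log(1.5)  # background


@dataclass
class PhenotypeSpec:
    """One cell phenotype: a log-normal intensity profile plus its
    abundance and the abundance shift planted in recurrent patients."""

    name: str
    lineage: str  # epithelial | stromal | immune | endothelial
    mean_log_intensity: dict[str, float]
    sd_log_intensity: float | dict[str, float] = 0.35
    baseline_fraction: float = 0.0
    fraction_shift_recurrent: float = 0.0

    def mean_vector(self, panel: list[str]) -> np.ndarray:
        return np.array([self.mean_log_intensity.get(m, _LO) for m in panel])

    def sd_vector(self, panel: list[str]) -> np.ndarray:
        if isinstance(self.sd_log_intensity, dict):
            sd = np.array([self.sd_log_intensity.get(m, 0.35) for m in panel])
        else:
            sd = np.full(len(panel), float(self.sd_log_intensity))
        if np.any(sd <= 0):
            raise ValueError(f"{self.name}: sd_log_intensity must be positive")
        return sd


def default_phenotypes() -> list[PhenotypeSpec]:
    """Eight phenotypes spanning the tissue compartments.

    The vimentin-high epithelial phenotype (vimentin+/cytokeratin+/
    E-cadherin+/ER+/PR+) is depleted by 0.15 in recurrent patients and
    the vimentin-low epithelial phenotype enriched by the same amount,
    mirroring the direction of the planted prognostic effect.
    """
    return [
        PhenotypeSpec(
            "epi_vim_high",
            "epithelial",
            {
                "cytokeratin": _HI, "Ecad": _HI, "vimentin": _HI,
                "ER": _HI, "PR": _HI, "Bcatenin": _MID, "Ki67": _MID,
            },
            baseline_fraction=0.30,
            fraction_shift_recurrent=-0.15,
        ),
        PhenotypeSpec(
            "epi_vim_low",
            "epithelial",
            {
                "cytokeratin": _HI, "Ecad": _HI, "vimentin": _LO,
                "ER": _MID, "PR": _LO, "Bcatenin": _MID, "p53": _MID, "Ki67": _MID,
            },
            baseline_fraction=0.25,
            fraction_shift_recurrent=0.15,
        ),
        PhenotypeSpec(
            "stromal_asma",
            "stromal",
            {"aSMA": _HI, "vimentin": _HI, "collagenI": _HI, "podoplanin": _MID},
            baseline_fraction=0.20,
        ),
        PhenotypeSpec(
            "endothelial",
            "endothelial",
            {"CD31": _HI, "vimentin": _MID, "VEGF": _MID},
            baseline_fraction=0.05,
        ),
        PhenotypeSpec(
            "t_cd8",
            "immune",
            {"CD45": _HI, "CD3": _HI, "CD8a": _HI, "vimentin": _MID},
            baseline_fraction=0.07,
        ),
        PhenotypeSpec(
            "t_cd4",
            "immune",
            {"CD45": _HI, "CD3": _HI, "CD4": _HI, "vimentin": _MID},
            baseline_fraction=0.06,
        ),
        PhenotypeSpec(
            "macrophage",
            "immune",
            {"CD45": _HI, "CD68": _HI, "vimentin": _MID},
            baseline_fraction=0.04,
        ),
        PhenotypeSpec(
            "b_cell",
            "immune",
            {"CD45": _HI, "CD20": _HI},
            baseline_fraction=0.03,
        ),
    ]


@dataclass
class SurvivalConfig:
    """Event times are exponential for recurrent patients (median 18
    months, matching the cohort's median time to recurrence); censoring
    times are uniform for non-recurrent patients."""

    median_event_months: float = 18.0
    censor_months: tuple[float, float] = (24.0, 120.0)


@dataclass
class CohortConfig:
    n_patients: int = 36
    n_recurrent: int = 17
    images_per_patient: tuple[int, int] = (1, 3)
    # weights over image counts 1..3; defaults mirror a cohort with six
    # single-image, twenty-nine two-image and one three-image tumor
    image_count_weights: tuple[float, ...] = (6.0, 29.0, 1.0)
    cells_per_image: tuple[int, int] = (1200, 2000)
    image_size_px: tuple[int, int] = (1024, 1024)
    cell_radius_px: tuple[float, float] = (3.0, 5.0)
    contact_fraction: float = 0.25
    n_batches: int = 2
    batch_scale_factors: dict[str, float | dict[str, float]] = field(
        default_factory=lambda: {"B1": 1.0, "B2": 1.5}
    )
    panel: list[str] = field(default_factory=lambda: list(CLUSTERING_MARKERS))
    phenotypes: list[PhenotypeSpec] = field(default_factory=default_phenotypes)
    # Dirichlet concentration controlling patient-to-patient composition noise
    patient_dispersion: float = 150.0
    survival: SurvivalConfig = field(default_factory=SurvivalConfig)
    seed: int = 0

    def __post_init__(self):
        if self.n_recurrent > self.n_patients:
            raise ValueError("n_recurrent cannot exceed n_patients")
        panel = set(self.panel)
        for ph in self.phenotypes:
            unknown = set(ph.mean_log_intensity) - panel
            if unknown:
                raise ValueError(f"{ph.name}: markers {sorted(unknown)} not in panel")
            ph.sd_vector(self.panel)  # validates sd > 0
        if len(self.image_count_weights) != self.images_per_patient[1] - self.images_per_patient[0] + 1:
            raise ValueError("image_count_weights must cover the images_per_patient range")

    def group_fractions(self, recurrent: bool) -> np.ndarray:
        """Phenotype fractions for a patient group, shift applied and
        renormalized to sum to 1."""
        f = np.array([p.baseline_fraction for p in self.phenotypes], dtype=float)
        if recurrent:
            f = f + np.array([p.fraction_shift_recurrent for p in self.phenotypes])
        if np.any(f < 0):
            raise ValueError("shifted fractions must be non-negative")
        if f.sum() <= 0:
            raise ValueError("fractions sum to zero")
        return f / f.sum()

    def batch_factor_vector(self, batch: str) -> np.ndarray:
        fac = self.batch_scale_factors[batch]
        if isinstance(fac, dict):
            return np.array([fac.get(m, 1.0) for m in self.panel])
        return np.full(len(self.panel), float(fac))


@dataclass
class SyntheticTruth:
    """Ground truth for recovery tests: per-cell phenotype and true mean
    intensity, per-patient group and planted composition, batch factors."""

    cells: pd.DataFrame  # patient_id, image_id, cell_id, phenotype + true_<marker>
    patients: pd.DataFrame  # patient_id, recurrent, composition per phenotype
    batch_factors: pd.DataFrame  # batch x marker
    contacts: pd.DataFrame | None = None  # image_id, cell_a, cell_b planted contacts


@dataclass
class SimulatedCohort:
    images: dict[str, np.ndarray]  # image_id -> (C, H, W) float32
    masks: dict[str, np.ndarray]  # image_id -> (H, W) uint16
    panel: pd.DataFrame  # channel_index, marker_name
    clinical: pd.DataFrame  # patient_id, image_id, batch, recurrent, time_months, event
    truth: SyntheticTruth


def _spawn(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), *map(int, key)]))


def _patient_layout(config: CohortConfig) -> pd.DataFrame:
    """Deterministic per-image layout: patients, groups, image counts,
    cell counts, batches, survival times."""
    rng = _spawn(config.seed, 0)
    rows = []
    lo, hi = config.images_per_patient
    w = np.array(config.image_count_weights, dtype=float)
    w = w / w.sum()
    n_img_choices = np.arange(lo, hi + 1)
    batches = [f"B{i + 1}" for i in range(config.n_batches)]
    surv = config.survival
    scale = surv.median_event_months / math.log(2)
    for i in range(config.n_patients):
        pid = f"P{i + 1:03d}"
        recurrent = i < config.n_recurrent
        n_img = int(rng.choice(n_img_choices, p=w))
        if recurrent:
            t = float(rng.exponential(scale))
            t = max(t, 0.5)
            ev = 1
        else:
            t = float(rng.uniform(*surv.censor_months))
            ev = 0
        for j in range(n_img):
            rows.append(
                {
                    "patient_id": pid,
                    "image_id": f"{pid}_img{j + 1}",
                    "batch": batches[min(j, len(batches) - 1)],
                    "recurrent": int(recurrent),
                    "time_months": round(t, 3),
                    "event": ev,
                    "n_cells": int(rng.integers(config.cells_per_image[0],
                                                config.cells_per_image[1] + 1)),
                }
            )
    return pd.DataFrame(rows)


def _sample_cells_for_image(
    config: CohortConfig,
    composition: np.ndarray,
    batch: str,
    n_cells: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (phenotype index, true intensity matrix) for one image.
    True intensity already includes the batch factor."""
    pheno_idx = rng.choice(len(config.phenotypes), size=n_cells, p=composition)
    means = np.stack([p.mean_vector(config.panel) for p in config.phenotypes])
    sds = np.stack([p.sd_vector(config.panel) for p in config.phenotypes])
    logs = rng.normal(means[pheno_idx], sds[pheno_idx])
    raw = np.exp(logs) * config.batch_factor_vector(batch)[None, :]
    return pheno_idx, raw


def simulate_cell_table(config: CohortConfig) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Fast path: the cohort's single-cell table without rasterized
    images. Identical config + seed gives identical output.

    Returns (cells, truth); *cells* has the same identity and marker
    columns a quantified image stack would produce (x, y, area absent).
    """
    layout = _patient_layout(config)
    cell_frames, truth_frames, patient_rows = [], [], []
    for pid, pat in layout.groupby("patient_id", sort=True):
        recurrent = bool(pat["recurrent"].iloc[0])
        comp_rng = _spawn(config.seed, 1, _pid_key(pid))
        base = config.group_fractions(recurrent)
        composition = comp_rng.dirichlet(base * config.patient_dispersion)
        patient_rows.append(
            {"patient_id": pid, "recurrent": int(recurrent),
             **{config.phenotypes[k].name: composition[k] for k in range(len(composition))}}
        )
        for _, img in pat.iterrows():
            rng = _spawn(config.seed, 2, _pid_key(pid), _img_key(img["image_id"]))
            pheno_idx, raw = _sample_cells_for_image(
                config, composition, img["batch"], img["n_cells"], rng
            )
            n = len(pheno_idx)
            base_df = pd.DataFrame(
                {
                    "cell_id": np.arange(1, n + 1),
                    "image_id": img["image_id"],
                    "patient_id": pid,
                    "batch": img["batch"],
                }
            )
            cell_frames.append(
                pd.concat([base_df, pd.DataFrame(raw, columns=config.panel)], axis=1)
            )
            truth_frames.append(
                pd.concat(
                    [
                        base_df[["patient_id", "image_id", "cell_id"]],
                        pd.DataFrame(
                            {"phenotype": [config.phenotypes[k].name for k in pheno_idx]}
                        ),
                        pd.DataFrame(raw, columns=[f"true_{m}" for m in config.panel]),
                    ],
                    axis=1,
                )
            )
    cells = pd.concat(cell_frames, ignore_index=True)
    truth = SyntheticTruth(
        cells=pd.concat(truth_frames, ignore_index=True),
        patients=pd.DataFrame(patient_rows),
        batch_factors=pd.DataFrame(
            {m: [config.batch_factor_vector(b)[j] for b in config.batch_scale_factors]
             for j, m in enumerate(config.panel)},
            index=list(config.batch_scale_factors),
        ),
    )
    return cells, truth


def _pid_key(pid: str) -> int:
    return int(pid.lstrip("P"))


def _img_key(image_id: str) -> int:
    return int(image_id.rsplit("img", 1)[1])


# ---------------------------------------------------------------- geometry

_GRID_GAP = 12  # px added to the cell diameter when spacing grid sites


def place_cells(
    n: int,
    image_size: tuple[int, int],
    radius_range: tuple[float, float],
    seed: int | np.random.Generator,
    contact_fraction: float = 0.0,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Rasterize *n* disjoint disk-shaped cells into a label mask.

    Cells sit on a jittered grid whose spacing guarantees disjointness;
    a *contact_fraction* of cells is placed as surface-contact pairs
    (centers at r1 + r2 + u, u < 1 px). Returns (mask uint16, contacts
    DataFrame with columns cell_a, cell_b).

    Raises ValueError when the geometry cannot host *n* cells.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    h, w = image_size
    mask = np.zeros((h, w), dtype=np.uint16)
    if n == 0:
        return mask, pd.DataFrame(columns=["cell_a", "cell_b"])
    r_lo, r_hi = radius_range
    if r_lo < 1 or r_hi < r_lo:
        raise ValueError("invalid radius range")
    spacing = int(math.ceil(2 * r_hi)) + _GRID_GAP
    margin = int(math.ceil(r_hi)) + 1
    nx = (w - 2 * margin) // spacing
    ny = (h - 2 * margin) // spacing
    if nx < 1 or ny < 1 or nx * ny < n:
        raise ValueError(
            f"infeasible geometry: {nx * ny} grid sites for {n} cells "
            f"({h}x{w} px, radius <= {r_hi})"
        )
    n_pairs = int(contact_fraction * n) // 2
    sites = [(ix, iy) for iy in range(ny) for ix in range(nx)]
    order = rng.permutation(len(sites))
    free = {sites[i] for i in order}
    centers_of = lambda ix, iy: (
        margin + spacing / 2 + ix * spacing,
        margin + spacing / 2 + iy * spacing,
    )

    placements: list[tuple[float, float, float]] = []  # (cx, cy, r)
    contacts: list[tuple[int, int]] = []
    radii = rng.uniform(r_lo, r_hi, size=n)
    # contact pairs first: two cells symmetric about a shared site center
    k = 0
    for i in order:
        if k >= 2 * n_pairs or n - k < 2:
            break
        s = sites[i]
        if s not in free:
            continue
        free.discard(s)
        cx, cy = centers_of(*s)
        r1, r2 = radii[k], radii[k + 1]
        theta = rng.uniform(0, 2 * math.pi)
        d = r1 + r2 + rng.uniform(0.1, 0.9)
        dx, dy = 0.5 * d * math.cos(theta), 0.5 * d * math.sin(theta)
        placements.append((cx - dx, cy - dy, r1))
        placements.append((cx + dx, cy + dy, r2))
        contacts.append((k + 1, k + 2))
        k += 2
    # singles on remaining sites with sub-pixel jitter
    for i in order:
        if k >= n:
            break
        s = sites[i]
        if s not in free:
            continue
        free.discard(s)
        cx, cy = centers_of(*s)
        placements.append(
            (cx + rng.uniform(-1, 1), cy + rng.uniform(-1, 1), radii[k])
        )
        k += 1
    if k < n:
        raise ValueError("infeasible geometry: ran out of grid sites")
    for label, (cx, cy, r) in enumerate(placements, start=1):
        rr, cc = draw_disk((cy, cx), r, shape=mask.shape)
        mask[rr, cc] = label
    return mask, pd.DataFrame(contacts, columns=["cell_a", "cell_b"], dtype=int)


def simulate_cohort(config: CohortConfig) -> SimulatedCohort:
    """Full path: multi-channel images, label masks, panel table,
    clinical table and ground truth.

    Each cell's disk is painted with its true mean intensity per
    channel (batch factor included), so mask-based quantification
    recovers the stored truth exactly up to float rounding.
    """
    cells, truth = simulate_cell_table(config)
    images: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    contact_frames = []
    h, w = config.image_size_px
    for image_id, img_cells in cells.groupby("image_id", sort=True):
        n = len(img_cells)
        rng = _spawn(config.seed, 3, _pid_key(img_cells["patient_id"].iloc[0]),
                     _img_key(image_id))
        mask, contacts = place_cells(
            n, config.image_size_px, config.cell_radius_px, rng,
            contact_fraction=config.contact_fraction,
        )
        contacts.insert(0, "image_id", image_id)
        contact_frames.append(contacts)
        image = np.zeros((len(config.panel), h, w), dtype=np.float32)
        raw = img_cells[config.panel].to_numpy(dtype=np.float32)
        flat = mask.ravel()
        pix = np.flatnonzero(flat)
        labels = flat[pix]
        for c in range(len(config.panel)):
            image[c].ravel()[pix] = raw[labels - 1, c]
        images[image_id] = image
        masks[image_id] = mask
    panel = pd.DataFrame(
        {"channel_index": range(len(config.panel)), "marker_name": config.panel}
    )
    clinical = (
        _patient_layout(config)
        .loc[:, ["patient_id", "image_id", "batch", "recurrent", "time_months", "event"]]
        .reset_index(drop=True)
    )
    truth.contacts = pd.concat(contact_frames, ignore_index=True)
    return SimulatedCohort(images=images, masks=masks, panel=panel,
                           clinical=clinical, truth=truth)


def simulate_survival_times(
    low_status: np.ndarray,
    hazard_ratio: float = 4.0,
    baseline_median_months: float = 60.0,
    censor_months: tuple[float, float] = (36.0, 96.0),
    rng: np.random.Generator | int = 0,
) -> pd.DataFrame:
    """Recurrence times under proportional hazards tied to a binary
    marker status (e.g. vimentin-low tumors at hazard_ratio x baseline),
    with uniform administrative censoring.

    Returns DataFrame(time_months, event, low) per patient.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    low = np.asarray(low_status, dtype=bool)
    lam0 = math.log(2) / baseline_median_months
    lam = np.where(low, lam0 * hazard_ratio, lam0)
    t_event = rng.exponential(1.0 / lam)
    t_cens = rng.uniform(*censor_months, size=low.size)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame({"time_months": np.maximum(time, 0.1), "event": event,
                         "low": low.astype(int)})


def write_cohort(cohort: SimulatedCohort, out_dir) -> None:
    """Write TIFF images/masks and CSV tables under *out_dir*."""
    import tifffile
    from pathlib import Path

    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for image_id, img in cohort.images.items():
        tifffile.imwrite(out / "images" / f"{image_id}.tiff", img)
        tifffile.imwrite(out / "masks" / f"{image_id}_mask.tiff", cohort.masks[image_id])
    cohort.panel.to_csv(out / "panel.csv", index=False)
    cohort.clinical.to_csv(out / "clinical.csv", index=False)
    cohort.truth.cells.to_csv(out / "truth_cells.csv", index=False)
    cohort.truth.patients.to_csv(out / "truth_patients.csv", index=False)
    if cohort.truth.contacts is not None:
        cohort.truth.contacts.to_csv(out / "truth_contacts.csv", index=False)
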