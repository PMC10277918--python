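"""Rule-based gating of major cell populations and compartment
subtraction arithmetic.

Gates follow the scheme: epithelial cells express E-cadherin and
cytokeratin and lack aSMA; non-epithelial cells express aSMA and lack
E-cadherin; CD8 T cells are CD8a+CD3+, CD4 T cells CD4+CD3+,
proliferative cells Ki-67+. Expression cut-offs are resolved per image
(Otsu by default, emulating per-image manual thresholds). Immune and
proliferative counts inside the epithelial compartment are estimated by
subtraction: counted inside the non-epithelial compartment, then
subtracted from the population total. Stromal cells are the
non-epithelial cells left after removing immune cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from imcrecur.markers import ASINH_PREFIX

__all__ = [
    "GatingRule",
    "default_gating_rules",
    "resolve_thresholds",
    "apply_gates",
    "compartment_counts",
    "IMMUNE_POPULATIONS",
]

IMMUNE_POPULATIONS = ("cd8_t", "cd4_t", "macrophage", "b_cell")


@dataclass
class GatingRule:
    """A population defined by required-positive and required-negative
    markers; thresholds resolved per image by *policy*:
    ``("otsu",)``, ``("quantile", q)`` or ``("fixed", value)``."""

    name: str
    positive: list[str]
    negative: list[str] = field(default_factory=list)
    policy: dict[str, tuple] = field(default_factory=dict)  # marker -> policy

    def __post_init__(self):
        overlap = set(self.positive) & set(self.negative)
        if overlap:
            raise ValueError(f"{self.name}: markers {sorted(overlap)} both + and -")

    def markers(self) -> set[str]:
        return set(self.positive) | set(self.negative)


def default_gating_rules() -> list[GatingRule]:
    return [
        GatingRule("epithelial", positive=["Ecad", "cytokeratin"], negative=["aSMA"]),
        GatingRule("non_epithelial", positive=["aSMA"], negative=["Ecad"]),
        GatingRule("cd8_t", positive=["CD8a", "CD3"]),
        GatingRule("cd4_t", positive=["CD4", "CD3"]),
        GatingRule("macrophage", positive=["CD68"]),
        GatingRule("b_cell", positive=["CD20"]),
        GatingRule("proliferative", positive=["Ki67"]),
    ]


_FALLBACK_QUANTILE = 0.75


def _resolve(values: np.ndarray, policy: tuple) -> float:
    kind = policy[0]
    if kind == "fixed":
        return float(policy[1])
    if kind == "quantile":
        return float(np.quantile(values, policy[1]))
    if kind == "otsu":
        if np.unique(values).size < 2:
            warnings.warn("constant channel: Otsu unresolvable, falling back to "
                          f"quantile {_FALLBACK_QUANTILE}")
            return float(np.quantile(values, _FALLBACK_QUANTILE))
        return float(threshold_otsu(values))
    raise ValueError(f"unknown threshold policy {policy!r}")


def resolve_thresholds(
    cells: pd.DataFrame, rules: list[GatingRule], default_policy: tuple = ("otsu",)
) -> pd.DataFrame:
    """Per-(image, marker) thresholds on arcsinh-transformed values."""
    markers = sorted(set().union(*(r.markers() for r in rules)))
    missing = [m for m in markers if ASINH_PREFIX + m not in cells.columns]
    if missing:
        raise ValueError(f"markers without transformed intensities: {missing}")
    rows = []
    policies = {}
    for r in rules:
        for m in r.markers():
            policies.setdefault(m, r.policy.get(m, default_policy))
    for image_id, img in cells.groupby("image_id", sort=True):
        for m in markers:
            rows.append(
                {
                    "image_id": image_id,
                    "marker": m,
                    "threshold": _resolve(img[ASINH_PREFIX + m].to_numpy(), policies[m]),
                }
            )
    return pd.DataFrame(rows)


def apply_gates(
    cells: pd.DataFrame,
    rules: list[GatingRule] | None = None,
    default_policy: tuple = ("otsu",),
) -> pd.DataFrame:
    """Boolean population labels per cell (columns = rule names).

    A cell is labeled when every required-positive marker exceeds its
    per-image threshold and no required-negative marker does. Labels may
    overlap across rules; the epithelial / non-epithelial pair is
    mutually exclusive by construction of its rules.
    """
    rules = rules or default_gating_rules()
    thresholds = resolve_thresholds(cells, rules, default_policy)
    thr = thresholds.set_index(["image_id", "marker"])["threshold"]
    out = pd.DataFrame(index=cells.index)
    img = cells["image_id"]
    above = {}
    for m in sorted(set().union(*(r.markers() for r in rules))):
        cut = img.map(thr.xs(m, level="marker")).to_numpy()
        above[m] = cells[ASINH_PREFIX + m].to_numpy() > cut
    for r in rules:
        lab = np.ones(len(cells), dtype=bool)
        for m in r.positive:
            lab &= above[m]
        for m in r.negative:
            lab &= ~above[m]
        out[r.name] = lab
    return out


def compartment_counts(
    labels: pd.DataFrame,
    patient_id: pd.Series,
    immune_populations: tuple[str, ...] = IMMUNE_POPULATIONS,
) -> pd.DataFrame:
    """Per-patient compartment bookkeeping.

    For each immune population and for proliferative cells the count in
    the epithelial compartment is *derived* by subtracting the count
    gated inside the non-epithelial compartment from the population
    total; stromal = non_epithelial - sum(immune in non-epithelial).
    Negative derived counts are floored at 0 with a warning.
    """
    immune_populations = [p for p in immune_populations if p in labels.columns]
    df = labels.copy()
    df["patient_id"] = np.asarray(patient_id)
    rows = []
    for pid, g in df.groupby("patient_id", sort=True):
        if len(g) == 0:
            warnings.warn(f"patient {pid}: zero cells, excluded")
            continue
        row = {
            "patient_id": pid,
            "total": len(g),
            "epithelial": int(g["epithelial"].sum()),
            "non_epithelial": int(g["non_epithelial"].sum()),
        }
        immune_in_nonepi_total = 0
        for pop in immune_populations:
            tot = int(g[pop].sum())
            in_nonepi = int((g[pop] & g["non_epithelial"]).sum())
            in_epi = tot - in_nonepi
            if in_epi < 0:
                warnings.warn(f"patient {pid}: negative derived count for {pop}, floored")
                in_epi = 0
            row[f"{pop}_total"] = tot
            row[f"{pop}_in_nonepithelial"] = in_nonepi
            row[f"{pop}_in_epithelial"] = in_epi
            immune_in_nonepi_total += in_nonepi
        if "proliferative" in g.columns:
            tot = int(g["proliferative"].sum())
            in_nonepi = int((g["proliferative"] & g["non_epithelial"]).sum())
            row["proliferative_total"] = tot
            row["proliferative_in_nonepithelial"] = in_nonepi
            row["proliferative_in_epithelial"] = max(tot - in_nonepi, 0)
        stromal = row["non_epithelial"] - immune_in_nonepi_total
        if stromal < 0:
            warnings.warn(f"patient {pid}: negative stromal count, floored")
            stromal = 0
        row["stromal"] = stromal
        row["ungated"] = int((~(g["epithelial"] | g["non_epithelial"])).sum())
        rows.append(row)
    return pd.DataFrame(rows)
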