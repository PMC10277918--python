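"""Survival layer: dichotomize tumors by median epithelial vimentin
expression and compare recurrence-free survival with Kaplan-Meier /
Mantel-Cox log-rank; also compare median epithelial vimentin between
recurrence groups.

Finds: vimentin-low tumors (which the generator enriches for the
recurrent group) show worse recurrence-free survival.
"""

import sys
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from cohort_config import RESULTS, SCRATCH

from imcrecur.gate import apply_gates
from imcrecur.stats_survival import dichotomize, km_logrank, mann_whitney_u


def main():
    cells = pd.read_csv(SCRATCH / "cells_proc.csv")
    clinical = pd.read_csv(SCRATCH / "clinical.csv")
    pat = clinical.drop_duplicates("patient_id").set_index("patient_id")

    labels = apply_gates(cells)
    epi = cells[labels["epithelial"].to_numpy()]
    vim = epi.groupby("patient_id")["asinh_vimentin"].median()

    rec = pat["recurrent"].reindex(vim.index)
    u, p_mw = mann_whitney_u(vim[rec == 0], vim[rec == 1])
    print(f"median epithelial vimentin, non-recurrent vs recurrent: "
          f"U = {u:.0f}, p = {p_mw:.4g}")

    groups = dichotomize(vim, rule="median")
    res = km_logrank(
        pat["time_months"].reindex(vim.index),
        pat["event"].reindex(vim.index),
        groups,
    )
    print(f"log-rank vimentin-low vs -high: chi2 = {res.chi2:.2f}, "
          f"p = {res.p_value:.4g}; groups {res.legend_counts()}")

    summary = res.summary.copy()
    summary["chi2"] = res.chi2
    summary["p_logrank"] = res.p_value
    summary["p_mannwhitney_vim"] = p_mw
    summary.to_csv(RESULTS / "survival_vimentin.csv", index=False)

    fig, ax = plt.subplots(figsize=(5, 4))
    for g, curve in res.curves.items():
        n, e = res.group_sizes[g]
        ax.step(curve["time"], curve["survival"], where="post",
                label=f"vimentin {g} {n} ({e})")
    ax.set_xlabel("months since primary treatment")
    ax.set_ylabel("recurrence-free survival")
    ax.set_ylim(0, 1.05)
    ax.legend()
    ax.set_title(f"log-rank p = {res.p_value:.3g}")
    fig.tight_layout()
    fig.savefig(RESULTS / "km_vimentin.png", dpi=120)
    print(f"results -> {RESULTS / 'survival_vimentin.csv'}, km_vimentin.png")


if __name__ == "__main__":
    main()
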