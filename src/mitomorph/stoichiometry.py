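"""Immunogold stoichiometry: per-compartment particle counts and
Pink1+Parkin co-localization.

In post-embedding immunogold TEM one gold particle marks one protein
molecule, so per-compartment particle counts are direct in-situ protein
amounts.  Summaries follow the study's unit conventions: particle totals
are per cell (50-cell scale), a mitochondrion is *positive* when it bears
at least one particle (threshold configurable), and each group is also
expressed as percent of the control-group mean.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import PROTEINS
from .cohort import Cohort
from .stats import percent_of_control, sem

__all__ = ["GoldSummary", "gold_summary", "colocalization", "stoichiometry_report"]


@dataclass
class GoldSummary:
    protein: str
    dose: float
    n_cells: int
    cytosol: tuple                 # (mean, sem) particles per cell
    mitochondria: tuple            # (mean, sem) particles within mitochondria per cell
    positive_mitochondria: tuple   # (mean, sem) mitochondria with >= threshold particles per cell
    per_mitochondrion: tuple       # secondary: (mean, sem) particles per mitochondrion
    cytosol_pct: tuple             # percent of control (value, sem)
    mitochondria_pct: tuple
    positive_mitochondria_pct: tuple


def _per_cell_tables(cohort: Cohort, protein: str, dose, threshold: int):
    cells = cohort.morpho_cells_at(dose)
    if len(cells) < 2:
        raise ValueError(f"dose {dose} uM: need >= 2 cells")
    mitos = cohort.mitochondria_of(cells["cell_id"])
    col = f"gold_{protein}"
    g = mitos.groupby("cell_id")[col]
    within = g.sum().reindex(cells["cell_id"]).fillna(0.0)
    positive = (
        mitos.assign(pos=mitos[col] >= threshold).groupby("cell_id")["pos"].sum()
        .reindex(cells["cell_id"]).fillna(0.0)
    )
    cytosol = cells.set_index("cell_id")[f"gold_{protein}_cyt"].astype(float)
    return cells, mitos, cytosol, within, positive


def gold_summary(cohort: Cohort, protein: str, dose, threshold: int = 1) -> GoldSummary:
    """Per-cell immunogold summary for one protein at one dose."""
    protein = protein.lower()
    if protein not in PROTEINS:
        raise KeyError(f"unknown protein {protein!r}; expected one of {PROTEINS}")
    control_dose = cohort.dose_levels[0]

    def stats_at(d):
        cells, mitos, cyt, within, pos = _per_cell_tables(cohort, protein, d, threshold)
        per_mito = mitos[f"gold_{protein}"].astype(float)
        return {
            "n": len(cells),
            "cytosol": (float(cyt.mean()), sem(cyt)),
            "mitochondria": (float(within.mean()), sem(within)),
            "positive": (float(pos.mean()), sem(pos)),
            "per_mito": (float(per_mito.mean()), sem(per_mito)),
        }

    grp = stats_at(dose)
    ctrl = stats_at(control_dose)

    def pct(key):
        # a protein absent from the control compartment has no control scale
        if ctrl[key][0] <= 0:
            return (float("nan"), float("nan"))
        return percent_of_control(*grp[key], ctrl[key][0])

    return GoldSummary(
        protein=protein, dose=float(dose), n_cells=grp["n"],
        cytosol=grp["cytosol"], mitochondria=grp["mitochondria"],
        positive_mitochondria=grp["positive"], per_mitochondrion=grp["per_mito"],
        cytosol_pct=pct("cytosol"),
        mitochondria_pct=pct("mitochondria"),
        positive_mitochondria_pct=pct("positive"),
    )


def colocalization(cohort: Cohort, dose, threshold: int = 1) -> tuple:
    """(mean, sem) per-cell count of mitochondria bearing both Pink1 and
    Parkin (>= ``threshold`` particles of each)."""
    cells = cohort.morpho_cells_at(dose)
    mitos = cohort.mitochondria_of(cells["cell_id"])
    both = (mitos["gold_pink1"] >= threshold) & (mitos["gold_parkin"] >= threshold)
    per_cell = (
        mitos.assign(coloc=both).groupby("cell_id")["coloc"].sum()
        .reindex(cells["cell_id"]).fillna(0.0)
    )
    return (float(per_cell.mean()), sem(per_cell))


def stoichiometry_report(cohort: Cohort, threshold: int = 1) -> pd.DataFrame:
    """Protein x dose x compartment rows with mean, SEM, percent of control."""
    rows = []
    for protein in PROTEINS:
        for dose in cohort.dose_levels:
            s = gold_summary(cohort, protein, dose, threshold=threshold)
            for comp, values, pct in (
                ("cytosol", s.cytosol, s.cytosol_pct),
                ("mitochondrion", s.mitochondria, s.mitochondria_pct),
                ("positive_mitochondria", s.positive_mitochondria, s.positive_mitochondria_pct),
            ):
                rows.append({
                    "protein": protein, "dose_um": s.dose, "compartment": comp,
                    "n_cells": s.n_cells, "mean": values[0], "sem": values[1],
                    "percent_of_control": pct[0], "percent_of_control_sem": pct[1],
                })
    for dose in cohort.dose_levels:
        mean, err = colocalization(cohort, dose, threshold=threshold)
        ctrl_mean, _ = colocalization(cohort, cohort.dose_levels[0], threshold=threshold)
        pct = percent_of_control(mean, err, ctrl_mean) if ctrl_mean > 0 else (np.nan, np.nan)
        rows.append({
            "protein": "pink1+parkin", "dose_um": float(dose), "compartment": "mitochondrion",
            "n_cells": len(cohort.morpho_cells_at(dose)), "mean": mean, "sem": err,
            "percent_of_control": pct[0], "percent_of_control_sem": pct[1],
        })
    return pd.DataFrame(rows)
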