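"""Mitochondrial damage classification, the four-stage integrity score,
per-group morphometry, and the total-fluorescence reconciliation model.

A mitochondrion is *altered* when any of the three elementary alterations
is present - matrix dilution (focal spots or widespread pallor), broken
cristae, or rupture of the inner and/or outer membrane - alone or in
combination; area is deliberately not part of the definition because section
geometry biases it.

The integrity score is ordinal, from severe to slight damage:

    Stage 1  ruptured membranes (worst feature dominates)
    Stage 2  broken crests without membrane rupture
    Stage 3  matrix dilution only
    Stage 4  intact

The rubric's named stages list co-occurring features (stage 1 = broken
crests + ruptured membranes + widespread dilution); combinations off the
rubric are resolved by worst-feature precedence membranes > crests >
dilution, so e.g. ruptured membranes alone still score 1 and widespread
dilution alone scores 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import Cohort, Dilution, assay_cells, sampled_mitochondria
from .stats import sem

__all__ = [
    "is_altered",
    "integrity_stage",
    "stage_table",
    "dilution_from_density",
    "GroupMorphometry",
    "group_morphometry",
    "morphometry_report",
    "reconcile_fluorescence",
]


def is_altered(m) -> bool:
    """True iff any elementary alteration is present; area plays no role."""
    return bool(m.dilution != Dilution.NONE or m.crests_broken or m.membranes_ruptured)


def integrity_stage(m) -> int:
    """Ordinal integrity stage in {1, 2, 3, 4} (1 worst, 4 intact)."""
    if m.membranes_ruptured:
        return 1
    if m.crests_broken:
        return 2
    if m.dilution != Dilution.NONE:
        return 3
    return 4


def stage_table() -> pd.DataFrame:
    """The full 12-row decision table (3 dilution levels x crests x membranes)."""
    rows = [
        (dil, crests, membranes,
         integrity_stage(_Flags(dil, crests, membranes)))
        for dil in Dilution.ORDER
        for crests in (False, True)
        for membranes in (False, True)
    ]
    return pd.DataFrame(rows, columns=["dilution", "crests_broken", "membranes_ruptured", "stage"])


@dataclass
class _Flags:
    dilution: str
    crests_broken: bool
    membranes_ruptured: bool


def _stage_series(mitos: pd.DataFrame) -> pd.Series:
    stage = pd.Series(4, index=mitos.index)
    stage[mitos["dilution"] != Dilution.NONE] = 3
    stage[mitos["crests_broken"].astype(bool)] = 2
    stage[mitos["membranes_ruptured"].astype(bool)] = 1
    return stage


def dilution_from_density(ed_norm, control_mean: float, factor: float = 0.8):
    """Threshold adapter: flag dilution when the measured matrix/cytosol
    density ratio falls below ``factor`` x the control mean.

    For use with rendered patches, where dilution is not a given label but a
    densitometric observation.
    """
    if not control_mean > 0:
        raise ValueError("control mean must be > 0")
    return np.asarray(ed_norm, dtype=float) < factor * control_mean


@dataclass
class GroupMorphometry:
    """Per-dose aggregate, (mean, sem) pairs on the study's scales.

    Per-cell counts average over the morphometry cells (50-cell scale);
    per-mitochondrion quantities average over the sampled mitochondria
    (150 per group); the matrix density is expressed as percent of the
    control-group mean.
    """

    dose: float
    n_cells: int
    n_mito: int
    total_mito_per_cell: tuple
    percent_altered: tuple
    d_max_um: tuple
    d_min_um: tuple
    area_um2: tuple
    ed_percent_of_control: tuple
    broken_crests_per_cell: tuple
    ruptured_membranes_per_cell: tuple
    mean_stage: tuple


def _mean_sem(values) -> tuple:
    arr = np.asarray(values, dtype=float)
    return (float(arr.mean()), sem(arr)) if arr.size else (float("nan"), 0.0)


def group_morphometry(cohort: Cohort, dose) -> GroupMorphometry:
    """Aggregate morphometry for one dose group of a cohort."""
    config = cohort.config
    n_cells = config.n_cells_morpho if config is not None else None
    control_dose = cohort.dose_levels[0]

    def per_cell_frame(d):
        cells = cohort.morpho_cells_at(d)
        if n_cells is not None:
            # the morphometry subset is already capped at n_cells per group
            cells = cells.head(n_cells)
        if len(cells) < 2:
            raise ValueError(f"dose {d} uM: need >= 2 morphometry cells")
        mitos = cohort.mitochondria_of(cells["cell_id"])
        stage = _stage_series(mitos)
        altered = stage < 4
        g = mitos.assign(altered=altered).groupby("cell_id")
        per_cell = pd.DataFrame({
            "total": g.size(),
            "altered_pct": g["altered"].mean() * 100.0,
            "crests": g["crests_broken"].sum(),
            "membranes": g["membranes_ruptured"].sum(),
        }).reindex(cells["cell_id"]).fillna(0.0)
        return per_cell, mitos, stage

    per_cell, _, _ = per_cell_frame(dose)
    mito_sample = sampled_mitochondria(cohort, dose)
    stage_sample = _stage_series(mito_sample)

    ctrl_sample = sampled_mitochondria(cohort, control_dose)
    ctrl_ed_mean = float(ctrl_sample["ed_norm"].mean())
    ed_mean, ed_sem = _mean_sem(mito_sample["ed_norm"])
    ed_pct = (100.0 * ed_mean / ctrl_ed_mean, 100.0 * ed_sem / ctrl_ed_mean)

    return GroupMorphometry(
        dose=float(dose),
        n_cells=int(len(per_cell)),
        n_mito=int(len(mito_sample)),
        total_mito_per_cell=_mean_sem(per_cell["total"]),
        percent_altered=_mean_sem(per_cell["altered_pct"]),
        d_max_um=_mean_sem(mito_sample["d_max_um"]),
        d_min_um=_mean_sem(mito_sample["d_min_um"]),
        area_um2=_mean_sem(mito_sample["area_um2"]),
        ed_percent_of_control=ed_pct,
        broken_crests_per_cell=_mean_sem(per_cell["crests"]),
        ruptured_membranes_per_cell=_mean_sem(per_cell["membranes"]),
        mean_stage=_mean_sem(stage_sample),
    )


def morphometry_report(cohort: Cohort) -> pd.DataFrame:
    """One row per dose with every :class:`GroupMorphometry` quantity."""
    rows = []
    for dose in cohort.dose_levels:
        g = group_morphometry(cohort, dose)
        row = {"dose_um": g.dose, "n_cells": g.n_cells, "n_mito": g.n_mito}
        for name in (
            "total_mito_per_cell", "percent_altered", "d_max_um", "d_min_um",
            "area_um2", "ed_percent_of_control", "broken_crests_per_cell",
            "ruptured_membranes_per_cell", "mean_stage",
        ):
            mean, err = getattr(g, name)
            row[f"{name}_mean"] = mean
            row[f"{name}_sem"] = err
        rows.append(row)
    return pd.DataFrame(rows)


def reconcile_fluorescence(count_ratio: float, area_fold: float) -> float:
    """Predicted total mitochondrial signal, percent of control.

    Total stainable mass model: bulk dye fluorescence scales with organelle
    count times mean organelle area, so a +25% count with two-fold area
    predicts 100 x 1.25 x 2.0 = 250% of control - reconciling bulk-dye
    densitometry with the much smaller increase in directly counted
    organelles.
    """
    if not (count_ratio > 0 and area_fold > 0):
        raise ValueError("count ratio and area fold must be > 0")
    return 100.0 * count_ratio * area_fold
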