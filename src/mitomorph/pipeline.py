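"""End-to-end orchestration: generate -> measure -> score -> summarize ->
test, with logged provenance and anchor reproduction.

A run writes the cohort tables, the morphometry/stoichiometry reports, the
statistical report (ANOVA + Scheffe per endpoint, group-level regressions)
and a manifest with a config hash, so a run is fully reproducible from
(config, seed).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import PROTEINS, CalibrationConfig, default_calibration
from .cohort import Cohort, assay_cells, generate_cohort, read_cohort, write_cohort
from .morphometry import morphometry_report, reconcile_fluorescence
from .stats import linear_regression, one_way_anova, scheffe_posthoc
from .stoichiometry import stoichiometry_report

log = logging.getLogger("mitomorph")

__all__ = [
    "PipelineError", "RunManifest", "run_pipeline", "analyze_cohort",
    "reproduce_targets", "compute_anchor_endpoints", "ANCHORS",
]


class PipelineError(RuntimeError):
    """A pipeline stage failed; ``stage`` names it."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    outputs: list
    anchor_checks: list  # per-endpoint dicts with value/expected/tolerance/passed

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))

    def content_hash(self) -> str:
        payload = json.dumps(
            {"config": self.config_hash, "seed": self.seed,
             "checks": self.anchor_checks}, sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


# Printed anchors the default calibration encodes; ``cmp`` "eq" checks
# |value - expected| <= tol, "ge" checks value >= expected - tol.
# Percent-of-population anchors ("roughly 20% of spared cells", "roughly 70%
# of cell loss") carry +-5 percentage points; ratio-to-control anchors ("in
# excess of 25%", "two-fold", "an excess of 200%", "roughly 50% of control")
# are folds and carry +-0.15.
ANCHORS = {
    "survival_pct_1000um": {"expected": 20.0, "cmp": "eq", "tol": 5.0,
                            "n": "n_cells_he", "dose": 1000},
    "tem_death_pct_1000um": {"expected": 70.0, "cmp": "eq", "tol": 5.0,
                             "n": "n_cells_tem_death", "dose": 1000},
    "mito_count_fold_100um": {"expected": 1.25, "cmp": "ge", "tol": 0.15,
                              "n": "n_cells_morpho", "dose": 100},
    "mtrg_fold_100um": {"expected": 2.0, "cmp": "ge", "tol": 0.15,
                        "n": "n_cells_fluor", "dose": 100},
    "fis1_mito_fold_100um": {"expected": 0.50, "cmp": "eq", "tol": 0.15,
                             "n": "n_cells_morpho", "dose": 100},
    "area_fold_500um": {"expected": 2.0, "cmp": "eq", "tol": 0.15,
                        "n": "n_mito_sampled", "dose": 500},
}


def compute_anchor_endpoints(cohort: Cohort) -> dict:
    """The anchored dose-response endpoints of one cohort, on print scales."""
    config = cohort.config
    if config is None:
        raise PipelineError("anchors", "cohort carries no calibration provenance")
    control = cohort.dose_levels[0]

    def alive_count(dose, n):
        return assay_cells(cohort, dose, n)["alive"].sum()

    n_he = config.n_cells_he
    survival_pct = 100.0 * alive_count(1000, n_he) / max(alive_count(control, n_he), 1)

    tem = assay_cells(cohort, 1000, config.n_cells_tem_death)
    tem_death_pct = 100.0 * tem["dead_by_tem"].mean()

    def mito_count_mean(dose):
        cells = cohort.morpho_cells_at(dose)
        mitos = cohort.mitochondria_of(cells["cell_id"])
        return mitos.groupby("cell_id").size().reindex(cells["cell_id"]).fillna(0).mean()

    count_ratio = mito_count_mean(100) / mito_count_mean(control)

    def mtrg_mean(dose):
        return assay_cells(cohort, dose, config.n_cells_fluor)["mtrg_od"].mean()

    mtrg_pct = 100.0 * mtrg_mean(100) / mtrg_mean(control)

    def fis1_within(dose):
        cells = cohort.morpho_cells_at(dose)
        mitos = cohort.mitochondria_of(cells["cell_id"])
        return mitos.groupby("cell_id")["gold_fis1"].sum().reindex(cells["cell_id"]).fillna(0).mean()

    fis1_pct = 100.0 * fis1_within(100) / fis1_within(control)

    def area_mean(dose):
        from .cohort import sampled_mitochondria

        return sampled_mitochondria(cohort, dose)["area_um2"].mean()

    return {
        "survival_pct_1000um": float(survival_pct),
        "tem_death_pct_1000um": float(tem_death_pct),
        "mito_count_fold_100um": float(count_ratio),
        "mtrg_fold_100um": float(mtrg_pct / 100.0),
        "fis1_mito_fold_100um": float(fis1_pct / 100.0),
        "area_fold_500um": float(area_mean(500) / area_mean(control)),
    }


# ---------------------------------------------------------------------------
# statistical battery


def _endpoint_samples(cohort: Cohort) -> dict:
    """Per-endpoint list of group samples (cell- or mitochondrion-level)."""
    from .cohort import sampled_mitochondria
    from .morphometry import _stage_series

    config = cohort.config
    doses = cohort.dose_levels
    samples = {}

    def per_cells(column, n, as_float=True):
        return [
            assay_cells(cohort, d, n)[column].astype(float).to_numpy() for d in doses
        ]

    samples["survival"] = per_cells("alive", config.n_cells_he)
    samples["fjb_positive"] = per_cells("fjb_positive", config.n_cells_he)
    samples["tb_positive"] = per_cells("tb_positive", config.n_cells_he)
    samples["tem_death"] = per_cells("dead_by_tem", config.n_cells_tem_death)
    samples["fjb_intensity"] = per_cells("fjb_intensity", config.n_cells_fluor)
    samples["mtrg_od"] = per_cells("mtrg_od", config.n_cells_fluor)
    samples["mtrr_od"] = per_cells("mtrr_od", config.n_cells_fluor)

    per_mito = {"area_um2": [], "d_max_um": [], "d_min_um": [], "ed_norm": [], "stage": []}
    per_cell_morpho = {"mito_per_cell": [], "altered_pct_per_cell": [],
                       "crests_per_cell": [], "membranes_per_cell": []}
    for d in doses:
        mitos = sampled_mitochondria(cohort, d)
        stage = _stage_series(mitos)
        for col in ("area_um2", "d_max_um", "d_min_um", "ed_norm"):
            per_mito[col].append(mitos[col].to_numpy(dtype=float))
        per_mito["stage"].append(stage.to_numpy(dtype=float))

        cells = cohort.morpho_cells_at(d)
        all_mitos = cohort.mitochondria_of(cells["cell_id"])
        all_stage = _stage_series(all_mitos)
        g = all_mitos.assign(altered=all_stage < 4).groupby("cell_id")
        idx = cells["cell_id"]
        per_cell_morpho["mito_per_cell"].append(
            g.size().reindex(idx).fillna(0).to_numpy(dtype=float))
        per_cell_morpho["altered_pct_per_cell"].append(
            (g["altered"].mean() * 100).reindex(idx).fillna(0).to_numpy(dtype=float))
        per_cell_morpho["crests_per_cell"].append(
            g["crests_broken"].sum().reindex(idx).fillna(0).to_numpy(dtype=float))
        per_cell_morpho["membranes_per_cell"].append(
            g["membranes_ruptured"].sum().reindex(idx).fillna(0).to_numpy(dtype=float))
    samples.update(per_mito)
    samples.update(per_cell_morpho)

    for protein in PROTEINS:
        cyt, mito = [], []
        for d in doses:
            cells = cohort.morpho_cells_at(d)
            mitos = cohort.mitochondria_of(cells["cell_id"])
            cyt.append(cells[f"gold_{protein}_cyt"].to_numpy(dtype=float))
            mito.append(mitos.groupby("cell_id")[f"gold_{protein}"].sum()
                        .reindex(cells["cell_id"]).fillna(0).to_numpy(dtype=float))
        samples[f"gold_{protein}_cytosol"] = cyt
        samples[f"gold_{protein}_mitochondrion"] = mito
    return samples


def stats_report(cohort: Cohort, alpha: float = 0.05) -> dict:
    """ANOVA + all Scheffe contrasts per endpoint, plus the two group-level
    regressions (cell death vs altered fraction; area vs altered fraction)."""
    doses = list(cohort.dose_levels)
    samples = _endpoint_samples(cohort)
    report = {"alpha": alpha, "doses_um": doses, "endpoints": {}, "regressions": {}}

    for name, groups in samples.items():
        anova = one_way_anova(groups)
        contrasts = scheffe_posthoc(anova, groups, alpha=alpha)
        report["endpoints"][name] = {
            "anova": {
                "f": anova.f, "df": [anova.df_between, anova.df_within],
                "p": anova.p, "ms_within": anova.ms_within,
                "group_means": list(anova.group_means),
                "group_ns": list(anova.group_ns),
                "degenerate": anova.degenerate,
            },
            "scheffe": [
                {"doses_um": [doses[c.pair[0]], doses[c.pair[1]]],
                 "mean_difference": c.mean_difference,
                 "f_scheffe": None if np.isinf(c.f_scheffe) else c.f_scheffe,
                 "critical": c.critical, "significant": c.significant}
                for c in contrasts
            ],
        }

    death_pct = [100.0 * g.mean() for g in samples["tem_death"]]
    altered_pct = [g.mean() for g in samples["altered_pct_per_cell"]]
    area_mean = [g.mean() for g in samples["area_um2"]]
    for name, x, y in (
        ("cell_death_vs_altered", altered_pct, death_pct),
        ("area_vs_altered", altered_pct, area_mean),
    ):
        res = linear_regression(x, y)
        report["regressions"][name] = {
            "x": list(map(float, x)), "y": list(map(float, y)),
            "slope": res.slope, "intercept": res.intercept,
            "r": res.r, "r2": res.r2, "n": res.n, "t": res.t, "p": res.p,
        }

    ratios = compute_anchor_endpoints(cohort)
    report["mtrg_reconciliation"] = {
        "count_ratio": ratios["mito_count_fold_100um"],
        "area_fold": ratios["area_fold_500um"],
        "predicted_total_signal_pct": reconcile_fluorescence(
            ratios["mito_count_fold_100um"], ratios["area_fold_500um"]),
        "observed_mtrg_pct": 100.0 * ratios["mtrg_fold_100um"],
    }
    return report


# ---------------------------------------------------------------------------
# orchestration


def _check_anchor(name: str, value: float) -> dict:
    spec = ANCHORS[name]
    if spec["cmp"] == "ge":
        passed = value >= spec["expected"] - spec["tol"]
    else:
        passed = abs(value - spec["expected"]) <= spec["tol"]
    return {"endpoint": name, "value": value, "expected": spec["expected"],
            "cmp": spec["cmp"], "tolerance": spec["tol"], "passed": bool(passed)}


def analyze_cohort(cohort: Cohort, out_dir) -> list:
    """Write morphometry/stoichiometry/stats reports for an existing cohort."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs = []
    morph = morphometry_report(cohort)
    morph.to_csv(out / "morphometry_report.csv", index=False)
    outputs.append("morphometry_report.csv")
    stoich = stoichiometry_report(cohort)
    stoich.to_csv(out / "stoichiometry_report.csv", index=False)
    outputs.append("stoichiometry_report.csv")
    report = stats_report(cohort)
    (out / "stats_report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    outputs.append("stats_report.json")
    return outputs


def run_pipeline(config: CalibrationConfig | str | None, seed: int, out_dir) -> RunManifest:
    """Full run: simulate, analyze, check anchors, write the manifest.

    ``config`` is a :class:`CalibrationConfig`, a YAML path, or ``None`` for
    the default calibration.  Any stage failure aborts with the stage name
    and removes partial outputs.
    """
    out = Path(out_dir)
    created = not out.exists()
    out.mkdir(parents=True, exist_ok=True)
    try:
        if config is None:
            config = default_calibration()
        elif not isinstance(config, CalibrationConfig):
            try:
                config = CalibrationConfig.from_yaml(config)
            except Exception as exc:
                raise PipelineError("configure", str(exc)) from exc
        try:
            config.validate()
        except Exception as exc:
            raise PipelineError("configure", str(exc)) from exc

        log.info("generating cohort (seed=%d, config=%s)", seed, config.content_hash()[:12])
        for key, value in config.assumed_entries():
            log.debug("assumed calibration value %s = %s", key, value)
        try:
            cohort = generate_cohort(config, seed=seed)
            paths = write_cohort(cohort, out)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("simulate", str(exc)) from exc
        outputs = [Path(p).name for p in paths.values()]

        try:
            outputs += analyze_cohort(cohort, out)
        except Exception as exc:
            raise PipelineError("analyze", str(exc)) from exc

        try:
            values = compute_anchor_endpoints(cohort)
            checks = [_check_anchor(name, values[name]) for name in ANCHORS]
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("reproduce", str(exc)) from exc

        manifest = RunManifest(
            config_hash=config.content_hash(), seed=seed, version=__version__,
            outputs=sorted(outputs), anchor_checks=checks,
        )
        manifest.to_json(out / "manifest.json")
        return manifest
    except Exception:
        # partial-output cleanup: never leave a half-written run directory
        if created:
            shutil.rmtree(out, ignore_errors=True)
        else:
            for name in ("cells.csv", "mitochondria.csv", "provenance.json",
                         "morphometry_report.csv", "stoichiometry_report.csv",
                         "stats_report.json", "manifest.json"):
                (out / name).unlink(missing_ok=True)
        raise


def reproduce_targets(run_dir) -> pd.DataFrame:
    """Recompute every anchored endpoint from a completed run's outputs."""
    run_dir = Path(run_dir)
    for required in ("cells.csv", "mitochondria.csv"):
        if not (run_dir / required).exists():
            raise PipelineError("reproduce", f"missing output {required}; run the pipeline first")
    cohort = read_cohort(run_dir)
    if cohort.config is None:
        raise PipelineError("reproduce", "run lacks provenance.json with the calibration")
    values = compute_anchor_endpoints(cohort)
    rows = [_check_anchor(name, values[name]) for name in ANCHORS]
    return pd.DataFrame(rows)
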