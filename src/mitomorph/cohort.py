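"""Seeded synthetic cohorts of cells and mitochondria.

One cohort is the endpoint of a single simulated 72 h exposure experiment:
for every dose and replicate a batch of cells is drawn, each carrying the
light-microscopy endpoints (H&E survival, Fluoro-Jade B, trypan blue,
MitoTracker densitometry, cytosolic immunogold counts), and a morphometry
subset of surviving cells additionally carries a full list of mitochondria
with ultrastructural damage flags, diameters, area, matrix electron density
and per-protein immunogold counts.

Randomness: one master seed; the substream for (dose, replicate) is
``numpy.random.SeedSequence(master, spawn_key=(dose_index, replicate))``,
so identical (config, seed) pairs reproduce byte-identical cohorts and
groups are independent of each other.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import PROTEINS, CalibrationConfig, CalibrationError

__all__ = [
    "Dilution",
    "MitochondrionRecord",
    "CellRecord",
    "Cohort",
    "CohortFormatError",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
    "assay_cells",
    "sampled_mitochondria",
]

GENERATOR_VERSION = "0.1.0"

CELL_COLUMNS = [
    "cell_id", "dose_um", "replicate", "alive", "dead_by_tem",
    "fjb_positive", "fjb_intensity", "tb_positive", "mtrg_od", "mtrr_od",
    "gold_fis1_cyt", "gold_drp1_cyt", "gold_pink1_cyt", "gold_parkin_cyt",
]
MITO_COLUMNS = [
    "mito_id", "cell_id", "dilution", "crests_broken", "membranes_ruptured",
    "d_max_um", "d_min_um", "area_um2", "ed_norm",
    "gold_fis1", "gold_drp1", "gold_pink1", "gold_parkin",
]

# Slack on the ellipse bound area <= pi * d_max * d_min / 4, for float noise.
ELLIPSE_SLACK = 1.05


class Dilution:
    """Matrix-dilution categories, ordered by severity."""

    NONE = "NONE"
    SPOTS = "SPOTS"
    WIDESPREAD = "WIDESPREAD"
    ORDER = (NONE, SPOTS, WIDESPREAD)


class CohortFormatError(ValueError):
    """Malformed cohort table; carries the 1-based CSV line number."""

    def __init__(self, path, line, message):
        self.path, self.line = str(path), line
        super().__init__(f"{path}, line {line}: {message}")


@dataclass
class MitochondrionRecord:
    mito_id: str
    cell_id: str
    dilution: str
    crests_broken: bool
    membranes_ruptured: bool
    d_max: float
    d_min: float
    area: float
    ed_norm: float
    gold: dict = field(default_factory=dict)  # protein -> particle count

    def validate(self) -> "MitochondrionRecord":
        if self.dilution not in Dilution.ORDER:
            raise ValueError(f"{self.mito_id}: unknown dilution {self.dilution!r}")
        if self.d_min > self.d_max:
            raise ValueError(f"{self.mito_id}: d_min > d_max")
        if not self.area > 0:
            raise ValueError(f"{self.mito_id}: area must be > 0")
        if self.area > np.pi * self.d_max * self.d_min / 4.0 * ELLIPSE_SLACK:
            raise ValueError(f"{self.mito_id}: area exceeds ellipse bound")
        if not self.ed_norm > 0:
            raise ValueError(f"{self.mito_id}: ed_norm must be > 0")
        if any(v < 0 for v in self.gold.values()):
            raise ValueError(f"{self.mito_id}: negative gold count")
        return self


@dataclass
class CellRecord:
    cell_id: str
    dose: float
    replicate: int
    alive: bool
    dead_by_tem: bool
    fjb_positive: bool
    fjb_intensity: float
    tb_positive: bool
    mtrg_od: float
    mtrr_od: float
    gold_cytosol: dict = field(default_factory=dict)
    mitochondria: list = field(default_factory=list)


class Cohort:
    """Generated cohort; tabular views plus record-level access.

    The two :class:`pandas.DataFrame` views (``cells``, ``mitochondria``)
    are the primary containers; :meth:`cell` and :meth:`iter_mitochondria`
    materialize dataclass records on demand.
    """

    def __init__(self, cells: pd.DataFrame, mitochondria: pd.DataFrame,
                 config: CalibrationConfig | None = None, seed: int | None = None):
        self.cells = cells.reset_index(drop=True)
        self.mitochondria = mitochondria.reset_index(drop=True)
        self.config = config
        self.seed = seed

    @property
    def dose_levels(self):
        if self.config is not None:
            return tuple(self.config.dose_levels)
        return tuple(sorted(self.cells["dose_um"].unique()))

    def cells_at(self, dose) -> pd.DataFrame:
        sel = self.cells[self.cells["dose_um"] == dose]
        if sel.empty:
            raise KeyError(f"dose {dose} uM absent from cohort")
        return sel

    def mitochondria_of(self, cell_ids) -> pd.DataFrame:
        return self.mitochondria[self.mitochondria["cell_id"].isin(cell_ids)]

    def morpho_cells_at(self, dose) -> pd.DataFrame:
        """Cells of the morphometry subset (those carrying mitochondria)."""
        with_mito = set(self.mitochondria["cell_id"])
        sel = self.cells_at(dose)
        return sel[sel["cell_id"].isin(with_mito)]

    def cell(self, cell_id: str) -> CellRecord:
        row = self.cells[self.cells["cell_id"] == cell_id]
        if row.empty:
            raise KeyError(cell_id)
        r = row.iloc[0]
        mitos = [
            _mito_record(m)
            for _, m in self.mitochondria[self.mitochondria["cell_id"] == cell_id].iterrows()
        ]
        return CellRecord(
            cell_id=r["cell_id"], dose=r["dose_um"], replicate=int(r["replicate"]),
            alive=bool(r["alive"]), dead_by_tem=bool(r["dead_by_tem"]),
            fjb_positive=bool(r["fjb_positive"]), fjb_intensity=float(r["fjb_intensity"]),
            tb_positive=bool(r["tb_positive"]), mtrg_od=float(r["mtrg_od"]),
            mtrr_od=float(r["mtrr_od"]),
            gold_cytosol={p: int(r[f"gold_{p}_cyt"]) for p in PROTEINS},
            mitochondria=mitos,
        )

    def iter_mitochondria(self):
        for _, m in self.mitochondria.iterrows():
            yield _mito_record(m)

    def __eq__(self, other):
        if not isinstance(other, Cohort):
            return NotImplemented
        return self.cells.equals(other.cells) and self.mitochondria.equals(other.mitochondria)


def _mito_record(row) -> MitochondrionRecord:
    return MitochondrionRecord(
        mito_id=row["mito_id"], cell_id=row["cell_id"], dilution=row["dilution"],
        crests_broken=bool(row["crests_broken"]),
        membranes_ruptured=bool(row["membranes_ruptured"]),
        d_max=float(row["d_max_um"]), d_min=float(row["d_min_um"]),
        area=float(row["area_um2"]), ed_norm=float(row["ed_norm"]),
        gold={p: int(row[f"gold_{p}"]) for p in PROTEINS},
    )


# ---------------------------------------------------------------------------
# generation


def _split(n: int, k: int) -> list:
    """Near-even split of n units across k replicates (first ones larger)."""
    base, extra = divmod(n, k)
    return [base + (1 if i < extra else 0) for i in range(k)]


def _replicate_rate(rng, p: float, concentration: float) -> float:
    """Replicate-level Bernoulli rate with beta dispersion around p."""
    if p <= 0.0 or p >= 1.0 or concentration <= 0:
        return p
    return float(rng.beta(p * concentration, (1.0 - p) * concentration))


def _lognormal_mean(rng, mean, sigma, size):
    """Log-normal draws whose arithmetic mean equals ``mean``."""
    if sigma == 0:
        return np.full(size, mean)
    return rng.lognormal(np.log(mean) - sigma**2 / 2.0, sigma, size)


def _truncated_normal(rng, mean, sigma, size, floor=1e-6):
    """Normal draws resampled to stay above ``floor`` (ratio must be > 0)."""
    out = rng.normal(mean, sigma, size)
    bad = out <= floor
    while bad.any():
        out[bad] = rng.normal(mean, sigma, bad.sum())
        bad = out <= floor
    return out


def generate_cohort(config: CalibrationConfig, seed: int | None = None) -> Cohort:
    """Draw one full cohort under ``config``.

    ``seed`` overrides ``config.seed``.  Per dose x replicate the generator
    draws the H&E-scale batch of cells (``n_cells_he`` per group) and
    attaches mitochondria to the first ``n_cells_morpho``-share surviving
    cells of each replicate (ultrastructural morphometry samples spared
    cells).  Flags are Bernoulli, counts Poisson, areas log-normal with
    diameters from an ellipse of the drawn area and an aspect ratio uniform
    on [1, 2.5], and the matrix/cytosol density ratio truncated-normal.
    """
    config.validate()
    master = config.seed if seed is None else seed
    noise = config.noise
    cell_rows, mito_rows = [], []

    for di, dose in enumerate(config.dose_levels):
        eff = config.effects[dose]
        n_cells_rep = _split(config.n_cells_he, config.n_replicates)
        n_morpho_rep = _split(config.n_cells_morpho, config.n_replicates)
        morpho_deficit = 0  # surviving-cell shortfall carried to later replicates
        for rep in range(config.n_replicates):
            rng = np.random.default_rng(np.random.SeedSequence(master, spawn_key=(di, rep)))
            n = n_cells_rep[rep]

            # replicate-level effects: beta-dispersed rates, multiplicative
            # N(1, sigma) on continuous channel means (drawn in fixed order).
            kappa = noise.rate_concentration
            p_alive = _replicate_rate(rng, eff.survival_fraction, kappa)
            p_tem = _replicate_rate(rng, eff.tem_death_fraction, kappa)
            p_fjb = _replicate_rate(rng, eff.fjb_positive_rate, kappa)
            p_tb = _replicate_rate(rng, eff.tb_positive_rate, kappa)
            rs = noise.replicate_sigma
            r = {
                name: float(rng.normal(1.0, rs)) if rs > 0 else 1.0
                for name in ("fjb_int", "mtrg", "mtrr", "count", "area", "ed", "gold")
            }

            alive = rng.random(n) < p_alive
            dead_tem = rng.random(n) < p_tem
            fjb_pos = rng.random(n) < p_fjb
            tb_pos = rng.random(n) < p_tb
            b = config.baselines
            fjb_int = _lognormal_mean(
                rng, b.fjb_intensity * eff.fjb_intensity_fold * r["fjb_int"],
                noise.fjb_intensity_sigma_log, n)
            mtrg = _lognormal_mean(rng, b.mtrg_od * eff.mtrg_fold * r["mtrg"], noise.od_sigma_log, n)
            mtrr = _lognormal_mean(rng, b.mtrr_od * eff.mtrr_fold * r["mtrr"], noise.od_sigma_log, n)
            gold_cyt = {
                p: rng.poisson(
                    max(b.gold_cytosol[p] * eff.gold_fold[p]["cytosol"] * r["gold"], 0.0), n)
                for p in PROTEINS
            }

            cell_ids = [f"d{dose}_r{rep}_c{i:04d}" for i in range(n)]
            for i in range(n):
                cell_rows.append((
                    cell_ids[i], float(dose), rep, bool(alive[i]), bool(dead_tem[i]),
                    bool(fjb_pos[i]), float(fjb_int[i]), bool(tb_pos[i]),
                    float(mtrg[i]), float(mtrr[i]),
                    *(int(gold_cyt[p][i]) for p in PROTEINS),
                ))

            # morphometry subset: first surviving cells of the replicate;
            # a replicate short of survivors passes its share on (the study
            # scanned further grids until the per-group N was reached)
            want = n_morpho_rep[rep] + morpho_deficit
            morpho_idx = np.flatnonzero(alive)[:want]
            morpho_deficit = want - len(morpho_idx)
            if rep == config.n_replicates - 1 and morpho_deficit > 0:
                warnings.warn(
                    f"dose {dose} uM: only {config.n_cells_morpho - morpho_deficit} "
                    f"surviving cells for a morphometry sample of {config.n_cells_morpho}"
                )
            count_mean = eff.mito_count_mean * r["count"]
            area_mean = b.area_um2 * eff.area_fold * r["area"]
            ed_mean = b.ed_norm * eff.ed_fold * r["ed"]
            # per-mitochondrion gold rate chosen so the expected per-cell
            # total within mitochondria scales by the configured fold
            gold_rate = {
                p: max(
                    b.gold_mito_per_cell[p] * eff.gold_fold[p]["mitochondrion"] * r["gold"], 0.0
                ) / eff.mito_count_mean
                for p in PROTEINS
            }
            p_spots, p_wide = eff.p_dilution_spots, eff.p_dilution_widespread
            for i in morpho_idx:
                m = int(rng.poisson(max(count_mean, 0.0)))
                areas = _lognormal_mean(rng, area_mean, noise.area_sigma_log, m)
                aspect = rng.uniform(1.0, 2.5, m)
                d_min = np.sqrt(4.0 * areas / (np.pi * aspect))
                d_max = aspect * d_min
                ed = _truncated_normal(rng, ed_mean, noise.ed_sigma, m)
                u = rng.random(m)
                dilution = np.where(
                    u < p_wide, Dilution.WIDESPREAD,
                    np.where(u < p_wide + p_spots, Dilution.SPOTS, Dilution.NONE))
                crests = rng.random(m) < eff.p_broken_crests
                membranes = rng.random(m) < eff.p_ruptured_membranes
                gold = {p: rng.poisson(gold_rate[p], m) for p in PROTEINS}
                cid = cell_ids[i]
                for j in range(m):
                    mito_rows.append((
                        f"{cid}_m{j:03d}", cid, str(dilution[j]), bool(crests[j]),
                        bool(membranes[j]), float(d_max[j]), float(d_min[j]),
                        float(areas[j]), float(ed[j]),
                        *(int(gold[p][j]) for p in PROTEINS),
                    ))

    cells = pd.DataFrame(cell_rows, columns=CELL_COLUMNS)
    mitos = pd.DataFrame(mito_rows, columns=MITO_COLUMNS)
    return Cohort(cells, mitos, config=config, seed=master)


# ---------------------------------------------------------------------------
# analysis subsets


def assay_cells(cohort: Cohort, dose, n: int, n_replicates: int | None = None) -> pd.DataFrame:
    """First ``n`` cells of the group, split near-evenly across replicates.

    Mirrors an assay run on its own stated N (e.g. densitometry on 90
    cells/group) drawn from the same three independent experiments.
    """
    sel = cohort.cells_at(dose)
    reps = sorted(sel["replicate"].unique()) if n_replicates is None else list(range(n_replicates))
    shares = _split(n, len(reps))
    parts = [sel[sel["replicate"] == rep].head(k) for rep, k in zip(reps, shares)]
    return pd.concat(parts, axis=0)


def sampled_mitochondria(cohort: Cohort, dose, n: int | None = None) -> pd.DataFrame:
    """The per-group mitochondrion sample for size/density statistics.

    Sampling is round-robin across the morphometry cells (first organelle of
    every cell, then the second, ...), mirroring a morphometrist reading a
    few organelles from each of many cells across the three experiments
    rather than exhausting one cell at a time.
    """
    cells = cohort.morpho_cells_at(dose)
    mitos = cohort.mitochondria_of(cells["cell_id"])
    if n is None and cohort.config is not None:
        n = cohort.config.n_mito_sampled
    if n is None or len(mitos) <= n:
        return mitos
    rank = mitos.groupby("cell_id").cumcount()
    order = mitos.assign(_rank=rank).sort_values(
        ["_rank", "cell_id"], kind="stable").index
    return mitos.loc[order[:n]].sort_index()


# ---------------------------------------------------------------------------
# persistence


def write_cohort(cohort: Cohort, out_dir) -> dict:
    """Write ``cells.csv``, ``mitochondria.csv`` and ``provenance.json``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "cells": out / "cells.csv",
        "mitochondria": out / "mitochondria.csv",
        "provenance": out / "provenance.json",
    }
    cohort.cells.to_csv(paths["cells"], index=False)
    cohort.mitochondria.to_csv(paths["mitochondria"], index=False)
    provenance = {
        "generator_version": GENERATOR_VERSION,
        "seed": cohort.seed,
        "config": None if cohort.config is None else cohort.config.to_dict(),
    }
    with open(paths["provenance"], "w") as fh:
        json.dump(provenance, fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}


def _read_table(path, required, parser_name):
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        line = getattr(exc, "lineno", None) or _parse_error_line(str(exc))
        raise CohortFormatError(path, line or 0, f"unparsable {parser_name} CSV: {exc}") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CohortFormatError(path, 1, f"missing required columns {missing}")
    return df


def _parse_error_line(message: str):
    import re

    m = re.search(r"line (\d+)", message)
    return int(m.group(1)) if m else None


def read_cohort(in_dir) -> Cohort:
    """Read a cohort back; tolerant of extra columns, strict on invariants.

    A missing ``provenance.json`` yields a provenance warning and a cohort
    without config; invariant violations raise :class:`CohortFormatError`
    with the offending CSV line number (header = line 1).
    """
    from pathlib import Path

    in_dir = Path(in_dir)
    cells = _read_table(in_dir / "cells.csv", CELL_COLUMNS, "cells")
    mitos = _read_table(in_dir / "mitochondria.csv", MITO_COLUMNS, "mitochondria")

    mito_path = in_dir / "mitochondria.csv"
    for idx, row in mitos.iterrows():
        line = idx + 2  # header is line 1
        if row["dilution"] not in Dilution.ORDER:
            raise CohortFormatError(mito_path, line, f"unknown dilution {row['dilution']!r}")
        if not row["area_um2"] > 0:
            raise CohortFormatError(mito_path, line, f"area {row['area_um2']} must be > 0")
        if row["d_min_um"] > row["d_max_um"]:
            raise CohortFormatError(mito_path, line, "d_min exceeds d_max")
        bound = np.pi * row["d_max_um"] * row["d_min_um"] / 4.0 * ELLIPSE_SLACK
        if row["area_um2"] > bound:
            raise CohortFormatError(mito_path, line, "area exceeds ellipse plausibility bound")
        if not row["ed_norm"] > 0:
            raise CohortFormatError(mito_path, line, "ed_norm must be > 0")
        if any(row[f"gold_{p}"] < 0 for p in PROTEINS):
            raise CohortFormatError(mito_path, line, "negative gold count")
    known = set(mitos["cell_id"]) - set(cells["cell_id"])
    if known:
        raise CohortFormatError(mito_path, 1, f"orphan cell ids {sorted(known)[:3]}")

    config, seed = None, None
    prov_path = in_dir / "provenance.json"
    if prov_path.exists():
        with open(prov_path) as fh:
            prov = json.load(fh)
        seed = prov.get("seed")
        if prov.get("config") is not None:
            config = CalibrationConfig.from_dict(prov["config"])
    else:
        warnings.warn(f"{prov_path} missing: cohort loaded without provenance")
    return Cohort(cells, mitos, config=config, seed=seed)
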