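"""Calibration of the synthetic dose-response cohort.

The generator emulates a 72 h methamphetamine (METH) exposure of PC12
catecholamine cells at five doses (0, 10, 100, 500, 1000 uM).  Every
dose-level effect is stored in one :class:`CalibrationConfig`; entries that
reproduce a number printed in the source study are registered as *anchored*,
everything the study reports only qualitatively carries ``assumed`` status
and is machine-distinguishable via :meth:`CalibrationConfig.assumed_entries`.

Anchored quantities (default calibration):

* H&E-style survival at 1000 uM: 20% of control.
* TEM-assessed cell death at 1000 uM: 70%.
* Total mitochondria per cell at 100 uM: in excess of +25% over control
  (default fold 1.30).
* Mean mitochondrial area at 500-1000 uM: two-fold of control.
* MitoTracker-Green densitometry at 100 uM: in excess of 200% of control
  (default fold 2.10).
* Fis1 immunogold within mitochondria at 100 uM: 50% of control.
"""

from __future__ import annotations

import copy
import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

__all__ = [
    "PROTEINS",
    "COMPARTMENTS",
    "CalibrationError",
    "DoseEffects",
    "NoiseModel",
    "Baselines",
    "CalibrationConfig",
    "default_calibration",
    "null_calibration",
]

PROTEINS = ("fis1", "drp1", "pink1", "parkin")
COMPARTMENTS = ("cytosol", "mitochondrion")


class CalibrationError(ValueError):
    """Invalid calibration; ``field`` names the offending entry."""

    def __init__(self, field_name: str, message: str):
        self.field = field_name
        super().__init__(f"{field_name}: {message}")


@dataclass
class DoseEffects:
    """Per-dose effect sizes.

    Folds are ratios to the untreated control; probabilities are per-cell or
    per-mitochondrion Bernoulli parameters; ``mito_count_mean`` is the
    absolute expected mitochondrion count per cell profile.
    """

    survival_fraction: float
    fjb_positive_rate: float
    fjb_intensity_fold: float
    tb_positive_rate: float
    tem_death_fraction: float
    mito_count_mean: float
    p_dilution_spots: float
    p_dilution_widespread: float
    p_broken_crests: float
    p_ruptured_membranes: float
    area_fold: float
    ed_fold: float
    mtrg_fold: float
    mtrr_fold: float
    # gold_fold[protein][compartment]; the mitochondrion entry is the fold on
    # the expected per-cell total of particles within mitochondria.
    gold_fold: dict = field(default_factory=dict)

    _PROBS = (
        "survival_fraction",
        "fjb_positive_rate",
        "tb_positive_rate",
        "tem_death_fraction",
        "p_dilution_spots",
        "p_dilution_widespread",
        "p_broken_crests",
        "p_ruptured_membranes",
    )
    _FOLDS = ("fjb_intensity_fold", "area_fold", "ed_fold", "mtrg_fold", "mtrr_fold")

    def validate(self, dose) -> None:
        for name in self._PROBS:
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise CalibrationError(f"effects[{dose}].{name}", f"probability {v} outside [0, 1]")
        if self.p_dilution_spots + self.p_dilution_widespread > 1.0:
            raise CalibrationError(
                f"effects[{dose}].p_dilution_spots",
                "dilution category probabilities sum above 1",
            )
        for name in self._FOLDS:
            v = getattr(self, name)
            if not v > 0:
                raise CalibrationError(f"effects[{dose}].{name}", f"fold {v} must be > 0")
        if not self.mito_count_mean > 0:
            raise CalibrationError(f"effects[{dose}].mito_count_mean", "must be > 0")
        for protein in PROTEINS:
            if protein not in self.gold_fold:
                raise CalibrationError(f"effects[{dose}].gold_fold", f"missing protein {protein!r}")
            for comp in COMPARTMENTS:
                v = self.gold_fold[protein].get(comp)
                if v is None or not v > 0:
                    raise CalibrationError(
                        f"effects[{dose}].gold_fold[{protein}][{comp}]", f"fold {v} must be > 0"
                    )


@dataclass
class NoiseModel:
    """Dispersion parameters shared across doses.

    ``area_sigma_log`` / ``od_sigma_log`` / ``fjb_intensity_sigma_log`` are
    log-normal shape parameters; ``ed_sigma`` is the (absolute) sd of the
    matrix/cytosol density ratio; ``rate_concentration`` is the beta
    concentration applied to Bernoulli rates at replicate level;
    ``replicate_sigma`` is the sd of the multiplicative replicate random
    effect on continuous channel means (5% of the mean by default).
    """

    area_sigma_log: float = 0.35
    ed_sigma: float = 0.12
    od_sigma_log: float = 0.20
    fjb_intensity_sigma_log: float = 0.25
    rate_concentration: float = 300.0
    replicate_sigma: float = 0.05

    def validate(self) -> None:
        for name in ("area_sigma_log", "ed_sigma", "od_sigma_log", "fjb_intensity_sigma_log"):
            if getattr(self, name) < 0:
                raise CalibrationError(f"noise.{name}", "must be >= 0")
        if self.rate_concentration <= 0:
            raise CalibrationError("noise.rate_concentration", "must be > 0")
        if self.replicate_sigma < 0:
            raise CalibrationError("noise.replicate_sigma", "must be >= 0")


@dataclass
class Baselines:
    """Control-group means the per-dose folds multiply."""

    mito_count_mean: float = 40.0
    area_um2: float = 0.25
    ed_norm: float = 1.4
    mtrg_od: float = 100.0
    mtrr_od: float = 100.0
    fjb_intensity: float = 100.0
    # Expected immunogold particles per cell, control group.
    gold_cytosol: dict = field(
        default_factory=lambda: {"fis1": 30.0, "drp1": 25.0, "pink1": 8.0, "parkin": 15.0}
    )
    gold_mito_per_cell: dict = field(
        default_factory=lambda: {"fis1": 20.0, "drp1": 16.0, "pink1": 6.0, "parkin": 10.0}
    )

    def validate(self) -> None:
        for name in ("mito_count_mean", "area_um2", "ed_norm", "mtrg_od", "mtrr_od", "fjb_intensity"):
            if not getattr(self, name) > 0:
                raise CalibrationError(f"baselines.{name}", "must be > 0")
        for comp_name in ("gold_cytosol", "gold_mito_per_cell"):
            table = getattr(self, comp_name)
            for protein in PROTEINS:
                if table.get(protein, 0.0) < 0:
                    raise CalibrationError(f"baselines.{comp_name}[{protein}]", "must be >= 0")


@dataclass
class CalibrationConfig:
    """Full calibration: group sizes, per-dose effects, baselines, noise."""

    dose_levels: tuple = (0, 10, 100, 500, 1000)
    n_cells_he: int = 300
    n_cells_tem_death: int = 100
    n_cells_fluor: int = 90
    n_cells_morpho: int = 50
    n_mito_sampled: int = 150
    n_replicates: int = 3
    effects: dict = field(default_factory=dict)  # dose -> DoseEffects
    baselines: Baselines = field(default_factory=Baselines)
    noise: NoiseModel = field(default_factory=NoiseModel)
    seed: int = 0
    # "effects[<dose>].<field>" keys whose values reproduce a printed number.
    anchored: tuple = ()

    # -- validation ---------------------------------------------------------

    def validate(self) -> "CalibrationConfig":
        if len(self.dose_levels) < 2:
            raise CalibrationError("dose_levels", "need at least control plus one dose")
        if list(self.dose_levels) != sorted(set(self.dose_levels)):
            raise CalibrationError("dose_levels", "must be strictly increasing")
        for name in (
            "n_cells_he",
            "n_cells_tem_death",
            "n_cells_fluor",
            "n_cells_morpho",
            "n_mito_sampled",
            "n_replicates",
        ):
            if getattr(self, name) < 2:
                raise CalibrationError(name, "group sizes must be >= 2")
        for dose in self.dose_levels:
            if dose not in self.effects:
                raise CalibrationError("effects", f"missing dose row for {dose} uM")
            self.effects[dose].validate(dose)
        control = self.effects[self.dose_levels[0]]
        for name in DoseEffects._FOLDS:
            if getattr(control, name) != 1.0:
                raise CalibrationError(f"effects[{self.dose_levels[0]}].{name}", "control fold must be 1.0")
        for protein in PROTEINS:
            for comp in COMPARTMENTS:
                if control.gold_fold[protein][comp] != 1.0:
                    raise CalibrationError(
                        f"effects[{self.dose_levels[0]}].gold_fold[{protein}][{comp}]",
                        "control fold must be 1.0",
                    )
        self.baselines.validate()
        self.noise.validate()
        return self

    # -- expectations derived from the calibration --------------------------

    def stage_probabilities(self, dose) -> dict:
        """P(stage 1..4) implied by the independent damage draws at ``dose``.

        Stage precedence mirrors the scoring rubric: ruptured membranes
        dominate, then broken crests, then any matrix dilution.
        """
        e = self.effects[dose]
        p_dil = e.p_dilution_spots + e.p_dilution_widespread
        p1 = e.p_ruptured_membranes
        p2 = (1 - p1) * e.p_broken_crests
        p3 = (1 - e.p_ruptured_membranes) * (1 - e.p_broken_crests) * p_dil
        p4 = 1.0 - p1 - p2 - p3
        return {1: p1, 2: p2, 3: p3, 4: p4}

    def expected_altered_fraction(self, dose) -> float:
        return 1.0 - self.stage_probabilities(dose)[4]

    def expected_mean_stage(self, dose) -> float:
        return sum(s * p for s, p in self.stage_probabilities(dose).items())

    # -- provenance ---------------------------------------------------------

    def assumed_entries(self) -> list:
        """(key, value) pairs for every per-dose scalar not anchored to print."""
        anchored = set(self.anchored)
        out = []
        for dose in self.dose_levels:
            e = self.effects[dose]
            for name in DoseEffects._PROBS + DoseEffects._FOLDS + ("mito_count_mean",):
                key = f"effects[{dose}].{name}"
                if key not in anchored:
                    out.append((key, getattr(e, name)))
            for protein in PROTEINS:
                for comp in COMPARTMENTS:
                    key = f"effects[{dose}].gold_fold[{protein}][{comp}]"
                    if key not in anchored:
                        out.append((key, e.gold_fold[protein][comp]))
        return out

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dose_levels"] = list(self.dose_levels)
        d["anchored"] = list(self.anchored)
        d["effects"] = {str(dose): asdict(self.effects[dose]) for dose in self.dose_levels}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationConfig":
        d = copy.deepcopy(d)
        doses = tuple(d.pop("dose_levels"))
        effects_raw = d.pop("effects")
        effects = {}
        for dose in doses:
            raw = effects_raw.get(str(dose), effects_raw.get(dose))
            if raw is None:
                raise CalibrationError("effects", f"missing dose row for {dose} uM")
            effects[dose] = DoseEffects(**raw)
        baselines = Baselines(**d.pop("baselines", {}))
        noise = NoiseModel(**d.pop("noise", {}))
        anchored = tuple(d.pop("anchored", ()))
        return cls(
            dose_levels=doses,
            effects=effects,
            baselines=baselines,
            noise=noise,
            anchored=anchored,
            **d,
        ).validate()

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "CalibrationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def content_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()


def _dose_table() -> dict:
    """Default per-dose effect rows (0, 10, 100, 500, 1000 uM)."""
    rows = {
        #        surv  fjb+   fjbI  tb+   temD  nMito  spots  wide  crest  memb  area   ed   mtrg  mtrr
        0:    (1.00, 0.02, 1.00, 0.02, 0.05, 40.0, 0.05, 0.01, 0.04, 0.02, 1.00, 1.00, 1.00, 1.00),
        10:   (0.95, 0.18, 1.50, 0.18, 0.10, 44.0, 0.15, 0.05, 0.12, 0.08, 1.20, 0.90, 1.30, 0.85),
        100:  (0.70, 0.40, 2.50, 0.28, 0.35, 52.0, 0.25, 0.12, 0.25, 0.18, 1.50, 0.80, 2.10, 0.50),
        500:  (0.45, 0.50, 2.50, 0.38, 0.55, 44.0, 0.30, 0.25, 0.45, 0.35, 2.00, 0.65, 1.40, 0.50),
        1000: (0.20, 0.55, 2.50, 0.48, 0.70, 40.0, 0.30, 0.30, 0.50, 0.40, 2.00, 0.60, 1.10, 0.50),
    }
    gold = {
        "fis1":   {"cytosol": (1.00, 0.90, 0.70, 0.65, 0.60), "mitochondrion": (1.00, 0.80, 0.50, 0.45, 0.40)},
        "drp1":   {"cytosol": (1.00, 0.90, 0.65, 0.60, 0.55), "mitochondrion": (1.00, 0.85, 0.62, 0.55, 0.50)},
        "pink1":  {"cytosol": (1.00, 1.15, 1.40, 1.45, 1.50), "mitochondrion": (1.00, 1.40, 2.00, 2.10, 2.20)},
        "parkin": {"cytosol": (1.00, 1.10, 1.30, 1.35, 1.40), "mitochondrion": (1.00, 1.30, 1.80, 1.90, 2.00)},
    }
    effects = {}
    for i, (dose, row) in enumerate(rows.items()):
        effects[dose] = DoseEffects(
            survival_fraction=row[0],
            fjb_positive_rate=row[1],
            fjb_intensity_fold=row[2],
            tb_positive_rate=row[3],
            tem_death_fraction=row[4],
            mito_count_mean=row[5],
            p_dilution_spots=row[6],
            p_dilution_widespread=row[7],
            p_broken_crests=row[8],
            p_ruptured_membranes=row[9],
            area_fold=row[10],
            ed_fold=row[11],
            mtrg_fold=row[12],
            mtrr_fold=row[13],
            gold_fold={
                p: {comp: gold[p][comp][i] for comp in COMPARTMENTS} for p in PROTEINS
            },
        )
    return effects


_ANCHORED = (
    "effects[1000].survival_fraction",     # 20% of spared cells at 1000 uM
    "effects[1000].tem_death_fraction",    # ~70% cell loss by TEM at 1000 uM
    "effects[100].mito_count_mean",        # count in excess of +25% of control
    "effects[500].area_fold",              # area two-fold of control
    "effects[1000].area_fold",
    "effects[100].mtrg_fold",              # MTR-G in excess of 200% of control
    "effects[100].gold_fold[fis1][mitochondrion]",  # Fis1 in situ ~50% of control
)


def default_calibration(seed: int = 0) -> CalibrationConfig:
    """Default calibration anchored to the study's printed dose-response.

    Anchored entries are listed in ``CalibrationConfig.anchored``; every
    other effect size is an assumed default chosen to preserve the printed
    orderings (degeneration already significant at 10 uM while cell loss is
    not; damage probabilities monotone non-decreasing with dose and maximal
    at 500-1000 uM; matrix density ratio non-increasing; fission proteins
    down and mitophagy proteins up, more strongly within mitochondria).
    """
    return CalibrationConfig(effects=_dose_table(), seed=seed, anchored=_ANCHORED).validate()


def null_calibration(seed: int = 0, **sizes) -> CalibrationConfig:
    """Calibration with every dose effect switched off.

    All folds are 1, all rates equal the control baseline, and the
    replicate-level random effect is zeroed so cells are iid within a group:
    the configuration is a true null for checking test size. ``sizes``
    overrides group-size fields (e.g. ``n_cells_he=30``) for cheap batches.
    """
    config = default_calibration(seed=seed)
    control = config.effects[config.dose_levels[0]]
    config.effects = {dose: copy.deepcopy(control) for dose in config.dose_levels}
    config.anchored = ()
    config.noise.replicate_sigma = 0.0
    for name, value in sizes.items():
        if not hasattr(config, name):
            raise CalibrationError(name, "unknown group-size override")
        setattr(config, name, value)
    return config.validate()
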