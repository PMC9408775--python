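"""Cohort generation: determinism, calibration recovery, invariants, I/O."""

import numpy as np
import pandas as pd
import pytest

from mitomorph import (
    CohortFormatError,
    default_calibration,
    generate_cohort,
    read_cohort,
    write_cohort,
)
from mitomorph.cohort import assay_cells, sampled_mitochondria


class TestDeterminism:
    def test_same_config_and_seed_reproduce_frames(self, default_config, cohort42):
        again = generate_cohort(default_config, seed=42)
        pd.testing.assert_frame_equal(cohort42.cells, again.cells)
        pd.testing.assert_frame_equal(cohort42.mitochondria, again.mitochondria)

    def test_write_twice_is_byte_identical(self, tmp_path, cohort42):
        write_cohort(cohort42, tmp_path / "a")
        write_cohort(cohort42, tmp_path / "b")
        for name in ("cells.csv", "mitochondria.csv", "provenance.json"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_different_seeds_differ(self, default_config, cohort42):
        other = generate_cohort(default_config, seed=43)
        assert not cohort42.cells.equals(other.cells)


class TestStructure:
    def test_group_sizes_match_config(self, default_config, cohort42):
        counts = cohort42.cells.groupby("dose_um").size()
        for dose in default_config.dose_levels:
            assert counts[dose] == default_config.n_cells_he
        reps = cohort42.cells["replicate"].unique()
        assert sorted(reps) == list(range(default_config.n_replicates))

    def test_morphometry_subset_is_surviving_cells(self, default_config, cohort42):
        for dose in default_config.dose_levels:
            morpho = cohort42.morpho_cells_at(dose)
            assert len(morpho) <= default_config.n_cells_morpho
            assert len(morpho) >= default_config.n_cells_morpho - 5
            assert morpho["alive"].all()

    def test_mitochondrion_geometry_invariants(self, cohort42):
        m = cohort42.mitochondria
        assert (m["area_um2"] > 0).all()
        assert (m["d_min_um"] <= m["d_max_um"]).all()
        bound = np.pi * m["d_max_um"] * m["d_min_um"] / 4.0 * 1.05
        assert (m["area_um2"] <= bound).all()
        assert (m["ed_norm"] > 0).all()
        aspect = m["d_max_um"] / m["d_min_um"]
        assert aspect.between(1.0, 2.5).all()

    def test_sampled_mitochondria_spread_across_cells(self, default_config, cohort42):
        sample = sampled_mitochondria(cohort42, 0)
        assert len(sample) == default_config.n_mito_sampled
        # round-robin sampling touches (almost) every morphometry cell
        assert sample["cell_id"].nunique() >= 45

    def test_assay_cells_takes_stated_n_split_over_replicates(self, cohort42):
        sub = assay_cells(cohort42, 100, 90)
        assert len(sub) == 90
        assert sub.groupby("replicate").size().tolist() == [30, 30, 30]


class TestCalibrationRecovery:
    def test_area_ratio_recovers_configured_fold(self, default_config, cohort42):
        a0 = sampled_mitochondria(cohort42, 0)["area_um2"].mean()
        a1000 = sampled_mitochondria(cohort42, 1000)["area_um2"].mean()
        target = default_config.effects[1000].area_fold
        assert a1000 / a0 == pytest.approx(target, rel=0.15)

    def test_degenerate_probability_forces_flag(self):
        cfg = default_calibration()
        cfg.effects[500].p_broken_crests = 1.0
        cohort = generate_cohort(cfg, seed=7)
        cells = cohort.morpho_cells_at(500)
        mitos = cohort.mitochondria_of(cells["cell_id"])
        assert mitos["crests_broken"].all()

    def test_anchor_recovery_with_large_group_sizes(self):
        """Empirical group statistics converge to the configured anchors as
        group sizes grow (cells x30, experiments x10, so that a 5% relative
        band is > 2 sigma of the remaining sampling noise)."""
        cfg = default_calibration()
        cfg.n_cells_he *= 30
        cfg.n_cells_fluor *= 10
        cfg.n_cells_morpho *= 10
        cfg.n_mito_sampled *= 10
        cfg.n_replicates *= 10
        cohort = generate_cohort(cfg, seed=123)

        alive = cohort.cells.groupby("dose_um")["alive"].mean()
        assert alive[1000] / alive[0] == pytest.approx(0.20, rel=0.05)

        mtrg = cohort.cells.groupby("dose_um")["mtrg_od"].mean()
        assert mtrg[100] / mtrg[0] == pytest.approx(
            cfg.effects[100].mtrg_fold, rel=0.05)

        def count_mean(dose):
            cells = cohort.morpho_cells_at(dose)
            return cohort.mitochondria_of(cells["cell_id"]).groupby("cell_id").size().mean()

        assert count_mean(100) / count_mean(0) == pytest.approx(
            cfg.effects[100].mito_count_mean / cfg.effects[0].mito_count_mean, rel=0.05)

        def fis1_mean(dose):
            cells = cohort.morpho_cells_at(dose)
            return (cohort.mitochondria_of(cells["cell_id"])
                    .groupby("cell_id")["gold_fis1"].sum().mean())

        assert fis1_mean(100) / fis1_mean(0) == pytest.approx(0.50, rel=0.05)


class TestRoundTrip:
    def test_write_read_equality(self, tmp_path, cohort42):
        write_cohort(cohort42, tmp_path)
        loaded = read_cohort(tmp_path)
        pd.testing.assert_frame_equal(loaded.cells, cohort42.cells)
        pd.testing.assert_frame_equal(loaded.mitochondria, cohort42.mitochondria)
        assert loaded.config.to_dict() == cohort42.config.to_dict()
        assert loaded.seed == cohort42.seed

    def test_record_access_round_trips(self, cohort42):
        cell_id = cohort42.mitochondria["cell_id"].iloc[0]
        record = cohort42.cell(cell_id)
        frame_count = (cohort42.mitochondria["cell_id"] == cell_id).sum()
        assert len(record.mitochondria) == frame_count
        m = record.mitochondria[0]
        assert m.validate() is m

    def test_negative_area_rejected_with_line_number(self, tmp_path, cohort42):
        write_cohort(cohort42, tmp_path)
        path = tmp_path / "mitochondria.csv"
        df = pd.read_csv(path)
        df.loc[4, "area_um2"] = -0.2
        df.to_csv(path, index=False)
        with pytest.raises(CohortFormatError, match="line 6"):
            read_cohort(tmp_path)

    def test_extra_column_preserved(self, tmp_path, cohort42):
        write_cohort(cohort42, tmp_path)
        path = tmp_path / "cells.csv"
        df = pd.read_csv(path)
        df["operator_note"] = "grid-3"
        df.to_csv(path, index=False)
        loaded = read_cohort(tmp_path)
        assert "operator_note" in loaded.cells.columns
        assert (loaded.cells["operator_note"] == "grid-3").all()

    def test_missing_provenance_warns(self, tmp_path, cohort42):
        write_cohort(cohort42, tmp_path)
        (tmp_path / "provenance.json").unlink()
        with pytest.warns(UserWarning, match="provenance"):
            loaded = read_cohort(tmp_path)
        assert loaded.config is None
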