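"""Duplicate averaging, control-bead normalization and ratio-to-control."""

import numpy as np
import pandas as pd
import pytest

from posthypoxia.panel import AnalytePanel
from posthypoxia.plate import CHEX_COLUMNS, LuminexPlate
from posthypoxia.preprocess import (
    average_duplicates,
    chex_normalize,
    ratio_to_control,
)
from posthypoxia.simulate import SimConfig, simulate_luminex_plate

PANEL2 = AnalytePanel(("A", "B"))


def toy_plate(rows):
    df = pd.DataFrame(
        rows, columns=["sample", "group", "tissue", "duplicate", "A", "B",
                       *CHEX_COLUMNS]
    )
    return LuminexPlate(data=df, panel=PANEL2)


class TestAverageDuplicates:
    def test_arithmetic_mean_of_duplicates(self):
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
            ("s1", "control", "plasma", 2, 120.0, 30.0, 1, 1, 1, 7.0),
        ])
        m = average_duplicates(plate)
        assert m.values.loc["s1", "A"] == 110.0
        assert m.values.loc["s1", "B"] == 20.0
        assert m.chex.loc["s1", "CHEX4"] == 6.0

    def test_single_well_sample_unchanged(self):
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
        ])
        assert average_duplicates(plate).values.loc["s1", "A"] == 100.0

    def test_zero_duplicate_cv_makes_duplicates_equal(self):
        cfg = SimConfig(noise_cv=0.1, well_scale_sd=0.0, duplicate_cv=0.0, seed=3)
        plate = simulate_luminex_plate(cfg)
        wide = plate.data.pivot(index="sample", columns="duplicate",
                                values=plate.analytes[0])
        assert np.allclose(wide[1], wide[2])
        m = average_duplicates(plate)
        assert np.allclose(m.values[plate.analytes[0]], wide[1])

    def test_three_wells_is_an_error(self):
        plate_df = pd.DataFrame([
            ("s1", "control", "plasma", 1, 1.0, 1.0, 1, 1, 1, 1.0),
            ("s1", "control", "plasma", 2, 1.0, 1.0, 1, 1, 1, 1.0),
        ], columns=["sample", "group", "tissue", "duplicate", "A", "B", *CHEX_COLUMNS])
        plate = LuminexPlate(plate_df, panel=PANEL2)
        plate.data = pd.concat(
            [plate.data, plate.data.iloc[[0]].assign(duplicate=2)],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="more than 2 wells"):
            average_duplicates(plate)


class TestChexNormalize:
    def test_equal_chex_is_identity(self):
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
            ("s2", "post1h", "plasma", 1, 50.0, 20.0, 1, 1, 1, 5.0),
        ])
        m = average_duplicates(plate)
        norm = chex_normalize(m)
        assert np.allclose(norm.values, m.values)

    def test_joint_rescaling_is_removed(self):
        # second sample is the first with every bead (analytes and Chex)
        # scaled by 2: normalization must make them equal
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
            ("s2", "control", "plasma", 1, 200.0, 20.0, 2, 2, 2, 10.0),
        ])
        norm = chex_normalize(average_duplicates(plate))
        assert np.allclose(norm.values.loc["s1"], norm.values.loc["s2"])

    def test_simulated_well_drift_removed_exactly(self):
        cfg = SimConfig(noise_cv=0.0, well_scale_sd=0.2, duplicate_cv=0.0,
                        affected_analytes=((0, "post1h", 2.0),), seed=11)
        drift_free = SimConfig(noise_cv=0.0, well_scale_sd=0.0, duplicate_cv=0.0,
                               affected_analytes=((0, "post1h", 2.0),), seed=11)
        norm = chex_normalize(average_duplicates(simulate_luminex_plate(cfg)))
        ref = chex_normalize(average_duplicates(simulate_luminex_plate(drift_free)))
        # exact removal up to the plate-median factor of the realized scales
        factor = norm.values.to_numpy() / ref.values.to_numpy()
        assert np.allclose(factor, factor.flat[0], rtol=1e-10)

    def test_missing_chex_rejected(self):
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
        ])
        m = average_duplicates(plate)
        m.chex = None
        with pytest.raises(ValueError, match="CHEX4"):
            chex_normalize(m)


class TestRatioToControl:
    def test_group_equal_to_control_gives_one(self):
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
            ("s2", "post1h", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
        ])
        m = chex_normalize(average_duplicates(plate))
        assert np.allclose(ratio_to_control(m, "post1h"), 1.0)

    def test_noise_free_fold_recovered_exactly(self):
        cfg = SimConfig(noise_cv=0.0, well_scale_sd=0.0, duplicate_cv=0.0,
                        affected_analytes=((0, "post1h", 2.0),), seed=0)
        m = chex_normalize(average_duplicates(simulate_luminex_plate(cfg)))
        ratios = ratio_to_control(m, "post1h")
        assert ratios.iloc[0] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(ratios.iloc[1:], 1.0)

    def test_unknown_group_rejected(self):
        plate = toy_plate([
            ("s1", "control", "plasma", 1, 100.0, 10.0, 1, 1, 1, 5.0),
        ])
        m = average_duplicates(plate)
        with pytest.raises(ValueError, match="post1h"):
            ratio_to_control(m, "post1h")

    def test_averaging_commutes_with_normalization_noise_free(self):
        cfg = SimConfig(noise_cv=0.0, well_scale_sd=0.1, duplicate_cv=0.0, seed=5)
        plate = simulate_luminex_plate(cfg)
        # normalize each well first, then average
        well = plate.data.copy()
        analytes = plate.analytes
        factor = well["CHEX4"] / np.median(well["CHEX4"])
        well[analytes] = well[analytes].div(factor, axis=0)
        first = well.groupby("sample", sort=False)[analytes].mean()
        # average duplicates first, then normalize
        second = chex_normalize(average_duplicates(plate)).values
        # medians of well-level vs sample-level Chex differ only by the
        # common plate rescaling, so compare up to one global factor
        ratio = (first / second.loc[first.index]).to_numpy()
        assert np.allclose(ratio, ratio.flat[0])
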