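"""Relative values, reduction factors, marker selection and the SPI."""

import numpy as np
import pandas as pd
import pytest

from saltscreen import simulate
from saltscreen.performance import (
    MarkerSelectionError,
    UndefinedRatioError,
    reduction_factors,
    relative_values,
    select_marker,
    spi,
    spi_correlations,
)


def _flat_panel(depression=1.0, params=("PIabs", "A"), n_varieties=3):
    """Noise-free panel: medium = depression x low for every parameter/stage."""
    rows = []
    for v in range(n_varieties):
        for stage in ("leaf3", "boot", "flowering"):
            for platform in ("low", "medium"):
                for rep in range(1, 7):
                    row = {
                        "variety": f"V{v + 1}",
                        "stage": stage,
                        "platform": platform,
                        "replicate": rep,
                    }
                    for p in params:
                        base = 2.0 + v
                        row[p] = base * (depression if platform == "medium" else 1.0)
                    row["dry_matter"] = 100.0 if stage == "flowering" else np.nan
                    rows.append(row)
    return pd.DataFrame(rows)


class TestRelativeValues:
    def test_direct_ratio(self):
        panel = _flat_panel(depression=0.5)
        rel = relative_values(panel)
        assert np.allclose(rel["relative_value"], 0.5)

    def test_identity_panel(self):
        rel = relative_values(_flat_panel(depression=1.0))
        assert np.allclose(rel["relative_value"], 1.0)
        assert np.allclose(rel["dm_gain"], 1.0)

    def test_planted_depression_recovered(self):
        cfg = simulate.PanelSimConfig(
            n_varieties=4,
            depression={p: {s: 0.6 for s in ("leaf3", "boot", "flowering")} for p in ("PIabs", "A")},
            variety_rf_sd=0.0,
            replicate_cv=0.01,
            seed=5,
        )
        rel = relative_values(simulate.simulate_panel(cfg))
        assert rel["relative_value"].mean() == pytest.approx(0.6, abs=0.02)

    def test_scale_invariance(self):
        panel = _flat_panel(depression=0.7)
        scaled = panel.copy()
        scaled[["PIabs", "A"]] *= 37.5
        r1 = relative_values(panel)["relative_value"]
        r2 = relative_values(scaled)["relative_value"]
        assert np.allclose(r1, r2)

    def test_zero_low_mean_raises(self):
        panel = _flat_panel()
        panel.loc[panel["platform"] == "low", "PIabs"] = 0.0
        with pytest.raises(UndefinedRatioError, match="PIabs"):
            relative_values(panel)


class TestReductionFactors:
    def test_direct_and_identity_ratios(self):
        rel = pd.DataFrame(
            {
                "variety": ["V1"] * 3 + ["V2"] * 3,
                "stage": ["leaf3", "boot", "flowering"] * 2,
                "parameter": ["PIabs"] * 6,
                "relative_value": [0.9, 0.6, 0.45, 0.8, 0.8, 0.8],
            }
        )
        rfs = reduction_factors(rel)
        by_v = rfs.set_index("variety")["RF"]
        assert by_v["V1"] == pytest.approx(2.0)
        assert by_v["V2"] == pytest.approx(1.0)

    def test_planted_rf_recovered(self, small_panel):
        rel = relative_values(small_panel)
        rfs = reduction_factors(rel, small_panel)
        mean_rf = rfs[rfs["parameter"] == "PIabs"]["RF"].mean()
        assert mean_rf == pytest.approx(0.85 / 0.37, rel=0.1)

    def test_significance_flag_from_contrast(self, small_panel):
        rfs = reduction_factors(relative_values(small_panel), small_panel)
        piabs = rfs[rfs["parameter"] == "PIabs"]
        assert piabs["significant"].all()


class TestSelectMarker:
    def test_highest_consistent_rf_wins(self, small_panel):
        rfs = reduction_factors(relative_values(small_panel), small_panel)
        marker, n = select_marker(rfs, consistency_fraction=1.0)
        assert marker == "PIabs"
        assert n == 2

    def test_rounding_floor_at_one(self):
        rfs = pd.DataFrame(
            {
                "variety": ["V1", "V2"] * 2,
                "parameter": ["A", "A", "B", "B"],
                "RF": [1.1, 1.2, 1.05, 1.1],
                "significant": [True] * 4,
            }
        )
        marker, n = select_marker(rfs)
        assert (marker, n) == ("A", 1)

    def test_tie_broken_order_invariantly(self):
        base = pd.DataFrame(
            {
                "variety": ["V1", "V2"] * 2,
                "parameter": ["X", "X", "Y", "Y"],
                "RF": [2.0, 2.0, 2.0, 2.0],
                "significant": [True, True, True, False],
            }
        )
        m1, _ = select_marker(base, consistency_fraction=0.5)
        m2, _ = select_marker(base.iloc[::-1].reset_index(drop=True), consistency_fraction=0.5)
        assert m1 == m2 == "X"  # larger significant fraction wins the tie

    def test_no_consistent_parameter_raises(self):
        rfs = pd.DataFrame(
            {
                "variety": ["V1", "V2"] * 2,
                "parameter": ["A", "A", "B", "B"],
                "RF": [2.0, 0.5, 1.5, 0.9],
                "significant": [True, False, False, False],
            }
        )
        with pytest.raises(MarkerSelectionError):
            select_marker(rfs)


class TestSPI:
    def _rel(self, a, b):
        return pd.DataFrame(
            {
                "variety": ["V1", "V1"],
                "stage": ["leaf3", "flowering"],
                "parameter": ["PIabs", "PIabs"],
                "relative_value": [a, b],
            }
        )

    def test_identity_is_zero(self):
        out = spi(self._rel(1.0, 1.0), "PIabs", 2)
        assert out["SPI"].iloc[0] == pytest.approx(0.0)

    def test_hand_computed(self):
        out = spi(self._rel(1.2, 0.6), "PIabs", 2)
        assert out["SPI"].iloc[0] == pytest.approx(
            np.log10(1.2) + 2 * np.log10(0.6)
        )
        assert out["SPI"].iloc[0] == pytest.approx(-0.3645, abs=5e-4)

    def test_nonpositive_raises(self):
        with pytest.raises(ValueError, match="non-positive"):
            spi(self._rel(1.0, 0.0), "PIabs", 2)

    def test_doubling_b_adds_n_log2(self):
        s1 = spi(self._rel(1.1, 0.4), "PIabs", 3)["SPI"].iloc[0]
        s2 = spi(self._rel(1.1, 0.8), "PIabs", 3)["SPI"].iloc[0]
        assert s2 - s1 == pytest.approx(3 * np.log10(2.0))

    def test_monotone_in_a_and_b(self):
        s = lambda a, b: spi(self._rel(a, b), "PIabs", 2)["SPI"].iloc[0]
        assert s(1.2, 0.5) > s(1.0, 0.5)
        assert s(1.0, 0.6) > s(1.0, 0.5)


class TestSPICorrelations:
    def test_self_correlation_is_one(self, small_panel):
        rel = relative_values(small_panel)
        out = spi(rel, "PIabs", 2)
        out["dm_gain"] = out["SPI"]  # SPI vs itself
        rep = spi_correlations(out)
        assert rep["pairs"]["SPI_vs_dm_gain"]["r"] == pytest.approx(1.0)

    def test_collinear_r2_is_one(self, small_panel):
        rel = relative_values(small_panel)
        out = spi(rel, "PIabs", 2)
        out["dm_gain"] = 2.0 * out["SPI"] + 1.0
        rep = spi_correlations(out)
        assert rep["pairs"]["SPI_vs_dm_gain"]["r2"] == pytest.approx(1.0)

    def test_zero_variance_raises(self, small_panel):
        rel = relative_values(small_panel)
        out = spi(rel, "PIabs", 2)
        out["dm_gain"] = 1.0
        with pytest.raises(ValueError, match="zero variance"):
            spi_correlations(out)

    def test_planted_dm_correlation_recovered(self):
        """Monte-Carlo: planted r = 0.8 between dry-matter gain and SPI, 18
        varieties; mean recovered r over repeated panels within 0.1."""
        rs = []
        for seed in range(60):
            panel = simulate.simulate_panel(simulate.PanelSimConfig(seed=seed))
            rel = relative_values(panel)
            out = spi(rel, "PIabs", 2)
            rep = spi_correlations(out)
            rs.append(rep["pairs"]["SPI_vs_dm_gain"]["r"])
        assert np.mean(rs) == pytest.approx(0.8, abs=0.1)
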