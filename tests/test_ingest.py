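import numpy as np
import pandas as pd
import pytest

from healthvuln import (
    CountryIndicatorRecord,
    InconsistencyError,
    OrdinalDataset,
    ValidationError,
    backout_levels,
    read_country_indicators,
)
from healthvuln.errors import ConfigurationError
from healthvuln.ingest import write_country_indicators


class TestCountryIndicatorRecord:
    def test_valid_record_with_prose_categories(self):
        rec = CountryIndicatorRecord(
            "Malawi", 40.0, 64.7, "Stagnation", "In Debt Distress"
        )
        assert rec.budget_space == "stagnation"
        assert rec.debt_risk == "in_distress_or_very_high"

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"che_per_capita": -1.0},
            {"external_share": 120.0},
            {"external_share": -0.1},
            {"budget_space": "boom"},
            {"debt_risk": "catastrophic"},
            {"poverty_rate": 101.0},
        ],
    )
    def test_out_of_range_values_rejected(self, kwargs):
        base = dict(
            country_name="X",
            che_per_capita=40.0,
            external_share=10.0,
            budget_space="expansion",
            debt_risk="low_or_na",
        )
        base.update(kwargs)
        with pytest.raises(ValidationError):
            CountryIndicatorRecord(**base)

    @pytest.mark.parametrize(
        "label,expected",
        [
            ("N/A", "low_or_na"), ("Low", "low_or_na"), ("Very High", "in_distress_or_very_high"),
            ("high", "high"), ("Moderate", "moderate"),
        ],
    )
    def test_debt_risk_synonyms(self, label, expected):
        rec = CountryIndicatorRecord("X", 40, 10, "expansion", label)
        assert rec.debt_risk == expected


class TestReadCountryIndicators:
    def _write(self, tmp_path, text):
        p = tmp_path / "in.csv"
        p.write_text(text, encoding="utf-8")
        return p

    def test_reads_valid_rows_in_order(self, tmp_path):
        p = self._write(
            tmp_path,
            "country,che_per_capita_usd,external_share_pct,budget_space,debt_risk\n"
            "Malawi,40,64.7,stagnation,in_distress_or_very_high\n"
            "Nigeria,91,6.8,expansion,low_or_na\n",
        )
        recs = read_country_indicators(p)
        assert [r.country_name for r in recs] == ["Malawi", "Nigeria"]
        assert recs[0].external_share == 64.7

    def test_missing_column_named_in_error(self, tmp_path):
        p = self._write(tmp_path, "country,che_per_capita_usd\nA,40\n")
        with pytest.raises(ConfigurationError, match="external_share_pct"):
            read_country_indicators(p)

    def test_column_map_renames(self, tmp_path):
        p = self._write(
            tmp_path,
            "name,che,ext,bsp,dsa\nMalawi,40,64.7,stagnation,high\n",
        )
        recs = read_country_indicators(
            p,
            column_map={
                "name": "country", "che": "che_per_capita_usd",
                "ext": "external_share_pct", "bsp": "budget_space", "dsa": "debt_risk",
            },
        )
        assert recs[0].country_name == "Malawi"

    def test_invalid_row_reported_with_row_number(self, tmp_path):
        p = self._write(
            tmp_path,
            "country,che_per_capita_usd,external_share_pct,budget_space,debt_risk\n"
            "A,40,10,expansion,low\n"
            "B,40,120,expansion,low\n",
        )
        with pytest.raises(ValidationError, match="row 2"):
            read_country_indicators(p)

    def test_empty_file_is_an_error(self, tmp_path):
        p = self._write(
            tmp_path,
            "country,che_per_capita_usd,external_share_pct,budget_space,debt_risk\n",
        )
        with pytest.raises(ValidationError, match="no records"):
            read_country_indicators(p)

    def test_roundtrip_write_read(self, tmp_path):
        recs = [
            CountryIndicatorRecord("Malawi", 40, 64.7, "stagnation", "high", 52.0),
            CountryIndicatorRecord("Nigeria", 91, 6.8, "expansion", "low_or_na", 31.0),
        ]
        p = tmp_path / "out.csv"
        write_country_indicators(recs, p)
        assert read_country_indicators(p) == recs


class TestOrdinalDataset:
    def test_level_bounds_enforced(self):
        with pytest.raises(ValidationError):
            OrdinalDataset(["A"], np.array([[5, 1]]), ["f1", "f2"], [4, 5], [4, 5])

    def test_metadata_lengths_enforced(self):
        with pytest.raises(ConfigurationError):
            OrdinalDataset(["A"], np.array([[1, 1]]), ["f1"], [4, 5], [4, 5])


class TestBackoutLevels:
    W = np.array([32.10, 30.70, 7.60, 29.60])
    DEN = [4, 5, 3, 5]

    def test_malawi_row(self):
        ds = backout_levels(
            np.array([[32.10, 30.70, 5.07, 23.68]]), self.W, self.DEN, countries=["Malawi"]
        )
        assert ds.levels.tolist() == [[4, 5, 2, 4]]

    def test_all_minimum_row(self):
        ds = backout_levels(np.array([[8.03, 6.14, 2.53, 5.92]]), self.W, self.DEN)
        assert ds.levels.tolist() == [[1, 1, 1, 1]]

    def test_inconsistent_cell_flagged_with_location(self):
        # 16.00 / 32.10 * 4 = 1.994, not an integer within the 2-dp band
        with pytest.raises(InconsistencyError, match="Gondor.*che"):
            backout_levels(
                np.array([[16.00, 6.14, 2.53, 5.92]]),
                self.W, self.DEN, countries=["Gondor"], factor_names=["che", "fad", "bsp", "ctb"],
            )

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ConfigurationError):
            backout_levels(np.array([[1.0, 1.0]]), [1.0, 0.0], [4, 5])

    def test_roundtrip_on_all_reference_rows(self, reference_components, reference_levels):
        """Recomputing level/denominator*weight reproduces every published
        component cell within the 2-dp print tolerance."""
        recomputed = reference_levels.levels / np.array(self.DEN) * self.W
        printed = reference_components[
            ["che_component", "fad_component", "bsp_component", "ctb_component"]
        ].to_numpy()
        assert np.abs(recomputed - printed).max() <= 0.005 + 1e-12
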