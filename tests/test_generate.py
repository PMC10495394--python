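"""Virtual-drug library: sampling, BCS classification, real-drug matching."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pkdistill import ParameterRanges, classify_bcs, match_real_drugs, sample_virtual_drugs
from pkdistill.generate import (
    DEFAULT_PERMEABILITY_THRESHOLD,
    DEFAULT_SOLUBILITY_THRESHOLD,
    MATCH_PROPERTIES,
)
from pkdistill.ranges import FEATURE_COLUMNS, ConfigurationError


class TestSampling:
    def test_exact_count_and_columns(self):
        lib = sample_virtual_drugs(n=50, seed=0)
        assert len(lib) == 50
        assert list(lib.columns) == ["id", *FEATURE_COLUMNS, "bcs_class"]

    def test_every_value_inside_its_range(self):
        ranges = ParameterRanges()
        lib = sample_virtual_drugs(ranges, n=2000, seed=3)
        for col, (lo, hi) in ranges.feature_bounds().items():
            assert lib[col].between(lo, hi).all(), col

    def test_seed_determinism_is_byte_stable(self):
        a = sample_virtual_drugs(n=200, seed=42).to_csv(index=False)
        b = sample_virtual_drugs(n=200, seed=42).to_csv(index=False)
        assert a == b
        c = sample_virtual_drugs(n=200, seed=43).to_csv(index=False)
        assert a != c

    def test_degenerate_range_rejected_with_parameter_name(self):
        with pytest.raises(ConfigurationError, match="solubility"):
            ParameterRanges(solubility=(5.0, 5.0))
        with pytest.raises(ConfigurationError, match="dose"):
            ParameterRanges(dose=(100.0, 10.0))

    def test_sample_mean_matches_uniform_mean(self):
        """Empirical solubility mean sits within 3 SE of the uniform mean."""
        lib = sample_virtual_drugs(n=10_000, seed=11)
        lo, hi = 0.001, 1000.0
        expected = (lo + hi) / 2
        se = (hi - lo) / np.sqrt(12 * len(lib))
        assert abs(lib["solubility"].mean() - expected) < 3 * se

    @pytest.mark.parametrize(
        "column", ["molecular_mass", "solubility", "fupc_liver", "vmax", "dose"]
    )
    def test_marginals_are_uniform(self, column):
        """KS test against the uniform CDF on the configured range."""
        ranges = ParameterRanges()
        lib = sample_virtual_drugs(ranges, n=10_000, seed=5)
        lo, hi = ranges.feature_bounds()[column]
        res = stats.kstest(lib[column], stats.uniform(loc=lo, scale=hi - lo).cdf)
        assert res.pvalue > 0.001

    def test_per_tissue_fupc_draws_are_independent(self):
        lib = sample_virtual_drugs(n=5000, seed=8)
        corr = lib[["fupc_liver", "fupc_colon"]].corr().iloc[0, 1]
        assert abs(corr) < 0.05


class TestBCS:
    def _drug_row(self, sol, perm):
        return pd.DataFrame({"solubility": [sol], "effective_permeability": [perm]})

    @pytest.mark.parametrize(
        "sol,perm,expected",
        [
            (1000.0, 8.0, "I"),  # both at range maxima
            (0.001, 0.015, "IV"),  # both at range minima
            (0.001, 8.0, "II"),
            (1000.0, 0.015, "III"),
        ],
    )
    def test_corner_classes(self, sol, perm, expected):
        cls = classify_bcs(self._drug_row(sol, perm))
        assert cls.iloc[0] == expected

    def test_threshold_value_counts_as_low(self):
        cls = classify_bcs(
            self._drug_row(DEFAULT_SOLUBILITY_THRESHOLD, DEFAULT_PERMEABILITY_THRESHOLD)
        )
        assert cls.iloc[0] == "IV"

    def test_classes_partition_library(self):
        lib = sample_virtual_drugs(n=3000, seed=2)
        counts = classify_bcs(lib, 100.0, 1.0).value_counts()
        assert counts.sum() == 3000
        assert set(counts.index) <= {"I", "II", "III", "IV"}

    def test_class_fractions_match_marginal_products(self):
        """Under uniform sampling the class fractions are products of the
        marginal exceedance probabilities of the two thresholds."""
        n = 15_000
        lib = sample_virtual_drugs(n=n, seed=13)
        counts = lib["bcs_class"].value_counts()
        p_sol = (1000.0 - 250.0) / (1000.0 - 0.001)
        p_perm = (8.0 - 3.5) / (8.0 - 0.015)
        expected = {
            "I": p_sol * p_perm,
            "II": (1 - p_sol) * p_perm,
            "III": p_sol * (1 - p_perm),
            "IV": (1 - p_sol) * (1 - p_perm),
        }
        for cls, p in expected.items():
            sd = np.sqrt(n * p * (1 - p))
            assert abs(counts[cls] - n * p) < 3 * sd, cls


class TestMatching:
    def _virtual(self):
        lib = sample_virtual_drugs(n=500, seed=21)
        return lib

    def test_identical_drug_is_a_close_match(self):
        virtual = self._virtual()
        row = virtual.iloc[7]
        real = pd.DataFrame(
            [{
                "molecular_mass": row["molecular_mass"],
                "density": row["drug_density"],
                "molar_volume": row["molar_volume"],
                "pka": row["pka"],
                "solubility": row["solubility"],
                "effective_permeability": row["effective_permeability"],
            }]
        )
        report = match_real_drugs(real, virtual)
        assert report.per_drug["match_grade"].iloc[0] == "close"
        assert report.close_frac == 1.0 and report.any_frac == 1.0

    def test_thirty_percent_offset_is_moderate_not_close(self):
        """A real drug whose every property sits exactly 30% away from its
        nearest virtual drug: 0.15 < 0.30 <= 0.50."""
        virtual = pd.DataFrame(
            [{
                "id": "vd0",
                "molecular_mass": 130.0,
                "drug_density": 0.13,
                "molar_volume": 130.0,
                "pka": 1.3,
                "solubility": 13.0,
                "effective_permeability": 1.3,
            }]
        )
        real = pd.DataFrame(
            [{
                "molecular_mass": 100.0,
                "density": 0.1,
                "molar_volume": 100.0,
                "pka": 1.0,
                "solubility": 10.0,
                "effective_permeability": 1.0,
            }]
        )
        report = match_real_drugs(real, virtual)
        assert report.per_drug["match_grade"].iloc[0] == "moderate"
        assert report.close_frac == 0.0 and report.any_frac == 1.0

    def test_missing_column_raises_with_names(self):
        real = pd.DataFrame([{"molecular_mass": 100.0, "pka": 2.0}])
        with pytest.raises(ValueError, match="solubility"):
            match_real_drugs(real, self._virtual())

    def test_enlarging_tolerance_never_reduces_any_frac(self):
        virtual = self._virtual()
        rng = np.random.default_rng(4)
        real = pd.DataFrame(
            {
                "molecular_mass": rng.uniform(50, 800, 10),
                "density": rng.uniform(0.2, 0.6, 10),
                "molar_volume": rng.uniform(50, 900, 10),
                "pka": rng.uniform(1, 12, 10),
                "solubility": rng.uniform(0.1, 500, 10),
                "effective_permeability": rng.uniform(0.1, 6, 10),
            }
        )
        fracs = [
            match_real_drugs(real, virtual, moderate_tol=t).any_frac
            for t in (0.3, 0.5, 0.8, 1.5)
        ]
        assert fracs == sorted(fracs)

    def test_case_insensitive_columns(self):
        virtual = self._virtual()
        real = pd.DataFrame(
            [{
                "Molecular_Mass": 300.0,
                "DENSITY": 0.4,
                "Molar_Volume": 300.0,
                "pKa": 5.0,
                "Solubility": 100.0,
                "Effective_Permeability": 3.0,
            }]
        )
        report = match_real_drugs(real, virtual)
        assert len(report.per_drug) == 1
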