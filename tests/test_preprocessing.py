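"""Cleaning filters, species-area model, under-sampling rule, ICE coverage."""

import numpy as np
import pandas as pd
import pytest

from islandpe import BoundingBox, GenusAnnotations, OccurrenceRecord
from islandpe.io_formats import ConfigurationError, ValidationError
from islandpe.preprocessing import (
    CoverageScore,
    exclude_undersampled,
    filter_bounding_box,
    filter_native_status,
    fit_richness_model,
    ice_coverage,
    ice_richness,
)


def rec(genus="A", island="I1", lat=0.0, lon=120.0):
    return OccurrenceRecord(genus, island, lat, lon)


class TestNativeStatusFilter:
    ann = GenusAnnotations(
        native_status={("A", "R1"): "non_native", ("B", "R1"): "native"}
    )
    regions = {"I1": "R1"}

    def test_non_native_removed(self):
        kept, rep = filter_native_status([rec("A")], self.ann, self.regions)
        assert kept == [] and rep.n_removed == 1

    def test_native_retained(self):
        kept, rep = filter_native_status([rec("B")], self.ann, self.regions)
        assert len(kept) == 1 and rep.n_removed == 0

    def test_unknown_status_falls_through(self):
        kept, rep = filter_native_status([rec("C")], self.ann, self.regions)
        assert len(kept) == 1 and rep.n_untested == 1

    def test_missing_region_mapping_passes_with_warning(self):
        kept, rep = filter_native_status([rec("A", island="I9")], self.ann, self.regions)
        assert len(kept) == 1 and rep.n_untested == 1

    def test_idempotent(self):
        records = [rec("A"), rec("B"), rec("C")]
        once, _ = filter_native_status(records, self.ann, self.regions)
        twice, rep2 = filter_native_status(once, self.ann, self.regions)
        assert twice == once and rep2.n_removed == 0


class TestBoundingBoxFilter:
    ann = GenusAnnotations(
        bounding_box={
            "A": BoundingBox(-10, 10, 100, 140),
            "W": BoundingBox(-10, 10, 170, -160),
        }
    )

    @pytest.mark.parametrize(
        "record, kept",
        [
            (rec("A", lat=0, lon=120), True),     # interior
            (rec("A", lat=25, lon=120), False),   # latitude outside
            (rec("A", lat=10, lon=140), True),    # boundary-inclusive
            (rec("W", lat=0, lon=179), True),     # antimeridian segment 1
            (rec("W", lat=0, lon=-170), True),    # antimeridian segment 2
            (rec("W", lat=0, lon=0), False),
        ],
    )
    def test_box_rules(self, record, kept):
        out, _ = filter_bounding_box([record], self.ann)
        assert (len(out) == 1) is kept

    def test_missing_box_passes(self):
        out, rep = filter_bounding_box([rec("Nobox")], self.ann)
        assert len(out) == 1 and rep.n_untested == 1

    def test_idempotent(self):
        records = [rec("A", lat=0), rec("A", lat=25), rec("Nobox")]
        once, _ = filter_bounding_box(records, self.ann)
        twice, rep2 = filter_bounding_box(once, self.ann)
        assert twice == once and rep2.n_removed == 0


class TestRichnessModel:
    @staticmethod
    def table(n, seed=None, sigma=0.0, c=3.0, z=0.25):
        rng = np.random.default_rng(seed or 0)
        area = 10 ** rng.uniform(0, 4, size=n)
        rich = c * area**z
        if sigma:
            rich = rich * rng.lognormal(0.0, sigma, size=n)
        return pd.DataFrame(
            {"island_id": [f"I{k}" for k in range(n)], "area": area, "richness": rich}
        )

    def test_exact_recovery_without_noise(self):
        model = fit_richness_model(self.table(50))
        assert model.slope_area == pytest.approx(0.25, abs=1e-9)
        assert 10**model.intercept == pytest.approx(3.0, rel=1e-9)

    def test_noisy_recovery_within_tolerance(self):
        model = fit_richness_model(self.table(200, seed=42, sigma=0.1 * np.log(10)))
        assert model.slope_area == pytest.approx(0.25, abs=0.05)

    def test_tiny_fit_flagged_unreliable(self):
        model = fit_richness_model(self.table(2))
        assert not model.reliable

    def test_degenerate_design_errors(self):
        df = pd.DataFrame({"island_id": ["a", "b"], "area": [10.0, 10.0], "richness": [3, 4]})
        with pytest.raises(ValidationError, match="degenerate"):
            fit_richness_model(df)

    def test_isolation_covariate(self):
        df = self.table(50)
        df["isolation"] = np.linspace(0, 1000, 50)
        model = fit_richness_model(df, use_isolation=True)
        preds = model.predict(df["area"], df["isolation"])
        assert (preds > 0).all()


class TestUndersamplingExclusion:
    @staticmethod
    def _run(observed, predicted_richness=49.0, factor=5.0):
        # one-island table against a fixed prediction via a stub model
        class Stub:
            slope_isolation = None

            def predict(self, area, isolation=None):
                return np.full(len(area), predicted_richness)

        df = pd.DataFrame({"island_id": ["I1"], "area": [10.0], "richness": [observed]})
        retained, report = exclude_undersampled(df, Stub(), factor)
        return retained, report

    def test_boundary_arithmetic_retained(self):
        retained, _ = self._run(10)  # 10 >= 49/5 = 9.8
        assert retained == ["I1"]

    def test_below_threshold_excluded(self):
        retained, report = self._run(9)
        assert retained == [] and bool(report["excluded"].iloc[0])

    def test_observed_equals_predicted_retained(self):
        retained, _ = self._run(49)
        assert retained == ["I1"]

    def test_factor_must_exceed_one(self):
        with pytest.raises(ConfigurationError):
            self._run(10, factor=1.0)

    def test_monotone_in_factor(self):
        rng = np.random.default_rng(7)
        n = 40
        df = pd.DataFrame(
            {
                "island_id": [f"I{k}" for k in range(n)],
                "area": 10 ** rng.uniform(0, 3, n),
                "richness": rng.integers(1, 50, n).astype(float),
            }
        )
        model = fit_richness_model(df)
        prev: set = set()
        for factor in (1.5, 2, 5, 10, 100):
            retained, _ = exclude_undersampled(df, model, factor)
            assert prev <= set(retained)  # larger factor retains more islands
            prev = set(retained)


def units_matrix(freqs, n_units):
    """Columns with given incidence frequencies (taxon j in freqs[j] units)."""
    m = np.zeros((n_units, len(freqs)), dtype=np.int8)
    for j, f in enumerate(freqs):
        m[:f, j] = 1
    return m


class TestIceCoverage:
    def test_all_frequent_taxa_gives_full_coverage(self):
        m = units_matrix([12, 15, 11], n_units=15)
        scores = ice_coverage({"I1": m})
        assert scores["I1"].icer == pytest.approx(1.0)
        assert scores["I1"].stable

    def test_all_singletons_falls_back_unstable(self):
        m = units_matrix([1], n_units=1)
        scores = ice_coverage({"I1": m})
        assert not scores["I1"].stable

    def test_zero_units_flagged(self):
        scores = ice_coverage({"I1": np.zeros((0, 0))})
        assert not scores["I1"].stable and np.isnan(scores["I1"].icer)

    def test_against_independent_formula(self):
        """Second straight-line coding of the Lee-Chao closed form.

        Fixture: 5 infrequent taxa over 4 units with Q1=3, Q2=2
        (frequencies 1,1,1,2,2) plus 2 frequent taxa.
        """
        cutoff = 10
        freqs = [1, 1, 1, 2, 2, 12, 13]
        n_units = 13
        m = units_matrix(freqs, n_units)

        # independent evaluation
        f = np.array(freqs)
        infreq = f[f <= cutoff]
        s_freq = int((f > cutoff).sum())
        s_inf = len(infreq)
        q1 = int((infreq == 1).sum())
        n_inf = int(infreq.sum())
        c_ice = 1 - q1 / n_inf
        m_inf = int((m[:, f <= cutoff].sum(axis=1) > 0).sum())
        sum_jj1 = sum(j * (j - 1) * int((infreq == j).sum()) for j in range(1, cutoff + 1))
        gamma2 = max(
            (s_inf / c_ice) * (m_inf / (m_inf - 1)) * sum_jj1 / n_inf**2 - 1, 0.0
        )
        expected = s_freq + s_inf / c_ice + (q1 / c_ice) * gamma2

        got, stable = ice_richness(m)
        assert stable
        assert got == pytest.approx(expected, rel=1e-12)
        scores = ice_coverage({"I1": m})
        assert scores["I1"].icer == pytest.approx(min(len(freqs) / expected, 1.0), rel=1e-12)

    def test_icer_in_unit_interval_and_decreases_with_singletons(self):
        rng = np.random.default_rng(1)
        base = [1, 2, 3, 4, 12]
        prev = 1.1
        for extra_singletons in (0, 1, 2, 4, 8):
            freqs = base + [1] * extra_singletons
            m = units_matrix(freqs, 12)
            s = ice_coverage({"I": m})["I"]
            assert 0 < s.icer <= 1
            assert s.icer <= prev + 1e-12  # weakly decreasing
            prev = s.icer
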