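"""Trait preparation rules, IP prediction, least-squares estimation, LRT, AICc."""

import datetime as dt
import math

import numpy as np
import pandas as pd
import pytest

from purgekit.ip_model import (
    GTableCache,
    ModelSpec,
    aicc,
    fit,
    fit_with_tests,
    legal_model_specs,
    longevity_window,
    lrt,
    model_scan,
    naive_reference_mean,
    predict,
    prepare_productivity,
    prepare_survival,
)
from purgekit.pedigree import Individual, Pedigree, inbreeding
from purgekit.synthetic_data import SimConfig, simulate_pedigree


def _ind(id_, sire=None, dam=None, sex="F", born=None, died=None, acc=False, loc="Almeria"):
    return Individual(
        id_, sire, dam, sex=sex, birth_date=born, death_date=died,
        accidental_death=acc, location=loc,
    )


@pytest.fixture
def dated_pedigree():
    b = dt.date(1990, 1, 1)
    return Pedigree(
        [
            _ind("A", sex="M", born=dt.date(1980, 1, 1)),
            _ind("B", born=dt.date(1980, 1, 1)),
            _ind("ok", "A", "B", born=b),  # no death date -> survives
            _ind("died10", "A", "B", born=b, died=b + dt.timedelta(days=10)),
            _ind("acc3", "A", "B", born=b, died=b + dt.timedelta(days=3), acc=True),
            _ind("acc40", "A", "B", born=b, died=b + dt.timedelta(days=40), acc=True),
            _ind("male", "A", "B", sex="M", born=dt.date(1995, 6, 1)),
            _ind("away", "A", "B", born=b, loc="Madrid"),
        ]
    )


class TestPrepareSurvival:
    def test_rules(self, dated_pedigree):
        table = prepare_survival(dated_pedigree, location="Almeria", vet_year=1993)
        assert "A" not in table.index  # founders have unknown trait
        assert "away" not in table.index  # other facility
        assert "acc3" not in table.index  # accidental early death
        assert table.at["ok", "W"] == 1.0  # missing death date
        assert table.at["died10", "W"] == 0.0
        assert table.at["acc40", "W"] == 1.0  # accident after the window
        assert table.at["male", "x_S"] == 1.0 and table.at["ok", "x_S"] == 0.0
        assert table.at["male", "x_POM"] == 1.0 and table.at["ok", "x_POM"] == 0.0
        assert table.at["ok", "dam_id"] == "B"


class TestPrepareProductivity:
    def test_percentile_window(self):
        spans = [2, 3, 5, 8, 10, 12, 14, 15, 18, 20]
        base = dt.date(1950, 1, 1)
        records = [
            _ind(f"L{i}", born=base, died=base + dt.timedelta(days=round(s * 365.25)))
            for i, s in enumerate(spans)
        ]
        ped = Pedigree(records)
        assert longevity_window(ped) == 18

    def test_counts_and_window_exclusion(self):
        b = dt.date(1980, 1, 1)
        records = [
            _ind("M0", sex="M", born=b, died=dt.date(1990, 1, 1)),
            _ind("F0", born=b, died=dt.date(1990, 1, 1)),
            _ind("F1", "M0", "F0", born=dt.date(1982, 1, 1), died=dt.date(1992, 1, 1)),
            _ind("late", "M0", "F0", born=dt.date(1999, 1, 1), died=dt.date(2000, 1, 1)),
        ]
        records += [
            _ind(f"kid{i}", "M0", "F1", born=dt.date(1985 + i, 1, 1), died=dt.date(1996, 1, 1))
            for i in range(4)
        ]
        ped = Pedigree(records)
        table = prepare_productivity(ped, window_years=9)
        # F1 born 1982, last birth year 1999: 17 >= 9 -> kept, 4 offspring
        assert table.at["F1", "W"] == 4.0
        # "late" born 1999: within 9 years of the end -> excluded
        assert "late" not in table.index
        # founders excluded even though F0 has offspring
        assert "F0" not in table.index


class TestPredict:
    def test_reference_point(self):
        assert predict({"W0": 0.9}, 0.0, 0.0) == pytest.approx(0.9)

    def test_direct_evaluation(self):
        assert predict({"W0": 1.0, "delta": 0.5}, 1.0, 0.0) == pytest.approx(
            math.exp(-0.5)
        )

    def test_null_model_constant(self):
        g = np.linspace(0, 1, 11)
        out = predict({"W0": 0.8, "delta": 0.0, "delta_m": 0.0}, g, g)
        assert np.allclose(out, 0.8)

    def test_vectorized_factors(self):
        out = predict(
            {"W0": 1.0, "beta_s": -0.1}, np.zeros(2), np.zeros(2), x_s=np.array([0, 1.0])
        )
        assert out[1] == pytest.approx(math.exp(-0.1))


class TestModelSpec:
    def test_d_requires_delta(self):
        with pytest.raises(ValueError):
            ModelSpec(d=True, delta=False)

    def test_pom_yob_exclusive(self):
        with pytest.raises(ValueError):
            ModelSpec(d=False, delta=True, pom=True, yob=True)

    def test_legal_enumeration_respects_constraints(self):
        specs = legal_model_specs()
        assert all((not s.pom) or (not s.yob) for s in specs)
        assert all(s.delta or not s.d for s in specs)
        assert len(specs) == len(set(specs))


class TestFit:
    @pytest.fixture
    def sim(self):
        return simulate_pedigree(SimConfig(years=18, max_breeding_females=14), seed=3)

    def test_noiseless_recovery(self, sim):
        truth = {"W0": 0.9, "delta": 0.8, "delta_m": 0.4, "beta_s": -0.12}
        d_true = 0.3
        cache = GTableCache(sim.pedigree)
        table = sim.traits.copy()
        g = cache.g(d_true)
        pos = np.array([sim.pedigree.position(i) for i in table.index])
        dam_pos = np.array(
            [sim.pedigree.position(d) if isinstance(d, str) else -1 for d in table["dam_id"]]
        )
        table["W"] = predict(
            truth,
            g[pos],
            np.where(dam_pos >= 0, g[dam_pos], 0.0),
            x_s=table["x_S"].to_numpy(),
        )
        spec = ModelSpec(d=True, delta=True, delta_m=True, sex=True)
        result = fit(table, sim.pedigree, spec, runs=4, seed=0, cache=cache, d_grid=11)
        assert result.rss == pytest.approx(0.0, abs=1e-8)
        assert result.estimates["d"] == pytest.approx(d_true, abs=1e-3)
        for name, value in truth.items():
            assert result.estimates[name] == pytest.approx(value, abs=1e-3)
        # well-conditioned data: run-to-run spread collapses
        assert all(se < 0.01 for se in result.run_se.values() if not math.isnan(se))

    def test_excluding_d_same_as_d_zero(self, sim):
        cache = GTableCache(sim.pedigree)
        F = inbreeding(sim.pedigree).to_numpy()
        assert np.array_equal(cache.g(0.0), F)
        no_d = fit(
            sim.traits,
            sim.pedigree,
            ModelSpec(d=False, delta=True, sex=True),
            runs=2,
            seed=1,
            cache=cache,
        )
        assert "d" not in no_d.estimates

    def test_too_few_rows(self, sim):
        tiny = sim.traits.iloc[:4]
        with pytest.raises(ValueError):
            fit(tiny, sim.pedigree, ModelSpec())

    def test_aicc_reduces_to_aic_large_n(self):
        logl, k = -120.0, 4
        aic = -2 * logl + 2 * k
        assert aicc(logl, k, 50) > aic
        assert aicc(logl, k, 10**7) == pytest.approx(aic, abs=1e-4)


class TestLRT:
    def _mock(self, spec, logl, n=500):
        from purgekit.ip_model import IPFit

        return IPFit(spec=spec, estimates={}, rss=1.0, n=n, logl=logl, aicc=0.0)

    def test_identical_fits_p_one(self):
        full = self._mock(ModelSpec(d=True, delta=True), -100.0)
        red = self._mock(ModelSpec(d=False, delta=True), -100.0)
        assert lrt(full, red) == 1.0

    def test_chi2_quantile(self):
        full = self._mock(ModelSpec(d=True, delta=True), -100.0)
        red = self._mock(ModelSpec(d=False, delta=True), -100.0 - 3.841 / 2)
        assert lrt(full, red) == pytest.approx(0.05, abs=5e-4)

    def test_boundary_mixture_halves_p(self):
        full = self._mock(ModelSpec(d=True, delta=True), -100.0)
        red = self._mock(ModelSpec(d=False, delta=True), -101.5)
        assert lrt(full, red, boundary=True) == pytest.approx(
            0.5 * lrt(full, red), abs=1e-12
        )

    def test_non_nested_rejected(self):
        full = self._mock(ModelSpec(d=False, delta=True, pom=True), -100.0)
        other = self._mock(ModelSpec(d=False, delta=True, yob=True), -101.0)
        with pytest.raises(ValueError):
            lrt(full, other)

    def test_reduced_better_clipped(self):
        full = self._mock(ModelSpec(d=True, delta=True), -105.0)
        red = self._mock(ModelSpec(d=False, delta=True), -100.0)
        assert lrt(full, red) == 1.0


class TestModelScan:
    def test_single_candidate(self):
        sim = simulate_pedigree(SimConfig(years=14, max_breeding_females=10), seed=9)
        spec = ModelSpec(d=False, delta=True)
        fits = model_scan(sim.traits, sim.pedigree, specs=[spec], runs=2, seed=0)
        assert len(fits) == 1 and fits[0].spec == spec

    def test_null_data_prefers_intercept_only(self):
        # no load, no sex effect: the intercept-only model should win AICc
        cfg = SimConfig(
            years=14,
            max_breeding_females=10,
            w0=0.85,
            delta=0.0,
            delta_m=0.0,
            beta_s=0.0,
            d_true=0.0,
            accident_prob=0.0,
        )
        wins = 0
        for rep in range(10):
            sim = simulate_pedigree(cfg, seed=100 + rep)
            fits = model_scan(
                sim.traits,
                sim.pedigree,
                specs=legal_model_specs(factors=("sex",)),
                runs=2,
                seed=rep,
            )
            best = fits[0]
            if best.k <= 2:
                wins += 1
            # an irrelevant factor should never improve AICc by much
            intercept = next(f for f in fits if f.k == 1)
            assert intercept.aicc - best.aicc < 2.0
        assert wins >= 8


class TestNaiveReference:
    def test_toy_mean_and_se(self, dated_pedigree):
        table = prepare_survival(dated_pedigree, location=None)
        table = table.loc[["ok", "died10", "acc40", "male"]]
        table["W"] = [1.0, 1.0, 0.0, 1.0]
        w0, se = naive_reference_mean(table, dated_pedigree)
        assert w0 == pytest.approx(0.75)
        assert se == pytest.approx(0.217, abs=1e-3)

    def test_inbred_dam_excluded(self):
        b = dt.date(1990, 1, 1)
        records = [
            _ind("A", sex="M", born=b),
            _ind("B", born=b),
            _ind("M2", sex="M", born=b),
            _ind("C", "A", "B", born=b),
            _ind("D", "A", "B", born=b),
            _ind("E", "C", "D", born=b),  # inbred (F = 0.25)
            _ind("X", "M2", "E", born=b),  # F = 0 but inbred dam
            _ind("Y", "M2", "B", born=b),  # F = 0, all ancestors non-inbred
        ]
        ped = Pedigree(records)
        F = inbreeding(ped)
        assert F["X"] == 0.0 and F["E"] == 0.25
        table = prepare_survival(ped)
        table["W"] = 0.0
        table.at["Y", "W"] = 1.0
        w0, _ = naive_reference_mean(table, ped)
        # only C, D, Y qualify (X has an inbred ancestor E): mean = 1/3
        assert w0 == pytest.approx(1.0 / 3.0)

    def test_no_qualifying_flagged(self, sib_line):
        table = pd.DataFrame(
            {"W": [1.0], "x_S": 0.0, "x_POM": 0.0, "yob": 2000.0, "dam_id": "F2"},
            index=pd.Index(["G"], name="id"),
        )
        w0, se = naive_reference_mean(table, sib_line)
        assert math.isnan(w0) and math.isnan(se)


def test_fit_with_tests_populates_p_values():
    sim = simulate_pedigree(SimConfig(years=16, max_breeding_females=12), seed=5)
    result = fit_with_tests(
        sim.traits,
        sim.pedigree,
        ModelSpec(d=True, delta=True, delta_m=True, sex=True),
        runs=2,
        seed=0,
    )
    assert 0.0 <= result.p_d <= 1.0
    assert 0.0 <= result.p_delta <= 1.0
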