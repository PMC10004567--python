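"""Tests for stratified prevalence estimation and the bootstrap."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from claimsprev.case_identification import AlgorithmSpec, CaseSet, identify_cases
from claimsprev.errors import (
    DoubleCountError,
    EmptyStratumError,
    ParameterError,
)
from claimsprev.prevalence_estimation import (
    PrevalenceEstimate,
    StratumKey,
    aggregate_prevalence,
    bootstrap_ci,
    combine_case_sets,
    midyear_denominator,
    stratum_prevalence,
)
from claimsprev.strata import AGE_GROUPS, SEXES

from conftest import make_claims, make_enrollment, random_instance

SPEC = AlgorithmSpec(1, False)


def _caseset(members, year=2018, spec=SPEC):
    return CaseSet(index_year=year, algorithm=spec, members=frozenset(members))


class TestEstimateInvariants:
    def test_rate_must_match_counts(self):
        with pytest.raises(ValueError):
            PrevalenceEstimate("x", 2018, StratumKey(), 5, 100, 999.0)

    def test_numerator_bounds(self):
        with pytest.raises(ValueError):
            PrevalenceEstimate("x", 2018, StratumKey(), 5, 4, 100000 * 5 / 4)

    def test_ci_ordering(self):
        with pytest.raises(ValueError):
            PrevalenceEstimate("x", 2018, StratumKey(), 1, 100, 1000.0, ci_low=5.0, ci_high=1.0)


class TestMidyearDenominator:
    def test_full_population(self):
        enr = make_enrollment([{"person_id": f"p{i}"} for i in range(1000)])
        assert midyear_denominator(enr, 2018) == 1000

    def test_sex_stratum(self):
        rows = [{"person_id": f"m{i}", "sex": "male"} for i in range(600)]
        rows += [{"person_id": f"f{i}", "sex": "female"} for i in range(400)]
        enr = make_enrollment(rows)
        assert midyear_denominator(enr, 2018, StratumKey(sex="female")) == 400

    def test_unaffiliated_excluded(self):
        enr = make_enrollment(
            [{"person_id": "a"}, {"person_id": "b", "affiliated": False}]
        )
        assert midyear_denominator(enr, 2018) == 1

    def test_underage_excluded(self):
        enr = make_enrollment([{"person_id": "a", "birth_year": 2000}])
        assert midyear_denominator(enr, 2018) == 0

    def test_age_group_half_open_bins(self):
        enr = make_enrollment(
            [
                {"person_id": "a", "birth_year": 2018 - 44},
                {"person_id": "b", "birth_year": 2018 - 45},
                {"person_id": "c", "birth_year": 2018 - 64},
                {"person_id": "d", "birth_year": 2018 - 65},
            ]
        )
        counts = [midyear_denominator(enr, 2018, StratumKey(age_group=g)) for g in AGE_GROUPS]
        assert counts == [1, 2, 1]
        assert sum(counts) == len(enr)  # partition, no overlap at 45/65


class TestStratumPrevalence:
    def test_arithmetic(self):
        enr = make_enrollment([{"person_id": f"p{i}"} for i in range(50_000)])
        est = stratum_prevalence(_caseset({f"p{i}" for i in range(5)}), enr)
        assert est.rate_per_100k == 10.0
        assert est.numerator == 5 and est.denominator == 50_000

    def test_zero_cases(self):
        enr = make_enrollment([{"person_id": "a"}])
        assert stratum_prevalence(_caseset(set()), enr).rate_per_100k == 0.0

    def test_empty_stratum_raises(self):
        enr = make_enrollment([{"person_id": "a", "sex": "male"}])
        with pytest.raises(EmptyStratumError):
            stratum_prevalence(_caseset(set()), enr, StratumKey(sex="female"))

    def test_numerator_respects_stratum(self):
        enr = make_enrollment(
            [{"person_id": "m", "sex": "male"}, {"person_id": "f", "sex": "female"}]
        )
        est = stratum_prevalence(_caseset({"m", "f"}), enr, StratumKey(sex="male"))
        assert est.numerator == 1 and est.denominator == 1


class TestAggregate:
    def test_arithmetic(self):
        est = aggregate_prevalence([2, 3], [5], 100_000)
        assert est.rate_per_100k == 10.0

    def test_zero(self):
        assert aggregate_prevalence([0, 0], [0], 1000).rate_per_100k == 0.0

    def test_mapping_inputs(self):
        n = {("Bogota", "45-64", "male"): 2, ("Central", "65+", "female"): 3}
        m = {("45-64", "male"): 5}
        assert aggregate_prevalence(n, m, 100_000).rate_per_100k == 10.0

    def test_zero_denominator_raises(self):
        with pytest.raises(EmptyStratumError):
            aggregate_prevalence([1], [1], 0)

    def test_sum_equals_union_rate(self, rng):
        # brute-force union oracle on a random synthetic instance
        for trial in range(5):
            enr, claims = random_instance(rng, n_persons=120)
            # split persons across regimes to mimic the two sub-populations
            regimes = np.where(np.arange(len(enr)) % 3 == 0, "subsidized", "contributory")
            enr = enr.copy()
            enr["regime"] = regimes
            enr.loc[enr["regime"] == "subsidized", "region"] = ""
            spec = AlgorithmSpec(2, False)
            cases = identify_cases(claims, enr, spec, 2018)
            contrib = enr[enr["regime"] == "contributory"]
            subs = enr[enr["regime"] == "subsidized"]
            n_ijk = {}
            for region in contrib["region"].unique():
                for sex in SEXES:
                    for ag in AGE_GROUPS:
                        key = StratumKey(regime="contributory", sex=sex, age_group=ag,
                                         region=region)
                        try:
                            n_ijk[(region, ag, sex)] = stratum_prevalence(
                                cases, contrib, key
                            ).numerator
                        except EmptyStratumError:
                            pass
            m_jk = {}
            for sex in SEXES:
                for ag in AGE_GROUPS:
                    key = StratumKey(regime="subsidized", sex=sex, age_group=ag)
                    try:
                        m_jk[(ag, sex)] = stratum_prevalence(cases, subs, key).numerator
                    except EmptyStratumError:
                        pass
            n_global = midyear_denominator(enr, 2018)
            agg = aggregate_prevalence(n_ijk, m_jk, n_global, index_year=2018)
            union = stratum_prevalence(cases, enr)
            assert agg.numerator == union.numerator
            assert agg.rate_per_100k == union.rate_per_100k

    def test_additivity_weighted_mean(self, rng):
        enr, claims = random_instance(rng, n_persons=150)
        cases = identify_cases(claims, enr, AlgorithmSpec(1, False), 2018)
        parts = []
        for sex in SEXES:
            try:
                parts.append(stratum_prevalence(cases, enr, StratumKey(sex=sex)))
            except EmptyStratumError:
                pass
        total = stratum_prevalence(cases, enr)
        assert sum(p.numerator for p in parts) == total.numerator
        weighted = sum(p.rate_per_100k * p.denominator for p in parts) / total.denominator
        assert weighted == pytest.approx(total.rate_per_100k, abs=1e-9)


class TestCombineCaseSets:
    def test_union(self):
        a = _caseset({"x"})
        b = _caseset({"y"})
        assert combine_case_sets(a, b).members == {"x", "y"}

    def test_overlap_raises(self):
        with pytest.raises(DoubleCountError):
            combine_case_sets(_caseset({"x"}), _caseset({"x", "y"}))


def _degenerate_universe(n=40):
    """Every person identical and a case: every resample gives the same rate."""
    enr = make_enrollment([{"person_id": f"p{i}"} for i in range(n)])
    claims = make_claims([(f"p{i}", 2018, m, "C341") for i in range(n) for m in (1, 2, 3, 4)])
    return enr, claims


class TestBootstrap:
    def test_b_floor(self):
        enr, claims = _degenerate_universe()
        with pytest.raises(ParameterError):
            bootstrap_ci(claims, enr, SPEC, 2018, B=1)

    def test_degenerate_ci_collapses(self):
        enr, claims = _degenerate_universe()
        est = bootstrap_ci(claims, enr, SPEC, 2018, B=50, seed=1)[0]
        assert est.ci_low == est.ci_high == est.rate_per_100k == 100000.0

    def test_same_seed_identical(self, rng):
        enr, claims = random_instance(rng, n_persons=80)
        a = bootstrap_ci(claims, enr, SPEC, 2018, B=100, seed=9)[0]
        b = bootstrap_ci(claims, enr, SPEC, 2018, B=100, seed=9)[0]
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_different_seed_differs(self, rng):
        enr, claims = random_instance(rng, n_persons=80)
        a = bootstrap_ci(claims, enr, SPEC, 2018, B=100, seed=9)[0]
        b = bootstrap_ci(claims, enr, SPEC, 2018, B=100, seed=10)[0]
        assert (a.ci_low, a.ci_high) != (b.ci_low, b.ci_high)

    def test_reports_n_boot_and_seed(self):
        enr, claims = _degenerate_universe()
        est = bootstrap_ci(claims, enr, SPEC, 2018, B=17, seed=4)[0]
        assert est.n_boot == 17 and est.seed == 4

    def test_ci_bounds_within_range(self, rng):
        enr, claims = random_instance(rng, n_persons=100)
        for est in bootstrap_ci(
            claims, enr, SPEC, 2018,
            strata=[StratumKey(), StratumKey(sex="male"), StratumKey(sex="female")],
            B=100, seed=2,
        ):
            assert 0 <= est.ci_low <= est.ci_high <= 100000

    def test_empty_replicate_stratum_warns_and_zeroes(self):
        # one female in the table: resamples frequently miss her entirely
        rows = [{"person_id": f"m{i}", "sex": "male"} for i in range(10)]
        rows.append({"person_id": "f0", "sex": "female"})
        enr = make_enrollment(rows)
        claims = make_claims([("f0", 2018, 1, "C341")])
        with pytest.warns(UserWarning, match="empty stratum"):
            est = bootstrap_ci(
                claims, enr, SPEC, 2018, strata=[StratumKey(sex="female")], B=200, seed=0
            )[0]
        assert est.ci_low == 0.0  # empty replicates contributed rate 0

    def test_matches_naive_resampling_oracle(self):
        """Weighted reweighting must equal materialising each resampled
        population and re-running identification + estimation."""
        rng = np.random.default_rng(77)
        enr, claims = random_instance(rng, n_persons=50)
        spec = AlgorithmSpec(2, True)
        strata = [StratumKey(), StratumKey(sex="male")]
        B, seed, n = 30, 123, len(enr)

        # oracle: same index stream, naive recompute per replicate
        oracle_rng = np.random.default_rng(seed)
        idx = oracle_rng.integers(0, n, size=(B, n))
        naive = np.empty((B, len(strata)))
        for b in range(B):
            boot_enr = enr.iloc[idx[b]].reset_index(drop=True).copy()
            fresh = [f"r{j}" for j in range(n)]
            old = boot_enr["person_id"].tolist()
            boot_claims_parts = []
            for j, pid in enumerate(old):
                own = claims[claims["person_id"] == pid].copy()
                own["person_id"] = fresh[j]
                boot_claims_parts.append(own)
            boot_claims = pd.concat(boot_claims_parts, ignore_index=True)
            boot_enr["person_id"] = fresh
            cs = identify_cases(boot_claims, boot_enr, spec, 2018)
            for s_i, stratum in enumerate(strata):
                try:
                    naive[b, s_i] = stratum_prevalence(cs, boot_enr, stratum).rate_per_100k
                except EmptyStratumError:
                    naive[b, s_i] = 0.0

        ests = bootstrap_ci(claims, enr, spec, 2018, strata=strata, B=B, seed=seed)
        for s_i, est in enumerate(ests):
            lo, hi = np.percentile(naive[:, s_i], [2.5, 97.5])
            assert est.ci_low == pytest.approx(lo, abs=1e-9)
            assert est.ci_high == pytest.approx(hi, abs=1e-9)

    def test_width_shrinks_with_population(self):
        """Median CI width decreases across growing populations at fixed
        true prevalence (scaled-down sizes to stay within test budget)."""
        from claimsprev.synthetic_claims import SimulationParams, generate_claims, generate_population

        widths = []
        for n in (2_000, 20_000, 200_000):
            per_seed = []
            for s in range(3):
                params = SimulationParams(
                    n_persons=n,
                    index_years=[2018],
                    strata=[dict(regime="contributory", sex="male", age_group="45-64",
                                 region="Central", weight=1.0, prevalence_per_100k=400.0)],
                    persistence_distribution=[0, 0, 0, 1.0] + [0] * 8,
                    seed=100 + s,
                )
                enr, truth = generate_population(params)
                cl = generate_claims(enr, truth, params)
                est = bootstrap_ci(cl, enr, AlgorithmSpec(4, False), 2018, B=100, seed=s)[0]
                per_seed.append(est.ci_high - est.ci_low)
            widths.append(np.median(per_seed))
        assert widths[0] > widths[1] > widths[2]
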