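"""Multiplier derivation, variability, and cross-database comparison.

The key check is oracle equivalence: `derive_multipliers` and
`variability_stats` are vectorized (pandas); the oracle below recomputes
both with plain nested loops sharing no code with the implementation, and
the two must agree exactly on randomized small databases.
"""

import numpy as np
import pytest

from spinemult import (
    AgeYM,
    DerivationError,
    DomainError,
    GrowthDatabase,
    GrowthRecord,
    Sex,
    compare_multiplier_sets,
    derive_multipliers,
    mean_multiplier_curve,
    variability_stats,
)
from conftest import make_database

MATURITY = {Sex.MALE: 216, Sex.FEMALE: 192}


# ---------------------------------------------------------------------------
# independent brute-force oracle (nested loops, no pandas, no shared code)


def oracle_derive(records, maturity_age):
    """{(sex, percentile, total_months): M} by direct search for Lm."""
    out = {}
    for rec in records:
        lm = None
        for other in records:
            if (
                other.sex == rec.sex
                and other.percentile == rec.percentile
                and other.age.total_months == maturity_age[rec.sex]
            ):
                lm = other.sitting_height
        assert lm is not None, "oracle input must satisfy database invariants"
        out[(rec.sex, rec.percentile, rec.age.total_months)] = lm / rec.sitting_height
    return out


def oracle_variability(multipliers):
    """Per-sex {age: max |M_p - mean|}, plus pooled mean/max, via loops."""
    per_sex = {}
    for sex in {k[0] for k in multipliers}:
        ages = sorted({k[2] for k in multipliers if k[0] == sex})
        per_age = {}
        for t in ages:
            values = [
                multipliers[k]
                for k in sorted(multipliers, key=lambda k: k[1])
                if k[0] == sex and k[2] == t
            ]
            mean = sum(values) / len(values)
            per_age[t] = max(abs(v - mean) for v in values)
        per_sex[sex] = per_age
    pooled = [v for per_age in per_sex.values() for v in per_age.values()]
    return per_sex, sum(pooled) / len(pooled), max(pooled)


def random_database(rng):
    """Complete-grid database: <=4 percentiles x <=10 ages per sex."""
    curves = {}
    for sex in (Sex.MALE, Sex.FEMALE):
        n_perc = rng.integers(1, 5)
        n_ages = rng.integers(1, 11)
        ages = sorted(rng.choice(np.arange(12, 180), size=n_ages, replace=False).tolist())
        for p in range(n_perc):
            label = f"P{p}"
            mature = float(rng.uniform(80, 100))
            heights = {int(t): float(rng.uniform(40, mature)) for t in ages}
            heights[MATURITY[sex]] = mature
            curves[(sex, label)] = heights
    return make_database(curves, maturity=MATURITY)


class TestDeriveMultipliers:
    def test_toy_division(self, toy_database):
        mset = derive_multipliers(toy_database)
        curve = mset.curve(Sex.MALE, "P50")
        assert curve[60] == pytest.approx(1.5)  # 90 / 60
        assert curve[216] == 1.0  # any record at maturity

    def test_scalar_multiple_percentiles_share_multipliers(self):
        base = {36: 55.0, 120: 70.0, 216: 90.0}
        curves = {
            (Sex.MALE, "P25"): {t: 0.9 * h for t, h in base.items()},
            (Sex.MALE, "P50"): base,
            (Sex.MALE, "P75"): {t: 1.1 * h for t, h in base.items()},
        }
        mset = derive_multipliers(make_database(curves, maturity=MATURITY))
        for label in ("P25", "P75"):
            np.testing.assert_allclose(
                mset.curve(Sex.MALE, label).to_numpy(),
                mset.curve(Sex.MALE, "P50").to_numpy(),
                rtol=1e-14,
            )
        report = variability_stats(mset)
        assert report.max_variability == pytest.approx(0.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        db = random_database(rng)
        mset = derive_multipliers(db)
        for factor in (0.1, 2.54, 1000.0):
            scaled = derive_multipliers(db.scaled(factor))
            np.testing.assert_allclose(
                scaled.frame["multiplier"], mset.frame["multiplier"], rtol=1e-12
            )

    def test_missing_maturity_record_names_percentile(self):
        records = [
            GrowthRecord(Sex.MALE, "P50", AgeYM(5, 0), 60.0),
            GrowthRecord(Sex.MALE, "P50", AgeYM(18, 0), 90.0),
            GrowthRecord(Sex.MALE, "P97", AgeYM(5, 0), 66.0),  # no maturity row
        ]
        with pytest.raises(DerivationError, match="P97"):
            GrowthDatabase(records, maturity_age=MATURITY)

    def test_duplicate_key_rejected(self):
        records = [
            GrowthRecord(Sex.MALE, "P50", AgeYM(5, 0), 60.0),
            GrowthRecord(Sex.MALE, "P50", AgeYM(5, 0), 61.0),
            GrowthRecord(Sex.MALE, "P50", AgeYM(18, 0), 90.0),
        ]
        with pytest.raises(DomainError, match="duplicate"):
            GrowthDatabase(records, maturity_age=MATURITY)


class TestOracleEquivalence:
    def test_randomized_small_databases_match_brute_force(self):
        rng = np.random.default_rng(20220917)
        for _ in range(200):
            db = random_database(rng)
            mset = derive_multipliers(db)
            expected = oracle_derive(db.records, db.maturity_age)
            got = {
                (Sex(row.sex), row.percentile, int(row.total_months)): row.multiplier
                for row in mset.frame.itertuples(index=False)
            }
            assert got.keys() == expected.keys()
            for key in expected:
                assert got[key] == expected[key], key  # exact: same float division

            per_sex, pooled_mean, pooled_max = oracle_variability(expected)
            report = variability_stats(mset)
            for sex, per_age in per_sex.items():
                sv = report.for_sex(sex)
                assert sv.per_age == pytest.approx(per_age, rel=1e-13, abs=1e-15)
                assert sv.max_variability == pytest.approx(max(per_age.values()), rel=1e-13, abs=1e-15)
            assert report.mean_variability == pytest.approx(pooled_mean, rel=1e-13, abs=1e-15)
            assert report.max_variability == pytest.approx(pooled_max, rel=1e-13, abs=1e-15)


class TestVariability:
    def test_single_percentile_all_zero(self, toy_database):
        report = variability_stats(derive_multipliers(toy_database))
        assert report.mean_variability == 0.0
        assert report.max_variability == 0.0

    def test_two_percentiles_symmetric_deviation(self):
        # multipliers 1.4 and 1.6 at one age: mean 1.5, max deviation 0.1
        curves = {
            (Sex.FEMALE, "A"): {120: 50.0, 192: 70.0},   # M = 1.4
            (Sex.FEMALE, "B"): {120: 43.75, 192: 70.0},  # M = 1.6
        }
        report = variability_stats(derive_multipliers(make_database(curves, maturity=MATURITY)))
        sv = report.for_sex(Sex.FEMALE)
        assert sv.per_age[120] == pytest.approx(0.1, rel=1e-12)


class TestMeanCurve:
    def test_single_percentile_is_identity(self, toy_database):
        mset = derive_multipliers(toy_database)
        curve = mean_multiplier_curve(mset, Sex.MALE)
        assert curve[60] == pytest.approx(1.5)

    def test_mean_of_two(self):
        curves = {
            (Sex.FEMALE, "A"): {120: 50.0, 192: 70.0},
            (Sex.FEMALE, "B"): {120: 43.75, 192: 70.0},
        }
        mset = derive_multipliers(make_database(curves, maturity=MATURITY))
        assert mean_multiplier_curve(mset, Sex.FEMALE)[120] == pytest.approx(1.5, rel=1e-12)

    def test_absent_sex_rejected(self, toy_database):
        with pytest.raises(DomainError):
            mean_multiplier_curve(derive_multipliers(toy_database), Sex.FEMALE)


class TestComparison:
    @pytest.fixture
    def mset(self):
        base = {int(t): 90.0 - 0.2 * (216 - t) for t in range(24, 216, 12)}
        base[216] = 90.0
        return derive_multipliers(
            make_database({(Sex.MALE, "P50"): base}, maturity=MATURITY)
        )

    def test_self_comparison_is_perfect(self, mset):
        result = compare_multiplier_sets(mset, mset, Sex.MALE, degree=3)
        assert result.r_squared == pytest.approx(1.0, abs=1e-12)
        assert result.rmse == pytest.approx(0.0, abs=1e-10)
        assert result.max_abs_difference == 0.0
        assert result.n_shared_ages == len(mean_multiplier_curve(mset, Sex.MALE))

    def test_affine_shift_absorbed_by_fit(self, mset):
        shifted = type(mset)(
            frame=mset.frame.assign(multiplier=mset.frame["multiplier"] + 0.01),
            provenance="shifted",
        )
        result = compare_multiplier_sets(mset, shifted, Sex.MALE, degree=1)
        assert result.r_squared == pytest.approx(1.0, abs=1e-9)
        assert result.rmse == pytest.approx(0.0, abs=1e-9)
        assert result.max_abs_difference == pytest.approx(0.01, rel=1e-9)

    def test_small_noise_small_rmse(self):
        # independent noise sd 0.005 on a copy: residual RMSE bounded by noise scale
        rng = np.random.default_rng(42)
        base = {int(t): float(90 / (1 + 0.01 * (180 - t))) for t in range(12, 180, 12)}
        base[216] = 90.0
        mset = derive_multipliers(
            make_database({(Sex.MALE, "P50"): base}, maturity=MATURITY)
        )
        noisy_frame = mset.frame.assign(
            multiplier=mset.frame["multiplier"] + rng.normal(0, 0.005, len(mset.frame))
        )
        noisy = type(mset)(frame=noisy_frame, provenance="noisy")
        result = compare_multiplier_sets(mset, noisy, Sex.MALE, degree=3)
        assert result.rmse <= 0.01

    def test_insufficient_shared_ages_rejected(self, toy_database):
        mset = derive_multipliers(toy_database)  # 2 ages only
        with pytest.raises(DomainError, match="shared ages"):
            compare_multiplier_sets(mset, mset, Sex.MALE, degree=3)
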