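"""Agreement statistics against independent brute-force oracles.

The oracles below recompute each statistic from first principles (explicit
ANOVA sums of squares, direct formula evaluation) so the implementation and
its check share no code path; pingouin provides a second, external check of
the ICC and its confidence interval.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import eatarch as ea
from eatarch.agreement_stats import (
    PairedSeries,
    StatsConfig,
    bland_altman,
    icc_consistency,
    pearson_ci,
)

# ---------------------------------------------------------------- oracles


def oracle_icc3(x, y, alpha=0.05):
    """Two-way ANOVA by explicit sums of squares; Shrout-Fleiss ICC(3,1)."""
    data = np.column_stack([x, y]).astype(float)
    n, k = data.shape
    grand = data.mean()
    ss_total = ((data - grand) ** 2).sum()
    ss_rows = k * ((data.mean(axis=1) - grand) ** 2).sum()
    ss_cols = n * ((data.mean(axis=0) - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    msb = ss_rows / (n - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    icc = (msb - mse) / (msb + (k - 1) * mse)
    f = msb / mse
    df1, df2 = n - 1, (n - 1) * (k - 1)
    lo = (f / sps.f.ppf(1 - alpha / 2, df1, df2) - 1) / (
        f / sps.f.ppf(1 - alpha / 2, df1, df2) + k - 1
    )
    hi = (f / sps.f.ppf(alpha / 2, df1, df2) - 1) / (
        f / sps.f.ppf(alpha / 2, df1, df2) + k - 1
    )
    return icc, lo, hi


def oracle_pearson(x, y, alpha=0.05):
    """Textbook product-moment formula plus Fisher transform."""
    n = len(x)
    sx, sy = sum(x), sum(y)
    sxy = sum(a * b for a, b in zip(x, y))
    sxx = sum(a * a for a in x)
    syy = sum(b * b for b in y)
    r = (n * sxy - sx * sy) / math.sqrt((n * sxx - sx**2) * (n * syy - sy**2))
    z = math.atanh(r)
    half = sps.norm.ppf(1 - alpha / 2) / math.sqrt(n - 3)
    return r, math.tanh(z - half), math.tanh(z + half)


FIXTURE_X = [4.2, 7.9, 6.1, 9.4, 5.0, 8.3]
FIXTURE_Y = [3.9, 7.1, 6.8, 8.6, 4.2, 7.7]


class TestICC:
    def test_identity_is_perfect(self):
        s = PairedSeries("v", [1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        icc, lo, hi = icc_consistency(s)
        assert icc == pytest.approx(1.0)

    def test_constant_offset_is_perfect(self):
        """Consistency ICC ignores a fixed shift between methods."""
        x = [1.0, 2.0, 3.0, 4.0]
        s = PairedSeries("v", x, [v + 5 for v in x])
        icc, _, _ = icc_consistency(s)
        assert icc == pytest.approx(1.0)

    def test_matches_anova_oracle_on_fixture(self):
        s = PairedSeries("v", FIXTURE_X, FIXTURE_Y)
        got = icc_consistency(s)
        want = oracle_icc3(FIXTURE_X, FIXTURE_Y)
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-10)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(7)
        x = rng.normal(10, 2, 25)
        y = x + rng.normal(1, 1.2, 25)
        s = PairedSeries("v", x, y)
        icc, lo, hi = icc_consistency(s)
        long = pd.DataFrame(
            {
                "subject": list(range(25)) * 2,
                "rater": ["a"] * 25 + ["b"] * 25,
                "score": np.concatenate([x, y]),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        ).set_index("Type")
        row = ref.loc["ICC(C,1)"]  # two-way mixed, consistency, single measure
        assert icc == pytest.approx(row["ICC"], rel=1e-8)
        ref_lo, ref_hi = row["CI95"]  # pingouin rounds the CI to 2 decimals
        assert lo == pytest.approx(ref_lo, abs=6e-3)
        assert hi == pytest.approx(ref_hi, abs=6e-3)

    def test_errors(self):
        with pytest.raises(ValueError, match="3 pairs"):
            icc_consistency(PairedSeries("v", [1.0, 2.0], [1.0, 2.0]))
        with pytest.raises(ValueError, match="degenerate"):
            icc_consistency(PairedSeries("v", [2.0, 2.0, 2.0], [2.0, 2.0, 2.0]))

    @given(st.floats(min_value=-50, max_value=50))
    @settings(max_examples=40, deadline=None)
    def test_shift_invariance(self, c):
        """Adding a constant to one method's values leaves ICC(3,1) unchanged."""
        x = np.array(FIXTURE_X)
        y = np.array(FIXTURE_Y)
        base, _, _ = icc_consistency(PairedSeries("v", x, y))
        shifted, _, _ = icc_consistency(PairedSeries("v", x, y + c))
        assert shifted == pytest.approx(base, rel=1e-9, abs=1e-12)


class TestBlandAltman:
    def test_identical_methods(self):
        s = PairedSeries("v", [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        mean_diff, sd, loa, pct, _ = bland_altman(s)
        assert mean_diff == 0 and sd == 0
        assert loa == (0, 0) and pct == 0

    def test_two_pair_fixture(self):
        s = PairedSeries("v", [5.0, 7.0], [4.0, 5.0])
        mean_diff, sd, loa, pct, points = bland_altman(s)
        assert mean_diff == pytest.approx(1.5)
        assert sd == pytest.approx(math.sqrt(0.5), rel=1e-12)
        assert loa[0] == pytest.approx(1.5 - 1.96 * math.sqrt(0.5), rel=1e-12)
        assert loa[1] == pytest.approx(1.5 + 1.96 * math.sqrt(0.5), rel=1e-12)
        assert list(points["mean"]) == [4.5, 6.0]
        assert list(points["diff"]) == [1.0, 2.0]

    def test_constant_offset(self):
        x = np.array([3.0, 5.0, 9.0])
        s = PairedSeries("v", x, x - 2.5)
        mean_diff, sd, loa, pct, _ = bland_altman(s)
        assert mean_diff == pytest.approx(2.5)
        assert sd == 0 and loa == (2.5, 2.5)

    def test_sign_convention_precise_minus_broad(self):
        # precise frequency above broad -> positive mean difference
        s = PairedSeries("frequency", [7.0, 8.0, 6.0], [5.0, 5.5, 4.0])
        mean_diff, *_ = bland_altman(s)
        assert mean_diff > 0

    def test_outside_share_near_nominal_for_gaussian_pairs(self):
        rng = np.random.default_rng(123)
        x = rng.normal(0, 1, 10_000)
        y = x + rng.normal(0, 1, 10_000)
        *_, pct, _ = bland_altman(PairedSeries("v", x, y))
        assert pct == pytest.approx(0.05, abs=0.02)

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            bland_altman(PairedSeries("v", [1.0], [2.0]))


class TestPearson:
    def test_perfect_linear(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        r, lo, hi = pearson_ci(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        assert lo <= r <= hi

    def test_perfect_negative(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r, _, _ = pearson_ci(x, -x)
        assert r == pytest.approx(-1.0)

    def test_matches_textbook_oracle_on_fixture(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 10)
        y = 0.6 * x + rng.normal(0, 0.8, 10)
        got = pearson_ci(x, y)
        want = oracle_pearson(list(x), list(y))
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=1e-10)

    def test_ci_contains_r_and_narrows_with_n(self):
        rng = np.random.default_rng(11)
        widths = []
        for n in (10, 100, 1000):
            x = rng.normal(0, 1, n)
            y = 0.4 * x + rng.normal(0, 1, n)
            r, lo, hi = pearson_ci(x, y)
            assert lo <= r <= hi
            widths.append(hi - lo)
        assert widths[0] > widths[1] > widths[2]

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pearson_ci(np.ones(6), np.arange(6.0))

    def test_null_coverage(self):
        """CI covers zero about 95% of the time for independent inputs."""
        rng = np.random.default_rng(2024)
        covered = 0
        reps = 300
        for _ in range(reps):
            x = rng.normal(0, 1, 30)
            y = rng.normal(0, 1, 30)
            _, lo, hi = pearson_ci(x, y)
            covered += lo <= 0 <= hi
        assert covered / reps > 0.9


class TestPairedSeriesAndTables:
    def test_undefined_pairs_dropped_and_counted(self):
        parts = [
            ea.ParticipantArchitecture("P1", "precise", 3, 7, 200, 250, 480, 1100, 620, 150),
            ea.ParticipantArchitecture("P1", "broad", 3, 5, 300, 350, 480, 1200, 720, 240),
            ea.ParticipantArchitecture("P2", "precise", 3, 1, 210, 260, 490, 490, 0, math.nan),
            ea.ParticipantArchitecture("P2", "broad", 3, 1, 310, 360, 480, 480, 0, math.nan),
        ]
        s = PairedSeries.from_architecture(parts, "interval_min")
        assert s.n == 1 and s.n_excluded == 1
        s2 = PairedSeries.from_architecture(parts, "frequency")
        assert s2.n == 2 and s2.n_excluded == 0

    def test_agreement_analysis_full_suite(self, default_architecture):
        _, participants = default_architecture
        results = ea.agreement_analysis(participants)
        frame = pd.DataFrame([r.to_row() for r in results])
        assert list(frame["variable"]) == list(ea.VARIABLES)
        assert ((frame["loa_low"] <= frame["mean_diff"]) & (frame["mean_diff"] <= frame["loa_high"])).all()
        assert frame["pct_outside"].between(0, 1).all()
        assert (frame["icc"] <= 1).all()

    def test_association_diagonal_is_unity(self, default_architecture):
        _, participants = default_architecture
        arch = ea.architecture_frame(participants)
        precise = arch[arch.method == "precise"]
        outcomes = precise[["participant_id", "size_g"]].rename(
            columns={"size_g": "OUT"}
        )
        table = ea.association_table(participants, outcomes, variables=("size_g",))
        row = table[(table.method == "precise")].iloc[0]
        assert row["r"] == pytest.approx(1.0)

    def test_association_requires_overlap(self, default_architecture):
        _, participants = default_architecture
        outcomes = pd.DataFrame({"participant_id": ["nope"], "TEI": [1.0]})
        with pytest.raises(ValueError, match="overlap"):
            ea.association_table(participants, outcomes)


def test_stats_config_validation():
    with pytest.raises(ValueError):
        StatsConfig(alpha=0)
    with pytest.raises(ValueError):
        StatsConfig(z=-1)
    with pytest.raises(ValueError):
        StatsConfig(k=3)
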