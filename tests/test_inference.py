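"""Dual-inference engine: r, p, BF10, triangulation, partials, stability."""

import numpy as np
import pandas as pd
import pytest

import creawell as cw
from creawell.inference import (
    BFSettings,
    PartialCorrelationResult,
    partial_correlations_for_supported,
)
from creawell.variables import ANALYSIS_VARIABLES


class TestPearsonR:
    def test_identity(self):
        x = np.array([1.0, 2, 4, 3, 5])
        r, n = cw.pearson_r(x, x)
        assert r == pytest.approx(1.0) and n == 5

    def test_perfect_linearity(self):
        r, n = cw.pearson_r([1, 2, 3, 4], [2, 4, 6, 8])
        assert r == pytest.approx(1.0) and n == 4

    def test_pairwise_deletion(self):
        x = [1.0, 2, np.nan, 4, 5]
        y = [2.0, np.nan, 3, 8, 10]
        _, n = cw.pearson_r(x, y)
        assert n == 3

    def test_insufficient_pairs_flagged(self):
        r, n = cw.pearson_r([1.0, np.nan], [2.0, 3.0])
        assert np.isnan(r) and n == 1

    def test_zero_variance_flagged(self):
        r, _ = cw.pearson_r([1.0, 1, 1, 1], [2.0, 3, 4, 5])
        assert np.isnan(r)

    def test_null_cohort_correlation_small(self, identity_cohort_scores):
        r, n = cw.pearson_r(
            identity_cohort_scores["life_satisfaction"],
            identity_cohort_scores["spq_disorganized"],
        )
        assert n > 4900 and abs(r) < 0.04


class TestPearsonP:
    @pytest.mark.parametrize(
        "r,n,expected",
        [(0.298, 72, 0.011), (0.333, 73, 0.004), (0.290, 73, 0.013)],
    )
    def test_reproduces_published_values(self, r, n, expected):
        assert round(cw.pearson_p(r, n), 3) == expected

    def test_r_zero_gives_one(self):
        assert cw.pearson_p(0.0, 50) == pytest.approx(1.0)

    def test_degenerate_r(self):
        assert 0 < cw.pearson_p(1.0, 10) < 1e-300


class TestBayesFactor:
    def test_quadrature_matches_closed_form_grid(self):
        rs = np.linspace(-0.9, 0.9, 10)
        ns = [5, 10, 20, 50, 80, 150]
        for r in rs:
            for n in ns:
                q = cw.correlation_bf10(float(r), n)
                c = cw.bf10_closed_form(float(r), n)
                assert abs(q - c) / c < 1e-6, (r, n)

    def test_matches_independent_reference(self):
        pg = pytest.importorskip("pingouin")
        for r, n in [(0.298, 72), (-0.44, 30), (0.05, 200)]:
            assert cw.correlation_bf10(r, n) == pytest.approx(
                float(pg.bayesfactor_pearson(r, n)), rel=1e-9
            )

    def test_two_sided_symmetry(self):
        for r in (0.1, 0.35, 0.8):
            for n in (10, 72):
                assert cw.correlation_bf10(r, n) == pytest.approx(
                    cw.correlation_bf10(-r, n), rel=1e-9
                )

    def test_monotone_in_abs_r(self):
        for n in (10, 40, 72):
            bfs = [cw.correlation_bf10(r, n) for r in np.linspace(0, 0.95, 12)]
            assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_monotone_in_n_for_informative_r(self):
        bfs = [cw.correlation_bf10(0.45, n) for n in (10, 30, 60, 120)]
        assert all(b2 > b1 for b1, b2 in zip(bfs, bfs[1:]))

    def test_null_evidence_grows_with_n(self):
        bf_small = cw.correlation_bf10(0.0, 20)
        bf_large = cw.correlation_bf10(0.0, 100)
        assert bf_large < bf_small < 1.0

    def test_kappa_widens_prior(self):
        """Wider prior (larger kappa) puts more mass on extreme rho."""
        narrow = cw.correlation_bf10(0.3, 73, BFSettings(kappa=0.5))
        default = cw.correlation_bf10(0.3, 73, BFSettings(kappa=1.0))
        assert narrow != pytest.approx(default, rel=1e-3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            cw.correlation_bf10(1.0, 50)
        with pytest.raises(ValueError):
            cw.correlation_bf10(0.5, 2)
        with pytest.raises(ValueError):
            BFSettings(kappa=0.0)

    def test_threshold_correspondence(self):
        """For n in 60-80 the |r| where BF10 crosses 3 and where p crosses
        0.05 differ by less than 0.08 (the two criteria nearly coincide)."""
        from scipy.optimize import brentq

        for n in range(60, 81, 4):
            r_bf = brentq(lambda r: cw.correlation_bf10(r, n) - 3.0, 0.01, 0.9)
            r_p = brentq(lambda r: cw.pearson_p(r, n) - 0.05, 0.01, 0.9)
            assert abs(r_bf - r_p) < 0.08


class TestEvidenceCategory:
    @pytest.mark.parametrize(
        "bf,label",
        [(1.51, "anecdotal"), (3.0001, "moderate"), (150, "extreme"),
         (15, "strong"), (45, "very_strong"), (0.5, "anecdotal_null"),
         (0.2, "moderate_null"), (0.005, "extreme_null")],
    )
    def test_bands(self, bf, label):
        assert cw.evidence_category(bf) == label

    def test_positive_required(self):
        with pytest.raises(ValueError):
            cw.evidence_category(0.0)


class TestTriangulate:
    @pytest.mark.parametrize(
        "p,bf,status",
        [(0.011, 3.58, "supported"), (0.029, 1.51, "partial_frequentist_only"),
         (0.05, 3.58, "none"), (0.01, 3.0, "partial_frequentist_only"),
         (0.2, 10.0, "none")],
    )
    def test_statuses(self, p, bf, status):
        assert cw.triangulate(p, bf) == status


class TestCorrelationMatrix:
    def test_all_pairs_present(self, identity_cohort_scores):
        results = cw.correlation_matrix(identity_cohort_scores)
        assert len(results) == 78
        pairs = {frozenset(r.pair) for r in results}
        assert len(pairs) == 78

    def test_complete_cohort_equal_n(self, identity_cohort_scores):
        results = cw.correlation_matrix(identity_cohort_scores)
        ns = {r.n for r in results if "aut" not in r.pair[0] and "aut" not in r.pair[1]}
        assert ns == {len(identity_cohort_scores)}

    def test_missingness_bounds_n(self, default_cohort):
        scores = cw.score_bundle(default_cohort)
        results = cw.correlation_matrix(scores)
        n_cohort = len(scores)
        per_var = {v: int(scores[v].notna().sum()) for v in ANALYSIS_VARIABLES}
        for res in results:
            nx, ny = per_var[res.pair[0]], per_var[res.pair[1]]
            assert max(0, nx + ny - n_cohort) <= res.n <= min(nx, ny)

    def test_dropping_one_participants_instrument_shifts_only_its_ns(self, default_cohort):
        scores = cw.score_bundle(default_cohort)
        target = scores.dropna().index[0]
        modified = scores.copy()
        modified.loc[target, ["positive_affect", "negative_affect"]] = np.nan
        before = {frozenset(r.pair): r.n for r in cw.correlation_matrix(scores)}
        after = {frozenset(r.pair): r.n for r in cw.correlation_matrix(modified)}
        for pair, n_before in before.items():
            touched = {"positive_affect", "negative_affect"} & set(pair)
            expected = n_before - 1 if touched else n_before
            assert after[pair] == expected


class TestPartialCorrelation:
    def test_uncorrelated_covariate_reduces_to_zero_order(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=(2, 2000))
        z = rng.normal(size=2000)
        res = cw.partial_correlation(x, x * 0.5 + y, z)
        assert res.r_partial == pytest.approx(res.zero_order_r, abs=0.02)

    def test_covariate_equal_to_x_flagged_zero(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=100)
        y = rng.normal(size=100)
        res = cw.partial_correlation(x, y, x)
        assert res.r_partial == 0.0
        assert res.flag == "collinear_covariate"

    def test_matches_residual_correlation_oracle(self):
        """The formula equals the correlation of OLS residuals of x|z and y|z."""
        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(10, 60))
            z = rng.normal(size=n)
            x = 0.5 * z + rng.normal(size=n)
            y = -0.3 * z + rng.normal(size=n)
            res = cw.partial_correlation(x, y, z)
            rx = x - np.polyval(np.polyfit(z, x, 1), z)
            ry = y - np.polyval(np.polyfit(z, y, 1), z)
            oracle = np.corrcoef(rx, ry)[0, 1]
            assert res.r_partial == pytest.approx(oracle, abs=1e-10)

    def test_matches_independent_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(80, 3)), columns=["x", "y", "z"])
        df["y"] += 0.4 * df["z"]
        res = cw.partial_correlation(df.x, df.y, df.z)
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert res.r_partial == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_listwise_deletion_and_delta_on_same_cases(self):
        x = np.array([1.0, 2, 3, 4, 5, np.nan])
        y = np.array([2.0, 1, 4, 3, 5, 6])
        z = np.array([1.0, 1, 2, 2, 3, 3])
        res = cw.partial_correlation(x, y, z)
        assert res.n == 5
        r_zero, _ = cw.pearson_r(x[:5], y[:5])
        assert res.zero_order_r == pytest.approx(r_zero)
        assert res.delta_from_zero_order == pytest.approx(res.r_partial - r_zero)

    def test_too_few_cases(self):
        with pytest.raises(ValueError):
            cw.partial_correlation([1, 2, 3], [2, 3, 1], [1, 1, 2])


class TestStabilityScreen:
    @staticmethod
    def _zero_order(pair, r):
        return cw.CorrelationResult(pair=pair, r=r, n=68, p=0.01, bf10=5.0,
                                    evidence="moderate", status="supported")

    @staticmethod
    def _partial(pair, r_zero, r_partial):
        return PartialCorrelationResult(
            pair=pair, covariate="age", r_partial=r_partial, n=68, p=0.01,
            zero_order_r=r_zero, delta_from_zero_order=r_partial - r_zero,
        )

    def test_within_band_cases(self):
        report = cw.stability_screen(
            [self._zero_order(("a", "b"), 0.5), self._zero_order(("c", "d"), 0.3)],
            [self._partial(("a", "b"), 0.5, 0.5), self._partial(("c", "d"), 0.3, 0.26)],
        )
        assert not report["exceeds_band"].any()  # delta 0.000 and -0.040 both within

    def test_flagged_case(self):
        report = cw.stability_screen(
            [self._zero_order(("x", "y"), 0.320)],
            [self._partial(("x", "y"), 0.320, 0.405)],
        )
        assert report["exceeds_band"].iloc[0]
        assert report["abs_delta"].iloc[0] == pytest.approx(0.085)

    def test_unmatched_pair_raises(self):
        with pytest.raises(ValueError):
            cw.stability_screen([], [self._partial(("x", "y"), 0.1, 0.1)])


def test_partials_only_for_supported_pairs(default_cohort):
    scores = cw.score_bundle(default_cohort)
    results = cw.correlation_matrix(scores)
    partials = partial_correlations_for_supported(scores, results)
    supported = {frozenset(r.pair) for r in results if r.status == "supported"}
    assert {frozenset(p.pair) for p in partials} == supported


def test_fdr_utility_monotone():
    p = [0.001, 0.01, 0.04, 0.2, 0.8]
    adj = cw.inference.fdr_adjust(p)
    assert (adj >= np.asarray(p) - 1e-12).all()
    assert (np.diff(adj[np.argsort(p)]) >= -1e-12).all()
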