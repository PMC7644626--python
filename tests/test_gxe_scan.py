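import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radgut.gxe_scan import (
    ScanConfig,
    build_observations,
    filter_markers,
    fit_marker_model,
    minor_allele_frequency,
    scan,
)
from tests.conftest import make_panel, make_phenotypes
from tests.oracles import ols_oracle, sse


class TestMinorAlleleFrequency:
    @pytest.mark.parametrize(
        "calls,expected",
        [
            ([0, 0, 0, 1], 0.25),
            ([1, 1, 1, 0], 0.25),  # label-swap symmetry
            ([0, 1, np.nan, np.nan], 0.5),  # missing excluded from denominator
            ([0, 0, 0, 0], 0.0),
            ([1, 1], 0.0),
        ],
    )
    def test_examples(self, calls, expected):
        assert minor_allele_frequency(calls) == pytest.approx(expected)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError, match="all calls missing"):
            minor_allele_frequency([np.nan, np.nan])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from([0.0, 1.0]), min_size=1, max_size=40))
    def test_in_range_and_swap_invariant(self, calls):
        maf = minor_allele_frequency(calls)
        assert 0.0 <= maf <= 0.5
        swapped = [1.0 - c for c in calls]
        assert minor_allele_frequency(swapped) == pytest.approx(maf)


class TestFilterMarkers:
    def test_exact_threshold_excluded(self):
        # MAF exactly 0.25 fails the strict > 0.25 rule
        panel = make_panel([[0, 0, 0, 1], [0, 0, 1, 1]])
        kept = filter_markers(panel, 0.25)
        assert [m.pos for m in kept.markers] == [2000]

    def test_monomorphic_always_excluded(self):
        panel = make_panel([[0, 0, 0, 0], [1, 1, 1, 1]])
        assert filter_markers(panel, 0.0).n_markers == 0

    def test_zero_threshold_keeps_all_polymorphic(self):
        panel = make_panel([[0, 0, 0, 1], [0, 1, 1, 1], [0, 0, 0, 0]])
        kept = filter_markers(panel, 0.0)
        assert kept.n_markers == 2

    def test_order_preserved(self):
        panel = make_panel([[0, 1, 0, 1], [1, 0, 0, 1], [0, 0, 1, 1]])
        kept = filter_markers(panel, 0.25)
        assert [m.pos for m in kept.markers] == [1000, 2000, 3000]


def _cell_means_phenotypes():
    """8 lines x 2 doses with exact cell means (0,0)->0.1 (0,1)->0.3
    (1,0)->0.1 (1,1)->0.6 under equal replication (20 flies)."""
    rows = []
    for i, (c0, c1) in enumerate([(1, 5), (3, 7), (1, 5), (3, 7)]):  # non-carriers
        rows.append((f"N{i}", 0, 20, c0))
        rows.append((f"N{i}", 100, 20, c1))
    for i, (c0, c1) in enumerate([(1, 11), (3, 13), (1, 11), (3, 13)]):  # carriers
        rows.append((f"C{i}", 0, 20, c0))
        rows.append((f"C{i}", 100, 20, c1))
    return make_phenotypes(rows)


class TestFitMarkerModel:
    def test_saturated_cell_means_identity(self):
        phen = _cell_means_phenotypes()
        calls = {f"N{i}": 0.0 for i in range(4)} | {f"C{i}": 1.0 for i in range(4)}
        fit = fit_marker_model(calls, phen)
        np.testing.assert_allclose(fit.params, [0.1, 0.0, 0.2, 0.3], atol=1e-12)
        assert not fit.degenerate

    def test_constant_response_degenerate(self):
        rows = [(f"L{i}", d, 20, 4) for i in range(4) for d in (0, 100)]
        calls = {"L0": 0.0, "L1": 0.0, "L2": 1.0, "L3": 1.0}
        fit = fit_marker_model(calls, make_phenotypes(rows))
        assert fit.degenerate
        np.testing.assert_allclose(fit.params[1:], 0.0, atol=1e-12)
        assert all(math.isnan(p) for p in fit.pvalues)

    def test_insufficient_observations_rejected(self):
        rows = [("L1", 0, 20, 1), ("L1", 100, 20, 5), ("L2", 0, 20, 2), ("L2", 100, 20, 9)]
        calls = {"L1": 0.0, "L2": 1.0}
        with pytest.raises(ValueError, match="insufficient data"):
            fit_marker_model(calls, make_phenotypes(rows))

    def test_monomorphic_after_dropping_is_degenerate(self):
        rows = [(f"L{i}", d, 20, c) for i, c in enumerate([1, 2, 3, 4]) for d in (0, 100)]
        calls = {"L0": 0.0, "L1": 0.0, "L2": 0.0, "L3": np.nan}
        fit = fit_marker_model(calls, make_phenotypes(rows))
        assert fit.degenerate and math.isnan(fit.params[0])

    def test_matches_first_principles_oracle(self):
        rng = np.random.default_rng(42)
        lines = [f"L{i}" for i in range(6)]
        rows = []
        for lid in lines:
            for d in (0, 100):
                rows.append((lid, d, 25, int(rng.integers(0, 26))))
        phen = make_phenotypes(rows)
        calls = dict(zip(lines, [0.0, 1.0, 0.0, 1.0, 1.0, 0.0]))
        fit = fit_marker_model(calls, phen)
        obs = build_observations(phen, ScanConfig())
        g = obs["line_id"].map(calls).to_numpy()
        X = np.column_stack([np.ones(len(g)), g, obs["dose"], g * obs["dose"]])
        beta, se, p = ols_oracle(X.tolist(), obs["y"].tolist())
        np.testing.assert_allclose(fit.params, beta, atol=1e-10)
        np.testing.assert_allclose(fit.bse, se, atol=1e-10)
        np.testing.assert_allclose(fit.pvalues, p, atol=1e-8)
        # the closed form also minimizes the sum of squared errors
        base = sse(X.tolist(), obs["y"].tolist(), fit.params)
        for j in range(4):
            nudged = fit.params.copy()
            nudged[j] += 1e-4
            assert sse(X.tolist(), obs["y"].tolist(), nudged) > base


def _random_dataset(rng, n_lines=10):
    lines = [f"L{i}" for i in range(n_lines)]
    rows = []
    for lid in lines:
        for d in (0, 100):
            rows.append((lid, d, 25, int(rng.integers(0, 26))))
    g = rng.integers(0, 2, size=n_lines).astype(float)
    while g.sum() in (0, n_lines):  # keep the design full rank
        g = rng.integers(0, 2, size=n_lines).astype(float)
    calls = np.tile(g, (3, 1))
    calls[1] = rng.integers(0, 2, size=n_lines)
    calls[2, 0] = np.nan
    return make_panel(calls, line_ids=lines), make_phenotypes(rows)


class TestScan:
    def test_batched_scan_equals_per_marker_fit(self):
        rng = np.random.default_rng(7)
        panel, phen = _random_dataset(rng)
        config = ScanConfig(maf_min=0.0, min_lines_per_cell=1)
        result = scan(panel, phen, config)
        for i, marker in enumerate(result.markers):
            row = list(panel.markers).index(marker)
            calls = dict(zip(panel.line_ids, panel.calls[row]))
            # align orientation with any scan-side re-orientation
            g = np.array([calls[l] for l in panel.line_ids])
            if np.nanmean(g) > 0.5:
                calls = {k: (1.0 - v if not math.isnan(v) else v) for k, v in calls.items()}
            fit = fit_marker_model(calls, phen, config)
            if fit.degenerate:
                assert result.degenerate[i]
                continue
            np.testing.assert_allclose(result.params[i], fit.params, atol=1e-10)
            np.testing.assert_allclose(result.pvalues[i], fit.pvalues, atol=1e-10)
            assert result.n_obs[i] == fit.n_obs

    def test_matches_statsmodels(self):
        sm = pytest.importorskip("statsmodels.api")
        rng = np.random.default_rng(11)
        panel, phen = _random_dataset(rng)
        config = ScanConfig(maf_min=0.0, min_lines_per_cell=1)
        result = scan(panel, phen, config)
        obs = build_observations(phen, config)
        for i, marker in enumerate(result.markers):
            if result.degenerate[i]:
                continue
            row = list(panel.markers).index(marker)
            calls = dict(zip(panel.line_ids, panel.calls[row]))
            g = obs["line_id"].map(calls).to_numpy()
            if np.nanmean(list(calls.values())) > 0.5:
                g = 1.0 - g
            keep = ~np.isnan(g)
            X = np.column_stack(
                [np.ones(keep.sum()), g[keep], obs["dose"][keep], g[keep] * obs["dose"][keep]]
            )
            ref = sm.OLS(obs["y"][keep].to_numpy(), X).fit()
            np.testing.assert_allclose(result.params[i], ref.params, atol=1e-10)
            np.testing.assert_allclose(result.pvalues[i], ref.pvalues, atol=1e-10)

    def test_planted_marker_attains_minimum_p(self):
        from radgut.synthetic_data import SimConfig, simulate_dataset

        hits = 0
        for rep in range(20):
            cfg = SimConfig(
                n_lines=60,
                n_markers=80,
                maf_range=(0.3, 0.5),
                baseline_p=0.1,
                dose_effect=0.15,
                line_sd=0.02,
                causal_markers=((17, 0.0, 0.25),),
                seed=1000 + rep,
            )
            panel, phen, truth = simulate_dataset(cfg)
            result = scan(panel, phen, ScanConfig(maf_min=0.0))
            best = result.ranking()[0]
            hits += result.markers[best] == truth.causal[0][0]
        assert hits == 20

    def test_all_markers_below_threshold_gives_empty_result(self):
        panel = make_panel([[0, 0, 0, 1, 0, 0, 0, 0]])
        rows = [(f"L{i + 1}", d, 20, 2 + i % 3) for i in range(8) for d in (0, 100)]
        result = scan(panel, make_phenotypes(rows), ScanConfig(maf_min=0.25))
        assert result.n_markers == 0 and result.tested_pvalues.size == 0

    def test_marker_order_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        panel, phen = _random_dataset(rng)
        config = ScanConfig(maf_min=0.0, min_lines_per_cell=1)
        res = scan(panel, phen, config)
        perm = [2, 0, 1]
        shuffled = panel.subset_markers(perm)
        res2 = scan(shuffled, phen, config)
        order = [list(res.markers).index(m) for m in res2.markers]
        np.testing.assert_allclose(
            res2.tested_pvalues, res.tested_pvalues[order], equal_nan=True
        )

    def test_observation_row_order_invariance(self):
        rng = np.random.default_rng(5)
        panel, phen = _random_dataset(rng)
        config = ScanConfig(maf_min=0.0, min_lines_per_cell=1)
        res = scan(panel, phen, config)
        shuffled_df = phen.df.sample(frac=1.0, random_state=1).reset_index(drop=True)
        res2 = scan(panel, type(phen)(shuffled_df), config)
        np.testing.assert_allclose(
            res2.tested_pvalues, res.tested_pvalues, atol=1e-12, equal_nan=True
        )

    def test_reorientation_warns_and_preserves_p(self, six_line_phen):
        panel_minor = make_panel([[1, 1, 0, 0, 0, 0]])
        panel_major = make_panel([[0, 0, 1, 1, 1, 1]])
        config = ScanConfig(maf_min=0.0, min_lines_per_cell=1)
        res_minor = scan(panel_minor, six_line_phen, config)
        with pytest.warns(UserWarning, match="re-oriented"):
            res_major = scan(panel_major, six_line_phen, config)
        assert res_major.n_reoriented == 1
        np.testing.assert_allclose(
            res_major.tested_pvalues, res_minor.tested_pvalues, atol=1e-12
        )
        np.testing.assert_allclose(
            res_major.params[0, 3], res_minor.params[0, 3], atol=1e-12
        )

    def test_disjoint_line_sets_rejected(self, six_line_phen):
        panel = make_panel([[0, 1, 0, 1]], line_ids=["X1", "X2", "X3", "X4"])
        with pytest.raises(ValueError, match="share only 0 lines"):
            scan(panel, six_line_phen)

    def test_logit_response_uses_haldane_anscombe(self):
        rows = [("L1", 0, 20, 0), ("L1", 100, 20, 20), ("L2", 0, 20, 5), ("L2", 100, 20, 10)]
        obs = build_observations(
            make_phenotypes(rows), ScanConfig(response="logit_proportion")
        )
        assert np.isfinite(obs["y"]).all()
        assert obs["y"].iloc[0] == pytest.approx(np.log(0.5 / 20.5))
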