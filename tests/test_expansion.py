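"""Expansion classification, beta-binomial machinery, Fisher comparator,
and negative-control calibration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import clonotrack as ct
from clonotrack.expansion import _as_pair_frame, default_calibration_grid


def pair(bt, bf, ft, ff, n1=200_000, n2=200_000, rearr="X"):
    return ct.ClonePair(rearr, bt, bf, ft, ff, n1, n2)


def pct(x):
    return x / 100.0


class TestClassifyExpansion:
    """Boundary semantics: strict 'above 0.025%' (new), strict 'over
    tenfold' and 'above 0.01%' (increased)."""

    @pytest.mark.parametrize(
        "p,expected",
        [
            # undetected at baseline, 0.03% at follow-up -> new
            (pair(0, 0.0, 60, pct(0.03)), ct.NEW),
            # undetected, 0.02% -> below the 0.025% bar
            (pair(0, 0.0, 40, pct(0.02)), ct.NONE),
            # 0.001% -> 0.02%: 20-fold and above 0.01% -> increased
            (pair(2, pct(0.001), 40, pct(0.02)), ct.INCREASED),
            # 0.005% -> 0.04%: 8-fold misses the fold rule
            (pair(10, pct(0.005), 80, pct(0.04)), ct.NONE),
            # exactly tenfold is not 'over tenfold'
            (pair(4, pct(0.002), 40, pct(0.02)), ct.NONE),
            # exactly at 0.025% is not 'above'
            (pair(0, 0.0, 50, pct(0.025)), ct.NONE),
            # 12-fold but follow-up exactly at 0.01% fails the freq rule
            (pair(1, pct(0.01) / 12, 20, pct(0.01)), ct.NONE),
        ],
    )
    def test_paper_rule_cases(self, p, expected):
        assert ct.classify_expansion(p).category == expected

    def test_fold_change_undefined_at_zero_baseline(self):
        call = ct.classify_expansion(pair(0, 0.0, 60, pct(0.03)))
        assert call.category == ct.NEW
        assert call.fold_change is None

    def test_category_invariants(self):
        c = ct.classify_expansion(pair(5, 1e-5, 600, 3e-3))
        assert c.category == ct.INCREASED
        assert c.fold_change == pytest.approx(300.0)

    @settings(derandomize=True, max_examples=80, deadline=None)
    @given(
        baseline=st.sampled_from([(0, 0.0), (2, 1e-5), (40, 2e-4)]),
        f1=st.floats(0.0, 5e-3),
        bump=st.floats(1e-7, 5e-3),
    )
    def test_monotone_in_followup_frequency(self, baseline, f1, bump):
        """Raising the follow-up frequency never revokes an expansion call."""
        bt, bf = baseline
        c1 = ct.classify_expansion(pair(bt, bf, 100, f1)).category
        c2 = ct.classify_expansion(pair(bt, bf, 100, f1 + bump)).category
        assert not (c1 != ct.NONE and c2 == ct.NONE)

    def test_decision_boundaries_exact(self):
        """Scanning the classifier recovers the thresholds exactly."""
        grid = np.arange(0.0, 1.001e-3, 5e-7)
        cats = [ct.classify_expansion(pair(0, 0.0, 9, f)).category for f in grid]
        last_none = grid[max(i for i, c in enumerate(cats) if c == ct.NONE)]
        assert last_none == pytest.approx(2.5e-4, abs=1e-12)

        # ample fold change: frequency bar for 'increased' sits at 0.01%
        cats = [
            ct.classify_expansion(pair(1, 1e-7, 9, f)).category for f in grid
        ]
        nones = [i for i, c in enumerate(cats) if c == ct.NONE]
        assert grid[max(nones)] == pytest.approx(1e-4, abs=1e-12)

        # ample frequency: fold bar sits exactly at 10 (grid of exactly
        # representable binary fractions so the ratio is computed exactly)
        bf = 2.0**-13  # ~0.012%, so a tenfold rise clears the 0.01% bar
        folds = np.arange(1.0, 20.25, 0.25)
        cats = [
            ct.classify_expansion(pair(4, bf, 9, fold * bf)).category
            for fold in folds
        ]
        last_none = folds[max(i for i, c in enumerate(cats) if c == ct.NONE)]
        assert last_none == 10.0


class TestPairSamples:
    def test_union_join(self, make_ready):
        b = make_ready({"A": 10})
        f = make_ready({"B": 10})
        pairs = ct.pair_samples(b, f)
        assert len(pairs) == 2
        row_a = pairs[pairs.rearrangement == "A"].iloc[0]
        row_b = pairs[pairs.rearrangement == "B"].iloc[0]
        assert (row_a.baseline_templates, row_a.followup_templates) == (10, 0)
        assert (row_b.baseline_templates, row_b.followup_templates) == (0, 10)
        assert row_a.followup_freq == 0.0

    def test_identical_samples_have_equal_freqs(self, make_ready):
        b = make_ready({"A": 5, "B": 15})
        f = make_ready({"A": 5, "B": 15}, sample_id="s2")
        pairs = ct.pair_samples(b, f)
        assert np.allclose(pairs.baseline_freq, pairs.followup_freq)

    def test_empty_followup(self, make_ready):
        b = make_ready({"A": 5, "B": 15})
        f = ct.RepertoireSample(sample_id="empty", subject_id="P1")
        pairs = ct.pair_samples(b, f)
        assert (pairs.followup_templates == 0).all()
        assert len(pairs) == 2

    def test_subject_mismatch_guard(self, make_ready):
        b = make_ready({"A": 5}, subject_id="P1")
        f = make_ready({"A": 5}, subject_id="P2")
        with pytest.raises(ValueError, match="subject mismatch"):
            ct.pair_samples(b, f)
        assert len(ct.pair_samples(b, f, allow_subject_mismatch=True)) == 1

    def test_iter_pairs_round_trip(self, make_ready):
        b = make_ready({"A": 5, "B": 15})
        f = make_ready({"A": 10, "C": 10}, sample_id="s2")
        pairs = ct.pair_samples(b, f)
        objs = list(ct.iter_pairs(pairs))
        assert len(objs) == 3
        assert _as_pair_frame(objs).sort_values("rearrangement").reset_index(
            drop=True
        ).equals(pairs.sort_values("rearrangement").reset_index(drop=True))


class TestCallExpansions:
    def test_identical_samples_no_calls(self, make_ready):
        b = make_ready({"A": 100, "B": 900})
        f = make_ready({"A": 100, "B": 900}, sample_id="s2")
        res = ct.call_expansions(b, f)
        assert (res.n_new, res.n_increased) == (0, 0)

    def test_constructed_new_and_riser(self, make_ready):
        # 5-clone toy: NEWCLONE spikes in at 0.05%, RISER rises 20-fold to 0.02%
        depth = 100_000
        b = make_ready({"A": 50_000, "B": 30_000, "C": 19_999, "RISER": 1})
        f = make_ready(
            {
                "A": int(depth * 0.4993),
                "B": int(depth * 0.3),
                "C": int(depth * 0.2),
                "RISER": int(depth * 0.0002),
                "NEWCLONE": int(depth * 0.0005),
            },
            sample_id="s2",
        )
        res = ct.call_expansions(b, f)
        assert (res.n_new, res.n_increased) == (1, 1)
        cats = dict(zip(res.calls.rearrangement, res.calls.category))
        assert cats["NEWCLONE"] == ct.NEW
        assert cats["RISER"] == ct.INCREASED

    def test_summary_matches_calls(self, make_ready):
        b = make_ready({"A": 10, "B": 10})
        f = make_ready({"A": 1, "B": 10, "C": 9}, sample_id="s2")
        res = ct.call_expansions(b, f)
        assert res.n_new == int((res.calls.category == ct.NEW).sum())
        assert res.n_increased == int((res.calls.category == ct.INCREASED).sum())

    def test_scalar_and_vector_paths_agree(self, make_ready):
        rng = np.random.default_rng(0)
        b = make_ready({f"C{i}": int(c) for i, c in enumerate(rng.integers(0, 50, 40)) if c})
        f = make_ready(
            {f"C{i}": int(c) for i, c in enumerate(rng.integers(0, 50, 45)) if c},
            sample_id="s2",
        )
        res = ct.call_expansions(b, f)
        for p in ct.iter_pairs(res.calls[_as_pair_frame([]).columns.tolist()]):
            scalar = ct.classify_expansion(p)
            row = res.calls[res.calls.rearrangement == p.rearrangement].iloc[0]
            assert scalar.category == row.category


class TestBetaBinomial:
    def test_uniform_closed_form(self):
        assert np.allclose(ct.betabinom_pmf(np.arange(11), 10, 1.0, 1.0), 1 / 11)

    def test_normalisation(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = int(rng.integers(1, 201))
            a, b = rng.uniform(0.1, 50, size=2)
            total = ct.betabinom_pmf(np.arange(n + 1), n, a, b).sum()
            assert total == pytest.approx(1.0, abs=1e-10)

    def test_binomial_limit(self):
        n, p = 20, 0.5
        k = np.arange(n + 1)
        big = 1e6
        mine = ct.betabinom_pmf(k, n, big, big)
        assert np.max(np.abs(mine - stats.binom.pmf(k, n, p))) < 1e-4

    def test_matches_scipy_reference(self):
        k = np.arange(201)
        mine = ct.betabinom_pmf(k, 200, 2.3, 7.7)
        ref = stats.betabinom.pmf(k, 200, 2.3, 7.7)
        assert np.max(np.abs(mine - ref)) < 1e-12

    @pytest.mark.parametrize("k,n,a,b", [(-1, 10, 1, 1), (11, 10, 1, 1), (0, 10, 0, 1), (0, 10, 1, -2)])
    def test_domain_errors(self, k, n, a, b):
        with pytest.raises(ValueError):
            ct.betabinom_pmf(k, n, a, b)


def _betabinom_pairs(rng, rho, n_clones=1000, depth=200_000):
    """Control pairs with true per-clone means and beta-binomial follow-up."""
    p = 1.0 / np.arange(1, n_clones + 1)
    p = p / p.sum() * 0.5
    x1 = rng.binomial(depth, p)
    if rho > 0:
        s = (1 - rho) / rho
        theta = rng.beta(p * s, (1 - p) * s)
    else:
        theta = p
    x2 = rng.binomial(depth, theta)
    return pd.DataFrame(
        {
            "rearrangement": [f"c{i}" for i in range(n_clones)],
            "baseline_templates": x1,
            "baseline_freq": x1 / depth,
            "followup_templates": x2,
            "followup_freq": x2 / depth,
            "baseline_total": depth,
            "followup_total": depth,
        }
    )


class TestEstimateDispersion:
    def test_pure_multinomial_noise_gives_tiny_rho(self):
        pairs = _betabinom_pairs(np.random.default_rng(0), rho=0.0)
        rho = ct.estimate_dispersion(pairs[pairs.baseline_templates > 0])
        assert rho < 1e-3

    def test_recovers_planted_rho_within_factor_two(self):
        pairs = _betabinom_pairs(np.random.default_rng(1), rho=0.01)
        rho = ct.estimate_dispersion(pairs[pairs.baseline_templates > 0])
        assert 0.005 <= rho <= 0.02

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError, match="synthetic"):
            ct.estimate_dispersion(_as_pair_frame([]))


def _brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    prev = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        prev = min(prev, p[i] * n / rank)
        q[i] = prev
    return q


class TestDifferentialAbundance:
    def test_identical_frequencies_central(self):
        # moderate overdispersion: the null stays unimodal around the
        # pooled mean, so an unchanged clone is maximally non-significant
        p = pair(200, 1e-3, 200, 1e-3)
        out = ct.betabinom_differential_abundance([p], rho=1e-5)
        assert out.p_value.iloc[0] > 0.5

    def test_rho_zero_limit_matches_exact_binomial(self):
        rng = np.random.default_rng(2)
        for _ in range(15):
            n1 = n2 = int(rng.integers(100, 500))
            x1 = int(rng.integers(0, 40))
            x2 = int(rng.integers(0, 40))
            p = pair(x1, x1 / n1, x2, x2 / n2, n1, n2)
            out = ct.betabinom_differential_abundance([p], rho=1e-12)
            pooled = (x1 + x2) / (n1 + n2)
            if pooled == 0:
                continue
            ref = stats.binomtest(x2, n2, pooled).pvalue
            assert out.p_value.iloc[0] == pytest.approx(ref, abs=1e-6)

    def test_bh_qvalues_match_brute_force(self):
        rng = np.random.default_rng(3)
        pairs = _betabinom_pairs(rng, rho=0.005, n_clones=400, depth=50_000)
        out = ct.betabinom_differential_abundance(pairs, rho=0.005, q_threshold=0.05)
        brute = _brute_force_bh(out.p_value.to_numpy())
        assert np.allclose(out.fdr_q.to_numpy(), brute, atol=1e-12)
        assert (out.fdr_q >= out.p_value - 1e-12).all()
        # q-values are monotone in p-values
        srt = out.sort_values("p_value")
        assert (np.diff(srt.fdr_q.to_numpy()) >= -1e-12).all()

    def test_direction_labels(self):
        up = pair(1, 1 / 1000, 30, 30 / 1000, 1000, 1000)
        down = pair(30, 30 / 1000, 1, 1 / 1000, 1000, 1000)
        out = ct.betabinom_differential_abundance([up, down], rho=1e-4)
        assert list(out.direction) == ["up", "down"]


class TestFisher:
    def test_empty_table_p_one(self):
        assert ct.fisher_exact_pair(pair(0, 0.0, 0, 0.0, 10, 10)) == 1.0

    def test_disjoint_example(self):
        # [[0,5],[5,0]]: all mass on one diagonal
        p = ct.fisher_exact_pair(pair(0, 0.0, 5, 1.0, 5, 5))
        assert p == pytest.approx(2 / 252, abs=1e-10)

    def test_symmetry_under_sample_swap(self):
        a = ct.fisher_exact_pair(pair(3, 0.03, 9, 0.09, 100, 100))
        b = ct.fisher_exact_pair(pair(9, 0.09, 3, 0.03, 100, 100))
        assert a == pytest.approx(b, abs=1e-12)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(4)
        rows = [
            pair(int(rng.integers(0, 20)), 0.0, int(rng.integers(0, 20)), 0.0, 500, 600, rearr=f"c{i}")
            for i in range(30)
        ]
        vec = ct.fisher_pvalues(rows)
        scal = np.array([ct.fisher_exact_pair(p) for p in rows])
        assert np.allclose(vec, scal, atol=1e-12)


def _stable_control_pairs(extra=()):
    """Control set: stable clones + optional planted fluctuations."""
    depth = 200_000
    base = {f"S{i}": 2_000 for i in range(50)}
    rows = []
    for rearr, t in base.items():
        rows.append(pair(t, t / depth, t, t / depth, depth, depth, rearr=rearr))
    rows.extend(extra)
    return _as_pair_frame(rows)


class TestCalibrateCriteria:
    def test_quiet_controls_give_least_stringent_point(self):
        crit = ct.calibrate_criteria([_stable_control_pairs()], max_false_positives=0)
        first = min(
            default_calibration_grid(),
            key=lambda c: (c.new_min_freq, c.increased_min_freq, c.increased_min_fold),
        )
        assert crit == first

    def test_planted_jump_forces_higher_new_threshold(self):
        depth = 200_000
        jump = pair(0, 0.0, 40, 0.0002, depth, depth, rearr="JUMP")  # 0.02% from absent
        controls = [_stable_control_pairs([jump])]
        grid = [
            ct.ExpansionCriteria.from_percent(0.015, 10, 0.01),
            ct.ExpansionCriteria.from_percent(0.025, 10, 0.01),
        ]
        crit = ct.calibrate_criteria(controls, grid, max_false_positives=0)
        assert crit.new_min_freq == pytest.approx(2.5e-4)

    def test_large_budget_keeps_least_stringent(self):
        depth = 200_000
        jump = pair(0, 0.0, 40, 0.0002, depth, depth, rearr="JUMP")
        crit = ct.calibrate_criteria(
            [_stable_control_pairs([jump])], max_false_positives=100
        )
        assert crit.new_min_freq == pytest.approx(5e-5)  # 0.005%

    def test_unreachable_budget_reports_best(self):
        depth = 200_000
        jump = pair(0, 0.0, 400, 0.002, depth, depth, rearr="JUMP")  # 0.2%
        with pytest.raises(ct.CalibrationError, match="best achievable"):
            ct.calibrate_criteria([_stable_control_pairs([jump])], max_false_positives=0)


class TestCriteriaSerialisation:
    def test_percent_json_round_trip(self, tmp_path):
        crit = ct.ExpansionCriteria()
        path = tmp_path / "criteria.json"
        crit.to_json(path)
        back = ct.ExpansionCriteria.from_json(path)
        assert back == crit
        assert crit.to_dict() == {
            "new_min_freq_pct": 0.025,
            "increased_min_fold": 10.0,
            "increased_min_freq_pct": 0.01,
        }

    def test_nonpositive_thresholds_rejected(self):
        with pytest.raises(ValueError):
            ct.ExpansionCriteria(new_min_freq=0.0)
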