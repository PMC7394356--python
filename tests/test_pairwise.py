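"""Pairwise differential-expression screen: t-test, BH, fold-change gate,
newly-detected rule, and the end-to-end pipeline against synthetic truth."""

import math

import numpy as np
import pytest
from scipy import stats

from persisterprot import (
    DifferentialRecord,
    SimParams,
    ValidationError,
    benjamini_hochberg,
    classify_differential,
    detect_newly_present,
    fold_change,
    generate_experiment,
    run_pairwise_screen,
    two_sample_t,
)

from conftest import make_matrix


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def textbook_t(a, b, variant):
    """Closed-form two-sample t from first principles (no scipy)."""
    a, b = list(map(float, a)), list(map(float, b))
    na, nb = len(a), len(b)
    ma, mb = sum(a) / na, sum(b) / nb
    va = sum((x - ma) ** 2 for x in a) / (na - 1)
    vb = sum((x - mb) ** 2 for x in b) / (nb - 1)
    if variant == "pooled":
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        t = (ma - mb) / math.sqrt(sp2 * (1 / na + 1 / nb))
        df = na + nb - 2
    else:
        se2 = va / na + vb / nb
        t = (ma - mb) / math.sqrt(se2)
        df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2 * stats.t.sf(abs(t), df)
    return t, p


def brute_force_bh(p, alpha):
    """Step-up rule directly from its definition: scan every rank k."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if p[i] <= rank * alpha / m:
            kmax = rank
    reject = [False] * m
    for rank, i in enumerate(order, start=1):
        if rank <= kmax:
            reject[i] = True
    q = [None] * m
    for rank, i in enumerate(order, start=1):
        q[i] = min(
            min(m * p[j] / r for r, j in enumerate(order, start=1) if r >= rank), 1.0
        )
    return q, reject


# ---------------------------------------------------------------------------
# t-test
# ---------------------------------------------------------------------------

class TestTwoSampleT:
    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_matches_textbook_formula(self, variant):
        rng = np.random.default_rng(11)
        cases = [((1, 2, 3), (4, 5, 6))]
        cases += [
            (rng.normal(0, 1, rng.integers(2, 8)), rng.normal(1, 2, rng.integers(2, 8)))
            for _ in range(30)
        ]
        for a, b in cases:
            t, p = two_sample_t(a, b, variant)
            t_ref, p_ref = textbook_t(a, b, variant)
            # sign convention: scipy reports t for A - B, as does the oracle
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_identical_groups_give_t_zero_p_one(self):
        t, p = two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == 0.0 and p == 1.0

    @pytest.mark.parametrize("variant", ["welch", "pooled"])
    def test_swapping_groups_flips_t_and_preserves_p(self, variant):
        a, b = [0.1, 0.4, 0.3], [0.5, 0.9, 0.7]
        t1, p1 = two_sample_t(a, b, variant)
        t2, p2 = two_sample_t(b, a, variant)
        assert t1 == -t2 and p1 == p2

    def test_group_of_one_rejected(self):
        with pytest.raises(ValidationError):
            two_sample_t([1.0], [1.0, 2.0])

    def test_degenerate_constant_groups(self):
        assert two_sample_t([2, 2, 2], [2, 2, 2]) == (0.0, 1.0)
        t, p = two_sample_t([2, 2, 2], [5, 5, 5])
        assert p == 0.0 and t == math.inf


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

class TestBenjaminiHochberg:
    def test_single_test(self):
        q, reject = benjamini_hochberg([0.03], alpha=0.1)
        assert reject[0] and q[0] == pytest.approx(0.03)

    def test_step_up_rescues_smaller_ranks(self):
        # largest k: p_(4) = 0.04 <= 4 * 0.05 / 4, so all four are rejected
        q, reject = benjamini_hochberg([0.01, 0.02, 0.03, 0.04], alpha=0.05)
        assert reject.all()

    def test_no_rejections_when_all_p_large(self):
        _, reject = benjamini_hochberg([0.3, 0.4], alpha=0.1)
        assert not reject.any()

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValidationError):
            benjamini_hochberg([0.5, 1.2])

    def test_q_values_monotone_in_p_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=40)
        q, _ = benjamini_hochberg(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)
        assert np.all((q >= 0) & (q <= 1))

    def test_matches_brute_force_definition_on_random_vectors(self):
        rng = np.random.default_rng(1234)
        for _ in range(1000):
            m = int(rng.integers(1, 51))
            p = rng.uniform(size=m) ** rng.uniform(0.5, 3)
            alpha = float(rng.uniform(0.01, 0.2))
            q, reject = benjamini_hochberg(p, alpha)
            q_ref, reject_ref = brute_force_bh(p, alpha)
            assert list(reject) == reject_ref
            assert np.allclose(q, q_ref, atol=1e-12)


# ---------------------------------------------------------------------------
# fold change and classification
# ---------------------------------------------------------------------------

class TestFoldChange:
    def test_ratio_of_group_means(self):
        assert fold_change([0.01, 0.01], [0.02, 0.02]) == pytest.approx(2.0)

    def test_identical_groups_give_one(self):
        assert fold_change([0.3, 0.5], [0.5, 0.3]) == pytest.approx(1.0)

    def test_zero_reference_mean_raises(self):
        with pytest.raises(ValidationError):
            fold_change([0.0, 0.0], [0.1, 0.2])

    def test_down_regulation_semantics(self):
        # a fold change of 0.18 means ~5.5-fold down in the test condition
        fc = fold_change([0.011, 0.011], [0.002, 0.00196])
        assert 1 / fc == pytest.approx(5.55, abs=0.05)


def _rec(fc, q):
    return DifferentialRecord(
        protein="P",
        mean_nsaf_A=0.01,
        mean_nsaf_B=0.01 * fc,
        fold_change=fc,
        log2_fc=math.log2(fc),
        p_value=q / 2,
        q_value=q,
        status="not_significant",
    )


class TestClassification:
    def test_significant_and_above_threshold_is_up(self):
        assert classify_differential(_rec(2.0, 0.05)) == "up"

    def test_significant_but_small_fold_change_stays_uncalled(self):
        # the chaperone boundary case: 1.44-fold down at good q is below the
        # 1.5-fold gate and must not be called
        assert classify_differential(_rec(1 / 1.44, 0.019)) == "not_significant"

    def test_not_significant_regardless_of_fold_change(self):
        assert classify_differential(_rec(3.0, 0.5)) == "not_significant"

    def test_significant_and_below_reciprocal_threshold_is_down(self):
        assert classify_differential(_rec(0.5, 0.05)) == "down"


class TestNewlyDetected:
    def make(self, pre, post):
        return make_matrix(
            {"P1": pre + post, "filler": [9, 9, 9, 9, 9, 9]},
            [("pre", 3), ("post", 3)],
        )

    def test_total_post_count_above_five_flagged(self):
        m = self.make([0, 0, 0], [3, 2, 2])  # total 7 > 5
        assert detect_newly_present(m, "pre", "post") == {"P1"}

    def test_total_exactly_five_not_flagged(self):
        m = self.make([0, 0, 0], [2, 2, 1])
        assert detect_newly_present(m, "pre", "post") == set()

    def test_any_baseline_detection_disqualifies(self):
        m = self.make([1, 0, 0], [40, 40, 40])
        assert detect_newly_present(m, "pre", "post") == set()

    def test_threshold_is_on_combined_technical_replicates(self):
        m = make_matrix(
            {"P1": [0, 0, 0, 0, 0, 0, 2, 2, 1, 1, 0, 0]},
            [("pre", 3), ("post", 3)],
            n_tech=2,
        )  # post bio-rep totals 4 + 2 + 0 = 6 > 5
        assert detect_newly_present(m, "pre", "post") == {"P1"}


# ---------------------------------------------------------------------------
# full screen
# ---------------------------------------------------------------------------

def _truth_screen(n=200, seed=7, **kw):
    # moderate abundance spread for the truth-recovery fixtures: NSAF is
    # compositional, so one-sided effects on dominant proteins shift every
    # other protein's relative abundance; a narrower dynamic range keeps the
    # injected effects, not that coupling, as the signal under test
    params = SimParams(
        n_proteins=n,
        frac_de=kw.pop("frac_de", 0.2),
        de_fold=4.0,
        dispersion=0.01,
        dropout_rate=0.0,
        abundance_log_sd=kw.pop("abundance_log_sd", 0.6),
        seed=seed,
        **kw,
    )
    m, truth = generate_experiment(params)
    return m, truth, run_pairwise_screen(m, "pre", "amp_5h")


class TestRunPairwiseScreen:
    def test_recovers_injected_fold_changes_with_controlled_false_calls(self):
        # 20 proteins up 4-fold and 20 down among 200, low dispersion: the
        # screen should recover most true effects, and false calls must stay
        # within the 10% false-discovery level the BH step controls
        m, truth, res = _truth_screen()
        lab = truth.label_of()
        up = {r.protein for r in res.with_status("up")}
        down = {r.protein for r in res.with_status("down")}
        true_up = truth.proteins_of("de_up")
        true_down = truth.proteins_of("de_down")
        assert len(up & true_up) > len(true_up) / 2
        assert len(down & true_down) > len(true_down) / 2
        false_calls = sum(lab[p] == "null" for p in up | down)
        assert false_calls / max(1, len(up | down)) <= 0.10

    def test_null_comparison_makes_no_calls(self):
        counts = {f"P{i}": [i + 3, i + 4, i + 5] * 2 for i in range(10)}
        m = make_matrix(counts, [("pre", 3), ("post", 3)])
        res = run_pairwise_screen(m, "pre", "post")
        assert not res.with_status("up") and not res.with_status("down")

    def test_newly_detected_routed_once_without_p_value(self):
        m = make_matrix(
            {"P1": [0, 0, 0, 3, 2, 2], "filler": [9, 9, 9, 9, 9, 9]},
            [("pre", 3), ("post", 3)],
        )
        res = run_pairwise_screen(m, "pre", "post")
        recs = [r for r in res.records if r.protein == "P1"]
        assert len(recs) == 1
        assert recs[0].status == "newly_detected"
        assert math.isnan(recs[0].p_value) and math.isnan(recs[0].q_value)

    def test_every_protein_lands_in_exactly_one_partition(self):
        m, truth, res = _truth_screen(frac_de=0.1, frac_newly_detected=0.03)
        assert len(res.records) == m.n_proteins
        assert len({r.protein for r in res.records}) == m.n_proteins
        tested = [
            r for r in res.records if r.status in {"up", "down", "not_significant"}
        ]
        assert (
            len(tested)
            + len(res.with_status("newly_detected"))
            + len(res.with_status("excluded"))
            == m.n_proteins
        )
        assert res.stages["tested"] == len(tested)

    def test_swapping_conditions_inverts_fold_change_and_preserves_p(self):
        m, _, res = _truth_screen(n=60)
        swapped = run_pairwise_screen(m, "amp_5h", "pre")
        fwd = {r.protein: r for r in res.records if not math.isnan(r.p_value)}
        rev = {r.protein: r for r in swapped.records if not math.isnan(r.p_value)}
        assert set(fwd) == set(rev)
        for protein, r in fwd.items():
            assert rev[protein].fold_change == pytest.approx(
                1.0 / r.fold_change, rel=1e-12
            )
            assert rev[protein].p_value == r.p_value

    def test_single_replicate_condition_rejected(self):
        m = make_matrix({"P1": [5, 5, 5, 5]}, [("pre", 3), ("post", 1)])
        with pytest.raises(ValidationError, match="post"):
            run_pairwise_screen(m, "pre", "post")

    def test_scalar_and_pipeline_t_tests_agree(self):
        """The vectorized per-protein tests inside the screen equal the
        public scalar operation."""
        from persisterprot.quantify import combine_technical_replicates, compute_nsaf
        m, _, res = _truth_screen(n=40)
        mc = combine_technical_replicates(m.subset_conditions(["pre", "amp_5h"]))
        quant = mc.subset_proteins(
            mc.counts.index[mc.counts.mean(axis=1) >= 3]
        )
        nsaf = compute_nsaf(quant)
        checked = 0
        for r in res.records:
            if math.isnan(r.p_value) or r.protein not in nsaf.nsaf.index:
                continue
            a = nsaf.nsaf.loc[r.protein, nsaf.run_ids("pre")]
            b = nsaf.nsaf.loc[r.protein, nsaf.run_ids("amp_5h")]
            _, p = two_sample_t(a, b, "welch")
            assert r.p_value == pytest.approx(p, abs=1e-12)
            checked += 1
        assert checked > 10
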