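"""Fisher r-to-z network comparison, FDR control, edge classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgenet.compare import (
    classify_edges,
    compare_networks,
    fdr_adjust,
    fisher_z,
    z_difference,
)
from cgenet.errors import DomainError, EmptyInput, RegionMismatch
from cgenet.expression import GroupKey
from cgenet.network import (
    CorrelationNetwork,
    correlation_pvalue,
    pearson_network,
    threshold_network,
)
from cgenet.simulate import CovarianceSpec, simulate_group

from conftest import SALINE, make_net, small_registry

DRUG = GroupKey("cfos", "adult", "D1Gq+D2")


def corr_net(r: np.ndarray, names, n=7, group=SALINE) -> CorrelationNetwork:
    names = list(names)
    r = np.asarray(r, dtype=float)
    np.fill_diagonal(r, 0.0)
    p = np.asarray(correlation_pvalue(r, n))
    np.fill_diagonal(p, 1.0)
    return CorrelationNetwork(
        group=group, regions=tuple(names),
        r=pd.DataFrame(r, index=names, columns=names),
        p=pd.DataFrame(p, index=names, columns=names), n=n,
    )


class TestFisherZ:
    def test_fixed_point_at_zero(self):
        assert fisher_z(0.0) == 0.0

    def test_closed_form_at_half(self):
        assert fisher_z(0.5) == pytest.approx(0.5 * np.log(3.0), abs=1e-12)

    @settings(max_examples=50, derandomize=True)
    @given(r=st.floats(-0.999, 0.999))
    def test_odd_symmetry(self, r):
        assert fisher_z(-r) == pytest.approx(-fisher_z(r), abs=1e-12)

    def test_degenerate_r_clamped_finite(self):
        assert np.isfinite(fisher_z(1.0))
        assert np.isfinite(fisher_z(-1.0))

    def test_domain_error_beyond_one(self):
        with pytest.raises(DomainError):
            fisher_z(1.5)


class TestZDifference:
    def test_identical_networks_give_null(self):
        rng = np.random.default_rng(30)
        r = rng.uniform(-0.5, 0.5, (4, 4))
        r = (r + r.T) / 2
        a = corr_net(r.copy(), "ABCD", group=DRUG)
        b = corr_net(r.copy(), "ABCD")
        diff = z_difference(a, b)
        assert np.allclose(diff["Z"], 0.0)
        assert np.allclose(diff["p"], 1.0)

    def test_closed_form_se_and_z(self):
        # n=7 both: SE = sqrt(1/4 + 1/4) = 0.70711;
        # r_a=0.9, r_b=0 -> Z = atanh(0.9)/0.70711 ~ 2.082, p ~ 0.0374
        r_a = np.zeros((2, 2)); r_a[0, 1] = r_a[1, 0] = 0.9
        a = corr_net(r_a, "AB", group=DRUG)
        b = corr_net(np.zeros((2, 2)), "AB")
        diff = z_difference(a, b)
        se = np.sqrt(0.25 + 0.25)
        assert se == pytest.approx(0.70711, abs=1e-5)
        z_expected = np.arctanh(0.9) / se
        assert diff["Z"].iloc[0] == pytest.approx(z_expected, abs=1e-9)
        assert diff["Z"].iloc[0] == pytest.approx(2.082, abs=2e-3)
        from scipy import stats
        assert diff["p"].iloc[0] == pytest.approx(
            2 * stats.norm.sf(z_expected), abs=1e-12)
        assert diff["p"].iloc[0] == pytest.approx(0.0374, abs=5e-4)

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(31)
        r1 = rng.uniform(-0.8, 0.8, (5, 5)); r1 = (r1 + r1.T) / 2
        r2 = rng.uniform(-0.8, 0.8, (5, 5)); r2 = (r2 + r2.T) / 2
        a = corr_net(r1, "ABCDE", group=DRUG)
        b = corr_net(r2, "ABCDE")
        fwd, rev = z_difference(a, b), z_difference(b, a)
        np.testing.assert_allclose(fwd["Z"], -rev["Z"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], atol=1e-12)

    def test_region_mismatch_rejected(self):
        a = corr_net(np.zeros((2, 2)), "AB")
        b = corr_net(np.zeros((2, 2)), "AC")
        with pytest.raises(RegionMismatch):
            z_difference(a, b)


class TestFdrAdjust:
    def test_hand_executed_bh_example(self):
        adjusted, reject = fdr_adjust(np.array([0.01, 0.02, 0.9]), 0.05)
        np.testing.assert_allclose(adjusted, [0.03, 0.03, 0.9])
        assert list(reject) == [True, True, False]

    def test_matches_brute_force_step_up_definition(self):
        # adjusted p_(i) = min_{j >= i} m p_(j) / j, capped at 1
        rng = np.random.default_rng(32)
        p = rng.uniform(size=51)
        m = len(p)
        order = np.argsort(p)
        expected = np.empty(m)
        for rank, idx in enumerate(order, start=1):
            expected[idx] = min(
                min(m * p[j] / (list(order).index(j) + 1)
                    for j in order[rank - 1:]),
                1.0,
            )
        adjusted, _ = fdr_adjust(p, 0.35)
        np.testing.assert_allclose(adjusted, expected, atol=1e-12)

    def test_all_null_input_no_discoveries(self):
        adjusted, reject = fdr_adjust(np.ones(10), 0.35)
        assert not reject.any()
        assert (adjusted == 1.0).all()

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_adjusted_at_least_raw(self, pvals):
        adjusted, _ = fdr_adjust(np.array(pvals), 0.35)
        assert (adjusted >= np.array(pvals) - 1e-12).all()

    def test_empty_input_rejected(self):
        with pytest.raises(EmptyInput):
            fdr_adjust(np.array([]), 0.35)

    def test_by_more_conservative_than_bh(self):
        rng = np.random.default_rng(33)
        p = rng.uniform(0, 0.2, 20)
        bh, _ = fdr_adjust(p, 0.35, method="bh")
        by, _ = fdr_adjust(p, 0.35, method="by")
        assert (by >= bh - 1e-12).all()


class TestClassification:
    @pytest.mark.parametrize(
        "w_base, w_drug, expected",
        [
            (0.0, 0.8, "gain_positive"),
            (0.8, 0.0, "loss_positive"),
            (0.0, -0.8, "gain_negative"),
            (-0.8, 0.0, "loss_negative"),
            (0.8, -0.8, "sign_reversal"),
            (-0.8, 0.8, "sign_reversal"),
        ],
    )
    def test_transition_rules(self, w_base, w_drug, expected):
        names = "AB"
        diff = pd.DataFrame(
            {"region_a": ["A"], "region_b": ["B"], "r_drug": [w_drug],
             "r_base": [w_base], "z_drug": [0.0], "z_base": [0.0],
             "Z": [5.0], "p": [1e-7]}
        )
        thr_a = make_net(np.array([[0, w_drug], [w_drug, 0]]), list(names))
        thr_b = make_net(np.array([[0, w_base], [w_base, 0]]), list(names))
        result = classify_edges(diff, thr_a, thr_b, q_level=0.35)
        assert result.edges["class"].iloc[0] == expected
        assert bool(result.edges["significant"].iloc[0])

    def test_same_sign_strength_change_gets_no_class(self):
        diff = pd.DataFrame(
            {"region_a": ["A"], "region_b": ["B"], "r_drug": [0.95],
             "r_base": [0.8], "z_drug": [0.0], "z_base": [0.0],
             "Z": [5.0], "p": [1e-7]}
        )
        thr_a = make_net(np.array([[0, 0.95], [0.95, 0]]), ["A", "B"])
        thr_b = make_net(np.array([[0, 0.8], [0.8, 0]]), ["A", "B"])
        result = classify_edges(diff, thr_a, thr_b)
        assert result.edges["class"].iloc[0] == "none"
        assert result.edges["strength_change"].iloc[0] == "pos->pos"

    def test_non_significant_edges_unclassified(self):
        diff = pd.DataFrame(
            {"region_a": ["A"], "region_b": ["B"], "r_drug": [0.3],
             "r_base": [0.0], "z_drug": [0.0], "z_base": [0.0],
             "Z": [0.5], "p": [0.6]}
        )
        thr = make_net(np.zeros((2, 2)), ["A", "B"])
        result = classify_edges(diff, thr, thr)
        assert result.edges["class"].iloc[0] == "none"
        assert not bool(result.edges["significant"].iloc[0])

    def test_planted_gain_detected_end_to_end(self):
        # baseline r = 0, drug r = 0.95, n = 30/group:
        # Z ~ atanh(0.95)/sqrt(2/27) ~ 6.7, detected at q = 0.35
        reg = small_registry(4)
        blocks = {"x": ("A", "B"), "y": ("C", "D")}
        base_spec = CovarianceSpec(blocks=blocks)
        drug_spec = CovarianceSpec(
            blocks=blocks, edge_overrides=(("A", "B", 0.95),)
        )
        rng = np.random.SeedSequence(34).spawn(2)
        t_base = simulate_group(SALINE, base_spec, 30,
                                np.random.default_rng(rng[0]), reg)
        t_drug = simulate_group(DRUG, drug_spec, 30,
                                np.random.default_rng(rng[1]), reg)
        net_b = pearson_network(t_base, SALINE, reg)
        net_a = pearson_network(t_drug, DRUG, reg)
        result = compare_networks(
            net_a, net_b, threshold_network(net_a), threshold_network(net_b),
            q_level=0.35,
        )
        row = result.edges.query("region_a == 'A' and region_b == 'B'").iloc[0]
        assert row["significant"]
        assert row["class"] == "gain_positive"

    def test_swap_exchanges_gain_and_loss(self):
        reg = small_registry(3)
        rng = np.random.default_rng(35)
        r1 = rng.uniform(-0.9, 0.9, (3, 3)); r1 = (r1 + r1.T) / 2
        r2 = rng.uniform(-0.9, 0.9, (3, 3)); r2 = (r2 + r2.T) / 2
        a = corr_net(r1, "ABC", n=20, group=DRUG)
        b = corr_net(r2, "ABC", n=20)
        thr_a = make_net(np.where(np.abs(r1) > 0.44, r1, 0.0), ["A", "B", "C"])
        thr_b = make_net(np.where(np.abs(r2) > 0.44, r2, 0.0), ["A", "B", "C"])
        fwd = classify_edges(z_difference(a, b), thr_a, thr_b)
        rev = classify_edges(z_difference(b, a), thr_b, thr_a)
        assert (fwd.edges["significant"] == rev.edges["significant"]).all()
        swap = {"gain_positive": "loss_positive",
                "loss_positive": "gain_positive",
                "gain_negative": "loss_negative",
                "loss_negative": "gain_negative",
                "sign_reversal": "sign_reversal", "none": "none"}
        assert list(rev.edges["class"]) == [
            swap[c] for c in fwd.edges["class"]
        ]


class TestPower:
    def test_detection_count_monotone_in_group_size(self):
        # fixed planted effects: more subjects per group -> at least as many
        # detected edges (seeded experiment over n in {7, 15, 30})
        reg = small_registry(6)
        blocks = {"x": ("A", "B", "C"), "y": ("D", "E", "F")}
        base = CovarianceSpec(blocks=blocks, within_r=0.2, between_r=0.0)
        drug = CovarianceSpec(
            blocks=blocks, within_r=0.2, between_r=0.0,
            edge_overrides=(("A", "B", 0.9), ("D", "E", 0.9),
                            ("C", "F", 0.8)),
        )
        planted = {("A", "B"), ("D", "E"), ("C", "F")}
        counts = []
        for n in (7, 15, 30):
            detected = 0
            streams = np.random.SeedSequence([37, n]).spawn(40)
            for k in range(0, 40, 2):
                t_b = simulate_group(SALINE, base, n,
                                     np.random.default_rng(streams[k]), reg)
                t_a = simulate_group(DRUG, drug, n,
                                     np.random.default_rng(streams[k + 1]),
                                     reg)
                diff = z_difference(pearson_network(t_a, DRUG, reg),
                                    pearson_network(t_b, SALINE, reg))
                _, reject = fdr_adjust(diff["p"].to_numpy(), 0.35)
                # count true detections: rejections on the planted edges
                # (at a liberal q the false-discovery count shrinks with n,
                # so total rejections need not be monotone)
                pairs = zip(diff["region_a"], diff["region_b"], reject)
                detected += sum(
                    1 for a, b, rej in pairs
                    if rej and ((a, b) in planted or (b, a) in planted)
                )
            counts.append(detected)
        assert counts[0] <= counts[1] <= counts[2]
        assert counts[2] > 0

    def test_planted_delta_z_recovered_without_bias(self):
        # (z_a - z_b) estimates the planted Fisher-z difference; bias
        # vanishes at large n
        reg = small_registry(2)
        blocks = {"x": ("A", "B")}
        base = CovarianceSpec(blocks=blocks, within_r=0.2)
        drug = CovarianceSpec(blocks=blocks, within_r=0.7)
        planted_dz = np.arctanh(0.7) - np.arctanh(0.2)
        streams = np.random.SeedSequence(38).spawn(100)
        ests = []
        for k in range(0, 100, 2):
            t_b = simulate_group(SALINE, base, 1000,
                                 np.random.default_rng(streams[k]), reg)
            t_a = simulate_group(DRUG, drug, 1000,
                                 np.random.default_rng(streams[k + 1]), reg)
            diff = z_difference(pearson_network(t_a, DRUG, reg),
                                pearson_network(t_b, SALINE, reg))
            ests.append(float(diff["z_drug"].iloc[0]
                              - diff["z_base"].iloc[0]))
        # mean over 50 replicates: MC SE ~ sqrt(2/997)/sqrt(50) ~ 0.006
        assert abs(np.mean(ests) - planted_dz) < 0.02


class TestCalibration:
    def test_null_rejection_rate_calibrated(self):
        # both groups drawn from the same correlation structure: raw
        # per-edge rejections at p < 0.05 occur ~5% of the time. (FDR-level
        # behavior, which depends on the far tail of the normal
        # approximation, is characterized in the acceptance suite.)
        reg = small_registry(5)
        spec = CovarianceSpec(blocks={"x": tuple("ABCDE")}, within_r=0.3)
        rng_seq = np.random.SeedSequence(36).spawn(240)
        raw_rej = total = 0
        for k in range(0, 240, 2):
            t_a = simulate_group(DRUG, spec, 7,
                                 np.random.default_rng(rng_seq[k]), reg)
            t_b = simulate_group(SALINE, spec, 7,
                                 np.random.default_rng(rng_seq[k + 1]), reg)
            diff = z_difference(pearson_network(t_a, DRUG, reg),
                                pearson_network(t_b, SALINE, reg))
            raw_rej += int((diff["p"] < 0.05).sum())
            total += len(diff)
        rate = raw_rej / total
        se = np.sqrt(0.05 * 0.95 / total)
        assert abs(rate - 0.05) < 4 * se
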