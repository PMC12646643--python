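"""Cross-entropy surrogate, ground-truth profiles, N/beta monotonicity, and
landscape scans."""

import numpy as np
import pytest

from telinfer.apriori import (
    AprioriTarget,
    cells_for_identifiability,
    cross_entropy_objective,
    ground_truth_profile,
    profile_at_n,
    scan_landscape,
    unit_profile,
)
from telinfer.cme import ParamVector
from telinfer.inference import log_likelihood
from telinfer.noise import CaptureModel
from telinfer.synthetic import sample_histogram


class TestCrossEntropy:
    def test_gibbs_minimality_and_entropy_value(self, theta_identifiable, rng):
        target = AprioriTarget(theta_identifiable, 200.0)
        p = np.asarray(target.p_tar.probabilities)
        h_tar = cross_entropy_objective(target, theta_identifiable)
        entropy = -(p[p > 0] @ np.log(p[p > 0]))
        assert h_tar == pytest.approx(200.0 * entropy, rel=1e-9)
        for _ in range(30):
            other = ParamVector(*10.0 ** rng.uniform(-2, 2, size=3))
            assert cross_entropy_objective(target, other) >= h_tar - 1e-9

    def test_linear_in_cell_number(self, theta_identifiable):
        t1 = AprioriTarget(theta_identifiable, 100.0)
        t2 = AprioriTarget(theta_identifiable, 200.0)
        other = ParamVector(0.1, 0.2, 8.0)
        assert cross_entropy_objective(t2, other) == pytest.approx(
            2.0 * cross_entropy_objective(t1, other), rel=1e-12
        )

    def test_neighboring_koff_within_one_ci(self, theta_weak, mini_library):
        # the slow-deactivation compensation valley: doubling koff costs less
        # than the chi-square threshold once kon and ksyn re-optimize, so
        # both koff values sit inside one profile CI at 200 cells
        res = ground_truth_profile(AprioriTarget(theta_weak, 200.0), mini_library)
        lb, ub = res.curves["koff"].ci
        assert lb <= theta_weak.koff <= ub
        assert lb <= 2 * theta_weak.koff <= ub

    def test_equals_mean_sampled_negative_ll(self, theta_identifiable):
        # E[-LL] over sampled replicates equals H pointwise
        target = AprioriTarget(theta_identifiable, 200.0)
        candidates = [
            theta_identifiable,
            ParamVector(0.05, 0.2, 10.0),
            ParamVector(0.1, 0.1, 8.0),
        ]
        n_reps = 300
        for th in candidates:
            h = cross_entropy_objective(target, th)
            vals = np.array([
                -log_likelihood(sample_histogram(theta_identifiable, 200, seed=s), th)
                for s in range(n_reps)
            ])
            se = vals.std(ddof=1) / np.sqrt(n_reps)
            assert abs(vals.mean() - h) <= 3 * se


class TestGroundTruthProfile:
    def test_identifiable_case_has_narrow_cis(self, mini_library, theta_identifiable):
        res = ground_truth_profile(
            AprioriTarget(theta_identifiable, 200.0), mini_library
        )
        assert res.identifiable
        assert res.overall_apm < 1.0
        for c in res.curves.values():
            assert not c.lower_at_edge and not c.upper_at_edge
            # profile envelope: never below the global minimum
            assert (c.minus_ll >= res.minus_ll_min - 1e-6).all()

    def test_weak_case_wider_than_identifiable(
        self, mini_library, theta_identifiable, theta_weak
    ):
        strong = ground_truth_profile(
            AprioriTarget(theta_identifiable, 200.0), mini_library
        )
        weak = ground_truth_profile(AprioriTarget(theta_weak, 200.0), mini_library)
        assert weak.overall_apm > strong.overall_apm
        ci_s = strong.curves["koff"].ci
        ci_w = weak.curves["koff"].ci
        assert ci_w[1] / ci_w[0] > ci_s[1] / ci_s[0]

    def test_ci_nesting_in_cell_number(self, mini_library, theta_identifiable):
        unit = unit_profile(theta_identifiable, 1.0, mini_library)
        res_n = profile_at_n(unit, 200.0)
        res_2n = profile_at_n(unit, 400.0)
        assert res_2n.overall_apm <= res_n.overall_apm + 1e-9
        for name in ("kon", "koff", "ksyn"):
            lb_n, ub_n = res_n.curves[name].ci
            lb_2n, ub_2n = res_2n.curves[name].ci
            assert lb_2n >= lb_n * (1 - 1e-9)
            assert ub_2n <= ub_n * (1 + 1e-9)

    def test_beta_mismatch_rejected(self, mini_library, theta_identifiable):
        with pytest.raises(ValueError):
            unit_profile(theta_identifiable, CaptureModel(0.3), mini_library)

    def test_lower_capture_degrades_identifiability(
        self, mini_library, mini_library_beta03, theta_identifiable
    ):
        full = ground_truth_profile(
            AprioriTarget(theta_identifiable, 200.0), mini_library
        )
        degraded = ground_truth_profile(
            AprioriTarget(theta_identifiable, 200.0, CaptureModel(0.3)),
            mini_library_beta03,
        )
        assert degraded.overall_apm >= full.overall_apm


class TestCellsForIdentifiability:
    def test_returns_first_sufficient_ladder_entry(
        self, mini_library, theta_identifiable
    ):
        n = cells_for_identifiability(
            theta_identifiable, 1.0, [200, 2000, 20000], mini_library
        )
        assert n == 200

    def test_rejects_decreasing_ladder(self, mini_library, theta_identifiable):
        with pytest.raises(ValueError):
            cells_for_identifiability(
                theta_identifiable, 1.0, [1000, 100], mini_library
            )


class TestLandscape:
    def test_deterministic_rerun(self, mini_library, fine_scan_beta1):
        again = scan_landscape(mini_library, N=1e4, subgrid=3)
        assert fine_scan_beta1.table.equals(again.table)

    def test_identifiable_cluster_at_slow_switching(self, fine_scan_beta1):
        t = fine_scan_beta1.table[~t_failed(fine_scan_beta1.table)]
        ident = t[t["identifiable"]]
        rest = t[~t["identifiable"]]
        assert len(ident) > 0 and len(rest) > 0
        assert np.median(np.log10(ident["kon"])) < np.median(np.log10(rest["kon"]))
        assert np.median(np.log10(ident["koff"])) < np.median(np.log10(rest["koff"]))

    def test_identifiable_region_grows_with_ksyn(self, fine_scan_beta1):
        t = fine_scan_beta1.table[~t_failed(fine_scan_beta1.table)]
        ks = np.sort(t["ksyn"].unique())
        low = t[t["ksyn"] == ks[0]]["identifiable"].mean()
        high = t[t["ksyn"] == ks[-1]]["identifiable"].mean()
        assert high > low

    def test_capture_loss_shrinks_identifiable_fraction(
        self, fine_scan_beta1, fine_scan_beta03
    ):
        assert (
            fine_scan_beta03.fraction_identifiable
            <= fine_scan_beta1.fraction_identifiable
        )

    def test_single_cell_identifies_nothing(self, mini_library):
        # even the optimistic grid-restricted profile mode finds nothing at
        # N = 1: one cell cannot pin three rates to within the T factors
        res = scan_landscape(mini_library, N=1, subgrid=4, fine=False)
        assert res.fraction_identifiable == 0.0


def t_failed(table):
    return table["failed"] if "failed" in table else np.zeros(len(table), bool)
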