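"""LOD arithmetic, meiosis classification, map functions, co-segregation, power."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from enuscreen import (
    Individual,
    MeiosisTally,
    Pedigree,
    cosegregation_test,
    informative_meioses,
    linkage_power,
    lod_score,
    lod_two_point,
    theta_from_distance,
)
from enuscreen.linkage import DegenerateTableError, PhaseUnknownError


class TestLodScore:
    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 200), st.integers(0, 200))
    def test_lod_is_zero_at_free_recombination(self, nr, r):
        assert float(lod_score(nr, r, 0.5)) == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_all_nonrecombinant(self):
        res = lod_two_point(MeiosisTally(nr=10, r=0))
        assert res.theta_hat == 0.0
        assert res.max_lod == pytest.approx(10 * np.log10(2), abs=1e-9)  # 3.0103
        assert not res.significant  # threshold 3.3

    def test_eleven_meioses_cross_genomewide_threshold(self):
        res = lod_two_point(MeiosisTally(nr=11, r=0))
        assert res.max_lod == pytest.approx(11 * np.log10(2), abs=1e-9)  # 3.3113
        assert res.significant

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(1, 150), st.integers(1, 150))
    def test_grid_maximum_matches_analytic_mle(self, nr, r):
        res = lod_two_point(MeiosisTally(nr=nr, r=r))
        theta_mle = min(r / (nr + r), 0.5)
        analytic_max = float(lod_score(nr, r, theta_mle))
        assert abs(res.theta_hat - theta_mle) <= 1e-3 + 1e-9
        # the grid never beats the analytic maximum, and misses it by at most
        # the grid-induced tolerance
        assert res.max_lod <= analytic_max + 1e-9
        assert res.max_lod >= analytic_max - 0.01

    def test_lod_additivity_over_sibships(self):
        t1, t2 = MeiosisTally(nr=12, r=3), MeiosisTally(nr=7, r=1)
        pooled = t1 + t2
        theta = 0.2
        assert float(lod_score(pooled.nr, pooled.r, theta)) == pytest.approx(
            float(lod_score(t1.nr, t1.r, theta)) + float(lod_score(t2.nr, t2.r, theta))
        )

    def test_empty_tally_rejected(self):
        with pytest.raises(ValueError):
            lod_two_point(MeiosisTally(nr=0, r=0))


class TestMapFunctions:
    def test_zero_distance(self):
        assert theta_from_distance(0.0) == 0.0

    def test_haldane_fifty_centimorgans(self):
        assert theta_from_distance(50.0, "haldane") == pytest.approx(
            0.5 * (1 - np.exp(-1)), abs=1e-12
        )  # ~0.316

    def test_kosambi_form(self):
        assert theta_from_distance(50.0, "kosambi") == pytest.approx(
            0.5 * np.tanh(1.0), abs=1e-12
        )

    @pytest.mark.parametrize("fn", ["haldane", "kosambi"])
    def test_monotone_and_bounded(self, fn):
        d = np.linspace(0, 300, 40)
        thetas = [theta_from_distance(x, fn) for x in d]
        assert all(a < b for a, b in zip(thetas, thetas[1:]))
        assert all(t <= 0.5 for t in thetas)

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            theta_from_distance(-1.0)


def _toy_pedigree():
    """Doubly-het cis parent with four phase-informative offspring."""
    ped = Pedigree()
    ped.add(Individual("P", None, None, "F", 1, rescue=True,
                       has_trait=True, has_marker=True))
    ped.phase["P"] = True
    combos = [
        ("c1", True, True, True),    # trait+marker together -> NR (rescue)
        ("c2", True, False, False),  # trait without marker -> R
        ("c3", False, True, False),  # marker without trait -> R
        ("c4", False, False, False),  # neither -> NR
    ]
    for iid, trait, marker, rescue in combos:
        ped.add(Individual(iid, "F5LL-ext", "P", "M", 2, rescue=rescue,
                           has_trait=trait, has_marker=marker,
                           transmitting_parent="P"))
    return ped


class TestInformativeMeioses:
    def test_phase_classification(self):
        tally = informative_meioses(_toy_pedigree())
        assert (tally.nr, tally.r) == (2, 2)
        rescues = informative_meioses(_toy_pedigree(), group="rescues")
        assert (rescues.nr, rescues.r) == (1, 0)
        litters = informative_meioses(_toy_pedigree(), group="littermates")
        assert (litters.nr, litters.r) == (1, 2)

    def test_unknown_phase_raises(self):
        ped = _toy_pedigree()
        del ped.phase["P"]
        with pytest.raises(PhaseUnknownError):
            informative_meioses(ped)

    def test_uninformative_meioses_counted_separately(self):
        ped = _toy_pedigree()
        ped.add(Individual("c5", "F5LL-ext", "P", "F", 2, rescue=False,
                           has_trait=None, has_marker=True, transmitting_parent="P"))
        tally = informative_meioses(ped)
        assert tally.uninformative == 1 and tally.n == 4

    def test_orphan_parent_rejected(self):
        ped = Pedigree()
        with pytest.raises(ValueError, match="neither in the pedigree"):
            ped.add(Individual("x", "ghost", None, "M", 2))


class TestCosegregation:
    def test_zero_recombinant_binomial_closed_form(self):
        res = cosegregation_test(
            MeiosisTally(nr=40, r=0, label="rescues"),
            MeiosisTally(nr=119, r=30, label="littermates"),
            theta_expected=0.141,
        )
        assert res.binomial_p == pytest.approx(0.859**40, rel=1e-12)  # ~0.0023
        assert res.fisher_p < 0.05

    def test_identical_proportions_give_fisher_one(self):
        res = cosegregation_test(
            MeiosisTally(nr=30, r=10, label="rescues"),
            MeiosisTally(nr=30, r=10, label="littermates"),
            theta_expected=0.25,
        )
        assert res.fisher_p == pytest.approx(1.0)

    def test_degenerate_table_rejected(self):
        with pytest.raises(DegenerateTableError):
            cosegregation_test(MeiosisTally(0, 0), MeiosisTally(0, 0), 0.141)

    def test_theta_bounds(self):
        with pytest.raises(ValueError):
            cosegregation_test(MeiosisTally(nr=5, r=0), MeiosisTally(nr=5, r=1), 0.0)


class TestLinkagePower:
    def test_fully_linked_marker_always_detected(self):
        est = linkage_power({"n_meioses": 50}, 1, [0.0], theta_true=0.0,
                            n_sim=300, seed=1, phenocopy_rate=0.0)
        assert est.power == 1.0  # LOD = 50*log10(2) >> 3.3 every replicate

    def test_unlinked_markers_rarely_fire(self):
        est = linkage_power({"n_meioses": 60}, 3, [0.0, 50.0, 100.0], theta_true=0.5,
                            n_sim=400, seed=2, phenocopy_rate=0.0)
        assert est.power <= 0.05

    def test_power_nondecreasing_in_pedigree_size(self):
        small = linkage_power({"n_meioses": 30}, 1, [0.0], theta_true=0.141,
                              n_sim=400, seed=3)
        large = linkage_power({"n_meioses": 120}, 1, [0.0], theta_true=0.141,
                              n_sim=400, seed=3)
        assert large.power >= small.power

    def test_marker_positions_validated(self):
        with pytest.raises(ValueError, match="outside map"):
            linkage_power({"n_meioses": 10}, 2, [0.0, 999.0], 0.141, n_sim=10, seed=0)

    def test_ci_brackets_point_estimate(self):
        est = linkage_power({"n_meioses": 40}, 2, [0.0, 30.0], theta_true=0.141,
                            n_sim=200, seed=4)
        assert est.ci_low <= est.power <= est.ci_high
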