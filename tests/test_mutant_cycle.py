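"""Interaction factor Omega, coupling energy, and error propagation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mutcycle.dose_response import ConstructSummary
from mutcycle.mutant_cycle import (
    RT_KJ_PER_MOL,
    CouplingCycle,
    CycleDefinition,
    build_cycle_table,
    compute_omega,
    coupling_energy,
    evaluate_cycle,
    predicted_independent_fold,
    propagate_coupling_sd,
    read_cycle_yaml,
)
from mutcycle.reference_data import construct_summaries, cycle_definitions


@pytest.fixture(scope="module")
def table():
    return build_cycle_table(construct_summaries(), cycle_definitions()).set_index(
        "cycle_id"
    )


def summary(label, ec50, sd=0.0, n=8):
    return ConstructSummary(label, ec50, sd, 1.8, 0.2, n)


def make_cycle(wt, singles, combined, sds=None):
    sds = sds or {}
    return CouplingCycle(
        wt=summary("WT", wt, sds.get("WT", 0.0)),
        singles=tuple(
            summary(f"m{i}", e, sds.get(f"m{i}", 0.0)) for i, e in enumerate(singles)
        ),
        combined=summary("comb", combined, sds.get("comb", 0.0)),
    )


class TestOmega:
    def test_generalized_form_reduces_to_pairwise_formula(self, rng):
        """On 1000 random EC50 quadruples the k=2 form equals the literal
        two-mutant expression wt*comb/(m1*m2)."""
        quads = rng.lognormal(mean=2.0, sigma=1.0, size=(1000, 4))
        for wt, m1, m2, comb in quads:
            cyc = make_cycle(wt, [m1, m2], comb)
            assert compute_omega(cyc) == pytest.approx(wt * comb / (m1 * m2), rel=1e-12)

    def test_independence_by_construction_gives_unity(self):
        wt, m1, m2, m3 = 9.4, 25.0, 3.0, 40.0
        comb = wt * (m1 / wt) * (m2 / wt) * (m3 / wt)
        assert compute_omega(make_cycle(wt, [m1, m2, m3], comb)) == pytest.approx(1.0, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(scale=st.floats(min_value=1e-3, max_value=1e3), seed=st.integers(0, 100))
    def test_omega_invariant_to_common_ec50_rescaling_and_single_order(self, scale, seed):
        r = np.random.default_rng(seed)
        wt, m1, m2, comb = r.lognormal(2.0, 0.8, 4)
        base = compute_omega(make_cycle(wt, [m1, m2], comb))
        scaled = compute_omega(make_cycle(wt * scale, [m1 * scale, m2 * scale], comb * scale))
        swapped = compute_omega(make_cycle(wt, [m2, m1], comb))
        assert scaled == pytest.approx(base, rel=1e-9)
        assert swapped == pytest.approx(base, rel=1e-12)

    def test_zero_ec50_rejected(self):
        cyc = make_cycle(9.4, [25.0, 0.0], 55.0)
        with pytest.raises(ValueError, match="positive"):
            compute_omega(cyc)


class TestCouplingEnergy:
    def test_unity_omega_has_zero_energy(self):
        assert coupling_energy(1.0) == 0.0

    def test_round_trip_omega_energy(self, rng):
        for omega in rng.lognormal(0.0, 1.5, 200):
            assert math.exp(coupling_energy(omega) / RT_KJ_PER_MOL) == pytest.approx(
                omega, rel=1e-12
            )

    def test_antisymmetric_under_swapping_combined_with_prediction(self):
        """If the combined EC50 over- or under-shoots the independence
        prediction by a factor x, ddG is +-RT ln x symmetrically."""
        wt, m1, m2 = 9.4, 25.0, 3.0
        pred = wt * (m1 / wt) * (m2 / wt)
        for x in (0.3, 2.0, 7.5):
            up = coupling_energy(compute_omega(make_cycle(wt, [m1, m2], pred * x)))
            down = coupling_energy(compute_omega(make_cycle(wt, [m1, m2], pred / x)))
            assert up == pytest.approx(-down, rel=1e-9)
            assert up == pytest.approx(RT_KJ_PER_MOL * math.log(x), rel=1e-9)

    def test_non_positive_omega_is_domain_error(self):
        with pytest.raises(ValueError):
            coupling_energy(0.0)
        with pytest.raises(ValueError):
            coupling_energy(-2.0)


class TestErrorPropagation:
    def test_zero_energy_annihilates_sd(self):
        wt, m1, m2 = 9.4, 25.0, 3.0
        comb = wt * (m1 / wt) * (m2 / wt)
        cyc = make_cycle(wt, [m1, m2], comb, sds={"WT": 1.8, "m0": 5.0, "m1": 0.6, "comb": 4.0})
        assert propagate_coupling_sd(cyc, 0.0) == 0.0

    def test_sd_scales_linearly_with_energy_magnitude(self):
        cyc = make_cycle(9.4, [25.0, 3.0], 55.0, sds={"WT": 1.8, "m0": 5.0, "m1": 0.6, "comb": 4.0})
        s1 = propagate_coupling_sd(cyc, 1.0)
        s3 = propagate_coupling_sd(cyc, -3.0)
        assert s3 == pytest.approx(3.0 * s1, rel=1e-12)

    def test_missing_sd_is_an_error(self):
        cyc = CouplingCycle(
            wt=summary("WT", 9.4, 1.8),
            singles=(ConstructSummary("m", 25.0, math.nan, 1.8, 0.2, 8),),
            combined=summary("comb", 55.0, 4.0),
        )
        with pytest.raises(ValueError, match="SD"):
            propagate_coupling_sd(cyc, -1.0)


class TestPublishedTableReproduction:
    """Arithmetic from the published per-construct means reproduces the
    published coupling table.

    A few rows deviate by more than the last printed digit because the
    published table was computed from unrounded per-oocyte means; those
    carry looser bounds below.
    """

    # cycle_id -> (omega, ddg, ddg_sd, predicted_magnitude) as printed
    PRINTED = {
        "E45A_P272G": (0.77, -0.64, 0.24, 7.69),
        "V46A_I264A": (0.44, -2.04, 0.82, 34.7),
        "V46A_P265A": (1.34, +0.72, 0.33, 2.56),
        "V46A_P265G": (0.15, -4.69, 1.90, 24.2),
        "V46A_P272G": (0.46, -1.94, 0.79, 33.0),
        "I264A_P265G": (0.11, -5.50, 2.48, 6.38),
        "I264A_P272G": (0.66, -1.01, 0.39, 8.72),
        "V46A_I264A_P265G": (0.01, -11.1, 5.7, 73.1),
        "V46A_I264A_P272G": (0.11, -5.43, 2.51, 99.9),
        "S266A_G182A.G188A": (0.22, -3.77, 1.57, 22.6),
        "S266A_E183A.E189A": (0.38, -2.42, 1.05, 8.11),
        "T267A_G182A.G188A": (0.24, -3.56, 1.40, 14.9),
        "S268A_G182A.G188A": (0.98, -0.05, 0.02, 1.20),
        "S268A_K218A.K224A": (1.93, +1.62, 0.88, 37.3),
        "S269A_K218A.K224A": (1.00, 0.00, 0.00, 21.5),
        "S266A.T267A_G182A.G188A": (0.05, -7.37, 3.49, 65.7),
        "S266A.T267A_E183A.E189A": (0.12, -5.20, 2.95, 23.6),
        "S268A.S269A_G182A.G188A": (1.10, +0.24, 0.11, 2.05),
        "S268A.S269A_K218A.K224A": (1.71, +1.33, 0.96, 91.5),
        "STGG4_G182A": (0.58, -1.36, 0.66, 3.80),
        "STGG4_G188A": (0.75, -0.70, 0.23, 3.12),
        "STGG4_G182A.G188A": (0.41, -2.20, 0.95, 7.77),
    }
    # rows known to reflect unrounded internal means
    LOOSE = {"T267A_G182A.G188A", "S268A_G182A.G188A", "S268A.S269A_K218A.K224A"}

    def test_omega_column(self, table):
        for cid, (omega, *_rest) in self.PRINTED.items():
            tol = 0.015 if cid not in self.LOOSE else 0.03
            assert table.loc[cid, "omega"] == pytest.approx(omega, abs=tol), cid

    def test_coupling_energy_column(self, table):
        for cid, (_o, ddg, *_rest) in self.PRINTED.items():
            tol = 0.015 if cid not in self.LOOSE else 0.05
            # the triple row is printed to 1 decimal
            tol = max(tol, 0.06 if cid == "V46A_I264A_P265G" else 0.0)
            assert table.loc[cid, "ddg_kj_mol"] == pytest.approx(ddg, abs=tol), cid

    def test_propagated_sd_column(self, table):
        for cid, (_o, _d, sd, _p) in self.PRINTED.items():
            tol = max(0.02, 0.15 * sd) if cid in self.LOOSE else max(0.015, 0.01 * sd)
            assert table.loc[cid, "ddg_sd_kj_mol"] == pytest.approx(sd, abs=tol), cid

    def test_predicted_fold_column(self, table):
        for cid, (*_rest, pred) in self.PRINTED.items():
            assert table.loc[cid, "predicted_magnitude"] == pytest.approx(pred, rel=0.01), cid

    def test_nonfunctional_combined_rows_are_predicted_only(self, table):
        row = table.loc["E45A_V46A"]
        assert np.isnan(row["omega"]) and np.isnan(row["ddg_kj_mol"])
        assert row["predicted_magnitude"] == pytest.approx(30.6, abs=0.1)


class TestCycleTablePlumbing:
    def test_empty_cycle_list_gives_empty_table(self):
        table = build_cycle_table(construct_summaries(), [])
        assert len(table) == 0

    def test_undefined_construct_named_in_error(self):
        cdef = CycleDefinition("bad", ("nope",), "alsono")
        with pytest.raises(KeyError, match="nope"):
            build_cycle_table(construct_summaries(), [cdef])

    def test_single_order_permutation_leaves_table_unchanged(self):
        summaries = construct_summaries()
        fwd = CycleDefinition("c", ("aV46A", "aI264A", "aP265G"), "aV46A+aI264A+aP265G")
        rev = CycleDefinition("c", ("aP265G", "aV46A", "aI264A"), "aV46A+aI264A+aP265G")
        a = build_cycle_table(summaries, [fwd])
        b = build_cycle_table(summaries, [rev])
        assert a.equals(b)

    def test_single_perturbation_prediction_equals_its_fold_change(self):
        cyc = make_cycle(9.4, [25.1], 25.1)
        pred = predicted_independent_fold(cyc)
        assert pred.magnitude == pytest.approx(25.1 / 9.4, rel=1e-12)
        assert pred.direction == "loss"

    def test_printed_mode_rounds_inputs_to_three_significant_figures(self):
        exact = ConstructSummary("WT", 9.40411, 1.823, 1.78, 0.35, 8)
        mut = ConstructSummary("m", 25.149, 5.51, 1.83, 0.31, 8)
        comb = ConstructSummary("c", 55.837, 8.21, 1.49, 0.18, 8)
        summaries = {"WT": exact, "m": mut, "c": comb}
        cdef = CycleDefinition("x", ("m", "m"), "c")
        printed = build_cycle_table(summaries, [cdef], mode="printed")
        expected = 9.40 * 55.8 / (25.1 * 25.1)
        assert printed.loc[0, "omega"] == pytest.approx(expected, rel=1e-12)

    def test_cycle_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cycles.yaml"
        path.write_text(
            "cycles:\n"
            "  - id: E45A_P272G\n"
            "    singles: [aE45A, aP272G]\n"
            "    combined: aE45A+aP272G\n"
        )
        defs = read_cycle_yaml(path)
        assert defs == [
            CycleDefinition("E45A_P272G", ("aE45A", "aP272G"), "aE45A+aP272G")
        ]


def test_evaluate_cycle_result_consistency():
    summaries = construct_summaries()
    cyc = CouplingCycle(
        wt=summaries["WT"],
        singles=(summaries["aE45A"], summaries["aP272G"]),
        combined=summaries["aE45A+aP272G"],
    )
    res = evaluate_cycle(cyc, "E45A_P272G")
    assert math.exp(res.ddg / RT_KJ_PER_MOL) == pytest.approx(res.omega, rel=1e-12)
    assert res.observed_fold.direction == "loss"
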