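"""Cohort engine: transition matrices, traces, and a path-enumeration oracle."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from argus_cua.calibrate import generate_synthetic_parameters
from argus_cua.markov import (
    CF, EXPLANTED, LP, MLP, RL, STATES,
    StructuralError, StructureConfig, build_transition_matrix, run_cohort,
)


def zeroed(ps):
    """Degenerate treatment effect: no movement, no events."""
    return ps.with_values(
        dict(pVAplus=0.0, pVAplusplus=0.0, pVAplusplusplus=0.0, pSAE=0.0, pExplant=0.0)
    )


class TestTransitionMatrix:
    def test_rows_sum_to_one_every_cycle(self, working, structure):
        for cycle in range(6):
            m = build_transition_matrix(working, structure, cycle)
            np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
            assert (m >= -1e-12).all()

    def test_identity_without_movement(self, table1, structure):
        ps = zeroed(table1)
        sc = StructureConfig(upward_rate=0.0, mode_policy="printed")
        m = build_transition_matrix(ps, sc, cycle=3)
        np.testing.assert_allclose(m, np.eye(5), atol=0)

    def test_cycle0_allocation_row(self, working, structure):
        # explantation starts at cycle 1, so cycle 0 is the pure allocation
        m = build_transition_matrix(working, structure, cycle=0)
        pv = (float(working.pVAplus), float(working.pVAplusplus), float(working.pVAplusplusplus))
        assert m[MLP, LP] == pytest.approx(pv[0])
        assert m[MLP, CF] == pytest.approx(pv[1])
        assert m[MLP, RL] == pytest.approx(pv[2])
        assert m[MLP, MLP] == pytest.approx(1.0 - sum(pv))
        assert m[MLP, EXPLANTED] == 0.0

    def test_upward_drift_with_competing_explant(self, working, structure):
        # later cycles: 10%/yr LP->CF thinned by the explantation hazard
        m = build_transition_matrix(working, structure, cycle=3)
        pexp = float(working.pExplant)
        assert m[LP, CF] == pytest.approx(0.10 * (1.0 - pexp))
        assert m[LP, EXPLANTED] == pytest.approx(pexp + 0.10 * pexp - 0.10 * pexp)  # = pexp
        assert m[RL, EXPLANTED] == pytest.approx(pexp)
        assert m[EXPLANTED, EXPLANTED] == 1.0  # absorbing

    def test_overfull_allocation_raises(self, table1):
        ps = table1.replace(pVAplus=0.9, pVAplusplus=0.2)
        sc = StructureConfig(mode_policy="printed")
        with pytest.raises(StructuralError, match="MLP"):
            build_transition_matrix(ps, sc, cycle=0)

    def test_overfull_allocation_tolerated_when_not_strict(self, table1):
        ps = table1.replace(pVAplus=0.9, pVAplusplus=0.2)
        sc = StructureConfig(mode_policy="printed")
        m = build_transition_matrix(ps, sc, cycle=0, strict=False)
        np.testing.assert_allclose(m.sum(axis=1), 1.0, atol=1e-12)
        assert m[MLP, MLP] < 0


class TestCohortTraces:
    def test_cau_stays_at_baseline(self, table1, structure):
        trace = run_cohort("cau", table1, structure, 25)
        np.testing.assert_array_equal(trace.occupancy[:, MLP], 1.0)
        assert trace.sae_incidence.sum() == 0
        assert trace.explant_incidence.sum() == 0

    def test_unknown_arm_rejected(self, table1, structure):
        with pytest.raises(ValueError, match="arm"):
            run_cohort("placebo", table1, structure, 25)

    def test_no_explants_without_hazard(self, table1, structure):
        ps = table1.replace(pExplant=0.0)
        trace = run_cohort("argus", ps, structure, 25)
        np.testing.assert_array_equal(trace.occupancy[:, EXPLANTED], 0.0)

    def test_cumulative_explants_match_geometric_survival(self, table1):
        # hazard on every implanted state from cycle 1 gives a pure
        # geometric survival curve: cum(T) = 1 - (1-p)^(T-1)
        sc = StructureConfig(explant_source="implanted", mode_policy="printed")
        trace = run_cohort("argus", table1, sc, 25)
        p = float(table1.pExplant)
        expected = 1.0 - (1.0 - p) ** 24
        assert trace.occupancy[-1, EXPLANTED] == pytest.approx(expected, rel=1e-12)
        assert trace.explant_incidence.sum() == pytest.approx(expected, rel=1e-12)

    def test_cumulative_explant_incidence_nondecreasing(self, working, structure):
        trace = run_cohort("argus", working, structure, 25)
        assert (trace.explant_incidence >= -1e-15).all()

    def test_sae_first_cycle_only(self, working, structure):
        trace = run_cohort("argus", working, structure, 25)
        assert trace.sae_incidence[0] == pytest.approx(float(working.pSAE))
        assert trace.sae_incidence[1:].sum() == 0

    def test_degenerate_argus_equals_cau(self, table1):
        sc = StructureConfig(upward_rate=0.0, mode_policy="printed")
        argus = run_cohort("argus", zeroed(table1), sc, 25)
        cau = run_cohort("cau", zeroed(table1), sc, 25)
        np.testing.assert_allclose(argus.occupancy, cau.occupancy, atol=1e-15)

    def test_reading_letters_monotone_without_explants(self, table1, structure):
        ps = table1.replace(pExplant=0.0)
        trace = run_cohort("argus", ps, structure, 25)
        rl = trace.occupancy[:, RL]
        assert (np.diff(rl) >= -1e-15).all()

    def test_tidy_export_shape(self, working, structure):
        df = run_cohort("argus", working, structure, 10).to_frame()
        assert set(df.columns) == {
            "cycle", "state", "occupancy", "sae_incidence", "explant_incidence", "arm"
        }
        assert len(df) == 10 * len(STATES)


@st.composite
def synthetic_cases(draw):
    seed = draw(st.integers(min_value=0, max_value=10_000))
    sc = StructureConfig(
        mlp_drift=draw(st.booleans()),
        explant_start=draw(st.integers(min_value=0, max_value=2)),
        explant_source=draw(st.sampled_from(["implanted", "va_states"])),
        explant_destination=draw(st.sampled_from(["explanted", "mlp"])),
        transition_semantics=draw(
            st.sampled_from(["first_cycle_allocation", "per_cycle_from_MLP"])
        ),
        upward_rate=draw(st.floats(min_value=0.0, max_value=1.0)),
        mode_policy="printed",
    )
    return generate_synthetic_parameters(seed), sc


class TestMassConservation:
    @given(synthetic_cases())
    @settings(max_examples=40, deadline=None)
    def test_occupancy_sums_to_one(self, case):
        ps, sc = case
        trace = run_cohort("argus", ps, sc, 12)
        np.testing.assert_allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        assert (trace.occupancy >= -1e-12).all()

    @given(synthetic_cases())
    @settings(max_examples=15, deadline=None)
    def test_path_enumeration_oracle(self, case):
        """Explicit enumeration over all state sequences reproduces the trace."""
        ps, sc = case
        horizon = 4
        mats = [build_transition_matrix(ps, sc, t) for t in range(horizon)]
        trace = run_cohort("argus", ps, sc, horizon)
        np.testing.assert_allclose(
            trace.occupancy, _enumerate_occupancy(mats, horizon), atol=1e-10
        )


def _enumerate_occupancy(mats, horizon):
    """Brute-force occupancy: sum path probabilities over all state prefixes."""
    n = len(STATES)
    occ = np.zeros((horizon, n))
    for t in range(horizon):
        for prefix in itertools.product(range(n), repeat=t + 1):
            prob = 1.0
            prev = MLP
            for i, s in enumerate(prefix):
                prob *= mats[i][prev, s]
                prev = s
                if prob == 0.0:
                    break
            else:
                occ[t, prefix[-1]] += prob
    return occ
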