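"""Unit and property tests for the four-cytotype invasion recursion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wolbsweep.model import (
    CYTOTYPES,
    CytotypeState,
    ModelParams,
    Trajectory,
    build_mating_table,
    classic_ci_recursion,
    mismatch_fraction,
    peak_mismatch,
    run_scenario,
    step,
)

FIG_PARAMS = dict(l_ci=0.98, mu=0.0, F_A=1.0, F_B=1.0)


def aggregate_double(state):
    return state.x_b1 + state.x_b2


# ---------------------------------------------------------------------------
# parameters and mating table
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "kwargs",
    [
        {"l_ci": -0.1},
        {"l_ci": 0.5, "mu": 1.5},
        {"l_ci": 0.5, "F_A": 0.0},
        {"l_ci": 0.5, "F_B": -1.0},
        {"l_ci": 0.5, "tau": 2.0},
        {"l_ci": 0.5, "acquisition": "psychic"},
    ],
)
def test_invalid_params_rejected(kwargs):
    with pytest.raises(ValueError):
        ModelParams(**kwargs)


def test_named_scenarios_expressible():
    p = ModelParams.paternal_transmission()
    assert (p.l_ci, p.tau, p.beta) == (0.98, 0.3, 0.0)
    h = ModelParams.heritable_horizontal()
    assert (h.alpha, h.beta, h.tau) == (1.0, 0.015, 0.0)
    s = ModelParams.somatic_horizontal()
    assert (s.alpha, s.beta) == (0.0, 0.3)
    for params in (p, h, s):
        assert params.mu == 0.0 and params.F_A == params.F_B == 1.0


def test_mating_table_strict_maternal_without_paternal_leak():
    """With tau=0 and mu=0 the incompatible cross yields only maternal-type
    survivors at weight F_A(1 - l_CI)."""
    table = build_mating_table(ModelParams(l_ci=0.98, tau=0.0))
    weight, dist = table.rows[("A1", "B2")]
    assert weight == pytest.approx(1.0 * 0.02)
    assert dist == {"A1": 1.0}


def test_mating_table_paternal_transmission_splits_survivors():
    table = build_mating_table(ModelParams.paternal_transmission())
    weight, dist = table.rows[("A1", "B2")]
    assert weight == pytest.approx(0.02)
    assert dist["B1"] == pytest.approx(0.3)
    assert dist["A1"] == pytest.approx(0.7)


def test_mating_table_rescue_cross_keeps_maternal_haplotype():
    params = ModelParams(l_ci=0.98, mu=0.05, F_B=1.3)
    table = build_mating_table(params)
    weight, dist = table.rows[("B2", "A1")]
    assert weight == pytest.approx(1.3)
    assert dist["B2"] == pytest.approx(0.95)
    assert dist["A2"] == pytest.approx(0.05)


def test_mating_table_offspring_distributions_normalised():
    table = build_mating_table(ModelParams(l_ci=0.7, mu=0.1, tau=0.2))
    for (m, f), (w, dist) in table.rows.items():
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)
        if m.startswith("A") and f.startswith("B"):
            assert w == pytest.approx(0.3)


# ---------------------------------------------------------------------------
# one-generation step
# ---------------------------------------------------------------------------


def test_neutral_dynamics_is_fixed_point():
    params = ModelParams(l_ci=0.0)
    state = CytotypeState(0.3, 0.2, 0.4, 0.1)
    nxt = step(state, params)
    assert np.allclose(nxt.as_array(), state.as_array(), atol=1e-15)


def test_step_matches_reduced_recursion_hand_value():
    """Half A1, half B2 under l_CI=0.98: the aggregate double frequency must
    equal p' = p / (1 - l_CI p(1-p)) = 0.5/0.755 from the reduced recursion."""
    params = ModelParams(**FIG_PARAMS)
    nxt = step(CytotypeState(0.5, 0.0, 0.0, 0.5), params)
    expected = 0.5 / (1.0 - 0.98 * 0.25)
    assert aggregate_double(nxt) == pytest.approx(expected, abs=1e-12)
    assert aggregate_double(nxt) == pytest.approx(0.6622516556291391, abs=1e-12)


def test_somatic_overlay_without_heritable_invader():
    """Pure resident population under somatic acquisition: heritable state
    unchanged, observed double-HT1 equals beta (1-alpha) x_A1."""
    params = ModelParams.somatic_horizontal()
    nxt = step(CytotypeState(1.0, 0.0, 0.0, 0.0), params)
    assert np.allclose(nxt.as_array(), [1.0, 0.0, 0.0, 0.0], atol=1e-15)
    assert nxt.observed_b1 == pytest.approx(0.3)
    assert nxt.observed_b2 == 0.0


def test_step_rejects_unnormalised_state():
    state = CytotypeState(0.5, 0.0, 0.0, 0.5)
    object.__setattr__(state, "x_a1", 0.9)  # corrupt past validation
    with pytest.raises(ValueError):
        step(state, ModelParams(l_ci=0.5))


def test_reproductive_output_stays_positive_in_worst_case():
    """Even with complete CI and complete leakage some crosses remain
    compatible, so the mean reproductive output never hits zero for a valid
    mixed population (the zero-output guard is unreachable from valid
    input)."""
    params = ModelParams(l_ci=1.0, mu=1.0)
    nxt = step(CytotypeState(0.5, 0.0, 0.0, 0.5), params)
    assert abs(nxt.heritable_sum() - 1.0) < 1e-12
    with pytest.raises(ValueError):
        classic_ci_recursion(1.5, l_ci=0.5)


# ---------------------------------------------------------------------------
# classic single-strain recursion (aggregation oracle)
# ---------------------------------------------------------------------------


def test_classic_recursion_absorbing_boundaries():
    assert classic_ci_recursion(0.0, 0.98) == 0.0
    assert classic_ci_recursion(1.0, 0.98, mu=0.0) == pytest.approx(1.0)


def test_classic_recursion_invasion_reaches_fixation():
    """From 1% the invader passes 99% in finitely many generations; the
    count is frozen from brute-force iteration."""
    p, gens = 0.01, 0
    while p < 0.99:
        p = classic_ci_recursion(p, 0.98)
        gens += 1
        assert gens < 1000
    assert gens == 108


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    p=st.floats(0.0, 1.0),
    l_ci=st.floats(0.0, 1.0),
    mu=st.floats(0.0, 0.5),
    F=st.floats(0.2, 3.0),
    scale=st.floats(0.2, 3.0),
)
def test_step_aggregates_to_classic_recursion(p, l_ci, mu, F, scale):
    """With tau=beta=0 the four-cytotype step, aggregated over haplotypes,
    must reproduce the single-strain recursion exactly (haplotypes are then
    neutral labels). F_A/F_B may be scaled jointly without effect."""
    params = ModelParams(l_ci=l_ci, mu=mu, F_A=scale, F_B=scale * F)
    state = CytotypeState(0.7 * (1 - p), 0.3 * (1 - p), 0.4 * p, 0.6 * p)
    assert aggregate_double(step(state, params)) == pytest.approx(
        classic_ci_recursion(p, l_ci, mu, F), abs=1e-12
    )


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    x=st.tuples(*[st.floats(0.001, 1.0)] * 4),
    l_ci=st.floats(0.0, 0.99),
    mu=st.floats(0.0, 0.9),
    tau=st.floats(0.0, 1.0),
    alpha=st.floats(0.0, 1.0),
    beta=st.floats(0.0, 0.9),
)
def test_step_conserves_total_frequency(x, l_ci, mu, tau, alpha, beta):
    total = sum(x)
    state = CytotypeState.from_array([v / total for v in x])
    params = ModelParams(l_ci=l_ci, mu=mu, tau=tau, alpha=alpha, beta=beta)
    nxt = step(state, params)
    assert abs(nxt.heritable_sum() - 1.0) < 1e-12
    observed_total = (
        nxt.observed_b1
        + nxt.observed_b2
        + (nxt.x_a1 + nxt.x_a2) * (1.0 - params.acquisition_rate(nxt.double_freq) * (1.0 - alpha))
    )
    assert observed_total == pytest.approx(1.0, abs=1e-12)


@settings(max_examples=100, deadline=None, derandomize=True)
@given(
    x=st.tuples(*[st.floats(0.01, 1.0)] * 4),
    F=st.floats(0.2, 3.0),
    gens=st.integers(1, 5),
)
def test_neutral_haplotype_frequency_invariant(x, F, gens):
    """With no CI, no paternal/horizontal transfer and equal fecundities,
    total HT1 frequency never changes (haplotypes are neutral)."""
    total = sum(x)
    state = CytotypeState.from_array([v / total for v in x])
    params = ModelParams(l_ci=0.0, F_A=F, F_B=F)
    ht1 = state.ht1_freq
    for _ in range(gens):
        state = step(state, params)
    assert state.ht1_freq == pytest.approx(ht1, abs=1e-12)


@pytest.mark.parametrize("p0", [0.001, 0.01, 0.3, 0.9])
def test_monotone_invasion_to_fixation(p0):
    """With perfect transmission and no fecundity cost, the invading strain's
    frequency is non-decreasing and reaches 1 from any positive start."""
    state = CytotypeState.founder(p0)
    params = ModelParams(**FIG_PARAMS)
    prev = aggregate_double(state)
    for _ in range(2000):
        state = step(state, params)
        cur = aggregate_double(state)
        assert cur >= prev - 1e-15
        prev = cur
    assert prev == pytest.approx(1.0, abs=1e-9)


# ---------------------------------------------------------------------------
# scenarios and mismatch summaries
# ---------------------------------------------------------------------------


def test_neutral_scenario_converges_immediately(founder):
    traj = run_scenario(founder, ModelParams(l_ci=0.0), max_gens=50)
    assert traj.converged and len(traj) == 2
    assert np.allclose(traj.final.as_array(), founder.as_array(), atol=1e-12)


def test_trajectory_requires_state_and_convergence_means_stable(founder):
    with pytest.raises(ValueError):
        Trajectory((), ModelParams(l_ci=0.5), False)
    traj = run_scenario(founder, ModelParams.paternal_transmission(), tol=1e-10)
    assert traj.converged
    delta = np.abs(traj.states[-1].as_array() - traj.states[-2].as_array())
    assert delta.max() < 1e-10


def test_paternal_scenario_permanent_mismatch(founder):
    traj = run_scenario(founder, ModelParams.paternal_transmission())
    assert traj.converged
    assert mismatch_fraction(traj.final, "infected") > 0.10


def test_somatic_scenario_transient_mismatch(founder):
    """Somatic acquisition shows a high transient mismatch that goes extinct
    once the invader fixes: nothing heritable ties it to the resident
    haplotype."""
    traj = run_scenario(founder, ModelParams.somatic_horizontal())
    gen, peak = peak_mismatch(traj, "all")
    assert peak > 0.20
    assert mismatch_fraction(traj.final, "all") < 1e-6
    assert traj.final.double_freq == pytest.approx(1.0, abs=1e-9)


def test_long_run_contrast_between_scenarios(founder, scenario_params):
    """Mismatch persists for paternal and heritable-horizontal transmission
    but vanishes for somatic transmission."""
    finals = {}
    for name, params in scenario_params.items():
        traj = run_scenario(founder, params)
        assert traj.converged
        finals[name] = mismatch_fraction(traj.final, "all")
    assert finals["paternal"] > 0.0
    assert finals["heritable"] > 0.0
    assert finals["somatic"] < 1e-6


def test_frequency_dependent_acquisition_reduces_early_conversion(founder):
    """Under mass-action acquisition the conversion flux scales with invader
    frequency, so far fewer resident-haplotype lineages are captured early
    and the permanent mismatch is much smaller."""
    const = run_scenario(founder, ModelParams.heritable_horizontal())
    freq_dep = run_scenario(
        founder, ModelParams(l_ci=0.98, alpha=1.0, beta=0.015, acquisition="frequency")
    )
    m_const = mismatch_fraction(const.final, "infected")
    m_freq = mismatch_fraction(freq_dep.final, "infected")
    assert m_freq < m_const


def test_mismatch_fraction_denominators():
    state = CytotypeState(0.0, 0.0, 0.2, 0.8)
    assert mismatch_fraction(state, "all") == pytest.approx(0.2)
    assert mismatch_fraction(state, "infected") == pytest.approx(0.2)
    none_infected = CytotypeState(1.0, 0.0, 0.0, 0.0)
    assert mismatch_fraction(none_infected, "all") == 0.0
    assert math.isnan(mismatch_fraction(none_infected, "infected"))
    with pytest.raises(ValueError):
        mismatch_fraction(state, "everyone")


def test_peak_mismatch_ties_and_trivial_cases():
    params = ModelParams(l_ci=0.0)
    flat = run_scenario(CytotypeState(1.0, 0.0, 0.0, 0.0), params, max_gens=5)
    assert peak_mismatch(flat, "all") == (0, 0.0)
    single = Trajectory((CytotypeState(0.0, 0.0, 0.3, 0.7),), params, False)
    gen, val = peak_mismatch(single, "all")
    assert gen == 0 and val == pytest.approx(0.3)


def test_sensitivity_of_final_mismatch_to_founder_frequency():
    """Larger founder frequencies shorten the sweep, leaving less time for
    paternal capture of the resident haplotype."""
    finals = []
    for p0 in (0.001, 0.01, 0.05):
        traj = run_scenario(CytotypeState.founder(p0), ModelParams.paternal_transmission())
        finals.append(mismatch_fraction(traj.final, "infected"))
    assert finals[0] > finals[1] > finals[2] > 0.10
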