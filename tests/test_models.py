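"""Kinetic models: generator construction, catalog topology and constraint
counts, forward likelihood against a path-enumeration oracle."""

import itertools

import numpy as np
import pytest

from smbind.fitting import SegmentedData, segment_loglikelihood, truncate_to_max_bound
from smbind.models import (
    ConstraintSet,
    KineticModel,
    State,
    Transition,
    build_generator_matrix,
    equilibrium_distribution,
    model_catalog,
    transition_matrix,
)

DT = 0.05
CONC = 1e-7  # 100 nM in molar


@pytest.fixture(scope="module")
def catalog():
    return model_catalog()


def random_params(model, constraints, rng):
    """Plausible random rates: non-binding ~ 0.3-3 /s, binding ~ 3e6-3e7 /M/s."""
    free = {}
    binding = model.binding_params()
    for name in constraints.free_names(model):
        free[name] = 10 ** rng.uniform(-0.5, 0.5) * (1e7 if name in binding else 1.0)
    return constraints.resolve(model, free)


def enumeration_loglik(model, params, classes, conc, dt):
    """Independent oracle: sum the path probability over every state sequence
    compatible with the observed classes."""
    Q = build_generator_matrix(model, params, conc)
    A = transition_matrix(Q, dt)
    pi = equilibrium_distribution(Q)
    cmap = list(model.class_map)
    n = model.n_states
    init = np.array([pi[s] if cmap[s] == classes[0] else 0.0 for s in range(n)])
    init /= init.sum()
    total = 0.0
    for path in itertools.product(range(n), repeat=len(classes)):
        if any(cmap[s] != c for s, c in zip(path, classes)):
            continue
        p = init[path[0]]
        for a, b in zip(path[:-1], path[1:]):
            p *= A[a, b]
        total += p
    return np.log(total)


class TestGeneratorMatrix:
    def test_rows_sum_to_zero(self, catalog):
        rng = np.random.default_rng(0)
        for model, constraints in catalog.values():
            Q = build_generator_matrix(model, random_params(model, constraints, rng), CONC)
            assert np.abs(Q.sum(axis=1)).max() < 1e-10

    def test_binding_rate_concentration_scaling(self, catalog):
        # kon = 2e6 /M/s at 100 nM gives an effective rate of 0.2 /s
        model, _ = catalog["M1.A"]
        Q = build_generator_matrix(model, {"kon": 2e6, "koff": 1.6}, 100e-9)
        assert Q[0, 1] == pytest.approx(0.2)

    def test_zero_concentration_kills_binding(self, catalog):
        model, _ = catalog["M1.A"]
        Q = build_generator_matrix(model, {"kon": 2e6, "koff": 1.6}, 0.0)
        assert Q[0, 1] == 0.0 and Q[1, 0] == pytest.approx(1.6)

    def test_unknown_parameter_rejected(self, catalog):
        model, _ = catalog["M1.A"]
        with pytest.raises(KeyError):
            build_generator_matrix(model, {"kon": 1e6}, CONC)


class TestTransitionMatrix:
    def test_zero_dt_identity(self):
        Q = np.array([[-1.0, 1.0], [2.0, -2.0]])
        assert np.allclose(transition_matrix(Q, 0.0), np.eye(2))

    def test_rows_stochastic(self, catalog):
        rng = np.random.default_rng(1)
        for model, constraints in catalog.values():
            Q = build_generator_matrix(model, random_params(model, constraints, rng), CONC)
            A = transition_matrix(Q, DT)
            assert np.abs(A.sum(axis=1) - 1).max() < 1e-10
            assert A.min() >= 0

    def test_two_state_closed_form(self):
        # A(t) for U<->B with rates a, b has the known spectral solution
        a, b, t = 0.2, 1.6, DT
        Q = np.array([[-a, a], [b, -b]])
        lam = a + b
        expected = np.array([
            [b / lam + a / lam * np.exp(-lam * t), a / lam - a / lam * np.exp(-lam * t)],
            [b / lam - b / lam * np.exp(-lam * t), a / lam + b / lam * np.exp(-lam * t)],
        ])
        assert np.abs(transition_matrix(Q, t) - expected).max() < 1e-8


class TestEquilibrium:
    def test_stationarity(self, catalog):
        rng = np.random.default_rng(2)
        for model, constraints in catalog.values():
            Q = build_generator_matrix(model, random_params(model, constraints, rng), CONC)
            pi = equilibrium_distribution(Q)
            assert np.abs(pi @ Q).max() < 1e-10
            assert pi.sum() == pytest.approx(1.0, abs=1e-12)


class TestCatalog:
    # printed free-parameter pattern: M2.F_ii matches M2.A_c (4); M2.C_i,
    # M2.F_ci and M2.F_ic match M2.B (6); cooperative C/D variants 8/10
    EXPECTED_FREE = {
        "M1.A": 2, "M1.B": 4, "M1.C": 4, "M1.D": 6, "M1.E": 6, "M1.F": 8,
        "M2.A_i": 2, "M2.A_c": 4, "M2.B": 6,
        "M2.C_i": 6, "M2.C_c": 8, "M2.D_i": 8, "M2.D_c": 10,
        "M2.E": 6, "M2.F_ii": 4, "M2.F_ci": 6, "M2.F_ic": 6,
    }

    def test_free_parameter_counts(self, catalog):
        for name, k in self.EXPECTED_FREE.items():
            model, constraints = catalog[name]
            assert len(constraints.free_names(model)) == k, name

    def test_all_models_valid(self, catalog):
        for name, (model, constraints) in catalog.items():
            constraints.validate(model)
            assert set(model.class_map) <= {0, 1, 2}

    def test_cooperativity_variants_present(self, catalog):
        for fam in ("C", "D", "E", "F"):
            for tag in ("p10", "p100", "n10", "n100"):
                assert f"M2.{fam}_{tag}" in catalog

    def test_split_cooperativity_equilibrium_factor(self, catalog):
        # kon2 = sqrt(f) kon1, koff2 = koff1/sqrt(f) -> equilibrium factor f
        model, constraints = catalog["M2.C_p10"]
        params = constraints.resolve(model, {
            "kon1": 1e7, "koff1": 2.0, "a1": 1.0, "b1": 1.0, "a2": 1.0, "b2": 1.0})
        ratio = (params["kon2"] / params["koff2"]) / (params["kon1"] / params["koff1"])
        assert ratio == pytest.approx(10.0)

    def test_identical_sites_equal_constrained_cooperative_model(self, catalog):
        # M2.A_i is M2.A_c with the second step tied to the first: the
        # likelihood of any data set must agree exactly
        m_i, c_i = catalog["M2.A_i"]
        m_c, c_c = catalog["M2.A_c"]
        data = SegmentedData(
            [np.array([0, 1, 1, 2, 1, 0], dtype=np.int8)], [CONC], ["m"], DT)
        p_i = c_i.resolve(m_i, {"kon1": 5e6, "koff1": 1.3})
        p_c = {"kon1": 5e6, "koff1": 1.3, "kon2": 5e6, "koff2": 1.3}
        assert segment_loglikelihood(m_i, p_i, data) == pytest.approx(
            segment_loglikelihood(m_c, p_c, data), abs=1e-12)

    def test_mwc_exchange_satisfies_detailed_balance(self, catalog):
        # every 4-cycle R_n<->A_n<->A_{n+1}<->R_{n+1} balances by construction
        model, constraints = catalog["M2.E"]
        rng = np.random.default_rng(3)
        params = random_params(model, constraints, rng)
        Q = build_generator_matrix(model, params, CONC)
        idx = model.state_index
        for n in range(2):
            r0, a0 = idx[f"R{n}"], idx[f"A{n}"]
            r1, a1 = idx[f"R{n+1}"], idx[f"A{n+1}"]
            forward = Q[r0, r1] * Q[r1, a1] * Q[a1, a0] * Q[a0, r0]
            backward = Q[r0, a0] * Q[a0, a1] * Q[a1, r1] * Q[r1, r0]
            assert forward == pytest.approx(backward, rel=1e-9)

    def test_invalid_topologies_rejected(self):
        with pytest.raises(ValueError):
            KineticModel(
                name="bad",
                states=(State("U", 0), State("B", 1)),
                transitions=(Transition("U", "B", "kon", 1.0, 0),),  # missing [L]
            )
        with pytest.raises(ValueError):
            KineticModel(
                name="bad2",
                states=(State("U", 0), State("B", 1)),
                transitions=(Transition("U", "X", "kon", 1.0, 1),),
            )

    def test_tie_referencing_non_free_parameter_rejected(self, catalog):
        model, _ = catalog["M1.A"]
        bad = ConstraintSet(ties={"kon": (1.0, (("missing", 1.0),))})
        with pytest.raises(ValueError):
            bad.validate(model)


class TestForwardLikelihood:
    def test_matches_path_enumeration_for_every_catalog_model(self, catalog):
        rng = np.random.default_rng(4)
        for name, (model, constraints) in catalog.items():
            params = random_params(model, constraints, rng)
            max_class = max(model.class_map)
            length = 8 if model.n_states <= 3 else 6
            classes = rng.integers(0, max_class + 1, size=length).astype(np.int8)
            data = SegmentedData([classes], [CONC], ["m"], DT)
            ll = segment_loglikelihood(model, params, data)
            oracle = enumeration_loglik(model, params, classes, CONC, DT)
            assert ll == pytest.approx(oracle, abs=1e-10), name

    def test_single_frame_segment_contributes_zero(self, catalog):
        model, _ = catalog["M1.A"]
        data = SegmentedData([np.array([1], dtype=np.int8)], [CONC], ["m"], DT)
        ll = segment_loglikelihood(model, {"kon": 2e6, "koff": 1.0}, data)
        assert ll == pytest.approx(0.0, abs=1e-12)

    def test_duplicated_data_doubles_loglik(self, catalog):
        model, _ = catalog["M1.B"]
        params = {"kon": 3e6, "koff": 2.0, "b12": 1.0, "b21": 0.5}
        seg = np.array([0, 0, 1, 1, 1, 0, 1, 0], dtype=np.int8)
        one = SegmentedData([seg], [CONC], ["m"], DT)
        two = SegmentedData([seg, seg], [CONC, CONC], ["m", "m2"], DT)
        assert segment_loglikelihood(model, params, two) == pytest.approx(
            2 * segment_loglikelihood(model, params, one), abs=1e-9)

    def test_observed_class_without_states_rejected(self, catalog):
        model, _ = catalog["M1.A"]  # classes 0/1 only
        data = SegmentedData([np.array([0, 1, 2], dtype=np.int8)], [CONC], ["m"], DT)
        with pytest.raises(ValueError):
            segment_loglikelihood(model, {"kon": 2e6, "koff": 1.0}, data)

    def test_long_run_chunked_recursion_stable(self, catalog):
        # chunked masked powers with renormalization must handle long dwells
        model, _ = catalog["M1.A"]
        seg = np.concatenate([np.zeros(4000), np.ones(50), np.zeros(1000)]).astype(np.int8)
        data = SegmentedData([seg], [CONC], ["m"], DT)
        ll = segment_loglikelihood(model, {"kon": 2e6, "koff": 1.0}, data)
        assert np.isfinite(ll)


class TestTruncation:
    def test_split_on_excess_occupancy(self):
        data = truncate_to_max_bound(
            [np.array([0, 1, 2, 1, 0])], [CONC], 1, DT)
        assert [s.tolist() for s in data.segments] == [[0, 1], [1, 0]]

    def test_no_truncation_single_segment(self):
        data = truncate_to_max_bound([np.array([0, 1, 0, 1])], [CONC], 1, DT)
        assert len(data.segments) == 1

    def test_fully_excluded_molecule_contributes_nothing(self):
        data = truncate_to_max_bound(
            [np.array([3, 3, 3]), np.array([0, 1, 0])], [CONC, CONC], 2, DT)
        assert len(data.segments) == 1
        assert data.molecule_ids == ["mol1"]
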