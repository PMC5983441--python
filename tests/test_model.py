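"""Network construction, Hill kinetics, and the compiled right-hand side."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from agegrn import (Edge, ParameterSet, RegulatoryNetwork, build_ageing_network,
                    compile_network, delete_edges, hill_activation,
                    hill_inhibition, read_network, write_network)
from agegrn.model import ACTIVATION, INHIBITION, AGEING_NODES


# --- literal transcription of the 13 model equations (independent oracle) ---

def literal_rhs(x, S=0.5, n=4, k=1.0, a=1.0, b=0.05, Stress=0.3, GS=0.2):
    p53, Mdm2, Wip1, ATM, p21, PTEN, AKT, Myc, E2F, RB, CycE, CycD, ARF = x
    Sn = S ** n

    def act(z):
        return z ** n / (Sn + z ** n)

    def inh(z):
        return Sn / (Sn + z ** n)

    return np.array([
        a*act(ARF) + a*act(p53) + a*act(ATM) + b*inh(Mdm2) + b*inh(Wip1) - k*p53,
        a*act(p53) + a*act(AKT) + a*act(Wip1) + b*inh(ATM) + b*inh(ARF) - k*Mdm2,
        a*act(p53) - k*Wip1,
        a*act(ATM) + a*act(Stress) + b*inh(Wip1) - k*ATM,
        a*act(p53) + b*inh(AKT) - k*p21,
        a*act(p53) - k*PTEN,
        b*inh(PTEN) - k*AKT,
        a*act(GS) - k*Myc,
        b*inh(p21) + a*act(E2F) + a*act(Myc) + b*inh(RB) - k*E2F,
        a*act(p21) + b*inh(CycD) + b*inh(CycE) - k*RB,
        a*act(E2F) + b*inh(p21) - k*CycE,
        a*act(Myc) + a*act(GS) + b*inh(p21) - k*CycD,
        a*act(Myc) - k*ARF,
    ])


@pytest.mark.parametrize("x,S,n,expected", [
    (0.5, 0.5, 4, 0.5),            # half-saturation at the threshold
    (0.0, 0.5, 4, 0.0),
    (1.0, 0.5, 4, 16 / 17),
])
def test_hill_activation_values(x, S, n, expected):
    assert hill_activation(x, S, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("x,S,n,expected", [
    (0.0, 0.5, 4, 1.0),            # no inhibitor leaves the full basal rate
    (0.5, 0.5, 4, 0.5),
    (1.0, 0.5, 4, 1 / 17),
])
def test_hill_inhibition_values(x, S, n, expected):
    assert hill_inhibition(x, S, n) == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize("fn", [hill_activation, hill_inhibition])
def test_hill_domain_errors(fn):
    with pytest.raises(ValueError):
        fn(-0.1, 0.5, 4)
    with pytest.raises(ValueError):
        fn(0.1, 0.0, 4)
    with pytest.raises(ValueError):
        fn(0.1, 0.5, 0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(x=st.floats(0, 50), S=st.floats(0.01, 5), n=st.integers(1, 8))
def test_hill_complementarity_and_range(x, S, n):
    up, down = hill_activation(x, S, n), hill_inhibition(x, S, n)
    assert up + down == pytest.approx(1.0, abs=1e-12)
    # bounds closed under floating point: x >> S rounds the fraction to 1
    assert 0 <= up <= 1 and 0 <= down <= 1


def test_hill_monotone():
    xs = np.linspace(0, 5, 200)
    assert np.all(np.diff(hill_activation(xs, 0.5, 4)) > 0)
    assert np.all(np.diff(hill_inhibition(xs, 0.5, 4)) < 0)


class TestAgeingNetwork:
    def test_counts(self, ageing):
        assert ageing.n_nodes == 13
        assert len(ageing.edges) == 32
        assert ageing.inputs == ("Stress", "GS")
        assert ageing.nodes == AGEING_NODES

    def test_regulator_sets(self, ageing):
        expect = {
            "p53": ({"ARF", "p53", "ATM"}, {"Mdm2", "Wip1"}),
            "Mdm2": ({"p53", "AKT", "Wip1"}, {"ATM", "ARF"}),
            "Wip1": ({"p53"}, set()),
            "ATM": ({"ATM", "Stress"}, {"Wip1"}),
            "p21": ({"p53"}, {"AKT"}),
            "PTEN": ({"p53"}, set()),
            "AKT": (set(), {"PTEN"}),
            "Myc": ({"GS"}, set()),
            "E2F": ({"E2F", "Myc"}, {"p21", "RB"}),
            "RB": ({"p21"}, {"CycD", "CycE"}),
            "CycE": ({"E2F"}, {"p21"}),
            "CycD": ({"Myc", "GS"}, {"p21"}),
            "ARF": ({"Myc"}, set()),
        }
        for node, (acts, inhs) in expect.items():
            assert set(ageing.regulators(node, ACTIVATION)) == acts, node
            assert set(ageing.regulators(node, INHIBITION)) == inhs, node

    def test_validation(self):
        with pytest.raises(ValueError):
            RegulatoryNetwork(("A",), (Edge("B", "A", ACTIVATION),))
        with pytest.raises(ValueError):
            RegulatoryNetwork(("A", "B"),
                              (Edge("A", "B", ACTIVATION),
                               Edge("A", "B", ACTIVATION)))
        with pytest.raises(ValueError):
            RegulatoryNetwork(("A",), (Edge("A", "A", "modulates"),))


class TestCompiledRhs:
    def test_matches_literal_equations(self, ageing, params, rng):
        """Edge-grouped evaluation reproduces the 13 equations exactly."""
        cn = compile_network(ageing, params)
        for _ in range(100):
            x = rng.uniform(0, 4, 13)
            assert cn.rhs(x) == pytest.approx(literal_rhs(x), abs=1e-12)

    def test_matches_literal_offdefault_parameters(self, ageing, rng):
        p = ParameterSet(S=0.7, n=3, k=0.8, a=1.4, b=0.3,
                         input_levels={"Stress": 0.6, "GS": 0.1})
        cn = compile_network(ageing, p)
        for _ in range(20):
            x = rng.uniform(0, 4, 13)
            ref = literal_rhs(x, S=0.7, n=3, k=0.8, a=1.4, b=0.3,
                              Stress=0.6, GS=0.1)
            assert cn.rhs(x) == pytest.approx(ref, abs=1e-12)

    def test_zero_state_derivatives(self, ageing, params):
        cn = compile_network(ageing, params)
        d = cn.rhs(np.zeros(13))
        assert d[0] == pytest.approx(0.10, abs=1e-12)       # p53: two b terms
        assert d[7] == pytest.approx(0.0016 / 0.0641, rel=1e-6)  # Myc from GS
        assert d[6] == pytest.approx(0.05, abs=1e-12)       # AKT: one b term

    def test_ensemble_rhs_matches_single(self, ageing, params, rng):
        cn = compile_network(ageing, params)
        X = rng.uniform(0, 3, (17, 13))
        batch = cn.rhs(X)
        for i in range(17):
            assert batch[i] == pytest.approx(cn.rhs(X[i]), abs=1e-12)

    def test_forward_invariance(self, ageing, params, rng):
        """A node at zero can only be produced, never pushed negative."""
        cn = compile_network(ageing, params)
        for _ in range(50):
            x = rng.uniform(0, 3, 13)
            i = rng.integers(13)
            x[i] = 0.0
            assert cn.rhs(x)[i] >= 0

    def test_dimension_mismatch(self, ageing, params):
        cn = compile_network(ageing, params)
        with pytest.raises(Exception):
            cn.rhs(np.zeros(12)) + 0  # wrong width must not evaluate cleanly


class TestDeleteEdges:
    def test_p53_inactivation(self, ageing):
        pert = delete_edges(ageing, [("ATM", "p53", ACTIVATION),
                                     ("ARF", "p53", ACTIVATION)])
        assert len(pert.edges) == 30
        assert set(pert.regulators("p53", ACTIVATION)) == {"p53"}
        assert len(ageing.edges) == 32          # original untouched

    def test_empty_deletion_is_identity(self, ageing):
        assert delete_edges(ageing, []) == ageing

    def test_missing_edge_named(self, ageing):
        with pytest.raises(KeyError, match="Wip1->Myc"):
            delete_edges(ageing, [("Wip1", "Myc", ACTIVATION)])


def test_network_roundtrip(tmp_path, ageing):
    path = tmp_path / "net.tsv"
    write_network(ageing, path)
    back = read_network(path)
    assert back == ageing


def test_parameterset_validation():
    with pytest.raises(ValueError):
        ParameterSet(S=0.0)
    with pytest.raises(ValueError):
        ParameterSet(k=0.0)
    with pytest.raises(ValueError):
        ParameterSet(input_levels={"Stress": -0.1, "GS": 0.2})
    per_node = ParameterSet(k={n: 1.0 for n in AGEING_NODES})
    assert per_node.k_vector(AGEING_NODES) == pytest.approx(np.ones(13))
    with pytest.raises(KeyError):
        ParameterSet(k={"p53": 1.0}).k_vector(AGEING_NODES)


def test_steady_states_respect_production_bound(ageing, params):
    """Every attractor level is capped by total production over degradation."""
    from agegrn import find_attractors
    att = find_attractors(ageing, params.with_(a=1.5), n_starts=60, seed=0)
    bound = np.array([
        1.5 * len(ageing.regulators(nd, ACTIVATION))
        + 0.05 * len(ageing.regulators(nd, INHIBITION))
        for nd in ageing.nodes])
    for s in att:
        assert np.all(s.state <= bound + 1e-9)
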