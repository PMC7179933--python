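"""Truth tables, mutual information, Omega, and function classification."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from grnplast.logic import (
    FunctionClass,
    TruthTable,
    class_distribution,
    classify_function,
    complexity_omega,
    enumerate_environments,
    is_linearly_separable,
    mutual_information,
    named_table,
    output_entropy,
    random_function,
)


def all_tables(ne):
    for outs in itertools.product((-1, 1), repeat=2**ne):
        yield TruthTable(ne, np.array(outs, dtype=np.int8))


# ---------------------------------------------------------------------------
# environments
# ---------------------------------------------------------------------------


def test_environment_enumeration_order_and_uniqueness():
    assert enumerate_environments(1).tolist() == [[-1], [1]]
    # bit 0 of the row index is EF_1
    assert enumerate_environments(2).tolist() == [
        [-1, -1], [1, -1], [-1, 1], [1, 1],
    ]
    envs3 = enumerate_environments(3)
    assert envs3.shape == (8, 3)
    assert len({tuple(e) for e in envs3.tolist()}) == 8


def test_environment_bounds():
    with pytest.raises(ValueError):
        enumerate_environments(0)
    with pytest.raises(ValueError):
        enumerate_environments(17)


def test_row_index_inverts_enumeration():
    for ne in (1, 2, 3):
        t = TruthTable.constant(ne, 1)
        for r, env in enumerate(enumerate_environments(ne)):
            assert t.row_index(env) == r


# ---------------------------------------------------------------------------
# mutual information (brute-force joint-histogram oracle)
# ---------------------------------------------------------------------------


def mi_oracle(table, i):
    """Independent joint-histogram computation of I(P, EF_i)."""
    envs = enumerate_environments(table.ne)
    pairs = list(zip(table.outputs.tolist(), envs[:, i].tolist()))
    n = len(pairs)

    def h(counts):
        return -sum(c / n * math.log2(c / n) for c in counts if c)

    joint = {}
    for pr in pairs:
        joint[pr] = joint.get(pr, 0) + 1
    hp = h([sum(v for (o, _), v in joint.items() if o == s) for s in (-1, 1)])
    he = h([sum(v for (_, e), v in joint.items() if e == s) for s in (-1, 1)])
    return hp + he - h(list(joint.values()))


@pytest.mark.parametrize("ne", [1, 2, 3])
def test_mutual_information_matches_histogram_oracle(ne):
    for table in all_tables(ne):
        for i in range(ne):
            assert mutual_information(table, i) == pytest.approx(
                mi_oracle(table, i), abs=1e-12
            )


def test_mutual_information_known_values():
    ident = TruthTable.single_input(2, 0)
    assert mutual_information(ident, 0) == pytest.approx(1.0)
    xor = named_table("XOR")
    assert mutual_information(xor, 0) == pytest.approx(0.0)
    # AND: H(P) = H(1/4) = 0.81128, H(P, EF_1) = 1.5
    andt = named_table("AND")
    assert mutual_information(andt, 0) == pytest.approx(0.31128, abs=1e-5)
    assert output_entropy(andt) == pytest.approx(0.81128, abs=1e-5)


def test_mutual_information_index_validation():
    with pytest.raises(ValueError):
        mutual_information(named_table("AND"), 2)


# ---------------------------------------------------------------------------
# Omega
# ---------------------------------------------------------------------------


def test_omega_landmarks():
    assert complexity_omega(named_table("XOR")).omega == pytest.approx(1.0)
    assert complexity_omega(named_table("XNOR")).omega == pytest.approx(1.0)
    for i in range(2):
        assert complexity_omega(TruthTable.single_input(2, i)).omega == pytest.approx(0.0)
    # 1 - 0.31128/0.81128
    assert complexity_omega(named_table("AND")).omega == pytest.approx(0.61631, abs=1e-5)


def test_omega_constant_policy():
    const = TruthTable.constant(2, 1)
    rep = complexity_omega(const)
    assert not rep.defined and math.isnan(rep.omega)
    rep0 = complexity_omega(const, constant_policy="zero")
    assert not rep0.defined and rep0.omega == 0.0
    with pytest.raises(ValueError):
        complexity_omega(const, constant_policy="bogus")


@pytest.mark.parametrize("ne", [2, 3])
def test_omega_bounds_and_symmetries(ne):
    """Omega is in [0,1] and invariant to output negation and input relabeling."""
    perm = list(range(ne))[::-1]
    for table in all_tables(ne):
        rep = complexity_omega(table)
        if not rep.defined:
            continue
        assert 0.0 <= rep.omega <= 1.0
        assert complexity_omega(table.negate()).omega == pytest.approx(rep.omega)
        assert complexity_omega(table.permute_inputs(perm)).omega == pytest.approx(
            rep.omega
        )


# ---------------------------------------------------------------------------
# separability and classes
# ---------------------------------------------------------------------------


def lp_separable(table):
    """LP feasibility oracle: exists (w, b) with y (w.x + b) >= 1."""
    from scipy.optimize import linprog

    envs = enumerate_environments(table.ne).astype(float)
    x = np.hstack([envs, np.ones((envs.shape[0], 1))])
    a_ub = -table.outputs[:, None] * x
    b_ub = -np.ones(x.shape[0])
    res = linprog(
        c=np.zeros(x.shape[1]),
        A_ub=a_ub,
        b_ub=b_ub,
        bounds=[(None, None)] * x.shape[1],
        method="highs",
    )
    return res.status == 0


@pytest.mark.parametrize("ne", [1, 2, 3])
def test_separability_perceptron_enumeration_and_lp_agree(ne):
    for table in all_tables(ne):
        lp = lp_separable(table)
        assert is_linearly_separable(table, method="enumeration") == lp
        assert is_linearly_separable(table, method="perceptron") == lp


def test_classification_landmarks():
    assert classify_function(TruthTable.constant(2, 1)) is FunctionClass.NON_PLASTIC
    assert classify_function(TruthTable.single_input(3, 1, negated=True)) is (
        FunctionClass.SINGLE_INPUT
    )
    assert classify_function(named_table("AND")) is FunctionClass.LINEAR_OTHER
    assert classify_function(named_table("XOR")) is FunctionClass.NON_LINEAR
    assert classify_function(named_table("XNOR")) is FunctionClass.NON_LINEAR


def test_class_distribution_small_ne():
    d1 = class_distribution(1)
    assert d1[FunctionClass.NON_PLASTIC] == pytest.approx(2 / 4)
    assert d1[FunctionClass.SINGLE_INPUT] == pytest.approx(2 / 4)
    assert d1[FunctionClass.NON_LINEAR] == 0.0
    d2 = class_distribution(2)
    counts = {fc: round(v * 16) for fc, v in d2.items()}
    assert counts == {
        FunctionClass.NON_PLASTIC: 2,
        FunctionClass.SINGLE_INPUT: 4,
        FunctionClass.LINEAR_OTHER: 8,
        FunctionClass.NON_LINEAR: 2,
    }
    assert sum(d2.values()) == pytest.approx(1.0)
    # ne=3: 104 threshold functions in total
    d3 = class_distribution(3)
    assert round(sum(d3[fc] for fc in (
        FunctionClass.NON_PLASTIC, FunctionClass.SINGLE_INPUT,
        FunctionClass.LINEAR_OTHER)) * 256) == 104
    with pytest.raises(ValueError):
        class_distribution(5)


# ---------------------------------------------------------------------------
# sampling
# ---------------------------------------------------------------------------


def test_random_function_class_constraint(rng):
    xor, xnor = named_table("XOR"), named_table("XNOR")
    for _ in range(10):
        t = random_function(2, FunctionClass.NON_LINEAR, rng)
        assert t == xor or t == xnor


def test_random_function_omega_constraints(rng):
    singles = {
        tuple(TruthTable.single_input(2, i, neg).outputs.tolist())
        for i in range(2)
        for neg in (False, True)
    }
    for _ in range(10):
        t = random_function(2, 0.0, rng)
        assert tuple(t.outputs.tolist()) in singles
    t = random_function(2, (0.5, 1.0), rng)
    assert 0.5 <= complexity_omega(t).omega <= 1.0
    with pytest.raises(ValueError):
        random_function(2, 0.123456, rng)


def test_random_function_is_seed_deterministic():
    a = random_function(3, FunctionClass.NON_LINEAR, np.random.default_rng(7))
    b = random_function(3, FunctionClass.NON_LINEAR, np.random.default_rng(7))
    assert a == b


def test_random_function_rejection_path_above_exhaustive_ne():
    # non-separable functions dominate at ne = 5, so rejection is quick
    t = random_function(5, FunctionClass.NON_LINEAR, np.random.default_rng(1))
    assert classify_function(t, method="perceptron") is FunctionClass.NON_LINEAR


# ---------------------------------------------------------------------------
# table container invariants
# ---------------------------------------------------------------------------


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    ne=st.integers(1, 3),
    data=st.data(),
)
def test_table_roundtrip_properties(ne, data):
    outs = data.draw(
        st.lists(st.sampled_from([-1, 1]), min_size=2**ne, max_size=2**ne)
    )
    t = TruthTable(ne, np.array(outs, dtype=np.int8))
    assert t.negate().negate() == t
    perm = data.draw(st.permutations(list(range(ne))))
    inverse = [perm.index(i) for i in range(ne)]
    assert t.permute_inputs(perm).permute_inputs(inverse) == t


def test_table_validation():
    with pytest.raises(ValueError):
        TruthTable(2, np.array([1, -1, 1]))
    with pytest.raises(ValueError):
        TruthTable(2, np.array([1, -1, 0, 1]))
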