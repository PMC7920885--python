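"""Joint-entropy estimator: analytic limits, oracle equivalence, invariants."""

import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from handmotion.entropy import (
    BinningSpec,
    EmptyInputError,
    default_binning,
    joint_entropy,
    marginal_entropy,
    operator_entropy,
)
from handmotion.kinematics import compute_kinematics


def enumeration_oracle(ix, iy):
    """Independent brute-force entropy over occupied cells."""
    c = Counter(zip(ix.tolist(), iy.tolist()))
    n = len(ix)
    return -sum((k / n) * math.log2(k / n) for k in c.values())


def oracle_digitize(x, edges):
    """Bin assignment by explicit per-sample scan (independent of searchsorted)."""
    out = []
    for v in x:
        i = 0
        for j in range(len(edges) - 1):
            if v >= edges[j]:
                i = j
        out.append(i)
    return np.array(out)


def test_constant_signals_have_zero_entropy():
    h = joint_entropy(np.full(50, 3.7), np.full(50, -1.2), BinningSpec("speed", n_bins=8))
    assert h == 0.0


def test_four_distinct_cells_give_exactly_two_bits():
    b = BinningSpec("speed", edges=[0.0, 1.0, 2.0])
    x = np.array([0.5, 0.5, 1.5, 1.5])
    y = np.array([0.5, 1.5, 0.5, 1.5])
    assert joint_entropy(x, y, b) == 2.0


@pytest.mark.parametrize("k", [2, 4, 8, 16])
def test_one_sample_per_diagonal_cell_gives_log2_k_exactly(k):
    b = BinningSpec("speed", edges=np.arange(k + 1, dtype=float))
    x = np.arange(k) + 0.5
    assert joint_entropy(x, x, b) == math.log2(k)


def test_uniform_pairs_on_4x4_bins_approach_4_bits():
    rng = np.random.default_rng(42)
    x, y = rng.random(10_000), rng.random(10_000)
    b = BinningSpec("speed", edges=np.linspace(0, 1, 5))
    assert abs(joint_entropy(x, y, b) - 4.0) < 0.02


@given(st.integers(0, 2**31 - 1))
def test_matches_enumeration_oracle_on_small_samples(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 101))
    x = rng.normal(0, rng.uniform(0.5, 20), n)
    y = rng.normal(0, rng.uniform(0.5, 20), n)
    spec = BinningSpec("speed", n_bins=int(rng.integers(2, 40)))
    h, n_used, edges = joint_entropy(x, y, spec, return_details=True)
    assert n_used == n
    expected = enumeration_oracle(
        oracle_digitize(np.clip(x, edges[0], None), edges),
        oracle_digitize(np.clip(y, edges[0], None), edges),
    )
    assert abs(h - expected) <= 1e-12


@given(st.integers(0, 2**31 - 1))
def test_bounds_and_subadditivity(seed):
    """0 <= H(X,Y) <= log2(n_bins^2) and H(X,Y) <= H(X) + H(Y) for the
    empirical distribution on shared edges."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 400))
    x = rng.normal(0, 3, n)
    y = 0.5 * x + rng.normal(0, 1, n)
    spec = BinningSpec("speed", n_bins=int(rng.integers(2, 33)))
    h, _, edges = joint_entropy(x, y, spec, return_details=True)
    assert 0.0 <= h <= 2 * math.log2(spec.n_bins) + 1e-12
    hx = marginal_entropy(x, spec, edges)
    hy = marginal_entropy(y, spec, edges)
    assert h <= hx + hy + 1e-12


@given(st.integers(0, 2**31 - 1))
def test_joint_permutation_invariance(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 200))
    x, y = rng.normal(size=n), rng.normal(size=n)
    perm = rng.permutation(n)
    spec = BinningSpec("speed", n_bins=8)
    assert joint_entropy(x, y, spec) == joint_entropy(x[perm], y[perm], spec)


def test_identical_series_collapse_to_marginal():
    rng = np.random.default_rng(3)
    x = rng.normal(size=500)
    spec = BinningSpec("speed", n_bins=16)
    h, _, edges = joint_entropy(x, x, spec, return_details=True)
    assert h == pytest.approx(marginal_entropy(x, spec, edges), abs=1e-12)


def test_nonfinite_pairs_are_dropped_pairwise():
    x = np.array([1.0, np.nan, 2.0, 3.0])
    y = np.array([1.0, 1.0, np.nan, 3.0])
    h, n, _ = joint_entropy(x, y, BinningSpec("speed", n_bins=4), return_details=True)
    assert n == 2


def test_error_cases():
    spec = BinningSpec("speed", n_bins=4)
    with pytest.raises(ValueError):
        joint_entropy(np.ones(3), np.ones(4), spec)
    with pytest.raises(EmptyInputError):
        joint_entropy(np.array([np.nan]), np.array([1.0]), spec)
    with pytest.raises(ValueError):
        BinningSpec("speed", n_bins=1)
    with pytest.raises(ValueError):
        BinningSpec("speed", edges=[0.0, 1.0, 0.5])


def test_direction_default_bins_span_0_to_180():
    b = default_binning("direction")
    assert b.n_bins == 8
    edges = b.resolve_edges(np.array([30.0, 90.0]))
    np.testing.assert_allclose(edges, np.linspace(0, 180, 9))
    # 22.5-degree bins
    np.testing.assert_allclose(np.diff(edges), 22.5)


def _series_from_positions(pos):
    return compute_kinematics(np.asarray(pos, float))


def test_operator_entropy_identical_hands_equals_marginal():
    rng = np.random.default_rng(11)
    pos = np.cumsum(rng.normal(0, 10, (300, 2)), axis=0)
    s = _series_from_positions(pos)
    trip = operator_entropy(s, s)
    assert trip.defined
    spec = default_binning("speed")
    x = s.speed[s.speed_valid]
    h, _, edges = joint_entropy(x, x, spec, return_details=True)
    assert trip.speed.bits == pytest.approx(h, abs=1e-12)
    assert trip.speed.bits == pytest.approx(marginal_entropy(x, spec, edges), abs=1e-12)


def test_operator_entropy_undefined_when_one_hand_missing():
    rng = np.random.default_rng(1)
    pos = np.cumsum(rng.normal(0, 10, (50, 2)), axis=0)
    good = _series_from_positions(pos)
    bad = _series_from_positions(np.full((50, 2), np.nan))
    trip = operator_entropy(good, bad)
    assert not trip.defined
    assert trip.speed.bits is None
    assert "undefined" in trip.speed.status
    with pytest.raises(ValueError):
        operator_entropy(good, _series_from_positions(pos[:20]))


def test_operator_entropy_records_binning_provenance():
    rng = np.random.default_rng(5)
    dom = _series_from_positions(np.cumsum(rng.normal(0, 8, (200, 2)), axis=0))
    nondom = _series_from_positions(np.cumsum(rng.normal(0, 8, (200, 2)), axis=0))
    trip = operator_entropy(dom, nondom)
    for feat in ("speed", "acceleration", "direction"):
        fe = trip[feat]
        assert fe.n_samples > 0
        assert fe.edges is not None and len(fe.edges) >= 3
        assert 0.0 <= fe.bits <= 2 * math.log2(len(fe.edges) - 1)
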