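"""Agreement statistics against independently coded brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nwu_kit import InputError, VoxelMask, bland_altman, dice, icc_2_1


# ---------------------------------------------------------------- oracles
def brute_force_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Direct voxel counting, no set algebra shared with the implementation."""
    inter = 0
    na = nb = 0
    for va, vb in zip(a.ravel().tolist(), b.ravel().tolist()):
        na += va != 0
        nb += vb != 0
        inter += (va != 0) and (vb != 0)
    return 1.0 if (na + nb) == 0 else 2.0 * inter / (na + nb)


def brute_force_icc21(x: np.ndarray, y: np.ndarray) -> float:
    """ICC(2,1) from explicitly accumulated two-way ANOVA sums of squares."""
    n, k = len(x), 2
    table = [[float(x[i]), float(y[i])] for i in range(n)]
    grand = sum(sum(row) for row in table) / (n * k)
    ss_rows = sum(k * (sum(row) / k - grand) ** 2 for row in table)
    col_means = [sum(table[i][j] for i in range(n)) / n for j in range(k)]
    ss_cols = sum(n * (m - grand) ** 2 for m in col_means)
    ss_tot = sum((v - grand) ** 2 for row in table for v in row)
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def brute_force_bland_altman(x, y):
    d = [float(a) - float(b) for a, b in zip(x, y)]
    n = len(d)
    bias = sum(d) / n
    sd = (sum((v - bias) ** 2 for v in d) / (n - 1)) ** 0.5
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


# ------------------------------------------------------------------- dice
def _mask(arr):
    return VoxelMask(np.asarray(arr, dtype=np.uint8), (1.0, 1.0, 1.0))


def test_dice_examples():
    a = np.zeros((4, 4, 4)); a[:2] = 1
    assert dice(_mask(a), _mask(a)) == 1.0
    b = np.zeros((4, 4, 4)); b[2:] = 1
    assert dice(_mask(a), _mask(b)) == 0.0
    a8 = np.zeros((4, 4, 4)); a8.ravel()[:8] = 1
    b8 = np.zeros((4, 4, 4)); b8.ravel()[2:10] = 1
    assert dice(_mask(a8), _mask(b8)) == pytest.approx(0.75)
    assert dice(_mask(np.zeros((4, 4, 4))), _mask(np.zeros((4, 4, 4)))) == 1.0


def test_dice_grid_mismatch_rejected():
    a = _mask(np.ones((4, 4, 4)))
    b = VoxelMask(np.ones((4, 4, 4), np.uint8), (2.0, 2.0, 2.0))
    with pytest.raises(InputError):
        dice(a, b)


def test_dice_matches_brute_force_on_random_masks(rng):
    for _ in range(100):
        a = rng.random((5, 5, 3)) > rng.uniform(0.2, 0.9)
        b = rng.random((5, 5, 3)) > rng.uniform(0.2, 0.9)
        assert dice(_mask(a), _mask(b)) == pytest.approx(
            brute_force_dice(a, b), abs=1e-9
        )


@given(st.integers(0, 2**30))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_dice_symmetric_and_bounded(seed):
    r = np.random.default_rng(seed)
    a = _mask(r.random((4, 4, 2)) > 0.5)
    b = _mask(r.random((4, 4, 2)) > 0.5)
    d = dice(a, b)
    assert d == dice(b, a)
    assert 0.0 <= d <= 1.0


# -------------------------------------------------------------------- icc
def test_icc_perfect_agreement():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert icc_2_1(x, x.copy()).icc == pytest.approx(1.0)


def test_icc_anticorrelated_matches_oracle():
    x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
    y = -x
    assert icc_2_1(x, y).icc == pytest.approx(brute_force_icc21(x, y), abs=1e-9)
    assert icc_2_1(x, y).icc < 0


def test_icc_worked_example_matches_oracle():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    y = np.array([1.1, 2.0, 3.2, 3.9, 5.1])
    st_ = icc_2_1(x, y)
    assert st_.icc == pytest.approx(brute_force_icc21(x, y), abs=1e-9)
    assert st_.icc_ci[0] <= st_.icc <= st_.icc_ci[1]


def test_icc_matches_pingouin():
    import pandas as pd
    import pingouin as pg

    rng = np.random.default_rng(3)
    x = rng.normal(10, 3, 12)
    y = x + rng.normal(0.5, 1.0, 12)
    mine = icc_2_1(x, y)
    df = pd.DataFrame({
        "targets": list(range(12)) * 2,
        "raters": ["a"] * 12 + ["b"] * 12,
        "score": np.r_[x, y],
    })
    ref = pg.intraclass_corr(df, "targets", "raters", "score")
    ref_row = ref[ref["Type"] == "ICC(A,1)"].iloc[0]
    assert mine.icc == pytest.approx(float(ref_row["ICC"]), abs=1e-9)
    np.testing.assert_allclose(mine.icc_ci, ref_row["CI95"], atol=0.01)


def test_icc_matches_brute_force_on_random_inputs(rng):
    for _ in range(100):
        n = int(rng.integers(3, 15))
        x = rng.normal(0, rng.uniform(0.5, 5), n)
        y = x * rng.uniform(0.5, 1.5) + rng.normal(0, 1, n)
        assert icc_2_1(x, y).icc == pytest.approx(
            brute_force_icc21(x, y), abs=1e-9
        )


def test_icc_absolute_agreement_penalizes_offset(rng):
    x = rng.normal(0, 2, 20)
    y = x + rng.normal(0, 0.1, 20)
    assert icc_2_1(x, y + 3.0).icc < icc_2_1(x, y).icc


def test_icc_degenerate_inputs_rejected():
    with pytest.raises(InputError):
        icc_2_1(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
    with pytest.raises(InputError):
        icc_2_1(np.full(5, 3.0), np.full(5, 3.0))


# ----------------------------------------------------------- bland-altman
def test_bland_altman_examples():
    x = np.array([1.0, 2.0, 3.0])
    st_ = bland_altman(x, x.copy())
    assert (st_.bias, st_.loa_low, st_.loa_high) == (0.0, 0.0, 0.0)
    st2 = bland_altman(np.array([1.0, 2.0, 3.0]), np.zeros(3))
    assert st2.bias == pytest.approx(2.0)
    assert st2.loa_low == pytest.approx(2.0 - 1.96)
    assert st2.loa_high == pytest.approx(2.0 + 1.96)


def test_bland_altman_antisymmetric(rng):
    x = rng.normal(10, 2, 15)
    y = rng.normal(9, 2, 15)
    a = bland_altman(x, y)
    b = bland_altman(y, x)
    assert a.bias == pytest.approx(-b.bias)
    assert a.loa_low == pytest.approx(-b.loa_high)
    assert a.loa_high == pytest.approx(-b.loa_low)


def test_bland_altman_matches_brute_force(rng):
    for _ in range(100):
        n = int(rng.integers(2, 25))
        x = rng.normal(0, 3, n)
        y = rng.normal(0, 3, n)
        got = bland_altman(x, y)
        bias, lo, hi = brute_force_bland_altman(x, y)
        assert got.bias == pytest.approx(bias, abs=1e-9)
        assert got.loa_low == pytest.approx(lo, abs=1e-9)
        assert got.loa_high == pytest.approx(hi, abs=1e-9)


@given(st.integers(0, 2**30))
@settings(max_examples=25, deadline=None, derandomize=True)
def test_bland_altman_loa_identity(seed):
    r = np.random.default_rng(seed)
    x = r.normal(0, 5, int(r.integers(2, 30)))
    y = r.normal(0, 5, x.size)
    s = bland_altman(x, y)
    sd = (x - y).std(ddof=1)
    assert s.loa_low == pytest.approx(s.bias - 1.96 * sd, abs=1e-9)
    assert s.loa_high == pytest.approx(s.bias + 1.96 * sd, abs=1e-9)
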