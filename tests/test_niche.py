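"""Niche evaluation: index-matrix assembly, standardization, CV weights,
adjusted values, widths, overlaps — spec'd hand examples, a brute-force
oracle, and conservation/monotonicity properties."""

import numpy as np
import pandas as pd
import pytest

from pandaniche import core


# ----- fixtures -----------------------------------------------------------

def _tiny_inputs():
    communities = pd.DataFrame({
        "community_id": ["C01", "C02"],
        "reserve_id": ["R1", "R1"],
        "inside_reserve": [1, 0],
        "AACL_2013": [60.0, 90.0], "AACL_2018": [55.0, 80.0],
        "TACL_2013": [100.0, 150.0], "TACL_2018": [100.0, 150.0],
        "AAFL_2013": [200.0, 300.0], "AAFL_2018": [190.0, 280.0],
        "TAFL_2013": [800.0, 900.0], "TAFL_2018": [820.0, 910.0],
        "LFQH_2013": [200, 300], "LFQH_2018": [180, 280],
        "TPR_2013": [500, 700], "TPR_2018": [490, 690],
        "x8_2013": [0.2, 0.3], "x8_2018": [0.3, 0.4],
        "x9_2013": [0.1, 0.2], "x9_2018": [0.1, 0.2],
        "x10_2013": [0.4, 0.1], "x10_2018": [0.5, 0.3],
    })
    panda = pd.DataFrame({
        "reserve_id": ["R1"], "AGPH3rd": [100.0], "AGPH4th": [120.0],
        "PGPH3rd": [10], "PGPH4th": [12], "ASFB": [50.0], "ANR": [200.0],
    })
    cd = pd.DataFrame({
        "community_id": ["C01", "C02", "C01", "C02"],
        "age_group": ["OAG", "OAG", "YAG", "YAG"],
        "n_households": [3, 3, 5, 5],
        "x1_state": [0.10, 0.30, 0.20, 0.40],
        "x1_potential": [-0.02, -0.05, -0.01, -0.04],
        "x2_state": [0.05, 0.20, 0.15, 0.35],
        "x2_potential": [-0.01, -0.02, -0.01, -0.03],
    })
    households = pd.DataFrame({
        "community_id": ["C01", "C01", "C02", "C02"],
        "perception_planting_regulation": [3, 5, 2, 4],
        "perception_fuelwood_regulation": [4, 4, 3, 5],
    })
    return cd, communities, panda, households


# ----- index matrix -------------------------------------------------------

def test_index_matrix_formulas():
    cd, communities, panda, households = _tiny_inputs()
    m = core.build_index_matrix(cd, communities, panda, households)
    s = m.state.loc[("C01", "OAG")]
    assert s["x11"] == pytest.approx(0.2)      # (120 - 100) / 100
    assert s["x13"] == pytest.approx(0.25)     # 50 / 200
    assert s["x12"] == pytest.approx(0.2)      # (12 - 10) / 10
    assert s["x14"] == pytest.approx(50.0 / 12.0)
    assert s["x3"] == pytest.approx(0.6)       # 60 / 100
    assert s["x6"] == pytest.approx(4.0)       # mean perception in C01
    # x9 has identical 2013/2018 values: zero increment
    assert m.potential.loc[("C01", "OAG"), "x9"] == pytest.approx(0.0)
    assert m.potential.loc[("C01", "OAG"), "x8"] == pytest.approx(0.1)
    # cross-sectional indexes carry no potential
    assert (m.potential[["x6", "x7", "x11", "x12", "x13", "x14"]]
            == 0).all().all()


def test_index_matrix_zero_denominator_is_named_error():
    cd, communities, panda, households = _tiny_inputs()
    panda.loc[0, "AGPH3rd"] = 0.0
    with pytest.raises(core.DataError, match="AGPH3rd"):
        core.build_index_matrix(cd, communities, panda, households)
    cd2, communities2, panda2, hh2 = _tiny_inputs()
    communities2.loc[0, "TACL_2013"] = 0.0
    with pytest.raises(core.DataError, match="TACL"):
        core.build_index_matrix(cd2, communities2, panda2, hh2)


def test_index_matrix_drops_memberless_groups():
    cd, communities, panda, households = _tiny_inputs()
    cd.loc[cd.index[-1], ["x1_state", "x2_state"]] = np.nan
    m = core.build_index_matrix(cd, communities, panda, households)
    assert len(m.state) == 3


# ----- standardization and weights ---------------------------------------

def test_zscore_hand_example():
    df = pd.DataFrame({"a": [2.0, 4.0, 6.0], "b": [1.0, 2.0, 4.0]})
    z = core.standardize(df)
    assert z["a"].to_numpy() == pytest.approx([-1.0, 0.0, 1.0])
    assert abs(z.mean()).max() < 1e-12
    assert z.std(ddof=1).to_numpy() == pytest.approx([1.0, 1.0])


def test_zscore_degenerate_column_rejected():
    with pytest.raises(core.DegenerateColumnError, match="a"):
        core.standardize(pd.DataFrame({"a": [1.0, 1.0, 1.0],
                                       "b": [1.0, 2.0, 3.0]}))
    with pytest.raises(core.DataError):
        core.standardize(pd.DataFrame({"a": [1.0]}))


def test_cv_weights_hand_example():
    # columns engineered to CVs 0.2 and 0.3 -> weights 0.4 / 0.6
    df = pd.DataFrame({"a": [0.8, 1.0, 1.2], "b": [0.7, 1.0, 1.3]})
    df["a"] = 1.0 + (df["a"] - 1.0) * (0.2 / df["a"].std(ddof=1))
    df["b"] = 1.0 + (df["b"] - 1.0) * (0.3 / df["b"].std(ddof=1))
    w = core.compute_weights(df, {"D1": ("a",), "D2": ("b",)})
    assert w.V.to_numpy() == pytest.approx([0.2, 0.3])
    assert w.W.to_numpy() == pytest.approx([0.4, 0.6])
    assert w.w_d.sum() == pytest.approx(1.0)


def test_cv_weights_single_and_symmetric():
    single = core.compute_weights(pd.DataFrame({"a": [1.0, 2.0, 3.0]}),
                                  {"D": ("a",)})
    assert single.W.to_numpy() == pytest.approx([1.0])
    sym = core.compute_weights(
        pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [2.0, 4.0, 6.0]}),
        {"D": ("a", "b")})
    assert sym.W.to_numpy() == pytest.approx([0.5, 0.5])


def test_cv_weights_zero_mean_rejected():
    with pytest.raises(core.DataError, match="weight undefined"):
        core.compute_weights(pd.DataFrame({"a": [-1.0, 0.0, 1.0]}),
                             {"D": ("a",)})


# ----- adjusted values ----------------------------------------------------

def _matrix_from(state, potential):
    return core.IndexMatrix(state=state, potential=potential)


def _full_matrix(rng, n=6):
    idx = pd.MultiIndex.from_product(
        [[f"C{i}" for i in range(n)], ["OAG"]],
        names=["community_id", "age_group"])
    state = pd.DataFrame(rng.uniform(0.1, 1.0, (n, 14)), index=idx,
                         columns=list(core.INDEX_COLUMNS))
    pot = pd.DataFrame(rng.uniform(-0.1, 0.1, (n, 14)), index=idx,
                       columns=list(core.INDEX_COLUMNS))
    return _matrix_from(state, pot)


def test_adjusted_value_formula_and_limits():
    rng = np.random.default_rng(0)
    m = _full_matrix(rng)
    m.state.iloc[0, 2] = 0.4
    m.potential.iloc[0, 2] = 0.1
    raw, scaled = core.adjusted_values(m, A=1.0, period_years=5)
    assert raw.iloc[0, 2] == pytest.approx(0.4 + 0.1 / 5)
    assert (scaled > 0).all().all() and (scaled <= 1).all().all()
    raw0, _ = core.adjusted_values(m, A=0.0)
    pd.testing.assert_frame_equal(raw0, m.state)   # potential ignored


def test_rescaling_preserves_order_and_inverts_cost_indexes():
    rng = np.random.default_rng(1)
    m = _full_matrix(rng)
    m.potential.iloc[:, :] = 0.0
    _, hab = core.adjusted_values(m, orientation="habitat")
    _, util = core.adjusted_values(m, orientation="utilization")
    for col in core.INDEX_COLUMNS:
        order = np.argsort(m.state[col].to_numpy())
        if core.INDEX_DIRECTIONS[col] < 0:
            assert np.array_equal(np.argsort(hab[col].to_numpy()),
                                  order[::-1])
        else:
            assert np.array_equal(np.argsort(hab[col].to_numpy()), order)
        assert np.array_equal(np.argsort(util[col].to_numpy()), order)


def test_constant_adjusted_column_errors_or_neutralizes():
    rng = np.random.default_rng(2)
    m = _full_matrix(rng)
    m.state["x5"] = 0.7
    m.potential["x5"] = 0.0
    with pytest.raises(core.DegenerateColumnError, match="x5"):
        core.adjusted_values(m)
    with pytest.warns(UserWarning, match="x5"):
        _, scaled = core.adjusted_values(m, on_constant="neutral")
    assert (scaled["x5"] == 1.0).all()


# ----- widths and overlaps: hand examples and oracle ----------------------

def test_width_share_hand_examples():
    scaled = pd.DataFrame({"x1": [1.0, 1.0, 2.0]},
                          index=["C1", "C2", "C3"])
    w = core.IndexWeights(V=pd.Series({"x1": 0.5}),
                          W=pd.Series({"x1": 1.0}),
                          w_d=pd.Series({"X1": 1.0}))
    n = core.relative_niche_width(scaled, w, "X1",
                                  dimensions={"X1": ("x1",)})
    assert n.to_numpy() == pytest.approx([0.25, 0.25, 0.5])
    # single community occupies the whole dimension
    n1 = core.relative_niche_width(scaled.iloc[[2]], w, "X1",
                                   dimensions={"X1": ("x1",)})
    assert n1.to_numpy() == pytest.approx([1.0])


def test_comprehensive_width_dot_product():
    widths = pd.DataFrame({"N_X1": [0.1], "N_X2": [0.2], "N_X3": [0.3],
                           "N_X4": [0.4]})
    w = core.IndexWeights(V=pd.Series(dtype=float), W=pd.Series(dtype=float),
                          w_d=pd.Series({"X1": 0.25, "X2": 0.25,
                                         "X3": 0.25, "X4": 0.25}))
    assert core.comprehensive_niche(widths, w).iloc[0] \
        == pytest.approx(0.25)
    with pytest.raises(core.DataError):
        core.comprehensive_niche(widths.drop(columns="N_X2"), w)


def test_overlap_hand_examples():
    assert core.pianka_overlap([0.3, 0.7], [0.3, 0.7]) \
        == pytest.approx(1.0)
    assert core.pianka_overlap([1, 0], [0, 1]) == pytest.approx(0.0)
    assert core.pianka_overlap([1, 0], [0.5, 0.5]) \
        == pytest.approx(np.sqrt(0.5), abs=1e-4)
    assert np.isnan(core.pianka_overlap([0, 0], [1, 1]))


def test_overlap_ratio_classification():
    assert core.overlap_ratio(0.4, 0.5) == (pytest.approx(0.8), "positive")
    assert core.overlap_ratio(0.6, 0.4) == (pytest.approx(1.5), "negative")
    ratio, cls = core.overlap_ratio(0.5, 0.5)
    assert ratio == pytest.approx(1.0) and cls == "undefined"
    ratio, cls = core.overlap_ratio(0.5, 0.0)
    assert np.isnan(ratio) and cls == "undefined"


def brute_force_widths_and_overlaps(raw, dims):
    """Independent oracle with explicit loops: CV weights, per-index
    shares, dimension widths, comprehensive widths, pairwise cosine
    overlaps."""
    rows = list(raw.index)
    cols = list(raw.columns)
    cv = {}
    for c in cols:
        vals = [raw.loc[r, c] for r in rows]
        mean = sum(vals) / len(vals)
        var = sum((v - mean) ** 2 for v in vals) / (len(vals) - 1)
        cv[c] = var ** 0.5 / abs(mean)
    wsum = sum(cv.values())
    W = {c: cv[c] / wsum for c in cols}
    wd = {d: sum(W[c] for c in members) for d, members in dims.items()}
    shares = {}
    for c in cols:
        tot = sum(raw.loc[r, c] for r in rows)
        for r in rows:
            shares[(r, c)] = raw.loc[r, c] / tot
    N = {}
    for d, members in dims.items():
        for r in rows:
            N[(r, d)] = sum((W[c] / wd[d]) * shares[(r, c)]
                            for c in members)
    M = {r: sum(N[(r, d)] * wd[d] for d in dims) for r in rows}
    O = {}
    for i, rj in enumerate(rows):
        for rk in rows[i + 1:]:
            pj = [raw.loc[rj, c] for c in cols]
            pk = [raw.loc[rk, c] for c in cols]
            pj = [v / sum(pj) for v in pj]
            pk = [v / sum(pk) for v in pk]
            num = sum(a * b for a, b in zip(pj, pk))
            den = (sum(a * a for a in pj) * sum(b * b for b in pk)) ** 0.5
            O[(rj, rk)] = num / den
    return W, wd, N, M, O


def test_widths_and_overlaps_match_brute_force_oracle(toy_adjusted):
    raw, dims = toy_adjusted
    W, wd, N, M, O = brute_force_widths_and_overlaps(raw, dims)
    weights = core.compute_weights(raw, dims)
    for c in raw.columns:
        assert weights.W[c] == pytest.approx(W[c], abs=1e-12)
    widths = pd.DataFrame(index=raw.index)
    for d in dims:
        widths[f"N_{d}"] = core.relative_niche_width(raw, weights, d,
                                                     dimensions=dims)
        for r in raw.index:
            assert widths.loc[r, f"N_{d}"] == pytest.approx(N[(r, d)],
                                                            abs=1e-12)
    m = core.comprehensive_niche(widths, weights)
    for r in raw.index:
        assert m[r] == pytest.approx(M[r], abs=1e-12)
    for (rj, rk), expected in O.items():
        assert core.pianka_overlap(raw.loc[rj], raw.loc[rk]) \
            == pytest.approx(expected, abs=1e-12)


# ----- properties ---------------------------------------------------------

def test_conservation_and_overlap_properties_random_instances():
    rng = np.random.default_rng(99)
    for _ in range(100):
        n = rng.integers(2, 8)
        raw = pd.DataFrame(rng.uniform(0.05, 3.0, (n, 14)),
                           columns=list(core.INDEX_COLUMNS))
        weights = core.compute_weights(raw)
        widths = pd.DataFrame(index=raw.index)
        for d in core.INDEX_DIMENSIONS:
            widths[f"N_{d}"] = core.relative_niche_width(raw, weights, d)
            assert widths[f"N_{d}"].sum() == pytest.approx(1.0, abs=1e-9)
        M = core.comprehensive_niche(widths, weights)
        assert M.sum() == pytest.approx(1.0, abs=1e-9)
        assert ((M > 0) & (M < 1 + 1e-12)).all()
        # overlap matrix: symmetric, unit diagonal, [0, 1]
        mat = raw.to_numpy()
        for j in range(n):
            assert core.pianka_overlap(mat[j], mat[j]) \
                == pytest.approx(1.0, abs=1e-12)
            for k in range(j + 1, n):
                o = core.pianka_overlap(mat[j], mat[k])
                assert 0.0 <= o <= 1.0
                assert o == pytest.approx(
                    core.pianka_overlap(mat[k], mat[j]), abs=1e-12)


def test_width_monotonicity_zero_sum():
    """Raising one unit's adjusted value on one index weakly raises its
    width and weakly lowers everyone else's."""
    rng = np.random.default_rng(3)
    for _ in range(20):
        raw = pd.DataFrame(rng.uniform(0.1, 2.0, (5, 14)),
                           columns=list(core.INDEX_COLUMNS))
        weights = core.compute_weights(raw)
        d = rng.choice(list(core.INDEX_DIMENSIONS))
        col = rng.choice(core.INDEX_DIMENSIONS[d])
        i = rng.integers(0, 5)
        base = core.relative_niche_width(raw, weights, d)
        bumped = raw.copy()
        bumped.loc[i, col] *= 1.5
        after = core.relative_niche_width(bumped, weights, d)
        assert after[i] >= base[i] - 1e-12
        others = [j for j in range(5) if j != i]
        assert (after[others] <= base[others] + 1e-12).all()
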