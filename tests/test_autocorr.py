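"""Moran's I, Mantel test, spatial weights: oracles and calibration."""

import itertools
import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from phylospatial import (
    GeoTable,
    build_weights,
    distance_matrix,
    fit_glm,
    mantel_test,
    morans_i,
    residual_moran,
)
from phylospatial.autocorr import SpatialWeights
from phylospatial.geo import ValidationError


def brute_force_moran(x, w):
    """Independent double-sum oracle for the statistic."""
    x = np.asarray(x, float)
    n = len(x)
    z = x - x.mean()
    num = sum(w[i, j] * z[i] * z[j] for i in range(n) for j in range(n))
    return (n / w.sum()) * num / (z @ z).item()


def coincident_pair_table():
    df = pd.DataFrame({"id": ["a", "b"], "lon": [10.0, 10.0], "lat": [5.0, 5.0]})
    return distance_matrix(GeoTable(df))


def test_weights_schemes():
    D = coincident_pair_table()
    W = build_weights(D, scheme="inverse_distance", d_floor=1.0)
    assert np.allclose(W.values, [[0.0, 1.0], [1.0, 0.0]])
    assert np.all(np.isfinite(W.values))

    rng = np.random.default_rng(2)
    df = pd.DataFrame({"id": [f"i{i}" for i in range(6)], "lon": rng.uniform(-50, 50, 6),
                       "lat": rng.uniform(-50, 50, 6)})
    D6 = distance_matrix(GeoTable(df))
    W6 = build_weights(D6, scheme="k_nearest", k=5)
    assert np.allclose(W6.values, 1.0 - np.eye(6))
    Wk = build_weights(D6, scheme="kernel", rho_w=1000.0)
    assert np.allclose(Wk.values, np.exp(-D6.values / 1000.0) - np.eye(6) * 1.0, atol=1e-12)
    Wr = build_weights(D6, row_standardize=True)
    assert np.allclose(Wr.values.sum(axis=1), 1.0)


def test_weight_errors(small_distance_matrix):
    with pytest.raises(ValidationError):
        build_weights(small_distance_matrix, scheme="k_nearest", k=0)
    with pytest.raises(ValidationError):
        build_weights(small_distance_matrix, scheme="unknown")
    with pytest.raises(ValidationError, match="zero"):
        SpatialWeights(np.zeros((3, 3)), ["a", "b", "c"], scheme="manual")


def test_moran_null_expectation_and_errors(make_table):
    t = make_table(n=30, seed=9)
    W = build_weights(distance_matrix(t))
    res = morans_i(t.covariate("env"), W)
    assert res.expected == pytest.approx(-1.0 / 29)
    with pytest.raises(ValidationError, match="zero variance"):
        morans_i(np.ones(30), W)
    with pytest.raises(ValidationError, match="n >= 4"):
        morans_i(np.array([1.0, 2.0, 3.0]), SpatialWeights(1 - np.eye(3), list("abc"), "manual"))


def test_moran_matches_brute_force_and_enumeration():
    # 4 points in two tight pairs; x aligned with the pairs
    df = pd.DataFrame({"id": list("abcd"), "lon": [0.0, 0.5, 120.0, 120.5], "lat": [0.0] * 4})
    D = distance_matrix(GeoTable(df))
    W = build_weights(D, scheme="k_nearest", k=1)
    x = np.array([1.0, 1.0, 0.0, 0.0])
    res = morans_i(x, W, method="permutation", exact=True)
    assert res.statistic == pytest.approx(brute_force_moran(x, W.values), abs=1e-12)

    # independent full-enumeration p oracle
    e_i = -1.0 / 3.0
    ref = abs(res.statistic - e_i)
    sims = [brute_force_moran(x[list(p)], W.values) for p in itertools.permutations(range(4))]
    p_exact = np.mean([abs(s - e_i) >= ref - 1e-12 for s in sims])
    assert res.p == pytest.approx(p_exact, abs=1e-12)


@given(a=st.floats(0.1, 10.0), b=st.floats(-5.0, 5.0))
@settings(max_examples=25, deadline=None)
def test_moran_affine_invariance(a, b):
    rng = np.random.default_rng(8)
    df = pd.DataFrame({"id": [f"i{i}" for i in range(15)], "lon": rng.uniform(-90, 90, 15),
                       "lat": rng.uniform(-60, 60, 15)})
    W = build_weights(distance_matrix(GeoTable(df)))
    x = rng.normal(size=15)
    i0 = morans_i(x, W).statistic
    i1 = morans_i(a * x + b, W).statistic
    assert i1 == pytest.approx(i0, rel=1e-9)


def test_checkerboard_dispersion():
    """A perfect checkerboard under rook adjacency is maximally dispersed."""
    size = 6
    coords = [(i, j) for i in range(size) for j in range(size)]
    n = len(coords)
    w = np.zeros((n, n))
    for a, (i, j) in enumerate(coords):
        for b, (k, l) in enumerate(coords):
            if abs(i - k) + abs(j - l) == 1:
                w[a, b] = 1.0
    W = SpatialWeights(w, [f"c{i}" for i in range(n)], scheme="rook")
    x = np.array([(i + j) % 2 for i, j in coords], dtype=float)
    res = morans_i(x, W)
    assert res.statistic < res.expected
    assert res.z < -2.0


def test_permutation_agrees_with_analytic_on_gaussian():
    rng = np.random.default_rng(12)
    df = pd.DataFrame({"id": [f"i{i}" for i in range(50)], "lon": rng.uniform(-180, 180, 50),
                       "lat": rng.uniform(-60, 60, 50)})
    W = build_weights(distance_matrix(GeoTable(df)))
    x = rng.normal(size=50)
    p_analytic = morans_i(x, W, method="randomization").p
    p_perm = morans_i(x, W, method="permutation", permutations=999, seed=5).p
    assert abs(p_analytic - p_perm) < 0.07


def test_matches_r_ape_moran():
    """Independent cross-check against ape::Moran.I (which row-standardizes)."""
    if shutil.which("Rscript") is None:
        pytest.skip("Rscript not on PATH")
    rng = np.random.default_rng(11)
    n = 20
    df = pd.DataFrame({"id": [f"i{i}" for i in range(n)], "lon": rng.uniform(-180, 180, n),
                       "lat": rng.uniform(-60, 60, n)})
    D = distance_matrix(GeoTable(df))
    x = rng.normal(size=n)
    res = morans_i(x, build_weights(D, row_standardize=True), method="randomization")
    w_raw = build_weights(D).values
    script = (
        "suppressMessages(library(ape));"
        f"w <- matrix(c({','.join(repr(float(v)) for v in w_raw.ravel(order='F'))}), nrow={n});"
        f"x <- c({','.join(repr(float(v)) for v in x)});"
        "m <- Moran.I(x, w);"
        'cat(sprintf("%.12f %.12f %.12f", m$observed, m$expected, m$sd))'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True, text=True, timeout=120)
    obs, exp, sd = map(float, out.stdout.split()[-3:])  # skip startup chatter
    assert res.statistic == pytest.approx(obs, abs=1e-9)
    assert res.expected == pytest.approx(exp, abs=1e-12)
    assert res.sd == pytest.approx(sd, abs=1e-9)


def test_residual_moran_checks(make_table):
    t = make_table(n=25, seed=6, binary_outcome=True)
    fit = fit_glm(t, "outcome ~ env")
    W = build_weights(distance_matrix(t))
    res = residual_moran(fit, W)
    assert res.n == 25

    W_bad = SpatialWeights(W.values, list(reversed(W.ids)), scheme=W.scheme)
    with pytest.raises(ValidationError, match="id order"):
        residual_moran(fit, W_bad)

    # perfect-fit Gaussian model: residuals vanish -> degenerate
    t2 = make_table(n=25, seed=6)
    t2.data["y"] = 2.0 * t2.data["env"] + 1.0
    perfect = fit_glm(
        GeoTable(t2.data, outcome_col="y", covariate_cols=["env"]), "y ~ env", family="gaussian"
    )
    with pytest.raises(ValidationError, match="degenerate|zero variance"):
        residual_moran(perfect, W)


def test_moran_json_fields(make_table):
    t = make_table(n=12, seed=1)
    res = morans_i(t.covariate("env"), build_weights(distance_matrix(t)), seed=3)
    payload = json.loads(res.to_json())
    assert list(payload) == ["statistic", "expected", "sd", "z", "p", "n", "method", "scheme", "seed"]


# ---------------------------------------------------------------------------
# Mantel


def test_mantel_trivial_and_affine(small_distance_matrix):
    A = small_distance_matrix.values
    r1 = mantel_test(A, A, permutations=99, seed=0)
    assert r1.r == pytest.approx(1.0)
    r2 = mantel_test(A, 3.0 * A + 2.0, permutations=99, seed=0)
    assert r2.r == pytest.approx(1.0)


def test_mantel_enumeration_oracle(rng):
    A = rng.random((4, 4))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 0.0)
    B = rng.random((4, 4))
    B = (B + B.T) / 2
    np.fill_diagonal(B, 0.0)
    res = mantel_test(A, B, exact=True)

    def tri(m):
        return m[np.tril_indices(4, k=-1)]

    hits = [
        float(np.corrcoef(tri(A[np.ix_(p, p)]), tri(B))[0, 1]) >= res.r - 1e-12
        for p in itertools.permutations(range(4))
    ]
    assert res.p == pytest.approx(np.mean(hits), abs=1e-12)
    assert res.permutations == 24


def test_mantel_matches_skbio(small_distance_matrix, rng):
    skbio_distance = pytest.importorskip("skbio.stats.distance")
    A = small_distance_matrix.values
    noise = rng.normal(size=A.shape)
    B = 2.0 * A + (noise + noise.T) ** 2
    np.fill_diagonal(B, 0.0)
    r_sk, _, _ = skbio_distance.mantel(
        skbio_distance.DistanceMatrix(A), skbio_distance.DistanceMatrix(B),
        method="pearson", permutations=0,
    )
    assert mantel_test(A, B, permutations=9, seed=0).r == pytest.approx(r_sk, abs=1e-12)


def test_mantel_input_validation(rng):
    A = np.zeros((4, 4))
    with pytest.raises(ValidationError, match="constant"):
        mantel_test(A, A)
    M = rng.random((4, 4))
    with pytest.raises(ValidationError, match="not symmetric"):
        mantel_test(M, M)
    S = (M + M.T) / 2
    np.fill_diagonal(S, 0.0)
    with pytest.raises(ValidationError, match="shape"):
        mantel_test(S, S[:3, :3])
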