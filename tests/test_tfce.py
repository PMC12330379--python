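from collections import Counter

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from vertexstats.cohort import CohortSurface
from vertexstats.glm import ModelSpec, StatMap
from vertexstats.simulate import SimulationConfig, simulate_cohort
from vertexstats.templates import build_icosphere, pair_adjacency, unique_edges
from vertexstats.tfce import (
    TFCEResult,
    permute_rows,
    tfce_enhance,
    tfce_null,
    tfce_threshold,
)


def brute_force_tfce(t, adjacency, thresholds, dh, ext_exp=1.0, height_exp=2.0):
    """Independent oracle: explicit component labelling at every level."""
    out = np.zeros(t.size)
    for sign in (1, -1):
        height = np.where(np.sign(t) == sign, np.abs(t), 0.0)
        for h in thresholds:
            mask = height >= h
            idx = np.flatnonzero(mask)
            if idx.size == 0:
                continue
            sub = adjacency[idx][:, idx]
            _, labels = connected_components(sub, directed=False)
            sizes = np.bincount(labels)
            out[idx] += sign * sizes[labels] ** ext_exp * h**height_exp * dh
    return out


@pytest.fixture(scope="module")
def small_sphere_pair():
    # one 162-vertex sphere per hemisphere
    left = build_icosphere(2, hemisphere="left")
    right = build_icosphere(2, hemisphere="right")
    return left, right


def test_tfce_matches_brute_force_oracle(small_sphere_pair, rng):
    left, right = small_sphere_pair
    v = left.n_vertices + right.n_vertices
    adjacency = pair_adjacency(left, right)
    t = rng.normal(size=v) * 2
    n_steps = 50
    hmax = np.abs(t).max()
    dh = hmax / n_steps
    thresholds = hmax * (np.arange(1, n_steps + 1) / n_steps)
    oracle = brute_force_tfce(t, adjacency, thresholds, dh)
    ours = tfce_enhance(t, small_sphere_pair, n_steps=n_steps)
    np.testing.assert_allclose(ours, oracle, rtol=1e-10, atol=1e-12)


def test_tfce_all_zero_map(small_sphere_pair):
    v = 2 * small_sphere_pair[0].n_vertices
    assert np.all(tfce_enhance(np.zeros(v), small_sphere_pair) == 0)


def test_tfce_single_isolated_vertex_analytic_limit(small_sphere_pair):
    # isolated spike of height h0: TFCE -> h0^3 / 3 as dh -> 0
    v = 2 * small_sphere_pair[0].n_vertices
    h0 = 4.0
    t = np.zeros(v)
    t[17] = h0
    out = tfce_enhance(t, small_sphere_pair, dh=h0 / 100)
    assert out[17] == pytest.approx(h0**3 / 3, rel=0.02)
    assert np.all(np.delete(out, 17) == 0)


def test_tfce_cubic_scaling_law(small_sphere_pair, rng):
    t = rng.normal(size=2 * small_sphere_pair[0].n_vertices)
    base = tfce_enhance(t, small_sphere_pair)
    for c in (0.5, 2.0, 7.3):
        scaled = tfce_enhance(c * t, small_sphere_pair)
        np.testing.assert_allclose(scaled, c**3 * base, rtol=1e-6)


def test_tfce_sign_structure_and_monotonicity(small_sphere_pair, rng):
    t = rng.normal(size=2 * small_sphere_pair[0].n_vertices)
    out = tfce_enhance(t, small_sphere_pair)
    nz = out != 0
    assert np.all(np.sign(out[nz]) == np.sign(t[nz]))
    # only sub-step heights may end up with zero TFCE
    dh = np.abs(t).max() / 100
    assert np.all(np.abs(t[~nz]) < dh)
    # raising one |t| never decreases any |TFCE| (checked on random bumps)
    for _ in range(5):
        i = rng.integers(t.size)
        t2 = t.copy()
        t2[i] += np.sign(t2[i] if t2[i] != 0 else 1.0) * 0.5
        hmax = max(np.abs(t).max(), np.abs(t2).max())
        dh = hmax / 100
        a = np.abs(tfce_enhance(t, small_sphere_pair, dh=dh))
        b = np.abs(tfce_enhance(t2, small_sphere_pair, dh=dh))
        assert np.all(b >= a - 1e-12)


def test_tfce_rejects_bad_step(small_sphere_pair):
    v = 2 * small_sphere_pair[0].n_vertices
    with pytest.raises(ValueError):
        tfce_enhance(np.ones(v), small_sphere_pair, dh=-1.0)
    with pytest.raises(ValueError):
        tfce_enhance(np.ones(v), small_sphere_pair, n_steps=0)


# ---------------------------------------------------------------------------
# permutation schemes


def _session_cohort(n_sub, n_ses, v=6):
    n = n_sub * n_ses
    data = np.arange(n * v, dtype=float).reshape(n, v)
    subj = [f"s{i}" for i in range(n_sub) for _ in range(n_ses)]
    sheet = pd.DataFrame(
        {
            "subject_id": subj,
            "session": np.tile(np.arange(n_ses, dtype=float), n_sub),
        }
    )
    c = CohortSurface(data, subj, "toy", "m", v // 2)
    return c, ModelSpec(sheet, "session", random_group="subject_id")


def test_permute_all_reaches_every_permutation():
    c, spec = _session_cohort(3, 1)
    rng = np.random.default_rng(0)
    seen = {tuple(permute_rows(c, spec, "all", rng)) for _ in range(500)}
    assert len(seen) == 6


def test_permute_within_uniform_over_block_shuffles():
    c, spec = _session_cohort(2, 2)
    rng = np.random.default_rng(1)
    counts = Counter(
        tuple(permute_rows(c, spec, "within", rng)) for _ in range(4000)
    )
    assert len(counts) == 4  # 2 blocks x 2 internal orders
    for perm in counts:
        # rows never leave their subject block
        assert set(perm[:2]) == {0, 1} and set(perm[2:]) == {2, 3}
        assert 0.22 <= counts[perm] / 4000 <= 0.28


def test_permute_between_moves_rigid_blocks():
    c, spec = _session_cohort(3, 2)
    rng = np.random.default_rng(2)
    perms = {tuple(permute_rows(c, spec, "between", rng)) for _ in range(1000)}
    assert len(perms) == 6
    for perm in perms:
        for slot in range(3):
            a, b = perm[2 * slot], perm[2 * slot + 1]
            assert b == a + 1 and a % 2 == 0  # block internal order intact


def test_permute_between_unequal_blocks_error():
    data = np.zeros((5, 4))
    subj = ["a", "a", "a", "b", "b"]
    sheet = pd.DataFrame({"subject_id": subj, "x": np.arange(5.0)})
    c = CohortSurface(data, subj, "toy", "m", 2)
    spec = ModelSpec(sheet, "x", random_group="subject_id")
    with pytest.raises(ValueError, match="equal block sizes"):
        permute_rows(c, spec, "between", np.random.default_rng(0))


def test_permute_within_between_composes():
    c, spec = _session_cohort(3, 2)
    rng = np.random.default_rng(3)
    perms = {tuple(permute_rows(c, spec, "within_between", rng)) for _ in range(2000)}
    # 3! block orders x 2^3 within flips = 48 distinct permutations
    assert len(perms) == 48


def test_permute_within_requires_session_structure():
    data = np.zeros((4, 4))
    sheet = pd.DataFrame({"x": np.arange(4.0)})
    c = CohortSurface(data, list("abcd"), "toy", "m", 2)
    spec = ModelSpec(sheet, "x")
    with pytest.raises(ValueError, match="session structure"):
        permute_rows(c, spec, "within", np.random.default_rng(0))


# ---------------------------------------------------------------------------
# null estimation and thresholding


@pytest.fixture(scope="module")
def null_cohort_spec():
    meshes = (
        build_icosphere(1, hemisphere="left"),
        build_icosphere(1, hemisphere="right"),
    )
    cfg = SimulationConfig(
        n_subjects=14, space_tag="synthetic-ico1", noise_smooth_fwhm=60.0, seed=5
    )
    cohort, sheet, _ = simulate_cohort(cfg, meshes=meshes)
    spec = ModelSpec(sheet[["age", "sex", "group"]], "group")
    return cohort, spec, meshes


def test_null_is_worker_count_invariant(null_cohort_spec):
    cohort, spec, meshes = null_cohort_spec
    r1 = tfce_null(cohort, spec, meshes, n_permutations=40, seed=9, n_workers=1)
    r4 = tfce_null(cohort, spec, meshes, n_permutations=40, seed=9, n_workers=4)
    np.testing.assert_array_equal(r1.perm_max_null, r4.perm_max_null)
    np.testing.assert_array_equal(r1.tfce_map, r4.tfce_map)


def test_threshold_reuses_null_without_refits(null_cohort_spec, monkeypatch):
    cohort, spec, meshes = null_cohort_spec
    r = tfce_null(cohort, spec, meshes, n_permutations=60, seed=1)

    import vertexstats.glm as glm_mod

    calls = {"n": 0}
    original = glm_mod.ols_t

    def counting(*args, **kwargs):
        calls["n"] += 1
        return original(*args, **kwargs)

    monkeypatch.setattr(glm_mod, "ols_t", counting)
    res_05 = tfce_threshold(r, meshes, p=0.05)
    res_01 = tfce_threshold(r, meshes, p=0.01)
    assert calls["n"] == 0  # zero model refits on re-thresholding
    # stricter p yields a vertex subset
    sig_05 = (res_05.pos_mask + res_05.neg_mask) > 0
    sig_01 = (res_01.pos_mask + res_01.neg_mask) > 0
    assert np.all(sig_01 <= sig_05)


def test_threshold_p_edges(null_cohort_spec):
    cohort, spec, meshes = null_cohort_spec
    r = tfce_null(cohort, spec, meshes, n_permutations=30, seed=2)
    # p -> 0: nothing survives (min achievable p is 1/(n+1))
    tiny = tfce_threshold(r, meshes, p=1.0 / (r.n_permutations + 1) / 2)
    assert tiny.n_clusters == 0
    with pytest.raises(ValueError):
        tfce_threshold(r, meshes, p=0.0)
    with pytest.raises(ValueError):
        tfce_threshold(r, meshes, p=1.0)


def test_threshold_liberal_quantile_edge(null_cohort_spec):
    # with a null list containing a zero (an empty permutation map), the
    # (1 - 1/(n+1)) threshold admits every nonzero-TFCE vertex
    cohort, spec, meshes = null_cohort_spec
    r = tfce_null(cohort, spec, meshes, n_permutations=19, seed=3)
    null = r.perm_max_null.copy()
    null[0] = 0.0
    r2 = TFCEResult(r.tfce_map, null, 19, r.perm_type, r.seed, stat=r.stat)
    res = tfce_threshold(r2, meshes, p=1.0 - 1.0 / 20)
    sig = (res.pos_mask + res.neg_mask) > 0
    np.testing.assert_array_equal(sig, r.tfce_map != 0)


def test_min_p_resolution(null_cohort_spec):
    cohort, spec, meshes = null_cohort_spec
    r = tfce_null(cohort, spec, meshes, n_permutations=30, seed=4)
    res = tfce_threshold(r, meshes, p=0.5)
    assert res.vertex_p.min() >= 1.0 / 31


def test_null_rejects_bad_args(null_cohort_spec):
    cohort, spec, meshes = null_cohort_spec
    with pytest.raises(ValueError):
        tfce_null(cohort, spec, meshes, n_permutations=0)
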