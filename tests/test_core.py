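import numpy as np
import pytest

from lfpca import (DegenerateDataError, SingularDesignError, backproject,
                   build_moment_design, component_trajectory, demean,
                   eigendecompose, estimate_cov_blocks, estimate_scores,
                   fit_lfpca, load_fit, reduce_stack, save_fit,
                   simulate_from_model, variance_table)
from lfpca.core import CovBlocks, LfpcaFit, ReducedData

from conftest import make_stack


# ---------------------------------------------------------------------------
# oracles

def full_space_cov_blocks(data, subject_id, time):
    """Brute-force moment estimator in voxel space (p^2 x m response)."""
    p = data.shape[0]
    design = build_moment_design(subject_id, time)
    F = design.F
    Y = np.column_stack([
        np.outer(data[:, j1], data[:, j2]).ravel()
        for j1, j2 in zip(design.j1, design.j2)
    ])
    K = Y @ F.T @ np.linalg.inv(F @ F.T)
    blocks = [K[:, q].reshape(p, p) for q in range(5)]
    k00, k01, k10, k11, kw = blocks
    k00 = 0.5 * (k00 + k00.T)
    k11 = 0.5 * (k11 + k11.T)
    kw = 0.5 * (kw + kw.T)
    k01 = 0.5 * (k01 + k10.T)
    return k00, k01, k01.T, k11, kw


def full_space_scores(data, subject_id, time, phi_x0, phi_x1, phi_w):
    """BLUP scores computed entirely in voxel space."""
    n_x, n_w = phi_x0.shape[1], phi_w.shape[1]
    sids = np.asarray(subject_id)
    xi, zeta = [], []
    start = 0
    for j in range(1, len(sids) + 1):
        if j == len(sids) or sids[j] != sids[start]:
            t = np.asarray(time[start:j], dtype=float)
            ji = t.size
            p = data.shape[0]
            B = np.zeros((ji * p, n_x + ji * n_w))
            for v in range(ji):
                B[v * p:(v + 1) * p, :n_x] = phi_x0 + t[v] * phi_x1
                B[v * p:(v + 1) * p, n_x + v * n_w:n_x + (v + 1) * n_w] = phi_w
            y = data[:, start:j].T.ravel()
            sol, *_ = np.linalg.lstsq(B, y, rcond=None)
            xi.append(sol[:n_x])
            zeta.append(sol[n_x:].reshape(ji, n_w))
            start = j
    return np.array(xi), np.vstack(zeta)


# ---------------------------------------------------------------------------
# demean / reduce

def test_demean_examples(rng):
    stack = make_stack([[0.0, 2.0]], [(0.0, 1.0)])
    mean, out = demean(stack)
    assert mean[0] == 1.0
    assert np.array_equal(out.data, [[-1.0, 1.0]])

    same = make_stack(np.ones((3, 2)), [(0.0, 1.0)])
    _, out = demean(same)
    assert np.all(out.data == 0.0)

    randstack = make_stack(rng.normal(size=(5, 6)), [(0, 1, 2)] * 2)
    _, out = demean(randstack)
    assert np.allclose(out.data.mean(axis=1), 0.0, atol=1e-12)


def test_reduce_rank_one_and_reconstruction(rng):
    u = rng.normal(size=50)
    v = rng.normal(size=12)
    rank1 = np.outer(u, v)
    red = reduce_stack(make_stack(rank1 - rank1.mean(1, keepdims=True) * 0,
                                  [(0, 1, 2, 3)] * 3))
    assert red.rank == 1

    data = rng.normal(size=(50, 12))
    red = reduce_stack(make_stack(data, [(0, 1, 2, 3)] * 3))
    recon = red.V @ red.W_red
    assert np.linalg.norm(recon - data) / np.linalg.norm(data) < 1e-10
    assert np.allclose(red.V.T @ red.V, np.eye(red.rank), atol=1e-10)


def test_reduce_rejects_zero_stack():
    with pytest.raises(DegenerateDataError):
        reduce_stack(make_stack(np.zeros((4, 4)), [(0, 1)] * 2))


# ---------------------------------------------------------------------------
# moment design

def test_moment_design_single_subject_two_visits():
    d = build_moment_design(np.array(["a"] * 2 + ["b"] * 3),
                            np.array([0.0, 1.0, 0.0, 1.0, 2.0]))
    # subject a pairs (order j1-major): (1,1),(1,2),(2,1),(2,2)
    expect = np.array([
        [1, 0, 0, 0, 1],
        [1, 1, 0, 0, 0],
        [1, 0, 1, 0, 0],
        [1, 1, 1, 1, 1],
    ], dtype=float).T
    assert np.array_equal(d.F[:, :4], expect)
    assert d.m == 4 + 9


def test_moment_design_pair_count():
    d = build_moment_design(np.array(["a"] * 3 + ["b"] * 3),
                            np.array([0, 1, 2, 0, 1, 2], dtype=float))
    assert d.m == 18


def test_moment_design_singular_when_single_time():
    # two visits per subject cannot identify 5 moment parameters
    with pytest.raises(SingularDesignError):
        build_moment_design(np.array(["a", "a", "b", "b"]),
                            np.array([0.0, 1.0, 0.0, 1.0]))


# ---------------------------------------------------------------------------
# covariance blocks

def test_reduced_blocks_match_full_space_oracle(rng):
    p, nsub = 6, 8
    times = [(0.0, 1.0, 2.0)] * nsub
    data = rng.normal(size=(p, 3 * nsub))
    stack = make_stack(data, times)
    _, centered = demean(stack)
    red = reduce_stack(centered)
    design = build_moment_design(stack.subject_id, stack.time)
    blocks = estimate_cov_blocks(red, design)
    oracle = full_space_cov_blocks(centered.data, stack.subject_id, stack.time)
    V = red.V
    for est, ref in zip(
            [blocks.K00, blocks.K01, blocks.K10, blocks.K11, blocks.KW],
            oracle):
        proj = V.T @ ref @ V
        assert np.linalg.norm(est - proj) / max(np.linalg.norm(proj), 1e-30) < 1e-8


def test_blocks_recover_identity_noise(rng):
    # pure visit-specific white noise: KW ~ sigma^2 I, KX blocks ~ 0,
    # errors shrinking as N grows
    p, sigma2 = 4, 1.0
    errs = []
    for nsub in [50, 400]:
        data = rng.normal(size=(p, 3 * nsub))
        stack = make_stack(data, [(0.0, 1.0, 2.0)] * nsub)
        _, centered = demean(stack)
        red = reduce_stack(centered)
        blocks = estimate_cov_blocks(
            red, build_moment_design(stack.subject_id, stack.time))
        V = red.V
        KW_full = V @ blocks.KW @ V.T
        KX_full = V @ blocks.K00 @ V.T
        errs.append((np.linalg.norm(KW_full - sigma2 * np.eye(p)),
                     np.linalg.norm(KX_full)))
    assert errs[1][0] < errs[0][0]
    assert errs[1][1] < errs[0][1]
    assert errs[1][0] < 0.5 and errs[1][1] < 0.5


def test_blocks_interpolate_tiny_noiseless_case(rng):
    # one subject, three visits, random-intercept-only data: the OLS fit
    # reproduces the observed second moments exactly at the design points
    x = rng.normal(size=3)
    data = np.column_stack([x, x, x])  # same image at t = 0, 1, 2
    stack = make_stack(data, [(0.0, 1.0, 2.0)])
    red = reduce_stack(stack)
    design = build_moment_design(stack.subject_id, stack.time)
    blocks = estimate_cov_blocks(red, design)
    V = red.V
    K00 = V @ blocks.K00 @ V.T
    K01 = V @ blocks.K01 @ V.T
    K10 = V @ blocks.K10 @ V.T
    K11 = V @ blocks.K11 @ V.T
    KW = V @ blocks.KW @ V.T
    for j1, t1 in enumerate([0.0, 1.0, 2.0]):
        for j2, t2 in enumerate([0.0, 1.0, 2.0]):
            pred = (K00 + t2 * K01 + t1 * K10 + t1 * t2 * K11
                    + (j1 == j2) * KW)
            obs = np.outer(data[:, j1], data[:, j2])
            assert np.allclose(pred, obs, atol=1e-8)


def test_blocks_symmetrization_invariants(rng):
    data = rng.normal(size=(5, 12))
    stack = make_stack(data, [(0.0, 1.0, 2.0)] * 4)
    _, centered = demean(stack)
    red = reduce_stack(centered)
    blocks = estimate_cov_blocks(
        red, build_moment_design(stack.subject_id, stack.time))
    assert np.allclose(blocks.K00, blocks.K00.T, atol=1e-10)
    assert np.allclose(blocks.K11, blocks.K11.T, atol=1e-10)
    assert np.allclose(blocks.KW, blocks.KW.T, atol=1e-10)
    assert np.allclose(blocks.K01, blocks.K10.T, atol=1e-10)


# ---------------------------------------------------------------------------
# eigendecomposition and variance table

def _fit_from_blocks(blocks, r, subject_id=None, visit=None, time=None,
                     **kw):
    red = ReducedData(V=np.eye(r), S=np.ones(r), U=np.eye(r))
    n = r if subject_id is None else len(subject_id)
    return eigendecompose(
        blocks, red,
        subject_id if subject_id is not None else np.array(["s"] * r),
        visit if visit is not None else np.arange(r),
        time if time is not None else np.zeros(r), **kw)


def test_eigendecompose_diagonal_case():
    r = 2
    K00 = np.diag([4.0, 0.0])
    K11 = np.diag([0.0, 1.0])
    blocks = CovBlocks(K00=K00, K01=np.zeros((r, r)), K10=np.zeros((r, r)),
                       K11=K11, KW=np.eye(r) * 0.5)
    fit = _fit_from_blocks(blocks, r, n_x=1.0, n_w=1.0)
    assert np.allclose(fit.lambda_x, [4.0, 1.0])
    # first eigenvector is the pure-baseline basis direction, second pure
    # longitudinal (up to sign, made positive by convention)
    assert np.allclose(np.abs(fit.A_x0[:, 0]), [1.0, 0.0])
    assert np.allclose(np.abs(fit.A_x1[:, 1]), [0.0, 1.0])
    assert fit.longitudinal_ratios[0] == pytest.approx(0.0, abs=1e-12)
    assert fit.longitudinal_ratios[1] == pytest.approx(1.0, abs=1e-12)


def test_eigendecompose_recovers_constructed_rank_two(rng):
    r = 6
    Q, _ = np.linalg.qr(rng.normal(size=(2 * r, 2)))
    lam = np.array([5.0, 1.5])
    KX = Q @ np.diag(lam) @ Q.T
    blocks = CovBlocks(K00=KX[:r, :r], K01=KX[:r, r:], K10=KX[r:, :r],
                       K11=KX[r:, r:], KW=0.1 * np.eye(r))
    fit = _fit_from_blocks(blocks, r, n_x=1.0, n_w=1.0)
    assert fit.n_x == 2
    assert np.allclose(fit.lambda_x, lam, atol=1e-6)


def test_truncation_count_fraction_and_negative_discard():
    r = 2
    blocks = CovBlocks(K00=np.diag([3.0, -1.0]), K01=np.zeros((r, r)),
                       K10=np.zeros((r, r)), K11=np.diag([1.0, 0.0]),
                       KW=np.diag([1.0, 0.0]))
    full = _fit_from_blocks(blocks, r, n_x=1.0, n_w=1.0)
    assert full.n_x == 2  # negative eigenvalue discarded, zeros discarded
    assert np.all(full.lambda_x > 0)
    frac = _fit_from_blocks(blocks, r, n_x=0.75, n_w=1.0)
    assert frac.n_x == 1
    count = _fit_from_blocks(blocks, r, n_x=5, n_w=5)
    assert count.n_x == 2 and count.n_w == 1


def test_variance_table_shares_and_ratios():
    r = 2
    blocks = CovBlocks(K00=np.diag([3.0, 0.0]), K01=np.zeros((r, r)),
                       K10=np.zeros((r, r)), K11=np.diag([0.0, 1.0]),
                       KW=np.diag([1.0, 0.0]))
    fit = _fit_from_blocks(blocks, r, n_x=1.0, n_w=1.0)
    table = variance_table(fit)
    assert np.allclose(sorted(table["variance_share"]), [0.2, 0.2, 0.6])
    assert table["variance_share"].sum() == pytest.approx(1.0)
    sub = table[table.process == "subject"]
    assert set(np.round(sub["longitudinal_ratio"], 12)) == {0.0, 1.0}


# ---------------------------------------------------------------------------
# scores

def test_scores_exact_recovery_noiseless(make_model_components):
    p, n_x = 30, 2
    phi0, phi1, phiw = make_model_components(p, n_x, 1, seed=3)
    stack, truth = simulate_from_model(
        phi0, phi1, phiw, [4.0, 1.0], [0.0], n_subjects=12,
        visit_times=(0.0, 1.0, 2.0), seed=5)
    red = reduce_stack(stack)
    fit = LfpcaFit(
        lambda_x=np.array([4.0, 1.0]), A_x0=red.V.T @ phi0,
        A_x1=red.V.T @ phi1, lambda_w=np.zeros(0),
        A_w=np.zeros((red.rank, 0)), reduced=red,
        subject_id=stack.subject_id, visit_index=stack.visit_index,
        time=stack.time)
    xi, zeta = estimate_scores(fit)
    assert np.allclose(xi, truth["xi"], atol=1e-8)
    assert zeta.shape == (stack.n_images, 0)


def test_scores_projection_case():
    # single pure-baseline component, data equal to phi at every visit and
    # all times zero: the score is the scalar projection onto phi
    p = 10
    phi = np.zeros(p)
    phi[3] = 1.0
    data = np.column_stack([phi, phi])
    red = ReducedData(V=phi[:, None], S=np.array([np.sqrt(2.0)]),
                      U=np.full((2, 1), 1 / np.sqrt(2)))
    fit = LfpcaFit(
        lambda_x=np.array([1.0]), A_x0=np.array([[1.0]]),
        A_x1=np.array([[0.0]]), lambda_w=np.zeros(0),
        A_w=np.zeros((1, 0)), reduced=red,
        subject_id=np.array(["a", "a"]), visit_index=np.array([1, 2]),
        time=np.array([0.0, 0.0]))
    xi, _ = estimate_scores(fit)
    assert xi[0, 0] == pytest.approx(1.0, abs=1e-10)


def test_scores_reduced_equals_full_space(rng, make_model_components):
    p = 40
    phi0, phi1, phiw = make_model_components(p, 2, 2, seed=11)
    stack, _ = simulate_from_model(
        phi0, phi1, phiw, [4.0, 1.0], [0.5, 0.2], n_subjects=10,
        visit_times=(0.0, 1.0, 2.0, 3.0), seed=13)
    stack = stack.with_data(stack.data + 0.05 * rng.normal(size=stack.data.shape))
    _, centered = demean(stack)
    fit = fit_lfpca(stack, n_x=2, n_w=2)
    phi0_est = backproject(fit, "baseline")
    phi1_est = backproject(fit, "longitudinal")
    phiw_est = backproject(fit, "visit")
    xi_full, zeta_full = full_space_scores(
        centered.data, stack.subject_id, stack.time,
        phi0_est, phi1_est, phiw_est)
    assert np.allclose(fit.xi, xi_full, atol=1e-9)
    assert np.allclose(fit.zeta, zeta_full, atol=1e-9)


# ---------------------------------------------------------------------------
# backprojection and trajectories

def test_backproject_identities(rng):
    data = rng.normal(size=(25, 12))
    stack = make_stack(data, [(0.0, 1.0, 2.0)] * 4)
    fit = fit_lfpca(stack, n_x=3, n_w=3)
    V = fit.reduced.V
    maps = backproject(fit, "baseline")
    assert np.allclose(maps, V @ fit.A_x0, atol=1e-12)
    # norm preservation and round trip through V
    A = np.vstack([fit.A_x0, fit.A_x1])
    stacked_maps = np.vstack([maps, backproject(fit, "longitudinal")])
    assert np.allclose(np.linalg.norm(stacked_maps, axis=0),
                       np.linalg.norm(A, axis=0), atol=1e-10)
    assert np.allclose(V.T @ (V @ fit.A_x0), fit.A_x0, atol=1e-10)
    with pytest.raises(IndexError):
        backproject(fit, "baseline", k=fit.n_x)


def test_component_trajectory_linearity(rng):
    data = rng.normal(size=(25, 12))
    fit = fit_lfpca(make_stack(data, [(0.0, 1.0, 2.0)] * 4), n_x=2, n_w=1)
    traj = component_trajectory(fit, 0, [0.0, 1.0, 2.0])
    base = backproject(fit, "baseline", 0)
    slope = backproject(fit, "longitudinal", 0)
    assert np.allclose(traj[0], base, atol=1e-12)
    assert np.allclose(traj[1] - traj[0], slope, atol=1e-12)
    assert np.allclose(traj[2] - traj[1], slope, atol=1e-12)


def test_unit_norm_invariant_after_fit(rng):
    data = rng.normal(size=(30, 15))
    fit = fit_lfpca(make_stack(data, [(0.0, 1.0, 2.0)] * 5), n_x=4, n_w=4)
    stacked = np.vstack([fit.A_x0, fit.A_x1])
    norms = np.linalg.norm(stacked, axis=0)
    assert np.allclose(norms, 1.0, atol=1e-8)
    assert np.allclose(np.linalg.norm(fit.A_w, axis=0), 1.0, atol=1e-8)
    # distinct stacked eigenvectors are mutually orthogonal
    gram = stacked.T @ stacked
    assert np.allclose(gram, np.eye(fit.n_x), atol=1e-8)
    # eigenvalues sorted descending
    assert np.all(np.diff(fit.lambda_x) <= 1e-12)


def test_fit_serialization_round_trip(tmp_path, rng):
    data = rng.normal(size=(20, 12))
    fit = fit_lfpca(make_stack(data, [(0.0, 1.0, 2.0)] * 4), n_x=2, n_w=2)
    path = tmp_path / "fit.npz"
    save_fit(fit, path)
    back = load_fit(path)
    assert np.allclose(back.lambda_x, fit.lambda_x)
    assert np.allclose(back.xi, fit.xi)
    assert np.allclose(back.reduced.V, fit.reduced.V)
    assert list(back.subject_id) == list(fit.subject_id)
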