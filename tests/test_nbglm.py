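"""Statistical engine: size factors, dispersion, Wald, LRT, binomial LRT."""

import numpy as np
import pytest
from scipy import stats

from splicemeth import nbglm
from splicemeth.nbglm import DesignInfo


def make_design(n_ctrl, n_trt):
    return DesignInfo(
        [f"s{i}" for i in range(n_ctrl + n_trt)],
        ["control"] * n_ctrl + ["treatment"] * n_trt,
    )


# ---------------------------------------------------------------------------
# size factors


def naive_median_of_ratios(m: np.ndarray) -> np.ndarray:
    """Independent loop-based oracle for the median-of-ratios method."""
    n_feat, n_samp = m.shape
    ref = []
    for i in range(n_feat):
        if all(m[i, j] > 0 for j in range(n_samp)):
            log_sum = sum(np.log(m[i, j]) for j in range(n_samp))
            ref.append((i, np.exp(log_sum / n_samp)))
    out = []
    for j in range(n_samp):
        ratios = sorted(m[i, j] / r for i, r in ref)
        k = len(ratios)
        med = ratios[k // 2] if k % 2 else 0.5 * (ratios[k // 2 - 1] + ratios[k // 2])
        out.append(med)
    return np.array(out)


def test_size_factors_identical_columns():
    m = np.tile(np.array([[10.0], [20.0], [3.0]]), (1, 4))
    assert np.allclose(nbglm.size_factors(m), 1.0)


def test_size_factors_doubled_column():
    m = np.column_stack([np.array([10.0, 50.0, 7.0]), 2 * np.array([10.0, 50.0, 7.0])])
    f = nbglm.size_factors(m)
    assert np.allclose(f, [1 / np.sqrt(2), np.sqrt(2)])


def test_size_factors_match_naive_oracle():
    rng = np.random.default_rng(3)
    m = rng.poisson(50, size=(50, 6)).astype(float)
    m[rng.random(m.shape) < 0.1] = 0  # some zeros -> excluded from reference
    assert np.allclose(nbglm.size_factors(m), naive_median_of_ratios(m), atol=0, rtol=0)


def test_size_factors_scale_equivariant_in_ratios():
    # scaling sample j's column by c scales factor j relative to every other
    # factor by exactly c (the geometric-mean reference absorbs c**(1/m),
    # so the absolute factors shift but their ratios are equivariant)
    rng = np.random.default_rng(4)
    m = rng.poisson(30, size=(40, 5)).astype(float) + 1
    f = nbglm.size_factors(m)
    m2 = m.copy()
    m2[:, 2] *= 3.5
    f2 = nbglm.size_factors(m2)
    assert np.allclose(f2[2] / f2[0], 3.5 * f[2] / f[0])
    assert np.allclose(np.delete(f2 / f2[0], 2), np.delete(f / f[0], 2))


def test_size_factors_no_all_positive_feature():
    m = np.array([[0.0, 5.0], [5.0, 0.0]])
    with pytest.raises(ValueError, match="pseudo"):
        nbglm.size_factors(m)
    f = nbglm.size_factors(m, allow_pseudo_reference=True)
    assert np.all(f > 0)


# ---------------------------------------------------------------------------
# dispersion


def test_dispersion_poisson_limit():
    rng = np.random.default_rng(10)
    d = make_design(25, 25)
    X = d.model_matrix()
    offset = np.zeros(50)
    est = [
        nbglm.estimate_dispersion_single(rng.poisson(500, size=50), X, offset)
        for _ in range(60)
    ]
    assert np.mean(np.array(est) < 0.05) >= 0.9


def test_dispersion_consistency_nb():
    rng = np.random.default_rng(11)
    d = make_design(100, 100)
    X = d.model_matrix()
    offset = np.zeros(200)
    est = []
    for _ in range(40):
        y = rng.poisson(rng.gamma(1 / 0.5, 0.5 * 100, size=200))
        est.append(nbglm.estimate_dispersion_single(y, X, offset))
    assert 0.35 <= np.median(est) <= 0.65


def test_dispersion_constant_feature_hits_floor():
    d = make_design(5, 5)
    y = np.full(10, 7)
    assert (
        nbglm.estimate_dispersion_single(y, d.model_matrix(), np.zeros(10))
        == nbglm.DISPERSION_FLOOR
    )


# ---------------------------------------------------------------------------
# Wald


def test_wald_fourfold_change():
    d = make_design(5, 5)
    ctrl = np.array([100, 110, 90, 105, 95])
    y = np.concatenate([ctrl, 4 * ctrl])
    log2fc, se, p, ok = nbglm.nb_wald(y, np.ones(10), d, 0.01)
    assert ok
    assert log2fc == pytest.approx(2.0, abs=0.05)
    assert p < 1e-6


def test_wald_matches_poisson_glm_in_zero_dispersion_limit():
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    d = make_design(9, 10)
    X = d.model_matrix()
    y = rng.poisson([60] * 9 + [90] * 10).astype(float)
    log2fc, se, p, ok = nbglm.nb_wald(y, np.ones(19), d, 1e-8)
    fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
    z_ours = (log2fc / se)
    z_sm = fit.params[1] / fit.bse[1]
    assert abs(z_ours - z_sm) < 1e-3


def test_wald_label_swap_negates_log2fc():
    rng = np.random.default_rng(13)
    y = rng.poisson([50] * 9 + [120] * 10).astype(float)
    d1 = make_design(9, 10)
    d2 = DesignInfo(d1.sample_ids, d1.condition, reference="treatment")
    f = np.ones(19)
    a = nbglm.nb_wald(y, f, d1, 0.05)
    b = nbglm.nb_wald(y, f, d2, 0.05)
    assert a[0] == pytest.approx(-b[0], abs=1e-9)
    assert a[2] == pytest.approx(b[2], abs=1e-9)


# ---------------------------------------------------------------------------
# LRT


def nb_logpmf_oracle(y, mu, alpha):
    """Independent likelihood evaluator via scipy's NB pmf."""
    r = 1.0 / alpha
    p = r / (r + mu)
    return float(np.sum(stats.nbinom.logpmf(y, r, p)))


def test_lrt_full_equals_reduced():
    d = make_design(5, 5)
    X = d.model_matrix()
    y = np.arange(10.0) + 5
    stat, df, p, ok, _ = nbglm.nb_lrt(y, X, X, np.zeros(10), 0.1)
    assert stat == pytest.approx(0.0, abs=1e-6)
    assert df == 0
    assert p == 1.0


def test_lrt_stat_matches_likelihood_oracle():
    rng = np.random.default_rng(14)
    d = make_design(9, 10)
    X = d.model_matrix()
    offset = np.log(np.linspace(0.8, 1.2, 19))
    y = rng.poisson(rng.gamma(10, 8, size=19)).astype(float)
    alpha = 0.1
    stat, df, p, ok, fit_full = nbglm.nb_lrt(y, X, X[:, :1], offset, alpha)
    fit_red = nbglm.fit_nb_glm(y, X[:, :1], offset, alpha)
    ll_full = nb_logpmf_oracle(y, fit_full.mu, alpha)
    ll_red = nb_logpmf_oracle(y, fit_red.mu, alpha)
    assert stat == pytest.approx(2 * (ll_full - ll_red), abs=1e-6)
    assert df == 1


def test_lrt_rejects_non_nested():
    d = make_design(5, 5)
    X = d.model_matrix()
    other = np.column_stack([np.arange(10.0)])
    with pytest.raises(ValueError, match="nested"):
        nbglm.nb_lrt(np.ones(10), X, other, np.zeros(10), 0.1)


# ---------------------------------------------------------------------------
# binomial LRT


def binomial_lrt_hand(mc, tc, mt, tt):
    """Closed-form deviance-difference oracle, written independently."""

    def ll(m, t, p):
        out = 0.0
        if m > 0:
            out += m * np.log(p)
        if t - m > 0:
            out += (t - m) * np.log(1 - p)
        return out

    p1, p2 = mc / tc, mt / tt
    p0 = (mc + mt) / (tc + tt)
    return 2 * (ll(mc, tc, p1) + ll(mt, tt, p2) - ll(mc + mt, tc + tt, p0))


def test_binomial_lrt_no_difference():
    d = make_design(3, 3)
    meth = np.array([5, 5, 5, 5, 5, 5])
    total = np.array([10, 10, 10, 10, 10, 10])
    effect, p = nbglm.binomial_lrt(meth, total, d)
    assert effect == 0.0
    assert p == pytest.approx(1.0)


def test_binomial_lrt_matches_hand_formula():
    rng = np.random.default_rng(15)
    for _ in range(50):
        tc, tt = rng.integers(5, 40, size=2)
        mc = rng.integers(0, tc + 1)
        mt = rng.integers(0, tt + 1)
        _, stat, p = nbglm.binomial_lrt_matrix(
            np.array([[mc, mt]]), np.array([[tc, tt]]), np.array([False, True]),
        )
        assert stat[0] == pytest.approx(binomial_lrt_hand(mc, tc, mt, tt), abs=1e-9)


def test_binomial_lrt_effect_scale():
    d = make_design(4, 4)
    meth = np.array([800] * 4 + [200] * 4)
    total = np.full(8, 1000)
    effect, p = nbglm.binomial_lrt(meth, total, d)
    assert effect == pytest.approx(-60.0)
    assert p < 1e-10


def test_binomial_lrt_boundary_proportions_finite():
    d = make_design(2, 2)
    effect, p = nbglm.binomial_lrt(
        np.array([0, 0, 10, 10]), np.array([10, 10, 10, 10]), d
    )
    assert effect == pytest.approx(100.0)
    assert np.isfinite(p)


# ---------------------------------------------------------------------------
# cross-test agreement


def test_wald_and_lrt_agree_at_large_n():
    rng = np.random.default_rng(16)
    d = make_design(100, 100)
    X = d.model_matrix()
    f = np.ones(200)
    for _ in range(10):
        y = rng.poisson(rng.gamma(1 / 0.2, 0.2 * 80, size=200)).astype(float)
        disp = nbglm.estimate_dispersion_single(y, X, np.zeros(200))
        _, _, p_wald, _ = nbglm.nb_wald(y, f, d, disp)
        _, _, p_lrt, _, _ = nbglm.nb_lrt(y, X, X[:, :1], np.zeros(200), disp)
        lo, hi = sorted([p_wald, p_lrt])
        assert hi <= max(2 * lo, lo + 1e-12) or hi < 1e-8
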