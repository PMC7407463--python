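"""Genomic evaluation: G matrix, GBLUP, trivariate SNP-BLUP, EBV scales."""

import numpy as np
import pytest

from crossbredsim import evaluation as ev
from crossbredsim import trait as tr


@pytest.fixture()
def single_pop():
    rng = np.random.default_rng(10)
    n, nc, p = 80, 20, 150
    freqs = rng.uniform(0.1, 0.9, p)
    z = rng.binomial(2, freqs, size=(n + nc, p)).astype(float)
    a_true = rng.normal(0, 0.08, p)
    y = 10 + (z[:n] - 2 * freqs) @ a_true + rng.normal(0, 1, n)
    fg = (z[:n] != 1).mean(axis=1)
    return dict(z=z, n=n, freqs=freqs, y=y, fg=fg)


# ---------------------------------------------------------------------------
# VanRaden G
# ---------------------------------------------------------------------------


def test_g_duplicate_rows_and_symmetry(single_pop):
    z = single_pop["z"].copy()
    z[1] = z[0]
    G = ev.vanraden_g(z, single_pop["freqs"])
    np.testing.assert_allclose(G[0], G[1])
    assert G[0, 0] == pytest.approx(G[1, 1]) == pytest.approx(G[0, 1])
    np.testing.assert_allclose(G, G.T)
    ev_min = np.linalg.eigvalsh(G).min()
    assert ev_min > -1e-10


def test_g_mean_diagonal_near_one_at_hwe():
    rng = np.random.default_rng(11)
    p = rng.uniform(0.1, 0.9, 3000)
    z = rng.binomial(2, p, size=(300, 3000)).astype(float)
    G = ev.vanraden_g(z, p)
    assert np.diag(G).mean() == pytest.approx(1.0, abs=0.03)


def test_g_rejects_monomorphic_denominator():
    with pytest.raises(ValueError, match="monomorphic"):
        ev.vanraden_g(np.zeros((4, 3)), np.zeros(3))


# ---------------------------------------------------------------------------
# GBLUP
# ---------------------------------------------------------------------------


def test_gblup_equals_centered_marker_ridge(single_pop):
    """GBLUP with G = MM'/sum 2pq is algebraically identical to ridge
    regression on centered markers with per-SNP variance su2/sum 2pq."""
    d = single_pop
    n, z, freqs = d["n"], d["z"], d["freqs"]
    su2, se2 = 0.6, 1.1
    rec = ev.PopRecords(y=d["y"], fg=d["fg"], dosages=z[:n])
    fit = ev.gblup_fit(rec, z[n:], su2, se2, freqs=freqs)

    M = z - 2 * freqs
    s = np.sum(2 * freqs * (1 - freqs))
    V = (su2 / s) * (M[:n] @ M[:n].T) + se2 * np.eye(n)
    X = np.column_stack([np.ones(n), d["fg"]])
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ d["y"])
    a_hat = (su2 / s) * M[:n].T @ (Vi @ (d["y"] - X @ beta))
    ridge_pred = M[n:] @ a_hat
    got = ev.ebv_purebred(fit)
    assert np.max(np.abs(got - ridge_pred)) <= 1e-6 * max(1.0, np.max(np.abs(ridge_pred)))


def test_gblup_matches_henderson_mme_oracle(single_pop):
    """Independent oracle: the classical mixed-model equations with
    explicit G inverse give the same solutions as the V-form solve."""
    d = single_pop
    n, z, freqs = 30, d["z"][:35], d["freqs"]
    y, fg = d["y"][:n], d["fg"][:n]
    su2, se2 = 0.8, 1.4
    G = ev.vanraden_g(z, freqs) + 1e-8 * np.eye(35)
    X = np.column_stack([np.ones(n), fg])
    Z = np.hstack([np.eye(n), np.zeros((n, 5))])
    C = np.block([
        [X.T @ X / se2, X.T @ Z / se2],
        [Z.T @ X / se2, Z.T @ Z / se2 + np.linalg.inv(G) * (1 / su2)],
    ])
    rhs = np.concatenate([X.T @ y / se2, Z.T @ y / se2])
    sol = np.linalg.solve(C, rhs)

    rec = ev.PopRecords(y=y, fg=fg, dosages=z[:n])
    fit = ev.gblup_fit(rec, z[n:], su2, se2, freqs=freqs)
    np.testing.assert_allclose(fit.u_hat, sol[2:], atol=1e-5)
    assert fit.b_hat["pop"] == pytest.approx(sol[1], abs=1e-5)


def test_gblup_no_genetics_limit_gives_ols_slope(single_pop):
    d = single_pop
    n = d["n"]
    rec = ev.PopRecords(y=d["y"], fg=d["fg"], dosages=d["z"][:n])
    fit = ev.gblup_fit(rec, d["z"][n:], 1e-12, 1.0, freqs=d["freqs"])
    assert np.max(np.abs(fit.u_hat)) < 1e-6
    slope = np.polyfit(d["fg"], d["y"], 1)[0]
    assert fit.b_hat["pop"] == pytest.approx(slope, rel=1e-4)


def test_gblup_constant_fg_dropped_with_warning(single_pop):
    d = single_pop
    n = d["n"]
    rec = ev.PopRecords(y=d["y"], fg=np.full(n, 0.5), dosages=d["z"][:n])
    with pytest.warns(UserWarning, match="constant"):
        fit = ev.gblup_fit(rec, d["z"][n:], 0.5, 1.0, freqs=d["freqs"])
    assert np.isnan(fit.b_hat["pop"])


def test_ebvp_invariant_to_phenotype_location(single_pop):
    d = single_pop
    n = d["n"]
    rec = ev.PopRecords(y=d["y"], fg=d["fg"], dosages=d["z"][:n])
    f1 = ev.gblup_fit(rec, d["z"][n:], 0.5, 1.0, freqs=d["freqs"])
    rec2 = ev.PopRecords(y=d["y"] + 100.0, fg=d["fg"], dosages=d["z"][:n])
    f2 = ev.gblup_fit(rec2, d["z"][n:], 0.5, 1.0, freqs=d["freqs"])
    np.testing.assert_allclose(ev.ebv_purebred(f1), ev.ebv_purebred(f2), atol=1e-8)


def test_gblup_accuracy_positive_and_monotone_in_training_size():
    rng = np.random.default_rng(12)
    p = 200
    freqs = rng.uniform(0.2, 0.8, p)
    z = rng.binomial(2, freqs, size=(700, p)).astype(float)
    a_true = rng.normal(0, np.sqrt(0.3 / (0.5 * p)), p)
    tbv = (z - 2 * freqs) @ a_true
    su2 = tbv[:500].var()
    se2 = su2 * (1 - 0.3) / 0.3
    y = 10 + tbv + rng.normal(0, np.sqrt(se2), 700)
    cand = slice(500, 700)
    accs = []
    for n_train in (100, 500):
        rec = ev.PopRecords(
            y=y[:n_train], fg=(z[:n_train] != 1).mean(axis=1), dosages=z[:n_train]
        )
        fit = ev.gblup_fit(rec, z[cand], su2, se2, freqs=freqs)
        accs.append(np.corrcoef(ev.ebv_purebred(fit), tbv[cand])[0, 1])
    assert accs[0] > 0.1
    assert accs[1] > accs[0]


# ---------------------------------------------------------------------------
# trivariate SNP-BLUP
# ---------------------------------------------------------------------------


def _three_pop_data(seed=20, n=60, p=100, with_dominance=True):
    rng = np.random.default_rng(seed)
    data, freqs = {}, {}
    for pop in ("P1", "P2", "CB"):
        f = rng.uniform(0.15, 0.85, p)
        z = rng.binomial(2, f, size=(n, p)).astype(float)
        y = 10 + rng.normal(0, 1, n)
        data[pop] = ev.PopRecords(y=y, fg=(z != 1).mean(axis=1), dosages=z)
        freqs[pop] = f
    return data, freqs


def test_trivariate_decouples_to_univariate_without_correlation():
    data, freqs = _three_pop_data()
    su = np.array([0.9, 0.5, 0.3])
    sv = np.zeros(3)
    se = np.array([1.0, 1.1, 0.9])
    fit = ev.trivariate_snpblup_fit(data, su, sv, se, 0.0, freqs)
    for t, pop in enumerate(("P1", "P2", "CB")):
        rec, f = data[pop], freqs[pop]
        n, p = rec.dosages.shape
        Z = rec.dosages - 2 * f
        X = np.column_stack([np.ones(n), rec.fg])
        lam = np.sum(2 * f * (1 - f)) / su[t]
        H = np.hstack([X, Z])
        C = H.T @ H / se[t]
        C[2:, 2:] += lam * np.eye(p)
        sol = np.linalg.solve(C, H.T @ rec.y / se[t])
        np.testing.assert_allclose(fit.a_hat[t], sol[2:], atol=1e-9)
    assert np.max(np.abs(fit.d_hat)) < 1e-8


def test_trivariate_pcg_matches_dense_solve():
    data, freqs = _three_pop_data(seed=21)
    su = np.array([0.9, 0.5, 0.3])
    sv = np.array([0.05, 0.08, 0.03])
    se = np.array([1.0, 1.1, 0.9])
    dense = ev.trivariate_snpblup_fit(data, su, sv, se, 0.5, freqs)
    pcg = ev.trivariate_snpblup_fit(data, su, sv, se, 0.5, freqs, dense_limit=1)
    assert pcg.converged
    np.testing.assert_allclose(pcg.a_hat, dense.a_hat, atol=1e-6)
    np.testing.assert_allclose(pcg.d_hat, dense.d_hat, atol=1e-6)
    for pop in ("P1", "P2", "CB"):
        assert pcg.b_hat[pop] == pytest.approx(dense.b_hat[pop], abs=1e-6)


def test_trivariate_snp_permutation_exchangeability():
    data, freqs = _three_pop_data(seed=22, p=40)
    su = np.array([0.9, 0.5, 0.3]); sv = np.array([0.05, 0.08, 0.03])
    se = np.array([1.0, 1.1, 0.9])
    fit = ev.trivariate_snpblup_fit(data, su, sv, se, 0.5, freqs)
    perm = np.random.default_rng(0).permutation(40)
    data2 = {
        pop: ev.PopRecords(y=r.y, fg=r.fg, dosages=r.dosages[:, perm])
        for pop, r in data.items()
    }
    freqs2 = {pop: f[perm] for pop, f in freqs.items()}
    fit2 = ev.trivariate_snpblup_fit(data2, su, sv, se, 0.5, freqs2)
    np.testing.assert_allclose(fit2.a_hat, fit.a_hat[:, perm], atol=1e-9)
    np.testing.assert_allclose(fit2.d_hat, fit.d_hat[:, perm], atol=1e-9)


def test_trivariate_missing_population_allowed():
    data, freqs = _three_pop_data(seed=23)
    data["CB"] = None
    fit = ev.trivariate_snpblup_fit(
        data, np.array([0.9, 0.5, 0.3]), np.array([0.05, 0.08, 0.03]),
        np.array([1.0, 1.1, 0.9]), 0.8, freqs,
    )
    # CB effects are inferred through the correlation with observed pops
    assert np.std(fit.a_hat[2]) > 0
    assert "CB" not in fit.mu


def test_trivariate_recovers_depression_parameter():
    """Data simulated under the fitted model: b-hat for the observed
    populations within 2 posterior SD of the simulated b = -10."""
    rng = np.random.default_rng(24)
    n, p = 500, 300
    su = np.array([0.8, 0.8, 0.8])
    sv = np.array([0.2, 0.2, 0.2])
    se = np.array([1.0, 1.0, 1.0])
    data, freqs = {}, {}
    for pop in ("P1", "P2", "CB"):
        f = rng.uniform(0.2, 0.8, p)
        z = rng.binomial(2, f, size=(n, p)).astype(float)
        s2pq = np.sum(2 * f * (1 - f))
        a = rng.normal(0, np.sqrt(0.8 / s2pq), p)
        d = rng.normal(0, np.sqrt(0.2 / np.sum((2 * f * (1 - f)) ** 2)), p)
        fg = (z != 1).mean(axis=1)
        het = (z == 1).astype(float)
        y = 10 - 10.0 * fg + (z - 2 * f) @ a + (het - 2 * f * (1 - f)) @ d \
            + rng.normal(0, 1.0, n)
        data[pop] = ev.PopRecords(y=y, fg=fg, dosages=z)
        freqs[pop] = f
    fit = ev.trivariate_snpblup_fit(data, su, sv, se, 0.0, freqs, compute_se=True)
    # each population within 3 posterior SD; their average within 2 SD of
    # the average's sampling error (three independent populations)
    devs, ses = [], []
    for pop in ("P1", "P2", "CB"):
        devs.append(fit.b_hat[pop] - (-10.0))
        ses.append(fit.b_se[pop])
        assert abs(devs[-1]) < 3 * ses[-1]
    assert abs(np.mean(devs)) < 2 * np.mean(ses) / np.sqrt(3)


# ---------------------------------------------------------------------------
# EBV scales
# ---------------------------------------------------------------------------


def test_fit_serialization_round_trip(tmp_path):
    data, freqs = _three_pop_data(seed=30, n=20, p=15)
    fit = ev.trivariate_snpblup_fit(
        data, np.array([0.9, 0.5, 0.3]), np.array([0.05, 0.08, 0.03]),
        np.array([1.0, 1.1, 0.9]), 0.5, freqs,
    )
    import pandas as pd

    path = tmp_path / "fit.tsv"
    ev.write_fit(fit, path)
    back = pd.read_csv(path, sep="\t", comment="#")
    np.testing.assert_allclose(back["a_CB"], fit.a_hat[2])
    np.testing.assert_allclose(back["d_P2"], fit.d_hat[1])
    assert "model=trivariate" in path.read_text().splitlines()[0]


def test_ebvc_requires_dominance_fit(single_pop):
    d = single_pop
    rec = ev.PopRecords(y=d["y"], fg=d["fg"], dosages=d["z"][: d["n"]])
    fit = ev.gblup_fit(rec, d["z"][d["n"]:], 0.5, 1.0, freqs=d["freqs"])
    with pytest.raises(ValueError, match="trivariate"):
        ev.ebv_crossbred(d["z"][d["n"]:], fit, d["freqs"], d["freqs"])


def test_ebvc_with_true_effects_equals_tbvc(small_map):
    """Plug-in consistency: scoring candidates with the *true* CB effects
    reproduces the crossbred-scale true breeding value exactly."""
    from conftest import make_cohort

    case = tr.VarianceCase.preset(2)
    arch = tr.sample_qtl_effects(case, 10, small_map.qtl_index, np.random.default_rng(1))
    c = make_cohort(small_map, 40, breed="P1", seed=2)
    own = c.allele_freqs(arch.qtl_loci)
    opp = np.random.default_rng(3).uniform(0.1, 0.9, arch.m)
    fit = ev.EvaluationFit(
        model="trivariate", mu={}, b_hat={}, b_se={}, freqs={},
        a_hat=arch.a, d_hat=arch.d,
    )
    got = ev.ebv_crossbred(c.dosages(arch.qtl_loci), fit, own, opp)
    want = tr.tbv_crossbred(c, arch, opposite_freqs=opp, own_freqs=own)
    np.testing.assert_allclose(got, want, atol=1e-10)


def test_ebvc_additive_only_and_balanced_identities(single_pop):
    d = single_pop
    p = d["freqs"].size
    a = np.random.default_rng(4).normal(size=(3, p))
    fit = ev.EvaluationFit(
        model="trivariate", mu={}, b_hat={}, b_se={}, freqs={},
        a_hat=a, d_hat=np.zeros((3, p)),
    )
    z = d["z"][:10]
    got = ev.ebv_crossbred(z, fit, d["freqs"], np.full(p, 0.123))
    np.testing.assert_allclose(got, (z - 2 * d["freqs"]) @ a[2])
    fit2 = ev.EvaluationFit(
        model="trivariate", mu={}, b_hat={}, b_se={}, freqs={},
        a_hat=a, d_hat=np.random.default_rng(5).normal(size=(3, p)),
    )
    got2 = ev.ebv_crossbred(z, fit2, d["freqs"], np.full(p, 0.5))
    np.testing.assert_allclose(got2, (z - 2 * d["freqs"]) @ a[2], atol=1e-12)
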