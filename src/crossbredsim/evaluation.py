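"""Genomic evaluation models.

Two evaluation models are provided, with variance components treated as
known (the calibrated simulation values):

* Univariate GBLUP with a genomic-inbreeding covariate, for scenarios
  that use purebred data only: y = 1 mu + fg b + u + e with
  u ~ N(0, G sigma_u^2) and G the VanRaden genomic relationship matrix
  built over records and candidates jointly.  Solved in the
  observation-space ("V") form, which tolerates a singular G and is
  algebraically identical to ridge regression on centered markers with
  per-SNP variance sigma_u^2 / sum 2pq.

* Trivariate SNP-BLUP over P1, P2 and CB records with "biological"
  additive and dominance SNP effects and a genomic-inbreeding covariate
  per population.  Per SNP, the effect triples across populations are
  MVN(0, Sigma*) with correlation r_qtl and per-population scales
  sigma_u_t^2 / sum 2 p_t q_t (additive) and
  sigma_v_t^2 / sum (2 p_t q_t)^2 (dominance).  Additive covariates are
  z - 2p_t, dominance covariates are het(z) - 2 p_t q_t.  The mixed-model
  equations are solved densely for small systems and otherwise by
  Jacobi-preconditioned conjugate gradients, matrix-free.

Estimated breeding values: EBVP is the GBLUP u-hat of a candidate (the
inbreeding covariate is excluded from the breeding value); EBVC scores a
candidate's markers with the CB-population SNP effects and the opposite
breed's allele frequencies, mirroring the crossbred-scale substitution
effect alpha_C = a_c + (q_opp - p_opp) d_c.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "PopRecords",
    "EvaluationFit",
    "vanraden_g",
    "gblup_fit",
    "trivariate_snpblup_fit",
    "ebv_purebred",
    "ebv_crossbred",
    "write_fit",
]

_POPS = ("P1", "P2", "CB")


@dataclass
class PopRecords:
    """Training records of one population: phenotypes, marker-based
    genomic inbreeding, and raw 0/1/2 marker dosages (one row each)."""

    y: np.ndarray
    fg: np.ndarray
    dosages: np.ndarray

    @property
    def n(self) -> int:
        return self.y.size


@dataclass
class EvaluationFit:
    """Solutions of a genomic evaluation.

    For GBLUP, ``u_hat`` covers records then candidates in input order.
    For the trivariate model, ``a_hat``/``d_hat`` are (3, p) arrays over
    the shared marker set, ordered (P1, P2, CB).
    """

    model: str  # "gblup" | "trivariate"
    mu: dict[str, float]
    b_hat: dict[str, float]
    b_se: dict[str, float]
    freqs: dict[str, np.ndarray]
    n_records: int = 0
    u_hat: np.ndarray | None = None
    a_hat: np.ndarray | None = None
    d_hat: np.ndarray | None = None
    iterations: int = 0
    converged: bool = True
    residual: float = 0.0


def vanraden_g(dosages: np.ndarray, freqs: np.ndarray) -> np.ndarray:
    """VanRaden genomic relationship matrix G = MM' / sum 2pq with
    M the dosages centered by 2p."""
    p = np.asarray(freqs, dtype=float)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("all markers monomorphic: zero VanRaden denominator")
    M = np.asarray(dosages, dtype=float) - 2.0 * p
    return (M @ M.T) / denom


def _fixed_design(n: int, fg: np.ndarray) -> tuple[np.ndarray, bool]:
    """Intercept plus fg covariate; the covariate is dropped (with a
    warning) when constant, which would make the equations singular."""
    fg = np.asarray(fg, dtype=float)
    if n > 0 and np.ptp(fg) > 0:
        return np.column_stack([np.ones(n), fg]), True
    if n > 0:
        warnings.warn("genomic-inbreeding covariate is constant; dropping it")
    return np.ones((n, 1)), False


def gblup_fit(
    records: PopRecords,
    candidate_dosages: np.ndarray,
    sigma_u2: float,
    sigma_e2: float,
    freqs: np.ndarray | None = None,
) -> EvaluationFit:
    """Univariate GBLUP with genomic-inbreeding covariate.

    G is built over records and candidates jointly, centered at the
    training-record allele frequencies (unless ``freqs`` is given).
    Solved as GLS plus u = sigma_u^2 G V^{-1} (y - X beta), which needs no
    G inverse.
    """
    n = records.n
    z_all = np.vstack([records.dosages, candidate_dosages])
    if freqs is None:
        freqs = records.dosages.mean(axis=0) / 2.0
    G = vanraden_g(z_all, freqs)

    X, has_fg = _fixed_design(n, records.fg)
    V = sigma_u2 * G[:n, :n] + sigma_e2 * np.eye(n)
    cf = cho_factor(V, lower=True)
    Vi_y = cho_solve(cf, records.y)
    Vi_X = cho_solve(cf, X)
    XtViX = X.T @ Vi_X
    beta_cov = np.linalg.inv(XtViX)
    beta = beta_cov @ (X.T @ Vi_y)
    resid = records.y - X @ beta
    u_hat = sigma_u2 * (G[:, :n] @ cho_solve(cf, resid))

    b_hat = float(beta[1]) if has_fg else float("nan")
    b_se = float(np.sqrt(beta_cov[1, 1])) if has_fg else float("nan")
    return EvaluationFit(
        model="gblup",
        mu={"pop": float(beta[0])},
        b_hat={"pop": b_hat},
        b_se={"pop": b_se},
        freqs={"pop": np.asarray(freqs, dtype=float)},
        n_records=n,
        u_hat=u_hat,
    )


def ebv_purebred(fit: EvaluationFit) -> np.ndarray:
    """Candidate breeding values from a GBLUP fit (fg contribution
    excluded)."""
    if fit.model != "gblup" or fit.u_hat is None:
        raise ValueError("purebred-scale EBV requires a GBLUP fit")
    return fit.u_hat[fit.n_records :]


def ebv_crossbred(
    candidate_dosages: np.ndarray,
    fit: EvaluationFit,
    own_freqs: np.ndarray,
    opposite_freqs: np.ndarray,
) -> np.ndarray:
    """Crossbred-scale EBV of purebred candidates.

    EBVC_i = sum_j (z_ij - 2 p_own,j) (a_C,j + (q_opp,j - p_opp,j) d_C,j)
    with CB-population SNP effect estimates.
    """
    if fit.a_hat is None or fit.d_hat is None:
        raise ValueError("crossbred-scale EBV requires a fit with additive "
                         "and dominance SNP effects (trivariate model)")
    c = _POPS.index("CB")
    p_own = np.asarray(own_freqs, dtype=float)
    p_opp = np.asarray(opposite_freqs, dtype=float)
    alpha_c = fit.a_hat[c] + (1.0 - 2.0 * p_opp) * fit.d_hat[c]
    z = np.asarray(candidate_dosages, dtype=float)
    return (z - 2.0 * p_own) @ alpha_c


def write_fit(fit: EvaluationFit, path) -> None:
    """Serialize a fit as TSV: a summary block (per-population intercept,
    depression regression, solver diagnostics) then, for SNP-effect fits,
    one row per marker with the additive and dominance solutions."""
    import pandas as pd

    with open(path, "w") as fh:
        fh.write(f"# model={fit.model} n_records={fit.n_records} "
                 f"iterations={fit.iterations} converged={fit.converged} "
                 f"residual={fit.residual:.3e}\n")
        for pop in fit.mu:
            fh.write(f"# {pop}: mu={fit.mu[pop]:.10g} b_hat={fit.b_hat[pop]:.10g} "
                     f"b_se={fit.b_se[pop]:.10g}\n")
        if fit.a_hat is not None:
            cols = {}
            for t, pop in enumerate(_POPS):
                cols[f"a_{pop}"] = fit.a_hat[t]
                cols[f"d_{pop}"] = fit.d_hat[t]
            pd.DataFrame(cols).to_csv(fh, sep="\t", index=False)
        elif fit.u_hat is not None:
            pd.DataFrame({"u_hat": fit.u_hat}).to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# trivariate SNP-BLUP
# ---------------------------------------------------------------------------


def _prior_precisions(
    sigma_u: np.ndarray,
    sigma_v: np.ndarray,
    sigma_e: np.ndarray,
    r_qtl: float,
    freqs: dict[str, np.ndarray],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """3x3 across-population prior covariances of per-SNP additive and
    dominance effects, and their inverses."""

    def cov(scales):
        root = np.sqrt(np.outer(scales, scales))
        c = r_qtl * root
        np.fill_diagonal(c, scales)
        return c

    s_add = np.empty(3)
    s_dom = np.empty(3)
    for t, pop in enumerate(_POPS):
        p = freqs[pop]
        w = 2.0 * p * (1.0 - p)
        s_add[t] = sigma_u[t] / max(np.sum(w), 1e-12)
        s_dom[t] = sigma_v[t] / max(np.sum(w**2), 1e-12)
    cov_a = cov(s_add)
    cov_d = cov(np.maximum(s_dom, 1e-12))
    eva = np.linalg.eigvalsh(cov_a)
    if eva.min() < -1e-10 * eva.max():
        raise ValueError("assumed effect covariance not positive semi-definite")
    return cov_a, cov_d, np.linalg.inv(cov_a), np.linalg.inv(cov_d)


def trivariate_snpblup_fit(
    data: dict[str, PopRecords | None],
    sigma_u: np.ndarray,
    sigma_v: np.ndarray,
    sigma_e: np.ndarray,
    r_qtl: float,
    freqs: dict[str, np.ndarray],
    dense_limit: int = 5000,
    tol: float = 1e-8,
    max_iter: int = 5000,
    compute_se: bool = False,
) -> EvaluationFit:
    """Joint additive + dominance SNP-BLUP over P1, P2 and CB records.

    ``data`` maps population name to its records (``None`` or zero rows
    allowed: effects of an unobserved population are still estimated
    through the across-population correlation).  ``freqs`` supplies the
    per-population allele frequencies used for covariate coding and prior
    scaling.  Residuals are independent across populations.
    """
    sigma_u = np.asarray(sigma_u, dtype=float)
    sigma_v = np.asarray(sigma_v, dtype=float)
    sigma_e = np.asarray(sigma_e, dtype=float)
    p_len = {len(np.asarray(freqs[pop])) for pop in _POPS}
    if len(p_len) != 1:
        raise ValueError("per-population frequency vectors differ in length")
    p = p_len.pop()

    _, _, lam_a, lam_d = _prior_precisions(sigma_u, sigma_v, sigma_e, r_qtl, freqs)

    # per-population designs
    Xs, Zs, Ws, ys, rinv, has_fg = {}, {}, {}, {}, {}, {}
    n_total = 0
    for t, pop in enumerate(_POPS):
        rec = data.get(pop)
        if rec is None or rec.n == 0:
            Xs[pop] = None
            continue
        pf = np.asarray(freqs[pop], dtype=float)
        z = rec.dosages.astype(np.float64)
        Zs[pop] = z - 2.0 * pf
        Ws[pop] = (z == 1).astype(np.float64) - 2.0 * pf * (1.0 - pf)
        Xs[pop], has_fg[pop] = _fixed_design(rec.n, rec.fg)
        ys[pop] = rec.y.astype(np.float64)
        rinv[pop] = 1.0 / sigma_e[t]
        n_total += rec.n

    obs_pops = [pop for pop in _POPS if Xs.get(pop) is not None]
    f_sizes = {pop: Xs[pop].shape[1] for pop in obs_pops}
    n_fixed = sum(f_sizes.values())
    n_unknown = n_fixed + 6 * p

    # block offsets: [fixed..., a_P1, a_P2, a_CB, d_P1, d_P2, d_CB]
    f_off = {}
    off = 0
    for pop in obs_pops:
        f_off[pop] = off
        off += f_sizes[pop]
    a_off = lambda t: n_fixed + t * p
    d_off = lambda t: n_fixed + 3 * p + t * p

    def rhs_vector():
        r = np.zeros(n_unknown)
        for pop in obs_pops:
            t = _POPS.index(pop)
            ry = ys[pop] * rinv[pop]
            r[f_off[pop] : f_off[pop] + f_sizes[pop]] = Xs[pop].T @ ry
            r[a_off(t) : a_off(t) + p] = Zs[pop].T @ ry
            r[d_off(t) : d_off(t) + p] = Ws[pop].T @ ry
        return r

    def apply_A(theta):
        out = np.zeros(n_unknown)
        A = theta[n_fixed : n_fixed + 3 * p].reshape(3, p)
        D = theta[n_fixed + 3 * p :].reshape(3, p)
        # data part
        for pop in obs_pops:
            t = _POPS.index(pop)
            lin = (
                Xs[pop] @ theta[f_off[pop] : f_off[pop] + f_sizes[pop]]
                + Zs[pop] @ A[t]
                + Ws[pop] @ D[t]
            ) * rinv[pop]
            out[f_off[pop] : f_off[pop] + f_sizes[pop]] += Xs[pop].T @ lin
            out[a_off(t) : a_off(t) + p] += Zs[pop].T @ lin
            out[d_off(t) : d_off(t) + p] += Ws[pop].T @ lin
        # prior part couples populations per SNP
        out[n_fixed : n_fixed + 3 * p] += (lam_a @ A).reshape(-1)
        out[n_fixed + 3 * p :] += (lam_d @ D).reshape(-1)
        return out

    rhs = rhs_vector()

    if n_unknown <= dense_limit:
        C = np.zeros((n_unknown, n_unknown))
        for pop in obs_pops:
            t = _POPS.index(pop)
            H = np.hstack([Xs[pop], Zs[pop], Ws[pop]])
            HtH = (H.T @ H) * rinv[pop]
            idx = np.concatenate([
                np.arange(f_off[pop], f_off[pop] + f_sizes[pop]),
                np.arange(a_off(t), a_off(t) + p),
                np.arange(d_off(t), d_off(t) + p),
            ])
            C[np.ix_(idx, idx)] += HtH
        j = np.arange(p)
        for t1 in range(3):
            for t2 in range(3):
                C[a_off(t1) + j, a_off(t2) + j] += lam_a[t1, t2]
                C[d_off(t1) + j, d_off(t2) + j] += lam_d[t1, t2]
        theta = np.linalg.solve(C, rhs)
        it, converged = 1, True
        res_norm = float(np.linalg.norm(C @ theta - rhs) / max(np.linalg.norm(rhs), 1e-300))
        Cinv_diag = np.diag(np.linalg.inv(C)) if compute_se else None
    else:
        theta, it, converged, res_norm = _pcg(apply_A, rhs, _jacobi_diag(
            obs_pops, Xs, Zs, Ws, rinv, lam_a, lam_d, f_off, f_sizes, n_fixed, p
        ), tol, max_iter)
        Cinv_diag = None

    A = theta[n_fixed : n_fixed + 3 * p].reshape(3, p).copy()
    D = theta[n_fixed + 3 * p :].reshape(3, p).copy()
    mu, b_hat, b_se = {}, {}, {}
    for pop in obs_pops:
        beta = theta[f_off[pop] : f_off[pop] + f_sizes[pop]]
        mu[pop] = float(beta[0])
        b_hat[pop] = float(beta[1]) if has_fg[pop] else float("nan")
        if Cinv_diag is not None and has_fg[pop]:
            b_se[pop] = float(np.sqrt(Cinv_diag[f_off[pop] + 1]))
        else:
            b_se[pop] = float("nan")
    if not converged:
        warnings.warn(
            f"trivariate SNP-BLUP did not converge: residual {res_norm:.2e} "
            f"after {it} iterations"
        )
    return EvaluationFit(
        model="trivariate",
        mu=mu, b_hat=b_hat, b_se=b_se,
        freqs={pop: np.asarray(freqs[pop], dtype=float) for pop in _POPS},
        n_records=n_total,
        a_hat=A, d_hat=D,
        iterations=it, converged=converged, residual=res_norm,
    )


def _jacobi_diag(obs_pops, Xs, Zs, Ws, rinv, lam_a, lam_d, f_off, f_sizes, n_fixed, p):
    diag = np.zeros(n_fixed + 6 * p)
    diag[n_fixed : n_fixed + 3 * p] = np.repeat(np.diag(lam_a), p)
    diag[n_fixed + 3 * p :] = np.repeat(np.diag(lam_d), p)
    for pop in obs_pops:
        t = _POPS.index(pop)
        diag[f_off[pop] : f_off[pop] + f_sizes[pop]] += (Xs[pop] ** 2).sum(axis=0) * rinv[pop]
        diag[n_fixed + t * p : n_fixed + (t + 1) * p] += (Zs[pop] ** 2).sum(axis=0) * rinv[pop]
        diag[n_fixed + (3 + t) * p : n_fixed + (4 + t) * p] += (Ws[pop] ** 2).sum(axis=0) * rinv[pop]
    return diag


def _pcg(apply_A, rhs, diag, tol, max_iter):
    """Jacobi-preconditioned conjugate gradients on the normal equations."""
    d = np.where(diag > 0, diag, 1.0)
    x = np.zeros_like(rhs)
    r = rhs.copy()
    z = r / d
    s = z.copy()
    rz = r @ z
    rhs_norm = max(np.linalg.norm(rhs), 1e-300)
    it = 0
    for it in range(1, max_iter + 1):
        As = apply_A(s)
        alpha = rz / (s @ As)
        x += alpha * s
        r -= alpha * As
        res = np.linalg.norm(r) / rhs_norm
        if res <= tol:
            return x, it, True, float(res)
        z = r / d
        rz_new = r @ z
        s = z + (rz_new / rz) * s
        rz = rz_new
    return x, it, False, float(np.linalg.norm(r) / rhs_norm)
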