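"""Two-stage landmarking: multivariate linear mixed models for covariate histories.

For each landmark age L, a trivariate linear mixed model is fitted by
maximum likelihood to all pre-L measurements of FEV1%, FVC% and weight of
the patients eligible at L:

    y_ik(age) = alpha_k + beta_k (age - L) + a_ik + b_ik (age - L) + eps_ik,

with the six random effects (intercept and slope per outcome) jointly
Gaussian with an unstructured 6x6 covariance and independent residuals
with outcome-specific variances.  Outcomes are z-scored on the pre-L data
before joint fitting (conditioning of the covariance) and back-transformed
afterwards.  Empirical-Bayes (BLUP) estimates give each patient's fitted
value and slope at the landmark age, which augment the landmark dataset as
additional predictors (the two-stage approach).

Estimation is by an expectation-maximization iteration (conditional
maximization for the fixed effects), which increases the log-likelihood at
every step; an optional REML criterion is optimized directly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .landmark import LandmarkDataset

__all__ = ["MixedModelFit", "fit_multivariate_mixed", "attach_mixed_features", "DEFAULT_MIXED_OUTCOMES"]

DEFAULT_MIXED_OUTCOMES: Tuple[str, ...] = ("fev1_pct", "fvc_pct", "weight")


@dataclass
class MixedModelFit:
    """ML fit of the trivariate random-intercept/slope model at landmark L.

    ``random_effects_covariance`` is ordered (intercept, slope) per outcome;
    all reported quantities are on the original measurement scales.
    """

    L: float
    outcomes: Tuple[str, ...]
    fixed_effects: Dict[str, Dict[str, float]]
    random_effects_covariance: np.ndarray
    residual_variances: Dict[str, float]
    per_patient_blups: pd.DataFrame
    loglik: float
    loglik_trace: List[float]
    n_patients: int
    n_observations: int
    converged: bool
    reml: bool = False


def _prepare(reviews: pd.DataFrame, L: float, outcomes: Sequence[str], patient_ids):
    pre = reviews[reviews["age"] <= L]
    if patient_ids is not None:
        pre = pre[pre["patient_id"].isin(np.asarray(patient_ids))]
    pre = pre.sort_values(["patient_id", "age"], kind="mergesort")
    if pre["age"].nunique() < 2:
        raise ValueError("fewer than 2 distinct observation ages; slopes are unidentifiable")
    return pre


def fit_multivariate_mixed(
    reviews: pd.DataFrame,
    L: float,
    outcomes: Sequence[str] = DEFAULT_MIXED_OUTCOMES,
    patient_ids: Optional[Sequence] = None,
    max_iter: int = 2000,
    tol: float = 1e-8,
    reml: bool = False,
) -> MixedModelFit:
    """Fit the multivariate mixed model to measurements up to age ``L``.

    ``reviews`` is the annual-reviews table (long format); ``patient_ids``
    optionally restricts to the landmark-eligible cohort.  Patients
    contribute whichever outcomes they have observed.
    """
    outcomes = tuple(outcomes)
    K = len(outcomes)
    q = 2 * K
    pre = _prepare(reviews, L, outcomes, patient_ids)

    # z-score each outcome on the pre-L data
    means = {k: float(pre[k].mean()) for k in outcomes}
    sds = {}
    for k in outcomes:
        sd = float(pre[k].std(ddof=0))
        sds[k] = sd if sd > 0 else 1.0

    # per-patient, per-outcome sufficient statistics:
    #   A_ik = Z_ik' Z_ik, c_ik = Z_ik' y_ik, yy_ik, n_ik  with Z rows (1, age-L)
    pid_codes, pid_index = pd.factorize(pre["patient_id"].to_numpy())
    n_pat = len(pid_index)
    A = np.zeros((n_pat, K, q, q))
    c = np.zeros((n_pat, K, q))
    yy = np.zeros((n_pat, K))
    counts = np.zeros((n_pat, K))
    ages = pre["age"].to_numpy(dtype=float) - L
    for kk, out in enumerate(outcomes):
        vals = pre[out].to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        z = (vals[ok] - means[out]) / sds[out]
        a = ages[ok]
        pc = pid_codes[ok]
        i0, i1 = 2 * kk, 2 * kk + 1
        np.add.at(counts, (pc, kk), 1.0)
        np.add.at(yy, (pc, kk), z**2)
        np.add.at(c, (pc, kk, np.full(len(pc), i0)), z)
        np.add.at(c, (pc, kk, np.full(len(pc), i1)), z * a)
        np.add.at(A, (pc, kk, np.full(len(pc), i0), np.full(len(pc), i0)), 1.0)
        np.add.at(A, (pc, kk, np.full(len(pc), i0), np.full(len(pc), i1)), a)
        np.add.at(A, (pc, kk, np.full(len(pc), i1), np.full(len(pc), i0)), a)
        np.add.at(A, (pc, kk, np.full(len(pc), i1), np.full(len(pc), i1)), a**2)
    has_any = counts.sum(axis=1) > 0
    A, c, yy, counts = A[has_any], c[has_any], yy[has_any], counts[has_any]
    pid_kept = np.asarray(pid_index)[has_any]
    n_pat = len(pid_kept)
    n_obs = int(counts.sum())
    n_per_outcome = counts.sum(axis=0)  # observations per outcome

    # initial values
    sigma2 = np.full(K, 0.5)
    G = np.eye(q) * 0.5
    beta = np.zeros(q)

    def posterior(beta, G, sigma2):
        Ginv = np.linalg.inv(G)
        M = (A / sigma2[None, :, None, None]).sum(axis=1)  # (n, q, q)
        csum = (c / sigma2[None, :, None]).sum(axis=1)  # (n, q)
        Omega = np.linalg.inv(M + Ginv[None])
        d = csum - M @ beta
        mu = np.einsum("nij,nj->ni", Omega, d)
        return M, csum, Omega, d, mu, Ginv

    def loglik_at(beta, G, sigma2):
        M, csum, Omega, d, mu, Ginv = posterior(beta, G, sigma2)
        # r' R^-1 r with r = y - X beta  (X == Z design)
        quad_R = (
            (yy / sigma2[None, :]).sum()
            - 2 * np.einsum("j,nkj,k->", beta, c, 1.0 / sigma2)
            + np.einsum("i,nkij,j,k->", beta, A, beta, 1.0 / sigma2)
        )
        quad = quad_R - np.einsum("ni,nij,nj->", d, Omega, d)
        sign_g, logdet_G = np.linalg.slogdet(G)
        _, logdet_MG = np.linalg.slogdet(M + Ginv[None])
        logdet_R = float((counts * np.log(sigma2)[None, :]).sum())
        ll = -0.5 * (quad + logdet_R + n_pat * logdet_G + logdet_MG.sum() + n_obs * np.log(2 * np.pi))
        return float(ll), (M, csum, Omega, d, mu)

    trace: List[float] = []
    ll_old = -np.inf
    converged = False
    for it in range(max_iter):
        M, csum, Omega, d, mu, Ginv = posterior(beta, G, sigma2)
        # beta step: GLS using X == Z identities (Woodbury)
        XtVX = M.sum(axis=0) - np.einsum("nij,njk,nkl->il", M, Omega, M)
        XtVy = csum.sum(axis=0) - np.einsum("nij,njk,nk->i", M, Omega, csum)
        beta = np.linalg.solve(XtVX, XtVy)
        # E step at new beta
        M, csum, Omega, d, mu, Ginv = posterior(beta, G, sigma2)
        # M step
        G_new = (np.einsum("ni,nj->ij", mu, mu) + Omega.sum(axis=0)) / n_pat
        G_new = 0.5 * (G_new + G_new.T)
        try:
            np.linalg.cholesky(G_new + 1e-12 * np.eye(q))
        except np.linalg.LinAlgError:
            G_new += 1e-8 * np.eye(q)  # diagonal inflation for a non-PSD iterate
        bm = beta[None, :] + mu  # (n, q) total coefficient per patient
        sigma2_new = np.empty(K)
        for kk in range(K):
            ss = (
                yy[:, kk].sum()
                - 2 * np.einsum("ni,ni->", bm, c[:, kk, :])
                + np.einsum("ni,nij,nj->", bm, A[:, kk], bm)
            )
            tr = np.einsum("nij,nji->", A[:, kk], Omega)
            sigma2_new[kk] = (ss + tr) / max(n_per_outcome[kk], 1.0)
        sigma2 = np.maximum(sigma2_new, 1e-10)
        G = G_new
        ll, _ = loglik_at(beta, G, sigma2)
        trace.append(ll)
        if np.isfinite(ll_old) and abs(ll - ll_old) <= tol * (1.0 + abs(ll)):
            converged = True
            ll_old = ll
            break
        ll_old = ll

    if reml:
        beta, G, sigma2, ll_reml = _reml_optimize(A, c, yy, counts, n_per_outcome, beta, G, sigma2)
        trace.append(ll_reml)
        ll_old = ll_reml
        converged = True

    ll_final, (M, csum, Omega, d, mu) = loglik_at(beta, G, sigma2)

    # BLUPs on the original scales
    blups = {}
    for kk, out in enumerate(outcomes):
        i0, i1 = 2 * kk, 2 * kk + 1
        fit_z = beta[i0] + mu[:, i0]
        slope_z = beta[i1] + mu[:, i1]
        blups[f"{out}_fit"] = means[out] + sds[out] * fit_z
        blups[f"{out}_slope"] = sds[out] * slope_z
    blup_df = pd.DataFrame(blups, index=pd.Index(pid_kept, name="patient_id"))

    D = np.diag([sds[out] for out in outcomes for _ in range(2)])
    G_orig = D @ G @ D
    fixed = {
        out: {
            "intercept": means[out] + sds[out] * beta[2 * kk],
            "slope": sds[out] * beta[2 * kk + 1],
        }
        for kk, out in enumerate(outcomes)
    }
    resid = {out: float(sigma2[kk] * sds[out] ** 2) for kk, out in enumerate(outcomes)}

    return MixedModelFit(
        L=float(L),
        outcomes=outcomes,
        fixed_effects=fixed,
        random_effects_covariance=G_orig,
        residual_variances=resid,
        per_patient_blups=blup_df,
        loglik=float(ll_final),
        loglik_trace=trace,
        n_patients=n_pat,
        n_observations=n_obs,
        converged=converged,
        reml=reml,
    )


def _reml_optimize(A, c, yy, counts, n_per_outcome, beta0, G0, sigma2_0):
    """Direct optimization of the REML criterion (used when reml=True)."""
    from scipy import optimize

    q = G0.shape[0]
    K = len(sigma2_0)
    tril = np.tril_indices(q)

    def unpack(theta):
        sigma2 = np.exp(theta[:K])
        Lmat = np.zeros((q, q))
        Lmat[tril] = theta[K:]
        d = np.arange(q)
        Lmat[d, d] = np.exp(Lmat[d, d])
        G = Lmat @ Lmat.T
        return sigma2, G

    def negloglik(theta):
        sigma2, G = unpack(theta)
        Ginv = np.linalg.inv(G + 1e-12 * np.eye(q))
        M = (A / sigma2[None, :, None, None]).sum(axis=1)
        csum = (c / sigma2[None, :, None]).sum(axis=1)
        Omega = np.linalg.inv(M + Ginv[None])
        XtVX = M.sum(axis=0) - np.einsum("nij,njk,nkl->il", M, Omega, M)
        XtVy = csum.sum(axis=0) - np.einsum("nij,njk,nk->i", M, Omega, csum)
        beta = np.linalg.solve(XtVX, XtVy)
        d = csum - M @ beta
        quad_R = (
            (yy / sigma2[None, :]).sum()
            - 2 * np.einsum("j,nkj,k->", beta, c, 1.0 / sigma2)
            + np.einsum("i,nkij,j,k->", beta, A, beta, 1.0 / sigma2)
        )
        quad = quad_R - np.einsum("ni,nij,nj->", d, Omega, d)
        _, logdet_G = np.linalg.slogdet(G + 1e-12 * np.eye(q))
        _, logdet_MG = np.linalg.slogdet(M + Ginv[None])
        logdet_R = float((counts * np.log(sigma2)[None, :]).sum())
        _, logdet_XtVX = np.linalg.slogdet(XtVX)
        n = counts.sum()
        return 0.5 * (quad + logdet_R + len(A) * logdet_G + logdet_MG.sum() + logdet_XtVX)

    L0 = np.linalg.cholesky(G0 + 1e-8 * np.eye(q))
    theta0 = np.concatenate([np.log(sigma2_0), _pack_chol(L0, tril)])
    res = optimize.minimize(negloglik, theta0, method="L-BFGS-B", options={"maxiter": 500})
    sigma2, G = unpack(res.x)
    Ginv = np.linalg.inv(G + 1e-12 * np.eye(q))
    M = (A / sigma2[None, :, None, None]).sum(axis=1)
    csum = (c / sigma2[None, :, None]).sum(axis=1)
    Omega = np.linalg.inv(M + Ginv[None])
    XtVX = M.sum(axis=0) - np.einsum("nij,njk,nkl->il", M, Omega, M)
    XtVy = csum.sum(axis=0) - np.einsum("nij,njk,nk->i", M, Omega, csum)
    beta = np.linalg.solve(XtVX, XtVy)
    return beta, G, sigma2, -float(res.fun)


def _pack_chol(Lmat, tril):
    out = Lmat[tril].copy()
    q = Lmat.shape[0]
    flat_idx = {(i, j): k for k, (i, j) in enumerate(zip(*tril))}
    for d in range(q):
        out[flat_idx[(d, d)]] = np.log(max(Lmat[d, d], 1e-8))
    return out


def attach_mixed_features(landmark_dataset: LandmarkDataset, fit: MixedModelFit) -> LandmarkDataset:
    """Append the six fitted-value/slope columns to a landmark dataset.

    Records without BLUPs (no usable pre-L measurements in the mixed fit)
    are excluded and counted in the exclusion log.
    """
    if float(fit.L) != float(landmark_dataset.L):
        raise ValueError(f"mixed fit is for L={fit.L} but dataset has L={landmark_dataset.L}")
    rec = landmark_dataset.records.merge(
        fit.per_patient_blups, left_on="patient_id", right_index=True, how="left"
    )
    cols = list(fit.per_patient_blups.columns)
    missing = rec[cols].isna().any(axis=1)
    log = dict(landmark_dataset.exclusion_log)
    log["missing_mixed_blup"] = log.get("missing_mixed_blup", 0) + int(missing.sum())
    rec = rec[~missing].reset_index(drop=True)
    return LandmarkDataset(L=landmark_dataset.L, records=rec, exclusion_log=log)
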