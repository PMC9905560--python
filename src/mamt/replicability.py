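"""Replicability assessment of meta-analysis signals.

A two-component mixture model scores each variant with a posterior
probability of replicability (PPR) from the strength and consistency of
its per-study effects.  Replicable variants carry a genuine shared
effect mu_j ~ N(0, tau2) observed with per-study noise; non-replicable
variants have mu_j = 0, but each study independently may be an outlier
(probability lambda_o) with its sampling variance inflated by a factor
alpha > 1.  To remove ancestry-driven effect heterogeneity before
fitting, effects are first residualized by weighted meta-regression on
principal components of the studies' genome-wide allele-frequency
profiles; residual variances are passed through unchanged (the
regression degrees of freedom are not charged — see the methods note).

Parameters are estimated by EM with the per-variant mean integrated out
in closed form; the observed-data log-likelihood is non-decreasing
across iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

_LOG2PI = np.log(2 * np.pi)


@dataclass
class AncestryPCs:
    """Principal-component scores of per-study allele-frequency profiles."""

    scores: np.ndarray  # studies x m
    explained_variance: np.ndarray
    loadings: np.ndarray  # variants x m


def ancestry_pcs(freqs: np.ndarray, m: int | None = None) -> AncestryPCs:
    """PCA of a study×variant allele-frequency matrix.

    Columns (variants) are centered across studies; scores are U·S from
    the SVD of the centered matrix.  The sign of each component is fixed
    by making its largest-magnitude loading positive, so results are
    deterministic.  ``m`` defaults to min(2, studies − 1).
    """
    f = np.asarray(freqs, float)
    if f.ndim != 2:
        raise ValueError("freqs must be a study×variant matrix")
    k = f.shape[0]
    if m is None:
        m = min(2, k - 1)
    if m > k - 1:
        raise ValueError(f"m={m} exceeds studies−1={k - 1}")
    centered = f - f.mean(axis=0, keepdims=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    u, s, vt = u[:, :m], s[:m], vt[:m]
    for i in range(m):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    scores = u * s
    ev = s**2 / max(k - 1, 1)
    return AncestryPCs(scores=scores, explained_variance=ev, loadings=vt.T)


def ancestry_adjust(
    betas: np.ndarray, ses: np.ndarray, pcs: AncestryPCs
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Residualize per-study effects on ancestry PCs by weighted meta-regression.

    ``betas``/``ses`` are variant×study matrices (NaN = unobserved).
    Per variant, a WLS fit of the observed betas on [1, PC scores] with
    weights 1/se² is removed; SEs pass through unchanged.  Variants
    observed in fewer than m+2 studies are passed through unadjusted and
    flagged in the returned boolean vector.
    """
    B = np.atleast_2d(np.asarray(betas, float))
    S = np.atleast_2d(np.asarray(ses, float))
    X_full = np.column_stack([np.ones(pcs.scores.shape[0]), pcs.scores])
    m = pcs.scores.shape[1]
    resid = B.copy()
    adjusted = np.zeros(B.shape[0], dtype=bool)
    for j in range(B.shape[0]):
        obs = np.isfinite(B[j]) & np.isfinite(S[j])
        if obs.sum() < m + 2:
            continue
        X = X_full[obs]
        w = 1.0 / S[j, obs] ** 2
        Xw = X * w[:, None]
        try:
            coef = np.linalg.solve(X.T @ Xw, Xw.T @ B[j, obs])
        except np.linalg.LinAlgError:
            continue
        resid[j, obs] = B[j, obs] - X @ coef
        adjusted[j] = True
    return resid, S, adjusted


@dataclass
class MambaFit:
    """Fitted mixture parameters and per-variant posteriors."""

    pi: float
    tau2: float
    lambda_o: float
    alpha: float
    ppr: np.ndarray
    loglik_trace: list = field(default_factory=list)
    converged: bool = True

    @property
    def loglik(self) -> float:
        return self.loglik_trace[-1] if self.loglik_trace else float("nan")


def _log_replicable(B, S2, obs, tau2):
    """log N(beta; 0, D + tau2*11') per variant via Sherman–Morrison."""
    inv = np.where(obs, 1.0 / S2, 0.0)
    a = inv.sum(axis=1)
    c = np.where(obs, B, 0.0) * inv
    c = c.sum(axis=1)
    q = (np.where(obs, B, 0.0) ** 2 * inv).sum(axis=1)
    k = obs.sum(axis=1)
    logdet = np.where(obs, np.log(S2, where=obs, out=np.zeros_like(S2)), 0.0).sum(axis=1)
    denom = 1.0 + tau2 * a
    quad = q - tau2 * c**2 / denom
    return -0.5 * (k * _LOG2PI + logdet + np.log(denom) + quad)


def _log_null_parts(B, S2, obs, lambda_o, alpha):
    """Per-entry log densities of the null mixture and outlier posteriors."""
    with np.errstate(divide="ignore", invalid="ignore"):
        lp_in = -0.5 * (_LOG2PI + np.log(S2) + B**2 / S2)
        lp_out = -0.5 * (_LOG2PI + np.log(alpha * S2) + B**2 / (alpha * S2))
    la = np.log1p(-lambda_o) + lp_in
    lb = np.log(lambda_o) + lp_out
    lmix = np.logaddexp(la, lb)
    q_out = np.exp(lb - lmix)
    lmix = np.where(obs, lmix, 0.0)
    q_out = np.where(obs, q_out, 0.0)
    return lmix.sum(axis=1), q_out


def _posterior(B, S2, obs, pi, tau2, lambda_o, alpha):
    l1 = _log_replicable(B, S2, obs, tau2)
    l0, q_out = _log_null_parts(B, S2, obs, lambda_o, alpha)
    num = np.log(pi) + l1
    den = np.log1p(-pi) + l0
    ll = logsumexp(np.stack([num, den]), axis=0)
    ppr = np.exp(num - ll)
    return ppr, q_out, float(ll.sum()), l1, l0


def mamba_posterior(
    betas: np.ndarray, ses: np.ndarray, pi: float, tau2: float, lambda_o: float, alpha: float
) -> np.ndarray:
    """PPR per variant under fixed mixture parameters (no fitting)."""
    B = np.atleast_2d(np.asarray(betas, float))
    S = np.atleast_2d(np.asarray(ses, float))
    obs = np.isfinite(B) & np.isfinite(S)
    S2 = np.where(obs, S**2, 1.0)
    Bo = np.where(obs, B, 0.0)
    ppr, _, _, _, _ = _posterior(Bo, S2, obs, pi, tau2, lambda_o, alpha)
    return ppr


def fit_mamba(
    betas: np.ndarray,
    ses: np.ndarray,
    init: MambaFit | None = None,
    tol: float = 1e-6,
    max_iter: int = 2000,
    n_restarts: int = 5,
    seed: int = 0,
) -> MambaFit:
    """Fit the replicability mixture by EM.

    ``betas``/``ses`` are variant×study matrices with NaN marking
    missing entries; each variant needs ≥2 observed studies.  The EM
    alternates closed-form posteriors (variant replicability R_j and
    per-entry outlier indicators O_jk) with exact M-steps; ``tol`` is a
    relative change threshold on the log-likelihood.  Because the
    likelihood is multimodal, ``n_restarts`` jittered initializations
    are run (seeded) and the best kept.  Default initialization:
    pi=0.1, tau2 at the 90th percentile of max(beta² − se², 0),
    lambda_o=0.01, alpha=5.
    """
    B = np.atleast_2d(np.asarray(betas, float))
    S = np.atleast_2d(np.asarray(ses, float))
    obs = np.isfinite(B) & np.isfinite(S)
    if np.any(obs.sum(axis=1) < 2):
        raise ValueError("each variant must be observed in at least 2 studies")
    S2 = np.where(obs, S**2, 1.0)
    Bo = np.where(obs, B, 0.0)

    excess = np.where(obs, B**2 - S**2, np.nan)
    tau2_0 = float(np.nanpercentile(np.clip(excess, 0, None), 90))
    tau2_0 = max(tau2_0, 1e-8)
    base = (0.1, tau2_0, 0.01, 5.0) if init is None else (init.pi, init.tau2, init.lambda_o, init.alpha)

    rng = np.random.default_rng(seed)
    best: MambaFit | None = None
    for r in range(max(n_restarts, 1)):
        if r == 0:
            pi, tau2, lam, alpha = base
        else:
            jit = rng.uniform(0.5, 2.0, size=4)
            pi = float(np.clip(base[0] * jit[0], 1e-3, 0.9))
            tau2 = base[1] * jit[1]
            lam = float(np.clip(base[2] * jit[2], 1e-4, 0.5))
            alpha = max(base[3] * jit[3], 1.5)
        fit = _em(Bo, S2, obs, pi, tau2, lam, alpha, tol, max_iter)
        if best is None or fit.loglik > best.loglik:
            best = fit
    return best


def _em(B, S2, obs, pi, tau2, lam, alpha, tol, max_iter) -> MambaFit:
    trace: list[float] = []
    converged = False
    inv = np.where(obs, 1.0 / S2, 0.0)
    a = inv.sum(axis=1)
    for _ in range(max_iter):
        ppr, q_out, ll, _, _ = _posterior(B, S2, obs, pi, tau2, lam, alpha)
        trace.append(ll)
        if len(trace) > 1 and abs(trace[-1] - trace[-2]) < tol * (abs(trace[-2]) + 1e-12):
            converged = True
            break
        # M-step
        pi = float(np.clip(ppr.mean(), 1e-6, 1 - 1e-6))
        c = (B * inv).sum(axis=1)
        v = 1.0 / (1.0 / max(tau2, 1e-300) + a)
        mu = v * c
        tau2 = float(np.clip((ppr * (mu**2 + v)).sum() / max(ppr.sum(), 1e-300), 1e-12, None))
        w0 = (1.0 - ppr)[:, None] * q_out
        denom_lam = ((1.0 - ppr)[:, None] * obs).sum()
        lam = float(np.clip(w0.sum() / max(denom_lam, 1e-300), 1e-6, 1 - 1e-6))
        num_a = (w0 * np.where(obs, B**2 / S2, 0.0)).sum()
        alpha = float(np.clip(num_a / max(w0.sum(), 1e-300), 1.0 + 1e-6, None))
    ppr, _, ll, _, _ = _posterior(B, S2, obs, pi, tau2, lam, alpha)
    trace.append(ll)
    return MambaFit(pi=pi, tau2=tau2, lambda_o=lam, alpha=alpha, ppr=ppr,
                    loglik_trace=trace, converged=converged)


def classify_replicable(fit: MambaFit, threshold: float = 0.90) -> np.ndarray:
    """Replicability call per variant: strictly PPR > threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return fit.ppr > threshold
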