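"""Multi-trait combination gated by genetic correlation.

The workflow mirrors a multi-ancestry, multi-trait (MAMT) meta-analysis:
per-ancestry per-trait IVW pooling; cross-trait LD-score regression on
the best-powered reference ancestry to estimate genetic correlations
with the target trait; Benjamini–Hochberg selection of correlated
auxiliary traits; a moment-based generalized-least-squares (GLS)
combination of z-scores across the selected traits within each ancestry
(excluding the HLA region, whose outlier effects violate the
homogeneous-covariance assumption); and a final cross-ancestry IVW
meta-analysis of the target trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .meta import ivw_meta, meta_to_study
from .sumstats import HLA_REGION, StudyTable, restrict_variants

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RgEstimate:
    """Cross-trait genetic correlation with jackknife uncertainty."""

    trait_a: str
    trait_b: str
    rg: float
    se: float
    pvalue: float
    h2_a: float
    h2_b: float
    gencov: float
    q_fdr: float = float("nan")


def _wls_slope(y: np.ndarray, x: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    """Weighted least squares of y on [1, x]; returns (intercept, slope)."""
    sw = w.sum()
    mx = (w * x).sum() / sw
    my = (w * y).sum() / sw
    sxx = (w * (x - mx) ** 2).sum()
    sxy = (w * (x - mx) * (y - my)).sum()
    slope = sxy / sxx
    return my - slope * mx, slope


def _ldsc_components(
    z1: np.ndarray, z2: np.ndarray, ell: np.ndarray, n1: float, n2: float, m: int
) -> tuple[float, float, float]:
    """Single-pass LDSC slopes: (h2_1, h2_2, genetic covariance).

    Heritabilities come from regressing χ² on N·ℓ/M; the genetic
    covariance from regressing z1·z2 on √(N1 N2)·ℓ/M.  A free intercept
    absorbs confounding/sample overlap; weights are 1/ℓ (single step,
    no iterative reweighting).
    """
    w = 1.0 / ell
    _, h2_1 = _wls_slope(z1**2, n1 * ell / m, w)
    _, h2_2 = _wls_slope(z2**2, n2 * ell / m, w)
    _, gcov = _wls_slope(z1 * z2, np.sqrt(n1 * n2) * ell / m, w)
    return h2_1, h2_2, gcov


def cross_trait_ldsc(
    z1: np.ndarray,
    z2: np.ndarray,
    ldscores: np.ndarray,
    n1: float,
    n2: float,
    n_blocks: int = 200,
    trait_a: str = "trait_a",
    trait_b: str = "trait_b",
) -> RgEstimate:
    """Genetic correlation between two traits from aligned z-scores.

    rg = gencov / √(h²₁ h²₂), with slopes from LD-score regression and
    the standard error from a delete-one block jackknife over
    ``n_blocks`` contiguous variant blocks.  The p-value is a two-sided
    normal test of rg = 0.
    """
    z1 = np.asarray(z1, float)
    z2 = np.asarray(z2, float)
    ell = np.asarray(ldscores, float)
    if np.any(ell <= 0):
        raise ValueError("LD scores must be positive")
    m = z1.size
    if m < 2 * n_blocks:
        raise ValueError(f"need at least {2 * n_blocks} variants for {n_blocks} jackknife blocks")

    def rg_of(idx: np.ndarray) -> float:
        h1, h2, gc = _ldsc_components(z1[idx], z2[idx], ell[idx], n1, n2, m)
        denom = np.sqrt(max(h1, 1e-12) * max(h2, 1e-12))
        return float(np.clip(gc / denom, -1.25, 1.25))

    full_idx = np.arange(m)
    rg = rg_of(full_idx)
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    pseudo = []
    for b in range(n_blocks):
        keep = np.concatenate([full_idx[: bounds[b]], full_idx[bounds[b + 1] :]])
        pseudo.append(rg_of(keep))
    pseudo = np.asarray(pseudo)
    se = float(np.sqrt((n_blocks - 1) / n_blocks * np.sum((pseudo - pseudo.mean()) ** 2)))
    se = max(se, 1e-12)
    p = float(2 * stats.norm.sf(abs(rg) / se))
    h1, h2, gc = _ldsc_components(z1, z2, ell, n1, n2, m)
    return RgEstimate(trait_a, trait_b, rg, se, max(min(p, 1.0), np.finfo(float).tiny), h1, h2, gc)


def fdr_select(rg_results: Sequence[RgEstimate], q: float = 0.05) -> list[str]:
    """Benjamini–Hochberg selection of traits correlated with the target."""
    if not 0 < q < 1:
        raise ValueError("q must be in (0, 1)")
    if not rg_results:
        return []
    pvals = np.array([r.pvalue for r in rg_results])
    reject, _, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")[:4]
    return [r.trait_b for r, rej in zip(rg_results, reject) if rej]


def attach_qvalues(rg_results: Sequence[RgEstimate]) -> list[RgEstimate]:
    """Return copies carrying BH-adjusted q-values."""
    if not rg_results:
        return []
    pvals = np.array([r.pvalue for r in rg_results])
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        RgEstimate(r.trait_a, r.trait_b, r.rg, r.se, r.pvalue, r.h2_a, r.h2_b, r.gencov, float(qv))
        for r, qv in zip(rg_results, qvals)
    ]


@dataclass(frozen=True)
class OmegaSigma:
    """Per-variant genetic covariance Ω and sampling covariance Σ of
    z-scores across traits (Σ has unit diagonal)."""

    omega: np.ndarray
    sigma: np.ndarray
    traits: tuple[str, ...] = ()


def _nearest_psd(a: np.ndarray) -> np.ndarray:
    a = (a + a.T) / 2
    vals, vecs = np.linalg.eigh(a)
    return (vecs * np.clip(vals, 0, None)) @ vecs.T


def estimate_omega_sigma(
    z: np.ndarray,
    null_mask: np.ndarray | None = None,
    null_z_max: float = 2.0,
    traits: Sequence[str] = (),
) -> OmegaSigma:
    """Moment estimates of the trait covariance structure of z-scores.

    Σ is the correlation of z restricted to null-looking variants
    (max |z| < ``null_z_max`` across traits unless an explicit mask is
    given), capturing sampling correlation from sample overlap.  Ω is
    the empirical second-moment matrix of z minus Σ, projected onto the
    positive-semidefinite cone by eigenvalue clipping.
    """
    z = np.asarray(z, float)
    if z.ndim != 2 or z.shape[1] < 2:
        raise ValueError("z must be a variant×trait matrix with ≥2 traits")
    if null_mask is None:
        null_mask = np.max(np.abs(z), axis=1) < null_z_max
    null_mask = np.asarray(null_mask, bool)
    n_null = int(null_mask.sum())
    if n_null < 100:
        logger.warning("only %d variants in the null mask for sigma estimation", n_null)
    if n_null < 2:
        raise ValueError("too few null variants to estimate sigma")
    sigma = np.corrcoef(z[null_mask].T)
    np.fill_diagonal(sigma, 1.0)
    if not np.all(np.isfinite(sigma)):
        raise ValueError("sigma estimate is not finite (zero-variance trait?)")
    # exactly duplicated traits make sigma singular; report it, the GLS
    # combiner raises when the combined covariance cannot be inverted
    if np.linalg.matrix_rank(sigma) < z.shape[1]:
        logger.warning("sigma estimate is singular (duplicated traits?)")
    second = z.T @ z / z.shape[0]
    omega = _nearest_psd(second - sigma)
    return OmegaSigma(omega=omega, sigma=sigma, traits=tuple(traits))


def mtag_combine(
    z: np.ndarray,
    ses: np.ndarray,
    model: OmegaSigma,
    target: int = 0,
) -> pd.DataFrame:
    """GLS combination of per-trait z-scores for the target trait.

    Under the moment condition that true per-variant effects across
    traits are proportional to the target's column of Ω, the target
    estimate is β̂_t = wᵀΛ⁻¹ẑ / (wᵀΛ⁻¹w) with w = ω_t/ω_tt and
    Λ = Ω − ω_tω_tᵀ/ω_tt + Σ, and effective standard error
    1/√(wᵀΛ⁻¹w) (all in z-score units).  Columns ``BETA``/``SE`` are
    rescaled to the target trait's effect scale via its input SEs, so
    ``Z = BETA/SE`` equals the z-scale estimate divided by its SE.
    With a single trait the input is returned unchanged; with diagonal
    Ω and Σ = I no strength is borrowed from other traits.
    """
    z = np.atleast_2d(np.asarray(z, float))
    ses = np.atleast_2d(np.asarray(ses, float))
    t = z.shape[1]
    if model.omega.shape != (t, t) or model.sigma.shape != (t, t):
        raise ValueError("model dimensions do not match trait count")
    se_t = ses[:, target]
    if t == 1:
        znew = z[:, 0]
        se_eff = np.ones_like(znew)
    else:
        omega, sigma = model.omega, model.sigma
        w_tt = omega[target, target]
        if w_tt <= 0:
            raise ValueError("target trait has non-positive genetic variance in omega")
        w = omega[:, target] / w_tt
        lam = omega - np.outer(omega[:, target], omega[:, target]) / w_tt + sigma
        try:
            lam_inv_w = np.linalg.solve(lam, w)
        except np.linalg.LinAlgError as e:
            raise ValueError("combined covariance is singular") from e
        denom = float(w @ lam_inv_w)
        if denom <= 0:
            raise ValueError("combined covariance is not positive definite")
        znew = z @ lam_inv_w / denom
        se_eff = np.full(z.shape[0], 1.0 / np.sqrt(denom))
    zscore = znew / se_eff
    return pd.DataFrame(
        {
            "BETA": znew * se_t,
            "SE": se_eff * se_t,
            "Z": zscore,
            "P": np.clip(stats.chi2.sf(zscore**2, df=1), np.finfo(float).tiny, 1.0),
        }
    )


def mamt_pipeline(
    studies: Sequence[StudyTable],
    target: str,
    ldscores: pd.Series,
    q: float = 0.05,
    reference_ancestry: str = "EUR",
    exclude_region: tuple[str, int, int] | None = HLA_REGION,
    n_blocks: int = 200,
    outdir: str | Path | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Full multi-ancestry multi-trait meta-analysis.

    Stages: (1) IVW pooling within each (ancestry, trait) cell;
    (2) cross-trait LDSC against the target on the reference ancestry and
    BH selection at FDR ``q``; (3) HLA exclusion and GLS multi-trait
    combination per ancestry over the selected traits; (4) cross-ancestry
    IVW of the target trait.  Returns the final MetaResult frame and a
    stage log; intermediates are written under ``outdir`` when given.

    ``ldscores`` is indexed by SNP id.
    """
    outdir = Path(outdir) if outdir is not None else None
    if outdir is not None:
        outdir.mkdir(parents=True, exist_ok=True)
    log: dict = {"stages": []}

    # stage 1: within-ancestry per-trait IVW
    cells: dict[tuple[str, str], StudyTable] = {}
    for (anc, trait) in sorted({(s.ancestry, s.trait) for s in studies}):
        group = [s for s in studies if s.ancestry == anc and s.trait == trait]
        pooled = ivw_meta(group)
        cells[(anc, trait)] = meta_to_study(pooled, ancestry=anc, trait=trait, study_id=f"{anc}:{trait}")
        if outdir is not None:
            pooled.to_csv(outdir / f"stage1_{anc}_{trait}.tsv", sep="\t", index=False)
    ancestries = sorted({a for a, _ in cells})
    traits = sorted({t for _, t in cells})
    for anc in ancestries:
        if (anc, target) not in cells:
            raise ValueError(f"target trait {target!r} missing in ancestry {anc!r}")
    log["stages"].append({"stage": 1, "cells": [f"{a}:{t}" for a, t in cells]})

    # stage 2: rg gating on the reference ancestry
    ref_anc = reference_ancestry if any(a == reference_ancestry for a in ancestries) else ancestries[0]
    aux_traits = [t for t in traits if t != target]
    selected: list[str] = []
    rgs: list[RgEstimate] = []
    if aux_traits:
        tgt = cells[(ref_anc, target)].df.set_index("SNP")
        for tr in aux_traits:
            if (ref_anc, tr) not in cells:
                continue
            aux = cells[(ref_anc, tr)].df.set_index("SNP")
            common = tgt.index.intersection(aux.index).intersection(ldscores.index)
            z1 = (tgt.loc[common, "BETA"] / tgt.loc[common, "SE"]).to_numpy()
            z2 = (aux.loc[common, "BETA"] / aux.loc[common, "SE"]).to_numpy()
            nb = min(n_blocks, len(common) // 2)
            rgs.append(
                cross_trait_ldsc(
                    z1, z2, ldscores.loc[common].to_numpy(),
                    float(tgt.loc[common, "N"].mean()), float(aux.loc[common, "N"].mean()),
                    n_blocks=max(nb, 2), trait_a=target, trait_b=tr,
                )
            )
        rgs = attach_qvalues(rgs)
        selected = fdr_select(rgs, q=q)
    log["stages"].append(
        {"stage": 2, "reference_ancestry": ref_anc, "selected_traits": selected,
         "rg": [{"trait": r.trait_b, "rg": r.rg, "p": r.pvalue, "q": r.q_fdr} for r in rgs]}
    )
    if outdir is not None and rgs:
        pd.DataFrame([r.__dict__ for r in rgs]).to_csv(outdir / "stage2_rg.tsv", sep="\t", index=False)

    # stage 3: per-ancestry multi-trait combination over [target] + selected
    per_ancestry: list[StudyTable] = []
    use_traits = [target] + [t for t in selected]
    for anc in ancestries:
        avail = [t for t in use_traits if (anc, t) in cells]
        tables = [cells[(anc, t)] for t in avail]
        if exclude_region is not None:
            tables = [restrict_variants(tb, exclude_regions=[exclude_region]) for tb in tables]
        if len(tables) == 1:
            per_ancestry.append(tables[0])
            continue
        base = tables[0].df.set_index("SNP")
        common = base.index
        for tb in tables[1:]:
            common = common.intersection(tb.df.set_index("SNP").index)
        zmat = np.column_stack(
            [
                (tb.df.set_index("SNP").loc[common, "BETA"] / tb.df.set_index("SNP").loc[common, "SE"]).to_numpy()
                for tb in tables
            ]
        )
        semat = np.column_stack(
            [tb.df.set_index("SNP").loc[common, "SE"].to_numpy() for tb in tables]
        )
        model = estimate_omega_sigma(zmat, traits=avail)
        combined = mtag_combine(zmat, semat, model, target=0)
        out = base.loc[common].reset_index()[["SNP", "CHR", "POS", "EA", "OA", "N", "EAF"]]
        out[["BETA", "SE", "Z", "P"]] = combined[["BETA", "SE", "Z", "P"]].to_numpy()
        per_ancestry.append(
            StudyTable(
                out[["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N", "EAF"]],
                ancestry=anc, trait=target, study_id=f"mamt:{anc}",
            )
        )
        if outdir is not None:
            out.to_csv(outdir / f"stage3_{anc}.tsv", sep="\t", index=False)
    log["stages"].append({"stage": 3, "ancestries": ancestries, "traits_used": use_traits})

    # stage 4: cross-ancestry IVW of the target
    final = ivw_meta(per_ancestry)
    if outdir is not None:
        final.to_csv(outdir / "stage4_final.tsv", sep="\t", index=False)
    log["stages"].append({"stage": 4, "n_variants": int(len(final))})
    return final, log
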