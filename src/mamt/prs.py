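"""Polygenic risk scores and their clinical evaluation.

Covers cohort genotype QC (PLINK-style filter chain), greedy clumping +
p-value thresholding (P+T) for score construction, EHR case definitions
of increasing stringency, clinical-lab binarization (ANA titers,
anti-dsDNA levels), and the diagnostic metrics used to judge a score:
Nagelkerke R² transformed to the liability scale under ascertained
case-control sampling, AUC with bootstrap confidence intervals and
DeLong model comparison, PRS-quintile odds ratios and lab-stratified
risk gradients, and the Youden operating point.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: The standard ladder of P+T p-value thresholds.
PT_THRESHOLDS = [5e-8, 5e-7, 1e-6, 5e-6, 5e-5, 5e-4, 5e-3, 0.01, 0.05, 0.10, 0.20, 0.50, 1.0]


@dataclass
class Cohort:
    """Individual-level data: dosages in [0,2] plus phenotype/covariates/labs."""

    dosages: pd.DataFrame                       # individuals x variants
    phenotype: pd.Series | None = None          # case boolean
    covariates: pd.DataFrame | None = None      # sex, PCs, HLA dosages
    ana_titer: pd.Series | None = None
    dsdna: pd.Series | None = None
    icd: pd.DataFrame | None = None             # individuals x ICD code counts
    eaf: pd.Series | None = None                # per-variant effect-allele freq

    def subset_individuals(self, keep: pd.Index) -> "Cohort":
        def sub(x):
            return x.loc[keep] if x is not None else None
        return replace(
            self, dosages=self.dosages.loc[keep], phenotype=sub(self.phenotype),
            covariates=sub(self.covariates), ana_titer=sub(self.ana_titer),
            dsdna=sub(self.dsdna), icd=sub(self.icd),
        )


# ---------------------------------------------------------------- cohort QC

def _hwe_pvalue(geno: np.ndarray) -> float:
    """χ²(1df) Hardy–Weinberg test on hard-called genotype counts."""
    g = geno[np.isfinite(geno)]
    n0 = float(np.sum(g == 0)); n1 = float(np.sum(g == 1)); n2 = float(np.sum(g == 2))
    n = n0 + n1 + n2
    if n == 0:
        return 1.0
    p = (2 * n2 + n1) / (2 * n)
    exp = np.array([n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2])
    obs = np.array([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.nansum(np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0))
    return float(stats.chi2.sf(chi2, df=1))


def qc_cohort(
    cohort: Cohort,
    geno: float = 0.01,
    mind: float = 0.01,
    maf: float = 0.05,
    hwe: float = 1e-6,
    het_sd: float = 3.0,
    rel_cutoff: float = 0.125,
) -> tuple[Cohort, dict]:
    """PLINK-style QC chain; returns the filtered cohort and step counts.

    In order: variant missingness > ``geno``; individual missingness >
    ``mind``; MAF < ``maf``; HWE p < ``hwe`` (χ² on hard calls);
    heterozygosity outliers (inbreeding coefficient beyond ``het_sd``
    SDs of the sample mean); greedy relatedness pruning at genomic
    relationship > ``rel_cutoff`` (the member with more missingness is
    dropped).
    """
    report: dict[str, int] = {}
    X = cohort.dosages.copy()

    vmiss = X.isna().mean(axis=0)
    drop_v = vmiss.index[vmiss > geno]
    report["variants_missingness"] = len(drop_v)
    X = X.drop(columns=drop_v)

    imiss = X.isna().mean(axis=1)
    drop_i = imiss.index[imiss > mind]
    report["individuals_missingness"] = len(drop_i)
    X = X.drop(index=drop_i)

    freq = X.mean(axis=0) / 2.0
    mafs = np.minimum(freq, 1 - freq)
    drop_v = mafs.index[mafs < maf]
    report["variants_maf"] = len(drop_v)
    X = X.drop(columns=drop_v)

    hard = X.round().to_numpy()
    hwe_p = np.array([_hwe_pvalue(hard[:, j]) for j in range(hard.shape[1])])
    drop_v = X.columns[hwe_p < hwe]
    report["variants_hwe"] = len(drop_v)
    X = X.drop(columns=drop_v)

    # heterozygosity / inbreeding: F = 1 - observed het / expected het
    hard = X.round()
    p_hat = hard.mean(axis=0).to_numpy() / 2.0
    exp_het = (2 * p_hat * (1 - p_hat)).sum()
    obs_het = (hard == 1).sum(axis=1).to_numpy().astype(float)
    F = 1.0 - obs_het / max(exp_het, 1e-12)
    mu, sd = F.mean(), F.std()
    het_out = np.abs(F - mu) > het_sd * sd if sd > 0 else np.zeros_like(F, bool)
    report["individuals_heterozygosity"] = int(het_out.sum())
    X = X.loc[X.index[~het_out]]

    # relatedness: GRM from standardized dosages, greedy removal
    p_hat = X.mean(axis=0).to_numpy() / 2.0
    denom = np.sqrt(2 * p_hat * (1 - p_hat))
    Z = (X.to_numpy() - 2 * p_hat) / np.where(denom > 0, denom, 1.0)
    Z = np.nan_to_num(Z)
    grm = Z @ Z.T / Z.shape[1]
    np.fill_diagonal(grm, 0.0)
    miss = cohort.dosages.loc[X.index].isna().mean(axis=1).to_numpy()
    active = np.ones(len(X), bool)
    removed = 0
    while True:
        sub = np.where(active)[0]
        block = grm[np.ix_(sub, sub)]
        i, j = np.unravel_index(np.argmax(block), block.shape)
        if block[i, j] <= rel_cutoff:
            break
        a, b = sub[i], sub[j]
        victim = a if (miss[a], a) >= (miss[b], b) else b
        active[victim] = False
        removed += 1
    report["individuals_relatedness"] = removed
    X = X.loc[X.index[active]]

    if X.empty or X.shape[1] == 0:
        raise ValueError("cohort is empty after QC")
    out = cohort.subset_individuals(X.index)
    out.dosages = X
    return out, report


# ------------------------------------------------------------ P+T construction

def clump_and_threshold(
    sumstats: pd.DataFrame,
    ld: pd.DataFrame | None,
    p1: float = 1.0,
    p2: float = 1.0,
    r2: float = 0.1,
    kb: float = 250.0,
    thresholds: Sequence[float] = tuple(PT_THRESHOLDS),
) -> dict[float, pd.DataFrame]:
    """Greedy LD clumping followed by p-value thresholding.

    ``sumstats`` needs SNP, CHR, POS, P, BETA (EA/EAF carried through if
    present); ``ld`` is a long-format frame (variant_a, variant_b, r2),
    with absent pairs treated as r² = 0.  The best remaining p-value
    (≤ ``p1``) becomes an index variant; candidates with p ≤ ``p2``
    within ``kb`` kilobases and r² > ``r2`` of it are clumped away.  One
    weight table per threshold is returned, containing the surviving
    index variants with p ≤ threshold and weight = BETA.
    """
    d = sumstats.sort_values(["P", "CHR", "POS"], kind="stable").reset_index(drop=True)
    r2map: dict[frozenset, float] = {}
    if ld is not None:
        for row in ld.itertuples(index=False):
            r2map[frozenset((row.variant_a, row.variant_b))] = float(row.r2)
    snps = d["SNP"].to_numpy()
    chroms = d["CHR"].astype(str).to_numpy()
    poss = d["POS"].to_numpy()
    ps = d["P"].to_numpy()
    available = np.ones(len(d), bool)
    index_rows: list[int] = []
    for i in range(len(d)):
        if not available[i] or ps[i] > p1:
            continue
        index_rows.append(i)
        available[i] = False
        near = (
            available
            & (chroms == chroms[i])
            & (np.abs(poss - poss[i]) <= kb * 1000)
            & (ps <= p2)
        )
        for j in np.flatnonzero(near):
            if r2map.get(frozenset((snps[i], snps[j])), 0.0) > r2:
                available[j] = False
    kept = d.iloc[index_rows]
    out = {}
    for thr in thresholds:
        out[float(thr)] = kept[kept["P"] <= thr].reset_index(drop=True)
    return out


def prs_score(dosages: pd.DataFrame, weights: pd.DataFrame) -> pd.Series:
    """Additive score: Σ_v dosage_iv · weight_v over shared variants.

    ``weights`` needs SNP and BETA (and EAF, used to impute missing
    dosages as 2·EAF; without EAF missing dosages count 0).
    """
    w = weights.drop_duplicates("SNP").set_index("SNP")
    common = dosages.columns.intersection(w.index)
    if len(common) == 0:
        raise ValueError("no overlap between dosage columns and weight variants")
    X = dosages[common].to_numpy(dtype=float)
    if "EAF" in w.columns:
        fill = 2.0 * w.loc[common, "EAF"].to_numpy(dtype=float)
        nanmask = ~np.isfinite(X)
        X = np.where(nanmask, fill[None, :], X)
    else:
        X = np.nan_to_num(X)
    score = X @ w.loc[common, "BETA"].to_numpy(dtype=float)
    return pd.Series(score, index=dosages.index, name="PRS")


# ------------------------------------------------------------- EHR phenotyping

def parse_ana_titer(value) -> float:
    """Titer denominator k from '1:k'; 0 for negative status; NaN otherwise."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip().lower()
    m = re.fullmatch(r"1\s*:\s*(\d+)", s)
    if m:
        return float(m.group(1))
    if s in {"negative", "neg"}:
        return 0.0
    if s in {"positive", "pos"}:
        return np.inf
    return np.nan


def lab_binarize(ana_titer, dsdna_value) -> tuple[float, float]:
    """Binarize clinical labs: ANA positive at titer ≥ 1:80; anti-dsDNA
    positive at ≥ 60 IU/mL or a positive status.  Unparseable values
    return NaN and are excluded from lab-stratified analyses.
    """
    k = parse_ana_titer(ana_titer)
    ana_pos = np.nan if np.isnan(k) else float(k >= 80)
    if dsdna_value is None or (isinstance(dsdna_value, float) and np.isnan(dsdna_value)):
        dsdna_pos = np.nan
    else:
        s = str(dsdna_value).strip().lower()
        if s in {"positive", "pos"}:
            dsdna_pos = 1.0
        elif s in {"negative", "neg"}:
            dsdna_pos = 0.0
        else:
            try:
                dsdna_pos = float(float(s) >= 60)
            except ValueError:
                dsdna_pos = np.nan
    return ana_pos, dsdna_pos


def ehr_phenotype(
    icd: pd.DataFrame,
    sle_codes: Sequence[str],
    exclusion_codes: Sequence[str],
    algorithm: str = "Def6",
    ana_titer: pd.Series | None = None,
) -> pd.Series:
    """EHR case definitions of increasing stringency.

    Def1: ≥1 SLE ICD code count.  Def6: ≥2 SLE counts and no systemic
    sclerosis / dermatomyositis exclusion codes.  Def12: ≥4 SLE counts,
    an ANA-positive titer at the strict 1:160 cutoff, and no exclusion
    codes; individuals with missing ANA are classified controls.
    """
    sle = [c for c in sle_codes if c in icd.columns]
    exc = [c for c in exclusion_codes if c in icd.columns]
    n_sle = icd[sle].sum(axis=1) if sle else pd.Series(0, index=icd.index)
    excluded = (icd[exc].sum(axis=1) > 0) if exc else pd.Series(False, index=icd.index)
    if algorithm == "Def1":
        return n_sle >= 1
    if algorithm == "Def6":
        return (n_sle >= 2) & ~excluded
    if algorithm == "Def12":
        if ana_titer is None:
            raise ValueError("Def12 requires ANA titers")
        k = ana_titer.map(parse_ana_titer)
        ana_strict = (k >= 160).fillna(False)
        return (n_sle >= 4) & ana_strict & ~excluded
    raise ValueError(f"unknown algorithm {algorithm!r}")


# ------------------------------------------------------------------ evaluation

@dataclass
class LogisticFit:
    params: pd.Series
    fitted: pd.Series
    loglik: float
    loglik_null: float
    nagelkerke_r2: float


def fit_logistic(y: pd.Series | np.ndarray, X: pd.DataFrame) -> LogisticFit:
    """Logistic regression (Newton/IRLS) with Nagelkerke pseudo-R².

    Adds an intercept; raises on quasi-separation (diverging
    coefficients) with a hint to penalize.
    """
    yv = np.asarray(y, float)
    Xd = sm.add_constant(X, has_constant="add")
    try:
        res = sm.Logit(yv, Xd).fit(disp=0, maxiter=200, tol=1e-8)
    except Exception as e:  # statsmodels raises PerfectSeparationError subclass
        raise ValueError(f"logistic fit failed ({e}); consider penalized regression") from e
    if np.any(np.abs(res.params) > 1e3):
        raise ValueError("separation detected (diverging coefficients); consider penalization")
    n = len(yv)
    ll1, ll0 = res.llf, res.llnull
    r2 = (1 - np.exp(2 * (ll0 - ll1) / n)) / (1 - np.exp(2 * ll0 / n))
    return LogisticFit(
        params=pd.Series(res.params, index=Xd.columns),
        fitted=pd.Series(res.predict(Xd), index=getattr(X, "index", None)),
        loglik=ll1, loglik_null=ll0, nagelkerke_r2=float(r2),
    )


def liability_r2(r2_observed: float, K: float = 0.001, P: float | None = None) -> float:
    """Observed-scale case-control R² transformed to the liability scale.

    Uses the liability-threshold transformation with ascertainment
    correction for a sample case fraction P differing from the
    population prevalence K: with t = Φ⁻¹(1−K), z = φ(t), m = z/K,
    C = K²(1−K)² / (z² P(1−P)) and θ = m(P−K)/(1−K)·(m(P−K)/(1−K) − t),
    R²_liab = C·R² / (1 + C·θ·R²).  With P = K the correction term
    vanishes and the plain K(1−K)/z² rescaling is recovered.
    """
    if not 0 <= r2_observed < 1:
        raise ValueError("r2_observed must be in [0, 1)")
    if P is None:
        P = K
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must be in (0, 1)")
    t = stats.norm.isf(K)
    z = stats.norm.pdf(t)
    m = z / K
    C = K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P))
    theta = m * (P - K) / (1 - K) * (m * (P - K) / (1 - K) - t)
    return float(C * r2_observed / (1 + C * theta * r2_observed))


def auc(scores: np.ndarray, y: np.ndarray) -> float:
    """AUC via the Mann–Whitney statistic, ties counted one half."""
    s = np.asarray(scores, float)
    yv = np.asarray(y).astype(bool)
    cases, controls = s[yv], s[~yv]
    if cases.size == 0 or controls.size == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(np.concatenate([cases, controls]))
    u = ranks[: cases.size].sum() - cases.size * (cases.size + 1) / 2
    return float(u / (cases.size * controls.size))


def _delong_components(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    yv = np.asarray(y).astype(bool)
    cases, controls = scores[yv], scores[~yv]
    v10 = np.array([(np.sum(c > controls) + 0.5 * np.sum(c == controls)) / controls.size for c in cases])
    v01 = np.array([(np.sum(cases > c) + 0.5 * np.sum(cases == c)) / cases.size for c in controls])
    return v10, v01


def auc_compare(
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    y: np.ndarray,
    sided: str = "two",
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Paired AUC comparison: bootstrap CIs plus DeLong's test.

    DeLong variance comes from structural components over cases and
    controls; ``sided="one"`` tests the alternative AUC_a > AUC_b.
    Identical score vectors give p = 1.  Percentile bootstrap CIs use
    ``n_boot`` seeded replicates.
    """
    sa = np.asarray(scores_a, float)
    sb = np.asarray(scores_b, float)
    yv = np.asarray(y).astype(bool)
    auc_a, auc_b = auc(sa, yv), auc(sb, yv)

    v10a, v01a = _delong_components(sa, yv)
    v10b, v01b = _delong_components(sb, yv)
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b])) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b])) if n > 1 else np.zeros((2, 2))
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n
    diff = auc_a - auc_b
    if var <= 0:
        p = 1.0 if diff == 0 else (0.0 if (sided == "one" and diff > 0) else (0.0 if sided == "two" else 1.0))
    else:
        zstat = diff / np.sqrt(var)
        p = float(stats.norm.sf(zstat)) if sided == "one" else float(2 * stats.norm.sf(abs(zstat)))

    rng = np.random.default_rng(seed)
    idx_case = np.flatnonzero(yv)
    idx_ctrl = np.flatnonzero(~yv)
    boots_a, boots_b = [], []
    for _ in range(n_boot):
        bi = np.concatenate([rng.choice(idx_case, idx_case.size), rng.choice(idx_ctrl, idx_ctrl.size)])
        boots_a.append(auc(sa[bi], yv[bi]))
        boots_b.append(auc(sb[bi], yv[bi]))
    ci_a = tuple(np.percentile(boots_a, [2.5, 97.5]))
    ci_b = tuple(np.percentile(boots_b, [2.5, 97.5]))
    return {"auc_a": auc_a, "ci_a": ci_a, "auc_b": auc_b, "ci_b": ci_b, "delong_p": p}


def youden_point(scores: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Threshold maximizing J = sensitivity + specificity − 1 (lowest wins ties)."""
    s = np.asarray(scores, float)
    yv = np.asarray(y).astype(bool)
    if yv.all() or not yv.any():
        raise ValueError("both classes must be present")
    best = None
    for thr in np.sort(np.unique(s)):
        pred = s >= thr
        sens = np.sum(pred & yv) / yv.sum()
        spec = np.sum(~pred & ~yv) / (~yv).sum()
        j = sens + spec - 1
        if best is None or j > best[0] + 1e-15:
            best = (j, thr, sens, spec)
    return best[1], best[2], best[3]


def _odds_ratio(case_q, ctrl_q, case_ref, ctrl_ref) -> tuple[float, float, float, bool]:
    cells = np.array([case_q, ctrl_q, case_ref, ctrl_ref], float)
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a, b, c, d = cells
    orr = (a * d) / (b * c)
    se = np.sqrt((1 / cells).sum())
    lo, hi = np.exp(np.log(orr) - 1.96 * se), np.exp(np.log(orr) + 1.96 * se)
    return float(orr), float(lo), float(hi), corrected


def quintile_stratify(
    prs: pd.Series,
    y: pd.Series | np.ndarray,
    strata: Mapping[str, np.ndarray] | None = None,
) -> dict:
    """PRS-quintile risk gradients, overall and within lab strata.

    Individuals are ranked by (PRS, individual id) for deterministic
    ties and cut into five equal-size groups on the analysis sample.
    Each quintile's odds ratio against the bottom quintile carries a
    Woolf 95% CI (log OR ± 1.96·√Σ1/cell; Haldane–Anscombe 0.5 applied
    and flagged on zero cells); per-quintile case prevalences and the
    top/bottom and top/middle (= third quintile) prevalence ratios are
    reported.  ``strata`` maps stratum names to boolean masks; the full
    analysis is repeated within each.
    """
    yv = pd.Series(np.asarray(y).astype(bool), index=prs.index)
    out = {"overall": _quintiles_one(prs, yv)}
    for name, mask in (strata or {}).items():
        m = pd.Series(np.asarray(mask).astype(bool), index=prs.index)
        if m.sum() >= 25:
            out[name] = _quintiles_one(prs[m], yv[m])
    return out


def _quintiles_one(prs: pd.Series, y: pd.Series) -> dict:
    order = pd.DataFrame({"prs": prs, "iid": prs.index.astype(str)}).sort_values(
        ["prs", "iid"], kind="stable"
    )
    n = len(order)
    q = np.minimum((np.arange(n) * 5) // n, 4)
    quint = pd.Series(q, index=order.index).reindex(prs.index)
    rows = []
    ref_cases = int(y[quint == 0].sum())
    ref_ctrls = int((~y[quint == 0]).sum())
    for k in range(5):
        cases = int(y[quint == k].sum())
        ctrls = int((~y[quint == k]).sum())
        prev = cases / max(cases + ctrls, 1)
        if k == 0:
            orr, lo, hi, corr = 1.0, 1.0, 1.0, False
        else:
            orr, lo, hi, corr = _odds_ratio(cases, ctrls, ref_cases, ref_ctrls)
        rows.append(
            {"quintile": k + 1, "n": cases + ctrls, "cases": cases, "prevalence": prev,
             "odds_ratio": orr, "or_ci_low": lo, "or_ci_high": hi, "zero_cell_corrected": corr}
        )
    tab = pd.DataFrame(rows)
    prev = tab["prevalence"].to_numpy()
    return {
        "table": tab,
        "top_bottom_ratio": float(prev[4] / prev[0]) if prev[0] > 0 else np.inf,
        "top_middle_ratio": float(prev[4] / prev[2]) if prev[2] > 0 else np.inf,
    }


def prevalence_ratios(prevalences: Sequence[float]) -> tuple[float, float]:
    """(top/bottom, top/middle) ratios from five quintile prevalences."""
    p = np.asarray(prevalences, float)
    if p.size != 5:
        raise ValueError("expected five quintile prevalences")
    return float(p[4] / p[0]), float(p[4] / p[2])
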