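"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of (parameters, seed): a single run
seed fans out to named substreams, so adding a generator never perturbs
existing outputs and reruns are bit-identical.  Ground truth (causal
variants and effects, ancestry allele frequencies, replicable/spurious
labels, cohort liability model) is returned alongside the data so
recovery tests can score estimates against it.

Ancestry structure uses the Balding–Nichols model: per-ancestry allele
frequencies are Beta-distributed around a shared ancestral frequency
with divergence F_ST (default 0.1), giving allele-frequency principal
components genuine population signal.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .prs import Cohort
from .sumstats import StudyTable


def substream(seed: int, name: str) -> np.random.Generator:
    """Deterministic named RNG substream derived from one master seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(name.encode())]))


# ------------------------------------------------------------------------- LD

@dataclass
class LDPanel:
    variants: pd.DataFrame          # SNP, CHR, POS, EA, OA, BLOCK
    blocks: list[np.ndarray]        # per-block correlation matrices
    ldscores: pd.Series             # indexed by SNP

    def pairwise_r2(self) -> pd.DataFrame:
        """Long-format (variant_a, variant_b, r2) for within-block pairs."""
        rows = []
        snps = self.variants["SNP"].to_numpy()
        offset = 0
        for D in self.blocks:
            b = len(D)
            for i in range(b):
                for j in range(i + 1, b):
                    rows.append((snps[offset + i], snps[offset + j], D[i, j] ** 2))
            offset += b
        return pd.DataFrame(rows, columns=["variant_a", "variant_b", "r2"])


def sim_ld(blocks: int = 20, block_size: int = 50, ar1_rho: float = 0.5, seed: int = 0) -> LDPanel:
    """Block-diagonal AR(1) LD: D_ij = rho^|i−j| within each block.

    LD scores are ℓ_j = Σ_i D_ij²; with rho = 0 every ℓ_j = 1.  Variant
    positions space blocks well apart (1 Mb between blocks, 1 kb within)
    across chromosomes 1..22.
    """
    if not abs(ar1_rho) < 1:
        raise ValueError("|ar1_rho| must be < 1")
    rng = substream(seed, "ld")
    idx = np.arange(block_size)
    D = ar1_rho ** np.abs(idx[:, None] - idx[None, :])
    mats = [D.copy() for _ in range(blocks)]
    rows = []
    alleles = np.array(["A", "C", "G", "T"])
    for b in range(blocks):
        chrom = str(b % 22 + 1)
        base = 1_000_000 + (b // 22) * 5_000_000 + b * 2_000_000
        for i in range(block_size):
            ea, oa = rng.choice(4, size=2, replace=False)
            rows.append((f"rs{b * block_size + i + 1}", chrom, base + i * 1000, alleles[ea], alleles[oa], b))
    var = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "EA", "OA", "BLOCK"])
    ell = np.concatenate([np.sum(D**2, axis=1) for D in mats])
    return LDPanel(variants=var, blocks=mats, ldscores=pd.Series(ell, index=var["SNP"].to_numpy()))


# ------------------------------------------------------ multi-study sumstats

@dataclass
class SimTruth:
    """Ground truth retained from a multi-study simulation."""

    causal: np.ndarray                    # boolean per variant
    beta_true: pd.DataFrame               # variant x trait true effects (shared scale)
    ancestry_freqs: pd.DataFrame          # variant x ancestry EAF
    spurious: np.ndarray                  # boolean per variant
    omega_true: np.ndarray | None = None
    overlap: np.ndarray | None = None
    meta: dict = field(default_factory=dict)


def sim_multistudy(
    panel: LDPanel,
    manifest: Sequence[dict],
    n_causal: int = 20,
    beta_sd: float = 0.05,
    trait_corr: np.ndarray | None = None,
    polygenic_h2: float = 0.2,
    fst: float = 0.1,
    overlap_corr: np.ndarray | None = None,
    n_spurious: int = 0,
    spurious_scale: float = 6.0,
    seed: int = 0,
) -> tuple[list[StudyTable], SimTruth]:
    """Simulate per-study GWAS summary statistics with known truth.

    ``manifest`` lists one dict per study with keys ``n``, ``ancestry``,
    ``trait`` and optional ``study_id``.  Causal variants get true
    effects drawn per trait from N(0, beta_sd²) with cross-trait
    correlation ``trait_corr`` (identity by default; rows/columns follow
    the lexicographically sorted trait labels); effects are shared
    across ancestries.  A polygenic background of total heritability
    ``polygenic_h2`` per trait is additionally spread over all variants
    with variance proportional to LD score (cross-trait correlation
    again ``trait_corr``), so LD-score regression on the output
    recovers heritability and genetic correlation.  Per-ancestry
    allele frequencies follow
    Balding–Nichols with divergence ``fst``.  Estimated effects are the
    truth plus noise with per-variant SE = 1/√(2p(1−p)n), correlated
    across studies by ``overlap_corr`` (the z-score correlation induced
    by shared samples; identity = disjoint cohorts).  ``n_spurious``
    variants receive a single-study inflated effect (z-scale SD
    ``spurious_scale``), emulating artefactual signals that a
    replicability model should down-weight.
    """
    rng = substream(seed, "multistudy")
    var = panel.variants
    m = len(var)
    traits = sorted({s["trait"] for s in manifest})
    t = len(traits)
    ancestries = sorted({s["ancestry"] for s in manifest})

    causal = np.zeros(m, bool)
    causal[rng.choice(m, size=min(n_causal, m), replace=False)] = True
    C = np.eye(t) if trait_corr is None else np.asarray(trait_corr, float)
    betas = np.zeros((m, t))
    betas[causal] = rng.multivariate_normal(np.zeros(t), beta_sd**2 * C, size=int(causal.sum()))
    beta_true = pd.DataFrame(betas, columns=traits)

    p_anc = rng.uniform(0.05, 0.95, size=m)
    freqs = {}
    for anc in ancestries:
        if fst > 0:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            freqs[anc] = np.clip(substream(seed, f"freq:{anc}").beta(a, b), 0.01, 0.99)
        else:
            freqs[anc] = p_anc.copy()
    freq_df = pd.DataFrame(freqs, index=var["SNP"].to_numpy())

    k = len(manifest)
    O = np.eye(k) if overlap_corr is None else np.asarray(overlap_corr, float)
    Lo = np.linalg.cholesky(O)
    noise_z = (Lo @ rng.standard_normal((k, m)))  # study x variant, unit scale

    # polygenic background: per-trait standardized z-scale effects whose
    # variance tracks the LD score (shared across ancestries/studies)
    ell = panel.ldscores.to_numpy()
    Lc = np.linalg.cholesky(C + 1e-10 * np.eye(t))
    poly = rng.standard_normal((m, t)) @ Lc.T  # unit-variance, trait-correlated

    spurious = np.zeros(m, bool)
    if n_spurious:
        pool = np.flatnonzero(~causal)
        spurious[rng.choice(pool, size=min(n_spurious, pool.size), replace=False)] = True

    studies = []
    for i, entry in enumerate(manifest):
        anc, trait, n = entry["ancestry"], entry["trait"], entry["n"]
        p = freqs[anc]
        se = 1.0 / np.sqrt(2 * p * (1 - p) * n)
        ti = traits.index(trait)
        poly_z = np.sqrt(n * ell * polygenic_h2 / m) * poly[:, ti]
        bhat = betas[:, ti] + (noise_z[i] + poly_z) * se
        if n_spurious:
            hit = spurious & (substream(seed, f"spurious:{i}").random(m) < 1.0 / k)
            bhat = np.where(hit, bhat + substream(seed, f"spurious_eff:{i}").normal(0, spurious_scale, m) * se, bhat)
        pval = stats.chi2.sf((bhat / se) ** 2, df=1)
        df = var[["SNP", "CHR", "POS", "EA", "OA"]].copy()
        df["BETA"] = bhat
        df["SE"] = se
        df["P"] = np.clip(pval, np.finfo(float).tiny, 1.0)
        df["N"] = n
        df["EAF"] = p
        studies.append(
            StudyTable(df, ancestry=anc, trait=trait, study_id=entry.get("study_id", f"{anc}:{trait}:{i}"))
        )
    truth = SimTruth(
        causal=causal, beta_true=beta_true, ancestry_freqs=freq_df, spurious=spurious,
        omega_true=beta_sd**2 * C, overlap=O,
        meta={"traits": traits, "ancestries": ancestries, "seed": seed},
    )
    return studies, truth


def sim_mamba_dataset(
    n_variants: int = 5000,
    n_studies: int = 8,
    pi: float = 0.2,
    tau2: float = 5e-4,
    lambda_o: float = 0.05,
    alpha: float = 10.0,
    se_low: float = 0.001,
    se_high: float = 0.004,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (betas, ses, replicable labels) from the replicability mixture.

    Replicable variants (fraction ``pi``) share a true effect
    mu ~ N(0, tau2) observed with per-study noise; the rest are null
    with each study independently an outlier (probability ``lambda_o``,
    variance inflation ``alpha``).  Default SEs span 0.001–0.004,
    the precision of per-study effects at biobank-scale sample sizes
    (a per-study effective n of a few hundred thousand), the regime in
    which signals entering a replicability screen live.
    """
    rng = substream(seed, "mamba")
    S = rng.uniform(se_low, se_high, size=(n_variants, n_studies))
    R = rng.random(n_variants) < pi
    mu = np.where(R, rng.normal(0, np.sqrt(tau2), n_variants), 0.0)
    out = (~R)[:, None] & (rng.random((n_variants, n_studies)) < lambda_o)
    scale = np.where(out, np.sqrt(alpha) * S, S)
    B = mu[:, None] + rng.standard_normal((n_variants, n_studies)) * scale
    return B, S, R


# ------------------------------------------------------------- expression/TWAS

def sim_expression(
    genes: int = 1000,
    celltypes: int = 10,
    spike_fraction: float = 0.02,
    spike_factor: float = 20.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Log-normal expression with genes spiked in one cell type each.

    Returns the raw gene×cell-type matrix and a truth frame (gene,
    celltype) listing which cell type each spiked gene is specific to.
    """
    if not 0 < spike_fraction < 1:
        raise ValueError("spike_fraction must be in (0, 1)")
    rng = substream(seed, "expression")
    base = rng.lognormal(mean=2.0, sigma=1.0, size=(genes, 1))
    noise = rng.lognormal(mean=0.0, sigma=0.3, size=(genes, celltypes))
    X = base * noise
    n_spike = int(round(spike_fraction * genes))
    spiked = rng.choice(genes, size=n_spike, replace=False)
    target = rng.integers(0, celltypes, size=n_spike)
    for g, c in zip(spiked, target):
        X[g, c] *= spike_factor
    gene_ids = [f"G{i:05d}" for i in range(genes)]
    ct_ids = [f"CT{j:02d}" for j in range(celltypes)]
    raw = pd.DataFrame(X, index=gene_ids, columns=ct_ids)
    labels = pd.DataFrame({"gene": [gene_ids[g] for g in spiked], "celltype": [ct_ids[c] for c in target]})
    return raw, labels


def sim_twas(
    genes: int = 2000,
    P: np.ndarray | None = None,
    enriched: np.ndarray | None = None,
    noncentrality: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Correlated gene-level TWAS Z-scores with an optional mean shift.

    Z ~ MVN(mu, P) with mu = √noncentrality on enriched genes (so their
    Z² has expectation 1 + noncentrality).  Returns a table with GENE,
    CHR, START, END, Z, P; genes are laid out 2 Mb apart.
    """
    rng = substream(seed, "twas")
    mu = np.zeros(genes)
    if enriched is not None:
        mu[np.asarray(enriched, bool)] = np.sqrt(noncentrality)
    if P is None:
        z = mu + rng.standard_normal(genes)
    else:
        L = np.linalg.cholesky(np.asarray(P, float))
        z = mu + L @ rng.standard_normal(genes)
    chrom = (np.arange(genes) % 22 + 1).astype(str)
    start = 1_000_000 + (np.arange(genes) // 22) * 2_000_000
    return pd.DataFrame(
        {"GENE": [f"G{i:05d}" for i in range(genes)], "CHR": chrom, "START": start,
         "END": start + 20_000, "Z": z, "P": stats.chi2.sf(z**2, df=1)}
    )


# ----------------------------------------------------------------- PRS cohort

def sim_cohort(
    n: int = 5000,
    m_variants: int = 200,
    liability_r2: float = 0.1,
    K: float = 0.05,
    ascertain_case_fraction: float | None = None,
    ana_sensitivity: float = 0.9,
    ana_specificity: float = 0.8,
    dsdna_sensitivity: float = 0.6,
    dsdna_specificity: float = 0.95,
    icd_mu_case: float = 4.0,
    icd_mu_control: float = 0.02,
    exclusion_rate: float = 0.01,
    seed: int = 0,
) -> tuple[Cohort, dict]:
    """Liability-threshold case-control cohort with labs and ICD records.

    A standardized genetic score explains ``liability_r2`` of a unit
    liability; cases exceed the Φ⁻¹(1−K) threshold.  With
    ``ascertain_case_fraction`` set, cases are oversampled to that
    fraction (of the n returned), emulating biobank case-control
    ascertainment.  ANA titers and anti-dsDNA levels are generated with
    the stated sensitivity/specificity against case status; SLE ICD
    counts are Poisson with case-dependent rates and rare exclusion-code
    flags (systemic sclerosis / dermatomyositis).  Returns the cohort
    and a truth dict (true weights, liability coefficient, labels).
    """
    if not 0 < liability_r2 < 1:
        raise ValueError("liability_r2 must be in (0, 1)")
    rng = substream(seed, "cohort")
    freq = rng.uniform(0.1, 0.9, size=m_variants)
    w = rng.normal(0, 1, size=m_variants)
    g_mean = float(2 * freq @ w)
    g_sd = float(np.sqrt(np.sum(2 * freq * (1 - freq) * w**2)))
    c = np.sqrt(liability_r2)
    thr = stats.norm.isf(K)

    def draw(size: int):
        Gc = rng.binomial(2, freq, size=(size, m_variants)).astype(np.float32)
        gs = (Gc @ w - g_mean) / g_sd
        liab = c * gs + rng.standard_normal(size) * np.sqrt(1 - liability_r2)
        return Gc, gs, liab > thr

    if ascertain_case_fraction is None:
        G, g_std, case = draw(n)
    else:
        # case-control ascertainment: accumulate in chunks until both
        # strata are filled (keeps memory flat at rare K)
        n_case = int(round(n * ascertain_case_fraction))
        n_ctrl = n - n_case
        got_case: list = []
        got_ctrl: list = []
        have_case = have_ctrl = 0
        chunk = max(min(int(n_case / K / 10) + 1, 500_000), n)
        for _ in range(1000):
            Gc, gs, cs = draw(chunk)
            if have_case < n_case:
                idx = np.flatnonzero(cs)[: n_case - have_case]
                got_case.append((Gc[idx], gs[idx]))
                have_case += idx.size
            if have_ctrl < n_ctrl:
                idx = np.flatnonzero(~cs)[: n_ctrl - have_ctrl]
                got_ctrl.append((Gc[idx], gs[idx]))
                have_ctrl += idx.size
            if have_case >= n_case and have_ctrl >= n_ctrl:
                break
        else:
            raise ValueError("could not accumulate enough cases; check K")
        G = np.vstack([g for g, _ in got_case] + [g for g, _ in got_ctrl])
        g_std = np.concatenate([s for _, s in got_case] + [s for _, s in got_ctrl])
        case = np.concatenate([np.ones(n_case, bool), np.zeros(n_ctrl, bool)])
        perm = rng.permutation(n)
        G, g_std, case = G[perm], g_std[perm], case[perm]
    n_eff = len(case)
    iids = pd.Index([f"I{i:06d}" for i in range(n_eff)], name="IID")

    sex = rng.integers(0, 2, n_eff)
    pcs = rng.standard_normal((n_eff, 10)) * 0.1
    hla = rng.binomial(2, 0.1, size=(n_eff, 3)).astype(float)
    cov = pd.DataFrame(
        np.column_stack([sex, pcs, hla]), index=iids,
        columns=["SEX"] + [f"PC{i}" for i in range(1, 11)] + ["HLA_DRB1_0301", "HLA_DRB1_0801", "HLA_DQA1_0102"],
    )

    titers = np.array(["negative", "1:40", "1:80", "1:160", "1:320"])
    ana_pos = np.where(case, rng.random(n_eff) < ana_sensitivity, rng.random(n_eff) > ana_specificity)
    ana = np.where(ana_pos, titers[rng.integers(2, 5, n_eff)], titers[rng.integers(0, 2, n_eff)])
    ds_pos = np.where(case, rng.random(n_eff) < dsdna_sensitivity, rng.random(n_eff) > dsdna_specificity)
    dsdna = np.where(ds_pos, rng.uniform(60, 300, n_eff), rng.uniform(0, 59, n_eff)).round(1)

    sle_counts = rng.poisson(np.where(case, icd_mu_case, icd_mu_control))
    sle_counts = np.where(case & (sle_counts == 0), 1, sle_counts)
    ssc = rng.poisson(exclusion_rate, n_eff)
    dm = rng.poisson(exclusion_rate, n_eff)
    icd = pd.DataFrame({"M32": sle_counts, "M34": ssc, "M33": dm}, index=iids)

    cohort = Cohort(
        dosages=pd.DataFrame(G, index=iids, columns=[f"rs{j+1}" for j in range(m_variants)]),
        phenotype=pd.Series(case, index=iids, name="SLE"),
        covariates=cov,
        ana_titer=pd.Series(ana, index=iids, name="ANA_TITER"),
        dsdna=pd.Series(dsdna, index=iids, name="DSDNA"),
        icd=icd,
        eaf=pd.Series(freq, index=[f"rs{j+1}" for j in range(m_variants)]),
    )
    truth = {
        "weights": pd.Series(w, index=cohort.dosages.columns),
        "liability_coefficient": float(c),
        "liability_r2": liability_r2,
        "prevalence": K,
        "genetic_score": pd.Series(g_std, index=iids),
        "sle_codes": ["M32"],
        "exclusion_codes": ["M34", "M33"],
    }
    return cohort, truth
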