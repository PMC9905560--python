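"""Cell-type enrichment of TWAS associations.

Pipeline: TPM-rescale a gene×cell-type expression matrix, convert it to
per-gene specificity scores, flag each cell type's top-5% most specific
genes, and test whether those gene sets are enriched for large squared
TWAS Z-scores with a generalized-least-squares regression that accounts
for LD-induced correlation between gene statistics.  Also provides
post-processing of gene-level TWAS results (Bonferroni-style
significance filter and iterative 1 Mb locus construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

TWAS_ALPHA = 2.5e-6  # Bonferroni threshold for ~20,000 genes


def prepare_expression(raw: pd.DataFrame) -> pd.DataFrame:
    """Drop unexpressed genes and rescale each cell type to 1e6 TPM.

    ``raw`` is gene×cell-type with nonnegative entries.  Genes with zero
    expression in every cell type are removed; each column is then
    rescaled to sum to one million so library size cannot drive
    specificity.  Idempotent on already-normalized matrices.
    """
    if (raw.to_numpy() < 0).any():
        raise ValueError("expression values must be nonnegative")
    expr = raw.loc[raw.sum(axis=1) > 0].copy()
    colsums = expr.sum(axis=0)
    if (colsums == 0).any():
        bad = list(colsums.index[colsums == 0])
        raise ValueError(f"cell types with zero total expression: {bad}")
    return expr * (1e6 / colsums)


def specificity_scores(expr: pd.DataFrame) -> pd.DataFrame:
    """Per-gene expression share by cell type; rows sum to 1."""
    rowsums = expr.sum(axis=1)
    if (rowsums == 0).any():
        raise ValueError("all-zero gene rows present; run prepare_expression first")
    return expr.div(rowsums, axis=0)


def specific_gene_sets(spec: pd.DataFrame, percentile: float = 5.0) -> pd.DataFrame:
    """0/1 indicator of each cell type's most specific genes.

    Per cell type, the ``ceil(percentile/100 · G)`` genes with the
    highest specificity are flagged; ties are broken by (score
    descending, gene id ascending) so every column has exactly that
    size deterministically.
    """
    if not 0 < percentile <= 100:
        raise ValueError("percentile must be in (0, 100]")
    g = len(spec)
    k = math.ceil(percentile / 100.0 * g)
    out = pd.DataFrame(0, index=spec.index, columns=spec.columns, dtype=np.int8)
    for ct in spec.columns:
        order = spec[[ct]].assign(_gene=spec.index.astype(str)).sort_values(
            [ct, "_gene"], ascending=[False, True], kind="stable"
        )
        out.loc[order.index[:k], ct] = 1
    return out


def gene_correlation(weights_a: np.ndarray, weights_b: np.ndarray, ld: np.ndarray) -> float:
    """Correlation of two genes' TWAS Z-statistics from prediction weights.

    With shared-variant weight vectors w_a, w_b and LD matrix D:
    rho = w_aᵀ D w_b / sqrt(w_aᵀ D w_a · w_bᵀ D w_b), clipped to [−1, 1].
    """
    wa = np.asarray(weights_a, float)
    wb = np.asarray(weights_b, float)
    D = np.asarray(ld, float)
    na = wa @ D @ wa
    nb = wb @ D @ wb
    if na <= 0 or nb <= 0:
        raise ValueError("weight vector has non-positive norm under the LD matrix")
    return float(np.clip(wa @ D @ wb / np.sqrt(na * nb), -1.0, 1.0))


def squared_stat_correlation(
    rho: float,
    B: int = 100_000,
    seed: int | None = None,
    method: str = "closed_form",
) -> float:
    """Correlation between squared statistics of a bivariate normal pair.

    For (Z1, Z2) standard bivariate normal with correlation rho,
    Corr(Z1², Z2²) = rho² exactly; ``method="closed_form"`` returns that
    directly (the default fast path).  ``method="monte_carlo"`` draws B
    pairs and returns the sample correlation of the squared draws.
    ``method="mean_product"`` averages the products of the unsquared
    draws, which estimates rho itself rather than the squared-statistic
    correlation; it is retained only for comparison.
    """
    rho = float(np.clip(rho, -1.0, 1.0))
    if method == "closed_form":
        return rho**2
    if B < 1000:
        raise ValueError("B must be at least 1000")
    rng = np.random.default_rng(seed)
    z1 = rng.standard_normal(B)
    e = rng.standard_normal(B)
    z2 = rho * z1 + np.sqrt(max(1 - rho**2, 0.0)) * e
    if method == "monte_carlo":
        if abs(rho) == 1.0:
            return 1.0
        return float(np.corrcoef(z1**2, z2**2)[0, 1])
    if method == "mean_product":
        return float(np.sum(z1 * z2) / (B - 1))
    raise ValueError(f"unknown method {method!r}")


def squared_corr_matrix(rho: np.ndarray, **kwargs) -> np.ndarray:
    """Elementwise squared-statistic correlation matrix with unit diagonal."""
    rho = np.asarray(rho, float)
    out = np.vectorize(lambda r: squared_stat_correlation(r, **kwargs))(rho)
    np.fill_diagonal(out, 1.0)
    return out


@dataclass
class EnrichmentResult:
    """Per-cell-type GLS coefficients with t-test p-values."""

    table: pd.DataFrame  # CELLTYPE, GAMMA, SE, P, SIGNIFICANT
    sigma2: float
    df_resid: int


def gls_enrichment(
    Y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    P: np.ndarray,
    ridge: float = 0.05,
    alpha: float = 0.05,
    intercept: bool = True,
) -> EnrichmentResult:
    """GLS regression of squared TWAS Z-scores on cell-type indicators.

    gamma_hat = (XᵀP⁻¹X)⁻¹XᵀP⁻¹Y with Var(gamma_hat) = s²(XᵀP⁻¹X)⁻¹ and
    s² the P-weighted residual variance on G − rank(X) degrees of
    freedom; each coefficient gets a two-sided t-test.  An intercept is
    prepended so each cell-type coefficient measures excess mean Z²
    over baseline.  P is shrunk toward the identity,
    (1−ridge)·P + ridge·I, before inversion (finite bootstrap estimates
    of P need not be positive definite); ``ridge=0`` uses P as given,
    and P = I reduces the fit to OLS exactly.
    """
    Y = np.asarray(Y, float)
    if np.any(Y < 0):
        raise ValueError("Y must be nonnegative squared statistics")
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [f"ct{i}" for i in range(np.asarray(X).shape[1])]
    Xm = np.asarray(X, float)
    g = Y.size
    if Xm.shape[0] != g or P.shape != (g, g):
        raise ValueError("dimension mismatch between Y, X, P")
    if intercept:
        Xm = np.column_stack([np.ones(g), Xm])
        names = ["intercept"] + names
    P = np.asarray(P, float)
    if np.array_equal(P, np.eye(g)):
        Xi, Yi = Xm, Y  # GLS with P = I is OLS; skip the whitening
    else:
        Preg = (1.0 - ridge) * P + ridge * np.eye(g)
        try:
            L = np.linalg.cholesky(Preg)
        except np.linalg.LinAlgError as e:
            raise ValueError("P is not positive definite after regularization") from e
        Xi = solve_triangular(L, Xm, lower=True)  # whitened design
        Yi = solve_triangular(L, Y, lower=True)
    xtx = Xi.T @ Xi
    rank = np.linalg.matrix_rank(Xm)
    if np.linalg.matrix_rank(xtx) < Xm.shape[1]:
        corr = np.corrcoef(Xm.T)
        bad = [names[i] for i in range(len(names)) if np.sum(np.abs(corr[i]) > 0.999) > 1]
        raise ValueError(f"design is singular; collinear columns: {bad or names}")
    gamma = np.linalg.solve(xtx, Xi.T @ Yi)
    resid = Yi - Xi @ gamma
    df = g - rank
    sigma2 = float(resid @ resid / df)
    cov = sigma2 * np.linalg.inv(xtx)
    se = np.sqrt(np.diag(cov))
    tstat = gamma / se
    pvals = 2 * stats.t.sf(np.abs(tstat), df)
    table = pd.DataFrame(
        {"CELLTYPE": names, "GAMMA": gamma, "SE": se, "P": pvals, "SIGNIFICANT": pvals < alpha}
    )
    return EnrichmentResult(table=table, sigma2=sigma2, df_resid=df)


@dataclass
class TwasLocus:
    lead_gene: str
    chrom: str
    start: int
    end: int
    pvalue: float
    members: list[str]
    novel: bool


def twas_postprocess(
    twas: pd.DataFrame,
    alpha: float = TWAS_ALPHA,
    window: int = 1_000_000,
    known_sentinels: list[tuple[str, int]] | None = None,
) -> tuple[pd.DataFrame, list[TwasLocus]]:
    """Filter gene-level TWAS results and build 1 Mb loci iteratively.

    ``twas`` needs columns GENE, CHR, START, END, Z, P.  Genes with
    p < ``alpha`` are significant; loci are built greedily: the most
    significant remaining gene defines a window (gene body ± 1 Mb),
    every significant gene overlapping the window joins its locus, and
    the process repeats.  A locus is novel iff its window midpoint gene
    is > 1 Mb from every known GWAS sentinel position.
    """
    required = {"GENE", "CHR", "START", "END", "P"}
    if not required.issubset(twas.columns):
        raise ValueError(f"twas table must have columns {sorted(required)}")
    sig = twas[twas["P"] < alpha].copy()
    if sig[["CHR", "START", "END"]].isna().any().any():
        bad = sig.loc[sig[["CHR", "START", "END"]].isna().any(axis=1), "GENE"].tolist()
        raise ValueError(f"missing coordinates for significant genes: {bad}")
    sig = sig.sort_values(["P", "CHR", "START"], kind="stable").reset_index(drop=True)
    catalog = list(known_sentinels or [])

    loci: list[TwasLocus] = []
    remaining = sig.copy()
    while len(remaining):
        lead = remaining.iloc[0]
        start = int(lead["START"]) - window
        end = int(lead["END"]) + window
        in_win = (
            (remaining["CHR"].astype(str) == str(lead["CHR"]))
            & (remaining["END"] >= start)
            & (remaining["START"] <= end)
        )
        members = remaining.loc[in_win, "GENE"].tolist()
        novel = not any(
            str(c) == str(lead["CHR"]) and start <= p <= end for c, p in catalog
        )
        loci.append(
            TwasLocus(
                lead_gene=str(lead["GENE"]), chrom=str(lead["CHR"]), start=start, end=end,
                pvalue=float(lead["P"]), members=members, novel=novel,
            )
        )
        remaining = remaining[~in_win]
    return sig, loci
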