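"""Fixed-effect meta-analysis and summary-statistic QC diagnostics.

Implements the pairwise λ_meta diagnostic (a median-based statistic
comparing paired effect-size differences against the χ²(1) median:
values near 1 indicate independent homogeneous studies, values well
below 1 indicate sample overlap, values well above 1 indicate effect
heterogeneity), genomic control, inverse-variance-weighted (IVW)
pooling, nested-study subtraction, overlap decorrelation, Cochran's Q
heterogeneity test, and greedy locus definition with novelty
classification.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import StudyTable

#: median of the χ²(1) distribution, chi2.ppf(0.5, 1) to 10 s.f.
CHI2_1_MEDIAN = 0.4549364231

GENOME_WIDE_SIG = 5e-8


@dataclass(frozen=True)
class PairDiagnostics:
    """λ_meta for a pair of studies over their shared variants."""

    lambda_meta: float
    n_shared: int


def _shared(a: StudyTable, b: StudyTable) -> tuple[pd.DataFrame, pd.DataFrame]:
    ka, kb = a.keys, b.keys
    common = ka.intersection(kb)
    if len(common) == 0:
        raise ValueError("no shared variants between studies")
    da = a.df.set_index(ka).loc[common]
    db = b.df.set_index(kb).loc[common]
    return da, db


def lambda_meta(a: StudyTable, b: StudyTable) -> PairDiagnostics:
    """Pairwise effect-concordance diagnostic.

    For each shared variant, T_i = (b_i1 - b_i2)^2 / (se_i1^2 + se_i2^2);
    λ_meta = median(T) / median(χ²₁).  Under independent studies with
    homogeneous effects each T_i is χ²₁ and λ_meta ≈ 1.
    """
    da, db = _shared(a, b)
    t = (da["BETA"].to_numpy() - db["BETA"].to_numpy()) ** 2 / (
        da["SE"].to_numpy() ** 2 + db["SE"].to_numpy() ** 2
    )
    return PairDiagnostics(float(np.median(t) / CHI2_1_MEDIAN), len(t))


def genomic_control(pvalues: np.ndarray | Sequence[float]) -> float:
    """λ_GC: median χ²₁ quantile of the p-values over the null median."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def variant_pvalue(beta: float, se: float) -> float:
    """Two-sided p-value from a Wald χ²(1df) statistic (beta/se)²."""
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be positive")
    return stats.chi2.sf((np.asarray(beta) / np.asarray(se)) ** 2, df=1)


def variant_log10_pvalue(beta: float, se: float) -> float:
    """log10 of the two-sided χ²(1df) p-value; stable for |z| >> 37.

    Uses p = 2·Φ(−|z|) (identical to the χ²₁ tail) through the normal
    log-survival function, which stays finite long after the linear
    p-value underflows.
    """
    if np.any(np.asarray(se) <= 0):
        raise ValueError("se must be positive")
    z = np.abs(np.asarray(beta) / np.asarray(se))
    return (np.log(2) + stats.norm.logsf(z)) / np.log(10)


def cochran_q(betas: Sequence[float], ses: Sequence[float]) -> tuple[float, int, float]:
    """Cochran's Q heterogeneity test across K study effects.

    Q = Σ w_k (β_k − β_pooled)² with w_k = 1/se_k²; df = K − 1.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size < 2:
        raise ValueError("Cochran's Q requires at least 2 studies")
    w = 1.0 / s**2
    pooled = np.sum(w * b) / np.sum(w)
    q = float(np.sum(w * (b - pooled) ** 2))
    df = int(b.size - 1)
    return q, df, float(stats.chi2.sf(q, df))


def ivw_meta(studies: Sequence[StudyTable], require_all: bool = False) -> pd.DataFrame:
    """Inverse-variance-weighted fixed-effect meta-analysis.

    Returns a MetaResult frame with pooled ``BETA``, ``SE``, ``Z``, ``P``
    plus per-variant ``N_STUDIES``, Cochran's ``Q``, ``Q_DF`` and ``Q_P``
    (NaN where only one study contributes).  Variant alignment is by
    ``(CHR, POS, EA, OA)``; studies must already be harmonized.
    """
    if not studies:
        raise ValueError("no studies given")
    frames = []
    for i, st in enumerate(studies):
        f = st.df[["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "N", "EAF"]].copy()
        f["_k"] = i
        frames.append(f)
    allf = pd.concat(frames, ignore_index=True)
    allf["_w"] = 1.0 / allf["SE"] ** 2

    grp = allf.groupby(["CHR", "POS", "EA", "OA"], sort=False)
    wsum = grp["_w"].sum()
    allf["_wb"] = allf["_w"] * allf["BETA"]
    wbsum = grp["_wb"].sum()
    nstud = grp["_k"].size()
    beta = wbsum / wsum
    se = 1.0 / np.sqrt(wsum)

    out = pd.DataFrame(
        {
            "SNP": grp["SNP"].first(),
            "N": grp["N"].sum(),
            "EAF": grp["EAF"].mean(),
            "BETA": beta,
            "SE": se,
            "N_STUDIES": nstud,
        }
    ).reset_index()
    if require_all:
        out = out[out["N_STUDIES"] == len(studies)].reset_index(drop=True)

    out["Z"] = out["BETA"] / out["SE"]
    out["P"] = np.clip(stats.chi2.sf(out["Z"] ** 2, df=1), np.finfo(float).tiny, 1.0)

    # heterogeneity: Q = sum w b^2 - (sum w b)^2 / sum w
    allf["_wb2"] = allf["_w"] * allf["BETA"] ** 2
    key = out.set_index(["CHR", "POS", "EA", "OA"]).index
    qall = (grp["_wb2"].sum() - wbsum**2 / wsum).reindex(key)
    out["Q"] = np.maximum(qall.to_numpy(), 0.0)
    out["Q_DF"] = out["N_STUDIES"] - 1
    out["Q_P"] = np.where(
        out["Q_DF"] > 0, stats.chi2.sf(out["Q"], np.maximum(out["Q_DF"], 1)), np.nan
    )
    out["POS"] = out["POS"].astype(np.int64)
    return out[
        ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "Z", "P", "N", "EAF", "N_STUDIES", "Q", "Q_DF", "Q_P"]
    ]


def meta_to_study(meta: pd.DataFrame, ancestry: str = "other", trait: str = "trait", study_id: str = "meta") -> StudyTable:
    """Wrap a MetaResult frame back into a StudyTable for further pooling."""
    df = meta[["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N", "EAF"]].copy()
    return StudyTable(df, ancestry=ancestry, trait=trait, study_id=study_id)


def subtract_sumstats(large: StudyTable, small: StudyTable) -> StudyTable:
    """Remove a nested sub-study from a meta-analysis by IVW inversion.

    With w = 1/se²: w_R = w_L − w_S, β_R = (w_L β_L − w_S β_S) / w_R.
    Used when one input study is itself a meta-analysis containing all
    samples of another, so that ancestry-specific analyses can use
    non-overlapping studies.  Raises if any shared variant has
    w_R ≤ 0, which signals the "small" study is not actually nested.
    """
    dl, ds = _shared(large, small)
    wl = 1.0 / dl["SE"].to_numpy() ** 2
    ws = 1.0 / ds["SE"].to_numpy() ** 2
    wr = wl - ws
    bad = wr <= 0
    if np.any(bad):
        snp = dl["SNP"].to_numpy()[bad][0]
        raise ValueError(
            f"non-positive residual weight at {snp}: smaller study is not nested in the larger"
        )
    beta = (wl * dl["BETA"].to_numpy() - ws * ds["BETA"].to_numpy()) / wr
    se = 1.0 / np.sqrt(wr)
    out = dl.reset_index(drop=True).copy()
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = np.clip(stats.chi2.sf((beta / se) ** 2, df=1), np.finfo(float).tiny, 1.0)
    out["N"] = np.maximum(dl["N"].to_numpy() - ds["N"].to_numpy(), 0)
    return StudyTable(
        out[["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N", "EAF"]],
        ancestry=large.ancestry,
        trait=large.trait,
        study_id=f"{large.study_id}-minus-{small.study_id}",
    )


def decorrelate_overlap(
    studies: Sequence[StudyTable], z_correlation: np.ndarray
) -> list[StudyTable]:
    """De-correlate z-scores of overlapping studies via inverse Cholesky.

    ``z_correlation`` is the K×K correlation of association z-scores
    induced by shared samples (estimable from null variants).  For each
    variant shared by all K studies the z vector is premultiplied by
    L⁻¹ where C = L Lᵀ; SEs are kept and betas rescaled so that
    β/se equals the transformed z.  With C = I the input is returned
    unchanged.  Variants missing from any study are passed through.
    """
    C = np.asarray(z_correlation, dtype=float)
    k = len(studies)
    if C.shape != (k, k):
        raise ValueError("correlation matrix shape does not match study count")
    if not np.allclose(C, C.T):
        raise ValueError("correlation matrix must be symmetric")
    try:
        L = np.linalg.cholesky(C)
    except np.linalg.LinAlgError as e:
        raise ValueError("z correlation matrix is not positive definite") from e
    Linv = np.linalg.inv(L)
    if np.allclose(C, np.eye(k)):
        return list(studies)

    common = studies[0].keys
    for st in studies[1:]:
        common = common.intersection(st.keys)
    out = []
    aligned = [st.df.set_index(st.keys) for st in studies]
    zmat = np.vstack(
        [ (d.loc[common, "BETA"] / d.loc[common, "SE"]).to_numpy() for d in aligned ]
    )  # K x M
    znew = Linv @ zmat
    for i, st in enumerate(studies):
        d = st.df.copy()
        idx = st.keys
        shared_mask = idx.isin(common)
        d_shared = d[shared_mask].set_index(idx[shared_mask]).loc[common]
        se = d_shared["SE"].to_numpy()
        d_shared["BETA"] = znew[i] * se
        d_shared["P"] = stats.chi2.sf(znew[i] ** 2, df=1)
        newdf = pd.concat([d_shared.reset_index(drop=True), d[~shared_mask]], ignore_index=True)
        out.append(st.with_df(newdf))
    return out


@dataclass
class Locus:
    """A sentinel variant and the hits it absorbs."""

    sentinel_snp: str
    chrom: str
    pos: int
    pvalue: float
    start: int
    end: int
    members: list[str]
    novel: bool


def define_loci(
    hits: pd.DataFrame,
    mode: str = "distance",
    window: int = 1_000_000,
    ld: pd.DataFrame | None = None,
    ld_r2: float = 0.2,
    known_catalog: Iterable[tuple[str, int]] | None = None,
) -> list[Locus]:
    """Greedy locus assignment over genome-wide-significant hits.

    The most significant unassigned variant becomes a sentinel and
    absorbs hits within ±``window`` bp on the same chromosome
    (``mode="distance"``) or with r² > ``ld_r2`` to it (``mode="ld"``,
    requiring a long-format ``ld`` frame with columns
    ``variant_a, variant_b, r2``).  P-value ties break on (CHR, POS).
    A locus is novel iff no catalog entry lies within ±``window`` bp of
    its sentinel.
    """
    if mode not in {"distance", "ld"}:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "ld" and ld is None:
        raise ValueError("mode='ld' requires a pairwise LD table")
    d = hits.sort_values(["P", "CHR", "POS"], kind="stable").reset_index(drop=True)
    catalog = list(known_catalog or [])

    r2map: dict[frozenset, float] = {}
    if ld is not None:
        for row in ld.itertuples(index=False):
            r2map[frozenset((row.variant_a, row.variant_b))] = float(row.r2)

    unassigned = np.ones(len(d), dtype=bool)
    loci: list[Locus] = []
    chroms = d["CHR"].astype(str).to_numpy()
    poss = d["POS"].to_numpy()
    snps = d["SNP"].to_numpy()
    ps = d["P"].to_numpy()
    while unassigned.any():
        i = int(np.flatnonzero(unassigned)[0])
        if mode == "distance":
            member_mask = unassigned & (chroms == chroms[i]) & (np.abs(poss - poss[i]) <= window)
        else:
            r2s = np.array(
                [r2map.get(frozenset((snps[i], s)), 0.0) if s != snps[i] else 1.0 for s in snps]
            )
            member_mask = unassigned & (r2s > ld_r2)
            member_mask[i] = True
        members = list(snps[member_mask])
        novel = not any(
            str(c).removeprefix("chr") == chroms[i].removeprefix("chr") and abs(p - poss[i]) <= window
            for c, p in catalog
        )
        loci.append(
            Locus(
                sentinel_snp=str(snps[i]),
                chrom=str(chroms[i]),
                pos=int(poss[i]),
                pvalue=float(ps[i]),
                start=int(poss[i] - window),
                end=int(poss[i] + window),
                members=members,
                novel=novel,
            )
        )
        unassigned &= ~member_mask
    return loci


def loci_to_frame(loci: Sequence[Locus]) -> pd.DataFrame:
    """Tabulate loci with SENTINEL, CHR, START, END, N_MEMBERS, NOVEL."""
    return pd.DataFrame(
        {
            "SENTINEL": [l.sentinel_snp for l in loci],
            "CHR": [l.chrom for l in loci],
            "POS": [l.pos for l in loci],
            "P": [l.pvalue for l in loci],
            "START": [l.start for l in loci],
            "END": [l.end for l in loci],
            "N_MEMBERS": [len(l.members) for l in loci],
            "NOVEL": [l.novel for l in loci],
        }
    )


def flag_heterogeneous_loci(meta: pd.DataFrame, loci: Sequence[Locus]) -> pd.DataFrame:
    """Bonferroni heterogeneity flag at 0.05 / n_loci on sentinel Q tests."""
    frame = loci_to_frame(loci)
    thr = 0.05 / max(len(loci), 1)
    qp = meta.set_index("SNP")["Q_P"].reindex(frame["SENTINEL"]).to_numpy()
    frame["Q_P"] = qp
    frame["HETEROGENEOUS"] = qp < thr
    return frame
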