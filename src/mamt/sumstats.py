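"""Reading, harmonizing, and filtering GWAS summary statistics.

Tables are held as pandas DataFrames with a canonical column set
(``SNP, CHR, POS, EA, OA, BETA, SE, P, N, EAF``), wrapped in
:class:`StudyTable` together with study metadata (ancestry, trait,
study id).  All downstream modules assume tables have passed through
:func:`parse_sumstats` / :func:`harmonize_alleles` so that effect
alleles are aligned to a common reference and duplicate variants have
been resolved.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical column order for summary-statistic tables.
CANONICAL_COLUMNS = ["SNP", "CHR", "POS", "EA", "OA", "BETA", "SE", "P", "N", "EAF"]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

VALID_ANCESTRIES = {"EUR", "EAS", "AMR", "other"}


class SumstatsError(ValueError):
    """Raised for malformed or empty summary-statistic inputs."""


def _complement(allele: str) -> str:
    return "".join(_COMPLEMENT.get(b, "N") for b in reversed(allele))


def is_strand_ambiguous(a1: str, a2: str) -> bool:
    """True for A/T and C/G pairs, whose strand cannot be inferred."""
    return len(a1) == 1 and len(a2) == 1 and _COMPLEMENT.get(a1) == a2


@dataclass
class StudyTable:
    """Harmonized per-variant summary statistics for one study.

    ``df`` uses the canonical columns; ``(CHR, POS, EA, OA)`` pairs are
    unique (the smaller-SE record wins on conflict).
    """

    df: pd.DataFrame
    ancestry: str = "other"
    trait: str = "trait"
    study_id: str = "study"

    def __post_init__(self) -> None:
        if not self.ancestry or not self.trait:
            raise SumstatsError("ancestry and trait labels must be non-empty")
        missing = [c for c in CANONICAL_COLUMNS if c not in self.df.columns]
        if missing:
            raise SumstatsError(f"missing canonical columns: {missing}")
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def keys(self) -> pd.Index:
        """(CHR, POS, EA, OA) multi-key as a string index."""
        d = self.df
        return pd.Index(
            d["CHR"].astype(str) + ":" + d["POS"].astype(str) + ":" + d["EA"] + ":" + d["OA"]
        )

    def with_df(self, df: pd.DataFrame) -> "StudyTable":
        return replace(self, df=df.reset_index(drop=True))


def _validate_rows(df: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows violating record invariants; count reasons."""
    counts: dict[str, int] = {}
    numeric = ["POS", "BETA", "SE", "P", "N", "EAF"]
    for col in numeric:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    bad_numeric = df[numeric].isna().any(axis=1)
    counts["unparseable"] = int(bad_numeric.sum())
    df = df[~bad_numeric]

    alleles_ok = df["EA"].str.fullmatch(r"[ACGT]+") & df["OA"].str.fullmatch(r"[ACGT]+")
    ok = (
        alleles_ok.fillna(False)
        & (df["SE"] > 0)
        & (df["P"] > 0)
        & (df["P"] <= 1)
        & (df["EAF"] >= 0)
        & (df["EAF"] <= 1)
        & (df["POS"] >= 1)
    )
    counts["invariant"] = int((~ok).sum())
    df = df[ok].copy()
    df["POS"] = df["POS"].astype(np.int64)

    # duplicate (CHR,POS,EA,OA): keep smallest SE
    df = df.sort_values("SE", kind="stable")
    dup = df.duplicated(subset=["CHR", "POS", "EA", "OA"], keep="first")
    counts["duplicate"] = int(dup.sum())
    if counts["duplicate"]:
        logger.warning("dropped %d duplicate variant records (kept smaller SE)", counts["duplicate"])
    df = df[~dup].sort_index()
    return df, counts


def parse_sumstats(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    ancestry: str = "other",
    trait: str = "trait",
    study_id: str | None = None,
) -> StudyTable:
    """Read a METAL-style TSV (optionally gzipped) into a :class:`StudyTable`.

    ``column_map`` maps canonical names to the file's header names, e.g.
    ``{"SNP": "MarkerName", "P": "P-value"}``.  Rows failing numeric
    parsing or record invariants (SE>0, P in (0,1], EAF in [0,1]) are
    dropped and counted in the log.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        df = pd.read_csv(fh, sep="\t", dtype=str)
    column_map = dict(column_map or {})
    rename = {column_map.get(c, c): c for c in CANONICAL_COLUMNS}
    missing = [src for src in rename if src not in df.columns]
    if missing:
        raise SumstatsError(f"{path}: missing mandatory columns {missing}")
    df = df.rename(columns=rename)[CANONICAL_COLUMNS]
    df["CHR"] = df["CHR"].astype(str).str.removeprefix("chr")
    df["EA"] = df["EA"].str.upper()
    df["OA"] = df["OA"].str.upper()
    df, counts = _validate_rows(df)
    dropped = sum(counts.values())
    if dropped:
        logger.warning("%s: dropped %d rows (%s)", path.name, dropped, counts)
    if df.empty:
        raise SumstatsError(f"{path}: no valid rows after parsing")
    return StudyTable(df, ancestry=ancestry, trait=trait, study_id=study_id or path.stem)


def write_sumstats(study: StudyTable, path: str | Path) -> None:
    """Write canonical TSV; round-trips through :func:`parse_sumstats`."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        study.df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def harmonize_alleles(
    study: StudyTable,
    reference: pd.DataFrame,
    ambiguous_policy: str = "drop",
    freq_diff_threshold: float = 0.2,
) -> StudyTable:
    """Align effect alleles to a reference of canonical (EA, OA) per site.

    ``reference`` needs columns ``CHR, POS, EA, OA`` (unique per site) and,
    for frequency-based resolution of strand-ambiguous variants,
    ``EAF``.  For each shared site: a matching allele pair is kept as-is;
    a swapped pair gets its beta sign flipped and EAF complemented; a
    strand-flipped pair is complemented then resolved the same way.
    A/T and C/G variants are dropped under the default policy
    (``ambiguous_policy="drop"``) because their strand is unresolvable
    from alleles alone; ``"freq"`` keeps them when the allele frequency
    is decisive (|EAF - ref EAF| comparison margin
    ``freq_diff_threshold``).  Variants absent from the reference, or
    with incompatible alleles, are dropped and counted.
    """
    if ambiguous_policy not in {"drop", "freq"}:
        raise ValueError(f"unknown ambiguous_policy {ambiguous_policy!r}")
    ref = reference.drop_duplicates(subset=["CHR", "POS"]).copy()
    ref["CHR"] = ref["CHR"].astype(str)
    ref_idx = ref.set_index(ref["CHR"] + ":" + ref["POS"].astype(str))

    d = study.df.copy()
    site = d["CHR"].astype(str) + ":" + d["POS"].astype(str)
    in_ref = site.isin(ref_idx.index)
    n_absent = int((~in_ref).sum())
    d = d[in_ref]
    site = site[in_ref]
    ref_rows = ref_idx.loc[site]
    rea = ref_rows["EA"].to_numpy()
    roa = ref_rows["OA"].to_numpy()
    ref_eaf = ref_rows["EAF"].to_numpy(dtype=float) if "EAF" in ref_rows else np.full(len(d), np.nan)

    ea = d["EA"].to_numpy()
    oa = d["OA"].to_numpy()
    cea = np.array([_complement(a) for a in ea])
    coa = np.array([_complement(a) for a in oa])
    ambiguous = np.array([is_strand_ambiguous(a, b) for a, b in zip(ea, oa)])

    match = (ea == rea) & (oa == roa)
    swap = (ea == roa) & (oa == rea)
    s_match = (cea == rea) & (coa == roa) & ~ambiguous
    s_swap = (cea == roa) & (coa == rea) & ~ambiguous

    keep = match | swap | s_match | s_swap
    flip = swap | s_swap
    if ambiguous_policy == "drop":
        drop_amb = ambiguous
    else:
        # for A/T and C/G a strand flip maps the pair onto itself; use the
        # frequency to decide orientation, dropping indecisive variants
        eaf = d["EAF"].to_numpy(dtype=float)
        diff_as_is = np.abs(eaf - ref_eaf)
        diff_flipped = np.abs((1.0 - eaf) - ref_eaf)
        decisive = (np.abs(diff_as_is - diff_flipped) > 0) & ~np.isnan(ref_eaf)
        resolvable = ambiguous & match & decisive & (np.minimum(diff_as_is, diff_flipped) <= freq_diff_threshold)
        flip = flip | (resolvable & (diff_flipped < diff_as_is))
        drop_amb = ambiguous & ~resolvable
    keep = keep & ~drop_amb

    n_incompat = int((~(match | swap | s_match | s_swap)).sum())
    n_amb = int(drop_amb.sum())
    if n_absent or n_incompat or n_amb:
        logger.info(
            "%s: harmonization dropped %d absent-from-reference, %d incompatible, %d strand-ambiguous",
            study.study_id, n_absent, n_incompat, n_amb,
        )

    d = d[keep].copy()
    flip = flip[keep]
    rea_k, roa_k = rea[keep], roa[keep]
    d.loc[flip, "BETA"] = -d.loc[flip, "BETA"]
    d.loc[flip, "EAF"] = 1.0 - d.loc[flip, "EAF"]
    d["EA"] = rea_k
    d["OA"] = roa_k
    return study.with_df(d)


def restrict_variants(
    study: StudyTable,
    whitelist: Iterable[str] | None = None,
    exclude_regions: Sequence[tuple[str, int, int]] | None = None,
) -> StudyTable:
    """Keep whitelisted variants (rsID or ``chr:pos:EA:OA`` keys) minus
    excluded regions.

    Regions are 1-based half-open ``[start, end)`` on the stated
    chromosome (note this diverges from 0-based BED).  Row order is
    preserved; an empty result is allowed.
    """
    d = study.df
    mask = np.ones(len(d), dtype=bool)
    if whitelist is not None:
        wl = set(whitelist)
        mask &= (d["SNP"].isin(wl) | study.keys.isin(wl)).to_numpy()
    for chrom, start, end in exclude_regions or []:
        in_region = (
            (d["CHR"].astype(str) == str(chrom).removeprefix("chr"))
            & (d["POS"] >= start)
            & (d["POS"] < end)
        ).to_numpy()
        mask &= ~in_region
    return study.with_df(d[mask])


#: Extended MHC interval on chromosome 6 (hg19); excluded from
#: multi-trait analysis because its outsized effects violate the
#: homogeneous-covariance assumption of the multi-trait combiner.
HLA_REGION: tuple[str, int, int] = ("6", 25_000_000, 35_000_000)


def read_regions(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3-column (chrom, start, end) TSV of 1-based half-open regions."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end"], dtype={"chrom": str})
    return [(str(r.chrom).removeprefix("chr"), int(r.start), int(r.end)) for r in df.itertuples()]
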