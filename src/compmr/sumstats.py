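"""GWAS summary statistics: containers, I/O, filtering, and LD pruning.

Summary statistics live on the standardized (SD/SD) scale: effects of a
single-allele dosage increment on an inverse-rank-normalized trait.
Effects estimated on a raw 0/1 disease indicator carry the tag
``raw-binary`` until :func:`standardize_binary` divides them by the
phenotypic SD, after which they are comparable with continuous traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Canonical column order of the tab-separated dialect.
COLUMNS = ["variant", "chrom", "pos", "ref", "alt", "minor_AF", "beta", "se", "pval", "n"]

#: Genome-wide significance threshold.
GWS = 5e-8

#: MHC/HLA region on chromosome 6 (GRCh37, 1-based inclusive).
HLA_REGION = ("6", 28_477_797, 33_448_354)


class SumStatsFormatError(ValueError):
    """A summary-statistics file is missing a mandatory column."""


def _norm_chrom(c) -> str:
    s = str(c)
    return s[3:] if s.lower().startswith("chr") else s


@dataclass
class SumStats:
    """One trait x one sex-group association table.

    Parameters
    ----------
    table
        Per-variant statistics with columns ``variant, chrom, pos, ref,
        alt, minor_AF, beta, se, pval, n``. Rows with NaN beta/se denote
        variants whose effect could not be estimated (e.g. monomorphic).
    trait
        Phenotype name.
    sex_group
        ``"male"``, ``"female"`` or ``"combined"``.
    scale
        ``"standardized"`` (SD/SD units) or ``"raw-binary"``.
    """

    table: pd.DataFrame
    trait: str = ""
    sex_group: str = "combined"
    scale: str = "standardized"

    def __post_init__(self) -> None:
        missing = [c for c in COLUMNS if c not in self.table.columns]
        if missing:
            raise SumStatsFormatError(f"missing mandatory column(s): {missing}")
        t = self.table
        if t["variant"].duplicated().any():
            raise ValueError("duplicate variant ids in summary statistics")
        ok = t["beta"].notna() & t["se"].notna()
        if (t.loc[ok, "se"] <= 0).any():
            raise ValueError("non-positive standard errors in summary statistics")
        self._check_pval_consistency()

    def _check_pval_consistency(self) -> None:
        # z-based two-sided normal p should agree with the stored p within
        # ~10% relative tolerance; disagreement is flagged, not fatal (a t
        # reference at modest n legitimately deviates).
        t = self.table
        ok = t["beta"].notna() & t["se"].notna() & t["pval"].notna()
        if not ok.any():
            return
        z = np.abs(t.loc[ok, "beta"] / t.loc[ok, "se"])
        expected = 2.0 * stats.norm.sf(z)
        stored = t.loc[ok, "pval"].to_numpy(float)
        sane = expected > 1e-300
        with np.errstate(divide="ignore", invalid="ignore"):
            rel = np.abs(stored[sane] - expected[sane]) / expected[sane]
        n_bad = int((rel > 0.10).sum()) if sane.any() else 0
        if n_bad:
            warnings.warn(
                f"{n_bad} rows have p-values inconsistent with beta/se under "
                "a two-sided normal test (>10% relative)",
                stacklevel=3,
            )

    def __len__(self) -> int:
        return len(self.table)

    @property
    def variants(self) -> pd.Index:
        return pd.Index(self.table["variant"])

    def indexed(self) -> pd.DataFrame:
        """Table indexed by variant id."""
        return self.table.set_index("variant")


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    trait: str = "",
    sex_group: str = "combined",
    scale: str = "standardized",
) -> SumStats:
    """Read a tab-separated summary-statistics file.

    ``column_map`` maps canonical names to the file's column names for
    foreign dialects, e.g. ``{"variant": "SNP", "pval": "P"}``. Rows with
    missing beta or se are dropped with a logged count.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        rename = {src: canon for canon, src in column_map.items()}
        miss = [src for src in column_map.values() if src not in df.columns]
        if miss:
            raise SumStatsFormatError(f"mapped column(s) absent from file: {miss}")
        df = df.rename(columns=rename)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SumStatsFormatError(f"missing mandatory column(s): {missing}")
    df = df[COLUMNS].copy()
    df["chrom"] = df["chrom"].map(_norm_chrom)
    for col in ("pos", "n"):
        df[col] = pd.to_numeric(df[col]).astype(np.int64)
    for col in ("minor_AF", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
    bad = df["beta"].isna() | df["se"].isna()
    if bad.any():
        logger.info("dropped %d rows with missing beta or se", int(bad.sum()))
        df = df.loc[~bad].reset_index(drop=True)
    return SumStats(df, trait=trait, sex_group=sex_group, scale=scale)


def write_sumstats(ss: SumStats, path) -> None:
    """Write the canonical tab-separated dialect."""
    ss.table.to_csv(path, sep="\t", index=False)


def standardize_binary(ss: SumStats, trait_variance: float) -> SumStats:
    """Convert raw-binary effects to the SD scale.

    Divides beta and se by ``sqrt(trait_variance)`` — for a disease of
    prevalence p the variance is p(1-p) — and retags the table
    ``standardized``. P-values are untouched (the z-score is invariant).
    """
    if ss.scale != "raw-binary":
        raise ValueError(f"expected a raw-binary table, got scale={ss.scale!r}")
    if not (0 < trait_variance <= 0.25):
        raise ValueError(
            f"trait_variance must lie in (0, 0.25] for a binary trait, got {trait_variance}"
        )
    factor = 1.0 / np.sqrt(trait_variance)
    t = ss.table.copy()
    t["beta"] = t["beta"] * factor
    t["se"] = t["se"] * factor
    return replace(ss, table=t, scale="standardized")


def filter_variants(
    ss: SumStats,
    maf_min: float = 0.001,
    exclusion_regions: Sequence[tuple[str, int, int]] = (HLA_REGION,),
) -> SumStats:
    """Apply the MAF floor and region exclusions.

    Variants with minor-allele frequency strictly below ``maf_min`` are
    removed (the boundary is kept), as are variants falling inside any
    exclusion region, 1-based and inclusive at both ends. The default
    exclusion is the HLA region, whose pervasive long-range LD breaks
    the independence assumptions of pruning and MR.
    """
    t = ss.table
    keep = t["minor_AF"] >= maf_min
    n_maf = int((~keep).sum())
    for chrom, start, end in exclusion_regions:
        chrom = _norm_chrom(chrom)
        inside = (t["chrom"].map(_norm_chrom) == chrom) & (t["pos"] >= start) & (t["pos"] <= end)
        keep &= ~inside
    n_region = int(len(t) - keep.sum() - n_maf)
    logger.info(
        "filter_variants: removed %d by MAF < %g, %d in excluded regions", n_maf, maf_min, n_region
    )
    return replace(ss, table=t.loc[keep].reset_index(drop=True))


# ---------------------------------------------------------------------------
# LD panel


@dataclass
class LDPanel:
    """Pairwise-r² lookup backed by a dosage matrix or a sparse pair list."""

    ids: pd.Index
    chrom: np.ndarray
    pos: np.ndarray
    _std_dosages: np.ndarray | None = None  # individuals x variants, standardized
    _pair_r2: dict | None = None
    _loc: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._loc = {v: i for i, v in enumerate(self.ids)}

    @classmethod
    def from_dosages(cls, dosages: np.ndarray, variants: pd.DataFrame) -> "LDPanel":
        """Build from an individuals x variants dosage matrix.

        ``variants`` needs columns ``variant, chrom, pos`` aligned with the
        dosage columns. Monomorphic columns get zero vectors (r² = 0 with
        everything, 1 with themselves by convention).
        """
        d = np.asarray(dosages, dtype=float)
        d = d - d.mean(axis=0)
        norm = np.sqrt((d**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            d = np.where(norm > 0, d / norm, 0.0)
        return cls(
            ids=pd.Index(variants["variant"]),
            chrom=variants["chrom"].map(_norm_chrom).to_numpy(),
            pos=variants["pos"].to_numpy(np.int64),
            _std_dosages=d,
        )

    @classmethod
    def from_pairs(cls, pairs: pd.DataFrame, variants: pd.DataFrame) -> "LDPanel":
        """Build from a 3-column (id_a, id_b, r2) pair list; absent pairs are r²=0."""
        lut: dict = {}
        for a, b, r2 in pairs.itertuples(index=False):
            lut[(a, b)] = float(r2)
            lut[(b, a)] = float(r2)
        return cls(
            ids=pd.Index(variants["variant"]),
            chrom=variants["chrom"].map(_norm_chrom).to_numpy(),
            pos=variants["pos"].to_numpy(np.int64),
            _pair_r2=lut,
        )

    def __contains__(self, vid: str) -> bool:
        return vid in self._loc

    def r2(self, a: str, b: str) -> float:
        """Squared LD correlation between two variants; r2(a, a) = 1."""
        if a == b:
            return 1.0
        if self._std_dosages is not None:
            r = float(self._std_dosages[:, self._loc[a]] @ self._std_dosages[:, self._loc[b]])
            return r * r
        return self._pair_r2.get((a, b), 0.0)

    def position(self, vid: str) -> tuple[str, int]:
        i = self._loc[vid]
        return str(self.chrom[i]), int(self.pos[i])


def _independent(panel: LDPanel, a: str, b: str, dist_bp: int, r2_max: float) -> bool:
    ca, pa = panel.position(a)
    cb, pb = panel.position(b)
    if ca != cb:
        return True
    if abs(pa - pb) > dist_bp:
        return True
    return panel.r2(a, b) < r2_max


def prune(
    candidates: Sequence[str],
    ld: LDPanel,
    dist_bp: int = 10_000_000,
    r2_max: float = 0.01,
) -> list[str]:
    """Greedy LD pruning of a priority-ordered candidate list.

    ``candidates`` must be ordered best-first (e.g. the output of
    :func:`multi_trait_priority`, or ascending p-value for a single
    trait). A candidate is kept iff against every already-kept variant it
    is on a different chromosome, OR more than ``dist_bp`` away, OR in
    linkage disequilibrium below ``r2_max``. The kept set is returned
    sorted by genomic position.
    """
    kept: list[str] = []
    n_absent = 0
    for vid in candidates:
        if vid not in ld:
            n_absent += 1
            continue
        if all(_independent(ld, vid, k, dist_bp, r2_max) for k in kept):
            kept.append(vid)
    if n_absent:
        warnings.warn(f"prune: {n_absent} candidate(s) absent from LD panel, dropped")

    def sort_key(v: str):
        c, p = ld.position(v)
        return (c.zfill(2) if c.isdigit() else c, p)

    return sorted(kept, key=sort_key)


def multi_trait_priority(pval_matrix: pd.DataFrame, gws: float = GWS) -> pd.Series:
    """Priority ordering of SNPs across traits by best within-trait rank.

    For each trait, genome-wide-significant SNPs are ranked by ascending
    p-value (rank 1 = smallest); each SNP's priority score is its best
    rank across traits. This stops a single well-powered trait from
    monopolizing the selection: a SNP that tops a weakly powered trait
    outranks one buried at rank 50 of a strong trait. Ties break by the
    smallest p-value across traits, then by variant id.

    Returns a Series of priority scores indexed by variant id, in
    selection order. SNPs significant nowhere are excluded; if none is
    significant the result is empty (with a warning).
    """
    pm = pval_matrix
    best_rank = pd.Series(np.inf, index=pm.index)
    for trait in pm.columns:
        p = pm[trait]
        sig = p < gws
        if not sig.any():
            continue
        ranks = p[sig].rank(method="first")
        best_rank.loc[ranks.index] = np.minimum(best_rank.loc[ranks.index], ranks)
    keep = best_rank[np.isfinite(best_rank)]
    if keep.empty:
        warnings.warn("no genome-wide significant SNP in any trait")
        return pd.Series(dtype=float, name="priority")
    order = pd.DataFrame(
        {"priority": keep, "best_p": pm.loc[keep.index].min(axis=1), "vid": keep.index}
    ).sort_values(["priority", "best_p", "vid"])
    out = order["priority"]
    out.name = "priority"
    return out
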