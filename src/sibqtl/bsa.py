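"""Pool-seq bulked-segregant Fst scan.

Two DNA pools (fast- and slow-growing extremes of a full-sib family) are
compared per SNP with a nucleotide-diversity based fixation index:

    Pi        = 1 - fA^2 - fC^2 - fG^2 - fT^2
    Pi_within = (Pi_pool1 + Pi_pool2) / 2
    Fst       = (Pi_total - Pi_within) / Pi_total

where fN is the frequency of nucleotide N in one pool and Pi_total is the Pi
of the combined allele-frequency vector of the two pools.  Sites passing the
allele-support, Fst and coverage filters are intersected with exon/promoter
annotations to nominate candidate genes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")
COUNT_COLS = ["nA", "nC", "nG", "nT"]

__all__ = [
    "PoolSiteCounts",
    "FstResult",
    "GeneFeature",
    "allele_frequencies",
    "site_pi",
    "site_fst",
    "fst_table",
    "scan",
    "annotate_candidates",
    "read_pool_counts",
    "read_features_bed",
    "read_features_gff3",
]


@dataclass(frozen=True)
class PoolSiteCounts:
    """Read counts of the four nucleotides at one site in one DNA pool."""

    site_id: str
    contig: str
    position: int  # 1-based
    nA: int
    nC: int
    nG: int
    nT: int

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        for base in BASES:
            if getattr(self, "n" + base) < 0:
                raise ValueError(f"negative {base} count at {self.site_id}")

    @property
    def counts(self) -> np.ndarray:
        return np.array([self.nA, self.nC, self.nG, self.nT], dtype=float)

    @property
    def depth(self) -> int:
        return self.nA + self.nC + self.nG + self.nT


@dataclass(frozen=True)
class FstResult:
    """Per-site diversity decomposition for a pair of pools.

    ``fst`` is ``nan`` when the site is monomorphic across both pools
    (Pi_total = 0): 0/0 carries no evidence and the site is treated as
    undefined rather than as Fst = 0.
    """

    site_id: str
    pi_pool1: float
    pi_pool2: float
    pi_within: float
    pi_total: float
    fst: float
    depth1: int
    depth2: int


@dataclass(frozen=True)
class GeneFeature:
    """A gene-anchored genomic interval (1-based, inclusive ends)."""

    gene_id: str
    contig: str
    start: int
    end: int
    feature_kind: str  # "exon", "promoter" or "other"
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"feature {self.gene_id}:{self.feature_kind} has start "
                f"{self.start} > end {self.end}"
            )


def allele_frequencies(counts: PoolSiteCounts | np.ndarray) -> np.ndarray:
    """Nucleotide frequencies fA, fC, fG, fT from read counts.

    Raises ``ZeroDivisionError`` at zero depth (undefined site).
    """
    c = counts.counts if isinstance(counts, PoolSiteCounts) else np.asarray(counts, dtype=float)
    depth = c.sum()
    if depth <= 0:
        raise ZeroDivisionError("allele frequencies undefined at zero depth")
    return c / depth


def site_pi(freqs: np.ndarray) -> float:
    """Nucleotide diversity Pi = 1 - sum(fN^2); in [0, 0.75]."""
    f = np.asarray(freqs, dtype=float)
    if not math.isclose(f.sum(), 1.0, abs_tol=1e-9):
        raise ValueError("frequencies must sum to 1")
    return float(1.0 - np.sum(f * f))


def site_fst(
    pool1: PoolSiteCounts,
    pool2: PoolSiteCounts,
    weighted: bool = False,
) -> FstResult:
    """Pi-based Fst for one site.

    ``weighted=False`` (default) forms the total frequency vector as the
    unweighted mean of the two pools' frequency vectors; the two pools were
    designed equal-sized, so each pool contributes equally regardless of its
    sequencing depth.  ``weighted=True`` pools the raw read counts instead.
    """
    if pool1.depth <= 0 or pool2.depth <= 0:
        raise ZeroDivisionError(f"zero depth at site {pool1.site_id}")
    f1 = allele_frequencies(pool1)
    f2 = allele_frequencies(pool2)
    pi1 = site_pi(f1)
    pi2 = site_pi(f2)
    pi_within = 0.5 * (pi1 + pi2)
    if weighted:
        f_tot = (pool1.counts + pool2.counts) / (pool1.depth + pool2.depth)
    else:
        f_tot = 0.5 * (f1 + f2)
    pi_total = site_pi(f_tot)
    fst = (pi_total - pi_within) / pi_total if pi_total > 0 else float("nan")
    return FstResult(
        site_id=pool1.site_id,
        pi_pool1=pi1,
        pi_pool2=pi2,
        pi_within=pi_within,
        pi_total=pi_total,
        fst=fst,
        depth1=pool1.depth,
        depth2=pool2.depth,
    )


def _freq_matrix(counts: np.ndarray) -> np.ndarray:
    depth = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return counts / depth


def fst_table(
    pool1: pd.DataFrame,
    pool2: pd.DataFrame,
    min_allele_reads: int = 4,
    min_fst: float = 0.5,
    min_coverage: int = 20,
    weighted: bool = False,
) -> pd.DataFrame:
    """Vectorised per-site Fst with filter flags for two pool-count tables.

    Input tables need columns site_id, contig, pos and nA, nC, nG, nT.  Sites
    present in only one table are dropped with a warning.  Within each pool,
    alleles supported by fewer than ``min_allele_reads`` reads are treated as
    unsupported (masked to zero) before frequencies are computed, mirroring
    the caller-side allele-support requirement; a site must remain polymorphic
    (>= 2 supported alleles across the union of pools) to pass.

    Returns one row per shared site with pi/fst values, depths and boolean
    columns ``pass_support``, ``pass_coverage``, ``pass_fst``, ``pass_all``.
    """
    p1 = pool1.set_index("site_id")
    p2 = pool2.set_index("site_id")
    shared = p1.index.intersection(p2.index)
    if len(shared) == 0:
        raise ValueError("pool tables share no sites")
    dropped = (len(p1) - len(shared)) + (len(p2) - len(shared))
    if dropped:
        warnings.warn(f"{dropped} sites present in only one pool were dropped")
    p1 = p1.loc[shared]
    p2 = p2.loc[shared]

    raw1 = p1[COUNT_COLS].to_numpy(dtype=float)
    raw2 = p2[COUNT_COLS].to_numpy(dtype=float)
    depth1 = raw1.sum(axis=1)
    depth2 = raw2.sum(axis=1)

    c1 = np.where(raw1 >= min_allele_reads, raw1, 0.0)
    c2 = np.where(raw2 >= min_allele_reads, raw2, 0.0)
    supported = ((c1 > 0) | (c2 > 0)).sum(axis=1)
    sup_depth1 = c1.sum(axis=1)
    sup_depth2 = c2.sum(axis=1)
    ok = (sup_depth1 > 0) & (sup_depth2 > 0)

    f1 = np.full_like(c1, np.nan)
    f2 = np.full_like(c2, np.nan)
    f1[ok] = _freq_matrix(c1[ok])
    f2[ok] = _freq_matrix(c2[ok])
    pi1 = 1.0 - np.sum(f1 * f1, axis=1)
    pi2 = 1.0 - np.sum(f2 * f2, axis=1)
    pi_within = 0.5 * (pi1 + pi2)
    if weighted:
        tot = c1 + c2
        f_tot = np.full_like(tot, np.nan)
        f_tot[ok] = _freq_matrix(tot[ok])
    else:
        f_tot = 0.5 * (f1 + f2)
    pi_total = 1.0 - np.sum(f_tot * f_tot, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fst = np.where(pi_total > 0, (pi_total - pi_within) / pi_total, np.nan)

    out = pd.DataFrame(
        {
            "site_id": shared,
            "contig": p1["contig"].to_numpy(),
            "pos": p1["pos"].to_numpy(),
            "pi1": pi1,
            "pi2": pi2,
            "pi_within": pi_within,
            "pi_total": pi_total,
            "fst": fst,
            "depth1": depth1.astype(int),
            "depth2": depth2.astype(int),
        }
    )
    out["pass_support"] = ok & (supported >= 2)
    out["pass_coverage"] = (depth1 > min_coverage) & (depth2 > min_coverage)
    out["pass_fst"] = np.nan_to_num(fst, nan=-1.0) > min_fst
    out["pass_all"] = out.pass_support & out.pass_coverage & out.pass_fst
    return out.reset_index(drop=True)


def scan(
    pool1: pd.DataFrame,
    pool2: pd.DataFrame,
    min_allele_reads: int = 4,
    min_fst: float = 0.5,
    min_coverage: int = 20,
    weighted: bool = False,
) -> pd.DataFrame:
    """Sites passing all filters, sorted by descending Fst (ties by contig,
    position)."""
    table = fst_table(
        pool1,
        pool2,
        min_allele_reads=min_allele_reads,
        min_fst=min_fst,
        min_coverage=min_coverage,
        weighted=weighted,
    )
    hits = table[table.pass_all].copy()
    hits = hits.sort_values(
        ["fst", "contig", "pos"], ascending=[False, True, True], kind="mergesort"
    )
    return hits.reset_index(drop=True)


def annotate_candidates(
    hits: pd.DataFrame,
    features: list[GeneFeature],
) -> tuple[pd.DataFrame, list[str]]:
    """Intersect scan hits with exon/promoter features.

    A site maps to every exon or promoter feature whose 1-based inclusive
    interval contains its position (strand ignored: a SNP position is
    strandless); sites overlapping no such feature are excluded.  Returns the
    site-to-gene table and the unique candidate-gene list (first-hit order),
    mirroring the many-SNPs-per-gene aggregation of the study design.
    """
    by_contig: dict[str, list[GeneFeature]] = {}
    for feat in features:
        if feat.feature_kind in ("exon", "promoter"):
            by_contig.setdefault(feat.contig, []).append(feat)

    rows = []
    for rec in hits.itertuples(index=False):
        for feat in by_contig.get(rec.contig, ()):
            if feat.start <= rec.pos <= feat.end:
                rows.append(
                    {
                        "site_id": rec.site_id,
                        "contig": rec.contig,
                        "pos": rec.pos,
                        "fst": rec.fst,
                        "gene_id": feat.gene_id,
                        "feature_kind": feat.feature_kind,
                    }
                )
    mapped = pd.DataFrame(
        rows, columns=["site_id", "contig", "pos", "fst", "gene_id", "feature_kind"]
    )
    genes = list(dict.fromkeys(mapped["gene_id"]))
    return mapped, genes


def read_pool_counts(path: str) -> pd.DataFrame:
    """Read a pool-counts TSV (site_id, contig, pos, ref, nA, nC, nG, nT)."""
    df = pd.read_csv(path, sep="\t")
    missing = {"site_id", "contig", "pos", *COUNT_COLS} - set(df.columns)
    if missing:
        raise ValueError(f"pool-counts table {path} lacks columns {sorted(missing)}")
    return df


def read_features_bed(path: str) -> list[GeneFeature]:
    """Read gene features from BED (0-based half-open; converted to 1-based
    inclusive).  The name column carries ``gene_id:feature_kind``."""
    df = pd.read_csv(
        path, sep="\t", header=None, comment="#",
        names=["contig", "start", "end", "name", "score", "strand"],
        usecols=range(6),
    )
    feats = []
    for rec in df.itertuples(index=False):
        gene_id, _, kind = str(rec.name).partition(":")
        feats.append(
            GeneFeature(
                gene_id=gene_id,
                contig=str(rec.contig),
                start=int(rec.start) + 1,
                end=int(rec.end),
                feature_kind=kind or "other",
                strand=str(rec.strand),
            )
        )
    return feats


def read_features_gff3(path: str) -> list[GeneFeature]:
    """Read gene features from GFF3 (1-based inclusive).  feature_kind is the
    type column; gene_id comes from the gene_id=, Parent= or ID= attribute."""
    feats = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 9:
                raise ValueError(f"malformed GFF3 line: {line!r}")
            contig, _, kind, start, end, _, strand, _, attrs = parts[:9]
            attr = dict(
                kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
            )
            gene_id = attr.get("gene_id") or attr.get("Parent") or attr.get("ID")
            if gene_id is None:
                raise ValueError(f"GFF3 record without identifier: {line!r}")
            feats.append(
                GeneFeature(
                    gene_id=gene_id,
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    feature_kind=kind,
                    strand=strand,
                )
            )
    return feats
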