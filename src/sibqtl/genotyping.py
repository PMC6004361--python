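"""Per-sample amplicon genotyping.

Demultiplexed read pairs are anchored to their amplicon by an exact match of
the primer region (the bases immediately after the barcode) against the known
amplicon reference prefixes/suffixes, the base at each target SNP offset is
tallied, and diploid genotypes are called from allele fractions.  Sites are
then filtered on minor allele frequency and call rate.

Amplicons are short (<= 290 bp) known sequences, so primer-anchored offset
lookup replaces read alignment: on such references an aligner changes nothing
about the tally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .fastq import ReadPair

__all__ = [
    "AmpliconTarget",
    "GenotypeCall",
    "GenotypeMatrix",
    "pileup_alleles",
    "call_genotype",
    "genotype_samples",
    "filter_sites",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
BASES = ("A", "C", "G", "T")
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

MAX_AMPLICON_LENGTH = 290


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class AmpliconTarget:
    """One target SNP on one amplicon reference.

    ``snp_offset`` is 1-based within the amplicon sequence.  Several targets
    may share an amplicon (same amplicon_id and sequence, different offsets),
    mirroring re-sequencing panels that carry more SNP loci than primer
    pairs.  ``site_id`` defaults to the amplicon id.
    """

    amplicon_id: str
    sequence: str
    snp_offset: int
    ref: str
    alt: str
    primer_len: int = 20
    site_id: str = ""

    def __post_init__(self) -> None:
        if not self.site_id:
            object.__setattr__(self, "site_id", self.amplicon_id)
        if len(self.sequence) > MAX_AMPLICON_LENGTH:
            raise ValueError(
                f"amplicon {self.amplicon_id} is {len(self.sequence)} bp; "
                f"PCR products are kept within {MAX_AMPLICON_LENGTH} bp"
            )
        if not (1 <= self.snp_offset <= len(self.sequence)):
            raise ValueError(f"SNP offset outside amplicon {self.amplicon_id}")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt at amplicon {self.amplicon_id}")

    @property
    def fwd_primer(self) -> str:
        return self.sequence[: self.primer_len]

    @property
    def rev_primer(self) -> str:
        """Primer region as it appears at the start of the reverse read."""
        return revcomp(self.sequence[-self.primer_len :])


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    site_id: str
    dosage: float  # 0/1/2 alt-allele dosage; nan if missing
    counts: tuple[int, int, int, int]
    depth: int
    reason: str | None = None  # populated for missing calls

    @property
    def missing(self) -> bool:
        return not np.isfinite(self.dosage)


def pileup_alleles(
    pairs: Iterable[ReadPair],
    targets: Iterable[AmpliconTarget],
    barcode_len: int = 20,
    read_len: int = 150,
) -> tuple[dict[str, np.ndarray], int]:
    """Tally the base at each target SNP across one sample's read pairs.

    Each pair is anchored via the forward-primer region of read 1 (or, for
    orientation-swapped pairs, of read 2); the SNP base is taken from
    whichever mate covers the offset.  Returns ({amplicon_id: ACGT counts},
    unanchored pair count).
    """
    targets = list(targets)
    groups: dict[str, list[AmpliconTarget]] = {}
    fwd: dict[str, str] = {}
    for t in targets:
        groups.setdefault(t.amplicon_id, []).append(t)
    for amp_id, grp in groups.items():
        if len({t.sequence for t in grp}) != 1:
            raise ValueError(f"conflicting sequences for amplicon {amp_id}")
        primer = grp[0].fwd_primer
        if primer in fwd:
            raise ValueError("amplicon primer regions are not unique")
        fwd[primer] = amp_id
    counts = {t.site_id: np.zeros(4, dtype=int) for t in targets}
    core = read_len - barcode_len
    unanchored = 0
    for pair in pairs:
        r1, r2 = pair.seq1, pair.seq2
        anchor1 = r1[barcode_len : barcode_len + 20]
        amp_id = fwd.get(anchor1)
        if amp_id is None and r2[barcode_len : barcode_len + 20] in fwd:
            # orientation-swapped pair
            r1, r2 = r2, r1
            amp_id = fwd[r1[barcode_len : barcode_len + 20]]
        if amp_id is None:
            unanchored += 1
            continue
        tallied = False
        for target in groups[amp_id]:
            base = _snp_base(r1, r2, target, barcode_len, core)
            if base is None:
                continue
            idx = _BASE_INDEX.get(base)
            if idx is not None:
                counts[target.site_id][idx] += 1
                tallied = True
        if not tallied:
            unanchored += 1
    return counts, unanchored


def _snp_base(
    r1: str, r2: str, target: AmpliconTarget, barcode_len: int, core: int
) -> str | None:
    """Base at the target SNP, read from whichever mate covers the offset."""
    off0 = target.snp_offset - 1
    if off0 < core:
        pos = barcode_len + off0
        if pos < len(r1):
            return r1[pos]
    length = len(target.sequence)
    tail_start = max(0, length - core)
    if off0 >= tail_start:
        pos_in_tail = off0 - tail_start
        tail_len = length - tail_start
        pos = barcode_len + (tail_len - 1 - pos_in_tail)
        if pos < len(r2):
            return r2[pos].translate(_COMPLEMENT)
    return None


def call_genotype(
    counts: np.ndarray,
    ref: str,
    alt: str,
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.25, 0.75),
    hom_min: float = 0.9,
) -> tuple[float, str | None]:
    """Diploid call from ACGT counts at one site for one sample.

    Returns (alt-allele dosage, reason); dosage is nan for missing calls.
    Depth below ``min_depth`` is missing; a top-allele fraction >= ``hom_min``
    is homozygous; a second-allele fraction inside ``het_band`` is
    heterozygous; anything else is missing(ambiguous).  Calls involving an
    allele other than ref/alt are missing(non_target_allele).
    """
    c = np.asarray(counts, dtype=float)
    depth = c.sum()
    if depth < min_depth:
        return float("nan"), "low_depth"
    order = np.argsort(c)[::-1]
    top, second = BASES[order[0]], BASES[order[1]]
    top_frac = c[order[0]] / depth
    second_frac = c[order[1]] / depth
    if top_frac >= hom_min:
        if top == ref:
            return 0.0, None
        if top == alt:
            return 2.0, None
        return float("nan"), "non_target_allele"
    if het_band[0] <= second_frac <= het_band[1]:
        if {top, second} == {ref, alt}:
            return 1.0, None
        return float("nan"), "non_target_allele"
    return float("nan"), "ambiguous"


@dataclass
class GenotypeMatrix:
    """Individuals x SNP sites dosage matrix with site metadata.

    ``dosage`` holds 0/1/2 alt-allele dosage with NaN for missing calls;
    ``sites`` has one row per site (site_id, ref, alt, ...).
    """

    dosage: pd.DataFrame
    sites: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        self.sites = self.sites.set_index("site_id") if "site_id" in self.sites.columns else self.sites
        missing = set(self.dosage.columns) - set(self.sites.index)
        if missing:
            raise ValueError(f"sites table lacks metadata for {sorted(missing)}")

    @property
    def site_ids(self) -> list[str]:
        return list(self.dosage.columns)

    @property
    def individuals(self) -> list[str]:
        return list(self.dosage.index)

    def call_rate(self) -> pd.Series:
        return self.dosage.notna().mean(axis=0)

    def maf(self) -> pd.Series:
        """Minor allele frequency on the allele-count (2n) basis over called
        genotypes."""
        called = self.dosage.notna().sum(axis=0)
        with np.errstate(invalid="ignore"):
            alt_freq = self.dosage.sum(axis=0, skipna=True) / (2.0 * called)
        return np.minimum(alt_freq, 1.0 - alt_freq)

    def genotype_labels(self, site_id: str) -> pd.Series:
        """Genotype strings (e.g. TT/TG/GG) for one site, NaN-preserving.
        Heterozygotes are written ref-then-alt."""
        ref = self.sites.loc[site_id, "ref"]
        alt = self.sites.loc[site_id, "alt"]
        mapping = {0.0: ref + ref, 1.0: ref + alt, 2.0: alt + alt}
        return self.dosage[site_id].map(mapping)

    def to_tsv(self, path: str, sites_path: str | None = None) -> None:
        coded = self.dosage.copy()
        coded.index.name = "individual_id"
        coded.to_csv(path, sep="\t", na_rep="NA")
        if sites_path:
            self.sites.to_csv(sites_path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str, sites_path: str) -> "GenotypeMatrix":
        dosage = pd.read_csv(path, sep="\t", index_col="individual_id", na_values="NA")
        dosage.index = dosage.index.astype(str)
        sites = pd.read_csv(sites_path, sep="\t")
        return cls(dosage=dosage, sites=sites)

    def to_vcf_like(self, path: str) -> None:
        """Minimal VCF-style export (CHROM=amplicon, POS=offset, GT codes)."""
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write(
                "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                + "\t".join(str(i) for i in self.individuals)
                + "\n"
            )
            for site in self.site_ids:
                meta = self.sites.loc[site]
                chrom = meta.get("amplicon_id", site)
                pos = int(meta.get("snp_offset", 1))
                gts = "\t".join(
                    gt_map.get(v, "./.") for v in self.dosage[site].tolist()
                )
                fh.write(
                    f"{chrom}\t{pos}\t{site}\t{meta['ref']}\t{meta['alt']}\t.\t.\t.\tGT\t{gts}\n"
                )


def genotype_samples(
    reads_by_sample: Mapping[str, Iterable[ReadPair]],
    targets: Iterable[AmpliconTarget],
    min_depth: int = 10,
    het_band: tuple[float, float] = (0.25, 0.75),
    hom_min: float = 0.9,
    barcode_len: int = 20,
) -> GenotypeMatrix:
    """Pile up and call every sample at every target SNP."""
    targets = list(targets)
    site_ids = [t.site_id for t in targets]
    rows = {}
    for sample, pairs in reads_by_sample.items():
        counts, _ = pileup_alleles(pairs, targets, barcode_len=barcode_len)
        rows[str(sample)] = [
            call_genotype(
                counts[t.site_id], t.ref, t.alt,
                min_depth=min_depth, het_band=het_band, hom_min=hom_min,
            )[0]
            for t in targets
        ]
    dosage = pd.DataFrame.from_dict(rows, orient="index", columns=site_ids)
    sites = pd.DataFrame(
        {
            "site_id": site_ids,
            "amplicon_id": [t.amplicon_id for t in targets],
            "snp_offset": [t.snp_offset for t in targets],
            "ref": [t.ref for t in targets],
            "alt": [t.alt for t in targets],
        }
    )
    return GenotypeMatrix(dosage=dosage, sites=sites)


def filter_sites(
    matrix: GenotypeMatrix,
    min_maf: float = 0.05,
    min_call_rate: float = 0.9,
) -> GenotypeMatrix:
    """Keep sites with MAF > ``min_maf`` and call rate > ``min_call_rate``
    (both strict, matching the screening thresholds); individuals untouched.
    Idempotent."""
    keep = (matrix.maf() > min_maf) & (matrix.call_rate() > min_call_rate)
    kept = [s for s in matrix.site_ids if keep[s]]
    if not kept:
        warnings.warn("all sites removed by MAF/call-rate filters")
    return GenotypeMatrix(
        dosage=matrix.dosage[kept].copy(),
        sites=matrix.sites.loc[kept].reset_index(),
    )
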