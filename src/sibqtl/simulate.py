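"""Synthetic full-sib family generator.

Emulates the statistical structure of a transgenic carp growth-mapping study:
one het x het parent pair, ~442 offspring segregating 1:2:1 at unlinked
biallelic markers, a bimodal weight/length distribution driven by a major
growth locus (genotypes TT < TG < GG) modulated by a helper locus, pooled
sequencing of the 30 individuals nearest each phenotype peak at ~40x depth,
and dual-barcoded paired amplicon reads for per-individual re-sequencing.

Phenotypes are a free 3x3 two-locus class-mean table plus Gaussian noise, so
non-additive patterns (the GG+CC / GG+TT combinations beating GG+CT) are
expressible.  All randomness flows from ``SimConfig.seed``; identical configs
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import effects
from .demux import BarcodeScheme
from .fastq import READ_LENGTH, ReadPair
from .genotyping import AmpliconTarget, revcomp

__all__ = [
    "SimConfig",
    "Pedigree",
    "DEFAULT_GENOTYPE_MEANS",
    "simulate_family",
    "simulate_pool_counts",
    "generate_amplicon_reads",
    "random_barcode_scheme",
    "make_amplicon_targets",
]

BASES = np.array(list("ACGT"))

MAJOR_REF, MAJOR_ALT = "T", "G"   # growth allele G; genotypes TT/TG/GG
HELPER_REF, HELPER_ALT = "C", "T"  # genotypes CC/CT/TT

# Two-locus class means (weight g, length mm), keyed (major, helper).
# Chosen once to emulate the study family: a bimodal distribution with a
# slow peak near 200 g / 180 mm and a fast peak near 1100 g / 340 mm, the
# major-locus ordering GG > TG > TT, and the GG+CC / GG+TT combinations
# leading the GG row.  The helper spreads the heterozygous TG row, which is
# what makes the fast density peak sit on the GG classes.
DEFAULT_GENOTYPE_MEANS: dict[tuple[str, str], tuple[float, float]] = {
    ("GG", "CC"): (1210.0, 352.0),
    ("GG", "CT"): (1180.0, 346.0),
    ("GG", "TT"): (1200.0, 350.0),
    ("TG", "CC"): (1100.0, 335.0),
    ("TG", "CT"): (900.0, 318.0),
    ("TG", "TT"): (700.0, 295.0),
    ("TT", "CC"): (250.0, 186.0),
    ("TT", "CT"): (200.0, 176.0),
    ("TT", "TT"): (230.0, 181.0),
}

_MAJOR_LABELS = {0: "TT", 1: "TG", 2: "GG"}
_HELPER_LABELS = {0: "CC", 1: "CT", 2: "TT"}


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic study.

    Defaults reproduce the emulated study conditions: 442 offspring, pools of
    30 at ~40x depth, 150 bp paired amplicon reads, and a 33% non-specific
    read fraction (two thirds of pooled amplicon data assignable to samples).
    """

    n_offspring: int = 442
    n_markers: int = 200
    n_causal: int = 2
    genotype_means: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GENOTYPE_MEANS)
    )
    residual_sd: tuple[float, float] = (120.0, 20.0)  # (g, mm)
    pool_size: int = 30
    pool_depth: float = 40.0
    amplicon_depth: int = 40
    read_error_rate: float = 0.001
    nonspecific_fraction: float = 0.33
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_offspring <= 0:
            raise ValueError("n_offspring must be positive")
        if self.pool_size > self.n_offspring / 2:
            raise ValueError("pool_size must not exceed half the offspring")
        if not 0 <= self.n_causal <= self.n_markers:
            raise ValueError("n_causal must be between 0 and n_markers")
        for rate in (self.read_error_rate, self.nonspecific_fraction):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n_causal >= 2:
            missing = {
                (m, h) for m in _MAJOR_LABELS.values() for h in _HELPER_LABELS.values()
            } - set(self.genotype_means)
            if missing:
                raise ValueError(f"genotype_means missing classes: {sorted(missing)}")

    def rng(self, stage: int) -> np.random.Generator:
        """Deterministic per-stage stream derived from the config seed."""
        return np.random.default_rng([self.seed, stage])


@dataclass
class Pedigree:
    """Two het x het parents and their full-sib offspring.

    ``dosage`` holds alt-allele dosage 0/1/2 per offspring x marker; both
    parents are heterozygous at every marker, so every offspring allele is by
    construction drawn from a parental allele and markers segregate 1:2:1.
    """

    markers: pd.DataFrame  # site_id, contig, pos, ref, alt, role
    dosage: pd.DataFrame   # individuals x site_ids
    parents: pd.DataFrame  # parent_id x site_ids (dosage, both 1)

    @property
    def major_site(self) -> str:
        return self.markers.loc[self.markers.role == "major", "site_id"].item()

    @property
    def helper_site(self) -> str:
        return self.markers.loc[self.markers.role == "helper", "site_id"].item()

    def class_labels(self) -> pd.DataFrame:
        """Per-individual (major, helper) genotype-class labels."""
        major = self.dosage[self.major_site].map(_MAJOR_LABELS)
        helper = self.dosage[self.helper_site].map(_HELPER_LABELS)
        return pd.DataFrame({"major": major, "helper": helper})


def _marker_table(config: SimConfig) -> pd.DataFrame:
    m = config.n_markers
    n_contigs = max(1, min(20, m // 10))
    contigs = [f"chr{c + 1:02d}" for c in range(n_contigs)]
    rng = config.rng(101)
    rows = []
    major_idx = m // 3
    helper_idx = (2 * m) // 3
    for i in range(m):
        if config.n_causal >= 1 and i == major_idx:
            ref, alt, role = MAJOR_REF, MAJOR_ALT, "major"
        elif config.n_causal >= 2 and i == helper_idx:
            ref, alt, role = HELPER_REF, HELPER_ALT, "helper"
        else:
            ref, alt = rng.choice(4, size=2, replace=False)
            ref, alt, role = BASES[ref], BASES[alt], "neutral"
        rows.append(
            {
                "site_id": f"m{i:04d}",
                "contig": contigs[i % n_contigs],
                "pos": 10_000 + 1_000 * (i // n_contigs),
                "ref": ref,
                "alt": alt,
                "role": role,
            }
        )
    return pd.DataFrame(rows)


def simulate_family(config: SimConfig) -> tuple[Pedigree, pd.DataFrame]:
    """Draw offspring genotypes and phenotypes for one synthetic family.

    Returns the pedigree and a phenotype table (individual_id, weight_g,
    length_mm).  Phenotype = two-locus class mean + independent Gaussian
    noise per trait; with ``n_causal`` < 2 the missing locus contributes the
    marginal class pattern of the remaining one (n_causal = 0 gives the
    family-wide mean).
    """
    markers = _marker_table(config)
    rng = config.rng(102)
    ids = [f"F{i + 1:04d}" for i in range(config.n_offspring)]
    dosage = pd.DataFrame(
        rng.binomial(2, 0.5, size=(config.n_offspring, config.n_markers)),
        index=pd.Index(ids, name="individual_id"),
        columns=markers.site_id,
    )
    parents = pd.DataFrame(
        1, index=pd.Index(["TM", "TF"], name="parent_id"), columns=markers.site_id
    )
    ped = Pedigree(markers=markers, dosage=dosage, parents=parents)

    if config.n_causal >= 2:
        labels = ped.class_labels()
        keys = list(zip(labels.major, labels.helper))
    elif config.n_causal == 1:
        major = dosage[ped.major_site].map(_MAJOR_LABELS)
        keys = [(m, "CT") for m in major]
    else:
        keys = [("TG", "CT")] * config.n_offspring
    try:
        means = np.array([config.genotype_means[k] for k in keys], dtype=float)
    except KeyError as exc:
        raise ValueError(f"genotype_means missing class {exc.args[0]}") from exc

    sd_w, sd_l = config.residual_sd
    weight = means[:, 0] + rng.normal(0.0, sd_w, size=len(keys)) if sd_w else means[:, 0]
    length = means[:, 1] + rng.normal(0.0, sd_l, size=len(keys)) if sd_l else means[:, 1]
    # body measures are positive; the far left tail of the slow class is
    # floored at a juvenile minimum rather than resampled
    phen = pd.DataFrame(
        {
            "individual_id": ids,
            "weight_g": np.maximum(weight, 20.0),
            "length_mm": np.maximum(length, 30.0),
        }
    )
    return ped, phen


def select_pools(
    ped: Pedigree, phen: pd.DataFrame, config: SimConfig
) -> tuple[list[str], list[str]]:
    """Pool membership: the ``pool_size`` individuals nearest each weight
    mode, one pool per subgroup (fast, slow)."""
    split = effects.split_subgroups(phen)
    if not split.is_bimodal:
        raise ValueError("phenotype distribution is not bimodal; cannot form pools")
    labels = split.labels
    pools = []
    for name, fallback_mode in (("fast", split.modes[1]), ("slow", split.modes[0])):
        members = phen[labels.loc[phen.individual_id].to_numpy() == name]
        if len(members) == 0:
            raise ValueError(f"{name} subgroup is empty")
        if len(members) < config.pool_size:
            raise ValueError(
                f"{name} subgroup has {len(members)} < pool_size={config.pool_size}"
            )
        mode = effects.subgroup_mode(
            members.weight_g.to_numpy(dtype=float), fallback=fallback_mode
        )
        nearest = (members.weight_g - mode).abs().nsmallest(config.pool_size)
        pools.append(members.loc[nearest.index, "individual_id"].tolist())
    return pools[0], pools[1]


def _pool_count_table(
    ped: Pedigree,
    members: Sequence[str],
    config: SimConfig,
    rng: np.random.Generator,
) -> pd.DataFrame:
    base_idx = {b: i for i, b in enumerate("ACGT")}
    dose = ped.dosage.loc[list(members)].to_numpy(dtype=float)
    alt_freq = dose.mean(axis=0) / 2.0
    m = len(alt_freq)
    depth = rng.poisson(config.pool_depth, size=m)
    alt_reads = rng.binomial(depth, alt_freq)
    ref_reads = depth - alt_reads
    counts = np.zeros((m, 4), dtype=int)
    ref_idx = ped.markers.ref.map(base_idx).to_numpy()
    alt_idx = ped.markers.alt.map(base_idx).to_numpy()
    counts[np.arange(m), ref_idx] = ref_reads
    counts[np.arange(m), alt_idx] += alt_reads
    e = config.read_error_rate
    if e > 0:
        for j in range(m):
            for src in np.flatnonzero(counts[j] > 0):
                n_err = rng.binomial(counts[j, src], e)
                if n_err:
                    counts[j, src] -= n_err
                    others = [k for k in range(4) if k != src]
                    counts[j, others] += rng.multinomial(n_err, [1 / 3] * 3)
    out = ped.markers[["site_id", "contig", "pos", "ref", "alt"]].copy()
    out[["nA", "nC", "nG", "nT"]] = counts
    return out


def simulate_pool_counts(
    ped: Pedigree,
    phen: pd.DataFrame,
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, list[str]]]:
    """Pooled read counts for the fast and slow DNA pools.

    Per site, depth ~ Poisson(pool_depth) and allele reads ~ Binomial(depth,
    pool allele frequency); sequencing error substitutes a uniform random
    other base.  Returns (fast table, slow table, pool membership).
    """
    fast, slow = select_pools(ped, phen, config)
    rng = config.rng(103)
    fast_tab = _pool_count_table(ped, fast, config, rng)
    slow_tab = _pool_count_table(ped, slow, config, rng)
    return fast_tab, slow_tab, {"fast": fast, "slow": slow}


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def random_barcode_scheme(
    sample_ids: Sequence[str],
    rng: np.random.Generator,
    barcode_len: int = 20,
) -> BarcodeScheme:
    """A combinatorial dual-barcode scheme: each sample gets a unique
    (F-barcode, R-barcode) pair from small F and R sets, as in combinatorial
    plate designs.  All 12-mer keys are distinct across both sets."""
    n = len(sample_ids)
    n_r = int(np.ceil(np.sqrt(n)))
    n_f = int(np.ceil(n / n_r))
    keys_seen: set[str] = set()
    pool: list[str] = []
    while len(pool) < n_f + n_r:
        bc = _random_seq(rng, barcode_len)
        key = bc[8:20]
        if key not in keys_seen:
            keys_seen.add(key)
            pool.append(bc)
    f_barcodes, r_barcodes = pool[:n_f], pool[n_f:]
    records = [
        (str(sid), f_barcodes[i // n_r], r_barcodes[i % n_r])
        for i, sid in enumerate(sample_ids)
    ]
    return BarcodeScheme.from_barcodes(records)


def make_amplicon_targets(
    ped: Pedigree,
    site_ids: Sequence[str],
    rng: np.random.Generator,
    length: int = 200,
    snp_offset: int = 101,
    primer_len: int = 20,
) -> list[AmpliconTarget]:
    """Synthesize one amplicon reference per selected marker, carrying the
    marker's ref allele at ``snp_offset``.  Primer regions are kept unique."""
    markers = ped.markers.set_index("site_id")
    targets: list[AmpliconTarget] = []
    fwd_seen: set[str] = set()
    for site in site_ids:
        ref = markers.loc[site, "ref"]
        alt = markers.loc[site, "alt"]
        while True:
            seq = _random_seq(rng, length)
            seq = seq[: snp_offset - 1] + ref + seq[snp_offset:]
            if seq[:primer_len] not in fwd_seen:
                break
        fwd_seen.add(seq[:primer_len])
        targets.append(
            AmpliconTarget(
                amplicon_id=f"amp_{site}",
                sequence=seq,
                snp_offset=snp_offset,
                ref=ref,
                alt=alt,
                primer_len=primer_len,
                site_id=site,
            )
        )
    return targets


def _mutate(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    n_err = rng.binomial(len(seq), error_rate)
    if n_err == 0:
        return seq
    chars = list(seq)
    for pos in rng.choice(len(seq), size=n_err, replace=False):
        current = chars[pos]
        alternatives = [b for b in "ACGT" if b != current]
        chars[pos] = alternatives[rng.integers(0, 3)]
    return "".join(chars)


def generate_amplicon_reads(
    ped: Pedigree,
    scheme: BarcodeScheme,
    targets: Iterable[AmpliconTarget],
    config: SimConfig,
) -> list[ReadPair]:
    """Barcoded paired reads for every sample x amplicon.

    Read 1 = F-barcode + amplicon prefix; read 2 = R-barcode + reverse
    complement of the amplicon suffix (the primer regions are part of the
    amplicon reference).  Heterozygotes emit each allele with probability 1/2
    per read; ``nonspecific_fraction`` of pairs carry random barcodes and a
    per-base error substitutes random other bases.  Read names encode the
    generating sample and amplicon as ground truth: "<sample>|<amplicon>|<i>".
    """
    targets = list(targets)
    rng = config.rng(104)
    barcode_len = len(scheme.table.f_barcode.iloc[0])
    core = READ_LENGTH - barcode_len
    scheme_samples = set(scheme.sample_ids)
    individuals = [i for i in ped.dosage.index if i in scheme_samples]
    if not individuals:
        raise ValueError("barcode scheme covers none of the pedigree individuals")
    bc = scheme.table.set_index("sample_id")

    # precompute per-target read cores for the two alleles
    cores: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {}
    for t in targets:
        seqs = []
        for allele in (t.ref, t.alt):
            seq = t.sequence[: t.snp_offset - 1] + allele + t.sequence[t.snp_offset :]
            seqs.append((seq[:core], revcomp(seq[-core:])))
        cores[t.site_id] = (seqs[0], seqs[1])

    depth = config.amplicon_depth
    e = config.read_error_rate
    nf = config.nonspecific_fraction
    pairs: list[ReadPair] = []
    for sample in individuals:
        f_bc = bc.loc[sample, "f_barcode"]
        r_bc = bc.loc[sample, "r_barcode"]
        for t in targets:
            dose = int(ped.dosage.loc[sample, t.site_id])
            if dose == 1:
                alleles = rng.integers(0, 2, size=depth)
            else:
                alleles = np.full(depth, 0 if dose == 0 else 1)
            nonspecific = rng.random(depth) < nf if nf > 0 else np.zeros(depth, bool)
            for i in range(depth):
                core1, core2 = cores[t.site_id][alleles[i]]
                if nonspecific[i]:
                    s1 = _random_seq(rng, barcode_len) + core1
                    s2 = _random_seq(rng, barcode_len) + core2
                else:
                    s1 = f_bc + core1
                    s2 = r_bc + core2
                if e > 0:
                    s1 = _mutate(s1, rng, e)
                    s2 = _mutate(s2, rng, e)
                pairs.append(ReadPair(f"{sample}|{t.amplicon_id}|{i}", s1, s2))
    return pairs


def with_seed(config: SimConfig, seed: int) -> SimConfig:
    """Copy of a config with a different seed."""
    return replace(config, seed=seed)
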