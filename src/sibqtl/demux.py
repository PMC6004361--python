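"""Dual-barcode demultiplexing of pooled paired amplicon reads.

Each individual is tagged by a unique combination of one F-barcode (prepended
to the forward primer) and one R-barcode (prepended to the reverse primer).
Assignment uses the 12-mer key formed by bases 9-20 of each barcode: a read
pair belongs to a sample iff one read carries the sample's F-key and the mate
carries its R-key, both starting within the first nine read positions and
matching exactly (no mismatch tolerance).  Pairs matching the keys of two
different samples are discarded as conflicting rather than arbitrated.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .fastq import ReadPair, iter_paired_fastq, write_paired_fastq

KEY_START = 8   # 0-based offset of barcode base 9
KEY_LEN = 12    # bases 9..20 inclusive
MIN_BARCODE_LEN = 20

UNASSIGNED_REASONS = ("no_f_match", "no_r_match", "unpaired_keys", "conflicting")


def barcode_key(barcode: str, sample_id: str = "?") -> str:
    """The 12-mer at barcode positions 9-20 (1-based, inclusive)."""
    barcode = barcode.upper()
    if len(barcode) < MIN_BARCODE_LEN:
        raise ValueError(
            f"barcode for sample {sample_id} is {len(barcode)} bp; need >= {MIN_BARCODE_LEN}"
        )
    if set(barcode) - set("ACGT"):
        raise ValueError(f"barcode for sample {sample_id} contains non-ACGT characters")
    return barcode[KEY_START : KEY_START + KEY_LEN]


@dataclass
class BarcodeScheme:
    """Per-sample (F-barcode, R-barcode) pairs with derived 12-mer keys."""

    table: pd.DataFrame  # sample_id, f_barcode, r_barcode, f_key, r_key
    pair_to_sample: dict[tuple[str, str], str] = field(repr=False, default_factory=dict)
    f_keys: frozenset[str] = frozenset()
    r_keys: frozenset[str] = frozenset()

    @classmethod
    def from_barcodes(cls, records: Iterable[tuple[str, str, str]]) -> "BarcodeScheme":
        """Build and validate a scheme from (sample_id, f_barcode, r_barcode)."""
        rows = []
        pair_map: dict[tuple[str, str], str] = {}
        for sample_id, f_bc, r_bc in records:
            f_key = barcode_key(f_bc, sample_id)
            r_key = barcode_key(r_bc, sample_id)
            if (f_key, r_key) in pair_map:
                raise ValueError(
                    f"duplicate barcode combination for samples "
                    f"{pair_map[(f_key, r_key)]} and {sample_id}"
                )
            pair_map[(f_key, r_key)] = str(sample_id)
            rows.append(
                {
                    "sample_id": str(sample_id),
                    "f_barcode": f_bc,
                    "r_barcode": r_bc,
                    "f_key": f_key,
                    "r_key": r_key,
                }
            )
        if not rows:
            raise ValueError("empty barcode scheme")
        table = pd.DataFrame(rows)
        return cls(
            table=table,
            pair_to_sample=pair_map,
            f_keys=frozenset(table.f_key),
            r_keys=frozenset(table.r_key),
        )

    @classmethod
    def from_tsv(cls, path: str) -> "BarcodeScheme":
        df = pd.read_csv(path, sep="\t", dtype=str)
        return cls.from_barcodes(
            df[["sample_id", "f_barcode", "r_barcode"]].itertuples(index=False, name=None)
        )

    def to_tsv(self, path: str) -> None:
        self.table[["sample_id", "f_barcode", "r_barcode"]].to_csv(
            path, sep="\t", index=False
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.sample_id)


def _find_keys(seq: str, keys: frozenset[str], max_key_start: int) -> set[str]:
    found = set()
    limit = min(max_key_start, len(seq) - KEY_LEN + 1)
    for off in range(limit):
        k = seq[off : off + KEY_LEN]
        if k in keys:
            found.add(k)
    return found


def assign_pair(
    read1: str,
    read2: str,
    scheme: BarcodeScheme,
    max_key_start: int = 9,
) -> tuple[str | None, str | None]:
    """Assign one read pair; returns (sample_id, None) or (None, reason).

    Both orientations are tried (sequencers do not guarantee that the
    F-barcoded end is read 1).
    """
    f1 = _find_keys(read1, scheme.f_keys, max_key_start)
    r2 = _find_keys(read2, scheme.r_keys, max_key_start)
    f2 = _find_keys(read2, scheme.f_keys, max_key_start)
    r1 = _find_keys(read1, scheme.r_keys, max_key_start)

    candidates = {
        scheme.pair_to_sample[(f, r)]
        for f in f1
        for r in r2
        if (f, r) in scheme.pair_to_sample
    }
    candidates.update(
        scheme.pair_to_sample[(f, r)]
        for f in f2
        for r in r1
        if (f, r) in scheme.pair_to_sample
    )
    if len(candidates) == 1:
        return candidates.pop(), None
    if len(candidates) > 1:
        return None, "conflicting"
    if not f1 and not f2:
        return None, "no_f_match"
    if not r1 and not r2:
        return None, "no_r_match"
    return None, "unpaired_keys"


@dataclass
class DemuxReport:
    """Bookkeeping for one demultiplexing run."""

    total_pairs: int
    assigned_pairs: int
    per_sample: dict[str, int]
    unassigned: dict[str, int]

    def __post_init__(self) -> None:
        if self.assigned_pairs + sum(self.unassigned.values()) != self.total_pairs:
            raise AssertionError("demux conservation violated: assigned + unassigned != total")
        if sum(self.per_sample.values()) != self.assigned_pairs:
            raise AssertionError("per-sample counts do not sum to assigned count")

    @property
    def assigned_fraction(self) -> float:
        return self.assigned_pairs / self.total_pairs if self.total_pairs else 0.0

    def to_json(self, path: str) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "total_pairs": self.total_pairs,
                    "assigned_pairs": self.assigned_pairs,
                    "assigned_fraction": self.assigned_fraction,
                    "unassigned": self.unassigned,
                    "per_sample": self.per_sample,
                },
                indent=2,
            )
        )

    def to_tsv(self, path: str) -> None:
        rows = [{"sample_id": s, "pairs": n} for s, n in self.per_sample.items()]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def demux_pairs(
    pairs: Iterable[ReadPair],
    scheme: BarcodeScheme,
    max_key_start: int = 9,
) -> tuple[dict[str, list[ReadPair]], DemuxReport]:
    """Split read pairs by sample; every pair lands in exactly one bin."""
    by_sample: dict[str, list[ReadPair]] = {s: [] for s in scheme.sample_ids}
    unassigned: Counter[str] = Counter()
    total = 0
    for pair in pairs:
        total += 1
        sample, reason = assign_pair(pair.seq1, pair.seq2, scheme, max_key_start)
        if sample is None:
            unassigned[reason] += 1
        else:
            by_sample[sample].append(pair)
    report = DemuxReport(
        total_pairs=total,
        assigned_pairs=total - sum(unassigned.values()),
        per_sample={s: len(v) for s, v in by_sample.items()},
        unassigned=dict(unassigned),
    )
    return by_sample, report


def demux(
    fastq1: str,
    fastq2: str,
    scheme: BarcodeScheme,
    out_dir: str,
    max_key_start: int = 9,
) -> DemuxReport:
    """File-level demultiplexer: per-sample paired FASTQs plus TSV/JSON report."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    by_sample, report = demux_pairs(
        iter_paired_fastq(fastq1, fastq2), scheme, max_key_start
    )
    for sample, pairs in by_sample.items():
        if pairs:
            write_paired_fastq(
                pairs, str(out / f"{sample}_R1.fastq"), str(out / f"{sample}_R2.fastq")
            )
    report.to_json(str(out / "demux_report.json"))
    report.to_tsv(str(out / "demux_report.tsv"))
    return report
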