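"""UMI-aware preprocessing of raw small RNA-seq reads.

Stage order is fixed and mirrors the published pipeline: UMIs and
adapters are located and trimmed, identical (insert, UMI) reads are
collapsed to a single exemplar carrying the per-position mean quality,
then length/quality filters are applied, and surviving exemplars are
stacked by unique sequence into a tag table of per-sample counts.
De-duplication deliberately precedes filtering so that a molecule is
kept or dropped on its consensus quality, not on any single copy.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

#: rejection reason codes used by extraction and filtering
REASON_NO_ADAPTER = "no_adapter"
REASON_SHORT_UMI = "short_umi"
REASON_SHORT = "short"
REASON_LOW_QUALITY = "low_quality"
REASON_N_BASE = "n_base"


@dataclass(frozen=True)
class UmiRead:
    """A trimmed read: insert sequence, its UMI and per-base Phred scores."""

    read_id: str
    insert: str
    umi: str
    qual: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.qual) != len(self.insert):
            raise ValueError(f"{self.read_id}: quality length != insert length")


def read_fastq(path: str | Path) -> Iterable[tuple[str, str, str]]:
    """Yield (read_id, sequence, quality-string) from a Sanger FASTQ."""
    with open(path) as fh:
        for title, seq, qual in FastqGeneralIterator(fh):
            yield title.split()[0], seq, qual


def write_fastq(records: Iterable[tuple[str, str, str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def extract_insert_and_umi(
    read_id: str, seq: str, qual: str, adapter: str, umi_len: int
) -> UmiRead | tuple[None, str]:
    """Split a raw read at the first exact adapter occurrence.

    The insert is everything before the adapter and the UMI is the
    ``umi_len`` bases immediately after it.  Returns the trimmed
    :class:`UmiRead`, or ``(None, reason)`` when the adapter is absent
    (``no_adapter``) or fewer than ``umi_len`` bases follow it
    (``short_umi``).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if umi_len < 1:
        raise ValueError("umi_len must be >= 1")
    pos = seq.find(adapter)
    if pos < 0:
        return (None, REASON_NO_ADAPTER)
    umi_start = pos + len(adapter)
    if len(seq) - umi_start < umi_len:
        return (None, REASON_SHORT_UMI)
    phred = tuple(ord(c) - 33 for c in qual[:pos])
    return UmiRead(read_id, seq[:pos], seq[umi_start:umi_start + umi_len], phred)


def umi_deduplicate(reads: Sequence[UmiRead]) -> list[UmiRead]:
    """Collapse identical (insert, UMI) reads to one exemplar per group.

    The exemplar carries, at each position, the arithmetic mean of the
    group's quality scores rounded half-up to an integer, and the
    lexicographically smallest read id of the group.  Output order is
    deterministic: sorted by (insert, UMI).
    """
    groups: dict[tuple[str, str], list[UmiRead]] = {}
    for read in reads:
        groups.setdefault((read.insert, read.umi), []).append(read)
    out: list[UmiRead] = []
    for (insert, umi) in sorted(groups):
        members = groups[(insert, umi)]
        if len(members) == 1:
            out.append(members[0])
            continue
        quals = np.array([m.qual for m in members], dtype=float)
        mean_q = np.floor(quals.mean(axis=0) + 0.5).astype(int)  # round half-up
        rid = min(m.read_id for m in members)
        out.append(UmiRead(rid, insert, umi, tuple(int(q) for q in mean_q)))
    return out


def quality_length_filter(
    reads: Sequence[UmiRead],
    min_len: int = 17,
    min_phred: int = 25,
    reject_n: bool = True,
) -> tuple[list[UmiRead], list[tuple[str, str]]]:
    """Keep reads with insert length >= ``min_len``, every base at Phred
    >= ``min_phred`` (both boundaries inclusive) and, by default, no N
    bases.  Returns (kept, [(read_id, reason), ...])."""
    if min_len < 1 or min_phred < 1:
        raise ValueError("thresholds must be positive")
    kept: list[UmiRead] = []
    rejected: list[tuple[str, str]] = []
    for read in reads:
        if len(read.insert) < min_len:
            rejected.append((read.read_id, REASON_SHORT))
        elif reject_n and "N" in read.insert:
            rejected.append((read.read_id, REASON_N_BASE))
        elif read.qual and min(read.qual) < min_phred:
            rejected.append((read.read_id, REASON_LOW_QUALITY))
        else:
            kept.append(read)
    return kept, rejected


def stack_tags(
    reads_by_sample: dict[str, Sequence[UmiRead]],
    manifest: pd.DataFrame,
) -> pd.DataFrame:
    """Stack surviving exemplars by unique insert sequence.

    Returns a tag table: unique sequences (rows, sorted) x samples
    (columns, manifest order) of integer counts; zeros where a sequence
    was not seen.  Every sample key must appear in the manifest's
    ``sample`` column.
    """
    samples = list(manifest["sample"])
    unknown = set(reads_by_sample) - set(samples)
    if unknown:
        raise ValueError(f"samples absent from manifest: {sorted(unknown)}")
    counts: dict[str, dict[str, int]] = {}
    for sample, reads in reads_by_sample.items():
        for read in reads:
            row = counts.setdefault(read.insert, {})
            row[sample] = row.get(sample, 0) + 1
    table = pd.DataFrame(
        [[counts[seq].get(s, 0) for s in samples] for seq in sorted(counts)],
        index=sorted(counts), columns=samples, dtype=int,
    )
    table.index.name = "sequence"
    return table


def preprocess_sample(
    fastq_path: str | Path,
    adapter: str,
    umi_len: int,
    min_len: int = 17,
    min_phred: int = 25,
    reject_n: bool = True,
) -> tuple[list[UmiRead], list[tuple[str, str]], dict[str, int]]:
    """Full per-sample chain: extract -> dedup -> filter.

    Returns (kept exemplars, rejection log, stage counters).  The
    counters satisfy ``raw = extracted + rejected_at_extraction`` and
    ``deduped = kept + rejected_at_filter``.
    """
    extracted: list[UmiRead] = []
    rejects: list[tuple[str, str]] = []
    n_raw = 0
    for rid, seq, qual in read_fastq(fastq_path):
        n_raw += 1
        result = extract_insert_and_umi(rid, seq, qual, adapter, umi_len)
        if isinstance(result, UmiRead):
            extracted.append(result)
        else:
            rejects.append((rid, result[1]))
    deduped = umi_deduplicate(extracted)
    kept, filter_rejects = quality_length_filter(
        deduped, min_len=min_len, min_phred=min_phred, reject_n=reject_n
    )
    rejects.extend(filter_rejects)
    counters = dict(
        raw=n_raw,
        extracted=len(extracted),
        duplicates_collapsed=len(extracted) - len(deduped),
        deduplicated=len(deduped),
        kept=len(kept),
        rejected=n_raw - len(extracted) + len(deduped) - len(kept),
    )
    return kept, rejects, counters
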