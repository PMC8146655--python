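"""Hierarchical sncRNA classification by exact reference matching.

Each unique tag sequence is searched, class by class in a configurable
priority order (default miRNA > tsRNA > rsRNA > piRNA), for exact
sense-strand substring occurrences in the mature reference sets; the
first class with a hit wins and hands the match to its subtype
classifier: tRNA-derived fragments are typed by their anchoring
relative to the mature tRNA ends and the 7-nt anticodon loop (tRF5 /
tRF3 / 5'-tRH / 3'-tRH / i-tRF), rRNA fragments inherit the species of
their source rRNA, and piRNA hits carry piRBase-style target
categories.  Sequences matching no reference are 'unannotated'.

This is reference-set matching, not genome alignment: it is the
desk-scale substitute for a genome-mapping + miRDeep2 stage and is
exact by construction, which is what makes it testable against a
naive-scan oracle.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .references import ReferenceBundle, ReferenceRecord

DEFAULT_PRIORITY = ("miRNA", "tsRNA", "rsRNA", "piRNA")

UNANNOTATED = "unannotated"


@dataclass(frozen=True)
class AnnotationRecord:
    """Class/subtype assignment of one tag sequence.

    ``match_start``/``match_end`` are 1-based inclusive coordinates on
    the named reference; both are 0 for unannotated sequences.
    ``subtype`` holds the tsRNA fragment type, the rRNA species, or the
    canonical miRNA (isomiR parent); empty otherwise.
    """

    sequence: str
    assigned_class: str
    ref_id: str = ""
    subtype: str = ""
    match_start: int = 0
    match_end: int = 0
    isoacceptor: str = ""
    target_type: str = ""
    target_location: str = ""


class SubstringIndex:
    """Exact-substring search over a set of reference sequences.

    References are concatenated with a '#' sentinel so a single C-level
    ``str.find`` sweep locates all occurrences; hit positions are
    mapped back to (ref_id, 1-based start) by bisection.
    """

    def __init__(self, records: Sequence[ReferenceRecord]):
        self.records = sorted(records, key=lambda r: r.ref_id)
        self._offsets: list[int] = []
        parts: list[str] = []
        pos = 0
        for rec in self.records:
            self._offsets.append(pos)
            parts.append(rec.sequence)
            pos += len(rec.sequence) + 1
        self._text = "#".join(parts)

    def find_all(self, query: str) -> list[tuple[ReferenceRecord, int, int]]:
        """All exact occurrences as (record, start, end), 1-based inclusive."""
        hits: list[tuple[ReferenceRecord, int, int]] = []
        if not query or not self._text:
            return hits
        t = self._text.find(query)
        while t >= 0:
            i = bisect_right(self._offsets, t) - 1
            start = t - self._offsets[i]  # cannot span records: query has no '#'
            hits.append((self.records[i], start + 1, start + len(query)))
            t = self._text.find(query, t + 1)
        return hits


def match_reference(
    sequence: str, records: Sequence[ReferenceRecord] | SubstringIndex
) -> list[tuple[str, int, int]]:
    """All exact sense-strand occurrences of ``sequence`` in a reference
    set, as (ref_id, start, end) with 1-based inclusive coordinates."""
    index = records if isinstance(records, SubstringIndex) else SubstringIndex(records)
    return [(rec.ref_id, s, e) for rec, s, e in index.find_all(sequence)]


def classify_tsrna_fragment(
    match_start: int,
    match_end: int,
    trna: ReferenceRecord,
    end_slack: int = 0,
    loop_margin: int = 2,
) -> str:
    """Type a tRNA fragment by its anchoring on the mature tRNA.

    The anticodon loop is the anticodon extended by ``loop_margin`` nt
    on each side (7 nt with the default margin).  Rules, in order:
    5'-anchored fragments ending inside the loop are 5'-tRHs; 3'-anchored
    fragments (measured against the CCA-inclusive terminus) starting
    inside the loop are 3'-tRHs; 5'-anchored fragments ending before the
    loop are tRF5s; 3'-anchored fragments starting after the loop are
    tRF3s; everything else is an internal fragment (i-tRF).
    """
    if trna.anticodon_start is None or trna.anticodon_end is None:
        raise ValueError(f"{trna.ref_id}: anticodon metadata missing")
    length = len(trna.sequence)
    if not 1 <= match_start <= match_end <= length:
        raise ValueError(f"fragment [{match_start},{match_end}] outside [1,{length}]")
    loop_lo = trna.anticodon_start - loop_margin
    loop_hi = trna.anticodon_end + loop_margin
    five_anchored = match_start <= 1 + end_slack
    three_anchored = match_end >= length - end_slack
    if five_anchored and loop_lo <= match_end <= loop_hi:
        return "5p_tRH"
    if three_anchored and loop_lo <= match_start <= loop_hi:
        return "3p_tRH"
    if five_anchored and match_end < loop_lo:
        return "tRF5"
    if three_anchored and match_start > loop_hi:
        return "tRF3"
    return "i_tRF"


def classify_rsrna_fragment(hit_record: ReferenceRecord) -> str:
    """rRNA species label of the matched reference (28S/18S/5.8S/5S/16S/12S)."""
    if hit_record.sncrna_class != "rsRNA" or hit_record.species is None:
        raise ValueError(f"{hit_record.ref_id} is not an rRNA reference")
    return hit_record.species


def _best_hit(
    hits: list[tuple[ReferenceRecord, int, int]]
) -> tuple[ReferenceRecord, int, int]:
    # longest match span first (spans are equal for exact full-tag matches,
    # so this is effectively a lexicographic ref_id, then position, tie-break)
    return min(hits, key=lambda h: (-(h[2] - h[1] + 1), h[0].ref_id, h[1]))


def classify_tag(
    sequence: str,
    bundle: ReferenceBundle | dict[str, SubstringIndex],
    priority: Sequence[str] = DEFAULT_PRIORITY,
    end_slack: int = 0,
) -> AnnotationRecord:
    """Assign one tag to the first class in priority order with a hit."""
    indexes = bundle if isinstance(bundle, dict) else build_class_indexes(bundle)
    for cls in priority:
        hits = indexes[cls].find_all(sequence)
        if not hits:
            continue
        rec, start, end = _best_hit(hits)
        subtype = ""
        kwargs: dict[str, str] = {}
        if cls == "tsRNA":
            subtype = classify_tsrna_fragment(start, end, rec, end_slack=end_slack)
            kwargs["isoacceptor"] = rec.isoacceptor or ""
        elif cls == "rsRNA":
            subtype = classify_rsrna_fragment(rec)
        elif cls == "miRNA":
            subtype = rec.ref_id  # isomiR parent
        elif cls == "piRNA":
            kwargs["target_type"] = rec.target_type or ""
            kwargs["target_location"] = rec.target_location or ""
        return AnnotationRecord(sequence, cls, rec.ref_id, subtype, start, end, **kwargs)
    return AnnotationRecord(sequence, UNANNOTATED)


def build_class_indexes(bundle: ReferenceBundle) -> dict[str, SubstringIndex]:
    return {cls: SubstringIndex(bundle.records(cls)) for cls in ("miRNA", "piRNA", "tsRNA", "rsRNA")}


def annotate_tags(
    sequences: Iterable[str],
    bundle: ReferenceBundle,
    priority: Sequence[str] = DEFAULT_PRIORITY,
    end_slack: int = 0,
) -> pd.DataFrame:
    """Classify every unique sequence; returns a sequence-indexed frame.

    Columns: assigned_class, ref_id, subtype, match_start, match_end,
    isoacceptor, target_type, target_location.  Every input sequence
    receives exactly one class (possibly 'unannotated').
    """
    if sorted(priority) != sorted(DEFAULT_PRIORITY):
        raise ValueError(f"priority must be a permutation of {DEFAULT_PRIORITY}")
    indexes = build_class_indexes(bundle)
    rows = []
    for seq in sequences:
        ann = classify_tag(seq, indexes, priority=priority, end_slack=end_slack)
        rows.append((seq, ann.assigned_class, ann.ref_id, ann.subtype,
                     ann.match_start, ann.match_end, ann.isoacceptor,
                     ann.target_type, ann.target_location))
    df = pd.DataFrame(
        rows,
        columns=["sequence", "assigned_class", "ref_id", "subtype",
                 "match_start", "match_end", "isoacceptor",
                 "target_type", "target_location"],
    ).set_index("sequence")
    return df


def group_isomirs(
    sequences: Iterable[str],
    mirna_records: Sequence[ReferenceRecord],
    max_5p_offset: int = 2,
    max_3p_offset: int = 5,
) -> dict[str, set[str]]:
    """Group miRNA-class sequences under their canonical mature miRNA.

    A sequence is an isomiR of canonical M when it matches M's mature
    sequence exactly over its full length with a 5' start offset within
    +/-``max_5p_offset`` nt and a 3' end offset within
    +/-``max_3p_offset`` nt of the canonical ends.  Each sequence maps
    to exactly one canonical (lexicographic ref_id tie-break).
    """
    index = SubstringIndex(mirna_records)
    groups: dict[str, set[str]] = {}
    for seq in sequences:
        eligible = []
        for rec, start, end in index.find_all(seq):
            off5 = start - 1
            off3 = end - len(rec.sequence)
            if abs(off5) <= max_5p_offset and abs(off3) <= max_3p_offset:
                eligible.append((rec, start, end))
        if not eligible:
            continue
        rec, _, _ = _best_hit(eligible)
        groups.setdefault(rec.ref_id, set()).add(seq)
    return groups
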