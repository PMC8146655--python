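"""piRNA sequence-signature analytics.

piRNAs produced by the primary pathway carry a 5' uridine (U1) while
ping-pong amplification leaves an adenine at position 10 (A10); the
balance of U1 vs non-U1 (V1) and A10 vs non-A10 (B10) expression is
therefore a fingerprint of how a piRNA population was made.  This
module computes expression-weighted positional nucleotide frequencies,
U1/A10 share summaries, length distributions with mode detection, the
perfect-match mapping of piRNAs onto the circular mitochondrial genome
(both strands, wrap-around included) with feature assignment, and
piRBase-style target-category expression shares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .references import MtFeature, reverse_complement

_NT_COLUMNS = ("A", "C", "G", "U")


def _as_weights(weights, n: int) -> np.ndarray:
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("weights and sequences have different lengths")
    if (w < 0).any():
        raise ValueError("weights must be non-negative")
    return w


def positional_nt_frequency(
    sequences: Sequence[str], weights=None, max_pos: int = 35
) -> pd.DataFrame:
    """Weighted nucleotide frequency at positions 1..``max_pos``.

    ``freq[p, b]`` = total weight of sequences with base ``b`` at
    position ``p`` divided by the total weight of sequences of length
    >= ``p``; rows with support therefore sum to 1.  DNA T is reported
    as U.  Rows beyond every sequence's length are all-zero.
    """
    n = len(sequences)
    if n == 0:
        raise ValueError("no sequences")
    w = _as_weights(weights, n)
    if w.sum() == 0:
        raise ValueError("all weights are zero")
    counts = np.zeros((max_pos, 4))
    support = np.zeros(max_pos)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
    for seq, wt in zip(sequences, w):
        if wt == 0:
            continue
        top = min(len(seq), max_pos)
        support[:top] += wt
        for p in range(top):
            b = base_idx.get(seq[p])
            if b is not None:
                counts[p, b] += wt
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(support[:, None] > 0, counts / support[:, None], 0.0)
    return pd.DataFrame(freq, index=pd.RangeIndex(1, max_pos + 1, name="position"),
                        columns=list(_NT_COLUMNS))


@dataclass(frozen=True)
class SignatureSummary:
    """Expression-weighted U1/V1 and A10/B10 shares.

    ``a10_share``/``b10_share`` are computed over sequences of length
    >= 10 only; ``short10_mass`` flags the weight fraction that was too
    short to have a position 10 (the shares are ``None`` when nothing
    reaches position 10, never silently 0).
    """

    u1_share: float
    v1_share: float
    a10_share: float | None
    b10_share: float | None
    short10_mass: float

    def to_dict(self) -> dict:
        return {
            "u1_share": self.u1_share, "v1_share": self.v1_share,
            "a10_share": self.a10_share, "b10_share": self.b10_share,
            "short10_mass": self.short10_mass,
        }


def u1_a10_summary(sequences: Sequence[str], weights=None) -> SignatureSummary:
    """U1 (5' U) and A10 (position-10 A) expression shares."""
    n = len(sequences)
    if n == 0:
        raise ValueError("no sequences")
    w = _as_weights(weights, n)
    total = w.sum()
    if total == 0:
        raise ValueError("all weights are zero")
    u1 = sum(wt for seq, wt in zip(sequences, w) if seq[:1] in ("T", "U"))
    long_mask = np.array([len(s) >= 10 for s in sequences])
    long_total = w[long_mask].sum()
    if long_total > 0:
        a10 = sum(wt for seq, wt in zip(sequences, w) if len(seq) >= 10 and seq[9] == "A")
        a10_share, b10_share = a10 / long_total, 1.0 - a10 / long_total
    else:
        a10_share = b10_share = None
    return SignatureSummary(
        u1_share=u1 / total, v1_share=1.0 - u1 / total,
        a10_share=a10_share, b10_share=b10_share,
        short10_mass=1.0 - long_total / total,
    )


def length_distribution(
    sequences: Sequence[str],
    weights=None,
    by: Sequence | None = None,
    min_len: int = 17,
    max_len: int = 35,
    min_mode_separation: int = 3,
) -> dict:
    """Weighted length histograms per group with modal length(s).

    Returns ``{group: {"histogram": Series(length -> weight),
    "modes": [...], "multimodal": bool}}``; a group is multimodal when
    it has >= 2 local maxima separated by >= ``min_mode_separation`` nt.
    """
    n = len(sequences)
    w = _as_weights(weights, n)
    groups = ["all"] * n if by is None else list(by)
    if len(groups) != n:
        raise ValueError("grouping labels do not align with sequences")
    lengths = np.arange(min_len, max_len + 1)
    out: dict = {}
    for g in sorted(set(groups), key=str):
        hist = pd.Series(0.0, index=pd.Index(lengths, name="length"))
        for seq, wt, gg in zip(sequences, w, groups):
            if gg == g and min_len <= len(seq) <= max_len:
                hist[len(seq)] += wt
        modes = _local_maxima(hist)
        multimodal = any(
            abs(a - b) >= min_mode_separation for i, a in enumerate(modes) for b in modes[i + 1:]
        )
        out[g] = {"histogram": hist, "modes": modes, "multimodal": multimodal}
    return out


def _local_maxima(hist: pd.Series) -> list[int]:
    v = hist.to_numpy()
    idx = hist.index.to_numpy()
    modes = []
    for i in range(len(v)):
        if v[i] == 0:
            continue
        left = v[i - 1] if i > 0 else -np.inf
        right = v[i + 1] if i < len(v) - 1 else -np.inf
        if v[i] >= left and v[i] > right or (v[i] > left and v[i] >= right):
            modes.append(int(idx[i]))
    return modes


@dataclass(frozen=True)
class MtMatch:
    """One perfect full-length piRNA match on the circular mt genome.

    ``start`` is the 1-based + strand coordinate of the matched
    segment's first base (for either strand); ``feature`` is the label
    of the first feature containing that coordinate, or 'intergenic'.
    """

    sequence: str
    strand: str
    start: int
    feature: str


def _feature_at(pos: int, features: Sequence[MtFeature]) -> str:
    for feat in features:
        if feat.start <= pos <= feat.end:
            return feat.label
    return "intergenic"


def mtdna_perfect_matches(
    sequences: Iterable[str],
    mt_genome: str,
    features: Sequence[MtFeature] = (),
) -> list[MtMatch]:
    """All exact full-length occurrences on the circular mt genome.

    Both the + strand and the reverse complement are searched;
    circularity is handled by scanning genome + prefix(L-1) and
    reporting the canonical start in [1, genome length].  Palindromic
    sequences are reported once per strand.
    """
    if not mt_genome:
        raise ValueError("empty mitochondrial genome")
    n = len(mt_genome)
    seqs = list(sequences)
    maxq = max((len(s) for s in seqs), default=1)
    ext = mt_genome + mt_genome[:maxq - 1]
    matches: list[MtMatch] = []
    for seq in seqs:
        if not seq or len(seq) > n:
            continue
        for strand, query in (("+", seq), ("-", reverse_complement(seq))):
            t = ext.find(query)
            while 0 <= t < n:
                matches.append(
                    MtMatch(seq, strand, t + 1, _feature_at(t + 1, features))
                )
                t = ext.find(query, t + 1)
    return matches


def pirbase_category_summary(
    annotations: pd.DataFrame, weights: Sequence[float] | pd.Series
) -> dict[str, pd.Series]:
    """Expression share by piRBase target type and target location.

    ``annotations`` must carry ``target_type`` and ``target_location``
    columns (piRNA rows); ``weights`` aligns with its rows.  Each
    returned Series sums to 1.
    """
    w = pd.Series(np.asarray(weights, dtype=float), index=annotations.index)
    if w.sum() <= 0:
        raise ValueError("total weight must be positive")
    out = {}
    for axis in ("target_type", "target_location"):
        shares = w.groupby(annotations[axis]).sum()
        out[axis] = shares / shares.sum()
    return out
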