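"""Synthetic study generator with known ground truth.

Emulates a five-region small RNA-seq study of sperm maturation: for
each region of the male tract (PAR, CAP, COR, CAU, SPZ) a
:class:`RegionProfile` fixes the sncRNA class mixture, the piRNA 5'-U /
10-A biases and length mode, the tsRNA subtype mixture and the rRNA
species mixture.  :func:`simulate_study` draws UMI-tagged single-end
reads from a generated :class:`~sncatlas.references.ReferenceBundle`
according to those profiles, adds PCR duplicates (shared insert + UMI),
sequencing errors and base-call qualities, and writes FASTQ files next
to per-read truth tables, so every downstream stage can be scored
against planted values.

Every emitted insert is an exact fragment of its named reference
(sequencing errors excepted, and flagged in the truth table): piRNA
reads are 5'-anchored prefixes of a piRNA reference, so the planted
position-1/-10 composition is preserved exactly; tsRNA reads are cut
according to the same anchoring rules the annotator uses; rsRNA and
mitochondrial piRNA reads are substrings of their source sequence.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .references import (
    CLASSES,
    REGIONS,
    RRNA_SPECIES,
    TSRNA_SUBTYPES,
    PIRNA_TARGET_TYPES,
    PIRNA_TARGET_LOCATIONS,
    MtFeature,
    ReferenceBundle,
    ReferenceRecord,
    reverse_complement,
    write_bundle,
)

_BASES = np.frombuffer(b"ACGT", dtype="S1")

#: Default 3' adapter (QIAseq-like layout: insert + adapter + UMI).
DEFAULT_ADAPTER = "AACTGTAGGCACCATCAAT"
DEFAULT_UMI_LEN = 12
DEFAULT_READ_LEN = 75

# deterministic filler appended after the UMI to pad reads to read_len
_FILLER = "GTTCAGAGTTCTACAGTCCGACGATCGTTCAGAGTTCTACAGTCCGACGATC"


def _rand_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


# ---------------------------------------------------------------------------
# region profiles


@dataclass
class RegionProfile:
    """Planted sncRNA composition for one sampling region."""

    region: str
    class_mix: dict[str, float]
    pirna_u1_frac: float
    pirna_a10_frac: float
    pirna_len_mode: int
    tsrna_subtype_mix: dict[str, float]
    rrna_species_mix: dict[str, float]
    mt_pirna_frac: float = 0.05

    def validate(self) -> None:
        for name, mix, keys in (
            ("class_mix", self.class_mix, CLASSES),
            ("tsrna_subtype_mix", self.tsrna_subtype_mix, TSRNA_SUBTYPES),
            ("rrna_species_mix", self.rrna_species_mix, RRNA_SPECIES),
        ):
            if not set(mix) <= set(keys):
                raise ValueError(f"{self.region}: {name} has unknown keys {set(mix) - set(keys)}")
            if any(not 0.0 <= v <= 1.0 for v in mix.values()):
                raise ValueError(f"{self.region}: {name} fractions outside [0,1]")
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"{self.region}: {name} does not sum to 1")
        for name in ("pirna_u1_frac", "pirna_a10_frac", "mt_pirna_frac"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{self.region}: {name} outside [0,1]")
        if not 17 <= self.pirna_len_mode <= 35:
            raise ValueError(f"{self.region}: pirna_len_mode outside [17,35]")


def default_region_profiles() -> dict[str, RegionProfile]:
    """The five default region profiles.

    Class mixtures follow the published per-region trends for bovine
    sperm (piRNA-dominated testis parenchyma at 78%, falling to 13% at
    cauda; miRNA rising to 38% in ejaculated sperm; rRNA fragments
    peaking at corpus), piRNA 5'-U shares are high (~0.8) in PAR/CAP
    and inverted at COR/CAU, position-10 A is ~0.25 except ~0.6 at COR,
    and the piRNA length mode is 30 nt at PAR versus 22 nt elsewhere.
    """
    mixes = {
        "PAR": dict(miRNA=0.01, piRNA=0.78, tsRNA=0.02, rsRNA=0.17, other=0.02),
        "CAP": dict(miRNA=0.05, piRNA=0.57, tsRNA=0.08, rsRNA=0.28, other=0.02),
        "COR": dict(miRNA=0.13, piRNA=0.20, tsRNA=0.19, rsRNA=0.46, other=0.02),
        "CAU": dict(miRNA=0.27, piRNA=0.13, tsRNA=0.26, rsRNA=0.32, other=0.02),
        "SPZ": dict(miRNA=0.38, piRNA=0.18, tsRNA=0.16, rsRNA=0.26, other=0.02),
    }
    u1 = {"PAR": 0.80, "CAP": 0.80, "COR": 0.35, "CAU": 0.40, "SPZ": 0.55}
    a10 = {"PAR": 0.25, "CAP": 0.25, "COR": 0.60, "CAU": 0.25, "SPZ": 0.25}
    len_mode = {"PAR": 30, "CAP": 22, "COR": 22, "CAU": 22, "SPZ": 22}
    ts_mix = {
        "PAR": dict(tRF5=0.25, tRF3=0.10, **{"5p_tRH": 0.30, "3p_tRH": 0.16}, i_tRF=0.19),
        "CAP": dict(tRF5=0.20, tRF3=0.10, **{"5p_tRH": 0.35, "3p_tRH": 0.15}, i_tRF=0.20),
        "COR": dict(tRF5=0.18, tRF3=0.08, **{"5p_tRH": 0.30, "3p_tRH": 0.14}, i_tRF=0.30),
        "CAU": dict(tRF5=0.15, tRF3=0.05, **{"5p_tRH": 0.12, "3p_tRH": 0.06}, i_tRF=0.62),
        "SPZ": dict(tRF5=0.25, tRF3=0.07, **{"5p_tRH": 0.15, "3p_tRH": 0.08}, i_tRF=0.45),
    }
    rr_mix = {
        "PAR": {"28S": 0.60, "18S": 0.15, "5.8S": 0.05, "5S": 0.03, "16S": 0.12, "12S": 0.05},
        "CAP": {"28S": 0.51, "18S": 0.18, "5.8S": 0.06, "5S": 0.04, "16S": 0.15, "12S": 0.06},
        "COR": {"28S": 0.30, "18S": 0.12, "5.8S": 0.36, "5S": 0.04, "16S": 0.12, "12S": 0.06},
        "CAU": {"28S": 0.25, "18S": 0.12, "5.8S": 0.10, "5S": 0.05, "16S": 0.38, "12S": 0.10},
        "SPZ": {"28S": 0.20, "18S": 0.10, "5.8S": 0.08, "5S": 0.05, "16S": 0.45, "12S": 0.12},
    }
    mt_frac = {"PAR": 0.02, "CAP": 0.03, "COR": 0.10, "CAU": 0.15, "SPZ": 0.08}
    profiles = {
        region: RegionProfile(
            region=region,
            class_mix=mixes[region],
            pirna_u1_frac=u1[region],
            pirna_a10_frac=a10[region],
            pirna_len_mode=len_mode[region],
            tsrna_subtype_mix=ts_mix[region],
            rrna_species_mix=rr_mix[region],
            mt_pirna_frac=mt_frac[region],
        )
        for region in REGIONS
    }
    for p in profiles.values():
        p.validate()
    return profiles


# ---------------------------------------------------------------------------
# reference bundle generation


@dataclass
class BundleConfig:
    """Sizes and shapes of the generated reference sets."""

    n_mirna: int = 200
    n_pirna: int = 2000
    n_trna: int = 40
    mt_len: int = 16000
    #: fraction of piRNA references drawn as exact substrings of the mt genome
    mt_pirna_ref_frac: float = 0.20
    pirna_len_range: tuple[int, int] = (26, 33)
    mirna_len_range: tuple[int, int] = (20, 24)
    rrna_lengths: dict[str, int] = field(
        default_factory=lambda: {"28S": 1800, "18S": 1200, "5.8S": 160, "5S": 120}
    )
    #: planted piRBase-style category probabilities
    target_type_probs: dict[str, float] = field(
        default_factory=lambda: {"none": 0.70, "LINE": 0.12, "SINE": 0.08, "LTR": 0.06, "Satellite": 0.04}
    )
    genic_prob: float = 0.20


_ISOACCEPTORS = [
    "Gly-GCC", "Gly-CCC", "Met-CAT", "Gln-TTG", "Gln-CTG", "Ser-GCT", "Ser-AGA",
    "Ala-AGC", "His-GTG", "Thr-AGT", "Arg-TCT", "Ile-AAT", "Val-AAC", "Glu-TTC",
    "Glu-CTC", "Lys-CTT", "Leu-AAG", "Pro-AGG", "Phe-GAA", "Asp-GTC",
]

_MT_CDS = ["ND1", "ND2", "COX1", "COX2", "ATP8", "ATP6", "COX3", "ND3",
           "ND4L", "ND4", "ND5", "ND6", "CYTB"]
_MT_TRNAS = ["Phe", "Val", "Leu", "Ile", "Gln", "Met", "Trp", "Ala", "Asn",
             "Cys", "Tyr", "Ser", "Asp", "Lys", "Gly", "Arg", "His", "Glu", "Thr", "Pro"]


def _make_mt_genome(rng: np.random.Generator, length: int) -> tuple[str, list[MtFeature]]:
    """Random circular mt genome with a D-loop, 12S/16S rRNAs, tRNAs and CDS."""
    genome = _rand_dna(rng, length)
    features: list[MtFeature] = []
    features.append(MtFeature("D-loop", 1, 900, "+"))
    features.append(MtFeature("rRNA:12S", 961, 1910, "+"))
    features.append(MtFeature("rRNA:16S", 1981, 3500, "+"))
    pos = 3571
    cds_len = (length - pos - 1500) // len(_MT_CDS)
    trna_iter = iter(_MT_TRNAS)
    for i, name in enumerate(_MT_CDS):
        end = min(pos + cds_len - 80, length)
        strand = "-" if name == "ND6" else "+"
        features.append(MtFeature(f"CDS:{name}", pos, end, strand))
        pos = end + 1
        # interleave a tRNA in the gap after most CDS
        trna = next(trna_iter, None)
        if trna is not None and pos + 69 < length:
            features.append(MtFeature(f"tRNA-{trna}", pos + 5, pos + 74, "+"))
            pos += 80
    return genome, features


def _pirna_trait_key(seq: str) -> tuple[bool, bool]:
    return seq[0] == "T", len(seq) >= 10 and seq[9] == "A"


def _draw_mt_pirna(
    rng: np.random.Generator, genome: str, length: int, want_u1: bool, want_a10: bool,
    forbidden: list[tuple[int, int]],
) -> str:
    """An exact mt-genome substring (either strand) with the requested
    position-1/-10 bases, avoiding the forbidden (rRNA) intervals."""
    n = len(genome)
    rc = reverse_complement(genome)
    for _ in range(10000):
        strand_plus = bool(rng.integers(2))
        text = genome if strand_plus else rc
        start = int(rng.integers(0, n - length))
        # map back to + strand coordinates to test the forbidden intervals
        if strand_plus:
            lo, hi = start + 1, start + length
        else:
            lo, hi = n - (start + length) + 1, n - start
        if any(not (hi < a or lo > b) for a, b in forbidden):
            continue
        seq = text[start:start + length]
        if (seq[0] == "T") == want_u1 and (seq[9] == "A") == want_a10:
            return seq
    raise RuntimeError("could not place an mt-derived piRNA with the requested bases")


def generate_reference_bundle(config: BundleConfig | None = None, seed: int = 0) -> ReferenceBundle:
    """Deterministically generate a class-labelled reference bundle.

    piRNA references are planted in balanced (5'-U, 10-A) trait pools so
    region simulation can hit any requested U1/A10 fraction exactly; a
    configurable fraction are exact substrings of the mitochondrial
    genome (outside its rRNA genes, so class assignment stays
    unambiguous).  16S/12S rRNA references are the corresponding mt
    gene sequences.
    """
    config = config or BundleConfig()
    for name in ("n_mirna", "n_pirna", "n_trna", "mt_len"):
        if getattr(config, name) < 0:
            raise ValueError(f"{name} must be non-negative")
    if config.mt_len < 6000:
        raise ValueError("mt_len too small to carry the feature table")
    rng = np.random.default_rng(seed)
    bundle = ReferenceBundle()
    bundle.mt_genome, bundle.mt_features = _make_mt_genome(rng, config.mt_len)
    rrna_intervals = [
        (f.start, f.end) for f in bundle.mt_features if f.label.startswith("rRNA:")
    ]

    for i in range(config.n_mirna):
        length = int(rng.integers(config.mirna_len_range[0], config.mirna_len_range[1] + 1))
        bundle.mirna.append(
            ReferenceRecord(f"miR-{i + 1:04d}", "miRNA", _rand_dna(rng, length))
        )

    n_mt = int(round(config.n_pirna * config.mt_pirna_ref_frac))
    lo, hi = config.pirna_len_range
    ttypes = list(config.target_type_probs)
    tprobs = np.array([config.target_type_probs[t] for t in ttypes])
    tprobs = tprobs / tprobs.sum()
    for i in range(config.n_pirna):
        from_mt = i < n_mt
        length = int(rng.integers(lo, hi + 1))
        # cycle traits so each (U1, A10) pool is populated evenly
        want_u1, want_a10 = bool(i & 1), bool(i & 2)
        if from_mt:
            seq = _draw_mt_pirna(rng, bundle.mt_genome, length, want_u1, want_a10, rrna_intervals)
        else:
            s = list(_rand_dna(rng, length))
            s[0] = "T" if want_u1 else rng.choice(["A", "C", "G"])
            s[9] = "A" if want_a10 else rng.choice(["C", "G", "T"])
            seq = "".join(s)
        bundle.pirna.append(
            ReferenceRecord(
                f"piR-{i + 1:06d}", "piRNA", seq,
                target_type=str(rng.choice(ttypes, p=tprobs)),
                target_location="genic" if rng.random() < config.genic_prob else "intergenic",
                from_mt=from_mt,
            )
        )

    for i in range(config.n_trna):
        iso = _ISOACCEPTORS[i % len(_ISOACCEPTORS)]
        length = int(rng.integers(74, 79))
        ac_start = int(rng.integers(33, 36))
        s = list(_rand_dna(rng, length))
        anticodon = iso.split("-")[1]
        s[ac_start - 1:ac_start + 2] = list(anticodon)
        s[-3:] = list("CCA")  # mature tRNAs carry the 3' CCA
        bundle.trna.append(
            ReferenceRecord(
                f"tRNA-{iso}-{i + 1:02d}", "tsRNA", "".join(s),
                isoacceptor=iso, anticodon_start=ac_start, anticodon_end=ac_start + 2,
            )
        )

    for species, length in config.rrna_lengths.items():
        bundle.rrna.append(
            ReferenceRecord(f"rRNA-{species}", "rsRNA", _rand_dna(rng, length), species=species)
        )
    for species in ("16S", "12S"):
        feat = next(f for f in bundle.mt_features if f.label == f"rRNA:{species}")
        bundle.rrna.append(
            ReferenceRecord(
                f"rRNA-{species}", "rsRNA",
                bundle.mt_genome[feat.start - 1:feat.end], species=species,
            )
        )
    bundle.validate()
    return bundle


# ---------------------------------------------------------------------------
# read simulation


def _pirna_pools(bundle: ReferenceBundle) -> dict[tuple[bool, bool, bool], list[ReferenceRecord]]:
    pools: dict[tuple[bool, bool, bool], list[ReferenceRecord]] = {}
    for rec in bundle.pirna:
        u1, a10 = _pirna_trait_key(rec.sequence)
        pools.setdefault((rec.from_mt, u1, a10), []).append(rec)
    return pools


class _WeightedPool:
    """Deterministic weighted sampling over a fixed record list."""

    def __init__(self, records: list[ReferenceRecord], weights: np.ndarray):
        self.records = records
        cum = np.cumsum(weights)
        self._cum = cum / cum[-1]

    def draw(self, rng: np.random.Generator) -> ReferenceRecord:
        return self.records[int(np.searchsorted(self._cum, rng.random(), side="right"))]


def _reference_weights(
    records: list[ReferenceRecord], sigma: float, seed: int
) -> dict[str, float]:
    """Lognormal per-reference abundance, fixed for a whole study.

    Real small RNA libraries are dominated by a handful of species; a
    lognormal abundance profile (sigma ~1.5) reproduces that skew and
    guarantees some features are detected in every library, which the
    median-of-ratios normalizer requires.
    """
    rng = np.random.default_rng(seed)
    w = rng.lognormal(mean=0.0, sigma=sigma, size=len(records))
    return {rec.ref_id: float(x) for rec, x in zip(records, w)}


def _cut_tsrna(rng: np.random.Generator, rec: ReferenceRecord, subtype: str,
               max_len: int) -> tuple[int, int]:
    """1-based fragment coordinates on the mature tRNA obeying the
    anchoring rules the annotator applies (anticodon loop = anticodon
    +/- 2 nt)."""
    L = len(rec.sequence)
    loop_lo, loop_hi = rec.anticodon_start - 2, rec.anticodon_end + 2
    if subtype == "tRF5":
        end = int(rng.integers(17, loop_lo))          # end before the loop
        return 1, end
    if subtype == "5p_tRH":
        end = int(rng.integers(loop_lo, min(loop_hi, max_len) + 1))
        return 1, end
    if subtype == "tRF3":
        start = int(rng.integers(loop_hi + 1, L - 17 + 2))
        return start, L
    if subtype == "3p_tRH":
        lo = max(loop_lo, L - max_len + 1)
        start = int(rng.integers(lo, loop_hi + 1))
        return start, L
    if subtype == "i_tRF":
        start = int(rng.integers(2, L - 17))
        length = int(rng.integers(17, min(30, L - start) + 1))
        return start, start + length - 1
    raise ValueError(f"unknown tsRNA subtype {subtype!r}")


def simulate_region_sample(
    profile: RegionProfile,
    bundle: ReferenceBundle,
    n_reads: int,
    dup_rate: float = 0.25,
    error_rate: float = 0.001,
    seed: int = 0,
    sample_id: str = "S",
    region: str | None = None,
    replicate: int = 1,
    read_len: int = DEFAULT_READ_LEN,
    adapter: str = DEFAULT_ADAPTER,
    umi_len: int = DEFAULT_UMI_LEN,
    low_q_rate: float = 0.002,
    isomir_rate: float = 0.3,
    abundance_sigma: float = 1.5,
    abundance_seed: int = 9001,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate one UMI-tagged library for a region.

    Returns ``(records, truth)`` where ``records`` are FASTQ tuples
    ``(read_id, sequence, quality)`` and ``truth`` has one row per read
    with its planted class, source reference, subtype, UMI and
    PCR-duplication group.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if not (0.0 <= dup_rate < 1.0 and 0.0 <= error_rate < 1.0):
        raise ValueError("rates must lie in [0, 1)")
    profile.validate()
    for cls, frac in profile.class_mix.items():
        if frac > 0 and cls != "other" and not bundle.records(cls):
            raise ValueError(f"class_mix requests {cls} but the bundle has no {cls} references")
    region = region or profile.region
    rng = np.random.default_rng(seed)
    max_insert = read_len - len(adapter) - umi_len

    classes = [c for c in CLASSES if profile.class_mix.get(c, 0) > 0]
    class_p = np.array([profile.class_mix[c] for c in classes])
    class_p = class_p / class_p.sum()
    ts_subtypes = [s for s in TSRNA_SUBTYPES if profile.tsrna_subtype_mix.get(s, 0) > 0]
    ts_p = np.array([profile.tsrna_subtype_mix[s] for s in ts_subtypes])
    ts_p = ts_p / ts_p.sum() if len(ts_p) else ts_p
    rr_species = [s for s in RRNA_SPECIES if profile.rrna_species_mix.get(s, 0) > 0]
    rr_p = np.array([profile.rrna_species_mix[s] for s in rr_species])
    rr_p = rr_p / rr_p.sum() if len(rr_p) else rr_p

    # study-wide skewed reference abundances (same for every sample)
    weights: dict[str, float] = {}
    for offset, cls in enumerate(("miRNA", "piRNA", "tsRNA", "rsRNA")):
        recs = bundle.records(cls)
        if recs:
            weights.update(_reference_weights(recs, abundance_sigma, abundance_seed + offset))

    def _pool(recs: list[ReferenceRecord]) -> _WeightedPool | None:
        if not recs:
            return None
        return _WeightedPool(recs, np.array([weights[r.ref_id] for r in recs]))

    pirna_pools = {key: _pool(recs) for key, recs in _pirna_pools(bundle).items()}
    mirna_pool = _pool(bundle.mirna)
    trna_pool = _pool(bundle.trna)
    rrna_pools = {
        s: _pool([r for r in bundle.rrna if r.species == s]) for s in RRNA_SPECIES
    }
    ts_cum = np.cumsum(ts_p) / ts_p.sum() if len(ts_p) else None
    rr_cum = np.cumsum(rr_p) / rr_p.sum() if len(rr_p) else None

    # chunk-drawn randomness for the hot per-molecule choices
    cls_draw = rng.choice(len(classes), size=n_reads, p=class_p)

    molecules = []  # (insert, truth-dict)
    reads_emitted = 0
    copies_list: list[int] = []
    mol_i = 0
    while reads_emitted < n_reads:
        cls = classes[cls_draw[mol_i % n_reads]]
        mol_i += 1
        truth = dict(sncrna_class=cls, ref_id="", subtype="", isoacceptor="",
                     species="", target_type="", target_location="",
                     from_mt=False, has_error=False)
        if cls == "piRNA":
            from_mt = rng.random() < profile.mt_pirna_frac
            u1 = rng.random() < profile.pirna_u1_frac
            a10 = rng.random() < profile.pirna_a10_frac
            pool = pirna_pools.get((from_mt, u1, a10))
            if pool is None:  # fall back to nuclear pool with the same traits
                pool = pirna_pools[(False, u1, a10)]
                from_mt = False
            rec = pool.draw(rng)
            length = int(np.clip(round(rng.normal(profile.pirna_len_mode, 1.5)),
                                 17, min(len(rec.sequence), 35)))
            insert = rec.sequence[:length]  # 5'-anchored: keeps pos 1 and 10
            truth.update(ref_id=rec.ref_id, from_mt=from_mt,
                         target_type=rec.target_type, target_location=rec.target_location)
        elif cls == "miRNA":
            rec = mirna_pool.draw(rng)
            L = len(rec.sequence)
            t5 = t3 = 0
            if rng.random() < isomir_rate:
                for _ in range(20):
                    t5 = int(rng.integers(0, 3))
                    t3 = int(rng.integers(0, 4))
                    if (t5 or t3) and L - t5 - t3 >= 17:
                        break
                else:
                    t5 = t3 = 0
            insert = rec.sequence[t5:L - t3] if t3 else rec.sequence[t5:]
            truth.update(ref_id=rec.ref_id, subtype=rec.ref_id)
        elif cls == "tsRNA":
            rec = trna_pool.draw(rng)
            subtype = ts_subtypes[int(np.searchsorted(ts_cum, rng.random(), side="right"))]
            start, end = _cut_tsrna(rng, rec, subtype, max_insert)
            insert = rec.sequence[start - 1:end]
            truth.update(ref_id=rec.ref_id, subtype=subtype, isoacceptor=rec.isoacceptor)
        elif cls == "rsRNA":
            species = rr_species[int(np.searchsorted(rr_cum, rng.random(), side="right"))]
            rec = rrna_pools[species].draw(rng)
            L = len(rec.sequence)
            length = int(rng.integers(17, min(35, L) + 1))
            start = int(rng.integers(0, L - length + 1))
            insert = rec.sequence[start:start + length]
            truth.update(ref_id=rec.ref_id, subtype=species, species=species)
        else:  # 'other': random sequence, exercises the unannotated path
            insert = _rand_dna(rng, int(rng.integers(20, 31)))

        if error_rate > 0:
            k = rng.binomial(len(insert), error_rate)
            if k:
                s = list(insert)
                for pos in rng.choice(len(insert), size=k, replace=False):
                    s[pos] = str(rng.choice([b for b in "ACGT" if b != s[pos]]))
                insert = "".join(s)
                truth["has_error"] = True

        umi = _rand_dna(rng, umi_len)
        copies = 1
        while reads_emitted + copies < n_reads and rng.random() < dup_rate:
            copies += 1
        reads_emitted += copies
        truth.update(umi=umi, insert=insert, dup_group=len(molecules))
        molecules.append(truth)
        copies_list.append(copies)

    # assemble reads + vectorized qualities
    read_ids, seqs, truth_rows = [], [], []
    lengths = []
    i_read = 0
    for truth, copies in zip(molecules, copies_list):
        full = truth["insert"] + adapter + truth["umi"]
        if len(full) < read_len:
            full = full + _FILLER[:read_len - len(full)]
        for _ in range(copies):
            rid = f"{sample_id}:{i_read:07d}"
            read_ids.append(rid)
            seqs.append(full)
            lengths.append(len(full))
            row = dict(truth)
            row["read_id"] = rid
            truth_rows.append(row)
            i_read += 1

    n = len(seqs)
    maxlen = max(lengths)
    q = rng.integers(30, 41, size=(n, maxlen))
    mask = rng.random((n, maxlen)) < low_q_rate
    if mask.any():
        q[mask] = rng.integers(2, 25, size=int(mask.sum()))
    qbytes = (q + 33).astype(np.uint8)
    quals = [qbytes[i, :lengths[i]].tobytes().decode("latin-1") for i in range(n)]

    records = list(zip(read_ids, seqs, quals))
    truth_df = pd.DataFrame(truth_rows)
    truth_df.insert(0, "sample", sample_id)
    truth_df.insert(1, "region", region)
    truth_df.insert(2, "replicate", replicate)
    cols = ["sample", "region", "replicate", "read_id", "sncrna_class", "ref_id",
            "subtype", "isoacceptor", "species", "target_type", "target_location",
            "from_mt", "has_error", "umi", "dup_group", "insert"]
    return records, truth_df[cols]


# ---------------------------------------------------------------------------
# full study


@dataclass
class StudyConfig:
    """Design of a full multi-region study (defaults mirror the five-region,
    three-bull design at desk scale)."""

    profiles: dict[str, RegionProfile] = field(default_factory=default_region_profiles)
    replicates: int = 3
    n_reads: int = 50_000
    dup_rate: float = 0.25
    error_rate: float = 0.001
    read_len: int = DEFAULT_READ_LEN
    adapter: str = DEFAULT_ADAPTER
    umi_len: int = DEFAULT_UMI_LEN
    low_q_rate: float = 0.002
    isomir_rate: float = 0.3
    abundance_sigma: float = 1.5
    abundance_seed: int = 9001
    bundle: BundleConfig = field(default_factory=BundleConfig)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)


def simulate_study(config: StudyConfig | None = None, seed: int = 0,
                   outdir: str | Path = "study") -> pd.DataFrame:
    """Generate references plus one FASTQ + truth table per library.

    Writes, under ``outdir``: ``references/`` (bundle files),
    ``<region>_<rep>.fastq``, ``truth/<sample>.truth.tsv``,
    ``manifest.tsv`` and ``study_config.json``.  Returns the manifest.
    Fully deterministic for a fixed (config, seed).
    """
    from .preprocess import write_fastq

    config = config or StudyConfig()
    missing = [r for r in REGIONS if r not in config.profiles]
    if missing:
        raise ValueError(f"missing region profiles: {missing}")
    outdir = Path(outdir)
    (outdir / "truth").mkdir(parents=True, exist_ok=True)

    ss = np.random.SeedSequence(seed)
    bundle_seed, *sample_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in ss.spawn(1 + len(REGIONS) * config.replicates)
    ]
    bundle = generate_reference_bundle(config.bundle, seed=bundle_seed)
    write_bundle(bundle, outdir / "references")

    rows = []
    i = 0
    for region in REGIONS:
        for rep in range(1, config.replicates + 1):
            sample = f"{region}_{rep}"
            records, truth = simulate_region_sample(
                config.profiles[region], bundle, config.n_reads,
                dup_rate=config.dup_rate, error_rate=config.error_rate,
                seed=sample_seeds[i], sample_id=sample, region=region,
                replicate=rep, read_len=config.read_len, adapter=config.adapter,
                umi_len=config.umi_len, low_q_rate=config.low_q_rate,
                isomir_rate=config.isomir_rate,
                abundance_sigma=config.abundance_sigma,
                abundance_seed=config.abundance_seed,
            )
            i += 1
            fastq = outdir / f"{sample}.fastq"
            write_fastq(records, fastq)
            truth_path = outdir / "truth" / f"{sample}.truth.tsv"
            truth.to_csv(truth_path, sep="\t", index=False)
            rows.append(dict(sample=sample, region=region, replicate=rep,
                             fastq=fastq.name, truth=truth_path.name))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.tsv", sep="\t", index=False)
    (outdir / "study_config.json").write_text(config.to_json())
    return manifest


# ---------------------------------------------------------------------------
# planted clustering structure


def planted_profile_matrix(
    n_clusters: int = 12,
    rows_per_cluster: int = 100,
    n_cols: int = 5,
    noise_sd: float = 0.15,
    min_centroid_dist: float = 2.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Row-standardized matrix with well-separated planted profiles.

    Centroids are standardized (mean 0, sd 1) region profiles kept only
    if pairwise Euclidean distance >= ``min_centroid_dist``; with the
    default noise sd this gives a centroid separation of more than four
    noise standard deviations, so cluster recovery is unambiguous.
    Returns ``(matrix, labels)``.
    """
    rng = np.random.default_rng(seed)
    centroids: list[np.ndarray] = []
    while len(centroids) < n_clusters:
        c = rng.normal(size=n_cols)
        c = (c - c.mean()) / c.std()
        if all(np.linalg.norm(c - o) >= min_centroid_dist for o in centroids):
            centroids.append(c)
    labels = np.repeat(np.arange(n_clusters), rows_per_cluster)
    X = np.vstack([centroids[g] for g in labels])
    X = X + rng.normal(scale=noise_sd, size=X.shape)
    X = (X - X.mean(axis=1, keepdims=True)) / X.std(axis=1, keepdims=True)
    cols = list(REGIONS) if n_cols == 5 else [f"c{i}" for i in range(n_cols)]
    index = [f"feat_{i:05d}" for i in range(len(labels))]
    return pd.DataFrame(X, index=index, columns=cols), labels
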