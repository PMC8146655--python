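"""Reference sequence sets and their on-disk representation.

A :class:`ReferenceBundle` plays the role that public annotation
databases (miRBase, piRBase, GtRNAdb, Ensembl/RFAM rRNA, the
mitochondrial genome) play in a real small RNA-seq annotation run: a
class-labelled collection of mature reference sequences with the
subtype metadata each class needs — anticodon coordinates for tRNAs,
species labels for rRNAs, target-type/-location categories for piRNAs —
plus a circular mitochondrial genome with a feature table.

On disk a bundle is a set of plain-text files: one FASTA per class
(written through Biopython), a metadata TSV sidecar, and a feature TSV
for the mitochondrial genome.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: sncRNA classes, in the order used throughout the package.
CLASSES = ("miRNA", "piRNA", "tsRNA", "rsRNA", "other")

#: The five sampling regions along the male reproductive tract, in
#: anatomical order: testis parenchyma, epididymis caput / corpus /
#: cauda, ejaculated sperm.
REGIONS = ("PAR", "CAP", "COR", "CAU", "SPZ")

#: tRNA-derived fragment subtypes.
TSRNA_SUBTYPES = ("tRF5", "tRF3", "5p_tRH", "3p_tRH", "i_tRF")

#: rRNA species (28S/18S/5.8S/5S nuclear, 16S/12S mitochondrial).
RRNA_SPECIES = ("28S", "18S", "5.8S", "5S", "16S", "12S")

PIRNA_TARGET_TYPES = ("LINE", "SINE", "LTR", "Satellite", "none")
PIRNA_TARGET_LOCATIONS = ("genic", "intergenic")

_DNA = set("ACGT")


@dataclass(frozen=True)
class ReferenceRecord:
    """One mature reference sequence with class-specific metadata.

    ``anticodon_start``/``anticodon_end`` are 1-based inclusive
    coordinates on the mature tRNA sequence (CCA included at the 3'
    end).  ``from_mt`` marks piRNA references that are exact substrings
    of the bundled mitochondrial genome.
    """

    ref_id: str
    sncrna_class: str
    sequence: str
    isoacceptor: str | None = None
    anticodon_start: int | None = None
    anticodon_end: int | None = None
    species: str | None = None
    target_type: str | None = None
    target_location: str | None = None
    from_mt: bool = False

    def __post_init__(self) -> None:
        if self.sncrna_class not in CLASSES:
            raise ValueError(f"unknown sncRNA class {self.sncrna_class!r}")
        if not set(self.sequence) <= _DNA:
            raise ValueError(f"{self.ref_id}: non-ACGT base in reference sequence")
        if self.sncrna_class == "tsRNA":
            s, e = self.anticodon_start, self.anticodon_end
            if s is None or e is None:
                raise ValueError(f"{self.ref_id}: tRNA record lacks anticodon coordinates")
            if not (1 <= s <= e <= len(self.sequence)) or e - s + 1 != 3:
                raise ValueError(f"{self.ref_id}: anticodon interval [{s},{e}] invalid")
        if self.sncrna_class == "rsRNA" and self.species not in RRNA_SPECIES:
            raise ValueError(f"{self.ref_id}: rRNA species {self.species!r} unknown")


@dataclass(frozen=True)
class MtFeature:
    """One annotated feature on the circular mitochondrial genome.

    Coordinates are 1-based inclusive on the + strand; features do not
    wrap across the origin.
    """

    label: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"feature {self.label}: bad interval [{self.start},{self.end}]")
        if self.strand not in ("+", "-"):
            raise ValueError(f"feature {self.label}: strand must be + or -")


@dataclass
class ReferenceBundle:
    """Class-labelled reference sets plus the mitochondrial genome."""

    mirna: list[ReferenceRecord] = field(default_factory=list)
    pirna: list[ReferenceRecord] = field(default_factory=list)
    trna: list[ReferenceRecord] = field(default_factory=list)
    rrna: list[ReferenceRecord] = field(default_factory=list)
    mt_genome: str = ""
    mt_features: list[MtFeature] = field(default_factory=list)

    _CLASS_ATTR = {"miRNA": "mirna", "piRNA": "pirna", "tsRNA": "trna", "rsRNA": "rrna"}

    def records(self, sncrna_class: str) -> list[ReferenceRecord]:
        """All records of one class ('other' has no reference set)."""
        if sncrna_class == "other":
            return []
        return getattr(self, self._CLASS_ATTR[sncrna_class])

    def by_id(self) -> dict[str, ReferenceRecord]:
        out: dict[str, ReferenceRecord] = {}
        for cls in self._CLASS_ATTR:
            for rec in self.records(cls):
                if rec.ref_id in out:
                    raise ValueError(f"duplicate reference id {rec.ref_id}")
                out[rec.ref_id] = rec
        return out

    def validate(self) -> None:
        self.by_id()  # raises on duplicates
        for feat in self.mt_features:
            if feat.end > len(self.mt_genome):
                raise ValueError(f"mt feature {feat.label} extends past genome end")


# ---------------------------------------------------------------------------
# on-disk representation

_META_COLUMNS = [
    "ref_id", "sncrna_class", "isoacceptor", "anticodon_start", "anticodon_end",
    "species", "target_type", "target_location", "from_mt",
]


def write_bundle(bundle: ReferenceBundle, outdir: str | os.PathLike) -> None:
    """Write a bundle as per-class FASTA + metadata TSV + mt feature TSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    for cls, attr in ReferenceBundle._CLASS_ATTR.items():
        recs = bundle.records(cls)
        seqrecs = [SeqRecord(Seq(r.sequence), id=r.ref_id, description="") for r in recs]
        SeqIO.write(seqrecs, outdir / f"{attr}.fasta", "fasta")
        for r in recs:
            row = asdict(r)
            del row["sequence"]
            row["sncrna_class"] = cls
            meta_rows.append(row)
    meta = pd.DataFrame(meta_rows, columns=_META_COLUMNS)
    meta.to_csv(outdir / "reference_metadata.tsv", sep="\t", index=False)
    SeqIO.write(
        [SeqRecord(Seq(bundle.mt_genome), id="mt_genome", description="circular")],
        outdir / "mt_genome.fasta", "fasta",
    )
    feats = pd.DataFrame(
        [(f.label, f.start, f.end, f.strand) for f in bundle.mt_features],
        columns=["label", "start", "end", "strand"],
    )
    feats.to_csv(outdir / "mt_features.tsv", sep="\t", index=False)


def read_bundle(indir: str | os.PathLike) -> ReferenceBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "reference_metadata.tsv", sep="\t")
    seqs: dict[str, str] = {}
    for attr in ("mirna", "pirna", "trna", "rrna"):
        path = indir / f"{attr}.fasta"
        if path.exists():
            for rec in SeqIO.parse(str(path), "fasta"):
                seqs[rec.id] = str(rec.seq)
    bundle = ReferenceBundle()
    for row in meta.itertuples(index=False):
        kwargs = dict(
            ref_id=row.ref_id,
            sncrna_class=row.sncrna_class,
            sequence=seqs[row.ref_id],
            from_mt=bool(row.from_mt),
        )
        for key in ("isoacceptor", "species", "target_type", "target_location"):
            val = getattr(row, key)
            kwargs[key] = None if pd.isna(val) else val
        for key in ("anticodon_start", "anticodon_end"):
            val = getattr(row, key)
            kwargs[key] = None if pd.isna(val) else int(val)
        rec = ReferenceRecord(**kwargs)
        bundle.records(rec.sncrna_class).append(rec)
    mt = list(SeqIO.parse(str(indir / "mt_genome.fasta"), "fasta"))
    bundle.mt_genome = str(mt[0].seq) if mt else ""
    feats = pd.read_csv(indir / "mt_features.tsv", sep="\t")
    bundle.mt_features = [
        MtFeature(r.label, int(r.start), int(r.end), r.strand)
        for r in feats.itertuples(index=False)
    ]
    bundle.validate()
    return bundle


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
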