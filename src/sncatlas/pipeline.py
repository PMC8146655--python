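"""End-to-end orchestration: simulate -> preprocess -> annotate ->
quantify -> signatures -> cluster -> report.

Each stage reads its inputs from, and writes its artifacts to, a single
output directory, so any stage can be re-run from cached inputs and
reproduce its outputs bit-identically.  All randomness flows from one
master seed; the machine-readable report carries per-stage record
counts, the per-region composition and signature tables, the DE summary,
the chosen k and cluster composition, and a SHA-256 checksum for every
artifact.  Identical (config, seed) yield byte-identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import DEFAULT_PRIORITY, annotate_tags
from .pirna import positional_nt_frequency, u1_a10_summary
from .preprocess import preprocess_sample, stack_tags
from .profiles import (
    average_and_standardize,
    bca_per_family,
    cluster_composition,
    select_k_elbow,
)
from .quantify import build_count_matrix, de_union, pairwise_de_summary
from .references import REGIONS, read_bundle
from .simulate import StudyConfig, simulate_study

log = logging.getLogger("sncatlas")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """All knobs of an end-to-end run.

    With ``simulate=True`` (default) the study is generated under
    ``output_dir/study``; otherwise ``study_dir`` must point at an
    existing directory with ``manifest.tsv``, FASTQ files and a
    ``references/`` bundle.
    """

    output_dir: str = "sncatlas_run"
    seed: int = 0
    simulate: bool = True
    study_dir: str | None = None
    study: StudyConfig = field(default_factory=StudyConfig)
    min_len: int = 17
    min_phred: int = 25
    alpha: float = 0.05
    fold_threshold: float = 2.5
    k_min: int = 2
    k_max: int = 25
    info_threshold: float = 0.90
    gain_threshold: float = 0.01
    n_starts: int = 100
    max_iter: int = 1000
    priority: tuple[str, ...] = DEFAULT_PRIORITY
    cluster_features: str = "de_union"  # or "all"

    def validate(self) -> None:
        if self.min_len < 1 or self.min_phred < 1:
            raise ValueError("filters must be positive")
        if not 0 < self.alpha < 1 or self.fold_threshold <= 1:
            raise ValueError("alpha must be in (0,1) and fold_threshold > 1")
        if not 2 <= self.k_min <= self.k_max:
            raise ValueError("need 2 <= k_min <= k_max")
        if self.cluster_features not in ("de_union", "all"):
            raise ValueError("cluster_features must be 'de_union' or 'all'")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix in (".yaml", ".yml"):
            import yaml
            raw = yaml.safe_load(text)
        else:
            raw = json.loads(text)
        study_raw = raw.pop("study", None)
        cfg = cls(**raw)
        if study_raw is not None:
            bundle_raw = study_raw.pop("bundle", None)
            profiles_raw = study_raw.pop("profiles", None)
            cfg.study = StudyConfig(**study_raw)
            if bundle_raw is not None:
                from .simulate import BundleConfig
                cfg.study.bundle = BundleConfig(**bundle_raw)
            if profiles_raw is not None:
                from .simulate import RegionProfile
                cfg.study.profiles = {
                    r: RegionProfile(**p) for r, p in profiles_raw.items()
                }
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _round(obj, ndigits: int = 10):
    """Recursively round floats so report JSON is stable and readable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round(v, ndigits) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return round(float(obj), ndigits)
    return obj


def _study_dir(config: PipelineConfig) -> Path:
    if config.simulate:
        return Path(config.output_dir) / "study"
    if not config.study_dir:
        raise PipelineError("stage simulate: no study_dir given and simulate=False")
    return Path(config.study_dir)


def stage_simulate(config: PipelineConfig) -> pd.DataFrame:
    sdir = _study_dir(config)
    if config.simulate:
        manifest = simulate_study(config.study, seed=config.seed, outdir=sdir)
    else:
        manifest = pd.read_csv(sdir / "manifest.tsv", sep="\t")
    return manifest


def stage_preprocess(config: PipelineConfig) -> dict:
    out = Path(config.output_dir)
    sdir = _study_dir(config)
    manifest = pd.read_csv(sdir / "manifest.tsv", sep="\t")
    reads_by_sample = {}
    counter_rows = []
    reject_rows = []
    for row in manifest.itertuples(index=False):
        kept, rejects, counters = preprocess_sample(
            sdir / row.fastq, config.study.adapter, config.study.umi_len,
            min_len=config.min_len, min_phred=config.min_phred,
        )
        reads_by_sample[row.sample] = kept
        counter_rows.append({"sample": row.sample, **counters})
        reject_rows.extend((row.sample, rid, reason) for rid, reason in rejects)
    counters = pd.DataFrame(counter_rows)
    counters.to_csv(out / "preprocess_counters.tsv", sep="\t", index=False)
    pd.DataFrame(reject_rows, columns=["sample", "read_id", "reason"]).to_csv(
        out / "rejected_reads.tsv", sep="\t", index=False
    )
    if counters["kept"].sum() == 0:
        raise PipelineError(
            "stage preprocess: zero reads survived extraction/filtering "
            f"(min_len={config.min_len}, min_phred={config.min_phred})"
        )
    tag_table = stack_tags(reads_by_sample, manifest)
    tag_table.to_csv(out / "tag_table.tsv", sep="\t")
    return {"samples": len(manifest), "counters": counter_rows,
            "unique_sequences": int(len(tag_table))}


def stage_annotate(config: PipelineConfig) -> dict:
    out = Path(config.output_dir)
    tag_table = pd.read_csv(out / "tag_table.tsv", sep="\t", index_col="sequence")
    bundle = read_bundle(_study_dir(config) / "references")
    ann = annotate_tags(tag_table.index, bundle, priority=config.priority)
    ann.to_csv(out / "annotations.tsv", sep="\t")
    class_counts = ann["assigned_class"].value_counts().sort_index().to_dict()
    (out / "class_summary.json").write_text(
        json.dumps(class_counts, indent=2, sort_keys=True) + "\n"
    )
    return {"class_counts": class_counts}


def _load_count_matrix(config: PipelineConfig):
    out = Path(config.output_dir)
    tag_table = pd.read_csv(out / "tag_table.tsv", sep="\t", index_col="sequence")
    ann = pd.read_csv(out / "annotations.tsv", sep="\t", index_col="sequence",
                      keep_default_na=False)
    manifest = pd.read_csv(_study_dir(config) / "manifest.tsv", sep="\t")
    return build_count_matrix(tag_table, ann, manifest).normalize()


def stage_quantify(config: PipelineConfig) -> dict:
    out = Path(config.output_dir)
    cm = _load_count_matrix(config)
    cm.size_factors.to_csv(out / "size_factors.tsv", sep="\t")
    from .quantify import class_proportions

    summary: dict = {"size_factors": cm.size_factors.round(6).to_dict()}
    for level in ("class", "tsrna_subtype", "isoacceptor", "rrna_species"):
        within, across = class_proportions(cm, level=level)
        within.to_csv(out / f"proportions_{level}_within_region.tsv", sep="\t")
        across.to_csv(out / f"proportions_{level}_across_regions.tsv", sep="\t")
        if level == "class":
            summary["class_proportions_within_region"] = {
                c: within[c].round(4).to_dict() for c in within.columns
            }
    de_table, results = pairwise_de_summary(
        cm, alpha=config.alpha, fold_threshold=config.fold_threshold
    )
    de_table.to_csv(out / "de_summary.tsv", sep="\t")
    union = de_union(results)
    pd.Series(sorted(union), name="sequence").to_csv(
        out / "de_union.tsv", sep="\t", index=False
    )
    for (a, b), res in results.items():
        res.round(8).to_csv(out / f"de_{a}_vs_{b}.tsv", sep="\t")
    summary["de_summary"] = {
        f"{a}_vs_{b}": int(res["significant"].sum()) for (a, b), res in results.items()
    }
    summary["de_union_size"] = int(len(union))
    return summary


def stage_signatures(config: PipelineConfig) -> dict:
    out = Path(config.output_dir)
    cm = _load_count_matrix(config)
    bundle = read_bundle(_study_dir(config) / "references")
    means = cm.region_means()
    pirna_mask = (cm.features["assigned_class"] == "piRNA").to_numpy()
    seqs = list(means.index[pirna_mask])
    summary: dict = {"u1_a10_per_region": {}}
    rows = []
    for region in means.columns:
        w = means.loc[pirna_mask, region].to_numpy()
        if not seqs or w.sum() == 0:
            continue
        sig = u1_a10_summary(seqs, w).to_dict()
        summary["u1_a10_per_region"][region] = sig
        rows.append({"region": region, **{k: v for k, v in sig.items()}})
        freq = positional_nt_frequency(seqs, w)
        freq.round(8).to_csv(out / f"positional_freq_{region}.tsv", sep="\t")
    pd.DataFrame(rows).to_csv(out / "u1_a10_regions.tsv", sep="\t", index=False)

    from .pirna import mtdna_perfect_matches, pirbase_category_summary

    matches = mtdna_perfect_matches(seqs, bundle.mt_genome, bundle.mt_features)
    pd.DataFrame(
        [(m.sequence, m.strand, m.start, m.feature) for m in matches],
        columns=["sequence", "strand", "start", "feature"],
    ).to_csv(out / "mt_matches.tsv", sep="\t", index=False)
    summary["mt_matched_pirnas"] = int(len({m.sequence for m in matches}))
    if pirna_mask.any():
        cats = pirbase_category_summary(
            cm.features[pirna_mask], cm.normalized.sum(axis=1)[pirna_mask]
        )
        for axis, series in cats.items():
            series.round(6).rename("share").to_csv(out / f"pirna_{axis}_shares.tsv", sep="\t")
        summary["pirna_target_location_shares"] = cats["target_location"].round(4).to_dict()
    return summary


def stage_cluster(config: PipelineConfig) -> dict:
    out = Path(config.output_dir)
    cm = _load_count_matrix(config)
    bundle = read_bundle(_study_dir(config) / "references")
    if config.cluster_features == "de_union":
        union = pd.read_csv(out / "de_union.tsv", sep="\t")["sequence"]
        subset = pd.Index(union)
    else:
        subset = None
    X, dropped = average_and_standardize(cm, subset)
    if len(X) < config.k_max:
        raise PipelineError(
            f"stage cluster: only {len(X)} profile rows for k_max={config.k_max}"
        )
    X.round(8).to_csv(out / "profile_matrix.tsv", sep="\t")
    ratios, chosen, models = select_k_elbow(
        X, range(config.k_min, config.k_max + 1),
        info_threshold=config.info_threshold, gain_threshold=config.gain_threshold,
        n_starts=config.n_starts, max_iter=config.max_iter, seed=config.seed,
    )
    ratios.round(8).to_csv(out / "elbow_ratio_trace.tsv", sep="\t")
    k = chosen if chosen is not None else max(ratios.index)
    model = models[k]
    model.assignments.to_csv(out / "cluster_assignments.tsv", sep="\t")
    model.centroids.round(8).to_csv(out / "cluster_centroids.tsv", sep="\t")
    comp = cluster_composition(model, cm, bundle.mt_genome, bundle.mt_features)
    comp_json = {
        str(g): _round({
            "n_features": e["n_features"],
            "peak_region": e["peak_region"],
            "class_shares": e["class_shares"].to_dict(),
            "u1_a10": e.get("u1_a10"),
            "mt_pirna_share": e.get("mt_pirna_share"),
            "length_modes": e["length_modes"],
        })
        for g, e in comp.items()
    }
    (out / "cluster_composition.json").write_text(
        json.dumps(comp_json, indent=2, sort_keys=True) + "\n"
    )
    bca = bca_per_family(cm)
    bca.round(8).to_csv(out / "bca_ratios.tsv", sep="\t")
    return {
        "chosen_k": None if chosen is None else int(chosen),
        "clustered_features": int(len(X)),
        "dropped_constant_rows": len(dropped),
        "ratio_at_chosen_k": _round(float(ratios[k])),
        "cluster_composition": comp_json,
        "bca_ratios": _round(bca.to_dict()),
    }


_STAGES = (
    ("simulate", stage_simulate),
    ("preprocess", stage_preprocess),
    ("annotate", stage_annotate),
    ("quantify", stage_quantify),
    ("signatures", stage_signatures),
    ("cluster", stage_cluster),
)


def run_end_to_end(config: PipelineConfig) -> dict:
    """Run every stage and write ``report.json``; returns the report."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": config.seed, "stages": {}}
    for name, fn in _STAGES:
        t0 = time.perf_counter()
        try:
            result = fn(config)
        except PipelineError:
            raise
        except Exception as exc:  # abort with the stage name, keep partial output
            raise PipelineError(f"stage {name}: {exc}") from exc
        log.info("stage %s finished in %.1fs", name, time.perf_counter() - t0)
        if name == "simulate":
            report["stages"][name] = {"samples": int(len(result)),
                                      "regions": sorted(set(result["region"]))}
        else:
            report["stages"][name] = _round(result)
    artifacts = sorted(
        p for p in out.rglob("*")
        if p.is_file() and p.name != "report.json"
    )
    report["artifacts"] = {
        str(p.relative_to(out)): _sha256(p) for p in artifacts
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n"
    )
    return report
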