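"""Generator: determinism, planted-truth fidelity, study layout."""

import numpy as np
import pandas as pd
import pytest

from sncatlas.references import CLASSES, REGIONS
from sncatlas.simulate import (
    BundleConfig,
    RegionProfile,
    StudyConfig,
    default_region_profiles,
    generate_reference_bundle,
    simulate_region_sample,
    simulate_study,
)


def _pirna_only_profile(**overrides):
    base = dict(
        region="PAR",
        class_mix={"piRNA": 1.0},
        pirna_u1_frac=0.8,
        pirna_a10_frac=0.25,
        pirna_len_mode=28,
        tsrna_subtype_mix={"tRF5": 1.0},
        rrna_species_mix={"28S": 1.0},
        mt_pirna_frac=0.0,
    )
    base.update(overrides)
    return RegionProfile(**base)


class TestBundle:
    def test_deterministic_for_fixed_seed(self):
        cfg = BundleConfig(n_mirna=10, n_pirna=40, n_trna=4)
        a = generate_reference_bundle(cfg, seed=5)
        b = generate_reference_bundle(cfg, seed=5)
        assert a.mt_genome == b.mt_genome
        for cls in ("miRNA", "piRNA", "tsRNA", "rsRNA"):
            assert a.records(cls) == b.records(cls)

    def test_zero_trnas_leaves_other_sets_populated(self):
        cfg = BundleConfig(n_mirna=10, n_pirna=40, n_trna=0)
        b = generate_reference_bundle(cfg, seed=1)
        assert b.trna == [] and len(b.mirna) == 10 and len(b.pirna) == 40

    def test_requested_pirna_count_and_unique_ids(self, bundle):
        ids = [r.ref_id for r in bundle.pirna]
        assert len(ids) == 240 and len(set(ids)) == 240

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            generate_reference_bundle(BundleConfig(n_mirna=-1), seed=0)

    def test_trna_metadata_well_formed(self, bundle):
        for rec in bundle.trna:
            assert rec.anticodon_end - rec.anticodon_start == 2
            assert 1 <= rec.anticodon_start <= len(rec.sequence)
            assert rec.sequence.endswith("CCA")

    def test_mt_features_inside_genome(self, bundle):
        for feat in bundle.mt_features:
            assert 1 <= feat.start <= feat.end <= len(bundle.mt_genome)


class TestRegionSample:
    def test_pure_pirna_mix_yields_only_pirna_truth(self, bundle):
        _, truth = simulate_region_sample(_pirna_only_profile(), bundle, 1000, seed=2)
        assert (truth["sncrna_class"] == "piRNA").all()

    def test_dup_rate_zero_gives_singleton_groups(self, bundle):
        _, truth = simulate_region_sample(
            _pirna_only_profile(), bundle, 500, dup_rate=0.0, seed=2
        )
        assert truth["dup_group"].value_counts().max() == 1

    def test_planted_u1_fraction_recovered(self, bundle):
        # binomial check against the generator's own truth table
        _, truth = simulate_region_sample(
            _pirna_only_profile(pirna_u1_frac=0.80), bundle, 10_000, seed=3
        )
        u1 = truth["insert"].str.startswith("T").mean()
        assert abs(u1 - 0.80) < 0.02

    def test_unknown_class_in_mix_rejected(self):
        cfg = BundleConfig(n_mirna=5, n_pirna=20, n_trna=0)
        b = generate_reference_bundle(cfg, seed=1)
        profile = _pirna_only_profile(class_mix={"tsRNA": 1.0})
        with pytest.raises(ValueError, match="tsRNA"):
            simulate_region_sample(profile, b, 100, seed=1)

    def test_inserts_are_exact_reference_fragments(self, bundle, profiles):
        _, truth = simulate_region_sample(
            profiles["COR"], bundle, 3000, error_rate=0.0, seed=4
        )
        by_id = bundle.by_id()
        annotated = truth[truth["sncrna_class"] != "other"]
        for insert, ref_id in zip(annotated["insert"], annotated["ref_id"]):
            assert insert in by_id[ref_id].sequence

    def test_truth_class_fractions_converge_to_mix(self, bundle, profiles):
        profile = profiles["CAU"]
        _, truth = simulate_region_sample(profile, bundle, 30_000, seed=5)
        observed = truth["sncrna_class"].value_counts(normalize=True)
        for cls in CLASSES:
            assert abs(observed.get(cls, 0.0) - profile.class_mix[cls]) < 0.03

    def test_reads_padded_to_read_length(self, bundle):
        records, _ = simulate_region_sample(_pirna_only_profile(), bundle, 200, seed=6)
        assert all(len(seq) == 75 and len(qual) == 75 for _, seq, qual in records)


class TestStudy:
    def test_default_layout_and_determinism(self, tmp_path):
        cfg = StudyConfig(n_reads=300, replicates=3,
                          bundle=BundleConfig(n_mirna=10, n_pirna=40, n_trna=4))
        m1 = simulate_study(cfg, seed=9, outdir=tmp_path / "a")
        assert len(m1) == 15
        assert sorted(set(m1["region"])) == sorted(REGIONS)
        assert all((tmp_path / "a" / f).exists() for f in m1["fastq"])
        simulate_study(cfg, seed=9, outdir=tmp_path / "b")
        assert (tmp_path / "a" / "manifest.tsv").read_bytes() == \
               (tmp_path / "b" / "manifest.tsv").read_bytes()
        for sample in m1["sample"]:
            assert (tmp_path / "a" / "truth" / f"{sample}.truth.tsv").read_bytes() == \
                   (tmp_path / "b" / "truth" / f"{sample}.truth.tsv").read_bytes()
            assert (tmp_path / "a" / f"{sample}.fastq").read_bytes() == \
                   (tmp_path / "b" / f"{sample}.fastq").read_bytes()

    def test_single_replicate_gives_five_libraries(self, tmp_path):
        cfg = StudyConfig(n_reads=100, replicates=1,
                          bundle=BundleConfig(n_mirna=10, n_pirna=40, n_trna=4))
        manifest = simulate_study(cfg, seed=1, outdir=tmp_path)
        assert len(manifest) == 5

    def test_missing_region_profile_rejected(self, tmp_path):
        cfg = StudyConfig(n_reads=100)
        del cfg.profiles["COR"]
        with pytest.raises(ValueError, match="COR"):
            simulate_study(cfg, seed=1, outdir=tmp_path)


def test_profile_validation_rejects_bad_mixes():
    with pytest.raises(ValueError, match="sum"):
        _pirna_only_profile(class_mix={"piRNA": 0.5}).validate()
    with pytest.raises(ValueError, match="len_mode"):
        _pirna_only_profile(pirna_len_mode=40).validate()
    for profile in default_region_profiles().values():
        profile.validate()
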