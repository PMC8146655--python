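"""Shared run configuration for the numbered analysis scripts.

The analysis chain works on one study directory (``results/study``) and
one run directory (``results/run``); every script accepts ``--seed``
and ``--results`` and builds the same PipelineConfig, so the scripts
can be run in order (01..06) and each picks up the previous outputs.
"""

import argparse
from pathlib import Path

from sncatlas.pipeline import PipelineConfig
from sncatlas.simulate import StudyConfig


def parse_args(description: str) -> argparse.Namespace:
    parser = argparse.ArgumentParser(description=description)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--results", type=Path, default=Path("results"))
    return parser.parse_args()


def make_config(args: argparse.Namespace) -> PipelineConfig:
    # 15 libraries x 20k reads: large enough for stable composition and a
    # few hundred DE features, small enough to run the whole chain in
    # minutes on one core
    cfg = PipelineConfig(
        output_dir=str(args.results / "run"),
        seed=args.seed,
        simulate=False,
        study_dir=str(args.results / "study"),
        study=StudyConfig(n_reads=20_000),
        k_max=12,
        n_starts=100,
        max_iter=1000,
    )
    Path(cfg.output_dir).mkdir(parents=True, exist_ok=True)
    return cfg
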