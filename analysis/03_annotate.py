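"""Classify every unique sequence into sncRNA classes and subtypes.

Each tag is matched exactly against the reference sets in priority
order (miRNA > tsRNA > rsRNA > piRNA); tsRNA hits are typed into
tRF5/tRF3/5'-tRH/3'-tRH/i-tRF by their anchoring on the mature tRNA,
rRNA hits inherit their source species, and piRNA hits carry
piRBase-style target categories.  Writes results/run/annotations.tsv.
"""

from _config import make_config, parse_args
from sncatlas.pipeline import stage_annotate


def main() -> None:
    args = parse_args(__doc__)
    cfg = make_config(args)
    summary = stage_annotate(cfg)
    total = sum(summary["class_counts"].values())
    print(f"annotated {total:,} unique sequences:")
    for cls, n in sorted(summary["class_counts"].items(), key=lambda kv: -kv[1]):
        print(f"  {cls:<12} {n:>8,}  ({100 * n / total:.1f}%)")


if __name__ == "__main__":
    main()
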