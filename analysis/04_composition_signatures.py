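"""Per-region composition and piRNA sequence signatures.

Normalizes counts by median-of-ratios, averages replicates per region
and reports: the share of each sncRNA class within each region
(piRNA-dominated parenchyma giving way to miRNA/tsRNA-rich ejaculated
sperm), tsRNA isoacceptor / subtype and rRNA species mixes, the
expression-weighted U1 (5'-uridine) and A10 (position-10 adenine)
piRNA shares per region, and the piRNAs perfectly matching the
mitochondrial genome.
"""

import pandas as pd

from _config import make_config, parse_args
from sncatlas.pipeline import stage_quantify, stage_signatures


def main() -> None:
    args = parse_args(__doc__)
    cfg = make_config(args)
    q = stage_quantify(cfg)
    run = args.results / "run"
    within = pd.read_csv(run / "proportions_class_within_region.tsv", sep="\t", index_col=0)
    print("class share (%) of each region's total expression:")
    print(within.round(1).to_string())
    s = stage_signatures(cfg)
    u1a10 = pd.read_csv(run / "u1_a10_regions.tsv", sep="\t")
    print("\npiRNA U1 / A10 expression shares per region:")
    print(u1a10[["region", "u1_share", "a10_share"]].round(3).to_string(index=False))
    print(f"\n{s['mt_matched_pirnas']:,} piRNA sequences match the mitochondrial "
          f"genome perfectly; piRBase target-location shares: "
          f"{s['pirna_target_location_shares']}")


if __name__ == "__main__":
    main()
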