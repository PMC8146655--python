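"""Spatiotemporal K-means profiling and between-class analysis.

Differentially expressed sncRNAs are reduced to standardized
five-region profiles and clustered with multi-start Lloyd K-means; the
number of clusters is chosen by the elbow on betweenss/totss
("information retained").  Reports the ratio trace, each cluster's
peak region and class composition, piRNA U1/A10 and mt-piRNA shares
per cluster, and the between-class inertia ratio of regions per sncRNA
family.
"""

import pandas as pd

from _config import make_config, parse_args
from sncatlas.pipeline import stage_cluster


def main() -> None:
    args = parse_args(__doc__)
    cfg = make_config(args)
    summary = stage_cluster(cfg)
    run = args.results / "run"
    trace = pd.read_csv(run / "elbow_ratio_trace.tsv", sep="\t", index_col=0)
    print("information retained (betweenss/totss) per k:")
    print(trace["ratio"].round(3).to_string())
    print(f"\nchosen k = {summary['chosen_k']} "
          f"(ratio {summary['ratio_at_chosen_k']:.3f}) over "
          f"{summary['clustered_features']:,} DE features")
    print("\nper-cluster peak region and dominant class:")
    for g, entry in sorted(summary["cluster_composition"].items(), key=lambda kv: int(kv[0])):
        shares = entry["class_shares"]
        top_cls = max(shares, key=shares.get)
        mt = entry.get("mt_pirna_share")
        extra = f", mt-piRNA {mt:.0f}%" if mt else ""
        print(f"  cluster {g}: peaks at {entry['peak_region']}, "
              f"{shares[top_cls]:.0f}% {top_cls} ({entry['n_features']} features{extra})")
    print("\nbetween-class inertia ratio (regions as classes):")
    print(pd.Series(summary["bca_ratios"]).round(3).to_string())


if __name__ == "__main__":
    main()
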