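"""Pairwise differential-expression screen between regions.

For every pair of regions, each feature's normalized group means are
compared with a simplified negative-binomial Wald test; features with
Benjamini-Hochberg adjusted p < 0.05 and fold difference > 2.5 are
called significant.  Prints the pairwise count matrix (the number of
differentially expressed sncRNAs grows with the anatomical distance
between regions) and the class breakdown of PAR vs SPZ calls.
"""

import pandas as pd

from _config import make_config, parse_args


def main() -> None:
    args = parse_args(__doc__)
    make_config(args)
    run = args.results / "run"
    de_summary = pd.read_csv(run / "de_summary.tsv", sep="\t", index_col=0)
    print("differentially expressed sncRNAs per region pair "
          "(adjusted p < 0.05, fold > 2.5):")
    print(de_summary.to_string())

    res = pd.read_csv(run / "de_PAR_vs_SPZ.tsv", sep="\t", index_col=0)
    sig = res[res["significant"]]
    if len(sig):
        down = sig[sig["log2_fold_change"] > 0]  # higher in PAR = lost by SPZ
        print(f"\nPAR vs SPZ: {len(sig):,} significant; "
              f"{100 * len(down) / len(sig):.0f}% under-expressed in ejaculated sperm")
        print("class breakdown of significant features (%):")
        print((100 * sig["assigned_class"].value_counts(normalize=True)).round(1).to_string())


if __name__ == "__main__":
    main()
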