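"""UMI preprocessing: trim, collapse PCR duplicates, filter, stack.

For every library: locate the 3' adapter, split off insert and UMI,
collapse identical (insert, UMI) reads to one exemplar with mean
quality, drop inserts shorter than 17 nt or with any base below Q25,
and stack survivors by unique sequence into a tag table
(results/run/tag_table.tsv).
"""

import pandas as pd

from _config import make_config, parse_args
from sncatlas.pipeline import stage_preprocess


def main() -> None:
    args = parse_args(__doc__)
    cfg = make_config(args)
    summary = stage_preprocess(cfg)
    counters = pd.DataFrame(summary["counters"])
    print(counters.to_string(index=False))
    frac_dup = counters["duplicates_collapsed"].sum() / counters["raw"].sum()
    print(f"\n{summary['unique_sequences']:,} unique sequences across "
          f"{summary['samples']} libraries; "
          f"{100 * frac_dup:.1f}% of reads were PCR duplicates")


if __name__ == "__main__":
    main()
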