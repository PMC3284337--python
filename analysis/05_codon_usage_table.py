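#!/usr/bin/env python
"""Reproduce the published two-codon usage bias table from printed counts.

Recomputes every usage percentage and per-family |delta u_T| from the
bundled published codon counts of the two subgenomes and writes the table
under results/.
"""

import os
import sys

sys.path.insert(0, os.path.dirname(os.path.abspath(__file__)))
from _common import results_dir

from homeoscan.codon_bias import bias_table, load_published_counts, round2


def main() -> None:
    pg, pe = load_published_counts()
    table, summary = bias_table(pg, pe)
    path = os.path.join(results_dir(), "published_codon_usage.tsv")
    table.to_csv(path, sep="\t", index=False)
    print(table.to_string(index=False))
    print(
        f"average |delta u_T| = {round2(summary['average'])}  "
        f"(median {round2(summary['median'])}, "
        f"Q1-Q3 {round2(summary['q1'])}-{round2(summary['q3'])})"
    )
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
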