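"""Over-representation analysis of the transcriptome clock's predictors.

Tests the clock's nonzero transcript genes against a gene-set collection
(a simulated collection with one deliberately age-loaded set, unless a GMT
path is configured) using the one-sided hypergeometric test with BH FDR;
a set is flagged when q < 0.05 with at least 3 overlapping genes.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_config  # noqa: E402

from kidbioage.pipeline import run_pipeline


def main() -> None:
    cfg = build_config(stages=("preprocess", "clock", "enrich"))
    manifest = run_pipeline(cfg)
    rec = manifest["stages"]["enrich"]
    top = rec["top_set"]
    print(f"{rec['n_sets']} gene sets tested; {rec['n_significant']} significant (q<0.05, k>=3)")
    print(f"top set: {top['name']} (k={top['k']}, p={top['p']:.2g}, q={top['q']:.2g})")
    print(f"table: {cfg.output_dir}/enrichment.csv")


if __name__ == "__main__":
    main()
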