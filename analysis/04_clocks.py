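"""Train the immunometabolic and transcriptome age clocks.

Elastic-net line search over alpha in {0, 0.1, ..., 1} with lambda chosen
by 10-fold cross-validated MSE; 25% of children held out for testing, and
the panel follow-up visit used for the paired one-tailed progression test.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from common import build_config  # noqa: E402

from kidbioage.pipeline import run_pipeline


def main() -> None:
    cfg = build_config(stages=("preprocess", "clock"))
    manifest = run_pipeline(cfg)
    for name, rec in manifest["stages"]["clock"].items():
        if name == "status":
            continue
        print(
            f"{name}: alpha={rec['alpha']}, lambda={rec['lambda']:.4g}, "
            f"{rec['nonzero_predictors']} predictors {rec['block_composition']}"
        )
        print(f"  held-out: r={rec['test_r']:.3f}, MAE={rec['test_mae_years']:.2f} y (n={rec['test_n']})")
        if "progression" in rec:
            p = rec["progression"]
            print(
                f"  visit-to-visit increase {p['mean_increase_years']:.2f} y over {p['n_pairs']} pairs, "
                f"one-sided p={p['one_sided_p']:.2g}"
            )


if __name__ == "__main__":
    main()
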