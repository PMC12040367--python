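"""Leave-centre-out external validation with stacked predictions.

For each of the four centres, the entire pipeline (phrase detection,
SGNS embedding, AIC code selection, TO/TC fits) is retrained on the
other three centres and the held-out centre is scored; the held-out
predictions are then stacked into a single set whose metrics are the
overall external performance.  Writes the per-centre + Overall table
(AUROC/AUPRC/Brier with CIs) under results/external/.

Usage: python analysis/03_external_validation.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from lungrisk import PipelineConfig, run_external
from lungrisk.records import read_jsonl


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    records = list(read_jsonl(ROOT / "scratch" / "cohort.jsonl"))
    cfg = PipelineConfig(embedding_dim=50, embedding_epochs=3,
                         bootstrap_B=1000, seed=args.seed)
    out = ROOT / "results" / "external"
    result, rows = run_external(records, cfg, out_dir=out)

    print(f"{'model':<6}{'test set':<12}{'AUROC (95% CI)':<26}"
          f"{'AUPRC':<10}{'Brier':<10}")
    for row in rows:
        print(f"{row['model']:<6}{row['test_set']:<12}"
              f"{row['auroc']:.4f} ({row['auroc_ci_lower']:.4f}-"
              f"{row['auroc_ci_upper']:.4f})   "
              f"{row['auprc']:.4f}    {row['brier']:.4f}")
    if result.excluded_centres:
        print(f"excluded centres (single outcome class): "
              f"{result.excluded_centres}")


if __name__ == "__main__":
    main()
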