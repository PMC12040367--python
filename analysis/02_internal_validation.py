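"""Internal validation of the TO and TC models on the simulated cohort.

Reads scratch/cohort.jsonl (produced by 01_simulate_cohort.py), runs the
outcome-stratified 60/20/20 split, fits the phrase-SGNS embedding and
both logistic risk models on the training split, and evaluates on the
held-out test split: AUROC/AUPRC/Brier with 95% percentile bootstrap
CIs (B=1000), a decile calibration table, and PPV-anchored operating
points for target PPVs 0.01-0.10.

Writes metric reports, curve TSVs and figures under results/internal/.

Usage: python analysis/02_internal_validation.py [--seed 1]
"""

import argparse
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from lungrisk import PipelineConfig, run_internal
from lungrisk.records import read_jsonl
from lungrisk.report import (
    plot_calibration,
    plot_precision_recall,
    write_calibration_tsv,
    write_operating_points_tsv,
    write_pr_tsv,
    write_roc_tsv,
)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    records = list(read_jsonl(ROOT / "scratch" / "cohort.jsonl"))
    cfg = PipelineConfig(embedding_dim=50, embedding_epochs=3,
                         bootstrap_B=1000, with_operating_cis=True,
                         seed=args.seed)
    out = ROOT / "results" / "internal"
    res = run_internal(records, cfg, out_dir=out)

    for name, rep in res.reports.items():
        preds = res.predictions[name]
        write_roc_tsv(preds, out / f"roc_{name}.tsv")
        write_pr_tsv(preds, out / f"pr_{name}.tsv")
        write_calibration_tsv(rep, out / f"calibration_{name}.tsv")
        write_operating_points_tsv(rep, out / f"operating_points_{name}.tsv")
    plot_precision_recall(res.predictions, out / "precision_recall.png")
    plot_calibration(res.reports, out / "calibration.png")

    print(f"selected ICPC codes: {res.selected_codes}")
    for name, rep in res.reports.items():
        a, lo, hi = rep.auroc
        p, plo, phi = rep.auprc
        b, blo, bhi = rep.brier
        print(f"{name}: AUROC {a:.3f} ({lo:.3f}-{hi:.3f})  "
              f"AUPRC {p:.3f} ({plo:.3f}-{phi:.3f})  "
              f"Brier {b:.4f} ({blo:.4f}-{bhi:.4f})  "
              f"[test n={rep.n}, {rep.n_positive} cases]")


if __name__ == "__main__":
    main()
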