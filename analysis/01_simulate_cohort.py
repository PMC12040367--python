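"""Simulate the study cohort: four GP centres, ~3% outcome prevalence.

Generates a desk-scale analogue of a multi-centre primary-care cohort
for lung-cancer case-finding: longitudinal free-text notes with a
symptom signal that intensifies during the pre-diagnostic year,
ICPC-coded episodes, and centre-specific documentation styles.

Writes the patient records (JSONL) and the ground truth (TSV) under
scratch/ (bulk data) and a cohort summary under results/.

Usage: python analysis/01_simulate_cohort.py [--seed 1] [--n 8000]
"""

import argparse
import collections
import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from lungrisk import SimulationConfig, generate_cohort
from lungrisk.config_io import save_config


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n", type=int, default=8000)
    args = ap.parse_args()

    cfg = SimulationConfig(n_patients=args.n, prevalence=0.03,
                           signal_gain=10.0, seed=args.seed)
    records, truth = generate_cohort(cfg)

    scratch = ROOT / "scratch"
    scratch.mkdir(exist_ok=True)
    from lungrisk.records import write_jsonl

    write_jsonl(records, scratch / "cohort.jsonl")
    truth.to_tsv(scratch / "ground_truth.tsv")
    save_config(cfg, scratch / "simulation_config.yaml")

    cases = [r for r in records if r.is_case]
    by_centre = collections.Counter(r.centre_id for r in records)
    case_by_centre = collections.Counter(r.centre_id for r in cases)
    summary = {
        "n_patients": len(records),
        "n_cases": len(cases),
        "prevalence": len(cases) / len(records),
        "per_centre_n": dict(sorted(by_centre.items())),
        "per_centre_case_rate": {
            c: case_by_centre[c] / by_centre[c] for c in sorted(by_centre)
        },
        "female_rate_cases": sum(r.sex == "female" for r in cases)
        / max(len(cases), 1),
        "mean_notes_per_patient": sum(len(r.notes) for r in records)
        / len(records),
        "seed": args.seed,
    }
    out = ROOT / "results"
    out.mkdir(exist_ok=True)
    (out / "cohort_summary.json").write_text(json.dumps(summary, indent=2))

    print(f"simulated {summary['n_patients']} patients, "
          f"{summary['n_cases']} lung-cancer cases "
          f"({100 * summary['prevalence']:.1f}%) across "
          f"{len(by_centre)} centres")
    print(f"case rate per centre: "
          + ", ".join(f"{c}: {r:.3f}"
                      for c, r in summary["per_centre_case_rate"].items()))
    print(f"records -> {scratch / 'cohort.jsonl'}")


if __name__ == "__main__":
    main()
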