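#!/usr/bin/env python
"""Train and evaluate the Gaussian naive Bayes classifier on the cohort.

Runs the repeated random-subsampling protocol (30 train + 20 test per
class, 1000 shuffled trials) and stratified 4-fold cross-validation on
the feature matrix from 02_extract_features.py, then prints the mean
accuracy, its SD over trials, and the per-true-class-normalised
confusion matrix.  Writes results/eval_report.json.
"""

import json
from pathlib import Path

import fasd_eeg as fe
from fasd_eeg.features import FeatureMatrix

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    features_csv = ROOT / "scratch" / "features.csv"
    if features_csv.exists():
        matrix = FeatureMatrix.from_csv(features_csv)
        print(f"loaded features from {features_csv}")
    else:
        print("features not found; regenerating default cohort + features")
        matrix = fe.extract_features(fe.generate_cohort(fe.SimConfig()))

    plan = fe.SplitPlan(n_train_per_class=30, n_test_per_class=20,
                        n_trials=1000, seed=0)
    report = fe.repeated_evaluation(matrix, plan)
    kfold = fe.kfold_cv(matrix, k=4, seed=0)

    payload = report.to_dict()
    payload["kfold_accuracy"] = kfold
    out = ROOT / "results" / "eval_report.json"
    out.parent.mkdir(exist_ok=True)
    out.write_text(json.dumps(payload, indent=1))

    c = report.confusion
    print(f"\ntrials:        {report.n_trials}")
    print(f"mean accuracy: {report.mean_accuracy:.3f}")
    print(f"sd accuracy:   {report.sd_accuracy:.3f}")
    print(f"4-fold CV:     {kfold:.3f}")
    print("confusion (% of each true class):")
    print(f"                predicted FASD   predicted control")
    print(f"  true FASD     TP {c['tp']:5.1f}        FN {c['fn']:5.1f}")
    print(f"  true control  FP {c['fp']:5.1f}        TN {c['tn']:5.1f}")
    print(f"\nwrote {out}")


if __name__ == "__main__":
    main()
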