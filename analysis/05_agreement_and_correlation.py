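#!/usr/bin/env python
"""Device agreement and the HRV-accuracy correlation.

Part 1 summarises the packaged 20-subject sensor-vs-monitor heart-rate
table by its absolute errors.  Part 2 correlates the per-window mean HRV
index with the per-window classification accuracy produced by
04_classify_fatigue.py (run that first), on min-max normalised 0-1
scales.
"""

import json
from pathlib import Path

import pandas as pd
from scipy import stats

import bcgfatigue as bf
from bcgfatigue.classify import AccuracyProfile

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    pairs = bf.load_sensor_monitor_pairs()
    report = bf.agreement(pairs[["hr_sensor", "hr_monitor"]].to_numpy())
    (results / "device_agreement.json").write_text(
        json.dumps(report.summary(), indent=2)
    )
    print("device agreement (sensor vs monitor, 20 subjects):")
    for k, v in report.summary().items():
        print(f"  {k}: {v:.4f}")

    profile_csv = results / "accuracy_profile.csv"
    if not profile_csv.exists():
        print("\nno accuracy_profile.csv yet - run 04_classify_fatigue.py first")
        return
    df = pd.read_csv(profile_csv)
    if len(df) < 3:
        print("\nfewer than 3 candidate windows in accuracy_profile.csv; "
              "correlation not computed (rerun 04 on a longer recording)")
        return
    profile = AccuracyProfile(
        window_indices=(df["window_start_min"] // 10).to_numpy(),
        mean_accuracy=df["mean_accuracy_pct"].to_numpy(),
        per_repeat=df["mean_accuracy_pct"].to_numpy()[:, None],
        mean_v=df["mean_v"].to_numpy(),
    )
    corr = bf.hrv_accuracy_correlation(profile)
    rho = stats.spearmanr(profile.window_indices, profile.mean_accuracy).statistic
    payload = {
        "pearson_r": corr.pearson_r,
        "spearman_accuracy_vs_window": float(rho),
        "mean_v_norm": corr.x_norm.tolist(),
        "mean_accuracy_norm": corr.y_norm.tolist(),
    }
    (results / "hrv_accuracy_correlation.json").write_text(
        json.dumps(payload, indent=2)
    )
    print(f"\nHRV-accuracy Pearson r = {corr.pearson_r:.3f} "
          f"(accuracy-vs-window Spearman rho = {rho:.3f}); "
          f"normalised curves in hrv_accuracy_correlation.json")


if __name__ == "__main__":
    main()
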