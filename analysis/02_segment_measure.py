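#!/usr/bin/env python
"""Segment and measure the synthetic cohort under three simulated observers.

Re-generates the seed-2023 cohort, runs the semi-automatic plate
segmentation (physical ROI crop -> three-class Otsu range threshold ->
morphological clean-up), measures per-observer morphometry (Af, Ae, ARI,
Vf, Ve, VRI), and scores pairwise observer agreement.  Writes
morphometry.csv, ari_by_subject.csv and kappa.csv to results/tables/.
"""

from pathlib import Path

import pandas as pd

from physometry.pipeline import analyze_cohort, config_from_dict, simulate_inputs

SEED = 2023
ROOT = Path(__file__).resolve().parents[1]
TABLES = ROOT / "results" / "tables"


def main() -> None:
    config = config_from_dict({"seed": SEED})
    studies, _truths, observers = simulate_inputs(config)
    report = analyze_cohort(studies, observers, config)

    TABLES.mkdir(parents=True, exist_ok=True)
    report.morphometry.to_csv(
        TABLES / "morphometry.csv", index=False, float_format="%.10g"
    )
    report.ari_by_subject.to_csv(
        TABLES / "ari_by_subject.csv", index=False, float_format="%.10g"
    )
    kappa_df = pd.DataFrame(
        {
            "observer_pair": f"{k.observer_pair[0]} vs {k.observer_pair[1]}",
            "kappa": k.kappa,
            "ci_low": k.ci_low,
            "ci_high": k.ci_high,
            "n_pixels": k.n,
        }
        for k in report.kappa
    )
    kappa_df.to_csv(TABLES / "kappa.csv", index=False, float_format="%.10g")

    print(f"measured {len(studies)} subjects x 3 observers (seed {SEED})")
    print("inter-observer agreement (pooled pixel-wise kappa within ROI):")
    print(kappa_df.round(4).to_string(index=False))
    morph = report.morphometry
    print(
        f"VRI == ARI for all {len(morph)} subject-observer rows: "
        f"{(morph['VRI'] == morph['ARI']).all()}"
    )


if __name__ == "__main__":
    main()
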