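#!/usr/bin/env python
"""Correlate chronological age with the mean ARI, by sex and overall.

Reads results/tables/ari_by_subject.csv (produced by 02_segment_measure)
and writes the age-ARI Pearson correlations with Fisher-z 95% CIs, the
sex-difference Mann-Whitney tests, and the normality checks that motivate
using a rank test for the group comparisons.
"""

from pathlib import Path

import pandas as pd

from physometry.pipeline import cohort_statistics

ROOT = Path(__file__).resolve().parents[1]
TABLES = ROOT / "results" / "tables"


def main() -> None:
    ari_df = pd.read_csv(TABLES / "ari_by_subject.csv")
    stats = cohort_statistics(ari_df)

    corr_df = pd.DataFrame(
        {
            "group": label,
            "N": c.n,
            "r": c.r,
            "ci_low": c.ci_low,
            "ci_high": c.ci_high,
            "p": c.p,
        }
        for label, c in stats["correlations"].items()
    )
    corr_df.to_csv(TABLES / "correlation.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        {"comparison": k, "U": u, "p": p}
        for k, (u, p) in stats["mann_whitney"].items()
    ).to_csv(TABLES / "mann_whitney.csv", index=False, float_format="%.10g")
    pd.DataFrame(
        {"variable": k, "D": d, "p": p} for k, (d, p) in stats["normality"].items()
    ).to_csv(TABLES / "normality.csv", index=False, float_format="%.10g")

    print("age vs mean ARI (Pearson, Fisher-z 95% CI):")
    print(corr_df.round(4).to_string(index=False))
    for k, (u, p) in stats["mann_whitney"].items():
        verdict = "no significant difference" if p > 0.05 else "significant difference"
        print(f"{k}: U={u:.1f}, p={p:.3f} -> {verdict} between sexes")


if __name__ == "__main__":
    main()
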