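#!/usr/bin/env python
"""Demographic and hair factor analyses of ROI quality.

On the hair-biased 61-session cohort: Pearson/Spearman/Kendall
correlations and Wilcoxon rank-sum tests of ROI quality against hair and
demographic factors (BH-FDR corrected), one-way ANOVA variance-explained
tables, and the alertness ceiling analysis.  Writes
results/factor_correlations.csv and results/factor_anova.csv.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from hdnirs import experiments as ex
from hdnirs.evaluation import (anova_variance_explained, ceiling_analysis,
                               factor_battery)
from hdnirs.montage import HAIR_COLOR_LEVELS, HAIR_DENSITY_LEVELS

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 3
ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
RESULTS.mkdir(exist_ok=True)

recs, rows = ex.quality_bias_cohort(SEED)
out = ex.quality_bias_analysis(recs, rows)
fac = out["factors"].copy()
fac["hair_color_ord"] = fac.hair_color.map(
    {lev: i for i, lev in enumerate(HAIR_COLOR_LEVELS)})
fac["hair_density_ord"] = fac.hair_density.map(
    {lev: i for i, lev in enumerate(HAIR_DENSITY_LEVELS)})

battery = factor_battery(
    out["scores"],
    fac[["age", "sex", "hair_length", "hair_color_ord", "hair_density_ord"]])
corr = pd.DataFrame([
    {"factor": r.factor, "kind": r.kind, **r.stats,
     "p_raw": r.p_raw, "p_fdr": r.p_fdr} for r in battery])
corr.to_csv(RESULTS / "factor_correlations.csv", index=False)

anova = anova_variance_explained(
    out["scores"], fac, ["hair_length", "hair_color", "hair_density"])
anova.to_csv(RESULTS / "factor_anova.csv", index=False)

alertness = fac.alertness.to_numpy(float)
ceil = ceiling_analysis(out["scores"], alertness, top_frac=0.2)

print(corr.to_string(index=False))
print(anova.to_string(index=False))
print(f"alertness ceiling: tau={ceil['kendall_tau']:.3f} "
      f"(p={ceil['p']:.3f}, top-quintile n={len(ceil['indices'])})")
print(f"-> {RESULTS}/factor_correlations.csv, factor_anova.csv")
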