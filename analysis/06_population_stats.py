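#!/usr/bin/env python
"""Comparative statistics on the individual estimates: sex, size and gravidity
effects on T_p, latitude trends, and multiplicity-adjusted pairwise
population comparisons."""

import argparse
import json
from pathlib import Path

import pandas as pd

from vipertherm import popstats

parser = argparse.ArgumentParser()
parser.add_argument("--datadir", type=Path, default=Path("results/data"))
parser.add_argument("--tset", type=Path, default=Path("results/tset_estimates.csv"))
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

roster = pd.read_csv(args.datadir / "roster.csv")
est = pd.read_csv(args.tset)
ind = (
    est[est["level"] == "individual"]
    .drop(columns=["population"])
    .merge(roster, left_on="unit_id", right_on="individual_id")
)

report = {}
fem, mal = ind[ind["sex"] == "female"], ind[ind["sex"] == "male"]
f = popstats.ols_fit(fem["svl_mm"], fem["t_p"])
m = popstats.ols_fit(mal["svl_mm"], mal["t_p"])
report["female_svl"] = {"b": f.slope, "p": f.p_value, "n": f.n}
report["male_svl"] = {"b": m.slope, "p": m.p_value, "n": m.n}
print(f"SVL on T_p, females: b = {f.slope:.3f}, P = {f.p_value:.3g} (n = {f.n})")
print(f"SVL on T_p, males:   b = {m.slope:.3f}, P = {m.p_value:.3g} (n = {m.n})")

w, p = popstats.wilcoxon_ranksum(fem["t_p"], mal["t_p"])
report["sex_wilcoxon"] = {"W": w, "p": p}
print(f"sex difference: Wilcoxon W = {w:.0f}, P = {p:.3f}")

gr, ng = fem[fem["gravid"]], fem[~fem["gravid"]]
if len(gr) and len(ng):
    w, p = popstats.wilcoxon_ranksum(gr["t_p"], ng["t_p"])
    report["gravidity_wilcoxon"] = {"W": w, "p": p}
    print(f"gravidity: Wilcoxon W = {w:.0f}, P = {p:.3f}")

for col, label in (("t_p", "T_p"), ("t_set_lower", "lower T_set"),
                   ("t_set_upper", "upper T_set")):
    fit = popstats.ols_fit(ind["latitude"], ind[col])
    report[f"latitude_{col}"] = {"b": fit.slope, "p": fit.p_value}
    print(f"latitude on {label}: b = {fit.slope:.3f}, P = {fit.p_value:.3g}")

pairs = popstats.pairwise_population_comparison(
    {pop: g["t_p"].to_numpy() for pop, g in ind.groupby("population")}
)
args.outdir.mkdir(parents=True, exist_ok=True)
pairs.to_csv(args.outdir / "pairwise_tp.csv", index=False, lineterminator="\n")
(args.outdir / "stats.json").write_text(json.dumps(report, indent=2) + "\n")
sig = pairs[pairs["p_adj"] < 0.05]
print("\npairwise T_p contrasts (Holm-adjusted):")
print(pairs.round(4).to_string(index=False))
if len(sig):
    print(f"significant pairs: "
          f"{[f'{r.group_a}-{r.group_b}' for r in sig.itertuples()]}")
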