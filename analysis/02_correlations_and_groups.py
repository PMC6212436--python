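#!/usr/bin/env python
"""Pairwise correlations and native-ocean-region grouping.

Recomputes the survey's correlation structure (NIS share vs distance, cargo
imports and local native richness; Hd vs distance; Hd vs pi among polymorphic
species) and the four-group native-region comparison with tie-corrected
Kruskal-Wallis tests. Writes results/correlations.json and
results/region_groups.csv.
"""

import json
from pathlib import Path

import pandas as pd

from nistrace.io import load_table1_fixture
from nistrace.pipeline import run_paper_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = run_paper_analysis(load_table1_fixture())
    corr = report["correlations"]
    for name, res in corr.items():
        if res:
            print(f"{name:34s} r={res['r']:+.3f} p={res['p']:.3f} "
                  f"(n={res['n']}, {res['method']})")
    print("\nNative-ocean-region groups (tie-corrected Kruskal-Wallis):")
    for var, res in report["groups"]["kruskal_wallis"].items():
        print(f"  {var:4s}: H={res['H']:.3f} Hc={res['Hc']:.3f} p={res['p']:.3f}")
    OUT.mkdir(exist_ok=True)
    (OUT / "correlations.json").write_text(json.dumps(
        {"correlations": corr,
         "kruskal_wallis": report["groups"]["kruskal_wallis"]}, indent=2))
    rows = []
    for g in report["groups"]["summary"]:
        rows.append({
            "group": g["label"], "n_members": g["n_members"],
            "mean_pct": g["mean_pct"], "sd_pct": g["sd_pct"],
            "pct_BB": g["sum_pct_by_region"].get("BB", 0.0),
            "pct_GL": g["sum_pct_by_region"].get("GL", 0.0),
            "mean_NH": g["mean_NH"], "mean_Hd": g["mean_Hd"],
            "mean_pi": g["mean_pi"],
        })
    pd.DataFrame(rows).to_csv(OUT / "region_groups.csv", index=False)
    print(f"\nwrote {OUT / 'correlations.json'} and {OUT / 'region_groups.csv'}")


if __name__ == "__main__":
    main()
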