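#!/usr/bin/env python
"""Gaussian log-link GLMs of NIS abundance and haplotype diversity.

Fits E[y] = exp(b0 + b1*x) for dependent variable a (NIS share of the
regional sample) and b (haplotype diversity Hd) against distance to the
native range, cargo imports and local native richness, on the non-cryptogenic
occurrence rows. Reports the scaled-deviance G test for each slope plus
Durbin-Watson and Breusch-Pagan diagnostics; writes results/glms.json.
"""

import json
from pathlib import Path

from nistrace.io import load_table1_fixture
from nistrace.pipeline import run_paper_analysis

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    report = run_paper_analysis(load_table1_fixture())
    glms = report["glms"]
    for dep, fits in glms.items():
        print(f"\n{dep}:")
        for x, fit in fits.items():
            if fit is None or "error" in fit:
                print(f"  ~ {x}: not fitted ({fit})")
                continue
            star = " *" if fit["p_slope"] < 0.05 else ""
            print(f"  ~ {x:10s} slope={fit['slope']:+.3f} ({fit['se_slope']:.3f}) "
                  f"phi={fit['phi']:.3f} G={fit['G']:.3f} "
                  f"p={fit['p_slope']:.3f}{star}  [dw={fit['dw']:.2f}, "
                  f"bp_p={fit['bp_p']:.2f}, n={fit['n']}]")
    OUT.mkdir(exist_ok=True)
    (OUT / "glms.json").write_text(json.dumps(glms, indent=2))
    print(f"\nwrote {OUT / 'glms.json'}")
    hd_dist = glms["dependent_b_Hd"]["distance"]
    if hd_dist and hd_dist.get("p_slope", 1) < 0.05 and hd_dist["slope"] > 0:
        print("Finding: NIS haplotype diversity increases with distance to the "
              "native range; cargo imports show no such association.")


if __name__ == "__main__":
    main()
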