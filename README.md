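# nistrace

Tracing the geographic origin of port-fouling non-indigenous species (NIS)
from DNA-barcode haplotypes, and modelling what makes a successful invader.

Port surveys of fouling invertebrates routinely turn up species far from
their native ranges, but *where a particular introduced population came
from* is much harder to establish than *what it is*. `nistrace` implements a
proof-of-concept inference framework for this problem, aimed at marine
invasion biologists working with COI/16S/18S barcodes:

- **best-match donor assignment** — each port haplotype is matched against
  geo-referenced voucher reference sequences; an assignment requires ≥ 99%
  pairwise identity over at least 100 comparable sites, and equal-identity
  ties between regions are broken toward the region great-circle-closest to
  the recipient port;
- **inference-strength (IS) weighting** — a coefficient in
  {0, 0.01, 0.1, 0.3, 0.5, 1} grading each species' geographic inference by
  its phylogeographic signal and reference-database coverage (0 = no
  phylogeographic pattern, 1 = strong signature with at least medium
  coverage); donor-region contributions are reported raw and IS-weighted;
- **diversity statistics** — number of haplotypes NH, Nei's unbiased
  haplotype diversity `Hd = n/(n−1)·(1 − Σ(cᵢ/n)²)` and per-site nucleotide
  diversity `π = Σ_{i<j} cᵢcⱼdᵢⱼ / (C(n,2)·L)`, plus the joint Hd/π
  interpretation of introduction history (high Hd & high π → multiple
  introductions; high Hd & low π → in-situ mutation or an expansive donor;
  low Hd & high π → a few very distinct lineages);
- **median-joining haplotype networks** — Bandelt-style construction over
  observed haplotypes plus cost-reducing median vectors, retaining
  equal-cost reticulations;
- **the statistical layer** — Pearson/Spearman correlations, an |r| > 0.8
  collinearity screen, tie-corrected Kruskal–Wallis comparisons of
  native-ocean-region groups, and Gaussian log-link GLMs
  `E[y] = exp(β₀ + β₁x)` with a scaled-deviance G test of the slope,
  Durbin–Watson and Breusch–Pagan diagnostics;
- **a synthetic-data generator** — infinite-sites simulation of regional
  reference databases and single/multiple/stepping-stones introduction
  scenarios with truth records, so the whole inference chain is testable
  end-to-end without any database download.

The package ships the occurrence table of a two-region European port survey
(south Bay of Biscay, BB, and Gulf of Lion, GL: 22 NIS/cryptogenic
populations, 297 NIS individuals out of 834 barcoded) as a versioned CSV
fixture, and the numbered scripts under `analysis/` re-run the survey's
analyses over it.

## Worked example

IS-weighted donor contributions for the Pacific oyster *Magallana gigas*
(IS = 0.5: good coverage, shallow phylogeographic signature), whose 21
best-match haplotypes split 13 / 7 / 1 across regions:

```python
from nistrace import DonorAssignment, weighted_contributions

asgs = {"Magallana gigas":
        [DonorAssignment(f"h{i}", [], 1.0, "Atlantic Arc") for i in range(13)]
        + [DonorAssignment(f"h{i}", [], 1.0, "NW Pacific") for i in range(13, 20)]
        + [DonorAssignment("h20", [], 1.0, "California")]}
for c in weighted_contributions(asgs, {"Magallana gigas": 0.5}):
    print(c.region, c.lineages_raw, c.lineages_weighted, round(c.pct_of_total, 1))
```

```
Atlantic Arc 13.0 6.5 61.9
California 1.0 0.5 4.8
NW Pacific 7.0 3.5 33.3
```

Running the survey analysis (`python analysis/01_occurrence_summary.py` and
`python analysis/03_diversity_glms.py`) prints, among others:

```
Antipode-origin individuals: 19.3% of all barcoded, 54.21% of NIS specimens
  most abundant: Ficopomatus enigmaticus = 10.67% over the barcoded total
...
dependent_b_Hd:
  ~ distance   slope=+0.296 (0.136) phi=0.108 G=9.088 p=0.012 *
  ~ cargo_pct  slope=+0.017 (0.041) phi=0.190 G=0.272 p=0.611
```

i.e. more than half of the NIS individuals in these European ports descend
from near-antipodal (Australia / New Zealand) source regions, and NIS
haplotype diversity *increases* with distance to the native range while
showing no association with cargo-import volume — the pattern expected if
long (direct or stepping-stones) voyages select for broadly tolerant,
repeatedly introduced lineages rather than propagule survival limiting
distant introductions.

## Analysis scripts

| script | what it does |
|---|---|
| `analysis/01_occurrence_summary.py` | abundance shares and the antipode fraction |
| `analysis/02_correlations_and_groups.py` | correlations; native-region groups + Kruskal–Wallis |
| `analysis/03_diversity_glms.py` | log-link GLMs of NIS share and Hd |
| `analysis/04_donor_inference.py` | IS rubric, worked example, synthetic end-to-end inference |
| `analysis/05_haplotype_networks.py` | median-joining network of a simulated pooled sample |
| `analysis/06_synthetic_validation.py` | 200-replicate simulate → infer → score validation |

Each writes its tables under `results/`.

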