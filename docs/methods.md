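# Methods

## The inference problem

A port survey yields, per non-indigenous species (NIS), a sample of barcode
sequences (COI for all species; 16S/18S where COI fails). Three questions
drive the package: (1) which donor region did each haplotype most plausibly
arrive from, (2) how trustworthy is that geographic inference, and (3) what
explains differences in NIS abundance and within-species genetic diversity
across species — distance to the native range, maritime imports, or the
native richness of the recipient sites?

## Diversity statistics

Sequences are collapsed to haplotypes after site filtering. The default
`complete_deletion` policy removes every alignment column containing a gap
or an ambiguous base anywhere in the sample before comparison (the common
default in haplotype software); the alternative `pairwise` policy keeps all
columns and compares each pair over its own unambiguous overlap. Under
`pairwise` the match relation is not transitive, so sequences are merged
greedily in input order — deterministic, but a known approximation flagged
here. IUPAC ambiguity codes other than N are normalised to N at parse time
so identity is always well defined.

Haplotype diversity uses Nei's unbiased estimator
`Hd = n/(n−1)·(1 − Σ(cᵢ/n)²)`, which equals the probability that two
individuals drawn without replacement carry different haplotypes (the
package tests this equivalence by enumeration). The small-sample correction
matters: the survey's printed per-species values (e.g. 0.5 for a {3,1}
spectrum, 0.286 for {6,1}, 0.833 for {2,1,1}) are reproduced only by the
corrected form. Nucleotide diversity is
`π = Σ_{i<j} cᵢcⱼ dᵢⱼ / (C(n,2)·L)` with dᵢⱼ counting positions where both
bases are unambiguous and differ; under `pairwise` each pair is normalised
by its own comparable length instead of a global L. Display rounding is 3
decimals for both, matching the source table.

## Best-match donor assignment

Identity between a query and a reference is the per-site match fraction over
the pairwise-complete overlap (both bases in {A,C,G,T}); an overlap shorter
than 100 sites is refused as incomparable. Assignment requires identity
≥ 0.99 (inclusive) — a local, reproducible stand-in for "best BLAST hit at
99–100% identity with E-value zero", which needs no remote database. When
references from several regions tie at the maximum identity the assignment
goes to the region whose centroid is great-circle-closest (haversine,
R = 6371 km) to the recipient port — the conservative choice, since a closer
source requires the weaker dispersal hypothesis. Non-voucher references are
parsed and kept but excluded from inference by default. Route distances used
in the statistical models are user-supplied data (maritime routing is out of
scope here); the great circle is used only for tie-breaking.

## Inference strength (IS)

The IS coefficient grades each species' donor inference from two ordinal
inputs: phylogeographic signal (absent < unknown < shallow < moderate <
strong) and reference coverage (minimal < moderate < medium < good). Six
anchor cases define the scale: absent signal → 0 regardless of coverage;
(unknown, minimal) → 0.01; (shallow, moderate) → 0.1; (moderate, medium) →
0.3; (shallow, good) → 0.5; strong signal with at least medium coverage → 1.
Unlisted combinations resolve to the largest anchor value dominated by the
requested combination (both inputs at or below it), i.e. the nearest lower
listed value; the anchor table is override-able for users who disagree with
that completion. Donor-region contributions are computed raw (IS = 1
everywhere) and weighted, because the with/without-IS comparison is the
robustness check: a uniform IS rescales contributions but never changes the
rank order of regions (property-tested). Weighting supports both haplotypes
(default, the applied convention) and individuals as the counting basis.

## Introduction-history calls

The joint pattern of Hd and π is interpreted with two thresholds, defaulting
to Hd ≥ 0.8 ("high haplotype diversity") and π ≥ 0.02 — the same cut-offs
used descriptively in the survey text. High/high → multiple introductions
from different donors; high Hd with low π → in-situ mutation or an expansive
donor population; low Hd with high π → few introductions of very distinct
lineages; low/low → uninformative. The call is a pure function of (Hd, π,
thresholds); it is a heuristic and inherits all caveats about unknown native
population structure.

## Median-joining networks

The construction iterates: (1) build the ε-relaxed minimum spanning network
(MSN) over the current node set — an edge of weight w is admitted when its
endpoints are in different components of the graph of all edges of weight
< w − ε; with ε = 0 this is exactly the union of all minimum spanning trees,
so equal-cost alternative connections are retained; (2) for triplets with at
least two MSN links, form the site-wise majority consensus (median vector)
and admit the candidate that most reduces the minimum spanning cost of the
augmented node set, if any; (3) repeat to fixpoint, then prune medians whose
removal leaves the spanning cost unchanged. Admitting only cost-reducing
medians keeps total cost monotonically non-increasing and bounded above by
the observed-only MST cost. ε defaults to 0 with uniform character weights;
ties are broken lexicographically so output is deterministic. The final
network is the MSN over the retained node set — a deliberate simplification
of full shortest-tree enumeration (exact Steiner refinement is out of
scope); on every small instance tested it coincides with the brute-force
union of minimum spanning trees when no median is admitted.

## Statistical layer

Correlations are Pearson by default (Spearman with average ranks where rank
correlation is requested), two-sided p at n − 2 df. Collinearity screening
drops the later-listed variable of each pair with |r| > 0.8, greedily in
column order, and reports what was dropped.

The GLM is Gaussian with log link, fitted by IRLS (working weights μ²,
working response η + (y − μ)/μ), started from OLS of log(y + δ) on x with δ
half the smallest positive response — the log link constrains the fitted
mean, not the data, so zero responses (monomorphic species with Hd = 0) are
admitted. Dispersion is φ = D_full/(n − 2) and the slope test is the scaled
deviance difference G = (D_null − D_full)/φ. For a Gaussian family G is
algebraically the F statistic with (1, n − 2) df, and the F reference is
exact at small n where the asymptotic χ²₁ reference over-rejects (≈ 6.5%
at n = 20 versus 5%); `p_slope` therefore uses F(1, n − 2) and the χ²₁
p-value is exposed separately as `p_slope_chi2`. Simulation places the null
rejection rate at the 0.05 cut within the binomial 95% CI of 0.05 over 2000
replicates at n = 20. Durbin–Watson uses input row order (no natural order
exists for these data; the statistic is flagged order-dependent) and
heteroskedasticity uses the studentised Breusch–Pagan test. No
multiple-testing correction is applied, matching the source analysis. The
published GLM coefficient table is *not* an acceptance target: its variable
scaling and row subset are not recoverable, so the package documents its own
scale (distance in thousand nautical miles, as in the occurrence table) and
validates the machinery by calibration and cross-implementation agreement
(statsmodels' Gaussian/log GLM to 1e-6) instead of coefficient mimicry.

Kruskal–Wallis reports both the uncorrected H and the tie-corrected
Hc = H / (1 − ΣTⱼ/(N³ − N)), Tⱼ = tⱼ³ − tⱼ, with p from χ²(k−1) on Hc;
scipy's implementation (which returns the corrected form) is the test
oracle.

## Occurrence-table fixture

The packaged CSV holds the 22 surveyed NIS/cryptogenic populations with
per-population n, within-region percentage, NH, Hd, π, mean native richness
at occupied sites, cargo-import percentage from the native range and
distance (thousand nautical miles). Percentage denominators are the
barcoded totals (671 BB, 163 GL, 834 overall). Known data quirks, handled
explicitly rather than silently: the Gulf of Lion caption total (200
sampled) differs from the barcoded denominator its printed percentages use
(163); one NW-Pacific population (Polydora triglanda) has no printed
distance and is treated as missing (complete-case analysis, n = 13 for
distance correlations); the two species present in both regions appear as
two rows keyed by (species, region). The native-ocean-region grouping maps
"N Atlantic, N Pacific" (Mytilus trossulus) to North Atlantic — the only
mapping under which the group's summed regional percentages close — and
routes Red Sea to "other", excluded from the four-group tests. The grouped
mean percentage is defined as the arithmetic mean of member percentages; the
source table's printed group means could not be reverse-engineered from its
own rows and are not asserted anywhere.

## Synthetic generator

The generator emulates the assumed structure of a traceable invasion: a
root haplotype; one founder per region carrying Poisson(divergence/2)
private mutations (so two founders differ by the divergence parameter in
expectation); per-region reference pools with Poisson(θ) private mutations
per non-founder reference; and introduction scenarios — *single* (all
propagules from one donor pool), *multiple* (propagules from ≥ 2 donor
pools) and *stepping-stones* (single-donor propagules with per-lineage
en-route Poisson mutation, at least one novel haplotype guaranteed when the
rate is positive). Every mutation hits a fresh alignment column
(infinite-sites), which makes Hamming distances additive and the expected
Hd/π of a scenario exact closed forms of its count spectrum — the property
the oracles exploit. All randomness flows through one seeded NumPy
generator; fixed seed → byte-identical output.

Validation conditions (chosen once as a realistic strong-signal species): 3
regions, founders ~20 substitutions apart over 600 sites (≈ 3.3% COI
divergence, typical of well-differentiated intraspecific phylogeography),
10 voucher references per region at θ = 3, port samples of 20 propagules.
Under these conditions 200-replicate recovery of the true donor region is
≥ 95% (observed ≈ 100%), and the history classifier calls "multiple
introductions" in ≥ 90% of multiple-donor replicates and ≤ 10% of
single-donor replicates — the single-donor case yields high Hd but low π,
which is exactly why the joint rule, not Hd alone, is used. What passing
does *not* show: real reference databases are sparse, unevenly geo-referenced
and occasionally mislabelled, real markers violate infinite sites
(homoplasy), and real introductions mix vectors; the generator models none
of these, so synthetic recovery rates are an upper bound on field
performance — which is the very gap the IS coefficient exists to express.

## Numerical and design choices

- Hd is clamped to [0, 1] against float round-off at the all-singleton
  extreme.
- IRLS tolerance 1e-12 on the max coefficient change, 200 iterations,
  linear predictor clipped to ±500 before exponentiation; non-convergence
  raises with the coefficient trace attached.
- Haplotype ids are assigned by count descending, then lexicographic
  sequence; all graph tie-breaks are lexicographic. Reruns are identical.
- The in-text correlation magnitudes of the source survey (r = 0.208 and
  r = −0.412 over the 14 non-cryptogenic rows) are not exactly recoverable
  from the printed occurrence table (recomputation gives +0.19 / −0.19);
  the signs and non-significance reproduce. The discrepancy is documented in
  the acceptance-test docstring rather than patched over.
- GLMs for inferred-lineage responses (lineages per donor region with and
  without IS, and % NIS haplotypes per donor region) run only when the user
  supplies a per-region lineage table, since building one requires a
  reference database; the pipeline accepts the schema and the analysis
  scripts demonstrate it with synthetic data.

## Limitations

Donor inference is only as good as the reference database — the package
deliberately reports "unassigned" below the identity threshold instead of
stretching matches. The pairwise-policy collapse is order-dependent in
pathological ambiguity patterns. The MJ implementation targets barcode-scale
haplotype sets (tens of haplotypes), not genome-scale data. The statistical
layer fits single-predictor models only, by design.
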