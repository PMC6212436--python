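"""Haplotype collapsing and the diversity statistics NH, Hd and pi.

Haplotype diversity uses Nei's unbiased estimator

    Hd = n/(n-1) * (1 - sum_i (c_i/n)^2)

and nucleotide diversity is the mean per-site proportion of differences over
all unordered sequence pairs,

    pi = sum_{i<j} c_i c_j d_ij / (C(n,2) * L),

computed from the haplotype count spectrum (pairs within a haplotype
contribute zero differences). Site handling follows the two usual policies:
``complete_deletion`` (default) drops every alignment column containing a gap
or N before any comparison; ``pairwise`` keeps all columns and compares each
pair over the sites where both bases are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

from nistrace.io import AlignedSequenceSet

_BASES = set("ACGT")

SitePolicy = str  # "complete_deletion" | "pairwise"


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes for one species/region sample.

    ``haplotypes`` is a list of (hap_id, sequence, count) sorted by count
    descending then sequence lexicographically; ``L`` is the number of sites
    retained for comparison.
    """

    species: str
    region: str
    haplotypes: list[tuple[str, str, int]]
    n: int
    L: int
    site_policy: SitePolicy = "complete_deletion"

    def __post_init__(self) -> None:
        if sum(c for _, _, c in self.haplotypes) != self.n:
            raise ValueError("haplotype counts must sum to n")

    @property
    def NH(self) -> int:
        return len(self.haplotypes)

    @property
    def counts(self) -> list[int]:
        return [c for _, _, c in self.haplotypes]


@dataclass
class DiversityStats:
    NH: int
    Hd: float
    pi: float

    def __post_init__(self) -> None:
        if self.NH == 1 and (self.Hd != 0 or self.pi != 0):
            raise ValueError("a monomorphic sample must have Hd = pi = 0")


def _complete_deletion_columns(seqs: list[str]) -> list[int]:
    L = len(seqs[0])
    return [j for j in range(L) if all(s[j] in _BASES for s in seqs)]


def _seqs_equal_pairwise(a: str, b: str) -> bool:
    return all(x == y for x, y in zip(a, b) if x in _BASES and y in _BASES)


def collapse_haplotypes(
    seqs: AlignedSequenceSet, site_policy: SitePolicy = "complete_deletion"
) -> HaplotypeTable:
    """Collapse identical sequences (over the used sites) into haplotypes.

    Under ``complete_deletion`` columns containing gaps or N anywhere in the
    sample are removed first and identity is exact string equality over the
    remainder. Under ``pairwise`` all columns are kept and two sequences are
    merged when they agree at every site where both are unambiguous; the
    match relation is not transitive, so each sequence joins the first
    existing haplotype it matches (insertion order = input order), which keeps
    the collapse deterministic.
    """
    if site_policy not in ("complete_deletion", "pairwise"):
        raise ValueError(f"unknown site_policy {site_policy!r}")
    if len(seqs) == 0:
        raise ValueError("cannot collapse an empty alignment")
    raw = [s for _, s in seqs.sequences]
    if site_policy == "complete_deletion":
        cols = _complete_deletion_columns(raw)
        used = ["".join(s[j] for j in cols) for s in raw]
        L = len(cols)
        groups: dict[str, int] = {}
        for u in used:
            groups[u] = groups.get(u, 0) + 1
        items = list(groups.items())
    else:
        L = seqs.length
        reps: list[str] = []
        counts: list[int] = []
        for s in raw:
            for k, rep in enumerate(reps):
                if _seqs_equal_pairwise(s, rep):
                    counts[k] += 1
                    break
            else:
                reps.append(s)
                counts.append(1)
        items = list(zip(reps, counts))
    # deterministic order: count descending, then lexicographic sequence
    items.sort(key=lambda kv: (-kv[1], kv[0]))
    haplotypes = [(f"H{i + 1}", seq, cnt) for i, (seq, cnt) in enumerate(items)]
    return HaplotypeTable(
        species=seqs.species, region=seqs.region, haplotypes=haplotypes,
        n=len(seqs), L=L, site_policy=site_policy,
    )


def haplotype_diversity(counts: list[int]) -> float:
    """Nei's unbiased haplotype diversity from a count spectrum.

    Requires n = sum(counts) >= 2. A monomorphic sample returns exactly 0.
    """
    if any(c <= 0 for c in counts):
        raise ValueError("counts must be positive")
    n = sum(counts)
    if n < 2:
        raise ValueError("haplotype diversity undefined for n < 2")
    hd = n / (n - 1) * (1.0 - sum((c / n) ** 2 for c in counts))
    return min(max(hd, 0.0), 1.0)  # guard float round-off at the extremes


def pairwise_differences(a: str, b: str, site_policy: SitePolicy = "complete_deletion"):
    """(differences, compared sites) between two aligned sequences.

    Positions count as differences only when both bases are unambiguous
    (A/C/G/T) and differ. Under complete_deletion the caller is expected to
    have pre-filtered columns, so every position is compared.
    """
    d = 0
    m = 0
    for x, y in zip(a, b):
        if x in _BASES and y in _BASES:
            m += 1
            if x != y:
                d += 1
    return d, m


def nucleotide_diversity(table: HaplotypeTable) -> float:
    """Per-site nucleotide diversity pi from a haplotype table.

    Averages the proportion of differing sites over all C(n,2) unordered
    sequence pairs, using haplotype counts (within-haplotype pairs contribute
    zero). Under the pairwise policy each pair is normalised by its own
    number of comparable sites.
    """
    n = table.n
    if n < 2:
        raise ValueError("nucleotide diversity undefined for n < 2")
    if table.L == 0:
        raise ValueError("no sites available after filtering")
    total = 0.0
    haps = table.haplotypes
    for i in range(len(haps)):
        for j in range(i + 1, len(haps)):
            d, m = pairwise_differences(haps[i][1], haps[j][1], table.site_policy)
            if table.site_policy == "complete_deletion":
                prop = d / table.L
            else:
                if m == 0:
                    continue
                prop = d / m
            total += haps[i][2] * haps[j][2] * prop
    return total / comb(n, 2)


def diversity_stats(table: HaplotypeTable) -> DiversityStats:
    """NH, Hd and pi for a haplotype table (monomorphic samples give 0/0)."""
    if table.NH == 1:
        return DiversityStats(NH=1, Hd=0.0, pi=0.0)
    return DiversityStats(
        NH=table.NH,
        Hd=haplotype_diversity(table.counts),
        pi=nucleotide_diversity(table),
    )
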