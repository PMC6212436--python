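"""Synthetic reference databases and introduction scenarios.

The generator emulates the structure donor inference assumes: a species with
well-differentiated regional lineages (a phylogeographic signal), sampled
into geo-referenced reference pools, and port populations founded by one or
more introduction events. Mutations follow an infinite-sites scheme - every
mutation hits a fresh alignment column - so Hamming distances are additive
and the expected diversities of a scenario follow in closed form from its
count spectrum.

Regions are labelled R1..Rk with centroids spaced around the equator so that
great-circle tie-breaking is well defined. All randomness flows through a
single seeded NumPy generator; a fixed seed reproduces byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from nistrace.io import AlignedSequenceSet, ReferenceRecord


@dataclass
class ScenarioConfig:
    """Parameters of one simulated world and introduction history.

    region_divergence is the expected number of substitutions BETWEEN two
    region-founder haplotypes (each founder draws Poisson(divergence/2)
    private mutations from the shared root); within_region_theta is the
    expected number of private mutations separating a reference haplotype
    from its regional founder; mutation_rate_en_route is the expected number
    of extra substitutions per introduced lineage under the stepping-stones
    scenario.
    """

    n_regions: int = 3
    refs_per_region: int = 5
    region_divergence: float = 20.0
    within_region_theta: float = 0.0
    introduction_events: list[tuple[str, int]] = field(
        default_factory=lambda: [("R1", 10), ("R2", 10)]
    )
    seq_length: int = 600
    mutation_rate_en_route: float = 1.0
    seed: int = 0
    species: str = "Synthetica exemplaris"

    def __post_init__(self) -> None:
        if self.n_regions < 1 or self.refs_per_region < 1:
            raise ValueError("counts must be >= 1")
        if self.seq_length < 100:
            raise ValueError("seq_length must be >= 100 (identity-overlap minimum)")
        for region, count in self.introduction_events:
            if count < 1:
                raise ValueError("propagule counts must be >= 1")

    @property
    def regions(self) -> list[str]:
        return [f"R{i + 1}" for i in range(self.n_regions)]

    def region_centroid(self, region: str) -> tuple[float, float]:
        i = self.regions.index(region)
        return (0.0, -180.0 + 360.0 * i / self.n_regions)


# Recipient port centroid used for tie-breaking (southern Bay of Biscay).
RECIPIENT_CENTROID = (43.5, -5.7)

_ALTS = {"A": "CGT", "C": "AGT", "G": "ACT", "T": "ACG"}


class _SiteAllocator:
    """Hands out fresh alignment columns (infinite-sites bookkeeping)."""

    def __init__(self, length: int):
        self.length = length
        self.next = 0

    def take(self, k: int) -> list[int]:
        if self.next + k > self.length:
            raise ValueError(
                "sequence length exhausted: increase seq_length or lower rates"
            )
        sites = list(range(self.next, self.next + k))
        self.next += k
        return sites


def _mutate(seq: str, k: int, alloc: _SiteAllocator, rng: np.random.Generator) -> str:
    chars = list(seq)
    for j in alloc.take(k):
        chars[j] = _ALTS[chars[j]][rng.integers(0, 3)]
    return "".join(chars)


def _build_world(cfg: ScenarioConfig):
    """(references, haplotype pools per region, site allocator, rng)."""
    rng = np.random.default_rng(cfg.seed)
    alloc = _SiteAllocator(cfg.seq_length)
    root = "A" * cfg.seq_length
    refs: list[ReferenceRecord] = []
    pools: dict[str, list[str]] = {}
    for region in cfg.regions:
        founder = _mutate(root, int(rng.poisson(cfg.region_divergence / 2.0)),
                          alloc, rng)
        pool = [founder]
        for _ in range(cfg.refs_per_region - 1):
            pool.append(_mutate(founder, int(rng.poisson(cfg.within_region_theta)),
                                alloc, rng))
        pools[region] = pool
        for j, seq in enumerate(pool):
            refs.append(ReferenceRecord(
                ref_id=f"{region}_ref{j + 1}", species=cfg.species,
                sequence=seq, region=region,
                centroid=cfg.region_centroid(region), voucher=True,
            ))
    return refs, pools, alloc, rng


def simulate_reference_db(cfg: ScenarioConfig) -> list[ReferenceRecord]:
    """Simulate a geo-referenced voucher reference database.

    One founder haplotype per region (independent mutations from a common
    root) plus ``refs_per_region - 1`` within-region variants at
    ``within_region_theta``. Deterministic under ``cfg.seed``.
    """
    refs, _, _, _ = _build_world(cfg)
    return refs


SCENARIOS = ("single", "multiple", "stepping_stones")


def simulate_introduction(
    cfg: ScenarioConfig, scenario: str = "multiple"
) -> tuple[AlignedSequenceSet, dict]:
    """Simulate a port sample under an introduction scenario.

    single
        all propagules drawn from the first event's donor pool (low expected
        Hd when the donor pool is shallow);
    multiple
        propagules drawn from every listed (donor, count) event (high Hd and
        high pi when donors are well diverged);
    stepping_stones
        propagules from the first donor with per-lineage en-route mutation
        (at least one lineage is guaranteed to carry a novel mutation when
        ``mutation_rate_en_route > 0``), emulating bottlenecked stops at
        intermediate ports.

    Returns the sampled alignment plus a truth record with the donor
    region(s), the event count and each sample's true donor.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; pick from {SCENARIOS}")
    refs, pools, alloc, rng = _build_world(cfg)
    for region, _ in cfg.introduction_events:
        if region not in pools:
            raise ValueError(f"donor region {region!r} not in the simulated world")
    events = (cfg.introduction_events if scenario == "multiple"
              else cfg.introduction_events[:1])
    sequences: list[tuple[str, str]] = []
    true_regions: list[str] = []
    for region, count in events:
        pool = pools[region]
        for _ in range(count):
            seq = pool[rng.integers(0, len(pool))]
            sequences.append((f"s{len(sequences) + 1}", seq))
            true_regions.append(region)
    if scenario == "stepping_stones" and cfg.mutation_rate_en_route > 0:
        mutated_any = False
        stepped: list[tuple[str, str]] = []
        for sid, seq in sequences:
            k = int(rng.poisson(cfg.mutation_rate_en_route))
            if k > 0:
                seq = _mutate(seq, k, alloc, rng)
                mutated_any = True
            stepped.append((sid, seq))
        if not mutated_any:  # construction guarantees >= 1 novel haplotype
            sid, seq = stepped[0]
            stepped[0] = (sid, _mutate(seq, 1, alloc, rng))
        sequences = stepped
    sample = AlignedSequenceSet(
        species=cfg.species, region="PORT", sequences=sequences, marker="COI"
    )
    truth = {
        "scenario": scenario,
        "donor_regions": sorted({r for r, _ in events}),
        "n_events": len(events),
        "per_sample_region": true_regions,
        "seed": cfg.seed,
    }
    return sample, truth
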