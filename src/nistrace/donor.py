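"""Donor-region inference: best-match assignment, IS weighting, history calls.

A query haplotype is assigned to the donor region of its best-matching
geo-referenced reference sequence when the pairwise identity over the
comparable overlap is at least 99%. When several references from different
regions tie at the maximum identity, the conservative rule assigns the region
whose centre is great-circle-closest to the recipient region.

Because reference coverage and phylogeographic signal vary wildly between
species, each species' geographic inference carries an inference-strength
coefficient IS in {0, 0.01, 0.1, 0.3, 0.5, 1}: 0 for species with known
absence of phylogeographic pattern, up to 1 for a strong phylogeographic
signature with at least medium database coverage. Contributions of donor
regions are reported both raw and IS-weighted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import asin, cos, radians, sin, sqrt

from nistrace.io import ReferenceRecord

EARTH_RADIUS_KM = 6371.0

PHYLOGEO_LEVELS = ("absent", "unknown", "shallow", "moderate", "strong")
COVERAGE_LEVELS = ("minimal", "moderate", "medium", "good")

# The six anchor cases of the IS rubric: (signal, coverage) -> IS.
IS_ANCHORS: dict[tuple[str, str], float] = {
    ("absent", "minimal"): 0.0,
    ("absent", "moderate"): 0.0,
    ("absent", "medium"): 0.0,
    ("absent", "good"): 0.0,
    ("unknown", "minimal"): 0.01,
    ("shallow", "moderate"): 0.1,
    ("moderate", "medium"): 0.3,
    ("shallow", "good"): 0.5,
    ("strong", "medium"): 1.0,
    ("strong", "good"): 1.0,
}


@dataclass
class ISCoefficient:
    species: str
    phylogeo_signal: str
    coverage: str
    value: float

    def __post_init__(self) -> None:
        if self.value not in (0, 0.01, 0.1, 0.3, 0.5, 1):
            raise ValueError(f"IS value {self.value} not on the rubric scale")


@dataclass
class DonorAssignment:
    """Best-match result for one query haplotype.

    ``assigned_region`` is "unassigned" when no reference reaches the
    identity threshold; ``tie_broken`` is set only when references from more
    than one region tied at the maximum identity.
    """

    hap_id: str
    best_refs: list[ReferenceRecord]
    identity: float
    assigned_region: str
    tie_broken: bool = False
    count: int = 1  # individuals carrying this haplotype (basis="individuals")


@dataclass
class DonorContribution:
    region: str
    lineages_raw: float
    lineages_weighted: float
    hap_variation_weighted: float
    pct_of_total: float


@dataclass
class IntroductionHistoryCall:
    species: str
    call: str  # multiple_introductions | in_situ_or_expansion | few_distinct_lineages | uninformative
    hd_threshold: float
    pi_threshold: float


def is_rubric(
    phylogeo_signal: str,
    coverage: str,
    species: str = "",
    anchors: dict[tuple[str, str], float] | None = None,
) -> ISCoefficient:
    """Map (phylogeographic signal, coverage) to an IS coefficient.

    Combinations not in the anchor list resolve to the nearest lower listed
    value: the maximum IS over anchors dominated by the requested combination
    (both signal and coverage at or below it), defaulting to 0. The anchor
    table can be overridden.
    """
    if phylogeo_signal not in PHYLOGEO_LEVELS:
        raise ValueError(f"unknown phylogeographic signal {phylogeo_signal!r}")
    if coverage not in COVERAGE_LEVELS:
        raise ValueError(f"unknown coverage class {coverage!r}")
    table = IS_ANCHORS if anchors is None else anchors
    if (phylogeo_signal, coverage) in table:
        value = table[(phylogeo_signal, coverage)]
    else:
        s = PHYLOGEO_LEVELS.index(phylogeo_signal)
        c = COVERAGE_LEVELS.index(coverage)
        dominated = [
            v for (sig, cov), v in table.items()
            if PHYLOGEO_LEVELS.index(sig) <= s and COVERAGE_LEVELS.index(cov) <= c
        ]
        value = max(dominated, default=0.0)
    return ISCoefficient(species=species, phylogeo_signal=phylogeo_signal,
                         coverage=coverage, value=value)


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance in km between (lat, lon) points."""
    lat1, lon1 = map(radians, a)
    lat2, lon2 = map(radians, b)
    h = sin((lat2 - lat1) / 2) ** 2 + cos(lat1) * cos(lat2) * sin((lon2 - lon1) / 2) ** 2
    return 2 * EARTH_RADIUS_KM * asin(min(1.0, sqrt(h)))


_BASES = set("ACGT")


def pairwise_identity(query: str, ref: str) -> tuple[float, int]:
    """(identity, overlap) over sites where both sequences are unambiguous."""
    match = 0
    overlap = 0
    for x, y in zip(query, ref):
        if x in _BASES and y in _BASES:
            overlap += 1
            if x == y:
                match += 1
    return (match / overlap if overlap else 0.0), overlap


class IncomparableSequencesError(ValueError):
    """Raised when the comparable overlap is shorter than the minimum."""


def best_match(
    query: str,
    refs: list[ReferenceRecord],
    recipient_centroid: tuple[float, float],
    hap_id: str = "query",
    min_identity: float = 0.99,
    min_overlap: int = 100,
    include_nonvoucher: bool = False,
    count: int = 1,
) -> DonorAssignment:
    """Assign a query haplotype to the donor region of its best match.

    Identity is the per-site match fraction over the pairwise-complete
    overlap (both bases A/C/G/T); an overlap below ``min_overlap`` sites with
    every reference raises :class:`IncomparableSequencesError`. Assignment
    requires identity >= ``min_identity`` (inclusive). Equal-identity
    references from different regions are tie-broken towards the region whose
    centroid is great-circle-closest to the recipient.
    """
    if not refs:
        raise ValueError("reference list is empty")
    usable = [r for r in refs if r.voucher or include_nonvoucher]
    if not usable:
        raise ValueError("no voucher-backed references available")
    scored = []
    any_comparable = False
    for ref in usable:
        ident, overlap = pairwise_identity(query, ref.sequence)
        if overlap >= min_overlap:
            any_comparable = True
            scored.append((ident, ref))
    if not any_comparable:
        raise IncomparableSequencesError(
            f"no reference shares >= {min_overlap} comparable sites with the query"
        )
    best_ident = max(ident for ident, _ in scored)
    best_refs = [ref for ident, ref in scored if ident == best_ident]
    if best_ident < min_identity:
        return DonorAssignment(hap_id=hap_id, best_refs=best_refs,
                               identity=best_ident, assigned_region="unassigned",
                               tie_broken=False, count=count)
    regions = {r.region for r in best_refs}
    if len(regions) > 1:
        closest = min(
            best_refs,
            key=lambda r: (great_circle_km(r.centroid, recipient_centroid), r.region),
        )
        return DonorAssignment(hap_id=hap_id, best_refs=best_refs,
                               identity=best_ident,
                               assigned_region=closest.region,
                               tie_broken=True, count=count)
    return DonorAssignment(hap_id=hap_id, best_refs=best_refs,
                           identity=best_ident,
                           assigned_region=next(iter(regions)),
                           tie_broken=len(best_refs) > 1, count=count)


class MissingISError(KeyError):
    """Raised when an assigned species has no IS coefficient."""


def weighted_contributions(
    assignments_by_species: dict[str, list[DonorAssignment]],
    is_map: dict[str, ISCoefficient | float],
    basis: str = "haplotypes",
) -> list[DonorContribution]:
    """Per-donor-region contributions, raw and IS-weighted.

    For each region, the weighted lineage count sums over species the number
    of that species' haplotypes (``basis="haplotypes"``, the applied
    convention) or individuals (``basis="individuals"``) assigned to the
    region, multiplied by the species' IS. Species with IS = 0 are excluded
    from the weighted sums; unassigned haplotypes are excluded from the
    normalisation. ``pct_of_total`` normalises the weighted contributions to
    100 over regions (empty when every weighted contribution is zero).
    """
    if basis not in ("haplotypes", "individuals"):
        raise ValueError(f"unknown basis {basis!r}")
    missing = [
        sp for sp, asgs in assignments_by_species.items()
        if sp not in is_map and any(a.assigned_region != "unassigned" for a in asgs)
    ]
    if missing:
        raise MissingISError(f"species missing IS coefficients: {sorted(missing)}")
    raw: dict[str, float] = {}
    weighted: dict[str, float] = {}
    hapvar: dict[str, float] = {}
    for sp, asgs in assignments_by_species.items():
        is_val = is_map.get(sp, 0.0)
        if isinstance(is_val, ISCoefficient):
            is_val = is_val.value
        for a in asgs:
            if a.assigned_region == "unassigned":
                continue
            unit = float(a.count) if basis == "individuals" else 1.0
            raw[a.assigned_region] = raw.get(a.assigned_region, 0.0) + unit
            if is_val > 0:
                weighted[a.assigned_region] = (
                    weighted.get(a.assigned_region, 0.0) + unit * is_val
                )
                hapvar[a.assigned_region] = hapvar.get(a.assigned_region, 0.0) + 1 * is_val
    total_w = sum(weighted.values())
    out = []
    for region in sorted(raw):
        w = weighted.get(region, 0.0)
        out.append(DonorContribution(
            region=region,
            lineages_raw=raw[region],
            lineages_weighted=w,
            hap_variation_weighted=hapvar.get(region, 0.0),
            pct_of_total=(100.0 * w / total_w) if total_w > 0 else float("nan"),
        ))
    return out


def classify_history(
    Hd: float,
    pi: float,
    species: str = "",
    hd_threshold: float = 0.8,
    pi_threshold: float = 0.02,
) -> IntroductionHistoryCall:
    """Joint Hd/pi interpretation of a NIS sample's introduction history.

    High Hd with high pi suggests multiple introductions from genetically
    different donor populations; high Hd with low pi suggests in-situ
    mutation or an expansive donor population; low Hd with high pi suggests a
    few introductions of very distinct lineages; low/low is uninformative.
    """
    if not (0.0 <= Hd <= 1.0) or pi < 0:
        raise ValueError("Hd must lie in [0,1] and pi must be >= 0")
    high_hd = Hd >= hd_threshold
    high_pi = pi >= pi_threshold
    if high_hd and high_pi:
        call = "multiple_introductions"
    elif high_hd:
        call = "in_situ_or_expansion"
    elif high_pi:
        call = "few_distinct_lineages"
    else:
        call = "uninformative"
    return IntroductionHistoryCall(species=species, call=call,
                                   hd_threshold=hd_threshold,
                                   pi_threshold=pi_threshold)
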