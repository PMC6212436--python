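"""Best-match donor assignment, the IS rubric, weighting and history calls."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nistrace.donor import (
    DonorAssignment,
    IncomparableSequencesError,
    MissingISError,
    best_match,
    classify_history,
    great_circle_km,
    is_rubric,
    weighted_contributions,
)
from nistrace.io import ReferenceRecord


def ref(ref_id, seq, region, centroid, voucher=True):
    return ReferenceRecord(ref_id=ref_id, species="Sp", sequence=seq,
                           region=region, centroid=centroid, voucher=voucher)


BISCAY = (43.5, -5.7)
JAPAN = (36.0, 138.0)
PORTUGAL = (39.5, -9.0)
AUSTRALIA = (-25.0, 135.0)


class TestISRubric:
    @pytest.mark.parametrize("signal,coverage,value", [
        ("absent", "good", 0.0),
        ("absent", "minimal", 0.0),
        ("unknown", "minimal", 0.01),
        ("shallow", "moderate", 0.1),
        ("moderate", "medium", 0.3),
        ("shallow", "good", 0.5),
        ("strong", "medium", 1.0),
        ("strong", "good", 1.0),
    ])
    def test_anchor_cases(self, signal, coverage, value):
        assert is_rubric(signal, coverage).value == value

    @pytest.mark.parametrize("signal,coverage,value", [
        ("strong", "minimal", 0.01),   # nearest lower listed value
        ("moderate", "good", 0.5),
        ("unknown", "good", 0.01),
        ("shallow", "minimal", 0.01),
    ])
    def test_gaps_resolve_downward(self, signal, coverage, value):
        assert is_rubric(signal, coverage).value == value

    def test_invalid_enum_rejected(self):
        with pytest.raises(ValueError):
            is_rubric("weak", "good")


class TestGreatCircle:
    def test_equator_quarter_turn(self):
        d = great_circle_km((0, 0), (0, 90))
        assert d == pytest.approx(math.pi / 2 * 6371, rel=1e-9)

    def test_symmetric_and_zero_on_self(self):
        assert great_circle_km(JAPAN, PORTUGAL) == pytest.approx(
            great_circle_km(PORTUGAL, JAPAN))
        assert great_circle_km(JAPAN, JAPAN) == 0.0


class TestBestMatch:
    Q = "ACGT" * 50  # 200 sites

    def test_single_exact_match(self):
        refs = [ref("r1", self.Q, "Australia", AUSTRALIA)]
        a = best_match(self.Q, refs, BISCAY)
        assert a.assigned_region == "Australia"
        assert a.identity == 1.0 and a.tie_broken is False

    def test_geographic_tie_break_prefers_closer_region(self):
        refs = [ref("jp", self.Q, "Japan", JAPAN),
                ref("pt", self.Q, "Portugal", PORTUGAL)]
        a = best_match(self.Q, refs, BISCAY)
        assert a.assigned_region == "Portugal" and a.tie_broken is True

    def test_below_identity_threshold_unassigned(self):
        far = "TGCA" * 50  # 0% identity
        mid = self.Q[:180] + "TGCATGCATGCATGCATGCA"  # 90% identity
        refs = [ref("a", far, "Japan", JAPAN), ref("b", mid, "Portugal", PORTUGAL)]
        a = best_match(self.Q, refs, BISCAY)
        assert a.assigned_region == "unassigned"
        assert a.identity == pytest.approx(0.9)

    def test_threshold_inclusive_at_99_percent(self):
        near = "T" + self.Q[1:] + ""  # 199/200 = 0.995
        refs = [ref("a", near, "Japan", JAPAN)]
        assert best_match(self.Q, refs, BISCAY).assigned_region == "Japan"

    def test_short_overlap_incomparable(self):
        refs = [ref("a", "N" * 150 + self.Q[150:], "Japan", JAPAN)]
        with pytest.raises(IncomparableSequencesError):
            best_match(self.Q, refs, BISCAY)

    def test_nonvoucher_excluded_by_default(self):
        refs = [ref("nv", self.Q, "Japan", JAPAN, voucher=False),
                ref("v", "T" + self.Q[1:], "Portugal", PORTUGAL)]
        a = best_match(self.Q, refs, BISCAY)
        assert a.assigned_region == "Portugal"
        a2 = best_match(self.Q, refs, BISCAY, include_nonvoucher=True)
        assert a2.assigned_region == "Japan"

    @given(st.lists(st.tuples(st.floats(-60, 60), st.floats(-179, 179)),
                    min_size=2, max_size=5, unique=True))
    @settings(max_examples=50, deadline=None)
    def test_tie_break_matches_brute_force_argmin(self, centroids):
        refs = [ref(f"r{i}", self.Q, f"Reg{i}", c) for i, c in enumerate(centroids)]
        a = best_match(self.Q, refs, BISCAY)
        dists = {r.region: great_circle_km(r.centroid, BISCAY) for r in refs}
        assert dists[a.assigned_region] == min(dists.values())


class TestWeightedContributions:
    def _magallana(self):
        asgs = ([DonorAssignment(f"h{i}", [], 1.0, "Atlantic Arc") for i in range(13)]
                + [DonorAssignment(f"h{i}", [], 1.0, "NW Pacific") for i in range(13, 20)]
                + [DonorAssignment("h20", [], 1.0, "California")])
        return {"Magallana gigas": asgs}

    def test_magallana_worked_example(self):
        out = weighted_contributions(self._magallana(), {"Magallana gigas": 0.5})
        w = {c.region: c.lineages_weighted for c in out}
        assert w == {"Atlantic Arc": 6.5, "NW Pacific": 3.5, "California": 0.5}

    def test_pct_sums_to_100(self):
        out = weighted_contributions(self._magallana(), {"Magallana gigas": 0.5})
        assert sum(c.pct_of_total for c in out) == pytest.approx(100.0, abs=1e-9)

    def test_single_region_is_100pct(self):
        asgs = {"Sp": [DonorAssignment("h1", [], 1.0, "Japan")]}
        out = weighted_contributions(asgs, {"Sp": 1.0})
        assert out[0].pct_of_total == 100.0

    def test_zero_is_species_flagged_empty(self):
        asgs = {"Sp": [DonorAssignment("h1", [], 1.0, "Japan")]}
        out = weighted_contributions(asgs, {"Sp": 0.0})
        assert out[0].lineages_weighted == 0.0
        assert math.isnan(out[0].pct_of_total)

    def test_missing_is_lists_species(self):
        with pytest.raises(MissingISError, match="Magallana"):
            weighted_contributions(self._magallana(), {})

    def test_unassigned_excluded_from_normalisation(self):
        asgs = {"Sp": [DonorAssignment("h1", [], 1.0, "Japan"),
                       DonorAssignment("h2", [], 0.9, "unassigned")]}
        out = weighted_contributions(asgs, {"Sp": 1.0})
        assert [c.region for c in out] == ["Japan"]
        assert out[0].pct_of_total == 100.0

    def test_individuals_basis_uses_counts(self):
        asgs = {"Sp": [DonorAssignment("h1", [], 1.0, "Japan", count=5),
                       DonorAssignment("h2", [], 1.0, "Chile", count=15)]}
        out = weighted_contributions(asgs, {"Sp": 1.0}, basis="individuals")
        w = {c.region: c.lineages_weighted for c in out}
        assert w == {"Japan": 5.0, "Chile": 15.0}

    @given(st.floats(0.01, 1.0))
    @settings(max_examples=20, deadline=None)
    def test_rank_order_invariant_to_uniform_is(self, is_value):
        """With/without-IS robustness: a uniform IS rescales but never reranks."""
        asgs = {"A": [DonorAssignment(f"a{i}", [], 1.0, "R1") for i in range(3)],
                "B": [DonorAssignment(f"b{i}", [], 1.0, "R2") for i in range(2)],
                "C": [DonorAssignment("c0", [], 1.0, "R3")]}
        uniform = {sp: is_value for sp in asgs}
        raw = {sp: 1.0 for sp in asgs}
        out_u = weighted_contributions(asgs, uniform)
        out_r = weighted_contributions(asgs, raw)
        rank_u = sorted(out_u, key=lambda c: -c.lineages_weighted)
        rank_r = sorted(out_r, key=lambda c: -c.lineages_weighted)
        assert [c.region for c in rank_u] == [c.region for c in rank_r]
        for cu, cr in zip(sorted(out_u, key=lambda c: c.region),
                          sorted(out_r, key=lambda c: c.region)):
            assert cu.pct_of_total == pytest.approx(cr.pct_of_total)

    def test_k_to_m_parameter_recovery(self):
        asgs = {"Sp": ([DonorAssignment(f"a{i}", [], 1.0, "A") for i in range(6)]
                       + [DonorAssignment(f"b{i}", [], 1.0, "B") for i in range(2)])}
        out = weighted_contributions(asgs, {"Sp": 1.0})
        w = {c.region: c.lineages_weighted for c in out}
        assert w["A"] / w["B"] == pytest.approx(3.0)


class TestClassifyHistory:
    @pytest.mark.parametrize("hd,pi,call", [
        (0.987, 0.054, "multiple_introductions"),  # Xenostrobus-like values
        (0.0, 0.0, "uninformative"),
        (0.1, 0.04, "few_distinct_lineages"),
        (0.9, 0.001, "in_situ_or_expansion"),
    ])
    def test_rule_quadrants(self, hd, pi, call):
        assert classify_history(hd, pi).call == call

    def test_pure_function_of_thresholds(self):
        assert classify_history(0.5, 0.01, hd_threshold=0.4,
                                pi_threshold=0.005).call == "multiple_introductions"

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            classify_history(1.2, 0.0)
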