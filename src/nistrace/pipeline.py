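"""End-to-end drivers: the occurrence-table analysis and the synthetic
validation of donor inference.

``run_paper_analysis`` reproduces the statistical layer of the port survey
from the packaged occurrence table: headline percentages, the in-text
correlations, native-ocean-region grouping with tie-corrected Kruskal-Wallis
comparisons, and the Gaussian log-link GLMs for NIS abundance (dependent
variable a) and haplotype diversity (dependent variable b). The GLMs for
inferred-lineage tables (dependent variables c and d) run only when the user
supplies such a table, since those inputs come from donor inference over a
reference database.

``run_synthetic_validation`` closes the loop on simulated data: simulate a
world and introduction histories, re-infer donor regions, and score recovery
and the Hd/pi introduction-history calls against the generator's truth
records.
"""

from __future__ import annotations

from dataclasses import asdict, replace

import numpy as np
import pandas as pd

from nistrace.donor import best_match, classify_history
from nistrace.hapstats import collapse_haplotypes, diversity_stats
from nistrace.io import NISRecord, load_table1_fixture
from nistrace.stats import correlation, glm_normal_log, kruskal_wallis
from nistrace.summary import (
    antipode_fraction,
    group_by_native_region,
    nis_percentages,
)
from nistrace.synthetic import (
    RECIPIENT_CENTROID,
    ScenarioConfig,
    simulate_introduction,
    simulate_reference_db,
)


def _records_df(records: list[NISRecord]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in records])


def _safe_corr(df: pd.DataFrame, xcol: str, ycol: str, method="pearson"):
    sub = df[[xcol, ycol]].dropna()
    if len(sub) < 3:
        return None
    res = correlation(sub[xcol], sub[ycol], method=method)
    return {"r": res.r, "p": res.p, "df": res.df, "n": len(sub), "method": method}


def _safe_glm(df: pd.DataFrame, ycol: str, xcol: str):
    sub = df[[ycol, xcol]].dropna()
    if len(sub) < 4:
        return None
    try:
        res = glm_normal_log(sub[ycol].to_numpy(), sub[xcol].to_numpy())
    except Exception as exc:
        return {"error": str(exc), "n": len(sub)}
    return {"slope": res.slope, "se_slope": res.se_slope,
            "intercept": res.intercept, "se_intercept": res.se_intercept,
            "phi": res.phi, "G": res.G, "p_slope": res.p_slope,
            "p_slope_chi2": res.p_slope_chi2, "dw": res.dw, "bp_p": res.bp_p,
            "n": res.n}


def run_paper_analysis(
    records: list[NISRecord] | None = None,
    donor_table: pd.DataFrame | None = None,
) -> dict:
    """Run the occurrence-table analysis; defaults to the packaged fixture.

    Returns a nested dict with the headline percentages, correlations
    (computed on complete cases; the %NIS-vs-richness correlation is reported
    both over all rows and over species-deduplicated rows, since the exact
    subset behind the published value is not recoverable), the regional
    grouping with Kruskal-Wallis statistics, and the per-variable GLMs. When
    ``donor_table`` (columns: region, lineages_with_is, lineages_without_is,
    pct_haplotypes, distance, cargo_pct, lat_crosses) is supplied, the
    inferred-lineage GLMs (dependent variables c and d) are fitted too.
    """
    if records is None:
        records = load_table1_fixture()
    report: dict = {"n_records": len(records)}
    if not records:
        report.update({"percentages": None, "correlations": None,
                       "groups": None, "glms": None})
        return report
    df = _records_df(records)

    pct = nis_percentages(records)
    anti_all, anti_nis = antipode_fraction(records)
    report["percentages"] = {
        "regional_nis_n": pct["regional_nis_n"],
        "overall_by_species": pct["overall"],
        "antipode_pct_of_all": anti_all,
        "antipode_pct_of_nis": anti_nis,
    }

    noncrypt = df[df["native_range"] != "Cryptogenic"]
    dedup = (df.groupby("species", as_index=False)
               .agg({"pct": "mean", "natives": "mean", "Hd": "mean",
                     "pi": "mean", "distance": "mean", "native_range": "first"}))
    nc_dedup = dedup[dedup["native_range"] != "Cryptogenic"]
    report["correlations"] = {
        "pct_vs_distance_noncryptogenic": _safe_corr(noncrypt, "pct", "distance"),
        "pct_vs_cargo_noncryptogenic": _safe_corr(noncrypt, "pct", "cargo_pct"),
        "pct_vs_natives_all_rows": _safe_corr(df, "pct", "natives"),
        "pct_vs_natives_dedup_species": _safe_corr(dedup, "pct", "natives"),
        "hd_vs_distance_dedup_species": _safe_corr(nc_dedup, "Hd", "distance"),
        "hd_vs_pi_polymorphic": _safe_corr(
            df[df["NH"] > 1], "Hd", "pi", method="spearman"),
    }

    groups = group_by_native_region(records)
    kw = {}
    for var in ("pct", "NH", "Hd", "pi"):
        vals = [[getattr(m, var) for m in g.members] for g in groups]
        if len(vals) >= 2:
            res = kruskal_wallis(vals)
            kw[var] = {"H": res.H, "Hc": res.Hc, "p": res.p, "k": res.k}
    report["groups"] = {
        "labels": [g.label for g in groups],
        "summary": [{
            "label": g.label, "n_members": len(g.members),
            "mean_pct": g.mean_pct, "sd_pct": g.sd_pct,
            "sum_pct_by_region": g.sum_pct_by_region,
            "mean_NH": g.mean_NH, "mean_Hd": g.mean_Hd, "mean_pi": g.mean_pi,
        } for g in groups],
        "kruskal_wallis": kw,
    }

    glms: dict = {"dependent_a_pct": {}, "dependent_b_Hd": {}}
    for xcol in ("distance", "cargo_pct", "natives"):
        glms["dependent_a_pct"][xcol] = _safe_glm(noncrypt, "pct", xcol)
    for xcol in ("distance", "cargo_pct", "pct", "natives"):
        glms["dependent_b_Hd"][xcol] = _safe_glm(noncrypt, "Hd", xcol)
    if donor_table is not None:
        glms["dependent_c_lineages"] = {}
        glms["dependent_d_pct_haplotypes"] = {}
        for ycol, slot in (("lineages_with_is", "with_is"),
                           ("lineages_without_is", "without_is")):
            glms["dependent_c_lineages"][slot] = {
                xcol: _safe_glm(donor_table, ycol, xcol)
                for xcol in ("distance", "cargo_pct", "lat_crosses")
                if xcol in donor_table.columns
            }
        glms["dependent_d_pct_haplotypes"] = {
            xcol: _safe_glm(donor_table, "pct_haplotypes", xcol)
            for xcol in ("distance", "cargo_pct", "lat_crosses")
            if xcol in donor_table.columns
        }
    report["glms"] = glms
    return report


# Study conditions for the synthetic validation: a species with a strong
# phylogeographic signature (founders ~20 substitutions apart over 600 sites),
# ten voucher references per region with moderate within-region diversity,
# and port samples of 20 propagules.
DEFAULT_VALIDATION_CONFIG = ScenarioConfig(
    n_regions=3,
    refs_per_region=10,
    region_divergence=20.0,
    within_region_theta=3.0,
    introduction_events=[("R1", 7), ("R2", 7), ("R3", 6)],
    seq_length=600,
    mutation_rate_en_route=1.0,
    seed=0,
)


def run_synthetic_validation(
    cfg: ScenarioConfig | None = None,
    n_replicates: int = 200,
    base_seed: int = 0,
    recovery_threshold: float = 0.95,
) -> dict:
    """Simulate -> infer -> score donor recovery and history calls.

    Per replicate: a fresh world is simulated, a multiple-introduction port
    sample is drawn and every sampled individual is re-assigned by best match
    against the world's voucher references; recovery is the fraction of
    individuals assigned to their true donor region. Introduction-history
    calls are scored on both multiple- and single-scenario replicates.
    """
    cfg = DEFAULT_VALIDATION_CONFIG if cfg is None else cfg
    recoveries = []
    calls = {"multiple": [], "single": []}
    for i in range(n_replicates):
        c = replace(cfg, seed=base_seed + i)
        refs = simulate_reference_db(c)
        sample, truth = simulate_introduction(c, "multiple")
        # assign each distinct sampled sequence once, then score individuals
        assignment_of: dict[str, str] = {}
        for seq in {s for _, s in sample.sequences}:
            asg = best_match(seq, refs, RECIPIENT_CENTROID)
            assignment_of[seq] = asg.assigned_region
        hits = sum(
            assignment_of[seq] == true_region
            for (_, seq), true_region in zip(sample.sequences,
                                             truth["per_sample_region"])
        )
        recoveries.append(hits / len(sample))
        for scenario in ("multiple", "single"):
            samp, _ = simulate_introduction(c, scenario)
            stats = diversity_stats(collapse_haplotypes(samp))
            call = classify_history(stats.Hd, stats.pi, species=c.species)
            calls[scenario].append(call.call)
    recovery = float(np.mean(recoveries))
    multi_rate = float(np.mean(
        [c == "multiple_introductions" for c in calls["multiple"]]))
    single_rate = float(np.mean(
        [c == "multiple_introductions" for c in calls["single"]]))
    return {
        "n_replicates": n_replicates,
        "recovery": recovery,
        "recovery_threshold": recovery_threshold,
        "recovery_ok": recovery >= recovery_threshold,
        "multiple_call_rate_in_multiple": multi_rate,
        "multiple_call_rate_in_single": single_rate,
        "history_calls_ok": multi_rate >= 0.90 and single_rate <= 0.10,
        "config": asdict(cfg),
        "base_seed": base_seed,
    }
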