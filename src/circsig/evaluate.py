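"""Planted-truth recovery metrics on simulated cohorts.

These functions run the full analysis stack on a simulated cohort and score
it against the generator's truth tables: TSI recovery of planted
tissue-specific circRNAs, sign-correct recovery of planted tumor effects,
null calibration of the differential-expression test, correlation strength
of coupled circRNAs with their drivers, and host-vs-RBP attribution
accuracy.  Both the test suite and the reproduction script consume them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .attribution import (
    attribute_dysregulated_circ,
    attribute_specific_circ,
    pearson_profile,
)
from .diffexpr import (
    _design,
    _nb_irls,
    de_per_cancer,
    de_test,
    estimate_dispersion,
    global_abundance_test,
    size_factors,
)
from .io_formats import PipelineConfig
from .quantify import rpm_matrix
from .specificity import categorize, filter_abundant, median_by_tissue, tsi_table
from .synthetic_data import Cohort, SimConfig, simulate_cohort


def tsi_recovery(cohort: Cohort, config: PipelineConfig | None = None) -> dict:
    """Fraction of planted single-tissue circRNAs recovered as tissue-specific.

    Recovery requires TSI >= the tissue-specific threshold AND the argmax
    tissue to equal the planted tissue.
    """
    config = config or PipelineConfig()
    rpm = rpm_matrix(cohort.junctions)
    profiles = filter_abundant(
        median_by_tissue(rpm), config.circ_abundance_median_rpm
    )
    table = categorize(tsi_table(profiles), config)
    planted = cohort.truth.circ.query("sim_class == 'tissue_specific'")
    scored = table.reindex(planted.index)
    hit = (scored["tsi"] >= config.tsi_specific_min) & (
        scored["argmax_tissue"] == planted["target_tissue"]
    )
    return {"rate": float(hit.fillna(False).mean()), "n": int(len(planted))}


def de_sign_recovery(
    cohort: Cohort, config: PipelineConfig | None = None
) -> tuple[dict, dict[str, pd.DataFrame]]:
    """Sign-correct call rate over planted tumor effects; returns DE tables too."""
    config = config or PipelineConfig()
    tables = de_per_cancer(cohort.junctions, config=config)
    combined = pd.concat(tables.values(), ignore_index=True)
    planted = cohort.truth.circ_de
    merged = combined.merge(
        planted, left_on=["feature_id", "cancer"], right_on=["circ_id", "cancer"],
        how="right",
    )
    correct = ((merged["direction"] == "up") & (merged["log2_effect"] > 0)) | (
        (merged["direction"] == "down") & (merged["log2_effect"] < 0)
    )
    return (
        {
            "rate": float(correct.mean()),
            "n": int(len(merged)),
            "median_abs_log2fc": float(merged["log2fc"].abs().median()),
        },
        tables,
    )


def de_null_type1(
    seed: int,
    n_reps: int = 8,
    n_genes: int = 400,
    patients: int = 10,
    alpha: float = 0.05,
) -> dict:
    """Empirical type-I error of the NB Wald test under the null.

    Simulates cohorts with no planted effects and no global tumor shift and
    reports the fraction of raw p-values below ``alpha``.
    """
    null = dict(
        frac_tissue_specific_circ=0.0,
        frac_ubiquitous_circ=0.0,
        frac_host_coupled=0.0,
        frac_rbp_coupled=0.0,
        de_frac_per_cancer=0.0,
        n_shared_consistent=0,
        n_shared_inconsistent=0,
        global_tumor_downscale=1.0,
        n_tissues=1,
        patients_per_tissue=patients,
        n_genes=n_genes,
    )
    hits, total = 0, 0
    per_rep = []
    for rep in range(n_reps):
        cohort = simulate_cohort(SimConfig(rng_seed=seed + rep, **null))
        res = de_test(
            cohort.junctions.back_spliced,
            cohort.junctions.circ_ids,
            cohort.samples,
        )
        p = res["p_value"].dropna()
        hits += int((p < alpha).sum())
        total += len(p)
        per_rep.append(float((p < alpha).mean()))
    return {
        "rate": hits / total,
        "n": total,
        "per_rep": per_rep,
        "n_reps": n_reps,
    }


def _specific_attribution(cohort: Cohort, config: PipelineConfig):
    rpm = rpm_matrix(cohort.junctions)
    circ_prof = filter_abundant(
        median_by_tissue(rpm), config.circ_abundance_median_rpm
    )
    gene_prof_all = median_by_tissue(cohort.gene_fpkm)
    gene_prof = filter_abundant(gene_prof_all, config.gene_abundance_median_fpkm)
    circ_tsi = categorize(tsi_table(circ_prof), config)
    gene_tsi = categorize(tsi_table(gene_prof), config)
    rbp_prof = gene_prof_all.loc[cohort.rbp_panel]
    rbp_tsi = categorize(tsi_table(rbp_prof), config)
    result = attribute_specific_circ(
        circ_tsi, circ_prof, gene_tsi, rbp_tsi, rbp_prof,
        cohort.host_gene_map, gene_profiles=gene_prof_all, config=config,
    )
    return result, circ_prof, gene_prof_all, rbp_prof


def coupled_profile_correlation(
    cohort: Cohort, config: PipelineConfig | None = None
) -> dict:
    """Fraction of coupled circRNAs reaching r >= corr_strong_min with their driver.

    Correlations run over per-tissue median profiles on normal samples, the
    same space the specificity attribution uses.
    """
    config = config or PipelineConfig()
    rpm = rpm_matrix(cohort.junctions)
    circ_prof = median_by_tissue(rpm)
    gene_prof = median_by_tissue(cohort.gene_fpkm)
    truth = cohort.truth.circ
    rs = []
    for circ_id, row in truth.iterrows():
        if row.sim_class == "host_coupled":
            driver = row.host_gene
        elif row.sim_class == "rbp_coupled":
            driver = row.coupled_rbp
        else:
            continue
        rs.append(
            pearson_profile(circ_prof.loc[circ_id], gene_prof.loc[driver])
        )
    rs = np.array(rs)
    return {
        "rate": float((rs >= config.corr_strong_min).mean()),
        "n": int(len(rs)),
        "median_r": float(np.median(rs)),
    }


def specific_attribution_accuracy(
    cohort: Cohort, config: PipelineConfig | None = None
) -> dict:
    """Driver-call accuracy for planted host-/RBP-coupled tissue-specific circRNAs.

    A host-coupled circRNA counts as correct when called host_gene (or both,
    when its tissue also hosts a specific RBP); an RBP-coupled one when
    called rbp_associated (or both).
    """
    config = config or PipelineConfig()
    result, *_ = _specific_attribution(cohort, config)
    truth = cohort.truth.circ
    merged = result.join(truth[["sim_class"]])
    host = merged[merged["sim_class"] == "host_coupled"]
    rbp = merged[merged["sim_class"] == "rbp_coupled"]
    host_ok = host["driver_call"].isin(["host_gene", "both"])
    rbp_ok = rbp["driver_call"].isin(["rbp_associated", "both"])
    n = len(host) + len(rbp)
    return {
        "rate": float((host_ok.sum() + rbp_ok.sum()) / n) if n else float("nan"),
        "host_rate": float(host_ok.mean()) if len(host) else float("nan"),
        "rbp_rate": float(rbp_ok.mean()) if len(rbp) else float("nan"),
        "n": int(n),
    }


def dysregulated_attribution_accuracy(
    cohort: Cohort,
    circ_de_tables: dict[str, pd.DataFrame],
    config: PipelineConfig | None = None,
    strong_r: float = 0.8,
) -> dict:
    """Driver-call accuracy for dysregulated circRNAs with known drivers.

    Host-coupled circRNAs whose host is significantly altered in the same
    direction must be host-explained; RBP-coupled circRNAs whose driver RBP
    is significantly altered, and whose realized within-cancer correlation
    with it reaches ``strong_r``, must be RBP-associated.
    """
    config = config or PipelineConfig()
    rpm = rpm_matrix(cohort.junctions)
    truth = cohort.truth.circ
    outcomes = []
    for cancer in sorted({s.tissue for s in cohort.samples}):
        cols = [j for j, s in enumerate(cohort.samples) if s.tissue == cancer]
        sub_samples = [cohort.samples[j] for j in cols]
        gene_de = de_test(
            cohort.gene_counts.values[:, cols].astype(int),
            cohort.gene_fpkm.feature_ids,
            sub_samples,
            cancer=cancer,
            config=config,
        )
        rbp_de = gene_de[gene_de["feature_id"].isin(cohort.rbp_panel)]
        sig_rbps = set(rbp_de.loc[rbp_de["direction"] != "ns", "feature_id"])
        circ_expr = pd.DataFrame(rpm.values[:, cols], index=rpm.feature_ids)
        rbp_expr = pd.DataFrame(
            cohort.gene_fpkm.values[:, cols], index=cohort.gene_fpkm.feature_ids
        ).loc[cohort.rbp_panel]
        att, _ = attribute_dysregulated_circ(
            circ_de_tables[cancer], gene_de, rbp_de, circ_expr, rbp_expr,
            cohort.host_gene_map, config,
        )
        gene_dir = gene_de.set_index("feature_id")["direction"]
        for row in att.itertuples():
            info = truth.loc[row.circ_id]
            if info.sim_class == "host_coupled":
                if gene_dir.get(info.host_gene, "ns") == row.direction:
                    outcomes.append(("host", row.driver_call == "host_gene"))
            elif info.sim_class == "rbp_coupled" and info.coupled_rbp in sig_rbps:
                r = pearson_profile(
                    circ_expr.loc[row.circ_id], rbp_expr.loc[info.coupled_rbp]
                )
                if np.isfinite(r) and r >= strong_r:
                    outcomes.append(("rbp", row.driver_call == "rbp_associated"))
    df = pd.DataFrame(outcomes, columns=["kind", "correct"])
    return {
        "rate": float(df["correct"].mean()) if len(df) else float("nan"),
        "n": int(len(df)),
        "host_n": int((df["kind"] == "host").sum()),
        "rbp_n": int((df["kind"] == "rbp").sum()),
    }


def global_abundance_summary(cohort: Cohort) -> dict:
    """Per-cancer tumor-vs-normal totals: count of cancers with lower tumor medians."""
    rpm = rpm_matrix(cohort.junctions)
    table = global_abundance_test(rpm)
    lower = table["tumor_median_total_rpm"] < table["normal_median_total_rpm"]
    return {
        "n_cancers_lower_in_tumor": int(lower.sum()),
        "n_cancers": int(len(table)),
        "max_p": float(table["p_value"].max()),
        "table": table,
    }
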