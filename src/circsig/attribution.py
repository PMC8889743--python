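"""Attribute circRNA expression patterns to host genes or RNA-binding proteins.

Two regimes share the same correlation primitive:

* tissue specificity — a tissue-specific circRNA is attributed to its host
  gene when the host is itself tissue-specific in the same tissue, and/or to
  an RBP when its profile correlates strongly (Pearson r >= 0.7) with a
  tissue-specific RBP; profiles here are per-tissue medians over normal
  samples;
* cancer dysregulation — a differentially expressed circRNA is explained by
  its host gene when the host is significantly altered in the same cancer
  with the same direction, and otherwise screened against dysregulated RBPs
  by per-sample correlation within that cancer's cohort.

Binding-site evidence (eCLIP peaks as BED intervals) over the introns
flanking a back-splice site provides the orthogonal overlap report.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import (
    CircRNARecord,
    GenomicIntervals,
    PipelineConfig,
    TranscriptModel,
)
from .quantify import flanking_introns

DRIVER_CALLS = ("host_gene", "rbp_associated", "both", "unexplained")
QUADRANTS = ("both_up", "both_down", "circ_up_gene_down", "circ_down_gene_up")


def pearson_profile(x, y) -> float:
    """Pearson correlation of two expression profiles.

    Returns NaN (flagged undefined) when either vector is constant; raises
    on length mismatch or fewer than 3 points.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.size < 3:
        raise ValueError("need >= 3 points for a correlation")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def best_rbp_correlation(
    circ_profile: np.ndarray, rbp_profiles: pd.DataFrame
) -> tuple[str, float]:
    """(RBP id, r) of the panel member best correlated with the circRNA profile."""
    best_id, best_r = "", -np.inf
    for rbp_id, row in rbp_profiles.iterrows():
        r = pearson_profile(circ_profile, row.values)
        if np.isnan(r):
            continue
        if r > best_r:
            best_id, best_r = str(rbp_id), r
    if best_id == "":
        return "", float("nan")
    return best_id, best_r


def attribute_specific_circ(
    circ_tsi: pd.DataFrame,
    circ_profiles: pd.DataFrame,
    gene_tsi: pd.DataFrame,
    rbp_tsi: pd.DataFrame,
    rbp_profiles: pd.DataFrame,
    host_gene: dict[str, str],
    gene_profiles: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Driver attribution for tissue-specific circRNAs.

    ``circ_tsi``/``gene_tsi``/``rbp_tsi`` are categorized TSI tables
    (specificity module); profiles are per-tissue median matrices.  Only
    tissue-specific RBPs enter the correlation screen.  circRNAs without a
    host gene are skipped with a flag.
    """
    config = config or PipelineConfig()
    specific = circ_tsi[circ_tsi["category"] == "tissue_specific"]
    specific_rbps = rbp_tsi[rbp_tsi["category"] == "tissue_specific"].index
    rbp_prof = rbp_profiles.loc[[r for r in specific_rbps if r in rbp_profiles.index]]
    rows = []
    for circ_id, circ_row in specific.iterrows():
        gene = host_gene.get(circ_id, "")
        if not gene:
            rows.append(
                {
                    "circ_id": circ_id,
                    "host_gene": "",
                    "host_r": np.nan,
                    "host_tissue_specific_match": False,
                    "best_rbp": "",
                    "best_rbp_r": np.nan,
                    "driver_call": "skipped_no_host",
                }
            )
            continue
        host_match = (
            gene in gene_tsi.index
            and gene_tsi.loc[gene, "category"] == "tissue_specific"
            and gene_tsi.loc[gene, "argmax_tissue"] == circ_row["argmax_tissue"]
        )
        profile = circ_profiles.loc[circ_id].values
        host_r = np.nan
        if gene_profiles is not None and gene in gene_profiles.index:
            host_r = pearson_profile(profile, gene_profiles.loc[gene].values)
        best_rbp, best_r = ("", np.nan)
        if len(rbp_prof):
            best_rbp, best_r = best_rbp_correlation(profile, rbp_prof)
        rbp_match = np.isfinite(best_r) and best_r >= config.corr_strong_min
        if host_match and rbp_match:
            call = "both"
        elif host_match:
            call = "host_gene"
        elif rbp_match:
            call = "rbp_associated"
        else:
            call = "unexplained"
        rows.append(
            {
                "circ_id": circ_id,
                "host_gene": gene,
                "host_r": host_r,
                "host_tissue_specific_match": bool(host_match),
                "best_rbp": best_rbp,
                "best_rbp_r": best_r,
                "driver_call": call,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "circ_id",
            "host_gene",
            "host_r",
            "host_tissue_specific_match",
            "best_rbp",
            "best_rbp_r",
            "driver_call",
        ],
    ).set_index("circ_id")


def host_correlations(
    circ_profiles: pd.DataFrame,
    gene_profiles: pd.DataFrame,
    host_gene: dict[str, str],
) -> pd.Series:
    """Pearson r between each circRNA profile and its host-gene profile."""
    out = {}
    for circ_id in circ_profiles.index:
        gene = host_gene.get(circ_id, "")
        if gene and gene in gene_profiles.index:
            out[circ_id] = pearson_profile(
                circ_profiles.loc[circ_id].values, gene_profiles.loc[gene].values
            )
        else:
            out[circ_id] = np.nan
    return pd.Series(out, name="host_r")


def fold_change_quadrant(circ_lfc: float, gene_lfc: float) -> tuple[str, bool]:
    """Quadrant of (circRNA, host linear transcript) fold changes and concordance."""
    if circ_lfc >= 0 and gene_lfc >= 0:
        return "both_up", True
    if circ_lfc < 0 and gene_lfc < 0:
        return "both_down", True
    if circ_lfc >= 0:
        return "circ_up_gene_down", False
    return "circ_down_gene_up", False


def attribute_dysregulated_circ(
    circ_de: pd.DataFrame,
    gene_de: pd.DataFrame,
    rbp_de: pd.DataFrame,
    circ_expr: pd.DataFrame,
    rbp_expr: pd.DataFrame,
    host_gene: dict[str, str],
    config: PipelineConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Driver attribution for one cancer's differentially expressed circRNAs.

    ``circ_de``/``gene_de``/``rbp_de`` are DE tables for the same cancer
    (diffexpr module); ``circ_expr``/``rbp_expr`` are per-sample expression
    frames over that cancer's samples (columns aligned).  Returns
    (attribution table, fold-change quadrant table).  The attribution
    reports both the direction-concordant host tally (the default
    ``host_explained``) and the any-direction tally.
    """
    config = config or PipelineConfig()
    gene_dir = gene_de.set_index("feature_id")["direction"].to_dict()
    gene_lfc = gene_de.set_index("feature_id")["log2fc"].to_dict()
    sig_rbps = rbp_de[rbp_de["direction"] != "ns"]["feature_id"].tolist()
    sig_circ = circ_de[circ_de["direction"] != "ns"]
    att_rows, quad_rows = [], []
    for row in sig_circ.itertuples(index=False):
        circ_id = row.feature_id
        gene = host_gene.get(circ_id, "")
        g_dir = gene_dir.get(gene, "ns")
        host_same_dir = g_dir == row.direction
        host_any_de = g_dir != "ns"
        best_rbp, best_r = "", np.nan
        if not host_same_dir and sig_rbps and circ_id in circ_expr.index:
            panel = rbp_expr.loc[[r for r in sig_rbps if r in rbp_expr.index]]
            if len(panel):
                best_rbp, best_r = best_rbp_correlation(
                    circ_expr.loc[circ_id].values, panel
                )
        rbp_match = np.isfinite(best_r) and best_r >= config.corr_strong_min
        if host_same_dir:
            call = "host_gene"
        elif rbp_match:
            call = "rbp_associated"
        else:
            call = "unexplained"
        att_rows.append(
            {
                "circ_id": circ_id,
                "cancer": row.cancer,
                "direction": row.direction,
                "host_gene": gene,
                "host_de_same_direction": host_same_dir,
                "host_de_any_direction": host_any_de,
                "best_rbp": best_rbp,
                "best_rbp_r": best_r,
                "driver_call": call,
            }
        )
        g_lfc = gene_lfc.get(gene, np.nan)
        if np.isfinite(g_lfc) and np.isfinite(row.log2fc):
            quadrant, concordant = fold_change_quadrant(row.log2fc, g_lfc)
            quad_rows.append(
                {
                    "circ_id": circ_id,
                    "cancer": row.cancer,
                    "circ_log2fc": row.log2fc,
                    "gene_log2fc": g_lfc,
                    "quadrant": quadrant,
                    "concordant": concordant,
                }
            )
    attribution = pd.DataFrame(
        att_rows,
        columns=[
            "circ_id",
            "cancer",
            "direction",
            "host_gene",
            "host_de_same_direction",
            "host_de_any_direction",
            "best_rbp",
            "best_rbp_r",
            "driver_call",
        ],
    )
    quadrants = pd.DataFrame(
        quad_rows,
        columns=[
            "circ_id",
            "cancer",
            "circ_log2fc",
            "gene_log2fc",
            "quadrant",
            "concordant",
        ],
    )
    return attribution, quadrants


def flanking_intron_peak_overlap(
    record: CircRNARecord,
    tx: TranscriptModel,
    peaks: GenomicIntervals,
) -> dict:
    """Count binding-site peaks in the introns flanking a back-splice site."""
    flanks = flanking_introns(record, tx)
    up = (
        peaks.count(record.chrom, *flanks.upstream)
        if flanks.upstream is not None
        else 0
    )
    down = (
        peaks.count(record.chrom, *flanks.downstream)
        if flanks.downstream is not None
        else 0
    )
    return {
        "circ_id": record.circ_id,
        "upstream_peaks": up,
        "downstream_peaks": down,
        "any_overlap": (up + down) > 0,
    }
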