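"""Tissue-specificity scoring.

The tissue-specificity index of a feature over n tissues is

    TSI = sum_i (1 - x_i / x_max) / (n - 1)

where x_i is the feature's median expression in tissue i across normal
samples and x_max the maximum of the x_i.  TSI is 0 for a perfectly uniform
profile and 1 for expression confined to a single tissue.  Features with
TSI <= 0.3 are called ubiquitous, TSI >= 0.85 tissue-specific, anything in
between intermediate.  Only normal-tissue samples enter the profile; tumors
never do.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_formats import ExpressionMatrix, PipelineConfig


def median_by_tissue(
    em: ExpressionMatrix, condition: str = "normal"
) -> pd.DataFrame:
    """Per-feature, per-tissue median expression over samples of one condition.

    Columns are tissues in canonical (sorted) order.  A tissue contributing
    zero samples of the requested condition is an error.
    """
    if em.samples is None:
        raise ValueError("expression matrix has no sample metadata attached")
    tissues = sorted({s.tissue for s in em.samples})
    empty = [
        t
        for t in tissues
        if not any(s.tissue == t and s.condition == condition for s in em.samples)
    ]
    if empty:
        raise ValueError(f"no {condition} samples for tissues: {empty}")
    cols = {}
    for t in tissues:
        idx = [
            j
            for j, s in enumerate(em.samples)
            if s.tissue == t and s.condition == condition
        ]
        cols[t] = np.median(em.values[:, idx], axis=1)
    return pd.DataFrame(cols, index=em.feature_ids)


def tsi(x) -> float:
    """Tissue-specificity index of one expression profile (vector over tissues)."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("profile must be a vector over >= 2 tissues")
    if (x < 0).any():
        raise ValueError("profile values must be non-negative")
    x_max = x.max()
    if x_max == 0:
        return float("nan")
    return float(np.sum(1.0 - x / x_max) / (x.size - 1))


def tsi_table(profiles: pd.DataFrame) -> pd.DataFrame:
    """TSI, argmax tissue and all-zero flag for every profile row.

    All-zero profiles get NaN TSI and are flagged rather than dropped, so
    the caller controls exclusion.  Ties for the maximum resolve to the
    first tissue in column (canonical) order.
    """
    values = profiles.values.astype(float)
    x_max = values.max(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        scores = (1.0 - values / x_max[:, None]).sum(axis=1) / (values.shape[1] - 1)
    argmax = profiles.columns[np.argmax(values, axis=1)]
    out = pd.DataFrame(
        {
            "tsi": np.where(x_max > 0, scores, np.nan),
            "argmax_tissue": argmax,
            "all_zero": x_max == 0,
        },
        index=profiles.index,
    )
    out.loc[out["all_zero"], "argmax_tissue"] = ""
    return out


def filter_abundant(profiles: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Keep features whose median expression reaches ``threshold`` (inclusive) in >= 1 tissue."""
    return profiles[profiles.max(axis=1) >= threshold]


def categorize(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> pd.DataFrame:
    """Three-way partition of TSI scores; both published boundaries inclusive."""
    config = config or PipelineConfig()
    cat = pd.Series("intermediate", index=table.index, dtype=object)
    cat[table["tsi"] <= config.tsi_ubiquitous_max] = "ubiquitous"
    cat[table["tsi"] >= config.tsi_specific_min] = "tissue_specific"
    cat[table["tsi"].isna()] = "excluded"
    out = table.copy()
    out["category"] = cat
    return out


def tsi_pipeline(
    em: ExpressionMatrix,
    abundance_threshold: float,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Median profiles on normals -> abundance filter -> TSI -> categories."""
    profiles = median_by_tissue(em, condition="normal")
    kept = filter_abundant(profiles, abundance_threshold)
    return categorize(tsi_table(kept), config)
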