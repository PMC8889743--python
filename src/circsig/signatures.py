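"""Cross-cancer signature classification of dysregulated circRNAs.

Given per-cancer differential-expression tables, every circRNA significant
in at least one cancer is classified as cancer-specific (exactly one cancer)
or shared (two or more).  Shared circRNAs are further split into consistent
(every significant call has the same fold-change direction) or inconsistent
(mixed directions), and flagged when dysregulated in at least four cancers.
Only significant entries contribute to the direction call; a circRNA
significant-up in one cancer and non-significantly down elsewhere counts as
consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

SHARED_TIER_MIN = 4


def _normalise_tables(
    de_tables: dict[str, pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """Accept {cancer: table} or one combined table with a cancer column."""
    if isinstance(de_tables, pd.DataFrame):
        combined = de_tables.copy()
    else:
        frames = []
        for cancer, tbl in de_tables.items():
            tbl = tbl.copy()
            tbl["cancer"] = cancer
            frames.append(tbl)
        combined = pd.concat(frames, ignore_index=True)
    required = {"feature_id", "cancer", "direction"}
    missing = required - set(combined.columns)
    if missing:
        raise ValueError(f"DE table missing columns: {sorted(missing)}")
    dup = combined.duplicated(subset=["feature_id", "cancer"])
    if dup.any():
        bad = combined.loc[dup, ["feature_id", "cancer"]].iloc[0]
        raise ValueError(
            f"duplicate entry for {bad.feature_id!r} in cancer {bad.cancer!r}"
        )
    return combined


def classify_signatures(
    de_tables: dict[str, pd.DataFrame] | pd.DataFrame,
) -> pd.DataFrame:
    """One row per circRNA significant in >= 1 cancer.

    Columns: ``cancers_affected`` ("cancer:direction" joined by ";", cancers
    sorted), ``n_cancers``, ``sig_class`` (cancer_specific/shared),
    ``shared_ge4``, ``consistency`` (consistent/inconsistent for shared
    entries, "" for specific ones).
    """
    combined = _normalise_tables(de_tables)
    sig = combined[combined["direction"].isin(["up", "down"])]
    rows = []
    for circ_id, grp in sig.groupby("feature_id"):
        pairs = sorted(zip(grp["cancer"], grp["direction"]))
        n = len(pairs)
        directions = {d for _, d in pairs}
        if n == 1:
            sig_class, consistency = "cancer_specific", ""
        else:
            sig_class = "shared"
            consistency = "consistent" if len(directions) == 1 else "inconsistent"
        rows.append(
            {
                "circ_id": circ_id,
                "cancers_affected": ";".join(f"{c}:{d}" for c, d in pairs),
                "n_cancers": n,
                "sig_class": sig_class,
                "shared_ge4": n >= SHARED_TIER_MIN,
                "consistency": consistency,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "circ_id",
            "cancers_affected",
            "n_cancers",
            "sig_class",
            "shared_ge4",
            "consistency",
        ],
    ).sort_values("circ_id", ignore_index=True)


def summarize_signatures(
    signature_table: pd.DataFrame,
) -> tuple[dict[str, int], pd.DataFrame]:
    """Summary counts and a signed-significance heatmap matrix.

    The matrix has circRNAs as rows, cancers as columns, entries +1/-1/0 for
    significant up/down/not significant.  Summary counts satisfy the
    partition identities: specific + shared == total and consistent +
    inconsistent == shared.
    """
    if signature_table.empty:
        return (
            {
                "n_total": 0,
                "n_cancer_specific": 0,
                "n_shared": 0,
                "n_shared_ge4": 0,
                "n_consistent": 0,
                "n_inconsistent": 0,
            },
            pd.DataFrame(),
        )
    summary = {
        "n_total": int(len(signature_table)),
        "n_cancer_specific": int(
            (signature_table["sig_class"] == "cancer_specific").sum()
        ),
        "n_shared": int((signature_table["sig_class"] == "shared").sum()),
        "n_shared_ge4": int(signature_table["shared_ge4"].sum()),
        "n_consistent": int((signature_table["consistency"] == "consistent").sum()),
        "n_inconsistent": int(
            (signature_table["consistency"] == "inconsistent").sum()
        ),
    }
    cancers = sorted(
        {
            pair.split(":")[0]
            for entry in signature_table["cancers_affected"]
            for pair in entry.split(";")
        }
    )
    matrix = pd.DataFrame(
        0, index=signature_table["circ_id"], columns=cancers, dtype=int
    )
    for row in signature_table.itertuples(index=False):
        for pair in row.cancers_affected.split(";"):
            cancer, direction = pair.split(":")
            matrix.loc[row.circ_id, cancer] = 1 if direction == "up" else -1
    return summary, matrix


def per_cancer_de_counts(
    de_tables: dict[str, pd.DataFrame] | pd.DataFrame,
) -> pd.Series:
    """Number of significant circRNAs per cancer (for extremes reporting)."""
    combined = _normalise_tables(de_tables)
    sig = combined[combined["direction"].isin(["up", "down"])]
    return sig.groupby("cancer")["feature_id"].nunique().sort_values(ascending=False)
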