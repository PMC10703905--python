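"""Stage 2: collapse feature-level associations to gene level (min-p).

Each gene is represented by its most significant feature within the omics —
the most significant variant for genotypes, CpG site for methylation,
transcript for expression.  No multiplicity correction is applied for the
number of features per gene (a known bias favouring feature-rich genes,
surfaced in the table metadata downstream); ties are broken by the
lexicographically smallest feature_id so outputs are reproducible.
"""

from __future__ import annotations

import pandas as pd

from transomics.association import AssociationTable

GENE_COLUMNS = ["gene_id", "omics_type", "outcome", "best_feature", "min_p"]


def collapse_to_genes(
    table: AssociationTable | pd.DataFrame,
    feature_map: pd.DataFrame,
) -> pd.DataFrame:
    """Collapse one omics x outcome association table to gene level.

    Returns a frame with columns ``gene_id, omics_type, outcome,
    best_feature, min_p`` — one row per gene with at least one tested
    feature.  Genes whose features are all degenerate keep min_p = 1.

    Raises ``KeyError`` listing offending ids when a tested feature is
    missing from the map for the matching omics.
    """
    frame = table.table if isinstance(table, AssociationTable) else table
    omics_type = frame["omics_type"].iloc[0] if len(frame) else None
    fmap = feature_map.loc[
        feature_map["omics_type"] == omics_type, ["feature_id", "gene_id"]
    ]
    merged = frame.merge(fmap, on="feature_id", how="left")
    unmapped = merged.loc[merged["gene_id"].isna(), "feature_id"]
    if len(unmapped):
        raise KeyError(
            f"features missing from the gene map: {sorted(unmapped)[:10]}"
            + ("..." if len(unmapped) > 10 else "")
        )
    merged = merged.sort_values(
        ["p_value", "feature_id"], kind="stable"
    ).drop_duplicates("gene_id", keep="first")
    out = merged[["gene_id", "omics_type", "outcome", "feature_id", "p_value"]].rename(
        columns={"feature_id": "best_feature", "p_value": "min_p"}
    )
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)
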