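"""TSV readers/writers for association, gene-level and score tables.

Association-table TSVs are also the entry point for real-data mode: a user
with pre-computed feature-level association results (one file per
omics x outcome, columns ``feature_id omics_type outcome estimate std_error
p_value n_used flag``) plus a feature->gene map can run stages 2-3 without
the simulator.
"""

from __future__ import annotations

import os

import pandas as pd

from transomics.association import AssociationTable, _TABLE_COLUMNS


def _float_repr(v) -> str:
    # shortest exact-roundtrip decimal form
    return repr(float(v))


def write_association_table(table: AssociationTable, path: str | os.PathLike) -> None:
    table.table[_TABLE_COLUMNS].to_csv(
        path, sep="\t", index=False, na_rep="", float_format=_float_repr
    )


def read_association_table(path: str | os.PathLike) -> AssociationTable:
    frame = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in _TABLE_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing association columns {missing}")
    return AssociationTable(
        omics_type=str(frame["omics_type"].iloc[0]),
        outcome=str(frame["outcome"].iloc[0]),
        model="external",
        covariates=(),
        cluster_col="",
        table=frame,
    )


def read_association_dir(
    directory: str | os.PathLike,
) -> dict[tuple[str, str], AssociationTable]:
    """Read every ``*.tsv`` association table in a directory."""
    tables: dict[tuple[str, str], AssociationTable] = {}
    for name in sorted(os.listdir(directory)):
        if not name.endswith(".tsv"):
            continue
        t = read_association_table(os.path.join(directory, name))
        tables[(t.omics_type, t.outcome)] = t
    if not tables:
        raise ValueError(f"no association tables found in {directory}")
    return tables


def write_gene_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False, na_rep="", float_format=_float_repr)


def write_score_table(frame: pd.DataFrame, path: str | os.PathLike) -> None:
    """Score TSV mirroring the report layout: per-omics min_p cells of genes
    absent from an omics are printed empty."""
    frame.to_csv(path, sep="\t", index=False, na_rep="", float_format=_float_repr)


def read_feature_map(path: str | os.PathLike) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t")
    needed = {"feature_id", "gene_id", "omics_type"}
    if not needed <= set(frame.columns):
        raise ValueError(f"{path}: feature map needs columns {sorted(needed)}")
    return frame
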