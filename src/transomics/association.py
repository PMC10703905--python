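"""Stage 1: feature-level association with the four coronary outcomes.

Every omics feature is regressed on each outcome with adjustment for age,
sex, weight, height and (when present) the omics' technical covariate, with
cluster-robust sandwich standard errors grouped on family.  The three model
families mirror the outcome types:

* ``test_binary``     — logistic regression (CAC presence, prevalent MI)
* ``test_continuous`` — linear regression of log CAC score, CAC>0 subset
* ``test_survival``   — Cox proportional hazards (incident MI)

These fixed-effect fits with exchangeable-cluster sandwich variance stand in
for GEE / mixed-model / pedigree-clustered formulations: the estimand is the
same for exchangeable family clusters, and per-feature fitting at genome
scale is far better behaved.  Degenerate fits (separation, constant
features, non-convergence) are flagged and assigned p_value = 1 rather than
dropped, so gene-level collapsing never loses a gene silently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from transomics import _batched
from transomics.simulate import OmicsDataset

logger = logging.getLogger(__name__)

BASE_COVARIATES = ("age", "sex", "weight", "height")

_TABLE_COLUMNS = [
    "feature_id",
    "omics_type",
    "outcome",
    "estimate",
    "std_error",
    "p_value",
    "n_used",
    "flag",
]


@dataclass
class AssociationTable:
    """Per-feature association results for one omics x outcome pair."""

    omics_type: str
    outcome: str
    model: str
    covariates: tuple[str, ...]
    cluster_col: str
    table: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        missing = [c for c in _TABLE_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"association table missing columns {missing}")
        if self.table["feature_id"].duplicated().any():
            raise ValueError("duplicate feature_ids in association table")


def _covariate_columns(covariates: pd.DataFrame, omics_type: str) -> list[str]:
    cols = list(BASE_COVARIATES)
    tech = f"tech_{omics_type}"
    if tech in covariates.columns:
        cols.append(tech)
    return cols


def _prepare(
    omics: OmicsDataset,
    outcome_frame: pd.DataFrame,
    covariates: pd.DataFrame,
    intercept: bool = True,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame, np.ndarray, list[str]]:
    """Align samples, drop missing outcomes, sort clusters contiguously.

    ``intercept=False`` for the Cox model, whose partial likelihood has no
    intercept term (an all-ones column would be singular).
    """
    cov = covariates.set_index("sample_id")
    keep = [s for s in omics.sample_ids if s in cov.index]
    merged = outcome_frame.reindex(keep).join(cov.loc[keep])
    merged = merged.dropna(subset=["__y__"])
    merged = merged.sort_values("family_id", kind="stable")
    idx = pd.Index(omics.sample_ids).get_indexer(merged.index)
    feats = omics.values[idx]
    cov_cols = _covariate_columns(covariates, omics.omics_type)
    blocks = [merged[c].to_numpy(dtype=float) for c in cov_cols]
    if intercept:
        blocks = [np.ones(len(merged))] + blocks
    X = np.column_stack(blocks)
    groups = merged["family_id"].to_numpy()
    return X, feats, merged, groups, cov_cols


def _as_table(
    omics: OmicsDataset,
    outcome: str,
    model: str,
    cov_cols: list[str],
    fit: _batched.BatchedFit,
) -> AssociationTable:
    n_degen = int(fit.degenerate.sum())
    if n_degen:
        logger.warning(
            "%s/%s: %d of %d features flagged degenerate",
            omics.omics_type,
            outcome,
            n_degen,
            len(omics.feature_ids),
        )
    table = pd.DataFrame(
        {
            "feature_id": omics.feature_ids,
            "omics_type": omics.omics_type,
            "outcome": outcome,
            "estimate": fit.estimate,
            "std_error": fit.se_robust,
            "p_value": fit.p_value,
            "n_used": fit.n_used,
            "flag": np.where(fit.degenerate, "degenerate", "ok"),
        }
    )
    return AssociationTable(
        omics_type=omics.omics_type,
        outcome=outcome,
        model=model,
        covariates=tuple(cov_cols),
        cluster_col="family_id",
        table=table,
    )


def test_binary(
    omics: OmicsDataset,
    outcome: pd.Series,
    covariates: pd.DataFrame,
    outcome_name: str = "cac_present",
) -> AssociationTable:
    """Logistic regression of a binary outcome on every feature.

    ``outcome`` must be indexed by sample_id.  Raises ``ValueError`` when
    only one class is present among usable samples.
    """
    frame = pd.DataFrame({"__y__": outcome.astype(float)})
    X, feats, merged, groups, cov_cols = _prepare(omics, frame, covariates)
    y = merged["__y__"].to_numpy(dtype=float)
    fit = _batched.logistic_cluster(X, feats, y, groups)
    return _as_table(omics, outcome_name, "logistic+cluster-sandwich", cov_cols, fit)


def test_continuous(
    omics: OmicsDataset,
    cac_score: pd.Series,
    covariates: pd.DataFrame,
    outcome_name: str = "cac_score",
    log_transform: bool = True,
) -> AssociationTable:
    """Linear regression of the (log) CAC score, CAC-positive subset only.

    Samples where ``cac_score`` is missing (CAC absent) are excluded; the
    score is log-transformed by default since the Agatston scale is strongly
    right-skewed.
    """
    y = cac_score.astype(float)
    if log_transform:
        y = np.log(y.where(y > 0))
    frame = pd.DataFrame({"__y__": y})
    X, feats, merged, groups, cov_cols = _prepare(omics, frame, covariates)
    if len(merged) < X.shape[1] + 3:
        raise ValueError(
            f"only {len(merged)} usable samples for {X.shape[1]} covariates"
        )
    yv = merged["__y__"].to_numpy(dtype=float)
    fit = _batched.linear_cluster(X, feats, yv, groups)
    return _as_table(omics, outcome_name, "linear+cluster-sandwich", cov_cols, fit)


def test_survival(
    omics: OmicsDataset,
    mi_time: pd.Series,
    mi_event: pd.Series,
    covariates: pd.DataFrame,
    outcome_name: str = "mi_incident",
) -> AssociationTable:
    """Cox PH regression of incident MI on every feature.

    Samples with missing ``mi_time`` (prevalent-MI cases removed upstream)
    are excluded.  Raises ``ValueError`` when no events remain.
    """
    frame = pd.DataFrame(
        {"__y__": mi_time.astype(float), "__e__": mi_event.astype(float)}
    )
    X, feats, merged, groups, cov_cols = _prepare(
        omics, frame, covariates, intercept=False
    )
    times = merged["__y__"].to_numpy(dtype=float)
    events = merged["__e__"].to_numpy(dtype=float)
    if events.sum() < 1:
        raise ValueError("no incident events among usable samples")
    fit = _batched.cox_cluster(X, feats, times, events, groups)
    return _as_table(omics, outcome_name, "coxph+cluster-sandwich", cov_cols, fit)


def run_all(
    omics: dict[str, OmicsDataset],
    outcomes: pd.DataFrame,
    covariates: pd.DataFrame,
) -> dict[tuple[str, str], AssociationTable]:
    """Run all omics x outcome combinations (3 x 4 = 12 tables).

    Samples missing from an omics dataset simply do not contribute to that
    omics' analyses; prevalent-MI samples are excluded from the incident-MI
    risk set.
    """
    out = outcomes.set_index("sample_id")
    tables: dict[tuple[str, str], AssociationTable] = {}
    for o, ds in omics.items():
        tables[(o, "cac_present")] = test_binary(
            ds, out["cac_present"], covariates, "cac_present"
        )
        tables[(o, "cac_score")] = test_continuous(
            ds, out["cac_score"], covariates, "cac_score"
        )
        tables[(o, "mi_prevalent")] = test_binary(
            ds, out["mi_prevalent"], covariates, "mi_prevalent"
        )
        incident_time = out["mi_time"].where(out["mi_prevalent"] == 0)
        tables[(o, "mi_incident")] = test_survival(
            ds, incident_time, out["mi_event"], covariates, "mi_incident"
        )
    return tables
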