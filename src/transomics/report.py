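"""Result surfaces and pipeline orchestration.

Produces the per-outcome top-N trans-omic score tables and the cross-outcome
top-100 overlap accounting, and drives the full three-stage pipeline
(simulate -> associate -> collapse -> aggregate -> report) from a single
YAML/dict configuration.  Every output is a plain TSV plus a manifest that
echoes the configuration, seed and package version, sufficient to reproduce
every file byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import logging
import os
import time

import pandas as pd
import yaml

import transomics
from transomics import io as tio
from transomics.association import run_all
from transomics.genes import collapse_to_genes
from transomics.rra import RRAConfig, aggregate
from transomics.simulate import (
    OUTCOMES,
    OutcomeParams,
    PlantedEffect,
    SimulationConfig,
    simulate_cohort,
    write_fixture,
)

logger = logging.getLogger(__name__)


def top_n(scores: pd.DataFrame, n: int) -> pd.DataFrame:
    """First n rows of a score table (ascending score, gene_id on ties)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(scores) == 0:
        raise ValueError("empty score list")
    if n > len(scores):
        logger.warning("top_n: requested %d rows but only %d genes", n, len(scores))
    ranked = scores.sort_values(["trans_omic_score", "gene_id"], kind="stable")
    return ranked.head(n).reset_index(drop=True)


def cross_outcome_overlap(
    scores_by_outcome: dict[str, pd.DataFrame], n: int = 100
) -> pd.DataFrame:
    """Genes appearing in >= 2 of the per-outcome top-n sets.

    Returns columns ``gene_id, outcomes, n_outcomes`` with ``outcomes`` a
    comma-joined list of the outcomes whose top-n set contains the gene.
    """
    if len(scores_by_outcome) < 2:
        raise ValueError("need score lists for at least 2 outcomes")
    membership: dict[str, list[str]] = {}
    for outcome, scores in scores_by_outcome.items():
        head = top_n(scores, min(n, len(scores)))
        for g in head["gene_id"]:
            membership.setdefault(g, []).append(outcome)
    rows = [
        {"gene_id": g, "outcomes": ",".join(sorted(o)), "n_outcomes": len(o)}
        for g, o in membership.items()
        if len(o) >= 2
    ]
    out = pd.DataFrame(rows, columns=["gene_id", "outcomes", "n_outcomes"])
    return out.sort_values(
        ["n_outcomes", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)


def _simulation_config(raw: dict, seed: int | None) -> SimulationConfig:
    raw = dict(raw or {})
    planted = [
        PlantedEffect(
            gene_id=e["gene_id"],
            omics_effects=dict(e.get("omics_effects", {})),
            outcome_effects=dict(e.get("outcome_effects", {})),
        )
        for e in raw.pop("planted_effects", [])
    ]
    outcome_params = OutcomeParams(**raw.pop("outcome_params", {}))
    if "features_per_gene_by_omics" in raw:
        raw["features_per_gene_by_omics"] = dict(raw["features_per_gene_by_omics"])
    if "maf_range" in raw:
        raw["maf_range"] = tuple(raw["maf_range"])
    cfg = SimulationConfig(
        planted_effects=tuple(planted), outcome_params=outcome_params, **raw
    )
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=seed)
    return cfg


def run_pipeline(
    config: dict | str | os.PathLike,
    out_dir: str | os.PathLike,
    seed: int | None = None,
    write_cohort: bool = False,
) -> dict:
    """Run the full pipeline and write all artifacts under ``out_dir``.

    ``config`` is a dict or a YAML file path with keys:

    * ``mode``: ``synthetic`` (default) or ``tables`` (pre-computed
      association TSVs via ``association_dir`` + ``feature_map``)
    * ``simulation``: :class:`SimulationConfig` fields (synthetic mode)
    * ``rra``: ``top_fraction`` (default 0.05), ``correction``
    * ``report``: ``top_n`` (default 10), ``overlap_n`` (default 100)

    Writes 12 association tables, 12 gene-level tables, 4 score tables,
    4 top-N reports, 1 overlap report and ``manifest.yaml``; returns a
    summary dict with the in-memory frames and artifact paths.
    """
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    config = dict(config or {})
    mode = config.get("mode", "synthetic")
    rra_raw = dict(config.get("rra", {}))
    rra_cfg = RRAConfig(
        n_lists=3,
        top_fraction=float(rra_raw.get("top_fraction", 0.05)),
        correction=rra_raw.get("correction", "bonferroni"),
    )
    report_cfg = dict(config.get("report", {}))
    n_top = int(report_cfg.get("top_n", 10))
    n_overlap = int(report_cfg.get("overlap_n", 100))

    out_dir = os.fspath(out_dir)
    for sub in ("associations", "genes", "scores", "reports"):
        os.makedirs(os.path.join(out_dir, sub), exist_ok=True)

    timings: dict[str, float] = {}
    t0 = time.perf_counter()
    sim_cfg = None
    if mode == "synthetic":
        sim_cfg = _simulation_config(config.get("simulation", {}), seed)
        omics, covariates, feature_map, outcomes = simulate_cohort(sim_cfg)
        if write_cohort:
            write_fixture(
                omics, covariates, feature_map, outcomes,
                os.path.join(out_dir, "cohort"),
            )
        timings["simulate"] = time.perf_counter() - t0
        logger.info("simulate: %.1fs", timings["simulate"])
        t0 = time.perf_counter()
        try:
            tables = run_all(omics, outcomes, covariates)
        except Exception as exc:  # surface the failing stage
            raise RuntimeError(f"association stage failed: {exc}") from exc
        timings["associate"] = time.perf_counter() - t0
        logger.info("associate: %.1fs", timings["associate"])
    elif mode == "tables":
        tables = tio.read_association_dir(config["association_dir"])
        feature_map = tio.read_feature_map(config["feature_map"])
        timings["read_tables"] = time.perf_counter() - t0
    else:
        raise ValueError(f"unknown mode {mode!r}")

    for (o, y), t in sorted(tables.items()):
        tio.write_association_table(t, os.path.join(out_dir, "associations", f"{o}_{y}.tsv"))

    t0 = time.perf_counter()
    gene_tables: dict[tuple[str, str], pd.DataFrame] = {}
    for key, t in tables.items():
        try:
            gene_tables[key] = collapse_to_genes(t, feature_map)
        except Exception as exc:
            raise RuntimeError(f"gene-summary stage failed for {key}: {exc}") from exc
        tio.write_gene_table(
            gene_tables[key], os.path.join(out_dir, "genes", f"{key[0]}_{key[1]}.tsv")
        )
    timings["collapse"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    outcomes_present = sorted(
        {y for (_, y) in tables},
        key=lambda y: (OUTCOMES.index(y) if y in OUTCOMES else len(OUTCOMES), y),
    )
    scores: dict[str, pd.DataFrame] = {}
    for y in outcomes_present:
        per_omics = {o: g for (o, yy), g in gene_tables.items() if yy == y}
        try:
            scores[y] = aggregate(per_omics, rra_cfg)
        except Exception as exc:
            raise RuntimeError(f"aggregation stage failed for {y}: {exc}") from exc
        tio.write_score_table(scores[y], os.path.join(out_dir, "scores", f"{y}.tsv"))
    timings["aggregate"] = time.perf_counter() - t0

    reports: dict[str, pd.DataFrame] = {}
    for y, s in scores.items():
        reports[y] = top_n(s, min(n_top, len(s)))
        reports[y].to_csv(
            os.path.join(out_dir, "reports", f"top{n_top}_{y}.tsv"),
            sep="\t", index=False, na_rep="",
        )
    overlap = cross_outcome_overlap(scores, n=n_overlap)
    overlap.to_csv(
        os.path.join(out_dir, "reports", f"overlap_top{n_overlap}.tsv"),
        sep="\t", index=False, na_rep="",
    )

    manifest = {
        "package_version": transomics.__version__,
        "mode": mode,
        "seed": seed if seed is not None else (sim_cfg.seed if sim_cfg else None),
        "simulation": dataclasses.asdict(sim_cfg) if sim_cfg else None,
        "rra": dataclasses.asdict(rra_cfg),
        "report": {"top_n": n_top, "overlap_n": n_overlap},
        "artifacts": {
            "association_tables": len(tables),
            "gene_tables": len(gene_tables),
            "score_tables": len(scores),
            "top_reports": len(reports),
            "overlap_reports": 1,
        },
        "timings_seconds": {k: round(v, 3) for k, v in timings.items()},
    }
    if sim_cfg is not None:
        manifest["simulation"]["maf_range"] = list(sim_cfg.maf_range)
        manifest["simulation"]["planted_effects"] = [
            dataclasses.asdict(e) for e in sim_cfg.planted_effects
        ]
    with open(os.path.join(out_dir, "manifest.yaml"), "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)

    return {
        "tables": tables,
        "gene_tables": gene_tables,
        "scores": scores,
        "reports": reports,
        "overlap": overlap,
        "manifest": manifest,
        "out_dir": out_dir,
    }
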