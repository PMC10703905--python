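"""Stage 3: robust rank aggregation into the per-gene trans-omic score.

Given the gene-level min-p lists of the three omics for one outcome, the top
5% of each list enters the aggregation.  For a gene with normalized ranks
r = (r_1, ..., r_n) across the n lists (r = rank / list-universe size; 1 for
lists the gene is absent from), sort r ascending and compute the
order-statistic *beta scores*

    beta_k = P(U_(k) <= r_(k))  =  sum_{l=k}^{n} C(n,l) r_(k)^l (1-r_(k))^(n-l)

the probability, under random shuffling of the lists, that the k-th smallest
of n independent uniform normalized ranks falls at or below the observed
k-th smallest rank.  The trans-omic score is

    rho = min(n * min_k beta_k, 1)

(Bonferroni correction over the n order statistics; a valid, conservative
p-value-like quantity — lower means stronger cross-omics support).  The
uncorrected min beta is also reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betainc

OMICS_P_COLUMN = {
    "genotype": "p_genomics",
    "methylation": "p_epigenomics",
    "expression": "p_transcriptomics",
}


@dataclass(frozen=True)
class RRAConfig:
    n_lists: int = 3
    top_fraction: float = 0.05
    correction: str = "bonferroni"  # or "none"

    def __post_init__(self):
        if self.n_lists < 1:
            raise ValueError("n_lists must be >= 1")
        if not (0.0 < self.top_fraction <= 1.0):
            raise ValueError("top_fraction must be in (0, 1]")
        if self.correction not in ("bonferroni", "none"):
            raise ValueError("correction must be 'bonferroni' or 'none'")


def truncate_top_fraction(gene_records: pd.DataFrame, fraction: float) -> pd.DataFrame:
    """Keep the best ceil(fraction * N) genes of one omics' gene-level list.

    N is the total number of genes tested in that omics (the list universe).
    Sorted ascending by min_p, ties broken by gene_id.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    if len(gene_records) == 0:
        raise ValueError("empty gene-level list")
    n_keep = math.ceil(fraction * len(gene_records))
    ranked = gene_records.sort_values(["min_p", "gene_id"], kind="stable")
    return ranked.head(n_keep).reset_index(drop=True)


def normalized_ranks(
    truncated: dict[str, pd.DataFrame],
    universe_sizes: dict[str, int],
    universe: dict[str, set] | None = None,
) -> pd.DataFrame:
    """Normalized rank vectors over the union of truncated-list genes.

    A gene at 1-based rank k in omics o's truncated list gets r_o = k / N_o
    with N_o the *full* per-omics universe size; genes absent from a list
    get r_o = 1 exactly.  Returns a frame indexed by gene_id with one ``r_*``
    column per omics.
    """
    genes: set[str] = set()
    for o, lst in truncated.items():
        if universe is not None and o in universe:
            unknown = set(lst["gene_id"]) - universe[o]
            if unknown:
                raise KeyError(f"genes outside the {o} universe: {sorted(unknown)[:5]}")
        genes |= set(lst["gene_id"])
    index = pd.Index(sorted(genes), name="gene_id")
    out = pd.DataFrame(index=index)
    for o, lst in truncated.items():
        n_o = universe_sizes[o]
        if n_o < len(lst):
            raise ValueError(f"universe size for {o} smaller than its list")
        r = pd.Series(
            (np.arange(len(lst)) + 1.0) / n_o, index=lst["gene_id"].to_numpy()
        )
        out[f"r_{o}"] = r.reindex(index).fillna(1.0)
    return out


def beta_scores(r: np.ndarray) -> np.ndarray:
    """Order-statistic beta scores for rank vectors.

    ``r`` has shape (..., n) with components in (0, 1]; the last axis is
    sorted ascending internally.  Returns beta with the same shape, where
    ``beta[..., k-1] = P(U_(k) <= r_(k))`` for n iid uniforms — the
    regularized incomplete beta function I_{r_(k)}(k, n-k+1).
    """
    r = np.asarray(r, dtype=float)
    if r.size and (np.min(r) <= 0.0 or np.max(r) > 1.0):
        raise ValueError("rank components must lie in (0, 1]")
    rs = np.sort(r, axis=-1)
    n = r.shape[-1]
    k = np.arange(1, n + 1, dtype=float)
    return betainc(k, n - k + 1.0, rs)


def rho_score(beta: np.ndarray, config: RRAConfig) -> tuple[np.ndarray, np.ndarray]:
    """Trans-omic score from beta scores: min over k, Bonferroni-corrected.

    Returns ``(rho, min_k)`` with ``min_k`` the 1-based order-statistic
    index attaining the minimum (smallest index on ties).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size == 0:
        raise ValueError("empty beta vector")
    min_k = np.argmin(beta, axis=-1) + 1
    rho = np.min(beta, axis=-1)
    if config.correction == "bonferroni":
        rho = np.minimum(config.n_lists * rho, 1.0)
    return rho, min_k


def permutation_oracle(
    r: np.ndarray, n_draws: int = 10**6, seed: int = 0
) -> float:
    """Monte-Carlo estimate of min_k P(U_(k) <= r_(k)) by shuffling.

    Draws ``n_draws`` sorted uniform vectors; intended as an independent
    test oracle for :func:`beta_scores` / :func:`rho_score`, not as the
    production scorer.
    """
    if n_draws < 10**4:
        raise ValueError("n_draws must be >= 10^4 for a usable estimate")
    r = np.sort(np.asarray(r, dtype=float))
    if np.min(r) <= 0.0 or np.max(r) > 1.0:
        raise ValueError("rank components must lie in (0, 1]")
    n = len(r)
    rng = np.random.default_rng(seed)
    hits = np.zeros(n)
    block = 200_000
    done = 0
    while done < n_draws:
        b = min(block, n_draws - done)
        u = np.sort(rng.random((b, n)), axis=1)
        hits += (u <= r[None, :]).sum(axis=0)
        done += b
    best = float(np.min(hits / n_draws))
    return best


def aggregate(
    gene_tables: dict[str, pd.DataFrame],
    config: RRAConfig | None = None,
) -> pd.DataFrame:
    """Full chain for one outcome: truncate -> rank -> beta -> rho.

    ``gene_tables`` maps omics type to that omics' gene-level frame
    (columns ``gene_id, min_p`` at least).  Output covers the union of
    truncated-list genes, sorted ascending by (trans_omic_score, gene_id),
    with per-omics gene-level min_p columns named after the omics layers
    (``p_genomics, p_epigenomics, p_transcriptomics``); the min_p of a gene
    never tested in an omics is left missing.
    """
    if config is None:
        config = RRAConfig(n_lists=len(gene_tables))
    non_empty = {o: t for o, t in gene_tables.items() if len(t)}
    if not non_empty:
        raise ValueError("all gene-level lists are empty")
    if config.n_lists < len(non_empty):
        raise ValueError("n_lists smaller than the number of supplied lists")
    truncated = {
        o: truncate_top_fraction(t, config.top_fraction) for o, t in non_empty.items()
    }
    universe_sizes = {o: len(t) for o, t in non_empty.items()}
    ranks = normalized_ranks(truncated, universe_sizes)
    # absent omics layers (beyond those provided) count as uninformative r=1
    r = np.ones((len(ranks), config.n_lists))
    for j, o in enumerate(sorted(non_empty)):
        r[:, j] = ranks[f"r_{o}"].to_numpy()
    beta = beta_scores(r)
    rho, min_k = rho_score(beta, config)
    out = pd.DataFrame(
        {
            "gene_id": ranks.index.to_numpy(),
            "trans_omic_score": rho,
            "min_beta": np.min(beta, axis=-1),
            "min_k": min_k,
        }
    )
    ordered = [o for o in OMICS_P_COLUMN if o in gene_tables]
    ordered += [o for o in sorted(gene_tables) if o not in OMICS_P_COLUMN]
    for o in ordered:
        col = OMICS_P_COLUMN.get(o, f"p_{o}")
        lookup = gene_tables[o].set_index("gene_id")["min_p"]
        out[col] = lookup.reindex(out["gene_id"]).to_numpy()
    return out.sort_values(
        ["trans_omic_score", "gene_id"], kind="stable"
    ).reset_index(drop=True)
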