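"""Synthetic multi-omics family cohort generator.

Generates a Framingham-like cohort: three sample-by-feature omics matrices
(genotype dosages, CpG methylation beta values, transcript expression),
anthropometric covariates, family cluster labels, and four coronary outcomes
(CAC presence, continuous CAC score restricted to CAC > 0, prevalent MI,
incident MI with censoring).  Marginal calibration defaults follow the
source cohort: 45.2% CAC prevalence, median CAC score 67.8 (IQR 10.8-274.9),
2.1% prevalent MI, and roughly 1.9% incident MI over a mean 8.2-year
follow-up.

Per-gene effects can be *planted* on any subset of the omics and outcomes;
downstream stages are evaluated against this simulated ground truth.  A
"concordant" planted gene carries signal in all three omics, a "discordant"
one in a strict subset — the contrast the rank-aggregation stage is designed
to exploit.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

OMICS_TYPES = ("genotype", "methylation", "expression")
OUTCOMES = ("cac_present", "cac_score", "mi_prevalent", "mi_incident")

_FEATURE_TAG = {"genotype": "snp", "methylation": "cpg", "expression": "tx"}

# Fixed covariate coefficients on each outcome's linear predictor scale.
# Signs follow the epidemiology: older age and male sex increase CAC and MI
# risk; weight increases it; height mildly protective.
_COVARIATE_BETAS = {
    "cac_present": {"age": 0.09, "sex": -0.90, "weight": 0.010, "height": -0.005},
    "cac_score": {"age": 0.030, "sex": -0.50, "weight": 0.005, "height": -0.002},
    "mi_prevalent": {"age": 0.07, "sex": -1.00, "weight": 0.012, "height": -0.004},
    "mi_incident": {"age": 0.07, "sex": -0.90, "weight": 0.010, "height": -0.004},
}


class ConfigError(ValueError):
    """Raised when a simulation configuration field is out of bounds."""


@dataclass(frozen=True)
class PlantedEffect:
    """A gene-level causal effect planted into the simulated cohort.

    The effect acts through one *causal feature* per listed omics (the
    gene's first feature in that omics).  The causal feature is z-scored
    within the cohort and contributes

        ``omics_effects[o] * outcome_effects[y] * z_feature``

    to outcome ``y``'s linear predictor (log-odds for binary outcomes,
    log-score slope for the continuous CAC score, log-hazard for incident
    MI).  Effects are therefore expressed per standard deviation of the
    causal feature, which makes effect sizes comparable across omics.
    """

    gene_id: str
    omics_effects: dict[str, float]
    outcome_effects: dict[str, float]

    @property
    def concordant(self) -> bool:
        """True when the effect spans all three omics."""
        return set(self.omics_effects) == set(OMICS_TYPES)


@dataclass(frozen=True)
class OutcomeParams:
    """Marginal calibration targets for the four outcomes.

    Defaults emulate the study cohort (n=3106): CAC prevalence 45.2%,
    log-median CAC score log(67.8), log-scale SD solved from the printed
    IQR (10.8, 274.9) of a log-normal, prevalent MI 2.1%, and an incidence
    rate giving ~60 events over a mean 8.2-year follow-up.
    """

    cac_prevalence: float = 0.452
    cac_score_log_median: float = math.log(67.8)
    # (log 274.9 - log 10.8) / (2 * 0.6745) for a log-normal IQR
    cac_score_log_sd: float = 2.40
    mi_prevalent_fraction: float = 0.021
    mi_incidence_rate: float = 0.00235  # events per person-year
    followup_years_mean: float = 8.2
    admin_censor_years: float = 9.2


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 3106
    n_genes: int = 2000
    features_per_gene_by_omics: dict[str, int] = field(
        default_factory=lambda: {"genotype": 3, "methylation": 3, "expression": 3}
    )
    n_families: int | None = None  # None: family sizes drawn uniform 1-6
    maf_range: tuple[float, float] = (0.05, 0.5)
    planted_effects: tuple[PlantedEffect, ...] = ()
    outcome_params: OutcomeParams = field(default_factory=OutcomeParams)
    seed: int = 0
    family_intercept_sd: float = 0.5
    technical_covariates: bool = True

    def __post_init__(self):
        object.__setattr__(self, "planted_effects", tuple(self.planted_effects))
        self.validate()

    def validate(self) -> None:
        if self.n_samples <= 0:
            raise ConfigError("n_samples must be > 0")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be > 0")
        for o, k in self.features_per_gene_by_omics.items():
            if o not in OMICS_TYPES:
                raise ConfigError(f"features_per_gene_by_omics: unknown omics {o!r}")
            if k <= 0:
                raise ConfigError("features_per_gene_by_omics counts must be > 0")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range bounds must be ordered and within (0, 0.5]")
        if self.n_families is not None and not (0 < self.n_families <= self.n_samples):
            raise ConfigError("n_families must be in [1, n_samples]")
        if self.family_intercept_sd < 0:
            raise ConfigError("family_intercept_sd must be >= 0")
        gene_ids = set(self.gene_ids())
        for eff in self.planted_effects:
            if eff.gene_id not in gene_ids:
                raise ConfigError(f"planted gene {eff.gene_id!r} not in gene universe")
            bad = set(eff.omics_effects) - set(OMICS_TYPES)
            if bad:
                raise ConfigError(f"planted effect lists unknown omics {sorted(bad)}")
            bad = set(eff.outcome_effects) - set(OUTCOMES)
            if bad:
                raise ConfigError(f"planted effect lists unknown outcomes {sorted(bad)}")
        p = self.outcome_params
        for name in ("cac_prevalence", "mi_prevalent_fraction"):
            v = getattr(p, name)
            if not (0.0 < v < 1.0):
                raise ConfigError(f"{name} must be in (0, 1)")
        for name in (
            "cac_score_log_sd",
            "mi_incidence_rate",
            "followup_years_mean",
            "admin_censor_years",
        ):
            if getattr(p, name) <= 0:
                raise ConfigError(f"{name} must be > 0")

    def gene_ids(self) -> list[str]:
        return [f"G{i:05d}" for i in range(self.n_genes)]


@dataclass
class OmicsDataset:
    """One sample-by-feature numeric matrix tagged with its omics type."""

    omics_type: str
    sample_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.feature_ids)):
            raise ValueError("values shape does not match id lists")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample_ids")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature_ids")
        if self.omics_type == "genotype" and self.values.size:
            if np.nanmin(self.values) < 0 or np.nanmax(self.values) > 2:
                raise ValueError("genotype dosages must lie in [0, 2]")
        if self.omics_type == "methylation" and self.values.size:
            if np.nanmin(self.values) <= 0 or np.nanmax(self.values) >= 1:
                raise ValueError("methylation beta values must lie in (0, 1)")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.feature_ids)

    def subset_samples(self, sample_ids: list[str]) -> "OmicsDataset":
        idx = pd.Index(self.sample_ids).get_indexer(sample_ids)
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return OmicsDataset(
            self.omics_type, list(sample_ids), list(self.feature_ids), self.values[idx]
        )


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), stream])


def _family_sizes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n = config.n_samples
    if config.n_families is None:
        sizes: list[int] = []
        total = 0
        while total < n:
            s = int(rng.integers(1, 7))
            sizes.append(s)
            total += s
        sizes[-1] -= total - n
        return np.asarray(sizes, dtype=int)
    # exactly n_families non-empty groups: random composition of n
    g = config.n_families
    if g == n:
        return np.ones(n, dtype=int)
    cuts = np.sort(rng.choice(n - 1, size=g - 1, replace=False)) + 1
    bounds = np.concatenate([[0], cuts, [n]])
    return np.diff(bounds)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, OmicsDataset], pd.DataFrame, pd.DataFrame]:
    """Draw the omics matrices, covariate table and feature->gene map.

    Returns ``(omics, covariates, feature_map)`` where ``omics`` maps each
    omics type to an :class:`OmicsDataset`, ``covariates`` has one row per
    sample (age, sex, weight, height, family_id, technical covariates) and
    ``feature_map`` has columns ``feature_id, gene_id, omics_type``.

    Genotype dosages are binomial(2, MAF) with a shared-parent family
    component (each family has two latent binomial parents; members receive
    one Bernoulli transmission per parent, so the marginal mean stays at
    2*MAF while siblings are correlated).  Methylation is logit-normal in
    (0, 1); expression is log-normal.  Fully determined by ``config.seed``.
    """
    config.validate()
    n = config.n_samples
    sample_ids = [f"S{i:06d}" for i in range(n)]
    gene_ids = config.gene_ids()

    rng_fam = _rng(config.seed, 1)
    sizes = _family_sizes(config, rng_fam)
    family_id = np.repeat(np.arange(len(sizes)), sizes)
    fam_labels = [f"F{i:05d}" for i in family_id]

    rng_cov = _rng(config.seed, 2)
    sex = (rng_cov.random(n) < 0.489).astype(int)  # 1 = female
    age = np.clip(rng_cov.normal(57.0, 10.0, n), 30.0, 90.0)
    height = np.where(
        sex == 1, rng_cov.normal(163.0, 6.5, n), rng_cov.normal(177.0, 7.0, n)
    )
    weight = np.where(
        sex == 1, rng_cov.normal(70.0, 13.0, n), rng_cov.normal(85.0, 14.0, n)
    )
    weight = np.clip(weight, 35.0, 180.0)
    covariates = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": age,
            "sex": sex,
            "weight": weight,
            "height": height,
            "family_id": fam_labels,
        }
    )
    if config.technical_covariates:
        for o in OMICS_TYPES:
            covariates[f"tech_{o}"] = rng_cov.standard_normal(n)

    map_rows: list[tuple[str, str, str]] = []
    omics: dict[str, OmicsDataset] = {}
    for stream, omics_type in enumerate(OMICS_TYPES, start=3):
        k = config.features_per_gene_by_omics.get(omics_type, 0)
        if k == 0:
            continue
        tag = _FEATURE_TAG[omics_type]
        feature_ids = [f"{g}_{tag}{j}" for g in gene_ids for j in range(k)]
        n_feat = len(feature_ids)
        rng_o = _rng(config.seed, stream)
        if omics_type == "genotype":
            lo, hi = config.maf_range
            maf = rng_o.uniform(lo, hi, n_feat)
            n_fam = len(sizes)
            p1 = rng_o.binomial(2, maf, size=(n_fam, n_feat)) / 2.0
            p2 = rng_o.binomial(2, maf, size=(n_fam, n_feat)) / 2.0
            values = rng_o.binomial(1, p1[family_id]).astype(float)
            values += rng_o.binomial(1, p2[family_id])
        elif omics_type == "methylation":
            mu = rng_o.normal(0.0, 2.0, n_feat)
            z = mu[None, :] + 0.8 * rng_o.standard_normal((n, n_feat))
            if config.technical_covariates:
                z += 0.1 * covariates["tech_methylation"].to_numpy()[:, None]
            values = expit(z)
            np.clip(values, 1e-12, 1 - 1e-12, out=values)
        else:  # expression
            mu = rng_o.normal(1.0, 0.5, n_feat)
            z = mu[None, :] + 0.5 * rng_o.standard_normal((n, n_feat))
            if config.technical_covariates:
                z += 0.1 * covariates["tech_expression"].to_numpy()[:, None]
            values = np.exp(z)
        omics[omics_type] = OmicsDataset(omics_type, sample_ids, feature_ids, values)
        map_rows.extend(
            (fid, fid.rsplit("_", 1)[0], omics_type) for fid in feature_ids
        )

    feature_map = pd.DataFrame(map_rows, columns=["feature_id", "gene_id", "omics_type"])
    return omics, covariates, feature_map


def _causal_column(omics: OmicsDataset, gene_id: str) -> int:
    # causal feature = the gene's lexicographically first feature in the omics
    prefix = f"{gene_id}_"
    for j, fid in enumerate(omics.feature_ids):
        if fid.startswith(prefix):
            return j
    raise KeyError(f"planted gene {gene_id!r} has no feature in {omics.omics_type}")


def _planted_lp(
    omics: dict[str, OmicsDataset],
    effects: tuple[PlantedEffect, ...],
    outcome: str,
    n: int,
) -> np.ndarray:
    lp = np.zeros(n)
    for eff in effects:
        w = eff.outcome_effects.get(outcome, 0.0)
        if w == 0.0:
            continue
        for o, loading in eff.omics_effects.items():
            if loading == 0.0:
                continue
            if o not in omics:
                raise KeyError(f"planted effect targets missing omics {o!r}")
            col = _causal_column(omics[o], eff.gene_id)
            x = omics[o].values[:, col]
            sd = x.std()
            if sd == 0:
                continue
            lp += loading * w * (x - x.mean()) / sd
    return lp


def _covariate_lp(covariates: pd.DataFrame, outcome: str) -> np.ndarray:
    betas = _COVARIATE_BETAS[outcome]
    lp = np.zeros(len(covariates))
    for name, b in betas.items():
        v = covariates[name].to_numpy(dtype=float)
        lp += b * (v - v.mean())
    return lp


def _solve_intercept(lp: np.ndarray, target: float) -> float:
    def f(c):
        return expit(c + lp).mean() - target

    return brentq(f, -40.0, 40.0, xtol=1e-12)


def _dropout_rate(mean_followup: float, admin: float) -> float:
    """Exponential dropout rate so E[min(Exp(rate), admin)] = mean_followup."""
    if mean_followup >= admin:
        return 1e-12

    def f(r):
        return (1.0 - math.exp(-r * admin)) / r - mean_followup

    return brentq(f, 1e-8, 50.0, xtol=1e-12)


def _calibrate_incidence(
    base_rate: float, mult: np.ndarray, r_drop: float, admin: float
) -> np.ndarray:
    """Scale per-sample hazards so the expected event count matches the
    homogeneous-rate cohort (hazard heterogeneity would otherwise depress
    the marginal incidence below the configured rate)."""

    def p_event(r: np.ndarray | float) -> np.ndarray | float:
        tot = r + r_drop
        return (r / tot) * (1.0 - np.exp(-tot * admin))

    target = float(np.mean(p_event(base_rate)))

    def f(kappa: float) -> float:
        return float(np.mean(p_event(kappa * base_rate * mult))) - target

    kappa = brentq(f, 1e-6, 1e4, xtol=1e-12)
    return kappa * base_rate * mult


def generate_outcomes(
    omics: dict[str, OmicsDataset],
    covariates: pd.DataFrame,
    config: SimulationConfig,
) -> pd.DataFrame:
    """Draw the four outcomes given the generated omics and covariates.

    Binary outcomes come from logistic models whose intercepts are solved by
    root-finding on the realised linear predictor so the expected prevalence
    hits the configured target.  The continuous CAC score is log-normal
    around the configured log-median, defined only where CAC is present.
    Incident MI is exponential with rate scaled by the planted log-hazard
    contributions, subject to exponential dropout and administrative
    censoring; prevalent-MI samples are excluded from the incident risk set
    (``mi_time`` is missing for them).
    """
    config.validate()
    n = len(covariates)
    for o, ds in omics.items():
        if list(ds.sample_ids) != list(covariates["sample_id"]):
            raise ValueError(f"sample ids of {o} omics not aligned with covariates")
    p = config.outcome_params
    rng = _rng(config.seed, 17)

    fam_codes, fam_idx = np.unique(covariates["family_id"].to_numpy(), return_inverse=True)
    n_fam = len(fam_codes)

    def fam_intercept() -> np.ndarray:
        if config.family_intercept_sd == 0:
            return np.zeros(n)
        u = rng.normal(0.0, config.family_intercept_sd, n_fam)
        return u[fam_idx]

    out = pd.DataFrame({"sample_id": covariates["sample_id"].to_numpy()})

    # --- CAC presence -----------------------------------------------------
    lp = (
        _covariate_lp(covariates, "cac_present")
        + _planted_lp(omics, config.planted_effects, "cac_present", n)
        + fam_intercept()
    )
    c0 = _solve_intercept(lp, p.cac_prevalence)
    out["cac_present"] = rng.binomial(1, expit(c0 + lp)).astype(int)

    # --- continuous CAC score (CAC-positive subset only) ------------------
    pos = out["cac_present"].to_numpy() == 1
    lp_score = (
        _covariate_lp(covariates, "cac_score")
        + _planted_lp(omics, config.planted_effects, "cac_score", n)
        + fam_intercept()
    )
    score = np.full(n, np.nan)
    if pos.any():
        lp_pos = lp_score[pos] - lp_score[pos].mean()
        log_score = (
            p.cac_score_log_median
            + lp_pos
            + rng.normal(0.0, p.cac_score_log_sd, pos.sum())
        )
        score[pos] = np.exp(log_score)
    out["cac_score"] = score

    # --- prevalent MI ------------------------------------------------------
    lp_mi = (
        _covariate_lp(covariates, "mi_prevalent")
        + _planted_lp(omics, config.planted_effects, "mi_prevalent", n)
        + fam_intercept()
    )
    c0 = _solve_intercept(lp_mi, p.mi_prevalent_fraction)
    out["mi_prevalent"] = rng.binomial(1, expit(c0 + lp_mi)).astype(int)

    # --- incident MI (prevalent cases leave the risk set) ------------------
    lp_inc = (
        _covariate_lp(covariates, "mi_incident")
        + _planted_lp(omics, config.planted_effects, "mi_incident", n)
        + fam_intercept()
    )
    lp_inc -= lp_inc.mean()
    mult = np.exp(lp_inc)
    r_drop = _dropout_rate(p.followup_years_mean, p.admin_censor_years)
    rate = _calibrate_incidence(
        p.mi_incidence_rate, mult, r_drop, p.admin_censor_years
    )
    t_event = rng.exponential(1.0 / rate)
    t_censor = np.minimum(rng.exponential(1.0 / r_drop, n), p.admin_censor_years)
    t_censor = np.maximum(t_censor, 1e-6)
    time = np.minimum(t_event, t_censor)
    event = (t_event <= t_censor).astype(int)
    prevalent = out["mi_prevalent"].to_numpy() == 1
    time[prevalent] = np.nan
    event[prevalent] = 0
    out["mi_time"] = time
    out["mi_event"] = event
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[dict[str, OmicsDataset], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: ``(omics, covariates, feature_map, outcomes)``."""
    omics, covariates, feature_map = generate_cohort(config)
    outcomes = generate_outcomes(omics, covariates, config)
    return omics, covariates, feature_map, outcomes


# ---------------------------------------------------------------------------
# fixture I/O (TSV dialects; see also transomics.io for association tables)
# ---------------------------------------------------------------------------

def _float_repr(v) -> str:
    # shortest exact-roundtrip decimal form (numpy scalars repr as np.float64)
    return repr(float(v))


def write_fixture(
    omics: dict[str, OmicsDataset],
    covariates: pd.DataFrame,
    feature_map: pd.DataFrame,
    outcomes: pd.DataFrame,
    directory: str | os.PathLike,
) -> None:
    """Write the cohort bundle as TSV files under ``directory``.

    Omics matrices use ``sample_id`` plus one column per feature with '.'
    for missing values; ``cac_score`` and ``mi_time`` are left empty where
    undefined.  Files round-trip losslessly through :func:`read_fixture`.
    """
    directory = os.fspath(directory)
    if directory == "":
        raise OSError("empty directory name")
    os.makedirs(directory, exist_ok=True)
    for o, ds in omics.items():
        frame = ds.to_frame()
        frame.index.name = "sample_id"
        # repr is the shortest exact-roundtrip decimal form of a float
        frame.to_csv(
            os.path.join(directory, f"{o}.tsv"), sep="\t", na_rep=".",
            float_format=_float_repr,
        )
    covariates.to_csv(
        os.path.join(directory, "covariates.tsv"), sep="\t", index=False,
        float_format=_float_repr,
    )
    feature_map.to_csv(os.path.join(directory, "feature_map.tsv"), sep="\t", index=False)
    outcomes.to_csv(
        os.path.join(directory, "outcomes.tsv"), sep="\t", index=False, na_rep="",
        float_format=_float_repr,
    )


def read_fixture(
    directory: str | os.PathLike,
) -> tuple[dict[str, OmicsDataset], pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Read a bundle written by :func:`write_fixture`."""
    directory = os.fspath(directory)
    omics: dict[str, OmicsDataset] = {}
    for o in OMICS_TYPES:
        path = os.path.join(directory, f"{o}.tsv")
        if not os.path.exists(path):
            continue
        frame = pd.read_csv(
            path, sep="\t", index_col="sample_id", na_values=".",
            float_precision="round_trip",
        )
        omics[o] = OmicsDataset(
            o, list(frame.index), list(frame.columns), frame.to_numpy(dtype=float)
        )
    covariates = pd.read_csv(
        os.path.join(directory, "covariates.tsv"), sep="\t",
        float_precision="round_trip",
    )
    feature_map = pd.read_csv(os.path.join(directory, "feature_map.tsv"), sep="\t")
    outcomes = pd.read_csv(
        os.path.join(directory, "outcomes.tsv"), sep="\t",
        float_precision="round_trip",
    )
    return omics, covariates, feature_map, outcomes


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Return a copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
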