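"""Synthetic multi-omics cohort generator with known survival structure.

The generator plants a low-dimensional latent factor model shared across
modalities: a subset of latent factors carries proportional-hazards survival
signal, informative features load on modality-specific subsets of latents,
and patient subtypes are planted as mean shifts of the hazard-carrying
latents (so subtypes differ both in feature space and in survival).

Expression modalities are emitted as negative-binomial raw counts plus
log-scale library-size-normalized values; methylation as logit-normal beta
values. Survival times follow a Weibull proportional-hazards model with
independent exponential censoring whose rate is solved numerically to hit a
target censored fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datamodel import (
    EXPRESSION_MODALITIES,
    MAX_FOLLOWUP_DAYS,
    MultiOmicsDataset,
    write_json,
)

logger = logging.getLogger(__name__)

_DEFAULT_FEATURES = {"mrna": 1000, "mirna": 300, "lncrna": 500, "methylation": 1500}
# hazard-carrying latents are 0..n_survival_latents-1; allocations overlap so
# several modalities carry partial survival signal
_DEFAULT_ALLOCATION = {
    "mrna": (0, 3),
    "lncrna": (1, 4),
    "mirna": (2, 5),
    "methylation": (0, 1),
}

CLINICAL_COLUMNS = [
    "age",
    "sex",
    "tumor_dim1_cm",
    "tumor_dim2_cm",
    "tumor_dim3_cm",
    "primary_diagnosis",
    "prior_malignancy",
    "synchronous_malignancy",
    "pathological_stage",
    "stage_t",
    "stage_n",
    "stage_m",
    "pack_years",
]

STAGE_LEVELS = {
    "pathological_stage": [
        "Stage 1", "Stage 1A", "Stage 1B",
        "Stage 2", "Stage 2A", "Stage 2B",
        "Stage 3", "Stage 3A", "Stage 3B",
        "Stage 4",
    ],
    "stage_t": ["T1", "T1a", "T1b", "T2", "T2a", "T2b", "T3", "T4"],
    "stage_n": ["N0", "N1", "N2"],
    "stage_m": ["M0", "M1", "M1a", "M1b"],
}

# missing-sample fractions mirroring the reference clinical table (counts/732)
_MISSING_FRACTIONS = {
    "age": 14 / 732,
    "tumor_dims": 220 / 732,
    "synchronous_malignancy": 54 / 732,
    "pathological_stage": 8 / 732,
    "stage_t": 3 / 732,
    "stage_n": 12 / 732,
    "stage_m": 199 / 732,
    "pack_years": 180 / 732,
}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``signal_allocation`` maps each modality to the latent indices its
    informative features may load on; hazard signal lives on latents
    ``0..n_survival_latents-1``.
    """

    n_patients: int = 400
    cohort_fraction: float = 0.55
    features_per_modality: Mapping[str, int] = field(
        default_factory=lambda: dict(_DEFAULT_FEATURES)
    )
    n_latent: int = 6
    n_survival_latents: int = 3
    signal_allocation: Mapping[str, tuple[int, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_ALLOCATION)
    )
    frac_informative: float = 0.10
    effect_size: float = 0.8
    baseline_hazard_scale: float = 1200.0  # days
    baseline_hazard_shape: float = 1.2
    censoring_rate: float = 0.6
    missing_rate: float = 0.0
    missing_elevated_frac: float = 0.0
    missing_elevated_rate: float = 0.5
    n_subtypes: int = 2
    subtype_shift: float = 0.0
    clinical_effect: float = 0.15
    nb_dispersion: float = 0.2
    loading_low: float = 0.4
    loading_high: float = 0.9
    probes_per_gene: int = 3
    probe_fraction_in_scope: float = 0.8
    frac_short_followup: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0:
            raise ConfigurationError("n_patients must be positive")
        for name, n in self.features_per_modality.items():
            if n <= 0:
                raise ConfigurationError(f"non-positive feature count for {name!r}")
        for frac_name in (
            "cohort_fraction", "frac_informative", "censoring_rate",
            "missing_rate", "missing_elevated_frac", "missing_elevated_rate",
            "probe_fraction_in_scope", "frac_short_followup",
        ):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{frac_name}={v} outside [0, 1]")
        if self.n_survival_latents > self.n_latent:
            raise ConfigurationError("n_survival_latents exceeds n_latent")
        for name, latents in self.signal_allocation.items():
            if name not in self.features_per_modality:
                raise ConfigurationError(
                    f"signal_allocation names unknown modality {name!r}"
                )
            if any(l < 0 or l >= self.n_latent for l in latents):
                raise ConfigurationError(f"latent index out of range for {name!r}")
        if self.n_subtypes < 1:
            raise ConfigurationError("n_subtypes must be >= 1")
        if self.censoring_rate in (0.0, 1.0):
            logger.warning("censoring_rate=%s is a degenerate boundary", self.censoring_rate)


@dataclass
class GroundTruth:
    """What the generator planted, for downstream oracle tests."""

    latent_matrix: pd.DataFrame
    informative_features: dict[str, list[str]]
    subtype_labels: pd.Series
    true_linear_predictor: pd.Series
    # expected between-subtype effect per informative feature: log2 fold
    # change for count modalities, M-value difference for methylation
    subtype_effects: dict[str, pd.Series]
    high_missingness_features: dict[str, list[str]]
    censoring_solution: float

    def de_features(self, modality: str, min_abs_log2fc: float) -> list[str]:
        eff = self.subtype_effects.get(modality)
        if eff is None or eff.empty:
            return []
        return list(eff.index[eff.abs() > min_abs_log2fc])

    def write_json(self, path) -> None:
        write_json(
            {
                "informative_features": self.informative_features,
                "subtype_labels": self.subtype_labels.to_dict(),
                "true_linear_predictor": self.true_linear_predictor.to_dict(),
                "subtype_effects": {k: v.to_dict() for k, v in self.subtype_effects.items()},
                "high_missingness_features": self.high_missingness_features,
                "censoring_solution": self.censoring_solution,
            },
            path,
        )


# --------------------------------------------------------------------------
# probe annotation


def generate_probe_annotation(
    config: SimulationConfig, seed: int | None = None
) -> pd.DataFrame:
    """Emit a methylation probe annotation table.

    Columns: ``probe_id``, ``gene_id``, ``in_cpg_island`` (bool),
    ``upstream_of_tss`` (bool; downstream probes are flagged, never given a
    negative distance), ``distance_upstream_tss`` (bp; distance to TSS on the
    flagged side). A ``probe_fraction_in_scope`` share of probes is both
    in-island and within 1500 bp upstream.
    """
    if "methylation" not in config.features_per_modality:
        raise ConfigurationError("methylation modality absent from configuration")
    n_probes = config.features_per_modality["methylation"]
    rng = np.random.default_rng(config.seed + 104729 if seed is None else seed)
    probe_ids = [f"probe_{i:06d}" for i in range(n_probes)]
    n_genes = max(1, n_probes // max(1, config.probes_per_gene))
    # round-robin so every gene is covered, then shuffle the assignment
    gene_idx = np.arange(n_probes) % n_genes
    rng.shuffle(gene_idx)
    gene_ids = [f"gene_{g:05d}" for g in gene_idx]

    n_scope = int(round(config.probe_fraction_in_scope * n_probes))
    in_scope = np.zeros(n_probes, dtype=bool)
    in_scope[rng.choice(n_probes, size=n_scope, replace=False)] = True

    in_island = np.empty(n_probes, dtype=bool)
    upstream = np.empty(n_probes, dtype=bool)
    distance = np.empty(n_probes, dtype=int)
    in_island[in_scope] = True
    upstream[in_scope] = True
    distance[in_scope] = rng.integers(0, 1501, size=n_scope)
    out = ~in_scope
    n_out = int(out.sum())
    if n_out:
        # fail at least one scope condition per out-of-scope probe
        mode = rng.integers(0, 3, size=n_out)
        in_island[out] = mode != 0
        upstream[out] = mode != 1
        d = np.where(mode == 2, rng.integers(1501, 5001, size=n_out),
                     rng.integers(0, 1501, size=n_out))
        distance[out] = d
    return pd.DataFrame(
        {
            "probe_id": probe_ids,
            "gene_id": gene_ids,
            "in_cpg_island": in_island,
            "upstream_of_tss": upstream,
            "distance_upstream_tss": distance,
        }
    )


# --------------------------------------------------------------------------
# main generator


def generate_dataset(config: SimulationConfig) -> tuple[MultiOmicsDataset, GroundTruth]:
    """Generate one cohort; bit-identical for identical (config, seed)."""
    ss = np.random.SeedSequence(config.seed)
    keys = ["latent", "cohort", "clinical", "survival", "annotation", "missing"] + [
        f"modality:{m}" for m in sorted(config.features_per_modality)
    ]
    children = {k: np.random.default_rng(s) for k, s in zip(keys, ss.spawn(len(keys)))}

    n = config.n_patients
    patient_ids = pd.Index([f"P{i:05d}" for i in range(n)], name="patient_id")

    # subtypes and latent factors
    rng = children["latent"]
    subtypes = rng.integers(0, config.n_subtypes, size=n)
    shift = _subtype_latent_shift(config)  # (n_subtypes, n_latent)
    Z = rng.standard_normal((n, config.n_latent)) + shift[subtypes]
    latent_df = pd.DataFrame(
        Z, index=patient_ids, columns=[f"latent_{j}" for j in range(config.n_latent)]
    )

    cohort = pd.Series(
        np.where(children["cohort"].random(n) < config.cohort_fraction, "A", "B"),
        index=patient_ids, name="cohort",
    )
    clinical = _generate_clinical(config, children["clinical"], patient_ids, cohort)

    annotation = generate_probe_annotation(
        config, seed=children["annotation"].integers(0, 2**63)
    ) if "methylation" in config.features_per_modality else None

    modalities: dict[str, pd.DataFrame] = {}
    counts: dict[str, pd.DataFrame] = {}
    informative: dict[str, list[str]] = {}
    effects: dict[str, pd.Series] = {}
    for name in sorted(config.features_per_modality):
        rng_m = children[f"modality:{name}"]
        if name == "methylation":
            beta, info, eff = _generate_methylation(config, rng_m, Z, subtypes, annotation)
            beta.index = patient_ids
            modalities[name] = beta
        else:
            norm, cnt, info, eff = _generate_expression(config, rng_m, Z, subtypes, name)
            norm.index = patient_ids
            cnt.index = patient_ids
            modalities[name] = norm
            counts[name] = cnt
        informative[name] = info
        effects[name] = eff

    # survival
    rng_s = children["survival"]
    age_z = (clinical["age"].to_numpy(dtype=float) - 66.1) / 9.5
    age_z = np.nan_to_num(age_z, nan=0.0)
    lp = config.effect_size * Z[:, : config.n_survival_latents].sum(axis=1)
    lp = lp + config.clinical_effect * age_z
    time, event, c_rate = _sample_survival(config, rng_s, lp)
    if config.frac_short_followup > 0:
        k = int(round(config.frac_short_followup * n))
        idx = rng_s.choice(n, size=k, replace=False)
        time[idx] = np.resize([0.0, 1.0], k)
        event[idx] = True
    survival = pd.DataFrame({"time_days": time, "event": event}, index=patient_ids)

    dataset = MultiOmicsDataset(
        modalities=modalities,
        counts=counts,
        clinical=clinical,
        survival=survival,
        cohort=cohort,
        probe_annotation=annotation,
    )

    high_missing: dict[str, list[str]] = {m: [] for m in modalities}
    if config.missing_rate > 0 or config.missing_elevated_frac > 0:
        rng_miss = children["missing"]
        elevated: dict[str, list[str]] = {}
        for name, mat in modalities.items():
            pool = [c for c in mat.columns if c not in set(informative[name])]
            k = int(round(config.missing_elevated_frac * mat.shape[1]))
            k = min(k, len(pool))
            elevated[name] = list(rng_miss.choice(pool, size=k, replace=False)) if k else []
        high_missing = elevated
        dataset = inject_missingness(
            dataset,
            config.missing_rate,
            seed=int(rng_miss.integers(0, 2**63)),
            elevated_features=elevated,
            elevated_rate=config.missing_elevated_rate,
        )

    dataset.validate()
    truth = GroundTruth(
        latent_matrix=latent_df,
        informative_features=informative,
        subtype_labels=pd.Series(subtypes, index=patient_ids, name="subtype"),
        true_linear_predictor=pd.Series(lp, index=patient_ids, name="lp"),
        subtype_effects=effects,
        high_missingness_features=high_missing,
        censoring_solution=c_rate,
    )
    return dataset, truth


def _subtype_latent_shift(config: SimulationConfig) -> np.ndarray:
    """Per-subtype mean offsets of the hazard-carrying latents."""
    shift = np.zeros((config.n_subtypes, config.n_latent))
    if config.n_subtypes > 1 and config.subtype_shift != 0.0:
        # symmetric spread so the population stays centered
        levels = np.linspace(-0.5, 0.5, config.n_subtypes) * config.subtype_shift * 2
        shift[:, : config.n_survival_latents] = levels[:, None]
    return shift


def _feature_loadings(config, rng, n_feat, modality):
    """One (latent index, coefficient) pair per informative feature."""
    n_info = int(np.ceil(config.frac_informative * n_feat))
    info_idx = np.sort(rng.choice(n_feat, size=n_info, replace=False))
    allocation = np.asarray(
        config.signal_allocation.get(modality, range(config.n_latent)), dtype=int
    )
    latent_of = allocation[rng.integers(0, len(allocation), size=n_info)]
    coef = rng.uniform(config.loading_low, config.loading_high, size=n_info)
    coef *= rng.choice([-1.0, 1.0], size=n_info)
    return info_idx, latent_of, coef


def _expected_subtype_effect(config, latent_of, coef):
    """Expected extreme-subtype contrast on the natural-log scale x log2(e)."""
    span = config.subtype_shift * 2 if config.n_subtypes > 1 else 0.0
    survival_latent = latent_of < config.n_survival_latents
    return np.where(survival_latent, coef * span, 0.0) * np.log2(np.e)


def _generate_expression(config, rng, Z, subtypes, modality):
    n, n_feat = Z.shape[0], config.features_per_modality[modality]
    feat_ids = [f"{modality}_{i:05d}" for i in range(n_feat)]
    info_idx, latent_of, coef = _feature_loadings(config, rng, n_feat, modality)

    log_mu = np.tile(rng.uniform(np.log(30.0), np.log(300.0), size=n_feat), (n, 1))
    log_mu[:, info_idx] += Z[:, latent_of] * coef
    libsize = np.exp(rng.normal(0.0, 0.15, size=n))  # relative size factors
    mu = np.exp(np.clip(log_mu, -30, 30)) * libsize[:, None]

    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=mu * alpha) if alpha > 0 else mu
    cnt = rng.poisson(lam).astype(np.int64)
    norm = np.log1p(cnt / libsize[:, None])

    eff = pd.Series(
        _expected_subtype_effect(config, latent_of, coef),
        index=[feat_ids[i] for i in info_idx],
    )
    return (
        pd.DataFrame(norm, columns=feat_ids),
        pd.DataFrame(cnt, columns=feat_ids),
        [feat_ids[i] for i in info_idx],
        eff,
    )


def _generate_methylation(config, rng, Z, subtypes, annotation):
    n, n_probes = Z.shape[0], config.features_per_modality["methylation"]
    feat_ids = list(annotation["probe_id"])
    n_info = int(np.ceil(config.frac_informative * n_probes))
    scope = (
        annotation["in_cpg_island"]
        & annotation["upstream_of_tss"]
        & (annotation["distance_upstream_tss"] <= 1500)
    ).to_numpy()
    # plant signal on probes the CpG-island/TSS filter retains
    pool = np.flatnonzero(scope)
    if len(pool) == 0:
        pool = np.arange(n_probes)
    n_info = min(n_info, len(pool))
    info_idx = np.sort(rng.choice(pool, size=n_info, replace=False))
    allocation = np.asarray(
        config.signal_allocation.get("methylation", range(config.n_latent)), dtype=int
    )
    latent_of = allocation[rng.integers(0, len(allocation), size=n_info)]
    coef = rng.uniform(config.loading_low, config.loading_high, size=n_info)
    coef *= rng.choice([-1.0, 1.0], size=n_info)

    logit = np.tile(rng.normal(0.0, 1.2, size=n_probes), (n, 1))
    logit[:, info_idx] += Z[:, latent_of] * coef
    logit += rng.normal(0.0, 0.4, size=(n, n_probes))
    beta = 1.0 / (1.0 + np.exp(-logit))

    eff = pd.Series(
        _expected_subtype_effect(config, latent_of, coef),
        index=[feat_ids[i] for i in info_idx],
    )
    return pd.DataFrame(beta, columns=feat_ids), [feat_ids[i] for i in info_idx], eff


def _generate_clinical(config, rng, patient_ids, cohort):
    n = len(patient_ids)
    age = np.clip(rng.normal(66.1, 9.5, size=n), 30.0, 95.0)
    dims = np.exp(rng.normal(-0.35, 0.35, size=(n, 3)))
    pack = np.clip(rng.normal(46.2, 28.1, size=n), 0.0, 160.0)
    stage_p = {k: _geometric_probs(len(v)) for k, v in STAGE_LEVELS.items()}
    df = pd.DataFrame(
        {
            "age": age,
            "sex": rng.choice(["Male", "Female"], size=n),
            "tumor_dim1_cm": dims[:, 0],
            "tumor_dim2_cm": dims[:, 1],
            "tumor_dim3_cm": dims[:, 2],
            "primary_diagnosis": np.where(
                cohort.to_numpy() == "A", "Adenocarcinoma", "Squamous cell carcinoma"
            ),
            "prior_malignancy": rng.choice(["Yes", "No"], size=n, p=[0.15, 0.85]),
            "synchronous_malignancy": rng.choice(["Yes", "No"], size=n, p=[0.08, 0.92]),
            "pathological_stage": rng.choice(
                STAGE_LEVELS["pathological_stage"], size=n, p=stage_p["pathological_stage"]
            ),
            "stage_t": rng.choice(STAGE_LEVELS["stage_t"], size=n, p=stage_p["stage_t"]),
            "stage_n": rng.choice(STAGE_LEVELS["stage_n"], size=n, p=stage_p["stage_n"]),
            "stage_m": rng.choice(STAGE_LEVELS["stage_m"], size=n, p=stage_p["stage_m"]),
            "pack_years": pack,
        },
        index=patient_ids,
    )
    # plant missingness mirroring the reference missing-sample counts
    for col, frac in _MISSING_FRACTIONS.items():
        k = int(round(frac * n))
        if k == 0:
            continue
        idx = rng.choice(n, size=k, replace=False)
        if col == "tumor_dims":
            for c in ("tumor_dim1_cm", "tumor_dim2_cm", "tumor_dim3_cm"):
                df.iloc[idx, df.columns.get_loc(c)] = np.nan
        else:
            df.iloc[idx, df.columns.get_loc(col)] = np.nan if df[col].dtype.kind == "f" else None
    return df


def _geometric_probs(k: int) -> np.ndarray:
    p = 0.75 ** np.arange(k)
    return p / p.sum()


def _sample_survival(config, rng, lp):
    """Weibull PH event times + exponential censoring tuned to the target
    censored fraction; administrative cap at the follow-up horizon."""
    n = len(lp)
    shape, scale = config.baseline_hazard_shape, config.baseline_hazard_scale
    u = rng.exponential(1.0, size=n)
    t_event = scale * (u / np.exp(lp)) ** (1.0 / shape)
    t_event = np.maximum(t_event, 1e-3)

    target = min(max(config.censoring_rate, 0.0), 1.0)
    if target <= 0.0:
        time, event, rate = t_event.copy(), np.ones(n, dtype=bool), 0.0
    else:
        target_eff = min(target, 1.0 - 1e-9)

        def censored_frac(log_rate):
            return np.mean(1.0 - np.exp(-np.exp(log_rate) * t_event)) - target_eff

        lo, hi = -30.0, 10.0
        rate = float(np.exp(brentq(censored_frac, lo, hi)))
        t_cens = rng.exponential(1.0 / rate, size=n)
        event = t_event <= t_cens
        time = np.minimum(t_event, t_cens)
    over = time > MAX_FOLLOWUP_DAYS
    time = np.where(over, MAX_FOLLOWUP_DAYS, time)
    event = event & ~over
    return time, event, rate


def inject_missingness(
    dataset: MultiOmicsDataset,
    missing_rate: float,
    seed: int,
    elevated_features: Mapping[str, list[str]] | None = None,
    elevated_rate: float = 0.5,
) -> MultiOmicsDataset:
    """Independently knock out entries of every value matrix.

    Value matrices get NaN; the matching raw-count entries are zeroed so the
    two stay consistent. ``elevated_features`` names per-modality feature
    subsets that receive ``elevated_rate`` instead, giving the downstream
    20%-missingness filter true positives.
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ConfigurationError(f"missing_rate={missing_rate} outside [0, 1]")
    out = dataset.copy()
    rng = np.random.default_rng(seed)
    for name in sorted(out.modalities):
        mat = out.modalities[name]
        rate = np.full(mat.shape[1], missing_rate)
        if elevated_features and name in elevated_features:
            cols = mat.columns.get_indexer(elevated_features[name])
            rate[cols[cols >= 0]] = elevated_rate
        mask = rng.random(mat.shape) < rate[None, :]
        vals = mat.to_numpy(dtype=float, copy=True)
        vals[mask] = np.nan
        out.modalities[name] = pd.DataFrame(vals, index=mat.index, columns=mat.columns)
        if name in out.counts:
            cnt = out.counts[name].to_numpy(copy=True)
            cnt[mask] = 0
            out.counts[name] = pd.DataFrame(
                cnt, index=mat.index, columns=mat.columns
            )
    return out
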