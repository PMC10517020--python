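"""End-to-end experiment orchestration.

One configuration = a modality subset, an integration scheme (early/late), a
dimensionality-reduction method, and a training/evaluation cohort choice.
Each run draws a stratified 80/20 patient split, fits every stage on the
training part only, and reports the Harrell C-index on the held-out test
patients; results aggregate over 5 independent runs (mean +/- SD).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import autoencoder as ae
from . import feature_selection as fs
from . import preprocess as pp
from . import survival as sv
from .datamodel import MultiOmicsDataset

logger = logging.getLogger(__name__)

DR_METHODS = ("lfs_ae", "ae_only", "pca", "lfs_only")


@dataclass(frozen=True)
class ExperimentConfig:
    modalities: tuple[str, ...] = ("mrna", "mirna", "lncrna", "methylation", "clinical")
    integration: str = "early"  # early | late
    train_cohort: str = "both"  # both | A | B
    eval_cohort: str = "both"  # both | A | B
    dr_method: str = "lfs_ae"
    n_runs: int = 5
    train_fraction: float = 0.8
    seeds: tuple[int, ...] | None = None
    k_caps: dict = field(default_factory=lambda: dict(fs.DEFAULT_K_CAPS))
    bottlenecks: dict | None = None
    top_variance_probes: int = pp.TOP_VARIANCE_PROBES
    ae_overrides: dict = field(default_factory=dict)
    cox_n_folds: int = 5
    cox_n_lambdas: int = 50
    ae_only_cap_factor: int = 4

    def __post_init__(self):
        if self.integration not in ("early", "late"):
            raise ValueError("integration must be 'early' or 'late'")
        if self.dr_method not in DR_METHODS:
            raise ValueError(f"dr_method must be one of {DR_METHODS}")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")

    @property
    def biological(self) -> list[str]:
        return [m for m in self.modalities if m != "clinical"]

    def bottleneck_of(self, modality: str) -> int:
        if self.bottlenecks and modality in self.bottlenecks:
            return int(self.bottlenecks[modality])
        if modality in ae.LATE_BOTTLENECKS and self.k_caps == fs.DEFAULT_K_CAPS:
            return ae.LATE_BOTTLENECKS[modality]
        return max(2, self.k_caps.get(modality, 100) // 10)

    def run_seeds(self) -> list[int]:
        if self.seeds is not None:
            if len(self.seeds) != self.n_runs:
                raise ValueError("seeds length must equal n_runs")
            return list(self.seeds)
        return list(range(self.n_runs))


@dataclass
class RunArtifacts:
    """Fitted state of a single run, kept for the biomarker arm."""

    seed: int
    cindex: float
    cox_fit: sv.CoxFit
    design_all: pd.DataFrame  # all patients x survival-model columns (train-standardized)
    train_ids: pd.Index
    test_ids: pd.Index
    selected_features: dict[str, list[str]]


@dataclass
class RunReport:
    config: ExperimentConfig
    cindices: list[float]
    artifacts: list[RunArtifacts] = field(default_factory=list)
    incomplete: int = 0

    @property
    def mean(self) -> float:
        return float(np.nanmean(self.cindices))

    @property
    def sd(self) -> float:
        return float(np.nanstd(self.cindices, ddof=1)) if len(self.cindices) > 1 else 0.0

    def summary(self) -> dict:
        return {
            "modalities": list(self.config.modalities),
            "integration": self.config.integration,
            "dr_method": self.config.dr_method,
            "cindices": self.cindices,
            "mean": self.mean,
            "sd": self.sd,
            "incomplete": self.incomplete,
        }

    def median_run(self) -> RunArtifacts:
        """The run with the median test C-index (designated run for the
        subtype arm)."""
        order = np.argsort(self.cindices, kind="stable")
        return self.artifacts[order[len(order) // 2]]


def split_train_test(
    dataset: MultiOmicsDataset, fraction: float = 0.8, seed: int = 0
) -> tuple[MultiOmicsDataset, MultiOmicsDataset]:
    """Patient-level split stratified jointly by event indicator and cohort."""
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    event = dataset.survival["event"].to_numpy(dtype=bool)
    cohort = (
        dataset.cohort.to_numpy()
        if dataset.cohort is not None
        else np.repeat("A", dataset.n_patients)
    )
    ids = dataset.patient_ids.to_numpy()
    train_ids, test_ids = [], []
    for co in np.unique(cohort):
        for ev in (False, True):
            stratum = ids[(cohort == co) & (event == ev)]
            if len(stratum) == 0:
                continue
            if len(stratum) < 2:
                raise ValueError(
                    f"stratum (cohort={co}, event={ev}) has {len(stratum)} "
                    "patient(s); cannot split"
                )
            perm = rng.permutation(stratum)
            n_train = int(round(fraction * len(stratum)))
            n_train = min(max(n_train, 1), len(stratum) - 1)
            train_ids.extend(perm[:n_train])
            test_ids.extend(perm[n_train:])
    # restore the dataset's patient order
    train_idx = dataset.patient_ids[dataset.patient_ids.isin(train_ids)]
    test_idx = dataset.patient_ids[dataset.patient_ids.isin(test_ids)]
    return dataset.subset_patients(train_idx), dataset.subset_patients(test_idx)


def _make_encoder_spec(config: ExperimentConfig, input_dim: int,
                       bottleneck: int, seed: int) -> ae.EncoderSpec:
    defaults = dict(noise_type="zeros", noise_level=0.3, activation="sigmoid")
    defaults.update(config.ae_overrides)
    return ae.EncoderSpec(
        input_dim=input_dim, bottleneck_dim=bottleneck, seed=seed, **defaults
    )


def _pca_embed(train: pd.DataFrame, full: pd.DataFrame, n_components: int, prefix: str):
    from sklearn.decomposition import PCA

    n_components = min(n_components, train.shape[1], train.shape[0] - 1)
    pca = PCA(n_components=n_components, svd_solver="full", random_state=0)
    pca.fit(train.to_numpy())
    cols = [f"{prefix}pc_{i:03d}" for i in range(n_components)]
    return pd.DataFrame(pca.transform(full.to_numpy()), index=full.index, columns=cols)


def _reduce(config, seed, train_mats, full_mats):
    """Dimensionality reduction fitted on train, applied to all patients.

    ``train_mats``/``full_mats`` map modality -> standardized selected
    matrices (train patients only / every patient).
    """
    method, integration = config.dr_method, config.integration
    if method == "lfs_only":
        return pd.concat([full_mats[m] for m in sorted(full_mats)], axis=1)
    if integration == "early":
        train_X = pd.concat([train_mats[m] for m in sorted(train_mats)], axis=1)
        full_X = pd.concat([full_mats[m] for m in sorted(full_mats)], axis=1)
        width = sum(config.bottleneck_of(m) for m in train_mats)
        if method == "pca":
            return _pca_embed(train_X, full_X, width, "early_")
        spec = _make_encoder_spec(config, train_X.shape[1], width, seed)
        model = ae.train_autoencoder(spec, train_X)
        return ae.encode(model, full_X)
    # late integration: one reducer per modality, embeddings concatenated
    parts = []
    for i, m in enumerate(sorted(train_mats)):
        width = config.bottleneck_of(m)
        if method == "pca":
            emb = _pca_embed(train_mats[m], full_mats[m], width, f"{m}_")
        else:
            spec = _make_encoder_spec(config, train_mats[m].shape[1], width, seed + i)
            model = ae.train_autoencoder(spec, train_mats[m])
            emb = ae.encode(model, full_mats[m])
            emb.columns = [f"{m}_{c}" for c in emb.columns]
        parts.append(emb)
    return pd.concat(parts, axis=1)


def _single_run(config: ExperimentConfig, dataset: MultiOmicsDataset, seed: int) -> RunArtifacts:
    train, test = split_train_test(dataset, config.train_fraction, seed)
    if config.train_cohort != "both":
        train = train.subset_patients(train.cohort.index[train.cohort == config.train_cohort])
    if config.eval_cohort != "both":
        test = test.subset_patients(test.cohort.index[test.cohort == config.eval_cohort])

    blocks_all: list[pd.DataFrame] = []
    selected: dict[str, list[str]] = {}
    bio = [m for m in config.biological if m in dataset.modalities]
    if bio:
        state = pp.fit_preprocess(
            train, modalities=bio, top_variance=config.top_variance_probes
        )
        train_z = pp.apply_preprocess(train, state)
        full_z = pp.apply_preprocess(dataset, state)
        t_time, t_event = train.survival["time_days"].to_numpy(), train.survival["event"].to_numpy(bool)

        train_mats, full_mats = {}, {}
        for m in bio:
            if config.dr_method == "ae_only":
                # no supervised screening: cap by training variance instead
                cap = config.k_caps.get(m, 300) * config.ae_only_cap_factor
                var = train_z[m].var(axis=0, ddof=0)
                order = np.argsort(-var.to_numpy(), kind="stable")[:cap]
                cols = list(train_z[m].columns[np.sort(order)])
            else:
                screen = fs.screen_modality(
                    train_z[m], t_time, t_event, config.k_caps.get(m, 300), modality=m
                )
                cols = fs.select_top_k(screen, config.k_caps.get(m, 300))
            selected[m] = cols
            train_mats[m] = train_z[m][cols]
            full_mats[m] = full_z[m][cols]
        blocks_all.append(_reduce(config, seed, train_mats, full_mats))

    if "clinical" in config.modalities:
        enc = pp.ClinicalEncoder().fit(train.clinical)
        blocks_all.append(enc.transform(dataset.clinical))

    if not blocks_all:
        raise ValueError("configuration selects no modalities")
    X_all = pd.concat(blocks_all, axis=1)
    # final column standardization fitted on training patients
    scaler = pp.Scaler().fit(X_all.loc[train.patient_ids])
    X_all = scaler.transform(X_all)

    fit = sv.fit_elastic_net_cox(
        X_all.loc[train.patient_ids],
        train.survival["time_days"].to_numpy(),
        train.survival["event"].to_numpy(bool),
        n_folds=config.cox_n_folds,
        seed=seed,
        n_lambdas=config.cox_n_lambdas,
    )
    risk = sv.predict_risk(fit, X_all.loc[test.patient_ids])
    result = sv.harrell_cindex(
        risk,
        test.survival["time_days"].to_numpy(),
        test.survival["event"].to_numpy(bool),
    )
    return RunArtifacts(
        seed=seed,
        cindex=result.c_index,
        cox_fit=fit,
        design_all=X_all,
        train_ids=train.patient_ids,
        test_ids=test.patient_ids,
        selected_features=selected,
    )


def run_configuration(config: ExperimentConfig, dataset: MultiOmicsDataset) -> RunReport:
    """Execute all runs of one configuration; failed runs are recorded as NaN
    and flagged, remaining seeds still execute."""
    dataset = pp.filter_patients_by_followup(dataset)
    cindices: list[float] = []
    artifacts: list[RunArtifacts] = []
    incomplete = 0
    for seed in config.run_seeds():
        try:
            art = _single_run(config, dataset, seed)
        except Exception:
            logger.exception("run with seed %d failed", seed)
            cindices.append(float("nan"))
            incomplete += 1
            continue
        cindices.append(art.cindex)
        artifacts.append(art)
    return RunReport(config=config, cindices=cindices, artifacts=artifacts,
                     incomplete=incomplete)


def sweep_modality_combinations(
    dataset: MultiOmicsDataset,
    base_config: ExperimentConfig,
    modalities: tuple[str, ...] | None = None,
    keep_artifacts: bool = False,
) -> pd.DataFrame:
    """Run every non-empty modality subset; returns a table ranked by mean
    C-index."""
    pool = list(modalities if modalities is not None else base_config.modalities)
    if len(pool) < 2:
        raise ValueError("need at least 2 modalities to sweep")
    rows = []
    for r in range(1, len(pool) + 1):
        for combo in itertools.combinations(pool, r):
            cfg = replace(base_config, modalities=combo)
            report = run_configuration(cfg, dataset)
            rows.append(
                {
                    "modalities": "+".join(combo),
                    "n_modalities": len(combo),
                    "integration": cfg.integration,
                    "mean_cindex": report.mean,
                    "sd_cindex": report.sd,
                    "incomplete": report.incomplete,
                }
            )
    table = pd.DataFrame(rows).sort_values("mean_cindex", ascending=False)
    return table.reset_index(drop=True)


@dataclass
class ComparisonResult:
    p_value: float
    degenerate: bool = False


def compare_configurations(report_a, report_b) -> ComparisonResult:
    """Welch two-sample t-test on the per-run C-index lists."""
    a = np.asarray(report_a.cindices if hasattr(report_a, "cindices") else report_a, float)
    b = np.asarray(report_b.cindices if hasattr(report_b, "cindices") else report_b, float)
    a, b = a[~np.isnan(a)], b[~np.isnan(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 runs per configuration")
    if a.var(ddof=1) == 0.0 and b.var(ddof=1) == 0.0:
        return ComparisonResult(p_value=1.0 if a.mean() == b.mean() else 0.0, degenerate=True)
    t = sps.ttest_ind(a, b, equal_var=False)
    return ComparisonResult(p_value=float(t.pvalue), degenerate=False)
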