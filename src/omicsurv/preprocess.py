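"""Filtering, train-fitted scaling/imputation, methylation probe pipeline and
clinical encoding.

Every statistic applied to held-out data (medians, means, SDs, retained
feature sets) is fitted on training patients only; the transform objects in
this module are the audit trail for that guarantee.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datamodel import (
    EXPRESSION_MODALITIES,
    EmptyModalityError,
    MultiOmicsDataset,
)

logger = logging.getLogger(__name__)

MISSINGNESS_THRESHOLD = 0.20
MAX_UPSTREAM_BP = 1500
TOP_VARIANCE_PROBES = 25000
M_VALUE_EPS = 1e-6

CONTINUOUS_CLINICAL = ("age", "tumor_volume", "pack_years")
ORDINAL_CLINICAL = ("pathological_stage", "stage_t", "stage_n", "stage_m")
CATEGORICAL_CLINICAL = (
    "sex",
    "primary_diagnosis",
    "prior_malignancy",
    "synchronous_malignancy",
)
MISSING_LEVEL = "__missing__"


def filter_features_by_missingness(
    matrix: pd.DataFrame, threshold: float = MISSINGNESS_THRESHOLD, name: str = "modality"
) -> pd.DataFrame:
    """Drop features whose zero-or-missing fraction is strictly above
    ``threshold`` (exactly at the threshold is retained); feature order
    preserved."""
    vals = matrix.to_numpy(dtype=float)
    bad = np.isnan(vals) | (vals == 0.0)
    frac = bad.mean(axis=0)
    keep = frac <= threshold
    if not keep.any():
        raise EmptyModalityError(f"all features of {name!r} failed the missingness filter")
    return matrix.loc[:, keep]


def filter_patients_by_followup(dataset: MultiOmicsDataset) -> MultiOmicsDataset:
    """Drop patients with follow-up time of 0 or 1 day from every component."""
    if dataset.survival is None:
        raise ValueError("dataset has no survival outcomes")
    keep = dataset.survival.index[dataset.survival["time_days"] > 1.0]
    if len(keep) == 0:
        raise EmptyModalityError("no patients left after follow-up filter")
    out = dataset.subset_patients(keep)
    out.validate()
    return out


@dataclass
class Scaler:
    """Train-fitted per-feature median imputation followed by z-scoring.

    Imputation happens before standardization (z-scoring a matrix that still
    contains NaN is ill-defined); means/SDs are computed on the imputed
    training matrix with the population (ddof=0) convention, so the
    transformed training matrix has exact zero mean and unit variance.
    Zero-variance features are dropped with a warning.
    """

    median: pd.Series | None = None
    mean: pd.Series | None = None
    sd: pd.Series | None = None

    def fit(self, train: pd.DataFrame) -> "Scaler":
        median = train.median(axis=0, skipna=True)
        # a column that is entirely NaN has no median; treat as zero-variance
        median = median.fillna(0.0)
        imputed = train.fillna(median)
        mean = imputed.mean(axis=0)
        sd = imputed.std(axis=0, ddof=0)
        keep = sd > 0
        if (~keep).any():
            logger.warning(
                "dropping %d zero-variance feature(s): %s...",
                int((~keep).sum()), list(sd.index[~keep][:5]),
            )
        self.median, self.mean, self.sd = median[keep], mean[keep], sd[keep]
        return self

    @property
    def columns(self) -> pd.Index:
        return self.median.index

    def transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        cols = self.columns
        mat = matrix.loc[:, cols].fillna(self.median)
        return (mat - self.mean) / self.sd

    def inverse_transform(self, matrix: pd.DataFrame) -> pd.DataFrame:
        return matrix * self.sd + self.mean

    def to_json(self, path: str | Path) -> None:
        payload = {
            "median": self.median.to_dict(),
            "mean": self.mean.to_dict(),
            "sd": self.sd.to_dict(),
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Scaler":
        payload = json.loads(Path(path).read_text())
        return cls(
            median=pd.Series(payload["median"]),
            mean=pd.Series(payload["mean"]),
            sd=pd.Series(payload["sd"]),
        )


def fit_scaler(train: pd.DataFrame) -> Scaler:
    return Scaler().fit(train)


def apply_scaler(matrix: pd.DataFrame, scaler: Scaler) -> pd.DataFrame:
    return scaler.transform(matrix)


def filter_methylation_probes(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    missing_threshold: float = MISSINGNESS_THRESHOLD,
    max_upstream: int = MAX_UPSTREAM_BP,
    top_variance: int = TOP_VARIANCE_PROBES,
) -> pd.DataFrame:
    """Three-step probe filter, order fixed: missingness -> CpG-island/TSS
    annotation -> top variance.

    Missingness is strict-greater removal; the annotation step keeps probes
    that are in a CpG island, upstream of the TSS, and at most
    ``max_upstream`` bp away (inclusive); variance is computed on beta values
    with missing entries excluded. If fewer than ``top_variance`` probes
    survive, all survivors are kept.
    """
    annot = annotation.set_index("probe_id")
    missing_ids = set(beta.columns) - set(annot.index)
    if missing_ids:
        raise ValueError(f"annotation missing {len(missing_ids)} probes")

    vals = beta.to_numpy(dtype=float)
    frac_missing = np.isnan(vals).mean(axis=0)
    keep = frac_missing <= missing_threshold
    if not keep.any():
        raise EmptyModalityError("all methylation probes failed the missingness filter")
    beta = beta.loc[:, keep]

    annot = annot.loc[beta.columns]
    in_scope = (
        annot["in_cpg_island"].astype(bool)
        & annot["upstream_of_tss"].astype(bool)
        & (annot["distance_upstream_tss"] <= max_upstream)
    ).to_numpy()
    if not in_scope.any():
        raise EmptyModalityError("no methylation probes pass the CpG-island/TSS filter")
    beta = beta.loc[:, in_scope]

    if beta.shape[1] > top_variance:
        var = np.nanvar(beta.to_numpy(dtype=float), axis=0)
        order = np.argsort(-var, kind="stable")[:top_variance]
        keep_mask = np.zeros(beta.shape[1], dtype=bool)
        keep_mask[order] = True
        beta = beta.loc[:, keep_mask]
    return beta


def beta_to_m(beta, eps: float = M_VALUE_EPS):
    """Logit transform of methylation betas on the log2 scale:
    M = log2(beta / (1 - beta)), with beta clamped to [eps, 1 - eps]."""
    arr = np.clip(np.asarray(beta, dtype=float), eps, 1.0 - eps)
    m = np.log2(arr / (1.0 - arr))
    if isinstance(beta, pd.DataFrame):
        return pd.DataFrame(m, index=beta.index, columns=beta.columns)
    if isinstance(beta, pd.Series):
        return pd.Series(m, index=beta.index, name=beta.name)
    return m


# --------------------------------------------------------------------------
# clinical encoding

_STAGE_DIGIT = re.compile(r"(\d+)")


def _main_stage(value) -> float:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    m = _STAGE_DIGIT.search(str(value))
    return float(m.group(1)) if m else np.nan


def compute_tumor_volume(clinical: pd.DataFrame) -> pd.Series:
    """Tumor volume as the plain product of the three recorded dimensions."""
    dims = clinical[["tumor_dim1_cm", "tumor_dim2_cm", "tumor_dim3_cm"]]
    return dims.prod(axis=1, skipna=False).rename("tumor_volume")


@dataclass
class ClinicalEncoder:
    """Encode the 11-feature clinical table to a numeric matrix.

    Continuous features (age, tumor volume, smoking pack-years) are
    median-imputed and z-scored with training statistics; staging variables
    are collapsed to their ordinal main stage (T1a -> 1) and median-imputed;
    the remaining categoricals are one-hot encoded with an explicit missing
    level. Unknown levels at apply time activate the missing level and are
    logged.
    """

    scaler: Scaler | None = None
    ordinal_median: pd.Series | None = None
    categories: dict[str, list[str]] = field(default_factory=dict)

    def _frame(self, clinical: pd.DataFrame) -> pd.DataFrame:
        df = clinical.copy()
        df["tumor_volume"] = compute_tumor_volume(clinical)
        return df

    def fit(self, clinical: pd.DataFrame) -> "ClinicalEncoder":
        df = self._frame(clinical)
        self.scaler = Scaler().fit(df[list(CONTINUOUS_CLINICAL)])
        ordinal = df[list(ORDINAL_CLINICAL)].map(_main_stage)
        self.ordinal_median = ordinal.median(axis=0, skipna=True).fillna(0.0)
        self.categories = {
            col: sorted(df[col].dropna().astype(str).unique())
            for col in CATEGORICAL_CLINICAL
        }
        return self

    def transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        if self.scaler is None:
            raise RuntimeError("encoder not fitted")
        df = self._frame(clinical)
        parts = [self.scaler.transform(df[list(CONTINUOUS_CLINICAL)])]
        ordinal = df[list(ORDINAL_CLINICAL)].map(_main_stage)
        parts.append(ordinal.fillna(self.ordinal_median))
        for col in CATEGORICAL_CLINICAL:
            levels = self.categories[col]
            raw = df[col].astype(object)
            known = raw.isin(levels)
            n_unknown = int((~known & raw.notna()).sum())
            if n_unknown:
                logger.warning("%d unknown level(s) in %r mapped to missing", n_unknown, col)
            onehot = pd.DataFrame(0.0, index=df.index,
                                  columns=[f"{col}={lv}" for lv in levels + [MISSING_LEVEL]])
            for lv in levels:
                onehot.loc[(raw == lv).to_numpy(), f"{col}={lv}"] = 1.0
            onehot.loc[(~known).to_numpy(), f"{col}={MISSING_LEVEL}"] = 1.0
            parts.append(onehot)
        return pd.concat(parts, axis=1)

    def fit_transform(self, clinical: pd.DataFrame) -> pd.DataFrame:
        return self.fit(clinical).transform(clinical)


def encode_clinical(
    train_clinical: pd.DataFrame, apply_clinical: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Convenience wrapper: fit on ``train_clinical``, transform
    ``apply_clinical`` (defaults to the training table)."""
    enc = ClinicalEncoder().fit(train_clinical)
    return enc.transform(train_clinical if apply_clinical is None else apply_clinical)


# --------------------------------------------------------------------------
# dataset-level fit/apply

@dataclass
class PreprocessState:
    """Train-fitted per-modality feature sets and scalers."""

    scalers: dict[str, Scaler] = field(default_factory=dict)
    kept_features: dict[str, list[str]] = field(default_factory=dict)


def fit_preprocess(
    train: MultiOmicsDataset,
    modalities: list[str] | None = None,
    missing_threshold: float = MISSINGNESS_THRESHOLD,
    top_variance: int = TOP_VARIANCE_PROBES,
) -> PreprocessState:
    state = PreprocessState()
    names = modalities if modalities is not None else list(train.modalities)
    for name in names:
        mat = train.modalities[name]
        if name == "methylation":
            if train.probe_annotation is None:
                raise ValueError("methylation present but no probe annotation")
            mat = filter_methylation_probes(
                mat, train.probe_annotation,
                missing_threshold=missing_threshold, top_variance=top_variance,
            )
        elif name in EXPRESSION_MODALITIES:
            mat = filter_features_by_missingness(mat, missing_threshold, name=name)
        scaler = Scaler().fit(mat)
        state.scalers[name] = scaler
        state.kept_features[name] = list(scaler.columns)
    return state


def apply_preprocess(
    dataset: MultiOmicsDataset, state: PreprocessState
) -> dict[str, pd.DataFrame]:
    """Apply train-fitted feature selection + scaling to any cohort."""
    return {
        name: state.scalers[name].transform(dataset.modalities[name])
        for name in state.scalers
    }
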