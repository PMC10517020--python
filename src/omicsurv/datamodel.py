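"""Aligned multi-omics dataset container and plain-text I/O.

All matrices are patients x features :class:`pandas.DataFrame` objects sharing
one patient index. Expression modalities are carried twice: raw negative-
binomial counts (for differential expression) and library-size normalized
log-scale values (for the survival pipeline). Methylation is carried as beta
values in (0, 1). Missing entries are ``NaN`` in the value matrices and ``0``
in the count matrices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

EXPRESSION_MODALITIES = ("mrna", "mirna", "lncrna")
BIOLOGICAL_MODALITIES = ("mrna", "mirna", "lncrna", "methylation")
ALL_MODALITIES = BIOLOGICAL_MODALITIES + ("clinical",)

#: Per-modality feature counts of the full-scale TCGA NSCLC reference data
#: that the synthetic generator scales down from.
FULL_SCALE_FEATURE_COUNTS = {
    "mirna": 1881,
    "mrna": 44162,
    "methylation": 485512,
    "lncrna": 12440,
    "clinical": 11,
}

#: Administrative right-censoring horizon (days).
MAX_FOLLOWUP_DAYS = 11000.0


def total_feature_count(counts: dict[str, int] | None = None) -> int:
    """Sum per-modality feature counts (dataset-schema audit).

    With no argument, audits the full-scale reference schema.
    """
    if counts is None:
        counts = FULL_SCALE_FEATURE_COUNTS
    return int(sum(int(v) for v in counts.values()))


class EmptyModalityError(ValueError):
    """A filter removed every feature (or patient) of a modality."""


@dataclass
class MultiOmicsDataset:
    """One patient cohort with aligned omics matrices, clinical table and
    survival outcomes.

    Attributes
    ----------
    modalities : dict of str -> DataFrame
        Patients x features value matrices (normalized expression, beta
        values for methylation). NaN marks missing.
    counts : dict of str -> DataFrame
        Raw count matrices for expression modalities (same shapes as the
        corresponding ``modalities`` entries).
    clinical : DataFrame
        Typed clinical columns (raw, un-encoded).
    survival : DataFrame
        Columns ``time_days`` (float) and ``event`` (bool; True = death).
    cohort : Series
        Per-patient label in {"A", "B"}.
    probe_annotation : DataFrame or None
        Methylation probe annotation (see :func:`omicsurv.simulate.generate_probe_annotation`).
    """

    modalities: dict[str, pd.DataFrame]
    counts: dict[str, pd.DataFrame] = field(default_factory=dict)
    clinical: pd.DataFrame | None = None
    survival: pd.DataFrame | None = None
    cohort: pd.Series | None = None
    probe_annotation: pd.DataFrame | None = None

    @property
    def patient_ids(self) -> pd.Index:
        return next(iter(self.modalities.values())).index

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def validate(self) -> None:
        """Check the alignment invariant: identical patient ordering across
        every component, unique feature ids within each modality."""
        ref = self.patient_ids
        for name, mat in self.modalities.items():
            if not mat.index.equals(ref):
                raise ValueError(f"modality {name!r} misaligned with patient index")
            if mat.columns.duplicated().any():
                raise ValueError(f"modality {name!r} has duplicate feature ids")
        for name, mat in self.counts.items():
            if not mat.index.equals(ref):
                raise ValueError(f"counts for {name!r} misaligned with patient index")
        for label, comp in (("clinical", self.clinical), ("survival", self.survival)):
            if comp is not None and not comp.index.equals(ref):
                raise ValueError(f"{label} table misaligned with patient index")
        if self.cohort is not None and not self.cohort.index.equals(ref):
            raise ValueError("cohort labels misaligned with patient index")
        if self.survival is not None:
            if (self.survival["time_days"] < 0).any():
                raise ValueError("negative survival times")

    def subset_patients(self, ids) -> "MultiOmicsDataset":
        """Return a new dataset restricted to ``ids`` (order preserved)."""
        ids = pd.Index(ids)
        if len(ids) == 0:
            raise EmptyModalityError("patient subset is empty")
        return MultiOmicsDataset(
            modalities={k: v.loc[ids] for k, v in self.modalities.items()},
            counts={k: v.loc[ids] for k, v in self.counts.items()},
            clinical=None if self.clinical is None else self.clinical.loc[ids],
            survival=None if self.survival is None else self.survival.loc[ids],
            cohort=None if self.cohort is None else self.cohort.loc[ids],
            probe_annotation=self.probe_annotation,
        )

    def copy(self) -> "MultiOmicsDataset":
        return MultiOmicsDataset(
            modalities={k: v.copy() for k, v in self.modalities.items()},
            counts={k: v.copy() for k, v in self.counts.items()},
            clinical=None if self.clinical is None else self.clinical.copy(),
            survival=None if self.survival is None else self.survival.copy(),
            cohort=None if self.cohort is None else self.cohort.copy(),
            probe_annotation=None
            if self.probe_annotation is None
            else self.probe_annotation.copy(),
        )

    # ------------------------------------------------------------------ I/O

    def write_tsv(self, outdir: str | Path) -> None:
        """Write one TSV per modality (rows = features, columns = patients),
        a patients TSV (clinical + survival + cohort) and the probe
        annotation."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, mat in self.modalities.items():
            mat.T.to_csv(outdir / f"{name}.tsv", sep="\t")
        for name, mat in self.counts.items():
            mat.T.to_csv(outdir / f"{name}_counts.tsv", sep="\t")
        patients = pd.DataFrame(index=self.patient_ids)
        if self.clinical is not None:
            patients = patients.join(self.clinical)
        if self.survival is not None:
            patients = patients.join(self.survival)
        if self.cohort is not None:
            patients["cohort"] = self.cohort
        patients.to_csv(outdir / "patients.tsv", sep="\t")
        if self.probe_annotation is not None:
            self.probe_annotation.to_csv(outdir / "probe_annotation.tsv", sep="\t", index=False)

    @classmethod
    def read_tsv(cls, indir: str | Path) -> "MultiOmicsDataset":
        indir = Path(indir)
        modalities: dict[str, pd.DataFrame] = {}
        counts: dict[str, pd.DataFrame] = {}
        for path in sorted(indir.glob("*.tsv")):
            stem = path.stem
            if stem in ("patients", "probe_annotation"):
                continue
            mat = pd.read_csv(path, sep="\t", index_col=0).T
            if stem.endswith("_counts"):
                counts[stem[: -len("_counts")]] = mat
            else:
                modalities[stem] = mat
        patients = pd.read_csv(indir / "patients.tsv", sep="\t", index_col=0)
        patients.index = pd.Index(patients.index.astype(str), name="patient_id")
        for mat in list(modalities.values()) + list(counts.values()):
            mat.index = pd.Index(mat.index.astype(str), name="patient_id")
            mat.columns.name = None
        survival = patients[["time_days", "event"]].copy()
        survival["event"] = survival["event"].astype(bool)
        cohort = patients["cohort"] if "cohort" in patients else None
        clinical_cols = [
            c for c in patients.columns if c not in ("time_days", "event", "cohort")
        ]
        annot_path = indir / "probe_annotation.tsv"
        annot = pd.read_csv(annot_path, sep="\t") if annot_path.exists() else None
        ds = cls(
            modalities=modalities,
            counts=counts,
            clinical=patients[clinical_cols] if clinical_cols else None,
            survival=survival,
            cohort=cohort,
            probe_annotation=annot,
        )
        ds.validate()
        return ds


def survival_arrays(survival: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Return (time, event) float/bool arrays from a survival table."""
    return (
        survival["time_days"].to_numpy(dtype=float),
        survival["event"].to_numpy(dtype=bool),
    )


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
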