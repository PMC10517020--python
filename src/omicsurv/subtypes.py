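"""Survival-subtype discovery and differential analysis.

K-means on the elastic-net-retained multimodal feature columns of one
designated training run, K chosen by mean silhouette width (K = 2..10),
Kaplan-Meier curves and a log-rank comparison between the clusters, then
negative-binomial Wald differential expression on raw counts and one-way
ANOVA on gene-averaged methylation M-values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .preprocess import beta_to_m
from .survival import CoxFit

logger = logging.getLogger(__name__)

LOW_SEPARATION = 0.3
FC_THRESHOLD = 1.5  # absolute fold change for expression significance
DISPERSION_FLOOR = 1e-8


@dataclass
class SubtypeResult:
    labels: pd.Series
    k: int
    silhouette_by_k: dict[int, float]
    logrank_stat: float
    logrank_p: float
    km_curves: dict[int, pd.DataFrame]
    differential: dict[str, pd.DataFrame] = field(default_factory=dict)


def survival_feature_set(fit: CoxFit) -> list[str]:
    """Columns the elastic net kept (nonzero coefficients)."""
    ids = fit.nonzero_ids
    if not ids:
        raise ValueError(
            "elastic net drove every coefficient to zero; refit with a smaller lambda"
        )
    return ids


def kmeans_cluster(X, k: int, seed: int = 0, n_restarts: int = 25) -> np.ndarray:
    """Lloyd's algorithm, k-means++ init, best of ``n_restarts`` by
    within-cluster SS. Labels are re-indexed by descending cluster size
    (ties: ascending centroid norm) so label ids are deterministic."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if k < 2:
        raise ValueError("k must be >= 2")
    if Xa.shape[0] <= k:
        raise ValueError("need more patients than clusters")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(Xa)
    sizes = np.bincount(raw, minlength=k)
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    order = sorted(range(k), key=lambda c: (-sizes[c], norms[c]))
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(k)
    return remap[raw]


def choose_k_silhouette(
    X, k_min: int = 2, k_max: int = 10, seed: int = 0, n_restarts: int = 25
) -> tuple[int, dict[int, float]]:
    """Mean silhouette width (Euclidean) over K in [k_min, k_max]; returns
    the argmax K (ties toward smaller K) and the full profile."""
    Xa = X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)
    if Xa.shape[0] <= k_max:
        raise ValueError("need more patients than k_max")
    profile: dict[int, float] = {}
    for k in range(k_min, k_max + 1):
        labels = kmeans_cluster(Xa, k, seed=seed, n_restarts=n_restarts)
        profile[k] = float(silhouette_score(Xa, labels, metric="euclidean"))
    best_k = max(profile, key=lambda k: (profile[k], -k))
    if profile[best_k] < LOW_SEPARATION:
        logger.warning(
            "low cluster separation: best silhouette %.3f at K=%d", profile[best_k], best_k
        )
    return best_k, profile


# --------------------------------------------------------------------------
# survival comparison


def kaplan_meier(time, event, labels=None) -> dict[int, pd.DataFrame]:
    """Product-limit estimator per group.

    Each group's table has one row per distinct event time: ``time``,
    ``n_at_risk``, ``n_events``, ``survival``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = np.zeros(len(time), dtype=int) if labels is None else np.asarray(labels)
    curves: dict[int, pd.DataFrame] = {}
    for g in np.unique(labels):
        t, e = time[labels == g], event[labels == g]
        order = np.argsort(t, kind="stable")
        t, e = t[order], e[order]
        rows = []
        s = 1.0
        for ut in np.unique(t[e]):
            n_risk = int((t >= ut).sum())
            d = int(((t == ut) & e).sum())
            s *= 1.0 - d / n_risk
            rows.append((float(ut), n_risk, d, s))
        curves[int(g)] = pd.DataFrame(
            rows, columns=["time", "n_at_risk", "n_events", "survival"]
        )
    return curves


def logrank_test(time, event, labels) -> tuple[float, float]:
    """Standard (unweighted) log-rank test across groups; returns the
    chi-square statistic and its p-value on (groups - 1) df."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if not event.any():
        raise ValueError("no events")
    k = len(groups)
    observed = np.zeros(k)
    expected = np.zeros(k)
    # variance of group event counts under the hypergeometric null
    var = np.zeros((k, k))
    for ut in np.unique(time[event]):
        at_risk = time >= ut
        n = int(at_risk.sum())
        d = int((event & (time == ut)).sum())
        if n == 0 or d == 0:
            continue
        n_g = np.array([int((at_risk & (labels == g)).sum()) for g in groups], dtype=float)
        d_g = np.array(
            [int((event & (time == ut) & (labels == g)).sum()) for g in groups], dtype=float
        )
        observed += d_g
        expected += d * n_g / n
        if n > 1:
            factor = d * (n - d) / (n - 1)
            p_g = n_g / n
            var += factor * (np.diag(p_g) - np.outer(p_g, p_g))
    diff = (observed - expected)[:-1]
    v = var[:-1, :-1]
    try:
        stat = float(diff @ np.linalg.solve(v, diff))
    except np.linalg.LinAlgError:
        stat = float(diff @ np.linalg.pinv(v) @ diff)
    stat = max(stat, 0.0)
    p = float(sps.chi2.sf(stat, df=k - 1))
    return stat, p


# --------------------------------------------------------------------------
# differential analysis


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios per-sample size factors (samples x genes input)."""
    counts = np.asarray(counts, dtype=float)
    with np.errstate(divide="ignore"):
        logc = np.log(counts)
    usable = np.all(np.isfinite(logc), axis=0)  # genes positive in every sample
    if not usable.any():
        raise ValueError("no gene has positive counts in all samples")
    log_gm = logc[:, usable].mean(axis=0)
    sf = np.exp(np.median(logc[:, usable] - log_gm[None, :], axis=1))
    return sf


def differential_expression(counts: pd.DataFrame, labels) -> pd.DataFrame:
    """Negative-binomial Wald test between two groups on raw counts.

    Median-of-ratios normalization; pooled method-of-moments dispersion
    (floored); Wald test on the group log fold change via the delta method;
    BH adjustment across the tested transcripts. Significant means adjusted
    p < 0.05 and |fold change| > 1.5. All-zero transcripts are excluded and
    flagged in the ``tested`` column.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if len(groups) != 2:
        raise ValueError("differential expression requires exactly 2 groups")
    for g in groups:
        if (labels == g).sum() < 2:
            raise ValueError(f"group {g} has fewer than 2 samples")
    C = counts.to_numpy(dtype=float)
    sf = size_factors(C)
    q = C / sf[:, None]  # normalized counts

    m1, m2 = labels == groups[0], labels == groups[1]
    n1, n2 = int(m1.sum()), int(m2.sum())
    mu1, mu2 = q[m1].mean(axis=0), q[m2].mean(axis=0)
    v1 = q[m1].var(axis=0, ddof=1)
    v2 = q[m2].var(axis=0, ddof=1)

    tested = (C.sum(axis=0) > 0)
    n_dropped = int((~tested).sum())
    if n_dropped:
        logger.info("excluding %d all-zero transcript(s)", n_dropped)

    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices of dropped genes
        # pooled method-of-moments NB dispersion: var = mu + a * mu^2
        disp = np.nanmean(
            np.stack([(v1 - mu1) / mu1**2, (v2 - mu2) / mu2**2]), axis=0
        )
    disp = np.where(np.isfinite(disp), disp, DISPERSION_FLOOR)
    disp = np.maximum(disp, DISPERSION_FLOOR)

    eps1, eps2 = 0.5 / n1, 0.5 / n2  # continuity guard for empty group means
    mu1s, mu2s = np.maximum(mu1, eps1), np.maximum(mu2, eps2)
    log_fc = np.log(mu1s) - np.log(mu2s)
    # delta method: Var(log mean) ~ (1/mu + disp) / n
    se = np.sqrt((1.0 / mu1s + disp) / n1 + (1.0 / mu2s + disp) / n2)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = log_fc / se
    p = 2.0 * sps.norm.sf(np.abs(z))
    p = np.where(tested, p, np.nan)

    adj = np.full_like(p, np.nan)
    adj[tested] = bh_adjust(p[tested])
    log2_fc = log_fc / np.log(2.0)
    significant = tested & (adj < 0.05) & (np.abs(log2_fc) > np.log2(FC_THRESHOLD))
    return pd.DataFrame(
        {
            "log2_fc": log2_fc,
            "p": p,
            "adj_p": adj,
            "significant": significant,
            "tested": tested,
            "base_mean": q.mean(axis=0),
        },
        index=counts.columns.rename("feature"),
    )


def anova_f_oneway(groups: list[np.ndarray]) -> tuple[float, float]:
    """Classical one-way (equal-variance) ANOVA F test."""
    k = len(groups)
    ns = np.array([len(g) for g in groups])
    n = int(ns.sum())
    if k < 2 or n <= k:
        raise ValueError("insufficient groups/samples for ANOVA")
    means = np.array([np.mean(g) for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float((ns * (means - grand) ** 2).sum())
    ss_within = float(sum(((g - m) ** 2).sum() for g, m in zip(groups, means)))
    df_b, df_w = k - 1, n - k
    if ss_within == 0.0:
        return (np.inf, 0.0) if ss_between > 0 else (0.0, 1.0)
    f = (ss_between / df_b) / (ss_within / df_w)
    return float(f), float(sps.f.sf(f, df_b, df_w))


def differential_methylation(
    beta: pd.DataFrame, labels, annotation: pd.DataFrame
) -> pd.DataFrame:
    """Gene-level methylation comparison.

    Betas are logit-transformed to M-values, probes are averaged per gene,
    and a one-way ANOVA tests the group difference in mean M-value
    (significant at raw p < 0.05, no multiplicity correction). Reports the
    group-1 minus group-2 mean difference.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    m_vals = beta_to_m(beta)
    probe_gene = annotation.set_index("probe_id")["gene_id"]
    genes = probe_gene.reindex(m_vals.columns)
    if genes.isna().any():
        missing = list(m_vals.columns[genes.isna()][:5])
        raise ValueError(f"probes without gene annotation, e.g. {missing}")
    gene_m = m_vals.T.groupby(genes).mean().T  # patients x genes

    rows = []
    for gene in gene_m.columns:
        vals = gene_m[gene].to_numpy()
        finite = np.isfinite(vals)
        if not finite.all():
            vals, lab = vals[finite], labels[finite]
        else:
            lab = labels
        per_group = [vals[lab == g] for g in groups]
        if any(len(g) < 2 for g in per_group):
            logger.info("gene %s skipped: a group has < 2 values", gene)
            continue
        f, p = anova_f_oneway(per_group)
        diff = float(per_group[0].mean() - per_group[1].mean()) if len(groups) == 2 else np.nan
        rows.append((gene, diff, f, p, p < 0.05))
    return pd.DataFrame(
        rows, columns=["gene", "mean_m_diff", "f_stat", "p", "significant"]
    ).set_index("gene")


# --------------------------------------------------------------------------
# full arm


def run_subtype_analysis(
    dataset,
    artifacts,
    k_min: int = 2,
    k_max: int = 10,
    seed: int = 0,
    n_restarts: int = 25,
) -> SubtypeResult:
    """Biomarker arm on one designated training run's fitted state."""
    cols = survival_feature_set(artifacts.cox_fit)
    X = artifacts.design_all[cols]
    # the pipeline applies the follow-up filter internally; align to its rows
    dataset = dataset.subset_patients(X.index)
    k, profile = choose_k_silhouette(X, k_min, k_max, seed=seed, n_restarts=n_restarts)
    labels = pd.Series(
        kmeans_cluster(X, k, seed=seed, n_restarts=n_restarts),
        index=X.index, name="cluster",
    )
    time = dataset.survival["time_days"].to_numpy()
    event = dataset.survival["event"].to_numpy(bool)
    stat, p = logrank_test(time, event, labels.to_numpy())
    curves = kaplan_meier(time, event, labels.to_numpy())

    differential: dict[str, pd.DataFrame] = {}
    if k == 2:
        lab = labels.to_numpy()
        for name, counts in dataset.counts.items():
            differential[name] = differential_expression(counts, lab)
        if "methylation" in dataset.modalities and dataset.probe_annotation is not None:
            differential["methylation"] = differential_methylation(
                dataset.modalities["methylation"], lab, dataset.probe_annotation
            )
    else:
        logger.warning("K=%d clusters selected; differential analysis is pairwise-only", k)
    return SubtypeResult(
        labels=labels,
        k=k,
        silhouette_by_k=profile,
        logrank_stat=stat,
        logrank_p=p,
        km_curves=curves,
        differential=differential,
    )
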