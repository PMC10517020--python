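"""Univariate Cox proportional-hazards screening (Wald tests) with
per-modality top-k selection.

Each feature is fitted by Newton iterations on the Breslow partial
likelihood, vectorized across features in blocks. Features with monotone
likelihood (diverging coefficient) or zero variance are flagged and excluded
from selection.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: Per-modality selection caps.
DEFAULT_K_CAPS = {"mrna": 500, "methylation": 500, "lncrna": 300, "mirna": 300}

BETA_CAP = 20.0
P_FLOOR = 1e-300
SCORE_TOL = 1e-8
MAX_NEWTON_ITER = 50


class ScreeningError(ValueError):
    pass


def _risk_set_layout(time: np.ndarray):
    """Sort ascending by time; return order, event mask and, per sorted
    index, the start of its tie group (risk set = suffix from there)."""
    order = np.argsort(time, kind="stable")
    t = time[order]
    n = len(t)
    new_group = np.r_[True, t[1:] != t[:-1]]
    group_start = np.maximum.accumulate(np.where(new_group, np.arange(n), 0))
    return order, group_start


def _suffix_cumsum(a: np.ndarray) -> np.ndarray:
    return np.cumsum(a[::-1], axis=0)[::-1]


def _breslow_stats(Xs, beta, gs, ev, want_derivs=True):
    """Log partial likelihood (and score/information) per feature column.

    ``Xs`` is sorted ascending by time; ``gs`` maps each row to its tie-group
    start; ``ev`` is the sorted event mask.
    """
    eta = Xs * beta[None, :]
    w = np.exp(np.clip(eta, -200, 200))
    S0 = _suffix_cumsum(w)[gs]
    ll = (eta[ev] - np.log(S0[ev])).sum(axis=0)
    if not want_derivs:
        return ll, None, None
    S1 = _suffix_cumsum(Xs * w)[gs]
    S2 = _suffix_cumsum(Xs * Xs * w)[gs]
    xbar = S1 / S0
    score = (Xs[ev] - xbar[ev]).sum(axis=0)
    info = (S2[ev] / S0[ev] - xbar[ev] ** 2).sum(axis=0)
    return ll, score, info


def univariate_cox(
    X: np.ndarray | pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    block_size: int = 2048,
) -> pd.DataFrame:
    """Fit a univariate Cox model per column of ``X``.

    Returns a table with columns ``beta``, ``se``, ``z``, ``p``,
    ``monotone`` (diverging fit), ``constant``; indexed by feature id.
    """
    if isinstance(X, pd.DataFrame):
        feature_ids = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.atleast_2d(np.asarray(X, dtype=float))
        if Xa.shape[0] == 1 and Xa.size == len(time):
            Xa = Xa.reshape(-1, 1)
        feature_ids = [f"f{i}" for i in range(Xa.shape[1])]
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if event.sum() < 2:
        raise ScreeningError("fewer than 2 events; screening undefined")

    order, gs = _risk_set_layout(time)
    ev = event[order]
    n, p = Xa.shape

    beta = np.zeros(p)
    se = np.full(p, np.nan)
    constant = Xa.std(axis=0) == 0.0
    monotone = np.zeros(p, dtype=bool)

    for start in range(0, p, block_size):
        cols = np.arange(start, min(start + block_size, p))
        cols = cols[~constant[cols]]
        if len(cols) == 0:
            continue
        Xs = Xa[order][:, cols]
        b = np.zeros(len(cols))
        ll_prev, score, info = _breslow_stats(Xs, b, gs, ev)
        active = np.ones(len(cols), dtype=bool)
        for _ in range(MAX_NEWTON_ITER):
            step = np.zeros_like(b)
            ok = active & (info > 1e-12)
            step[ok] = score[ok] / info[ok]
            if not ok.any():
                break
            # step-halving where the likelihood would decrease
            for _halve in range(30):
                b_new = b + step
                ll_new, _, _ = _breslow_stats(Xs, b_new, gs, ev, want_derivs=False)
                bad = ok & (ll_new < ll_prev - 1e-12)
                if not bad.any():
                    break
                step[bad] *= 0.5
            b = np.where(ok, b + step, b)
            diverged = np.abs(b) >= BETA_CAP
            b = np.clip(b, -BETA_CAP, BETA_CAP)
            monotone[cols[diverged]] = True
            active = active & ~diverged
            ll_prev, score, info = _breslow_stats(Xs, b, gs, ev)
            active = active & (np.abs(score) >= SCORE_TOL)
            if not active.any():
                break
        beta[cols] = b
        with np.errstate(divide="ignore"):
            se[cols] = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(se > 0, beta / se, 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(z))
    pval = np.maximum(pval, P_FLOOR)
    pval[constant] = 1.0
    z[constant] = 0.0
    beta[constant] = 0.0
    return pd.DataFrame(
        {
            "beta": beta,
            "se": se,
            "z": z,
            "p": pval,
            "monotone": monotone,
            "constant": constant,
        },
        index=pd.Index(feature_ids, name="feature"),
    )


def univariate_cox_single(
    x: np.ndarray, time: np.ndarray, event: np.ndarray
) -> tuple[float, float, float, float]:
    """Single-feature convenience wrapper: (beta, se, z, p)."""
    row = univariate_cox(np.asarray(x, dtype=float).reshape(-1, 1), time, event).iloc[0]
    return float(row["beta"]), float(row["se"]), float(row["z"]), float(row["p"])


def select_top_k(screen: pd.DataFrame, k: int) -> list[str]:
    """Pick the ``k`` features with the smallest Wald p-values.

    Ties broken by |z| descending then feature id; flagged (monotone or
    constant) features are never selected. Returns fewer than ``k`` ids with
    a warning when the modality is too small.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    eligible = screen.loc[~(screen["monotone"] | screen["constant"])].copy()
    eligible["_absz"] = eligible["z"].abs()
    eligible = eligible.sort_values(
        by=["p", "_absz", eligible.index.name or "feature"],
        ascending=[True, False, True],
        kind="stable",
    )
    if len(eligible) < k:
        logger.warning("requested top %d but only %d eligible features", k, len(eligible))
    return list(eligible.index[:k])


def screen_modality(
    matrix: pd.DataFrame,
    time: np.ndarray,
    event: np.ndarray,
    k_cap: int,
    modality: str = "modality",
) -> pd.DataFrame:
    """Screen one modality and mark the selected top-``k_cap`` features."""
    screen = univariate_cox(matrix, time, event)
    selected = set(select_top_k(screen, k_cap))
    screen["selected"] = [f in selected for f in screen.index]
    screen["modality"] = modality
    screen["k_cap"] = k_cap
    return screen
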