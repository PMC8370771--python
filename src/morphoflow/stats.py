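"""Differential cluster-abundance testing.

Counts of events per cluster and per sample are modeled negative-binomially
(variance mu + phi*mu^2) with a log link and the log of the per-sample total
as offset, so the tested quantity is the *relative* abundance of a cluster.
A single common dispersion phi is estimated across clusters by maximizing a
Cox-Reid-adjusted profile likelihood, then each cluster gets a
likelihood-ratio test of the condition effect, with Benjamini-Hochberg FDR
across clusters.  A one-way ANOVA path on relative abundances is provided
for simple multi-group comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import minimize_scalar
from scipy.special import gammaln
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

_PHI_POISSON = 1e-8   # below this, use the Poisson limit of the NB likelihood


@dataclass
class CountMatrix:
    """Integer counts, rows = clusters, cols = samples, plus condition map."""

    counts: pd.DataFrame
    conditions: pd.Series

    def __post_init__(self):
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if list(self.counts.columns) != list(self.conditions.index):
            self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            raise ValueError("every sample needs a condition")

    @property
    def totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def _nb_loglik(y, mu, phi):
    """NB log-likelihood (size r = 1/phi), Poisson in the phi -> 0 limit."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(np.asarray(mu, dtype=float), 1e-12)
    if phi < _PHI_POISSON:
        return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1)))
    r = 1.0 / phi
    return float(np.sum(gammaln(y + r) - gammaln(r) - gammaln(y + 1)
                        + r * np.log(r / (r + mu)) + y * np.log(mu / (r + mu))))


def _fit_group_log_mean(y, t, phi, n_iter: int = 30):
    """MLE of u = log lambda in the model mu_s = t_s * exp(u), NB(phi).

    Vectorized Newton over the leading axes of y, t (…, n_samples).
    The phi = 0 case is the exact Poisson closed form.
    """
    y = np.asarray(y, dtype=float)
    t = np.asarray(t, dtype=float)
    tot_y = y.sum(axis=-1)
    tot_t = t.sum(axis=-1)
    with np.errstate(divide="ignore"):
        u = np.log(np.maximum(tot_y, 0.5) / tot_t)   # Poisson MLE as start
    if phi < _PHI_POISSON:
        return u
    for _ in range(n_iter):
        mu = t * np.exp(u)[..., None]
        denom = 1.0 + phi * mu
        score = np.sum((y - mu) / denom, axis=-1)
        info = np.sum(mu * (1.0 + phi * y) / denom**2, axis=-1)
        step = score / np.maximum(info, 1e-12)
        u = u + np.clip(step, -2.0, 2.0)
        if np.max(np.abs(step)) < 1e-10:
            break
    return u


def _profile_loglik(counts, totals, groups, phi, adjust: bool = True):
    """Sum over clusters of the NB log-likelihood with per-(cluster, group)
    means profiled out; optionally Cox-Reid adjusted (-1/2 log det X'WX)."""
    ll = 0.0
    adj = 0.0
    mu_all = np.zeros_like(counts, dtype=float)
    for g in np.unique(groups):
        sel = groups == g
        y, t = counts[:, sel], totals[sel]
        u = _fit_group_log_mean(y, t, phi)
        mu = t * np.exp(u)[:, None]
        mu_all[:, sel] = mu
        if adjust:
            w = mu / (1.0 + phi * mu)            # GLM working weights
            adj += 0.5 * np.sum(np.log(np.maximum(w.sum(axis=1), 1e-12)))
    ll = _nb_loglik(counts, mu_all, phi)
    return ll - adj


def estimate_common_dispersion(counts: CountMatrix, bound: float = 10.0,
                               tol: float = 1e-6) -> float:
    """Single NB dispersion phi >= 0 maximizing the adjusted profile
    likelihood over clusters, with cluster x condition means profiled out
    and log sample totals as offsets.  Bounded search on [0, bound]."""
    y = counts.counts.to_numpy(dtype=float)
    if y.sum() == 0:
        raise ValueError("all counts are zero")
    t = counts.totals.to_numpy(dtype=float)
    groups = counts.conditions.to_numpy()
    res = minimize_scalar(lambda p: -_profile_loglik(y, t, groups, p),
                          bounds=(0.0, bound), method="bounded",
                          options={"xatol": tol})
    phi = float(res.x)
    # the bounded optimizer never returns exactly 0; snap when the boundary fits
    if phi < 1e-4 and _profile_loglik(y, t, groups, 0.0) >= -res.fun - 1e-9:
        phi = 0.0
    log.info("common NB dispersion: phi=%.5f", phi)
    return phi


def nb_test(counts: CountMatrix, phi: float | None = None) -> pd.DataFrame:
    """Per-cluster NB GLM likelihood-ratio test of the condition effect.

    Model: log mu = offset(log total) + b0 + b1 * condition; p-value from the
    LRT of b1 = 0 against chi2(1); logFC = b1 / ln 2 for the second condition
    level relative to the first.  Clusters that are all-zero get p = 1,
    logFC = 0 and ``flagged = True``.  FDR is Benjamini-Hochberg across
    clusters.
    """
    conds = counts.conditions
    levels = sorted(pd.unique(conds))   # deterministic contrast direction
    if len(levels) != 2:
        raise ValueError(f"nb_test needs exactly 2 conditions, got {levels}")
    if phi is None:
        phi = estimate_common_dispersion(counts)
    y = counts.counts.to_numpy(dtype=float)
    t = counts.totals.to_numpy(dtype=float)
    is_b = (conds == levels[1]).to_numpy()

    u_null = _fit_group_log_mean(y, t, phi)
    mu_null = t * np.exp(u_null)[:, None]
    u_a = _fit_group_log_mean(y[:, ~is_b], t[~is_b], phi)
    u_b = _fit_group_log_mean(y[:, is_b], t[is_b], phi)
    mu_full = np.zeros_like(y)
    mu_full[:, ~is_b] = t[~is_b] * np.exp(u_a)[:, None]
    mu_full[:, is_b] = t[is_b] * np.exp(u_b)[:, None]

    rows = []
    for i, cl in enumerate(counts.counts.index):
        if y[i].sum() == 0:
            rows.append({"cluster": cl, "logFC": 0.0, "pvalue": 1.0,
                         "mean_abundance": 0.0, "flagged": True})
            continue
        ll0 = _nb_loglik(y[i], mu_null[i], phi)
        ll1 = _nb_loglik(y[i], mu_full[i], phi)
        lrt = max(0.0, 2.0 * (ll1 - ll0))
        p = float(sps.chi2.sf(lrt, df=1))
        logfc = float((u_b[i] - u_a[i]) / np.log(2.0))
        rows.append({"cluster": cl, "logFC": logfc, "pvalue": p,
                     "mean_abundance": float((y[i] / t).mean()), "flagged": False})
    out = pd.DataFrame(rows).set_index("cluster")
    out["fdr"] = bh_fdr(out["pvalue"].to_numpy())
    out.attrs["dispersion"] = phi
    out.attrs["contrast"] = f"{levels[1]} vs {levels[0]}"
    return out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_bh(rel_abundance: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """One-way ANOVA per cluster on per-sample relative abundances, with BH.

    ``rel_abundance`` is clusters x samples; ``groups`` maps sample -> group
    (>= 2 groups with >= 2 replicates each).  Clusters with zero variance in
    every group get an undefined test and are flagged.
    """
    groups = groups.reindex(rel_abundance.columns)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need at least 2 groups")
    for g in levels:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 replicates")
    rows = []
    for cl in rel_abundance.index:
        arrs = [rel_abundance.loc[cl, groups == g].to_numpy(dtype=float)
                for g in levels]
        if all(a.std() == 0 for a in arrs):
            rows.append({"cluster": cl, "F": np.nan, "pvalue": np.nan, "flagged": True})
            continue
        f, p = sps.f_oneway(*arrs)
        rows.append({"cluster": cl, "F": float(f), "pvalue": float(p), "flagged": False})
    out = pd.DataFrame(rows).set_index("cluster")
    ok = out["pvalue"].notna()
    out["fdr"] = np.nan
    out.loc[ok, "fdr"] = bh_fdr(out.loc[ok, "pvalue"].to_numpy())
    return out


def volcano_export(diff: pd.DataFrame, max_neglog10: float = 300.0) -> pd.DataFrame:
    """Volcano-plot table: logFC vs -log10(FDR), one row per cluster."""
    out = pd.DataFrame({
        "cluster": diff.index,
        "logFC": diff["logFC"].to_numpy(),
        "neg_log10_fdr": -np.log10(np.maximum(diff["fdr"].to_numpy(),
                                              10.0 ** -max_neglog10)),
    })
    out["significant"] = diff["fdr"].to_numpy() <= 0.01
    return out.reset_index(drop=True)
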