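"""Feature trimming, replicate QC, transformation and normalization.

The stage between feature extraction and clustering:

1. trim redundant features (Spearman |rho| >= 0.85 on a reference sample);
2. drop replicate samples whose mean-feature vector correlates < 0.85 with
   the rest of the set;
3. logicle-transform fluorescence intensity features;
4. align the 2N/4N DNA-content peaks across samples with a landmark-based
   piecewise-linear warp (removes per-sample intensity drift);
5. scale every feature to unit standard deviation.

All transforms are per-feature monotone, so between-feature Spearman
correlations are invariant under steps 3-4.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import gaussian_kde, spearmanr

from .core import is_fluorescence
from .logicle import LogicleParams, LogicleTransform, estimate_logicle

log = logging.getLogger(__name__)

#: intensity-statistic suffixes eligible for logicle transformation
FLUOR_STAT_SUFFIXES = ("_intensity", "_mean_intensity", "_max_pixel", "_contrast")

ID_COLUMNS = ("event_id", "sample_id", "condition", "cluster_id", "unsegmentable",
              "retained", "population", "ploidy", "is_doublet", "is_debris")


def feature_columns(table: pd.DataFrame) -> list[str]:
    """Numeric non-identifier, non-gate-flag columns of an EventTable."""
    out = []
    for c in table.columns:
        if c in ID_COLUMNS or c.startswith("pass_"):
            continue
        if pd.api.types.is_numeric_dtype(table[c]):
            out.append(c)
    return out


def fluorescence_features(features: list[str]) -> list[str]:
    """Features that are fluorescence intensity statistics (logicle targets)."""
    return [f for f in features
            if is_fluorescence(f.split("_")[0]) and f.endswith(FLUOR_STAT_SUFFIXES)]


# ---------------------------------------------------------------------------
# 1. feature trimming

def spearman_trim(table: pd.DataFrame, threshold: float = 0.85,
                  reference_sample: str | None = None,
                  features: list[str] | None = None):
    """Greedily trim one member of every feature pair with |rho| >= threshold.

    Spearman correlations are computed over all events of the reference
    sample (default: the sample with the most events).  Pairs are visited in
    panel order and the later-listed feature of a correlated pair is dropped,
    so the earlier feature of each pair survives.  Constant features have
    undefined rho; they are kept and flagged.

    Returns ``(kept features, report DataFrame)`` where the report lists one
    row per trimmed pair (kept, dropped, rho).
    """
    features = features or feature_columns(table)
    if len(features) < 2:
        raise ValueError("need at least 2 features to trim")
    if reference_sample is None:
        reference_sample = table["sample_id"].value_counts().idxmax()
    ref = table.loc[table["sample_id"] == reference_sample, features].dropna()
    if ref.empty:
        raise ValueError(f"reference sample {reference_sample!r} has no events")
    constant = [f for f in features if ref[f].nunique() <= 1]
    if constant:
        warnings.warn(f"constant features (rho undefined), kept: {constant}")
    with np.errstate(invalid="ignore"):
        rho = ref.corr(method="spearman").to_numpy()
    kept = [True] * len(features)
    rows = []
    for i in range(len(features)):
        if not kept[i] or features[i] in constant:
            continue
        for j in range(i + 1, len(features)):
            if not kept[j] or features[j] in constant:
                continue
            r = rho[i, j]
            if np.isfinite(r) and abs(r) >= threshold:
                kept[j] = False
                rows.append({"kept": features[i], "dropped": features[j],
                             "rho": float(r)})
    survivors = [f for f, k in zip(features, kept) if k]
    log.info("trimmed %d/%d features at |rho|>=%.2f on sample %s",
             len(features) - len(survivors), len(features), threshold,
             reference_sample)
    return survivors, pd.DataFrame(rows, columns=["kept", "dropped", "rho"])


# ---------------------------------------------------------------------------
# 2. replicate QC

def replicate_outlier_check(table: pd.DataFrame, threshold: float = 0.85,
                            features: list[str] | None = None):
    """Drop replicate samples whose mean-feature vector is discordant.

    Each sample's vector of per-feature means is Spearman-correlated against
    the element-wise median vector of all *other* samples (leave-one-out);
    samples below ``threshold`` are dropped.  With fewer than 3 samples the
    check is skipped with a warning.

    Returns ``(kept sample ids, dropped sample ids, pairwise correlation
    DataFrame)``.
    """
    features = features or feature_columns(table)
    means = table.groupby("sample_id")[features].mean()
    corr = means.T.corr(method="spearman")
    if len(means) < 3:
        warnings.warn("replicate QC skipped: fewer than 3 samples")
        return list(means.index), [], corr
    kept, dropped = [], []
    for sid in means.index:
        ref = means.drop(index=sid).median(axis=0)
        r = spearmanr(means.loc[sid], ref).statistic
        (kept if r >= threshold else dropped).append(sid)
        if r < threshold:
            log.info("sample %s dropped by replicate QC (rho=%.3f)", sid, r)
    return kept, dropped, corr


# ---------------------------------------------------------------------------
# 3-4. transforms

def logicle_transform(values, params: LogicleParams | None = None):
    """Logicle-transform a value array; returns (transformed, params used)."""
    if params is None:
        params = estimate_logicle(values)
    return LogicleTransform(params)(values), params


@dataclass
class LandmarkWarp:
    """Monotone piecewise-linear map aligning sample landmarks to base ones.

    Identity-sloped extrapolation outside the landmark range; a single
    landmark degenerates to a pure shift.
    """

    src: list[float]
    dst: list[float]

    def __call__(self, x):
        x = np.asarray(x, dtype=float)
        s, d = np.asarray(self.src), np.asarray(self.dst)
        y = np.interp(x, s, d)
        y = np.where(x < s[0], d[0] + (x - s[0]), y)
        y = np.where(x > s[-1], d[-1] + (x - s[-1]), y)
        return y


def _kde_landmarks(values: np.ndarray, n_landmarks: int) -> list[float]:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 10 or v.std() == 0:
        return []
    kde = gaussian_kde(v, bw_method="silverman")
    grid = np.linspace(v.min(), v.max(), 512)
    dens = kde(grid)
    peaks, props = find_peaks(dens, prominence=dens.max() * 1e-3)
    if len(peaks) == 0:
        return []
    order = np.argsort(props["prominences"])[::-1][:n_landmarks]
    return sorted(float(grid[p]) for p in peaks[order])


def dna_peak_normalize(table: pd.DataFrame, dna_feature: str,
                       n_landmarks: int = 2):
    """Align per-sample 2N/4N DNA peaks to common landmark positions.

    Per sample, a Gaussian KDE (Silverman bandwidth) of the DNA feature
    provides up to ``n_landmarks`` highest-prominence modes, ordered
    ascending.  The base landmarks are the per-landmark medians across
    samples; each sample is warped onto them with a monotone piecewise-linear
    map (identity-sloped outside).  Samples with fewer landmarks are aligned
    on what was found; samples with none are left unwarped and flagged.

    Returns ``(table with warped feature, {sample_id: LandmarkWarp | None})``.
    """
    samples = table["sample_id"].unique()
    landmarks = {}
    for sid in samples:
        lm = _kde_landmarks(table.loc[table["sample_id"] == sid, dna_feature], n_landmarks)
        if len(lm) < n_landmarks:
            warnings.warn(f"sample {sid}: found {len(lm)} DNA landmark(s), "
                          f"expected {n_landmarks}")
        landmarks[sid] = lm
    n_found = max((len(v) for v in landmarks.values()), default=0)
    base = []
    for i in range(n_found):
        vals = [lm[i] for lm in landmarks.values() if len(lm) > i]
        base.append(float(np.median(vals)))
    out = table.copy()
    warps: dict[str, LandmarkWarp | None] = {}
    for sid in samples:
        lm = landmarks[sid]
        if not lm:
            warps[sid] = None
            continue
        dst = base[: len(lm)] if len(lm) <= len(base) else lm
        warp = LandmarkWarp(src=lm, dst=dst)
        warps[sid] = warp
        idx = out["sample_id"] == sid
        out.loc[idx, dna_feature] = warp(out.loc[idx, dna_feature].to_numpy())
    return out, warps


# ---------------------------------------------------------------------------
# 5. scaling

def scale_features(table: pd.DataFrame, features: list[str] | None = None) -> pd.DataFrame:
    """Divide each feature by its pooled standard deviation (mean unshifted)."""
    features = features or feature_columns(table)
    out = table.copy()
    for f in features:
        sd = float(out[f].std(ddof=1))
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"feature {f!r} has zero or undefined SD")
        out[f] = out[f] / sd
    return out


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class TransformSpec:
    """Record of every per-feature transform applied, for provenance."""

    trimmed: list[str] = field(default_factory=list)
    kept: list[str] = field(default_factory=list)
    dropped_samples: list[str] = field(default_factory=list)
    logicle: dict[str, dict] = field(default_factory=dict)
    dna_feature: str | None = None
    landmark_warps: dict[str, dict | None] = field(default_factory=dict)
    scale_sd: dict[str, float] = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)


def preprocess_table(table: pd.DataFrame, trim_threshold: float = 0.85,
                     outlier_threshold: float = 0.85,
                     dna_feature: str = "DNA_intensity",
                     reference_sample: str | None = None):
    """Run the full preprocessing stage on a gated EventTable.

    Returns ``(processed table, TransformSpec)``.  The processed table keeps
    identifier columns plus the surviving, transformed, unit-SD features.
    """
    spec = TransformSpec()
    feats = feature_columns(table)
    kept_feats, report = spearman_trim(table, trim_threshold, reference_sample, feats)
    spec.kept = kept_feats
    spec.trimmed = list(report["dropped"])

    kept_samples, dropped, _ = replicate_outlier_check(table, outlier_threshold, kept_feats)
    spec.dropped_samples = dropped
    t = table[table["sample_id"].isin(kept_samples)].copy()

    for f in fluorescence_features(kept_feats):
        t[f], params = logicle_transform(t[f].to_numpy())
        spec.logicle[f] = params.__dict__
    if dna_feature in kept_feats:
        spec.dna_feature = dna_feature
        t, warps = dna_peak_normalize(t, dna_feature)
        spec.landmark_warps = {
            s: (None if w is None else {"src": w.src, "dst": w.dst})
            for s, w in warps.items()}

    for f in kept_feats:
        spec.scale_sd[f] = float(t[f].std(ddof=1))
    t = scale_features(t, kept_feats)
    id_cols = [c for c in table.columns if c in ID_COLUMNS or c.startswith("pass_")]
    return t[id_cols + kept_feats], spec
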