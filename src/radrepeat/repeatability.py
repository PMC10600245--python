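"""Repeatability quantification by one-way random-effects ICC.

The intraclass correlation used throughout is ICC(1) in the McGraw &
Wong taxonomy: one-way random, absolute agreement, single rater,

    ICC = (MS_R - MS_W) / (MS_R + (k - 1) MS_W),

with MS_R the between-subject and MS_W the within-subject (residual)
mean square of a balanced subjects x repeats panel.  Confidence
intervals come from the F statistic MS_R / MS_W with (n - 1, n(k - 1))
degrees of freedom.  A ``k_plus_1_denominator`` audit switch swaps
(k - 1) for (k + 1).

The module also hosts the feature filters of the modelling workflow:
volume dependence (|Pearson r| to mesh volume), the ICC threshold
filter, the perturbation/test-retest agreement table, and the
point-biserial univariate outcome screen.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatPanel",
    "ICCEstimate",
    "icc_one_way",
    "feature_icc_table",
    "volume_dependence_filter",
    "repeatability_filter",
    "agreement_table",
    "univariate_significance",
]


@dataclass
class RepeatPanel:
    """A balanced subjects-by-repeats measurement panel."""

    subject_ids: list[str]
    values: np.ndarray  # shape (n_subjects, k_repeats)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("panel values must be 2D (subjects x repeats)")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise ValueError(f"panel needs n >= 2 subjects and k >= 2 repeats, got {n}x{k}")
        if len(self.subject_ids) != n:
            raise ValueError("subject_ids length does not match panel rows")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def k_repeats(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCEstimate:
    """Point estimate, 95% CI and design sizes of one ICC computation."""

    icc: float
    ci95: tuple[float, float]
    n_subjects: int
    k_repeats: int
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and not (self.ci95[0] <= self.icc <= self.ci95[1]):
            # guard against numerically inverted bounds
            lo, hi = min(self.ci95), max(self.ci95)
            self.ci95 = (min(lo, self.icc), max(hi, self.icc))


def icc_one_way(
    panel: RepeatPanel,
    alpha: float = 0.05,
    k_plus_1_denominator: bool = False,
) -> ICCEstimate:
    """One-way random, absolute agreement, single-rater ICC with CI.

    Zero total variance makes the ICC undefined: the estimate is
    returned NaN with the degeneracy flag set, and is treated downstream
    as non-repeatable.
    """
    y = panel.values
    if not np.all(np.isfinite(y)):
        raise ValueError("panel contains non-finite values")
    n, k = y.shape
    if np.ptp(y) == 0.0:  # constant panel: no variance to partition
        return ICCEstimate(np.nan, (np.nan, np.nan), n, k, degenerate=True)
    grand = y.mean()
    row_means = y.mean(axis=1)
    ss_between = k * ((row_means - grand) ** 2).sum()
    ss_within = ((y - row_means[:, None]) ** 2).sum()
    ms_r = ss_between / (n - 1)
    ms_w = ss_within / (n * (k - 1))

    if ms_r <= 0 and ms_w <= 0:
        return ICCEstimate(np.nan, (np.nan, np.nan), n, k, degenerate=True)

    denom_k = (k + 1) if k_plus_1_denominator else (k - 1)
    icc = (ms_r - ms_w) / (ms_r + denom_k * ms_w)

    if ms_w == 0:
        return ICCEstimate(float(icc), (float(icc), float(icc)), n, k)

    f_obs = ms_r / ms_w
    df1, df2 = n - 1, n * (k - 1)
    f_upper = stats.f.ppf(1 - alpha / 2, df1, df2)
    f_lower = stats.f.ppf(1 - alpha / 2, df2, df1)
    fl = f_obs / f_upper
    fu = f_obs * f_lower
    lo = (fl - 1) / (fl + denom_k)
    hi = (fu - 1) / (fu + denom_k)
    return ICCEstimate(float(icc), (float(lo), float(hi)), n, k)


def build_panels(table: pd.DataFrame) -> dict[str, RepeatPanel]:
    """Split a (subject, repeat)-indexed feature table into per-feature panels.

    Subjects missing any repeat are dropped with a logged count, never
    silently.
    """
    counts = table.groupby(level="subject").size()
    k = int(counts.max())
    complete = counts[counts == k].index
    dropped = len(counts) - len(complete)
    if dropped:
        logger.warning("dropping %d subject(s) with incomplete repeats", dropped)
    sub = table.loc[complete].sort_index()
    ids = list(complete)
    panels = {}
    for col in table.columns:
        values = sub[col].to_numpy().reshape(len(ids), k)
        panels[col] = RepeatPanel(ids, values)
    return panels


def feature_icc_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    k_plus_1_denominator: bool = False,
) -> pd.DataFrame:
    """Per-feature ICC estimates from a repeated feature table.

    ``table`` is indexed by (subject, repeat) as produced by
    :func:`radrepeat.features.extract_table`; every retained subject
    must carry the full repeat set.  Returns a DataFrame indexed by
    descriptor with columns icc, ci_low, ci_high, n, k, degenerate.
    """
    rows = {}
    for col, panel in build_panels(table).items():
        if not np.all(np.isfinite(panel.values)):
            rows[col] = {"icc": np.nan, "ci_low": np.nan, "ci_high": np.nan,
                         "n": panel.n_subjects, "k": panel.k_repeats,
                         "degenerate": True}
            continue
        est = icc_one_way(panel, alpha, k_plus_1_denominator)
        rows[col] = {"icc": est.icc, "ci_low": est.ci95[0], "ci_high": est.ci95[1],
                     "n": est.n_subjects, "k": est.k_repeats,
                     "degenerate": est.degenerate}
    return pd.DataFrame.from_dict(rows, orient="index")


def volume_dependence_filter(
    features: pd.DataFrame,
    mesh_volumes: np.ndarray | pd.Series,
    r_threshold: float = 0.6,
) -> list[str]:
    """Drop features with |Pearson r| above threshold against mesh volume.

    Operates on an unperturbed (one row per subject) feature table.
    Zero-variance features have undefined correlation and are retained
    with a warning.  Shape features other than the volume itself compete
    like any other feature.
    """
    vols = np.asarray(mesh_volumes, dtype=np.float64)
    if np.any(vols <= 0):
        raise ValueError("mesh volumes must be strictly positive")
    retained = []
    for col in features.columns:
        x = features[col].to_numpy(dtype=np.float64)
        if np.std(x) == 0 or not np.all(np.isfinite(x)):
            warnings.warn(f"feature {col}: undefined volume correlation, retained")
            retained.append(col)
            continue
        r = np.corrcoef(x, vols)[0, 1]
        if abs(r) <= r_threshold:
            retained.append(col)
    return retained


def repeatability_filter(icc_table: pd.DataFrame, threshold: float) -> list[str]:
    """Features with ICC >= threshold; degenerate ICCs are excluded."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    ok = (~icc_table["degenerate"].astype(bool)) & (icc_table["icc"] >= threshold)
    return list(icc_table.index[ok])


def agreement_table(
    icc_perturb: pd.DataFrame,
    icc_retest: pd.DataFrame,
    threshold: float,
) -> dict[str, int]:
    """2x2 counts of repeatability agreement between the two sources.

    Keys: ``P+/TR+``, ``P+/TR-``, ``P-/TR+``, ``P-/TR-`` where P/TR mark
    the perturbation / test-retest assessments and +/- repeatable or not
    at the given threshold.  Counts sum to the descriptor universe size.
    """
    if set(icc_perturb.index) != set(icc_retest.index):
        raise ValueError("ICC tables cover different descriptor universes")
    p_ok = set(repeatability_filter(icc_perturb, threshold))
    t_ok = set(repeatability_filter(icc_retest, threshold))
    universe = list(icc_perturb.index)
    counts = {"P+/TR+": 0, "P+/TR-": 0, "P-/TR+": 0, "P-/TR-": 0}
    for d in universe:
        key = ("P+" if d in p_ok else "P-") + "/" + ("TR+" if d in t_ok else "TR-")
        counts[key] += 1
    return counts


def univariate_significance(values: np.ndarray, outcomes: np.ndarray) -> float:
    """Two-sided p-value of the point-biserial correlation with a binary outcome."""
    y = np.asarray(outcomes)
    x = np.asarray(values, dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("both outcome classes must be present")
    if np.std(x) == 0 or not np.all(np.isfinite(x)):
        warnings.warn("zero-variance or non-finite feature: p-value set to 1")
        return 1.0
    return float(stats.pointbiserialr(y, x).pvalue)
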