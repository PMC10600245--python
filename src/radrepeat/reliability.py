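"""Model reliability: internal generalizability and robustness.

Internal generalizability is the agreement of discriminative
performance (AUC with subject-level bootstrap CIs) between training and
held-out testing data; robustness is the repeatability of the model's
predicted probabilities across perturbed or retest inputs, quantified
by the same one-way random-effects ICC used for features.  The module
also provides segmentation-similarity metrics (Dice, Hausdorff) and the
end-to-end threshold-sweep comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy import ndimage
from scipy.stats import rankdata

from .features import extract_table, mesh_volume
from .image import ImageVolume, SegmentationMask
from .modeling import ModelBundle, ModelConfig, mrmr_rank, train_easy_ensemble
from .perturbation import PerturbationSpace, perturb_subject
from .preprocessing import PreprocessConfig
from .repeatability import (
    ICCEstimate,
    RepeatPanel,
    feature_icc_table,
    icc_one_way,
    repeatability_filter,
    volume_dependence_filter,
)
from .synthetic import SyntheticCohort, split_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "auc",
    "bootstrap_ci",
    "permutation_compare",
    "prediction_icc",
    "dice",
    "hausdorff_mm",
    "ReliabilityReport",
    "run_comparison",
]


def auc(outcomes: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve (rank / Mann-Whitney formulation).

    Ties are handled by midranks; equals the fraction of
    (positive, negative) pairs ranked correctly, counting ties as 1/2.
    """
    y = np.asarray(outcomes).astype(bool)
    s = np.asarray(scores, dtype=np.float64)
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both outcome classes")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def bootstrap_ci(
    outcomes: np.ndarray,
    scores: np.ndarray,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[float, tuple[float, float]]:
    """Point AUC with percentile 95% CI from subject-level bootstrapping.

    Resamples that lose an outcome class are redrawn so the iteration
    count stays fixed.
    """
    if n_iter < 100:
        raise ValueError("n_iter must be >= 100")
    y = np.asarray(outcomes)
    s = np.asarray(scores, dtype=np.float64)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    point = auc(y, s)
    stats = np.empty(n_iter)
    n = len(y)
    for it in range(n_iter):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        stats[it] = auc(y[idx], s[idx])
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return point, (float(lo), float(hi))


def permutation_compare(
    outcomes: np.ndarray,
    scores_a: np.ndarray,
    scores_b: np.ndarray,
    n_iter: int = 1000,
    seed: int | np.random.Generator = 0,
) -> float:
    """Two-sided permutation p-value for AUC(a) - AUC(b) on the same subjects.

    The null distribution swaps the (a, b) score pair independently per
    subject with probability 1/2; the p-value uses +1 smoothing.
    """
    y = np.asarray(outcomes)
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if not (len(y) == len(a) == len(b)):
        raise ValueError("outcomes and both score vectors must share subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    observed = auc(y, a) - auc(y, b)
    count = 0
    for _ in range(n_iter):
        swap = rng.random(len(y)) < 0.5
        pa = np.where(swap, b, a)
        pb = np.where(swap, a, b)
        if abs(auc(y, pa) - auc(y, pb)) >= abs(observed):
            count += 1
    return float((count + 1) / (n_iter + 1))


def prediction_icc(
    bundle: ModelBundle,
    repeated_table: pd.DataFrame,
    alpha: float = 0.05,
) -> ICCEstimate:
    """ICC of predicted probabilities over a (subject, repeat) feature table.

    Builds a balanced prediction panel (k = repeats per subject) and
    delegates to the one-way ICC estimator.
    """
    counts = repeated_table.groupby(level="subject").size()
    k = int(counts.max())
    complete = counts[counts == k].index
    if len(complete) < len(counts):
        logger.warning("prediction ICC: dropping %d incomplete subject(s)",
                       len(counts) - len(complete))
    sub = repeated_table.loc[complete].sort_index()
    preds = bundle.predict_proba(sub)
    panel = RepeatPanel(list(complete), preds.reshape(len(complete), k))
    if np.var(panel.values) == 0.0:
        return ICCEstimate(np.nan, (np.nan, np.nan),
                           panel.n_subjects, panel.k_repeats, degenerate=True)
    return icc_one_way(panel, alpha)


def dice(mask_a: SegmentationMask, mask_b: SegmentationMask) -> float:
    """Dice similarity coefficient 2|A.B| / (|A| + |B|)."""
    if mask_a.array.shape != mask_b.array.shape:
        raise ValueError("masks live on different grids")
    na, nb = mask_a.voxel_count, mask_b.voxel_count
    if na + nb == 0:
        raise ValueError("Dice of two empty masks is undefined")
    inter = int(np.logical_and(mask_a.array, mask_b.array).sum())
    return 2.0 * inter / (na + nb)


def _boundary_coords_mm(mask: SegmentationMask) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask.array)
    boundary = mask.array & ~eroded
    return np.argwhere(boundary) * np.asarray(mask.spacing_mm)


def hausdorff_mm(mask_a: SegmentationMask, mask_b: SegmentationMask) -> float:
    """Symmetric Hausdorff distance (mm) between mask boundary voxels."""
    if mask_a.is_empty() or mask_b.is_empty():
        raise ValueError("Hausdorff distance requires two non-empty masks")
    pa = _boundary_coords_mm(mask_a)
    pb = _boundary_coords_mm(mask_b)
    d_ab = cKDTree(pb).query(pa)[0].max()
    d_ba = cKDTree(pa).query(pb)[0].max()
    return float(max(d_ab, d_ba))


# ------------------------------------------------------------ end-to-end


@dataclass
class ReliabilityReport:
    """Threshold-sweep comparison results.

    ``rows`` holds one record per (repeatability source, ICC threshold,
    classifier) with train/test AUCs + CIs, the three prediction ICCs +
    CIs, and the permutation p-value against the threshold-0 baseline.
    ``skipped`` lists configurations where too few features survived.
    """

    rows: pd.DataFrame
    skipped: list[dict]
    manifest: dict

    def write(self, outdir) -> None:
        from pathlib import Path
        import json

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(outdir / "reliability_report.csv", index=False)
        (outdir / "reliability_manifest.json").write_text(
            json.dumps({"manifest": self.manifest, "skipped": self.skipped}, indent=2))


def extract_cohort_tables(
    cohort: SyntheticCohort,
    space: PerturbationSpace,
    config: PreprocessConfig,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """Extract unperturbed, perturbed and retest feature tables.

    Returns ``{"unperturbed", "perturbed", "retest"}`` tables indexed by
    (subject, repeat); the retest table pairs the unperturbed scan
    (repeat 0) with the retest scan (repeat 1) for subjects having one.
    """
    root = np.random.SeedSequence(seed)
    per_subject = root.spawn(len(cohort.subject_ids))

    unperturbed = extract_table(
        [(sid, 0, *cohort.subjects[sid]) for sid in cohort.subject_ids], config)

    perturbed_entries = []
    for sid, sseq in zip(cohort.subject_ids, per_subject):
        img, msk = cohort.subjects[sid]
        for r, (p_img, p_msk, _) in enumerate(
                perturb_subject(img, msk, space, seed=np.random.default_rng(sseq)), 1):
            perturbed_entries.append((sid, r, p_img, p_msk))
    perturbed = extract_table(perturbed_entries, config)

    retest_entries = [(sid, 1, *cohort.retest_pairs[sid])
                      for sid in cohort.subject_ids if sid in cohort.retest_pairs]
    retest_only = extract_table(retest_entries, config)
    retest_ids = [sid for sid in cohort.subject_ids if sid in cohort.retest_pairs]
    retest = pd.concat([unperturbed.loc[retest_ids], retest_only]).sort_index()

    return {"unperturbed": unperturbed, "perturbed": perturbed, "retest": retest}


def run_comparison(
    cohort: SyntheticCohort,
    thresholds: tuple[float, ...] = (0.0, 0.5, 0.75, 0.9, 0.95),
    model_configs: tuple[ModelConfig, ...] = (ModelConfig(),),
    space: PerturbationSpace | None = None,
    preprocess: PreprocessConfig | None = None,
    train_fraction: float = 0.6,
    n_bootstrap: int = 1000,
    n_permutation: int = 1000,
    seed: int = 0,
    tables: dict[str, pd.DataFrame] | None = None,
    icc_k_plus_1: bool = False,
) -> ReliabilityReport:
    """Full comparison: filter -> mRMR -> train -> evaluate per cell.

    For each repeatability source (perturbation, test-retest), ICC
    threshold and classifier, the pipeline removes volume-dependent
    features, keeps features repeatable at the threshold, ranks them by
    mRMR, trains an easy-ensemble of the given classifier on the top-k,
    and evaluates train/test AUC (bootstrap CIs), the three prediction
    ICCs and the permutation p-value against the threshold-0 baseline.
    Cells whose threshold leaves fewer than k features are skipped with
    a logged reason.
    """
    space = space or PerturbationSpace()
    preprocess = preprocess or PreprocessConfig()
    thresholds = tuple(sorted(thresholds))
    rng = np.random.default_rng(seed)

    if tables is None:
        tables = extract_cohort_tables(cohort, space, preprocess,
                                       seed=int(rng.integers(2**31 - 1)))
    unpert, pert, retest = tables["unperturbed"], tables["perturbed"], tables["retest"]

    train_ids, test_ids = split_cohort(cohort, train_fraction,
                                       seed=int(rng.integers(2**31 - 1)))
    y_train = cohort.outcome_vector(train_ids)
    y_test = cohort.outcome_vector(test_ids)

    train_unpert = unpert.loc[train_ids].droplevel("repeat")
    test_unpert = unpert.loc[test_ids].droplevel("repeat")

    # finite-everywhere descriptor universe
    finite = [c for c in unpert.columns
              if np.isfinite(unpert[c]).all() and np.isfinite(pert[c]).all()
              and np.isfinite(retest[c]).all()]

    vols = train_unpert["original|shape|MeshVolume"].to_numpy()
    vol_ok = set(volume_dependence_filter(train_unpert[finite], vols))

    icc_tables = {
        "perturbation": feature_icc_table(
            pert.loc[train_ids][finite], k_plus_1_denominator=icc_k_plus_1),
        "test_retest": feature_icc_table(
            retest[finite], k_plus_1_denominator=icc_k_plus_1),
    }

    records, skipped = [], []
    baselines: dict[tuple[str, str], np.ndarray] = {}
    for source, icc_tab in icc_tables.items():
        for thr in thresholds:
            repeatable = set(repeatability_filter(icc_tab, thr))
            candidates = sorted(vol_ok & repeatable)
            for mc in model_configs:
                if len(candidates) < mc.n_selected:
                    reason = (f"{source}@{thr}/{mc.classifier_kind}: only "
                              f"{len(candidates)} features survived, need {mc.n_selected}")
                    logger.warning("skipping %s", reason)
                    skipped.append({"source": source, "threshold": thr,
                                    "classifier": mc.classifier_kind,
                                    "n_candidates": len(candidates)})
                    continue
                cell_seed = int(rng.integers(2**31 - 1))
                ranked = mrmr_rank(train_unpert, y_train, candidates, mc.n_selected)
                bundle = train_easy_ensemble(
                    train_unpert, y_train,
                    ModelConfig(mc.classifier_kind, mc.n_selected,
                                mc.n_ensemble, cell_seed),
                    selected=ranked)
                s_train = bundle.predict_proba(train_unpert)
                s_test = bundle.predict_proba(test_unpert)
                tr_auc, tr_ci = bootstrap_ci(y_train, s_train, n_bootstrap, rng)
                te_auc, te_ci = bootstrap_ci(y_test, s_test, n_bootstrap, rng)

                icc_tr_p = prediction_icc(bundle, pert.loc[train_ids])
                icc_te_p = prediction_icc(bundle, pert.loc[test_ids])
                icc_rt = prediction_icc(bundle, retest)

                key = (source, mc.classifier_kind)
                if thr == thresholds[0]:
                    baselines[key] = s_test
                p_base = (np.nan if key not in baselines or thr == thresholds[0]
                          else permutation_compare(y_test, s_test, baselines[key],
                                                   n_permutation, rng))
                records.append({
                    "source": source, "threshold": thr,
                    "classifier": mc.classifier_kind,
                    "n_candidates": len(candidates),
                    "selected": ";".join(ranked),
                    "train_auc": tr_auc, "train_ci_low": tr_ci[0], "train_ci_high": tr_ci[1],
                    "test_auc": te_auc, "test_ci_low": te_ci[0], "test_ci_high": te_ci[1],
                    "icc_train_perturb": icc_tr_p.icc,
                    "icc_train_perturb_low": icc_tr_p.ci95[0],
                    "icc_train_perturb_high": icc_tr_p.ci95[1],
                    "icc_test_perturb": icc_te_p.icc,
                    "icc_test_perturb_low": icc_te_p.ci95[0],
                    "icc_test_perturb_high": icc_te_p.ci95[1],
                    "icc_retest": icc_rt.icc,
                    "icc_retest_low": icc_rt.ci95[0],
                    "icc_retest_high": icc_rt.ci95[1],
                    "p_vs_baseline": p_base,
                })

    manifest = {
        "seed": seed,
        "thresholds": list(thresholds),
        "classifiers": [mc.classifier_kind for mc in model_configs],
        "n_subjects": len(cohort.subject_ids),
        "n_perturbations": space.n_perturbations,
        "train_ids": train_ids,
        "test_ids": test_ids,
    }
    return ReliabilityReport(pd.DataFrame.from_records(records), skipped, manifest)
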