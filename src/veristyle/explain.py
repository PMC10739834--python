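"""Misclassification (confusion-quadrant) stylometric analysis.

After cross-validation, each fold's test set is partitioned into the four
confusion quadrants (positive class = truthful): TP truthful predicted
truthful, TN deceptive predicted deceptive, FN truthful predicted deceptive,
FP deceptive predicted truthful.  Four stylometric contrasts are then run
per fold — FN vs FP, TN vs FN, TP vs FP and TP vs TN — each an
independent-samples permutation test over the 26 features with Holm
correction applied within that fold-contrast family.  Across folds, the
report counts how often each feature stayed significant and averages the
CLES / Cohen's d point estimates and their CI bounds (the study's own
aggregation rule; averaged CI bounds have no strict coverage guarantee).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .harness import PredictionRecord
from .stats import AnalysisConfig, ComparisonResult, compare_groups
from .stylometry import FEATURE_NAMES

__all__ = [
    "CONTRASTS",
    "OutcomeGroups",
    "FoldContrastResult",
    "partition_outcomes",
    "fold_contrasts",
    "aggregate_contrasts",
]

logger = logging.getLogger("veristyle.explain")

#: Contrast name -> (first group, second group); CLES > 0.5 means higher in
#: the first-listed group.
CONTRASTS: dict[str, tuple[str, str]] = {
    "FN_vs_FP": ("FN", "FP"),
    "TN_vs_FN": ("TN", "FN"),
    "TP_vs_FP": ("TP", "FP"),
    "TP_vs_TN": ("TP", "TN"),
}

MIN_GROUP_SIZE = 2


@dataclass(frozen=True)
class OutcomeGroups:
    fold_index: int
    TP: frozenset[str]
    TN: frozenset[str]
    FP: frozenset[str]
    FN: frozenset[str]

    def group(self, name: str) -> frozenset[str]:
        return getattr(self, name)

    @property
    def test_size(self) -> int:
        return len(self.TP) + len(self.TN) + len(self.FP) + len(self.FN)


@dataclass(frozen=True)
class FoldContrastResult:
    contrast: str
    fold_index: int
    results: tuple[ComparisonResult, ...]  # empty when skipped
    skipped_reason: str | None = None


def partition_outcomes(records: Sequence[PredictionRecord],
                       ) -> list[OutcomeGroups]:
    """Quadrant partition of every fold's test set.

    Exact by construction: the four id sets are disjoint and cover each
    fold's records.  A statement appearing twice within a fold is an error.
    """
    by_fold: dict[int, dict[str, set[str]]] = {}
    seen: dict[int, set[str]] = {}
    for rec in records:
        fold = by_fold.setdefault(
            rec.fold_index, {"TP": set(), "TN": set(), "FP": set(), "FN": set()})
        ids = seen.setdefault(rec.fold_index, set())
        if rec.statement_id in ids:
            raise ValueError(
                f"duplicate statement {rec.statement_id!r} in fold {rec.fold_index}")
        ids.add(rec.statement_id)
        truthful = rec.true_label == "truthful"
        predicted_truthful = rec.predicted_label == "truthful"
        if truthful and predicted_truthful:
            fold["TP"].add(rec.statement_id)
        elif not truthful and not predicted_truthful:
            fold["TN"].add(rec.statement_id)
        elif truthful:
            fold["FN"].add(rec.statement_id)
        else:
            fold["FP"].add(rec.statement_id)
    return [OutcomeGroups(fold_index=i, TP=frozenset(g["TP"]),
                          TN=frozenset(g["TN"]), FP=frozenset(g["FP"]),
                          FN=frozenset(g["FN"]))
            for i, g in sorted(by_fold.items())]


def fold_contrasts(groups: Sequence[OutcomeGroups], features: pd.DataFrame,
                   config: AnalysisConfig,
                   feature_names: Sequence[str] = FEATURE_NAMES,
                   ) -> list[FoldContrastResult]:
    """Per-fold, per-contrast permutation comparisons over the 26 features.

    ``features`` must cover every test statement (indexed by statement id).
    A contrast whose either quadrant has fewer than two statements is
    skipped with a logged reason.  Holm correction is applied within each
    fold-contrast family.
    """
    out: list[FoldContrastResult] = []
    for fold in groups:
        missing = (fold.TP | fold.TN | fold.FP | fold.FN) - set(features.index)
        if missing:
            raise ValueError(
                f"fold {fold.fold_index}: feature matrix lacks statements "
                f"{sorted(missing)[:5]}")
        for contrast, (first, second) in CONTRASTS.items():
            ids1 = sorted(fold.group(first))
            ids2 = sorted(fold.group(second))
            if len(ids1) < MIN_GROUP_SIZE or len(ids2) < MIN_GROUP_SIZE:
                reason = (f"group sizes {first}={len(ids1)}, "
                          f"{second}={len(ids2)} below {MIN_GROUP_SIZE}")
                logger.info("fold %d %s skipped: %s",
                            fold.fold_index, contrast, reason)
                out.append(FoldContrastResult(
                    contrast=contrast, fold_index=fold.fold_index,
                    results=(), skipped_reason=reason))
                continue
            # reuse the group-comparison engine with the first-listed group
            # in the 'truthful' slot, so CLES > 0.5 reads "higher in first"
            sub = pd.concat([
                features.loc[ids1, list(feature_names)].assign(veracity="truthful"),
                features.loc[ids2, list(feature_names)].assign(veracity="deceptive"),
            ])
            results = compare_groups(sub, "independent", config, feature_names)
            out.append(FoldContrastResult(
                contrast=contrast, fold_index=fold.fold_index,
                results=tuple(results)))
    return out


def aggregate_contrasts(results: Sequence[FoldContrastResult],
                        ) -> dict[str, pd.DataFrame]:
    """Cross-fold aggregation per contrast.

    Per feature: the number of folds in which it survived Holm correction,
    the number of folds in which it was tested at all, the arithmetic means
    of the per-fold CLES / d points and CI bounds, and the dominant effect
    direction.  Features are ordered by significance count (descending);
    features never tested in any fold are omitted rather than zero-filled.
    """
    tables: dict[str, pd.DataFrame] = {}
    for contrast in CONTRASTS:
        per_feature: dict[str, list[ComparisonResult]] = {}
        n_folds = 0
        for fc in results:
            if fc.contrast != contrast:
                continue
            n_folds += 1
            for res in fc.results:
                per_feature.setdefault(res.feature, []).append(res)
        rows = []
        for feature, items in per_feature.items():
            n_sig = sum(r.significant for r in items)
            directions = [r.direction for r in items if r.direction != "none"]
            dominant = (max(set(directions), key=directions.count)
                        if directions else "none")
            rows.append({
                "feature": feature,
                "n_significant_folds": n_sig,
                "n_folds_tested": len(items),
                "mean_cles": float(np.mean([r.effect.cles for r in items])),
                "mean_cles_lo": float(np.mean([r.effect.cles_ci[0] for r in items])),
                "mean_cles_hi": float(np.mean([r.effect.cles_ci[1] for r in items])),
                "mean_d": float(np.mean([r.effect.d for r in items])),
                "mean_d_lo": float(np.mean([r.effect.d_ci[0] for r in items])),
                "mean_d_hi": float(np.mean([r.effect.d_ci[1] for r in items])),
                "dominant_direction": dominant,
            })
        frame = pd.DataFrame(rows)
        if not frame.empty:
            frame = frame.sort_values(
                ["n_significant_folds", "feature"],
                ascending=[False, True]).reset_index(drop=True)
        tables[contrast] = frame
    return tables
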