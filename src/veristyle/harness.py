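"""Three-scenario cross-validated classification harness.

Scenario 1 is k-fold cross-validation within one corpus; Scenario 2 trains
on the union of two full corpora and tests on the held-out third; Scenario 3
concatenates the Scenario-1 folds of all corpora fold-by-fold, so the same
cached splits serve both scenarios and every classifier sees identical
train/test partitions.  Splits are grouped by subject where required so no
participant contributes to both train and test of the same fold.

Classifiers plug in through a minimal adapter contract (fit on texts +
labels, predict label strings); a bag-of-words + L2 logistic-regression
baseline and a constant dummy are built in.  Predicted strings are parsed
case-insensitively to the two labels; unparseable outputs are tallied and
scored as a misclassification of the true class.  The positive class is
``truthful`` throughout.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Protocol, Sequence

import numpy as np
from sklearn.feature_extraction.text import CountVectorizer
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import Pipeline

from .corpus import Corpus, Statement, VERACITY_LABELS

__all__ = [
    "FoldSplit",
    "ScenarioSpec",
    "EvaluationUnit",
    "PredictionRecord",
    "RunSummary",
    "ClassifierAdapter",
    "BowLogisticAdapter",
    "DummyAdapter",
    "make_folds",
    "build_scenario",
    "parse_label",
    "run_cv",
]

logger = logging.getLogger("veristyle.harness")


@dataclass(frozen=True)
class FoldSplit:
    fold_index: int
    train_ids: frozenset[str]
    test_ids: frozenset[str]


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative scenario description.

    S1: ``train_corpora == test_corpora`` is one corpus, k-fold CV.
    S2: two disjoint train corpora, one held-out test corpus, no folds.
    S3: k-fold CV over the union of all named corpora, fold-aligned.
    """

    scenario: str  # S1 | S2 | S3
    train_corpora: tuple[str, ...]
    test_corpora: tuple[str, ...]
    k: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("S1", "S2", "S3"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "S2" and set(self.train_corpora) & set(self.test_corpora):
            raise ValueError("S2 requires disjoint train and test corpora")


@dataclass(frozen=True)
class EvaluationUnit:
    """One fit/predict unit: a fold of S1/S3, or the single S2 pairing."""

    fold_index: int | None
    train: tuple[Statement, ...]
    test: tuple[Statement, ...]


@dataclass(frozen=True)
class PredictionRecord:
    statement_id: str
    fold_index: int
    true_label: str
    predicted_label: str
    raw_output: str


@dataclass
class RunSummary:
    fold_accuracies: list[float]
    mean_accuracy: float
    sd_accuracy: float
    confusion_mean: np.ndarray  # [[TP, FN], [FP, TN]], positive = truthful
    confusion_sd: np.ndarray
    unparseable_outputs: int


# ---------------------------------------------------------------------------
# Folds and scenarios
# ---------------------------------------------------------------------------

def make_folds(corpus: Corpus, k: int, seed: int,
               group_by_subject: bool = False) -> list[FoldSplit]:
    """Seeded k-fold partition of statements (or subjects, when grouped).

    Units are shuffled and dealt into k near-equal partitions (the first
    n mod k partitions take one extra unit); fold i tests on partition i and
    trains on the rest.  Grouped splitting keeps every statement of a
    subject inside a single partition, so no subject straddles train and
    test.  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if group_by_subject:
        units = corpus.subjects()
        members: dict[str, list[str]] = {}
        for st in corpus:
            members.setdefault(st.subject_id, []).append(st.id)
    else:
        units = corpus.ids()
        members = {sid: [sid] for sid in units}
    if len(units) < k:
        raise ValueError(
            f"cannot make {k} folds from {len(units)} "
            f"{'subjects' if group_by_subject else 'statements'}")
    rng = np.random.default_rng(seed)
    shuffled = list(units)
    rng.shuffle(shuffled)
    base, extra = divmod(len(shuffled), k)
    partitions: list[list[str]] = []
    start = 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        partitions.append(shuffled[start:start + size])
        start += size
    all_ids = frozenset(corpus.ids())
    folds = []
    for i in range(k):
        test_ids = frozenset(m for unit in partitions[i] for m in members[unit])
        folds.append(FoldSplit(fold_index=i, train_ids=all_ids - test_ids,
                               test_ids=test_ids))
    return folds


def _statements_by_id(corpus: Corpus) -> dict[str, Statement]:
    return {st.id: st for st in corpus}


def build_scenario(spec: ScenarioSpec, corpora: Mapping[str, Corpus],
                   folds: Mapping[str, Sequence[FoldSplit]] | None = None,
                   ) -> list[EvaluationUnit]:
    """Materialize the train/test statement sets of a scenario.

    ``folds`` is the cache of per-corpus splits (required for S1/S3 so that
    different classifiers evaluate on identical partitions); S2 ignores it.
    """
    for name in set(spec.train_corpora) | set(spec.test_corpora):
        if name not in corpora:
            raise ValueError(f"unknown corpus {name!r}")

    if spec.scenario == "S2":
        train = tuple(st for name in spec.train_corpora for st in corpora[name])
        test = tuple(st for name in spec.test_corpora for st in corpora[name])
        return [EvaluationUnit(fold_index=None, train=train, test=test)]

    names = tuple(dict.fromkeys(spec.train_corpora))
    if spec.scenario == "S1" and len(names) != 1:
        raise ValueError("S1 uses exactly one corpus")
    if folds is None:
        folds = {name: make_folds(corpora[name], spec.k, spec.seed)
                 for name in names}
    units = []
    for i in range(spec.k):
        train: list[Statement] = []
        test: list[Statement] = []
        for name in names:
            by_id = _statements_by_id(corpora[name])
            split = folds[name][i]
            train.extend(by_id[sid] for sid in corpora[name].ids()
                         if sid in split.train_ids)
            test.extend(by_id[sid] for sid in corpora[name].ids()
                        if sid in split.test_ids)
        units.append(EvaluationUnit(fold_index=i, train=tuple(train),
                                    test=tuple(test)))
    return units


# ---------------------------------------------------------------------------
# Classifier adapters
# ---------------------------------------------------------------------------

class ClassifierAdapter(Protocol):
    """Contract every classifier must satisfy: ``fit`` consumes raw training
    texts with their label strings; ``predict`` returns one string per input
    text (parsed downstream, so a text-to-text model can answer in free
    form).  ``fit`` must reset any previous state."""

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> None: ...

    def predict(self, texts: Sequence[str]) -> list[str]: ...


class BowLogisticAdapter:
    """Bag-of-words counts + L2-regularized logistic regression.

    The vocabulary is built from the training texts only; out-of-vocabulary
    tokens at predict time are ignored by construction of the count
    vectorizer.
    """

    def __init__(self, max_features: int | None = 5000, C: float = 1.0,
                 ngram_range: tuple[int, int] = (1, 1), seed: int = 0):
        self.max_features = max_features
        self.C = C
        self.ngram_range = ngram_range
        self.seed = seed
        self._pipeline: Pipeline | None = None

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> None:
        if len(set(labels)) < 2:
            raise ValueError("training set must contain both labels")
        self._pipeline = Pipeline([
            ("bow", CountVectorizer(max_features=self.max_features,
                                    ngram_range=self.ngram_range,
                                    lowercase=True)),
            ("logreg", LogisticRegression(C=self.C, max_iter=2000,
                                          random_state=self.seed)),
        ])
        self._pipeline.fit(list(texts), list(labels))

    def predict(self, texts: Sequence[str]) -> list[str]:
        if self._pipeline is None:
            raise RuntimeError("adapter not fitted")
        return [str(lbl) for lbl in self._pipeline.predict(list(texts))]


class DummyAdapter:
    """Constant-answer adapter (degenerate baseline / test double)."""

    def __init__(self, answer: str = "truthful"):
        self.answer = answer

    def fit(self, texts: Sequence[str], labels: Sequence[str]) -> None:
        pass

    def predict(self, texts: Sequence[str]) -> list[str]:
        return [self.answer] * len(texts)


def parse_label(raw: str) -> str | None:
    """Parse a generated label string to a canonical veracity label.

    Case-insensitive; surrounding punctuation and whitespace ignored.
    Returns None for unparseable output.
    """
    cleaned = "".join(ch for ch in raw.lower() if ch.isalpha())
    return cleaned if cleaned in VERACITY_LABELS else None


# ---------------------------------------------------------------------------
# Cross-validation driver
# ---------------------------------------------------------------------------

def _other_label(label: str) -> str:
    return "deceptive" if label == "truthful" else "truthful"


def run_cv(units: Sequence[EvaluationUnit], adapter: ClassifierAdapter,
           ) -> tuple[list[PredictionRecord], RunSummary]:
    """Fit/predict every evaluation unit and aggregate fold metrics.

    Per fold: accuracy, and the confusion matrix [[TP, FN], [FP, TN]] with
    truthful as the positive class; across folds the elementwise mean and
    sample sd.  Unparseable adapter outputs are logged, tallied and scored
    as a misclassification of the true label, which keeps the quadrant
    partition of every test set exact.
    """
    if not units:
        raise ValueError("no evaluation units")
    records: list[PredictionRecord] = []
    accuracies: list[float] = []
    confusions: list[np.ndarray] = []
    unparseable = 0
    for unit in units:
        fold = unit.fold_index if unit.fold_index is not None else 0
        try:
            adapter.fit([st.text for st in unit.train],
                        [st.veracity for st in unit.train])
            raw_outputs = adapter.predict([st.text for st in unit.test])
        except Exception as exc:
            raise RuntimeError(f"adapter failed on fold {fold}: {exc}") from exc
        if len(raw_outputs) != len(unit.test):
            raise RuntimeError(
                f"adapter returned {len(raw_outputs)} predictions for "
                f"{len(unit.test)} test statements on fold {fold}")
        confusion = np.zeros((2, 2))
        correct = 0
        for st, raw in zip(unit.test, raw_outputs):
            predicted = parse_label(raw)
            if predicted is None:
                unparseable += 1
                logger.warning("fold %d: unparseable output %r for %s",
                               fold, raw, st.id)
                predicted = _other_label(st.veracity)
            if predicted == st.veracity:
                correct += 1
            row = 0 if st.veracity == "truthful" else 1
            col = 0 if predicted == "truthful" else 1
            confusion[row, col] += 1
            records.append(PredictionRecord(
                statement_id=st.id, fold_index=fold,
                true_label=st.veracity, predicted_label=predicted,
                raw_output=raw))
        accuracies.append(correct / len(unit.test))
        confusions.append(confusion)
        logger.info("fold %d: train=%d test=%d accuracy=%.4f",
                    fold, len(unit.train), len(unit.test), accuracies[-1])
    stack = np.stack(confusions)
    mean_acc = float(np.mean(accuracies))
    sd_acc = float(np.std(accuracies, ddof=1)) if len(accuracies) > 1 else float("nan")
    summary = RunSummary(
        fold_accuracies=accuracies,
        mean_accuracy=mean_acc,
        sd_accuracy=sd_acc,
        confusion_mean=stack.mean(axis=0),
        confusion_sd=(stack.std(axis=0, ddof=1) if stack.shape[0] > 1
                      else np.full((2, 2), np.nan)),
        unparseable_outputs=unparseable,
    )
    return records, summary
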