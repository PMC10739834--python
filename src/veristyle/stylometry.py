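"""The 26-feature theory-based style vector.

The feature set operationalizes four psychological accounts of deception:

* Cognitive Load — length/complexity statistics (sentence, word, syllable
  counts, Flesch reading ease and Flesch-Kincaid grade), under the idea that
  fabrication yields shorter, simpler statements;
* Distancing — self- vs. other-reference pronoun percentages;
* Reality Monitoring — perceptual/contextual/affective vs. cognitive word
  percentages plus the mean lexical concreteness of content words;
* Verifiability — counts of unique named entities about people, times,
  places and quantities (checkable details).

Lexicon scores are percentages of word tokens; composites are sums of
category percentages; the reality-monitoring score is
perceptual + contextual + affect - cognition.  ``Analytic``, ``Authentic``
and ``Tone`` are 0-100 summary scales computed with documented open
approximations of the proprietary originals.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from .corpus import (ConfigurationError, Corpus, DataError, Statement,
                     is_word_token, tokenize, word_tokens)
from .resources import (CategoryLexicon, ConcretenessTable, EntityAnnotation,
                        NER_LABEL_MAP, StyleResources)

__all__ = [
    "FEATURE_NAMES",
    "META_COLUMNS",
    "split_sentences",
    "count_syllables",
    "score_lexicon",
    "readability_block",
    "concreteness_score",
    "entity_counts",
    "composite_features",
    "extract_style_vector",
    "extract_features",
    "write_feature_matrix",
    "read_feature_matrix",
]

#: The 26 features, in report order.
FEATURE_NAMES = (
    "num_sentences", "num_words", "num_syllables", "avg_syllabes_per_word",
    "fk_grade", "fk_read",
    "Analytic", "Authentic", "Tone",
    "tone_pos", "tone_neg", "Cognition", "memory",
    "focuspast", "focuspresent", "focusfuture",
    "Self_reference", "Other_reference",
    "Perceptual_details", "Contextual_Embedding", "Reality_Monitoring",
    "Concreteness_score",
    "People", "Temporal_details", "Spatial_details", "Quantity_details",
)

META_COLUMNS = ("subject_id", "domain", "topic", "veracity")

ENTITY_FEATURES = {
    "People": "People", "Temporal": "Temporal_details",
    "Spatial": "Spatial_details", "Quantity": "Quantity_details",
}


# ---------------------------------------------------------------------------
# Sentences and syllables
# ---------------------------------------------------------------------------

#: Words before a period that do not end a sentence.
ABBREVIATIONS = frozenset({
    "mr", "mrs", "ms", "dr", "prof", "st", "etc", "vs", "e.g", "i.e",
    "jr", "sr", "approx", "dept",
})

_BOUNDARY_RE = re.compile(r"([.!?]+)\s+(?=[\"'(]?[A-Z])")


def split_sentences(text: str, abbreviations: frozenset[str] = ABBREVIATIONS,
                    ) -> list[str]:
    """Split on terminal ``. ! ?`` followed by whitespace and an uppercase
    letter, skipping boundaries after known abbreviations."""
    sentences: list[str] = []
    start = 0
    for m in _BOUNDARY_RE.finditer(text):
        candidate = text[start:m.end(1)]
        words = candidate.split()
        last = words[-1].rstrip(".!?").strip("\"'(),;:").lower() if words else ""
        if "." in m.group(1) and last in abbreviations:
            continue
        sentences.append(candidate.strip())
        start = m.end()
    tail = text[start:].strip()
    if tail:
        sentences.append(tail)
    return [s for s in sentences if any(ch.isalnum() for ch in s)]


_VOWEL_GROUPS_RE = re.compile(r"[aeiouy]+")
_SILENT_E_RE = re.compile(r"[^aeiouy]e$")


def count_syllables(word: str) -> int:
    """Vowel-group heuristic: count runs of a/e/i/o/u/y, subtract a silent
    terminal 'e' unless it is the word's only vowel group; minimum 1."""
    w = word.lower()
    n = len(_VOWEL_GROUPS_RE.findall(w))
    if n > 1 and _SILENT_E_RE.search(w):
        n -= 1
    return max(n, 1)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def score_lexicon(tokens: Sequence[str], lexicon: CategoryLexicon,
                  ) -> dict[str, float]:
    """Percentage of word tokens matching each lexicon category.

    Matching is case-insensitive; a token may count toward several
    categories.  Raises on an empty token list (percentages undefined).
    """
    words = [t for t in tokens if is_word_token(t)]
    if not words:
        raise DataError("cannot score an empty token list")
    counts = {name: 0 for name in lexicon.categories}
    for tok in words:
        for cat in lexicon.match(tok):
            counts[cat] += 1
    total = len(words)
    return {name: 100.0 * c / total for name, c in counts.items()}


@dataclass(frozen=True)
class ReadabilityBlock:
    num_sentences: int
    num_words: int
    num_syllables: int
    avg_syllabes_per_word: float
    fk_grade: float
    fk_read: float


def readability_block(text: str) -> ReadabilityBlock:
    """Cognitive-load statistics and the Flesch/Flesch-Kincaid indices.

    fk_grade = 0.39 (W/S) + 11.8 (Y/W) - 15.59;
    fk_read = 206.835 - 1.015 (W/S) - 84.6 (Y/W),
    with W words, S sentences, Y syllables.
    """
    words = word_tokens(text)
    sentences = split_sentences(text)
    if not words or not sentences:
        raise DataError("readability undefined without words and sentences")
    n_words = len(words)
    n_sents = len(sentences)
    n_syll = sum(count_syllables(w) for w in words)
    wps = n_words / n_sents
    spw = n_syll / n_words
    return ReadabilityBlock(
        num_sentences=n_sents,
        num_words=n_words,
        num_syllables=n_syll,
        avg_syllabes_per_word=spw,
        fk_grade=0.39 * wps + 11.8 * spw - 15.59,
        fk_read=206.835 - 1.015 * wps - 84.6 * spw,
    )


def concreteness_score(
    text: str,
    table: ConcretenessTable,
    stopwords: frozenset[str],
    lemmatizer: Callable[[str], str],
) -> tuple[float | None, int]:
    """Mean concreteness of matched content words, with the match count.

    Pipeline: lowercase -> tokenize -> drop stopwords and punctuation ->
    lemmatize -> look up.  Unmatched words are excluded from the mean; when
    nothing matches the score is ``None`` (undefined), never zero.
    """
    if not table:
        raise ConfigurationError("concreteness table is empty")
    scores: list[float] = []
    for tok in word_tokens(text.lower()):
        if tok in stopwords:
            continue
        lemma = lemmatizer(tok)
        if lemma in table:
            scores.append(table[lemma])
    if not scores:
        return None, 0
    return sum(scores) / len(scores), len(scores)


def _normalize_surface(surface: str) -> str:
    return " ".join(surface.casefold().split())


def entity_counts(
    text: str,
    recognizer: Callable[[str], list[EntityAnnotation]],
) -> dict[str, int]:
    """Unique named-entity counts per verifiable-detail category.

    Surfaces are case-folded and whitespace-collapsed before uniqueness;
    recognizer labels are mapped through :data:`NER_LABEL_MAP` (PERSON ->
    People, DATE/TIME -> Temporal, locations -> Spatial, numeric labels ->
    Quantity); unmapped labels are ignored.
    """
    unique: dict[str, set[str]] = {c: set() for c in ENTITY_FEATURES}
    for ann in recognizer(text):
        category = NER_LABEL_MAP.get(ann.label)
        if category is None:
            continue
        unique[category].add(_normalize_surface(ann.surface))
    return {ENTITY_FEATURES[c]: len(s) for c, s in unique.items()}


def _clamp(value: float, lo: float = 0.0, hi: float = 100.0) -> float:
    return min(max(value, lo), hi)


def composite_features(categories: Mapping[str, float]) -> dict[str, float]:
    """Composite style scores from category percentages.

    Self/Other reference and the perceptual/contextual sums follow the
    feature table exactly; ``Tone`` maps the positive/negative balance onto
    0-100 with equality at 50; ``Analytic`` is the categorical-dynamic
    index (30 + article + prep - ppron - ipron - auxverb - conj - adverb -
    negate) and ``Authentic`` an analogous open composite rewarding
    self-reference and cognitive elaboration and penalizing negative tone
    and motion framing — both clamped to [0, 100] and documented as
    approximations of the proprietary summary scales.
    """
    required = ("i", "we", "shehe", "they", "you", "attention", "visual",
                "auditory", "feeling", "space", "motion", "time", "Affect",
                "Cognition", "tone_pos", "tone_neg", "article", "prep",
                "ppron", "ipron", "auxverb", "conj", "adverb", "negate")
    for name in required:
        if name not in categories:
            raise ConfigurationError(f"missing lexicon category {name!r}")
    c = categories
    perceptual = c["attention"] + c["visual"] + c["auditory"] + c["feeling"]
    contextual = c["space"] + c["motion"] + c["time"]
    tp, tn = c["tone_pos"], c["tone_neg"]
    tone = 50.0 if tp + tn == 0 else 50.0 * (1.0 + (tp - tn) / (tp + tn))
    analytic = _clamp(30.0 + c["article"] + c["prep"] - c["ppron"] - c["ipron"]
                      - c["auxverb"] - c["conj"] - c["adverb"] - c["negate"])
    authentic = _clamp(30.0 + c["i"] + c["we"] + c["Cognition"]
                       - c["tone_neg"] - c["motion"])
    return {
        "Self_reference": c["i"] + c["we"],
        "Other_reference": c["shehe"] + c["they"] + c["you"],
        "Perceptual_details": perceptual,
        "Contextual_Embedding": contextual,
        "Reality_Monitoring": perceptual + contextual + c["Affect"] - c["Cognition"],
        "Tone": tone,
        "Analytic": analytic,
        "Authentic": authentic,
    }


def extract_style_vector(statement: Statement,
                         resources: StyleResources) -> dict[str, float]:
    """One 26-feature style vector (dict keyed by :data:`FEATURE_NAMES`).

    ``Concreteness_score`` is NaN when no content word matches the
    concreteness table; every other feature is always defined.
    Deterministic for fixed resources.
    """
    try:
        tokens = tokenize(statement.text)
        block = readability_block(statement.text)
        cats = score_lexicon(tokens, resources.lexicon)
        composites = composite_features(cats)
        conc, _n_matched = concreteness_score(
            statement.text, resources.concreteness,
            resources.stopwords, resources.lemmatizer)
        entities = entity_counts(statement.text, resources.recognizer)
    except ConfigurationError:
        raise
    except Exception as exc:
        raise DataError(f"feature extraction failed for statement "
                        f"{statement.id!r}: {exc}") from exc
    vector: dict[str, float] = {
        "num_sentences": block.num_sentences,
        "num_words": block.num_words,
        "num_syllables": block.num_syllables,
        "avg_syllabes_per_word": block.avg_syllabes_per_word,
        "fk_grade": block.fk_grade,
        "fk_read": block.fk_read,
        "tone_pos": cats["tone_pos"],
        "tone_neg": cats["tone_neg"],
        "Cognition": cats["Cognition"],
        "memory": cats["memory"],
        "focuspast": cats["focuspast"],
        "focuspresent": cats["focuspresent"],
        "focusfuture": cats["focusfuture"],
        "Concreteness_score": math.nan if conc is None else conc,
    }
    vector.update(composites)
    vector.update(entities)
    return {name: float(vector[name]) for name in FEATURE_NAMES}


def extract_features(corpus: Corpus, resources: StyleResources) -> pd.DataFrame:
    """Feature matrix for a whole corpus: one row per statement, indexed by
    statement id, with the 26 feature columns plus subject/domain/topic/
    veracity metadata."""
    rows = []
    for st in corpus:
        vec = extract_style_vector(st, resources)
        vec.update({"subject_id": st.subject_id, "domain": st.domain,
                    "topic": st.topic, "veracity": st.veracity})
        rows.append(vec)
    frame = pd.DataFrame(rows, index=pd.Index(corpus.ids(), name="id"))
    return frame[list(META_COLUMNS) + list(FEATURE_NAMES)]


def write_feature_matrix(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, index_label="id")


def read_feature_matrix(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, index_col="id")
    missing = [f for f in FEATURE_NAMES if f not in frame.columns]
    if missing:
        raise DataError(f"feature matrix lacks columns: {missing}")
    return frame
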