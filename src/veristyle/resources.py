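"""Pluggable lexical resources for stylometric feature extraction.

The feature extractor is resource-agnostic: it consumes a category lexicon
(LIWC-style ``.dic`` format, literal words plus trailing-asterisk stems), a
word-to-concreteness table (the shape of the Brysbaert et al. norms), a
stopword list, a lemmatizer (any word -> lemma callable) and a named-entity
recognizer (any text -> annotation-list callable).  Because the reference
LIWC-22 dictionary is proprietary, this module also ships a small open
fixture lexicon covering every required category; feature values are
comparable to published LIWC-based numbers only when an equivalent
dictionary is supplied.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Mapping

from .corpus import ConfigurationError, tokenize

__all__ = [
    "REQUIRED_CATEGORIES",
    "CategoryLexicon",
    "ConcretenessTable",
    "EntityAnnotation",
    "NER_LABEL_MAP",
    "GazetteerRecognizer",
    "identity_lemmatizer",
    "DictLemmatizer",
    "DEFAULT_STOPWORDS",
    "load_stopwords",
    "fixture_lexicon",
    "fixture_concreteness",
    "fixture_recognizer",
    "StyleResources",
    "fixture_resources",
]

#: Categories every lexicon must provide (composite features depend on them).
REQUIRED_CATEGORIES = (
    "i", "we", "shehe", "they", "you",
    "article", "prep", "ppron", "ipron", "auxverb", "conj", "adverb", "negate",
    "tone_pos", "tone_neg",
    "Cognition", "memory",
    "focuspast", "focuspresent", "focusfuture",
    "attention", "visual", "auditory", "feeling",
    "space", "motion", "time",
    "Affect",
)


class CategoryLexicon:
    """A category -> entries lexicon with trailing-asterisk stem matching.

    Entries are lowercase; ``run*`` matches any word token starting with
    ``run`` (so ``running`` matches, ``ran`` does not).  One token may count
    toward several categories.
    """

    def __init__(self, categories: Mapping[str, Iterable[str]]):
        self.categories: dict[str, frozenset[str]] = {}
        for name, entries in categories.items():
            entries = frozenset(entries)
            if not entries:
                raise ConfigurationError(f"lexicon category {name!r} is empty")
            for e in entries:
                if e != e.lower():
                    raise ConfigurationError(
                        f"lexicon entry {e!r} in {name!r} must be lowercase")
                if "*" in e[:-1]:
                    raise ConfigurationError(
                        f"lexicon entry {e!r}: wildcard only allowed in final position")
            self.categories[name] = entries
        # fast matcher structures
        self._literals: dict[str, set[str]] = {}
        self._prefixes: list[tuple[str, str]] = []
        for name, entries in self.categories.items():
            for e in entries:
                if e.endswith("*"):
                    self._prefixes.append((e[:-1], name))
                else:
                    self._literals.setdefault(e, set()).add(name)

    def validate_required(self) -> None:
        missing = [c for c in REQUIRED_CATEGORIES if c not in self.categories]
        if missing:
            raise ConfigurationError(f"lexicon lacks required categories: {missing}")

    def match(self, token: str) -> set[str]:
        """Categories matched by one word token (case-insensitive)."""
        tok = token.lower()
        cats = set(self._literals.get(tok, ()))
        for prefix, name in self._prefixes:
            if tok.startswith(prefix):
                cats.add(name)
        return cats

    def entries(self, category: str) -> frozenset[str]:
        return self.categories[category]

    def literal_entries(self, category: str) -> tuple[str, ...]:
        return tuple(sorted(e for e in self.categories[category] if not e.endswith("*")))

    # -- LIWC-style .dic format ------------------------------------------
    @classmethod
    def from_dic(cls, path: str | Path) -> "CategoryLexicon":
        """Read a ``.dic`` dictionary: %-delimited id/name header, then
        ``word<TAB>id id ...`` rows."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        try:
            first = lines.index("%")
            second = lines.index("%", first + 1)
        except ValueError as exc:
            raise ConfigurationError(f"{path}: not a %-delimited .dic file") from exc
        id_to_name: dict[str, str] = {}
        for line in lines[first + 1:second]:
            if not line.strip():
                continue
            cid, name = line.split(None, 1)
            id_to_name[cid] = name.strip()
        cats: dict[str, set[str]] = {name: set() for name in id_to_name.values()}
        for line in lines[second + 1:]:
            if not line.strip():
                continue
            parts = line.split()
            word, ids = parts[0].lower(), parts[1:]
            for cid in ids:
                if cid not in id_to_name:
                    raise ConfigurationError(f"{path}: unknown category id {cid!r}")
                cats[id_to_name[cid]].add(word)
        return cls(cats)

    def to_dic(self, path: str | Path) -> None:
        names = sorted(self.categories)
        ids = {name: str(i + 1) for i, name in enumerate(names)}
        word_ids: dict[str, list[str]] = {}
        for name in names:
            for e in self.categories[name]:
                word_ids.setdefault(e, []).append(ids[name])
        out = ["%"]
        out += [f"{ids[name]}\t{name}" for name in names]
        out.append("%")
        out += [f"{w}\t" + "\t".join(word_ids[w]) for w in sorted(word_ids)]
        Path(path).write_text("\n".join(out) + "\n", encoding="utf-8")


class ConcretenessTable(dict):
    """Lowercase lemma -> concreteness score in [1, 5]."""

    def __init__(self, scores: Mapping[str, float]):
        super().__init__()
        for word, score in scores.items():
            score = float(score)
            if not 1.0 <= score <= 5.0:
                raise ConfigurationError(
                    f"concreteness score for {word!r} outside [1, 5]: {score}")
            self[word.lower()] = score

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ConcretenessTable":
        scores: dict[str, float] = {}
        for line in Path(path).read_text(encoding="utf-8").splitlines():
            if not line.strip() or line.lower().startswith("word\t"):
                continue
            word, score = line.split("\t")[:2]
            scores[word] = float(score)
        return cls(scores)

    def to_tsv(self, path: str | Path) -> None:
        rows = [f"{w}\t{s}" for w, s in sorted(self.items())]
        Path(path).write_text("word\tscore\n" + "\n".join(rows) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Lemmatizers and stopwords
# ---------------------------------------------------------------------------

def identity_lemmatizer(word: str) -> str:
    return word


class DictLemmatizer:
    """Lemmatizer backed by an explicit word -> lemma mapping."""

    def __init__(self, mapping: Mapping[str, str]):
        self.mapping = {k.lower(): v.lower() for k, v in mapping.items()}

    def __call__(self, word: str) -> str:
        return self.mapping.get(word, word)


DEFAULT_STOPWORDS = frozenset("""
a an the and or but if then is are was were be been am i me my we us our you
your he she it they them this that these those to of in on at with from for
not no do does did have has had will would can could should as by so
""".split())


def load_stopwords(path: str | Path) -> frozenset[str]:
    words = Path(path).read_text(encoding="utf-8").split()
    return frozenset(w.lower() for w in words)


def write_stopwords(stopwords: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(sorted(stopwords)) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Named-entity recognition
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EntityAnnotation:
    surface: str
    label: str


#: Recognizer label -> verifiable-detail category.  Covers the spaCy-style
#: label inventory plus the category names themselves.
NER_LABEL_MAP = {
    "PERSON": "People", "PER": "People", "People": "People",
    "DATE": "Temporal", "TIME": "Temporal", "Temporal": "Temporal",
    "GPE": "Spatial", "LOC": "Spatial", "LOCATION": "Spatial",
    "FAC": "Spatial", "FACILITY": "Spatial", "Spatial": "Spatial",
    "PERCENT": "Quantity", "MONEY": "Quantity", "QUANTITY": "Quantity",
    "ORDINAL": "Quantity", "CARDINAL": "Quantity", "Quantity": "Quantity",
}

_TIME_RE = re.compile(r"^\d{1,2}:\d{2}$")
_PERCENT_RE = re.compile(r"^\d+(\.\d+)?%$")
_NUMBER_RE = re.compile(r"^\d+(\.\d+)?$")


class GazetteerRecognizer:
    """Deterministic named-entity stub: gazetteer lists plus number patterns.

    Matches single word tokens case-insensitively against people / place /
    temporal / quantity gazetteers, plus regex patterns for clock times,
    percentages and bare numbers; a number followed by a currency or unit
    token is merged into one annotation ("5 $", "100 m").
    """

    UNIT_TOKENS = frozenset({"$", "€", "£", "m", "km", "kg", "miles", "percent"})
    MERIDIEM = frozenset({"am", "pm"})

    def __init__(self, people: Iterable[str], places: Iterable[str],
                 temporal: Iterable[str], quantity_words: Iterable[str]):
        self.people = frozenset(w.lower() for w in people)
        self.places = frozenset(w.lower() for w in places)
        self.temporal = frozenset(w.lower() for w in temporal)
        self.quantity_words = frozenset(w.lower() for w in quantity_words)

    def __call__(self, text: str) -> list[EntityAnnotation]:
        tokens = tokenize(text)
        annotations: list[EntityAnnotation] = []
        i = 0
        while i < len(tokens):
            tok = tokens[i]
            low = tok.lower()
            nxt = tokens[i + 1].lower() if i + 1 < len(tokens) else ""
            if low in self.people:
                annotations.append(EntityAnnotation(tok, "PERSON"))
            elif low in self.places:
                annotations.append(EntityAnnotation(tok, "GPE"))
            elif low in self.temporal:
                annotations.append(EntityAnnotation(tok, "DATE"))
            elif _TIME_RE.match(low):
                if nxt in self.MERIDIEM:
                    annotations.append(
                        EntityAnnotation(f"{tok} {tokens[i + 1]}", "TIME"))
                    i += 2
                    continue
                annotations.append(EntityAnnotation(tok, "TIME"))
            elif _PERCENT_RE.match(low):
                annotations.append(EntityAnnotation(tok, "PERCENT"))
            elif _NUMBER_RE.match(low):
                if nxt in self.UNIT_TOKENS:
                    annotations.append(
                        EntityAnnotation(f"{tok} {tokens[i + 1]}", "QUANTITY"))
                    i += 2
                    continue
                annotations.append(EntityAnnotation(tok, "CARDINAL"))
            elif low in self.quantity_words:
                annotations.append(EntityAnnotation(tok, "CARDINAL"))
            i += 1
        return annotations


# ---------------------------------------------------------------------------
# Fixture resources (open, deterministic, test-scale)
# ---------------------------------------------------------------------------

_FIXTURE_CATEGORIES: dict[str, tuple[str, ...]] = {
    "i": ("i", "me", "my", "mine", "myself"),
    "we": ("we", "us", "our", "ours", "ourselves"),
    "shehe": ("he", "she", "him", "her", "his", "hers", "himself", "herself"),
    "they": ("they", "them", "their", "theirs", "themselves"),
    "you": ("you", "your", "yours", "yourself"),
    "article": ("a", "an", "the"),
    "prep": ("in", "on", "at", "with", "from", "to", "of", "for", "about",
             "over", "under"),
    "ipron": ("it", "its", "this", "that", "these", "those", "something",
              "anything"),
    "auxverb": ("is", "are", "was", "were", "be", "been", "am", "have", "has",
                "had", "do", "does", "did", "will", "would", "can", "could",
                "should"),
    "conj": ("and", "but", "or", "so", "because", "while", "although"),
    "adverb": ("very", "really", "quite", "just", "too", "also", "often",
               "always"),
    "negate": ("not", "no", "never", "none", "cannot", "nothing"),
    "tone_pos": ("happy", "good", "great", "wonderful", "nice", "glad", "joy",
                 "love", "loved"),
    "tone_neg": ("sad", "bad", "terrible", "awful", "angry", "worried", "fear",
                 "hate", "hated"),
    "Cognition": ("think*", "thought", "know*", "believe*", "reason*",
                  "because", "consider*", "understand*", "wonder*"),
    "memory": ("remember*", "forget*", "forgot", "recall*", "memory",
               "memories"),
    "focuspast": ("was", "were", "did", "had", "went", "yesterday", "ago",
                  "earlier"),
    "focuspresent": ("is", "are", "am", "now", "today", "currently"),
    "focusfuture": ("will", "shall", "tomorrow", "soon", "later", "plan*",
                    "going"),
    "attention": ("attention", "notice*", "watch*", "look*", "observe*"),
    "visual": ("see", "saw", "seen", "bright", "dark", "visible", "color*"),
    "auditory": ("hear*", "heard", "sound*", "loud", "quiet", "noise"),
    "feeling": ("feel*", "felt", "touch*", "warm", "cold", "soft"),
    "space": ("room", "place*", "near", "far", "above", "below", "inside",
              "outside", "area"),
    "motion": ("go", "went", "goes", "move*", "walk*", "drive*", "arrive*",
               "travel*"),
    "time": ("when", "hour*", "minute*", "day", "days", "week*", "month*",
             "year*", "moment"),
}
# ppron is the union of the five personal-pronoun categories; Affect is the
# union of the two tone categories, as in the reference dictionary's hierarchy.
_FIXTURE_CATEGORIES["ppron"] = tuple(sorted(
    set(_FIXTURE_CATEGORIES["i"]) | set(_FIXTURE_CATEGORIES["we"])
    | set(_FIXTURE_CATEGORIES["shehe"]) | set(_FIXTURE_CATEGORIES["they"])
    | set(_FIXTURE_CATEGORIES["you"])))
_FIXTURE_CATEGORIES["Affect"] = tuple(sorted(
    set(_FIXTURE_CATEGORIES["tone_pos"]) | set(_FIXTURE_CATEGORIES["tone_neg"])))

#: High- and low-concreteness word pools (synthetic norms in the [1, 5]
#: convention of the published concreteness ratings).
CONCRETE_WORDS: dict[str, float] = {
    "apple": 5.0, "hammer": 4.95, "table": 4.9, "chair": 4.9, "bottle": 4.9,
    "bread": 4.9, "stone": 4.8, "window": 4.8, "ladder": 4.85, "river": 4.7,
}
ABSTRACT_WORDS: dict[str, float] = {
    "notion": 1.4, "justice": 1.45, "freedom": 1.6, "theory": 1.4,
    "belief": 1.5, "concept": 1.3, "honor": 1.6, "virtue": 1.4,
    "logic": 1.5, "ethics": 1.45,
}

GAZETTEER_PEOPLE = (
    "Mary", "Paul", "Adam", "Sarah", "John", "Emma", "David", "Laura",
    "Peter", "Anna", "James", "Lucy", "Robert", "Alice", "Henry", "Clara",
    "Thomas", "Julia", "Brian", "Nora",
)
GAZETTEER_PLACES = (
    "Tokyo", "Paris", "Berlin", "London", "Madrid", "Rome", "Oslo", "Vienna",
    "Dublin", "Prague", "Lisbon", "Athens", "Cairo", "Sydney", "Toronto",
    "Denver", "Austin", "Boston", "Seattle", "Chicago",
)
GAZETTEER_TEMPORAL = (
    "Monday", "Tuesday", "Wednesday", "Thursday", "Friday", "Saturday",
    "Sunday", "January", "February", "April", "June", "July", "August",
    "September", "October", "November", "December", "Christmas", "Easter",
    "midnight",
)
GAZETTEER_QUANTITY = (
    "ten", "twenty", "thirty", "forty", "fifty", "hundred", "thousand",
    "dozen", "first", "second", "third", "fourth", "fifth",
)


def fixture_lexicon() -> CategoryLexicon:
    lex = CategoryLexicon(_FIXTURE_CATEGORIES)
    lex.validate_required()
    return lex


def fixture_concreteness() -> ConcretenessTable:
    return ConcretenessTable({**CONCRETE_WORDS, **ABSTRACT_WORDS})


def fixture_recognizer() -> GazetteerRecognizer:
    return GazetteerRecognizer(GAZETTEER_PEOPLE, GAZETTEER_PLACES,
                               GAZETTEER_TEMPORAL, GAZETTEER_QUANTITY)


@dataclass
class StyleResources:
    """Everything the feature extractor needs, bundled."""

    lexicon: CategoryLexicon
    concreteness: ConcretenessTable
    stopwords: frozenset[str]
    lemmatizer: Callable[[str], str] = identity_lemmatizer
    recognizer: Callable[[str], list[EntityAnnotation]] = field(
        default_factory=fixture_recognizer)

    def __post_init__(self) -> None:
        self.lexicon.validate_required()


def fixture_resources() -> StyleResources:
    """The open test-scale resource bundle (also used by the synthetic
    generator, whose carrier words are drawn from these same lists)."""
    return StyleResources(
        lexicon=fixture_lexicon(),
        concreteness=fixture_concreteness(),
        stopwords=DEFAULT_STOPWORDS,
        lemmatizer=identity_lemmatizer,
        recognizer=fixture_recognizer(),
    )
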