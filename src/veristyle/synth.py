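"""Synthetic two-class, three-domain corpora with known ground truth.

Statements are template-assembled word sequences, not fluent prose: every
downstream computation here is lexical or statistical, so a corpus built
from a neutral word pool plus controlled injections exercises the full
pipeline while keeping the generative recipe exactly known.  Injections:

* lexicon-category carriers (words matching one target category) raise a
  percentage feature by a chosen number of points in one class;
* length draws shift ``num_words`` (and sentence-pacing shifts
  ``num_sentences``);
* named-entity mentions from per-domain gazetteer pools shift the four
  unique-entity counts;
* mixing high- vs. low-concreteness pools shifts ``Concreteness_score``;
* optional class-marker words give classifiers a learnable signal, either
  shared across domains or strictly domain-specific (the construction that
  reproduces the cross-domain generalization collapse of Scenario 2).

Injection probabilities are rescaled per statement so that expected planted
shifts equal their configured values exactly; the realized recipe is
returned as a :class:`GroundTruth` so recovery tests never reverse-engineer
the generator.  Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .corpus import ConfigurationError, Corpus, Statement
from .resources import (ABSTRACT_WORDS, CONCRETE_WORDS, GAZETTEER_PEOPLE,
                        GAZETTEER_PLACES, GAZETTEER_QUANTITY,
                        GAZETTEER_TEMPORAL, StyleResources,
                        fixture_resources)
from .stylometry import FEATURE_NAMES, extract_features

__all__ = [
    "PlantedEffect",
    "SyntheticConfig",
    "GroundTruth",
    "generate_corpus",
    "generate_domain_corpora",
    "planted_truth_check",
    "NEUTRAL_POOL",
]

#: Filler vocabulary: concrete-ish nouns that match no lexicon category, no
#: gazetteer entry and no concreteness-table row (asserted at build time).
NEUTRAL_POOL: tuple[str, ...] = (
    "garden", "market", "letter", "music", "bridge", "cloud", "engine",
    "forest", "meadow", "copper", "pencil", "ribbon", "saddle", "lantern",
    "marble", "velvet", "barrel", "canvas", "cellar", "orchard", "pepper",
    "timber", "wagon", "willow", "anchor", "basket", "candle", "falcon",
    "garnet", "harbor", "island", "jacket", "kettle", "linen", "mirror",
    "needle", "otter", "puzzle", "quartz", "rocket", "shovel", "tunnel",
    "turnip", "valley", "walnut", "zephyr", "amber", "branch", "drum",
    "elbow", "fabric", "gravel", "hinge", "ivory", "jungle", "knot",
    "lemon", "mosaic", "nickel", "oak", "parcel", "quilt", "reef",
    "satchel", "thread", "urn", "vessel", "wheat", "yarn", "zinc",
    "acorn", "badger", "cedar", "dome", "fern", "goose", "hazel",
    "iris", "jade", "kiln", "lotus", "maple", "nutmeg", "olive", "pebble",
)

#: Class-marker vocabulary (truthful word, deceptive word) per scope.
SHARED_MARKERS = ("crimson", "indigo")
DOMAIN_MARKERS = {
    "opinion": ("sapphire", "emerald"),
    "memory": ("topaz", "obsidian"),
    "intention": ("cobalt", "magenta"),
}

#: Lexicon categories each percentage feature may draw carriers from.
_CARRIER_CATEGORIES: dict[str, tuple[str, ...]] = {
    "tone_pos": ("tone_pos",),
    "tone_neg": ("tone_neg",),
    "Cognition": ("Cognition",),
    "memory": ("memory",),
    "focuspast": ("focuspast",),
    "focuspresent": ("focuspresent",),
    "focusfuture": ("focusfuture",),
    "Self_reference": ("i", "we"),
    "Other_reference": ("shehe", "they", "you"),
    "Perceptual_details": ("attention", "visual", "auditory", "feeling"),
    "Contextual_Embedding": ("space", "motion", "time"),
    "Reality_Monitoring": ("attention", "visual", "auditory", "feeling",
                           "space", "motion", "time"),
}
#: Parent categories implied by membership (hierarchy of the fixture lexicon).
_IMPLIED = {
    "i": ("ppron",), "we": ("ppron",), "shehe": ("ppron",),
    "they": ("ppron",), "you": ("ppron",),
    "tone_pos": ("Affect",), "tone_neg": ("Affect",),
}
#: Which categories each lexicon-derived feature depends on (used to compute
#: incidental contamination of non-planted features).
_FEATURE_DEPS: dict[str, frozenset[str]] = {
    "tone_pos": frozenset({"tone_pos"}), "tone_neg": frozenset({"tone_neg"}),
    "Cognition": frozenset({"Cognition"}), "memory": frozenset({"memory"}),
    "focuspast": frozenset({"focuspast"}),
    "focuspresent": frozenset({"focuspresent"}),
    "focusfuture": frozenset({"focusfuture"}),
    "Self_reference": frozenset({"i", "we"}),
    "Other_reference": frozenset({"shehe", "they", "you"}),
    "Perceptual_details": frozenset({"attention", "visual", "auditory",
                                     "feeling"}),
    "Contextual_Embedding": frozenset({"space", "motion", "time"}),
    "Reality_Monitoring": frozenset({"attention", "visual", "auditory",
                                     "feeling", "space", "motion", "time",
                                     "Affect", "Cognition"}),
    "Tone": frozenset({"tone_pos", "tone_neg"}),
    "Analytic": frozenset({"article", "prep", "ppron", "ipron", "auxverb",
                           "conj", "adverb", "negate"}),
    "Authentic": frozenset({"i", "we", "Cognition", "tone_neg", "motion"}),
}

_ENTITY_FEATURES = ("People", "Temporal_details", "Spatial_details",
                    "Quantity_details")
_SYLLABLE_BLOCK = frozenset({"num_syllables", "avg_syllabes_per_word",
                             "fk_grade", "fk_read"})

_ENTITY_POOLS = {
    "People": GAZETTEER_PEOPLE,
    "Spatial_details": GAZETTEER_PLACES,
    "Temporal_details": GAZETTEER_TEMPORAL,
    "Quantity_details": GAZETTEER_QUANTITY + tuple(
        str(n) for n in (3, 7, 12, 15, 19, 24, 31, 42, 57, 68, 73, 86, 91)),
}


@dataclass(frozen=True)
class PlantedEffect:
    """One planted truthful-minus-deceptive mean shift, in feature units
    (percentage points for lexicon features, words for num_words, unique
    entities for the entity counts, score points for Concreteness_score)."""

    feature: str
    delta: float


@dataclass(frozen=True)
class SyntheticConfig:
    """The generative recipe.

    ``n_subjects`` is per domain; opinion-like subjects contribute five
    statements each (half truthful and half deceptive plus one extra,
    alternating by subject), other domains one statement per subject with
    alternating labels, so classes stay exactly balanced (``n_subjects``
    must be even).  Lengths are normal draws (words), floored at 6.
    ``class_signal`` is ``none``, ``shared`` or ``domain_specific``;
    ``domain_specific`` additionally makes every planted carrier pool
    disjoint across domains.
    """

    domains: tuple[str, ...] = ("opinion", "memory", "intention")
    n_subjects: int = 120
    length_mean: float = 55.0
    length_sd: float = 20.0
    planted_effects: tuple[PlantedEffect, ...] = ()
    domain_specific: bool = False
    class_signal: str = "none"
    signal_rate: float = 0.12
    seed: int = 0
    background_category_rate: float = 0.25
    entity_rate: float = 0.8
    concreteness_rate: float = 0.15
    words_per_sentence: int = 9

    def __post_init__(self) -> None:
        for d in self.domains:
            if d not in ("opinion", "memory", "intention"):
                raise ConfigurationError(f"unknown synthetic domain {d!r}")
        if self.n_subjects < 2 or self.n_subjects % 2:
            raise ConfigurationError("n_subjects must be even and >= 2")
        if self.length_mean < 6:
            raise ConfigurationError("length_mean must be >= 6 words")
        if self.class_signal not in ("none", "shared", "domain_specific"):
            raise ConfigurationError(f"unknown class_signal {self.class_signal!r}")
        for eff in self.planted_effects:
            if eff.feature not in FEATURE_NAMES:
                raise ConfigurationError(f"unknown feature {eff.feature!r}")


@dataclass
class GroundTruth:
    """The generator's own record of what it planted.

    ``expected_shifts`` are exact expected truthful-minus-deceptive mean
    differences; ``carriers`` maps domain -> feature -> injected word pool;
    ``contaminated`` lists features with incidental class asymmetry (carrier
    words touching extra categories, syllable-profile differences), which
    recovery tests must not treat as null; ``clean_null_features`` is the
    complement actually expected to center on zero.
    """

    config: SyntheticConfig
    expected_shifts: dict[str, float]
    carriers: dict[str, dict[str, tuple[str, ...]]]
    contaminated: frozenset[str]
    marker_words: dict[str, tuple[str, str]]

    @property
    def clean_null_features(self) -> frozenset[str]:
        return (frozenset(FEATURE_NAMES) - set(self.expected_shifts)
                - self.contaminated)


# ---------------------------------------------------------------------------
# Carrier planning
# ---------------------------------------------------------------------------

def _split_round_robin(items: Sequence[str], n: int) -> list[tuple[str, ...]]:
    return [tuple(items[i::n]) for i in range(n)]


def _exclusive_carriers(feature: str, lexicon) -> list[str]:
    """Literal entries of the feature's categories whose full category
    membership stays inside the feature's own dependency set (plus the
    implied hierarchy parents), so one injected word moves exactly the
    intended percentage features."""
    cats = _CARRIER_CATEGORIES[feature]
    allowed = set(cats)
    for c in cats:
        allowed.update(_IMPLIED.get(c, ()))
    words: list[str] = []
    for cat in cats:
        for w in lexicon.literal_entries(cat):
            if lexicon.match(w) <= allowed and w not in words:
                words.append(w)
    if not words:
        raise ConfigurationError(
            f"no exclusive carrier words available for {feature!r}")
    return words


def _plan(config: SyntheticConfig, resources: StyleResources) -> GroundTruth:
    lexicon = resources.lexicon
    n_domains = len(config.domains)
    expected: dict[str, float] = {}
    carriers: dict[str, dict[str, tuple[str, ...]]] = {d: {} for d in config.domains}
    contaminated: set[str] = set()
    touched_categories: set[str] = set()

    for eff in config.planted_effects:
        f, delta = eff.feature, float(eff.delta)
        if f in expected:
            raise ConfigurationError(f"feature {f!r} planted twice")
        if f in _CARRIER_CATEGORIES:
            words = _exclusive_carriers(f, lexicon)
            if config.domain_specific:
                chunks = _split_round_robin(words, n_domains)
                if any(not c for c in chunks):
                    raise ConfigurationError(
                        f"not enough carrier words for {f!r} across domains")
            else:
                chunks = [tuple(words)] * n_domains
            for d, chunk in zip(config.domains, chunks):
                carriers[d][f] = chunk
            for w in words:
                touched_categories.update(lexicon.match(w))
        elif f in _ENTITY_FEATURES:
            pool = _ENTITY_POOLS[f]
            if config.domain_specific:
                chunks = _split_round_robin(pool, n_domains)
            else:
                chunks = [tuple(pool)] * n_domains
            for d, chunk in zip(config.domains, chunks):
                carriers[d][f] = chunk
        elif f == "num_words":
            contaminated.update({"num_sentences"})
        elif f == "num_sentences":
            contaminated.update({"fk_grade", "fk_read"})
        elif f == "Concreteness_score":
            if abs(delta) > _conc_span():
                raise ConfigurationError(
                    f"Concreteness_score shift {delta} exceeds the pool span")
        else:
            raise ConfigurationError(
                f"feature {f!r} has no available carrier (readability and "
                f"summary-scale features cannot be planted directly)")
        expected[f] = delta

    # carrier words touching extra categories contaminate the features that
    # depend on those categories
    for feature, deps in _FEATURE_DEPS.items():
        if feature in expected:
            continue
        if deps & touched_categories:
            contaminated.add(feature)
    # any class-asymmetric word choice perturbs the syllable profile
    if expected or config.class_signal != "none":
        contaminated.update(_SYLLABLE_BLOCK)
    contaminated -= set(expected)

    markers: dict[str, tuple[str, str]] = {}
    if config.class_signal == "shared":
        markers = {d: SHARED_MARKERS for d in config.domains}
    elif config.class_signal == "domain_specific":
        markers = {d: DOMAIN_MARKERS[d] for d in config.domains}

    _assert_inert(resources, markers)
    return GroundTruth(config=config, expected_shifts=expected,
                       carriers=carriers, contaminated=frozenset(contaminated),
                       marker_words=markers)


def _conc_span() -> float:
    return (float(np.mean(list(CONCRETE_WORDS.values())))
            - float(np.mean(list(ABSTRACT_WORDS.values()))))


def _assert_inert(resources: StyleResources,
                  markers: Mapping[str, tuple[str, str]]) -> None:
    """Neutral-pool and marker words must be invisible to every resource."""
    lexicon = resources.lexicon
    gazetteers = set()
    for pool in _ENTITY_POOLS.values():
        gazetteers.update(w.lower() for w in pool)
    suspects = list(NEUTRAL_POOL)
    for pair in markers.values():
        suspects.extend(pair)
    for w in suspects:
        if lexicon.match(w):
            raise ConfigurationError(
                f"pool word {w!r} matches lexicon categories {lexicon.match(w)}")
        if w in resources.concreteness:
            raise ConfigurationError(f"pool word {w!r} is in the concreteness table")
        if w in gazetteers:
            raise ConfigurationError(f"pool word {w!r} collides with a gazetteer")


# ---------------------------------------------------------------------------
# Statement assembly
# ---------------------------------------------------------------------------

def _veracity_pattern(domain: str, subject_index: int,
                      per_subject: int) -> list[str]:
    if domain == "opinion":
        return ["truthful" if (j + subject_index) % 2 == 0 else "deceptive"
                for j in range(per_subject)]
    return ["truthful" if subject_index % 2 == 0 else "deceptive"]


_OPINION_TOPICS = ("abortion", "cannabis", "euthanasia", "immigration",
                   "gay_marriage")


@dataclass(frozen=True)
class _Pools:
    background: tuple[str, ...]
    concrete: tuple[str, ...]
    abstract: tuple[str, ...]


def _make_pools(resources: StyleResources) -> _Pools:
    lexicon = resources.lexicon
    background = tuple(sorted(
        {w for cat in lexicon.categories for w in lexicon.literal_entries(cat)}))
    return _Pools(background=background,
                  concrete=tuple(sorted(CONCRETE_WORDS)),
                  abstract=tuple(sorted(ABSTRACT_WORDS)))


def _build_statement_text(rng: np.random.Generator, config: SyntheticConfig,
                          truth: GroundTruth, pools: _Pools, domain: str,
                          veracity: str) -> str:
    truthful = veracity == "truthful"
    length_delta = truth.expected_shifts.get("num_words", 0.0)
    mean = config.length_mean + (length_delta / 2 if truthful else -length_delta / 2)
    n_words = max(6, int(round(rng.normal(mean, config.length_sd))))

    # entity injections first: unique surfaces, one slot each
    entity_words: list[str] = []
    for feature in _ENTITY_FEATURES:
        pool = truth.carriers[domain].get(feature, _ENTITY_POOLS[feature]
                                          if config.entity_rate > 0 else ())
        lam = config.entity_rate
        delta = truth.expected_shifts.get(feature, 0.0)
        if (delta > 0) == truthful and delta != 0:
            lam += abs(delta)
        if lam <= 0 or not pool:
            continue
        count = min(int(rng.poisson(lam)), len(pool),
                    max(n_words // 4 - len(entity_words), 0))
        if count > 0:
            picks = rng.choice(len(pool), size=count, replace=False)
            entity_words.extend(pool[int(i)] for i in picks)
    n_free = n_words - len(entity_words)

    # per-slot injection probabilities, rescaled so that expected token
    # fractions over the whole statement are exact despite entity slots
    scale = n_words / n_free if n_free > 0 else 0.0
    intervals: list[tuple[float, str, object]] = []
    cum = 0.0
    for feature, words in truth.carriers[domain].items():
        if feature in _ENTITY_FEATURES:
            continue
        delta = truth.expected_shifts[feature]
        if (delta > 0) == truthful and delta != 0:
            p = abs(delta) / 100.0 * scale
            intervals.append((cum + p, "carrier", words))
            cum += p
    if truth.marker_words:
        marker = truth.marker_words[domain][0 if truthful else 1]
        p = config.signal_rate * scale
        intervals.append((cum + p, "marker", marker))
        cum += p
    conc_delta = truth.expected_shifts.get("Concreteness_score", 0.0)
    mix_shift = conc_delta / _conc_span() / 2.0
    conc_mix = 0.5 + (mix_shift if truthful else -mix_shift)
    p = config.concreteness_rate * scale
    intervals.append((cum + p, "concrete", conc_mix))
    cum += p
    p = config.background_category_rate * scale
    intervals.append((cum + p, "background", None))
    cum += p
    if cum > 1.0:
        raise ConfigurationError(
            "total injection probability exceeds 1; lower the planted deltas "
            "or rates")

    background_words = pools.background
    concrete_pool = pools.concrete
    abstract_pool = pools.abstract

    words: list[str] = []
    for _ in range(n_free):
        u = rng.random()
        chosen: str | None = None
        for bound, kind, payload in intervals:
            if u < bound:
                if kind == "carrier":
                    chosen = payload[int(rng.integers(len(payload)))]
                elif kind == "marker":
                    chosen = str(payload)
                elif kind == "concrete":
                    if rng.random() < float(payload):
                        chosen = concrete_pool[int(rng.integers(len(concrete_pool)))]
                    else:
                        chosen = abstract_pool[int(rng.integers(len(abstract_pool)))]
                else:
                    chosen = background_words[int(rng.integers(len(background_words)))]
                break
        if chosen is None:
            chosen = NEUTRAL_POOL[int(rng.integers(len(NEUTRAL_POOL)))]
        words.append(chosen)

    # scatter entity mentions over the statement
    if entity_words:
        positions = sorted(rng.choice(len(words) + len(entity_words),
                                      size=len(entity_words), replace=False))
        for pos, ent in zip(positions, entity_words):
            words.insert(min(pos, len(words)), ent)

    # sentence pacing; an optional planted num_sentences shift adjusts the
    # words-per-sentence of one class
    wps = float(config.words_per_sentence)
    sent_delta = truth.expected_shifts.get("num_sentences", 0.0)
    if sent_delta:
        base_sents = config.length_mean / wps
        target = base_sents + (sent_delta / 2 if truthful else -sent_delta / 2)
        wps = config.length_mean / max(target, 1.0)
    wps_n = max(2, int(round(wps)))
    sentences = [words[i:i + wps_n] for i in range(0, len(words), wps_n)]
    rendered = []
    for sent in sentences:
        sent = list(sent)
        sent[0] = sent[0][:1].upper() + sent[0][1:]
        rendered.append(" ".join(sent) + ".")
    return " ".join(rendered)


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def generate_domain_corpora(config: SyntheticConfig,
                            resources: StyleResources | None = None,
                            ) -> tuple[dict[str, Corpus], GroundTruth]:
    """One corpus per configured domain, sharing a single GroundTruth."""
    if resources is None:
        resources = fixture_resources()
    truth = _plan(config, resources)
    pools = _make_pools(resources)
    # planted carrier words must reach a class only through their planted
    # injections (and, under domain_specific, only in their own domain), so
    # they are removed from the symmetric background draw
    planted_words = {w for per_domain in truth.carriers.values()
                     for f, words in per_domain.items()
                     if f not in _ENTITY_FEATURES for w in words}
    if planted_words:
        pools = _Pools(
            background=tuple(w for w in pools.background
                             if w not in planted_words),
            concrete=pools.concrete, abstract=pools.abstract)
    rng = np.random.default_rng(config.seed)
    corpora: dict[str, Corpus] = {}
    for domain in config.domains:
        per_subject = 5 if domain == "opinion" else 1
        statements: list[Statement] = []
        for s in range(config.n_subjects):
            subject_id = f"{domain[:3]}_s{s:04d}"
            pattern = _veracity_pattern(domain, s, per_subject)
            for j, veracity in enumerate(pattern):
                text = _build_statement_text(rng, config, truth, pools,
                                             domain, veracity)
                topic = (_OPINION_TOPICS[j % len(_OPINION_TOPICS)]
                         if domain == "opinion" else "")
                statements.append(Statement(
                    id=f"{domain[:3]}_{s:04d}_{j}", subject_id=subject_id,
                    domain=domain, veracity=veracity, text=text, topic=topic))
        corpora[domain] = Corpus(name=domain, statements=statements,
                                 provenance=f"synthetic seed={config.seed}")
    return corpora, truth


def generate_corpus(config: SyntheticConfig,
                    resources: StyleResources | None = None,
                    ) -> tuple[Corpus, GroundTruth]:
    """All configured domains concatenated into one corpus."""
    corpora, truth = generate_domain_corpora(config, resources)
    statements = [st for d in config.domains for st in corpora[d]]
    name = "synthetic" if len(corpora) > 1 else config.domains[0]
    return Corpus(name=name, statements=statements,
                  provenance=f"synthetic seed={config.seed}"), truth


def planted_truth_check(corpus: Corpus, truth: GroundTruth,
                        resources: StyleResources | None = None,
                        ) -> pd.DataFrame:
    """Realized truthful-minus-deceptive mean shifts vs. the ground truth.

    Returns one row per feature with the realized shift, its standard
    error, the expected shift (0 for clean null features, NaN for
    contaminated ones) and the z-score of realized minus expected — the
    oracle table for parameter-recovery tests.
    """
    if resources is None:
        resources = fixture_resources()
    features = extract_features(corpus, resources)
    rows = []
    for feature in FEATURE_NAMES:
        x = features.loc[features["veracity"] == "truthful", feature].dropna()
        y = features.loc[features["veracity"] == "deceptive", feature].dropna()
        shift = float(x.mean() - y.mean())
        se = float(np.sqrt(x.var(ddof=1) / len(x) + y.var(ddof=1) / len(y)))
        if feature in truth.expected_shifts:
            expected = truth.expected_shifts[feature]
        elif feature in truth.contaminated:
            expected = np.nan
        else:
            expected = 0.0
        z = (shift - expected) / se if se > 0 and np.isfinite(expected) else np.nan
        rows.append({"feature": feature, "realized_shift": shift,
                     "se": se, "expected_shift": expected, "z": z})
    return pd.DataFrame(rows).set_index("feature")
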