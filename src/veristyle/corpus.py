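"""Labelled statement corpora: loading, validation and descriptive statistics.

A corpus is an ordered collection of short statements, each carrying a
veracity label (``truthful`` or ``deceptive``), a subject identifier, a
domain (personal opinions, autobiographical memories, future intentions, or
synthetic) and an optional topic.  This module owns the package tokenizer —
the single word-counting contract used by every downstream computation —
plus the Table-2-style summary statistics (per-group word-count ranges and
the Jaccard vocabulary-overlap index between the truthful and deceptive
vocabularies).
"""

from __future__ import annotations

import csv
import json
import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

__all__ = [
    "Statement",
    "Corpus",
    "GroupWordStats",
    "CorpusSummary",
    "RowError",
    "ConfigurationError",
    "DataError",
    "VERACITY_LABELS",
    "DOMAINS",
    "tokenize",
    "word_tokens",
    "count_words",
    "load_corpus",
    "write_corpus_csv",
    "write_corpus_jsonl",
    "corpus_summary",
    "jaccard_vocabulary",
    "HIPPOCORPUS_PROFILE",
    "OSF_INTENTION_PROFILE",
]

VERACITY_LABELS = ("truthful", "deceptive")
DOMAINS = ("opinion", "memory", "intention", "synthetic")

CANONICAL_COLUMNS = ("id", "subject_id", "domain", "topic", "veracity", "text")


class ConfigurationError(ValueError):
    """A column mapping or resource configuration problem."""


class DataError(ValueError):
    """Invalid data content (untranslatable label, empty text, duplicate id)."""


# ---------------------------------------------------------------------------
# Tokenizer
# ---------------------------------------------------------------------------

def _is_punct_char(ch: str) -> bool:
    return not ch.isalnum()


def tokenize(text: str) -> list[str]:
    """Deterministic whitespace tokenizer with edge-punctuation splitting.

    Rules: split on whitespace; leading and trailing punctuation characters
    of each chunk become their own single-character tokens; everything
    internal is kept attached, so clitic apostrophes ("it's") and internal
    symbols ("2:30") stay inside one token.  Case is preserved.
    """
    tokens: list[str] = []
    for chunk in text.split():
        lead: list[str] = []
        trail: list[str] = []
        while chunk and _is_punct_char(chunk[0]):
            lead.append(chunk[0])
            chunk = chunk[1:]
        while chunk and _is_punct_char(chunk[-1]):
            trail.append(chunk[-1])
            chunk = chunk[:-1]
        tokens.extend(lead)
        if chunk:
            tokens.append(chunk)
        tokens.extend(reversed(trail))
    return tokens


def is_word_token(token: str) -> bool:
    """A word token contains at least one alphanumeric character."""
    return any(ch.isalnum() for ch in token)


def word_tokens(text: str) -> list[str]:
    return [t for t in tokenize(text) if is_word_token(t)]


def count_words(text: str) -> int:
    return len(word_tokens(text))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Statement:
    """One labelled statement."""

    id: str
    subject_id: str
    domain: str
    veracity: str
    text: str
    topic: str = ""

    def validate(self) -> None:
        if not self.id:
            raise DataError("statement id must be non-empty")
        if self.domain not in DOMAINS:
            raise DataError(f"statement {self.id}: unknown domain {self.domain!r}")
        if self.veracity not in VERACITY_LABELS:
            raise DataError(
                f"statement {self.id}: veracity must be one of {VERACITY_LABELS}, "
                f"got {self.veracity!r}"
            )
        if count_words(self.text) == 0:
            raise DataError(f"statement {self.id}: text has no word tokens")


@dataclass
class Corpus:
    name: str
    statements: list[Statement]
    provenance: str = ""
    load_errors: list["RowError"] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self.statements:
            raise DataError(f"corpus {self.name!r} is empty")
        seen: set[str] = set()
        for st in self.statements:
            st.validate()
            if st.id in seen:
                raise DataError(f"corpus {self.name!r}: duplicate id {st.id!r}")
            seen.add(st.id)

    def __len__(self) -> int:
        return len(self.statements)

    def __iter__(self):
        return iter(self.statements)

    def ids(self) -> list[str]:
        return [s.id for s in self.statements]

    def subjects(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for s in self.statements:
            if s.subject_id not in seen:
                seen.add(s.subject_id)
                out.append(s.subject_id)
        return out

    def by_veracity(self, label: str) -> list[Statement]:
        if label not in VERACITY_LABELS:
            raise ValueError(f"unknown veracity label {label!r}")
        return [s for s in self.statements if s.veracity == label]


@dataclass(frozen=True)
class RowError:
    row: int
    reason: str


@dataclass(frozen=True)
class GroupWordStats:
    n: int
    min_words: int | None
    max_words: int | None
    mean_words: float | None
    sd_words: float | None  # sample (n-1) sd; None when undefined (n < 2)


@dataclass(frozen=True)
class CorpusSummary:
    n_total: int
    n_truthful: int
    n_deceptive: int
    overall: GroupWordStats
    truthful: GroupWordStats
    deceptive: GroupWordStats
    jaccard_index: float | None


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

#: Column-mapping profiles for the two public corpus layouts.
HIPPOCORPUS_PROFILE = {
    "id": "AssignmentId",
    "subject_id": "WorkerId",
    "text": "story",
    "veracity": "memType",
    "label_map": {"recalled": "truthful", "retold": "truthful", "imagined": "deceptive"},
    "domain": "memory",
}

OSF_INTENTION_PROFILE = {
    "id": "id",
    "subject_id": "id",
    "text": "statement",
    "veracity": "outcome_class",
    "label_map": {"t": "truthful", "d": "deceptive"},
    "domain": "intention",
}


def _read_rows(path: Path) -> list[dict]:
    if path.suffix.lower() in {".jsonl", ".json"}:
        rows = []
        with path.open(encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    rows.append(json.loads(line))
        return rows
    with path.open(encoding="utf-8", newline="") as fh:
        return list(csv.DictReader(fh))


def load_corpus(
    path: str | Path,
    mapping: Mapping[str, object],
    *,
    name: str | None = None,
    permissive: bool = False,
    row_filter=None,
) -> Corpus:
    """Load a CSV or JSONL corpus under a column mapping.

    ``mapping`` names the source column/key for ``id``, ``subject_id``,
    ``text`` and ``veracity`` (``domain`` and ``topic`` optional; a literal
    default domain may be given under ``"domain"`` when no such column
    exists).  ``label_map`` translates raw veracity values (matched
    case-insensitively) to the canonical labels.  In permissive mode invalid
    rows are rejected into ``Corpus.load_errors`` instead of aborting the
    load; ``row_filter`` (row-dict -> bool) drops rows before validation.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"corpus file not found: {path}")
    rows = _read_rows(path)
    if not rows:
        raise DataError(f"{path}: empty corpus file")
    if row_filter is not None:
        rows = [r for r in rows if row_filter(r)]
        if not rows:
            raise DataError(f"{path}: row filter removed every row")

    for key in ("text", "veracity"):
        if key not in mapping:
            raise ConfigurationError(f"column mapping lacks required key {key!r}")
    label_map = {
        str(k).strip().lower(): v for k, v in dict(mapping.get("label_map", {})).items()
    }
    default_domain = None
    domain_col = None
    dom = mapping.get("domain")
    if dom in DOMAINS:
        default_domain = str(dom)
    elif dom is not None:
        domain_col = str(dom)

    def col(row: dict, key: str, i: int, required: bool = True) -> str:
        src = mapping.get(key)
        if src is None:
            return ""
        if src not in row:
            raise ConfigurationError(
                f"{path}: mapped column {src!r} (for {key!r}) missing in row {i}"
            )
        return str(row[src]) if row[src] is not None else ""

    statements: list[Statement] = []
    errors: list[RowError] = []
    for i, row in enumerate(rows):
        try:
            text = col(row, "text", i)
            raw_label = col(row, "veracity", i).strip()
            key = raw_label.lower()
            if label_map:
                if key not in label_map:
                    raise DataError(
                        f"{path}: row {i}: untranslatable veracity label {raw_label!r}"
                    )
                veracity = str(label_map[key])
            elif key in VERACITY_LABELS:
                veracity = key
            else:
                raise DataError(
                    f"{path}: row {i}: untranslatable veracity label {raw_label!r}"
                )
            sid = col(row, "id", i) if "id" in mapping else str(i)
            subject = col(row, "subject_id", i) if "subject_id" in mapping else sid
            if domain_col is not None:
                domain = str(row.get(domain_col, "")).strip() or "synthetic"
            else:
                domain = default_domain or "synthetic"
            topic = str(row.get(mapping.get("topic", ""), "") or "")
            st = Statement(
                id=sid, subject_id=subject or sid, domain=domain,
                veracity=veracity, text=text, topic=topic,
            )
            st.validate()
            statements.append(st)
        except ConfigurationError:
            raise
        except (DataError, ValueError) as exc:
            if permissive:
                errors.append(RowError(row=i, reason=str(exc)))
            else:
                raise
    if not statements:
        raise DataError(f"{path}: no valid rows after validation")
    corpus = Corpus(
        name=name or path.stem,
        statements=statements,
        provenance=f"loaded from {path.name}",
    )
    corpus.load_errors = errors
    return corpus


def write_corpus_csv(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for s in corpus:
            writer.writerow([s.id, s.subject_id, s.domain, s.topic, s.veracity, s.text])


def write_corpus_jsonl(corpus: Corpus, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for s in corpus:
            fh.write(json.dumps({
                "id": s.id, "subject_id": s.subject_id, "domain": s.domain,
                "topic": s.topic, "veracity": s.veracity, "text": s.text,
            }, ensure_ascii=False) + "\n")


#: Canonical mapping for files written by :func:`write_corpus_csv`.
CANONICAL_PROFILE = {
    "id": "id", "subject_id": "subject_id", "domain": "domain",
    "topic": "topic", "text": "text", "veracity": "veracity",
}


def load_canonical(path: str | Path, name: str | None = None) -> Corpus:
    return load_corpus(path, CANONICAL_PROFILE, name=name)


# ---------------------------------------------------------------------------
# Descriptive statistics
# ---------------------------------------------------------------------------

def _group_stats(counts: Sequence[int]) -> GroupWordStats:
    n = len(counts)
    if n == 0:
        return GroupWordStats(n=0, min_words=None, max_words=None,
                              mean_words=None, sd_words=None)
    mean = sum(counts) / n
    sd = statistics.stdev(counts) if n >= 2 else None
    return GroupWordStats(n=n, min_words=min(counts), max_words=max(counts),
                          mean_words=mean, sd_words=sd)


def corpus_summary(corpus: Corpus) -> CorpusSummary:
    """Word-count summary per veracity group plus the Jaccard overlap index.

    Word counts use the package tokenizer; the standard deviation is the
    sample (n-1) form.  A veracity group with no statements yields
    ``None``-flagged fields and no Jaccard index.
    """
    counts = {lbl: [] for lbl in VERACITY_LABELS}
    all_counts: list[int] = []
    for s in corpus:
        c = count_words(s.text)
        counts[s.veracity].append(c)
        all_counts.append(c)
    truthful = _group_stats(counts["truthful"])
    deceptive = _group_stats(counts["deceptive"])
    jac = None
    if truthful.n > 0 and deceptive.n > 0:
        jac = jaccard_vocabulary(corpus)
    return CorpusSummary(
        n_total=len(all_counts),
        n_truthful=truthful.n,
        n_deceptive=deceptive.n,
        overall=_group_stats(all_counts),
        truthful=truthful,
        deceptive=deceptive,
        jaccard_index=jac,
    )


def _vocabulary(statements: Iterable[Statement], lowercase: bool) -> set[str]:
    vocab: set[str] = set()
    for s in statements:
        for tok in word_tokens(s.text):
            vocab.add(tok.lower() if lowercase else tok)
    return vocab


def jaccard_vocabulary(corpus: Corpus, *, lowercase: bool = True) -> float:
    """|intersection| / |union| of the truthful and deceptive vocabularies.

    Vocabularies are sets of unique word tokens (punctuation tokens excluded,
    lowercased by default, no lemmatization).  Symmetric in the two groups
    and invariant to duplicated statements.
    """
    truthful = corpus.by_veracity("truthful")
    deceptive = corpus.by_veracity("deceptive")
    if not truthful or not deceptive:
        raise DataError(
            f"corpus {corpus.name!r}: both veracity groups must be non-empty"
        )
    a = _vocabulary(truthful, lowercase)
    b = _vocabulary(deceptive, lowercase)
    union = a | b
    if not union:
        raise DataError("empty vocabulary union")
    return len(a & b) / len(union)
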