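"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's own vectorized code paths: exact
permutation p-values by full enumeration, the Holm procedure by sequential
rejection, and lexicon scoring by a naive per-token loop.
"""

from __future__ import annotations

import itertools

import numpy as np


def enum_p_independent(x, y) -> float:
    """Exact two-sided permutation p by enumerating all group assignments."""
    pooled = np.array(list(x) + list(y), dtype=float)
    n1 = len(x)
    t_obs = abs(np.mean(x) - np.mean(y))
    total = 0
    ge = 0
    for idx in itertools.combinations(range(pooled.size), n1):
        mask = np.zeros(pooled.size, dtype=bool)
        mask[list(idx)] = True
        t = abs(pooled[mask].mean() - pooled[~mask].mean())
        total += 1
        if t >= t_obs - 1e-12:
            ge += 1
    return ge / total


def enum_p_paired(x, y) -> float:
    """Exact two-sided sign-flip p by enumerating all 2^n sign patterns."""
    diffs = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    t_obs = abs(diffs.mean())
    n = diffs.size
    ge = 0
    for bits in range(2 ** n):
        signs = np.array([1 if bits >> i & 1 else -1 for i in range(n)])
        if abs((signs * diffs).mean()) >= t_obs - 1e-12:
            ge += 1
    return ge / 2 ** n


def holm_rejections(p_values, alpha) -> set[int]:
    """Sequential-rejection Holm: reject smallest p while p <= alpha/(m-k)."""
    order = sorted(range(len(p_values)), key=lambda i: p_values[i])
    rejected: set[int] = set()
    m = len(p_values)
    for k, i in enumerate(order):
        if p_values[i] < alpha / (m - k):
            rejected.add(i)
        else:
            break
    return rejected


def naive_category_percentages(tokens, categories) -> dict[str, float]:
    """Per-token loop over raw category entries (wildcards as prefixes)."""
    words = [t for t in tokens if any(ch.isalnum() for ch in t)]
    out = {}
    for name, entries in categories.items():
        hits = 0
        for tok in words:
            low = tok.lower()
            for e in entries:
                if (e.endswith("*") and low.startswith(e[:-1])) or low == e:
                    hits += 1
                    break
        out[name] = 100.0 * hits / len(words)
    return out
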