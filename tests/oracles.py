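"""Independent brute-force oracles the test suite checks the package against.

Each oracle re-derives its answer by a different route than the
implementation: the diagnosis oracle is a literal transcription of the
criteria text ("would adding one manifestation complete a pathway?"),
the confusion-table oracle a naive double loop, and the per-category
oracle an explicit one-vs-rest 2x2 collapse.
"""

from __future__ import annotations

import numpy as np


def would_be_definite(n_major: int, n_minor: int, recurrent: bool) -> bool:
    """Does the manifestation count complete a diagnostic pathway?"""
    if n_major >= 2:
        return True
    if n_major >= 1 and n_minor >= 2:
        return True
    if recurrent and n_minor >= 3:
        return True
    return False


def oracle_category(
    n_major: int,
    n_minor: int,
    strep: bool,
    recurrent: bool,
    judgement: str | None,
) -> str:
    """Literal transcription of the criteria table's diagnosis text."""
    if strep and would_be_definite(n_major, n_minor, recurrent):
        return "definite"
    # "falls short ... by either: one major or one minor manifestation,
    # OR no evidence of preceding Strep A infection"
    one_short = n_major + n_minor >= 1 and (
        would_be_definite(n_major + 1, n_minor, recurrent)
        or would_be_definite(n_major, n_minor + 1, recurrent)
    )
    shortfall = (strep and one_short) or (
        not strep and would_be_definite(n_major, n_minor, recurrent)
    )
    if not shortfall:
        return "not-arf"
    answer = judgement if judgement is not None else "uncertain"
    return {"yes": "probable", "uncertain": "possible", "no": "not-arf"}[answer]


def oracle_confusion(gold, predicted, categories) -> np.ndarray:
    """Naive double-loop cross-tabulation."""
    counts = np.zeros((len(categories), len(categories)), dtype=np.int64)
    for i, g in enumerate(categories):
        for j, p in enumerate(categories):
            counts[i, j] = sum(
                1 for gg, pp in zip(gold, predicted) if gg == g and pp == p
            )
    return counts


def oracle_kappa(counts: np.ndarray) -> float:
    """Textbook kappa from scratch (no shared code with the package)."""
    counts = np.asarray(counts, dtype=float)
    n = counts.sum()
    po = sum(counts[i, i] for i in range(counts.shape[0])) / n
    pe = sum(
        counts[i, :].sum() * counts[:, i].sum() for i in range(counts.shape[0])
    ) / n**2
    return (po - pe) / (1 - pe)


def oracle_one_vs_rest(counts: np.ndarray, k: int) -> tuple[float | None, float | None]:
    """Collapse class k to a 2x2 table and read off sens/spec."""
    counts = np.asarray(counts)
    n = counts.sum()
    tp = counts[k, k]
    fn = counts[k, :].sum() - tp
    fp = counts[:, k].sum() - tp
    tn = n - tp - fn - fp
    sens = tp / (tp + fn) if tp + fn > 0 else None
    spec = tn / (tn + fp) if tn + fp > 0 else None
    return sens, spec
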