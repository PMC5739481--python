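"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's vectorised code paths: AUC is
counted pair by pair, average precision is accumulated cut by cut over the
descending-score blocks, and Kendall tau-b enumerates every pair. They exist
so the fast implementations can be checked against slow, obviously-correct
arithmetic.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

from dermeval.cohort import ScoredCohort


# ---------------------------------------------------------------------------
# Oracles
# ---------------------------------------------------------------------------

def auc_pairwise_oracle(scores, labels) -> float:
    """Mann-Whitney count: (pos > neg pairs + half ties) / (n_pos * n_neg)."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def ap_rank_cut_oracle(scores, labels) -> float:
    """Average precision by enumerating every rank cut (tie groups as blocks)."""
    order = sorted(range(len(scores)), key=lambda i: -scores[i])
    n_pos = sum(labels)
    ap = 0.0
    tp = 0
    depth = 0
    prev_recall = 0.0
    i = 0
    while i < len(order):
        j = i
        while j < len(order) and scores[order[j]] == scores[order[i]]:
            tp += labels[order[j]]
            depth += 1
            j += 1
        recall = tp / n_pos
        precision = tp / depth
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap


def kendall_tau_b_oracle(r1, r2) -> float:
    """Tau-b by exhaustive concordant/discordant pair enumeration."""
    nc = nd = tie_x = tie_y = n0 = 0
    for (a1, a2), (b1, b2) in itertools.combinations(list(zip(r1, r2)), 2):
        dx, dy = a1 - b1, a2 - b2
        n0 += 1
        if dx == 0:
            tie_x += 1
        if dy == 0:
            tie_y += 1
        if dx * dy > 0:
            nc += 1
        elif dx * dy < 0:
            nd += 1
    denom = math.sqrt((n0 - tie_x) * (n0 - tie_y))
    return (nc - nd) / denom if denom else float("nan")


def random_cohort(rng: np.random.Generator, n_max: int = 200) -> ScoredCohort:
    """Random cohort with both classes, discretised scores so ties occur."""
    n = int(rng.integers(4, n_max + 1))
    labels = np.zeros(n, dtype=int)
    n_pos = int(rng.integers(1, n))
    labels[:n_pos] = 1
    # coarse grid makes score ties likely, exercising the tie conventions
    grid = int(rng.integers(2, 20))
    scores = rng.integers(0, grid + 1, size=n) / grid
    return ScoredCohort(scores, labels)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@pytest.fixture
def four_record_cohort() -> ScoredCohort:
    """Scores (0.9 M, 0.7 B, 0.6 M, 0.3 B): AUC 0.75 by hand enumeration."""
    return ScoredCohort([0.9, 0.7, 0.6, 0.3], [1, 0, 1, 0])


@pytest.fixture
def five_record_cohort() -> ScoredCohort:
    """Scores (0.9 M, 0.8 M, 0.7 B, 0.4 M, 0.2 B): spec@SE>=0.95 is 0.5."""
    return ScoredCohort([0.9, 0.8, 0.7, 0.4, 0.2], [1, 1, 0, 1, 0])


@pytest.fixture
def perfect_cohort() -> ScoredCohort:
    return ScoredCohort([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
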