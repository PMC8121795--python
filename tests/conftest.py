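"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from decimal import Decimal, getcontext

import numpy as np
import pytest

from speechphen.pipeline import RunConfig, featurize_corpus
from speechphen.synthetic import (
    generate_corpus,
    null_preset,
    clinical_effects_preset,
    toy_backend,
)

# ---------------------------------------------------------------------------
# oracles (independent of the implementation paths they check)
# ---------------------------------------------------------------------------


def log_odds_oracle(y_a, y_b, n_a, n_b, alpha0, digits: int = 50):
    """Direct Decimal evaluation of the weighted log-odds formula.

    Returns (delta, z) per word at ``digits`` precision, using prior
    pseudo-counts proportional to pooled relative frequency.
    """
    getcontext().prec = digits
    y_a = [Decimal(int(v)) for v in y_a]
    y_b = [Decimal(int(v)) for v in y_b]
    n_a, n_b = Decimal(int(n_a)), Decimal(int(n_b))
    alpha0 = Decimal(str(alpha0))
    pooled = [a + b for a, b in zip(y_a, y_b)]
    total = sum(pooled)
    out = []
    for ya, yb, pw in zip(y_a, y_b, pooled):
        if pw == 0:
            out.append(None)  # unscorable: zero prior mass
            continue
        aw = alpha0 * pw / total
        delta = ((ya + aw) / (n_a + alpha0 - ya - aw)).ln() - (
            (yb + aw) / (n_b + alpha0 - yb - aw)
        ).ln()
        var = 1 / (ya + aw) + 1 / (yb + aw)
        out.append((float(delta), float(delta / var.sqrt())))
    return out


def auc_pair_counting(scores, labels) -> float:
    """Brute-force Mann-Whitney AUC: enumerate every (pos, neg) pair."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def ols_closed_form(x, y):
    """Hand least-squares: slope = Sxy/Sxx, intercept = ybar - slope*xbar."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    slope = np.sum((x - xbar) * (y - ybar)) / np.sum((x - xbar) ** 2)
    return float(ybar - slope * xbar), float(slope)


# ---------------------------------------------------------------------------
# corpora (session-scoped: generated once, reused across modules)
# ---------------------------------------------------------------------------

PRESET_SEED = 11


@pytest.fixture(scope="session")
def preset_corpus():
    return generate_corpus(clinical_effects_preset(seed=PRESET_SEED, n_per_group=15))


@pytest.fixture(scope="session")
def null_corpus():
    return generate_corpus(null_preset(seed=PRESET_SEED, n_per_group=15))


@pytest.fixture(scope="session")
def preset_bundle(preset_corpus):
    transcripts, ratings = preset_corpus
    return featurize_corpus(transcripts, ratings, RunConfig(seed=PRESET_SEED))


@pytest.fixture()
def backend():
    return toy_backend(seed=3)
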