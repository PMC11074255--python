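import itertools

import numpy as np
import pandas as pd
import pytest

from tiderhythm import ExpressionMatrix, ExpressionSimConfig, \
    generate_expression_dataset


def brute_force_umbrella(values, n_phases, pairs):
    """Oracle: statistic from the Mann–Whitney definition, double loop."""
    values = np.asarray(values, dtype=float)
    groups = [np.flatnonzero(np.arange(len(values)) % n_phases == g)
              for g in range(n_phases)]
    total = 0.0
    for (u, v) in pairs:
        for a in groups[u]:
            for b in groups[v]:
                if values[a] < values[b]:
                    total += 1.0
                elif values[a] == values[b]:
                    total += 0.5
    return total


def brute_force_pvalue(values, n_phases, pairs):
    """Oracle: one-sided p by enumerating every permutation of the series.

    Statistics are computed in doubled-integer arithmetic per group pair so
    the tail comparison is exact.  Independent of the package's enumeration
    (which walks distinct multiset arrangements and vectorizes through the
    pairwise comparison tensor).
    """
    values = np.asarray(values, dtype=float)
    n = len(values)
    groups = [np.flatnonzero(np.arange(n) % n_phases == g)
              for g in range(n_phases)]
    perms = np.array(list(itertools.permutations(range(n))))
    V = values[perms]                      # (n!, n)
    A2 = np.zeros(len(perms), dtype=np.int64)
    for (u, v) in pairs:
        for a in groups[u]:
            for b in groups[v]:
                x, y = V[:, a], V[:, b]
                A2 += 2 * (x < y) + (x == y)
    obs2 = A2[0]  # identity permutation first
    return float((A2 >= obs2).mean())


@pytest.fixture
def small_matrix():
    """6-gene toy TPM matrix: 2 low-mean, 1 flat, 3 rhythmic genes."""
    t = np.round(np.arange(8) * 3.1, 10)
    rows = {
        "low1": np.full(8, 0.5),
        "low2": np.full(8, 0.9),
        "flat": np.full(8, 5.0),
        "osc1": 10 + 5 * np.cos(2 * np.pi * t / 12.4),
        "osc2": 20 + 8 * np.cos(2 * np.pi * (t - 3.0) / 12.4),
        "osc3": 8 + 4 * np.cos(2 * np.pi * t / 24.8),
    }
    df = pd.DataFrame(rows, index=t).T
    return ExpressionMatrix(df)


@pytest.fixture
def default_sim():
    cfg = ExpressionSimConfig(n_genes=200, seed=42, frac_circatidal=0.2,
                              frac_circadian=0.2, peak_trough_ratio=2.0,
                              noise_cv=0.1)
    return generate_expression_dataset(cfg)
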