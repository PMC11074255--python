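"""Nonparametric detection of circatidal and circadian expression rhythms.

A gene's time course on a uniform grid (spacing ``dt`` hours) is folded at a
candidate period ``T = m * dt`` into ``m`` phase groups (timepoint ``k`` goes
to group ``k mod m``), so the repeated cycles of the recording supply the
within-phase replicates.  Rhythmicity at that period is an umbrella
alternative on the phase groups: expression rises to some peak phase and
falls afterwards.  The building block is the Mack–Wolfe umbrella statistic

    A(h) = sum_{i<j<=h} U_ij  +  sum_{h<=i<j} U_ji,

the number of pairwise orderings concordant with an umbrella peaking at
phase ``h``, where ``U_uv`` is the Mann–Whitney count of pairs with the
group-``u`` value below the group-``v`` value (ties count 1/2, the midrank
convention).

Because the alternative is periodic, detection evaluates two pair-set shapes
per peak phase, both cyclic generalizations of the umbrella:

* the *symmetric cyclic umbrella*: groups reordered trough -> peak -> trough
  (the linear umbrella on the fixed order 0..m-1 cannot represent peaks near
  the fold boundary);
* the *crest* contrast: the half-cycle of groups nearest the peak against
  the remaining groups (all cross pairs), which captures waveforms whose
  peak falls between sampled phases and therefore plateau across two groups.

P-values are one-sided upper tail under the permutation null.  For tie-free
series the null distribution of each statistic is computed exactly by a
rank-insertion dynamic program shared across genes; tied series are
enumerated exactly over the distinct arrangements of the value multiset when
feasible, and otherwise use a normal approximation whose null variance is
exact for the observed tie pattern (assembled from permutation moments of
the pairwise comparison kernel; it reduces to the classical Mack–Wolfe
variance without ties).  The minimum p over (period, phase, shape)
alternatives is Bonferroni-corrected for the number of alternatives, which
is conservative relative to the original RAIN correction.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PeriodWindow",
    "CIRCATIDAL_WINDOW",
    "CIRCADIAN_WINDOW",
    "RhythmTestResult",
    "umbrella_statistic",
    "umbrella_max_statistic",
    "umbrella_exact_pvalue",
    "rhythm_pvalue",
    "detect_rhythms",
    "rhythm_class_transitions",
    "overlap_counts",
]

#: p-values are floored here so log(p) is always finite downstream.
P_FLOOR = 1e-300

#: exact enumeration (tied series) is used when the number of distinct
#: arrangements of the observed value multiset does not exceed this.
EXACT_ENUMERATION_LIMIT = 1_000_000

#: DP table size guard (n_states * statistic support); beyond this the
#: normal approximation is used instead.
DP_STATE_LIMIT = 50_000_000


@dataclass(frozen=True)
class PeriodWindow:
    """A period search window: ``center ± half_width`` hours.

    Candidate periods are the multiples of the sampling interval inside the
    closed window, so that phase folding produces balanced, non-empty groups.
    """

    name: str
    center_hours: float
    half_width_hours: float

    def candidate_folds(self, dt_hours: float, n_timepoints: int) -> list[int]:
        """Fold sizes m with m*dt inside the window; every group must be non-empty."""
        if dt_hours <= 0:
            raise ValueError("dt_hours must be positive")
        lo = self.center_hours - self.half_width_hours
        hi = self.center_hours + self.half_width_hours
        m_min = max(2, math.ceil(lo / dt_hours - 1e-9))
        m_max = math.floor(hi / dt_hours + 1e-9)
        folds = [m for m in range(m_min, m_max + 1)]
        if not folds:
            raise ValueError(
                f"window {self.name} [{lo}, {hi}] h contains no multiple of dt={dt_hours} h"
            )
        bad = [m for m in folds if m > n_timepoints]
        if bad:
            raise ValueError(
                f"fold {bad[0]} exceeds the number of timepoints ({n_timepoints}); "
                "a phase group would be empty"
            )
        return folds

    def candidate_periods(self, dt_hours: float, n_timepoints: int) -> list[float]:
        return [m * dt_hours for m in self.candidate_folds(dt_hours, n_timepoints)]


CIRCATIDAL_WINDOW = PeriodWindow("circatidal", 12.4, 3.1)
CIRCADIAN_WINDOW = PeriodWindow("circadian", 24.8, 3.1)


@dataclass(frozen=True)
class RhythmTestResult:
    gene_id: str
    window: str
    p_value: float
    best_period_hours: float
    best_peak_phase_index: int
    statistic: float


# ---------------------------------------------------------------------------
# pair-set shapes
# ---------------------------------------------------------------------------


def _umbrella_pairs(m: int, peak: int) -> list[tuple[int, int]]:
    """Linear Mack–Wolfe pair set: rising to ``peak`` on order 0..m-1, then falling."""
    rising = [(i, j) for i in range(m) for j in range(i + 1, m) if j <= peak]
    falling = [(j, i) for i in range(peak, m) for j in range(i + 1, m)]
    return rising + falling


def _cyclic_umbrella_pairs(m: int, peak: int) -> list[tuple[int, int]]:
    """Umbrella pair set on the cyclically rotated order trough -> peak -> trough."""
    trough = (peak + (m + 1) // 2) % m
    order = [(trough + i) % m for i in range(m)]
    pos = (peak - trough) % m
    rising = [(order[i], order[j]) for i in range(m) for j in range(i + 1, m)
              if j <= pos]
    falling = [(order[j], order[i]) for i in range(pos, m)
               for j in range(i + 1, m)]
    return rising + falling


def _crest_pairs(m: int, peak: int) -> list[tuple[int, int]]:
    """All cross pairs: half-cycle of groups starting at ``peak`` above the rest."""
    q = max(1, m // 2)
    crest = {(peak + i) % m for i in range(q)}
    return [(u, v) for u in range(m) for v in sorted(crest) if u not in crest]


def _shape_family(m: int, kind: str) -> list[dict]:
    """Alternatives tested per fold: list of {pairs, phase, shape}."""
    if kind == "linear":
        return [{"pairs": _umbrella_pairs(m, h), "phase": h, "shape": "umbrella"}
                for h in range(m)]
    if kind == "cyclic":
        return [{"pairs": _cyclic_umbrella_pairs(m, h), "phase": h,
                 "shape": "umbrella"} for h in range(m)]
    if kind == "detect":
        fam = [{"pairs": _cyclic_umbrella_pairs(m, h), "phase": h,
                "shape": "umbrella"} for h in range(m)]
        fam += [{"pairs": _crest_pairs(m, h), "phase": h, "shape": "crest"}
                for h in range(m)]
        return fam
    raise ValueError(f"unknown shape kind {kind!r}")


# ---------------------------------------------------------------------------
# fold geometry and null-moment coefficients
# ---------------------------------------------------------------------------


def _pair_coefficients(sizes: np.ndarray, pairs: list[tuple[int, int]]):
    """Multiplicities of slot-overlap configurations among statistic terms.

    The statistic is a sum of pairwise comparison kernels psi(X_a, X_b) over
    slots a in G_i, b in G_j for each (i, j) in ``pairs``.  Its permutation
    variance is the sum over ordered term pairs of their covariance, and the
    covariance depends only on how the two slot pairs overlap: identical,
    shared first slot, shared second slot, chained (one term's second slot
    is the other's first, in either direction), or disjoint.  This returns
    the count of each configuration; the value-dependent kernel moments are
    supplied per series by :func:`_psi_moments`.
    """
    c_id = c_t1 = c_t2 = c_t3 = c_d = 0
    n = sizes.astype(np.int64)
    for (i, j) in pairs:
        for (k, l) in pairs:
            tot = int(n[i] * n[j] * n[k] * n[l])
            nid = int(n[i] * n[j]) if (i, j) == (k, l) else 0
            nt1 = int(n[i] * (n[j] * n[l] - (n[j] if j == l else 0))) if i == k else 0
            nt2 = int(n[j] * (n[i] * n[k] - (n[i] if i == k else 0))) if j == l else 0
            nt3 = 0
            if j == k:  # (a,b) then (b, b'): chained through the shared slot
                nt3 += int(n[i] * n[j] * n[l])
            if i == l:  # (a,b) then (a', a)
                nt3 += int(n[i] * n[j] * n[k])
            c_id += nid
            c_t1 += nt1
            c_t2 += nt2
            c_t3 += nt3
            c_d += tot - nid - nt1 - nt2 - nt3
    return c_id, c_t1, c_t2, c_t3, c_d


@lru_cache(maxsize=256)
def _fold_plan(n: int, m: int, kind: str = "linear"):
    """Group structure and per-alternative coefficients for an n-point, m-phase fold."""
    if m < 2:
        raise ValueError("a fold needs at least 2 phase groups")
    if m > n:
        raise ValueError("empty phase group: fold size exceeds series length")
    groups = np.arange(n) % m
    sizes = np.bincount(groups, minlength=m)
    onehot = np.zeros((n, m))
    onehot[np.arange(n), groups] = 1.0
    peaks = []
    for alt in _shape_family(m, kind):
        pairs = alt["pairs"]
        npairs = sum(int(sizes[i] * sizes[j]) for i, j in pairs)
        idx = (np.array([i for i, _ in pairs]), np.array([j for _, j in pairs]))
        peaks.append({
            "pairs": pairs,
            "pair_idx": idx,
            "phase": alt["phase"],
            "shape": alt["shape"],
            "mean": 0.5 * npairs,
            "max": float(npairs),
            "coeffs": _pair_coefficients(sizes, pairs),
        })
    return {"groups": groups, "sizes": sizes, "onehot": onehot, "peaks": peaks}


# ---------------------------------------------------------------------------
# pairwise-comparison kernel and its exact permutation moments
# ---------------------------------------------------------------------------


def _psi(X: np.ndarray) -> np.ndarray:
    """psi[g, a, b] = 1 if X[g,a] < X[g,b], 1/2 on ties (diagonal unused)."""
    lt = (X[:, :, None] < X[:, None, :]).astype(float)
    eq = (X[:, :, None] == X[:, None, :]).astype(float)
    return lt + 0.5 * eq


def _psi_moments(X: np.ndarray):
    """Exact permutation moments of psi over random distinct slot tuples.

    Returns (q0, t1, t2, t3, d): E[psi^2] on a shared slot pair, E[psi psi']
    on the three one-shared-slot configurations, and on four distinct slots.
    Each equals 1/4 for continuous data; ties shift them, which is exactly
    what makes the normal-approximation variance tie-corrected.
    """
    G, n = X.shape
    a = (X[:, None, :] < X[:, :, None]).sum(axis=2).astype(float)  # strictly below u
    b = (X[:, None, :] > X[:, :, None]).sum(axis=2).astype(float)  # strictly above u
    e = n - 1 - a - b                                              # tied with u
    S = b + 0.5 * e     # sum_w psi(x_u, x_w)
    Sp = a + 0.5 * e    # sum_w psi(x_w, x_u)
    Q = b + 0.25 * e    # sum_w psi(x_u, x_w)^2
    Qp = a + 0.25 * e
    P_lt = a.sum(axis=1)
    P_eq = e.sum(axis=1)
    N2 = n * (n - 1)
    N3 = N2 * (n - 2)
    N4 = N3 * (n - 3)
    q0 = (P_lt + 0.25 * P_eq) / N2
    sum_t1 = (S**2 - Q).sum(axis=1)
    sum_t2 = (Sp**2 - Qp).sum(axis=1)
    sum_t3 = (S * Sp - 0.25 * e).sum(axis=1)
    t1 = sum_t1 / N3
    t2 = sum_t2 / N3
    t3 = sum_t3 / N3
    T = N2 / 2.0
    if N4 > 0:
        d4 = (
            T**2
            - (P_lt + 0.25 * P_eq)   # identical ordered pair
            - 0.25 * P_eq            # reversed pair
            - sum_t1 - sum_t2 - 2.0 * sum_t3
        )
        d = d4 / N4
    else:
        d = np.full(G, 0.25)  # no 4-distinct-slot configuration exists
    return q0, t1, t2, t3, d


def _fold_statistics(X: np.ndarray, m: int, kind: str = "linear"):
    """Statistics and exact null moments for every alternative of one fold.

    Returns (A, mean, var): arrays of shape (G, K), (K,), (G, K) where K is
    the number of alternatives in the fold's shape family.
    """
    G, n = X.shape
    plan = _fold_plan(n, m, kind)
    psi = _psi(X)
    U = np.einsum("gab,ai,bj->gij", psi, plan["onehot"], plan["onehot"])
    q0, t1, t2, t3, d = _psi_moments(X)
    K = len(plan["peaks"])
    A = np.empty((G, K))
    var = np.empty((G, K))
    mean = np.empty(K)
    for k, peak in enumerate(plan["peaks"]):
        ii, jj = peak["pair_idx"]
        A[:, k] = U[:, ii, jj].sum(axis=1)
        mean[k] = peak["mean"]
        c_id, c_t1, c_t2, c_t3, c_d = peak["coeffs"]
        var[:, k] = (
            c_id * (q0 - 0.25)
            + c_t1 * (t1 - 0.25)
            + c_t2 * (t2 - 0.25)
            + c_t3 * (t3 - 0.25)
            + c_d * (d - 0.25)
        )
    return A, mean, var


def _normal_peak_pvalues(A: np.ndarray, mean: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Upper-tail normal p per (gene, alternative); degenerate null gives p = 1."""
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (A - mean[None, :]) / sd
    p = norm.sf(z)
    p = np.where(sd <= 0, 1.0, p)
    return np.clip(p, P_FLOOR, 1.0)


# ---------------------------------------------------------------------------
# exact null distribution for tie-free data (rank-insertion DP)
# ---------------------------------------------------------------------------


def _compositions(total: int, parts: int):
    """All nonnegative integer compositions of ``total`` into ``parts`` parts."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, parts - 1):
            yield (first,) + rest


@lru_cache(maxsize=4096)
def _null_sf(n: int, m: int, alt_index: int, kind: str,
             mults: tuple | None = None):
    """Exact null survival function of one fold alternative.

    The statistic depends on the data only through ranks, so its permutation
    distribution is determined by the fold geometry and the tie pattern
    ``mults`` (multiplicities of the distinct values in ascending order;
    None means tie-free).  It is computed by dynamic programming: distinct
    values are placed smallest-first, each tie class distributed over the
    phase groups in all possible compositions.  Placing ``w_g`` copies in
    group ``g`` raises the doubled statistic by ``2 * sum c_u w_v + sum
    w_u w_v`` over the alternative's pair set (the second term is the
    within-class tie contribution at 1/2 per cross pair).  States are the
    per-group placement counts (mixed-radix encoded); path weights
    accumulate to the multinomial total.

    Returns sf2 with sf2[a] = P(2*A >= a) for integer a in [0, 2*A_max],
    or None when the table would exceed :data:`DP_STATE_LIMIT`.
    """
    plan = _fold_plan(n, m, kind)
    sizes = plan["sizes"].astype(np.int64)
    pairs = plan["peaks"][alt_index]["pairs"]
    if mults is None:
        mults = (1,) * n
    if sum(mults) != n:
        raise ValueError("tie multiplicities must sum to the series length")
    amax2 = 2 * int(sum(sizes[u] * sizes[v] for u, v in pairs))
    radices = sizes + 1
    n_states = int(np.prod(radices))
    n_comps = sum(math.comb(w + m - 1, m - 1) for w in mults)
    if n_states * (amax2 + 1) > DP_STATE_LIMIT or n_states * n_comps > DP_STATE_LIMIT:
        return None
    strides = np.ones(m, dtype=np.int64)
    for g in range(m - 2, -1, -1):
        strides[g] = strides[g + 1] * radices[g + 1]
    counts = np.empty((n_states, m), dtype=np.int64)
    rem = np.arange(n_states, dtype=np.int64)
    for g in range(m):
        counts[:, g] = rem // strides[g]
        rem = rem % strides[g]
    placed = counts.sum(axis=1)
    # alpha[u] = 2 * sum of w_v over pairs (u, v) is composition-dependent;
    # precompute the pair adjacency instead
    out_w = np.zeros((m, m), dtype=np.int64)   # out_w[u, v] = 1 if (u,v) in pairs
    for (u, v) in pairs:
        out_w[u, v] += 1

    dp = np.zeros((n_states, amax2 + 1))
    dp[0, 0] = 1.0
    done = 0
    for w in mults:
        new = np.zeros_like(dp)
        active = placed == done
        for comp in _compositions(w, m):
            wv = np.asarray(comp, dtype=np.int64)
            ok = active & np.all(counts + wv[None, :] <= sizes[None, :], axis=1)
            if not ok.any():
                continue
            src = np.nonzero(ok)[0]
            dst = src + int(wv @ strides)
            alpha = 2 * (out_w @ wv)                     # per group u
            const2 = int(wv @ out_w @ wv)                # within-class ties
            delta = counts[src] @ alpha + const2
            weight = math.factorial(w)
            for x in comp:
                weight //= math.factorial(x)
            for v in np.unique(delta):
                sel = delta == v
                new[dst[sel], v:] += weight * dp[src[sel], :dp.shape[1] - v]
        dp = new
        done += w
    pmf = dp[n_states - 1]
    pmf = pmf / pmf.sum()
    return np.cumsum(pmf[::-1])[::-1]


def _tie_pattern(x: np.ndarray) -> tuple:
    """Multiplicities of the distinct values in ascending order."""
    _, counts = np.unique(x, return_counts=True)
    return tuple(int(c) for c in counts)


def _has_ties(X: np.ndarray) -> np.ndarray:
    """Per-gene flag: any tied values in the series."""
    G, n = X.shape
    eq = (X[:, :, None] == X[:, None, :]).sum(axis=(1, 2))
    return eq > n  # diagonal alone contributes n


# ---------------------------------------------------------------------------
# exact enumeration (tied series)
# ---------------------------------------------------------------------------


def n_distinct_arrangements(values) -> int:
    """Number of distinct orderings of the value multiset."""
    values = np.asarray(values).ravel()
    count = math.factorial(len(values))
    for mult in Counter(values.tolist()).values():
        count //= math.factorial(mult)
    return count


def _psi2_int(X: np.ndarray) -> np.ndarray:
    """Doubled comparison kernel in integers: 2 if <, 1 if tie, 0 if >."""
    lt = (X[:, :, None] < X[:, None, :]).astype(np.int64)
    eq = (X[:, :, None] == X[:, None, :]).astype(np.int64)
    return 2 * lt + eq


def _exact_fold_pvalues(values: np.ndarray, m: int, kind: str = "linear",
                        chunk: int = 20000):
    """Exact one-sided p per fold alternative by enumerating arrangements.

    The statistic depends on the data only through ranks, so enumeration
    runs over distinct arrangements of the observed multiset; ties are
    therefore handled exactly.  Works in doubled-integer arithmetic so the
    tail comparison A_perm >= A_obs is exact.
    """
    from sympy.utilities.iterables import multiset_permutations

    values = np.asarray(values, dtype=float).ravel()
    n = len(values)
    plan = _fold_plan(n, m, kind)
    onehot = plan["onehot"]
    K = len(plan["peaks"])
    U2_obs = np.einsum("gab,ai,bj->gij", _psi2_int(values[None, :]),
                       onehot, onehot)[0]
    obs2 = np.array(
        [int(round(U2_obs[peak["pair_idx"]].sum())) for peak in plan["peaks"]],
        dtype=np.int64,
    )
    ge = np.zeros(K, dtype=np.int64)
    total = 0
    it = multiset_permutations(values.tolist())
    while True:
        batch = list(itertools.islice(it, chunk))
        if not batch:
            break
        V = np.asarray(batch, dtype=float)
        psi2 = _psi2_int(V)
        U2 = np.einsum("gab,ai,bj->gij", psi2, onehot, onehot)
        for k, peak in enumerate(plan["peaks"]):
            ii, jj = peak["pair_idx"]
            A2 = U2[:, ii, jj].sum(axis=1)
            ge[k] += int((A2 >= obs2[k]).sum())
        total += len(batch)
    p = ge / total
    return np.clip(p, P_FLOOR, 1.0), obs2 / 2.0


# ---------------------------------------------------------------------------
# public single-series API
# ---------------------------------------------------------------------------


def umbrella_statistic(series, n_phases: int, peak_phase: int,
                       cyclic: bool = False) -> float:
    """Mack–Wolfe umbrella statistic of a series folded into ``n_phases`` groups.

    The series is folded by timepoint index modulo ``n_phases``; ties
    contribute 1/2 to the pairwise counts (midrank convention).  By default
    the umbrella is the classical linear rise-to-peak-then-fall on groups
    0..n_phases-1 (monotone extremes included); with ``cyclic=True`` it runs
    trough -> peak -> trough on the cyclically rotated group order, as used
    in detection.
    """
    x = np.asarray(series, dtype=float).ravel()
    if not 0 <= peak_phase < n_phases:
        raise ValueError("peak_phase must lie in [0, n_phases)")
    kind = "cyclic" if cyclic else "linear"
    A, _, _ = _fold_statistics(x[None, :], n_phases, kind)
    return float(A[0, peak_phase])


def umbrella_max_statistic(series_length: int, n_phases: int, peak_phase: int,
                           cyclic: bool = False) -> float:
    """Largest attainable umbrella statistic (all pairwise counts concordant)."""
    kind = "cyclic" if cyclic else "linear"
    plan = _fold_plan(series_length, n_phases, kind)
    return plan["peaks"][peak_phase]["max"]


def umbrella_exact_pvalue(series, n_phases: int, peak_phase: int,
                          cyclic: bool = False) -> float:
    """Exact one-sided permutation p-value of the umbrella statistic."""
    x = np.asarray(series, dtype=float).ravel()
    if not 0 <= peak_phase < n_phases:
        raise ValueError("peak_phase must lie in [0, n_phases)")
    kind = "cyclic" if cyclic else "linear"
    p, _ = _exact_fold_pvalues(x, n_phases, kind)
    return float(p[peak_phase])


def rhythm_pvalue(
    series,
    window: PeriodWindow,
    dt_hours: float,
    gene_id: str = "",
    exact: str | bool = "auto",
) -> RhythmTestResult:
    """Test one series for rhythmicity inside a period window.

    For each candidate period ``m * dt`` and each peak phase the one-sided
    p-values of the cyclic umbrella and crest statistics are computed; the
    reported p-value is the minimum, Bonferroni-corrected for the number of
    (period, phase, shape) alternatives and capped at 1.  Per-alternative p
    is exact for tie-free series (rank-insertion DP null), exact by multiset
    enumeration for tied series whose arrangement count permits, and a
    tie-corrected normal approximation otherwise; ``exact=False`` forces the
    approximation everywhere.
    """
    x = np.asarray(series, dtype=float).ravel()
    p, period, phase, stat = (v[0] for v in
                              _window_pvalues_matrix(x[None, :], window,
                                                     dt_hours, exact))
    return RhythmTestResult(gene_id, window.name, float(p), float(period),
                            int(phase), float(stat))


# ---------------------------------------------------------------------------
# matrix-level detection
# ---------------------------------------------------------------------------


def _window_pvalues_matrix(X: np.ndarray, window: PeriodWindow, dt_hours: float,
                           exact: str | bool = "auto"):
    """Per-gene window test over a genes x timepoints array.

    Policy per gene and fold: exact DP null for tie-free series, exact
    multiset enumeration for tied series with a feasible arrangement count,
    tie-corrected normal approximation otherwise (always, if exact=False).
    """
    if exact not in (True, False, "auto"):
        raise ValueError("exact must be True, False or 'auto'")
    G, n = X.shape
    folds = window.candidate_folds(dt_hours, n)
    tied = _has_ties(X)
    p_all = []
    stat_all = []
    periods, phases = [], []
    for m in folds:
        plan = _fold_plan(n, m, "detect")
        K = len(plan["peaks"])
        A, mean, var = _fold_statistics(X, m, "detect")
        p = _normal_peak_pvalues(A, mean, var)
        if exact is not False:
            untied = ~tied
            if untied.any():
                for k in range(K):
                    sf2 = _null_sf(n, m, k, "detect")
                    if sf2 is None:
                        continue
                    ai = np.rint(2 * A[untied, k]).astype(int)
                    p[untied, k] = sf2[np.clip(ai, 0, len(sf2) - 1)]
            for g in np.nonzero(tied)[0]:
                pattern = _tie_pattern(X[g])
                sf2s = [_null_sf(n, m, k, "detect", pattern) for k in range(K)]
                if all(s is not None for s in sf2s):
                    for k, sf2 in enumerate(sf2s):
                        ai = int(np.rint(2 * A[g, k]))
                        p[g, k] = sf2[min(max(ai, 0), len(sf2) - 1)]
                elif (exact is True or n_distinct_arrangements(X[g])
                        <= EXACT_ENUMERATION_LIMIT):
                    p_peaks, A_obs = _exact_fold_pvalues(X[g], m, "detect")
                    p[g, :] = p_peaks
                    A[g, :] = A_obs
        p_all.append(np.clip(p, P_FLOOR, 1.0))
        stat_all.append(A)
        periods.extend([m * dt_hours] * K)
        phases.extend(peak["phase"] for peak in plan["peaks"])
    p_cat = np.concatenate(p_all, axis=1)
    stat_cat = np.concatenate(stat_all, axis=1)
    n_alternatives = p_cat.shape[1]
    best_idx = np.argmin(p_cat, axis=1)
    rows = np.arange(G)
    p_win = np.clip(p_cat[rows, best_idx] * n_alternatives, P_FLOOR, 1.0)
    return (
        p_win,
        np.asarray(periods)[best_idx],
        np.asarray(phases, dtype=int)[best_idx],
        stat_cat[rows, best_idx],
    )


def detect_rhythms(
    matrix,
    windows=(CIRCATIDAL_WINDOW, CIRCADIAN_WINDOW),
    alpha: float = 0.01,
    exact: str | bool = "auto",
):
    """Per-gene rhythm tests for each window plus significant gene sets.

    Parameters
    ----------
    matrix : ExpressionMatrix
        Filtered TPM matrix (see :mod:`tiderhythm.filters`).
    windows : iterable of PeriodWindow
    alpha : float
        Strict significance threshold: a gene is called oscillating in a
        window when ``p < alpha`` (not <=).

    Returns
    -------
    (results, sets) : (pandas.DataFrame, dict)
        ``results`` has one row per gene per window with columns gene_id,
        window, p_value, best_period_hours, best_peak_phase_index,
        statistic.  ``sets`` maps window name to the set of significant
        genes.
    """
    X = matrix.tpm.to_numpy(dtype=float)
    gene_ids = matrix.tpm.index.to_numpy()
    dt = matrix.dt
    rows = []
    sets: dict[str, set] = {}
    for window in windows:
        p, period, phase, stat = _window_pvalues_matrix(X, window, dt, exact)
        rows.append(pd.DataFrame({
            "gene_id": gene_ids,
            "window": window.name,
            "p_value": p,
            "best_period_hours": period,
            "best_peak_phase_index": phase.astype(int),
            "statistic": stat,
        }))
        sets[window.name] = set(gene_ids[p < alpha])
    results = pd.concat(rows, ignore_index=True)
    return results, sets


def rhythm_class_transitions(results_a: pd.DataFrame, results_b: pd.DataFrame,
                             alpha: float = 0.01) -> set:
    """Genes that switch from circadian-only rhythmicity in condition A to
    circatidal-only rhythmicity in condition B (e.g. control -> entrained)."""
    ua = set(results_a["gene_id"])
    ub = set(results_b["gene_id"])
    if ua != ub:
        raise ValueError("result tables cover different gene universes")

    def _sig(df, window):
        sub = df[df["window"] == window]
        return set(sub.loc[sub["p_value"] < alpha, "gene_id"])

    a_cir, a_tid = _sig(results_a, "circadian"), _sig(results_a, "circatidal")
    b_cir, b_tid = _sig(results_b, "circadian"), _sig(results_b, "circatidal")
    return (a_cir - a_tid) & (b_tid - b_cir)


def overlap_counts(gene_sets: dict) -> pd.DataFrame:
    """Pairwise intersection counts between labelled gene sets (Venn counts)."""
    labels = sorted(gene_sets)
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            rows.append({
                "set_a": a,
                "set_b": b,
                "n_a": len(gene_sets[a]),
                "n_b": len(gene_sets[b]),
                "n_overlap": len(gene_sets[a] & gene_sets[b]),
            })
    return pd.DataFrame(rows, columns=["set_a", "set_b", "n_a", "n_b", "n_overlap"])
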