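"""Nonparametric k-group comparison: Kruskal-Wallis omnibus test, Dunn's
pairwise post hoc z-tests on pooled mid-ranks, Holm step-down adjustment,
and compact letter displays.

All statistics are computed here from their rank-sum definitions (mid-ranks
with the standard tie correction) rather than delegated, so the pipeline's
inferential chain is auditable end to end; library implementations serve as
independent cross-checks in the test suite.

Notation: k groups with sizes n_a, pooled size N, pooled mid-ranks r.

    H = (12 / (N (N+1)) * sum_a n_a (rbar_a - (N+1)/2)^2) / C
    C = 1 - sum_t (t^3 - t) / (N^3 - N)                       (tie correction)
    p = P(chi2_{k-1} >= H)

Dunn's z for groups a, b:

    z_ab = (rbar_a - rbar_b) / sqrt( (N(N+1)/12 - T/(12(N-1))) (1/n_a + 1/n_b) )
    T    = sum_t (t^3 - t)

with two-sided normal p-values, Holm-adjusted over all k(k-1)/2 pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_ALPHA = 0.05


@dataclass
class GroupSample:
    label: str
    values: np.ndarray

    def __init__(self, label: str, values: Sequence[float]):
        self.label = str(label)
        self.values = np.asarray(values, dtype=float)
        if self.values.size == 0:
            raise ValueError(f"group {label!r} has no values")


@dataclass(frozen=True)
class KruskalResult:
    h: float
    df: int
    p: float


@dataclass(frozen=True)
class PairwiseResult:
    pair: tuple[str, str]
    z: float
    p_raw: float
    p_adj: float
    significant: bool


def _pooled_ranks(groups: Sequence[GroupSample]) -> tuple[np.ndarray, np.ndarray, float]:
    """Pooled mid-ranks, group index per observation, and tie term T."""
    pooled = np.concatenate([g.values for g in groups])
    idx = np.concatenate([np.full(g.values.size, i) for i, g in enumerate(groups)])
    ranks = stats.rankdata(pooled)  # mid-ranks
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts.astype(float) ** 3 - counts))
    return ranks, idx, tie_term


def kruskal_wallis(groups: Sequence[GroupSample]) -> KruskalResult:
    """Tie-corrected Kruskal-Wallis H with chi-square upper-tail p-value.

    Degenerate input where every pooled value is identical yields H = 0,
    p = 1 (no evidence of any location difference).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    n_total = sum(g.values.size for g in groups)
    if n_total < 3:
        raise ValueError("need at least three observations in total")
    ranks, idx, tie_term = _pooled_ranks(groups)
    df = len(groups) - 1
    correction = 1.0 - tie_term / (n_total**3 - n_total)
    if correction <= 0:  # all pooled values identical
        return KruskalResult(h=0.0, df=df, p=1.0)
    grand_mean = (n_total + 1) / 2.0
    h = 0.0
    for i, g in enumerate(groups):
        rbar = ranks[idx == i].mean()
        h += g.values.size * (rbar - grand_mean) ** 2
    h *= 12.0 / (n_total * (n_total + 1))
    h /= correction
    return KruskalResult(h=float(h), df=df, p=float(stats.chi2.sf(h, df)))


def holm_adjust(p_values: Sequence[float]) -> list[float]:
    """Holm step-down adjustment, returned in input order.

    Sorted ascending, p_(i) is multiplied by (m - i), a running maximum
    enforces monotonicity, and results are clipped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    out = np.empty(m)
    out[order] = adj_sorted
    return out.tolist()


def dunn_posthoc(
    groups: Sequence[GroupSample],
    alpha: float = DEFAULT_ALPHA,
) -> list[PairwiseResult]:
    """Dunn's z-tests for all pairs on pooled mid-ranks, Holm-adjusted.

    Two-sided, tie-corrected pooled variance, no continuity correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    ranks, idx, tie_term = _pooled_ranks(groups)
    n_total = ranks.size
    mean_ranks = [ranks[idx == i].mean() for i in range(len(groups))]
    var_core = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_core -= tie_term / (12.0 * (n_total - 1))

    pairs = list(itertools.combinations(range(len(groups)), 2))
    zs: list[float] = []
    for a, b in pairs:
        se2 = var_core * (1.0 / groups[a].values.size + 1.0 / groups[b].values.size)
        if se2 <= 0:  # all pooled values tied: no rank information
            zs.append(0.0)
        else:
            zs.append((mean_ranks[a] - mean_ranks[b]) / np.sqrt(se2))
    p_raw = [float(2.0 * stats.norm.sf(abs(z))) for z in zs]
    p_adj = holm_adjust(p_raw)
    return [
        PairwiseResult(
            pair=(groups[a].label, groups[b].label),
            z=float(z),
            p_raw=pr,
            p_adj=pa,
            significant=pa < alpha,
        )
        for (a, b), z, pr, pa in zip(pairs, zs, p_raw, p_adj)
    ]


def compact_letters(
    results: Sequence[PairwiseResult],
    labels: Sequence[str] | None = None,
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Starts from one letter covering all labels; every significant pair
    splits each letter set containing both members; redundant (subset)
    letter sets are absorbed.  Two labels share a letter if and only if
    their comparison is non-significant — validated on the output.
    """
    sig: dict[frozenset[str], bool] = {}
    seen_labels: list[str] = []
    for r in results:
        key = frozenset(r.pair)
        if key in sig and sig[key] != r.significant:
            raise ValueError(f"conflicting significance for pair {tuple(sorted(key))}")
        sig[key] = r.significant
        for lab in r.pair:
            if lab not in seen_labels:
                seen_labels.append(lab)
    if labels is None:
        labels = seen_labels
    labels = list(labels)

    sets: list[set[str]] = [set(labels)]
    for key, is_sig in sig.items():
        if not is_sig:
            continue
        a, b = sorted(key)
        new_sets: list[set[str]] = []
        for s in sets:
            if a in s and b in s:
                new_sets.append(s - {a})
                new_sets.append(s - {b})
            else:
                new_sets.append(s)
        # absorb: drop sets contained in another
        sets = [
            s
            for i, s in enumerate(new_sets)
            if s and not any(i != j and s < t or (s == t and i > j) for j, t in enumerate(new_sets))
        ]

    # letters in order of first appearance over the given label order
    def first_position(s: set[str]) -> int:
        return min(labels.index(lab) for lab in s)

    sets.sort(key=first_position)
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    display: dict[str, list[str]] = {lab: [] for lab in labels}
    for i, s in enumerate(sets):
        letter = alphabet[i] if i < len(alphabet) else f"z{i}"
        for lab in labels:
            if lab in s:
                display[lab].append(letter)

    out = {lab: "".join(letters) for lab, letters in display.items()}
    _validate_letters(out, sig)
    return out


def _validate_letters(display: dict[str, str], sig: dict[frozenset[str], bool]) -> None:
    for key, is_sig in sig.items():
        a, b = sorted(key)
        if a not in display or b not in display:
            continue
        shares = bool(set(display[a]) & set(display[b]))
        if shares == is_sig:
            raise AssertionError(
                f"letter display violates share-letter <=> non-significant for pair ({a}, {b})"
            )


def pairwise_frame(results: Sequence[PairwiseResult], metric: str | None = None):
    """Long-format table of pairwise results (for CSV export)."""
    import pandas as pd

    rows = [
        {
            "metric": metric,
            "group_a": r.pair[0],
            "group_b": r.pair[1],
            "z": r.z,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
            "significant": r.significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)
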