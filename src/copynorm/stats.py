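"""Comparison statistics for community profiles.

Distances between observed and expected profiles use a Hellinger-style
transform: relative abundances are square-root transformed, renormalized to
100%, and compared by Euclidean distance. Group comparisons use the
Mann-Whitney U test (exact when sample sizes allow and there are no ties).
Dominance is summarized by the Berger-Parker index — the relative abundance
of the single most abundant taxon — and an incremental procedure reports
the fraction of sample pairs whose dominance is statistically unchanged by
a correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "DistanceReport",
    "hellinger_transform",
    "profile_distance",
    "align_profiles",
    "mann_whitney",
    "berger_parker",
    "incremental_nonsig_fraction",
]

#: Above this combined sample size the exact Mann-Whitney enumeration is
#: replaced by the tie-corrected normal approximation.
EXACT_MW_LIMIT = 20


@dataclass
class DistanceReport:
    """Per-sample transformed distances for two groups plus their test."""

    distances: Dict[str, float]
    groups: Dict[str, str]  # sample -> group label
    u_statistic: Optional[float] = None
    p_value: Optional[float] = None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"sample": s, "group": self.groups.get(s, ""),
                 "distance": d} for s, d in self.distances.items()]
        return pd.DataFrame(rows)


def hellinger_transform(percent: np.ndarray) -> np.ndarray:
    """Square-root transform a percent vector and renormalize to 100."""
    v = np.sqrt(np.asarray(percent, dtype=float))
    total = v.sum()
    if total <= 0:
        raise ValueError("empty profile")
    return v * 100.0 / total


def align_profiles(observed: Mapping[str, float],
                   expected: Mapping[str, float]) -> Tuple[np.ndarray, np.ndarray]:
    """Align two taxon->percent maps on the union of taxa, zero-filling."""
    taxa = sorted(set(observed) | set(expected))
    obs = np.array([observed.get(t, 0.0) for t in taxa])
    exp = np.array([expected.get(t, 0.0) for t in taxa])
    return obs, exp


def profile_distance(observed, expected) -> float:
    """Distance between two percent profiles after the Hellinger-style
    transform (sqrt, renormalize to 100, Euclidean).

    Accepts aligned vectors or taxon->percent mappings (aligned on the
    union of taxa with zero fill).
    """
    if isinstance(observed, Mapping) or isinstance(expected, Mapping):
        observed, expected = align_profiles(dict(observed), dict(expected))
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("profiles must be aligned to the same taxa")
    return float(np.linalg.norm(hellinger_transform(observed)
                                - hellinger_transform(expected)))


def mann_whitney(x: Sequence[float], y: Sequence[float],
                 alternative: str = "two_sided",
                 method: str = "auto") -> Tuple[float, float]:
    """Mann-Whitney U test; returns (U, p).

    ``method='exact'`` enumerates the permutation distribution (valid
    without ties); with ties it falls back to the tie-corrected normal
    approximation with a warning. ``auto`` picks exact when
    n_x + n_y <= 20 and there are no ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("both samples must be non-empty")
    alt = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[alternative]
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if method == "auto":
        method = "exact" if (len(pooled) <= EXACT_MW_LIMIT and not has_ties) \
            else "normal"
    if method == "exact" and has_ties:
        warnings.warn("ties present; exact Mann-Whitney falls back to the "
                      "normal approximation")
        method = "normal"
    scipy_method = "exact" if method == "exact" else "asymptotic"
    res = _sps.mannwhitneyu(x, y, alternative=alt, method=scipy_method)
    return float(res.statistic), float(res.pvalue)


def berger_parker(percent: Sequence[float]) -> float:
    """Berger-Parker dominance index: the largest relative abundance."""
    v = np.asarray(percent, dtype=float)
    if v.size == 0:
        raise ValueError("empty profile")
    return float(v.max())


def incremental_nonsig_fraction(paired_bp: Sequence[Tuple[float, float]],
                                alpha: float = 0.05) -> float:
    """Fraction of samples whose dominance is unchanged by correction.

    ``paired_bp`` holds (uncorrected, corrected) Berger-Parker values per
    sample. Pairs are sorted by |corrected - uncorrected| ascending; for
    each prefix of k >= 2 pairs a two-sided Mann-Whitney test compares the
    k uncorrected against the k corrected values. Returns the largest k/n
    for which p >= alpha (0.0 if even the two most similar pairs differ).
    """
    pairs = sorted(paired_bp, key=lambda p: abs(p[1] - p[0]))
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    best = 0.0
    for k in range(2, n + 1):
        unc = [p[0] for p in pairs[:k]]
        cor = [p[1] for p in pairs[:k]]
        if unc == cor:
            p_val = 1.0
        else:
            _, p_val = mann_whitney(unc, cor, alternative="two_sided")
        if p_val >= alpha:
            best = k / n
    return best
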