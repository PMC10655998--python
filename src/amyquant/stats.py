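"""Rank statistics: group medians, Kruskal-Wallis with Dunn's post-hoc
test, and exact small-sample Spearman correlation.

The omnibus test is the tie-corrected Kruskal-Wallis H with a chi-square
reference; selected pairwise contrasts are tested with Dunn's z computed
from pooled mid-rank means and the tie-corrected rank variance, with
Bonferroni adjustment over the requested comparison set (the behaviour of
the usual "Dunn's multiple comparison" procedure). Comparison sets are
explicit inputs because study designs typically test selected contrasts
(each transgenic line against its control), not all pairs.

Spearman correlation at n <= 10 without ties is tested exactly by
enumerating all n! rank permutations; the one-sided p-value is the
fraction of permutations at least as extreme as the observed coefficient
in its own direction. At n = 5 a coefficient of 0.9 gives p = 5/120
(0.04 at two decimals); at n = 4 a coefficient of -0.8 gives p = 4/24
(0.17) - values that a two-sided convention would double.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import StatsError

__all__ = [
    "KWDunnResult",
    "SpearmanResult",
    "kruskal_dunn",
    "spearman_exact",
    "summarize_groups",
]

# A GroupTable is any mapping from group label to a sequence of measurements.
GroupTable = Mapping[str, Sequence[float]]


@dataclass
class KWDunnResult:
    H: float
    p_omnibus: float
    pairwise: pd.DataFrame = field(repr=False)


@dataclass
class SpearmanResult:
    rho: float
    p_one_sided: float
    method: str  # exact | asymptotic
    n: int


def _validate_groups(table: GroupTable) -> dict[str, np.ndarray]:
    if len(table) < 2:
        raise StatsError("need >= 2 groups")
    out = {}
    for name, vals in table.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise StatsError(f"group {name!r} is empty")
        out[str(name)] = arr
    return out


def kruskal_dunn(
    table: GroupTable,
    comparisons: Sequence[tuple[str, str]] | str = "all",
) -> KWDunnResult:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise z tests.

    ``comparisons`` is either ``"all"`` or an explicit list of group-label
    pairs; adjusted p-values are Bonferroni over exactly that set, capped
    at 1. Fully tied data (every pooled value identical) returns H = 0 and
    p = 1 by convention rather than an error.
    """
    groups = _validate_groups(table)
    names = list(groups)
    pooled = np.concatenate([groups[g] for g in names])
    n_total = pooled.size
    ranks = sps.rankdata(pooled)

    if np.all(pooled == pooled[0]):
        h, p_omni = 0.0, 1.0
    else:
        h, p_omni = sps.kruskal(*[groups[g] for g in names])
        h, p_omni = float(h), float(p_omni)

    # Mean mid-rank per group and tie-corrected Dunn variance.
    offsets = np.cumsum([0] + [groups[g].size for g in names])
    mean_rank = {g: float(ranks[offsets[i]:offsets[i + 1]].mean())
                 for i, g in enumerate(names)}
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts))
    var_base = n_total * (n_total + 1) / 12.0
    if n_total > 1:
        var_base -= tie_term / (12.0 * (n_total - 1))

    if comparisons == "all":
        pairs = list(itertools.combinations(names, 2))
    else:
        pairs = [(str(a), str(b)) for a, b in comparisons]
        unknown = {g for pair in pairs for g in pair} - set(names)
        if unknown:
            raise StatsError(f"comparison references unknown groups: {sorted(unknown)}")
    m = len(pairs)
    rows = []
    for g1, g2 in pairs:
        se = math.sqrt(var_base * (1.0 / groups[g1].size + 1.0 / groups[g2].size))
        z = (mean_rank[g1] - mean_rank[g2]) / se if se > 0 else 0.0
        p_raw = 2.0 * sps.norm.sf(abs(z))
        rows.append((g1, g2, z, p_raw, min(1.0, p_raw * m)))
    pairwise = pd.DataFrame(rows, columns=["group_i", "group_j", "z", "p", "p_adjusted"])
    return KWDunnResult(H=h, p_omnibus=p_omni, pairwise=pairwise)


@lru_cache(maxsize=None)
def _perm_rho_table(n: int) -> np.ndarray:
    """Spearman rho of every permutation of 1..n against the identity ranks."""
    ranks = np.arange(1, n + 1)
    perms = np.array(list(itertools.permutations(ranks)), dtype=float)
    d2 = ((perms - ranks) ** 2).sum(axis=1)
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def _spearman_rho_noties(x: np.ndarray, y: np.ndarray) -> float:
    n = x.size
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    d2 = float(((rx - ry) ** 2).sum())
    return 1.0 - 6.0 * d2 / (n * (n * n - 1))


def spearman_exact(x: Sequence[float], y: Sequence[float]) -> SpearmanResult:
    """Spearman correlation with an exact one-sided permutation p-value.

    For n <= 10 with no ties in either vector, the p-value is the exact
    fraction of the n! rank permutations whose coefficient is at least as
    extreme as observed, in the direction of the observed sign (positive
    direction when rho = 0). Ties or n > 10 fall back to the asymptotic
    one-sided test with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise StatsError("x and y must have equal length")
    n = int(x.size)
    if n < 3:
        raise StatsError("need n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise StatsError("constant input vector")
    has_ties = len(np.unique(x)) < n or len(np.unique(y)) < n
    if has_ties or n > 10:
        reason = "ties present" if has_ties else f"n = {n} > 10"
        warnings.warn(f"falling back to asymptotic Spearman p ({reason})",
                      stacklevel=2)
        res = sps.spearmanr(x, y)
        rho = float(res.statistic)
        p_two = float(res.pvalue)
        p_one = p_two / 2.0 if not math.isnan(p_two) else math.nan
        return SpearmanResult(rho=rho, p_one_sided=p_one, method="asymptotic", n=n)
    rho = _spearman_rho_noties(x, y)
    tab = _perm_rho_table(n)
    eps = 1e-12
    if rho >= 0:
        count = int(np.count_nonzero(tab >= rho - eps))
    else:
        count = int(np.count_nonzero(tab <= rho + eps))
    p = count / math.factorial(n)
    return SpearmanResult(rho=rho, p_one_sided=p, method="exact", n=n)


def summarize_groups(table: GroupTable) -> pd.DataFrame:
    """Per-group n, median and IQR.

    The median uses the midpoint convention for even n; the IQR is the
    25th-to-75th percentile span with linear interpolation.
    """
    groups = _validate_groups(table) if len(table) >= 2 else {
        str(k): np.asarray(v, dtype=float) for k, v in table.items()
    }
    rows = []
    for name, arr in groups.items():
        if arr.size == 0:
            raise StatsError(f"group {name!r} is empty")
        q25, q75 = np.percentile(arr, [25, 75])
        rows.append((name, int(arr.size), float(np.median(arr)), float(q75 - q25)))
    return pd.DataFrame(rows, columns=["group", "n", "median", "iqr"])
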