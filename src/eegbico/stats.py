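"""Session-comparison statistics: paired/unpaired t-tests, Wilcoxon
rank-sum, and per-channel significance screening.

All tests are two-sided. No multiple-comparison correction is applied by
default (per-channel maps report uncorrected P < alpha); an optional
Benjamini-Hochberg FDR mode exists and is always recorded in the output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "SessionComparison",
    "DegenerateDataError",
    "paired_t",
    "unpaired_t",
    "wilcoxon_ranksum",
    "per_channel_screen",
]


class DegenerateDataError(ValueError):
    """Test statistic undefined for this input (e.g. zero variance)."""


@dataclass
class SessionComparison:
    """Outcome of one statistical comparison."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    alpha: float = 0.05
    method: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.p_value <= 1):
            raise ValueError("p-value outside [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha


def _check_finite(*arrays: np.ndarray) -> None:
    for a in arrays:
        if not np.all(np.isfinite(a)):
            raise ValueError("samples must be finite")


def paired_t(x, y, alpha: float = 0.05) -> SessionComparison:
    """Classical paired t-test, two-sided.

    ``x = y`` elementwise gives t = 0, p = 1; constant nonzero differences
    have zero variance and raise ``DegenerateDataError``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples must have equal length >= 2")
    _check_finite(x, y)
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            return SessionComparison("paired_t", 0.0, 1.0, (x.size,), alpha)
        raise DegenerateDataError(
            "differences are a nonzero constant: paired t undefined"
        )
    res = sps.ttest_rel(x, y)
    return SessionComparison("paired_t", float(res.statistic), float(res.pvalue),
                             (x.size,), alpha)


def unpaired_t(x, y, alpha: float = 0.05, equal_var: bool = False) -> SessionComparison:
    """Two-sample t-test, Welch by default (pooled with ``equal_var=True``)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    _check_finite(x, y)
    if np.all(x == x[0]) and np.all(y == y[0]):
        if x[0] == y[0]:
            return SessionComparison(
                "unpaired_t", 0.0, 1.0, (x.size, y.size), alpha,
                method="welch" if not equal_var else "pooled",
            )
        raise DegenerateDataError("both groups constant: t undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return SessionComparison(
        "unpaired_t", float(res.statistic), float(res.pvalue),
        (x.size, y.size), alpha, method="welch" if not equal_var else "pooled",
    )


def wilcoxon_ranksum(x, y, alpha: float = 0.05) -> SessionComparison:
    """Wilcoxon rank-sum (Mann-Whitney) test, two-sided.

    Exact p-value for combined n <= 20 without ties; normal approximation
    with tie correction otherwise. The reported statistic is the rank sum
    of the first sample; the method used is recorded.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("each group needs at least one observation")
    _check_finite(x, y)
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        raise DegenerateDataError("all values identical: rank-sum test undefined")
    ties = len(np.unique(pooled)) < pooled.size
    exact = (x.size + y.size) <= 20 and not ties
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    # rank sum of x: W = U + n1(n1+1)/2
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0
    return SessionComparison(
        "wilcoxon_ranksum", w, float(min(res.pvalue, 1.0)),
        (x.size, y.size), alpha,
        method="exact" if exact else "normal approximation, tie-corrected",
    )


def per_channel_screen(
    after: pd.DataFrame,
    before: pd.DataFrame,
    alpha: float = 0.05,
    test: str = "paired_t",
    fdr: bool = False,
) -> pd.DataFrame:
    """Significance mask over (channel, band) cells across units.

    ``after`` and ``before`` are long-format tables with columns
    (unit, channel, band, value), one value per experimental unit (rat).
    Each (channel, band) cell is tested across units; the result has one
    row per cell with statistic, p, and a significance flag at ``alpha``.
    With ``fdr=True`` p-values are Benjamini-Hochberg adjusted and the
    adjustment is recorded in the ``correction`` column.
    """
    tests = {"paired_t": paired_t, "wilcoxon_ranksum": wilcoxon_ranksum,
             "unpaired_t": unpaired_t}
    if test not in tests:
        raise ValueError(f"unknown test {test!r}")
    for df in (after, before):
        missing = {"unit", "channel", "band", "value"} - set(df.columns)
        if missing:
            raise ValueError(f"table missing columns {sorted(missing)}")
    cells_a = set(map(tuple, after[["channel", "band"]].drop_duplicates().values))
    cells_b = set(map(tuple, before[["channel", "band"]].drop_duplicates().values))
    if cells_a != cells_b:
        raise ValueError("after/before tables cover different (channel, band) cells")
    a_idx = after.set_index(["channel", "band", "unit"])["value"].sort_index()
    b_idx = before.set_index(["channel", "band", "unit"])["value"].sort_index()
    rows = []
    for ch, band in sorted(cells_a):
        xa = a_idx.loc[(ch, band)]
        xb = b_idx.loc[(ch, band)]
        if test == "paired_t" and not xa.index.equals(xb.index):
            raise ValueError(f"units mismatch in cell ({ch}, {band})")
        try:
            cmp = tests[test](xa.values, xb.values, alpha=alpha)
            stat, p = cmp.statistic, cmp.p_value
        except DegenerateDataError:
            stat, p = np.nan, 1.0
        rows.append({"channel": ch, "band": band, "statistic": stat, "p": p})
    out = pd.DataFrame(rows)
    if fdr:
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests(out["p"], alpha=alpha, method="fdr_bh")
        out["p"] = p_adj
        out["correction"] = "fdr_bh"
    else:
        out["correction"] = "none"
    out["significant"] = out["p"] < alpha
    out["test"] = test
    out["alpha"] = alpha
    return out
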