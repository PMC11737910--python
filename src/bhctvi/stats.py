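"""Paired nonparametric comparison of section ratios across body positions.

Each (lung, section) cell is compared between the supine reference and the
three other positions with the Wilcoxon signed-rank test.  P-values are
exact — computed from the full distribution of the signed-rank sum W under
the null (all 2^n sign assignments equally likely), with zero differences
dropped and mid-ranks for tied absolute differences — for n ≤ 25; beyond
that a normal approximation with continuity correction is used.  The
per-comparison significance threshold is Bonferroni-adjusted: alpha / m
with m = 3 position contrasts (0.05/3, conventionally displayed truncated
as 0.016).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

__all__ = [
    "WilcoxonResult",
    "wilcoxon_signed_rank",
    "bonferroni_threshold",
    "compare_positions",
    "CONTRASTS",
]

EXACT_ENUMERATION_MAX_N = 25
CONTRASTS = ("supine_vs_prone", "supine_vs_right_lateral", "supine_vs_left_lateral")


@dataclass(frozen=True)
class WilcoxonResult:
    w: float            # sum of signed ranks
    p_value: float      # two-sided; NaN when undefined (all differences zero)
    n: int              # pairs remaining after dropping zero differences
    exact: bool

    @property
    def defined(self) -> bool:
        return not math.isnan(self.p_value)


def _exact_two_sided_p(ranks: np.ndarray, w_obs: float) -> float:
    """P(|W| >= |w_obs|) under random signs, by dynamic programming.

    Doubling the (possibly half-integer) mid-ranks makes them integers, so
    the distribution of the positive-rank sum S+ is a polynomial whose
    coefficients we accumulate by convolution; W = 2 S+ − Σr.
    """
    r2 = np.rint(2.0 * ranks).astype(np.int64)
    total = int(r2.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    top = 0
    for r in r2:
        counts[r : top + r + 1] += counts[: top + 1]
        top += r
    w2 = np.abs(np.rint(2.0 * w_obs))
    s = np.arange(total + 1)
    wvals = np.abs(2 * s - total)  # |W| doubled
    prob = counts[wvals >= w2 - 1e-9].sum() / 2.0 ** len(r2)
    return float(min(1.0, prob))


def wilcoxon_signed_rank(paired_a, paired_b) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Zero differences are dropped (Wilcoxon's convention); tied absolute
    differences receive mid-ranks.  W is the sum of signed ranks.  If all
    differences are zero the p-value is undefined (NaN, flagged).
    """
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1D and of equal length")
    d = a - b
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(w=0.0, p_value=float("nan"), n=0, exact=True)
    ranks = rankdata(np.abs(d), method="average")
    w = float(np.sum(np.sign(d) * ranks))
    if n <= EXACT_ENUMERATION_MAX_N:
        p = _exact_two_sided_p(ranks, w)
        return WilcoxonResult(w=w, p_value=p, n=n, exact=True)
    # normal approximation: Var(W) = Σ r_i² under random signs (mid-ranks
    # absorb the tie correction), continuity-corrected
    sigma = math.sqrt(float(np.sum(ranks**2)))
    z = (abs(w) - 0.5) / sigma if sigma > 0 else 0.0
    p = 2.0 * (1.0 - norm.cdf(z))
    return WilcoxonResult(w=w, p_value=float(min(1.0, p)), n=n, exact=False)


def bonferroni_threshold(alpha: float, m: int) -> tuple[float, str]:
    """Per-comparison threshold alpha/m and its display form.

    The display value is truncated (not rounded) to three decimals — the
    convention that turns 0.05/3 = 0.01666… into "0.016".
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    t = alpha / m
    display = f"{math.floor(t * 1000) / 1000:.3f}"
    return t, display


def compare_positions(
    reports: dict[str, pd.DataFrame],
    alpha: float = 0.05,
    m: int = 3,
    reference: str = "supine",
) -> pd.DataFrame:
    """Wilcoxon tests of each (lung, section) cell vs the reference position.

    ``reports`` maps position name to a tidy DataFrame with columns
    ``subject, lung, section, ratio_pct`` (one row per subject per cell).
    Returns one row per lung × section × contrast with the paired n, W,
    p-value and the Bonferroni significance flag.
    """
    if reference not in reports:
        raise ValueError(f"reference position {reference!r} missing from reports")
    threshold, display = bonferroni_threshold(alpha, m)
    ref = reports[reference]
    required = {"subject", "lung", "section", "ratio_pct"}
    rows = []
    for position, df in reports.items():
        if position == reference:
            continue
        if not required.issubset(df.columns) or not required.issubset(ref.columns):
            raise ValueError(f"reports need columns {sorted(required)}")
        for (lung, section), grp in ref.groupby(["lung", "section"], sort=False):
            other = df[(df["lung"] == lung) & (df["section"] == section)]
            merged = grp.merge(other, on="subject", suffixes=("_ref", "_cmp"))
            if len(merged) != len(grp) or len(merged) != len(other):
                raise ValueError(
                    f"subject mismatch between {reference} and {position} "
                    f"for {lung}/{section}"
                )
            res = wilcoxon_signed_rank(
                merged["ratio_pct_ref"].to_numpy(), merged["ratio_pct_cmp"].to_numpy()
            )
            rows.append(
                dict(
                    lung=lung,
                    section=section,
                    contrast=f"{reference}_vs_{position}",
                    n=res.n,
                    w=res.w,
                    p_value=res.p_value,
                    significant=bool(res.defined and res.p_value < threshold),
                    threshold=threshold,
                    threshold_display=display,
                )
            )
    return pd.DataFrame(rows)
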