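"""Nonparametric effect sizes and tests for cohort contrasts.

Cliff's delta is the primary effect measure: the difference between the
probability that a value from one sample exceeds a value from the other and
the reverse, in [-1, 1]; ties contribute zero.  The accompanying p-value for
each feature contrast is the two-sample Kolmogorov-Smirnov test's.  The
Mann-Whitney U and Pearson chi-squared operations cover the demographic
comparisons (age, sex) between cohorts.

No multiple-testing correction is applied anywhere: effect tables report raw
KS p-values.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidArgumentError
from .records import FEATURE_NAMES


def cliffs_delta(xs: Sequence[float], ys: Sequence[float]) -> float:
    """Cliff's delta ``(#{x>y} - #{x<y}) / (|xs| * |ys|)``.

    Positive when ``xs`` is stochastically larger than ``ys``.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("samples must be non-empty")
    diff = x[:, None] - y[None, :]
    return float((np.sign(diff)).sum() / (x.size * y.size))


def ks_test(xs: Sequence[float], ys: Sequence[float], method: str = "asymp") -> dict:
    """Two-sample two-sided Kolmogorov-Smirnov test.

    ``method``: "asymp" (default, matching the cohort sample sizes here),
    "exact", or "auto" for scipy's sample-size rule.
    """
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("samples must be non-empty")
    res = stats.ks_2samp(x, y, alternative="two-sided", method=method)
    return {"statistic": float(res.statistic), "p": float(min(res.pvalue, 1.0))}


def mann_whitney_u(xs: Sequence[float], ys: Sequence[float]) -> dict:
    """Mann-Whitney U for ``xs`` (midrank ties, normal approximation with
    tie correction, two-sided)."""
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidArgumentError("samples must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return {"U": float(res.statistic), "p": float(res.pvalue)}


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> dict:
    """Pearson chi-squared (1 df, no continuity correction) on [[a, b], [c, d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise InvalidArgumentError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise InvalidArgumentError("all margins must be positive")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return {"chi2": float(chi2), "p": float(p)}


def effect_table(
    features_a: pd.DataFrame,
    features_b: pd.DataFrame,
    reference_contrast: Optional[pd.DataFrame] = None,
    feature_names: Sequence[str] = FEATURE_NAMES,
    ks_method: str = "asymp",
) -> pd.DataFrame:
    """Per-feature Cliff's delta + KS p for the contrast A vs B.

    Orientation: delta is ``cliffs_delta(B, A)``, positive when cohort B's
    values are stochastically larger than cohort A's, so with A = controls
    and B = the clinical cohort a slower/more variable clinical cohort gets
    positive deltas.  Rows with missing (NaN) values in either cohort are
    flagged ``incomplete`` and carry NaN statistics.

    ``reference_contrast``: an earlier effect table; when given, a column
    ``change = |delta| - |delta_reference|`` is added.
    """
    rows = []
    for name in feature_names:
        a = features_a[name].to_numpy(dtype=float)
        b = features_b[name].to_numpy(dtype=float)
        complete = not (np.any(np.isnan(a)) or np.any(np.isnan(b)))
        if complete:
            delta = cliffs_delta(b, a)
            ks = ks_test(a, b, method=ks_method)
            rows.append((name, delta, ks["statistic"], ks["p"], True))
        else:
            rows.append((name, np.nan, np.nan, np.nan, False))
    table = pd.DataFrame(
        rows, columns=["feature", "cliffs_delta", "ks_statistic", "ks_p", "complete"]
    )
    if reference_contrast is not None:
        ref = reference_contrast.set_index("feature")["cliffs_delta"]
        table["change"] = (
            table["cliffs_delta"].abs().to_numpy()
            - ref.reindex(table["feature"]).abs().to_numpy()
        )
    return table
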