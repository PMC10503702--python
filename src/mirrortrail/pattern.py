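"""Randomization test for the effect-size change pattern across task groups.

Observation to test: splitting the clinical cohort by CAARMS (0 vs > 0), the
effect sizes versus controls change a lot for the mirror-game features but
stay nearly flat for the TMT features.  For a split of SU into halves
(half1, half2), define per feature

    change = |delta(CC, half2)| - |delta(CC, half1)|

(the analogue of the study's |es_>0 - es_=0| column, with half2 playing the
CAARMS > 0 role), and summarise the pattern with the statistic

    T = min(median Solo change, median LF change) - median TMT change,

large when *simultaneously* both mirror-game groups change more than TMT.
The significance of the observed (true CAARMS) split is the fraction of
random equal-size splits of SU whose T is at least as large -- a standard
randomization p-value, exact under exchangeability of the SU cohort.

Descriptively, the per-group booleans {tmt_low, solo_high, lf_high} compare
each group's median change against the overall 18-feature median change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidArgumentError
from .records import FEATURE_NAMES, LF_FEATURES, SOLO_FEATURES, TMT_FEATURES

_GROUP_SLICES = {
    "TMT": slice(0, 6),
    "Solo": slice(6, 10),
    "LF": slice(10, 18),
}


@dataclass
class SplitPattern:
    """Per-group median effect-size changes for one split of the SU cohort."""

    changes: np.ndarray  # per-feature, canonical order
    median_tmt: float
    median_solo: float
    median_lf: float
    overall_median: float
    statistic: float  # min(solo, lf) - tmt medians
    tmt_low: bool
    solo_high: bool
    lf_high: bool

    @property
    def event(self) -> bool:
        """Descriptive overall-median pattern: TMT below, Solo and LF above."""
        return self.tmt_low and self.solo_high and self.lf_high


@dataclass
class BootstrapPatternResult:
    p_value: float
    n_splits: int
    observed: SplitPattern
    split_statistics: np.ndarray


def _delta_contributions(cc: np.ndarray, su: np.ndarray) -> np.ndarray:
    """Per-SU-member, per-feature Cliff's-delta numerator contributions.

    ``delta(CC, S) = -sum_{j in S} d[j] / (n_cc * |S|)`` where
    ``d[j, f] = #{cc < su_j} - #{cc > su_j}`` on feature f; precomputing d
    makes delta over any SU subset a single matrix product.
    """
    # sign(su_j - cc_i) summed over cc_i -> (n_su, n_features)
    return np.sign(su[:, None, :] - cc[None, :, :]).sum(axis=1)


def _pattern_from_changes(changes: np.ndarray) -> SplitPattern:
    med = {g: float(np.median(changes[s])) for g, s in _GROUP_SLICES.items()}
    overall = float(np.median(changes))
    return SplitPattern(
        changes=changes,
        median_tmt=med["TMT"],
        median_solo=med["Solo"],
        median_lf=med["LF"],
        overall_median=overall,
        statistic=min(med["Solo"], med["LF"]) - med["TMT"],
        tmt_low=med["TMT"] < overall,
        solo_high=med["Solo"] > overall,
        lf_high=med["LF"] > overall,
    )


def _as_matrix(features: pd.DataFrame) -> np.ndarray:
    return features[list(FEATURE_NAMES)].to_numpy(dtype=float)


def split_change_pattern(
    cc_features: pd.DataFrame,
    su_features: pd.DataFrame,
    split_labels: np.ndarray,
) -> SplitPattern:
    """Effect-size change profile for one split of SU.

    ``split_labels`` is boolean over SU rows: True marks half2 (the
    CAARMS > 0 analogue).  Change per feature is
    ``|delta(CC, half2)| - |delta(CC, half1)|``.
    """
    labels = np.asarray(split_labels, dtype=bool)
    if labels.all() or not labels.any():
        raise InvalidArgumentError("split must leave both halves non-empty")
    cc = _as_matrix(cc_features)
    su = _as_matrix(su_features)
    if len(labels) != len(su):
        raise InvalidArgumentError("split labels must align with SU rows")
    d = _delta_contributions(cc, su)
    n_cc = len(cc)
    delta2 = -d[labels].sum(axis=0) / (n_cc * labels.sum())
    delta1 = -d[~labels].sum(axis=0) / (n_cc * (~labels).sum())
    return _pattern_from_changes(np.abs(delta2) - np.abs(delta1))


def bootstrap_pattern_test(
    cc_features: pd.DataFrame,
    su_features: pd.DataFrame,
    true_split: np.ndarray,
    n: int = 10_000,
    seed: int = 0,
    plus_one: bool = False,
) -> BootstrapPatternResult:
    """Randomization p-value of the observed change pattern.

    ``n`` random splits of SU preserve the observed half sizes; the p-value
    is the fraction of splits with ``T_split >= T_observed`` (with a +1/+1
    small-sample correction if ``plus_one``).
    """
    labels = np.asarray(true_split, dtype=bool)
    observed = split_change_pattern(cc_features, su_features, labels)
    cc = _as_matrix(cc_features)
    su = _as_matrix(su_features)
    d = _delta_contributions(cc, su)
    n_cc, n_su = len(cc), len(su)
    n_half2 = int(labels.sum())
    rng = np.random.default_rng(seed)

    # Vectorised: membership matrix (n_splits, n_su) -> delta over each half.
    member = np.zeros((n, n_su), dtype=bool)
    for i in range(n):
        member[i, rng.choice(n_su, size=n_half2, replace=False)] = True
    total = d.sum(axis=0)  # (n_features,)
    sum2 = member.astype(float) @ d  # (n_splits, n_features)
    delta2 = -sum2 / (n_cc * n_half2)
    delta1 = -(total[None, :] - sum2) / (n_cc * (n_su - n_half2))
    changes = np.abs(delta2) - np.abs(delta1)

    med_t = np.median(changes[:, _GROUP_SLICES["TMT"]], axis=1)
    med_s = np.median(changes[:, _GROUP_SLICES["Solo"]], axis=1)
    med_l = np.median(changes[:, _GROUP_SLICES["LF"]], axis=1)
    stats = np.minimum(med_s, med_l) - med_t

    hits = int(np.sum(stats >= observed.statistic))
    p = (hits + 1) / (n + 1) if plus_one else hits / n
    return BootstrapPatternResult(
        p_value=float(p), n_splits=n, observed=observed, split_statistics=stats
    )
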