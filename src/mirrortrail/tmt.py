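"""The 6 trail-making-task features: inter-click-time statistics.

ICT = times in ms between successive mouse clicks; IoTCT = times between
successive *on-target* (correct) clicks, i.e. differences along the on-target
subsequence.  Parts A and B are analysed together; the first of the three
repetitions is a familiarisation run and is excluded.  Features are the mean,
unbiased standard deviation and median of each pooled interval list.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np

from .errors import DegenerateInputError
from .records import TMTClickLog

logger = logging.getLogger(__name__)

INCLUDED_REPETITIONS = (2, 3)
PARTS = ("A", "B")

TMT_FEATURE_NAMES = (
    "TMT ICT mean",
    "TMT ICT std",
    "TMT ICT median",
    "TMT IoTCT mean",
    "TMT IoTCT std",
    "TMT IoTCT median",
)


def inter_click_times(log: TMTClickLog) -> np.ndarray:
    """Successive differences of all click times, in ms."""
    if len(log.click_times_ms) < 2:
        raise DegenerateInputError("need at least 2 clicks")
    return np.diff(log.click_times_ms)


def inter_on_target_click_times(log: TMTClickLog) -> np.ndarray:
    """Successive differences along the on-target click subsequence, in ms."""
    on = log.click_times_ms[log.on_target]
    if len(on) < 2:
        raise DegenerateInputError("need at least 2 on-target clicks")
    return np.diff(on)


def extract_tmt_features(
    logs: Sequence[TMTClickLog],
    included_repetitions: Sequence[int] = INCLUDED_REPETITIONS,
) -> dict[str, float]:
    """The 6 TMT features from one participant's click logs.

    Intervals are concatenated across parts A and B and the included
    repetitions before the statistics are taken.  A missing part/repetition
    flags all six features as NaN with a logged reason.
    """
    out: dict[str, float] = {name: np.nan for name in TMT_FEATURE_NAMES}
    wanted = {
        (part, rep) for part in PARTS for rep in included_repetitions
    }
    present = {(lg.part, lg.repetition) for lg in logs}
    missing = wanted - present
    if missing:
        logger.warning("missing TMT runs %s; TMT features flagged missing", sorted(missing))
        return out
    included = [lg for lg in logs if (lg.part, lg.repetition) in wanted]
    try:
        ict = np.concatenate([inter_click_times(lg) for lg in included])
        iotct = np.concatenate([inter_on_target_click_times(lg) for lg in included])
    except DegenerateInputError as exc:
        logger.warning("degenerate TMT log: %s", exc)
        return out
    out["TMT ICT mean"] = float(np.mean(ict))
    out["TMT ICT std"] = float(np.std(ict, ddof=1))
    out["TMT ICT median"] = float(np.median(ict))
    out["TMT IoTCT mean"] = float(np.mean(iotct))
    out["TMT IoTCT std"] = float(np.std(iotct, ddof=1))
    out["TMT IoTCT median"] = float(np.median(iotct))
    return out
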