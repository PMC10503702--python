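"""Brute-force reference implementations used to validate the fast paths."""

import numpy as np


def delta_oracle(xs, ys):
    """Cliff's delta by full pair enumeration."""
    gt = lt = 0
    for x in xs:
        for y in ys:
            gt += x > y
            lt += x < y
    return (gt - lt) / (len(xs) * len(ys))


def u_oracle(xs, ys):
    """Mann-Whitney U by full pair enumeration (ties count one half)."""
    u = 0.0
    for x in xs:
        for y in ys:
            u += (x > y) + 0.5 * (x == y)
    return u


def ks_oracle(xs, ys):
    """Two-sample KS statistic as the sup of the ECDF difference."""
    grid = np.unique(np.concatenate([xs, ys]))
    fx = np.searchsorted(np.sort(xs), grid, side="right") / len(xs)
    fy = np.searchsorted(np.sort(ys), grid, side="right") / len(ys)
    return np.max(np.abs(fx - fy))
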