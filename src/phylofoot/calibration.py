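"""Exact null distribution of PWM window scores and p-value thresholds.

Under the background model, the score of a random window is the sum of W
independent per-position log-odds terms.  Its exact distribution is obtained
by discretizing each column's four weights onto a fixed bin grid (default
0.01 bits) and convolving the per-column laws; the discretization error of a
window score is bounded by W * bin_width / 2.  From the survival function we
derive, per matrix m, the smallest score t_m whose background tail
probability does not exceed the target p-value (default 5e-5), which the
alignment scanner then uses as its calibrated cutoff.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import inf

import numpy as np

from .pwm import BackgroundModel, LogOddsMatrix, UNIFORM_BG

DEFAULT_BIN_WIDTH = 0.01
DEFAULT_PVALUE = 5e-5


def snap_weights(lom: LogOddsMatrix, bin_width: float) -> np.ndarray:
    """Integer bin index of every log-odds weight, rounded to nearest."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    return np.rint(lom.weights / bin_width).astype(np.int64)


@dataclass
class ScoreDistribution:
    """Discretized exact law of the background window score.

    ``support`` holds ascending bin centers (bits); ``mass`` the probability
    of each bin; ``survival[i] = P(SCORE >= support[i])``.
    """

    pwm_id: str
    bin_width: float
    support: np.ndarray
    mass: np.ndarray
    survival: np.ndarray
    support_bins: np.ndarray  # integer grid indices backing `support`

    def __post_init__(self):
        if abs(self.mass.sum() - 1.0) > 1e-9:
            raise ValueError("probability masses must sum to 1")
        if (np.diff(self.survival) > 1e-12).any():
            raise ValueError("survival function must be non-increasing")


@dataclass
class CalibratedThreshold:
    """Per-PWM score cutoff t_m at a target background p-value.

    ``attainable`` is False when even the maximum achievable score is more
    probable than the target (threshold +inf: no window can ever be called).
    """

    pwm_id: str
    threshold: float
    achieved_pvalue: float
    target_pvalue: float
    bin_width: float
    attainable: bool = True

    @property
    def threshold_bin(self) -> int:
        if not self.attainable:
            raise ValueError(f"{self.pwm_id}: no attainable threshold")
        return int(round(self.threshold / self.bin_width))


def _distribution_from_bins(pwm_id, bin_width, bins, masses) -> ScoreDistribution:
    order = np.argsort(bins)
    bins = np.asarray(bins)[order]
    masses = np.asarray(masses, dtype=float)[order]
    total = masses.sum()
    masses = masses / total  # guard drift from long convolutions
    survival = masses[::-1].cumsum()[::-1]
    return ScoreDistribution(
        pwm_id=pwm_id,
        bin_width=bin_width,
        support=bins * bin_width,
        mass=masses,
        survival=survival,
        support_bins=bins,
    )


def exact_score_distribution(
    lom: LogOddsMatrix,
    bg: BackgroundModel = UNIFORM_BG,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> ScoreDistribution:
    """Column-wise convolution of the snapped per-position score laws."""
    wbins = snap_weights(lom, bin_width)
    lo = int(wbins.min(axis=1).sum())
    hi = int(wbins.max(axis=1).sum())
    # dense probability vector over [cur_lo, cur_hi]
    probs = np.array([1.0])
    cur_lo = 0
    for w in range(lom.width):
        col_lo = int(wbins[w].min())
        col_hi = int(wbins[w].max())
        new = np.zeros(len(probs) + (col_hi - col_lo))
        for n in range(4):
            off = int(wbins[w, n]) - col_lo
            new[off:off + len(probs)] += probs * bg.probs[n]
        probs = new
        cur_lo += col_lo
    assert cur_lo == lo and cur_lo + len(probs) - 1 == hi
    nz = probs > 0
    bins = np.arange(lo, hi + 1)[nz]
    return _distribution_from_bins(lom.pwm_id, bin_width, bins, probs[nz])


def brute_force_score_distribution(
    lom: LogOddsMatrix,
    bg: BackgroundModel = UNIFORM_BG,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_width: int = 10,
) -> ScoreDistribution:
    """Exhaustive 4^W enumeration oracle for :func:`exact_score_distribution`.

    Refuses widths above ``max_width``; enumeration is exponential.
    """
    if lom.width > max_width:
        raise ValueError(
            f"brute force refuses width {lom.width} > {max_width}")
    wbins = snap_weights(lom, bin_width)
    acc: dict[int, float] = {}
    for window in itertools.product(range(4), repeat=lom.width):
        score = int(sum(wbins[w, n] for w, n in enumerate(window)))
        p = float(np.prod([bg.probs[n] for n in window]))
        acc[score] = acc.get(score, 0.0) + p
    bins = sorted(acc)
    return _distribution_from_bins(
        lom.pwm_id, bin_width, np.array(bins), [acc[b] for b in bins])


def threshold_for_pvalue(
    dist: ScoreDistribution, alpha: float = DEFAULT_PVALUE
) -> CalibratedThreshold:
    """Smallest support score whose survival probability is <= alpha."""
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    idx = np.nonzero(dist.survival <= alpha)[0]
    if len(idx) == 0:
        return CalibratedThreshold(
            pwm_id=dist.pwm_id, threshold=inf, achieved_pvalue=0.0,
            target_pvalue=alpha, bin_width=dist.bin_width, attainable=False)
    i = int(idx[0])
    return CalibratedThreshold(
        pwm_id=dist.pwm_id,
        threshold=float(dist.support[i]),
        achieved_pvalue=float(dist.survival[i]),
        target_pvalue=alpha,
        bin_width=dist.bin_width,
    )


def pvalue_of_score(dist: ScoreDistribution, s: float) -> float:
    """P(SCORE >= s) under the background, with s snapped down to the grid."""
    s_bin = int(np.floor(s / dist.bin_width + 1e-9))
    i = np.searchsorted(dist.support_bins, s_bin)
    if i >= len(dist.support_bins):
        return 0.0
    return float(dist.survival[i])


def calibrate_collection(
    loms,
    alpha: float = DEFAULT_PVALUE,
    bg: BackgroundModel = UNIFORM_BG,
    bin_width: float = DEFAULT_BIN_WIDTH,
) -> dict[str, CalibratedThreshold]:
    """Calibrate t_m for every matrix; keyed by pwm_id."""
    out = {}
    for lom in loms:
        dist = exact_score_distribution(lom, bg, bin_width)
        out[lom.pwm_id] = threshold_for_pvalue(dist, alpha)
    return out


def write_calibration_tsv(thresholds, widths, stream) -> None:
    """Export calibration as TSV: pwm_id, width, threshold_bits, achieved, target."""
    stream.write("pwm_id\twidth\tthreshold_bits\tachieved_pvalue\ttarget_pvalue\n")
    for pwm_id, thr in thresholds.items():
        t = "inf" if not thr.attainable else f"{thr.threshold:.6g}"
        stream.write(
            f"{pwm_id}\t{widths[pwm_id]}\t{t}\t"
            f"{thr.achieved_pvalue:.6g}\t{thr.target_pvalue:.6g}\n")
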