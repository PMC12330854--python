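"""Behavioural pipeline for the urge-to-blink task.

Urge ratings are down-sampled to 1 Hz and z-scored per run (Random seconds
and experimental Okay/Suppress seconds standardised separately); blink
occurrence is binarised per second.  The module then provides the
urge-blink logistic regression, peri-blink averaging with 5 s edge
exclusion, temporal-shape statistics (peak latency, skewness, kurtosis) with
normality-gated group tests, linear-vs-quadratic model comparison of the
peri-blink curve, and the per-condition block summary tests (one-tailed
paired t-test on urge, Wilcoxon signed-rank on blink rates).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .synthgen import OKAY, RANDOM, SUPPRESS, BlinkTrain, BlockSchedule, UrgeTrace

__all__ = [
    "StandardisedUrge",
    "PeriBlinkCurve",
    "TemporalStats",
    "LogisticResult",
    "CurvilinearResult",
    "BlockSummary",
    "NoRetainedBlinksError",
    "DegenerateInputError",
    "downsample_standardise",
    "binarize_blinks",
    "blink_urge_logistic",
    "periblink_average",
    "periblink_stats",
    "curvilinear_fit",
    "block_summary_tests",
]

LAGS = np.arange(-5, 6)  # seconds, 1 Hz


class DegenerateInputError(ValueError):
    """Raised when an input has no variance where variance is required."""


class NoRetainedBlinksError(ValueError):
    """Raised when the 5 s edge rules leave no blinks to average.

    Callers treat this as the participant-exclusion signal (the study
    excluded two subjects with no escape blinks).
    """


@dataclass(frozen=True)
class StandardisedUrge:
    """Urge z-scores at 1 Hz with their standardisation grouping.

    Standardisation groups are the Random seconds and the experimental
    (Okay + Suppress) seconds of one run, z-scored separately.
    """

    values: np.ndarray        # z per second
    condition: np.ndarray     # block label per second
    group: np.ndarray         # 'random' | 'experimental' per second

    @property
    def n_seconds(self) -> int:
        return len(self.values)

    def experimental_seconds(self):
        """(second-onset, z) pairs for the experimental period, in run time."""
        idx = np.flatnonzero(self.group == "experimental")
        return [(float(i), float(self.values[i])) for i in idx]


@dataclass(frozen=True)
class PeriBlinkCurve:
    """Mean urge z at lags -5..+5 s around retained blinks."""

    lags: np.ndarray
    values: np.ndarray
    n_blinks: int

    def __post_init__(self):
        if len(self.values) != 11:
            raise ValueError("peri-blink curve must have 11 samples")
        if self.n_blinks < 1:
            raise ValueError("peri-blink curve needs at least one blink")


@dataclass(frozen=True)
class StatTest:
    kind: str                 # 't' | 'wilcoxon'
    statistic: float
    df_or_n: int
    p: float


@dataclass(frozen=True)
class TemporalStats:
    peak_latency_s: np.ndarray     # per participant
    skewness: np.ndarray
    kurtosis: np.ndarray
    excess_kurtosis: np.ndarray
    tests: dict                    # name -> StatTest


@dataclass(frozen=True)
class LogisticResult:
    B: float
    ExpB: float
    wald: float
    wald_df: int
    model_chi2: float
    chi2_df: int
    cox_snell_r2: float
    n: int


@dataclass(frozen=True)
class PolyFit:
    intercept: float
    coefficients: np.ndarray   # (slope,) or (t, t^2)
    F: float
    df: tuple
    adj_r2: float
    quad_p: float | None = None


@dataclass(frozen=True)
class CurvilinearResult:
    linear: PolyFit
    quadratic: PolyFit
    chosen: str | None        # 'linear' | 'quadratic' | None


@dataclass(frozen=True)
class BlockSummary:
    urge_means: dict          # condition -> per-participant means (% scale)
    blink_rates: dict         # condition -> per-participant blinks/min
    urge_test: StatTest       # paired t, one-tailed Suppress > Okay
    blink_test: StatTest      # Wilcoxon, one-tailed Suppress < Okay


def downsample_standardise(urge: UrgeTrace) -> StandardisedUrge:
    """10 Hz -> 1 Hz by within-second mean, then per-group z-scoring.

    The Random seconds and the experimental seconds of the run are z-scored
    separately (mean subtraction, division by sd).  A zero-variance group
    raises :class:`DegenerateInputError` rather than propagating NaNs.
    """
    rate = urge.rate_hz
    per_sec = int(round(rate))
    if abs(rate - per_sec) > 1e-9 or per_sec < 1:
        raise ValueError(f"rate {rate} Hz does not bin evenly into 1 Hz")
    n_sec = len(urge.values) // per_sec
    vals = urge.values[: n_sec * per_sec].reshape(n_sec, per_sec).mean(axis=1)
    # label each second by the condition at its start
    cond = urge.condition[:: per_sec][:n_sec]
    group = np.where(cond == RANDOM, "random", "experimental")
    z = np.empty(n_sec)
    for g in ("random", "experimental"):
        sel = group == g
        if not sel.any():
            continue
        sd = vals[sel].std(ddof=0)
        if sd < 1e-12:
            raise DegenerateInputError(f"{g} urge samples have zero variance")
        z[sel] = (vals[sel] - vals[sel].mean()) / sd
    return StandardisedUrge(values=z, condition=cond, group=group)


def binarize_blinks(blinks: BlinkTrain, n_seconds: int) -> np.ndarray:
    """Per-second blink occurrence (1 if any onset in [s, s+1), else 0)."""
    if n_seconds < 1:
        raise ValueError("n_seconds must be >= 1")
    sec = np.floor(blinks.onsets_s).astype(int)
    if sec.size and sec.max() >= n_seconds:
        raise ValueError(
            f"blink onset at {blinks.onsets_s.max():.2f}s beyond {n_seconds}s"
        )
    out = np.zeros(n_seconds, int)
    out[sec] = 1
    return out


def blink_urge_logistic(urge_z: np.ndarray, blinks_binary: np.ndarray) -> LogisticResult:
    """Maximum-likelihood logistic regression of blink occurrence on urge z.

    Reports the slope B (log-odds per urge-z unit), Exp(B), its Wald
    statistic, the likelihood-ratio chi-square against the intercept-only
    model, and Cox & Snell R^2.  A single-class outcome or perfect
    separation raises :class:`DegenerateInputError`; no estimates are
    returned in that case.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    y = np.asarray(blinks_binary, float)
    x = np.asarray(urge_z, float)
    if y.shape != x.shape:
        raise ValueError("urge and blink vectors differ in length")
    if len(np.unique(y)) < 2:
        raise DegenerateInputError("blink outcome has a single class")
    X = sm.add_constant(x)
    try:
        with np.errstate(all="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=False)
    except (PerfectSeparationError, np.linalg.LinAlgError) as err:
        raise DegenerateInputError(f"logistic fit degenerate: {err}") from err
    if not fit.mle_retvals.get("converged", True) or not np.all(np.isfinite(fit.bse)):
        raise DegenerateInputError(
            "logistic fit degenerate (separation or non-convergence); no estimates"
        )
    b = float(fit.params[1])
    wald = float((fit.params[1] / fit.bse[1]) ** 2)
    chi2 = float(2 * (fit.llf - fit.llnull))
    n = len(y)
    return LogisticResult(
        B=b,
        ExpB=float(np.exp(b)),
        wald=wald,
        wald_df=1,
        model_chi2=chi2,
        chi2_df=1,
        cox_snell_r2=float(1.0 - np.exp(-chi2 / n)),
        n=n,
    )


def periblink_average(
    urge_z: StandardisedUrge,
    blinks: BlinkTrain,
    schedule: BlockSchedule,
    condition: str,
) -> PeriBlinkCurve:
    """Average 11-second urge windows centred on retained blinks.

    Blinks are retained when they fall in a block of ``condition`` at least
    5 s after its start and at least 5 s before its end (urge needs time to
    adjust after a transition, and the window must not straddle the next
    block).  Raises :class:`NoRetainedBlinksError` when nothing survives.
    """
    if condition not in (OKAY, SUPPRESS):
        raise ValueError(f"condition must be {OKAY!r} or {SUPPRESS!r}")
    windows = []
    n_sec = urge_z.n_seconds
    for onset in blinks.onsets_s:
        block = next(
            (b for b in schedule.blocks_of(condition) if b.onset_s <= onset < b.end_s),
            None,
        )
        if block is None:
            continue
        if onset - block.onset_s < 5 or block.end_s - onset <= 5:
            continue
        s = int(onset)  # second containing the blink
        if s - 5 < 0 or s + 5 >= n_sec:
            continue
        windows.append(urge_z.values[s - 5 : s + 6])
    if not windows:
        raise NoRetainedBlinksError(f"no retained blinks in condition {condition!r}")
    return PeriBlinkCurve(
        lags=LAGS.astype(float),
        values=np.mean(windows, axis=0),
        n_blinks=len(windows),
    )


def curve_shape(curve: PeriBlinkCurve, shift: str = "min"):
    """Peak latency, skewness and kurtosis of one peri-blink curve.

    The curve is treated as a weight distribution over the lags; because
    urge z-scores can be negative the curve is first shifted to be
    non-negative (by its minimum by default).  The peak latency is the lag
    of the curve maximum, ties resolving to the earliest lag.
    """
    v = curve.values
    peak = float(curve.lags[int(np.argmax(v))])
    w = v - v.min() if shift == "min" else v
    total = w.sum()
    if total <= 0:
        return peak, 0.0, 0.0
    p = w / total
    mu = float(p @ curve.lags)
    var = float(p @ (curve.lags - mu) ** 2)
    if var <= 0:
        return peak, 0.0, 0.0
    skew = float(p @ (curve.lags - mu) ** 3) / var ** 1.5
    kurt = float(p @ (curve.lags - mu) ** 4) / var ** 2
    return peak, skew, kurt


def _one_sample_test(values: np.ndarray, popmean: float, alpha: float = 0.05) -> StatTest:
    """Two-tailed one-sample test, t unless Shapiro-Wilk rejects normality."""
    values = np.asarray(values, float)
    diffs = values - popmean
    normal = True
    if len(values) >= 3 and np.ptp(values) > 0:
        normal = stats.shapiro(values).pvalue > alpha
    if normal:
        res = stats.ttest_1samp(values, popmean)
        return StatTest("t", float(res.statistic), len(values) - 1, float(res.pvalue))
    if np.all(diffs == 0):
        return StatTest("wilcoxon", 0.0, len(values), 1.0)
    res = stats.wilcoxon(diffs)
    return StatTest("wilcoxon", float(res.statistic), len(values), float(res.pvalue))


def periblink_stats(curves, shift: str = "min") -> TemporalStats:
    """Group temporal-shape statistics over per-participant peri-blink curves.

    Peak latency is tested against 0 s, skewness against 0, and kurtosis
    against 3 (the normal value); excess kurtosis (kurtosis - 3) is reported
    alongside.  Each test is a two-tailed one-sample t-test, replaced by a
    Wilcoxon signed-rank test when Shapiro-Wilk rejects normality at 0.05.
    """
    if len(curves) < 3:
        raise ValueError("need at least 3 participants")
    shape = np.array([curve_shape(c, shift) for c in curves])
    lat, skew, kurt = shape.T
    tests = {
        "peak_latency": _one_sample_test(lat, 0.0),
        "skewness": _one_sample_test(skew, 0.0),
        "kurtosis": _one_sample_test(kurt, 3.0),
    }
    return TemporalStats(
        peak_latency_s=lat,
        skewness=skew,
        kurtosis=kurt,
        excess_kurtosis=kurt - 3.0,
        tests=tests,
    )


def _poly_ols(t: np.ndarray, y: np.ndarray, degree: int) -> PolyFit:
    X = np.column_stack([t ** d for d in range(degree + 1)])
    n, p = X.shape
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    rss = float(((y - fitted) ** 2).sum())
    tss = float(((y - y.mean()) ** 2).sum())
    df_model, df_resid = p - 1, n - p
    if np.ptp(y) < 1e-12:
        tss = 0.0  # constant input: report degenerate zero-variance fits
    if tss <= 0:
        return PolyFit(float(beta[0]), beta[1:], 0.0, (df_model, df_resid), 0.0,
                       quad_p=1.0 if degree == 2 else None)
    r2 = 1 - rss / tss
    F = (tss - rss) / df_model / (rss / df_resid) if rss > 0 else np.inf
    adj = 1 - (1 - r2) * (n - 1) / df_resid
    quad_p = None
    if degree == 2:
        mse = rss / df_resid
        cov = mse * np.linalg.inv(X.T @ X)
        se = np.sqrt(cov[2, 2])
        tval = beta[2] / se if se > 0 else np.inf
        quad_p = float(2 * stats.t.sf(abs(tval), df_resid))
    return PolyFit(float(beta[0]), beta[1:], float(F), (df_model, df_resid),
                   float(adj), quad_p)


def curvilinear_fit(curve: PeriBlinkCurve, alpha: float = 0.05) -> CurvilinearResult:
    """Linear and quadratic least-squares fits of mean urge z on lag.

    The quadratic model is chosen when its squared-term coefficient is
    significant at ``alpha`` *and* its overall F statistic exceeds the linear
    model's (a higher adjusted R^2 alone with a lower F and a non-significant
    squared term keeps the linear model); otherwise the linear model is
    chosen.  A constant curve yields both fits with R^2 = 0 and no chosen
    model.
    """
    t, y = curve.lags, curve.values
    lin = _poly_ols(t, y, 1)
    quad = _poly_ols(t, y, 2)
    if np.ptp(y) < 1e-12:
        chosen = None
    elif quad.quad_p is not None and quad.quad_p <= alpha and quad.F > lin.F:
        chosen = "quadratic"
    else:
        chosen = "linear"
    return CurvilinearResult(linear=lin, quadratic=quad, chosen=chosen)


def block_summary_tests(participants) -> BlockSummary:
    """Per-condition urge means and blink rates with directional group tests.

    ``participants`` is a sequence of ``(urge, blinks, schedule)`` triples
    (one per participant; multi-run participants should pass concatenated
    traces or a representative run).  Urge means are on the raw 0-100 scale;
    blink rates are blinks per minute within the condition blocks.  The urge
    difference uses a paired t-test, one-tailed in the direction
    Suppress > Okay; the blink difference uses a Wilcoxon signed-rank test,
    one-tailed in the direction Suppress < Okay.
    """
    if len(participants) < 2:
        raise ValueError("need at least 2 participants for group tests")
    urge_means = {OKAY: [], SUPPRESS: []}
    blink_rates = {OKAY: [], SUPPRESS: []}
    for urge, blinks, schedule in participants:
        times = urge.times_s
        for cond in (OKAY, SUPPRESS):
            blocks = schedule.blocks_of(cond)
            if not blocks:
                raise ValueError(f"schedule missing condition {cond!r}")
            sel = np.zeros(len(times), bool)
            minutes = 0.0
            nblinks = 0
            for b in blocks:
                sel |= (times >= b.onset_s) & (times < b.end_s)
                minutes += b.duration_s / 60.0
                nblinks += int(
                    np.sum((blinks.onsets_s >= b.onset_s) & (blinks.onsets_s < b.end_s))
                )
            urge_means[cond].append(float(urge.values[sel].mean()))
            blink_rates[cond].append(nblinks / minutes)
    u_ok, u_sup = np.array(urge_means[OKAY]), np.array(urge_means[SUPPRESS])
    b_ok, b_sup = np.array(blink_rates[OKAY]), np.array(blink_rates[SUPPRESS])
    if np.all(u_sup - u_ok == 0):
        urge_test = StatTest("t", 0.0, len(u_ok) - 1, 0.5)
    else:
        t_res = stats.ttest_rel(u_sup, u_ok, alternative="greater")
        urge_test = StatTest("t", float(t_res.statistic), len(u_ok) - 1, float(t_res.pvalue))
    diffs = b_sup - b_ok
    if np.all(diffs == 0):
        blink_test = StatTest("wilcoxon", 0.0, len(diffs), 0.5)
    else:
        w_res = stats.wilcoxon(b_sup, b_ok, alternative="less")
        blink_test = StatTest("wilcoxon", float(w_res.statistic), len(diffs), float(w_res.pvalue))
    return BlockSummary(
        urge_means={k: np.array(v) for k, v in urge_means.items()},
        blink_rates={k: np.array(v) for k, v in blink_rates.items()},
        urge_test=urge_test,
        blink_test=blink_test,
    )
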