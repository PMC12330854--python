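"""Synthetic behavioural traces and multi-echo fMRI phantoms.

The generator reproduces the statistical structure the analysis assumes: a
420 s blink-suppression run (30 s "Random" pads around three alternating
pairs of 60 s "Okay to blink" / "Suppress" blocks), a continuous 0-100
urge-to-blink rating at 10 Hz that rises during suppression and drops after
each blink, blink trains that are much sparser under suppression, and sparse
``dR2*`` events in labelled ROIs expressed across echoes through the
linear-TE BOLD model (TR = 1800 ms, TEs = 12/35/58 ms by default).

Ground truth (event onsets/amplitudes, ROI labels, the pre-clipping urge
trace) is kept alongside every simulated object so recovery tests can score
the pipeline against what was planted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hemo import HRFModel, build_convolution_operator, canonical_hrf

__all__ = [
    "Block",
    "BlockSchedule",
    "UrgeTrace",
    "BlinkTrain",
    "GroundTruth",
    "MultiEchoSeries",
    "UrgeBlinkParams",
    "make_block_schedule",
    "simulate_urge_and_blinks",
    "make_ground_truth",
    "simulate_multiecho_run",
]

RANDOM, OKAY, SUPPRESS = "Random", "Okay", "Suppress"


@dataclass(frozen=True)
class Block:
    label: str
    onset_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.onset_s + self.duration_s


@dataclass(frozen=True)
class BlockSchedule:
    """Contiguous, non-overlapping condition blocks covering the run."""

    blocks: tuple
    run_length_s: float

    def __post_init__(self):
        t = 0.0
        for b in self.blocks:
            if abs(b.onset_s - t) > 1e-9:
                raise ValueError("blocks must be contiguous and non-overlapping")
            t = b.end_s
        if abs(t - self.run_length_s) > 1e-9:
            raise ValueError("blocks do not cover the run length")

    def condition_at(self, t: float) -> str:
        for b in self.blocks:
            if b.onset_s <= t < b.end_s:
                return b.label
        if t == self.run_length_s:
            return self.blocks[-1].label
        raise ValueError(f"time {t} outside run")

    def condition_labels(self, times) -> np.ndarray:
        edges = [b.onset_s for b in self.blocks] + [self.run_length_s]
        idx = np.searchsorted(edges, np.asarray(times, float), side="right") - 1
        idx = idx.clip(0, len(self.blocks) - 1)
        return np.array([self.blocks[i].label for i in idx])

    def experimental_interval(self) -> tuple:
        """(start, end) in seconds of the non-Random (Okay/Suppress) segment."""
        exp = [b for b in self.blocks if b.label != RANDOM]
        return exp[0].onset_s, exp[-1].end_s

    def blocks_of(self, label: str):
        return [b for b in self.blocks if b.label == label]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(
                onset=[b.onset_s for b in self.blocks],
                duration=[b.duration_s for b in self.blocks],
                trial_type=[b.label for b in self.blocks],
            )
        )


@dataclass(frozen=True)
class UrgeTrace:
    """Continuous urge-to-blink rating in [0, 100].

    ``latent`` is the pre-clipping trace the generator produced; planted
    peri-blink-template oracles are exact on it.
    """

    rate_hz: float
    values: np.ndarray
    condition: np.ndarray
    latent: np.ndarray | None = None

    def __post_init__(self):
        if self.values.min() < 0 or self.values.max() > 100:
            raise ValueError("urge values must lie in [0, 100]")
        if len(self.values) != len(self.condition):
            raise ValueError("values and condition labels differ in length")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(len(self.values)) / self.rate_hz

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time_s=self.times_s, urge=self.values, condition=self.condition)
        )


@dataclass(frozen=True)
class BlinkTrain:
    """Blink events as sorted onsets (s) with durations (s)."""

    onsets_s: np.ndarray
    durations_s: np.ndarray
    run_length_s: float

    def __post_init__(self):
        o = self.onsets_s
        if np.any(np.diff(o) < 0):
            raise ValueError("blink onsets must be sorted")
        if o.size and (o[0] < 0 or o[-1] > self.run_length_s):
            raise ValueError("blink onsets outside run")
        if np.any(self.durations_s < 0):
            raise ValueError("negative blink duration")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(onset=self.onsets_s, duration=self.durations_s, trial_type="blink")
        )


@dataclass(frozen=True)
class GroundTruth:
    """Planted events per ROI plus the nuisance parameters used."""

    roi_labels: np.ndarray              # 3D int volume; 0 = background
    event_onsets: dict                  # roi id -> TR indices (array)
    event_amplitudes: dict              # roi id -> dR2* per event (s^-1)
    noise_sd_pct: float                 # white noise sd, percent-signal units
    drift_coefficients: np.ndarray      # Legendre coefficients (percent units)

    def __post_init__(self):
        for r, amps in self.event_amplitudes.items():
            if not np.all(np.isfinite(amps)):
                raise ValueError(f"non-finite amplitude in ROI {r}")

    @property
    def roi_ids(self):
        return sorted(self.event_onsets)


@dataclass(frozen=True)
class MultiEchoSeries:
    """Per-echo 4D volumes sharing one grid, with TR/TE metadata."""

    echoes: tuple                       # of 4D arrays (X, Y, Z, T)
    tes_ms: tuple
    tr_ms: float
    mean_image: np.ndarray
    brain_mask: np.ndarray
    truth: GroundTruth | None = None

    def __post_init__(self):
        if len(self.echoes) < 2:
            raise ValueError("need at least 2 echoes")
        shapes = {e.shape for e in self.echoes}
        if len(shapes) != 1:
            raise ValueError("echoes must share grid and timepoint count")
        if np.any(np.diff(self.tes_ms) <= 0):
            raise ValueError("TEs must be strictly increasing")

    @property
    def n_timepoints(self) -> int:
        return self.echoes[0].shape[-1]

    @property
    def grid(self) -> tuple:
        return self.echoes[0].shape[:-1]

    def volume_times_s(self) -> np.ndarray:
        return np.arange(self.n_timepoints) * self.tr_ms / 1000.0


def make_block_schedule(
    start_with_suppress: bool = False,
    run_length_s: float = 420.0,
    pad_s: float = 30.0,
    block_s: float = 60.0,
) -> BlockSchedule:
    """Standard run template: Random pads around 3 alternating Okay/Suppress pairs.

    The order of the experimental conditions is set by ``start_with_suppress``
    (half the study's runs started with suppression).
    """
    if abs(run_length_s - (2 * pad_s + 6 * block_s)) > 1e-9:
        raise ValueError(
            f"run_length {run_length_s}s inconsistent with 2x{pad_s}s pads + 6x{block_s}s blocks"
        )
    first, second = (SUPPRESS, OKAY) if start_with_suppress else (OKAY, SUPPRESS)
    blocks = [Block(RANDOM, 0.0, pad_s)]
    t = pad_s
    for _ in range(3):
        for lab in (first, second):
            blocks.append(Block(lab, t, block_s))
            t += block_s
    blocks.append(Block(RANDOM, t, pad_s))
    return BlockSchedule(blocks=tuple(blocks), run_length_s=run_length_s)


@dataclass(frozen=True)
class UrgeBlinkParams:
    """Shape parameters of the behavioural generator.

    Defaults target the observed per-condition blink rates (~31/min free
    blinking, ~5/min suppression) and urge means (~23% vs ~56%).
    """

    rate_hz: float = 10.0
    blink_rate_okay_per_min: float = 31.2
    blink_rate_suppress_per_min: float = 5.1
    urge_growth_per_s: float = 6.5       # urge rise rate under Suppress (%/s)
    urge_cap: float = 92.0               # soft ceiling of the suppression rise
    escape_threshold: float = 30.0       # escape blinks need urge above this
    escape_scale: float = 24.0           # hazard doubles this far above threshold
    post_blink_reset: float = 18.0       # urge relief after an escape blink (%)
    post_blink_reset_okay: float = 3.0   # mild relief after a free blink (%)
    relief_delay_s: float = 0.7          # urge keeps rising briefly after the blink
    relief_duration_s: float = 3.5       # relief spread over this long, not a step
    okay_baseline: float = 24.0          # mean urge level when blinking is free (%)
    random_baseline: float = 8.0
    okay_relax_per_s: float = 0.5        # pull toward baseline under Okay/Random
    urge_rate_coupling: float = 0.02     # blink-rate modulation per urge unit (Okay)
    noise_sd: float = 2.0                # white measurement noise (% units)
    blink_duration_s: float = 0.2
    refractory_s: float = 0.3

    def validate(self):
        for name in (
            "rate_hz",
            "blink_rate_okay_per_min",
            "blink_rate_suppress_per_min",
            "urge_growth_per_s",
            "post_blink_reset",
            "noise_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"parameter {name} must be non-negative")


def simulate_urge_and_blinks(
    schedule: BlockSchedule,
    params: UrgeBlinkParams | None = None,
    seed: int | None = 0,
) -> tuple:
    """Coupled urge trace and blink train for one run.

    Urge dynamics: under Suppress the latent urge rises toward a soft ceiling
    and, after each (escape) blink, keeps rising for ``relief_delay_s`` before
    relief spreads the ``post_blink_reset`` drop over ``relief_duration_s`` —
    so the latent peri-blink template peaks at the blink (lag 0 at 1 Hz
    resolution; the observed group curve peaked at/just after blink onset).
    Under Okay/Random the urge relaxes toward a baseline with only mild
    post-blink relief, giving a flat-to-linear peri-blink shape.  Blinks are
    drawn per 0.1 s bin from an inhomogeneous Bernoulli process whose rate
    follows the current urge (escape blinks cluster at high urge) and is far
    lower under Suppress.  Reported urge adds white noise and clips to
    [0, 100]; the pre-clipping latent trace is kept on the returned
    :class:`UrgeTrace`.
    """
    params = params or UrgeBlinkParams()
    params.validate()
    rng = np.random.default_rng(seed)
    dt = 1.0 / params.rate_hz
    n = int(round(schedule.run_length_s * params.rate_hz))
    times = np.arange(n) * dt
    condition = schedule.condition_labels(times)

    latent = np.empty(n)
    onsets = []
    u = params.random_baseline
    last_blink = -np.inf
    reliefs = []  # (start_s, end_s, drop_per_s) scheduled urge releases
    def hazard(rate_per_min: float) -> float:
        # Bernoulli hazard corrected for the refractory dead time so the
        # realised rate matches the nominal one
        lam = rate_per_min / 60.0
        return lam / max(1.0 - lam * params.refractory_s, 1e-6) * dt

    for i, (t, cond) in enumerate(zip(times, condition)):
        relieving = any(start <= t < end for start, end, _ in reliefs)
        if cond == SUPPRESS:
            if not relieving:  # growth pauses while relief is under way
                u += params.urge_growth_per_s * (1.0 - u / params.urge_cap) * dt
            # escape blinks need high urge; threshold coupling keeps the
            # peri-blink windows clear of immediately preceding blinks
            p = (
                hazard(params.blink_rate_suppress_per_min)
                * max(u - params.escape_threshold, 0.0)
                / params.escape_scale
            )
            reset = params.post_blink_reset
        elif cond == OKAY:
            target = params.okay_baseline
            u += params.okay_relax_per_s * (target - u) * dt
            p = hazard(params.blink_rate_okay_per_min) * (
                1.0 + params.urge_rate_coupling * (u - target)
            )
            reset = params.post_blink_reset_okay
        else:  # Random pad: no rated task demand, occasional natural blinks
            u += params.okay_relax_per_s * (params.random_baseline - u) * dt
            p = hazard(params.blink_rate_okay_per_min)
            reset = params.post_blink_reset_okay
        for start, end, rate in reliefs:
            if start <= t < end:
                u = max(u - rate * dt, 0.0)
        reliefs = [r for r in reliefs if r[1] > t]
        latent[i] = u
        if t - last_blink >= params.refractory_s and rng.random() < max(p, 0.0):
            onsets.append(t)
            last_blink = t
            reliefs.append(
                (
                    t + params.relief_delay_s,
                    t + params.relief_delay_s + params.relief_duration_s,
                    reset / params.relief_duration_s,
                )
            )

    noisy = latent + (rng.normal(0.0, params.noise_sd, n) if params.noise_sd > 0 else 0.0)
    values = np.clip(noisy, 0.0, 100.0)
    onsets = np.asarray(onsets, float)
    urge = UrgeTrace(rate_hz=params.rate_hz, values=values, condition=condition, latent=latent)
    blinks = BlinkTrain(
        onsets_s=onsets,
        durations_s=np.full(onsets.shape, params.blink_duration_s),
        run_length_s=schedule.run_length_s,
    )
    return urge, blinks


def _cuboid_rois(grid: tuple, n_rois: int, rng: np.random.Generator, roi_size=(4, 4, 3)) -> np.ndarray:
    """Non-overlapping cuboid ROIs labelled 1..n_rois on the grid."""
    labels = np.zeros(grid, int)
    occupied = np.zeros(grid, bool)
    placed = 0
    attempts = 0
    while placed < n_rois:
        attempts += 1
        if attempts > 1000:
            raise RuntimeError("could not place non-overlapping ROIs; shrink roi_size")
        corner = [rng.integers(0, g - s + 1) for g, s in zip(grid, roi_size)]
        sl = tuple(slice(c, c + s) for c, s in zip(corner, roi_size))
        if occupied[sl].any():
            continue
        placed += 1
        labels[sl] = placed
        occupied[sl] = True
    return labels


def make_ground_truth(
    grid: tuple = (20, 20, 10),
    n_rois: int = 3,
    events_per_roi: int = 2,
    amplitude: float = -0.3,
    noise_sd_pct: float = 0.0,
    drift_amp_pct: float = 0.0,
    n_timepoints: int = 233,
    event_window: tuple | None = None,
    min_separation: int = 12,
    seed: int | None = 0,
    roi_size=(4, 4, 3),
) -> GroundTruth:
    """Plant sparse negative-``dR2*`` (positive-BOLD) events in cuboid ROIs.

    ``event_window`` restricts onsets to a TR-index range (defaults to the
    interior of the run, away from the edges of the experimental segment);
    events within an ROI are at least ``min_separation`` TRs apart.
    """
    rng = np.random.default_rng(seed)
    labels = _cuboid_rois(grid, n_rois, rng, roi_size)
    lo, hi = event_window or (25, n_timepoints - 25)
    onsets, amps = {}, {}
    for r in range(1, n_rois + 1):
        chosen = []
        candidates = rng.permutation(np.arange(lo, hi))
        for c in candidates:
            if all(abs(c - x) >= min_separation for x in chosen):
                chosen.append(int(c))
            if len(chosen) == events_per_roi:
                break
        if len(chosen) < events_per_roi:
            raise ValueError("event window too small for requested events/separation")
        onsets[r] = np.sort(np.asarray(chosen))
        amps[r] = np.full(events_per_roi, amplitude)
    order = rng.integers(1, 4)  # low-order polynomial drift
    drift = rng.normal(0.0, drift_amp_pct, order + 1) if drift_amp_pct > 0 else np.zeros(1)
    return GroundTruth(
        roi_labels=labels,
        event_onsets=onsets,
        event_amplitudes=amps,
        noise_sd_pct=noise_sd_pct,
        drift_coefficients=drift,
    )


def simulate_multiecho_run(
    schedule: BlockSchedule,
    truth: GroundTruth,
    hrf: HRFModel | None = None,
    grid: tuple | None = None,
    tes_ms=(12.0, 35.0, 58.0),
    tr_ms: float = 1800.0,
    seed: int | None = 0,
    baseline: float = 1000.0,
    ar1_rho: float = 0.0,
) -> MultiEchoSeries:
    """Forward-simulate a multi-echo run from planted ``dR2*`` events.

    For echo ``k`` the noiseless fractional signal change is
    ``-TE_k[s] * (HRF (*) dR2*-train)``; the stored signal is
    ``mean_image * (1 + change + drift + noise)`` with drift and white (or
    optionally AR(1)) Gaussian noise expressed in percent-signal units.
    """
    tes = np.asarray(tes_ms, float)
    if np.any(tes < 1.0):
        raise ValueError(f"TEs look like seconds ({tes.tolist()}); pass milliseconds")
    if tr_ms < 10.0:
        raise ValueError(f"TR looks like seconds ({tr_ms}); pass milliseconds")
    if grid is None:
        grid = truth.roi_labels.shape
    if truth.roi_labels.shape != grid:
        raise ValueError("ROI label volume does not match grid")
    rng = np.random.default_rng(seed)
    hrf = hrf or canonical_hrf(tr_ms)
    T = int(round(schedule.run_length_s * 1000.0 / tr_ms))
    H = build_convolution_operator(hrf, T).matrix

    # per-ROI convolved dR2* response, shared by all voxels of the ROI
    conv = {}
    for r in truth.roi_ids:
        train = np.zeros(T)
        np.add.at(train, truth.event_onsets[r], truth.event_amplitudes[r])
        conv[r] = H @ train

    labels = truth.roi_labels.reshape(-1)
    nvox = labels.size
    mean_image = np.full(grid, baseline)
    brain_mask = np.ones(grid, bool)

    drift = np.zeros(T)
    if np.any(truth.drift_coefficients):
        x = np.linspace(-1.0, 1.0, T)
        drift = np.polynomial.legendre.legval(x, truth.drift_coefficients)

    echoes = []
    for te in tes:
        frac = np.zeros((nvox, T))
        for r in truth.roi_ids:
            frac[labels == r] = -(te / 1000.0) * conv[r]
        pct = 100.0 * frac + drift[None, :]
        if truth.noise_sd_pct > 0:
            noise = rng.normal(0.0, truth.noise_sd_pct, (nvox, T))
            if ar1_rho:
                for t in range(1, T):
                    noise[:, t] += ar1_rho * noise[:, t - 1]
            pct = pct + noise
        echoes.append((baseline * (1.0 + pct / 100.0)).reshape(grid + (T,)))

    return MultiEchoSeries(
        echoes=tuple(echoes),
        tes_ms=tuple(tes.tolist()),
        tr_ms=float(tr_ms),
        mean_image=mean_image,
        brain_mask=brain_mask,
        truth=truth,
    )
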