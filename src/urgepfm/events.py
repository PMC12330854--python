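"""Post-deconvolution event detection.

The deconvolved ``dR2*`` maps are cleaned with a spatiotemporal rule (a
3-point temporal maximum-absolute filter followed by per-volume removal of
connected components smaller than 10 voxels), summarised as an activation
timeseries (ATS: the number of voxels with a negative coefficient per
timepoint), and thresholded against a surrogate run in which the volume
order of the raw data was randomly permuted before any analysis.  Peaks of
the ROI-restricted ATS that rise strictly above the median of the surrogate
ATS are selected as events, each carrying the 3D activation map at its
timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .hemo import HRFModel
from .mespfm import DeconvolutionResult, deconvolve_run
from .synthgen import BlockSchedule, MultiEchoSeries

__all__ = [
    "ATSeries",
    "SurrogateResult",
    "EventSet",
    "temporal_max_filter",
    "spatial_cluster_mask",
    "compute_ats",
    "surrogate_threshold",
    "select_roi_peaks",
    "trim_to_experimental",
    "clean_and_count",
    "detect_events",
]

_STRUCTURES = {6: 1, 18: 2, 26: 3}


@dataclass
class ATSeries:
    """Per-timepoint counts of positive-BOLD (negative-coefficient) voxels."""

    counts: np.ndarray
    threshold: float | None = None
    peaks: np.ndarray | None = None


@dataclass
class SurrogateResult:
    """Null run: one volume-order permutation pushed through the pipeline."""

    permutation: np.ndarray
    seed: int | None
    ats: ATSeries
    threshold: float
    masked_decon: np.ndarray  # cleaned surrogate estimates (grid + (T,))


@dataclass
class EventSet:
    """Selected ATS peaks with their 3D activation maps."""

    timepoints: np.ndarray           # indices into the trimmed series
    maps: np.ndarray                 # (n_events,) + grid of dR2* estimates
    roi_mask: np.ndarray
    ats: ATSeries
    metadata: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.timepoints)


def temporal_max_filter(values: np.ndarray, window: int = 3) -> np.ndarray:
    """Replace each sample by the largest-|.| value in its temporal window.

    The sign of the dominating value is retained; windows at the run
    boundaries are truncated.  Operates on the last axis.
    """
    if window % 2 == 0 or window < 1:
        raise ValueError(f"window must be odd and positive, got {window}")
    values = np.asarray(values, float)
    T = values.shape[-1]
    half = window // 2
    flat = values.reshape(-1, T)
    best = flat.copy()
    best_abs = np.abs(flat)
    for off in range(-half, half + 1):
        if off == 0:
            continue
        shifted = np.zeros_like(flat)
        if off > 0:
            shifted[:, off:] = flat[:, :-off]
        else:
            shifted[:, :off] = flat[:, -off:]
        cand_abs = np.abs(shifted)
        take = cand_abs > best_abs
        best[take] = shifted[take]
        best_abs[take] = cand_abs[take]
    return best.reshape(values.shape)


def spatial_cluster_mask(
    filtered: np.ndarray,
    original: np.ndarray,
    min_size: int = 10,
    connectivity: int = 6,
):
    """Drop small connected components per volume; mask the original data.

    ``filtered`` (grid + (T,)) defines the nonzero pattern to cluster; the
    surviving spatiotemporal mask is applied to ``original`` (the unfiltered
    estimates).  Returns ``(mask, masked_original)``.
    """
    if min_size < 1:
        raise ValueError("min_size must be >= 1")
    if connectivity not in _STRUCTURES:
        raise ValueError(f"connectivity must be one of {sorted(_STRUCTURES)}")
    structure = ndimage.generate_binary_structure(3, _STRUCTURES[connectivity])
    filtered = np.asarray(filtered)
    T = filtered.shape[-1]
    mask = np.zeros(filtered.shape, bool)
    for t in range(T):
        vol = filtered[..., t] != 0
        if not vol.any():
            continue
        lab, nlab = ndimage.label(vol, structure=structure)
        if nlab == 0:
            continue
        sizes = np.bincount(lab.reshape(-1))
        keep = np.flatnonzero(sizes >= min_size)
        keep = keep[keep > 0]
        if keep.size:
            mask[..., t] = np.isin(lab, keep)
    return mask, np.where(mask, original, 0.0)


def compute_ats(masked_decon: np.ndarray, roi_mask: np.ndarray | None = None) -> ATSeries:
    """Count voxels with negative deconvolved coefficient per timepoint."""
    values = np.asarray(masked_decon)
    if roi_mask is not None:
        values = values[np.asarray(roi_mask, bool)]
    T = values.shape[-1]
    counts = (values.reshape(-1, T) < 0).sum(axis=0)
    return ATSeries(counts=counts.astype(int))


def trim_to_experimental(series: MultiEchoSeries, schedule: BlockSchedule):
    """Drop the Random pads: keep volumes acquired in the Okay/Suppress segment.

    Returns ``(trimmed_series, volume_indices)`` where indices refer to the
    original run.
    """
    start, end = schedule.experimental_interval()
    times = series.volume_times_s()
    keep = np.flatnonzero((times >= start) & (times < end))
    from dataclasses import replace

    trimmed = replace(series, echoes=tuple(e[..., keep] for e in series.echoes))
    return trimmed, keep


def clean_and_count(
    decon: DeconvolutionResult,
    window: int = 3,
    min_size: int = 10,
    connectivity: int = 6,
):
    """Temporal max filter -> small-cluster removal -> ATS.

    Returns ``(masked_decon, ats)``.
    """
    filtered = temporal_max_filter(decon.estimates, window=window)
    _, masked = spatial_cluster_mask(
        filtered, decon.estimates, min_size=min_size, connectivity=connectivity
    )
    return masked, compute_ats(masked)


def surrogate_threshold(
    series: MultiEchoSeries,
    mask: np.ndarray | None = None,
    hrf: HRFModel | None = None,
    seed: int | None = 0,
    median_over: str = "all",
    **pipeline_kwargs,
) -> SurrogateResult:
    """Null distribution: permute volume order, rerun the whole pipeline.

    ``series`` must already be trimmed to the experimental segment.  One
    volume-order permutation (shared across voxels and echoes) is applied to
    the raw data before percent-change conversion; the permuted run is then
    deconvolved, filtered, clustered and counted exactly like the original.
    The detection threshold is the median of the surrogate ATS counts — over
    all timepoints by default (``median_over='nonzero'`` restricts to nonzero
    counts).
    """
    from dataclasses import replace

    rng = np.random.default_rng(seed)
    perm = rng.permutation(series.n_timepoints)
    shuffled = replace(series, echoes=tuple(e[..., perm] for e in series.echoes))
    decon = deconvolve_run(shuffled, mask=mask, hrf=hrf, **pipeline_kwargs)
    masked, ats = clean_and_count(decon)
    counts = ats.counts if median_over == "all" else ats.counts[ats.counts > 0]
    threshold = float(np.median(counts)) if counts.size else 0.0
    ats.threshold = threshold
    return SurrogateResult(
        permutation=perm, seed=seed, ats=ats, threshold=threshold, masked_decon=masked
    )


def _segment_peaks(counts: np.ndarray, threshold: float) -> list:
    """One peak per maximal supra-threshold segment.

    The peak is the segment's maximum; a plateau of tied maxima resolves to
    its midpoint (the earlier sample for even plateau length).
    """
    above = counts > threshold
    peaks = []
    t = 0
    T = len(counts)
    while t < T:
        if not above[t]:
            t += 1
            continue
        start = t
        while t < T and above[t]:
            t += 1
        seg = counts[start:t]
        top = np.flatnonzero(seg == seg.max())
        peaks.append(start + int(top[(len(top) - 1) // 2]))
    return peaks


def select_roi_peaks(
    masked_decon: np.ndarray,
    roi_mask: np.ndarray,
    surrogate: SurrogateResult,
    median_over: str = "all",
) -> EventSet:
    """Events: ROI-ATS peaks strictly above the ROI surrogate median.

    The ATS of both the original and the surrogate run are restricted to the
    ROI; the threshold is the median of the ROI-restricted surrogate counts,
    and candidate peaks are the per-segment maxima of the original ROI counts
    strictly above it.  An empty result is valid (not every run shows
    supra-threshold ROI activity); an empty ROI is an error.
    """
    roi_mask = np.asarray(roi_mask, bool)
    if not roi_mask.any():
        raise ValueError("ROI mask is empty")
    ats = compute_ats(masked_decon, roi_mask)
    surr_counts = compute_ats(surrogate.masked_decon, roi_mask).counts
    pool = surr_counts if median_over == "all" else surr_counts[surr_counts > 0]
    threshold = float(np.median(pool)) if pool.size else 0.0
    ats.threshold = threshold
    peaks = np.asarray(_segment_peaks(ats.counts, threshold), int)
    ats.peaks = peaks
    maps = np.stack([masked_decon[..., t] for t in peaks]) if peaks.size else np.empty(
        (0,) + masked_decon.shape[:-1]
    )
    return EventSet(
        timepoints=peaks,
        maps=maps,
        roi_mask=roi_mask,
        ats=ats,
        metadata=dict(threshold=threshold, surrogate_seed=surrogate.seed),
    )


def detect_events(
    series: MultiEchoSeries,
    schedule: BlockSchedule,
    roi_mask: np.ndarray,
    mask: np.ndarray | None = None,
    hrf: HRFModel | None = None,
    seed: int | None = 0,
    **pipeline_kwargs,
):
    """Full detection pipeline for one run.

    Trims the Random pads, deconvolves the original and one surrogate
    permutation of the trimmed raw data, cleans both, and selects
    ROI-restricted supra-threshold ATS peaks.  Returns
    ``(event_set, decon_result, surrogate, volume_indices)`` where
    ``volume_indices`` maps trimmed timepoints back to the full run.
    """
    trimmed, keep = trim_to_experimental(series, schedule)
    decon = deconvolve_run(trimmed, mask=mask, hrf=hrf, **pipeline_kwargs)
    masked, _ = clean_and_count(decon)
    surrogate = surrogate_threshold(trimmed, mask=mask, hrf=hrf, seed=seed, **pipeline_kwargs)
    events = select_roi_peaks(masked, roi_mask, surrogate)
    return events, decon, surrogate, keep
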