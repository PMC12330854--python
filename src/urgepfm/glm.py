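"""First-level GLM with the 10-regressor design, contrasts and overlap metrics.

The design holds five HRF-convolved regressors of interest — Random, Okay
and Suppress block boxcars, a parametric regressor carrying the standardised
urge ratings of the experimental period (one rating per second), and a blink
event regressor — plus one temporal derivative per regressor.  Voxelwise
ordinary least squares yields contrast Z maps thresholded at Z >= 3.2, and
binary maps are compared with conjunction, percent overlap, Jaccard and Dice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .hemo import HRFModel, canonical_hrf
from .synthgen import OKAY, RANDOM, SUPPRESS, BlinkTrain, BlockSchedule

__all__ = [
    "DesignMatrix",
    "ContrastResult",
    "OverlapReport",
    "build_design_matrix",
    "fit_glm",
    "conjunction",
    "overlap_metrics",
]

BASE_COLUMNS = (RANDOM, OKAY, SUPPRESS, "Urge", "Blink")


@dataclass
class DesignMatrix:
    matrix: np.ndarray            # T x 10
    columns: tuple                # labels, derivatives suffixed ".deriv"
    tr_ms: float

    def column(self, label: str) -> np.ndarray:
        return self.matrix[:, self.columns.index(label)]

    def contrast_vector(self, positive, negative=()) -> np.ndarray:
        """Unit contrast: mean(positive columns) - mean(negative columns)."""
        c = np.zeros(len(self.columns))
        for lab in positive:
            c[self.columns.index(lab)] = 1.0 / len(positive)
        for lab in negative:
            c[self.columns.index(lab)] -= 1.0 / len(negative)
        return c


@dataclass
class ContrastResult:
    contrast: np.ndarray
    effect: np.ndarray
    z: np.ndarray
    binary: np.ndarray
    threshold: float
    dof: int


@dataclass
class OverlapReport:
    n_a: int
    n_b: int
    n_intersection: int
    percent_of_b: float | None    # 100*|A&B|/|B|, None when B is empty
    jaccard: float
    dice: float
    flags: list = field(default_factory=list)


def _events_to_tr_grid(events, n_vols: int, tr_s: float,
                       run_end_s: float | None = None) -> np.ndarray:
    """Fraction-of-TR overlap regressor from (onset, duration, weight) triples.

    Events beyond the last acquired volume but inside the behavioural run
    (``run_end_s``) contribute nothing; events outside the run are an error.
    """
    x = np.zeros(n_vols)
    grid_end = n_vols * tr_s
    run_end = run_end_s if run_end_s is not None else grid_end
    for onset, duration, weight in events:
        if onset < 0 or onset > run_end:
            raise ValueError(f"event onset {onset}s outside run of {run_end}s")
        end = min(onset + max(duration, 1e-9), grid_end)
        if onset >= grid_end:
            continue
        i0 = int(onset // tr_s)
        i1 = min(int(np.ceil(end / tr_s)), n_vols)
        for i in range(i0, i1):
            lo, hi = i * tr_s, (i + 1) * tr_s
            x[i] += weight * max(0.0, min(end, hi) - max(onset, lo)) / tr_s
    return x


def build_design_matrix(
    schedule: BlockSchedule,
    urge_z,
    blinks: BlinkTrain,
    hrf: HRFModel | None = None,
    tr_ms: float = 1800.0,
    n_vols: int | None = None,
) -> DesignMatrix:
    """Assemble the T x 10 first-level design.

    ``urge_z`` is a :class:`~urgepfm.behaviour.StandardisedUrge`; only its
    experimental-period seconds enter the parametric regressor (Random-period
    ratings are removed).  All base regressors are sampled on the TR grid as
    fractional-overlap stimulus functions, convolved with the canonical HRF,
    and paired with first-difference temporal derivatives.
    """
    tr_s = tr_ms / 1000.0
    if n_vols is None:
        n_vols = int(round(schedule.run_length_s / tr_s))
    hrf = hrf or canonical_hrf(tr_ms)
    kernel = hrf.kernel

    stimulus = {}
    for lab in (RANDOM, OKAY, SUPPRESS):
        stimulus[lab] = _events_to_tr_grid(
            [(b.onset_s, b.duration_s, 1.0) for b in schedule.blocks_of(lab)],
            n_vols,
            tr_s,
            run_end_s=schedule.run_length_s,
        )
    exp = urge_z.experimental_seconds()
    stimulus["Urge"] = _events_to_tr_grid(
        [(t, 1.0, z) for t, z in exp], n_vols, tr_s,
        run_end_s=schedule.run_length_s,
    )
    stimulus["Blink"] = _events_to_tr_grid(
        [(o, d, 1.0) for o, d in zip(blinks.onsets_s, blinks.durations_s)],
        n_vols,
        tr_s,
        run_end_s=schedule.run_length_s,
    )

    cols, labels = [], []
    for lab in BASE_COLUMNS:
        conv = np.convolve(stimulus[lab], kernel)[:n_vols]
        cols.append(conv)
        labels.append(lab)
    for lab, conv in zip(BASE_COLUMNS, list(cols)):
        deriv = np.diff(conv, prepend=0.0)
        cols.append(deriv)
        labels.append(f"{lab}.deriv")
    return DesignMatrix(matrix=np.column_stack(cols), columns=tuple(labels), tr_ms=tr_ms)


def _collinear_columns(M: np.ndarray, columns) -> list:
    """Labels of columns involved in rank deficiency (smallest singular vectors)."""
    _, s, Vt = np.linalg.svd(M, full_matrices=False)
    bad = []
    tol = s.max() * max(M.shape) * np.finfo(float).eps if s.max() > 0 else 0
    for i, sv in enumerate(s):
        if sv <= tol:
            involved = np.flatnonzero(np.abs(Vt[i]) > 1e-8)
            bad.extend(columns[j] for j in involved)
    return sorted(set(bad))


def fit_glm(
    data: np.ndarray,
    design: DesignMatrix,
    contrast: np.ndarray,
    mask: np.ndarray | None = None,
    threshold: float = 3.2,
) -> ContrastResult:
    """Voxelwise OLS with a t-contrast converted to a Z statistic.

    ``data`` has time on the last axis (a (..., T) array); voxels outside
    ``mask`` get Z = 0.  The t statistic ``c'b / se(c'b)`` is mapped through
    the t and standard-normal quantile functions so its two-sided tail
    probability is preserved, and the map is binarised at ``Z >= threshold``.
    """
    M = design.matrix
    T, p = M.shape
    c = np.asarray(contrast, float)
    if c.shape != (p,):
        raise ValueError(f"contrast length {c.shape} does not match {p} columns")
    if not np.any(c):
        raise ValueError("contrast vector is all zeros")
    if np.linalg.matrix_rank(M) < p:
        raise ValueError(
            "design matrix is rank deficient; collinear columns: "
            f"{_collinear_columns(M, design.columns)}"
        )
    data = np.asarray(data, float)
    grid = data.shape[:-1]
    Y = data.reshape(-1, T).T  # T x V
    if mask is not None:
        mflat = np.asarray(mask, bool).reshape(-1)
        Y = Y[:, mflat]
    dof = T - p
    MtM_inv = np.linalg.inv(M.T @ M)
    beta = MtM_inv @ (M.T @ Y)
    resid = Y - M @ beta
    sigma2 = (resid ** 2).sum(axis=0) / dof
    effect = c @ beta
    se = np.sqrt(sigma2 * float(c @ MtM_inv @ c))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, effect / se, 0.0)
    z = _t_to_z(tstat, dof)

    def unflatten(v):
        full = np.zeros(int(np.prod(grid)))
        if mask is not None:
            full[mflat] = v
        else:
            full = v
        return full.reshape(grid)

    zmap = unflatten(z)
    return ContrastResult(
        contrast=c,
        effect=unflatten(effect),
        z=zmap,
        binary=zmap >= threshold,
        threshold=threshold,
        dof=dof,
    )


def _t_to_z(t: np.ndarray, dof: int) -> np.ndarray:
    """Sign-preserving t -> Z conversion via matched tail probabilities."""
    t = np.asarray(t, float)
    # work on |t| for numerical symmetry, restore the sign afterwards
    p_tail = stats.t.sf(np.abs(t), dof)
    z = stats.norm.isf(np.clip(p_tail, 1e-300, 1.0))
    return np.sign(t) * z


def conjunction(mask_a: np.ndarray, mask_b: np.ndarray) -> np.ndarray:
    """Voxelwise logical AND of two binary maps on the same grid."""
    a, b = np.asarray(mask_a, bool), np.asarray(mask_b, bool)
    if a.shape != b.shape:
        raise ValueError(f"grid mismatch: {a.shape} vs {b.shape}")
    return a & b


def overlap_metrics(mespfm_mask: np.ndarray, glm_mask: np.ndarray) -> OverlapReport:
    """Percent-of-GLM overlap, Jaccard and Dice between two binary maps."""
    inter = conjunction(mespfm_mask, glm_mask)
    a = int(np.asarray(mespfm_mask, bool).sum())
    b = int(np.asarray(glm_mask, bool).sum())
    i = int(inter.sum())
    union = a + b - i
    flags = []
    if b == 0:
        flags.append("empty GLM mask: percent overlap undefined")
        pct = None
    else:
        pct = 100.0 * i / b
    jac = i / union if union else 0.0
    dice = 2 * i / (a + b) if (a + b) else 0.0
    return OverlapReport(
        n_a=a, n_b=b, n_intersection=i, percent_of_b=pct, jaccard=jac, dice=dice, flags=flags
    )
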