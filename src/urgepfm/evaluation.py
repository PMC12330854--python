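"""End-to-end property evaluations on synthetic data.

Each function sets up a planted-truth simulation at a desk-scale problem
size, runs the relevant part of the pipeline from scratch, and returns the
measured operating characteristics (recovery rates, calibration errors,
selection rates).  The test suite asserts on these numbers and the
reproduction script reports them; problem sizes are documented in the
methods note.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy import stats

from . import behaviour, events, glm, hemo, mapclust, mespfm, synthgen

__all__ = [
    "amplitude_for_cnr",
    "forward_inverse_recovery",
    "detection_characteristics",
    "null_exchangeability",
    "clustering_recovery",
    "glm_calibration",
    "overlap_identities",
    "logistic_recovery",
    "curvilinear_selection",
    "periblink_latency",
    "small_system_oracle_gap",
]


def amplitude_for_cnr(cnr: float, noise_sd_pct: float, te_ms: float = 35.0,
                      tr_ms: float = 1800.0) -> float:
    """|dR2*| giving peak percent change = ``cnr`` x noise sd at echo ``te_ms``."""
    kernel_peak = hemo.canonical_hrf(tr_ms).kernel.max()
    return cnr * (noise_sd_pct / 100.0) / ((te_ms / 1000.0) * kernel_peak)


def _planted_trimmed_onsets(truth, keep):
    """Planted event onsets re-indexed to the trimmed (experimental) series."""
    out = {}
    for r in truth.roi_ids:
        out[r] = truth.event_onsets[r] - keep[0]
    return out


def forward_inverse_recovery(seed: int = 0, grid=(20, 20, 10), n_rois: int = 3,
                             events_per_roi: int = 2, amplitude: float = -0.5):
    """Noiseless phantom: deconvolution must return the planted events exactly.

    Simulates a full run, trims the Random pads (leaving T = 200 volumes at
    TR = 1.8 s), deconvolves every voxel, and scores onset/amplitude recovery
    against the planted truth.
    """
    sched = synthgen.make_block_schedule()
    truth = synthgen.make_ground_truth(
        grid=grid, n_rois=n_rois, events_per_roi=events_per_roi,
        amplitude=amplitude, noise_sd_pct=0.0, seed=seed,
    )
    series = synthgen.simulate_multiecho_run(sched, truth, seed=seed)
    trimmed, keep = events.trim_to_experimental(series, sched)
    decon = mespfm.deconvolve_run(trimmed)
    onsets = _planted_trimmed_onsets(truth, keep)

    n_events = 0
    n_exact = 0
    rel_errors = []
    labels = truth.roi_labels
    for r in truth.roi_ids:
        vox = np.argwhere(labels == r)
        for onset, amp in zip(onsets[r], truth.event_amplitudes[r]):
            for x, y, z in vox:
                n_events += 1
                est = decon.estimates[x, y, z, onset]
                if est != 0:
                    n_exact += 1
                    rel_errors.append(abs(est - amp) / abs(amp))
    return dict(
        n_voxel_events=n_events,
        onset_recovery_fraction=n_exact / n_events,
        amplitude_max_rel_error=max(rel_errors) if rel_errors else np.inf,
        n_timepoints=decon.estimates.shape[-1],
    )


def _event_phantom(seed: int, grid, roi_size, n_events: int, cnr: float,
                   noise_sd_pct: float, null: bool = False):
    sched = synthgen.make_block_schedule()
    amp = -amplitude_for_cnr(cnr, noise_sd_pct)
    truth = synthgen.make_ground_truth(
        grid=grid, n_rois=1, events_per_roi=n_events, amplitude=amp,
        noise_sd_pct=noise_sd_pct, seed=seed, roi_size=roi_size,
    )
    if null:
        from dataclasses import replace

        truth = replace(
            truth,
            event_amplitudes={r: np.zeros_like(a) for r, a in truth.event_amplitudes.items()},
        )
    series = synthgen.simulate_multiecho_run(sched, truth, seed=seed)
    return sched, truth, series


def detection_characteristics(n_seeds: int = 20, grid=(8, 8, 4), roi_size=(3, 3, 2),
                              n_events: int = 6, cnr: float = 3.0,
                              noise_sd_pct: float = 0.5, tol_tr: int = 1,
                              base_seed: int = 0):
    """Planted-event detection vs matched null phantoms, paired over seeds.

    Per seed: one CNR-``cnr`` phantom with ``n_events`` events in a single ROI
    and one matched event-free phantom (same noise seed) are pushed through
    the full detection pipeline (deconvolution, cleaning, surrogate
    thresholding, ROI peak selection).
    """
    recovered, n_event_peaks, n_null_peaks = [], [], []
    for seed in range(base_seed, base_seed + n_seeds):
        sched, truth, series = _event_phantom(
            seed, grid, roi_size, n_events, cnr, noise_sd_pct
        )
        roi = truth.roi_labels == 1
        ev, _, _, keep = events.detect_events(series, sched, roi, seed=seed)
        onsets = _planted_trimmed_onsets(truth, keep)[1]
        hits = sum(
            any(abs(int(p) - int(o)) <= tol_tr for p in ev.timepoints) for o in onsets
        )
        recovered.append(hits)
        n_event_peaks.append(len(ev))

        _, truth0, series0 = _event_phantom(
            seed, grid, roi_size, n_events, cnr, noise_sd_pct, null=True
        )
        ev0, _, _, _ = events.detect_events(series0, sched, truth0.roi_labels == 1, seed=seed)
        n_null_peaks.append(len(ev0))
    recovered = np.asarray(recovered, float)
    n_event_peaks = np.asarray(n_event_peaks, float)
    n_null_peaks = np.asarray(n_null_peaks, float)
    return dict(
        mean_events_recovered=float(recovered.mean()),
        n_planted=n_events,
        mean_event_peaks=float(n_event_peaks.mean()),
        mean_null_peaks=float(n_null_peaks.mean()),
        null_strictly_fewer=bool(n_null_peaks.mean() < n_event_peaks.mean()),
        seeds=n_seeds,
    )


def null_exchangeability(n_seeds: int = 50, grid=(6, 6, 4),
                         noise_sd_pct: float = 0.5, base_seed: int = 0):
    """On event-free phantoms the original and surrogate ATS should match.

    Per seed, the original and one surrogate (volume-shuffled) run are fully
    analysed and their ATS count distributions compared with a two-sample
    Kolmogorov-Smirnov test.
    """
    n_ok = 0
    for seed in range(base_seed, base_seed + n_seeds):
        sched, truth, series = _event_phantom(
            seed, grid, (2, 2, 2), 1, cnr=0.0, noise_sd_pct=noise_sd_pct, null=True
        )
        trimmed, _ = events.trim_to_experimental(series, sched)
        decon = mespfm.deconvolve_run(trimmed)
        _, ats = events.clean_and_count(decon)
        surr = events.surrogate_threshold(trimmed, seed=seed)
        if np.ptp(ats.counts) == 0 and np.ptp(surr.ats.counts) == 0 and (
            ats.counts[0] == surr.ats.counts[0]
        ):
            p = 1.0  # identical degenerate distributions
        else:
            p = stats.ks_2samp(ats.counts, surr.ats.counts).pvalue
        n_ok += p > 0.05
    return dict(ks_p_gt_05_fraction=n_ok / n_seeds, seeds=n_seeds)


def _planted_map_stack(rng: np.random.Generator, n_groups: int, n_maps: int = 60,
                       n_voxels: int = 120, separation: float = 6.0,
                       within_sd: float = 1.0):
    """Map stack with well-separated planted groups (between >> within)."""
    from scipy.spatial.distance import pdist

    centers = rng.normal(0.0, 1.0, (n_groups, n_voxels))
    centers *= separation * np.sqrt(n_voxels) / pdist(centers).min()
    labels = rng.integers(0, n_groups, n_maps)
    # ensure every group occupied
    labels[:n_groups] = np.arange(n_groups)
    maps = centers[labels] + rng.normal(0.0, within_sd, (n_maps, n_voxels))
    return mapclust.ActivationMapStack(maps=maps), labels


def clustering_recovery(n_seeds: int = 50, n_groups: int = 3, n_maps: int = 60,
                        consensus_iters: int = 100, base_seed: int = 0):
    """Consensus k selection and k-means partition recovery on planted groups."""
    from sklearn.metrics import adjusted_rand_score

    correct_k = 0
    ari_ok = 0
    for seed in range(base_seed, base_seed + n_seeds):
        rng = np.random.default_rng(seed)
        stack, truth_labels = _planted_map_stack(rng, n_groups, n_maps=n_maps)
        report = mapclust.consensus_select_k(stack, iters=consensus_iters, seed=seed)
        correct_k += report.chosen_k == n_groups
        labels, _ = mapclust.kmeans_maps(stack, n_groups, seed=seed)
        ari_ok += adjusted_rand_score(truth_labels, labels) >= 0.9
    return dict(
        correct_k_fraction=correct_k / n_seeds,
        ari_ge_09_fraction=ari_ok / n_seeds,
        seeds=n_seeds,
    )


def glm_calibration(n_draws: int = 1_000_000, threshold: float = 3.2,
                    seed: int = 0, batch: int = 100_000):
    """Empirical P(Z >= threshold) under pure white noise vs the normal tail."""
    sched = synthgen.make_block_schedule()
    urge, blinks = synthgen.simulate_urge_and_blinks(sched, seed=seed)
    design = glm.build_design_matrix(
        sched, behaviour.downsample_standardise(urge), blinks
    )
    n_timepoints = design.matrix.shape[0]
    c = design.contrast_vector(["Suppress"], ["Okay"])
    rng = np.random.default_rng(seed)
    n_hits = 0
    done = 0
    while done < n_draws:
        b = min(batch, n_draws - done)
        data = rng.standard_normal((b, n_timepoints))
        res = glm.fit_glm(data, design, c)
        n_hits += int(res.binary.sum())
        done += b
    p_emp = n_hits / n_draws
    p_nom = float(stats.norm.sf(threshold))
    mc_sd = float(np.sqrt(p_nom * (1 - p_nom) / n_draws))
    return dict(
        empirical_tail_prob=p_emp,
        nominal_tail_prob=p_nom,
        mc_sd=mc_sd,
        abs_error_in_mc_sds=abs(p_emp - p_nom) / mc_sd,
        n_draws=n_draws,
    )


def overlap_identities(n_pairs: int = 100, grid=(12, 12, 6), seed: int = 0):
    """Dice = 2J/(1+J) and conjunction vs independent set arithmetic."""
    rng = np.random.default_rng(seed)
    max_gap = 0.0
    conj_ok = True
    for _ in range(n_pairs):
        a = rng.random(grid) < rng.uniform(0.05, 0.5)
        b = rng.random(grid) < rng.uniform(0.05, 0.5)
        rep = glm.overlap_metrics(a, b)
        # independent oracle: python set arithmetic on voxel indices
        sa = {tuple(v) for v in np.argwhere(a)}
        sb = {tuple(v) for v in np.argwhere(b)}
        inter, union = len(sa & sb), len(sa | sb)
        j = inter / union if union else 0.0
        d = 2 * inter / (len(sa) + len(sb)) if (sa or sb) else 0.0
        max_gap = max(
            max_gap,
            abs(rep.jaccard - j),
            abs(rep.dice - d),
            abs(rep.dice - 2 * rep.jaccard / (1 + rep.jaccard)) if rep.jaccard < 1 else 0.0,
        )
        conj = glm.conjunction(a, b)
        conj_ok &= {tuple(v) for v in np.argwhere(conj)} == (sa & sb)
    return dict(max_identity_gap=max_gap, conjunction_matches_bruteforce=conj_ok)


def logistic_recovery(n_seeds: int = 200, n_samples: int = 10_000,
                      b_true: float = -0.2, b0: float = -2.0,
                      base_seed: int = 0):
    """Mean bias of the logistic slope against Bernoulli draws from the truth."""
    estimates = []
    for seed in range(base_seed, base_seed + n_seeds):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(n_samples)
        p = 1.0 / (1.0 + np.exp(-(b0 + b_true * x)))
        y = rng.random(n_samples) < p
        res = behaviour.blink_urge_logistic(x, y.astype(float))
        estimates.append(res.B)
    estimates = np.asarray(estimates)
    return dict(
        mean_B=float(estimates.mean()),
        bias=float(estimates.mean() - b_true),
        b_true=b_true,
        seeds=n_seeds,
    )


def curvilinear_selection(n_seeds: int = 200, noise_sd: float = 0.08,
                          base_seed: int = 0):
    """Generate-and-refit: model choice on planted quadratic and linear curves.

    Planted shapes use the scale of the observed group templates (intercept
    ~0.9, |t| coefficient ~0.04, |t^2| coefficient ~0.02 in z units).
    """
    lags = np.arange(-5.0, 6.0)
    quad_correct = lin_correct = 0
    coef_ok = 0
    for seed in range(base_seed, base_seed + n_seeds):
        rng = np.random.default_rng(seed)
        y_q = 0.9 - 0.04 * lags - 0.02 * lags ** 2 + rng.normal(0, noise_sd, 11)
        y_l = -0.6 - 0.05 * lags + rng.normal(0, noise_sd, 11)
        cq = behaviour.curvilinear_fit(
            behaviour.PeriBlinkCurve(lags=lags, values=y_q, n_blinks=1)
        )
        cl = behaviour.curvilinear_fit(
            behaviour.PeriBlinkCurve(lags=lags, values=y_l, n_blinks=1)
        )
        quad_correct += cq.chosen == "quadratic"
        lin_correct += cl.chosen == "linear"
        # coefficient recovery within 3 SEs (quadratic term)
        se = noise_sd  # conservative upper bound for the t^2 SE on 11 points
        coef_ok += abs(cq.quadratic.coefficients[1] + 0.02) < 3 * se
    return dict(
        quadratic_selection_fraction=quad_correct / n_seeds,
        linear_selection_fraction=lin_correct / n_seeds,
        quad_coef_within_3se_fraction=coef_ok / n_seeds,
        seeds=n_seeds,
    )


def periblink_latency(n_seeds: int = 100, base_seed: int = 0):
    """Mean Suppress peri-blink peak latency across simulated participants.

    The generator's planted template peaks at the blink (lag 0), so the
    group-average estimated latency should be ~0 s.
    """
    sched = synthgen.make_block_schedule()
    latencies = []
    for seed in range(base_seed, base_seed + n_seeds):
        urge, blinks = synthgen.simulate_urge_and_blinks(sched, seed=seed)
        z = behaviour.downsample_standardise(urge)
        try:
            curve = behaviour.periblink_average(z, blinks, sched, synthgen.SUPPRESS)
        except behaviour.NoRetainedBlinksError:
            continue
        latencies.append(behaviour.curve_shape(curve)[0])
    latencies = np.asarray(latencies)
    return dict(
        mean_latency_s=float(latencies.mean()),
        sd_latency_s=float(latencies.std()),
        n_participants=len(latencies),
    )


def _exhaustive_penalised_min(X: np.ndarray, y: np.ndarray, alpha: float,
                              max_support: int = 2):
    """Global min of (1/2n)||y-Xb||^2 + alpha*||b||_1 over supports <= max_support.

    Independent oracle: for each candidate support and sign pattern the
    stationary point has a closed form; candidates violating their sign
    pattern are discarded and the objective is evaluated directly.
    """
    n, T = X.shape

    def objective(beta):
        r = y - X @ beta
        return 0.5 / n * float(r @ r) + alpha * float(np.abs(beta).sum())

    best = objective(np.zeros(T))
    for k in range(1, max_support + 1):
        for support in itertools.combinations(range(T), k):
            Xs = X[:, support]
            A = Xs.T @ Xs
            for signs in itertools.product([-1.0, 1.0], repeat=k):
                s = np.asarray(signs)
                try:
                    b = np.linalg.solve(A, Xs.T @ y - n * alpha * s)
                except np.linalg.LinAlgError:
                    continue
                if np.any(np.sign(b) * s < 0):
                    continue
                beta = np.zeros(T)
                beta[list(support)] = b
                best = min(best, objective(beta))
    return best


def small_system_oracle_gap(n_seeds: int = 5, T: int = 10, n_echoes: int = 2,
                            base_seed: int = 0):
    """Max objective gap between path solutions and exhaustive support search.

    Tiny systems (T <= 12) with a single planted event keep the lasso support
    within two entries, so exhaustive search over supports of size <= 2 finds
    the global penalised minimum; the homotopy path must attain it.
    """
    hrf = hemo.canonical_hrf(1800.0)
    design = mespfm.build_detrended_design(hrf, T, (12.0, 35.0), detrend_order=1)
    X = design.matrix
    n = X.shape[0]
    max_gap = 0.0
    max_support = 0
    for seed in range(base_seed, base_seed + n_seeds):
        rng = np.random.default_rng(seed)
        onset = rng.integers(1, T - 2)
        y = X[:, onset] * (-0.4) + rng.normal(0, 0.002, n)
        path = mespfm.solve_sparse_path(y, design, n_alphas=15)
        for i, alpha in enumerate(path.alphas):
            beta = path.coefs[:, i]
            k = int(path.support_sizes[i])
            max_support = max(max_support, k)
            if k > 2:
                continue
            obj = 0.5 / n * float(path.rss[i]) + alpha * float(np.abs(beta).sum())
            oracle = _exhaustive_penalised_min(X, y, alpha)
            max_gap = max(max_gap, abs(obj - oracle))
    return dict(max_objective_gap=max_gap, max_support_seen=max_support, seeds=n_seeds)
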