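"""Stage detection, ensemble alignment, scission inference and kinetics.

This is the analysis pipeline for patch trajectories: detect each track's
alignment reference (motion inflection for coat proteins, rising half-max
intensity for actin markers), align and average tracks on a common relative
time grid, infer the moment of vesicle scission from the jump in the
across-track displacement SD, and estimate the invagination speed from the
mean displacement ramp.

Inflection detection
--------------------
The motion signature of a coat protein is flat (stationary assembly), then a
linear ramp (invagination), then diffusive wander (released vesicle). The
default detector fits this shape directly: a three-segment least-squares
changepoint scan on the distance-from-origin series gives a coarse estimate,
refined by a continuous flat-then-ramp (hinge) fit on the 2D positions in a
local window. Working on the 2D positions in the refinement step matters:
distance-from-origin shares the noisy first-frame position across every
sample, which injects a random flat/ramp level offset of the order of the
localization noise and de-localizes the kink. The simpler published rule —
the minimum of the displacement series minus its own regression line — is
available as ``method="residual"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import (
    AlignedEnsemble,
    AlignmentReference,
    Track,
    displacement_from_origin,
    frame_displacements,
)
from .errors import DegenerateInputError, InsufficientDataError, PairingError

__all__ = [
    "StageReport",
    "filter_crowded",
    "inflection_point",
    "half_max_time",
    "compute_references",
    "align_tracks",
    "detect_scission",
    "invagination_speed",
    "patch_lifetime",
    "align_two_channel",
    "signal_onset",
    "run_stage_pipeline",
]

logger = logging.getLogger(__name__)

#: Default exclusion radius for crowded patches: 5 live-imaging pixels.
MIN_SEPARATION_NM = 325.0


@dataclass
class StageReport:
    """Summary of one ensemble's internalization stages."""

    mode: str
    t_scission: float | None
    displacement_at_scission: float | None
    speed: float | None
    speed_stderr: float | None
    n_tracks: int


# ---------------------------------------------------------------------------
# crowding filter


def filter_crowded(
    tracks: Sequence[Track], min_separation: float = MIN_SEPARATION_NM
) -> list[Track]:
    """Drop every track that ever comes within ``min_separation`` nm of
    another concurrent track.

    Both members of a close pair are removed: neither patch can be measured
    cleanly while they overlap. Concurrency is judged on frame indices.
    """
    grids = []
    for tr in tracks:
        frames = np.round(tr.times / tr.frame_interval).astype(int)
        grids.append(dict(zip(frames.tolist(), tr.positions())))
    flagged: set[int] = set()
    for i in range(len(tracks)):
        for j in range(i + 1, len(tracks)):
            common = grids[i].keys() & grids[j].keys()
            if not common:
                continue
            pi = np.array([grids[i][f] for f in sorted(common)])
            pj = np.array([grids[j][f] for f in sorted(common)])
            if np.min(np.hypot(*(pi - pj).T)) < min_separation:
                flagged.update((i, j))
                logger.info(
                    "excluding tracks %s and %s: closer than %g nm while concurrent",
                    tracks[i].track_id, tracks[j].track_id, min_separation,
                )
    return [tr for idx, tr in enumerate(tracks) if idx not in flagged]


# ---------------------------------------------------------------------------
# changepoint machinery


def _segment_tables(t: np.ndarray, y: np.ndarray):
    """Prefix sums giving O(1) least-squares SSE of any segment [i, j)."""
    zero = np.zeros(1)
    S1 = np.concatenate([zero, np.cumsum(np.ones_like(y))])
    St = np.concatenate([zero, np.cumsum(t)])
    Stt = np.concatenate([zero, np.cumsum(t * t)])
    Sy = np.concatenate([zero, np.cumsum(y)])
    Syy = np.concatenate([zero, np.cumsum(y * y)])
    Sty = np.concatenate([zero, np.cumsum(t * y)])

    def line_sse(i, j):
        n = S1[j] - S1[i]
        st = St[j] - St[i]
        stt = Stt[j] - Stt[i]
        sy = Sy[j] - Sy[i]
        syy = Syy[j] - Syy[i]
        sty = Sty[j] - Sty[i]
        var_t = stt - st * st / n
        cov_ty = sty - st * sy / n
        slope = np.where(var_t > 1e-12, cov_ty / np.where(var_t > 1e-12, var_t, 1.0), 0.0)
        return np.maximum(syy - sy * sy / n - slope * cov_ty, 0.0)

    def const_sse(i, j):
        n = S1[j] - S1[i]
        sy = Sy[j] - Sy[i]
        syy = Syy[j] - Syy[i]
        return np.maximum(syy - sy * sy / n, 0.0)

    return line_sse, const_sse


def _coarse_changepoint(t: np.ndarray, y: np.ndarray, min_seg: int = 3) -> list[int]:
    """Candidate flat→ramp boundaries from a flat/line/line/line segmentation.

    Returns the first two fitted changepoints, earliest first. The first is
    usually the kink; when the diffusive tail mimics a ramp continuation the
    optimum occasionally wastes its first changepoint inside the flat phase
    and the true kink surfaces as the second changepoint, so both are
    offered to the local refinement step for adjudication.

    Exhaustive least squares over three changepoints (O(n²) via prefix
    tables). Four segments matter: the post-scission diffusive wander is the
    dominant variance in the series, and with only one segment available
    after the ramp the optimum spends its changepoints subdividing that
    wander and merges the (weak) ramp into the flat phase. With two tail
    segments the wander is absorbed and the flat→ramp kink is recovered.
    On exact ties the latest first-changepoint wins (in noise-free data a
    line fits the flat zeros as well as a constant would, so the first
    changepoint would otherwise collapse to the left edge).
    """
    n = len(y)
    line_sse, const_sse = _segment_tables(t, y)

    if n <= 4 * min_seg:  # too short for four segments: flat/line scan
        best_sse, best_k = np.inf, min_seg
        for k1 in range(min_seg, n - min_seg):
            total = const_sse(0, k1 + 1) + line_sse(k1, n)
            if total <= best_sse:
                best_sse, best_k = total, k1
        return [best_k]

    # tail_split[j] = best SSE of [j, n) split into two line segments
    tail_split = np.full(n + 1, np.inf)
    tail_argmin = np.zeros(n + 1, dtype=int)
    for j in range(min_seg, n - 2 * min_seg + 1):
        k3 = np.arange(j + min_seg, n - min_seg + 1)
        totals = line_sse(j, k3) + line_sse(k3, n)
        i = int(np.argmin(totals))
        tail_split[j], tail_argmin[j] = float(totals[i]), int(k3[i])

    best_sse, best = np.inf, [min_seg]
    for k1 in range(min_seg, n - 3 * min_seg):
        k2 = np.arange(k1 + min_seg, n - 2 * min_seg + 1)
        total = const_sse(0, k1 + 1) + line_sse(k1, k2) + tail_split[k2]
        j = int(np.argmin(total))
        if total[j] <= best_sse:
            best_sse, best = total[j], [k1, int(k2[j])]
    return best


def _hinge_refine_2d(
    t: np.ndarray, pos: np.ndarray, k0: int, back: int, fwd: int
) -> tuple[int, float]:
    """Refine a kink index with a continuous flat→drift fit on 2D positions.

    Model within the window: position constant until the kink, then linear in
    time (continuity built in). Both coordinates are fit jointly. The window
    must end before scission, so ``fwd`` stays below the directed-phase
    length in frames. Returns the refined index and the fraction of the
    stationary-model SSE the hinge explains — near zero when the window
    holds no real transition, so callers can reject spurious candidates.
    """
    lo, hi = max(0, k0 - back), min(len(t), k0 + fwd)
    tt, pp = t[lo:hi], pos[lo:hi]
    sse_const = float(((pp - pp.mean(axis=0)) ** 2).sum())
    best_sse, best_k = np.inf, k0
    ones = np.ones(hi - lo)
    for k in range(max(lo + 2, 2), hi - 2):
        z = np.maximum(tt - t[k], 0.0)
        design = np.column_stack([ones, z])
        coef, *_ = np.linalg.lstsq(design, pp, rcond=None)
        sse = float(((pp - design @ coef) ** 2).sum())
        if sse < best_sse:
            best_sse, best_k = sse, k
    improvement = 1.0 - best_sse / sse_const if sse_const > 0 else 1.0
    return best_k, improvement


def _arm_drifts(
    t: np.ndarray, pos: np.ndarray, lo: int, hi: int, threshold: float = 0.15
) -> bool:
    """True when positions over [lo, hi] drift (a line beats a constant).

    Used on both sides of a kink candidate: a genuine inflection has a flat
    pre-arm and a drifting post-arm; a candidate whose pre-arm drifts sits
    too late (on the drift→diffusion transition), one whose post-arm is flat
    is a noise artefact inside the stationary phase.
    """
    lo, hi = max(0, lo), min(len(t), hi)
    seg, tt = pos[lo:hi], t[lo:hi]
    if len(seg) < 8:
        return False
    sse_const = float(((seg - seg.mean(axis=0)) ** 2).sum())
    design = np.column_stack([np.ones(len(tt)), tt])
    coef, *_ = np.linalg.lstsq(design, seg, rcond=None)
    sse_line = float(((seg - design @ coef) ** 2).sum())
    return sse_const > 0 and (1.0 - sse_line / sse_const) > threshold


def inflection_point(
    track: Track,
    method: Literal["changepoint", "residual"] = "changepoint",
    smooth_window: int = 3,
    displacement: Literal["from_origin", "frame_by_frame"] = "from_origin",
    refine_back: int = 40,
    refine_fwd: int = 25,
    min_frames: int = 10,
) -> AlignmentReference:
    """Time at which a patch transitions from stationary to directed motion.

    ``method="changepoint"`` (default) fits the flat/ramp/release shape
    explicitly and localizes the kink on the 2D positions (see module notes).
    ``method="residual"`` is the regression-residual rule: subtract the OLS
    line from the displacement series and take the argmin (earliest tie
    wins), optionally after a centered moving average of ``smooth_window``
    frames.
    """
    if len(track) < min_frames:
        raise InsufficientDataError(
            f"track {track.track_id!r}: {len(track)} frames < {min_frames} needed for inflection"
        )
    if np.allclose(frame_displacements(track).values, 0.0):
        raise DegenerateInputError(f"track {track.track_id!r}: no motion at all")

    if method == "changepoint":
        series = displacement_from_origin(track)
        y = _moving_average(series.values, smooth_window)
        candidates = _coarse_changepoint(series.times, y)
        pos = track.positions()
        refined = [
            _hinge_refine_2d(track.times, pos, k0, refine_back, refine_fwd)
            for k0 in candidates
        ]
        # earliest candidate that looks like a genuine flat->drift
        # transition; fall back to the first changepoint otherwise
        k = next(
            (
                k
                for k, gain in refined
                if gain > 0.05 and _arm_drifts(track.times, pos, k, k + refine_fwd)
            ),
            refined[0][0],
        )
        # walk back while the pre-arm still drifts: the candidate then sits
        # on the drift->diffusion kink and the flat->drift kink lies earlier
        for _ in range(6):
            if not _arm_drifts(track.times, pos, k - refine_back, k + 1):
                break
            k_new, gain = _hinge_refine_2d(
                track.times, pos, max(k - refine_fwd, 2), refine_back, refine_fwd
            )
            if gain <= 0.05 or k_new >= k:
                break
            k = k_new
        t_ref = float(track.times[k])
    elif method == "residual":
        series = (
            displacement_from_origin(track)
            if displacement == "from_origin"
            else frame_displacements(track)
        )
        y = _moving_average(series.values, smooth_window)
        fit = stats.linregress(series.times, y)
        residual = y - (fit.intercept + fit.slope * series.times)
        t_ref = float(series.times[int(np.argmin(residual))])
    else:
        raise ValueError(f"unknown method {method!r}")
    return AlignmentReference(track_id=track.track_id, mode="inflection", t_ref=t_ref)


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y
    pad = window // 2
    padded = np.pad(y, pad, mode="edge")
    smoothed = np.convolve(padded, np.ones(window) / window, mode="valid")
    return smoothed[: len(y)]


def half_max_time(track: Track) -> AlignmentReference:
    """First rising crossing of 50% of the raw intensity maximum.

    Linear interpolation between the bracketing frames. If the track starts
    already above half-max the first time point is returned, flagged.
    """
    intensity = track.intensity
    half = 0.5 * intensity.max()
    above = intensity >= half
    first = int(np.argmax(above))
    if first == 0:
        return AlignmentReference(track.track_id, "half_max", float(track.times[0]), flagged=True)
    i0, i1 = first - 1, first
    frac = (half - intensity[i0]) / (intensity[i1] - intensity[i0])
    t_ref = track.times[i0] + frac * (track.times[i1] - track.times[i0])
    return AlignmentReference(track.track_id, "half_max", float(t_ref))


def compute_references(
    tracks: Sequence[Track],
    mode: Literal["inflection", "half_max"],
    **inflection_kwargs,
) -> list[AlignmentReference | None]:
    """Per-track alignment references; None where detection fails (logged)."""
    refs: list[AlignmentReference | None] = []
    for tr in tracks:
        try:
            if mode == "inflection":
                refs.append(inflection_point(tr, **inflection_kwargs))
            elif mode == "half_max":
                refs.append(half_max_time(tr))
            else:
                raise ValueError(f"unknown alignment mode {mode!r}")
        except (InsufficientDataError, DegenerateInputError) as exc:
            logger.info("no %s reference for track %s: %s", mode, tr.track_id, exc)
            refs.append(None)
    return refs


# ---------------------------------------------------------------------------
# ensemble alignment


def _track_rel_series(track: Track, t_ref: float):
    """Relative times, rescaled intensity and displacement-from-reference."""
    rel = track.times - t_ref
    x_ref = np.interp(t_ref, track.times, track.x)
    y_ref = np.interp(t_ref, track.times, track.y)
    disp = np.hypot(track.x - x_ref, track.y - y_ref)
    return rel, track.intensity / track.intensity.max(), disp


def refine_references(
    tracks: Sequence[Track],
    refs: Sequence[AlignmentReference | None],
    iterations: int = 1,
    max_shift: float = 4.0,
    window: tuple[float, float] = (-3.0, 8.0),
) -> list[AlignmentReference | None]:
    """Sharpen per-track references by registration to the ensemble average.

    Per-track detectors occasionally misplace a reference by many frames
    (the per-frame displacement gain can sit well below the localization
    noise); such outliers smear the ensemble and inflate its SD band. Each
    pass builds the ensemble mean displacement and then re-times every track
    by the shift (within ``max_shift`` seconds) that best matches its own
    displacement-from-reference curve to that template over ``window``
    (relative time, seconds). One pass removes gross outliers; the procedure
    is deterministic and typically converges in a single iteration.
    """
    refs = list(refs)
    pairs = [(i, tr, r) for i, (tr, r) in enumerate(zip(tracks, refs)) if r is not None]
    if len(pairs) < 3 or iterations < 1:
        return refs
    dt = min(tr.frame_interval for _, tr, _ in pairs)
    shifts = np.arange(-int(round(max_shift / dt)), int(round(max_shift / dt)) + 1) * dt
    for _ in range(iterations):
        ensemble = align_tracks(
            [tr for _, tr, _ in pairs],
            refs=[r for _, _, r in pairs],
            n_min=3,
            refine_iterations=0,
        )
        sel = (
            (ensemble.rel_times >= window[0])
            & (ensemble.rel_times <= window[1])
            & np.isfinite(ensemble.mean_displacement)
        )
        grid = ensemble.rel_times[sel]
        template = ensemble.mean_displacement[sel]
        if len(grid) < 8:
            break
        best_shifts = np.zeros(len(pairs))
        for idx, (i, tr, ref) in enumerate(pairs):
            best_score, best_shift = np.inf, 0.0
            for delta in shifts:
                t_new = ref.t_ref + delta
                if not (tr.times[0] <= t_new <= tr.times[-1]):
                    continue
                rel, _, disp = _track_rel_series(tr, t_new)
                inside = (grid >= rel[0]) & (grid <= rel[-1])
                if inside.sum() < 8:
                    continue
                values = np.interp(grid[inside], rel, disp)
                score = float(np.mean((values - template[inside]) ** 2))
                if score < best_score:
                    best_score, best_shift = score, float(delta)
            best_shifts[idx] = best_shift
        # registration only fixes *relative* offsets; recentre on the median
        # shift so the consensus clock of the per-track detector is kept and
        # outlier corrections cannot drag every reference coherently
        best_shifts -= np.median(best_shifts)
        if np.allclose(best_shifts, 0.0):
            break
        for idx, (i, tr, ref) in enumerate(pairs):
            new_ref = AlignmentReference(
                ref.track_id, ref.mode, ref.t_ref + best_shifts[idx], ref.flagged
            )
            pairs[idx] = (i, tr, new_ref)
            refs[i] = new_ref
    return refs


def align_tracks(
    tracks: Sequence[Track],
    mode: Literal["inflection", "half_max"] = "inflection",
    n_min: int = 3,
    refs: Sequence[AlignmentReference | None] | None = None,
    grid: np.ndarray | None = None,
    refine_iterations: int = 0,
    **inflection_kwargs,
) -> AlignedEnsemble:
    """Align tracks at their references and average on a uniform grid.

    Each track's clock is shifted so its reference sits at 0, its intensity
    is rescaled to its own maximum, and its displacement is measured from its
    position *at the reference time* (pre-reference jitter would otherwise
    offset the origin). Series are linearly interpolated — never extrapolated
    — onto a grid at the smallest frame interval present; bins covered by
    fewer than ``n_min`` tracks are masked (NaN). ``refine_iterations`` > 0
    additionally registers each track's displacement curve to the ensemble
    template (see :func:`refine_references`); useful when references are
    noisy and the mean displacement shape is sharp, counterproductive when
    the per-frame displacement gain is small against the localization noise.
    """
    if refs is None:
        refs = compute_references(tracks, mode, **inflection_kwargs)
        if refine_iterations > 0:
            refs = refine_references(tracks, refs, iterations=refine_iterations)
    pairs = [(tr, ref) for tr, ref in zip(tracks, refs) if ref is not None]
    if len(pairs) < 3:
        raise InsufficientDataError(f"only {len(pairs)} alignable tracks; need at least 3")

    dt = min(tr.frame_interval for tr, _ in pairs)
    rel_series = [
        _track_rel_series(tr, ref.t_ref) for tr, ref in pairs
    ]

    if grid is None:
        lo = min(rel[0] for rel, _, _ in rel_series)
        hi = max(rel[-1] for rel, _, _ in rel_series)
        grid = np.arange(int(np.ceil(lo / dt - 1e-9)), int(np.floor(hi / dt + 1e-9)) + 1) * dt
    grid = np.asarray(grid, dtype=float)

    n_bins = len(grid)
    stack_i = np.full((len(rel_series), n_bins), np.nan)
    stack_d = np.full((len(rel_series), n_bins), np.nan)
    for row, (rel, norm_i, disp) in enumerate(rel_series):
        inside = (grid >= rel[0] - 1e-9) & (grid <= rel[-1] + 1e-9)
        stack_i[row, inside] = np.interp(grid[inside], rel, norm_i)
        stack_d[row, inside] = np.interp(grid[inside], rel, disp)

    counts = np.sum(np.isfinite(stack_i), axis=0)
    keep = counts >= n_min

    def _stats(stack):
        import warnings as _warnings

        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1)
        mean[~keep] = np.nan
        sd[~keep] = np.nan
        return mean, sd

    mean_i, sd_i = _stats(stack_i)
    mean_d, sd_d = _stats(stack_d)
    return AlignedEnsemble(
        rel_times=grid,
        mean_intensity=mean_i,
        sd_intensity=sd_i,
        mean_displacement=mean_d,
        sd_displacement=sd_d,
        n_per_bin=np.where(keep, counts, 0),
        mode=mode,
    )


# ---------------------------------------------------------------------------
# stage inference


def detect_scission(
    ensemble: AlignedEnsemble,
    k: float = 2.0,
    m: int = 3,
    baseline_window: tuple[float, float] = (0.0, 2.0),
) -> float | None:
    """Relative time of the displacement-SD jump marking vesicle release.

    Baseline = median displacement SD over ``baseline_window`` (the early
    directed phase, where regular movement keeps the across-track SD small).
    Scission is the first bin beyond the window where the SD exceeds
    ``k`` × baseline for ``m`` consecutive bins; None if never triggered.
    """
    rel, sd = ensemble.rel_times, ensemble.sd_displacement
    base_mask = (rel >= baseline_window[0]) & (rel <= baseline_window[1]) & np.isfinite(sd)
    if not base_mask.any():
        raise InsufficientDataError("no valid bins in the scission baseline window")
    baseline = float(np.median(sd[base_mask]))
    threshold = k * baseline

    candidates = np.flatnonzero((rel > baseline_window[1]) & np.isfinite(sd))
    run = 0
    for pos, idx in enumerate(candidates):
        consecutive = pos > 0 and candidates[pos - 1] == idx - 1
        if sd[idx] > threshold:
            run = run + 1 if (run and consecutive) else 1
            if run >= m:
                return float(rel[idx - m + 1])
        else:
            run = 0
    return None


def invagination_speed(
    ensemble: AlignedEnsemble, t_scission: float, debias: bool = True
) -> tuple[float, float]:
    """OLS slope (nm/s ± SE) of mean displacement over (0, t_scission].

    With ``debias`` (default) the pre-reference mean displacement — a pure
    localization-noise floor, since the patch is stationary before the
    reference — is subtracted in quadrature before the fit. The ensemble
    mean of a displacement *magnitude* sits on that floor, which otherwise
    drags the fitted slope below the true speed.
    """
    if not (t_scission is not None and t_scission > 0):
        raise InsufficientDataError("invagination speed needs a positive scission time")
    rel, disp = ensemble.rel_times, ensemble.mean_displacement
    window = (rel > 0) & (rel <= t_scission + 1e-9) & np.isfinite(disp)
    if window.sum() < 4:
        raise InsufficientDataError(
            f"only {int(window.sum())} bins in (0, {t_scission:g}]; need at least 4"
        )
    y = disp[window]
    if debias:
        pre = (rel < 0) & np.isfinite(disp)
        floor = float(np.median(disp[pre])) if pre.any() else 0.0
        y = np.sqrt(np.maximum(y**2 - floor**2, 0.0))
    fit = stats.linregress(rel[window], y)
    return float(fit.slope), float(fit.stderr)


def patch_lifetime(track: Track, frac: float = 0.1) -> float:
    """Seconds between the first and last crossings of ``frac`` × peak
    intensity, with linear interpolation at both ends."""
    if frac < 0:
        raise ValueError("frac must be non-negative")
    if frac == 0:
        return track.duration
    intensity, times = track.intensity, track.times
    threshold = frac * intensity.max()
    above = intensity >= threshold
    if not above.any():
        raise DegenerateInputError(
            f"track {track.track_id!r}: intensity never reaches {frac:g} of peak"
        )
    first = int(np.argmax(above))
    last = len(above) - 1 - int(np.argmax(above[::-1]))
    if first == 0:
        t_start = times[0]
    else:
        frac_up = (threshold - intensity[first - 1]) / (intensity[first] - intensity[first - 1])
        t_start = times[first - 1] + frac_up * (times[first] - times[first - 1])
    if last == len(above) - 1:
        t_end = times[-1]
    else:
        frac_down = (intensity[last] - threshold) / (intensity[last] - intensity[last + 1])
        t_end = times[last] + frac_down * (times[last + 1] - times[last])
    return float(t_end - t_start)


# ---------------------------------------------------------------------------
# two-channel co-alignment


def align_two_channel(
    event_pairs: Sequence[tuple[Track, Track]],
    reference: Literal["A", "B"] = "A",
    mode: Literal["inflection", "half_max"] = "inflection",
    n_min: int = 3,
    **inflection_kwargs,
) -> tuple[AlignedEnsemble, AlignedEnsemble]:
    """Co-align two-channel events: the reference channel's alignment time
    shifts *both* channels of each event, and both ensembles share one grid.
    """
    bad = [
        (a.track_id, b.track_id)
        for a, b in event_pairs
        if max(a.times[0], b.times[0]) >= min(a.times[-1], b.times[-1])
    ]
    if bad:
        raise PairingError(f"channel pairs without temporal overlap: {bad}")

    tracks_a = [a for a, _ in event_pairs]
    tracks_b = [b for _, b in event_pairs]
    ref_tracks = tracks_a if reference == "A" else tracks_b
    base_refs = compute_references(ref_tracks, mode, **inflection_kwargs)
    refs_a = [
        None if r is None else AlignmentReference(a.track_id, r.mode, r.t_ref, r.flagged)
        for a, r in zip(tracks_a, base_refs)
    ]
    refs_b = [
        None if r is None else AlignmentReference(b.track_id, r.mode, r.t_ref, r.flagged)
        for b, r in zip(tracks_b, base_refs)
    ]

    dt = min(tr.frame_interval for tr in (*tracks_a, *tracks_b))
    rel_bounds = [
        (tr.times[0] - r.t_ref, tr.times[-1] - r.t_ref)
        for tr, r in [*zip(tracks_a, refs_a), *zip(tracks_b, refs_b)]
        if r is not None
    ]
    if len(rel_bounds) < 6:
        raise InsufficientDataError("fewer than 3 alignable events for two-channel alignment")
    lo = min(b[0] for b in rel_bounds)
    hi = max(b[1] for b in rel_bounds)
    grid = np.arange(int(np.ceil(lo / dt - 1e-9)), int(np.floor(hi / dt + 1e-9)) + 1) * dt

    ens_a = align_tracks(tracks_a, mode, n_min=n_min, refs=refs_a, grid=grid)
    ens_b = align_tracks(tracks_b, mode, n_min=n_min, refs=refs_b, grid=grid)
    return ens_a, ens_b


def signal_onset(
    ensemble: AlignedEnsemble, baseline_end: float, factor: float = 3.0
) -> float | None:
    """First bin whose mean intensity exceeds the pre-event baseline by
    ``factor`` × the baseline's SD. Baseline bins are those before
    ``baseline_end`` (relative time)."""
    rel, mean_i = ensemble.rel_times, ensemble.mean_intensity
    base = (rel < baseline_end) & np.isfinite(mean_i)
    if not base.any():
        raise InsufficientDataError("no valid bins before the onset baseline end")
    level = float(np.mean(mean_i[base]) + factor * np.std(mean_i[base]))
    after = np.flatnonzero((rel >= baseline_end) & np.isfinite(mean_i) & (mean_i > level))
    return float(rel[after[0]]) if after.size else None


# ---------------------------------------------------------------------------
# end-to-end convenience


def run_stage_pipeline(
    tracks: Sequence[Track],
    mode: Literal["inflection", "half_max"] = "inflection",
    min_separation: float | None = None,
    k: float = 2.0,
    m: int = 3,
    n_min: int = 3,
    **inflection_kwargs,
) -> tuple[StageReport, AlignedEnsemble]:
    """Crowding filter → references → alignment → scission → speed."""
    kept = list(tracks)
    if min_separation is not None:
        kept = filter_crowded(kept, min_separation)
    ensemble = align_tracks(kept, mode, n_min=n_min, **inflection_kwargs)
    t_scission = detect_scission(ensemble, k=k, m=m)
    speed = stderr = disp_at_scission = None
    if t_scission is not None:
        speed, stderr = invagination_speed(ensemble, t_scission)
        idx = int(np.argmin(np.abs(ensemble.rel_times - t_scission)))
        value = ensemble.mean_displacement[idx]
        disp_at_scission = float(value) if np.isfinite(value) else None
    report = StageReport(
        mode=mode,
        t_scission=t_scission,
        displacement_at_scission=disp_at_scission,
        speed=speed,
        speed_stderr=stderr,
        n_tracks=int(np.max(ensemble.n_per_bin)) if len(ensemble) else 0,
    )
    return report, ensemble
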