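"""Per-cell calcium-trace analysis.

The pipeline quantifies odor responses of mitral cells recorded with
two-photon calcium imaging: fractional fluorescence change (dF/F) against a
pre-stimulus baseline, moving-average smoothing, effect-size response
detection on trial-averaged traces, response magnitudes, exact permutation
comparison of paired conditions, tuning-curve statistics, a population
sharpening ratio with confidence borders, and a baseline-activity shift
estimate.

All analysis windows are expressed in seconds relative to odor onset and
converted to frame indices by rounding, with half-open [start, end)
intervals.  Standard deviations use the sample (n-1) convention.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "ImagingSession",
    "ResponseCall",
    "PairedResponse",
    "TuningSummary",
    "SharpeningEstimate",
    "compute_dff",
    "smooth_trace",
    "detect_response",
    "response_magnitude",
    "compare_before_after",
    "permutation_pvalues",
    "trial_response_means",
    "analyze_session",
    "classify_pairs",
    "tuning_summary",
    "estimate_sharpening",
    "baseline_shift",
    "responsiveness",
]

Sign = Literal["excited", "suppressed", "none"]

# Analysis-window defaults (seconds relative to odor onset).
F0_WINDOW = (-5.0, -2.0)
RESPONSE_WINDOW = (0.0, 4.0)
BASELINE_WINDOW = (-6.0, -2.0)
MAGNITUDE_WINDOW = (0.0, 5.0)
ES_THRESHOLD = 5.0
SMOOTH_SPAN = 5


@dataclass
class ImagingSession:
    """One imaging session: a dense fluorescence tensor plus stimulus timing.

    Parameters
    ----------
    fluorescence
        Raw fluorescence, shape ``(n_cells, n_odors, n_trials, n_frames)``,
        arbitrary units.
    frame_rate
        Acquisition rate in Hz.
    onset_frame
        Frame index of odor onset, identical across trials.
    condition
        Condition label, e.g. ``"before"`` / ``"after"``.
    background
        Optional per-frame background (cell-free region) fluorescence trace,
        length ``n_frames``, used for baseline-activity estimation.
    """

    fluorescence: np.ndarray
    frame_rate: float
    onset_frame: int
    condition: str = ""
    subject_id: str = ""
    cell_ids: Sequence[str] = ()
    odor_ids: Sequence[str] = ()
    stim_s: float = 2.0
    background: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 4:
            raise ValueError(
                "fluorescence must be (cells, odors, trials, frames), got "
                f"shape {self.fluorescence.shape}"
            )
        if not np.isfinite(self.fluorescence).all():
            raise ValueError("fluorescence tensor contains non-finite values")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        n_cells, n_odors, _, n_frames = self.fluorescence.shape
        if not self.cell_ids:
            self.cell_ids = tuple(f"cell{i:03d}" for i in range(n_cells))
        if not self.odor_ids:
            self.odor_ids = tuple(f"odor{i:02d}" for i in range(n_odors))
        if not 0 <= self.onset_frame < n_frames:
            raise ValueError("onset_frame outside recording")
        # The full pipeline needs 6 s of pre-stimulus baseline and 5 s of
        # post-onset response per trial.
        pre_s = self.onset_frame / self.frame_rate
        post_s = (n_frames - self.onset_frame) / self.frame_rate
        if pre_s < 6.0 - 1e-9 or post_s < 5.0 - 1e-9:
            raise ValueError(
                f"recording too short for analysis windows: {pre_s:.2f} s "
                f"pre-onset (need >= 6) and {post_s:.2f} s post-onset (need >= 5)"
            )

    @property
    def n_cells(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_odors(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def n_trials(self) -> int:
        return self.fluorescence.shape[2]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[3]

    def window_slice(self, start_s: float, end_s: float) -> slice:
        """Half-open frame slice for a window in seconds relative to onset."""
        a = self.onset_frame + int(round(start_s * self.frame_rate))
        b = self.onset_frame + int(round(end_s * self.frame_rate))
        if a < 0 or b > self.n_frames or a >= b:
            raise ValueError(
                f"window ({start_s}, {end_s}) s does not fit the recording"
            )
        return slice(a, b)


@dataclass
class ResponseCall:
    """Detection result for one cell-odor pair."""

    cell_id: str
    odor_id: str
    effect_size: float
    sign: Sign
    significant: bool
    magnitude: float  # dF/F * s, integral of the mean trace 0-5 s post onset
    extremum_value: float
    extremum_frame: int
    truncated: bool = False  # extremum neighbors clipped at a trace edge
    degenerate: bool = False  # zero pooled std


@dataclass
class PairedResponse:
    """A cell-odor pair observed in both conditions."""

    cell_id: str
    odor_id: str
    call_before: ResponseCall
    call_after: ResponseCall
    perm_p: float | None
    delta_magnitude: float
    changed: bool


@dataclass
class TuningSummary:
    """Per-cell tuning curves (ranked response magnitudes over odors).

    All cell-odor pairs enter regardless of their significance
    classification; ``tuning_sd`` is the sample standard deviation of each
    cell's magnitudes over odors.
    """

    condition: str
    ranked: np.ndarray  # (n_cells, n_odors), non-increasing along axis 1
    tuning_sd: np.ndarray  # (n_cells,)
    mean_sd: float = field(init=False)
    sem_sd: float = field(init=False)

    def __post_init__(self) -> None:
        self.ranked = np.asarray(self.ranked, dtype=float)
        self.tuning_sd = np.asarray(self.tuning_sd, dtype=float)
        self.mean_sd = float(self.tuning_sd.mean())
        n = len(self.tuning_sd)
        self.sem_sd = float(self.tuning_sd.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0


@dataclass
class SharpeningEstimate:
    """Population sharpening ratio with confidence borders.

    ``sharpening`` is mean tuning-curve std in the first condition over mean
    tuning-curve std in the second; the confidence borders are the extrema of
    (Avg +/- SEM)_before / (Avg -/+ SEM)_after.
    """

    sharpening: float
    ci_low: float
    ci_high: float


# ---------------------------------------------------------------------------
# dF/F and smoothing
# ---------------------------------------------------------------------------

def compute_dff(
    session: ImagingSession, f0_window: tuple[float, float] = F0_WINDOW
) -> np.ndarray:
    """Fractional fluorescence change (f - f0) / f0.

    The baseline f0 is, for each cell and trial, the mean raw fluorescence
    over ``f0_window`` (default 5-2 s before odor onset).
    """
    sl = session.window_slice(*f0_window)
    f = session.fluorescence
    f0 = f[..., sl].mean(axis=-1, keepdims=True)  # (cells, odors, trials, 1)
    bad = np.nonzero(f0[..., 0] <= 0)
    if bad[0].size:
        c, o, t = bad[0][0], bad[1][0], bad[2][0]
        raise ValueError(
            "non-positive baseline fluorescence f0 for cell "
            f"{session.cell_ids[c]!r}, odor {session.odor_ids[o]!r}, trial {t}"
        )
    return (f - f0) / f0


def smooth_trace(trace: np.ndarray, span: int = SMOOTH_SPAN) -> np.ndarray:
    """Centered moving average with shrinking windows at the boundaries.

    Near each edge the window shrinks to the largest centered odd window that
    fits: the first point is returned unsmoothed, the second is averaged over
    3 points, and so on.  Output length equals input length.  Operates along
    the last axis of ``trace``.
    """
    if span < 1 or span % 2 == 0:
        raise ValueError("span must be a positive odd integer")
    x = np.asarray(trace, dtype=float)
    n = x.shape[-1]
    if n == 0:
        raise ValueError("trace must be non-empty")
    half = span // 2
    out = np.empty_like(x)
    csum = np.cumsum(np.concatenate([np.zeros(x.shape[:-1] + (1,)), x], axis=-1), axis=-1)
    for i in range(n):
        k = min(half, i, n - 1 - i)
        out[..., i] = (csum[..., i + k + 1] - csum[..., i - k]) / (2 * k + 1)
    return out


def mean_smoothed_trace(dff_trials: np.ndarray, span: int = SMOOTH_SPAN) -> np.ndarray:
    """Trial mean of smoothed per-trial dF/F traces (trials on axis -2)."""
    return smooth_trace(dff_trials, span=span).mean(axis=-2)


# ---------------------------------------------------------------------------
# Response detection and magnitude
# ---------------------------------------------------------------------------

def _window_indices(
    onset_frame: int, frame_rate: float, window: tuple[float, float], n_frames: int
) -> tuple[int, int]:
    a = onset_frame + int(round(window[0] * frame_rate))
    b = onset_frame + int(round(window[1] * frame_rate))
    if a < 0 or b > n_frames or a >= b:
        raise ValueError(f"window {window} s does not fit the trace")
    return a, b


def _sample_around(trace: np.ndarray, idx: int, half: int = 3) -> tuple[np.ndarray, bool]:
    lo, hi = idx - half, idx + half + 1
    truncated = lo < 0 or hi > len(trace)
    return trace[max(lo, 0): min(hi, len(trace))], truncated


def detect_response(
    mean_trace: np.ndarray,
    frame_rate: float,
    onset_frame: int,
    *,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    es_threshold: float = ES_THRESHOLD,
    cell_id: str = "",
    odor_id: str = "",
) -> ResponseCall:
    """Classify a trial-averaged (smoothed) dF/F trace as excited/suppressed.

    The sign of the trace integral over the response window (0-4 s post
    onset) selects a maximum (positive) or minimum (negative) search within
    that window.  The extremum with its 3 neighbors on each side forms the
    response sample; the same-type extremum within the baseline window
    (6-2 s pre onset) with its 6 neighbors forms the baseline sample.  The
    effect size is the difference of sample means over the mean of the two
    sample standard deviations; |ES| > 5 marks a significant response.
    """
    trace = np.asarray(mean_trace, dtype=float)
    n = len(trace)
    ra, rb = _window_indices(onset_frame, frame_rate, response_window, n)
    ba, bb = _window_indices(onset_frame, frame_rate, baseline_window, n)
    # integral measured against the pre-stimulus level so that the
    # excited/suppressed decision is invariant to a constant offset; on a
    # dF/F trace (baseline ~ 0) this equals the plain window integral
    integral = (trace[ra:rb] - trace[ba:bb].mean()).sum() / frame_rate
    magnitude = response_magnitude(trace, frame_rate, onset_frame)

    # a constant trace accumulates ~1e-16 round-off in the integral; treat
    # integrals negligible relative to the trace scale as no response
    tol = 1e-9 * max(float(np.abs(trace).max()), 1e-300) * (rb - ra) / frame_rate
    if abs(integral) <= tol:
        return ResponseCall(cell_id, odor_id, 0.0, "none", False, magnitude,
                            float(trace[ra]), ra)

    sign: Sign = "excited" if integral > 0 else "suppressed"
    pick = np.argmax if sign == "excited" else np.argmin
    # earliest frame wins ties (argmax/argmin return the first occurrence)
    ext = ra + int(pick(trace[ra:rb]))
    bext = ba + int(pick(trace[ba:bb]))
    resp_sample, trunc_r = _sample_around(trace, ext)
    base_sample, trunc_b = _sample_around(trace, bext)

    sd_pool = 0.5 * (resp_sample.std(ddof=1) + base_sample.std(ddof=1))
    diff = resp_sample.mean() - base_sample.mean()
    # constant samples yield std ~ 1e-17, not 0, from round-off
    sample_scale = max(np.abs(resp_sample).max(), np.abs(base_sample).max(), 1e-300)
    degenerate = sd_pool <= 1e-12 * sample_scale
    if degenerate:
        es = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        es = float(diff / sd_pool)
    return ResponseCall(
        cell_id, odor_id, es, sign,
        significant=abs(es) > es_threshold,
        magnitude=magnitude,
        extremum_value=float(trace[ext]),
        extremum_frame=ext,
        truncated=trunc_r or trunc_b,
        degenerate=degenerate,
    )


def response_magnitude(
    mean_trace: np.ndarray,
    frame_rate: float,
    onset_frame: int,
    window: tuple[float, float] = MAGNITUDE_WINDOW,
) -> float:
    """Signed integral (Riemann sum) of the mean trace 0-5 s post onset."""
    trace = np.asarray(mean_trace, dtype=float)
    a, b = _window_indices(onset_frame, frame_rate, window, len(trace))
    return float(trace[a:b].sum() / frame_rate)


# ---------------------------------------------------------------------------
# Exact permutation comparison
# ---------------------------------------------------------------------------

def _split_masks(n1: int, n2: int) -> np.ndarray:
    """Boolean masks (one per equal-split relabeling) selecting sample 1."""
    idx = list(itertools.combinations(range(n1 + n2), n1))
    masks = np.zeros((len(idx), n1 + n2), dtype=bool)
    for r, cols in enumerate(idx):
        masks[r, list(cols)] = True
    return masks


def compare_before_after(
    trial_means_before: Sequence[float], trial_means_after: Sequence[float]
) -> float:
    """Exact two-sided permutation p-value for two small samples.

    The statistic is the absolute difference of sample means; all
    C(n1+n2, n1) relabelings are enumerated (252 for 5+5), so p-values are
    exact multiples of 1/N_partitions.
    """
    a = np.asarray(trial_means_before, dtype=float)
    b = np.asarray(trial_means_after, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each condition needs at least 2 trials")
    pooled = np.concatenate([a, b])
    masks = _split_masks(len(a), len(b))
    stat_obs = abs(a.mean() - b.mean())
    stats = np.abs(
        pooled @ masks.T / len(a) - pooled @ (~masks).T / len(b)
    )
    return float(np.mean(stats >= stat_obs - 1e-12))


def permutation_pvalues(before: np.ndarray, after: np.ndarray) -> np.ndarray:
    """Vectorized exact permutation p-values for many 5+5-style pairs.

    ``before`` and ``after`` have shape (n_pairs, n_trials).
    """
    a = np.asarray(before, dtype=float)
    b = np.asarray(after, dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    pooled = np.concatenate([a, b], axis=1)  # (n_pairs, n1+n2)
    masks = _split_masks(n1, n2).astype(float)
    stats = np.abs(pooled @ masks.T / n1 - pooled @ (1.0 - masks).T / n2)
    obs = np.abs(a.mean(axis=1) - b.mean(axis=1))
    return (stats >= obs[:, None] - 1e-12).mean(axis=1)


# ---------------------------------------------------------------------------
# Session-level analysis
# ---------------------------------------------------------------------------

def trial_response_means(
    session: ImagingSession,
    *,
    window: tuple[float, float] = RESPONSE_WINDOW,
    span: int = SMOOTH_SPAN,
) -> np.ndarray:
    """Per-trial mean smoothed dF/F over the response window.

    Returns shape (n_cells, n_odors, n_trials); these are the per-trial
    scalars entering both the permutation test and the population response
    clouds.
    """
    dff = smooth_trace(compute_dff(session), span=span)
    sl = session.window_slice(*window)
    return dff[..., sl].mean(axis=-1)


def analyze_session(
    session: ImagingSession,
    *,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    es_threshold: float = ES_THRESHOLD,
    span: int = SMOOTH_SPAN,
) -> list[list[ResponseCall]]:
    """Run detection for every cell-odor pair; calls[cell][odor]."""
    dff = compute_dff(session)
    mean_traces = mean_smoothed_trace(dff, span=span)  # (cells, odors, frames)
    calls: list[list[ResponseCall]] = []
    for c in range(session.n_cells):
        row = []
        for o in range(session.n_odors):
            row.append(
                detect_response(
                    mean_traces[c, o], session.frame_rate, session.onset_frame,
                    response_window=response_window,
                    baseline_window=baseline_window,
                    es_threshold=es_threshold,
                    cell_id=str(session.cell_ids[c]),
                    odor_id=str(session.odor_ids[o]),
                )
            )
        calls.append(row)
    return calls


def responsiveness(calls: list[list[ResponseCall]]) -> np.ndarray:
    """Number of odors with a significant call, per cell."""
    return np.array([sum(c.significant for c in row) for row in calls])


def classify_pairs(
    session_before: ImagingSession,
    session_after: ImagingSession,
    *,
    response_window: tuple[float, float] = RESPONSE_WINDOW,
    permutation_window: tuple[float, float] | None = None,
    baseline_window: tuple[float, float] = BASELINE_WINDOW,
    es_threshold: float = ES_THRESHOLD,
    span: int = SMOOTH_SPAN,
    alpha: float = 0.05,
) -> tuple[list[PairedResponse], dict[str, list[PairedResponse]]]:
    """Pair cell-odor responses across conditions and build response pools.

    Every pair with a significant excited (suppressed) call in either
    condition joins the excited (suppressed) pool together with its couple,
    regardless of the couple's classification; a pair that flips sign
    between conditions appears in both pools.  Permutation p-values are
    computed only for pairs with at least one significant call.
    """
    sb, sa = session_before, session_after
    if (sb.n_cells, sb.n_odors, sb.n_trials) != (sa.n_cells, sa.n_odors, sa.n_trials):
        raise ValueError("sessions are structurally different")
    if tuple(sb.cell_ids) != tuple(sa.cell_ids) or tuple(sb.odor_ids) != tuple(sa.odor_ids):
        raise ValueError("cell/odor sets differ between sessions")
    perm_window = permutation_window or response_window
    kw = dict(response_window=response_window, baseline_window=baseline_window,
              es_threshold=es_threshold, span=span)
    calls_b = analyze_session(sb, **kw)
    calls_a = analyze_session(sa, **kw)
    tm_b = trial_response_means(sb, window=perm_window, span=span)
    tm_a = trial_response_means(sa, window=perm_window, span=span)

    paired: list[PairedResponse] = []
    pools: dict[str, list[PairedResponse]] = {"excited": [], "suppressed": []}
    for c in range(sb.n_cells):
        for o in range(sb.n_odors):
            cb, ca = calls_b[c][o], calls_a[c][o]
            any_sig = cb.significant or ca.significant
            p = compare_before_after(tm_b[c, o], tm_a[c, o]) if any_sig else None
            pr = PairedResponse(
                cell_id=cb.cell_id, odor_id=cb.odor_id,
                call_before=cb, call_after=ca, perm_p=p,
                delta_magnitude=ca.magnitude - cb.magnitude,
                changed=(p is not None and p < alpha),
            )
            paired.append(pr)
            for sign in ("excited", "suppressed"):
                if (cb.significant and cb.sign == sign) or (
                    ca.significant and ca.sign == sign
                ):
                    pools[sign].append(pr)
    return paired, pools


# ---------------------------------------------------------------------------
# Tuning curves and sharpening
# ---------------------------------------------------------------------------

def tuning_summary(magnitudes: np.ndarray, condition: str = "") -> TuningSummary:
    """Tuning summary from a (n_cells, n_odors) magnitude matrix.

    All cell-odor pairs are ranked and included regardless of significance.
    """
    m = np.asarray(magnitudes, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a (n_cells, n_odors>=2) magnitude matrix")
    ranked = np.sort(m, axis=1)[:, ::-1]
    return TuningSummary(condition, ranked, m.std(axis=1, ddof=1))


def session_tuning(session: ImagingSession, span: int = SMOOTH_SPAN) -> TuningSummary:
    """Tuning summary of a session from 0-5 s response-magnitude integrals."""
    dff = compute_dff(session)
    mean_traces = mean_smoothed_trace(dff, span=span)
    mags = np.array(
        [
            [
                response_magnitude(mean_traces[c, o], session.frame_rate, session.onset_frame)
                for o in range(session.n_odors)
            ]
            for c in range(session.n_cells)
        ]
    )
    return tuning_summary(mags, session.condition)


def estimate_sharpening(
    summary_before: TuningSummary, summary_after: TuningSummary
) -> SharpeningEstimate:
    """Population sharpening ratio Avg[sd_before] / Avg[sd_after].

    Confidence borders are the minimum and maximum of
    (Avg_before +/- SEM_before) / (Avg_after -/+ SEM_after).
    """
    if len(summary_before.tuning_sd) != len(summary_after.tuning_sd):
        raise ValueError("summaries cover different cell sets")
    ab, sb = summary_before.mean_sd, summary_before.sem_sd
    aa, sa = summary_after.mean_sd, summary_after.sem_sd
    if aa == 0:
        raise ValueError("zero mean tuning std in the denominator condition")
    ratios = [
        (ab + eb * sb) / (aa + ea * sa)
        for eb in (-1.0, 1.0)
        for ea in (-1.0, 1.0)
        if aa + ea * sa > 0
    ]
    return SharpeningEstimate(ab / aa, min(ratios), max(ratios))


# ---------------------------------------------------------------------------
# Baseline activity
# ---------------------------------------------------------------------------

def _baseline_points(
    session: ImagingSession, window: tuple[float, float], n_points: int
) -> tuple[np.ndarray, bool]:
    """Per-cell mean background-relative fluorescence over pre-stimulus points.

    Frames are drawn from the ``window`` (default 3-5 s before onset) of each
    stimulus presentation in order, concatenated until ``n_points`` samples
    are collected.
    """
    if session.background is None:
        raise ValueError("session has no background trace")
    sl = session.window_slice(*window)
    bg = np.asarray(session.background, dtype=float)[sl]
    # relative to background: ratio of cell fluorescence to the background ROI
    rel = session.fluorescence[..., sl] / bg  # (cells, odors, trials, w)
    # presentation order: trials are the outer loop of an imaging session
    rel = rel.transpose(0, 2, 1, 3).reshape(session.n_cells, -1)
    flagged = rel.shape[1] < n_points
    return rel[:, :n_points].mean(axis=1), flagged


def baseline_shift(
    session_before: ImagingSession,
    session_after: ImagingSession,
    *,
    window: tuple[float, float] = (-5.0, -3.0),
    n_points: int = 60,
) -> tuple[np.ndarray, bool]:
    """Per-cell change in background-relative baseline fluorescence.

    Positive values mean the baseline increased in the second condition.
    Returns (shifts, flagged) where ``flagged`` reports that fewer than
    ``n_points`` pre-stimulus frames were available.
    """
    vb, fb = _baseline_points(session_before, window, n_points)
    va, fa = _baseline_points(session_after, window, n_points)
    return va - vb, fb or fa
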