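"""Synthetic two-photon imaging sessions with known ground truth.

The generator emulates the structure of mitral-cell calcium recordings:
7 Hz acquisition, 2-s odor stimuli, 11 odors x 5 trials, excited and
suppressed double-exponential transients, per-frame Gaussian noise, and a
paired "after" condition whose response amplitudes are scaled by a
quenching factor and whose raw baseline may be shifted.  Raw traces are
synthesized as f = f0_cell * (1 + dF/F), with per-cell f0 drawn uniformly
in [100, 1000] a.u., so the dF/F stage of the pipeline is genuinely
exercised.

It does not model spike-to-calcium biophysics, sniffing, motion artifacts
or neuropil contamination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .traces import ImagingSession

__all__ = ["SynthConfig", "GroundTruth", "generate_model_odors", "generate_session_pair"]

_F0_RANGE = (100.0, 1000.0)
_BACKGROUND_LEVEL = 50.0
_MIN_AMP = 0.05
_MAX_AMP = 0.9  # keeps suppressed dF/F above -1


@dataclass
class SynthConfig:
    """Parameters of a paired synthetic before/after imaging experiment."""

    n_cells: int = 50
    n_odors: int = 11
    n_trials: int = 5
    frame_rate: float = 7.0
    pre_s: float = 6.0
    stim_s: float = 2.0
    post_s: float = 8.0
    p_excited: float = 0.3
    p_suppressed: float = 0.2
    amp_mean: float = 0.6  # dF/F peak amplitude
    amp_sd: float = 0.2
    tau_rise: float = 0.15  # s
    tau_decay: float = 0.8  # s, GCaMP6f-like decay
    noise_sd: float = 0.05  # per-frame additive noise, dF/F units
    quench_factor: float = 1.0  # "after" amplitudes = before * quench_factor
    baseline_shift: float = 0.0  # additive raw-baseline offset (dF/F of f0) in "after"
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cells, self.n_odors, self.n_trials) < 1:
            raise ValueError("counts must be positive")
        if not (0 <= self.p_excited <= 1 and 0 <= self.p_suppressed <= 1):
            raise ValueError("response probabilities must lie in [0, 1]")
        if self.p_excited + self.p_suppressed > 1:
            raise ValueError("p_excited + p_suppressed must not exceed 1")
        if min(self.frame_rate, self.tau_rise, self.tau_decay, self.stim_s) <= 0:
            raise ValueError("rates and time constants must be positive")
        if self.tau_rise >= self.tau_decay:
            raise ValueError("tau_rise must be smaller than tau_decay")
        if self.quench_factor < 0:
            raise ValueError("quench_factor must be non-negative")
        if self.noise_sd < 0 or self.amp_sd < 0:
            raise ValueError("noise_sd and amp_sd must be non-negative")
        if self.pre_s < 6.0 or self.stim_s + self.post_s < 5.0:
            raise ValueError(
                "recording shorter than the analysis windows: need >= 6 s "
                "pre-stimulus and >= 5 s post-onset"
            )

    @property
    def n_frames(self) -> int:
        return int(round((self.pre_s + self.stim_s + self.post_s) * self.frame_rate))

    @property
    def onset_frame(self) -> int:
        return int(round(self.pre_s * self.frame_rate))


@dataclass
class GroundTruth:
    """True response structure behind a generated session pair."""

    sign: np.ndarray  # (cells, odors) in {+1, -1, 0}
    amp_before: np.ndarray  # (cells, odors) peak dF/F amplitude
    amp_after: np.ndarray  # = amp_before * quench_factor
    f0: np.ndarray  # (cells,) raw baseline fluorescence
    kernel: np.ndarray  # (n_frames,) unit-peak transient, aligned to the trial
    quench_factor: float = 1.0
    baseline_shift: float = 0.0
    background_level: float = _BACKGROUND_LEVEL
    kernel_integral_s: float = field(init=False)

    def __post_init__(self) -> None:
        self.kernel_integral_s = float(self.kernel.sum())  # set properly below


def generate_model_odors(n_mc: int, n_odors: int, seed: int) -> np.ndarray:
    """Odor input matrix z of shape (n_mc, n_odors), i.i.d. standard normal."""
    if n_mc < 1 or n_odors < 1:
        raise ValueError("n_mc and n_odors must be positive")
    return np.random.default_rng(seed).standard_normal((n_mc, n_odors))


def _transient_kernel(config: SynthConfig) -> np.ndarray:
    """Unit-peak difference-of-exponentials transient starting at odor onset."""
    n = config.n_frames
    t = (np.arange(n) - config.onset_frame) / config.frame_rate
    k = np.where(
        t >= 0,
        np.exp(-np.maximum(t, 0) / config.tau_decay)
        - np.exp(-np.maximum(t, 0) / config.tau_rise),
        0.0,
    )
    peak = k.max()
    if peak <= 0:  # degenerate timing; cannot happen with validated config
        raise ValueError("transient kernel has no positive peak")
    return k / peak


def _session(
    config: SynthConfig,
    dff_signal: np.ndarray,
    condition: str,
    shift: float,
    f0: np.ndarray,
    noise_rng: np.random.Generator,
) -> ImagingSession:
    shape = (config.n_cells, config.n_odors, config.n_trials, config.n_frames)
    noise = (
        noise_rng.normal(0.0, config.noise_sd, size=shape)
        if config.noise_sd > 0
        else np.zeros(shape)
    )
    dff = dff_signal[:, :, None, :] + noise
    raw = f0[:, None, None, None] * (1.0 + dff + shift)
    return ImagingSession(
        fluorescence=raw,
        frame_rate=config.frame_rate,
        onset_frame=config.onset_frame,
        condition=condition,
        subject_id=f"synth-{config.seed}",
        stim_s=config.stim_s,
        background=np.full(config.n_frames, _BACKGROUND_LEVEL),
    )


def generate_session_pair(
    config: SynthConfig,
) -> tuple[ImagingSession, ImagingSession, GroundTruth]:
    """Paired before/after sessions sharing response identities.

    Response signs and amplitudes are drawn from a stream keyed by the
    config seed alone, so both conditions share them; frame noise comes from
    streams keyed by (seed, condition).  "After" amplitudes equal "before"
    amplitudes times ``quench_factor``, and the raw "after" baseline is
    offset by ``baseline_shift`` (in units of each cell's f0).
    """
    shared = np.random.default_rng(config.seed)
    f0 = shared.uniform(*_F0_RANGE, size=config.n_cells)
    u = shared.uniform(size=(config.n_cells, config.n_odors))
    sign = np.where(
        u < config.p_excited, 1, np.where(u < config.p_excited + config.p_suppressed, -1, 0)
    )
    amp = np.clip(
        shared.normal(config.amp_mean, config.amp_sd, size=sign.shape), _MIN_AMP, _MAX_AMP
    )
    amp_before = np.abs(sign) * amp
    amp_after = amp_before * config.quench_factor

    kernel = _transient_kernel(config)
    sig_before = (sign * amp_before)[:, :, None] * kernel
    sig_after = (sign * amp_after)[:, :, None] * kernel

    before = _session(
        config, sig_before, "before", 0.0, f0, np.random.default_rng([config.seed, 0])
    )
    after = _session(
        config, sig_after, "after", config.baseline_shift, f0,
        np.random.default_rng([config.seed, 1]),
    )
    truth = GroundTruth(
        sign=sign,
        amp_before=amp_before,
        amp_after=amp_after,
        f0=f0,
        kernel=kernel,
        quench_factor=config.quench_factor,
        baseline_shift=config.baseline_shift,
    )
    truth.kernel_integral_s = float(kernel.sum() / config.frame_rate)
    return before, after, truth
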