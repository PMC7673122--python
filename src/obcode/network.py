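"""Recurrent olfactory-bulb network: mitral cells inhibited by granule cells.

Linear firing-rate model of the mitral-cell (MC) / granule-cell (GC) /
adult-born granule-cell (abGC) circuit.  Neurons of each population sit
uniformly on a ring; connection strength between two neurons falls off as a
Gaussian of their wrap-around angular distance with peak J and width sigma.
abGCs share the output connectivity of mature GCs but have broader input
connectivity (factor b) and higher excitability (gain g); their efficacy is
g_eff = b * g.

MCs receive baseline input I0 plus odor input I1 * z (z i.i.d. standard
normal per MC per odor) and recurrent inhibition from both GC populations.
Because all transfer functions are linear the self-consistent rates solve a
single n_mc-dimensional linear system; no dynamics are integrated.  Rates
may go negative (no rectification) — a warning is emitted when they do.

The model reduces to three effective parameters: the abGC fraction f, the
efficacy g_eff, and the mean MC lateral inhibition J_eff = J0_out * J0_in
where J0 = J * sigma / sqrt(2*pi) is the ring-averaged connection strength.
Closed forms follow for MC tuning (std of the normalized response over
odors) with the full circuit, tuning after silencing all abGCs, and the
sharpening ratios between those conditions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

__all__ = [
    "NetworkParams",
    "Connectivity",
    "NetworkSolution",
    "EffectiveParams",
    "build_connectivity",
    "solve_rates",
    "silence",
    "effective_params",
    "mean_connection_strength",
    "inhibition_factor",
    "sharpening_abgcs",
    "constraint_curve",
    "asymptotic_geff",
    "population_tuning",
]

SilenceTarget = Literal["abgc", "mature_gc"]

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_BLOCK = 4096  # granule neurons per block when forming effective inhibition


@dataclass(frozen=True)
class NetworkParams:
    """Model configuration.

    Desk-scale defaults keep the biological ratios of the reference circuit:
    500 MCs, a 1:40 MC:granule ratio, and abGCs at 2.5% of the 20,000-cell
    granule population (19,500 mature + 500 adult-born).
    """

    n_mc: int = 500
    n_gc: int = 19500
    n_abgc: int = 500
    j_peak: float = 10.0  # peak connection strength, all population pairs
    sigma_gc_mc: float = 0.5  # width of GC <- MC input profile, radians
    sigma_mc_gc: float = 0.5  # width of MC <- GC output profile, radians
    b: float = 3.0  # abGC input broadness ratio (sigma_abgc<-mc = b * sigma_gc<-mc)
    g: float = 5.0  # abGC excitability ratio
    i0: float = 1.0  # baseline input
    i1: float = 0.1  # odor input scale
    silence_target: SilenceTarget | None = None
    silence_fraction: float = 0.0

    def __post_init__(self) -> None:
        if min(self.n_mc, self.n_gc) < 1 or self.n_abgc < 0:
            raise ValueError("population sizes must be positive")
        if self.sigma_gc_mc <= 0 or self.sigma_mc_gc <= 0:
            raise ValueError("connectivity widths must be positive")
        if self.b < 1 or self.g < 1:
            raise ValueError("abGC broadness b and excitability g must be >= 1")
        if self.i0 <= 0:
            raise ValueError("baseline input I0 must be positive")
        if not 0.0 <= self.silence_fraction <= 1.0:
            raise ValueError("silence_fraction must lie in [0, 1]")

    @property
    def f(self) -> float:
        """abGC fraction of the total granule population."""
        return self.n_abgc / (self.n_gc + self.n_abgc)

    @property
    def sigma_abgc_mc(self) -> float:
        return self.b * self.sigma_gc_mc

    @property
    def sigma_mc_abgc(self) -> float:
        # abGC output connectivity matches mature GCs
        return self.sigma_mc_gc


def mean_connection_strength(j_peak: float, sigma: float) -> float:
    """Ring-averaged connection strength J0 = J * sigma / sqrt(2*pi)."""
    return j_peak * sigma / _SQRT_2PI


def _wrap_distance(theta_a: np.ndarray, theta_b: np.ndarray) -> np.ndarray:
    d = np.abs(theta_a[:, None] - theta_b[None, :])
    return np.minimum(d, 2.0 * math.pi - d)


def _gaussian_weights(
    theta_post: np.ndarray, theta_pre: np.ndarray, j_peak: float, sigma: float
) -> np.ndarray:
    d = _wrap_distance(theta_post, theta_pre)
    return j_peak * np.exp(-(d**2) / (2.0 * sigma**2))


@dataclass
class Connectivity:
    """Neuron positions plus on-demand Gaussian weight matrices."""

    params: NetworkParams
    theta_mc: np.ndarray
    theta_gc: np.ndarray
    theta_abgc: np.ndarray

    def theta(self, pop: str) -> np.ndarray:
        return {"mc": self.theta_mc, "gc": self.theta_gc, "abgc": self.theta_abgc}[pop]

    def sigma(self, post: str, pre: str) -> float:
        p = self.params
        table = {
            ("gc", "mc"): p.sigma_gc_mc,
            ("abgc", "mc"): p.sigma_abgc_mc,
            ("mc", "gc"): p.sigma_mc_gc,
            ("mc", "abgc"): p.sigma_mc_abgc,
        }
        return table[(post, pre)]

    def weights(
        self, post: str, pre: str, pre_idx: np.ndarray | None = None
    ) -> np.ndarray:
        """Weight matrix J[post <- pre], optionally for a subset of pre cells."""
        tp = self.theta(pre)
        if pre_idx is not None:
            tp = tp[pre_idx]
        return _gaussian_weights(self.theta(post), tp, self.params.j_peak,
                                 self.sigma(post, pre))


def build_connectivity(
    params: NetworkParams,
    seed: int | None = None,
    placement: Literal["grid", "random"] = "grid",
) -> Connectivity:
    """Place the three populations uniformly on [0, 2*pi).

    The default placement is an even grid ("arranged uniformly on a ring"),
    which makes the ring-average property J0 = J*sigma/sqrt(2*pi) hold to
    discretization accuracy; ``placement="random"`` draws i.i.d. uniform
    positions using ``seed`` instead.
    """
    if placement == "grid":
        pos = lambda n: np.arange(n) * (2.0 * math.pi / n)
    else:
        rng = np.random.default_rng(seed)
        pos = lambda n: rng.uniform(0.0, 2.0 * math.pi, size=n)
    return Connectivity(params, pos(params.n_mc), pos(params.n_gc), pos(params.n_abgc))


def silence(
    params: NetworkParams, target: SilenceTarget, fraction: float
) -> NetworkParams:
    """Clamp a fraction of one granule subpopulation to zero rate.

    Silenced cells stay in the network (the #GC + #abGC normalizer is
    unchanged) but emit no inhibition — mimicking chemogenetic silencing
    rather than ablation.
    """
    if target not in ("abgc", "mature_gc"):
        raise ValueError("target must be 'abgc' or 'mature_gc'")
    return replace(params, silence_target=target, silence_fraction=float(fraction))


def _silenced_mask(n: int, fraction: float) -> np.ndarray:
    """Boolean mask of active cells; silenced indices are evenly spaced."""
    active = np.ones(n, dtype=bool)
    k = int(round(fraction * n))
    if k > 0:
        active[(np.arange(k) * n // max(k, 1)).astype(int)] = False
    return active


def _active_masks(params: NetworkParams) -> tuple[np.ndarray, np.ndarray]:
    gc = np.ones(params.n_gc, dtype=bool)
    ab = np.ones(params.n_abgc, dtype=bool)
    if params.silence_target == "mature_gc":
        gc = _silenced_mask(params.n_gc, params.silence_fraction)
    elif params.silence_target == "abgc":
        ab = _silenced_mask(params.n_abgc, params.silence_fraction)
    return gc, ab


@dataclass
class NetworkSolution:
    """Self-consistent firing rates for a set of odors."""

    params: NetworkParams
    r_mc: np.ndarray  # (n_mc, n_odors)
    r_baseline: np.ndarray  # (n_mc,), z = 0
    response: np.ndarray  # (n_mc, n_odors) normalized response R
    h_gc: np.ndarray  # (n_gc, n_odors) inputs (silenced rows included)
    h_abgc: np.ndarray
    r_gc: np.ndarray  # rates; zero for silenced cells
    r_abgc: np.ndarray
    negative_rate_fraction: float = 0.0


def _effective_inhibition(conn: Connectivity, params: NetworkParams) -> np.ndarray:
    """MC->MC inhibition matrix W from the two granule loops, in GC blocks."""
    n_mc = params.n_mc
    n_gran = params.n_gc + params.n_abgc
    active_gc, active_ab = _active_masks(params)
    w = np.zeros((n_mc, n_mc))
    for pop, gain, active in (("gc", 1.0, active_gc), ("abgc", params.g, active_ab)):
        idx = np.nonzero(active)[0]
        for start in range(0, len(idx), _BLOCK):
            block = idx[start: start + _BLOCK]
            tp = conn.theta(pop)[block]
            j_in = _gaussian_weights(tp, conn.theta_mc, params.j_peak,
                                     conn.sigma(pop, "mc"))
            j_out = _gaussian_weights(conn.theta_mc, tp, params.j_peak,
                                      conn.sigma("mc", pop))
            w += gain * (j_out @ j_in)
    return w / (n_gran * n_mc)


def _granule_rates(
    conn: Connectivity, params: NetworkParams, r_mc: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Inputs and rates of both granule populations given MC rates."""
    active_gc, active_ab = _active_masks(params)
    out = []
    for pop, gain, active in (("gc", 1.0, active_gc), ("abgc", params.g, active_ab)):
        n = len(conn.theta(pop))
        h = np.empty((n, r_mc.shape[1]))
        for start in range(0, n, _BLOCK):
            tp = conn.theta(pop)[start: start + _BLOCK]
            j_in = _gaussian_weights(tp, conn.theta_mc, params.j_peak,
                                     conn.sigma(pop, "mc"))
            h[start: start + _BLOCK] = j_in @ r_mc / params.n_mc
        r = gain * h
        r[~active] = 0.0
        out.extend([h, r])
    return out[0], out[2], out[1], out[3]  # h_gc, h_abgc, r_gc, r_abgc


def solve_rates(
    conn: Connectivity, params: NetworkParams, z: np.ndarray
) -> NetworkSolution:
    """Solve the linear fixed point for MC rates and recover granule rates.

    ``z`` is the (n_mc, n_odors) odor input matrix.  The baseline solution
    uses z = 0 and defines the normalized response
    R = (r(odor) - r(0)) / r(0).
    """
    z = np.asarray(z, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    if z.shape[0] != params.n_mc:
        raise ValueError("z must have n_mc rows")
    w = _effective_inhibition(conn, params)
    a = np.eye(params.n_mc) + w
    rhs = np.concatenate(
        [np.full((params.n_mc, 1), params.i0), params.i0 + params.i1 * z], axis=1
    )
    try:
        sol = np.linalg.solve(a, rhs)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "singular rate equations: recurrent inhibition cancels the identity"
        ) from exc
    r0, r_mc = sol[:, 0], sol[:, 1:]
    neg = float((r_mc < 0).mean())
    if neg > 0 or (r0 <= 0).any():
        warnings.warn(
            f"{neg:.1%} of MC rates are negative (linear model, no rectification)",
            RuntimeWarning,
            stacklevel=2,
        )
    response = (r_mc - r0[:, None]) / r0[:, None]
    h_gc, h_abgc, r_gc, r_abgc = _granule_rates(conn, params, r_mc)
    return NetworkSolution(
        params=params, r_mc=r_mc, r_baseline=r0, response=response,
        h_gc=h_gc, h_abgc=h_abgc, r_gc=r_gc, r_abgc=r_abgc,
        negative_rate_fraction=neg,
    )


def population_tuning(solution: NetworkSolution) -> float:
    """Population-mean MC tuning: mean over MCs of std of R over odors."""
    return float(solution.response.std(axis=1, ddof=1).mean())


# ---------------------------------------------------------------------------
# Closed forms
# ---------------------------------------------------------------------------

def inhibition_factor(params: NetworkParams) -> float:
    """1 + J_eff * (active-granule mixture), the tuning amplification factor.

    With no silencing the mixture is (1-f) + g_eff*f; silencing scales the
    targeted subpopulation's contribution while the normalizer stays fixed.
    """
    j_eff = _j_eff(params)
    g_eff = params.b * params.g
    f = params.f
    s_m = params.silence_fraction if params.silence_target == "mature_gc" else 0.0
    s_a = params.silence_fraction if params.silence_target == "abgc" else 0.0
    mix = (1.0 - f) * (1.0 - s_m) + g_eff * f * (1.0 - s_a)
    return 1.0 + j_eff * mix


def _j_eff(params: NetworkParams) -> float:
    return mean_connection_strength(params.j_peak, params.sigma_mc_gc) * (
        mean_connection_strength(params.j_peak, params.sigma_gc_mc)
    )


def sharpening_abgcs(j_eff: float, g_eff: float, f: float) -> float:
    """Sharpening from abGCs: tuning(intact) / tuning(all abGCs silenced)."""
    return (1.0 + j_eff * (1.0 + (g_eff - 1.0) * f)) / (1.0 + j_eff * (1.0 - f))


@dataclass
class EffectiveParams:
    """Reduced model: three parameters and the tuning/sharpening they imply."""

    j_eff: float
    g_eff: float
    f: float
    tuning_input: float  # I1 / I0
    tuning_before: float
    tuning_after: float  # all abGCs silenced
    sharpening_all_gcs: float
    sharpening_abgcs: float


def effective_params(params: NetworkParams) -> EffectiveParams:
    """Closed-form reduction of the network to (J_eff, g_eff, f)."""
    j_eff = _j_eff(params)
    g_eff = params.b * params.g
    f = params.f
    tin = params.i1 / params.i0
    s_all = 1.0 + j_eff * (1.0 + (g_eff - 1.0) * f)
    t_before = tin * s_all
    t_after = tin * (1.0 + j_eff * (1.0 - f))
    return EffectiveParams(
        j_eff=j_eff, g_eff=g_eff, f=f, tuning_input=tin,
        tuning_before=t_before, tuning_after=t_after,
        sharpening_all_gcs=s_all,
        sharpening_abgcs=sharpening_abgcs(j_eff, g_eff, f),
    )


def constraint_curve(
    sharpening: float,
    f: float,
    j_eff_grid: np.ndarray,
    *,
    ci_low: float | None = None,
    ci_high: float | None = None,
) -> dict[str, np.ndarray]:
    """Invert the sharpening relation for g_eff along a J_eff grid.

    A measured sharpening S constrains a curve g_eff(J_eff); the optional
    confidence borders constrain a band around it.  Grid points where the
    required g_eff would be <= 1 are marked infeasible (NaN).
    """
    if sharpening <= 1.0:
        raise ValueError("sharpening must exceed 1 to constrain abGC efficacy")
    grid = np.asarray(j_eff_grid, dtype=float)

    def invert(s: float) -> np.ndarray:
        g = 1.0 + (s * (1.0 + grid * (1.0 - f)) - 1.0 - grid) / (grid * f)
        return np.where(g > 1.0, g, np.nan)

    out = {"j_eff": grid, "g_eff": invert(sharpening)}
    if ci_low is not None:
        out["g_eff_low"] = invert(ci_low) if ci_low > 1.0 else np.full_like(grid, np.nan)
    if ci_high is not None:
        out["g_eff_high"] = invert(ci_high)
    return out


def asymptotic_geff(sharpening: float, f: float) -> float:
    """J_eff -> infinity limit of the g_eff needed for a given sharpening.

    At the boundary sharpening = 1/(1-f) the limit is exactly 1 (ordinary
    granule cells suffice); below it no efficacy achieves the sharpening.
    """
    excess = sharpening * (1.0 - f) - 1.0
    if excess < -1e-12:
        raise ValueError("sharpening * (1 - f) must be at least 1 for a finite limit")
    return 1.0 + max(excess, 0.0) / f
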