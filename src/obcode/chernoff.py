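"""Chernoff-distance discriminability under Poisson trial noise.

Trial-to-trial spike-count noise of a mitral cell is modelled as Poisson
with mean equal to its odor-evoked rate.  For two Poisson distributions
with means lambda1, lambda2 the Chernoff distance has the closed form

    D_c = max_alpha [ alpha*l1 + (1-alpha)*l2 - l1^alpha * l2^(1-alpha) ]

(nats), with an analytic maximizer.  Averaged over random odors the model
gives an expected per-MC Chernoff distance proportional to the same
inhibition factor that amplifies tuning, which yields the
iso-discrimination curve: the number of MCs required to hold total
discriminability fixed as the abGC fraction f varies, and the fraction
f_half = 1/(2 + rho), rho = J_eff*(g_eff - 1)/(1 + J_eff), at which half
of the total potential MC-count reduction (between an abGC-free and an
all-abGC network) is reached.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq

from .network import (
    NetworkParams,
    build_connectivity,
    effective_params,
    inhibition_factor,
    solve_rates,
)
from .synth import generate_model_odors

__all__ = [
    "ChernoffResult",
    "IsoDiscriminationCurve",
    "chernoff_poisson",
    "chernoff_poisson_array",
    "expected_dc",
    "monte_carlo_dc",
    "iso_discrimination",
]


@dataclass
class ChernoffResult:
    """Chernoff distance between Poisson(lambda1) and Poisson(lambda2)."""

    alpha_star: float
    d_c: float  # nats
    lambda1: float
    lambda2: float
    degenerate: bool = False  # both rates zero


@dataclass
class IsoDiscriminationCurve:
    """MC count required to hold total Chernoff distance at a reference."""

    f_grid: np.ndarray
    n_mc: np.ndarray
    expected_dc: np.ndarray
    reference_n_mc: int
    reference_f: float
    reference_total: float
    f_half: float | None  # closed form 1/(2 + rho); None when g_eff = 1
    f_half_numeric: float | None
    rho: float


def chernoff_poisson(lambda1: float, lambda2: float) -> ChernoffResult:
    """Closed-form Chernoff distance for two Poisson means (nats)."""
    l1, l2 = float(lambda1), float(lambda2)
    if l1 < 0 or l2 < 0:
        raise ValueError("Poisson rates must be non-negative")
    if l1 == l2:
        return ChernoffResult(0.5, 0.0, l1, l2, degenerate=(l1 == 0.0))
    if l1 == 0.0 or l2 == 0.0:
        # the non-zero distribution against a point mass at zero:
        # D_alpha = alpha * lambda, supremum at alpha -> 1
        return ChernoffResult(1.0, max(l1, l2), l1, l2)
    log_ratio = math.log(l1 / l2)
    geo = (l1 - l2) / log_ratio  # optimal l1^a * l2^(1-a)
    alpha = math.log(geo / l2) / log_ratio
    d_c = alpha * l1 + (1.0 - alpha) * l2 - geo
    return ChernoffResult(alpha, d_c, l1, l2)


def chernoff_poisson_array(lambda1: np.ndarray, lambda2: np.ndarray) -> np.ndarray:
    """Vectorized Chernoff distances for arrays of Poisson means."""
    l1 = np.asarray(lambda1, dtype=float)
    l2 = np.asarray(lambda2, dtype=float)
    if (l1 < 0).any() or (l2 < 0).any():
        raise ValueError("Poisson rates must be non-negative")
    out = np.zeros(np.broadcast_shapes(l1.shape, l2.shape))
    l1, l2 = np.broadcast_arrays(l1, l2)
    zero = (l1 == 0.0) | (l2 == 0.0)
    out[zero] = np.maximum(l1, l2)[zero]
    reg = ~zero & (l1 != l2)
    a, b = l1[reg], l2[reg]
    lr = np.log(a / b)
    geo = (a - b) / lr
    alpha = np.log(geo / b) / lr
    out[reg] = alpha * a + (1.0 - alpha) * b - geo
    out[(l1 == l2)] = 0.0
    return out


def expected_dc(params: NetworkParams) -> float:
    """Expected per-MC Chernoff distance between two typical odors (nats).

    Small-signal closed form (I1^2 / 4*I0) * inhibition factor; the factor
    respects any silencing recorded in ``params``.
    """
    return params.i1**2 / (4.0 * params.i0) * inhibition_factor(params)


def monte_carlo_dc(
    params: NetworkParams, n_odors: int = 20, seed: int = 0
) -> tuple[float, float]:
    """Simulation estimate of the expected per-MC Chernoff distance.

    Solves the network for ``n_odors`` random odors, clips negative rates
    at zero, and averages the Poisson Chernoff distance over all MCs and
    all unordered odor pairs.  Returns (estimate, clipped_fraction); a
    warning is attached when more than 5% of rates were clipped.
    """
    conn = build_connectivity(params)
    z = generate_model_odors(params.n_mc, n_odors, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        sol = solve_rates(conn, params, z)
    rates = np.clip(sol.r_mc, 0.0, None)
    clipped = float((sol.r_mc < 0).mean())
    if clipped > 0.05:
        warnings.warn(
            f"{clipped:.1%} of MC rates clipped at zero before Poisson sampling",
            RuntimeWarning,
            stacklevel=2,
        )
    pairs = list(itertools.combinations(range(n_odors), 2))
    i, j = np.array(pairs).T
    d = chernoff_poisson_array(rates[:, i], rates[:, j])  # (n_mc, n_pairs)
    return float(d.mean()), clipped


def iso_discrimination(
    params: NetworkParams,
    reference_n_mc: int = 1000,
    reference_f: float = 0.025,
    f_grid: np.ndarray | None = None,
) -> IsoDiscriminationCurve:
    """Required MC count vs abGC fraction at fixed total discrimination.

    Total discrimination is n_mc times the expected per-MC Chernoff
    distance (independent neurons are additive).  The curve is anchored at
    the reference point and n_mc(f) = reference_total / expected_dc(f).
    ``f_half`` is the fraction where n_mc reaches the midpoint between the
    f=0 and f=1 endpoints; its closed form 1/(2 + rho) is cross-checked by
    a bracketed numeric solve on the continuous curve.
    """
    if f_grid is None:
        f_grid = np.linspace(0.0, 1.0, 201)
    f_grid = np.asarray(f_grid, dtype=float)
    if (f_grid < 0).any() or (f_grid > 1).any():
        raise ValueError("f_grid must lie within [0, 1]")
    base = replace(params, silence_target=None, silence_fraction=0.0)
    eff = effective_params(base)
    j_eff, g_eff = eff.j_eff, eff.g_eff
    prefactor = base.i1**2 / (4.0 * base.i0)

    def dc_of_f(f: float | np.ndarray) -> np.ndarray:
        return prefactor * (1.0 + j_eff * (1.0 + (g_eff - 1.0) * np.asarray(f)))

    reference_total = reference_n_mc * float(dc_of_f(reference_f))
    n_mc = reference_total / dc_of_f(f_grid)
    rho = j_eff * (g_eff - 1.0) / (1.0 + j_eff)
    if g_eff == 1.0:
        # abGCs indistinguishable from mature GCs: flat curve, no midpoint
        return IsoDiscriminationCurve(
            f_grid, n_mc, dc_of_f(f_grid), reference_n_mc, reference_f,
            reference_total, None, None, rho,
        )
    f_half = 1.0 / (2.0 + rho)
    midpoint = 0.5 * (reference_total / dc_of_f(0.0) + reference_total / dc_of_f(1.0))
    f_half_numeric = float(
        brentq(lambda f: reference_total / dc_of_f(f) - midpoint, 0.0, 1.0)
    )
    return IsoDiscriminationCurve(
        f_grid, n_mc, dc_of_f(f_grid), reference_n_mc, reference_f,
        reference_total, f_half, f_half_numeric, rho,
    )
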