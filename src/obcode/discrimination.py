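"""Population odor discriminability: n-dimensional d-prime and DCI.

For two odors with per-trial population response matrices p and q
(cells x trials), d' is the Euclidean distance between the trial-mean
population vectors divided by the mean of the two inner distances, where
each inner distance is the average Euclidean distance of single trials
from their own centroid.  Because both numerator and denominator scale as
sqrt(n_cells), d' is dimensionless and comparable across animals with
different cell counts.

The discrimination change index DCI = (d'_after - d'_before) /
(d'_after + d'_before) lies in [-1, 1]; negative values mean
discrimination worsened after the manipulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .traces import ImagingSession, trial_response_means, RESPONSE_WINDOW, SMOOTH_SPAN

__all__ = [
    "OdorResponseCloud",
    "DPrimeMatrix",
    "DCIMatrix",
    "dprime",
    "dprime_matrix",
    "dci_matrix",
    "aggregate_weighted",
    "response_clouds",
]


@dataclass
class OdorResponseCloud:
    """Per-odor trial clouds: list of (n_cells x n_trials) matrices."""

    clouds: list[np.ndarray]
    odor_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.clouds = [np.asarray(c, dtype=float) for c in self.clouds]
        shapes = {c.shape for c in self.clouds}
        if len(shapes) != 1:
            raise ValueError("all odors must share n_cells and n_trials")
        if any(not np.isfinite(c).all() for c in self.clouds):
            raise ValueError("clouds contain non-finite entries")
        if not self.odor_ids:
            self.odor_ids = tuple(f"odor{i:02d}" for i in range(len(self.clouds)))

    @property
    def n_cells(self) -> int:
        return self.clouds[0].shape[0]

    @property
    def n_odors(self) -> int:
        return len(self.clouds)


@dataclass
class DPrimeMatrix:
    """Symmetric odors x odors matrix of pairwise d' values (diagonal 0)."""

    values: np.ndarray
    n_cells: int
    odor_ids: tuple[str, ...] = ()
    invalid: np.ndarray | None = None  # entries where d' was undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.invalid is None:
            self.invalid = np.zeros_like(self.values, dtype=bool)


@dataclass
class DCIMatrix:
    """Entrywise discrimination change index with a one-sample t-test vs 0."""

    values: np.ndarray  # NaN where undefined
    mean_dci: float
    t_stat: float
    p_value: float
    n_excluded: int
    odor_ids: tuple[str, ...] = ()


def dprime(p: np.ndarray, q: np.ndarray) -> float:
    """Population d' between two odors from their trial matrices.

    ``p`` and ``q`` are (n_cells, n_trials) matrices of per-trial responses.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.ndim == 1:
        p = p[None, :]
    if q.ndim == 1:
        q = q[None, :]
    if p.shape[0] != q.shape[0]:
        raise ValueError("cell dimensions differ")
    if p.shape[1] < 2 or q.shape[1] < 2:
        raise ValueError("need at least 2 trials per odor")
    mp, mq = p.mean(axis=1), q.mean(axis=1)
    between = float(np.linalg.norm(mp - mq))
    inner_p = float(np.linalg.norm(p - mp[:, None], axis=0).mean())
    inner_q = float(np.linalg.norm(q - mq[:, None], axis=0).mean())
    denom = 0.5 * (inner_p + inner_q)
    if denom == 0.0:
        raise ZeroDivisionError("both inner distances are zero; d' undefined")
    return between / denom


def dprime_matrix(clouds: OdorResponseCloud) -> DPrimeMatrix:
    """All pairwise d' values (66 unique entries for 11 odors)."""
    n = clouds.n_odors
    if n < 2:
        raise ValueError("need at least 2 odors")
    vals = np.zeros((n, n))
    invalid = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d = dprime(clouds.clouds[i], clouds.clouds[j])
            except ZeroDivisionError:
                d, invalid[i, j] = np.nan, True
                invalid[j, i] = True
            vals[i, j] = vals[j, i] = d
    return DPrimeMatrix(vals, clouds.n_cells, clouds.odor_ids, invalid)


def dci_matrix(
    before: DPrimeMatrix, after: DPrimeMatrix, n_comparisons: int = 1
) -> DCIMatrix:
    """Entrywise DCI with a two-sided one-sample t-test of the entries vs 0.

    ``n_comparisons`` applies a Bonferroni factor when several conditions
    are tested together.  Entries where d'_after + d'_before = 0 (or either
    d' is undefined) are excluded and counted.  The t-test treats the 66
    pair entries as a sample even though they are not independent; this is
    a documented limitation, not corrected.
    """
    if before.values.shape != after.values.shape:
        raise ValueError("odor sets differ between conditions")
    n = before.values.shape[0]
    iu = np.triu_indices(n, k=1)
    b, a = before.values[iu], after.values[iu]
    denom = a + b
    ok = np.isfinite(b) & np.isfinite(a) & (denom != 0)
    vals = np.full((n, n), np.nan)
    dci = np.where(ok, (a - b) / np.where(denom == 0, 1.0, denom), np.nan)
    vals[iu] = dci
    vals[(iu[1], iu[0])] = dci
    entries = dci[ok]
    if len(entries) >= 2:
        t, p = stats.ttest_1samp(entries, 0.0)
        p = min(1.0, float(p) * n_comparisons)
    else:
        t, p = np.nan, np.nan
    return DCIMatrix(
        values=vals,
        mean_dci=float(entries.mean()) if entries.size else np.nan,
        t_stat=float(t),
        p_value=float(p),
        n_excluded=int((~ok).sum()),
        odor_ids=before.odor_ids,
    )


def aggregate_weighted(matrices: list[DPrimeMatrix]) -> DPrimeMatrix:
    """Entrywise cross-subject mean weighted by each subject's cell count."""
    if not matrices:
        raise ValueError("no matrices to aggregate")
    shape = matrices[0].values.shape
    if any(m.values.shape != shape for m in matrices):
        raise ValueError("odor sets differ between subjects")
    w = np.array([m.n_cells for m in matrices], dtype=float)
    stack = np.stack([m.values for m in matrices])
    vals = np.einsum("s,sij->ij", w, stack) / w.sum()
    return DPrimeMatrix(vals, int(w.sum()), matrices[0].odor_ids)


def response_clouds(
    session: ImagingSession,
    *,
    window: tuple[float, float] = RESPONSE_WINDOW,
    span: int = SMOOTH_SPAN,
) -> OdorResponseCloud:
    """Per-odor trial clouds from a session.

    The per-trial scalar is the mean smoothed dF/F over the response window
    (consistent with the permutation-test samples); all imaged cells are
    included regardless of their significance classification.
    """
    tm = trial_response_means(session, window=window, span=span)
    return OdorResponseCloud(
        [tm[:, o, :] for o in range(session.n_odors)],
        tuple(str(o) for o in session.odor_ids),
    )
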