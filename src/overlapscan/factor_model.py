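"""Two-factor additive decomposition of intergenic distances across taxa.

Each observed distance of an orthologous (COG-pair) gene pair in some phylum
is modeled as

    d_k[i, j] = C_i + P_j + e_k

where ``C_i`` is a COG-pair-specific effect, ``P_j`` a phylum-specific
effect with the reference phylum pinned to 0 (removing the additive gauge
freedom), and ``e_k`` residual noise.  The fit minimizes the sum of squared
residuals over all observations; cells are typically unbalanced (most COG
pairs are absent from most phyla), which the observation-level loss handles
without imputation.

The default solver is alternating minimization with exact coordinate
updates — each sweep sets every ``C_i`` to the mean residual of its
observations given ``P``, then every ``P_j`` likewise given ``C``, then
re-imposes the reference constraint along the gauge direction (which leaves
the loss unchanged).  The loss is therefore non-increasing across sweeps.
A direct sparse least-squares path (dummy-coded design, LSQR) is provided
as an independent cross-check.
"""

from __future__ import annotations


from collections import Counter, defaultdict
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import lsqr

__all__ = [
    "DistanceObservation",
    "FactorFit",
    "IdentifiabilityError",
    "select_widespread_cog_pairs",
    "fit_two_factor_model",
    "adjust_distances",
    "summarize_cog_pair",
    "factor_dispersion",
]


@dataclass(frozen=True, slots=True)
class DistanceObservation:
    """One gene pair's intergenic distance tagged with COG pair and phylum."""

    cog_pair_id: str
    phylum: str
    distance: float

    def __post_init__(self) -> None:
        if not self.cog_pair_id or not self.phylum:
            raise ValueError("cog_pair_id and phylum must be non-empty")


@dataclass(frozen=True)
class FactorFit:
    """Fitted effects, residuals and dispersions of the two-factor model."""

    C: Mapping[str, float]
    P: Mapping[str, float]
    residuals: np.ndarray
    sse: float
    sd_C: float
    sd_P: float
    reference_phylum: str
    n_sweeps: int
    sse_trace: tuple[float, ...] = ()


class IdentifiabilityError(ValueError):
    """The COG-pair/phylum incidence graph is disconnected; effects are not unique."""


def select_widespread_cog_pairs(
    observations: Iterable[DistanceObservation], min_phyla: int = 25
) -> list[DistanceObservation]:
    """Keep observations of COG pairs present in >= ``min_phyla`` distinct phyla."""
    observations = list(observations)
    phyla_of: dict[str, set[str]] = defaultdict(set)
    for obs in observations:
        phyla_of[obs.cog_pair_id].add(obs.phylum)
    keep = {cog for cog, phyla in phyla_of.items() if len(phyla) >= min_phyla}
    return [obs for obs in observations if obs.cog_pair_id in keep]


def _encode(
    observations: Sequence[DistanceObservation],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    cogs = sorted({o.cog_pair_id for o in observations})
    phyla = sorted({o.phylum for o in observations})
    cog_index = {c: i for i, c in enumerate(cogs)}
    phy_index = {p: j for j, p in enumerate(phyla)}
    d = np.array([o.distance for o in observations], dtype=float)
    ci = np.array([cog_index[o.cog_pair_id] for o in observations], dtype=np.intp)
    pj = np.array([phy_index[o.phylum] for o in observations], dtype=np.intp)
    return d, ci, pj, cogs, phyla


def _check_connected(ci: np.ndarray, pj: np.ndarray, cogs: list[str], phyla: list[str]) -> None:
    n_c, n_p = len(cogs), len(phyla)
    n = n_c + n_p
    data = np.ones(len(ci))
    adj = coo_matrix((data, (ci, pj + n_c)), shape=(n, n))
    n_comp, labels = connected_components(adj, directed=False)
    if n_comp > 1:
        groups: dict[int, list[str]] = defaultdict(list)
        names = cogs + phyla
        for node, lab in enumerate(labels):
            groups[lab].append(names[node])
        detail = "; ".join(
            f"component {lab}: {sorted(members)[:6]}" for lab, members in sorted(groups.items())
        )
        raise IdentifiabilityError(
            f"COG-pair/phylum incidence graph has {n_comp} components — effects are "
            f"not identifiable ({detail})"
        )


def _group_mean(values: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    sums = np.bincount(codes, weights=values, minlength=n_groups)
    counts = np.bincount(codes, minlength=n_groups)
    return sums / counts


def fit_two_factor_model(
    observations: Sequence[DistanceObservation],
    reference_phylum: str | None = None,
    *,
    method: Literal["alternating", "direct"] = "alternating",
    tol: float = 1e-10,
    max_sweeps: int = 10_000,
) -> FactorFit:
    """Least-squares fit of ``d = C_i + P_j + e`` with ``P[reference] = 0``.

    Parameters
    ----------
    reference_phylum:
        Phylum whose effect is pinned to 0.  Defaults to the phylum with the
        most observations.
    method:
        ``"alternating"`` (exact coordinate descent; default) or ``"direct"``
        (sparse LSQR on the dummy-coded design; cross-check path).
    tol:
        Convergence threshold on the relative (or, near zero, absolute)
        per-sweep improvement of the sum of squared residuals.
    """
    observations = list(observations)
    if not observations:
        raise ValueError("at least one observation is required")
    d, ci, pj, cogs, phyla = _encode(observations)
    if reference_phylum is None:
        reference_phylum = Counter(o.phylum for o in observations).most_common(1)[0][0]
    if reference_phylum not in phyla:
        raise ValueError(f"reference phylum {reference_phylum!r} has no observations")
    _check_connected(ci, pj, cogs, phyla)
    ref = phyla.index(reference_phylum)
    n_c, n_p = len(cogs), len(phyla)

    if method == "direct":
        C_vec, P_vec = _direct_solve(d, ci, pj, n_c, n_p, ref)
        sse_trace: list[float] = []
        n_sweeps = 0
    elif method == "alternating":
        C_vec = np.zeros(n_c)
        P_vec = np.zeros(n_p)
        sse_trace = []
        prev = np.inf
        n_sweeps = 0
        for sweep in range(1, max_sweeps + 1):
            C_vec = _group_mean(d - P_vec[pj], ci, n_c)
            P_vec = _group_mean(d - C_vec[ci], pj, n_p)
            # shift along the gauge direction (loss-invariant) to pin P[ref]=0
            delta = P_vec[ref]
            P_vec -= delta
            C_vec += delta
            resid = d - C_vec[ci] - P_vec[pj]
            sse = float(resid @ resid)
            sse_trace.append(sse)
            n_sweeps = sweep
            if prev - sse <= tol * max(sse, 1.0):
                break
            prev = sse
    else:
        raise ValueError(f"unknown method {method!r}")

    resid = d - C_vec[ci] - P_vec[pj]
    sse = float(resid @ resid)
    sd_C = float(np.std(C_vec, ddof=1)) if n_c > 1 else 0.0
    sd_P = float(np.std(P_vec, ddof=1)) if n_p > 1 else 0.0
    return FactorFit(
        C={c: float(v) for c, v in zip(cogs, C_vec)},
        P={p: float(v) for p, v in zip(phyla, P_vec)},
        residuals=resid,
        sse=sse,
        sd_C=sd_C,
        sd_P=sd_P,
        reference_phylum=reference_phylum,
        n_sweeps=n_sweeps,
        sse_trace=tuple(sse_trace),
    )


def _direct_solve(
    d: np.ndarray, ci: np.ndarray, pj: np.ndarray, n_c: int, n_p: int, ref: int
) -> tuple[np.ndarray, np.ndarray]:
    """Dummy-coded sparse least squares with the reference column dropped."""
    n_obs = len(d)
    rows = np.concatenate([np.arange(n_obs), np.arange(n_obs)[pj != ref]])
    # phylum columns: index shifted past the reference
    pj_free = pj[pj != ref]
    pj_cols = n_c + pj_free - (pj_free > ref).astype(np.intp)
    cols = np.concatenate([ci, pj_cols])
    data = np.ones(len(rows))
    design = coo_matrix((data, (rows, cols)), shape=(n_obs, n_c + n_p - 1)).tocsr()
    solution = lsqr(design, d, atol=1e-14, btol=1e-14, iter_lim=20_000)[0]
    C_vec = solution[:n_c]
    P_vec = np.zeros(n_p)
    free = [j for j in range(n_p) if j != ref]
    P_vec[free] = solution[n_c:]
    return C_vec, P_vec


def adjust_distances(
    observations: Iterable[DistanceObservation], fit: FactorFit
) -> list[DistanceObservation]:
    """Subtract the fitted phylum effect: taxonomically adjusted distances.

    Reference-phylum distances are unchanged (its effect is 0).
    """
    adjusted = []
    for obs in observations:
        if obs.phylum not in fit.P:
            raise KeyError(f"phylum {obs.phylum!r} not covered by the fit")
        adjusted.append(replace(obs, distance=obs.distance - fit.P[obs.phylum]))
    return adjusted


def summarize_cog_pair(
    observations: Iterable[DistanceObservation],
    statistic: Literal["mean", "median"] = "median",
) -> dict[str, float]:
    """Per-COG-pair mean or median of (adjusted) distances."""
    grouped: dict[str, list[float]] = defaultdict(list)
    for obs in observations:
        grouped[obs.cog_pair_id].append(obs.distance)
    if statistic == "mean":
        return {c: float(np.mean(v)) for c, v in grouped.items()}
    if statistic == "median":
        return {c: float(np.median(v)) for c, v in grouped.items()}
    raise ValueError(f"unknown statistic {statistic!r}")


def factor_dispersion(fit: FactorFit) -> tuple[float, float]:
    """Sample standard deviations of the COG-pair and phylum effect vectors.

    The reference phylum's pinned 0 is included in the phylum vector.
    """
    return fit.sd_C, fit.sd_P
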