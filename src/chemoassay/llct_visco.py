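"""Viscoelastic decomposition of low load compression (LLCT) records.

A biofilm is compressed to a constant strain (20% in 1 s) and the induced
stress is monitored for 100 s. Two quantities are extracted:

- the percentage stress relaxation ``R = 100 * (s(0) - s(100)) / s(0)``,
- a four-arm generalized Maxwell (Prony series) decomposition
  ``E(t) = s(t)/strain = sum_i E_i exp(-t / tau_i)``.

Each arm is allocated to a biofilm constituent by its relaxation time
constant: free water (tau < 0.5 s), bound water (0.5-3 s), EPS
(3-100 s) and bacteria (> 100 s). The relative importance of each arm is
its spring constant as a percentage of the total at t = 0, before
relaxation starts.

Fitting uses variable projection: the time constants are optimized inside
their component bins (guaranteeing allocatable output) while the spring
constants are recovered at each step by non-negative linear least squares.
Residuals are evaluated at the record's own sample times (the
maximum-likelihood weighting for uniformly sampled homoscedastic noise);
a log-time subset is available for speed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares, nnls

__all__ = [
    "RelaxationRecord",
    "EvaporationReference",
    "MaxwellModel",
    "ComponentContributions",
    "TAU_BINS",
    "COMPONENT_LABELS",
    "correct_evaporation",
    "stress_relaxation_pct",
    "fit_maxwell",
    "relative_importance",
    "allocate_components",
    "AllocationError",
    "FitConvergenceError",
]

#: Half-open component bins [lower, upper) for the four relaxation time
#: constants, in seconds. The slowest bin is unbounded in principle; 1e4 s
#: is its finite surrogate upper bound during constrained fitting.
TAU_BINS: tuple[tuple[float, float], ...] = (
    (1e-3, 0.5),
    (0.5, 3.0),
    (3.0, 100.0),
    (100.0, 1e4),
)

COMPONENT_LABELS: tuple[str, ...] = ("free_water", "bound_water", "eps", "bacteria")


class AllocationError(ValueError):
    """A time constant cannot be assigned to exactly one component bin."""


class FitConvergenceError(RuntimeError):
    """All multi-start fits failed; carries the best diagnostics found."""

    def __init__(self, message: str, best=None):
        super().__init__(message)
        self.best = best


@dataclass(frozen=True)
class RelaxationRecord:
    """A stress-relaxation trace under constant strain.

    ``time_s`` starts at 0 (= end of the compression ramp) and must span at
    least ``duration_s``. ``stress_pa`` is force normalized over the plunger
    cross-sectional area.
    """

    time_s: np.ndarray
    stress_pa: np.ndarray
    strain: float = 0.2
    duration_s: float = 100.0

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.stress_pa, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time_s and stress_pa must be equal-length 1-D")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing with >= 2 samples")
        if t[0] != 0.0:
            raise ValueError("time_s must start at 0 (end of compression ramp)")
        if t[-1] < self.duration_s:
            raise ValueError(
                f"record spans {t[-1]:g} s but duration_s is {self.duration_s:g} s"
            )
        if not (0.0 < self.strain < 1.0):
            raise ValueError("strain must be in (0, 1)")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "stress_pa", s)


@dataclass(frozen=True)
class EvaporationReference:
    """A blank (no-sample) trace recording baseline drift from evaporation."""

    time_s: np.ndarray
    stress_pa: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_s, dtype=float)
        s = np.asarray(self.stress_pa, dtype=float)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("time_s and stress_pa must be equal-length 1-D")
        if t.size < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("time_s must be strictly increasing with >= 2 samples")
        object.__setattr__(self, "time_s", t)
        object.__setattr__(self, "stress_pa", s)


@dataclass(frozen=True)
class MaxwellModel:
    """Four (E_i, tau_i) pairs, tau ascending, plus the fit residual SS."""

    E: np.ndarray
    tau: np.ndarray
    sse: float = 0.0

    def __post_init__(self) -> None:
        E = np.asarray(self.E, dtype=float)
        tau = np.asarray(self.tau, dtype=float)
        if E.shape != (4,) or tau.shape != (4,):
            raise ValueError("E and tau must be 4-vectors")
        if np.any(E < 0):
            raise ValueError("spring constants must be non-negative")
        if np.any(tau <= 0) or np.any(np.diff(tau) <= 0):
            raise ValueError("tau must be positive and strictly ascending")
        object.__setattr__(self, "E", E)
        object.__setattr__(self, "tau", tau)

    def relaxation_modulus(self, t) -> np.ndarray:
        """E(t) = sum_i E_i exp(-t / tau_i)."""
        t = np.asarray(t, dtype=float)
        return np.exp(-t[..., None] / self.tau) @ self.E


@dataclass(frozen=True)
class ComponentContributions:
    """Relative importances (%) ordered free water, bound water, EPS, bacteria."""

    pct: np.ndarray

    def __post_init__(self) -> None:
        pct = np.asarray(self.pct, dtype=float)
        if pct.shape != (4,):
            raise ValueError("pct must be a 4-vector")
        if np.any(pct < 0):
            raise ValueError("importances must be non-negative")
        if abs(pct.sum() - 100.0) > 1e-9:
            raise ValueError(f"importances must sum to 100, got {pct.sum()!r}")
        object.__setattr__(self, "pct", pct)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(COMPONENT_LABELS, map(float, self.pct)))


def correct_evaporation(record: RelaxationRecord,
                        ref: EvaporationReference) -> RelaxationRecord:
    """Subtract an evaporation reference trace (interpolated to record times).

    The correction is additive, so it commutes with any force-to-stress
    normalization. The reference must cover the record's full time range.
    """
    if ref.time_s[0] > record.time_s[0] or ref.time_s[-1] < record.time_s[-1]:
        raise ValueError(
            f"reference spans [{ref.time_s[0]:g}, {ref.time_s[-1]:g}] s but the "
            f"record needs [{record.time_s[0]:g}, {record.time_s[-1]:g}] s"
        )
    drift = np.interp(record.time_s, ref.time_s, ref.stress_pa)
    return replace(record, stress_pa=record.stress_pa - drift)


def estimate_tail_drift(record: RelaxationRecord, tail_s: float = 20.0) -> float:
    """Linear drift slope (Pa/s) estimated from the record's final samples.

    A fallback when no blank reference trace exists; assumes the Maxwell
    decay is negligible over the fitted tail, which over-corrects when slow
    arms are still relaxing. Prefer :func:`correct_evaporation`.
    """
    sel = record.time_s >= record.time_s[-1] - tail_s
    if sel.sum() < 2:
        raise ValueError("tail window contains fewer than 2 samples")
    slope = np.polyfit(record.time_s[sel], record.stress_pa[sel], 1)[0]
    return float(slope)


def stress_relaxation_pct(record: RelaxationRecord) -> float:
    """Percentage stress relaxation R over the hold duration.

    ``R = 100 * (s(0) - s(D)) / s(0)`` with s read at the nearest samples
    (linear interpolation at ``duration_s`` if it falls between samples).
    Raises when the initial stress is non-positive (non-physical record).
    """
    s0 = float(record.stress_pa[0])
    if s0 <= 0:
        raise ValueError(f"initial stress must be positive, got {s0:g} Pa")
    s_end = float(np.interp(record.duration_s, record.time_s, record.stress_pa))
    return 100.0 * (s0 - s_end) / s0


def _fit_times(record: RelaxationRecord, n_points: int | None) -> np.ndarray:
    """Sample times used for fitting: all of them, or a log-time subset."""
    t = record.time_s
    t = t[t <= record.duration_s]
    if n_points is None:
        return t
    pos = t[t > 0]
    if pos.size <= n_points:
        return t
    targets = np.geomspace(pos[0], pos[-1], n_points - 1)
    idx = np.unique(np.searchsorted(pos, targets))
    idx = np.clip(idx, 0, pos.size - 1)
    return np.concatenate([[0.0], pos[np.unique(idx)]])


def fit_maxwell(record: RelaxationRecord,
                bins: Sequence[tuple[float, float]] | None = TAU_BINS,
                restarts: int = 8,
                seed: int = 0,
                n_points: int | None = None) -> MaxwellModel:
    """Fit the four-arm generalized Maxwell model to a relaxation record.

    Minimizes ``sum_t (s(t)/strain - sum_i E_i exp(-t/tau_i))^2`` over the
    record's sample times up to ``duration_s``, subject to ``E_i >= 0`` and
    each ``tau_i`` inside its component bin (``bins=None`` removes the bin
    constraints; time constants are then only ordered at the end). With
    uniformly sampled, homoscedastic noise the unweighted full-record fit
    is the maximum-likelihood estimate; pass an integer ``n_points`` to fit
    a log-time subset instead (faster, but the sparsely sampled tail then
    carries less weight and the slow-arm split becomes noisier).

    Multi-start: the first start places each tau at its bin log-midpoint,
    the rest jitter log-uniformly within the bins (deterministic given
    ``seed``). Returns the lowest-SSE solution.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    s0 = float(record.stress_pa[0])
    if s0 <= 0:
        raise ValueError("record must have positive initial stress "
                         "(apply evaporation correction first)")
    constrained = bins is not None
    if constrained:
        b = np.asarray(bins, dtype=float)
        if b.shape != (4, 2) or np.any(b[:, 0] >= b[:, 1]) or np.any(
                b[1:, 0] < b[:-1, 1] - 1e-12):
            raise ValueError("bins must be 4 ordered disjoint (lo, hi) intervals")
    else:
        b = np.tile([1e-3, 1e4], (4, 1)).astype(float)

    t_fit = _fit_times(record, n_points)
    y = np.interp(t_fit, record.time_s, record.stress_pa) / record.strain

    lo, hi = np.log(b[:, 0]), np.log(b[:, 1])

    def solve_E(log_tau: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        A = np.exp(-t_fit[:, None] / np.exp(log_tau))
        E, _ = nnls(A, y)
        return E, A @ E - y

    def residuals(log_tau: np.ndarray) -> np.ndarray:
        return solve_E(log_tau)[1]

    rng = np.random.default_rng(seed)
    starts = [0.5 * (lo + hi)]
    starts += [rng.uniform(lo, hi) for _ in range(restarts - 1)]

    best = None
    failures: list[str] = []
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception as exc:  # pragma: no cover - scipy-internal failures
            failures.append(str(exc))
            continue
        E, res = solve_E(sol.x)
        sse = float(res @ res)
        if best is None or sse < best[2]:
            best = (E, np.exp(sol.x), sse)
    if best is None:
        raise FitConvergenceError(
            f"all {restarts} restarts failed: {failures}", best=failures)

    E, tau, sse = best
    order = np.argsort(tau)
    tau = tau[order]
    E = E[order]
    # keep tau strictly ascending even if the optimizer parked two arms on a
    # shared bound in unconstrained mode
    for i in range(1, 4):
        if tau[i] <= tau[i - 1]:
            tau[i] = np.nextafter(tau[i - 1], np.inf)
    return MaxwellModel(E=E, tau=tau, sse=sse)


def relative_importance(model: MaxwellModel) -> ComponentContributions:
    """Spring constants as percentages of their sum at t = 0.

    Ordered by ascending tau, i.e. (free water, bound water, EPS, bacteria)
    for a bin-constrained fit.
    """
    total = float(model.E.sum())
    if total <= 0:
        raise ValueError("all spring constants are zero; importances undefined")
    return ComponentContributions(pct=100.0 * model.E / total)


def allocate_components(tau: Sequence[float],
                        bins: Sequence[tuple[float, float]] = TAU_BINS
                        ) -> tuple[str, ...]:
    """Map each time constant to its component label by bin membership.

    Bins are half-open ``[lower, upper)`` with the slowest bin unbounded
    above, so a boundary value such as tau = 0.5 s belongs to the slower
    (bound water) bin. Raises :class:`AllocationError` when a tau falls
    outside every bin or two tau share one bin.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(np.diff(tau) <= 0):
        raise ValueError("tau must be strictly ascending")
    labels = []
    seen: set[int] = set()
    for t in tau:
        hit = None
        for k, (lo, hi) in enumerate(bins):
            in_lower = t > 0.0 if k == 0 else t >= lo  # fastest bin: any tau > 0
            in_upper = t < hi or k == len(bins) - 1    # slowest bin unbounded
            if in_lower and in_upper:
                hit = k
                break
        if hit is None:
            raise AllocationError(
                f"tau = {t:g} s falls outside every component bin {list(bins)}")
        if hit in seen:
            raise AllocationError(
                f"two time constants fall in the {COMPONENT_LABELS[hit]} bin")
        seen.add(hit)
        labels.append(COMPONENT_LABELS[hit])
    return tuple(labels)
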