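"""Incidence-based species-richness estimation.

Implements the sample-based (incidence) rarefaction/extrapolation framework
of Colwell et al. / Chao et al. as popularised by iNEXT, for binary
taxon x sampling-unit data where the sampling unit is a collection day:

* interpolation (rarefaction) of expected richness at t <= T units,
* the bias-corrected Chao2 asymptotic estimator,
* extrapolation beyond T driven by the estimated number of undetected
  species Q0_hat = S_hat - S_obs,
* a unit-resampling percentile bootstrap for confidence intervals.

Only richness (Hill number q = 0) is computed; abundance-based estimators
are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb
from pathlib import Path

import numpy as np

from .io import IncidenceMatrix

__all__ = [
    "CurvePoint",
    "IncidenceAccumulation",
    "accumulation",
    "bootstrap_ci",
    "chao2",
    "extrapolate",
    "incidence_frequencies",
    "rarefy",
]


def incidence_frequencies(
    inc: IncidenceMatrix,
) -> tuple[int, int, dict[int, int]]:
    """Return (T, S_obs, Q) where Q[k] = #species found in exactly k units."""
    counts = inc.incidence_counts
    q: dict[int, int] = {}
    for k in counts:
        q[int(k)] = q.get(int(k), 0) + 1
    return inc.T, int(len(counts)), q


def chao2(T: int, S_obs: int, Q1: int, Q2: int) -> float:
    """Bias-corrected Chao2 asymptotic richness estimate.

    S_hat = S_obs + ((T-1)/T) * Q1^2 / (2 Q2)            if Q2 > 0
    S_hat = S_obs + ((T-1)/T) * Q1 (Q1 - 1) / 2          if Q2 = 0

    where Q1/Q2 are the numbers of species found in exactly one/two units.
    """
    if T < 2:
        raise ValueError("Chao2 is undefined for fewer than 2 sampling units")
    factor = (T - 1) / T
    if Q2 > 0:
        return S_obs + factor * Q1 * Q1 / (2 * Q2)
    return S_obs + factor * Q1 * (Q1 - 1) / 2


def _q0_hat(T: int, S_obs: int, Q1: int, Q2: int) -> float:
    return chao2(T, S_obs, Q1, Q2) - S_obs


def rarefy(inc: IncidenceMatrix, t: int) -> float:
    """Expected richness in a random subset of t of the T sampling units.

    S(t) = S_obs - sum_i C(T - Y_i, t) / C(T, t), the exact hypergeometric
    expectation over all C(T, t) subsets (C(a, b) = 0 when a < b).
    """
    T = inc.T
    if not 0 <= t <= T:
        raise ValueError(f"t must be in [0, {T}], got {t}")
    counts = inc.incidence_counts
    denom = comb(T, t)
    missing = sum(comb(T - int(y), t) for y in counts) / denom
    return len(counts) - missing


def extrapolate(inc: IncidenceMatrix, t_star: int) -> float:
    """Expected richness after t_star additional sampling units beyond T.

    S(T + t*) = S_obs + Q0_hat * [1 - (1 - Q1 / (Q1 + T Q0_hat))^{t*}],
    with Q0_hat from the bias-corrected Chao2.  Flat at S_obs when Q1 = 0.
    """
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    T, s_obs, q = incidence_frequencies(inc)
    q1, q2 = q.get(1, 0), q.get(2, 0)
    if q1 == 0 or t_star == 0:
        return float(s_obs)
    q0 = _q0_hat(T, s_obs, q1, q2)
    if q0 == 0:
        return float(s_obs)
    return s_obs + q0 * (1.0 - (1.0 - q1 / (q1 + T * q0)) ** t_star)


def _curve_estimate(inc: IncidenceMatrix, t: int) -> float:
    return rarefy(inc, t) if t <= inc.T else extrapolate(inc, t - inc.T)


@dataclass(frozen=True)
class CurvePoint:
    t: int
    method: str  # "interpolated" | "observed" | "extrapolated"
    estimate: float
    ci_low: float | None = None
    ci_high: float | None = None


def bootstrap_ci(
    inc: IncidenceMatrix,
    knots: list[int],
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray, tuple[float, float]]:
    """Percentile bootstrap over sampling units.

    The T unit columns are resampled with replacement B times; species
    undetected in a replicate are dropped and the full curve plus the Chao2
    asymptote are recomputed.  Returns ``(ci_low, ci_high)`` arrays aligned
    with ``knots`` and the asymptote's interval.  Deterministic for a fixed
    seed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    rng = np.random.default_rng(seed)
    T = inc.T
    curves = np.empty((B, len(knots)))
    asymptotes = np.empty(B)
    for b in range(B):
        cols = rng.integers(0, T, size=T)
        m = inc.matrix[:, cols]
        detected = m.sum(axis=1) > 0
        m = m[detected]
        rep = IncidenceMatrix(
            tuple(str(i) for i in range(m.shape[0])),
            tuple(str(j) for j in range(T)),
            m,
        )
        for k, t in enumerate(knots):
            curves[b, k] = _curve_estimate(rep, t)
        rep_T, rep_s, rep_q = incidence_frequencies(rep)
        asymptotes[b] = chao2(rep_T, rep_s, rep_q.get(1, 0), rep_q.get(2, 0))
    alpha = 100 * (1 - level) / 2
    lo = np.percentile(curves, alpha, axis=0)
    hi = np.percentile(curves, 100 - alpha, axis=0)
    asy = (
        float(np.percentile(asymptotes, alpha)),
        float(np.percentile(asymptotes, 100 - alpha)),
    )
    return lo, hi, asy


@dataclass(frozen=True)
class IncidenceAccumulation:
    """Full rarefaction/extrapolation result for one incidence matrix."""

    T: int
    S_obs: int
    Q: dict[int, int]
    S_hat: float
    curve: tuple[CurvePoint, ...]
    asymptote_ci: tuple[float, float] | None = None

    @property
    def Q0_hat(self) -> float:
        """Estimated number of undetected species."""
        return self.S_hat - self.S_obs

    def summary_dict(self) -> dict:
        return {
            "T": self.T,
            "S_obs": self.S_obs,
            "Q1": self.Q.get(1, 0),
            "Q2": self.Q.get(2, 0),
            "S_hat": self.S_hat,
            "Q0_hat": self.Q0_hat,
            "asymptote_ci": list(self.asymptote_ci)
            if self.asymptote_ci
            else None,
        }

    def write_summary_json(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_curve_tsv(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("t\tmethod\testimate\tci_low\tci_high\n")
            for p in self.curve:
                lo = "NA" if p.ci_low is None else repr(float(p.ci_low))
                hi = "NA" if p.ci_high is None else repr(float(p.ci_high))
                fh.write(
                    f"{p.t}\t{p.method}\t{repr(float(p.estimate))}\t"
                    f"{lo}\t{hi}\n"
                )


def accumulation(
    inc: IncidenceMatrix,
    endpoint: int | None = None,
    step: int = 1,
    B: int = 1000,
    level: float = 0.95,
    seed: int | None = None,
) -> IncidenceAccumulation:
    """Build the interpolated/extrapolated richness curve with bootstrap CI.

    ``endpoint`` defaults to 2T (the iNEXT convention); the curve is
    evaluated at integer knots every ``step`` units, always including 0, T
    and the endpoint.  ``B = 0`` skips the bootstrap.
    """
    T, s_obs, q = incidence_frequencies(inc)
    if endpoint is None:
        endpoint = 2 * T
    if endpoint < T:
        raise ValueError("endpoint must be >= T")
    s_hat = chao2(T, s_obs, q.get(1, 0), q.get(2, 0))
    knots = sorted({0, T, endpoint} | set(range(0, endpoint + 1, step)))
    estimates = [_curve_estimate(inc, t) for t in knots]
    if B > 0:
        lo, hi, asy_ci = bootstrap_ci(inc, knots, B=B, level=level, seed=seed)
        lo_l: list[float | None] = list(map(float, lo))
        hi_l: list[float | None] = list(map(float, hi))
    else:
        lo_l = hi_l = [None] * len(knots)
        asy_ci = None
    points = []
    for t, est, l, h in zip(knots, estimates, lo_l, hi_l):
        if t < T:
            method = "interpolated"
        elif t == T:
            method = "observed"
        else:
            method = "extrapolated"
        points.append(CurvePoint(t, method, float(est), l, h))
    return IncidenceAccumulation(
        T=T,
        S_obs=s_obs,
        Q=q,
        S_hat=float(s_hat),
        curve=tuple(points),
        asymptote_ci=asy_ci,
    )
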