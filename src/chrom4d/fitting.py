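"""Fit experimental summaries as convex combinations of simulated bases.

The observable (a saddle plot, an E1 profile, or a P(s) curve) of a mixed
cell population is modelled as a convex combination ``sum_m c_m * B_m`` of
the summaries of candidate single-state models: coefficients are
nonnegative and sum to one, interpreted as population fractions.  The
least-squares problem over the simplex is convex; it is solved exactly by
nonnegative least squares (Lawson-Hanson active set) with the sum
constraint imposed as a heavily weighted extra equation, which returns the
global minimiser deterministically.

For contact-probability curves a single positive multiplicative scale,
shared across conditions, is fitted jointly: writing d = scale * c, the
joint problem is plain NNLS in d, and scale = sum(d).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = ["FitResult", "fit_simplex_combination", "fit_contact_probability",
           "SimplexMixture"]

_SUM_PENALTY = 1e6


@dataclass
class FitResult:
    """Simplex-mixture fit: coefficients, objective and bookkeeping."""

    coefficients: np.ndarray
    objective: float
    basis_ids: list[str] = field(default_factory=list)
    fit_range: tuple[float, float] | None = None
    scale: float | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.coefficients, dtype=float)
        if np.any(c < -1e-9):
            raise ValueError("coefficients must be nonnegative")
        if abs(c.sum() - 1.0) > 1e-6:
            raise ValueError(f"coefficients must sum to 1, got {c.sum():.8f}")
        self.coefficients = c

    def summary(self) -> str:
        lines = ["Simplex mixture fit", "-" * 40]
        ids = self.basis_ids or [f"basis_{m}" for m in range(len(self.coefficients))]
        for name, c in zip(ids, self.coefficients):
            lines.append(f"{name:<24s} {c:8.4f}")
        lines.append("-" * 40)
        lines.append(f"objective (SSQ)          {self.objective:10.6g}")
        if self.scale is not None:
            lines.append(f"global scale             {self.scale:10.6g}")
        if self.fit_range is not None:
            lines.append(f"fit range                {self.fit_range}")
        return "\n".join(lines)


def _design(basis: list[np.ndarray]) -> np.ndarray:
    cols = [np.asarray(b, dtype=float).ravel() for b in basis]
    shapes = {np.asarray(b).shape for b in basis}
    if len(shapes) != 1:
        raise ValueError(f"basis elements have mismatched shapes: {shapes}")
    return np.column_stack(cols)


def _collapse_duplicates(B: np.ndarray) -> tuple[np.ndarray, list[int], list[list[int]]]:
    """Group exactly identical columns; returns (reduced design, first-index
    per group, member lists)."""
    groups: list[list[int]] = []
    firsts: list[int] = []
    for m in range(B.shape[1]):
        for gi, g in enumerate(groups):
            if np.array_equal(B[:, g[0]], B[:, m]):
                groups[gi].append(m)
                break
        else:
            groups.append([m])
            firsts.append(m)
    return B[:, firsts], firsts, groups


def fit_simplex_combination(target, basis: list, basis_ids: list[str] | None = None,
                            weights: np.ndarray | None = None) -> FitResult:
    """Global least-squares fit of ``target`` over the simplex of ``basis``.

    ``target`` and every basis element must share one shape (matrix or
    vector).  ``weights`` (per-point standard-deviation reciprocals) turn
    the objective into a chi-square.  Exactly duplicated basis elements are
    collapsed and their combined mass assigned to the first occurrence (the
    documented degeneracy rule); the objective is unaffected.
    """
    if not basis:
        raise ValueError("need at least one basis element")
    t = np.asarray(target, dtype=float).ravel()
    B = _design(basis)
    if B.shape[0] != t.size:
        raise ValueError(f"target shape does not match basis: {t.size} vs {B.shape[0]}")
    if weights is not None:
        w = np.asarray(weights, dtype=float).ravel()
        B = B * w[:, None]
        t = t * w
    Bred, firsts, groups = _collapse_duplicates(B)
    scale = max(float(np.abs(t).max()), 1e-30)
    A = np.vstack([Bred / scale, np.full((1, Bred.shape[1]), _SUM_PENALTY)])
    y = np.concatenate([t / scale, [_SUM_PENALTY]])
    c_red, _ = nnls(A, y)
    s = c_red.sum()
    if s <= 0:
        raise RuntimeError("degenerate fit: all coefficients zero")
    c_red = c_red / s
    c = np.zeros(B.shape[1])
    for val, g in zip(c_red, groups):
        c[g[0]] = val
    obj = float(np.sum((B @ c - t) ** 2))
    return FitResult(coefficients=c, objective=obj,
                     basis_ids=basis_ids or [f"basis_{m}" for m in range(B.shape[1])])


def fit_contact_probability(
    target_ps: np.ndarray,
    basis_ps: list[np.ndarray],
    s_bp: np.ndarray,
    fit_range_bp: tuple[float, float] = (15_000.0, 2_500_000.0),
    basis_ids: list[str] | None = None,
    weights: np.ndarray | None = None,
) -> FitResult:
    """Joint fit of simplex coefficients and one positive global scale.

    All curves must live on the common genomic-separation grid ``s_bp``;
    the chi-square is computed only inside ``fit_range_bp`` (default
    15 kb - 2.5 Mb, the regime where P(s) is informative about extrusion
    and affinity).  Substituting d = scale * c makes the joint problem an
    unconstrained NNLS; scale = sum(d) and c = d / scale.
    """
    t = np.asarray(target_ps, dtype=float)
    s_bp = np.asarray(s_bp, dtype=float)
    lo, hi = fit_range_bp
    mask = (s_bp >= lo) & (s_bp <= hi)
    if not mask.any():
        raise ValueError(f"fit range {fit_range_bp} contains no grid points")
    B = _design([np.asarray(b, dtype=float)[mask] for b in basis_ps])
    tm = t[mask]
    if weights is not None:
        w = np.asarray(weights, dtype=float)[mask]
        B = B * w[:, None]
        tm = tm * w
    Bred, firsts, groups = _collapse_duplicates(B)
    d_red, _ = nnls(Bred, tm)
    scale = float(d_red.sum())
    if scale <= 0:
        raise RuntimeError("degenerate fit: zero optimal scale")
    c = np.zeros(B.shape[1])
    for val, g in zip(d_red / scale, groups):
        c[g[0]] = val
    obj = float(np.sum((scale * (B @ c) - tm) ** 2))
    return FitResult(coefficients=c, objective=obj, scale=scale,
                     fit_range=(lo, hi),
                     basis_ids=basis_ids or [f"basis_{m}" for m in range(B.shape[1])])


class SimplexMixture:
    """Model-style wrapper: bind a target and basis, then ``fit()``.

    >>> res = SimplexMixture(target, basis, kind="saddle").fit()
    >>> print(res.summary())
    """

    def __init__(self, target, basis: list, kind: str = "saddle",
                 s_bp: np.ndarray | None = None,
                 fit_range_bp: tuple[float, float] = (15_000.0, 2_500_000.0),
                 basis_ids: list[str] | None = None) -> None:
        if kind not in ("saddle", "profile", "ps"):
            raise ValueError("kind must be 'saddle', 'profile' or 'ps'")
        if kind == "ps" and s_bp is None:
            raise ValueError("P(s) fits need the genomic-separation grid s_bp")
        self.target, self.basis, self.kind = target, basis, kind
        self.s_bp, self.fit_range_bp, self.basis_ids = s_bp, fit_range_bp, basis_ids

    def fit(self) -> FitResult:
        if self.kind == "ps":
            return fit_contact_probability(self.target, self.basis, self.s_bp,
                                           self.fit_range_bp, self.basis_ids)
        return fit_simplex_combination(self.target, self.basis, self.basis_ids)
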