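"""Permutation-based Leslie–Davis removal estimation.

With immobile individuals and independent surveyors, each surveyor's search
plays the role of a removal pass: individuals already found by an earlier
surveyor count as "removed". Under a constant per-occasion detection
probability p, the expected number of new detections at a pass is
p·(N − x), linear in the number x already detected, so the x-axis intercept
of an ordinary least-squares fit of new detections on prior detections
estimates N. Because the surveyors worked independently and uninformed,
their order is exchangeable: reshuffling it and refitting yields a
permutation distribution whose median and 2.5/97.5 percentiles give the
point estimate and 95% confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class LeslieFit:
    """OLS depletion-regression fit: y (new) on x (previously detected)."""

    slope: float
    intercept: float
    x_intercept: float | None
    degenerate: bool


@dataclass(frozen=True)
class RemovalEstimate:
    """Permutation-median abundance with percentile CI.

    ``n_degenerate`` counts permutations with no finite estimate (slope >= 0
    or undefined); they are excluded from the median/percentiles.
    ``below_mln`` flags a point estimate under the minimum larva number
    (regression can undershoot; flagged, not an error).
    """

    point_estimate: float
    ci95: tuple[float, float]
    n_permutations: int
    n_degenerate: int
    seed: int | None
    below_mln: bool = False

    @property
    def failed(self) -> bool:
        return not np.isfinite(self.point_estimate)


def depletion_pairs(D: np.ndarray, order: np.ndarray | list[int]) -> list[tuple[int, int]]:
    """Depletion pairs (x_t, y_t) for one occasion ordering.

    y_t = individuals first detected at the t-th occasion of ``order``;
    x_t = distinct individuals detected at any earlier occasion (x_1 = 0).
    """
    D = np.asarray(D)
    order = np.asarray(order)
    if sorted(order.tolist()) != list(range(D.shape[1])):
        raise ValueError("order must be a permutation of occasion indices")
    Dp = D[:, order]
    pairs = []
    x = 0
    for t in range(Dp.shape[1]):
        new = int(np.sum(Dp[:, t] & (Dp[:, :t].sum(axis=1) == 0)))
        pairs.append((x, new))
        x += new
    return pairs


def leslie_fit(pairs: list[tuple[float, float]]) -> LeslieFit:
    """OLS of new detections on prior detections; x-intercept estimates N.

    The x-intercept −intercept/slope is reported only for a declining fit
    (slope < 0); otherwise the fit is degenerate.
    """
    if len(pairs) < 2:
        raise ValueError("need at least 2 depletion pairs")
    x = np.array([p[0] for p in pairs], dtype=float)
    y = np.array([p[1] for p in pairs], dtype=float)
    sxx = np.sum((x - x.mean()) ** 2)
    if sxx == 0.0:
        return LeslieFit(np.nan, np.nan, None, degenerate=True)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    if slope >= 0.0:
        return LeslieFit(slope, intercept, None, degenerate=True)
    return LeslieFit(slope, intercept, -intercept / slope, degenerate=False)


def permutation_removal(
    D: np.ndarray,
    n_perm: int = 10_000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> RemovalEstimate:
    """Removal estimate over uniformly random surveyor orders.

    Orders are sampled with replacement from the T! permutations. Degenerate
    permutations are excluded from the summaries and counted. The point
    estimate is the median of the finite x-intercepts; the CI spans their
    2.5th to 97.5th percentiles (linear interpolation).
    """
    D = np.asarray(D, dtype=np.int8)
    M, T = D.shape
    if T < 2:
        raise ValueError("need at least 2 occasions")
    if rng is None:
        rng = np.random.default_rng(seed)

    # Vectorised across permutations: argsort of uniforms gives uniform
    # random orders; first-detection positions give y_t by bincount.
    orders = np.argsort(rng.random((n_perm, T)), axis=1)
    estimates = np.full(n_perm, np.nan)
    if M > 0:
        Dp = D[:, orders]                      # (M, n_perm, T)
        Dp = np.moveaxis(Dp, 1, 0)             # (n_perm, M, T)
        detected = Dp.any(axis=2)              # (n_perm, M)
        first = np.argmax(Dp, axis=2)          # first detection position
        # y[k, t] = count of individuals first detected at position t
        offs = first + T * np.arange(n_perm)[:, None]
        y = np.bincount(offs[detected], minlength=n_perm * T).reshape(n_perm, T).astype(float)
        x = np.concatenate([np.zeros((n_perm, 1)), np.cumsum(y, axis=1)[:, :-1]], axis=1)

        xm = x.mean(axis=1, keepdims=True)
        ym = y.mean(axis=1, keepdims=True)
        sxx = np.sum((x - xm) ** 2, axis=1)
        sxy = np.sum((x - xm) * (y - ym), axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            slope = sxy / sxx
            intercept = ym[:, 0] - slope * xm[:, 0]
            est = -intercept / slope
        ok = (sxx > 0) & (slope < 0) & np.isfinite(est)
        estimates[ok] = est[ok]

    finite = estimates[np.isfinite(estimates)]
    n_degenerate = n_perm - finite.size
    if finite.size == 0:
        return RemovalEstimate(np.nan, (np.nan, np.nan), n_perm, n_degenerate, seed)
    point = float(np.median(finite))
    lo, hi = np.percentile(finite, [2.5, 97.5])
    mln = int((D.sum(axis=1) >= 1).sum())
    return RemovalEstimate(
        point_estimate=point,
        ci95=(float(lo), float(hi)),
        n_permutations=n_perm,
        n_degenerate=int(n_degenerate),
        seed=seed,
        below_mln=point < mln,
    )
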