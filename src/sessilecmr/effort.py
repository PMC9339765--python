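"""Reduced-effort survey evaluation.

Long-term monitoring rarely has nine or ten surveyors per plot; this module
asks how much accuracy and precision are lost with fewer. For every plot and
every subset of k of its expert surveyors (k from 2 to 6), the detection
matrix is restricted to those occasions, individuals no longer detected are
dropped, and a Huggins model is refit — with a constant detection
probability when only two survey rounds remain, time-dependent otherwise.
Each refit is scored against the full-effort estimate N̂_f by its relative
error |N̂_i − N̂_f| / N̂_f (accuracy) and by its relative CI width
(upper − lower) / N̂_i (precision). A single expert's count can also be
scaled up by a detection probability into a design-free abundance estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .dataset import DetectionDataset, experts_of
from .huggins import HugginsFit, ModelSpec, fit

#: A fit counts as reliable when the optimizer converged, the abundance
#: variance is finite and the CI upper bound is not absurd (< 50 × N̂).
RELIABLE_CI_FACTOR = 50.0


@dataclass(frozen=True)
class EffortResult:
    plot_id: str
    surveyor_subset: frozenset[str]
    k: int
    n_hat: float
    ci95: tuple[float, float]
    relative_error: float
    relative_ci_width: float
    reliable: bool


def relative_error(n_i: float, n_f: float) -> float:
    """|N̂_i − N̂_f| / N̂_f — accuracy of a reduced-effort estimate."""
    if not n_f > 0:
        raise ValueError("full-effort estimate must be positive")
    return float(np.sqrt((n_i - n_f) ** 2) / n_f)


def relative_ci_width(ci95: tuple[float, float], n_i: float) -> float:
    """(upper − lower) / N̂_i — precision of a reduced-effort estimate."""
    lo, hi = ci95
    if hi < lo:
        raise ValueError(f"invalid interval ({lo}, {hi})")
    if not n_i > 0:
        raise ValueError("estimate must be positive")
    return float((hi - lo) / n_i)


def _is_reliable(fit_result: HugginsFit, plot_id: str) -> bool:
    g = fit_result.groups[plot_id]
    return bool(
        fit_result.converged
        and not fit_result.boundary
        and np.isfinite(g.var_n)
        and np.all(np.isfinite(g.ci95))
        and g.ci95[1] < RELIABLE_CI_FACTOR * g.n_hat
    )


def reduced_effort_scan(
    ds: DetectionDataset,
    n_full: dict[str, float],
    experts: dict[str, list[str]] | None = None,
    k_min: int = 2,
    k_max: int = 6,
) -> list[EffortResult]:
    """Refit every k-expert subset of every plot and score it.

    Parameters
    ----------
    ds
        Closure-filtered detection dataset.
    n_full
        Full-effort (all-surveyor) abundance estimate per plot — the
        reference N̂_f for relative error.
    experts
        Optional override ``plot_id -> expert surveyor ids``; defaults to
        the experts who searched each plot.

    Failed or degenerate refits are returned flagged ``reliable=False``,
    never raised.
    """
    results: list[EffortResult] = []
    for plot_id in ds.plot_ids:
        roster = experts[plot_id] if experts is not None else experts_of(ds, plot_id)
        n_f = n_full[plot_id]
        for k in range(k_min, min(k_max, len(roster)) + 1):
            for subset in combinations(roster, k):
                results.append(_one_refit(ds, plot_id, subset, n_f))
    return results


def _one_refit(ds, plot_id, subset, n_f) -> EffortResult:
    spec = ModelSpec(structure="constant" if len(subset) == 2 else "occasion")
    try:
        sub = ds.subset_occasions(plot_id, subset)
        if sub.matrix(plot_id).shape[0] == 0:
            raise ValueError("no individuals detected by subset")
        f = fit(sub, spec)
        g = f.groups[plot_id]
        ok = _is_reliable(f, plot_id)
        return EffortResult(
            plot_id=plot_id,
            surveyor_subset=frozenset(subset),
            k=len(subset),
            n_hat=g.n_hat,
            ci95=g.ci95,
            relative_error=relative_error(g.n_hat, n_f) if np.isfinite(g.n_hat) else np.nan,
            relative_ci_width=(
                relative_ci_width(g.ci95, g.n_hat)
                if ok and np.all(np.isfinite(g.ci95))
                else np.nan
            ),
            reliable=ok,
        )
    except (ValueError, RuntimeError, KeyError):
        return EffortResult(
            plot_id=plot_id,
            surveyor_subset=frozenset(subset),
            k=len(subset),
            n_hat=np.nan,
            ci95=(np.nan, np.nan),
            relative_error=np.nan,
            relative_ci_width=np.nan,
            reliable=False,
        )


def summarize_by_k(results: list[EffortResult]) -> pd.DataFrame:
    """Arithmetic means of error and CI width over reliable fits, by k."""
    df = pd.DataFrame(
        {
            "plot_id": [r.plot_id for r in results],
            "k": [r.k for r in results],
            "relative_error": [r.relative_error for r in results],
            "relative_ci_width": [r.relative_ci_width for r in results],
            "reliable": [r.reliable for r in results],
        }
    )
    ok = df[df["reliable"]]
    out = (
        ok.groupby("k")
        .agg(
            n_models=("relative_error", "size"),
            mean_relative_error=("relative_error", "mean"),
            mean_relative_ci_width=("relative_ci_width", "mean"),
        )
        .reset_index()
    )
    out["n_total"] = df.groupby("k").size().reindex(out["k"]).to_numpy()
    return out


def single_surveyor_estimate(count: int, p_scale: float) -> float:
    """Scale one surveyor's count by a detection probability: count / p.

    ``p_scale`` is either the surveyor's own estimated detection probability
    or the expert-group mean, both taken from a full-effort fit.
    """
    if not 0.0 < p_scale <= 1.0:
        raise ValueError(f"p_scale must be in (0, 1], got {p_scale}")
    return float(count / p_scale)


def single_surveyor_errors(
    ds: DetectionDataset,
    fit_result: HugginsFit,
    n_full: dict[str, float],
    use_surveyor_p: bool = True,
) -> pd.DataFrame:
    """Relative errors of single-expert scaled counts against N̂_f.

    One row per (expert, plot) pair; the scaling factor is the surveyor's
    own p̂ or the expert-group mean depending on ``use_surveyor_p``.
    """
    from .huggins import mean_group_p

    mean_p = mean_group_p(fit_result, ds, "expert")
    rows = []
    for plot_id in ds.plot_ids:
        m = ds.matrix(plot_id)
        order = ds.occasions[plot_id]
        for t, sid in enumerate(order):
            if ds.surveyors[sid].experience != "expert":
                continue
            count = int(m[:, t].sum())
            p = fit_result.p_table[sid][0] if use_surveyor_p else mean_p
            est = single_surveyor_estimate(count, p)
            rows.append(
                {
                    "plot_id": plot_id,
                    "surveyor_id": sid,
                    "count": count,
                    "p_scale": p,
                    "n_hat": est,
                    "relative_error": relative_error(est, n_full[plot_id]),
                }
            )
    return pd.DataFrame(rows)
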