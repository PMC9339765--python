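"""Huggins closed-population capture-mark-recapture with multiple surveyors.

The Huggins model conditions each individual's likelihood on being detected
at least once, so abundance never enters the likelihood: detection
parameters are estimated by conditional maximum likelihood and abundance is
recovered afterwards by Horvitz–Thompson, N̂ = Σ_i 1/p*_i, where
p*_i = 1 − Π_t (1 − p_t) is the probability individual i was detected at
least once over its plot's occasions. Capture and recapture probabilities
are shared (p = c): an immobile individual cannot respond behaviourally to
having been found, since marks are removed between surveyors.

Detection structures
--------------------
``constant``    one p for all occasions (M0).
``occasion``    one p per surveyor (Mt); a surveyor searching several plots
                contributes a single shared parameter, which is the only
                structure consistent with reporting surveyor-specific
                detection probabilities pooled across plots.
``experience``  logit p = β0 + β1·[expert], a two-level occasion covariate.

All parameters live on the logit scale. Confidence intervals for p are Wald
on the logit scale, back-transformed; intervals for N̂ use the MARK-style
log-normal interval on f0 = N̂ − M, which is bounded below by the number of
individuals actually observed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import expit, log_expit

from .dataset import DetectionDataset

BOUNDARY_LOGIT = 10.0


@dataclass(frozen=True)
class ModelSpec:
    """Detection structure for a Huggins fit."""

    structure: str = "occasion"
    share_recapture: bool = True
    grouping: str = "plot"

    def __post_init__(self) -> None:
        if self.structure not in ("constant", "occasion", "experience"):
            raise ValueError(f"unknown detection structure {self.structure!r}")
        if not self.share_recapture:
            raise ValueError("only shared capture/recapture (p = c) is supported")


@dataclass(frozen=True)
class GroupEstimate:
    """Per-plot abundance: observed count M, N̂, f0 and log-normal CI."""

    plot_id: str
    m_observed: int
    p_star: float
    n_hat: float
    f0: float
    var_n: float
    ci95: tuple[float, float]


@dataclass
class HugginsFit:
    """Result of a conditional-likelihood fit."""

    spec: ModelSpec
    param_names: list[str]
    beta: np.ndarray
    beta_se: np.ndarray
    vcov: np.ndarray
    loglik: float
    converged: bool
    boundary: bool
    groups: dict[str, GroupEstimate] = field(default_factory=dict)
    p_table: dict[str, tuple[float, float, float]] = field(default_factory=dict)

    def p_hat(self, occasion_param: str) -> float:
        return self.p_table[occasion_param][0]


def p_star(p: np.ndarray | list[float]) -> float:
    """Probability of at least one detection: 1 − Π(1 − p_t)."""
    p = np.asarray(p, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("detection probabilities must lie in [0, 1]")
    with np.errstate(divide="ignore"):  # p_t = 1 gives log(0) = -inf, p* = 1
        return float(-np.expm1(np.sum(np.log1p(-p))))


# -- design ----------------------------------------------------------------


def _build_design(ds: DetectionDataset, spec: ModelSpec):
    """Per-plot design matrices X with logit p = X @ beta, plus sufficient
    statistics (per-occasion detection totals n_t and group sizes M)."""
    if spec.structure == "constant":
        names = ["p"]
    elif spec.structure == "occasion":
        names = []
        for plot_id in ds.plot_ids:
            for sid in ds.occasions[plot_id]:
                if sid not in names:
                    names.append(sid)
    else:
        names = ["intercept", "expert"]

    designs: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    sizes: dict[str, int] = {}
    for plot_id in ds.plot_ids:
        order = ds.occasions[plot_id]
        X = np.zeros((len(order), len(names)))
        for t, sid in enumerate(order):
            if spec.structure == "constant":
                X[t, 0] = 1.0
            elif spec.structure == "occasion":
                X[t, names.index(sid)] = 1.0
            else:
                X[t, 0] = 1.0
                X[t, 1] = 1.0 if ds.surveyors[sid].experience == "expert" else 0.0
        designs[plot_id] = X
        m = ds.matrix(plot_id)
        counts[plot_id] = m.sum(axis=0).astype(float)
        sizes[plot_id] = m.shape[0]
    return names, designs, counts, sizes


def _group_ll_grad(beta, X, n, M):
    """Conditional log-likelihood contribution of one plot and its gradient
    with respect to the linear predictor parameters."""
    eta = X @ beta
    logp = log_expit(eta)
    logq = log_expit(-eta)
    s = logq.sum()                      # log(1 - p*)
    log_pstar = np.log(-np.expm1(s)) if s < 0 else -np.inf
    ll = float(n @ logp + (M - n) @ logq - M * log_pstar)
    p = expit(eta)
    pstar = -np.expm1(s)
    # d ll / d eta_t = n_t(1−p_t) − (M−n_t)p_t − M(1−p*)p_t/p*
    d_eta = n * (1 - p) - (M - n) * p - M * (1 - pstar) * p / pstar
    return ll, X.T @ d_eta


def conditional_loglik(beta, ds: DetectionDataset, spec: ModelSpec) -> float:
    """Huggins conditional log-likelihood at link-scale parameters ``beta``.

    Equals Σ_i [Σ_t D_it·ln p_t + (1−D_it)·ln(1−p_t)] − Σ_i ln p*_i over the
    observed individuals, with each individual's occasion set that of its
    plot (computed via per-plot sufficient statistics).
    """
    beta = np.asarray(beta, dtype=float)
    _, designs, counts, sizes = _build_design(ds, spec)
    ll = 0.0
    for plot_id, X in designs.items():
        if sizes[plot_id] == 0:
            continue
        g, _ = _group_ll_grad(beta, X, counts[plot_id], sizes[plot_id])
        ll += g
    return ll


def _neg_ll_and_grad(beta, designs, counts, sizes):
    ll = 0.0
    grad = np.zeros_like(beta)
    for plot_id, X in designs.items():
        if sizes[plot_id] == 0:
            continue
        g, d = _group_ll_grad(beta, X, counts[plot_id], sizes[plot_id])
        ll += g
        grad += d
    return -ll, -grad


def _numeric_hessian(fun_grad, beta, step=1e-5):
    k = beta.size
    H = np.zeros((k, k))
    for j in range(k):
        h = step * max(1.0, abs(beta[j]))
        bp, bm = beta.copy(), beta.copy()
        bp[j] += h
        bm[j] -= h
        _, gp = fun_grad(bp)
        _, gm = fun_grad(bm)
        H[:, j] = (gp - gm) / (2 * h)
    return 0.5 * (H + H.T)


def fit(ds: DetectionDataset, spec: ModelSpec | None = None) -> HugginsFit:
    """Maximize the conditional likelihood and derive per-plot abundances.

    Quasi-Newton (BFGS) with analytic gradient, restarted from logit p in
    {−2, −1, 0} if a start fails. Standard errors come from the inverse of a
    finite-difference observed information. Convergence requires a gradient
    infinity-norm below 1e-6 on the link scale; estimates with |logit p|
    beyond 10 are flagged as boundary (the corresponding p is numerically 0
    or 1) and yield no abundance interval.
    """
    if spec is None:
        spec = ModelSpec()
    for plot_id in ds.plot_ids:
        if len(ds.occasions[plot_id]) < 2:
            raise ValueError(f"plot {plot_id!r}: need at least 2 occasions")
    names, designs, counts, sizes = _build_design(ds, spec)
    k = len(names)

    def fg(beta):
        return _neg_ll_and_grad(beta, designs, counts, sizes)

    best = None
    for start in (-1.0, -2.0, 0.0):
        beta0 = np.full(k, start)
        if spec.structure == "experience":
            beta0 = np.array([start, 0.0])
        try:
            res = optimize.minimize(
                fg, beta0, jac=True, method="BFGS",
                options={"gtol": 1e-9, "maxiter": 500},
            )
        except (FloatingPointError, ValueError):
            continue
        if not np.isfinite(res.fun):
            continue
        if best is None or res.fun < best.fun - 1e-10:
            best = res
        if np.max(np.abs(res.jac)) < 1e-6:
            break
    if best is None:
        raise RuntimeError("conditional likelihood could not be evaluated at any start")

    beta = best.x
    grad = best.jac
    # Newton polish: BFGS can stall on precision loss just short of the
    # gradient criterion; a few damped Newton steps finish the job.
    for _ in range(25):
        if np.max(np.abs(grad)) < 1e-8 or np.any(np.abs(beta) > BOUNDARY_LOGIT):
            break
        H = _numeric_hessian(fg, beta)
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            break
        f0_val, _ = fg(beta)
        scale = 1.0
        while scale > 1e-4:
            cand = beta - scale * step
            f_new, g_new = fg(cand)
            if np.isfinite(f_new) and f_new <= f0_val + 1e-12:
                beta, grad = cand, g_new
                break
            scale /= 2
        else:
            break
    grad_norm = float(np.max(np.abs(grad)))
    converged = grad_norm < 1e-6
    boundary = bool(np.any(np.abs(beta) > BOUNDARY_LOGIT))

    H = _numeric_hessian(lambda b: fg(b), beta)
    try:
        vcov = np.linalg.inv(H)
        if np.any(np.diag(vcov) < 0):
            raise np.linalg.LinAlgError
        beta_se = np.sqrt(np.diag(vcov))
    except np.linalg.LinAlgError:
        vcov = np.full((k, k), np.nan)
        beta_se = np.full(k, np.nan)

    fitres = HugginsFit(
        spec=spec,
        param_names=list(names),
        beta=beta,
        beta_se=beta_se,
        vcov=vcov,
        loglik=-float(fg(beta)[0]),
        converged=converged,
        boundary=boundary,
    )
    _fill_p_table(fitres, ds, designs)
    for plot_id in ds.plot_ids:
        fitres.groups[plot_id] = _group_abundance(
            plot_id, beta, vcov, designs[plot_id], sizes[plot_id],
            usable=converged and not boundary,
        )
    return fitres


def _fill_p_table(fitres: HugginsFit, ds: DetectionDataset, designs) -> None:
    spec = fitres.spec
    beta, vcov = fitres.beta, fitres.vcov
    rows: dict[str, np.ndarray] = {}
    if spec.structure == "constant":
        rows["p"] = np.array([1.0])
    elif spec.structure == "occasion":
        for j, name in enumerate(fitres.param_names):
            x = np.zeros(len(fitres.param_names))
            x[j] = 1.0
            rows[name] = x
    else:
        rows["novice"] = np.array([1.0, 0.0])
        rows["expert"] = np.array([1.0, 1.0])
    for name, x in rows.items():
        eta = float(x @ beta)
        se = float(np.sqrt(x @ vcov @ x)) if np.all(np.isfinite(vcov)) else np.nan
        lo, hi = eta - 1.96 * se, eta + 1.96 * se
        fitres.p_table[name] = (float(expit(eta)), float(expit(lo)), float(expit(hi)))


def _group_abundance(plot_id, beta, vcov, X, M, usable=True) -> GroupEstimate:
    eta = X @ beta
    p = expit(eta)
    s = np.sum(log_expit(-eta))
    pstar = float(-np.expm1(s))
    if pstar <= 0 or M == 0:
        return GroupEstimate(plot_id, M, pstar, np.nan, np.nan, np.nan, (np.nan, np.nan))
    n_hat = M / pstar
    f0 = n_hat - M
    # Huggins two-term variance: binomial part Σ(1−p*)/p*² plus the
    # delta-method term for detection-parameter uncertainty.
    var_bin = M * (1 - pstar) / pstar**2
    dpstar_deta = (1 - pstar) * p          # ∂p*/∂eta_t
    J = -(M / pstar**2) * (X.T @ dpstar_deta)
    var_par = float(J @ vcov @ J) if np.all(np.isfinite(vcov)) else np.nan
    var_n = var_bin + var_par
    ci = _lognormal_f0_ci(M, f0, var_n) if usable else (np.nan, np.nan)
    return GroupEstimate(plot_id, M, pstar, float(n_hat), float(f0), float(var_n), ci)


def _lognormal_f0_ci(M: int, f0: float, var_n: float) -> tuple[float, float]:
    if f0 <= 1e-12:
        return (float(M), float(M))
    if not np.isfinite(var_n):
        return (np.nan, np.nan)
    c = np.exp(1.96 * np.sqrt(np.log1p(var_n / f0**2)))
    return (float(M + f0 / c), float(M + f0 * c))


def abundance(fit_result: HugginsFit, plot_id: str) -> tuple[float, tuple[float, float]]:
    """Horvitz–Thompson abundance and log-normal CI for one plot."""
    if plot_id not in fit_result.groups:
        raise KeyError(f"unknown group {plot_id!r}")
    g = fit_result.groups[plot_id]
    return g.n_hat, g.ci95


def experience_model_p(fit_result: HugginsFit) -> dict[str, tuple[float, float, float]]:
    """Back-transformed (estimate, lcl, ucl) per experience level."""
    if fit_result.spec.structure != "experience":
        raise ValueError("fit was not made with the experience structure")
    return {k: fit_result.p_table[k] for k in ("expert", "novice")}


def mean_group_p(fit_result: HugginsFit, ds: DetectionDataset, level: str) -> float:
    """Arithmetic mean of surveyor-specific p̂ over one experience level
    (occasion-structure fits)."""
    if fit_result.spec.structure != "occasion":
        raise ValueError("mean_group_p needs an occasion-structure fit")
    vals = [
        fit_result.p_table[sid][0]
        for sid in fit_result.param_names
        if ds.surveyors[sid].experience == level
    ]
    return float(np.mean(vals))
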