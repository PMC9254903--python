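"""Univariate overall-survival association of gene expression.

Each gene is fit as the single covariate of a Cox proportional-hazards model
on overall survival (Breslow handling of tied event times; the covariate is
standardized log2(FPKM + 1), or a median split when dichotomized). A gene is
classified poor prognosis when the Wald p < 0.1 with HR > 1, good prognosis
when p < 0.1 with HR < 1, else none — raw p-values, no multiplicity
correction (an optional BH column is emitted for transparency).

The solver is a vectorized Newton iteration on the single-covariate partial
likelihood, so thousands of gene-level fits cost one pass of matrix algebra;
it matches general-purpose Cox implementations (e.g. lifelines) on tie-free
data, where Breslow and Efron coincide.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix

SURV_P_DEFAULT = 0.1
MIN_SAMPLES_DEFAULT = 20
MIN_EVENTS_DEFAULT = 5
_BETA_BOUND = 20.0     # |log HR| beyond this on a standardized covariate
_MAX_ITER = 60         # signals monotone likelihood / separation
_TOL = 1e-10


def cox_univariate(x: np.ndarray, time: np.ndarray, event: np.ndarray,
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Newton fit of per-row Cox models sharing one survival outcome.

    ``x`` is (n_models, n_samples): each row is one covariate vector fit
    against the common ``(time, event)`` outcome with Breslow tie handling.
    Returns ``(beta, se, p, converged)`` arrays of length n_models; a model
    whose likelihood is monotone (perfect separation) is reported
    unconverged rather than silently returned at the bound.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="mergesort")
    t_s = time[order]
    e_s = event[order]
    xs = x[:, order]
    n_models, n = xs.shape
    # risk set of an event at t_i = all samples with time >= t_i; with ties,
    # every sample sharing the event time belongs to the risk set
    first_at_time = np.searchsorted(t_s, t_s, side="left")
    ev_idx = np.flatnonzero(e_s == 1)
    ev_start = first_at_time[ev_idx]

    beta = np.zeros(n_models)
    converged = np.zeros(n_models, dtype=bool)
    info = np.full(n_models, np.nan)
    active = np.ones(n_models, dtype=bool)
    for _ in range(_MAX_ITER):
        if not active.any():
            break
        b = beta[active, None]
        xa = xs[active]
        w = np.exp(np.clip(b * xa, -700, 700))
        # reverse cumulative sums over the ascending-time axis
        s0 = np.cumsum(w[:, ::-1], axis=1)[:, ::-1]
        s1 = np.cumsum((w * xa)[:, ::-1], axis=1)[:, ::-1]
        s2 = np.cumsum((w * xa * xa)[:, ::-1], axis=1)[:, ::-1]
        d0 = s0[:, ev_start]
        mu = s1[:, ev_start] / d0
        grad = (xa[:, ev_idx] - mu).sum(axis=1)
        fisher = (s2[:, ev_start] / d0 - mu ** 2).sum(axis=1)
        ok = fisher > 1e-12
        step = np.zeros_like(grad)
        step[ok] = grad[ok] / fisher[ok]
        step = np.clip(step, -2.0, 2.0)
        beta_a = beta[active] + step
        idx = np.flatnonzero(active)
        beta[idx] = beta_a
        info[idx] = fisher
        done = (np.abs(step) < _TOL) & ok
        diverged = (np.abs(beta_a) > _BETA_BOUND) | ~ok
        converged[idx[done]] = True
        active[idx[done | diverged]] = False
    se = np.where(info > 0, 1.0 / np.sqrt(np.maximum(info, 1e-300)), np.nan)
    with np.errstate(invalid="ignore"):
        z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    p = np.where(np.isnan(p), 1.0, p)
    return beta, se, p, converged


def fit_univariate_ph(expression_vector: np.ndarray, time: np.ndarray,
                      event: np.ndarray) -> dict:
    """Single-gene univariate Cox fit of a standardized covariate.

    Returns hr (per 1 SD), p (two-sided Wald), n, n_events and diagnostics;
    cohorts below 20 samples or 5 events, all-censored cohorts and constant
    covariates are flagged unevaluable.
    """
    x = np.asarray(expression_vector, dtype=float)
    event = np.asarray(event, dtype=int)
    n, n_events = x.size, int(event.sum())
    if n < MIN_SAMPLES_DEFAULT or n_events < MIN_EVENTS_DEFAULT:
        return {"hr": np.nan, "p": np.nan, "n": n, "n_events": n_events,
                "evaluable": False, "reason": "too few samples or events"}
    sd = x.std()
    if sd == 0:
        return {"hr": np.nan, "p": np.nan, "n": n, "n_events": n_events,
                "evaluable": False, "reason": "constant covariate"}
    z = (x - x.mean()) / sd
    beta, se, p, conv = cox_univariate(z[None, :], time, event)
    if not conv[0]:
        return {"hr": np.nan, "p": np.nan, "n": n, "n_events": n_events,
                "evaluable": False, "reason": "monotone likelihood"}
    return {"hr": float(np.exp(beta[0])), "se": float(se[0]),
            "p": float(p[0]), "n": n, "n_events": n_events,
            "evaluable": True, "reason": "ok"}


def classify_prognosis(hr: float, p: float,
                       p_threshold: float = SURV_P_DEFAULT) -> str:
    """poor: p < threshold and HR > 1; good: p < threshold and HR < 1."""
    if not (np.isfinite(hr) and np.isfinite(p)):
        return "none"
    if p < p_threshold and hr > 1:
        return "poor"
    if p < p_threshold and hr < 1:
        return "good"
    return "none"


def survival_results(expression: ExpressionMatrix, clinical: pd.DataFrame,
                     cancer_type: str, p_threshold: float = SURV_P_DEFAULT,
                     covariate: str = "continuous") -> pd.DataFrame:
    """Per-gene univariate survival table for one cancer type.

    ``covariate='continuous'`` fits standardized log2(FPKM+1);
    ``covariate='median'`` fits the above/below-median indicator instead.
    The survival evidence flag is prognosis ≠ none.
    """
    if covariate not in ("continuous", "median"):
        raise ValueError("covariate must be 'continuous' or 'median'")
    tumours = expression.tumour_samples()
    clin = clinical[clinical["sample_id"].isin(tumours)]
    clin = clin.drop_duplicates("sample_id")
    samples = clin["sample_id"].to_list()
    time = clin["os_time"].to_numpy(dtype=float)
    event = clin["os_event"].to_numpy(dtype=int)
    genes = expression.values.index
    n, n_events = len(samples), int(event.sum())

    base = pd.DataFrame({"gene_id": genes, "cancer_type": cancer_type,
                         "n": n, "n_events": n_events})
    if n < MIN_SAMPLES_DEFAULT or n_events < MIN_EVENTS_DEFAULT:
        return base.assign(hr=np.nan, p=np.nan, q=np.nan, prognosis="none",
                           surv_flag=False, reason="too few samples or events")
    expr = np.log2(expression.values[samples].to_numpy(dtype=float) + 1.0)
    sd = expr.std(axis=1)
    constant = sd == 0
    if covariate == "continuous":
        z = (expr - expr.mean(axis=1, keepdims=True)) / np.where(sd == 0, 1, sd)[:, None]
    else:
        med = np.median(expr, axis=1, keepdims=True)
        z = (expr > med).astype(float)
        constant = constant | (z.std(axis=1) == 0)
    beta, se, p, conv = cox_univariate(z, time, event)
    hr = np.exp(beta)
    evaluable = conv & ~constant
    hr = np.where(evaluable, hr, np.nan)
    p = np.where(evaluable, p, np.nan)
    q = np.full(len(genes), np.nan)
    if evaluable.any():
        q[evaluable] = stats.false_discovery_control(p[evaluable], method="bh")
    prognosis = np.array([classify_prognosis(h, pv, p_threshold)
                          for h, pv in zip(hr, p)], dtype=object)
    reason = np.where(constant, "constant covariate",
                      np.where(~conv, "monotone likelihood", "ok"))
    return base.assign(hr=hr, p=p, q=q, prognosis=prognosis,
                       surv_flag=prognosis != "none", reason=reason)
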