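"""Model selection over a candidate list scored on estimation/validation data.

Six selection methods operate on per-model scores:

* ``ssr``        — smallest estimation-data SSR;
* ``first_chi2`` — the simplest model passing the chi-square test;
* ``best_chi2``  — the passing model with the greatest margin below the
  chi-square threshold (margin = threshold - SSR, an absolute difference);
* ``aic`` / ``bic`` — smallest SSR + 2p, resp. SSR + p ln N (known-sigma
  Gaussian forms, constants dropped);
* ``validation`` — each model is fitted on the estimation split only and
  the model with the smallest SSR on the held-out validation split wins.

All ties break to the fewest parameters, then to the lexically smallest
model id.  ``p`` is the number of free parameters (free fluxes for network
models, coefficients otherwise).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.stats

from .emu_engine import TracerSpec, full_emu
from .estimation import (
    FitConfig,
    MeasurementSet,
    MFAProblem,
    aggregate_replicates,
)
from .network_model import NetworkModel

__all__ = [
    "ModelScore",
    "SelectionResult",
    "chi2_test",
    "score_models",
    "select_ssr",
    "select_first_chi2",
    "select_best_chi2",
    "select_aic",
    "select_bic",
    "select_validation",
    "apply_selection",
    "rescale_scores",
    "run_selection",
    "MFACandidate",
    "METHODS",
]

METHODS = ["ssr", "first_chi2", "best_chi2", "aic", "bic", "validation"]


def chi2_test(ssr: float, N: int, p: int, alpha: float = 0.95) -> tuple[bool, float]:
    """Goodness-of-fit test: SSR < inverse-chi-square(alpha, N - p).

    Returns (pass, threshold).  Raises if the degrees of freedom N - p are
    not positive or alpha is not in (0, 1).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if N <= p:
        raise ValueError("degrees of freedom non-positive")
    threshold = float(scipy.stats.chi2.ppf(alpha, N - p))
    return bool(ssr < threshold), threshold


@dataclass
class ModelScore:
    """Per-model statistics consumed by the selection methods."""

    model_id: str
    p: int
    N: int
    ssr_est: float
    chi2_threshold: float
    passes_chi2: bool
    margin: float
    aic: float
    bic: float
    ssr_val: float | None = None
    params: np.ndarray | None = field(default=None, repr=False)
    fit_failed: bool = False

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "p": self.p,
            "N": self.N,
            "ssr_est": self.ssr_est,
            "chi2_threshold": self.chi2_threshold,
            "passes_chi2": self.passes_chi2,
            "margin": self.margin,
            "aic": self.aic,
            "bic": self.bic,
            "ssr_val": self.ssr_val,
            "fit_failed": self.fit_failed,
        }


@dataclass
class SelectionResult:
    method: str
    chosen: str | None
    scores: list[ModelScore]
    tie_break_applied: bool = False
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "chosen": self.chosen,
            "tie_break_applied": self.tie_break_applied,
            "note": self.note,
            "scores": [s.to_dict() for s in self.scores],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


class MFACandidate:
    """Adapter giving a network model the candidate fit/score interface."""

    def __init__(
        self,
        model: NetworkModel,
        tracers: dict[str, TracerSpec],
        normalized_flux: str | None = None,
        fit_config: FitConfig | None = None,
        estimation_tracers: list[str] | None = None,
    ):
        names = estimation_tracers or list(tracers)
        self.problem = MFAProblem(
            model, [tracers[n] for n in names], normalized_flux=normalized_flux
        )
        self.tracers = dict(tracers)
        self.fit_config = fit_config or FitConfig()
        self.model_id = model.name

    @property
    def n_params(self) -> int:
        return self.problem.n_free_parameters

    def fit(self, data: MeasurementSet) -> tuple[np.ndarray, float]:
        res = self.problem.fit(data, self.fit_config)
        return res.v_star, res.ssr_star

    def ssr(self, v: np.ndarray, data: MeasurementSet) -> float:
        """Weighted SSR of the flux vector `v` against `data`.

        Works for tracers outside the estimation set: the compiled cascade
        is re-solved for whatever tracers the data references.
        """
        agg = aggregate_replicates(data)
        df = agg.data
        names = list(dict.fromkeys(df["tracer"]))
        trs = tuple(self.tracers[n] for n in names)
        X, _, _ = self.problem.cascade._solve(np.asarray(v, float), trs, strict=False)
        tpos = {n: i for i, n in enumerate(names)}
        yhat = np.empty(len(df))
        for i, row in enumerate(df.itertuples(index=False)):
            bi, r = self.problem.cascade.locate(
                full_emu(self.problem.model, row.metabolite)
            )
            yhat[i] = X[bi][r, int(row.mass_isotopomer), tpos[row.tracer]]
        r = (yhat - df["value"].to_numpy(float)) / df["sd"].to_numpy(float)
        return float(r @ r)


def score_models(
    candidates: list,
    d_est: MeasurementSet,
    d_val: MeasurementSet | None = None,
    alpha: float = 0.95,
) -> list[ModelScore]:
    """Fit every candidate on `d_est` and assemble its ModelScore.

    Replicates are aggregated to means with standard errors before any
    fitting or scoring; N is the aggregated estimation record count.  A
    candidate whose fit raises is scored with infinite SSRs and flagged.
    """
    est = aggregate_replicates(d_est)
    val = aggregate_replicates(d_val) if d_val is not None and len(d_val) else None
    N = len(est)
    scores = []
    for cand in candidates:
        p = cand.n_params
        try:
            params, ssr_est = cand.fit(est)
            ssr_val = cand.ssr(params, val) if val is not None else None
            failed = False
        except Exception:
            params, ssr_est, ssr_val, failed = None, np.inf, np.inf, True
            if val is None:
                ssr_val = None
        passes, threshold = chi2_test(ssr_est, N, p, alpha) if N > p else (
            False, np.nan)
        scores.append(
            ModelScore(
                model_id=cand.model_id,
                p=p,
                N=N,
                ssr_est=float(ssr_est),
                chi2_threshold=threshold,
                passes_chi2=passes,
                margin=threshold - ssr_est,
                aic=float(ssr_est + 2 * p),
                bic=float(ssr_est + p * np.log(N)),
                ssr_val=None if ssr_val is None else float(ssr_val),
                params=params,
                fit_failed=failed,
            )
        )
    return scores


_TIE_RTOL = 1e-6
_TIE_ATOL = 1e-9


def _argbest(scores: list[ModelScore], key, method: str,
             minimize: bool = True, note: str = "") -> SelectionResult:
    if not scores:
        raise ValueError("empty candidate list")
    sign = 1.0 if minimize else -1.0
    vals = {s.model_id: sign * key(s) for s in scores}
    best_val = min(vals.values())
    if not np.isfinite(best_val):
        return SelectionResult(method, None, scores, note=note or
                               "no candidate produced a finite score")
    # Criterion values equal up to optimizer/floating-point resolution are
    # ties; comparing beyond that resolution would pick a model by noise.
    tol = _TIE_ATOL + _TIE_RTOL * abs(best_val)
    tied = [s for s in scores if vals[s.model_id] <= best_val + tol]
    best = min(tied, key=lambda s: (s.p, s.model_id))
    return SelectionResult(method, best.model_id, scores,
                           tie_break_applied=len(tied) > 1, note=note)


def select_ssr(scores: list[ModelScore]) -> SelectionResult:
    """Smallest estimation-data SSR."""
    return _argbest(scores, lambda s: s.ssr_est, "ssr")


def select_first_chi2(scores: list[ModelScore]) -> SelectionResult:
    """Simplest model (ascending p) passing the chi-square test."""
    if not scores:
        raise ValueError("empty candidate list")
    for s in sorted(scores, key=lambda s: (s.p, s.model_id)):
        if s.passes_chi2:
            return SelectionResult("first_chi2", s.model_id, scores)
    return SelectionResult("first_chi2", None, scores,
                           note="no model passed the chi-square test")


def select_best_chi2(scores: list[ModelScore]) -> SelectionResult:
    """Passing model with the greatest margin = threshold - SSR."""
    passing = [s for s in scores if s.passes_chi2]
    if not passing:
        if not scores:
            raise ValueError("empty candidate list")
        return SelectionResult("best_chi2", None, scores,
                               note="no model passed the chi-square test")
    res = _argbest(passing, lambda s: s.margin, "best_chi2", minimize=False)
    res.scores = scores
    return res


def select_aic(scores: list[ModelScore]) -> SelectionResult:
    """Smallest SSR + 2p."""
    return _argbest(scores, lambda s: s.aic, "aic")


def select_bic(scores: list[ModelScore]) -> SelectionResult:
    """Smallest SSR + p ln N."""
    return _argbest(scores, lambda s: s.bic, "bic")


def select_validation(scores: list[ModelScore]) -> SelectionResult:
    """Smallest SSR on the held-out validation split.

    Requires `ssr_val` on every score (i.e. score_models was given a
    nonempty validation split).  The chosen model has not been subjected
    to final testing on independent data; the result records this.
    """
    if any(s.ssr_val is None for s in scores):
        raise ValueError("validation selection requires validation-split scores")
    return _argbest(
        scores, lambda s: s.ssr_val, "validation",
        note="selected by validation SSR; final model testing on "
             "independent data not performed",
    )


_SELECTORS = {
    "ssr": select_ssr,
    "first_chi2": select_first_chi2,
    "best_chi2": select_best_chi2,
    "aic": select_aic,
    "bic": select_bic,
    "validation": select_validation,
}


def apply_selection(
    scores: list[ModelScore],
    methods: list[str] | None = None,
) -> dict[str, SelectionResult]:
    """Apply the named selection methods to precomputed scores."""
    methods = methods or METHODS
    unknown = set(methods) - set(_SELECTORS)
    if unknown:
        raise ValueError(f"unknown selection methods {sorted(unknown)}")
    return {m: _SELECTORS[m](scores) for m in methods}


def rescale_scores(
    scores: list[ModelScore],
    c: float,
    alpha: float = 0.95,
) -> list[ModelScore]:
    """Scores after multiplying every believed sigma by the constant c.

    Weighted least squares with sigmas c*sigma has the same minimizer as
    with sigmas sigma, and every SSR scales by exactly 1/c**2.  One fit
    therefore serves any homogeneous rescaling of the believed sigmas;
    only the derived statistics (chi-square pass, margin, AIC, BIC) need
    recomputing.
    """
    if c <= 0:
        raise ValueError("sigma scale factor must be positive")
    out = []
    for s in scores:
        ssr = s.ssr_est / c**2
        passes, threshold = (
            chi2_test(ssr, s.N, s.p, alpha) if s.N > s.p else (False, np.nan)
        )
        out.append(ModelScore(
            model_id=s.model_id, p=s.p, N=s.N,
            ssr_est=float(ssr),
            chi2_threshold=threshold,
            passes_chi2=passes,
            margin=threshold - ssr,
            aic=float(ssr + 2 * s.p),
            bic=float(ssr + s.p * np.log(s.N)),
            ssr_val=None if s.ssr_val is None else float(s.ssr_val / c**2),
            params=s.params,
            fit_failed=s.fit_failed,
        ))
    return out


def run_selection(
    candidates: list,
    data: MeasurementSet,
    methods: list[str] | None = None,
    alpha: float = 0.95,
) -> dict[str, SelectionResult]:
    """Split `data` by its split tags, score candidates, apply methods."""
    methods = methods or METHODS
    unknown = set(methods) - set(_SELECTORS)
    if unknown:
        raise ValueError(f"unknown selection methods {sorted(unknown)}")
    d_est = data.subset("est")
    d_val = data.subset("val")
    need_val = "validation" in methods and len(d_val) > 0
    if "validation" in methods and not need_val:
        raise ValueError("validation selection requires a 'val' split")
    scores = score_models(candidates, d_est, d_val if need_val else None,
                          alpha=alpha)
    return apply_selection(scores, methods)
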