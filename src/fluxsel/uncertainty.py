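"""Prediction and flux uncertainty: profile likelihood, MCMC, novelty.

Two interval methods over a fitted weighted-least-squares objective f(u):

* prediction profile likelihood — the scalar prediction of interest is
  pushed away from its best-fit value by re-optimizing f plus a stiff
  penalty W (p_target - p_sim(u))^2; the interval collects every target
  value whose profiled (unpenalized) objective stays within a chi-square
  cutoff of the optimum;
* Metropolis-Hastings sampling of the density proportional to
  exp(-f(u)/2); the interval is the range (or percentile band) of the
  prediction over samples within a chi-square threshold of the optimum.

Also: profile confidence intervals for individual fluxes, and an
assessment of whether a validation dataset is informative (neither too
similar to the estimation data nor too novel to be predicted).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize
import scipy.stats

__all__ = [
    "PPLConfig",
    "PredictionProfile",
    "PosteriorSample",
    "NoveltyReport",
    "profile_prediction",
    "ppl_interval",
    "flux_ci",
    "mcmc_sample",
    "MCMCConfig",
    "prediction_interval",
    "assess_novelty",
    "tracer_rank_surrogate",
]


@dataclass(frozen=True)
class PPLConfig:
    """Stepping configuration for profile intervals.

    `W` is the penalty stiffness; `step` the initial target increment (in
    prediction units); near the cutoff the step is halved down to
    `step / 2**max_halvings`, and while the profile stays far below the
    cutoff the step may grow by `growth` up to `max_step` so wide (weakly
    constrained) profiles terminate in reasonable time.
    """

    W: float = 1e6
    step: float = 0.005
    alpha: float = 0.95
    cutoff: float | None = None  # default: chi-square(alpha, 1) quantile
    max_steps: int = 400
    max_halvings: int = 6
    growth: float = 1.0  # 1.0 = fixed step; >1 enables adaptive growth
    max_step: float = np.inf
    lo_bound: float = 0.0
    hi_bound: float = 1.0

    def resolved_cutoff(self) -> float:
        if self.cutoff is not None:
            return float(self.cutoff)
        return float(scipy.stats.chi2.ppf(self.alpha, 1))


@dataclass
class PredictionProfile:
    """Profiled objective along one scalar prediction."""

    target: str
    p_best: float
    f_star: float
    cutoff: float
    W: float
    grid: list[tuple[float, float]]  # (p_target, profiled unpenalized f)
    lo: float
    hi: float
    unbounded_lo: bool = False
    unbounded_hi: bool = False

    @property
    def interval(self) -> tuple[float, float]:
        return self.lo, self.hi

    @property
    def width(self) -> float:
        return self.hi - self.lo

    def to_dict(self) -> dict:
        return {
            "target": self.target, "p_best": self.p_best,
            "f_star": self.f_star, "cutoff": self.cutoff, "W": self.W,
            "lo": self.lo, "hi": self.hi,
            "unbounded_lo": self.unbounded_lo,
            "unbounded_hi": self.unbounded_hi,
            "grid": self.grid,
        }


def _penalized_min(fg, u0, W, p_target, bounds, constraints):
    """Minimize f(u) + W (p_target - pred(u))^2 warm-started at u0."""

    def gfun(u):
        f, gf, pred, gp = fg(u)
        d = p_target - pred
        return f + W * d * d, gf - 2.0 * W * d * gp

    res = scipy.optimize.minimize(
        gfun, u0, jac=True, method="SLSQP", bounds=bounds,
        constraints=constraints, options={"maxiter": 500, "ftol": 1e-9},
    )
    f, _, pred, _ = fg(res.x)
    return res.x, float(f), float(pred)


def profile_prediction(
    fg,
    u_star: np.ndarray,
    config: PPLConfig | None = None,
    bounds=None,
    constraints=(),
    target: str = "prediction",
) -> PredictionProfile:
    """Profile the scalar prediction returned by `fg`.

    `fg(u) -> (f, grad_f, pred, grad_pred)` evaluates the objective and
    the scalar prediction with gradients.  The target value is stepped up
    and down from the best-fit prediction; the interval endpoint in each
    direction is the last target whose re-optimized unpenalized objective
    stays within `cutoff` of the optimum.  Endpoints are clipped to the
    configured prediction bounds; hitting a bound before exceeding the
    cutoff flags that side as unbounded.
    """
    config = config or PPLConfig()
    cutoff = config.resolved_cutoff()
    f_star, _, p_best, _ = fg(np.asarray(u_star, float))
    f_star = float(f_star)
    p_best = float(p_best)
    grid = [(p_best, f_star)]
    endpoints = {}
    flags = {}
    for direction, bound in ((+1.0, config.hi_bound), (-1.0, config.lo_bound)):
        u = np.asarray(u_star, float).copy()
        p_t = p_best
        endpoint = p_best
        unbounded = False
        step = config.step
        halvings = 0
        for _ in range(config.max_steps):
            nxt = p_t + direction * step
            hit_bound = (direction > 0 and nxt >= bound) or (
                direction < 0 and nxt <= bound)
            if hit_bound:
                nxt = bound
            u_try, f_prof, _ = _penalized_min(
                fg, u, config.W, nxt, bounds, constraints)
            if f_prof > f_star + cutoff:
                if halvings < config.max_halvings and step > 1e-12:
                    step /= 2.0
                    halvings += 1
                    continue
                break
            grid.append((nxt, f_prof))
            endpoint, p_t, u = nxt, nxt, u_try
            if hit_bound:
                unbounded = True
                break
            if config.growth > 1.0 and f_prof < f_star + 0.5 * cutoff:
                step = min(step * config.growth, config.max_step)
        endpoints[direction] = endpoint
        flags[direction] = unbounded
    grid.sort()
    return PredictionProfile(
        target=target, p_best=p_best, f_star=f_star, cutoff=cutoff,
        W=config.W, grid=grid, lo=endpoints[-1.0], hi=endpoints[1.0],
        unbounded_lo=flags[-1.0], unbounded_hi=flags[1.0],
    )


def _mfa_fg(problem, bound, t_idx: int, b_idx: int, r_idx: int, m_idx: int):
    """Combined objective/target evaluator for a network-flux problem.

    `bound` is the problem's bound measurement set; the target is the
    simulated fraction X[b_idx][r_idx, m_idx, t_idx].
    """

    def fg(u):
        X, dX = problem.sens.simulate(u, problem.tracers)
        yhat = np.array(
            [X[b][r, m, t] for t, b, r, m in
             zip(bound.t_idx, bound.b_idx, bound.r_idx, bound.m_idx)]
        )
        J = np.stack(
            [dX[b][:, r, m, t] for t, b, r, m in
             zip(bound.t_idx, bound.b_idx, bound.r_idx, bound.m_idx)]
        )
        r = (yhat - bound.y) / bound.sigma
        f = float(r @ r)
        gf = 2.0 * (J.T @ (r / bound.sigma))
        pred = float(X[b_idx][r_idx, m_idx, t_idx])
        gp = np.array([dX[b_idx][i, r_idx, m_idx, t_idx]
                       for i in range(problem.sens.p)])
        return f, gf, pred, gp

    return fg


def ppl_interval(
    problem,
    data,
    u_star: np.ndarray,
    omega: tuple[str, str, int],
    config: PPLConfig | None = None,
) -> PredictionProfile:
    """Profile interval for one mass fraction of a network-flux problem.

    `omega` = (tracer name, metabolite, mass index).  The problem must
    carry the tracer; `u_star` is the fitted free-flux vector.
    """
    from .emu_engine import full_emu

    tracer, metabolite, mass = omega
    bound = problem.bind(data)
    bi, row = problem.cascade.locate(full_emu(problem.model, metabolite))
    t_i = problem.tracer_index[tracer]
    fg = _mfa_fg(problem, bound, t_i, bi, row, int(mass))
    cons, bnds = _mfa_constraints(problem)
    return profile_prediction(
        fg, u_star, config, bounds=bnds, constraints=cons,
        target=f"{tracer}:{metabolite}:M+{mass}",
    )


def _mfa_constraints(problem):
    cons = [{"type": "ineq",
             "fun": lambda u: problem.param.K @ u,
             "jac": lambda u: problem.param.K}]
    if problem.param.fixed_index is not None:
        row = problem.param.K[problem.param.fixed_index]
        cons.append({"type": "eq",
                     "fun": lambda u, row=row: row @ u - 1.0,
                     "jac": lambda u, row=row: row[None, :]})
    bnds = [(problem.param.lb, problem.param.ub)] * problem.param.nullity
    return cons, bnds


def flux_ci(
    problem,
    data,
    u_star: np.ndarray,
    flux_index: int,
    alpha: float = 0.95,
    config: PPLConfig | None = None,
) -> PredictionProfile:
    """Profile confidence interval for one net flux.

    Same stepping machinery as the prediction profile, with the penalty
    applied to v[flux_index] = (K u)[flux_index] and cutoff the
    chi-square(alpha, 1) quantile.  Fluxes are unbounded above, so the
    default configuration uses an adaptively growing step and a large
    upper stepping bound.
    """
    if config is None:
        config = PPLConfig(step=0.01, alpha=alpha, growth=2.0, max_step=5.0,
                           lo_bound=0.0, hi_bound=1e3)
    bound = problem.bind(data)
    k_row = problem.param.K[flux_index]

    def fg(u):
        f, gf = bound.ssr_and_grad(u)
        return f, gf, float(k_row @ u), k_row

    cons, bnds = _mfa_constraints(problem)
    name = problem.model.reactions[flux_index].id
    return profile_prediction(fg, u_star, config, bounds=bnds,
                              constraints=cons, target=f"flux:{name}")


# ---------------------------------------------------------------------------
# MCMC


@dataclass(frozen=True)
class MCMCConfig:
    n_samples: int = 100_000
    seed: int = 0
    proposal_scale: float | None = None  # default 0.05 per coordinate
    alpha: float = 0.95
    dof: int | None = None  # default: dimension of u
    burn_in_fraction: float = 0.1
    adapt_interval: int = 200


@dataclass
class PosteriorSample:
    chain: np.ndarray  # (n, p), post burn-in
    f_values: np.ndarray
    acceptance_rate: float
    seed: int
    threshold: float
    alpha: float
    dof: int
    proposal_scale: float

    def retained(self) -> np.ndarray:
        """Samples acceptable w.r.t. the estimation data."""
        return self.chain[self.f_values <= self.threshold]

    def retained_f(self) -> np.ndarray:
        return self.f_values[self.f_values <= self.threshold]


def mcmc_sample(
    f,
    u_star: np.ndarray,
    config: MCMCConfig | None = None,
    feasible=None,
    f_star: float | None = None,
) -> PosteriorSample:
    """Metropolis-Hastings over u with target density exp(-f(u)/2).

    The isotropic Gaussian proposal scale adapts during burn-in toward an
    acceptance rate in [0.2, 0.4].  Infeasible proposals (feasible(u)
    False) are rejected outright.  The retained set keeps every sample
    with f within the chi-square(alpha, dof) quantile of the optimum,
    dof defaulting to the parameter count.
    """
    config = config or MCMCConfig()
    rng = np.random.default_rng(config.seed)
    u = np.asarray(u_star, float).copy()
    p = u.size
    dof = config.dof if config.dof is not None else p
    fu = float(f(u))
    best = fu if f_star is None else min(float(f_star), fu)
    scale = config.proposal_scale or 0.05
    n = int(config.n_samples)
    burn = int(round(config.burn_in_fraction * n))
    chain = np.empty((n, p))
    fvals = np.empty(n)
    accepted = 0
    window_accepted = 0
    for i in range(burn + n):
        prop = u + rng.normal(0.0, scale, size=p)
        ok = feasible(prop) if feasible is not None else True
        if ok:
            fp = float(f(prop))
            if fp <= fu or rng.random() < np.exp(-(fp - fu) / 2.0):
                u, fu = prop, fp
                best = min(best, fu)
                if i >= burn:
                    accepted += 1
                else:
                    window_accepted += 1
        if i < burn and (i + 1) % config.adapt_interval == 0:
            rate = window_accepted / config.adapt_interval
            if rate < 0.2:
                scale *= 0.6
            elif rate > 0.4:
                scale *= 1.5
            window_accepted = 0
        if i >= burn:
            chain[i - burn] = u
            fvals[i - burn] = fu
    acceptance = accepted / n
    if acceptance < 0.01:
        raise RuntimeError(
            "MCMC acceptance rate below 1% after adaptation; rescale the "
            "proposal (decrease proposal_scale) or reparameterize"
        )
    threshold = best + float(scipy.stats.chi2.ppf(config.alpha, dof))
    return PosteriorSample(
        chain=chain, f_values=fvals, acceptance_rate=acceptance,
        seed=config.seed, threshold=threshold, alpha=config.alpha,
        dof=dof, proposal_scale=scale,
    )


def prediction_interval(
    sample: PosteriorSample,
    predict,
    mode: str = "minmax",
) -> tuple[float, float]:
    """Interval of `predict(u)` over the retained posterior samples.

    mode "minmax" takes the full range; "percentile" the 2.5/97.5 band.
    """
    retained = sample.retained()
    if len(retained) == 0:
        raise RuntimeError("no retained samples below the threshold")
    vals = np.array([predict(u) for u in retained])
    if mode == "minmax":
        return float(vals.min()), float(vals.max())
    if mode == "percentile":
        lo, hi = np.percentile(vals, [2.5, 97.5])
        return float(lo), float(hi)
    raise ValueError(f"unknown interval mode {mode!r}")


# ---------------------------------------------------------------------------
# Validation-data novelty


@dataclass
class NoveltyReport:
    entries: list[dict]
    verdict: str  # too_similar | too_novel | informative
    width_threshold: float
    diff_multiplier: float
    surrogate: dict | None = field(default=None)

    def to_dict(self) -> dict:
        return {
            "verdict": self.verdict,
            "width_threshold": self.width_threshold,
            "diff_multiplier": self.diff_multiplier,
            "entries": self.entries,
            "emu_input_rank_surrogate": self.surrogate,
        }


def assess_novelty(
    predictions: list[dict],
    est_data,
    sigma_b: float,
    width_threshold: float = 0.9,
    diff_multiplier: float = 2.0,
    surrogate: dict | None = None,
) -> NoveltyReport:
    """Classify a validation design from its prediction intervals.

    `predictions`: one dict per validation mass fraction with keys
    metabolite, mass_isotopomer, lo, hi, predicted.  Each is compared to
    the estimation-data observation of the same metabolite and mass index
    whose value is closest to the prediction.  Verdicts per entry:

    * too_novel    — interval width > `width_threshold` (the prediction
      uncertainty approaches the whole [0, 1] range);
    * different    — |predicted - nearest estimation observation| >
      `diff_multiplier` * sigma_b;
    * similar      — otherwise.

    Summary: too_novel if any entry is too novel; too_similar if no entry
    differs from the estimation data; informative otherwise.
    """
    df = est_data.data
    entries = []
    any_novel = False
    any_diff = False
    for pr in predictions:
        width = float(pr["hi"]) - float(pr["lo"])
        match = df[
            (df["metabolite"] == pr["metabolite"])
            & (df["mass_isotopomer"] == pr["mass_isotopomer"])
        ]
        if len(match):
            diffs = np.abs(match["value"].to_numpy(float) - float(pr["predicted"]))
            ref = float(match["value"].to_numpy(float)[np.argmin(diffs)])
            diff = float(diffs.min())
        else:
            ref, diff = np.nan, np.inf
        if width > width_threshold:
            verdict = "too_novel"
            any_novel = True
        elif diff > diff_multiplier * sigma_b:
            verdict = "different"
            any_diff = True
        else:
            verdict = "similar"
        entries.append({**{k: pr[k] for k in
                           ("metabolite", "mass_isotopomer", "lo", "hi",
                            "predicted")},
                        "reference": ref, "difference": diff,
                        "verdict": verdict})
    if any_novel:
        overall = "too_novel"
    elif not any_diff:
        overall = "too_similar"
    else:
        overall = "informative"
    return NoveltyReport(
        entries=entries, verdict=overall,
        width_threshold=width_threshold, diff_multiplier=diff_multiplier,
        surrogate=surrogate,
    )


def tracer_rank_surrogate(cascade, est_tracers, val_tracer) -> dict:
    """Rank-based check whether a validation tracer adds input information.

    Stacks each tracer's substrate-EMU MID vectors into one row and
    compares the rank of the estimation-tracer matrix with and without the
    validation tracer.  This is a simplified surrogate for a full
    EMU-basis-vector independence analysis and is labelled as such.
    """
    substrate_emus = sorted(
        {ref[1] for b in cascade.blocks for entry in b.y_entries
         for ref in entry if ref[0] == "x"}
    )

    def row(tracer):
        parts = []
        for emu in substrate_emus:
            parts.append(cascade._tracer_mid(tracer, emu))
        return np.concatenate(parts)

    M_est = np.array([row(t) for t in est_tracers])
    M_all = np.vstack([M_est, row(val_tracer)])
    r_est = int(np.linalg.matrix_rank(M_est, tol=1e-10))
    r_all = int(np.linalg.matrix_rank(M_all, tol=1e-10))
    return {
        "method": "surrogate",
        "rank_estimation": r_est,
        "rank_with_validation": r_all,
        "adds_information": r_all > r_est,
    }
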