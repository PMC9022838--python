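"""Profile likelihood, MCMC, and novelty assessment.

Oracle: the linear-Gaussian toy model y = a*x has closed-form profile and
posterior prediction intervals (p_hat +/- z * sigma_pred); both interval
methods are checked against it.
"""

import numpy as np
import pytest
import scipy.stats

from fluxsel.uncertainty import (
    MCMCConfig,
    PPLConfig,
    assess_novelty,
    mcmc_sample,
    prediction_interval,
    profile_prediction,
    tracer_rank_surrogate,
)


def _linear_toy(sigma=0.5, x_star=2.0, seed=0, n=12):
    """Returns (fg, a_hat, analytic prediction sd, x, y)."""
    rng = np.random.default_rng(seed)
    x = np.linspace(0.5, 3.0, n)
    a_true = 1.7
    y = a_true * x + rng.normal(0, sigma, size=n)
    a_hat = float((x @ y) / (x @ x))
    sigma_a = sigma / np.sqrt(x @ x)
    sigma_pred = abs(x_star) * sigma_a

    def fg(u):
        a = u[0]
        r = (a * x - y) / sigma
        f = float(r @ r)
        gf = np.array([2.0 * float((x / sigma) @ r)])
        return f, gf, a * x_star, np.array([x_star])

    return fg, a_hat, sigma_pred, x, y


def test_ppl_matches_analytic_interval():
    fg, a_hat, sigma_pred, *_ = _linear_toy()
    config = PPLConfig(step=0.002, lo_bound=-100.0, hi_bound=100.0,
                       max_steps=2000)
    prof = profile_prediction(fg, np.array([a_hat]), config)
    z = np.sqrt(scipy.stats.chi2.ppf(0.95, 1))
    want = 2 * z * sigma_pred
    assert abs(prof.width - want) / want < 0.02
    assert prof.lo < prof.p_best < prof.hi
    assert not prof.unbounded_lo and not prof.unbounded_hi


def test_ppl_cutoff_monotone():
    """A larger confidence level gives a wider interval."""
    fg, a_hat, *_ = _linear_toy()
    widths = []
    for alpha in (0.68, 0.95, 0.99):
        config = PPLConfig(step=0.002, alpha=alpha, lo_bound=-100.0,
                           hi_bound=100.0, max_steps=2000)
        widths.append(profile_prediction(fg, np.array([a_hat]), config).width)
    assert widths[0] < widths[1] < widths[2]


def test_ppl_collapses_for_sharp_data():
    """Noise approaching zero: the interval collapses to the step scale."""
    fg, a_hat, *_ = _linear_toy(sigma=1e-5)
    # the penalty must dominate the (very stiff) data term
    config = PPLConfig(W=1e14, step=0.01, lo_bound=-100.0, hi_bound=100.0)
    prof = profile_prediction(fg, np.array([a_hat]), config)
    assert prof.width <= 2 * config.step


def test_ppl_unbounded_flag():
    """An unconstrained prediction runs to the stepping bound."""

    def fg(u):
        # objective ignores u entirely: any prediction is equally good
        return 0.0, np.zeros(1), float(u[0]), np.ones(1)

    config = PPLConfig(step=0.2, lo_bound=0.0, hi_bound=1.0, max_steps=50)
    prof = profile_prediction(fg, np.array([0.5]), config)
    assert prof.unbounded_lo and prof.unbounded_hi
    assert prof.interval == (0.0, 1.0)


def test_mcmc_matches_analytic_interval():
    fg, a_hat, sigma_pred, x, y = _linear_toy()

    def f(u):
        f_val, _, _, _ = fg(u)
        return f_val

    sample = mcmc_sample(f, np.array([a_hat]),
                         MCMCConfig(n_samples=40_000, seed=0, dof=1))
    assert 0.05 < sample.acceptance_rate
    lo, hi = prediction_interval(sample, lambda u: 2.0 * u[0])
    z = np.sqrt(scipy.stats.chi2.ppf(0.95, 1))
    want = 2 * z * sigma_pred
    got = hi - lo
    # minmax over retained samples under-/overshoots only by MC error
    assert abs(got - want) / want < 0.1


def test_mcmc_deterministic():
    fg, a_hat, *_ = _linear_toy()
    f = lambda u: fg(u)[0]
    s1 = mcmc_sample(f, np.array([a_hat]), MCMCConfig(n_samples=2000, seed=3))
    s2 = mcmc_sample(f, np.array([a_hat]), MCMCConfig(n_samples=2000, seed=3))
    assert np.array_equal(s1.chain, s2.chain)
    assert s1.acceptance_rate == s2.acceptance_rate


def test_mcmc_feasibility_respected():
    fg, a_hat, *_ = _linear_toy()
    f = lambda u: fg(u)[0]
    sample = mcmc_sample(f, np.array([a_hat]),
                         MCMCConfig(n_samples=5000, seed=1),
                         feasible=lambda u: u[0] >= a_hat)
    assert (sample.chain[:, 0] >= a_hat).all()


def test_mcmc_low_acceptance_raises():
    f = lambda u: float(1e6 * u @ u)
    with pytest.raises(RuntimeError, match="acceptance rate"):
        mcmc_sample(f, np.zeros(1),
                    MCMCConfig(n_samples=2000, seed=0,
                               proposal_scale=1e6, burn_in_fraction=0.0))


def test_prediction_interval_modes():
    fg, a_hat, *_ = _linear_toy()
    f = lambda u: fg(u)[0]
    sample = mcmc_sample(f, np.array([a_hat]),
                         MCMCConfig(n_samples=10_000, seed=0, dof=1))
    mn = prediction_interval(sample, lambda u: u[0], mode="minmax")
    pc = prediction_interval(sample, lambda u: u[0], mode="percentile")
    assert mn[0] <= pc[0] <= pc[1] <= mn[1]
    with pytest.raises(ValueError, match="unknown interval mode"):
        prediction_interval(sample, lambda u: u[0], mode="median")


def test_prediction_interval_no_retained():
    fg, a_hat, *_ = _linear_toy()
    f = lambda u: fg(u)[0]
    sample = mcmc_sample(f, np.array([a_hat]),
                         MCMCConfig(n_samples=500, seed=0), f_star=-1e9)
    with pytest.raises(RuntimeError, match="no retained samples"):
        prediction_interval(sample, lambda u: u[0])


# -- MFA wiring ---------------------------------------------------------------


@pytest.fixture(scope="module")
def fitted_cycle():
    from conftest import small_networks
    from fluxsel.estimation import FitConfig, MeasurementSet, MFAProblem

    model, v_true, tracers = small_networks()[3]
    tracer = tracers[0]
    problem = MFAProblem(model, [tracer], normalized_flux="EFC")
    mids = problem.predict_mids(v_true)
    rng = np.random.default_rng(11)
    recs = [dict(tracer=tracer.name, metabolite=met, mass_isotopomer=k,
                 value=float(val) + rng.normal(0, 0.01), sd=0.01)
            for met in ("B", "C")
            for k, val in enumerate(mids[(tracer.name, met)])]
    data = MeasurementSet.from_records(recs)
    res = problem.fit(data, FitConfig(n_starts=6, seed=2))
    return problem, data, res, v_true, tracer


def test_ppl_interval_mfa(fitted_cycle):
    from fluxsel.uncertainty import ppl_interval

    problem, data, res, v_true, tracer = fitted_cycle
    prof = ppl_interval(problem, data, res.u_star, (tracer.name, "C", 2),
                        PPLConfig(step=0.005))
    assert 0.0 <= prof.lo <= prof.p_best <= prof.hi <= 1.0
    assert prof.width < 0.5


def test_flux_ci_covers_truth(fitted_cycle):
    from fluxsel.uncertainty import flux_ci

    problem, data, res, v_true, tracer = fitted_cycle
    idx = problem.model.reaction_index("UPT")
    prof = flux_ci(problem, data, res.u_star, idx)
    assert prof.lo <= v_true[idx] <= prof.hi


def test_assess_novelty_verdicts():
    from fluxsel.estimation import MeasurementSet

    est = MeasurementSet.from_records([
        dict(tracer="t", metabolite="B", mass_isotopomer=0,
             value=0.5, sd=0.01),
    ])

    def entry(lo, hi, predicted):
        return {"metabolite": "B", "mass_isotopomer": 0,
                "lo": lo, "hi": hi, "predicted": predicted}

    wide = assess_novelty([entry(0.0, 0.99, 0.5)], est, 0.01)
    assert wide.verdict == "too_novel"
    close = assess_novelty([entry(0.49, 0.51, 0.5)], est, 0.01)
    assert close.verdict == "too_similar"
    informative = assess_novelty([entry(0.3, 0.45, 0.4)], est, 0.01)
    assert informative.verdict == "informative"
    assert informative.entries[0]["verdict"] == "different"


def test_tracer_rank_surrogate(cycle_model):
    from fluxsel.emu_engine import TracerSpec, measured_cascade

    cascade = measured_cascade(cycle_model)
    est = [TracerSpec("e", "A.ext", "10")]
    novel = tracer_rank_surrogate(cascade, est, TracerSpec("v", "A.ext", "11"))
    assert novel["adds_information"]
    same = tracer_rank_surrogate(cascade, est, TracerSpec("v", "A.ext", "10"))
    assert not same["adds_information"]
    assert novel["method"] == "surrogate"


def test_tca_validation_tracer_adds_information(tca):
    from fluxsel.emu_engine import measured_cascade

    cascade = measured_cascade(tca.models[tca.true_model])
    rep = tracer_rank_surrogate(
        cascade,
        tca.tracer_list(tca.estimation_tracers),
        tca.tracers[tca.validation_tracer],
    )
    assert rep["adds_information"]
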