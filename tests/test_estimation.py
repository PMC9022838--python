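"""Measurement tables, aggregation, SSR, and flux fitting."""

import numpy as np
import pytest

from fluxsel.emu_engine import TracerSpec
from fluxsel.estimation import (
    FitConfig,
    MeasurementSet,
    MFAProblem,
    NoiseSpec,
    aggregate_replicates,
    sem,
    ssr,
)


def _records(values, sd=0.1, split="est", tracer="t", met="B"):
    return [dict(tracer=tracer, metabolite=met, mass_isotopomer=k,
                 value=v, sd=sd, split=split) for k, v in enumerate(values)]


def test_from_records_defaults():
    ms = MeasurementSet.from_records(
        [dict(tracer="t", metabolite="B", mass_isotopomer=0,
              value=0.5, sd=0.1)])
    row = ms.data.iloc[0]
    assert row["n_replicates"] == 1
    assert row["replicate"] == 0
    assert row["split"] == "est"


def test_nonpositive_sd_rejected():
    with pytest.raises(ValueError, match="sd must be positive"):
        MeasurementSet.from_records(_records([0.5], sd=0.0))


def test_unknown_split_rejected():
    with pytest.raises(ValueError, match="split"):
        MeasurementSet.from_records(_records([0.5], split="test"))


def test_sem():
    assert sem(0.3, 9) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        sem(0.3, 0)


def test_aggregate_replicates_mean_and_sem():
    recs = []
    for rep, v in enumerate([0.4, 0.5, 0.6]):
        recs.append(dict(tracer="t", metabolite="B", mass_isotopomer=0,
                         value=v, sd=0.09, replicate=rep))
    agg = aggregate_replicates(MeasurementSet.from_records(recs))
    assert len(agg) == 1
    assert agg.data["value"].iloc[0] == pytest.approx(0.5)
    assert agg.data["sd"].iloc[0] == pytest.approx(0.09 / np.sqrt(3))
    assert agg.data["n_replicates"].iloc[0] == 3


def test_aggregate_idempotent():
    recs = _records([0.4, 0.6]) + _records([0.5, 0.7])
    once = aggregate_replicates(MeasurementSet.from_records(recs))
    twice = aggregate_replicates(once)
    assert np.allclose(once.data["value"], twice.data["value"])
    assert np.allclose(once.data["sd"], twice.data["sd"])


def test_ssr_vector_and_dict():
    data = MeasurementSet.from_records(_records([0.5, 0.3], sd=0.1))
    assert ssr(np.array([0.5, 0.3]), data) == pytest.approx(0.0)
    assert ssr(np.array([0.6, 0.3]), data) == pytest.approx(1.0)
    pred = {("t", "B"): np.array([0.6, 0.4])}
    assert ssr(pred, data) == pytest.approx(2.0)


def test_ssr_sigma_scale():
    """Scaling all sigmas by c scales the SSR by exactly 1/c^2."""
    data = MeasurementSet.from_records(_records([0.5, 0.3], sd=0.1))
    base = ssr(np.array([0.65, 0.35]), data)
    scaled = ssr(np.array([0.65, 0.35]), data.with_sigma(
        data.data["sd"].to_numpy() * 10.0))
    assert scaled == pytest.approx(base / 100.0)


def test_noise_spec_validation():
    with pytest.raises(ValueError):
        NoiseSpec(np.array([0.1, -0.1]), np.array([0.1, 0.1]))


def test_csv_roundtrip(tmp_path):
    data = MeasurementSet.from_records(_records([0.5, 0.3]))
    p = tmp_path / "d.csv"
    data.to_csv(p)
    again = MeasurementSet.read_csv(p)
    assert np.allclose(again.data["value"], data.data["value"])
    assert list(again.data.columns) == list(data.data.columns)


# -- fitting on a small identifiable network ---------------------------------


@pytest.fixture(scope="module")
def cycle_problem():
    from conftest import small_networks

    model, v, tracers = small_networks()[3]  # dilution cycle
    problem = MFAProblem(model, [tracers[0]], normalized_flux="EFC")
    return problem, v, tracers[0]


def test_fit_recovers_identifiable_ratio(cycle_problem):
    """Noiseless self-generated data: the dilution fraction is recovered."""
    problem, v_true, tracer = cycle_problem
    mids = problem.predict_mids(v_true)
    recs = []
    for met in ("B", "C"):
        for k, val in enumerate(mids[(tracer.name, met)]):
            recs.append(dict(tracer=tracer.name, metabolite=met,
                             mass_isotopomer=k, value=float(val), sd=0.01))
    data = MeasurementSet.from_records(recs)
    res = problem.fit(data, FitConfig(n_starts=8, seed=1))
    assert res.ssr_star < 1e-10
    # labeled inflow fraction UPT/(UPT+DIL) is identifiable
    v = res.v_star
    got = v[0] / (v[0] + v[1])
    want = v_true[0] / (v_true[0] + v_true[1])
    assert got == pytest.approx(want, abs=1e-4)


def test_fit_result_fields(cycle_problem):
    problem, v_true, tracer = cycle_problem
    mids = problem.predict_mids(v_true)
    recs = [dict(tracer=tracer.name, metabolite="C", mass_isotopomer=k,
                 value=float(val), sd=0.05)
            for k, val in enumerate(mids[(tracer.name, "C")])]
    res = problem.fit(MeasurementSet.from_records(recs),
                      FitConfig(n_starts=4, seed=0))
    assert res.n_starts == 4
    assert res.n_converged >= 1
    assert len(res.residuals) == 3
    assert np.isfinite(res.ssr_star)
    # normalization honored
    assert res.v_star[problem.param.fixed_index] == pytest.approx(1.0, abs=1e-8)


def test_fit_deterministic(cycle_problem):
    problem, v_true, tracer = cycle_problem
    mids = problem.predict_mids(v_true)
    rng = np.random.default_rng(5)
    recs = [dict(tracer=tracer.name, metabolite=met, mass_isotopomer=k,
                 value=float(val) + rng.normal(0, 0.02), sd=0.02)
            for met in ("B", "C")
            for k, val in enumerate(mids[(tracer.name, met)])]
    data = MeasurementSet.from_records(recs)
    r1 = problem.fit(data, FitConfig(n_starts=5, seed=7))
    r2 = problem.fit(data, FitConfig(n_starts=5, seed=7))
    assert r1.ssr_star == r2.ssr_star
    assert np.array_equal(r1.u_star, r2.u_star)


def test_sample_starts_feasible(cycle_problem):
    problem, _, _ = cycle_problem
    starts = problem.sample_starts(20, np.random.default_rng(0))
    for u in starts:
        assert problem.param.is_feasible(u)
        assert (problem.param.K @ u >= -1e-9).all()


def test_bound_gradient_matches_fd(cycle_problem):
    problem, v_true, tracer = cycle_problem
    mids = problem.predict_mids(v_true)
    recs = [dict(tracer=tracer.name, metabolite="C", mass_isotopomer=k,
                 value=float(val) + 0.01, sd=0.05)
            for k, val in enumerate(mids[(tracer.name, "C")])]
    bound = problem.bind(MeasurementSet.from_records(recs))
    u0 = problem.sample_starts(1, np.random.default_rng(3))[0]
    f0, g = bound.ssr_and_grad(u0)
    h = 1e-6
    for i in range(len(u0)):
        up, dn = u0.copy(), u0.copy()
        up[i] += h
        dn[i] -= h
        fd = (bound.ssr_value(up) - bound.ssr_value(dn)) / (2 * h)
        assert g[i] == pytest.approx(fd, abs=1e-5)
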