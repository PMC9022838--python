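"""Chi-square testing and the six selection methods.

Oracle notes: chi-square thresholds are checked against independently
computed quantile values (scipy inverse CDF at textbook arguments);
AIC/BIC cases are hand-computed arithmetic.
"""

import numpy as np
import pytest

from fluxsel.estimation import MeasurementSet
from fluxsel.example_models import get_linear_family, get_polynomial_family
from fluxsel.model_selection import (
    METHODS,
    ModelScore,
    apply_selection,
    chi2_test,
    rescale_scores,
    run_selection,
    score_models,
    select_aic,
    select_best_chi2,
    select_bic,
    select_first_chi2,
    select_ssr,
    select_validation,
)
from fluxsel.synthetic_data import gen_linear, gen_polynomial


def test_chi2_threshold_values():
    # independently known quantiles of the chi-square distribution
    ok, thr = chi2_test(10.0, 15, 3, alpha=0.95)
    assert thr == pytest.approx(21.0261, abs=1e-3)  # dof 12
    assert ok
    ok, thr = chi2_test(30.0, 18, 3, alpha=0.95)
    assert thr == pytest.approx(24.9958, abs=1e-3)  # dof 15
    assert not ok


def test_chi2_dof_and_alpha_validation():
    with pytest.raises(ValueError, match="degrees of freedom"):
        chi2_test(1.0, 3, 3)
    with pytest.raises(ValueError, match="alpha"):
        chi2_test(1.0, 10, 3, alpha=1.0)


def _score(mid, p, ssr_est, N=20, ssr_val=None):
    ok, thr = chi2_test(ssr_est, N, p) if N > p else (False, np.nan)
    return ModelScore(
        model_id=mid, p=p, N=N, ssr_est=ssr_est, chi2_threshold=thr,
        passes_chi2=ok, margin=thr - ssr_est, aic=ssr_est + 2 * p,
        bic=ssr_est + p * np.log(N), ssr_val=ssr_val,
    )


def test_select_ssr_smallest():
    scores = [_score("a", 2, 5.0), _score("b", 3, 3.0), _score("c", 4, 4.0)]
    assert select_ssr(scores).chosen == "b"


def test_select_ssr_tie_prefers_fewest_params():
    scores = [_score("complex", 5, 3.0), _score("simple", 2, 3.0 + 1e-9)]
    res = select_ssr(scores)
    assert res.chosen == "simple"
    assert res.tie_break_applied


def test_select_first_chi2_simplest_passing():
    # dof 18, threshold ~28.87; dof 17 ~27.59
    scores = [_score("a", 2, 50.0), _score("b", 3, 20.0), _score("c", 4, 1.0)]
    assert select_first_chi2(scores).chosen == "b"


def test_select_first_chi2_none():
    scores = [_score("a", 2, 500.0), _score("b", 3, 400.0)]
    res = select_first_chi2(scores)
    assert res.chosen is None
    assert "no model passed" in res.note


def test_select_best_chi2_margin():
    scores = [_score("a", 2, 20.0), _score("b", 3, 5.0), _score("c", 4, 6.0)]
    # margins: a: 28.87-20=8.87, b: 27.59-5=22.59, c: 26.30-6=20.30
    assert select_best_chi2(scores).chosen == "b"


def test_select_aic_bic_arithmetic():
    # aic: a 5+4=9, b 4+6=10 -> a; bic (N=20, ln 20=2.9957):
    # a 5+2*2.9957=10.99, b 4+3*2.9957=12.99 -> a
    scores = [_score("a", 2, 5.0), _score("b", 3, 4.0)]
    assert select_aic(scores).chosen == "a"
    assert select_bic(scores).chosen == "a"
    # larger SSR gap flips both
    scores = [_score("a", 2, 12.0), _score("b", 3, 4.0)]
    assert select_aic(scores).chosen == "b"
    assert select_bic(scores).chosen == "b"


def test_select_validation_smallest_val_ssr():
    scores = [_score("a", 2, 9.0, ssr_val=4.0), _score("b", 3, 1.0, ssr_val=6.0)]
    res = select_validation(scores)
    assert res.chosen == "a"
    assert "final model testing" in res.note


def test_select_validation_requires_val_scores():
    with pytest.raises(ValueError, match="validation"):
        select_validation([_score("a", 2, 9.0)])


def test_rescale_scores_exact():
    scores = [_score("a", 2, 8.0, ssr_val=4.0)]
    out = rescale_scores(scores, 2.0)[0]
    assert out.ssr_est == pytest.approx(2.0)
    assert out.ssr_val == pytest.approx(1.0)
    assert out.aic == pytest.approx(2.0 + 4)
    assert out.chi2_threshold == scores[0].chi2_threshold
    with pytest.raises(ValueError):
        rescale_scores(scores, 0.0)


def test_rescale_matches_direct_scoring():
    """Benchmark shortcut check: scoring with c*sigma equals rescaling."""
    data = gen_polynomial(seed=3)
    cands = get_polynomial_family()
    d_est, d_val = data.subset("est"), data.subset("val")
    base = score_models(cands, d_est, d_val)
    c = 10.0
    scaled_direct = score_models(
        cands,
        d_est.with_sigma(d_est.data["sd"].to_numpy() * c),
        d_val.with_sigma(d_val.data["sd"].to_numpy() * c),
    )
    derived = rescale_scores(base, c)
    for sd, dv in zip(scaled_direct, derived):
        assert sd.ssr_est == pytest.approx(dv.ssr_est, rel=1e-9)
        assert sd.ssr_val == pytest.approx(dv.ssr_val, rel=1e-9)
        assert sd.passes_chi2 == dv.passes_chi2


def test_apply_selection_unknown_method():
    with pytest.raises(ValueError, match="unknown selection methods"):
        apply_selection([_score("a", 2, 1.0)], ["bogus"])


def test_run_selection_polynomial_noiseless_sanity():
    """On exact degree-7 data every order >= 7 fits to numerical zero;
    those ties resolve to the simplest, so SSR and validation choose h07."""
    from fluxsel.example_models import (
        PolynomialModel,
        polynomial_design,
        polynomial_validation_mask,
        true_polynomial_coefficients,
    )

    x = polynomial_design()
    truth = PolynomialModel(7).evaluate(x, true_polynomial_coefficients())
    val = polynomial_validation_mask()
    data = MeasurementSet.from_records([
        dict(tracer="design", metabolite="y", mass_isotopomer=i,
             value=float(truth[i]), sd=0.2,
             split="val" if val[i] else "est")
        for i in range(len(x))
    ])
    res = run_selection(get_polynomial_family(), data,
                        ["ssr", "validation"])
    assert res["ssr"].chosen == "h07"
    assert res["validation"].chosen == "h07"


def test_run_selection_linear_family_exact():
    """On exact data from the diagonal truth, A3..A6 all fit to numerical
    zero; ties resolve to the simplest, and A1/A2 cannot fit, so every
    method that sees the fit quality picks A3."""
    from fluxsel.example_models import (
        LinearModel,
        linear_inputs,
        linear_validation_mask,
        true_linear_parameters,
    )

    X = linear_inputs()
    truth = LinearModel(3)
    a = true_linear_parameters()
    val = linear_validation_mask()
    recs = []
    for j in range(len(X)):
        y = truth.evaluate(X[j], a)
        for k in range(3):
            recs.append(dict(tracer=f"x{j}", metabolite="y",
                             mass_isotopomer=k, value=float(y[k]), sd=5.0,
                             split="val" if val[j] else "est"))
    res = run_selection(get_linear_family(),
                        MeasurementSet.from_records(recs), METHODS)
    for method in ("validation", "best_chi2", "ssr"):
        assert res[method].chosen == "A3", method


def test_run_selection_linear_noisy_ssr_prefers_complex():
    data = gen_linear(seed=0)
    res = run_selection(get_linear_family(), data, ["ssr"])
    assert res["ssr"].chosen == "A6"  # most parameters wins on SSR


def test_run_selection_requires_val_split():
    data = gen_linear(seed=0)
    est_only = MeasurementSet(
        data.data[data.data["split"] == "est"].reset_index(drop=True))
    with pytest.raises(ValueError, match="requires a 'val' split"):
        run_selection(get_linear_family(), est_only, ["validation"])


def test_selection_result_serializable():
    data = gen_linear(seed=1)
    res = run_selection(get_linear_family(), data, ["aic"])["aic"]
    import json

    payload = json.loads(res.to_json())
    assert payload["method"] == "aic"
    assert len(payload["scores"]) == 6
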