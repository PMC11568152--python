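"""Posterior-summary machinery and the three model families."""

import numpy as np
import pytest
from scipy import stats

from stagespec import (Draws, PlotSpecialization, PredictionDraws,
                       RichnessRecord, ZONES, averaged_elevation_draws,
                       averaged_elevation_effect, contrast,
                       difference_of_differences, fit_beta_model,
                       fit_richness_model, fit_ses_model, generate_communities,
                       generate_design, get_scenario, hdi, linear_combination,
                       minmax_normalize, percent_change_per_sd, predict_richness,
                       species_richness, summarize, summarize_vector, zscore)
from stagespec.diversity import PairwiseDissimilarity
from stagespec.inference import FittingError

from conftest import one_zone_design


# ---------------------------------------------------------------------------
# z-transform
# ---------------------------------------------------------------------------

def test_zscore_hand_example():
    z, mean, sd = zscore([1.0, 2.0, 3.0])
    assert z.tolist() == [-1.0, 0.0, 1.0]
    assert (mean, sd) == (2.0, 1.0)


def test_zscore_idempotent_and_invertible():
    rng = np.random.default_rng(0)
    x = rng.normal(5, 3, size=200)
    z, mean, sd = zscore(x)
    z2, m2, s2 = zscore(z)
    np.testing.assert_allclose(z, z2, atol=1e-12)
    np.testing.assert_allclose(z * sd + mean, x, atol=1e-10)


def test_zscore_constant_vector_rejected():
    with pytest.raises(ValueError):
        zscore([3.0, 3.0, 3.0])


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def _draws(x, response_sd=1.0, name="b"):
    x = np.asarray(x, dtype=float)
    return Draws((name,), x[:, None], response_sd)


def test_standard_normal_summary():
    x = np.random.default_rng(1).normal(size=100_000)
    s = summarize(_draws(x), "b")
    assert s.hdi_low == pytest.approx(-1.96, abs=0.05)
    assert s.hdi_high == pytest.approx(1.96, abs=0.05)
    assert s.pd == pytest.approx(0.5, abs=0.01)
    mass = np.mean((x >= s.hdi_low) & (x <= s.hdi_high))
    assert 0.945 <= mass <= 0.955


def test_hdi_matches_independent_implementation():
    import arviz
    x = np.random.default_rng(2).gamma(2.0, 1.5, size=20_000)
    lo, hi = hdi(x, 0.95)
    ref = arviz.hdi(x, hdi_prob=0.95)
    assert lo == pytest.approx(float(ref[0]), abs=0.02)
    assert hi == pytest.approx(float(ref[1]), abs=0.02)


def test_degenerate_draws_inside_rope():
    s = summarize(_draws(np.full(2000, 0.001)), "b")
    assert s.rope_pct == 100.0
    assert s.pd == 1.0
    assert s.map == pytest.approx(0.001)


def test_separated_draws_outside_rope():
    x = np.random.default_rng(3).normal(5.0, 1.0, size=5000)
    s = summarize(_draws(x), "b")
    assert s.rope_pct == 0.0
    assert s.pd == 1.0
    assert s.hdi_low <= s.map <= s.hdi_high


def test_pd_tracks_frequentist_p_value():
    """For Gaussian draws, pd ~ 1 - p/2 of the corresponding z-test."""
    rng = np.random.default_rng(4)
    for shift in (0.0, 0.5, 1.0, 2.0):
        x = rng.normal(shift, 1.0, size=200_000)
        pd = summarize(_draws(x), "b").pd
        p = 2 * stats.norm.sf(abs(shift))
        assert pd == pytest.approx(1 - p / 2, abs=0.01)


def test_summary_requires_enough_draws():
    with pytest.raises(ValueError):
        summarize(_draws(np.zeros(999)), "b")


def test_contrast_linearity_and_self_difference():
    rng = np.random.default_rng(5)
    samples = rng.normal(size=(3000, 3))
    d = Draws(("a", "b", "c"), samples, 1.0)
    ab = linear_combination(d, {"a": 1, "b": -1})
    bc = linear_combination(d, {"b": 1, "c": -1})
    ac = linear_combination(d, {"a": 1, "c": -1})
    np.testing.assert_allclose(ab + bc, ac, atol=1e-12)
    # a coefficient contrasted with itself: all-zero draws, fully in ROPE
    self_diff = contrast(d, {"a": 1.0, "b": 0.0, "c": 0.0}, name="a-a")
    assert self_diff.hdi_low < self_diff.hdi_high
    zero = summarize(Draws(("a",), samples[:, :1] - samples[:, :1], 1.0), "a")
    assert zero.rope_pct == 100.0
    assert zero.pd == 1.0


# ---------------------------------------------------------------------------
# Gaussian location-scale SES model
# ---------------------------------------------------------------------------

def _plot_ses_fixture(rng, zone_means, zone_sds, n=50):
    design = generate_design()
    out = []
    for zi, z in enumerate(ZONES):
        plots = design.zone_plots(z)[:n]
        vals = rng.normal(zone_means[zi], zone_sds[zi], size=len(plots))
        out.extend(PlotSpecialization(p.plot_id, z, float(v), 5)
                   for p, v in zip(plots, vals))
    return out, design


def test_ses_model_recovers_zone_means():
    rng = np.random.default_rng(6)
    plot_ses, design = _plot_ses_fixture(rng, (1.0, 0.0, -1.0), (0.3,) * 3)
    d = fit_ses_model(plot_ses, design, backend="bootstrap", n_draws=2000,
                      rng=rng)
    for z, truth in zip(ZONES, (1.0, 0.0, -1.0)):
        assert summarize(d, f"mu_{z}").map == pytest.approx(truth, abs=0.15)
    c = contrast(d, {"mu_submontane": 1.0, "mu_montane": -1.0})
    assert c.map == pytest.approx(1.0, abs=0.2)


def test_ses_model_null_contrasts_modest():
    """Equal-mean simulation: no directional support, and the ROPE share
    matches the Gaussian closed form for the fitted contrast."""
    rng = np.random.default_rng(7)
    plot_ses, design = _plot_ses_fixture(rng, (0.0, 0.0, 0.0), (0.5,) * 3)
    d = fit_ses_model(plot_ses, design, backend="bootstrap", n_draws=2000,
                      rng=rng)
    c = contrast(d, {"mu_submontane": 1.0, "mu_subalpine": -1.0})
    assert c.pd < 0.9
    vec = d["mu_submontane"] - d["mu_subalpine"]
    m, s = vec.mean(), vec.std(ddof=1)
    expected = 100 * (stats.norm.cdf((c.rope_high - m) / s)
                      - stats.norm.cdf((c.rope_low - m) / s)) / 0.95
    assert c.rope_pct == pytest.approx(expected, abs=10.0)
    assert c.rope_pct > 10.0  # far from the zero share of a separated effect


def test_ses_model_detects_heteroscedasticity():
    rng = np.random.default_rng(8)
    plot_ses, design = _plot_ses_fixture(rng, (0.0, 0.0, 0.0), (0.2, 0.5, 0.8))
    d = fit_ses_model(plot_ses, design, backend="bootstrap", n_draws=2000,
                      rng=rng)
    c = contrast(d, {"log_sigma_subalpine": 1.0, "log_sigma_submontane": -1.0})
    assert c.pd > 0.99
    assert c.map > 0


def test_ses_model_backend_agreement():
    rng = np.random.default_rng(9)
    plot_ses, design = _plot_ses_fixture(rng, (1.0, 0.0, -1.0), (0.4,) * 3)
    boot = fit_ses_model(plot_ses, design, backend="bootstrap", n_draws=4000,
                         rng=np.random.default_rng(10))
    lap = fit_ses_model(plot_ses, design, backend="laplace", n_draws=4000,
                        rng=np.random.default_rng(11))
    for z in ZONES:
        b = summarize(boot, f"mu_{z}")
        l = summarize(lap, f"mu_{z}")
        sd = boot[f"mu_{z}"].std()
        assert abs(b.map - l.map) < 0.5 * sd


def test_ses_model_needs_two_zones():
    design = generate_design()
    one = [PlotSpecialization(p.plot_id, "montane", 0.5, 3)
           for p in design.zone_plots("montane")]
    with pytest.raises(FittingError):
        fit_ses_model(one, design)


# ---------------------------------------------------------------------------
# Negative-binomial richness model
# ---------------------------------------------------------------------------

def _poisson_richness(design, slope=0.2, seed=0):
    elev = np.array([p.elevation_m for p in design.plots])
    ez = (elev - elev.mean()) / elev.std(ddof=1)
    rng = np.random.default_rng(seed)
    y = rng.poisson(np.exp(3.0 + slope * ez))
    return [RichnessRecord(p.plot_id, "t", int(v))
            for p, v in zip(design.plots, y)]


def test_richness_model_recovers_elevation_slope():
    design = generate_design()
    maps = []
    for seed in range(20):
        rich = _poisson_richness(design, slope=0.2, seed=seed)
        d = fit_richness_model(rich, design, backend="laplace", n_draws=1000,
                               rng=np.random.default_rng(seed),
                               group_intercepts=False)
        maps.append(summarize(d, "elev").map)
    assert np.mean(maps) == pytest.approx(0.2, abs=0.05)


def test_richness_interactions_negligible_when_absent():
    design = generate_design()
    rich = _poisson_richness(design, slope=0.0, seed=3)
    d = fit_richness_model(rich, design, backend="laplace", n_draws=2000,
                           rng=np.random.default_rng(3), group_intercepts=False)
    from stagespec import STAGES
    for s in STAGES[1:]:
        assert summarize(d, f"elev:stage[{s}]").rope_pct > 50.0


def test_u_shape_scenario_gap_exceeds_optimum():
    cfg, scenarios = get_scenario("U_shape")
    design = generate_design(cfg)
    inc = generate_communities(design, scenarios[0])
    rich = species_richness(inc)
    d = fit_richness_model(rich, design, backend="laplace", n_draws=2000,
                           rng=np.random.default_rng(0))
    c = contrast(d, {"stage[optimum]": -1.0})  # gap - optimum offset
    assert c.map > 0
    assert c.pd > 0.95


def test_richness_model_rejects_empty_response():
    design = generate_design()
    rich = [RichnessRecord(p.plot_id, "t", 0) for p in design.plots]
    with pytest.raises(FittingError):
        fit_richness_model(rich, design)


def test_richness_backend_agreement():
    design = generate_design()
    rich = _poisson_richness(design, slope=0.2, seed=1)
    boot = fit_richness_model(rich, design, backend="bootstrap", n_draws=1000,
                              rng=np.random.default_rng(1),
                              group_intercepts=False)
    lap = fit_richness_model(rich, design, backend="laplace", n_draws=1000,
                             rng=np.random.default_rng(2),
                             group_intercepts=False)
    for name in ("intercept", "elev"):
        sd = boot[name].std()
        assert abs(summarize(boot, name).map
                   - summarize(lap, name).map) < 0.5 * sd


# ---------------------------------------------------------------------------
# Beta dissimilarity model
# ---------------------------------------------------------------------------

def _beta_pairs(zone_probs, n=300, phi=20.0, seed=0, with_boundary=False):
    rng = np.random.default_rng(seed)
    pairs = []
    for z, mu in zip(ZONES, zone_probs):
        y = rng.beta(mu * phi, (1 - mu) * phi, size=n)
        if with_boundary:
            y[:3] = 1.0
        for i, v in enumerate(y):
            pairs.append(PairwiseDissimilarity(
                f"{z}_a{i}", f"{z}_b{i}", z, "gap", "optimum", float(v),
                float(rng.uniform(100, 3000)), float(rng.uniform(0, 300)),
                None))
    return pairs


def test_beta_model_zone_contrast_recovery():
    d = fit_beta_model(_beta_pairs((0.8, 0.4, 0.4), seed=12),
                       backend="laplace", n_draws=2000,
                       rng=np.random.default_rng(12))
    c = contrast(d, {"mu_submontane": 1.0, "mu_montane": -1.0})
    assert c.pd > 0.99
    from scipy.special import logit
    assert c.map == pytest.approx(logit(0.8) - logit(0.4), abs=0.3)


def test_beta_model_null_contrasts_centred():
    d = fit_beta_model(_beta_pairs((0.6, 0.6, 0.6), seed=13),
                       backend="laplace", n_draws=2000,
                       rng=np.random.default_rng(13))
    for a, b in (("submontane", "montane"), ("montane", "subalpine")):
        c = contrast(d, {f"mu_{a}": 1.0, f"mu_{b}": -1.0})
        assert abs(c.map) < 0.2
        assert c.pd < 0.99


def test_beta_model_boundary_values_shrunk():
    d = fit_beta_model(_beta_pairs((0.7, 0.5, 0.5), seed=14,
                                   with_boundary=True),
                       backend="laplace", n_draws=1000,
                       rng=np.random.default_rng(14))
    assert np.isfinite(d.samples).all()


def test_beta_model_requires_pairs():
    with pytest.raises(FittingError):
        fit_beta_model(_beta_pairs((0.5, 0.5, 0.5), n=2)[:6])


# ---------------------------------------------------------------------------
# Derived effects
# ---------------------------------------------------------------------------

def _injected_richness_draws(baseline=0.3,
                             interactions=(0.1, 0.2, -0.1, -0.2), n=2000):
    from stagespec import STAGES
    names = (["intercept"] + [f"stage[{s}]" for s in STAGES[1:]] + ["elev"]
             + [f"elev:stage[{s}]" for s in STAGES[1:]])
    cols = [np.full(n, 2.0)] + [np.zeros(n)] * 4 + [np.full(n, baseline)] + \
           [np.full(n, v) for v in interactions]
    return Draws(tuple(names), np.column_stack(cols), 1.0,
                 meta={"std": {"elev_mean": 1000.0, "elev_sd": 300.0}})


def test_averaged_elevation_effect_arithmetic():
    d = _injected_richness_draws(baseline=0.3,
                                 interactions=(0.1, 0.2, -0.1, -0.2))
    vec = averaged_elevation_draws(d)
    assert vec == pytest.approx(np.full(2000, 0.3))
    s = averaged_elevation_effect(d)
    assert s.map == pytest.approx(0.3, abs=1e-6)


def test_averaged_effect_equals_baseline_without_interactions():
    d = _injected_richness_draws(baseline=0.25, interactions=(0, 0, 0, 0))
    assert averaged_elevation_effect(d).map == pytest.approx(0.25, abs=1e-6)


def test_percent_change_inversion():
    d = _injected_richness_draws(baseline=float(np.log(0.839)),
                                 interactions=(0, 0, 0, 0))
    s = percent_change_per_sd(d, averaged_elevation_draws(d))
    assert s.map == pytest.approx(-16.1, abs=0.05)
    zero = percent_change_per_sd(_injected_richness_draws(baseline=0.0,
                                                          interactions=(0,) * 4),
                                 "elev")
    assert zero.map == pytest.approx(0.0, abs=1e-9)


def test_percent_change_monotone():
    betas = (-0.3, -0.1, 0.0, 0.2)
    maps = [percent_change_per_sd(
        _injected_richness_draws(baseline=b, interactions=(0,) * 4),
        "elev").map for b in betas]
    assert maps == sorted(maps)


def test_predict_richness_closed_form():
    d = _injected_richness_draws(baseline=0.0, interactions=(0, 0, 0, 0))
    design = generate_design()
    pred = predict_richness(d, design, [1000.0])  # the stored mean elevation
    # at mean elevation with zero stage offsets: exp(intercept) = exp(2)
    np.testing.assert_allclose(pred.values, np.exp(2.0), rtol=1e-12)


def test_prediction_minmax_normalization():
    x = np.array([3.0, 7.0, 11.0])
    n = minmax_normalize(x)
    assert n.tolist() == [0.0, 0.5, 1.0]


def test_difference_of_differences_zero_when_homogeneous():
    vals = np.full((1500, 5, 3), 6.0)
    vals[:, 2, :] = 4.0  # optimum lower, same in every zone
    pred = PredictionDraws(vals, ("gap", "establishment", "optimum", "plenter",
                                  "terminal"), (700.0, 1100.0, 1500.0), 1.0)
    for s in difference_of_differences(pred):
        assert s.map == pytest.approx(0.0, abs=1e-9)
        assert s.rope_pct == 100.0


def test_difference_of_differences_hand_value():
    vals = np.full((1500, 5, 3), 4.0)  # every stage at optimum level...
    vals[:, 0, 0] = 10.0  # ...except gap: 10 submontane,
    vals[:, 0, 1] = 6.0   # 6 montane,
    vals[:, 0, 2] = 6.0   # 6 subalpine
    pred = PredictionDraws(vals, ("gap", "establishment", "optimum", "plenter",
                                  "terminal"), (700.0, 1100.0, 1500.0), 1.0)
    out = {s.name: s for s in difference_of_differences(pred)}
    gap_mon = out["dod[gap vs optimum]: submontane - montane"]
    gap_sal = out["dod[gap vs optimum]: submontane - subalpine"]
    assert gap_mon.map == pytest.approx(4.0)  # |10-4| - |6-4|
    assert gap_sal.map == pytest.approx(4.0)


def test_zone_shift_leaves_within_zone_gaps_unchanged():
    rng = np.random.default_rng(15)
    vals = rng.uniform(2, 10, size=(1500, 5, 3))
    shifted = vals.copy()
    shifted[:, :, 1] += 3.0  # constant added to every stage of one zone
    a = difference_of_differences(
        PredictionDraws(vals, ("gap", "establishment", "optimum", "plenter",
                               "terminal"), (1.0, 2.0, 3.0), 1.0))
    b = difference_of_differences(
        PredictionDraws(shifted, ("gap", "establishment", "optimum", "plenter",
                                  "terminal"), (1.0, 2.0, 3.0), 1.0))
    for x, y in zip(a, b):
        assert x.map == pytest.approx(y.map, abs=1e-9)


def test_arthropod_decline_recovers_negative_effect():
    cfg, scenarios = get_scenario("arthropod_decline")
    design = generate_design(cfg)
    inc = generate_communities(design, scenarios[0])
    d = fit_richness_model(species_richness(inc), design, backend="laplace",
                           n_draws=2000, rng=np.random.default_rng(0))
    s = averaged_elevation_effect(d)
    assert s.map < 0
    pct = percent_change_per_sd(d, averaged_elevation_draws(d))
    assert pct.map < -5.0  # clearly negative decline per SD of elevation
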