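"""Model fitting and posterior-summary machinery for the hypothesis tests.

Three model families are fitted on pipeline outputs:

* a Gaussian *location-scale* model for plot-level specialization SES, with
  zone-specific means and zone-specific dispersions (the SES spread differs
  between zones);
* a *negative-binomial* model for plot species richness with a stage x
  elevation interaction, optional day-of-year covariate and grouped
  (neighbourhood) intercepts;
* a *beta* model for pairwise cross-stage Jaccard dissimilarity with
  zone-specific means and spatial/elevational (optionally quadratic) distance
  covariates.

Draw backends are pluggable behind the :class:`Draws` contract.  The
reference backend is a parametric bootstrap — maximum-likelihood fit, then
simulate-and-refit — because it is dependency-light and deterministic under
a seed; ``"laplace"`` draws from the asymptotic normal approximation at the
MLE and is much faster.

Every posterior (or bootstrap) sample is summarized the same way: MAP (mode
of a Gaussian-kernel density estimate, Silverman bandwidth), 95% highest
density interval, probability of direction (pd), and the ROPE percentage —
the share of the draws inside the 95% HDI that fall within a region of
practical equivalence of +/- 0.1 standard deviations of the response.

All continuous predictors are z-transformed (mean 0, SD 1) before fitting;
the standardization record travels with the draws so predictions can be made
on the metre scale.
"""

from __future__ import annotations

import logging
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.discrete.discrete_model import NegativeBinomial
from statsmodels.tools.numdiff import approx_hess1
from statsmodels.tools.sm_exceptions import (ConvergenceWarning,
                                             HessianInversionWarning)


@contextmanager
def _quiet_fit():
    # Poisson-like data put the NB dispersion on its boundary; the resulting
    # convergence/Hessian warnings are expected and handled by fallbacks
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", HessianInversionWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        yield

from .data_model import Design, STAGES, ZONES
from .diversity import PairwiseDissimilarity, RichnessRecord
from .specialization import PlotSpecialization

logger = logging.getLogger(__name__)

MIN_DRAWS_FOR_SUMMARY = 1000

__all__ = [
    "Draws", "PosteriorSummary", "ModelSpec", "FittingError",
    "zscore", "summarize", "summarize_vector", "hdi", "probability_of_direction",
    "contrast", "linear_combination",
    "fit_ses_model", "fit_richness_model", "fit_beta_model",
    "averaged_elevation_effect", "averaged_elevation_draws",
    "percent_change_per_sd", "predict_richness", "PredictionDraws",
    "minmax_normalize", "difference_of_differences",
]


class FittingError(RuntimeError):
    """A model could not be fitted on the supplied data."""


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelSpec:
    """Record of a fitted model's family, terms and standardization."""

    family: str
    response: str
    terms: tuple[str, ...]
    standardization: Mapping[str, tuple[float, float]]  # name -> (mean, sd)
    dispersion_terms: tuple[str, ...] = ()
    group_variable: str | None = None
    quadratic_terms: tuple[str, ...] = ()


@dataclass(frozen=True)
class Draws:
    """Named coefficient draws (posterior or bootstrap).

    ``samples`` has one row per draw and one column per coefficient.
    ``response_sd`` is the SD of the modelled response, kept for ROPE bounds.
    """

    names: tuple[str, ...]
    samples: np.ndarray
    response_sd: float
    meta: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        if s.ndim != 2 or s.shape[1] != len(self.names):
            raise ValueError(f"samples shape {s.shape} does not match "
                             f"{len(self.names)} coefficient names")
        if len(set(self.names)) != len(self.names):
            raise ValueError("coefficient names must be unique")
        object.__setattr__(self, "samples", s)

    @property
    def n_draws(self) -> int:
        return self.samples.shape[0]

    def __getitem__(self, name: str) -> np.ndarray:
        try:
            j = self.names.index(name)
        except ValueError:
            raise KeyError(f"no coefficient {name!r}; have {self.names}") from None
        return self.samples[:, j]


@dataclass(frozen=True)
class PosteriorSummary:
    """MAP, HDI, pd and ROPE percentage for one coefficient or contrast."""

    name: str
    map: float
    hdi_low: float
    hdi_high: float
    pd: float
    rope_pct: float
    rope_low: float
    rope_high: float


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------

def zscore(x) -> tuple[np.ndarray, float, float]:
    """Standardize to mean 0, SD 1 (sample SD); returns (z, mean, sd)."""
    x = np.asarray(x, dtype=float)
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    if sd == 0.0:
        raise ValueError("cannot z-transform a constant vector")
    return (x - mean) / sd, mean, sd


# ---------------------------------------------------------------------------
# Posterior summaries
# ---------------------------------------------------------------------------

def hdi(x: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Shortest interval containing ``level`` of the draws."""
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    k = int(np.ceil(level * n))
    if k >= n:
        return float(x[0]), float(x[-1])
    widths = x[k:] - x[: n - k]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + k])


def probability_of_direction(x: np.ndarray) -> float:
    """pd = max(P(draw >= 0), P(draw <= 0)); in [0.5, 1]."""
    x = np.asarray(x, dtype=float)
    return float(max(np.mean(x >= 0), np.mean(x <= 0)))


def _kde_mode(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo < 1e-12:
        return float(x[0])
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def summarize_vector(x: np.ndarray, response_sd: float, name: str,
                     hdi_level: float = 0.95, rope_multiplier: float = 0.1,
                     rope_within_hdi: bool = True) -> PosteriorSummary:
    """Summarize an arbitrary vector of draws (no minimum-size check)."""
    x = np.asarray(x, dtype=float)
    lo, hi = hdi(x, hdi_level)
    m = min(max(_kde_mode(x), lo), hi)
    rope_lo = -rope_multiplier * response_sd
    rope_hi = rope_multiplier * response_sd
    base = x[(x >= lo) & (x <= hi)] if rope_within_hdi else x
    if base.size == 0:
        rope_pct = float("nan")
    else:
        rope_pct = 100.0 * float(np.mean((base >= rope_lo) & (base <= rope_hi)))
    return PosteriorSummary(name=name, map=m, hdi_low=lo, hdi_high=hi,
                            pd=probability_of_direction(x), rope_pct=rope_pct,
                            rope_low=rope_lo, rope_high=rope_hi)


def summarize(draws: Draws, name: str, hdi_level: float = 0.95,
              rope_multiplier: float = 0.1,
              rope_within_hdi: bool = True) -> PosteriorSummary:
    """MAP / HDI / pd / ROPE summary of one named coefficient."""
    if draws.n_draws < MIN_DRAWS_FOR_SUMMARY:
        raise ValueError(f"need >= {MIN_DRAWS_FOR_SUMMARY} draws for a reported "
                         f"summary, have {draws.n_draws}")
    return summarize_vector(draws[name], draws.response_sd, name,
                            hdi_level=hdi_level, rope_multiplier=rope_multiplier,
                            rope_within_hdi=rope_within_hdi)


def linear_combination(draws: Draws, weights: Mapping[str, float]) -> np.ndarray:
    """Per-draw value of ``sum_k w_k * coefficient_k``."""
    out = np.zeros(draws.n_draws)
    for name, w in weights.items():
        out += w * draws[name]
    return out


def contrast(draws: Draws, weights: Mapping[str, float],
             name: str | None = None, **summary_kwargs) -> PosteriorSummary:
    """Summary of a linear combination of coefficients (e.g. a zone contrast)."""
    if draws.n_draws < MIN_DRAWS_FOR_SUMMARY:
        raise ValueError(f"need >= {MIN_DRAWS_FOR_SUMMARY} draws, have "
                         f"{draws.n_draws}")
    if name is None:
        name = " + ".join(f"{w:+g}*{k}" for k, w in weights.items())
    return summarize_vector(linear_combination(draws, weights),
                            draws.response_sd, name, **summary_kwargs)


# ---------------------------------------------------------------------------
# Gaussian location-scale model for plot-level SES
# ---------------------------------------------------------------------------

def _shrunken_group_effects(y: np.ndarray, groups: np.ndarray
                            ) -> tuple[np.ndarray, float]:
    """Method-of-moments random-intercept estimates (per-observation effects).

    Group means are shrunk toward zero by the usual ratio of between-group to
    total variance; returns the per-observation effect and the between-group
    SD estimate.
    """
    labels, inv = np.unique(groups, return_inverse=True)
    n_k = np.bincount(inv)
    means = np.bincount(inv, weights=y) / n_k
    within = float(np.mean((y - means[inv]) ** 2)) if y.size > len(labels) else 0.0
    var_b = max(0.0, float(np.var(means, ddof=1)) - within * float(np.mean(1.0 / n_k)))
    shrink = var_b / (var_b + within / np.maximum(n_k, 1)) if within > 0 else 1.0
    effects = means * shrink
    return effects[inv], float(np.sqrt(var_b))


def fit_ses_model(plot_ses: Sequence[PlotSpecialization], design: Design,
                  backend: str = "bootstrap", n_draws: int = 2000,
                  rng: np.random.Generator | None = None,
                  group_intercepts: bool = False,
                  species_ses=None, inc=None) -> Draws:
    """Gaussian location-scale fit of plot mean SES on elevational zone.

    Produces draws of the three zone means (``mu_<zone>``) and zone
    log-dispersions (``log_sigma_<zone>``), plus ``group_sd`` when grouped
    intercepts are requested.  Plots flagged missing (no usable species) are
    dropped.

    Backends
    --------
    ``"bootstrap"``
        Parametric bootstrap treating plots as independent observations.
    ``"laplace"``
        Asymptotic-normal draws at the MLE (plots independent).
    ``"species_bootstrap"``
        Resamples *species* with replacement within each zone and recomputes
        every plot mean; requires ``species_ses`` (the per-species SES list)
        and ``inc`` (the incidence table).  Plot means within a zone share
        species, so plot-iid backends understate the uncertainty of a zone
        mean; resampling the species — the exchangeable units behind the
        averages — propagates that shared sampling variation and is the
        backend the pipeline uses.
    """
    if backend == "species_bootstrap":
        return _fit_ses_species_bootstrap(plot_ses, design, species_ses, inc,
                                          n_draws, rng)
    rng = rng if rng is not None else np.random.default_rng()
    rows = [(p.plot_id, p.zone, p.mean_ses) for p in plot_ses
            if np.isfinite(p.mean_ses)]
    if not rows:
        raise FittingError("no plot-level SES values to fit")
    zones_present = [z for z in ZONES if any(r[1] == z for r in rows)]
    if len(zones_present) < 2:
        raise FittingError("need >= 2 zones with data")
    y = np.array([r[2] for r in rows])
    zone = np.array([r[1] for r in rows])
    groups = np.array([design[r[0]].spatial_group for r in rows])

    if group_intercepts:
        eff, group_sd_hat = _shrunken_group_effects(
            y - np.array([y[zone == z].mean() for z in zone]), groups)
        y_adj = y - eff
    else:
        y_adj = y
        group_sd_hat = 0.0

    mu = {z: float(y_adj[zone == z].mean()) for z in zones_present}
    sd = {z: float(y_adj[zone == z].std(ddof=1)) for z in zones_present}
    n_z = {z: int((zone == z).sum()) for z in zones_present}
    if any(sd[z] == 0 for z in zones_present):
        raise FittingError("zero within-zone variance; location-scale model "
                           "is singular")

    names = ([f"mu_{z}" for z in zones_present]
             + [f"log_sigma_{z}" for z in zones_present]
             + (["group_sd"] if group_intercepts else []))

    if backend == "bootstrap":
        cols = []
        for z in zones_present:
            sims = rng.normal(mu[z], sd[z], size=(n_draws, n_z[z]))
            cols.append(sims)
        mu_draws = [c.mean(axis=1) for c in cols]
        sd_draws = [c.std(axis=1, ddof=1) for c in cols]
        sample_cols = mu_draws + [np.log(s) for s in sd_draws]
        if group_intercepts:
            sample_cols.append(np.full(n_draws, group_sd_hat))
        samples = np.column_stack(sample_cols)
    elif backend == "laplace":
        sample_cols = [rng.normal(mu[z], sd[z] / np.sqrt(n_z[z]), size=n_draws)
                       for z in zones_present]
        sample_cols += [rng.normal(np.log(sd[z]),
                                   1.0 / np.sqrt(2.0 * (n_z[z] - 1)),
                                   size=n_draws)
                        for z in zones_present]
        if group_intercepts:
            sample_cols.append(np.full(n_draws, group_sd_hat))
        samples = np.column_stack(sample_cols)
    else:
        raise ValueError(f"unknown backend {backend!r}")

    spec = ModelSpec(family="gaussian_location_scale", response="mean_ses",
                     terms=tuple(f"mu_{z}" for z in zones_present),
                     standardization={},
                     dispersion_terms=tuple(f"log_sigma_{z}" for z in zones_present),
                     group_variable="spatial_group" if group_intercepts else None)
    return Draws(names=tuple(names), samples=samples,
                 response_sd=float(y.std(ddof=1)),
                 meta={"model_spec": spec, "backend": backend,
                       "n_per_zone": n_z, "mle": {"mu": mu, "sigma": sd}})


def _fit_ses_species_bootstrap(plot_ses, design: Design, species_ses, inc,
                               n_draws: int,
                               rng: np.random.Generator | None) -> Draws:
    if species_ses is None or inc is None:
        raise ValueError("species_bootstrap backend needs species_ses and inc")
    rng = rng if rng is not None else np.random.default_rng()
    usable: dict[str, dict[str, float]] = {}
    for s in species_ses:
        if not s.excluded and np.isfinite(s.ses):
            usable.setdefault(s.zone, {})[s.species_id] = s.ses
    zones_present = [z for z in ZONES if usable.get(z)]
    if len(zones_present) < 2:
        raise FittingError("need >= 2 zones with usable species")

    all_plot_means = np.array([p.mean_ses for p in plot_ses
                               if np.isfinite(p.mean_ses)])
    mu_cols, ls_cols = [], []
    for z in zones_present:
        sp = sorted(usable[z])
        v = np.array([usable[z][s] for s in sp])
        col = {s: j for j, s in enumerate(sp)}
        plots = [p for p in design.zone_plots(z) if p.plot_id in inc.plot_ids]
        pres = np.zeros((len(plots), len(sp)))
        for i, p in enumerate(plots):
            for s in inc.species_set(p.plot_id):
                if s in col:
                    pres[i, col[s]] = 1.0
        keep = pres.sum(axis=1) > 0
        pres = pres[keep]
        if pres.shape[0] < 2:
            raise FittingError(f"zone {z}: fewer than 2 plots with usable species")
        # multinomial species resampling; each draw reweights every plot mean
        counts = rng.multinomial(len(sp), np.full(len(sp), 1.0 / len(sp)),
                                 size=n_draws).astype(float)  # draws x species
        num = counts * v[None, :] @ pres.T  # draws x plots
        den = counts @ pres.T
        den[den == 0] = np.nan
        means = num / den
        mu_cols.append(np.nanmean(means, axis=1))
        ls_cols.append(np.log(np.nanstd(means, axis=1, ddof=1)))

    names = [f"mu_{z}" for z in zones_present] + \
            [f"log_sigma_{z}" for z in zones_present]
    samples = np.column_stack(mu_cols + ls_cols)
    spec = ModelSpec(family="gaussian_location_scale", response="mean_ses",
                     terms=tuple(f"mu_{z}" for z in zones_present),
                     standardization={},
                     dispersion_terms=tuple(f"log_sigma_{z}"
                                            for z in zones_present))
    return Draws(names=tuple(names), samples=samples,
                 response_sd=float(all_plot_means.std(ddof=1)),
                 meta={"model_spec": spec, "backend": "species_bootstrap"})


# ---------------------------------------------------------------------------
# Negative-binomial richness model
# ---------------------------------------------------------------------------

def _nb_design_matrix(design: Design, plot_ids: Sequence[str],
                      day_covariate: bool, group_intercepts: bool,
                      std: dict | None = None):
    """Design matrix: intercept, stage offsets (gap baseline), z-elevation,
    stage x elevation interactions, optional z-day, sum-coded group dummies."""
    recs = [design[p] for p in plot_ids]
    elev = np.array([r.elevation_m for r in recs])
    if std is None:
        std = {}
        _, std["elev_mean"], std["elev_sd"] = zscore(elev)
    elev_z = (elev - std["elev_mean"]) / std["elev_sd"]
    stage = np.array([r.stage for r in recs])

    cols = {"intercept": np.ones(len(recs))}
    for s in STAGES[1:]:
        cols[f"stage[{s}]"] = (stage == s).astype(float)
    cols["elev"] = elev_z
    for s in STAGES[1:]:
        cols[f"elev:stage[{s}]"] = elev_z * (stage == s)
    if day_covariate:
        days = [r.day_of_year for r in recs]
        if any(d is None for d in days):
            raise FittingError("day covariate requested but day_of_year missing")
        day = np.array(days, dtype=float)
        if "day_mean" not in std:
            _, std["day_mean"], std["day_sd"] = zscore(day)
        cols["day"] = (day - std["day_mean"]) / std["day_sd"]
    group_labels: tuple[str, ...] = ()
    if group_intercepts:
        g = np.array([r.spatial_group for r in recs])
        group_labels = tuple(sorted(set(g)))
        # sum (deviation) coding: effects sum to zero, predictions at the
        # average group marginalize the intercepts at 0
        for lab in group_labels[:-1]:
            col = (g == lab).astype(float) - (g == group_labels[-1]).astype(float)
            cols[f"group[{lab}]"] = col
    X = np.column_stack(list(cols.values()))
    return X, list(cols.keys()), std, group_labels


def _group_sd_from_draws(samples: np.ndarray, names: list[str]) -> np.ndarray:
    gcols = [i for i, n in enumerate(names) if n.startswith("group[")]
    if not gcols:
        return np.zeros(samples.shape[0])
    g = samples[:, gcols]
    full = np.column_stack([g, -g.sum(axis=1)])  # implied last group effect
    return full.std(axis=1, ddof=1)


def _nb_covariance(model: NegativeBinomial, res) -> np.ndarray:
    # cov_params is unavailable when the dispersion sits on its boundary;
    # fall back to the (pseudo-)inverse observed information with alpha
    # nudged off zero, eigenvalues clipped to keep the matrix PSD
    try:
        cov = np.asarray(res.cov_params())
        if np.all(np.isfinite(cov)):
            return cov
    except (ValueError, np.linalg.LinAlgError):
        pass
    params = np.asarray(res.params).copy()
    params[-1] = max(params[-1], 1e-5)
    cov = np.linalg.pinv(-model.hessian(params))
    cov = (cov + cov.T) / 2.0
    w, v = np.linalg.eigh(cov)
    return (v * np.clip(w, 0.0, None)) @ v.T


def fit_richness_model(richness: Sequence[RichnessRecord], design: Design,
                       day_covariate: bool = False,
                       group_intercepts: bool = True,
                       backend: str = "bootstrap", n_draws: int = 2000,
                       rng: np.random.Generator | None = None) -> Draws:
    """Negative-binomial (NB2) fit of plot richness on stage x elevation.

    Coefficient draws cover the intercept (gap baseline), four stage offsets,
    the elevation slope, four stage x elevation interactions, the optional
    day-of-year term, the NB dispersion ``alpha``, the individual group
    intercepts (sum-coded) and their spread ``group_sd``.
    """
    rng = rng if rng is not None else np.random.default_rng()
    plot_ids = [r.plot_id for r in richness]
    y = np.array([r.richness for r in richness], dtype=float)
    if y.max() == 0:
        raise FittingError("all-zero richness response")
    X, names, std, group_labels = _nb_design_matrix(
        design, plot_ids, day_covariate, group_intercepts)

    model = NegativeBinomial(y, X, loglike_method="nb2")
    try:
        with _quiet_fit():
            res = model.fit(disp=0, maxiter=500, method="bfgs")
    except Exception as exc:  # pragma: no cover - singular designs
        raise FittingError(f"negative-binomial fit failed: {exc}") from exc
    params = np.asarray(res.params)  # betas then alpha
    if not np.all(np.isfinite(params)):
        raise FittingError("negative-binomial fit did not converge")
    alpha = max(float(params[-1]), 1e-8)
    all_names = names + ["alpha"]

    if backend == "bootstrap":
        mu = np.exp(X @ params[:-1])
        draws = np.empty((n_draws, len(params)))
        attempts = 0
        got = 0
        while got < n_draws and attempts < int(1.5 * n_draws) + 20:
            attempts += 1
            if alpha > 1e-6:
                y_star = rng.negative_binomial(1.0 / alpha,
                                               1.0 / (1.0 + alpha * mu))
            else:
                y_star = rng.poisson(mu)
            try:
                with _quiet_fit():
                    r_star = NegativeBinomial(y_star.astype(float), X,
                                              loglike_method="nb2").fit(
                        disp=0, maxiter=200, method="bfgs", start_params=params)
            except Exception:
                continue
            p = np.asarray(r_star.params)
            if not np.all(np.isfinite(p)):
                continue
            draws[got] = p
            got += 1
        if got < n_draws:
            raise FittingError(f"bootstrap refits failed ({got}/{n_draws})")
        samples = draws
    elif backend == "laplace":
        cov = _nb_covariance(model, res)
        samples = rng.multivariate_normal(params, cov, size=n_draws,
                                          method="eigh", check_valid="ignore")
    else:
        raise ValueError(f"unknown backend {backend!r}")
    samples[:, -1] = np.clip(samples[:, -1], 1e-8, None)

    group_sd = _group_sd_from_draws(samples, names)
    samples = np.column_stack([samples, group_sd])
    all_names = all_names + ["group_sd"]

    spec = ModelSpec(family="negative_binomial", response="richness",
                     terms=tuple(names),
                     standardization={"elev": (std["elev_mean"], std["elev_sd"]),
                                      **({"day": (std["day_mean"], std["day_sd"])}
                                         if day_covariate else {})},
                     group_variable="spatial_group" if group_intercepts else None)
    zone_elev = {z: float(np.mean([p.elevation_m for p in design.zone_plots(z)]))
                 for z in ZONES if design.zone_plots(z)}
    return Draws(names=tuple(all_names), samples=samples,
                 response_sd=float(y.std(ddof=1)),
                 meta={"model_spec": spec, "backend": backend, "std": std,
                       "zone_elevations": zone_elev, "mle": params,
                       "group_labels": group_labels})


# ---------------------------------------------------------------------------
# Beta model for pairwise Jaccard dissimilarity
# ---------------------------------------------------------------------------

def _shrink_unit_interval(y: np.ndarray) -> np.ndarray:
    """Boundary shrinkage ``(y (n-1) + 0.5) / n`` when exact 0/1 present."""
    if ((y <= 0) | (y >= 1)).any():
        n = y.size
        return (y * (n - 1) + 0.5) / n
    return y


def _beta_negloglik(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> float:
    eta = X @ theta[:-1]
    mu = special.expit(eta)
    phi = np.exp(theta[-1])
    a = mu * phi
    b = (1.0 - mu) * phi
    ll = (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
          + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
    return -float(ll.sum())


def _beta_negscore(theta: np.ndarray, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    eta = X @ theta[:-1]
    mu = special.expit(eta)
    phi = np.exp(theta[-1])
    a = mu * phi
    b = (1.0 - mu) * phi
    y_star = np.log(y) - np.log1p(-y)
    mu_star = special.digamma(a) - special.digamma(b)
    g_beta = phi * (X.T @ ((y_star - mu_star) * mu * (1.0 - mu)))
    dl_dphi = np.sum(special.digamma(phi) - mu * special.digamma(a)
                     - (1.0 - mu) * special.digamma(b)
                     + mu * np.log(y) + (1.0 - mu) * np.log1p(-y))
    return -np.append(g_beta, dl_dphi * phi)


def fit_beta_model(pairs: Sequence[PairwiseDissimilarity],
                   day_covariate: bool = False,
                   quadratic: Sequence[str] = (),
                   backend: str = "bootstrap", n_draws: int = 2000,
                   rng: np.random.Generator | None = None) -> Draws:
    """Beta regression (logit link) of Jaccard dissimilarity on zone.

    Zone enters as three zone-mean intercepts on the logit scale
    (``mu_<zone>``); z-scored spatial and elevational pair distances are
    always included, a z-scored day-of-year difference optionally, and any
    covariate named in ``quadratic`` ({"spatial", "elevational", "day"}) also
    gets a squared term.  Precision is a single ``log_phi``.
    """
    if len(pairs) < 10:
        raise FittingError(f"need >= 10 pairs, have {len(pairs)}")
    rng = rng if rng is not None else np.random.default_rng()
    y = _shrink_unit_interval(np.array([p.jaccard for p in pairs], dtype=float))
    zone = np.array([p.zone for p in pairs])
    zones_present = [z for z in ZONES if (zone == z).any()]

    std: dict[str, tuple[float, float]] = {}
    cols: dict[str, np.ndarray] = {}
    for z in zones_present:
        cols[f"mu_{z}"] = (zone == z).astype(float)

    def add_cov(label: str, values: np.ndarray) -> None:
        vz, m, s = zscore(values)
        std[label] = (m, s)
        cols[label] = vz
        if label.split("_")[0] in quadratic:
            cols[f"{label}^2"] = vz**2

    add_cov("spatial_distance", np.array([p.spatial_distance_m for p in pairs]))
    add_cov("elevational_distance",
            np.array([p.elevational_distance_m for p in pairs]))
    if day_covariate:
        days = [p.day_difference for p in pairs]
        if any(d is None for d in days):
            raise FittingError("day covariate requested but day differences missing")
        add_cov("day_difference", np.array(days, dtype=float))

    X = np.column_stack(list(cols.values()))
    names = list(cols.keys())

    # starting values: logits of zone means, zero slopes, moment phi
    theta0 = np.zeros(X.shape[1] + 1)
    for j, z in enumerate(zones_present):
        mz = float(np.clip(y[zone == z].mean(), 1e-3, 1 - 1e-3))
        theta0[j] = special.logit(mz)
    v = float(y.var())
    mbar = float(y.mean())
    theta0[-1] = np.log(max(mbar * (1 - mbar) / max(v, 1e-6) - 1.0, 2.0))

    def fit_once(yy: np.ndarray, start: np.ndarray) -> np.ndarray | None:
        r = optimize.minimize(_beta_negloglik, start, args=(X, yy),
                              jac=_beta_negscore, method="BFGS",
                              options={"maxiter": 500, "gtol": 1e-6})
        return r.x if np.all(np.isfinite(r.x)) else None

    theta = fit_once(y, theta0)
    if theta is None:
        raise FittingError("beta regression did not converge")

    if backend == "bootstrap":
        mu_hat = special.expit(X @ theta[:-1])
        phi_hat = np.exp(theta[-1])
        draws = np.empty((n_draws, theta.size))
        got = 0
        attempts = 0
        while got < n_draws and attempts < int(1.5 * n_draws) + 20:
            attempts += 1
            y_star = rng.beta(mu_hat * phi_hat, (1.0 - mu_hat) * phi_hat)
            y_star = np.clip(y_star, 1e-9, 1 - 1e-9)
            t = fit_once(y_star, theta)
            if t is None:
                continue
            draws[got] = t
            got += 1
        if got < n_draws:
            raise FittingError(f"bootstrap refits failed ({got}/{n_draws})")
        samples = draws
    elif backend == "laplace":
        hess = approx_hess1(theta, _beta_negloglik, args=(X, y))
        try:
            cov = np.linalg.inv(hess)
        except np.linalg.LinAlgError as exc:
            raise FittingError("singular Hessian in beta regression") from exc
        samples = rng.multivariate_normal(theta, cov, size=n_draws,
                                          method="eigh")
    else:
        raise ValueError(f"unknown backend {backend!r}")

    spec = ModelSpec(family="beta", response="jaccard",
                     terms=tuple(names), standardization=std,
                     quadratic_terms=tuple(q for q in quadratic))
    return Draws(names=tuple(names + ["log_phi"]), samples=samples,
                 response_sd=float(y.std(ddof=1)),
                 meta={"model_spec": spec, "backend": backend, "std": std})


# ---------------------------------------------------------------------------
# Derived effects and predictions
# ---------------------------------------------------------------------------

def averaged_elevation_draws(draws: Draws) -> np.ndarray:
    """Per-draw elevation effect averaged over the five stages.

    The gap (baseline) stage contributes the bare elevation slope; every
    other stage contributes slope + its interaction term.
    """
    total = np.zeros(draws.n_draws)
    for s in STAGES:
        total += draws["elev"]
        if s != STAGES[0]:
            total += draws[f"elev:stage[{s}]"]
    return total / len(STAGES)


def averaged_elevation_effect(draws: Draws, **summary_kwargs) -> PosteriorSummary:
    """Summary of the stage-averaged elevation effect (log scale per SD)."""
    return summarize_vector(averaged_elevation_draws(draws), draws.response_sd,
                            "elevation (stage-averaged)", **summary_kwargs)


def percent_change_per_sd(draws: Draws, coefficient, **summary_kwargs
                          ) -> PosteriorSummary:
    """Per-draw ``(exp(beta) - 1) * 100`` for a log-link coefficient.

    ``coefficient`` is a draw-column name or an explicit vector of draws
    (e.g. the stage-averaged elevation effect).
    """
    if isinstance(coefficient, str):
        vec = draws[coefficient]
        label = f"% change per SD [{coefficient}]"
    else:
        vec = np.asarray(coefficient, dtype=float)
        label = "% change per SD"
    pct = (np.exp(vec) - 1.0) * 100.0
    return summarize_vector(pct, draws.response_sd, label, **summary_kwargs)


@dataclass(frozen=True)
class PredictionDraws:
    """Response-scale richness predictions per stage x elevation.

    ``values`` has shape (n_draws, n_stages, n_elevations); group intercepts
    are marginalized at zero and the day covariate held at its mean.
    """

    values: np.ndarray
    stages: tuple[str, ...]
    elevations_m: tuple[float, ...]
    response_sd: float


def predict_richness(draws: Draws, design: Design,
                     elevations: Sequence[float]) -> PredictionDraws:
    """Predict species richness for each stage at the given elevations (m)."""
    std = draws.meta.get("std")
    if std is None:
        raise ValueError("draws carry no standardization record; "
                         "fit with fit_richness_model")
    elev_z = (np.asarray(elevations, dtype=float) - std["elev_mean"]) / std["elev_sd"]
    n_stage = len(STAGES)
    out = np.empty((draws.n_draws, n_stage, elev_z.size))
    for si, s in enumerate(STAGES):
        eta = draws["intercept"].copy()
        slope = draws["elev"].copy()
        if s != STAGES[0]:
            eta += draws[f"stage[{s}]"]
            slope += draws[f"elev:stage[{s}]"]
        out[:, si, :] = np.exp(eta[:, None] + slope[:, None] * elev_z[None, :])
    return PredictionDraws(values=out, stages=STAGES,
                           elevations_m=tuple(float(e) for e in elevations),
                           response_sd=draws.response_sd)


def minmax_normalize(x: np.ndarray) -> np.ndarray:
    """Map an array linearly onto [0, 1] by its own min and max."""
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def difference_of_differences(pred: PredictionDraws, **summary_kwargs
                              ) -> list[PosteriorSummary]:
    """Zone comparison of |stage - optimum| richness gaps.

    Requires predictions at exactly three elevations, taken in zone order
    (submontane, montane, subalpine).  For each stage s != optimum and each
    draw: ``d_z(s) = |pred_z(s) - pred_z(optimum)|``; reported contrasts are
    ``d_submontane - d_montane`` and ``d_submontane - d_subalpine``.
    """
    if len(pred.elevations_m) != 3:
        raise ValueError("difference-of-differences needs predictions at the "
                         "three zone elevations")
    opt = pred.stages.index("optimum")
    out = []
    for si, s in enumerate(pred.stages):
        if si == opt:
            continue
        d = np.abs(pred.values[:, si, :] - pred.values[:, opt, :])
        for zi, zname in ((1, "montane"), (2, "subalpine")):
            vec = d[:, 0] - d[:, zi]
            out.append(summarize_vector(
                vec, pred.response_sd,
                f"dod[{s} vs optimum]: submontane - {zname}", **summary_kwargs))
    return out
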