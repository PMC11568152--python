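"""End-to-end orchestration: simulate -> specialize -> diversity -> infer.

A :class:`RunConfig` names either a built-in scenario or input files, plus
the null-model and draw settings; :func:`run` executes every stage in order,
writes intermediate CSVs, and returns a machine-readable :class:`Report`
holding one table per hypothesis:

* H I  — pairwise zone contrasts of mean plot specialization (SES);
* H II — stage-averaged elevation effect on richness and the corresponding
  percent change per SD of elevation;
* H III — pairwise zone contrasts of cross-stage Jaccard dissimilarity;
* H IV — difference-of-differences of |stage - optimum| richness predictions
  across zones.

Reproducibility: the master seed is mandatory and every stage/taxon/zone
RNG stream is derived from it by hashing, so adding a taxon never perturbs
another taxon's results.  Identical config and seed give identical reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .data_model import (Design, IncidenceTable, STAGES, ZONES, read_incidence,
                         read_plots, write_incidence, write_plots)
from .diversity import cross_stage_pairs, dissimilarity_table, species_richness
from .inference import (Draws, averaged_elevation_draws,
                        averaged_elevation_effect, contrast,
                        difference_of_differences, fit_beta_model,
                        fit_richness_model, fit_ses_model, percent_change_per_sd,
                        predict_richness, summarize_vector)
from .specialization import plot_mean_ses, ses_specialization
from .synthetic_data import generate_communities, get_scenario
from .pipeline_schema import REPORT_SCHEMA_VERSION, validate_report

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "Report", "run", "summarize_descriptives", "derive_seed"]


def derive_seed(master_seed: int, *labels: str) -> int:
    """Deterministic child seed from the master seed and a label path."""
    h = hashlib.blake2b(digest_size=4)
    h.update(str(int(master_seed)).encode())
    for lab in labels:
        h.update(b"/")
        h.update(str(lab).encode())
    return int.from_bytes(h.digest(), "big") % (2**31 - 1)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``scenario`` (a built-in synthetic scenario name) or
    ``plots_path`` + ``incidence_paths`` must be supplied.  ``seed`` is
    mandatory; all randomness derives from it.
    """

    seed: int | None = None
    scenario: str | None = None
    plots_path: str | Path | None = None
    incidence_paths: Mapping[str, str | Path] = field(default_factory=dict)
    n_null: int = 500
    draws: int = 2000
    backend: str = "bootstrap"
    day_covariate_taxa: frozenset[str] = frozenset()
    rope_multiplier: float = 0.1
    hdi_level: float = 0.95
    out_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("RunConfig.seed is mandatory")
        if (self.scenario is None) == (self.plots_path is None):
            raise ValueError("supply exactly one of scenario or plots_path")


@dataclass
class Report:
    """Machine-readable results of a pipeline run."""

    h1_specialization: dict
    h2_richness: dict
    h3_beta_diversity: dict
    h4_difference_of_differences: dict
    descriptives: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "h1_specialization": self.h1_specialization,
            "h2_richness": self.h2_richness,
            "h3_beta_diversity": self.h3_beta_diversity,
            "h4_difference_of_differences": self.h4_difference_of_differences,
            "descriptives": self.descriptives,
            "provenance": self.provenance,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


def _summary_dict(s) -> dict:
    return {"name": s.name, "map": s.map, "hdi_low": s.hdi_low,
            "hdi_high": s.hdi_high, "pd": s.pd, "rope_pct": s.rope_pct}


def _resolve_inputs(config: RunConfig) -> tuple[Design, dict[str, IncidenceTable]]:
    if config.scenario is not None:
        cfg, scenarios = get_scenario(config.scenario)
        cfg = dataclasses.replace(
            cfg, seed=derive_seed(config.seed, "design", config.scenario))
        from .synthetic_data import generate_design
        design = generate_design(cfg)
        tables = {}
        for sc in scenarios:
            rng = np.random.default_rng(
                derive_seed(config.seed, "communities", sc.taxon))
            tables[sc.taxon] = generate_communities(design, sc, rng=rng)
        return design, tables
    design = read_plots(config.plots_path)
    tables = {}
    for taxon, path in config.incidence_paths.items():
        inc = read_incidence(path, taxon=taxon)
        inc.validate_against(design)
        tables[taxon] = inc
    return design, tables


def run(config: RunConfig) -> Report:
    """Execute the full pipeline; see module docstring for the stages."""
    design, tables = _resolve_inputs(config)
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
        write_plots(design, out_dir / "plots.csv")

    skw = {"rope_multiplier": config.rope_multiplier,
           "hdi_level": config.hdi_level}
    h1, h2, h3, h4 = {}, {}, {}, {}
    exclusions: dict[str, dict] = {}

    for taxon, inc in tables.items():
        logger.info("pipeline stage=specialization taxon=%s", taxon)
        try:
            ses_all = []
            for zone in ZONES:
                rng = np.random.default_rng(
                    derive_seed(config.seed, "null", taxon, zone))
                ses_all.extend(ses_specialization(
                    inc, design, zone, n_null=config.n_null, rng=rng))
            plot_ses = plot_mean_ses(ses_all, inc, design)
            n_excluded = sum(s.excluded for s in ses_all)
            # species are the exchangeable units behind plot-averaged SES;
            # plot-iid backends would understate zone-mean uncertainty
            rng = np.random.default_rng(derive_seed(config.seed, "ses_fit", taxon))
            ses_draws = fit_ses_model(plot_ses, design,
                                      backend="species_bootstrap",
                                      n_draws=config.draws, rng=rng,
                                      species_ses=ses_all, inc=inc)
            h1[taxon] = [
                _summary_dict(contrast(
                    ses_draws, {f"mu_{a}": 1.0, f"mu_{b}": -1.0},
                    name=f"SES {a} - {b}", **skw))
                for a, b in (("submontane", "montane"),
                             ("submontane", "subalpine"),
                             ("montane", "subalpine"))]

            logger.info("pipeline stage=diversity taxon=%s", taxon)
            rich = species_richness(inc)
            pairs = dissimilarity_table(inc, design)
            known = set(inc.plot_ids)
            n_candidate_pairs = sum(
                1 for z in ZONES for a, b in cross_stage_pairs(design, z)
                if a in known and b in known)

            rng = np.random.default_rng(derive_seed(config.seed, "nb_fit", taxon))
            day = taxon in config.day_covariate_taxa
            rich_draws = fit_richness_model(rich, design, day_covariate=day,
                                            backend=config.backend,
                                            n_draws=config.draws, rng=rng)
            avg = averaged_elevation_effect(rich_draws, **skw)
            pct = percent_change_per_sd(rich_draws,
                                        averaged_elevation_draws(rich_draws),
                                        **skw)
            h2[taxon] = {"averaged_elevation_effect": _summary_dict(avg),
                         "percent_change_per_sd": _summary_dict(pct)}

            rng = np.random.default_rng(derive_seed(config.seed, "beta_fit", taxon))
            beta_draws = fit_beta_model(pairs, day_covariate=day,
                                        backend=config.backend,
                                        n_draws=config.draws, rng=rng)
            h3[taxon] = [
                _summary_dict(contrast(
                    beta_draws, {f"mu_{a}": 1.0, f"mu_{b}": -1.0},
                    name=f"Jaccard(logit) {a} - {b}", **skw))
                for a, b in (("submontane", "montane"),
                             ("submontane", "subalpine"),
                             ("montane", "subalpine"))]

            zone_elev = rich_draws.meta["zone_elevations"]
            pred = predict_richness(rich_draws, design,
                                    [zone_elev[z] for z in ZONES])
            h4[taxon] = [_summary_dict(s)
                         for s in difference_of_differences(pred, **skw)]

            exclusions[taxon] = {
                "species_sd_zero": int(n_excluded),
                "species_zone_records": len(ses_all),
                "empty_union_pairs_dropped": int(n_candidate_pairs - len(pairs)),
            }
            if out_dir:
                _write_taxon_outputs(out_dir, taxon, inc, ses_all, plot_ses,
                                     rich, pairs)
        except Exception as exc:
            raise RuntimeError(
                f"pipeline failed at taxon {taxon!r}: {exc}") from exc

    descriptives = summarize_descriptives(tables, design).to_dict(orient="index")
    provenance = {
        "package_version": _version,
        "seed": int(config.seed),
        "config": _config_dict(config),
        "config_hash": hashlib.blake2b(
            json.dumps(_config_dict(config), sort_keys=True).encode(),
            digest_size=8).hexdigest(),
        "exclusions": exclusions,
    }
    report = Report(h1, h2, h3, h4, descriptives, provenance)
    validate_report(report.to_dict())
    if out_dir:
        (out_dir / "report.json").write_text(report.to_json())
    return report


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["incidence_paths"] = {k: str(v) for k, v in d["incidence_paths"].items()}
    d["day_covariate_taxa"] = sorted(d["day_covariate_taxa"])
    d["plots_path"] = str(d["plots_path"]) if d["plots_path"] else None
    d["out_dir"] = str(d["out_dir"]) if d["out_dir"] else None
    return d


def _write_taxon_outputs(out_dir: Path, taxon: str, inc, ses_all, plot_ses,
                         rich, pairs) -> None:
    write_incidence(inc, out_dir / f"incidence_{taxon}.csv")
    pd.DataFrame([{
        "species_id": s.species_id, "zone": s.zone, "B_obs": s.B_obs,
        "null_mean": s.null_mean, "null_sd": s.null_sd, "ses": s.ses,
        "excluded": s.excluded} for s in ses_all]).to_csv(
        out_dir / f"ses_{taxon}.csv", index=False)
    pd.DataFrame([{
        "plot_id": p.plot_id, "zone": p.zone, "mean_ses": p.mean_ses,
        "n_species": p.n_species} for p in plot_ses]).to_csv(
        out_dir / f"plot_ses_{taxon}.csv", index=False)
    pd.DataFrame([{"plot_id": r.plot_id, "richness": r.richness}
                  for r in rich]).to_csv(
        out_dir / f"richness_{taxon}.csv", index=False)
    pd.DataFrame([{
        "plot_a": p.plot_a, "plot_b": p.plot_b, "zone": p.zone,
        "stage_a": p.stage_a, "stage_b": p.stage_b, "jaccard": p.jaccard,
        "spatial_distance_m": p.spatial_distance_m,
        "elevational_distance_m": p.elevational_distance_m,
        "day_difference": p.day_difference} for p in pairs]).to_csv(
        out_dir / f"beta_{taxon}.csv", index=False)


def summarize_descriptives(tables: Mapping[str, IncidenceTable],
                           design: Design) -> pd.DataFrame:
    """Per-taxon descriptive statistics.

    Mean number of developmental stages used per species (within zones),
    mean per-plot richness, and mean cross-stage Jaccard dissimilarity.
    """
    rows = {}
    for taxon, inc in tables.items():
        stages_used = []
        for zone in ZONES:
            zone_plots = design.zone_plots(zone)
            idx = [inc.plot_ids.index(p.plot_id) for p in zone_plots
                   if p.plot_id in inc.plot_ids]
            if not idx:
                continue
            stage_lab = np.array([design[inc.plot_ids[i]].stage for i in idx])
            sub = inc.matrix[idx]
            used = np.zeros(sub.shape[1])
            for s in STAGES:
                used += (sub[stage_lab == s].sum(axis=0) > 0)
            stages_used.extend(used[used > 0])
        pairs = dissimilarity_table(inc, design)
        rows[taxon] = {
            "mean_stages_used": float(np.mean(stages_used)) if stages_used
            else float("nan"),
            "mean_plot_richness": float(np.mean(inc.richness())),
            "mean_cross_stage_jaccard": float(np.mean([p.jaccard for p in pairs]))
            if pairs else float("nan"),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
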