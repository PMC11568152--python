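import numpy as np
import pytest

from stagespec import (Design, DesignConfig, PlotRecord, STAGES, TaxonScenario,
                       generate_communities, generate_design, incidence_from_long)


@pytest.fixture(scope="session")
def design150():
    """Canonical 5 stages x 3 zones x 10 replicates design."""
    return generate_design(DesignConfig(seed=101))


@pytest.fixture(scope="session")
def null_inc(design150):
    """Structure-free community: flat stage affinities, no trends."""
    scenario = TaxonScenario(taxon="null", n_species=200, occupancy_rate=0.25,
                             breadth_concentration={z: 1e6 for z in
                                                    ("submontane", "montane",
                                                     "subalpine")},
                             seed=42)
    return generate_communities(design150, scenario)


def one_zone_design(n_per_stage=1, zone="submontane"):
    """Minimal single-zone design, one or more plots per stage."""
    plots = []
    k = 0
    for stage in STAGES:
        for r in range(n_per_stage):
            plots.append(PlotRecord(
                plot_id=f"p_{stage}_{r}", stage=stage, zone=zone,
                elevation_m=700.0 + 10 * k, x_m=1000.0 + 200.0 * k, y_m=5000.0,
                spatial_group="g0", day_of_year=180))
            k += 1
    return Design(tuple(plots))


@pytest.fixture
def five_plot_design():
    return one_zone_design(n_per_stage=1)


def incidence_for(design, occurrences, taxon="t"):
    """Build an incidence table from {species: [plot ids]}."""
    records = [(pid, sp) for sp, pids in occurrences.items() for pid in pids]
    inc = incidence_from_long(taxon, records)
    return inc
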