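"""Per-plot species richness and cross-stage Jaccard dissimilarity.

Richness is the number of species recorded at a plot.  Beta diversity across
forest developmental stages is the Jaccard dissimilarity between every pair
of plots from *different* stages within the same elevational zone, carried
with the covariates of the downstream beta regression: planar distance,
absolute elevation difference and (when sampling days are known) absolute
day-of-year difference.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .data_model import Design, IncidenceTable, ZONES

logger = logging.getLogger(__name__)

__all__ = ["RichnessRecord", "PairwiseDissimilarity", "species_richness",
           "jaccard_dissimilarity", "cross_stage_pairs", "dissimilarity_table"]


@dataclass(frozen=True)
class RichnessRecord:
    plot_id: str
    taxon: str
    richness: int


@dataclass(frozen=True)
class PairwiseDissimilarity:
    """One unordered cross-stage plot pair within a zone."""

    plot_a: str
    plot_b: str
    zone: str
    stage_a: str
    stage_b: str
    jaccard: float
    spatial_distance_m: float
    elevational_distance_m: float
    day_difference: int | None = None


def species_richness(inc: IncidenceTable) -> list[RichnessRecord]:
    """Species count per plot (sum of the plot's incidence row)."""
    counts = inc.richness()
    return [RichnessRecord(pid, inc.taxon, int(c))
            for pid, c in zip(inc.plot_ids, counts)]


def jaccard_dissimilarity(a, b) -> float:
    """``1 - |a n b| / |a u b|`` between two species sets.

    Undefined (raises) when both sets are empty; symmetric in its arguments.
    """
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        raise ValueError("Jaccard dissimilarity undefined for two empty sets")
    return 1.0 - len(a & b) / union


def cross_stage_pairs(design: Design, zone: str) -> list[tuple[str, str]]:
    """All unordered same-zone plot pairs whose stages differ."""
    plots = design.zone_plots(zone)
    return [(p.plot_id, q.plot_id)
            for p, q in combinations(plots, 2) if p.stage != q.stage]


def dissimilarity_table(inc: IncidenceTable,
                        design: Design) -> list[PairwiseDissimilarity]:
    """Cross-stage Jaccard dissimilarities with covariates, all zones.

    Pairs where both plots host no species (empty union) are dropped — the
    beta regression downstream needs a defined response — and the number of
    drops is logged.
    """
    sets = {pid: inc.species_set(pid) for pid in inc.plot_ids}
    out: list[PairwiseDissimilarity] = []
    n_dropped = 0
    for zone in ZONES:
        if not design.zone_plots(zone):
            continue
        for pid_a, pid_b in cross_stage_pairs(design, zone):
            if pid_a not in sets or pid_b not in sets:
                continue
            pa, pb = design[pid_a], design[pid_b]
            sa, sb = sets[pid_a], sets[pid_b]
            if not (sa | sb):
                n_dropped += 1
                continue
            day = None
            if pa.day_of_year is not None and pb.day_of_year is not None:
                day = abs(pa.day_of_year - pb.day_of_year)
            out.append(PairwiseDissimilarity(
                plot_a=pid_a, plot_b=pid_b, zone=zone,
                stage_a=pa.stage, stage_b=pb.stage,
                jaccard=jaccard_dissimilarity(sa, sb),
                spatial_distance_m=math.hypot(pa.x_m - pb.x_m, pa.y_m - pb.y_m),
                elevational_distance_m=abs(pa.elevation_m - pb.elevation_m),
                day_difference=day))
    if n_dropped:
        logger.info("dropped %d empty-union plot pair(s) for taxon %s",
                    n_dropped, inc.taxon)
    return out
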