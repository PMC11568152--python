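"""Niche breadth, fixed-margin null models, and the specialization SES.

Habitat specialization of a species within an elevational zone is measured
from its proportional use of the five forest developmental stages:

    B = 1 / sum_i p_i^2

the reciprocal Simpson (inverse concentration) index, where ``p_i`` is the
share of the species' occupied plots that lie in stage ``i``.  ``B`` runs
from 1 (perfect specialist) to 5 (perfectly even use of all stages).

Raw ``B`` is confounded with occupancy: a species seen on more plots uses
more stages by chance alone.  The standardized effect size removes this by
comparing the observed ``B`` against ``B`` recomputed on random communities
that preserve every species' occupancy and every plot's richness (fixed row
and column sums).  Each null matrix is generated by an independent restart
from the observed matrix (non-sequential), using the curveball algorithm by
default.  The SES is sign-flipped so that larger values mean stronger
specialization:

    SES = -(B_obs - mean(B_null)) / sd(B_null)

Species whose incidence row is invariant under margin-preserving
randomization (sd = 0) carry no information and are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from numba import njit

from .data_model import Design, IncidenceTable, STAGES, STAGE_INDEX, ZONES

__all__ = [
    "ProportionalUse", "SpecializationSES", "PlotSpecialization",
    "niche_breadth", "proportional_use", "permute_fixed_margins",
    "ses_specialization", "plot_mean_ses",
]


# ---------------------------------------------------------------------------
# Niche breadth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProportionalUse:
    """A species' proportional use of the five stages within one zone."""

    species_id: str
    zone: str
    p: tuple[float, ...]
    n_occupied: int
    B: float


def niche_breadth(p) -> float:
    """Reciprocal Simpson index ``1 / sum(p_i^2)`` of a proportion vector.

    Bounded by [1, k] for k categories with nonzero proportions.
    """
    p = np.asarray(p, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    total = p.sum()
    if total == 0:
        raise ValueError("all-zero proportion vector has no defined breadth")
    if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-8):
        raise ValueError(f"proportions must sum to 1, got {total}")
    return float(1.0 / np.square(p).sum())


def proportional_use(inc: IncidenceTable, design: Design,
                     zone: str) -> list[ProportionalUse]:
    """Per-species stage-use proportions and breadth within one zone.

    Species with zero occupancy in the zone are dropped; stages with no plots
    in the zone contribute ``p_i = 0``.
    """
    zone_plots = design.zone_plots(zone)
    if not zone_plots:
        raise ValueError(f"zone {zone!r} has no plots")
    idx = [inc.plot_ids.index(p.plot_id) for p in zone_plots
           if p.plot_id in inc.plot_ids]
    if not idx:
        raise ValueError(f"no incidence rows for zone {zone!r}")
    stage_i = np.array([STAGE_INDEX[design[inc.plot_ids[i]].stage] for i in idx])
    sub = inc.matrix[idx]  # zone plots x species

    out = []
    counts = np.zeros((len(STAGES), sub.shape[1]), dtype=np.int64)
    for si in range(len(STAGES)):
        counts[si] = sub[stage_i == si].sum(axis=0)
    occ = counts.sum(axis=0)
    for j in np.flatnonzero(occ):
        p = counts[:, j] / occ[j]
        out.append(ProportionalUse(
            species_id=inc.species_ids[j], zone=zone,
            p=tuple(float(v) for v in p),
            n_occupied=int(occ[j]), B=niche_breadth(p)))
    return out


# ---------------------------------------------------------------------------
# Fixed-margin randomization (rows = species, columns = plots)
# ---------------------------------------------------------------------------

@njit(cache=True)
def _curveball_kernel(m, n_steps, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n_rows, n_cols = m.shape
    excl = np.empty(n_cols, np.int64)
    for _ in range(n_steps):
        r1 = np.random.randint(0, n_rows)
        r2 = np.random.randint(0, n_rows)
        if r1 == r2:
            continue
        k = 0
        k1 = 0
        for c in range(n_cols):
            if m[r1, c] != m[r2, c]:
                excl[k] = c
                k += 1
                if m[r1, c] == 1:
                    k1 += 1
        if k1 == 0 or k1 == k:
            continue
        # Fisher-Yates shuffle of the exclusive columns, then deal the first
        # k1 to row r1 and the rest to row r2 (a "trade").
        for t in range(k - 1, 0, -1):
            j = np.random.randint(0, t + 1)
            tmp = excl[t]
            excl[t] = excl[j]
            excl[j] = tmp
        for t in range(k):
            c = excl[t]
            if t < k1:
                m[r1, c] = 1
                m[r2, c] = 0
            else:
                m[r1, c] = 0
                m[r2, c] = 1
    return m


@njit(cache=True)
def _trialswap_kernel(m, n_steps, seed):  # pragma: no cover - exercised via wrapper
    np.random.seed(seed)
    n_rows, n_cols = m.shape
    for _ in range(n_steps):
        r1 = np.random.randint(0, n_rows)
        r2 = np.random.randint(0, n_rows)
        c1 = np.random.randint(0, n_cols)
        c2 = np.random.randint(0, n_cols)
        if r1 == r2 or c1 == c2:
            continue
        a, b = m[r1, c1], m[r1, c2]
        c, d = m[r2, c1], m[r2, c2]
        if a == 1 and d == 1 and b == 0 and c == 0:
            m[r1, c1] = 0
            m[r1, c2] = 1
            m[r2, c1] = 1
            m[r2, c2] = 0
        elif a == 0 and d == 0 and b == 1 and c == 1:
            m[r1, c1] = 1
            m[r1, c2] = 0
            m[r2, c1] = 0
            m[r2, c2] = 1
    return m


def default_n_steps(n_rows: int) -> int:
    """Default mixing length: 5 trades per species row, at least 1000."""
    return max(1000, 5 * n_rows)


def permute_fixed_margins(matrix: np.ndarray, method: str = "curveball",
                          n_steps: int | None = None,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """One random binary matrix with the same row sums, column sums and fill.

    Starts from the supplied matrix every call (independent restart, not a
    continuing chain).  ``method`` is ``"curveball"`` (default; uniform over
    the fixed-margin class) or ``"trialswap"`` (2x2 checkerboard swaps).
    """
    m = np.asarray(matrix)
    if m.ndim != 2:
        raise ValueError("matrix must be 2-D")
    if m.size and not np.isin(m, (0, 1)).all():
        raise ValueError("matrix entries must be 0 or 1")
    rng = rng if rng is not None else np.random.default_rng()
    steps = default_n_steps(m.shape[0]) if n_steps is None else int(n_steps)
    seed = int(rng.integers(0, 2**31 - 1))
    work = np.ascontiguousarray(m, dtype=np.int8).copy()
    if method == "curveball":
        return _curveball_kernel(work, steps, seed)
    if method == "trialswap":
        return _trialswap_kernel(work, steps, seed)
    raise ValueError(f"unknown permutation method {method!r}")


# ---------------------------------------------------------------------------
# SES of specialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpecializationSES:
    """Sign-flipped standardized effect size of niche breadth for one species."""

    species_id: str
    zone: str
    B_obs: float
    null_mean: float
    null_sd: float
    ses: float
    n_null: int
    excluded: bool


_SD_ZERO_TOL = 1e-12


def _breadth_from_counts(counts: np.ndarray) -> np.ndarray:
    # counts: species x stages occupancy counts; rows with zero total -> nan
    occ = counts.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = counts / occ
        b = 1.0 / np.square(p).sum(axis=1)
    return b


def ses_specialization(inc: IncidenceTable, design: Design, zone: str,
                       n_null: int = 500,
                       rng: np.random.Generator | None = None,
                       method: str = "curveball",
                       n_steps: int | None = None,
                       matrix_scope: str = "zone") -> list[SpecializationSES]:
    """SES of habitat specialization for every species occurring in a zone.

    The null model randomizes the species x plot incidence submatrix of the
    zone (``matrix_scope="zone"``, default) or the full matrix across all
    zones (``matrix_scope="pooled"``) with fixed margins, recomputing ``B``
    for each of ``n_null`` independent permutations.  Species with zero null
    variation are flagged ``excluded`` (their ``ses`` is NaN).
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    if matrix_scope not in ("zone", "pooled"):
        raise ValueError(f"unknown matrix_scope {matrix_scope!r}")
    rng = rng if rng is not None else np.random.default_rng()

    zone_plots = design.zone_plots(zone)
    if not zone_plots:
        raise ValueError(f"zone {zone!r} has no plots")
    zone_idx = [inc.plot_ids.index(p.plot_id) for p in zone_plots
                if p.plot_id in inc.plot_ids]
    zone_stage = np.array([STAGE_INDEX[design[inc.plot_ids[i]].stage]
                           for i in zone_idx])
    zone_sub = inc.matrix[zone_idx]  # zone plots x species
    occ = zone_sub.sum(axis=0)
    sp_idx = np.flatnonzero(occ)  # species occurring in the zone

    if matrix_scope == "zone":
        # Rows = species occurring in the zone, columns = zone plots.
        base = np.ascontiguousarray(zone_sub[:, sp_idx].T, dtype=np.int8)
        col_stage = zone_stage
        zone_cols = slice(None)
    else:
        present = np.flatnonzero(inc.matrix.sum(axis=0))
        base = np.ascontiguousarray(inc.matrix[:, present].T, dtype=np.int8)
        col_stage = None  # stages looked up per column below
        # map columns of the pooled matrix back to the zone
        zone_cols = np.array(zone_idx)
        pooled_stage = zone_stage
        # rows of `base` corresponding to species of this zone
        sp_rows = np.array([int(np.flatnonzero(present == j)[0]) for j in sp_idx])

    stage_onehot = np.zeros((base.shape[1] if matrix_scope == "zone"
                             else len(zone_idx), len(STAGES)))
    if matrix_scope == "zone":
        stage_onehot[np.arange(len(zone_stage)), zone_stage] = 1.0
    else:
        stage_onehot[np.arange(len(pooled_stage)), pooled_stage] = 1.0

    def species_breadth(mat: np.ndarray) -> np.ndarray:
        if matrix_scope == "zone":
            counts = mat.astype(np.float64) @ stage_onehot
            return _breadth_from_counts(counts)
        sub = mat[np.ix_(sp_rows, zone_cols)]
        counts = sub.astype(np.float64) @ stage_onehot
        return _breadth_from_counts(counts)

    b_obs = species_breadth(base)
    steps = default_n_steps(base.shape[0]) if n_steps is None else int(n_steps)

    b_null = np.empty((n_null, b_obs.size))
    for i in range(n_null):
        null = permute_fixed_margins(base, method=method, n_steps=steps, rng=rng)
        b_null[i] = species_breadth(null)
    # pooled scope can leave a species without zone occurrences (NaN breadth);
    # two-pass nan moments keep an invariant row's SD at numerical zero
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(b_null, axis=0)
        sd = np.nanstd(b_null, axis=0, ddof=1)

    out = []
    for k, j in enumerate(sp_idx):
        excluded = not np.isfinite(sd[k]) or sd[k] < _SD_ZERO_TOL
        ses = float("nan") if excluded else float(-(b_obs[k] - mean[k]) / sd[k])
        out.append(SpecializationSES(
            species_id=inc.species_ids[j], zone=zone,
            B_obs=float(b_obs[k]), null_mean=float(mean[k]),
            null_sd=float(sd[k]) if np.isfinite(sd[k]) else 0.0,
            ses=ses, n_null=int(n_null), excluded=bool(excluded)))
    return out


# ---------------------------------------------------------------------------
# Plot-level averaging
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotSpecialization:
    """Mean SES over the non-excluded species present at one plot.

    ``mean_ses`` is NaN and ``n_species`` 0 for plots hosting no usable
    species (flagged missing, never silently dropped).
    """

    plot_id: str
    zone: str
    mean_ses: float
    n_species: int


def plot_mean_ses(ses: list[SpecializationSES], inc: IncidenceTable,
                  design: Design) -> list[PlotSpecialization]:
    """Average the species SES over the species present at each plot.

    Only species of the plot's own zone (SES is zone-specific) that are not
    excluded contribute.
    """
    by_zone: dict[str, dict[str, float]] = {}
    for s in ses:
        if not s.excluded:
            by_zone.setdefault(s.zone, {})[s.species_id] = s.ses

    out = []
    for p in design.plots:
        if p.zone not in by_zone:
            continue
        usable = by_zone[p.zone]
        present = (inc.species_set(p.plot_id)
                   if p.plot_id in inc.plot_ids else frozenset())
        values = [usable[sp] for sp in present if sp in usable]
        if values:
            out.append(PlotSpecialization(p.plot_id, p.zone,
                                          float(np.mean(values)), len(values)))
        else:
            out.append(PlotSpecialization(p.plot_id, p.zone, float("nan"), 0))
    return out
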