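"""Climate-envelope vulnerability scoring and 2090 vegetation projection.

Each ERU carries a climate envelope: the pre-1990 mean ``x̄`` and the
inter-annual pre-1990 standard deviation ``s`` of each of (by default five)
climate variables, over the ERU's mapped extent.  The vulnerability of an
ERU at a location with projected 2090 value ``Val`` of one variable is the
standardized departure

    VS = |x̄ − Val| / (2 s)

so VS = 0 when the future climate sits at the envelope centre and VS = 1
when it sits two inter-annual SDs away.  Per-variable scores are combined
(mean by default) into an aggregate score.

Projection of a cell's 2090 vegetation type asks which envelopes still
admit the cell's projected climate: an envelope admits the cell when every
variable lies within k·s of the envelope mean (default k = 2, i.e.
per-variable VS ≤ 1).  Overlapping envelopes can admit more than one
future type; the candidate set keeps them all and downstream habitat
rendering can either err toward inclusion (any candidate) or use the single
most-likely type (minimum aggregate vulnerability).  If no envelope admits
the cell, the least-departed envelope is the sole candidate.

Ecological transition rules then constrain the candidates:

* shrub types never convert to woodland or forest (site factors, shrub
  recruitment and fire perpetuate shrub dominance) — a shrub cell may only
  move to shrubland, grassland or desert types;
* woodlands at their lower ecotone may convert to grassland or shrubland;
* riparian types are never produced (not modelable from the climate
  envelope); riparian cells persist as themselves;
* if the rules empty a candidate set, the current type persists.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .landscape import Landscape
from .taxonomy import Taxonomy, ERUClass

__all__ = [
    "ClimateEnvelope",
    "ProjectionResult",
    "vulnerability_score",
    "aggregate_vulnerability",
    "candidate_future_erus",
    "apply_transition_rules",
    "project_landscape",
]

#: Candidate-set zones a shrub type may transition to.
_SHRUB_TARGET_ZONES = frozenset({"shrubland", "grassland", "desert"})


@dataclass(frozen=True)
class ClimateEnvelope:
    """Pre-1990 climate envelope of one ERU.

    ``means[v]`` and ``sds[v]`` are x̄ and the inter-annual SD s of variable
    ``variables[v]``.  All envelopes in an analysis must share the same
    variable list.
    """

    eru_id: str
    variables: tuple[str, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self) -> None:
        if not (len(self.variables) == len(self.means) == len(self.sds)):
            raise ValueError("variables, means and sds must have equal length")
        if any(s <= 0 for s in self.sds):
            raise ValueError(f"envelope {self.eru_id!r}: every s must be > 0")


def vulnerability_score(mean: float, sd: float, future_value: float) -> float:
    """Standardized climate departure VS = |x̄ − Val| / (2 s) for one variable.

    Zero iff the future value equals the envelope mean; symmetric in the
    sign of the departure; strictly increasing in |departure| and strictly
    decreasing in s.
    """
    if sd <= 0:
        raise ValueError("s must be > 0")
    return abs(mean - future_value) / (2.0 * sd)


def aggregate_vulnerability(cell_climate: dict[str, float],
                            envelope: ClimateEnvelope,
                            method: str = "mean") -> float:
    """Combine per-variable vulnerability scores into one cell score."""
    if set(cell_climate) != set(envelope.variables):
        raise ValueError(
            f"variable sets differ: {sorted(cell_climate)} vs "
            f"{sorted(envelope.variables)}")
    scores = [vulnerability_score(m, s, cell_climate[v])
              for v, m, s in zip(envelope.variables, envelope.means, envelope.sds)]
    if method == "mean":
        return float(np.mean(scores))
    if method == "max":
        return float(max(scores))
    raise ValueError(f"method must be 'mean' or 'max', got {method!r}")


def candidate_future_erus(cell_climate: dict[str, float],
                          envelopes: list[ClimateEnvelope],
                          k: float = 2.0,
                          method: str = "mean") -> set[str]:
    """ERUs whose envelope admits a cell's projected climate.

    An envelope admits the cell when |Val − x̄| ≤ k·s for every variable.
    If no envelope admits it, the single envelope with minimal aggregate
    vulnerability is returned (first in list order on exact ties).
    """
    if not envelopes:
        raise ValueError("need at least one envelope")
    if k <= 0:
        raise ValueError("k must be > 0")
    admitted = set()
    for env in envelopes:
        ok = all(abs(cell_climate[v] - m) <= k * s
                 for v, m, s in zip(env.variables, env.means, env.sds))
        if ok:
            admitted.add(env.eru_id)
    if admitted:
        return admitted
    best = min(envelopes,
               key=lambda e: aggregate_vulnerability(cell_climate, e, method))
    return {best.eru_id}


def apply_transition_rules(current: ERUClass, candidates: set[str],
                           taxonomy: Taxonomy) -> set[str]:
    """Constrain raw envelope candidates by the ecological transition rules.

    Returns a non-empty set; falls back to the current ERU when the rules
    remove every candidate (persistence — cells are never projected to
    "no vegetation").
    """
    if not candidates:
        raise ValueError("candidate set must be non-empty")
    out = set()
    for cid in candidates:
        c = taxonomy[cid]
        if c.zone == "riparian":
            continue  # riparian is never a projectable outcome
        if current.is_shrub_type and c.zone not in _SHRUB_TARGET_ZONES:
            continue  # shrub never converts to woodland/forest
        out.add(cid)
    if not out:
        return {current.id}
    return out


@dataclass
class ProjectionResult:
    """Per-cell outcome of projecting a landscape to 2090.

    ``candidate`` is a boolean array of shape (nrows, ncols, n_erus) over
    ``eru_order``; ``most_likely`` the single best future ERU id per cell;
    ``current_vs`` the aggregate vulnerability of each cell's *current* ERU
    (NaN for riparian cells, which have no envelope).
    """

    landscape: Landscape
    eru_order: tuple[str, ...]
    candidate: np.ndarray
    most_likely: np.ndarray
    current_vs: np.ndarray

    def candidate_mask(self, eru_id: str) -> np.ndarray:
        """Boolean grid: cells with ``eru_id`` among their 2090 candidates."""
        return self.candidate[:, :, self.eru_order.index(eru_id)]

    def candidates_contain_current(self) -> np.ndarray:
        """Boolean grid: cells whose candidate set contains the current ERU."""
        out = np.zeros(self.landscape.shape, dtype=bool)
        for idx, eid in enumerate(self.eru_order):
            here = self.landscape.eru == eid
            out[here] = self.candidate[:, :, idx][here]
        return out

    def candidate_count(self) -> np.ndarray:
        return self.candidate.sum(axis=2)


def project_landscape(landscape: Landscape,
                      climate_2090: dict[str, np.ndarray],
                      envelopes: list[ClimateEnvelope],
                      taxonomy: Taxonomy,
                      k: float = 2.0,
                      method: str = "mean") -> ProjectionResult:
    """Project every cell's 2090 vegetation type from its projected climate.

    Vectorized equivalent of running :func:`candidate_future_erus` +
    :func:`apply_transition_rules` per cell, plus the most-likely pick
    (minimum aggregate vulnerability among allowed candidates, ties broken
    by taxonomy order) and the vulnerability score of the current ERU.

    Riparian cells are not modelable and persist: their sole candidate is
    their current ERU and their vulnerability is NaN.
    """
    if not envelopes:
        raise ValueError("need at least one envelope")
    variables = envelopes[0].variables
    for env in envelopes:
        if env.variables != variables:
            raise ValueError("all envelopes must share one variable list")
    missing = [v for v in variables if v not in climate_2090]
    if missing:
        raise ValueError(f"climate surfaces missing variables: {missing}")
    nr, nc = landscape.shape
    for v in variables:
        if np.asarray(climate_2090[v]).shape != (nr, nc):
            raise ValueError(f"climate surface {v!r} does not cover the landscape")

    # envelopes in taxonomy order => argmin tie-break = taxonomy order
    env_by_id = {e.eru_id: e for e in envelopes}
    order = tuple(eid for eid in taxonomy.ids if eid in env_by_id)
    envs = [env_by_id[eid] for eid in order]
    n_env = len(envs)

    vals = np.stack([np.asarray(climate_2090[v], dtype=float) for v in variables],
                    axis=0)  # (V, nr, nc)
    means = np.array([[e.means[i] for i in range(len(variables))] for e in envs])
    sds = np.array([[e.sds[i] for i in range(len(variables))] for e in envs])

    # per-envelope per-cell: departure over 2s
    dep = np.abs(vals[None, :, :, :] - means[:, :, None, None])  # (E, V, nr, nc)
    vs = dep / (2.0 * sds[:, :, None, None])
    if method == "mean":
        agg = vs.mean(axis=1)  # (E, nr, nc)
    elif method == "max":
        agg = vs.max(axis=1)
    else:
        raise ValueError(f"method must be 'mean' or 'max', got {method!r}")
    admitted = (dep <= k * sds[:, :, None, None]).all(axis=1)  # (E, nr, nc)

    # cells admitted by nothing: sole candidate = least-departed envelope
    none_adm = ~admitted.any(axis=0)
    if none_adm.any():
        best = np.argmin(agg, axis=0)
        rows, cols = np.nonzero(none_adm)
        admitted[best[rows, cols], rows, cols] = True

    candidate = np.moveaxis(admitted, 0, 2).copy()  # (nr, nc, E)

    # transition rules, applied per current-ERU group
    riparian_col = np.array([taxonomy[eid].zone == "riparian" for eid in order])
    shrub_ok_col = np.array([taxonomy[eid].zone in _SHRUB_TARGET_ZONES
                             for eid in order])
    candidate[:, :, riparian_col] = False
    current_vs = np.full((nr, nc), np.nan)
    for eid in landscape.eru_ids_present():
        cur = taxonomy[eid]
        here = landscape.eru == eid
        if cur.zone == "riparian":
            # not modelable: persist, no vulnerability score
            candidate[here, :] = False
            if eid in order:
                candidate[here, order.index(eid)] = True
            continue
        if eid not in order:
            raise ValueError(f"no climate envelope for ERU {eid!r} present on "
                             "the landscape")
        if cur.is_shrub_type:
            block = candidate[here, :]
            block[:, ~shrub_ok_col] = False
            candidate[here, :] = block
        current_vs[here] = agg[order.index(eid)][here]

    # riparian cells with current ERU not in envelope order still need a
    # candidate column; extend order if necessary
    rip_ids = [eid for eid in landscape.eru_ids_present()
               if taxonomy[eid].zone == "riparian" and eid not in order]
    if rip_ids:
        extra = np.zeros((nr, nc, len(rip_ids)), dtype=bool)
        for j, eid in enumerate(rip_ids):
            extra[landscape.eru == eid, j] = True
        candidate = np.concatenate([candidate, extra], axis=2)
        order = order + tuple(rip_ids)
        pad = np.full((len(rip_ids), nr, nc), np.inf)
        agg = np.concatenate([agg, pad], axis=0)

    # fallback: rules emptied the set -> persist as current ERU
    empty = ~candidate.any(axis=2)
    if empty.any():
        for eid in np.unique(np.asarray(landscape.eru)[empty]):
            sel = empty & (landscape.eru == eid)
            candidate[sel, order.index(eid)] = True

    # most likely = allowed candidate with minimal aggregate VS; taxonomy
    # order breaks ties because argmin returns the first minimum
    agg_cells = np.moveaxis(agg, 0, 2)  # (nr, nc, E)
    masked = np.where(candidate, agg_cells, np.inf)
    # riparian persistence cells carry inf everywhere except their own
    # column (inf too); replace their own column by 0 so argmin lands there
    own = candidate & ~np.isfinite(masked)
    masked[own] = 0.0
    best_idx = np.argmin(masked, axis=2)
    order_arr = np.array(order)
    most_likely = order_arr[best_idx]

    return ProjectionResult(landscape, order, candidate, most_likely, current_vs)
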