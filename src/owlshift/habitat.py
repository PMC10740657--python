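"""Species habitat profiles, habitat maps, change metrics and overlays.

A species' breeding habitat profile is a set of ERUs (the vegetation types
it breeds in) intersected with a set of model zones (biogeographic
constraint regions).  Rendering a profile against the current landscape
gives the current habitat map; rendering it against a 2090 projection
gives the projected map, either *inclusive* (a cell counts if any of its
candidate future types is in the profile — erring toward inclusion, the
default) or *most_likely* (only the single best future type counts).

Change metrics follow the published table conventions: extents in
hectares, percent change displayed rounded to the nearest multiple of 5
(ties away from zero) with the raw value retained, and projected habitat
decomposed into persisted + gained.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape, HabitatMap, buffer_mask, extent_ha
from .projection import ProjectionResult
from .synthetic import OccurrenceRecord, Territory
from .taxonomy import Taxonomy

__all__ = [
    "SpeciesProfile",
    "ChangeSummary",
    "TransitionMatrix",
    "CaptureCounts",
    "render_habitat",
    "change_summary",
    "round_to_nearest_5",
    "capture_records",
    "overlay_territories",
    "transition_matrix",
    "profile_retention",
    "thin_points",
    "load_species_profiles",
]


@dataclass(frozen=True)
class SpeciesProfile:
    """Breeding habitat profile of one species.

    ``zones_2090`` defaults to the current zone set; a species projected to
    expand northward gets extra 2090 zones.
    """

    species: str
    eru_ids: frozenset[str]
    zone_ids: frozenset[str]
    zone_ids_2090: frozenset[str] | None = None
    buffer_m: float = 1000.0

    def __post_init__(self) -> None:
        if not self.eru_ids:
            raise ValueError("profile ERU set must be non-empty")
        object.__setattr__(self, "eru_ids", frozenset(self.eru_ids))
        object.__setattr__(self, "zone_ids", frozenset(self.zone_ids))
        if self.zone_ids_2090 is not None:
            object.__setattr__(self, "zone_ids_2090",
                               frozenset(self.zone_ids_2090))

    @property
    def zones_2090(self) -> frozenset[str]:
        return self.zone_ids_2090 if self.zone_ids_2090 is not None else self.zone_ids

    def validate(self, landscape: Landscape, taxonomy: Taxonomy) -> None:
        bad = [e for e in self.eru_ids if e not in taxonomy]
        if bad:
            raise ValueError(f"profile {self.species!r}: unknown ERUs {bad}")
        zones = set(landscape.zone_ids_present())
        bad = [z for z in self.zone_ids | self.zones_2090 if z not in zones]
        if bad:
            raise ValueError(f"profile {self.species!r}: unknown zones {bad}")


def load_species_profiles(path=None, landscape: Landscape | None = None
                          ) -> dict[str, SpeciesProfile]:
    """Load profiles from CSV (default: the packaged eight-species table).

    Columns: species, eru_ids (``;``-separated), zones (``;``-separated or
    the token ``all``), zones_2090 (optional), buffer_m.  ``all`` resolves
    to every zone on ``landscape`` if given, else to the literal token and
    must be resolved before rendering.
    """
    import csv
    from importlib.resources import files

    all_zones = set(landscape.zone_ids_present()) if landscape is not None else None

    def _zones(tok: str):
        if tok.strip() == "all":
            if all_zones is None:
                raise ValueError("'all' zones need a landscape to resolve against")
            return frozenset(all_zones)
        return frozenset(z for z in tok.split(";") if z)

    if path is None:
        fh = (files("owlshift") / "data" / "species_profiles.csv").open(newline="")
    else:
        fh = open(path, newline="")
    with fh:
        out = {}
        for r in csv.DictReader(fh):
            z2090 = r.get("zones_2090", "").strip()
            out[r["species"]] = SpeciesProfile(
                species=r["species"],
                eru_ids=frozenset(r["eru_ids"].split(";")),
                zone_ids=_zones(r["zones"]),
                zone_ids_2090=_zones(z2090) if z2090 else None,
                buffer_m=float(r.get("buffer_m") or 1000.0),
            )
    return out


def render_habitat(profile: SpeciesProfile, landscape: Landscape,
                   projection: ProjectionResult | None = None,
                   mode: str = "inclusive") -> HabitatMap:
    """Render a profile to a habitat mask.

    Current habitat (no projection): cell is habitat iff its ERU is in the
    profile and its zone is in the current zone set.  Projected habitat:
    the 2090 zone set applies, and the cell is habitat iff any candidate
    future ERU (``inclusive``) or the most-likely future ERU
    (``most_likely``) is in the profile.
    """
    if mode not in {"inclusive", "most_likely"}:
        raise ValueError(f"mode must be 'inclusive' or 'most_likely', got {mode!r}")
    zones_present = set(landscape.zone_ids_present())
    if projection is None:
        zone_set = profile.zone_ids
    else:
        zone_set = profile.zones_2090
    unknown = zone_set - zones_present
    if unknown:
        raise ValueError(f"profile {profile.species!r}: zones {sorted(unknown)} "
                         "not on landscape")
    zmask = landscape.zone_mask(zone_set)
    if projection is None:
        veg = landscape.eru_mask(profile.eru_ids)
        return HabitatMap(landscape, veg & zmask, provenance="current")
    if projection.landscape is not landscape:
        if projection.landscape.shape != landscape.shape:
            raise ValueError("projection does not cover the landscape")
    if mode == "inclusive":
        veg = np.zeros(landscape.shape, dtype=bool)
        for eid in profile.eru_ids:
            if eid in projection.eru_order:
                veg |= projection.candidate_mask(eid)
    else:
        veg = np.isin(projection.most_likely, list(profile.eru_ids))
    return HabitatMap(landscape, veg & zmask, provenance="projected")


def round_to_nearest_5(x: float) -> int:
    """Round to the nearest multiple of 5, ties away from zero.

    This display rule reproduces every published rounded percent-change
    entry from its own extent pair.
    """
    return int(math.copysign(5 * math.floor(abs(x) / 5 + 0.5), x))


@dataclass(frozen=True)
class ChangeSummary:
    """Current-to-projected habitat change for one species (hectares)."""

    species: str
    current_ha: float
    projected_ha: float
    persisted_ha: float
    gained_ha: float
    lost_ha: float

    @property
    def pct_change_raw(self) -> float | None:
        if self.current_ha == 0:
            return None
        return 100.0 * (self.projected_ha - self.current_ha) / self.current_ha

    @property
    def pct_change_rounded(self) -> int | None:
        raw = self.pct_change_raw
        return None if raw is None else round_to_nearest_5(raw)


def change_summary(current: HabitatMap, projected: HabitatMap,
                   species: str = "") -> ChangeSummary:
    """Extent change between a current and a projected habitat map."""
    if current.landscape.shape != projected.landscape.shape:
        raise ValueError("maps must share a landscape")
    area = current.landscape.cell_area_ha
    cur, proj = current.mask, projected.mask
    return ChangeSummary(
        species=species,
        current_ha=float(cur.sum()) * area,
        projected_ha=float(proj.sum()) * area,
        persisted_ha=float((cur & proj).sum()) * area,
        gained_ha=float((~cur & proj).sum()) * area,
        lost_ha=float((cur & ~proj).sum()) * area,
    )


@dataclass(frozen=True)
class CaptureCounts:
    """Partition of occurrence records by the habitat map and its buffer."""

    within_model: int
    within_buffer_only: int
    outside: int

    @property
    def total(self) -> int:
        return self.within_model + self.within_buffer_only + self.outside


def capture_records(records: list[OccurrenceRecord], habitat: HabitatMap,
                    buffer_distance: float = 1000.0) -> CaptureCounts:
    """Count records inside the unbuffered mask, inside only the buffered
    mask, and outside both.  Off-landscape records count as outside (with a
    warning)."""
    if habitat.buffered:
        raise ValueError("pass the unbuffered habitat map")
    buffered = buffer_mask(habitat, buffer_distance)
    ls = habitat.landscape
    n_model = n_buf = n_out = 0
    n_off = 0
    for r in records:
        cell = ls.cell_of_point(r.x, r.y)
        if cell is None:
            n_off += 1
            n_out += 1
            continue
        if habitat.mask[cell]:
            n_model += 1
        elif buffered.mask[cell]:
            n_buf += 1
        else:
            n_out += 1
    if n_off:
        warnings.warn(f"{n_off} record(s) off the landscape counted as outside",
                      stacklevel=2)
    return CaptureCounts(n_model, n_buf, n_out)


def overlay_territories(territories: list[Territory], landscape: Landscape,
                        projection: ProjectionResult,
                        generalization: dict[str, str]) -> list[Territory]:
    """Fill each territory's current and projected generalized vegetation
    labels from the containing cell's ERU and most-likely 2090 ERU."""
    missing = [e for e in landscape.eru_ids_present() if e not in generalization]
    if missing:
        raise ValueError(f"generalization map lacks ERUs {missing}")
    off = [i for i, t in enumerate(territories)
           if landscape.cell_of_point(t.x, t.y) is None]
    if off:
        raise ValueError(f"territories off the landscape at indices {off}")
    out = []
    for t in territories:
        i, j = landscape.cell_of_point(t.x, t.y)
        out.append(Territory(
            species_id=t.species_id, x=t.x, y=t.y,
            current_label=generalization[landscape.eru[i, j]],
            projected_label=generalization[projection.most_likely[i, j]],
        ))
    return out


@dataclass
class TransitionMatrix:
    """Cross-tabulation of territories by (current, projected) vegetation.

    ``table`` is a counts DataFrame with current labels as rows and
    projected labels as columns.
    """

    table: pd.DataFrame

    @property
    def grand_total(self) -> int:
        return int(self.table.values.sum())

    def row_totals(self) -> pd.Series:
        return self.table.sum(axis=1)

    def column_totals(self) -> pd.Series:
        return self.table.sum(axis=0)

    def with_totals(self) -> pd.DataFrame:
        out = self.table.copy()
        out["Total"] = out.sum(axis=1)
        out.loc["Total"] = out.sum(axis=0)
        return out


def transition_matrix(territories: list[Territory]) -> TransitionMatrix:
    """Cross-tabulate labelled territories into a transition matrix."""
    for t in territories:
        if t.current_label is None or t.projected_label is None:
            raise ValueError("territory labels must be filled first")
    df = pd.DataFrame({
        "current": [t.current_label for t in territories],
        "projected": [t.projected_label for t in territories],
    })
    table = pd.crosstab(df["current"], df["projected"])
    table.index.name = "current"
    table.columns.name = "projected"
    return TransitionMatrix(table)


def profile_retention(matrix: TransitionMatrix, profile_labels: set[str],
                      query_labels: set[str] | None = None
                      ) -> tuple[float | None, float | None, float | None]:
    """Territory retention percentages relative to a habitat profile.

    Returns ``(pct_currently_in_profile, pct_remaining_in_profile,
    pct_of_current_moving_to_query)`` where the first two are out of all
    territories and the third (None if no query) is out of the territories
    currently in profile.  Zero denominators yield None.
    """
    t = matrix.table
    unknown = profile_labels - set(t.index) - set(t.columns)
    if unknown:
        raise ValueError(f"profile labels not in matrix: {sorted(unknown)}")
    grand = matrix.grand_total
    rows_in = [r for r in t.index if r in profile_labels]
    cols_in = [c for c in t.columns if c in profile_labels]
    n_current = int(t.loc[rows_in].values.sum()) if rows_in else 0
    n_remain = int(t.loc[rows_in, cols_in].values.sum()) if rows_in and cols_in else 0
    pct_current = 100.0 * n_current / grand if grand else None
    pct_remain = 100.0 * n_remain / grand if grand else None
    pct_query = None
    if query_labels is not None:
        cols_q = [c for c in t.columns if c in query_labels]
        n_q = int(t.loc[rows_in, cols_q].values.sum()) if rows_in and cols_q else 0
        pct_query = 100.0 * n_q / n_current if n_current else None
    return pct_current, pct_remain, pct_query


def thin_points(points: list[tuple[float, float]],
                min_separation: float = 250.0) -> list[int]:
    """Greedy spatial thinning: indices of points kept so that no two kept
    points are closer than ``min_separation`` metres (non-overlapping discs
    of that diameter).  Processes points in input order, so the result is
    order-dependent; used to turn clustered detections into approximately
    independent samples of habitat use."""
    kept: list[int] = []
    for i, (x, y) in enumerate(points):
        ok = all((x - points[k][0]) ** 2 + (y - points[k][1]) ** 2
                 >= min_separation ** 2 for k in kept)
        if ok:
            kept.append(i)
    return kept
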