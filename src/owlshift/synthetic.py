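"""Synthetic landscapes, climate surfaces, envelopes, occurrences, territories.

The generator emulates the structure the analysis assumes without any real
geodata: a smooth elevation surface (base plane plus seeded Gaussian
hills), vegetation types arranged in elevation bands (desert and grassland
low, woodland and forest mid to high, alpine on the summits), a narrow
riparian corridor threaded through the valleys, model zones as vertical
slabs, and climate variables that vary linearly with elevation (a lapse
rate per variable) plus seeded spatial noise.

Warming is parameterized as *equivalent uplift* in metres: the warmed 2090
value of every variable at elevation h equals its unwarmed value at
elevation h − Δ, so one knob moves all variables coherently through their
lapse rates and directly expresses the upslope-shift hypothesis.

Everything is deterministic under the config seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .landscape import Landscape, HabitatMap, buffer_mask
from .projection import ClimateEnvelope
from .taxonomy import Taxonomy, default_taxonomy

__all__ = [
    "SyntheticConfig",
    "OccurrenceParams",
    "OccurrenceRecord",
    "Territory",
    "generate_landscape",
    "generate_climate",
    "fit_envelopes",
    "generate_occurrences",
    "generate_territories",
    "territory_transition_fixture",
    "published_capture_counts",
    "published_regional_extents",
]

#: Default elevation bands, metres: ERU id -> [low, high).  Contiguous and
#: covering the generated elevation range; ordered desert -> alpine.
DEFAULT_BANDS: tuple[tuple[str, float, float], ...] = (
    ("CDS", 700.0, 950.0),     # Chihuahuan desert scrub
    ("IMSS", 950.0, 1150.0),   # intermountain salt scrub (basin shrubland)
    ("CPGB", 1150.0, 1400.0),  # Colorado Plateau / Great Basin grassland
    ("GAMB", 1400.0, 1600.0),  # Gambel oak shrubland
    ("JUG", 1600.0, 1780.0),   # juniper grass
    ("PJW", 1780.0, 2020.0),   # pinyon-juniper woodland
    ("PPF", 2020.0, 2270.0),   # ponderosa pine forest
    ("MCFF", 2270.0, 2520.0),  # mixed conifer, frequent fires
    ("MCA", 2520.0, 2770.0),   # mixed conifer with aspen
    ("SFF", 2770.0, 3020.0),   # spruce-fir forest
    ("BPF", 3020.0, 3270.0),   # bristlecone pine forest (treeline belt)
    ("ALP", 3270.0, 3520.0),   # alpine tundra
)

#: Placeholder climate variables.  The real envelope set is five variables
#: chosen to optimize class separation (one example being the Julian date
#: at which growing degree-days >5 C reach 100); here they are generic
#: elevation-driven surrogates with distinct lapse rates and units.
DEFAULT_VARIABLES: tuple[str, ...] = ("var1", "var2", "var3", "var4", "var5")
DEFAULT_LAPSE: tuple[float, ...] = (0.04, -0.0065, 0.5, -0.01, 0.02)
DEFAULT_INTERCEPT: tuple[float, ...] = (60.0, 28.0, 200.0, 40.0, 5.0)


@dataclass(frozen=True)
class OccurrenceParams:
    """Occurrence/territory generator knobs.

    ``commission_fraction`` of points are placed off-profile (riparian or
    other non-habitat cells, preferentially within 1 km of habitat),
    mirroring the finding that most off-model records sit in riparian
    corridors nestled within the woodlands and forests.
    """

    n_points: int = 100
    commission_fraction: float = 0.15
    riparian_share: float = 0.6
    positional_error_sd_m: float = 50.0


@dataclass(frozen=True)
class SyntheticConfig:
    """Full configuration of the synthetic world.

    The defaults are the study conditions every test and example runs
    under: a 200 x 200 grid of 100 m cells (40,000 ha), elevation
    700-3520 m in twelve vegetation bands of at most 250 m width, five
    climate variables, and a 300 m equivalent-uplift warming offset for
    2090 (about the regional ~15 m/decade observed upslope vegetation
    shift compounded over a century).  The inter-annual SD is expressed as
    175 m of elevation equivalent per variable, chosen so that an
    envelope's 2-SD admission window (350 m) always exceeds the maximum
    possible within-ERU climate spread — band width (250 m) plus ecotone
    jitter (2 x 25 m) plus truncated noise (2 x 16 m) — which makes the
    zero-warming recovery identity hold by construction.
    """

    nrows: int = 200
    ncols: int = 200
    cell_size: float = 100.0
    seed: int = 0
    bands: tuple[tuple[str, float, float], ...] = DEFAULT_BANDS
    n_hills: int = 12
    base_relief_weight: float = 0.35
    relief_skew: float = 2.0
    variables: tuple[str, ...] = DEFAULT_VARIABLES
    lapse: tuple[float, ...] = DEFAULT_LAPSE
    intercept: tuple[float, ...] = DEFAULT_INTERCEPT
    interannual_sd_equiv_m: float = 175.0
    noise_sd_equiv_m: float = 4.0
    warming_offset_m: float = 300.0
    edge_jitter_fraction: float = 0.3
    jitter_margin_m: float = 25.0
    n_zones: int = 4
    riparian_corridor: bool = True
    riparian_max_elev_m: float = 2600.0
    occurrence: OccurrenceParams = field(default_factory=OccurrenceParams)

    def __post_init__(self) -> None:
        if len(self.variables) != len(self.lapse) or len(self.variables) != len(
                self.intercept):
            raise ValueError("variables, lapse and intercept lengths differ")
        for k in range(len(self.bands) - 1):
            if self.bands[k][2] != self.bands[k + 1][1]:
                raise ValueError("elevation bands must be contiguous and "
                                 "non-overlapping")
        if any(lo >= hi for _, lo, hi in self.bands):
            raise ValueError("every band must have low < high")

    @property
    def elev_min(self) -> float:
        return self.bands[0][1]

    @property
    def elev_max(self) -> float:
        return self.bands[-1][2]

    def interannual_sd(self) -> dict[str, float]:
        """Per-variable inter-annual SD s (config input, not estimated)."""
        return {v: abs(l) * self.interannual_sd_equiv_m
                for v, l in zip(self.variables, self.lapse)}


@dataclass
class OccurrenceRecord:
    """One georeferenced occurrence (museum, iNaturalist or survey point)."""

    species_id: str
    x: float
    y: float
    source: str = "survey"
    precision_m: float = 100.0

    def __post_init__(self) -> None:
        # records coarser than 1 km are excluded upstream and never emitted
        if self.precision_m > 1000.0:
            raise ValueError("record precision must be <= 1000 m")


@dataclass
class Territory:
    """One breeding territory with (optionally filled) vegetation labels."""

    species_id: str
    x: float = math.nan
    y: float = math.nan
    current_label: str | None = None
    projected_label: str | None = None


# ---------------------------------------------------------------------------
# landscape


def _elevation_surface(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    i, j = np.mgrid[0:cfg.nrows, 0:cfg.ncols]
    base = j / max(cfg.ncols - 1, 1)
    hills = np.zeros((cfg.nrows, cfg.ncols))
    for _ in range(cfg.n_hills):
        cy = rng.uniform(0, cfg.nrows)
        cx = rng.uniform(0, cfg.ncols)
        sigma = rng.uniform(0.08, 0.20) * max(cfg.nrows, cfg.ncols)
        amp = rng.uniform(0.3, 1.0)
        hills += amp * np.exp(-(((i - cy) ** 2 + (j - cx) ** 2) / (2 * sigma ** 2)))
    if hills.max() > 0:
        hills = hills / hills.max()
    raw = cfg.base_relief_weight * base + (1 - cfg.base_relief_weight) * hills
    lo, hi = raw.min(), raw.max()
    u = (raw - lo) / (hi - lo)
    # hypsometric skew: montane terrain has broad basins and scarce summits,
    # so cell area should decay with elevation (exponent > 1 pushes mass low)
    u = u ** cfg.relief_skew
    span = cfg.elev_max - cfg.elev_min
    # keep strictly below the top band edge so every cell falls in a band
    return cfg.elev_min + u * (span - 0.1)


def generate_landscape(config: SyntheticConfig,
                       taxonomy: Taxonomy | None = None) -> Landscape:
    """Generate the banded synthetic landscape (deterministic per seed).

    Each cell's ERU is the elevation band containing it; a seeded fraction
    of cells within ``jitter_margin_m`` of a band boundary is flipped to
    the band across that boundary (fuzzy ecotones); a riparian corridor is
    threaded along a sinuous valley line below ``riparian_max_elev_m``;
    model zones are ``n_zones`` vertical slabs ``Z1..Zn``.
    """
    taxonomy = taxonomy or default_taxonomy()
    for eid, _, _ in config.bands:
        if eid not in taxonomy:
            raise ValueError(f"band ERU {eid!r} not in taxonomy")
    rng = np.random.default_rng([config.seed, 1])
    elev = _elevation_surface(config, rng)
    if elev.min() < config.elev_min or elev.max() >= config.elev_max:
        raise ValueError("elevation bands do not cover the generated range")

    edges = np.array([b[1] for b in config.bands] + [config.bands[-1][2]])
    band_ids = np.array([b[0] for b in config.bands])
    idx = np.searchsorted(edges, elev, side="right") - 1

    # fuzzy ecotones: jitter a fraction of near-boundary cells across it
    if config.edge_jitter_fraction > 0:
        u = rng.random(elev.shape)
        for b, edge in enumerate(edges[1:-1], start=1):
            near = np.abs(elev - edge) <= config.jitter_margin_m
            flip = near & (u < config.edge_jitter_fraction)
            below = flip & (idx == b - 1)
            above = flip & (idx == b)
            idx[below] = b
            idx[above] = b - 1
    eru = band_ids[idx]

    if config.riparian_corridor:
        rows = np.arange(config.nrows)
        phase = rng.uniform(0, 2 * np.pi)
        center = (config.ncols / 2
                  + 0.3 * config.ncols * np.sin(2 * np.pi * rows / config.nrows
                                                + phase))
        cols = np.clip(np.round(center).astype(int), 0, config.ncols - 1)
        stream = np.zeros(elev.shape, dtype=bool)
        stream[rows, cols] = True
        stream &= elev < config.riparian_max_elev_m
        eru = eru.copy()
        eru[stream] = "RIP"

    zone_idx = (np.arange(config.ncols) * config.n_zones) // config.ncols
    zone_row = np.array([f"Z{z + 1}" for z in zone_idx])
    zone = np.tile(zone_row, (config.nrows, 1))

    return Landscape(eru=eru, zone=zone, elevation=elev,
                     cell_size=config.cell_size)


# ---------------------------------------------------------------------------
# climate


def generate_climate(landscape: Landscape, config: SyntheticConfig,
                     warmed: bool = False) -> dict[str, np.ndarray]:
    """Per-cell surfaces of each climate variable.

    Unwarmed: ``v = intercept_v + lapse_v * (elev + noise)``.  Warmed: the
    same with ``elev`` replaced by ``elev − warming_offset_m`` (climate
    moves upslope).  The noise field depends only on the seed, not on
    ``warmed``, so a zero offset reproduces the unwarmed surfaces exactly.
    Noise is Gaussian in elevation-equivalent metres, truncated at +-4 SD
    so departures from band climatology are bounded.
    """
    rng = np.random.default_rng([config.seed, 2])
    eff = landscape.elevation - (config.warming_offset_m if warmed else 0.0)
    out: dict[str, np.ndarray] = {}
    for v, lapse, intercept in zip(config.variables, config.lapse,
                                   config.intercept):
        if config.noise_sd_equiv_m > 0:
            noise = rng.normal(0.0, config.noise_sd_equiv_m, landscape.shape)
            noise = np.clip(noise, -4 * config.noise_sd_equiv_m,
                            4 * config.noise_sd_equiv_m)
        else:
            noise = 0.0
        out[v] = intercept + lapse * (eff + noise)
    return out


def fit_envelopes(landscape: Landscape,
                  climate: dict[str, np.ndarray],
                  interannual_sd: dict[str, float],
                  eru_ids: list[str] | None = None,
                  taxonomy: Taxonomy | None = None) -> list[ClimateEnvelope]:
    """Fit per-ERU climate envelopes from unwarmed surfaces.

    x̄ is the spatial mean of each variable over the ERU's cells; s is the
    configured *inter-annual* SD (no time series exists in the synthetic
    world, so s is an input, not an estimate).  Riparian ERUs get no
    envelope (not modelable); requested ERUs with zero cells are excluded
    with a warning.
    """
    taxonomy = taxonomy or default_taxonomy()
    variables = list(climate)
    for v in variables:
        if v not in interannual_sd:
            raise ValueError(f"no inter-annual SD configured for {v!r}")
        if interannual_sd[v] <= 0:
            raise ValueError(f"inter-annual SD for {v!r} must be > 0")
    if eru_ids is None:
        eru_ids = [e for e in landscape.eru_ids_present()
                   if taxonomy[e].zone != "riparian"]
    envelopes = []
    for eid in eru_ids:
        here = landscape.eru == eid
        if not here.any():
            warnings.warn(f"ERU {eid!r} has no cells; excluded from envelopes",
                          stacklevel=2)
            continue
        means = tuple(float(climate[v][here].mean()) for v in variables)
        sds = tuple(float(interannual_sd[v]) for v in variables)
        envelopes.append(ClimateEnvelope(eid, tuple(variables), means, sds))
    return envelopes


# ---------------------------------------------------------------------------
# occurrences and territories


def _cell_center_xy(i: np.ndarray, j: np.ndarray, cs: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    # uniform position within each chosen cell
    x = j * cs + rng.uniform(-cs / 2, cs / 2, size=np.shape(i))
    y = i * cs + rng.uniform(-cs / 2, cs / 2, size=np.shape(i))
    return x, y


def _commission_cells(habitat: HabitatMap, landscape: Landscape,
                      taxonomy: Taxonomy) -> tuple[np.ndarray, np.ndarray]:
    """(riparian, other) candidate cells for commission points: non-habitat
    cells preferentially within 1 km of habitat."""
    near = buffer_mask(habitat, 1000.0).mask & ~habitat.mask
    rip = np.isin(landscape.eru,
                  [e.id for e in taxonomy if e.zone == "riparian"])
    rip_near = near & rip
    other_near = near & ~rip
    if not near.any():  # fall back to anywhere off-habitat
        off = ~habitat.mask
        rip_near = off & rip
        other_near = off & ~rip
    return rip_near, other_near


def generate_occurrences(profile, habitat: HabitatMap, landscape: Landscape,
                         config: SyntheticConfig,
                         taxonomy: Taxonomy | None = None) -> list[OccurrenceRecord]:
    """Seeded occurrence records for one species.

    ``(1 − commission) · n`` points fall uniformly over habitat cells; the
    rest fall in riparian (with probability ``riparian_share``) or other
    non-habitat cells near habitat.  Gaussian positional error is applied
    to every point.
    """
    taxonomy = taxonomy or default_taxonomy()
    p = config.occurrence
    if p.n_points <= 0:
        raise ValueError("n_points must be >= 1")
    if not habitat.mask.any():
        raise ValueError("habitat mask is empty")
    rng = np.random.default_rng([config.seed, 3])
    cs = landscape.cell_size
    n_comm = int(round(p.commission_fraction * p.n_points))
    n_hab = p.n_points - n_comm

    pts = []
    hi, hj = np.nonzero(habitat.mask)
    if n_hab:
        pick = rng.integers(0, len(hi), size=n_hab)
        x, y = _cell_center_xy(hi[pick], hj[pick], cs, rng)
        pts.append((x, y))
    if n_comm:
        rip_near, other_near = _commission_cells(habitat, landscape, taxonomy)
        ri, rj = np.nonzero(rip_near)
        oi, oj = np.nonzero(other_near)
        xs, ys = [], []
        for _ in range(n_comm):
            use_rip = len(ri) > 0 and (len(oi) == 0
                                       or rng.random() < p.riparian_share)
            ii, jj = (ri, rj) if use_rip else (oi, oj)
            k = rng.integers(0, len(ii))
            x, y = _cell_center_xy(np.array([ii[k]]), np.array([jj[k]]), cs, rng)
            xs.append(x[0]); ys.append(y[0])
        pts.append((np.array(xs), np.array(ys)))

    species = getattr(profile, "species", str(profile))
    records = []
    sources = ("museum", "inaturalist", "survey")
    for x, y in pts:
        if p.positional_error_sd_m > 0:
            x = x + rng.normal(0, p.positional_error_sd_m, size=x.shape)
            y = y + rng.normal(0, p.positional_error_sd_m, size=y.shape)
        for xi, yi in zip(x, y):
            records.append(OccurrenceRecord(
                species_id=species, x=float(xi), y=float(yi),
                source=sources[rng.integers(0, 3)],
                precision_m=float(rng.choice([10.0, 100.0, 500.0]))))
    return records


def generate_territories(profile, habitat: HabitatMap, landscape: Landscape,
                         config: SyntheticConfig, n: int = 148,
                         taxonomy: Taxonomy | None = None) -> list[Territory]:
    """Seeded breeding territories: like occurrences but without positional
    error (territory centres are mapped accurately) and returned as
    :class:`Territory` with labels unfilled."""
    occ = replace(config, occurrence=replace(
        config.occurrence, n_points=n, positional_error_sd_m=0.0))
    recs = generate_occurrences(profile, habitat, landscape, occ, taxonomy)
    species = getattr(profile, "species", str(profile))
    return [Territory(species_id=species, x=r.x, y=r.y) for r in recs]


# ---------------------------------------------------------------------------
# packaged fixtures


def _read_packaged_csv(name: str):
    import csv
    from importlib.resources import files

    with (files("owlshift") / "data" / name).open(newline="") as fh:
        return list(csv.DictReader(fh))


def territory_transition_fixture(species_id: str = "flammulated_owl") -> list[Territory]:
    """The 148-territory current/projected vegetation transition fixture.

    Expands the packaged transition-count table into one labelled
    :class:`Territory` per count, so cross-tabulating them reproduces the
    printed matrix and its marginals exactly.  Territories carry no
    coordinates (the fixture is a label table, not a map).
    """
    rows = _read_packaged_csv("territory_transitions.csv")
    out = []
    for r in rows:
        for _ in range(int(r["count"])):
            out.append(Territory(species_id=species_id,
                                 current_label=r["current"],
                                 projected_label=r["projected"]))
    return out


def published_capture_counts():
    """Packaged per-species capture/simulation count summaries (list of
    dicts with integer fields)."""
    rows = _read_packaged_csv("capture_counts.csv")
    for r in rows:
        for k in r:
            if k != "species":
                r[k] = int(r[k])
    return rows


def published_regional_extents():
    """Packaged per-species current/projected regional extents (hectares)
    with the published rounded percent change."""
    rows = _read_packaged_csv("regional_extents.csv")
    for r in rows:
        r["current_ha"] = float(r["current_ha"])
        r["projected_ha"] = float(r["projected_ha"])
        r["published_pct_change"] = int(r["published_pct_change"])
    return rows
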