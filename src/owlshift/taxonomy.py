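"""Vegetation taxonomy: Ecological Response Units (ERUs) and life zones.

An ERU is a mapped vegetation/ecosystem type similar in vegetation
potential, plant dominants, fire regime, and succession.  ERUs are the unit
of habitat composition throughout this package: species habitat profiles
are sets of ERUs, climate envelopes are fitted per ERU, and vegetation-type
projection moves cells between ERUs.

The default taxonomy covers the foothill and mountain vegetation of the
Southwestern US (Arizona / New Mexico): two subalpine, four montane and
eight woodland forest types, plus grassland, shrubland, riparian, desert
and alpine classes needed as transition targets.  Riparian types exist in
the taxonomy but are never produced by climate-envelope projection (they
are controlled by hydrology, not the regional climate envelope).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "ZONES",
    "FOREST_WOODLAND_ZONES",
    "ERUClass",
    "Taxonomy",
    "default_taxonomy",
    "default_generalization",
    "GENERAL_LABELS",
]

ZONES = (
    "subalpine",
    "montane",
    "woodland",
    "shrubland",
    "grassland",
    "riparian",
    "desert",
    "alpine",
)

#: Life zones whose ERUs count as forest or woodland.
FOREST_WOODLAND_ZONES = frozenset({"subalpine", "montane", "woodland"})

_LIFEFORMS = ("tree", "shrub", "herb")


@dataclass(frozen=True)
class ERUClass:
    """One Ecological Response Unit (vegetation type).

    Parameters
    ----------
    id : str
        Short stable key (e.g. ``"PPF"``).
    name : str
        Display name.
    zone : str
        Life zone, one of :data:`ZONES`.
    lifeform : str
        Dominant lifeform: ``"tree"``, ``"shrub"`` or ``"herb"``.
    is_forest_or_woodland : bool
        Whether the type counts as forest/woodland habitat.  Derived from
        the zone and validated on construction.
    """

    id: str
    name: str
    zone: str
    lifeform: str
    is_forest_or_woodland: bool

    def __post_init__(self) -> None:
        if self.zone not in ZONES:
            raise ValueError(f"unknown zone {self.zone!r} for ERU {self.id!r}")
        if self.lifeform not in _LIFEFORMS:
            raise ValueError(f"unknown lifeform {self.lifeform!r} for ERU {self.id!r}")
        if self.zone in FOREST_WOODLAND_ZONES and not self.is_forest_or_woodland:
            raise ValueError(
                f"ERU {self.id!r}: zone {self.zone!r} implies forest/woodland"
            )
        if self.zone in {"shrubland", "grassland", "desert", "alpine"} and (
            self.is_forest_or_woodland
        ):
            raise ValueError(
                f"ERU {self.id!r}: zone {self.zone!r} cannot be forest/woodland"
            )

    @property
    def is_shrub_type(self) -> bool:
        return self.lifeform == "shrub"


class Taxonomy:
    """Ordered collection of :class:`ERUClass` keyed by id.

    Iteration order is the order of definition; this order is the
    deterministic tie-break used when projection has to pick one of several
    equally plausible future types.
    """

    def __init__(self, erus: list[ERUClass]):
        self._erus: dict[str, ERUClass] = {}
        for e in erus:
            if e.id in self._erus:
                raise ValueError(f"duplicate ERU id {e.id!r}")
            self._erus[e.id] = e

    def __getitem__(self, eru_id: str) -> ERUClass:
        try:
            return self._erus[eru_id]
        except KeyError:
            raise KeyError(f"unknown ERU id {eru_id!r}") from None

    def __contains__(self, eru_id: str) -> bool:
        return eru_id in self._erus

    def __iter__(self):
        return iter(self._erus.values())

    def __len__(self) -> int:
        return len(self._erus)

    @property
    def ids(self) -> list[str]:
        return list(self._erus)

    def order_index(self, eru_id: str) -> int:
        """Position of an ERU in taxonomy order (tie-break key)."""
        return self.ids.index(eru_id)

    def subset_ids(self, *, zones: set[str] | None = None,
                   forest_or_woodland: bool | None = None) -> list[str]:
        out = []
        for e in self:
            if zones is not None and e.zone not in zones:
                continue
            if (forest_or_woodland is not None
                    and e.is_forest_or_woodland != forest_or_woodland):
                continue
            out.append(e.id)
        return out


def _eru(id_, name, zone, lifeform):
    return ERUClass(id_, name, zone, lifeform,
                    is_forest_or_woodland=zone in FOREST_WOODLAND_ZONES)


def default_taxonomy() -> Taxonomy:
    """The default Southwestern US foothill/mountain ERU taxonomy.

    Contains every subalpine, montane and woodland ERU of the regional
    classification, plus grassland, shrubland, riparian, desert and alpine
    classes so that downslope transitions have somewhere to go.  Desert
    scrub types are carried with lifeform ``"herb"`` as a simplification:
    in this taxonomy the shrub lifeform marks exactly the upland-shrubland
    classes that the shrub transition rule applies to.
    """
    return Taxonomy([
        # subalpine zone
        _eru("SFF", "Spruce-fir forest", "subalpine", "tree"),
        _eru("BPF", "Bristlecone pine forest", "subalpine", "tree"),
        # montane zone
        _eru("MCA", "Mixed conifer with aspen", "montane", "tree"),
        _eru("MCFF", "Mixed conifer - frequent fires", "montane", "tree"),
        _eru("PPF", "Ponderosa pine forest", "montane", "tree"),
        _eru("PPE", "Ponderosa pine - evergreen oak forest", "montane", "tree"),
        # woodland zone
        _eru("PJW", "Pinyon-juniper woodland", "woodland", "tree"),
        _eru("MPO", "Madrean pinyon-oak woodland", "woodland", "tree"),
        _eru("MEW", "Madrean encinal woodland", "woodland", "tree"),
        _eru("PJS", "Pinyon-juniper sagebrush", "woodland", "tree"),
        _eru("PJES", "Pinyon-juniper evergreen shrub", "woodland", "tree"),
        _eru("PJDS", "Pinyon-juniper deciduous shrub", "woodland", "tree"),
        _eru("PJG", "Pinyon-juniper grass", "woodland", "tree"),
        _eru("JUG", "Juniper grass", "woodland", "tree"),
        # transition-target classes
        _eru("CPGB", "Colorado Plateau / Great Basin grassland", "grassland", "herb"),
        _eru("MSG", "Montane / subalpine grassland", "grassland", "herb"),
        _eru("GAMB", "Gambel oak shrubland", "shrubland", "shrub"),
        _eru("SAGE", "Sagebrush shrubland", "shrubland", "shrub"),
        _eru("IMSS", "Intermountain salt scrub", "shrubland", "shrub"),
        _eru("RIP", "Riparian woodland/shrubland", "riparian", "tree"),
        _eru("CDS", "Chihuahuan desert scrub", "desert", "herb"),
        _eru("ALP", "Alpine tundra", "alpine", "herb"),
    ])


#: Generalized vegetation vocabulary used for territory overlays.
GENERAL_LABELS = (
    "Dry Forest",
    "Mixed Conifer with Aspen",
    "Pinyon-Juniper",
    "Madrean Woodland",
    "Riparian",
    "Upland Shrub",
    "Gambel Oak Shrubland",
    "Spruce-Fir Forest",
    "Grassland",
    "Desert Scrub",
    "Alpine",
)


def default_generalization() -> dict[str, str]:
    """Map every default ERU id to its generalized vegetation label.

    Dry forest pools ponderosa pine, ponderosa pine-evergreen oak and
    frequent-fire mixed conifer; mixed conifer with aspen stays on its own;
    all pinyon-juniper and juniper types pool to "Pinyon-Juniper"; the two
    Madrean woodland types pool to "Madrean Woodland".
    """
    return {
        "PPF": "Dry Forest",
        "PPE": "Dry Forest",
        "MCFF": "Dry Forest",
        "MCA": "Mixed Conifer with Aspen",
        "PJW": "Pinyon-Juniper",
        "PJS": "Pinyon-Juniper",
        "PJES": "Pinyon-Juniper",
        "PJDS": "Pinyon-Juniper",
        "PJG": "Pinyon-Juniper",
        "JUG": "Pinyon-Juniper",
        "MPO": "Madrean Woodland",
        "MEW": "Madrean Woodland",
        "RIP": "Riparian",
        "SAGE": "Upland Shrub",
        "IMSS": "Upland Shrub",
        "GAMB": "Gambel Oak Shrubland",
        "SFF": "Spruce-Fir Forest",
        "BPF": "Spruce-Fir Forest",
        "CPGB": "Grassland",
        "MSG": "Grassland",
        "CDS": "Desert Scrub",
        "ALP": "Alpine",
    }
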