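"""Geographic strata: named wintering (breeding) and summer (feeding) regions.

A stratum is a named spatial region classed as ``winter`` or ``summer``.
Summer (feeding) strata lie north of a dividing latitude (default 32°N) and
winter (breeding) strata south of it, reflecting the latitudinal segregation
of feeding and breeding habitat in a migratory baleen whale population.

Extents are lists of latitude/longitude boxes (the default basin-scale
stratification) or arbitrary polygons.  Longitudes use the −180…180
convention; a box whose ``lon_min`` exceeds its ``lon_max`` wraps across the
antimeridian.  Polygons must be supplied already split at the seam.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import yaml

from .errors import ValidationError

WINTER = "winter"
SUMMER = "summer"
SEASONS = (WINTER, SUMMER)

DEFAULT_SPLIT_LATITUDE = 32.0


@dataclass(frozen=True)
class LatLonBox:
    """Closed lat/lon box; wraps the antimeridian when lon_min > lon_max."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float

    def __post_init__(self) -> None:
        if not (-90.0 <= self.lat_min <= self.lat_max <= 90.0):
            raise ValidationError(f"invalid latitude range: {self}")
        for lon in (self.lon_min, self.lon_max):
            if not -180.0 <= lon <= 180.0:
                raise ValidationError(f"longitude out of [-180, 180]: {self}")

    @property
    def wraps(self) -> bool:
        return self.lon_min > self.lon_max

    def contains(self, lat: float, lon: float) -> bool:
        if not self.lat_min <= lat <= self.lat_max:
            return False
        if self.wraps:
            return lon >= self.lon_min or lon <= self.lon_max
        return self.lon_min <= lon <= self.lon_max


@dataclass(frozen=True)
class StratumDef:
    """A named stratum with a season class and a spatial extent.

    ``boxes`` and ``polygon`` are alternative extent encodings; at least one
    must be non-empty.  ``polygon`` is a sequence of (lat, lon) vertices and
    is tested with shapely.
    """

    name: str
    season_class: str
    boxes: tuple[LatLonBox, ...] = ()
    polygon: tuple[tuple[float, float], ...] = ()
    _shape: object = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("stratum name must be non-empty")
        if self.season_class not in SEASONS:
            raise ValidationError(
                f"stratum {self.name!r}: season_class must be one of {SEASONS}"
            )
        if not self.boxes and not self.polygon:
            raise ValidationError(f"stratum {self.name!r} has an empty extent")
        if self.polygon:
            from shapely.geometry import Polygon

            poly = Polygon([(lon, lat) for lat, lon in self.polygon])
            if poly.is_empty or not poly.is_valid:
                raise ValidationError(f"stratum {self.name!r}: invalid polygon")
            object.__setattr__(self, "_shape", poly)

    def contains(self, lat: float, lon: float) -> bool:
        if any(b.contains(lat, lon) for b in self.boxes):
            return True
        if self._shape is not None:
            from shapely.geometry import Point

            return bool(self._shape.covers(Point(lon, lat)))
        return False

    def lat_bounds(self) -> tuple[float, float]:
        lats = [b.lat_min for b in self.boxes] + [p[0] for p in self.polygon]
        lats_hi = [b.lat_max for b in self.boxes] + [p[0] for p in self.polygon]
        return min(lats), max(lats_hi)


@dataclass(frozen=True)
class StrataConfig:
    """An ordered collection of strata plus the winter/summer split latitude.

    Order matters: when extents touch, the first stratum containing a point
    wins, making assignment deterministic.
    """

    strata: tuple[StratumDef, ...]
    split_latitude: float = DEFAULT_SPLIT_LATITUDE

    def __post_init__(self) -> None:
        names = [s.name for s in self.strata]
        if len(names) != len(set(names)):
            raise ValidationError("stratum names must be unique")
        for s in self.strata:
            lo, hi = s.lat_bounds()
            if s.season_class == SUMMER and lo < self.split_latitude:
                raise ValidationError(
                    f"summer stratum {s.name!r} extends south of "
                    f"{self.split_latitude}°N"
                )
            if s.season_class == WINTER and hi > self.split_latitude:
                raise ValidationError(
                    f"winter stratum {s.name!r} extends north of "
                    f"{self.split_latitude}°N"
                )

    def __iter__(self):
        return iter(self.strata)

    def names(self, season_class: str | None = None) -> list[str]:
        return [
            s.name
            for s in self.strata
            if season_class is None or s.season_class == season_class
        ]

    def get(self, name: str) -> StratumDef:
        for s in self.strata:
            if s.name == name:
                return s
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return name in self.names()

    def season_class_of(self, name: str) -> str:
        return self.get(name).season_class

    def locate(self, lat: float, lon: float) -> StratumDef | None:
        """First stratum containing the point, or None."""
        for s in self.strata:
            if s.contains(lat, lon):
                return s
        return None


def _box(lat_min, lat_max, lon_min, lon_max) -> tuple[LatLonBox, ...]:
    return (LatLonBox(lat_min, lat_max, lon_min, lon_max),)


def default_strata() -> StrataConfig:
    """Basin-scale default stratification: 7 feeding, 6 breeding regions.

    Boxes are coarse rectangles approximating the commonly used North Pacific
    regions (Kamchatka, western and eastern/northern Bering Sea, Gulf of
    Alaska, southeast Alaska/northern British Columbia, southern British
    Columbia/Washington, California/Oregon; western Pacific, Hawai'i, Baja
    California, Revillagigedo Islands, Mainland Mexico, Central America and
    southern Mexico).  They are intended for synthetic data and coarse
    assignment; supply exact survey polygons for real analyses.
    """
    strata = (
        # summer (feeding) strata, north of 32°N, west to east
        StratumDef("Kamchatka", SUMMER, _box(48, 62, 150, 166)),
        StratumDef("WBerSea", SUMMER, _box(48, 62, 166, 180)),
        StratumDef("ENBerSea", SUMMER, _box(52, 70, -180, -157)),
        StratumDef("GulfOfAK", SUMMER, _box(52, 62, -157, -136)),
        StratumDef("SEAKNBC", SUMMER, _box(50.5, 60, -136, -125)),
        StratumDef("SBCWA", SUMMER, _box(46, 50.5, -128, -121)),
        StratumDef("CAOR", SUMMER, _box(32, 46, -126, -115)),
        # winter (breeding) strata, south of 32°N, west to east
        StratumDef("WPac", WINTER, _box(10, 32, 120, 160)),
        StratumDef("Hawaii", WINTER, _box(15, 26, -163, -152)),
        StratumDef("MexBajaCal", WINTER, _box(23, 32, -118, -109.5)),
        StratumDef("MexIsl", WINTER, _box(17, 20.5, -115, -110)),
        StratumDef("MexMld", WINTER, _box(15.5, 23, -109.5, -103)),
        StratumDef("CenAmSMex", WINTER, _box(5, 15.5, -104, -77)),
    )
    return StrataConfig(strata=strata)


def load_strata(path) -> StrataConfig:
    """Read a strata configuration from a YAML file.

    Schema::

        split_latitude: 32.0        # optional
        strata:
          - name: Hawaii
            season_class: winter
            boxes: [[15, 26, -163, -152]]     # lat_min, lat_max, lon_min, lon_max
          - name: SEAKNBC
            season_class: summer
            polygon: [[50.5, -136], [60, -136], [60, -125], [50.5, -125]]
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "strata" not in raw:
        raise ValidationError(f"{path}: expected a mapping with a 'strata' list")
    strata = []
    for entry in raw["strata"]:
        boxes = tuple(LatLonBox(*b) for b in entry.get("boxes", ()))
        polygon = tuple((float(a), float(b)) for a, b in entry.get("polygon", ()))
        strata.append(
            StratumDef(
                name=str(entry["name"]),
                season_class=str(entry["season_class"]),
                boxes=boxes,
                polygon=polygon,
            )
        )
    return StrataConfig(
        strata=tuple(strata),
        split_latitude=float(raw.get("split_latitude", DEFAULT_SPLIT_LATITUDE)),
    )


def dump_strata(config: StrataConfig, path) -> None:
    """Write a strata configuration to YAML (inverse of :func:`load_strata`)."""
    payload = {
        "split_latitude": config.split_latitude,
        "strata": [
            {
                "name": s.name,
                "season_class": s.season_class,
                **(
                    {
                        "boxes": [
                            [b.lat_min, b.lat_max, b.lon_min, b.lon_max]
                            for b in s.boxes
                        ]
                    }
                    if s.boxes
                    else {}
                ),
                **({"polygon": [list(p) for p in s.polygon]} if s.polygon else {}),
            }
            for s in config.strata
        ],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)
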