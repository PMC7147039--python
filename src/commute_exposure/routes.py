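"""Route records shared by the GPS, routing and validation stages."""

from __future__ import annotations

from dataclasses import dataclass, field

from shapely.geometry import LineString

from .errors import DataError

GPS = "GPS"
SNR = "SNR"
WNR = "WNR"
SOURCES = (GPS, SNR, WNR)


@dataclass
class RouteRecord:
    """A single directed route polyline with provenance.

    ``source`` records how the geometry was obtained: a GPS trace (GPS), the
    distance-shortest network route (SNR) or the impedance-weighted network
    route (WNR).  Lengths are kilometers; geometry is planar meters.
    """

    participant_id: str
    direction: str
    source: str
    geometry: LineString
    #: node path on the network (SNR/WNR only)
    node_path: list | None = field(default=None, repr=False)
    #: total weight in the routing metric (SNR: meters; WNR: cost units)
    total_weight: float | None = None

    def __post_init__(self) -> None:
        if self.source not in SOURCES:
            raise DataError(f"unknown route source {self.source!r}")
        if self.geometry is None or len(self.geometry.coords) < 2:
            raise DataError("route geometry needs at least two vertices")
        if self.geometry.length <= 0:
            raise DataError("route geometry has zero length")

    @property
    def length_km(self) -> float:
        return self.geometry.length / 1000.0

    def reversed(self) -> "RouteRecord":
        return RouteRecord(
            participant_id=self.participant_id,
            direction=self.direction,
            source=self.source,
            geometry=LineString(list(self.geometry.coords)[::-1]),
            node_path=None if self.node_path is None else self.node_path[::-1],
            total_weight=self.total_weight,
        )
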