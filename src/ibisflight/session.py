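"""Shared session metadata carried by every per-flight data container."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class SessionMeta:
    """Identity of one wind-tunnel flight session.

    ``logger_shape`` is the housing mounted for the session (``cube`` or
    ``drop``); ``wind_angle`` is the outlet-nozzle setting (``+2`` or
    ``+6`` degrees).  Empty strings mean "not applicable" (e.g. bare
    synthetic traces).
    """

    bird: str = ""
    date: str = ""
    flight_number: int = 1
    logger_shape: str = ""
    wind_angle: str = ""

    def as_dict(self) -> dict:
        return {
            "bird": self.bird,
            "date": self.date,
            "flight_number": self.flight_number,
            "logger_shape": self.logger_shape,
            "wind_angle": self.wind_angle,
        }
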