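"""25-electrode scalp montage: names, aliases, 2D positions, regions.

The montage is the 19 classic ten-twenty sites plus the inferior chain
(F9/F10, T9/T10, P9/P10).  Old nomenclature (T3/T4/T5/T6) is canonical in
all outputs; the modern equivalents (T7/T8/P7/P8) are accepted on input.

Positions are an azimuthal-equidistant projection of the standard spherical
layout onto the unit disc, with the inferior chain on the rim: x points to
the subject's right, y anterior.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterator, Optional, Sequence

from .errors import MontageError

__all__ = ["Electrode", "Montage", "standard_montage", "ROI_ELECTRODES"]

#: The 11-electrode posterior region of interest used in the group comparison.
ROI_ELECTRODES: tuple[str, ...] = (
    "O1", "O2", "P9", "P10", "P3", "P4", "Pz", "T5", "T6", "T4", "T3",
)


@dataclass(frozen=True)
class Electrode:
    """A single scalp electrode."""

    name: str
    alt_name: Optional[str]
    pos2d: tuple[float, float]
    region: str

    @property
    def x(self) -> float:
        return self.pos2d[0]

    @property
    def y(self) -> float:
        return self.pos2d[1]


# (name, alt_name, polar angle from vertex [deg], azimuth from anterior axis
#  [deg, positive to the subject's right], region).  Polar angle 108 deg (the
#  inferior chain) maps to the rim of the unit disc.
_RIM_DEG = 108.0
_LAYOUT: tuple[tuple[str, Optional[str], float, float, str], ...] = (
    ("Fp1", None, 90.0, -18.0, "frontal"),
    ("Fp2", None, 90.0, 18.0, "frontal"),
    ("F9", None, 108.0, -54.0, "inferior"),
    ("F7", None, 90.0, -54.0, "frontal"),
    ("F3", None, 60.0, -40.0, "frontal"),
    ("Fz", None, 45.0, 0.0, "frontal"),
    ("F4", None, 60.0, 40.0, "frontal"),
    ("F8", None, 90.0, 54.0, "frontal"),
    ("F10", None, 108.0, 54.0, "inferior"),
    ("T9", None, 108.0, -90.0, "inferior"),
    ("T3", "T7", 90.0, -90.0, "temporal"),
    ("C3", None, 45.0, -90.0, "central"),
    ("Cz", None, 0.0, 0.0, "central"),
    ("C4", None, 45.0, 90.0, "central"),
    ("T4", "T8", 90.0, 90.0, "temporal"),
    ("T10", None, 108.0, 90.0, "inferior"),
    ("T5", "P7", 90.0, -126.0, "temporal"),
    ("P3", None, 60.0, -140.0, "parietal"),
    ("Pz", None, 45.0, 180.0, "parietal"),
    ("P4", None, 60.0, 140.0, "parietal"),
    ("T6", "P8", 90.0, 126.0, "temporal"),
    ("P9", None, 108.0, -126.0, "inferior"),
    ("P10", None, 108.0, 126.0, "inferior"),
    ("O1", None, 90.0, -162.0, "occipital"),
    ("O2", None, 90.0, 162.0, "occipital"),
)


def _project(polar_deg: float, azimuth_deg: float) -> tuple[float, float]:
    r = polar_deg / _RIM_DEG
    a = math.radians(azimuth_deg)
    return (r * math.sin(a), r * math.cos(a))


class Montage:
    """Ordered, alias-aware collection of electrodes."""

    def __init__(self, electrodes: Sequence[Electrode]):
        self.electrodes = tuple(electrodes)
        names = [e.name for e in self.electrodes]
        if len(set(n.upper() for n in names)) != len(names):
            raise MontageError("duplicate electrode names in montage")
        self._by_name: dict[str, Electrode] = {}
        for e in self.electrodes:
            self._by_name[e.name.upper()] = e
            if e.alt_name is not None:
                self._by_name[e.alt_name.upper()] = e

    def __len__(self) -> int:
        return len(self.electrodes)

    def __iter__(self) -> Iterator[Electrode]:
        return iter(self.electrodes)

    def __contains__(self, name: str) -> bool:
        return name.upper() in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(e.name for e in self.electrodes)

    def lookup(self, name: str) -> Electrode:
        """Resolve an electrode by canonical or modern name (case-insensitive)."""
        try:
            return self._by_name[name.upper()]
        except KeyError:
            raise MontageError(f"electrode {name!r} not in montage") from None

    def canonical(self, name: str) -> str:
        return self.lookup(name).name

    def positions(self, names: Optional[Sequence[str]] = None):
        """2D positions for the given names (default: all), as an (n, 2) list."""
        names = self.names if names is None else names
        return [self.lookup(n).pos2d for n in names]

    def to_table(self, path) -> None:
        """Export as a plain-text table: name, alt_name, x, y, region."""
        with open(path, "w") as fh:
            fh.write("name\talt_name\tx\ty\tregion\n")
            for e in self.electrodes:
                alt = e.alt_name if e.alt_name is not None else ""
                fh.write(f"{e.name}\t{alt}\t{e.x:.6f}\t{e.y:.6f}\t{e.region}\n")


def standard_montage() -> Montage:
    """The 25-electrode clinical array (ten-twenty sites + inferior chain)."""
    return Montage(
        [Electrode(n, alt, _project(pol, az), region)
         for n, alt, pol, az, region in _LAYOUT]
    )
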