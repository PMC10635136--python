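"""Protein stoichiometry and genome-packing arithmetic.

A complete T-number capsid contains 60T major capsid proteins (MCPs)
arranged in 12 pentamers and 10(T-1) hexamers.  In tailed phages one
pentameric vertex is usually replaced by the dodecameric portal
complex, removing the five MCPs of that vertex (hence 415 MCPs for a
T=7 phage capsid).  Accessory (cement/decoration) proteins that bind
only the hexamers — such as the dimers bridging the 2-fold chasm of
split hexamers — scale with the hexamer count.

Genome packing density is reported as base pairs per cubic nanometre of
the internal capsid volume, modelled as a sphere of the stated internal
diameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import InvalidStepError, NotATNumberError
from .hexlattice import is_t_number

__all__ = [
    "ProteinCensus",
    "CapsidPayload",
    "protein_census",
    "genome_density",
    "density_ratio",
]


@dataclass(frozen=True)
class ProteinCensus:
    """Copy numbers of the shell proteins of one capsid."""

    T: int
    portal_present: bool
    mcp_count: int
    pentamer_count: int
    hexamer_count: int
    accessory_per_hexamer: int
    accessory_total: int


@dataclass(frozen=True)
class CapsidPayload:
    """A packaged genome and the internal volume that holds it."""

    genome_length_kb: float
    internal_diameter_nm: float

    @property
    def density(self) -> float:
        """Packing density in bp per nm^3 (spherical internal volume)."""
        return genome_density(self.genome_length_kb, self.internal_diameter_nm)


def protein_census(T: int, portal: bool = False,
                   accessory_per_hexamer: int = 2) -> ProteinCensus:
    """MCP, capsomer and accessory-protein copy numbers for a T-number.

    With ``portal=True`` one pentameric vertex is occupied by the portal
    complex: 11 pentamers and 60T - 5 MCPs remain (the portal itself is
    not counted as MCPs).  ``accessory_per_hexamer`` defaults to 2, the
    stoichiometry of a chasm-bridging dimer; accessory proteins bind
    hexamers only, so the total is simply per-hexamer copies times
    10(T-1).
    """
    if not is_t_number(T):
        raise NotATNumberError(f"{T!r} is not a triangulation number")
    if accessory_per_hexamer < 0:
        raise InvalidStepError("accessory_per_hexamer must be >= 0")
    pentamers = 11 if portal else 12
    mcp = 60 * T - 5 if portal else 60 * T
    hexamers = 10 * (T - 1)
    return ProteinCensus(
        T=T,
        portal_present=portal,
        mcp_count=mcp,
        pentamer_count=pentamers,
        hexamer_count=hexamers,
        accessory_per_hexamer=accessory_per_hexamer,
        accessory_total=accessory_per_hexamer * hexamers,
    )


def genome_density(genome_length_kb: float, internal_diameter_nm: float) -> float:
    """Genome packing density in bp/nm^3 for a spherical internal volume."""
    if genome_length_kb <= 0 or internal_diameter_nm <= 0:
        raise InvalidStepError("genome length and diameter must be positive")
    volume = (4.0 / 3.0) * math.pi * (internal_diameter_nm / 2.0) ** 3
    return genome_length_kb * 1000.0 / volume


def density_ratio(a: CapsidPayload, b: CapsidPayload) -> float:
    """Percent change of packing density of ``a`` relative to ``b``:
    ``100 * (density_a / density_b - 1)``.

    With equal internal diameters this reduces to the genome-length
    ratio.
    """
    return 100.0 * (a.density / b.density - 1.0)
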