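"""Blood, red-cell and plasma volume derived from tHb-mass and the blood panel.

With tHb-mass (g) and venous [Hb] (g/l) known, blood volume follows from
mass = concentration × volume, corrected by the cell factor (~0.91): the
ratio of whole-body to venous hematocrit, which accounts for the lower
hematocrit of capillary/small-vessel blood.

    BV  [ml] = tHb-mass × 100 / ([Hb] g/dl × cell factor)
    RCV [ml] = BV × hct × cell factor
    PV  [ml] = BV − RCV

[Hb] is converted from g/l to g/dl at this boundary only, keeping a single
unit-conversion point in the package.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "DEFAULT_CELL_FACTOR",
    "VolumeSet",
    "blood_volume",
    "red_cell_volume",
    "plasma_volume",
    "derive_volumes",
]

DEFAULT_CELL_FACTOR = 0.91


@dataclass(frozen=True)
class VolumeSet:
    bv_ml: float
    rcv_ml: float
    pv_ml: float
    cell_factor: float

    def __post_init__(self) -> None:
        if min(self.bv_ml, self.rcv_ml, self.pv_ml) < 0:
            raise ValueError("volumes cannot be negative")
        if abs(self.bv_ml - (self.rcv_ml + self.pv_ml)) > 1e-6 * max(self.bv_ml, 1.0):
            raise ValueError("BV must equal RCV + PV")


def blood_volume(
    thb_mass_g: float, hb_g_l: float, cell_factor: float = DEFAULT_CELL_FACTOR
) -> float:
    """Blood volume (ml) from tHb-mass (g) and venous [Hb] (g/l)."""
    if thb_mass_g <= 0 or hb_g_l <= 0 or cell_factor <= 0:
        raise ValueError("thb_mass_g, hb_g_l and cell_factor must be positive")
    hb_g_dl = hb_g_l / 10.0
    return thb_mass_g * 100.0 / (hb_g_dl * cell_factor)


def red_cell_volume(
    bv_ml: float, hct: float, cell_factor: float = DEFAULT_CELL_FACTOR
) -> float:
    """Red-cell volume (ml) from blood volume and venous hematocrit fraction."""
    if not 0 < hct < 1:
        raise ValueError("hct must be a fraction in (0, 1)")
    if bv_ml <= 0:
        raise ValueError("bv_ml must be positive")
    return bv_ml * hct * cell_factor


def plasma_volume(bv_ml: float, rcv_ml: float) -> float:
    """Plasma volume (ml) as blood volume minus red-cell volume."""
    if rcv_ml > bv_ml:
        raise ValueError("red-cell volume cannot exceed blood volume")
    return bv_ml - rcv_ml


def derive_volumes(
    thb_mass_g: float,
    hb_g_l: float,
    hct: float,
    cell_factor: float = DEFAULT_CELL_FACTOR,
) -> VolumeSet:
    """Full BV/RCV/PV derivation; BV = RCV + PV holds exactly by construction."""
    bv = blood_volume(thb_mass_g, hb_g_l, cell_factor)
    rcv = red_cell_volume(bv, hct, cell_factor)
    pv = plasma_volume(bv, rcv)
    return VolumeSet(bv_ml=bv, rcv_ml=rcv, pv_ml=pv, cell_factor=cell_factor)
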