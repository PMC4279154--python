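"""Sample-preparation arithmetic for the willow NMR protocol.

Deterministic dilution and stock-molarity calculations for the buffered
D2O:CD3OD extract recipe: concentrated phosphate buffer and EDTA "slugs"
added to a 700 µL NMR aliquot, plus first-principles molarity of the
stock solutions themselves.  All values are carried at full precision;
rounding to a printed prep-sheet is a presentation step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "Additive",
    "final_concentration",
    "stock_molarity",
    "buffer_recipe",
    "MW",
    "prep_sheet",
]

# Molecular weights (g/mol) used by the protocol arithmetic.
MW = {
    "EDTA-Na2.2H2O": 372.24,
    "K2HPO4": 174.18,
    "KH2PO4": 136.09,
    "TSP-d4 sodium salt": 172.27,
    "KF": 58.10,
}


@dataclass(frozen=True)
class Additive:
    """One volumetric addition to the NMR aliquot.

    Parameters
    ----------
    species : str
        Chemical species delivered, e.g. ``"EDTA"``, ``"phosphate"``, ``"KF"``.
    volume_uL : float
        Volume added (µL), must be positive.
    stock_conc_mM : float
        Concentration of the stock solution in mM (pass M × 1000).
    """

    species: str
    volume_uL: float
    stock_conc_mM: float

    def __post_init__(self) -> None:
        if self.volume_uL <= 0:
            raise ValueError(f"additive {self.species}: volume must be > 0 µL")
        if self.stock_conc_mM < 0:
            raise ValueError(f"additive {self.species}: stock concentration must be >= 0")


def final_concentration(
    additives: list[Additive], base_volume_uL: float = 700.0
) -> dict[str, float]:
    """Final in-tube concentration (mM) of each added species.

    Volume-additive mixing: each species' amount is summed over additives and
    divided by the total final volume (base aliquot plus *all* additive
    volumes).  Removal of an aliquot to the NMR tube afterwards does not
    change concentrations and is ignored.  Order-independent by construction.

    Returns a mapping species -> mM (multiply by 1000 for µM).
    """
    if base_volume_uL <= 0:
        raise ValueError("base volume must be > 0 µL")
    total_volume = base_volume_uL + sum(a.volume_uL for a in additives)
    amounts: dict[str, float] = {}
    for a in additives:
        # nmol = mM * µL; nmol / µL = mM
        amounts[a.species] = amounts.get(a.species, 0.0) + a.stock_conc_mM * a.volume_uL
    return {sp: amt / total_volume for sp, amt in amounts.items()}


def stock_molarity(mass_mg: float, mw_g_per_mol: float, volume_mL: float) -> float:
    """Molarity (mM) of ``mass_mg`` of a compound dissolved in ``volume_mL``."""
    if mw_g_per_mol <= 0:
        raise ValueError("molecular weight must be > 0")
    if volume_mL <= 0:
        raise ValueError("volume must be > 0")
    if mass_mg < 0:
        raise ValueError("mass must be >= 0")
    return mass_mg / mw_g_per_mol / volume_mL * 1000.0


def buffer_recipe(
    masses_g: dict[str, float],
    mws: dict[str, float] | None = None,
    volume_mL: float = 10.0,
) -> tuple[float, float]:
    """Total molarity (M) and base:acid mole ratio of a phosphate buffer.

    ``masses_g`` maps salt name to mass in grams.  The ratio returned is
    K2HPO4 : KH2PO4 (dibasic over monobasic); ``inf`` when only one salt is
    present (degenerate single-salt buffer).
    """
    if not masses_g:
        raise ValueError("at least one salt required")
    if volume_mL <= 0:
        raise ValueError("volume must be > 0")
    mws = {**MW, **(mws or {})}
    moles: dict[str, float] = {}
    for salt, mass in masses_g.items():
        if salt not in mws:
            raise KeyError(f"unknown salt {salt!r}: supply its molecular weight")
        moles[salt] = mass / mws[salt]
    total_molar = sum(moles.values()) / (volume_mL / 1000.0)
    base = moles.get("K2HPO4", 0.0)
    acid = moles.get("KH2PO4", 0.0)
    ratio = base / acid if acid > 0 else float("inf")
    return total_molar, ratio


# Protocol constants: the two prep variants.  Method "a" extracts in
# H2O:CH3OH and re-dissolves the dried 700 µL aliquot in deuterated solvent
# (recording the extract mass); method "b" extracts directly into the
# deuterated solvent, skipping the dry-down.
PROTOCOL_ADDITIVES = [
    Additive("phosphate", volume_uL=20.0, stock_conc_mM=2600.0),
    Additive("EDTA", volume_uL=10.0, stock_conc_mM=32.0),
]


def prep_sheet(method: str = "a") -> str:
    """Human-readable prep sheet for protocol method ``"a"`` or ``"b"``."""
    if method not in ("a", "b"):
        raise ValueError("method must be 'a' or 'b'")
    edta_mM = stock_molarity(12.0, MW["EDTA-Na2.2H2O"], 1.0)
    buf_M, buf_ratio = buffer_recipe({"K2HPO4": 4.19, "KH2PO4": 0.808})
    finals = final_concentration(PROTOCOL_ADDITIVES)
    lines = [
        f"Willow NMR prep sheet - method {method}",
        "Tissue: 15.0 mg freeze-dried milled, triplicate aliquots",
    ]
    if method == "a":
        lines += [
            "Extraction: 1.0 mL H2O:CH3OH 4:1, 50 C 10 min; 850 uL supernatant,",
            "  90 C 2 min heat shock; 700 uL dried (record extract mass),",
            "  re-dissolved in 700 uL D2O:CD3OD 4:1 + 0.01% w/v d4-TSP",
        ]
    else:
        lines += [
            "Extraction: 1.0 mL D2O:CD3OD 4:1 + 0.01% w/v d4-TSP, 50 C 10 min;",
            "  850 uL supernatant, 90 C 2 min heat shock; 700 uL to NMR prep",
            "  (no dry-down; expect elevated ascorbate and acetate)",
        ]
    lines += [
        "Stocks:",
        f"  EDTA: 12 mg EDTA-Na2.2H2O in 1 mL D2O = {edta_mM:.1f} mM (label 32 mM)",
        f"  buffer: 4.19 g K2HPO4 + 0.808 g KH2PO4 in 10 mL D2O"
        f" = {buf_M:.2f} M computed (label 2.6 M), base:acid {buf_ratio:.2f}, pH 7.4",
        "Additions to the 700 uL aliquot:",
    ]
    for a in PROTOCOL_ADDITIVES:
        lines.append(f"  {a.volume_uL:.0f} uL of {a.stock_conc_mM:g} mM {a.species}")
    lines.append("Final in-tube concentrations:")
    for sp, mM in finals.items():
        if mM < 1.0:
            lines.append(f"  {sp}: {mM * 1000:.0f} uM")
        else:
            lines.append(f"  {sp}: {mM:.0f} mM")
    lines.append("Transfer 650 uL to a 5 mm NMR tube after 30 min standing.")
    return "\n".join(lines)
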