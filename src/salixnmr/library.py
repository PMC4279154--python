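"""Metabolite NMR signature library.

A signature is the set of multiplets (centre, pattern, J couplings, proton
count, natural linewidth) a metabolite contributes to a 1D 1H spectrum,
plus its compound class and molecular weight.  The library drives both
spectrum synthesis and targeted Lorentzian-fit quantitation, the same way
a Chenomx-style compound database anchors profiling software.

Serialisation is plain JSON; loading validates every invariant and fails
with diagnostics that name the offending signature and field.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterator, Literal

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "PhModel",
    "Multiplet",
    "MetaboliteSignature",
    "SignatureLibrary",
    "LibraryValidationError",
    "PATTERN_ARITY",
    "expand_multiplet",
    "validate_signature",
    "load_library",
    "save_library",
    "builtin_willow_library",
]

# Number of J values each splitting pattern carries.  "ab" is one half of an
# AB spin system rendered as a plain doublet (roof effect ignored: second
# order distortion is negligible at 600 MHz when the shift difference far
# exceeds J).  "m" is an unresolved multiplet rendered as a single broadened
# line.
PATTERN_ARITY = {"s": 0, "d": 1, "dd": 2, "t": 1, "q": 1, "m": 0, "ab": 1}

# Default reference pH of the buffered solvent system.
REFERENCE_PH = 7.4


class PhModel(BaseModel):
    """Two-state (protonated/deprotonated) chemical-shift model.

    The observed centre is the Henderson-Hasselbalch-weighted mean of the
    two state shifts at the sample pH; ``pka`` holds the relevant pKa
    (first entry used).
    """

    model_config = ConfigDict(extra="forbid")

    pka: list[float]
    delta_acid: float
    delta_base: float

    def center_at(self, ph: float) -> float:
        frac_base = 1.0 / (1.0 + 10.0 ** (self.pka[0] - ph))
        return frac_base * self.delta_base + (1.0 - frac_base) * self.delta_acid


class Multiplet(BaseModel):
    model_config = ConfigDict(extra="forbid")

    center_ppm: float
    pattern: Literal["s", "d", "dd", "t", "q", "m", "ab"]
    j_hz: list[float] = Field(default_factory=list)
    n_protons: int
    fwhm_hz: float = 1.0
    ph_model: PhModel | None = None
    exchangeable: bool = False
    exchange_rate_per_h: float | None = None
    provenance: Literal["protocol", "reference"] = "reference"


class MetaboliteSignature(BaseModel):
    model_config = ConfigDict(extra="forbid", populate_by_name=True)

    name: str
    compound_class: Literal[
        "carbohydrate", "amino acid", "organic acid", "aromatic", "other"
    ] = Field(alias="class")
    mw: float
    ca_sensitive: bool = False
    multiplets: list[Multiplet] = Field(default_factory=list)

    @property
    def n_protons_total(self) -> int:
        return sum(m.n_protons for m in self.multiplets)


class SignatureLibrary(BaseModel):
    model_config = ConfigDict(extra="forbid")

    field_mhz: float = 600.0
    solvent_tag: str = ""
    signatures: list[MetaboliteSignature] = Field(default_factory=list)

    def __getitem__(self, name: str) -> MetaboliteSignature:
        for sig in self.signatures:
            if sig.name == name:
                return sig
        raise KeyError(name)

    def __contains__(self, name: str) -> bool:
        return any(sig.name == name for sig in self.signatures)

    def __iter__(self) -> Iterator[MetaboliteSignature]:  # type: ignore[override]
        return iter(self.signatures)

    def __len__(self) -> int:
        return len(self.signatures)

    @property
    def names(self) -> list[str]:
        return [sig.name for sig in self.signatures]


class LibraryValidationError(ValueError):
    """Raised on load when a library violates signature invariants."""

    def __init__(self, diagnostics: list[str]):
        self.diagnostics = diagnostics
        super().__init__("; ".join(diagnostics))


def expand_multiplet(m: Multiplet) -> tuple[np.ndarray, np.ndarray]:
    """Expand a splitting pattern into line offsets (Hz) and weights.

    Offsets are relative to the multiplet centre; weights sum to 1.  The
    expansion is the standard convolution-of-doublets picture: each coupling
    splits every line in two, so t = 1:2:1 at offsets (-J, 0, +J) and
    q = 1:3:3:1 at (+-J/2, +-3J/2).
    """
    p = m.pattern
    if p in ("s", "m"):
        return np.array([0.0]), np.array([1.0])
    if p in ("d", "ab"):
        j = m.j_hz[0]
        return np.array([-j / 2, j / 2]), np.array([0.5, 0.5])
    if p == "t":
        j = m.j_hz[0]
        return np.array([-j, 0.0, j]), np.array([0.25, 0.5, 0.25])
    if p == "q":
        j = m.j_hz[0]
        return (
            np.array([-1.5 * j, -0.5 * j, 0.5 * j, 1.5 * j]),
            np.array([1, 3, 3, 1]) / 8.0,
        )
    if p == "dd":
        j1, j2 = m.j_hz
        offs = np.array(
            [(-j1 - j2) / 2, (-j1 + j2) / 2, (j1 - j2) / 2, (j1 + j2) / 2]
        )
        return offs, np.full(4, 0.25)
    raise ValueError(f"unknown pattern {p!r}")  # pragma: no cover


def multiplet_span_hz(m: Multiplet) -> float:
    """Full extent (Hz) of the expanded line pattern."""
    offs, _ = expand_multiplet(m)
    return float(offs.max() - offs.min())


def validate_signature(
    sig: MetaboliteSignature,
    field_mhz: float = 600.0,
    n_points: int = 65536,
    sweep_ppm: float = 12.0,
) -> list[str]:
    """Check a signature's invariants; return diagnostics (empty if valid).

    Hard violations are plain strings; resolvability issues (line spacing
    below the digital resolution of the acquisition grid) are prefixed
    ``"warning:"`` and do not fail a load.
    """
    diags: list[str] = []
    tag = f"signature {sig.name!r}"
    if not sig.multiplets:
        diags.append(f"{tag}: multiplets: at least one multiplet required")
    if sig.mw <= 0:
        diags.append(f"{tag}: mw: molecular weight must be > 0")
    digital_res_hz = sweep_ppm * field_mhz / n_points
    for i, m in enumerate(sig.multiplets):
        mtag = f"{tag} multiplet[{i}] at {m.center_ppm} ppm"
        if m.n_protons < 1:
            diags.append(f"{mtag}: n_protons: must be >= 1 (got {m.n_protons})")
        if m.fwhm_hz <= 0:
            diags.append(f"{mtag}: fwhm_hz: must be > 0 (got {m.fwhm_hz})")
        arity = PATTERN_ARITY[m.pattern]
        if len(m.j_hz) != arity:
            diags.append(
                f"{mtag}: j_hz: pattern {m.pattern!r} takes {arity} coupling(s), "
                f"got {len(m.j_hz)}"
            )
            continue
        if m.ph_model is not None:
            lo = min(m.ph_model.delta_acid, m.ph_model.delta_base)
            hi = max(m.ph_model.delta_acid, m.ph_model.delta_base)
            if not (lo <= m.center_ppm <= hi):
                diags.append(
                    f"{mtag}: ph_model: state shifts [{lo}, {hi}] do not bracket "
                    f"centre {m.center_ppm}"
                )
        if m.fwhm_hz > 0 and m.n_protons >= 1:
            offs, _ = expand_multiplet(m)
            uniq = np.unique(np.round(offs, 9))
            if len(uniq) > 1:
                min_gap = float(np.diff(uniq).min())
                if min_gap < digital_res_hz:
                    diags.append(
                        f"warning: {mtag}: line spacing {min_gap:.3g} Hz below "
                        f"digital resolution {digital_res_hz:.3g} Hz at "
                        f"{field_mhz:g} MHz"
                    )
    return diags


def validate_library(lib: SignatureLibrary) -> list[str]:
    diags: list[str] = []
    if lib.field_mhz <= 0:
        diags.append("library: field_mhz must be > 0")
    seen: set[str] = set()
    for sig in lib.signatures:
        if sig.name in seen:
            diags.append(f"library: duplicate signature name {sig.name!r}")
        seen.add(sig.name)
        diags.extend(validate_signature(sig, lib.field_mhz))
    return diags


def load_library(path: str | Path) -> SignatureLibrary:
    """Read and validate a JSON signature library.

    Signatures are returned sorted by name (deterministic ordering).
    Raises ``LibraryValidationError`` on invariant violations and the
    underlying json/pydantic error on malformed input.
    """
    with open(path) as fh:
        data = json.load(fh)
    lib = SignatureLibrary.model_validate(data)
    hard = [d for d in validate_library(lib) if not d.startswith("warning:")]
    if hard:
        raise LibraryValidationError(hard)
    lib.signatures.sort(key=lambda s: s.name)
    return lib


def save_library(lib: SignatureLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(lib.model_dump(by_alias=True, exclude_none=True), fh, indent=1)
        fh.write("\n")


def builtin_willow_library() -> SignatureLibrary:
    from ._willow_data import build_library

    return build_library()
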