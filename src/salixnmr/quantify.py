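"""Targeted metabolite quantitation by signature-library Lorentzian fitting.

Profiling superimposes the library's Lorentzian multiplet templates onto a
referenced spectrum and solves a constrained least-squares problem

    model = sum_m c_m * template_m(shift_m, width_m) + per-window baseline

with non-negative concentrations, per-multiplet shift offsets bounded by a
tolerance (0.01 ppm default, absorbing residual pH misalignment) and
linewidths bounded to a physical range.  Concentrations are calibrated
against the internal standard:  c_m = (fitted area per proton of m) /
(TSP area per proton) * c_TSP, which makes the result invariant to any
global intensity scaling of the spectrum.

The solver is deterministic: an initial non-negative linear solve at zero
offsets, followed by coordinate-wise bounded refinement of each multiplet's
shift offset and each metabolite's linewidth factor, re-solving the linear
problem after each pass.  Exchange-labile multiplets (catechin C-6/C-8) and
multiplets falling inside solvent-excision regions are left out of the
templates, so quantitation rests on stable protons only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import lsq_linear, minimize_scalar

from .library import SignatureLibrary, builtin_willow_library, expand_multiplet
from .preprocess import DEFAULT_EXCLUSIONS
from .simulate import (
    AREA_K,
    DEFAULT_TSP_TUBE_MM,
    LINE_BROADENING_HZ,
    Spectrum,
    SimulatorConfig,
)

__all__ = [
    "PrepRecipe",
    "FitOptions",
    "QuantResult",
    "FitResult",
    "fit_signatures",
    "tube_to_tissue_units",
    "batch_profile",
]


@dataclass(frozen=True)
class PrepRecipe:
    """Volumes and masses of the extraction + additive protocol."""

    tissue_mass_mg: float = 15.0
    extraction_volume_mL: float = 1.0
    supernatant_taken_uL: float = 850.0
    aliquot_to_nmr_uL: float = 700.0
    additive_volumes_uL: tuple[float, ...] = (20.0, 10.0)  # buffer, EDTA
    tsp_conc_mM: float = DEFAULT_TSP_TUBE_MM
    prep_method: str = "a"

    def __post_init__(self) -> None:
        vols = (
            self.tissue_mass_mg,
            self.extraction_volume_mL,
            self.supernatant_taken_uL,
            self.aliquot_to_nmr_uL,
        )
        if any(v <= 0 for v in vols) or any(v <= 0 for v in self.additive_volumes_uL):
            raise ValueError("all masses and volumes must be > 0")
        if not (
            self.aliquot_to_nmr_uL
            <= self.supernatant_taken_uL
            <= self.extraction_volume_mL * 1000.0
        ):
            raise ValueError("aliquot <= supernatant <= extraction volume violated")

    @property
    def tube_volume_uL(self) -> float:
        return self.aliquot_to_nmr_uL + sum(self.additive_volumes_uL)


@dataclass(frozen=True)
class FitOptions:
    shift_tol_ppm: float = 0.01
    fwhm_bounds_hz: tuple[float, float] = (0.5, 6.0)
    window_pad_ppm: float = 0.02
    refine_passes: int = 2
    baseline: bool = True
    model_solvents: bool = True  # include water/methanol residual templates
    exclude_exchangeable: bool = True
    solvent_exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS[:2]
    noise_snr: float = 3.0
    tsp_conc_mM: float | None = None  # default: spectrum metadata, else protocol value


@dataclass
class QuantResult:
    metabolite: str
    conc_tube_mM: float
    conc_umol_per_g: float | None = None
    conc_mg_per_g: float | None = None
    shift_offsets_ppm: dict = field(default_factory=dict)
    fitted_fwhm_hz: dict = field(default_factory=dict)
    residual_norm: float = 0.0
    flags: tuple[str, ...] = ()


@dataclass
class FitResult:
    results: dict[str, QuantResult]
    tsp_coefficient: float
    noise_sd: float
    residual: Spectrum  # observed minus model over the fit windows

    def __getitem__(self, name: str) -> QuantResult:
        return self.results[name]

    def concentrations(self) -> dict[str, float]:
        return {n: r.conc_tube_mM for n, r in self.results.items()}


class _MultipletTerm:
    """One multiplet of one metabolite, with its fit window and state."""

    __slots__ = (
        "metabolite", "center", "offsets_ppm", "weights", "base_fwhm_hz",
        "area_per_mM", "window", "delta", "width_factor",
    )

    def __init__(self, metabolite, mult, field_mhz, pad, tol, m_width_factor):
        self.metabolite = metabolite
        offsets, weights = expand_multiplet(mult)
        self.center = mult.center_ppm
        self.offsets_ppm = offsets / field_mhz
        self.weights = weights
        fwhm = mult.fwhm_hz
        if mult.pattern == "m":
            fwhm = fwhm * m_width_factor
        self.base_fwhm_hz = fwhm + LINE_BROADENING_HZ
        self.area_per_mM = mult.n_protons * AREA_K
        span = (offsets.max() - offsets.min()) / field_mhz
        self.window = (
            self.center - span / 2 - pad - tol,
            self.center + span / 2 + pad + tol,
        )
        self.delta = 0.0
        self.width_factor = 1.0

    def render(self, ppm, field_mhz, delta=None, width_factor=None):
        delta = self.delta if delta is None else delta
        wf = self.width_factor if width_factor is None else width_factor
        gamma = self.base_fwhm_hz * wf / field_mhz / 2.0
        out = np.zeros_like(ppm)
        for off, w in zip(self.offsets_ppm, self.weights):
            c = self.center + delta + off
            out += (self.area_per_mM * w) * (gamma / np.pi) / ((ppm - c) ** 2 + gamma ** 2)
        return out


def _intersects(win, region):
    return win[0] < region[1] and win[1] > region[0]


def _estimate_noise(spectrum: Spectrum) -> float:
    """Noise sd from signal-free axis extremes (first/last 2% of points)."""
    n = max(16, len(spectrum.intensity) // 50)
    tails = np.concatenate([spectrum.intensity[:n], spectrum.intensity[-n:]])
    med = np.median(tails)
    return float(np.median(np.abs(tails - med)) * 1.4826) or 1e-12


def fit_signatures(
    spectrum: Spectrum,
    library: SignatureLibrary | None = None,
    options: FitOptions | None = None,
) -> FitResult:
    """Fit the signature library to one referenced spectrum.

    TSP anchors the concentration scale and must be present in both the
    library and the spectrum.  Returns per-metabolite concentrations with
    fit diagnostics; metabolites whose every usable multiplet lies below
    the noise floor report 0 mM with a ``below_noise`` flag.
    """
    library = library or builtin_willow_library()
    options = options or FitOptions()
    if "TSP" not in library:
        raise ValueError("library has no TSP signature; cannot calibrate")
    field_mhz = spectrum.field_mhz
    tsp_conc = options.tsp_conc_mM
    if tsp_conc is None:
        tsp_conc = spectrum.meta.get("tsp_conc_mM", DEFAULT_TSP_TUBE_MM)

    # Build fit terms, skipping exchangeable and solvent-obscured multiplets.
    terms: list[_MultipletTerm] = []
    names: list[str] = []
    skipped: dict[str, list[str]] = {}
    for sig in library:
        usable = []
        for mult in sig.multiplets:
            if options.exclude_exchangeable and mult.exchangeable:
                skipped.setdefault(sig.name, []).append("exchangeable")
                continue
            term = _MultipletTerm(
                sig.name, mult, field_mhz, options.window_pad_ppm,
                options.shift_tol_ppm, SimulatorConfig.m_width_factor,
            )
            if any(_intersects(term.window, r) for r in options.solvent_exclusions):
                skipped.setdefault(sig.name, []).append("solvent_overlap")
                continue
            if term.window[1] < spectrum.ppm[0] or term.window[0] > spectrum.ppm[-1]:
                skipped.setdefault(sig.name, []).append("off_axis")
                continue
            usable.append(term)
        if usable:
            terms.extend(usable)
            if sig.name not in names:
                names.append(sig.name)
    if "TSP" not in names:
        raise ValueError("TSP multiplet unusable on this axis; cannot calibrate")

    ppm = spectrum.ppm
    y = spectrum.intensity
    # Union of fit windows, as connected segments for per-window baselines.
    in_window = np.zeros(len(ppm), dtype=bool)
    for t in terms:
        lo, hi = np.searchsorted(ppm, t.window)
        in_window[lo:hi] = True
    idx = np.flatnonzero(in_window)
    seg_breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, seg_breaks + 1)

    col_of = {n: k for k, n in enumerate(names)}
    n_met = len(names)
    ppm_w = ppm[idx]
    cfg = SimulatorConfig()
    solvent_cols = 2 if options.model_solvents else 0

    def _solvent_template(center, fwhm_hz):
        gamma = fwhm_hz / field_mhz / 2.0
        return (gamma / np.pi) / ((ppm_w - center) ** 2 + gamma ** 2)

    def design():
        # Full templates: each metabolite column carries all its multiplets
        # over every fit point, so cross-window Lorentzian tails are modelled.
        n_cols = n_met + solvent_cols + (2 * len(segments) if options.baseline else 0)
        A = np.zeros((len(idx), n_cols))
        for t in terms:
            A[:, col_of[t.metabolite]] += t.render(ppm_w, field_mhz)
        k = n_met
        if options.model_solvents:
            A[:, k] = _solvent_template(cfg.water_center_ppm, cfg.water_fwhm_hz)
            A[:, k + 1] = _solvent_template(cfg.meoh_center_ppm, cfg.meoh_fwhm_hz)
            k += 2
        if options.baseline:
            pos = {j: r for r, j in enumerate(idx)}
            for s, seg in enumerate(segments):
                rows = np.fromiter((pos[j] for j in seg), dtype=int, count=len(seg))
                x = ppm[seg]
                x0 = (x - x.mean()) / max(np.ptp(x) / 2.0, 1e-9)
                A[rows, k + 2 * s] = 1.0
                A[rows, k + 2 * s + 1] = x0
        return A

    yw = y[idx]
    n_extra = solvent_cols + (2 * len(segments) if options.baseline else 0)
    lb = np.concatenate(
        [np.zeros(n_met + solvent_cols),
         np.full(n_extra - solvent_cols, -np.inf)]
    )
    ub = np.full(n_met + n_extra, np.inf)

    def solve(A):
        # QR reduction: bounded least squares on the small triangular system
        # is equivalent to the full problem and much faster.
        Q, R = np.linalg.qr(A)
        res = lsq_linear(R, Q.T @ yw, bounds=(lb, ub), tol=1e-14, method="bvls")
        return res.x

    A = design()
    coefs = solve(A)

    # Coordinate-wise refinement of shift offsets and width factors.
    tol = options.shift_tol_ppm
    wlo, whi = options.fwhm_bounds_hz
    for _ in range(options.refine_passes):
        model_w = A @ coefs
        pos = {j: k for k, j in enumerate(idx)}
        for t in terms:
            # refine even zero-amplitude terms: a shifted peak can leave its
            # template unmatched in the initial solve
            c = coefs[col_of[t.metabolite]]
            lo, hi = np.searchsorted(ppm, t.window)
            sl = np.arange(lo, hi)
            rows = np.fromiter((pos[j] for j in sl), dtype=int, count=len(sl))
            partial = yw[rows] - model_w[rows] + c * t.render(ppm[sl], field_mhz)

            def sse_delta(d):
                tm = t.render(ppm[sl], field_mhz, delta=d)
                denom = tm @ tm
                if denom <= 0:
                    return float(partial @ partial)
                a = max(0.0, (partial @ tm) / denom)
                r = partial - a * tm
                return float(r @ r)

            res = minimize_scalar(sse_delta, bounds=(-tol, tol), method="bounded",
                                  options={"xatol": 1e-6})
            # accept only a real improvement over the current offset
            if res.fun < sse_delta(t.delta) * (1.0 - 1e-9):
                t.delta = float(res.x)

            wf_lo = wlo / t.base_fwhm_hz
            wf_hi = whi / t.base_fwhm_hz

            def sse_width(wf):
                tm = t.render(ppm[sl], field_mhz, width_factor=wf)
                denom = tm @ tm
                a = max(0.0, (partial @ tm) / denom)
                r = partial - a * tm
                return float(r @ r)

            res = minimize_scalar(sse_width, bounds=(max(wf_lo, 0.25), min(wf_hi, 4.0)),
                                  method="bounded", options={"xatol": 1e-4})
            if res.fun < sse_width(t.width_factor) * (1.0 - 1e-9):
                t.width_factor = float(res.x)
        A = design()
        coefs = solve(A)

    resid = yw - A @ coefs
    noise = _estimate_noise(spectrum)
    tsp_coef = coefs[col_of["TSP"]]
    if tsp_coef <= 0:
        raise ValueError("TSP fit failed (zero amplitude); cannot calibrate")
    scale = tsp_conc / tsp_coef

    results: dict[str, QuantResult] = {}
    pos = {j: k for k, j in enumerate(idx)}
    for name in names:
        c_raw = coefs[col_of[name]]
        conc = c_raw * scale
        mterms = [t for t in terms if t.metabolite == name]
        flags = []
        # peak heights implied by the fit vs the noise floor
        max_height = 0.0
        rnorm = 0.0
        for t in mterms:
            lo, hi = np.searchsorted(ppm, t.window)
            sl = np.arange(lo, hi)
            tm = c_raw * t.render(ppm[sl], field_mhz)
            max_height = max(max_height, float(tm.max(initial=0.0)))
            rows = np.fromiter((pos[j] for j in sl), dtype=int, count=len(sl))
            rnorm += float(resid[rows] @ resid[rows])
            if abs(t.delta) >= tol * 0.999:
                flags.append("boundary_shift")
            w = t.base_fwhm_hz * t.width_factor
            if w <= wlo * 1.001 or w >= whi * 0.999:
                flags.append("boundary_width")
        if max_height < options.noise_snr * noise:
            conc = 0.0
            flags.append("below_noise")
        if name in skipped:
            flags.append("partial_signature")
        overlapping = _has_overlap(mterms, terms)
        if overlapping:
            flags.append("overlapped")
        results[name] = QuantResult(
            metabolite=name,
            conc_tube_mM=conc,
            shift_offsets_ppm={t.center: t.delta for t in mterms},
            fitted_fwhm_hz={t.center: t.base_fwhm_hz * t.width_factor for t in mterms},
            residual_norm=np.sqrt(rnorm),
            flags=tuple(dict.fromkeys(flags)),
        )
    residual_full = np.zeros_like(y)
    residual_full[idx] = resid
    residual_spec = Spectrum(
        ppm.copy(), residual_full, field_mhz,
        {**spectrum.meta, "residual_of": spectrum.meta.get("sample_id", "")},
    )
    return FitResult(results, tsp_coef, noise, residual_spec)


def _has_overlap(mterms, terms) -> bool:
    for t in mterms:
        for u in terms:
            if u.metabolite != t.metabolite and _intersects(t.window, u.window):
                return True
    return False


def tube_to_tissue_units(
    conc_tube_mM: float,
    prep: PrepRecipe | None = None,
    mw: float | None = None,
) -> tuple[float, float | None]:
    """Convert an in-tube concentration to tissue units.

    Back-corrects the additive dilution (tube volume / NMR aliquot), then
    scales by extraction volume over tissue mass:

        umol/g = c_tube * V_tube/V_aliquot * V_extraction / m_tissue

    mg/g additionally requires the molecular weight.  Returns
    (umol per g dry weight, mg per g dry weight or None).
    """
    prep = prep or PrepRecipe()
    c_extract = conc_tube_mM * prep.tube_volume_uL / prep.aliquot_to_nmr_uL
    umol_g = c_extract * prep.extraction_volume_mL / (prep.tissue_mass_mg / 1000.0)
    mg_g = umol_g * mw / 1000.0 if mw is not None else None
    return umol_g, mg_g


def batch_profile(
    spectra: list[Spectrum],
    library: SignatureLibrary | None = None,
    prep: PrepRecipe | Mapping[str, PrepRecipe] | None = None,
    options: FitOptions | None = None,
    metabolites: list[str] | None = None,
) -> pd.DataFrame:
    """Quantify every spectrum; one row per sample x metabolite.

    Technical replicates are preserved (averaging is a downstream step).
    ``prep`` may be one recipe for all samples or a mapping keyed by sample
    id (a missing sample raises, naming it).  ``metabolites`` restricts the
    output rows (the fit always uses the full library).
    """
    library = library or builtin_willow_library()
    rows = []
    for spec in spectra:
        sid = spec.meta.get("sample_id", "")
        if isinstance(prep, Mapping):
            if sid not in prep:
                raise KeyError(f"no prep recipe for sample {sid!r}")
            recipe = prep[sid]
        else:
            recipe = prep or PrepRecipe()
        fit = fit_signatures(spec, library, options)
        for name, qr in fit.results.items():
            if metabolites is not None and name not in metabolites:
                continue
            umol_g, mg_g = tube_to_tissue_units(
                qr.conc_tube_mM, recipe, library[name].mw
            )
            rows.append(
                {
                    "sample_id": sid,
                    "metabolite": name,
                    "conc_tube_mM": qr.conc_tube_mM,
                    "conc_umol_per_g": umol_g,
                    "conc_mg_per_g": mg_g,
                    "flags": ";".join(qr.flags),
                }
            )
    return pd.DataFrame(rows)
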