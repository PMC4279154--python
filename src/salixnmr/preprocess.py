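"""Referencing, excision, bucketing and scaling of 1D 1H spectra.

The fingerprinting pipeline reduces each referenced spectrum to integrated
buckets of equal width (0.015 ppm by default), after scaling intensities to
the TSP reference region (delta 0.05 to -0.05) and excising the unsuppressed
water (4.865-4.775), residual methanol (3.335-3.285) and TSP regions.
Buckets that overlap an excluded region are dropped whole, matching the
bucket-count bookkeeping of spreadsheet workflows.

The bucket grid is anchored at -0.05 ppm with edges -0.05 + k*width so the
TSP region tiles cleanly.  Bucket values are trapezoidal integrals; because
adjacent buckets share edges, the sum of all bucket values telescopes to the
integral over the full range exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import cumulative_trapezoid

from .simulate import Spectrum

__all__ = [
    "DEFAULT_EXCLUSIONS",
    "TSP_REGION",
    "CATECHIN_EXCHANGE_PPM",
    "BucketTable",
    "ReferencingError",
    "reference_to_tsp",
    "integrate_region",
    "bin_spectrum",
    "scale_to_tsp",
    "assemble_bucket_table",
    "process_spectra",
]

TSP_REGION = (-0.05, 0.05)
WATER_REGION = (4.775, 4.865)
MEOD_REGION = (3.285, 3.335)
DEFAULT_EXCLUSIONS = (WATER_REGION, MEOD_REGION, TSP_REGION)

# Catechin C-6 / C-8 aromatic shifts whose buckets carry the H/D-exchange
# false-positive risk.
CATECHIN_EXCHANGE_PPM = (6.09, 6.00)


class ReferencingError(RuntimeError):
    pass


@dataclass
class BucketTable:
    """Samples x buckets matrix with exclusion mask and scaling state."""

    data: pd.DataFrame  # index: sample ids; columns: bucket centres (ppm)
    width: float
    excluded_regions: tuple[tuple[float, float], ...]
    scaled: bool = False
    catechin_bins_dropped: bool = False
    tsp_areas: dict = field(default_factory=dict)

    @property
    def bucket_centers(self) -> np.ndarray:
        return self.data.columns.to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        """First row bucket centres, then one row per sample."""
        self.data.to_csv(path, index_label="sample_id")

    def drop_catechin_bins(self) -> "BucketTable":
        keep = [
            c
            for c in self.data.columns
            if not any(
                c - self.width / 2 <= p < c + self.width / 2
                for p in CATECHIN_EXCHANGE_PPM
            )
        ]
        return BucketTable(
            self.data[keep],
            self.width,
            self.excluded_regions,
            self.scaled,
            catechin_bins_dropped=True,
            tsp_areas=self.tsp_areas,
        )


def _cumulative(spectrum: Spectrum) -> np.ndarray:
    return np.concatenate(
        ([0.0], cumulative_trapezoid(spectrum.intensity, spectrum.ppm))
    )


def integrate_region(spectrum: Spectrum, left: float, right: float) -> float:
    """Trapezoidal integral of intensity over [left, right] ppm."""
    cum = _cumulative(spectrum)
    lo, hi = np.interp([left, right], spectrum.ppm, cum)
    return float(hi - lo)


def reference_to_tsp(
    spectrum: Spectrum, search_halfwidth: float = 0.3, min_snr: float = 5.0
) -> Spectrum:
    """Shift the ppm axis so the tallest peak near 0 ppm sits at 0.00.

    The apex of the tallest peak in [-search_halfwidth, +search_halfwidth]
    is taken as TSP.  Ties are broken deterministically toward the candidate
    nearest 0 ppm.  Raises ``ReferencingError`` when no peak rises above the
    window's noise floor (median + min_snr * scaled MAD).
    """
    mask = np.abs(spectrum.ppm) <= search_halfwidth
    if not mask.any():
        raise ReferencingError("axis does not cover the TSP search window")
    window = spectrum.intensity[mask]
    ppm_win = spectrum.ppm[mask]
    med = np.median(window)
    mad = np.median(np.abs(window - med)) * 1.4826
    floor = med + min_snr * mad
    peak = window.max()
    if peak <= floor or peak <= 0:
        raise ReferencingError(
            f"no peak above the noise floor ({floor:.3g}) in the TSP window"
        )
    candidates = np.flatnonzero(window >= peak * (1 - 1e-12))
    apex_idx = candidates[np.argmin(np.abs(ppm_win[candidates]))]
    apex_ppm = float(ppm_win[apex_idx])
    out = spectrum.copy()
    out.ppm = out.ppm - apex_ppm
    out.meta["referencing_shift_ppm"] = -apex_ppm
    out.meta["referenced"] = True
    return out


def _bucket_edges(width: float, rng: tuple[float, float]) -> np.ndarray:
    left, right = rng
    if width <= 0:
        raise ValueError("bucket width must be > 0")
    if right <= left:
        raise ValueError("range inverted")
    n = int(np.floor((right - left) / width + 1e-9))
    return left + width * np.arange(n + 1)


def bin_spectrum(
    spectrum: Spectrum,
    width: float = 0.015,
    range: tuple[float, float] = (-0.05, 10.0),
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
) -> pd.Series:
    """Integrate a referenced spectrum into equal-width buckets.

    Bucket value = trapezoidal integral over the half-open bucket interval;
    buckets whose interval intersects any exclusion are dropped entirely.
    Returns a Series indexed by bucket centre.
    """
    edges = _bucket_edges(width, range)
    cum = _cumulative(spectrum)
    cum_at_edges = np.interp(edges, spectrum.ppm, cum)
    values = np.diff(cum_at_edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    keep = np.ones(len(centers), dtype=bool)
    for a, b in exclusions:
        keep &= ~((edges[:-1] < b - 1e-12) & (edges[1:] > a + 1e-12))
    return pd.Series(values[keep], index=np.round(centers[keep], 6))


def scale_to_tsp(
    spectrum: Spectrum, region: tuple[float, float] = TSP_REGION
) -> tuple[Spectrum, float]:
    """Divide intensities by the TSP-region integral.

    Returns the scaled spectrum and the TSP area (stored in metadata as
    ``tsp_area`` for later absolute quantitation).  Idempotent: after
    scaling the TSP-region integral is exactly 1.
    """
    area = integrate_region(spectrum, *region)
    if area <= 0:
        raise ValueError(f"TSP region integral is {area:.3g}; cannot scale")
    out = spectrum.copy()
    out.intensity = out.intensity / area
    out.meta["tsp_area"] = area * spectrum.meta.get("tsp_area_cumulative", 1.0)
    out.meta["scaled_to_tsp"] = True
    return out, area


def assemble_bucket_table(
    spectra: list[Spectrum],
    width: float = 0.015,
    range: tuple[float, float] = (-0.05, 10.0),
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
    drop_catechin_bins: bool = False,
    scaled: bool = False,
) -> BucketTable:
    """Bin each spectrum and stack rows into a bucket table.

    Rows are ordered by sample id.  ``drop_catechin_bins`` removes the
    buckets containing the exchangeable catechin shifts (6.09/6.00 ppm),
    the guard against H/D-exchange false positives in fingerprint mining.
    """
    rows = {}
    grid = None
    for spec in spectra:
        s = bin_spectrum(spec, width, range, exclusions)
        if grid is None:
            grid = s.index
        elif not np.array_equal(grid, s.index):
            raise ValueError("mixed bucket grids across spectra")
        sid = spec.meta.get("sample_id", f"sample{len(rows)}")
        rows[sid] = s
    data = pd.DataFrame(rows).T.sort_index()
    table = BucketTable(
        data,
        width,
        tuple(exclusions),
        scaled=scaled,
        tsp_areas={
            s.meta["sample_id"]: s.meta["tsp_area"]
            for s in spectra
            if "tsp_area" in s.meta and "sample_id" in s.meta
        },
    )
    if drop_catechin_bins:
        table = table.drop_catechin_bins()
    return table


def process_spectra(
    spectra: list[Spectrum],
    width: float = 0.015,
    range: tuple[float, float] = (-0.05, 10.0),
    exclusions: tuple[tuple[float, float], ...] = DEFAULT_EXCLUSIONS,
    drop_catechin_bins: bool = False,
) -> BucketTable:
    """Full preprocessing chain: reference -> TSP-scale -> bin -> assemble."""
    processed = []
    for spec in spectra:
        ref = reference_to_tsp(spec)
        scaled, _ = scale_to_tsp(ref)
        processed.append(scaled)
    return assemble_bucket_table(
        processed, width, range, exclusions, drop_catechin_bins, scaled=True
    )
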