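"""Extractable-pool accounting, replicate statistics and metabolite screens.

The extractable metabolite pool -- the dried mass of the 700 uL NMR aliquot
relative to the tissue mass extracted -- varies ~3-fold down the stem, so
per-tissue metabolite trajectories are reported both on an absolute basis
(per g dry tissue) and normalised back to a constant 3 mg pool weight.
A raw top->bottom change smaller than the pool ratio can reverse direction
under normalisation; larger changes keep direction with attenuated
magnitude.

Replicate statistics follow the platform's conventions: technical %RSD is
computed within each biological sample then averaged across samples of a
tissue; genotype screens average technical replicates first, then run a
one-way ANOVA per tissue x position x metabolite and report raw p-values
sorted ascending (an optional Benjamini-Hochberg correction is off by
default).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .library import SignatureLibrary
from .quantify import PrepRecipe

logger = logging.getLogger(__name__)

__all__ = [
    "ExtractRecord",
    "percent_extractable",
    "normalize_to_pool",
    "technical_rsd",
    "oneway_anova",
    "genotype_screen",
    "trajectory",
    "class_totals",
]

POSITION_ORDER = ("bottom", "middle", "top")


@dataclass(frozen=True)
class ExtractRecord:
    sample_id: str
    extract_mass_mg: float
    prep: PrepRecipe = PrepRecipe()

    def __post_init__(self) -> None:
        if self.extract_mass_mg < 0:
            raise ValueError("extract mass must be >= 0")


def percent_extractable(
    record: ExtractRecord | float, prep: PrepRecipe | None = None
) -> float:
    """Extractable pool as % of tissue dry mass.

    The dried aliquot is only ``aliquot/extraction volume`` of the whole
    extract, so the measured mass is scaled up before dividing by the
    tissue mass:  % = m_aliquot * (V_extract / V_aliquot) / m_tissue * 100.
    """
    if isinstance(record, ExtractRecord):
        mass, prep = record.extract_mass_mg, record.prep
    else:
        mass, prep = float(record), prep or PrepRecipe()
    if prep.tissue_mass_mg <= 0:
        raise ValueError("tissue mass must be > 0")
    whole_extract_mg = mass * (prep.extraction_volume_mL * 1000.0 / prep.aliquot_to_nmr_uL)
    return whole_extract_mg / prep.tissue_mass_mg * 100.0


def normalize_to_pool(values, extract_mass_mg: float, target_mg: float = 3.0):
    """Rescale values to a constant extractable-pool mass (default 3 mg)."""
    if extract_mass_mg <= 0:
        raise ValueError("extract mass must be > 0 to normalise (flag the sample)")
    return np.asarray(values, dtype=float) * (target_mg / extract_mass_mg)


def technical_rsd(
    table: pd.DataFrame,
    value_col: str = "conc_tube_mM",
    bio_keys: tuple[str, ...] = ("genotype", "tissue", "position", "biological_rep"),
    tissue_key: str = "tissue",
) -> pd.DataFrame:
    """Average technical %RSD per metabolite per tissue.

    Within each biological sample: RSD = 100 * sd / mean over technical
    replicates (sd with n-1 denominator); then averaged across all samples
    of a tissue.  Undefined RSDs (zero mean) are reported missing.
    """
    def _rsd(x):
        m = x.mean()
        if m == 0 or len(x) < 2:
            return np.nan
        return 100.0 * x.std(ddof=1) / m

    per_bio = (
        table.groupby(list(bio_keys) + ["metabolite"], observed=True)[value_col]
        .apply(_rsd)
        .reset_index(name="rsd")
    )
    out = (
        per_bio.groupby([tissue_key, "metabolite"], observed=True)["rsd"]
        .mean()
        .reset_index(name="mean_rsd_percent")
    )
    return out


def oneway_anova(values, labels) -> tuple[float, float]:
    """Classical one-way ANOVA (F statistic, p from the F distribution)."""
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) < 1 for g in groups):
        raise ValueError("every group needs at least one observation")
    n = len(values)
    df_between = len(groups) - 1
    df_within = n - len(groups)
    if df_within < 1:
        raise ValueError("at least 2 total residual degrees of freedom required")
    grand = values.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ssb <= 0:
        return 0.0, 1.0
    if ssw == 0:
        return float("inf"), 0.0
    f = (ssb / df_between) / (ssw / df_within)
    p = float(sps.f.sf(f, df_between, df_within))
    return float(f), p


def genotype_screen(
    table: pd.DataFrame,
    value_col: str = "conc_tube_mM",
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per tissue x position x metabolite genotype ANOVA screen.

    Technical replicates are averaged into biological means first.  Returns
    columns (tissue, position, metabolite, F, p, significant) sorted
    ascending by p.  Cells with fewer than two genotypes or insufficient
    replication are skipped with a log entry.  ``bh_correction`` adds a
    Benjamini-Hochberg adjusted q column (raw p-values are the default
    screen output).
    """
    if table["genotype"].nunique() < 2:
        return pd.DataFrame(
            columns=["tissue", "position", "metabolite", "F", "p", "significant"]
        )
    bio = (
        table.groupby(
            ["genotype", "tissue", "position", "biological_rep", "metabolite"],
            observed=True,
        )[value_col]
        .mean()
        .reset_index()
    )
    rows = []
    for (tissue, position, metab), cell in bio.groupby(
        ["tissue", "position", "metabolite"], observed=True
    ):
        counts = cell.groupby("genotype", observed=True)[value_col].count()
        if len(counts) < 2 or counts.sum() - len(counts) < 1:
            logger.info(
                "screen: skipping %s/%s/%s (insufficient replication)",
                tissue, position, metab,
            )
            continue
        f, p = oneway_anova(cell[value_col].to_numpy(), cell["genotype"].to_numpy())
        rows.append(
            {"tissue": tissue, "position": position, "metabolite": metab,
             "F": f, "p": p}
        )
    if not rows:
        return pd.DataFrame(
            columns=["tissue", "position", "metabolite", "F", "p", "significant"]
        )
    out = pd.DataFrame(rows).sort_values("p", kind="mergesort").reset_index(drop=True)
    out["significant"] = out["p"] < alpha
    if bh_correction and len(out):
        from statsmodels.stats.multitest import multipletests

        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def trajectory(
    table: pd.DataFrame,
    metabolite: str,
    value_col: str = "conc_tube_mM",
    normalised: bool = False,
    target_mg: float = 3.0,
) -> pd.DataFrame:
    """Positional trajectory of one metabolite per genotype x tissue.

    Technical replicates are averaged; the mean and range (min/max error
    bars -- with two biological replicates a standard deviation would be
    misleading) are computed over biological replicates, ordered bottom,
    middle, top.  The normalised variant rescales each sample to the target
    extractable-pool mass first (requires an ``extract_mass_mg`` column).
    """
    sub = table[table["metabolite"] == metabolite].copy()
    if sub.empty:
        raise KeyError(f"metabolite {metabolite!r} not in table")
    if normalised:
        if "extract_mass_mg" not in sub.columns:
            raise ValueError("normalised trajectory needs extract_mass_mg column")
        sub[value_col] = [
            float(normalize_to_pool(v, m, target_mg))
            for v, m in zip(sub[value_col], sub["extract_mass_mg"])
        ]
    bio = (
        sub.groupby(
            ["genotype", "tissue", "position", "biological_rep"], observed=True
        )[value_col]
        .mean()
        .reset_index()
    )
    agg = (
        bio.groupby(["genotype", "tissue", "position"], observed=True)[value_col]
        .agg(mean="mean", low="min", high="max")
        .reset_index()
    )
    agg["position"] = pd.Categorical(
        agg["position"], categories=list(POSITION_ORDER), ordered=True
    )
    return agg.sort_values(["genotype", "tissue", "position"]).reset_index(drop=True)


def class_totals(
    table: pd.DataFrame,
    library: SignatureLibrary,
    mg_col: str = "conc_mg_per_g",
    extract_pct_col: str = "percent_extractable",
) -> pd.DataFrame:
    """Per-sample compound-class sums (mg/g d.w.) and pool proportions.

    Pool proportion divides each class sum by the extractable pool expressed
    in mg/g d.w. (percent_extractable/100 * 1000); the remainder row is the
    unquantified / NMR-invisible balance, floored at zero with a flag when
    the quantified total exceeds the measured pool.
    """
    classes = {sig.name: sig.compound_class for sig in library}
    unknown = sorted(set(table["metabolite"]) - set(classes))
    if unknown:
        raise KeyError(f"metabolites without a compound class: {unknown}")
    sub = table.copy()
    sub["compound_class"] = sub["metabolite"].map(classes)
    rows = []
    for sid, g in sub.groupby("sample_id", observed=True):
        pool_mg_g = float(g[extract_pct_col].iloc[0]) / 100.0 * 1000.0
        sums = g.groupby("compound_class", observed=True)[mg_col].sum()
        total = float(sums.sum())
        remainder = pool_mg_g - total
        flagged = remainder < 0
        for cls, v in sums.items():
            rows.append(
                {"sample_id": sid, "compound_class": cls, "mg_per_g": float(v),
                 "pool_proportion": float(v) / pool_mg_g,
                 "over_budget": flagged}
            )
        rows.append(
            {"sample_id": sid, "compound_class": "unquantified/NMR-invisible",
             "mg_per_g": max(0.0, remainder),
             "pool_proportion": max(0.0, remainder) / pool_mg_g,
             "over_budget": flagged}
        )
    return pd.DataFrame(rows)
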