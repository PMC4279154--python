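"""Builtin signature library for willow (Salix) polar extracts at 600 MHz.

Covers the abundant primary metabolites of leaf and stem plus the
Salix-specific secondary products (salicin, salicortin, triandrin,
catechin-family flavanols), the d4-TSP reference singlet, and the
Ca-EDTA / free-EDTA peaks introduced by the buffered prep.  Shifts printed
in the source protocol carry provenance "protocol"; everything else is a
standard literature value for pH 7.4 aqueous-methanolic conditions and is
marked "reference".

The catechin C-6/C-8 aromatic protons are flagged exchangeable: in the
buffered deuterated solvent they undergo slow keto-enol-mediated H/D
exchange and their signals decay over ~12 h of standing.
"""

from __future__ import annotations

from .library import (
    Multiplet,
    MetaboliteSignature,
    PhModel,
    SignatureLibrary,
)

SOLVENT_TAG = "D2O:CD3OD 4:1, pH 7.4 phosphate + EDTA, 0.01% d4-TSP"


def _m(center, pattern, j=(), nh=1, fwhm=1.0, **kw) -> Multiplet:
    return Multiplet(
        center_ppm=center,
        pattern=pattern,
        j_hz=list(j),
        n_protons=nh,
        fwhm_hz=fwhm,
        **kw,
    )


def _sig(name, cls, mw, multiplets, ca_sensitive=False) -> MetaboliteSignature:
    return MetaboliteSignature(
        name=name,
        compound_class=cls,
        mw=mw,
        ca_sensitive=ca_sensitive,
        multiplets=multiplets,
    )


def build_library() -> SignatureLibrary:
    P = {"provenance": "protocol"}
    sigs = [
        # --- references / prep additives -------------------------------
        _sig("TSP", "other", 172.27, [_m(0.000, "s", nh=9, **P)]),
        _sig(
            "Ca-EDTA",
            "other",
            348.35,
            [
                _m(3.10, "q", j=(16.0,), nh=8, **P),
                _m(2.55, "s", nh=4, **P),
            ],
        ),
        _sig(
            "EDTA",
            "other",
            292.24,
            [_m(3.61, "s", nh=8), _m(3.18, "s", nh=4)],
        ),
        # --- carbohydrates ----------------------------------------------
        _sig(
            "sucrose",
            "carbohydrate",
            342.30,
            [
                _m(5.410, "d", j=(3.8,), nh=1, **P),
                _m(4.21, "d", j=(8.8,), nh=1),
                _m(4.04, "t", j=(8.5,), nh=1),
                _m(3.75, "m", nh=6),
            ],
        ),
        _sig(
            "glucose",
            "carbohydrate",
            180.16,
            [
                _m(5.220, "d", j=(3.8,), nh=1, **P),  # alpha anomeric
                _m(4.64, "d", j=(7.9,), nh=1),  # beta anomeric
                _m(3.46, "m", nh=4),
            ],
        ),
        _sig(
            "fructose",
            "carbohydrate",
            180.16,
            [_m(4.10, "m", nh=3), _m(3.69, "m", nh=3)],
        ),
        _sig(
            "galactose",
            "carbohydrate",
            180.16,
            [_m(5.26, "d", j=(3.8,), nh=1), _m(4.58, "d", j=(7.9,), nh=1)],
        ),
        _sig(
            "maltose",
            "carbohydrate",
            342.30,
            [_m(5.40, "d", j=(3.9,), nh=1), _m(3.60, "m", nh=3)],
        ),
        _sig(
            "raffinose",
            "carbohydrate",
            504.44,
            [
                _m(5.43, "d", j=(3.9,), nh=1),
                _m(4.99, "d", j=(3.7,), nh=1),
                _m(3.85, "m", nh=4),
            ],
        ),
        _sig(
            "stachyose",
            "carbohydrate",
            666.58,
            [_m(5.04, "d", j=(3.0,), nh=2), _m(3.92, "m", nh=4)],
        ),
        _sig(
            "myo-inositol",
            "carbohydrate",
            180.16,
            [
                _m(4.06, "t", j=(2.8,), nh=1),
                _m(3.62, "dd", j=(10.0, 2.8), nh=2),
                _m(3.52, "dd", j=(10.0, 9.5), nh=2),
                _m(3.27, "t", j=(9.3,), nh=1),
            ],
        ),
        # --- organic acids ----------------------------------------------
        _sig(
            "citrate",
            "organic acid",
            192.12,
            [
                _m(
                    2.70, "ab", j=(15.6,), nh=2,
                    ph_model=PhModel(pka=[6.4], delta_acid=2.85, delta_base=2.685),
                    **P,
                ),
                _m(
                    2.56, "ab", j=(15.6,), nh=2,
                    ph_model=PhModel(pka=[6.4], delta_acid=2.74, delta_base=2.542),
                    **P,
                ),
            ],
            ca_sensitive=True,
        ),
        _sig(
            "malate",
            "organic acid",
            134.09,
            [
                _m(
                    4.30, "dd", j=(10.2, 3.0), nh=1,
                    ph_model=PhModel(pka=[5.1], delta_acid=4.38, delta_base=4.299),
                ),
                _m(2.68, "dd", j=(15.4, 3.0), nh=1),
                _m(2.37, "dd", j=(15.4, 10.2), nh=1),
            ],
            ca_sensitive=True,
        ),
        _sig("succinate", "organic acid", 118.09, [_m(2.41, "s", nh=4)]),
        _sig(
            "ascorbate",
            "organic acid",
            176.12,
            [
                _m(4.52, "d", j=(2.0,), nh=1),
                _m(4.01, "m", nh=1),
                _m(3.73, "m", nh=2),
            ],
        ),
        _sig(
            "lactate",
            "organic acid",
            90.08,
            [_m(4.11, "q", j=(6.9,), nh=1), _m(1.33, "d", j=(6.9,), nh=3)],
        ),
        _sig("fumarate", "organic acid", 116.07, [_m(6.52, "s", nh=2)]),
        _sig("acetate", "organic acid", 60.05, [_m(1.92, "s", nh=3)]),
        _sig(
            "2-oxoglutarate",
            "organic acid",
            146.10,
            [_m(3.00, "t", j=(6.9,), nh=2), _m(2.45, "t", j=(6.9,), nh=2)],
        ),
        _sig(
            "quinate",
            "organic acid",
            192.17,
            [
                _m(4.14, "m", nh=1),
                _m(4.02, "dd", j=(9.5, 3.5), nh=1),
                _m(3.55, "dd", j=(9.5, 3.2), nh=1),
                _m(2.05, "dd", j=(14.5, 3.2), nh=1, **P),
                _m(1.95, "m", nh=2, **P),
                _m(1.87, "dd", j=(13.5, 10.5), nh=1, **P),
            ],
        ),
        _sig("2-hydroxyisobutyrate", "organic acid", 104.10, [_m(1.36, "s", nh=6)]),
        _sig(
            "3-hydroxy-3-methylglutarate",
            "organic acid",
            162.14,
            [_m(2.42, "ab", j=(15.4,), nh=4), _m(1.30, "s", nh=3)],
        ),
        # --- amino acids -------------------------------------------------
        _sig(
            "alanine",
            "amino acid",
            89.09,
            [_m(3.78, "q", j=(7.2,), nh=1), _m(1.48, "d", j=(7.2,), nh=3)],
        ),
        _sig("glycine", "amino acid", 75.07, [_m(3.56, "s", nh=2)]),
        _sig(
            "threonine",
            "amino acid",
            119.12,
            [
                _m(4.25, "m", nh=1),
                _m(3.58, "d", j=(4.9,), nh=1),
                _m(1.32, "d", j=(6.6,), nh=3),
            ],
        ),
        _sig(
            "valine",
            "amino acid",
            117.15,
            [
                _m(2.27, "m", nh=1),
                _m(1.04, "d", j=(7.0,), nh=3),
                _m(0.98, "d", j=(7.0,), nh=3),
            ],
        ),
        _sig(
            "leucine",
            "amino acid",
            131.17,
            [_m(1.70, "m", nh=3), _m(0.95, "m", nh=6)],
        ),
        _sig(
            "isoleucine",
            "amino acid",
            131.17,
            [
                _m(1.97, "m", nh=1),
                _m(1.00, "d", j=(7.0,), nh=3),
                _m(0.93, "t", j=(7.4,), nh=3),
            ],
        ),
        _sig(
            "GABA",
            "amino acid",
            103.12,
            [
                _m(3.01, "t", j=(7.5,), nh=2),
                _m(2.29, "t", j=(7.3,), nh=2),
                _m(1.90, "m", nh=2),
            ],
        ),
        _sig(
            "glutamine",
            "amino acid",
            146.15,
            [_m(3.77, "t", j=(6.2,), nh=1), _m(2.45, "m", nh=2), _m(2.13, "m", nh=2)],
        ),
        _sig(
            "glutamate",
            "amino acid",
            147.13,
            [_m(3.75, "dd", j=(7.2, 4.8), nh=1), _m(2.34, "m", nh=2), _m(2.06, "m", nh=2)],
        ),
        _sig(
            "asparagine",
            "amino acid",
            132.12,
            [
                _m(4.00, "dd", j=(7.6, 4.3), nh=1),
                _m(2.95, "dd", j=(16.9, 4.3), nh=1),
                _m(2.85, "dd", j=(16.9, 7.6), nh=1),
            ],
        ),
        _sig(
            "aspartate",
            "amino acid",
            133.10,
            [
                _m(3.89, "dd", j=(8.9, 3.7), nh=1),
                _m(2.80, "dd", j=(17.4, 3.7), nh=1),
                _m(2.66, "dd", j=(17.4, 8.9), nh=1),
            ],
        ),
        _sig(
            "arginine",
            "amino acid",
            174.20,
            [_m(3.24, "t", j=(6.9,), nh=2), _m(1.91, "m", nh=2), _m(1.68, "m", nh=2)],
        ),
        _sig(
            "lysine",
            "amino acid",
            146.19,
            [_m(3.02, "t", j=(7.6,), nh=2), _m(1.72, "m", nh=2), _m(1.47, "m", nh=2)],
        ),
        _sig(
            "methionine",
            "amino acid",
            149.21,
            [_m(2.64, "t", j=(7.5,), nh=2), _m(2.14, "s", nh=3)],
        ),
        _sig(
            "tryptophan",
            "amino acid",
            204.23,
            [
                _m(7.73, "d", j=(8.0,), nh=1),
                _m(7.54, "d", j=(8.1,), nh=1),
                _m(7.31, "s", nh=1),
            ],
        ),
        _sig(
            "tyrosine",
            "amino acid",
            181.19,
            [_m(7.19, "d", j=(8.5,), nh=2), _m(6.89, "d", j=(8.5,), nh=2)],
        ),
        _sig(
            "phenylalanine",
            "amino acid",
            165.19,
            [_m(7.42, "m", nh=3), _m(7.32, "d", j=(7.3,), nh=2)],
        ),
        # --- aromatics / secondary metabolites ---------------------------
        _sig(
            "catechin",
            "aromatic",
            290.27,
            [
                _m(6.93, "d", j=(1.9,), nh=1, **P),
                _m(6.92, "dd", j=(8.2, 1.9), nh=1, **P),
                _m(6.85, "d", j=(8.2,), nh=1, **P),
                _m(6.09, "d", j=(2.2,), nh=1, exchangeable=True, **P),  # H-6
                _m(6.00, "d", j=(2.2,), nh=1, exchangeable=True, **P),  # H-8
                _m(4.57, "d", j=(7.5,), nh=1),
                _m(2.86, "dd", j=(16.1, 5.4), nh=1, **P),
            ],
        ),
        _sig(
            "gallocatechin",
            "aromatic",
            306.27,
            [
                _m(6.49, "s", nh=2),
                _m(4.54, "d", j=(7.4,), nh=1),
                _m(2.76, "dd", j=(16.2, 5.5), nh=1),
            ],
        ),
        _sig(
            "dihydromyricetin",
            "aromatic",
            320.25,
            [
                _m(6.58, "s", nh=2),
                _m(5.01, "d", j=(11.3,), nh=1),
                _m(4.60, "d", j=(11.3,), nh=1),
            ],
        ),
        _sig(
            "chlorogenic acid",
            "aromatic",
            354.31,
            [
                _m(7.62, "d", j=(15.9,), nh=1),
                _m(7.15, "d", j=(2.0,), nh=1),
                _m(6.95, "d", j=(8.3,), nh=1),
                _m(6.38, "d", j=(15.9,), nh=1),
            ],
        ),
        _sig(
            "salicin",
            "aromatic",
            286.28,
            [
                _m(7.30, "m", nh=2),
                _m(7.10, "m", nh=2),
                _m(4.71, "d", j=(7.3,), nh=1),
            ],
        ),
        _sig(
            "salicortin",
            "aromatic",
            424.40,
            [_m(7.26, "m", nh=2), _m(7.08, "m", nh=2), _m(4.75, "d", j=(7.5,), nh=1)],
        ),
        _sig(
            "triandrin",
            "aromatic",
            312.32,
            [
                _m(7.38, "d", j=(8.6,), nh=2),
                _m(6.98, "d", j=(8.6,), nh=2),
                _m(6.55, "d", j=(16.0,), nh=1),
                _m(6.30, "d", j=(16.0,), nh=1),
            ],
        ),
        _sig(
            "2-phenylethylamine",
            "aromatic",
            121.18,
            [
                _m(7.39, "m", nh=5),
                _m(3.22, "t", j=(7.2,), nh=2),
                _m(2.93, "t", j=(7.2,), nh=2),
            ],
        ),
        _sig(
            "trigonelline",
            "aromatic",
            137.14,
            [
                _m(9.12, "s", nh=1),
                _m(8.83, "m", nh=2),
                _m(8.08, "m", nh=1),
                _m(4.43, "s", nh=3),
            ],
        ),
        _sig(
            "uridine",
            "aromatic",
            244.20,
            [
                _m(7.87, "d", j=(8.1,), nh=1),
                _m(5.90, "m", nh=2),
            ],
        ),
        _sig(
            "3-hydroxymandelate",
            "aromatic",
            168.15,
            [_m(7.35, "m", nh=4), _m(4.95, "s", nh=1)],
        ),
        # --- other -------------------------------------------------------
        _sig("betaine", "other", 117.15, [_m(3.90, "s", nh=2), _m(3.26, "s", nh=9)]),
        _sig("choline", "other", 104.17, [_m(4.06, "m", nh=2), _m(3.20, "s", nh=9)]),
    ]
    lib = SignatureLibrary(field_mhz=600.0, solvent_tag=SOLVENT_TAG, signatures=sigs)
    lib.signatures.sort(key=lambda s: s.name)
    return lib
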