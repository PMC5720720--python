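"""Renal function: the MDRD estimating equation and category codings.

eGFR is estimated with the IDMS-traceable four-variable MDRD study equation

    eGFR = 175 * Scr^-1.154 * age^-0.203 * 0.742^[female] (* 1.212^[black])

in ml/min/1.73m^2, with serum creatinine in mg/dL.  The race coefficient is
off by default and available behind a flag.  Categorical codings for eGFR,
CD4 count and HIV-1 RNA follow the conventional clinical cut-points
(eGFR <=50 / 51-70 / 71-90 / >90; CD4 <=200 / 201-350 / >350;
viral load <=50 / 51-500 / >500).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

EGFR_CATEGORIES = ("<=50", "51-70", "71-90", ">90")
CD4_CATEGORIES = ("<=200", "201-350", ">350")
VL_CATEGORIES = ("<=50", "51-500", ">500")


def mdrd_egfr(scr, age, female, black=False):
    """Four-variable MDRD eGFR (ml/min/1.73m^2).

    Parameters
    ----------
    scr : float or array
        Serum creatinine, mg/dL. Must be positive.
    age : float or array
        Age in years. Must be positive.
    female : bool or array
        Sex indicator (female=True applies the 0.742 factor).
    black : bool or array, optional
        Apply the 1.212 race coefficient (off by default).
    """
    scr = np.asarray(scr, dtype=float)
    age = np.asarray(age, dtype=float)
    if np.any(scr <= 0) or np.any(age <= 0):
        raise ValueError("serum creatinine and age must be positive")
    out = 175.0 * scr ** -1.154 * age ** -0.203
    out = np.where(np.asarray(female, dtype=bool), out * 0.742, out)
    if np.any(black):
        out = np.where(np.asarray(black, dtype=bool), out * 1.212, out)
    return out if out.shape else float(out)


def scr_from_egfr(egfr, age, female):
    """Invert the MDRD equation: creatinine (mg/dL) giving this eGFR."""
    egfr = np.asarray(egfr, dtype=float)
    base = 175.0 * np.asarray(age, dtype=float) ** -0.203
    base = np.where(np.asarray(female, dtype=bool), base * 0.742, base)
    out = (egfr / base) ** (-1.0 / 1.154)
    return out if out.shape else float(out)


def _cut(values, bounds, labels):
    values = np.asarray(values, dtype=float)
    idx = np.searchsorted(bounds, values, side="left")
    return pd.Categorical.from_codes(idx, categories=list(labels), ordered=True)


def egfr_category(egfr):
    """eGFR category: <=50, 51-70, 71-90, >90 ml/min/1.73m^2."""
    return _cut(egfr, [50.0 + 1e-12, 70.0 + 1e-12, 90.0 + 1e-12], EGFR_CATEGORIES)


def cd4_category(cd4):
    """CD4 category: <=200, 201-350, >350 cells/mm^3."""
    return _cut(cd4, [200.0 + 1e-12, 350.0 + 1e-12], CD4_CATEGORIES)


def vl_category(vl_copies):
    """Viral load category: <=50, 51-500, >500 copies/mL."""
    return _cut(vl_copies, [50.0 + 1e-12, 500.0 + 1e-12], VL_CATEGORIES)
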