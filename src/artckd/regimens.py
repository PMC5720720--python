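"""Five-category antiretroviral regimen classification.

Regimens are grouped by whether they contain tenofovir disoproxil fumarate
(TDF) and whether the anchor agent is a ritonavir-boosted protease inhibitor
(rbPI) or a non-nucleoside reverse-transcriptase inhibitor (NNRTI).  Anything
else (e.g. integrase-inhibitor-anchored combinations) is ``OTHER``.
"""

from __future__ import annotations

import warnings

TDF_RBPI = "TDF_rbPI"
TDF_NNRTI = "TDF_NNRTI"
NOTDF_RBPI = "noTDF_rbPI"
NOTDF_NNRTI = "noTDF_NNRTI"
OTHER = "OTHER"

#: Categories in the order used for initial-regimen shares and reports.
CATEGORIES = (TDF_NNRTI, TDF_RBPI, NOTDF_NNRTI, NOTDF_RBPI, OTHER)

#: Reference category for every hazard-ratio contrast.
REFERENCE_CATEGORY = TDF_NNRTI

# Drug-class lookup.  Codes are matched case-insensitively; common full names
# are accepted as aliases of the three-letter codes.
NNRTI_DRUGS = {"EFV", "NVP", "ETR", "RPV"}
PI_DRUGS = {"DRV", "ATV", "LPV", "FPV", "SQV", "TPV", "IDV", "NFV"}
BOOSTERS = {"RTV"}
TDF_CODES = {"TDF"}

_ALIASES = {
    "EFAVIRENZ": "EFV",
    "NEVIRAPINE": "NVP",
    "ETRAVIRINE": "ETR",
    "RILPIVIRINE": "RPV",
    "DARUNAVIR": "DRV",
    "ATAZANAVIR": "ATV",
    "LOPINAVIR": "LPV",
    "FOSAMPRENAVIR": "FPV",
    "SAQUINAVIR": "SQV",
    "TIPRANAVIR": "TPV",
    "INDINAVIR": "IDV",
    "NELFINAVIR": "NFV",
    "RITONAVIR": "RTV",
    "TENOFOVIR": "TDF",
}

# Backbone / other agents we recognise but that never decide the category.
_NEUTRAL = {
    "FTC", "3TC", "ABC", "AZT", "ZDV", "DDI", "D4T", "RAL", "DTG", "EVG",
    "MVC", "ENF", "T20", "COBI",
}


def _canonical(code: str) -> str:
    c = str(code).strip().upper()
    return _ALIASES.get(c, c)


def classify_regimen(drug_components) -> str:
    """Map a set of drug codes to one of the five regimen categories.

    The category is decided by TDF presence and by the presence of a
    ritonavir-boosted PI (a PI plus ritonavir) or, failing that, an NNRTI.
    A boosted PI takes precedence if both anchors are present.  Unknown codes
    are ignored with a warning.
    """
    comps = {_canonical(c) for c in drug_components if str(c).strip()}
    if not comps:
        raise ValueError("empty drug component set")
    unknown = comps - NNRTI_DRUGS - PI_DRUGS - BOOSTERS - TDF_CODES - _NEUTRAL
    if unknown:
        warnings.warn(
            f"unknown drug code(s) {sorted(unknown)}; classifying on known components",
            stacklevel=2,
        )
        comps -= unknown
    has_tdf = bool(comps & TDF_CODES)
    has_rbpi = bool(comps & PI_DRUGS) and bool(comps & BOOSTERS)
    has_nnrti = bool(comps & NNRTI_DRUGS)
    if has_rbpi:
        return TDF_RBPI if has_tdf else NOTDF_RBPI
    if has_nnrti:
        return TDF_NNRTI if has_tdf else NOTDF_NNRTI
    return OTHER


def parse_drug_field(field: str):
    """Split a ``'TDF+FTC+DRV+RTV'``-style string into components."""
    return [p for p in str(field).replace(",", "+").split("+") if p.strip()]


#: Representative combinations written by the simulator for each category.
REPRESENTATIVE_DRUGS = {
    TDF_NNRTI: "TDF+FTC+EFV",
    TDF_RBPI: "TDF+FTC+DRV+RTV",
    NOTDF_NNRTI: "ABC+3TC+NVP",
    NOTDF_RBPI: "ABC+3TC+LPV+RTV",
    OTHER: "TDF+FTC+RAL",
}
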