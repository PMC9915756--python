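"""Built-in NSCLC immunomonitoring cohort data.

Per-antigen responder tallies and clinical characteristics from a
26-patient NSCLC cohort whose PBMCs were expanded against a 14-antigen
HLA-A*02:01 peptide panel, plus the 8 additional patients used for the
anti-PD-1 combination experiments. These printed tallies serve as the
package's worked example and as desk-checkable inputs for the cohort
arithmetic: denominators differ between antigens because not every
patient was tested on every peptide mix.
"""

from __future__ import annotations

import pandas as pd

DISCOVERY_COHORT_SIZE = 26

#: antigen → (n responders, n patients tested)
ANTIGEN_RESPONSE_TALLIES: dict[str, tuple[int, int]] = {
    "MAGE-A1": (0, 14),
    "MAGE-A2": (9, 14),
    "MAGE-A3.1": (1, 14),
    "MAGE-A3.2": (9, 26),
    "MAGE-A4": (6, 14),
    "MAGE-A9": (9, 14),
    "MAGE-A10": (4, 14),
    "NY-ESO-1": (5, 14),
    "CAMEL": (6, 14),
    "GLULD1": (4, 14),
    "SURVIVIN": (7, 12),
    "HER2": (4, 26),
    "MUC-1": (3, 26),
    "WT-1": (1, 12),
}

#: patients responding to at least one tumor antigen
AT_LEAST_ONE_TALLY: tuple[int, int] = (22, 26)

_CLINICAL_ROWS = [
    ("1", "SCC", "IIB", "Active"),
    ("2", "AC", "IIIA", "Active"),
    ("3", "SCC", "IA", "Active"),
    ("4", "AC", "IA", "Former"),
    ("5", "AC", "IIA", "Non-smoker"),
    ("6", "TC", "IB", "Former"),
    ("7", "SCC", "IIA", "Active"),
    ("8", "SCC", "IB", "Active"),
    ("9", "AC", "IIIA", "Active"),
    ("10", "AC", "IIB", "Former"),
    ("11", "AC", "IIIA", "Active"),
    ("12", "AC", "IIIA", "Active"),
    ("13", "AC", "IA", "Active"),
    ("14", "AC", "IV", "Active"),
    ("15", "LCNC", "IIIA", "Active"),
    ("16", "AC", "IIB", "Active"),
    ("17", "AC", "IA", "Active"),
    ("18", "AC", "IB", "Active"),
    ("19", "SCC", "IIB", "Active"),
    ("20", "AC", "IB", "Former"),
    ("21", "AC", "IIA", "Active"),
    ("22", "AC", "IA", "Active"),
    ("23", "TC", "IA", "Active"),
    ("24", "AC", "nd", "Former"),
    ("25", "SCC", "nd", "Unknown"),
    ("26", "AC", "II", "Former"),
    ("27", "SCC", "IIB", "Active"),
    ("28", "SCC", "IIIA", "Active"),
    ("29", "AC", "IIb", "Former"),
    ("30", "AC", "IIB", "Former"),
    ("31", "AC", "IIA", "Former"),
    ("32", "AC", "IB", "Former"),
    ("33", "AC", "IIB", "Non-smoker"),
    ("34", "SCC", "IV", "Former"),
]


def clinical_table() -> pd.DataFrame:
    """Clinical characteristics of all 34 patients, indexed by patient id.

    Histology codes: AC adenocarcinoma, SCC squamous cell carcinoma,
    TC typical carcinoid, LCNC large-cell neuroendocrine carcinoma.
    """
    frame = pd.DataFrame(_CLINICAL_ROWS, columns=["patient_id", "histology", "stage", "smoking"])
    return frame.set_index("patient_id")


def discovery_cohort() -> pd.DataFrame:
    """Clinical table restricted to the 26 immunomonitoring patients."""
    return clinical_table().iloc[:DISCOVERY_COHORT_SIZE]


def ici_cohort() -> pd.DataFrame:
    """Clinical table restricted to the 8 anti-PD-1 combination patients."""
    return clinical_table().iloc[DISCOVERY_COHORT_SIZE:]
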