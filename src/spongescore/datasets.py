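"""Bundled reference tables.

Currently one dataset: the published table of 12 candidate miRNA
biomarkers for prostate cancer metastasis, with each miRNA's
differential-expression call between primary (pPCa) and metastatic (mPCa)
tumours, its NSR counts with their significance in the mPCa-specific
ceRNA network, and its ROC AUC for separating the two groups.  Used for
worked examples and for checking the model's definitional identities
against published values.
"""

from __future__ import annotations

import pandas as pd

_CANDIDATE_ROWS = [
    # mirna_id, de_adj_p, log2_fc, nsr_mrna, p_mrna, nsr_lncrna, p_lncrna,
    # nsr_sponge, p_sponge, auc
    ("miR-23b-3p", 2.76e-16, -1.9452, 9, 4.02e-16, 21, 8.52e-13, 30, 1.43e-14, 0.9567),
    ("miR-204-5p", 3.43e-08, -2.0896, 13, 1.39e-17, 12, 4.25e-08, 25, 2.14e-12, 0.8506),
    ("miR-26b-5p", 2.75e-07, -1.6402, 10, 1.25e-16, 15, 1.91e-11, 25, 2.14e-12, 0.7489),
    ("miR-27b-3p", 1.22e-14, -1.7558, 12, 2.78e-17, 12, 4.25e-08, 24, 2.19e-12, 0.9574),
    ("miR-145-5p", 8.00e-25, -3.2157, 4, 5.89e-06, 16, 7.45e-12, 20, 7.79e-11, 0.9928),
    ("miR-29b-3p", 4.49e-06, -1.0465, 4, 5.89e-06, 14, 1.60e-10, 18, 1.44e-09, 0.7468),
    ("miR-143-3p", 9.38e-29, -4.0419, 3, 4.25e-04, 14, 1.60e-10, 17, 1.21e-08, 0.9942),
    ("miR-130a-3p", 2.43e-17, -1.9649, 3, 4.25e-04, 12, 4.25e-08, 15, 1.41e-06, 0.9365),
    ("miR-363-3p", 4.45e-08, -2.0687, 4, 5.89e-06, 11, 9.37e-07, 15, 1.41e-06, 0.7792),
    ("miR-218-5p", 7.87e-11, -1.6984, 4, 5.89e-06, 9, 1.14e-03, 13, 1.92e-04, 0.8709),
    ("miR-30c-5p", 2.16e-07, -1.0445, 4, 5.89e-06, 9, 1.14e-03, 13, 1.92e-04, 0.8225),
    ("miR-101-3p", 1.26e-08, -1.0684, 3, 4.25e-04, 8, 2.07e-02, 11, 1.16e-02, 0.7915),
]

_COLUMNS = [
    "mirna_id",
    "de_adj_p",
    "log2_fc",
    "nsr_mrna",
    "p_mrna",
    "nsr_lncrna",
    "p_lncrna",
    "nsr_sponge",
    "p_sponge",
    "auc",
]


def load_candidate_biomarkers() -> pd.DataFrame:
    """The published prostate-cancer-metastasis candidate miRNA table.

    All 12 candidates are down-regulated in the metastatic group
    (negative log2FC); NSR counts refer to the mPCa-specific ceRNA
    network.
    """
    return pd.DataFrame(_CANDIDATE_ROWS, columns=_COLUMNS)
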