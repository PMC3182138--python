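"""Bundled reference expression tables from the cowpea drought experiment.

Normalized expression (TPTM) of mature miRNAs in two cowpea genotypes —
IT93K503-1 (drought-tolerant, libraries 503-C/503-D) and CB46
(drought-sensitive, CB46-C/CB46-D) — under control (C) and drought (D)
growth conditions, together with the published log2 ratios and Bonferroni-
adjusted Audic-Claverie p-values.  These small tables are inputs for
re-deriving the fold-change columns and the two-fold-in-one-genotype-only
classifications from the TPTM values alone.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

TPTM_COLUMNS = ["IT_C", "IT_D", "CB_C", "CB_D"]

# miRNAs with genotype-specific expression (mature sequence, TPTM x4)
_GENOTYPE_SPECIFIC = [
    ("vun_cand058", "UUAAGCAGAAUGAUCAAAUUG", 942, 1546, 3, 0),
    ("vun_cand048", "UGGUCUCUAAACUUUAGAAAUGAA", 746, 263, 0, 2),
    ("vun_cand036", "UCAGAGGAAACAACACUUGUAC", 59, 23, 0, 0),
    ("vun_cand045", "CGUGCUGAGAAAGUUGCUUCU", 52, 79, 14, 5),
    ("vun_cand053", "GUAAUUGAGUUAAAAGGACUAUAU", 43, 6, 0, 2),
    ("vun_cand052", "CGAGAGCCACUCGCCUAAGCGA", 34, 55, 0, 0),
    ("vun_cand055", "CCACUGUAGUAGCUCUCGCUCA", 30, 40, 0, 0),
    ("vun_cand054", "AGCAAGUUGAGGAUGGAGCUU", 9, 48, 231, 252),
    ("vun_cand014", "UUCGGGAGUGAGAGCCAGUGA", 3, 0, 56, 5),
]

# at least two-fold change under drought only in IT93K503-1
# (id, TPTM x4, published log2 503-D/503-C, log2 CB46-D/CB46-C,
#  adjusted p 503, adjusted p CB46)
_TWOFOLD_ONLY_TOLERANT = [
    ("miR1515", 489, 1366, 1415, 2700, 1.48, 0.93, 5e-63, 4e-60),
    ("miR160a", 437, 877, 1048, 1102, 1.01, 0.07, 3e-21, 1.0),
    ("miR160b", 13, 244, 139, 178, 4.18, 0.35, 9e-36, 1.0),
    ("miR167b", 1649, 4488, 7539, 13930, 1.44, 0.89, 2e-201, 1e-288),
    ("miR171e", 25, 137, 59, 43, 2.44, -0.45, 4e-11, 1.0),
    ("miR319b", 1019, 2638, 685, 1215, 1.37, 0.83, 5e-109, 2e-21),
    ("miR390a", 2141, 7242, 3586, 5308, 1.76, 0.57, 0.0, 3e-49),
    ("vun_cand009", 582, 1519, 1025, 1903, 1.38, 0.89, 4e-63, 4e-39),
    ("vun_cand015", 62, 297, 61, 96, 2.25, 0.66, 2e-23, 1.0),
    ("vun_cand020", 4462, 12349, 6115, 10535, 1.47, 0.78, 0.0, 6e-177),
    ("vun_cand033", 478, 172, 96, 113, -1.48, 0.23, 0.0, 1.0),
    ("vun_cand048", 746, 263, 0, 2, -1.51, np.nan, 0.0, 1.0),
]

# at least two-fold change under drought only in CB46
_TWOFOLD_ONLY_SENSITIVE = [
    ("miR166a", 7796, 12734, 7334, 21341, 0.71, 1.54, 4e-177, 0.0),
    ("miR171b", 406, 441, 195, 397, 0.12, 1.02, 1.0, 3e-09),
    ("miR171d", 58, 55, 85, 215, -0.08, 1.33, 1.0, 2e-07),
    ("miR2111a", 458, 678, 191, 1105, 0.57, 2.53, 5e-05, 1e-106),
    ("miR2111b", 241, 340, 107, 333, 0.50, 1.64, 0.48, 4e-17),
    ("miR390b", 52, 33, 110, 34, -0.65, -1.69, 1.0, 8e-05),
    ("miR393", 392, 400, 1120, 258, 0.03, -2.12, 1.0, 0.0),
    ("miR396b", 4517, 2958, 5165, 2411, -0.61, -1.10, 0.0, 0.0),
    ("miR482", 19518, 10487, 49339, 13487, -0.90, -1.87, 0.0, 0.0),
    ("vun_cand030", 848, 431, 531, 196, -0.98, -1.44, 0.0, 0.0),
]


def genotype_specific_mirnas() -> pd.DataFrame:
    """TPTM of the nine miRNAs expressed predominantly in one genotype."""
    return pd.DataFrame(
        [r[2:] for r in _GENOTYPE_SPECIFIC],
        index=pd.Index([r[0] for r in _GENOTYPE_SPECIFIC], name="id"),
        columns=TPTM_COLUMNS,
    ).assign(mature=[r[1] for r in _GENOTYPE_SPECIFIC])


def _build(rows) -> pd.DataFrame:
    cols = TPTM_COLUMNS + ["log2_IT", "log2_CB", "p_adj_IT", "p_adj_CB"]
    return pd.DataFrame(
        [r[1:] for r in rows],
        index=pd.Index([r[0] for r in rows], name="id"),
        columns=cols,
    )


def twofold_only_tolerant() -> pd.DataFrame:
    """miRNAs reported as >= two-fold drought-changed only in IT93K503-1."""
    return _build(_TWOFOLD_ONLY_TOLERANT)


def twofold_only_sensitive() -> pd.DataFrame:
    """miRNAs reported as >= two-fold drought-changed only in CB46."""
    return _build(_TWOFOLD_ONLY_SENSITIVE)


# rows whose published log2 column agrees with the value recomputed from the
# rounded TPTM columns at 2 decimals (the remaining rows were evidently
# computed from raw counts before TPTM rounding)
FOLD_CHANGE_CHECK_ROWS = [
    ("miR1515", "IT"),
    ("miR166a", "CB"),
    ("miR2111a", "CB"),
    ("miR393", "CB"),
    ("miR482", "CB"),
]
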