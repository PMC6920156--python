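"""Shared genotype encoding.

Genotypes are encoded as the count of male-parent (M) alleles carried:

====  =====  =========================================
code  label  meaning
====  =====  =========================================
2     MM     homozygous for the male-parent allele
1     MF     heterozygous
0     FF     homozygous for the female-parent allele
-1    NA     missing / uncallable
====  =====  =========================================

The integer form makes the additive dosage ``code - 1`` and keeps
bin-by-individual matrices compact (int8).
"""

from __future__ import annotations

import numpy as np

FF: int = 0
MF: int = 1
MM: int = 2
MISSING: int = -1

CODE_TO_LABEL = {FF: "FF", MF: "MF", MM: "MM", MISSING: "NA"}
LABEL_TO_CODE = {v: k for k, v in CODE_TO_LABEL.items()}


def labels_to_codes(labels) -> np.ndarray:
    """Vectorized ``{"MM","MF","FF","NA"} -> {2,1,0,-1}``."""
    out = np.empty(len(labels), dtype=np.int8)
    for i, lab in enumerate(labels):
        try:
            out[i] = LABEL_TO_CODE[lab]
        except KeyError:
            raise ValueError(f"unknown genotype label: {lab!r}") from None
    return out


def codes_to_labels(codes) -> list[str]:
    return [CODE_TO_LABEL[int(c)] for c in codes]
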