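"""Published verification-table inputs.

The study's verification stage reports, for the major locus (called "17",
genotypes GG/TG/TT) and the helper locus ("14", CC/CT/TT), the class sizes
and the number of individuals above the 500 g threshold in each two-locus
class.  Those printed counts are reference inputs: reconstructing one
individual per count lets the summary operations be checked against the
published frequencies to 2 decimals.
"""

from __future__ import annotations

import pandas as pd

# (major genotype, helper genotype) -> (n, n with weight > 500 g)
PUBLISHED_CLASS_COUNTS: dict[tuple[str, str], tuple[int, int]] = {
    ("GG", "CC"): (27, 23),
    ("GG", "CT"): (61, 42),
    ("GG", "TT"): (28, 25),
    ("TG", "CC"): (67, 42),
    ("TG", "CT"): (110, 67),
    ("TG", "TT"): (50, 29),
    ("TT", "CC"): (23, 7),
    ("TT", "CT"): (52, 18),
    ("TT", "TT"): (24, 5),
}

FAMILY_SIZE = 442
FAMILY_OVER_500 = 258


def reconstruct_verification_family() -> pd.DataFrame:
    """Per-individual reconstruction of the printed class counts.

    Weights are placed on either side of the 500 g threshold (600 vs 400 g)
    so every class reproduces its printed n and n>500 g exactly; lengths get
    a constant placeholder.  Columns: individual_id, gt17, gt14, weight_g,
    length_mm.
    """
    rows = []
    i = 0
    for (g17, g14), (n, n_over) in PUBLISHED_CLASS_COUNTS.items():
        for k in range(n):
            rows.append(
                {
                    "individual_id": f"T{i:04d}",
                    "gt17": g17,
                    "gt14": g14,
                    "weight_g": 600.0 if k < n_over else 400.0,
                    "length_mm": 280.0,
                }
            )
            i += 1
    df = pd.DataFrame(rows)
    assert len(df) == FAMILY_SIZE
    assert int((df.weight_g > 500).sum()) == FAMILY_OVER_500
    return df
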