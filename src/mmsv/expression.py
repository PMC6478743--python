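"""Immunoglobulin isotype and light-chain calls from expression values.

The heavy-chain isotype is the most highly expressed constant region,
accepted only when it reaches 5000 FPKM; the light chain is whichever of
the cumulative IgK and IgL (variable + joining + constant) expressions is
higher, with no minimum by default.
"""

from __future__ import annotations

import pandas as pd

from .model import ValidationError, warn

MIN_ISOTYPE_FPKM = 5000.0

#: IgH constant regions in genomic order (used for deterministic tie-breaks).
IGH_CONSTANT_ORDER = ["IGHM", "IGHG3", "IGHG1", "IGHA1", "IGHG2", "IGHA2"]


def call_heavy_isotype(
    constant_fpkm: dict[str, float] | pd.Series,
    min_fpkm: float = MIN_ISOTYPE_FPKM,
    genomic_order: list[str] = IGH_CONSTANT_ORDER,
) -> str | None:
    """Most highly expressed IgH constant region, or None below ``min_fpkm``.

    An exact tie at the maximum resolves to the first region in genomic
    order, with a warning.
    """
    fpkm = dict(constant_fpkm)
    if any(v < 0 for v in fpkm.values()):
        raise ValidationError("negative FPKM")
    if not fpkm:
        return None
    best = max(fpkm.values())
    if best < min_fpkm:
        return None
    winners = [k for k, v in fpkm.items() if v == best]
    if len(winners) > 1:
        ordered = sorted(
            winners,
            key=lambda k: genomic_order.index(k) if k in genomic_order else len(genomic_order),
        )
        warn(f"isotype tie between {winners}; taking {ordered[0]} (genomic order)")
        return ordered[0]
    return winners[0]


def call_light_chain(igk_cumulative_fpkm: float, igl_cumulative_fpkm: float) -> str:
    """'kappa' iff cumulative IgK expression exceeds IgL; ties go to lambda
    (arbitrary, warned)."""
    if igk_cumulative_fpkm < 0 or igl_cumulative_fpkm < 0:
        raise ValidationError("negative FPKM")
    if igk_cumulative_fpkm == igl_cumulative_fpkm:
        warn("IgK and IgL cumulative FPKM tie; calling lambda")
        return "lambda"
    return "kappa" if igk_cumulative_fpkm > igl_cumulative_fpkm else "lambda"


def call_expression_table(
    table: pd.DataFrame,
    constant_cols: list[str] = IGH_CONSTANT_ORDER,
    igk_col: str = "IGK",
    igl_col: str = "IGL",
    min_fpkm: float = MIN_ISOTYPE_FPKM,
) -> pd.DataFrame:
    """Per-sample isotype and light-chain calls for a sample x feature FPKM table."""
    rows = []
    for sample, row in table.iterrows():
        isotype = call_heavy_isotype(
            {c: row[c] for c in constant_cols if c in row}, min_fpkm=min_fpkm
        )
        rows.append(
            {
                "sample": sample,
                "isotype": isotype if isotype is not None else "none",
                "light_chain": call_light_chain(row[igk_col], row[igl_col]),
            }
        )
    return pd.DataFrame(rows)
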