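"""Study-style summary outputs: recurrence matrices and validation rates."""

from __future__ import annotations

from typing import Iterable, Optional, Union

import pandas as pd

from .effects import is_non_silent

#: gene x sample cell vocabulary, most severe first (one cell per gene-sample)
RECURRENCE_SEVERITY = (
    "homozygous_deletion",
    "amplification",
    "hom_stopgain_or_indel",
    "het_stopgain_or_indel",
    "hom_nonsyn_SNV",
    "het_nonsyn_SNV",
)

_TRUNCATING = {
    "stopgain_SNV",
    "stoploss_SNV",
    "frameshift_deletion",
    "frameshift_insertion",
    "nonframeshift_deletion",
    "nonframeshift_insertion",
    "splicing",
}


def _mutation_cell(category: str, zygosity: str) -> Optional[str]:
    if category == "nonsynonymous_SNV":
        return "hom_nonsyn_SNV" if zygosity == "homozygous" else "het_nonsyn_SNV"
    if category in _TRUNCATING:
        return (
            "hom_stopgain_or_indel"
            if zygosity == "homozygous"
            else "het_stopgain_or_indel"
        )
    return None


def recurrence_matrix(
    variants: pd.DataFrame,
    gene_cnv_calls: Optional[pd.DataFrame] = None,
    min_samples: int = 2,
    integrated: bool = False,
) -> pd.DataFrame:
    """Gene x sample aberration matrix.

    ``variants`` needs columns sample, gene, category, zygosity (non-silent
    somatic calls).  With ``integrated=True``, ``gene_cnv_calls`` (columns
    sample, gene, status with amplification/homozygous_deletion rows)
    contributes copy-number cells.  Genes are retained when aberrant in at
    least ``min_samples`` samples; when a gene-sample pair has several
    aberrations the most severe is displayed.  Output is deterministic and
    independent of input row order.
    """
    cells: dict[tuple[str, str], str] = {}

    def put(gene: str, sample: str, cell: str) -> None:
        if not gene:
            return
        key = (gene, sample)
        old = cells.get(key)
        if old is None or RECURRENCE_SEVERITY.index(cell) < RECURRENCE_SEVERITY.index(old):
            cells[key] = cell

    for row in variants.itertuples(index=False):
        if not is_non_silent(row.category):
            continue
        cell = _mutation_cell(row.category, row.zygosity)
        if cell is not None:
            put(row.gene, row.sample, cell)

    if integrated and gene_cnv_calls is not None:
        for row in gene_cnv_calls.itertuples(index=False):
            if row.status in ("amplification", "homozygous_deletion"):
                put(row.gene, row.sample, row.status)

    samples = sorted({s for _, s in cells})
    genes = sorted({g for g, _ in cells})
    matrix = pd.DataFrame("none", index=genes, columns=samples)
    for (g, s), cell in cells.items():
        matrix.loc[g, s] = cell
    aberrant = (matrix != "none").sum(axis=1)
    return matrix[aberrant >= min_samples]


SANGER_OUTCOMES = ("somatic", "germline", "wildtype", "different_mutation")


def sanger_concordance(validation_table: Union[pd.DataFrame, Iterable[dict]]) -> pd.DataFrame:
    """Validated/analyzed counts and rates from a Sanger validation table.

    Input rows: sample, tier (free-form, e.g. high/low), category,
    outcome (somatic | germline | wildtype | different_mutation).  A variant
    counts as validated when the outcome is somatic.  Rates are
    100 * validated / analyzed, rounded to one decimal; pooled rates are
    ratios of summed counts, never means of per-sample rates.  Zero
    analyzed leaves the rate not applicable (NaN).
    """
    df = pd.DataFrame(validation_table)
    bad = set(df["outcome"]) - set(SANGER_OUTCOMES)
    if bad:
        raise ValueError(f"unknown Sanger outcome labels: {sorted(bad)}")
    df["validated"] = (df["outcome"] == "somatic").astype(int)

    def rate(sub: pd.DataFrame) -> dict:
        analyzed = len(sub)
        validated = int(sub["validated"].sum())
        return {
            "validated": validated,
            "analyzed": analyzed,
            "rate_percent": round(100.0 * validated / analyzed, 1) if analyzed else float("nan"),
        }

    rows = []
    for tier, tier_df in df.groupby("tier", sort=True):
        rows.append({"tier": tier, "group": "pooled", **rate(tier_df)})
        for sample, s_df in tier_df.groupby("sample", sort=True):
            rows.append({"tier": tier, "group": f"sample:{sample}", **rate(s_df)})
        for cat, c_df in tier_df.groupby("category", sort=True):
            rows.append({"tier": tier, "group": f"category:{cat}", **rate(c_df)})
    return pd.DataFrame(rows, columns=["tier", "group", "validated", "analyzed", "rate_percent"])
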