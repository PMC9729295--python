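"""Quantitative pull-down (AP-MS) interactor enrichment.

Bait pull-downs (e.g. anti-filamin A, anti-tubulin) are compared with IgG
isotype-control pull-downs.  Non-detected proteins (0 psm) are first
transformed to 1 psm so ratios are defined; each bait/control replicate pair
is then normalised by the median of the protein-wise ratios (scaling the bait
intensities, so the post-normalisation median ratio is 1).  Each protein is
placed on a scatter with x = log2 of the average bait/IgG ratio and
y = log10 of the sum of the average intensities, and flagged as a candidate
interactor when it shows evidence of specificity (x > 2 or never detected in
IgG) together with an abundance floor (>= 3 psm total in bait, or >= 1 psm in
every bait replicate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_LOG2_THRESHOLD = 2.0
DEFAULT_MIN_PSM_BAIT = 3
DEFAULT_MIN_PSM_EACH_REP = 1


@dataclass(frozen=True)
class PulldownTable:
    """Per-protein bait and IgG-control intensities with replicates.

    ``bait`` and ``igg`` are DataFrames indexed by protein_id with one column
    per replicate (equal replicate counts).  ``igg_undetected`` records, per
    protein, whether all IgG replicates were 0 *before* any zero
    substitution; it is filled by :func:`zero_substitute`.
    """

    bait: pd.DataFrame
    igg: pd.DataFrame
    cell_line: str = ""
    bait_name: str = ""
    igg_undetected: pd.Series | None = field(default=None, compare=False)
    #: bait values before substitution/normalisation (psm floors use these)
    bait_raw: pd.DataFrame | None = field(default=None, compare=False)
    substituted: bool = False
    normalized: bool = False

    def __post_init__(self):
        if self.bait.shape[1] < 1 or self.bait.shape != self.igg.shape:
            raise ValidationError("bait and igg need identical shape with >=1 replicate")
        if not self.bait.index.equals(self.igg.index):
            raise ValidationError("bait and igg must share the protein index")
        if (self.bait.to_numpy() < 0).any() or (self.igg.to_numpy() < 0).any():
            raise ValidationError("intensities must be nonnegative")

    @property
    def proteins(self) -> list[str]:
        return list(self.bait.index)

    @property
    def n_replicates(self) -> int:
        return self.bait.shape[1]


@dataclass(frozen=True)
class PulldownPoint:
    protein_id: str
    x: float  # log2 average bait/IgG ratio
    y: float  # log10 (average bait + average IgG intensity)
    is_candidate: bool
    igg_undetected: bool


def zero_substitute(table: PulldownTable) -> PulldownTable:
    """Transform every 0 intensity to 1 (idempotent), recording which proteins
    were entirely undetected in the IgG control beforehand."""
    if table.igg_undetected is not None:
        undetected = table.igg_undetected
    else:
        undetected = (table.igg == 0).all(axis=1)
    return replace(
        table,
        bait=table.bait.where(table.bait != 0, 1.0).astype(float),
        igg=table.igg.where(table.igg != 0, 1.0).astype(float),
        igg_undetected=undetected,
        bait_raw=table.bait_raw if table.bait_raw is not None else table.bait.copy(),
        substituted=True,
    )


def normalize_median_ratio(table: PulldownTable) -> PulldownTable:
    """Divide each replicate pair's ratios by their median, scaling bait.

    Requires zero substitution first.  With fewer than 3 proteins the
    normalisation is skipped with a warning.  Idempotent up to floating
    point: the median ratio after normalisation is exactly 1 for odd protein
    counts and the midpoint-convention value for even counts.
    """
    if not table.substituted:
        raise ValidationError("apply zero_substitute before normalisation")
    if len(table.proteins) < 3:
        logger.warning("normalize_median_ratio: <3 proteins, skipping")
        return table
    bait = table.bait.copy()
    for col_b, col_i in zip(bait.columns, table.igg.columns):
        ratios = bait[col_b] / table.igg[col_i]
        med = float(np.median(ratios))
        if med <= 0:
            raise ValidationError(f"nonpositive median ratio in replicate {col_b!r}")
        bait[col_b] = bait[col_b] / med
    return replace(table, bait=bait, normalized=True)


def score_and_filter(
    table: PulldownTable,
    log2_threshold: float = DEFAULT_LOG2_THRESHOLD,
    min_psm_bait: float = DEFAULT_MIN_PSM_BAIT,
    min_psm_each_rep: float = DEFAULT_MIN_PSM_EACH_REP,
) -> list[PulldownPoint]:
    """Scatter coordinates and candidate calls for every protein.

    is_candidate = (x > log2_threshold OR undetected in IgG)
                   AND (bait total >= min_psm_bait
                        OR every bait replicate >= min_psm_each_rep).
    The abundance clause applies to both evidence branches (so a 1-psm
    IgG-absent protein is not called) and is evaluated on the raw bait psm
    values, before zero substitution or normalisation.
    """
    if not table.normalized:
        raise ValidationError("apply normalize_median_ratio before scoring")
    assert table.igg_undetected is not None and table.bait_raw is not None
    bait_avg = table.bait.mean(axis=1)
    igg_avg = table.igg.mean(axis=1)
    x = np.log2(bait_avg / igg_avg)
    y = np.log10(bait_avg + igg_avg)
    bait_total = table.bait_raw.sum(axis=1)
    every_rep = (table.bait_raw >= min_psm_each_rep).all(axis=1)
    evidence = (x > log2_threshold) | table.igg_undetected
    abundance = (bait_total >= min_psm_bait) | every_rep
    cand = evidence & abundance
    return [
        PulldownPoint(
            protein_id=str(pid), x=float(x[pid]), y=float(y[pid]),
            is_candidate=bool(cand[pid]),
            igg_undetected=bool(table.igg_undetected[pid]),
        )
        for pid in table.proteins
    ]


def prepare(table: PulldownTable) -> PulldownTable:
    """Convenience: zero substitution followed by median-ratio normalisation."""
    return normalize_median_ratio(zero_substitute(table))


def compare_cell_lines(table_a: PulldownTable, table_b: PulldownTable,
                       protein_id: str) -> float:
    """Fold change of a protein's average bait-bound intensity, line B over A.

    Both tables are zero-substituted and normalised first if needed; a protein
    absent from one table contributes intensity 1 (the substitution rule).
    """
    in_a = protein_id in table_a.bait.index
    in_b = protein_id in table_b.bait.index
    if not in_a and not in_b:
        raise KeyError(f"protein {protein_id!r} in neither table")

    def avg(table: PulldownTable, present: bool) -> float:
        if not present:
            return 1.0
        t = table if table.normalized else prepare(table)
        return float(t.bait.loc[protein_id].mean())

    return avg(table_b, in_b) / avg(table_a, in_a)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_pulldown_table(path: str | Path) -> PulldownTable:
    """Read ``protein_id, cell_line, bait, bait_rep1..K, igg_rep1..K`` TSV."""
    df = pd.read_csv(path, sep="\t")
    for col in ("protein_id", "cell_line", "bait"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    bait_cols = sorted(c for c in df.columns if c.startswith("bait_rep"))
    igg_cols = sorted(c for c in df.columns if c.startswith("igg_rep"))
    if not bait_cols or len(bait_cols) != len(igg_cols):
        raise FormatError(f"{path}: need matching bait_rep*/igg_rep* columns")
    idx = pd.Index(df["protein_id"].astype(str), name="protein_id")
    return PulldownTable(
        bait=pd.DataFrame(df[bait_cols].to_numpy(dtype=float), index=idx,
                          columns=bait_cols),
        igg=pd.DataFrame(df[igg_cols].to_numpy(dtype=float), index=idx,
                         columns=igg_cols),
        cell_line=str(df["cell_line"].iloc[0]),
        bait_name=str(df["bait"].iloc[0]),
    )


def write_pulldown_table(table: PulldownTable, path: str | Path) -> None:
    out = pd.DataFrame({"protein_id": table.proteins})
    out["cell_line"] = table.cell_line
    out["bait"] = table.bait_name
    for c in table.bait.columns:
        out[c] = table.bait[c].to_numpy()
    for c in table.igg.columns:
        out[c] = table.igg[c].to_numpy()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")
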