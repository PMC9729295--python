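"""Immunohistochemistry biomarker confirmation.

Candidate markers from the phosphoscreen are re-tested on independent patient
cohorts stained by IHC.  Each stain is summarised by an H-score,
``(3*%high + 2*%medium + 1*%low) / 100`` in [0, 3]; patients above the
cohort's 75th percentile are "High" and the pCR proportion of High patients is
compared with the rest via risk ratio, odds ratio and a two-sided Pearson
chi-square test (no continuity correction), Bonferroni-adjusted over the
number of markers tested.  Calls follow the adjusted p: < 0.01 significant,
0.01-0.1 borderline, otherwise ns.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_BONFERRONI_M = 5  # comparisons per marker panel

SUBTYPES = ("HR+", "HER2", "TNBC")

#: tidy cohort table columns
IHC_COLUMNS = ("patient_id", "marker", "pct_high", "pct_medium", "pct_low",
               "h_score", "subtype", "pcr")


@dataclass(frozen=True)
class IhcRecord:
    patient_id: str
    marker: str
    pct_high: float
    pct_medium: float
    pct_low: float
    h_score: float
    subtype: str
    pcr: bool

    def validate(self) -> None:
        pcts = (self.pct_high, self.pct_medium, self.pct_low)
        if any(p < 0 for p in pcts) or sum(pcts) > 100 + 1e-9:
            raise ValidationError(
                f"{self.patient_id}/{self.marker}: area percentages must be "
                f"nonnegative with sum <= 100"
            )
        expected = h_score(*pcts)
        if abs(self.h_score - expected) > 1e-9:
            raise ValidationError(
                f"{self.patient_id}/{self.marker}: h_score {self.h_score} != "
                f"formula value {expected}"
            )


@dataclass(frozen=True)
class MarkerAssociation:
    marker: str
    n_q1: int
    n_rest: int
    pcr_q1: int
    pcr_rest: int
    risk_ratio: float
    odds_ratio: float
    or_haldane_corrected: bool
    chi2_stat: float
    p_raw: float
    p_bonferroni: float
    call: str  # significant | borderline | ns
    cutoff: float


def h_score(pct_high: float, pct_medium: float, pct_low: float) -> float:
    """H-score = (3*%high + 2*%medium + 1*%low) / 100, in [0, 3]."""
    pcts = (pct_high, pct_medium, pct_low)
    if any(p < 0 or p > 100 for p in pcts):
        raise ValidationError("area percentages must lie in [0, 100]")
    if sum(pcts) > 100 + 1e-9:
        raise ValidationError("area percentages must sum to <= 100")
    return (pct_high * 3 + pct_medium * 2 + pct_low * 1) / 100.0


def quartile_categorize(h_scores: Sequence[float]) -> tuple[list[str], float]:
    """Dichotomise at the 75th percentile (linear-interpolation quantile).

    'High' iff strictly above the cutoff; values exactly at the cutoff are
    'Low'.  Returns (labels, cutoff).
    """
    arr = np.asarray(h_scores, dtype=float)
    if arr.size < 4:
        raise InsufficientDataError("quartile dichotomisation needs n >= 4")
    cutoff = float(np.quantile(arr, 0.75, method="linear"))
    return ["High" if v > cutoff else "Low" for v in arr], cutoff


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Pearson chi-square without continuity correction on [[a,b],[c,d]]."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if table.sum() == 0 or (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def association_test(records: pd.DataFrame, m_comparisons: int = DEFAULT_BONFERRONI_M
                     ) -> MarkerAssociation:
    """Upper-quartile vs rest pCR association for one marker.

    ``records`` is a tidy cohort table restricted to a single marker (columns
    ``patient_id, h_score, pcr`` at least).  The odds ratio is the 2x2
    cross-product (the exponentiated univariate logistic coefficient for a
    binary covariate); a zero cell triggers the 0.5 Haldane-Anscombe
    correction, flagged in the output.
    """
    markers = records["marker"].unique() if "marker" in records else ["?"]
    if len(markers) != 1:
        raise ValidationError(f"association_test expects one marker, got {list(markers)}")
    labels, cutoff = quartile_categorize(records["h_score"].to_numpy())
    high = np.array([l == "High" for l in labels])
    pcr = records["pcr"].to_numpy().astype(bool)
    if not high.any() or high.all():
        raise InsufficientDataError("both High and Low groups must be nonempty")
    n_q1, n_rest = int(high.sum()), int((~high).sum())
    pcr_q1, pcr_rest = int(pcr[high].sum()), int(pcr[~high].sum())
    rate_rest = pcr_rest / n_rest
    risk_ratio = (pcr_q1 / n_q1) / rate_rest if rate_rest > 0 else math.inf
    a, b = pcr_q1, n_q1 - pcr_q1
    c, d = pcr_rest, n_rest - pcr_rest
    haldane = 0 in (a, b, c, d)
    if haldane:
        aa, bb, cc, dd = (v + 0.5 for v in (a, b, c, d))
        logger.info("association_test(%s): zero cell, Haldane-Anscombe OR", markers[0])
    else:
        aa, bb, cc, dd = a, b, c, d
    odds_ratio = (aa * dd) / (bb * cc)
    chi2, p = _chi2_2x2(a, b, c, d)
    p_adj = min(1.0, m_comparisons * p)
    if p_adj < 0.01:
        call = "significant"
    elif p_adj <= 0.1:
        call = "borderline"
    else:
        call = "ns"
    return MarkerAssociation(
        marker=str(markers[0]), n_q1=n_q1, n_rest=n_rest, pcr_q1=pcr_q1,
        pcr_rest=pcr_rest, risk_ratio=float(risk_ratio),
        odds_ratio=float(odds_ratio), or_haldane_corrected=haldane,
        chi2_stat=chi2, p_raw=p, p_bonferroni=p_adj, call=call, cutoff=cutoff,
    )


@dataclass(frozen=True)
class CombinedMarkerRate:
    marker_a: str
    marker_b: str
    n_both_high: int
    pcr_both_high: int
    pcr_rate_both_high: float
    se_proportion: float
    n_rest: int
    pcr_rate_rest: float
    chi2_stat: float
    p_raw: float
    note: str


def combined_marker_rate(records: pd.DataFrame, marker_a: str, marker_b: str
                         ) -> CombinedMarkerRate:
    """pCR rate of patients High on both markers vs everyone else.

    Reports the standard error of the proportion and the two-sided chi-square
    comparison against the remaining patients; degenerate strata (no or all
    patients doubly High) are reported with a note rather than an error.
    """
    wide = records.pivot(index="patient_id", columns="marker", values="h_score")
    for m in (marker_a, marker_b):
        if m not in wide.columns:
            raise ValidationError(f"marker {m!r} not present in cohort")
    wide = wide.dropna(subset=[marker_a, marker_b])
    pcr = (records.drop_duplicates("patient_id")
           .set_index("patient_id")["pcr"].astype(bool).reindex(wide.index))
    la, _ = quartile_categorize(wide[marker_a].to_numpy())
    lb, _ = quartile_categorize(wide[marker_b].to_numpy())
    both = np.array([x == "High" and y == "High" for x, y in zip(la, lb)])
    n_both = int(both.sum())
    n_rest = int((~both).sum())
    if n_both == 0:
        return CombinedMarkerRate(marker_a, marker_b, 0, 0, math.nan, math.nan,
                                  n_rest, float(pcr[~both].mean()), math.nan,
                                  math.nan, "empty stratum: no patient High on both")
    rate_both = float(pcr[both].mean())
    se = math.sqrt(rate_both * (1 - rate_both) / n_both)
    if n_rest == 0:
        return CombinedMarkerRate(marker_a, marker_b, n_both, int(pcr[both].sum()),
                                  rate_both, se, 0, math.nan, math.nan, math.nan,
                                  "degenerate stratum: all patients High on both")
    a = int(pcr[both].sum())
    c = int(pcr[~both].sum())
    chi2, p = _chi2_2x2(a, n_both - a, c, n_rest - c)
    return CombinedMarkerRate(marker_a, marker_b, n_both, a, rate_both, se,
                              n_rest, float(pcr[~both].mean()), chi2, p, "")


def marker_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pairwise Pearson correlation of two markers' H-scores (r, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InsufficientDataError("need paired H-scores with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("zero variance: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def records_to_frame(records: Sequence[IhcRecord]) -> pd.DataFrame:
    for r in records:
        r.validate()
    return pd.DataFrame([r.__dict__ for r in records], columns=IHC_COLUMNS)
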