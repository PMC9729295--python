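"""Per-peptide responder-vs-nonresponder analysis behind the volcano plots.

For every phosphopeptide the group medians of the raw spectral intensities are
compared.  Because a spectral intensity of 0 means "not detected", a median of
0 is replaced by 1 *for the ratio only* (a change of one intensity unit is
biologically negligible when detected peptides sit at 2^10-2^20), producing
the characteristic lateral "exclusive" clouds at x = ±log2(median) for
peptides detected in only one group.  Significance comes from a two-sided
Mann-Whitney-Wilcoxon test whose null distribution is obtained by Monte-Carlo
label permutation (default 100,000 permutations, add-one estimator, so p has
5-decimal resolution and is never 0), followed by Benjamini-Hochberg FDR
adjustment across peptides.

Zeros are kept as observed values (tied at the bottom ranks) inside the rank
test; only the median ratio uses the 0 -> 1 substitution.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientDataError, ValidationError
from .io import IntensityMatrix, SampleAnnotation, response_mask

logger = logging.getLogger(__name__)

DEFAULT_N_PERM = 100_000
#: volcano hit thresholds: >16-fold, MWW p < 10^-2.5, BH FDR < 0.25
DEFAULT_FC_THRESHOLD_LOG2 = 4.0
DEFAULT_P_THRESHOLD = 10 ** -2.5
DEFAULT_FDR_THRESHOLD = 0.25

CLOUD_SHARED = "shared"
CLOUD_EXCL_RESP = "exclusive_responder"
CLOUD_EXCL_NONRESP = "exclusive_nonresponder"


@dataclass(frozen=True)
class DifferentialResult:
    peptide_id: str
    median_responder: float
    median_nonresponder: float
    log2_fc: float  # responder over nonresponder, after 0 -> 1 substitution
    p_raw: float
    q_bh: float
    cloud: str
    is_hit: bool


# ---------------------------------------------------------------------------
# normality gate
# ---------------------------------------------------------------------------

def normality_gate(values: Sequence[float], alpha: float = 0.05) -> str:
    """Shapiro-Wilk gate: 'nonparametric' if normality is rejected at alpha.

    Applied once to the pooled intensity distribution; heavy-tailed spectral
    intensities essentially always reject, selecting the Mann-Whitney branch.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise InsufficientDataError("Shapiro-Wilk needs n >= 3")
    if np.ptp(arr) == 0:
        raise InsufficientDataError("constant vector: insufficient variation")
    if arr.size > 5000:  # Shapiro-Wilk p is unreliable past n=5000
        arr = arr[:5000]
    _, p = stats.shapiro(arr)
    return "nonparametric" if p < alpha else "parametric"


# ---------------------------------------------------------------------------
# medians and fold change
# ---------------------------------------------------------------------------

def median_log2_fc(row: Sequence[float], resp_mask: Sequence[bool]
                   ) -> tuple[float, float, float, str]:
    """Group medians, zero-substituted log2 fold change and cloud label.

    Medians are computed on raw intensities (zeros included as observed
    values); only for the ratio is a zero median replaced by 1.
    """
    row = np.asarray(row, dtype=float)
    mask = np.asarray(resp_mask, dtype=bool)
    if not mask.any() or mask.all():
        raise InsufficientDataError("both groups must be nonempty")
    med_r = float(np.median(row[mask]))
    med_n = float(np.median(row[~mask]))
    lfc = math.log2((med_r if med_r > 0 else 1.0) / (med_n if med_n > 0 else 1.0))
    if med_n == 0 and med_r > 0:
        cloud = CLOUD_EXCL_RESP
    elif med_r == 0 and med_n > 0:
        cloud = CLOUD_EXCL_NONRESP
    else:
        cloud = CLOUD_SHARED
    return med_r, med_n, lfc, cloud


# ---------------------------------------------------------------------------
# Mann-Whitney-Wilcoxon by Monte-Carlo permutation
# ---------------------------------------------------------------------------

def _u_statistic(ranks: np.ndarray, n1: int) -> float:
    """U of group 1 from midranks of the pooled sample (first n1 entries)."""
    r1 = float(ranks[:n1].sum())
    return r1 - n1 * (n1 + 1) / 2.0


def mww_permutation_test(x: Sequence[float], y: Sequence[float],
                         n_perm: int = DEFAULT_N_PERM, seed: int = 0) -> float:
    """Two-sided Monte-Carlo Mann-Whitney-Wilcoxon p-value.

    Midranks handle ties; extremeness is |U - E[U]|; the add-one estimator
    p = (1 + #extreme) / (n_perm + 1) never returns 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("each group needs >= 2 values")
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        logger.info("mww_permutation_test: all values tied; p = 1")
        return 1.0
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    e_u = x.size * y.size / 2.0
    obs = abs(_u_statistic(ranks, n1) - e_u)
    rng = np.random.default_rng(seed)
    count = 0
    chunk = 20_000
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        # m random label permutations: take n1 random positions per row
        order = rng.random((m, n)).argsort(axis=1)[:, :n1]
        r1 = ranks[order].sum(axis=1)
        u = r1 - n1 * (n1 + 1) / 2.0
        count += int(np.count_nonzero(np.abs(u - e_u) >= obs - 1e-9))
        done += m
    return (1 + count) / (n_perm + 1)


def mww_exact_test(x: Sequence[float], y: Sequence[float]) -> float:
    """Exact two-sided MWW p by exhaustive enumeration of all C(n, n1) splits.

    Independent small-sample reference for the Monte-Carlo estimator; only
    feasible for small groups.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    ranks = stats.rankdata(pooled)
    n1, n = x.size, pooled.size
    e_u = x.size * y.size / 2.0
    obs = abs(_u_statistic(ranks, n1) - e_u)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n1):
        r1 = ranks[list(idx)].sum()
        u = r1 - n1 * (n1 + 1) / 2.0
        if abs(u - e_u) >= obs - 1e-9:
            count += 1
        total += 1
    return count / total


def mww_permutation_matrix(values: np.ndarray, resp_mask: np.ndarray,
                           n_perm: int = DEFAULT_N_PERM, seed: int = 0
                           ) -> np.ndarray:
    """Vectorised Monte-Carlo MWW over all peptide rows at once.

    Ranks depend only on the data, so they are computed once per row; a label
    permutation merely selects which ranks fall in group 1, making the whole
    null distribution a rank-matrix x permutation-mask product.  All rows
    share the same permutation stream (as a per-row loop with a common seed
    would).
    """
    values = np.asarray(values, dtype=float)
    resp_mask = np.asarray(resp_mask, dtype=bool)
    n_pep, n = values.shape
    n1 = int(resp_mask.sum())
    if n1 < 2 or n - n1 < 2:
        raise InsufficientDataError("each group needs >= 2 samples")
    ranks = stats.rankdata(values, axis=1)
    e_u = n1 * (n - n1) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    obs = np.abs(ranks[:, resp_mask].sum(axis=1) - offset - e_u)
    constant = np.ptp(values, axis=1) == 0
    rng = np.random.default_rng(seed)
    counts = np.zeros(n_pep, dtype=np.int64)
    chunk = max(1, min(20_000, int(2e8 // max(n_pep, 1))))
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        sel = rng.random((n, m)).argsort(axis=0) < n1  # (n, m) masks with n1 Trues
        u = ranks @ sel - offset  # (n_pep, m)
        counts += (np.abs(u - e_u) >= obs[:, None] - 1e-9).sum(axis=1)
        done += m
    p = (1 + counts) / (n_perm + 1)
    p[constant] = 1.0
    return p


# ---------------------------------------------------------------------------
# multiple testing and hit classification
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)) or np.isnan(p).any():
        raise ValidationError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def classify_volcano_hits(
    results: pd.DataFrame,
    fc_threshold_log2: float = DEFAULT_FC_THRESHOLD_LOG2,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Flag hits (strict thresholds) and add volcano coordinates.

    A hit needs |log2_fc| > fc_threshold_log2 AND p_raw < p_threshold AND
    q_bh < fdr_threshold.  Adds columns ``is_hit``, ``volcano_x`` (= log2_fc)
    and ``volcano_y`` (= -log10 p_raw).
    """
    out = results.copy()
    out["is_hit"] = (
        (out["log2_fc"].abs() > fc_threshold_log2)
        & (out["p_raw"] < p_threshold)
        & (out["q_bh"] < fdr_threshold)
    )
    out["volcano_x"] = out["log2_fc"]
    out["volcano_y"] = -np.log10(out["p_raw"])
    return out


# ---------------------------------------------------------------------------
# full per-peptide screen
# ---------------------------------------------------------------------------

def run_differential(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    arm: str = "all",
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fc_threshold_log2: float = DEFAULT_FC_THRESHOLD_LOG2,
    p_threshold: float = DEFAULT_P_THRESHOLD,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
) -> pd.DataFrame:
    """Responder-vs-nonresponder screen over every peptide of one arm.

    ``arm`` restricts the analysis to 'standard' or 'experimental' samples
    ('all' uses the whole trial); the per-arm analyses share this single code
    path.  Returns one row per peptide with medians, log2 fold change, cloud
    label, Monte-Carlo MWW p, BH q, hit flag and volcano coordinates.
    """
    if arm != "all":
        keep = [a for a in annotations if a.arm == arm]
    else:
        keep = list(annotations)
    sub = matrix.restrict_samples([a.sample_id for a in keep])
    mask = response_mask(keep)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise InsufficientDataError(
            f"arm {arm!r}: need >=2 samples per response group"
        )
    vals = sub.values.to_numpy()
    med_r = np.median(vals[:, mask], axis=1)
    med_n = np.median(vals[:, ~mask], axis=1)
    lfc = np.log2(np.where(med_r > 0, med_r, 1.0) / np.where(med_n > 0, med_n, 1.0))
    cloud = np.where(
        (med_n == 0) & (med_r > 0), CLOUD_EXCL_RESP,
        np.where((med_r == 0) & (med_n > 0), CLOUD_EXCL_NONRESP, CLOUD_SHARED),
    )
    p_raw = mww_permutation_matrix(vals, mask, n_perm=n_perm, seed=seed)
    q = benjamini_hochberg(p_raw)
    res = pd.DataFrame(
        {
            "peptide_id": sub.values.index,
            "median_responder": med_r,
            "median_nonresponder": med_n,
            "log2_fc": lfc,
            "p_raw": p_raw,
            "q_bh": q,
            "cloud": cloud,
        }
    )
    res = classify_volcano_hits(res, fc_threshold_log2, p_threshold, fdr_threshold)
    logger.info(
        "differential screen (arm=%s): %d peptides, %d vs %d samples, %d hits",
        arm, len(res), int(mask.sum()), int((~mask).sum()), int(res["is_hit"].sum()),
    )
    return res
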