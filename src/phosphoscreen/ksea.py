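"""Kinase-set enrichment analysis (KSEA).

Phosphopeptides are mapped back to the kinases that can phosphorylate them by
matching each peptide's 15-residue sequence window against linear
kinase-substrate motifs (HPRD PhosphoMotif-style patterns).  The peptides
matching any motif of a kinase form that kinase's "set"; sets entering the
enrichment must have more than 5 and fewer than 1000 members.  Peptides are
ranked by a two-sample t-statistic (responders minus nonresponders, on
log2(intensity+1) by default) and each kinase set is scored with the classic
(unweighted) Kolmogorov-Smirnov-like running-sum enrichment statistic.
Significance comes from phenotype-label permutations with full re-ranking:
the normalized enrichment score (NES) divides the observed ES by the mean
magnitude of same-sign permutation scores, the permutation p is the add-one
same-sign tail fraction, and the FDR q is the ratio of null to observed
same-sign NES tail fractions, clipped to [0, 1].
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError
from .io import CENTER, PAD_CHAR, WINDOW_LENGTH, IntensityMatrix, SampleAnnotation, response_mask

logger = logging.getLogger(__name__)

DEFAULT_MIN_SIZE = 6  # ">5"
DEFAULT_MAX_SIZE = 999  # "<1000"
DEFAULT_N_PERM = 1000
DEFAULT_FDR_THRESHOLD = 0.20


# ---------------------------------------------------------------------------
# motif patterns
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MotifPattern:
    """One linear substrate motif: residue constraints at offsets from the site.

    ``constraints`` maps an offset in [-7, +7] to the set of allowed residues;
    offset 0 (if present) constrains the phosphoacceptor itself and must be a
    subset of {S, T, Y}.
    """

    kinase_id: str
    constraints: tuple[tuple[int, frozenset[str]], ...]
    source: str = field(default="", compare=False)

    def __post_init__(self):
        offsets = [o for o, _ in self.constraints]
        if len(set(offsets)) != len(offsets):
            raise ValidationError(f"{self.kinase_id}: duplicate offsets in pattern")
        for off, allowed in self.constraints:
            if not -CENTER <= off <= CENTER:
                raise ValidationError(f"{self.kinase_id}: offset {off} outside ±{CENTER}")
            if not allowed:
                raise ValidationError(f"{self.kinase_id}: empty residue set at {off}")
            if off == 0 and not allowed <= {"S", "T", "Y"}:
                raise ValidationError(
                    f"{self.kinase_id}: centre constraint must be within S/T/Y"
                )


_TOKEN_RE = re.compile(r"^(X|\[[A-Z]+\]|[A-Z])$")


def _parse_token(tok: str) -> frozenset[str] | None:
    """One non-centre pattern token -> allowed residue set (None = wildcard)."""
    if not _TOKEN_RE.match(tok):
        raise FormatError(f"bad motif token {tok!r}")
    if tok == "X":
        return None
    if tok.startswith("["):
        return frozenset(tok[1:-1])
    return frozenset(tok)


def parse_motif_pattern(kinase_id: str, pattern: str) -> MotifPattern:
    """Parse a dash-separated motif string, e.g. ``R-X-X-pS/pT`` or ``[RK]-X-pS``.

    ``X`` is a wildcard, ``[RK]`` a residue group, and the token starting with
    ``p`` (``pS``, ``pS/pT``, ``pS/pT/pY``...) marks the centred
    phosphoacceptor; offsets are counted relative to it.
    """
    tokens = pattern.strip().split("-")
    centre_idx = [i for i, t in enumerate(tokens) if t.startswith("p")]
    if len(centre_idx) != 1:
        raise FormatError(
            f"{kinase_id}: pattern {pattern!r} must contain exactly one p-token"
        )
    ci = centre_idx[0]
    acceptors = frozenset(part[1:] for part in tokens[ci].split("/"))
    if not acceptors <= {"S", "T", "Y"} or not acceptors:
        raise FormatError(f"{kinase_id}: bad phosphoacceptor token {tokens[ci]!r}")
    constraints: list[tuple[int, frozenset[str]]] = [(0, acceptors)]
    for i, tok in enumerate(tokens):
        if i == ci:
            continue
        allowed = _parse_token(tok)
        if allowed is not None:
            constraints.append((i - ci, allowed))
    return MotifPattern(kinase_id, tuple(sorted(constraints)), source=pattern)


def read_motif_library(path, dialect: str | None = None) -> list[MotifPattern]:
    """Read a motif library TSV with columns ``kinase_id, pattern``."""
    sep = "," if (dialect == "csv" or str(path).endswith(".csv")) else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("kinase_id", "pattern"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    return [parse_motif_pattern(k, p) for k, p in zip(df["kinase_id"], df["pattern"])]


def write_motif_library(patterns: Sequence[MotifPattern], path) -> None:
    pd.DataFrame(
        {"kinase_id": [p.kinase_id for p in patterns],
         "pattern": [p.source or _pattern_to_string(p) for p in patterns]}
    ).to_csv(path, sep="\t", index=False)


def _pattern_to_string(p: MotifPattern) -> str:
    cons = dict(p.constraints)
    offs = sorted(cons)
    lo, hi = min(offs + [0]), max(offs + [0])
    toks = []
    for off in range(lo, hi + 1):
        if off == 0:
            toks.append("/".join("p" + r for r in sorted(cons[0])))
        elif off in cons:
            s = sorted(cons[off])
            toks.append(s[0] if len(s) == 1 else "[" + "".join(s) + "]")
        else:
            toks.append("X")
    return "-".join(toks)


def match_motifs(window: str, residue: str,
                 patterns: Iterable[MotifPattern]) -> set[str]:
    """Kinases with at least one fully satisfied motif on this window.

    The window is 15 residues with the phosphosite at the centre; '_' padding
    never satisfies a constraint.
    """
    if len(window) != WINDOW_LENGTH:
        raise ValidationError(f"window must be {WINDOW_LENGTH} chars, got {len(window)}")
    hits: set[str] = set()
    for pat in patterns:
        if pat.kinase_id in hits:
            continue
        ok = True
        for off, allowed in pat.constraints:
            c = residue if off == 0 else window[CENTER + off]
            if c == PAD_CHAR or c not in allowed:
                ok = False
                break
        if ok:
            hits.add(pat.kinase_id)
    return hits


# ---------------------------------------------------------------------------
# kinase sets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KinaseSet:
    kinase_id: str
    member_peptide_ids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.member_peptide_ids)


def build_kinase_sets(
    matrix: IntensityMatrix,
    patterns: Sequence[MotifPattern],
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
) -> list[KinaseSet]:
    """Motif-match every peptide and keep sets with min_size <= size <= max_size.

    Default bounds implement the strict >5 and <1000 size limits.  Excluded
    sets are logged; an empty result is a warning, not an error.
    """
    if not patterns:
        raise ValidationError("patterns must be nonempty")
    members: dict[str, set[str]] = {}
    windows = matrix.meta["sequence_window"]
    residues = matrix.meta["residue"]
    for pid in matrix.peptide_ids:
        for k in match_motifs(windows[pid], residues[pid], patterns):
            members.setdefault(k, set()).add(pid)
    sets = []
    for k in sorted(members):
        size = len(members[k])
        if min_size <= size <= max_size:
            sets.append(KinaseSet(k, frozenset(members[k])))
        else:
            logger.info("build_kinase_sets: excluding %s (size %d)", k, size)
    if not sets:
        logger.warning("build_kinase_sets: no kinase set within size limits")
    return sets


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------

def _tstat_matrix(x: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Pooled-variance two-sample t for every row of ``x`` under each mask.

    ``masks`` is (n_samples, n_perm) boolean with a fixed group-1 size per
    column; returns (n_rows, n_perm).  Zero pooled variance yields t = 0.
    """
    masks = masks.astype(float)
    n = x.shape[1]
    n1 = masks[:, 0].sum()
    n2 = n - n1
    s1 = x @ masks  # (rows, perms) group-1 sums
    stot = x.sum(axis=1, keepdims=True)
    m1 = s1 / n1
    m2 = (stot - s1) / n2
    x2 = x ** 2
    q1 = x2 @ masks
    qtot = x2.sum(axis=1, keepdims=True)
    ss1 = q1 - n1 * m1 ** 2
    ss2 = (qtot - q1) - n2 * m2 ** 2
    sp2 = (ss1 + ss2) / (n1 + n2 - 2)
    # constant rows leave cancellation noise in the sum-of-squares form;
    # anything below 1e-10 of the mean square is zero variance -> t = 0
    floor = 1e-10 * (qtot / n)
    sp2 = np.where(sp2 <= floor, 0.0, sp2)
    se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (m1 - m2) / se, 0.0)
    return t


def rank_by_tstat(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    log_transform: bool = True,
) -> pd.DataFrame:
    """Rank peptides by the responder-minus-nonresponder pooled t-statistic.

    Intensities are log2(x+1)-transformed by default.  Returns a DataFrame
    with columns ``peptide_id, t`` in descending t order, ties broken by
    lexicographic peptide_id; zero-variance peptides get t = 0.
    """
    mask = response_mask(annotations)
    if mask.sum() < 2 or (~mask).sum() < 2:
        raise InsufficientDataError("each response group needs >= 2 samples")
    x = matrix.values.to_numpy()
    if log_transform:
        x = np.log2(x + 1.0)
    t = _tstat_matrix(x, mask[:, None])[:, 0]
    df = pd.DataFrame({"peptide_id": matrix.peptide_ids, "t": t})
    return df.sort_values(["t", "peptide_id"], ascending=[False, True],
                          kind="mergesort").reset_index(drop=True)


# ---------------------------------------------------------------------------
# classic running-sum enrichment score
# ---------------------------------------------------------------------------

def enrichment_score_classic(ranked_ids: Sequence[str],
                             set_members: set[str] | frozenset[str]) -> float:
    """Unweighted (classic) running-sum enrichment score.

    Walking down the ranked list, add 1/n_hit at members and subtract
    1/(N - n_hit) at non-members; the ES is the signed extremum of the running
    sum (first occurrence on ties), bounded in [-1, 1].
    """
    ranked_ids = list(ranked_ids)
    n = len(ranked_ids)
    hit = np.fromiter((pid in set_members for pid in ranked_ids), dtype=bool, count=n)
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise ValidationError("set is disjoint from the ranked list")
    if n_hit == n:
        raise ValidationError("set covers the whole ranked list")
    steps = np.where(hit, 1.0 / n_hit, -1.0 / (n - n_hit))
    running = np.cumsum(steps)
    # first index within 1e-12 of the extremum: cumsum round-off must not
    # flip which of two analytically tied extrema is reported
    absr = np.abs(running)
    i = int(np.argmax(absr >= absr.max() - 1e-12))
    return float(running[i])


def _es_for_orders(member_matrix: np.ndarray, orders: np.ndarray) -> np.ndarray:
    """ES of every set under every ranking order.

    ``member_matrix`` is (n_sets, N) boolean membership (list positions are
    fixed peptide indices); ``orders`` is (n_perm, N) giving each ranking as
    peptide indices from best to worst.  Returns (n_sets, n_perm).
    """
    n_sets, n = member_matrix.shape
    n_hit = member_matrix.sum(axis=1).astype(float)
    inc = 1.0 / n_hit
    dec = 1.0 / (n - n_hit)
    out = np.empty((n_sets, orders.shape[0]))
    for j, order in enumerate(orders):
        mo = member_matrix[:, order]  # (n_sets, N) in ranked order
        steps = np.where(mo, inc[:, None], -dec[:, None])
        running = np.cumsum(steps, axis=1)
        absr = np.abs(running)
        # first position within 1e-12 of the row maximum (tie/round-off rule)
        idx = np.argmax(absr >= absr.max(axis=1, keepdims=True) - 1e-12, axis=1)
        out[:, j] = running[np.arange(n_sets), idx]
    return out


# ---------------------------------------------------------------------------
# permutation NES / p / FDR
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KseaResult:
    kinase_id: str
    set_size: int
    es: float
    nes: float
    p_perm: float
    fdr_q: float
    direction: str  # high_in_responders | high_in_nonresponders
    significant: bool


def _phenotype_permutations(n: int, n1: int, n_perm: int, seed: int
                            ) -> tuple[np.ndarray, bool]:
    """(n_perm', n) boolean label masks; exhaustive if C(n, n1) <= n_perm."""
    total = math.comb(n, n1)
    if total <= n_perm:
        logger.info("ksea: enumerating all %d label assignments exhaustively", total)
        import itertools

        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(itertools.combinations(range(n), n1)):
            masks[i, list(idx)] = True
        return masks, True
    rng = np.random.default_rng(seed)
    masks = rng.random((n_perm, n)).argsort(axis=1) < n1
    return masks, False


def ksea_run(
    matrix: IntensityMatrix,
    annotations: Sequence[SampleAnnotation],
    patterns: Sequence[MotifPattern],
    n_perm: int = DEFAULT_N_PERM,
    seed: int = 0,
    fdr_threshold: float = DEFAULT_FDR_THRESHOLD,
    log_transform: bool = True,
    min_size: int = DEFAULT_MIN_SIZE,
    max_size: int = DEFAULT_MAX_SIZE,
    permute: str = "phenotype",
) -> list[KseaResult]:
    """Full KSEA: sets, ranking, observed ES, permutation NES/p/FDR.

    Phenotype-label permutation with per-permutation re-ranking is the
    default; ``permute='members'`` draws random member sets of the same size
    instead.  One RNG stream drives all sets.  Kinases whose set passes the
    size filter are scored; significance is fdr_q < fdr_threshold.
    """
    sets = build_kinase_sets(matrix, patterns, min_size=min_size, max_size=max_size)
    if not sets:
        return []
    mask = response_mask(annotations)
    x = matrix.values.to_numpy()
    if log_transform:
        x = np.log2(x + 1.0)
    pep_ids = np.array(matrix.peptide_ids)
    n_pep = len(pep_ids)
    # deterministic tie-break: pre-sort peptide indices lexicographically so a
    # stable argsort on -t keeps lexicographic order within ties
    lex = np.argsort(pep_ids, kind="mergesort")
    x_lex = x[lex]
    member = np.zeros((len(sets), n_pep), dtype=bool)
    id_pos = {pid: i for i, pid in enumerate(pep_ids[lex])}
    for si, ks in enumerate(sets):
        for pid in ks.member_peptide_ids:
            member[si, id_pos[pid]] = True

    t_obs = _tstat_matrix(x_lex, mask[:, None])[:, 0]
    order_obs = np.argsort(-t_obs, kind="mergesort")[None, :]
    es_obs = _es_for_orders(member, order_obs)[:, 0]

    if permute == "phenotype":
        masks, _ = _phenotype_permutations(len(mask), int(mask.sum()), n_perm, seed)
        null_es = np.empty((len(sets), masks.shape[0]))
        chunk = max(1, int(2e7 // max(n_pep, 1)))
        for start in range(0, masks.shape[0], chunk):
            mchunk = masks[start:start + chunk]
            t_null = _tstat_matrix(x_lex, mchunk.T)  # (n_pep, m)
            orders = np.argsort(-t_null.T, axis=1, kind="mergesort")
            null_es[:, start:start + chunk] = _es_for_orders(member, orders)
    elif permute == "members":
        rng = np.random.default_rng(seed)
        null_es = np.empty((len(sets), n_perm))
        sizes = member.sum(axis=1)
        for j in range(n_perm):
            perm = rng.permutation(n_pep)
            shuffled = np.zeros_like(member)
            for si, sz in enumerate(sizes):
                shuffled[si, perm[:sz]] = True
                perm = np.roll(perm, sz)
            null_es[:, j] = _es_for_orders(shuffled, order_obs)[:, 0]
    else:
        raise ValidationError(f"permute must be 'phenotype' or 'members', got {permute!r}")

    results = []
    nes_obs = np.empty(len(sets))
    null_nes_pool: list[np.ndarray] = []
    for si in range(len(sets)):
        es = es_obs[si]
        null = null_es[si]
        same = null >= 0 if es >= 0 else null < 0
        same_vals = np.abs(null[same])
        denom = same_vals.mean() if same_vals.size else np.abs(null).mean()
        if denom == 0:
            denom = 1.0
        nes_obs[si] = es / denom
        # normalised null for the FDR pool: each sign normalised by its own mean
        pos = null[null >= 0]
        neg = null[null < 0]
        pos_m = np.abs(pos).mean() if pos.size else 1.0
        neg_m = np.abs(neg).mean() if neg.size else 1.0
        null_nes_pool.append(np.concatenate([
            pos / pos_m if pos_m > 0 else pos,
            neg / neg_m if neg_m > 0 else neg,
        ]))
    pooled_null = np.concatenate(null_nes_pool)

    for si, ks in enumerate(sets):
        es = float(es_obs[si])
        nes = float(nes_obs[si])
        null = null_es[si]
        same = null >= 0 if es >= 0 else null < 0
        same_vals = np.abs(null[same])
        k = int(np.count_nonzero(same_vals >= abs(es) - 1e-12))
        p = (1 + k) / (1 + int(same.sum())) if same.sum() else 1.0
        if nes >= 0:
            null_tail = np.count_nonzero(pooled_null >= nes - 1e-12)
            null_base = np.count_nonzero(pooled_null >= 0)
            obs_tail = np.count_nonzero(nes_obs >= nes - 1e-12)
            obs_base = np.count_nonzero(nes_obs >= 0)
        else:
            null_tail = np.count_nonzero(pooled_null <= nes + 1e-12)
            null_base = np.count_nonzero(pooled_null < 0)
            obs_tail = np.count_nonzero(nes_obs <= nes + 1e-12)
            obs_base = np.count_nonzero(nes_obs < 0)
        num = null_tail / null_base if null_base else 1.0
        den = obs_tail / obs_base if obs_base else 1.0
        q = min(1.0, num / den) if den > 0 else 1.0
        results.append(
            KseaResult(
                kinase_id=ks.kinase_id,
                set_size=ks.size,
                es=es,
                nes=nes,
                p_perm=float(p),
                fdr_q=float(q),
                direction="high_in_responders" if es >= 0 else "high_in_nonresponders",
                significant=bool(q < fdr_threshold),
            )
        )
    return results


def barcode_positions(matrix: IntensityMatrix,
                      annotations: Sequence[SampleAnnotation],
                      kinase_set: KinaseSet,
                      log_transform: bool = True) -> np.ndarray:
    """0-based positions of a kinase's peptides in the observed ranked list
    (the vertical lines of a KSEA barcode plot)."""
    ranked = rank_by_tstat(matrix, annotations, log_transform=log_transform)
    ids = ranked["peptide_id"].to_numpy()
    return np.flatnonzero(np.isin(ids, list(kinase_set.member_peptide_ids)))
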