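"""Synthetic data generators for every pipeline stage.

The generators emulate the statistical structure the analysis assumes, so the
whole pipeline is testable without any external download:

* phospho matrices: per-cell log-normal spectral intensities (log2 scale) with
  intensity-dependent detection dropout (missing = 0), optional peptides
  detected in only one response group (the lateral volcano clouds), and
  kinase-substrate activation effects planted in responders together with a
  motif library consistent with the kinase assignment;
* IHC cohorts: correlated continuous H-scores with a planted
  upper-quartile/pCR association;
* pull-down tables: background proteins with bait ~ IgG intensity, planted
  interactors enriched in bait by a configured log2 amount, optionally absent
  from the IgG control.

One global integer seed is fanned out to named substreams
(``numpy.random.SeedSequence.spawn``) so adding a generator never shifts the
streams of existing ones; identical config + seed gives bit-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .ihc import IhcRecord, h_score
from .io import CENTER, WINDOW_LENGTH, IntensityMatrix, PhosphoPeptideRecord, SampleAnnotation
from .ksea import MotifPattern, parse_motif_pattern
from .pulldown import PulldownTable

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: residue reserved for non-substrate windows at the constrained offsets
_BLOCK_RESIDUE = "G"
_MOTIF_ALPHABET = [a for a in AMINO_ACIDS if a != _BLOCK_RESIDUE]
_MOTIF_OFFSETS = (-3, 2)  # constrained positions of every synthetic motif


def _check_prob(name: str, value: float) -> None:
    if not 0.0 <= value <= 1.0:
        raise ConfigError(f"{name} must lie in [0, 1], got {value}")


# ---------------------------------------------------------------------------
# phospho matrix + motif library
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhosphoSimConfig:
    """Study conditions for the synthetic phosphoproteomic trial.

    Defaults mirror a trial-arm-sized comparison: 20 responders vs 20
    nonresponders, 2000 phosphopeptides with log2 intensities around 15
    (detected peptides in the 2^10-2^20 range), 40 kinases with 8 substrates
    each, mild detection dropout and a small fraction of peptides detected in
    only one group.
    """

    n_responders: int = 20
    n_nonresponders: int = 20
    n_peptides: int = 2000
    n_kinases: int = 40
    substrates_per_kinase: int = 8
    planted_kinases: tuple[tuple[str, float], ...] = ()
    baseline_log2_mean: float = 15.0
    baseline_log2_sd: float = 2.0
    dropout_baseline: float = 0.10
    dropout_shift_per_log2: float = 0.02
    exclusive_fraction: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("dropout_baseline", "exclusive_fraction"):
            _check_prob(name, getattr(self, name))
        if self.dropout_shift_per_log2 < 0:
            raise ConfigError("dropout_shift_per_log2 must be >= 0")
        if self.n_responders < 2 or self.n_nonresponders < 2:
            raise ConfigError("need >= 2 samples per response group")
        if self.substrates_per_kinase < 1:
            raise ConfigError("substrates_per_kinase must be >= 1")
        if self.n_kinases * self.substrates_per_kinase > self.n_peptides:
            raise ConfigError("kinase substrates exceed the number of peptides")
        if self.n_kinases > len(_MOTIF_ALPHABET) ** 2:
            raise ConfigError(f"at most {len(_MOTIF_ALPHABET) ** 2} distinct motifs")
        known = {f"K{i + 1:03d}" for i in range(self.n_kinases)}
        for kid, _ in self.planted_kinases:
            if kid not in known:
                raise ConfigError(f"planted kinase {kid!r} outside K001..K{self.n_kinases:03d}")


def _kinase_motifs(n_kinases: int) -> list[MotifPattern]:
    """Disjoint two-position motifs: kinase i requires (aa_i at -3, aa_j at +2)."""
    patterns = []
    m = len(_MOTIF_ALPHABET)
    for i in range(n_kinases):
        a, b = _MOTIF_ALPHABET[i // m], _MOTIF_ALPHABET[i % m]
        pattern = f"{a}-X-X-pS/pT/pY-X-{b}"
        patterns.append(parse_motif_pattern(f"K{i + 1:03d}", pattern))
    return patterns


def simulate_phospho_dataset(config: PhosphoSimConfig) -> tuple[
        IntensityMatrix, list[SampleAnnotation], list[MotifPattern], dict]:
    """Generate (matrix, annotations, motif library, truth record).

    Substrate assignment is disjoint: the first
    ``n_kinases * substrates_per_kinase`` peptides (after shuffling) are split
    evenly among kinases; their windows carry the kinase's motif residues,
    every other window carries a residue no motif allows at the constrained
    offsets, so set membership is unambiguous for truth checking.  Planted
    kinases add their log2 effect to responders' intensities of their
    substrates before dropout.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_assign, rng_window, rng_intensity, rng_dropout, rng_exclusive = (
        np.random.default_rng(s) for s in ss.spawn(5))

    n_pep = config.n_peptides
    pep_ids = [f"pep{i + 1:05d}" for i in range(n_pep)]
    samples = [f"R{i + 1:03d}" for i in range(config.n_responders)] + [
        f"N{i + 1:03d}" for i in range(config.n_nonresponders)]
    resp = np.array([True] * config.n_responders + [False] * config.n_nonresponders)

    # kinase-substrate assignment (disjoint)
    patterns = _kinase_motifs(config.n_kinases)
    shuffled = rng_assign.permutation(n_pep)
    substrates: dict[str, list[str]] = {}
    kinase_of = np.full(n_pep, -1)
    for ki in range(config.n_kinases):
        idx = shuffled[ki * config.substrates_per_kinase:(ki + 1) * config.substrates_per_kinase]
        kinase_of[idx] = ki
        substrates[f"K{ki + 1:03d}"] = sorted(pep_ids[i] for i in idx)

    # sequence windows
    residues = rng_window.choice(list("STY"), size=n_pep, p=[0.70, 0.25, 0.05])
    windows = rng_window.choice(list(AMINO_ACIDS), size=(n_pep, WINDOW_LENGTH))
    windows[:, CENTER] = residues
    m = len(_MOTIF_ALPHABET)
    for i in range(n_pep):
        ki = kinase_of[i]
        if ki >= 0:
            windows[i, CENTER + _MOTIF_OFFSETS[0]] = _MOTIF_ALPHABET[ki // m]
            windows[i, CENTER + _MOTIF_OFFSETS[1]] = _MOTIF_ALPHABET[ki % m]
        else:
            windows[i, CENTER + _MOTIF_OFFSETS[0]] = _BLOCK_RESIDUE
            windows[i, CENTER + _MOTIF_OFFSETS[1]] = _BLOCK_RESIDUE

    peptides = [
        PhosphoPeptideRecord(
            peptide_id=pep_ids[i],
            protein_ids=(f"PROT{i // 2 + 1:04d}",),
            residue=str(residues[i]),
            site_position=int(rng_window.integers(1, 1000)),
            sequence_window="".join(windows[i]),
        )
        for i in range(n_pep)
    ]

    # intensities: iid log-normal on the log2 scale, planted effects in responders
    log2x = rng_intensity.normal(config.baseline_log2_mean, config.baseline_log2_sd,
                                 size=(n_pep, len(samples)))
    effects = dict(config.planted_kinases)
    for kid, eff in effects.items():
        rows = [pep_ids.index(p) for p in substrates[kid]]
        log2x[np.ix_(rows, np.flatnonzero(resp))] += eff

    # intensity-dependent dropout: rarer for brighter peptides
    p_drop = np.clip(
        config.dropout_baseline
        - config.dropout_shift_per_log2 * (log2x - config.baseline_log2_mean),
        0.0, 1.0)
    values = np.exp2(log2x)
    values[rng_dropout.random(size=values.shape) < p_drop] = 0.0

    # group-exclusive peptides (lateral volcano clouds)
    n_excl = int(round(config.exclusive_fraction * n_pep))
    excl_idx = rng_exclusive.choice(n_pep, size=n_excl, replace=False) if n_excl else []
    exclusive = []
    for i in excl_idx:
        zero_resp = bool(rng_exclusive.random() < 0.5)
        values[i, resp if zero_resp else ~resp] = 0.0
        exclusive.append({"peptide_id": pep_ids[i],
                          "zero_group": "responder" if zero_resp else "nonresponder"})

    matrix = IntensityMatrix.from_records(peptides, samples, values)
    annotations = [
        SampleAnnotation(sample_id=s, arm="standard",
                         response="responder" if r else "nonresponder")
        for s, r in zip(samples, resp)
    ]
    truth = {
        "planted_kinases": [{"kinase_id": k, "log2_effect": e}
                            for k, e in config.planted_kinases],
        "substrates": substrates,
        "exclusive_peptides": exclusive,
        "config": dataclasses.asdict(config),
    }
    return matrix, annotations, patterns, truth


# ---------------------------------------------------------------------------
# IHC cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IhcSimConfig:
    """Study conditions for a synthetic IHC confirmation cohort.

    pCR is Bernoulli with probability ``pcr_rate_upper_quartile`` for patients
    High (above the cohort 75th percentile) on every driver marker and
    ``pcr_rate_low`` otherwise; by default the first listed marker drives the
    outcome and the others merely correlate with it (latent Gaussian
    correlation ``marker_correlation``).
    """

    n_patients: int = 101  # a Set-2-sized TNBC cohort
    markers: tuple[str, ...] = ("CDK4", "FLNA")
    pcr_rate_low: float = 0.30
    pcr_rate_upper_quartile: float = 0.90
    marker_correlation: float = 0.5
    driver_markers: tuple[str, ...] | None = None  # default: first marker
    subtype: str = "TNBC"
    seed: int = 0

    def validate(self) -> None:
        _check_prob("pcr_rate_low", self.pcr_rate_low)
        _check_prob("pcr_rate_upper_quartile", self.pcr_rate_upper_quartile)
        if not -1.0 <= self.marker_correlation <= 1.0:
            raise ConfigError("marker_correlation must lie in [-1, 1]")
        if self.n_patients < 8:
            raise ConfigError("n_patients must be >= 8")
        if not self.markers:
            raise ConfigError("at least one marker required")
        drivers = self.driver_markers or (self.markers[0],)
        if not set(drivers) <= set(self.markers):
            raise ConfigError("driver_markers must be listed in markers")


def simulate_ihc_cohort(config: IhcSimConfig) -> list[IhcRecord]:
    """Correlated continuous H-scores with a planted quartile/pCR association.

    A latent standard normal per patient drives the first marker; each other
    marker mixes it with fresh noise at the configured correlation.  The
    latent quantile u = Phi(z) is turned into staining area fractions
    (stained area 100u, of which a fraction u stains at high intensity and
    the rest splits evenly between medium and low), giving the continuous,
    monotone H-score 1.5*u*(1+u) in (0, 3).
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_latent, rng_pcr = (np.random.default_rng(s) for s in ss.spawn(2))
    n, k = config.n_patients, len(config.markers)
    z0 = rng_latent.normal(size=n)
    rho = config.marker_correlation
    z = np.empty((n, k))
    z[:, 0] = z0
    for j in range(1, k):
        z[:, j] = rho * z0 + np.sqrt(max(0.0, 1 - rho ** 2)) * rng_latent.normal(size=n)
    from scipy.stats import norm

    u = norm.cdf(z)
    stained = 100.0 * u
    pct_high = stained * u
    pct_med = stained * (1 - u) / 2
    pct_low = stained * (1 - u) / 2
    scores = np.array([[h_score(pct_high[i, j], pct_med[i, j], pct_low[i, j])
                        for j in range(k)] for i in range(n)])

    drivers = config.driver_markers or (config.markers[0],)
    high = np.ones(n, dtype=bool)
    for m in drivers:
        j = config.markers.index(m)
        cutoff = np.quantile(scores[:, j], 0.75, method="linear")
        high &= scores[:, j] > cutoff
    p = np.where(high, config.pcr_rate_upper_quartile, config.pcr_rate_low)
    pcr = rng_pcr.random(n) < p

    records = []
    for i in range(n):
        for j, marker in enumerate(config.markers):
            records.append(
                IhcRecord(
                    patient_id=f"pt{i + 1:04d}", marker=marker,
                    pct_high=float(pct_high[i, j]), pct_medium=float(pct_med[i, j]),
                    pct_low=float(pct_low[i, j]), h_score=float(scores[i, j]),
                    subtype=config.subtype, pcr=bool(pcr[i]),
                )
            )
    return records


# ---------------------------------------------------------------------------
# pull-down tables
# ---------------------------------------------------------------------------

def simulate_pulldown_tables(
    n_proteins: int,
    planted: Sequence[tuple[str, float]] = (),
    replicates: int = 2,
    seed: int = 0,
    igg_absent_fraction: float = 0.5,
    base_log2_mean: float = 17.0,
    base_log2_sd: float = 2.0,
    noise_log2_sd: float = 0.5,
    cell_line: str = "MDA-MB-231",
    bait: str = "FLNA",
) -> PulldownTable:
    """Bait/IgG tables: ``n_proteins`` background proteins (bait ~ IgG) plus
    one extra protein per ``planted`` entry enriched in bait by the stated
    log2 amount; a random ``igg_absent_fraction`` of the planted proteins is
    set to 0 in every IgG replicate.
    """
    if replicates < 1:
        raise ConfigError("replicates must be >= 1")
    _check_prob("igg_absent_fraction", igg_absent_fraction)
    ss = np.random.SeedSequence(seed)
    rng_base, rng_noise, rng_absent = (np.random.default_rng(s) for s in ss.spawn(3))
    ids = [f"BG{i + 1:04d}" for i in range(n_proteins)] + [p for p, _ in planted]
    n_total = len(ids)
    base = rng_base.normal(base_log2_mean, base_log2_sd, size=n_total)
    bait_l2 = base[:, None] + rng_noise.normal(0, noise_log2_sd, (n_total, replicates))
    igg_l2 = base[:, None] + rng_noise.normal(0, noise_log2_sd, (n_total, replicates))
    for j, (_, enrich) in enumerate(planted):
        bait_l2[n_proteins + j] += enrich
    bait_vals = np.exp2(bait_l2)
    igg_vals = np.exp2(igg_l2)
    absent = rng_absent.random(len(planted)) < igg_absent_fraction
    igg_vals[n_proteins:][absent] = 0.0
    idx = pd.Index(ids, name="protein_id")
    return PulldownTable(
        bait=pd.DataFrame(bait_vals, index=idx,
                          columns=[f"bait_rep{r + 1}" for r in range(replicates)]),
        igg=pd.DataFrame(igg_vals, index=idx,
                         columns=[f"igg_rep{r + 1}" for r in range(replicates)]),
        cell_line=cell_line, bait_name=bait,
    )
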