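"""Shared data model and tabular I/O.

The central container is :class:`IntensityMatrix`: non-negative spectral
intensities of phosphopeptides (rows) across tumour samples (columns), where an
intensity of exactly 0 means "not detected".  Peptide metadata (protein
accessions, phosphoacceptor residue, site position and a 15-residue sequence
window centred on the phosphosite) travel alongside the intensities and are
what the motif-matching stage consumes.

All tables are plain TSV/CSV; floats are written with 17 significant digits so
read(write(x)) round-trips to full double precision.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import FormatError, InsufficientDataError, ValidationError

logger = logging.getLogger(__name__)

WINDOW_LENGTH = 15
CENTER = WINDOW_LENGTH // 2
PHOSPHO_RESIDUES = frozenset("STY")
PAD_CHAR = "_"

#: mandatory metadata columns of a phosphopeptide table, in canonical order
META_COLUMNS = ("peptide_id", "protein_ids", "residue", "site_position", "sequence_window")

ARMS = ("standard", "experimental", "unknown")
RESPONSES = ("responder", "nonresponder")


@dataclass(frozen=True)
class PhosphoPeptideRecord:
    """One phosphopeptide: identity, site annotation and sequence context."""

    peptide_id: str
    protein_ids: tuple[str, ...]
    residue: str  # one of S, T, Y
    site_position: int  # 1-based position in the protein
    sequence_window: str  # 15 residues, phosphosite at the centre, '_'-padded

    def validate(self) -> None:
        if not self.peptide_id:
            raise ValidationError("peptide_id must be non-empty")
        if len(self.protein_ids) < 1:
            raise ValidationError(f"{self.peptide_id}: needs >=1 protein accession")
        if self.residue not in PHOSPHO_RESIDUES:
            raise ValidationError(
                f"{self.peptide_id}: residue {self.residue!r} not in S/T/Y"
            )
        if self.site_position < 1:
            raise ValidationError(f"{self.peptide_id}: site_position must be >=1")
        if len(self.sequence_window) != WINDOW_LENGTH:
            raise ValidationError(
                f"{self.peptide_id}: sequence_window must be {WINDOW_LENGTH} chars, "
                f"got {len(self.sequence_window)}"
            )
        center = self.sequence_window[CENTER]
        if center == PAD_CHAR:
            raise ValidationError(
                f"{self.peptide_id}: degenerate window with padded centre"
            )
        if center != self.residue:
            raise ValidationError(
                f"{self.peptide_id}: window centre {center!r} != residue {self.residue!r}"
            )


@dataclass(frozen=True)
class SampleAnnotation:
    """Treatment arm and pathologic response for one trial sample."""

    sample_id: str
    arm: str  # standard | experimental | unknown
    response: str  # responder (pCR / RCB=0) | nonresponder (RCB>0)
    site: str | None = None

    def validate(self) -> None:
        if self.arm not in ARMS:
            raise ValidationError(f"{self.sample_id}: arm {self.arm!r} not in {ARMS}")
        if self.response not in RESPONSES:
            raise ValidationError(
                f"{self.sample_id}: response {self.response!r} not in {RESPONSES}"
            )


class IntensityMatrix:
    """Phosphopeptide intensities (peptides x samples) plus peptide metadata.

    ``values`` is a float DataFrame indexed by peptide_id with one column per
    sample; 0 encodes "not detected" (no NaN state is kept).  ``meta`` is
    indexed identically and carries the :data:`META_COLUMNS` minus peptide_id.
    """

    def __init__(self, meta: pd.DataFrame, values: pd.DataFrame, validate: bool = True):
        self.meta = meta
        self.values = values.astype(float)
        if validate:
            self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_records(
        cls,
        peptides: Sequence[PhosphoPeptideRecord],
        samples: Sequence[str],
        values: np.ndarray,
    ) -> "IntensityMatrix":
        meta = pd.DataFrame(
            {
                "protein_ids": [p.protein_ids for p in peptides],
                "residue": [p.residue for p in peptides],
                "site_position": [p.site_position for p in peptides],
                "sequence_window": [p.sequence_window for p in peptides],
            },
            index=pd.Index([p.peptide_id for p in peptides], name="peptide_id"),
        )
        vals = pd.DataFrame(np.asarray(values, dtype=float), index=meta.index,
                            columns=list(samples))
        return cls(meta, vals)

    # -- accessors ---------------------------------------------------------

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def peptides(self) -> list[PhosphoPeptideRecord]:
        out = []
        for pid, row in self.meta.iterrows():
            out.append(
                PhosphoPeptideRecord(
                    peptide_id=str(pid),
                    protein_ids=tuple(row["protein_ids"]),
                    residue=row["residue"],
                    site_position=int(row["site_position"]),
                    sequence_window=row["sequence_window"],
                )
            )
        return out

    def restrict_samples(self, samples: Sequence[str]) -> "IntensityMatrix":
        return IntensityMatrix(self.meta, self.values[list(samples)], validate=False)

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        if not self.values.index.equals(self.meta.index):
            raise ValidationError("values and meta must share the same peptide index")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate peptide_id(s): {dups[:5]}")
        if pd.Index(self.values.columns).duplicated().any():
            raise ValidationError("duplicate sample IDs")
        arr = self.values.to_numpy()
        if np.isnan(arr).any():
            raise ValidationError("NaN intensities are not allowed (use 0 = not detected)")
        neg = np.argwhere(arr < 0)
        if neg.size:
            r, c = neg[0]
            raise ValidationError(
                f"negative intensity at row {r} ({self.values.index[r]!r}), "
                f"sample {self.values.columns[c]!r}"
            )
        for rec in self.peptides():
            rec.validate()

    def __eq__(self, other: object) -> bool:  # mainly for round-trip tests
        if not isinstance(other, IntensityMatrix):
            return NotImplemented
        return (
            self.values.equals(other.values)
            and self.meta.drop(columns="protein_ids").equals(
                other.meta.drop(columns="protein_ids"))
            and list(self.meta["protein_ids"].map(tuple))
            == list(other.meta["protein_ids"].map(tuple))
        )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sep_for(path: Path, dialect: str | None) -> str:
    if dialect is None:
        dialect = "csv" if Path(path).suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}")
    return "\t" if dialect == "tsv" else ","


def read_intensity_table(path: str | Path, dialect: str | None = None) -> IntensityMatrix:
    """Read a phosphopeptide intensity table (TSV/CSV).

    Columns: ``peptide_id, protein_ids (';'-separated), residue,
    site_position, sequence_window, <sample_1>, ..., <sample_n>``.
    Empty intensity cells are read as 0 ("not detected").
    """
    sep = _sep_for(Path(path), dialect)
    df = pd.read_csv(path, sep=sep, dtype={"peptide_id": str},
                     float_precision="round_trip")
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    if df["peptide_id"].duplicated().any():
        dups = df.loc[df["peptide_id"].duplicated(), "peptide_id"].tolist()
        raise ValidationError(f"{path}: duplicate peptide_id(s) {dups[:5]}")
    sample_cols = [c for c in df.columns if c not in META_COLUMNS]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    meta = pd.DataFrame(
        {
            "protein_ids": [tuple(p for p in str(s).split(";") if p)
                            for s in df["protein_ids"]],
            "residue": df["residue"].astype(str).to_numpy(),
            "site_position": df["site_position"].astype(int).to_numpy(),
            "sequence_window": df["sequence_window"].astype(str).to_numpy(),
        },
        index=pd.Index(df["peptide_id"], name="peptide_id"),
    )
    values = df[sample_cols].apply(pd.to_numeric, errors="raise")
    values.index = meta.index
    values = values.fillna(0.0)
    return IntensityMatrix(meta, values)


def write_intensity_table(matrix: IntensityMatrix, path: str | Path,
                          dialect: str | None = None) -> None:
    sep = _sep_for(Path(path), dialect)
    out = pd.DataFrame(
        {
            "peptide_id": matrix.values.index,
            "protein_ids": [";".join(p) for p in matrix.meta["protein_ids"]],
            "residue": matrix.meta["residue"].to_numpy(),
            "site_position": matrix.meta["site_position"].to_numpy(),
            "sequence_window": matrix.meta["sequence_window"].to_numpy(),
        }
    )
    for s in matrix.samples:
        out[s] = matrix.values[s].to_numpy()
    out.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_annotation_table(path: str | Path, dialect: str | None = None
                          ) -> list[SampleAnnotation]:
    """Read sample annotations (``sample_id, arm, response[, site]``)."""
    sep = _sep_for(Path(path), dialect)
    df = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "arm", "response"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing mandatory column {col!r}")
    anns = []
    for _, row in df.iterrows():
        site = row.get("site")
        ann = SampleAnnotation(
            sample_id=row["sample_id"],
            arm=row["arm"],
            response=row["response"],
            site=None if site is None or pd.isna(site) else str(site),
        )
        ann.validate()
        anns.append(ann)
    return anns


def write_annotation_table(annotations: Sequence[SampleAnnotation],
                           path: str | Path, dialect: str | None = None) -> None:
    sep = _sep_for(Path(path), dialect)
    pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in annotations],
            "arm": [a.arm for a in annotations],
            "response": [a.response for a in annotations],
            "site": [a.site if a.site is not None else "" for a in annotations],
        }
    ).to_csv(path, sep=sep, index=False)


def write_results_table(records: Iterable, path: str | Path,
                        dialect: str | None = None) -> None:
    """Write a homogeneous list of result dataclasses (or a DataFrame) as TSV.

    Stable column order (dataclass field order); floats at 17 significant
    digits so re-reading reproduces values to full double precision.
    An empty record list yields a header-only file only when given a DataFrame;
    for lists the record type is needed, so empty lists produce an empty file
    with a warning.
    """
    sep = _sep_for(Path(path), dialect)
    if isinstance(records, pd.DataFrame):
        records.to_csv(path, sep=sep, index=False, float_format="%.17g")
        return
    records = list(records)
    if not records:
        logger.warning("write_results_table: empty record list -> empty file %s", path)
        Path(path).write_text("")
        return
    first_type = type(records[0])
    if not dataclasses.is_dataclass(records[0]):
        raise TypeError(f"records must be dataclasses, got {first_type.__name__}")
    if any(type(r) is not first_type for r in records):
        raise TypeError("heterogeneous records: all rows must share one type")
    cols = [f.name for f in dataclasses.fields(first_type)]
    df = pd.DataFrame([dataclasses.asdict(r) for r in records], columns=cols)
    df.to_csv(path, sep=sep, index=False, float_format="%.17g")


def read_results_table(path: str | Path, dialect: str | None = None) -> pd.DataFrame:
    return pd.read_csv(path, sep=_sep_for(Path(path), dialect))


# ---------------------------------------------------------------------------
# annotation alignment
# ---------------------------------------------------------------------------

def align_annotations(
    matrix: IntensityMatrix, annotations: Sequence[SampleAnnotation]
) -> tuple[IntensityMatrix, list[SampleAnnotation]]:
    """Restrict matrix and annotations to their common samples, order-synced.

    Requires at least 2 samples per response group in the intersection.
    Dropped sample IDs are logged.
    """
    by_id = {a.sample_id: a for a in annotations}
    kept = [s for s in matrix.samples if s in by_id]
    dropped_m = [s for s in matrix.samples if s not in by_id]
    dropped_a = [a.sample_id for a in annotations if a.sample_id not in set(matrix.samples)]
    if dropped_m:
        logger.info("align_annotations: dropping unannotated samples %s", dropped_m)
    if dropped_a:
        logger.info("align_annotations: dropping annotations without samples %s", dropped_a)
    kept_anns = [by_id[s] for s in kept]
    counts = {r: sum(a.response == r for a in kept_anns) for r in RESPONSES}
    if any(c < 2 for c in counts.values()):
        raise InsufficientDataError(
            f"need >=2 samples per response group after alignment, got {counts}"
        )
    return matrix.restrict_samples(kept), kept_anns


def response_mask(annotations: Sequence[SampleAnnotation]) -> np.ndarray:
    """Boolean array: True for responders (pCR), in annotation order."""
    return np.array([a.response == "responder" for a in annotations], dtype=bool)
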