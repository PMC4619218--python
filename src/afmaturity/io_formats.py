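"""Readers, writers and validated in-memory containers for every external
format the pipeline touches.

Formats
-------
* expression matrix / tissue atlas: TSV, genes in rows, samples/tissues in
  the header row, first column holds gene identifiers
* sample metadata: TSV with columns ``sample_id, stage, weeks, sex,
  morbidities`` (morbidities semicolon-separated)
* marker database: GMT dialect (label, description, gene symbols...)
* splice junctions: BED12 as emitted by spliced aligners; the score column
  carries the junction read count, the two blocks are the exonic anchors

All writers emit UTF-8 with LF line endings.  Gene identifiers are treated
as opaque, case-insensitive symbols (uppercased on read where matching
across files matters); no identifier remapping is performed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

STAGES = ("PN", "PT", "FT")
#: gestational-week windows consistent with each stage label
STAGE_WEEKS = {"PN": (18.0, 24.0), "PT": (34.0, 36.0), "FT": (39.0, 40.0)}
SEXES = ("male", "female", "unknown")
MORBIDITIES = ("respiratory_support", "gavage_feeding")


class FormatError(ValueError):
    """A file does not parse as the declared format."""


class ValidationError(ValueError):
    """Parsed content violates a container invariant."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix.

    ``scale`` flags whether values are RPKM-like ("rpkm") or raw-count-like
    ("counts"); normalization expects counts, filtering and downstream
    statistics expect RPKM.
    """

    data: pd.DataFrame  # index: gene ids, columns: sample ids
    scale: str = "rpkm"

    def __post_init__(self) -> None:
        if self.scale not in ("rpkm", "counts"):
            raise ValidationError(f"unknown scale tag {self.scale!r}")
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "sample id")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            bad = np.argwhere(~np.isfinite(values))[0]
            raise ValidationError(
                f"non-finite value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )
        if (values < 0).any():
            bad = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative value at gene {self.data.index[bad[0]]!r}, "
                f"sample {self.data.columns[bad[1]]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    stage: str
    gestational_weeks: float | None = None
    fetal_sex: str = "unknown"
    morbidity_flags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValidationError(
                f"sample {self.sample_id!r}: stage {self.stage!r} not in {STAGES}"
            )
        if self.fetal_sex not in SEXES:
            raise ValidationError(
                f"sample {self.sample_id!r}: sex {self.fetal_sex!r} not in {SEXES}"
            )
        unknown = set(self.morbidity_flags) - set(MORBIDITIES)
        if unknown:
            raise ValidationError(
                f"sample {self.sample_id!r}: unknown morbidity flags {sorted(unknown)}"
            )
        if self.gestational_weeks is not None:
            lo, hi = STAGE_WEEKS[self.stage]
            if not (lo <= self.gestational_weeks <= hi):
                raise ValidationError(
                    f"sample {self.sample_id!r}: {self.gestational_weeks} weeks "
                    f"inconsistent with stage {self.stage} ({lo}-{hi})"
                )


@dataclass
class TissueAtlas:
    """Genes x tissues mean-expression reference used for specificity scoring."""

    data: pd.DataFrame  # index: gene ids, columns: tissue labels

    def __post_init__(self) -> None:
        _check_unique(self.data.index, "gene id")
        _check_unique(self.data.columns, "tissue label")
        if self.data.shape[1] < 3:
            raise ValidationError(
                f"atlas needs >= 3 tissues, got {self.data.shape[1]}"
            )
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all() or (values < 0).any():
            raise ValidationError("atlas values must be finite and >= 0")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def tissue_labels(self) -> list[str]:
        return list(self.data.columns)


class MarkerDatabase(dict):
    """Mapping marker-set label -> frozenset of (uppercased) gene symbols."""

    def __init__(self, sets: Mapping[str, Iterable[str]]):
        super().__init__()
        for label, genes in sets.items():
            genes = frozenset(str(g).upper() for g in genes)
            if not genes:
                raise ValidationError(f"marker set {label!r} is empty")
            if label in self:
                raise ValidationError(f"duplicate marker-set label {label!r}")
            self[label] = genes


@dataclass(frozen=True, order=True)
class JunctionRecord:
    """A splice junction: the intron it spans plus supporting read count.

    Coordinates are 0-based half-open on the genome: ``intron_start`` is the
    first intronic base, ``intron_end`` one past the last.
    """

    chrom: str
    intron_start: int
    intron_end: int
    strand: str = "."
    read_count: int = 0
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.intron_start >= self.intron_end:
            raise ValidationError(
                f"junction {self.chrom}:{self.intron_start}-{self.intron_end}: "
                "intron_start must be < intron_end"
            )
        if self.read_count < 0:
            raise ValidationError("read_count must be >= 0")
        if self.strand not in ("+", "-", "."):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, int]:
        """Coordinate identity used for matching across samples and panels."""
        return (self.chrom, self.intron_start, self.intron_end)


def _check_unique(labels: Sequence, what: str) -> None:
    seen: set = set()
    for lab in labels:
        if lab in seen:
            raise ValidationError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


# ---------------------------------------------------------------------------
# expression matrix / atlas TSV
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, scale_tag: str = "rpkm") -> ExpressionMatrix:
    df = _read_gene_table(path)
    return ExpressionMatrix(df, scale=scale_tag)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    _write_gene_table(matrix.data, path, index_label="gene_id")


def read_tissue_atlas(path: str | Path) -> TissueAtlas:
    return TissueAtlas(_read_gene_table(path))


def write_tissue_atlas(atlas: TissueAtlas, path: str | Path) -> None:
    _write_gene_table(atlas.data, path, index_label="gene_id")


def _read_gene_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0)
    except Exception as exc:  # pandas raises a zoo of types
        raise FormatError(f"{path}: cannot parse as TSV gene table: {exc}") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression values: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return df


def _write_gene_table(df: pd.DataFrame, path: str | Path, index_label: str) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        df.to_csv(fh, sep="\t", index_label=index_label, lineterminator="\n")


# ---------------------------------------------------------------------------
# sample metadata TSV
# ---------------------------------------------------------------------------

def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"sample_id", "stage"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing metadata columns {sorted(missing)}")
    out: list[SampleMetadata] = []
    seen: set[str] = set()
    for _, row in df.iterrows():
        sid = row["sample_id"]
        if sid in seen:
            raise ValidationError(f"duplicate sample id {sid!r}")
        seen.add(sid)
        weeks = row.get("weeks", "")
        flags = frozenset(f for f in row.get("morbidities", "").split(";") if f)
        out.append(
            SampleMetadata(
                sample_id=sid,
                stage=row["stage"],
                gestational_weeks=float(weeks) if weeks else None,
                fetal_sex=row.get("sex", "") or "unknown",
                morbidity_flags=flags,
            )
        )
    return out


def write_sample_metadata(samples: Sequence[SampleMetadata], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("sample_id\tstage\tweeks\tsex\tmorbidities\n")
        for s in samples:
            weeks = "" if s.gestational_weeks is None else f"{s.gestational_weeks:g}"
            fh.write(
                f"{s.sample_id}\t{s.stage}\t{weeks}\t{s.fetal_sex}\t"
                f"{';'.join(sorted(s.morbidity_flags))}\n"
            )


# ---------------------------------------------------------------------------
# marker database (GMT)
# ---------------------------------------------------------------------------

def read_marker_database(path: str | Path) -> MarkerDatabase:
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3 or not any(g for g in parts[2:]):
                raise ValidationError(
                    f"{path}:{lineno}: marker set {parts[0]!r} has no genes"
                )
            label = parts[0]
            if label in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate label {label!r}")
            sets[label] = [g for g in parts[2:] if g]
    return MarkerDatabase(sets)


def write_marker_database(db: MarkerDatabase, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for label in db:
            genes = "\t".join(sorted(db[label]))
            fh.write(f"{label}\tna\t{genes}\n")


# ---------------------------------------------------------------------------
# junction BED12
# ---------------------------------------------------------------------------

#: exonic anchor length used when writing junction records back to BED12
_ANCHOR = 20


def read_junctions_bed(path: str | Path, sample_id: str = "") -> tuple[list[JunctionRecord], int]:
    """Parse a junction BED12 file into :class:`JunctionRecord` s.

    The BED span covers both exonic anchors; the intron is recovered as
    ``intron_start = chromStart + blockSizes[0]`` and
    ``intron_end = chromStart + blockStarts[1]``.  Records whose block count
    is not 2 are skipped with a warning.

    Returns ``(records, n_skipped)`` with records sorted by
    ``(chrom, intron_start, intron_end)``.
    """
    path = Path(path)
    records: list[JunctionRecord] = []
    n_skipped = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("track", "browser", "#")):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise FormatError(f"{path}:{lineno}: expected 12 BED columns, got {len(parts)}")
            try:
                chrom_start = int(parts[1])
                score = int(parts[4])
                block_count = int(parts[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer BED field: {exc}") from exc
            if block_count != 2:
                warnings.warn(
                    f"{path}:{lineno}: skipping record with {block_count} blocks",
                    stacklevel=2,
                )
                n_skipped += 1
                continue
            block_sizes = [int(x) for x in parts[10].rstrip(",").split(",")]
            block_starts = [int(x) for x in parts[11].rstrip(",").split(",")]
            if len(block_sizes) != 2 or len(block_starts) != 2:
                raise FormatError(f"{path}:{lineno}: block lists disagree with blockCount")
            records.append(
                JunctionRecord(
                    chrom=parts[0],
                    intron_start=chrom_start + block_sizes[0],
                    intron_end=chrom_start + block_starts[1],
                    strand=parts[5] if parts[5] in ("+", "-") else ".",
                    read_count=score,
                    sample_id=sample_id,
                )
            )
    records.sort(key=lambda r: (r.chrom, r.intron_start, r.intron_end))
    return records, n_skipped


def write_junctions_bed(records: Iterable[JunctionRecord], path: str | Path) -> None:
    """Write junctions as two-block BED12 lines (inverse of the reader)."""
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for i, r in enumerate(records):
            anchor = min(_ANCHOR, r.intron_start)  # keep chromStart >= 0
            chrom_start = r.intron_start - anchor
            chrom_end = r.intron_end + _ANCHOR
            block_starts = f"0,{r.intron_end - chrom_start}"
            fh.write(
                f"{r.chrom}\t{chrom_start}\t{chrom_end}\tJUNC{i + 1:05d}\t"
                f"{r.read_count}\t{r.strand}\t{chrom_start}\t{chrom_end}\t0\t2\t"
                f"{anchor},{_ANCHOR}\t{block_starts}\n"
            )
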