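"""Core in-memory types and file readers/writers for the circRNA pipeline.

Every downstream stage (quantification, tissue specificity, differential
expression, attribution, signature classification) consumes only the types
defined here.  Coordinates are 0-based, half-open (BED convention)
throughout; GTF input is converted on read.

External dialects handled:

* CIRCexplorer2-style back-splice call files (BED12+ with a read-count
  column), one per sample;
* sample metadata TSV (sample, tissue, condition, patient, mapped reads);
* feature-by-sample expression/count TSV matrices;
* BED6 interval files (RBP binding peaks, repeat elements);
* GTF gene models (exon/CDS features);
* a circBase ID-map TSV (coordinates to ``hsa_circ`` accession), so that
  annotation-membership filtering needs no network access;
* a key-value YAML configuration overriding :class:`PipelineConfig`.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

__all__ = [
    "FormatError",
    "CircRNARecord",
    "SampleMeta",
    "JunctionCountMatrix",
    "ExpressionMatrix",
    "PipelineConfig",
    "TranscriptModel",
    "GenomicIntervals",
    "CircCalls",
    "read_circ_calls",
    "read_id_map",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_expression_tsv",
    "write_expression_tsv",
    "read_intervals_bed",
    "read_transcript_models",
    "load_config",
    "assemble_junction_matrix",
]

logger = logging.getLogger("circsig")

VALID_UNITS = ("RPM", "FPKM", "raw_count")
CONDITIONS = ("tumor", "normal")


class FormatError(ValueError):
    """An input file violates the dialect this pipeline expects."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CircRNARecord:
    """One back-splice locus.

    ``start`` is the 0-based inclusive back-splice acceptor coordinate and
    ``end`` the exclusive donor coordinate.  ``exon_blocks`` are half-open
    genomic intervals of the circularised exons, sorted and non-overlapping,
    contained in ``[start, end)``.
    """

    chrom: str
    start: int
    end: int
    strand: str
    circ_id: str
    host_gene: str = ""
    exon_blocks: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise FormatError(
                f"{self.circ_id}: start {self.start} must be < end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"{self.circ_id}: bad strand {self.strand!r}")
        blocks = self.exon_blocks or ((self.start, self.end),)
        object.__setattr__(self, "exon_blocks", tuple(tuple(b) for b in blocks))
        prev_end = self.start - 1
        for s, e in self.exon_blocks:
            if s >= e:
                raise FormatError(f"{self.circ_id}: empty exon block ({s},{e})")
            if s < self.start or e > self.end:
                raise FormatError(
                    f"{self.circ_id}: block ({s},{e}) outside [{self.start},{self.end})"
                )
            if s <= prev_end:
                raise FormatError(f"{self.circ_id}: blocks unsorted or overlapping")
            prev_end = e

    @property
    def exon_count(self) -> int:
        return len(self.exon_blocks)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exon_blocks)

    @property
    def coord_key(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass(frozen=True)
class SampleMeta:
    """One sequenced sample with its pairing key and sequencing depth.

    ``mapped_reads`` is the per-sample (uniquely) mapped-read total used as
    the reads-per-million denominator; which flavour of mapping total it is
    travels with the metadata rather than being guessed downstream.
    """

    sample_id: str
    tissue: str
    condition: str
    patient_id: str
    mapped_reads: int

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise FormatError(
                f"{self.sample_id}: condition must be one of {CONDITIONS}, "
                f"got {self.condition!r}"
            )
        if self.mapped_reads <= 0:
            raise FormatError(f"{self.sample_id}: mapped_reads must be > 0")


@dataclass
class JunctionCountMatrix:
    """Back-spliced and forward-spliced junction read counts, circRNAs x samples."""

    records: list[CircRNARecord]
    samples: list[SampleMeta]
    back_spliced: np.ndarray
    forward_spliced: np.ndarray

    def __post_init__(self) -> None:
        self.back_spliced = np.asarray(self.back_spliced)
        self.forward_spliced = np.asarray(self.forward_spliced)
        shape = (len(self.records), len(self.samples))
        for name, mat in (
            ("back_spliced", self.back_spliced),
            ("forward_spliced", self.forward_spliced),
        ):
            if mat.shape != shape:
                raise FormatError(f"{name} shape {mat.shape} != {shape}")
            if (mat < 0).any():
                raise FormatError(f"{name} contains negative counts")

    @property
    def circ_ids(self) -> list[str]:
        return [r.circ_id for r in self.records]

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def mapped_reads(self) -> np.ndarray:
        return np.array([s.mapped_reads for s in self.samples], dtype=float)

    def subset_records(self, index: Sequence[int]) -> "JunctionCountMatrix":
        index = list(index)
        return JunctionCountMatrix(
            [self.records[i] for i in index],
            self.samples,
            self.back_spliced[index, :],
            self.forward_spliced[index, :],
        )

    def subset_samples(self, keep: Sequence[str]) -> "JunctionCountMatrix":
        keep = set(keep)
        idx = [i for i, s in enumerate(self.samples) if s.sample_id in keep]
        return JunctionCountMatrix(
            self.records,
            [self.samples[i] for i in idx],
            self.back_spliced[:, idx],
            self.forward_spliced[:, idx],
        )

    def for_tissue(self, tissue: str) -> "JunctionCountMatrix":
        return self.subset_samples(
            [s.sample_id for s in self.samples if s.tissue == tissue]
        )


@dataclass
class ExpressionMatrix:
    """Normalized abundance or raw counts, features x samples, single unit."""

    feature_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    unit: str
    samples: list[SampleMeta] | None = None

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise FormatError(f"unit must be one of {VALID_UNITS}, got {self.unit!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise FormatError(
                f"values shape {self.values.shape} != "
                f"({len(self.feature_ids)}, {len(self.sample_ids)})"
            )
        if (self.values < 0).any():
            raise FormatError("expression values must be non-negative")
        dup = pd.Index(self.feature_ids).duplicated()
        if dup.any():
            bad = [f for f, d in zip(self.feature_ids, dup) if d]
            raise FormatError(f"duplicate feature IDs: {sorted(set(bad))[:5]}")
        if self.samples is not None:
            meta_ids = [s.sample_id for s in self.samples]
            if meta_ids != self.sample_ids:
                raise FormatError("sample metadata does not match sample_ids order")

    @property
    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.feature_ids, columns=self.sample_ids
        )

    def attach_samples(self, samples: Sequence[SampleMeta]) -> "ExpressionMatrix":
        """Align columns to the given metadata; error on samples absent from the matrix."""
        by_id = {s.sample_id: s for s in samples}
        missing = [sid for sid in by_id if sid not in self.sample_ids]
        if missing:
            raise FormatError(f"metadata samples absent from matrix: {missing}")
        order = [self.sample_ids.index(sid) for sid in by_id]
        return ExpressionMatrix(
            list(self.feature_ids),
            list(by_id),
            self.values[:, order],
            self.unit,
            samples=list(by_id.values()),
        )

    def subset_features(self, keep: Sequence[str]) -> "ExpressionMatrix":
        keep_set = set(keep)
        idx = [i for i, f in enumerate(self.feature_ids) if f in keep_set]
        return ExpressionMatrix(
            [self.feature_ids[i] for i in idx],
            list(self.sample_ids),
            self.values[idx, :],
            self.unit,
            samples=self.samples,
        )


@dataclass
class PipelineConfig:
    """Analysis thresholds; defaults follow standard practice for this analysis."""

    min_support_reads: int = 2
    circ_abundance_median_rpm: float = 0.1
    gene_abundance_median_fpkm: float = 10.0
    tsi_ubiquitous_max: float = 0.3
    tsi_specific_min: float = 0.85
    de_min_fold_change: float = 2.0
    de_max_padj: float = 0.05
    de_prevalence_fraction: float = 0.10
    de_prevalence_min_rpm: float = 0.1
    corr_strong_min: float = 0.7
    junction_ratio_dominant_min: float = 0.5
    rbp_abundance_prefilter: bool = False
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "min_support_reads",
            "circ_abundance_median_rpm",
            "gene_abundance_median_fpkm",
            "tsi_ubiquitous_max",
            "tsi_specific_min",
            "de_min_fold_change",
            "de_max_padj",
            "de_prevalence_fraction",
            "de_prevalence_min_rpm",
            "corr_strong_min",
            "junction_ratio_dominant_min",
        ):
            if getattr(self, name) <= 0:
                raise FormatError(f"config threshold {name} must be positive")
        if self.tsi_ubiquitous_max >= self.tsi_specific_min:
            raise FormatError("tsi_ubiquitous_max must be < tsi_specific_min")

    def provenance(self) -> str:
        items = ", ".join(f"{k}={v}" for k, v in asdict(self).items())
        return f"circsig config: {items}"


@dataclass(frozen=True)
class TranscriptModel:
    """A gene model transcript: sorted exons plus an optional CDS span.

    All intervals 0-based half-open.  UTR intervals are derived from the exon
    structure and the CDS span; ``five prime`` / ``three prime`` assignment
    respects strand.
    """

    tx_id: str
    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "exons", tuple(sorted(tuple(e) for e in self.exons)))
        if not self.exons:
            raise FormatError(f"{self.tx_id}: transcript without exons")

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def cds_length(self) -> int:
        if self.cds is None:
            return 0
        return sum(
            max(0, min(e, self.cds[1]) - max(s, self.cds[0])) for s, e in self.exons
        )

    def _exonic_clip(self, lo: int, hi: int) -> tuple[tuple[int, int], ...]:
        out = []
        for s, e in self.exons:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                out.append((a, b))
        return tuple(out)

    @property
    def cds_intervals(self) -> tuple[tuple[int, int], ...]:
        if self.cds is None:
            return ()
        return self._exonic_clip(*self.cds)

    @property
    def utr5_intervals(self) -> tuple[tuple[int, int], ...]:
        if self.cds is None:
            return ()
        left = self._exonic_clip(self.span[0], self.cds[0])
        right = self._exonic_clip(self.cds[1], self.span[1])
        return left if self.strand == "+" else right

    @property
    def utr3_intervals(self) -> tuple[tuple[int, int], ...]:
        if self.cds is None:
            return ()
        left = self._exonic_clip(self.span[0], self.cds[0])
        right = self._exonic_clip(self.cds[1], self.span[1])
        return right if self.strand == "+" else left


class GenomicIntervals:
    """Strand-agnostic interval set with per-chromosome overlap queries."""

    def __init__(self) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self.n = 0

    def add(self, chrom: str, start: int, end: int, name: str = "") -> None:
        if start >= end:
            raise FormatError(f"empty interval {chrom}:{start}-{end}")
        self._trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
        self.n += 1

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str]]:
        tree = self._trees.get(chrom)
        if tree is None:
            return []
        return sorted((iv.begin, iv.end, iv.data) for iv in tree.overlap(start, end))

    def count(self, chrom: str, start: int, end: int) -> int:
        return len(self.overlapping(chrom, start, end))

    def __len__(self) -> int:
        return self.n


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


@dataclass
class CircCalls:
    """Parsed per-sample back-splice calls.

    ``unannotated`` lists coordinate keys of rows absent from the circBase
    ID map (callers decide whether to drop them); kept + unannotated rows
    always account for every input row.
    """

    sample_id: str
    records: list[CircRNARecord]
    back_spliced: np.ndarray | None
    n_input_rows: int
    unannotated: list[str]


def _parse_int(text: str, what: str, lineno: int) -> int:
    try:
        return int(text)
    except ValueError as exc:
        raise FormatError(f"line {lineno}: non-integer {what}: {text!r}") from exc


def read_circ_calls(
    path: str | Path,
    sample_id: str,
    id_map: Mapping[str, str] | None = None,
    keep_unannotated: bool = True,
) -> CircCalls:
    """Parse a CIRCexplorer2-style BED12+ back-splice call file.

    Columns 1-12 follow BED12 (blocks give the circularised exons); column 13,
    when present, is the back-spliced junction read count and column 15 the
    host-gene symbol.  Rows whose coordinates are missing from ``id_map`` are
    flagged as unannotated; their ``circ_id`` falls back to the coordinate key.
    """
    path = Path(path)
    records: list[CircRNARecord] = []
    counts: list[int] = []
    unannotated: list[str] = []
    have_counts = True
    n_rows = 0
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            n_rows += 1
            cols = line.split("\t")
            if len(cols) < 12:
                raise FormatError(
                    f"{path.name} line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(cols)}"
                )
            chrom = cols[0]
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            if end <= start:
                raise FormatError(
                    f"{path.name} line {lineno}: end {end} <= start {start}"
                )
            strand = cols[5]
            n_blocks = _parse_int(cols[9], "blockCount", lineno)
            try:
                sizes = [int(x) for x in cols[10].rstrip(",").split(",")]
                offsets = [int(x) for x in cols[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise FormatError(
                    f"{path.name} line {lineno}: malformed block lists"
                ) from exc
            if len(sizes) != n_blocks or len(offsets) != n_blocks:
                raise FormatError(
                    f"{path.name} line {lineno}: block lists disagree with blockCount"
                )
            blocks = tuple(
                (start + off, start + off + size) for off, size in zip(offsets, sizes)
            )
            coord_key = f"{chrom}:{start}-{end}"
            circ_id = (id_map or {}).get(coord_key, "")
            if not circ_id:
                unannotated.append(coord_key)
                if not keep_unannotated:
                    continue
                circ_id = coord_key
            host_gene = cols[14] if len(cols) > 14 else ""
            try:
                record = CircRNARecord(
                    chrom, start, end, strand, circ_id, host_gene, blocks
                )
            except FormatError as exc:
                raise FormatError(f"{path.name} line {lineno}: {exc}") from exc
            records.append(record)
            if len(cols) > 12 and cols[12] != "":
                counts.append(_parse_int(cols[12], "readNumber", lineno))
            else:
                have_counts = False
    if n_rows == 0:
        logger.warning("%s: empty circRNA call file", path.name)
    if unannotated:
        logger.warning(
            "%s: %d/%d rows lack a circBase ID", path.name, len(unannotated), n_rows
        )
    back = np.array(counts, dtype=int) if have_counts and records else None
    return CircCalls(sample_id, records, back, n_rows, unannotated)


def read_id_map(path: str | Path) -> dict[str, str]:
    """TSV of chrom, start, end, circ_id -> {``chrom:start-end``: circ_id}."""
    df = pd.read_csv(
        path, sep="\t", comment="#", names=["chrom", "start", "end", "circ_id"]
    )
    return {
        f"{r.chrom}:{r.start}-{r.end}": r.circ_id for r in df.itertuples(index=False)
    }


_META_COLS = ["sample_id", "tissue", "condition", "patient_id", "mapped_reads"]


def read_sample_metadata(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _META_COLS if c not in df.columns]
    if missing:
        raise FormatError(f"sample metadata missing columns: {missing}")
    samples = [
        SampleMeta(
            str(r.sample_id),
            str(r.tissue),
            str(r.condition),
            str(r.patient_id),
            int(r.mapped_reads),
        )
        for r in df.itertuples(index=False)
    ]
    seen: set[tuple[str, str]] = set()
    for s in samples:
        key = (s.patient_id, s.condition)
        if key in seen:
            raise FormatError(f"duplicate (patient_id, condition): {key}")
        seen.add(key)
    return samples


def write_sample_metadata(samples: Sequence[SampleMeta], path: str | Path) -> None:
    df = pd.DataFrame([asdict(s) for s in samples], columns=_META_COLS)
    df.to_csv(path, sep="\t", index=False)


def read_expression_tsv(
    path: str | Path,
    unit: str,
    samples: Sequence[SampleMeta] | None = None,
) -> ExpressionMatrix:
    """Read a feature-by-sample TSV matrix (first column feature IDs)."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise FormatError(f"duplicate feature IDs in {path}: {dups[:5]}")
    if (df.values < 0).any():
        raise FormatError(f"negative values in {path}")
    em = ExpressionMatrix(
        [str(i) for i in df.index],
        [str(c) for c in df.columns],
        df.values.astype(float),
        unit,
    )
    if samples is not None:
        em = em.attach_samples(samples)
    return em


def write_expression_tsv(
    em: ExpressionMatrix, path: str | Path, header_comment: str | None = None
) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        em.frame.to_csv(fh, sep="\t", index_label="feature_id", float_format="%.6g")


def read_intervals_bed(path: str | Path) -> GenomicIntervals:
    """Parse BED (>= 3 columns, 0-based half-open) into an overlap-queryable set."""
    intervals = GenomicIntervals()
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise FormatError(f"BED line {lineno}: fewer than 3 columns")
            start = _parse_int(cols[1], "start", lineno)
            end = _parse_int(cols[2], "end", lineno)
            name = cols[3] if len(cols) > 3 else f"iv{lineno}"
            intervals.add(cols[0], start, end, name)
    return intervals


def read_transcript_models(gtf_path: str | Path) -> list[TranscriptModel]:
    """Build transcript models from a GTF (1-based inclusive, converted here)."""
    import gffutils

    db = gffutils.create_db(
        str(gtf_path),
        ":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    models = []
    for tx in db.features_of_type("transcript"):
        exons = [
            (f.start - 1, f.end) for f in db.children(tx, featuretype="exon")
        ]
        cds_parts = [
            (f.start - 1, f.end) for f in db.children(tx, featuretype="CDS")
        ]
        cds = None
        if cds_parts:
            cds = (min(s for s, _ in cds_parts), max(e for _, e in cds_parts))
        gene = tx.attributes.get("gene_name", tx.attributes.get("gene_id", [""]))[0]
        models.append(
            TranscriptModel(tx.id, gene, tx.seqid, tx.strand, tuple(exons), cds)
        )
    return models


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from an optional YAML file plus overrides."""
    values: dict = {}
    if path is not None:
        with Path(path).open() as fh:
            loaded = yaml.safe_load(fh) or {}
        if not isinstance(loaded, dict):
            raise FormatError("config file must be a key-value mapping")
        values.update(loaded)
    values.update(overrides)
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(values) - known
    if unknown:
        raise FormatError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**values)


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def assemble_junction_matrix(
    calls: Sequence[CircCalls],
    samples: Sequence[SampleMeta],
    forward: Mapping[str, Mapping[str, int]] | None = None,
    drop_unannotated: bool = False,
) -> JunctionCountMatrix:
    """Union per-sample call files into one counts matrix.

    ``forward`` optionally supplies linear-junction counts as
    ``{circ_id: {sample_id: count}}``; absent entries default to zero.
    """
    by_sample = {c.sample_id: c for c in calls}
    missing = [s.sample_id for s in samples if s.sample_id not in by_sample]
    if missing:
        raise FormatError(f"no call file for samples: {missing}")
    union: dict[str, CircRNARecord] = {}
    for c in calls:
        for rec in c.records:
            if drop_unannotated and rec.circ_id == rec.coord_key:
                continue
            union.setdefault(rec.circ_id, rec)
    records = sorted(union.values(), key=lambda r: (r.chrom, r.start, r.end))
    index = {r.circ_id: i for i, r in enumerate(records)}
    back = np.zeros((len(records), len(samples)), dtype=int)
    fwd = np.zeros_like(back)
    for j, s in enumerate(samples):
        c = by_sample[s.sample_id]
        counts = c.back_spliced
        if counts is None:
            raise FormatError(f"{s.sample_id}: call file lacks read counts")
        for rec, n in zip(c.records, counts):
            if rec.circ_id in index:
                back[index[rec.circ_id], j] = n
    if forward is not None:
        for circ_id, per_sample in forward.items():
            if circ_id not in index:
                continue
            for j, s in enumerate(samples):
                fwd[index[circ_id], j] = per_sample.get(s.sample_id, 0)
    return JunctionCountMatrix(records, list(samples), back, fwd)


def paired_samples(samples: Sequence[SampleMeta]) -> list[tuple[SampleMeta, SampleMeta]]:
    """(tumor, normal) pairs by patient; unpaired samples are dropped with a warning."""
    by_patient: dict[str, dict[str, SampleMeta]] = {}
    for s in samples:
        by_patient.setdefault(s.patient_id, {})[s.condition] = s
    pairs = []
    for patient, conds in by_patient.items():
        if "tumor" in conds and "normal" in conds:
            pairs.append((conds["tumor"], conds["normal"]))
        else:
            logger.warning("patient %s unpaired; excluded from paired analyses", patient)
    return pairs
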