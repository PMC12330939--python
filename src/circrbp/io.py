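"""Readers, writers and core domain containers.

Everything downstream operates on a handful of plain containers: a genome
(chromosome name -> uppercase DNA string), circRNA backsplice records with
0-based half-open coordinates, integer count matrices, RBP position
probability matrices, and per-sample metadata.  All RNA-space inputs are
folded into DNA space (U -> T) on read so genome slices and PWM columns
share one alphabet.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

DNA_ALPHABET = frozenset("ACGTN")
BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class FormatError(ValueError):
    """Raised when an input file violates its expected format."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeStore:
    """In-memory genome: chromosome -> uppercase DNA over {A,C,G,T,N}."""

    sequences: dict[str, str]

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if not (0 <= start <= end <= len(seq)):
            raise ValueError(
                f"interval {chrom}:{start}-{end} out of bounds (len {len(seq)})"
            )
        return seq[start:end]

    def validate(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - DNA_ALPHABET
            if bad:
                raise FormatError(f"chromosome {name}: illegal characters {sorted(bad)}")
            if len(seq) == 0:
                raise FormatError(f"chromosome {name}: empty sequence")


@dataclass
class CircRecord:
    """A circRNA defined by its backsplice interval (0-based half-open)."""

    circ_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exon_blocks: list[tuple[int, int]] | None = None
    host_gene: str | None = None
    annotation_class: str = "exonic"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.circ_id}: strand must be + or -, got {self.strand!r}")
        if not 0 <= self.start < self.end:
            raise ValueError(f"{self.circ_id}: require 0 <= start < end, got [{self.start},{self.end})")
        if self.exon_blocks is not None:
            prev_end = self.start - 1
            for (bs, be) in self.exon_blocks:
                if not (self.start <= bs < be <= self.end):
                    raise ValueError(f"{self.circ_id}: block ({bs},{be}) outside [{self.start},{self.end})")
                if bs <= prev_end:
                    raise ValueError(f"{self.circ_id}: blocks overlap or are unsorted")
                prev_end = be - 1

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class CountMatrix:
    """Non-negative integer counts, features x samples."""

    counts: pd.DataFrame  # index: feature ids, columns: sample ids
    feature_kind: str = "gene"  # {"circRNA", "gene"}

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.duplicated().any():
            dups = df.index[df.index.duplicated()].tolist()
            raise FormatError(f"duplicate feature ids: {dups}")
        if df.columns.duplicated().any():
            raise FormatError("duplicate sample ids")
        arr = df.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(np.equal(np.mod(arr, 1), 0)):
                raise FormatError("counts must be integral")
            self.counts = df.astype(np.int64)
            arr = self.counts.to_numpy()
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class PWMRecord:
    """Position probability matrix over A/C/G/T for one RBP motif."""

    rbp_name: str
    matrix: np.ndarray  # positions x 4, rows sum to 1
    source: str = "CISBP_RNA"  # {"CISBP_RNA", "RBNS"}

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4:
            raise ValueError(f"{self.rbp_name}: PWM must be positions x 4")
        if m.shape[0] < 4:
            raise ValueError(f"{self.rbp_name}: PWM must have >= 4 positions")
        if (m < 0).any():
            raise ValueError(f"{self.rbp_name}: negative probability")
        sums = m.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"{self.rbp_name}: PWM rows must sum to 1")
        self.matrix = m

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class SampleMeta:
    sample_id: str
    group: str  # {"GBM_PRM", "GBM_REC", "HB"}
    subtype: str | None = None  # {classical, mesenchymal, neural, proneural}
    survival_time: float | None = None
    event: int | None = None

    def __post_init__(self) -> None:
        if (self.survival_time is None) != (self.event is None):
            raise ValueError(f"{self.sample_id}: survival_time and event must be present together")
        if self.survival_time is not None and self.survival_time <= 0:
            raise ValueError(f"{self.sample_id}: survival_time must be > 0")


@dataclass
class PipelineConfig:
    """Flat bundle of pipeline thresholds and lengths.

    All of the tunables that the analysis stages consult live here so a
    single file pins an entire run; every stochastic stage derives its RNG
    from ``seed``.
    """

    k: int = 6
    flank_len: int = 1000
    boundary_len: int = 50
    de_fdr: float = 0.05
    motif_fdr: float = 0.1
    chi2_alpha: float = 0.01
    anova_alpha: float = 0.05
    corr_alpha: float = 0.05
    separation_threshold: float = 3.0
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("k", "flank_len", "boundary_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("de_fdr", "motif_fdr", "chi2_alpha", "anova_alpha", "corr_alpha"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {v}")
        self.k_range = tuple(int(k) for k in self.k_range)

    @classmethod
    def from_file(cls, path: str | os.PathLike) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_file(self, path: str | os.PathLike) -> None:
        data = dataclasses.asdict(self)
        data["k_range"] = list(self.k_range)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_fasta(path: str | os.PathLike) -> GenomeStore:
    """Read a genome FASTA; uppercase, U folded to T, alphabet-checked."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        name = record.id
        if not name:
            raise FormatError(f"{path}: FASTA record with empty header")
        if name in sequences:
            raise FormatError(f"{path}: duplicate FASTA header {name!r}")
        seq = str(record.seq).upper().replace("U", "T")
        if len(seq) == 0:
            raise FormatError(f"{path}: record {name!r} has empty sequence")
        bad = set(seq) - DNA_ALPHABET
        if bad:
            raise FormatError(f"{path}: record {name!r} has illegal characters {sorted(bad)}")
        sequences[name] = seq
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return GenomeStore(sequences)


def write_fasta(store: GenomeStore | Mapping[str, str], path: str | os.PathLike, width: int = 80) -> None:
    seqs = store.sequences if isinstance(store, GenomeStore) else store
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_circ_bed(path: str | os.PathLike) -> list[CircRecord]:
    """Read circRNA annotations from BED6 / BED12 (0-based half-open)."""
    records: list[CircRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: expected >= 6 tab-separated columns, got {len(fields)}")
            chrom, start_s, end_s, name, _score, strand = fields[:6]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(f"{path}:{lineno}: start >= end ({start} >= {end})")
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: unknown strand {strand!r}")
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate circ_id {name!r}")
            seen.add(name)
            exon_blocks = None
            if len(fields) >= 12:
                try:
                    n_blocks = int(fields[9])
                    sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
                    starts = [int(x) for x in fields[11].rstrip(",").split(",")]
                except ValueError as exc:
                    raise FormatError(f"{path}:{lineno}: malformed BED12 block columns") from exc
                if len(sizes) != n_blocks or len(starts) != n_blocks:
                    raise FormatError(f"{path}:{lineno}: block count mismatch")
                exon_blocks = [(start + s, start + s + sz) for s, sz in zip(starts, sizes)]
            try:
                rec = CircRecord(name, chrom, start, end, strand, exon_blocks=exon_blocks)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            records.append(rec)
    return records


def write_circ_bed(records: Sequence[CircRecord], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for rec in records:
            cols = [rec.chrom, str(rec.start), str(rec.end), rec.circ_id, "0", rec.strand]
            if rec.exon_blocks:
                sizes = ",".join(str(be - bs) for bs, be in rec.exon_blocks)
                starts = ",".join(str(bs - rec.start) for bs, be in rec.exon_blocks)
                cols += [str(rec.start), str(rec.end), "0", str(len(rec.exon_blocks)), sizes, starts]
            fh.write("\t".join(cols) + "\n")


def read_count_matrix(path: str | os.PathLike, feature_kind: str = "gene") -> CountMatrix:
    """Read a TSV count matrix: first column feature id, header = sample ids."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: ragged or malformed TSV ({exc})") from exc
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate feature ids {dups}")
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise FormatError(f"{path}: non-numeric cells in count matrix")
    if np.isnan(arr.astype(float)).any():
        raise FormatError(f"{path}: missing values in count matrix")
    if not np.all(np.equal(np.mod(arr, 1), 0)):
        raise FormatError(f"{path}: non-integer counts")
    if (arr < 0).any():
        raise FormatError(f"{path}: negative counts")
    df.index = df.index.astype(str)
    return CountMatrix(df.astype(np.int64), feature_kind=feature_kind)


def write_count_matrix(cm: CountMatrix, path: str | os.PathLike) -> None:
    cm.counts.to_csv(path, sep="\t", index_label="feature_id")


def _read_pwm_file(path: Path) -> PWMRecord:
    df = pd.read_csv(path, sep="\t")
    cols = [c.upper() for c in df.columns]
    # tolerate a leading position-index column
    base_cols = []
    for base in ("A", "C", "G", "U", "T"):
        if base in cols:
            base_cols.append(df.columns[cols.index(base)])
    if len(base_cols) != 4:
        raise FormatError(f"{path}: expected columns A C G U (or T), got {list(df.columns)}")
    m = df[base_cols].to_numpy(dtype=float)  # A C G U/T order -> A C G T
    if (m < 0).any():
        raise FormatError(f"{path}: negative probability")
    sums = m.sum(axis=1)
    bad = np.abs(sums - 1.0) > 1e-3
    if bad.any():
        rows = np.nonzero(bad)[0] + 1
        raise FormatError(f"{path}: rows {rows.tolist()} sum to {sums[bad].tolist()}, deviating > 1e-3 from 1")
    m = m / sums[:, None]  # renormalize within-tolerance rows
    stem = path.stem
    if "__" in stem:
        name, source = stem.split("__", 1)
    else:
        name, source = stem, "CISBP_RNA"
    if source not in ("CISBP_RNA", "RBNS"):
        raise FormatError(f"{path}: unknown PWM source tag {source!r}")
    try:
        return PWMRecord(name, m, source=source)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def read_pwm_library(path_or_dir: str | os.PathLike) -> list[PWMRecord]:
    """Read tab-delimited position probability matrices (A C G U columns).

    ``path_or_dir`` may be a single file or a directory of ``*.txt``/``*.tsv``
    files, one matrix per file, named ``<RBP>.txt`` or ``<RBP>__<SOURCE>.txt``.
    """
    p = Path(path_or_dir)
    if p.is_dir():
        files = sorted(list(p.glob("*.txt")) + list(p.glob("*.tsv")))
        if not files:
            raise FormatError(f"{p}: no PWM files (*.txt, *.tsv) found")
        return [_read_pwm_file(f) for f in files]
    return [_read_pwm_file(p)]


def write_pwm_library(pwms: Sequence[PWMRecord], outdir: str | os.PathLike) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for pwm in pwms:
        df = pd.DataFrame(pwm.matrix, columns=["A", "C", "G", "U"])
        df.insert(0, "Pos", np.arange(1, len(pwm) + 1))
        df.to_csv(outdir / f"{pwm.rbp_name}__{pwm.source}.txt", sep="\t", index=False)


def read_sample_meta(path: str | os.PathLike) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: sample metadata needs columns {sorted(required)}")
    metas = []
    for _, row in df.iterrows():
        st = row.get("survival_time")
        ev = row.get("event")
        st = None if pd.isna(st) else float(st)
        ev = None if pd.isna(ev) else int(ev)
        subtype = row.get("subtype")
        subtype = None if pd.isna(subtype) else str(subtype)
        metas.append(SampleMeta(str(row["sample_id"]), str(row["group"]), subtype, st, ev))
    return metas


def write_sample_meta(metas: Sequence[SampleMeta], path: str | os.PathLike) -> None:
    df = pd.DataFrame([dataclasses.asdict(m) for m in metas])
    df.to_csv(path, sep="\t", index=False)


def read_gene_list(path: str | os.PathLike) -> list[str]:
    """One gene symbol per line (the human RBP list format)."""
    with open(path) as fh:
        symbols = [line.strip() for line in fh if line.strip()]
    if not symbols:
        raise FormatError(f"{path}: empty gene list")
    return symbols


# ---------------------------------------------------------------------------
# generic results writer
# ---------------------------------------------------------------------------

def write_results_table(records, path: str | os.PathLike, columns: Sequence[str] | None = None) -> None:
    """Write homogeneous records (dicts / dataclasses / DataFrame) as TSV.

    Column order is deterministic (first record's order); floats rendered at
    6 significant digits so the table round-trips through ``pd.read_csv``.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        schema = None
        for rec in records:
            if dataclasses.is_dataclass(rec):
                rec = dataclasses.asdict(rec)
            if not isinstance(rec, dict):
                raise TypeError(f"unsupported record type {type(rec)}")
            if schema is None:
                schema = list(rec.keys())
            elif list(rec.keys()) != schema:
                raise ValueError(f"records with mismatched schemas: {schema} vs {list(rec.keys())}")
            rows.append(rec)
        if schema is None:
            schema = list(columns) if columns else []
        df = pd.DataFrame(rows, columns=schema)
    if columns is not None and len(df) == 0:
        df = pd.DataFrame(columns=list(columns))
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_results_table(path: str | os.PathLike) -> pd.DataFrame:
    # keep_default_na=False so a literal "null" DE status survives the round
    # trip; empty cells are still missing values
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
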