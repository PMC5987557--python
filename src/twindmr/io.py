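"""Readers and writers for the on-disk formats the pipeline consumes.

All genomic intervals are 0-based half-open internally.  Cytosine reports
(bismark CX layout) carry 1-based positions; the shift happens on read and
is undone on write, so a write→read round trip is the identity.
"""

from __future__ import annotations

import gzip
import io as _io
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

VALID_CONTEXTS = frozenset({"CG", "CHG", "CHH"})


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


class ValidationError(ValueError):
    """Raised when a parsed record violates a structural invariant."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CytosineRecord:
    """One cytosine: strand, context and methylated/unmethylated read counts.

    ``pos`` is 0-based (converted from the 1-based report coordinate).
    """

    chrom: str
    pos: int
    strand: str
    meth_count: int
    unmeth_count: int
    context: str
    tri: str | None = None

    def __post_init__(self) -> None:
        if self.meth_count < 0 or self.unmeth_count < 0:
            raise ValidationError(f"negative read count at {self.chrom}:{self.pos}")
        if self.pos < 0:
            raise ValidationError(f"negative position {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValidationError(f"bad strand {self.strand!r}")

    @property
    def depth(self) -> int:
        return self.meth_count + self.unmeth_count

    @property
    def level(self) -> float:
        """Methylation level; defined only at depth > 0."""
        if self.depth == 0:
            raise ValidationError(
                f"methylation level undefined at zero depth ({self.chrom}:{self.pos})"
            )
        return self.meth_count / self.depth


class MethylomeSample:
    """Position-indexed per-cytosine methylome for one individual.

    Backed by a DataFrame sorted by (chrom, pos, strand) with per-chromosome
    position arrays for O(log n) interval queries.
    """

    COLUMNS = ("chrom", "pos", "strand", "meth", "unmeth", "context")

    def __init__(self, sample_id: str, frame: pd.DataFrame):
        missing = set(self.COLUMNS) - set(frame.columns)
        if missing:
            raise ValidationError(f"methylome frame missing columns {sorted(missing)}")
        frame = frame.sort_values(["chrom", "pos", "strand"], kind="mergesort")
        frame = frame.reset_index(drop=True)
        dup = frame.duplicated(["chrom", "pos", "strand"])
        if dup.any():
            row = frame[dup].iloc[0]
            raise ValidationError(
                f"duplicate site {row.chrom}:{row.pos}({row.strand}) in {sample_id}"
            )
        self.sample_id = sample_id
        self.frame = frame
        self._by_chrom: dict[str, tuple[int, int, np.ndarray]] = {}
        chroms = frame["chrom"].to_numpy()
        pos = frame["pos"].to_numpy()
        if len(frame):
            bounds = np.flatnonzero(chroms[1:] != chroms[:-1]) + 1
            starts = np.concatenate([[0], bounds])
            ends = np.concatenate([bounds, [len(frame)]])
            for lo, hi in zip(starts, ends):
                self._by_chrom[chroms[lo]] = (lo, hi, pos[lo:hi])

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def chroms(self) -> list[str]:
        return list(self._by_chrom)

    def chrom_arrays(self, chrom: str) -> pd.DataFrame:
        """All records on one chromosome as a positional slice of the frame."""
        if chrom not in self._by_chrom:
            return self.frame.iloc[0:0]
        lo, hi, _ = self._by_chrom[chrom]
        return self.frame.iloc[lo:hi]

    def query(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        """Records with pos in the half-open interval [start, end)."""
        if chrom not in self._by_chrom:
            return self.frame.iloc[0:0]
        lo, hi, pos = self._by_chrom[chrom]
        i = int(np.searchsorted(pos, start, side="left"))
        j = int(np.searchsorted(pos, end, side="left"))
        return self.frame.iloc[lo + i : lo + j]

    def records(self) -> Iterator[CytosineRecord]:
        for row in self.frame.itertuples(index=False):
            raw_tri = getattr(row, "tri", None)
            tri = raw_tri if isinstance(raw_tri, str) else None
            yield CytosineRecord(
                row.chrom, int(row.pos), row.strand,
                int(row.meth), int(row.unmeth), row.context, tri,
            )

    @classmethod
    def from_records(cls, sample_id: str, records: Iterable[CytosineRecord]) -> "MethylomeSample":
        rows = [
            (r.chrom, r.pos, r.strand, r.meth_count, r.unmeth_count, r.context, r.tri)
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=list(cls.COLUMNS) + ["tri"])
        return cls(sample_id, frame)

    def collapse_strands(self) -> "MethylomeSample":
        """Sum counts of symmetric +/− CpG pairs onto the + position.

        A −-strand CG record at pos p is merged into a +-strand record at
        p−1 when one exists; unpaired − records are re-anchored at p−1 on
        the + strand.  Non-CG contexts are passed through unchanged.
        """
        f = self.frame.copy()
        cg = f["context"] == "CG"
        minus = cg & (f["strand"] == "-")
        f.loc[minus, "pos"] -= 1
        f.loc[minus, "strand"] = "+"
        grouped = (
            f.groupby(["chrom", "pos", "strand", "context"], as_index=False, sort=False)
            .agg(meth=("meth", "sum"), unmeth=("unmeth", "sum"))
        )
        return MethylomeSample(self.sample_id, grouped)


@dataclass(frozen=True)
class GeneModel:
    """A transcript: span, coding bounds and exon structure, 0-based half-open."""

    gene_name: str
    transcript_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.tx_start >= self.tx_end:
            raise ValidationError(f"{self.transcript_id}: tx_start >= tx_end")
        if self.cds_start > self.cds_end:
            raise ValidationError(f"{self.transcript_id}: cds_start > cds_end")
        if not (self.tx_start <= self.cds_start and self.cds_end <= self.tx_end):
            raise ValidationError(f"{self.transcript_id}: CDS outside transcript span")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.transcript_id}: empty exon ({s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValidationError(f"{self.transcript_id}: exon outside span")
            if prev_end is not None and s < prev_end:
                raise ValidationError(f"{self.transcript_id}: exons overlap or unsorted")
            prev_end = e

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def tss(self) -> int:
        """Transcription start site (0-based position of the first base)."""
        return self.tx_start if self.strand == "+" else self.tx_end - 1

    def introns(self) -> list[tuple[int, int]]:
        out = []
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 < s1:
                out.append((e0, s1))
        return out

    def utr5(self) -> list[tuple[int, int]]:
        """Exonic intervals 5' of the CDS on the transcript's strand."""
        if not self.is_coding:
            return []
        if self.strand == "+":
            return _clip_exons(self.exons, self.tx_start, self.cds_start)
        return _clip_exons(self.exons, self.cds_end, self.tx_end)

    def utr3(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return []
        if self.strand == "+":
            return _clip_exons(self.exons, self.cds_end, self.tx_end)
        return _clip_exons(self.exons, self.tx_start, self.cds_start)

    def coding_exons(self) -> list[tuple[int, int]]:
        if not self.is_coding:
            return list(self.exons)
        return _clip_exons(self.exons, self.cds_start, self.cds_end)


def _clip_exons(exons: Sequence[tuple[int, int]], lo: int, hi: int) -> list[tuple[int, int]]:
    out = []
    for s, e in exons:
        s2, e2 = max(s, lo), min(e, hi)
        if s2 < e2:
            out.append((s2, e2))
    return out


@dataclass(frozen=True)
class TFBSRecord:
    """A named transcription-factor binding interval (0-based half-open)."""

    chrom: str
    start: int
    end: int
    tf_name: str
    score: float | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(f"TFBS {self.tf_name}: start >= end")


@dataclass
class CloneMatrix:
    """Clones × CpG binary methylation matrix from bisulfite clone sequencing.

    Entries are 1 (methylated), 0 (unmethylated) or NaN (missing).
    """

    sample_id: str
    cpg_positions: tuple[int, ...]
    matrix: np.ndarray  # float array, shape (n_clones, n_cpgs)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValidationError("clone matrix must be 2-dimensional")
        if self.matrix.shape[0] < 1:
            raise ValidationError("clone matrix needs at least one clone")
        if self.matrix.shape[1] != len(self.cpg_positions):
            raise ValidationError("clone matrix width != number of CpG positions")
        vals = self.matrix[~np.isnan(self.matrix)]
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValidationError("clone matrix entries must be 0, 1 or missing")

    @property
    def n_clones(self) -> int:
        return self.matrix.shape[0]


# ---------------------------------------------------------------------------
# Cytosine reports
# ---------------------------------------------------------------------------

def parse_cytosine_report_line(line: str, line_no: int = 0) -> CytosineRecord:
    """Parse one bismark cytosine-report line into a record.

    Columns: chrom, 1-based position, strand, methylated count,
    unmethylated count, context[, trinucleotide].
    """
    fields = line.rstrip("\n").split("\t")
    if len(fields) < 6:
        raise ParseError(f"line {line_no}: expected >= 6 tab-separated fields, got {len(fields)}")
    chrom, pos_s, strand, meth_s, unmeth_s, context = fields[:6]
    tri = fields[6] if len(fields) > 6 else None
    try:
        pos = int(pos_s)
        meth = int(meth_s)
        unmeth = int(unmeth_s)
    except ValueError as exc:
        raise ParseError(f"line {line_no}: non-integer field ({exc})") from None
    if pos < 1:
        raise ParseError(f"line {line_no}: position must be >= 1, got {pos}")
    if meth < 0 or unmeth < 0:
        raise ParseError(f"line {line_no}: negative read count")
    if context not in VALID_CONTEXTS:
        raise ParseError(f"line {line_no}: unknown context {context!r}")
    return CytosineRecord(chrom, pos - 1, strand, meth, unmeth, context, tri)


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        if "w" in mode:
            # mtime=0 keeps rewritten files byte-identical across runs
            raw = gzip.GzipFile(path, mode="wb", mtime=0)
            return _io.TextIOWrapper(raw)
        return gzip.open(path, mode)
    return open(path, mode)


def read_cytosine_report(
    path: str | Path,
    context_filter: set[str] | frozenset[str] | None = frozenset({"CG"}),
    min_depth: int = 0,
    sample_id: str | None = None,
    normalize_chrom: bool = False,
    collapse_strands: bool = False,
) -> MethylomeSample:
    """Load a (possibly gzipped) cytosine report into a MethylomeSample.

    Keeps only records whose context is in ``context_filter`` (None keeps
    all) with depth >= ``min_depth``.  Duplicate (chrom, pos, strand) sites
    raise; unsorted input is sorted on load.
    """
    records = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            rec = parse_cytosine_report_line(line, i)
            if context_filter is not None and rec.context not in context_filter:
                continue
            if rec.depth < min_depth:
                continue
            records.append(rec)
    sid = sample_id or Path(path).name.split(".")[0]
    if normalize_chrom:
        records = [
            CytosineRecord(
                r.chrom if r.chrom.startswith("chr") else "chr" + r.chrom,
                r.pos, r.strand, r.meth_count, r.unmeth_count, r.context, r.tri,
            )
            for r in records
        ]
    sample = MethylomeSample.from_records(sid, records)
    if collapse_strands:
        sample = sample.collapse_strands()
    return sample


def write_cytosine_report(sample: MethylomeSample, path: str | Path) -> None:
    """Write a sample back to the 7-column 1-based report layout."""
    with _open_text(path, "wt") as fh:
        for row in sample.frame.itertuples(index=False):
            raw_tri = getattr(row, "tri", None)
            tri = raw_tri if isinstance(raw_tri, str) else row.context
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.strand}\t{row.meth}\t"
                f"{row.unmeth}\t{row.context}\t{tri}\n"
            )


# ---------------------------------------------------------------------------
# Gene models
# ---------------------------------------------------------------------------

def read_gene_models(path: str | Path, dialect: str = "refflat") -> list[GeneModel]:
    """Read transcript models from refFlat or BED12 (both 0-based starts)."""
    if dialect not in ("refflat", "bed12"):
        raise ValueError(f"unknown gene-model dialect {dialect!r}")
    models = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.rstrip("\n").split("\t")
            try:
                if dialect == "refflat":
                    models.append(_parse_refflat(fields))
                else:
                    models.append(_parse_bed12(fields))
            except (ValidationError, ValueError, IndexError) as exc:
                raise ParseError(f"{path} line {i}: {exc}") from None
    return models


def _parse_refflat(f: Sequence[str]) -> GeneModel:
    if len(f) < 11:
        raise ValueError(f"refFlat needs 11 fields, got {len(f)}")
    exon_starts = [int(x) for x in f[9].rstrip(",").split(",")]
    exon_ends = [int(x) for x in f[10].rstrip(",").split(",")]
    n = int(f[8])
    if len(exon_starts) != n or len(exon_ends) != n:
        raise ValueError("exonCount does not match exon lists")
    return GeneModel(
        gene_name=f[0], transcript_id=f[1], chrom=f[2], strand=f[3],
        tx_start=int(f[4]), tx_end=int(f[5]),
        cds_start=int(f[6]), cds_end=int(f[7]),
        exons=tuple(zip(exon_starts, exon_ends)),
    )


def _parse_bed12(f: Sequence[str]) -> GeneModel:
    if len(f) < 12:
        raise ValueError(f"BED12 needs 12 fields, got {len(f)}")
    start = int(f[1])
    n = int(f[9])
    sizes = [int(x) for x in f[10].rstrip(",").split(",")]
    offsets = [int(x) for x in f[11].rstrip(",").split(",")]
    if len(sizes) != n or len(offsets) != n:
        raise ValueError("blockCount does not match block lists")
    exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
    return GeneModel(
        gene_name=f[3], transcript_id=f[3], chrom=f[0], strand=f[5],
        tx_start=start, tx_end=int(f[2]),
        cds_start=int(f[6]), cds_end=int(f[7]),
        exons=exons,
    )


def write_gene_models_refflat(models: Iterable[GeneModel], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for m in models:
            starts = ",".join(str(s) for s, _ in m.exons) + ","
            ends = ",".join(str(e) for _, e in m.exons) + ","
            fh.write(
                f"{m.gene_name}\t{m.transcript_id}\t{m.chrom}\t{m.strand}\t"
                f"{m.tx_start}\t{m.tx_end}\t{m.cds_start}\t{m.cds_end}\t"
                f"{len(m.exons)}\t{starts}\t{ends}\n"
            )


# ---------------------------------------------------------------------------
# TFBS, chrom sizes
# ---------------------------------------------------------------------------

def read_tfbs_bed(path: str | Path) -> list[TFBSRecord]:
    """BED with a name column: chrom, start, end, tf_name[, score]."""
    out = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 4:
                raise ParseError(f"{path} line {i}: TFBS BED needs >= 4 fields")
            score = float(f[4]) if len(f) > 4 and f[4] not in (".", "") else None
            try:
                out.append(TFBSRecord(f[0], int(f[1]), int(f[2]), f[3], score))
            except (ValueError, ValidationError) as exc:
                raise ParseError(f"{path} line {i}: {exc}") from None
    return out


def write_tfbs_bed(records: Iterable[TFBSRecord], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for r in records:
            score = "." if r.score is None else f"{r.score:g}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.tf_name}\t{score}\n")


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    sizes: dict[str, int] = {}
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            f = line.split()
            if len(f) < 2:
                raise ParseError(f"{path} line {i}: chrom.sizes needs 2 columns")
            sizes[f[0]] = int(f[1])
    return sizes


def write_chrom_sizes(sizes: dict[str, int], path: str | Path) -> None:
    with _open_text(path, "wt") as fh:
        for name, length in sizes.items():
            fh.write(f"{name}\t{length}\n")


# ---------------------------------------------------------------------------
# DMR BED output
# ---------------------------------------------------------------------------

def bed_score_from_p(p: float) -> int:
    """Phred-like BED score: min(1000, round(−10·log10 p)); p=0 caps at 1000."""
    if p <= 0:
        return 1000
    return min(1000, int(round(-10.0 * math.log10(p))))


def write_dmrs_bed(dmrs: Sequence, path: str | Path) -> None:
    """BED6+3: chrom, start, end, direction, score, '.', n_cpgs, mean_s1, mean_s2."""
    with _open_text(path, "wt") as fh:
        fh.write("# chrom\tstart\tend\tdirection\tscore\tstrand\tn_cpgs\tmean_s1\tmean_s2\n")
        for d in dmrs:
            fh.write(
                f"{d.chrom}\t{d.start}\t{d.end}\t{d.direction}\t"
                f"{bed_score_from_p(d.p_value)}\t.\t{d.n_cpgs}\t"
                f"{d.mean_s1:.6g}\t{d.mean_s2:.6g}\n"
            )


def read_dmrs_bed(path: str | Path):
    """Read DMRs back from the BED6+3 layout written by write_dmrs_bed.

    The p-value is reconstructed from the score, so it is accurate only to
    the score's integer precision.
    """
    from .dmr import DMR  # local import to avoid a cycle

    out = []
    with _open_text(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9:
                raise ParseError(f"{path} line {i}: DMR BED needs 9 fields")
            out.append(
                DMR(
                    chrom=f[0], start=int(f[1]), end=int(f[2]), direction=f[3],
                    n_windows=1, n_cpgs=int(f[6]),
                    p_value=10 ** (-int(f[4]) / 10.0),
                    mean_s1=float(f[7]), mean_s2=float(f[8]),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Clone matrices and cohort tables
# ---------------------------------------------------------------------------

def read_clone_matrix(path: str | Path, sample_id: str | None = None) -> CloneMatrix:
    """Clone matrix TSV: header 'clone' + CpG positions; one row per clone.

    Entries are 0/1 with 'NA' (or empty) for missing.
    """
    frame = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", ""])
    positions = tuple(int(c) for c in frame.columns)
    sid = sample_id or Path(path).name.split(".")[0]
    return CloneMatrix(sid, positions, frame.to_numpy(dtype=float))


def write_clone_matrix(cm: CloneMatrix, path: str | Path) -> None:
    frame = pd.DataFrame(
        cm.matrix,
        index=[f"clone{i + 1}" for i in range(cm.n_clones)],
        columns=[str(p) for p in cm.cpg_positions],
    )
    with _open_text(path, "wt") as fh:
        frame.to_csv(fh, sep="\t", index_label="clone", na_rep="NA",
                     float_format="%g")


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    """Cohort TSV: sample_id, group in {case, control}, expression."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "group", "expression"}
    missing = required - set(frame.columns)
    if missing:
        raise ParseError(f"{path}: cohort table missing columns {sorted(missing)}")
    bad = ~frame["group"].isin(["case", "control"])
    if bad.any():
        raise ParseError(f"{path}: group must be 'case' or 'control'")
    return frame


def write_cohort_table(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
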