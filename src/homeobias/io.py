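"""Shared domain types and readers/writers for the formats the pipeline touches.

Coordinate convention: everything in memory is 0-based half-open, the
convention of BED and bedGraph.  GFF3's 1-based closed coordinates are
converted at the boundary, in both directions.  All readers and writers are
gzip-transparent (a ``.gz`` suffix switches compression on).
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
import numpy as np
import pandas as pd

logger = logging.getLogger("homeobias")

#: column layout of a BLAST-style tabular hits file:
#: the 12 standard columns plus query_length and subject_length
HITS_COLUMNS = [
    "query_id",
    "subject_id",
    "pct_identity",
    "aln_length",
    "mismatches",
    "gap_opens",
    "q_start",
    "q_end",
    "s_start",
    "s_end",
    "e_value",
    "bit_score",
    "query_length",
    "subject_length",
]

_CHROM_SUBGENOME_RE = re.compile(r"^\d+([MU])$")


class FormatError(ValueError):
    """A file did not conform to its declared format."""


def _open_text(path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def subgenome_of(chrom: str, chrom_map: dict[str, str] | None = None) -> str:
    """Subgenome ('M' or 'U') of a chromosome.

    By default the subgenome is read from the chromosome-name suffix
    (``1M`` ... ``7U``); ``chrom_map`` overrides this for non-standard names.
    """
    if chrom_map is not None and chrom in chrom_map:
        return chrom_map[chrom]
    m = _CHROM_SUBGENOME_RE.match(chrom)
    if m is None:
        raise FormatError(
            f"cannot derive subgenome from chromosome name {chrom!r}; "
            "provide a chromosome->subgenome map"
        )
    return m.group(1)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneModel:
    """A gene with subgenome, coordinates and strand-aware coding start.

    ``start``/``end`` are 0-based half-open; ``cds_start`` is the first coding
    base in transcription order (the leftmost CDS base on '+', the rightmost
    on '-'), also 0-based.
    """

    gene_id: str
    subgenome: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_start: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"{self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if not (self.start <= self.cds_start < self.end):
            raise ValueError(
                f"{self.gene_id}: cds_start {self.cds_start} outside "
                f"[{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: bad strand {self.strand!r}")
        if self.subgenome not in ("M", "U"):
            raise ValueError(f"{self.gene_id}: bad subgenome {self.subgenome!r}")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, pos: float) -> bool:
        return self.start <= pos < self.end


@dataclass
class SRARegionSet:
    """Structural-rearrangement blocks; non-overlapping per chromosome."""

    regions: list = field(default_factory=list)  # (GenomicInterval, region_id)

    def add(self, interval: GenomicInterval, region_id: str):
        self.regions.append((interval, region_id))

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)

    def region_of(self, chrom: str, pos: float) -> str | None:
        """Id of the region containing position ``pos``, or None."""
        for iv, rid in self.regions:
            if iv.chrom == chrom and iv.contains(pos):
                return rid
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(iv.chrom, iv.start, iv.end, rid) for iv, rid in self.regions],
            columns=["chrom", "start", "end", "region_id"],
        )


class SignalTrack:
    """A per-chromosome step function of fold enrichment.

    Stores sorted, non-overlapping intervals per chromosome; positions not
    covered by any interval have signal 0.
    """

    def __init__(self, frame: pd.DataFrame):
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in frame.groupby("chrom", sort=True):
            sub = sub.sort_values("start")
            starts = sub["start"].to_numpy(dtype=np.int64)
            ends = sub["end"].to_numpy(dtype=np.int64)
            if np.any(ends[:-1] > starts[1:]):
                raise FormatError(
                    f"overlapping bedGraph intervals on {chrom}: "
                    "signal must be a step function"
                )
            values = sub["value"].to_numpy(dtype=float)
            # cumulative area up to the start of each interval
            cum = np.concatenate([[0.0], np.cumsum((ends - starts) * values)])
            self._chroms[chrom] = (starts, ends, values, cum)

    @property
    def chroms(self) -> list[str]:
        return list(self._chroms)

    def _cum_at(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Area under the step function over (-inf, pos)."""
        starts, ends, values, cum = self._chroms[chrom]
        idx = np.searchsorted(starts, pos, side="right") - 1
        i = np.clip(idx, 0, None)
        inside = np.clip(pos - starts[i], 0, ends[i] - starts[i])
        out = cum[i] + values[i] * inside
        return np.where(idx < 0, 0.0, out)

    def integrate(self, chrom: str, start, end) -> float:
        """Area under the step function over [start, end), in signal*bp."""
        return float(self.integrate_many(chrom, np.asarray([start]), np.asarray([end]))[0])

    def integrate_many(self, chrom: str, starts, ends) -> np.ndarray:
        """Vectorised `integrate` over parallel start/end arrays."""
        starts = np.asarray(starts, dtype=float)
        ends = np.asarray(ends, dtype=float)
        if chrom not in self._chroms:
            return np.zeros(len(starts))
        return self._cum_at(chrom, ends) - self._cum_at(chrom, starts)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Signal value at each (0-based) position; 0 outside covered spans."""
        if chrom not in self._chroms:
            return np.zeros(len(positions))
        starts, ends, values, _ = self._chroms[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        out = np.zeros(len(positions))
        ok = idx >= 0
        inside = ok & (positions < ends[np.clip(idx, 0, None)])
        out[inside] = values[idx[inside]]
        return out

    def max_over(self, chrom: str, start, end) -> float:
        """Maximum signal value over [start, end) (0 if uncovered)."""
        return float(self.max_over_many(chrom, [start], [end])[0])

    def max_over_many(self, chrom: str, starts_q, ends_q) -> np.ndarray:
        """Vectorised `max_over` over parallel start/end arrays."""
        starts_q = np.asarray(starts_q)
        ends_q = np.asarray(ends_q)
        if chrom not in self._chroms:
            return np.zeros(len(starts_q))
        starts, ends, values, _ = self._chroms[chrom]
        i0 = np.searchsorted(ends, starts_q, side="right")
        i1 = np.searchsorted(starts, ends_q, side="left")
        out = np.zeros(len(starts_q))
        for k in range(len(starts_q)):
            if i0[k] < i1[k]:
                out[k] = values[i0[k] : i1[k]].max()
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for chrom, (starts, ends, values, _) in self._chroms.items():
            rows.append(
                pd.DataFrame(
                    {"chrom": chrom, "start": starts, "end": ends, "value": values}
                )
            )
        return pd.concat(rows, ignore_index=True)


class PeakSet:
    """Reproducible peak intervals, queryable by overlap."""

    def __init__(self, frame: pd.DataFrame):
        self._frame = frame.sort_values(["chrom", "start"]).reset_index(drop=True)
        self._chroms: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, sub in self._frame.groupby("chrom"):
            self._chroms[chrom] = (
                sub["start"].to_numpy(dtype=np.int64),
                sub["end"].to_numpy(dtype=np.int64),
            )

    def __len__(self) -> int:
        return len(self._frame)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        """True iff any peak overlaps [start, end)."""
        if chrom not in self._chroms:
            return False
        starts, ends = self._chroms[chrom]
        return bool(np.any((starts < end) & (ends > start)))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


class ExpressionMatrix:
    """Gene x tissue TPM matrix with expression and retention flags.

    A gene/tissue cell is *expressed* when TPM >= 1; a gene is *retained*
    for analysis when its cumulative TPM across tissues is >= 10.
    """

    EXPRESSED_TPM = 1.0
    MIN_CUMULATIVE = 10.0

    def __init__(self, tpm: pd.DataFrame):
        if tpm.shape[1] == 0:
            raise FormatError("expression matrix has no tissue columns")
        if tpm.isna().any().any():
            raise FormatError("expression matrix contains missing TPM values")
        if (tpm < 0).any().any():
            raise FormatError("negative TPM values")
        self.tpm = tpm.astype(float)

    @property
    def tissues(self) -> list[str]:
        return list(self.tpm.columns)

    @property
    def genes(self) -> pd.Index:
        return self.tpm.index

    @property
    def expressed(self) -> pd.DataFrame:
        return self.tpm >= self.EXPRESSED_TPM

    def retained(self, min_cumulative: float | None = None) -> pd.Series:
        if min_cumulative is None:
            min_cumulative = self.MIN_CUMULATIVE
        return self.tpm.sum(axis=1) >= min_cumulative


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_gff3(
    path, chrom_map: dict[str, str] | None = None
) -> dict[str, GeneModel]:
    """Read gene models from a GFF3 file.

    Returns a mapping gene_id -> GeneModel.  GFF3 1-based closed coordinates
    are converted to 0-based half-open.  ``cds_start`` is the leftmost CDS
    base for '+' genes and the rightmost for '-' genes; genes without CDS
    children fall back to the gene span.
    """
    path = Path(path)
    text = _open_text(path).read()
    if not text.strip():
        logger.warning("GFF3 file %s is empty", path)
        return {}
    _validate_gff3_lines(text, path)
    try:
        db = gffutils.create_db(
            text,
            dbfn=":memory:",
            from_string=True,
            merge_strategy="error",
            keep_order=True,
        )
    except Exception as exc:  # gffutils raises several types
        raise FormatError(f"failed to parse GFF3 {path}: {exc}") from exc

    genes: dict[str, GeneModel] = {}
    for g in db.features_of_type("gene"):
        if g.id in genes:
            raise FormatError(f"duplicate gene_id {g.id!r} in {path}")
        cds = list(db.children(g, featuretype="CDS"))
        start0, end0 = g.start - 1, g.end
        if cds:
            left = min(c.start for c in cds) - 1
            right = max(c.end for c in cds)
        else:
            left, right = start0, end0
        cds_start = left if g.strand == "+" else right - 1
        genes[g.id] = GeneModel(
            gene_id=g.id,
            subgenome=subgenome_of(g.seqid, chrom_map),
            chrom=g.seqid,
            start=start0,
            end=end0,
            strand=g.strand,
            cds_start=cds_start,
        )
    return genes


def _validate_gff3_lines(text: str, path):
    for i, line in enumerate(text.splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        if len(line.split("\t")) != 9:
            raise FormatError(f"{path}:{i}: malformed GFF3 line (expected 9 columns)")


def read_hits_table(path) -> pd.DataFrame:
    """Read a 14-column BLAST-style tabular hits file.

    Columns are the 12 standard tabular alignment fields plus query_length
    and subject_length.  Lines starting with '#' are skipped; row order is
    preserved.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] != len(HITS_COLUMNS):
        raise FormatError(
            f"{path}: expected {len(HITS_COLUMNS)} tab-separated columns "
            "(12 standard BLAST tabular fields plus query_length and "
            f"subject_length), got {df.shape[1]}; regenerate the hits table "
            "with '-outfmt \"6 std qlen slen\"'"
        )
    df.columns = HITS_COLUMNS
    numeric = HITS_COLUMNS[2:]
    try:
        df[numeric] = df[numeric].apply(pd.to_numeric)
    except (ValueError, TypeError) as exc:
        raise FormatError(f"{path}: non-numeric value in hits table: {exc}") from exc
    return df


def read_bedgraph(path) -> SignalTrack:
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str},
    )
    return SignalTrack(df)


def read_bed(path) -> PeakSet:
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(f"{path}: BED needs at least 3 columns")
    out = df.iloc[:, :3].copy()
    out.columns = ["chrom", "start", "end"]
    out["start"] = out["start"].astype(np.int64)
    out["end"] = out["end"].astype(np.int64)
    if df.shape[1] >= 4:
        out["name"] = df.iloc[:, 3]
    return PeakSet(out)


def read_sra_regions(path) -> SRARegionSet:
    """Read SRA blocks from a BED-like TSV (chrom, start, end[, region_id])."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    regions = SRARegionSet()
    for i, row in df.iterrows():
        rid = row[3] if df.shape[1] >= 4 else f"SRA{i + 1}"
        regions.add(GenomicInterval(row[0], int(row[1]), int(row[2])), rid)
    return regions


def read_tpm_matrix(path, allow_missing: bool = False) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    if df.isna().any().any():
        if not allow_missing:
            n = int(df.isna().sum().sum())
            raise FormatError(
                f"{path}: {n} missing TPM values (pass allow_missing to drop "
                "genes with missing values)"
            )
        df = df.dropna()
    return ExpressionMatrix(df)


def read_depth_table(path) -> pd.DataFrame:
    """Read a per-bin depth table: chrom, pos_bin (0-based start), depth."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "pos_bin", "depth"],
        dtype={"chrom": str},
    )
    return df


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_gff3(path, genes: Iterable[GeneModel]):
    """Write gene/mRNA/CDS features to GFF3.

    The single CDS runs from the coding start to the gene's 3' end, so the
    strand-aware ``cds_start`` survives a write/read round trip.
    """
    with _open_text(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id)):
            s1, e1 = g.start + 1, g.end  # back to 1-based closed
            if g.strand == "+":
                cs1, ce1 = g.cds_start + 1, g.end
            else:
                cs1, ce1 = g.start + 1, g.cds_start + 1
            fh.write(
                f"{g.chrom}\thomeobias\tgene\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\thomeobias\tmRNA\t{s1}\t{e1}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.1;Parent={g.gene_id}\n"
            )
            fh.write(
                f"{g.chrom}\thomeobias\tCDS\t{cs1}\t{ce1}\t.\t{g.strand}\t0\t"
                f"ID={g.gene_id}.cds;Parent={g.gene_id}.1\n"
            )


def write_hits_table(path, hits: pd.DataFrame):
    hits.to_csv(path, sep="\t", header=False, index=False)


def write_bedgraph(path, track: SignalTrack):
    frame = track.to_frame().sort_values(["chrom", "start"])
    frame.to_csv(path, sep="\t", header=False, index=False, float_format="%.6f")


def write_bed(path, peaks: PeakSet):
    peaks.to_frame().to_csv(path, sep="\t", header=False, index=False)


def write_sra_regions(path, regions: SRARegionSet):
    regions.to_frame().to_csv(path, sep="\t", header=False, index=False)


def write_tpm_matrix(path, matrix: ExpressionMatrix):
    matrix.tpm.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6f")


def write_results(path, table: pd.DataFrame):
    """Write a results table as TSV with header, 6-decimal floats."""
    table.to_csv(path, sep="\t", index=False, float_format="%.6f")
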