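"""Genomic interval containers, file I/O, and interval arithmetic.

All coordinates are 0-based half-open (BED convention). The containers here
are the atoms consumed by every downstream stage: chromosome size tables,
in-memory genome sequences, peak intervals, and a flat TSS-anchored gene
annotation.

Interval arithmetic (replicate merging, intersection, nearest-gene
assignment) is implemented directly on sorted coordinate arrays so that the
support-counting and tie-breaking rules are explicit and testable against
brute-force oracles.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("comotif")

VALID_STRANDS = {"+", "-", "."}


class ValidationError(ValueError):
    """Raised when an input violates a documented precondition."""


class BedParseError(ValueError):
    """Raised on a malformed BED line; message names the line number."""


# ---------------------------------------------------------------------------
# containers


class ChromTable:
    """Ordered chromosome-name -> length (bp) table.

    Names must be unique and lengths strictly positive.
    """

    def __init__(self, entries: Iterable[tuple[str, int]]):
        self._names: list[str] = []
        self._lengths: dict[str, int] = {}
        for name, length in entries:
            if name in self._lengths:
                raise ValidationError(f"duplicate chromosome name {name!r}")
            length = int(length)
            if length <= 0:
                raise ValidationError(f"chromosome {name!r} has non-positive length {length}")
            self._names.append(name)
            self._lengths[name] = length

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def __contains__(self, name: str) -> bool:
        return name in self._lengths

    def __len__(self) -> int:
        return len(self._names)

    def __getitem__(self, name: str) -> int:
        return self._lengths[name]

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for name in self._names:
            yield name, self._lengths[name]

    def __eq__(self, other) -> bool:
        return isinstance(other, ChromTable) and list(self) == list(other)

    @classmethod
    def read(cls, path) -> "ChromTable":
        """Read a two-column (name, length) TSV, e.g. a ``.chrom.sizes`` file."""
        entries = []
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) < 2:
                    raise BedParseError(f"{path}:{i}: expected 2 tab-separated columns")
                entries.append((parts[0], int(parts[1])))
        return cls(entries)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for name, length in self:
                fh.write(f"{name}\t{length}\n")


class SequenceStore:
    """In-memory genome: chromosome name -> uppercase DNA over {A,C,G,T,N}."""

    def __init__(self, sequences: dict[str, str], chroms: Optional[ChromTable] = None):
        self._seqs = {name: seq.upper() for name, seq in sequences.items()}
        if chroms is not None:
            for name, seq in self._seqs.items():
                if name in chroms and len(seq) != chroms[name]:
                    raise ValidationError(
                        f"sequence length {len(seq)} for {name!r} does not match "
                        f"chromosome table length {chroms[name]}"
                    )

    def __contains__(self, name: str) -> bool:
        return name in self._seqs

    def __getitem__(self, name: str) -> str:
        return self._seqs[name]

    def names(self) -> list[str]:
        return list(self._seqs)

    def copy(self) -> "SequenceStore":
        return SequenceStore(dict(self._seqs))

    def set_slice(self, chrom: str, start: int, seq: str) -> None:
        """Overwrite ``chrom[start:start+len(seq)]`` with ``seq`` (in place)."""
        old = self._seqs[chrom]
        if start < 0 or start + len(seq) > len(old):
            raise ValidationError(f"slice [{start}, {start + len(seq)}) outside {chrom}")
        self._seqs[chrom] = old[:start] + seq.upper() + old[start + len(seq):]

    def chrom_table(self) -> ChromTable:
        return ChromTable((name, len(seq)) for name, seq in self._seqs.items())

    @classmethod
    def read_fasta(cls, path, chroms: Optional[ChromTable] = None) -> "SequenceStore":
        seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(seqs, chroms)

    def write_fasta(self, path, width: int = 70) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self._seqs.items()
        ]
        with open(path, "w") as fh:
            writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
            writer.write_file(records)


@dataclass(frozen=True)
class Interval:
    """A genomic span with 0-based half-open coordinates."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    strand: str = "."

    def __post_init__(self):
        if self.start < 0 or self.start >= self.end:
            raise ValidationError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} (need 0 <= start < end)"
            )
        if self.strand not in VALID_STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def key(self) -> str:
        return self.name if self.name else f"{self.chrom}:{self.start}-{self.end}"

    def overlaps(self, other: "Interval", min_bp: int = 1) -> bool:
        if self.chrom != other.chrom:
            return False
        return min(self.end, other.end) - max(self.start, other.start) >= min_bp


class PeakSet:
    """A labelled, sorted collection of intervals (e.g. one factor's peaks)."""

    def __init__(self, label: str, intervals: Iterable[Interval],
                 chroms: Optional[ChromTable] = None):
        ivs = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        if chroms is not None:
            for iv in ivs:
                if iv.chrom not in chroms:
                    raise ValidationError(f"interval on unknown chromosome {iv.chrom!r}")
                if iv.end > chroms[iv.chrom]:
                    raise ValidationError(
                        f"interval {iv.chrom}:{iv.start}-{iv.end} exceeds chromosome "
                        f"length {chroms[iv.chrom]}"
                    )
        self.label = label
        self.intervals: list[Interval] = ivs

    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[Interval]:
        return iter(self.intervals)

    def __getitem__(self, i: int) -> Interval:
        return self.intervals[i]

    def by_chrom(self) -> dict[str, list[Interval]]:
        out: dict[str, list[Interval]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append(iv)
        return out

    def coord_arrays(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """Per-chromosome (starts, ends) arrays, sorted by start."""
        out = {}
        for chrom, ivs in self.by_chrom().items():
            out[chrom] = (
                np.array([iv.start for iv in ivs], dtype=np.int64),
                np.array([iv.end for iv in ivs], dtype=np.int64),
            )
        return out


@dataclass(frozen=True)
class GeneRecord:
    gene_id: str
    chrom: str
    strand: str
    tss: int
    body: Interval

    def __post_init__(self):
        if not (self.body.start <= self.tss <= self.body.end):
            raise ValidationError(
                f"gene {self.gene_id}: TSS {self.tss} outside body "
                f"[{self.body.start}, {self.body.end}]"
            )


class GeneAnnot:
    """Flat gene annotation: unique gene ids with TSS and body interval."""

    def __init__(self, records: Iterable[GeneRecord]):
        self.records = list(records)
        ids = [r.gene_id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValidationError("gene_id values must be unique")
        self._by_id = {r.gene_id: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.records)

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self._by_id[gene_id]

    def gene_ids(self) -> list[str]:
        return [r.gene_id for r in self.records]

    @classmethod
    def read_tsv(cls, path) -> "GeneAnnot":
        """Read a TSV with header gene_id, chrom, strand, tss, start, end."""
        df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
        required = {"gene_id", "chrom", "strand", "tss", "start", "end"}
        missing = required - set(df.columns)
        if missing:
            raise ValidationError(f"gene annotation missing columns: {sorted(missing)}")
        records = [
            GeneRecord(
                gene_id=row.gene_id,
                chrom=row.chrom,
                strand=row.strand,
                tss=int(row.tss),
                body=Interval(row.chrom, int(row.start), int(row.end)),
            )
            for row in df.itertuples(index=False)
        ]
        return cls(records)

    def write_tsv(self, path) -> None:
        df = pd.DataFrame(
            {
                "gene_id": [r.gene_id for r in self.records],
                "chrom": [r.chrom for r in self.records],
                "strand": [r.strand for r in self.records],
                "tss": [r.tss for r in self.records],
                "start": [r.body.start for r in self.records],
                "end": [r.body.end for r in self.records],
            }
        )
        df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# BED I/O


def read_bed(path, chroms: Optional[ChromTable] = None, strict: bool = True,
             label: Optional[str] = None) -> PeakSet:
    """Parse a BED3+ file into a sorted :class:`PeakSet`.

    Lines on chromosomes absent from ``chroms`` raise (strict) or are
    skipped with a warning (lenient). Malformed lines always raise a
    :class:`BedParseError` naming the offending line number.
    """
    intervals = []
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise BedParseError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            if start < 0 or start >= end:
                raise ValidationError(
                    f"{path}:{lineno}: invalid coordinates start={start} end={end}"
                )
            if chroms is not None and chrom not in chroms:
                if strict:
                    raise ValidationError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
                logger.warning("%s:%d: skipping unknown chromosome %r", path, lineno, chrom)
                continue
            name = parts[3] if len(parts) > 3 and parts[3] != "." else None
            strand = parts[5] if len(parts) > 5 and parts[5] in VALID_STRANDS else "."
            intervals.append(Interval(chrom, start, end, name=name, strand=strand))
    return PeakSet(label or path.stem, intervals, chroms)


def write_bed(peaks: PeakSet, path) -> None:
    """Write BED6 when names/strands are present, else BED3; round-trip exact."""
    with open(path, "w") as fh:
        for iv in peaks:
            if iv.name is not None or iv.strand != ".":
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}\t0\t{iv.strand}\n")
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


# ---------------------------------------------------------------------------
# interval arithmetic


def merge_replicates(replicates: list[PeakSet], min_support: int = 2,
                     label: Optional[str] = None) -> PeakSet:
    """Merge replicate peak sets into maximal overlapping runs.

    Intervals from the union of all replicates are merged wherever they
    share at least one base. A merged run is retained iff intervals from at
    least ``min_support`` distinct replicates contributed to it. With
    ``min_support=1`` this is a plain union-merge.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    if not replicates:
        raise ValidationError("need at least one replicate")
    if min_support > len(replicates):
        raise ValidationError(
            f"min_support={min_support} exceeds number of replicates {len(replicates)}"
        )
    tagged: dict[str, list[tuple[int, int, int]]] = {}
    for rep_idx, ps in enumerate(replicates):
        for iv in ps:
            tagged.setdefault(iv.chrom, []).append((iv.start, iv.end, rep_idx))
    merged: list[Interval] = []
    for chrom in sorted(tagged):
        runs = sorted(tagged[chrom])
        cur_start, cur_end, support = runs[0][0], runs[0][1], {runs[0][2]}
        for start, end, rep in runs[1:]:
            if start < cur_end:  # >=1 bp shared; book-ended intervals not merged
                cur_end = max(cur_end, end)
                support.add(rep)
            else:
                if len(support) >= min_support:
                    merged.append(Interval(chrom, cur_start, cur_end))
                cur_start, cur_end, support = start, end, {rep}
        if len(support) >= min_support:
            merged.append(Interval(chrom, cur_start, cur_end))
    return PeakSet(label or replicates[0].label, merged)


def merge_spans(peaks: PeakSet) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Union-merge a peak set into disjoint sorted spans per chromosome."""
    out = {}
    for chrom, ivs in peaks.by_chrom().items():
        spans = []
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start < cur_end:
                cur_end = max(cur_end, iv.end)
            else:
                spans.append((cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        spans.append((cur_start, cur_end))
        starts, ends = zip(*spans)
        out[chrom] = (np.array(starts, dtype=np.int64), np.array(ends, dtype=np.int64))
    return out


def intersect(a: PeakSet, b: PeakSet, min_bp: int = 1) -> tuple[PeakSet, float]:
    """Intervals of ``a`` sharing >= ``min_bp`` with any single interval of ``b``.

    Returns the overlapping subset of ``a`` (each a-interval counted once
    however many b-intervals it touches) and the fraction of ``a`` overlapping.
    """
    if min_bp < 1:
        raise ValidationError("min_bp must be >= 1")
    b_by_chrom = b.coord_arrays()
    hits = []
    for iv in a:
        if iv.chrom not in b_by_chrom:
            continue
        b_starts, b_ends = b_by_chrom[iv.chrom]
        # candidates: b.start < iv.end - min_bp + 1 is necessary; scan the
        # window of b intervals that could reach iv
        hi = int(np.searchsorted(b_starts, iv.end - min_bp, side="right"))
        ov = np.minimum(b_ends[:hi], iv.end) - np.maximum(b_starts[:hi], iv.start)
        if hi > 0 and ov.max(initial=0) >= min_bp:
            hits.append(iv)
    frac = len(hits) / len(a) if len(a) else 0.0
    return PeakSet(f"{a.label}&{b.label}", hits), frac


@dataclass(frozen=True)
class NearestGenes:
    upstream: Optional[str]
    downstream: Optional[str]
    upstream_dist: Optional[int]
    downstream_dist: Optional[int]


def assign_nearest_genes(peaks: PeakSet, genes: GeneAnnot) -> dict[str, NearestGenes]:
    """Nearest upstream/downstream gene (by TSS) for each peak.

    Upstream means the gene with the largest TSS <= peak start; downstream
    the smallest TSS >= peak end; distances are edge-to-TSS, non-negative.
    A gene whose TSS lies inside the peak fills both slots at distance 0.
    Ties are broken by lexicographically smaller gene_id.
    """
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for rec in genes:
        by_chrom.setdefault(rec.chrom, []).append((rec.tss, rec.gene_id))
    for chrom in by_chrom:
        by_chrom[chrom].sort()  # (tss, gene_id): gene_id ascending breaks TSS ties

    out: dict[str, NearestGenes] = {}
    for iv in peaks:
        if iv.chrom not in by_chrom:
            logger.warning("peak %s: no gene on chromosome %s", iv.key, iv.chrom)
            out[iv.key] = NearestGenes(None, None, None, None)
            continue
        entries = by_chrom[iv.chrom]
        tss_arr = [t for t, _ in entries]
        # genes with TSS inside [start, end) fill both slots at distance 0
        import bisect
        lo = bisect.bisect_left(tss_arr, iv.start)
        hi = bisect.bisect_left(tss_arr, iv.end)
        if hi > lo:
            inside = min(g for _, g in entries[lo:hi])
            out[iv.key] = NearestGenes(inside, inside, 0, 0)
            continue
        # upstream: largest tss <= start (lo here is first tss >= start; since
        # no TSS in [start,end), tss_arr[lo-1] <= start unless lo==0 or equal)
        up_idx = bisect.bisect_right(tss_arr, iv.start) - 1
        if up_idx >= 0:
            up_tss = tss_arr[up_idx]
            cands = [g for t, g in entries if t == up_tss]
            upstream, up_d = min(cands), iv.start - up_tss
        else:
            upstream, up_d = None, None
        down_idx = bisect.bisect_left(tss_arr, iv.end)
        if down_idx < len(entries):
            down_tss = tss_arr[down_idx]
            cands = [g for t, g in entries if t == down_tss]
            downstream, down_d = min(cands), down_tss - iv.end
        else:
            downstream, down_d = None, None
        out[iv.key] = NearestGenes(upstream, downstream, up_d, down_d)
    return out


def extract_sequences(peaks: PeakSet, store: SequenceStore) -> dict[str, str]:
    """Forward-strand genomic substring (uppercased) for every peak."""
    out: dict[str, str] = {}
    for iv in peaks:
        if iv.chrom not in store:
            raise ValidationError(f"chromosome {iv.chrom!r} absent from sequence store")
        seq = store[iv.chrom]
        if iv.end > len(seq):
            raise ValidationError(
                f"peak {iv.key} extends beyond {iv.chrom} length {len(seq)}"
            )
        out[iv.key] = seq[iv.start:iv.end]
    return out


def configure_logging(level: str = "WARNING") -> None:
    """Route package logs to standard error at the requested level."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(level.upper())
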