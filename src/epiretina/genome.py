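"""Genome model: intervals, gene annotation, aligned reads and interval primitives.

Coordinate convention: every in-memory coordinate is 0-based half-open
(`[start, end)`), like BED.  GTF is converted from its native 1-based
inclusive convention on read and back on write.  TSS and TTS are
strand-aware: the TSS is the 5' end of the gene span (the `end`
coordinate for a minus-strand gene), the TTS its 3' end.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from gffutils.feature import feature_from_line


@dataclass(frozen=True, slots=True)
class Interval:
    """A genomic window, 0-based half-open, strand in {'+', '-', '.'}."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


@dataclass(frozen=True, slots=True)
class ReadAlignment:
    """One aligned sequencing read (the atomic evidence unit)."""

    chrom: str
    start: int
    end: int
    strand: str
    split_mapped: bool = False

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError("read start must precede end")
        if self.strand not in ("+", "-"):
            raise ValueError("read strand must be '+' or '-'")


@dataclass(slots=True)
class GeneModel:
    """A gene span with strand-aware TSS/TTS and per-transcript lengths.

    ``transcript_lengths`` are exon-sum lengths in bp; the gene length used
    for RPK is their median.  ``exons``/``utr5``/``utr3`` are merged
    sub-feature intervals when the annotation provides them.
    """

    gene_id: str
    chrom: str
    strand: str
    start: int
    end: int
    transcript_lengths: list[int] = field(default_factory=list)
    biotype: str = "protein_coding"
    exons: list[tuple[int, int]] = field(default_factory=list)
    utr5: list[tuple[int, int]] = field(default_factory=list)
    utr3: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be +/-")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: empty span")
        if not self.transcript_lengths:
            self.transcript_lengths = [self.end - self.start]
        if any(l <= 0 for l in self.transcript_lengths):
            raise ValueError(f"gene {self.gene_id}: non-positive transcript length")

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end

    @property
    def tts(self) -> int:
        return self.end if self.strand == "+" else self.start

    @property
    def span(self) -> Interval:
        return Interval(self.chrom, self.start, self.end, self.strand)

    @property
    def median_transcript_length(self) -> float:
        return float(np.median(self.transcript_lengths))


class GenomeAnnotation:
    """Gene models plus chromosome sizes."""

    def __init__(self, genes: Iterable[GeneModel], chrom_sizes: Mapping[str, int]):
        self.chrom_sizes: dict[str, int] = dict(chrom_sizes)
        self.genes: dict[str, GeneModel] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            size = self.chrom_sizes.get(g.chrom)
            if size is not None and g.end > size:
                raise ValueError(
                    f"gene {g.gene_id} extends past {g.chrom} length {size}"
                )
            self.genes[g.gene_id] = g

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self) -> Iterator[GeneModel]:
        return iter(self.genes.values())

    def __getitem__(self, gene_id: str) -> GeneModel:
        return self.genes[gene_id]

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes.values() if g.chrom == chrom]

    def gene_lengths_kb(self) -> pd.Series:
        return pd.Series(
            {g.gene_id: g.median_transcript_length / 1000.0 for g in self},
            name="length_kb",
        )


# ---------------------------------------------------------------------------
# Columnar read container


class ReadLibrary:
    """Columnar store for one sequencing library.

    Iterating yields :class:`ReadAlignment` records; numeric columns are
    numpy arrays so overlap counting stays vectorised for libraries of
    10^5-10^6 reads.
    """

    def __init__(
        self,
        chrom: np.ndarray,
        start: np.ndarray,
        end: np.ndarray,
        strand: np.ndarray,
        split_mapped: np.ndarray | None = None,
    ):
        n = len(start)
        self.chrom = np.asarray(chrom, dtype=object)
        self.start = np.asarray(start, dtype=np.int64)
        self.end = np.asarray(end, dtype=np.int64)
        self.strand = np.asarray(strand, dtype="U1")
        if split_mapped is None:
            split_mapped = np.zeros(n, dtype=bool)
        self.split_mapped = np.asarray(split_mapped, dtype=bool)
        if not (len(self.chrom) == len(self.end) == len(self.strand) == n):
            raise ValueError("column length mismatch")
        if np.any(self.start >= self.end):
            raise ValueError("reads with start >= end")

    def __len__(self) -> int:
        return len(self.start)

    def __iter__(self) -> Iterator[ReadAlignment]:
        for c, s, e, st, sp in zip(
            self.chrom, self.start, self.end, self.strand, self.split_mapped
        ):
            yield ReadAlignment(str(c), int(s), int(e), str(st), bool(sp))

    @classmethod
    def from_reads(cls, reads: Iterable[ReadAlignment]) -> "ReadLibrary":
        reads = list(reads)
        return cls(
            np.array([r.chrom for r in reads], dtype=object),
            np.array([r.start for r in reads], dtype=np.int64),
            np.array([r.end for r in reads], dtype=np.int64),
            np.array([r.strand for r in reads], dtype="U1"),
            np.array([r.split_mapped for r in reads], dtype=bool),
        )

    @classmethod
    def empty(cls) -> "ReadLibrary":
        z = np.empty(0, dtype=np.int64)
        return cls(np.empty(0, dtype=object), z, z.copy(), np.empty(0, dtype="U1"))

    @classmethod
    def concat(cls, libraries: Sequence["ReadLibrary"]) -> "ReadLibrary":
        if not libraries:
            return cls.empty()
        return cls(
            np.concatenate([l.chrom for l in libraries]),
            np.concatenate([l.start for l in libraries]),
            np.concatenate([l.end for l in libraries]),
            np.concatenate([l.strand for l in libraries]),
            np.concatenate([l.split_mapped for l in libraries]),
        )

    def subset(self, mask: np.ndarray) -> "ReadLibrary":
        return ReadLibrary(
            self.chrom[mask],
            self.start[mask],
            self.end[mask],
            self.strand[mask],
            self.split_mapped[mask],
        )

    def on_strand(self, strand: str) -> "ReadLibrary":
        return self.subset(self.strand == strand)

    def deduplicated(self) -> "ReadLibrary":
        """Collapse identical (chrom, start, end, strand) reads to one copy."""
        df = pd.DataFrame(
            {"c": self.chrom, "s": self.start, "e": self.end, "t": self.strand}
        )
        keep = ~df.duplicated().to_numpy()
        return self.subset(keep)

    def extended(
        self, chrom_sizes: Mapping[str, int], target_length: int = 200
    ) -> "ReadLibrary":
        """Extend each read 3'-ward to ``target_length`` bp, clipped to the
        chromosome.  Reads already longer are left unchanged."""
        start = self.start.copy()
        end = self.end.copy()
        short = (end - start) < target_length
        plus = short & (self.strand == "+")
        minus = short & (self.strand == "-")
        end[plus] = start[plus] + target_length
        start[minus] = end[minus] - target_length
        np.clip(start, 0, None, out=start)
        sizes = np.array(
            [chrom_sizes.get(c, np.iinfo(np.int64).max) for c in self.chrom],
            dtype=np.int64,
        )
        np.minimum(end, sizes, out=end)
        return ReadLibrary(self.chrom, start, end, self.strand, self.split_mapped)

    def sorted(self) -> "ReadLibrary":
        order = np.lexsort((self.strand, self.end, self.start, self.chrom.astype(str)))
        return self.subset(order)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": self.chrom,
                "start": self.start,
                "end": self.end,
                "strand": self.strand,
                "split_mapped": self.split_mapped,
            }
        )


class ReadIndex:
    """Per-chromosome sorted-endpoint index for O(log n) overlap counting.

    A read overlaps ``[s, e)`` iff read.start < e and read.end > s; the count
    is ``#(start < e) - #(end <= s)`` on the sorted start/end arrays.
    """

    def __init__(self, library: ReadLibrary):
        self.total = len(library)
        self._by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        chroms = library.chrom.astype(str)
        for c in np.unique(chroms):
            m = chroms == c
            self._by_chrom[str(c)] = (
                np.sort(library.start[m]),
                np.sort(library.end[m]),
            )

    def count(self, region: Interval) -> int:
        got = self._by_chrom.get(region.chrom)
        if got is None:
            return 0
        starts, ends = got
        return int(
            np.searchsorted(starts, region.end, side="left")
            - np.searchsorted(ends, region.start, side="right")
        )

    def count_many(
        self, chrom: str, starts: np.ndarray, ends: np.ndarray
    ) -> np.ndarray:
        got = self._by_chrom.get(chrom)
        if got is None:
            return np.zeros(len(starts), dtype=np.int64)
        rs, re = got
        return np.searchsorted(rs, ends, side="left") - np.searchsorted(
            re, starts, side="right"
        )


# ---------------------------------------------------------------------------
# Parsers / writers


def read_chrom_sizes(path) -> dict[str, int]:
    """Two-column TSV: chromosome name, length in bp."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_gene_annotation(gtf_path, chrom_sizes: Mapping[str, int] | None = None) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    GTF coordinates (1-based inclusive) are shifted to 0-based half-open.
    Transcript lengths are exon sums; a gene without any transcript is kept
    with its span as a single transcript (with a warning).
    """
    genes: dict[str, GeneModel] = {}
    tx_gene: dict[str, str] = {}
    tx_len: dict[str, int] = {}
    utr5: dict[str, list[tuple[int, int]]] = {}
    utr3: dict[str, list[tuple[int, int]]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    max_end: dict[str, int] = {}

    with _open_text(gtf_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises several types
                raise ValueError(f"malformed GTF line {lineno}: {exc}") from exc
            if feat.start is None or feat.end is None or not feat.featuretype:
                raise ValueError(f"malformed GTF line {lineno}: incomplete fields")
            ftype = feat.featuretype
            start0, end0 = feat.start - 1, feat.end  # 1-based incl -> 0-based half-open
            if ftype == "gene":
                gid = feat.attributes.get("gene_id", [None])[0]
                if gid is None:
                    raise ValueError(f"malformed GTF line {lineno}: missing gene_id")
                biotype = feat.attributes.get(
                    "gene_biotype", feat.attributes.get("gene_type", ["protein_coding"])
                )[0]
                genes[gid] = GeneModel(
                    gid, feat.seqid, feat.strand, start0, end0, [], biotype
                )
            elif ftype == "transcript":
                gid = feat.attributes.get("gene_id", [None])[0]
                tid = feat.attributes.get("transcript_id", [None])[0]
                if gid and tid:
                    tx_gene[tid] = gid
                    tx_len.setdefault(tid, 0)
            elif ftype == "exon":
                tid = feat.attributes.get("transcript_id", [None])[0]
                gid = feat.attributes.get("gene_id", [None])[0]
                if tid is not None:
                    if tid not in tx_gene and gid:
                        tx_gene[tid] = gid
                    tx_len[tid] = tx_len.get(tid, 0) + (end0 - start0)
                if gid:
                    exons.setdefault(gid, []).append((start0, end0))
            elif ftype == "five_prime_utr":
                gid = feat.attributes.get("gene_id", [None])[0]
                if gid:
                    utr5.setdefault(gid, []).append((start0, end0))
            elif ftype == "three_prime_utr":
                gid = feat.attributes.get("gene_id", [None])[0]
                if gid:
                    utr3.setdefault(gid, []).append((start0, end0))
            max_end[feat.seqid] = max(max_end.get(feat.seqid, 0), end0)

    for tid, gid in tx_gene.items():
        if gid in genes and tx_len.get(tid, 0) > 0:
            genes[gid].transcript_lengths.append(tx_len[tid])
    out = []
    for gid, g in genes.items():
        # __post_init__ seeded transcript_lengths with the span; drop that
        # placeholder when real transcripts were found.
        real = g.transcript_lengths[1:]
        if real:
            g.transcript_lengths = real
        else:
            warnings.warn(
                f"gene {gid} has no transcript; using gene span as its transcript"
            )
        g.exons = merge_interval_tuples(exons.get(gid, []))
        g.utr5 = merge_interval_tuples(utr5.get(gid, []))
        g.utr3 = merge_interval_tuples(utr3.get(gid, []))
        out.append(g)
    if chrom_sizes is None:
        chrom_sizes = {c: e for c, e in max_end.items()}
    return GenomeAnnotation(out, chrom_sizes)


def write_gene_annotation(annotation: GenomeAnnotation, gtf_path) -> None:
    """Write genes (and one transcript per stored transcript length) as GTF."""
    with open(gtf_path, "w") as fh:
        for g in sorted(annotation, key=lambda g: (g.chrom, g.start, g.gene_id)):
            attrs = (
                f'gene_id "{g.gene_id}"; gene_biotype "{g.biotype}";'
            )
            fh.write(
                f"{g.chrom}\tepiretina\tgene\t{g.start + 1}\t{g.end}\t.\t"
                f"{g.strand}\t.\t{attrs}\n"
            )
            for i, length in enumerate(g.transcript_lengths, start=1):
                tid = f"{g.gene_id}.t{i}"
                tattrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{tid}"; '
                    f'gene_biotype "{g.biotype}";'
                )
                # synthetic single-exon transcript anchored at the 5' end
                if g.strand == "+":
                    ts, te = g.start, min(g.start + length, g.end)
                else:
                    ts, te = max(g.end - length, g.start), g.end
                fh.write(
                    f"{g.chrom}\tepiretina\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )
                fh.write(
                    f"{g.chrom}\tepiretina\texon\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tattrs}\n"
                )


def read_bed_reads(path) -> ReadLibrary:
    """BED6 -> ReadLibrary; a name containing 'split' marks a split-mapped read."""
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    split = df["name"].fillna("").str.contains("split").to_numpy()
    return ReadLibrary(
        df["chrom"].to_numpy(dtype=object),
        df["start"].to_numpy(np.int64),
        df["end"].to_numpy(np.int64),
        df["strand"].to_numpy(dtype="U1"),
        split,
    )


def write_bed_reads(library: ReadLibrary, path) -> None:
    names = np.where(library.split_mapped, "read_split", "read")
    df = pd.DataFrame(
        {
            "chrom": library.chrom,
            "start": library.start,
            "end": library.end,
            "name": names,
            "score": 0,
            "strand": library.strand,
        }
    )
    df.to_csv(path, sep="\t", header=False, index=False)


def read_bed_intervals(path) -> list[Interval]:
    """BED3/BED6 -> list of Interval (strand taken from column 6 if present)."""
    rows = []
    with _open_text(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            parts = line.rstrip("\n").split("\t")
            strand = parts[5] if len(parts) >= 6 and parts[5] in "+-" else "."
            rows.append(Interval(parts[0], int(parts[1]), int(parts[2]), strand))
    return rows


def write_bed_intervals(intervals: Sequence[Interval], path, names=None) -> None:
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            name = names[i] if names is not None else f"region_{i + 1}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t0\t{iv.strand}\n")


def read_alignments_from_sam(path) -> ReadLibrary:
    """Optional SAM/BAM adapter (requires pysam).

    Each primary alignment maps to one read; split_mapped is set when the
    CIGAR contains an N operation or the alignment is supplementary.
    """
    import pysam

    reads = []
    with pysam.AlignmentFile(str(path)) as fh:
        for aln in fh:
            if aln.is_unmapped or aln.is_secondary:
                continue
            has_n = any(op == 3 for op, _ in (aln.cigartuples or []))
            reads.append(
                ReadAlignment(
                    aln.reference_name,
                    aln.reference_start,
                    aln.reference_end,
                    "-" if aln.is_reverse else "+",
                    has_n or aln.is_supplementary,
                )
            )
    return ReadLibrary.from_reads(reads)


# ---------------------------------------------------------------------------
# Interval primitives


def merge_interval_tuples(ivs: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of (start, end) tuples as a sorted non-overlapping list."""
    ivs = sorted(ivs)
    out: list[tuple[int, int]] = []
    for s, e in ivs:
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def union_length_within(a: Interval, b_set: Iterable[Interval]) -> int:
    """Length of a covered by the union of b_set (same chromosome only)."""
    clipped = [
        (max(b.start, a.start), min(b.end, a.end))
        for b in b_set
        if b.chrom == a.chrom and b.start < a.end and b.end > a.start
    ]
    return sum(e - s for s, e in merge_interval_tuples(clipped))


def extend_read(
    read: ReadAlignment, target_length: int = 200, chrom_length: int | None = None
) -> Interval:
    """Extend a read 3'-ward to ``target_length`` bp; never shrink; clip to
    the chromosome."""
    s, e = read.start, read.end
    if e - s < target_length:
        if read.strand == "+":
            e = s + target_length
        else:
            s = e - target_length
    s = max(s, 0)
    if chrom_length is not None:
        e = min(e, chrom_length)
    return Interval(read.chrom, s, e, read.strand)


def extend_gene_region(
    gene: GeneModel,
    upstream: int = 3000,
    downstream: int = 10000,
    chrom_length: int | None = None,
) -> Interval:
    """Strand-aware extension: ``upstream`` bp past the TSS and ``downstream``
    bp past the TTS, clipped to the chromosome."""
    if gene.strand == "+":
        s, e = gene.start - upstream, gene.end + downstream
    else:
        s, e = gene.start - downstream, gene.end + upstream
    s = max(s, 0)
    if chrom_length is not None:
        e = min(e, chrom_length)
    return Interval(gene.chrom, s, e, gene.strand)


def derive_intergenic_regions(
    annotation: GenomeAnnotation, min_length: int = 1000
) -> list[Interval]:
    """Complement of the union of gene spans per chromosome.

    Regions shorter than ``min_length`` are discarded (degenerate
    normalization windows); pass 0 to keep the exact partition.
    """
    if len(annotation) == 0:
        raise ValueError("annotation has no genes")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in annotation:
        if g.chrom not in annotation.chrom_sizes:
            raise ValueError(f"chromosome {g.chrom} missing from chrom_sizes")
        by_chrom.setdefault(g.chrom, []).append((g.start, g.end))
    out: list[Interval] = []
    for chrom in sorted(annotation.chrom_sizes):
        size = annotation.chrom_sizes[chrom]
        pos = 0
        for s, e in merge_interval_tuples(by_chrom.get(chrom, [])):
            if s - pos >= max(1, min_length):
                out.append(Interval(chrom, pos, s))
            pos = max(pos, e)
        if size - pos >= max(1, min_length):
            out.append(Interval(chrom, pos, size))
    return out


class TssIndex:
    """Sorted TSS lookup with the (chrom, tss, gene_id) tie-break."""

    def __init__(self, annotation: GenomeAnnotation):
        self._by_chrom: dict[str, tuple[np.ndarray, list[GeneModel]]] = {}
        by_chrom: dict[str, list[GeneModel]] = {}
        for g in annotation:
            by_chrom.setdefault(g.chrom, []).append(g)
        for chrom, gs in by_chrom.items():
            gs.sort(key=lambda g: (g.tss, g.gene_id))
            self._by_chrom[chrom] = (np.array([g.tss for g in gs]), gs)

    def nearest(self, chrom: str, pos: int) -> tuple[GeneModel | None, float]:
        got = self._by_chrom.get(chrom)
        if got is None:
            return None, float("inf")
        tss, gs = got
        i = int(np.searchsorted(tss, pos))
        best = None
        best_key = None
        for j in (i - 1, i, i + 1):
            if 0 <= j < len(gs):
                d = abs(int(tss[j]) - pos)
                key = (d, int(tss[j]), gs[j].gene_id)
                if best_key is None or key < best_key:
                    best_key = key
                    best = gs[j]
        assert best is not None
        signed = pos - best.tss if best.strand == "+" else best.tss - pos
        return best, float(signed)


def annotate_to_nearest_tss(
    intervals: Sequence[Interval], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Assign each interval to the gene whose TSS is nearest its midpoint.

    Distance is signed in the gene's orientation (negative = upstream of the
    TSS).  Equidistant TSSs resolve to the gene earlier in (chrom, tss,
    gene_id) order; an interval on a gene-less chromosome gets gene_id None
    and infinite distance.
    """
    idx = TssIndex(annotation)
    rows = []
    for iv in intervals:
        gene, dist = idx.nearest(iv.chrom, iv.midpoint)
        rows.append(
            {
                "chrom": iv.chrom,
                "start": iv.start,
                "end": iv.end,
                "gene_id": gene.gene_id if gene else None,
                "distance": dist,
            }
        )
    return pd.DataFrame(rows)
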