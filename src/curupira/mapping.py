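"""Placement of collapsed sequence tags (and WGS reads) on the genome.

Tags are placed by exact substring search over both strands, optionally
allowing one mismatch; all placements at the best stratum (fewest mismatches)
are reported and a tag's read count is spread over its placements as
``weight = total / n_genomic_hits``, so total read mass is conserved under
multi-mapping.  External aligner output (SAM/BAM) can be imported under the
same contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
from Bio import SeqIO

from ._sequtil import revcomp
from .preprocess import SequenceTag, tag_name

DEFAULT_MAX_HITS = 100


@dataclass(frozen=True)
class TagHit:
    """One genomic placement of a sequence tag.

    ``n_genomic_hits`` is the total number of placements of the tag genome-wide
    at its best stratum; ``weight`` is the tag's total read count divided by
    that number.
    """

    tag: SequenceTag
    contig: str
    start: int  # 0-based
    end: int  # exclusive
    strand: str
    n_genomic_hits: int
    weight: float

    def library_weight(self, library: str) -> float:
        return self.tag.counts.get(library, 0) / self.n_genomic_hits


class GenomeIndex:
    """Exact-substring index over both strands of a genome (seed k-mer table)."""

    def __init__(self, sequences: Mapping[str, str], k: int = 12):
        if not sequences:
            raise ValueError("genome is empty")
        self.sequences = {name: str(seq).upper() for name, seq in sequences.items()}
        shortest = min(len(s) for s in self.sequences.values())
        self.k = min(k, shortest)
        self._kmers: dict[str, list[tuple[str, int]]] = {}
        for name, seq in self.sequences.items():
            for i in range(len(seq) - self.k + 1):
                self._kmers.setdefault(seq[i : i + self.k], []).append((name, i))

    # -- exact search ------------------------------------------------------

    def _find_forward(self, pattern: str) -> list[tuple[str, int]]:
        """All forward-genome occurrences of ``pattern`` (overlaps included)."""
        L = len(pattern)
        if L < self.k:
            out = []
            for name, seq in self.sequences.items():
                i = seq.find(pattern)
                while i != -1:
                    out.append((name, i))
                    i = seq.find(pattern, i + 1)
            return out
        out = []
        for name, pos in self._kmers.get(pattern[: self.k], ()):
            if self.sequences[name][pos : pos + L] == pattern:
                out.append((name, pos))
        return out

    def find(self, query: str) -> list[tuple[str, int, str]]:
        """Exact placements of ``query`` on both strands as (contig, start, strand)."""
        query = query.upper()
        hits = [(c, p, "+") for c, p in self._find_forward(query)]
        rc = revcomp(query)
        hits += [(c, p, "-") for c, p in self._find_forward(rc)]
        return sorted(set(hits))

    def find_one_mismatch(self, query: str) -> list[tuple[str, int, str]]:
        """Placements with exactly one mismatch (exact matches excluded)."""
        query = query.upper()
        out = set()
        for oriented, strand in ((query, "+"), (revcomp(query), "-")):
            for c, p in self._candidates(oriented):
                window = self.sequences[c][p : p + len(oriented)]
                if len(window) < len(oriented):
                    continue
                mm = sum(a != b for a, b in zip(window, oriented))
                if mm == 1:
                    out.add((c, p, strand))
        return sorted(out)

    def _candidates(self, pattern: str) -> set[tuple[str, int]]:
        L, k = len(pattern), self.k
        if L < 2 * k:  # pigeonhole needs two disjoint seeds; fall back to full scan
            cands = set()
            for name, seq in self.sequences.items():
                for i in range(len(seq) - L + 1):
                    cands.add((name, i))
            return cands
        cands = set(self._kmers.get(pattern[:k], ()))
        for c, p in self._kmers.get(pattern[L - k :], ()):
            if p - (L - k) >= 0:
                cands.add((c, p - (L - k)))
        return cands


def build_index(genome: Mapping[str, str] | str | Path, k: int = 12) -> GenomeIndex:
    """Build a :class:`GenomeIndex` from a sequence mapping or a FASTA path."""
    if isinstance(genome, (str, Path)):
        sequences: dict[str, str] = {}
        for rec in SeqIO.parse(str(genome), "fasta"):
            if rec.id in sequences:
                raise ValueError(f"duplicate contig name {rec.id!r} in genome FASTA")
            sequences[rec.id] = str(rec.seq).upper()
        return GenomeIndex(sequences, k=k)
    names = list(genome)
    if len(names) != len(set(names)):
        raise ValueError("duplicate contig names in genome")
    return GenomeIndex(genome, k=k)


@dataclass
class MapResult:
    hits: list[TagHit]
    unmapped: list[SequenceTag]
    dropped_repetitive: list[SequenceTag]


def map_tags(
    tags: Sequence[SequenceTag],
    index: GenomeIndex,
    max_mismatch: int = 0,
    max_hits: int = DEFAULT_MAX_HITS,
) -> MapResult:
    """Place every tag at its best stratum and weight placements 1/n.

    Tags with no placement go to ``unmapped``; tags with more than ``max_hits``
    placements are dropped as hyper-repetitive (``dropped_repetitive``).
    """
    if max_mismatch not in (0, 1):
        raise ValueError("max_mismatch must be 0 or 1")
    hits: list[TagHit] = []
    unmapped: list[SequenceTag] = []
    dropped: list[SequenceTag] = []
    for tag in tags:
        placements = index.find(tag.sequence)
        if not placements and max_mismatch == 1:
            placements = index.find_one_mismatch(tag.sequence)
        if not placements:
            unmapped.append(tag)
            continue
        n = len(placements)
        if n > max_hits:
            dropped.append(tag)
            continue
        w = tag.total / n
        for contig, start, strand in placements:
            hits.append(TagHit(tag, contig, start, start + len(tag.sequence), strand, n, w))
    return MapResult(hits, unmapped, dropped)


def import_alignments(
    path: str | Path, tags: Sequence[SequenceTag] | Mapping[str, SequenceTag]
) -> list[TagHit]:
    """Read SAM/BAM produced by an external aligner into TagHit records.

    Query names must follow the ``tag{serial}-{total}`` convention of
    :func:`curupira.preprocess.write_tags` (or ``tags`` may be a mapping from
    query name to tag).  ``n_genomic_hits`` is the number of mapped records
    (primary plus secondary) per query name.
    """
    if isinstance(tags, Mapping):
        by_name = dict(tags)
    else:
        by_name = {tag_name(i + 1, t.total): t for i, t in enumerate(tags)}
    mode = "rb" if str(path).endswith(".bam") else "r"
    records = []
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped:
                continue
            records.append(
                (
                    rec.query_name,
                    rec.reference_name,
                    rec.reference_start,
                    rec.reference_end,
                    "-" if rec.is_reverse else "+",
                )
            )
    per_name: dict[str, int] = {}
    for qname, *_ in records:
        per_name[qname] = per_name.get(qname, 0) + 1
    hits = []
    for qname, contig, start, end, strand in records:
        tag = by_name.get(qname)
        if tag is None:
            warnings.warn(f"query name {qname!r} does not resolve to a tag; skipped")
            continue
        n = per_name[qname]
        hits.append(TagHit(tag, contig, start, end, strand, n, tag.total / n))
    return hits


def write_sam(hits: Iterable[TagHit], index: GenomeIndex, path: str | Path) -> None:
    """Write tag placements as SAM with a minimal @SQ header."""
    serial = {}
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in index.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for hit in hits:
            key = hit.tag.sequence
            if key not in serial:
                serial[key] = len(serial) + 1
            qname = tag_name(serial[key], hit.tag.total)
            flag = 16 if hit.strand == "-" else 0
            L = len(hit.tag.sequence)
            seq = hit.tag.sequence if hit.strand == "+" else revcomp(hit.tag.sequence)
            fh.write(
                f"{qname}\t{flag}\t{hit.contig}\t{hit.start + 1}\t255\t{L}M\t*\t0\t0\t"
                f"{seq}\t{'I' * L}\tNH:i:{hit.n_genomic_hits}\n"
            )


@dataclass(frozen=True)
class AlignedRead:
    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    n_hits: int


def align_reads_exact(
    records: Iterable[tuple[str, str]], index: GenomeIndex
) -> list[AlignedRead]:
    """Exact-match single placement per read (first placement in sorted order).

    Suitable for error-free simulated WGS reads; reads with no exact placement
    are skipped.
    """
    out = []
    for rid, seq in records:
        placements = index.find(seq)
        if not placements:
            continue
        contig, start, strand = placements[0]
        out.append(AlignedRead(rid, contig, start, start + len(seq), strand, len(placements)))
    return out


def write_alignments_sam(
    reads: Iterable[AlignedRead],
    index: GenomeIndex,
    path: str | Path,
    read_length: int | None = None,
) -> None:
    """Write AlignedRead records as SAM (sequence re-extracted from the genome)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unsorted\n")
        for name, seq in index.sequences.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for r in reads:
            L = r.end - r.start
            frag = index.sequences[r.contig][r.start : r.end]
            seq = frag if r.strand == "+" else revcomp(frag)
            flag = 16 if r.strand == "-" else 0
            fh.write(
                f"{r.read_id}\t{flag}\t{r.contig}\t{r.start + 1}\t255\t{L}M\t*\t0\t0\t"
                f"{seq}\t{'I' * L}\n"
            )
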