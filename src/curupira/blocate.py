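"""B-chromosome localization by B+/B- read-depth ratio and B-specific SNP calling.

B-resident sequence is duplicated in carrier genomes, so contigs copied onto
the B chromosome show elevated depth in B+ whole-genome sequencing.  Depth is
normalized by library-wide total mapped bases and a contig is flagged when the
normalized B+/B- ratio is strictly greater than 2.  The ratio is a qualitative
indicator of B residency, not a copy-number estimate.

B-specific SNPs are sites where the B+ pileup shows an alternate allele at
appreciable frequency while the B- pileup is (near) reference-pure; sites
polymorphic in both samples are ordinary population SNPs and are excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from ._sequtil import revcomp
from .clustercall import PiRNACluster
from .mapping import GenomeIndex

RATIO_THRESHOLD = 2.0

_BASE_CODE = np.full(128, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i


@dataclass
class DepthTrack:
    contig: str
    depth: np.ndarray  # per-base read coverage
    sample: str  # 'B-' or 'B+'
    total_mapped_bases: int  # library-wide, for normalization

    @property
    def mean_depth(self) -> float:
        return float(self.depth.mean()) if self.depth.size else 0.0


@dataclass
class CoverageRatioRecord:
    contig: str
    mean_depth_bminus: float
    mean_depth_bplus: float
    norm_ratio: float  # math.inf when the B- mean is zero
    flagged: bool


@dataclass(frozen=True)
class WGSAlignment:
    """A placed WGS read with its forward-strand sequence (for pileups)."""

    read_id: str
    contig: str
    start: int
    end: int
    strand: str
    fwd_seq: str


def align_wgs(
    records: Iterable[tuple[str, str]], index: GenomeIndex, max_mismatch: int = 1
) -> list[WGSAlignment]:
    """Place WGS reads on the genome (exact first, then one mismatch).

    One mismatch is enough to place reads carrying a single B-specific SNP
    allele.  Reads with multiple placements take the first in sorted order;
    unplaceable reads are skipped.
    """
    out = []
    for rid, seq in records:
        placements = index.find(seq)
        if not placements and max_mismatch >= 1:
            placements = index.find_one_mismatch(seq)
        if not placements:
            continue
        contig, start, strand = placements[0]
        fwd = seq if strand == "+" else revcomp(seq)
        out.append(WGSAlignment(rid, contig, start, start + len(seq), strand, fwd))
    return out


def depth_tracks(
    alignments: Sequence[WGSAlignment],
    contig_lengths: Mapping[str, int],
    sample: str,
) -> dict[str, DepthTrack]:
    """Per-base depth per contig; depth[i] counts reads whose span covers i."""
    total = sum(a.end - a.start for a in alignments)
    diffs = {c: np.zeros(L + 1, dtype=np.int64) for c, L in contig_lengths.items()}
    for a in alignments:
        diffs[a.contig][a.start] += 1
        diffs[a.contig][a.end] -= 1
    return {
        c: DepthTrack(c, np.cumsum(d[:-1]), sample, total) for c, d in diffs.items()
    }


def depth_from_sam(
    path: str | Path, sample: str, contig_lengths: Mapping[str, int] | None = None
) -> dict[str, DepthTrack]:
    """Depth tracks from an external SAM/BAM alignment."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        lengths = contig_lengths or dict(zip(fh.references, fh.lengths))
        diffs = {c: np.zeros(L + 1, dtype=np.int64) for c, L in lengths.items()}
        total = 0
        for rec in fh.fetch(until_eof=True):
            if rec.is_unmapped or rec.reference_name not in diffs:
                continue
            start, end = rec.reference_start, rec.reference_end
            diffs[rec.reference_name][start] += 1
            diffs[rec.reference_name][end] -= 1
            total += end - start
    return {
        c: DepthTrack(c, np.cumsum(d[:-1]), sample, total) for c, d in diffs.items()
    }


def depth_profile(path: str | Path, contig: str, sample: str = "") -> DepthTrack:
    """Depth track for a single contig of an external alignment file."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode) as fh:
        if contig not in fh.references:
            raise ValueError(f"contig {contig!r} absent from alignment header")
    return depth_from_sam(path, sample)[contig]


def coverage_ratio(
    track_bplus: DepthTrack,
    track_bminus: DepthTrack,
    threshold: float = RATIO_THRESHOLD,
) -> CoverageRatioRecord:
    """Normalized B+/B- mean-depth ratio; flagged when strictly > threshold."""
    if track_bplus.contig != track_bminus.contig:
        raise ValueError("tracks are for different contigs")
    if track_bplus.total_mapped_bases <= 0 or track_bminus.total_mapped_bases <= 0:
        raise ValueError("zero total mapped bases; cannot normalize")
    mean_bp = track_bplus.mean_depth
    mean_bm = track_bminus.mean_depth
    norm_bp = mean_bp / track_bplus.total_mapped_bases
    norm_bm = mean_bm / track_bminus.total_mapped_bases
    ratio = math.inf if norm_bm == 0 else norm_bp / norm_bm
    return CoverageRatioRecord(
        contig=track_bplus.contig,
        mean_depth_bminus=mean_bm,
        mean_depth_bplus=mean_bp,
        norm_ratio=ratio,
        flagged=ratio > threshold,
    )


def coverage_ratios(
    tracks_bplus: Mapping[str, DepthTrack],
    tracks_bminus: Mapping[str, DepthTrack],
    threshold: float = RATIO_THRESHOLD,
) -> list[CoverageRatioRecord]:
    return [
        coverage_ratio(tracks_bplus[c], tracks_bminus[c], threshold)
        for c in sorted(tracks_bplus)
        if c in tracks_bminus
    ]


def flag_b_intervals(
    records: Sequence[CoverageRatioRecord],
    clusters: Sequence[PiRNACluster],
    threshold: float = RATIO_THRESHOLD,
) -> list[PiRNACluster]:
    """Annotate clusters as B-candidates when their contig's ratio exceeds threshold."""
    by_contig = {r.contig: r for r in records}
    for c in clusters:
        if c.contig not in by_contig:
            raise ValueError(f"no coverage-ratio record for cluster contig {c.contig!r}")
        c.b_candidate = by_contig[c.contig].norm_ratio > threshold
    return list(clusters)


# ---------------------------------------------------------------------------
# pileups and B-specific variants


def pileups(
    alignments: Sequence[WGSAlignment], contig_lengths: Mapping[str, int]
) -> dict[str, np.ndarray]:
    """Per-site base tallies as a (4, contig_length) array per contig (A,C,G,T rows)."""
    by_contig: dict[str, list[WGSAlignment]] = {c: [] for c in contig_lengths}
    for a in alignments:
        by_contig[a.contig].append(a)
    out = {}
    for contig, L in contig_lengths.items():
        reads = by_contig[contig]
        if not reads:
            out[contig] = np.zeros((4, L), dtype=np.int64)
            continue
        pos_parts = []
        code_parts = []
        for a in reads:
            codes = _BASE_CODE[np.frombuffer(a.fwd_seq.encode(), dtype=np.uint8)]
            keep = codes >= 0
            pos = np.arange(a.start, a.end)[keep]
            pos_parts.append(pos)
            code_parts.append(codes[keep].astype(np.int64))
        pos_all = np.concatenate(pos_parts)
        code_all = np.concatenate(code_parts)
        counts = np.bincount(code_all * L + pos_all, minlength=4 * L)
        out[contig] = counts.reshape(4, L)
    return out


def b_specific_variants(
    pileup_bminus: Mapping[str, np.ndarray],
    pileup_bplus: Mapping[str, np.ndarray],
    reference: Mapping[str, str],
    min_depth: int = 5,
    min_alt_bplus: float = 0.2,
    max_alt_bminus: float = 0.02,
) -> pd.DataFrame:
    """Sites with an alternate allele in B+ reads only.

    A site is reported when both samples reach ``min_depth``, the B+ alternate
    allele frequency is >= ``min_alt_bplus`` and the B- alternate frequency is
    <= ``max_alt_bminus``.  Returns a VCF-like table with 1-based positions.
    """
    rows = []
    for contig in sorted(pileup_bplus):
        if contig not in pileup_bminus:
            continue
        bp = pileup_bplus[contig]
        bm = pileup_bminus[contig]
        ref_codes = _BASE_CODE[
            np.frombuffer(reference[contig].upper().encode(), dtype=np.uint8)
        ]
        depth_bp = bp.sum(axis=0)
        depth_bm = bm.sum(axis=0)
        L = bp.shape[1]
        cols = np.arange(L)
        ref_bp = np.where(ref_codes >= 0, bp[np.clip(ref_codes, 0, 3), cols], 0)
        ref_bm = np.where(ref_codes >= 0, bm[np.clip(ref_codes, 0, 3), cols], 0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq_bp = np.where(depth_bp > 0, (depth_bp - ref_bp) / depth_bp, 0.0)
            freq_bm = np.where(depth_bm > 0, (depth_bm - ref_bm) / depth_bm, 0.0)
        mask = (
            (depth_bp >= min_depth)
            & (depth_bm >= min_depth)
            & (freq_bp >= min_alt_bplus)
            & (freq_bm <= max_alt_bminus)
            & (ref_codes >= 0)
        )
        for pos in np.flatnonzero(mask):
            alt_counts = bp[:, pos].copy()
            alt_counts[ref_codes[pos]] = 0
            alt = "ACGT"[int(alt_counts.argmax())]
            rows.append(
                {
                    "contig": contig,
                    "pos": int(pos) + 1,
                    "ref": reference[contig][pos],
                    "alt": alt,
                    "depth_bminus": int(depth_bm[pos]),
                    "depth_bplus": int(depth_bp[pos]),
                    "alt_freq_bminus": round(float(freq_bm[pos]), 4),
                    "alt_freq_bplus": round(float(freq_bp[pos]), 4),
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "contig", "pos", "ref", "alt",
            "depth_bminus", "depth_bplus", "alt_freq_bminus", "alt_freq_bplus",
        ],
    )


# ---------------------------------------------------------------------------
# output


def ratio_table(records: Sequence[CoverageRatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "contig": r.contig,
                "mean_depth_bminus": round(r.mean_depth_bminus, 3),
                "mean_depth_bplus": round(r.mean_depth_bplus, 3),
                "norm_ratio": "inf" if math.isinf(r.norm_ratio) else round(r.norm_ratio, 4),
                "flagged": r.flagged,
            }
            for r in records
        ]
    )


def write_bedgraph(track: DepthTrack, path: str | Path, append: bool = False) -> None:
    """Export a depth track as BedGraph (runs of equal depth collapsed)."""
    depth = track.depth
    with open(path, "a" if append else "w") as fh:
        if depth.size == 0:
            return
        boundaries = np.flatnonzero(np.diff(depth)) + 1
        starts = np.concatenate(([0], boundaries))
        ends = np.concatenate((boundaries, [depth.size]))
        for s, e in zip(starts, ends):
            fh.write(f"{track.contig}\t{s}\t{e}\t{int(depth[s])}\n")
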