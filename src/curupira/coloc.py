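"""miRNA / piRNA-cluster colocalization: per-contig classes and Venn counts.

piRNA clusters live in repeat-rich regions while miRNA genes sit near
euchromatin, so contigs carrying both annotation types are rare and contigs
where a pre-miRNA lies inside a piRNA cluster are the interesting exceptions.
Internally all intervals are 0-based half-open; reported coordinates are
1-based inclusive, and the BED/GFF3 readers convert at the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib.resources import files
from pathlib import Path
from typing import Sequence

import pandas as pd


@dataclass(frozen=True)
class GenomicInterval:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty interval {self.contig}:{self.start}-{self.end}")


def from_1based(contig: str, start: int, end: int, strand: str = ".", label: str = "") -> GenomicInterval:
    """Build an interval from printed 1-based inclusive coordinates."""
    return GenomicInterval(contig, start - 1, end, strand, label)


def interval_overlap(a, b) -> int:
    """Overlap in bp between two intervals; 0 if disjoint or on different contigs.

    Strand is ignored: sense and antisense miRNAs both count as superposed.
    """
    if a.contig != b.contig:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def coloc_table(
    mirnas: Sequence[GenomicInterval], clusters: Sequence
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Classify contigs by miRNA/piRNA content.

    Returns a per-contig table (class and, for 'both' contigs, whether any
    miRNA-cluster pair overlaps by >= 1 bp) and the Venn counts.  ``clusters``
    may be any objects with contig/start/end attributes (e.g. called
    piRNA clusters or plain intervals).
    """
    mirna_contigs: dict[str, list[GenomicInterval]] = {}
    for m in mirnas:
        mirna_contigs.setdefault(m.contig, []).append(m)
    cluster_contigs: dict[str, list] = {}
    for c in clusters:
        cluster_contigs.setdefault(c.contig, []).append(c)

    rows = []
    counts = {
        "mirna_only": 0,
        "pirna_only": 0,
        "both": 0,
        "both_superposed": 0,
        "both_not_superposed": 0,
    }
    for contig in sorted(set(mirna_contigs) | set(cluster_contigs)):
        has_m = contig in mirna_contigs
        has_p = contig in cluster_contigs
        if has_m and has_p:
            superposed = any(
                interval_overlap(m, c) >= 1
                for m in mirna_contigs[contig]
                for c in cluster_contigs[contig]
            )
            cls = "both-superposed" if superposed else "both-not-superposed"
            counts["both"] += 1
            counts["both_superposed" if superposed else "both_not_superposed"] += 1
        elif has_m:
            cls = "miRNA-only"
            counts["mirna_only"] += 1
        else:
            cls = "piRNA-only"
            counts["pirna_only"] += 1
        rows.append(
            {
                "contig": contig,
                "n_mirnas": len(mirna_contigs.get(contig, ())),
                "n_clusters": len(cluster_contigs.get(contig, ())),
                "class": cls,
            }
        )
    table = pd.DataFrame(rows, columns=["contig", "n_mirnas", "n_clusters", "class"])
    return table, counts


# ---------------------------------------------------------------------------
# interval file readers (coordinate conversion happens here)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """BED is already 0-based half-open; no conversion."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            strand = f[5] if len(f) > 5 else "."
            label = f[3] if len(f) > 3 else ""
            out.append(GenomicInterval(f[0], int(f[1]), int(f[2]), strand, label))
    return out


def read_gff3(path: str | Path) -> list[GenomicInterval]:
    """GFF3 is 1-based inclusive; converted on read."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 8:
                continue
            out.append(from_1based(f[0], int(f[3]), int(f[4]), f[6], f[8] if len(f) > 8 else ""))
    return out


# ---------------------------------------------------------------------------
# packaged colocalization fixture (printed 1-based coordinates)


def load_colocalization_fixture() -> tuple[list[GenomicInterval], list[GenomicInterval], pd.DataFrame]:
    """Load the packaged miRNA/piRNA colocalization table.

    Returns (mirna intervals, unique cluster intervals, raw table).  The raw
    table keeps the printed 1-based inclusive coordinates; the interval lists
    are converted to the internal convention.  One row's transcription:strand
    is missing in the source and stored empty.
    """
    path = files("curupira.data").joinpath("colocalization_fixture.tsv")
    with path.open() as fh:
        raw = pd.read_csv(fh, sep="\t", keep_default_na=False)
    mirnas = [
        from_1based(r.contig, r.mirna_start, r.mirna_end, r.mirna_strand, r.mirna_id)
        for r in raw.itertuples()
    ]
    clusters = []
    seen = set()
    for r in raw.itertuples():
        key = (r.contig, r.cluster_start, r.cluster_end)
        if key in seen:
            continue
        seen.add(key)
        clusters.append(
            from_1based(
                r.contig, r.cluster_start, r.cluster_end, ".", str(r.cluster_id)
            )
        )
    return mirnas, clusters, raw
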