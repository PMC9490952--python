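"""piRNA cluster calling from weighted tag placements.

A gap-based scanner proposes candidate loci (maximal runs of placements whose
consecutive starts are at most ``max_gap`` apart, with minimum tag diversity
and weighted read mass), and each candidate is accepted when it satisfies the
three piRNA-cluster criteria: span >= 1000 bp, weighted fraction of member
reads with a 5' uridine or an adenine at position 10 >= 0.75, and weighted
fraction with typical piRNA length (24-35 nt) >= 0.75.  Accepted clusters are
classified as mono- or bidirectional from the weighted main-strand fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .mapping import TagHit

MIN_CLUSTER_SIZE = 1000
MIN_FRAC_1U10A = 0.75
MIN_FRAC_TYPICAL_LEN = 0.75
MONO_STRAND_FRACTION = 0.75
TYPICAL_LEN_RANGE = (24, 35)
DEFAULT_MIN_EXPR = 5.0


@dataclass
class Candidate:
    contig: str
    start: int
    end: int
    hits: list[TagHit]


@dataclass
class ClusterMetrics:
    size: int
    frac_1u10a: float
    frac_typical_len: float
    n_tags: int
    total_weight: float
    main_strand_fraction: float
    plus_fraction: float


@dataclass
class PiRNACluster:
    id: str
    contig: str
    start: int  # 0-based half-open internally
    end: int
    directionality: str
    metrics: ClusterMetrics
    weight_per_library: dict[str, float] = field(default_factory=dict)
    expressed_in: list[str] = field(default_factory=list)
    b_candidate: bool | None = None

    @property
    def size(self) -> int:
        return self.end - self.start


def scan_candidates(
    hits: Iterable[TagHit],
    max_gap: int = 500,
    min_tags: int = 10,
    min_weight: float = 20.0,
) -> list[Candidate]:
    """Maximal runs of placements with consecutive starts <= max_gap apart.

    A run becomes a candidate when it contains at least ``min_tags`` distinct
    tag sequences and at least ``min_weight`` summed placement weight; the
    candidate span is the min start to max end of member placements.
    """
    by_contig: dict[str, list[TagHit]] = {}
    for h in hits:
        by_contig.setdefault(h.contig, []).append(h)
    candidates = []
    for contig in sorted(by_contig):
        chits = sorted(by_contig[contig], key=lambda h: (h.start, h.end))
        run: list[TagHit] = []
        for h in chits:
            if run and h.start - run[-1].start > max_gap:
                cand = _finish_run(contig, run, min_tags, min_weight)
                if cand:
                    candidates.append(cand)
                run = []
            run.append(h)
        cand = _finish_run(contig, run, min_tags, min_weight)
        if cand:
            candidates.append(cand)
    return candidates


def _finish_run(
    contig: str, run: list[TagHit], min_tags: int, min_weight: float
) -> Candidate | None:
    if not run:
        return None
    n_tags = len({h.tag.sequence for h in run})
    weight = sum(h.weight for h in run)
    if n_tags < min_tags or weight < min_weight:
        return None
    return Candidate(contig, min(h.start for h in run), max(h.end for h in run), run)


def _weighted_metrics(
    hits: Sequence[TagHit],
    start: int,
    end: int,
    typical_len_range: tuple[int, int] = TYPICAL_LEN_RANGE,
) -> ClusterMetrics:
    total = sum(h.weight for h in hits)
    w_1u10a = 0.0
    w_len = 0.0
    w_plus = 0.0
    lo, hi = typical_len_range
    for h in hits:
        seq = h.tag.sequence
        if seq[0] == "T" or (len(seq) >= 10 and seq[9] == "A"):
            w_1u10a += h.weight
        if lo <= len(seq) <= hi:
            w_len += h.weight
        if h.strand == "+":
            w_plus += h.weight
    plus_frac = w_plus / total if total else 0.0
    return ClusterMetrics(
        size=end - start,
        frac_1u10a=w_1u10a / total if total else 0.0,
        frac_typical_len=w_len / total if total else 0.0,
        n_tags=len({h.tag.sequence for h in hits}),
        total_weight=total,
        main_strand_fraction=max(plus_frac, 1 - plus_frac),
        plus_fraction=plus_frac,
    )


def cluster_filters(
    candidate: Candidate,
    min_size: int = MIN_CLUSTER_SIZE,
    min_frac_1u10a: float = MIN_FRAC_1U10A,
    min_frac_typical_len: float = MIN_FRAC_TYPICAL_LEN,
    typical_len_range: tuple[int, int] = TYPICAL_LEN_RANGE,
) -> tuple[bool, ClusterMetrics]:
    """Apply the three acceptance criteria; thresholds pass on equality (>=)."""
    if not candidate.hits:
        raise ValueError("candidate has no member hits")
    m = _weighted_metrics(
        candidate.hits, candidate.start, candidate.end, typical_len_range
    )
    accept = (
        m.size >= min_size
        and m.frac_1u10a >= min_frac_1u10a
        and m.frac_typical_len >= min_frac_typical_len
    )
    return accept, m


def classify_directionality(
    hits: Sequence[TagHit] | ClusterMetrics, mono_threshold: float = MONO_STRAND_FRACTION
) -> str:
    """mono:+ / mono:- when the weighted main-strand fraction >= 0.75, else bi."""
    if isinstance(hits, ClusterMetrics):
        m = hits
    else:
        if not hits:
            raise ValueError("no member hits")
        m = _weighted_metrics(hits, 0, 1)
    if m.main_strand_fraction >= mono_threshold:
        return "mono:+" if m.plus_fraction >= 0.5 else "mono:-"
    return "bi"


def call_clusters(
    hits: Iterable[TagHit],
    max_gap: int = 500,
    min_tags: int = 10,
    min_weight: float = 20.0,
    min_size: int = MIN_CLUSTER_SIZE,
    min_frac_1u10a: float = MIN_FRAC_1U10A,
    min_frac_typical_len: float = MIN_FRAC_TYPICAL_LEN,
    min_expr: float = DEFAULT_MIN_EXPR,
    id_prefix: str = "cluster",
) -> list[PiRNACluster]:
    """scan -> filter -> classify; flags per-library expression at min_expr mass."""
    clusters = []
    for cand in scan_candidates(hits, max_gap=max_gap, min_tags=min_tags, min_weight=min_weight):
        accept, metrics = cluster_filters(
            cand,
            min_size=min_size,
            min_frac_1u10a=min_frac_1u10a,
            min_frac_typical_len=min_frac_typical_len,
        )
        if not accept:
            continue
        per_lib: dict[str, float] = {}
        for h in cand.hits:
            for lib in h.tag.counts:
                per_lib[lib] = per_lib.get(lib, 0.0) + h.library_weight(lib)
        cluster = PiRNACluster(
            id=f"{id_prefix}-{len(clusters) + 1}",
            contig=cand.contig,
            start=cand.start,
            end=cand.end,
            directionality=classify_directionality(metrics),
            metrics=metrics,
            weight_per_library=per_lib,
            expressed_in=sorted(lib for lib, w in per_lib.items() if w >= min_expr),
        )
        clusters.append(cluster)
    return clusters


def merge_clusters(runs: Sequence[Sequence[PiRNACluster]]) -> list[PiRNACluster]:
    """Union-merge overlapping accepted clusters from parameter re-runs.

    Overlapping intervals on the same contig are merged to their union span;
    per-library weights are taken as the per-library maximum over members (the
    runs re-count the same reads, so summing would double-count).
    """
    pool = sorted(
        (c for run in runs for c in run), key=lambda c: (c.contig, c.start, c.end)
    )
    merged: list[PiRNACluster] = []
    for c in pool:
        if merged and merged[-1].contig == c.contig and c.start < merged[-1].end:
            prev = merged[-1]
            prev.end = max(prev.end, c.end)
            for lib, w in c.weight_per_library.items():
                prev.weight_per_library[lib] = max(prev.weight_per_library.get(lib, 0.0), w)
            prev.expressed_in = sorted(set(prev.expressed_in) | set(c.expressed_in))
        else:
            merged.append(
                PiRNACluster(
                    c.id, c.contig, c.start, c.end, c.directionality, c.metrics,
                    dict(c.weight_per_library), list(c.expressed_in), c.b_candidate,
                )
            )
    return merged


# ---------------------------------------------------------------------------
# output


def clusters_to_frame(clusters: Sequence[PiRNACluster]) -> pd.DataFrame:
    """Cluster table with 1-based inclusive coordinates for human-facing reports."""
    rows = []
    for c in clusters:
        row = {
            "id": c.id,
            "contig": c.contig,
            "start": c.start + 1,
            "end": c.end,
            "size": c.size,
            "directionality": c.directionality,
            "frac_1u10a": round(c.metrics.frac_1u10a, 6),
            "frac_typical_len": round(c.metrics.frac_typical_len, 6),
            "main_strand_fraction": round(c.metrics.main_strand_fraction, 6),
            "n_tags": c.metrics.n_tags,
            "expressed_in": ",".join(c.expressed_in),
        }
        if c.b_candidate is not None:
            row["b_candidate"] = c.b_candidate
        for lib, w in sorted(c.weight_per_library.items()):
            row[f"weight_{lib}"] = round(w, 3)
        rows.append(row)
    return pd.DataFrame(rows)


def write_cluster_table(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    clusters_to_frame(clusters).to_csv(path, sep="\t", index=False)


def write_cluster_bed(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in clusters:
            strand = {"mono:+": "+", "mono:-": "-"}.get(c.directionality, ".")
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.id}\t0\t{strand}\n")


def write_cluster_gff3(clusters: Sequence[PiRNACluster], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for c in clusters:
            strand = {"mono:+": "+", "mono:-": "-"}.get(c.directionality, ".")
            attrs = f"ID={c.id};directionality={c.directionality}"
            fh.write(
                f"{c.contig}\tcurupira\tpiRNA_cluster\t{c.start + 1}\t{c.end}\t.\t"
                f"{strand}\t.\t{attrs}\n"
            )
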