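"""TE annotation, Kimura two-parameter divergence, and repeat landscapes.

The age structure of transposable-element invasions is summarized by the
"repeat landscape": every TE copy's divergence from its family consensus is
expressed as the Kimura (1980) two-parameter distance

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

with p the transition and q the transversion proportion, and copies are
binned by K (percent) with their aligned bp as mass.  Recent invasions pile
up near K = 0; anciently degenerate families sit in high bins.  Comparing
the landscapes of B-lacking and B-carrying assemblies highlights family/bin
combinations where B-resident copies amplified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from ._sequtil import is_transition
from .mapping import TagHit

MAJOR_CLASSES = ("DNA", "LINE", "SINE", "LTR")


class DivergenceDomainError(ValueError):
    """Raised when (p, q) lie outside the Kimura model's domain."""


@dataclass(frozen=True)
class TEAnnotation:
    contig: str
    start: int  # 0-based half-open
    end: int
    strand: str
    repeat_name: str
    class_subclass: str  # e.g. "DNA/hAT-Ac", "LINE/L2"
    divergence_pct: float

    @property
    def major_class(self) -> str:
        head = self.class_subclass.split("/")[0]
        return head if head in MAJOR_CLASSES else "Other"


@dataclass(frozen=True)
class KimuraEstimate:
    p: float
    q: float
    K: float
    n_sites: int
    cpg_excluded: bool = False


def parse_repeatmasker_out(path: str | Path) -> list[TEAnnotation]:
    """Parse a RepeatMasker .out file (3 header lines, whitespace columns).

    Coordinates are converted from 1-based inclusive to 0-based half-open and
    the 'C' (complement) orientation becomes strand '-'.
    """
    annotations = []
    with open(path) as fh:
        lines = fh.readlines()
    for lineno, line in enumerate(lines[3:], start=4):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) < 14:
            raise ValueError(
                f"{path}:{lineno}: expected >= 14 whitespace-separated columns, "
                f"got {len(fields)}"
            )
        try:
            div = float(fields[1])
            start = int(fields[5])
            end = int(fields[6])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed numeric column: {exc}") from exc
        strand = "-" if fields[8] == "C" else "+"
        annotations.append(
            TEAnnotation(
                contig=fields[4],
                start=start - 1,
                end=end,
                strand=strand,
                repeat_name=fields[9],
                class_subclass=fields[10],
                divergence_pct=div,
            )
        )
    return annotations


def classify_pirna_te(
    hits: Iterable[TagHit], annotations: Sequence[TEAnnotation]
) -> pd.DataFrame:
    """Fraction of per-library piRNA mass overlapping each major TE class.

    Each placement is assigned to the overlapping annotation with the largest
    overlap (ties broken by leftmost annotation start); placements overlapping
    nothing count as ``non-TE``.  Percentages are of total piRNA mass per
    library, so TE-class percentages sum to <= 100.
    """
    trees: dict[str, IntervalTree] = {}
    for a in annotations:
        trees.setdefault(a.contig, IntervalTree()).addi(a.start, a.end, a)
    mass: dict[tuple[str, str], float] = {}
    totals: dict[str, float] = {}
    for h in hits:
        tree = trees.get(h.contig)
        best = None
        if tree is not None:
            best_key = None
            for iv in tree.overlap(h.start, h.end):
                ov = min(h.end, iv.end) - max(h.start, iv.begin)
                key = (-ov, iv.data.start)
                if best_key is None or key < best_key:
                    best_key, best = key, iv.data
        te_class = best.major_class if best is not None else "non-TE"
        for lib in h.tag.counts:
            w = h.library_weight(lib)
            totals[lib] = totals.get(lib, 0.0) + w
            mass[(lib, te_class)] = mass.get((lib, te_class), 0.0) + w
    rows = [
        {
            "library": lib,
            "te_class": te_class,
            "percent": 100.0 * m / totals[lib],
        }
        for (lib, te_class), m in sorted(mass.items())
    ]
    return pd.DataFrame(rows, columns=["library", "te_class", "percent"])


def kimura2p(p: float, q: float) -> float:
    """Kimura two-parameter distance K = -1/2 ln((1-2p-q) sqrt(1-2q)).

    Valid for 1-2p-q > 0 and 1-2q > 0; beyond that the observed divergence
    saturates the model and a :class:`DivergenceDomainError` is raised.
    """
    if p < 0 or q < 0:
        raise DivergenceDomainError("p and q must be non-negative")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise DivergenceDomainError("divergence beyond model domain")
    return -0.5 * math.log(a * math.sqrt(b))


def alignment_divergence(
    copy: str, consensus: str, exclude_cpg: bool = False
) -> KimuraEstimate:
    """Counted transition/transversion proportions of an aligned pair, plus K.

    The two sequences must be the same (aligned) length; columns where either
    side is a gap are stripped pairwise before counting, and only positions
    where both bases are in ACGT contribute to ``n_sites``.  With
    ``exclude_cpg`` the positions of CpG dinucleotides in the (gap-stripped)
    consensus are masked out, approximating the conventional CpG-aware
    landscape calculation by exclusion rather than reweighting.
    """
    if len(copy) != len(consensus):
        raise ValueError("aligned pair must have equal lengths")
    pairs = [
        (c.upper(), k.upper())
        for c, k in zip(copy, consensus)
        if c not in "-." and k not in "-."
    ]
    if exclude_cpg:
        skip = set()
        cons = [k for _, k in pairs]
        for i in range(len(cons) - 1):
            if cons[i] == "C" and cons[i + 1] == "G":
                skip.add(i)
                skip.add(i + 1)
        pairs = [pq for i, pq in enumerate(pairs) if i not in skip]
    usable = [(c, k) for c, k in pairs if c in "ACGT" and k in "ACGT"]
    n = len(usable)
    if n == 0:
        raise ValueError("no usable aligned sites")
    ts = sum(1 for c, k in usable if c != k and is_transition(c, k))
    tv = sum(1 for c, k in usable if c != k and not is_transition(c, k))
    p, q = ts / n, tv / n
    return KimuraEstimate(p=p, q=q, K=kimura2p(p, q), n_sites=n, cpg_excluded=exclude_cpg)


def landscape(
    estimates: Iterable[tuple[str, KimuraEstimate, int]],
    bin_width: int = 1,
    max_bin: int = 50,
) -> pd.DataFrame:
    """Bin copies by Kimura distance (percent) into a (family, bin, bp) table.

    Each copy contributes its aligned bp to bin ``floor(100 * K)`` (labelled by
    the bin's lower edge, clamped at ``max_bin``), so summed bp over bins
    equals summed copy lengths exactly.
    """
    mass: dict[tuple[str, int], int] = {}
    for family, est, length in estimates:
        b = int(100.0 * est.K // bin_width) * bin_width
        b = min(b, max_bin)
        mass[(family, b)] = mass.get((family, b), 0) + length
    rows = [
        {"family": fam, "bin": b, "bp": bp} for (fam, b), bp in sorted(mass.items())
    ]
    return pd.DataFrame(rows, columns=["family", "bin", "bp"])


def landscape_from_annotations(
    annotations: Sequence[TEAnnotation], bin_width: int = 1, max_bin: int = 50
) -> pd.DataFrame:
    """Landscape built directly from the divergence column of a .out file.

    The annotation's percent divergence is trusted as-is (binned directly);
    family labels are the class/subclass strings.
    """
    mass: dict[tuple[str, int], int] = {}
    for a in annotations:
        b = int(a.divergence_pct // bin_width) * bin_width
        b = min(b, max_bin)
        key = (a.class_subclass, b)
        mass[key] = mass.get(key, 0) + (a.end - a.start)
    rows = [
        {"family": fam, "bin": b, "bp": bp} for (fam, b), bp in sorted(mass.items())
    ]
    return pd.DataFrame(rows, columns=["family", "bin", "bp"])


def compare_landscapes(
    b_minus: pd.DataFrame,
    b_plus: pd.DataFrame,
    fold: float = 1.5,
    min_bp: int = 50,
) -> pd.DataFrame:
    """Per-family, per-bin difference between two landscapes (B+ minus B-).

    Each landscape is normalized to its total bp before differencing, so the
    comparison is robust to assembly-size differences.  A bin is flagged when
    the normalized B+ mass exceeds ``fold`` times the normalized B- mass and
    the raw B+ mass reaches ``min_bp`` aligned bp (small-noise floor).
    """
    for df in (b_minus, b_plus):
        if not {"family", "bin", "bp"}.issubset(df.columns):
            raise ValueError("landscape tables need columns family, bin, bp")
    bins_bm = set(b_minus["bin"]) if len(b_minus) else set()
    bins_bp = set(b_plus["bin"]) if len(b_plus) else set()
    widths = {w for b in (bins_bm, bins_bp) if len(b) > 1 for w in {_gcd_step(sorted(b))}}
    if len(widths) > 1:
        raise ValueError("landscapes use different binnings")
    tot_bm = b_minus["bp"].sum() or 1
    tot_bp = b_plus["bp"].sum() or 1
    bm = {(r.family, r.bin): r.bp for r in b_minus.itertuples()}
    bp = {(r.family, r.bin): r.bp for r in b_plus.itertuples()}
    rows = []
    for key in sorted(set(bm) | set(bp)):
        fam, b = key
        m_bm = bm.get(key, 0) / tot_bm
        m_bp = bp.get(key, 0) / tot_bp
        rows.append(
            {
                "family": fam,
                "bin": b,
                "norm_bminus": m_bm,
                "norm_bplus": m_bp,
                "difference": m_bp - m_bm,
                "flagged": bool(m_bp > fold * m_bm and bp.get(key, 0) >= min_bp),
            }
        )
    return pd.DataFrame(
        rows, columns=["family", "bin", "norm_bminus", "norm_bplus", "difference", "flagged"]
    )


def _gcd_step(sorted_bins: list[int]) -> int:
    step = 0
    for a, b in zip(sorted_bins, sorted_bins[1:]):
        step = math.gcd(step, b - a)
    return step or 1
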