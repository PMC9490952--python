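"""Synthetic genomes, small-RNA libraries and whole-genome read sets with ground truth.

This module emulates the data layout of a gonadal small-RNA study of a fish
population segregating a supernumerary (B) chromosome:

* a contig-level genome assembly in which some contigs are "B-resident",
  i.e. present in extra copies in B-carrying (B+) individuals;
* planted piRNA clusters (mono- or bidirectional, with 5'U / 10A base biases)
  and planted miRNA loci;
* transposable-element copies mutated away from a consensus at controlled
  transition/transversion rates;
* four gonadal small-RNA libraries (FB-, FB+, MB-, MB+) and B-/B+ WGS read
  sets in which B-resident contigs show elevated depth and carry B-specific
  SNP alleles.

Everything is driven by explicit integer seeds; the same arguments and seed
produce byte-identical output files.  Ground truth is carried in
:class:`GenomeTruth` and can be round-tripped through plain-text BED/TSV files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._sequtil import TRANSITION, TRANSVERSIONS, revcomp

BASES = np.array(list("ACGT"))

GROUPS = ("FB-", "FB+", "MB-", "MB+")

DIRECTIONALITIES = ("mono:+", "mono:-", "bi")

#: default piRNA-read length profile: peak at 28-29 nt, support 26-31 nt
DEFAULT_LENGTH_PROFILE = {26: 0.08, 27: 0.15, 28: 0.27, 29: 0.27, 30: 0.15, 31: 0.08}


def normalize_group(group: str) -> str:
    """Map a library label onto the canonical FB-/FB+/MB-/MB+ spelling.

    Accepts the typographic minus sign often used in print ("FB−").
    """
    g = group.replace("−", "-").replace("–", "-").upper()
    if g not in GROUPS:
        raise ValueError(f"unknown library group {group!r}; expected one of {GROUPS}")
    return g


@dataclass(frozen=True)
class PlantedCluster:
    """A planted piRNA cluster interval with its transcriptional parameters.

    ``strand_fraction`` is the fraction of reads drawn from the main strand
    (the '+' strand for mono:+ and bi, the '-' strand for mono:-).
    ``b_exclusive`` marks clusters that exist only on the B chromosome and
    therefore must never yield reads in B- libraries.
    """

    contig: str
    start: int
    end: int
    directionality: str = "mono:+"
    strand_fraction: float = 0.95
    u1_prob: float = 0.9
    a10_prob: float = 0.5
    b_exclusive: bool = False

    def __post_init__(self) -> None:
        if self.directionality not in DIRECTIONALITIES:
            raise ValueError(f"directionality must be one of {DIRECTIONALITIES}")
        if not 0.5 <= self.strand_fraction <= 1.0:
            raise ValueError("strand_fraction must lie in [0.5, 1]")

    @property
    def main_strand(self) -> str:
        return "-" if self.directionality == "mono:-" else "+"

    @property
    def strands(self) -> tuple[str, ...]:
        if self.directionality == "bi":
            return ("+", "-")
        return (self.main_strand,)


@dataclass(frozen=True)
class PlantedMirna:
    contig: str
    start: int
    end: int
    strand: str = "+"


@dataclass(frozen=True)
class PlantedTECopy:
    """A TE copy inserted into the genome, mutated away from its consensus."""

    contig: str
    start: int
    end: int
    family: str
    subclass: str
    p: float  # realized transition proportion
    q: float  # realized transversion proportion


@dataclass(frozen=True)
class BSpecificSNP:
    contig: str
    position: int  # 0-based
    ref: str
    alt: str


@dataclass
class GenomeTruth:
    """A synthetic genome plus every planted feature, fully determined by a seed."""

    sequences: dict[str, str]
    planted_clusters: list[PlantedCluster] = field(default_factory=list)
    planted_mirnas: list[PlantedMirna] = field(default_factory=list)
    te_copies: list[PlantedTECopy] = field(default_factory=list)
    copy_multiplier: dict[str, float] = field(default_factory=dict)
    b_specific_snps: list[BSpecificSNP] = field(default_factory=list)
    seed: int = 0

    @property
    def contigs(self) -> list[tuple[str, int]]:
        return [(name, len(seq)) for name, seq in self.sequences.items()]

    def multiplier(self, contig: str) -> float:
        return self.copy_multiplier.get(contig, 1.0)

    def validate(self) -> None:
        for name, m in self.copy_multiplier.items():
            if m < 1:
                raise ValueError(f"copy multiplier for {name} must be >= 1, got {m}")
        for c in self.planted_clusters + self.planted_mirnas + self.te_copies:
            if c.contig not in self.sequences:
                raise ValueError(f"planted feature on unknown contig {c.contig!r}")
            L = len(self.sequences[c.contig])
            if not (0 <= c.start < c.end <= L):
                raise ValueError(
                    f"interval {c.contig}:{c.start}-{c.end} outside contig bounds (length {L})"
                )
        # planted clusters may not overlap on a shared strand
        by_contig: dict[str, list[PlantedCluster]] = {}
        for cl in self.planted_clusters:
            by_contig.setdefault(cl.contig, []).append(cl)
        for cls in by_contig.values():
            cls.sort(key=lambda c: c.start)
            for a, b in zip(cls, cls[1:]):
                if b.start < a.end and set(a.strands) & set(b.strands):
                    raise ValueError(
                        f"planted clusters overlap on the same strand: "
                        f"{a.contig}:{a.start}-{a.end} and {b.contig}:{b.start}-{b.end}"
                    )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=length)])


def mutate_te_copy(
    consensus: str, p_target: float, q_target: float, seed: int
) -> tuple[str, float, float]:
    """Mutate a TE consensus to a diverged copy with exact substitution counts.

    ``round(p_target * n)`` sites receive a transition and ``round(q_target * n)``
    distinct sites a transversion, with no back-mutation (each site is hit at
    most once), so the realized proportions returned are the exact counted
    proportions of differing sites.

    Returns ``(mutated_sequence, realized_p, realized_q)``.
    """
    n = len(consensus)
    if n < 50:
        raise ValueError(f"consensus too short for divergence simulation ({n} < 50 bp)")
    if p_target < 0 or q_target < 0 or p_target + q_target >= 0.75:
        raise ValueError("require p_target, q_target >= 0 and p_target + q_target < 0.75")
    n_ts = int(round(p_target * n))
    n_tv = int(round(q_target * n))
    rng = np.random.default_rng(seed)
    sites = rng.choice(n, size=n_ts + n_tv, replace=False)
    seq = list(consensus.upper())
    for i in sites[:n_ts]:
        seq[i] = TRANSITION[seq[i]]
    for i in sites[n_ts:]:
        seq[i] = TRANSVERSIONS[seq[i]][rng.integers(0, 2)]
    return "".join(seq), n_ts / n, n_tv / n


def simulate_genome(
    n_contigs: int,
    contig_length: int,
    te_library: Mapping[str, str] | None = None,
    cluster_spec: Sequence[PlantedCluster | dict] = (),
    b_contigs: Mapping[str, float] | None = None,
    seed: int = 0,
    *,
    mirna_spec: Sequence[PlantedMirna | dict] = (),
    te_spec: Sequence[dict] = (),
    snps_per_b_contig: int = 0,
) -> GenomeTruth:
    """Build a random ACGT genome with planted features and known ground truth.

    Parameters
    ----------
    n_contigs, contig_length
        Number of contigs (named ``contig_1`` ...) and their common length.
    te_library
        Map family name -> consensus sequence; required when ``te_spec``
        requests planted copies.
    cluster_spec, mirna_spec
        Planted piRNA cluster / miRNA locus descriptions (dataclass instances
        or dicts of their fields).
    te_spec
        Dicts with keys ``contig, start, family, subclass, p, q``; each plants
        one mutated consensus copy (the genome slice is overwritten).
    b_contigs
        Map contig name -> copy multiplier (>= 2 for B-resident contigs).
    snps_per_b_contig
        Number of random B-specific SNPs planted on every contig with
        multiplier >= 2.
    """
    rng = np.random.default_rng(seed)
    names = [f"contig_{i + 1}" for i in range(n_contigs)]
    sequences = {name: _random_sequence(rng, contig_length) for name in names}

    clusters = [c if isinstance(c, PlantedCluster) else PlantedCluster(**c) for c in cluster_spec]
    mirnas = [m if isinstance(m, PlantedMirna) else PlantedMirna(**m) for m in mirna_spec]

    te_copies: list[PlantedTECopy] = []
    if te_spec:
        if not te_library:
            raise ValueError("te_spec given but te_library is empty")
        for spec in te_spec:
            fam = spec["family"]
            consensus = te_library[fam]
            sub_seed = int(rng.integers(0, 2**31 - 1))
            mutated, p, q = mutate_te_copy(consensus, spec["p"], spec["q"], sub_seed)
            contig, start = spec["contig"], spec["start"]
            end = start + len(mutated)
            if end > len(sequences[contig]):
                raise ValueError(f"TE copy {fam} at {contig}:{start} exceeds contig bounds")
            s = sequences[contig]
            sequences[contig] = s[:start] + mutated + s[end:]
            te_copies.append(
                PlantedTECopy(contig, start, end, fam, spec.get("subclass", fam), p, q)
            )

    multipliers = {name: 1.0 for name in names}
    if b_contigs:
        for name, m in b_contigs.items():
            if name not in multipliers:
                raise ValueError(f"b_contigs names unknown contig {name!r}")
            multipliers[name] = float(m)

    snps: list[BSpecificSNP] = []
    if snps_per_b_contig:
        for name in names:
            if multipliers[name] < 2:
                continue
            # SNP sites are kept >= 300 bp apart so no typical short read
            # spans two of them (keeps single-mismatch placement exact)
            grid = np.arange(200, len(sequences[name]) - 200, 300)
            positions = sorted(rng.choice(grid, size=snps_per_b_contig, replace=False))
            for pos in positions:
                ref = sequences[name][pos]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
                snps.append(BSpecificSNP(name, int(pos), ref, alt))

    truth = GenomeTruth(
        sequences=sequences,
        planted_clusters=clusters,
        planted_mirnas=mirnas,
        te_copies=te_copies,
        copy_multiplier=multipliers,
        b_specific_snps=snps,
        seed=seed,
    )
    truth.validate()
    return truth


# ---------------------------------------------------------------------------
# small-RNA library simulation


def _draw_lengths(rng: np.random.Generator, profile: Mapping[int, float], n: int) -> np.ndarray:
    lengths = np.array(sorted(profile))
    probs = np.array([profile[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(lengths, size=n, p=probs)


def _read_from(seq: str, start: int, length: int, strand: str) -> str:
    frag = seq[start : start + length]
    return revcomp(frag) if strand == "-" else frag


def _biased_cluster_read(
    rng: np.random.Generator,
    seq: str,
    cluster: PlantedCluster,
    strand: str,
    length: int,
    want_u: bool,
    want_a: bool,
    max_tries: int = 300,
) -> tuple[int, str]:
    """Pick a start position whose genomic sequence satisfies the requested biases.

    Base biases are realized by position choice (rejection sampling), never by
    editing bases, so every simulated read is an exact genomic substring and
    maps back at zero mismatches.
    """
    lo, hi = cluster.start, cluster.end - length
    read = ""
    start = lo
    for _ in range(max_tries):
        start = int(rng.integers(lo, hi + 1))
        read = _read_from(seq, start, length, strand)
        if want_u and read[0] != "T":
            continue
        if want_a and length >= 10 and read[9] != "A":
            continue
        return start, read
    return start, read  # bias unsatisfiable in this window; accept last draw


def simulate_srna_library(
    truth: GenomeTruth,
    group: str,
    n_reads: int,
    length_profile: Mapping[int, float] | None = None,
    u1_prob: float = 0.9,
    a10_prob: float = 0.5,
    noise_frac: float = 0.05,
    seed: int = 0,
    *,
    mirna_frac: float = 0.25,
) -> list[tuple[str, str]]:
    """Simulate one gonadal small-RNA library as ``(read_id, sequence)`` records.

    Reads are a mixture of piRNA-cluster fragments (lengths from
    ``length_profile``, default peaking at 28-29 nt), mature-miRNA reads of
    21-22 nt from planted miRNA loci, and ``noise_frac`` uniform-random genomic
    fragments.  B- groups never draw from clusters marked ``b_exclusive``.
    Read ids encode origin (``pirna``/``mirna``/``noise``) for downstream truth
    checks.
    """
    group = normalize_group(group)
    if not 0 <= u1_prob <= 1 or not 0 <= a10_prob <= 1:
        raise ValueError("u1_prob and a10_prob must lie in [0, 1]")
    if length_profile is None:
        length_profile = DEFAULT_LENGTH_PROFILE
    rng = np.random.default_rng(seed)

    b_plus = group.endswith("+")
    clusters = [c for c in truth.planted_clusters if b_plus or not c.b_exclusive]
    mirnas = truth.planted_mirnas
    names = list(truth.sequences)
    contig_lens = np.array([len(truth.sequences[n]) for n in names], dtype=float)

    n_noise = int(round(noise_frac * n_reads))
    n_mirna = int(round(mirna_frac * n_reads)) if mirnas else 0
    n_pirna = n_reads - n_noise - n_mirna
    if not clusters:
        n_noise += n_pirna
        n_pirna = 0

    records: list[tuple[str, str]] = []

    if n_pirna:
        weights = np.array([c.end - c.start for c in clusters], dtype=float)
        weights /= weights.sum()
        choices = rng.choice(len(clusters), size=n_pirna, p=weights)
        lengths = _draw_lengths(rng, length_profile, n_pirna)
        for i, (ci, length) in enumerate(zip(choices, lengths)):
            c = clusters[ci]
            length = int(min(length, c.end - c.start))
            if c.directionality == "bi":
                strand = "+" if rng.random() < 0.5 else "-"
            else:
                strand = c.main_strand if rng.random() < c.strand_fraction else (
                    "-" if c.main_strand == "+" else "+"
                )
            want_u = rng.random() < u1_prob
            want_a = rng.random() < a10_prob
            _, read = _biased_cluster_read(
                rng, truth.sequences[c.contig], c, strand, length, want_u, want_a
            )
            records.append((f"{group}:pirna:{i}", read))

    for i in range(n_mirna):
        m = mirnas[int(rng.integers(0, len(mirnas)))]
        length = int(min(21 + rng.integers(0, 2), m.end - m.start))
        if m.strand == "-":
            read = revcomp(truth.sequences[m.contig][m.end - length : m.end])
        else:
            read = truth.sequences[m.contig][m.start : m.start + length]
        records.append((f"{group}:mirna:{i}", read))

    if n_noise:
        lengths = _draw_lengths(rng, length_profile, n_noise)
        probs = contig_lens / contig_lens.sum()
        contig_idx = rng.choice(len(names), size=n_noise, p=probs)
        for i, (ci, length) in enumerate(zip(contig_idx, lengths)):
            seq = truth.sequences[names[ci]]
            start = int(rng.integers(0, len(seq) - int(length) + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            records.append((f"{group}:noise:{i}", _read_from(seq, start, int(length), strand)))

    return records


# ---------------------------------------------------------------------------
# WGS simulation


def simulate_wgs(
    truth: GenomeTruth,
    mean_depth: float,
    read_length: int = 100,
    b_status: str = "B-",
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, str]]:
    """Simulate single-end WGS reads as ``(read_id, sequence)`` records.

    For ``b_status='B+'`` the expected depth of a contig is
    ``mean_depth * copy_multiplier`` and reads covering a planted B-specific
    SNP carry the alt allele with frequency (m-1)/m for multiplier m — every
    B-resident copy descends from one founder carrying the alt.  For 'B-' the
    multipliers are ignored and only reference alleles are emitted.

    Read ids encode the true placement ``{b_status}:{contig}:{start}:{strand}``.
    """
    if mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    b_status = b_status.replace("−", "-").upper()
    if b_status not in ("B-", "B+"):
        raise ValueError(f"b_status must be 'B-' or 'B+', got {b_status!r}")
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    snps_by_contig: dict[str, list[BSpecificSNP]] = {}
    for s in truth.b_specific_snps:
        snps_by_contig.setdefault(s.contig, []).append(s)

    for name, seq in truth.sequences.items():
        L = len(seq)
        if L < read_length:
            continue
        mult = truth.multiplier(name) if b_status == "B+" else 1.0
        n = int(round(mean_depth * mult * L / read_length))
        starts = rng.integers(0, L - read_length + 1, size=n)
        strands = rng.random(n) < 0.5
        m = truth.multiplier(name)
        snps = snps_by_contig.get(name, [])
        emit_alt = b_status == "B+" and m >= 2 and snps
        b_origin = rng.random(n) < (m - 1) / m if emit_alt else np.zeros(n, bool)
        for i in range(n):
            start = int(starts[i])
            frag = seq[start : start + read_length]
            if emit_alt and b_origin[i]:
                for s in snps:
                    if start <= s.position < start + read_length:
                        off = s.position - start
                        frag = frag[:off] + s.alt + frag[off + 1 :]
            if error_rate > 0:
                frag = _add_errors(rng, frag, error_rate)
            strand = "-" if strands[i] else "+"
            if strand == "-":
                frag = revcomp(frag)
            records.append((f"{b_status}:{name}:{start}:{strand}:{i}", frag))
    return records


def _add_errors(rng: np.random.Generator, frag: str, rate: float) -> str:
    hits = np.flatnonzero(rng.random(len(frag)) < rate)
    if hits.size == 0:
        return frag
    chars = list(frag)
    for i in hits:
        chars[i] = str(rng.choice([b for b in "ACGT" if b != chars[i]]))
    return "".join(chars)


# ---------------------------------------------------------------------------
# plain-text output and truth round-trip


def write_fastq(records: Iterable[tuple[str, str]], path: str | Path) -> None:
    """Write records as Phred+33 FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_genome_fasta(truth: GenomeTruth, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in truth.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_truth(truth: GenomeTruth, outdir: str | Path) -> dict[str, Path]:
    """Write ground-truth BED6/TSV files; returns the paths keyed by content."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "clusters": outdir / "truth_clusters.bed",
        "mirnas": outdir / "truth_mirnas.bed",
        "te_copies": outdir / "truth_te_copies.bed",
        "multipliers": outdir / "truth_multipliers.tsv",
        "snps": outdir / "truth_snps.tsv",
    }
    with open(paths["clusters"], "w") as fh:
        for i, c in enumerate(truth.planted_clusters):
            strand = "." if c.directionality == "bi" else c.main_strand
            name = f"cluster_{i + 1}|{c.directionality}|b_exclusive={int(c.b_exclusive)}"
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{name}\t0\t{strand}\n")
    with open(paths["mirnas"], "w") as fh:
        for i, m in enumerate(truth.planted_mirnas):
            fh.write(f"{m.contig}\t{m.start}\t{m.end}\tmirna_{i + 1}\t0\t{m.strand}\n")
    with open(paths["te_copies"], "w") as fh:
        for i, t in enumerate(truth.te_copies):
            name = f"{t.family}|{t.subclass}|p={t.p:.6f}|q={t.q:.6f}"
            fh.write(f"{t.contig}\t{t.start}\t{t.end}\t{name}\t0\t+\n")
    with open(paths["multipliers"], "w") as fh:
        fh.write("contig\tmultiplier\n")
        for name, m in truth.copy_multiplier.items():
            fh.write(f"{name}\t{m:g}\n")
    with open(paths["snps"], "w") as fh:
        fh.write("contig\tpos_1based\tref\talt\n")
        for s in truth.b_specific_snps:
            fh.write(f"{s.contig}\t{s.position + 1}\t{s.ref}\t{s.alt}\n")
    return paths


def read_truth_clusters(path: str | Path) -> list[PlantedCluster]:
    """Parse a truth cluster BED back into planted-cluster records.

    Only the fields encoded in the BED survive the round trip (coordinates,
    directionality, B-exclusivity); probabilities default.
    """
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, name, _score, _strand = line.rstrip("\n").split("\t")
            _, directionality, bexcl = name.split("|")
            out.append(
                PlantedCluster(
                    contig,
                    int(start),
                    int(end),
                    directionality=directionality,
                    b_exclusive=bool(int(bexcl.split("=")[1])),
                )
            )
    return out


def read_truth_mirnas(path: str | Path) -> list[PlantedMirna]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            contig, start, end, _name, _score, strand = line.rstrip("\n").split("\t")
            out.append(PlantedMirna(contig, int(start), int(end), strand))
    return out
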