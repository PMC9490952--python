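"""End-to-end orchestration: simulate -> preprocess -> map -> call -> locate -> profile.

The pipeline runs the whole analysis on a synthetic study whose layout mirrors
the biological design: a contig-level assembly, planted mono- and
bidirectional piRNA clusters (two of them B-exclusive on high-copy contigs),
planted miRNA loci, TE copies at controlled divergence, four gonadal
small-RNA libraries and B-/B+ WGS read sets.  Every stage writes a re-loadable
plain-text table under the output directory and all randomness derives from
one seed, so identical configs reproduce identical outputs byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from itertools import chain
from pathlib import Path

from . import blocate, clustercall, coloc, mapping, preprocess, quant, simdata, telandscape
from .simdata import GenomeTruth, PlantedCluster, PlantedMirna


@dataclass
class RunConfig:
    """Flat, fully-logged parameter set for a pipeline run."""

    outdir: str = "curupira_run"
    seed: int = 1
    # genome
    n_contigs: int = 10
    contig_length: int = 50_000
    n_clusters: int = 5
    cluster_size: int = 2_000
    n_b_contigs: int = 2
    b_multiplier: float = 3.0
    snps_per_b_contig: int = 3
    n_mirnas: int = 6
    # small-RNA libraries
    srna_reads: int = 200_000
    u1_prob: float = 0.9
    a10_prob: float = 0.5
    noise_frac: float = 0.0
    mirna_frac: float = 0.25
    # WGS
    wgs_depth: float = 20.0
    wgs_read_length: int = 100
    wgs_error_rate: float = 0.0
    # preprocess
    min_len: int = 24
    max_len: int = 35
    # mapping
    max_mismatch: int = 0
    max_hits: int = 100
    # cluster calling
    max_gap: int = 500
    min_tags: int = 10
    min_weight: float = 20.0
    min_size: int = 1000
    min_frac_1u10a: float = 0.75
    min_frac_typical_len: float = 0.75
    min_expr: float = 5.0
    # B localization
    ratio_threshold: float = 2.0
    snp_min_depth: int = 5
    snp_min_alt_bplus: float = 0.2
    snp_max_alt_bminus: float = 0.02
    # qPCR stage
    qpcr_n_per_group: int = 8
    qpcr_noise_sd: float = 0.15
    qpcr_n_perm: int = 10_000


def load_config(path: str | Path) -> RunConfig:
    """Parse a flat ``key = value`` config file; unknown keys are rejected."""
    fields = {f.name: f for f in dataclasses.fields(RunConfig)}
    kwargs = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = (s.strip() for s in line.split("=", 1))
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            kwargs[key] = _coerce(value, fields[key].type)
    return RunConfig(**kwargs)


def _coerce(value: str, typ) -> object:
    name = typ if isinstance(typ, str) else typ.__name__
    if name == "int":
        return int(value)
    if name == "float":
        return float(value)
    return value


def default_te_library(config: RunConfig) -> dict[str, str]:
    """Three TE family consensus sequences (500 bp each), derived from the seed."""
    import numpy as np

    lib_rng = np.random.default_rng(config.seed + 11)
    return {
        fam: "".join(simdata.BASES[lib_rng.integers(0, 4, size=500)])
        for fam in ("PAO", "L2", "hAT")
    }


def default_truth(config: RunConfig) -> GenomeTruth:
    """Build the standard synthetic study genome for a config.

    Clusters are planted on the first ``n_clusters`` contigs with
    directionalities cycling mono:+, mono:-, mono:+, bi, bi...; the last
    ``n_b_contigs`` clustered contigs get the B multiplier and their clusters
    are B-exclusive.  miRNA loci alternate between cluster-free contigs and
    positions inside clusters (so the colocalization stage sees both Venn
    classes).  Three TE families are planted at distinct divergence levels,
    with extra young copies on B contigs only.
    """
    n = config.n_contigs
    if config.n_clusters > n:
        raise ValueError("more clusters than contigs")
    directionality = ["mono:+", "mono:-", "mono:+", "bi", "bi"]
    b_first = config.n_clusters - config.n_b_contigs
    cluster_spec = []
    cluster_at = 20_000 % max(1, config.contig_length - config.cluster_size)
    for i in range(config.n_clusters):
        is_b = i >= b_first
        cluster_spec.append(
            PlantedCluster(
                contig=f"contig_{i + 1}",
                start=cluster_at,
                end=cluster_at + config.cluster_size,
                directionality=directionality[i % len(directionality)],
                strand_fraction=0.5 if directionality[i % len(directionality)] == "bi" else 0.95,
                u1_prob=config.u1_prob,
                a10_prob=config.a10_prob,
                b_exclusive=is_b,
            )
        )
    b_contigs = {
        f"contig_{i + 1}": config.b_multiplier
        for i in range(b_first, config.n_clusters)
    }

    mirna_spec = []
    mirna_at = min(40_000, config.contig_length - 100)
    for j in range(config.n_mirnas):
        if j % 2 == 0 and j // 2 < config.n_clusters:
            # inside a planted cluster -> a 'both-superposed' contig
            c = cluster_spec[j // 2]
            mirna_spec.append(PlantedMirna(c.contig, c.start + 200, c.start + 270, "+"))
        else:
            contig = f"contig_{config.n_clusters + 1 + (j % max(1, n - config.n_clusters))}"
            mirna_spec.append(PlantedMirna(contig, mirna_at, mirna_at + 70, "+"))

    te_library = default_te_library(config)
    subclass = {"PAO": "LTR/Pao", "L2": "LINE/L2", "hAT": "DNA/hAT-Ac"}
    divergence = {"PAO": (0.18, 0.09), "L2": (0.08, 0.04), "hAT": (0.02, 0.01)}
    te_spec = []
    for i in range(n):
        contig = f"contig_{i + 1}"
        for k, fam in enumerate(("PAO", "L2", "hAT")):
            p, q = divergence[fam]
            te_spec.append(
                {
                    "contig": contig,
                    "start": 5_000 + 600 * k,
                    "family": fam,
                    "subclass": subclass[fam],
                    "p": p,
                    "q": q,
                }
            )
        if contig in b_contigs:
            # extra young copies only on B-resident contigs
            for extra in range(2):
                te_spec.append(
                    {
                        "contig": contig,
                        "start": 8_000 + 600 * extra,
                        "family": "hAT",
                        "subclass": subclass["hAT"],
                        "p": 0.01,
                        "q": 0.005,
                    }
                )

    return simdata.simulate_genome(
        n_contigs=n,
        contig_length=config.contig_length,
        te_library=te_library,
        cluster_spec=cluster_spec,
        b_contigs=b_contigs,
        seed=config.seed,
        mirna_spec=mirna_spec,
        te_spec=te_spec,
        snps_per_b_contig=config.snps_per_b_contig,
    )


# ---------------------------------------------------------------------------


def evaluate_recovery(
    clusters: list[clustercall.PiRNACluster],
    truth: GenomeTruth,
    min_reciprocal: float = 0.8,
) -> dict:
    """Precision/recall of called clusters against planted truth.

    A call matches a planted cluster when both reciprocal overlaps
    (overlap/size_called and overlap/size_truth) reach ``min_reciprocal``.
    Directionality accuracy is computed over matched pairs.
    """
    matched_calls = set()
    matched_truth = 0
    directionality_ok = 0
    for t in truth.planted_clusters:
        best = None
        for i, c in enumerate(clusters):
            if i in matched_calls or c.contig != t.contig:
                continue
            ov = max(0, min(c.end, t.end) - max(c.start, t.start))
            if ov / c.size >= min_reciprocal and ov / (t.end - t.start) >= min_reciprocal:
                best = i
                break
        if best is not None:
            matched_calls.add(best)
            matched_truth += 1
            if clusters[best].directionality == t.directionality:
                directionality_ok += 1
    n_called = len(clusters)
    n_truth = len(truth.planted_clusters)
    return {
        "n_called": n_called,
        "n_truth": n_truth,
        "precision": len(matched_calls) / n_called if n_called else 0.0,
        "recall": matched_truth / n_truth if n_truth else 0.0,
        "directionality_accuracy": (
            directionality_ok / matched_truth if matched_truth else 0.0
        ),
    }


def run_all(config: RunConfig) -> dict:
    """Execute every stage, writing tables under ``config.outdir``.

    Returns a result bundle with the in-memory objects and output paths.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines = [f"{f.name} = {getattr(config, f.name)}" for f in dataclasses.fields(RunConfig)]

    def _stage(name):
        log_lines.append(f"stage: {name}")

    try:
        _stage("simulate")
        truth = default_truth(config)
        simdata.write_genome_fasta(truth, out / "genome.fasta")
        simdata.write_truth(truth, out)
        libraries = {}
        for i, group in enumerate(simdata.GROUPS):
            recs = simdata.simulate_srna_library(
                truth,
                group,
                config.srna_reads,
                u1_prob=config.u1_prob,
                a10_prob=config.a10_prob,
                noise_frac=config.noise_frac,
                mirna_frac=config.mirna_frac,
                seed=config.seed + 100 + i,
            )
            path = out / f"srna_{group.replace('+', 'plus').replace('-', 'minus')}.fastq"
            simdata.write_fastq(recs, path)
            libraries[group] = (path, recs)
        wgs = {}
        for i, b_status in enumerate(("B-", "B+")):
            recs = simdata.simulate_wgs(
                truth,
                config.wgs_depth,
                read_length=config.wgs_read_length,
                b_status=b_status,
                error_rate=config.wgs_error_rate,
                seed=config.seed + 200 + i,
            )
            path = out / f"wgs_{b_status.replace('+', 'plus').replace('-', 'minus')}.fastq"
            simdata.write_fastq(recs, path)
            wgs[b_status] = recs

        _stage("preprocess")
        reads = chain.from_iterable(
            (preprocess.SmallRNARead(rid, seq, group) for rid, seq in recs)
            for group, (_path, recs) in libraries.items()
        )
        filtered = preprocess.length_filter(reads, config.min_len, config.max_len)
        tags = preprocess.collapse(filtered)
        preprocess.write_tags(tags, out / "tags.fasta", out / "tag_counts.tsv")
        hist = preprocess.length_histogram(
            preprocess.SmallRNARead(rid, seq, group)
            for group, (_path, recs) in libraries.items()
            for rid, seq in recs
        )
        hist.to_csv(out / "length_histogram.tsv", sep="\t", index=False)

        _stage("map")
        index = mapping.build_index(truth.sequences)
        result = mapping.map_tags(tags, index, config.max_mismatch, config.max_hits)
        mapping.write_sam(result.hits, index, out / "tag_hits.sam")

        _stage("callclusters")
        clusters = clustercall.call_clusters(
            result.hits,
            max_gap=config.max_gap,
            min_tags=config.min_tags,
            min_weight=config.min_weight,
            min_size=config.min_size,
            min_frac_1u10a=config.min_frac_1u10a,
            min_frac_typical_len=config.min_frac_typical_len,
            min_expr=config.min_expr,
        )

        _stage("blocate")
        contig_lengths = {name: len(seq) for name, seq in truth.sequences.items()}
        aligned = {b: blocate.align_wgs(recs, index) for b, recs in wgs.items()}
        tracks = {
            b: blocate.depth_tracks(al, contig_lengths, b) for b, al in aligned.items()
        }
        records = blocate.coverage_ratios(
            tracks["B+"], tracks["B-"], config.ratio_threshold
        )
        blocate.ratio_table(records).to_csv(out / "coverage_ratio.tsv", sep="\t", index=False)
        blocate.flag_b_intervals(records, clusters, threshold=config.ratio_threshold)
        clustercall.write_cluster_table(clusters, out / "clusters.tsv")
        clustercall.write_cluster_bed(clusters, out / "clusters.bed")
        clustercall.write_cluster_gff3(clusters, out / "clusters.gff3")
        piles = {
            b: blocate.pileups(al, contig_lengths) for b, al in aligned.items()
        }
        variants = blocate.b_specific_variants(
            piles["B-"],
            piles["B+"],
            truth.sequences,
            min_depth=config.snp_min_depth,
            min_alt_bplus=config.snp_min_alt_bplus,
            max_alt_bminus=config.snp_max_alt_bminus,
        )
        variants.to_csv(out / "b_specific_sites.tsv", sep="\t", index=False)

        _stage("telandscape")
        te_library = default_te_library(config)
        estimates = []
        for copy in truth.te_copies:
            seq = truth.sequences[copy.contig][copy.start : copy.end]
            est = telandscape.alignment_divergence(seq, te_library[copy.family])
            estimates.append((copy, est))
        land_bm = telandscape.landscape(
            (c.family, e, c.end - c.start)
            for c, e in estimates
            if truth.multiplier(c.contig) == 1
        )
        land_bp = telandscape.landscape(
            (c.family, e, c.end - c.start) for c, e in estimates
        )
        land_bm.to_csv(out / "landscape_bminus.tsv", sep="\t", index=False)
        land_bp.to_csv(out / "landscape_bplus.tsv", sep="\t", index=False)
        diff = telandscape.compare_landscapes(land_bm, land_bp)
        diff.to_csv(out / "landscape_compare.tsv", sep="\t", index=False)
        annotations = [
            telandscape.TEAnnotation(
                c.contig, c.start, c.end, "+", c.family, c.subclass, 100 * e.K
            )
            for c, e in estimates
        ]
        profile = telandscape.classify_pirna_te(result.hits, annotations)
        profile.to_csv(out / "pirna_te_profile.tsv", sep="\t", index=False)

        _stage("coloc")
        mirna_ivals = [
            coloc.GenomicInterval(m.contig, m.start, m.end, m.strand, f"mirna_{i}")
            for i, m in enumerate(truth.planted_mirnas)
        ]
        table, venn = coloc.coloc_table(mirna_ivals, clusters)
        table.to_csv(out / "coloc.tsv", sep="\t", index=False)
        (out / "venn_counts.json").write_text(json.dumps(venn, indent=2) + "\n")

        _stage("quant")
        cq = quant.simulate_cq_table(
            n_per_group=config.qpcr_n_per_group,
            noise_sd=config.qpcr_noise_sd,
            seed=config.seed + 300,
        )
        cq.to_csv(out / "cq_table.tsv", sep="\t", index=False)
        gdr = quant.gene_dose_ratio(cq, "pld6", "hprt1")
        gdr.to_csv(out / "gdr.tsv", sep="\t", index=False, float_format="%.6f")
        p_b = quant.permutation_test(
            gdr["gdr"].to_numpy(),
            gdr["b_status"].to_numpy(),
            n_perm=config.qpcr_n_perm,
            seed=config.seed + 301,
        )
        (out / "gdr_pvalue.json").write_text(
            json.dumps({"gdr_permutation_p": p_b}, indent=2) + "\n"
        )

        recovery = evaluate_recovery(clusters, truth)
        (out / "recovery.json").write_text(json.dumps(recovery, indent=2) + "\n")
    except Exception as exc:
        stage = next(
            (l.split(": ")[1] for l in reversed(log_lines) if l.startswith("stage: ")),
            "config",
        )
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    for path in sorted(out.iterdir()):
        if path.is_file() and path.suffix in (".tsv", ".bed", ".gff3", ".fasta", ".fastq", ".sam", ".json"):
            digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
            log_lines.append(f"sha256:{digest}  {path.name}")
    (out / "run_log.txt").write_text("\n".join(log_lines) + "\n")

    return {
        "truth": truth,
        "tags": tags,
        "hits": result.hits,
        "clusters": clusters,
        "ratio_records": records,
        "variants": variants,
        "landscapes": (land_bm, land_bp, diff),
        "coloc": (table, venn),
        "gdr": gdr,
        "gdr_pvalue": p_b,
        "recovery": recovery,
        "outdir": out,
    }
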