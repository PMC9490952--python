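"""Length filtering and collapsing of small-RNA reads into unique sequence tags."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

PIRNA_MIN_LEN = 24
PIRNA_MAX_LEN = 35


@dataclass(frozen=True)
class SmallRNARead:
    id: str
    sequence: str
    library: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __len__(self) -> int:
        return len(self.sequence)


def read_fastq(path: str | Path, library: str) -> Iterator[SmallRNARead]:
    """Stream a FASTQ file as reads labelled with their library of origin."""
    with open(path) as fh:
        for rid, seq, _qual in FastqGeneralIterator(fh):
            yield SmallRNARead(rid.split()[0], seq.upper().replace("U", "T"), library)


def length_filter(
    reads: Iterable[SmallRNARead],
    min_len: int = PIRNA_MIN_LEN,
    max_len: int = PIRNA_MAX_LEN,
) -> Iterator[SmallRNARead]:
    """Keep reads with min_len <= length <= max_len (24-35 nt selects mature piRNAs)."""
    if min_len > max_len:
        raise ValueError("min_len must not exceed max_len")
    for r in reads:
        if min_len <= r.length <= max_len:
            yield r


def trim_adapter(reads: Iterable[SmallRNARead], adapter: str) -> Iterator[SmallRNARead]:
    """Trim an exact 3' adapter match (first occurrence) when one is supplied."""
    adapter = adapter.upper().replace("U", "T")
    for r in reads:
        i = r.sequence.find(adapter)
        if i >= 0:
            r = SmallRNARead(r.id, r.sequence[:i], r.library)
        yield r


def collapse(reads: Iterable[SmallRNARead]) -> list[SequenceTag]:
    """Collapse reads into unique sequence tags with per-library counts.

    Reads containing N are discarded (tag identity must be unambiguous);
    U was already normalized to T on input.  The sum of tag totals equals the
    number of N-free input reads.
    """
    tags: dict[str, SequenceTag] = {}
    for r in reads:
        if "N" in r.sequence:
            continue
        tag = tags.get(r.sequence)
        if tag is None:
            tag = tags[r.sequence] = SequenceTag(r.sequence)
        tag.counts[r.library] = tag.counts.get(r.library, 0) + 1
    return list(tags.values())


def length_histogram(reads: Iterable[SmallRNARead]) -> pd.DataFrame:
    """Per-library read-length histogram as a (library, length, count) table."""
    counts: dict[tuple[str, int], int] = {}
    for r in reads:
        key = (r.library, r.length)
        counts[key] = counts.get(key, 0) + 1
    rows = [
        {"library": lib, "length": length, "count": n}
        for (lib, length), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["library", "length", "count"])


def tag_name(serial: int, total: int) -> str:
    return f"tag{serial}-{total}"


def write_tags(
    tags: list[SequenceTag], fasta_path: str | Path, counts_path: str | Path
) -> None:
    """Serialize tags as FASTA (``>tag{serial}-{total}``) plus a per-library TSV."""
    libraries = sorted({lib for t in tags for lib in t.counts})
    with open(fasta_path, "w") as fa, open(counts_path, "w") as tsv:
        tsv.write("tag\tsequence\t" + "\t".join(libraries) + "\n")
        for i, t in enumerate(tags, start=1):
            name = tag_name(i, t.total)
            fa.write(f">{name}\n{t.sequence}\n")
            row = "\t".join(str(t.counts.get(lib, 0)) for lib in libraries)
            tsv.write(f"{name}\t{t.sequence}\t{row}\n")


def read_tags(counts_path: str | Path) -> list[SequenceTag]:
    df = pd.read_csv(counts_path, sep="\t")
    libraries = [c for c in df.columns if c not in ("tag", "sequence")]
    out = []
    for _, row in df.iterrows():
        counts = {lib: int(row[lib]) for lib in libraries if row[lib] > 0}
        out.append(SequenceTag(row["sequence"], counts))
    return out
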