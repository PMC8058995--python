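"""Raw small-RNA FASTQ -> annotated unique tags and library statistics.

Every raw read is assigned to exactly one class: ``valid`` (an 18-25 nt
insert surviving all filters), ``adapter_only``, ``too_short``/``too_long``,
``junk`` (poly-N), ``low_quality``, one of the ncRNA classes (rRNA, tRNA,
snoRNA, snRNA, other_ncRNA) or ``repeat``.  The per-library class totals
therefore always sum back to the raw read count, mirroring the usual
high-throughput sequencing statistics table (raw reads; adapter/length
filter; junk; Rfam classes; repeats; valid reads).

Adapter trimming removes the read suffix starting at the leftmost position
where a prefix of the 3' adapter of at least ``adapter_min_overlap``
nucleotides matches with at most one mismatch.  ncRNA/repeat annotation is
exact substring matching on both strands, with class precedence
rRNA > tRNA > snoRNA > snRNA > other, then repeats.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

NCRNA_PRECEDENCE = ("rRNA", "tRNA", "snoRNA", "snRNA", "other_ncRNA")
CLASSES = (
    "valid", "junk", "rRNA", "tRNA", "snRNA", "snoRNA", "other_ncRNA",
    "repeat", "adapter_only", "too_short", "too_long", "low_quality",
)

from ._util import revcomp


@dataclass(frozen=True)
class FilterParams:
    adapter: str
    min_len: int = 18
    max_len: int = 25
    max_n_fraction: float = 0.10
    min_mean_quality: float = 20.0
    adapter_min_overlap: int = 6

    def __post_init__(self):
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.adapter:
            raise ValueError("adapter sequence required")


@dataclass
class UniqueTag:
    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: str = "valid"

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def trim_adapter(sequence: str, params: FilterParams) -> tuple[str, str | None]:
    """Return (insert, label).  label='adapter_only' when no insert remains.

    The suffix is removed at the leftmost position where >=
    ``adapter_min_overlap`` nt of the adapter prefix match with <= 1
    mismatch; reads without an adapter hit are returned untrimmed.
    """
    adapter = params.adapter
    n, m = len(sequence), len(adapter)
    for i in range(0, n - params.adapter_min_overlap + 1):
        overlap = min(m, n - i)
        mismatches = 0
        for a, b in zip(sequence[i : i + overlap], adapter[:overlap]):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        else:
            if i == 0:
                return "", "adapter_only"
            return sequence[:i], None
    return sequence, None


def classify_read(sequence: str, quality: list[int] | None, params: FilterParams) -> tuple[str, str]:
    """(insert, class) for one raw read; class 'valid' means it survives.

    Order: adapter trim -> length gates -> poly-N junk -> mean quality.
    """
    insert, label = trim_adapter(sequence, params)
    if label is not None:
        return insert, label
    if len(insert) < params.min_len:
        return insert, "too_short"
    if len(insert) > params.max_len:
        return insert, "too_long"
    n_frac = insert.upper().count("N") / len(insert)
    if n_frac > params.max_n_fraction:
        return insert, "junk"
    if quality is not None and len(quality) >= len(insert):
        mean_q = sum(quality[: len(insert)]) / len(insert)
        if mean_q < params.min_mean_quality:
            return insert, "low_quality"
    return insert, "valid"


def filter_reads(
    reads, params: FilterParams
) -> tuple[Counter, Counter]:
    """Classify an iterable of (id, sequence, quality-scores) raw reads.

    Returns (kept tag Counter over insert sequences, per-class read
    Counter).  Quality may be None.
    """
    kept: Counter = Counter()
    stats: Counter = Counter()
    for _, seq, qual in reads:
        insert, label = classify_read(seq, qual, params)
        stats[label] += 1
        if label == "valid":
            kept[insert] += 1
    return kept, stats


def annotate_ncrna(
    tags: dict[str, "UniqueTag"],
    ncrna_refs: dict[str, tuple[str, str]],
    repeat_refs: dict[str, str] | None = None,
) -> None:
    """Assign ncRNA/repeat classes to valid tags in place.

    Exact substring match against either strand of a reference; precedence
    rRNA > tRNA > snoRNA > snRNA > other_ncRNA, then repeats; unmatched
    tags stay 'valid'.
    """
    by_class: dict[str, list[str]] = {}
    for _, (cls, seq) in ncrna_refs.items():
        key = cls if cls in NCRNA_PRECEDENCE else "other_ncRNA"
        by_class.setdefault(key, []).append(seq)
    repeats = list((repeat_refs or {}).values())

    for tag in tags.values():
        if tag.annotation != "valid":
            continue
        probes = (tag.sequence, revcomp(tag.sequence))
        hit = None
        for cls in NCRNA_PRECEDENCE:
            if any(p in ref for ref in by_class.get(cls, ()) for p in probes):
                hit = cls
                break
        if hit is None and any(p in ref for ref in repeats for p in probes):
            hit = "repeat"
        if hit is not None:
            tag.annotation = hit


def collapse_unique(per_library: dict[str, Counter]) -> dict[str, UniqueTag]:
    """Merge per-library kept-read counters into UniqueTags keyed by sequence."""
    tags: dict[str, UniqueTag] = {}
    for lib, counter in per_library.items():
        for seq, c in counter.items():
            tag = tags.setdefault(seq, UniqueTag(seq))
            tag.counts[lib] = tag.counts.get(lib, 0) + c
    return tags


def count_matrix(tags: dict[str, UniqueTag], libraries: list[str]) -> pd.DataFrame:
    """Tag x library raw count matrix (valid tags only)."""
    data = {
        seq: [t.counts.get(lib, 0) for lib in libraries]
        for seq, t in tags.items()
        if t.annotation == "valid"
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=libraries).sort_index()


def length_distribution(
    tags: dict[str, UniqueTag], min_len: int = 18, max_len: int = 25
) -> pd.DataFrame:
    """Total and unique valid-tag counts per insert length."""
    rows = []
    for length in range(min_len, max_len + 1):
        sel = [t for t in tags.values()
               if t.annotation == "valid" and len(t.sequence) == length]
        rows.append((length, sum(t.total for t in sel), len(sel)))
    return pd.DataFrame(rows, columns=["length", "total", "unique"]).set_index("length")


def library_stats(
    per_library_stats: dict[str, Counter],
    tags: dict[str, UniqueTag] | None = None,
) -> pd.DataFrame:
    """Per-library totals shaped like a sequencing-statistics table.

    Rows: raw reads; the aggregate adapter/length filter row
    (adapter_only + too_short + too_long); junk; low-quality; each ncRNA
    class; repeats; valid reads.  Row groups sum to the raw totals.
    """
    libs = list(per_library_stats)
    rows = {}
    get = lambda lib, cls: per_library_stats[lib].get(cls, 0)
    rows["raw_reads"] = [sum(per_library_stats[lib].values()) for lib in libs]
    rows["3ADT_length_filter"] = [
        get(l, "adapter_only") + get(l, "too_short") + get(l, "too_long") for l in libs
    ]
    rows["junk_reads"] = [get(l, "junk") for l in libs]
    rows["low_quality"] = [get(l, "low_quality") for l in libs]
    if tags is not None:
        # ncRNA/repeat classes are assigned on collapsed tags; spread the
        # per-library totals from the tag count columns
        for cls in NCRNA_PRECEDENCE + ("repeat",):
            rows[cls] = [
                sum(t.counts.get(l, 0) for t in tags.values() if t.annotation == cls)
                for l in libs
            ]
        rows["valid_reads"] = [
            sum(t.counts.get(l, 0) for t in tags.values() if t.annotation == "valid")
            for l in libs
        ]
    else:
        for cls in NCRNA_PRECEDENCE + ("repeat",):
            rows[cls] = [get(l, cls) for l in libs]
        rows["valid_reads"] = [get(l, "valid") for l in libs]
    return pd.DataFrame(rows, index=libs).T


def read_fastq(path) -> list[tuple[str, str, list[int]]]:
    """(id, sequence, Phred scores) records from a Phred+33 FASTQ file."""
    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        out.append((rec.id, str(rec.seq), rec.letter_annotations["phred_quality"]))
    return out


def preprocess_library(reads, params: FilterParams) -> tuple[Counter, Counter]:
    """Alias for filter_reads, the single-library entry point."""
    return filter_reads(reads, params)


def preprocess_libraries(
    libraries: dict[str, list],
    params: FilterParams,
    ncrna_refs: dict[str, tuple[str, str]] | None = None,
    repeat_refs: dict[str, str] | None = None,
):
    """Full preprocessing over several libraries.

    Returns (tags, stats table, per-library class counters).
    """
    per_kept: dict[str, Counter] = {}
    per_stats: dict[str, Counter] = {}
    for lib, reads in libraries.items():
        per_kept[lib], per_stats[lib] = filter_reads(reads, params)
    tags = collapse_unique(per_kept)
    if ncrna_refs:
        annotate_ncrna(tags, ncrna_refs, repeat_refs)
    stats = library_stats(per_stats, tags)
    return tags, stats, per_stats
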