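"""Known-miRNA identification and novel-miRNA prediction.

Catalogue matching replaces BLAST with exact substring matching at desk
scale: a valid tag hits a catalogue precursor when it occurs verbatim with
its start within a window (default +/-4 nt) of the annotated mature start.
Matched miRNAs fall into three groups by whether the tag and/or its
catalogue precursor also occur in the species transcriptome:

* group 1 — tag and precursor both map to the transcriptome (known);
* group 2 — the tag maps but its precursor does not (conserved);
* group 3 — neither maps, the tag is catalogue-only (conserved).

Unannotated valid tags that map to the transcriptome seed novel-miRNA
candidates: a flanking window (default 150 nt each side) is excised around
the tag, overlapping windows are merged, and each candidate is folded and
scored against the hairpin criteria (see :mod:`lilimir.hairpin`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .hairpin import HairpinCriteria, HairpinEvaluation, evaluate_hairpin


@dataclass
class PrecursorMatch:
    tag: str
    precursor: str
    offset: int  # tag start minus annotated mature start (0 = exact)
    strand: str = "+"


@dataclass
class MirnaRecord:
    name: str
    mature: str
    family: str
    group: int | str  # 1/2/3 or "novel"
    precursor_ids: list[str] = field(default_factory=list)
    locus: tuple[str, int, int, str] | None = None  # transcript, start, end, strand


def map_to_precursors(
    tags,
    precursors: dict[str, tuple[str, int, int]],
    window: int = 4,
) -> list[PrecursorMatch]:
    """Match tags to catalogue precursors (sequence, mature start, end; 1-based).

    A tag may hit several family paralogues; every hit within the mature
    window is reported.
    """
    matches = []
    for tag in tags:
        for pname, (pseq, ms, _me) in precursors.items():
            start = pseq.find(tag)
            while start != -1:
                offset = (start + 1) - ms
                if abs(offset) <= window:
                    matches.append(PrecursorMatch(tag, pname, offset))
                start = pseq.find(tag, start + 1)
    return matches


def _maps_to_transcriptome(seq: str, transcriptome: dict[str, str]):
    for tname, tseq in transcriptome.items():
        pos = tseq.find(seq)
        if pos != -1:
            return tname, pos + 1
    return None


def classify_groups(
    matches: list[PrecursorMatch],
    precursors: dict[str, tuple[str, int, int]],
    transcriptome: dict[str, str],
    precursor_families: dict[str, str] | None = None,
) -> list[MirnaRecord]:
    """Assign catalogue-matched tags to groups 1-3 (one record per tag)."""
    by_tag: dict[str, list[PrecursorMatch]] = {}
    for m in matches:
        by_tag.setdefault(m.tag, []).append(m)

    records = []
    for tag, tag_matches in by_tag.items():
        prec_ids = sorted({m.precursor for m in tag_matches})
        tag_hit = _maps_to_transcriptome(tag, transcriptome)
        prec_in_txome = any(
            _maps_to_transcriptome(precursors[p][0], transcriptome) for p in prec_ids
        )
        if tag_hit and prec_in_txome:
            group = 1
        elif tag_hit:
            group = 2
        else:
            group = 3
        family = ""
        if precursor_families:
            family = precursor_families.get(prec_ids[0], "")
        locus = None
        if tag_hit:
            locus = (tag_hit[0], tag_hit[1], tag_hit[1] + len(tag) - 1, "+")
        records.append(MirnaRecord(prec_ids[0].removeprefix("pre-"), tag, family, group, prec_ids, locus))
    return records


def assign_families(records: list[MirnaRecord]) -> pd.DataFrame:
    """Family table with member counts; novel records get sequential miRn#."""
    novel_serial = 0
    rows = []
    for rec in records:
        fam = rec.family
        if rec.group == "novel":
            novel_serial += 1
            fam = rec.family = f"miRn{novel_serial}"
            rec.name = fam
        rows.append((rec.name, fam))
    df = pd.DataFrame(rows, columns=["mirna", "family"])
    if df.empty:
        return pd.DataFrame(columns=["family", "members"])
    return (
        df.groupby("family")["mirna"].nunique().rename("members").reset_index()
        .sort_values(["members", "family"], ascending=[False, True], ignore_index=True)
    )


@dataclass
class CandidateLocus:
    transcript: str
    start: int  # 1-based inclusive window on the transcript
    end: int
    tags: list[tuple[str, int]] = field(default_factory=list)  # (tag, tag start)

    def sequence(self, transcriptome: dict[str, str]) -> str:
        return self.transcriptome_seq(transcriptome)

    def transcriptome_seq(self, transcriptome):
        return transcriptome[self.transcript][self.start - 1 : self.end]


def find_novel_candidates(
    tags,
    transcriptome: dict[str, str],
    flank: int = 150,
) -> list[CandidateLocus]:
    """Excise candidate precursor windows around transcriptome-mapped tags.

    ``tags`` is an iterable of unannotated valid tag sequences (or a
    mapping tag -> abundance).  Overlapping windows on the same transcript
    are merged into one candidate locus.
    """
    hits: dict[str, list[tuple[int, int, str, int]]] = {}
    for tag in tags:
        for tname, tseq in transcriptome.items():
            pos = tseq.find(tag)
            while pos != -1:
                s = max(1, pos + 1 - flank)
                e = min(len(tseq), pos + len(tag) + flank)
                hits.setdefault(tname, []).append((s, e, tag, pos + 1))
                pos = tseq.find(tag, pos + 1)

    loci = []
    for tname, intervals in hits.items():
        intervals.sort()
        cur: CandidateLocus | None = None
        for s, e, tag, tag_start in intervals:
            if cur is not None and s <= cur.end:
                cur.end = max(cur.end, e)
                cur.tags.append((tag, tag_start))
            else:
                cur = CandidateLocus(tname, s, e, [(tag, tag_start)])
                loci.append(cur)
    return loci


def evaluate_candidates(
    loci: list[CandidateLocus],
    transcriptome: dict[str, str],
    abundance: dict[str, float] | None = None,
    criteria: HairpinCriteria = HairpinCriteria(),
    temperature: float = 37.0,
) -> list[tuple[CandidateLocus, str, HairpinEvaluation]]:
    """Fold each candidate locus and evaluate the hairpin criteria.

    The mature within a merged locus is its most abundant tag (ties by
    sequence).  Returns (locus, mature tag, evaluation) triples.
    """
    out = []
    for locus in loci:
        if abundance:
            mature, tag_start = max(
                locus.tags, key=lambda t: (abundance.get(t[0], 0.0), t[0])
            )
        else:
            mature, tag_start = locus.tags[0]
        seq = locus.transcriptome_seq(transcriptome)
        ms = tag_start - locus.start + 1
        me = ms + len(mature) - 1
        ev = evaluate_hairpin(
            seq, ms, me, criteria,
            candidate_id=f"{locus.transcript}:{locus.start}-{locus.end}",
            temperature=temperature,
        )
        out.append((locus, mature, ev))
    return out


def catalogue_novel(
    evaluations: list[tuple[CandidateLocus, str, HairpinEvaluation]],
) -> tuple[list[MirnaRecord], pd.DataFrame]:
    """Passing candidates become novel miRNA records (miRn#) with a summary.

    The summary reports mature-length, hairpin-length and MFE extremes in
    the shape of a novel-miRNA results table; the hairpin is the stem-loop
    spanned by the outermost stem pair (re-folded on its own for the MFE),
    not the whole excision window.  Duplicate loci (same transcript
    window) are collapsed.
    """
    from .hairpin import fold

    records = []
    seen = set()
    stats = []
    for locus, mature, ev in evaluations:
        if not ev.passed:
            continue
        key = (locus.transcript, locus.start, locus.end)
        if key in seen:
            continue
        seen.add(key)
        serial = len(records) + 1
        hp_seq = ev.sequence[ev.hairpin_start - 1 : ev.hairpin_end]
        _, hp_mfe = fold(hp_seq)
        records.append(
            MirnaRecord(
                name=f"miRn{serial}",
                mature=mature,
                family=f"miRn{serial}",
                group="novel",
                precursor_ids=[ev.candidate_id],
                locus=(locus.transcript, locus.start, locus.end, "+"),
            )
        )
        stats.append((len(mature), len(hp_seq), hp_mfe))
    if stats:
        df = pd.DataFrame(stats, columns=["mature_len", "hairpin_len", "mfe"])
        summary = pd.DataFrame(
            {
                "n_novel": [len(records)],
                "mature_len_min": [df.mature_len.min()],
                "mature_len_max": [df.mature_len.max()],
                "hairpin_len_min": [df.hairpin_len.min()],
                "hairpin_len_max": [df.hairpin_len.max()],
                "mfe_min": [df.mfe.min()],
                "mfe_max": [df.mfe.max()],
            }
        )
    else:
        summary = pd.DataFrame(
            columns=["n_novel", "mature_len_min", "mature_len_max",
                     "hairpin_len_min", "hairpin_len_max", "mfe_min", "mfe_max"]
        )
    return records, summary
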