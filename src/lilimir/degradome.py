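"""Degradome (PARE) target validation: duplex scoring, cleavage-site
category assignment, and T-plot export.

Scoring follows the classic plant miRNA-target penalty scheme: each
mismatch costs 1, each G:U wobble 0.5 and each single-nucleotide bulge 1,
with penalties doubled at miRNA positions 2-13 (counting from the miRNA
5' end); alignments with total penalty <= 4 (configurable) are candidate
binding sites.  The expected cleavage position is the transcript
nucleotide opposite miRNA position 10, which is where a diagnostic
degradome tag's 5' end falls.

Cleavage-site evidence categories (the standard degradome convention):

* 4 — exactly one tag at the cleavage position;
* 0 — tag count equals the transcript maximum, and the maximum is unique;
* 1 — tag count equals the maximum, attained at more than one position;
* 2 — count above the median of nonzero positions but below the maximum;
* 3 — anything else (more than one tag, at or below the median).

The median is taken over nonzero positions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}

# penalty[mirna_base, transcript_base]: 0 perfect, 0.5 G:U wobble, 1 mismatch
_PENALTY = np.ones((5, 5))
for _m, _t in (("A", "T"), ("C", "G"), ("G", "C"), ("T", "A")):
    _PENALTY[_BASE_INDEX[_m], _BASE_INDEX[_t]] = 0.0
_PENALTY[_BASE_INDEX["G"], _BASE_INDEX["T"]] = 0.5  # G:U
_PENALTY[_BASE_INDEX["T"], _BASE_INDEX["G"]] = 0.5  # U:G


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(c, 4) for c in seq.upper()], dtype=np.int8)


def position_weight(i: int, seed_start: int = 2, seed_end: int = 13) -> float:
    """Penalty multiplier at miRNA position ``i`` (1-based from the 5' end)."""
    return 2.0 if seed_start <= i <= seed_end else 1.0


@dataclass
class DuplexAlignment:
    mirna: str
    transcript: str
    start: int  # 1-based site interval on the transcript (sense strand)
    end: int
    score: float
    mirna_seq: str = ""

    @property
    def cleavage_pos(self) -> int:
        """Transcript coordinate opposite miRNA position 10."""
        return self.end - 9


def score_duplex(mirna: str, site: str, max_gaps: int = 1,
                 gap_penalty: float = 1.0, seed_start: int = 2,
                 seed_end: int = 13) -> float:
    """Minimal penalty of the miRNA:site duplex (site 5'->3', sense strand).

    The miRNA 5' end faces the site 3' end.  A small DP allows up to
    ``max_gaps`` single-nucleotide bulges on either strand.  Penalties are
    doubled at miRNA positions ``seed_start``..``seed_end``.
    """
    m = len(mirna)
    s = len(site)
    if abs(m - s) > max_gaps:
        return np.inf
    mi = _encode(mirna)
    ti = _encode(site)[::-1]  # walk the site from its 3' end
    INF = np.inf
    # dp[i][j][g]: min cost pairing the first i miRNA nt with the first j
    # site nt (from the 3' end) using g single-nt bulges.  Bulges are
    # weighted by the next miRNA position's multiplier.
    dp = np.full((m + 1, s + 1, max_gaps + 1), INF)
    dp[0, 0, 0] = 0.0
    for i in range(m + 1):
        w = position_weight(i + 1, seed_start, seed_end)
        for j in range(s + 1):
            for g in range(max_gaps + 1):
                cur = dp[i, j, g]
                if cur == INF:
                    continue
                if i < m and j < s:  # pair / mismatch / wobble
                    pen = _PENALTY[mi[i], ti[j]] if mi[i] < 4 and ti[j] < 4 else 1.0
                    v = cur + pen * w
                    if v < dp[i + 1, j + 1, g]:
                        dp[i + 1, j + 1, g] = v
                if g < max_gaps:
                    if i < m:  # miRNA nt bulged out (no site partner)
                        v = cur + gap_penalty * w
                        if v < dp[i + 1, j, g + 1]:
                            dp[i + 1, j, g + 1] = v
                    if j < s:  # site nt bulged out (no miRNA partner)
                        v = cur + gap_penalty * w
                        if v < dp[i, j + 1, g + 1]:
                            dp[i, j + 1, g + 1] = v
    return float(dp[m, s, :].min())


def _ungapped_scores(mirna: str, transcript: str) -> np.ndarray:
    """Vectorized ungapped duplex penalty at every site start position."""
    m = len(mirna)
    t = _encode(transcript)
    L = len(t) - m + 1
    if L <= 0:
        return np.empty(0)
    mi = _encode(mirna)
    weights = np.array([position_weight(i) for i in range(1, m + 1)])
    scores = np.zeros(L)
    # miRNA position i (1-based) pairs transcript position start + m - i
    for i in range(m):
        tb = t[m - 1 - i : m - 1 - i + L]
        pen = np.where((mi[i] < 4) & (tb < 4), _PENALTY[mi[i], np.minimum(tb, 3)], 1.0)
        pen = np.where(tb == 4, 1.0, pen)
        scores += pen * weights[i]
    return scores


def predict_sites(
    mirna_seq: str,
    transcript_seq: str,
    mirna_name: str = "miRNA",
    transcript_name: str = "transcript",
    threshold: float = 4.0,
    max_gaps: int = 1,
    prescreen_margin: float = 4.0,
) -> list[DuplexAlignment]:
    """Scan a transcript for candidate miRNA binding sites.

    An ungapped vectorized scan prescreens start positions; candidates
    within ``prescreen_margin`` of the threshold are rescored with the
    gapped DP over site lengths len(miRNA) +/- max_gaps.  Overlapping hits
    keep the best-scoring window.
    """
    m = len(mirna_seq)
    scores = _ungapped_scores(mirna_seq, transcript_seq)
    hits: list[DuplexAlignment] = []
    for start0 in np.nonzero(scores <= threshold + prescreen_margin)[0]:
        best = np.inf
        best_end = start0 + m  # 1-based inclusive end
        for site_len in range(m - max_gaps, m + max_gaps + 1):
            site = transcript_seq[start0 : start0 + site_len]
            if len(site) < site_len:
                continue
            sc = score_duplex(mirna_seq, site, max_gaps=max_gaps)
            if sc < best:
                best, best_end = sc, start0 + site_len
        if best <= threshold:
            hits.append(
                DuplexAlignment(mirna_name, transcript_name, int(start0) + 1,
                                int(best_end), best, mirna_seq)
            )
    # overlapping windows: keep the best score per cluster
    hits.sort(key=lambda h: (h.start, h.score))
    dedup: list[DuplexAlignment] = []
    for h in hits:
        if dedup and h.start <= dedup[-1].end - m // 2:
            if h.score < dedup[-1].score:
                dedup[-1] = h
        else:
            dedup.append(h)
    return dedup


def map_degradome(
    tags: list[tuple[str, str]],
    transcriptome: dict[str, str],
    fractional: bool = False,
) -> tuple[dict[str, np.ndarray], int]:
    """Pile up degradome tag 5' ends on the sense strand of each transcript.

    Returns (profiles: transcript -> per-position 5'-end counts (1-based
    position p stored at index p-1), unmapped tag count).  A tag matching
    several loci counts once per locus, or 1/n per locus in fractional
    mode.
    """
    profiles = {t: np.zeros(len(seq)) for t, seq in transcriptome.items()}
    unmapped = 0
    for _tid, tag in tags:
        loci = []
        for tname, tseq in transcriptome.items():
            pos = tseq.find(tag)
            while pos != -1:
                loci.append((tname, pos))
                pos = tseq.find(tag, pos + 1)
        if not loci:
            unmapped += 1
            continue
        w = 1.0 / len(loci) if fractional else 1.0
        for tname, pos in loci:
            profiles[tname][pos] += w
    return profiles, unmapped


def classify_category(position: int, profile: np.ndarray) -> int:
    """Evidence category (0-4) of a cleavage position on a tag profile.

    ``position`` is 1-based.  Raises on zero evidence (no cleavage tag).
    """
    count = profile[position - 1]
    if count <= 0:
        raise ValueError("no degradome evidence at the cleavage position")
    if count == 1:
        return 4
    nonzero = profile[profile > 0]
    mx = nonzero.max()
    if count == mx:
        return 0 if (nonzero == mx).sum() == 1 else 1
    med = float(np.median(nonzero))
    if count > med:
        return 2
    return 3


@dataclass
class CleavageSite:
    mirna: str
    transcript: str
    cleavage_pos: int
    count: float
    category: int
    alignment: DuplexAlignment


def call_targets(
    alignments: list[DuplexAlignment],
    profiles: dict[str, np.ndarray],
    window: int = 1,
) -> list[CleavageSite]:
    """Validate predicted sites against the degradome tag profiles.

    For each alignment the expected cleavage position (opposite miRNA
    position 10) is inspected within +/- ``window`` nt; the best-supported
    position in the window (exact position preferred on ties) yields a
    CleavageSite with its evidence category.  Sites with no tag support
    are dropped.
    """
    sites = []
    for aln in alignments:
        profile = profiles.get(aln.transcript)
        if profile is None:
            continue
        exp = aln.cleavage_pos
        best_pos, best_count = None, 0.0
        for offset in sorted(range(-window, window + 1), key=abs):
            p = exp + offset
            if 1 <= p <= len(profile) and profile[p - 1] > best_count:
                best_pos, best_count = p, profile[p - 1]
        if best_pos is None:
            continue
        sites.append(
            CleavageSite(
                aln.mirna, aln.transcript, best_pos, float(best_count),
                classify_category(best_pos, profile), aln,
            )
        )
    return sites


def tplot_data(
    profile: np.ndarray, sites: list[CleavageSite] | None = None
) -> pd.DataFrame:
    """Per-position table (position, count, site flag) for target plots."""
    flagged = {s.cleavage_pos for s in sites or []}
    return pd.DataFrame(
        {
            "position": np.arange(1, len(profile) + 1),
            "count": profile,
            "is_site": [p in flagged for p in range(1, len(profile) + 1)],
        }
    )


def targets_table(sites: list[CleavageSite]) -> pd.DataFrame:
    """Flat TSV-ready table of validated targets."""
    return pd.DataFrame(
        [
            {
                "mirna": s.mirna,
                "transcript": s.transcript,
                "site_start": s.alignment.start,
                "site_end": s.alignment.end,
                "score": s.alignment.score,
                "cleavage_pos": s.cleavage_pos,
                "count": s.count,
                "category": s.category,
            }
            for s in sites
        ]
    )
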