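"""Hairpin folding and the novel-miRNA precursor criteria.

A candidate precursor is folded at its minimum free energy (ViennaRNA) and
judged on the stem-loop statistics conventionally required of a plant
pre-miRNA:

* no single bulge (contiguous unpaired run) in the stem larger than
  ``max_stem_bulge`` nucleotides, nor larger than ``max_mature_bulge``
  within the mature region;
* at least ``min_stem_pairs`` base pairs in the stem that carries the
  mature sequence;
* at most ``max_mature_errors`` unpaired nucleotides inside the mature
  sequence, and at most ``max_biased_errors`` asymmetric (biased)
  unpaired nucleotides in any single mature-region bulge;
* the mature sequence may not run into the terminal loop.

"Stem" here means the helix containing the mature arm, followed outward
and inward through its interior loops until the terminal loop, a
multiloop branch point, or the exterior loop is reached.  "Biased errors"
are the asymmetric portion of an internal loop (|left gap - right gap|),
measured only for loops touching the mature region; this reading of the
criterion is isolated here so it can be revised in one place.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import RNA

MIN_LOOP = 3  # minimal hairpin loop size enforced by the folding model


@dataclass(frozen=True)
class HairpinCriteria:
    """Thresholds for accepting a candidate precursor."""

    max_stem_bulge: int = 12
    max_mature_bulge: int = 4
    min_stem_pairs: int = 16
    max_mature_errors: int = 2
    max_biased_errors: int = 2

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class HairpinEvaluation:
    """Measured stem-loop statistics and the per-criterion verdict."""

    candidate_id: str
    sequence: str
    structure: str
    mfe: float  # kcal/mol
    stem_bulge: int = 0
    mature_bulge: int = 0
    stem_pairs: int = 0
    mature_errors: int = 0
    biased_errors: int = 0
    flags: dict = field(default_factory=dict)
    reject_reason: str | None = None
    passed: bool = False
    hairpin_start: int = 0  # outermost stem pair (1-based); 0 when no stem
    hairpin_end: int = 0

    @property
    def mfe_per_nt(self) -> float:
        return self.mfe / len(self.sequence) if self.sequence else 0.0


def fold(sequence: str, temperature: float = 37.0) -> tuple[str, float]:
    """MFE structure and free energy (kcal/mol) of an RNA/DNA-alphabet sequence."""
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(sequence.replace("T", "U").replace("t", "u"), md)
    structure, mfe = fc.mfe()
    return structure, float(mfe)


def energy_of_structure(sequence: str, structure: str, temperature: float = 37.0) -> float:
    """Free energy of a given structure on a given sequence (kcal/mol)."""
    md = RNA.md()
    md.temperature = temperature
    fc = RNA.fold_compound(sequence.replace("T", "U").replace("t", "u"), md)
    return float(fc.eval_structure(structure))


def pair_table(structure: str) -> list[int]:
    """1-based pairing partners; index 0 unused, 0 = unpaired."""
    pt = RNA.ptable(structure)
    return list(pt)


def _direct_children(pt: list[int], i: int, j: int) -> list[tuple[int, int]]:
    """Base pairs directly nested inside (i, j)."""
    children = []
    k = i + 1
    while k < j:
        if pt[k] > k:
            children.append((k, pt[k]))
            k = pt[k] + 1
        else:
            k += 1
    return children


def _stem_through(pt: list[int], anchor: tuple[int, int], max_span: int | None = None,
                  walk_break: int | None = None):
    """Follow the helix containing ``anchor`` inward and outward.

    Returns (stem pairs outer-to-inner, terminal loop interval or None).
    The walk stops inward at the terminal loop or a multiloop, and
    outward at the exterior loop, a multiloop, or — when ``max_span`` is
    set — at the pair that would stretch the stem beyond ``max_span``
    nucleotides.  An interior loop with an unpaired run larger than
    ``walk_break`` also ends the stem on the outward side: candidate
    windows excised from a transcript carry flanking sequence whose
    pairing is not part of the precursor helix.
    """
    inward = []
    cur = anchor
    terminal_loop = None
    while True:
        inward.append(cur)
        children = _direct_children(pt, cur[0], cur[1])
        if len(children) == 0:
            terminal_loop = (cur[0] + 1, cur[1] - 1)
            break
        if len(children) > 1:  # multiloop: helix ends here
            break
        cur = children[0]

    outward = []
    cur = anchor
    while True:
        i, j = cur
        enclosing = None
        a = i - 1
        while a >= 1:
            if pt[a] != 0:
                if pt[a] > j:
                    enclosing = (a, pt[a])
                break  # sibling helix (multiloop/exterior) -> stop
            a -= 1
        if enclosing is None:
            break
        if max_span is not None and enclosing[1] - enclosing[0] + 1 > max_span:
            break
        if walk_break is not None:
            gap = max(i - enclosing[0] - 1, enclosing[1] - j - 1)
            if gap > walk_break:
                break
        outward.append(enclosing)
        cur = enclosing

    pairs = list(reversed(outward)) + inward
    return pairs, terminal_loop


def evaluate_hairpin(
    sequence: str,
    mature_start: int,
    mature_end: int,
    criteria: HairpinCriteria = HairpinCriteria(),
    candidate_id: str = "candidate",
    temperature: float = 37.0,
    structure: str | None = None,
    max_stem_span: int | None = 250,
    stem_walk_break: int | None = 20,
) -> HairpinEvaluation:
    """Fold a candidate precursor and score it against the hairpin criteria.

    ``mature_start``/``mature_end`` are 1-based inclusive coordinates of the
    mature sequence within ``sequence``.  A pre-computed ``structure`` may be
    supplied (it is then evaluated, not re-folded).  Degenerate candidates are
    rejected with a reason, never raised on.
    """
    n = len(sequence)
    if not (1 <= mature_start <= mature_end <= n):
        raise ValueError("mature interval outside candidate sequence")
    mature_len = mature_end - mature_start + 1

    if structure is None:
        structure, mfe = fold(sequence, temperature=temperature)
    else:
        mfe = energy_of_structure(sequence, structure, temperature=temperature)
    ev = HairpinEvaluation(candidate_id, sequence, structure, mfe)

    if n < mature_len + MIN_LOOP + 1:
        ev.reject_reason = "too_short"
        return ev

    pt = pair_table(structure)
    mature = range(mature_start, mature_end + 1)
    ev.mature_errors = sum(1 for i in mature if pt[i] == 0)

    paired_mature = [i for i in mature if pt[i] != 0]
    if not paired_mature:
        ev.reject_reason = "mature_unpaired"
        return ev
    if any(mature_start <= pt[i] <= mature_end for i in paired_mature):
        ev.reject_reason = "mature_self_pairing"
        return ev

    anchor_i = paired_mature[0]
    anchor = (min(anchor_i, pt[anchor_i]), max(anchor_i, pt[anchor_i]))
    stem, terminal_loop = _stem_through(
        pt, anchor, max_span=max_stem_span, walk_break=stem_walk_break
    )
    ev.stem_pairs = len(stem)
    ev.hairpin_start, ev.hairpin_end = stem[0]

    if terminal_loop is not None:
        lo, hi = terminal_loop
        if lo <= hi and not (mature_end < lo or mature_start > hi):
            ev.reject_reason = "mature_in_terminal_loop"
            return ev

    def in_mature(a: int, b: int) -> bool:
        # does [a, b] (possibly empty, a > b) overlap the mature interval?
        return a <= b and not (b < mature_start or a > mature_end)

    stem_bulge = mature_bulge = biased = 0
    for (a, b), (c, d) in zip(stem, stem[1:]):
        left = c - a - 1  # unpaired run on the 5' side of the loop
        right = b - d - 1  # unpaired run on the 3' side
        if left == 0 and right == 0:
            continue
        run = max(left, right)
        stem_bulge = max(stem_bulge, run)
        touches_mature = (
            in_mature(a + 1, c - 1)
            or in_mature(d + 1, b - 1)
            or (mature_start <= a <= mature_end and mature_start <= c <= mature_end)
            or (mature_start <= d <= mature_end and mature_start <= b <= mature_end)
        )
        if touches_mature:
            mature_bulge = max(mature_bulge, run)
            biased = max(biased, abs(left - right))

    ev.stem_bulge = stem_bulge
    ev.mature_bulge = mature_bulge
    ev.biased_errors = biased

    ev.flags = {
        "stem_bulge": ev.stem_bulge <= criteria.max_stem_bulge,
        "mature_bulge": ev.mature_bulge <= criteria.max_mature_bulge,
        "stem_pairs": ev.stem_pairs >= criteria.min_stem_pairs,
        "mature_errors": ev.mature_errors <= criteria.max_mature_errors,
        "biased_errors": ev.biased_errors <= criteria.max_biased_errors,
    }
    ev.passed = all(ev.flags.values()) and ev.reject_reason is None
    return ev
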