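"""Synthetic small-RNA study generator.

Builds every input the pipeline consumes — a transcriptome with embedded
miRNA precursors, a mature/precursor catalogue, ncRNA contaminant
references, stage-structured small-RNA libraries, a degradome tag library
and a qPCR Ct table — together with ground-truth tables, so the discovery,
differential-expression, degradome and network stages can be tested end to
end without any external download.

The default design mirrors a five-stage developmental series (VJ_I, VJ_II,
FI_I, FI_II, FD) with three replicates per stage: ageing-pathway-like
abundance trajectories (miR156-like decreasing, miR172-like increasing),
flat null miRNAs, poly-N junk reads, rRNA/tRNA/snRNA/snoRNA contaminants,
3'-adapter read-through, and degradome tags whose 5' ends sit opposite
miRNA position 10 of a planted target site.

Planted precursors are designed as reverse-complement stems around the
mature sequence and then *verified* with the same hairpin evaluator the
discovery module uses; decoy precursors are constructed to violate a single
criterion each (oversized stem bulge, >2 mature mismatches, or a biased
mature-region bulge) and are likewise verified before being accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import random_seq, revcomp, rng_for
from .hairpin import HairpinCriteria, evaluate_hairpin

DEFAULT_STAGES = ("VJ_I", "VJ_II", "FI_I", "FI_II", "FD")
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq small-RNA 3' adapter

# mature-length weights; modal valid-read length 24 nt, 21 nt next
MATURE_LENGTH_WEIGHTS = {18: 0.02, 19: 0.03, 20: 0.07, 21: 0.25,
                         22: 0.13, 23: 0.12, 24: 0.33, 25: 0.05}

KNOWN_FAMILIES = [
    "miR156", "miR166", "miR169", "miR159", "miR172", "miR160", "miR164",
    "miR397", "miR398", "miR408", "miR162", "miR171", "miR319", "miR394",
    "miR5179", "miR828",
]

# families tied to expression shapes (ageing-pathway-like trajectories)
DECREASING_FAMILIES = {"miR156", "miR166"}
INCREASING_FAMILIES = {"miR172", "miR159", "miR171"}
PEAKED_FAMILIES = {"miR5179"}

DECOY_CLASSES = ("stem_bulge", "mature_errors", "biased_errors")


@dataclass(frozen=True)
class SimConfig:
    """Study-design knobs for the synthetic generator."""

    seed: int = 0
    n_transcripts: int = 80
    n_known_mirnas: int = 40
    n_novel_mirnas: int = 10
    n_decoy_hairpins: int = 10
    n_contaminant_refs: int = 12
    n_target_sites: int = 15
    stages: tuple[str, ...] = DEFAULT_STAGES
    replicates_per_stage: int = 3
    library_depth: int = 20000
    adapter: str = DEFAULT_ADAPTER
    junk_fraction: float = 0.05
    contaminant_fraction: float = 0.10
    lowqual_fraction: float = 0.03
    raw_read_length: int = 50
    isomir_probs: tuple[float, float, float] = (0.90, 0.08, 0.02)
    nb_dispersion: float = 0.1
    count_model: str = "nb"  # "nb" or "poisson"

    def validate(self) -> None:
        if self.n_transcripts <= 0:
            raise ValueError("n_transcripts must be positive")
        if not self.stages:
            raise ValueError("at least one stage required")
        fracs = (self.junk_fraction, self.contaminant_fraction, self.lowqual_fraction)
        if any(f < 0 for f in fracs) or sum(fracs) >= 1:
            raise ValueError("read-class fractions must be non-negative and sum to < 1")
        if self.library_depth < 0:
            raise ValueError("library_depth must be non-negative")
        if self.replicates_per_stage <= 0:
            raise ValueError("replicates_per_stage must be positive")
        if self.count_model not in ("nb", "poisson"):
            raise ValueError("count_model must be 'nb' or 'poisson'")
        n_prec = self.n_known_mirnas + self.n_novel_mirnas + self.n_decoy_hairpins
        if self.n_transcripts < n_prec + self.n_target_sites:
            raise ValueError(
                "n_transcripts too small to host all precursors and target sites"
            )

    @property
    def samples(self) -> list[tuple[str, int]]:
        return [(s, r + 1) for s in self.stages for r in range(self.replicates_per_stage)]


@dataclass
class PrecursorInfo:
    name: str
    sequence: str
    mature_start: int  # 1-based inclusive, within precursor
    mature_end: int
    family: str
    is_novel: bool
    transcript: str | None = None  # embedding transcript (None: catalogue-only)
    position: int | None = None  # 1-based start of precursor in transcript

    @property
    def mature(self) -> str:
        return self.sequence[self.mature_start - 1 : self.mature_end]


@dataclass
class StageProfile:
    """Per-miRNA expected linear-scale abundance per stage."""

    stages: tuple[str, ...]
    expected: pd.DataFrame  # miRNA x stage, linear scale
    shape: dict[str, str]  # miRNA -> decreasing | increasing | peaked | flat

    def __post_init__(self):
        if (self.expected.values < 0).any():
            raise ValueError("expected abundances must be non-negative")


@dataclass
class ReferenceBundle:
    config: SimConfig
    transcriptome: dict[str, str]
    precursors: dict[str, PrecursorInfo]
    mature_catalogue: dict[str, str]  # catalogue ("miRBase-like"): known only
    ncrna_refs: dict[str, tuple[str, str]]  # name -> (class, sequence)
    repeat_refs: dict[str, str]
    annotation_table: pd.DataFrame  # columns: transcript, term
    profile: StageProfile
    truth: dict[str, pd.DataFrame] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# hairpin construction


def _design_hairpin(rng, mature_len: int, flank: int = 12, loop_len: int = 8,
                    decoy: str | None = None) -> tuple[str, int, int]:
    """One random candidate precursor; mature on the 5' arm.

    ``decoy`` selects a single-criterion violation to engineer:
    ``stem_bulge`` (14-nt insertion in the 3' flank helix),
    ``mature_errors`` (3 mismatches opposite the mature) or
    ``biased_errors`` (3-nt asymmetric insertion opposite the mature).
    """
    if decoy == "stem_bulge":
        flank = 18  # strong outer helix so the bulged stem folds in context
    mature = random_seq(rng, mature_len)
    left = random_seq(rng, flank, "GGCCAT" if decoy == "stem_bulge" else "ACGT")
    loop = random_seq(rng, loop_len, "AC")
    arm = left + mature
    star = revcomp(arm)
    n = len(arm)
    if decoy == "stem_bulge":
        cut = mature_len + flank // 2
        star = star[:cut] + random_seq(rng, 14, "AC") + star[cut:]
    elif decoy == "mature_errors":
        star_l = list(star)
        third = mature_len // 3
        for mpos in (flank + third // 2, flank + mature_len // 2, flank + mature_len - 1 - third // 2):
            spos = n - 1 - mpos
            star_l[spos] = {"A": "C", "C": "A", "G": "A", "T": "C"}[arm[mpos]]
        star = "".join(star_l)
    elif decoy == "biased_errors":
        cut = n - 1 - (flank + mature_len // 2)
        star = star[:cut] + random_seq(rng, 3, "AC") + star[cut:]
    elif decoy is not None:
        raise ValueError(f"unknown decoy class {decoy!r}")
    seq = arm + loop + star
    return seq, flank + 1, flank + mature_len


def make_verified_hairpin(rng, mature_len: int, decoy: str | None = None,
                          criteria: HairpinCriteria = HairpinCriteria(),
                          max_tries: int = 200):
    """Draw candidate precursors until the evaluator confirms the design.

    A planted (non-decoy) hairpin must pass every criterion; a decoy must
    fail *exactly* its intended criterion.  Returns (sequence, mature_start,
    mature_end, evaluation).
    """
    for _ in range(max_tries):
        seq, ms, me = _design_hairpin(rng, mature_len, decoy=decoy)
        ev = evaluate_hairpin(seq, ms, me, criteria)
        if decoy is None:
            if ev.passed:
                return seq, ms, me, ev
        else:
            failed = [k for k, ok in ev.flags.items() if not ok]
            if not ev.passed and ev.reject_reason is None and failed == [decoy]:
                return seq, ms, me, ev
    raise RuntimeError(f"could not design hairpin (decoy={decoy}) in {max_tries} tries")


# ---------------------------------------------------------------------------
# reference generation


def _draw_mature_len(rng) -> int:
    lens = np.array(list(MATURE_LENGTH_WEIGHTS))
    w = np.array(list(MATURE_LENGTH_WEIGHTS.values()))
    return int(rng.choice(lens, p=w / w.sum()))


def _stage_multipliers(shape: str, n_stages: int) -> np.ndarray:
    """Linear-scale per-stage multipliers; flat = 1 everywhere.

    Non-flat trajectories swing hard (~50-fold overall, as ageing-pathway
    miRNAs do across development), with every non-central stage at least
    ~4.6-fold (|log2| >= 2.2) away from the profile median.  That keeps
    differentially expressed miRNAs outside the |delta log2| < 2 subset
    the normalization regression is fitted on, so the planted nulls stay
    null after correction.
    """
    if shape == "flat":
        return np.ones(n_stages)
    t = np.linspace(1.0, -1.0, n_stages)  # +1 = earliest stage
    if shape == "decreasing":
        d = np.where(t == 0, 0.0, np.sign(t) * (3.0 + 0.4 * np.abs(t)))
    elif shape == "increasing":
        d = np.where(t == 0, 0.0, -np.sign(t) * (3.0 + 0.4 * np.abs(t)))
    elif shape == "peaked":
        d = 3.2 * np.cos(np.pi * t)
    else:
        raise ValueError(f"unknown shape {shape!r}")
    return 2.0 ** d


def generate_reference(config: SimConfig) -> ReferenceBundle:
    """Deterministically generate the full reference bundle for a config."""
    config.validate()
    rng = rng_for(config.seed, "reference")

    # --- known + novel precursors (verified pass-expected hairpins)
    precursors: dict[str, PrecursorInfo] = {}
    matures: dict[str, str] = {}
    fam_counters: dict[str, int] = {}
    hairpin_rows = []

    def next_name(family: str) -> str:
        i = fam_counters.get(family, 0)
        fam_counters[family] = i + 1
        return f"{family}{chr(ord('a') + i)}" if i < 26 else f"{family}-{i}"

    fam_weights = np.array([3.0, 2.0, 2.0] + [1.0] * (len(KNOWN_FAMILIES) - 3))
    fam_weights /= fam_weights.sum()

    for k in range(config.n_known_mirnas):
        family = str(rng.choice(KNOWN_FAMILIES, p=fam_weights))
        name = next_name(family)
        seq, ms, me, ev = make_verified_hairpin(rng, _draw_mature_len(rng))
        precursors[f"pre-{name}"] = PrecursorInfo(f"pre-{name}", seq, ms, me, family, False)
        matures[name] = seq[ms - 1 : me]
        hairpin_rows.append((f"pre-{name}", "planted", True, ""))

    for k in range(config.n_novel_mirnas):
        name = f"nov{k + 1}"
        seq, ms, me, ev = make_verified_hairpin(rng, _draw_mature_len(rng))
        precursors[f"pre-{name}"] = PrecursorInfo(f"pre-{name}", seq, ms, me, "novel", True)
        hairpin_rows.append((f"pre-{name}", "planted", True, ""))

    decoys: dict[str, PrecursorInfo] = {}
    for k in range(config.n_decoy_hairpins):
        cls = DECOY_CLASSES[k % len(DECOY_CLASSES)]
        name = f"decoy{k + 1}"
        seq, ms, me, ev = make_verified_hairpin(rng, 21, decoy=cls)
        decoys[f"pre-{name}"] = PrecursorInfo(f"pre-{name}", seq, ms, me, "decoy", True)
        hairpin_rows.append((f"pre-{name}", "decoy", False, cls))

    # --- group structure for the catalogue-matching stage:
    # most known precursors are embedded in the transcriptome (group 1);
    # a slice get only their mature planted (group 2); a slice get neither
    # (group 3: catalogue-only).
    known_names = [n for n in matures]
    n_g3 = max(1, config.n_known_mirnas // 8) if config.n_known_mirnas else 0
    n_g2 = max(1, config.n_known_mirnas // 8) if config.n_known_mirnas else 0
    group3 = set(known_names[-n_g3:]) if n_g3 else set()
    group2 = set(known_names[-(n_g3 + n_g2) : -n_g3]) if n_g2 else set()
    group_truth = {
        n: (3 if n in group3 else 2 if n in group2 else 1) for n in known_names
    }

    # --- transcripts hosting precursors, mature-only sites, and target sites
    embedded = [
        p for p in precursors.values()
        if not (p.name.removeprefix("pre-") in group2 | group3)
    ] + list(decoys.values())

    transcripts: dict[str, str] = {}
    t_serial = 0

    def new_transcript(insert: str | None = None, min_len: int = 700,
                       max_len: int = 1500, margin: int = 30) -> tuple[str, int]:
        nonlocal t_serial
        t_serial += 1
        name = f"Unigene{t_serial}"
        length = int(rng.integers(min_len, max_len + 1))
        if insert is not None and length < len(insert) + 2 * margin:
            raise ValueError("transcript too short to host the requested insert")
        seq = random_seq(rng, length)
        pos = 0
        if insert is not None:
            pos = int(rng.integers(margin, length - len(insert) - margin))
            seq = seq[:pos] + insert + seq[pos + len(insert):]
        transcripts[name] = seq
        return name, pos + 1

    # precursors are embedded between unpairable A/C spacers so the planted
    # hairpin — not chance pairing with transcript context — defines the
    # local structure; margins keep candidate excision windows un-clipped.
    # Hairpin-predicted precursors (novel + decoy) are additionally verified
    # in their actual excision-window context and re-embedded if the window
    # fold does not reproduce the intended verdict.
    spacer = 40
    flank_window = 150  # matches the novel-candidate excision default

    def window_verdict(p: PrecursorInfo, tseq: str, prec_pos: int) -> bool:
        tag_start = prec_pos + p.mature_start - 1  # 1-based on transcript
        tag_end = tag_start + len(p.mature) - 1
        s = max(1, tag_start - flank_window)
        e = min(len(tseq), tag_end + flank_window)
        ev = evaluate_hairpin(tseq[s - 1 : e], tag_start - s + 1, tag_end - s + 1)
        return ev.passed

    for p in embedded:
        hairpin_predicted = p.is_novel  # novel + decoy loci go through folding
        for attempt in range(30):
            pad5 = random_seq(rng, spacer, "AC")
            pad3 = random_seq(rng, spacer, "AC")
            tname, pos = new_transcript(pad5 + p.sequence + pad3, margin=170)
            prec_pos = pos + spacer
            if not hairpin_predicted:
                break
            want_pass = p.family != "decoy"
            if window_verdict(p, transcripts[tname], prec_pos) == want_pass:
                break
            del transcripts[tname]
        else:
            raise RuntimeError(f"could not embed {p.name} with a stable context")
        p.transcript, p.position = tname, prec_pos

    # group-2 matures: mature sequence only, no precursor context
    for n in group2:
        new_transcript(matures[n])

    # planted miRNA target sites (for degradome validation), category-cycled
    site_rows = []
    site_mirnas = [known_names[i % max(len(known_names), 1)]
                   for i in range(config.n_target_sites)]
    for i, mir in enumerate(site_mirnas):
        site_seq = revcomp(matures[mir])
        tname, pos = new_transcript(site_seq, min_len=700, max_len=1500)
        s, e = pos, pos + len(site_seq) - 1
        cleavage = s + len(site_seq) - 10  # opposite miRNA position 10
        site_rows.append((mir, tname, s, e, cleavage, i % 5))

    while len(transcripts) < config.n_transcripts:
        new_transcript(None)

    # --- contaminant and repeat references (kept clear of mature sequences)
    ncrna_refs: dict[str, tuple[str, str]] = {}
    classes = ["rRNA", "tRNA", "snRNA", "snoRNA"]
    all_matures = [m for m in matures.values()] + [
        p.mature for p in precursors.values() if p.is_novel
    ]
    for k in range(config.n_contaminant_refs):
        cls = classes[k % len(classes)]
        while True:
            seq = random_seq(rng, int(rng.integers(80, 300)))
            if not any(m in seq or revcomp(m) in seq for m in all_matures):
                break
        ncrna_refs[f"{cls}_{k + 1}"] = (cls, seq)
    repeat_refs = {f"repeat_{k + 1}": random_seq(rng, 200) for k in range(2)}

    # --- verbatim-embedding invariant
    for p in embedded:
        hits = sum(t.count(p.sequence) for t in transcripts.values())
        if hits != 1:
            raise RuntimeError(f"{p.name} occurs {hits} times in the transcriptome")

    # --- stage profiles.  Only the first two members of a shaped family
    # are differentially expressed (the usual case: a few homologs move,
    # the rest are stable), and DE miRNAs are capped in base abundance so
    # stage totals stay dominated by stable sequences — otherwise the
    # compositional swing would defeat the median-reference normalization
    # the pipeline is meant to exercise.
    shapes: dict[str, str] = {}
    for name in known_names:
        fam = precursors[f"pre-{name}"].family
        member = name.removeprefix(fam)
        is_lead = member in ("a", "b")
        if fam in DECREASING_FAMILIES and is_lead:
            shapes[name] = "decreasing"
        elif fam in INCREASING_FAMILIES and is_lead:
            shapes[name] = "increasing"
        elif fam in PEAKED_FAMILIES and is_lead:
            shapes[name] = "peaked"
        else:
            shapes[name] = "flat"
    for k in range(config.n_novel_mirnas):
        shapes[f"nov{k + 1}"] = "decreasing" if k % 5 == 0 else "flat"
    for d in decoys.values():
        shapes[d.name.removeprefix("pre-")] = "flat"

    # mature lookup for simulation includes novel + decoy matures
    sim_matures = dict(matures)
    for p in list(precursors.values()) + list(decoys.values()):
        if p.is_novel:
            sim_matures[p.name.removeprefix("pre-")] = p.mature

    bases = {}
    for name, shape in shapes.items():
        hi = 3.3 if shape == "flat" else 2.5
        bases[name] = 10 ** rng.uniform(1.3, hi)
    # rescale base abundances so the aggregate read mass per mature length
    # follows the configured length weights (the realized mode is then a
    # design property, not a lottery over heavy-tailed abundances)
    class_mass: dict[int, float] = {}
    for name, b in bases.items():
        class_mass[len(sim_matures[name])] = class_mass.get(len(sim_matures[name]), 0) + b
    total_mass = sum(class_mass.values())
    target = {L: MATURE_LENGTH_WEIGHTS[L] for L in class_mass}
    target_total = sum(target.values())
    for name in bases:
        L = len(sim_matures[name])
        bases[name] *= (target[L] / target_total) / (class_mass[L] / total_mass)

    rows = {}
    for name, shape in shapes.items():
        rows[name] = bases[name] * _stage_multipliers(shape, len(config.stages))
    expected = pd.DataFrame.from_dict(rows, orient="index", columns=list(config.stages))
    profile = StageProfile(config.stages, expected, shapes)

    # --- annotation table: 1-3 generic terms per transcript, plus one term
    # concentrated on the target-site transcripts (enrichment signal)
    terms = [f"GO:{i:07d}" for i in range(1, 11)] + ["ko00030", "ko00710", "ko00941"]
    annot_rows = []
    target_transcripts = {r[1] for r in site_rows}
    for t in transcripts:
        for term in rng.choice(terms, size=int(rng.integers(1, 4)), replace=False):
            annot_rows.append((t, str(term)))
        if t in target_transcripts:
            annot_rows.append((t, "GO:0009409"))  # response to cold
    annotation = pd.DataFrame(sorted(set(annot_rows)), columns=["transcript", "term"])

    truth = {
        "mirnas": pd.DataFrame(
            {
                "mirna": list(shapes),
                "family": [
                    precursors.get(f"pre-{n}", decoys.get(f"pre-{n}")).family
                    for n in shapes
                ],
                "shape": list(shapes.values()),
                "is_novel": [
                    precursors.get(f"pre-{n}", decoys.get(f"pre-{n}")).is_novel
                    for n in shapes
                ],
                "is_decoy": [f"pre-{n}" in decoys for n in shapes],
                "de_expected": [s != "flat" for s in shapes.values()],
            }
        ),
        "groups": pd.DataFrame(
            {"mirna": known_names, "group": [group_truth[n] for n in known_names]}
        ),
        "hairpins": pd.DataFrame(
            hairpin_rows, columns=["precursor", "kind", "expected_pass", "violated_criterion"]
        ),
        "target_sites": pd.DataFrame(
            site_rows,
            columns=["mirna", "transcript", "site_start", "site_end",
                     "cleavage_pos", "intended_category"],
        ),
        "sim_matures": pd.DataFrame(
            {"mirna": list(sim_matures), "mature": list(sim_matures.values())}
        ),
    }

    bundle = ReferenceBundle(
        config=config,
        transcriptome=transcripts,
        precursors={**precursors, **decoys},
        mature_catalogue=matures,
        ncrna_refs=ncrna_refs,
        repeat_refs=repeat_refs,
        annotation_table=annotation,
        profile=profile,
        truth=truth,
    )
    return bundle


# ---------------------------------------------------------------------------
# library simulation


def _phred_string(rng, length: int, mean_q: int, spread: int = 3) -> str:
    qs = np.clip(rng.integers(mean_q - spread, mean_q + spread + 1, size=length), 2, 41)
    return "".join(chr(33 + int(q)) for q in qs)


def simulate_srna_library(
    bundle: ReferenceBundle,
    stage: str,
    replicate: int = 1,
    depth: int | None = None,
    seed: int | None = None,
) -> list[tuple[str, str, str]]:
    """Simulate one small-RNA library as (id, sequence, quality) records.

    Valid reads are mature sequences (with 0-2 nt of 3' isomiR trimming)
    followed by the 3' adapter, read through to the raw read length; counts
    follow a negative binomial around the stage expectation.  Junk,
    contaminant and low-quality reads are mixed in at the configured
    fractions.
    """
    cfg = bundle.config
    if stage not in cfg.stages:
        raise ValueError(f"unknown stage {stage!r}")
    depth = cfg.library_depth if depth is None else depth
    if depth == 0:
        warnings.warn("depth=0: returning an empty library")
        return []
    rng = rng_for(cfg.seed if seed is None else seed, "srna", stage, replicate)

    p_junk, p_cont, p_low = cfg.junk_fraction, cfg.contaminant_fraction, cfg.lowqual_fraction
    p_valid = 1 - p_junk - p_cont - p_low

    matures = dict(zip(bundle.truth["sim_matures"]["mirna"],
                       bundle.truth["sim_matures"]["mature"]))
    mu = bundle.profile.expected.loc[list(matures), stage].to_numpy(float)
    mu = mu / mu.sum() * depth * p_valid
    if cfg.count_model == "poisson":
        counts = rng.poisson(mu)
    else:
        r = 1.0 / cfg.nb_dispersion
        counts = rng.negative_binomial(r, r / (r + np.maximum(mu, 1e-9)))

    # junk / contaminant / low-quality counts follow the *realized* valid
    # total so empirical class fractions converge to the configured ones
    realized = max(int(counts.sum()), 1)
    n_junk = rng.poisson(realized * p_junk / p_valid)
    n_cont = rng.poisson(realized * p_cont / p_valid)
    n_low = rng.poisson(realized * p_low / p_valid)

    reads: list[tuple[str, str, str]] = []
    serial = 0

    def emit(insert: str, mean_q: int = 38):
        nonlocal serial
        serial += 1
        raw = insert + cfg.adapter
        if len(raw) < cfg.raw_read_length:
            raw += random_seq(rng, cfg.raw_read_length - len(raw))
        raw = raw[: cfg.raw_read_length]
        reads.append(
            (f"{stage}_{replicate}:{serial}", raw, _phred_string(rng, len(raw), mean_q))
        )

    trims = np.array([0, 1, 2])
    for (name, mat), c in zip(matures.items(), counts):
        if c <= 0:
            continue
        tvec = rng.choice(trims, size=int(c), p=np.array(cfg.isomir_probs))
        for t in tvec:
            t = min(int(t), len(mat) - 18)  # never trim below the valid range
            emit(mat[: len(mat) - t] if t else mat)

    for _ in range(n_low):
        mat = matures[str(rng.choice(list(matures)))]
        emit(mat, mean_q=10)

    for _ in range(n_junk):
        length = int(rng.integers(18, 26))
        ins = "".join(
            "N" if rng.random() < 0.3 else random_seq(rng, 1) for _ in range(length)
        )
        if ins.count("N") == 0:  # guarantee poly-N content
            ins = "N" * max(3, length // 3) + ins[max(3, length // 3):]
        emit(ins)

    nc_names = list(bundle.ncrna_refs)
    for _ in range(n_cont):
        _, ref = bundle.ncrna_refs[str(rng.choice(nc_names))]
        length = int(rng.integers(18, 26))
        start = int(rng.integers(0, len(ref) - length + 1))
        sub = ref[start : start + length]
        if rng.random() < 0.5:
            sub = revcomp(sub)
        emit(sub)

    order = rng.permutation(len(reads))
    return [reads[i] for i in order]


def simulate_degradome(
    bundle: ReferenceBundle,
    seed: int | None = None,
    background_rate: float = 0.1,
    tag_len: tuple[int, int] = (20, 21),
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Degradome 5'-tag library for the bundle's planted target sites.

    For each planted site the tag 5' end is the transcript nucleotide
    opposite miRNA position 10.  Per-site signal abundance is set by the
    intended evidence category (dominant unique peak for 0, tied peaks for
    1, above-median for 2, at/below-median for 3, singleton for 4); decoy
    peaks and forced singletons shape the rest of the transcript profile,
    and uniform background tags are added at ``background_rate`` x signal.
    Returns (tags, site plan table).
    """
    cfg = bundle.config
    rng = rng_for(cfg.seed if seed is None else seed, "degradome")
    sites = bundle.truth["target_sites"]
    tags: list[tuple[str, str]] = []
    serial = 0

    def emit(transcript: str, pos: int):
        """One tag whose 5' end is 1-based ``pos`` on ``transcript``."""
        nonlocal serial
        serial += 1
        seq = bundle.transcriptome[transcript]
        L = int(rng.integers(tag_len[0], tag_len[1] + 1))
        frag = seq[pos - 1 : pos - 1 + L]
        if len(frag) < tag_len[0]:
            raise ValueError(f"tag at {transcript}:{pos} runs off the transcript end")
        tags.append((f"deg:{serial}", frag))

    plan_rows = []
    for _, row in sites.iterrows():
        t, pos, cat = row["transcript"], int(row["cleavage_pos"]), int(row["intended_category"])
        tlen = len(bundle.transcriptome[t])
        if not (1 <= pos <= tlen):
            raise ValueError(f"planted site outside transcript {t}")

        def rand_pos(n, lo=1):
            # background/decoy positions away from the planted cleavage site
            out = []
            while len(out) < n:
                p = int(rng.integers(lo, tlen - tag_len[1]))
                if abs(p - pos) > 3:
                    out.append(p)
            return out

        if cat == 0:
            n_sig, decoy_counts = 40, []
        elif cat == 1:
            n_sig, decoy_counts = 20, [20]
        elif cat == 2:
            n_sig, decoy_counts = 8, [25] + [1] * 6
        elif cat == 3:
            n_sig, decoy_counts = 2, [25] + [3] * 10 + [1] * 4
        else:
            n_sig, decoy_counts = 1, [4, 3]
        for _ in range(n_sig):
            emit(t, pos)
        for dpos, dcount in zip(rand_pos(len(decoy_counts)), decoy_counts):
            for _ in range(dcount):
                emit(t, dpos)
        n_bg = rng.poisson(background_rate * n_sig)
        for bpos in rand_pos(n_bg):
            emit(t, bpos)
        plan_rows.append((row["mirna"], t, pos, cat, n_sig))

    plan = pd.DataFrame(
        plan_rows, columns=["mirna", "transcript", "cleavage_pos",
                            "intended_category", "signal_tags"]
    )
    return tags, plan


def simulate_ct_table(
    expression: pd.DataFrame,
    reference_genes: list[str] | tuple[str, ...] = ("5S",),
    baseline: float = 30.0,
    reference_ct: float = 15.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Ct table from a gene x sample linear-scale expression matrix.

    Ct = baseline - log2(expression) + noise for targets; reference genes
    are flat at ``reference_ct`` (+ noise).  Zero-noise tables make the
    2^-ddCt arithmetic exact.
    """
    if (expression.values <= 0).any():
        raise ValueError("expression must be strictly positive for a Ct table")
    rng = rng_for(seed, "ct")
    ct = baseline - np.log2(expression)
    for g in reference_genes:
        ct.loc[g] = reference_ct
    if noise_sd > 0:
        ct = ct + rng.normal(0, noise_sd, size=ct.shape)
    return ct


# ---------------------------------------------------------------------------
# writers


def write_fasta(records: dict[str, str] | list[tuple[str, str]], path) -> None:
    items = records.items() if isinstance(records, dict) else records
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n{seq}\n")


def write_fastq(reads: list[tuple[str, str, str]], path) -> None:
    with open(path, "w") as fh:
        for rid, seq, qual in reads:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def write_bundle(bundle: ReferenceBundle, outdir) -> None:
    """Write the bundle as FASTA/FASTQ/TSV files under ``outdir``."""
    import os

    os.makedirs(outdir, exist_ok=True)
    j = lambda name: os.path.join(outdir, name)
    write_fasta(bundle.transcriptome, j("transcriptome.fasta"))
    write_fasta(
        [
            (
                f"{p.name} family={p.family} mature={p.mature_start}-{p.mature_end}",
                p.sequence,
            )
            for p in bundle.precursors.values()
            if not p.is_novel
        ],
        j("precursors.fasta"),
    )
    write_fasta(bundle.mature_catalogue, j("matures.fasta"))
    write_fasta(
        [(f"{n} class={c}", s) for n, (c, s) in bundle.ncrna_refs.items()],
        j("ncrna.fasta"),
    )
    write_fasta(bundle.repeat_refs, j("repeats.fasta"))
    bundle.annotation_table.to_csv(j("annotation.tsv"), sep="\t", index=False)
    bundle.profile.expected.rename_axis("mirna").to_csv(j("stage_profile.tsv"), sep="\t")
    for key, df in bundle.truth.items():
        df.to_csv(j(f"truth_{key}.tsv"), sep="\t", index=False)
    for stage, rep in bundle.config.samples:
        reads = simulate_srna_library(bundle, stage, rep)
        write_fastq(reads, j(f"srna_{stage}_rep{rep}.fastq"))
    tags, plan = simulate_degradome(bundle)
    write_fasta(tags, j("degradome.fasta"))
    plan.to_csv(j("degradome_plan.tsv"), sep="\t", index=False)
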