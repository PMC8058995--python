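"""End-to-end pipeline over a synthetic (or real) study bundle.

Chains the stages: preprocess raw libraries -> identify known miRNAs and
predict novel ones -> normalize and call differential expression ->
validate targets against the degradome -> build the coexpression network.
Each stage is a thin call into the corresponding module; the returned
:class:`PipelineResult` carries every intermediate table so analyses and
tests can inspect any step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import catalog, degradome, expression, network, preprocess
from .simulate import ReferenceBundle, simulate_degradome, simulate_srna_library


@dataclass
class PipelineResult:
    tags: dict = field(default_factory=dict)
    stats: pd.DataFrame | None = None
    counts: pd.DataFrame | None = None
    known_records: list = field(default_factory=list)
    novel_records: list = field(default_factory=list)
    novel_summary: pd.DataFrame | None = None
    mirna_counts: pd.DataFrame | None = None
    expr: pd.DataFrame | None = None
    norm_fits: list = field(default_factory=list)
    de_table: pd.DataFrame | None = None
    targets: pd.DataFrame | None = None
    net: network.CoexpressionNetwork | None = None
    design: dict[str, str] = field(default_factory=dict)


def run_pipeline(
    bundle: ReferenceBundle,
    run_novel: bool = True,
    run_degradome: bool = True,
    run_network: bool = True,
    depth: int | None = None,
) -> PipelineResult:
    """Run the full analysis over simulated libraries from ``bundle``."""
    cfg = bundle.config
    res = PipelineResult()
    params = preprocess.FilterParams(adapter=cfg.adapter)

    libraries = {}
    for stage, rep in cfg.samples:
        lib = f"{stage}_rep{rep}"
        reads = simulate_srna_library(bundle, stage, rep, depth=depth)
        libraries[lib] = [(rid, seq, [ord(c) - 33 for c in qual]) for rid, seq, qual in reads]
        res.design[lib] = stage

    res.tags, res.stats, _ = preprocess.preprocess_libraries(
        libraries, params, bundle.ncrna_refs, bundle.repeat_refs
    )
    res.counts = preprocess.count_matrix(res.tags, list(libraries))

    # --- known miRNAs
    prec = {
        p.name: (p.sequence, p.mature_start, p.mature_end)
        for p in bundle.precursors.values()
        if not p.is_novel
    }
    fams = {p.name: p.family for p in bundle.precursors.values()}
    valid_tags = list(res.counts.index)
    matches = catalog.map_to_precursors(valid_tags, prec)
    res.known_records = catalog.classify_groups(matches, prec, bundle.transcriptome, fams)

    matched_tags = {m.tag for m in matches}

    # --- novel miRNAs from unannotated transcriptome-mapped tags
    if run_novel:
        unannot = [t for t in valid_tags if t not in matched_tags]
        abundance = res.counts.sum(axis=1).to_dict()
        loci = catalog.find_novel_candidates(unannot, bundle.transcriptome)
        evals = catalog.evaluate_candidates(loci, bundle.transcriptome, abundance)
        res.novel_records, res.novel_summary = catalog.catalogue_novel(evals)

    # --- per-miRNA count matrix: sum tag counts assigned to each mature
    mature_of = {}
    for rec in res.known_records:
        cur = mature_of.get(rec.name)
        if cur is None or len(rec.mature) > len(cur):  # isomiRs: keep full mature
            mature_of[rec.name] = rec.mature
    for rec in res.novel_records:
        mature_of[rec.name] = rec.mature
    rows = {}
    for name, mat in mature_of.items():
        sel = [t for t in res.counts.index if t == mat or (mat.startswith(t) and len(mat) - len(t) <= 2)]
        if sel:
            rows[name] = res.counts.loc[sel].sum(axis=0)
    res.mirna_counts = pd.DataFrame(rows).T

    # --- normalization + DE
    res.expr, res.norm_fits = expression.normalize_matrix(res.mirna_counts)
    res.de_table = expression.anova_de(res.expr, res.design)

    # --- degradome target validation
    if run_degradome:
        tags, _plan = simulate_degradome(bundle)
        profiles, _ = degradome.map_degradome(tags, bundle.transcriptome)
        target_transcripts = set(bundle.truth["target_sites"]["transcript"])
        alignments = []
        for name, mat in mature_of.items():
            for tname in target_transcripts:
                alignments.extend(
                    degradome.predict_sites(mat, bundle.transcriptome[tname], name, tname)
                )
        sites = degradome.call_targets(alignments, profiles)
        res.targets = degradome.targets_table(sites)

    # --- coexpression network over the normalized miRNA expression
    if run_network and res.expr is not None and len(res.expr) >= 4:
        net = network.build_network(res.expr, network.NetworkParams())
        res.net = network.detect_modules(net, res.expr)

    return res
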