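"""End-to-end orchestration of the ortholog-selection/tree pipeline.

Mirrors the study's funnel: reference proteomes -> pairwise Inparanoid
seeding -> transitive-closure core groups -> phylogenetic orthology
filter -> top-hit profile search in the transcriptomes -> lineage
coverage and composition-bias filters -> per-gene trimming -> supermatrix
-> ML tree with bootstrap.  Every stage logs input/output counts so the
selection funnel is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .io_formats import (
    MultipleAlignment,
    Proteome,
    SeqRecord,
    Supermatrix,
    log_stage,
    split_id,
)
from .ml_engine import (
    SubstitutionModel,
    bootstrap,
    get_model,
    nni_search,
    wag_model,
)
from .ml_engine.likelihood import encode_alignment
from .ortholog_inference import (
    CladeConstraint,
    OrthologGroup,
    SimilarityEngine,
    build_core_orthologs,
    cluster_inparalogs,
    phylogenetic_filter,
    reciprocal_best_hits,
)
from .profile_search import build_profile, search_top_hit
from .supermatrix import (
    DEFAULT_LINEAGE_MAP,
    DEFAULT_REQUIRED_LINEAGES,
    TrimParams,
    composition_test,
    concatenate,
    coverage_filter,
    coverage_report,
    progressive_align,
    trim_columns,
)
from .synthetic_study import (
    CHLOROPHYTES,
    LAND_PLANTS,
    REFERENCE_TAXA,
    TRANSCRIPTOME_TAXA,
    SimulationConfig,
    generate_study,
)

DEFAULT_CONSTRAINTS = [
    CladeConstraint("land plants", frozenset(LAND_PLANTS)),
    CladeConstraint("chlorophyte outgroups", frozenset(CHLOROPHYTES)),
]


@dataclass
class PipelineSettings:
    """Thresholds shared by the pipeline stages."""

    matrix: str = "BLOSUM62"
    gap_open: float = 11.0
    gap_extend: float = 1.0
    score_cutoff: float = 40.0
    confidence_cutoff: float = 0.05
    min_profile_score: float = 30.0
    trim: TrimParams = field(default_factory=TrimParams)
    composition_alpha: float = 0.05
    filter_model: str = "WAG+G"
    tree_model: str = "LG+G+F"
    gamma_alpha: float = 1.0
    bootstrap_reps: int = 20


@dataclass
class PipelineResult:
    core_groups: list[OrthologGroup]
    filtered_groups: list[OrthologGroup]
    extended_groups: list[OrthologGroup]
    matrix: Optional[Supermatrix]
    coverage: Optional[object]
    tree: Optional[object]
    support: Optional[dict]
    funnel: dict[str, int]
    gene_alignments: dict[str, MultipleAlignment] = field(default_factory=dict)


# ---------------------------------------------------------------------- #
# stage drivers
# ---------------------------------------------------------------------- #
def support_for_clade(
    support: Mapping[frozenset, float], all_taxa: Sequence[str], ingroup: Sequence[str]
) -> Optional[float]:
    """Bootstrap percent for a split given as either of its sides."""
    total = frozenset(all_taxa)
    group = frozenset(ingroup)
    anchor = min(total)
    canonical = group if anchor not in group else total - group
    return support.get(canonical)


def group_alignment(
    group: OrthologGroup,
    sequences: Mapping[str, SeqRecord],
    taxa: Sequence[str],
) -> MultipleAlignment:
    """Align one representative per taxon; rows renamed to taxon names."""
    records = []
    for taxon in taxa:
        ids = group.members.get(taxon)
        if not ids:
            continue
        rep = group.representative(taxon)
        records.append(SeqRecord(rep, sequences[rep].residues))
    aln = progressive_align(records)
    return MultipleAlignment(
        {split_id(name)[0]: seq for name, seq in aln.rows.items()}
    )


def infer_core_orthologs(
    proteomes: Mapping[str, Proteome],
    settings: PipelineSettings,
    constraints: Sequence[CladeConstraint] = tuple(DEFAULT_CONSTRAINTS),
) -> tuple[list[OrthologGroup], list[OrthologGroup], dict[str, int], SimilarityEngine]:
    """Pairwise RBH + in-paralogs, TC extension, phylogenetic filter."""
    engine = SimilarityEngine(settings.matrix, settings.gap_open, settings.gap_extend)
    taxa = sorted(proteomes)
    pairwise_groups = []
    for i, ta in enumerate(taxa):
        for tb in taxa[i + 1 :]:
            seeds = reciprocal_best_hits(
                proteomes[ta], proteomes[tb], engine, settings.score_cutoff
            )
            for seed in seeds:
                pairwise_groups.append(
                    cluster_inparalogs(
                        seed,
                        proteomes[ta],
                        proteomes[tb],
                        engine,
                        settings.confidence_cutoff,
                    )
                )
    core, n_discarded = build_core_orthologs(pairwise_groups, taxa)

    sequences = {rec.id: rec for p in proteomes.values() for rec in p}
    filter_model = get_model(
        settings.filter_model, gamma_alpha=settings.gamma_alpha
    ) if "+F" not in settings.filter_model else None
    kept = []
    for group in core:
        aln = group_alignment(group, sequences, taxa)
        trimmed, _ = trim_columns(aln, settings.trim, gene=group.name)
        model = filter_model or wag_model(settings.gamma_alpha)
        tree = nni_search(None, trimmed, model).tree
        ok, _reason = phylogenetic_filter(group, tree, constraints)
        if ok:
            kept.append(group)
    funnel = {
        "pairwise_groups": len(pairwise_groups),
        "core_components_discarded": n_discarded,
        "core_groups": len(core),
        "filtered_core_groups": len(kept),
    }
    log_stage("phylo-filter", len(core), len(kept))
    return core, kept, funnel, engine


def extend_with_profiles(
    groups: Sequence[OrthologGroup],
    transcriptomes: Mapping[str, Proteome],
    sequences: Mapping[str, SeqRecord],
    reference_taxa: Sequence[str],
    settings: PipelineSettings,
) -> tuple[list[OrthologGroup], dict[str, int]]:
    """Top-hit profile search of every unigene set for every core group.

    Only groups with at least one transcriptome hit are retained.
    """
    extended = []
    for group in groups:
        aln = group_alignment(group, sequences, reference_taxa)
        profile = build_profile(aln)
        members = {t: list(ids) for t, ids in group.members.items()}
        confidences = dict(group.confidences)
        n_hits = 0
        for taxon in sorted(transcriptomes):
            hit = search_top_hit(
                profile, transcriptomes[taxon], settings.min_profile_score
            )
            if hit is not None:
                members.setdefault(taxon, []).append(hit)
                confidences[hit] = 1.0
                n_hits += 1
        if n_hits >= 1:
            extended.append(
                OrthologGroup(
                    name=group.name,
                    members=members,
                    seed=group.seed,
                    provenance="extended",
                    confidences=confidences,
                )
            )
    log_stage("hamstr", len(groups), len(extended), ">=1 transcriptome hit")
    return extended, {"extended_groups": len(extended)}


def assemble_matrix(
    groups: Sequence[OrthologGroup],
    sequences: Mapping[str, SeqRecord],
    taxa: Sequence[str],
    settings: PipelineSettings,
    lineage_map: Mapping[str, str] = DEFAULT_LINEAGE_MAP,
    required_lineages: Sequence[str] = DEFAULT_REQUIRED_LINEAGES,
    reference_taxa: Sequence[str] = tuple(REFERENCE_TAXA),
) -> tuple[Optional[Supermatrix], dict[str, MultipleAlignment], dict[str, int]]:
    """Coverage filter -> composition filter -> per-gene trim -> concatenate."""
    covered = coverage_filter(groups, lineage_map, required_lineages, reference_taxa)
    alignments: dict[str, MultipleAlignment] = {}
    n_flagged = 0
    for group in covered:
        aln = group_alignment(group, sequences, taxa)
        result = composition_test(aln, settings.composition_alpha)
        if result.flagged:
            n_flagged += 1
            continue
        trimmed, _ = trim_columns(aln, settings.trim, gene=group.name)
        alignments[group.name] = trimmed
    log_stage("composition-filter", len(covered), len(covered) - n_flagged)
    funnel = {
        "coverage_passed": len(covered),
        "composition_flagged": n_flagged,
        "matrix_genes": len(alignments),
    }
    if not alignments:
        return None, {}, funnel
    matrix = concatenate(alignments, list(taxa))
    return matrix, alignments, funnel


def infer_tree(
    matrix: Supermatrix,
    settings: PipelineSettings,
    seed: int = 0,
):
    """ML tree on the supermatrix with bootstrap supports."""
    aln = matrix.alignment
    model = _matrix_model(aln, settings)
    best = nni_search(None, aln, model)
    annotated, support = bootstrap(
        aln, model, settings.bootstrap_reps, seed=seed, best_tree=best.tree
    )
    return best, annotated, support


def _matrix_model(aln: MultipleAlignment, settings: PipelineSettings) -> SubstitutionModel:
    taxa = sorted(aln.rows)
    codes = encode_alignment(aln, taxa)
    observed = codes[codes < 20]
    freqs = np.bincount(observed, minlength=20).astype(float)
    freqs = (freqs + 1.0) / (freqs.sum() + 20.0)
    return get_model(
        settings.tree_model,
        empirical_frequencies=freqs,
        gamma_alpha=settings.gamma_alpha,
    )


# ---------------------------------------------------------------------- #
# whole synthetic study
# ---------------------------------------------------------------------- #
def run_study(
    cfg: SimulationConfig,
    settings: Optional[PipelineSettings] = None,
    bootstrap_seed: int = 0,
    with_tree: bool = True,
):
    """Simulate a study and run the full pipeline on it.

    Returns (truth, PipelineResult).
    """
    settings = settings or PipelineSettings()
    truth, per_taxon, _ = generate_study(cfg)
    ref_proteomes = {
        t: Proteome(t, sorted(per_taxon[t], key=lambda r: r.id))
        for t in REFERENCE_TAXA
    }
    transcriptomes = {
        t: Proteome(t, sorted(per_taxon[t], key=lambda r: r.id))
        for t in TRANSCRIPTOME_TAXA
    }
    sequences = {rec.id: rec for recs in per_taxon.values() for rec in recs}
    taxa = cfg.species_tree.leaf_names()

    core, filtered, funnel, _engine = infer_core_orthologs(ref_proteomes, settings)
    extended, f2 = extend_with_profiles(
        filtered, transcriptomes, sequences, REFERENCE_TAXA, settings
    )
    funnel.update(f2)
    matrix, gene_alns, f3 = assemble_matrix(
        extended, sequences, taxa, settings
    )
    funnel.update(f3)

    tree_res, annotated, support = None, None, None
    if with_tree and matrix is not None:
        tree_res, annotated, support = infer_tree(matrix, settings, seed=bootstrap_seed)
    coverage = (
        coverage_report(matrix, TRANSCRIPTOME_TAXA) if matrix is not None else None
    )
    result = PipelineResult(
        core_groups=core,
        filtered_groups=filtered,
        extended_groups=extended,
        matrix=matrix,
        coverage=coverage,
        tree=annotated if annotated is not None else (tree_res.tree if tree_res else None),
        support=support,
        funnel=funnel,
        gene_alignments=gene_alns,
    )
    return truth, result
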