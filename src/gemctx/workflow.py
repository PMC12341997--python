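"""End-to-end convenience pipeline used by the CLI and the recovery tests:
preprocess both omics tables, collapse to per-feature values, map through
GPRs, fuse, scale, classify, run iMAT, and extract the context model."""

from __future__ import annotations

from dataclasses import dataclass

from .contextualize import (
    IMATSolution,
    ReactionClassification,
    classify_reactions,
    extract_context_model,
    imat,
)
from .integration import (
    ActivityVector,
    integrate,
    map_to_reactions,
    to_threshold_scale,
)
from .model import MetabolicModel
from .preprocess import (
    OmicsTable,
    filter_low_count_genes,
    filter_proteins_by_validity,
    group_means,
    knn_impute,
    log2_transform,
)


@dataclass
class ContextualizationResult:
    transcript_av: ActivityVector
    protein_av: ActivityVector
    integrated: ActivityVector
    scaled: ActivityVector
    classification: ReactionClassification
    imat_solution: IMATSolution
    context_model: MetabolicModel


def preprocess_transcripts(table: OmicsTable, min_total: int = 10, k: int = 10) -> OmicsTable:
    table = filter_low_count_genes(table, min_total=min_total)
    table = log2_transform(table, pseudocount=1.0)
    if table.missing_mask.any():
        table = knn_impute(table, k=k)
    return table


def preprocess_proteins(
    table: OmicsTable, min_valid_fraction: float = 0.70, k: int = 10
) -> OmicsTable:
    table = log2_transform(table, pseudocount=1.0)
    table = filter_proteins_by_validity(table, min_valid_fraction=min_valid_fraction)
    if table.missing_mask.any():
        table = knn_impute(table, k=k)
    return table


def contextualize_from_omics(
    model: MetabolicModel,
    transcript: OmicsTable,
    protein: OmicsTable,
    group: str | None = None,
    n_components: int = 2,
    low_threshold: float = -500.0,
    high_threshold: float = 500.0,
    epsilon: float = 1.0,
) -> ContextualizationResult:
    t_clean = preprocess_transcripts(transcript)
    p_clean = preprocess_proteins(protein)
    t_av = map_to_reactions(model, group_means(t_clean, group), provenance="transcript")
    p_av = map_to_reactions(model, group_means(p_clean, group), provenance="protein")
    fused = integrate(t_av, p_av, n_components=n_components)
    scaled = to_threshold_scale(fused, low=low_threshold, high=high_threshold)
    classification = classify_reactions(
        scaled, model, low_threshold=low_threshold, high_threshold=high_threshold
    )
    solution = imat(model, classification, epsilon=epsilon)
    context = extract_context_model(model, solution, classification)
    return ContextualizationResult(
        transcript_av=t_av,
        protein_av=p_av,
        integrated=fused,
        scaled=scaled,
        classification=classification,
        imat_solution=solution,
        context_model=context,
    )
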