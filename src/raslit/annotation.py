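"""Biology-facing outputs: branch reduction, gene ranking, shared-gene filter.

The ten pathway labels collapse into three disease branches (hypertension-,
cardiac-disease- and diabetes-related). A binary label matrix reduces by OR
over member pathways; a probability matrix reduces by MAX (a branch is hit if
any of its pathways is). Per-pathway gene rankings sort by predicted
probability, descending, with lexicographic tie-breaks, mirroring the
"most important gene by max predicted probability" readout; the shared-gene
filter selects genes scoring above a threshold in several pathways at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import PathwayRegistry
from .models import LabelMatrix, ScoreMatrix


def reduce_to_branches(matrix: LabelMatrix | ScoreMatrix,
                       registry: PathwayRegistry):
    """Collapse pathway columns into branch columns.

    Binary labels → OR over a branch's member pathways; probability scores →
    MAX. The result's column order follows the registry's branch order. Any
    pathway column missing from the branch map is a hard error.
    """
    missing = [p for p in matrix.pathway_ids if p not in registry.branch_map]
    if missing:
        raise KeyError(f"pathway(s) missing from branch map: {missing}")
    branches = registry.branch_ids
    col = {b: j for j, b in enumerate(branches)}
    values = np.asarray(matrix.values.toarray()
                        if hasattr(matrix.values, "toarray") else matrix.values)
    out = np.zeros((values.shape[0], len(branches)), dtype=float)
    for j, p in enumerate(matrix.pathway_ids):
        b = col[registry.branch_map[p]]
        out[:, b] = np.maximum(out[:, b], values[:, j])
    if isinstance(matrix, LabelMatrix):
        return LabelMatrix(values=out.astype(np.int8),
                           gene_ids=matrix.gene_ids, pathway_ids=branches)
    return ScoreMatrix(values=out, gene_ids=matrix.gene_ids,
                       pathway_ids=branches)


@dataclass
class GeneRanking:
    """Per-pathway descending (gene_id, probability) lists."""

    rankings: dict[str, list[tuple[str, float]]]

    def top(self, pathway_id: str) -> str:
        return self.rankings[pathway_id][0][0]

    def table(self, top_n: int = 10) -> list[tuple[str, int, str, float]]:
        """Flat (pathway, rank, gene_id, probability) rows, top-n per pathway."""
        rows = []
        for pathway, ranking in self.rankings.items():
            for rank, (gene, prob) in enumerate(ranking[:top_n], start=1):
                rows.append((pathway, rank, gene, prob))
        return rows


def rank_genes(scores: ScoreMatrix) -> GeneRanking:
    """Per-pathway gene ranking by predicted probability, descending.

    Ties break lexicographically by gene_id, making the ranking a
    deterministic permutation of the genes for every pathway.
    """
    values = np.asarray(scores.values)
    rankings: dict[str, list[tuple[str, float]]] = {}
    for j, pathway in enumerate(scores.pathway_ids):
        order = sorted(zip(scores.gene_ids, values[:, j]),
                       key=lambda t: (-t[1], t[0]))
        rankings[pathway] = [(g, float(v)) for g, v in order]
    return GeneRanking(rankings=rankings)


def shared_high_score_genes(scores: ScoreMatrix, threshold: float = 0.9,
                            min_pathways: int = 3
                            ) -> list[tuple[str, list[str]]]:
    """Genes scoring ≥ threshold in at least ``min_pathways`` pathways.

    Returns (gene_id, qualifying pathway list) pairs, gene order preserved;
    an empty result is allowed.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    if min_pathways < 1:
        raise ValueError("min_pathways must be >= 1")
    values = np.asarray(scores.values)
    hits = values >= threshold
    out = []
    for i, gene in enumerate(scores.gene_ids):
        qualifying = [p for j, p in enumerate(scores.pathway_ids) if hits[i, j]]
        if len(qualifying) >= min_pathways:
            out.append((gene, qualifying))
    return out


def write_ranking_tsv(ranking: GeneRanking, path, top_n: int = 10) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("pathway\trank\tgene_id\tprobability\n")
        for pathway, rank, gene, prob in ranking.table(top_n):
            fh.write(f"{pathway}\t{rank}\t{gene}\t{prob:.6g}\n")
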