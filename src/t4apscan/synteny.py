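"""Flanking-gene context of T4aP clusters and conserved-anchor tests.

The comparative signal here is positional: which genes sit immediately up-
and downstream of a cluster, and whether the riboflavin kinase gene (ribF)
is conserved directly downstream of pilB — the synteny marker separating
clustered-organization lineages (ribF linked) from dispersed ones (ribF
elsewhere in the genome).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cluster_detect import GeneCluster
from .genome_io import GeneFeature, Genome
from .homology import FamilyAssignment, UNASSIGNED

FLANK_K = 5
MAX_INTERVENING = 1


@dataclass(frozen=True)
class AnchorEvidence:
    family_a: str
    family_b: str
    gene_a: str | None
    gene_b: str | None
    intervening: int | None
    linked: bool


@dataclass
class SyntenyContext:
    genome_id: str
    cluster: GeneCluster
    upstream: list[GeneFeature]  # nearest first: offset -1, -2, ...
    downstream: list[GeneFeature]  # offset +1, +2, ...


def flanking_context(genome: Genome, cluster: GeneCluster, k: int = FLANK_K) -> SyntenyContext:
    """The k genes before the first member and after the last member of the
    cluster on its contig, truncated at contig ends. Cluster-internal genes
    (including gap occupants) are never part of the context."""
    contig = genome.contig(cluster.contig_id)
    genes = contig.genes
    first, last = cluster.first_locus_index, cluster.last_locus_index
    upstream = [genes[i] for i in range(first - 1, max(first - k - 1, -1), -1)]
    downstream = [genes[i] for i in range(last + 1, min(last + k + 1, len(genes)))]
    return SyntenyContext(genome.genome_id, cluster, upstream, downstream)


def anchor_adjacent(
    genome: Genome,
    assignments: Iterable[FamilyAssignment],
    family_a: str,
    family_b: str,
    max_intervening: int = MAX_INTERVENING,
) -> AnchorEvidence:
    """True iff some family_a gene has a family_b gene downstream of it — in
    family_a's transcription direction, on the same contig — separated by at
    most ``max_intervening`` genes.

    Strand-consistent: reversing a contig (coordinates and strands) leaves
    the verdict unchanged.
    """
    fam_by_gene = {a.gene_id: a.family for a in assignments if a.family != UNASSIGNED}
    best: AnchorEvidence | None = None
    for contig in genome.contigs:
        genes = contig.genes
        for i, g in enumerate(genes):
            if fam_by_gene.get(g.gene_id) != family_a:
                continue
            step = 1 if g.strand == "+" else -1
            j = i + step
            while 0 <= j < len(genes):
                between = abs(j - i) - 1
                if between > max_intervening:
                    break
                if fam_by_gene.get(genes[j].gene_id) == family_b:
                    ev = AnchorEvidence(
                        family_a, family_b, g.gene_id, genes[j].gene_id, between, True
                    )
                    if best is None or (best.intervening or 0) > between:
                        best = ev
                    break
                j += step
    if best is not None:
        return best
    return AnchorEvidence(family_a, family_b, None, None, None, False)


def synteny_conservation(
    contexts: Sequence[SyntenyContext],
    assignments_by_genome: Mapping[str, Mapping[str, str]],
    k: int = FLANK_K,
) -> pd.DataFrame:
    """Per-offset frequency of each flanking family/annotation token.

    For each offset -k..-1, +1..+k the fraction of contexts whose gene at
    that offset carries a given label: the family assignment where one
    exists, else the first token of the free-text product annotation.
    Frequencies at an offset sum to <= 1 (contexts truncated at contig ends
    contribute nothing there).
    """
    if not contexts:
        raise ValueError("need at least one synteny context")
    counts: dict[int, dict[str, int]] = {
        off: {} for off in list(range(-k, 0)) + list(range(1, k + 1))
    }
    for ctx in contexts:
        fam_map = assignments_by_genome.get(ctx.genome_id, {})

        def label(gene: GeneFeature) -> str:
            if gene.gene_id in fam_map:
                return fam_map[gene.gene_id]
            return gene.product.split()[0] if gene.product else "unannotated"

        for rank, gene in enumerate(ctx.upstream, start=1):
            if rank > k:
                break
            lab = label(gene)
            counts[-rank][lab] = counts[-rank].get(lab, 0) + 1
        for rank, gene in enumerate(ctx.downstream, start=1):
            if rank > k:
                break
            lab = label(gene)
            counts[rank][lab] = counts[rank].get(lab, 0) + 1
    n = len(contexts)
    rows = [
        {"offset": off, "token": tok, "frequency": cnt / n}
        for off in sorted(counts)
        for tok, cnt in sorted(counts[off].items())
    ]
    return pd.DataFrame(rows, columns=["offset", "token", "frequency"])


def contexts_table(contexts: Iterable[SyntenyContext],
                   assignments_by_genome: Mapping[str, Mapping[str, str]]) -> pd.DataFrame:
    rows = []
    for ctx in contexts:
        fam_map = assignments_by_genome.get(ctx.genome_id, {})
        for off, gene in list(
            zip(range(-1, -len(ctx.upstream) - 1, -1), ctx.upstream)
        ) + list(zip(range(1, len(ctx.downstream) + 1), ctx.downstream)):
            rows.append(
                {
                    "genome": ctx.genome_id,
                    "contig": ctx.cluster.contig_id,
                    "cluster_label": ctx.cluster.label,
                    "offset": off,
                    "gene_id": gene.gene_id,
                    "family_or_product": fam_map.get(
                        gene.gene_id, gene.product or "unannotated"
                    ),
                }
            )
    return pd.DataFrame(
        rows,
        columns=["genome", "contig", "cluster_label", "offset", "gene_id",
                 "family_or_product"],
    ).sort_values(["genome", "contig", "cluster_label", "offset"]).reset_index(drop=True)
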