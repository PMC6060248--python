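"""Genomic cluster detection and organization calling for T4aP genes.

Genes assigned to T4aP families are grouped into clusters by scanning each
contig in locus order: two assigned genes join the same cluster when the
number of intervening non-member genes between them is at most ``max_gap``.
Clusters are labelled by composition (``main`` multi-family locus,
``minor_pilin`` loci such as fimU-pilW-pilV-pilY1-pilX, the ``mnopq`` core
envelope cluster, or ``other``), and each genome receives an organization
call: *clustered* lineages carry one large main locus, *dispersed* lineages
keep only pilMNOPQ contiguous with the remaining genes scattered. Draft
assemblies whose main locus is broken across two contig ends are recognised
and rescued by the split-cluster heuristic.

Anchor families (ribF) are never cluster members; they are handled by the
synteny stage.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .genome_io import Genome
from .homology import (
    CORE_FAMILIES,
    MINOR_PILIN_FAMILIES,
    FamilyAssignment,
    ReferencePanel,
    UNASSIGNED,
)

#: defaults sized so that "large" main loci (15+ genes in clustered lineages)
#: and the 5-gene pilMNOPQ locus of dispersed lineages are well separated
MAX_GAP = 5
MAIN_MIN_SIZE = 10
MIN_CORE_FAMILIES = 5
EDGE_WINDOW = 5

MNOPQ = frozenset({"pilM", "pilN", "pilO", "pilP", "pilQ"})


@dataclass
class GeneCluster:
    contig_id: str
    members: list[tuple[str, str, str]]  # (gene_id, family, strand), locus order
    gaps: list[int]  # intervening non-member gene counts
    label: str = "other"  # main | minor_pilin | mnopq | other
    first_locus_index: int = 0
    last_locus_index: int = 0
    split_flag: bool = False
    pilrs_pairs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.gaps) != max(len(self.members) - 1, 0):
            raise ValueError("gaps must have one entry per adjacent member pair")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def families(self) -> list[str]:
        return [fam for _, fam, _ in self.members]

    @property
    def family_set(self) -> frozenset[str]:
        return frozenset(self.families)

    @property
    def architecture(self) -> str:
        return architecture_string(self.families, self.gaps)


def architecture_string(families: Sequence[str], gaps: Sequence[int]) -> str:
    """Families joined by '-'; a run of k intervening genes renders as 'x'
    (k = 1) or '[k]' (k > 1), nothing for adjacency."""
    if not families:
        return ""
    parts = [families[0]]
    for fam, gap in zip(families[1:], gaps):
        if gap == 1:
            parts.append("x")
        elif gap > 1:
            parts.append(f"[{gap}]")
        parts.append(fam)
    return "-".join(parts)


def parse_architecture(arch: str) -> tuple[list[str], list[int]]:
    """Invert :func:`architecture_string` losslessly."""
    if not arch:
        return [], []
    families: list[str] = []
    gaps: list[int] = []
    pending = 0
    for token in arch.split("-"):
        if token == "x":
            pending = 1
        elif m := re.fullmatch(r"\[(\d+)\]", token):
            pending = int(m.group(1))
        else:
            if families:
                gaps.append(pending)
            families.append(token)
            pending = 0
    return families, gaps


def detect_clusters(
    genome: Genome,
    assignments: Iterable[FamilyAssignment],
    max_gap: int = MAX_GAP,
    panel: ReferencePanel | None = None,
) -> list[GeneCluster]:
    """Scan each contig by locus_index and emit maximal runs of assigned genes
    whose pairwise intervening-gene counts are <= max_gap.

    Anchor-role families (looked up in ``panel``; ribF by default) are
    excluded from membership and count as intervening occupants, as do
    unassigned genes. Singletons come out as size-1 clusters.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    fam_by_gene: dict[str, str] = {}
    known = {g.gene_id for g in genome.genes()}
    anchors = (
        {f.family for f in panel if f.role == "anchor"} if panel else {"ribF"}
    )
    for a in assignments:
        if a.gene_id not in known:
            raise ValueError(f"assignment references unknown gene {a.gene_id}")
        if a.family != UNASSIGNED and a.family not in anchors:
            fam_by_gene[a.gene_id] = a.family

    clusters: list[GeneCluster] = []
    for contig in genome.contigs:
        run: list = []  # GeneFeature members of the open cluster
        prev_index = None
        for gene in contig.genes:
            if gene.gene_id not in fam_by_gene:
                continue
            if prev_index is not None and gene.locus_index - prev_index - 1 > max_gap:
                clusters.append(_make_cluster(contig.contig_id, run, fam_by_gene))
                run = []
            run.append(gene)
            prev_index = gene.locus_index
        if run:
            clusters.append(_make_cluster(contig.contig_id, run, fam_by_gene))
    return clusters


def _make_cluster(contig_id: str, genes: list, fam_by_gene: Mapping[str, str]) -> GeneCluster:
    members = [(g.gene_id, fam_by_gene[g.gene_id], g.strand) for g in genes]
    gaps = [
        b.locus_index - a.locus_index - 1 for a, b in zip(genes, genes[1:])
    ]
    return GeneCluster(
        contig_id=contig_id,
        members=members,
        gaps=gaps,
        first_locus_index=genes[0].locus_index,
        last_locus_index=genes[-1].locus_index,
    )


def classify_cluster(
    cluster: GeneCluster,
    panel: ReferencePanel | None = None,
    main_min_size: int = MAIN_MIN_SIZE,
    min_core_families: int = MIN_CORE_FAMILIES,
) -> GeneCluster:
    """Label a cluster by composition and resolve pilRS pairs in main loci.

    main: >= main_min_size members covering >= min_core_families core
    families; minor_pilin: all members are minor pilins / PilY1; mnopq: the
    family set is within pilMNOPQ with >= 4 distinct members.
    """
    fams = cluster.family_set
    n_core = len(fams & CORE_FAMILIES)
    if cluster.size >= main_min_size and n_core >= min_core_families:
        label = "main"
    elif cluster.size >= 2 and fams <= MINOR_PILIN_FAMILIES:
        label = "minor_pilin"
    elif fams and fams <= MNOPQ and len(fams) >= 4:
        label = "mnopq"
    else:
        label = "other"
    out = replace(cluster, label=label)
    out.pilrs_pairs = _resolve_pilrs(out) if label == "main" else []
    return out


def _resolve_pilrs(cluster: GeneCluster) -> list[str]:
    """Number successive pilRS genes inside a main cluster into two-component
    pairs by locus order: the genome's many stray regulators alias to the
    combined pilRS family, so the positional context is what distinguishes
    pilR1S1 from pilR2S2."""
    rs_genes = [gid for gid, fam, _ in cluster.members if fam == "pilRS"]
    pairs = []
    for i in range(len(rs_genes) // 2):
        pairs.append(f"pilR{i + 1}S{i + 1}")
    return pairs


def classify_all(
    clusters: Iterable[GeneCluster],
    panel: ReferencePanel | None = None,
    main_min_size: int = MAIN_MIN_SIZE,
    min_core_families: int = MIN_CORE_FAMILIES,
) -> list[GeneCluster]:
    return [
        classify_cluster(c, panel, main_min_size, min_core_families) for c in clusters
    ]


@dataclass(frozen=True)
class OrganizationCall:
    genome_id: str
    call: str  # clustered | dispersed | ambiguous
    main_cluster_size: int
    evidence: tuple[str, ...]
    split_candidate: bool = False


def flag_split_clusters(
    genome: Genome,
    clusters: list[GeneCluster],
    edge_window: int = EDGE_WINDOW,
    main_min_size: int = MAIN_MIN_SIZE,
    min_core_families: int = MIN_CORE_FAMILIES,
) -> list[GeneCluster]:
    """Flag pairs of clusters that look like one main locus cut by a contig
    break in a draft assembly.

    Both fragments must sit on different contigs, have >= 3 members each,
    disjoint family sets, lie within ``edge_window`` genes of a contig end,
    and their union must qualify as a main cluster.
    """
    if len(genome.contigs) < 2:
        return clusters
    n_genes = {c.contig_id: len(c.genes) for c in genome.contigs}

    def near_edge(cl: GeneCluster) -> bool:
        total = n_genes[cl.contig_id]
        return (
            cl.first_locus_index < edge_window
            or total - 1 - cl.last_locus_index < edge_window
        )

    out = [replace(c, split_flag=c.split_flag) for c in clusters]
    for i, a in enumerate(out):
        for j in range(i + 1, len(out)):
            b = out[j]
            if a.contig_id == b.contig_id:
                continue
            if a.size < 3 or b.size < 3:
                continue
            if a.family_set & b.family_set:
                continue
            if not (near_edge(a) and near_edge(b)):
                continue
            union_size = a.size + b.size
            union_core = len((a.family_set | b.family_set) & CORE_FAMILIES)
            if union_size >= main_min_size and union_core >= min_core_families:
                a.split_flag = True
                b.split_flag = True
    return out


def call_organization(genome: Genome, clusters: Sequence[GeneCluster]) -> OrganizationCall:
    """Per-genome verdict: clustered (a main locus, possibly split across
    contig ends), dispersed (no main locus but pilMNOPQ contiguous), else
    ambiguous."""
    labels = tuple(c.label for c in clusters)
    mains = [c for c in clusters if c.label == "main"]
    split = any(c.split_flag for c in clusters)
    if mains:
        size = max(c.size for c in mains)
        return OrganizationCall(genome.genome_id, "clustered", size, labels, split)
    if split:
        frags = [c for c in clusters if c.split_flag]
        size = sum(c.size for c in frags)
        return OrganizationCall(genome.genome_id, "clustered", size, labels, True)
    if any(c.label == "mnopq" for c in clusters):
        return OrganizationCall(genome.genome_id, "dispersed", 0, labels, False)
    return OrganizationCall(genome.genome_id, "ambiguous", 0, labels, False)


def count_paralogs(assignments: Iterable[FamilyAssignment], family: str) -> int:
    """Number of genes assigned to a family (e.g. pilA copy number 1..7)."""
    return sum(1 for a in assignments if a.family == family)


def clusters_table(genome_id: str, clusters: Iterable[GeneCluster]) -> pd.DataFrame:
    rows = [
        {
            "genome": genome_id,
            "contig": c.contig_id,
            "label": c.label,
            "architecture": c.architecture,
            "n_members": c.size,
            "members": ",".join(gid for gid, _, _ in c.members),
            "gaps": ",".join(map(str, c.gaps)),
            "split_flag": c.split_flag,
            "pilrs_pairs": ",".join(c.pilrs_pairs),
        }
        for c in clusters
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "genome", "contig", "label", "architecture", "n_members",
            "members", "gaps", "split_flag", "pilrs_pairs",
        ],
    )
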