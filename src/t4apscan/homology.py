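"""Family assignment by exact local alignment against a reference panel.

Each gene's protein is aligned (Smith–Waterman, BLOSUM62, affine gaps
open 11 / extend 1) against every reference sequence of every family in the
panel. A hit survives only if it clears all three filters jointly: E-value
<= 1e-5, reference (query) coverage >= 35% and similarity >= 35% — where
similarity counts positively scoring aligned pairs over aligned columns
including gaps (the BLAST "positives" reading). The winning family per gene is
the highest bit score; a winner belonging to a decoy family (type II secretion
system paralogs) leaves the gene unassigned with ``excluded_as_decoy`` set, a
competitive filter standing in for manual removal of T2SS machinery.

The E-value is a simplified desk-scale form E = m * n * 2**(-bits); bits are
derived from the raw Smith–Waterman score with standard gapped BLOSUM62
Karlin–Altschul constants (lambda = 0.267, K = 0.041). Only the relative
cutoff behaviour matters here and the constants are configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

UNASSIGNED = "UNASSIGNED"

#: the ten core structural/motor genes of the T4aP machinery
CORE_FAMILIES = frozenset(
    {"pilA", "pilB", "pilC", "pilD", "pilM", "pilN", "pilO", "pilP", "pilQ", "pilT"}
)
#: minor (low-abundance) pilins and the PilY1 adhesin of the priming subcomplex
MINOR_PILIN_FAMILIES = frozenset({"fimU", "pilV", "pilW", "pilX", "pilE", "pilY1"})

GAP_OPEN = 11
GAP_EXTEND = 1
# Karlin-Altschul constants for gapped BLOSUM62 11/1
KA_LAMBDA = 0.267
KA_K = 0.041

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def _aligner(mode: str) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner(
        mode=mode,
        substitution_matrix=_BLOSUM62,
        # gap of length k costs GAP_OPEN + k * GAP_EXTEND (BLAST convention)
        open_gap_score=-(GAP_OPEN + GAP_EXTEND),
        extend_gap_score=-GAP_EXTEND,
    )
    return a


_LOCAL = _aligner("local")
_GLOBAL = _aligner("global")


@dataclass(frozen=True)
class FamilyDef:
    """One reference family: name, functional role, reference sequences."""

    family: str
    role: str  # core | noncore | minor_pilin | regulatory | anchor | decoy
    reference_seqs: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.reference_seqs:
            raise ValueError(f"family {self.family}: needs >=1 reference sequence")
        if self.role not in {
            "core",
            "noncore",
            "minor_pilin",
            "regulatory",
            "anchor",
            "decoy",
        }:
            raise ValueError(f"family {self.family}: unknown role {self.role!r}")


@dataclass
class ReferencePanel:
    families: list[FamilyDef]

    def __post_init__(self) -> None:
        names = [f.family for f in self.families]
        if len(names) != len(set(names)):
            raise ValueError("duplicate family names in panel")

    def __iter__(self):
        return iter(self.families)

    def get(self, family: str) -> FamilyDef:
        for f in self.families:
            if f.family == family:
                return f
        raise KeyError(family)

    def non_decoy(self) -> list[FamilyDef]:
        return [f for f in self.families if f.role != "decoy"]

    def role_of(self, family: str) -> str:
        return self.get(family).role


def read_panel(path: str | Path) -> ReferencePanel:
    """Read a panel FASTA whose headers are ``family|role`` (optionally with a
    trailing ``|variant`` token); sequences of the same family are pooled."""
    seqs: dict[tuple[str, str], list[str]] = {}
    order: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        tokens = rec.id.split("|")
        if len(tokens) < 2:
            raise ValueError(f"panel header {rec.id!r}: expected family|role")
        key = (tokens[0], tokens[1])
        if key not in seqs:
            seqs[key] = []
            order.append(key)
        seqs[key].append(str(rec.seq))
    return ReferencePanel(
        [FamilyDef(fam, role, tuple(seqs[(fam, role)])) for fam, role in order]
    )


def write_panel(panel: ReferencePanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for fam in panel:
            for i, seq in enumerate(fam.reference_seqs):
                fh.write(f">{fam.family}|{fam.role}|{i}\n{seq}\n")


@dataclass(frozen=True)
class FilterThresholds:
    """The three conjunctive homology filters."""

    max_evalue: float = 1e-5
    min_query_coverage_pct: float = 35.0
    min_similarity_pct: float = 35.0

    def __post_init__(self) -> None:
        if self.max_evalue <= 0:
            raise ValueError("max_evalue must be positive")
        for v in (self.min_query_coverage_pct, self.min_similarity_pct):
            if not 0 < v <= 100:
                raise ValueError("percentage thresholds must lie in (0, 100]")


@dataclass(frozen=True)
class LocalAlignment:
    """Aligned column pairs of an optimal local alignment plus its raw score."""

    raw_score: float
    score_bits: float
    query_aligned: str  # reference side, with '-' for gaps
    target_aligned: str  # gene side
    query_span: tuple[int, int]  # [start, end) on the reference
    target_span: tuple[int, int]


def raw_to_bits(raw_score: float) -> float:
    """Convert a raw alignment score to bits via Karlin–Altschul constants."""
    return (KA_LAMBDA * raw_score - math.log(KA_K)) / math.log(2)


def local_align(seq_a: str, seq_b: str) -> LocalAlignment:
    """Optimal Smith–Waterman local alignment of reference ``seq_a`` vs gene
    ``seq_b`` under BLOSUM62 with affine gaps (open 11, extend 1).

    The local score is floored at zero (the empty alignment), as in BLAST.
    """
    if not seq_a or not seq_b:
        raise ValueError("local_align requires nonempty sequences")
    score = _LOCAL.score(seq_a, seq_b)
    if score <= 0:
        return LocalAlignment(0.0, raw_to_bits(0.0), "", "", (0, 0), (0, 0))
    aln = next(iter(_LOCAL.align(seq_a, seq_b)))
    qa, ta = str(aln[0]), str(aln[1])
    qspan = (int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1]))
    tspan = (int(aln.aligned[1][0][0]), int(aln.aligned[1][-1][1]))
    return LocalAlignment(float(score), raw_to_bits(float(score)), qa, ta, qspan, tspan)


def global_align(seq_a: str, seq_b: str) -> tuple[float, str, str]:
    """Needleman–Wunsch global alignment under the same scoring scheme."""
    if not seq_a or not seq_b:
        raise ValueError("global_align requires nonempty sequences")
    aln = next(iter(_GLOBAL.align(seq_a, seq_b)))
    return float(aln.score), str(aln[0]), str(aln[1])


def estimate_evalue(score_bits: float, query_len: int, db_len: int) -> float:
    """Simplified E-value: E = m * n * 2**(-bits), monotone decreasing in
    score. Desk-scale stand-in for the full Karlin–Altschul statistic."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("sequence lengths must be positive")
    return query_len * db_len * math.pow(2.0, -score_bits)


def alignment_stats(query_aligned: str, target_aligned: str) -> tuple[float, float, int]:
    """(identity_pct, similarity_pct, aligned_columns) over a pair of aligned
    strings. Similarity counts pairs with positive BLOSUM62 score; both are
    percentages of all aligned columns including gap columns."""
    assert len(query_aligned) == len(target_aligned)
    columns = len(query_aligned)
    if columns == 0:
        return 0.0, 0.0, 0
    ident = simil = 0
    for qa, ta in zip(query_aligned, target_aligned):
        if qa == "-" or ta == "-":
            continue
        if qa == ta:
            ident += 1
        try:
            if _BLOSUM62[qa, ta] > 0:
                simil += 1
        except IndexError:  # X or other ambiguity codes score nothing
            pass
    return 100.0 * ident / columns, 100.0 * simil / columns, columns


@dataclass(frozen=True)
class HomologyHit:
    query_family: str
    gene_id: str
    bitscore: float
    evalue: float
    identity_pct: float
    similarity_pct: float
    query_coverage_pct: float
    aln_span_query: tuple[int, int]
    aln_span_target: tuple[int, int]


def score_hit(
    family: str, gene_id: str, reference_len: int, aln: LocalAlignment,
    gene_len: int,
) -> HomologyHit:
    """Turn a local alignment of reference-vs-gene into a filterable hit.

    Query coverage is measured on the reference (family) sequence.
    """
    identity, similarity, _ = alignment_stats(aln.query_aligned, aln.target_aligned)
    coverage = 100.0 * (aln.query_span[1] - aln.query_span[0]) / reference_len
    return HomologyHit(
        query_family=family,
        gene_id=gene_id,
        bitscore=aln.score_bits,
        evalue=estimate_evalue(aln.score_bits, reference_len, gene_len),
        identity_pct=identity,
        similarity_pct=similarity,
        query_coverage_pct=coverage,
        aln_span_query=aln.query_span,
        aln_span_target=aln.target_span,
    )


def hit_passes(hit: HomologyHit, thresholds: FilterThresholds) -> bool:
    """All three filters must hold jointly."""
    return (
        hit.evalue <= thresholds.max_evalue
        and hit.query_coverage_pct >= thresholds.min_query_coverage_pct
        and hit.similarity_pct >= thresholds.min_similarity_pct
    )


@dataclass(frozen=True)
class FamilyAssignment:
    gene_id: str
    family: str  # family name or UNASSIGNED
    winning_hit: HomologyHit | None = None
    excluded_as_decoy: bool = False

    def __post_init__(self) -> None:
        if self.excluded_as_decoy and self.family != UNASSIGNED:
            raise ValueError("decoy-excluded genes must be UNASSIGNED")


def _best_hit_for_gene(
    gene_id: str,
    protein: str,
    panel: ReferencePanel,
    thresholds: FilterThresholds,
) -> HomologyHit | None:
    """Best passing hit across all families (decoys included so they can
    outcompete), or None. Score-only prescreen skips alignment traceback for
    reference/gene pairs whose bit score cannot clear the E-value filter."""
    best: HomologyHit | None = None
    for fam in panel:
        for ref in fam.reference_seqs:
            raw = _LOCAL.score(ref, protein)
            bits = raw_to_bits(raw)
            if estimate_evalue(bits, len(ref), len(protein)) > thresholds.max_evalue:
                continue
            aln = local_align(ref, protein)
            hit = score_hit(fam.family, gene_id, len(ref), aln, len(protein))
            if not hit_passes(hit, thresholds):
                continue
            if best is None or (
                (-hit.bitscore, hit.evalue, hit.query_family)
                < (-best.bitscore, best.evalue, best.query_family)
            ):
                best = hit
    return best


def assign_families(
    genome,
    panel: ReferencePanel,
    thresholds: FilterThresholds | None = None,
) -> list[FamilyAssignment]:
    """Assign every translated gene of the genome to its best-hit family.

    The winner is the highest bit score over all passing hits (ties broken by
    lower E-value, then alphabetical family); a decoy winner leaves the gene
    UNASSIGNED with ``excluded_as_decoy`` set. Deterministic and independent
    of gene iteration order.
    """
    if not panel.non_decoy():
        raise ValueError("panel must contain at least one non-decoy family")
    thresholds = thresholds or FilterThresholds()
    assignments: list[FamilyAssignment] = []
    for gene in genome.genes():
        protein = genome.protein(gene.gene_id)
        if not protein:
            assignments.append(FamilyAssignment(gene.gene_id, UNASSIGNED))
            continue
        best = _best_hit_for_gene(gene.gene_id, protein, panel, thresholds)
        if best is None:
            assignments.append(FamilyAssignment(gene.gene_id, UNASSIGNED))
        elif panel.role_of(best.query_family) == "decoy":
            assignments.append(
                FamilyAssignment(gene.gene_id, UNASSIGNED, best, excluded_as_decoy=True)
            )
        else:
            assignments.append(FamilyAssignment(gene.gene_id, best.query_family, best))
    return assignments


def assignments_table(assignments: Iterable[FamilyAssignment]) -> pd.DataFrame:
    """Hits table: gene_id, family, bitscore, evalue, identity, similarity,
    coverage, assigned flag."""
    rows = []
    for a in assignments:
        h = a.winning_hit
        rows.append(
            {
                "gene_id": a.gene_id,
                "family": a.family,
                "bitscore": round(h.bitscore, 2) if h else float("nan"),
                "evalue": h.evalue if h else float("nan"),
                "identity": round(h.identity_pct, 2) if h else float("nan"),
                "similarity": round(h.similarity_pct, 2) if h else float("nan"),
                "coverage": round(h.query_coverage_pct, 2) if h else float("nan"),
                "assigned": a.family != UNASSIGNED,
                "excluded_as_decoy": a.excluded_as_decoy,
            }
        )
    return pd.DataFrame(rows)


def assignment_map(assignments: Iterable[FamilyAssignment]) -> dict[str, str]:
    """gene_id -> family for assigned genes only."""
    return {a.gene_id: a.family for a in assignments if a.family != UNASSIGNED}
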