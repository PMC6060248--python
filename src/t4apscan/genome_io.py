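"""Annotated-genome I/O and the coordinate model shared by all analysis stages.

A :class:`Genome` is an ordered list of contigs, each carrying stranded gene
features with 1-based inclusive nucleotide coordinates (GFF3 convention) and a
``locus_index`` — the 0-based rank of the gene on its contig ordered by start.
All neighbourhood logic downstream (cluster gaps, flanking context, anchor
adjacency) is expressed in locus_index units, i.e. counts of intervening genes,
never nucleotide distance.

Readers accept GFF3 plus a protein FASTA whose headers carry the gene_id as the
first whitespace-delimited token; writers emit the same pair deterministically
so that ``read(write(G)) == G`` field-by-field.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger("t4apscan")

AA_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")


class GenomeFormatError(ValueError):
    """Raised for malformed GFF3/FASTA input or inconsistent genome state."""


@dataclass(frozen=True)
class GeneFeature:
    """One gene call: stranded 1-based inclusive coordinates on a contig."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    locus_index: int = -1
    product: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise GenomeFormatError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in {"+", "-"}:
            raise GenomeFormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")


@dataclass
class Contig:
    contig_id: str
    length: int
    genes: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.genes = _rank(self.contig_id, self.genes)
        for g in self.genes:
            if g.end > self.length:
                raise GenomeFormatError(
                    f"gene {g.gene_id} end {g.end} exceeds contig "
                    f"{self.contig_id} length {self.length}"
                )


def _rank(contig_id: str, genes: Iterable[GeneFeature]) -> list[GeneFeature]:
    """Sort by start and assign consecutive locus_index values from 0."""
    ranked = sorted(genes, key=lambda g: (g.start, g.end, g.gene_id))
    return [
        replace(g, contig_id=contig_id, locus_index=i) for i, g in enumerate(ranked)
    ]


@dataclass
class Genome:
    """Contigs plus a gene_id -> amino-acid sequence mapping.

    Every protein key must match exactly one gene feature; genes may lack a
    translation (empty string) and then act only as positional occupants.
    """

    genome_id: str
    taxon_label: str
    contigs: list[Contig] = field(default_factory=list)
    proteins: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.gene_id for c in self.contigs for g in c.genes]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise GenomeFormatError(f"duplicate gene_id(s): {', '.join(dup)}")
        known = set(ids)
        for gid, seq in self.proteins.items():
            if gid not in known:
                raise GenomeFormatError(f"protein {gid} has no gene feature")
            bad = set(seq) - AA_ALPHABET
            if bad:
                raise GenomeFormatError(
                    f"protein {gid}: non-amino-acid letters {sorted(bad)}"
                )

    # -- convenience lookups used throughout the pipeline ---------------------

    def genes(self) -> list[GeneFeature]:
        return [g for c in self.contigs for g in c.genes]

    def gene(self, gene_id: str) -> GeneFeature:
        for c in self.contigs:
            for g in c.genes:
                if g.gene_id == gene_id:
                    return g
        raise KeyError(gene_id)

    def contig(self, contig_id: str) -> Contig:
        for c in self.contigs:
            if c.contig_id == contig_id:
                return c
        raise KeyError(contig_id)

    def protein(self, gene_id: str) -> str:
        return self.proteins.get(gene_id, "")


# ---------------------------------------------------------------------------
# GFF3 + protein FASTA reading
# ---------------------------------------------------------------------------


def _prevalidate_gff3(path: Path) -> dict[str, int]:
    """Check column structure line by line; return contig lengths from
    ``##sequence-region`` pragmas. Errors name the offending line number."""
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("##sequence-region"):
                parts = line.split()
                if len(parts) != 4:
                    raise GenomeFormatError(
                        f"{path}:{lineno}: malformed sequence-region pragma"
                    )
                lengths[parts[1]] = int(parts[3])
                continue
            if line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise GenomeFormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns, "
                    f"got {len(cols)}"
                )
            if cols[6] not in {"+", "-", ".", "?"}:
                raise GenomeFormatError(f"{path}:{lineno}: bad strand {cols[6]!r}")
            try:
                int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise GenomeFormatError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
    return lengths


def read_genome(
    gff3_path: str | Path,
    protein_fasta_path: str | Path | None = None,
    genome_id: str | None = None,
    taxon_label: str | None = None,
) -> Genome:
    """Read a genome from GFF3 (gene/CDS features) plus a protein FASTA.

    locus_index is assigned per contig by ascending start regardless of record
    order in the file. Genes lacking a protein sequence are retained with an
    empty sequence and a logged warning.
    """
    gff3_path = Path(gff3_path)
    seq_lengths = _prevalidate_gff3(gff3_path)
    has_features = any(
        line.strip() and not line.startswith("#")
        for line in gff3_path.read_text().splitlines()
    )
    feature_iter = ()
    if has_features:
        db = gffutils.create_db(
            str(gff3_path),
            ":memory:",
            merge_strategy="error",
            keep_order=True,
            from_string=False,
        )
        feature_iter = db.all_features()
    by_contig: dict[str, list[GeneFeature]] = {}
    contig_order: list[str] = list(seq_lengths)
    seen: set[str] = set()
    for feat in feature_iter:
        if feat.featuretype not in {"gene", "CDS"}:
            continue
        gid = feat.attributes.get("ID", [feat.id])[0]
        if feat.featuretype == "CDS" and gid in seen:
            continue  # CDS mirroring its gene record
        if gid in seen:
            raise GenomeFormatError(f"duplicate gene_id {gid} in {gff3_path}")
        seen.add(gid)
        product = feat.attributes.get("product", [""])[0]
        if feat.seqid not in contig_order:
            contig_order.append(feat.seqid)
        by_contig.setdefault(feat.seqid, []).append(
            GeneFeature(
                gene_id=gid,
                contig_id=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                product=product,
            )
        )

    contigs = []
    for cid in contig_order:
        genes = by_contig.get(cid, [])
        if not genes and cid not in seq_lengths:
            continue
        length = seq_lengths.get(cid, max((g.end for g in genes), default=0))
        contigs.append(Contig(contig_id=cid, length=length, genes=genes))

    proteins: dict[str, str] = {}
    if protein_fasta_path is not None:
        for rec in SeqIO.parse(str(protein_fasta_path), "fasta"):
            gid = rec.id.split()[0]
            proteins[gid] = str(rec.seq)

    gid_set = {g.gene_id for c in contigs for g in c.genes}
    proteins = {k: v for k, v in proteins.items() if k in gid_set}
    missing = sorted(gid_set - set(proteins))
    if missing and protein_fasta_path is not None:
        logger.warning(
            "%d gene(s) lack a protein sequence (e.g. %s); retained as "
            "positional occupants",
            len(missing),
            missing[0],
        )
    for gid in missing:
        proteins[gid] = ""

    return Genome(
        genome_id=genome_id or gff3_path.stem,
        taxon_label=taxon_label or genome_id or gff3_path.stem,
        contigs=contigs,
        proteins=proteins,
    )


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------


def write_genome(
    genome: Genome,
    gff3_path: str | Path,
    protein_fasta_path: str | Path | None = None,
) -> None:
    """Emit GFF3 (version pragma + one gene line per feature) and protein FASTA.

    Ordering is deterministic: contigs in genome order, genes by start.
    """
    lines = ["##gff-version 3"]
    for contig in genome.contigs:
        lines.append(f"##sequence-region {contig.contig_id} 1 {contig.length}")
    for contig in genome.contigs:
        for g in contig.genes:
            attrs = f"ID={g.gene_id}"
            if g.product:
                attrs += f";product={g.product}"
            lines.append(
                "\t".join(
                    [
                        contig.contig_id,
                        "t4apscan",
                        "gene",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    Path(gff3_path).write_text("\n".join(lines) + "\n")

    if protein_fasta_path is not None:
        records = [
            SeqRecord(Seq(genome.proteins.get(g.gene_id, "")), id=g.gene_id,
                      description="")
            for c in genome.contigs
            for g in c.genes
            if genome.proteins.get(g.gene_id, "")
        ]
        with open(protein_fasta_path, "w") as fh:
            SeqIO.write(records, fh, "fasta")


# ---------------------------------------------------------------------------
# iTOL binary-trait export
# ---------------------------------------------------------------------------


def write_itol_binary(
    genomes: Sequence[Genome],
    family_presence_table: Mapping[str, Mapping[str, int]],
    path: str | Path,
    dataset_label: str = "T4aP gene presence",
) -> None:
    """Write an iTOL DATASET_BINARY annotation file.

    ``family_presence_table`` maps genome_id -> {family: 1 (present) or -1
    (absent)}. Rows are emitted in ``genomes`` order, columns in sorted family
    order, so output is bit-stable.
    """
    families = sorted({f for row in family_presence_table.values() for f in row})
    for gid, row in family_presence_table.items():
        for fam, v in row.items():
            if v not in (1, -1):
                raise ValueError(
                    f"presence entry for {gid}/{fam} must be 1 or -1, got {v}"
                )
    out = io.StringIO()
    out.write("DATASET_BINARY\n")
    out.write("SEPARATOR TAB\n")
    out.write(f"DATASET_LABEL\t{dataset_label}\n")
    out.write("COLOR\t#d95f02\n")
    if families:
        out.write("FIELD_LABELS\t" + "\t".join(families) + "\n")
        out.write("FIELD_SHAPES\t" + "\t".join(["1"] * len(families)) + "\n")
        out.write("FIELD_COLORS\t" + "\t".join(["#d95f02"] * len(families)) + "\n")
    out.write("DATA\n")
    for genome in genomes:
        row = family_presence_table.get(genome.genome_id, {})
        values = [str(row.get(f, -1)) for f in families]
        out.write("\t".join([genome.taxon_label] + values) + "\n")
    Path(path).write_text(out.getvalue())


def read_itol_binary(path: str | Path) -> dict[str, dict[str, int]]:
    """Parse a DATASET_BINARY file back to taxon_label -> {family: value}."""
    families: list[str] = []
    table: dict[str, dict[str, int]] = {}
    in_data = False
    for line in Path(path).read_text().splitlines():
        if not line:
            continue
        if line.startswith("FIELD_LABELS\t"):
            families = line.split("\t")[1:]
        elif line == "DATA":
            in_data = True
        elif in_data:
            parts = line.split("\t")
            table[parts[0]] = {
                f: int(v) for f, v in zip(families, parts[1:])
            }
    return table
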