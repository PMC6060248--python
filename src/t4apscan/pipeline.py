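"""End-to-end orchestration: configuration, stage runners, report bundle.

The pipeline runs scan -> cluster -> pilin -> synteny -> phylo -> report over
a directory of annotated genomes (paired ``<name>.gff3`` / ``<name>.faa``
files) and a reference panel FASTA, writing tab-separated report tables, a
Newick tree per marker, an iTOL presence/absence annotation, and a per-genome
summary. All tunables live in a flat ``key: value`` config file; every
random choice descends from one master seed, so two runs with equal config
and seed produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import cluster_detect, genome_io, homology, pilin_analysis, phylo, synteny
from .genome_io import Genome, read_genome
from .homology import FamilyAssignment, FilterThresholds, ReferencePanel, UNASSIGNED

logger = logging.getLogger("t4apscan")

PACKAGED_PANEL = Path(__file__).parent / "data" / "panel_synthetic.fasta"


@dataclass
class RunConfig:
    """Every tunable of the pipeline with its documented default."""

    max_evalue: float = 1e-5
    min_query_coverage_pct: float = 35.0
    min_similarity_pct: float = 35.0
    max_gap: int = 5
    main_min_size: int = 10
    min_core_families: int = 5
    edge_window: int = 5
    max_intervening: int = 1
    flank_k: int = 5
    cleavage_motif: str = pilin_analysis.CLEAVAGE_MOTIF
    search_window: int = 50
    cterm_fraction: float = 0.5
    min_loop: int = 6
    max_loop: int = 60
    terminal_window: int = 15
    nterm_window: int = 60
    bootstrap_n: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        for name in ("main_min_size", "min_core_families", "edge_window",
                     "flank_k", "search_window", "min_loop", "max_loop",
                     "terminal_window", "nterm_window", "bootstrap_n"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_intervening < 0:
            raise ValueError("max_intervening must be >= 0")
        if not 0 < self.cterm_fraction <= 1:
            raise ValueError("cterm_fraction must lie in (0, 1]")
        self.thresholds = FilterThresholds(
            self.max_evalue, self.min_query_coverage_pct, self.min_similarity_pct
        )

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name}: {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def validate_config(path: str | Path | None) -> RunConfig:
    """Parse a flat ``key: value`` config file; unknown keys and
    non-parseable values are rejected by name; absent keys take defaults."""
    known = {f.name: f.type for f in dataclasses.fields(RunConfig)}
    kwargs: dict = {}
    if path is not None:
        text = Path(path).read_text()
        for lineno, line in enumerate(text.splitlines(), start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if ":" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key: value'")
            key, _, raw = line.partition(":")
            key, raw = key.strip(), raw.strip()
            if key not in known:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            default = getattr(RunConfig, "__dataclass_fields__")[key].default
            try:
                if isinstance(default, bool):
                    kwargs[key] = raw.lower() in {"1", "true", "yes"}
                elif isinstance(default, int):
                    kwargs[key] = int(raw)
                elif isinstance(default, float):
                    kwargs[key] = float(raw)
                else:
                    kwargs[key] = raw
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric value for {key!r}: {raw!r}"
                ) from exc
    config = RunConfig(**kwargs)
    logger.info("[config] effective config: %s", dataclasses.asdict(config))
    return config


# ---------------------------------------------------------------------------
# Input discovery
# ---------------------------------------------------------------------------


def load_genomes(genomes_dir: str | Path) -> list[Genome]:
    genomes_dir = Path(genomes_dir)
    if not genomes_dir.is_dir():
        raise FileNotFoundError(f"genome directory not found: {genomes_dir}")
    genomes = []
    for gff in sorted(genomes_dir.glob("*.gff3")):
        faa = gff.with_suffix(".faa")
        if not faa.exists():
            raise FileNotFoundError(f"missing protein FASTA: {faa}")
        genomes.append(read_genome(gff, faa))
    if not genomes:
        raise FileNotFoundError(f"no *.gff3 genomes in {genomes_dir}")
    return genomes


def load_panel(panel_path: str | Path | None) -> ReferencePanel:
    path = Path(panel_path) if panel_path else PACKAGED_PANEL
    if not path.exists():
        raise FileNotFoundError(f"panel FASTA not found: {path}")
    return homology.read_panel(path)


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------


def stage_scan(
    genomes: Sequence[Genome], panel: ReferencePanel, config: RunConfig
) -> dict[str, list[FamilyAssignment]]:
    out = {}
    for g in genomes:
        logger.info("[scan] %s: %d genes", g.genome_id, len(g.genes()))
        out[g.genome_id] = homology.assign_families(g, panel, config.thresholds)
    return out


def stage_cluster(
    genomes: Sequence[Genome],
    assignments: Mapping[str, list[FamilyAssignment]],
    panel: ReferencePanel,
    config: RunConfig,
) -> tuple[dict[str, list], dict[str, cluster_detect.OrganizationCall]]:
    clusters_by_genome: dict[str, list] = {}
    calls: dict[str, cluster_detect.OrganizationCall] = {}
    for g in genomes:
        clusters = cluster_detect.detect_clusters(
            g, assignments[g.genome_id], config.max_gap, panel
        )
        clusters = cluster_detect.classify_all(
            clusters, panel, config.main_min_size, config.min_core_families
        )
        clusters = cluster_detect.flag_split_clusters(
            g, clusters, config.edge_window, config.main_min_size,
            config.min_core_families,
        )
        clusters_by_genome[g.genome_id] = clusters
        calls[g.genome_id] = cluster_detect.call_organization(g, clusters)
        logger.info("[cluster] %s: %s", g.genome_id, calls[g.genome_id].call)
    return clusters_by_genome, calls


def _cluster_member_ids(clusters: Sequence, labels: set[str]) -> set[str]:
    return {
        gid
        for c in clusters
        if c.label in labels
        for gid, _, _ in c.members
    }


def stage_pilin(
    genomes: Sequence[Genome],
    assignments: Mapping[str, list[FamilyAssignment]],
    clusters_by_genome: Mapping[str, list],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    features = []
    cluster_matures = []
    for g in genomes:
        in_main = _cluster_member_ids(clusters_by_genome[g.genome_id], {"main"})
        for a in assignments[g.genome_id]:
            if a.family != "pilA":
                continue
            seq = g.protein(a.gene_id)
            if not seq:
                continue
            feat = pilin_analysis.pilin_features(
                a.gene_id,
                seq,
                in_t4ap_cluster=a.gene_id in in_main,
                motif=config.cleavage_motif,
                search_window=config.search_window,
                cterm_fraction=config.cterm_fraction,
                min_loop=config.min_loop,
                max_loop=config.max_loop,
                terminal_window=config.terminal_window,
            )
            features.append(feat)
            if feat.in_t4ap_cluster:
                cluster_matures.append(
                    pilin_analysis.mature_sequence(seq, feat.cleavage_pos)
                )
    ftable = pilin_analysis.features_table(features)
    if len(cluster_matures) >= 2:
        prof = pilin_analysis.nterm_conservation(
            cluster_matures, window=config.nterm_window
        )
        ctable = pd.DataFrame(
            {
                "column": range(len(prof.column_fractions)),
                "fraction": [round(f, 4) for f in prof.column_fractions],
            }
        )
    else:
        ctable = pd.DataFrame(columns=["column", "fraction"])
    logger.info("[pilin] %d pilA genes profiled", len(features))
    return ftable, ctable


def stage_synteny(
    genomes: Sequence[Genome],
    assignments: Mapping[str, list[FamilyAssignment]],
    clusters_by_genome: Mapping[str, list],
    config: RunConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    fam_maps = {
        gid: homology.assignment_map(asg) for gid, asg in assignments.items()
    }
    contexts = []
    anchor_rows = []
    for g in genomes:
        for c in clusters_by_genome[g.genome_id]:
            if c.label in {"main", "mnopq"}:
                contexts.append(synteny.flanking_context(g, c, config.flank_k))
        ev = synteny.anchor_adjacent(
            g, assignments[g.genome_id], "pilB", "ribF", config.max_intervening
        )
        anchor_rows.append(
            {
                "genome": g.genome_id,
                "pair": "pilB-ribF",
                "linked": ev.linked,
                "intervening": ev.intervening if ev.intervening is not None else -1,
            }
        )
    ctx_table = synteny.contexts_table(contexts, fam_maps)
    freq = (
        synteny.synteny_conservation(contexts, fam_maps, config.flank_k)
        if contexts
        else pd.DataFrame(columns=["offset", "token", "frequency"])
    )
    logger.info("[synteny] %d contexts, %d anchor tests", len(contexts), len(anchor_rows))
    return ctx_table, pd.DataFrame(anchor_rows), freq


def stage_phylo(
    genomes: Sequence[Genome],
    assignments: Mapping[str, list[FamilyAssignment]],
    clusters_by_genome: Mapping[str, list],
    config: RunConfig,
    out_dir: Path,
) -> pd.DataFrame:
    """Bootstrap NJ trees for the PilT marker (full length) and PilA
    (conserved N-terminal window), plus the cluster-resident PilT monophyly
    verdict."""
    rows = []
    for family, window in (("pilT", None), ("pilA", config.nterm_window)):
        labels, seqs, resident = [], [], []
        for g in genomes:
            in_main = _cluster_member_ids(clusters_by_genome[g.genome_id], {"main"})
            for a in assignments[g.genome_id]:
                if a.family != family:
                    continue
                seq = g.protein(a.gene_id)
                if not seq:
                    continue
                if family == "pilA":
                    pos = pilin_analysis.find_cleavage_site(
                        seq, config.cleavage_motif, config.search_window
                    )
                    seq = pilin_analysis.mature_sequence(seq, pos)
                lab = f"{g.genome_id}.{a.gene_id}"
                labels.append(lab)
                seqs.append(seq)
                if a.gene_id in in_main:
                    resident.append(lab)
        if len(labels) < 4:
            logger.info("[phylo] %s: only %d sequences, skipping", family, len(labels))
            continue
        aln = phylo.progressive_align(seqs, labels)
        if window is not None:
            aln = aln.slice_columns(0, window)
        tree = phylo.bootstrap_support(aln, config.bootstrap_n, config.seed)
        path = out_dir / f"{family}_nj.nwk"
        phylo.write_newick(tree, path)
        if 2 <= len(resident) <= len(labels) - 2:
            verdict = phylo.test_monophyly(tree, resident)
            rows.append(
                {
                    "marker": family,
                    "subset": "cluster_resident",
                    "n_taxa": len(labels),
                    "n_subset": len(resident),
                    "monophyletic": verdict.is_monophyletic,
                    "support": verdict.support_pct
                    if verdict.support_pct is not None
                    else -1,
                }
            )
        logger.info("[phylo] %s: %d taxa -> %s", family, len(labels), path.name)
    return pd.DataFrame(
        rows, columns=["marker", "subset", "n_taxa", "n_subset", "monophyletic",
                       "support"]
    )


def presence_table(
    panel: ReferencePanel,
    assignments: Mapping[str, list[FamilyAssignment]],
) -> dict[str, dict[str, int]]:
    families = [f.family for f in panel.non_decoy()]
    out = {}
    for gid, asg in assignments.items():
        found = {a.family for a in asg if a.family != UNASSIGNED}
        out[gid] = {f: (1 if f in found else -1) for f in families}
    return out


def run_all(
    config: RunConfig,
    genomes_dir: str | Path,
    out_dir: str | Path,
    panel_path: str | Path | None = None,
) -> dict[str, Path]:
    """Execute every stage and write the full report bundle. Returns the
    mapping of artifact names to paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = load_genomes(genomes_dir)
    panel = load_panel(panel_path)

    assignments = stage_scan(genomes, panel, config)
    hits = pd.concat(
        [
            homology.assignments_table(assignments[g.genome_id]).assign(
                genome=g.genome_id
            )
            for g in genomes
        ],
        ignore_index=True,
    )

    clusters_by_genome, calls = stage_cluster(genomes, assignments, panel, config)
    ctables = [
        cluster_detect.clusters_table(g.genome_id, clusters_by_genome[g.genome_id])
        for g in genomes
    ]
    clusters_tsv = pd.concat(ctables, ignore_index=True)
    org_tsv = pd.DataFrame(
        [
            {
                "genome": c.genome_id,
                "call": c.call,
                "main_cluster_size": c.main_cluster_size,
                "split_candidate": c.split_candidate,
            }
            for c in calls.values()
        ]
    )

    pilin_tsv, conservation_tsv = stage_pilin(
        genomes, assignments, clusters_by_genome, config
    )
    synteny_tsv, anchors_tsv, freq_tsv = stage_synteny(
        genomes, assignments, clusters_by_genome, config
    )
    monophyly_tsv = stage_phylo(
        genomes, assignments, clusters_by_genome, config, out
    )

    summary_rows = []
    for g in genomes:
        call = calls[g.genome_id]
        anchor = anchors_tsv.loc[anchors_tsv["genome"] == g.genome_id, "linked"]
        summary_rows.append(
            {
                "genome": g.genome_id,
                "organization": call.call,
                "main_cluster_size": call.main_cluster_size,
                "split_candidate": call.split_candidate,
                "n_pilA": cluster_detect.count_paralogs(
                    assignments[g.genome_id], "pilA"
                ),
                "pilB_ribF_linked": bool(anchor.iloc[0]) if len(anchor) else False,
            }
        )
    summary = pd.DataFrame(summary_rows)

    genome_io.write_itol_binary(
        genomes, presence_table(panel, assignments), out / "itol_presence.txt"
    )

    paths = {}
    for name, frame in [
        ("hits", hits),
        ("clusters", clusters_tsv),
        ("organization", org_tsv),
        ("pilin_features", pilin_tsv),
        ("pilin_conservation", conservation_tsv),
        ("synteny", synteny_tsv),
        ("anchors", anchors_tsv),
        ("synteny_frequency", freq_tsv),
        ("monophyly", monophyly_tsv),
        ("summary", summary),
    ]:
        p = out / f"{name}.tsv"
        frame.to_csv(p, sep="\t", index=False)
        paths[name] = p
    config.to_file(out / "effective_config.txt")
    paths["itol"] = out / "itol_presence.txt"
    logger.info("[report] %d genomes summarized -> %s", len(genomes), out)
    return paths
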