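"""Synthetic annotated genomes with planted T4aP architectures.

Every pipeline stage is exercised against ground truth produced here. Two
genome organizations are emulated: *clustered* genomes carry a 17-gene main
T4aP locus (family order read from a packaged, editable layout file) with the
riboflavin kinase anchor ribF immediately downstream of pilB, two
fimU-pilW-pilV-pilY1-pilX minor pilin loci and one pilW-x-pilY1 locus, plus
scattered singletons; *dispersed* genomes keep only pilMNOPQ contiguous, with
every other family (and ribF) scattered far apart. Pilin (PilA) sequences are
built as a prepilin leader + cleavage motif, a conserved N-terminal stalk
evolving slowly, and a divergent C-terminal head carrying a planted terminal
cysteine pair; scattered extra PilA paralogs are emitted without the pair,
mirroring the second-pilin arrangement seen in clustered lineages. T2SS-like
decoy families are derived from the pilB/pilC/pilD ancestors at intermediate
divergence to exercise competitive decoy exclusion, and draft-assembly
fragmentation is emulated by cutting contigs at random intergenic points.

Substitutions are BLOSUM62-biased (exchanges with positive substitution
scores are favoured), so percent similarity decays more slowly than percent
identity, as in real proteins — which is what makes the 35% similarity filter
meaningfully different from an identity filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd

from .genome_io import Contig, GeneFeature, Genome
from .homology import (
    CORE_FAMILIES,
    FamilyDef,
    ReferencePanel,
    _BLOSUM62,
    alignment_stats,
    global_align,
)

AA20 = "ACDEFGHIKLMNPQRSTVWY"
_AA20_IDX = {c: i for i, c in enumerate(AA20)}

# replacement weights: residue a -> residue b (b != a), favouring exchanges
# with positive BLOSUM62 score so similarity outlives identity
_REPL = np.zeros((20, 20))
for _i, _a in enumerate(AA20):
    for _j, _b in enumerate(AA20):
        if _i != _j:
            _REPL[_i, _j] = math.pow(2.0, float(_BLOSUM62[_a, _b]) / 2.0)
_REPL /= _REPL.sum(axis=1, keepdims=True)

#: neutral vocabulary for background-gene products (signal-free noise for
#: product-token flanking comparisons)
BACKGROUND_PRODUCTS = (
    "hypothetical protein",
    "ABC transporter permease",
    "MFS transporter",
    "aldehyde dehydrogenase",
    "acyl-CoA ligase",
    "TonB-dependent receptor",
    "serine protease",
    "GNAT acetyltransferase",
    "glycosyltransferase",
    "response regulator",
    "sensor histidine kinase",
    "outer membrane lipoprotein",
)

MIN_SPACER = 6  # background genes between planted elements (> default max_gap)

PILIN_FAMILIES = ("pilA", "fimU", "pilV", "pilW", "pilX", "pilE")
DEFAULT_ROSTER: dict[str, str] = {
    "pilA": "core", "pilB": "core", "pilC": "core", "pilD": "core",
    "pilM": "core", "pilN": "core", "pilO": "core", "pilP": "core",
    "pilQ": "core", "pilT": "core",
    "pilE": "minor_pilin", "fimU": "minor_pilin", "pilV": "minor_pilin",
    "pilW": "minor_pilin", "pilX": "minor_pilin", "pilY1": "minor_pilin",
    "pilF": "noncore", "pilG": "noncore", "pilH": "noncore", "pilI": "noncore",
    "pilRS": "regulatory",
    "tsaP": "noncore",
    "ribF": "anchor",
}
DECOY_SOURCES = {"t2ssE": "pilB", "t2ssF": "pilC", "t2ssO": "pilD"}


def main_locus_order() -> list[str]:
    """Transcription-order slot names of the main locus from the packaged
    layout file (pilS*/pilR* slots alias to family pilRS)."""
    text = (
        resources.files("t4apscan").joinpath("data/main_locus_layout.txt").read_text()
    )
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


def slot_family(slot: str) -> str:
    return "pilRS" if slot.startswith(("pilR", "pilS")) else slot


# ---------------------------------------------------------------------------
# Sequence machinery
# ---------------------------------------------------------------------------


def _random_protein(rng: np.random.Generator, length: int, exclude: str = "") -> str:
    pool = np.array([c for c in AA20 if c not in exclude])
    return "".join(pool[rng.integers(0, len(pool), size=length)])


def mutate(
    seq: str,
    divergence: float,
    rng: np.random.Generator,
    protected: frozenset[int] = frozenset(),
    slow_span: tuple[int, int] | None = None,
    slow_factor: float = 0.2,
) -> str:
    """Per-site substitution at rate ``divergence`` expected substitutions per
    site (Poisson, so the hit probability is 1 - exp(-d)); sites inside
    ``slow_span`` evolve at ``slow_factor`` times the rate and ``protected``
    sites never change. Replacements are BLOSUM62-biased."""
    p_fast = 1.0 - math.exp(-divergence)
    p_slow = 1.0 - math.exp(-divergence * slow_factor)
    u = rng.random(len(seq))
    out = list(seq)
    for i, c in enumerate(seq):
        if i in protected or c not in _AA20_IDX:
            continue
        p = p_slow if slow_span and slow_span[0] <= i < slow_span[1] else p_fast
        if u[i] < p:
            out[i] = AA20[rng.choice(20, p=_REPL[_AA20_IDX[c]])]
    return "".join(out)


@dataclass(frozen=True)
class Ancestor:
    """Per-family ancestral sequence plus the sites under purifying
    selection (protected) and the slowly evolving span, if any."""

    name: str
    family: str
    seq: str
    protected: frozenset[int] = frozenset()
    slow_span: tuple[int, int] | None = None
    cys_positions: tuple[int, ...] = ()  # absolute indices, pilA only
    cleavage_pos: int | None = None


def _make_pila_ancestor(rng: np.random.Generator) -> Ancestor:
    """Prepilin leader + class III cleavage motif + conserved 60-residue
    mature N-terminus + divergent C-terminal head ending in a Cys pair."""
    leader = _random_protein(rng, 5, exclude="GC")
    motif = "G" + "FY"[rng.integers(2)] + "ST"[rng.integers(2)] + "L" + "ILMV"[rng.integers(4)] + "E"
    conserved = _random_protein(rng, 55, exclude="C")
    var_len = int(rng.integers(80, 161))
    variable = list(_random_protein(rng, var_len, exclude="C"))
    sep = int(rng.integers(10, 15))
    c2 = var_len - 3
    c1 = c2 - sep
    variable[c1] = "C"
    variable[c2] = "C"
    seq = leader + motif + conserved + "".join(variable)
    head = len(leader)  # cleavage Gly index
    var_start = head + 6 + 55
    cys_abs = (var_start + c1, var_start + c2)
    protected = frozenset(range(head, head + 6)) | frozenset(cys_abs)
    return Ancestor(
        name="pilA",
        family="pilA",
        seq=seq,
        protected=protected,
        slow_span=(0, var_start),  # leader + motif + conserved stalk
        cys_positions=cys_abs,
        cleavage_pos=head,
    )


def generate_panel(
    seed: int, families: dict[str, str] | None = None
) -> tuple[ReferencePanel, dict[str, Ancestor]]:
    """Build a reference panel of synthetic family ancestors plus T2SS-like
    decoys derived from the pilB/pilC/pilD ancestors at intermediate
    divergence (global-alignment identity kept inside (35%, 65%)).

    Returns the panel and the ancestor registry used to spawn genome genes
    (keyed by family; the two-component pilRS family contributes separate
    ``pilR`` and ``pilS`` ancestors).
    """
    roster = dict(families) if families is not None else dict(DEFAULT_ROSTER)
    missing = CORE_FAMILIES - set(roster)
    if missing:
        raise ValueError(f"roster missing core families: {sorted(missing)}")
    rng = np.random.default_rng([0, seed])
    ancestors: dict[str, Ancestor] = {}
    defs: list[FamilyDef] = []

    for fam in sorted(roster):
        role = roster[fam]
        if fam == "pilA":
            anc = _make_pila_ancestor(rng)
            ancestors["pilA"] = anc
            defs.append(FamilyDef("pilA", role, (anc.seq,)))
        elif fam == "pilRS":
            r = Ancestor("pilR", "pilRS", _random_protein(rng, int(rng.integers(380, 480))))
            s = Ancestor("pilS", "pilRS", _random_protein(rng, int(rng.integers(300, 420))))
            ancestors["pilR"] = r
            ancestors["pilS"] = s
            defs.append(FamilyDef("pilRS", role, (r.seq, s.seq)))
        else:
            if fam in PILIN_FAMILIES:
                length = int(rng.integers(140, 231))
            elif fam == "pilQ":
                length = int(rng.integers(600, 901))
            else:
                length = int(rng.integers(200, 501))
            anc = Ancestor(fam, fam, _random_protein(rng, length))
            ancestors[fam] = anc
            defs.append(FamilyDef(fam, role, (anc.seq,)))

    for decoy, source in DECOY_SOURCES.items():
        if source not in ancestors:
            continue
        src = ancestors[source].seq
        for _ in range(25):
            d = float(rng.uniform(0.45, 0.55))
            cand = mutate(src, d, rng)
            _, a, b = global_align(src, cand)
            ident, _, _ = alignment_stats(a, b)
            if 35.0 < ident < 65.0:
                break
        ancestors[decoy] = Ancestor(decoy, decoy, cand)
        defs.append(FamilyDef(decoy, "decoy", (cand,)))

    return ReferencePanel(defs), ancestors


# ---------------------------------------------------------------------------
# Genome generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimProfile:
    """Study conditions for one synthetic genome."""

    organization: str  # clustered | dispersed
    n_pila_paralogs: int = 2
    divergence: float = 0.1
    decoy_families: int = 3
    fragmentation: float = 0.0  # expected contig breaks
    tandem_pila: bool = False  # two pilA side by side in the main locus
    seed: int = 0
    genome_id: str = "sim"
    taxon_label: str = ""

    def __post_init__(self) -> None:
        if self.organization not in {"clustered", "dispersed"}:
            raise ValueError(f"unknown organization {self.organization!r}")
        if not 1 <= self.n_pila_paralogs <= 7:
            raise ValueError("n_pila_paralogs must lie in 1..7")
        if not 0.0 <= self.divergence <= 0.6:
            raise ValueError("divergence must lie in [0, 0.6]")
        if self.fragmentation < 0 or self.decoy_families < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class PlantedTruth:
    genome_id: str
    organization: str
    family_by_gene: dict[str, str]  # truth family | 'background' | decoy name
    cluster_by_gene: dict[str, str]  # main | minor1..3 | mnopq (members only)
    n_pila: int
    pila_cluster_gene_ids: tuple[str, ...]
    pilb_gene_id: str | None
    ribf_gene_id: str | None
    fragmented: bool = False
    cut_inside_main: bool = False
    cys_mutated_gene_ids: tuple[str, ...] = ()


@dataclass
class _Row:
    seq: str
    product: str
    truth: str  # family / decoy name / 'background'
    cluster: str | None
    strand: str


def _spawn_gene(
    fam_key: str,
    ancestors: dict[str, Ancestor],
    divergence: float,
    rng: np.random.Generator,
    drop_cys: bool = False,
) -> str:
    anc = ancestors[fam_key]
    if anc.family == "pilA":
        seq = mutate(
            anc.seq, divergence, rng, protected=anc.protected, slow_span=anc.slow_span
        )
        if drop_cys:
            out = list(seq)
            for pos in anc.cys_positions:
                out[pos] = "S"
            seq = "".join(out)
        return seq
    return mutate(anc.seq, divergence, rng)


def generate_genome(
    profile: SimProfile, ancestors: dict[str, Ancestor]
) -> tuple[Genome, PlantedTruth]:
    """Emit one annotated genome matching the profile, plus its truth table.

    Clustered layout: minor pilin loci and scattered singletons, then the
    main locus emitted with pilB at its ribF-proximal end (all '+' strand) so
    ribF sits directly downstream of pilB in transcription direction.
    Dispersed layout: contiguous pilMNOPQ, everything else (ribF included)
    scattered with >= MIN_SPACER background genes in between.
    """
    rng = np.random.default_rng([1, profile.seed])
    rows: list[_Row] = []

    def add_bg(k: int) -> None:
        for _ in range(k):
            rows.append(
                _Row(
                    seq=_random_protein(rng, int(rng.integers(150, 351))),
                    product=BACKGROUND_PRODUCTS[rng.integers(len(BACKGROUND_PRODUCTS))],
                    truth="background",
                    cluster=None,
                    strand="+-"[rng.integers(2)],
                )
            )

    def add_gene(
        fam_key: str, cluster: str | None, strand: str = "+", drop_cys: bool = False
    ) -> None:
        fam = ancestors[fam_key].family
        rows.append(
            _Row(
                seq=_spawn_gene(fam_key, ancestors, profile.divergence, rng, drop_cys),
                product=f"{fam} family protein",
                truth=fam,
                cluster=cluster,
                strand=strand,
            )
        )

    def spacer() -> None:
        add_bg(MIN_SPACER + int(rng.integers(0, 4)))

    n_scattered_pila = profile.n_pila_paralogs - (2 if profile.tandem_pila else 1)
    decoys = list(DECOY_SOURCES)[: profile.decoy_families]

    if profile.organization == "clustered":
        add_bg(int(rng.integers(3, 7)))
        for fam in ("fimU", "pilW", "pilV", "pilY1", "pilX"):
            add_gene(fam, "minor1")
        spacer()
        for fam in ("fimU", "pilW", "pilV", "pilY1", "pilX"):
            add_gene(fam, "minor2")
        spacer()
        add_gene("pilW", "minor3")
        add_bg(1)  # the single intervening gene of the pilW-x-pilY1 locus
        add_gene("pilY1", "minor3")
        spacer()
        scattered = ["pilD", "pilF", "pilE"] + ["pilA"] * n_scattered_pila + decoys
        for fam in scattered:
            add_gene(fam, None, strand="+-"[rng.integers(2)], drop_cys=(fam == "pilA"))
            spacer()
        # main locus: reversed transcription order puts pilB last, ribF at +1
        slots = list(reversed(main_locus_order()))
        for slot in slots:
            key = slot if slot_family(slot) != "pilRS" else ("pilR" if slot.startswith("pilR") else "pilS")
            add_gene(key, "main")
            if slot == "pilA" and profile.tandem_pila:
                add_gene("pilA", "main")
        add_gene("ribF", None)
        add_bg(int(rng.integers(3, 7)))
    else:
        add_bg(int(rng.integers(3, 7)))
        for fam in ("pilM", "pilN", "pilO", "pilP", "pilQ"):
            add_gene(fam, "mnopq")
        spacer()
        scattered = (
            ["pilA"] * profile.n_pila_paralogs
            + ["pilB", "pilC", "pilD", "pilT", "tsaP", "fimU", "pilV", "pilW",
               "pilX", "pilE", "pilY1", "pilF", "pilG", "pilH", "pilI",
               "pilR", "pilS", "ribF"]
            + decoys
        )
        for i, fam in enumerate(scattered):
            add_gene(fam, None, strand="+-"[rng.integers(2)],
                     drop_cys=(fam == "pilA" and i > 0))
            spacer()
        add_bg(int(rng.integers(0, 4)))

    # fragmentation: cut at random intergenic points
    n_cuts = int(rng.poisson(profile.fragmentation)) if profile.fragmentation > 0 else 0
    n_cuts = min(n_cuts, len(rows) - 1)
    cut_points = sorted(
        int(c) for c in rng.choice(np.arange(1, len(rows)), size=n_cuts, replace=False)
    ) if n_cuts else []

    gid = profile.genome_id
    gene_ids = [f"{gid}_g{i:04d}" for i in range(len(rows))]
    bounds = [0] + cut_points + [len(rows)]
    contigs: list[Contig] = []
    proteins: dict[str, str] = {}
    for ci, (lo, hi) in enumerate(zip(bounds, bounds[1:]), start=1):
        cid = f"{gid}_c{ci}"
        pos = 1
        feats = []
        for i in range(lo, hi):
            row = rows[i]
            start = pos + int(rng.integers(20, 201))
            end = start + 3 * len(row.seq) + 2
            feats.append(
                GeneFeature(
                    gene_id=gene_ids[i],
                    contig_id=cid,
                    start=start,
                    end=end,
                    strand=row.strand,
                    product=row.product,
                )
            )
            proteins[gene_ids[i]] = row.seq
            pos = end
        contigs.append(Contig(contig_id=cid, length=pos + 100, genes=feats))

    genome = Genome(
        genome_id=gid,
        taxon_label=profile.taxon_label or gid,
        contigs=contigs,
        proteins=proteins,
    )

    main_idx = [i for i, r in enumerate(rows) if r.cluster == "main"]
    cut_inside_main = bool(main_idx) and any(
        main_idx[0] < c <= main_idx[-1] for c in cut_points
    )
    pilb = next(
        (gene_ids[i] for i, r in enumerate(rows) if r.truth == "pilB"), None
    )
    ribf = next(
        (gene_ids[i] for i, r in enumerate(rows) if r.truth == "ribF"), None
    )
    truth = PlantedTruth(
        genome_id=gid,
        organization=profile.organization,
        family_by_gene={gene_ids[i]: r.truth for i, r in enumerate(rows)},
        cluster_by_gene={
            gene_ids[i]: r.cluster for i, r in enumerate(rows) if r.cluster
        },
        n_pila=profile.n_pila_paralogs,
        pila_cluster_gene_ids=tuple(
            gene_ids[i]
            for i, r in enumerate(rows)
            if r.truth == "pilA" and r.cluster == "main"
        ),
        pilb_gene_id=pilb,
        ribf_gene_id=ribf,
        fragmented=n_cuts > 0,
        cut_inside_main=cut_inside_main,
        cys_mutated_gene_ids=tuple(
            gene_ids[i]
            for i, r in enumerate(rows)
            if r.truth == "pilA" and r.cluster is None
        ),
    )
    return genome, truth


def generate_cohort(
    n: int,
    mix: float,
    seed: int,
    ancestors: dict[str, Ancestor] | None = None,
    divergence_range: tuple[float, float] = (0.05, 0.35),
    fragmentation: float = 0.0,
) -> tuple[list[tuple[Genome, PlantedTruth]], pd.DataFrame]:
    """A cohort of independent genomes: the first ``round(n * mix)`` are
    clustered, the rest dispersed. Per-genome divergence is drawn uniformly
    from ``divergence_range`` and pilA copy number from 1..7. Per-genome
    seeds derive from the master seed, so equal master seeds give identical
    cohorts."""
    if n < 1 or not 0.0 <= mix <= 1.0:
        raise ValueError("need n >= 1 and mix in [0, 1]")
    master = np.random.default_rng([2, seed])
    if ancestors is None:
        _, ancestors = generate_panel(int(master.integers(0, 2**31 - 1)))
    n_clustered = round(n * mix)
    out = []
    rows = []
    for i in range(n):
        org = "clustered" if i < n_clustered else "dispersed"
        profile = SimProfile(
            organization=org,
            n_pila_paralogs=int(master.integers(1, 8)),
            divergence=float(master.uniform(*divergence_range)),
            fragmentation=fragmentation,
            seed=int(master.integers(0, 2**31 - 1)),
            genome_id=f"sim{i:03d}",
        )
        genome, truth = generate_genome(profile, ancestors)
        out.append((genome, truth))
        rows.append(
            {
                "genome": genome.genome_id,
                "organization": truth.organization,
                "n_pila": truth.n_pila,
                "divergence": round(profile.divergence, 4),
                "fragmented": truth.fragmented,
                "cut_inside_main": truth.cut_inside_main,
            }
        )
    return out, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures transcribed from known architectures
# ---------------------------------------------------------------------------


def dk1622_fixture(
    ancestors: dict[str, Ancestor], seed: int = 1, divergence: float = 0.1
) -> tuple[Genome, PlantedTruth]:
    """Single-contig genome with the canonical 17-gene main locus, the three
    minor pilin loci of the Myxococcaceae arrangement, and a second scattered
    pilA paralog."""
    return generate_genome(
        SimProfile(
            organization="clustered",
            n_pila_paralogs=2,
            divergence=divergence,
            fragmentation=0.0,
            seed=seed,
            genome_id="MxDK1622_fixture",
            taxon_label="Myxococcus-like fixture",
        ),
        ancestors,
    )


def saurantiaca_fixture(
    ancestors: dict[str, Ancestor], seed: int = 2, divergence: float = 0.1
) -> tuple[Genome, PlantedTruth]:
    """Clustered genome with tandem pilA genes inside the main locus (the
    Stigmatella-like arrangement)."""
    return generate_genome(
        SimProfile(
            organization="clustered",
            n_pila_paralogs=2,
            divergence=divergence,
            fragmentation=0.0,
            tandem_pila=True,
            seed=seed,
            genome_id="Saur_fixture",
            taxon_label="Stigmatella-like fixture",
        ),
        ancestors,
    )


def seeded_validation_cohort(
    ancestors: dict[str, Ancestor],
    n: int = 100,
    fragmentation: float = 0.3,
) -> list[tuple[Genome, PlantedTruth]]:
    """Planted-recovery cohort with per-genome seeds 1..n: the first half
    clustered, the second dispersed; divergence drawn per genome from
    [0.05, 0.35] and pilA copy number from 1..7 off the genome's own seed."""
    out = []
    for i in range(1, n + 1):
        rng = np.random.default_rng(i)
        profile = SimProfile(
            organization="clustered" if i <= n // 2 else "dispersed",
            n_pila_paralogs=int(rng.integers(1, 8)),
            divergence=float(rng.uniform(0.05, 0.35)),
            fragmentation=fragmentation,
            seed=i,
            genome_id=f"val{i:03d}",
        )
        out.append(generate_genome(profile, ancestors))
    return out


def generate_pilt_subfamilies(
    seed: int,
    ancestors: dict[str, Ancestor],
    n_cluster: int = 6,
    n_scattered: int = 6,
    within_divergence: float = 0.06,
    between_factor: float = 3.0,
) -> tuple[list[str], list[str], list[str]]:
    """PilT sequences from two subfamilies: cluster-resident copies descend
    from one subfamily ancestor, scattered copies from another, with
    between-subfamily divergence ``between_factor`` times the within-subfamily
    divergence. Returns (labels, sequences, cluster_resident_labels)."""
    rng = np.random.default_rng([3, seed])
    root = ancestors["pilT"].seq
    # pairwise within ~ 2*dw; between ~ 2*db + 2*dw  =>  db = (f-1)*dw
    db = (between_factor - 1.0) * within_divergence
    anc_cluster = mutate(root, db, rng)
    anc_scattered = mutate(root, db, rng)
    labels, seqs, resident = [], [], []
    for i in range(n_cluster):
        labels.append(f"cluster_pilT_{i}")
        seqs.append(mutate(anc_cluster, within_divergence, rng))
        resident.append(labels[-1])
    for i in range(n_scattered):
        labels.append(f"scattered_pilT_{i}")
        seqs.append(mutate(anc_scattered, within_divergence, rng))
    return labels, seqs, resident
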