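"""Sequence diagnostics of major pilin (PilA) proteins.

Type IVa major pilins are made as prepilins: a short positively charged
leader peptide is cleaved by the prepilin peptidase PilD immediately after an
invariant glycine (the class III signal), leaving a mature protein whose
first ~60 residues (the alpha-helical stalk) are strongly conserved while the
C-terminal globular head diverges. Cluster-resident PilA proteins typically
end in a disulfide-bonded loop (DSL / D-region): two cysteines close to the
C-terminus that staple the receptor-binding loop. Paralogs encoded away from
the main T4aP cluster often lack the terminal pair or carry a mid-C-terminal
pair instead — the diagnostics here classify exactly that contrast.

All positional defaults (motif, window, loop bounds) are configurable; they
describe canonical prepilin biology rather than any one genome.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .homology import alignment_stats, global_align
from .phylo import MultipleAlignment, progressive_align

#: class III signal peptide consensus around the PilD cleavage glycine
CLEAVAGE_MOTIF = r"G[FY][ST]L[ILMV]E"
SEARCH_WINDOW = 50
CTERM_FRACTION = 0.5
MIN_LOOP = 6
MAX_LOOP = 60
TERMINAL_WINDOW = 15
NTERM_WINDOW = 60


@dataclass(frozen=True)
class PilinFeatures:
    gene_id: str
    cleavage_pos: int | None  # 0-based index of the motif Gly; mature = seq[pos+1:]
    nterm_extension_len: int | None  # residues strictly before the cleavage Gly
    cys_positions: tuple[int, ...]  # mature-sequence indices
    dsl_class: str  # terminal_dsl | mid_cterm_pair | none
    in_t4ap_cluster: bool = False


def find_cleavage_site(
    sequence: str,
    motif: str = CLEAVAGE_MOTIF,
    search_window: int = SEARCH_WINDOW,
) -> int | None:
    """Leftmost match of the prepilin motif whose glycine lies within the
    first ``search_window`` residues; cleavage occurs after that glycine.
    Returns the 0-based index of the glycine, or None."""
    m = re.search(motif, sequence[: search_window + len(motif) - 1])
    if m is None or m.start() >= search_window:
        return None
    return m.start()


def mature_sequence(sequence: str, cleavage_pos: int | None) -> str:
    """Sequence downstream of the cleavage glycine (whole input if no site)."""
    return sequence if cleavage_pos is None else sequence[cleavage_pos + 1 :]


def find_dsl(
    mature_seq: str,
    cterm_fraction: float = CTERM_FRACTION,
    min_loop: int = MIN_LOOP,
    max_loop: int = MAX_LOOP,
    terminal_window: int = TERMINAL_WINDOW,
) -> tuple[tuple[int, ...], str]:
    """Locate the disulfide-bonded-loop cysteine pair in the C-terminal
    region of a mature pilin.

    Only cysteines in the C-terminal ``cterm_fraction`` of the sequence are
    considered. The loop is defined by the last Cys pair whose separation
    lies in [min_loop, max_loop]; it is ``terminal_dsl`` when the downstream
    Cys sits within ``terminal_window`` residues of the C-terminus, else
    ``mid_cterm_pair``. With fewer than two such cysteines: ``none``.
    """
    if not mature_seq:
        raise ValueError("empty mature sequence")
    L = len(mature_seq)
    floor = int(L * (1.0 - cterm_fraction))
    cys = tuple(i for i, c in enumerate(mature_seq) if c == "C" and i >= floor)
    if len(cys) < 2:
        return cys, "none"
    pair = None
    for b in range(len(cys) - 1, 0, -1):
        for a in range(b - 1, -1, -1):
            if min_loop <= cys[b] - cys[a] <= max_loop:
                pair = (cys[a], cys[b])
                break
        if pair:
            break
    if pair is None:
        return cys, "none"
    if L - 1 - pair[1] <= terminal_window:
        return cys, "terminal_dsl"
    return cys, "mid_cterm_pair"


def pilin_features(
    gene_id: str,
    sequence: str,
    in_t4ap_cluster: bool = False,
    motif: str = CLEAVAGE_MOTIF,
    search_window: int = SEARCH_WINDOW,
    **dsl_params,
) -> PilinFeatures:
    """Full diagnostic record for one pilin candidate. DSL classification is
    computed on the mature sequence, so it is invariant to prepending
    signal-peptide residues."""
    pos = find_cleavage_site(sequence, motif, search_window)
    mature = mature_sequence(sequence, pos)
    cys, dsl = find_dsl(mature, **dsl_params) if mature else ((), "none")
    return PilinFeatures(
        gene_id=gene_id,
        cleavage_pos=pos,
        nterm_extension_len=pos if pos is not None else None,
        cys_positions=cys,
        dsl_class=dsl,
        in_t4ap_cluster=in_t4ap_cluster,
    )


@dataclass
class ConservationProfile:
    column_fractions: np.ndarray  # per-column modal-residue fraction
    window_mean: float
    window: int

    def tail_mean(self) -> float:
        """Mean conservation over the columns after the N-terminal window."""
        tail = self.column_fractions[self.window :]
        return float(tail.mean()) if tail.size else float("nan")


def nterm_conservation(
    mature_sequences: Sequence[str],
    window: int = NTERM_WINDOW,
    alignment: MultipleAlignment | None = None,
) -> ConservationProfile:
    """Per-column conservation of aligned mature pilins; ``window_mean`` is
    the mean modal-residue fraction over the first ``window`` columns (the
    conserved N-terminal stalk). Gap characters count as a column symbol."""
    if alignment is None:
        if len(mature_sequences) < 2:
            raise ValueError("need >=2 sequences")
        alignment = progressive_align(list(mature_sequences))
    cols = np.array([list(r) for r in alignment.rows])
    fractions = np.empty(cols.shape[1])
    for j in range(cols.shape[1]):
        _, counts = np.unique(cols[:, j], return_counts=True)
        fractions[j] = counts.max() / cols.shape[0]
    head = fractions[: min(window, len(fractions))]
    return ConservationProfile(fractions, float(head.mean()), window)


def paralog_matrix(
    pilin_sequences: Sequence[str], labels: Sequence[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise percent identity and similarity from global alignment of each
    pair; symmetric, diagonal 100. Returns (identity, similarity) frames."""
    n = len(pilin_sequences)
    if n < 2:
        raise ValueError("need >=2 sequences")
    labels = list(labels) if labels is not None else [f"p{i}" for i in range(n)]
    ident = np.full((n, n), 100.0)
    simil = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            _, a, b = global_align(pilin_sequences[i], pilin_sequences[j])
            pid, psim, _ = alignment_stats(a, b)
            ident[i, j] = ident[j, i] = pid
            simil[i, j] = simil[j, i] = psim
    return (
        pd.DataFrame(ident, index=labels, columns=labels),
        pd.DataFrame(simil, index=labels, columns=labels),
    )


def features_table(features: Sequence[PilinFeatures]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": f.gene_id,
            "cleavage_pos": f.cleavage_pos if f.cleavage_pos is not None else -1,
            "n_cys": len(f.cys_positions),
            "dsl_class": f.dsl_class,
            "in_cluster": f.in_t4ap_cluster,
        }
        for f in features
    ]
    return pd.DataFrame(
        rows, columns=["gene_id", "cleavage_pos", "n_cys", "dsl_class", "in_cluster"]
    )
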