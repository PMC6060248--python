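"""Cluster detection, architecture strings, organization calls."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import clusters_by_components
from t4apscan import (
    architecture_string,
    call_organization,
    classify_all,
    classify_cluster,
    count_paralogs,
    detect_clusters,
    flag_split_clusters,
    parse_architecture,
)
from t4apscan.cluster_detect import GeneCluster
from t4apscan.genome_io import Contig, GeneFeature, Genome
from t4apscan.homology import FamilyAssignment, UNASSIGNED


def toy_genome(n_genes, contig="c1", n_contigs=1):
    contigs = []
    for c in range(n_contigs):
        genes = [
            GeneFeature(f"{contig}{c}_g{i}", f"{contig}{c}", 100 * i + 1, 100 * i + 50, "+")
            for i in range(n_genes)
        ]
        contigs.append(Contig(f"{contig}{c}", 100 * n_genes + 100, genes))
    return Genome("toy", "toy", contigs)


def assign(genome, fam_by_gene):
    return [
        FamilyAssignment(g.gene_id, fam_by_gene.get(g.gene_id, UNASSIGNED))
        for g in genome.genes()
    ]


class TestDetectClusters:
    def test_no_assigned_genes_gives_empty_list(self):
        genome = toy_genome(8)
        assert detect_clusters(genome, assign(genome, {}), 5) == []

    def test_gap_rule_boundary(self):
        genome = toy_genome(10)
        fams = {"c10_g0": "pilB", "c10_g3": "pilT"}  # 2 intervening genes
        got = detect_clusters(genome, assign(genome, fams), max_gap=2)
        assert len(got) == 1 and got[0].gaps == [2]
        got = detect_clusters(genome, assign(genome, fams), max_gap=1)
        assert [c.size for c in got] == [1, 1]

    def test_unknown_gene_in_assignments_rejected(self):
        genome = toy_genome(3)
        with pytest.raises(ValueError, match="unknown gene"):
            detect_clusters(genome, [FamilyAssignment("ghost", "pilB")], 5)

    def test_matches_component_oracle_on_random_contigs(self):
        rng = np.random.default_rng(99)
        fams = ["pilA", "pilB", "pilM", "pilT", "fimU"]
        for _ in range(300):
            n = int(rng.integers(1, 21))
            genome = toy_genome(n)
            genes = genome.contigs[0].genes
            mask = rng.random(n) < 0.4
            fam_by_gene = {
                genes[i].gene_id: fams[int(rng.integers(len(fams)))]
                for i in range(n) if mask[i]
            }
            max_gap = int(rng.integers(0, 6))
            got = detect_clusters(genome, assign(genome, fam_by_gene), max_gap)
            got_idx = [
                [m[0] for m in c.members] for c in got
            ]
            expected = clusters_by_components(
                [g.locus_index for g in genes if g.gene_id in fam_by_gene], max_gap
            )
            expected_ids = [[genes[i].gene_id for i in comp] for comp in expected]
            assert got_idx == expected_ids

    def test_clusters_partition_assigned_genes(self, dk):
        genome, _, assignments, clusters = dk
        member_ids = [gid for c in clusters for gid, _, _ in c.members]
        assert len(member_ids) == len(set(member_ids))
        assigned = {
            a.gene_id for a in assignments
            if a.family not in (UNASSIGNED, "ribF")
        }
        assert set(member_ids) == assigned

    def test_reversal_invariance(self):
        genome = toy_genome(12)
        fams = {"c10_g1": "pilB", "c10_g2": "pilT", "c10_g6": "pilM",
                "c10_g7": "pilN", "c10_g8": "pilO"}
        fwd = detect_clusters(genome, assign(genome, fams), 2)
        # reverse coordinates and strands on the same contig
        L = genome.contigs[0].length
        rev_genes = [
            GeneFeature(g.gene_id, g.contig_id, L - g.end + 1, L - g.start + 1,
                        "-" if g.strand == "+" else "+")
            for g in genome.contigs[0].genes
        ]
        rev = Genome("toy", "toy", [Contig("c10", L, rev_genes)])
        bwd = detect_clusters(rev, assign(rev, fams), 2)
        fwd_sets = sorted(
            (frozenset(gid for gid, _, _ in c.members) for c in fwd), key=sorted
        )
        bwd_sets = sorted(
            (frozenset(gid for gid, _, _ in c.members) for c in bwd), key=sorted
        )
        assert fwd_sets == bwd_sets
        # member order (hence the architecture string) reverses per cluster
        fwd_by_set = {frozenset(m[0] for m in c.members): c for c in fwd}
        for c in bwd:
            mate = fwd_by_set[frozenset(m[0] for m in c.members)]
            assert [m[0] for m in c.members] == [m[0] for m in mate.members][::-1]
            assert c.gaps == mate.gaps[::-1]


class TestArchitecture:
    @pytest.mark.parametrize(
        "families,gaps,expected",
        [
            (["fimU", "pilW", "pilV", "pilY1", "pilX"], [0, 0, 0, 0],
             "fimU-pilW-pilV-pilY1-pilX"),
            (["pilW", "pilY1"], [1], "pilW-x-pilY1"),
            (["pilB", "pilT"], [3], "pilB-[3]-pilT"),
            (["pilQ"], [], "pilQ"),
        ],
    )
    def test_rendering(self, families, gaps, expected):
        assert architecture_string(families, gaps) == expected

    @settings(max_examples=200, deadline=None)
    @given(
        families=st.lists(
            st.sampled_from(["pilA", "pilB", "pilW", "pilY1", "fimU", "tsaP"]),
            min_size=1, max_size=8,
        ),
        gaps=st.lists(st.integers(min_value=0, max_value=9), max_size=7),
    )
    def test_parse_round_trip(self, families, gaps):
        gaps = (gaps + [0] * len(families))[: len(families) - 1]
        arch = architecture_string(families, gaps)
        assert parse_architecture(arch) == (families, gaps)


def _cluster(families, gaps=None, contig="c1", first=10):
    gaps = gaps if gaps is not None else [0] * (len(families) - 1)
    members = [(f"{contig}_{f}_{i}", f, "+") for i, f in enumerate(families)]
    last = first + len(families) - 1 + sum(gaps)
    return GeneCluster(contig, members, gaps, first_locus_index=first,
                       last_locus_index=last)


class TestClassify:
    def test_minor_pilin_cluster(self):
        c = classify_cluster(_cluster(["fimU", "pilW", "pilV", "pilY1", "pilX"]))
        assert c.label == "minor_pilin"
        assert c.architecture == "fimU-pilW-pilV-pilY1-pilX"

    def test_pilw_x_pily1(self):
        c = classify_cluster(_cluster(["pilW", "pilY1"], [1]))
        assert c.label == "minor_pilin"
        assert c.architecture == "pilW-x-pilY1"

    def test_mnopq(self):
        c = classify_cluster(_cluster(["pilM", "pilN", "pilO", "pilP", "pilQ"]))
        assert c.label == "mnopq"

    def test_minor_singleton_is_other(self):
        assert classify_cluster(_cluster(["pilE"])).label == "other"

    def test_main_requires_size_and_core(self):
        fams = ["pilB", "pilT", "pilC", "pilA", "pilM", "pilN", "pilO", "pilP",
                "pilQ", "tsaP"]
        assert classify_cluster(_cluster(fams)).label == "main"
        # ten members but too few core families
        fams2 = ["pilB", "fimU", "pilV", "pilW", "pilX", "pilE", "pilY1",
                 "pilG", "pilH", "pilI"]
        assert classify_cluster(_cluster(fams2)).label != "main"


class TestOrganization:
    def test_clustered_fixture(self, dk):
        genome, _, _, clusters = dk
        call = call_organization(genome, clusters)
        assert call.call == "clustered"
        assert call.main_cluster_size == 17

    def test_zero_t4ap_genes_is_ambiguous(self):
        genome = toy_genome(5)
        assert call_organization(genome, []).call == "ambiguous"

    def test_dispersed_profile(self):
        genome = toy_genome(5)
        clusters = classify_all(
            [_cluster(["pilM", "pilN", "pilO", "pilP", "pilQ"]), _cluster(["pilB"])]
        )
        assert call_organization(genome, clusters).call == "dispersed"


MAIN_FAMS = ["pilQ", "pilP", "pilO", "pilN", "pilM", "tsaP", "pilI", "pilH",
             "pilG", "pilRS", "pilRS", "pilRS", "pilRS", "pilA", "pilC",
             "pilT", "pilB"]


def split_genome(pad_left=0, pad_right=0):
    """17-gene main locus cut 9/8 across two contigs, with optional padding
    placing the fragments away from the contig ends."""
    rows_a = ["bg"] * pad_left + MAIN_FAMS[:9] + ["bg"] * pad_right
    rows_b = ["bg"] * pad_left + MAIN_FAMS[9:] + ["bg"] * pad_right
    contigs, fam_by_gene = [], {}
    for cid, rows in (("cA", rows_a), ("cB", rows_b)):
        genes = []
        for i, fam in enumerate(rows):
            gid = f"{cid}_g{i}"
            genes.append(GeneFeature(gid, cid, 100 * i + 1, 100 * i + 50, "+"))
            if fam != "bg":
                fam_by_gene[gid] = fam
        contigs.append(Contig(cid, 100 * len(rows) + 100, genes))
    genome = Genome("split", "split", contigs)
    return genome, fam_by_gene


class TestSplitClusters:
    def test_edge_fragments_flagged_and_upgraded(self):
        genome, fams = split_genome()
        clusters = classify_all(detect_clusters(genome, assign(genome, fams), 5))
        assert all(c.label != "main" for c in clusters)
        clusters = flag_split_clusters(genome, clusters)
        assert sum(c.split_flag for c in clusters) == 2
        call = call_organization(genome, clusters)
        assert call.call == "clustered" and call.split_candidate
        assert call.main_cluster_size == 17

    def test_mid_contig_fragments_not_flagged(self):
        genome, fams = split_genome(pad_left=8, pad_right=8)
        clusters = classify_all(detect_clusters(genome, assign(genome, fams), 5))
        clusters = flag_split_clusters(genome, clusters)
        assert not any(c.split_flag for c in clusters)
        assert call_organization(genome, clusters).call == "ambiguous"

    def test_single_contig_never_flagged(self, dk):
        genome, _, _, clusters = dk
        assert not any(
            c.split_flag for c in flag_split_clusters(genome, clusters)
        )


class TestParalogCount:
    def test_planted_counts_recovered(self, panel, ancestors):
        from t4apscan import SimProfile, assign_families, generate_genome

        for k in (1, 4, 7):
            genome, truth = generate_genome(
                SimProfile(organization="clustered", n_pila_paralogs=k,
                           divergence=0.3, seed=40 + k, genome_id=f"pk{k}"),
                ancestors,
            )
            assignments = assign_families(genome, panel)
            assert count_paralogs(assignments, "pilA") == k

    def test_absent_family_counts_zero(self, dk):
        _, _, assignments, _ = dk
        assert count_paralogs(assignments, "pilZ") == 0

    def test_invariant_under_contig_order(self):
        a = [FamilyAssignment("g1", "pilA"), FamilyAssignment("g2", "pilA")]
        assert count_paralogs(a, "pilA") == count_paralogs(a[::-1], "pilA") == 2
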