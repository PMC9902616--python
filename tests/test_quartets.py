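"""Quartet topology weighting, discordance testing and ingroup scores."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from arctos.core import ArctosError, ConfigurationError
from arctos.quartets import (
    GeneTreeSet,
    analyze_quartets,
    assign_species_topology,
    count_quartets,
    count_triplets,
    dstat,
    gene_trees_from_haplotypes,
    ingroup_scores,
    quartet_topologies,
    quartet_weights,
    simplex_coords,
    topology_key,
    tree_quartet_weights,
    zscore,
)


def gts_from_newicks(newicks, chroms, tip_pop):
    trees = [dendropy.Tree.get(data=nwk, schema="newick") for nwk in newicks]
    return GeneTreeSet(trees=trees, chrom=chroms, tip_pop=tip_pop)


QUARTET = ("A", "B", "C", "D")
TIP4 = {"a1": "A", "b1": "B", "c1": "C", "d1": "D"}


class TestWeights:
    def test_single_tip_per_population_resolved_tree(self):
        gts = gts_from_newicks(["((a1,b1),(c1,d1));"], ["c1"], TIP4)
        w = quartet_weights(gts, QUARTET)
        np.testing.assert_allclose(w.loc["c1"].to_numpy(), [1.0, 0.0, 0.0])

    def test_consistent_multi_tip_tree_gives_unit_weight(self):
        tip = {"a1": "A", "a2": "A", "b1": "B", "b2": "B",
               "c1": "C", "c2": "C", "d1": "D", "d2": "D"}
        nwk = "(((a1,a2),(b1,b2)),((c1,c2),(d1,d2)));"
        gts = gts_from_newicks([nwk], ["c1"], tip)
        w = quartet_weights(gts, QUARTET)
        np.testing.assert_allclose(w.loc["c1"].to_numpy(), [1.0, 0.0, 0.0])

    def test_weights_sum_to_one_per_tree(self, rng):
        for _ in range(5):
            labels = [f"{p.lower()}{i}" for p in QUARTET for i in (1, 2)]
            perm = rng.permutation(labels)
            nwk = f"((({perm[0]},{perm[1]}),({perm[2]},{perm[3]})),(({perm[4]},{perm[5]}),({perm[6]},{perm[7]})));"
            tip = {lab: lab[0].upper() for lab in labels}
            gts = gts_from_newicks([nwk], ["c1"], tip)
            w = tree_quartet_weights(gts, 0, QUARTET)
            assert w.sum() == pytest.approx(1.0)

    def test_sampling_close_to_exhaustive(self, rng):
        labels = [f"{p.lower()}{i}" for p in QUARTET for i in (1, 2)]
        perm = rng.permutation(labels)
        nwk = ("(((" + ",".join(perm[:2]) + "),(" + ",".join(perm[2:4]) + ")),"
               "((" + ",".join(perm[4:6]) + "),(" + ",".join(perm[6:]) + ")));")
        tip = {lab: lab[0].upper() for lab in labels}
        gts = gts_from_newicks([nwk], ["c1"], tip)
        exact = tree_quartet_weights(gts, 0, QUARTET, max_exhaustive=10_000)
        n_samp = 2000
        sampled = tree_quartet_weights(gts, 0, QUARTET, max_exhaustive=n_samp - 1,
                                       rng=np.random.default_rng(3))
        se = np.sqrt(exact * (1 - exact) / n_samp) + 1e-9
        assert np.all(np.abs(sampled - exact) <= 3 * se + 0.02)

    def test_haplotype_relabelling_leaves_weights_unchanged(self):
        nwk = "((a1,b2),((a2,b1),(c1,d1)));"
        tip = {"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C", "d1": "D"}
        gts = gts_from_newicks([nwk], ["c1"], tip)
        w1 = tree_quartet_weights(gts, 0, QUARTET)
        swapped = {"a1": "A", "a2": "A", "b2": "B", "b1": "B", "c1": "C", "d1": "D"}
        gts2 = gts_from_newicks([nwk], ["c1"], swapped)
        w2 = tree_quartet_weights(gts2, 0, QUARTET)
        np.testing.assert_allclose(w1, w2)

    def test_population_absent_from_all_trees_raises(self):
        gts = gts_from_newicks(["((a1,b1),(c1,d1));"], ["c1"], TIP4)
        with pytest.raises(ConfigurationError):
            quartet_weights(gts, ("A", "B", "C", "E"))


class TestSpeciesTopology:
    def test_pruning_worked_examples(self):
        ref = dendropy.Tree.get(data="((A,B),(C,D),E);", schema="newick")
        assert assign_species_topology(ref, ["A", "B", "C", "D"]) == \
            topology_key(("A", "B"), ("C", "D"))
        assert assign_species_topology(ref, ["A", "C", "D", "E"]) == \
            topology_key(("C", "D"), ("A", "E"))

    def test_missing_population_raises(self):
        ref = dendropy.Tree.get(data="((A,B),(C,D));", schema="newick")
        with pytest.raises(ConfigurationError):
            assign_species_topology(ref, ["A", "B", "C", "X"])

    def test_agrees_with_rf_distance_minimisation(self, rng):
        """Cross-oracle: the pruned-tree topology is the zero-RF candidate."""
        pops = [f"P{i}" for i in range(8)]
        for _ in range(30):
            # random binary topology by sequential random joins
            nodes = [dendropy.Node() for _ in pops]
            taxa = dendropy.TaxonNamespace(pops)
            for node, p in zip(nodes, pops):
                node.taxon = taxa.get_taxon(p)
            while len(nodes) > 3:
                i, j = sorted(rng.choice(len(nodes), 2, replace=False))
                parent = dendropy.Node()
                parent.add_child(nodes[i])
                parent.add_child(nodes[j])
                nodes = [nodes[k] for k in range(len(nodes)) if k not in (i, j)] + [parent]
            root = dendropy.Node()
            for node in nodes:
                root.add_child(node)
            ref = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
            ref.is_rooted = False
            quartet = sorted(rng.choice(pops, 4, replace=False))
            mine = assign_species_topology(ref, quartet)

            # oracle: build the three candidate quartet trees, pick zero RF
            pruned = ref.extract_tree_with_taxa_labels(labels=quartet)
            best = None
            for topo in quartet_topologies(quartet):
                (x1, x2), (y1, y2) = [sorted(p) for p in sorted(topo, key=sorted)]
                tns = dendropy.TaxonNamespace(quartet)
                cand = dendropy.Tree.get(data=f"(({x1},{x2}),({y1},{y2}));",
                                         schema="newick", taxon_namespace=tns)
                cand.encode_bipartitions()
                pr = dendropy.Tree.get(data=pruned.as_string(schema="newick"),
                                       schema="newick", taxon_namespace=tns)
                pr.encode_bipartitions()
                rf = dendropy.calculate.treecompare.symmetric_difference(cand, pr)
                if rf == 0:
                    best = topo
            assert best is not None and mine == best


class TestDandZ:
    def test_dstat_values(self):
        assert dstat(10, 10) == 0.0
        assert dstat(5, 0) == 1.0
        assert dstat(30, 10) == pytest.approx(0.5)
        with pytest.raises(ArctosError):
            dstat(0, 0)

    def test_zscore_definition_and_edge_cases(self):
        d = [0.2, 0.3, 0.25, 0.15]
        expected = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(4))
        assert zscore(d) == pytest.approx(expected)
        assert zscore([0.5, 0.5, 0.5]) == math.inf
        assert zscore([0.0, 0.0]) == 0.0
        with pytest.raises(ArctosError):
            zscore([0.1])


class TestCountsAndSimplex:
    def test_combinatorial_counts(self):
        assert count_quartets(31) == 31465
        assert count_triplets(26) == 7800
        assert count_quartets(4) == 1
        # every pair of 31 populations appears in C(29, 2) quartets
        assert math.comb(31 - 2, 2) == 406

    def test_simplex_vertices_and_centroid(self):
        assert simplex_coords(1, 0, 0) == pytest.approx((0.5, math.sqrt(3) / 2))
        assert simplex_coords(0, 1, 0) == (0.0, 0.0)
        x, y = simplex_coords(1 / 3, 1 / 3, 1 / 3)
        assert (x, y) == pytest.approx((0.5, math.sqrt(3) / 6))
        assert simplex_coords(2, 2, 2) == pytest.approx(simplex_coords(1, 1, 1))


class TestIngroupScores:
    def _results(self, pops, rejected_quartets):
        """Quartet results over a star reference (q1 by lexicographic pairs)."""
        ref_newick = "(" + ",".join(f"({p}1)" for p in pops) + ");"
        # build a caterpillar reference: ((((A,B),C),D),...)
        nwk = pops[0]
        for p in pops[1:]:
            nwk = f"({nwk},{p})"
        ref = dendropy.Tree.get(data=nwk + ";", schema="newick")
        results = []
        from arctos.quartets import QuartetResult
        for quartet in itertools.combinations(sorted(pops), 4):
            q1 = assign_species_topology(ref, quartet)
            alts = [t for t in quartet_topologies(quartet) if t != q1]
            rejected = quartet in rejected_quartets
            results.append(QuartetResult(
                quartet=quartet, t1=10.0, t2=3.0, t3=1.0,
                q1=q1, q2=alts[0], d=0.5, z=6.0 if rejected else 1.0,
                rejected=rejected, n_chroms=4))
        return ref, results

    def test_no_rejections_gives_all_zero_scores(self):
        pops = ["A", "B", "C", "D", "E", "F"]
        _, results = self._results(pops, set())
        scores = ingroup_scores(results, pops)
        assert (scores["score"] == 0).all()
        assert (scores["n_alt"] + scores["n_t1"] == math.comb(4, 2)).all()

    def test_missing_quartets_detected(self):
        pops = ["A", "B", "C", "D", "E"]
        _, results = self._results(pops, set())
        with pytest.raises(ConfigurationError):
            ingroup_scores(results[:-1], pops)


class TestGeneTreesFromHaplotypes:
    def test_perfectly_structured_haplotypes_give_expected_topology(self):
        # 2 samples per pop; pops A,B identical blocks vs C,D
        n_sites = 30
        hap = np.zeros((8, n_sites), dtype=np.int8)
        hap[0:4, :10] = 1   # A+B haplotypes share derived block
        hap[4:8, 10:20] = 1  # C+D share another
        hap[0:2, 20:25] = 1  # A private
        hap[4:6, 25:30] = 1  # C private
        pos = np.arange(1, n_sites + 1) * 100
        chrom = np.array(["c1"] * n_sites, dtype=object)
        gts = gene_trees_from_haplotypes(
            hap, chrom, pos, ["sA", "sB", "sC", "sD"], ["A", "B", "C", "D"],
            locus_bp=10_000, min_sites=5)
        assert len(gts.trees) == 1
        w = quartet_weights(gts, QUARTET)
        topos = quartet_topologies(QUARTET)
        assert w.iloc[0, topos.index(topology_key(("A", "B"), ("C", "D")))] == \
            pytest.approx(1.0)

    def test_roundtrip_through_files(self, tmp_path, rng):
        hap = rng.integers(0, 2, size=(8, 40)).astype(np.int8)
        pos = np.arange(1, 41) * 100
        chrom = np.array(["c1"] * 40, dtype=object)
        gts = gene_trees_from_haplotypes(
            hap, chrom, pos, ["s1", "s2", "s3", "s4"], ["A", "A", "B", "B"],
            locus_bp=2_000, min_sites=3)
        nwk = tmp_path / "trees.nwk"
        side = tmp_path / "chrom.tsv"
        gts.write(str(nwk), str(side))
        from arctos.core import PopulationMap
        pm = PopulationMap.from_pairs({"s1": "A", "s2": "A", "s3": "B", "s4": "B"})
        back = GeneTreeSet.read(str(nwk), str(side), popmap=pm)
        assert len(back.trees) == len(gts.trees)
        assert back.chrom == gts.chrom
        assert set(back.populations()) == {"A", "B"}
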