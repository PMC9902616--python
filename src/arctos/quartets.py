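"""Quartet-topology weighting over gene trees and discordance testing.

Under the multispecies coalescent, incomplete lineage sorting makes gene
trees disagree with the species tree, but for any four populations the two
non-species quartet topologies are expected at *equal* frequency.  An excess
of one alternative (t2 > t3) indicates introgression.  For each population
quartet, gene trees are weighted by the fraction of one-tip-per-population
combinations inducing each of the three unrooted topologies (exact
enumeration up to a combination budget, seeded uniform sampling beyond it).
Weights are aggregated per chromosome; the imbalance is summarised as
``D = (t2 - t3) / (t2 + t3)`` with a z-score over chromosome-level D values,
and the null t2 = t3 is rejected at ``z >= 5``.  The ingroup-score
``n_t2 / n_alt`` then ranks population pairs by how often they form the
favoured alternative ingroup across all quartets, a genome-wide
introgression summary.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
import pandas as pd

from .core import ArctosError, ConfigurationError
from .trees import bionj, leaf_distance_matrix

Topology = frozenset  # frozenset({frozenset({A,B}), frozenset({C,D})})


def topology_key(pair1: Sequence[str], pair2: Sequence[str]) -> Topology:
    return frozenset({frozenset(pair1), frozenset(pair2)})


def quartet_topologies(quartet: Sequence[str]) -> list[Topology]:
    """The three unrooted topologies of a 4-population set, canonical order."""
    a, b, c, d = sorted(quartet)
    return [topology_key((a, b), (c, d)),
            topology_key((a, c), (b, d)),
            topology_key((a, d), (b, c))]


@dataclass
class GeneTreeSet:
    """Unrooted gene trees with haplotype tips mapped to populations."""

    trees: list[dendropy.Tree]
    chrom: list[str]  # chromosome label per tree
    tip_pop: dict[str, str]  # tip label -> population
    _dm_cache: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.trees) != len(self.chrom):
            raise ConfigurationError("one chromosome label per tree required")
        for tree in self.trees:
            for leaf in tree.leaf_node_iter():
                if leaf.taxon.label not in self.tip_pop:
                    raise ConfigurationError(
                        f"tip {leaf.taxon.label!r} maps to no population")
        self._dm_cache = [None] * len(self.trees)

    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.tip_pop.values():
            seen.setdefault(p, None)
        return list(seen)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def _topo_dm(self, k: int) -> tuple[dict[str, int], np.ndarray]:
        if self._dm_cache[k] is None:
            labels, dm = leaf_distance_matrix(self.trees[k], topological=True)
            self._dm_cache[k] = ({lab: i for i, lab in enumerate(labels)}, dm)
        return self._dm_cache[k]

    # -- I/O ------------------------------------------------------------
    def write(self, newick_path: str, sidecar_path: str) -> None:
        with open(newick_path, "w") as fh:
            for tree in self.trees:
                fh.write(tree.as_string(schema="newick", suppress_rooting=True))
        with open(sidecar_path, "w") as fh:
            fh.write("tree\tchrom\n")
            for i, c in enumerate(self.chrom):
                fh.write(f"{i}\t{c}\n")

    @classmethod
    def read(cls, newick_path: str, sidecar_path: str,
             tip_pop: dict[str, str] | None = None,
             popmap=None, sep: str = "|") -> "GeneTreeSet":
        """Read a multi-newick file plus a (tree index, chromosome) sidecar.

        Tip labels have the form ``sample<sep>hap``.  With a ``popmap``
        (:class:`~arctos.core.PopulationMap`) the sample part is looked up
        there; without one (and without an explicit ``tip_pop``) the sample
        part itself is used as the population label.
        """
        trees = dendropy.TreeList.get(path=newick_path, schema="newick")
        sidecar = pd.read_csv(sidecar_path, sep="\t")
        chrom = [str(c) for c in sidecar.sort_values("tree")["chrom"]]
        if tip_pop is None:
            tip_pop = {}
            for tree in trees:
                for leaf in tree.leaf_node_iter():
                    lab = leaf.taxon.label
                    sample = lab.split(sep)[0]
                    tip_pop[lab] = (popmap.population(sample) if popmap is not None
                                    else sample)
        return cls(trees=list(trees), chrom=chrom, tip_pop=tip_pop)


def tree_quartet_weights(
    gts: GeneTreeSet,
    tree_index: int,
    quartet: Sequence[str],
    max_exhaustive: int = 10_000,
    rng: Optional[np.random.Generator] = None,
) -> Optional[np.ndarray]:
    """Topology weights of one tree for one population quartet.

    Returns weights for the three canonical topologies (summing to 1), or
    None when some quartet population has no tip in this tree.  All
    one-tip-per-population combinations are enumerated when their number is
    at most ``max_exhaustive``; otherwise that many are sampled uniformly.
    The topology induced by a combination is read off the tree with the
    four-point condition on edge-count distances; exact ties (the
    combination sits on a polytomy) split their weight equally.
    """
    index, dm = gts._topo_dm(tree_index)
    tips = {p: [] for p in quartet}
    for lab, pop in gts.tip_pop.items():
        if pop in tips and lab in index:
            tips[pop].append(index[lab])
    sizes = [len(tips[p]) for p in quartet]
    if min(sizes) == 0:
        return None
    total = math.prod(sizes)
    qsorted = sorted(quartet)
    arrays = [np.array(tips[p]) for p in qsorted]
    if total <= max_exhaustive:
        combos = np.array(list(itertools.product(*arrays)))
    else:
        rng = rng or np.random.default_rng()
        combos = np.column_stack([rng.choice(a, size=max_exhaustive) for a in arrays])
    w, x, y, z = combos.T
    s = np.stack([
        dm[w, x] + dm[y, z],  # (q0,q1)|(q2,q3)
        dm[w, y] + dm[x, z],  # (q0,q2)|(q1,q3)
        dm[w, z] + dm[x, y],  # (q0,q3)|(q1,q2)
    ])
    mins = s.min(axis=0)
    eq = s == mins
    weights = (eq / eq.sum(axis=0)).sum(axis=1) / combos.shape[0]
    return weights


def quartet_weights(
    gts: GeneTreeSet,
    quartet: Sequence[str],
    max_exhaustive: int = 10_000,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-chromosome topology weights for one quartet, summed over trees.

    Rows are chromosomes, columns the three canonical topologies (keyed by
    :func:`quartet_topologies` order).
    """
    if any(p not in gts.populations() for p in quartet):
        missing = [p for p in quartet if p not in gts.populations()]
        raise ConfigurationError(f"populations absent from all trees: {missing}")
    rng = np.random.default_rng(seed)
    chroms = gts.chromosomes()
    acc = {c: np.zeros(3) for c in chroms}
    any_contribution = False
    for k in range(len(gts.trees)):
        w = tree_quartet_weights(gts, k, quartet, max_exhaustive=max_exhaustive, rng=rng)
        if w is None:
            continue
        acc[gts.chrom[k]] += w
        any_contribution = True
    if not any_contribution:
        raise ArctosError(f"no tree contains all of quartet {tuple(quartet)}")
    return pd.DataFrame.from_dict(acc, orient="index", columns=[0, 1, 2]).loc[chroms]


def assign_species_topology(
    reference_tree: dendropy.Tree, quartet: Sequence[str]
) -> Topology:
    """Species topology q1 of a quartet, by pruning the reference tree.

    Equivalent to picking the candidate topology with zero Robinson-Foulds
    distance to the pruned reference.
    """
    labels = {lf.taxon.label for lf in reference_tree.leaf_node_iter()}
    missing = [p for p in quartet if p not in labels]
    if missing:
        raise ConfigurationError(f"quartet populations missing from reference tree: {missing}")
    pruned = reference_tree.extract_tree_with_taxa_labels(labels=list(quartet))
    tip_labels, dm = leaf_distance_matrix(pruned, topological=True)
    idx = {lab: i for i, lab in enumerate(tip_labels)}
    a, b, c, d = sorted(quartet)
    sums = [
        dm[idx[a], idx[b]] + dm[idx[c], idx[d]],
        dm[idx[a], idx[c]] + dm[idx[b], idx[d]],
        dm[idx[a], idx[d]] + dm[idx[b], idx[c]],
    ]
    order = np.argsort(sums)
    if sums[order[0]] == sums[order[1]]:
        raise ArctosError(f"reference tree is unresolved for quartet {tuple(quartet)}")
    return quartet_topologies(quartet)[int(order[0])]


def dstat(t2: float, t3: float) -> float:
    """D = (t2 - t3) / (t2 + t3)."""
    if t2 + t3 <= 0:
        raise ArctosError("t2 + t3 must be positive for D")
    return (t2 - t3) / (t2 + t3)


def zscore(per_chrom_d: Sequence[float]) -> float:
    """z = mean(D_chrom) / (sd(D_chrom) / sqrt(n_chroms)), sample sd.

    A zero standard deviation with a non-zero mean yields ``inf`` (flagged
    distinctly by callers); fewer than two chromosome blocks raise.
    """
    d = np.asarray([v for v in per_chrom_d if not np.isnan(v)], dtype=float)
    if d.size < 2:
        raise ArctosError("z-score needs at least 2 chromosome blocks")
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0:
        return math.inf if mean > 0 else (-math.inf if mean < 0 else 0.0)
    return float(mean / (sd / math.sqrt(d.size)))


@dataclass
class QuartetResult:
    quartet: tuple[str, str, str, str]
    t1: float
    t2: float
    t3: float
    q1: Topology
    q2: Topology
    d: float
    z: float
    rejected: bool
    n_chroms: int


def analyze_quartets(
    gts: GeneTreeSet,
    reference_tree: dendropy.Tree,
    quartets: Optional[Sequence[Sequence[str]]] = None,
    z_threshold: float = 5.0,
    max_exhaustive: int = 10_000,
    seed: int = 0,
) -> list[QuartetResult]:
    """Full quartet scan: weights, species-topology assignment, D and z.

    t2/t3 labelling is fixed on genome totals before computing per-chromosome
    D values (which may therefore be negative); a genome-total tie t2 = t3 is
    resolved by the lexicographic order of the induced ingroup pairs and
    yields D = 0.
    """
    pops = gts.populations()
    if quartets is None:
        quartets = list(itertools.combinations(sorted(pops), 4))
    results = []
    for quartet in quartets:
        quartet = tuple(sorted(quartet))
        topos = quartet_topologies(quartet)
        per_chrom = quartet_weights(gts, quartet, max_exhaustive=max_exhaustive, seed=seed)
        q1 = assign_species_topology(reference_tree, quartet)
        alt = [t for t in topos if t != q1]
        if q1 not in topos:
            raise ArctosError("species topology not among candidate topologies")
        totals = per_chrom.sum(axis=0).to_numpy()
        t1 = float(totals[topos.index(q1)])
        wa, wb = (float(totals[topos.index(t)]) for t in alt)
        # deterministic alternative ordering: by weight, then lexicographic
        alt_sorted = sorted(zip(alt, (wa, wb)),
                            key=lambda tw: (-tw[1], sorted(sorted(p) for p in tw[0])))
        (q2, t2), (q3, t3) = alt_sorted
        d = dstat(t2, t3) if t2 + t3 > 0 else float("nan")
        i2, i3 = topos.index(q2), topos.index(q3)
        w2 = per_chrom.iloc[:, i2].to_numpy()
        w3 = per_chrom.iloc[:, i3].to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            d_chrom = np.where(w2 + w3 > 0, (w2 - w3) / (w2 + w3), np.nan)
        z = zscore(d_chrom)
        results.append(QuartetResult(
            quartet=quartet, t1=t1, t2=t2, t3=t3, q1=q1, q2=q2,
            d=d, z=z, rejected=bool(z >= z_threshold),
            n_chroms=int(np.sum(~np.isnan(d_chrom))),
        ))
    return results


def results_table(results: Sequence[QuartetResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append({
            "quartet": ",".join(r.quartet),
            "t1": r.t1, "t2": r.t2, "t3": r.t3,
            "q1": _topo_str(r.q1), "q2": _topo_str(r.q2),
            "D": r.d, "z": r.z, "rejected": r.rejected, "n_chroms": r.n_chroms,
        })
    return pd.DataFrame(rows)


def _topo_str(t: Topology) -> str:
    pairs = sorted(sorted(p) for p in t)
    return ";".join(",".join(p) for p in pairs)


def ingroup_scores(
    results: Sequence[QuartetResult], populations: Sequence[str]
) -> pd.DataFrame:
    """Ingroup-score matrix over population pairs.

    For a pair (x, y): ``n_t2`` counts quartets containing both in which the
    pair groups together in q2 and the null t2 = t3 is rejected; ``n_alt``
    counts quartets containing both in which the pair does *not* group
    together in q1.  The score is ``n_t2 / n_alt``.  Requires the complete
    C(npops, 4) quartet set over ``populations``.
    """
    pops = sorted(populations)
    expected = set(itertools.combinations(pops, 4))
    present = {r.quartet for r in results}
    gaps = expected - present
    if gaps:
        raise ConfigurationError(
            f"incomplete quartet set: {len(gaps)} missing, e.g. {sorted(gaps)[:3]}")
    per_pair_expected = math.comb(len(pops) - 2, 2)
    rows = []
    for x, y in itertools.combinations(pops, 2):
        pair = frozenset({x, y})
        n_t1 = n_alt = n_t2 = n_total = 0
        for r in results:
            if x not in r.quartet or y not in r.quartet:
                continue
            n_total += 1
            if pair in r.q1:
                n_t1 += 1
            else:
                n_alt += 1
                if r.rejected and pair in r.q2:
                    n_t2 += 1
        if n_total != per_pair_expected:
            raise ConfigurationError(
                f"pair ({x},{y}) appears in {n_total} quartets, expected {per_pair_expected}")
        score = n_t2 / n_alt if n_alt > 0 else 0.0
        rows.append({"x": x, "y": y, "n_t1": n_t1, "n_alt": n_alt,
                     "n_t2": n_t2, "score": score})
    return pd.DataFrame(rows)


def simplex_coords(t1: float, t2: float, t3: float) -> tuple[float, float]:
    """Barycentric (t1, t2, t3) to 2-D simplex coordinates.

    The t1 vertex is the apex (0.5, sqrt(3)/2); t2 and t3 sit at (0, 0) and
    (1, 0).  Coordinates are invariant to scaling of the total weight.
    """
    total = t1 + t2 + t3
    if total <= 0:
        raise ValueError("topology weights must have a positive sum")
    x = (0.5 * t1 + 1.0 * t3) / total
    y = (math.sqrt(3) / 2) * t1 / total
    return x, y


def count_quartets(npops: int) -> int:
    """Number of population quartets: C(npops, 4)."""
    return math.comb(npops, 4)


def count_triplets(npops: int) -> int:
    """Number of ordered triplets (A; {B,C}): npops * C(npops-1, 2)."""
    return npops * math.comb(npops - 1, 2)


# ---------------------------------------------------------------------------
# gene trees from phased haplotypes
# ---------------------------------------------------------------------------

def gene_trees_from_haplotypes(
    haplotypes: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    sample_ids: Sequence[str],
    sample_populations: Sequence[str],
    locus_bp: int = 25_000,
    min_sites: int = 5,
) -> GeneTreeSet:
    """BioNJ gene trees from phased 0/1 haplotypes, one per genomic locus.

    Haplotype rows come in pairs per sample (rows 2k and 2k+1).  Each
    chromosome is cut into non-overlapping loci of ``locus_bp``; loci with
    fewer than ``min_sites`` segregating sites are skipped.  Tips are
    labelled ``sample|1`` and ``sample|2``.
    """
    haplotypes = np.asarray(haplotypes)
    if haplotypes.shape[0] != 2 * len(sample_ids):
        raise ConfigurationError("expected two haplotype rows per sample")
    labels = []
    tip_pop = {}
    for sid, pop in zip(sample_ids, sample_populations):
        for h in (1, 2):
            lab = f"{sid}|{h}"
            labels.append(lab)
            tip_pop[lab] = pop
    trees: list[dendropy.Tree] = []
    chroms_out: list[str] = []
    chrom = np.asarray(chrom, dtype=object)
    pos = np.asarray(pos)
    seen: dict[str, None] = {}
    for c in chrom:
        seen.setdefault(c, None)
    for c in seen:
        on = np.nonzero(chrom == c)[0]
        if on.size == 0:
            continue
        loci = (pos[on] - 1) // locus_bp
        for w in np.unique(loci):
            cols = on[loci == w]
            if cols.size < min_sites:
                continue
            block = haplotypes[:, cols].astype(np.float64)
            diff = (block[:, None, :] != block[None, :, :]).mean(axis=2)
            trees.append(bionj(diff, labels))
            chroms_out.append(str(c))
    if not trees:
        raise ArctosError("no locus had enough segregating sites for a gene tree")
    return GeneTreeSet(trees=trees, chrom=chroms_out, tip_pop=tip_pop)
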