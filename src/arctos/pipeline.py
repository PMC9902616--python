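"""Configuration-driven orchestration of the analysis stages.

A run config (YAML or dict) lists stages with parameter blocks:

.. code-block:: yaml

    seed: 7
    stages:
      - stage: simulate
        params: {family: pulse_admixture, a: 0.5, rescale_q: 50}
      - stage: f3
        params: {triplet: [p12, p1, p2]}

Each stage reads named artifacts (``vcf``, ``popmap``, ``windows`` ...)
produced by earlier stages (explicit paths in ``params`` override them),
writes its outputs into a numbered subdirectory, and records a manifest
with parameters, the derived stage seed, input hashes and the package
version, so any stage can be reproduced in isolation.  The global seed is
turned into per-stage substreams by hashing the stage name, so adding a
stage does not perturb the randomness of the others.
"""

from __future__ import annotations

import hashlib
import json
import os
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__, distances, filtering, fstats, microsat, quartets, simulate, trees
from . import windows as windows_mod
from .core import ArctosError, ConfigurationError, GenotypeMatrix, PopulationMap, SampleInfo
from .io import read_popmap, read_vcf, write_popmap, write_vcf


class DependencyError(ArctosError):
    pass


def stage_seed(global_seed: int, stage_name: str) -> int:
    """Per-stage substream seed: global seed combined with the hashed name."""
    h = zlib.crc32(stage_name.encode())
    return int(np.random.SeedSequence(entropy=global_seed, spawn_key=(h,))
               .generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunContext:
    outdir: Path
    seed: int
    artifacts: dict[str, Path] = field(default_factory=dict)

    def need(self, name: str, params: dict, stage: str) -> Path:
        if name in params:
            return Path(params[name])
        if name not in self.artifacts:
            raise DependencyError(
                f"stage {stage!r} needs artifact {name!r}; no earlier stage produced it")
        return self.artifacts[name]


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

_SCENARIOS: dict[str, Callable[..., simulate.SimScenario]] = {
    "single": simulate.scenario_single_population,
    "stepping_stone_split": simulate.scenario_stepping_stone_split,
    "star_to_chain": simulate.scenario_star_to_chain,
    "pulse_admixture": simulate.scenario_pulse_admixture,
    "bottleneck_roh": simulate.scenario_bottleneck_roh,
}


def _stage_simulate(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    params = dict(params)
    family = params.pop("family", "single")
    q = params.pop("rescale_q", 1)
    if family not in _SCENARIOS:
        raise ConfigurationError(f"unknown scenario family {family!r}")
    scn = _SCENARIOS[family](seed=seed, **params)
    if q > 1:
        scn = simulate.rescale(scn, q)
    result = simulate.run_scenario(scn)
    outputs = []
    gen, sample = max(result.samples.items())
    vcf = out / "simulated.vcf"
    write_vcf(sample.genotypes, vcf)
    popmap = PopulationMap({
        sid: SampleInfo(pop) for sid, pop in
        zip(sample.genotypes.sample_ids, sample.sample_populations)
    })
    pm_path = out / "popmap.tsv"
    write_popmap(popmap, pm_path)
    traj = out / "trajectory.tsv"
    result.trajectory.to_csv(traj, sep="\t", index=False)
    ctx.artifacts["vcf"] = vcf
    ctx.artifacts["popmap"] = pm_path
    ctx.artifacts["trajectory"] = traj
    outputs += [vcf, pm_path, traj]
    return outputs


def _stage_filter(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    gm = read_vcf(ctx.need("vcf", params, "filter"))
    gm = filtering.filter_snps(
        gm,
        max_snp_missing=params.get("max_snp_missing", 0.01),
        max_ind_missing=params.get("max_ind_missing", 0.1),
        min_mac=params.get("min_mac", 2),
        thin_bp=params.get("thin_bp", 20_000),
    )
    vcf = out / "filtered.vcf"
    write_vcf(gm, vcf)
    ctx.artifacts["vcf"] = vcf
    return [vcf]


def _stage_windows(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    gm = read_vcf(ctx.need("vcf", params, "windows"))
    wt = windows_mod.count_windows(
        gm,
        window_bp=params.get("window_bp", 20_000),
        chrom_lengths=params.get("chrom_lengths"),
        all_sites_called=params.get("all_sites_called", False),
    )
    path = out / "windows.tsv"
    wt.to_csv(path, sep="\t", index=False)
    ctx.artifacts["windows"] = path
    return [path]


def _stage_roh(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    wt = pd.read_csv(ctx.need("windows", params, "roh"), sep="\t")
    rohs = windows_mod.call_roh(
        wt,
        he_threshold=params.get("he_threshold", 0.0005),
        min_windows=params.get("min_windows", 10),
        max_gap_windows=params.get("max_gap_windows", 2),
    )
    tsv = out / "roh.tsv"
    pd.DataFrame([{
        "sample": r.sample, "chrom": r.chrom, "start": r.start, "end": r.end,
        "n_windows": r.n_windows, "mean_he": r.mean_he,
    } for r in rohs]).to_csv(tsv, sep="\t", index=False)
    bed = out / "roh.bed"
    with open(bed, "w") as fh:
        for r in rohs:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.sample}\n")
    froh_rows = []
    for sid in sorted(wt["sample"].unique()):
        cb = windows_mod.callable_bp(wt, sid)
        f = windows_mod.froh([r for r in rohs if r.sample == sid], cb) if cb else np.nan
        froh_rows.append({"sample": sid, "froh": f, "callable_bp": cb})
    froh_path = out / "froh.tsv"
    pd.DataFrame(froh_rows).to_csv(froh_path, sep="\t", index=False)
    ctx.artifacts["roh"] = tsv
    return [tsv, bed, froh_path]


def _stage_dist(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    gm = read_vcf(ctx.need("vcf", params, "dist"))
    metric = params.get("metric", "d")
    if metric == "d":
        labels, dm = distances.pairwise_d(gm)
    else:
        labels, dm = distances.snp_distance(gm, metric=metric)
    path = out / f"dist_{metric}.tsv"
    pd.DataFrame(dm, index=labels, columns=labels).to_csv(path, sep="\t")
    ctx.artifacts["dist"] = path
    return [path]


def _stage_tree(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    df = pd.read_csv(ctx.need("dist", params, "tree"), sep="\t", index_col=0)
    labels = [str(c) for c in df.index]
    dm = df.to_numpy(dtype=float).copy()
    if params.get("zero_diagonal", True):
        # uncorrected d matrices store He/2 on the diagonal; clustering wants 0
        np.fill_diagonal(dm, 0.0)
    tree = trees.bionj(dm, labels)
    newick = out / "bionj.nwk"
    tree.write(path=str(newick), schema="newick", suppress_rooting=True)
    res = trees.tree_residuals(tree, dm, labels)
    res_path = out / "residuals.tsv"
    pd.DataFrame(res, index=labels, columns=labels).to_csv(res_path, sep="\t")
    edges = trees.mst(dm, labels)
    mst_path = out / "mst.tsv"
    pd.DataFrame(edges, columns=["a", "b", "weight"]).to_csv(mst_path, sep="\t", index=False)
    ctx.artifacts["tree"] = newick
    return [newick, res_path, mst_path]


def _stage_f3(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    gm = read_vcf(ctx.need("vcf", params, "f3"))
    popmap = read_popmap(ctx.need("popmap", params, "f3"))
    triplet = tuple(params["triplet"])
    res = fstats.f3_windows(
        gm, popmap, triplet,
        window_bp=params.get("window_bp", 50_000),
        exclusion_bound=params.get("exclusion_bound", 5.0),
        normalize=params.get("normalize", True),
    )
    win_path = out / "f3_windows.tsv"
    res.windows.to_csv(win_path, sep="\t", index=False)
    summary = out / "f3_summary.tsv"
    pd.DataFrame([{
        "triplet": ";".join(triplet), "mean_f3": res.mean_f3,
        "prop_negative": res.prop_negative, "n_excluded": res.n_excluded,
        "n_windows": res.n_windows,
    }]).to_csv(summary, sep="\t", index=False)
    ctx.artifacts["f3"] = summary
    return [win_path, summary]


def _stage_f4(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    gm = read_vcf(ctx.need("vcf", params, "f4"))
    popmap = read_popmap(ctx.need("popmap", params, "f4"))
    freqs = filtering.allele_frequencies(gm, popmap)
    a, b, c, d = (freqs.of(p) for p in params["quartet"])
    value = fstats.f4(a, b, c, d)
    path = out / "f4.tsv"
    pd.DataFrame([{"quartet": ";".join(params["quartet"]), "f4": value}]).to_csv(
        path, sep="\t", index=False)
    return [path]


def _stage_fst(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    gm = read_vcf(ctx.need("vcf", params, "fst"))
    popmap = read_popmap(ctx.need("popmap", params, "fst"))
    pa, pb = params["pair"]
    value = fstats.wc_fst(gm, popmap, pa, pb)
    path = out / "fst.tsv"
    pd.DataFrame([{"pair": f"{pa};{pb}", "fst": value}]).to_csv(path, sep="\t", index=False)
    return [path]


def _stage_quartets(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    popmap = None
    if "popmap" in params or "popmap" in ctx.artifacts:
        popmap = read_popmap(ctx.need("popmap", params, "quartets"))
    gts = quartets.GeneTreeSet.read(
        ctx.need("gene_trees", params, "quartets"),
        ctx.need("gene_trees_chrom", params, "quartets"),
        popmap=popmap,
    )
    import dendropy

    ref = dendropy.Tree.get(path=str(ctx.need("reference_tree", params, "quartets")),
                            schema="newick")
    results = quartets.analyze_quartets(
        gts, ref,
        z_threshold=params.get("z_threshold", 5.0),
        max_exhaustive=params.get("max_exhaustive", 10_000),
        seed=seed,
    )
    table = quartets.results_table(results)
    res_path = out / "quartets.tsv"
    table.to_csv(res_path, sep="\t", index=False)
    scores = quartets.ingroup_scores(results, gts.populations())
    score_path = out / "ingroup_scores.tsv"
    scores.to_csv(score_path, sep="\t", index=False)
    simplex = out / "simplex.tsv"
    pd.DataFrame([
        {"quartet": ",".join(r.quartet),
         **dict(zip(("x", "y"), quartets.simplex_coords(r.t1, r.t2, r.t3))),
         "rejected": r.rejected}
        for r in results
    ]).to_csv(simplex, sep="\t", index=False)
    ctx.artifacts["quartet_results"] = res_path
    return [res_path, score_path, simplex]


def _stage_microsat(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    loci = microsat.read_loci(ctx.need("microsat_loci", params, "microsat"))
    reads_raw = microsat.read_reads_tsv(ctx.need("microsat_reads", params, "microsat"))
    grouped = {tuple(k.split("\t")): v for k, v in reads_raw.items()}
    table = microsat.genotype_table(grouped, loci, min_depth=params.get("min_depth", 3))
    path = out / "microsat_genotypes.tsv"
    table.to_csv(path, sep="\t", index=False)
    return [path]


def _stage_demo(ctx: RunContext, out: Path, params: dict, seed: int) -> list[Path]:
    paths = make_demo_dataset(seed, out)
    ctx.artifacts.update(paths)
    return list(paths.values())


_STAGES: dict[str, Callable] = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "windows": _stage_windows,
    "roh": _stage_roh,
    "dist": _stage_dist,
    "tree": _stage_tree,
    "f3": _stage_f3,
    "f4": _stage_f4,
    "fst": _stage_fst,
    "quartets": _stage_quartets,
    "microsat": _stage_microsat,
    "demo": _stage_demo,
}


def run_pipeline(config: dict | str | os.PathLike, outdir: str | os.PathLike) -> Path:
    """Execute a stage list; returns the run directory containing manifests."""
    if not isinstance(config, dict):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if "stages" not in config or not isinstance(config["stages"], list):
        raise ConfigurationError("config must contain a 'stages' list")
    seed = int(config.get("seed", 0))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ctx = RunContext(outdir=outdir, seed=seed)
    for i, block in enumerate(config["stages"]):
        name = block.get("stage")
        if name not in _STAGES:
            raise ConfigurationError(f"unknown stage name {name!r}")
        params = block.get("params") or {}
        stage_dir = outdir / f"{i:02d}_{name}"
        stage_dir.mkdir(parents=True, exist_ok=True)
        sseed = stage_seed(seed, f"{i:02d}_{name}")
        inputs = {k: str(v) for k, v in ctx.artifacts.items()}
        outputs = _STAGES[name](ctx, stage_dir, params, sseed)
        manifest = {
            "stage": name,
            "index": i,
            "params": params,
            "seed": sseed,
            "global_seed": seed,
            "version": __version__,
            "inputs": {k: _sha256(Path(v)) for k, v in inputs.items() if Path(v).is_file()},
            "outputs": {p.name: _sha256(p) for p in outputs if p.is_file()},
        }
        with open(stage_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# demo dataset
# ---------------------------------------------------------------------------

def demo_scenario(seed: int = 0) -> simulate.SimScenario:
    """Six-population demo: ladder species tree, one pulse, one bottleneck.

    Desk-scale parameters: Ne 100 per population, splits every 60 generations
    (0.3 coalescent units, so gene trees carry plenty of incomplete lineage
    sorting).  p6 is founded by a recent pulse with 45% ancestry from p5 and
    55% from p1, so the pair (p5, p6) carries the introgression signal; p4
    collapses to 15 diploids, so it accumulates ROHs.  One realisation is an
    85 kb chromosome; twelve of them make the ~1 Mb demo genome.
    """
    ne = 100
    ev = simulate.Event
    events = [
        ev(0, "split", {"parent": "p0", "children": [("p1", ne), ("q1", ne)]}),
        ev(60, "split", {"parent": "q1", "children": [("p2", ne), ("q2", ne)]}),
        ev(120, "split", {"parent": "q2", "children": [("p3", ne), ("q3", ne)]}),
        ev(180, "split", {"parent": "q3", "children": [("p4", ne), ("p5", ne)]}),
        ev(280, "pulse", {"name": "p6", "size": ne, "sources": {"p5": 0.45, "p1": 0.55}}),
        ev(280, "size_change", {"population": "p4", "size": 15}),
    ]
    return simulate.SimScenario(
        populations=[simulate.PopulationSpec("p0", ne)],
        genome_length=85_000,
        mutation_rate=1.2e-6,
        recombination_rate=5e-7,
        events=events,
        burn_in=800,
        run_generations=300,
        sample_size=10,
        seed=seed,
        metadata={"family": "demo"},
    )


def make_demo_dataset(seed: int, outdir: str | os.PathLike) -> dict[str, Path]:
    """Small bundled inputs: VCF, popmap, gene trees, reference tree, reads.

    Twelve independent 85 kb chromosomes (~1 Mb total), 6 populations of 10
    diploid samples.  Gene trees are BioNJ trees on 12.5 kb loci of the
    phased haplotypes; the reference tree is the known demographic topology.
    Deterministic for a fixed seed.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scn = demo_scenario(seed)
    results = simulate.run_chromosomes(scn, n_chromosomes=12)
    outs = [max(r.samples.items())[1] for r in results]

    gms = [o.genotypes for o in outs]
    sample_ids = gms[0].sample_ids
    chrom = np.concatenate([g.chrom for g in gms])
    pos = np.concatenate([g.pos for g in gms])
    geno = np.concatenate([g.genotypes for g in gms], axis=1)
    gm = GenotypeMatrix(sample_ids=sample_ids, chrom=chrom, pos=pos, genotypes=geno)
    vcf = outdir / "demo.vcf"
    write_vcf(gm, vcf)

    # popmap with a synthetic west-east transect for IBD analyses
    lat0, lon0 = 55.0, 10.0
    pops = sorted(set(outs[0].sample_populations))
    coords = {p: (lat0, lon0 + 12.0 * i) for i, p in enumerate(pops)}
    popmap = PopulationMap({
        sid: SampleInfo(pop, None, *coords[pop])
        for sid, pop in zip(sample_ids, outs[0].sample_populations)
    })
    pm_path = outdir / "demo_popmap.tsv"
    write_popmap(popmap, pm_path)

    haplotypes = np.concatenate([o.haplotypes for o in outs], axis=1)
    gts = quartets.gene_trees_from_haplotypes(
        haplotypes, chrom, pos, sample_ids, outs[0].sample_populations,
        locus_bp=12_500, min_sites=8,
    )
    trees_path = outdir / "demo_gene_trees.nwk"
    sidecar = outdir / "demo_gene_trees_chrom.tsv"
    gts.write(str(trees_path), str(sidecar))

    ref_path = outdir / "demo_reference_tree.nwk"
    with open(ref_path, "w") as fh:
        fh.write("((p1,p6),(p2,(p3,(p4,p5))));\n")

    # microsatellite fixture: 3 loci, reads for 4 samples with known genotypes
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(77,)))
    loci = [
        microsat.RepeatLocus(f"ms{i + 1}", "chr1", 1000 + 500 * i,
                             1000 + 500 * i + 4 * units, motif, units)
        for i, (motif, units) in enumerate([("ACAG", 8), ("ATCT", 7), ("AGAT", 9)])
    ]
    loci_path = outdir / "demo_microsat_loci.tsv"
    microsat.write_loci(loci, loci_path)
    reads = {}
    truth_rows = []
    for s in range(4):
        for loc in loci:
            a1 = int(loc.ref_units + rng.integers(-1, 2))
            a2 = int(loc.ref_units + rng.integers(-1, 2))
            gt = tuple(sorted((a1, a2)))
            rs = microsat.simulate_reads(
                loc, gt, depth=25, read_length=100, error_rate=0.002,
                stutter_rate=0.01, seed=int(rng.integers(2**31)))
            reads[(f"s{s + 1}", loc.name)] = rs
            truth_rows.append({"sample": f"s{s + 1}", "locus": loc.name,
                               "allele1": gt[0], "allele2": gt[1]})
    reads_path = outdir / "demo_microsat_reads.tsv"
    microsat.write_reads_tsv(reads, reads_path)
    truth_path = outdir / "demo_microsat_truth.tsv"
    pd.DataFrame(truth_rows).to_csv(truth_path, sep="\t", index=False)

    return {
        "vcf": vcf,
        "popmap": pm_path,
        "gene_trees": trees_path,
        "gene_trees_chrom": sidecar,
        "reference_tree": ref_path,
        "microsat_loci": loci_path,
        "microsat_reads": reads_path,
        "microsat_truth": truth_path,
    }
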