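"""Forward-in-time neutral Wright-Fisher simulator with recombination.

The engine tracks diploid individuals as pairs of haplotypes, each a sorted
array of derived-mutation positions on a single linear chromosome.
Mutations are laid down under an infinite-alleles convention: a mutation
event landing on a position that already carries a derived allele receives a
tiny fractional offset (the integer part remains the genomic site), so
distinct origins at one site stay distinguishable.  A site is multi-allelic
— and excluded from every output, mirroring the usual VCF filtering — only
when two origins actually coexist at observation time.  Every
generation each population produces its next cohort by random mating:
a child draws a source population (itself, or — with the backward migration
probability ``m`` — a neighbour), draws two parents from that source, and
receives one recombinant gamete from each parent.  Crossover counts are
Poisson with mean ``r * L`` (breakpoints uniform along the chromosome), new
mutations Poisson with mean ``mu * L`` at uniform positions.  Positions hit
by more than one independent mutation event are flagged and excluded from
all outputs (multi-allelic filtering), so the remaining sites behave as
infinite-sites biallelic SNPs.

Demographic programs are expressed as a :class:`SimScenario`: initial
populations, a backward migration matrix, and a time-stamped event list
(splits, size changes, pulse-admixture foundings, migration changes).
The scenario builders at the bottom encode the four standard experiment
families: a two-into-four stepping-stone split, a star-to-chain transition,
a two-source pulse admixture, and a bottleneck for ROH equilibration.
Full-scale defaults (Ne 5000, 50 Mb, mu 1.2e-8, r 1e-8, 25000 burn-in
generations) are expensive; :func:`rescale` compresses a scenario by a
factor ``Q`` while preserving theta = 4*Ne*mu, rho = 4*Ne*r and Ne*m.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ConfigurationError,
    ExtinctionError,
    GenotypeMatrix,
)


@dataclass(frozen=True)
class PopulationSpec:
    name: str
    size: int  # diploid census size, used as Ne


@dataclass(frozen=True)
class Event:
    """Demographic event applied at the start of ``generation``.

    Kinds and parameters:

    - ``split``: ``parent``, ``children`` = list of (name, size); the parent
      is removed after founding its children.
    - ``size_change``: ``population``, ``size``.
    - ``pulse``: ``name``, ``size``, ``sources`` = {pop: proportion}; founds
      a new admixed population in a single generation.
    - ``migration_change``: either ``matrix`` = {dest: {src: rate}}
      (replaces the whole matrix) or ``dest``/``src``/``rate``.
    """

    generation: int
    kind: str
    params: dict


@dataclass
class SimScenario:
    populations: list[PopulationSpec]
    genome_length: int
    mutation_rate: float
    recombination_rate: float
    migration: dict = field(default_factory=dict)  # dest -> {src: backward rate}
    events: list[Event] = field(default_factory=list)
    burn_in: int = 0
    run_generations: int = 0
    sample_size: int = 10
    sample_at: Optional[Sequence[int]] = None  # generations (0 = end of burn-in)
    record: list[tuple] = field(default_factory=list)  # ("he", p) / ("fst", a, b) / ...
    record_every: int = 5
    seed: int = 0
    metadata: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ConfigurationError("rates must be non-negative")
        if self.genome_length <= 0:
            raise ConfigurationError("genome length must be positive")
        names = {p.name for p in self.populations}
        if len(names) != len(self.populations):
            raise ConfigurationError("duplicate population names")
        for dest, row in self.migration.items():
            if any(r < 0 for r in row.values()):
                raise ConfigurationError("migration rates must be non-negative")
            if sum(r for s, r in row.items() if s != dest) > 1.0 + 1e-12:
                raise ConfigurationError(f"migration into {dest!r} exceeds 1")
        gens = [e.generation for e in self.events]
        if gens != sorted(gens):
            raise ConfigurationError("events must be sorted by generation")
        for ev in self.events:
            if ev.kind == "pulse":
                props = list(ev.params["sources"].values())
                if any(not 0 < a < 1 for a in props) or abs(sum(props) - 1) > 1e-9:
                    raise ConfigurationError("pulse proportions must lie in (0,1) and sum to 1")


@dataclass
class SampleOutput:
    """One sampling time point: genotypes plus the underlying phased haplotypes."""

    generation: int
    genotypes: GenotypeMatrix
    haplotypes: np.ndarray  # (2 * n_samples, n_sites) 0/1, rows 2k, 2k+1 per sample
    sample_populations: list[str]


@dataclass
class SimResult:
    samples: dict[int, SampleOutput]
    trajectory: pd.DataFrame  # generation, stat, value
    scenario: SimScenario


def _pop_rng(seed: int, name: str, stream: int = 0) -> np.random.Generator:
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key, stream)))


class _Pop:
    __slots__ = ("name", "size", "haps", "rng", "founder_sources")

    def __init__(self, name: str, size: int, seed: int):
        self.name = name
        self.size = size
        self.haps: list[np.ndarray] = [np.empty(0, dtype=np.float64) for _ in range(2 * size)]
        self.rng = _pop_rng(seed, name)
        self.founder_sources: Optional[dict[str, float]] = None


class WrightFisher:
    """Stateful engine; normally driven via :func:`run_scenario`.

    The engine is exposed so that tests and pipelines can fork a burned-in
    state into several continuations (e.g. one equilibrium ancestor, many
    bottleneck sizes) without repeating the burn-in.
    """

    PRUNE_INTERVAL = 64

    def __init__(self, scenario: SimScenario):
        scenario.validate()
        self.scn = scenario
        self.L = int(scenario.genome_length)
        self.mu_L = scenario.mutation_rate * self.L
        self.r_L = scenario.recombination_rate * self.L
        self.pops: dict[str, _Pop] = {
            p.name: _Pop(p.name, p.size, scenario.seed) for p in scenario.populations
        }
        self.migration = {d: dict(row) for d, row in scenario.migration.items()}
        self.seen = np.zeros(self.L, dtype=bool)  # sites that ever carried an allele
        self.fixed_mask = np.zeros(self.L, dtype=bool)
        self._collision_count: dict[int, int] = {}
        self.fixed: list[np.ndarray] = []
        self.generation = 0  # main-phase generation counter (after burn-in)
        self._obs_rng = np.random.default_rng(
            np.random.SeedSequence(entropy=scenario.seed, spawn_key=(0x0B5,))
        )
        self._steps_done = 0
        self._pending_removal: list[str] = []

    # ------------------------------------------------------------------
    def _apply_events(self, generation: int) -> None:
        for ev in self.scn.events:
            if ev.generation != generation:
                continue
            if ev.kind == "split":
                parent = ev.params["parent"]
                if parent not in self.pops:
                    raise ConfigurationError(f"split references unknown population {parent!r}")
                for name, size in ev.params["children"]:
                    pop = _Pop(name, int(size), self.scn.seed)
                    pop.founder_sources = {parent: 1.0}
                    self.pops[name] = pop
                if not ev.params.get("keep_parent", False):
                    self._pending_removal.append(parent)
            elif ev.kind == "size_change":
                name = ev.params["population"]
                if name not in self.pops:
                    raise ConfigurationError(f"size_change references unknown population {name!r}")
                self.pops[name].size = int(ev.params["size"])
            elif ev.kind == "pulse":
                sources = ev.params["sources"]
                for s in sources:
                    if s not in self.pops:
                        raise ConfigurationError(f"pulse references unknown population {s!r}")
                pop = _Pop(ev.params["name"], int(ev.params["size"]), self.scn.seed)
                pop.founder_sources = dict(sources)
                self.pops[ev.params["name"]] = pop
            elif ev.kind == "migration_change":
                if "matrix" in ev.params:
                    self.migration = {d: dict(r) for d, r in ev.params["matrix"].items()}
                else:
                    self.migration.setdefault(ev.params["dest"], {})[ev.params["src"]] = (
                        ev.params["rate"]
                    )
                for dest, row in self.migration.items():
                    for s in row:
                        if s not in self.pops and s != dest:
                            raise ConfigurationError(
                                f"migration references unknown population {s!r}")
            else:
                raise ConfigurationError(f"unknown event kind {ev.kind!r}")

    # ------------------------------------------------------------------
    def _recombine(self, h1, h2, bps, first):
        hs = (h1, h2) if first == 0 else (h2, h1)
        parts = []
        prev = 0
        k = len(bps)
        for idx in range(k + 1):
            src = hs[idx & 1]
            hi = np.searchsorted(src, bps[idx]) if idx < k else src.size
            lo = np.searchsorted(src, prev) if idx > 0 else 0
            parts.append(src[lo:hi])
            if idx < k:
                prev = bps[idx]
        return np.concatenate(parts)

    def step(self) -> None:
        """One synchronous Wright-Fisher generation across all populations."""
        order = sorted(self.pops)
        old = {name: (self.pops[name].haps, len(self.pops[name].haps) // 2) for name in order}
        new_haps: dict[str, list[np.ndarray]] = {}
        L = self.L
        for name in order:
            pop = self.pops[name]
            n = pop.size
            if n <= 0:
                raise ExtinctionError(f"population {name!r} reached size 0")
            rng = pop.rng
            # source population per child
            if pop.founder_sources is not None:
                srcs = sorted(pop.founder_sources)
                probs = np.array([pop.founder_sources[s] for s in srcs])
                src_idx = rng.choice(len(srcs), size=n, p=probs) if len(srcs) > 1 else np.zeros(n, int)
                src_names = srcs
                pop.founder_sources = None
            else:
                row = self.migration.get(name, {})
                row = {s: r for s, r in sorted(row.items()) if r > 0 and s != name}
                if row:
                    srcs = list(row)
                    edges = np.cumsum([row[s] for s in srcs])
                    u = rng.random(n)
                    src_idx = np.searchsorted(edges, u)  # == len(srcs) -> stay home
                    src_names = srcs + [name]
                else:
                    src_idx = np.zeros(n, dtype=int)
                    src_names = [name]
            # parent pairs, drawn per source group in deterministic order
            parents = np.empty((n, 2), dtype=np.int64)
            for k, s in enumerate(src_names):
                members = np.nonzero(src_idx == k)[0]
                if members.size == 0:
                    continue
                if s not in old:
                    raise ConfigurationError(f"migration source {s!r} does not exist")
                n_src = old[s][1]
                if n_src == 0:
                    raise ExtinctionError(f"source population {s!r} is empty")
                parents[members] = rng.integers(0, n_src, size=(members.size, 2))
            n_g = 2 * n
            ncx = rng.poisson(self.r_L, n_g) if self.r_L > 0 else np.zeros(n_g, dtype=np.int64)
            nmut = rng.poisson(self.mu_L, n_g) if self.mu_L > 0 else np.zeros(n_g, dtype=np.int64)
            coins = rng.integers(0, 2, n_g)
            bp_all = rng.integers(0, L, int(ncx.sum())) if ncx.any() else np.empty(0, np.int64)
            mut_all = rng.integers(0, L, int(nmut.sum())) if nmut.any() else np.empty(0, np.int64)
            mut_eff = mut_all.astype(np.float64)
            if mut_all.size:
                # a repeat hit on a previously mutated site founds a distinct
                # allele: give it a fractional offset so origins stay separate
                need = self.seen[mut_all].copy()
                order = np.argsort(mut_all, kind="stable")
                sv = mut_all[order]
                need[order[1:][sv[1:] == sv[:-1]]] = True
                for i in np.nonzero(need)[0]:
                    p = int(mut_all[i])
                    k = min(self._collision_count.get(p, 0) + 1, 63)
                    self._collision_count[p] = k
                    mut_eff[i] = p + k / 64.0
                self.seen[mut_all] = True
            haps: list[np.ndarray] = []
            bp_off = 0
            mut_off = 0
            for i in range(n):
                src_haps = old[src_names[src_idx[i]]][0]
                for t in (0, 1):
                    gi = 2 * i + t
                    p = parents[i, t]
                    h1 = src_haps[2 * p]
                    h2 = src_haps[2 * p + 1]
                    k = ncx[gi]
                    if k == 0:
                        g = h1 if coins[gi] == 0 else h2
                    else:
                        bps = np.sort(bp_all[bp_off:bp_off + k])
                        bp_off += k
                        g = self._recombine(h1, h2, bps, coins[gi])
                    m = nmut[gi]
                    if m:
                        g = np.union1d(g, mut_eff[mut_off:mut_off + m])
                        mut_off += m
                    haps.append(g)
            new_haps[name] = haps
        for name, haps in new_haps.items():
            self.pops[name].haps = haps
        for name in self._pending_removal:
            del self.pops[name]
        self._pending_removal = []
        self._steps_done += 1
        if self._steps_done % self.PRUNE_INTERVAL == 0:
            self._prune_fixed()

    def _prune_fixed(self) -> None:
        all_haps = [h for pop in self.pops.values() for h in pop.haps]
        if not all_haps:
            return
        inter = min(all_haps, key=len)
        for h in all_haps:
            if inter.size == 0:
                return
            if h is inter:
                continue
            inter = inter[np.isin(inter, h, assume_unique=True)]
        if inter.size == 0:
            return
        for pop in self.pops.values():
            pop.haps = [h[~np.isin(h, inter, assume_unique=True)] for h in pop.haps]
        self.fixed.append(inter)
        self.fixed_mask[np.floor(inter).astype(np.int64)] = True

    def _biallelic_filter(self, alleles: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Keep alleles at clean biallelic sites; return (mask, site positions).

        ``alleles`` is a sorted array of live allele values.  A site is
        dropped when two origins coexist (duplicated integer part) or when a
        distinct allele already went to fixation there.
        """
        floors = np.floor(alleles).astype(np.int64)
        dup = np.zeros(floors.size, dtype=bool)
        same = floors[1:] == floors[:-1]
        dup[1:][same] = True
        dup[:-1][same] = True
        ok = ~dup & ~self.fixed_mask[floors]
        return ok, floors

    # ------------------------------------------------------------------
    def derived_frequencies(self, pop_name: str) -> tuple[np.ndarray, np.ndarray, int]:
        """(site positions, derived counts, 2N) over clean biallelic sites."""
        pop = self.pops[pop_name]
        arrs = [h for h in pop.haps if h.size]
        two_n = len(pop.haps)
        if not arrs:
            return np.empty(0, np.int64), np.empty(0, np.int64), two_n
        u, c = np.unique(np.concatenate(arrs), return_counts=True)
        ok, floors = self._biallelic_filter(u)
        return floors[ok], c[ok], two_n

    def heterozygosity(self, pop_name: str) -> float:
        """Population expected per-site heterozygosity (pi per bp)."""
        u, c, two_n = self.derived_frequencies(pop_name)
        if two_n < 2:
            return 0.0
        p = c / two_n
        return float(np.sum(2 * p * (1 - p)) * two_n / (two_n - 1) / self.L)

    def _allele_counts(self, pop_name: str) -> tuple[np.ndarray, np.ndarray, int]:
        pop = self.pops[pop_name]
        arrs = [h for h in pop.haps if h.size]
        two_n = len(pop.haps)
        if not arrs:
            return np.empty(0, np.float64), np.empty(0, np.int64), two_n
        u, c = np.unique(np.concatenate(arrs), return_counts=True)
        return u, c, two_n

    def _aligned_freqs(self, pop_names: Iterable[str]) -> dict[str, np.ndarray]:
        # biallelic filtering must look across *all* involved populations:
        # two origins at one site may live in different demes
        data = {p: self._allele_counts(p) for p in pop_names}
        union = np.unique(np.concatenate([d[0] for d in data.values()]
                                         + [np.empty(0, np.float64)]))
        ok, _ = self._biallelic_filter(union)
        union = union[ok]
        out = {}
        for p, (u, c, two_n) in data.items():
            f = np.zeros(union.size)
            if u.size:
                keep = np.isin(u, union, assume_unique=True)
                f[np.searchsorted(union, u[keep])] = c[keep] / two_n
            out[p] = f
        return out

    def sample_genotypes(self, pops: Optional[Sequence[str]] = None,
                         sample_size: Optional[int] = None,
                         chrom: str = "1") -> SampleOutput:
        """Draw individuals without replacement and emit genotypes + haplotypes."""
        pops = sorted(self.pops) if pops is None else list(pops)
        k = self.scn.sample_size if sample_size is None else sample_size
        chosen: list[tuple[str, np.ndarray]] = []
        for p in pops:
            n = self.pops[p].size
            take = min(k, n)
            idx = np.sort(self._obs_rng.choice(n, size=take, replace=False))
            chosen.append((p, idx))
        hap_arrays: list[np.ndarray] = []
        sample_ids: list[str] = []
        sample_pops: list[str] = []
        for p, idx in chosen:
            haps = self.pops[p].haps
            for i in idx:
                hap_arrays.extend((haps[2 * i], haps[2 * i + 1]))
                sample_ids.append(f"{p}_{i}")
                sample_pops.append(p)
        nonempty = [h for h in hap_arrays if h.size]
        if nonempty:
            union = np.unique(np.concatenate(nonempty))
            ok, floors = self._biallelic_filter(union)
            union, positions = union[ok], floors[ok]
        else:
            union = np.empty(0, np.float64)
            positions = np.empty(0, np.int64)
        hap_mat = np.zeros((len(hap_arrays), union.size), dtype=np.int8)
        for r, h in enumerate(hap_arrays):
            if h.size:
                hap_mat[r, np.isin(union, h, assume_unique=True)] = 1
        geno = hap_mat[0::2] + hap_mat[1::2]
        gm = GenotypeMatrix(
            sample_ids=sample_ids,
            chrom=np.array([chrom] * union.size, dtype=object),
            pos=positions + 1,  # 1-based VCF convention
            genotypes=geno,
        )
        return SampleOutput(
            generation=self.generation,
            genotypes=gm,
            haplotypes=hap_mat,
            sample_populations=sample_pops,
        )

    # ------------------------------------------------------------------
    def _record_stats(self, rows: list) -> None:
        from . import fstats

        gen = self.generation
        for spec in self.scn.record:
            kind = spec[0]
            if any(p not in self.pops for p in spec[1:]):
                continue  # population not founded yet (or already removed)
            if kind == "he":
                rows.append((gen, f"he:{spec[1]}", self.heterozygosity(spec[1])))
            elif kind in {"f3", "f3n"}:
                f = self._aligned_freqs(spec[1:4])
                a, b, c = (f[p] for p in spec[1:4])
                try:
                    v = fstats.f3(a, b, c, normalize=(kind == "f3n"))
                except Exception:
                    v = np.nan
                rows.append((gen, f"{kind}:{','.join(spec[1:4])}", v))
            elif kind == "f4":
                f = self._aligned_freqs(spec[1:5])
                a, b, c, d = (f[p] for p in spec[1:5])
                rows.append((gen, f"f4:{','.join(spec[1:5])}", fstats.f4(a, b, c, d)))
            elif kind == "fst":
                out = self.sample_genotypes(pops=list(spec[1:3]))
                rows_a = [i for i, p in enumerate(out.sample_populations) if p == spec[1]]
                rows_b = [i for i, p in enumerate(out.sample_populations) if p == spec[2]]
                try:
                    v = fstats.wc_fst_from_genotypes(
                        out.genotypes.genotypes[rows_a], out.genotypes.genotypes[rows_b])
                except Exception:
                    v = np.nan
                rows.append((gen, f"fst:{spec[1]},{spec[2]}", v))
            else:
                raise ConfigurationError(f"unknown trajectory statistic {kind!r}")

    def run(self) -> SimResult:
        scn = self.scn
        for _ in range(scn.burn_in):
            self.step()
        sample_at = set(scn.sample_at if scn.sample_at is not None else [scn.run_generations])
        samples: dict[int, SampleOutput] = {}
        rows: list = []
        if 0 in sample_at:
            samples[0] = self.sample_genotypes()
        if scn.record:
            self._record_stats(rows)
        for g in range(scn.run_generations):
            self._apply_events(g)
            self.step()
            self.generation = g + 1
            if scn.record and ((self.generation % scn.record_every == 0)
                               or self.generation == scn.run_generations):
                self._record_stats(rows)
            if self.generation in sample_at:
                samples[self.generation] = self.sample_genotypes()
        traj = pd.DataFrame(rows, columns=["generation", "stat", "value"])
        return SimResult(samples=samples, trajectory=traj, scenario=scn)

    # -- test/inspection helpers ---------------------------------------
    def full_haplotype_sets(self, pop_name: str) -> list[set[int]]:
        """Haplotype derived-allele sets including pruned fixed positions."""
        fixed = set()
        for arr in self.fixed:
            fixed.update(arr.tolist())
        return [fixed | set(h.tolist()) for h in self.pops[pop_name].haps]


def run_scenario(scn: SimScenario) -> SimResult:
    """Run a scenario start to finish; fixed seed gives bit-identical output."""
    return WrightFisher(scn).run()


# ---------------------------------------------------------------------------
# scenario builders (full-scale defaults; rescale() for desk-scale work)
# ---------------------------------------------------------------------------

_FULL = dict(genome_length=50_000_000, mutation_rate=1.2e-8, recombination_rate=1e-8)


def scenario_single_population(
    ne: int = 5000,
    burn_in: int = 25_000,
    run_generations: int = 0,
    genome_length: int = _FULL["genome_length"],
    mutation_rate: float = _FULL["mutation_rate"],
    recombination_rate: float = _FULL["recombination_rate"],
    sample_size: int = 10,
    seed: int = 0,
    record_every: int = 5,
) -> SimScenario:
    """Single population evolving to mutation-drift equilibrium (He = 4*Ne*mu)."""
    return SimScenario(
        populations=[PopulationSpec("p0", ne)],
        genome_length=genome_length,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        burn_in=burn_in,
        run_generations=run_generations,
        sample_size=sample_size,
        record=[("he", "p0")],
        record_every=record_every,
        seed=seed,
        metadata={"family": "single"},
    )


def scenario_stepping_stone_split(
    m: float,
    ne: int = 5000,
    t_max: int = 500,
    isolation_generations: int = 2500,
    burn_in: int = 25_000,
    genome_length: int = _FULL["genome_length"],
    mutation_rate: float = _FULL["mutation_rate"],
    recombination_rate: float = _FULL["recombination_rate"],
    sample_size: int = 10,
    seed: int = 0,
    record_every: int = 2,
) -> SimScenario:
    """Two isolated populations each split into two, forming a chain.

    An ancestral population splits into p1 and p2, which evolve in isolation;
    at the restructuring generation each splits in two, yielding the chain
    p11 - p21 - p22 - p12 (peripheral p11 and p12) with per-link backward
    migration rate ``m``.  The f4 of the new grouping ((p11,p21),(p12,p22))
    starts positive (it reflects the old p1/p2 split) and converges to zero
    within about 1/m generations; pairwise Fst re-equilibrates on the same
    timescale.
    """
    iso = isolation_generations
    chain = ["p11", "p21", "p22", "p12"]
    mig = {}
    for i, dest in enumerate(chain):
        row = {}
        if i > 0:
            row[chain[i - 1]] = m
        if i < len(chain) - 1:
            row[chain[i + 1]] = m
        mig[dest] = row
    events = [
        Event(0, "split", {"parent": "p0", "children": [("p1", ne), ("p2", ne)]}),
        Event(iso, "split", {"parent": "p1", "children": [("p11", ne), ("p12", ne)]}),
        Event(iso, "split", {"parent": "p2", "children": [("p21", ne), ("p22", ne)]}),
        Event(iso, "migration_change", {"matrix": mig}),
    ]
    return SimScenario(
        populations=[PopulationSpec("p0", ne)],
        genome_length=genome_length,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        events=events,
        burn_in=burn_in,
        run_generations=iso + t_max,
        sample_size=sample_size,
        record=[
            ("f4", "p11", "p21", "p12", "p22"),
            ("fst", "p11", "p21"),
            ("fst", "p11", "p12"),
        ],
        record_every=record_every,
        seed=seed,
        metadata={"family": "stepping_stone", "restructure_generation": iso, "m": m},
    )


def scenario_star_to_chain(
    m: float,
    ne: int = 5000,
    t_max: int = 500,
    star_generations: int = 2500,
    burn_in: int = 25_000,
    genome_length: int = _FULL["genome_length"],
    mutation_rate: float = _FULL["mutation_rate"],
    recombination_rate: float = _FULL["recombination_rate"],
    sample_size: int = 10,
    seed: int = 0,
    record_every: int = 5,
) -> SimScenario:
    """Star population structure of five populations becomes a chain.

    Five populations split simultaneously from the ancestor and drift in
    isolation (equal pairwise divergence: the star).  At the transition,
    chain neighbours (p1-p2-p3-p4-p5) start exchanging migrants at per-link
    backward rate ``m``: adjacent divergences collapse within about 1/m
    generations while distant ones persist, so the middle populations start
    to look admixed — f3(pX; pY, pZ) turns negative exactly when Y < X < Z,
    an isolation-by-distance signal with no admixture event behind it.
    """
    pops = [f"p{i}" for i in range(1, 6)]
    chain = {}
    for i, dest in enumerate(pops):
        row = {}
        if i > 0:
            row[pops[i - 1]] = m
        if i < len(pops) - 1:
            row[pops[i + 1]] = m
        chain[dest] = row
    events = [
        Event(0, "split", {"parent": "p0", "children": [(p, ne) for p in pops]}),
        Event(star_generations, "migration_change", {"matrix": chain}),
    ]
    record = []
    for x in pops:
        for y, z in [(a, b) for a in pops for b in pops if a < b and x not in (a, b)]:
            record.append(("f3n", x, y, z))
    return SimScenario(
        populations=[PopulationSpec("p0", ne)],
        genome_length=genome_length,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        events=events,
        burn_in=burn_in,
        run_generations=star_generations + t_max,
        sample_size=sample_size,
        record=record,
        record_every=record_every,
        seed=seed,
        metadata={"family": "star_to_chain", "chain_generation": star_generations, "m": m},
    )


def scenario_pulse_admixture(
    a: float,
    ne: int = 5000,
    t_max: int = 500,
    divergence_generations: int = 2500,
    burn_in: int = 25_000,
    genome_length: int = _FULL["genome_length"],
    mutation_rate: float = _FULL["mutation_rate"],
    recombination_rate: float = _FULL["recombination_rate"],
    sample_size: int = 10,
    seed: int = 0,
    record_every: int = 2,
) -> SimScenario:
    """Pulse admixture: p1 and p2 found p12 with proportions a : (1 - a).

    Immediately after the pulse f3(p12; p1, p2) is negative; with all gene
    flow stopped, drift raises the normalised score by 1/(4*Ne) per
    generation, crossing zero after about -b*4*Ne generations where b is the
    initial score.
    """
    div = divergence_generations
    events = [
        Event(0, "split", {"parent": "p0", "children": [("p1", ne), ("p2", ne)]}),
        Event(div, "pulse", {"name": "p12", "size": ne, "sources": {"p1": a, "p2": 1 - a}}),
    ]
    return SimScenario(
        populations=[PopulationSpec("p0", ne)],
        genome_length=genome_length,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        events=events,
        burn_in=burn_in,
        run_generations=div + t_max,
        sample_size=sample_size,
        record=[("f3n", "p12", "p1", "p2"), ("f3", "p12", "p1", "p2")],
        record_every=record_every,
        seed=seed,
        metadata={"family": "pulse", "admixture_generation": div, "a": a},
    )


def scenario_bottleneck_roh(
    ne_new: int,
    t: int,
    ne_ancestral: int = 5000,
    burn_in: int = 25_000,
    genome_length: int = _FULL["genome_length"],
    mutation_rate: float = _FULL["mutation_rate"],
    recombination_rate: float = _FULL["recombination_rate"],
    sample_size: int = 10,
    sample_at: Optional[Sequence[int]] = None,
    seed: int = 0,
) -> SimScenario:
    """Population-size reduction for ROH equilibration studies."""
    return SimScenario(
        populations=[PopulationSpec("p0", ne_ancestral)],
        genome_length=genome_length,
        mutation_rate=mutation_rate,
        recombination_rate=recombination_rate,
        events=[Event(0, "size_change", {"population": "p0", "size": ne_new})],
        burn_in=burn_in,
        run_generations=t,
        sample_size=sample_size,
        sample_at=sample_at,
        record=[("he", "p0")],
        record_every=max(1, t // 100),
        seed=seed,
        metadata={"family": "bottleneck", "ne_new": ne_new},
    )


class RescaleError(ValueError):
    pass


def rescale(scn: SimScenario, q: float) -> SimScenario:
    """Desk-scale a scenario by factor ``q``: Ne/q, generations/q, mu*q, r*q, m*q.

    Preserves theta = 4*Ne*mu, rho = 4*Ne*r and Ne*m exactly, so equilibrium
    diversity and the migration/drift balance are unchanged while wall-clock
    cost drops roughly as q^2.  An approximation: drift becomes coarser, so
    q must not push any census size below 20 diploids.
    """
    if q < 1:
        raise RescaleError("rescale factor Q must be >= 1")
    if q == 1:
        return scn

    def size(n: int) -> int:
        out = int(round(n / q))
        if out < 20:
            raise RescaleError(f"rescale Q={q} pushes a population below 20 diploids")
        return out

    def gens(g: int) -> int:
        return max(1, int(round(g / q))) if g > 0 else 0

    events = []
    for ev in scn.events:
        params = dict(ev.params)
        if ev.kind == "split":
            params["children"] = [(n, size(s)) for n, s in params["children"]]
        elif ev.kind in {"size_change", "pulse"}:
            params["size"] = size(params["size"])
        elif ev.kind == "migration_change":
            if "matrix" in params:
                params["matrix"] = {
                    d: {s: r * q for s, r in row.items()} for d, row in params["matrix"].items()
                }
            else:
                params["rate"] = params["rate"] * q
        events.append(Event(gens(ev.generation), ev.kind, params))
    out = replace(
        scn,
        populations=[PopulationSpec(p.name, size(p.size)) for p in scn.populations],
        mutation_rate=scn.mutation_rate * q,
        recombination_rate=scn.recombination_rate * q,
        migration={d: {s: r * q for s, r in row.items()} for d, row in scn.migration.items()},
        events=events,
        burn_in=gens(scn.burn_in),
        run_generations=gens(scn.run_generations),
        sample_at=None if scn.sample_at is None else [gens(g) for g in scn.sample_at],
        metadata={**scn.metadata, "rescale_q": q,
                  **{k: gens(v) for k, v in scn.metadata.items()
                     if k.endswith("_generation")}},
    )
    out.validate()
    return out


def run_chromosomes(scn: SimScenario, n_chromosomes: int) -> list[SimResult]:
    """Run independent replicates labelled as chromosomes.

    Chromosomes assort independently, so simulating them as independent
    realisations of the same demographic program (with per-chromosome
    derived seeds) reproduces between-chromosome variation without linkage.
    """
    seeds = np.random.SeedSequence(scn.seed).generate_state(n_chromosomes) % (2**31)
    results = []
    for i in range(n_chromosomes):
        sub = replace(scn, seed=int(seeds[i]))
        res = run_scenario(sub)
        for out in res.samples.values():
            label = f"chr{i + 1}"
            out.genotypes.chrom = np.array([label] * out.genotypes.n_sites, dtype=object)
        results.append(res)
    return results


def trajectory_values(result: SimResult, stat: str) -> tuple[np.ndarray, np.ndarray]:
    """(generations, values) for one trajectory statistic label."""
    sel = result.trajectory[result.trajectory["stat"] == stat]
    return sel["generation"].to_numpy(), sel["value"].to_numpy()
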