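"""Tetranucleotide microsatellite genotyping from aligned short reads.

Repeat lengths are read directly off individual reads: a read contributes a
repeat count only if it fully spans the repeat tract plus at least one
flanking anchor base on each side (reads truncated inside the repeat are
discarded, since the true allele length cannot be known).  Per-locus allele
depths are then scored with simple depth rules: alleles below the minimum
read depth (3) are dropped; zero remaining alleles is a missing genotype,
one a homozygote, two a heterozygote; with more than two, the two best
supported are kept unless the second and third tie, in which case the locus
is scored homozygous for the best supported allele.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core import ArctosError, ConfigurationError

OK = "ok"
TRUNCATED = "truncated"
DISCORDANT = "discordant"


@dataclass(frozen=True)
class RepeatLocus:
    """A tetranucleotide repeat tract on the reference.

    ``start``/``end`` are 0-based half-open reference coordinates of the
    repeat tract; ``ref_units`` its repeat count in the reference (7-9 units
    is the reliably typeable range for short reads).  ``left_flank`` /
    ``right_flank`` hold reference sequence immediately around the tract and
    provide the anchor bases.
    """

    name: str
    chrom: str
    start: int
    end: int
    motif: str
    ref_units: int
    left_flank: str = ""
    right_flank: str = ""

    def __post_init__(self) -> None:
        if len(self.motif) != 4:
            raise ConfigurationError(f"motif must be 4 bp, got {self.motif!r}")
        if self.end - self.start != 4 * self.ref_units:
            raise ConfigurationError(
                f"locus span {self.end - self.start} != 4 * {self.ref_units} units")


@dataclass(frozen=True)
class ReadCall:
    status: str  # OK / TRUNCATED / DISCORDANT
    units: Optional[int] = None


def extract_repeat_length(seq: str, read_start: int, locus: RepeatLocus) -> ReadCall:
    """Repeat count carried by one read, or a rejection.

    ``read_start`` is the 0-based reference position of the read's first
    base, taken from the alignment.  The read must begin at least one base
    before the repeat (left anchor) and extend at least one base past the
    end of the repeat as observed *in the read* (right anchor); otherwise
    the repeat is truncated and the read rejected.  A read that covers the
    expected repeat start but does not show the motif there is flagged
    discordant (counted separately from truncation).
    """
    motif = locus.motif
    offset = locus.start - read_start
    if offset < 1 or offset >= len(seq):
        return ReadCall(TRUNCATED)
    if locus.left_flank and seq[offset - 1] != locus.left_flank[-1]:
        return ReadCall(DISCORDANT)
    first = seq[offset:offset + 4]
    if len(first) < 4:
        return ReadCall(TRUNCATED) if motif.startswith(first) else ReadCall(DISCORDANT)
    if first != motif:
        return ReadCall(DISCORDANT)
    units = 0
    i = offset
    while seq[i:i + 4] == motif:
        units += 1
        i += 4
    rest = seq[i:]
    if not rest:
        return ReadCall(TRUNCATED)  # repeat runs into the read end
    if len(rest) < 4 and rest == motif[:len(rest)]:
        return ReadCall(TRUNCATED)  # partial motif at read end: may continue
    if locus.right_flank and rest[0] != locus.right_flank[0]:
        return ReadCall(DISCORDANT)
    return ReadCall(OK, units=units)


def allele_depths(calls: Iterable[ReadCall]) -> dict[int, int]:
    """Aggregate OK read calls into repeat-count -> supporting-read depth."""
    depths: dict[int, int] = {}
    for call in calls:
        if call.status == OK:
            depths[call.units] = depths.get(call.units, 0) + 1
    return depths


def score_genotype(depths: dict[int, int], min_depth: int = 3) -> Optional[tuple[int, int]]:
    """Depth-based genotype scoring; ``None`` is a missing genotype.

    Alleles with depth < ``min_depth`` are discarded.  With more than two
    surviving alleles the two deepest are kept; a depth tie between the
    second and third best makes the locus homozygous for the best allele.
    Remaining ties (e.g. first and second equally deep) prefer the smaller
    repeat count, which keeps scoring deterministic.
    """
    kept = sorted(((d, u) for u, d in depths.items() if d >= min_depth),
                  key=lambda x: (-x[0], x[1]))
    if not kept:
        return None
    if len(kept) == 1:
        u = kept[0][1]
        return (u, u)
    if len(kept) > 2 and kept[1][0] == kept[2][0]:
        u = kept[0][1]
        return (u, u)
    alleles = sorted((kept[0][1], kept[1][1]))
    return (alleles[0], alleles[1])


def genotype_reads(
    reads: Sequence[tuple[str, int]], locus: RepeatLocus, min_depth: int = 3
) -> tuple[Optional[tuple[int, int]], dict[str, int]]:
    """Genotype one sample at one locus from (sequence, ref_start) reads.

    Returns the genotype (or None) and a tally of read fates.
    """
    tally = {OK: 0, TRUNCATED: 0, DISCORDANT: 0}
    calls = []
    for seq, start in reads:
        call = extract_repeat_length(seq, start, locus)
        tally[call.status] += 1
        calls.append(call)
    return score_genotype(allele_depths(calls), min_depth=min_depth), tally


# ---------------------------------------------------------------------------
# synthetic reads
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_flanks(locus: RepeatLocus, length: int, rng: np.random.Generator
                   ) -> tuple[str, str]:
    def extend(seed_seq: str, n: int, left: bool) -> str:
        extra = "".join(rng.choice(_BASES, size=max(0, n - len(seed_seq))))
        return (extra + seed_seq) if left else (seed_seq + extra)
    left = extend(locus.left_flank, length, left=True)
    right = extend(locus.right_flank, length, left=False)
    # a random base adjacent to the repeat must not extend the motif
    if not locus.right_flank and right[0] == locus.motif[0]:
        right = ("T" if locus.motif[0] != "T" else "A") + right[1:]
    return left, right


def simulate_reads(
    locus: RepeatLocus,
    genotype: tuple[int, int],
    depth: int = 30,
    read_length: int = 100,
    error_rate: float = 0.0,
    stutter_rate: float = 0.0,
    seed: int = 0,
) -> list[tuple[str, int]]:
    """Synthetic aligned reads over a repeat locus for one diploid genotype.

    Reads start uniformly over positions overlapping the repeat tract; each
    read copies one of the two alleles (fair coin), optionally with
    polymerase stutter (+/- one repeat unit with probability
    ``stutter_rate``) and per-base substitution errors.  Returned reference
    start coordinates assume the left flank aligns to the reference, which
    holds for every read that can pass the anchoring rules.
    """
    rng = np.random.default_rng(seed)
    if read_length < 8:
        raise ValueError("read_length too short to span any repeat")
    left, right = _random_flanks(locus, read_length, rng)
    reads: list[tuple[str, int]] = []
    import warnings
    if read_length < 4 * min(genotype) + 2:
        warnings.warn("read length shorter than the repeat span; all reads truncated")
    for _ in range(depth):
        units = int(genotype[rng.integers(2)])
        if stutter_rate > 0 and rng.random() < stutter_rate:
            units = max(1, units + (1 if rng.random() < 0.5 else -1))
        template = left + locus.motif * units + right
        template_repeat_start = len(left)
        lo = max(0, template_repeat_start - read_length + 1)
        hi = template_repeat_start + 4 * units  # last start overlapping the tract
        s = int(rng.integers(lo, hi))
        read = template[s:s + read_length]
        if error_rate > 0:
            arr = np.frombuffer(read.encode(), dtype="S1").astype("U1")
            errs = rng.random(arr.size) < error_rate
            if errs.any():
                arr[errs] = rng.choice(_BASES, size=int(errs.sum()))
                read = "".join(arr)
        ref_start = locus.start - (template_repeat_start - s)
        reads.append((read, ref_start))
    return reads


# ---------------------------------------------------------------------------
# file interfaces
# ---------------------------------------------------------------------------

def read_loci(path: str | os.PathLike) -> list[RepeatLocus]:
    """Read a locus table: name, chrom, start, end, motif, ref_units[, flanks]."""
    df = pd.read_csv(path, sep="\t").fillna("")
    required = {"name", "chrom", "start", "end", "motif", "ref_units"}
    if not required.issubset(df.columns):
        raise ConfigurationError(f"locus table must have columns {sorted(required)}")
    out = []
    for _, row in df.iterrows():
        out.append(RepeatLocus(
            name=str(row["name"]), chrom=str(row["chrom"]),
            start=int(row["start"]), end=int(row["end"]),
            motif=str(row["motif"]), ref_units=int(row["ref_units"]),
            left_flank=str(row.get("left_flank", "") or ""),
            right_flank=str(row.get("right_flank", "") or ""),
        ))
    return out


def write_loci(loci: Sequence[RepeatLocus], path: str | os.PathLike) -> None:
    pd.DataFrame([{
        "name": l.name, "chrom": l.chrom, "start": l.start, "end": l.end,
        "motif": l.motif, "ref_units": l.ref_units,
        "left_flank": l.left_flank, "right_flank": l.right_flank,
    } for l in loci]).to_csv(path, sep="\t", index=False)


def read_reads_tsv(path: str | os.PathLike) -> dict[str, list[tuple[str, int]]]:
    """Read aligned reads from a TSV: sample, locus, sequence, ref_start."""
    df = pd.read_csv(path, sep="\t")
    out: dict[str, list[tuple[str, int]]] = {}
    for _, row in df.iterrows():
        out.setdefault(f"{row['sample']}\t{row['locus']}", []).append(
            (str(row["sequence"]), int(row["ref_start"])))
    return out


def write_reads_tsv(
    reads: dict[tuple[str, str], list[tuple[str, int]]], path: str | os.PathLike
) -> None:
    rows = []
    for (sample, locus), lst in reads.items():
        for seq, start in lst:
            rows.append({"sample": sample, "locus": locus,
                         "sequence": seq, "ref_start": start})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reads_sam(path: str | os.PathLike, sample: str | None = None
                   ) -> list[tuple[str, str, int]]:
    """Aligned reads from a SAM file as (chrom, sequence, 0-based start)."""
    import pysam

    out = []
    with pysam.AlignmentFile(os.fspath(path), "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.query_sequence is None:
                continue
            out.append((rec.reference_name, rec.query_sequence, rec.reference_start))
    return out


def genotype_table(
    reads_by_sample_locus: dict[tuple[str, str], list[tuple[str, int]]],
    loci: Sequence[RepeatLocus],
    min_depth: int = 3,
) -> pd.DataFrame:
    """Genotype every (sample, locus) read group; MISSING rows keep NaN alleles."""
    by_name = {l.name: l for l in loci}
    rows = []
    for (sample, locus_name), reads in sorted(reads_by_sample_locus.items()):
        if locus_name not in by_name:
            raise ConfigurationError(f"unknown locus {locus_name!r}")
        gt, tally = genotype_reads(reads, by_name[locus_name], min_depth=min_depth)
        rows.append({
            "sample": sample, "locus": locus_name,
            "allele1": gt[0] if gt else np.nan,
            "allele2": gt[1] if gt else np.nan,
            "n_ok": tally[OK], "n_truncated": tally[TRUNCATED],
            "n_discordant": tally[DISCORDANT],
        })
    return pd.DataFrame(rows)
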