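"""File input/output: VCF, population-map TSV and distance-matrix tables."""

from __future__ import annotations

import os
from typing import Optional

import numpy as np
import pandas as pd
import pysam

from .core import (
    DIPLOID,
    HAPLOID_AS_DIPLOID,
    MISSING,
    ConfigurationError,
    EmptyMatrixError,
    GenotypeMatrix,
    PopulationMap,
    SampleInfo,
    VcfParseError,
)

_BASES = {"A", "C", "G", "T"}


def read_vcf(
    path: str | os.PathLike,
    region: Optional[str] = None,
    promote_haploid: bool = False,
) -> GenotypeMatrix:
    """Read biallelic SNPs from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records and non-SNP records (indels, symbolic alleles) are
    dropped.  Missing genotypes become :data:`MISSING`.  Haploid genotype
    calls are promoted to homozygous diploid codes when ``promote_haploid``
    is set (``0 -> 0``, ``1 -> 2``); otherwise a haploid call raises.

    ``region`` is a samtools-style region string (requires an indexed file).
    """
    try:
        vf = pysam.VariantFile(os.fspath(path))
    except (OSError, ValueError) as exc:
        raise VcfParseError(f"cannot parse VCF {path}: {exc}") from exc

    sample_ids = list(vf.header.samples)
    chroms: list[str] = []
    positions: list[int] = []
    rows: list[list[int]] = []
    saw_het = False
    try:
        records = vf.fetch(region=region) if region else vf
        for n_record, rec in enumerate(records, start=1):
            alts = rec.alts or ()
            if len(alts) != 1:
                continue
            if rec.ref not in _BASES or alts[0] not in _BASES:
                continue
            codes = []
            for sid in sample_ids:
                gt = rec.samples[sid].get("GT")
                if gt is None or all(a is None for a in gt):
                    codes.append(MISSING)
                    continue
                if len(gt) == 1:
                    if not promote_haploid:
                        raise VcfParseError(
                            f"haploid genotype at record {n_record} "
                            f"({rec.chrom}:{rec.pos}); pass promote_haploid=True"
                        )
                    a = gt[0]
                    codes.append(MISSING if a is None else (0 if a == 0 else 2))
                    continue
                if any(a is None for a in gt):
                    codes.append(MISSING)
                    continue
                codes.append(int(gt[0] != 0) + int(gt[1] != 0))
            chroms.append(rec.chrom)
            positions.append(rec.pos)
            rows.append(codes)
            if 1 in codes:
                saw_het = True
    except VcfParseError:
        raise
    except Exception as exc:  # malformed record mid-file
        raise VcfParseError(f"malformed VCF {path} near record {len(rows) + 1}: {exc}") from exc
    finally:
        vf.close()

    if not rows:
        raise EmptyMatrixError(f"no biallelic SNPs found in {path}")

    gm = GenotypeMatrix(
        sample_ids=sample_ids,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(positions, dtype=np.int64),
        genotypes=np.array(rows, dtype=np.int8).T,
        ploidy_flag=HAPLOID_AS_DIPLOID if (promote_haploid and not saw_het) else DIPLOID,
    )
    gm.validate()
    return gm


_GT_STRINGS = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(gm: GenotypeMatrix, path: str | os.PathLike) -> None:
    """Write a :class:`GenotypeMatrix` as a minimal GT-only VCF.

    Allele identities are not tracked internally, so sites are emitted with
    placeholder REF=A / ALT=T alleles; genotype codes round-trip exactly.
    """
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=arctos\n")
        for c in gm.chromosomes():
            length = int(gm.pos[gm.chrom == c].max()) + 1
            fh.write(f"##contig=<ID={c},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(gm.sample_ids) + "\n")
        gt = gm.genotypes
        for j in range(gm.n_sites):
            calls = "\t".join(_GT_STRINGS[int(g)] for g in gt[:, j])
            fh.write(f"{gm.chrom[j]}\t{gm.pos[j]}\t.\tA\tT\t.\tPASS\t.\tGT\t{calls}\n")


def read_popmap(path: str | os.PathLike) -> PopulationMap:
    """Read a 2-5 column TSV: sample, population, [sex], [lat], [lon].

    A header line is optional and detected by the literal first field
    ``sample``.
    """
    entries: dict[str, SampleInfo] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if lineno == 1 and fields[0].lower() == "sample":
                continue
            if len(fields) < 2:
                raise ConfigurationError(f"{path}:{lineno}: expected >=2 tab-separated fields")
            sid, pop = fields[0], fields[1]
            sex = fields[2] if len(fields) > 2 and fields[2] != "" else None
            lat = float(fields[3]) if len(fields) > 3 and fields[3] != "" else None
            lon = float(fields[4]) if len(fields) > 4 and fields[4] != "" else None
            entries[sid] = SampleInfo(population=pop, sex=sex, latitude=lat, longitude=lon)
    return PopulationMap(entries)


def write_popmap(popmap: PopulationMap, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sample\tpopulation\tsex\tlat\tlon\n")
        for sid, info in popmap.entries.items():
            fh.write(
                f"{sid}\t{info.population}\t{info.sex or ''}\t"
                f"{'' if info.latitude is None else info.latitude}\t"
                f"{'' if info.longitude is None else info.longitude}\n"
            )


def write_distance_matrix(labels: list[str], matrix: np.ndarray, path: str | os.PathLike) -> None:
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


def read_distance_matrix(path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return [str(c) for c in df.index], df.to_numpy(dtype=float)
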