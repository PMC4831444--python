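"""Standard-format I/O: VCF (read via cyvcf2, write as text), Genepop, TSV.

Coordinate conventions: VCF POS is 1-based; the internal ``snp_offset`` is
0-based (``POS = snp_offset + 1`` at both boundaries).  The VCF CHROM field
carries the stack identifier.
"""
from __future__ import annotations

import logging
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from .core import MISSING, CoverageMatrix, GenotypeMatrix, LocusAnnotation, SampleGroups

logger = logging.getLogger(__name__)


class VcfParseError(ValueError):
    pass


class VcfReadResult(NamedTuple):
    genotypes: GenotypeMatrix
    coverage: CoverageMatrix
    n_multiallelic: int


def _stack_from_chrom(chrom: str) -> int:
    token = chrom.rsplit("_", 1)[-1] if not chrom.isdigit() else chrom
    try:
        return int(token)
    except ValueError as e:
        raise VcfParseError(f"cannot derive a stack id from CHROM {chrom!r}") from e


def read_vcf(path: str | Path, default_depth: int = 10) -> VcfReadResult:
    """Read biallelic SNP records from a VCF into genotype + coverage matrices.

    Genotype dosage is decoded from GT (number of alt alleles); an absent or
    half-missing GT becomes :data:`MISSING`.  Depth is taken from FORMAT/DP
    when present; otherwise missing genotypes get depth 0 and called
    genotypes the ``default_depth`` (logged loudly, as it silently passes a
    >=10x coverage filter).  Records with more than one ALT allele are
    excluded and counted.
    """
    from cyvcf2 import VCF

    path = Path(path)
    try:
        vcf = VCF(str(path))
    except Exception as e:  # cyvcf2 raises bare exceptions on malformed headers
        raise VcfParseError(f"cannot parse VCF {path}: {e}") from e
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path} contains zero samples")

    dosage_rows: list[np.ndarray] = []
    depth_rows: list[np.ndarray] = []
    loci: list[LocusAnnotation] = []
    n_multi = 0
    used_default = False
    try:
        for lineno, var in enumerate(vcf, start=1):
            if len(var.ALT) != 1:
                n_multi += 1
                continue
            gts = np.array(var.genotypes, dtype=object)
            dos = np.empty(len(samples), dtype=np.int8)
            for j, gt in enumerate(var.genotypes):
                a1, a2 = gt[0], gt[1]
                dos[j] = MISSING if (a1 < 0 or a2 < 0) else a1 + a2
            try:
                dp = var.format("DP")
            except KeyError:  # DP absent from the FORMAT header entirely
                dp = None
            if dp is not None:
                depth = np.asarray(dp).reshape(-1).astype(np.int64)
                depth = np.where(depth < 0, 0, depth)
            else:
                used_default = True
                depth = np.full(len(samples), default_depth, dtype=np.int64)
            depth = np.where(dos == MISSING, 0, depth)
            dosage_rows.append(dos)
            depth_rows.append(depth.astype(np.int32))
            loci.append(
                LocusAnnotation(_stack_from_chrom(var.CHROM), var.POS - 1, var.REF, var.ALT[0])
            )
    except VcfParseError:
        raise
    except Exception as e:
        raise VcfParseError(f"malformed VCF record near data line {len(loci) + n_multi + 1} of {path}: {e}") from e

    if n_multi:
        logger.info("excluded %d multi-allelic record(s) from %s", n_multi, path)
    if used_default:
        logger.warning(
            "FORMAT/DP absent in %s: called genotypes assigned default depth %dx "
            "(this passes a >=10x coverage filter)", path, default_depth,
        )
    g = GenotypeMatrix(
        np.array(dosage_rows, dtype=np.int8).reshape(len(loci), len(samples)),
        loci,
        samples,
    )
    return VcfReadResult(g, CoverageMatrix(np.array(depth_rows, dtype=np.int32).reshape(len(loci), len(samples))), n_multi)


def write_vcf(g: GenotypeMatrix, c: CoverageMatrix | None, path: str | Path) -> None:
    """Write a minimal VCF 4.2 with GT (and DP when coverage is given)."""
    if c is not None:
        c.validate_against(g)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        if c is not None:
            fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">\n')
        for chrom in dict.fromkeys(l.stack_id for l in g.loci):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        gt_code = {MISSING: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        fmt = "GT:DP" if c is not None else "GT"
        for i, loc in enumerate(g.loci):
            cells = []
            for j in range(g.n_samples):
                gt = gt_code[int(g.dosages[i, j])]
                cells.append(f"{gt}:{int(c.depth[i, j])}" if c is not None else gt)
            fh.write(
                f"{loc.stack_id}\t{loc.snp_offset + 1}\t{loc.locus_id}\t{loc.ref}\t{loc.alt}"
                f"\t.\tPASS\t.\t{fmt}\t" + "\t".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# Genepop


def write_genepop(
    g: GenotypeMatrix,
    groups: SampleGroups,
    path: str | Path,
    group_by: str = "species_location",
    title: str = "radscan export",
) -> None:
    """Write a Genepop file with one POP block per grouping unit.

    Alleles are coded on two digits (ref=01, alt=02), missing as 0000.
    """
    if g.n_loci == 0:
        raise ValueError("refusing to write a Genepop file with zero loci")
    labels = groups.labels(g.samples, by=group_by)
    code = {MISSING: "0000", 0: "0101", 1: "0102", 2: "0202"}
    path = Path(path)
    with path.open("w") as fh:
        fh.write(title + "\n")
        for lid in g.locus_ids:
            fh.write(lid.replace(":", "_") + "\n")
        for unit in sorted(set(labels)):
            fh.write("POP\n")
            for j in np.flatnonzero(labels == unit):
                alleles = " ".join(code[int(g.dosages[i, j])] for i in range(g.n_loci))
                fh.write(f"{g.samples[j]} ,  {alleles}\n")


def read_genepop(path: str | Path) -> tuple[GenotypeMatrix, list[str]]:
    """Read back a two-digit biallelic Genepop file written by
    :func:`write_genepop`.  Returns the genotype matrix and the POP label
    (block index as a string) per sample."""
    lines = Path(path).read_text().splitlines()
    if len(lines) < 3:
        raise ValueError(f"{path}: not a Genepop file (too short)")
    locus_names: list[str] = []
    i = 1
    while i < len(lines) and lines[i].strip().upper() != "POP":
        locus_names.extend(t.strip() for t in lines[i].split(",") if t.strip())
        i += 1
    loci = []
    for name in locus_names:
        stack, _, off = name.rpartition("_")
        loci.append(LocusAnnotation(int(stack), int(off)))
    samples: list[str] = []
    pops: list[str] = []
    rows: list[list[int]] = []
    pop = -1
    decode = {"0101": 0, "0102": 1, "0201": 1, "0202": 2, "0000": MISSING}
    for line in lines[i:]:
        if line.strip().upper() == "POP":
            pop += 1
            continue
        if not line.strip():
            continue
        name, _, rest = line.partition(",")
        calls = rest.split()
        if len(calls) != len(loci):
            raise ValueError(f"{path}: sample {name.strip()} has {len(calls)} calls, expected {len(loci)}")
        samples.append(name.strip())
        pops.append(str(pop))
        rows.append([decode[c] for c in calls])
    dos = np.array(rows, dtype=np.int8).T.reshape(len(loci), len(samples))
    return GenotypeMatrix(dos, loci, samples), pops


# ---------------------------------------------------------------------------
# TSV matrices and metadata


def write_genotype_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(g.dosages, index=g.locus_ids, columns=g.samples).to_csv(path, sep="\t")


def read_genotype_tsv(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    loci = []
    for lid in df.index.astype(str):
        stack, _, off = lid.partition(":")
        loci.append(LocusAnnotation(int(stack), int(off or 0)))
    return GenotypeMatrix(df.to_numpy(dtype=np.int8), loci, [str(s) for s in df.columns])


def write_depth_tsv(c: CoverageMatrix, g: GenotypeMatrix, path: str | Path) -> None:
    pd.DataFrame(c.depth, index=g.locus_ids, columns=g.samples).to_csv(path, sep="\t")


def read_depth_tsv(path: str | Path) -> CoverageMatrix:
    return CoverageMatrix(pd.read_csv(path, sep="\t", index_col=0).to_numpy(dtype=np.int32))


def write_metadata_tsv(groups: SampleGroups, path: str | Path) -> None:
    rows = [
        {"sample": s, "species": sp, "location": loc}
        for s, (sp, loc) in groups.assignment.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_metadata_tsv(path: str | Path) -> SampleGroups:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample", "species", "location"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: metadata TSV needs columns {sorted(required)}")
    return SampleGroups(
        {row["sample"]: (row["species"], row["location"]) for _, row in df.iterrows()}
    )
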