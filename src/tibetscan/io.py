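"""VCF / TSV input-output and provenance headers.

Panels are exchanged as phased biallelic VCF (read with cyvcf2, written
with pysam) plus a two-column population map. Archaic and outgroup allele
tracks travel as tab-delimited (chrom, pos, allele). Window tables are
written both as 1-based inclusive report TSV and BED-compatible 0-based
half-open TSV.
"""

from __future__ import annotations

import hashlib
from importlib import metadata

import numpy as np
import pandas as pd

from .data_model import MISSING, HaplotypePanel, WindowTable

__all__ = [
    "read_population_map",
    "write_population_map",
    "read_vcf",
    "write_vcf",
    "read_allele_track",
    "write_allele_track",
    "write_table",
    "provenance_lines",
]


def _version() -> str:
    try:
        return metadata.version("tibetscan")
    except metadata.PackageNotFoundError:  # pragma: no cover
        return "unknown"


def provenance_lines(seed: int | None = None, **extra: object) -> list[str]:
    """Comment lines recording version/seed/parameters for output files."""
    lines = [f"# tibetscan={_version()}"]
    if seed is not None:
        lines.append(f"# seed={seed}")
    for key, val in extra.items():
        lines.append(f"# {key}={val}")
    return lines


def config_hash(payload: str) -> str:
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_population_map(path: str) -> dict[str, str]:
    """Two-column (sample, population) TSV, '#' comments allowed."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None, dtype=str)
    if df.shape[1] < 2:
        raise ValueError("population map needs two columns: sample, population")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_population_map(panel: HaplotypePanel, path: str) -> None:
    with open(path, "w") as fh:
        seen = set()
        for ind in panel.haplotype_individuals:
            ind = str(ind)
            if ind not in seen:
                seen.add(ind)
                fh.write(f"{ind}\t{panel.individual_populations[ind]}\n")


def write_vcf(
    panel: HaplotypePanel,
    path: str,
    contig_length: int | None = None,
    seed: int | None = None,
) -> None:
    """Write a panel as phased biallelic VCF (REF = ancestral as allele A,
    ALT = derived as allele T; INFO/AA records the ancestral allele)."""
    import pysam

    length = contig_length or int(panel.positions[-1]) + 1 if panel.n_sites else 1
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={panel.chromosome},length={length}>")
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    for line in provenance_lines(seed):
        header.add_line("##" + line.lstrip("# "))
    individuals: list[str] = []
    for ind in panel.haplotype_individuals:
        if str(ind) not in individuals:
            individuals.append(str(ind))
    for ind in individuals:
        header.add_sample(ind)
    hap_of = {ind: [] for ind in individuals}
    for h, ind in enumerate(panel.haplotype_individuals):
        hap_of[str(ind)].append(h)
    with pysam.VariantFile(path, "w", header=header) as out:
        for j in range(panel.n_sites):
            rec = out.new_record(
                contig=panel.chromosome,
                start=int(panel.positions[j]) - 1,  # pysam is 0-based
                alleles=("A", "T"),
            )
            rec.info["AA"] = "A"
            for ind in individuals:
                alleles = tuple(
                    None if panel.alleles[h, j] == MISSING else int(panel.alleles[h, j])
                    for h in hap_of[ind]
                )
                rec.samples[ind]["GT"] = alleles
                rec.samples[ind].phased = True
            out.write(rec)


def read_vcf(
    path: str,
    population_map: dict[str, str],
    ancestral: str = "AA",
) -> HaplotypePanel:
    """Read a phased biallelic VCF into a panel.

    Alleles are polarized against the ancestral allele: INFO field named by
    ``ancestral`` when present, otherwise REF. Multi-allelic records raise
    (split upstream); only the first contig in the file is read.
    """
    from cyvcf2 import VCF

    vcf = VCF(path, gts012=False)
    samples = list(vcf.samples)
    missing_pop = [s for s in samples if s not in population_map]
    if missing_pop:
        raise ValueError(f"samples without population assignment: {missing_pop[:5]}")
    positions: list[int] = []
    rows: list[np.ndarray] = []
    chrom = None
    last_pos = -1
    for var in vcf:
        if chrom is None:
            chrom = var.CHROM
        elif var.CHROM != chrom:
            break
        if len(var.ALT) != 1:
            raise ValueError(f"multi-allelic record at {var.CHROM}:{var.POS}; split upstream")
        if var.POS == last_pos:
            continue
        last_pos = var.POS
        aa = var.INFO.get(ancestral) if ancestral else None
        flip = aa is not None and str(aa).upper() == str(var.ALT[0]).upper()
        gt = np.array(var.genotype.array())[:, :2]  # (samples, 2)
        hap = gt.reshape(-1).astype(np.int8)
        hap = np.where(hap < 0, MISSING, hap)
        if flip:
            hap = np.where(hap == MISSING, MISSING, 1 - hap)
        positions.append(var.POS)
        rows.append(hap)
    if not rows:
        raise ValueError("no biallelic records found")
    alleles = np.vstack(rows).T  # (haplotypes, sites)
    hap_inds = np.repeat(samples, 2)
    return HaplotypePanel(
        chromosome=str(chrom),
        positions=np.array(positions, dtype=np.int64),
        alleles=alleles,
        haplotype_individuals=hap_inds,
        individual_populations={s: population_map[s] for s in samples},
    )


def read_allele_track(path: str) -> pd.DataFrame:
    """(chrom, pos, allele) TSV; allele is 0/1/. (missing)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "pos", "allele"], dtype={"chrom": str},
    )
    df["allele"] = df["allele"].replace(".", MISSING).astype(int)
    return df


def write_allele_track(
    chromosome: str, positions: np.ndarray, alleles: np.ndarray, path: str,
    seed: int | None = None,
) -> None:
    with open(path, "w") as fh:
        for line in provenance_lines(seed):
            fh.write(line + "\n")
        for pos, al in zip(positions, alleles):
            token = "." if al == MISSING else str(int(al))
            fh.write(f"{chromosome}\t{int(pos)}\t{token}\n")


def write_table(
    table: pd.DataFrame | WindowTable,
    path: str,
    bed: bool = False,
    seed: int | None = None,
    **extra: object,
) -> None:
    """Write a report TSV (1-based) or BED-compatible TSV (0-based starts)
    with a provenance header."""
    if isinstance(table, WindowTable):
        df = table.to_bed() if bed else table.table
    else:
        df = table.copy()
        if bed and "start" in df.columns:
            df["start"] = df["start"] - 1
    with open(path, "w") as fh:
        for line in provenance_lines(seed, **extra):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False)
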