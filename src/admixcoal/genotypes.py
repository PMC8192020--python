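"""Biallelic diploid genotype table backed by VCF + population map.

The central exchange container between the simulator, the SNP-filtering
pipeline and the SFS builders.  Genotypes are stored as ALT-allele dosages
(0/1/2, -1 for missing) in an (n_snps, n_samples) int8 matrix; SNP metadata
(RAD locus ID, 1-based position, REF/ALT nucleotides) lives in a pandas
DataFrame.  One RAD locus corresponds to one VCF contig (CHROM).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeTable", "read_popmap", "write_popmap"]


def read_popmap(path) -> dict[str, str]:
    """Read a two-column (sample, population) whitespace-separated text file."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(f"malformed popmap line: {line!r}")
            out[parts[0]] = parts[1]
    return out


def write_popmap(path, samples, pops) -> None:
    with open(path, "w") as fh:
        for s, p in zip(samples, pops):
            fh.write(f"{s}\t{p}\n")


@dataclass
class GenotypeTable:
    """Biallelic SNP genotypes with population labels and locus IDs."""

    snps: pd.DataFrame                 # columns: locus, pos, ref, alt
    geno: np.ndarray                   # int8 (n_snps, n_samples); -1 = missing
    samples: list[str]
    sample_pops: np.ndarray = field(default=None)  # population label per sample

    def __post_init__(self):
        self.snps = self.snps.reset_index(drop=True)
        self.geno = np.asarray(self.geno, dtype=np.int8)
        if self.geno.shape != (len(self.snps), len(self.samples)):
            raise ValueError(
                f"genotype matrix shape {self.geno.shape} does not match "
                f"{len(self.snps)} SNPs x {len(self.samples)} samples")
        self.sample_pops = np.asarray(self.sample_pops, dtype=object)
        if self.sample_pops.shape[0] != len(self.samples):
            raise ValueError("one population label per sample required")

    # -- basic views ------------------------------------------------------
    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def populations(self) -> list[str]:
        seen: list[str] = []
        for p in self.sample_pops:
            if p not in seen:
                seen.append(p)
        return seen

    def pop_mask(self, pop: str) -> np.ndarray:
        mask = self.sample_pops == pop
        if not mask.any():
            raise KeyError(f"unknown population label {pop!r}")
        return mask

    def subset_snps(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(self.snps.loc[mask].copy(), self.geno[mask],
                             list(self.samples), self.sample_pops.copy())

    # -- per-population summaries ----------------------------------------
    def genotype_counts(self, pop: str) -> np.ndarray:
        """(n_snps, 4) array of [n_hom_ref, n_het, n_hom_alt, n_missing]."""
        g = self.geno[:, self.pop_mask(pop)]
        out = np.empty((self.n_snps, 4), dtype=np.int64)
        out[:, 0] = (g == 0).sum(axis=1)
        out[:, 1] = (g == 1).sum(axis=1)
        out[:, 2] = (g == 2).sum(axis=1)
        out[:, 3] = (g == -1).sum(axis=1)
        return out

    def alt_counts(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        """Per-SNP ALT allele count and number of called alleles in ``pop``."""
        g = self.geno[:, self.pop_mask(pop)].astype(np.int64)
        called = g >= 0
        alt = np.where(called, g, 0).sum(axis=1)
        return alt, 2 * called.sum(axis=1)

    # -- VCF I/O ----------------------------------------------------------
    @classmethod
    def from_vcf(cls, vcf_path, popmap) -> "GenotypeTable":
        """Load biallelic SNPs from a VCF v4.x file.

        ``popmap`` is a {sample: population} dict or a path to a two-column
        text file.  Multi-allelic or non-SNP records are rejected.
        """
        from cyvcf2 import VCF

        if not isinstance(popmap, dict):
            popmap = read_popmap(popmap)
        vcf = VCF(str(vcf_path), gts012=True)
        samples = list(vcf.samples)
        missing = [s for s in samples if s not in popmap]
        if missing:
            raise ValueError(f"samples absent from population map: {missing}")
        loci, pos, ref, alt, rows = [], [], [], [], []
        for lineno, var in enumerate(vcf):
            if len(var.ALT) != 1:
                raise ValueError(
                    f"record {var.CHROM}:{var.POS} is not biallelic")
            if len(var.REF) != 1 or len(var.ALT[0]) != 1:
                raise ValueError(f"record {var.CHROM}:{var.POS} is not a SNP")
            loci.append(var.CHROM)
            pos.append(var.POS)
            ref.append(var.REF)
            alt.append(var.ALT[0])
            gt = var.gt_types.astype(np.int8)  # gts012: 0,1,2, 3=missing
            gt[gt == 3] = -1
            rows.append(gt)
        snps = pd.DataFrame({"locus": loci, "pos": pos, "ref": ref, "alt": alt})
        geno = (np.vstack(rows) if rows
                else np.empty((0, len(samples)), dtype=np.int8))
        pops = np.array([popmap[s] for s in samples], dtype=object)
        return cls(snps, geno, samples, pops)

    def to_vcf(self, path) -> None:
        """Write a minimal VCF v4.2 (GT only, one contig per RAD locus)."""
        gt_str = {-1: "./.", 0: "0/0", 1: "0/1", 2: "1/1"}
        with open(path, "w") as fh:
            fh.write("##fileformat=VCFv4.2\n")
            fh.write("##source=admixcoal\n")
            for locus in pd.unique(self.snps["locus"]):
                fh.write(f"##contig=<ID={locus}>\n")
            fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
            fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                     + "\t".join(self.samples) + "\n")
            for i, row in enumerate(self.snps.itertuples(index=False)):
                gts = "\t".join(gt_str[int(g)] for g in self.geno[i])
                fh.write(f"{row.locus}\t{row.pos}\t.\t{row.ref}\t{row.alt}"
                         f"\t.\tPASS\t.\tGT\t{gts}\n")

    def write_popmap(self, path) -> None:
        write_popmap(path, self.samples, self.sample_pops)
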