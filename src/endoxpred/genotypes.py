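"""Genotype dosage matrices and VCF/TSV input-output.

Dosages count copies of the minor allele (0/1/2, NaN for missing) per
sample. The minor allele of each site is determined from the sample allele
frequencies at load time; ties are broken by taking the alphabetically
earlier allele as minor. Positions are 1-based base-pair coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


class GenotypeIOError(ValueError):
    """Malformed genotype input."""


@dataclass
class GenotypeMatrix:
    """Samples x SNPs minor-allele dosage matrix.

    ``snps`` holds one row per SNP with at least ``snp_id``, ``chrom``,
    ``pos`` (1-based) and ``minor_allele`` columns, aligned with the columns
    of ``dosages``.
    """

    sample_ids: list[str]
    snps: pd.DataFrame
    dosages: np.ndarray  # float, entries in {0, 1, 2, NaN}

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise GenotypeIOError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and not np.isin(observed, (0.0, 1.0, 2.0)).all():
            raise GenotypeIOError("dosages must be 0, 1, 2 or missing")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return self.snps["snp_id"].tolist()

    def dosage_of(self, snp_id: str) -> np.ndarray:
        j = self.snps.index[self.snps["snp_id"] == snp_id]
        if len(j) != 1:
            raise GenotypeIOError(f"SNP {snp_id!r} not present exactly once")
        return self.dosages[:, int(j[0])]

    def subset_snps(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            self.sample_ids,
            self.snps.iloc[idx].reset_index(drop=True),
            self.dosages[:, idx],
        )

    def subset_samples(self, indices) -> "GenotypeMatrix":
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            [self.sample_ids[i] for i in idx],
            self.snps.copy(),
            self.dosages[idx, :],
        )

    def sorted_by_position(self) -> "GenotypeMatrix":
        order = self.snps.sort_values(["chrom", "pos"], kind="mergesort").index.to_numpy()
        return self.subset_snps(order)


def _orient_to_minor(alt_dosage: np.ndarray, ref: str, alt: str) -> tuple[np.ndarray, str]:
    """Flip ALT dosages so they count the minor allele; return (dosage, minor)."""
    observed = alt_dosage[~np.isnan(alt_dosage)]
    if observed.size == 0:
        return alt_dosage, min(ref, alt)
    alt_freq = observed.sum() / (2 * observed.size)
    if alt_freq < 0.5:
        return alt_dosage, alt
    if alt_freq > 0.5:
        return 2 - alt_dosage, ref
    minor = min(ref, alt)  # tie: alphabetical
    return (alt_dosage if minor == alt else 2 - alt_dosage), minor


def load_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read genotypes from a VCF (GT field) or a wide TSV.

    The TSV layout is one row per SNP: ``snp_id  chrom  pos  minor_allele``
    followed by one dosage column per sample (empty/NA = missing). VCF GT
    calls are converted to ALT dosages, then oriented to the sample minor
    allele; multiallelic records are skipped with a warning.
    """
    if format == "tsv":
        return _load_tsv(path)
    if format == "vcf":
        return _load_vcf(path)
    raise GenotypeIOError(f"unknown genotype format {format!r}")


def _load_tsv(path) -> GenotypeMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#")
    fixed = ["snp_id", "chrom", "pos", "minor_allele"]
    if not set(fixed) <= set(frame.columns):
        raise GenotypeIOError(f"genotype TSV must have columns {fixed} plus one per sample")
    sample_cols = [c for c in frame.columns if c not in fixed]
    if not sample_cols:
        raise GenotypeIOError("genotype TSV has no sample columns")
    dosages = frame[sample_cols].to_numpy(dtype=float).T
    snps = frame[fixed].copy()
    snps["chrom"] = snps["chrom"].astype(str)
    return GenotypeMatrix(list(sample_cols), snps.reset_index(drop=True), dosages)


def _load_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise GenotypeIOError("VCF has no samples")
    records, columns = [], []
    for variant in vcf:
        if len(variant.ALT) != 1:
            warnings.warn(
                f"skipping non-biallelic record {variant.ID or variant.POS}", stacklevel=2
            )
            continue
        gts = np.asarray(variant.gt_types, dtype=float)  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        alt_dosage = np.where(gts == 3, 2.0, np.where(gts == 2, np.nan, gts))
        dosage, minor = _orient_to_minor(alt_dosage, variant.REF, variant.ALT[0])
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        records.append((snp_id, str(variant.CHROM), int(variant.POS), minor))
        columns.append(dosage)
    if not records:
        raise GenotypeIOError(f"no usable biallelic records in {path}")
    snps = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "minor_allele"])
    return GenotypeMatrix(sample_ids, snps, np.column_stack(columns))


def write_genotypes_tsv(matrix: GenotypeMatrix, path, header_comment: str | None = None) -> None:
    dosage_frame = pd.DataFrame(matrix.dosages.T, columns=matrix.sample_ids)
    frame = pd.concat(
        [matrix.snps[["snp_id", "chrom", "pos", "minor_allele"]].reset_index(drop=True), dosage_frame],
        axis=1,
    )
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, sep="\t", index=False, na_rep="NA")


def write_vcf(matrix: GenotypeMatrix, path, header_comment: str | None = None) -> None:
    """Write a minimal VCF 4.2 with GT calls (ALT = minor allele).

    The major allele is written as REF "A" unless that collides with the
    minor-allele label, in which case "G" is used.
    """
    m = matrix.sorted_by_position()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        if header_comment:
            fh.write(f"##comment={header_comment}\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(m.sample_ids)
            + "\n"
        )
        gt_map = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
        for j, rec in m.snps.iterrows():
            minor = str(rec.get("minor_allele", "C"))
            ref = "A" if minor != "A" else "G"
            calls = [
                "./." if np.isnan(d) else gt_map[d] for d in m.dosages[:, j]
            ]
            fh.write(
                f"{rec['chrom']}\t{int(rec['pos'])}\t{rec['snp_id']}\t{ref}\t{minor}"
                f"\t.\t.\t.\tGT\t" + "\t".join(calls) + "\n"
            )
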