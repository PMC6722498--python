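"""Association scan: probe QC, PCA outliers, trend test, allele ORs, HWE, power.

The scan compares minor-allele frequencies between the MR < cutoff and
MR >= cutoff groups with the Cochran-Armitage trend test (additive scores
0/1/2), reports the allele-count odds ratio with a Woolf (normal
approximation) 95% CI, and flags significance against a Bonferroni-corrected
threshold. Supporting QC mirrors the study's genotyping pipeline: probes
missing in more than ``max_missing`` samples are dropped, samples are
screened by PCA on theta values, genomic inflation is summarised by lambda,
and per-SNP Hardy-Weinberg equilibrium is checked by a 1-df chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import GenotypeMatrix

#: Median of the chi-square distribution with 1 df, the null reference for
#: the genomic inflation factor.
CHI2_1DF_MEDIAN = 0.4549364231195724


class AssociationError(ValueError):
    """Invalid input to an association-layer operation."""


# ---------------------------------------------------------------------------
# QC


def filter_probes(matrix: GenotypeMatrix, max_missing: int = 4) -> tuple[GenotypeMatrix, list[str]]:
    """Drop probes with missing dosages in more than ``max_missing`` samples.

    A probe missing in exactly ``max_missing`` samples is retained (the rule
    is strictly "more than").
    """
    n_missing = np.isnan(matrix.dosages).sum(axis=0)
    keep = n_missing <= max_missing
    dropped = [sid for sid, k in zip(matrix.snp_ids, keep) if not k]
    return matrix.subset_snps(np.flatnonzero(keep)), dropped


def pca_qc(theta: np.ndarray, n_components: int = 2, mad_factor: float = 6.0):
    """PCA-based sample outlier screen on array theta values.

    Columns are mean-centred and the matrix decomposed by SVD; a sample is an
    outlier when its Euclidean distance from the coordinate-wise median in
    the first ``n_components`` components exceeds ``mad_factor`` times the
    median absolute deviation of those distances.

    Returns ``(coordinates, outlier_indices)``.
    """
    theta = np.asarray(theta, dtype=float)
    if theta.ndim != 2 or theta.shape[0] < 3:
        raise AssociationError("PCA QC needs a 2-d matrix with at least 3 samples")
    if not np.all(np.isfinite(theta)):
        raise AssociationError("PCA QC input contains non-finite values")
    centred = theta - theta.mean(axis=0, keepdims=True)
    u, s, _ = np.linalg.svd(centred, full_matrices=False)
    coords = u[:, :n_components] * s[:n_components]
    if coords.shape[1] < n_components:  # fewer probes than components
        raise AssociationError("degenerate input: rank below requested components")
    centre = np.median(coords, axis=0)
    dist = np.linalg.norm(coords - centre, axis=1)
    med = np.median(dist)
    mad = np.median(np.abs(dist - med))
    outliers = np.flatnonzero(dist > med + mad_factor * mad)
    return coords, outliers


# ---------------------------------------------------------------------------
# Tests and effect sizes


def trend_test(genotype_counts: np.ndarray) -> tuple[float, float]:
    """Cochran-Armitage trend test on a 2 (group) x 3 (genotype) count table.

    Genotypes are scored additively (0, 1, 2 minor-allele copies). Returns
    the 1-df chi-square statistic and its two-sided p-value.
    """
    table = np.asarray(genotype_counts, dtype=float)
    if table.shape != (2, 3):
        raise AssociationError(f"trend test needs a 2x3 table, got shape {table.shape}")
    if np.any(table < 0) or not np.allclose(table, np.round(table)):
        raise AssociationError("trend test needs nonnegative integer counts")
    r = table[0]  # first-group counts per genotype
    n = table.sum(axis=0)  # column totals
    big_n = n.sum()
    r1 = r.sum()
    if r1 == 0 or r1 == big_n:
        raise AssociationError("both groups must be non-empty")
    scores = np.array([0.0, 1.0, 2.0])
    # U = sum_i s_i (r_i - n_i * R1 / N); Var under H0 with fixed margins.
    u = float(scores @ (r - n * r1 / big_n))
    p_bar = r1 / big_n
    s_var = float(scores**2 @ n - (scores @ n) ** 2 / big_n)
    var_u = p_bar * (1 - p_bar) * s_var
    if var_u == 0:  # monomorphic or degenerate scores
        return 0.0, 1.0
    chi2 = u * u / var_u
    p = float(stats.chi2.sf(chi2, df=1))
    return float(chi2), p


def allele_or(allele_counts: np.ndarray) -> tuple[float, float, float]:
    """Odds ratio and Woolf 95% CI from a 2x2 allele-count table.

    Rows are groups (e.g. MR-below, MR-above); columns are minor-allele and
    other-allele counts. OR is the cross-product ratio; the CI is
    ``exp(ln OR +/- 1.96 * sqrt(sum 1/n_ij))``. When any cell is zero the
    Haldane-Anscombe correction adds 0.5 to every cell first.
    """
    t = np.asarray(allele_counts, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0):
        raise AssociationError("allele OR needs a nonnegative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        # e.g. a monomorphic SNP: no minor alleles observed in either group
        raise AssociationError("undefined OR: empty row or column in the allele table")
    if np.any(t == 0):
        t = t + 0.5
    a, b = t[0]
    c, d = t[1]
    or_point = (a * d) / (b * c)
    se = np.sqrt((1 / t).sum())
    z = stats.norm.ppf(0.975)
    log_or = np.log(or_point)
    return float(or_point), float(np.exp(log_or - z * se)), float(np.exp(log_or + z * se))


def bonferroni_threshold(alpha: float = 0.05, m: int = 1) -> float:
    """Per-test significance threshold alpha / m."""
    if m < 1:
        raise AssociationError("number of tests m must be >= 1")
    if not 0 < alpha < 1:
        raise AssociationError("alpha must be in (0, 1)")
    return alpha / m


def hwe_test(genotype_counts) -> tuple[float, float, bool]:
    """1-df chi-square test of Hardy-Weinberg proportions.

    ``genotype_counts`` is the (n_ref_hom, n_het, n_alt_hom) vector for one
    SNP. Returns ``(chi2, p, monomorphic)``; monomorphic SNPs get chi2=0,
    p=1 with the flag set.
    """
    obs = np.asarray(genotype_counts, dtype=float)
    if obs.shape != (3,) or np.any(obs < 0):
        raise AssociationError("HWE test needs a nonnegative 3-vector of genotype counts")
    n = obs.sum()
    if n == 0:
        raise AssociationError("HWE test needs at least one sample")
    q = (2 * obs[2] + obs[1]) / (2 * n)  # alt-allele frequency
    if q == 0 or q == 1:
        return 0.0, 1.0, True
    expected = n * np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, df=1)), False


def genomic_lambda(chi2_stats) -> float:
    """Genomic inflation factor: median test statistic over the chi2_1 median."""
    x = np.asarray(chi2_stats, dtype=float)
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise AssociationError("lambda needs at least one finite statistic")
    return float(np.median(x) / CHI2_1DF_MEDIAN)


def power_two_freq(
    n_per_group: int = 96, f1: float = 0.3, f2: float = 0.45, alpha: float = 0.05
) -> tuple[float, bool]:
    """Normal-approximation power for a two-group allele-frequency comparison.

    Each group of ``n_per_group`` samples contributes ``2 * n_per_group``
    alleles. Returns ``(power, null_flag)``; when ``f1 == f2`` the power is
    ``alpha`` by convention and the flag is set.
    """
    if not (0 < f1 < 1 and 0 < f2 < 1):
        raise AssociationError("allele frequencies must lie in (0, 1)")
    if n_per_group < 2:
        raise AssociationError("need at least 2 samples per group")
    if f1 == f2:
        return alpha, True
    m = 2 * n_per_group
    z_crit = stats.norm.ppf(1 - alpha / 2)
    pooled = (f1 + f2) / 2
    se0 = np.sqrt(2 * pooled * (1 - pooled) / m)
    se1 = np.sqrt(f1 * (1 - f1) / m + f2 * (1 - f2) / m)
    delta = abs(f1 - f2)
    power = stats.norm.sf((z_crit * se0 - delta) / se1) + stats.norm.cdf(
        (-z_crit * se0 - delta) / se1
    )
    return float(power), False


# ---------------------------------------------------------------------------
# Scan


@dataclass
class AssociationResult:
    """Per-SNP association summary between the two MR groups."""

    snp_id: str
    genotype_counts: np.ndarray  # 2 groups x 3 genotype classes
    allele_counts: np.ndarray  # 2 groups x (minor, other)
    maf: float
    or_point: float
    ci_low: float
    ci_high: float
    p_trend: float
    significant: bool


@dataclass
class QcReport:
    dropped_probes: list[str] = field(default_factory=list)
    pca_coordinates: np.ndarray | None = None
    outlier_samples: list[str] = field(default_factory=list)
    lambda_gc: float | None = None


def run_association_scan(
    matrix: GenotypeMatrix, below: np.ndarray, alpha: float = 0.05
) -> list[AssociationResult]:
    """Trend test + allele OR for every SNP, with a Bonferroni threshold.

    ``below`` is the per-sample boolean MR < cutoff indicator aligned with
    the matrix samples. Missing dosages are excluded pairwise per SNP;
    all-missing SNPs are skipped with a warning. Significance is judged
    against ``bonferroni_threshold(alpha, number of SNPs tested)``.
    """
    below = np.asarray(below, dtype=bool)
    if below.shape != (matrix.n_samples,):
        raise AssociationError("below-threshold labels must align with matrix samples")
    testable: list[tuple[str, np.ndarray]] = []
    for j, snp_id in enumerate(matrix.snp_ids):
        dos = matrix.dosages[:, j]
        mask = ~np.isnan(dos)
        if not mask.any():
            warnings.warn(f"SNP {snp_id} has no observed dosages; skipped", stacklevel=2)
            continue
        testable.append((snp_id, j))
    threshold = bonferroni_threshold(alpha, len(testable))
    results = []
    for snp_id, j in testable:
        dos = matrix.dosages[:, j]
        mask = ~np.isnan(dos)
        d = dos[mask].astype(int)
        grp = below[mask]
        geno = np.zeros((2, 3))
        for g, row in ((True, 0), (False, 1)):
            geno[row] = np.bincount(d[grp == g], minlength=3)[:3]
        minor = geno @ np.array([0.0, 1.0, 2.0])
        total = 2 * geno.sum(axis=1)
        alleles = np.column_stack([minor, total - minor])
        maf = float(minor.sum() / total.sum())
        try:
            or_point, lo, hi = allele_or(alleles)
        except AssociationError:
            or_point = lo = hi = float("nan")
        _, p = trend_test(geno)
        results.append(
            AssociationResult(snp_id, geno, alleles, maf, or_point, lo, hi, p, p < threshold)
        )
    return results


def scan_to_frame(results: list[AssociationResult], matrix: GenotypeMatrix) -> pd.DataFrame:
    """Tabulate scan results with positions (Table-2-style columns)."""
    info = matrix.snps.set_index("snp_id")
    rows = []
    for r in results:
        rec = info.loc[r.snp_id]
        rows.append(
            {
                "snp_id": r.snp_id,
                "chrom": rec["chrom"],
                "pos": int(rec["pos"]),
                "minor_allele": rec.get("minor_allele", "A"),
                "maf": r.maf,
                "or": r.or_point,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p_trend,
                "significant": r.significant,
            }
        )
    return pd.DataFrame(rows)
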