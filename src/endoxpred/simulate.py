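"""Synthetic tamoxifen-pharmacogenomics cohorts.

Generates complete cohorts with the statistical structure the downstream
stages assume: CYP2D6 diplotype groups drawn from the study cohort's
frequencies, per-group metabolic-ratio (MR) distributions (normal truncated
at zero), metabolite panels consistent with each sample's MR, and three
classes of SNPs — chromosome-22 SNPs in LD with the impaired-CYP2D6 allele
count (haplotype copying calibrated to a target r^2), independent-effect
SNPs whose population allele-count odds ratio for below-threshold MR is
calibrated exactly, and null SNPs under Hardy-Weinberg equilibrium. The
96+96 extreme-phenotype subset design used for the GWAS stage is provided
as a selection operation over the active-metabolite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .cyp2d6 import IMPAIRED_GROUPS, SEVEN_GROUPS, group_impaired
from .genotypes import GenotypeMatrix
from .metabolites import ANALYTES, ENDOXIFEN, MR_CUTOFF, MetabolitePanel, activity_ratio

#: Diplotype-group frequencies of the 287-patient study cohort.
DEFAULT_DIPLOTYPE_FREQS: dict[str, float] = {
    "NM/UM": 0.063,
    "NM/NM": 0.314,
    "NM/IM": 0.153,
    "NM/PM": 0.345,
    "IM/IM": 0.010,
    "IM/PM": 0.042,
    "PM/PM": 0.073,
}

#: Per-group MR mean and SD of the study cohort.
DEFAULT_MR_PARAMS: dict[str, tuple[float, float]] = {
    "NM/UM": (0.0201, 0.0076),
    "NM/NM": (0.0185, 0.0057),
    "NM/IM": (0.0125, 0.0054),
    "NM/PM": (0.0108, 0.0043),
    "IM/IM": (0.0063, 0.0022),
    "IM/PM": (0.0047, 0.0014),
    "PM/PM": (0.0037, 0.0013),
}

#: Fixed composition of the 14 non-(Z)-endoxifen analytes as fractions of the
#: total denominator; dominated by tamoxifen and NDM-Tam, as in plasma.
DENOMINATOR_COMPOSITION: dict[str, float] = {
    "tamoxifen": 0.550,
    "NDM-Tam": 0.300,
    "(E)-endoxifen": 0.010,
    "3-OH-NDM-Tam": 0.010,
    "4'-OH-NDM-Tam": 0.020,
    "(Z)-4-OH-Tam": 0.004,
    "3-OH-Tam": 0.002,
    "4'-OH-Tam": 0.002,
    "(Z)-a-OH-Tam": 0.002,
    "(E)-a-OH-Tam": 0.002,
    "Tam-N-oxide": 0.030,
    "Tam-N-gluc": 0.020,
    "(E/Z)-4-OH-NDM-Tam-gluc": 0.030,
    "(E)-4-OH-Tam-O-gluc": 0.018,
}

#: Number of IM or PM alleles implied by each diplotype group.
IMPAIRED_ALLELE_COUNT = {
    "NM/UM": 0,
    "NM/NM": 0,
    "NM/IM": 1,
    "NM/PM": 1,
    "IM/IM": 2,
    "IM/PM": 2,
    "PM/PM": 2,
}


class CohortConfigError(ValueError):
    """Invalid cohort configuration."""


class CalibrationError(ValueError):
    """Requested (r^2, MAF) or (OR, MAF) combination is unreachable."""


@dataclass(frozen=True)
class LinkedSnpSpec:
    """A SNP in LD with the impaired-allele count (haplotype copying)."""

    snp_id: str
    target_r2: float
    maf: float
    chrom: str = "22"
    pos: int = 0


@dataclass(frozen=True)
class EffectSnpSpec:
    """A SNP with an independent effect on below-threshold MR status."""

    snp_id: str
    target_or: float
    maf: float
    chrom: str = "1"
    pos: int = 0


def default_ld_spec() -> list[LinkedSnpSpec]:
    # The impaired-allele frequency implied by the default diplotype
    # frequencies is ~0.374; a proxy SNP's maximum attainable r^2 shrinks as
    # its MAF moves away from that value, so the default targets stay inside
    # the feasible region with margin for sampling variation.
    return [
        LinkedSnpSpec("chr22_linked_1", 0.75, 0.37, "22", 42_000_367),
        LinkedSnpSpec("chr22_linked_2", 0.55, 0.32, "22", 42_010_000),
        LinkedSnpSpec("chr22_linked_3", 0.35, 0.28, "22", 42_020_000),
    ]


def default_effect_spec() -> list[EffectSnpSpec]:
    # OR magnitudes on the scale of the study's verified independent-effect
    # SNPs (protective ~0.3-0.5, risk ~1.9).
    return [
        EffectSnpSpec("eff_chr5_protective", 0.51, 0.45, "5", 76_875_427),
        EffectSnpSpec("eff_chr7_risk", 1.93, 0.48, "7", 155_902_980),
        EffectSnpSpec("eff_chr22_protective", 0.28, 0.33, "22", 42_085_845),
    ]


@dataclass
class CohortConfig:
    n_samples: int = 287
    diplotype_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_DIPLOTYPE_FREQS))
    mr_params: Mapping[str, tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_MR_PARAMS))
    ld_spec: Sequence[LinkedSnpSpec] = field(default_factory=default_ld_spec)
    effect_spec: Sequence[EffectSnpSpec] = field(default_factory=default_effect_spec)
    n_null_snps: int = 200
    maf_range_null: tuple[float, float] = (0.05, 0.5)
    denominator_mean_ngml: float = 400.0
    denominator_sigma: float = 0.4  # lognormal shape of the total denominator
    mr_cutoff: float = MR_CUTOFF
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 0:
            raise CohortConfigError("n_samples must be nonnegative")
        total = sum(self.diplotype_freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise CohortConfigError(f"diplotype frequencies sum to {total}, not 1")
        if any(p < 0 for p in self.diplotype_freqs.values()):
            raise CohortConfigError("diplotype frequencies must be nonnegative")
        unknown = set(self.diplotype_freqs) - set(SEVEN_GROUPS)
        if unknown:
            raise CohortConfigError(f"unknown diplotype groups {sorted(unknown)}")
        for group, (_, sd) in self.mr_params.items():
            if sd <= 0:
                raise CohortConfigError(f"MR sd for {group} must be > 0")
        for spec in self.ld_spec:
            if not 0 <= spec.target_r2 <= 1:
                raise CohortConfigError(f"{spec.snp_id}: target r^2 must lie in [0, 1]")
            if not 0 < spec.maf <= 0.5:
                raise CohortConfigError(f"{spec.snp_id}: MAF must lie in (0, 0.5]")
        for spec in self.effect_spec:
            if spec.target_or <= 0:
                raise CohortConfigError(f"{spec.snp_id}: target OR must be > 0")
            if not 0 < spec.maf <= 0.5:
                raise CohortConfigError(f"{spec.snp_id}: MAF must lie in (0, 0.5]")
        lo, hi = self.maf_range_null
        if not 0 < lo <= hi <= 0.5:
            raise CohortConfigError("null-SNP MAF range must lie within (0, 0.5]")
        if self.denominator_mean_ngml <= 0:
            raise CohortConfigError("denominator mean must be positive")
        if not 0 <= self.missing_rate < 1:
            raise CohortConfigError("missing rate must lie in [0, 1)")


@dataclass
class Cohort:
    sample_ids: list[str]
    diplotypes: np.ndarray  # group labels
    impaired: np.ndarray  # bool
    mr_values: np.ndarray
    mr_below: np.ndarray  # bool, MR < cutoff
    panels: list[MetabolitePanel]
    genotypes: GenotypeMatrix
    truth: dict
    config: CohortConfig

    def activity_ratios(self) -> np.ndarray:
        return np.array([activity_ratio(p) for p in self.panels])


# ---------------------------------------------------------------------------
# Stage operations


def sample_diplotypes(n: int, freqs: Mapping[str, float], seed: int) -> np.ndarray:
    """Draw ``n`` diplotype-group labels from the configured frequencies."""
    if n < 0:
        raise CohortConfigError("n must be nonnegative")
    total = sum(freqs.values())
    if abs(total - 1.0) > 1e-9 or any(p < 0 for p in freqs.values()):
        raise CohortConfigError("frequencies must be nonnegative and sum to 1")
    groups = list(freqs)
    probs = np.array([freqs[g] for g in groups], dtype=float)
    rng = np.random.default_rng(seed)
    return rng.choice(np.array(groups, dtype=object), size=n, p=probs / probs.sum()).astype(str)


def sample_mr(
    diplotypes: np.ndarray, mr_params: Mapping[str, tuple[float, float]], seed: int
) -> np.ndarray:
    """Per-group MR draws from normal distributions truncated at zero."""
    diplotypes = np.asarray(diplotypes, dtype=str)
    missing = set(np.unique(diplotypes)) - set(mr_params) if diplotypes.size else set()
    if missing:
        raise CohortConfigError(f"no MR parameters for groups {sorted(missing)}")
    rng = np.random.default_rng(seed)
    mr = np.empty(diplotypes.size, dtype=float)
    for group in np.unique(diplotypes):
        mean, sd = mr_params[group]
        mask = diplotypes == group
        a = (0.0 - mean) / sd  # truncation at zero, in standard units
        mr[mask] = stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=mask.sum(), random_state=rng)
    return mr


def expand_metabolite_panel(
    mr: np.ndarray,
    denominator_mean: float = 400.0,
    seed: int = 0,
    sigma: float = 0.4,
    sample_ids: Sequence[str] | None = None,
) -> list[MetabolitePanel]:
    """Construct 15-analyte panels whose MR equals the given values exactly.

    Each sample's total non-(Z)-endoxifen denominator D is drawn lognormal
    with the configured mean, split across the 14 other analytes by the
    fixed composition vector, and (Z)-endoxifen is set to ``mr * D``.
    """
    mr = np.asarray(mr, dtype=float)
    if np.any(mr <= 0):
        raise CohortConfigError("all MR values must be positive")
    if denominator_mean <= 0:
        raise CohortConfigError("denominator mean must be positive")
    rng = np.random.default_rng(seed)
    mu = np.log(denominator_mean) - sigma**2 / 2
    denominators = rng.lognormal(mean=mu, sigma=sigma, size=mr.size)
    if sample_ids is None:
        sample_ids = [f"S{i:04d}" for i in range(mr.size)]
    panels = []
    for sid, m, d in zip(sample_ids, mr, denominators):
        conc = {a: frac * d for a, frac in DENOMINATOR_COMPOSITION.items()}
        conc[ENDOXIFEN] = m * d
        panels.append(MetabolitePanel(sid, conc))
    return panels


def select_extreme_subsets(
    ratios: np.ndarray, n_per_tail: int, sample_ids: Sequence[str] | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``n_per_tail`` lowest and highest activity ratios.

    Ties are broken deterministically by sample id; the two tails are always
    disjoint (requires ``2 * n_per_tail <= n``).
    """
    ratios = np.asarray(ratios, dtype=float)
    n = ratios.size
    if 2 * n_per_tail > n:
        raise CohortConfigError(f"2 x {n_per_tail} tail samples exceed cohort size {n}")
    ids = np.array(sample_ids if sample_ids is not None else [f"S{i:04d}" for i in range(n)], dtype=str)
    order = np.lexsort((ids, ratios))  # ascending ratio, ties by id
    return order[:n_per_tail].copy(), order[n - n_per_tail :].copy()


# ---------------------------------------------------------------------------
# Genotype generation


def _solve_effect_frequencies(target_or: float, maf: float, prevalence: float) -> tuple[float, float]:
    """Allele frequencies (f_below, f_above) giving the target allele OR.

    Solves pi * f1 + (1 - pi) * f0 = maf with odds(f1) = OR * odds(f0),
    under HWE within each MR group.
    """
    if not 0 < prevalence < 1:
        raise CalibrationError("below-threshold prevalence must lie strictly in (0, 1)")

    def f1_of(f0: float) -> float:
        odds = target_or * f0 / (1 - f0)
        return odds / (1 + odds)

    def gap(f0: float) -> float:
        return prevalence * f1_of(f0) + (1 - prevalence) * f0 - maf

    eps = 1e-12
    if gap(eps) > 0 or gap(1 - eps) < 0:
        raise CalibrationError(
            f"no allele frequencies reach OR={target_or} at MAF={maf}, prevalence={prevalence}"
        )
    f0 = optimize.brentq(gap, eps, 1 - eps, xtol=1e-14)
    return f1_of(f0), f0


def _solve_copy_probability(
    target_r2: float, maf: float, tag_freq: float, var_count: float, cov_haplotypes: float
) -> tuple[float, float]:
    """Copying probability phi and background frequency for a linked SNP.

    Each haplotype copies the impaired-allele tag with probability phi and
    otherwise draws an independent background allele whose frequency is set
    so the SNP's marginal MAF is preserved. phi is solved numerically so the
    squared correlation between the SNP dosage and the impaired-allele count
    matches ``target_r2`` given the cohort's realised tag-count moments.
    """
    if var_count <= 0:
        raise CalibrationError("impaired-allele count has zero variance; no LD target reachable")
    if target_r2 == 0:
        return 0.0, maf

    def r2_of(phi: float) -> float:
        p_l = phi * tag_freq + (1 - phi) * _background(phi)
        var_l = 2 * p_l * (1 - p_l) + 2 * phi**2 * cov_haplotypes
        if var_l <= 0:
            return 0.0
        return phi**2 * var_count / var_l

    def _background(phi: float) -> float:
        return (maf - phi * tag_freq) / (1 - phi) if phi < 1 else maf

    # phi upper bound keeps the background frequency within [0, 1]
    hi = 1.0 - 1e-9
    if tag_freq > maf:
        hi = min(hi, maf / tag_freq - 1e-9)
    if tag_freq < maf:
        hi = min(hi, (1 - maf) / (1 - tag_freq) - 1e-9)
    if hi <= 0 or r2_of(hi) < target_r2:
        raise CalibrationError(
            f"target r^2={target_r2} unreachable at MAF={maf} with tag frequency {tag_freq:.3f}"
        )
    phi = optimize.brentq(lambda f: r2_of(f) - target_r2, 0.0, hi, xtol=1e-12)
    return phi, _background(phi)


def sample_genotypes(
    diplotypes: np.ndarray,
    mr_below: np.ndarray,
    ld_spec: Sequence[LinkedSnpSpec],
    effect_spec: Sequence[EffectSnpSpec],
    n_null: int,
    maf_range: tuple[float, float],
    seed: int,
    missing_rate: float = 0.0,
) -> tuple[GenotypeMatrix, dict]:
    """Generate the four SNP classes and the truth record.

    (i) two CYP2D6 tag SNPs derived deterministically from the diplotype
    groups (dosage = number of PM alleles, resp. IM alleles); (ii) linked
    SNPs by calibrated haplotype copying from the impaired-allele count;
    (iii) effect SNPs drawn conditional on below-threshold status with
    calibrated group allele frequencies; (iv) null SNPs binomial(2, MAF)
    under HWE.
    """
    diplotypes = np.asarray(diplotypes, dtype=str)
    mr_below = np.asarray(mr_below, dtype=bool)
    n = diplotypes.size
    if mr_below.shape != (n,):
        raise CohortConfigError("mr_below must align with diplotypes")
    rng = np.random.default_rng(seed)
    columns: list[np.ndarray] = []
    records: list[tuple[str, str, int, str]] = []
    truth: dict = {"cyp2d6_tags": [], "linked": {}, "effect": {}, "null": []}

    # (i) deterministic CYP2D6 tag SNPs
    pm_count = np.array([g.count("PM") for g in diplotypes], dtype=float)
    im_count = np.array([g.count("IM") for g in diplotypes], dtype=float)
    for snp_id, pos, dosage in (
        ("cyp2d6_pm_tag", 42_128_945, pm_count),
        ("cyp2d6_im_tag", 42_130_692, im_count),
    ):
        records.append((snp_id, "22", pos, "T"))
        columns.append(dosage.copy())
        truth["cyp2d6_tags"].append(snp_id)

    # (ii) linked SNPs: haplotype copying from the impaired-allele tag.
    # Heterozygous-impaired samples place their impaired allele on a random
    # haplotype so both haplotype tags are exchangeable Bernoulli(tag_freq).
    count = np.array([IMPAIRED_ALLELE_COUNT[g] for g in diplotypes], dtype=float)
    tag_freq = count.mean() / 2 if n else 0.0
    var_count = count.var()
    het = count == 1
    first = rng.random(n) < 0.5
    t1 = np.where(het, first, count == 2).astype(float)
    t2 = np.where(het, ~first, count == 2).astype(float)
    cov_h = float(np.mean(count == 2) - tag_freq**2)
    for spec in ld_spec:
        phi, background = _solve_copy_probability(
            spec.target_r2, spec.maf, tag_freq, var_count, cov_h
        )
        dosage = np.zeros(n)
        for tags in (t1, t2):
            copy = rng.random(n) < phi
            allele = np.where(copy, tags, (rng.random(n) < background).astype(float))
            dosage += allele
        records.append((spec.snp_id, spec.chrom, spec.pos, "C"))
        columns.append(dosage)
        truth["linked"][spec.snp_id] = {
            "target_r2": spec.target_r2,
            "maf": spec.maf,
            "copy_probability": phi,
            "background_freq": background,
        }

    # (iii) effect SNPs conditional on below-threshold status
    prevalence = float(mr_below.mean()) if n else 0.0
    for spec in effect_spec:
        if spec.target_or == 1.0:
            f1 = f0 = spec.maf
        else:
            f1, f0 = _solve_effect_frequencies(spec.target_or, spec.maf, prevalence)
        freqs = np.where(mr_below, f1, f0)
        dosage = rng.binomial(2, freqs).astype(float)
        records.append((spec.snp_id, spec.chrom, spec.pos, "G"))
        columns.append(dosage)
        truth["effect"][spec.snp_id] = {
            "target_or": spec.target_or,
            "maf": spec.maf,
            "freq_below": f1,
            "freq_above": f0,
            "prevalence_below": prevalence,
        }

    # (iv) null SNPs under HWE
    lo, hi = maf_range
    null_chroms = rng.integers(1, 22, size=n_null)  # autosomes 1-21
    null_pos = rng.integers(1_000_000, 200_000_000, size=n_null)
    for i in range(n_null):
        maf = float(rng.uniform(lo, hi))
        snp_id = f"null_{i:04d}"
        records.append((snp_id, str(null_chroms[i]), int(null_pos[i]), "A"))
        columns.append(rng.binomial(2, maf, size=n).astype(float))
        truth["null"].append(snp_id)

    dosages = np.column_stack(columns) if columns else np.zeros((n, 0))
    if missing_rate > 0:
        mask = rng.random(dosages.shape) < missing_rate
        dosages[mask] = np.nan
    snps = pd.DataFrame(records, columns=["snp_id", "chrom", "pos", "minor_allele"])
    matrix = GenotypeMatrix([f"S{i:04d}" for i in range(n)], snps, dosages)
    return matrix, truth


# ---------------------------------------------------------------------------
# Full cohort


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a complete cohort from one master seed.

    Stage seeds are derived from the master seed as named substreams, so
    each stage is independently reproducible.
    """
    streams = np.random.SeedSequence(config.seed).generate_state(4, dtype="uint32") >> 1
    diplo_seed, mr_seed, panel_seed, geno_seed = (int(s) for s in streams)
    diplotypes = sample_diplotypes(config.n_samples, config.diplotype_freqs, diplo_seed)
    impaired = np.array([group_impaired(g) for g in diplotypes], dtype=bool)
    mr = sample_mr(diplotypes, config.mr_params, mr_seed)
    mr_below = mr < config.mr_cutoff
    sample_ids = [f"S{i:04d}" for i in range(config.n_samples)]
    panels = expand_metabolite_panel(
        mr, config.denominator_mean_ngml, panel_seed, config.denominator_sigma, sample_ids
    )
    genotypes, truth = sample_genotypes(
        diplotypes,
        mr_below,
        config.ld_spec,
        config.effect_spec,
        config.n_null_snps,
        config.maf_range_null,
        geno_seed,
        config.missing_rate,
    )
    truth["stage_seeds"] = {
        "diplotypes": diplo_seed,
        "mr": mr_seed,
        "panels": panel_seed,
        "genotypes": geno_seed,
    }
    return Cohort(
        sample_ids=sample_ids,
        diplotypes=diplotypes,
        impaired=impaired,
        mr_values=mr,
        mr_below=mr_below,
        panels=panels,
        genotypes=genotypes,
        truth=truth,
        config=config,
    )
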