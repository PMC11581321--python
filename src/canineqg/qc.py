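"""SNP and sample quality control.

Filters are applied in a fixed order — non-autosomal / duplicate-position
SNPs, low-call-rate samples, low-call-rate SNPs, low-MAF SNPs, exact-test
Hardy-Weinberg failures, then identity-by-state duplicate samples — because
allele frequencies and HWE depend on the retained sample set. Every stage
is logged so the report reconciles: input SNPs - removed = remaining.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, QcError
from .formats import GenotypeMatrix

__all__ = ["QcConfig", "QcReport", "hwe_test", "ibs_matrix", "apply_qc", "impute_mean"]


@dataclass(frozen=True)
class QcConfig:
    maf_min: float = 0.05
    snp_call_rate_min: float = 0.90
    sample_call_rate_min: float = 0.90
    hwe_p_min: float = 1e-6
    ibs_duplicate_threshold: float = 0.99
    drop_nonautosomal: bool = True
    check_ibs_duplicates: bool = True
    n_autosomes: int = 38

    def validate(self) -> None:
        for name in (
            "maf_min", "snp_call_rate_min", "sample_call_rate_min",
            "hwe_p_min", "ibs_duplicate_threshold",
        ):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v}")


@dataclass
class QcReport:
    n_snps_in: int
    n_animals_in: int
    stage_log: list[tuple[str, int]] = field(default_factory=list)
    duplicate_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    n_snps_remaining: int = 0
    n_animals_remaining: int = 0

    def removed(self, stage: str) -> int:
        return dict(self.stage_log).get(stage, 0)

    def total_snps_removed(self) -> int:
        sample_stages = {"sample_call_rate", "ibs_duplicate"}
        return sum(n for s, n in self.stage_log if s not in sample_stages)


def hwe_test(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value (Wigginton-style, no mid-p).

    Enumerates all heterozygote counts compatible with the observed allele
    counts and sums the probabilities of configurations no more likely than
    the observed one. Returns a value in (0, 1].
    """
    counts = (n_hom_minor, n_het, n_hom_major)
    if any(c < 0 for c in counts):
        raise ConfigError("genotype counts must be non-negative")
    n = sum(counts)
    if n == 0:
        raise QcError("HWE test undefined with zero genotyped animals")
    n_rare = 2 * n_hom_minor + n_het
    if n_rare > n:  # orient so the 'rare' allele really is the rarer one
        n_rare = 2 * n - n_rare
    # het counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    probs = np.zeros(len(hets))
    # anchor the recurrence at the distribution's mode (numerical range)
    mid = int(n_rare * (2 * n - n_rare) / (2.0 * n))
    if mid % 2 != n_rare % 2:
        mid += 1
    k0 = int(np.searchsorted(hets, mid))
    probs[k0] = 1.0
    for k in range(k0, 0, -1):
        h = int(hets[k])
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[k - 1] = probs[k] * h * (h - 1.0) / (4.0 * (hom_r + 1.0) * (hom_c + 1.0))
    for k in range(k0, len(hets) - 1):
        h = int(hets[k])
        hom_r = (n_rare - h) // 2
        hom_c = n - h - hom_r
        probs[k + 1] = probs[k] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
    probs /= probs.sum()
    p_obs = probs[int(np.searchsorted(hets, n_het))]
    p = probs[probs <= p_obs * (1.0 + 1e-12)].sum()
    return float(min(p, 1.0))


def ibs_matrix(genotypes: GenotypeMatrix) -> np.ndarray:
    """Pairwise identity-by-state similarity.

    similarity(i, j) = mean over jointly observed SNPs of
    (2 - |dosage_i - dosage_j|) / 2; diagonal 1; NaN where a pair shares no
    observed SNP.
    """
    X = genotypes.dosage
    n = X.shape[0]
    if n < 2:
        raise ConfigError("IBS requires at least 2 animals")
    S = np.eye(n)
    obs = ~np.isnan(X)
    for i in range(n):
        for j in range(i + 1, n):
            joint = obs[i] & obs[j]
            if not joint.any():
                S[i, j] = S[j, i] = np.nan
                continue
            sim = np.mean((2.0 - np.abs(X[i, joint] - X[j, joint])) / 2.0)
            S[i, j] = S[j, i] = sim
    return S


def _is_autosomal(label: str, n_autosomes: int) -> bool:
    s = str(label)
    if s.lower().startswith("chr"):
        s = s[3:]
    return s.isdigit() and 1 <= int(s) <= n_autosomes


def apply_qc(
    genotypes: GenotypeMatrix, config: QcConfig = QcConfig()
) -> tuple[GenotypeMatrix, QcReport]:
    """Run the full SNP/sample QC pipeline; see the module docstring for the
    stage order. MAF and HWE use the retained sample set. IBS duplicate
    pairs drop the later-listed member."""
    config.validate()
    report = QcReport(genotypes.n_snps, genotypes.n_animals)
    gm = genotypes

    # stage 1: non-autosomal + duplicate-position SNPs
    keep = np.ones(gm.n_snps, dtype=bool)
    if config.drop_nonautosomal:
        for j in range(gm.n_snps):
            if not _is_autosomal(gm.chromosome[j], config.n_autosomes):
                keep[j] = False
    seen: set[tuple[str, int]] = set()
    for j in range(gm.n_snps):
        if not keep[j]:
            continue
        key = (str(gm.chromosome[j]), int(gm.position_bp[j]))
        if key in seen:
            keep[j] = False
        else:
            seen.add(key)
    report.stage_log.append(("nonautosomal_or_duplicate_position", int((~keep).sum())))
    gm = gm.subset(snps=keep)

    # stage 2: sample call rate
    scr = gm.sample_call_rate()
    keep_a = scr >= config.sample_call_rate_min
    report.stage_log.append(("sample_call_rate", int((~keep_a).sum())))
    gm = gm.subset(animals=[a for a, k in zip(gm.animal_ids, keep_a) if k])

    # stage 3: SNP call rate
    keep = gm.snp_call_rate() >= config.snp_call_rate_min
    report.stage_log.append(("snp_call_rate", int((~keep).sum())))
    gm = gm.subset(snps=keep)

    # stage 4: MAF (NaN frequency -> dropped whenever a threshold is set)
    if config.maf_min > 0:
        with np.errstate(invalid="ignore"):
            keep = gm.maf() >= config.maf_min
    else:
        keep = np.ones(gm.n_snps, dtype=bool)
    report.stage_log.append(("maf", int((~keep).sum())))
    gm = gm.subset(snps=keep)

    # stage 5: HWE exact test
    keep = np.ones(gm.n_snps, dtype=bool)
    if config.hwe_p_min > 0:
        X = gm.dosage
        for j in range(gm.n_snps):
            col = X[:, j]
            col = col[~np.isnan(col)]
            if col.size == 0:
                keep[j] = False
                continue
            p = hwe_test(int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))
            keep[j] = p >= config.hwe_p_min
    report.stage_log.append(("hwe", int((~keep).sum())))
    gm = gm.subset(snps=keep)
    if gm.n_snps == 0:
        raise QcError("all SNPs removed by QC; empty panel")

    # stage 6: IBS duplicates (drop the later-listed member of each pair)
    n_dropped = 0
    if config.check_ibs_duplicates and gm.n_animals >= 2:
        S = ibs_matrix(gm)
        drop: set[int] = set()
        for i in range(gm.n_animals):
            for j in range(i + 1, gm.n_animals):
                if np.isnan(S[i, j]) or S[i, j] <= config.ibs_duplicate_threshold:
                    continue
                report.duplicate_pairs.append(
                    (gm.animal_ids[i], gm.animal_ids[j], float(S[i, j]))
                )
                if i not in drop:
                    drop.add(j)
        n_dropped = len(drop)
        if drop:
            gm = gm.subset(
                animals=[a for k, a in enumerate(gm.animal_ids) if k not in drop]
            )
    report.stage_log.append(("ibs_duplicate", n_dropped))

    report.n_snps_remaining = gm.n_snps
    report.n_animals_remaining = gm.n_animals
    assert report.n_snps_in - report.total_snps_removed() == report.n_snps_remaining
    return gm, report


def impute_mean(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing cells with the SNP's observed mean dosage.

    Observed cells are unchanged; imputed cells are real-valued, preserving
    each SNP's allele frequency. A SNP with no observed genotypes cannot be
    imputed and raises.
    """
    X = genotypes.dosage
    if not np.isnan(X).any():
        return genotypes
    all_missing = np.isnan(X).all(axis=0)
    if all_missing.any():
        bad = [genotypes.snp_ids[j] for j in np.flatnonzero(all_missing)[:5]]
        raise QcError(f"cannot impute SNPs with no observed genotypes: {bad}")
    means = np.nanmean(X, axis=0)
    filled = np.where(np.isnan(X), means, X)
    return GenotypeMatrix(
        genotypes.animal_ids, genotypes.snp_ids, genotypes.chromosome,
        genotypes.position_bp, genotypes.allele_minor, genotypes.allele_major,
        filled,
    )
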