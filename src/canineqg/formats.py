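"""Standard file formats: PLINK text/binary genotypes, pedigree and
phenotype CSV, gene BED, and GEMMA-style GWAS TSV.

Internal conventions (fixed at the boundary, never revisited downstream):

* genomic coordinates are 1-based inclusive; UCSC BED (0-based half-open)
  is converted on read/write;
* dosage counts copies of the *minor* allele, oriented from observed
  frequencies at load time (ties broken lexicographically);
* missing genotypes are ``NaN``, a distinct sentinel never conflated with
  dosage 0.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import FormatError, IntegrityError
from .pedigree import Pedigree

PathLike = Union[str, Path]
_VALID_ALLELES = frozenset("ACGT0")

#: BED magic bytes and SNP-major mode flag (PLINK 1.9 binary dialect)
_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"


@dataclass
class GenotypeMatrix:
    """Animals x SNPs minor-allele dosage matrix with SNP metadata.

    ``dosage`` is float (n_animals, n_snps) with values in {0, 1, 2} or NaN
    for missing; after mean imputation cells may hold real values.
    """

    animal_ids: list[str]
    snp_ids: list[str]
    chromosome: np.ndarray
    position_bp: np.ndarray
    allele_minor: np.ndarray
    allele_major: np.ndarray
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.animal_ids = list(map(str, self.animal_ids))
        self.snp_ids = list(map(str, self.snp_ids))
        self.chromosome = np.asarray(self.chromosome, dtype=object)
        self.position_bp = np.asarray(self.position_bp, dtype=np.int64)
        self.allele_minor = np.asarray(self.allele_minor, dtype=object)
        self.allele_major = np.asarray(self.allele_major, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        n, m = self.dosage.shape
        if len(self.animal_ids) != n or len(self.snp_ids) != m:
            raise IntegrityError("dosage shape inconsistent with id lists")
        if len(set(self.animal_ids)) != n:
            raise IntegrityError("duplicate animal identifiers")
        if len(set(self.snp_ids)) != m:
            raise IntegrityError("duplicate SNP identifiers")

    @property
    def n_animals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    def maf(self) -> np.ndarray:
        """Observed minor-allele frequency per SNP (NaN-aware)."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=1)

    def subset(
        self,
        animals: Optional[Sequence] = None,
        snps: Optional[Sequence] = None,
    ) -> "GenotypeMatrix":
        """Restrict to the given animal ids and/or SNP boolean mask/ids."""
        ai = np.arange(self.n_animals)
        if animals is not None:
            idx = {a: i for i, a in enumerate(self.animal_ids)}
            try:
                ai = np.array([idx[str(a)] for a in animals], dtype=np.int64)
            except KeyError as exc:
                raise IntegrityError(f"unknown animal id {exc.args[0]!r}") from exc
        si = np.arange(self.n_snps)
        if snps is not None:
            snps = np.asarray(snps)
            if snps.dtype == bool:
                si = np.flatnonzero(snps)
            else:
                idx = {s: i for i, s in enumerate(self.snp_ids)}
                try:
                    si = np.array([idx[str(s)] for s in snps], dtype=np.int64)
                except KeyError as exc:
                    raise IntegrityError(f"unknown SNP id {exc.args[0]!r}") from exc
        return GenotypeMatrix(
            [self.animal_ids[i] for i in ai],
            [self.snp_ids[j] for j in si],
            self.chromosome[si],
            self.position_bp[si],
            self.allele_minor[si],
            self.allele_major[si],
            self.dosage[np.ix_(ai, si)],
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.animal_ids == other.animal_ids
            and self.snp_ids == other.snp_ids
            and np.array_equal(self.chromosome, other.chromosome)
            and np.array_equal(self.position_bp, other.position_bp)
            and np.array_equal(self.allele_minor, other.allele_minor)
            and np.array_equal(self.allele_major, other.allele_major)
            and np.array_equal(self.dosage, other.dosage, equal_nan=True)
        )


def _orient_minor(
    count_a1: np.ndarray, a1: np.ndarray, a2: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Re-orient dosages so they count the observed minor allele.

    ``count_a1`` counts allele a1. Where a1's frequency exceeds 0.5, or ties
    at 0.5 with a2 lexicographically smaller, the orientation is flipped.
    Monomorphic columns keep dosage 0 with the observed allele as major and
    '0' as the (unknown) minor allele.
    """
    count_a1 = np.asarray(count_a1, dtype=float)
    a1 = np.asarray(a1, dtype=object).copy()
    a2 = np.asarray(a2, dtype=object).copy()
    n_obs = (~np.isnan(count_a1)).sum(axis=0)
    sums = np.nansum(count_a1, axis=0)
    # all-missing columns get NaN frequency and are never flipped
    freq = np.where(n_obs > 0, sums / (2.0 * np.maximum(n_obs, 1)), np.nan)
    flip = freq > 0.5
    tie = freq == 0.5
    for j in np.flatnonzero(tie):
        if str(a2[j]) < str(a1[j]):
            flip[j] = True
    dosage = count_a1.copy()
    dosage[:, flip] = 2.0 - dosage[:, flip]
    a1[flip], a2[flip] = a2[flip].copy(), a1[flip].copy()
    return dosage, a1, a2


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def read_plink_text(ped_path: PathLike, map_path: PathLike) -> GenotypeMatrix:
    """Read a PLINK 1.9 PED/MAP pair into a :class:`GenotypeMatrix`.

    ``0 0`` allele pairs become missing; the minor allele is determined from
    observed frequency (ties broken lexicographically) and dosage counts it.
    """
    snp_ids, chrom, pos = [], [], []
    with open(map_path) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise FormatError(f"MAP line with {len(parts)} fields: {line!r}")
            chrom.append(parts[0])
            snp_ids.append(parts[1])
            pos.append(int(parts[3]))
    m = len(snp_ids)
    animal_ids = []
    rows = []
    pairs = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"PED line {lineno}: expected {6 + 2 * m} fields, got {len(parts)}"
                )
            animal_ids.append(parts[1])
            al = parts[6:]
            row = np.empty(m, dtype=float)
            prow = []
            for j in range(m):
                a, b = al[2 * j], al[2 * j + 1]
                for x in (a, b):
                    if x not in _VALID_ALLELES:
                        raise FormatError(
                            f"PED line {lineno}, SNP {snp_ids[j]}: invalid allele {x!r}"
                        )
                if a == "0" and b == "0":
                    row[j] = np.nan
                elif a == "0" or b == "0":
                    raise FormatError(
                        f"PED line {lineno}, SNP {snp_ids[j]}: half-missing pair {a} {b}"
                    )
                else:
                    row[j] = np.nan  # filled after allele census
                prow.append((a, b))
            rows.append(row)
            pairs.append(prow)
    n = len(animal_ids)
    # census alleles per SNP, then count the first-seen allele
    a1 = np.array(["0"] * m, dtype=object)
    a2 = np.array(["0"] * m, dtype=object)
    for j in range(m):
        seen: list[str] = []
        for i in range(n):
            for x in pairs[i][j]:
                if x != "0" and x not in seen:
                    seen.append(x)
        if len(seen) > 2:
            raise FormatError(f"SNP {snp_ids[j]}: more than two alleles observed")
        if seen:
            a1[j] = seen[0]
        if len(seen) > 1:
            a2[j] = seen[1]
    count_a1 = np.full((n, m), np.nan)
    for i in range(n):
        for j in range(m):
            a, b = pairs[i][j]
            if a == "0":
                continue
            count_a1[i, j] = (a == a1[j]) + (b == a1[j])
    dosage, amin, amaj = _orient_minor(count_a1, a1, a2)
    return GenotypeMatrix(animal_ids, snp_ids, chrom, pos, amin, amaj, dosage)


def write_plink_text(gm: GenotypeMatrix, ped_path: PathLike, map_path: PathLike) -> None:
    with open(map_path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(f"{gm.chromosome[j]}\t{gm.snp_ids[j]}\t0\t{gm.position_bp[j]}\n")
    with open(ped_path, "w") as fh:
        for i, animal in enumerate(gm.animal_ids):
            fields = [animal, animal, "0", "0", "0", "-9"]
            for j in range(gm.n_snps):
                d = gm.dosage[i, j]
                mi, ma = str(gm.allele_minor[j]), str(gm.allele_major[j])
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [mi, mi]
                elif d == 1:
                    fields += [mi, ma]
                elif d == 0:
                    fields += [ma, ma]
                else:
                    raise FormatError(
                        f"non-integer dosage {d} cannot be written as PED alleles"
                    )
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM)
# ---------------------------------------------------------------------------

def read_plink_binary(
    bed_path: PathLike, bim_path: PathLike, fam_path: PathLike
) -> GenotypeMatrix:
    """Read PLINK 1.9 binary genotypes (SNP-major only).

    2-bit codes per the PLINK spec: 00 = homozygous A1 (dosage 2 of A1),
    01 = missing, 10 = heterozygous, 11 = homozygous A2. A1 counts are then
    re-oriented to the observed minor allele, so the result equals
    :func:`read_plink_text` on the same cohort.
    """
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "pos", "a1", "a2"], dtype=str,
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"bad BED magic bytes {raw[:2]!r}; not a PLINK BED file")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError("sample-major BED files are not supported")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw[3:], dtype=np.uint8)
    if payload.size != bytes_per_snp * m:
        raise FormatError(
            f"BED payload size mismatch: {payload.size} bytes for "
            f"{m} SNPs x {n} samples (expected {bytes_per_snp * m})"
        )
    codes = payload.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, sample-fastest within byte (little-endian pairs)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    expanded = expanded.reshape(m, bytes_per_snp * 4)[:, :n]
    lut = np.array([2.0, np.nan, 1.0, 0.0])  # code -> count of A1
    count_a1 = lut[expanded].T  # (n, m)
    dosage, amin, amaj = _orient_minor(
        count_a1, bim["a1"].to_numpy(dtype=object), bim["a2"].to_numpy(dtype=object)
    )
    return GenotypeMatrix(
        fam["iid"].tolist(), bim["snp"].tolist(), bim["chrom"].to_numpy(dtype=object),
        bim["pos"].astype(np.int64).to_numpy(), amin, amaj, dosage,
    )


def write_plink_binary(
    gm: GenotypeMatrix, bed_path: PathLike, bim_path: PathLike, fam_path: PathLike
) -> None:
    with open(bim_path, "w") as fh:
        for j in range(gm.n_snps):
            fh.write(
                f"{gm.chromosome[j]}\t{gm.snp_ids[j]}\t0\t{gm.position_bp[j]}"
                f"\t{gm.allele_minor[j]}\t{gm.allele_major[j]}\n"
            )
    with open(fam_path, "w") as fh:
        for animal in gm.animal_ids:
            fh.write(f"{animal} {animal} 0 0 0 -9\n")
    n, m = gm.n_animals, gm.n_snps
    code = np.empty((m, n), dtype=np.uint8)
    d = gm.dosage.T
    code[d == 2] = 0b00
    code[d == 1] = 0b10
    code[d == 0] = 0b11
    code[np.isnan(d)] = 0b01
    if not np.isin(d[~np.isnan(d)], [0, 1, 2]).all():
        raise FormatError("non-integer dosages cannot be written to BED")
    pad = (-n) % 4
    if pad:  # trailing bits in the last byte of each SNP are zero-padded
        code = np.concatenate([code, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    packed = (
        code.reshape(m, -1, 4) << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2).astype(np.uint8)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Pedigree / phenotype CSV
# ---------------------------------------------------------------------------

def read_pedigree_csv(path: PathLike) -> Pedigree:
    """Headered CSV (animal, sire, dam, sex[, generation]); 0 = unknown.

    Rows may be in any order; a topological sort is applied.
    """
    df = pd.read_csv(path, dtype=str)
    cols = [c.lower() for c in df.columns]
    df.columns = cols
    required = ["animal", "sire", "dam", "sex"]
    for c in required:
        if c not in cols:
            raise FormatError(f"pedigree CSV missing column {c!r}")
    fields = required + (["generation"] if "generation" in cols else [])
    return Pedigree.from_tuples(df[fields].itertuples(index=False, name=None))


def write_pedigree_csv(pedigree: Pedigree, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("animal,sire,dam,sex,generation\n")
        for r in pedigree.records:
            fh.write(
                f"{r.animal_id},{r.sire_id or 0},{r.dam_id or 0},"
                f"{r.sex},{r.generation}\n"
            )


def read_phenotypes_csv(path: PathLike) -> pd.DataFrame:
    """Phenotype table: animal_id, trait columns, sex, measurement_date, age."""
    df = pd.read_csv(path, dtype={"animal_id": str})
    if "animal_id" not in df.columns:
        raise FormatError("phenotype CSV missing 'animal_id' column")
    if df["animal_id"].duplicated().any():
        raise IntegrityError("duplicate animal_id rows in phenotype CSV")
    return df


def write_phenotypes_csv(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Gene BED and GWAS TSV
# ---------------------------------------------------------------------------

def read_gene_bed(path: PathLike) -> pd.DataFrame:
    """4+-column BED of gene spans -> table with 1-based inclusive coords.

    Columns: gene_id, chromosome, start_bp, end_bp, name. The BED 'chr'
    prefix, if present, is stripped so labels match PLINK chromosome codes.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith(("#", "track", "browser")):
                continue
            if len(parts) < 4:
                raise FormatError(f"gene BED line {lineno}: fewer than 4 columns")
            chrom = parts[0][3:] if parts[0].lower().startswith("chr") else parts[0]
            start0, end0 = int(parts[1]), int(parts[2])
            if start0 >= end0:
                raise FormatError(f"gene BED line {lineno}: empty/negative interval")
            name = parts[3]
            rows.append((name, chrom, start0 + 1, end0, name))
    df = pd.DataFrame(rows, columns=["gene_id", "chromosome", "start_bp", "end_bp", "name"])
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise IntegrityError(f"duplicate gene_id in gene table: {dups}")
    return df


def write_gwas_tsv(table, path: PathLike) -> None:
    """Write per-SNP association results, GEMMA `.assoc.txt`-compatible.

    Accepts a :class:`canineqg.gwas.GwasTable` or its DataFrame.
    """
    df = table.snps if hasattr(table, "snps") else table
    out = pd.DataFrame(
        {
            "chr": df["chromosome"],
            "rs": df["snp_id"],
            "ps": df["position_bp"],
            "allele1": df["allele_minor"],
            "allele0": df["allele_major"],
            "af": df["maf"],
            "beta": df["beta"],
            "se": df["se_beta"],
            "p_wald": df["p_wald"],
        }
    )
    out.to_csv(path, sep="\t", index=False)
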