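"""PLINK binary (.bed/.bim/.fam) and GCTA GRM binary I/O.

The .bed format is PLINK 1 binary, SNP-major: after the three magic bytes
``0x6C 0x1B 0x01`` each SNP occupies ``ceil(n_samples / 4)`` bytes, two bits
per sample, least-significant pair first:

====  =========================
bits  genotype
====  =========================
00    homozygous A1 (dosage 2)
01    missing
10    heterozygous (dosage 1)
11    homozygous A2 (dosage 0)
====  =========================

Dosages here count copies of the A1 allele; missing is stored as -1.

The GCTA GRM binary triple is ``<prefix>.grm.bin`` (float32, lower triangle
including the diagonal, row-major), ``<prefix>.grm.N.bin`` (float32 marker
counts, same layout) and ``<prefix>.grm.id`` (two-column text: FID IID).
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .exceptions import DataError

BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# dosage -> 2-bit code and back
_DOSAGE_TO_CODE = {2: 0b00, -1: 0b01, 1: 0b10, 0: 0b11}
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)


def write_bed(path: str, dosages: np.ndarray) -> None:
    """Write an (n_samples, n_snps) dosage matrix (int, -1 = missing)."""
    d = np.asarray(dosages)
    if d.ndim != 2:
        raise DataError("dosage matrix must be 2-D (samples x SNPs)")
    n, m = d.shape
    codes = np.empty((m, n), dtype=np.uint8)
    dt = d.T
    codes[dt == 2] = 0b00
    codes[dt == -1] = 0b01
    codes[dt == 1] = 0b10
    codes[dt == 0] = 0b11
    n_bytes = (n + 3) // 4
    padded = np.full((m, n_bytes * 4), 0b01, dtype=np.uint8)  # pad = missing
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(path, "wb") as fh:
        fh.write(BED_MAGIC)
        fh.write(packed.tobytes())


def read_bed(path: str, n_samples: int, n_snps: int) -> np.ndarray:
    """Read a SNP-major .bed file back into (n_samples, n_snps) int8 dosages."""
    with open(path, "rb") as fh:
        magic = fh.read(3)
        if magic != BED_MAGIC:
            raise DataError(f"{path}: not a SNP-major PLINK .bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n_samples + 3) // 4
    if raw.size != n_bytes * n_snps:
        raise DataError(f"{path}: size does not match {n_samples} samples x {n_snps} SNPs")
    raw = raw.reshape(n_snps, n_bytes)
    codes = np.empty((n_snps, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = raw & 0b11
    codes[:, 1::4] = (raw >> 2) & 0b11
    codes[:, 2::4] = (raw >> 4) & 0b11
    codes[:, 3::4] = (raw >> 6) & 0b11
    return _CODE_TO_DOSAGE[codes[:, :n_samples]].T.copy()


def write_bim(path: str, snp_meta: pd.DataFrame) -> None:
    out = pd.DataFrame(
        {
            "chrom": snp_meta["chrom"],
            "snp_id": snp_meta["snp_id"],
            "cm": 0,
            "pos": snp_meta["pos"],
            "a1": snp_meta["a1"],
            "a2": snp_meta["a2"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"snp_id": str, "a1": str, "a2": str},
    )
    return bim.drop(columns=["cm"])


def write_fam(path: str, sample_ids, sex) -> None:
    sex_code = np.where(np.asarray(sex) == "male", 1, 2)
    out = pd.DataFrame(
        {
            "fid": sample_ids,
            "iid": sample_ids,
            "father": 0,
            "mother": 0,
            "sex": sex_code,
            "pheno": -9,
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)


def read_fam(path: str) -> pd.DataFrame:
    fam = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"fid": str, "iid": str},
    )
    fam["sex"] = np.where(fam["sex"] == 1, "male", "female")
    return fam


def write_grm(prefix: str, A: np.ndarray, sample_ids, n_markers: int) -> None:
    """Write a GRM as the GCTA binary triple (grm.bin / grm.N.bin / grm.id)."""
    n = A.shape[0]
    tril = np.tril_indices(n)
    A[tril].astype(np.float32).tofile(prefix + ".grm.bin")
    np.full(tril[0].size, n_markers, dtype=np.float32).tofile(prefix + ".grm.N.bin")
    pd.DataFrame({"fid": sample_ids, "iid": sample_ids}).to_csv(
        prefix + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix: str):
    """Read a GCTA binary GRM triple; returns (A, sample_ids, n_markers)."""
    ids = pd.read_csv(prefix + ".grm.id", sep=r"\s+", header=None, dtype=str)
    sample_ids = ids.iloc[:, 1].to_numpy()
    n = len(sample_ids)
    vals = np.fromfile(prefix + ".grm.bin", dtype=np.float32).astype(np.float64)
    if vals.size != n * (n + 1) // 2:
        raise DataError(f"{prefix}.grm.bin does not match {n} ids")
    A = np.zeros((n, n))
    tril = np.tril_indices(n)
    A[tril] = vals
    A = A + A.T - np.diag(np.diag(A))
    nbin = np.fromfile(prefix + ".grm.N.bin", dtype=np.float32)
    n_markers = int(round(float(nbin[0]))) if nbin.size else 0
    return A, sample_ids, n_markers


def _check_writable(path: str) -> None:
    parent = os.path.dirname(os.path.abspath(path))
    if not os.path.isdir(parent):
        raise DataError(f"directory does not exist: {parent}")
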