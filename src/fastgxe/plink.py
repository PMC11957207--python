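"""Minimal PLINK 1 binary (bed/bim/fam) reader and writer.

Only the SNP-major layout is supported (the only layout modern PLINK
writes).  Dosages count the A1 allele: the 2-bit codes 00/10/11 map to
2/1/0 and 01 marks a missing genotype (NaN).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = 0x01

# 2-bit code -> A1 dosage
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


class PlinkFormatError(ValueError):
    """Malformed bed/bim/fam input."""


def read_bim(path: str | Path) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "snp": str, "a1": str, "a2": str})
    bim["pos"] = bim["pos"].astype(np.int64)  # 1-based physical positions
    return bim


def read_fam(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                       dtype={"fid": str, "iid": str})


def read_plink(prefix: str | Path):
    """Read a bed/bim/fam triple.

    Returns ``(dosages, bim, fam)`` with ``dosages`` an (n_samples,
    n_snps) float array of A1-allele counts (NaN = missing).
    """
    prefix = str(prefix)
    bim = read_bim(prefix + ".bim")
    fam = read_fam(prefix + ".fam")
    n, m = len(fam), len(bim)
    raw = Path(prefix + ".bed").read_bytes()
    if raw[:2] != MAGIC:
        raise PlinkFormatError(
            f"bad magic bytes at offset 0: {raw[:2].hex()} != {MAGIC.hex()}")
    if raw[2] != SNP_MAJOR:
        raise PlinkFormatError(
            f"unsupported mode byte {raw[2]:#04x} at offset 2 "
            "(only SNP-major supported)")
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"bed size {len(raw)} != expected {expected} bytes "
            f"(truncated at offset {len(raw)})")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3)
    data = data.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, low bits first within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    return _CODE_TO_DOSAGE[codes].T.copy(), bim, fam


def write_plink(prefix: str | Path, dosages: np.ndarray,
                bim: pd.DataFrame | None = None,
                fam: pd.DataFrame | None = None) -> None:
    """Write dosages (n x m A1-allele counts, NaN missing) as bed/bim/fam."""
    prefix = str(prefix)
    dosages = np.asarray(dosages, dtype=np.float64)
    n, m = dosages.shape
    if bim is None:
        bim = pd.DataFrame({
            "chrom": np.ones(m, dtype=int).astype(str),
            "snp": [f"snp{i}" for i in range(m)],
            "cm": 0, "pos": np.arange(1, m + 1),
            "a1": "A", "a2": "B"})
    if fam is None:
        fam = pd.DataFrame({
            "fid": [f"s{i}" for i in range(n)],
            "iid": [f"s{i}" for i in range(n)],
            "father": "0", "mother": "0", "sex": 0, "phenotype": -9})
    if len(bim) != m or len(fam) != n:
        raise PlinkFormatError("bim/fam row counts do not match dosages")
    code = np.full(dosages.shape, 0b01, dtype=np.uint8)  # missing
    code[dosages == 2] = 0b00
    code[dosages == 1] = 0b10
    code[dosages == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b11, dtype=np.uint8)
    padded[:, :n] = code.T
    packed = (padded[:, 0::4] | (padded[:, 1::4] << 2)
              | (padded[:, 2::4] << 4) | (padded[:, 3::4] << 6))
    # padding samples must be zero bits per the format
    pad_start = n % 4
    if pad_start:
        mask = (1 << (2 * pad_start)) - 1
        packed[:, -1] &= mask
    with open(prefix + ".bed", "wb") as fh:
        fh.write(MAGIC)
        fh.write(bytes([SNP_MAJOR]))
        fh.write(packed.tobytes())
    bim[BIM_COLUMNS].to_csv(prefix + ".bim", sep="\t", header=False,
                            index=False)
    fam[FAM_COLUMNS].to_csv(prefix + ".fam", sep="\t", header=False,
                            index=False)
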