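"""PLINK 1 binary fileset (.bed/.bim/.fam) reading and writing.

Only the variant-major dialect is supported (mode byte ``0x01``). Each
variant occupies ``ceil(n_samples / 4)`` bytes; within a byte the lowest two
bits belong to the first sample. The 2-bit codes map to allele1 counts as

====  =====================  ======
code  genotype               dosage
====  =====================  ======
0b00  homozygous allele1     2
0b01  missing                -1
0b10  heterozygous           1
0b11  homozygous allele2     0
====  =====================  ======

so that with allele1 written as the minor allele, dosage is the
minor-allele count — the convention the QC and association stages assume.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import VARIANT_COLUMNS, GenotypeBlock

__all__ = ["read_plink", "write_plink", "write_phenotype_table", "read_phenotype_table"]

_MAGIC = bytes((0x6C, 0x1B))
_VARIANT_MAJOR = 0x01

# code -> dosage and back
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, -1: 1, 1: 2, 0: 3}


class PlinkFormatError(ValueError):
    """Raised for malformed or unsupported .bed payloads."""


def _ext(prefix: Path, ext: str) -> Path:
    return prefix.parent / f"{prefix.name}.{ext}"


def read_plink(prefix: str | Path) -> GenotypeBlock:
    """Read a ``.bed/.bim/.fam`` fileset into a :class:`GenotypeBlock`.

    Sample and variant metadata are preserved in file order; file order is
    the authoritative ordering downstream.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        _ext(prefix, "bim"),
        sep="\t",
        header=None,
        names=VARIANT_COLUMNS,
        dtype={"chrom": str, "variant_id": str, "allele1": str, "allele2": str},
    )
    fam = pd.read_csv(
        _ext(prefix, "fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "sample_id": str},
    )
    n_samples, n_variants = len(fam), len(bim)
    raw = _ext(prefix, "bed").read_bytes()
    if len(raw) < 3 or raw[:2] != _MAGIC:
        raise PlinkFormatError("not a PLINK 1 .bed file (bad magic bytes)")
    if raw[2] != _VARIANT_MAJOR:
        raise PlinkFormatError(
            f"unsupported .bed mode byte 0x{raw[2]:02X}; only variant-major (0x01)"
        )
    bpv = (n_samples + 3) // 4
    if len(raw) != 3 + bpv * n_variants:
        raise PlinkFormatError(
            f".bed payload is {len(raw) - 3} bytes, expected {bpv * n_variants}"
        )
    body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(n_variants, bpv)
    # unpack 2-bit codes, lowest bits first within each byte
    codes = (body[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 0b11
    codes = codes.reshape(n_variants, bpv * 4)[:, :n_samples]
    dosages = _CODE_TO_DOSAGE[codes].T  # samples x variants
    samples = fam[["sample_id", "fid"]].copy()
    return GenotypeBlock(np.ascontiguousarray(dosages), bim, samples)


def write_plink(block: GenotypeBlock, prefix: str | Path) -> None:
    """Write a :class:`GenotypeBlock` as a variant-major PLINK 1 fileset.

    Variant ids must be unique; dosages are written as allele1 counts.
    """
    prefix = Path(prefix)
    if block.variants["variant_id"].duplicated().any():
        dup = block.variants["variant_id"][block.variants["variant_id"].duplicated()]
        raise ValueError(f"duplicate variant ids: {sorted(set(dup))[:5]!r}")
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n_samples, n_variants = block.dosages.shape
    bpv = (n_samples + 3) // 4
    codes = np.empty((n_variants, bpv * 4), dtype=np.uint8)
    codes[:] = 0  # padding bits are zero
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, code in _DOSAGE_TO_CODE.items():
        lut[dosage % 4] = code  # -1 -> index 3
    codes[:, :n_samples] = lut[block.dosages.T % 4]
    packed = (
        codes.reshape(n_variants, bpv, 4)
        << np.array([0, 2, 4, 6], dtype=np.uint8)
    ).sum(axis=2, dtype=np.uint8) if n_variants else np.empty((0, bpv), np.uint8)
    with open(_ext(prefix, "bed"), "wb") as fh:
        fh.write(_MAGIC)
        fh.write(bytes([_VARIANT_MAJOR]))
        fh.write(packed.tobytes())
    block.variants[VARIANT_COLUMNS].to_csv(
        _ext(prefix, "bim"), sep="\t", header=False, index=False
    )
    fam = pd.DataFrame(
        {
            "fid": block.samples.get("fid", block.samples["sample_id"]),
            "sample_id": block.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": 0,
            "phenotype": -9,
        }
    )
    fam.to_csv(_ext(prefix, "fam"), sep="\t", header=False, index=False)


def write_phenotype_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write the per-sample phenotype/covariate/label table as TSV."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, sep="\t", index=False)


def read_phenotype_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str, "node_id": str})
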