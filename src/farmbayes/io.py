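"""Readers/writers: PLINK .bed/.bim/.fam, TSV dosages, phenotype CSV, config.

PLINK binary genotypes are the SNP-major 2-bit format (magic bytes
0x6c 0x1b 0x01): per marker, ceil(n/4) bytes, individuals packed from the
low bits, codes 00 = homozygous A1, 10 = heterozygous, 11 = homozygous A2,
01 = missing.  Dosages count copies of the .bim A1 allele.  Missing
genotypes are mean-imputed (rounded to the nearest dosage) with a logged
count, or rejected above a configurable missing rate.

Every table this package writes starts with '# key: value' header comments
carrying the config hash and master seed, so a run is reconstructible from
its outputs; the readers here skip such comments.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_plink",
    "write_plink",
    "read_tsv_dosage",
    "write_tsv_dosage",
    "read_phenotypes",
    "load_config",
    "config_hash",
    "write_table",
]

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit code -> A1 dosage (code 1 = missing)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0, 1: 2, 0: 3, -1: 1}


# ---------------------------------------------------------------------- #
# PLINK triplet
# ---------------------------------------------------------------------- #
def read_plink(prefix, max_missing_rate: float = 0.1) -> GenotypeMatrix:
    """Read a .bed/.bim/.fam triplet into a GenotypeMatrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "marker_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    n, m = len(fam), len(bim)
    raw = prefix.with_suffix(".bed").read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(
            f"bad .bed magic bytes {raw[:3].hex()} (expected {_BED_MAGIC.hex()}, SNP-major)"
        )
    bytes_per_snp = (n + 3) // 4
    expected = 3 + bytes_per_snp * m
    if len(raw) != expected:
        raise ValueError(
            f".bed is {len(raw)} bytes, expected {expected} "
            f"({expected - len(raw)} bytes short)" if len(raw) < expected
            else f".bed is {len(raw)} bytes, expected {expected}"
        )
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    # unpack 2-bit codes, low bits first
    codes = np.stack([(data >> s) & 0b11 for s in (0, 2, 4, 6)], axis=2)
    codes = codes.reshape(m, -1)[:, :n]                   # (m, n)
    dosages = _CODE_TO_DOSAGE[codes].T.astype(np.float64)  # (n, m)

    missing = dosages < 0
    n_missing = int(missing.sum())
    if n_missing:
        rate = missing.mean()
        if rate > max_missing_rate:
            raise ValueError(f"missing-genotype rate {rate:.3f} exceeds {max_missing_rate}")
        col_means = np.where(
            missing.all(axis=0), 1.0,
            np.nanmean(np.where(missing, np.nan, dosages), axis=0),
        )
        fill = np.clip(np.rint(col_means), 0, 2)
        dosages = np.where(missing, fill[None, :], dosages)
        logger.info("mean-imputed %d missing genotypes", n_missing)

    return GenotypeMatrix.from_dosages(
        dosages.astype(np.int8),
        marker_ids=bim["marker_id"].to_numpy(),
        chrom=bim["chrom"].to_numpy(),
        pos=bim["pos"].to_numpy(),
        animal_ids=fam["iid"].astype(str).to_numpy(),
    )


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a .bed/.bim/.fam triplet (SNP-major)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n_animals, G.n_markers
    bim = pd.DataFrame(
        {"chrom": G.chrom, "marker_id": G.marker_ids, "cm": 0,
         "pos": G.pos, "a1": "A", "a2": "B"}
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {"fid": G.animal_ids, "iid": G.animal_ids, "father": 0, "mother": 0,
         "sex": 0, "pheno": -9}
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    codes = np.empty((m, n), dtype=np.uint8)
    for d, c in _DOSAGE_TO_CODE.items():
        codes[G.dosages.T == d] = c
    pad = (-n) % 4
    if pad:
        codes = np.column_stack([codes, np.zeros((m, pad), dtype=np.uint8)])
    quads = codes.reshape(m, -1, 4)
    packed = (
        quads[:, :, 0] | (quads[:, :, 1] << 2) | (quads[:, :, 2] << 4) | (quads[:, :, 3] << 6)
    ).astype(np.uint8)
    prefix.with_suffix(".bed").write_bytes(_BED_MAGIC + packed.tobytes())


# ---------------------------------------------------------------------- #
# TSV dosage matrix
# ---------------------------------------------------------------------- #
def write_tsv_dosage(G: GenotypeMatrix, path) -> None:
    """Animals x markers dosage TSV; first column animal_id, headers marker ids."""
    df = pd.DataFrame(G.dosages, columns=G.marker_ids)
    df.insert(0, "animal_id", G.animal_ids)
    df.to_csv(path, sep="\t", index=False)


def read_tsv_dosage(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", comment="#")
    if "animal_id" not in df.columns:
        raise ValueError("dosage TSV must have an 'animal_id' first column")
    animal_ids = df["animal_id"].astype(str).to_numpy()
    mat = df.drop(columns="animal_id")
    return GenotypeMatrix.from_dosages(
        mat.to_numpy(dtype=np.int8),
        marker_ids=mat.columns.to_numpy(),
        animal_ids=animal_ids,
    )


def read_genotypes(path, fmt: str = "auto") -> GenotypeMatrix:
    """Dispatch on format: 'plink_bed' (triplet prefix) or 'tsv_dosage'."""
    path = Path(path)
    if fmt == "auto":
        fmt = "plink_bed" if path.with_suffix(".bed").exists() else "tsv_dosage"
    if fmt == "plink_bed":
        return read_plink(path)
    if fmt == "tsv_dosage":
        return read_tsv_dosage(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def write_genotypes(G: GenotypeMatrix, path, fmt: str = "tsv_dosage") -> None:
    if fmt == "plink_bed":
        write_plink(G, path)
    elif fmt == "tsv_dosage":
        write_tsv_dosage(G, path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}")


# ---------------------------------------------------------------------- #
# phenotypes / tables / config
# ---------------------------------------------------------------------- #
def read_phenotypes(path, required=("cow_id", "adjusted_mean")) -> pd.DataFrame:
    """Typed adjusted-phenotype table; duplicate cows and bad values rejected."""
    df = pd.read_csv(path, comment="#")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file missing columns: {missing}")
    dup = df["cow_id"].duplicated()
    if dup.any():
        raise ValueError(f"duplicate cow ids: {df.loc[dup, 'cow_id'].tolist()[:5]}")
    vals = pd.to_numeric(df["adjusted_mean"], errors="coerce")
    if vals.isna().any():
        row = int(np.flatnonzero(vals.isna())[0])
        raise ValueError(f"non-numeric adjusted_mean at data row {row}")
    df["adjusted_mean"] = vals
    return df


def config_hash(params: dict) -> str:
    """Short stable hash of a parameter mapping (for output provenance)."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path, allowed_keys=None) -> dict:
    """YAML config; unknown keys are rejected so typos cannot pass silently."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config file must contain a mapping")
    if allowed_keys is not None:
        unknown = set(cfg) - set(allowed_keys)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return cfg


def write_table(df: pd.DataFrame, path, meta: dict | None = None, sep: str = ",") -> None:
    """CSV/TSV with '# key: value' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep=sep, index=False)
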