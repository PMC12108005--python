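"""Reading and writing the packed-ASCII EIGENSTRAT triplet (geno/snp/ind).

The geno file holds one row per locus and one character per sample from the
alphabet ``{0, 1, 2, 9}`` (9 = missing).  The snp file is whitespace
delimited: locus id, chromosome, genetic position, physical position and the
two alleles; it is carried as opaque metadata.  The ind file holds sample id,
sex, and a group label.  Only this tabular dialect is supported (the binary
PACKEDANCESTRYMAP variant is not).
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, FormatError
from .panel import GenotypePanel, infer_ploidy

_SNP_COLUMNS = ["chrom", "genetic_pos", "physical_pos", "allele1", "allele2"]

# geno characters decode via byte arithmetic: '0' -> 0 ... '9' -> 9
_VALID_BYTES = frozenset(b"0129")


def read_panel(
    geno_path: str | os.PathLike,
    snp_path: str | os.PathLike,
    ind_path: str | os.PathLike,
    ploidy: np.ndarray | str = "infer",
) -> GenotypePanel:
    """Parse an EIGENSTRAT triplet into a :class:`GenotypePanel`.

    Locus order follows the snp file; sample order follows the ind file.
    ``ploidy`` may be an explicit per-sample array of modes, overriding the
    default inference (pseudo-haploid iff no heterozygous call observed).

    Raises
    ------
    FormatError
        Ragged geno rows or characters outside ``{0,1,2,9}``.
    ConsistencyError
        Row/column counts disagreeing with the snp/ind files.
    """
    ind = _read_ind(ind_path)
    snp = _read_snp(snp_path)
    n_samples = len(ind)

    raw = Path(geno_path).read_bytes()
    lines = raw.splitlines()
    widths = {len(ln) for ln in lines}
    if lines and widths != {n_samples}:
        if len(widths) > 1:
            raise FormatError(f"ragged geno rows: widths {sorted(widths)}")
        raise ConsistencyError(
            f"geno rows have {widths.pop()} columns but ind file lists "
            f"{n_samples} samples"
        )
    if len(lines) != len(snp):
        raise ConsistencyError(
            f"geno has {len(lines)} rows but snp file lists {len(snp)} loci"
        )

    flat = np.frombuffer(b"".join(lines), dtype=np.uint8)
    bad = ~np.isin(flat, np.frombuffer(b"0129", dtype=np.uint8))
    if bad.any():
        ch = chr(int(flat[bad][0]))
        raise FormatError(f"genotype character {ch!r} outside {{0,1,2,9}}")
    genotypes = (flat - ord("0")).astype(np.int8).reshape(len(lines), n_samples)

    if isinstance(ploidy, str):
        if ploidy != "infer":
            raise ValueError(f"unknown ploidy policy {ploidy!r}")
        modes = infer_ploidy(genotypes)
    else:
        modes = np.asarray(ploidy, dtype=object)

    return GenotypePanel(
        genotypes=genotypes,
        locus_ids=snp.index.to_numpy(dtype=object),
        sample_ids=ind.index.to_numpy(dtype=object),
        sample_labels=ind["group"].to_numpy(dtype=object),
        ploidy_mode=modes,
        snp_meta=snp,
    )


def write_panel(
    panel: GenotypePanel,
    geno_path: str | os.PathLike,
    snp_path: str | os.PathLike,
    ind_path: str | os.PathLike,
) -> None:
    """Write a panel as an EIGENSTRAT triplet; bit-exact round-trip for geno.

    Missing genotypes are written as ``9``.  When the panel lacks snp
    metadata, placeholder columns (chromosome 1, unit-spaced physical
    positions, alleles A/G) are emitted.
    """
    panel.validate()
    chars = (panel.genotypes + ord("0")).astype(np.uint8)
    with open(geno_path, "wb") as fh:
        for row in chars:
            fh.write(row.tobytes())
            fh.write(b"\n")

    snp = panel.snp_meta
    if snp is None:
        snp = default_snp_meta(panel.locus_ids)
    with open(snp_path, "w") as fh:
        for locus_id, row in snp.iterrows():
            fh.write(
                f"{locus_id}\t{row['chrom']}\t{row['genetic_pos']}\t"
                f"{row['physical_pos']}\t{row['allele1']}\t{row['allele2']}\n"
            )

    labels = panel.sample_labels
    if labels is None:
        labels = np.full(panel.n_samples, "Unknown", dtype=object)
    with open(ind_path, "w") as fh:
        for sid, grp in zip(panel.sample_ids, labels):
            fh.write(f"{sid}\tU\t{grp}\n")


def default_snp_meta(locus_ids: np.ndarray) -> pd.DataFrame:
    """Placeholder snp metadata (1-based physical positions on chromosome 1)."""
    n = len(locus_ids)
    return pd.DataFrame(
        {
            "chrom": np.ones(n, dtype=int),
            "genetic_pos": np.zeros(n),
            "physical_pos": np.arange(1, n + 1),
            "allele1": np.full(n, "A", dtype=object),
            "allele2": np.full(n, "G", dtype=object),
        },
        index=pd.Index(np.asarray(locus_ids, dtype=object), name="locus_id"),
    )


def _read_snp(path: str | os.PathLike) -> pd.DataFrame:
    try:
        snp = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["locus_id"] + _SNP_COLUMNS,
            dtype={"locus_id": str, "allele1": str, "allele2": str},
            index_col="locus_id",
        )
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=_SNP_COLUMNS, index=pd.Index([], name="locus_id"))
    if snp.index.has_duplicates:
        raise FormatError("duplicate locus ids in snp file")
    return snp


def _read_ind(path: str | os.PathLike) -> pd.DataFrame:
    try:
        ind = pd.read_csv(
            path,
            sep=r"\s+",
            header=None,
            names=["sample_id", "sex", "group"],
            dtype=str,
            index_col="sample_id",
        )
    except pd.errors.EmptyDataError:
        raise FormatError("empty ind file") from None
    if ind.index.has_duplicates:
        raise FormatError("duplicate sample ids in ind file")
    return ind
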