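"""Genotype I/O, quality control, standardization and window construction.

Genotypes are held as hard-call allele counts of the A1 allele (the first
allele column of the .bim file), with missing calls stored as ``MISSING``
(-1) in an int8 matrix of shape (n_samples, n_variants).

Coordinate conventions: .bim positions are 1-based; windows and BED
annotations use 0-based half-open intervals. A variant at 1-based position
``p`` falls in fixed window ``(p - 1) // size``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

MISSING = np.int8(-1)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # v1.x SNP-major

# 2-bit codes (per variant byte-stream, 4 samples/byte, LSB first):
#   00 -> hom A1 (dosage 2), 01 -> missing, 10 -> het (1), 11 -> hom A2 (0)
_CODE_TO_DOSAGE = np.array([2, -1, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, 1: 0b10, 0: 0b11, -1: 0b01}


class PlinkFormatError(ValueError):
    """Raised when a bed/bim/fam triplet is malformed or inconsistent."""


@dataclass
class GenotypeDataset:
    """Hard-call dosages plus per-variant and per-sample metadata.

    Attributes
    ----------
    dosages : int8 ndarray, shape (N, M)
        A1-allele counts in {0, 1, 2}; missing entries are ``MISSING``.
    variants : DataFrame
        Columns chrom, pos, id, allele_a, allele_b, maf, missing_rate;
        sorted by (chrom, pos). ``pos`` is 1-based.
    samples : list of str
        Individual IDs, in row order of ``dosages``.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    samples: list[str]

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x variants)")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError(
                f"dosage matrix has {self.dosages.shape[1]} variants but the "
                f"variant table has {len(self.variants)}"
            )
        if self.dosages.shape[0] != len(self.samples):
            raise ValueError("sample count mismatch between dosages and IDs")
        if not {"maf", "missing_rate"}.issubset(self.variants.columns):
            self.variants = compute_variant_stats(self.dosages, self.variants)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, index: np.ndarray) -> "GenotypeDataset":
        """Column subset keeping the variant table aligned."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.dosages[:, index],
            self.variants.iloc[index].reset_index(drop=True),
            list(self.samples),
        )


@dataclass(frozen=True)
class Window:
    """A tested SNP set: a genomic interval plus member variant indices.

    ``start``/``end`` are 0-based half-open; ``variant_indices`` index into
    the owning :class:`GenotypeDataset`.
    """

    chrom: str
    start: int
    end: int
    variant_indices: tuple[int, ...]
    label: str

    @property
    def n_snps(self) -> int:
        return len(self.variant_indices)


@dataclass
class WindowSet:
    """Ordered collection of windows (sorted by chrom then start)."""

    windows: list[Window] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.windows)

    def __iter__(self) -> Iterator[Window]:
        return iter(self.windows)

    def __getitem__(self, i: int) -> Window:
        return self.windows[i]

    def neighbors(self, i: int, flank: int) -> list[int]:
        """Indices of the target window plus up to ``flank`` same-chromosome
        neighbours on each side (clipped at chromosome ends)."""
        chrom = self.windows[i].chrom
        out = []
        for j in range(i - flank, i + flank + 1):
            if 0 <= j < len(self.windows) and self.windows[j].chrom == chrom:
                out.append(j)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "chrom": w.chrom,
                    "start": w.start,
                    "end": w.end,
                    "n_snps": w.n_snps,
                    "label": w.label,
                }
                for w in self.windows
            ]
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def compute_variant_stats(dosages: np.ndarray, variants: pd.DataFrame) -> pd.DataFrame:
    """Attach maf and missing_rate columns computed from the dosage matrix."""
    dos = np.asarray(dosages)
    miss = dos == MISSING
    n_obs = (~miss).sum(axis=0)
    with np.errstate(invalid="ignore"):
        freq_a = np.where(
            n_obs > 0,
            np.where(miss, 0, dos).sum(axis=0) / np.maximum(2 * n_obs, 1),
            np.nan,
        )
    maf = np.minimum(freq_a, 1.0 - freq_a)
    variants = variants.copy()
    variants["maf"] = maf
    variants["missing_rate"] = miss.sum(axis=0) / dos.shape[0]
    return variants


# ---------------------------------------------------------------------------
# PLINK bed/bim/fam
# ---------------------------------------------------------------------------


def load_plink(prefix: str | Path) -> GenotypeDataset:
    """Read a PLINK v1 bed/bim/fam triplet into a :class:`GenotypeDataset`.

    Dosages count copies of the A1 allele (column 5 of the .bim). Missing
    genotypes are preserved as ``MISSING``. Variants are sorted by
    (chrom, pos); the bed columns are reordered accordingly.
    """
    prefix = Path(prefix)
    bim = _read_bim(prefix.with_suffix(".bim"))
    fam = _read_fam(prefix.with_suffix(".fam"))
    n, m = len(fam), len(bim)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: bad magic bytes {raw[:3]!r} "
            "(expected SNP-major PLINK v1 bed)"
        )
    bytes_per_variant = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != bytes_per_variant * m:
        raise PlinkFormatError(
            f"{prefix.with_suffix('.bed')}: {body.size} data bytes, expected "
            f"{bytes_per_variant * m} for N={n}, M={m}"
        )
    blocks = body.reshape(m, bytes_per_variant)
    # unpack 4 samples/byte, least-significant pair first
    codes = np.empty((m, bytes_per_variant * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosages = _CODE_TO_DOSAGE[codes[:, :n]].T  # (N, M)

    order = np.lexsort((bim["pos"].to_numpy(), bim["chrom"].to_numpy()))
    bim = bim.iloc[order].reset_index(drop=True)
    dosages = np.ascontiguousarray(dosages[:, order])
    variants = compute_variant_stats(dosages, bim)
    return GenotypeDataset(dosages, variants, list(fam["iid"]))


def write_plink(g: GenotypeDataset, prefix: str | Path) -> None:
    """Write a dataset as bed/bim/fam (SNP-major v1 bed)."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = g.n_samples, g.n_variants

    code = np.empty(g.dosages.shape, dtype=np.uint8)
    for dos, c in _DOSAGE_TO_CODE.items():
        code[g.dosages == dos] = c
    pad = (-n) % 4
    if pad:
        code = np.vstack([code, np.full((pad, m), 0b01, dtype=np.uint8)])
    codeT = code.T  # (M, N+pad)
    packed = (
        codeT[:, 0::4]
        | (codeT[:, 1::4] << 2)
        | (codeT[:, 2::4] << 4)
        | (codeT[:, 3::4] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())

    bim = g.variants
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for _, v in bim.iterrows():
            fh.write(
                f"{v['chrom']}\t{v['id']}\t0\t{int(v['pos'])}\t"
                f"{v['allele_a']}\t{v['allele_b']}\n"
            )
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for iid in g.samples:
            fh.write(f"{iid}\t{iid}\t0\t0\t0\t-9\n")


def _read_bim(path: Path) -> pd.DataFrame:
    bim = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chrom", "id", "cm", "pos", "allele_a", "allele_b"],
        dtype={"chrom": str, "id": str, "allele_a": str, "allele_b": str},
    )
    if bim["pos"].isna().any():
        raise PlinkFormatError(f"{path}: missing positions")
    return bim.drop(columns="cm")


def _read_fam(path: Path) -> pd.DataFrame:
    fam = pd.read_csv(path, sep=r"\s+", header=None, dtype=str)
    if fam.shape[1] < 2:
        raise PlinkFormatError(f"{path}: expected at least FID and IID columns")
    fam = fam.rename(columns={0: "fid", 1: "iid"})
    return fam[["fid", "iid"]]


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


def hwe_pvalues(dosages: np.ndarray) -> np.ndarray:
    """1-df chi-square goodness-of-fit p-value for Hardy-Weinberg
    proportions, per variant (missing calls are ignored)."""
    dos = np.asarray(dosages)
    obs = np.stack([(dos == k).sum(axis=0) for k in (0, 1, 2)]).astype(float)
    n = obs.sum(axis=0)
    p = (2 * obs[2] + obs[1]) / np.maximum(2 * n, 1)
    exp = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2]) * n
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / np.where(exp > 0, exp, 1), 0).sum(
            axis=0
        )
    # monomorphic variants fit HWE exactly
    chi2 = np.where(n > 0, chi2, 0.0)
    return stats.chi2.sf(chi2, df=1)


def qc_filter(
    g: GenotypeDataset,
    maf_min: float = 0.01,
    miss_max: float = 0.01,
    hwe_alpha: float = 1e-7,
    exclude_regions: Sequence[tuple[str, int, int]] = (),
) -> GenotypeDataset:
    """Variant QC: MAF >= maf_min, missingness <= miss_max, HWE
    goodness-of-fit p >= hwe_alpha, and outside every excluded region
    (0-based half-open (chrom, start, end) tuples, e.g. the MHC
    ("6", 25_000_000, 35_000_000))."""
    v = compute_variant_stats(g.dosages, g.variants)
    keep = (
        (v["maf"].to_numpy() >= maf_min)
        & (v["missing_rate"].to_numpy() <= miss_max)
        & (hwe_pvalues(g.dosages) >= hwe_alpha)
    )
    for chrom, start, end in exclude_regions:
        in_region = (
            (v["chrom"].to_numpy() == str(chrom))
            & (v["pos"].to_numpy() - 1 >= start)
            & (v["pos"].to_numpy() - 1 < end)
        )
        keep &= ~in_region
    if not keep.any():
        logger.warning("QC removed every variant; returning an empty dataset")
    return GenotypeDataset(g.dosages[:, keep], v.loc[keep].reset_index(drop=True), list(g.samples))


# ---------------------------------------------------------------------------
# Standardization
# ---------------------------------------------------------------------------


def standardize(g: GenotypeDataset, variant_indices: Sequence[int] | None = None) -> np.ndarray:
    """Mean-imputed, column-standardized dosages (mean 0, variance 1 with the
    1/N convention). Raises on zero-variance columns, naming the variant."""
    idx = (
        np.arange(g.n_variants)
        if variant_indices is None
        else np.asarray(variant_indices)
    )
    dos = g.dosages[:, idx].astype(np.float64)
    miss = dos == MISSING
    n_obs = (~miss).sum(axis=0)
    col_mean = np.where(miss, 0.0, dos).sum(axis=0) / np.maximum(n_obs, 1)
    dos = np.where(miss, col_mean, dos)
    mean = dos.mean(axis=0)
    dos -= mean
    var = (dos**2).mean(axis=0)
    bad = np.flatnonzero(var <= 0)
    if bad.size:
        names = g.variants["id"].iloc[idx[bad]].tolist()
        raise ValueError(f"zero-variance variant(s) after imputation: {names}")
    dos /= np.sqrt(var)
    return dos


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def make_fixed_windows(
    g: GenotypeDataset, size_bp: int = 100_000, min_snps: int = 3
) -> WindowSet:
    """Non-overlapping fixed-size windows [k*size, (k+1)*size) per
    chromosome; windows with fewer than ``min_snps`` members are dropped."""
    windows: list[Window] = []
    if g.n_variants == 0:
        return WindowSet(windows)
    chroms = g.variants["chrom"].to_numpy()
    pos = g.variants["pos"].to_numpy()
    bins = (pos - 1) // size_bp
    for chrom in pd.unique(chroms):
        on_chrom = np.flatnonzero(chroms == chrom)
        for b in np.unique(bins[on_chrom]):
            members = on_chrom[bins[on_chrom] == b]
            if members.size < min_snps:
                continue
            start = int(b) * size_bp
            windows.append(
                Window(
                    chrom=str(chrom),
                    start=start,
                    end=start + size_bp,
                    variant_indices=tuple(int(i) for i in members),
                    label=f"{chrom}:{start}-{start + size_bp}",
                )
            )
    return WindowSet(windows)


def read_bed_annotation(path: str | Path) -> pd.DataFrame:
    """Parse a BED file (0-based half-open) of gene intervals.

    Columns: chrom, start, end and optional name. Malformed lines raise with
    the 1-based line number.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line has {len(parts)} fields, need >=3")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as e:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from e
            if end < start:
                raise ValueError(f"{path}:{ln}: end < start")
            name = parts[3] if len(parts) > 3 else f"{parts[0]}:{start}-{end}"
            rows.append({"chrom": parts[0], "start": start, "end": end, "name": name})
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


def make_gene_windows(
    g: GenotypeDataset, annotation: pd.DataFrame | str | Path, min_snps: int = 3
) -> WindowSet:
    """One window per annotated gene, containing every variant whose 0-based
    position falls inside the interval. Genes with fewer than ``min_snps``
    variants, or on chromosomes absent from the dataset, are dropped.
    Overlapping genes yield overlapping windows.
    """
    if not isinstance(annotation, pd.DataFrame):
        annotation = read_bed_annotation(annotation)
    chroms = g.variants["chrom"].to_numpy()
    pos0 = g.variants["pos"].to_numpy() - 1
    present = set(chroms)
    windows: list[Window] = []
    for _, gene in annotation.iterrows():
        if gene["chrom"] not in present:
            logger.info("gene %s on chromosome %s absent from dataset; dropped",
                        gene["name"], gene["chrom"])
            continue
        members = np.flatnonzero(
            (chroms == gene["chrom"]) & (pos0 >= gene["start"]) & (pos0 < gene["end"])
        )
        if members.size < min_snps:
            continue
        windows.append(
            Window(
                chrom=str(gene["chrom"]),
                start=int(gene["start"]),
                end=int(gene["end"]),
                variant_indices=tuple(int(i) for i in members),
                label=str(gene["name"]),
            )
        )
    windows.sort(key=lambda w: (w.chrom, w.start))
    return WindowSet(windows)
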