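"""Biallelic SNP marker matrices: data model, file I/O, platform
intersection, random imputation, and marker QC.

Dosages are counts of the alternate allele, coded 0/1/2, with ``NaN``
for missing calls.  Centering and standardization are deliberately NOT
done here — relationship-matrix construction owns that step so that the
stored matrix always holds raw dosages.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "MarkerMatrix",
    "QCReport",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "intersect_platforms",
    "impute_random",
    "filter_markers",
]


class GenotypeParseError(ValueError):
    """Malformed genotype file; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclasses.dataclass
class MarkerMatrix:
    """Individuals x markers dosage matrix.

    Parameters
    ----------
    individual_ids : sequence of str
        Row labels, unique.
    marker_ids : sequence of str
        Column labels, unique.
    dosages : ndarray, shape (n_individuals, n_markers)
        Float array with entries in {0, 1, 2} or NaN for missing.
    chrom, pos : optional per-marker chromosome label and position.
    """

    individual_ids: np.ndarray
    marker_ids: np.ndarray
    dosages: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self):
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.marker_ids = np.asarray(self.marker_ids, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.individual_ids), len(self.marker_ids)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.individual_ids)} individuals x {len(self.marker_ids)} markers"
            )
        for name, ids in (("individual", self.individual_ids), ("marker", self.marker_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} ids")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            bad = vals[~np.isin(vals, (0.0, 1.0, 2.0))]
            raise ValueError(f"dosages must be 0/1/2 or missing; found {bad[:5]}")

    # -- basic properties -------------------------------------------------

    @property
    def n_individuals(self) -> int:
        return len(self.individual_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.dosages).sum())

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per marker, f = mean(dosage)/2 over
        non-missing calls. NaN for all-missing markers."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def minor_allele_frequencies(self) -> np.ndarray:
        f = self.allele_frequencies()
        return np.minimum(f, 1.0 - f)

    # -- subsetting -------------------------------------------------------

    def subset_markers(self, mask_or_ids) -> "MarkerMatrix":
        idx = self._marker_index(mask_or_ids)
        return MarkerMatrix(
            self.individual_ids.copy(),
            self.marker_ids[idx],
            self.dosages[:, idx].copy(),
            None if self.chrom is None else self.chrom[idx],
            None if self.pos is None else self.pos[idx],
        )

    def subset_individuals(self, ids) -> "MarkerMatrix":
        lookup = {i: k for k, i in enumerate(self.individual_ids)}
        idx = np.array([lookup[i] for i in ids])
        return MarkerMatrix(
            self.individual_ids[idx],
            self.marker_ids.copy(),
            self.dosages[idx].copy(),
            self.chrom,
            self.pos,
        )

    def _marker_index(self, mask_or_ids) -> np.ndarray:
        arr = np.asarray(mask_or_ids)
        if arr.dtype == bool:
            return np.flatnonzero(arr)
        lookup = {m: k for k, m in enumerate(self.marker_ids)}
        return np.array([lookup[m] for m in arr], dtype=int)

    def equals(self, other: "MarkerMatrix") -> bool:
        return (
            list(self.individual_ids) == list(other.individual_ids)
            and list(self.marker_ids) == list(other.marker_ids)
            and np.array_equal(self.dosages, other.dosages, equal_nan=True)
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.individual_ids, columns=self.marker_ids
        )


@dataclasses.dataclass
class QCReport:
    """Bookkeeping for the marker QC funnel: counts are conserved,
    n_retained = n_input - n_removed_monomorphic - n_removed_maf."""

    n_input_markers: int
    n_removed_monomorphic: int
    n_removed_maf: int
    n_retained: int
    maf_threshold: float
    n_overlap: int | None = None

    def __post_init__(self):
        counts = (
            self.n_input_markers,
            self.n_removed_monomorphic,
            self.n_removed_maf,
            self.n_retained,
        )
        if any(c < 0 for c in counts):
            raise ValueError("QC counts must be non-negative")
        if self.n_retained != (
            self.n_input_markers - self.n_removed_monomorphic - self.n_removed_maf
        ):
            raise ValueError("QC counts are not conserved")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


# ---------------------------------------------------------------------------
# File I/O


def read_genotypes(path, format: str = "delimited") -> MarkerMatrix:
    """Read a marker matrix from ``delimited`` (header = marker ids, first
    column = individual id, tab or comma separated, NA = missing) or
    ``vcf`` (GT field; 0/0, 0/1, 1/1, ./. map to 0, 1, 2, missing)."""
    if format == "delimited":
        return _read_delimited(path)
    if format == "vcf":
        return _read_vcf(path)
    raise ValueError(f"unknown genotype format {format!r}")


def write_genotypes(mm: MarkerMatrix, path, format: str = "delimited", sep: str = "\t"):
    if format == "delimited":
        df = mm.to_frame()
        df.index.name = "id"
        df.to_csv(path, sep=sep, na_rep="NA")
    elif format == "vcf":
        _write_vcf(mm, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _read_delimited(path) -> MarkerMatrix:
    try:
        df = pd.read_csv(path, sep=None, engine="python", index_col=0,
                         na_values=["NA"], dtype=str, keep_default_na=True)
    except pd.errors.ParserError as exc:
        raise GenotypeParseError(str(exc)) from exc
    dosages = np.full(df.shape, np.nan)
    values = df.to_numpy()
    for j in range(df.shape[1]):
        col = values[:, j]
        for i, v in enumerate(col):
            if v is None or (isinstance(v, float) and np.isnan(v)):
                continue
            v = str(v).strip()
            if v in ("", "NA"):
                continue
            if v not in ("0", "1", "2", "0.0", "1.0", "2.0"):
                raise GenotypeParseError(
                    f"invalid dosage {v!r} for marker {df.columns[j]!r}", line=i + 2
                )
            dosages[i, j] = float(v)
    return MarkerMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        dosages,
    )


def _read_vcf(path) -> MarkerMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    marker_ids, chroms, poss, rows = [], [], [], []
    for k, variant in enumerate(vcf):
        if len(variant.ALT) > 1:
            raise GenotypeParseError(
                f"multi-allelic site {variant.ID or variant.POS} is not supported"
            )
        row = np.full(len(samples), np.nan)
        for s, gt in enumerate(variant.genotypes):
            alleles = [a for a in gt[:-1] if a >= 0]
            if any(a > 1 for a in alleles):
                raise GenotypeParseError(
                    f"multi-allelic genotype call at {variant.ID or variant.POS}"
                )
            if alleles:
                row[s] = float(sum(alleles))
        marker_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
        chroms.append(variant.CHROM)
        poss.append(variant.POS)
        rows.append(row)
    vcf.close()
    dosages = np.array(rows).T if rows else np.empty((len(samples), 0))
    return MarkerMatrix(
        np.array(samples, dtype=object),
        np.array(marker_ids, dtype=object),
        dosages,
        np.array(chroms, dtype=object),
        np.array(poss),
    )


_GT_CODE = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(mm: MarkerMatrix, path):
    chrom = mm.chrom if mm.chrom is not None else np.array(["1"] * mm.n_markers)
    pos = mm.pos if mm.pos is not None else np.arange(1, mm.n_markers + 1)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=rcgs\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(str(i) for i in mm.individual_ids)
            + "\n"
        )
        for j in range(mm.n_markers):
            calls = [
                "./." if np.isnan(d) else _GT_CODE[d] for d in mm.dosages[:, j]
            ]
            fh.write(
                f"{chrom[j]}\t{int(pos[j])}\t{mm.marker_ids[j]}\tA\tB\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )


# ---------------------------------------------------------------------------
# Platform intersection, imputation, QC


def intersect_platforms(mm_a: MarkerMatrix, mm_b: MarkerMatrix):
    """Restrict two marker matrices to their shared markers, both returned
    in the same sorted marker order.  Mirrors merging genotyping platforms
    of different density before joint analysis."""
    common = sorted(set(mm_a.marker_ids) & set(mm_b.marker_ids))
    return mm_a.subset_markers(common), mm_b.subset_markers(common)


def impute_random(mm: MarkerMatrix, seed: int, mode: str = "hwe") -> MarkerMatrix:
    """Fill missing dosages by random draws at each marker's observed
    allele frequency f.

    mode="hwe" draws the genotype from Hardy-Weinberg proportions
    {(1-f)^2, 2f(1-f), f^2}; mode="allele" draws two Bernoulli(f) alleles
    independently.  Both leave the expected frequency at f.
    """
    if mode not in ("hwe", "allele"):
        raise ValueError("mode must be 'hwe' or 'allele'")
    missing = np.isnan(mm.dosages)
    if not missing.any():
        return MarkerMatrix(
            mm.individual_ids.copy(), mm.marker_ids.copy(), mm.dosages.copy(),
            mm.chrom, mm.pos,
        )
    all_missing = missing.all(axis=0)
    if all_missing.any():
        bad = mm.marker_ids[all_missing][0]
        raise ValueError(f"marker {bad!r} has no non-missing calls; cannot impute")
    rng = np.random.default_rng(seed)
    f = mm.allele_frequencies()
    dosages = mm.dosages.copy()
    rows, cols = np.nonzero(missing)
    # two allele draws per missing genotype: HWE and independent-allele
    # imputation coincide for unphased dosage data
    draws = rng.random((rows.size, 2)) < f[cols, None]
    dosages[rows, cols] = draws.sum(axis=1).astype(float)
    return MarkerMatrix(
        mm.individual_ids.copy(), mm.marker_ids.copy(), dosages, mm.chrom, mm.pos
    )


def filter_markers(
    mm: MarkerMatrix,
    maf_threshold: float = 0.05,
    inclusive: bool = False,
    n_overlap: int | None = None,
) -> tuple[MarkerMatrix, QCReport]:
    """Remove monomorphic markers and markers below the minor-allele
    frequency threshold.

    The retention rule is strict by default: MAF exactly at the threshold
    is kept. ``inclusive=True`` removes markers at the threshold too.
    Requires a fully imputed matrix (no missing entries).
    """
    if np.isnan(mm.dosages).any():
        raise ValueError("filter_markers requires no missing entries; impute first")
    maf = mm.minor_allele_frequencies()
    mono = maf == 0.0
    if inclusive:
        low = (~mono) & (maf <= maf_threshold)
    else:
        low = (~mono) & (maf < maf_threshold)
    keep = ~(mono | low)
    report = QCReport(
        n_input_markers=mm.n_markers,
        n_removed_monomorphic=int(mono.sum()),
        n_removed_maf=int(low.sum()),
        n_retained=int(keep.sum()),
        maf_threshold=maf_threshold,
        n_overlap=n_overlap,
    )
    return mm.subset_markers(keep), report
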