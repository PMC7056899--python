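"""Genotype and phenotype containers plus PLINK-format readers and writers.

Genotypes are held as an individuals x markers dosage matrix counting copies
of the A1 allele (the minor allele when a dataset is loaded from text, where
polarity is decided at read time).  Missing calls are ``NaN``.  Supported
on-disk formats are PLINK 1 text (PED/MAP) and binary (BED/BIM/FAM,
SNP-major), and a tab-separated phenotype table.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeDataset",
    "PhenotypeTable",
    "FormatError",
    "read_plink_text",
    "write_plink_text",
    "read_plink_binary",
    "write_plink_binary",
    "read_phenotypes",
    "write_phenotypes",
]

MARKER_COLUMNS = ["snp_id", "chrom", "pos", "a1", "a2"]
SAMPLE_COLUMNS = ["fid", "iid", "sire", "dam", "sex"]

_BED_MAGIC = b"\x6c\x1b"
_BED_SNP_MAJOR = b"\x01"


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def _chrom_sort_key(labels: pd.Series) -> pd.Series:
    """Natural ordering for chromosome / linkage-group labels.

    Numeric labels sort numerically, everything else lexicographically after
    them, so "2" < "10" but "LG3" stays an opaque string.
    """

    def key(label: str) -> tuple[int, float, str]:
        s = str(label)
        if re.fullmatch(r"\d+", s):
            return (0, int(s), "")
        return (1, np.inf, s)

    return labels.map(key)


@dataclass
class GenotypeDataset:
    """Dosage matrix with its marker map and sample metadata.

    Attributes
    ----------
    dosages : ndarray of shape (n_individuals, n_markers)
        A1-allele counts in {0, 1, 2}; ``NaN`` marks missing calls.
    markers : DataFrame with columns snp_id, chrom, pos, a1, a2,
        sorted by (chromosome, position).
    samples : DataFrame with columns fid, iid, sire, dam, sex.
    """

    dosages: np.ndarray
    markers: pd.DataFrame
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.float64)
        if self.dosages.ndim != 2:
            raise ValueError("dosage matrix must be 2-D")
        n, m = self.dosages.shape
        if len(self.markers) != m:
            raise ValueError(f"marker map has {len(self.markers)} rows for {m} matrix columns")
        if len(self.samples) != n:
            raise ValueError(f"sample table has {len(self.samples)} rows for {n} matrix rows")
        if self.markers["snp_id"].duplicated().any():
            dup = self.markers.loc[self.markers["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicate marker ID {dup!r}")
        if (self.markers["pos"].to_numpy() < 0).any():
            raise ValueError("marker positions must be non-negative")

    @classmethod
    def new(cls, dosages, markers, samples) -> "GenotypeDataset":
        """Construct, sorting markers by (chromosome, position)."""
        markers = pd.DataFrame(markers).reset_index(drop=True)
        order = markers.assign(_k=_chrom_sort_key(markers["chrom"])).sort_values(
            ["_k", "pos"], kind="stable"
        ).index.to_numpy()
        markers = markers.loc[order].reset_index(drop=True)
        dosages = np.asarray(dosages, dtype=np.float64)[:, order]
        return cls(dosages, markers, pd.DataFrame(samples).reset_index(drop=True))

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    @property
    def individual_ids(self) -> pd.Series:
        """Composite FID_IID identifiers (PLINK allows duplicate IIDs across families)."""
        return self.samples["fid"].astype(str) + "_" + self.samples["iid"].astype(str)

    def subset(self, individuals=None, markers=None) -> "GenotypeDataset":
        """Return a new dataset restricted to row / marker-ID selections.

        ``individuals`` is a boolean mask or integer index over rows;
        ``markers`` is an iterable of marker IDs (order ignored, map order kept).
        """
        ds = self
        dosages, marker_df, sample_df = ds.dosages, ds.markers, ds.samples
        if individuals is not None:
            idx = np.asarray(individuals)
            if idx.dtype == bool:
                idx = np.flatnonzero(idx)
            dosages = dosages[idx]
            sample_df = sample_df.iloc[idx].reset_index(drop=True)
        if markers is not None:
            wanted = set(markers)
            unknown = wanted - set(marker_df["snp_id"])
            if unknown:
                raise KeyError(f"unknown marker IDs: {sorted(unknown)[:5]}")
            keep = marker_df["snp_id"].isin(wanted).to_numpy()
            dosages = dosages[:, keep]
            marker_df = marker_df.loc[keep].reset_index(drop=True)
        return GenotypeDataset(dosages.copy(), marker_df.copy(), sample_df.copy())


@dataclass
class PhenotypeTable:
    """Per-individual trait values and categorical fixed-effect factors."""

    data: pd.DataFrame  # indexed by individual ID
    trait_columns: list[str] = field(default_factory=list)
    factor_columns: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate individual ID {dup!r} in phenotype table")
        missing = [c for c in self.trait_columns + self.factor_columns if c not in self.data.columns]
        if missing:
            raise ValueError(f"columns not present: {missing}")

    @property
    def ids(self) -> pd.Index:
        return self.data.index

    def trait(self, name: str) -> pd.Series:
        return self.data[name].astype(float)


# ---------------------------------------------------------------------------
# PLINK text (PED/MAP)
# ---------------------------------------------------------------------------

def _read_map(map_path) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) not in (3, 4):
                raise FormatError(f"{map_path}:{ln}: expected 3 or 4 MAP fields, got {len(parts)}")
            chrom, snp_id = parts[0], parts[1]
            pos = int(parts[-1])
            rows.append((snp_id, chrom, pos))
    return pd.DataFrame(rows, columns=["snp_id", "chrom", "pos"])


def read_plink_text(ped_path, map_path) -> GenotypeDataset:
    """Read a PED/MAP pair, coding dosage as the count of the minor allele.

    The minor allele is determined per marker after reading (ties broken
    toward the alphabetically first allele); "0 0" codes a missing call.
    """
    marker_df = _read_map(map_path)
    m = len(marker_df)
    sample_rows, allele_rows = [], []
    with open(ped_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{ln}: expected {6 + 2 * m} fields for {m} markers, got {len(parts)}"
                )
            sample_rows.append(parts[:6])
            allele_rows.append(parts[6:])
    if not sample_rows:
        raise FormatError(f"{ped_path}: no individuals")
    samples = pd.DataFrame(sample_rows, columns=["fid", "iid", "sire", "dam", "sex", "pheno"])
    samples = samples[SAMPLE_COLUMNS]
    alleles = np.array(allele_rows, dtype=object).reshape(len(sample_rows), m, 2)

    n = len(sample_rows)
    dosages = np.full((n, m), np.nan)
    a1_list, a2_list = [], []
    for j in range(m):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq = sorted(set(observed.tolist()))
        if len(uniq) > 2:
            raise FormatError(
                f"marker {marker_df['snp_id'][j]!r}: {len(uniq)} distinct alleles {uniq}"
            )
        if not uniq:
            a1, a2 = "0", "0"
        elif len(uniq) == 1:
            a1, a2 = uniq[0], "0"
        else:
            counts = {a: int((observed == a).sum()) for a in uniq}
            # minor allele = lower count; tie -> alphabetically first
            a1 = min(uniq, key=lambda a: (counts[a], a))
            a2 = uniq[0] if a1 == uniq[1] else uniq[1]
        a1_list.append(a1)
        a2_list.append(a2)
        nonmiss = (col != "0").all(axis=1)
        dosages[nonmiss, j] = (col[nonmiss] == a1).sum(axis=1)
    marker_df["a1"] = a1_list
    marker_df["a2"] = a2_list
    return GenotypeDataset.new(dosages, marker_df, samples)


def write_plink_text(dataset: GenotypeDataset, ped_path, map_path) -> None:
    """Write PED/MAP; dosage d becomes d copies of A1 and 2-d of A2."""
    with open(map_path, "w") as fh:
        for _, r in dataset.markers.iterrows():
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{int(r.pos)}\n")
    a1 = dataset.markers["a1"].to_numpy()
    a2 = dataset.markers["a2"].to_numpy()
    with open(ped_path, "w") as fh:
        for i, s in dataset.samples.iterrows():
            fields = [str(s.fid), str(s.iid), str(s.sire), str(s.dam), str(s.sex), "-9"]
            row = dataset.dosages[i]
            for j, d in enumerate(row):
                if np.isnan(d):
                    fields += ["0", "0"]
                elif d == 2:
                    fields += [a1[j], a1[j]]
                elif d == 1:
                    fields += [a1[j], a2[j]]
                else:
                    fields += [a2[j], a2[j]]
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (BED/BIM/FAM, SNP-major)
# ---------------------------------------------------------------------------

# 2-bit genotype codes, PLINK 1: 00=hom A1, 01=missing, 10=het, 11=hom A2.
_DECODE = np.array([2.0, np.nan, 1.0, 0.0])
_SHIFTS = np.array([0, 2, 4, 6], dtype=np.uint8)


def read_plink_binary(bed_path, bim_path, fam_path) -> GenotypeDataset:
    """Read a PLINK 1 BED/BIM/FAM trio; dosage counts the BIM A1 allele."""
    bim = pd.read_csv(
        bim_path, sep=r"\s+", header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        fam_path, sep=r"\s+", header=None,
        names=["fid", "iid", "sire", "dam", "sex", "pheno"], dtype=str,
    )
    n, m = len(fam), len(bim)
    raw = Path(bed_path).read_bytes()
    if raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes {raw[:2]!r}")
    if raw[2:3] != _BED_SNP_MAJOR:
        raise FormatError(f"{bed_path}: not SNP-major (mode byte {raw[2:3]!r})")
    bytes_per_snp = (n + 3) // 4
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if body.size != m * bytes_per_snp:
        raise FormatError(
            f"{bed_path}: expected {m * bytes_per_snp} data bytes for {n} x {m}, got {body.size}"
        )
    codes = (body.reshape(m, bytes_per_snp)[:, :, None] >> _SHIFTS) & 0b11
    dosages = _DECODE[codes.reshape(m, -1)[:, :n]].T  # (n, m)
    markers = bim[MARKER_COLUMNS].copy()
    markers["pos"] = markers["pos"].astype(int)
    return GenotypeDataset.new(dosages, markers, fam[SAMPLE_COLUMNS])


def write_plink_binary(dataset: GenotypeDataset, bed_path, bim_path, fam_path) -> None:
    dataset.markers.assign(cm=0)[["chrom", "snp_id", "cm", "pos", "a1", "a2"]].to_csv(
        bim_path, sep="\t", header=False, index=False
    )
    dataset.samples.assign(pheno="-9")[["fid", "iid", "sire", "dam", "sex", "pheno"]].to_csv(
        fam_path, sep="\t", header=False, index=False
    )
    n, m = dataset.dosages.shape
    d = dataset.dosages.T  # SNP-major
    codes = np.full((m, n), 0b01, dtype=np.uint8)  # missing
    codes[d == 2] = 0b00
    codes[d == 1] = 0b10
    codes[d == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k, shift in enumerate(_SHIFTS):
        packed |= padded[:, k::4] << shift
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC + _BED_SNP_MAJOR)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# Phenotype tables
# ---------------------------------------------------------------------------

def read_phenotypes(path, trait_columns, factor_columns=(), id_column="id",
                    missing_sentinel="NA") -> PhenotypeTable:
    """Read a tab-separated phenotype table with a header row.

    Trait cells must parse as reals or equal the missing sentinel; factor
    columns are kept as labels.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if id_column not in df.columns:
        raise FormatError(f"{path}: no {id_column!r} column in header {list(df.columns)}")
    if df[id_column].duplicated().any():
        dup = df.loc[df[id_column].duplicated(), id_column].iloc[0]
        raise FormatError(f"{path}: duplicate individual ID {dup!r}")
    df = df.set_index(id_column)
    for col in trait_columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing trait column {col!r}")
        raw = df[col]

        def parse(v):  # float() is correctly rounded; pandas' fast parser is not
            if pd.isna(v) or v == missing_sentinel:
                return np.nan
            try:
                return float(v)
            except ValueError:
                raise FormatError(
                    f"{path}: non-numeric value {v!r} in trait column {col!r}"
                ) from None

        df[col] = raw.map(parse)
    for col in factor_columns:
        if col not in df.columns:
            raise FormatError(f"{path}: missing factor column {col!r}")
    return PhenotypeTable(df, list(trait_columns), list(factor_columns))


def write_phenotypes(table: PhenotypeTable, path, missing_sentinel="NA") -> None:
    out = table.data.copy()
    out.index.name = out.index.name or "id"
    # default float formatting is shortest-round-trip repr, so reads are exact
    out.to_csv(path, sep="\t", na_rep=missing_sentinel)
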