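"""Reading and writing the tabular and genotype formats used by the pipeline.

Genotypes travel as a samples x SNPs matrix of minor-allele dosage codes
(0, 1, 2, or :data:`MISSING`), the convention PLINK uses after ``--recode``.
This module is pure plumbing: allele orientation is decided here (minor =
less frequent allele among all non-missing calls in the file, ties broken
lexicographically) but no filtering or statistics happen here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SnpInfo",
    "GenotypeDataset",
    "SampleTable",
    "FormatError",
    "SchemaError",
    "read_ped_map",
    "write_ped_map",
    "read_covariates",
    "write_covariates",
    "write_results_tsv",
]

#: Sentinel dosage code for a missing genotype call ("0 0" in .ped files).
MISSING: int = -1


class FormatError(ValueError):
    """A genotype file violates the PLINK text format."""


class SchemaError(ValueError):
    """A covariate table is missing required columns or has invalid values."""


@dataclass(frozen=True)
class SnpInfo:
    """Map information for one biallelic SNP."""

    snp_id: str
    chrom: str
    pos: int
    allele_minor: str
    allele_major: str

    def __post_init__(self) -> None:
        if self.pos <= 0:
            raise ValueError(f"SNP {self.snp_id}: position must be positive")


@dataclass
class GenotypeDataset:
    """Samples x SNPs matrix of minor-allele dosage codes with SNP metadata.

    Parameters
    ----------
    sample_ids
        Unique sample identifiers, one per matrix row.
    snps
        Per-column :class:`SnpInfo` metadata.
    matrix
        ``(n_samples, n_snps)`` integer array with entries in
        ``{0, 1, 2, MISSING}`` counting copies of the minor allele.
    """

    sample_ids: list[str]
    snps: list[SnpInfo]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.int8)
        if self.matrix.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        valid = np.isin(self.matrix, (0, 1, 2, MISSING))
        if not valid.all():
            bad = self.matrix[~valid][0]
            raise ValueError(f"invalid genotype code {bad}; expected 0/1/2/{MISSING}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("sample_ids are not unique")
        ids = [s.snp_id for s in self.snps]
        if len(set(ids)) != len(ids):
            raise ValueError("snp_ids are not unique")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    def snp_index(self, snp_id: str) -> int:
        try:
            return self.snp_ids.index(snp_id)
        except ValueError:
            raise KeyError(f"unknown SNP id {snp_id!r}") from None

    def sample_index(self, sample_id: str) -> int:
        try:
            return self.sample_ids.index(sample_id)
        except ValueError:
            raise KeyError(f"unknown sample id {sample_id!r}") from None

    def subset(
        self,
        sample_mask: np.ndarray | None = None,
        snp_mask: np.ndarray | None = None,
    ) -> "GenotypeDataset":
        """Return a new dataset restricted to the masked samples/SNPs."""
        smask = np.ones(self.n_samples, bool) if sample_mask is None else np.asarray(sample_mask, bool)
        vmask = np.ones(self.n_snps, bool) if snp_mask is None else np.asarray(snp_mask, bool)
        return GenotypeDataset(
            sample_ids=[sid for sid, keep in zip(self.sample_ids, smask) if keep],
            snps=[s for s, keep in zip(self.snps, vmask) if keep],
            matrix=self.matrix[np.ix_(smask, vmask)],
        )

    def snp_frame(self) -> pd.DataFrame:
        return pd.DataFrame([dataclasses.asdict(s) for s in self.snps])


# Canonical covariate columns, their dtypes and validators.
_REQUIRED_COLS = ("sample_id", "phenotype", "age", "sex")
_OPTIONAL_COLS = (
    "education",
    "bmi",
    "smoking",
    "apoe_e4",
    "stage",
    "matched_set_id",
    "stratum_id",
)


@dataclass
class SampleTable:
    """Per-sample phenotype and covariate table.

    Wraps a :class:`pandas.DataFrame` with canonical columns: ``sample_id``,
    ``phenotype`` ('case'/'control'), ``age`` (years), ``sex`` ('F'/'M'),
    and optionally ``education`` (years), ``bmi`` (kg/m^2), ``smoking``
    ('ever'/'never'), ``apoe_e4`` (0/1 carrier flag), ``stage`` (1/2),
    ``matched_set_id`` and ``stratum_id``. Unknown columns are preserved.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        for col in _REQUIRED_COLS:
            if col not in df.columns:
                raise SchemaError(f"missing required column {col!r}")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise SchemaError(f"duplicated sample_id {dup!r}")
        bad_pheno = set(df["phenotype"]) - {"case", "control"}
        if bad_pheno:
            raise SchemaError(f"phenotype values must be case/control, got {bad_pheno}")
        age = pd.to_numeric(df["age"], errors="coerce")
        if age.isna().any():
            raise SchemaError("non-numeric age")
        if (age <= 0).any():
            raise SchemaError("age must be positive")
        df = df.copy()
        df["age"] = age.astype(float)
        df["sample_id"] = df["sample_id"].astype(str)
        self.data = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def sample_ids(self) -> list[str]:
        return self.data["sample_id"].tolist()

    @property
    def is_case(self) -> np.ndarray:
        return (self.data["phenotype"] == "case").to_numpy()

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.data.loc[np.asarray(mask, bool)].reset_index(drop=True))

    def aligned_to(self, genotypes: GenotypeDataset) -> "SampleTable":
        """Reorder rows to match ``genotypes.sample_ids`` (error if not 1:1)."""
        order = {sid: i for i, sid in enumerate(self.data["sample_id"])}
        missing = [sid for sid in genotypes.sample_ids if sid not in order]
        if missing:
            raise SchemaError(f"samples absent from covariate table: {missing[:5]}")
        idx = [order[sid] for sid in genotypes.sample_ids]
        return SampleTable(self.data.iloc[idx].reset_index(drop=True))


def _split_nonempty(line: str) -> list[str]:
    return line.split()


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> GenotypeDataset:
    """Read PLINK text ``.ped``/``.map`` files into a :class:`GenotypeDataset`.

    The minor allele at each SNP is the less frequent allele among all
    non-missing calls in the file (ties broken lexicographically); ``0 0``
    allele pairs become :data:`MISSING`.
    """
    map_rows: list[tuple[str, str, int]] = []
    with open(map_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_nonempty(line)
            if len(fields) != 4:
                raise FormatError(
                    f"{map_path}:{lineno}: expected 4 fields, got {len(fields)}"
                )
            chrom, snp_id, _cm, pos = fields
            map_rows.append((chrom, snp_id, int(pos)))
    m = len(map_rows)

    sample_ids: list[str] = []
    allele_rows: list[list[str]] = []
    with open(ped_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = _split_nonempty(line)
            if len(fields) != 6 + 2 * m:
                raise FormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * m} fields "
                    f"({m} SNPs), got {len(fields)}"
                )
            sample_ids.append(fields[1])
            allele_rows.append(fields[6:])
    n = len(sample_ids)

    alleles = np.array(allele_rows, dtype="U8").reshape(n, m, 2) if n else np.empty((0, m, 2), "U8")
    matrix = np.full((n, m), MISSING, dtype=np.int8)
    snps: list[SnpInfo] = []
    for j, (chrom, snp_id, pos) in enumerate(map_rows):
        a = alleles[:, j, :]
        nonmiss = a != "0"
        observed = a[nonmiss]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise FormatError(
                f"SNP {snp_id}: more than 2 alleles observed: {sorted(uniq)}"
            )
        if len(uniq) == 0:
            minor, major = "A", "A"  # all calls missing; arbitrary but stable
        elif len(uniq) == 1:
            minor, major = uniq[0], uniq[0]
        else:
            # minor = less frequent; tie -> lexicographically smaller
            if counts[0] < counts[1] or (counts[0] == counts[1] and uniq[0] < uniq[1]):
                minor, major = uniq[0], uniq[1]
            else:
                minor, major = uniq[1], uniq[0]
        row_nonmiss = nonmiss.all(axis=1)
        matrix[row_nonmiss, j] = (a[row_nonmiss] == minor).sum(axis=1)
        snps.append(SnpInfo(snp_id, chrom, pos, minor, major))
    return GenotypeDataset(sample_ids=sample_ids, snps=snps, matrix=matrix)


def write_ped_map(
    dataset: GenotypeDataset,
    ped_path: str | Path,
    map_path: str | Path,
    phenotype: Sequence[str] | None = None,
) -> None:
    """Write a dataset as PLINK text ``.ped``/``.map``.

    ``phenotype`` (optional, 'case'/'control' per sample) is encoded 2/1 in
    the sixth column; otherwise -9.
    """
    with open(map_path, "w", encoding="utf-8") as fh:
        for s in dataset.snps:
            fh.write(f"{s.chrom}\t{s.snp_id}\t0\t{s.pos}\n")
    pheno_codes = ["-9"] * dataset.n_samples
    if phenotype is not None:
        pheno_codes = ["2" if p == "case" else "1" for p in phenotype]
    with open(ped_path, "w", encoding="utf-8") as fh:
        for i, sid in enumerate(dataset.sample_ids):
            fields = [sid, sid, "0", "0", "0", pheno_codes[i]]
            for j, s in enumerate(dataset.snps):
                code = dataset.matrix[i, j]
                if code == MISSING:
                    fields += ["0", "0"]
                elif code == 0:
                    fields += [s.allele_major, s.allele_major]
                elif code == 1:
                    fields += [s.allele_minor, s.allele_major]
                else:
                    fields += [s.allele_minor, s.allele_minor]
            fh.write(" ".join(fields) + "\n")


def read_covariates(tsv_path: str | Path) -> SampleTable:
    """Read a per-sample covariate/phenotype TSV into a :class:`SampleTable`."""
    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str})
    return SampleTable(df)


def write_covariates(table: SampleTable, tsv_path: str | Path) -> None:
    table.data.to_csv(tsv_path, sep="\t", index=False)


def write_results_tsv(
    records: Iterable[Mapping] | pd.DataFrame,
    path: str | Path,
    float_format: str = "%.6g",
) -> None:
    """Write homogeneous result records as a TSV with a header row.

    An empty record list still produces a header-only file when the records
    are given as a DataFrame; a plain empty iterable writes an empty file.
    """
    df = records if isinstance(records, pd.DataFrame) else pd.DataFrame(list(records))
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
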