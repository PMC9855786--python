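"""Tabular inputs: contig abundance tables, 16S tables, sample metadata.

Abundance tables follow the de facto dialect of pseudo-alignment
quantifiers: a TSV with columns ``target_id, length, eff_length,
est_counts, tpm`` (extra columns ignored).  16S tables are taxon x sample
matrices of relative abundances in [0, 1]; percent-scaled tables are
accepted only with an explicit flag, never auto-guessed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AbundanceTable",
    "TaxonAbundanceTable",
    "SampleMetadata",
    "DIETS",
    "read_abundance_table",
    "write_abundance_table",
    "read_16s_table",
    "write_16s_table",
    "read_sample_metadata",
    "write_sample_metadata",
]

logger = logging.getLogger(__name__)

#: The three dietary regimes: fiber-free, fiber-rich, alternating.
DIETS = ("F", "R", "FR")

TPM_TOTAL = 1e6


@dataclass
class AbundanceTable:
    """Per-contig transcript abundances (TPM) of one sample."""

    sample_id: str
    data: pd.DataFrame  # index contig_id; columns length, eff_length, est_counts, tpm

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"sample {self.sample_id}: duplicate target_id {dups}")
        tpm = self.data["tpm"].to_numpy(dtype=float)
        if (tpm < 0).any():
            row = int(np.flatnonzero(tpm < 0)[0]) + 1
            raise ValueError(
                f"sample {self.sample_id}: negative tpm at data row {row}"
            )
        total = float(tpm.sum())
        if total > 0 and abs(total - TPM_TOTAL) / TPM_TOTAL > 1e-4:
            warnings.warn(
                f"sample {self.sample_id}: tpm column sums to {total:.6g}, "
                f"expected {TPM_TOTAL:.0f}",
                stacklevel=2,
            )

    def tpm(self) -> pd.Series:
        return self.data["tpm"].astype(float)


def read_abundance_table(path: str | Path, sample_id: str) -> AbundanceTable:
    """Read one quantifier output TSV (``target_id ... tpm``)."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = {"target_id", "tpm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    for col in ("length", "eff_length", "est_counts"):
        if col not in df.columns:
            df[col] = np.nan
    tpm = pd.to_numeric(df["tpm"], errors="coerce")
    if tpm.isna().any():
        row = int(tpm.isna().idxmax()) + 1
        raise ValueError(f"{path}: non-numeric tpm at data row {row}")
    neg = tpm < 0
    if neg.any():
        row = int(neg.idxmax()) + 1
        raise ValueError(f"{path}: negative tpm at data row {row}")
    if df["target_id"].duplicated().any():
        dup = df.loc[df["target_id"].duplicated(), "target_id"].iloc[0]
        raise ValueError(f"{path}: duplicate target_id {dup!r}")
    df = df[["target_id", "length", "eff_length", "est_counts", "tpm"]].copy()
    df["tpm"] = tpm
    return AbundanceTable(sample_id=sample_id, data=df.set_index("target_id"))


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write in the quantifier dialect with full float precision."""
    out = table.data.reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


@dataclass
class TaxonAbundanceTable:
    """16S-based relative abundances: taxa (rows) x samples (columns)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any() or (values > 1).any():
            raise ValueError("16S relative abundances must lie in [0, 1]")
        col_sums = values.sum(axis=0)
        if (col_sums > 1 + 1e-6).any():
            bad = self.data.columns[int(np.argmax(col_sums > 1 + 1e-6))]
            raise ValueError(
                f"16S column {bad!r} sums to {col_sums.max():.6g} > 1"
            )

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)


def read_16s_table(path: str | Path, percent: bool = False) -> TaxonAbundanceTable:
    """Read a taxon x sample relative-abundance TSV.

    With ``percent=True`` values are divided by 100 before validation.
    Taxa absent from any catalog group are retained: they form the
    unclassified remainder of the community.
    """
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            taxon = vals.index[int(vals.isna().to_numpy().argmax())]
            raise ValueError(f"{path}: non-numeric cell at ({taxon!r}, {col!r})")
        df[col] = vals
    if percent:
        df = df / 100.0
    over = df > 1
    if over.to_numpy().any():
        i, j = np.argwhere(over.to_numpy())[0]
        raise ValueError(
            f"{path}: value {df.iat[i, j]!r} > 1 at ({df.index[i]!r}, "
            f"{df.columns[j]!r}); use percent=True for percent-scaled tables"
        )
    return TaxonAbundanceTable(data=df.astype(float))


def write_16s_table(table: TaxonAbundanceTable, path: str | Path) -> None:
    table.data.to_csv(path, sep="\t", float_format="%.17g", index_label="taxon")


@dataclass
class SampleMetadata:
    """Sample -> subject -> diet assignment; subjects nest in one diet."""

    data: pd.DataFrame  # index sample_id; columns subject_id, diet

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate sample_id {dup!r}")
        bad = set(self.data["diet"]) - set(DIETS)
        if bad:
            raise ValueError(
                f"unknown diet token(s) {sorted(bad)}; allowed: {set(DIETS)}"
            )
        diets_per_subject = self.data.groupby("subject_id")["diet"].nunique()
        if (diets_per_subject > 1).any():
            subj = diets_per_subject.index[int((diets_per_subject > 1).argmax())]
            raise ValueError(f"subject {subj!r} assigned to more than one diet")

    @property
    def samples(self) -> list[str]:
        return list(self.data.index)

    def diet_of(self, sample_id: str) -> str:
        return str(self.data.loc[sample_id, "diet"])

    def samples_by_diet(self) -> dict[str, list[str]]:
        """Diet -> sorted sample ids, diets in canonical F, R, FR order."""
        out: dict[str, list[str]] = {}
        for diet in DIETS:
            ids = sorted(self.data.index[self.data["diet"] == diet])
            if ids:
                out[diet] = ids
        return out

    def restrict(self, sample_ids) -> "SampleMetadata":
        keep = [s for s in self.data.index if s in set(sample_ids)]
        return SampleMetadata(data=self.data.loc[keep].copy())


def read_sample_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "subject_id", "diet"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
    return SampleMetadata(data=df.set_index("sample_id")[["subject_id", "diet"]])


def write_sample_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.data.reset_index().to_csv(path, sep="\t", index=False)
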