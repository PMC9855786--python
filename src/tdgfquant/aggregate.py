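"""Group-abundance formulas: per-sample marker TPM totals and their
per-diet summaries under two normalizations.

For each sample (mouse) the abundance of a functional group is the sum of
TPM values over the contigs retained for the group's marker (RNA-seq route)
or the sum of 16S relative abundances over the group's member taxa
(taxonomic route).  Per diet, the *whole-community* normalization reports
the arithmetic mean of those per-sample totals over the diet's k mice; the
*distinguished-groups* normalization first expresses each group as its
share of the summed abundance of all modeled groups within the same mouse
(ignoring the unclassified remainder) and then averages the k shares, so
per-diet mean shares sum to exactly 1.

All sums run sequentially over ids in lexicographic order, making every
reported number bit-reproducible across platforms and row orders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .catalog import Catalog
from .io_tables import AbundanceTable, SampleMetadata, TaxonAbundanceTable

__all__ = [
    "SampleGroupAbundance",
    "GroupAbundanceResult",
    "tdgf_tpm_per_sample",
    "tdgf_tpm_matrix",
    "group_values_rnaseq",
    "group_values_16s",
    "group_abundance_rnaseq",
    "group_abundance_16s",
    "normalize_to_distinguished",
    "confidence_interval",
    "results_frame",
    "per_sample_frame",
]

METHOD_RNASEQ = "rnaseq_tdgf"
METHOD_16S = "taxonomic_16s"

NORM_WHOLE = "whole_community"
NORM_DISTINGUISHED = "distinguished_groups"


def _ordered_sum(values: Mapping[str, float]) -> float:
    """Sequential IEEE sum over keys in lexicographic order."""
    total = 0.0
    for key in sorted(values):
        total += float(values[key])
    return total


@dataclass(frozen=True)
class SampleGroupAbundance:
    """One group's abundance in one sample, before any per-diet averaging."""

    sample_id: str
    group_id: str
    value: float
    method: str

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ValueError("group abundance must be non-negative")
        if self.method == METHOD_16S and self.value > 1 + 1e-6:
            raise ValueError(
                f"16S group abundance {self.value} > 1 in sample {self.sample_id}"
            )


@dataclass(frozen=True)
class GroupAbundanceResult:
    """Per-diet summary of one group under one quantification route."""

    group_id: str
    diet: str
    method: str
    normalization: str
    sample_ids: tuple[str, ...]
    values: tuple[float, ...]
    mean: float
    ci_low: float
    ci_high: float

    @property
    def n(self) -> int:
        return len(self.values)


def tdgf_tpm_per_sample(
    table: AbundanceTable, retained: Mapping[str, Iterable[str]]
) -> dict[str, float]:
    """Total TPM per marker: sum over its retained contigs in this sample.

    Retained contigs absent from the table contribute 0 with a warning
    (synthetic subsets and re-assemblies legitimately drop contigs).
    """
    tpm = table.tpm()
    totals: dict[str, float] = {}
    for tdgf_id, contig_ids in retained.items():
        contig_ids = set(contig_ids)
        missing = sorted(contig_ids - set(tpm.index))
        if missing:
            warnings.warn(
                f"sample {table.sample_id}: retained contigs absent from "
                f"abundance table (counted as 0): {missing}",
                stacklevel=2,
            )
        totals[tdgf_id] = _ordered_sum(
            {c: float(tpm[c]) for c in contig_ids if c in tpm.index}
        )
    return totals


def tdgf_tpm_matrix(
    tables: Mapping[str, AbundanceTable], retained: Mapping[str, Iterable[str]]
) -> pd.DataFrame:
    """Samples x markers matrix of summed TPM values."""
    rows = {
        sample_id: tdgf_tpm_per_sample(table, retained)
        for sample_id, table in tables.items()
    }
    out = pd.DataFrame.from_dict(rows, orient="index").fillna(0.0)
    return out.sort_index().sort_index(axis=1)


def group_values_rnaseq(
    tpm_by_tdgf: pd.DataFrame,
    catalog: Catalog,
    multi_tdgf: bool = False,
) -> pd.DataFrame:
    """Samples x groups matrix of marker-based group abundances.

    Default single-marker mode uses each group's one assigned marker;
    ``multi_tdgf`` sums a group's markers instead (an extension for
    multi-marker catalogs, where the relative contribution of each marker
    to the trait is an open modelling question).
    """
    out = pd.DataFrame(index=tpm_by_tdgf.index.copy())
    for gid in sorted(catalog.groups):
        if multi_tdgf:
            tids = sorted(catalog.groups[gid].tdgf_ids)
        else:
            tids = [catalog.single_tdgf(gid).id]
        col = pd.Series(0.0, index=out.index)
        for sample in out.index:
            col[sample] = _ordered_sum(
                {t: float(tpm_by_tdgf.loc[sample, t]) if t in tpm_by_tdgf.columns else 0.0 for t in tids}
            )
        out[gid] = col
    return out


def group_values_16s(
    taxon_table: TaxonAbundanceTable, catalog: Catalog
) -> pd.DataFrame:
    """Samples x groups matrix of summed member-taxon relative abundances.

    A taxon belonging to several groups contributes to each of their sums;
    member taxa missing from the table count as 0 with a warning.
    """
    data = taxon_table.data
    out = pd.DataFrame(index=pd.Index(taxon_table.samples))
    for gid in sorted(catalog.groups):
        members = catalog.groups[gid].member_taxa
        missing = sorted(set(members) - set(data.index))
        if missing:
            warnings.warn(
                f"group {gid}: member taxa absent from 16S table "
                f"(counted as 0): {missing}",
                stacklevel=2,
            )
        col = pd.Series(0.0, index=out.index)
        for sample in out.index:
            col[sample] = _ordered_sum(
                {t: float(data.loc[t, sample]) for t in members if t in data.index}
            )
        out[gid] = col
    return out


def confidence_interval(
    values: Sequence[float],
    level: float = 0.95,
    method: str = "t",
    n_boot: int = 2000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided CI for the mean of a small sample.

    Default is the Student t interval ``mean +/- t_{1-a/2, k-1} * sd/sqrt(k)``;
    ``method="bootstrap"`` gives a seeded percentile bootstrap.  With k = 1
    the interval degenerates to the point, with a warning.
    """
    arr = np.asarray(values, dtype=float)
    k = arr.size
    if k == 0:
        raise ValueError("confidence_interval requires at least one value")
    mean = _mean(arr)
    if k == 1:
        warnings.warn("k=1: confidence interval degenerates to the point",
                      stacklevel=2)
        return mean, mean
    if method == "t":
        sd = float(np.std(arr, ddof=1))
        half = float(stats.t.ppf(0.5 + level / 2, df=k - 1)) * sd / np.sqrt(k)
        return mean - half, mean + half
    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        boots = rng.choice(arr, size=(n_boot, k), replace=True).mean(axis=1)
        lo, hi = np.quantile(boots, [0.5 - level / 2, 0.5 + level / 2])
        return float(lo), float(hi)
    raise ValueError(f"unknown CI method {method!r}")


def _mean(values: Sequence[float]) -> float:
    total = 0.0
    for v in values:
        total += float(v)
    return total / len(values)


def _summarize(
    values_df: pd.DataFrame,
    metadata: SampleMetadata,
    method: str,
    normalization: str,
    ci_method: str = "t",
    ci_seed: int | None = None,
) -> list[GroupAbundanceResult]:
    """Per-(group, diet) mean and CI from a samples x groups matrix."""
    results = []
    by_diet = metadata.restrict(values_df.index).samples_by_diet()
    for gid in values_df.columns:
        for diet, sample_ids in by_diet.items():
            vals = tuple(float(values_df.loc[s, gid]) for s in sample_ids)
            mean = _mean(vals)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                lo, hi = confidence_interval(vals, method=ci_method, seed=ci_seed)
            results.append(
                GroupAbundanceResult(
                    group_id=str(gid),
                    diet=diet,
                    method=method,
                    normalization=normalization,
                    sample_ids=tuple(sample_ids),
                    values=vals,
                    mean=mean,
                    ci_low=lo,
                    ci_high=hi,
                )
            )
    return results


def group_abundance_rnaseq(
    tpm_by_tdgf: pd.DataFrame,
    metadata: SampleMetadata,
    catalog: Catalog,
    multi_tdgf: bool = False,
    ci_method: str = "t",
) -> list[GroupAbundanceResult]:
    """Whole-community marker abundances: per-diet mean of per-mouse totals."""
    values = group_values_rnaseq(tpm_by_tdgf, catalog, multi_tdgf=multi_tdgf)
    return _summarize(values, metadata, METHOD_RNASEQ, NORM_WHOLE, ci_method)


def group_abundance_16s(
    taxon_table: TaxonAbundanceTable,
    metadata: SampleMetadata,
    catalog: Catalog,
    ci_method: str = "t",
) -> list[GroupAbundanceResult]:
    """Whole-community 16S abundances: per-diet mean of per-mouse sums."""
    values = group_values_16s(taxon_table, catalog)
    return _summarize(values, metadata, METHOD_16S, NORM_WHOLE, ci_method)


def normalize_to_distinguished(
    values_df: pd.DataFrame,
    metadata: SampleMetadata,
    method: str,
    pooled_ratio: bool = False,
    ci_method: str = "t",
) -> list[GroupAbundanceResult]:
    """Share of each group among all distinguished groups.

    Default: per mouse, divide each group's value by the sum over all
    groups in that same mouse, then average the k shares per diet — shares
    then sum to exactly 1 both per mouse and per diet mean.  The
    ``pooled_ratio`` alternative divides the diet-summed numerator by the
    diet-summed denominator instead (a ratio of totals rather than a mean
    of per-mouse ratios).
    """
    totals = {}
    for sample in values_df.index:
        totals[sample] = _ordered_sum(
            {str(g): float(values_df.loc[sample, g]) for g in values_df.columns}
        )
        if totals[sample] <= 0:
            raise ValueError(
                f"sample {sample!r}: all distinguished-group values are zero"
            )
    if not pooled_ratio:
        shares = values_df.copy().astype(float)
        for sample in shares.index:
            shares.loc[sample] = shares.loc[sample] / totals[sample]
        return _summarize(shares, metadata, method, NORM_DISTINGUISHED, ci_method)

    # pooled-ratio variant: sum numerator and denominator over the diet's mice
    results = []
    by_diet = metadata.restrict(values_df.index).samples_by_diet()
    for gid in values_df.columns:
        for diet, sample_ids in by_diet.items():
            num = _ordered_sum(
                {s: float(values_df.loc[s, gid]) for s in sample_ids}
            )
            den = _ordered_sum({s: totals[s] for s in sample_ids})
            ratio = num / den
            results.append(
                GroupAbundanceResult(
                    group_id=str(gid),
                    diet=diet,
                    method=method,
                    normalization=NORM_DISTINGUISHED,
                    sample_ids=tuple(sample_ids),
                    values=(ratio,),
                    mean=ratio,
                    ci_low=ratio,
                    ci_high=ratio,
                )
            )
    return results


def per_sample_frame(results: Iterable[GroupAbundanceResult]) -> pd.DataFrame:
    """Long-format per-sample values underlying a result list."""
    rows = []
    for r in results:
        for sample_id, value in zip(r.sample_ids, r.values):
            rows.append(
                {
                    "group_id": r.group_id,
                    "diet": r.diet,
                    "method": r.method,
                    "normalization": r.normalization,
                    "sample_id": sample_id,
                    "value": value,
                }
            )
    return pd.DataFrame(rows)


def results_frame(results: Iterable[GroupAbundanceResult]) -> pd.DataFrame:
    """Long-format per-diet summary table (one row per group x diet)."""
    rows = [
        {
            "group_id": r.group_id,
            "diet": r.diet,
            "method": r.method,
            "normalization": r.normalization,
            "n": r.n,
            "mean": r.mean,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
        }
        for r in results
    ]
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.sort_values(
            ["method", "normalization", "group_id", "diet"]
        ).reset_index(drop=True)
    return df
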