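"""Cross-validation of marker-based against 16S-based group abundances.

The two quantification routes measure different things — transcript
activity versus taxonomic standing stock — so agreement is assessed as
correlation of per-group abundance patterns across diets (or across
matched mice), plus Welch's unequal-variance t test for between-diet
contrasts.  With only three diets the diet-mean correlations rest on
n = 3 points and are flagged as descriptive.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .aggregate import GroupAbundanceResult, results_frame

__all__ = [
    "MethodComparison",
    "DietContrast",
    "correlate_methods",
    "welch_test",
    "build_report",
]

_MIN_POINTS_QUANTITATIVE = 4


@dataclass(frozen=True)
class MethodComparison:
    """Correlation between the two quantification routes for one group."""

    group_id: str
    normalization: str
    level: str  # "diet_means" | "per_sample"
    rnaseq_values: tuple[float, ...]
    s16_values: tuple[float, ...]
    r: float  # NaN when undefined
    n_points: int

    @property
    def defined(self) -> bool:
        return not np.isnan(self.r)

    @property
    def descriptive_only(self) -> bool:
        return self.n_points < _MIN_POINTS_QUANTITATIVE


@dataclass(frozen=True)
class DietContrast:
    """Welch's t test between two diets for one group."""

    group_id: str
    diet_a: str
    diet_b: str
    values_a: tuple[float, ...]
    values_b: tuple[float, ...]
    t_statistic: float
    welch_df: float
    p_value: float


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.spearmanr(x, y).statistic)


def correlate_methods(
    rnaseq_results: Iterable[GroupAbundanceResult],
    s16_results: Iterable[GroupAbundanceResult],
    level: str = "diet_means",
    method: str = "pearson",
) -> list[MethodComparison]:
    """Per-group correlation of the two routes over matched values.

    ``level="diet_means"`` pairs the per-diet means (3 points with the
    full diet design); ``level="per_sample"`` pairs mouse-matched values
    for samples covered by both routes.  The correlation is NaN (flagged
    undefined) with fewer than 2 pairs or when either vector is constant.
    """
    if level not in ("diet_means", "per_sample"):
        raise ValueError(f"unknown level {level!r}")
    corr = {"pearson": _pearson, "spearman": _spearman}[method]
    rna = list(rnaseq_results)
    s16 = list(s16_results)
    norms_rna = {r.normalization for r in rna}
    norms_16s = {r.normalization for r in s16}
    if norms_rna != norms_16s:
        raise ValueError(
            f"normalization mismatch between result sets: "
            f"{sorted(norms_rna)} vs {sorted(norms_16s)}"
        )
    groups = sorted({r.group_id for r in rna} & {r.group_id for r in s16})
    out: list[MethodComparison] = []
    for norm in sorted(norms_rna):
        for gid in groups:
            pairs: list[tuple[float, float]] = []
            ra = {r.diet: r for r in rna if r.group_id == gid and r.normalization == norm}
            sa = {r.diet: r for r in s16 if r.group_id == gid and r.normalization == norm}
            for diet in sorted(set(ra) & set(sa)):
                if level == "diet_means":
                    pairs.append((ra[diet].mean, sa[diet].mean))
                else:
                    r_by_sample = dict(zip(ra[diet].sample_ids, ra[diet].values))
                    s_by_sample = dict(zip(sa[diet].sample_ids, sa[diet].values))
                    for sample in sorted(set(r_by_sample) & set(s_by_sample)):
                        pairs.append((r_by_sample[sample], s_by_sample[sample]))
            x = np.array([p[0] for p in pairs])
            y = np.array([p[1] for p in pairs])
            if len(pairs) < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
                r_val = float("nan")
                if len(pairs) >= 2:
                    warnings.warn(
                        f"group {gid} ({norm}): constant values, "
                        "correlation undefined",
                        stacklevel=2,
                    )
            else:
                r_val = corr(x, y)
            out.append(
                MethodComparison(
                    group_id=gid,
                    normalization=norm,
                    level=level,
                    rnaseq_values=tuple(float(v) for v in x),
                    s16_values=tuple(float(v) for v in y),
                    r=r_val,
                    n_points=len(pairs),
                )
            )
    return out


def welch_test(
    values_a: Sequence[float],
    values_b: Sequence[float],
    group_id: str = "",
    diet_a: str = "",
    diet_b: str = "",
) -> DietContrast:
    """Welch's two-sided unequal-variance t test.

    ``t = (mean_a - mean_b) / sqrt(s_a^2/k_a + s_b^2/k_b)`` with the
    Welch–Satterthwaite degrees of freedom; degenerate zero-variance
    inputs yield p = 1 for equal means and p = 0 (with a warning)
    otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_test requires at least 2 values per side")
    va = float(np.var(a, ddof=1))
    vb = float(np.var(b, ddof=1))
    ma, mb = float(a.mean()), float(b.mean())
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            t, df, p = 0.0, float(a.size + b.size - 2), 1.0
        else:
            warnings.warn(
                "zero variance on both sides with different means: p = 0",
                stacklevel=2,
            )
            t = np.inf if ma > mb else -np.inf
            df, p = float(a.size + b.size - 2), 0.0
    else:
        sa, sb = va / a.size, vb / b.size
        t = (ma - mb) / np.sqrt(sa + sb)
        df = (sa + sb) ** 2 / (
            sa**2 / (a.size - 1) + sb**2 / (b.size - 1)
        )
        p = 2 * float(stats.t.sf(abs(t), df=df))
    return DietContrast(
        group_id=group_id,
        diet_a=diet_a,
        diet_b=diet_b,
        values_a=tuple(float(v) for v in a),
        values_b=tuple(float(v) for v in b),
        t_statistic=float(t),
        welch_df=float(df),
        p_value=float(p),
    )


def diet_contrasts(
    results: Iterable[GroupAbundanceResult],
    contrasts: Iterable[tuple[str, str]],
) -> list[DietContrast]:
    """Welch tests for the named diet pairs within each group/normalization."""
    res = list(results)
    out = []
    norms = sorted({r.normalization for r in res})
    for norm in norms:
        for gid in sorted({r.group_id for r in res if r.normalization == norm}):
            by_diet = {
                r.diet: r
                for r in res
                if r.group_id == gid and r.normalization == norm
            }
            for diet_a, diet_b in contrasts:
                if diet_a in by_diet and diet_b in by_diet:
                    out.append(
                        welch_test(
                            by_diet[diet_a].values,
                            by_diet[diet_b].values,
                            group_id=gid,
                            diet_a=diet_a,
                            diet_b=diet_b,
                        )
                    )
    return out


def comparisons_frame(comparisons: Iterable[MethodComparison]) -> pd.DataFrame:
    rows = [
        {
            "group_id": c.group_id,
            "normalization": c.normalization,
            "level": c.level,
            "r": c.r,
            "n_points": c.n_points,
            "descriptive_only": c.descriptive_only,
        }
        for c in comparisons
    ]
    return pd.DataFrame(rows)


def contrasts_frame(contrasts: Iterable[DietContrast]) -> pd.DataFrame:
    rows = [
        {
            "group_id": c.group_id,
            "diet_a": c.diet_a,
            "diet_b": c.diet_b,
            "t_statistic": c.t_statistic,
            "welch_df": c.welch_df,
            "p_value": c.p_value,
        }
        for c in contrasts
    ]
    return pd.DataFrame(rows)


def build_report(
    comparisons: Iterable[MethodComparison],
    contrasts: Iterable[DietContrast],
    results: Iterable[GroupAbundanceResult],
    out_dir: str | Path,
) -> dict:
    """Write the combined report bundle (TSV + JSON), deterministically.

    Emits ``results.tsv`` (all group x diet summaries), ``correlations.tsv``,
    ``contrasts.tsv`` (omitted when no contrasts were run), and
    ``report.json`` holding the same content in one document.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res_df = results_frame(results)
    comp_df = comparisons_frame(list(comparisons))
    cont_df = contrasts_frame(list(contrasts))
    if not comp_df.empty:
        comp_df = comp_df.sort_values(["normalization", "group_id"]).reset_index(
            drop=True
        )
    if not cont_df.empty:
        cont_df = cont_df.sort_values(
            ["group_id", "diet_a", "diet_b"]
        ).reset_index(drop=True)

    res_df.to_csv(out_dir / "results.tsv", sep="\t", index=False,
                  float_format="%.17g")
    comp_df.to_csv(out_dir / "correlations.tsv", sep="\t", index=False,
                   float_format="%.17g")
    report = {
        "results": res_df.to_dict(orient="records"),
        "correlations": comp_df.to_dict(orient="records"),
    }
    if not cont_df.empty:
        cont_df.to_csv(out_dir / "contrasts.tsv", sep="\t", index=False,
                       float_format="%.17g")
        report["contrasts"] = cont_df.to_dict(orient="records")
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, allow_nan=True)
        fh.write("\n")
    return report
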