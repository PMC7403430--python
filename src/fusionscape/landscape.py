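"""Cohort alteration landscape and the statistics reported over it.

Expression is normalised in two steps: raw gene counts become RPKM
(reads per kilobase of transcript per million mapped reads), and because the
pooled cohort mixes several sequencing batches, MGMT expression is re-centred
as a within-cohort Z-score before any cross-cohort comparison.

Alteration frequencies use assay-specific denominators — a patient whose
methylation was never assayed does not enter the methylation denominator —
and the fusion frequency carries an exact (Clopper–Pearson) binomial
confidence interval. Group comparisons use the Wilcoxon rank-sum test and
Fisher's exact test.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinomialCI",
    "rpkm",
    "cohort_zscore",
    "assemble_landscape",
    "binomial_ci",
    "fisher_enrichment",
    "wilcoxon_compare",
    "tally_frequencies",
    "round_percent",
]

ALTERATION_COLUMNS = ("idh_status", "codel_1p19q", "hypomethylation", "hypermutation", "fusion")


@dataclass(frozen=True)
class BinomialCI:
    successes: int
    trials: int
    level: float
    lower: float
    upper: float
    method: str = "clopper-pearson"


def rpkm(counts: int, gene_length_bp: int, total_mapped: int) -> float:
    """Reads per kilobase of transcript per million mapped reads."""
    if gene_length_bp <= 0 or total_mapped <= 0:
        raise ValueError("gene length and total mapped reads must be positive")
    if counts < 0:
        raise ValueError("counts must be non-negative")
    return counts * 1e9 / (gene_length_bp * total_mapped)


def cohort_zscore(values: pd.Series, cohorts: pd.Series) -> pd.Series:
    """Within-cohort Z-score (sample SD, ddof=1).

    Cohorts with fewer than two values, or zero spread, yield NaN — a
    singleton sample cannot be placed on a batch-relative scale.
    """
    values = pd.Series(values, dtype=float)
    out = pd.Series(np.nan, index=values.index)
    for _, idx in values.groupby(pd.Series(cohorts, index=values.index)).groups.items():
        group = values.loc[idx]
        if len(group) < 2:
            continue
        sd = group.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            continue
        out.loc[idx] = (group - group.mean()) / sd
    return out


def binomial_ci(x: int, n: int, level: float = 0.95) -> BinomialCI:
    """Exact Clopper–Pearson interval for a binomial proportion.

    lower = Beta^-1(alpha/2; x, n-x+1) (0 when x=0);
    upper = Beta^-1(1-alpha/2; x+1, n-x) (1 when x=n).
    """
    if n < 1 or not 0 <= x <= n:
        raise ValueError(f"need 0 <= x <= n with n >= 1, got x={x}, n={n}")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    alpha = 1.0 - level
    lower = 0.0 if x == 0 else float(stats.beta.ppf(alpha / 2, x, n - x + 1))
    upper = 1.0 if x == n else float(stats.beta.ppf(1 - alpha / 2, x + 1, n - x))
    return BinomialCI(x, n, level, lower, upper)


def fisher_enrichment(a: int, b: int, c: int, d: int, alternative: str = "two-sided") -> float:
    """Fisher's exact test on the 2x2 table [[a, b], [c, d]]."""
    if min(a, b, c, d) < 0:
        raise ValueError("table entries must be non-negative")
    if a + b + c + d == 0:
        raise ValueError("empty 2x2 table")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative=alternative).pvalue)


def wilcoxon_compare(group_a, group_b) -> tuple[float, float]:
    """Wilcoxon rank-sum comparison of two independent samples.

    Exact null distribution when combined n <= 20 and there are no ties;
    otherwise the normal approximation with tie correction. Returns the
    rank-sum statistic W of the first group and the two-sided P.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    exact_ok = pooled.size <= 20 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="exact" if exact_ok else "asymptotic"
    )
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank-sum of group a
    return w, float(res.pvalue)


def round_percent(fraction: float, decimals: int = 1) -> float:
    """Percentage rounded half-up to the printed style (e.g. 0.384 -> 38.4)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(str(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def assemble_landscape(
    cohort: pd.DataFrame,
    idh_calls: pd.DataFrame | None = None,
    upstream_calls: pd.DataFrame | None = None,
    fusion_summary: pd.DataFrame | None = None,
    expression: pd.Series | None = None,
) -> pd.DataFrame:
    """Join all per-patient evidence into one landscape frame.

    One row per patient, sorted by patient_id; missing assays become "NA".
    ``idh_calls`` is the hotspot-call frame (sample_id/status), ``upstream_calls``
    carries codel_1p19q and hypermutation, ``fusion_summary`` the per-patient
    fusion flags, ``expression`` MGMT RPKM indexed by patient_id.
    Duplicated patient_ids are an error.
    """
    if cohort["patient_id"].duplicated().any():
        dupes = cohort.loc[cohort["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id(s): {dupes}")
    out = cohort.copy()
    out["patient_id"] = out["patient_id"].astype(str)

    if "hypomethylation" in out.columns and "mgmt_methylation" not in out.columns:
        out["mgmt_methylation"] = out["hypomethylation"].map(
            {"yes": "unmethylated", "no": "methylated"}
        ).fillna("NA")

    if idh_calls is not None and len(idh_calls):
        # a patient is IDH-mutant if any assessed hotspot is mutant; NA only
        # if every hotspot was unassessable
        def _combine(group: pd.DataFrame) -> str:
            statuses = set(group["status"])
            if "mutant" in statuses:
                return "yes"
            if "wildtype" in statuses:
                return "no"
            return "NA"

        idh = (
            idh_calls.groupby("sample_id")[["status"]]
            .apply(_combine)
            .rename("idh_status")
        )
        out = out.merge(idh, left_on="patient_id", right_index=True, how="left")
    if "idh_status" not in out.columns:
        out["idh_status"] = "NA"
    out["idh_status"] = out["idh_status"].fillna("NA")

    if upstream_calls is not None and len(upstream_calls):
        cols = [c for c in upstream_calls.columns if c != "patient_id"]
        out = out.merge(
            upstream_calls[["patient_id"] + cols],
            on="patient_id",
            how="left",
            suffixes=("", "_upstream"),
        )
        for col in cols:
            up = f"{col}_upstream"
            if up in out.columns:
                out[col] = out[up].fillna(out[col] if col in cohort.columns else "NA")
                out = out.drop(columns=[up])
            else:
                out[col] = out[col].fillna("NA")
    for col in ("codel_1p19q", "hypermutation"):
        if col not in out.columns:
            out[col] = "NA"
        out[col] = out[col].fillna("NA")

    if fusion_summary is not None and len(fusion_summary):
        out = out.merge(
            fusion_summary[["patient_id", "fusion_positive", "fusion_names"]],
            on="patient_id",
            how="left",
        )
        out["fusion"] = out["fusion_positive"].fillna(
            out["fusion"] if "fusion" in cohort.columns else "no"
        )
        out = out.drop(columns=["fusion_positive"])
    if "fusion" not in out.columns:
        out["fusion"] = "NA"
    if "fusion_names" not in out.columns:
        out["fusion_names"] = ""
    out["fusion_names"] = out["fusion_names"].fillna("")

    if expression is not None:
        out["mgmt_rpkm"] = out["patient_id"].map(expression).astype(float)
        out["mgmt_z"] = cohort_zscore(
            pd.Series(np.log2(out["mgmt_rpkm"] + 1.0), index=out.index), out["cohort"]
        )

    return out.sort_values("patient_id").reset_index(drop=True)


def tally_frequencies(landscape: pd.DataFrame, alterations=None) -> pd.DataFrame:
    """Alteration frequencies with assay-specific denominators.

    For each alteration column the denominator counts non-NA patients only;
    percent is rounded half-up to one decimal, NaN when nothing was assayed.
    """
    alterations = [
        c for c in (alterations or ALTERATION_COLUMNS) if c in landscape.columns
    ]
    rows = []
    for col in alterations:
        values = landscape[col].astype(str)
        assayed = int((values != "NA").sum())
        positive = int((values == "yes").sum())
        percent = round_percent(positive / assayed) if assayed else float("nan")
        rows.append(
            {"alteration": col, "positive": positive, "assayed": assayed, "percent": percent}
        )
    return pd.DataFrame(rows)
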