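"""Relative quantitation and ranking of pooled LNPs from barcode peak areas.

The quantitative readout of a pooled screen is one integrated peak area per
animal per barcode.  Absolute areas are not comparable across animals
(injection amount, recovery and instrument response all vary), so each
animal's areas are divided by that animal's area for a designated reference
barcode -- typically the barcode carried by a standard benchmark LNP.  The
resulting fold changes are summarised per LNP (mean +/- SD across the
group) and the LNPs ranked by mean fold change.

Also here: exact small-n Wilcoxon matched-pairs signed-rank testing (used
to compare rankings between methods or arms), squared Pearson correlation
for method agreement, and lower-limit-of-quantitation (LOQ) censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "PEAK_TABLE_COLUMNS",
    "PER_BARCODE_LOQ_FMOL_PER_UL",
    "PER_BARCODE_PROTEIN_LOQ_NG_PER_ML",
    "validate_peak_table",
    "loq_censor",
    "normalize_to_reference",
    "group_summary",
    "rank_lnps",
    "RankingResult",
    "WilcoxonExactResult",
    "wilcoxon_signed_rank_exact",
    "method_correlation",
    "pool_detection_limit",
]

PEAK_TABLE_COLUMNS = ("animal_id", "group_id", "barcode_id", "peak_area")

# Empirical per-barcode sensitivity limits.  The molar LOQ is what the MS
# assay resolves per barcode peptide; the protein-equivalent value is the
# serum concentration of a ~30 kDa carrier at which a barcode reaches its
# LOQ after the full sample-processing chain.  They are independent
# measured constants and are deliberately not derived from one another.
PER_BARCODE_LOQ_FMOL_PER_UL = 2.0
PER_BARCODE_PROTEIN_LOQ_NG_PER_ML = 0.6


def validate_peak_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check required columns, non-negative areas, unique (animal, barcode)."""
    missing = set(PEAK_TABLE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"peak table missing columns: {sorted(missing)}")
    if (table["peak_area"] < 0).any():
        raise ValueError("peak areas must be >= 0")
    dup = table.duplicated(subset=["animal_id", "barcode_id"])
    if dup.any():
        pairs = table.loc[dup, ["animal_id", "barcode_id"]].values.tolist()
        raise ValueError(f"duplicate (animal_id, barcode_id) rows: {pairs[:5]}")
    return table


def loq_censor(table: pd.DataFrame, loq_value: float) -> pd.DataFrame:
    """Censor areas below the LOQ by substituting the LOQ itself.

    Rows below ``loq_value`` get ``below_loq=True`` and ``peak_area`` set to
    the censoring value; the original area is preserved in
    ``peak_area_raw``.  Substitution at the LOQ (rather than LOQ/2 or row
    exclusion) is the conservative default -- it never inflates a weak
    barcode's apparent signal relative to the threshold; other rules can be
    applied upstream by the caller.
    """
    if loq_value <= 0:
        raise ValueError("loq_value must be > 0")
    validate_peak_table(table)
    out = table.copy()
    if "peak_area_raw" not in out.columns:
        out["peak_area_raw"] = out["peak_area"]
    below = out["peak_area"] < loq_value
    out["below_loq"] = below
    out.loc[below, "peak_area"] = loq_value
    return out


def normalize_to_reference(
    table: pd.DataFrame, reference_barcode: str
) -> pd.DataFrame:
    """Per-animal fold change relative to ``reference_barcode``.

    Each animal's peak areas are divided by that animal's area for the
    reference barcode, cancelling any animal-level multiplicative factor.
    Animals in which the reference is absent or below LOQ are excluded with
    a warning naming them.
    """
    validate_peak_table(table)
    out = table.copy()
    ref = out[out["barcode_id"] == reference_barcode]
    if "below_loq" in ref.columns:
        ref_ok = ref[~ref["below_loq"].fillna(False) & (ref["peak_area"] > 0)]
    else:
        ref_ok = ref[ref["peak_area"] > 0]
    ref_by_animal = ref_ok.set_index("animal_id")["peak_area"]
    all_animals = out["animal_id"].unique()
    excluded = sorted(set(all_animals) - set(ref_by_animal.index))
    if excluded:
        warnings.warn(
            f"reference {reference_barcode!r} missing or below LOQ in animals "
            f"{excluded}; they are excluded from normalization",
            stacklevel=2,
        )
        out = out[~out["animal_id"].isin(excluded)]
    out = out.copy()
    out["fold_change"] = (
        out["peak_area"] / out["animal_id"].map(ref_by_animal).astype(float)
    )
    return out


def group_summary(
    normalized: pd.DataFrame, assignment: dict[str, str | None] | None = None
) -> pd.DataFrame:
    """Mean +/- SD of fold change per LNP (or per barcode if no assignment)."""
    df = normalized.copy()
    if assignment is not None:
        df["lnp"] = df["barcode_id"].map(assignment)
        df = df[df["lnp"].notna()]
    else:
        df["lnp"] = df["barcode_id"]
    grouped = df.groupby("lnp")["fold_change"]
    summary = grouped.agg(mean="mean", sd="std", n="count").reset_index()
    summary["sd"] = summary["sd"].fillna(0.0)
    return summary


@dataclass(frozen=True)
class RankingResult:
    """LNPs ordered by mean fold change, best first; ties share average rank."""

    table: pd.DataFrame  # columns: lnp, mean, sd, n, rank

    @property
    def order(self) -> list[str]:
        return self.table["lnp"].tolist()


def rank_lnps(
    normalized: pd.DataFrame, assignment: dict[str, str | None] | None = None
) -> RankingResult:
    """Rank LNPs by descending group-mean fold change.

    Exact ties receive the average of the ranks they span; within a tie the
    output rows are ordered alphabetically by label so the result is
    deterministic.
    """
    summary = group_summary(normalized, assignment)
    if len(summary) < 2:
        raise ValueError("need >= 2 LNPs to rank")
    summary["rank"] = stats.rankdata(-summary["mean"].to_numpy(), method="average")
    summary = summary.sort_values(["rank", "lnp"], kind="mergesort").reset_index(drop=True)
    return RankingResult(table=summary[["lnp", "mean", "sd", "n", "rank"]])


@dataclass(frozen=True)
class WilcoxonExactResult:
    statistic: float  # W+ = sum of ranks of positive differences
    pvalue: float
    n_used: int  # pairs remaining after dropping zero differences
    degenerate: bool  # all differences were zero


def wilcoxon_signed_rank_exact(x, y) -> WilcoxonExactResult:
    """Exact two-sided Wilcoxon matched-pairs signed-rank test.

    Differences of zero are dropped (the usual convention); the absolute
    differences are ranked with average ranks for ties, and the null
    distribution of W+ (sum of ranks of positive differences) is obtained
    by enumerating all 2^n sign assignments -- no normal approximation and
    no continuity correction.  The two-sided p-value doubles the smaller
    tail and is capped at 1.  Restricted to n <= 20 pairs, the regime where
    full enumeration is exact and fast.

    Five pairs whose differences all share one sign give the smallest
    attainable two-sided p at n = 5: 2/2^5 = 0.0625.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return WilcoxonExactResult(statistic=0.0, pvalue=1.0, n_used=0, degenerate=True)
    if n > 20:
        raise ValueError(f"exact enumeration supports n <= 20 pairs, got {n}")
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())

    # Null distribution of W+ over all 2^n equally likely sign patterns,
    # built by convolving one rank at a time.  Doubling the ranks makes
    # them integers even under average-rank ties.
    ranks2 = np.rint(2 * ranks).astype(int)
    counts = np.zeros(ranks2.sum() + 1, dtype=float)
    counts[0] = 1.0
    for r2 in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r2:] = counts[: len(counts) - r2]
        counts = counts + shifted
    total = 2.0**n
    w2 = int(np.rint(2 * w_plus))
    p_le = counts[: w2 + 1].sum() / total
    p_ge = counts[w2:].sum() / total
    pvalue = min(1.0, 2.0 * min(p_le, p_ge))
    return WilcoxonExactResult(
        statistic=w_plus, pvalue=float(pvalue), n_used=n, degenerate=False
    )


def method_correlation(x, y) -> float:
    """Squared Pearson correlation (r^2) between two quantitation methods."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need >= 3 finite pairs")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("r^2 undefined: zero variance in one input")
    r = stats.pearsonr(x, y).statistic
    return float(r * r)


def pool_detection_limit(per_barcode_loq: float, pool_size: int) -> float:
    """Minimum detectable total protein for a pool.

    For every LNP in a pool of size k to be quantifiable, each barcode must
    reach the per-barcode LOQ, so the pool must yield at least
    ``k * per_barcode_loq`` of total protein (assuming full recovery and
    comparable expression).  With a protein-equivalent per-barcode LOQ of
    0.6 ng/mL, a 10-LNP pool needs about 6 ng/mL total.
    """
    if per_barcode_loq <= 0:
        raise ValueError("per_barcode_loq must be > 0")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    return per_barcode_loq * pool_size
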