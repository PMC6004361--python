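"""Verification-stage genotype effect analysis.

The full-sib family's weight distribution is bimodal; this module splits it
into fast- and slow-growing subgroups at the density valley, runs per-locus
one-way ANOVA, summarizes genotype and two-locus genotype-combination classes
(n, n over a weight threshold, frequency %, mean +/- sd for weight and
length), and ranks "dominant" classes — those whose carriers exceed the
family-wide proportion of individuals over 500 g.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SplitResult",
    "AnovaResult",
    "split_subgroups",
    "one_way_anova",
    "genotype_summary",
    "combination_summary",
    "rank_dominant",
    "letter_groups",
    "histogram_table",
]

SUMMARY_COLUMNS = [
    "label",
    "n",
    "n_over_threshold",
    "frequency_over_threshold",
    "mean_length",
    "sd_length",
    "mean_weight",
    "sd_weight",
]


@dataclass
class SplitResult:
    """Fast/slow partition of a bimodal phenotype."""

    labels: pd.Series  # individual_id -> "fast" | "slow"
    threshold_weight: float
    threshold_length: float
    modes: tuple[float, float]  # (slow mode, fast mode) in grams
    method: str  # "kde_valley" | "largest_gap"
    is_bimodal: bool
    slow_range: tuple[float, float] = (np.nan, np.nan)
    fast_range: tuple[float, float] = (np.nan, np.nan)


def _kde_modes_and_valley(values: np.ndarray) -> tuple[list[float], float | None, np.ndarray, np.ndarray]:
    """Grid-evaluated Silverman KDE: mode locations (density-descending) and
    the density-minimum between the two largest modes."""
    kde = stats.gaussian_kde(values, bw_method="silverman")
    pad = 0.05 * (values.max() - values.min())
    grid = np.linspace(values.min() - pad, values.max() + pad, 1024)
    dens = kde(grid)
    interior = (dens[1:-1] > dens[:-2]) & (dens[1:-1] >= dens[2:])
    peaks = np.where(interior)[0] + 1
    order = peaks[np.argsort(dens[peaks])[::-1]]
    modes = [float(grid[i]) for i in order]
    if len(order) < 2:
        return modes, None, grid, dens
    lo, hi = sorted(grid[order[:2]])
    mask = (grid > lo) & (grid < hi)
    valley = float(grid[mask][np.argmin(dens[mask])])
    return modes, valley, grid, dens


def split_subgroups(phen: pd.DataFrame, min_n: int = 20) -> SplitResult:
    """Split a phenotype table (individual_id, weight_g, length_mm) into
    fast/slow subgroups at the weight-density valley between the two largest
    modes (Silverman-bandwidth KDE).  For very small samples the midpoint of
    the largest gap in sorted weights is used instead.  A unimodal density
    yields a flagged no-split result (all individuals labeled "fast").
    """
    if len(phen) < min_n:
        raise ValueError(f"need at least {min_n} individuals to split, got {len(phen)}")
    w = phen["weight_g"].to_numpy(dtype=float)
    idx = phen["individual_id"]

    method = "kde_valley"
    if len(w) < 30:
        method = "largest_gap"
        threshold, modes = _largest_gap_threshold(w)
    else:
        modes_all, valley, _, _ = _kde_modes_and_valley(w)
        if valley is None:
            return SplitResult(
                labels=pd.Series("fast", index=idx, name="subgroup"),
                threshold_weight=float("nan"),
                threshold_length=float("nan"),
                modes=(float("nan"), modes_all[0]),
                method=method,
                is_bimodal=False,
            )
        threshold = valley
        modes = tuple(sorted(modes_all[:2]))

    fast = w > threshold
    if fast.all() or not fast.any():
        return SplitResult(
            labels=pd.Series(np.where(fast, "fast", "slow"), index=idx, name="subgroup"),
            threshold_weight=float(threshold),
            threshold_length=float("nan"),
            modes=(float(modes[0]), float(modes[1])),
            method=method,
            is_bimodal=False,
        )
    lengths = phen["length_mm"].to_numpy(dtype=float)
    # induced boundary, reported as the midpoint between the flanking values
    thr_w = 0.5 * (w[~fast].max() + w[fast].min())
    thr_l = 0.5 * (lengths[~fast].max() + lengths[fast].min())
    return SplitResult(
        labels=pd.Series(np.where(fast, "fast", "slow"), index=idx, name="subgroup"),
        threshold_weight=float(thr_w),
        threshold_length=float(thr_l),
        modes=(float(modes[0]), float(modes[1])),
        method=method,
        is_bimodal=True,
        slow_range=(float(w[~fast].min()), float(w[~fast].max())),
        fast_range=(float(w[fast].min()), float(w[fast].max())),
    )


def subgroup_mode(values: np.ndarray, fallback: float) -> float:
    """Peak (KDE mode) of one subgroup's own weight distribution; pools are
    drawn from the individuals nearest this peak."""
    if len(values) < 10 or np.ptp(values) == 0:
        return fallback
    try:
        modes, _, _, _ = _kde_modes_and_valley(np.asarray(values, dtype=float))
    except np.linalg.LinAlgError:
        return fallback
    return modes[0] if modes else fallback


def _largest_gap_threshold(w: np.ndarray) -> tuple[float, tuple[float, float]]:
    s = np.sort(w)
    gaps = np.diff(s)
    i = int(np.argmax(gaps))
    threshold = 0.5 * (s[i] + s[i + 1])
    return threshold, (float(np.median(s[: i + 1])), float(np.median(s[i + 1 :])))


@dataclass
class AnovaResult:
    F: float
    p: float
    group_means: dict[str, float]
    used_groups: list[str] = field(default_factory=list)
    testable: bool = True


def one_way_anova(groups: dict[str, np.ndarray]) -> AnovaResult:
    """One-way ANOVA across genotype classes; groups with n < 2 are excluded
    with a warning.  Identical constant groups give F = 0, p = 1."""
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items() if len(v) >= 2}
    dropped = set(groups) - set(usable)
    if dropped:
        warnings.warn(f"groups excluded from ANOVA (n < 2): {sorted(dropped)}")
    means = {k: float(np.mean(v)) for k, v in usable.items()}
    if len(usable) < 2:
        return AnovaResult(float("nan"), float("nan"), means, list(usable), testable=False)
    values = list(usable.values())
    if np.ptp(np.concatenate(values)) == 0:
        return AnovaResult(0.0, 1.0, means, list(usable))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        F, p = stats.f_oneway(*values)
    if not np.isfinite(F):  # zero between-group variance
        F, p = 0.0, 1.0
    return AnovaResult(float(F), float(p), means, list(usable))


def _summary_row(label: str, sub: pd.DataFrame, threshold: float) -> dict:
    n = len(sub)
    n_over = int((sub["weight_g"] > threshold).sum())  # strict inequality
    return {
        "label": label,
        "n": n,
        "n_over_threshold": n_over,
        "frequency_over_threshold": round(100.0 * n_over / n, 2),
        "mean_length": float(sub["length_mm"].mean()),
        "sd_length": float(sub["length_mm"].std(ddof=1)) if n > 1 else float("nan"),
        "mean_weight": float(sub["weight_g"].mean()),
        "sd_weight": float(sub["weight_g"].std(ddof=1)) if n > 1 else float("nan"),
    }


def _joined(genotypes: pd.Series, phen: pd.DataFrame) -> pd.DataFrame:
    gt = genotypes.rename("genotype").rename_axis("individual_id").dropna()
    return phen.merge(gt.reset_index(), on="individual_id")


def genotype_summary(
    genotypes: pd.Series,
    phen: pd.DataFrame,
    site_label: str = "",
    weight_threshold: float = 500.0,
) -> pd.DataFrame:
    """Per-genotype class statistics plus a family-wide row.

    ``genotypes`` maps individual_id to a genotype string (e.g. "GG"); missing
    genotypes are excluded from class rows.  The family row uses every
    phenotyped individual.  ``n_over_threshold`` counts weight strictly above
    the threshold and frequencies are reported in percent to 2 decimals.
    """
    joined = _joined(genotypes, phen)
    rows = [_summary_row("family", phen, weight_threshold)]
    for gt, sub in sorted(joined.groupby("genotype")):
        if len(sub) == 0:
            warnings.warn(f"empty genotype class {gt} omitted")
            continue
        rows.append(_summary_row(f"{site_label}{gt}", sub, weight_threshold))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def combination_summary(
    genotypes_a: pd.Series,
    genotypes_b: pd.Series,
    phen: pd.DataFrame,
    site_labels: tuple[str, str] = ("", ""),
    weight_threshold: float = 500.0,
) -> pd.DataFrame:
    """Two-locus genotype-combination statistics.

    Individuals missing either site's call are excluded.  Class labels are
    formatted "<siteA><gtA> + <siteB><gtB>" (e.g. "17GG + 14CC").
    """
    a = genotypes_a.rename("gt_a").rename_axis("individual_id").dropna()
    b = genotypes_b.rename("gt_b").rename_axis("individual_id").dropna()
    both = a.to_frame().join(b, how="inner").reset_index()
    joined = phen.merge(both, on="individual_id")
    la, lb = site_labels
    rows = []
    for (ga, gb), sub in sorted(joined.groupby(["gt_a", "gt_b"])):
        rows.append(_summary_row(f"{la}{ga} + {lb}{gb}", sub, weight_threshold))
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def rank_dominant(
    summaries: pd.DataFrame,
    family_row: pd.Series | None = None,
    min_n: int = 10,
) -> pd.DataFrame:
    """Order genotype classes by frequency over the weight threshold.

    Ties break by mean weight, then label (deterministic).  Each class is
    annotated with its percentage-point advantage over the family-wide
    frequency; classes with n < ``min_n`` are flagged small-sample and should
    be excluded from statistical claims.
    """
    df = summaries[summaries.label != "family"].copy()
    if family_row is None:
        fam = summaries[summaries.label == "family"]
        if len(fam) != 1:
            raise ValueError("family row absent; pass family_row explicitly")
        family_row = fam.iloc[0]
    df["advantage_points"] = (
        df["frequency_over_threshold"] - family_row["frequency_over_threshold"]
    )
    df["small_sample"] = df["n"] < min_n
    df = df.sort_values(
        ["frequency_over_threshold", "mean_weight", "label"],
        ascending=[False, False, True],
        kind="mergesort",
    )
    return df.reset_index(drop=True)


def letter_groups(
    groups: dict[str, np.ndarray],
    alpha: float = 0.01,
) -> dict[str, str]:
    """Connected-letters display from pairwise Welch tests with Bonferroni
    correction: classes sharing a letter are not significantly different.

    The exact post-hoc procedure behind published letter groupings varies;
    this is a stated, conservative stand-in.
    """
    names = sorted(groups, key=lambda k: -float(np.mean(groups[k])))
    pairs = list(combinations(names, 2))
    m = len(pairs) or 1
    differs = set()
    for a, b in pairs:
        _, p = stats.ttest_ind(groups[a], groups[b], equal_var=False)
        if p * m < alpha:
            differs.add((a, b))
            differs.add((b, a))
    # greedy clique cover in mean order
    letter_sets: list[set[str]] = []
    for name in names:
        placed = False
        for s in letter_sets:
            if all((name, other) not in differs for other in s):
                s.add(name)
                placed = True
        if not placed:
            letter_sets.append({name})
    alphabet = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    out: dict[str, str] = {}
    for name in names:
        out[name] = "".join(
            alphabet[i] for i, s in enumerate(letter_sets) if name in s
        )
    return out


def histogram_table(
    phen: pd.DataFrame,
    column: str = "weight_g",
    bins: int = 40,
) -> pd.DataFrame:
    """Frequency-distribution table (bin midpoint, count) for plotting."""
    counts, edges = np.histogram(phen[column].to_numpy(dtype=float), bins=bins)
    return pd.DataFrame(
        {"bin_mid": 0.5 * (edges[:-1] + edges[1:]), "count": counts}
    )
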