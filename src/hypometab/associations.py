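"""Correlation fingerprints and the group-comparison battery.

The fingerprint is the signed pattern of significant Pearson correlations
between the hypoxia score and a feature panel (pathway deregulation
scores or metabolite abundances), computed on the whole cohort and —
when a metabolic-type assignment is supplied — within each type
separately.  Counting significant features per type measures how broadly
hypoxia couples to metabolism in that type.

Group comparisons follow the conventional gated battery: Shapiro–Wilk
normality at alpha=0.05 per group, then unpaired two-tailed t-test or
Mann–Whitney for two groups, Kruskal–Wallis with Dunn's Bonferroni-style
post hoc for more than two.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .signatures import ScoreTable

logger = logging.getLogger("hypometab")

ALL_STRATUM = "all"


@dataclass
class CorrelationFingerprint:
    """Long-format records: one row per (stratum, feature).

    Columns: stratum, feature, r, p, n, significant, sign.  Constant
    features carry r = NA and are never counted as significant.
    """

    records: pd.DataFrame
    alpha: float = 0.05
    multiplicity: str = "none"

    def stratum(self, name: str) -> pd.DataFrame:
        return self.records[self.records["stratum"] == name]

    @property
    def strata(self) -> list[str]:
        return list(dict.fromkeys(self.records["stratum"]))


def pearson_screen(x: np.ndarray, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized Pearson r and two-sided p of x against each feature row.

    ``features`` is (n_features, n).  Constant rows (or constant x) give
    r = NaN, p = NaN.  p-values come from the exact t reference
    distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, float)
    y = np.asarray(features, float)
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean(axis=1, keepdims=True)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(axis=1))
    denom = sx * sy
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, yc @ xc / np.where(denom == 0, 1, denom), np.nan)
        r = np.clip(r, -1.0, 1.0)
        tstat = r * np.sqrt((n - 2) / np.maximum(1 - r ** 2, np.finfo(float).tiny))
    p = 2 * stats.t.sf(np.abs(tstat), df=n - 2)
    p = np.where(np.isnan(r), np.nan, np.minimum(p, 1.0))
    return r, p


def _stratum_records(
    name: str,
    hs: np.ndarray,
    feats: pd.DataFrame,
    alpha: float,
    multiplicity: str,
) -> pd.DataFrame:
    r, p = pearson_screen(hs, feats.to_numpy())
    n_const = int(np.isnan(r).sum())
    if n_const:
        logger.warning("stratum %s: %d constant feature(s) excluded",
                       name, n_const)
    ok = ~np.isnan(p)
    if multiplicity == "bh":
        p_eff = np.full_like(p, np.nan)
        if ok.any():
            p_eff[ok] = multipletests(p[ok], method="fdr_bh")[1]
    elif multiplicity == "none":
        p_eff = p
    else:
        raise ValueError(f"unknown multiplicity mode {multiplicity!r}")
    sig = ok & (p_eff < alpha)
    sign = np.where(~ok | (r == 0), "0", np.where(r > 0, "+", "-"))
    return pd.DataFrame(
        {
            "stratum": name,
            "feature": feats.index,
            "r": r,
            "p": p,
            "n": hs.size,
            "significant": sig,
            "sign": sign,
        }
    )


def correlate(
    hs: ScoreTable,
    features: pd.DataFrame,
    groups=None,
    alpha: float = 0.05,
    multiplicity: str = "none",
    min_n: int = 3,
) -> CorrelationFingerprint:
    """Pearson screen of the hypoxia score against every feature row.

    ``features`` is features x samples.  With ``groups`` (a
    ClusterAssignment), the screen additionally runs within each type;
    strata with fewer than ``min_n`` shared samples are skipped with a
    warning.  ``multiplicity`` is "none" (each feature at raw p < alpha)
    or "bh" (Benjamini–Hochberg within stratum).
    """
    shared = hs.table.index.intersection(features.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between scores and features")
    if len(shared) < min_n:
        raise ValueError(f"only {len(shared)} shared samples, {min_n} required")
    hs_vec = hs.table.loc[shared, "hs"].to_numpy(float)
    feats = features[shared]
    frames = [_stratum_records(ALL_STRATUM, hs_vec, feats, alpha, multiplicity)]
    if groups is not None:
        labels = groups.table.loc[
            groups.table.index.intersection(shared), "label"
        ]
        for lab in sorted(labels.unique()):
            ids = labels.index[labels == lab]
            if len(ids) < min_n:
                logger.warning(
                    "stratum %s skipped: %d shared samples < %d",
                    lab, len(ids), min_n,
                )
                continue
            frames.append(_stratum_records(
                lab, hs.table.loc[ids, "hs"].to_numpy(float),
                feats[ids], alpha, multiplicity,
            ))
    records = pd.concat(frames, ignore_index=True)
    return CorrelationFingerprint(records, alpha=alpha, multiplicity=multiplicity)


def count_significant(
    fp: CorrelationFingerprint,
    require_consistency: CorrelationFingerprint | None = None,
) -> pd.DataFrame:
    """Per-stratum counts of significantly positive / negative features.

    With a second fingerprint (e.g. a validation cohort), a feature is
    counted only when significant with the SAME sign in both — the
    discovery/validation consistency rule.
    """
    recs = fp.records
    if require_consistency is not None:
        other = require_consistency.records
        merged = recs.merge(
            other, on=["stratum", "feature"], suffixes=("", "_b"), how="inner"
        )
        lost = len(recs) - len(merged)
        if lost:
            logger.warning(
                "consistency counting: %d record(s) without a partner "
                "in the second fingerprint were dropped", lost
            )
        keep = (
            merged["significant"] & merged["significant_b"]
            & (merged["sign"] == merged["sign_b"])
        )
        recs = merged[list(fp.records.columns)].copy()
        recs["significant"] = keep
    sig = recs[recs["significant"]]
    out = pd.DataFrame(
        {
            "n_positive": sig[sig["sign"] == "+"].groupby("stratum").size(),
            "n_negative": sig[sig["sign"] == "-"].groupby("stratum").size(),
        }
    ).reindex(list(dict.fromkeys(recs["stratum"]))).fillna(0).astype(int)
    out.index.name = "stratum"
    return out


def fingerprint_breadth(fp: CorrelationFingerprint) -> pd.DataFrame:
    """Clusters ordered by how many features correlate with the hypoxia
    score in them (descending); ties keep label order and are flagged."""
    counts = count_significant(fp)
    counts = counts.drop(index=ALL_STRATUM, errors="ignore")
    counts["n_significant"] = counts["n_positive"] + counts["n_negative"]
    out = counts.sort_values(
        ["n_significant"], ascending=False, kind="stable"
    )
    out["tied"] = out["n_significant"].duplicated(keep=False)
    return out


@dataclass
class GroupComparison:
    test: str
    statistic: float
    p: float
    posthoc: pd.DataFrame | None = None


def _dunn_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    """Dunn's multiple-comparison test after Kruskal–Wallis.

    Pairwise z statistics from pooled mean ranks with tie correction;
    two-sided p-values Bonferroni-adjusted over the number of pairs
    (the Bonferroni-style variant of Dunn's procedure).
    """
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n_tot = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, sizes, start = {}, {}, 0
    for g in labels:
        k = groups[g].size
        mean_rank[g] = ranks[start:start + k].mean()
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (12 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12 - tie_term
    n_pairs = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p_adj = min(2 * stats.norm.sf(abs(z)) * n_pairs, 1.0)
        rows.append({"group_a": a, "group_b": b, "z": z, "p_adj": p_adj})
    return pd.DataFrame(rows)


def compare_groups(
    groups: dict[str, np.ndarray], alpha_normality: float = 0.05
) -> GroupComparison:
    """Compare value distributions across named groups.

    Two groups: Shapiro–Wilk on each; both normal -> unpaired two-tailed
    t-test, else Mann–Whitney U.  More than two: Kruskal–Wallis with
    Dunn's post hoc.  Groups need >= 3 values each.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = {k: np.asarray(v, float) for k, v in groups.items()}
    for name, vals in arrays.items():
        if vals.size < 3:
            raise ValueError(f"group {name!r} has {vals.size} values, 3 required")
    vals = list(arrays.values())
    if len(vals) == 2:
        def _normal(v: np.ndarray) -> bool:
            if np.ptp(v) == 0:       # Shapiro is undefined on constants
                return False
            return stats.shapiro(v).pvalue >= alpha_normality
        if _normal(vals[0]) and _normal(vals[1]):
            res = stats.ttest_ind(vals[0], vals[1])
            return GroupComparison("t-test", float(res.statistic), float(res.pvalue))
        res = stats.mannwhitneyu(vals[0], vals[1], alternative="two-sided")
        return GroupComparison("mann-whitney", float(res.statistic), float(res.pvalue))
    res = stats.kruskal(*vals)
    return GroupComparison(
        "kruskal-wallis", float(res.statistic), float(res.pvalue),
        posthoc=_dunn_posthoc(arrays),
    )
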