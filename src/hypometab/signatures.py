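"""Hypoxia scoring by cohort-median dichotomization of a gene signature.

Each signature gene contributes a call of +1 (expression above the
cohort median of that gene) or -1 (at or below it); the per-sample sum of
calls is the hypoxia score (HS).  Samples with HS > 0 form the HS-high
group, HS <= 0 the HS-low group.  Medians are always recomputed on the
cohort being scored, so the score of a sample depends on which cohort it
is scored in — by design.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix

logger = logging.getLogger("hypometab")


@dataclass(frozen=True)
class GeneSignature:
    name: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("signature has no genes")
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("signature genes must be unique")


#: 8 hypoxia-responsive genes (primary signature).
HYPOXIA_8 = GeneSignature(
    "hypoxia8",
    ("DDIT4", "LDHA", "MXI1", "NDRG1", "P4HA1", "PGK1", "SLC2A1", "VEGFA"),
)

#: Buffa 15-gene hypoxia metagene (replication signature).  Odd size, so
#: HS is odd and the high/low split has no boundary ties.
BUFFA_15 = GeneSignature(
    "buffa15",
    ("ACOT7", "ADM", "ALDOA", "CDKN3", "ENO1", "LDHA", "MIF", "MRPS17",
     "NDRG1", "P4HA1", "PGAM1", "SLC2A1", "TPI1", "TUBB6", "VEGFA"),
)

BUILTIN_SIGNATURES = {"8gene": HYPOXIA_8, "buffa15": BUFFA_15}


def load_signature(spec: str) -> GeneSignature:
    """Resolve ``builtin:<name>`` or a path to a one-symbol-per-line file."""
    if spec.startswith("builtin:"):
        key = spec.split(":", 1)[1]
        if key not in BUILTIN_SIGNATURES:
            raise KeyError(
                f"unknown builtin signature {key!r}; "
                f"available: {sorted(BUILTIN_SIGNATURES)}"
            )
        return BUILTIN_SIGNATURES[key]
    with open(spec, encoding="utf-8") as fh:
        genes = tuple(g.strip() for g in fh if g.strip())
    return GeneSignature(spec, genes)


@dataclass
class ScoreTable:
    """Per-sample hypoxia score, group label, and the underlying calls."""

    table: pd.DataFrame          # index sample_id; columns hs, group, n_genes_found
    per_gene_calls: pd.DataFrame | None = None  # genes x samples in {+1,-1}
    signature: str = ""

    @property
    def hs(self) -> pd.Series:
        return self.table["hs"]

    @property
    def group(self) -> pd.Series:
        return self.table["group"]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def score_signature(
    expr: ExpressionMatrix,
    sig: GeneSignature = HYPOXIA_8,
    tie_rule: str = "le_minus",
) -> ScoreTable:
    """Score every sample of a cohort against a hypoxia signature.

    Parameters
    ----------
    expr
        The cohort to score.  Medians are computed on these samples only.
    sig
        Signature gene list; genes absent from ``expr`` are skipped and
        their count logged (cross-platform panels routinely miss symbols).
    tie_rule
        What a value exactly at the median contributes: ``le_minus``
        (default) calls it -1, mirroring the conservative "HS <= 0 is low"
        group rule; ``strict_half`` calls it +1, for sensitivity checks.

    Returns
    -------
    ScoreTable with integer ``hs`` (= column sum of the ±1 call matrix)
    and ``group`` = "high" iff hs > 0.
    """
    if tie_rule not in ("le_minus", "strict_half"):
        raise ValueError(f"unknown tie_rule {tie_rule!r}")
    found = [g for g in sig.genes if g in expr.values.index]
    missing = len(sig.genes) - len(found)
    if not found:
        raise ValueError(
            f"none of the {len(sig.genes)} signature genes of "
            f"{sig.name!r} are present in the expression matrix"
        )
    if missing:
        logger.warning("signature %s: %d gene(s) not found, scoring on %d",
                       sig.name, missing, len(found))
    if expr.shape[1] < 2:
        raise ValueError("median split undefined for a single sample")

    sub = expr.values.loc[found]
    medians = sub.median(axis=1, skipna=True)
    if tie_rule == "le_minus":
        above = sub.gt(medians, axis=0)
    else:
        above = sub.ge(medians, axis=0)
    n_na = int(sub.isna().sum().sum())
    if n_na:
        # missing expression cannot witness induction: conservative -1 call
        logger.warning("signature %s: %d NA expression values called -1",
                       sig.name, n_na)
        above = above & sub.notna()
    calls = above.astype(int) * 2 - 1
    hs = calls.sum(axis=0)
    table = pd.DataFrame(
        {
            "hs": hs.astype(int),
            "group": np.where(hs > 0, "high", "low"),
            "n_genes_found": len(found),
        }
    )
    table.index.name = "sample_id"
    return ScoreTable(table, per_gene_calls=calls, signature=sig.name)


def stratify(scores: ScoreTable) -> ScoreTable:
    """(Re)assign the high/low group labels from the hypoxia scores.

    "high" iff hs > 0; hs == 0 falls in the low group.
    """
    scores.table["group"] = np.where(scores.table["hs"] > 0, "high", "low")
    return scores
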