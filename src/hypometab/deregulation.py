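"""Pathway-deregulation scores from principal curves.

For each gene set, the pathway's expression submatrix is z-scored against
a reference (supplied normal samples, else the whole cohort), reduced by
PCA, and a principal curve is fitted in the reduced space.  A sample's
deregulation score is its arc-length distance from the reference origin
on that curve, min-max normalized so every non-skipped pathway spans
[0, 1].  The higher the score, the further the sample lies from the
reference state along the pathway's principal trajectory.

This is a reimplementation of the concept popularized by the Pathifier
method; it does not attempt bit-compatibility with that tool (no
bootstrap stability filtering, no minimum-spanning-tree sample filter),
because downstream stages consume only the scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .curves import fit_principal_curve, _project_to_polyline
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger("hypometab")


@dataclass(frozen=True)
class DeregulationConfig:
    """Knobs of the deregulation stage.

    min_genes: smallest usable pathway (sets with fewer found genes are
    skipped, not an error).  var_frac/max_pc: keep the smallest number of
    principal components explaining >= var_frac of variance, capped at
    max_pc.  smoother_span, max_iter, tol, min_samples are forwarded to
    the principal-curve fit.
    """

    min_genes: int = 3
    var_frac: float = 0.85
    max_pc: int = 10
    max_iter: int = 10
    tol: float = 1e-4
    smoother_span: float = 0.3
    min_samples: int = 10


@dataclass
class DeregulationMatrix:
    """Pathways x samples deregulation scores in [0, 1]."""

    scores: pd.DataFrame                       # non-skipped pathways only
    skipped: list[tuple[str, str]] = field(default_factory=list)

    @property
    def pathway_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def mean_per_sample(self) -> pd.Series:
        return self.scores.mean(axis=0)


def _fix_component_signs(scores: np.ndarray, loadings: np.ndarray) -> np.ndarray:
    """Flip components so the largest-|loading| gene loads positively."""
    lead = np.abs(loadings).argmax(axis=1)
    signs = np.sign(loadings[np.arange(loadings.shape[0]), lead])
    signs[signs == 0] = 1.0
    return scores * signs


def _reduce(z: np.ndarray, cfg: DeregulationConfig) -> np.ndarray:
    """PCA to the smallest k with cumulative variance >= var_frac."""
    n, g = z.shape
    n_max = min(cfg.max_pc, g, n - 1)
    pca = PCA(n_components=n_max, svd_solver="full")
    scores = pca.fit_transform(z)
    cum = np.cumsum(pca.explained_variance_ratio_)
    k = int(np.searchsorted(cum, cfg.var_frac) + 1)
    k = min(max(k, 1), n_max)
    return _fix_component_signs(scores[:, :k], pca.components_[:k])


def score_pathway(
    expr: ExpressionMatrix,
    genes: list[str],
    normal_ids: list[str] | None = None,
    cfg: DeregulationConfig = DeregulationConfig(),
) -> pd.Series:
    """Deregulation score of one pathway for every sample.

    Raises ``ValueError`` when fewer than ``cfg.min_genes`` pathway genes
    are found (callers scoring a collection catch this and record the
    pathway as skipped).
    """
    found = [g.strip() for g in genes if g.strip() in expr.values.index]
    if len(found) < cfg.min_genes:
        raise ValueError(
            f"insufficient genes: {len(found)} found, "
            f"{cfg.min_genes} required"
        )
    sub = expr.values.loc[found]            # genes x samples
    normals = list(normal_ids or [])
    ref = sub[normals] if normals else sub
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    usable = sd > 0
    if not usable.all():
        logger.warning("dropping %d zero-variance gene(s)",
                       int((~usable).sum()))
        sub, mu, sd = sub[usable], mu[usable], sd[usable]
        if sub.shape[0] < cfg.min_genes:
            raise ValueError(
                f"insufficient genes: {sub.shape[0]} with variance, "
                f"{cfg.min_genes} required"
            )
    z = ((sub.sub(mu, axis=0)).div(sd, axis=0)).to_numpy().T  # samples x genes
    if np.isnan(z).any():
        z = np.nan_to_num(z, nan=0.0)       # NA -> reference mean

    sample_ids = expr.sample_ids
    normal_pos = [sample_ids.index(s) for s in normals] or None
    return pd.Series(scores_from_standardized(z, normal_pos, cfg),
                     index=sample_ids)


def scores_from_standardized(
    z: np.ndarray,
    normal_pos: list[int] | None = None,
    cfg: DeregulationConfig = DeregulationConfig(),
) -> np.ndarray:
    """Deregulation scores from an already-standardized samples x genes
    matrix: PCA reduction, principal-curve fit, arc-length distance from
    the reference origin, min-max normalized.

    The result is invariant (to numerical precision) under orthogonal
    rotation of the gene space, since every step sees only the PCA
    geometry of the point cloud.
    """
    reduced = _reduce(z, cfg)
    curve = fit_principal_curve(
        reduced, max_iter=cfg.max_iter, tol=cfg.tol,
        smoother_span=cfg.smoother_span, min_samples=cfg.min_samples,
    )
    t = curve.projections

    if normal_pos:
        t0 = float(np.median(t[normal_pos]))
    else:
        # no normal reference: anchor at the cohort's median point
        # projected onto the curve
        median_pt = np.median(reduced, axis=0)[None, :]
        t0 = float(
            _project_to_polyline(median_pt, curve.nodes, curve.arclen)[0][0]
        )
    raw = np.abs(t - t0)
    peak = raw.max()
    if peak == 0:
        raise ValueError("degenerate pathway: all samples at the origin")
    return raw / peak


def score_collection(
    expr: ExpressionMatrix,
    gene_sets: GeneSetCollection,
    normal_ids: list[str] | None = None,
    cfg: DeregulationConfig = DeregulationConfig(),
) -> DeregulationMatrix:
    """Score every pathway of a collection; skipped sets are recorded
    (pathway name, reason) instead of aborting the run.  The stage is
    deterministic: same input, same scores, bit for bit."""
    rows: dict[str, pd.Series] = {}
    skipped: list[tuple[str, str]] = []
    for name, (_, genes) in gene_sets:
        try:
            rows[name] = score_pathway(expr, genes, normal_ids, cfg)
        except ValueError as exc:
            logger.warning("pathway %s skipped: %s", name, exc)
            skipped.append((name, str(exc)))
    if not rows:
        raise ValueError("all pathways skipped")
    scores = pd.DataFrame(rows).T
    scores.index.name = "pathway"
    return DeregulationMatrix(scores, skipped)
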