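"""Synthetic breast-tumor cohorts with planted hypoxia-metabolism structure.

The generator plants exactly the statistical structure the analysis
pipeline assumes, with full ground truth, so every stage is testable
without controlled-access data:

* a latent per-sample hypoxia level ``h`` that drives the signature
  genes (both the 8-gene and the Buffa 15-gene panels are emitted);
* three sample types with increasing baseline pathway deregulation
  (M1 < M2 < M3) and an elevated hypoxia mean in M3;
* per-type differences in how many pathways track hypoxia — most in M1,
  fewest in M3 (the fingerprint-breadth pattern), mirrored in a small
  metabolite panel;
* exponential survival whose log-hazard increases with ``h``.

All randomness flows from one seed; the same seed reproduces the cohort
bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ClinicalTable, ExpressionMatrix, GeneSetCollection
from .signatures import BUFFA_15, HYPOXIA_8

TYPE_NAMES = ("M1", "M2", "M3")

#: monthly baseline hazard and censoring horizon giving ~30% events at h=0
_BASE_HAZARD = 0.006
_CENSOR_MAX = 120.0
_LOG_HR_PER_H = 0.4

#: scale of the pathway/metabolite latent positions.  Correlations with h
#: are scale-free, but the type offsets (type_separation) act on the
#: latent's magnitude, so the latent spread fixes how far apart the
#: planted deregulation levels sit relative to within-type variation.
_LATENT_SCALE = 0.5


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generator."""

    h: pd.Series                       # latent hypoxia per sample
    label: pd.Series                   # true type per sample
    coupled_pathways: dict[str, list[str]]   # type -> pathways tracking h
    pathway_latent: pd.DataFrame       # pathways x samples latent positions
    coupled_metabolites: dict[str, list[str]]


@dataclass
class SyntheticCohort:
    expr: ExpressionMatrix
    metabolites: pd.DataFrame          # features x samples
    clinical: ClinicalTable
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def _type_labels(n: int, props: tuple[float, ...], rng) -> np.ndarray:
    """Deterministic largest-remainder counts, then a random permutation."""
    props_arr = np.asarray(props, float)
    if props_arr.min() < 0 or abs(props_arr.sum() - 1.0) > 1e-9:
        raise ValueError("type proportions must be nonnegative and sum to 1")
    raw = props_arr * n
    counts = np.floor(raw).astype(int)
    rem = n - counts.sum()
    counts[np.argsort(-(raw - counts), kind="stable")[:rem]] += 1
    labels = np.repeat(np.arange(len(props)), counts)
    return labels[rng.permutation(n)]


def generate_cohort(
    n_samples: int = 600,
    type_props: tuple[float, float, float] = (0.5, 0.25, 0.25),
    n_pathways: int = 90,
    breadth: tuple[int, int, int] = (30, 18, 7),
    hypoxia_shift_m3: float = 1.0,
    coupling: float = 0.6,
    noise_sd: float = 0.5,
    type_separation: float = 0.25,
    n_metabolites: int = 50,
    seed: int = 1,
) -> SyntheticCohort:
    """Simulate a cohort with planted hypoxia-metabolism crosstalk.

    Parameters
    ----------
    n_samples, type_props
        Cohort size and the M1/M2/M3 mixing proportions.
    n_pathways, breadth
        Number of synthetic metabolic pathways, and how many of them
        track the hypoxia latent within each type (M1, M2, M3).
    hypoxia_shift_m3
        Mean shift of the hypoxia latent in M3 (M1 and M2 sit at 0).
    coupling
        Linear coefficient tying signature genes, coupled pathway
        latents and coupled metabolites to ``h``.
    noise_sd
        Gene-level observation noise (log-expression scale).
    type_separation
        Per-type offset step added to the magnitude of every pathway
        latent (0, step, 2*step for M1, M2, M3) — the planted
        M1 < M2 < M3 deregulation ordering.
    """
    if max(breadth) > n_pathways:
        raise ValueError("breadth values cannot exceed n_pathways")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    type_idx = _type_labels(n_samples, type_props, rng)
    labels = np.array(TYPE_NAMES)[type_idx]

    mu = np.array([0.0, 0.0, hypoxia_shift_m3])[type_idx]
    h = rng.normal(mu, 1.0)

    # signature genes (8-gene panel plus the Buffa genes) track h directly
    sig_genes = list(dict.fromkeys(HYPOXIA_8.genes + BUFFA_15.genes))
    sig_expr = coupling * h + rng.normal(0.0, noise_sd,
                                         size=(len(sig_genes), n_samples))

    # pathways: per-sample latent u, coupled to h for the first
    # breadth[t] pathways of each sample's type
    pw_names = [f"MET_PW_{j + 1:03d}" for j in range(n_pathways)]
    u_noise = np.sqrt(max(1.0 - coupling ** 2, 1e-12))
    coupled_mask = np.zeros((n_pathways, n_samples), bool)
    for t, b in enumerate(breadth):
        coupled_mask[:b, type_idx == t] = True
    u = _LATENT_SCALE * np.where(
        coupled_mask,
        coupling * h[None, :] + rng.normal(0.0, u_noise, (n_pathways, n_samples)),
        rng.normal(0.0, 1.0, (n_pathways, n_samples)),
    )
    offsets = (type_separation * np.arange(3))[type_idx]
    sign = np.where(u >= 0, 1.0, -1.0)
    u = sign * (np.abs(u) + offsets[None, :])

    sets: dict[str, tuple[str, list[str]]] = {}
    pw_rows, pw_gene_names = [], []
    for j, name in enumerate(pw_names):
        size = int(rng.integers(8, 16))
        genes = [f"{name}_G{i + 1:02d}" for i in range(size)]
        loadings = rng.uniform(0.6, 1.0, size)
        pw_rows.append(loadings[:, None] * u[j]
                       + rng.normal(0.0, noise_sd, (size, n_samples)))
        pw_gene_names.extend(genes)
        sets[name] = ("synthetic metabolic pathway", genes)

    expr = pd.DataFrame(
        np.vstack([sig_expr, *pw_rows]),
        index=sig_genes + pw_gene_names,
        columns=samples,
    )

    # metabolites mirror the pathway breadth pattern, scaled to the panel
    met_names = [f"MET_{j + 1:03d}" for j in range(n_metabolites)]
    met_breadth = [int(round(b * n_metabolites / n_pathways)) for b in breadth]
    met_mask = np.zeros((n_metabolites, n_samples), bool)
    for t, b in enumerate(met_breadth):
        met_mask[:b, type_idx == t] = True
    metabolites = pd.DataFrame(
        _LATENT_SCALE * np.where(
            met_mask,
            coupling * h[None, :]
            + rng.normal(0.0, u_noise, (n_metabolites, n_samples)),
            rng.normal(0.0, 1.0, (n_metabolites, n_samples)),
        ),
        index=met_names,
        columns=samples,
    )

    clinical = _simulate_clinical(h, samples, rng)

    truth = SyntheticTruth(
        h=pd.Series(h, index=samples, name="h"),
        label=pd.Series(labels, index=samples, name="label"),
        coupled_pathways={
            TYPE_NAMES[t]: pw_names[: breadth[t]] for t in range(3)
        },
        pathway_latent=pd.DataFrame(u, index=pw_names, columns=samples),
        coupled_metabolites={
            TYPE_NAMES[t]: met_names[: met_breadth[t]] for t in range(3)
        },
    )
    return SyntheticCohort(
        expr=ExpressionMatrix(expr),
        metabolites=metabolites,
        clinical=clinical,
        gene_sets=GeneSetCollection(sets),
        truth=truth,
    )


def _simulate_clinical(h: np.ndarray, samples: list[str], rng) -> ClinicalTable:
    """Exponential survival (log-hazard 0.4*h), uniform censoring, and
    hypoxia-tilted grade plus unrelated stage/PAM50 covariates."""
    n = len(samples)
    cols: dict[str, np.ndarray] = {}
    lam = _BASE_HAZARD * np.exp(_LOG_HR_PER_H * h)
    for endpoint in ("os", "dss", "rfs"):
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(0.0, _CENSOR_MAX, n)
        cols[f"time_{endpoint}"] = np.minimum(t_event, t_cens)
        cols[f"event_{endpoint}"] = (t_event <= t_cens).astype(int)
    # grade leans on h so high-grade tumors carry higher hypoxia scores
    logits = np.stack([np.zeros(n), 0.4 * h, 0.8 * h])
    gumbel = rng.gumbel(size=(3, n))
    cols["grade"] = (np.argmax(logits + gumbel, axis=0) + 1).astype(int)
    cols["stage"] = rng.choice([1, 2, 3, 4], n, p=[0.3, 0.4, 0.2, 0.1])
    cols["pam50"] = rng.choice(
        ["LumA", "LumB", "Her2", "Basal", "Normal"], n,
        p=[0.4, 0.2, 0.15, 0.15, 0.1],
    )
    table = pd.DataFrame(cols, index=pd.Index(samples, name="sample_id"))
    return ClinicalTable(table)


# ---------------------------------------------------------------------------
# worked example: a tiny hand-checkable fixture
# ---------------------------------------------------------------------------

#: 8 signature genes x 10 samples; every row is a permutation of 1..10,
#: so each per-gene cohort median is 5.5 and a call is +1 iff value >= 6.
#: s01 holds every gene's maximum (HS = +8) and s02 every minimum
#: (HS = -8); each of s03..s10 holds each of the values 2..9 exactly once
#: across the eight genes — four values above 5.5, four below — so their
#: HS is 0.
_WORKED_VALUES = [
    # s01 s02 s03 s04 s05 s06 s07 s08 s09 s10
    [10, 1, 2, 3, 4, 5, 6, 7, 8, 9],   # DDIT4
    [10, 1, 3, 4, 5, 6, 7, 8, 9, 2],   # LDHA
    [10, 1, 4, 5, 6, 7, 8, 9, 2, 3],   # MXI1
    [10, 1, 5, 6, 7, 8, 9, 2, 3, 4],   # NDRG1
    [10, 1, 6, 7, 8, 9, 2, 3, 4, 5],   # P4HA1
    [10, 1, 7, 8, 9, 2, 3, 4, 5, 6],   # PGK1
    [10, 1, 8, 9, 2, 3, 4, 5, 6, 7],   # SLC2A1
    [10, 1, 9, 2, 3, 4, 5, 6, 7, 8],   # VEGFA
]

_WORKED_HS = [8, -8, 0, 0, 0, 0, 0, 0, 0, 0]


def generate_worked_example() -> tuple[ExpressionMatrix, pd.DataFrame]:
    """The committed hand-verified scoring fixture.

    Returns the 8x10 expression matrix and its expected score table
    (columns hs, group), both reproducible from the literals above.
    """
    samples = [f"s{i + 1:02d}" for i in range(10)]
    expr = ExpressionMatrix(pd.DataFrame(
        np.asarray(_WORKED_VALUES, float),
        index=list(HYPOXIA_8.genes),
        columns=samples,
    ))
    expected = pd.DataFrame(
        {
            "hs": _WORKED_HS,
            "group": ["high" if v > 0 else "low" for v in _WORKED_HS],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    return expr, expected
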