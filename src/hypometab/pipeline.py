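"""End-to-end orchestration: simulate/ingest -> score -> deregulate ->
type -> correlate -> survive, with a resolved config and a
machine-readable summary written next to every run's outputs.

Stage outputs are pure functions of (inputs, resolved config, seed):
re-running the same config reproduces byte-identical tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as hio
from .associations import correlate, count_significant, fingerprint_breadth
from .deregulation import DeregulationConfig, score_collection
from .metabolic_types import cluster_types, summarize_hs_by_type
from .signatures import load_signature, score_signature
from .survival import cox_ph, encode_covariates, logrank
from .synthetic import generate_cohort

logger = logging.getLogger("hypometab")

SUMMARY_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run (YAML-serializable)."""

    out_dir: str = "hypometab_run"
    # inputs: either simulate=True or paths to expression (+ optional gmt,
    # clinical, normals)
    simulate: bool = False
    n_samples: int = 600
    expr: str | None = None
    orientation: str = "genes_rows"
    gmt: str | None = None
    clinical: str | None = None
    normals: str | None = None
    signature: str = "builtin:8gene"
    tie_rule: str = "le_minus"
    dereg: dict = field(default_factory=dict)     # DeregulationConfig overrides
    k: int = 3
    cluster_method: str = "kmeans"
    alpha: float = 0.05
    multiplicity: str = "none"
    endpoints: tuple[str, ...] = ("os", "dss", "rfs")
    seed: int = 17

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "endpoints" in raw:
            raw["endpoints"] = tuple(raw["endpoints"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["endpoints"] = list(data["endpoints"])
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)


@dataclass
class RunReport:
    stages: dict[str, str]
    summary: dict
    out_dir: Path


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round_floats(obj, ndigits=10):
    """Round floats recursively so the summary JSON is byte-stable."""
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def run_pipeline(cfg: RunConfig) -> RunReport:
    """Execute the full analysis; stages whose inputs are absent are
    marked "skipped" in the report rather than failing the run."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    stages: dict[str, str] = {}
    summary: dict = {"schema_version": SUMMARY_SCHEMA_VERSION,
                     "seed": cfg.seed}
    try:
        # ---- inputs -----------------------------------------------------
        stage = "input"
        try:
            normals = None
            clinical = None
            gene_sets = None
            if cfg.simulate:
                cohort = generate_cohort(n_samples=cfg.n_samples, seed=cfg.seed)
                expr, clinical, gene_sets = (
                    cohort.expr, cohort.clinical, cohort.gene_sets
                )
                hio.write_table(expr, out / "expr.tsv")
                hio.write_table(clinical, out / "clinical.tsv")
                hio.write_gmt(gene_sets, out / "pathways.gmt")
                hio.write_table(cohort.metabolites, out / "metabolites.tsv",
                                index_label="metabolite")
                truth = cohort.truth.label.to_frame().assign(h=cohort.truth.h)
                hio.write_table(truth, out / "truth.tsv",
                                index_label="sample_id")
            else:
                if not cfg.expr:
                    raise ValueError("config has neither simulate=true nor "
                                     "an expression path")
                expr = hio.read_expression(cfg.expr, cfg.orientation)
                if cfg.gmt:
                    gene_sets = hio.read_gmt(cfg.gmt)
                if cfg.clinical:
                    clinical = hio.read_clinical(cfg.clinical)
                if cfg.normals:
                    with open(cfg.normals, encoding="utf-8") as fh:
                        normals = [s.strip() for s in fh if s.strip()]
            stages[stage] = "ok"
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- hypoxia scoring -------------------------------------------
        stage = "score"
        try:
            scores = score_signature(
                expr, load_signature(cfg.signature), tie_rule=cfg.tie_rule
            )
            hio.write_table(scores, out / "scores.tsv")
            counts = scores.group.value_counts()
            summary["hs_groups"] = {
                "n_high": int(counts.get("high", 0)),
                "n_low": int(counts.get("low", 0)),
            }
            stages[stage] = "ok"
        except Exception as exc:
            raise StageError(stage, exc) from exc

        # ---- pathway deregulation --------------------------------------
        stage = "deregulate"
        dereg = None
        if gene_sets is None:
            stages[stage] = "skipped"
            logger.info("no gene sets supplied: deregulation stage skipped")
        else:
            try:
                dereg = score_collection(
                    expr, gene_sets, normals, DeregulationConfig(**cfg.dereg)
                )
                hio.write_table(dereg.scores, out / "dereg.tsv",
                                index_label="pathway")
                hio.write_table(
                    pd.DataFrame(dereg.skipped,
                                 columns=["pathway", "reason"])
                    .set_index("pathway"),
                    out / "skipped.tsv", index_label="pathway",
                )
                stages[stage] = "ok"
            except Exception as exc:
                raise StageError(stage, exc) from exc

        # ---- metabolic typing ------------------------------------------
        stage = "type"
        assign = None
        if dereg is None:
            stages[stage] = "skipped"
        else:
            try:
                assign = cluster_types(
                    dereg, k=cfg.k, method=cfg.cluster_method, seed=cfg.seed
                )
                hio.write_table(assign, out / "types.tsv")
                per_type, comparison = summarize_hs_by_type(scores, assign)
                hio.write_table(per_type, out / "hs_by_type.tsv",
                                index_label="label")
                summary["hs_by_type"] = {
                    lab: {"mean_hs": float(row["mean_hs"]),
                          "sem_hs": float(row["sem_hs"]),
                          "n": int(row["n"])}
                    for lab, row in per_type.iterrows()
                }
                summary["hs_by_type_test"] = {
                    "test": comparison.test, "p": float(comparison.p)
                }
                stages[stage] = "ok"
            except Exception as exc:
                raise StageError(stage, exc) from exc

        # ---- correlation fingerprint -----------------------------------
        stage = "correlate"
        if dereg is None:
            stages[stage] = "skipped"
        else:
            try:
                fp = correlate(scores, dereg.scores, groups=assign,
                               alpha=cfg.alpha, multiplicity=cfg.multiplicity)
                hio.write_table(fp.records.set_index("stratum"),
                                out / "fingerprint.tsv", index_label="stratum")
                counts = count_significant(fp)
                summary["fingerprint_counts"] = {
                    str(s): {"positive": int(row["n_positive"]),
                             "negative": int(row["n_negative"])}
                    for s, row in counts.iterrows()
                }
                breadth = fingerprint_breadth(fp)
                summary["fingerprint_breadth_order"] = list(breadth.index)
                stages[stage] = "ok"
            except Exception as exc:
                raise StageError(stage, exc) from exc

        # ---- survival ---------------------------------------------------
        stage = "survive"
        if clinical is None:
            stages[stage] = "skipped"
            logger.info("no clinical table: survival stage skipped")
        else:
            try:
                summary["survival"] = {}
                rows = []
                for ep in cfg.endpoints:
                    try:
                        time, event = clinical.endpoint(ep)
                    except KeyError:
                        continue
                    shared = time.index.intersection(scores.table.index)
                    grp = scores.table.loc[shared, "group"]
                    chi2, p = logrank(time.loc[shared], event.loc[shared], grp)
                    design = encode_covariates(clinical, scores,
                                               covariates=())
                    design = design.loc[design.index.intersection(shared)]
                    cox = cox_ph(time.loc[design.index],
                                 event.loc[design.index], design)
                    summary["survival"][ep] = {
                        "logrank_chi2": float(chi2),
                        "logrank_p": float(p),
                        "cox_hr_hs_high": float(cox.table.loc["hs_high", "hr"]),
                        "cox_p_hs_high": float(cox.table.loc["hs_high", "p"]),
                        "n_events": cox.n_events,
                    }
                    rows.append({"endpoint": ep, "logrank_chi2": chi2,
                                 "logrank_p": p,
                                 "cox_hr_hs_high": cox.table.loc["hs_high", "hr"],
                                 "cox_p_hs_high": cox.table.loc["hs_high", "p"]})
                if rows:
                    hio.write_table(
                        pd.DataFrame(rows).set_index("endpoint"),
                        out / "survival_report.tsv", index_label="endpoint",
                    )
                    stages[stage] = "ok"
                else:
                    stages[stage] = "skipped"
            except Exception as exc:
                raise StageError(stage, exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()

    summary["stages"] = stages
    cfg.to_yaml(out / "config.yaml")
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(_round_floats(summary), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return RunReport(stages=stages, summary=summary, out_dir=out)
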