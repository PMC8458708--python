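"""Tabular IO, pipeline configuration and stage orchestration.

Conventions: tab-separated for matrices and MAF-like tables, comma accepted
for small tables (sniffed from the .tsv/.csv extension); UTF-8; '.' decimal;
missing values as empty strings.  JSON result documents report proportions
in [0, 1] — percentages appear only in human-readable text output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .alterations import (
    AlterationRecord,
    DriverCatalog,
    eligible_driver_genes,
    filter_drivers,
    flag_driver_enriched,
    total_target_mutational_load,
)
from .correlation import (
    pairwise_correlation,
    rank_cancers_by_correlation,
    summarize_correlation,
)
from .expression import ExpressionMatrix, classify_expression, differential_expression
from .immune import (
    InfiltrationTable,
    SurvivalRecord,
    cd8_box_flag,
    cox_classify,
    gene_infiltration_correlation,
    suppressive_box_flag,
)
from .integrate import build_evidence, build_evidence_from_criteria, candidates
from .meta import ProportionMetaAnalysis, StudyRecord
from .panel import DEFAULT_PANEL, TargetPanel

logger = logging.getLogger("lenvicb")


def _sep(path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


# ---------------------------------------------------------------- study table


def read_study_table(path) -> list[StudyRecord]:
    """Read cohort records; requires columns study_id, tumor_type, n, orr_pct.

    ``dcr_pct`` and any extra columns are optional; blank percentage cells
    become missing endpoints.  Malformed rows raise with their row number.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = {"study_id", "tumor_type", "n", "orr_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    if df.empty:
        raise ValueError(f"{path}: no cohort rows")
    records = []
    for i, row in df.iterrows():
        def num(col, kind=float):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)) or str(v).strip() == "":
                return None
            try:
                return kind(v)
            except ValueError as exc:
                raise ValueError(f"{path} row {i + 2}: bad {col}={v!r}") from exc

        n = num("n", int)
        if n is None:
            raise ValueError(f"{path} row {i + 2}: missing n")
        records.append(
            StudyRecord(
                study_id=str(row["study_id"]),
                tumor_type=str(row["tumor_type"]),
                n=n,
                orr_pct=num("orr_pct"),
                dcr_pct=num("dcr_pct") if "dcr_pct" in df.columns else None,
            )
        )
    return records


def write_study_table(records: list[StudyRecord], path) -> None:
    rows = [
        {
            "study_id": r.study_id,
            "tumor_type": r.tumor_type,
            "n": r.n,
            "orr_pct": "" if r.orr_pct is None else r.orr_pct,
            "dcr_pct": "" if r.dcr_pct is None else r.dcr_pct,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep=_sep(path), index=False)


def load_bundled_study_table() -> list[StudyRecord]:
    """The bundled 20-cohort combination-therapy trial table."""
    ref = resources.files("lenvicb.data") / "combination_trials.tsv"
    with resources.as_file(ref) as p:
        return read_study_table(p)


def load_published_criteria() -> dict:
    """The bundled per-characteristic cancer lists from the published analyses."""
    ref = resources.files("lenvicb.data") / "published_criteria.json"
    return json.loads(ref.read_text(encoding="utf-8"))


# ------------------------------------------------------------- expression IO


def read_expression(matrix_path, annotation_path, cancer_type: str) -> ExpressionMatrix:
    """Wide matrix (first column gene, others samples) + sample/condition annotation."""
    mat = pd.read_csv(matrix_path, sep=_sep(matrix_path), index_col=0)
    ann = pd.read_csv(annotation_path, sep=_sep(annotation_path), dtype=str)
    cond = dict(zip(ann["sample"], ann["condition"]))
    missing = [s for s in mat.columns if s not in cond]
    if missing:
        raise ValueError(f"{annotation_path}: unannotated samples {missing[:5]}")
    return ExpressionMatrix(
        cancer_type=cancer_type,
        genes=[str(g) for g in mat.index],
        samples=[str(s) for s in mat.columns],
        values=mat.to_numpy(dtype=float),
        condition=[cond[s] for s in mat.columns],
    )


def write_expression(matrix: ExpressionMatrix, matrix_path, annotation_path) -> None:
    matrix.to_frame().to_csv(matrix_path, sep=_sep(matrix_path), float_format="%.10g")
    pd.DataFrame({"sample": matrix.samples, "condition": matrix.condition}).to_csv(
        annotation_path, sep=_sep(annotation_path), index=False
    )


# ------------------------------------------------------------- alteration IO


def read_alterations(path) -> list[AlterationRecord]:
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    out = []
    for _, row in df.iterrows():
        pc = row.get("protein_change")
        out.append(
            AlterationRecord(
                sample_id=str(row["sample_id"]),
                cancer_type=str(row["cancer_type"]),
                gene=DEFAULT_PANEL.resolve_symbol(str(row["gene"])),
                alteration_class=str(row["alteration_class"]),
                protein_change=None if pc is None or pd.isna(pc) or pc == "" else str(pc),
            )
        )
    return out


def write_alterations(records: list[AlterationRecord], path) -> None:
    pd.DataFrame(
        [
            {**dataclasses.asdict(r), "protein_change": r.protein_change or ""}
            for r in records
        ]
    ).to_csv(path, sep=_sep(path), index=False)


def read_profiled_counts(path) -> dict[str, int]:
    df = pd.read_csv(path, sep=_sep(path))
    return {str(r["cancer_type"]): int(r["profiled"]) for _, r in df.iterrows()}


def write_profiled_counts(counts: dict[str, int], path) -> None:
    pd.DataFrame(
        [{"cancer_type": c, "profiled": n} for c, n in sorted(counts.items())]
    ).to_csv(path, sep=_sep(path), index=False)


def read_driver_catalog(path) -> DriverCatalog:
    return DriverCatalog.from_frame(pd.read_csv(path, sep=_sep(path), dtype=str))


def write_driver_catalog(catalog: DriverCatalog, path) -> None:
    catalog.to_frame().to_csv(path, sep=_sep(path), index=False)


# ------------------------------------------------------ infiltration/survival


def read_infiltration(path, cancer_type: str) -> InfiltrationTable:
    """Sample x cell-type table; an optional 'purity' column is split off."""
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    purity = None
    if "purity" in df.columns:
        purity = df.pop("purity").to_numpy(dtype=float)
    return InfiltrationTable(
        cancer_type=cancer_type,
        samples=[str(s) for s in df.index],
        cell_types=[str(c) for c in df.columns],
        values=df.to_numpy(dtype=float),
        purity=purity,
    )


def write_infiltration(table: InfiltrationTable, path) -> None:
    table.to_frame().to_csv(path, sep=_sep(path), float_format="%.10g")


def read_survival(path) -> list[SurvivalRecord]:
    df = pd.read_csv(path, sep=_sep(path))
    return [
        SurvivalRecord(
            sample_id=str(r["sample_id"]),
            time=float(r["time"]),
            event=int(r["event"]),
            covariate=float(r["covariate"]),
        )
        for _, r in df.iterrows()
    ]


def write_survival(records: list[SurvivalRecord], path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(
        path, sep=_sep(path), index=False, float_format="%.10g"
    )


# ------------------------------------------------------------------ pipeline


@dataclass
class PipelineConfig:
    """All tunables, defaulting to the published thresholds.

    Input paths left as None disable the corresponding stage; integration
    runs on whatever flags the enabled stages produce (missing = false).
    """

    outdir: str = "lenvicb_out"
    seed: int = 0
    # inputs
    study_table: str | None = None
    expression_dir: str | None = None  # <C>_expression.tsv + <C>_samples.tsv pairs
    alterations: str | None = None
    profiled_counts: str | None = None
    driver_catalog: str | None = None
    infiltration_dir: str | None = None  # <C>_infiltration.csv (+ <C>_survival.csv)
    criteria_json: str | None = None  # direct integration input, bypasses stages
    # analysis settings (published defaults)
    alpha: float = 0.05
    positive_r: float = 0.1
    strong_r: float = 0.15
    lenv_driver_threshold: float = 0.09
    pdl1_driver_threshold: float = 0.02
    top_m: int = 16
    transform: str = "double_arcsine"
    ci_level: float = 0.95
    i2_threshold: float = 50.0
    pan_cancer_mode: str = "pooled"
    correlation_method: str = "spearman"

    def __post_init__(self) -> None:
        for name in ("positive_r", "strong_r", "lenv_driver_threshold", "pdl1_driver_threshold"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0,1]")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls(**(data or {}))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_json(obj, path) -> None:
    Path(path).write_text(
        json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n",
        encoding="utf-8",
    )


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and write all outputs.

    Returns the manifest (also written to ``<outdir>/manifest.json``): stage
    status, row counts, thresholds used, config hash and seed.  A stage
    failure is recorded and skipped; integration still runs on available
    flags.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    panel = DEFAULT_PANEL
    cfg_dict = dataclasses.asdict(config)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "config": cfg_dict,
        "config_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest()[:16],
        "stages": {},
    }

    expression_high: set[str] = set()
    load_top: set[str] = set()
    lenv_high: set[str] = set()
    pdl1_high: set[str] = set()
    cd8_set: set[str] = set()
    seen_cancers: set[str] = set()

    def stage(name):
        def deco(fn):
            try:
                info = fn() or {}
                manifest["stages"][name] = {"status": "ok", **info}
                logger.info("stage %s ok: %s", name, info)
            except Exception as exc:
                manifest["stages"][name] = {"status": "failed", "error": str(exc)}
                logger.warning("stage %s failed: %s", name, exc)
            return fn

        return deco

    if config.study_table:
        @stage("meta")
        def _meta():
            studies = read_study_table(config.study_table)
            info = {"n_cohorts": len(studies)}
            for endpoint in ("ORR", "DCR"):
                try:
                    res = ProportionMetaAnalysis(
                        studies,
                        endpoint=endpoint,
                        transform=config.transform,
                        i2_threshold=config.i2_threshold,
                        ci_level=config.ci_level,
                    ).fit()
                except ValueError:
                    continue
                _write_json(res.to_dict(), out / f"meta_{endpoint.lower()}.json")
                res.forest_data().to_csv(
                    out / f"forest_{endpoint.lower()}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.10g",
                )
                info[endpoint] = round(res.estimate, 4)
            return info

    expr_matrices: dict[str, ExpressionMatrix] = {}
    if config.expression_dir:
        @stage("expression")
        def _expr():
            edir = Path(config.expression_dir)
            cats = {}
            for mpath in sorted(edir.glob("*_expression.tsv")):
                cancer = mpath.name.rsplit("_expression.tsv", 1)[0]
                em = read_expression(mpath, edir / f"{cancer}_samples.tsv", cancer)
                expr_matrices[cancer] = em
                seen_cancers.add(cancer)
                results = differential_expression(em, alpha=config.alpha)
                pd.DataFrame([r.__dict__ for r in results]).to_csv(
                    out / f"expression_de_{cancer}.tsv", sep="\t", index=False,
                    float_format="%.10g",
                )
                cat = classify_expression(results, panel, cancer)
                cats[cancer] = {
                    "lenv_up": cat.lenv_up_count,
                    "icb_up": cat.icb_up_count,
                    "category": cat.category,
                }
                if cat.category == "high":
                    expression_high.add(cancer)
            if not cats:
                raise FileNotFoundError(f"no *_expression.tsv under {edir}")
            _write_json(cats, out / "expression_categories.json")
            return {"n_cancers": len(cats), "alpha": config.alpha}

        @stage("correlation")
        def _corr():
            summaries = []
            for cancer, em in sorted(expr_matrices.items()):
                cm = pairwise_correlation(em, panel)
                cm.to_frame().to_csv(out / f"correlation_{cancer}.tsv", sep="\t",
                                     float_format="%.10g")
                summaries.append(
                    summarize_correlation(cm, config.positive_r, config.strong_r)
                )
            ranked = rank_cancers_by_correlation(summaries)
            pd.DataFrame(
                [
                    {
                        "cancer_type": s.cancer_type,
                        "positive_pairs": s.positive_pair_count,
                        "group": s.group,
                    }
                    for s in ranked
                ]
            ).to_csv(out / "correlation_ranking.tsv", sep="\t", index=False)
            return {"n_cancers": len(ranked), "positive_r": config.positive_r}

    if config.alterations and config.profiled_counts and config.driver_catalog:
        @stage("alterations")
        def _alt():
            records = read_alterations(config.alterations)
            profiled = read_profiled_counts(config.profiled_counts)
            catalog = read_driver_catalog(config.driver_catalog)
            seen_cancers.update(profiled)
            drivers = filter_drivers(records, catalog)
            flags = flag_driver_enriched(
                drivers, panel, profiled,
                config.lenv_driver_threshold, config.pdl1_driver_threshold,
            )
            flags.to_csv(out / "driver_frequencies.tsv", sep="\t", index=False,
                         float_format="%.10g")
            load_table, top = total_target_mutational_load(
                records, panel, profiled, m=config.top_m
            )
            load_table.to_csv(out / "mutational_load.tsv", sep="\t", index=False,
                              float_format="%.10g")
            lenv_high.update(
                flags.loc[flags["lenvatinib_driver_high"], "cancer_type"]
            )
            pdl1_high.update(flags.loc[flags["pdl1_driver_high"], "cancer_type"])
            load_top.update(top)
            _write_json(
                {
                    "lenvatinib_driver_high": sorted(lenv_high),
                    "pdl1_driver_high": sorted(pdl1_high),
                    "top_mutational_load": top,
                },
                out / "alteration_flags.json",
            )
            return {
                "n_records": len(records),
                "n_drivers": len(drivers),
                "n_dropped_vus": len(records) - len(drivers),
                "thresholds": [config.lenv_driver_threshold, config.pdl1_driver_threshold],
            }

    if config.infiltration_dir:
        @stage("immune")
        def _immune():
            idir = Path(config.infiltration_dir)
            rows, calls = [], []
            n_cancers = 0
            for ipath in sorted(idir.glob("*_infiltration.csv")):
                cancer = ipath.name.rsplit("_infiltration.csv", 1)[0]
                if cancer not in expr_matrices:
                    continue
                n_cancers += 1
                seen_cancers.add(cancer)
                infil = read_infiltration(ipath, cancer)
                corrs = gene_infiltration_correlation(
                    expr_matrices[cancer], infil, panel, method=config.correlation_method
                )
                for c in corrs:
                    rows.append({"cancer_type": cancer, **dataclasses.asdict(c)})
                by_cell: dict[str, list[float]] = {}
                for c in corrs:
                    by_cell.setdefault(c.cell_type, []).append(c.r)
                if "CD8_T" in by_cell and cd8_box_flag(by_cell["CD8_T"]):
                    cd8_set.add(cancer)
                spath = idir / f"{cancer}_survival.csv"
                if spath.exists():
                    call = cox_classify(read_survival(spath), cancer, "infiltration")
                    calls.append(dataclasses.asdict(call))
            if n_cancers == 0:
                raise FileNotFoundError(
                    f"no *_infiltration.csv under {idir} matching an expression matrix"
                )
            pd.DataFrame(rows).to_csv(out / "immune_correlations.tsv", sep="\t",
                                      index=False, float_format="%.10g")
            _write_json({"cd8_negative": sorted(cd8_set)}, out / "immune_flags.json")
            if calls:
                pd.DataFrame(calls).to_csv(out / "prognostic_calls.tsv", sep="\t",
                                           index=False, float_format="%.10g")
            return {"n_cancers": n_cancers, "n_survival_fits": len(calls)}

    @stage("integration")
    def _integrate():
        if config.criteria_json:
            criteria = json.loads(Path(config.criteria_json).read_text(encoding="utf-8"))
            evidence = build_evidence_from_criteria(criteria)
        else:
            evidence = build_evidence(
                expression_high, load_top, lenv_high, cd8_set,
                pdl1_driver_high=pdl1_high, cancers=seen_cancers,
            )
        evidence.to_csv(out / "evidence.tsv", sep="\t", index=False)
        cands = candidates(evidence)
        _write_json({"candidates": cands, "n_candidates": len(cands)},
                    out / "candidates.json")
        return {"n_cancers": len(evidence), "n_candidates": len(cands)}

    _write_json(manifest, out / "manifest.json")
    return manifest
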