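"""Seeded generators for TCGA-portal-like inputs to every pipeline stage.

Real inputs to this pipeline are extracts from pan-cancer web portals
(expression matrices, alteration tables, immune-infiltration scores,
survival tables).  These generators emulate their statistical structure so
that the full pipeline can run and be tested without any download:

- expression: log-normal values; normal-tissue log2 levels are Gaussian
  with per-gene locations, tumor samples are shifted by log2(fold_change),
  and a Gaussian copula plants the requested inter-gene correlation;
- alterations: per-sample Bernoulli events per (gene, alteration class);
  a configurable fraction of the generated (gene, protein_change) keys is
  entered in the driver catalog, the remainder stay VUS;
- infiltration: each cell type's score is softplus(linear combination of
  standardized gene log-expression + Gaussian noise), optionally
  renormalised across cell types;
- survival: exponential times with log-hazard linear in the standardized
  infiltration of a designated cell type, with independent exponential
  censoring;
- study table: per-cohort true proportions from a logit-normal
  distribution around a common response rate (between-study variance
  tau^2), binomial event draws, percentages derived.

All randomness flows from one master seed: child generators are derived
with ``numpy.random.SeedSequence([master_seed, stream_index])`` where the
stream indices are fixed per module (0 expression, 1 alterations,
2 infiltration/survival, 3 study table), so each stage can be regenerated
independently and reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .alterations import AlterationRecord, DriverCatalog
from .expression import ExpressionMatrix
from .immune import InfiltrationTable, SurvivalRecord
from .meta import StudyRecord
from .panel import DEFAULT_PANEL, TargetPanel

_STREAMS = {"expression": 0, "alterations": 1, "infiltration": 2, "study_table": 3}


def _rng(seed: int, stream: str, extra: int = 0) -> np.random.Generator:
    return np.random.Generator(
        np.random.PCG64(np.random.SeedSequence([int(seed), _STREAMS[stream], int(extra)]))
    )


@dataclass
class CancerSimConfig:
    """Generator settings for one synthetic cancer type."""

    cancer_type: str
    n_tumor: int = 60
    n_normal: int = 30
    # per-gene location of log2 expression in normal tissue; unlisted genes use base_loc
    base_loc: float = 5.0
    base_scale: float = 1.5
    gene_loc: dict[str, float] = field(default_factory=dict)
    # multiplicative tumor shift per gene (1.0 = no differential expression)
    fold_changes: dict[str, float] = field(default_factory=dict)
    # planted inter-gene correlation (uniform off-diagonal); per-pair overrides allowed
    gene_rho: float = 0.0
    pair_rho: dict[tuple[str, str], float] = field(default_factory=dict)
    # (gene, class) -> per-sample alteration probability
    alteration_rates: dict[tuple[str, str], float] = field(default_factory=dict)
    driver_fraction: float = 1.0
    # cell_type -> (gene -> weight, noise sd); scores built on standardized log expression
    infiltration_link: dict[str, tuple[dict[str, float], float]] = field(default_factory=dict)
    normalize_fractions: bool = False
    # survival: exponential baseline, log-hazard slope on one cell's standardized score
    survival_cell: str | None = None
    baseline_rate: float = 0.05
    log_hazard_coef: float = 0.0
    censoring_rate: float = 0.02


@dataclass
class SimulationConfig:
    """Master configuration: one seed, one entry per synthetic cancer."""

    seed: int
    cancers: list[CancerSimConfig]
    panel: TargetPanel = field(default_factory=lambda: DEFAULT_PANEL)

    def __post_init__(self) -> None:
        for c in self.cancers:
            for (g1, g2), rho in c.pair_rho.items():
                if not -1.0 <= rho <= 1.0:
                    raise ValueError(f"pair_rho[{g1},{g2}]={rho} outside [-1,1]")
            for key, rate in c.alteration_rates.items():
                if not 0.0 <= rate <= 1.0:
                    raise ValueError(f"alteration rate {key}={rate} outside [0,1]")
            if not 0.0 <= c.driver_fraction <= 1.0:
                raise ValueError("driver_fraction outside [0,1]")


def _correlation_matrix(genes: list[str], cfg: CancerSimConfig) -> np.ndarray:
    g = len(genes)
    corr = np.full((g, g), cfg.gene_rho)
    np.fill_diagonal(corr, 1.0)
    idx = {gene: i for i, gene in enumerate(genes)}
    for (g1, g2), rho in cfg.pair_rho.items():
        if g1 in idx and g2 in idx:
            corr[idx[g1], idx[g2]] = corr[idx[g2], idx[g1]] = rho
    # validate positive semi-definiteness up front
    eigmin = float(np.linalg.eigvalsh(corr).min())
    if eigmin < -1e-10:
        raise ValueError(f"planted gene correlation matrix is not PSD (min eig {eigmin:.3g})")
    return corr


def generate_expression(config: SimulationConfig) -> dict[str, ExpressionMatrix]:
    """One tumor+normal expression matrix per configured cancer (deterministic per seed)."""
    out: dict[str, ExpressionMatrix] = {}
    genes = sorted(config.panel.all_targets)
    for ci, cfg in enumerate(config.cancers):
        rng = _rng(config.seed, "expression", ci)
        corr = _correlation_matrix(genes, cfg)
        loc = np.array([cfg.gene_loc.get(g, cfg.base_loc) for g in genes])
        shift = np.log2([cfg.fold_changes.get(g, 1.0) for g in genes])
        L = np.linalg.cholesky(corr + 1e-12 * np.eye(len(genes)))
        def draw(n: int, mean: np.ndarray) -> np.ndarray:
            z = rng.standard_normal((len(genes), n))
            logv = mean[:, None] + cfg.base_scale * (L @ z)
            return np.maximum(np.exp2(logv) - 1.0, 0.0)  # invert log2(x+1)
        values = np.concatenate([draw(cfg.n_tumor, loc + shift), draw(cfg.n_normal, loc)], axis=1)
        samples = [f"{cfg.cancer_type}-T{i:03d}" for i in range(cfg.n_tumor)] + [
            f"{cfg.cancer_type}-N{i:03d}" for i in range(cfg.n_normal)
        ]
        condition = ["tumor"] * cfg.n_tumor + ["normal"] * cfg.n_normal
        out[cfg.cancer_type] = ExpressionMatrix(
            cfg.cancer_type, list(genes), samples, values, condition
        )
    return out


def generate_alterations(
    config: SimulationConfig,
) -> tuple[list[AlterationRecord], DriverCatalog, dict[str, int]]:
    """Bernoulli alteration events, a driver catalog covering ``driver_fraction``
    of the generated (gene, protein_change) keys, and profiled counts."""
    records: list[AlterationRecord] = []
    catalog = DriverCatalog()
    profiled: dict[str, int] = {}
    for ci, cfg in enumerate(config.cancers):
        rng = _rng(config.seed, "alterations", ci)
        profiled[cfg.cancer_type] = cfg.n_tumor
        for (gene, alt_class), rate in sorted(cfg.alteration_rates.items()):
            gene = config.panel.resolve_symbol(gene)
            hits = rng.random(cfg.n_tumor) < rate
            is_driver_key = rng.random() < cfg.driver_fraction
            change = f"{gene[0]}{100 + (hash(gene) % 400)}X" if alt_class == "missense" else None
            for si in np.flatnonzero(hits):
                records.append(
                    AlterationRecord(
                        sample_id=f"{cfg.cancer_type}-T{si:03d}",
                        cancer_type=cfg.cancer_type,
                        gene=gene,
                        alteration_class=alt_class,
                        protein_change=change,
                    )
                )
            if is_driver_key and hits.any():
                if change is not None:
                    catalog.add_change(gene, change)
                else:
                    catalog.add_class(gene, alt_class)
    return records, catalog, profiled


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.log1p(np.exp(-np.abs(x))) + np.maximum(x, 0.0)


def generate_infiltration_and_survival(
    config: SimulationConfig, expression: dict[str, ExpressionMatrix]
) -> tuple[dict[str, InfiltrationTable], dict[str, list[SurvivalRecord]]]:
    """Cell scores linked linearly (plus noise) to gene log-expression, and
    exponential survival with log-hazard linear in one cell's score."""
    infil: dict[str, InfiltrationTable] = {}
    surv: dict[str, list[SurvivalRecord]] = {}
    for ci, cfg in enumerate(config.cancers):
        if not cfg.infiltration_link:
            continue
        rng = _rng(config.seed, "infiltration", ci)
        em = expression[cfg.cancer_type]
        tmask = em.tumor_mask()
        samples = [s for s, m in zip(em.samples, tmask) if m]
        logv = em.log_values()[:, tmask]
        z = (logv - logv.mean(axis=1, keepdims=True)) / np.where(
            logv.std(axis=1, keepdims=True) == 0, 1.0, logv.std(axis=1, keepdims=True)
        )
        gidx = {g: i for i, g in enumerate(em.genes)}
        cell_types = sorted(cfg.infiltration_link)
        cols = []
        for cell in cell_types:
            weights, noise_sd = cfg.infiltration_link[cell]
            lin = np.zeros(len(samples))
            for gene, w in weights.items():
                lin += w * z[gidx[config.panel.resolve_symbol(gene)]]
            cols.append(_softplus(lin + noise_sd * rng.standard_normal(len(samples))))
        values = np.column_stack(cols)
        if cfg.normalize_fractions:
            values = values / values.sum(axis=1, keepdims=True)
        infil[cfg.cancer_type] = InfiltrationTable(cfg.cancer_type, samples, cell_types, values)

        if cfg.survival_cell is not None:
            j = cell_types.index(cfg.survival_cell)
            cov = values[:, j]
            zc = (cov - cov.mean()) / (cov.std() if cov.std() > 0 else 1.0)
            hazard = cfg.baseline_rate * np.exp(cfg.log_hazard_coef * zc)
            t_event = rng.exponential(1.0 / hazard)
            if cfg.censoring_rate > 0:
                t_cens = rng.exponential(1.0 / cfg.censoring_rate, size=len(samples))
            else:
                t_cens = np.full(len(samples), np.inf)
            surv[cfg.cancer_type] = [
                SurvivalRecord(
                    sample_id=s,
                    time=float(min(te, tc)),
                    event=int(te <= tc),
                    covariate=float(c),
                )
                for s, te, tc, c in zip(samples, t_event, t_cens, cov)
            ]
    return infil, surv


def generate_study_table(
    true_p: float,
    tau2: float,
    k: int,
    n_range: tuple[int, int] = (20, 200),
    seed: int = 0,
    endpoint_gap: float = 0.0,
) -> list[StudyRecord]:
    """Cohort table with logit-normal between-study heterogeneity.

    Per cohort: logit(p_i) ~ Normal(logit(true_p), tau2); events are
    binomial(n_i, p_i); ORR% derives from the events.  DCR% is generated
    the same way around ``min(true_p + endpoint_gap, 1)`` when
    ``endpoint_gap > 0``, otherwise left missing.
    """
    if not 0.0 <= true_p <= 1.0:
        raise ValueError("true_p outside [0,1]")
    if k < 1:
        raise ValueError("k must be >= 1")
    rng = _rng(seed, "study_table")

    def draw_pct(p0: float, n: int) -> float:
        if p0 <= 0.0:
            return 0.0
        if p0 >= 1.0:
            return 100.0
        logit = np.log(p0 / (1 - p0)) + np.sqrt(tau2) * rng.standard_normal()
        p_i = 1.0 / (1.0 + np.exp(-logit))
        return 100.0 * rng.binomial(n, p_i) / n

    records = []
    for i in range(k):
        n = int(rng.integers(n_range[0], n_range[1] + 1))
        orr = draw_pct(true_p, n)
        dcr = draw_pct(min(true_p + endpoint_gap, 1.0), n) if endpoint_gap > 0 else None
        records.append(
            StudyRecord(
                study_id=f"SIM{i:02d}",
                tumor_type=f"C{i % 10}",
                n=n,
                orr_pct=float(orr),
                dcr_pct=None if dcr is None else float(dcr),
            )
        )
    return records


def example_config(seed: int, n_tumor: int = 60, n_normal: int = 30) -> SimulationConfig:
    """A two-cancer demonstration scenario: one planted positive, one null.

    ``SYNPOS`` carries every treatment-related characteristic: a strong
    tumor up-shift on six lenvatinib and three ICB targets, lenvatinib-set
    driver alterations above the 9% flag threshold plus a CD274
    amplification above 2%, a strongly negative lenvatinib-gene link to
    CD8_T infiltration, and Treg infiltration that raises the hazard
    (log-hazard slope 0.7).  ``SYNNEG`` is null everywhere: no expression
    shift, near-zero alteration rates, noise-only infiltration, zero
    hazard slope.
    """
    up_lenv = {"KDR": 4.0, "FGFR1": 4.0, "FGFR2": 4.0, "FGFR3": 4.0, "PDGFRB": 4.0, "RET": 4.0}
    up_icb = {"PDCD1": 3.0, "CD274": 3.0, "CTLA4": 3.0}
    lenv_genes = sorted(DEFAULT_PANEL.lenvatinib_targets)
    cd8_link = {g: -0.45 for g in lenv_genes}
    treg_link = {g: +0.45 for g in lenv_genes}
    pos = CancerSimConfig(
        cancer_type="SYNPOS",
        n_tumor=n_tumor,
        n_normal=n_normal,
        fold_changes={**up_lenv, **up_icb},
        alteration_rates={
            ("FGFR3", "missense"): 0.08,
            ("KDR", "missense"): 0.05,
            ("FGFR1", "amplification"): 0.04,
            ("CD274", "amplification"): 0.04,
        },
        driver_fraction=1.0,
        infiltration_link={
            "CD8_T": (cd8_link, 0.4),
            "Treg": (treg_link, 0.4),
            "M2_macrophage": ({}, 1.0),
        },
        survival_cell="Treg",
        baseline_rate=0.05,
        log_hazard_coef=0.7,
        censoring_rate=0.02,
    )
    neg = CancerSimConfig(
        cancer_type="SYNNEG",
        n_tumor=n_tumor,
        n_normal=n_normal,
        alteration_rates={("FGFR3", "missense"): 0.01},
        driver_fraction=1.0,
        infiltration_link={
            "CD8_T": ({}, 1.0),
            "Treg": ({}, 1.0),
            "M2_macrophage": ({}, 1.0),
        },
        survival_cell="Treg",
        baseline_rate=0.05,
        log_hazard_coef=0.0,
        censoring_rate=0.02,
    )
    return SimulationConfig(seed=seed, cancers=[pos, neg])


def write_fixture_directory(config: SimulationConfig, outdir) -> dict:
    """Generate every synthetic input and write it under ``outdir``.

    Layout: ``study_table.tsv``; ``expression/<C>_expression.tsv`` and
    ``<C>_samples.tsv``; ``alterations.tsv``, ``profiled_counts.tsv``,
    ``driver_catalog.tsv``; ``infiltration/<C>_infiltration.csv`` and
    ``<C>_survival.csv``; plus ``sim_manifest.json`` recording the seed and
    per-file row counts.  Returns the manifest dict.
    """
    import json
    from pathlib import Path

    from . import io as _io

    out = Path(outdir)
    (out / "expression").mkdir(parents=True, exist_ok=True)
    (out / "infiltration").mkdir(parents=True, exist_ok=True)

    studies = generate_study_table(
        true_p=0.38, tau2=0.2, k=20, n_range=(20, 360), seed=config.seed, endpoint_gap=0.40
    )
    _io.write_study_table(studies, out / "study_table.tsv")

    expr = generate_expression(config)
    for cancer, em in expr.items():
        _io.write_expression(
            em,
            out / "expression" / f"{cancer}_expression.tsv",
            out / "expression" / f"{cancer}_samples.tsv",
        )

    records, catalog, profiled = generate_alterations(config)
    _io.write_alterations(records, out / "alterations.tsv")
    _io.write_profiled_counts(profiled, out / "profiled_counts.tsv")
    _io.write_driver_catalog(catalog, out / "driver_catalog.tsv")

    infil, surv = generate_infiltration_and_survival(config, expr)
    for cancer, table in infil.items():
        _io.write_infiltration(table, out / "infiltration" / f"{cancer}_infiltration.csv")
    for cancer, recs in surv.items():
        _io.write_survival(recs, out / "infiltration" / f"{cancer}_survival.csv")

    manifest = {
        "seed": config.seed,
        "generator": "numpy PCG64 seeded via SeedSequence([seed, stream, cancer_index])",
        "cancers": [c.cancer_type for c in config.cancers],
        "n_study_rows": len(studies),
        "n_alteration_records": len(records),
        "n_catalog_entries": len(catalog.entries),
    }
    (out / "sim_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
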