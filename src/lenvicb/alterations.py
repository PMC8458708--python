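"""Mutation and copy-number alteration frequencies of the target genes.

Portal-style "altered / profiled" semantics throughout: a sample carrying
any number of qualifying alterations counts once, and frequencies divide
distinct altered samples by the number of samples profiled in that cancer.

Driver filtering mirrors annotation-catalog lookups (OncoKB / Cancer
Hotspots style): records are kept only when they match a catalog entry —
a (gene, protein_change) literal, a (gene, alteration class) wildcard such
as any CD274 amplification, or a gene-level "any".  Everything unmatched
is a variant of unknown significance (VUS) and treated as a likely
passenger.

Five of the fifteen targets (FLT1, FLT4, PDCD1, LAG3, CTLA4) lack
sufficient driver-annotation evidence and are excluded from driver-level
scoring, leaving CD274 as the only ICB target; its driver frequency is
computed over amplification records only.  Flag thresholds: lenvatinib-set
driver frequency >= 9% and CD274 amplification frequency >= 2%, both
inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .panel import TargetPanel

ALTERATION_CLASSES = frozenset(
    {"missense", "truncating", "inframe", "fusion", "amplification", "deep_deletion", "other"}
)
# targets without driver-annotation evidence, excluded from driver scoring
DRIVER_INELIGIBLE = frozenset({"FLT1", "FLT4", "PDCD1", "LAG3", "CTLA4"})
LENV_DRIVER_FREQ = 0.09
PDL1_DRIVER_FREQ = 0.02
DEFAULT_TOP_M = 16


@dataclass(frozen=True)
class AlterationRecord:
    """One alteration call in one sample."""

    sample_id: str
    cancer_type: str
    gene: str
    alteration_class: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if self.alteration_class not in ALTERATION_CLASSES:
            raise ValueError(f"unknown alteration class {self.alteration_class!r}")


class DriverCatalog:
    """Driver-annotation lookup with literal, class-wildcard and gene-level entries.

    Entry kinds, in the order a record is matched:

    - ``(gene, 'change:<protein_change>')``  hotspot literal, e.g. FGFR3 S249C
    - ``(gene, 'class:<alteration_class>')`` e.g. any CD274 amplification
    - ``(gene, 'any')``                      all alterations of the gene

    Unmatched records default to VUS.
    """

    def __init__(self, entries: set[tuple[str, str]] | None = None):
        self.entries: set[tuple[str, str]] = set(entries or ())

    def add_change(self, gene: str, protein_change: str) -> None:
        self.entries.add((gene, f"change:{protein_change}"))

    def add_class(self, gene: str, alteration_class: str) -> None:
        self.entries.add((gene, f"class:{alteration_class}"))

    def add_gene(self, gene: str) -> None:
        self.entries.add((gene, "any"))

    def is_driver(self, record: AlterationRecord) -> bool:
        g = record.gene
        if record.protein_change and (g, f"change:{record.protein_change}") in self.entries:
            return True
        if (g, f"class:{record.alteration_class}") in self.entries:
            return True
        return (g, "any") in self.entries

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene, matcher in sorted(self.entries):
            kind, _, value = matcher.partition(":")
            rows.append({"gene": gene, "matcher_kind": kind, "matcher_value": value})
        return pd.DataFrame(rows, columns=["gene", "matcher_kind", "matcher_value"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "DriverCatalog":
        cat = cls()
        for _, row in df.iterrows():
            kind = row["matcher_kind"]
            value = "" if pd.isna(row.get("matcher_value")) else str(row["matcher_value"])
            matcher = "any" if kind == "any" else f"{kind}:{value}"
            cat.entries.add((str(row["gene"]), matcher))
        return cat


def filter_drivers(
    records: list[AlterationRecord], catalog: DriverCatalog
) -> list[AlterationRecord]:
    """Keep exactly the records matching a driver entry; input order preserved."""
    return [r for r in records if catalog.is_driver(r)]


def eligible_driver_genes(panel: TargetPanel) -> frozenset[str]:
    """The panel minus the five driver-annotation-ineligible targets (10 genes)."""
    return panel.all_targets - DRIVER_INELIGIBLE


def set_driver_frequency(
    driver_records: list[AlterationRecord],
    gene_set: frozenset[str] | set[str],
    profiled: dict[str, int],
) -> pd.DataFrame:
    """Fraction of profiled samples with >=1 driver record in any gene of the set.

    Returns one row per cancer in ``profiled`` with columns altered_samples,
    profiled, frequency.  Cancers carrying records but missing a profiled
    count are an error.
    """
    altered: dict[str, set[str]] = {c: set() for c in profiled}
    for r in driver_records:
        if r.gene not in gene_set:
            continue
        if r.cancer_type not in profiled:
            raise KeyError(f"no profiled-sample count for cancer {r.cancer_type!r}")
        altered[r.cancer_type].add(r.sample_id)
    rows = []
    for cancer in sorted(profiled):
        n_alt, n_prof = len(altered[cancer]), profiled[cancer]
        if n_prof < 1:
            raise ValueError(f"{cancer}: profiled count must be positive")
        rows.append(
            {
                "cancer_type": cancer,
                "altered_samples": n_alt,
                "profiled": n_prof,
                "frequency": n_alt / n_prof,
            }
        )
    return pd.DataFrame(rows)


def flag_driver_enriched(
    driver_records: list[AlterationRecord],
    panel: TargetPanel,
    profiled: dict[str, int],
    lenv_threshold: float = LENV_DRIVER_FREQ,
    pdl1_threshold: float = PDL1_DRIVER_FREQ,
) -> pd.DataFrame:
    """Per-cancer flags: lenvatinib-set driver frequency >= 9% and CD274
    amplification frequency >= 2% (inclusive thresholds)."""
    lenv_set = eligible_driver_genes(panel) & panel.lenvatinib_targets
    lenv_freq = set_driver_frequency(driver_records, lenv_set, profiled)
    pdl1_amp = [
        r for r in driver_records if r.gene == "CD274" and r.alteration_class == "amplification"
    ]
    pdl1_freq = set_driver_frequency(pdl1_amp, {"CD274"}, profiled)
    out = lenv_freq[["cancer_type", "frequency"]].rename(columns={"frequency": "lenv_driver_freq"})
    out = out.merge(
        pdl1_freq[["cancer_type", "frequency"]].rename(columns={"frequency": "pdl1_amp_freq"}),
        on="cancer_type",
    )
    out["lenvatinib_driver_high"] = out["lenv_driver_freq"] >= lenv_threshold
    out["pdl1_driver_high"] = out["pdl1_amp_freq"] >= pdl1_threshold
    return out


def total_target_mutational_load(
    records: list[AlterationRecord],
    panel: TargetPanel,
    profiled: dict[str, int],
    m: int = DEFAULT_TOP_M,
    drivers_only_catalog: DriverCatalog | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Altered-sample fraction over the full 15-gene panel (drivers + VUS).

    Returns (ranked table, top-m cancer codes).  Rank is descending load
    with alphabetical tie-break.  Pass a catalog via ``drivers_only_catalog``
    to restrict the load to driver records instead (config alternative).
    """
    use = records if drivers_only_catalog is None else filter_drivers(records, drivers_only_catalog)
    table = set_driver_frequency(use, panel.all_targets, profiled).rename(
        columns={"frequency": "load"}
    )
    table = table.sort_values(["load", "cancer_type"], ascending=[False, True]).reset_index(
        drop=True
    )
    table["rank"] = range(1, len(table) + 1)
    top = table["cancer_type"].head(m).tolist()
    return table, top


def summarize_alteration_composition(records: list[AlterationRecord]) -> pd.DataFrame:
    """Proportions of alteration classes per (cancer, gene); sums to 1 within each group."""
    if not records:
        return pd.DataFrame(
            columns=["cancer_type", "gene", "alteration_class", "count", "proportion"]
        )
    df = pd.DataFrame([r.__dict__ for r in records])
    counts = (
        df.groupby(["cancer_type", "gene", "alteration_class"]).size().rename("count").reset_index()
    )
    totals = counts.groupby(["cancer_type", "gene"])["count"].transform("sum")
    counts["proportion"] = counts["count"] / totals
    return counts
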