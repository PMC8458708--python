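"""Canonical target-gene panels for lenvatinib and immune-checkpoint blockade.

Lenvatinib is a multi-target tyrosine-kinase inhibitor of the VEGF receptors
(FLT1/KDR/FLT4), the FGF receptors 1-4, the PDGF receptors alpha/beta, KIT
and RET; checkpoint blockade antibodies act on PDCD1 (PD-1), CD274 (PD-L1),
LAG3 and CTLA4.  Every analysis stage in this package scores these fifteen
genes, so the panel, its receptor-name aliases and the cancer-type
vocabulary live here and nowhere else.

Canonical names are HGNC gene symbols; receptor-protein names (``VEGFR2``,
``PD-L1``, ``c-kit``...) are accepted as input everywhere and normalised at
parse time via :func:`resolve_symbol`.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources


class UnknownGeneError(KeyError):
    """Raised when a symbol cannot be resolved against the target panel."""


@dataclass(frozen=True)
class TargetPanel:
    """The 15 target genes split by therapy arm, with alias resolution.

    Parameters
    ----------
    lenvatinib_targets, icb_targets
        Disjoint sets of canonical HGNC symbols (11 and 4 genes by default).
    alias_map
        Upper-cased alias symbol -> canonical symbol.
    """

    lenvatinib_targets: frozenset[str]
    icb_targets: frozenset[str]
    alias_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = self.lenvatinib_targets & self.icb_targets
        if overlap:
            raise ValueError(f"genes in both arms: {sorted(overlap)}")
        bad = set(self.alias_map.values()) - self.all_targets
        if bad:
            raise ValueError(f"aliases resolving outside the panel: {sorted(bad)}")

    @property
    def all_targets(self) -> frozenset[str]:
        return self.lenvatinib_targets | self.icb_targets

    def resolve_symbol(self, name: str) -> str:
        """Map a gene symbol or receptor-name alias to its canonical symbol.

        Matching is case-insensitive; surrounding whitespace is ignored.
        Raises :class:`UnknownGeneError` for anything outside the panel.
        """
        key = name.strip().upper()
        if not key:
            raise UnknownGeneError("unknown gene: empty symbol")
        if key in self.all_targets:
            return key
        if key in self.alias_map:
            return self.alias_map[key]
        raise UnknownGeneError(f"unknown gene: {name!r}")

    def membership(self, gene: str) -> str:
        """Return which therapy arm ('lenvatinib' or 'icb') a canonical gene belongs to."""
        gene = self.resolve_symbol(gene)
        return "lenvatinib" if gene in self.lenvatinib_targets else "icb"

    @classmethod
    def from_tsv(cls, path) -> "TargetPanel":
        """Load a panel from a TSV with columns canonical, arm, aliases (comma-separated)."""
        lenv: set[str] = set()
        icb: set[str] = set()
        aliases: dict[str, str] = {}
        with open(path, newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                canonical = row["canonical"].strip().upper()
                arm = row["arm"].strip().lower()
                (lenv if arm == "lenvatinib" else icb).add(canonical)
                for alias in (row.get("aliases") or "").split(","):
                    alias = alias.strip().upper()
                    if alias:
                        aliases[alias] = canonical
        return cls(frozenset(lenv), frozenset(icb), aliases)

    @classmethod
    def default(cls) -> "TargetPanel":
        """The bundled 15-gene panel (11 lenvatinib + 4 ICB targets)."""
        with resources.as_file(resources.files("lenvicb.data") / "panel.tsv") as p:
            return cls.from_tsv(p)


def load_cancer_codes() -> dict[str, str]:
    """The 33 TCGA study abbreviations used in pan-cancer analyses, code -> label.

    Cancer codes elsewhere in the package are free strings (synthetic
    'cancers' are legal); this table is a convenience vocabulary only.
    """
    ref = resources.files("lenvicb.data") / "tcga_codes.tsv"
    with resources.as_file(ref) as p, open(p, newline="", encoding="utf-8") as fh:
        return {r["code"]: r["label"] for r in csv.DictReader(fh, delimiter="\t")}


DEFAULT_PANEL = TargetPanel.default()


def resolve_symbol(name: str) -> str:
    """Resolve against the bundled default panel (module-level convenience)."""
    return DEFAULT_PANEL.resolve_symbol(name)


def panel_membership(gene: str) -> str:
    """Therapy arm of a gene in the bundled default panel."""
    return DEFAULT_PANEL.membership(gene)
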