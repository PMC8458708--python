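"""Evidence integration: three characteristic flags and the >=2 candidate rule.

Each cancer receives three boolean treatment-related characteristics:

- ``char_expression``  — expression category is "high" (>=4 lenvatinib and
  >=2 ICB targets up-regulated);
- ``char_alteration``  — in the top-m total-mutational-load set AND the
  lenvatinib driver-frequency flag (>=9%) holds.  The two are conjoined
  because the criterion couples high mutational load with high driver
  frequency; the PD-L1 amplification flag (>=2%) is carried in the table
  for reference but does not enter this characteristic;
- ``char_cd8``         — the CD8+ T-cell depletion box rule holds.

A cancer with at least two true flags is a combination-therapy candidate.
Missing stages default the corresponding flag to false (conservative),
with a warning.
"""

from __future__ import annotations

import warnings

import pandas as pd

FLAG_COLUMNS = ("char_expression", "char_alteration", "char_cd8")


def build_evidence(
    expression_high: set[str],
    load_top_set: set[str],
    lenv_driver_high: set[str],
    cd8_flags: set[str],
    pdl1_driver_high: set[str] | None = None,
    cancers: set[str] | None = None,
) -> pd.DataFrame:
    """Assemble the per-cancer evidence table and candidate calls.

    Each argument is the set of cancer codes satisfying one criterion;
    ``cancers`` optionally widens the row universe beyond the union of the
    criterion sets.  Rows are alphabetical; ``candidate`` is true iff
    ``n_characteristics >= 2``.
    """
    pdl1 = pdl1_driver_high or set()
    universe = (
        set(expression_high) | set(load_top_set) | set(lenv_driver_high) | set(cd8_flags) | pdl1
    )
    if cancers:
        universe |= set(cancers)
    if not universe:
        warnings.warn("no cancers in any criterion set; empty evidence table", stacklevel=2)
    rows = []
    for cancer in sorted(universe):
        char_expr = cancer in expression_high
        char_alt = cancer in load_top_set and cancer in lenv_driver_high
        char_cd8 = cancer in cd8_flags
        n = int(char_expr) + int(char_alt) + int(char_cd8)
        rows.append(
            {
                "cancer_type": cancer,
                "char_expression": char_expr,
                "char_alteration": char_alt,
                "char_cd8": char_cd8,
                "pdl1_driver_high": cancer in pdl1,
                "n_characteristics": n,
                "candidate": n >= 2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "cancer_type",
            *FLAG_COLUMNS,
            "pdl1_driver_high",
            "n_characteristics",
            "candidate",
        ],
    )


def candidates(evidence: pd.DataFrame) -> list[str]:
    """Cancer codes called candidates (alphabetical)."""
    return evidence.loc[evidence["candidate"], "cancer_type"].tolist()


def explain(evidence: pd.DataFrame, cancer: str) -> list[str]:
    """Human-readable justification lines for one cancer's call."""
    match = evidence[evidence["cancer_type"] == cancer]
    if match.empty:
        raise KeyError(f"cancer {cancer!r} not in the evidence table")
    row = match.iloc[0]
    descriptions = {
        "char_expression": "high expression of both target-gene sets "
        "(>=4 lenvatinib and >=2 ICB targets up-regulated, p<0.05)",
        "char_alteration": "high total target mutational load (top-ranked) with "
        "lenvatinib-target driver alterations at >=9% frequency",
        "char_cd8": "lenvatinib-target expression negatively correlated with "
        "CD8+ T-cell infiltration (>=8 negative, >=5 at r<=-0.15)",
    }
    lines = [f"{cancer}: {int(row['n_characteristics'])} of 3 characteristics"]
    for col in FLAG_COLUMNS:
        mark = "+" if row[col] else "-"
        lines.append(f"  [{mark}] {descriptions[col]}")
    if row["pdl1_driver_high"]:
        lines.append("  (note) PD-L1 amplification at >=2% frequency")
    lines.append(
        f"{cancer} is {'a candidate' if row['candidate'] else 'not a candidate'} "
        "for combination therapy (>=2 characteristics required)"
    )
    return lines


def build_evidence_from_criteria(criteria: dict) -> pd.DataFrame:
    """Build the evidence table from a criteria document of per-characteristic code lists.

    Expected keys: ``expression_high``, ``top_mutational_load``,
    ``lenvatinib_driver_high``, ``cd8_negative``; optional
    ``pdl1_driver_high``.
    """
    return build_evidence(
        expression_high=set(criteria["expression_high"]),
        load_top_set=set(criteria["top_mutational_load"]),
        lenv_driver_high=set(criteria["lenvatinib_driver_high"]),
        cd8_flags=set(criteria["cd8_negative"]),
        pdl1_driver_high=set(criteria.get("pdl1_driver_high", ())),
    )
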