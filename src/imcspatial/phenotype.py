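"""Hierarchical rule-based lineage assignment.

The basic lineage table follows standard IMC phenotyping: cancer PanCK+,
macrophages CD68+, neutrophils MPO+, endothelial cells CD31+, B cells
CD20+, cytotoxic T cells CD3+CD8+, helper T cells CD3+CD4+.  Extended
types (Treg CD3+CD4+FOXP3+, monocyte CD14+CD68-) ship as overridable
defaults.  Rules are evaluated in priority order (lower first); the first
rule whose positive and negative requirements are all met assigns the
lineage, so multi-marker rules must outrank the single-marker rules they
refine — e.g. a CD3+CD4+FOXP3+ cell is a Treg, never a helper T cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .io import positive_col, table_markers

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class GatingRule:
    lineage: str
    requires_positive: frozenset[str] = field(default_factory=frozenset)
    requires_negative: frozenset[str] = field(default_factory=frozenset)
    priority: int = 0

    def __post_init__(self) -> None:
        overlap = self.requires_positive & self.requires_negative
        if overlap:
            raise ConfigurationError(
                f"rule {self.lineage!r}: markers {sorted(overlap)} required "
                "both positive and negative")


def make_rule(lineage, positive=(), negative=(), priority=0) -> GatingRule:
    return GatingRule(
        lineage=lineage,
        requires_positive=frozenset(positive),
        requires_negative=frozenset(negative),
        priority=priority,
    )


def default_rules() -> list[GatingRule]:
    """The basic lineage table plus documented extended defaults.

    Multi-marker rules come first so that subset phenotypes win:
    Treg (CD3+CD4+FOXP3+) before helper T (CD3+CD4+), monocyte
    (CD14+CD68-) before macrophage (CD68+).
    """
    return [
        make_rule("Treg", ["CD3", "CD4", "FOXP3"], priority=0),
        make_rule("cytotoxic T cell", ["CD3", "CD8"], priority=1),
        make_rule("helper T cell", ["CD3", "CD4"], priority=2),
        make_rule("monocyte", ["CD14"], ["CD68"], priority=3),
        make_rule("macrophage", ["CD68"], priority=4),
        make_rule("neutrophil", ["MPO"], priority=5),
        make_rule("endothelial", ["CD31"], priority=6),
        make_rule("B cell", ["CD20"], priority=7),
        make_rule("cancer", ["PanCK"], priority=8),
    ]


def rules_from_config(entries: list[dict]) -> list[GatingRule]:
    """Build rules from YAML entries: {lineage, positive, negative, priority}."""
    rules = []
    for i, e in enumerate(entries):
        rules.append(make_rule(
            e["lineage"],
            e.get("positive", ()),
            e.get("negative", ()),
            e.get("priority", i),
        ))
    return rules


def rules_to_config(rules: list[GatingRule]) -> list[dict]:
    return [
        {
            "lineage": r.lineage,
            "positive": sorted(r.requires_positive),
            "negative": sorted(r.requires_negative),
            "priority": r.priority,
        }
        for r in rules
    ]


def assign_lineages(
    cells: pd.DataFrame, rules: list[GatingRule] | None = None
) -> pd.DataFrame:
    """Assign every cell a lineage by the first matching rule.

    Rules are evaluated in ascending priority; cells matching none are
    labeled "unassigned", making the assignment a total function.
    """
    if rules is None:
        rules = default_rules()
    priorities = [r.priority for r in rules]
    if len(set(priorities)) != len(priorities):
        raise ConfigurationError("rule priorities must be unique")
    markers = set(table_markers(cells)) or {
        c[len("positive_"):] for c in cells.columns if c.startswith("positive_")
    }
    for r in rules:
        unknown = (r.requires_positive | r.requires_negative) - markers
        if unknown:
            raise ConfigurationError(
                f"rule {r.lineage!r} references unknown markers {sorted(unknown)}")
    out = cells.copy()
    lineage = pd.Series(UNASSIGNED, index=out.index, dtype=object)
    unassigned = pd.Series(True, index=out.index)
    for rule in sorted(rules, key=lambda r: r.priority):
        match = unassigned.copy()
        for m in rule.requires_positive:
            match &= out[positive_col(m)]
        for m in rule.requires_negative:
            match &= ~out[positive_col(m)]
        lineage[match] = rule.lineage
        unassigned &= ~match
    out["lineage"] = lineage
    return out


def abundance_table(
    cells: pd.DataFrame,
    sample_of: dict | pd.Series | None = None,
    samples: list | None = None,
) -> pd.DataFrame:
    """Per-sample lineage counts and fractions.

    Fractions per sample sum to 1 over all lineages including
    "unassigned".  ``samples`` optionally fixes the sample universe;
    samples with no cells get all-zero rows flagged valid=False.
    Returns a long-format frame: sample_id, lineage, count, fraction,
    valid.
    """
    cells = cells.copy()
    if sample_of is not None:
        if isinstance(sample_of, dict):
            cells["sample_id"] = cells["cell_id"].map(sample_of)
        else:
            cells["sample_id"] = sample_of
    elif "sample_id" not in cells.columns:
        cells["sample_id"] = "sample1"
    if cells["sample_id"].isna().any():
        raise ValidationError("every cell must map to a sample")
    lineages = sorted(cells["lineage"].unique()) or [UNASSIGNED]
    if samples is None:
        samples = sorted(cells["sample_id"].unique())
    rows = []
    grouped = dict(tuple(cells.groupby("sample_id", sort=True)))
    for sid in samples:
        grp = grouped.get(sid)
        n = 0 if grp is None else len(grp)
        counts = grp["lineage"].value_counts() if n else {}
        for lin in lineages:
            c = int(counts.get(lin, 0))
            rows.append({
                "sample_id": sid, "lineage": lin, "count": c,
                "fraction": c / n if n else 0.0, "valid": n > 0,
            })
    return pd.DataFrame(rows)
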