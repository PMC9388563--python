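"""Boolean-marker phenotyping via a configurable rule registry.

A :class:`PhenotypeRule` names a population by its marker signature
(required-positive and required-negative markers around a lineage
marker). A cell receives every rule label whose signature it satisfies,
so parent labels (``CD8+``) co-occur with full sub-type labels
(``CD8+PD-1+LAG-3−TIM-3−``). Tumour-flagged cells are never assigned an
immune phenotype.

Canonical names use the Unicode minus sign (U+2212) for negated markers;
the registry also resolves common aliases (``LAG3`` for ``LAG-3``, ASCII
trailing ``-``, and the macrophage-polarity shorthands M1/M2 as printed
in the source panels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

from .errors import ConfigurationError

MINUS = "−"  # − in canonical rule names

#: Alias → canonical marker spelling.
MARKER_ALIASES = {
    "LAG3": "LAG-3",
    "TIM3": "TIM-3",
    "PD1": "PD-1",
    "PDL1": "PD-L1",
    "HLADR": "HLA-DR",
    "CTLA4": "CTLA-4",
}


@dataclass(frozen=True)
class PhenotypeRule:
    """Named boolean marker signature defining one population."""

    name: str
    lineage_marker: str
    positive: frozenset[str]
    negative: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.positive & self.negative:
            raise ConfigurationError(
                f"rule '{self.name}': markers in both positive and negative sets: "
                f"{sorted(self.positive & self.negative)}"
            )
        if self.lineage_marker not in self.positive:
            raise ConfigurationError(
                f"rule '{self.name}': lineage marker '{self.lineage_marker}' not in positive set"
            )

    def matches(self, markers: Mapping[str, bool]) -> bool:
        return all(markers[m] for m in self.positive) and not any(
            markers[m] for m in self.negative
        )

    @property
    def referenced_markers(self) -> frozenset[str]:
        return self.positive | self.negative


def canonical_name(positive: Iterable[str], negative: Iterable[str], order: Iterable[str]) -> str:
    """Build the canonical signature string, markers in panel order."""
    pos, neg = set(positive), set(negative)
    parts = []
    for m in order:
        if m in pos:
            parts.append(f"{m}+")
        elif m in neg:
            parts.append(f"{m}{MINUS}")
    return "".join(parts)


def _normalise(name: str) -> str:
    s = name[:-1] + MINUS if name.endswith("-") else name
    s = s.replace(MINUS, "\0")  # protect the sign before alias rewriting
    for alias, canon in MARKER_ALIASES.items():
        s = s.replace(alias, canon)
    return s.replace("\0", MINUS)


class PhenotypeRegistry:
    """Ordered collection of phenotype rules with alias lookup."""

    def __init__(self, rules: Iterable[PhenotypeRule] = (), aliases: Mapping[str, str] | None = None):
        self._rules: dict[str, PhenotypeRule] = {}
        self._aliases: dict[str, str] = {}
        for r in rules:
            self.add(r)
        for alias, target in (aliases or {}).items():
            self.add_alias(alias, target)

    def add(self, rule: PhenotypeRule) -> None:
        if rule.name in self._rules:
            raise ConfigurationError(f"duplicate rule name '{rule.name}'")
        self._rules[rule.name] = rule

    def add_alias(self, alias: str, target: str) -> None:
        if target not in self._rules:
            raise ConfigurationError(f"alias '{alias}' targets unknown rule '{target}'")
        self._aliases[alias] = target

    def get(self, name: str) -> PhenotypeRule:
        for candidate in (name, self._aliases.get(name), _normalise(name)):
            if candidate is not None and candidate in self._rules:
                return self._rules[candidate]
        norm = _normalise(name)
        if norm in self._aliases:
            return self._rules[self._aliases[norm]]
        raise ConfigurationError(f"unknown phenotype '{name}'")

    def __contains__(self, name: str) -> bool:
        try:
            self.get(name)
            return True
        except ConfigurationError:
            return False

    def __iter__(self) -> Iterator[PhenotypeRule]:
        return iter(self._rules.values())

    def __len__(self) -> int:
        return len(self._rules)

    @property
    def names(self) -> list[str]:
        return list(self._rules)

    def validate_panel(self, panel_markers: Iterable[str]) -> None:
        """Fail fast if any rule references a marker outside the panel."""
        panel = set(panel_markers)
        for rule in self:
            missing = rule.referenced_markers - panel
            if missing:
                raise ConfigurationError(
                    f"rule '{rule.name}' references markers absent from the panel: {sorted(missing)}"
                )

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "rules": [
                {
                    "name": r.name,
                    "lineage_marker": r.lineage_marker,
                    "positive": sorted(r.positive),
                    "negative": sorted(r.negative),
                }
                for r in self
            ],
            "aliases": dict(self._aliases),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False, allow_unicode=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PhenotypeRegistry":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        rules = [
            PhenotypeRule(
                name=r["name"],
                lineage_marker=r["lineage_marker"],
                positive=frozenset(r["positive"]),
                negative=frozenset(r.get("negative", ())),
            )
            for r in payload["rules"]
        ]
        return cls(rules, aliases=payload.get("aliases", {}))


def _rule(lineage: str, pos: Iterable[str] = (), neg: Iterable[str] = ()) -> PhenotypeRule:
    positive = frozenset({lineage, *pos})
    negative = frozenset(neg)
    order = (lineage, "PD-1", "LAG-3", "TIM-3", "FoxP3", "CTLA-4", "PD-L1",
             "CD163", "HLA-DR", "STING")
    return PhenotypeRule(
        name=canonical_name(positive, negative, order),
        lineage_marker=lineage,
        positive=positive,
        negative=negative,
    )


def default_registry() -> PhenotypeRegistry:
    """Registry of the populations analysed in the source study's main panels.

    The full 26-population catalogue is supplementary-only; these are the
    populations named in the main text and figures, which include all
    four signature components. User-defined rules can be added via YAML.
    """
    reg = PhenotypeRegistry()

    # lineages
    for lineage in ("CD8", "CD4", "CD68", "CD20", "CD66b"):
        reg.add(_rule(lineage))

    # CD8 checkpoint family: the 8 full-sign PD-1/LAG-3/TIM-3 combinations
    cps = ("PD-1", "LAG-3", "TIM-3")
    for mask in range(8):
        pos = [m for i, m in enumerate(cps) if mask >> i & 1]
        neg = [m for i, m in enumerate(cps) if not mask >> i & 1]
        reg.add(_rule("CD8", pos, neg))

    # partial-sign CD8 subsets named in the text
    reg.add(_rule("CD8", ["PD-1"], ["LAG-3"]))
    reg.add(_rule("CD8", [], ["PD-1", "LAG-3"]))
    reg.add(_rule("CD8", ["PD-1", "LAG-3"]))
    reg.add(_rule("CD8", ["PD-1", "TIM-3"]))
    reg.add(_rule("CD8", ["TIM-3"], ["PD-1"]))

    # CD4 / Treg subsets
    reg.add(_rule("CD4", ["FoxP3"]))
    reg.add(_rule("CD4", [], ["FoxP3"]))
    reg.add(_rule("CD4", ["FoxP3", "CTLA-4"]))
    reg.add(_rule("CD4", ["CTLA-4"], ["FoxP3"]))
    reg.add(_rule("CD4", ["FoxP3", "PD-L1"]))
    reg.add(_rule("CD4", ["PD-L1"], ["FoxP3"]))

    # macrophage subsets; M1/M2 aliases follow the source panels verbatim
    # (note they invert the common convention)
    reg.add(_rule("CD68", ["STING"]))
    reg.add(_rule("CD68", ["CD163"], ["HLA-DR"]))
    reg.add(_rule("CD68", ["HLA-DR"], ["CD163"]))
    reg.add(_rule("CD68", ["HLA-DR", "STING"], ["CD163"]))

    reg.add_alias("M1", canonical_name({"CD68", "CD163"}, {"HLA-DR"}, ("CD68", "CD163", "HLA-DR")))
    reg.add_alias("M2", canonical_name({"CD68", "HLA-DR"}, {"CD163"}, ("CD68", "CD163", "HLA-DR")))
    return reg


def assign_phenotypes(
    markers: Mapping[str, bool],
    registry: PhenotypeRegistry,
    is_tumour_cell: bool = False,
) -> set[str]:
    """Return the names of every rule the cell satisfies (empty for tumour cells)."""
    if is_tumour_cell:
        return set()
    referenced = set().union(*(r.referenced_markers for r in registry)) if len(registry) else set()
    missing = referenced - set(markers)
    if missing:
        raise ConfigurationError(f"cell markers do not cover the registry: missing {sorted(missing)}")
    return {r.name for r in registry if r.matches(markers)}


def phenotype_matrix(cells: pd.DataFrame, registry: PhenotypeRegistry) -> pd.DataFrame:
    """Vectorised rule application: boolean frame of shape (cells, rules).

    Tumour-flagged cells get all-False rows. Column order follows the
    registry; row index follows ``cells``.
    """
    registry.validate_panel(
        c for c in cells.columns
        if c not in ("cell_id", "patient_id", "roi_id", "roi_class", "compartment",
                     "x_um", "y_um", "is_tumour_cell")
    )
    immune = ~cells["is_tumour_cell"].to_numpy()
    out = {}
    for rule in registry:
        mask = immune.copy()
        for m in rule.positive:
            mask &= cells[m].to_numpy()
        for m in rule.negative:
            mask &= ~cells[m].to_numpy()
        out[rule.name] = mask
    return pd.DataFrame(out, index=cells.index)
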