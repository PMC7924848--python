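"""From enzyme availabilities to terminal lipid A products and summaries.

Per-taxon strain-level enzyme percentages are binarized at a configurable
threshold (default: an enzyme is credited when at least half of a taxon's
sequenced strains carry it), the credited complement is walked through the
pathway model to a terminal product, and products are summarized three
ways:

* per-group taxon counts per stage (the bar-plot view),
* abundance-weighted product distributions, with the option to drop
  no-pathway mass before renormalizing — the convention used when quoting
  "final-stage products comprised X% of the total",
* a species-level acylation/modification distribution splitting late-stage
  producers into tetra-, penta- and hexa-acylated bis-phosphorylated
  classes plus a dephosphorylated class.

A Sankey graph (product → taxon links weighted by AVD) summarizes the
taxon-to-product assignment for plotting.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .cohort import AvdVector
from .io import DataValidationError, EnzymeProfileSet
from .pathway import (
    MODIFICATION_ENZYMES,
    NO_PATHWAY,
    AcylPhosphoState,
    PathwayModel,
    ProductStage,
    acyl_phospho_state,
    build_default_pathway,
    terminal_product,
)

__all__ = [
    "EnzymeSetMap",
    "ProductAssignment",
    "ProductDistribution",
    "SankeyGraph",
    "ACYL_CLASSES",
    "binarize_enzymes",
    "assign_products",
    "stage_counts",
    "product_distribution",
    "final_stage_fraction",
    "group_endproduct_delta",
    "acylation_distribution",
    "build_sankey",
]

#: Classes reported by the species-level acylation summary.
ACYL_CLASSES = (
    "hexa-acyl-bisP",      # unmodified hexa-acylated lipid A: potent agonist
    "penta-acyl-bisP",
    "tetra-acyl-bisP",
    "dephosphorylated",    # >=1 phosphate removed by LpxE/LpxF
    "no-late-stage",       # complement does not reach lipid IVA
)


@dataclass
class EnzymeSetMap:
    """Credited enzyme complements after thresholding availabilities."""

    sets: dict[str, frozenset[str]]
    threshold_used: float

    @property
    def taxa(self) -> list[str]:
        return list(self.sets)

    def __getitem__(self, taxon: str) -> frozenset[str]:
        return self.sets[taxon]


@dataclass
class ProductAssignment:
    """Per-taxon terminal product (and acyl state where defined)."""

    stages: dict[str, ProductStage]
    acyl_states: dict[str, AcylPhosphoState] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return list(self.stages)

    def __getitem__(self, taxon: str) -> ProductStage:
        return self.stages[taxon]


@dataclass
class ProductDistribution:
    """Percent of a group's (included) AVD mass per terminal product."""

    group: str
    percentages: dict[str, float]
    included_mass: float  # percent of the group's total AVD that was included
    exclude_no_pathway: bool

    def __getitem__(self, token: str) -> float:
        return self.percentages.get(token, 0.0)


@dataclass
class SankeyGraph:
    """Nodes and weighted links of the product → taxon flow diagram."""

    nodes: list[dict]
    links: list[dict]

    def to_dict(self) -> dict:
        return {"nodes": self.nodes, "links": self.links}

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def binarize_enzymes(
    profiles: EnzymeProfileSet,
    threshold: float = 50.0,
    include_modifications: bool = False,
) -> EnzymeSetMap:
    """Credit an enzyme to a taxon iff availability >= threshold percent.

    The core nine enzymes are always considered; LpxE/LpxF are included
    only when ``include_modifications`` is set (they feed the species-level
    modification analysis, not the stage assignment).
    """
    if not (0.0 < threshold <= 100.0):
        raise DataValidationError(f"threshold {threshold} outside (0, 100]")
    sets = {}
    for taxon, prof in profiles.profiles.items():
        credited = {
            e
            for e, pct in prof.items()
            if pct >= threshold
            and (include_modifications or e not in MODIFICATION_ENZYMES)
        }
        sets[taxon] = frozenset(credited)
    return EnzymeSetMap(sets=sets, threshold_used=float(threshold))


def assign_products(
    setmap: EnzymeSetMap, model: PathwayModel | None = None
) -> ProductAssignment:
    """Walk each taxon's complement to its terminal product.

    Taxa reaching at least lipid IVA also get an acyl/phospho state
    (computed without modifications; see :func:`acylation_distribution`
    for the modification-aware species summary).
    """
    if model is None:
        model = build_default_pathway()
    lipid_iva_rank = model.stage("lipid-IVA").rank
    stages: dict[str, ProductStage] = {}
    acyl_states: dict[str, AcylPhosphoState] = {}
    for taxon, enzymes in setmap.sets.items():
        core = frozenset(e for e in enzymes if e in model.enzymes)
        stage = terminal_product(core, model)
        stages[taxon] = stage
        if stage.rank >= lipid_iva_rank:
            mods = frozenset(e for e in enzymes if e in model.modification_enzymes)
            acyl_states[taxon] = acyl_phospho_state(core, mods, model)
    return ProductAssignment(stages=stages, acyl_states=acyl_states)


def stage_counts(
    assignments: ProductAssignment,
    groups: Mapping[str, Iterable[str]],
    model: PathwayModel | None = None,
) -> pd.DataFrame:
    """Taxon counts (and percent of list size) per product, per taxon list.

    ``groups`` maps a list name (e.g. "MAG", "MAG0", "MIG") to its taxa.
    Returns a tidy frame with columns list, product, rank, count, percent.
    """
    if model is None:
        model = build_default_pathway()
    rows = []
    for name, taxa in groups.items():
        taxa = list(taxa)
        missing = [t for t in taxa if t not in assignments.stages]
        if missing:
            raise DataValidationError(f"taxa without assignments: {missing}")
        tally: dict[str, int] = {}
        for t in taxa:
            tally[assignments[t].token] = tally.get(assignments[t].token, 0) + 1
        for token in model.product_order():
            count = tally.get(token, 0)
            rows.append(
                {
                    "list": name,
                    "product": token,
                    "rank": model.stage(token).rank,
                    "count": count,
                    "percent": 100.0 * count / len(taxa) if taxa else 0.0,
                }
            )
    return pd.DataFrame(rows)


def product_distribution(
    assignments: ProductAssignment,
    avd: AvdVector,
    exclude_no_pathway: bool = True,
    model: PathwayModel | None = None,
) -> ProductDistribution:
    """Abundance-weighted percent of AVD mass per terminal product.

    Taxa in the AVD vector without an assignment are treated as
    NO-PATHWAY (mass must stay accounted for).  With ``exclude_no_pathway``
    the no-pathway mass is dropped before renormalizing to 100, the
    convention behind "X% of total products when genera without enzymes
    were excluded".
    """
    mass: dict[str, float] = {}
    total = 0.0
    for taxon, value in avd.values.items():
        value = float(value)
        total += value
        token = (
            assignments.stages[taxon].token
            if taxon in assignments.stages
            else NO_PATHWAY
        )
        mass[token] = mass.get(token, 0.0) + value
    if exclude_no_pathway:
        mass.pop(NO_PATHWAY, None)
    included = sum(mass.values())
    if included <= 0:
        raise DataValidationError("no AVD mass left after exclusion")
    percentages = {tok: 100.0 * m / included for tok, m in mass.items()}
    return ProductDistribution(
        group=avd.group,
        percentages=percentages,
        included_mass=100.0 * included / total if total > 0 else 0.0,
        exclude_no_pathway=exclude_no_pathway,
    )


def final_stage_fraction(
    dist: ProductDistribution, model: PathwayModel | None = None
) -> float:
    """Percent of distribution mass on final-stage (KDO2-bearing) products."""
    if model is None:
        model = build_default_pathway()
    return float(
        sum(pct for tok, pct in dist.percentages.items() if tok in model.final_stage_products)
    )


def group_endproduct_delta(
    dist_case: ProductDistribution,
    dist_control: ProductDistribution,
    model: PathwayModel | None = None,
) -> float:
    """Case minus control final-stage fraction, in percentage points."""
    if dist_case.exclude_no_pathway != dist_control.exclude_no_pathway:
        raise DataValidationError(
            "distributions computed with different exclude_no_pathway settings"
        )
    return final_stage_fraction(dist_case, model) - final_stage_fraction(
        dist_control, model
    )


def acylation_distribution(
    species_setmap: EnzymeSetMap,
    species_avd: AvdVector,
    model: PathwayModel | None = None,
) -> dict[str, float]:
    """Abundance-weighted late-stage acylation/modification classes.

    Species-level view: each species reaching at least lipid IVA is placed
    in an acyl class from its credited complement, with any credited
    LpxE/LpxF moving it to the dephosphorylated class; species that do not
    reach lipid IVA (including no-pathway species and those absent from
    the enzyme matrix) pool into "no-late-stage".  Percentages are of
    total AVD mass and sum to 100.
    """
    if model is None:
        model = build_default_pathway()
    lipid_iva_rank = model.stage("lipid-IVA").rank
    mass = {cls: 0.0 for cls in ACYL_CLASSES}
    total = 0.0
    for taxon, value in species_avd.values.items():
        value = float(value)
        total += value
        enzymes = species_setmap.sets.get(taxon, frozenset())
        core = frozenset(e for e in enzymes if e in model.enzymes)
        mods = frozenset(e for e in enzymes if e in model.modification_enzymes)
        stage = terminal_product(core, model)
        if stage.rank < lipid_iva_rank:
            cls = "no-late-stage"
        else:
            state = acyl_phospho_state(core, mods, model)
            if state.phosphates != "bis":
                cls = "dephosphorylated"
            else:
                cls = f"{state.acyl_count}-acyl-bisP"
        mass[cls] += value
    if total <= 0:
        raise DataValidationError("species AVD has no mass")
    return {cls: 100.0 * m / total for cls, m in mass.items()}


def build_sankey(
    assignments: ProductAssignment,
    avd: AvdVector,
    model: PathwayModel | None = None,
) -> SankeyGraph:
    """Product → taxon flow graph; link width = the taxon's AVD.

    Node set is the union of used product tokens (sources, ordered by
    stage rank) and taxa (targets, ordered by descending AVD).  One link
    per taxon carries its full AVD, so per-taxon link mass equals AVD.
    """
    if model is None:
        model = build_default_pathway()
    taxa = [t for t in avd.values.sort_values(ascending=False).index]
    used_tokens = sorted(
        {
            (assignments.stages[t].token if t in assignments.stages else NO_PATHWAY)
            for t in taxa
        },
        key=lambda tok: model.stage(tok).rank,
    )
    nodes = [
        {"id": tok, "kind": "product", "rank": model.stage(tok).rank}
        for tok in used_tokens
    ] + [{"id": t, "kind": "taxon"} for t in taxa]
    links = []
    for t in taxa:
        token = assignments.stages[t].token if t in assignments.stages else NO_PATHWAY
        links.append({"source": token, "target": t, "weight": float(avd[t])})
    return SankeyGraph(nodes=nodes, links=links)


def write_products_table(
    assignments: ProductAssignment,
    avds: Mapping[str, AvdVector],
    path: str | Path,
    model: PathwayModel | None = None,
) -> None:
    """products.tsv: taxon, terminal product, rank, acyl class, per-group AVD."""
    if model is None:
        model = build_default_pathway()
    rows = []
    for taxon, stage in assignments.stages.items():
        state = assignments.acyl_states.get(taxon)
        row = {
            "taxon": taxon,
            "terminal_product": stage.token,
            "rank": stage.rank,
            "acyl_count": state.acyl_count if state else "",
            "phosphates": state.phosphates if state else "",
            "immunostimulant_class": state.immunostimulant_class if state else "",
        }
        for group, avd in avds.items():
            row[f"avd_{group}"] = avd[taxon]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
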