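"""Raetz pathway model: the conserved nine-step lipid A biosynthesis chain.

The constitutive route from UDP-N-acetylglucosamine to KDO2-lipid A is
catalyzed by nine essential enzymes (LpxA, LpxC, LpxD, LpxH, LpxB, LpxK,
WaaA, LpxL, LpxM).  A taxon's *terminal product* is the furthest pathway
intermediate its credited enzyme complement can synthesize: the chain is
walked step by step, and stops at the last step whose entire upstream
prefix is satisfied.  A configurable set of steps (by default only LpxH,
whose lipid-X-forming reaction is known to be bypassed in some organisms
via alternative hydrolases) may be skipped — but a skip is only credited
when a downstream enzyme is actually present, so a complement that ends
just before a skippable step terminates at the pre-skip product.

Late-stage acylation and modification are tracked separately: LpxL is
required for penta-acylation, LpxM for hexa-acylation, and the LpxE/LpxF
phosphatases each remove one of the two lipid A phosphate groups.
Hexa-acylated, bis-phosphorylated lipid A is the potent TLR4/MD-2
immunostimulant; every other acylation/phosphorylation state is classed
as reduced.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "PathwayError",
    "UnknownEnzymeError",
    "PathwayStep",
    "PathwayModel",
    "ProductStage",
    "AcylPhosphoState",
    "PATHWAY_ENZYMES",
    "MODIFICATION_ENZYMES",
    "NO_PATHWAY",
    "build_default_pathway",
    "terminal_product",
    "acyl_phospho_state",
]


class PathwayError(ValueError):
    """Structural problem in a pathway definition or query."""


class UnknownEnzymeError(PathwayError):
    """An enzyme token outside the pathway's vocabulary."""


NO_PATHWAY = "NO-PATHWAY"

#: The nine essential enzymes, in catalytic order.
PATHWAY_ENZYMES = (
    "LpxA", "LpxC", "LpxD", "LpxH", "LpxB", "LpxK", "WaaA", "LpxL", "LpxM",
)

#: Phosphatases that dephosphorylate lipid A, lowering immunogenicity.
MODIFICATION_ENZYMES = frozenset({"LpxE", "LpxF"})

# (enzyme, EC, substrate, product); EC numbers in standard notation, with
# nonstandard spellings seen in circulation kept as aliases.
_DEFAULT_STEPS = (
    ("LpxA", "2.3.1.129", "UDP-GlcNAc", "UDP-3-acyl-GlcNAc"),
    ("LpxC", "3.5.1.108", "UDP-3-acyl-GlcNAc", "UDP-3-acyl-GlcN"),
    ("LpxD", "2.3.1.191", "UDP-3-acyl-GlcN", "UDP-2,3-diacyl-GlcN"),
    ("LpxH", "3.6.1.54", "UDP-2,3-diacyl-GlcN", "lipid-X"),
    ("LpxB", "2.4.1.182", "lipid-X", "lipid-A-disaccharide-1P"),
    ("LpxK", "2.7.1.130", "lipid-A-disaccharide-1P", "lipid-IVA"),
    ("WaaA", "2.4.99.12", "lipid-IVA", "KDO2-lipid-IVA"),
    ("LpxL", "2.3.1.241", "KDO2-lipid-IVA", "KDO2-lipid-A-penta"),
    ("LpxM", "2.3.1.243", "KDO2-lipid-A-penta", "KDO2-lipid-A"),
)

EC_ALIASES = {
    "2.4.99.12": ("2.499.12",),
    "2.3.1.241": ("23.1.241",),
    "2.3.1.243": ("23.1.243",),
}

#: Products whose synthesis marks the final (KDO2-bearing acylated) stage.
DEFAULT_FINAL_STAGE_PRODUCTS = frozenset(
    {"KDO2-lipid-IVA", "KDO2-lipid-A-penta", "KDO2-lipid-A"}
)


@dataclass(frozen=True)
class PathwayStep:
    index: int
    enzyme: str
    ec_number: str
    substrate: str
    product: str


@dataclass(frozen=True)
class ProductStage:
    """A pathway intermediate plus its rank in the synthesis order.

    Rank 0 is the no-pathway state; ranks 1..9 follow the step order, so
    rank comparisons express "further along the chain".
    """

    token: str
    rank: int

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.token


@dataclass(frozen=True)
class AcylPhosphoState:
    """Late-stage acylation / phosphorylation of a synthesized lipid A."""

    acyl_count: str  # tetra | penta | hexa
    phosphates: str  # bis | mono | none
    immunostimulant_class: str  # high | reduced

    def __post_init__(self) -> None:
        if self.acyl_count not in ("tetra", "penta", "hexa"):
            raise PathwayError(f"bad acyl count {self.acyl_count!r}")
        if self.phosphates not in ("bis", "mono", "none"):
            raise PathwayError(f"bad phosphate state {self.phosphates!r}")
        expected = (
            "high"
            if (self.acyl_count == "hexa" and self.phosphates == "bis")
            else "reduced"
        )
        if self.immunostimulant_class != expected:
            raise PathwayError(
                "immunostimulant class inconsistent with acyl/phosphate state"
            )


@dataclass(frozen=True)
class PathwayModel:
    steps: tuple[PathwayStep, ...]
    skip_allowed: frozenset[str] = frozenset({"LpxH"})
    modification_enzymes: frozenset[str] = MODIFICATION_ENZYMES
    final_stage_products: frozenset[str] = DEFAULT_FINAL_STAGE_PRODUCTS

    def __post_init__(self) -> None:
        if len(self.steps) != 9:
            raise PathwayError(f"expected 9 steps, got {len(self.steps)}")
        for i, step in enumerate(self.steps, start=1):
            if step.index != i:
                raise PathwayError("step indices must be consecutive 1..9")
        for prev, nxt in zip(self.steps, self.steps[1:]):
            if nxt.substrate != prev.product:
                raise PathwayError(
                    f"broken chain: step {nxt.index} substrate "
                    f"{nxt.substrate!r} != step {prev.index} product "
                    f"{prev.product!r}"
                )
        products = {s.product for s in self.steps}
        if not self.final_stage_products <= products:
            raise PathwayError("final_stage_products must be step products")
        unknown_skips = self.skip_allowed - self.enzymes
        if unknown_skips:
            raise UnknownEnzymeError(f"skip_allowed not in pathway: {sorted(unknown_skips)}")

    @property
    def enzymes(self) -> frozenset[str]:
        return frozenset(s.enzyme for s in self.steps)

    @property
    def enzyme_order(self) -> tuple[str, ...]:
        return tuple(s.enzyme for s in self.steps)

    def stage(self, token: str) -> ProductStage:
        """The ProductStage for a product token (or the no-pathway state)."""
        if token == NO_PATHWAY:
            return ProductStage(NO_PATHWAY, 0)
        for step in self.steps:
            if step.product == token:
                return ProductStage(token, step.index)
        raise PathwayError(f"unknown product token {token!r}")

    def product_order(self) -> tuple[str, ...]:
        """All stage tokens from NO-PATHWAY to the terminal product."""
        return (NO_PATHWAY,) + tuple(s.product for s in self.steps)

    def with_skip(self, skip_allowed: Iterable[str]) -> "PathwayModel":
        return PathwayModel(
            steps=self.steps,
            skip_allowed=frozenset(skip_allowed),
            modification_enzymes=self.modification_enzymes,
            final_stage_products=self.final_stage_products,
        )

    # -- serialization -------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "steps": [
                {
                    "index": s.index,
                    "enzyme": s.enzyme,
                    "ec": s.ec_number,
                    "substrate": s.substrate,
                    "product": s.product,
                }
                for s in self.steps
            ],
            "skip_allowed": sorted(self.skip_allowed),
            "modification_enzymes": sorted(self.modification_enzymes),
            "final_stage_products": sorted(self.final_stage_products),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PathwayModel":
        steps = tuple(
            PathwayStep(
                index=int(d["index"]),
                enzyme=str(d["enzyme"]),
                ec_number=str(d["ec"]),
                substrate=str(d["substrate"]),
                product=str(d["product"]),
            )
            for d in sorted(doc["steps"], key=lambda d: int(d["index"]))
        )
        return cls(
            steps=steps,
            skip_allowed=frozenset(doc.get("skip_allowed", ["LpxH"])),
            modification_enzymes=frozenset(
                doc.get("modification_enzymes", sorted(MODIFICATION_ENZYMES))
            ),
            final_stage_products=frozenset(
                doc.get("final_stage_products", sorted(DEFAULT_FINAL_STAGE_PRODUCTS))
            ),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PathwayModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


def build_default_pathway(
    skip_allowed: Iterable[str] = ("LpxH",),
) -> PathwayModel:
    """The canonical nine-step chain LpxA → ... → LpxM.

    ``skip_allowed`` configures which steps may be bypassed when walking a
    complement; by default only the LpxH step.
    """
    steps = tuple(
        PathwayStep(index=i, enzyme=e, ec_number=ec, substrate=sub, product=prod)
        for i, (e, ec, sub, prod) in enumerate(_DEFAULT_STEPS, start=1)
    )
    return PathwayModel(steps=steps, skip_allowed=frozenset(skip_allowed))


def _check_enzymes(enzymes: Iterable[str], model: PathwayModel) -> frozenset[str]:
    enzymes = frozenset(enzymes)
    unknown = enzymes - model.enzymes
    if unknown:
        raise UnknownEnzymeError(f"unknown pathway enzymes: {sorted(unknown)}")
    return enzymes


def terminal_product(
    enzymes: Iterable[str], model: PathwayModel | None = None
) -> ProductStage:
    """Furthest intermediate synthesizable by a credited enzyme complement.

    Walks the chain and returns the product of the deepest step k such that
    every step 1..k is either present in ``enzymes`` or in the model's skip
    set, *and* step k's own enzyme is present.  Requiring presence at step k
    means a bypass is only credited when a post-bypass enzyme exists: a
    complement lacking LpxH with nothing downstream terminates at the
    pre-LpxH product.  Returns the rank-0 NO-PATHWAY stage when even the
    first step is unreachable.
    """
    if model is None:
        model = build_default_pathway()
    enzymes = _check_enzymes(enzymes, model)
    best = 0
    for step in model.steps:
        if step.enzyme in enzymes:
            best = step.index
        elif step.enzyme in model.skip_allowed:
            continue  # provisionally skippable; credited only if a later step lands
        else:
            break
    if best == 0:
        return ProductStage(NO_PATHWAY, 0)
    return model.stage(model.steps[best - 1].product)


def acyl_phospho_state(
    enzymes: Iterable[str],
    modifications: Iterable[str] = (),
    model: PathwayModel | None = None,
) -> AcylPhosphoState:
    """Acylation/phosphorylation state of the lipid A a complement yields.

    Only defined for complements reaching at least lipid IVA (the first
    tetra-acylated bis-phosphorylated intermediate).  LpxM credits
    hexa-acylation, otherwise LpxL credits penta-acylation, otherwise the
    molecule stays tetra-acylated; each LpxE/LpxF phosphatase present
    removes one phosphate.
    """
    if model is None:
        model = build_default_pathway()
    enzymes = _check_enzymes(enzymes, model)
    mods = frozenset(modifications)
    bad_mods = mods - model.modification_enzymes
    if bad_mods:
        raise UnknownEnzymeError(f"unknown modification enzymes: {sorted(bad_mods)}")

    stage = terminal_product(enzymes, model)
    lipid_iva_rank = model.stage("lipid-IVA").rank
    if stage.rank < lipid_iva_rank:
        raise PathwayError(
            f"acyl/phospho state undefined below lipid-IVA (terminal {stage.token})"
        )

    if stage.token == "KDO2-lipid-A":
        acyl = "hexa"
    elif stage.token == "KDO2-lipid-A-penta":
        acyl = "penta"
    else:
        acyl = "tetra"
    phosphates = {0: "bis", 1: "mono", 2: "none"}[len(mods)]
    immuno = "high" if (acyl == "hexa" and phosphates == "bis") else "reduced"
    return AcylPhosphoState(acyl, phosphates, immuno)


def rank_of(token: str, model: PathwayModel | None = None) -> int:
    """Convenience: rank of a product token under a model."""
    if model is None:
        model = build_default_pathway()
    return model.stage(token).rank
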