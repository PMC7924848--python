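"""Synthetic two-group cohorts and enzyme profiles for pipeline testing.

Abundances are drawn from a Dirichlet compositional model: each sample's
genus composition is Dirichlet-distributed around a group mean vector,
with a single ``dispersion`` knob (concentration = mean / dispersion, so
dispersion → 0 pins every sample to the mean).  Case-group means are the
control means multiplied by planted fold changes and renormalized; taxa
planted as NOVEL_IN_CASE have zero mean in the control group.

Enzyme profiles are drawn from archetypes describing where a taxon's
pathway complement ends:

* ``full_set`` — all nine enzymes at high availability,
* ``truncated_at:K`` — steps 1..K high, the rest low (K in 1..8),
* ``bypass_lpxh`` — everything high except LpxH (the skippable step),
* ``none`` — no pathway enzymes.

A per-cell noise rate perturbs availabilities within [0, 100] without
moving a high cell below or a low cell above a majority threshold at
noise rates < 0.5.

The packaged ``paper_like`` scenario emulates the shape of a published
ASD-vs-control gut cohort: 36 case and 21 control samples, ~100 genera,
~77% Gram-negative control mass with one dominant genus near 44%, ten
planted increased Gram-negative genera carrying the full pathway, and a
few taxa novel to the case group.  Its parameters are scenario choices,
not measurements of any real cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import NOVEL_IN_CASE
from .io import AbundanceTable, DataValidationError, EnzymeProfileSet, GramAnnotation
from .pathway import PATHWAY_ENZYMES

__all__ = [
    "TaxonSpec",
    "CohortConfig",
    "ArchetypeMap",
    "generate_cohort",
    "generate_enzyme_profiles",
    "load_scenario",
    "paper_like_scenario",
]

ARCHETYPES = ("full_set", "none", "bypass_lpxh", "truncated_at")


@dataclass(frozen=True)
class TaxonSpec:
    name: str
    gram: str  # negative | positive | unknown
    base_mean: float  # control-group mean relative abundance (percent scale)


@dataclass
class CohortConfig:
    taxa: list[TaxonSpec]
    planted_changes: dict[str, float | str] = field(default_factory=dict)
    n_case: int = 36
    n_control: int = 21
    dispersion: float = 0.25
    seed: int = 0
    case_label: str = "case"
    control_label: str = "control"

    def __post_init__(self) -> None:
        if self.n_case < 1 or self.n_control < 1:
            raise DataValidationError("group sizes must be >= 1")
        if self.dispersion <= 0:
            raise DataValidationError("dispersion must be positive")
        names = [t.name for t in self.taxa]
        if len(names) != len(set(names)):
            raise DataValidationError("duplicate taxa in config")
        known = set(names)
        for taxon, change in self.planted_changes.items():
            if taxon not in known:
                raise DataValidationError(f"planted change on unknown taxon {taxon!r}")
            if change != NOVEL_IN_CASE and float(change) <= 0:
                raise DataValidationError(f"non-positive fold change for {taxon!r}")
        for t in self.taxa:
            if t.base_mean < 0:
                raise DataValidationError(f"negative base mean for {t.name!r}")


@dataclass
class ArchetypeMap:
    """Taxon → pathway archetype, plus a cell-level noise rate."""

    archetypes: dict[str, str]
    noise: float = 0.05
    modifications: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.noise <= 1.0):
            raise DataValidationError("noise rate must be in [0, 1]")
        for taxon, arch in self.archetypes.items():
            kind, k = _parse_archetype(arch)
            if kind == "truncated_at" and not (1 <= k <= 8):
                raise DataValidationError(f"truncation step {k} outside 1..8")


def _parse_archetype(arch: str) -> tuple[str, int | None]:
    if ":" in arch:
        kind, _, num = arch.partition(":")
        kind = kind.strip()
        if kind != "truncated_at":
            raise DataValidationError(f"unknown archetype {arch!r}")
        return kind, int(num)
    if arch not in ("full_set", "none", "bypass_lpxh"):
        raise DataValidationError(f"unknown archetype {arch!r}")
    return arch, None


def _mean_vectors(cfg: CohortConfig) -> tuple[np.ndarray, np.ndarray]:
    base = np.array([t.base_mean for t in cfg.taxa], dtype=float)
    control = base.copy()
    case = base.copy()
    for i, t in enumerate(cfg.taxa):
        change = cfg.planted_changes.get(t.name)
        if change is None:
            continue
        if change == NOVEL_IN_CASE:
            control[i] = 0.0  # base_mean acts as the case-group mean
        else:
            case[i] = base[i] * float(change)
    if control.sum() <= 0 or case.sum() <= 0:
        raise DataValidationError("degenerate config: a group has zero total mean")
    return case, control


def _draw_group(
    rng: np.random.Generator, means: np.ndarray, n: int, dispersion: float
) -> np.ndarray:
    """n Dirichlet compositions (percent) around a mean vector."""
    means = means / means.sum()
    out = np.zeros((n, means.size))
    pos = means > 0
    alpha = means[pos] * 100.0 / dispersion
    out[:, pos] = rng.dirichlet(alpha, size=n)
    return out * 100.0


def generate_cohort(cfg: CohortConfig) -> tuple[AbundanceTable, GramAnnotation]:
    """Draw a two-group abundance table plus its Gram annotation.

    Deterministic given ``cfg.seed``; rows sum to 100.
    """
    rng = np.random.default_rng(cfg.seed)
    case_means, control_means = _mean_vectors(cfg)
    names = [t.name for t in cfg.taxa]

    case = _draw_group(rng, case_means, cfg.n_case, cfg.dispersion)
    control = _draw_group(rng, control_means, cfg.n_control, cfg.dispersion)

    width = len(str(max(cfg.n_case, cfg.n_control)))
    case_ids = [f"{cfg.case_label}_{i + 1:0{width}d}" for i in range(cfg.n_case)]
    control_ids = [
        f"{cfg.control_label}_{i + 1:0{width}d}" for i in range(cfg.n_control)
    ]
    values = pd.DataFrame(
        np.vstack([case, control]),
        index=pd.Index(case_ids + control_ids, name="sample_id"),
        columns=names,
    )
    labels = pd.Series(
        [cfg.case_label] * cfg.n_case + [cfg.control_label] * cfg.n_control,
        index=values.index,
        name="group",
    )
    table = AbundanceTable(values, labels).normalize()
    annot = GramAnnotation({t.name: t.gram for t in cfg.taxa})
    return table, annot


def _high_low(arch: str) -> tuple[set[str], set[str]]:
    kind, k = _parse_archetype(arch)
    enzymes = list(PATHWAY_ENZYMES)
    if kind == "full_set":
        high = set(enzymes)
    elif kind == "none":
        high = set()
    elif kind == "bypass_lpxh":
        high = set(enzymes) - {"LpxH"}
    else:  # truncated_at:k
        high = set(enzymes[:k])
    return high, set(enzymes) - high


def generate_enzyme_profiles(
    taxa: list[str], archmap: ArchetypeMap, seed: int = 0
) -> EnzymeProfileSet:
    """Availability matrix from archetypes; deterministic given seed.

    High cells sit in [100·(1−noise), 100], low cells in [0, 100·noise];
    taxa without an archetype default to ``none``.  Modification enzymes
    (LpxE/LpxF) listed for a taxon are emitted as high cells.
    """
    rng = np.random.default_rng(seed)
    profiles: dict[str, dict[str, float]] = {}
    noise = archmap.noise
    for taxon in taxa:
        arch = archmap.archetypes.get(taxon, "none")
        high, low = _high_low(arch)
        row: dict[str, float] = {}
        for enzyme in PATHWAY_ENZYMES:
            u = float(rng.random())
            if enzyme in high:
                row[enzyme] = 100.0 - 100.0 * noise * u
            else:
                row[enzyme] = 100.0 * noise * u
        for enzyme in sorted(archmap.modifications.get(taxon, frozenset())):
            row[enzyme] = 100.0 - 100.0 * noise * float(rng.random())
        profiles[taxon] = row
    return EnzymeProfileSet(profiles)


# ---------------------------------------------------------------------------
# scenarios


def load_scenario(path: str | Path, seed: int = 0) -> tuple[CohortConfig, ArchetypeMap]:
    """Load a YAML scenario describing taxa, planted changes and archetypes."""
    doc = yaml.safe_load(Path(path).read_text())
    taxa = [
        TaxonSpec(
            name=str(t["name"]),
            gram=str(t.get("gram", "unknown")),
            base_mean=float(t["base_mean"]),
        )
        for t in doc["taxa"]
    ]
    planted: dict[str, float | str] = {}
    for taxon, change in (doc.get("planted_changes") or {}).items():
        planted[str(taxon)] = (
            NOVEL_IN_CASE if str(change) == NOVEL_IN_CASE else float(change)
        )
    cfg = CohortConfig(
        taxa=taxa,
        planted_changes=planted,
        n_case=int(doc.get("n_case", 36)),
        n_control=int(doc.get("n_control", 21)),
        dispersion=float(doc.get("dispersion", 0.25)),
        seed=seed,
    )
    mods = {
        str(t): frozenset(str(e) for e in enzymes)
        for t, enzymes in (doc.get("modifications") or {}).items()
    }
    archmap = ArchetypeMap(
        archetypes={str(t["name"]): str(t.get("archetype", "none")) for t in doc["taxa"]},
        noise=float(doc.get("enzyme_noise", 0.05)),
        modifications=mods,
    )
    return cfg, archmap


def paper_like_scenario(seed: int = 0) -> tuple[CohortConfig, ArchetypeMap]:
    """The packaged default scenario (see module docstring)."""
    ref = resources.files("lipaflow") / "scenarios" / "paper_like.yaml"
    with resources.as_file(ref) as path:
        return load_scenario(path, seed=seed)
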