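"""Reading, validating and writing the pipeline's tabular inputs/outputs.

Three inputs drive the analysis:

* an abundance table (TSV; samples as rows, taxa as columns, counts or
  relative abundances) plus a sample → group map,
* a Gram-status annotation (TSV; taxon → negative/positive/unknown),
* an enzyme-availability matrix (TSV; taxa as rows, enzymes as columns,
  cells = percent of sequenced strains carrying the enzyme).

Every abundance row is renormalized to percent so downstream code can
assume compositional rows summing to 100.  Taxon matching across the three
inputs is exact and case-sensitive after stripping surrounding whitespace;
placeholder names such as ``Lachnospiraceae_noname`` are kept verbatim.
All writers can emit a JSON sidecar recording run metadata (seed, config,
input checksums) next to the data file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .pathway import MODIFICATION_ENZYMES, PATHWAY_ENZYMES

logger = logging.getLogger(__name__)

__all__ = [
    "DataValidationError",
    "AbundanceTable",
    "GramAnnotation",
    "EnzymeProfileSet",
    "read_abundance_table",
    "read_gram_annotations",
    "read_enzyme_profiles",
    "write_abundance_table",
    "write_gram_annotations",
    "write_enzyme_profiles",
    "write_sidecar",
]

GRAM_STATUSES = ("negative", "positive", "unknown")
_VALID_ENZYME_COLUMNS = frozenset(PATHWAY_ENZYMES) | MODIFICATION_ENZYMES


class DataValidationError(ValueError):
    """An input table violates its contract."""


@dataclass
class AbundanceTable:
    """Samples × taxa relative abundances (percent) with group labels.

    ``values`` is a DataFrame indexed by sample id with taxon columns;
    ``group_labels`` maps each sample id to its cohort label.  Rows sum to
    100 after :meth:`normalize`.
    """

    values: pd.DataFrame
    group_labels: pd.Series
    level: str = "genus"

    def __post_init__(self) -> None:
        self.values.index = self.values.index.astype(str).str.strip()
        self.values.columns = self.values.columns.astype(str).str.strip()
        self.group_labels.index = self.group_labels.index.astype(str).str.strip()
        self.validate()

    def validate(self) -> None:
        if self.values.empty:
            raise DataValidationError("abundance table is empty")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise DataValidationError(f"duplicate sample ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].tolist()
            raise DataValidationError(f"duplicate taxon names: {dups}")
        arr = self.values.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            raise DataValidationError("non-finite abundance values")
        if (arr < 0).any():
            raise DataValidationError("negative abundance values")
        missing = set(self.values.index) - set(self.group_labels.index)
        if missing:
            raise DataValidationError(f"samples without a group label: {sorted(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.values.columns)

    @property
    def groups(self) -> list[str]:
        return sorted(set(self.group_labels.loc[self.sample_ids]))

    def samples_in(self, group: str) -> list[str]:
        labels = self.group_labels.loc[self.sample_ids]
        return [s for s in self.sample_ids if labels[s] == group]

    def normalize(self) -> "AbundanceTable":
        """Rescale every sample row to sum to 100 (percent composition)."""
        sums = self.values.sum(axis=1)
        zero = sums[sums <= 0]
        if len(zero):
            raise DataValidationError(
                f"zero-sum sample rows (upstream corruption?): {list(zero.index)}"
            )
        vals = self.values.div(sums, axis=0) * 100.0
        return AbundanceTable(vals, self.group_labels.copy(), self.level)

    def is_normalized(self, tol: float = 1e-6) -> bool:
        return bool(np.allclose(self.values.sum(axis=1), 100.0, atol=tol))


@dataclass
class GramAnnotation:
    """Taxon → Gram status (negative / positive / unknown)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        clean = {}
        for taxon, status in self.mapping.items():
            status = str(status).strip().lower()
            if status not in GRAM_STATUSES:
                raise DataValidationError(
                    f"bad Gram status {status!r} for {taxon!r}; "
                    f"expected one of {GRAM_STATUSES}"
                )
            clean[str(taxon).strip()] = status
        self.mapping = clean

    def status(self, taxon: str) -> str:
        """Status for a taxon; unannotated taxa are 'unknown'."""
        return self.mapping.get(taxon, "unknown")

    def __getitem__(self, taxon: str) -> str:
        return self.status(taxon)


@dataclass
class EnzymeProfileSet:
    """Per-taxon percentage of strains carrying each pathway enzyme.

    ``profiles`` maps taxon → {enzyme → percent in [0, 100]}; enzymes may
    be the nine core Lpx/Waa enzymes plus the optional LpxE/LpxF
    modification phosphatases.  Missing enzymes read as 0.
    """

    profiles: dict[str, dict[str, float]]
    strain_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, dict[str, float]] = {}
        for taxon, prof in self.profiles.items():
            taxon = str(taxon).strip()
            row: dict[str, float] = {}
            for enzyme, pct in prof.items():
                enzyme = str(enzyme).strip()
                if enzyme not in _VALID_ENZYME_COLUMNS:
                    raise DataValidationError(f"unknown enzyme column {enzyme!r}")
                pct = float(pct)
                if not (0.0 <= pct <= 100.0):
                    raise DataValidationError(
                        f"availability {pct} for {taxon}/{enzyme} outside [0, 100]"
                    )
                row[enzyme] = pct
            clean[taxon] = row
        self.profiles = clean
        for taxon, n in self.strain_counts.items():
            if int(n) <= 0:
                raise DataValidationError(f"non-positive strain count for {taxon!r}")

    @property
    def taxa(self) -> list[str]:
        return list(self.profiles)

    def availability(self, taxon: str, enzyme: str) -> float:
        return self.profiles.get(taxon, {}).get(enzyme, 0.0)

    def to_frame(self, enzymes: tuple[str, ...] = PATHWAY_ENZYMES) -> pd.DataFrame:
        """Taxa × enzymes percent matrix (the heatmap artifact)."""
        return pd.DataFrame(
            {e: [self.availability(t, e) for t in self.taxa] for e in enzymes},
            index=pd.Index(self.taxa, name="taxon"),
        )


# ---------------------------------------------------------------------------
# readers


def read_abundance_table(
    path: str | Path, group_map: str | Path, level: str = "genus"
) -> AbundanceTable:
    """Read a samples × taxa TSV plus a sample → group TSV.

    Values may be counts or percentages; each sample row is renormalized
    to percent.  Fails on negative entries, zero-sum rows, or samples
    missing from the group map.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise DataValidationError(f"empty abundance table: {path}")
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise DataValidationError(f"non-numeric abundance values in {path}: {exc}")
    gm = pd.read_csv(group_map, sep="\t", index_col=0).iloc[:, 0].astype(str)
    gm.index = gm.index.astype(str)
    table = AbundanceTable(df, gm, level=level)
    return table.normalize()


def read_gram_annotations(path: str | Path) -> GramAnnotation:
    """Read a two-column taxon → status TSV."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.shape[1] < 1:
        raise DataValidationError(f"gram annotation {path} needs a status column")
    return GramAnnotation(dict(df.iloc[:, 0].astype(str)))


def read_enzyme_profiles(path: str | Path) -> EnzymeProfileSet:
    """Read a taxa × enzymes percent TSV; blank cells read as 0.

    An optional ``n_strains`` column carries per-taxon strain counts.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    strain_counts: dict[str, int] = {}
    for col in df.columns:
        if str(col).strip().lower() in ("n_strains", "strain_count", "strains"):
            strain_counts = {
                str(t).strip(): int(v)
                for t, v in df[col].dropna().items()
            }
            df = df.drop(columns=[col])
    df = df.fillna(0.0)
    profiles = {
        str(taxon): {str(e): float(v) for e, v in row.items()}
        for taxon, row in df.iterrows()
    }
    return EnzymeProfileSet(profiles, strain_counts)


# ---------------------------------------------------------------------------
# writers


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def write_sidecar(data_path: str | Path, metadata: Mapping) -> Path:
    """Write ``<data file>.meta.json`` with run metadata and a checksum."""
    data_path = Path(data_path)
    doc = dict(metadata)
    doc["file"] = data_path.name
    doc["sha256_16"] = _checksum(data_path)
    sidecar = data_path.with_suffix(data_path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    return sidecar


def write_abundance_table(
    table: AbundanceTable,
    path: str | Path,
    group_map_path: str | Path | None = None,
    metadata: Mapping | None = None,
) -> None:
    path = Path(path)
    table.values.to_csv(path, sep="\t", index_label="sample_id")
    if group_map_path is not None:
        table.group_labels.rename("group").loc[table.sample_ids].to_csv(
            group_map_path, sep="\t", index_label="sample_id"
        )
    if metadata is not None:
        write_sidecar(path, metadata)


def write_gram_annotations(
    annot: GramAnnotation, path: str | Path, metadata: Mapping | None = None
) -> None:
    path = Path(path)
    pd.Series(annot.mapping, name="gram_status").to_csv(
        path, sep="\t", index_label="taxon"
    )
    if metadata is not None:
        write_sidecar(path, metadata)


def write_enzyme_profiles(
    profiles: EnzymeProfileSet, path: str | Path, metadata: Mapping | None = None
) -> None:
    path = Path(path)
    enzymes = tuple(PATHWAY_ENZYMES) + tuple(sorted(MODIFICATION_ENZYMES))
    used = [
        e
        for e in enzymes
        if any(e in prof for prof in profiles.profiles.values())
    ]
    df = profiles.to_frame(tuple(used))
    if profiles.strain_counts:
        df["n_strains"] = [profiles.strain_counts.get(t, "") for t in df.index]
    df.to_csv(path, sep="\t", index_label="taxon")
    if metadata is not None:
        write_sidecar(path, metadata)
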