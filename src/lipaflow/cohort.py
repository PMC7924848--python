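"""Group-level abundance summaries: AVD, Gram splits and rankings.

AVD ("average value distribution") is the per-group arithmetic mean of a
taxon's relative abundance.  From AVD vectors the module derives:

* Gram-status fractions — AVD mass per Gram stratum as percent of total,
* percent increase of each taxon in the case group versus control, with
  taxa absent from control flagged as novel rather than given an infinite
  ratio,
* the MAG/MAG0-style "top N most abundant" rankings (optionally Gram
  filtered), and the MIG-style "top N most increased" ranking.

Rankings are descriptive: no hypothesis testing is attached, matching the
way these comparisons are usually reported for small two-group cohorts.
Ties break lexicographically by taxon name so results are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import AbundanceTable, DataValidationError, GramAnnotation

__all__ = [
    "AvdVector",
    "ChangeTable",
    "GramSplit",
    "RankedTaxa",
    "compute_avd",
    "gram_fractions",
    "percent_increase",
    "top_abundant",
    "top_increased",
]

NOVEL_IN_CASE = "NOVEL_IN_CASE"
ABSENT_IN_CASE = "ABSENT_IN_CASE"


@dataclass
class AvdVector:
    """Per-taxon mean relative abundance (percent) within one group."""

    group: str
    values: pd.Series  # taxon -> percent

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index = self.values.index.astype(str)
        if (self.values < 0).any():
            raise DataValidationError("negative AVD values")

    @property
    def taxa(self) -> list[str]:
        return list(self.values.index)

    def __getitem__(self, taxon: str) -> float:
        return float(self.values.get(taxon, 0.0))

    def total(self) -> float:
        return float(self.values.sum())


@dataclass
class GramSplit:
    """Percent of a group's AVD mass per Gram stratum."""

    group: str
    percent_negative: float
    percent_positive: float
    percent_unknown: float

    def as_dict(self) -> dict[str, float]:
        return {
            "negative": self.percent_negative,
            "positive": self.percent_positive,
            "unknown": self.percent_unknown,
        }


@dataclass
class ChangeTable:
    """Per-taxon case-vs-control abundance change.

    ``frame`` columns: avd_case, avd_control, percent_increase (NaN where
    undefined), flag (empty, NOVEL_IN_CASE, or ABSENT_IN_CASE).
    """

    frame: pd.DataFrame

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    def novel_in_case(self) -> list[str]:
        return list(self.frame.index[self.frame["flag"] == NOVEL_IN_CASE])

    def absent_in_case(self) -> list[str]:
        return list(self.frame.index[self.frame["flag"] == ABSENT_IN_CASE])


@dataclass
class RankedTaxa:
    """A top-N ranking with per-taxon metric and cumulative share."""

    frame: pd.DataFrame  # index: taxon; columns: metric, cumulative_percent
    metric_name: str
    novel: list[str] = field(default_factory=list)

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)


def compute_avd(table: AbundanceTable, group: str) -> AvdVector:
    """Arithmetic mean of relative abundances over one group's samples."""
    samples = table.samples_in(group)
    if not samples:
        raise DataValidationError(f"no samples in group {group!r}")
    means = table.values.loc[samples].mean(axis=0)
    return AvdVector(group=group, values=means)


def gram_fractions(avd: AvdVector, annot: GramAnnotation) -> GramSplit:
    """Split a group's AVD mass by Gram status, as percent of total mass."""
    sums = {"negative": 0.0, "positive": 0.0, "unknown": 0.0}
    for taxon, value in avd.values.items():
        sums[annot.status(taxon)] += float(value)
    total = sum(sums.values())
    if total <= 0:
        # an all-zero AVD has no mass to apportion
        return GramSplit(avd.group, 0.0, 0.0, 100.0)
    return GramSplit(
        group=avd.group,
        percent_negative=100.0 * sums["negative"] / total,
        percent_positive=100.0 * sums["positive"] / total,
        percent_unknown=100.0 * sums["unknown"] / total,
    )


def percent_increase(avd_case: AvdVector, avd_control: AvdVector) -> ChangeTable:
    """Percent change of each taxon's AVD in case relative to control.

    Taxa with zero control AVD but positive case AVD are flagged
    NOVEL_IN_CASE (no finite ratio exists); taxa with zero case AVD are
    flagged ABSENT_IN_CASE.
    """
    taxa = sorted(set(avd_case.taxa) | set(avd_control.taxa))
    rows = []
    for taxon in taxa:
        case, control = avd_case[taxon], avd_control[taxon]
        if control > 0:
            pct = 100.0 * (case - control) / control
            flag = ABSENT_IN_CASE if case == 0 else ""
        elif case > 0:
            pct, flag = np.nan, NOVEL_IN_CASE
        else:
            pct, flag = np.nan, ""  # absent everywhere: no change to report
        rows.append((taxon, case, control, pct, flag))
    frame = pd.DataFrame(
        rows, columns=["taxon", "avd_case", "avd_control", "percent_increase", "flag"]
    ).set_index("taxon")
    return ChangeTable(frame)


def _ranked(series: pd.Series, n: int) -> pd.Series:
    """Sort descending with lexicographic tie-break; keep the top n."""
    df = series.rename("metric").reset_index()
    df.columns = ["taxon", "metric"]
    df = df.sort_values(["metric", "taxon"], ascending=[False, True])
    return df.set_index("taxon")["metric"].head(n)


def top_abundant(
    avd: AvdVector,
    annot: GramAnnotation | None = None,
    n: int = 15,
    gram_filter: str | None = None,
) -> RankedTaxa:
    """The n most abundant taxa, optionally restricted to one Gram stratum.

    ``cumulative_percent`` is the running share of the *filtered* AVD mass,
    so with ``gram_filter='negative'`` it reads "percent of the Gram-negative
    population", the way MAG coverage is quoted.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    values = avd.values
    if gram_filter is not None:
        if annot is None:
            raise DataValidationError("gram_filter requires an annotation")
        keep = [t for t in values.index if annot.status(t) == gram_filter]
        values = values.loc[keep]
    total = float(values.sum())
    top = _ranked(values, n)
    cumulative = (
        100.0 * top.cumsum() / total if total > 0 else top.cumsum() * 0.0
    )
    frame = pd.DataFrame({"metric": top, "cumulative_percent": cumulative})
    return RankedTaxa(frame=frame, metric_name=f"avd_{avd.group}")


def top_increased(changes: ChangeTable, n: int = 10) -> RankedTaxa:
    """The n taxa with the greatest finite percent increase.

    Taxa flagged NOVEL_IN_CASE carry no finite ratio; they are excluded
    from the ranking and returned on the side in ``novel``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    finite = changes.frame["percent_increase"].dropna()
    top = _ranked(finite, n)
    frame = pd.DataFrame({"metric": top})
    frame["cumulative_percent"] = np.nan  # shares are not meaningful for ratios
    return RankedTaxa(
        frame=frame,
        metric_name="percent_increase",
        novel=changes.novel_in_case(),
    )


# ---------------------------------------------------------------------------
# artifact writers


def write_avd(avds: list[AvdVector], path: str | Path) -> None:
    rows = [
        {"taxon": t, "group": a.group, "avd": float(v)}
        for a in avds
        for t, v in a.values.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_changes(changes: ChangeTable, path: str | Path) -> None:
    changes.frame.to_csv(path, sep="\t", index_label="taxon")


def write_rankings(rankings: dict[str, RankedTaxa], path: str | Path) -> None:
    rows = []
    for name, ranking in rankings.items():
        for rank, (taxon, row) in enumerate(ranking.frame.iterrows(), start=1):
            rows.append(
                {
                    "list": name,
                    "rank": rank,
                    "taxon": taxon,
                    "metric_name": ranking.metric_name,
                    "metric": row["metric"],
                    "cumulative_percent": row["cumulative_percent"],
                }
            )
        for taxon in ranking.novel:
            rows.append(
                {
                    "list": name,
                    "rank": "",
                    "taxon": taxon,
                    "metric_name": NOVEL_IN_CASE,
                    "metric": "",
                    "cumulative_percent": "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
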