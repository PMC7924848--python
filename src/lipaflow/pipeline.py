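"""End-to-end orchestration: inputs → AVD → rankings → products → summary.

``run_full_pipeline`` strings the analysis stages together and writes the
shared artifact set into an output directory:

* ``avd.tsv`` — per-group mean abundances,
* ``changes.tsv`` — case-vs-control change table,
* ``rankings.tsv`` — MAG/MAG0/MIG rankings,
* ``heatmap.tsv`` — taxa × enzymes availability matrix (+ PNG),
* ``products.tsv`` — per-taxon terminal products,
* ``sankey.json`` — product → taxon flow graph (+ PNG),
* ``summary.json`` — Gram splits, product distributions, final-stage
  fractions and the case-minus-control end-product delta,
* ``run.log`` — one structured line per stage.

The summary reports the abundance-weighted final-stage fractions (the
headline numbers) alongside genus-count-weighted fractions, and reports
distributions both with and without the no-pathway mass excluded, so the
reader can see which convention a number uses.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import cohort as co
from . import inference as inf
from . import io as lio
from .pathway import NO_PATHWAY, PathwayModel, build_default_pathway

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "PipelineError", "run_full_pipeline"]

ARTIFACTS = (
    "avd.tsv",
    "changes.tsv",
    "rankings.tsv",
    "heatmap.tsv",
    "products.tsv",
    "sankey.json",
    "summary.json",
    "run.log",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class RunConfig:
    abundance: Path
    group_map: Path
    gram_annotation: Path
    enzyme_profiles: Path
    out_dir: Path
    species_abundance: Path | None = None
    species_enzyme_profiles: Path | None = None
    case_label: str = "case"
    control_label: str = "control"
    n_top_abundant: int = 15
    n_top_increased: int = 10
    binarize_threshold: float = 50.0
    exclude_no_pathway: bool = True
    skip_allowed: tuple[str, ...] = ("LpxH",)
    seed: int = 0
    render_images: bool = True

    def __post_init__(self) -> None:
        if self.n_top_abundant < 1 or self.n_top_increased < 1:
            raise lio.DataValidationError("top-N sizes must be >= 1")
        if not (0.0 < self.binarize_threshold <= 100.0):
            raise lio.DataValidationError("binarize threshold outside (0, 100]")

    def config_hash(self) -> str:
        # fingerprint of the analysis, not of where it writes
        doc = {
            k: str(v)
            for k, v in dataclasses.asdict(self).items()
            if k not in ("out_dir", "render_images")
        }
        return hashlib.sha256(
            json.dumps(doc, sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(log, name: str, **params):
    log.append(
        json.dumps({"stage": name, **{k: str(v) for k, v in params.items()}},
                   sort_keys=True)
    )
    logger.info("stage %s %s", name, params)


def run_full_pipeline(cfg: RunConfig, model: PathwayModel | None = None) -> Path:
    """Run every stage and write all artifacts; returns the output dir."""
    if model is None:
        model = build_default_pathway(skip_allowed=cfg.skip_allowed)
    else:
        model = model.with_skip(cfg.skip_allowed)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}

    def _fail(stage: str, exc: Exception) -> PipelineError:
        return PipelineError(f"stage {stage!r} failed: {exc}")

    # -- ingest ---------------------------------------------------------
    try:
        table = lio.read_abundance_table(cfg.abundance, cfg.group_map)
        annot = lio.read_gram_annotations(cfg.gram_annotation)
        profiles = lio.read_enzyme_profiles(cfg.enzyme_profiles)
    except Exception as exc:
        raise _fail("ingest", exc)
    _stage(log, "ingest", abundance=cfg.abundance, samples=len(table.sample_ids),
           taxa=len(table.taxa))

    # -- stratify -------------------------------------------------------
    try:
        avd_case = co.compute_avd(table, cfg.case_label)
        avd_control = co.compute_avd(table, cfg.control_label)
        split_case = co.gram_fractions(avd_case, annot)
        split_control = co.gram_fractions(avd_control, annot)
    except Exception as exc:
        raise _fail("stratify", exc)
    co.write_avd([avd_case, avd_control], out / "avd.tsv")
    _stage(log, "stratify", case=cfg.case_label, control=cfg.control_label)

    # -- rank -----------------------------------------------------------
    try:
        changes = co.percent_increase(avd_case, avd_control)
        mag = co.top_abundant(avd_case, annot, cfg.n_top_abundant, "negative")
        mag0 = co.top_abundant(avd_control, annot, cfg.n_top_abundant, "negative")
        mig = co.top_increased(changes, cfg.n_top_increased)
    except Exception as exc:
        raise _fail("rank", exc)
    co.write_changes(changes, out / "changes.tsv")
    co.write_rankings({"MAG": mag, "MAG0": mag0, "MIG": mig}, out / "rankings.tsv")
    _stage(log, "rank", n_top_abundant=cfg.n_top_abundant,
           n_top_increased=cfg.n_top_increased)

    # -- infer ----------------------------------------------------------
    try:
        setmap = inf.binarize_enzymes(profiles, cfg.binarize_threshold)
        # taxa observed in the cohort but missing from the matrix stay
        # no-pathway; keep their mass accounted for
        missing = [t for t in table.taxa if t not in setmap.sets]
        if missing:
            logger.warning(
                "%d taxa missing from enzyme matrix; assigned no pathway", len(missing)
            )
        assignments = inf.assign_products(setmap, model)
        counts = inf.stage_counts(
            assignments,
            {
                "MAG": [t for t in mag.taxa if t in assignments.stages],
                "MAG0": [t for t in mag0.taxa if t in assignments.stages],
                "MIG": [t for t in mig.taxa if t in assignments.stages],
            },
            model,
        )
        dists = {}
        for excl in (True, False):
            dists[excl] = {
                "case": inf.product_distribution(assignments, avd_case, excl, model),
                "control": inf.product_distribution(assignments, avd_control, excl, model),
            }
        excl = cfg.exclude_no_pathway
        delta = inf.group_endproduct_delta(
            dists[excl]["case"], dists[excl]["control"], model
        )
        sankey_case = inf.build_sankey(assignments, avd_case, model)
    except Exception as exc:
        raise _fail("infer", exc)

    profiles.to_frame().to_csv(out / "heatmap.tsv", sep="\t", index_label="taxon")
    inf.write_products_table(
        assignments, {"case": avd_case, "control": avd_control},
        out / "products.tsv", model,
    )
    sankey_case.to_json(out / "sankey.json")
    _stage(log, "infer", threshold=cfg.binarize_threshold,
           exclude_no_pathway=cfg.exclude_no_pathway)

    # -- species-level acylation (optional) ------------------------------
    acylation = None
    if cfg.species_abundance is not None and cfg.species_enzyme_profiles is not None:
        try:
            sp_table = lio.read_abundance_table(cfg.species_abundance, cfg.group_map)
            sp_profiles = lio.read_enzyme_profiles(cfg.species_enzyme_profiles)
            sp_setmap = inf.binarize_enzymes(
                sp_profiles, cfg.binarize_threshold, include_modifications=True
            )
            acylation = {
                g: inf.acylation_distribution(
                    sp_setmap, co.compute_avd(sp_table, g), model
                )
                for g in (cfg.case_label, cfg.control_label)
            }
        except Exception as exc:
            raise _fail("acylation", exc)
        _stage(log, "acylation", species_abundance=cfg.species_abundance)

    # -- summarize -------------------------------------------------------
    def _dist_doc(dist: inf.ProductDistribution) -> dict:
        return {
            "percent_by_product": {
                k: dist.percentages[k] for k in sorted(dist.percentages)
            },
            "included_mass_percent": dist.included_mass,
            "exclude_no_pathway": dist.exclude_no_pathway,
            "final_stage_percent": inf.final_stage_fraction(dist, model),
        }

    count_frac = {}
    for name in ("MAG", "MAG0", "MIG"):
        sub = counts[counts["list"] == name]
        total = sub["count"].sum()
        final = sub[sub["product"].isin(model.final_stage_products)]["count"].sum()
        count_frac[name] = 100.0 * final / total if total else 0.0

    summary = {
        "metadata": meta,
        "gram_split_percent_of_avd_mass": {
            "case": split_case.as_dict(),
            "control": split_control.as_dict(),
            "gram_negative_difference_pp": split_case.percent_negative
            - split_control.percent_negative,
        },
        "rankings": {
            "MAG": mag.taxa,
            "MAG0": mag0.taxa,
            "MIG": mig.taxa,
            "novel_in_case": mig.novel,
        },
        "product_distribution_abundance_weighted": {
            "excluding_no_pathway": {
                g: _dist_doc(d) for g, d in dists[True].items()
            },
            "including_no_pathway": {
                g: _dist_doc(d) for g, d in dists[False].items()
            },
        },
        "final_stage_percent_of_list_genus_counts": count_frac,
        "endproduct_delta_pp": delta,
        "stage_counts": counts.to_dict(orient="records"),
        "acylation_distribution_percent": acylation,
        "threshold_sensitivity": _threshold_sensitivity(
            profiles, avd_case, avd_control, model, cfg
        ),
    }
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log) + "\n")

    if cfg.render_images:
        from . import report

        report.render_heatmap(out / "heatmap.tsv", out / "heatmap.png")
        report.render_sankey(out / "sankey.json", out / "sankey.png")
    return out


def _threshold_sensitivity(profiles, avd_case, avd_control, model, cfg):
    """Final-stage fractions at credit thresholds 10/50/90 percent."""
    rows = {}
    for thr in (10.0, 50.0, 90.0):
        setmap = inf.binarize_enzymes(profiles, thr)
        assignments = inf.assign_products(setmap, model)
        doc = {}
        for label, avd in (("case", avd_case), ("control", avd_control)):
            dist = inf.product_distribution(
                assignments, avd, cfg.exclude_no_pathway, model
            )
            doc[label] = inf.final_stage_fraction(dist, model)
        rows[f"threshold_{int(thr)}"] = doc
    return rows
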