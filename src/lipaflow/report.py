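"""Static figure rendering and human-readable report assembly.

Everything here reads the artifacts written by the pipeline and lays them
out; no number in the report is computed independently of the artifact
files, so the report is always traceable to a TSV/JSON row.
"""

from __future__ import annotations

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["render_heatmap", "render_sankey", "render_report", "ReportError"]


class ReportError(FileNotFoundError):
    """A required artifact is missing."""


def render_heatmap(heatmap_tsv: str | Path, png: str | Path) -> None:
    """Taxa × enzymes availability heatmap (blue 0% → red 100%)."""
    df = pd.read_csv(heatmap_tsv, sep="\t", index_col=0)
    fig, ax = plt.subplots(
        figsize=(0.6 * len(df.columns) + 2, 0.22 * len(df) + 1.5)
    )
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="coolwarm", vmin=0, vmax=100)
    ax.set_xticks(range(len(df.columns)), df.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(df)), df.index, fontsize=5)
    fig.colorbar(im, ax=ax, label="% strains with enzyme")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)


def render_sankey(sankey_json: str | Path, png: str | Path, max_taxa: int = 30) -> None:
    """Two-column ribbon plot of product → taxon flows, widths = AVD."""
    doc = json.loads(Path(sankey_json).read_text())
    links = sorted(doc["links"], key=lambda l: -l["weight"])[:max_taxa]
    products = [n["id"] for n in doc["nodes"] if n["kind"] == "product"]
    prod_mass = {p: 0.0 for p in products}
    for l in links:
        prod_mass[l["source"]] += l["weight"]
    total = sum(l["weight"] for l in links) or 1.0

    fig, ax = plt.subplots(figsize=(8, max(4, 0.25 * len(links))))
    gap = 0.02 * total
    # left column: products stacked by rank; right column: taxa by weight
    y = 0.0
    left_pos = {}
    for p in products:
        if prod_mass[p] <= 0:
            continue
        left_pos[p] = y
        ax.fill_betweenx([y, y + prod_mass[p]], -0.05, 0.0, color="tab:blue")
        ax.text(-0.07, y + prod_mass[p] / 2, p, ha="right", va="center", fontsize=7)
        y += prod_mass[p] + gap
    y = 0.0
    cmap = plt.get_cmap("tab20")
    for i, l in enumerate(links):
        w = l["weight"]
        y0_left = left_pos[l["source"]]
        left_pos[l["source"]] += w
        xs = np.linspace(0, 1, 50)
        ease = 3 * xs**2 - 2 * xs**3
        top = y0_left + (y - y0_left) * ease
        ax.fill_between(xs, top, top + w, color=cmap(i % 20), alpha=0.6, lw=0)
        ax.text(1.02, y + w / 2, f"{l['target']} ({w:.1f})", va="center", fontsize=6)
        y += w + gap
    ax.set_xlim(-0.6, 1.6)
    ax.axis("off")
    ax.set_title("Terminal lipid A product per taxon (ribbon width = AVD %)")
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)


def _require(path: Path) -> Path:
    if not path.exists():
        raise ReportError(f"missing artifact: {path.name}")
    return path


def render_report(artifact_dir: str | Path) -> Path:
    """Assemble report.md (+ figures) from a pipeline artifact directory."""
    d = Path(artifact_dir)
    summary = json.loads(_require(d / "summary.json").read_text())
    rankings = pd.read_csv(_require(d / "rankings.tsv"), sep="\t")
    _require(d / "avd.tsv")
    _require(d / "changes.tsv")
    _require(d / "products.tsv")
    heatmap_tsv = _require(d / "heatmap.tsv")
    sankey_json = _require(d / "sankey.json")

    render_heatmap(heatmap_tsv, d / "heatmap.png")
    render_sankey(sankey_json, d / "sankey.png")
    _render_gram_pies(summary, d / "gram_split.png")
    _render_stage_bars(summary, d / "stage_counts.png")

    lines = ["# Endotoxin production potential report", ""]

    lines += ["## 1. Gram-status stratification", ""]
    gram = summary["gram_split_percent_of_avd_mass"]
    for group in ("case", "control"):
        s = gram[group]
        lines.append(
            f"- **{group}**: {s['negative']:.1f}% Gram-negative, "
            f"{s['positive']:.1f}% Gram-positive, {s['unknown']:.1f}% unknown"
        )
    lines.append(
        f"- Gram-negative difference (case − control): "
        f"{gram['gram_negative_difference_pp']:+.2f} pp"
    )
    lines += ["", "![gram split](gram_split.png)", ""]

    lines += ["## 2. Abundance and increase rankings", ""]
    for name in ("MAG", "MAG0", "MIG"):
        sub = rankings[rankings["list"] == name]
        lines.append(f"### {name}")
        lines.append("")
        lines.append("| rank | taxon | metric | cumulative % |")
        lines.append("|---|---|---|---|")
        for _, row in sub.iterrows():
            lines.append(
                f"| {row['rank']} | {row['taxon']} | {row['metric']} "
                f"| {row['cumulative_percent']} |"
            )
        lines.append("")

    lines += ["## 3. Enzyme availability heatmap", "", "![heatmap](heatmap.png)", ""]
    lines += ["## 4. Synthesis-stage genus counts", "",
              "![stage counts](stage_counts.png)", ""]
    lines += ["## 5. Taxon → product flows", "", "![sankey](sankey.png)", ""]

    lines += ["## 6. End products and acylation", ""]
    excl = summary["product_distribution_abundance_weighted"]["excluding_no_pathway"]
    for group in ("case", "control"):
        lines.append(
            f"- **{group}** final-stage products (no-pathway mass excluded): "
            f"{excl[group]['final_stage_percent']:.1f}%"
        )
    lines.append(
        f"- End-product delta (case − control): "
        f"{summary['endproduct_delta_pp']:+.2f} pp"
    )
    acyl = summary.get("acylation_distribution_percent")
    if acyl:
        lines += ["", "| class | case % | control % |", "|---|---|---|"]
        for cls in sorted(acyl["case"]):
            lines.append(
                f"| {cls} | {acyl['case'][cls]:.2f} | {acyl['control'][cls]:.2f} |"
            )
    lines.append("")

    out = d / "report.md"
    out.write_text("\n".join(lines))
    return out


def _render_gram_pies(summary: dict, png: Path) -> None:
    gram = summary["gram_split_percent_of_avd_mass"]
    fig, axes = plt.subplots(1, 2, figsize=(8, 4))
    for ax, group in zip(axes, ("control", "case")):
        s = gram[group]
        vals = [s["negative"], s["positive"], s["unknown"]]
        labels = [f"Gram −ve {vals[0]:.0f}%", f"Gram +ve {vals[1]:.0f}%",
                  f"unknown {vals[2]:.0f}%"]
        keep = [i for i, v in enumerate(vals) if v > 0]
        ax.pie([vals[i] for i in keep], labels=[labels[i] for i in keep],
               colors=["tab:red", "tab:blue", "tab:gray"][: len(keep)])
        ax.set_title(group)
    fig.tight_layout()
    fig.savefig(png, dpi=120)
    plt.close(fig)


def _render_stage_bars(summary: dict, png: Path) -> None:
    counts = pd.DataFrame(summary["stage_counts"])
    if counts.empty:
        return
    pivot = counts.pivot_table(
        index="product", columns="list", values="count", sort=False
    )
    order = counts.drop_duplicates("product").sort_values("rank")["product"]
    pivot = pivot.loc[order]
    ax = pivot.plot.bar(figsize=(9, 4))
    ax.set_ylabel("genus count")
    ax.set_xlabel("terminal product")
    plt.xticks(rotation=45, ha="right")
    plt.tight_layout()
    plt.savefig(png, dpi=120)
    plt.close()
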