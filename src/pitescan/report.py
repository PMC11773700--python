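"""CSV export and figure rendering.

Output schema of the hits CSV (RFC 4180, one row per hit, scan order)::

    pirna_name,pirna_sequence,te_name,te_family,te_class,chrom,start,end,
    te_strand,match_offset,orientation,seed_mismatches,complementarity_percent

Coordinates are 0-based half-open; records without a parseable locus leave
chrom/start/end empty. Figures: a per-class bar chart of distinct matched
TE counts with a star over classes enriched at P ≤ 0.05, and a karyotype-
style plot of matched TE midpoints along chromosome ideograms.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .errors import NothingToPlot
from .reference import CLASS_ORDER, ChromTable, natural_sort_key
from .scan import MatchHit
from .stats import EnrichmentResult

logger = logging.getLogger(__name__)

CSV_COLUMNS = [
    "pirna_name", "pirna_sequence", "te_name", "te_family", "te_class",
    "chrom", "start", "end", "te_strand", "match_offset", "orientation",
    "seed_mismatches", "complementarity_percent",
]

_CLASS_COLORS = {
    "DNA": "#1f77b4", "LTR": "#d62728", "LINE": "#2ca02c", "SINE": "#9467bd",
    "RC": "#ff7f0e", "Satellite": "#8c564b", "Unclassified": "#7f7f7f",
}


def hit_to_row(hit: MatchHit) -> list[str]:
    te = hit.te
    return [
        hit.pirna_name,
        hit.pirna_sequence,
        te.name,
        te.family,
        te.te_class,
        te.chrom if te.has_locus else "",
        str(te.start) if te.has_locus else "",
        str(te.end) if te.has_locus else "",
        te.strand,
        str(hit.offset),
        hit.orientation,
        str(hit.seed_mismatches),
        f"{hit.complementarity_percent:.1f}",
    ]


def export_csv(hits: Iterable[MatchHit], path: str | Path) -> Path:
    """Write the hits CSV; header-only file when there are no hits."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for hit in hits:
            writer.writerow(hit_to_row(hit))
    return path


def export_enrichment_csv(results: Iterable[EnrichmentResult], path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["te_class", "observed", "total", "null_p", "p_value",
                         "significant"])
        for r in results:
            writer.writerow([r.te_class, r.observed, r.total,
                             f"{r.null_p:.6g}", f"{r.p_value:.6g}",
                             "yes" if r.significant else "no"])
    return path


def plot_class_counts(results: Sequence[EnrichmentResult], path: str | Path,
                      image_format: str = "png", dpi: int = 150,
                      title: str = "Complementary TEs by class") -> Path:
    """Bar chart of distinct matched TE records per class.

    Only classes with at least one matched record get a bar; classes
    enriched at P ≤ 0.05 are starred. Raises :class:`NothingToPlot` when
    every class count is zero.
    """
    if dpi < 72:
        raise ValueError("dpi must be >= 72")
    shown = [r for r in sorted(results, key=lambda r: CLASS_ORDER.index(r.te_class))
             if r.observed > 0]
    if not shown:
        raise NothingToPlot("no matched TE records to plot")
    path = Path(path).with_suffix("." + image_format.lower())
    fig, ax = plt.subplots(figsize=(6, 4))
    xs = range(len(shown))
    heights = [r.observed for r in shown]
    colors = [_CLASS_COLORS[r.te_class] for r in shown]
    ax.bar(xs, heights, color=colors, edgecolor="black", linewidth=0.5)
    pad = max(heights) * 0.03
    for x, r in zip(xs, shown):
        if r.significant:
            ax.text(x, r.observed + pad, "*", ha="center", va="bottom",
                    fontsize=16, fontweight="bold")
    ax.set_xticks(list(xs))
    ax.set_xticklabels([r.te_class for r in shown])
    ax.set_ylabel("Distinct complementary TE copies")
    ax.set_xlabel("TE class (* : binomial P ≤ 0.05)")
    ax.set_title(title)
    ax.set_ylim(0, max(heights) * 1.15 + 1)
    fig.tight_layout()
    fig.savefig(path, format=image_format.lower(), dpi=dpi)
    plt.close(fig)
    return path


def plot_chromosomal(hits: Sequence[MatchHit], chrom_table: ChromTable,
                     path: str | Path, image_format: str = "png",
                     dpi: int = 150,
                     title: str = "Complementary TE loci") -> Path:
    """Karyotype-style plot: one ideogram per chromosome, one mark per hit.

    Each matched TE is marked at its interval midpoint, colored by class.
    Hits without a locus, or on chromosomes absent from the table, are
    dropped with a warning; raises :class:`NothingToPlot` when nothing
    remains.
    """
    if dpi < 72:
        raise ValueError("dpi must be >= 72")
    placed: list[tuple[str, float, str]] = []  # (display chrom, midpoint, class)
    for hit in hits:
        te = hit.te
        if not te.has_locus:
            logger.warning("hit on %s has no locus; excluded from chromosomal plot",
                           te.name)
            continue
        display = chrom_table.display_name(te.chrom)
        if display is None:
            logger.warning("chromosome %r not in length table; hit on %s dropped",
                           te.chrom, te.name)
            continue
        placed.append((display, te.midpoint, te.te_class))
    if not placed:
        raise NothingToPlot("no hits with plottable loci")
    chroms = sorted(chrom_table.names(), key=natural_sort_key)
    ypos = {name: i for i, name in enumerate(reversed(chroms))}
    path = Path(path).with_suffix("." + image_format.lower())
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(chroms) + 1.5))
    for name in chroms:
        length = chrom_table.get(name)
        ax.hlines(ypos[name], 0, length, color="lightgray", linewidth=6, zorder=1)
    seen_classes: list[str] = []
    for display, mid, cls in placed:
        ax.scatter(mid, ypos[display], marker="|", s=140,
                   color=_CLASS_COLORS[cls], zorder=2,
                   label=cls if cls not in seen_classes else None)
        if cls not in seen_classes:
            seen_classes.append(cls)
    ax.set_yticks([ypos[c] for c in chroms])
    ax.set_yticklabels(chroms)
    ax.set_xlabel("Position (bp)")
    ax.set_title(title)
    ax.legend(loc="upper right", fontsize=8, title="TE class")
    fig.tight_layout()
    fig.savefig(path, format=image_format.lower(), dpi=dpi)
    plt.close(fig)
    return path


def read_hits_csv(path: str | Path) -> list[list[str]]:
    """Read back a hits CSV as raw rows (header excluded)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != CSV_COLUMNS:
        raise ValueError(f"{path} is not a pitescan hits CSV")
    return rows[1:]
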