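"""Peak annotation: nearest transcriptional unit, location and transcript class.

Classification is by peak midpoint with precedence promoter-TSS > TES >
exon > intergenic, using strand-aware windows around the TSS and TES. The
assigned gene is the one with the nearest TSS within a search radius;
distance to TSS is signed, negative upstream of the TSS on the gene's
strand. A midpoint equidistant from two TSSs (e.g. a bidirectional
promoter) is assigned the lexicographically smaller gene_id.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

logger = logging.getLogger(__name__)

LOCATION_CLASSES = ("promoter-TSS", "TES", "exon", "intergenic")


@dataclass(frozen=True)
class PeakAnnotation:
    peak_id: str
    gene_id: str | None
    distance_to_tss: int | None
    location_class: str
    transcript_class: str


def _parse_exons(spec: str) -> list[tuple[int, int]]:
    blocks = []
    for block in str(spec).split(","):
        if "-" in block:
            a, b = block.split("-")
            blocks.append((int(a), int(b)))
    return blocks


def annotate_peaks(
    peaks: Sequence[GenomicInterval],
    gene_models: pd.DataFrame,
    promoter_window: tuple[int, int] = (-1000, 100),
    tes_window: tuple[int, int] = (-100, 1000),
    search_radius: int = 10000,
) -> pd.DataFrame:
    """Annotate peaks against a stranded gene table.

    ``gene_models`` needs columns gene_id, chrom, strand, tss, tes, biotype
    and optionally exons ("start-end[,start-end...]"); without an exons
    column the gene body (min/max of tss/tes) is used as a single exon
    block. Returns a DataFrame with one row per peak: gene_id,
    distance_to_tss, location_class, transcript_class.
    """
    if len(gene_models) == 0:
        logger.warning("empty gene model: all peaks annotated intergenic")
        return pd.DataFrame(
            {
                "peak_id": [p.name for p in peaks],
                "gene_id": "",
                "distance_to_tss": np.nan,
                "location_class": "intergenic",
                "transcript_class": "other",
            }
        ).set_index("peak_id")

    genes = gene_models.reset_index(drop=True)
    by_chrom: dict[str, pd.DataFrame] = {
        str(c): g.sort_values(["tss", "gene_id"]).reset_index(drop=True)
        for c, g in genes.groupby("chrom")
    }

    rows = []
    for peak in peaks:
        mid = peak.midpoint
        g = by_chrom.get(peak.chrom)
        record = {
            "peak_id": peak.name,
            "gene_id": "",
            "distance_to_tss": np.nan,
            "location_class": "intergenic",
            "transcript_class": "other",
        }
        if g is not None:
            tss = g["tss"].to_numpy()
            abs_d = np.abs(tss - mid)
            within = abs_d <= search_radius
            if within.any():
                cand = np.flatnonzero(within)
                best_abs = abs_d[cand].min()
                tied = cand[abs_d[cand] == best_abs]
                # ties (bidirectional promoters): lexicographically smaller id
                gi = tied[np.argmin(g.loc[tied, "gene_id"].to_numpy())]
                gene = g.loc[gi]
                sign = 1 if gene["strand"] == "+" else -1
                record["gene_id"] = gene["gene_id"]
                record["distance_to_tss"] = int(sign * (mid - gene["tss"]))
                record["transcript_class"] = (
                    gene["biotype"] if gene["biotype"] in ("mRNA", "tRNA") else "other"
                )
                record["location_class"] = _classify(
                    mid, gene, promoter_window, tes_window
                )
        rows.append(record)
    return pd.DataFrame(rows).set_index("peak_id")


def _classify(
    mid: int,
    gene: pd.Series,
    promoter_window: tuple[int, int],
    tes_window: tuple[int, int],
) -> str:
    sign = 1 if gene["strand"] == "+" else -1
    d_tss = sign * (mid - gene["tss"])
    if promoter_window[0] <= d_tss <= promoter_window[1]:
        return "promoter-TSS"
    d_tes = sign * (mid - gene["tes"])
    if tes_window[0] <= d_tes <= tes_window[1]:
        return "TES"
    if "exons" in gene.index and pd.notna(gene.get("exons")):
        blocks = _parse_exons(gene["exons"])
    else:
        lo, hi = sorted((int(gene["tss"]), int(gene["tes"])))
        blocks = [(lo, hi)]
    for a, b in blocks:
        if a <= mid < b:
            return "exon"
    return "intergenic"
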