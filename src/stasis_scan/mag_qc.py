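"""MAG bookkeeping: bin curation, quality tiers, genome size, coding density.

Completeness and contamination are consumed as externally estimated values
(CheckM-style percentages); nothing here re-estimates them. Retention
follows the survey design: bins with completeness >= 40% and contamination
<= 5% count as MAGs, tiered into high (>= 90%), medium (70-89%) and partial
(40-69%) quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .records import GenomeRecord

__all__ = [
    "classify_quality",
    "estimate_genome_size",
    "classify_genome_size",
    "coding_density",
    "curate_bin",
    "CurationReport",
    "SMALL_GENOME_MBP",
]

SMALL_GENOME_MBP = 2_100_000  # small/large split: est. genome size <= 2.1 Mbp
GC_DEVIATION_FRACTION = 0.15  # relative band around the bin median GC
FOREIGN_LABEL_FRACTION = 0.30  # max share of labels from a non-modal class


def classify_quality(completeness: float, contamination: float) -> str:
    """Quality tier from (completeness, contamination), both percentages.

    Returns one of ``high`` (completeness >= 90), ``medium`` (70-89),
    ``partial`` (40-69) or ``rejected`` (completeness < 40 or
    contamination > 5).
    """
    for name, v in (("completeness", completeness), ("contamination", contamination)):
        if not 0.0 <= v <= 100.0:
            raise ValueError(f"{name} out of range [0, 100]: {v}")
    if completeness < 40.0 or contamination > 5.0:
        return "rejected"
    if completeness >= 90.0:
        return "high"
    if completeness >= 70.0:
        return "medium"
    return "partial"


def estimate_genome_size(
    assembly_length: float, completeness: float, contamination: float
) -> float:
    """Estimated genome size in bp.

    The assembly length is scaled up by the estimated completeness and down
    by the estimated contamination:
    ``length / (completeness/100) * ((100 - contamination)/100)``.
    """
    if completeness <= 0:
        raise ZeroDivisionError("completeness must be > 0 to estimate genome size")
    return assembly_length / (completeness / 100.0) * ((100.0 - contamination) / 100.0)


def classify_genome_size(est_size: float) -> str:
    """``small`` iff estimated size <= 2.1 Mbp, else ``large``."""
    if est_size <= 0:
        raise ValueError("estimated genome size must be > 0")
    return "small" if est_size <= SMALL_GENOME_MBP else "large"


def coding_density(gene_spans, genome_length: int) -> float:
    """Fraction of the genome covered by coding sequence.

    ``gene_spans`` is an iterable of (start, end) 1-based inclusive pairs or
    objects with ``.start``/``.end``; overlapping spans are counted once
    (interval union). Coding density serves as a surrogate for genome size
    in the downstream analyses.
    """
    if genome_length <= 0:
        raise ValueError("genome length must be > 0")
    spans = []
    for g in gene_spans:
        s, e = (g.start, g.end) if hasattr(g, "start") else (g[0], g[1])
        if not (1 <= s <= e <= genome_length):
            raise ValueError(f"gene span ({s}, {e}) outside genome of {genome_length} bp")
        spans.append((s, e))
    if not spans:
        return 0.0
    spans.sort()
    covered = 0
    cur_s, cur_e = spans[0]
    for s, e in spans[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered / genome_length


@dataclass
class CurationReport:
    """Outcome of post-binning curation for one bin."""

    mag_id: str
    bin_class: str | None
    discards: pd.DataFrame  # columns: contig_id, rule, detail


def curate_bin(record: GenomeRecord) -> tuple[GenomeRecord, CurationReport]:
    """Taxonomy- and GC-based post-binning curation.

    The bin class is the modal class over all contig protein labels (ties
    broken lexicographically). A contig is discarded when (a) more than 30%
    of its own labels belong to a class other than the bin class, (b) it
    carries no taxonomy labels at all, or (c) its GC content deviates from
    the bin median GC by more than 15% of that median (relative band).
    Discarding every contig yields an empty bin with a warning-style report,
    not an error.
    """
    if not record.contigs:
        raise ValueError("bin has no contigs")
    all_labels = [l for labs in record.contig_taxonomy.values() for l in labs]
    if all_labels:
        counts = pd.Series(all_labels).value_counts()
        top = counts[counts == counts.max()]
        bin_class = sorted(top.index)[0]
    else:
        bin_class = None
    gcs = record.contig_gc or {}
    median_gc = float(np.median([gcs[c] for c in record.contigs])) if gcs else 0.0

    discards = []
    kept: dict[str, str] = {}
    for cid, seq in record.contigs.items():
        labels = record.contig_taxonomy.get(cid, [])
        if not labels:
            discards.append(
                {"contig_id": cid, "rule": "no_taxonomy", "detail": "0 labels"}
            )
            continue
        foreign = sum(l != bin_class for l in labels) / len(labels)
        if foreign > FOREIGN_LABEL_FRACTION:
            discards.append(
                {
                    "contig_id": cid,
                    "rule": "foreign_class",
                    "detail": f"{100 * foreign:.1f}% labels outside {bin_class}",
                }
            )
            continue
        gc = gcs.get(cid, median_gc)
        if median_gc > 0 and abs(gc - median_gc) > GC_DEVIATION_FRACTION * median_gc:
            discards.append(
                {
                    "contig_id": cid,
                    "rule": "gc_outlier",
                    "detail": f"GC {gc:.2f} vs median {median_gc:.2f}",
                }
            )
            continue
        kept[cid] = seq

    report = CurationReport(
        mag_id=record.mag_id,
        bin_class=bin_class,
        discards=pd.DataFrame(discards, columns=["contig_id", "rule", "detail"]),
    )
    if not kept:
        import warnings

        warnings.warn(f"bin {record.mag_id}: all contigs discarded", stacklevel=2)
    curated = GenomeRecord(
        mag_id=record.mag_id,
        contigs=kept,
        est_completeness=record.est_completeness,
        est_contamination=record.est_contamination,
        contig_taxonomy={c: record.contig_taxonomy.get(c, []) for c in kept},
        contig_gc={c: (record.contig_gc or {}).get(c, 0.0) for c in kept},
    )
    return curated, report
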