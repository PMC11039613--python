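"""Core in-memory records shared across the pipeline.

The pipeline operates on draft bacterial genomes (typically
metagenome-assembled genomes, MAGs), their gene models and proteomes, and
the species clusters they form. These light dataclasses are the common
currency between the modules; tabular results are plain pandas DataFrames.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import pandas as pd

__all__ = [
    "GenomeRecord",
    "GeneModel",
    "Segment",
    "ProteinRecord",
    "SpeciesCluster",
    "gc_percent",
]


def gc_percent(seq: str) -> float:
    """GC content of a nucleotide sequence, in percent."""
    if not seq:
        return 0.0
    s = seq.upper()
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


@dataclass
class GeneModel:
    """A protein-coding gene on a contig (1-based, inclusive coordinates)."""

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str = "+"
    ko: str | None = None
    compartment: str | None = None  # truth or predicted label: "SP" | "CP"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GenomeRecord:
    """A (possibly partial) genome: contigs plus quality metadata.

    ``contig_taxonomy`` maps contig_id -> list of class-level labels, one per
    protein top-hit on that contig; it is consumed by the bin-curation rules.
    ``contig_gc`` is computed lazily from the sequences unless provided.
    """

    mag_id: str
    contigs: dict[str, str]
    est_completeness: float = 100.0
    est_contamination: float = 0.0
    contig_taxonomy: dict[str, list[str]] = field(default_factory=dict)
    contig_gc: dict[str, float] | None = None

    def __post_init__(self) -> None:
        for cid, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {cid!r} of {self.mag_id!r} is empty")
        if self.est_completeness <= 0:
            raise ValueError("completeness must be > 0")
        if self.contig_gc is None:
            self.contig_gc = {c: gc_percent(s) for c, s in self.contigs.items()}

    @property
    def length(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class Segment:
    """One topology segment of a protein (1-based, inclusive)."""

    kind: str  # "signal" | "cytoplasmic" | "non_cytoplasmic" | "transmembrane"
    start: int
    end: int

    KINDS = ("signal", "cytoplasmic", "non_cytoplasmic", "transmembrane")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if not (1 <= self.start <= self.end):
            raise ValueError(f"bad segment coordinates ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ProteinRecord:
    """A protein with (optionally) its membrane topology.

    The compartment is derived, not stored: a protein belongs to the secreted
    proteome (SP) iff its topology contains a signal-peptide segment,
    otherwise to the cytoplasmic proteome (CP).
    """

    protein_id: str
    sequence: str = ""
    topology: list[Segment] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = sorted(self.topology, key=lambda s: s.start)
        for a, b in zip(segs, segs[1:]):
            if b.start <= a.end:
                raise ValueError(
                    f"{self.protein_id}: overlapping topology segments "
                    f"{(a.start, a.end)} and {(b.start, b.end)}"
                )
        self.topology = segs
        if self.sequence and segs and segs[-1].end > len(self.sequence):
            raise ValueError(f"{self.protein_id}: topology extends past sequence end")

    @property
    def compartment(self) -> str:
        return "SP" if any(s.kind == "signal" for s in self.topology) else "CP"


@dataclass
class SpeciesCluster:
    """A set of genomes grouped at the bacterial species threshold.

    Membership requires every retained within-cluster edge to pass ANI >= 95%
    with conserved-DNA fraction >= 0.70; clusters with at least
    ``min_members`` genomes (9 by default) are flagged eligible for the
    intraspecific analyses.
    """

    cluster_id: str
    members: list[str]
    ani_matrix: pd.DataFrame | None = None
    analysis_eligible: bool = False

    @cached_property
    def mean_ani(self) -> float:
        """Mean pairwise ANI over the off-diagonal of the matrix."""
        if self.ani_matrix is None or len(self.members) < 2:
            return float("nan")
        m = self.ani_matrix.to_numpy(dtype=float)
        iu = np.triu_indices_from(m, k=1)
        vals = m[iu]
        return float(np.nanmean(vals)) if len(vals) else float("nan")
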