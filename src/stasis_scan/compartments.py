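"""Proteome compartmentalization: secreted (SP) vs. cytoplasmic (CP).

A protein is assigned to the secreted proteome iff its topology contains an
N-terminal signal peptide. Topologies come either from a Phobius "long"
output file (parsed, never recomputed) or, for synthetic data, from a
deterministic heuristic that recognises the classical tripartite signal
architecture (charged n-region, hydrophobic h-region, c-region with an
A-x-A cleavage site).
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass

import pandas as pd

from .records import ProteinRecord, Segment

__all__ = [
    "PhobiusParseError",
    "parse_phobius_long",
    "predict_signal_heuristic",
    "benchmark_accuracy",
    "topology_segment_lengths",
    "TopologyLengths",
    "split_proteome",
    "write_topology_tsv",
    "read_topology_tsv",
    "KYTE_DOOLITTLE",
]

# Kyte-Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# heuristic predictor constants (documented; chosen so the synthetic
# generator and the predictor agree by construction)
SCAN_WINDOW = 45  # residues of the N-terminus scanned
NREGION_SPAN = 5  # a K/R must occur within the first 5 residues
HCORE_LEN = 8  # minimal hydrophobic core length
HCORE_MEAN_KD = 1.6  # minimal mean hydropathy over the core window
CLEAVAGE_SEARCH = 6  # residues after the h-region searched for A-x-A


class PhobiusParseError(ValueError):
    """Malformed or truncated Phobius long-format input."""


_FT_RE = re.compile(
    r"^FT\s+(?P<key>SIGNAL|TRANSMEM|DOMAIN|REGION|TOPO_DOM)\s+"
    r"(?P<start>\d+)\s+(?P<end>\d+)\s*(?P<desc>.*)$"
)


def parse_phobius_long(stream) -> list[ProteinRecord]:
    """Parse a Phobius ``-long`` output stream into protein records.

    Recognised feature rows: ``SIGNAL`` (signal peptide), ``TRANSMEM``
    (transmembrane helix) and ``DOMAIN``/``TOPO_DOM`` rows whose description
    is ``CYTOPLASMIC.`` or ``NON CYTOPLASMIC.``. Sub-features of the signal
    peptide (N/H/C-REGION rows) are skipped, as they lie inside the SIGNAL
    span. Entries are terminated by ``//``.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    records: list[ProteinRecord] = []
    current_id: str | None = None
    segments: list[Segment] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip():
            continue
        if line.startswith("ID"):
            parts = line.split()
            if len(parts) < 2:
                raise PhobiusParseError(f"line {lineno}: ID row without identifier")
            current_id = parts[1]
            segments = []
        elif line.startswith("//"):
            if current_id is None:
                raise PhobiusParseError(f"line {lineno}: terminator before ID row")
            records.append(ProteinRecord(protein_id=current_id, topology=segments))
            current_id, segments = None, []
        elif line.startswith("FT"):
            if current_id is None:
                raise PhobiusParseError(f"line {lineno}: FT row before ID row")
            m = _FT_RE.match(line)
            if m is None:
                raise PhobiusParseError(f"line {lineno}: malformed FT row: {line!r}")
            key, desc = m["key"], m["desc"].strip().rstrip(".")
            start, end = int(m["start"]), int(m["end"])
            if key == "SIGNAL":
                segments.append(Segment("signal", start, end))
            elif key == "TRANSMEM":
                segments.append(Segment("transmembrane", start, end))
            elif key in ("DOMAIN", "TOPO_DOM"):
                if desc.upper() == "NON CYTOPLASMIC":
                    segments.append(Segment("non_cytoplasmic", start, end))
                elif desc.upper() == "CYTOPLASMIC":
                    segments.append(Segment("cytoplasmic", start, end))
                # other domain annotations (e.g. N-REGION) are not topology
        # other rows (blank separators, comments) are ignored
    if current_id is not None:
        raise PhobiusParseError(
            f"truncated file: entry {current_id!r} lacks '//' terminator"
        )
    return records


def predict_signal_heuristic(sequence: str) -> list[Segment]:
    """Stand-in signal-peptide predictor for synthetic proteomes.

    Scans the first 45 residues for (i) a positive charge (K/R) within the
    first 5 residues, (ii) a hydrophobic core: an 8-residue window of mean
    Kyte-Doolittle hydropathy >= 1.6, extended while following residues stay
    hydrophobic, and (iii) an A-x-A cleavage site whose first alanine lies
    within 6 residues after the core. On success the topology is a signal
    segment ending at the cleavage site with the remainder non-cytoplasmic;
    otherwise the whole protein is called cytoplasmic.

    This is a test double for Phobius on simulator output, not a general
    predictor; real analyses should supply Phobius output instead.
    """
    seq = sequence.upper()
    n = len(seq)
    if n < 30:
        raise ValueError(f"sequence too short for topology scan ({n} < 30 aa)")
    topology_cp = [Segment("cytoplasmic", 1, n)]
    if not any(c in "KR" for c in seq[:NREGION_SPAN]):
        return topology_cp
    kd = [KYTE_DOOLITTLE.get(c, 0.0) for c in seq]
    limit = min(n, SCAN_WINDOW)
    core_start = None
    for s in range(0, limit - HCORE_LEN + 1):
        if sum(kd[s : s + HCORE_LEN]) / HCORE_LEN >= HCORE_MEAN_KD:
            core_start = s
            break
    if core_start is None:
        return topology_cp
    core_end = core_start + HCORE_LEN - 1  # 0-based inclusive
    while core_end + 1 < limit and kd[core_end + 1] >= HCORE_MEAN_KD:
        core_end += 1
    for j in range(core_end + 1, min(core_end + 1 + CLEAVAGE_SEARCH, n - 2)):
        if seq[j] == "A" and seq[j + 2] == "A":
            cleave = j + 2  # 0-based index of the last signal residue
            segs = [Segment("signal", 1, cleave + 1)]
            if cleave + 1 < n:
                segs.append(Segment("non_cytoplasmic", cleave + 2, n))
            return segs
    return topology_cp


def benchmark_accuracy(
    predicted: list[str], truth: list[str]
) -> tuple[float, dict[str, float]]:
    """Prediction accuracy: 100 x correct / total, plus per-class accuracies.

    Per-class accuracy is computed over the proteins whose *true* label is
    that class (e.g. the fraction of true-SP proteins called SP).
    """
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth label lists differ in length")
    if not truth:
        raise ValueError("cannot compute accuracy of an empty set")
    correct = sum(p == t for p, t in zip(predicted, truth))
    overall = 100.0 * correct / len(truth)
    per_class: dict[str, float] = {}
    for cls in sorted(set(truth)):
        idx = [i for i, t in enumerate(truth) if t == cls]
        per_class[cls] = 100.0 * sum(predicted[i] == cls for i in idx) / len(idx)
    return overall, per_class


@dataclass(frozen=True)
class TopologyLengths:
    """Concatenated per-class residue counts for one protein."""

    cytoplasmic: int
    non_cytoplasmic: int
    transmembrane: int


def topology_segment_lengths(record: ProteinRecord) -> TopologyLengths:
    """Total residues per topology class (signal segments excluded).

    The three reported classes mirror the subcellular localisation fragment
    analysis: cytoplasmic, non-cytoplasmic and transmembrane spans are each
    summed over the protein; the signal peptide is not one of them.
    """
    totals = {"cytoplasmic": 0, "non_cytoplasmic": 0, "transmembrane": 0}
    for seg in record.topology:  # records validate overlap on construction
        if seg.kind in totals:
            totals[seg.kind] += seg.length
    return TopologyLengths(**totals)


def split_proteome(
    records: list[ProteinRecord],
) -> tuple[list[ProteinRecord], list[ProteinRecord], tuple[float, float]]:
    """Partition a proteome into (SP, CP) with the (SP, CP) proportions.

    The partition is exhaustive and disjoint; proportions sum to 1 for a
    non-empty proteome.
    """
    sp = [r for r in records if r.compartment == "SP"]
    cp = [r for r in records if r.compartment == "CP"]
    n = len(records)
    props = (len(sp) / n, len(cp) / n) if n else (0.0, 0.0)
    return sp, cp, props


def write_topology_tsv(records: list[ProteinRecord], path) -> None:
    """Write one row per topology segment (protein_id, kind, start, end)."""
    rows = [
        {"protein_id": r.protein_id, "kind": s.kind, "start": s.start, "end": s.end}
        for r in records
        for s in r.topology
    ]
    for r in records:
        if not r.topology:
            rows.append({"protein_id": r.protein_id, "kind": ".", "start": 0, "end": 0})
    pd.DataFrame(rows, columns=["protein_id", "kind", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def read_topology_tsv(path) -> list[ProteinRecord]:
    df = pd.read_csv(path, sep="\t")
    records = []
    for pid, grp in df.groupby("protein_id", sort=False):
        segs = [
            Segment(row.kind, int(row.start), int(row.end))
            for row in grp.itertuples()
            if row.kind != "."
        ]
        records.append(ProteinRecord(protein_id=str(pid), topology=segs))
    return records
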