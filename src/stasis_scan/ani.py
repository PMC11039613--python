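"""Fragment-based average nucleotide identity and species clustering.

Genomes are cut into consecutive 1200-bp fragments; each fragment is
locally aligned against the other genome, hits are accepted under the
Goris-style criteria (identity >= 30% over >= 70% of the fragment length,
no internal gap longer than 150 nt) and must map reciprocally. ANI is the
mean percent identity over accepted fragments from both directions, and
the conserved-DNA fraction is the share of fragmented genome length that
participates in accepted hits. Species clusters are the connected
components of the graph whose edges pass ANI >= 95% with conserved DNA
>= 0.70; clusters with >= 9 members are eligible for the intraspecific
analyses.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import edlib
import networkx as nx
import numpy as np
import pandas as pd

from .records import GenomeRecord, SpeciesCluster

__all__ = [
    "ANIParams",
    "PairwiseANI",
    "fragment_genome",
    "compute_ani",
    "ani_table",
    "cluster_species",
]

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class ANIParams:
    """Fragment-ANI acceptance cutoffs."""

    fragment_len: int = 1200
    min_tail: int = 100  # terminal fragment kept if at least this long
    min_identity: float = 0.30
    min_coverage: float = 0.70  # of the fragment length
    max_gap: int = 150  # longest tolerated internal indel run, nt
    min_reciprocal_overlap: float = 0.50


@dataclass
class PairwiseANI:
    """Symmetric fragment-ANI result for one genome pair."""

    mag_a: str
    mag_b: str
    ani: float  # percent; NaN when no fragment was retained
    conserved_dna: float  # fraction of fragment length in accepted hits
    n_fragments: int = 0


def fragment_genome(
    genome: GenomeRecord | dict[str, str], fragment_len: int = 1200, min_tail: int = 100
) -> list[tuple[str, int, str]]:
    """Cut each contig into consecutive windows of ``fragment_len`` bp.

    Returns (contig_id, 0-based offset, sequence) triples. The terminal
    remainder of a contig is kept when it is at least ``min_tail`` bp,
    otherwise dropped.
    """
    contigs = genome.contigs if isinstance(genome, GenomeRecord) else genome
    out = []
    for cid, seq in contigs.items():
        for off in range(0, len(seq), fragment_len):
            piece = seq[off : off + fragment_len]
            if len(piece) == fragment_len or len(piece) >= min_tail:
                out.append((cid, off, piece))
    return out


# per-column scores used to clip the glocal alignment path down to its
# best local segment (BLASTN-like: match +2, mismatch -3, gap open -5,
# gap extend -2); clipping emulates the local behaviour of the search
# tool the fragment method was designed around
_COL_SCORE = {"=": 2.0, "X": -3.0}
_GAP_OPEN_EXTRA = -3.0
_GAP_EXTEND = -2.0


@dataclass
class _Hit:
    """Clipped best local hit of one fragment on a target genome."""

    contig_id: str
    target_start: int  # 0-based on the contig
    target_end: int  # exclusive
    query_start: int  # 0-based on the fragment
    query_end: int
    identity: float
    max_gap: int

    @property
    def query_cols(self) -> int:
        return self.query_end - self.query_start


def _expand_cigar(cigar: str) -> np.ndarray:
    """Alignment columns as an array of op codes ('=', 'X', 'I', 'D')."""
    ops = []
    for num, op in _CIGAR_RE.findall(cigar):
        ops.append(np.full(int(num), op, dtype="U1"))
    return np.concatenate(ops) if ops else np.empty(0, dtype="U1")


def _clip_local(ops: np.ndarray) -> tuple[int, int] | None:
    """Max-scoring contiguous column range [i, j) of an alignment path."""
    if len(ops) == 0:
        return None
    scores = np.empty(len(ops))
    prev_gap = False
    for i, op in enumerate(ops):
        if op in "ID":
            scores[i] = _GAP_EXTEND + (0.0 if prev_gap else _GAP_OPEN_EXTRA)
            prev_gap = True
        else:
            scores[i] = _COL_SCORE[op]
            prev_gap = False
    best_sum = run_sum = 0.0
    best = None
    start = 0
    for i, s in enumerate(scores):
        if run_sum <= 0.0:
            run_sum, start = s, i
        else:
            run_sum += s
        if run_sum > best_sum:
            best_sum, best = run_sum, (start, i + 1)
    return best


def _best_hit(fragment: str, contigs: dict[str, str]) -> _Hit | None:
    """Best clipped local hit of a fragment against any contig of a genome."""
    best = None
    for cid in sorted(contigs):
        res = edlib.align(fragment, contigs[cid], mode="HW", task="distance")
        d = res["editDistance"]
        if d >= 0 and (best is None or d < best[1]):
            best = (cid, d)
    if best is None:
        return None
    cid = best[0]
    res = edlib.align(fragment, contigs[cid], mode="HW", task="path")
    ops = _expand_cigar(res["cigar"])
    clip = _clip_local(ops)
    if clip is None:
        return None
    i, j = clip
    q_start = int(np.count_nonzero(np.isin(ops[:i], ["=", "X", "I"])))
    q_cols = int(np.count_nonzero(np.isin(ops[i:j], ["=", "X", "I"])))
    t_off = int(np.count_nonzero(np.isin(ops[:i], ["=", "X", "D"])))
    t_cols = int(np.count_nonzero(np.isin(ops[i:j], ["=", "X", "D"])))
    seg = ops[i:j]
    matches = int(np.count_nonzero(seg == "="))
    max_gap = 0
    run = 0
    for op in seg:
        run = run + 1 if op in "ID" else 0
        max_gap = max(max_gap, run)
    t_start = res["locations"][0][0] + t_off
    return _Hit(
        contig_id=cid,
        target_start=t_start,
        target_end=t_start + t_cols,
        query_start=q_start,
        query_end=q_start + q_cols,
        identity=matches / len(seg) if len(seg) else 0.0,
        max_gap=max_gap,
    )


def _directional_hits(
    frags: list[tuple[str, int, str]],
    source: dict[str, str],
    target: dict[str, str],
    params: ANIParams,
) -> tuple[list[float], int]:
    """Accepted fragment identities (source -> target) and their total length."""
    identities: list[float] = []
    accepted_len = 0
    for cid, off, frag in frags:
        hit = _best_hit(frag, target)
        if hit is None:
            continue
        if hit.identity < params.min_identity:
            continue
        if hit.query_cols / len(frag) < params.min_coverage:
            continue
        if hit.max_gap > params.max_gap:
            continue
        # reciprocal check: the matched target region must map back onto
        # the originating fragment
        region = target[hit.contig_id][hit.target_start : hit.target_end]
        back = _best_hit(region, source)
        if back is None or back.contig_id != cid:
            continue
        bs = back.target_start
        be = back.target_end
        overlap = min(be, off + len(frag)) - max(bs, off)
        if overlap < params.min_reciprocal_overlap * len(frag):
            continue
        identities.append(hit.identity)
        accepted_len += len(frag)
    return identities, accepted_len


def compute_ani(
    genome_a: GenomeRecord | dict[str, str],
    genome_b: GenomeRecord | dict[str, str],
    params: ANIParams | None = None,
) -> PairwiseANI:
    """Reciprocal fragment-based ANI between two genomes."""
    params = params or ANIParams()
    contigs_a = genome_a.contigs if isinstance(genome_a, GenomeRecord) else genome_a
    contigs_b = genome_b.contigs if isinstance(genome_b, GenomeRecord) else genome_b
    name_a = genome_a.mag_id if isinstance(genome_a, GenomeRecord) else "A"
    name_b = genome_b.mag_id if isinstance(genome_b, GenomeRecord) else "B"
    if not contigs_a or not contigs_b:
        raise ValueError("both genomes must be non-empty")

    frags_a = fragment_genome(contigs_a, params.fragment_len, params.min_tail)
    frags_b = fragment_genome(contigs_b, params.fragment_len, params.min_tail)
    ids_ab, len_ab = _directional_hits(frags_a, contigs_a, contigs_b, params)
    ids_ba, len_ba = _directional_hits(frags_b, contigs_b, contigs_a, params)
    identities = ids_ab + ids_ba
    total_frag_len = sum(len(f[2]) for f in frags_a) + sum(len(f[2]) for f in frags_b)
    conserved = (len_ab + len_ba) / total_frag_len if total_frag_len else 0.0
    ani = 100.0 * float(np.mean(identities)) if identities else float("nan")
    return PairwiseANI(
        mag_a=name_a,
        mag_b=name_b,
        ani=ani,
        conserved_dna=conserved,
        n_fragments=len(identities),
    )


def ani_table(
    genomes: list[GenomeRecord],
    params: ANIParams | None = None,
    groups: dict[str, str] | None = None,
) -> pd.DataFrame:
    """All-vs-all pairwise ANI as a long-format table.

    When ``groups`` maps mag_id -> taxonomic pre-group, only within-group
    pairs are compared (the survey computes ANI within taxonomically
    homogeneous groups); otherwise all pairs are.
    """
    rows = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1 :]:
            if groups is not None and groups.get(ga.mag_id) != groups.get(gb.mag_id):
                continue
            pair = compute_ani(ga, gb, params)
            rows.append(
                {
                    "mag_a": pair.mag_a,
                    "mag_b": pair.mag_b,
                    "ani": pair.ani,
                    "conserved_dna": pair.conserved_dna,
                    "n_fragments": pair.n_fragments,
                }
            )
    return pd.DataFrame(
        rows, columns=["mag_a", "mag_b", "ani", "conserved_dna", "n_fragments"]
    )


def cluster_species(
    pairs: pd.DataFrame,
    ani_threshold: float = 95.0,
    conserved_threshold: float = 0.70,
    min_members: int = 9,
    all_mags: list[str] | None = None,
) -> list[SpeciesCluster]:
    """Single-linkage species clusters from a pairwise ANI table.

    Clusters are connected components of the graph whose edges are pairs
    with ANI >= ``ani_threshold`` and conserved DNA >= ``conserved_threshold``.
    Components with at least ``min_members`` genomes are flagged eligible
    for intraspecific analyses.
    """
    g = nx.Graph()
    if all_mags:
        g.add_nodes_from(all_mags)
    g.add_nodes_from(pairs["mag_a"])
    g.add_nodes_from(pairs["mag_b"])
    ok = pairs[
        (pairs["ani"] >= ani_threshold)
        & (pairs["conserved_dna"] >= conserved_threshold)
    ]
    g.add_edges_from(zip(ok["mag_a"], ok["mag_b"]))

    lookup: dict[tuple[str, str], float] = {}
    for row in pairs.itertuples():
        lookup[(row.mag_a, row.mag_b)] = row.ani
        lookup[(row.mag_b, row.mag_a)] = row.ani

    clusters = []
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for k, comp in enumerate(components):
        members = sorted(comp)
        mat = pd.DataFrame(
            [
                [100.0 if a == b else lookup.get((a, b), float("nan")) for b in members]
                for a in members
            ],
            index=members,
            columns=members,
        )
        clusters.append(
            SpeciesCluster(
                cluster_id=f"cluster_{k:03d}",
                members=members,
                ani_matrix=mat,
                analysis_eligible=len(members) >= min_members,
            )
        )
    return clusters
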