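"""Per-compartment amino-acid identity within and between species clusters.

AAI between two proteomes is the mean percent identity over reciprocal
best-hit (RBH) protein pairs from BLOSUM62 local alignments, with hits
admitted at >= 30% identity over >= 70% of the shorter protein. Within a
species cluster, AAI is computed separately for the secreted (SP) and
cytoplasmic (CP) subsets of every unordered member pair; the per-species
SP/CP similarity index is the ratio of the two pair-level medians. An
index above 1 marks a species whose secreted proteome is the more
conserved one — the signature of adaptive stasis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats as sps

from . import mag_qc
from .records import SpeciesCluster
from .stats import compare_groups  # noqa: F401  (re-exported pipeline surface)

__all__ = [
    "AAIParams",
    "PairwiseAAI",
    "compute_aai",
    "species_aai_profile",
    "SPCPIndex",
    "spcp_index",
    "correlate_index_density",
    "compare_groups",
    "intragenus_aai",
    "GENUS_AAI_THRESHOLD",
]

GENUS_AAI_THRESHOLD = 65.0  # whole-proteome AAI defining genus-level boundaries


@dataclass(frozen=True)
class AAIParams:
    """RBH admission cutoffs for proteome comparisons."""

    min_identity: float = 0.30
    min_coverage: float = 0.70  # aligned fraction of the shorter protein


@dataclass
class PairwiseAAI:
    """AAI between two (possibly compartment-filtered) proteomes."""

    mag_a: str
    mag_b: str
    compartment: str  # "SP" | "CP" | "whole"
    aai: float  # percent; NaN when no RBH survives the cutoffs
    n_rbh: int
    fraction_compared: float  # RBHs / size of the smaller proteome


def _aligner() -> Align.PairwiseAligner:
    al = Align.PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "local"
    return al


def _alignment_identity(al: Align.PairwiseAligner, sa: str, sb: str) -> tuple[float, float]:
    """(identity, coverage-of-shorter) for the best local alignment."""
    try:
        aln = al.align(sa, sb)[0]
    except IndexError:  # no positive-scoring alignment
        return 0.0, 0.0
    matches = 0
    columns = 0
    aligned_a = 0
    aligned_b = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        seg_a = sa[a0:a1]
        seg_b = sb[b0:b1]
        matches += sum(x == y for x, y in zip(seg_a, seg_b))
        columns += a1 - a0
        aligned_a += a1 - a0
        aligned_b += b1 - b0
    # count gap columns between aligned blocks
    blocks_a, blocks_b = aln.aligned
    for i in range(1, len(blocks_a)):
        columns += (blocks_a[i][0] - blocks_a[i - 1][1]) + (
            blocks_b[i][0] - blocks_b[i - 1][1]
        )
    if columns == 0:
        return 0.0, 0.0
    shorter = min(len(sa), len(sb))
    coverage = min(aligned_a, aligned_b) / shorter
    return matches / columns, coverage


def compute_aai(
    proteome_a: dict[str, str],
    proteome_b: dict[str, str],
    params: AAIParams | None = None,
    mag_a: str = "A",
    mag_b: str = "B",
    compartment: str = "whole",
) -> PairwiseAAI:
    """Reciprocal best-hit AAI between two proteomes (id -> sequence maps).

    Best hits are chosen by local BLOSUM62 alignment score in both
    directions; a pair is an RBH when each protein is the other's best hit.
    RBHs are admitted at identity >= 30% over >= 70% of the shorter
    protein; AAI is the mean percent identity over admitted RBHs.
    """
    params = params or AAIParams()
    if not proteome_a or not proteome_b:
        raise ValueError("both proteomes must be non-empty")
    al = _aligner()
    ids_a = sorted(proteome_a)
    ids_b = sorted(proteome_b)
    scores = np.full((len(ids_a), len(ids_b)), -np.inf)
    for i, pa in enumerate(ids_a):
        sa = proteome_a[pa]
        for j, pb in enumerate(ids_b):
            scores[i, j] = al.score(sa, proteome_b[pb])
    best_ab = scores.argmax(axis=1)
    best_ba = scores.argmax(axis=0)
    identities = []
    for i, j in enumerate(best_ab):
        if best_ba[j] != i or not np.isfinite(scores[i, j]):
            continue
        identity, coverage = _alignment_identity(
            al, proteome_a[ids_a[i]], proteome_b[ids_b[j]]
        )
        if identity >= params.min_identity and coverage >= params.min_coverage:
            identities.append(identity)
    # fraction of proteins participating in RBHs, relative to the larger
    # proteome: genome-specific proteins lower it, mirroring the pangenome
    # framing of "percentage of proteins compared"
    return PairwiseAAI(
        mag_a=mag_a,
        mag_b=mag_b,
        compartment=compartment,
        aai=100.0 * float(np.mean(identities)) if identities else float("nan"),
        n_rbh=len(identities),
        fraction_compared=len(identities) / max(len(ids_a), len(ids_b)),
    )


def species_aai_profile(
    cluster: SpeciesCluster,
    proteomes: dict[str, dict[str, str]],
    compartments: dict[str, str],
    params: AAIParams | None = None,
    include_whole: bool = False,
) -> pd.DataFrame:
    """Pairwise SP- and CP-AAI over all unordered member pairs of a cluster.

    ``proteomes`` maps mag_id -> {protein_id: sequence}; ``compartments``
    maps protein_id -> "SP"/"CP". Members without proteome data are
    excluded with a warning. For an n-member cluster each compartment
    contributes C(n, 2) pair values.
    """
    members = []
    for m in cluster.members:
        if m in proteomes and proteomes[m]:
            members.append(m)
        else:
            warnings.warn(f"{m}: no proteome data; excluded from AAI", stacklevel=2)
    rows = []
    comps = ["SP", "CP"] + (["whole"] if include_whole else [])
    for a, b in combinations(members, 2):
        for comp in comps:
            if comp == "whole":
                sub_a, sub_b = proteomes[a], proteomes[b]
            else:
                sub_a = {p: s for p, s in proteomes[a].items() if compartments.get(p) == comp}
                sub_b = {p: s for p, s in proteomes[b].items() if compartments.get(p) == comp}
            if not sub_a or not sub_b:
                warnings.warn(
                    f"pair ({a}, {b}): empty {comp} compartment; skipped", stacklevel=2
                )
                continue
            pair = compute_aai(sub_a, sub_b, params, a, b, comp)
            rows.append(
                {
                    "mag_a": a,
                    "mag_b": b,
                    "compartment": comp,
                    "aai": pair.aai,
                    "n_rbh": pair.n_rbh,
                    "fraction_compared": pair.fraction_compared,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["mag_a", "mag_b", "compartment", "aai", "n_rbh", "fraction_compared"],
    )


@dataclass
class SPCPIndex:
    """Per-species summary: compartment medians, index, ANI normalizations."""

    species_id: str
    median_sp_aai: float
    median_cp_aai: float
    index: float  # median SP-AAI / median CP-AAI
    coding_density: float
    est_size: float
    size_class: str
    sp_over_ani: float
    cp_over_ani: float


def spcp_index(
    profile: pd.DataFrame,
    coding_density: float,
    est_size: float,
    mean_ani: float,
    species_id: str = "species",
    normalize: str = "identity",
) -> SPCPIndex:
    """SP/CP similarity index and ANI-normalized compartment similarities.

    The index divides the median SP-AAI by the median CP-AAI over the
    cluster's pairs. ANI normalization defaults to the identity ratio
    (AAI / ANI, matching an "SP/ANI" axis); ``normalize="distance"``
    instead uses the dissimilarity ratio (100 - AAI) / (100 - ANI).
    """
    sp = profile.loc[profile["compartment"] == "SP", "aai"].dropna()
    cp = profile.loc[profile["compartment"] == "CP", "aai"].dropna()
    if sp.empty or cp.empty:
        raise ValueError("both compartments need at least one AAI value")
    med_sp = float(sp.median())
    med_cp = float(cp.median())
    if normalize == "identity":
        sp_norm = med_sp / mean_ani
        cp_norm = med_cp / mean_ani
    elif normalize == "distance":
        sp_norm = (100.0 - med_sp) / (100.0 - mean_ani)
        cp_norm = (100.0 - med_cp) / (100.0 - mean_ani)
    else:
        raise ValueError(f"unknown normalization {normalize!r}")
    return SPCPIndex(
        species_id=species_id,
        median_sp_aai=med_sp,
        median_cp_aai=med_cp,
        index=med_sp / med_cp,
        coding_density=coding_density,
        est_size=est_size,
        size_class=mag_qc.classify_genome_size(est_size),
        sp_over_ani=sp_norm,
        cp_over_ani=cp_norm,
    )


def correlate_index_density(indices: list[SPCPIndex]) -> tuple[float, float, float]:
    """Spearman correlation of SP/CP index against coding density.

    Returns (rho, S, p) where S = sum of squared rank differences (the
    statistic R prints for its Spearman test; with ties it is derived from
    average ranks). The p-value is the two-sided scipy asymptotic value.
    """
    if len(indices) < 4:
        raise ValueError("need at least 4 species for a rank correlation")
    x = np.array([i.index for i in indices], dtype=float)
    y = np.array([i.coding_density for i in indices], dtype=float)
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        raise ValueError("constant vector: correlation undefined")
    rho, p = sps.spearmanr(x, y)
    d = sps.rankdata(x) - sps.rankdata(y)
    s = float(np.sum(d * d))
    return float(rho), s, float(p)


def intragenus_aai(
    genus_clusters: dict[str, list[SpeciesCluster]],
    proteomes: dict[str, dict[str, str]],
    compartments: dict[str, str],
    params: AAIParams | None = None,
    max_pairs_per_species_pair: int | None = None,
) -> pd.DataFrame:
    """Between-species AAI distributions (SP/CP/whole) within each genus.

    For every genus with >= 2 species clusters, cross-cluster member pairs
    are compared per compartment and as whole proteomes. The genus claim is
    validated against the 65% whole-proteome AAI genus boundary: the genus
    median whole-AAI is reported with a flag. Singleton genera are skipped
    with a note.
    """
    rows = []
    for genus, clusters in sorted(genus_clusters.items()):
        if len(clusters) < 2:
            warnings.warn(f"genus {genus!r} has a single species; skipped", stacklevel=2)
            continue
        for ca, cb in combinations(clusters, 2):
            pairs = [
                (a, b)
                for a in ca.members
                for b in cb.members
                if a in proteomes and b in proteomes
            ]
            if max_pairs_per_species_pair is not None:
                pairs = pairs[:max_pairs_per_species_pair]
            for a, b in pairs:
                for comp in ("SP", "CP", "whole"):
                    if comp == "whole":
                        sub_a, sub_b = proteomes[a], proteomes[b]
                    else:
                        sub_a = {
                            p: s for p, s in proteomes[a].items()
                            if compartments.get(p) == comp
                        }
                        sub_b = {
                            p: s for p, s in proteomes[b].items()
                            if compartments.get(p) == comp
                        }
                    if not sub_a or not sub_b:
                        continue
                    pair = compute_aai(sub_a, sub_b, params, a, b, comp)
                    rows.append(
                        {
                            "genus": genus,
                            "species_a": ca.cluster_id,
                            "species_b": cb.cluster_id,
                            "mag_a": a,
                            "mag_b": b,
                            "compartment": comp,
                            "aai": pair.aai,
                        }
                    )
    df = pd.DataFrame(
        rows,
        columns=["genus", "species_a", "species_b", "mag_a", "mag_b", "compartment", "aai"],
    )
    if not df.empty:
        whole = df[df["compartment"] == "whole"].groupby("genus")["aai"].median()
        df["genus_whole_median_aai"] = df["genus"].map(whole)
        df["genus_boundary_ok"] = df["genus_whole_median_aai"] >= GENUS_AAI_THRESHOLD
    return df
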