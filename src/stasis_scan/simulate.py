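"""Forward simulation of bacterial species clusters with known truth.

The generator builds, per species, an ancestral genome of protein-coding
genes separated by intergenic spacers, evolves a population of members by
uniform nucleotide substitution (with a compartment-specific rate for
signal-peptide-bearing genes) plus homologous recombination imports from a
diverged donor, and finally degrades each member into a MAG-like assembly
(fragmented contigs, incomplete, optionally contaminated with contigs from
another species). Every random draw derives from one top-level seed through
fixed per-genome streams, so outputs are reproducible byte-for-byte and
member counts can change without reshuffling earlier members.

Substitutions act uniformly over nucleotide sites (no codon model): the
downstream statistics are identity-based, not dN/dS-based. Start and stop
codons, and the signal-peptide-encoding region of SP genes, are excluded
from mutable sites so ORFs and compartment truth labels stay intact; a
substitution that would create an internal stop codon is redirected to the
next non-stop base in the stream order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .compartments import predict_signal_heuristic
from .config import ConfigurationError, SimulationConfig
from .records import GeneModel, GenomeRecord, ProteinRecord, Segment

__all__ = [
    "Ancestor",
    "SimulatedGenome",
    "SyntheticMAG",
    "SyntheticDataset",
    "generate_ancestor",
    "evolve_population",
    "degrade_to_mags",
    "simulate_dataset",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INDEX = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INDEX[_b] = _i
_STOPS = {"TAA", "TAG", "TGA"}

_AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
# standard bacterial codon table, stop codons excluded
_CODONS_BY_AA: dict[str, list[str]] = {}
for _b1 in "TCAG":
    for _b2 in "TCAG":
        for _b3 in "TCAG":
            _codon = _b1 + _b2 + _b3
            if _codon in _STOPS:
                continue
            _aa = str(Seq(_codon).translate())
            _CODONS_BY_AA.setdefault(_aa, []).append(_codon)

_HYDROPHOBIC = "LIVFM"  # h-region residues, all KD >= 1.9
_POLAR = "STNQG"  # polar spacer residues, KD < 1.6


def _rng_for(seed: int, *key: int) -> np.random.Generator:
    """Independent, order-stable stream for one (species, member) slot."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=key))


def _codon_weights(gc_target: float) -> dict[str, np.ndarray]:
    """Synonymous-codon weights from an i.i.d. base model at the GC target."""
    p = {b: (gc_target / 2 if b in "GC" else (1 - gc_target) / 2) for b in "ACGT"}
    out = {}
    for aa, codons in _CODONS_BY_AA.items():
        w = np.array([p[c[0]] * p[c[1]] * p[c[2]] for c in codons])
        out[aa] = w / w.sum()
    return out


def _sample_signal_peptide(rng: np.random.Generator) -> str:
    """One signal peptide matching the motif grammar the predictor scans for.

    Layout: M, n-region (a K/R within the first 5 residues), h-region of
    8-11 hydrophobic residues, a 1-2 residue polar spacer, and an A-x-A
    cleavage site. Lengths are constrained so the heuristic predictor's
    cleavage-site search window always reaches the motif.
    """
    n_extra = int(rng.integers(0, 3))
    n_region = str(rng.choice(list("KR"))) + "".join(
        rng.choice(list(_POLAR), size=n_extra)
    )
    h_len = int(rng.integers(8, 12))
    h_region = "".join(rng.choice(list(_HYDROPHOBIC), size=h_len))
    spacer = "".join(rng.choice(list(_POLAR), size=int(rng.integers(1, 3))))
    cleavage = "A" + str(rng.choice(list(_POLAR))) + "A"
    return "M" + n_region + h_region + spacer + cleavage


def _sample_protein(rng: np.random.Generator, length: int, secreted: bool) -> tuple[str, int]:
    """Return (sequence, signal_length_aa); signal_length is 0 for CP."""
    if secreted:
        signal = _sample_signal_peptide(rng)
        mature = "".join(rng.choice(list(_AA_ALPHABET), size=length - len(signal)))
        return signal + mature, len(signal)
    for _ in range(200):
        seq = "M" + "".join(rng.choice(list(_AA_ALPHABET), size=length - 1))
        if predict_signal_heuristic(seq)[0].kind != "signal":
            return seq, 0
    raise RuntimeError("could not sample a motif-free cytoplasmic protein")


@dataclass
class Ancestor:
    """Ancestral genome of one species, with per-gene truth labels."""

    species: int
    class_label: str
    sequence: np.ndarray  # uint8 array of ASCII bases
    genes: list[GeneModel]
    signal_nt: dict[str, int]  # gene_id -> signal-encoding length (nt)
    mutable: np.ndarray = field(repr=False)  # bool mask over sites
    gene_of_pos: np.ndarray = field(repr=False)  # gene index per site, -1 intergenic
    coding_density: float = 0.0

    @property
    def seq_str(self) -> str:
        return self.sequence.tobytes().decode()

    def gene_truth(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": [g.gene_id for g in self.genes],
                "species": self.species,
                "compartment": [g.compartment for g in self.genes],
                "ko": [g.ko for g in self.genes],
            }
        )


def _assign_kos(
    rng: np.random.Generator, gene_ids: list[str], pool: list[str], rate: float
) -> dict[str, str]:
    """KO labels with a planted functional-redundancy ratio.

    The number of distinct labels is round((1 - rate) * n), so the
    redundancy ratio 1 - unique/total recovers ``rate`` exactly up to
    integer rounding.
    """
    n = len(gene_ids)
    if n == 0:
        return {}
    n_unique = max(1, round((1.0 - rate) * n))
    labels = list(rng.choice(pool, size=n_unique, replace=False))
    order = list(rng.permutation(n))
    assignment: dict[str, str] = {}
    for rank, idx in enumerate(order):
        if rank < n_unique:
            assignment[gene_ids[idx]] = labels[rank]
        else:
            assignment[gene_ids[idx]] = str(rng.choice(labels))
    return assignment


def generate_ancestor(config: SimulationConfig, species: int = 0) -> Ancestor:
    """Build the ancestral genome of one species.

    Genes are laid head-to-tail on the forward strand, separated by
    intergenic spacers sized so the realized coding density matches the
    target. Signal-peptide-truth genes begin with the deterministic motif
    grammar; KO labels are planted to a known redundancy ratio per
    compartment (SP and CP draw from disjoint label sets).
    """
    rng = _rng_for(config.seed, species, 0)
    weights = _codon_weights(config.gc_target)
    n = config.n_genes

    lengths = np.maximum(
        30, np.rint(rng.normal(config.mean_gene_len, 0.2 * config.mean_gene_len, n))
    ).astype(int)
    n_sp = round(config.sp_fraction * n)
    sp_idx = set(rng.choice(n, size=n_sp, replace=False).tolist())

    proteins: list[str] = []
    signal_aa: list[int] = []
    for i in range(n):
        seq, sig = _sample_protein(rng, int(lengths[i]), i in sp_idx)
        proteins.append(seq)
        signal_aa.append(sig)

    stop_codons = ["TAA", "TAG", "TGA"]
    stop_w = np.array([0.5, 0.25, 0.25])
    gene_nt: list[str] = []
    for seq in proteins:
        codons = [
            _CODONS_BY_AA[aa][rng.choice(len(_CODONS_BY_AA[aa]), p=weights[aa])]
            for aa in seq
        ]
        codons.append(stop_codons[rng.choice(3, p=stop_w)])
        gene_nt.append("".join(codons))

    coding_total = sum(len(g) for g in gene_nt)
    d = config.coding_density_target
    spacer_total = int(round(coding_total * (1.0 - d) / d))
    n_spacers = n + 1
    spacer_lens = rng.multinomial(spacer_total, np.full(n_spacers, 1.0 / n_spacers))

    gc = config.gc_target
    base_p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])

    parts: list[np.ndarray] = []
    genes: list[GeneModel] = []
    signal_nt: dict[str, int] = {}
    pos = 0
    for i in range(n + 1):
        sp_len = int(spacer_lens[i])
        parts.append(_BASES[rng.choice(4, size=sp_len, p=base_p)])
        pos += sp_len
        if i < n:
            gid = f"S{species}G{i:04d}"
            gseq = np.frombuffer(gene_nt[i].encode(), dtype=np.uint8)
            parts.append(gseq)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    contig_id="genome",
                    start=pos + 1,
                    end=pos + len(gseq),
                    compartment="SP" if i in sp_idx else "CP",
                )
            )
            signal_nt[gid] = 3 * signal_aa[i]
            pos += len(gseq)
    sequence = np.concatenate(parts)
    realized_density = coding_total / len(sequence)
    if abs(realized_density - d) > 0.02:
        raise ConfigurationError(
            f"realized coding density {realized_density:.3f} misses target {d}"
        )

    pool = [f"K{j:05d}" for j in range(1, config.ko_pool_size + 1)]
    pool_perm = [pool[j] for j in rng.permutation(len(pool))]
    sp_ids = [g.gene_id for g in genes if g.compartment == "SP"]
    cp_ids = [g.gene_id for g in genes if g.compartment == "CP"]
    half = len(sp_ids)
    ko_map = _assign_kos(rng, sp_ids, pool_perm[:half], config.duplication_rate)
    ko_map.update(
        _assign_kos(rng, cp_ids, pool_perm[half:], config.duplication_rate)
    )
    for g in genes:
        g.ko = ko_map.get(g.gene_id)

    mutable = np.ones(len(sequence), dtype=bool)
    gene_of_pos = np.full(len(sequence), -1, dtype=np.int32)
    for gi, g in enumerate(genes):
        s0 = g.start - 1
        gene_of_pos[s0 : g.end] = gi
        mutable[s0 : s0 + 3] = False  # start codon
        mutable[g.end - 3 : g.end] = False  # stop codon
        sig = signal_nt[g.gene_id]
        if sig:
            mutable[s0 : s0 + sig] = False  # signal peptide stays intact

    return Ancestor(
        species=species,
        class_label=f"c__SimClass{species}",
        sequence=sequence,
        genes=genes,
        signal_nt=signal_nt,
        mutable=mutable,
        gene_of_pos=gene_of_pos,
        coding_density=realized_density,
    )


@dataclass
class SimulatedGenome:
    """One evolved member of a species population (pre-degradation)."""

    mag_id: str
    species: int
    sequence: np.ndarray
    genes: list[GeneModel]
    signal_nt: dict[str, int]
    imports: list[tuple[int, int, float]]  # (1-based position, length, divergence)
    subs_sp: int = 0  # realized substitutions in SP gene space vs. ancestor
    subs_cp: int = 0

    @property
    def seq_str(self) -> str:
        return self.sequence.tobytes().decode()

    def proteins(self) -> list[ProteinRecord]:
        """Translate gene models; SP-truth proteins carry a signal segment."""
        out = []
        seq = self.seq_str
        for g in self.genes:
            aa = str(Seq(seq[g.start - 1 : g.end]).translate()).rstrip("*")
            sig = self.signal_nt[g.gene_id] // 3
            topo = [Segment("signal", 1, sig)] if sig else []
            out.append(ProteinRecord(protein_id=g.gene_id, sequence=aa, topology=topo))
        return out


def _apply_substitutions(
    seq: np.ndarray,
    positions: np.ndarray,
    rng: np.random.Generator,
    gene_of_pos: np.ndarray,
    genes: list[GeneModel],
) -> None:
    """Substitute each position to a different base, avoiding new stop codons."""
    if len(positions) == 0:
        return
    old_idx = _BASE_INDEX[seq[positions]]
    shifts = rng.integers(1, 4, size=len(positions))
    seq[positions] = _BASES[(old_idx + shifts) % 4]
    # repair any internal stop codons created inside genes: advance to the
    # next non-stop alternative base (at most two of three can be stops)
    for p, oi, sh in zip(positions, old_idx, shifts):
        gi = gene_of_pos[p]
        if gi < 0:
            continue
        g = genes[gi]
        c0 = p - (p - (g.start - 1)) % 3
        for extra in range(3):
            if seq[c0 : c0 + 3].tobytes().decode() not in _STOPS:
                break
            seq[p] = _BASES[(oi + (sh - 1 + extra + 1) % 3 + 1) % 4]


def evolve_population(
    ancestor: Ancestor, config: SimulationConfig
) -> list[SimulatedGenome]:
    """Evolve a population of members from one ancestor.

    Each member independently receives recombination imports (segments
    replaced by donor sequence diverged at ``donor_divergence``) and point
    substitutions at per-site rate ``mu_cp`` (CP genes and intergenic) or
    ``mu_cp * sp_rate_multiplier`` (SP genes, outside the frozen
    signal-encoding region).
    """
    mu_sp = config.mu_cp * config.sp_rate_multiplier
    worst = max(config.mu_cp, mu_sp)
    if 2.0 * worst > 0.10:
        warnings.warn(
            "substitution rates imply expected within-species ANI < 90%; "
            "species clusters may fragment",
            stacklevel=2,
        )
    L = len(ancestor.sequence)
    # Immutable sites (start/stop codons, signal-peptide region) would
    # otherwise depress a gene's realized divergence below its nominal
    # rate, so the rate on the mutable sites of each gene is scaled up to
    # conserve the expected per-gene substitution count.
    rate = np.full(L, config.mu_cp)
    factor = np.ones(L)  # per-site compensation for frozen sites in a gene
    for g in ancestor.genes:
        base = mu_sp if g.compartment == "SP" else config.mu_cp
        span = slice(g.start - 1, g.end)
        n_mutable = int(np.count_nonzero(ancestor.mutable[span]))
        if n_mutable:
            factor[span] = g.length / n_mutable
            rate[span] = min(0.75, base * g.length / n_mutable)
    rate[~ancestor.mutable] = 0.0

    sp_mask = np.zeros(L, dtype=bool)
    cp_mask = np.zeros(L, dtype=bool)
    for g in ancestor.genes:
        (sp_mask if g.compartment == "SP" else cp_mask)[g.start - 1 : g.end] = True

    members = []
    for m in range(config.members_per_species):
        rng = _rng_for(config.seed, ancestor.species, m + 1)
        seq = ancestor.sequence.copy()
        imports: list[tuple[int, int, float]] = []
        for _ in range(config.recomb_events_per_genome):
            ilen = min(L, int(rng.geometric(1.0 / config.import_length_mean)))
            start = int(rng.integers(0, max(1, L - ilen + 1)))
            window = np.arange(start, start + ilen)
            window = window[ancestor.mutable[window]]
            p = np.minimum(0.75, config.donor_divergence * factor[window])
            hit = window[rng.random(len(window)) < p]
            _apply_substitutions(
                seq, hit, rng, ancestor.gene_of_pos, ancestor.genes
            )
            imports.append((start + 1, ilen, config.donor_divergence))
        hits = np.flatnonzero(rng.random(L) < rate)
        _apply_substitutions(seq, hits, rng, ancestor.gene_of_pos, ancestor.genes)

        diff = seq != ancestor.sequence
        members.append(
            SimulatedGenome(
                mag_id=f"S{ancestor.species}M{m:02d}",
                species=ancestor.species,
                sequence=seq,
                genes=[
                    GeneModel(
                        g.gene_id, g.contig_id, g.start, g.end, g.strand,
                        g.ko, g.compartment,
                    )
                    for g in ancestor.genes
                ],
                signal_nt=dict(ancestor.signal_nt),
                imports=imports,
                subs_sp=int(np.count_nonzero(diff & sp_mask)),
                subs_cp=int(np.count_nonzero(diff & cp_mask)),
            )
        )
    return members


@dataclass
class SyntheticMAG:
    """A degraded, MAG-like view of one simulated member."""

    record: GenomeRecord
    genes: list[GeneModel]  # contig-relative coordinates
    proteins: list[ProteinRecord]
    species: int
    planted_completeness: float
    planted_contamination: float
    realized_completeness: float
    contaminant_contigs: list[str]


def _species_contig_bounds(
    member: SimulatedGenome, config: SimulationConfig, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Contig spans (start0, end0-exclusive) for one species; cuts fall between genes.

    Cut positions are drawn once per species (gene coordinates are shared by
    all members), so homologous contigs tile the same coordinates across the
    population.
    """
    L = len(member.sequence)
    gaps = []
    prev_end = 0
    for g in member.genes:
        if g.start - 1 > prev_end:
            gaps.append((prev_end + g.start - 1) // 2)  # gap midpoint
        prev_end = g.end
    target = min(config.contig_len_mean, max(1, L // config.min_contigs))
    jitter = min(config.contig_len_jitter, max(1, target // 3))
    cuts: list[int] = []
    next_cut = target + int(rng.integers(-jitter, jitter + 1))
    for mid in gaps:
        if mid >= next_cut:
            cuts.append(mid)
            next_cut = mid + target + int(rng.integers(-jitter, jitter + 1))
    bounds = [0] + cuts + [L]
    return [
        (bounds[i], bounds[i + 1])
        for i in range(len(bounds) - 1)
        if bounds[i + 1] > bounds[i]
    ]


def degrade_to_mags(
    populations: list[list[SimulatedGenome]], config: SimulationConfig
) -> list[SyntheticMAG]:
    """Degrade evolved members into MAG-like assemblies.

    Each member genome is fragmented into contigs (cut points in intergenic
    spacers), contigs are dropped at random down to a planted completeness,
    and contamination is added as contigs copied from a member of the next
    species, tagged in the truth output. Planted completeness/contamination
    are recorded as the "estimated" values the downstream QC consumes.
    """
    n_species = len(populations)
    species_bounds = {
        s: _species_contig_bounds(pop[0], config, _rng_for(config.seed, s, 999))
        for s, pop in enumerate(populations)
    }
    frags = {
        m.mag_id: [
            (f"{m.mag_id}_c{i:03d}", b, e)
            for i, (b, e) in enumerate(species_bounds[m.species])
        ]
        for pop in populations
        for m in pop
    }
    mags: list[SyntheticMAG] = []
    for s, pop in enumerate(populations):
        for i, member in enumerate(pop):
            rng = _rng_for(config.seed, s, 2000 + i)
            lo, hi = config.completeness_range
            planted_comp = float(rng.uniform(lo, hi))
            lo, hi = config.contamination_range
            planted_cont = float(rng.uniform(lo, hi))

            spans = frags[member.mag_id]
            total = len(member.sequence)
            target_len = planted_comp / 100.0 * total
            if planted_comp >= 100.0:
                kept = list(spans)
            else:
                order = [spans[j] for j in rng.permutation(len(spans))]
                kept, acc = [], 0
                for span in order:
                    span_len = span[2] - span[1]
                    if kept and abs(acc + span_len - target_len) > abs(acc - target_len):
                        break
                    kept.append(span)
                    acc += span_len
                kept.sort(key=lambda t: t[1])
            kept_len = sum(e - b for _, b, e in kept)

            contigs: dict[str, str] = {}
            taxonomy: dict[str, list[str]] = {}
            genes: list[GeneModel] = []
            proteins: list[ProteinRecord] = []
            seq = member.seq_str
            member_prot = {p.protein_id: p for p in member.proteins()}
            for cid, b, e in kept:
                contigs[cid] = seq[b:e]
                labels = []
                for g in member.genes:
                    if g.start - 1 >= b and g.end <= e:
                        genes.append(
                            GeneModel(
                                g.gene_id, cid, g.start - b, g.end - b,
                                g.strand, g.ko, g.compartment,
                            )
                        )
                        labels.append(f"c__SimClass{s}")
                        proteins.append(member_prot[g.gene_id])
                taxonomy[cid] = labels

            contaminants: list[str] = []
            if planted_cont > 0 and n_species > 1:
                donor_species = (s + 1) % n_species
                donor = populations[donor_species][i % len(populations[donor_species])]
                donor_spans = frags[donor.mag_id]
                donor_seq = donor.seq_str
                donor_genes = donor.genes
                target_cont = planted_cont / 100.0 * kept_len
                acc = 0
                for j in rng.permutation(len(donor_spans)):
                    cid0, b, e = donor_spans[j]
                    span_len = e - b
                    if abs(acc + span_len - target_cont) > abs(acc - target_cont):
                        break  # adding this contig would overshoot the target
                    xid = f"{member.mag_id}_x{len(contaminants):03d}"
                    contigs[xid] = donor_seq[b:e]
                    labels = []
                    for g in donor_genes:
                        if g.start - 1 >= b and g.end <= e:
                            labels.append(f"c__SimClass{donor_species}")
                    taxonomy[xid] = labels
                    contaminants.append(xid)
                    acc += span_len
                    if acc >= target_cont:
                        break

            record = GenomeRecord(
                mag_id=member.mag_id,
                contigs=contigs,
                est_completeness=planted_comp,
                est_contamination=planted_cont,
                contig_taxonomy=taxonomy,
            )
            mags.append(
                SyntheticMAG(
                    record=record,
                    genes=genes,
                    proteins=proteins,
                    species=s,
                    planted_completeness=planted_comp,
                    planted_contamination=planted_cont,
                    realized_completeness=100.0 * kept_len / total,
                    contaminant_contigs=contaminants,
                )
            )
    return mags


@dataclass
class SyntheticDataset:
    """Everything one simulation run produces, truth included."""

    config: SimulationConfig
    ancestors: list[Ancestor]
    populations: list[list[SimulatedGenome]]
    mags: list[SyntheticMAG]

    def gene_truth(self) -> pd.DataFrame:
        return pd.concat([a.gene_truth() for a in self.ancestors], ignore_index=True)

    def genome_truth(self) -> pd.DataFrame:
        rows = []
        for mag in self.mags:
            member = next(
                m
                for m in self.populations[mag.species]
                if m.mag_id == mag.record.mag_id
            )
            rows.append(
                {
                    "mag_id": mag.record.mag_id,
                    "species": mag.species,
                    "planted_completeness": mag.planted_completeness,
                    "planted_contamination": mag.planted_contamination,
                    "realized_completeness": mag.realized_completeness,
                    "n_contaminant_contigs": len(mag.contaminant_contigs),
                    "subs_sp": member.subs_sp,
                    "subs_cp": member.subs_cp,
                }
            )
        return pd.DataFrame(rows)

    def import_truth(self) -> pd.DataFrame:
        rows = [
            {
                "mag_id": m.mag_id,
                "position": pos,
                "length": length,
                "donor_divergence": div,
            }
            for pop in self.populations
            for m in pop
            for pos, length, div in m.imports
        ]
        return pd.DataFrame(
            rows, columns=["mag_id", "position", "length", "donor_divergence"]
        )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Run the full generator: ancestors -> populations -> MAG degradation."""
    ancestors = [generate_ancestor(config, s) for s in range(config.n_species)]
    populations = [evolve_population(a, config) for a in ancestors]
    mags = degrade_to_mags(populations, config)
    return SyntheticDataset(
        config=config, ancestors=ancestors, populations=populations, mags=mags
    )
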