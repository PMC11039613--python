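"""Secreted vs. cytoplasmic proteome conservation within a species.

Partitions simulated proteomes into SP/CP with the signal-peptide
heuristic, computes per-compartment reciprocal-best-hit AAI over all member
pairs, and derives the SP/CP similarity index. With the secreted proteome
diverging twice as fast, the index falls below 1; a conserved secreted
proteome (the adaptive-stasis signature) would push it above 1.
"""

import itertools

import numpy as np

from stasis_scan import SimulationConfig, simulate_dataset
from stasis_scan.aai import species_aai_profile, spcp_index
from stasis_scan.ani import compute_ani
from stasis_scan.compartments import predict_signal_heuristic
from stasis_scan.records import SpeciesCluster

ds = simulate_dataset(
    SimulationConfig(seed=3, n_species=1, members_per_species=4, n_genes=30,
                     mu_cp=0.01, sp_rate_multiplier=2.0,
                     recomb_events_per_genome=0,
                     completeness_range=(100, 100), contamination_range=(0, 0))
)
proteomes = {m.record.mag_id: {p.protein_id: p.sequence for p in m.proteins}
             for m in ds.mags}
compartments = {}
for m in ds.mags:
    for p in m.proteins:
        topo = predict_signal_heuristic(p.sequence)
        compartments[p.protein_id] = "SP" if topo[0].kind == "signal" else "CP"

cluster = SpeciesCluster("species_1", sorted(proteomes), analysis_eligible=True)
profile = species_aai_profile(cluster, proteomes, compartments)
mean_ani = float(np.mean([
    compute_ani(a.record, b.record).ani
    for a, b in itertools.combinations(ds.mags, 2)
]))
idx = spcp_index(profile, coding_density=0.9, est_size=1.5e6, mean_ani=mean_ani)

print(profile.groupby("compartment")["aai"].describe()[["count", "mean", "min", "max"]])
print(f"\nmean within-species ANI: {mean_ani:.2f}%")
print(f"median SP-AAI: {idx.median_sp_aai:.2f}%   median CP-AAI: {idx.median_cp_aai:.2f}%")
print(f"SP/CP similarity index: {idx.index:.3f}")
print(f"SP/ANI: {idx.sp_over_ani:.3f}   CP/ANI: {idx.cp_over_ani:.3f}")
print(
    "\nAn index < 1 means the secreted proteome is the faster-evolving one,\n"
    "as planted here with a 2x SP substitution rate."
)
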