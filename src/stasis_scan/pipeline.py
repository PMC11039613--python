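"""End-to-end run on simulated data: simulate -> QC -> ANI -> AAI -> FRR.

This is the orchestration layer used by the command line, the examples and
the reproduction script. Every stage is a thin call into the corresponding
module, and all stage outputs are returned (and optionally written) as tidy
tables so the run is fully inspectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import aai, ani, compartments, mag_qc
from .config import SimulationConfig
from .records import SpeciesCluster
from .redundancy import annotation_coverage, functional_redundancy_ratio
from .simulate import SyntheticDataset, simulate_dataset

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """All tables produced by one pipeline run."""

    dataset: SyntheticDataset
    qc: pd.DataFrame
    ani_pairs: pd.DataFrame
    clusters: list[SpeciesCluster]
    cluster_table: pd.DataFrame
    compartment_table: pd.DataFrame
    aai_profiles: dict[str, pd.DataFrame]
    index_table: pd.DataFrame
    frr_table: pd.DataFrame
    indices: list[aai.SPCPIndex] = field(default_factory=list)

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        fmt = "%.6f"
        self.qc.to_csv(outdir / "qc.tsv", sep="\t", index=False, float_format=fmt)
        self.ani_pairs.to_csv(
            outdir / "ani_pairs.tsv", sep="\t", index=False, float_format=fmt
        )
        self.cluster_table.to_csv(
            outdir / "clusters.tsv", sep="\t", index=False, float_format=fmt
        )
        self.compartment_table.to_csv(
            outdir / "compartments.tsv", sep="\t", index=False
        )
        if self.aai_profiles:
            pd.concat(
                [df.assign(cluster_id=cid) for cid, df in self.aai_profiles.items()],
                ignore_index=True,
            ).to_csv(outdir / "aai_pairs.tsv", sep="\t", index=False, float_format=fmt)
        self.index_table.to_csv(
            outdir / "spcp_index.tsv", sep="\t", index=False, float_format=fmt
        )
        self.frr_table.to_csv(
            outdir / "frr.tsv", sep="\t", index=False, float_format=fmt
        )


def run_pipeline(
    config: SimulationConfig,
    min_members: int | None = None,
    ani_params: ani.ANIParams | None = None,
    aai_params: aai.AAIParams | None = None,
    outdir=None,
) -> PipelineResult:
    """Simulate a dataset and run every analysis stage over it.

    ``min_members`` defaults to the configured population size so that the
    simulated clusters are analysis-eligible at any scale; pass 9 to apply
    the survey's eligibility rule verbatim.
    """
    if min_members is None:
        min_members = config.members_per_species
    dataset = simulate_dataset(config)

    # --- MAG QC -----------------------------------------------------------
    qc_rows = []
    curated = {}
    genes_by_mag = {}
    for mag in dataset.mags:
        rec, report = mag_qc.curate_bin(mag.record)
        curated[rec.mag_id] = rec
        kept_genes = [g for g in mag.genes if g.contig_id in rec.contigs]
        genes_by_mag[rec.mag_id] = kept_genes
        est_size = mag_qc.estimate_genome_size(
            rec.length, rec.est_completeness, rec.est_contamination
        )
        if rec.contigs:
            coding_bp = sum(
                mag_qc.coding_density(
                    [g for g in kept_genes if g.contig_id == cid], len(seq)
                )
                * len(seq)
                for cid, seq in rec.contigs.items()
            )
            density = coding_bp / rec.length
        else:
            density = float("nan")
        qc_rows.append(
            {
                "mag_id": rec.mag_id,
                "species_truth": mag.species,
                "tier": mag_qc.classify_quality(
                    rec.est_completeness, rec.est_contamination
                ),
                "est_size": est_size,
                "size_class": mag_qc.classify_genome_size(est_size),
                "coding_density": float(density),
                "n_contigs_discarded": len(report.discards),
            }
        )
    qc = pd.DataFrame(qc_rows)

    # --- ANI + species clustering ----------------------------------------
    retained = [curated[m] for m in sorted(curated) if curated[m].contigs]
    ani_pairs = ani.ani_table(retained, ani_params)
    clusters = ani.cluster_species(
        ani_pairs, min_members=min_members, all_mags=[r.mag_id for r in retained]
    )
    cluster_table = pd.DataFrame(
        [
            {
                "cluster_id": c.cluster_id,
                "n_members": len(c.members),
                "analysis_eligible": c.analysis_eligible,
                "mean_ani": c.mean_ani,
                "members": ",".join(c.members),
            }
            for c in clusters
        ]
    )

    # --- compartment partition (heuristic stand-in on synthetic data) ----
    proteomes: dict[str, dict[str, str]] = {}
    comp_rows = []
    compartment_of: dict[str, str] = {}
    for mag in dataset.mags:
        proteomes[mag.record.mag_id] = {
            p.protein_id: p.sequence for p in mag.proteins
        }
        for p in mag.proteins:
            topo = compartments.predict_signal_heuristic(p.sequence)
            called = "SP" if topo[0].kind == "signal" else "CP"
            compartment_of[p.protein_id] = called
            comp_rows.append(
                {
                    "mag_id": mag.record.mag_id,
                    "protein_id": p.protein_id,
                    "compartment": called,
                    "compartment_truth": p.compartment,
                }
            )
    compartment_table = pd.DataFrame(comp_rows)

    # --- per-cluster AAI and SP/CP index ----------------------------------
    qc_idx = qc.set_index("mag_id")
    profiles: dict[str, pd.DataFrame] = {}
    indices: list[aai.SPCPIndex] = []
    for c in clusters:
        if not c.analysis_eligible or len(c.members) < 2:
            continue
        profile = aai.species_aai_profile(c, proteomes, compartment_of, aai_params)
        profiles[c.cluster_id] = profile
        members = [m for m in c.members if m in qc_idx.index]
        indices.append(
            aai.spcp_index(
                profile,
                coding_density=float(qc_idx.loc[members, "coding_density"].mean()),
                est_size=float(qc_idx.loc[members, "est_size"].mean()),
                mean_ani=c.mean_ani,
                species_id=c.cluster_id,
            )
        )
    index_table = pd.DataFrame(
        [
            {
                "species_id": i.species_id,
                "median_sp_aai": i.median_sp_aai,
                "median_cp_aai": i.median_cp_aai,
                "index": i.index,
                "coding_density": i.coding_density,
                "est_size": i.est_size,
                "size_class": i.size_class,
                "sp_over_ani": i.sp_over_ani,
                "cp_over_ani": i.cp_over_ani,
            }
            for i in indices
        ],
        columns=[
            "species_id", "median_sp_aai", "median_cp_aai", "index",
            "coding_density", "est_size", "size_class", "sp_over_ani", "cp_over_ani",
        ],
    )

    # --- functional redundancy --------------------------------------------
    frr_rows = []
    for mag in dataset.mags:
        mid = mag.record.mag_id
        size_class = qc_idx.loc[mid, "size_class"] if mid in qc_idx.index else None
        for comp in ("SP", "CP"):
            kos = [
                g.ko for g in genes_by_mag.get(mid, []) if g.compartment == comp
            ]
            frr_rows.append(
                {
                    "mag_id": mid,
                    "size_class": size_class,
                    "compartment": comp,
                    "frr": functional_redundancy_ratio(kos) if kos else float("nan"),
                    "annotation_coverage": annotation_coverage(kos) if kos else float("nan"),
                    "n_genes": len(kos),
                }
            )
    frr_table = pd.DataFrame(frr_rows)

    result = PipelineResult(
        dataset=dataset,
        qc=qc,
        ani_pairs=ani_pairs,
        clusters=clusters,
        cluster_table=cluster_table,
        compartment_table=compartment_table,
        aai_profiles=profiles,
        index_table=index_table,
        frr_table=frr_table,
        indices=indices,
    )
    if outdir is not None:
        result.write(outdir)
    return result
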