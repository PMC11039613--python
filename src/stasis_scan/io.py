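"""Reading and writing the pipeline's on-disk formats.

Genomes travel as FASTA (one file per MAG), gene models as GFF3 (1-based,
inclusive, CDS features with ID/ko/compartment attributes), proteins as
FASTA with IDs equal to gene IDs, and metadata/label/truth tables as TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import GeneModel, GenomeRecord, gc_percent
from .simulate import SyntheticDataset

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_dataset",
    "read_genome_dir",
]


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_gff3(genes: list[GeneModel], path, source: str = "stasis_scan") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = [f"ID={g.gene_id}"]
            if g.ko:
                attrs.append(f"ko={g.ko}")
            if g.compartment:
                attrs.append(f"compartment={g.compartment}")
            fh.write(
                "\t".join(
                    [
                        g.contig_id,
                        source,
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        ";".join(attrs),
                    ]
                )
                + "\n"
            )


def read_gff3(path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9 or cols[2] != "CDS":
                continue
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            genes.append(
                GeneModel(
                    gene_id=attrs.get("ID", ""),
                    contig_id=cols[0],
                    start=int(cols[3]),
                    end=int(cols[4]),
                    strand=cols[6],
                    ko=attrs.get("ko"),
                    compartment=attrs.get("compartment"),
                )
            )
    return genes


def write_dataset(dataset: SyntheticDataset, outdir) -> None:
    """Emit a simulated dataset as the file set the pipeline consumes.

    Per MAG: ``<mag>.fna`` (contigs), ``<mag>.gff`` (gene models),
    ``<mag>.faa`` (proteins). Dataset-wide: ``metadata.tsv`` (mag_id,
    species_truth, completeness, contamination, gc), ``labels.tsv`` (one
    row per protein top-hit: mag_id, contig_id, class_label), and the
    truth tables ``truth_genes.tsv``, ``truth_genomes.tsv``,
    ``truth_imports.tsv``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta_rows = []
    label_rows = []
    for mag in dataset.mags:
        rec = mag.record
        write_fasta(rec.contigs, outdir / f"{rec.mag_id}.fna")
        write_gff3(mag.genes, outdir / f"{rec.mag_id}.gff")
        write_fasta(
            {p.protein_id: p.sequence for p in mag.proteins},
            outdir / f"{rec.mag_id}.faa",
        )
        full = "".join(rec.contigs.values())
        meta_rows.append(
            {
                "mag_id": rec.mag_id,
                "species_truth": mag.species,
                "completeness": round(mag.planted_completeness, 4),
                "contamination": round(mag.planted_contamination, 4),
                "gc": round(gc_percent(full), 4),
            }
        )
        for cid, labels in rec.contig_taxonomy.items():
            for lab in labels:
                label_rows.append(
                    {"mag_id": rec.mag_id, "contig_id": cid, "class_label": lab}
                )
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)
    pd.DataFrame(label_rows, columns=["mag_id", "contig_id", "class_label"]).to_csv(
        outdir / "labels.tsv", sep="\t", index=False
    )
    dataset.gene_truth().to_csv(outdir / "truth_genes.tsv", sep="\t", index=False)
    dataset.genome_truth().to_csv(
        outdir / "truth_genomes.tsv", sep="\t", index=False, float_format="%.6f"
    )
    dataset.import_truth().to_csv(outdir / "truth_imports.tsv", sep="\t", index=False)


def read_genome_dir(indir) -> tuple[list[GenomeRecord], dict[str, list[GeneModel]]]:
    """Load a dataset directory written by :func:`write_dataset`."""
    indir = Path(indir)
    meta = pd.read_csv(indir / "metadata.tsv", sep="\t")
    labels = pd.read_csv(indir / "labels.tsv", sep="\t")
    genomes = []
    genes: dict[str, list[GeneModel]] = {}
    for row in meta.itertuples():
        contigs = read_fasta(indir / f"{row.mag_id}.fna")
        tax: dict[str, list[str]] = {c: [] for c in contigs}
        for lab in labels[labels["mag_id"] == row.mag_id].itertuples():
            tax.setdefault(lab.contig_id, []).append(lab.class_label)
        genomes.append(
            GenomeRecord(
                mag_id=str(row.mag_id),
                contigs=contigs,
                est_completeness=float(row.completeness),
                est_contamination=float(row.contamination),
                contig_taxonomy=tax,
            )
        )
        genes[str(row.mag_id)] = read_gff3(indir / f"{row.mag_id}.gff")
    return genomes, genes
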