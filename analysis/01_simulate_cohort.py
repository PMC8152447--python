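#!/usr/bin/env python
"""Generate the synthetic homolog cohort used by the downstream analyses.

Writes, under results/cohort/: per-organism transcript FASTA, the true
nucleotide alignments (aligned FASTA, for oracle comparisons), the
footprint and offset tables, the annotation, the planted-site truth table,
and the context annotation tables (exons, domains, disorder, TM, SNPs).
"""

from __future__ import annotations

import json
from pathlib import Path

from stallsites import io
from stallsites.simulate import (
    SimConfig,
    simulate_context_annotations,
    simulate_footprints,
    simulate_homolog_sequences,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"

CONFIG = SimConfig(n_organisms=3, n_genes=60, seed=11)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    truth = simulate_homolog_sequences(CONFIG)
    fp = simulate_footprints(truth, CONFIG)
    tables = simulate_context_annotations(truth, CONFIG)

    for org in CONFIG.organisms:
        seqs = {
            per[org].transcript_id: per[org].sequence
            for per in truth.transcripts.values()
        }
        io.write_fasta(seqs, OUT / f"transcripts_{org}.fa")
    aligned = {}
    for gene_id in truth.transcripts:
        for org, row in truth.true_alignment(gene_id).items():
            aligned[f"{gene_id}|{org}"] = row
    io.write_fasta(aligned, OUT / "true_alignment.fa")

    io.write_footprints(fp.table, OUT / "footprints.tsv")
    io.write_offsets(fp.offsets, OUT / "offsets.tsv")
    truth.annotation_table().to_csv(OUT / "annotation.tsv", sep="\t",
                                    index=False)
    truth.truth_table().to_csv(OUT / "truth_sites.tsv", sep="\t", index=False)
    for name, table in tables.items():
        table.to_csv(OUT / f"{name}.tsv", sep="\t", index=False)
    io.write_snps_vcf(tables["snps"], OUT / "snps.vcf")
    (OUT / "config.json").write_text(
        json.dumps(
            {"n_organisms": CONFIG.n_organisms, "n_genes": CONFIG.n_genes,
             "seed": CONFIG.seed},
            indent=2,
        )
    )

    n_sites = len(truth.sites)
    n_cons = sum(1 for s in truth.sites if s.conserved)
    print(f"cohort: {CONFIG.n_genes} genes x {CONFIG.n_organisms} organisms")
    print(f"planted sites: {n_sites} ({n_cons} conserved groups)")
    print(f"footprint records: {len(fp.table)}")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
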