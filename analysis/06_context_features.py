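#!/usr/bin/env python
"""Structural, positional and termination context of the conserved sites.

Folds 51-nt sliding windows around conserved sites (built-in base-pair
maximisation stub by default) with random-position and codon-permutation
controls, locates sites relative to exon and protein-domain boundaries,
summarises disorder scores, checks TM-anchor positioning, computes the
premature-termination log2 coverage ratios, and the fragment-length
metaplots around stop codons vs stall sites.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from stallsites import profiles
from stallsites.contextfeatures import (
    abort_ratio,
    abort_summary,
    disorder_meta,
    domain_distance,
    exon_position_stats,
    fragment_length_metaplot,
    mfe_sliding,
    structure_metaplot,
    tm_position_distribution,
)
from stallsites.nullmodel import snp_overlap
from stallsites.pipeline import run_synthetic_pipeline
from stallsites.simulate import SimConfig, simulate_context_annotations

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cfg = SimConfig(
        **json.loads((ROOT / "cohort" / "config.json").read_text())
    )
    result = run_synthetic_pipeline(cfg, alignment_source="true")
    truth = result.truth
    css = result.css_table()
    if css.empty:
        raise SystemExit("no conserved sites; run 01-03 first")
    tables = simulate_context_annotations(truth, cfg)
    annotation = truth.annotation_table()

    # one representative member per conserved site keeps folding cheap
    anchor = css.drop_duplicates("css_id")
    subset = anchor.head(40)
    tracks = {}
    for tx_id in subset["transcript_id"].unique():
        tx = truth.transcript(tx_id)
        tracks[tx_id] = mfe_sliding(
            tx.sequence, tx.cds_start, tx.cds_end, transcript_id=tx_id
        )
    seqs = {t: truth.transcript(t).sequence for t in tracks}
    meta = structure_metaplot(
        subset, tracks, seqs, n_random=200, n_perm=20, seed=5
    )
    pd.DataFrame(
        {"offset": meta["offsets"], "css_mfe": meta["css"],
         "control_mfe": meta["control"], "control_lo": meta["control_lo"],
         "control_hi": meta["control_hi"],
         "permutation_mfe": meta["permutation"]}
    ).to_csv(ROOT / "structure_metaplot.tsv", sep="\t", index=False)
    inside = float(np.mean(
        (meta["css"] >= meta["control_lo"])
        & (meta["css"] <= meta["control_hi"])
    ))
    print(f"structure: {meta['n_sites']} sites folded; "
          f"{inside:.0%} of the stall-site MFE curve inside the "
          f"5th-95th percentile control band (no planted structure)")

    exon_stats = exon_position_stats(anchor, tables["exons"], annotation)
    exon_stats.to_csv(ROOT / "exon_positions.tsv", sep="\t", index=False)
    print(f"exon positions: {len(exon_stats)} sites, median relative "
          f"position {exon_stats['relative_position'].median():.2f}")

    prot_lens = {
        tx.transcript_id: (tx.cds_end - tx.cds_start) // 3 - 1
        for per in truth.transcripts.values()
        for tx in per.values()
    }
    dom = domain_distance(anchor, tables["domains"], seed=6,
                          protein_lengths=prot_lens)
    dom.to_csv(ROOT / "domain_distance.tsv", sep="\t", index=False)
    have = dom["distance"].notna()
    print(f"domains: {have.sum()} sites downstream of a domain "
          f"(median distance {dom.loc[have, 'distance'].median():.0f} aa)")

    dis = disorder_meta(anchor, tables["disorder"], seed=7)
    print(f"disorder: coil fraction {dis['css_coil_fraction']:.1%} at sites "
          f"vs {dis['control_coil_fraction']:.1%} random "
          f"(t-test p = {dis['t_test_p']:.2f})")

    tm = tm_position_distribution(anchor, tables["tm"])
    print(f"TM proteins: {len(tm['offsets'])} sites downstream of an anchor "
          f"(uniformity p = {tm['uniformity_p']})")

    term_stats = []
    for _, row in css.iterrows():
        prof = result.profiles[row["transcript_id"]]
        term_stats.append(
            abort_ratio(row["css_id"], int(row["codon_index"]), prof.counts)
        )
    summary = abort_summary(term_stats)
    pd.DataFrame(
        [{"css_id": s.css_id, "log2_ratio": s.log2_ratio,
          "eligible": s.eligible} for s in term_stats]
    ).to_csv(ROOT / "abort_ratios.tsv", sep="\t", index=False)
    print(f"termination: {summary['n_eligible']} eligible sites, "
          f"{summary['n_aborted']} with log2 up/down ratio > 2 "
          f"({summary['fraction_aborted']:.1%}) - planted stalls do not "
          f"abort translation")

    profs = profiles.build_codon_profiles(
        result.footprints.table, result.footprints.offsets, annotation,
        selected_lengths=sorted(result.footprints.offsets),
        keep_per_length=True,
    )
    per_len = {tx: p.per_length_coverage for tx, p in profs.items()}
    stops = [
        (tx.transcript_id, tx.cds_end - 3)
        for per in truth.transcripts.values()
        for tx in per.values()
    ]
    css_anchors = [
        (row["transcript_id"],
         truth.transcript(row["transcript_id"]).cds_start
         + 3 * int(row["codon_index"]))
        for _, row in anchor.iterrows()
    ]
    for name, anchors in (("stop", stops), ("css", css_anchors)):
        fragment_length_metaplot(per_len, anchors).to_csv(
            ROOT / f"fragment_lengths_{name}.tsv", sep="\t", index=False
        )
    print("fragment-length metaplots written for stop-codon and stall-site "
          "anchors")

    cds_starts = {
        tx.transcript_id: tx.cds_start
        for per in truth.transcripts.values()
        for tx in per.values()
    }
    obs, ctl, exp = snp_overlap(
        anchor, tables["snps"],
        {t: (truth.transcript(t).cds_end - truth.transcript(t).cds_start) // 3
         for t in anchor["transcript_id"]},
        cds_starts, seed=8,
    )
    print(f"SNP overlap: {obs} observed vs {ctl} control vs {exp:.1f} "
          f"expected at uniform density")


if __name__ == "__main__":
    main()
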