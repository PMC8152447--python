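#!/usr/bin/env python
"""Characterise the sequence context of the conserved stall sites.

Builds amino-acid windows around every conserved site, attributes each to a
stalling mechanism (P-site Pro/Gly/Asp, A-site Glu, lysine stretches,
negative charge entering the exit tunnel), compares the attribution to the
planted category mix, and writes the enrichment matrices, exit-tunnel
charge profile, nucleotide PFM, and the [CGA][CGA]N motif resampling test.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from stallsites.nullmodel import motif_resampling_test
from stallsites.pipeline import run_synthetic_pipeline
from stallsites.seqfeatures import (
    aa_enrichment_matrix,
    contexts_from_truth,
    extract_context,
    kmer_enrichment,
    mechanism_breakdown,
    nucleotide_pfm,
    pfm_to_meme,
    tunnel_charge_profile,
)
from stallsites.simulate import SimConfig

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
    contexts = contexts_from_truth(truth, css)
    print(f"contexts for {len(contexts)} conserved-site members")

    rng = np.random.default_rng(2)
    bg_rows = []
    for _, row in css.iterrows():
        tx = truth.transcript(row["transcript_id"])
        n_codons = (tx.cds_end - tx.cds_start) // 3
        bg_rows.append(
            {
                "css_id": f"bg_{row['css_id']}",
                "transcript_id": row["transcript_id"],
                "codon_index": int(rng.integers(11, n_codons - 12)),
            }
        )
    background = contexts_from_truth(truth, pd.DataFrame(bg_rows))

    freq, enr = aa_enrichment_matrix(contexts, background)
    freq.to_csv(ROOT / "aa_frequency.tsv", sep="\t")
    enr.to_csv(ROOT / "aa_enrichment.tsv", sep="\t")

    breakdown = mechanism_breakdown(contexts)
    breakdown.to_csv(ROOT / "mechanism_breakdown.tsv", sep="\t", index=False)
    explained = 1.0 - breakdown.set_index("category").loc[
        "unexplained", "fraction"
    ]
    print("mechanistic attribution:")
    for _, r in breakdown.iterrows():
        print(f"  {r['category']:>11}: {r['fraction']:.1%} ({r['count']})")
    print(f"explained by sequence features: {explained:.1%}")

    for k in (2, 3):
        kmer_enrichment(contexts, k, background).head(20).to_csv(
            ROOT / f"kmer_{k}.tsv", sep="\t", index=False
        )

    prots = {}
    for per in truth.transcripts.values():
        for tx in per.values():
            cds = tx.sequence[tx.cds_start : tx.cds_end - 3]
            prots[tx.transcript_id] = str(Seq(cds).translate())
    charge = tunnel_charge_profile(contexts, prots, n_background=2000, seed=3)
    charge_df = pd.DataFrame(
        {"position": charge["positions"],
         **{cls: charge["fractions"][cls]
            for cls in ("positive", "negative", "special", "other")}}
    )
    charge_df.to_csv(ROOT / "tunnel_charge.tsv", sep="\t", index=False)

    pfm = nucleotide_pfm(contexts)
    pfm.to_csv(ROOT / "nucleotide_pfm.tsv", sep="\t")
    (ROOT / "nucleotide_pfm.meme").write_text(pfm_to_meme(pfm))

    site_codons, pools = [], []
    for _, row in css.iterrows():
        tx = truth.transcript(row["transcript_id"])
        i = int(row["codon_index"])
        site_codons.append(
            tx.sequence[tx.cds_start + 3 * i : tx.cds_start + 3 * i + 3]
        )
        cds = tx.sequence[tx.cds_start : tx.cds_end]
        pools.append([cds[j : j + 3] for j in range(0, len(cds) - 3, 3)])
    obs, exp, pval = motif_resampling_test(
        site_codons, pools, "[CGA][CGA]N", n_resample=1000, seed=4
    )
    print(f"[CGA][CGA]N motif: observed {obs} vs resampled mean {exp:.1f} "
          f"of {len(site_codons)} sites (chi-square p = {pval:.2e})")
    pd.DataFrame(
        [{"observed": obs, "expected_mean": exp, "p_value": pval,
          "n_sites": len(site_codons)}]
    ).to_csv(ROOT / "motif_test.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
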