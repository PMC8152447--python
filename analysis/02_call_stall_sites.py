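#!/usr/bin/env python
"""Call stall peaks from the cohort's footprint table.

Reads the TSV outputs of 01_simulate_cohort.py (the canonical interchange
path), rebuilds P-site codon profiles, applies the z > 5 calling rule, and
writes results/peaks.tsv plus the ribosome metaprofile. Also reports how
many planted sites the calls recover.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from stallsites import calling, io, profiles

ROOT = Path(__file__).resolve().parent.parent / "results"
COHORT = ROOT / "cohort"


def main() -> None:
    footprints = io.read_footprints(COHORT / "footprints.tsv")
    offsets = io.read_offsets(COHORT / "offsets.tsv")
    annotation = io.read_annotation(COHORT / "annotation.tsv")

    selected = profiles.periodic_lengths(footprints, annotation, offsets)
    print(f"periodic footprint lengths: {selected}")

    profs = profiles.build_codon_profiles(
        footprints, offsets, annotation, selected_lengths=selected
    )
    n_expressed = sum(calling.is_well_expressed(p) for p in profs.values())
    print(f"well-expressed transcripts: {n_expressed}/{len(profs)}")

    peaks = calling.call_peaks_table(profs, annotation=annotation)
    peaks.to_csv(ROOT / "peaks.tsv", sep="\t", index=False)
    print(f"called peaks: {len(peaks)} "
          f"(median z = {peaks['z_score'].median():.1f})")

    truth = pd.read_csv(COHORT / "truth_sites.tsv", sep="\t")
    planted = set(zip(truth["transcript_id"], truth["codon_index"]))
    called = set(zip(peaks["transcript_id"], peaks["codon_index"]))
    recovered = len(planted & called)
    print(f"planted member sites recovered: {recovered}/{len(planted)} "
          f"({recovered / len(planted):.1%}); "
          f"false calls: {len(called - planted)}")

    cov = {tx: p.nt_coverage for tx, p in profs.items()}
    mp = profiles.metaprofile(cov, annotation)
    mp.to_csv(ROOT / "metaprofile.tsv", sep="\t", index=False)
    cds = mp[mp["region"].isin(["cds_start", "cds_end"])]
    frac0 = cds.loc[cds["frame"] == 0, "coverage"].sum() / cds["coverage"].sum()
    print(f"metaprofile frame-0 fraction within CDS windows: {frac0:.2f}")


if __name__ == "__main__":
    main()
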