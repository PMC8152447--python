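"""End-to-end synthetic pipeline: simulate -> profile -> call -> conserve.

Convenience drivers used by the analysis scripts and the recovery
benchmarks; each step delegates to the corresponding module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import pandas as pd

from stallsites import calling, profiles
from stallsites.conservation import ConservedStallSite, iterative_conservation
from stallsites.simulate import (
    SimConfig,
    SimTruth,
    SimulatedFootprints,
    simulate_footprints,
    simulate_homolog_sequences,
)


@dataclass
class PipelineResult:
    truth: SimTruth
    footprints: SimulatedFootprints
    profiles: dict[str, profiles.CodonProfile]
    peaks: dict[str, list[calling.StallPeak]]  # transcript -> peaks
    css: dict[str, list[ConservedStallSite]]   # gene -> conserved sites

    def peak_table(self) -> pd.DataFrame:
        ann = self.truth.annotation_table()
        return calling.call_peaks_table(self.profiles, annotation=ann)

    def css_table(self) -> pd.DataFrame:
        rows = []
        for gene, sites in self.css.items():
            for css in sites:
                for org, tx, codon, col in css.members:
                    rows.append(
                        {
                            "css_id": css.css_id,
                            "group_id": gene,
                            "conservation_level": css.conservation_level,
                            "organism": org,
                            "transcript_id": tx,
                            "codon_index": codon,
                            "column": col,
                        }
                    )
        return pd.DataFrame(
            rows,
            columns=["css_id", "group_id", "conservation_level", "organism",
                     "transcript_id", "codon_index", "column"],
        )


def run_synthetic_pipeline(
    config: SimConfig,
    params: Optional[calling.CallingParams] = None,
    alignment_source: str = "true",
    truth: Optional[SimTruth] = None,
) -> PipelineResult:
    """Run the full desk-scale pipeline on a simulated cohort.

    ``alignment_source`` selects how homologs are aligned for conservation:
    "true" uses the simulation's ground-truth alignment, "builtin" the
    center-star aligner, "external" an MSA tool on PATH.
    """
    if params is None:
        params = calling.CallingParams()
    if truth is None:
        truth = simulate_homolog_sequences(config)
    fp = simulate_footprints(truth, config)
    ann = truth.annotation_table()
    profs = profiles.build_codon_profiles(
        fp.table, fp.offsets, ann, selected_lengths=sorted(fp.offsets)
    )
    peaks = {tx: calling.call_peaks(p, params) for tx, p in profs.items()}

    css: dict[str, list[ConservedStallSite]] = {}
    for gene_id, per_org in truth.transcripts.items():
        seqs = {org: t.sequence for org, t in per_org.items()}
        peaks_by_org = {
            org: peaks.get(t.transcript_id, []) for org, t in per_org.items()
        }
        if sum(1 for v in peaks_by_org.values() if v) < 2:
            css[gene_id] = []
            continue
        kwargs = {}
        if alignment_source == "true":
            kwargs["full_alignment"] = truth.true_alignment(gene_id)
        else:
            kwargs["backend"] = alignment_source
        css[gene_id] = iterative_conservation(
            seqs, peaks_by_org, group_id=gene_id, **kwargs
        )
    return PipelineResult(
        truth=truth, footprints=fp, profiles=profs, peaks=peaks, css=css
    )


def score_peak_recovery(
    truth: SimTruth, peaks: Mapping[str, Sequence[calling.StallPeak]]
) -> tuple[float, float]:
    """(recall of planted sites, empirical FDR of called peaks).

    A planted site member counts as recovered when a peak is called at its
    exact codon; a called peak not at any planted member is a false call.
    """
    planted = set()
    for site in truth.sites:
        for org, idx in site.codon_index.items():
            planted.add((truth.transcripts[site.gene_id][org].transcript_id, idx))
    hits = set()
    n_false = 0
    n_called = 0
    for tx, plist in peaks.items():
        for p in plist:
            n_called += 1
            if (tx, p.codon_index) in planted:
                hits.add((tx, p.codon_index))
            else:
                n_false += 1
    recall = len(hits) / len(planted) if planted else float("nan")
    fdr = n_false / n_called if n_called else 0.0
    return recall, fdr


def score_group_recovery(
    truth: SimTruth, css: Mapping[str, Sequence[ConservedStallSite]]
) -> float:
    """Fraction of planted conserved groups matched by a conserved stall
    site covering at least two of the group's (organism, codon) members."""
    groups = [s for s in truth.sites if s.conserved]
    if not groups:
        return float("nan")
    n_found = 0
    for site in groups:
        member_keys = {
            (truth.transcripts[site.gene_id][org].transcript_id, idx)
            for org, idx in site.codon_index.items()
        }
        found = False
        for css_site in css.get(site.gene_id, []):
            overlap = sum(
                1
                for _, tx, codon, _ in css_site.members
                if (tx, codon) in member_keys
            )
            if overlap >= 2:
                found = True
                break
        if found:
            n_found += 1
    return n_found / len(groups)
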