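"""Synthetic-cohort generator: mutation model, planted truth, footprints."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stallsites.conservation import pos_to_column
from stallsites.simulate import (
    CONTEXT_EXEMPT_DOWN,
    CONTEXT_EXEMPT_UP,
    STOP_CODONS,
    SimConfig,
    simulate_context_annotations,
    simulate_footprints,
    simulate_homolog_sequences,
)


def test_config_validation_rejects_bad_inputs():
    with pytest.raises(ValueError):
        SimConfig(n_organisms=1)
    with pytest.raises(ValueError):
        SimConfig(n_organisms=6)
    with pytest.raises(ValueError):
        SimConfig(dwell_factor=0.5)
    with pytest.raises(ValueError):
        SimConfig(context_probs={"ProP": 0.5, "none": 0.4})
    with pytest.raises(ValueError):
        SimConfig(length_distribution={28: 1.0}, offset_table={29: 12})
    with pytest.raises(ValueError):
        # too short to host the planted sites and their exclusion zones
        SimConfig(cds_codons_mean=60, cds_codons_sd=0)


def test_zero_mutation_gives_identical_homologs():
    cfg = SimConfig(
        n_organisms=3, n_genes=4, substitution_rate=0.0, codon_indel_rate=0.0,
        seed=1,
    )
    truth = simulate_homolog_sequences(cfg)
    for per_org in truth.transcripts.values():
        cds = {
            tx.sequence[tx.cds_start : tx.cds_end] for tx in per_org.values()
        }
        assert len(cds) == 1


def test_conserved_groups_span_all_organisms(small_truth, small_config):
    for site in small_truth.sites:
        if site.conserved:
            assert set(site.codon_index) == set(small_config.organisms)
        else:
            assert len(site.codon_index) == 1


def test_cds_structure_is_valid(small_truth):
    for per_org in small_truth.transcripts.values():
        for tx in per_org.values():
            cds = tx.sequence[tx.cds_start : tx.cds_end]
            assert len(cds) % 3 == 0
            assert cds.startswith("ATG")
            assert cds[-3:] in STOP_CODONS
            internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
            assert not any(c in STOP_CODONS for c in internal)


def test_substitution_rate_recovered_from_mismatch_counts():
    """Observed per-nt substitution fraction over mutable positions matches
    the configured rate to within 3 Monte-Carlo standard errors."""
    rate = 0.05
    cfg = SimConfig(
        n_organisms=2, n_genes=1000, cds_codons_mean=120, cds_codons_sd=0,
        planted_conserved_per_gene=1, planted_private_per_gene=0,
        substitution_rate=rate, codon_indel_rate=0.0, seed=5,
    )
    truth = simulate_homolog_sequences(cfg)
    mismatches = 0
    total = 0
    for gene_id, per_org in truth.transcripts.items():
        anc = truth.ancestors[gene_id]
        exempt = set()
        for site in truth.sites:
            if site.gene_id != gene_id:
                continue
            p = next(iter(site.codon_index.values()))
            for off in range(-CONTEXT_EXEMPT_UP, CONTEXT_EXEMPT_DOWN + 1):
                exempt.add(p + off)
        n_codons = len(anc) // 3
        for tx in per_org.values():
            cds = tx.sequence[tx.cds_start : tx.cds_end]
            assert len(cds) == len(anc)
            for ci in range(1, n_codons - 1):
                if ci in exempt:
                    continue
                for f in range(3):
                    total += 1
                    mismatches += cds[3 * ci + f] != anc[3 * ci + f]
    observed = mismatches / total
    se = np.sqrt(rate * (1 - rate) / total)
    assert abs(observed - rate) <= 3 * se


def test_true_alignment_is_consistent(small_truth):
    """Ungapping each row reproduces the transcript, and conserved members
    share the alignment column of their P-site nucleotide."""
    for gene_id, per_org in small_truth.transcripts.items():
        aln = small_truth.true_alignment(gene_id)
        widths = {len(r) for r in aln.values()}
        assert len(widths) == 1
        for org, row in aln.items():
            assert row.replace("-", "") == per_org[org].sequence
    for site in small_truth.sites:
        if not site.conserved:
            continue
        aln = small_truth.true_alignment(site.gene_id)
        cols = set()
        for org, idx in site.codon_index.items():
            tx = small_truth.transcripts[site.gene_id][org]
            cols.add(pos_to_column(aln[org], tx.cds_start + 3 * idx))
        assert len(cols) == 1


def test_determinism_same_seed_same_output(small_config, small_truth,
                                           small_footprints):
    truth2 = simulate_homolog_sequences(small_config)
    for gene_id, per_org in small_truth.transcripts.items():
        for org, tx in per_org.items():
            assert truth2.transcripts[gene_id][org].sequence == tx.sequence
    fp2 = simulate_footprints(truth2, small_config)
    pd.testing.assert_frame_equal(fp2.table, small_footprints.table)


def test_footprint_count_conservation(small_footprints):
    total_records = small_footprints.table["count"].sum()
    total_draws = sum(
        c.sum() for c in small_footprints.true_codon_counts.values()
    )
    assert total_records == total_draws


def test_offset_round_trip_recovers_codon(small_truth, small_footprints):
    """Applying the offset table to every record lands on the P-site codon
    the count was drawn for (in frame, within the CDS)."""
    by_tx = {
        tx.transcript_id: tx
        for per in small_truth.transcripts.values()
        for tx in per.values()
    }
    tbl = small_footprints.table
    psite = tbl["five_prime_pos"].to_numpy() + np.array(
        [small_footprints.offsets[l] for l in tbl["length"]]
    )
    for tx_id, grp_psite in pd.Series(psite).groupby(tbl["transcript_id"]):
        tx = by_tx[tx_id]
        rel = grp_psite.to_numpy() - tx.cds_start
        assert (rel % 3 == 0).all()
        assert (rel >= 0).all() and (rel < tx.cds_end - tx.cds_start).all()


def test_dwell_factor_one_is_indistinguishable_from_background():
    cfg = SimConfig(
        n_organisms=2, n_genes=30, cds_codons_mean=200, cds_codons_sd=0,
        dwell_factor=1.0, seed=9,
    )
    truth = simulate_homolog_sequences(cfg)
    fp = simulate_footprints(truth, cfg)
    stall_counts, bg_counts = [], []
    for tx_id, counts in fp.true_codon_counts.items():
        stalls = set(fp.stall_codons[tx_id])
        for i, c in enumerate(counts):
            (stall_counts if i in stalls else bg_counts).append(c)
    from scipy import stats

    p = stats.mannwhitneyu(stall_counts, bg_counts).pvalue
    assert p > 0.01


def test_dwell_factor_scales_planted_mean():
    """Mean count at planted codons is expression_mean * dwell_factor over
    >=10^3 planted member sites (law of large numbers)."""
    cfg = SimConfig(
        n_organisms=3, n_genes=100, cds_codons_mean=150, cds_codons_sd=0,
        dwell_factor=20.0, expression_mean=10.0, seed=11,
        planted_conserved_per_gene=3, planted_private_per_gene=1,
    )
    truth = simulate_homolog_sequences(cfg)
    fp = simulate_footprints(truth, cfg)
    stall_counts = []
    for tx_id, counts in fp.true_codon_counts.items():
        stall_counts.extend(counts[i] for i in fp.stall_codons[tx_id])
    stall_counts = np.array(stall_counts)
    assert len(stall_counts) >= 1000
    expected = 200.0
    sd = np.sqrt(expected + expected**2 / cfg.nb_dispersion)
    se = sd / np.sqrt(len(stall_counts))
    assert abs(stall_counts.mean() - expected) <= 4 * se


def test_snp_density_zero_and_recovered(small_truth, small_config):
    empty = simulate_context_annotations(
        small_truth, small_config, snp_density=0.0
    )
    assert empty["snps"].empty
    d = 0.009
    tables = simulate_context_annotations(small_truth, small_config,
                                          snp_density=d)
    total_nt = sum(
        tx.cds_end - tx.cds_start
        for per in small_truth.transcripts.values()
        for tx in per.values()
    )
    observed = len(tables["snps"]) / total_nt
    se = np.sqrt(d * (1 - d) / total_nt)
    assert abs(observed - d) <= 3 * se


def test_domain_longer_than_cds_is_an_error(small_truth, small_config):
    with pytest.raises(ValueError):
        simulate_context_annotations(
            small_truth, small_config, domain_len=(10_000, 20_000)
        )


def test_context_annotation_invariants(small_truth, small_annotations_tables):
    tables = small_annotations_tables
    assert ((tables["disorder"]["score"] >= 0)
            & (tables["disorder"]["score"] <= 1)).all()
    for tx_id, sub in tables["exons"].groupby("transcript_id"):
        sub = sub.sort_values("exon_index")
        assert sub.iloc[0]["start"] == 0
        tx = small_truth.transcript(tx_id)
        assert sub.iloc[-1]["end"] == len(tx.sequence)
        assert (sub["end"].to_numpy()[:-1] == sub["start"].to_numpy()[1:]).all()
    for tx_id, sub in tables["domains"].groupby("transcript_id"):
        sub = sub.sort_values("start_aa")
        starts = sub["start_aa"].to_numpy()
        ends = sub["end_aa"].to_numpy()
        assert (ends > starts).all()
        assert (starts[1:] >= ends[:-1]).all()  # non-overlapping
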