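"""Sequence context of stall sites: windows, enrichment, charge profiles,
position frequency matrices and mechanistic attribution."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from stallsites.seqfeatures import (
    MECHANISM_CATEGORIES,
    SiteContext,
    aa_enrichment_matrix,
    aa_frequency_matrix,
    arrest_peptide_frequencies,
    classify_mechanism,
    contexts_from_truth,
    extract_context,
    kmer_enrichment,
    mechanism_breakdown,
    nucleotide_pfm,
    tunnel_charge_profile,
)

# 21-codon CDS translating to MAAAPKKDEGLLLSSTTVVW* around a central site
_CODONS = [
    "ATG", "GCC", "GCA", "GCG", "CCC", "AAA", "AAG", "GAC", "GAA", "GGC",
    "CTG", "CTA", "CTC", "AGC", "AGT", "ACA", "ACC", "GTG", "GTT", "TGG",
    "TAA",
]
_CDS = "".join(_CODONS)


def _ctx(p_site=10, utr=6):
    seq = "T" * utr + _CDS + "T" * utr
    return extract_context("s", "t", p_site, seq, utr, utr + len(_CDS))


class TestExtractContext:
    def test_windows_match_manual_translation(self):
        ctx = _ctx(p_site=10)
        assert ctx.peptide[0] == "L"
        assert ctx.peptide[1] == "L"   # A-site
        assert ctx.peptide[-1] == "G"  # E-site
        assert ctx.peptide[-10] == "M"
        assert ctx.codons[0] == "CTG"
        assert ctx.codons[-1] == "GGC"
        assert -10 not in ctx.truncated

    def test_site_at_codon_zero_truncates_upstream(self):
        ctx = _ctx(p_site=0)
        assert all(off in ctx.truncated for off in range(-10, 0))
        assert ctx.peptide[0] == "M"

    def test_p_site_is_translation_of_peak_codon(self, small_truth):
        site = small_truth.sites[0]
        org, idx = next(iter(site.codon_index.items()))
        tx = small_truth.transcripts[site.gene_id][org]
        ctx = extract_context("s", tx.transcript_id, idx, tx.sequence,
                              tx.cds_start, tx.cds_end)
        from Bio.Seq import Seq
        codon = tx.sequence[tx.cds_start + 3 * idx : tx.cds_start + 3 * idx + 3]
        assert ctx.peptide[0] == str(Seq(codon).translate())

    def test_outside_cds_errors(self):
        with pytest.raises(ValueError):
            _ctx(p_site=25)


class TestAaMatrices:
    def test_self_background_enrichment_is_one(self):
        ctxs = [_ctx(10), _ctx(12)]
        freq, enr = aa_enrichment_matrix(ctxs, ctxs)
        vals = enr.to_numpy()
        assert np.allclose(vals[~np.isnan(vals)], 1.0)

    def test_planted_proline_has_frequency_one(self):
        ctx = _ctx(4)  # codon 4 is CCC = Pro
        freq = aa_frequency_matrix([ctx])
        assert freq.loc["P", 0] == 1.0

    def test_columns_sum_to_one(self):
        freq = aa_frequency_matrix([_ctx(10), _ctx(11), _ctx(9)])
        sums = freq.sum(axis=0).to_numpy()
        assert np.allclose(sums[sums > 0], 1.0)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            aa_frequency_matrix([])


def _peptide_only_ctx(peptide_by_offset):
    ctx = SiteContext("s", "t", 50)
    base = {off: "A" for off in range(-10, 11)}
    base.update(peptide_by_offset)
    ctx.peptide = base
    return ctx


class TestKmers:
    def test_planted_double_proline_ranks_top(self, rng):
        aas = "CDEFGHIKLMNQRSTVWY"  # background without A or P
        def random_ctx():
            return _peptide_only_ctx(
                {off: str(rng.choice(list(aas))) for off in range(-10, 11)}
            )
        bg = [random_ctx() for _ in range(50)]
        sites = []
        for _ in range(50):
            ctx = random_ctx()
            ctx.peptide[-1] = "P"
            ctx.peptide[0] = "P"
            sites.append(ctx)
        table = kmer_enrichment(sites, 2, bg)
        assert table.iloc[0]["kmer"] == "PP"

    def test_unsupported_k_errors(self):
        with pytest.raises(ValueError):
            kmer_enrichment([_ctx()], 4, [_ctx()])


class TestTunnelCharge:
    def test_partition_sums_to_one(self, small_truth, small_peaks):
        rows = [
            {"css_id": s.site_id,
             "transcript_id": small_truth.transcripts[s.gene_id][o].transcript_id,
             "codon_index": i}
            for s in small_truth.sites
            for o, i in s.codon_index.items()
        ]
        ctxs = contexts_from_truth(small_truth, pd.DataFrame(rows))
        from Bio.Seq import Seq
        prots = {}
        for per in small_truth.transcripts.values():
            for tx in per.values():
                cds = tx.sequence[tx.cds_start : tx.cds_end - 3]
                prots[tx.transcript_id] = str(Seq(cds).translate())
        out = tunnel_charge_profile(ctxs, prots, n_background=100, seed=0)
        total = sum(
            out["fractions"][c]
            for c in ("positive", "negative", "special", "other")
        )
        assert np.allclose(total[~np.isnan(total)], 1.0)
        for cls, band in out["background"].items():
            assert band["lo"] <= band["mean"] <= band["hi"]

    def test_planted_asp_at_minus2(self):
        # codon 9 is GGC (Gly); codon 7 = GAC (Asp) sits at -2
        ctxs = [_ctx(9)] * 10
        prots = {"t": "MAAAPKKDEGLLLSSTTVVW"}
        out = tunnel_charge_profile(ctxs, prots, n_background=50, seed=0)
        idx = out["positions"].index(-2)
        assert out["fractions"]["negative"][idx] == 1.0

    def test_all_glycine_proteome_is_special(self):
        seq = "T" * 6 + "ATG" + "GGC" * 40 + "TAA" + "T" * 6
        ctx = extract_context("s", "t", 35, seq, 6, 6 + 3 * 42)
        out = tunnel_charge_profile([ctx], {"t": "M" + "G" * 40},
                                    n_background=20, seed=0)
        frac = out["fractions"]["special"]
        inner = frac[1:]  # position -30.. -1 excluding the -30 edge codon
        assert np.all(inner[~np.isnan(inner)] >= 0.96)


class TestNucleotidePfm:
    def test_all_ccg_at_p_site(self):
        seq = "T" * 6 + "ATG" + "CCG" * 20 + "TAA" + "T" * 6
        ctx = extract_context("s", "t", 10, seq, 6, 6 + 3 * 22)
        pfm = nucleotide_pfm([ctx])
        assert pfm.loc["C", "+0.0"] == 1.0
        assert pfm.loc["C", "+0.1"] == 1.0
        assert pfm.loc["G", "+0.2"] == 1.0

    def test_columns_sum_to_one(self):
        pfm = nucleotide_pfm([_ctx(10), _ctx(9)])
        sums = pfm.sum(axis=0).to_numpy()
        assert np.allclose(sums[sums > 0], 1.0)

    def test_split_by_p_site_amino_acid(self):
        out = nucleotide_pfm([_ctx(4), _ctx(10)], split_by_aa=True)
        assert set(out) == {"P", "L"}


class TestClassifyMechanism:
    def test_hierarchy_pro_beats_glu(self):
        ctx = _peptide_only_ctx({0: "P", 1: "E"})
        assert classify_mechanism(ctx) == "ProP"

    def test_lysine_pair_is_polyk(self):
        assert classify_mechanism(_peptide_only_ctx({-1: "K", 0: "K"})) == "polyK"
        assert classify_mechanism(_peptide_only_ctx({-2: "K", -1: "K"})) == "polyK"

    def test_negative_at_minus2(self):
        assert classify_mechanism(_peptide_only_ctx({-2: "E"})) == "NegMinus2"

    def test_truncated_window_unexplained(self):
        ctx = _peptide_only_ctx({0: "P"})
        del ctx.peptide[-2]
        assert classify_mechanism(ctx) == "unexplained"

    def test_planted_categories_recovered_exactly(self, small_truth):
        rows, expected = [], []
        for s in small_truth.sites:
            org, idx = next(iter(s.codon_index.items()))
            rows.append({
                "css_id": s.site_id,
                "transcript_id": small_truth.transcripts[s.gene_id][org].transcript_id,
                "codon_index": idx,
            })
            expected.append("unexplained" if s.category == "none" else s.category)
        ctxs = contexts_from_truth(small_truth, pd.DataFrame(rows))
        got = [classify_mechanism(c) for c in ctxs]
        assert got == expected

    def test_attribution_partition(self, small_truth):
        rows = []
        for s in small_truth.sites:
            org, idx = next(iter(s.codon_index.items()))
            rows.append({
                "css_id": s.site_id,
                "transcript_id": small_truth.transcripts[s.gene_id][org].transcript_id,
                "codon_index": idx,
            })
        ctxs = contexts_from_truth(small_truth, pd.DataFrame(rows))
        bd = mechanism_breakdown(ctxs)
        assert set(bd["category"]) == set(MECHANISM_CATEGORIES)
        assert bd["count"].sum() == len(ctxs)
        assert bd["fraction"].sum() == pytest.approx(1.0)
        unexplained = bd.set_index("category").loc["unexplained", "fraction"]
        explained = bd[bd["category"] != "unexplained"]["fraction"].sum()
        assert explained == pytest.approx(1.0 - unexplained)


class TestArrestPeptides:
    def test_self_control_not_significant(self):
        windows = ["MAAAPKKDEGLLLSSTTVVW" * 2] * 20
        table, p = arrest_peptide_frequencies(windows, windows)
        assert p == pytest.approx(1.0)
        assert table["site_frequency"].sum() == pytest.approx(1.0)
        assert table["control_frequency"].sum() == pytest.approx(1.0)

    def test_planted_trp_excess_detected(self, rng):
        aas = "ACDEFGHIKLMNPQRSTVY"  # background without W
        controls = [
            "".join(rng.choice(list(aas), size=40)) for _ in range(100)
        ]
        sites = [
            "W" * 10 + "".join(rng.choice(list(aas), size=30))
            for _ in range(100)
        ]
        _, p = arrest_peptide_frequencies(sites, controls)
        assert p < 0.05

    def test_empty_windows_error(self):
        with pytest.raises(ValueError):
            arrest_peptide_frequencies([], ["MA"])
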