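"""Structure, positional and termination analyses around stall sites."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from stallsites.contextfeatures import (
    abort_ratio,
    abort_summary,
    disorder_meta,
    domain_distance,
    exon_position_stats,
    fold_stub,
    fragment_length_metaplot,
    mfe_sliding,
    structure_metaplot,
    tm_position_distribution,
)

HAIRPIN = "G" * 20 + "AAAAA" + "C" * 20  # 45 nt, perfect 20-bp stem


class TestFolding:
    def test_polya_has_no_structure(self):
        assert fold_stub("A" * 51) == 0.0

    def test_perfect_hairpin_scores_its_stem(self):
        assert fold_stub(HAIRPIN + "AAAAAA") <= -20.0

    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError):
            fold_stub("ACGTX" * 11)

    def test_track_length(self):
        seq = "T" * 10 + "ATG" + "ACGGCA" * 40 + "TAA" + "T" * 10
        cds_len = 3 + 240 + 3
        track = mfe_sliding(seq, 10, 10 + cds_len)
        assert len(track.values) == cds_len - 51 + 1

    def test_cds_shorter_than_window_errors(self):
        with pytest.raises(ValueError):
            mfe_sliding("A" * 100, 30, 60)


def _structured_cohort(rng, n_tx=6, n_codons=120, plant_hairpin=False,
                       site_codon=55):
    """Random-codon transcripts with one site each; optionally a hairpin
    planted 31 nt downstream of the site."""
    seqs, tracks, rows = {}, {}, []
    for t in range(n_tx):
        codons = ["".join(rng.choice(list("ACGT"), size=3))
                  for _ in range(n_codons)]
        cds = "ATG" + "".join(codons)[: 3 * (n_codons - 2)] + "TAA"
        if plant_hairpin:
            at = 3 * site_codon + 31
            cds = cds[:at] + HAIRPIN + cds[at + len(HAIRPIN):]
        seq = "T" * 20 + cds + "T" * 20
        tx = f"t{t}"
        seqs[tx] = seq
        tracks[tx] = mfe_sliding(seq, 20, 20 + len(cds), transcript_id=tx)
        rows.append({"css_id": f"s{t}", "transcript_id": tx,
                     "codon_index": site_codon})
    return pd.DataFrame(rows), tracks, seqs


class TestStructureMetaplot:
    def test_null_sites_stay_inside_background_band(self, rng):
        # adjacent offsets share most of their 51-nt window, so the curve
        # has few independent points; a wide (1st-99th percentile) band and
        # long CDSs (wide control support) make the pointwise check sound
        css, tracks, seqs = _structured_cohort(rng, n_tx=16, n_codons=300,
                                               site_codon=150)
        out = structure_metaplot(css, tracks, seqs, n_random=200, n_perm=0,
                                 seed=5, percentiles=(1.0, 99.0))
        inside = (
            (out["css"] >= out["control_lo"])
            & (out["css"] <= out["control_hi"])
        )
        assert inside.mean() >= 0.8

    def test_planted_downstream_hairpin_dips_below_control(self, rng):
        css, tracks, seqs = _structured_cohort(rng, plant_hairpin=True)
        out = structure_metaplot(css, tracks, seqs, n_random=100, n_perm=0,
                                 seed=5)
        downstream = out["offsets"] >= 30
        assert (out["css"][downstream].min()
                < out["control_lo"][downstream].min())

    def test_permuting_identical_codons_changes_nothing(self):
        n_codons = 120
        cds = "ATG" + "ACG" * (n_codons - 2) + "TAA"
        seq = "T" * 20 + cds + "T" * 20
        track = mfe_sliding(seq, 20, 20 + len(cds), transcript_id="t")
        css = pd.DataFrame(
            [{"css_id": "s", "transcript_id": "t", "codon_index": 55}]
        )
        out = structure_metaplot(css, {"t": track}, {"t": seq},
                                 n_random=20, n_perm=3, seed=0)
        assert np.allclose(out["permutation"], out["css"])

    def test_no_eligible_site_errors(self, rng):
        css, tracks, seqs = _structured_cohort(rng, n_tx=1)
        css["codon_index"] = 5  # too close to the start codon
        with pytest.raises(ValueError):
            structure_metaplot(css, tracks, seqs, n_random=10, n_perm=0)


def _single_exon_setup(n_codons=100, exon_splits=()):
    cds_len = 3 * n_codons
    ann = pd.DataFrame(
        [{"transcript_id": "t", "gene_id": "g", "transcript_length": cds_len,
          "cds_start": 0, "cds_end": cds_len}]
    )
    bounds = [0, *exon_splits, cds_len]
    exons = pd.DataFrame(
        [
            {"transcript_id": "t", "exon_index": i, "start": bounds[i],
             "end": bounds[i + 1]}
            for i in range(len(bounds) - 1)
        ]
    )
    return ann, exons


class TestExonPositions:
    def test_midpoint_relative_position(self):
        ann, exons = _single_exon_setup(100)
        css = pd.DataFrame([{"transcript_id": "t", "codon_index": 50}])
        out = exon_position_stats(css, exons, ann)
        assert out.iloc[0]["relative_position"] == pytest.approx(0.5)

    def test_single_exon_distances(self):
        ann, exons = _single_exon_setup(100)
        css = pd.DataFrame([{"transcript_id": "t", "codon_index": 40}])
        out = exon_position_stats(css, exons, ann)
        assert out.iloc[0]["dist_upstream"] == 120
        assert out.iloc[0]["dist_downstream"] == 300 - 120 - 3

    def test_excluded_zones_dropped(self):
        ann, exons = _single_exon_setup(100)
        css = pd.DataFrame(
            [{"transcript_id": "t", "codon_index": c} for c in (5, 99)]
        )
        assert exon_position_stats(css, exons, ann).empty

    def test_uniform_placement_is_flat(self, rng):
        # sample only the two interior exons so the CDS-edge exclusion
        # zones cannot skew the relative-position distribution
        ann, exons = _single_exon_setup(400, exon_splits=(300, 600, 900))
        codons = rng.integers(100, 300, size=600)
        css = pd.DataFrame(
            [{"transcript_id": "t", "codon_index": int(c)} for c in codons]
        )
        out = exon_position_stats(css, exons, ann)
        hist, _ = np.histogram(out["relative_position"], bins=5,
                               range=(0, 1))
        assert stats.chisquare(hist).pvalue > 0.05


class TestDomainDistance:
    _domains = pd.DataFrame(
        [{"transcript_id": "t", "domain_index": 0, "start_aa": 10,
          "end_aa": 60}]
    )

    def test_distance_after_domain_end(self):
        css = pd.DataFrame([{"transcript_id": "t", "codon_index": 70}])
        out = domain_distance(css, self._domains, protein_lengths={"t": 200})
        assert out.iloc[0]["distance"] == 10

    def test_site_before_any_domain_excluded_but_counted(self):
        css = pd.DataFrame([{"transcript_id": "t", "codon_index": 5}])
        out = domain_distance(css, self._domains, protein_lengths={"t": 200})
        assert len(out) == 1
        assert np.isnan(out.iloc[0]["distance"])

    def test_planted_offset_is_point_mass(self):
        css = pd.DataFrame(
            [{"transcript_id": "t", "codon_index": 90}] * 10
        )
        out = domain_distance(css, self._domains, protein_lengths={"t": 200})
        assert (out["distance"] == 30).all()


class TestDisorderMeta:
    def _scores(self, values):
        return pd.DataFrame(
            [{"transcript_id": "t", "residue_index": i, "score": v}
             for i, v in enumerate(values)]
        )

    def test_constant_scores_degenerate_no_difference(self):
        scores = self._scores([0.6] * 120)
        css = pd.DataFrame([{"transcript_id": "t", "codon_index": 60}])
        out = disorder_meta(css, scores, n_random=20, seed=0)
        assert out["css_coil_fraction"] == 1.0
        assert out["control_coil_fraction"] == 1.0
        assert out["t_test_p"] == 1.0

    def test_sites_planted_at_score_peaks_detected(self, rng):
        values = np.clip(rng.normal(0.3, 0.05, size=200), 0, 1)
        peak_positions = [40, 90, 140]
        for p in peak_positions:
            values[p] = 0.95
        scores = self._scores(values)
        css = pd.DataFrame(
            [{"transcript_id": "t", "codon_index": p} for p in peak_positions]
        )
        out = disorder_meta(css, scores, n_random=100, seed=1)
        assert out["css_mean"] > out["control_mean"]
        assert out["t_test_p"] < 0.05

    def test_random_placement_no_difference(self, rng):
        values = np.clip(rng.normal(0.5, 0.1, size=400), 0, 1)
        scores = self._scores(values)
        css = pd.DataFrame(
            [{"transcript_id": "t", "codon_index": int(c)}
             for c in rng.integers(20, 380, size=10)]
        )
        out = disorder_meta(css, scores, n_random=50, seed=2)
        assert abs(out["css_mean"] - out["control_mean"]) < 0.1
        assert out["t_test_p"] > 0.05


class TestTmPositions:
    def test_no_tm_sites_is_empty_not_error(self):
        css = pd.DataFrame([{"transcript_id": "t", "codon_index": 50}])
        tm = pd.DataFrame(
            [{"transcript_id": "u", "tm_type": "II", "anchor_aa": 10}]
        )
        out = tm_position_distribution(css, tm)
        assert len(out["offsets"]) == 0
        assert np.isnan(out["uniformity_p"])

    def test_planted_offset_mode(self):
        tm = pd.DataFrame(
            [{"transcript_id": f"t{i}", "tm_type": "II", "anchor_aa": 20}
             for i in range(30)]
        )
        css = pd.DataFrame(
            [{"transcript_id": f"t{i}", "codon_index": 72} for i in range(30)]
        )
        out = tm_position_distribution(css, tm)
        vals, counts = np.unique(out["offsets"], return_counts=True)
        assert vals[counts.argmax()] == 52
        assert out["uniformity_p"] < 0.05

    def test_uniform_placement_not_significant(self, rng):
        tm = pd.DataFrame(
            [{"transcript_id": f"t{i}", "tm_type": "I", "anchor_aa": 0}
             for i in range(200)]
        )
        css = pd.DataFrame(
            [{"transcript_id": f"t{i}", "codon_index": int(c)}
             for i, c in enumerate(rng.integers(0, 100, size=200))]
        )
        out = tm_position_distribution(css, tm)
        assert out["uniformity_p"] > 0.05


class TestAbortRatio:
    def test_flat_coverage_ratio_zero(self):
        counts = np.full(100, 6)
        out = abort_ratio("s", 50, counts)
        assert out.eligible
        assert out.log2_ratio == pytest.approx(0.0)

    def test_eightfold_drop_is_three(self):
        counts = np.concatenate([np.full(50, 80), np.full(50, 10)])
        out = abort_ratio("s", 49, counts)
        assert out.log2_ratio == pytest.approx(3.0, abs=1e-6)

    def test_antisymmetry_under_flank_swap(self, rng):
        counts = rng.integers(1, 50, size=120)
        fwd = abort_ratio("s", 60, counts)
        rev = abort_ratio("s", len(counts) - 1 - 60, counts[::-1].copy())
        assert fwd.log2_ratio == pytest.approx(-rev.log2_ratio)

    def test_zero_downstream_is_infinite_and_aborted(self):
        counts = np.concatenate([np.full(60, 10), np.zeros(60)])
        out = abort_ratio("s", 59, counts)
        assert np.isinf(out.log2_ratio)
        summary = abort_summary([out])
        assert summary["n_aborted"] == 1

    def test_ineligible_near_edges(self):
        out = abort_ratio("s", 10, np.ones(100))
        assert not out.eligible

    def test_symmetric_coverage_rarely_aborts(self, rng):
        stats_list = []
        for i in range(200):
            counts = rng.poisson(10, size=120)
            stats_list.append(abort_ratio(f"s{i}", 60, counts))
        summary = abort_summary(stats_list)
        assert summary["fraction_aborted"] <= 0.02


class TestFragmentLengthMetaplot:
    def test_single_length_gives_flat_curve(self):
        cov = {"t": {28: np.ones(100)}}
        out = fragment_length_metaplot(cov, [("t", 50)])
        assert len(out) == 31
        assert np.allclose(out["mean_length"], 28.0)

    def test_longer_fragments_at_stop_anchors_only(self):
        base = np.ones(200)
        long_track = np.zeros(200)
        long_track[100] = 50  # long footprints pile up at the stop
        cov = {"t": {28: base, 33: long_track}}
        at_stop = fragment_length_metaplot(cov, [("t", 100)])
        away = fragment_length_metaplot(cov, [("t", 50)])
        mid = 15
        assert at_stop["mean_length"][mid] > away["mean_length"][mid]
        assert away["mean_length"][mid] == pytest.approx(28.0)

    def test_no_anchors_errors(self):
        with pytest.raises(ValueError):
            fragment_length_metaplot({}, [])
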