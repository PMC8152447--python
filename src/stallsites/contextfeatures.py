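"""Structural, positional and termination context of conserved stall sites.

Covers: sliding-window mRNA minimum free energy around stall sites with a
random-position control and a codon-permutation control; distances to exon
and protein-domain boundaries; disorder-score meta-profiles; transmembrane
anchor positioning; the premature-termination (upstream/downstream
coverage) ratio; and fragment-length metaplots around anchors.

Folding backends: ``nussinov`` is a built-in base-pair maximisation stub
(score -1 per pair, NOT thermodynamic — suitable for relative comparisons
and tests only); ``rnafold`` shells out to ViennaRNA's RNAfold when it is
on PATH and returns true thermodynamic MFEs in kcal/mol.
"""

from __future__ import annotations

import shutil
import subprocess
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy import stats

MFE_WINDOW = 51


# --- folding backends -----------------------------------------------------

_PAIR_OK = np.zeros((4, 4), dtype=np.int8)
for _a, _b in (("A", "T"), ("G", "C"), ("G", "T")):
    _i, _j = "ACGT".index(_a), "ACGT".index(_b)
    _PAIR_OK[_i, _j] = _PAIR_OK[_j, _i] = 1


def _encode(seq: str) -> np.ndarray:
    seq = seq.upper().replace("U", "T")
    if set(seq) - set("ACGT"):
        raise ValueError("sequence contains non-ACGU/T characters")
    return np.array([("ACGT").index(c) for c in seq], dtype=np.int8)


@njit(cache=False)
def _nussinov_pairs(code: np.ndarray, pair_ok: np.ndarray, min_loop: int) -> int:
    n = len(code)
    dp = np.zeros((n, n), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(n - span):
            j = i + span
            best = dp[i + 1, j]
            if dp[i, j - 1] > best:
                best = dp[i, j - 1]
            if pair_ok[code[i], code[j]] and dp[i + 1, j - 1] + 1 > best:
                best = dp[i + 1, j - 1] + 1
            for k in range(i + 1, j):
                v = dp[i, k] + dp[k + 1, j]
                if v > best:
                    best = v
            dp[i, j] = best
    return dp[0, n - 1]


def fold_stub(seq: str, min_loop: int = 3) -> float:
    """Non-thermodynamic MFE stand-in: -1 per base pair under Nussinov
    base-pair maximisation (AU, GC, GU wobble; hairpin loop >= 3)."""
    code = _encode(seq)
    if len(code) <= min_loop + 1:
        return 0.0
    return -float(_nussinov_pairs(code, _PAIR_OK, min_loop))


def fold_rnafold(seq: str) -> float:
    """Thermodynamic MFE in kcal/mol via the RNAfold executable."""
    exe = shutil.which("RNAfold")
    if exe is None:
        raise RuntimeError("RNAfold not found on PATH")
    proc = subprocess.run(
        [exe, "--noPS"], input=seq + "\n", capture_output=True, text=True,
        check=True,
    )
    last = proc.stdout.strip().splitlines()[-1]
    return float(last[last.rindex("(") + 1 : last.rindex(")")])


_BACKENDS = {"nussinov": fold_stub, "rnafold": fold_rnafold}


@dataclass
class MfeTrack:
    transcript_id: str
    window_size: int
    values: np.ndarray  # one value per window start within the CDS
    cds_start: int
    cds_end: int
    backend: str

    def centered(self, cds_nt_pos: int) -> float:
        """MFE of the window centered on a CDS nucleotide position."""
        start = cds_nt_pos - self.window_size // 2
        if not 0 <= start < len(self.values):
            raise IndexError("window not fully inside the CDS")
        return float(self.values[start])


def mfe_sliding(
    sequence: str,
    cds_start: int,
    cds_end: int,
    window: int = MFE_WINDOW,
    backend: str = "nussinov",
    transcript_id: str = "",
) -> MfeTrack:
    """Sliding-window MFE over the CDS; one value per window start."""
    cds = sequence[cds_start:cds_end]
    if len(cds) < window:
        raise ValueError("CDS shorter than the folding window")
    fold = _BACKENDS[backend]
    values = np.array(
        [fold(cds[i : i + window]) for i in range(len(cds) - window + 1)]
    )
    return MfeTrack(
        transcript_id=transcript_id, window_size=window, values=values,
        cds_start=cds_start, cds_end=cds_end, backend=backend,
    )


def structure_metaplot(
    css_sites: pd.DataFrame,
    tracks: Mapping[str, MfeTrack],
    sequences: Mapping[str, str],
    n_random: int = 10000,
    n_perm: int = 100,
    seed: int = 0,
    upstream_nt: int = 30,
    downstream_nt: int = 60,
    backend: str = "nussinov",
    percentiles: tuple[float, float] = (5.0, 95.0),
) -> dict:
    """Mean MFE curve around stall sites vs two controls.

    Only sites more than ``upstream_nt`` nt downstream of the start codon
    and ``downstream_nt`` nt upstream of the stop codon are eligible. The
    random control re-anchors each site at a random eligible CDS position
    outside the site's own window, ``n_random`` times, reading the
    precomputed track; the permutation control keeps the stall codon fixed,
    permutes the codons at -30..-1 and +1..+60 (codon units), refolds and
    averages over ``n_perm`` permutations.
    """
    rng = np.random.default_rng(seed)
    fold = _BACKENDS[backend]
    half = MFE_WINDOW // 2
    offsets = np.arange(-upstream_nt, downstream_nt + 1)

    eligible = []
    for _, row in css_sites.iterrows():
        track = tracks[row["transcript_id"]]
        pos = 3 * int(row["codon_index"])  # CDS nt of the codon's first nt
        cds_len = track.cds_end - track.cds_start
        if (
            pos > upstream_nt
            and cds_len - pos > downstream_nt
            and pos - upstream_nt - half >= 0
            and pos + downstream_nt + half < cds_len
        ):
            eligible.append((row["transcript_id"], pos))
    if not eligible:
        raise ValueError("no eligible stall site for the structure metaplot")

    def curve_at(tx: str, pos: int) -> np.ndarray:
        track = tracks[tx]
        starts = pos + offsets - half
        return track.values[starts]

    css_curve = np.mean([curve_at(tx, pos) for tx, pos in eligible], axis=0)

    rep_curves = np.empty((n_random, len(offsets)))
    lo_needed = upstream_nt + half
    for r in range(n_random):
        acc = np.zeros(len(offsets))
        for tx, pos in eligible:
            track = tracks[tx]
            cds_len = track.cds_end - track.cds_start
            hi = cds_len - downstream_nt - half
            while True:
                cand = int(rng.integers(lo_needed, hi))
                if abs(cand - pos) > upstream_nt + downstream_nt:
                    break
            acc += curve_at(tx, cand)
        rep_curves[r] = acc / len(eligible)
    control_curve = rep_curves.mean(axis=0)
    band_lo = np.percentile(rep_curves, percentiles[0], axis=0)
    band_hi = np.percentile(rep_curves, percentiles[1], axis=0)

    perm_curve = None
    if n_perm > 0:
        up_codons, down_codons = upstream_nt // 3, downstream_nt // 3
        acc = np.zeros(len(offsets))
        for tx, pos in eligible:
            track = tracks[tx]
            cds = sequences[tx][track.cds_start : track.cds_end]
            c0 = pos // 3
            window_codons = [
                cds[3 * i : 3 * i + 3]
                for i in range(c0 - up_codons, c0 + down_codons + 1)
            ]
            stall_at = up_codons  # index of the fixed stall codon
            flank_pad = half  # context needed to fold edge windows
            left = cds[3 * (c0 - up_codons) - flank_pad : 3 * (c0 - up_codons)]
            right = cds[
                3 * (c0 + down_codons + 1) : 3 * (c0 + down_codons + 1) + flank_pad
            ]
            site_acc = np.zeros(len(offsets))
            for _ in range(n_perm):
                others = [
                    c for i, c in enumerate(window_codons) if i != stall_at
                ]
                perm = [others[i] for i in rng.permutation(len(others))]
                rebuilt = perm[:stall_at] + [window_codons[stall_at]] + perm[stall_at:]
                region = left + "".join(rebuilt) + right
                for j, off in enumerate(offsets):
                    w0 = len(left) + upstream_nt + off - half
                    site_acc[j] += fold(region[w0 : w0 + MFE_WINDOW])
            acc += site_acc / n_perm
        perm_curve = acc / len(eligible)

    return {
        "offsets": offsets,
        "css": css_curve,
        "control": control_curve,
        "control_lo": band_lo,
        "control_hi": band_hi,
        "permutation": perm_curve,
        "n_sites": len(eligible),
    }


# --- exon / domain / disorder / TM positioning ---------------------------

def exon_position_stats(
    css_sites: pd.DataFrame,
    exons: pd.DataFrame,
    annotation: pd.DataFrame,
    exclude_head_nt: int = 45,
    exclude_tail_nt: int = 3,
) -> pd.DataFrame:
    """Distances to exon boundaries and relative position within the exon.

    Sites within the first ``exclude_head_nt`` or last ``exclude_tail_nt``
    nucleotides of the CDS are dropped (mirroring the codon trims used by
    peak calling). Relative position is (pos - exon_start) / exon_length.
    """
    cds = annotation.set_index("transcript_id")[["cds_start", "cds_end"]]
    ex_by_tx = {tx: sub.sort_values("start") for tx, sub in exons.groupby("transcript_id")}
    rows = []
    for _, row in css_sites.iterrows():
        tx = row["transcript_id"]
        start, end = cds.loc[tx]
        pos = int(start) + 3 * int(row["codon_index"])
        if pos < start + exclude_head_nt or pos >= end - exclude_tail_nt:
            continue
        sub = ex_by_tx.get(tx)
        if sub is None:
            raise ValueError(f"no exon annotation for {tx}")
        hit = sub[(sub["start"] <= pos) & (pos < sub["end"])]
        if hit.empty:
            raise ValueError(f"stall site not inside any exon of {tx}")
        ex = hit.iloc[0]
        length = int(ex["end"] - ex["start"])
        rows.append(
            {
                "css_id": row.get("css_id", ""),
                "transcript_id": tx,
                "dist_upstream": pos - int(ex["start"]),
                "dist_downstream": int(ex["end"]) - pos - exclude_tail_nt,
                "relative_position": (pos - int(ex["start"])) / length,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["css_id", "transcript_id", "dist_upstream",
                 "dist_downstream", "relative_position"],
    )


def domain_distance(
    css_sites: pd.DataFrame,
    domains: pd.DataFrame,
    seed: int = 0,
    protein_lengths: Optional[Mapping[str, int]] = None,
) -> pd.DataFrame:
    """Minimum distance (aa) from each stall site to the closest upstream
    C-terminal domain boundary, with a paired random same-gene control.

    Sites with no domain ending upstream are excluded but counted
    (excluded rows carry NaN distances).
    """
    rng = np.random.default_rng(seed)
    dom_by_tx = {
        tx: np.sort(sub["end_aa"].to_numpy())
        for tx, sub in domains.groupby("transcript_id")
    }
    rows = []
    for _, row in css_sites.iterrows():
        tx = row["transcript_id"]
        aa_pos = int(row["codon_index"])
        ends = dom_by_tx.get(tx, np.array([]))
        upstream = ends[ends <= aa_pos]
        if len(upstream) == 0:
            rows.append({"css_id": row.get("css_id", ""), "transcript_id": tx,
                         "distance": np.nan, "control_distance": np.nan})
            continue
        dist = aa_pos - int(upstream[-1])
        n_aa = (
            protein_lengths[tx]
            if protein_lengths is not None
            else int(ends[-1]) + 50
        )
        ctl_pos = int(rng.integers(0, n_aa))
        ctl_up = ends[ends <= ctl_pos]
        ctl = ctl_pos - int(ctl_up[-1]) if len(ctl_up) else np.nan
        rows.append({"css_id": row.get("css_id", ""), "transcript_id": tx,
                     "distance": dist, "control_distance": ctl})
    return pd.DataFrame(rows)


def disorder_meta(
    css_sites: pd.DataFrame,
    disorder: pd.DataFrame,
    threshold: float = 0.516,
    n_random: int = 100,
    seed: int = 0,
    halfwidth: int = 10,
    exclude_head: int = 15,
    exclude_tail: int = 2,
) -> dict:
    """Disorder meta-curve around stall sites, coil fraction at the default
    threshold, and a two-sample t-test vs random same-protein positions.

    Controls exclude the first ``exclude_head`` residues, the last
    ``exclude_tail`` and the stall-site residues themselves; ``n_random``
    repetitions per protein.
    """
    rng = np.random.default_rng(seed)
    scores = {
        tx: sub.sort_values("residue_index")["score"].to_numpy()
        for tx, sub in disorder.groupby("transcript_id")
    }
    offsets = np.arange(-halfwidth, halfwidth + 1)
    curve_sum = np.zeros(len(offsets))
    curve_n = np.zeros(len(offsets))
    css_scores, ctl_scores = [], []
    css_by_tx: dict[str, list[int]] = {}
    for _, row in css_sites.iterrows():
        css_by_tx.setdefault(row["transcript_id"], []).append(
            int(row["codon_index"])
        )
    for tx, positions in css_by_tx.items():
        s = scores.get(tx)
        if s is None:
            raise ValueError(f"no disorder scores for {tx}")
        n = len(s)
        banned = set(positions)
        allowed = [
            i
            for i in range(exclude_head, n - exclude_tail)
            if i not in banned
        ]
        for pos in positions:
            if not 0 <= pos < n:
                raise ValueError("score vector length mismatch")
            css_scores.append(s[pos])
            for j, off in enumerate(offsets):
                i = pos + off
                if 0 <= i < n:
                    curve_sum[j] += s[i]
                    curve_n[j] += 1
        if allowed:
            draws = rng.choice(allowed, size=n_random * len(positions))
            ctl_scores.extend(s[draws])
    css_scores = np.array(css_scores)
    ctl_scores = np.array(ctl_scores)
    if ctl_scores.std() < 1e-12 and css_scores.std() < 1e-12:
        t_p = 1.0  # degenerate: constant scores, no difference by definition
    else:
        t_p = float(stats.ttest_ind(css_scores, ctl_scores).pvalue)
    return {
        "offsets": offsets,
        "curve": np.where(curve_n > 0, curve_sum / np.maximum(curve_n, 1), np.nan),
        "css_coil_fraction": float((css_scores > threshold).mean()),
        "control_coil_fraction": float((ctl_scores > threshold).mean())
        if len(ctl_scores)
        else np.nan,
        "t_test_p": t_p,
        "css_mean": float(css_scores.mean()),
        "control_mean": float(ctl_scores.mean()) if len(ctl_scores) else np.nan,
    }


def tm_position_distribution(
    css_sites: pd.DataFrame,
    tm_table: pd.DataFrame,
    n_bins: int = 10,
) -> dict:
    """Offsets of stall sites downstream of TM/signal anchors plus a
    chi-square uniformity test over position bins. Empty input (no stall
    site on a TM protein) yields an empty result, not an error."""
    anchors = tm_table.set_index("transcript_id")
    offsets = []
    types = []
    for _, row in css_sites.iterrows():
        tx = row["transcript_id"]
        if tx not in anchors.index:
            continue
        anchor = int(anchors.loc[tx, "anchor_aa"])
        off = int(row["codon_index"]) - anchor
        if off >= 0:
            offsets.append(off)
            types.append(str(anchors.loc[tx, "tm_type"]))
    offsets = np.array(offsets)
    if len(offsets) == 0:
        return {"offsets": offsets, "tm_types": [], "uniformity_p": np.nan}
    hist, _ = np.histogram(offsets, bins=n_bins)
    if len(offsets) >= n_bins:
        p = float(stats.chisquare(hist).pvalue)
    else:
        p = np.nan
    return {"offsets": offsets, "tm_types": types, "uniformity_p": p}


# --- premature termination ------------------------------------------------

@dataclass
class TerminationStats:
    css_id: str
    upstream_mean: float
    downstream_mean: float
    log2_ratio: float
    eligible: bool


def abort_ratio(
    css_id: str,
    codon_index: int,
    counts: np.ndarray,
    flank_codons: int = 15,
    exclude_head: int = 15,
    exclude_tail: int = 2,
) -> TerminationStats:
    """log2 of mean coverage over the 15 codons upstream vs downstream of a
    stall site; eligibility requires both flanks inside the gene body
    (excluding the first 15 and last 2 codons). Zero downstream coverage
    reports +inf (counted as aborted, i.e. ratio > 2)."""
    n = len(counts)
    lo = codon_index - flank_codons
    hi = codon_index + flank_codons
    eligible = lo >= exclude_head and hi < n - exclude_tail
    if not eligible:
        return TerminationStats(css_id, np.nan, np.nan, np.nan, False)
    up = float(np.mean(counts[lo:codon_index]))
    down = float(np.mean(counts[codon_index + 1 : hi + 1]))
    if down == 0.0:
        ratio = np.inf if up > 0 else 0.0
    elif up == 0.0:
        ratio = -np.inf
    else:
        ratio = float(np.log2(up / down))
    return TerminationStats(css_id, up, down, ratio, True)


def abort_summary(stats_list: Sequence[TerminationStats]) -> dict:
    ratios = np.array([s.log2_ratio for s in stats_list if s.eligible])
    return {
        "n_eligible": int(len(ratios)),
        "n_aborted": int((ratios > 2).sum()),
        "fraction_aborted": float((ratios > 2).mean()) if len(ratios) else np.nan,
    }


def fragment_length_metaplot(
    per_length_coverage: Mapping[str, Mapping[int, np.ndarray]],
    anchors: Sequence[tuple[str, int]],
    halfwidth: int = 15,
) -> pd.DataFrame:
    """Position-wise count-weighted mean footprint length around anchors
    (transcript nt coordinates); one row per offset in -15..+15."""
    if not anchors:
        raise ValueError("no anchors")
    offs = np.arange(-halfwidth, halfwidth + 1)
    weighted = np.zeros(len(offs))
    total = np.zeros(len(offs))
    for tx, pos in anchors:
        tracks = per_length_coverage.get(tx, {})
        for length, cov in tracks.items():
            for j, off in enumerate(offs):
                i = pos + off
                if 0 <= i < len(cov) and cov[i] > 0:
                    weighted[j] += length * cov[i]
                    total[j] += cov[i]
    mean_len = np.where(total > 0, weighted / np.maximum(total, 1), np.nan)
    return pd.DataFrame(
        {"offset": offs, "mean_length": mean_len, "n_reads": total}
    )
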