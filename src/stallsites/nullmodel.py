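"""Chance-conservation null model and associated statistical tests.

The core quantity is the probability that at least one of k random stall
peaks in a homolog lands inside the m-codon window matching a peak in
another homolog (the peak codon plus adjacent codons), on a gene of n
codons:

    p = 1 - C(n-m, k) / C(n, k)

computed with exact integer binomial coefficients. At the catalogue's scale
(n=500 codons, k=3 peaks per gene, m=3 matching codons) this gives
p = 0.018; for j organisms the chance probability is p^(j-1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class NullModelParams:
    n: int = 500  # codons per gene (median gene length)
    k: int = 3    # peaks per gene
    m: int = 3    # codons matching a peak (peak codon +- 1)

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.n and 0 <= self.k <= self.n):
            raise ValueError("need 0 <= m <= n and 0 <= k <= n")


def match_probability(params: NullModelParams) -> float:
    """P(at least one of k peaks falls in a fixed m-codon window).

    Exact integer binomials, one final division; C(a, b) = 0 for b > a.
    """
    n, k, m = params.n, params.k, params.m
    total = math.comb(n, k)
    if total == 0:
        return 0.0
    avoid = math.comb(n - m, k) if k <= n - m else 0
    return (total - avoid) / total


def multi_organism_probability(p: float, j: int) -> float:
    """Chance probability across j organisms: p^(j-1)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be a probability")
    if j < 2:
        raise ValueError("need at least 2 organisms")
    return p ** (j - 1)


def expected_random_overlaps(p: float, n_genes: int) -> float:
    """Expected chance matches over ``n_genes`` compared homolog pairs.

    The literal per-gene probability times gene count.
    """
    if n_genes < 0:
        raise ValueError("n_genes must be non-negative")
    return p * n_genes


def monte_carlo_match_probability(
    params: NullModelParams,
    n_genes: int,
    seed: int,
    batch: int = 200_000,
) -> float:
    """Monte-Carlo estimate of :func:`match_probability`.

    Per simulated gene, one anchor peak is placed in homolog A such that its
    m-codon window (the peak and its adjacent codons) lies inside the gene,
    and k distinct random peaks are placed in homolog B; the gene counts as
    matched when any B peak falls within the window, i.e. within one codon
    of the anchor.
    """
    n, k, m = params.n, params.k, params.m
    rng = np.random.default_rng(seed)
    matched = 0
    done = 0
    while done < n_genes:
        b = min(batch, n_genes - done)
        starts = rng.integers(0, n - m + 1, size=b)
        peaks = _distinct_uniform(rng, n, k, b)
        hit = ((peaks >= starts[:, None]) & (peaks < (starts + m)[:, None])).any(
            axis=1
        )
        matched += int(hit.sum())
        done += b
    return matched / n_genes


def _distinct_uniform(
    rng: np.random.Generator, n: int, k: int, rows: int
) -> np.ndarray:
    """``rows`` draws of k distinct codon indices from range(n)."""
    out = rng.integers(0, n, size=(rows, k))
    while True:
        sorted_rows = np.sort(out, axis=1)
        bad = (np.diff(sorted_rows, axis=1) == 0).any(axis=1)
        if not bad.any():
            return out
        out[bad] = rng.integers(0, n, size=(int(bad.sum()), k))


def conservation_binomial_test(
    observed: int, trials: int, p0: float = 0.018
) -> float:
    """One-tailed exact binomial p-value P(X >= observed | trials, p0)."""
    if not 0 <= observed <= trials:
        raise ValueError("need 0 <= observed <= trials")
    return float(
        stats.binomtest(observed, trials, p0, alternative="greater").pvalue
    )


# --- motif resampling null ------------------------------------------------

_IUPAC = {
    "N": set("ACGT"), "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "U": {"T"}, "R": set("AG"), "Y": set("CT"), "S": set("CG"),
    "W": set("AT"), "K": set("GT"), "M": set("AC"),
}


def parse_codon_motif(motif: str) -> list[set[str]]:
    """Parse a 3-position codon pattern like ``[CGA][CGA]N``."""
    classes: list[set[str]] = []
    i = 0
    while i < len(motif):
        if motif[i] == "[":
            j = motif.index("]", i)
            classes.append(set(motif[i + 1 : j].upper()))
            i = j + 1
        else:
            ch = motif[i].upper()
            if ch not in _IUPAC:
                raise ValueError(f"unknown motif symbol {ch!r}")
            classes.append(set(_IUPAC[ch]))
            i += 1
    if len(classes) != 3:
        raise ValueError("motif must cover exactly 3 nucleotide positions")
    return classes


def _codon_matches(codon: str, classes: list[set[str]]) -> bool:
    return len(codon) == 3 and all(c in cl for c, cl in zip(codon, classes))


def motif_resampling_test(
    site_codons: Sequence[str],
    gene_codon_pools: Sequence[Sequence[str]],
    motif: str,
    n_resample: int = 1000,
    codons_per_site: int = 11,
    seed: int = 0,
) -> tuple[int, float, float]:
    """Observed vs resampled motif matches at stall-site P-site codons.

    For each site, ``codons_per_site`` codons are drawn from the site's gene
    per resampling round; the per-round match count is rescaled to the
    per-site scale and averaged into the expectation. Pearson chi-square
    with 1 df on (observed, n-observed) against the expectation.

    Returns (observed, expected_mean, p_value).
    """
    classes = parse_codon_motif(motif)
    n_sites = len(site_codons)
    if n_sites == 0:
        raise ValueError("no sites")
    observed = sum(_codon_matches(c, classes) for c in site_codons)
    rng = np.random.default_rng(seed)
    per_round = np.empty(n_resample)
    match_flags = []
    for pool in gene_codon_pools:
        if len(pool) < codons_per_site:
            raise ValueError("gene shorter than the resampling need")
        match_flags.append(
            np.array([_codon_matches(c, classes) for c in pool], dtype=float)
        )
    for r in range(n_resample):
        total = 0.0
        for flags in match_flags:
            idx = rng.integers(0, len(flags), size=codons_per_site)
            total += flags[idx].sum()
        per_round[r] = total / codons_per_site
    expected = float(per_round.mean())
    if abs(expected - observed) < 1e-12:
        return observed, expected, 1.0
    exp_pair = np.array([expected, n_sites - expected], dtype=float)
    obs_pair = np.array([observed, n_sites - observed], dtype=float)
    exp_pair = np.clip(exp_pair, 1e-9, None)
    chi2 = float(((obs_pair - exp_pair) ** 2 / exp_pair).sum())
    return observed, expected, float(stats.chi2.sf(chi2, df=1))


# --- SNP overlap ----------------------------------------------------------

def snp_overlap(
    css_sites: pd.DataFrame,
    snp_table: pd.DataFrame,
    gene_codon_counts: Mapping[str, int],
    cds_starts: Mapping[str, int],
    p_snp: float = 0.009,
    seed: int = 0,
) -> tuple[int, int, float]:
    """SNP overlap at conserved stall sites vs random same-gene codons.

    ``css_sites`` needs transcript_id and codon_index; SNP positions are in
    transcript coordinates. A site overlaps when any of its codon's three
    nucleotides carries a SNP. The control draws one random codon on the
    same gene per site. Expected = 1 - (1 - p_snp)^3 per site (three
    Bernoulli positions per codon).
    """
    rng = np.random.default_rng(seed)
    snp_pos: dict[str, set[int]] = {}
    for tx, sub in snp_table.groupby("transcript_id"):
        snp_pos[tx] = set(int(p) for p in sub["pos"])
    observed = control = 0
    for _, row in css_sites.iterrows():
        tx = row["transcript_id"]
        start = cds_starts[tx]
        hits = snp_pos.get(tx, set())
        codon_nt = start + 3 * int(row["codon_index"])
        if any(codon_nt + i in hits for i in range(3)):
            observed += 1
        rand_codon = int(rng.integers(0, gene_codon_counts[tx]))
        rand_nt = start + 3 * rand_codon
        if any(rand_nt + i in hits for i in range(3)):
            control += 1
    expected = len(css_sites) * (1.0 - (1.0 - p_snp) ** 3)
    return observed, control, expected


# --- matched control sets -------------------------------------------------

@dataclass
class ControlSet:
    indices: np.ndarray
    p_value: float
    flagged: bool  # True when the matching tolerance was not reached


def match_control_set(
    pool_values: np.ndarray,
    reference_values: np.ndarray,
    size: int,
    seed: int = 0,
    p_threshold: float = 0.5,
    max_iter: int = 200,
) -> ControlSet:
    """Sample a control subset matched in distribution to a reference.

    Stratified sampling by deciles of the reference distribution, repeated
    until a two-sample Mann-Whitney U test between control and reference
    values gives p >= ``p_threshold``. If that cannot be achieved within
    ``max_iter`` attempts the best attempt is returned flagged.
    """
    pool_values = np.asarray(pool_values, dtype=float)
    reference_values = np.asarray(reference_values, dtype=float)
    if len(pool_values) <= size:
        raise ValueError("pool must be larger than the requested size")
    rng = np.random.default_rng(seed)
    edges = np.quantile(reference_values, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf
    strata = [
        np.nonzero((pool_values >= lo) & (pool_values < hi))[0]
        for lo, hi in zip(edges[:-1], edges[1:])
    ]
    per_stratum = _allocate(size, strata)
    best: Optional[ControlSet] = None
    for _ in range(max_iter):
        chosen = []
        for idx, want in zip(strata, per_stratum):
            if want == 0:
                continue
            take = min(want, len(idx))
            if take:
                chosen.append(rng.choice(idx, size=take, replace=False))
        idx = np.concatenate(chosen) if chosen else np.array([], dtype=int)
        if len(idx) < 2:
            p = 0.0
        else:
            p = float(
                stats.mannwhitneyu(
                    pool_values[idx], reference_values, alternative="two-sided"
                ).pvalue
            )
        candidate = ControlSet(indices=idx, p_value=p, flagged=p < p_threshold)
        if best is None or candidate.p_value > best.p_value:
            best = candidate
        if not candidate.flagged:
            return candidate
    assert best is not None
    return best


def _allocate(size: int, strata: Sequence[np.ndarray]) -> list[int]:
    """Spread ``size`` draws over deciles, proportional to reference mass."""
    base = size // len(strata)
    alloc = [base] * len(strata)
    for i in range(size - base * len(strata)):
        alloc[i % len(strata)] += 1
    # shift demand away from empty strata
    for i, idx in enumerate(strata):
        if len(idx) < alloc[i]:
            deficit = alloc[i] - len(idx)
            alloc[i] = len(idx)
            for j in range(len(strata)):
                if len(strata[j]) > alloc[j]:
                    move = min(deficit, len(strata[j]) - alloc[j])
                    alloc[j] += move
                    deficit -= move
                    if deficit == 0:
                        break
    return alloc


def translational_efficiency(
    ribo_fpkm: Mapping[str, float], rna_fpkm: Mapping[str, float]
) -> dict[str, float]:
    """TE = FPKM(ribo) / FPKM(rna) per transcript (inputs, not a pipeline)."""
    return {
        tx: ribo_fpkm[tx] / rna_fpkm[tx]
        for tx in ribo_fpkm
        if tx in rna_fpkm and rna_fpkm[tx] > 0
    }
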