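"""Sequence context of conserved stall sites.

Positions follow the ribosome convention: 0 is the P-site (the stalled
codon), +1 the A-site, -1 the E-site, and increasingly negative positions
run down the exit tunnel toward the N-terminus of the nascent peptide.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from scipy import stats

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
POSITIVE_AA = set("KRH")  # H is pH-dependent; configurable at call sites
NEGATIVE_AA = set("DE")
SPECIAL_AA = set("PG")

MECHANISM_CATEGORIES = (
    "ProP", "GlyP", "AspP", "GluA", "polyK", "NegMinus2", "unexplained"
)

PEPTIDE_HALFWIDTH = 10
TUNNEL_WIDTH = 30
NT_CODON_HALFWIDTH = 5


@dataclass
class SiteContext:
    """Amino-acid and nucleotide windows around one stall site."""

    css_id: str
    transcript_id: str
    codon_index: int
    peptide: dict[int, str] = field(default_factory=dict)   # -10..+10
    tunnel: dict[int, str] = field(default_factory=dict)    # -30..-1
    codons: dict[int, str] = field(default_factory=dict)    # -5..+5
    truncated: set[int] = field(default_factory=set)

    @property
    def p_site_aa(self) -> Optional[str]:
        return self.peptide.get(0)


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def extract_context(
    css_id: str,
    transcript_id: str,
    codon_index: int,
    sequence: str,
    cds_start: int,
    cds_end: int,
) -> SiteContext:
    """Translated windows around a stall site; truncation at CDS edges is
    flagged per position, windows never cross CDS boundaries."""
    n_codons = (cds_end - cds_start) // 3
    if not 0 <= codon_index < n_codons:
        raise ValueError("stall site outside the CDS")
    ctx = SiteContext(css_id=css_id, transcript_id=transcript_id,
                      codon_index=codon_index)
    lo = -max(PEPTIDE_HALFWIDTH, TUNNEL_WIDTH)
    for off in range(lo, PEPTIDE_HALFWIDTH + 1):
        i = codon_index + off
        if not 0 <= i < n_codons:
            ctx.truncated.add(off)
            continue
        codon = sequence[cds_start + 3 * i : cds_start + 3 * i + 3]
        aa = translate_codon(codon)
        if -PEPTIDE_HALFWIDTH <= off <= PEPTIDE_HALFWIDTH:
            ctx.peptide[off] = aa
        if -TUNNEL_WIDTH <= off <= -1:
            ctx.tunnel[off] = aa
        if -NT_CODON_HALFWIDTH <= off <= NT_CODON_HALFWIDTH:
            ctx.codons[off] = codon
    return ctx


def contexts_from_truth(truth, css_sites: pd.DataFrame) -> list[SiteContext]:
    """Convenience: build contexts for a CSS table against simulated
    transcripts (columns css_id, transcript_id, codon_index)."""
    out = []
    for _, row in css_sites.iterrows():
        tx = truth.transcript(row["transcript_id"])
        out.append(
            extract_context(
                str(row["css_id"]), tx.transcript_id, int(row["codon_index"]),
                tx.sequence, tx.cds_start, tx.cds_end,
            )
        )
    return out


# --- amino-acid / k-mer enrichment ---------------------------------------

def aa_frequency_matrix(
    contexts: Sequence[SiteContext],
) -> pd.DataFrame:
    """20 x 21 per-position amino-acid frequencies over non-truncated sites
    (positions -10..+10; columns sum to 1)."""
    if not contexts:
        raise ValueError("no contexts")
    positions = list(range(-PEPTIDE_HALFWIDTH, PEPTIDE_HALFWIDTH + 1))
    freq = pd.DataFrame(0.0, index=list(AMINO_ACIDS), columns=positions)
    for pos in positions:
        counts = Counter(
            ctx.peptide[pos]
            for ctx in contexts
            if pos in ctx.peptide and ctx.peptide[pos] in freq.index
        )
        total = sum(counts.values())
        if total:
            for aa, c in counts.items():
                freq.loc[aa, pos] = c / total
    return freq


def aa_enrichment_matrix(
    contexts: Sequence[SiteContext],
    background_contexts: Sequence[SiteContext],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(frequency, enrichment) matrices; enrichment = site frequency over
    background frequency, NaN where the background frequency is zero."""
    freq = aa_frequency_matrix(contexts)
    bg = aa_frequency_matrix(background_contexts)
    with np.errstate(divide="ignore", invalid="ignore"):
        enr = freq / bg.replace(0.0, np.nan)
    return freq, enr


def _peptide_string(ctx: SiteContext) -> tuple[str, int]:
    """Contiguous peptide over -10..+10 with the index of position 0."""
    chars = []
    zero_at = -1
    for off in range(-PEPTIDE_HALFWIDTH, PEPTIDE_HALFWIDTH + 1):
        if off in ctx.peptide:
            if off == 0:
                zero_at = len(chars)
            chars.append(ctx.peptide[off])
    return "".join(chars), zero_at


def kmer_enrichment(
    contexts: Sequence[SiteContext],
    k: int,
    background_contexts: Sequence[SiteContext],
) -> pd.DataFrame:
    """Ranked amino-acid k-mer (k in {2, 3}) enrichment over the peptide
    windows, sorted by descending enrichment then count."""
    if k not in (2, 3):
        raise ValueError("only 2-mers and 3-mers are supported")

    def count(ctxs: Sequence[SiteContext]) -> tuple[Counter, int]:
        c: Counter = Counter()
        total = 0
        for ctx in ctxs:
            pep, _ = _peptide_string(ctx)
            for i in range(len(pep) - k + 1):
                c[pep[i : i + k]] += 1
                total += 1
        return c, total

    obs, n_obs = count(contexts)
    bg, n_bg = count(background_contexts)
    rows = []
    for kmer, c in obs.items():
        f_obs = c / n_obs
        f_bg = bg.get(kmer, 0) / n_bg if n_bg else 0.0
        rows.append(
            {
                "kmer": kmer,
                "count": c,
                "frequency": f_obs,
                "background_frequency": f_bg,
                "enrichment": f_obs / f_bg if f_bg > 0 else np.inf,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["enrichment", "count"], ascending=False, kind="mergesort")
        .reset_index(drop=True)
    )


# --- exit-tunnel charge profile ------------------------------------------

def _charge_class(aa: str, positive: set[str]) -> str:
    if aa in positive:
        return "positive"
    if aa in NEGATIVE_AA:
        return "negative"
    if aa in SPECIAL_AA:
        return "special"
    return "other"


def tunnel_charge_profile(
    contexts: Sequence[SiteContext],
    proteins: Mapping[str, str],
    n_background: int = 10000,
    percentiles: tuple[float, float] = (5.0, 95.0),
    seed: int = 0,
    positive: set[str] = POSITIVE_AA,
) -> dict:
    """Per-position charge-class fractions over the exit tunnel (-30..-1,
    with the P-site at 0 reported alongside) plus a resampled background
    band.

    The background redraws, ``n_background`` times, one random residue per
    site's protein, averages the class fractions within each repetition,
    and reports the (5th, 95th) percentile band across repetitions.
    """
    positions = list(range(-TUNNEL_WIDTH, 1))
    classes = ("positive", "negative", "special", "other")
    frac = {cls: np.zeros(len(positions)) for cls in classes}
    denom = np.zeros(len(positions))
    for ctx in contexts:
        window = dict(ctx.tunnel)
        if 0 in ctx.peptide:
            window[0] = ctx.peptide[0]
        for j, pos in enumerate(positions):
            aa = window.get(pos)
            if aa is None:
                continue
            denom[j] += 1
            frac[_charge_class(aa, positive)][j] += 1
    with np.errstate(invalid="ignore"):
        profile = {
            cls: np.where(denom > 0, frac[cls] / denom, np.nan)
            for cls in classes
        }

    rng = np.random.default_rng(seed)
    prots = [proteins[ctx.transcript_id] for ctx in contexts]
    class_codes = []
    for p in prots:
        class_codes.append(
            np.array([classes.index(_charge_class(aa, positive)) for aa in p])
        )
    reps = {cls: np.empty(n_background) for cls in classes}
    for r in range(n_background):
        drawn = np.array(
            [codes[rng.integers(len(codes))] for codes in class_codes]
        )
        counts = np.bincount(drawn, minlength=4)
        for ci, cls in enumerate(classes):
            reps[cls][r] = counts[ci] / len(drawn)
    lo, hi = percentiles
    background = {
        cls: {
            "mean": float(reps[cls].mean()),
            "lo": float(np.percentile(reps[cls], lo)),
            "hi": float(np.percentile(reps[cls], hi)),
        }
        for cls in classes
    }
    return {"positions": positions, "fractions": profile,
            "background": background}


# --- nucleotide position frequency matrices ------------------------------

def nucleotide_pfm(
    contexts: Sequence[SiteContext],
    split_by_aa: bool = False,
) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """4 x 33 position frequency matrix over codons -5..+5 (columns sum to
    1 where data exist); optionally stratified by the P-site amino acid."""
    if split_by_aa:
        groups: dict[str, list[SiteContext]] = {}
        for ctx in contexts:
            aa = ctx.p_site_aa
            if aa:
                groups.setdefault(aa, []).append(ctx)
        return {aa: nucleotide_pfm(g) for aa, g in sorted(groups.items())}
    n_cols = 3 * (2 * NT_CODON_HALFWIDTH + 1)
    counts = np.zeros((4, n_cols))
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for ctx in contexts:
        for off, codon in ctx.codons.items():
            col0 = 3 * (off + NT_CODON_HALFWIDTH)
            for j, b in enumerate(codon):
                if b in base_idx:
                    counts[base_idx[b], col0 + j] += 1
    sums = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pfm = np.where(sums > 0, counts / sums, 0.0)
    cols = [
        f"{off:+d}.{j}"
        for off in range(-NT_CODON_HALFWIDTH, NT_CODON_HALFWIDTH + 1)
        for j in range(3)
    ]
    return pd.DataFrame(pfm, index=list("ACGT"), columns=cols)


def pfm_to_meme(pfm: pd.DataFrame, name: str = "css_pfm") -> str:
    """Serialise a PFM in MEME minimal motif format."""
    lines = [
        "MEME version 4", "", "ALPHABET= ACGT", "",
        "strands: +", "",
        "Background letter frequencies", "A 0.25 C 0.25 G 0.25 T 0.25", "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pfm.shape[1]}",
    ]
    for col in pfm.columns:
        lines.append(" ".join(f"{pfm.loc[b, col]:.6f}" for b in "ACGT"))
    return "\n".join(lines) + "\n"


# --- mechanistic attribution ----------------------------------------------

def classify_mechanism(ctx: SiteContext) -> str:
    """Hierarchical attribution of a stall site to a sequence mechanism.

    First matching rule wins: P-site Pro, P-site Gly, P-site Asp, A-site
    Glu, a lysine pair adjacent to the peak (positions -1..0 or -2..-1),
    then Asp/Glu at -2 (the first residue inside the exit tunnel); anything
    else is unexplained. Sites whose windows are truncated at the positions
    a rule needs are unexplained.
    """
    pep = ctx.peptide
    needed = (-2, -1, 0, 1)
    if any(off not in pep for off in needed):
        return "unexplained"
    if pep[0] == "P":
        return "ProP"
    if pep[0] == "G":
        return "GlyP"
    if pep[0] == "D":
        return "AspP"
    if pep[1] == "E":
        return "GluA"
    if (pep[-1] == "K" and pep[0] == "K") or (pep[-2] == "K" and pep[-1] == "K"):
        return "polyK"
    if pep[-2] in NEGATIVE_AA:
        return "NegMinus2"
    return "unexplained"


def mechanism_breakdown(contexts: Sequence[SiteContext]) -> pd.DataFrame:
    """Category counts and fractions; fractions sum to 1 and the explained
    fraction is 1 minus the unexplained fraction."""
    labels = [classify_mechanism(ctx) for ctx in contexts]
    counts = Counter(labels)
    total = len(labels)
    rows = [
        {
            "category": cat,
            "count": counts.get(cat, 0),
            "fraction": counts.get(cat, 0) / total if total else 0.0,
        }
        for cat in MECHANISM_CATEGORIES
    ]
    return pd.DataFrame(rows)


# --- arrest-peptide frequencies ------------------------------------------

def arrest_peptide_frequencies(
    site_windows: Sequence[str],
    control_windows: Sequence[str],
) -> tuple[pd.DataFrame, float]:
    """Amino-acid frequencies in upstream windows (default use: 40 aa) of
    stall sites vs controls, with a chi-square goodness-of-fit p-value of
    the site counts against the control distribution."""
    def freq(windows: Sequence[str]) -> tuple[np.ndarray, int]:
        c: Counter = Counter()
        for w in windows:
            c.update(ch for ch in w if ch in AMINO_ACIDS)
        total = sum(c.values())
        return (
            np.array([c.get(aa, 0) for aa in AMINO_ACIDS], dtype=float),
            total,
        )

    obs_counts, n_obs = freq(site_windows)
    ctl_counts, n_ctl = freq(control_windows)
    if n_obs == 0 or n_ctl == 0:
        raise ValueError("empty windows")
    expected = ctl_counts / n_ctl * n_obs
    keep = expected > 0
    chi2 = float(((obs_counts[keep] - expected[keep]) ** 2
                  / expected[keep]).sum())
    dof = int(keep.sum()) - 1
    p = float(stats.chi2.sf(chi2, df=max(dof, 1)))
    table = pd.DataFrame(
        {
            "aa": list(AMINO_ACIDS),
            "site_frequency": obs_counts / n_obs,
            "control_frequency": ctl_counts / n_ctl,
        }
    )
    return table, p
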