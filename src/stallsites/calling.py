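"""Per-library stall-peak calling from codon profiles.

A transcript qualifies when its median codon coverage is above zero. Codon
counts (with the first codon and the last two codons trimmed) are
standardised to z-scores, and codons with z strictly above the threshold
(default 5.0) are reported as stall peaks, excluding the first five codons
of the CDS where initiation pile-ups accumulate in some libraries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from stallsites.profiles import CodonProfile


@dataclass
class CallingParams:
    z_threshold: float = 5.0
    head_exclusion_codons: int = 5
    trim_start_codons: int = 1
    trim_end_codons: int = 2

    def __post_init__(self) -> None:
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if min(self.head_exclusion_codons, self.trim_start_codons,
               self.trim_end_codons) < 0:
            raise ValueError("exclusions must be non-negative")


@dataclass
class StallPeak:
    transcript_id: str
    organism: str
    library_id: str
    codon_index: int
    z_score: float
    raw_count: int
    p_site_nt: int


def is_well_expressed(profile: CodonProfile) -> bool:
    """Median codon coverage over the full CDS strictly above zero."""
    if profile.n_codons == 0:
        raise ValueError("empty profile")
    return float(np.median(profile.counts)) > 0.0


def zscore_profile(
    profile: CodonProfile, params: CallingParams = CallingParams()
) -> np.ndarray:
    """Per-codon z-scores over the trimmed codon set.

    The first ``trim_start_codons`` and last ``trim_end_codons`` codons
    (start codon, stop codon and the codon before it, by default) are
    excluded from both the mean/sd estimate and the returned scores (NaN
    there). Population (1/N) standard deviation. A zero sd yields all-NaN
    scores, i.e. no peaks, not an error.
    """
    counts = profile.counts.astype(float)
    z = np.full(profile.n_codons, np.nan)
    lo = params.trim_start_codons
    hi = profile.n_codons - params.trim_end_codons
    if hi - lo < 2:
        return z
    included = counts[lo:hi]
    sd = included.std()  # population form
    if sd == 0.0:
        return z
    z[lo:hi] = (included - included.mean()) / sd
    return z


def call_peaks(
    profile: CodonProfile,
    params: CallingParams = CallingParams(),
    library_id: str = "",
) -> list[StallPeak]:
    """Stall peaks: trimmed z-scores strictly above the threshold, with
    peaks inside the first ``head_exclusion_codons`` codons discarded."""
    if not is_well_expressed(profile):
        return []
    z = zscore_profile(profile, params)
    with np.errstate(invalid="ignore"):
        hits = np.nonzero(np.nan_to_num(z, nan=-np.inf) > params.z_threshold)[0]
    peaks = []
    for i in hits:
        i = int(i)
        if i < params.head_exclusion_codons:
            continue
        peak = StallPeak(
            transcript_id=profile.transcript_id,
            organism=profile.organism,
            library_id=library_id,
            codon_index=i,
            z_score=float(z[i]),
            raw_count=int(profile.counts[i]),
            p_site_nt=profile.cds_start + 3 * i,
        )
        _assert_peak_valid(peak, profile, params)
        peaks.append(peak)
    return peaks


def _assert_peak_valid(
    peak: StallPeak, profile: CodonProfile, params: CallingParams
) -> None:
    last = profile.n_codons - 1
    assert peak.z_score > params.z_threshold
    assert peak.codon_index >= params.head_exclusion_codons
    assert peak.codon_index not in (0, last - 1, last)


def call_peaks_table(
    profiles: dict[str, CodonProfile],
    params: CallingParams = CallingParams(),
    library_id: str = "",
    annotation: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Peak table over a library's transcripts (TSV-ready)."""
    gene_of = {}
    if annotation is not None:
        gene_of = dict(zip(annotation["transcript_id"], annotation["gene_id"]))
    rows = []
    for tx, profile in profiles.items():
        for p in call_peaks(profile, params, library_id):
            rows.append(
                {
                    "library_id": p.library_id,
                    "organism": p.organism,
                    "gene_id": gene_of.get(tx, ""),
                    "transcript_id": p.transcript_id,
                    "codon_index": p.codon_index,
                    "p_site_nt": p.p_site_nt,
                    "raw_count": p.raw_count,
                    "z_score": p.z_score,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "library_id", "organism", "gene_id", "transcript_id",
            "codon_index", "p_site_nt", "raw_count", "z_score",
        ],
    )
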