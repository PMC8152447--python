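"""P-site assignment, codon coverage and ribosome meta-profiles.

Footprint records (transcript, 5' position, length, count) are shifted by a
per-length P-site offset table to nucleotide coverage, binned into codons
over the CDS, and summarised as meta-profiles around CDS boundaries. All
coordinates are 0-based, half-open; codon index 0 is the start codon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import numpy as np
import pandas as pd

FOOTPRINT_COLUMNS = ["transcript_id", "five_prime_pos", "length", "count"]


@dataclass
class CodonProfile:
    """Per-codon P-site counts over one transcript's CDS."""

    transcript_id: str
    organism: str
    cds_start: int
    cds_end: int
    counts: np.ndarray
    nt_coverage: Optional[np.ndarray] = None
    per_length_coverage: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (self.cds_end - self.cds_start) % 3 != 0:
            raise ValueError("CDS length must be divisible by 3")
        if len(self.counts) != (self.cds_end - self.cds_start) // 3:
            raise ValueError("counts length does not match CDS span")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_codons(self) -> int:
        return len(self.counts)


def select_longest_transcript(annotation: pd.DataFrame) -> pd.DataFrame:
    """One transcript per gene: the longest, ties to the smallest id.

    ``annotation`` needs columns gene_id, transcript_id and transcript_length.
    """
    if annotation.empty:
        raise ValueError("empty annotation")
    ordered = annotation.sort_values(
        ["gene_id", "transcript_length", "transcript_id"],
        ascending=[True, False, True],
        kind="mergesort",
    )
    return ordered.groupby("gene_id", as_index=False).head(1).reset_index(drop=True)


def periodic_lengths(
    footprints: pd.DataFrame,
    annotation: pd.DataFrame,
    offsets: Mapping[int, int],
    frame_threshold: float = 0.5,
) -> list[int]:
    """Footprint lengths whose offset-shifted 5' ends are frame-0 periodic.

    A length is kept when, over CDS-internal positions, the modal frame of
    its P-site positions is frame 0 and the frame-0 fraction exceeds
    ``frame_threshold``. Acts as a quality gate on an externally supplied
    offset table.
    """
    if footprints.empty:
        raise ValueError("empty footprint table")
    ann = annotation.set_index("transcript_id")
    selected = []
    for length, sub in footprints.groupby("length"):
        if length not in offsets:
            continue
        psite = sub["five_prime_pos"].to_numpy() + offsets[length]
        tx_ids = sub["transcript_id"].to_numpy()
        starts = ann.loc[tx_ids, "cds_start"].to_numpy()
        ends = ann.loc[tx_ids, "cds_end"].to_numpy()
        in_cds = (psite >= starts) & (psite < ends)
        if not in_cds.any():
            continue
        frames = (psite[in_cds] - starts[in_cds]) % 3
        weights = sub["count"].to_numpy()[in_cds]
        frame_counts = np.bincount(frames, weights=weights, minlength=3)
        frac0 = frame_counts[0] / frame_counts.sum()
        if frac0 > frame_threshold and frame_counts.argmax() == 0:
            selected.append(int(length))
    if not selected:
        raise ValueError(
            "no footprint length passed the periodicity gate; "
            "inspect offsets and frame fractions"
        )
    return sorted(selected)


def psite_coverage(
    footprints: pd.DataFrame,
    offsets: Mapping[int, int],
    selected_lengths: Iterable[int],
    transcript_lengths: Mapping[str, int],
    keep_per_length: bool = False,
) -> tuple[dict[str, np.ndarray], dict[str, dict[int, np.ndarray]], int]:
    """Per-transcript nucleotide P-site coverage.

    Each record contributes ``count`` at ``five_prime_pos + offset[length]``;
    records of unselected lengths are dropped, and records whose P-site falls
    outside the transcript are skipped (their number is returned).
    """
    selected = set(int(l) for l in selected_lengths)
    coverage: dict[str, np.ndarray] = {
        tx: np.zeros(n, dtype=np.int64) for tx, n in transcript_lengths.items()
    }
    per_length: dict[str, dict[int, np.ndarray]] = {}
    n_skipped = 0
    sub = footprints[footprints["length"].isin(selected)]
    for (tx, length), grp in sub.groupby(["transcript_id", "length"]):
        if tx not in coverage:
            n_skipped += int(len(grp))
            continue
        psite = grp["five_prime_pos"].to_numpy() + offsets[int(length)]
        cnt = grp["count"].to_numpy()
        ok = (psite >= 0) & (psite < len(coverage[tx]))
        n_skipped += int((~ok).sum())
        np.add.at(coverage[tx], psite[ok], cnt[ok])
        if keep_per_length:
            track = per_length.setdefault(tx, {}).setdefault(
                int(length), np.zeros(len(coverage[tx]), dtype=np.int64)
            )
            np.add.at(track, psite[ok], cnt[ok])
    return coverage, per_length, n_skipped


def codon_coverage(
    nt_coverage: np.ndarray, cds_start: int, cds_end: int
) -> np.ndarray:
    """Sum nucleotide coverage into per-codon counts over the CDS."""
    if (cds_end - cds_start) % 3 != 0:
        raise ValueError("CDS length must be divisible by 3")
    cds = np.asarray(nt_coverage[cds_start:cds_end])
    return cds.reshape(-1, 3).sum(axis=1)


def build_codon_profiles(
    footprints: pd.DataFrame,
    offsets: Mapping[int, int],
    annotation: pd.DataFrame,
    selected_lengths: Optional[Iterable[int]] = None,
    keep_per_length: bool = False,
) -> dict[str, CodonProfile]:
    """Footprints -> :class:`CodonProfile` per transcript, end to end."""
    if selected_lengths is None:
        selected_lengths = periodic_lengths(footprints, annotation, offsets)
    tx_lengths = dict(
        zip(annotation["transcript_id"], annotation["transcript_length"])
    )
    coverage, per_length, _ = psite_coverage(
        footprints, offsets, selected_lengths, tx_lengths,
        keep_per_length=keep_per_length,
    )
    profiles = {}
    for _, row in annotation.iterrows():
        tx = row["transcript_id"]
        nt = coverage[tx]
        profiles[tx] = CodonProfile(
            transcript_id=tx,
            organism=row.get("organism", ""),
            cds_start=int(row["cds_start"]),
            cds_end=int(row["cds_end"]),
            counts=codon_coverage(nt, int(row["cds_start"]), int(row["cds_end"])),
            nt_coverage=nt,
            per_length_coverage=per_length.get(tx, {}),
        )
    return profiles


def metaprofile(
    coverage: Mapping[str, np.ndarray],
    annotation: pd.DataFrame,
    utr5_window: int = 30,
    cds_window: int = 60,
    utr3_window: int = 30,
) -> pd.DataFrame:
    """Summed coverage over (last 30 nt 5'UTR | first/last 60 nt CDS | first
    30 nt 3'UTR) across transcripts that carry all four features at the
    minimum lengths. Frame is annotated per position (-1 outside the CDS)."""
    segments = []
    n_used = 0
    for _, row in annotation.iterrows():
        tx = row["transcript_id"]
        if tx not in coverage:
            continue
        nt = coverage[tx]
        s, e = int(row["cds_start"]), int(row["cds_end"])
        if s < utr5_window or len(nt) - e < utr3_window or e - s < 2 * cds_window:
            continue
        seg = np.concatenate(
            [
                nt[s - utr5_window : s],
                nt[s : s + cds_window],
                nt[e - cds_window : e],
                nt[e : e + utr3_window],
            ]
        )
        segments.append(seg)
        n_used += 1
    if n_used == 0:
        raise ValueError("no transcript qualifies for the metaprofile")
    total = np.sum(segments, axis=0)
    pos = np.arange(len(total))
    region = (
        ["utr5"] * utr5_window
        + ["cds_start"] * cds_window
        + ["cds_end"] * cds_window
        + ["utr3"] * utr3_window
    )
    frame = np.full(len(total), -1)
    frame[utr5_window : utr5_window + cds_window] = (
        np.arange(cds_window) % 3
    )
    # frame of the last cds_window nt depends on CDS length; with CDS length
    # divisible by 3 the last window ends on a codon boundary
    frame[utr5_window + cds_window : utr5_window + 2 * cds_window] = (
        np.arange(-cds_window, 0) % 3
    )
    return pd.DataFrame(
        {"position": pos, "region": region, "frame": frame, "coverage": total,
         "n_transcripts": n_used}
    )
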