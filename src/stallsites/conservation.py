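"""Cross-species stall-peak matching through nucleotide alignments.

Homologous transcripts are compared in alignment-column space: a stall peak
in one organism is conserved when a peak in another organism maps to the
same or an adjacent codon (within 3 columns, i.e. one codon, of the peak's
first nucleotide). Matching starts from the alignment of the maximal
organism set and falls back to smaller subsets so that a divergent member
cannot mask conservation among the others.
"""

from __future__ import annotations

import itertools
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
from Bio import Align

from stallsites.calling import StallPeak

GAP = "-"

# built-in aligner scores (config-exposed); adequate at low divergence
MATCH_SCORE = 2.0
MISMATCH_SCORE = -1.0
GAP_OPEN = -5.0
GAP_EXTEND = -1.0


@dataclass
class HomologGroup:
    group_id: str
    members: dict[str, str]  # organism -> transcript_id
    alignment: dict[str, str]  # organism -> aligned row

    def __post_init__(self) -> None:
        lengths = {len(row) for row in self.alignment.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows must have equal length")

    def validate_against(self, sequences: Mapping[str, str]) -> None:
        for org, row in self.alignment.items():
            if row.replace(GAP, "") != sequences[org]:
                raise ValueError(f"ungapped row for {org} != input sequence")


@dataclass
class ConservedStallSite:
    css_id: str
    group_id: str
    conservation_level: int
    members: list[tuple[str, str, int, int]]  # (org, transcript, codon, column)
    anchor_organism: str

    def __post_init__(self) -> None:
        orgs = {m[0] for m in self.members}
        assert self.conservation_level == len(orgs) >= 2


def _pairwise_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN
    aligner.extend_gap_score = GAP_EXTEND
    return aligner


def _pairwise_rows(a: str, b: str) -> tuple[str, str]:
    aln = _pairwise_aligner().align(a, b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    assert row_a.replace(GAP, "") == a and row_b.replace(GAP, "") == b
    assert len(row_a) == len(row_b)
    return row_a, row_b


def _identity(a: str, b: str) -> float:
    ra, rb = _pairwise_rows(a, b)
    same = sum(1 for x, y in zip(ra, rb) if x == y and x != GAP)
    return same / max(len(a), len(b))


def align_builtin(sequences: Mapping[str, str]) -> dict[str, str]:
    """Center-star progressive multiple alignment.

    The center is the sequence with the highest total pairwise identity;
    every other sequence is globally aligned to it and the pairwise
    alignments are merged on center coordinates (once a gap, always a gap).
    """
    orgs = list(sequences)
    if len(orgs) < 2:
        raise ValueError("need at least 2 sequences")
    for org, seq in sequences.items():
        if set(seq) - set("ACGTN"):
            raise ValueError(f"sequence for {org} contains non-ACGTN characters")
    if len(orgs) == 2:
        ra, rb = _pairwise_rows(sequences[orgs[0]], sequences[orgs[1]])
        return {orgs[0]: ra, orgs[1]: rb}

    ident = {org: 0.0 for org in orgs}
    for a, b in itertools.combinations(orgs, 2):
        i = _identity(sequences[a], sequences[b])
        ident[a] += i
        ident[b] += i
    center = max(orgs, key=lambda o: (ident[o], o))
    center_seq = sequences[center]

    pair_rows = {}
    for org in orgs:
        if org == center:
            continue
        rc, ro = _pairwise_rows(center_seq, sequences[org])
        pair_rows[org] = (rc, ro)

    # gaps inserted into the center, per center position (before position i)
    n_c = len(center_seq)
    gap_before = np.zeros(n_c + 1, dtype=int)
    per_org_layout = {}
    for org, (rc, ro) in pair_rows.items():
        runs = np.zeros(n_c + 1, dtype=int)
        ci = 0
        for ch in rc:
            if ch == GAP:
                runs[ci] += 1
            else:
                ci += 1
        per_org_layout[org] = runs
        gap_before = np.maximum(gap_before, runs)

    def merge(rc: str, ro: str, runs: np.ndarray) -> str:
        out = []
        ci = 0
        pending = []
        for ch_c, ch_o in zip(rc, ro):
            if ch_c == GAP:
                pending.append(ch_o)
            else:
                out.append(pending + [GAP] * (gap_before[ci] - len(pending)))
                out.append([ch_o])
                pending = []
                ci += 1
        out.append(pending + [GAP] * (gap_before[n_c] - len(pending)))
        return "".join(ch for block in out for ch in block)

    center_row = []
    for i in range(n_c):
        center_row.append(GAP * gap_before[i] + center_seq[i])
    center_row.append(GAP * gap_before[n_c])
    result = {center: "".join(center_row)}
    for org, (rc, ro) in pair_rows.items():
        result[org] = merge(rc, ro, per_org_layout[org])

    width = len(result[center])
    for org, row in result.items():
        assert len(row) == width, "center-star merge produced ragged rows"
        assert row.replace(GAP, "") == sequences[org]
    return result


def align_external(
    sequences: Mapping[str, str], tool: str = "mafft"
) -> dict[str, str]:
    """Round-trip through an external MSA tool (aligned-FASTA interface)."""
    exe = shutil.which(tool)
    if exe is None:
        raise RuntimeError(f"external aligner {tool!r} not found on PATH")
    with tempfile.TemporaryDirectory() as tmp:
        fin = Path(tmp) / "in.fa"
        with open(fin, "w") as fh:
            for org, seq in sequences.items():
                fh.write(f">{org}\n{seq}\n")
        proc = subprocess.run(
            [exe, "--quiet", "--retree", "2", str(fin)],
            capture_output=True, text=True, check=True,
        )
    out: dict[str, str] = {}
    name = None
    for line in proc.stdout.splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            out[name] = ""
        elif name is not None:
            out[name] += line.strip()
    return {org: out[org].upper() for org in sequences}


def align_group(
    sequences: Mapping[str, str], backend: str = "builtin"
) -> dict[str, str]:
    """Multiple-align a homolog group's transcript sequences."""
    if backend == "builtin":
        return align_builtin(sequences)
    if backend == "external":
        return align_external(sequences)
    raise ValueError(f"unknown alignment backend {backend!r}")


def pos_to_column(row: str, nt_pos: int) -> int:
    """Alignment column of the ``nt_pos``-th ungapped nucleotide of ``row``."""
    if nt_pos < 0:
        raise IndexError("position out of range")
    seen = -1
    for col, ch in enumerate(row):
        if ch != GAP:
            seen += 1
            if seen == nt_pos:
                return col
    raise IndexError("position out of range")


def column_to_pos(row: str, column: int) -> int:
    """Ungapped position at ``column``; the column must not be a gap."""
    if not 0 <= column < len(row):
        raise IndexError("column out of range")
    if row[column] == GAP:
        raise ValueError("column is a gap in this row")
    return sum(1 for ch in row[:column] if ch != GAP)


def _column_maps(row: str) -> np.ndarray:
    """Vectorised pos -> column lookup for one aligned row."""
    arr = np.frombuffer(row.encode(), dtype="S1")
    return np.nonzero(arr != GAP.encode())[0]


@dataclass
class _Candidate:
    columns: dict[tuple[str, int], int]  # (organism, peak index) -> column

    @property
    def organisms(self) -> set[str]:
        return {org for org, _ in self.columns}


def match_peaks_in_alignment(
    alignment: Mapping[str, str],
    peaks_by_organism: Mapping[str, Sequence[StallPeak]],
    tolerance_nt: int = 3,
) -> list[dict]:
    """Single-linkage clustering of peak alignment columns across organisms.

    A cluster becomes a candidate conserved site when its column diameter is
    at most ``tolerance_nt`` (gaps count: columns are the shared coordinate)
    and it spans at least two organisms. Each peak belongs to at most one
    cluster.
    """
    entries = []  # (column, organism, peak)
    for org, peaks in peaks_by_organism.items():
        if org not in alignment or not peaks:
            continue
        posmap = _column_maps(alignment[org])
        for peak in peaks:
            if peak.p_site_nt >= len(posmap):
                continue
            entries.append((int(posmap[peak.p_site_nt]), org, peak))
    entries.sort(key=lambda e: (e[0], e[1]))
    clusters: list[list[tuple[int, str, StallPeak]]] = []
    for entry in entries:
        if clusters and entry[0] - clusters[-1][-1][0] <= tolerance_nt:
            clusters[-1].append(entry)
        else:
            clusters.append([entry])
    out = []
    for cluster in clusters:
        cols = [e[0] for e in cluster]
        orgs = {e[1] for e in cluster}
        if max(cols) - min(cols) <= tolerance_nt and len(orgs) >= 2:
            out.append(
                {
                    "members": [(org, peak, col) for col, org, peak in cluster],
                    "organisms": orgs,
                }
            )
    return out


def iterative_conservation(
    sequences: Mapping[str, str],
    peaks_by_organism: Mapping[str, Sequence[StallPeak]],
    backend: str = "builtin",
    tolerance_nt: int = 3,
    group_id: str = "",
    aligner: Optional[Callable[[Mapping[str, str]], dict[str, str]]] = None,
    full_alignment: Optional[Mapping[str, str]] = None,
) -> list[ConservedStallSite]:
    """Match peaks starting from the full organism set, then all smaller
    subsets in decreasing size (lexicographic within a size); a peak settles
    at the first subset where it matches. Clusters sharing a peak merge with
    the union's organism count as conservation level.

    ``full_alignment`` short-circuits the aligner with a known alignment
    (e.g. the simulation ground truth); subset alignments are then derived
    by dropping rows and all-gap columns.
    """
    orgs = sorted(o for o in sequences if peaks_by_organism.get(o))
    if len(orgs) < 2:
        return []

    def align_subset(subset: tuple[str, ...]) -> Mapping[str, str]:
        if full_alignment is not None:
            rows = {o: full_alignment[o] for o in subset}
            return _drop_allgap_columns(rows)
        sub_seqs = {o: sequences[o] for o in subset}
        if aligner is not None:
            return aligner(sub_seqs)
        return align_group(sub_seqs, backend=backend)

    settled: set[tuple[str, int]] = set()  # (organism, codon_index)
    raw_clusters: list[list[tuple[str, StallPeak, int]]] = []

    sizes = range(len(orgs), 1, -1)
    for size in sizes:
        for subset in itertools.combinations(orgs, size):
            remaining = {
                o: [
                    p
                    for p in peaks_by_organism.get(o, [])
                    if (o, p.codon_index) not in settled
                ]
                for o in subset
            }
            if sum(1 for o in subset if remaining[o]) < 2:
                continue
            alignment = align_subset(subset)
            for cand in match_peaks_in_alignment(
                alignment, remaining, tolerance_nt
            ):
                raw_clusters.append(cand["members"])
                for org, peak, _ in cand["members"]:
                    settled.add((org, peak.codon_index))

    merged = _merge_shared(raw_clusters)
    css_list = []
    for i, members in enumerate(merged):
        orgs_in = sorted({m[0] for m in members})
        anchor = max(
            orgs_in, key=lambda o: (len(peaks_by_organism.get(o, [])), o)
        )
        css_list.append(
            ConservedStallSite(
                css_id=f"{group_id}_css{i}" if group_id else f"css{i}",
                group_id=group_id,
                conservation_level=len(orgs_in),
                members=[
                    (org, peak.transcript_id, peak.codon_index, col)
                    for org, peak, col in sorted(
                        members, key=lambda m: (m[0], m[1].codon_index)
                    )
                ],
                anchor_organism=anchor,
            )
        )
    css_list.sort(key=lambda c: min(m[3] for m in c.members))
    for j, css in enumerate(css_list):
        css.css_id = f"{group_id}_css{j}" if group_id else f"css{j}"
    return css_list


def _drop_allgap_columns(rows: Mapping[str, str]) -> dict[str, str]:
    mat = np.array([list(r) for r in rows.values()])
    keep = ~(mat == GAP).all(axis=0)
    return {
        org: "".join(np.array(list(row))[keep]) for org, row in rows.items()
    }


def _merge_shared(
    clusters: list[list[tuple[str, StallPeak, int]]]
) -> list[list[tuple[str, StallPeak, int]]]:
    """Merge clusters that share a peak (same organism + codon index)."""
    key = lambda m: (m[0], m[1].transcript_id, m[1].codon_index)
    merged: list[dict] = []
    for cluster in clusters:
        keys = {key(m) for m in cluster}
        hit = None
        for entry in merged:
            if entry["keys"] & keys:
                hit = entry
                break
        if hit is None:
            merged.append({"keys": keys, "members": list(cluster)})
        else:
            for m in cluster:
                if key(m) not in hit["keys"]:
                    hit["members"].append(m)
                    hit["keys"].add(key(m))
    return [entry["members"] for entry in merged]


def css_per_organism(css_list: Sequence[ConservedStallSite]) -> dict[str, int]:
    """Per-organism conserved-peak accounting: for each organism, the number
    of its peaks that belong to any conserved stall site."""
    counts: dict[str, int] = {}
    for css in css_list:
        for org, _, _, _ in css.members:
            counts[org] = counts.get(org, 0) + 1
    return counts
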