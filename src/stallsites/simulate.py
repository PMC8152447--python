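"""Synthetic homolog / ribosome-footprint generator with planted stall sites.

Emulates the statistical structure the downstream analyses assume: sets of
homologous CDSs across 2-5 pseudo-organisms related by point substitutions
and occasional whole-codon indels, planted stall sites with configurable
P-/A-site amino-acid context, and per-codon footprint counts drawn from an
overdispersed (negative-binomial) model with elevated dwell at stalls.

Ground truth (planted site positions, conservation groups, the true
nucleotide alignment) is retained so recovery can be scored exactly.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

STOP_CODONS = ("TAA", "TAG", "TGA")
_BASES = "ACGT"
SENSE_CODONS = tuple(
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in STOP_CODONS
)

# most frequent human codon per amino acid, used for context planting
_COMMON_CODON = {"P": "CCC", "G": "GGC", "D": "GAC", "E": "GAG", "K": "AAG"}
# neutral codons for sanitising the -2..+1 window before planting a context
# (Ala/Leu/Ser/Val: none of them triggers any attribution rule)
_NEUTRAL_CODONS = ("GCC", "CTG", "AGC", "GTG")

CONTEXT_CATEGORIES = ("ProP", "GlyP", "AspP", "GluA", "polyK", "NegMinus2", "none")

# planting edits must stay clear of substitution; codons -2..+1 around the
# P-site are exempt from point mutation, +-10 codons from indels
CONTEXT_EXEMPT_UP = 2
CONTEXT_EXEMPT_DOWN = 1
INDEL_EXCLUSION_CODONS = 10


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the scale at which the chance-conservation null model is
    parameterised: ~500-codon genes, up to 3 peaks per gene, and the
    mechanistic category mix used throughout the sequence analyses.
    """

    n_organisms: int = 3
    n_genes: int = 50
    cds_codons_mean: int = 500
    cds_codons_sd: int = 50
    utr5_nt: int = 50
    utr3_nt: int = 50
    substitution_rate: float = 0.02
    codon_indel_rate: float = 0.1
    planted_conserved_per_gene: int = 3
    planted_private_per_gene: int = 1
    dwell_factor: float = 20.0
    expression_mean: float = 10.0
    nb_dispersion: float = 10.0
    length_distribution: dict[int, float] = field(
        default_factory=lambda: {28: 0.5, 29: 0.3, 30: 0.2}
    )
    offset_table: dict[int, int] = field(
        default_factory=lambda: {28: 12, 29: 12, 30: 13}
    )
    context_probs: dict[str, float] = field(
        default_factory=lambda: {
            "ProP": 0.15,
            "GlyP": 0.12,
            "AspP": 0.17,
            "GluA": 0.10,
            "polyK": 0.02,
            "NegMinus2": 0.07,
            "none": 0.37,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if not 2 <= self.n_organisms <= 5:
            raise ValueError("n_organisms must be between 2 and 5")
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if not 0.0 <= self.substitution_rate <= 1.0:
            raise ValueError("substitution_rate must be a probability")
        if not 0.0 <= self.codon_indel_rate <= 1.0:
            raise ValueError("codon_indel_rate must be a probability")
        if self.dwell_factor < 1.0:
            raise ValueError("dwell_factor must be >= 1")
        if self.expression_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("expression_mean and nb_dispersion must be positive")
        for cat in self.context_probs:
            if cat not in CONTEXT_CATEGORIES:
                raise ValueError(f"unknown context category {cat!r}")
        total = sum(self.context_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("context_probs must sum to 1")
        if any(p < 0 for p in self.context_probs.values()):
            raise ValueError("context_probs must be non-negative")
        ld_total = sum(self.length_distribution.values())
        if abs(ld_total - 1.0) > 1e-9 or any(
            p < 0 for p in self.length_distribution.values()
        ):
            raise ValueError("length_distribution must be a probability map")
        for length, p in self.length_distribution.items():
            if p > 0 and length not in self.offset_table:
                raise ValueError(f"no P-site offset for footprint length {length}")
        n_sites = self.planted_conserved_per_gene + self.planted_private_per_gene
        min_codons = 2 * 15 + n_sites * 25
        if self.cds_codons_mean - 3 * self.cds_codons_sd < min_codons:
            raise ValueError(
                "cds too short to host planted sites after exclusion zones"
            )

    @property
    def organisms(self) -> list[str]:
        return [f"org{i + 1}" for i in range(self.n_organisms)]


@dataclass
class OrganismTranscript:
    organism: str
    transcript_id: str
    gene_id: str
    sequence: str
    cds_start: int
    cds_end: int
    exon_boundaries: list[int]
    aligned_row: str  # true alignment row over the full transcript


@dataclass
class PlantedSite:
    site_id: str
    gene_id: str
    category: str
    group_id: Optional[str]  # None for organism-private sites
    codon_index: dict[str, int]  # organism -> CDS codon index (P-site)

    @property
    def conserved(self) -> bool:
        return self.group_id is not None


@dataclass
class SimTruth:
    """Ground truth of a simulated cohort."""

    config: SimConfig
    transcripts: dict[str, dict[str, OrganismTranscript]]  # gene -> org -> tx
    sites: list[PlantedSite]
    ancestors: dict[str, str] = field(default_factory=dict)  # gene -> CDS

    def transcript(self, transcript_id: str) -> OrganismTranscript:
        for per_org in self.transcripts.values():
            for tx in per_org.values():
                if tx.transcript_id == transcript_id:
                    return tx
        raise KeyError(transcript_id)

    def annotation_table(self) -> pd.DataFrame:
        rows = []
        for gene_id, per_org in self.transcripts.items():
            for tx in per_org.values():
                rows.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "organism": tx.organism,
                        "gene_id": gene_id,
                        "transcript_length": len(tx.sequence),
                        "cds_start": tx.cds_start,
                        "cds_end": tx.cds_end,
                        "exon_boundaries": ";".join(
                            str(b) for b in tx.exon_boundaries
                        ),
                    }
                )
        return pd.DataFrame(rows)

    def truth_table(self) -> pd.DataFrame:
        rows = []
        for site in self.sites:
            for org, idx in site.codon_index.items():
                tx = self.transcripts[site.gene_id][org]
                rows.append(
                    {
                        "site_id": site.site_id,
                        "gene_id": site.gene_id,
                        "group_id": site.group_id or "",
                        "category": site.category,
                        "organism": org,
                        "transcript_id": tx.transcript_id,
                        "codon_index": idx,
                    }
                )
        return pd.DataFrame(rows)

    def true_alignment(self, gene_id: str) -> dict[str, str]:
        return {
            org: tx.aligned_row for org, tx in self.transcripts[gene_id].items()
        }


def _gene_rng(seed: int, gene_id: str, stream: int) -> np.random.Generator:
    """Per-gene substream: stable hash of the gene id spliced into the seed."""
    return np.random.default_rng(
        [seed & 0x7FFFFFFF, zlib.crc32(gene_id.encode()), stream]
    )


def _random_cds(rng: np.random.Generator, n_codons: int) -> list[str]:
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = STOP_CODONS[rng.integers(len(STOP_CODONS))]
    return ["ATG", *body.tolist(), stop]


def _plant_context(codons: list[str], p_site: int, category: str) -> None:
    """Edit the minimal codons to realise ``category`` unambiguously.

    The -2..+1 window is first set to neutral amino acids so a planted
    category never accidentally satisfies a higher-precedence attribution
    rule (e.g. a chance P-site proline on a 'GluA' site).
    """
    for k, off in enumerate(range(-CONTEXT_EXEMPT_UP, CONTEXT_EXEMPT_DOWN + 1)):
        codons[p_site + off] = _NEUTRAL_CODONS[k % len(_NEUTRAL_CODONS)]
    if category == "ProP":
        codons[p_site] = _COMMON_CODON["P"]
    elif category == "GlyP":
        codons[p_site] = _COMMON_CODON["G"]
    elif category == "AspP":
        codons[p_site] = _COMMON_CODON["D"]
    elif category == "GluA":
        codons[p_site + 1] = _COMMON_CODON["E"]
    elif category == "polyK":
        codons[p_site - 1] = _COMMON_CODON["K"]
        codons[p_site] = _COMMON_CODON["K"]
    elif category == "NegMinus2":
        codons[p_site - 2] = _COMMON_CODON["D"]
    elif category != "none":
        raise ValueError(f"unknown category {category!r}")


def _site_positions(
    rng: np.random.Generator, n_codons: int, n_sites: int, min_sep: int = 25
) -> list[int]:
    """Distinct planted P-site codon indices, away from CDS edges."""
    lo, hi = 15, n_codons - 18
    if hi <= lo:
        raise ValueError("cds too short to host planted sites after exclusion zones")
    for _ in range(1000):
        pos = np.sort(rng.choice(np.arange(lo, hi), size=n_sites, replace=False))
        if n_sites < 2 or np.min(np.diff(pos)) >= min_sep:
            return pos.tolist()
    raise ValueError("cds too short to host planted sites after exclusion zones")


def _substitute(
    rng: np.random.Generator,
    codons: list[str],
    rate: float,
    exempt_codons: set[int],
) -> list[str]:
    """Apply point substitutions at per-nt probability ``rate``.

    Substitution count is Binomial(#mutable nt, rate); positions are drawn
    without replacement with third codon positions preferred (weight 4:1),
    biasing toward synonymous changes while keeping the per-nt rate exact.
    Codon 0 (start), the stop codon and planted-context codons are exempt;
    a substitution is never allowed to create an in-frame stop.
    """
    if rate == 0.0:
        return list(codons)
    out = list(codons)
    mutable: list[int] = []
    weights: list[float] = []
    last = len(codons) - 1
    for ci in range(len(codons)):
        if ci == 0 or ci == last or ci in exempt_codons:
            continue
        for frame in range(3):
            mutable.append(3 * ci + frame)
            weights.append(4.0 if frame == 2 else 1.0)
    if not mutable:
        return out
    n_sub = rng.binomial(len(mutable), rate)
    if n_sub == 0:
        return out
    w = np.asarray(weights) / sum(weights)
    chosen = rng.choice(mutable, size=n_sub, replace=False, p=w)
    for pos in chosen:
        ci, frame = divmod(int(pos), 3)
        codon = out[ci]
        alts = [b for b in _BASES if b != codon[frame]]
        for alt in (alts[j] for j in rng.permutation(len(alts))):
            cand = codon[:frame] + alt + codon[frame + 1 :]
            if cand not in STOP_CODONS:
                out[ci] = cand
                break
    return out


def _mutate_utr(rng: np.random.Generator, utr: str, rate: float) -> str:
    if rate == 0.0 or not utr:
        return utr
    n_sub = rng.binomial(len(utr), rate)
    if n_sub == 0:
        return utr
    out = list(utr)
    for pos in rng.choice(len(utr), size=n_sub, replace=False):
        out[pos] = rng.choice([b for b in _BASES if b != out[pos]])
    return "".join(out)


def _exon_boundaries(rng: np.random.Generator, tx_len: int) -> list[int]:
    """Internal exon boundaries (transcript coords), exon lengths ~150 nt."""
    bounds = []
    pos = 0
    while True:
        step = max(30, int(rng.gamma(4.0, 37.5)))
        pos += step
        if pos >= tx_len - 30:
            break
        bounds.append(pos)
    return bounds


def simulate_homolog_sequences(config: SimConfig) -> SimTruth:
    """Generate homologous transcript sets with planted stall-site contexts.

    An ancestor CDS of random sense codons is drawn per gene; each organism
    is derived by synonymous-biased point substitutions and at most one
    whole-codon indel per gene (never within +-10 codons of a planted site,
    so planted signal and its alignment mapping survive). Planted contexts
    (codons -2..+1 of each P-site) are exempt from substitution, preserving
    conservation.
    """
    organisms = config.organisms
    transcripts: dict[str, dict[str, OrganismTranscript]] = {}
    sites: list[PlantedSite] = []
    ancestors: dict[str, str] = {}

    for g in range(config.n_genes):
        gene_id = f"g{g:04d}"
        rng = _gene_rng(config.seed, gene_id, stream=0)

        n_codons = int(
            np.clip(
                round(rng.normal(config.cds_codons_mean, config.cds_codons_sd)),
                2 * 15 + 25 * (config.planted_conserved_per_gene
                               + config.planted_private_per_gene) + 10,
                None,
            )
        )
        ancestor = _random_cds(rng, n_codons)

        # plant conserved sites on the ancestor (shared by every organism)
        n_cons = config.planted_conserved_per_gene
        n_priv = config.planted_private_per_gene
        positions = [int(p) for p in rng.permutation(
            _site_positions(rng, n_codons, n_cons + n_priv)
        )]
        cats = list(config.context_probs)
        probs = np.array([config.context_probs[c] for c in cats])

        cons_positions = sorted(positions[:n_cons])
        priv_positions = sorted(positions[n_cons : n_cons + n_priv])
        gene_sites: list[PlantedSite] = []
        for j, p_site in enumerate(cons_positions):
            cat = str(rng.choice(cats, p=probs))
            _plant_context(ancestor, p_site, cat)
            gene_sites.append(
                PlantedSite(
                    site_id=f"{gene_id}_c{j}",
                    gene_id=gene_id,
                    category=cat,
                    group_id=f"{gene_id}_grp{j}",
                    codon_index={org: p_site for org in organisms},
                )
            )
        # private sites: planted on the ancestor too (context identical in all
        # organisms) but footprint dwell is elevated in one organism only
        for j, p_site in enumerate(priv_positions):
            cat = str(rng.choice(cats, p=probs))
            _plant_context(ancestor, p_site, cat)
            org = organisms[int(rng.integers(len(organisms)))]
            gene_sites.append(
                PlantedSite(
                    site_id=f"{gene_id}_p{j}",
                    gene_id=gene_id,
                    category=cat,
                    group_id=None,
                    codon_index={org: p_site},
                )
            )

        all_planted = cons_positions + priv_positions
        sub_exempt = {
            p + off
            for p in all_planted
            for off in range(-CONTEXT_EXEMPT_UP, CONTEXT_EXEMPT_DOWN + 1)
        }
        indel_exempt = {
            p + off
            for p in all_planted
            for off in range(-INDEL_EXCLUSION_CODONS, INDEL_EXCLUSION_CODONS + 1)
        }

        utr5 = "".join(rng.choice(list(_BASES), size=config.utr5_nt))
        utr3 = "".join(rng.choice(list(_BASES), size=config.utr3_nt))

        per_org: dict[str, OrganismTranscript] = {}
        org_ops: dict[str, tuple[Optional[tuple[str, int, str]], list[str]]] = {}
        for org in organisms:
            org_rng = _gene_rng(config.seed, gene_id, stream=10 + organisms.index(org))
            # at most one whole-codon indel per gene (per-gene probability)
            indel: Optional[tuple[str, int, str]] = None
            if org_rng.random() < config.codon_indel_rate:
                allowed = [
                    i
                    for i in range(2, n_codons - 2)
                    if i not in indel_exempt
                ]
                if allowed:
                    pos = int(org_rng.choice(allowed))
                    if org_rng.random() < 0.5:
                        indel = ("del", pos, "")
                    else:
                        indel = ("ins", pos, str(org_rng.choice(SENSE_CODONS)))

            # apply indel to the codon list, tracking ancestor origin
            tagged: list[tuple[Optional[int], str]] = [
                (i, c) for i, c in enumerate(ancestor)
            ]
            if indel is not None:
                kind, pos, ins_codon = indel
                if kind == "del":
                    tagged = [t for t in tagged if t[0] != pos]
                else:
                    at = next(k for k, t in enumerate(tagged) if t[0] == pos)
                    tagged.insert(at, (None, ins_codon))

            # exempt set in this organism's own codon coordinates
            shift = {anc: k for k, (anc, _) in enumerate(tagged) if anc is not None}
            exempt_here = {shift[i] for i in sub_exempt if i in shift}
            codons_here = _substitute(
                org_rng, [c for _, c in tagged], config.substitution_rate, exempt_here
            )
            tagged = [(anc, c) for (anc, _), c in zip(tagged, codons_here)]
            org_ops[org] = (indel, codons_here)

            utr5_o = _mutate_utr(org_rng, utr5, config.substitution_rate)
            utr3_o = _mutate_utr(org_rng, utr3, config.substitution_rate)
            cds = "".join(codons_here)
            seq = utr5_o + cds + utr3_o
            tx_id = f"{org}_{gene_id}"
            exon_rng = _gene_rng(config.seed, gene_id, stream=30 + organisms.index(org))
            per_org[org] = OrganismTranscript(
                organism=org,
                transcript_id=tx_id,
                gene_id=gene_id,
                sequence=seq,
                cds_start=len(utr5_o),
                cds_end=len(utr5_o) + len(cds),
                exon_boundaries=_exon_boundaries(exon_rng, len(seq)),
                aligned_row="",  # filled below
            )

            # shift planted codon indices for this organism
            if indel is not None:
                kind, pos, _ = indel
                delta = -1 if kind == "del" else 1
                for site in gene_sites:
                    if org in site.codon_index and site.codon_index[org] > pos:
                        site.codon_index[org] += delta
                    elif (
                        org in site.codon_index
                        and kind == "ins"
                        and site.codon_index[org] == pos
                    ):
                        site.codon_index[org] += 1

        _build_true_alignment(per_org, org_ops, organisms, n_codons)
        transcripts[gene_id] = per_org
        sites.extend(gene_sites)
        ancestors[gene_id] = "".join(ancestor)

    return SimTruth(
        config=config, transcripts=transcripts, sites=sites, ancestors=ancestors
    )


def _build_true_alignment(
    per_org: dict[str, OrganismTranscript],
    org_ops: dict[str, tuple[Optional[tuple[str, int, str]], list[str]]],
    organisms: list[str],
    n_anc: int,
) -> None:
    """Reconstruct the true CDS alignment from the recorded edit operations."""
    # per organism: deletion position, insertions {ancestor_idx: codon}
    dels: dict[str, set[int]] = {org: set() for org in organisms}
    inss: dict[str, dict[int, str]] = {org: {} for org in organisms}
    for org in organisms:
        indel, _ = org_ops[org]
        if indel is None:
            continue
        kind, pos, ins_codon = indel
        if kind == "del":
            dels[org].add(pos)
        else:
            inss[org][pos] = ins_codon

    # organism codon content indexed by ancestor coordinate
    content: dict[str, dict[int, str]] = {}
    inserted: dict[str, dict[int, str]] = {org: {} for org in organisms}
    for org in organisms:
        indel, codons_here = org_ops[org]
        tagged: list[tuple[Optional[int], str]] = []
        anc = 0
        skip = dels[org]
        ins_at = inss[org]
        k = 0
        for anc_i in range(n_anc + 1):
            if anc_i in ins_at:
                tagged.append((None, codons_here[k]))
                inserted[org][anc_i] = codons_here[k]
                k += 1
            if anc_i < n_anc and anc_i not in skip:
                tagged.append((anc_i, codons_here[k]))
                k += 1
        content[org] = {anc_i: c for anc_i, c in tagged if anc_i is not None}

    rows = {org: [] for org in organisms}
    for anc_i in range(n_anc + 1):
        for org in organisms:
            if anc_i in inserted[org]:
                for o2 in organisms:
                    rows[o2].append(
                        inserted[org][anc_i] if o2 == org else "---"
                    )
        if anc_i < n_anc:
            for org in organisms:
                rows[org].append(content[org].get(anc_i, "---"))

    for org in organisms:
        tx = per_org[org]
        utr5 = tx.sequence[: tx.cds_start]
        utr3 = tx.sequence[tx.cds_end :]
        tx.aligned_row = utr5 + "".join(rows[org]) + utr3
        assert tx.aligned_row.replace("-", "") == tx.sequence


@dataclass
class SimulatedFootprints:
    """Footprint table plus the per-codon draws it was generated from."""

    table: pd.DataFrame  # transcript_id, five_prime_pos, length, count
    offsets: dict[int, int]
    true_codon_counts: dict[str, np.ndarray]
    stall_codons: dict[str, list[int]]


def simulate_footprints(truth: SimTruth, config: SimConfig) -> SimulatedFootprints:
    """Draw per-codon footprint counts and scatter them over read lengths.

    Per-codon counts are negative binomial with mean ``expression_mean``
    (times ``dwell_factor`` at planted stall codons) and size
    ``nb_dispersion``. Each codon's count is multinomially split over the
    footprint length distribution; a record's 5' position is the P-site
    nucleotide minus the length's offset, so re-applying the offset table
    recovers the codon exactly.
    """
    lengths = sorted(l for l, p in config.length_distribution.items() if p > 0)
    probs = np.array([config.length_distribution[l] for l in lengths])
    r = config.nb_dispersion

    rows_tx: list[str] = []
    rows_pos: list[np.ndarray] = []
    rows_len: list[np.ndarray] = []
    rows_cnt: list[np.ndarray] = []
    true_counts: dict[str, np.ndarray] = {}
    stall_codons: dict[str, list[int]] = {}

    organisms = truth.config.organisms
    for gene_id, per_org in truth.transcripts.items():
        gene_stalls: dict[str, list[int]] = {org: [] for org in organisms}
        for site in truth.sites:
            if site.gene_id != gene_id:
                continue
            for org, idx in site.codon_index.items():
                gene_stalls[org].append(idx)
        for org, tx in per_org.items():
            rng = _gene_rng(config.seed, gene_id, stream=50 + organisms.index(org))
            n_codons = (tx.cds_end - tx.cds_start) // 3
            mean = np.full(n_codons, config.expression_mean, dtype=float)
            for idx in gene_stalls[org]:
                mean[idx] *= config.dwell_factor
            counts = rng.negative_binomial(r, r / (r + mean))
            true_counts[tx.transcript_id] = counts
            stall_codons[tx.transcript_id] = sorted(gene_stalls[org])

            nz = np.nonzero(counts)[0]
            if nz.size == 0:
                continue
            split = rng.multinomial(counts[nz], probs)  # (n_nz, n_lengths)
            for li, length in enumerate(lengths):
                col = split[:, li]
                keep = col > 0
                if not keep.any():
                    continue
                codon_idx = nz[keep]
                p_site_nt = tx.cds_start + 3 * codon_idx
                five_prime = p_site_nt - config.offset_table[length]
                rows_tx.extend([tx.transcript_id] * int(keep.sum()))
                rows_pos.append(five_prime)
                rows_len.append(np.full(keep.sum(), length))
                rows_cnt.append(col[keep])

    if rows_pos:
        table = pd.DataFrame(
            {
                "transcript_id": rows_tx,
                "five_prime_pos": np.concatenate(rows_pos),
                "length": np.concatenate(rows_len),
                "count": np.concatenate(rows_cnt),
            }
        )
    else:
        table = pd.DataFrame(
            columns=["transcript_id", "five_prime_pos", "length", "count"]
        )
    return SimulatedFootprints(
        table=table,
        offsets=dict(config.offset_table),
        true_codon_counts=true_counts,
        stall_codons=stall_codons,
    )


def simulate_context_annotations(
    truth: SimTruth,
    config: SimConfig,
    snp_density: float = 0.009,
    domain_len: tuple[int, int] = (50, 120),
    n_domains: tuple[int, int] = (1, 3),
    tm_fraction: float = 0.2,
) -> dict[str, pd.DataFrame]:
    """Exon / domain / disorder / TM / SNP tables consistent with the cohort.

    Disorder scores are a logistic squash of boxcar-smoothed Gaussian noise
    (values in [0, 1]); SNP positions are uniform over the CDS at
    ``snp_density`` per nucleotide; domain intervals are non-overlapping in
    protein coordinates.
    """
    if not 0.0 <= snp_density <= 1.0:
        raise ValueError("snp_density must be a probability")
    exon_rows, dom_rows, dis_rows, tm_rows, snp_rows = [], [], [], [], []
    for gene_id, per_org in truth.transcripts.items():
        rng = _gene_rng(config.seed, gene_id, stream=90)
        for org, tx in per_org.items():
            bounds = [0, *tx.exon_boundaries, len(tx.sequence)]
            for i in range(len(bounds) - 1):
                exon_rows.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "exon_index": i,
                        "start": bounds[i],
                        "end": bounds[i + 1],
                    }
                )
            n_aa = (tx.cds_end - tx.cds_start) // 3 - 1  # minus stop
            if domain_len[0] > n_aa:
                raise ValueError("domain intervals requested longer than CDS")
            # non-overlapping domains laid out left to right
            k_dom = int(rng.integers(n_domains[0], n_domains[1] + 1))
            cursor = int(rng.integers(5, 30))
            for d in range(k_dom):
                size = int(rng.integers(domain_len[0], domain_len[1] + 1))
                if cursor + size > n_aa:
                    break
                dom_rows.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "domain_index": d,
                        "start_aa": cursor,
                        "end_aa": cursor + size,
                    }
                )
                cursor += size + int(rng.integers(10, 60))
            noise = rng.normal(size=n_aa + 14)
            smooth = np.convolve(noise, np.ones(15) / 15, mode="valid")
            score = 1.0 / (1.0 + np.exp(-3.0 * smooth))
            for i in range(n_aa):
                dis_rows.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "residue_index": i,
                        "score": float(score[i]),
                    }
                )
            if rng.random() < tm_fraction:
                tm_rows.append(
                    {
                        "transcript_id": tx.transcript_id,
                        "tm_type": "I" if rng.random() < 0.5 else "II",
                        "anchor_aa": int(rng.integers(10, max(11, n_aa // 3))),
                    }
                )
            if snp_density > 0:
                cds_len = tx.cds_end - tx.cds_start
                hits = np.nonzero(rng.random(cds_len) < snp_density)[0]
                for h in hits:
                    pos = tx.cds_start + int(h)
                    ref = tx.sequence[pos]
                    alt = str(rng.choice([b for b in _BASES if b != ref]))
                    snp_rows.append(
                        {
                            "transcript_id": tx.transcript_id,
                            "pos": pos,
                            "ref": ref,
                            "alt": alt,
                        }
                    )
    return {
        "exons": pd.DataFrame(exon_rows),
        "domains": pd.DataFrame(dom_rows),
        "disorder": pd.DataFrame(dis_rows),
        "tm": pd.DataFrame(tm_rows),
        "snps": pd.DataFrame(
            snp_rows, columns=["transcript_id", "pos", "ref", "alt"]
        ),
    }
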