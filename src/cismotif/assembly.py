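"""Assembly of enriched 8-mers into merged regions, PSSMs and logo matrices.

Three steps:

1. rank the 3-mer and 4-mer "cores" by how many (enriched 8-mer, window)
   pairs contain them, and keep the 8-mers carrying a top-10 core;
2. map the kept 8-mers back onto the group's promoters and merge
   occurrences that overlap by at least one base into maximal regions;
3. stack the region sequences — anchored on the leftmost occurrence of the
   top-ranked core, since relative offsets of exact matches are known and a
   gapped aligner would only add nondeterminism — and tabulate per-column
   base frequencies into a position-specific scoring matrix (PSSM), with an
   information-content-weighted logo matrix.

Also provides reverse-complement palindrome classification of 8-mers (the
heat-shock element GAAnnTTC being the canonical full palindrome) and a
TSS-distance histogram of merged regions.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .promoters import PromoterRecord, PromoterSet, reverse_complement

ALPHABET = "ACGT"


@dataclass
class CoreKmerRanking:
    core_length: int
    entries: list[tuple[str, int]]  # (core, count), counts non-increasing
    tied_at_cutoff: list[str] = field(default_factory=list)

    @property
    def cores(self) -> list[str]:
        return [c for c, _ in self.entries]


def rank_core_kmers(
    enriched_8mers: list[str], core_length: int, top: int = 10
) -> CoreKmerRanking:
    """Count every length-`core_length` window of every enriched 8-mer.

    A core appearing in two windows of one 8-mer counts twice.  Returns the
    top `top` cores by count, ties broken lexicographically; cores outside
    the cutoff that tie with the last kept count are reported in
    tied_at_cutoff.
    """
    if core_length >= 8:
        raise ValueError("core length must be < 8")
    counts: Counter[str] = Counter()
    for motif in enriched_8mers:
        for i in range(len(motif) - core_length + 1):
            counts[motif[i : i + core_length]] += 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    entries = ranked[:top]
    tied = []
    if len(ranked) > top and entries:
        cutoff = entries[-1][1]
        tied = [c for c, n in ranked[top:] if n == cutoff]
    return CoreKmerRanking(core_length, entries, tied)


def select_step1_motifs(
    enriched_8mers: list[str],
    ranking3: CoreKmerRanking,
    ranking4: CoreKmerRanking,
    require_both: bool = False,
) -> list[str]:
    """8-mers containing a top-10 3-mer or a top-10 4-mer (union by default)."""
    cores3 = set(ranking3.cores)
    cores4 = set(ranking4.cores)

    def has_core(motif: str, cores: set[str], L: int) -> bool:
        return any(motif[i : i + L] in cores for i in range(len(motif) - L + 1))

    out = []
    for motif in enriched_8mers:
        h3 = has_core(motif, cores3, 3)
        h4 = has_core(motif, cores4, 4)
        if (h3 and h4) if require_both else (h3 or h4):
            out.append(motif)
    return out


@dataclass
class MergedRegion:
    promoter_id: str
    start_offset: int  # 0-based half-open within the promoter
    end_offset: int
    sequence: str
    contributing_motifs: list[tuple[str, int]]  # (motif, offset)

    @property
    def length(self) -> int:
        return self.end_offset - self.start_offset


def map_and_merge(motifs: list[str], group_promoters: PromoterSet) -> list[MergedRegion]:
    """Locate all exact occurrences and merge per-promoter overlapping ones.

    Occurrences sharing >= 1 base on the same promoter are merged
    transitively into a maximal region; occurrences on different promoters
    never merge.
    """
    regions: list[MergedRegion] = []
    motif_set = sorted(set(motifs))
    for rec in group_promoters.records:
        seq = rec.sequence
        occs: list[tuple[int, str]] = []
        for m in motif_set:
            start = seq.find(m)
            while start != -1:
                occs.append((start, m))
                start = seq.find(m, start + 1)
        if not occs:
            continue
        occs.sort()
        cur_start, cur_end = occs[0][0], occs[0][0] + len(occs[0][1])
        cur_motifs = [(occs[0][1], occs[0][0])]
        for start, m in occs[1:]:
            end = start + len(m)
            if start < cur_end:  # >=1 base overlap
                cur_end = max(cur_end, end)
                cur_motifs.append((m, start))
            else:
                regions.append(
                    MergedRegion(
                        rec.promoter_id, cur_start, cur_end,
                        seq[cur_start:cur_end], cur_motifs,
                    )
                )
                cur_start, cur_end, cur_motifs = start, end, [(m, start)]
        regions.append(
            MergedRegion(rec.promoter_id, cur_start, cur_end, seq[cur_start:cur_end], cur_motifs)
        )
    return regions


@dataclass
class PSSM:
    frequencies: np.ndarray  # columns x 4, rows sum to 1 per column
    support: int
    pseudocount: float
    consensus: str
    information_content: np.ndarray  # bits per column, in [0, 2]

    @property
    def n_columns(self) -> int:
        return self.frequencies.shape[0]

    def logo_matrix(self) -> np.ndarray:
        """Per-column frequency scaled by information content (logo heights)."""
        return self.frequencies * self.information_content[:, None]


def build_pssm(
    regions: list[MergedRegion],
    anchor_core: str | None = None,
    pseudocount: float = 0.0,
    min_column_support: float = 0.5,
) -> PSSM:
    """Stack region sequences and tabulate per-column base frequencies.

    Each region is anchored at the start of its leftmost occurrence of
    `anchor_core` (typically the group's top-ranked core k-mer); regions
    lacking the core anchor at offset 0.  Columns supported by fewer than
    `min_column_support` of the regions are trimmed from both ends.
    Information content per column is 2 - H (bits), H the Shannon entropy
    of the column distribution.
    """
    if not regions:
        raise ValueError("no regions to build a PSSM from")
    offsets = []
    for r in regions:
        anchor = r.sequence.find(anchor_core) if anchor_core else -1
        offsets.append(anchor if anchor != -1 else 0)
    max_off = max(offsets)
    width = max(max_off - off + len(r.sequence) for off, r in zip(offsets, regions))
    counts = np.zeros((width, 4), dtype=float)
    coverage = np.zeros(width, dtype=int)
    for off, r in zip(offsets, regions):
        shift = max_off - off
        for i, base in enumerate(r.sequence):
            counts[shift + i, ALPHABET.index(base)] += 1
            coverage[shift + i] += 1

    keep = coverage >= min_column_support * len(regions)
    if keep.any():  # trim low-support flanks only
        first, last = int(np.argmax(keep)), int(len(keep) - np.argmax(keep[::-1]) - 1)
        counts = counts[first : last + 1]
        coverage = coverage[first : last + 1]
    counts = counts + pseudocount
    col_tot = counts.sum(axis=1, keepdims=True)
    col_tot[col_tot == 0] = 1.0
    freqs = counts / col_tot
    with np.errstate(divide="ignore", invalid="ignore"):
        logf = np.where(freqs > 0, np.log2(np.where(freqs > 0, freqs, 1.0)), 0.0)
    entropy = -(freqs * logf).sum(axis=1)
    ic = np.clip(2.0 - entropy, 0.0, 2.0)
    consensus = "".join(ALPHABET[int(i)] for i in freqs.argmax(axis=1))
    return PSSM(
        frequencies=freqs,
        support=len(regions),
        pseudocount=pseudocount,
        consensus=consensus,
        information_content=ic,
    )


def classify_palindrome(motif_8mer: str) -> str:
    """Classify an 8-mer as 'full', 'flank_1'..'flank_3', or 'none'.

    full: the reverse complement equals the motif (position i pairs with
    position 9-i for all i).  flank_k: the outer k base pairs satisfy
    reverse-complementarity but some inner pair does not; the maximal such
    k in 1..3 is reported.
    """
    m = motif_8mer.upper()
    if len(m) != 8 or not set(m) <= set(ALPHABET):
        raise ValueError(f"need an ACGT 8-mer, got {motif_8mer!r}")
    if reverse_complement(m) == m:
        return "full"
    pair = dict(zip("ACGT", "TGCA"))
    k = 0
    for i in range(3):  # outer pairs (1,8), (2,7), (3,6)
        if pair[m[i]] == m[7 - i]:
            k = i + 1
        else:
            break
    return f"flank_{k}" if k else "none"


def tss_distance_profile(
    regions: list[MergedRegion],
    promoters: PromoterSet,
    bin_size: int = 100,
    promoter_length: int = 1000,
) -> np.ndarray:
    """Histogram of region midpoints by distance upstream of the TSS.

    Promoter sequences run 5'->3' toward the TSS, so a midpoint at offset o
    in a promoter of length L lies L - o bases upstream.  Bins cover
    [0, promoter_length) in steps of bin_size.
    """
    lengths = {r.promoter_id: len(r.sequence) for r in promoters.records}
    n_bins = math.ceil(promoter_length / bin_size)
    hist = np.zeros(n_bins, dtype=int)
    for region in regions:
        L = lengths[region.promoter_id]
        mid = (region.start_offset + region.end_offset) / 2.0
        dist = L - mid
        b = min(int(dist // bin_size), n_bins - 1)
        hist[b] += 1
    return hist


# ---------------------------------------------------------------------------
# output writers


def write_meme_motif(pssm: PSSM, name: str, path: str | Path) -> None:
    """Write the PSSM in MEME minimal motif format."""
    lines = [
        "MEME version 4",
        "",
        "ALPHABET= ACGT",
        "",
        "strands: +",
        "",
        "Background letter frequencies",
        "A 0.25 C 0.25 G 0.25 T 0.25",
        "",
        f"MOTIF {name}",
        f"letter-probability matrix: alength= 4 w= {pssm.n_columns} nsites= {pssm.support}",
    ]
    for row in pssm.frequencies:
        lines.append(" ".join(f"{v:.6f}" for v in row))
    lines.append("")
    Path(path).write_text("\n".join(lines))


def write_regions_tsv(regions: list[MergedRegion], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("promoter_id\tstart\tend\tsequence\tmotifs\n")
        for r in regions:
            motifs = ",".join(f"{m}@{o}" for m, o in r.contributing_motifs)
            fh.write(
                f"{r.promoter_id}\t{r.start_offset}\t{r.end_offset}\t{r.sequence}\t{motifs}\n"
            )
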