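"""Background-calibrated k-mer enrichment on promoter sets.

All 4-8-mers over {A,C,G,T} (87,296 motifs) are indexed against a
genome-wide promoter background; for a co-expressed gene group two
hypergeometric upper-tail tests are run per motif:

* presence enrichment — successes are *genes* whose promoter(s) contain the
  motif; the population is all background genes;
* number enrichment — successes are motif *occurrences*; the population is
  all possible match start positions (sum of L-k+1 over promoters).

A motif significant under both (p < 0.001) is called enriched — the first
quadrant of a presence-vs-number significance plot.  Matching is exact,
forward-strand, and counts overlapping occurrences.

k-mers are handled as 2-bit codes (A=0, C=1, G=2, T=3, big-endian within
the word) so whole-background counting is a handful of numpy passes.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .promoters import PromoterSet, reverse_complement

ALPHABET = "ACGT"
_BASE_TO_CODE = {b: i for i, b in enumerate(ALPHABET)}
_ENC = np.full(128, 255, dtype=np.uint8)
for _b, _i in _BASE_TO_CODE.items():
    _ENC[ord(_b)] = _i


def enumerate_kmers(k_min: int = 4, k_max: int = 8) -> list[str]:
    """All A/C/G/T strings of lengths k_min..k_max, lexicographic within length."""
    if not (1 <= k_min <= k_max):
        raise ValueError(f"invalid k range ({k_min}, {k_max})")
    out = []
    for k in range(k_min, k_max + 1):
        out.extend(code_to_kmer(c, k) for c in range(4**k))
    return out


def kmer_to_code(kmer: str) -> int:
    code = 0
    for ch in kmer:
        if ch not in _BASE_TO_CODE:
            raise ValueError(f"invalid base {ch!r} in motif {kmer!r}")
        code = code * 4 + _BASE_TO_CODE[ch]
    return code


def code_to_kmer(code: int, k: int) -> str:
    chars = []
    for _ in range(k):
        chars.append(ALPHABET[code & 3])
        code >>= 2
    return "".join(reversed(chars))


def encode_sequence(seq: str) -> np.ndarray:
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid base {bad!r} in sequence")
    return arr


def window_codes(encoded: np.ndarray, k: int) -> np.ndarray:
    """Codes of every length-k window of an encoded sequence (possibly empty)."""
    n = encoded.size - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = encoded[:n].astype(np.int64)
    for j in range(1, k):
        codes = codes * 4 + encoded[j : j + n]
    return codes


def count_occurrences(sequence: str, motif: str) -> int:
    """Exact overlapping forward-strand match count of motif in sequence."""
    seq = sequence.upper()
    m = motif.upper()
    count = 0
    start = seq.find(m)
    while start != -1:
        count += 1
        start = seq.find(m, start + 1)
    return count


@dataclass
class BackgroundIndex:
    """Genome-wide per-motif presence and occurrence counts.

    presence[k][code] = number of genes with >=1 occurrence in their
    promoter(s); number[k][code] = total occurrences over all promoters;
    position_totals[k] = total valid start positions.
    """

    n_genes: int
    k_min: int
    k_max: int
    position_totals: dict[int, int]
    presence: dict[int, np.ndarray]
    number: dict[int, np.ndarray]
    both_strands: bool = False

    def m_presence(self, motif: str) -> int:
        return int(self.presence[len(motif)][kmer_to_code(motif)])

    def m_number(self, motif: str) -> int:
        return int(self.number[len(motif)][kmer_to_code(motif)])

    def save(self, path: str | Path) -> None:
        doc = {
            "n_genes": self.n_genes,
            "k_min": self.k_min,
            "k_max": self.k_max,
            "both_strands": self.both_strands,
            "position_totals": {str(k): v for k, v in self.position_totals.items()},
            "presence": {str(k): v.tolist() for k, v in self.presence.items()},
            "number": {str(k): v.tolist() for k, v in self.number.items()},
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def load(cls, path: str | Path) -> "BackgroundIndex":
        doc = json.loads(Path(path).read_text())
        return cls(
            n_genes=doc["n_genes"],
            k_min=doc["k_min"],
            k_max=doc["k_max"],
            both_strands=doc.get("both_strands", False),
            position_totals={int(k): v for k, v in doc["position_totals"].items()},
            presence={int(k): np.array(v, dtype=np.int64) for k, v in doc["presence"].items()},
            number={int(k): np.array(v, dtype=np.int64) for k, v in doc["number"].items()},
        )


def _gene_sequences(ps: PromoterSet, both_strands: bool) -> dict[str, list[str]]:
    by_gene: dict[str, list[str]] = {}
    for r in ps.records:
        seqs = by_gene.setdefault(r.gene_id, [])
        seqs.append(r.sequence)
        if both_strands:
            seqs.append(reverse_complement(r.sequence))
    return by_gene


def _count_sequences(
    seqs_by_gene: dict[str, list[str]], k: int
) -> tuple[np.ndarray, np.ndarray, int]:
    """(presence counts, occurrence counts, total positions) for one k."""
    size = 4**k
    presence = np.zeros(size, dtype=np.int64)
    number = np.zeros(size, dtype=np.int64)
    positions = 0
    for seqs in seqs_by_gene.values():
        codes = [window_codes(encode_sequence(s), k) for s in seqs]
        positions += sum(c.size for c in codes)
        if not codes:
            continue
        all_codes = np.concatenate(codes) if len(codes) > 1 else codes[0]
        if all_codes.size == 0:
            continue
        counts = np.bincount(all_codes, minlength=size)
        number += counts
        presence[np.unique(all_codes)] += 1
    return presence, number, positions


def build_background(
    ps: PromoterSet, k_min: int = 4, k_max: int = 8, both_strands: bool = False
) -> BackgroundIndex:
    """Scan every k-mer (k_min..k_max) over the whole promoter set.

    Genes with several promoters contribute presence once per gene and
    occurrences summed over their promoters.  With both_strands, the
    reverse complement of each promoter is scanned as well (positions and
    occurrences double-count accordingly).
    """
    if len(ps) == 0:
        raise ValueError("empty promoter set")
    if not (1 <= k_min <= k_max):
        raise ValueError(f"invalid k range ({k_min}, {k_max})")
    by_gene = _gene_sequences(ps, both_strands)
    presence: dict[int, np.ndarray] = {}
    number: dict[int, np.ndarray] = {}
    totals: dict[int, int] = {}
    for k in range(k_min, k_max + 1):
        presence[k], number[k], totals[k] = _count_sequences(by_gene, k)
    return BackgroundIndex(
        n_genes=len(by_gene),
        k_min=k_min,
        k_max=k_max,
        position_totals=totals,
        presence=presence,
        number=number,
        both_strands=both_strands,
    )


def hypergeom_upper_tail(x: int, n: int, M: int, N: int) -> float:
    """P(X >= x) for X ~ Hypergeometric(population N, successes M, draws n).

    Computed in log space via the survival function; exactly 1.0 at x = 0.
    """
    if not (0 <= M <= N and 0 <= n <= N and 0 <= x <= min(n, M)):
        raise ValueError(f"inconsistent hypergeometric counts x={x} n={n} M={M} N={N}")
    if x == 0:
        return 1.0
    return float(stats.hypergeom.sf(x - 1, N, M, n))


def presence_enrichment(
    motif: str,
    group_gene_ids: list[str],
    group_promoters: PromoterSet,
    bg: BackgroundIndex,
) -> float:
    """Upper-tail p for the number of group genes whose promoters hold the motif."""
    by_gene = _gene_sequences(group_promoters, bg.both_strands)
    missing = [g for g in group_gene_ids if g not in by_gene]
    if missing:
        warnings.warn(
            f"{len(missing)} group gene(s) without promoters excluded", stacklevel=2
        )
    genes = [g for g in group_gene_ids if g in by_gene]
    x = sum(
        1 for g in genes if any(count_occurrences(s, motif) for s in by_gene[g])
    )
    n = len(genes)
    return hypergeom_upper_tail(x, n, bg.m_presence(motif), bg.n_genes)


def number_enrichment(
    motif: str, group_promoters: PromoterSet, bg: BackgroundIndex
) -> float:
    """Upper-tail p for the motif's occurrence count over group match positions."""
    k = len(motif)
    by_gene = _gene_sequences(group_promoters, bg.both_strands)
    x = 0
    n = 0
    for seqs in by_gene.values():
        for s in seqs:
            x += count_occurrences(s, motif)
            n += max(0, len(s) - k + 1)
    return hypergeom_upper_tail(x, n, bg.m_number(motif), bg.position_totals[k])


@dataclass
class EnrichmentResult:
    motif: str
    k: int
    x_presence: int
    p_presence: float
    x_number: int
    p_number: float
    enriched: bool
    quadrant: int


def enrich_group(
    group_gene_ids: list[str],
    ps: PromoterSet,
    bg: BackgroundIndex,
    alpha: float = 0.001,
    k: int = 8,
) -> list[EnrichmentResult]:
    """Presence and number enrichment for every k-mer occurring in the group.

    ps must contain the promoters of the group genes only (promoters of
    other genes are ignored).  Quadrants follow the significance plane:
    1 = both tests significant (enriched), 2 = number only, 4 = presence
    only, 3 = neither.
    """
    group_set = set(group_gene_ids)
    sub = PromoterSet([r for r in ps.records if r.gene_id in group_set])
    by_gene = _gene_sequences(sub, bg.both_strands)
    missing = group_set - set(by_gene)
    if missing:
        warnings.warn(
            f"{len(missing)} group gene(s) without promoters excluded", stacklevel=2
        )
    n_genes = len(by_gene)
    size = 4**k
    x_presence = np.zeros(size, dtype=np.int64)
    x_number = np.zeros(size, dtype=np.int64)
    n_positions = 0
    for seqs in by_gene.values():
        codes = [window_codes(encode_sequence(s), k) for s in seqs]
        n_positions += sum(c.size for c in codes)
        all_codes = np.concatenate(codes) if codes else np.empty(0, dtype=np.int64)
        if all_codes.size == 0:
            continue
        x_number += np.bincount(all_codes, minlength=size)
        x_presence[np.unique(all_codes)] += 1

    occurring = np.flatnonzero(x_number)
    Mp = bg.presence[k][occurring]
    Mn = bg.number[k][occurring]
    xp = x_presence[occurring]
    xn = x_number[occurring]
    with np.errstate(divide="ignore"):
        p_pres = stats.hypergeom.sf(xp - 1, bg.n_genes, Mp, n_genes)
        p_num = stats.hypergeom.sf(xn - 1, bg.position_totals[k], Mn, n_positions)
    p_pres = np.where(xp == 0, 1.0, p_pres)
    p_num = np.where(xn == 0, 1.0, p_num)

    results = []
    for code, xpi, xni, ppi, pni in zip(occurring, xp, xn, p_pres, p_num):
        sig_p = ppi < alpha
        sig_n = pni < alpha
        quadrant = 1 if (sig_p and sig_n) else 2 if sig_n else 4 if sig_p else 3
        results.append(
            EnrichmentResult(
                motif=code_to_kmer(int(code), k),
                k=k,
                x_presence=int(xpi),
                p_presence=float(ppi),
                x_number=int(xni),
                p_number=float(pni),
                enriched=bool(sig_p and sig_n),
                quadrant=quadrant,
            )
        )
    return results


def write_enrichment_tsv(results: list[EnrichmentResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "motif\tk\tx_presence\tp_presence\tx_number\tp_number\tenriched\tquadrant\n"
        )
        for r in results:
            fh.write(
                f"{r.motif}\t{r.k}\t{r.x_presence}\t{r.p_presence:.6e}\t"
                f"{r.x_number}\t{r.p_number:.6e}\t{int(r.enriched)}\t{r.quadrant}\n"
            )
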