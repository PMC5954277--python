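"""Genomic promoter dataset construction.

A promoter is the 1000 bp immediately upstream of a transcription start
site, read 5'->3' relative to the gene (minus-strand promoters are
reverse-complemented).  Promoters containing ambiguous IUPAC bases are
dropped, and promoters of transcripts of the same gene whose intervals
overlap (or abut) are merged into a single region so one motif occurrence
is never counted twice for a gene.

Coordinates are 1-based inclusive internally; BED output is 0-based
half-open per the standard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from pyfaidx import Fasta

COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")
VALID_BASES = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


@dataclass
class TSSRecord:
    transcript_id: str
    gene_id: str
    chromosome: str
    tss_position: int  # 1-based
    strand: str  # '+' or '-'

    def __post_init__(self) -> None:
        if self.tss_position < 1:
            raise ValueError(f"{self.transcript_id}: TSS position must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.transcript_id}: invalid strand {self.strand!r}")


@dataclass
class PromoterRecord:
    promoter_id: str
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str
    sequence: str  # 5'->3' relative to the gene, uppercase

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class PromoterSet:
    records: list[PromoterRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def by_gene(self) -> dict[str, list[PromoterRecord]]:
        out: dict[str, list[PromoterRecord]] = {}
        for r in self.records:
            out.setdefault(r.gene_id, []).append(r)
        return out

    @property
    def gene_ids(self) -> list[str]:
        return sorted({r.gene_id for r in self.records})


class GenomeLookup:
    """Uniform 1-based inclusive fetch over a dict of sequences or a FASTA file."""

    def __init__(self, source: str | Path | Mapping[str, str]):
        if isinstance(source, (str, Path)):
            self._fasta = Fasta(str(source), as_raw=True, sequence_always_upper=True)
            self._dict = None
        else:
            self._fasta = None
            self._dict = {k: v.upper() for k, v in source.items()}

    def __contains__(self, chrom: str) -> bool:
        if self._dict is not None:
            return chrom in self._dict
        return chrom in self._fasta

    def length(self, chrom: str) -> int:
        if self._dict is not None:
            return len(self._dict[chrom])
        return len(self._fasta[chrom])

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Sequence of [start, end], 1-based inclusive, uppercase, forward strand."""
        if start < 1 or end > self.length(chrom) or start > end:
            raise ValueError(f"invalid interval {chrom}:{start}-{end}")
        if self._dict is not None:
            return self._dict[chrom][start - 1 : end]
        return str(self._fasta[chrom][start - 1 : end]).upper()


def extract_promoter(
    tss: TSSRecord, genome: GenomeLookup, length: int = 1000
) -> PromoterRecord | None:
    """Extract the `length` bp upstream of the TSS, excluding the TSS base.

    Plus strand: genomic [tss-length, tss-1]; minus strand: genomic
    [tss+1, tss+length] reverse-complemented.  The interval is truncated at
    the chromosome boundary; a TSS with no upstream sequence at all yields
    None with a warning.
    """
    chrom_len = genome.length(tss.chromosome)
    if tss.strand == "+":
        start = max(1, tss.tss_position - length)
        end = tss.tss_position - 1
        if end < start:
            warnings.warn(f"{tss.transcript_id}: no upstream sequence", stacklevel=2)
            return None
        seq = genome.fetch(tss.chromosome, start, end)
    else:
        start = tss.tss_position + 1
        end = min(chrom_len, tss.tss_position + length)
        if end < start:
            warnings.warn(f"{tss.transcript_id}: no upstream sequence", stacklevel=2)
            return None
        seq = reverse_complement(genome.fetch(tss.chromosome, start, end))
    return PromoterRecord(
        promoter_id=tss.transcript_id,
        gene_id=tss.gene_id,
        chromosome=tss.chromosome,
        start=start,
        end=end,
        strand=tss.strand,
        sequence=seq.upper(),
    )


def filter_ambiguous(ps: PromoterSet) -> PromoterSet:
    """Drop promoters containing any base outside A/C/G/T (N, S, K, M, R, W...)."""
    kept = []
    dropped = 0
    for r in ps.records:
        seq = r.sequence.upper()
        if set(seq) <= VALID_BASES:
            if seq != r.sequence:
                r = PromoterRecord(
                    r.promoter_id, r.gene_id, r.chromosome, r.start, r.end, r.strand, seq
                )
            kept.append(r)
        else:
            dropped += 1
    if dropped:
        warnings.warn(f"removed {dropped} promoter(s) with ambiguous bases", stacklevel=2)
    return PromoterSet(kept)


def merge_promoters(
    records: list[PromoterRecord], genome: GenomeLookup, merge_gap: int = 0
) -> list[PromoterRecord]:
    """Merge overlapping/book-ended promoter intervals of one gene.

    Intervals whose genomic gap is <= merge_gap (0 = overlap or adjacency)
    are replaced by their union, with the sequence re-extracted from the
    genome; disjoint intervals stay separate.  Output ids are deterministic:
    gene_id.p<ordinal> by genomic start.
    """
    if not records:
        return []
    gene_ids = {r.gene_id for r in records}
    chroms = {r.chromosome for r in records}
    strands = {r.strand for r in records}
    if len(gene_ids) != 1 or len(chroms) != 1:
        raise ValueError("merge_promoters: records must share gene and chromosome")
    if len(strands) != 1:
        raise ValueError(f"mixed strands for gene {records[0].gene_id}")
    gene_id = records[0].gene_id
    chrom = records[0].chromosome
    strand = records[0].strand

    intervals = sorted((r.start, r.end) for r in records)
    merged: list[list[int]] = [list(intervals[0])]
    for s, e in intervals[1:]:
        if s <= merged[-1][1] + 1 + merge_gap:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])

    out = []
    for i, (s, e) in enumerate(merged, start=1):
        seq = genome.fetch(chrom, s, e)
        if strand == "-":
            seq = reverse_complement(seq)
        out.append(
            PromoterRecord(
                promoter_id=f"{gene_id}.p{i}",
                gene_id=gene_id,
                chromosome=chrom,
                start=s,
                end=e,
                strand=strand,
                sequence=seq.upper(),
            )
        )
    return out


def build_promoter_set(
    tss_records: Iterable[TSSRecord],
    genome: GenomeLookup,
    length: int = 1000,
    merge_gap: int = 0,
) -> PromoterSet:
    """Extract, ambiguity-filter, and per-gene merge promoters for all TSSs."""
    raw = []
    for tss in tss_records:
        rec = extract_promoter(tss, genome, length)
        if rec is not None:
            raw.append(rec)
    filtered = filter_ambiguous(PromoterSet(raw))
    out: list[PromoterRecord] = []
    for gene_id in sorted({r.gene_id for r in filtered.records}):
        gene_recs = [r for r in filtered.records if r.gene_id == gene_id]
        out.extend(merge_promoters(gene_recs, genome, merge_gap))
    # re-filter: a merged union can re-introduce ambiguity from the gap
    return filter_ambiguous(PromoterSet(out))


# ---------------------------------------------------------------------------
# I/O


def read_tss_table(path: str | Path) -> list[TSSRecord]:
    """TSV with columns transcript_id, gene_id, chrom, pos (1-based), strand."""
    records = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        idx = {name: i for i, name in enumerate(header)}
        for line in fh:
            f = line.rstrip("\n").split("\t")
            records.append(
                TSSRecord(
                    transcript_id=f[idx["transcript_id"]],
                    gene_id=f[idx["gene_id"]],
                    chromosome=f[idx["chrom"]],
                    tss_position=int(f[idx["pos"]]),
                    strand=f[idx["strand"]],
                )
            )
    return records


def write_tss_table(records: Iterable[TSSRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\tgene_id\tchrom\tpos\tstrand\n")
        for r in records:
            fh.write(
                f"{r.transcript_id}\t{r.gene_id}\t{r.chromosome}\t"
                f"{r.tss_position}\t{r.strand}\n"
            )


def write_promoters(ps: PromoterSet, fasta_path: str | Path, bed_path: str | Path) -> None:
    """FASTA (headers `promoter_id|gene_id|chrom:start-end(strand)`) + BED6."""
    with open(fasta_path, "w") as fa:
        for r in ps.records:
            fa.write(
                f">{r.promoter_id}|{r.gene_id}|{r.chromosome}:{r.start}-{r.end}({r.strand})\n"
            )
            for i in range(0, len(r.sequence), 60):
                fa.write(r.sequence[i : i + 60] + "\n")
    with open(bed_path, "w") as bed:
        for r in ps.records:
            bed.write(
                f"{r.chromosome}\t{r.start - 1}\t{r.end}\t{r.promoter_id}\t0\t{r.strand}\n"
            )


def read_promoters(fasta_path: str | Path) -> PromoterSet:
    """Re-read a promoter FASTA written by write_promoters."""
    records = []
    header = None
    chunks: list[str] = []

    def flush():
        if header is None:
            return
        promoter_id, gene_id, loc = header.split("|")
        chrom, rest = loc.rsplit(":", 1)
        coords, strand = rest[:-1].split("(")
        start, end = coords.split("-")
        records.append(
            PromoterRecord(
                promoter_id=promoter_id,
                gene_id=gene_id,
                chromosome=chrom,
                start=int(start),
                end=int(end),
                strand=strand,
                sequence="".join(chunks).upper(),
            )
        )

    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:]
                chunks = []
            else:
                chunks.append(line)
        flush()
    return PromoterSet(records)
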