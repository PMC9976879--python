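"""Toy reference genome, trinucleotide contexts and genomic tracks."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .intervals import GenomicInterval

BASES = "ACGT"
_CODE = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0], dtype=np.uint8)  # A<->T, C<->G

#: The 32 pyrimidine-centred trinucleotides (centre C or T), lexicographic.
TRINUCLEOTIDES_32 = [
    five + centre + three
    for centre in "CT"
    for five in BASES
    for three in BASES
]
_TRINUC_INDEX = {t: i for i, t in enumerate(TRINUCLEOTIDES_32)}

#: 96 single-base-substitution channels in COSMIC order:
#: C>A, C>G, C>T, T>A, T>C, T>G, each over the 16 five'/three' contexts.
SBS_CHANNELS_96 = [
    f"{five}[{ref}>{alt}]{three}"
    for ref, alts in (("C", "AGT"), ("T", "ACG"))
    for alt in alts
    for five in BASES
    for three in BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(SBS_CHANNELS_96)}


def encode_sequence(seq: str) -> np.ndarray:
    return np.array([_CODE[b] for b in seq.upper()], dtype=np.uint8)


class Genome:
    """In-memory reference: chromosome name -> base codes (0=A,1=C,2=G,3=T)."""

    def __init__(self, chromosomes: Mapping[str, np.ndarray]):
        self.chromosomes = {c: np.asarray(v, dtype=np.uint8) for c, v in chromosomes.items()}

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str]) -> "Genome":
        return cls({c: encode_sequence(s) for c, s in seqs.items()})

    @property
    def sizes(self) -> dict[str, int]:
        return {c: len(v) for c, v in self.chromosomes.items()}

    def codes(self, chrom: str, start: int, end: int) -> np.ndarray:
        return self.chromosomes[chrom][start:end]

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return "".join(BASES[i] for i in self.codes(chrom, start, end))

    def base(self, chrom: str, pos: int) -> str:
        return BASES[self.chromosomes[chrom][pos]]

    def trinucleotide(self, chrom: str, pos: int) -> str:
        """Trinucleotide context centred at ``pos`` (requires 1 bp margin)."""
        return self.sequence(chrom, pos - 1, pos + 2)


def collapse_trinucleotide(trinuc: str) -> str:
    """Reverse-complement purine-centred contexts onto the 32 pyrimidine ones."""
    if trinuc[1] in "CT":
        return trinuc
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    return "".join(comp[b] for b in reversed(trinuc))


def collapse_substitution(trinuc: str, alt: str) -> str:
    """Map a (context, alt) pair onto its pyrimidine-centred 96-channel label."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if trinuc[1] in "CT":
        ref = trinuc[1]
        return f"{trinuc[0]}[{ref}>{alt}]{trinuc[2]}"
    rc = "".join(comp[b] for b in reversed(trinuc))
    return f"{rc[0]}[{rc[1]}>{comp[alt]}]{rc[2]}"


def trinucleotide_counts(genome: Genome, intervals: Iterable[GenomicInterval]) -> np.ndarray:
    """Counts of the 32 collapsed trinucleotide contexts over interval bases.

    Positions whose 3-mer window would leave the chromosome are skipped.
    """
    counts = np.zeros(32, dtype=np.int64)
    for iv in intervals:
        chrom_len = len(genome.chromosomes[iv.chrom])
        start = max(iv.start, 1)
        end = min(iv.end, chrom_len - 1)
        if end <= start:
            continue
        seq = genome.chromosomes[iv.chrom]
        five, centre, three = seq[start - 1:end - 1], seq[start:end], seq[start + 1:end + 1]
        # collapse purine centres (A=0, G=2) by reverse-complementing the 3-mer
        pur = (centre == 0) | (centre == 2)
        c5 = np.where(pur, _COMPLEMENT[three], five)
        cc = np.where(pur, _COMPLEMENT[centre], centre)
        c3 = np.where(pur, _COMPLEMENT[five], three)
        # index: centre C->0, T->1; code 1->0, 3->1
        idx = (cc == 3).astype(np.int64) * 16 + c5.astype(np.int64) * 4 + c3.astype(np.int64)
        counts += np.bincount(idx, minlength=32)
    return counts


def gc_content(genome: Genome, intervals: Iterable[GenomicInterval]) -> float:
    total = 0
    gc = 0
    for iv in intervals:
        codes = genome.codes(iv.chrom, iv.start, iv.end)
        total += len(codes)
        gc += int(np.count_nonzero((codes == 1) | (codes == 2)))
    return gc / total if total else float("nan")


@dataclass
class SteppedTrack:
    """Piecewise-constant genomic track (BedGraph-like), e.g. replication timing."""

    steps: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]
    # chrom -> (starts, ends, values), sorted by start, non-overlapping

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, float]]) -> "SteppedTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in records:
            per.setdefault(chrom, []).append((start, end, value))
        steps = {}
        for chrom, rows in per.items():
            rows.sort()
            arr = np.array(rows, dtype=float)
            steps[chrom] = (arr[:, 0].astype(np.int64), arr[:, 1].astype(np.int64), arr[:, 2])
        return cls(steps)

    def values_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        starts, ends, values = self.steps[chrom]
        idx = np.searchsorted(starts, positions, side="right") - 1
        ok = (idx >= 0) & (positions < ends[np.clip(idx, 0, len(ends) - 1)])
        out = np.full(len(positions), np.nan)
        out[ok] = values[idx[ok]]
        return out

    def mean_over(self, intervals: Iterable[GenomicInterval]) -> float:
        """Length-weighted mean of the track over the intervals."""
        weight = 0.0
        acc = 0.0
        for iv in intervals:
            if iv.chrom not in self.steps:
                continue
            starts, ends, values = self.steps[iv.chrom]
            lo = np.clip(np.maximum(starts, iv.start), iv.start, iv.end)
            hi = np.clip(np.minimum(ends, iv.end), iv.start, iv.end)
            overlap = np.maximum(hi - lo, 0)
            acc += float(np.dot(overlap, values))
            weight += float(overlap.sum())
        return acc / weight if weight else float("nan")
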