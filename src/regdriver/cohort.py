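"""Sample QC, high-CADD SNV selection and per-gene mutation accounting.

High-pathogenicity ("high-CADD") single-nucleotide variants are SNVs whose
CADD PHRED score reaches a cutoff (default 10).  Each genomic position can
yield up to three *theoretical* high-CADD mutations, one per alternative
allele; the per-gene count ``s`` of such (position, alt) pairs inside the
regulatory space is the denominator of the high-CADD mutation frequency
``n / (s k)``, where ``n`` is the number of cohort samples carrying at least
one high-CADD SNV in the space (at most one mutation counted per sample, to
damp local hypermutation/kataegis) and ``k`` the cohort size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, RegulatorySpace

logger = logging.getLogger(__name__)

#: POLE-deficiency and mismatch-repair-deficiency (MSI) signature labels whose
#: exposure marks hypermutator samples.
HYPERMUTATOR_SIGNATURES = frozenset(
    {
        "SBS10a", "SBS10b", "DBS3",            # POLE-MUT
        "SBS6", "SBS14", "SBS15", "SBS20",     # MSI
        "SBS21", "SBS44", "DBS7", "DBS10", "ID7",
    }
)

#: Canonical column set for mutation tables throughout the package.
MUTATION_COLUMNS = ["sample_id", "chrom", "pos", "ref", "alt", "cadd_phred"]


@dataclass(frozen=True)
class MutationRecord:
    """A somatic SNV call (0-based position)."""

    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    cadd_phred: float = float("nan")

    def __post_init__(self) -> None:
        if len(self.ref) != 1 or len(self.alt) != 1:
            raise ValueError("only single-nucleotide variants are supported")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")


@dataclass
class SampleInfo:
    sample_id: str
    tissue: str
    has_rna: bool
    signature_exposures: dict[str, float]


def mutations_frame(records: Iterable[MutationRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=MUTATION_COLUMNS)


class CaddTable:
    """Lookup (chrom, pos, alt) -> CADD PHRED, position 0-based.

    Backed by per-chromosome position-sorted arrays so that interval queries
    and theoretical high-CADD counting are vectorised.
    """

    def __init__(self, table: pd.DataFrame):
        required = {"chrom", "pos", "alt", "phred"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"CADD table missing columns: {sorted(missing)}")
        if (table["phred"] < 0).any():
            raise ValueError("CADD PHRED scores must be non-negative")
        self._chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for chrom, sub in table.groupby("chrom", sort=False):
            sub = sub.sort_values(["pos", "alt"], kind="mergesort")
            self._chrom[str(chrom)] = (
                sub["pos"].to_numpy(np.int64),
                sub["alt"].to_numpy(object),
                sub["phred"].to_numpy(float),
            )

    def in_interval(self, iv: GenomicInterval) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(positions, alts, phreds) of all table rows inside the interval."""
        if iv.chrom not in self._chrom:
            empty = np.array([])
            return empty.astype(np.int64), empty.astype(object), empty
        pos, alt, phred = self._chrom[iv.chrom]
        lo, hi = np.searchsorted(pos, [iv.start, iv.end])
        return pos[lo:hi], alt[lo:hi], phred[lo:hi]

    def lookup(self, chrom: str, position: int, alt: str) -> float:
        if chrom not in self._chrom:
            return float("nan")
        pos, alts, phred = self._chrom[chrom]
        lo, hi = np.searchsorted(pos, [position, position + 1])
        for i in range(lo, hi):
            if alts[i] == alt:
                return float(phred[i])
        return float("nan")

    def annotate(self, mutations: pd.DataFrame) -> pd.Series:
        return pd.Series(
            [self.lookup(c, p, a) for c, p, a in zip(mutations["chrom"], mutations["pos"], mutations["alt"])],
            index=mutations.index,
            dtype=float,
        )


def filter_hypermutator_samples(
    exposures: pd.DataFrame,
    exclusion_signatures: Iterable[str] = HYPERMUTATOR_SIGNATURES,
    threshold: float = 0.20,
) -> list[str]:
    """Retain samples with no listed signature exposure *over* the threshold.

    ``exposures`` is samples x signatures (fractions in [0, 1]); signatures
    missing from the table count as zero exposure.  A sample at exactly the
    threshold is retained (exclusion requires strictly greater exposure).
    """
    present = [s for s in exclusion_signatures if s in exposures.columns]
    absent = sorted(set(exclusion_signatures) - set(present))
    if absent:
        logger.info("exposure table lacks %s; treated as zero", absent)
    if not present:
        return list(exposures.index)
    keep = (exposures[present] <= threshold).all(axis=1)
    return list(exposures.index[keep])


def theoretical_highcadd_count(
    space: RegulatorySpace,
    cadd: CaddTable,
    cutoff: float = 10.0,
    strict: bool = True,
) -> int:
    """Number ``s`` of (position, alt) pairs in the space with PHRED >= cutoff.

    In strict mode, every space position must carry all three alternative
    alleles in the table; lenient mode counts uncovered pairs as below the
    cutoff with a warning.
    """
    s = 0
    for seg in space.segments:
        pos, _alt, phred = cadd.in_interval(seg)
        covered = len(np.unique(pos))
        if covered < len(seg):
            msg = f"CADD table covers {covered}/{len(seg)} positions of {seg}"
            if strict:
                raise ValueError(msg)
            logger.warning("%s; uncovered pairs counted as low-CADD", msg)
        s += int(np.count_nonzero(phred >= cutoff))
    return s


def select_highcadd_snvs(
    mutations: pd.DataFrame,
    cutoff: float = 10.0,
    cadd: CaddTable | None = None,
) -> pd.DataFrame:
    """Keep SNVs with CADD PHRED at least ``cutoff`` (inclusive).

    Records missing a score are annotated from ``cadd`` when provided;
    records still unscored are dropped with a warning.
    """
    scores = mutations["cadd_phred"].astype(float)
    if scores.isna().any() and cadd is not None:
        need = scores.isna()
        scores = scores.copy()
        scores[need] = cadd.annotate(mutations.loc[need])
    dropped = int(scores.isna().sum())
    if dropped:
        logger.warning("dropping %d SNVs without a CADD score", dropped)
    out = mutations.copy()
    out["cadd_phred"] = scores
    return out[scores >= cutoff]


def mutations_in_space(mutations: pd.DataFrame, space: RegulatorySpace) -> pd.DataFrame:
    """Subset of mutation records falling inside the space segments."""
    if len(mutations) == 0:
        return mutations
    mask = np.zeros(len(mutations), dtype=bool)
    pos = mutations["pos"].to_numpy()
    chrom = mutations["chrom"].to_numpy()
    for seg in space.segments:
        mask |= (chrom == seg.chrom) & (pos >= seg.start) & (pos < seg.end)
    return mutations.loc[mask]


def count_mutated_samples(
    space: RegulatorySpace, highcadd_mutations: pd.DataFrame
) -> tuple[int, dict[str, int]]:
    """Distinct samples with >= 1 high-CADD SNV in the space.

    At most one mutation per sample counts towards ``n``; the per-sample raw
    record counts are returned alongside for downstream analyses.
    """
    inside = mutations_in_space(highcadd_mutations, space)
    per_sample = inside.groupby("sample_id").size().to_dict()
    return len(per_sample), {str(k): int(v) for k, v in per_sample.items()}


def highcadd_frequency(n: int, s: int, k: int) -> float:
    """High-CADD mutation frequency ``n / (s k)`` per theoretical mutation per sample."""
    if s <= 0:
        raise ValueError("gene has no theoretical high-CADD mutations (s = 0); exclude it")
    if k <= 0:
        raise ValueError("cohort size k must be positive")
    if n < 0 or n > k:
        raise ValueError(f"require 0 <= n <= k, got n={n}, k={k}")
    return n / (s * k)
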