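"""Post-hoc confidence filters for called driver candidates.

Three orthogonal false-positive screens annotate (never remove) candidates:

* ``neighbor_underestimate`` — the background model locally underestimates
  mutagenesis: the median observed/expected mutated-sample ratio of other
  analysed genes with TSS within 100 kb exceeds 2.
* ``shared_region_secondary`` — the candidate shares a mutated regulatory
  segment with another candidate and is not the one with the highest
  expression evidence (score_E) in the sharing group.
* ``low_size_effect`` — the absolute expression size effect falls below
  0.4326 (a calibration constant corresponding to the 33rd percentile of
  targets lacking tissue-matched literature evidence; taken as a config
  default, not recomputed).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import mutations_in_space
from .intervals import RegulatorySpace

logger = logging.getLogger(__name__)

NEIGHBOR_DISTANCE = 100_000
NEIGHBOR_RATIO_CUT = 2.0
SIZE_EFFECT_CUT = 0.4326

FLAG_NEIGHBOR = "neighbor_underestimate"
FLAG_SHARED = "shared_region_secondary"
FLAG_SIZE = "low_size_effect"


def neighbor_ratio_filter(
    candidates: Sequence[str],
    gene_stats: pd.DataFrame,
    max_dist: int = NEIGHBOR_DISTANCE,
    ratio_cut: float = NEIGHBOR_RATIO_CUT,
) -> dict[str, float]:
    """Flag candidates whose neighbourhood is systematically over-mutated.

    ``gene_stats`` needs one row per analysed gene with columns ``gene_id``,
    ``chrom``, ``tss``, ``n`` (observed mutated samples) and ``expected_n``
    (k times the model's per-sample probability).  Neighbours are other
    analysed genes with TSS within ``max_dist`` (TSS-to-TSS).  Returns
    flagged gene -> median neighbour observed/expected ratio.
    """
    stats_by_gene = gene_stats.set_index("gene_id")
    flags: dict[str, float] = {}
    for gene in candidates:
        row = stats_by_gene.loc[gene]
        near = gene_stats[
            (gene_stats["chrom"] == row["chrom"])
            & (gene_stats["gene_id"] != gene)
            & ((gene_stats["tss"] - row["tss"]).abs() <= max_dist)
        ]
        ratios = []
        for _, nb in near.iterrows():
            if nb["expected_n"] <= 0:
                logger.info("neighbour %s of %s has zero expectation; skipped", nb["gene_id"], gene)
                continue
            ratios.append(nb["n"] / nb["expected_n"])
        if ratios and float(np.median(ratios)) > ratio_cut:
            flags[gene] = float(np.median(ratios))
    return flags


def shared_region_filter(
    candidates: Sequence[str],
    spaces: Mapping[str, RegulatorySpace],
    highcadd_mutations: pd.DataFrame,
    score_e: Mapping[str, float],
    size_effect: Mapping[str, float],
) -> dict[str, float]:
    """Flag all but the strongest-expression gene in each sharing group.

    Two candidates share when a *mutated* segment (containing >= 1 candidate
    high-CADD SNV) of one overlaps a mutated segment of the other; groups are
    the connected components of that relation.  Within a group the gene with
    the highest score_E survives; ties break by larger |size effect|, then
    by lexicographically smallest gene id.  Returns flagged gene -> the
    winning competitor's score_E.
    """
    mutated_segments: dict[str, list] = {}
    for gene in candidates:
        segs = []
        for seg in spaces[gene].segments:
            sub = mutations_in_space(
                highcadd_mutations, RegulatorySpace(gene, spaces[gene].tissue, [seg], 0.0)
            )
            if len(sub):
                segs.append(seg)
        mutated_segments[gene] = segs

    parent = {g: g for g in candidates}

    def find(g: str) -> str:
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    cand = list(candidates)
    for i, g1 in enumerate(cand):
        for g2 in cand[i + 1:]:
            if any(s1.overlaps(s2) for s1 in mutated_segments[g1] for s2 in mutated_segments[g2]):
                parent[find(g1)] = find(g2)

    groups: dict[str, list[str]] = {}
    for g in cand:
        groups.setdefault(find(g), []).append(g)

    flags: dict[str, float] = {}
    for members in groups.values():
        if len(members) < 2:
            continue
        ranked = sorted(
            members,
            key=lambda g: (-score_e.get(g, float("-inf")), -abs(size_effect.get(g, 0.0)), g),
        )
        winner = ranked[0]
        for loser in ranked[1:]:
            flags[loser] = score_e.get(winner, float("nan"))
    return flags


def size_effect_filter(
    size_effect: Mapping[str, float], cut: float = SIZE_EFFECT_CUT
) -> dict[str, float]:
    """Flag candidates with |expression size effect| strictly below the cut."""
    return {
        gene: abs(effect)
        for gene, effect in size_effect.items()
        if np.isfinite(effect) and abs(effect) < cut
    }


def apply_confidence_filters(
    calls: pd.DataFrame,
    gene_stats: pd.DataFrame,
    spaces: Mapping[str, RegulatorySpace],
    highcadd_mutations: pd.DataFrame,
) -> pd.DataFrame:
    """Annotate all three confidence flags on a candidate call table.

    The filters are order-independent and only append to a
    ``confidence_flags`` column; candidacy, P-values and q-values are never
    altered.
    """
    calls = calls.copy()
    candidates = list(calls.loc[calls["is_candidate"], "gene_id"])
    score_e = {
        g: (-np.log10(p) if np.isfinite(p) and p > 0 else float("nan"))
        for g, p in zip(calls["gene_id"], calls["p_e"])
    }
    size_effect = dict(zip(calls["gene_id"], calls["size_effect"]))

    neighbor = neighbor_ratio_filter(candidates, gene_stats)
    shared = shared_region_filter(candidates, spaces, highcadd_mutations, score_e, size_effect)
    low = size_effect_filter({g: size_effect[g] for g in candidates})

    flag_sets = []
    for gene, cand in zip(calls["gene_id"], calls["is_candidate"]):
        flags = set()
        if cand:
            if gene in neighbor:
                flags.add(FLAG_NEIGHBOR)
            if gene in shared:
                flags.add(FLAG_SHARED)
            if gene in low:
                flags.add(FLAG_SIZE)
        flag_sets.append(",".join(sorted(flags)))
    calls["confidence_flags"] = flag_sets
    return calls
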