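"""Downstream characterisation of called driver candidates.

Enrichment of known cancer driver genes (CDGs), oncogenes and tumour
suppressors among candidate targets; trinucleotide-normalised mutational
profiles and cosine similarity to signature catalogs; enrichment of
motif-breaking / motif-gaining TFBS events; mutation-to-TSS distance
summaries; knockout-screen essentiality summaries with tissue-matched
resampling; and the recurrent "top hit" selection used for the B-cell
lymphoma subset.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genome import Genome, SBS_CHANNELS_96, TRINUCLEOTIDES_32, collapse_substitution, collapse_trinucleotide, trinucleotide_counts
from .intervals import GeneAnnotation, GenomicInterval

logger = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Observed/expected overlap of candidates with an annotated gene set."""

    observed: int        # O: annotated genes among candidates
    expected: float      # E = R * D / G
    n_candidates: int    # R
    n_annotated: int     # D
    n_universe: int      # G
    log2_fc: float
    fisher_p: float


def cdg_enrichment(
    candidate_genes: Iterable[str],
    annotated_set: Iterable[str],
    universe: Iterable[str],
) -> EnrichmentResult:
    """Fold-enrichment log2(O/E) of an annotated gene set among candidates.

    All counts are restricted to the analysis universe (expressed genes with
    enhancers in the tissue); the P-value is a two-tailed Fisher's exact test
    on the candidate x annotated 2x2 table.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty analysis universe")
    cand = set(candidate_genes) & universe
    annot = set(annotated_set) & universe
    if set(candidate_genes) - universe:
        raise ValueError("candidate genes must lie within the universe")
    O = len(cand & annot)
    R, D, G = len(cand), len(annot), len(universe)
    E = R * D / G
    table = [[O, R - O], [D - O, G - R - (D - O)]]
    fisher_p = float(stats.fisher_exact(table, alternative="two-sided")[1])
    log2_fc = np.log2(O / E) if O > 0 and E > 0 else float("-inf")
    return EnrichmentResult(O, E, R, D, G, float(log2_fc), fisher_p)


def oncogene_tsg_enrichment(
    up_genes: Iterable[str],
    down_genes: Iterable[str],
    non_candidate_genes: Iterable[str],
    oncogene_set: Iterable[str],
    tsg_set: Iterable[str],
    non_cdg_set: Iterable[str],
) -> dict[str, dict]:
    """Oncogenes among driver-upregulated and TSGs among driver-downregulated.

    Each arm is a two-tailed Fisher test with rows = (driver-up vs
    non-candidate genes) and columns = (oncogene vs non-CDG), and the
    analogous table for TSGs vs driver-downregulated genes.
    """
    non_cand = set(non_candidate_genes)
    non_cdg = set(non_cdg_set)

    def one_arm(genes: set[str], annotated: set[str]) -> dict:
        a = len(genes & annotated)
        b = len(genes & non_cdg)
        c = len(non_cand & annotated)
        d = len(non_cand & non_cdg)
        if min(a + b, c + d, a + c, b + d) == 0:
            logger.warning("degenerate margin in oncogene/TSG table; p = 1")
            p = 1.0
        else:
            p = float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])
        return {"observed": a, "table": [[a, b], [c, d]], "fisher_p": p}

    return {
        "oncogene_up": one_arm(set(up_genes), set(oncogene_set)),
        "tsg_down": one_arm(set(down_genes), set(tsg_set)),
    }


# ---------------------------------------------------------------------------
# mutational profiles


def region_trinucleotide_frequency(
    genome: Genome, regions: Sequence[GenomicInterval]
) -> pd.Series:
    counts = trinucleotide_counts(genome, regions)
    total = counts.sum()
    if total == 0:
        raise ValueError("regions contain no scorable trinucleotides")
    return pd.Series(counts / total, index=TRINUCLEOTIDES_32)


def mutational_profile(
    mutations: pd.DataFrame,
    genome: Genome,
    region_trinuc_freq: pd.Series,
) -> pd.Series:
    """Region-normalised 96-channel substitution profile of a mutation set.

    Raw pyrimidine-collapsed channel counts are divided by the trinucleotide
    frequency of the matching context in the analysed regions (so sequence
    composition of the regions does not masquerade as a signature), then
    renormalised to sum to 1.
    """
    counts = pd.Series(0.0, index=SBS_CHANNELS_96)
    for _, row in mutations.iterrows():
        trinuc = genome.trinucleotide(row["chrom"], int(row["pos"]))
        channel = collapse_substitution(trinuc, row["alt"])
        counts[channel] += 1.0
    normalised = counts.copy()
    for channel in SBS_CHANNELS_96:
        context = channel[0] + channel[2] + channel[-1]
        freq = float(region_trinuc_freq.get(context, 0.0))
        if counts[channel] > 0 and freq == 0:
            raise ValueError(f"mutations observed in context {context} absent from the regions")
        normalised[channel] = counts[channel] / freq if freq > 0 else 0.0
    total = normalised.sum()
    if total == 0:
        raise ValueError("empty mutational profile")
    return normalised / total


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must have equal length")
    if (a < 0).any() or (b < 0).any():
        raise ValueError("profiles must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine similarity undefined for a zero profile")
    return float(np.dot(a, b) / (na * nb))


def best_signature_match(profile: pd.Series, catalog: pd.DataFrame) -> pd.Series:
    """Cosine similarity of a profile against every catalog signature column."""
    sims = {
        sig: cosine_similarity(profile.to_numpy(), catalog[sig].reindex(profile.index).to_numpy())
        for sig in catalog.columns
    }
    return pd.Series(sims).sort_values(ascending=False)


# ---------------------------------------------------------------------------
# TFBS events


def tfbs_enrichment(
    driver_events: pd.DataFrame,
    n_driver_mutations: int,
    control_events: pd.DataFrame,
    n_control_mutations: int,
) -> pd.DataFrame:
    """Per-event-class enrichment of TFBS changes in driver vs control SNVs.

    Event tables have one row per (mutation, event, TF) with an ``event``
    column in {break, gain}; a mutation with any row counts once per class.
    Rows: any / break / gain; columns: fractions, ratio, two-tailed Fisher p.
    """
    if len(driver_events) == 0 and len(control_events) == 0:
        raise ValueError("no annotated TFBS events in either mutation set")

    def mutated_keys(events: pd.DataFrame, event_class: str | None) -> int:
        sub = events if event_class is None else events[events["event"] == event_class]
        return sub.drop_duplicates(subset=["chrom", "pos", "alt"]).shape[0] if len(sub) else 0

    rows = []
    for label, event_class in (("any", None), ("break", "break"), ("gain", "gain")):
        a = mutated_keys(driver_events, event_class)
        c = mutated_keys(control_events, event_class)
        frac_driver = a / n_driver_mutations if n_driver_mutations else float("nan")
        frac_control = c / n_control_mutations if n_control_mutations else float("nan")
        ratio = frac_driver / frac_control if frac_control else float("inf")
        p = float(
            stats.fisher_exact(
                [[a, n_driver_mutations - a], [c, n_control_mutations - c]],
                alternative="two-sided",
            )[1]
        )
        rows.append((label, a, frac_driver, c, frac_control, ratio, p))
    return pd.DataFrame(
        rows,
        columns=["event", "n_driver", "frac_driver", "n_control", "frac_control", "ratio", "fisher_p"],
    ).set_index("event")


# ---------------------------------------------------------------------------
# mutation-gene distances


def mutation_gene_pairs(
    mutations: pd.DataFrame,
    target_gene: str,
    genes: Mapping[str, GeneAnnotation],
) -> pd.DataFrame:
    """Distance annotation of candidate driver mutations to their target gene.

    For each mutation: |pos - TSS| to the target, and whether the target is
    the closest gene overall / closest protein-coding gene by TSS distance
    (ties count as closest).
    """
    target = genes[target_gene]
    rows = []
    for _, m in mutations.iterrows():
        pos = int(m["pos"])
        dist = abs(pos - target.tss)
        same_chrom = [g for g in genes.values() if g.chrom == m["chrom"]]
        min_all = min(abs(pos - g.tss) for g in same_chrom)
        coding = [g for g in same_chrom if g.gene_type == "protein_coding"]
        min_coding = min((abs(pos - g.tss) for g in coding), default=None)
        rows.append(
            {
                "chrom": m["chrom"],
                "pos": pos,
                "gene_id": target_gene,
                "distance_bp": dist if m["chrom"] == target.chrom else np.inf,
                "gene_is_closest": m["chrom"] == target.chrom and dist <= min_all,
                "gene_is_closest_coding": (
                    m["chrom"] == target.chrom
                    and target.gene_type == "protein_coding"
                    and min_coding is not None
                    and dist <= min_coding
                ),
            }
        )
    return pd.DataFrame(rows)


def distance_summary(pairs: pd.DataFrame) -> dict[str, float]:
    """Fractions of mutation-gene pairs by TSS distance class.

    promoter-range (<= 250 bp), distal (> 20 kb), target-is-closest flags and
    the median distance.
    """
    if len(pairs) == 0:
        raise ValueError("no mutation-gene pairs to summarise")
    d = pairs["distance_bp"].to_numpy(dtype=float)
    return {
        "frac_promoter_250bp": float(np.mean(d <= 250)),
        "frac_distal_20kb": float(np.mean(d > 20_000)),
        "frac_gene_closest": float(pairs["gene_is_closest"].mean()),
        "frac_gene_closest_coding": float(pairs["gene_is_closest_coding"].mean()),
        "median_distance_bp": float(np.median(d)),
    }


# ---------------------------------------------------------------------------
# essentiality (knockout-screen dependency)


def essentiality_summary(
    dependency: pd.DataFrame,
    cellline_expression: pd.DataFrame,
    gene_set: Iterable[str],
    control_genes: Iterable[str],
    line_tissues: pd.Series,
    tissue: str | None = None,
    dep_cut: float = 0.5,
    expr_cut: float = 1.0,
    n_iter: int = 10_000,
    rng: np.random.Generator | None = None,
) -> dict:
    """Dependency-score summaries of a gene set vs control genes.

    ``dependency`` and ``cellline_expression`` are genes x cell-lines; a
    gene's score in a line only counts when its expression there exceeds
    ``expr_cut`` (TPM-like gating of unexpressed genes).  Reports the mean
    expression-gated dependency per gene set, the percentage of dependent
    (score > dep_cut) gene/line pairs, a two-tailed rank-sum comparison of
    per-gene mean dependencies, and — when a tissue is given — the fraction
    of genes with >= 1 dependent tissue-matched line together with a
    resampling P-value against draws of equally many unmatched lines
    (p = 2 x the lower one-tailed proportion, floored at 1/n_iter).
    """
    rng = rng or np.random.default_rng()
    genes = [g for g in gene_set if g in dependency.index]
    ctrl = [g for g in control_genes if g in dependency.index]
    if not genes:
        raise ValueError("gene set has no overlap with the dependency matrix")

    gated = dependency.where(cellline_expression.reindex_like(dependency) > expr_cut)

    def per_gene_mean(rows: list[str], cols: pd.Index) -> pd.Series:
        return gated.loc[rows, cols].mean(axis=1)

    all_lines = dependency.columns
    set_means = per_gene_mean(genes, all_lines)
    ctrl_means = per_gene_mean(ctrl, all_lines)
    sub = gated.loc[genes, all_lines]
    dep_mask = (sub > dep_cut).astype(float).where(sub.notna())  # keep unexpressed as NaN
    pct_dependent = float(np.nanmean(dep_mask.to_numpy()) * 100)
    if len(ctrl_means.dropna()) and len(set_means.dropna()):
        ranksum_p = float(
            stats.mannwhitneyu(set_means.dropna(), ctrl_means.dropna(), alternative="two-sided")[1]
        )
    else:
        ranksum_p = float("nan")

    out = {
        "mean_dependency": float(set_means.mean()),
        "control_mean_dependency": float(ctrl_means.mean()) if len(ctrl) else float("nan"),
        "pct_dependent": pct_dependent,
        "ranksum_p": ranksum_p,
    }

    if tissue is not None:
        matched = [c for c in all_lines if line_tissues.get(c) == tissue]
        if not matched:
            logger.warning("no cell lines for tissue %s; tissue-level outputs missing", tissue)
            return out
        unmatched = [c for c in all_lines if line_tissues.get(c) != tissue]

        def frac_with_dependent_line(cols: list[str]) -> float:
            return float(((gated.loc[genes, cols] > dep_cut).any(axis=1)).mean())

        observed = frac_with_dependent_line(matched)
        draws = np.empty(n_iter)
        unmatched_arr = np.array(unmatched, dtype=object)
        for i in range(n_iter):
            cols = list(rng.choice(unmatched_arr, size=len(matched), replace=False))
            draws[i] = frac_with_dependent_line(cols)
        lower = float(np.mean(draws <= observed))
        upper = float(np.mean(draws >= observed))
        p = max(2.0 * min(lower, upper), 1.0 / n_iter)
        out.update(
            tissue=tissue,
            n_matched_lines=len(matched),
            frac_genes_with_matched_dependent_line=observed,
            resampling_null_mean=float(draws.mean()),
            resampling_p=min(p, 1.0),
        )
    return out


# ---------------------------------------------------------------------------
# recurrent 'top hit' selection (lymphoma analysis)


def dlbcl_top_hits(
    candidate_mutations: pd.DataFrame,
    tfbs_annotations: pd.DataFrame,
    regulator_classes: Mapping[str, str],
    expression: pd.DataFrame,
    mutation_gene: Mapping[tuple[str, int], str],
    cadd_cut: float = 10.0,
    min_gain: int = 2,
    min_break: int = 3,
    min_fold: float = 3.0,
) -> pd.DataFrame:
    """Rank the most promising recurrent regulatory driver mutations.

    A genomic position qualifies when (a) a mutation there breaks the TFBS of
    a negative regulator of transcription or creates the TFBS of a positive
    regulator ("both"-annotated TFs satisfy either arm), (b) it is high-CADD,
    (c) it recurs in >= ``min_gain`` patients for gains / >= ``min_break``
    for breaks, and (d) the mean expression of the target gene in mutated
    samples is >= ``min_fold``-fold above or below the wild-type median.
    Hits are keyed by position, pooling alternative alleles.
    """
    ann = tfbs_annotations.copy()
    ann["tf_class"] = ann["tf_name"].map(lambda t: regulator_classes.get(t, "unknown"))
    rows = []
    for (chrom, pos), group in candidate_mutations.groupby(["chrom", "pos"], sort=True):
        gene = mutation_gene.get((chrom, int(pos)))
        if gene is None or gene not in expression.index:
            continue
        if not (group["cadd_phred"] >= cadd_cut).any():
            continue
        here = ann[(ann["chrom"] == chrom) & (ann["pos"] == pos)]
        breaks = here[(here["event"] == "break") & (here["tf_class"].isin({"negative", "both"}))]
        gains = here[(here["event"] == "gain") & (here["tf_class"].isin({"positive", "both"}))]
        n_patients = group["sample_id"].nunique()
        qualifies = (len(breaks) > 0 and n_patients >= min_break) or (
            len(gains) > 0 and n_patients >= min_gain
        )
        if not qualifies:
            continue
        mut_samples = [s for s in group["sample_id"].unique() if s in expression.columns]
        wt_samples = [s for s in expression.columns if s not in set(group["sample_id"])]
        wt_median = float(expression.loc[gene, wt_samples].median()) if wt_samples else 0.0
        if wt_median == 0:
            logger.warning("zero wild-type median expression for %s at %s:%d; hit excluded", gene, chrom, pos)
            continue
        folds = expression.loc[gene, mut_samples].astype(float) / wt_median
        mean_fold = float(folds.mean()) if len(folds) else float("nan")
        if not (mean_fold >= min_fold or (mean_fold > 0 and mean_fold <= 1.0 / min_fold)):
            continue
        rows.append(
            {
                "chrom": chrom,
                "pos": int(pos),
                "gene_id": gene,
                "n_patients": int(n_patients),
                "events": sorted(set(here["event"])),
                "tfs": sorted(set(breaks["tf_name"]) | set(gains["tf_name"])),
                "mean_fold_change": mean_fold,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["chrom", "pos", "gene_id", "n_patients", "events", "tfs", "mean_fold_change"],
    )
    if len(out):
        out = out.sort_values(
            ["n_patients", "mean_fold_change"], ascending=[False, False]
        ).reset_index(drop=True)
    return out
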