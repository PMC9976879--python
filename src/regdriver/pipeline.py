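"""End-to-end orchestration: sample QC to confidence-flagged driver calls."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import background as bg
from . import calling
from .cohort import (
    count_mutated_samples,
    filter_hypermutator_samples,
    highcadd_frequency,
    mutations_in_space,
    select_highcadd_snvs,
    theoretical_highcadd_count,
)
from .confidence import apply_confidence_filters
from .context import cdg_enrichment
from .expression import expression_pvalue
from .intervals import build_regulatory_space, flanking_regions

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable knobs of a pipeline run (defaults are the study conditions)."""

    cadd_cutoff: float = 10.0
    pm_cut: float = calling.PM_CUT
    pe_cut: float = calling.PE_CUT
    q_cut: float = calling.Q_CUT
    pad: int = 250
    flank: int = 50_000
    min_snvs: int = 2
    screen_p_cut: float = 0.001
    glm_mode: str = "frequency"          # or "offset"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pm_cut", "pe_cut", "q_cut"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1)")


@dataclass
class PipelineResult:
    results: pd.DataFrame                 # one row per analysed gene
    fit: bg.BackgroundFit
    spaces: dict
    flanks: dict
    retained_samples: list[str]
    rna_samples: list[str]
    highcadd: pd.DataFrame
    universe: list[str]
    config: RunConfig

    @property
    def candidates(self) -> list[str]:
        return list(self.results.loc[self.results["is_candidate"], "gene_id"])

    def write(self, outdir: str | Path) -> None:
        from .io import write_candidates_bed, write_results_tsv

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        write_results_tsv(self.results, out / "results.tsv")
        write_candidates_bed(self.spaces, self.candidates, out / "candidates.bed")
        with open(out / "background_fit.json", "w") as fh:
            json.dump(self.fit.to_dict(), fh, indent=1, sort_keys=True)
        with open(out / "run_config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=1, sort_keys=True)


def expressed_universe(expression: pd.DataFrame, rna_samples: list[str]) -> set[str]:
    """Analysis universe: genes with median expression > 0 in RNA samples."""
    cols = [s for s in rna_samples if s in expression.columns]
    if not cols:
        return set()
    med = expression[cols].median(axis=1)
    return set(med.index[med > 0])


def run_pipeline(bundle, config: RunConfig | None = None) -> PipelineResult:
    """Run QC, space construction, both evidence channels and driver calling.

    ``bundle`` provides genome, chrom_sizes, genes, links, repl_track, cadd,
    mutations, expression, cnv, samples and exposures (see ``io.InputBundle``
    and ``synthetic.SyntheticCohort``).  Deterministic given inputs.
    """
    cfg = config or RunConfig()

    # 1. sample QC by signature exposure
    retained = [
        s
        for s in filter_hypermutator_samples(bundle.exposures)
        if s in set(bundle.samples["sample_id"])
    ]
    k = len(retained)
    if k == 0:
        raise ValueError("no samples retained after hypermutator exclusion")
    rna_flag = dict(zip(bundle.samples["sample_id"], bundle.samples["has_rna"]))
    rna_samples = [s for s in retained if rna_flag.get(s, False)]
    mutations = bundle.mutations[bundle.mutations["sample_id"].isin(retained)].reset_index(drop=True)

    # 2. regulatory spaces and flanks
    spaces = build_regulatory_space(bundle.links, bundle.genes, pad=cfg.pad, chrom_sizes=bundle.chrom_sizes)
    all_enhancers = [l.enhancer for l in bundle.links]
    coding_all = [iv for g in bundle.genes.values() for iv in g.coding_intervals]

    universe = sorted(
        set(spaces) & expressed_universe(bundle.expression, rna_samples)
    )
    if len(universe) < 30:
        raise ValueError(f"analysis universe too small ({len(universe)} genes)")

    # 3. high-CADD selection and per-gene accounting
    highcadd = select_highcadd_snvs(mutations, cutoff=cfg.cadd_cutoff, cadd=bundle.cadd)
    rows = []
    features = {}
    flanks = {}
    for gene in universe:
        space = spaces[gene]
        s = theoretical_highcadd_count(space, bundle.cadd, cutoff=cfg.cadd_cutoff)
        if s == 0:
            logger.info("%s has no theoretical high-CADD mutations; excluded", gene)
            continue
        n, per_sample = count_mutated_samples(space, highcadd)
        fl = flanking_regions(space, all_enhancers, coding_all, flank=cfg.flank, chrom_sizes=bundle.chrom_sizes)
        flanks[gene] = fl
        features[gene] = bg.compute_gene_features(
            space, fl, bundle.genome, bundle.repl_track, mutations, k,
            tissue_median_local_freq=0.0,
        )
        rows.append(
            {
                "gene_id": gene,
                "chrom": space.segments[0].chrom,
                "tss": bundle.genes[gene].tss,
                "n": n,
                "k": k,
                "s": s,
                "freq": highcadd_frequency(n, s, k),
                "n_records": sum(per_sample.values()),
                "mutated_samples": ",".join(sorted(per_sample)),
            }
        )
    stats = pd.DataFrame(rows)
    if len(stats) < 30:
        raise ValueError("too few genes with theoretical high-CADD mutations")

    # impute tissue-median local frequency where flanks were empty
    locals_ = np.array([features[g].local_mut_freq for g in stats["gene_id"]])
    median_local = float(np.median(locals_))
    for g in stats["gene_id"]:
        if features[g].flank_imputed or (
            sum(len(iv) for iv in flanks[g]) == 0
        ):
            features[g].local_mut_freq = median_local

    # 4. background mutagenesis model -> p_M
    X = bg.features_frame({g: features[g] for g in stats["gene_id"]})
    freq = stats["freq"].to_numpy()
    counts = stats["n"].to_numpy(dtype=float)
    offset = (
        np.log(stats["s"].to_numpy(dtype=float) * k) if cfg.glm_mode == "offset" else None
    )
    response = freq if cfg.glm_mode == "frequency" else counts
    selected = bg.univariable_screen(X, response, p_cut=cfg.screen_p_cut, offset=offset)
    fit = bg.fit_background(
        X, response, selected_features=selected, mode=cfg.glm_mode, offset=offset,
        train_meta={"seed": cfg.seed, "cadd_cutoff": cfg.cadd_cutoff},
    )
    f_hat = bg.predict_f(fit, X)
    p_sample = np.empty(len(stats))
    p_m = np.empty(len(stats))
    for i, (n, s) in enumerate(zip(stats["n"], stats["s"])):
        p_sample[i], p_m[i] = bg.mutation_pvalue(int(n), k, float(f_hat[i]), int(s))
    stats["f"] = f_hat
    stats["p_sample"] = p_sample
    stats["expected_n"] = k * p_sample
    stats["p_m"] = p_m
    stats["score_m"] = [bg.score_from_pvalue(p) for p in p_m]

    # 5. expression model -> p_E
    rna_in_expr = [s for s in rna_samples if s in bundle.expression.columns]
    p_e = []
    size_effect = []
    n_mut_rna = []
    for _, row in stats.iterrows():
        gene = row["gene_id"]
        in_space = mutations_in_space(highcadd, spaces[gene])
        in_space_rna = in_space[in_space["sample_id"].isin(rna_in_expr)]
        mut_status = pd.Series(0.0, index=pd.Index(rna_in_expr))
        mut_status[mut_status.index.isin(set(in_space_rna["sample_id"]))] = 1.0
        expr_row = bundle.expression.loc[gene, rna_in_expr]
        cnv_row = (
            bundle.cnv.loc[gene, rna_in_expr]
            if bundle.cnv is not None and gene in bundle.cnv.index
            else None
        )
        est = expression_pvalue(
            gene, expr_row, mut_status, cnv_row, n_snvs_rna=len(in_space_rna), min_snvs=cfg.min_snvs
        )
        p_e.append(est.p_e)
        size_effect.append(est.size_effect)
        n_mut_rna.append(est.n_mut_rna)
    stats["p_e"] = p_e
    stats["size_effect"] = size_effect
    stats["n_mut_rna"] = n_mut_rna
    stats["score_e"] = [
        bg.score_from_pvalue(p) if np.isfinite(p) else np.nan for p in stats["p_e"]
    ]

    # 6. combine, adjust, call
    stats["combined_p"] = calling.combine_pvalues_brown(
        stats["p_m"].to_numpy(), stats["p_e"].to_numpy()
    )
    stats["q"] = calling.bh_adjust(stats["combined_p"].to_numpy())
    stats = calling.call_candidates(stats, cfg.pm_cut, cfg.pe_cut, cfg.q_cut)

    # 7. post-hoc confidence annotation
    stats = apply_confidence_filters(stats, stats, spaces, highcadd)

    return PipelineResult(
        results=stats.reset_index(drop=True),
        fit=fit,
        spaces=spaces,
        flanks=flanks,
        retained_samples=retained,
        rna_samples=rna_samples,
        highcadd=highcadd,
        universe=sorted(stats["gene_id"]),
        config=cfg,
    )


def crossvalidate_background(bundle, config: RunConfig | None = None, folds=None) -> pd.DataFrame:
    """Chromosome-fold cross-validation of the background model on a bundle."""
    cfg = config or RunConfig()
    result = run_pipeline(bundle, cfg)
    stats = result.results
    X = bg.features_frame(
        {
            g: bg.compute_gene_features(
                result.spaces[g], result.flanks[g], bundle.genome, bundle.repl_track,
                bundle.mutations[bundle.mutations["sample_id"].isin(result.retained_samples)],
                len(result.retained_samples), tissue_median_local_freq=0.0,
            )
            for g in stats["gene_id"]
        }
    )
    return bg.crossvalidate(
        X,
        stats["freq"].to_numpy(),
        stats["n"].to_numpy(dtype=float),
        stats["s"].to_numpy(),
        int(stats["k"].iloc[0]),
        stats["chrom"].tolist(),
        folds=folds,
        p_cut=cfg.screen_p_cut,
        mode=cfg.glm_mode,
    )


def cadd_cutoff_sweep(
    bundle,
    cdg_set,
    cutoffs=tuple(range(0, 24, 2)),
    config: RunConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Re-run selection + calling per CADD cutoff and correlate enrichment.

    Returns the per-cutoff table (cutoff, candidates, CDG log2 enrichment)
    and the Pearson correlation of cutoff vs log2 enrichment over the
    cutoffs with a defined enrichment.
    """
    from dataclasses import replace

    cfg = config or RunConfig()
    rows = []
    for cutoff in cutoffs:
        try:
            res = run_pipeline(bundle, replace(cfg, cadd_cutoff=float(cutoff)))
        except ValueError as exc:
            logger.warning("cutoff %s failed: %s", cutoff, exc)
            rows.append((cutoff, 0, np.nan, np.nan))
            continue
        enr = cdg_enrichment(res.candidates, cdg_set, res.universe)
        lfc = enr.log2_fc if np.isfinite(enr.log2_fc) else np.nan
        if not res.candidates:
            lfc = np.nan
            logger.info("cutoff %s yields no candidates; point excluded", cutoff)
        rows.append((cutoff, len(res.candidates), lfc, enr.fisher_p))
    table = pd.DataFrame(rows, columns=["cutoff", "n_candidates", "log2_fc", "fisher_p"])
    r = calling.cutoff_trend(table["cutoff"].to_numpy(), table["log2_fc"].to_numpy())
    return table, r
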