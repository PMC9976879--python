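"""Seeded toy genomes and tumour cohorts with known ground truth.

The generator emulates the full input bundle of the driver-discovery
pipeline: a random reference genome, gene annotations with coding exons, a
tissue enhancer-gene map with base activities, a stepped replication-timing
track, a CADD-like per-position per-alt pathogenicity table, per-sample
somatic SNVs, an expression matrix with copy-number-linked scaling, a
signature-exposure table and TFBS event annotations.

Mutagenesis follows the same generative model the background GLM assumes:
each theoretical high-CADD (position, alt) pair in a gene's regulatory space
mutates per sample with probability ``f = exp(b0 + b_repl * timing +
b_act * (activity - 1))``; a configurable subset of *spiked driver* genes
gets that rate multiplied and their mutated samples' expression scaled by
``exp(beta)``, so both the recurrence and the expression channel carry
signal.  Everything is drawn from one seeded generator; identical configs
give byte-identical bundles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import CaddTable
from .genome import BASES, Genome, SteppedTrack
from .intervals import (
    EnhancerGeneLink,
    GeneAnnotation,
    GenomicInterval,
    build_regulatory_space,
    merge_intervals,
)

PAD = 250  # enhancer padding used when deriving the true regulatory spaces

TF_CLASSES = {
    "TF_ACT1": "positive",
    "TF_ACT2": "positive",
    "TF_REP1": "negative",
    "TF_REP2": "negative",
    "TF_DUAL": "both",
}


@dataclass
class SyntheticConfig:
    """Study conditions of the simulated cohort (all randomness via ``seed``)."""

    seed: int
    n_chromosomes: int = 6
    chrom_length: int = 2_000_000
    include_x: bool = False
    n_genes: int = 300
    min_enhancers: int = 1
    max_enhancers: int = 3
    enhancer_share_prob: float = 0.10
    max_enhancer_distance: int = 200_000
    n_samples: int = 200
    rna_fraction: float = 0.6
    background_intercept: float = -11.6
    background_repl_coef: float = 0.35
    background_activity_coef: float = 0.30
    high_cadd_density: float = 0.10
    n_spiked_drivers: int = 10
    spiked_rate_multiplier: float = 10.0
    spiked_expression_beta: float = 1.0
    spiked_up_fraction: float = 0.8
    genomewide_rate: float = 1.2e-6       # SNVs per bp per sample outside enhancers
    expression_baseline_log_mean: float = float(np.log(500.0))
    expression_baseline_log_sd: float = 0.6
    expression_noise_sd: float = 0.5
    cnv_noise_sd: float = 0.15
    n_hypermutators: int = 4
    hypermutator_rate_multiplier: float = 5.0
    n_ig_genes: int = 0
    tfbs_driver_fraction: float = 0.5
    tfbs_background_fraction: float = 0.15
    tissue: str = "toy_tissue"

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_samples"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.max_enhancer_distance * 2 >= self.chrom_length:
            raise ValueError("enhancer placement window exceeds chromosome length")


@dataclass
class GroundTruth:
    driver_genes: list[str]
    true_f: dict[str, float]            # per-gene expected frequency (incl. spike)
    true_beta: dict[str, float]         # per-gene expression effect (0 for nulls)


@dataclass
class SyntheticCohort:
    """Full in-memory input bundle plus ground truth."""

    config: SyntheticConfig
    genome: Genome
    chrom_sizes: dict[str, int]
    genes: dict[str, GeneAnnotation]
    links: list[EnhancerGeneLink]
    repl_track: SteppedTrack
    cadd_df: pd.DataFrame
    mutations: pd.DataFrame
    expression: pd.DataFrame            # genes x samples
    cnv: pd.DataFrame                   # genes x samples
    samples: pd.DataFrame               # sample_id, tissue, has_rna
    exposures: pd.DataFrame             # samples x signatures
    tfbs: pd.DataFrame
    truth: GroundTruth
    cadd: CaddTable = field(init=False)

    def __post_init__(self) -> None:
        self.cadd = CaddTable(self.cadd_df)

    def write(self, outdir: str | Path) -> None:
        """Serialise the bundle in the package's native TSV dialects."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "genome.fa", "w") as fh:
            for chrom in sorted(self.chrom_sizes):
                fh.write(f">{chrom}\n")
                seq = self.genome.sequence(chrom, 0, self.chrom_sizes[chrom])
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        gene_rows = []
        for g in self.genes.values():
            blocks = ";".join(f"{iv.start}-{iv.end}" for iv in g.coding_intervals)
            gene_rows.append((g.gene_id, g.gene_type, g.strand, g.chrom, g.tss, blocks))
        pd.DataFrame(
            gene_rows, columns=["gene_id", "gene_type", "strand", "chrom", "tss", "coding_blocks"]
        ).to_csv(out / "genes.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                (l.enhancer.chrom, l.enhancer.start, l.enhancer.end, l.gene_id, l.tissue, l.base_activity)
                for l in self.links
            ],
            columns=["chrom", "start", "end", "TargetGene", "CellType", "base_activity"],
        ).to_csv(out / "enhancers.tsv", sep="\t", index=False, float_format="%.6g")
        track_rows = []
        for chrom in sorted(self.repl_track.steps):
            starts, ends, values = self.repl_track.steps[chrom]
            for s, e, v in zip(starts, ends, values):
                track_rows.append((chrom, int(s), int(e), float(v)))
        pd.DataFrame(track_rows, columns=["chrom", "start", "end", "value"]).to_csv(
            out / "repl_timing.bedgraph", sep="\t", index=False, header=False, float_format="%.6g"
        )
        cadd_1based = self.cadd_df.copy()
        cadd_1based["pos"] = cadd_1based["pos"] + 1
        cadd_1based.to_csv(out / "cadd.tsv", sep="\t", index=False, float_format="%.4f")
        muts = self.mutations.copy()
        muts["pos"] = muts["pos"] + 1
        muts.to_csv(out / "mutations.tsv", sep="\t", index=False, float_format="%.4f")
        self.expression.to_csv(out / "expression.tsv", sep="\t", float_format="%.4f")
        self.cnv.to_csv(out / "cnv.tsv", sep="\t", float_format="%.4f")
        self.samples.to_csv(out / "samples.tsv", sep="\t", index=False)
        self.exposures.to_csv(out / "exposures.tsv", sep="\t", float_format="%.4f")
        tfbs = self.tfbs.copy()
        tfbs["pos"] = tfbs["pos"] + 1
        tfbs.to_csv(out / "tfbs.tsv", sep="\t", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(asdict(self.truth), fh, indent=1, sort_keys=True)


def _place_genes(cfg: SyntheticConfig, rng: np.random.Generator, chroms: list[str]) -> dict[str, GeneAnnotation]:
    genes: dict[str, GeneAnnotation] = {}
    per_chrom = int(np.ceil(cfg.n_genes / len(chroms)))
    margin = cfg.max_enhancer_distance + 10_000
    idx = 0
    for chrom in chroms:
        slots = np.linspace(margin, cfg.chrom_length - margin, per_chrom + 1)
        for i in range(per_chrom):
            if idx >= cfg.n_genes:
                break
            lo, hi = int(slots[i]), int(slots[i + 1]) - 5_000
            tss = int(rng.integers(lo, max(hi, lo + 1)))
            strand = "+" if rng.random() < 0.5 else "-"
            coding = [
                GenomicInterval(chrom, tss + 500, tss + 650),
                GenomicInterval(chrom, tss + 2_000, tss + 2_150),
            ]
            gene_id = f"G{idx + 1:04d}"
            gene_type = "immunoglobulin" if idx < cfg.n_ig_genes else "protein_coding"
            genes[gene_id] = GeneAnnotation(gene_id, gene_type, strand, chrom, tss, coding)
            idx += 1
    return genes


def _place_enhancers(
    cfg: SyntheticConfig, rng: np.random.Generator, genes: dict[str, GeneAnnotation]
) -> list[EnhancerGeneLink]:
    links: list[EnhancerGeneLink] = []
    last_enhancer: dict[str, tuple[GenomicInterval, float]] = {}
    for gene in genes.values():
        n_enh = int(rng.integers(cfg.min_enhancers, cfg.max_enhancers + 1))
        for j in range(n_enh):
            share = (
                j == 0
                and gene.chrom in last_enhancer
                and rng.random() < cfg.enhancer_share_prob
            )
            if share:
                enh, act = last_enhancer[gene.chrom]
            else:
                length = int(rng.integers(300, 1_500))
                offset = int(rng.integers(1_000, cfg.max_enhancer_distance))
                sign = 1 if rng.random() < 0.5 else -1
                start = max(0, gene.tss + sign * offset)
                start = min(start, cfg.chrom_length - length - 1)
                enh = GenomicInterval(gene.chrom, start, start + length)
                act = float(np.exp(rng.normal(0.0, 0.5)))
            links.append(EnhancerGeneLink(enh, gene.gene_id, cfg.tissue, act))
        last = [l for l in links if l.gene_id == gene.gene_id]
        last_enhancer[gene.chrom] = (last[0].enhancer, last[0].base_activity)
    return links


def _cadd_table(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    genome: Genome,
    covered: list[GenomicInterval],
) -> pd.DataFrame:
    """Per-position per-alt PHRED scores over the padded enhancer territory."""
    frames = []
    for iv in covered:
        pos = np.arange(iv.start, iv.end, dtype=np.int64)
        ref_codes = genome.codes(iv.chrom, iv.start, iv.end)
        # the three non-reference alleles per position
        alts_per_base = np.array(
            [[b for b in range(4) if b != ref] for ref in range(4)], dtype=np.uint8
        )
        alt_codes = alts_per_base[ref_codes].reshape(-1)
        pos3 = np.repeat(pos, 3)
        ref3 = np.repeat(ref_codes, 3)
        high = rng.random(len(pos3)) < cfg.high_cadd_density
        phred = np.where(high, 10.0 + 30.0 * rng.random(len(pos3)), 10.0 * rng.random(len(pos3)))
        frames.append(
            pd.DataFrame(
                {
                    "chrom": iv.chrom,
                    "pos": pos3,
                    "ref": np.array(list(BASES))[ref3],
                    "alt": np.array(list(BASES))[alt_codes],
                    "phred": np.round(phred, 4),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Draw a complete cohort bundle with ground truth from one seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)

    chroms = [f"chr{i + 1}" for i in range(cfg.n_chromosomes)]
    if cfg.include_x:
        chroms.append("chrX")
    chrom_sizes = {c: cfg.chrom_length for c in chroms}
    genome = Genome({c: rng.integers(0, 4, cfg.chrom_length).astype(np.uint8) for c in chroms})

    bin_size = 50_000
    track_records = []
    for chrom in chroms:
        edges = np.arange(0, cfg.chrom_length + bin_size, bin_size)
        values = rng.normal(0.0, 1.0, len(edges) - 1)
        for s, e, v in zip(edges[:-1], edges[1:], values):
            track_records.append((chrom, int(s), int(min(e, cfg.chrom_length)), float(v)))
    repl_track = SteppedTrack.from_records(track_records)

    genes = _place_genes(cfg, rng, chroms)
    links = _place_enhancers(cfg, rng, genes)

    padded = merge_intervals(
        [
            GenomicInterval(l.enhancer.chrom, max(0, l.enhancer.start - PAD), l.enhancer.end + PAD)
            for l in links
        ]
    )
    cadd_df = _cadd_table(cfg, rng, genome, padded)
    cadd = CaddTable(cadd_df)
    spaces = build_regulatory_space(links, genes, pad=PAD, chrom_sizes=chrom_sizes)

    # --- samples, exposures, hypermutators -------------------------------
    sample_ids = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    has_rna = np.zeros(cfg.n_samples, dtype=bool)
    has_rna[rng.choice(cfg.n_samples, int(round(cfg.rna_fraction * cfg.n_samples)), replace=False)] = True
    hyper_idx = rng.choice(cfg.n_samples, cfg.n_hypermutators, replace=False) if cfg.n_hypermutators else np.array([], dtype=int)
    rate_mult = np.ones(cfg.n_samples)
    rate_mult[hyper_idx] = cfg.hypermutator_rate_multiplier
    exposures = pd.DataFrame(
        {
            "SBS1": rng.uniform(0.2, 0.5, cfg.n_samples),
            "SBS5": rng.uniform(0.2, 0.5, cfg.n_samples),
            "SBS10a": rng.uniform(0.0, 0.10, cfg.n_samples),
            "SBS6": rng.uniform(0.0, 0.10, cfg.n_samples),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    exposures.iloc[hyper_idx, exposures.columns.get_loc("SBS10a")] = rng.uniform(
        0.3, 0.6, len(hyper_idx)
    )
    samples = pd.DataFrame(
        {"sample_id": sample_ids, "tissue": cfg.tissue, "has_rna": has_rna}
    )

    # --- true rates and spiked drivers -----------------------------------
    eligible = [g for g, sp in spaces.items() if genes[g].gene_type == "protein_coding"]
    eligible_s = {
        g: int(np.sum([np.count_nonzero(cadd.in_interval(seg)[2] >= 10) for seg in spaces[g].segments]))
        for g in eligible
    }
    # spikes go into spaces large enough for a 10x rate to be observable
    spikeable = [g for g in eligible if eligible_s[g] >= 300]
    drivers = sorted(
        rng.choice(spikeable, size=min(cfg.n_spiked_drivers, len(spikeable)), replace=False).tolist()
    )
    true_f: dict[str, float] = {}
    true_beta: dict[str, float] = {}
    for g in eligible:
        sp = spaces[g]
        eta = (
            cfg.background_intercept
            + cfg.background_repl_coef * repl_track.mean_over(sp.segments)
            + cfg.background_activity_coef * (sp.mean_base_activity - 1.0)
        )
        f = float(np.exp(eta))
        beta = 0.0
        if g in drivers:
            f *= cfg.spiked_rate_multiplier
            sign = 1.0 if rng.random() < cfg.spiked_up_fraction else -1.0
            beta = sign * cfg.spiked_expression_beta
        true_f[g] = f
        true_beta[g] = beta

    # --- in-space mutations ----------------------------------------------
    mut_rows: list[tuple] = []
    mutated_samples: dict[str, set[str]] = {g: set() for g in eligible}
    for g in eligible:
        sp = spaces[g]
        pos_all, alt_all, phred_all = [], [], []
        for seg in sp.segments:
            p, a, ph = cadd.in_interval(seg)
            pos_all.append(p)
            alt_all.append(a)
            phred_all.append(ph)
        pos_all = np.concatenate(pos_all)
        alt_all = np.concatenate(alt_all)
        phred_all = np.concatenate(phred_all)
        chrom = sp.segments[0].chrom
        for mask, rate in (
            (phred_all >= 10.0, true_f[g]),                       # under selection if spiked
            (phred_all < 10.0, float(np.exp(
                cfg.background_intercept
                + cfg.background_repl_coef * repl_track.mean_over(sp.segments)
                + cfg.background_activity_coef * (sp.mean_base_activity - 1.0)
            ))),                                                  # low-CADD: background only
        ):
            n_pairs = int(mask.sum())
            if n_pairs == 0:
                continue
            counts = rng.binomial(n_pairs, np.minimum(rate * rate_mult, 1.0))
            for j in np.nonzero(counts)[0]:
                chosen = rng.choice(n_pairs, size=min(counts[j], n_pairs), replace=False)
                idx = np.nonzero(mask)[0][chosen]
                for i in idx:
                    pos = int(pos_all[i])
                    mut_rows.append(
                        (sample_ids[j], chrom, pos, genome.base(chrom, pos), alt_all[i], float(phred_all[i]))
                    )
                    if phred_all[i] >= 10.0:
                        mutated_samples[g].add(sample_ids[j])

    # --- genome-wide background SNVs outside enhancers --------------------
    alts_per_base = np.array([[b for b in range(4) if b != ref] for ref in range(4)], dtype=np.uint8)
    covered_by_chrom: dict[str, np.ndarray] = {}
    for iv in padded:
        covered_by_chrom.setdefault(iv.chrom, [])
        covered_by_chrom[iv.chrom].append((iv.start, iv.end))
    total_mult = float(rate_mult.sum())
    sample_prob = rate_mult / total_mult
    for chrom in chroms:
        starts, ends, values = repl_track.steps[chrom]
        for s, e, v in zip(starts, ends, values):
            expected = cfg.genomewide_rate * np.exp(cfg.background_repl_coef * v) * (e - s) * total_mult
            n_events = rng.poisson(expected)
            if n_events == 0:
                continue
            positions = rng.integers(s, e, n_events)
            for pos in positions:
                inside = any(a <= pos < b for a, b in covered_by_chrom.get(chrom, []))
                if inside:
                    continue
                sample = sample_ids[int(rng.choice(cfg.n_samples, p=sample_prob))]
                ref_code = int(genome.chromosomes[chrom][pos])
                alt = BASES[int(alts_per_base[ref_code][rng.integers(0, 3)])]
                high = rng.random() < cfg.high_cadd_density
                phred = 10.0 + 30.0 * rng.random() if high else 10.0 * rng.random()
                mut_rows.append((sample, chrom, int(pos), BASES[ref_code], alt, round(float(phred), 4)))

    mutations = (
        pd.DataFrame(mut_rows, columns=["sample_id", "chrom", "pos", "ref", "alt", "cadd_phred"])
        .drop_duplicates(subset=["sample_id", "chrom", "pos", "alt"])
        .sort_values(["chrom", "pos", "sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )

    # --- expression and CNV ------------------------------------------------
    gene_index = pd.Index(sorted(genes), name="gene_id")
    cnv = pd.DataFrame(
        2.0 * np.exp(rng.normal(0.0, cfg.cnv_noise_sd, (len(gene_index), cfg.n_samples))),
        index=gene_index,
        columns=sample_ids,
    )
    baseline = np.exp(
        rng.normal(cfg.expression_baseline_log_mean, cfg.expression_baseline_log_sd, len(gene_index))
    )
    noise = np.exp(rng.normal(0.0, cfg.expression_noise_sd, (len(gene_index), cfg.n_samples)))
    expr = baseline[:, None] * (cnv.to_numpy() / 2.0) * noise
    expression = pd.DataFrame(expr, index=gene_index, columns=sample_ids)
    for g, beta in true_beta.items():
        if beta != 0.0 and mutated_samples.get(g):
            cols = sorted(mutated_samples[g])
            expression.loc[g, cols] *= float(np.exp(beta))

    # --- TFBS event annotations -------------------------------------------
    tf_names = sorted(TF_CLASSES)
    tfbs_rows = []
    driver_space_mask = np.zeros(len(mutations), dtype=bool)
    for g in drivers:
        for seg in spaces[g].segments:
            driver_space_mask |= (
                (mutations["chrom"] == seg.chrom)
                & (mutations["pos"] >= seg.start)
                & (mutations["pos"] < seg.end)
            ).to_numpy()
    for i, row in mutations.iterrows():
        frac = cfg.tfbs_driver_fraction if driver_space_mask[i] else cfg.tfbs_background_fraction
        if rng.random() >= frac:
            continue
        event = "gain" if rng.random() < 0.35 else "break"
        tf = tf_names[int(rng.integers(0, len(tf_names)))]
        tfbs_rows.append((row["chrom"], int(row["pos"]), row["alt"], event, tf, TF_CLASSES[tf]))
    tfbs = pd.DataFrame(
        tfbs_rows, columns=["chrom", "pos", "alt", "event", "tf_name", "tf_regulator_class"]
    ).drop_duplicates()

    truth = GroundTruth(driver_genes=drivers, true_f=true_f, true_beta=true_beta)
    return SyntheticCohort(
        config=cfg,
        genome=genome,
        chrom_sizes=chrom_sizes,
        genes=genes,
        links=links,
        repl_track=repl_track,
        cadd_df=cadd_df,
        mutations=mutations,
        expression=expression,
        cnv=cnv,
        samples=samples,
        exposures=exposures,
        tfbs=tfbs,
        truth=truth,
    )


def evaluate_against_truth(calls: pd.DataFrame, truth: GroundTruth) -> dict[str, float]:
    """Sensitivity / precision / observed FDR of candidate calls vs the spikes."""
    if not truth.driver_genes:
        raise ValueError("ground truth contains no drivers; sensitivity undefined")
    called = set(calls.loc[calls["is_candidate"], "gene_id"])
    true_set = set(truth.driver_genes)
    tp = len(called & true_set)
    fp = len(called - true_set)
    sensitivity = tp / len(true_set)
    precision = tp / len(called) if called else float("nan")
    fdr = fp / len(called) if called else float("nan")
    return {"sensitivity": sensitivity, "precision": precision, "observed_fdr": fdr,
            "n_called": len(called), "n_true": len(true_set)}


def toy_signature_catalog() -> pd.DataFrame:
    """A small synthetic 96-channel signature catalog for similarity tests.

    Contains a flat signature, a C>T-dominated one (deamination-like) and a
    T>A-dominated one.  Channel order matches ``SBS_CHANNELS_96``.
    """
    from .genome import SBS_CHANNELS_96

    idx = pd.Index(SBS_CHANNELS_96, name="channel")
    flat = pd.Series(1.0 / 96, index=idx)
    ct = pd.Series([1.0 if "[C>T]" in c else 0.01 for c in idx], index=idx)
    ta = pd.Series([1.0 if "[T>A]" in c else 0.01 for c in idx], index=idx)
    cat = pd.DataFrame({"SIG_FLAT": flat, "SIG_CT": ct / ct.sum(), "SIG_TA": ta / ta.sum()})
    return cat
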