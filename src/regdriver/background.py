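"""Background mutagenesis model and the recurrence P-value p_M.

The expected high-CADD mutation frequency of each gene's regulatory space is
modelled with a log-link Poisson-family GLM fitted per tissue, one data point
per expressed gene.  The response is the observed frequency ``n / (s k)``
(a non-integer rate handled as quasi-likelihood: the coefficients solve the
Poisson score equations, and a Pearson chi-square dispersion scales every
standard error).  Candidate covariates are the 32 pyrimidine-centred
trinucleotide frequencies, number of positions, GC content, mean replication
timing, mean enhancer base activity, and the local mutation frequency in the
+/- 50 kb non-coding non-enhancer flanks.  Only covariates passing a
univariable prescreen (P < 0.001) enter the multivariable model.

Given the predicted per-theoretical-mutation per-sample frequency ``f``, the
probability that a sample carries at least one high-CADD mutation in a space
with ``s`` theoretical high-CADD mutations is ``p = 1 - (1 - f)^s``, and the
recurrence P-value p_M is the right tail of Binomial(k, p) at the observed
mutated-sample count ``n``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .genome import Genome, SteppedTrack, TRINUCLEOTIDES_32, gc_content, trinucleotide_counts
from .intervals import GenomicInterval, RegulatorySpace

logger = logging.getLogger(__name__)

#: Non-trinucleotide covariates, in canonical order.
SCALAR_FEATURES = [
    "n_positions",
    "gc_content",
    "repl_timing",
    "base_activity",
    "local_mut_freq",
]
ALL_FEATURES = TRINUCLEOTIDES_32 + SCALAR_FEATURES

#: Autosome grouping used for the 6-fold chromosome cross-validation.
HUMAN_AUTOSOME_FOLDS: list[frozenset[str]] = [
    frozenset({"chr1", "chr2"}),
    frozenset({"chr3", "chr4", "chr5"}),
    frozenset({"chr6", "chr7", "chr8"}),
    frozenset({"chr9", "chr10", "chr11"}),
    frozenset({"chr12", "chr13", "chr14", "chr15", "chr16"}),
    frozenset({"chr17", "chr18", "chr19", "chr20", "chr21", "chr22"}),
]

SEX_CHROMOSOMES = frozenset({"chrX", "chrY", "X", "Y"})

F_FLOOR = 1e-12
F_CEIL = 1.0 - 1e-12


@dataclass
class GeneFeatures:
    """Per-gene covariates of the background mutagenesis model."""

    trinuc_freq: np.ndarray          # 32 fractions, sums to 1
    n_positions: int                 # regulatory-space length in bp
    gc_content: float
    repl_timing: float               # length-weighted mean track value
    base_activity: float             # length-weighted mean enhancer activity
    local_mut_freq: float            # SNVs per bp per sample in the flanks
    flank_imputed: bool = False

    def as_series(self) -> pd.Series:
        values = dict(zip(TRINUCLEOTIDES_32, self.trinuc_freq))
        values.update(
            n_positions=self.n_positions,
            gc_content=self.gc_content,
            repl_timing=self.repl_timing,
            base_activity=self.base_activity,
            local_mut_freq=self.local_mut_freq,
        )
        return pd.Series(values, dtype=float)


@dataclass
class BackgroundFit:
    """Fitted background model with z-scoring metadata."""

    selected_features: list[str]
    coefficients: dict[str, float]           # on the z-scored feature scale
    dispersion: float
    feature_means: dict[str, float]
    feature_sds: dict[str, float]
    mode: str = "frequency"                  # or "offset"
    train_meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "selected_features": self.selected_features,
            "coefficients": self.coefficients,
            "dispersion": self.dispersion,
            "feature_means": self.feature_means,
            "feature_sds": self.feature_sds,
            "mode": self.mode,
            "train_meta": self.train_meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BackgroundFit":
        return cls(**d)


def compute_gene_features(
    space: RegulatorySpace,
    flanks: Sequence[GenomicInterval],
    genome: Genome,
    repl_track: SteppedTrack,
    all_mutations: pd.DataFrame,
    k: int,
    tissue_median_local_freq: float | None = None,
) -> GeneFeatures:
    """Assemble the background-model covariates for one gene.

    ``all_mutations`` must contain *all* cohort SNVs (no CADD filter): the
    local mutation frequency estimates raw regional mutagenesis from the
    non-coding non-enhancer flanks as mutations / (flank bp x k).  When the
    flanks are empty the tissue median is imputed and the gene flagged.
    """
    counts = trinucleotide_counts(genome, space.segments)
    total = counts.sum()
    trinuc_freq = counts / total if total else np.zeros(32)

    flank_bp = sum(len(iv) for iv in flanks)
    if flank_bp == 0:
        if tissue_median_local_freq is None:
            raise ValueError(f"{space.gene_id}: empty flanks and no tissue median to impute")
        local = tissue_median_local_freq
        imputed = True
    else:
        in_flanks = 0
        pos = all_mutations["pos"].to_numpy()
        chrom = all_mutations["chrom"].to_numpy()
        for iv in flanks:
            in_flanks += int(np.count_nonzero((chrom == iv.chrom) & (pos >= iv.start) & (pos < iv.end)))
        local = in_flanks / (flank_bp * k)
        imputed = False

    return GeneFeatures(
        trinuc_freq=trinuc_freq,
        n_positions=space.total_length,
        gc_content=gc_content(genome, space.segments),
        repl_timing=repl_track.mean_over(space.segments),
        base_activity=space.mean_base_activity,
        local_mut_freq=local,
        flank_imputed=imputed,
    )


def features_frame(features: Mapping[str, GeneFeatures]) -> pd.DataFrame:
    """Gene x feature matrix in canonical column order."""
    return pd.DataFrame({g: f.as_series() for g, f in features.items()}).T[ALL_FEATURES]


# ---------------------------------------------------------------------------
# GLM machinery


def _glm_fit(y, X, offset=None):
    """Quasi-Poisson fit: Poisson score equations + Pearson chi2/df dispersion.

    The dispersion is attached as ``dispersion`` (a degenerate perfect fit
    keeps unit scale) and applied to standard errors via ``_quasi_bse``
    rather than refit, since IRLS convergence checks misbehave at near-zero
    fixed scales.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # non-integer Poisson endog is intended
        model = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset)
        res = model.fit(maxiter=200)
    phi = res.pearson_chi2 / res.df_resid if res.df_resid > 0 else 1.0
    if not np.isfinite(phi) or phi <= 0:
        phi = 1.0
    res.dispersion = float(phi)
    return res


def _quasi_bse(result) -> np.ndarray:
    return result.bse * np.sqrt(result.dispersion)


def _t_pvalues(result) -> np.ndarray:
    """Two-sided coefficient P-values from the t distribution on residual df."""
    df = max(int(result.df_resid), 1)
    tvals = result.params / _quasi_bse(result)
    return 2 * stats.t.sf(np.abs(tvals), df)


def _zscore(X: pd.DataFrame, means: Mapping[str, float], sds: Mapping[str, float]) -> pd.DataFrame:
    Z = X.copy().astype(float)
    for col in Z.columns:
        sd = sds[col]
        Z[col] = (Z[col] - means[col]) / sd if sd > 0 else 0.0
    return Z


def univariable_screen(
    X: pd.DataFrame,
    response: np.ndarray,
    p_cut: float = 0.001,
    offset: np.ndarray | None = None,
) -> list[str]:
    """Keep covariates individually predictive of the response (P < p_cut).

    Each candidate is z-scored and fitted alone (plus intercept) in the same
    Poisson-family/ dispersion framework as the multivariable model.
    Constant covariates are skipped.  An empty selection (intercept-only
    downstream model) is legitimate.
    """
    if len(X) < 30:
        raise ValueError("univariable screen requires at least 30 genes")
    selected: list[str] = []
    y = np.asarray(response, dtype=float)
    for col in X.columns:
        x = X[col].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or not np.isfinite(sd):
            logger.warning("feature %s is constant; skipped", col)
            continue
        design = sm.add_constant(pd.DataFrame({col: (x - x.mean()) / sd}))
        try:
            res = _glm_fit(y, design, offset=offset)
        except Exception as exc:  # noqa: BLE001 - fit failure excludes feature
            logger.warning("univariable fit failed for %s: %s", col, exc)
            continue
        if _t_pvalues(res)[1] < p_cut:
            selected.append(col)
    return selected


def fit_background(
    X: pd.DataFrame,
    response: np.ndarray,
    selected_features: Sequence[str] | None = None,
    mode: str = "frequency",
    offset: np.ndarray | None = None,
    train_meta: dict | None = None,
) -> BackgroundFit:
    """Fit the multivariable quasi-Poisson background model.

    In ``frequency`` mode the response is the per-gene frequency ``n/(s k)``
    fitted directly; in ``offset`` mode it is the count ``n`` with offset
    ``ln(s k)`` (the orthodox rate formulation — both predict the same
    ``f``).  Features are z-scored on the training set; the transform is
    stored in the fit for prediction.
    """
    y = np.asarray(response, dtype=float)
    if np.all(y == 0):
        raise ValueError("response is identically zero; degenerate likelihood")
    if mode not in {"frequency", "offset"}:
        raise ValueError(f"unknown mode {mode!r}")
    if selected_features is None:
        selected_features = list(X.columns)
    selected_features = [f for f in selected_features if X[f].std() > 0]

    means = {f: float(X[f].mean()) for f in selected_features}
    sds = {f: float(X[f].std()) for f in selected_features}
    Z = _zscore(X[selected_features], means, sds) if selected_features else pd.DataFrame(index=X.index)
    design = sm.add_constant(Z, has_constant="add")
    res = _glm_fit(y, design, offset=offset)
    if not res.converged:
        raise RuntimeError(f"background GLM did not converge after {res.fit_history['iteration']} iterations")

    coef = {name: float(v) for name, v in res.params.items()}
    fit = BackgroundFit(
        selected_features=list(selected_features),
        coefficients=coef,
        dispersion=float(res.dispersion),
        feature_means=means,
        feature_sds=sds,
        mode=mode,
        train_meta=dict(train_meta or {}, n_genes=len(X)),
    )
    fit.train_meta["coef_se"] = {
        name: float(v) for name, v in zip(res.params.index, _quasi_bse(res))
    }
    fit.train_meta["coef_p"] = {
        name: float(p) for name, p in zip(res.params.index, _t_pvalues(res))
    }
    return fit


def predict_f(fit: BackgroundFit, X: pd.DataFrame) -> np.ndarray:
    """Expected frequency per theoretical high-CADD mutation per sample.

    ``f = exp(X beta)`` clamped into [1e-12, 1 - 1e-12]; clamping is logged
    because a predictor above zero signals a degenerate fit or covariate
    drift between train and test.
    """
    missing = [f for f in fit.selected_features if f not in X.columns]
    if missing:
        raise ValueError(f"missing features for prediction: {missing}")
    eta = np.full(len(X), fit.coefficients["const"], dtype=float)
    if fit.selected_features:
        Z = _zscore(X[fit.selected_features], fit.feature_means, fit.feature_sds)
        for name in fit.selected_features:
            eta += fit.coefficients[name] * Z[name].to_numpy(dtype=float)
    f = np.exp(eta)
    n_clamped = int(np.count_nonzero((f < F_FLOOR) | (f > F_CEIL)))
    if n_clamped:
        logger.warning("clamped %d predicted frequencies into [%g, %g]", n_clamped, F_FLOOR, F_CEIL)
    return np.clip(f, F_FLOOR, F_CEIL)


def mutation_pvalue(n: int, k: int, f: float, s: int) -> tuple[float, float]:
    """Per-sample probability and right-sided binomial recurrence P-value.

    ``p_sample = 1 - (1 - f)^s`` and ``p_M = P(X >= n)`` for
    X ~ Binomial(k, p_sample).  ``p_M`` is 1 when ``n = 0``.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if not 0 <= n <= k:
        raise ValueError(f"require 0 <= n <= k, got n={n}, k={k}")
    if s < 1:
        if n > 0:
            raise ValueError("observed mutations in a space with s = 0 theoretical ones")
        raise ValueError("s must be >= 1")
    if not 0 <= f < 1:
        raise ValueError(f"require 0 <= f < 1, got f={f}")
    p_sample = -np.expm1(s * np.log1p(-f))
    p_m = float(stats.binom.sf(n - 1, k, p_sample))
    return float(p_sample), min(max(p_m, 0.0), 1.0)


def score_from_pvalue(p: float) -> float:
    """-log10(p), the display scale of the recurrence/expression evidence."""
    return float(-np.log10(max(p, 1e-300)))


# ---------------------------------------------------------------------------
# cross-validation


def assign_folds(
    chromosomes: Iterable[str],
    folds: Sequence[frozenset[str]] | None = None,
) -> list[frozenset[str]]:
    """Chromosome grouping for cross-validation.

    ``None`` uses the canonical human-autosome grouping when the chromosome
    names match it, otherwise one fold per chromosome (toy genomes).
    """
    chroms = sorted(set(chromosomes))
    if folds is not None:
        return [frozenset(f) for f in folds]
    covered = set().union(*HUMAN_AUTOSOME_FOLDS)
    if set(chroms) - SEX_CHROMOSOMES <= covered:
        return HUMAN_AUTOSOME_FOLDS
    return [frozenset({c}) for c in chroms if c not in SEX_CHROMOSOMES]


def crossvalidate(
    X: pd.DataFrame,
    response: np.ndarray,
    observed_counts: np.ndarray,
    s: np.ndarray,
    k: int,
    chrom_labels: Sequence[str],
    folds: Sequence[frozenset[str]] | None = None,
    p_cut: float = 0.001,
    mode: str = "frequency",
) -> pd.DataFrame:
    """Chromosome-fold cross-validated explained variance of the model.

    For each fold the smaller chromosome set is the test set and the rest the
    training set.  Explained variance is the squared Pearson correlation of
    predicted vs observed mutated-sample counts on the test genes, after
    excluding sex chromosomes and the top 1% most mutated elements (threshold
    computed on the pooled counts before splitting).  Folds with fewer than 3
    usable test genes report NaN.
    """
    chrom_labels = np.asarray(chrom_labels, dtype=object)
    counts = np.asarray(observed_counts, dtype=float)
    usable = ~np.isin(chrom_labels, list(SEX_CHROMOSOMES))
    cutoff = np.quantile(counts[usable], 0.99) if usable.any() else np.inf
    usable &= counts <= cutoff

    rows = []
    for fold in assign_folds(chrom_labels, folds):
        test_mask = usable & np.isin(chrom_labels, list(fold))
        train_mask = usable & ~np.isin(chrom_labels, list(fold))
        if train_mask.sum() < test_mask.sum():  # larger part always trains
            test_mask, train_mask = train_mask, test_mask
        fold_name = ",".join(sorted(fold))
        if test_mask.sum() < 3 or train_mask.sum() < 30:
            logger.warning("fold %s has too few genes; NaN", fold_name)
            rows.append((fold_name, int(test_mask.sum()), np.nan))
            continue
        Xtr, ytr = X.loc[train_mask], response[train_mask]
        off_tr = np.log(s[train_mask] * k) if mode == "offset" else None
        sel = univariable_screen(Xtr, ytr if mode == "frequency" else counts[train_mask],
                                 p_cut=p_cut, offset=off_tr)
        fit = fit_background(
            Xtr,
            ytr if mode == "frequency" else counts[train_mask],
            selected_features=sel,
            mode=mode,
            offset=off_tr,
        )
        f_pred = predict_f(fit, X.loc[test_mask])
        pred_counts = k * (1.0 - np.power(1.0 - f_pred, s[test_mask]))
        obs = counts[test_mask]
        if np.ptp(pred_counts) == 0 or np.ptp(obs) == 0:
            r2 = np.nan
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # near-constant predictions
                r2 = float(stats.pearsonr(pred_counts, obs)[0] ** 2)
        rows.append((fold_name, int(test_mask.sum()), r2))
    return pd.DataFrame(rows, columns=["fold", "n_test", "explained_variance"])
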