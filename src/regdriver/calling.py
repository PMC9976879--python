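"""Combining recurrence and expression evidence into driver calls.

Per gene, p_M (recurrence) and p_E (expression) are combined with the
empirical Brown's method: X = -2(ln p_M + ln p_E) follows a scaled
chi-square whose scale and degrees of freedom are matched to the empirical
covariance of the two -2 ln p statistics across genes, absorbing their
dependence.  Benjamini-Hochberg over the combined P-values yields the
q-value, and a gene is a candidate regulatory driver iff p_M < 0.05,
p_E < 0.05 and q < 0.15, with the direction (up/down) given by the sign of
the expression size effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

PM_CUT = 0.05
PE_CUT = 0.05
Q_CUT = 0.15


@dataclass
class DriverCall:
    gene_id: str
    tissue: str
    p_m: float
    p_e: float
    combined_p: float
    q: float
    is_candidate: bool
    direction: str | None = None           # "up" / "down", candidates only
    size_effect: float = float("nan")
    confidence_flags: set[str] = field(default_factory=set)


def combine_pvalues_brown(p_m: np.ndarray, p_e: np.ndarray) -> np.ndarray:
    """Empirical Brown combination of two dependent P-value vectors.

    Genes with missing p_E get a missing combined P-value and do not enter
    the covariance estimate.  With fewer than 10 complete genes the
    covariance is not estimable and Fisher's method (chi-square, 4 df) is
    used with a warning.  Each -2 ln p term has chi-square(2) margins
    (mean 2, variance 4); the empirical cross-covariance is clipped to the
    attainable [-4, 4] range.
    """
    p_m = np.asarray(p_m, dtype=float)
    p_e = np.asarray(p_e, dtype=float)
    complete = np.isfinite(p_m) & np.isfinite(p_e)
    if ((p_m[np.isfinite(p_m)] <= 0) | (p_m[np.isfinite(p_m)] > 1)).any() or (
        (p_e[complete] <= 0) | (p_e[complete] > 1)
    ).any():
        raise ValueError("P-values must lie in (0, 1]")

    out = np.full(len(p_m), np.nan)
    if complete.sum() == 0:
        return out
    x_m = -2.0 * np.log(p_m[complete])
    x_e = -2.0 * np.log(p_e[complete])
    statistic = x_m + x_e

    if complete.sum() < 10:
        logger.warning(
            "only %d genes with both P-values; falling back to Fisher's method",
            int(complete.sum()),
        )
        out[complete] = stats.chi2.sf(statistic, df=4)
        return out

    cov = float(np.cov(x_m, x_e)[0, 1])
    cov = float(np.clip(cov, -4.0, 4.0))
    mean = 4.0
    var = 8.0 + 2.0 * cov
    scale = var / (2.0 * mean)
    df = 2.0 * mean**2 / var
    out[complete] = stats.chi2.sf(statistic / scale, df=df)
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values; missing in, missing out.

    The number of tests m counts only the non-missing entries.
    """
    p = np.asarray(p, dtype=float)
    out = np.full(len(p), np.nan)
    ok = np.isfinite(p)
    if ok.sum() == 0:
        return out
    out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def call_candidates(
    stats_table: pd.DataFrame,
    pm_cut: float = PM_CUT,
    pe_cut: float = PE_CUT,
    q_cut: float = Q_CUT,
) -> pd.DataFrame:
    """Annotate candidacy and direction on a per-gene stats table.

    ``stats_table`` needs columns ``p_m``, ``p_e``, ``q`` and
    ``size_effect``.  Candidacy requires all three strict inequalities; a
    missing value can never satisfy them.  Direction is defined for
    candidates only.
    """
    df = stats_table.copy()
    with np.errstate(invalid="ignore"):
        cand = (
            (df["p_m"].to_numpy() < pm_cut)
            & (df["p_e"].to_numpy() < pe_cut)
            & (df["q"].to_numpy() < q_cut)
        )
    cand &= np.isfinite(df["p_m"]) & np.isfinite(df["p_e"]) & np.isfinite(df["q"])
    df["is_candidate"] = cand
    direction = np.where(df["size_effect"] > 0, "up", "down")
    df["direction"] = np.where(cand, direction, None)
    return df


def pan_cancer_union(per_tissue: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Union of per-tissue candidates, keyed by gene, provenance retained."""
    rows: dict[str, dict] = {}
    for tissue, calls in per_tissue.items():
        for _, row in calls[calls["is_candidate"]].iterrows():
            entry = rows.setdefault(
                row["gene_id"], {"gene_id": row["gene_id"], "tissues": [], "directions": []}
            )
            entry["tissues"].append(tissue)
            entry["directions"].append(row["direction"])
    out = pd.DataFrame(list(rows.values()), columns=["gene_id", "tissues", "directions"])
    return out.sort_values("gene_id").reset_index(drop=True) if len(out) else out


def cutoff_trend(cutoffs: np.ndarray, log2_enrichments: np.ndarray) -> float:
    """Pearson correlation of CADD cutoff vs log2 CDG enrichment.

    Undefined points (NaN/inf from zero-candidate cutoffs) are excluded;
    fewer than 2 usable points or zero variance is an error / NaN per the
    sweep contract.
    """
    c = np.asarray(cutoffs, dtype=float)
    e = np.asarray(log2_enrichments, dtype=float)
    ok = np.isfinite(c) & np.isfinite(e)
    if ok.sum() < 2:
        raise ValueError("need at least two usable cutoffs for a correlation")
    if np.std(c[ok]) == 0 or np.std(e[ok]) == 0:
        logger.warning("zero variance in sweep; correlation undefined")
        return float("nan")
    return float(stats.pearsonr(c[ok], e[ok])[0])
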