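"""Expression evidence p_E: a GLM of expression on mutation status and CNV.

For each gene, expression (FPKM-UQ-like, non-negative) of the tissue's
RNA-bearing samples is regressed on the binary mutation status MUT (1 when
the sample carries a high-CADD SNV in the gene's regulatory space) and the
gene-level copy number CNV, with a log-link Poisson-family GLM and estimated
dispersion:  FPKM-UQ ~ MUT + CNV.  p_E is the two-sided P-value of the MUT
coefficient's t-statistic and the coefficient itself is the signed size
effect (positive = upregulation in mutated samples).  Genes with fewer than
``min_snvs`` high-CADD SNV records in the space among RNA samples get a
missing p_E, preventing single-mutation artefacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .background import _glm_fit, _t_pvalues, score_from_pvalue

logger = logging.getLogger(__name__)


@dataclass
class GeneExpressionStats:
    gene_id: str
    p_e: float              # NaN when undefined
    size_effect: float      # MUT coefficient on the log scale; NaN when undefined
    n_mut_rna: int
    n_wt_rna: int

    @property
    def score_e(self) -> float:
        return score_from_pvalue(self.p_e) if np.isfinite(self.p_e) else float("nan")


def expression_pvalue(
    gene_id: str,
    expression: pd.Series,
    mut_status: pd.Series,
    cnv: pd.Series | None,
    n_snvs_rna: int,
    min_snvs: int = 2,
) -> GeneExpressionStats:
    """Fit FPKM-UQ ~ MUT + CNV for one gene over RNA-bearing samples.

    All three series are indexed by sample id; samples missing CNV are
    dropped.  ``n_snvs_rna`` is the count of high-CADD SNV *records* (not
    distinct samples) in the gene's space among RNA samples; below
    ``min_snvs`` the P-value is reported missing.
    """
    samples = expression.index
    mut = mut_status.reindex(samples).fillna(0).astype(float)
    n_mut = int((mut > 0).sum())
    n_wt = int(len(samples) - n_mut)

    undefined = GeneExpressionStats(gene_id, float("nan"), float("nan"), n_mut, n_wt)
    if n_snvs_rna < min_snvs:
        return undefined
    y = expression.astype(float)
    if (y < 0).any():
        raise ValueError(f"{gene_id}: negative expression values")
    if (y == 0).all():
        logger.info("%s: all-zero expression; skipped", gene_id)
        return undefined
    if mut.nunique() < 2:
        logger.info("%s: mutation status constant across RNA samples", gene_id)
        return undefined

    design = pd.DataFrame({"MUT": mut})
    if cnv is not None:
        design["CNV"] = cnv.reindex(samples).astype(float)
        keep = design["CNV"].notna()
        if not keep.all():
            design, y = design.loc[keep], y.loc[keep]
            logger.info("%s: dropped %d samples without CNV", gene_id, int((~keep).sum()))
    else:
        logger.info("%s: no CNV table; MUT-only model", gene_id)
    design = sm.add_constant(design)

    try:
        res = _glm_fit(y.to_numpy(), design)
    except Exception as exc:  # noqa: BLE001 - degenerate designs yield missing p_E
        logger.warning("%s: expression GLM failed (%s)", gene_id, exc)
        return undefined
    idx = list(res.params.index).index("MUT")
    p_e = float(_t_pvalues(res)[idx])
    return GeneExpressionStats(gene_id, p_e, float(res.params["MUT"]), n_mut, n_wt)
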