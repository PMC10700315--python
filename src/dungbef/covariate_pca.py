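"""First-axis PCA summaries of climate and paired diversity differences.

Both moderators used downstream are first principal components: one over
the 13 bioclimatic variables of each landscape (``PCA1_Climate``) and one
over the paired low-minus-high differences of the diversity metrics
(``PCA1_Diversity``).  The PCA is computed on the correlation matrix
(variables z-scored), so it is invariant to the heterogeneous units of the
inputs, and the arbitrary eigenvector sign is anchored: the climate axis
is oriented so mean annual temperature loads negatively, the diversity
axis so the FDisBehavior difference loads positively (positive scores then
mean higher diversity under low-intensity management).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ValidationError

__all__ = ["PCASummary", "pca_axis1", "diversity_differences"]

#: Diversity metrics whose paired differences feed the diversity PCA.
DIVERSITY_METRICS = ("abundance", "richness", "fdis_behavior", "fdis_morphology")


@dataclass
class PCASummary:
    """First-axis PCA result on the correlation matrix."""

    scores: pd.Series            # axis-1 score per observation
    loadings: pd.Series          # correlation of each variable with axis 1
    variance_fraction: float     # share of total variance on axis 1
    variance_fractions: pd.Series  # per-axis shares (sum to 1)
    anchor: str
    anchor_sign: int


def pca_axis1(X: pd.DataFrame, anchor: str, anchor_sign: int = 1) -> PCASummary:
    """First principal component of the correlation matrix of ``X``.

    Constant columns are dropped with a warning (they cannot be z-scored).
    The component sign is flipped, if needed, so that the loading of
    ``anchor`` has sign ``anchor_sign``.
    """
    if anchor_sign not in (1, -1):
        raise ValueError("anchor_sign must be +1 or -1")
    X = X.dropna(axis=0)
    if len(X) < 2:
        raise ValueError("PCA needs at least two complete observations")
    sd = X.std(ddof=1)
    keep = sd > 1e-12 * (X.abs().mean() + 1.0)   # constant up to rounding
    if not keep.all():
        warnings.warn(f"constant column(s) dropped from PCA: "
                      f"{list(X.columns[~keep])}", stacklevel=2)
        X = X.loc[:, keep]
    if X.shape[1] < 2:
        raise ValueError("PCA needs at least two non-constant variables")
    if anchor not in X.columns:
        raise KeyError(f"anchor variable {anchor!r} not among the PCA columns")

    Z = (X - X.mean()) / X.std(ddof=1)
    R = np.corrcoef(Z.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    v1 = eigvec[:, 0]
    # variable-axis correlations: loading_j = v_j * sqrt(lambda_1)
    loadings = pd.Series(v1 * np.sqrt(max(eigval[0], 0.0)), index=X.columns)
    if loadings[anchor] * anchor_sign < 0:
        v1, loadings = -v1, -loadings
    scores = pd.Series(Z.to_numpy() @ v1, index=X.index, name="pca1")
    fractions = pd.Series(np.clip(eigval, 0, None) / X.shape[1],
                          index=[f"axis{i+1}" for i in range(len(eigval))])
    return PCASummary(scores=scores, loadings=loadings,
                      variance_fraction=float(fractions.iloc[0]),
                      variance_fractions=fractions,
                      anchor=anchor, anchor_sign=anchor_sign)


def diversity_differences(metrics: pd.DataFrame) -> pd.DataFrame:
    """Low-minus-high paired differences of the diversity metrics.

    ``metrics`` is the per-pasture table from
    :func:`~dungbef.community_diversity.community_metrics`.  Positive
    differences mean higher diversity under low-intensity management.
    Returns one row per landscape with ``d_<metric>`` columns.
    """
    wide = metrics.pivot(index="landscape_id", columns="regime",
                         values=list(DIVERSITY_METRICS))
    for metric in DIVERSITY_METRICS:
        for regime in ("low", "high"):
            if (metric, regime) not in wide.columns or wide[(metric, regime)].isna().any():
                bad = (wide.index[wide[(metric, regime)].isna()][0]
                       if (metric, regime) in wide.columns else wide.index[0])
                raise ValidationError(
                    f"unpaired landscape {bad!r}: missing {regime}-regime {metric}")
    out = pd.DataFrame({
        f"d_{metric}": wide[(metric, "low")] - wide[(metric, "high")]
        for metric in DIVERSITY_METRICS
    })
    return out.reset_index()
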