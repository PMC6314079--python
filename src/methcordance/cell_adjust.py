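"""Reference-based cell-composition estimation and regression adjustment.

Bulk methylation is a mixture over constituent cell types; both tissues
here are heterogeneous, so composition differences masquerade as
inter-individual variation. Proportions are estimated per sample by
constrained least squares of observed signature-CpG betas on reference
cell-type profiles (nonnegative weights summing to one — the projection at
the heart of reference-based deconvolution), and composition-driven
variance is then removed per CpG by regressing betas on the estimated
proportions and keeping recentred residuals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .data_io import BetaMatrix

__all__ = [
    "ReferenceProfiles",
    "ProportionEstimates",
    "estimate_proportions",
    "adjust_composition",
]

#: weight of the sum-to-one row appended to the least-squares system; large
#: enough that the constraint binds to ~1e-10 before the final renormalisation
_SUM_WEIGHT = 1e4


@dataclass
class ReferenceProfiles:
    """Expected beta of each signature CpG in each pure cell type."""

    profiles: pd.DataFrame  # signature probes x cell types

    def __post_init__(self) -> None:
        if self.profiles.shape[1] < 2:
            raise ValueError("need at least 2 cell types")
        arr = self.profiles.to_numpy(dtype=float)
        if np.isnan(arr).any() or (arr < 0).any() or (arr > 1).any():
            raise ValueError("reference profiles must be beta values in [0,1]")

    @property
    def probe_ids(self) -> pd.Index:
        return self.profiles.index

    @property
    def cell_types(self) -> pd.Index:
        return self.profiles.columns


@dataclass
class ProportionEstimates:
    """Estimated cell-type weights per sample (rows sum to 1)."""

    weights: pd.DataFrame  # samples x cell types

    def __post_init__(self) -> None:
        w = self.weights.to_numpy(dtype=float)
        if (w < -1e-9).any():
            raise ValueError("weights must be nonnegative")
        if np.abs(w.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("weights must sum to 1 per sample")

    @property
    def sample_ids(self) -> pd.Index:
        return self.weights.index

    @property
    def cell_types(self) -> pd.Index:
        return self.weights.columns


def estimate_proportions(beta: BetaMatrix, ref: ReferenceProfiles) -> ProportionEstimates:
    """Solve, per sample, min ||R w - b|| subject to w >= 0 and sum(w) = 1.

    R is the reference profile matrix restricted to signature CpGs present
    in ``beta``; the equality constraint is enforced through a heavily
    weighted augmented row, followed by an exact renormalisation.
    """
    common = ref.probe_ids.intersection(beta.probe_ids)
    if len(common) < 2:
        raise ValueError("fewer than 2 signature CpGs present in the beta matrix")
    R = ref.profiles.loc[common].to_numpy(dtype=float)
    k = R.shape[1]
    if np.linalg.matrix_rank(R) < k:
        corr = np.corrcoef(R.T)
        i, j = divmod(int(np.nanargmax(np.abs(corr - np.eye(k)))), k)
        raise ValueError(
            "rank-deficient reference profiles: cell types "
            f"{ref.cell_types[i]!r} and {ref.cell_types[j]!r} are collinear"
        )
    B = beta.values.loc[common].to_numpy(dtype=float)
    A = np.vstack([R, _SUM_WEIGHT * np.ones((1, k))])
    out = np.empty((beta.values.shape[1], k))
    for s in range(B.shape[1]):
        b = B[:, s]
        keep = ~np.isnan(b)
        if keep.sum() < 2:
            raise ValueError(f"sample {beta.sample_ids[s]!r} has < 2 usable signature CpGs")
        rows = np.concatenate([np.flatnonzero(keep), [len(b)]])
        w, _ = nnls(A[rows], np.concatenate([b[keep], [_SUM_WEIGHT]]))
        out[s] = w / w.sum()
    return ProportionEstimates(
        pd.DataFrame(out, index=beta.sample_ids, columns=ref.cell_types)
    )


def adjust_composition(
    beta: BetaMatrix, props: ProportionEstimates
) -> tuple[BetaMatrix, int]:
    """Remove estimated-composition variance from every CpG.

    Per CpG, betas are regressed across samples on k-1 proportion columns
    (one dropped: with rows summing to one the full set is collinear with
    the intercept; results do not depend on which is dropped). The adjusted
    value is the residual plus the intercept plus the mean fitted
    composition contribution, i.e. the sample's beta moved to the average
    composition, then clipped to [0, 1].

    Returns the adjusted matrix and the number of clipped cells.
    """
    if not beta.sample_ids.equals(props.sample_ids):
        if set(beta.sample_ids) != set(props.sample_ids):
            raise ValueError("sample ids of beta and proportions differ")
        props = ProportionEstimates(props.weights.loc[beta.sample_ids])
    n = len(beta.sample_ids)
    k = len(props.cell_types)
    if n < k + 1:  # k-1 covariates + intercept, plus a residual df
        raise ValueError(f"need at least {k + 1} samples to adjust for {k} cell types")
    X = props.weights.iloc[:, :-1].to_numpy(dtype=float)  # drop last cell type
    design = np.column_stack([np.ones(n), X])
    Y = beta.values.to_numpy(dtype=float).T  # samples x probes
    coef, *_ = np.linalg.lstsq(design, np.nan_to_num(Y), rcond=None)
    has_na = np.isnan(Y).any()
    if has_na:
        # refit probes with missing entries individually on observed samples
        for j in np.flatnonzero(np.isnan(Y).any(axis=0)):
            keep = ~np.isnan(Y[:, j])
            if keep.sum() < k + 1:
                coef[:, j] = 0.0
                coef[0, j] = np.nanmean(Y[:, j])
            else:
                coef[:, j], *_ = np.linalg.lstsq(design[keep], Y[keep, j], rcond=None)
    comp = X @ coef[1:]  # composition contribution, samples x probes
    adjusted = Y - comp + comp.mean(axis=0, keepdims=True)
    clipped = int(((adjusted < 0) | (adjusted > 1)).sum())
    adjusted = np.clip(adjusted, 0.0, 1.0)
    adjusted[np.isnan(Y)] = np.nan
    return (
        BetaMatrix(
            pd.DataFrame(adjusted.T, index=beta.probe_ids, columns=beta.sample_ids),
            tissue=beta.tissue,
            cohort=beta.cohort,
        ),
        clipped,
    )
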