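"""Cross-tissue concordance and informative-site calling.

A CpG is *informative* when it is both variable across individuals
(reference range >= 0.05 in both tissues) and highly correlated between
the two tissues. The correlation cutoff is derived per cohort by fitting a
two-component Gaussian mixture to the Spearman rho of highly variable CpGs
(reference range > 0.10 in both tissues): one component captures
uncorrelated CpGs near zero, the other the right-shifted, highly
concordant CpGs; the threshold is the concordant component's mean minus
two of its standard deviations. Informative calls are intersected across
cohorts for the consensus set.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit
from sklearn.mixture import GaussianMixture

from ._stats import rowwise_spearman
from .data_io import BetaMatrix
from .variability import reference_range_rows

__all__ = [
    "cross_tissue_correlation",
    "fit_rho_mixture",
    "call_informative",
    "consensus_informative",
    "MixtureFit",
    "DegenerateFitError",
]


class DegenerateFitError(RuntimeError):
    """The mixture collapsed (components indistinguishable or EM failed)."""


@dataclass
class MixtureFit:
    """Two-component mixture over rho; the higher-mean component defines the
    informative-site correlation threshold (mean - 2 SD)."""

    means: tuple[float, float]  # (low, high)
    sds: tuple[float, float]
    weights: tuple[float, float]
    threshold: float
    converged: bool
    log_likelihood: float
    family: str = "gaussian"

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def cross_tissue_correlation(beta_a: BetaMatrix, beta_b: BetaMatrix) -> pd.DataFrame:
    """Per-CpG Spearman correlation between matched samples of two tissues.

    Midrank tie handling, two-sided p. Probes constant in either tissue
    have no defined rank correlation and are recorded as NaN. Also carries
    each tissue's reference range for downstream informative-site filters.
    """
    if not beta_a.probe_ids.equals(beta_b.probe_ids):
        raise ValueError("probe sets must match")
    if not beta_a.sample_ids.equals(beta_b.sample_ids):
        raise ValueError("samples must be matched and ordered identically")
    if len(beta_a.sample_ids) < 5:
        raise ValueError("need at least 5 matched pairs")
    A = beta_a.values.to_numpy(dtype=float)
    B = beta_b.values.to_numpy(dtype=float)
    rho, p = rowwise_spearman(A, B)
    return pd.DataFrame(
        {
            "spearman_rho": rho,
            "spearman_p": p,
            "rr_a": reference_range_rows(A),
            "rr_b": reference_range_rows(B),
        },
        index=beta_a.probe_ids,
    )


def fit_rho_mixture(
    rho: np.ndarray,
    seed: int = 0,
    n_restarts: int = 10,
    min_separation: float = 0.05,
    family: str = "gaussian",
) -> MixtureFit:
    """Fit a two-component mixture to rho values of highly variable CpGs.

    ``family='gaussian'`` (default) fits on rho directly; rho spans negative
    values, so a Beta family on raw rho is unsupported — ``family='beta'``
    offers a sensitivity variant that fits the Gaussian mixture on
    logit((rho+1)/2) and maps fitted quantiles back.

    EM with k-means initialisation, ``n_restarts`` random restarts keeping
    the best log-likelihood; deterministic given ``seed``. Raises
    :class:`DegenerateFitError` when EM fails to converge or the component
    means are closer than ``min_separation``.
    """
    rho = np.asarray(rho, dtype=float)
    rho = rho[~np.isnan(rho)]
    if rho.size < 200:
        raise ValueError(f"need >= 200 rho values to fit the mixture, got {rho.size}")
    if family not in ("gaussian", "beta"):
        raise ValueError("family must be 'gaussian' or 'beta'")
    if family == "gaussian":
        x = rho
    else:
        x = logit((np.clip(rho, -1 + 1e-9, 1 - 1e-9) + 1.0) / 2.0)
    gm = GaussianMixture(
        n_components=2,
        covariance_type="full",
        n_init=n_restarts,
        init_params="k-means++",
        tol=1e-8,
        max_iter=500,
        random_state=seed,
    ).fit(x[:, None])
    if not gm.converged_:
        raise DegenerateFitError("EM did not converge after restarts")
    means = gm.means_.ravel()
    sds = np.sqrt(gm.covariances_.reshape(-1))
    weights = gm.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]
    if means[1] - means[0] < min_separation:
        raise DegenerateFitError(
            f"component means {means[0]:.3f} and {means[1]:.3f} closer than {min_separation}"
        )
    if family == "gaussian":
        threshold = float(means[1] - 2.0 * sds[1])
    else:
        # back-map the (mean - 2 SD) quantile of the high component to rho scale
        from scipy.special import expit

        threshold = float(2.0 * expit(means[1] - 2.0 * sds[1]) - 1.0)
    return MixtureFit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        threshold=threshold,
        converged=True,
        log_likelihood=float(gm.score(x[:, None]) * x.size),
        family=family,
    )


def call_informative(
    table: pd.DataFrame,
    fit: MixtureFit,
    min_rr: float = 0.05,
) -> pd.Series:
    """Boolean informative flag: rho >= threshold AND reference range >=
    ``min_rr`` in both tissues. ``table`` is a cross_tissue_correlation
    output (columns spearman_rho, rr_a, rr_b)."""
    if not fit.converged:
        raise ValueError("mixture fit did not converge")
    rho = table["spearman_rho"]
    flag = (rho >= fit.threshold) & (table["rr_a"] >= min_rr) & (table["rr_b"] >= min_rr)
    return flag.fillna(False).rename("informative")


def mixture_subset(table: pd.DataFrame, min_rr: float = 0.10) -> np.ndarray:
    """rho values of CpGs with reference range > ``min_rr`` in both tissues —
    the high-variability subset the mixture is fitted on."""
    keep = (table["rr_a"] > min_rr) & (table["rr_b"] > min_rr)
    return table.loc[keep, "spearman_rho"].to_numpy(dtype=float)


def consensus_informative(
    per_cohort_flags: Mapping[str, pd.Series] | Sequence[pd.Series],
) -> pd.Index:
    """Probes informative in every cohort (set intersection)."""
    flags = (
        list(per_cohort_flags.values())
        if isinstance(per_cohort_flags, Mapping)
        else list(per_cohort_flags)
    )
    if len(flags) < 2:
        raise ValueError("need at least two cohorts for a consensus")
    sets = [set(f.index[f.astype(bool)]) for f in flags]
    common = set.intersection(*sets)
    if not common:
        warnings.warn("consensus informative set is empty", stacklevel=2)
    ordered = [p for p in flags[0].index if p in common]
    return pd.Index(ordered, name="probe_id")
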