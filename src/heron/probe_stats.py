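"""Probe-level significance for each positive sample.

Two one-sided tests are available per probe and positive sample:

* a *global* z-test of the probe's signal against the pooled distribution of
  every intensity in the experiment, optionally shifted by a multiple of the
  pooled SD (high absolute binding);
* a *differential* t-test of the positive sample's signal against the
  negative-group mean plus an absolute shift, with the probe's SD estimated
  from the negative samples (binding above control).

When both are enabled they are merged with Wilkinson's max (the Beta(2, 1)
null of the larger of two p-values), and the combined p-values are adjusted
with Benjamini-Hochberg within each positive-sample column.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DegenerateDataError, ProbeDataset, PValueTable, StatParams

logger = logging.getLogger(__name__)

#: lower clip applied to every p-value before log/tan transforms downstream
P_FLOOR = 1e-300


def _clip(p: np.ndarray) -> np.ndarray:
    return np.clip(p, P_FLOOR, 1.0)


def compute_global_pvalues(data: ProbeDataset, sd_shift: float = 0.0) -> PValueTable:
    """One-sided z-test of each positive-sample entry against all pooled data.

    The null is a normal with the mean and SD of *every* cell in the
    intensity matrix (all probes, all samples); ``sd_shift`` is subtracted
    from the z-score, so p = P(Z > (x - mu)/sigma - sd_shift).
    """
    if sd_shift < 0:
        raise ValueError("sd_shift must be non-negative")
    all_values = data.intensities.to_numpy(dtype=float)
    mu = all_values.mean()
    sigma = all_values.std(ddof=0)
    if sigma == 0:
        raise DegenerateDataError("constant intensity matrix: pooled SD is zero")
    pos = data.intensities[data.positive_samples].to_numpy(dtype=float)
    z = (pos - mu) / sigma - sd_shift
    p = _clip(stats.norm.sf(z))
    return PValueTable(
        "global", pd.DataFrame(p, index=data.probe_ids, columns=data.positive_samples)
    )


def compute_differential_pvalues(
    data: ProbeDataset,
    abs_shift: float = 0.0,
    sd_percentile_floor: float = 1.0,
) -> PValueTable:
    """One-sided t-test of each positive sample against the negative group.

    Each positive sample is treated as a single observation sharing the
    probe's negative-group SD:  t = (x - mean_neg - shift) / (sd * sqrt(1 +
    1/n_neg)) with df = n_neg - 1.  Per-probe SDs are floored at the
    ``sd_percentile_floor`` percentile of all per-probe negative SDs so that
    zero-variance probes cannot produce infinite statistics.
    """
    if abs_shift < 0:
        raise ValueError("abs_shift must be non-negative")
    neg_cols = data.negative_samples
    n_neg = len(neg_cols)
    if n_neg < 2:
        raise DegenerateDataError("differential test needs >= 2 negative samples")
    neg = data.intensities[neg_cols].to_numpy(dtype=float)
    pos = data.intensities[data.positive_samples].to_numpy(dtype=float)
    mean_neg = neg.mean(axis=1)
    sd_neg = neg.std(axis=1, ddof=1)
    floor = np.percentile(sd_neg, sd_percentile_floor)
    if floor <= 0:
        positive_sds = sd_neg[sd_neg > 0]
        floor = positive_sds.min() if positive_sds.size else np.finfo(float).eps
    n_floored = int((sd_neg < floor).sum())
    if n_floored:
        logger.warning("floored %d per-probe negative SDs at %.3g", n_floored, floor)
    sd = np.maximum(sd_neg, floor)
    t = (pos - mean_neg[:, None] - abs_shift) / (sd[:, None] * np.sqrt(1.0 + 1.0 / n_neg))
    p = _clip(stats.t.sf(t, df=n_neg - 1))
    return PValueTable(
        "differential", pd.DataFrame(p, index=data.probe_ids, columns=data.positive_samples)
    )


def combine_probe_pvalues(
    p_global: PValueTable | None,
    p_differential: PValueTable | None,
    params: StatParams,
) -> PValueTable:
    """Wilkinson's-max combination of the global and differential layers.

    For two p-values the max order statistic is Beta(2, 1) under the null,
    so the combined p is simply max(p_g, p_d)**2.  With a single enabled
    layer the layer passes through unchanged.
    """
    use_g = params.use_global and p_global is not None
    use_d = params.use_differential and p_differential is not None
    if not (use_g or use_d):
        raise ValueError("no p-value layer enabled")
    if use_g and use_d:
        if p_global.values.shape != p_differential.values.shape:
            raise ValueError("global and differential tables have different shapes")
        merged = np.maximum(p_global.values.to_numpy(), p_differential.values.to_numpy()) ** 2
        frame = pd.DataFrame(
            merged, index=p_global.values.index, columns=p_global.values.columns
        )
    else:
        frame = (p_global if use_g else p_differential).values.copy()
    return PValueTable("combined", frame)


def adjust_bh(p: PValueTable, scope: str = "per_sample") -> PValueTable:
    """Benjamini-Hochberg step-up adjustment.

    ``scope="per_sample"`` adjusts within each positive-sample column over
    all features (each sample's calls are independent decisions);
    ``scope="matrix"`` adjusts over the flattened matrix.
    """
    values = p.values.to_numpy(dtype=float)
    if values.size == 0:
        return PValueTable("adjusted", p.values.copy())
    if scope == "per_sample":
        adj = np.empty_like(values)
        for j in range(values.shape[1]):
            adj[:, j] = multipletests(values[:, j], method="fdr_bh")[1]
    elif scope == "matrix":
        adj = multipletests(values.ravel(), method="fdr_bh")[1].reshape(values.shape)
    else:
        raise ValueError(f"unknown BH scope {scope!r}")
    return PValueTable("adjusted", pd.DataFrame(adj, index=p.values.index, columns=p.values.columns))


def probe_pvalue_layers(
    data: ProbeDataset, params: StatParams
) -> dict[str, PValueTable]:
    """Compute all enabled probe-level layers: global, differential, combined, adjusted."""
    layers: dict[str, PValueTable] = {}
    if params.use_global:
        layers["global"] = compute_global_pvalues(data, params.global_sd_shift)
    if params.use_differential:
        layers["differential"] = compute_differential_pvalues(data, params.diff_abs_shift)
    layers["combined"] = combine_probe_pvalues(
        layers.get("global"), layers.get("differential"), params
    )
    layers["adjusted"] = adjust_bh(layers["combined"], scope=params.bh_scope)
    return layers
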