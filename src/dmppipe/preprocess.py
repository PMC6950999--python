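"""Beta computation, detection-p filtering and within-array normalization.

Beta values follow the standard Illumina form beta = M / (M + U + offset)
with offset 100 by default. The detection filter applies the strict
p < threshold call rule and reports per-sample call rates. Normalization is
a deterministic subset-quantile adjustment that maps type-II probe values
onto the within-sample type-I distribution (probe-type chemistry is not
simulated, so the full CpG-content-matched procedure is not applicable).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["compute_beta", "detection_filter", "normalize_within_array"]


def compute_beta(methylated, unmethylated, offset: float = 100.0):
    """beta = M / (M + U + offset), elementwise; in [0, 1) for offset > 0."""
    if offset <= 0:
        raise ValueError("offset must be positive")
    m = np.asarray(methylated, dtype=float)
    u = np.asarray(unmethylated, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise ValueError("intensities must be non-negative")
    beta = m / (m + u + offset)
    if np.isscalar(methylated) and np.isscalar(unmethylated):
        return float(beta)
    return beta


def detection_filter(
    detection_p: pd.DataFrame, threshold: float = 0.01
) -> tuple[pd.DataFrame, pd.Series, pd.Index]:
    """Apply the strict detection-p call rule.

    Returns
    -------
    (mask, call_rate, failed_probes)
        ``mask``: True where detection_p < threshold (probe called in that
        sample). ``call_rate``: per-sample fraction of called probes.
        ``failed_probes``: probes failing in at least one sample — the
        default policy excludes these from testing.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    mask = detection_p < threshold
    call_rate = mask.mean(axis=0)
    call_rate.name = "call_rate"
    failed = mask.index[~mask.all(axis=1)]
    return mask, call_rate, failed


def normalize_within_array(beta: pd.DataFrame, design_type: pd.Series) -> pd.DataFrame:
    """Quantile-map type-II probe values onto the type-I distribution.

    Per sample, each type-II value at empirical quantile q is replaced by
    the type-I quantile function evaluated at q (plotting positions
    (rank-1)/(n-1), linear interpolation). Type-I values are untouched; rank
    order within each type is preserved; the map is idempotent because ranks
    are unchanged by a monotone transform.
    """
    types = design_type.reindex(beta.index)
    if types.isna().any():
        raise ValueError("design_type missing for some probes")
    is_one = (types == "I").to_numpy()
    is_two = (types == "II").to_numpy()
    if not (is_one.any() and is_two.any()):
        warnings.warn("only one probe design type present; returning input unchanged", stacklevel=2)
        return beta.copy()

    out = beta.copy()
    for col in beta.columns:
        ref = np.sort(beta[col].to_numpy()[is_one])
        x = beta[col].to_numpy()[is_two]
        q = (rankdata(x, method="average") - 1.0) / (len(x) - 1) if len(x) > 1 else np.array([0.5])
        out.loc[is_two, col] = np.quantile(ref, np.clip(q, 0, 1), method="linear")
    return out
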