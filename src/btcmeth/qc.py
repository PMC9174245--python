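"""Sample quality control on β-value distributions.

FFPE-derived arrays sometimes yield aberrant β distributions — instead
of the expected bimodal shape (most CpGs near 0 or 1), degraded samples
pile up at intermediate methylation. Two per-sample summaries capture
this:

* ``intermediate_fraction`` — share of non-missing probes with
  0.3 < β < 0.7;
* ``bimodality`` — the sample bimodality coefficient
  b = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3))) with g1 the sample
  skewness and g2 the excess kurtosis; the uniform distribution scores
  5/9 ≈ 0.555, genuinely bimodal β distributions score higher.

A sample fails QC if its intermediate fraction exceeds
``max_intermediate`` (default 0.35) OR its bimodality coefficient falls
below ``min_bimodality`` (default 0.555). The rule's form is a declared
surrogate for the unpublished filter used in the original study; both
thresholds are configurable and every exclusion is reported with its
scores. A matched normal is never auto-excluded when its tumour fails.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "DEFAULT_MAX_INTERMEDIATE",
    "DEFAULT_MIN_BIMODALITY",
    "qc_score",
    "qc_filter",
]

DEFAULT_MAX_INTERMEDIATE = 0.35
DEFAULT_MIN_BIMODALITY = 5.0 / 9.0
MIN_PROBES = 1000


def qc_score(beta_vector, min_probes: int = MIN_PROBES) -> tuple[float, float]:
    """Intermediate-β fraction and bimodality coefficient of one sample.

    Requires at least ``min_probes`` (default 1,000) non-missing probes
    for a stable estimate; lower it only for small simulated panels.
    """
    v = np.asarray(beta_vector, dtype=float)
    v = v[~np.isnan(v)]
    n = v.size
    if n < max(min_probes, 5):
        raise ValueError(
            f"need at least {max(min_probes, 5)} non-missing probes, got {n}"
        )
    intermediate = float(np.mean((v > 0.3) & (v < 0.7)))
    g1 = stats.skew(v, bias=False)
    g2 = stats.kurtosis(v, fisher=True, bias=False)
    denom = g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3))
    bimodality = float((g1**2 + 1.0) / denom)
    return intermediate, bimodality


def qc_filter(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    max_intermediate: float = DEFAULT_MAX_INTERMEDIATE,
    min_bimodality: float = DEFAULT_MIN_BIMODALITY,
    min_probes: int = MIN_PROBES,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Exclude samples with aberrant β distributions.

    Parameters
    ----------
    beta
        Probe × sample β matrix.
    sheet
        Sample sheet indexed by sample id (used to check that both
        groups survive).
    max_intermediate, min_bimodality
        Exclusion thresholds; a sample fails on either.

    Returns
    -------
    (kept_beta, report)
        ``kept_beta`` restricted to passing samples, and a per-sample
        report with columns ``intermediate_fraction``, ``bimodality``,
        ``passed``, ``max_intermediate``, ``min_bimodality``.
    """
    if not 0.0 < max_intermediate <= 1.0:
        raise ValueError("max_intermediate must lie in (0, 1]")
    rows = []
    for sid in beta.columns:
        inter, bim = qc_score(beta[sid], min_probes=min_probes)
        passed = (inter <= max_intermediate) and (bim >= min_bimodality)
        rows.append((sid, inter, bim, passed))
    report = pd.DataFrame(
        rows,
        columns=["sample_id", "intermediate_fraction", "bimodality", "passed"],
    ).set_index("sample_id")
    report["max_intermediate"] = max_intermediate
    report["min_bimodality"] = min_bimodality
    kept = report.index[report["passed"]]
    if len(kept) == 0:
        raise ValueError(
            "QC excluded every sample; review --qc-max-intermediate / "
            "--qc-min-bimodality thresholds"
        )
    groups = sheet.loc[sheet.index.intersection(kept), "group"]
    if groups.nunique() < 2:
        raise ValueError(
            "QC left no overlap between tumour and normal groups; "
            "review thresholds"
        )
    return beta[kept], report
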