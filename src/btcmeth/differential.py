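"""Per-CpG-island differential methylation between tumour and normal.

The analysis unit is the CpG island (CGI). Probe β-values are averaged
within each island per sample (``aggregate_to_cgi``); the island-level
effect size is the difference of group means

    Δβ = mean β(tumour) − mean β(normal),

and significance comes from per-probe two-sample tests combined across
the island's probes (Fisher's method by default, Stouffer or a single
t-test on island means as alternatives). Benjamini–Hochberg adjustment
is applied across islands; both the nominal combined p and the adjusted
p are reported, since small discovery cohorts typically lose all
islands after FDR correction while the nominal Δβ/p filter remains the
working criterion.

Matched tumour/normal pairing is deliberately ignored by the tests —
groups are pooled — and kept only for reporting.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "aggregate_to_cgi",
    "differential_cgi",
    "somatic_changes",
    "combine_pvalues_fisher",
]

logger = logging.getLogger(__name__)

_P_FLOOR = 1e-300

DELTA_THRESH = 0.20
P_THRESH = 0.05


def aggregate_to_cgi(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    min_probes: int = 3,
) -> tuple[pd.DataFrame, pd.Series]:
    """Average probe β within each CpG island, per sample.

    Missing probe values are ignored in the mean. Islands with fewer
    than ``min_probes`` assigned probes are dropped (logged).

    Returns
    -------
    (cgi_meth, n_probes)
        ``cgi_meth``: island × sample matrix of mean β;
        ``n_probes``: probes contributing per retained island.
    """
    ann = annotation.loc[annotation["cgi_id"].notna()]
    common = beta.index.intersection(ann.index)
    grouped = beta.loc[common].groupby(ann.loc[common, "cgi_id"], sort=True)
    cgi_meth = grouped.mean()
    n_probes = grouped.size().rename("n_probes")
    keep = n_probes >= min_probes
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "dropping %d CGIs with fewer than %d probes", n_drop, min_probes
        )
    cgi_meth = cgi_meth.loc[keep]
    n_probes = n_probes.loc[keep]
    if cgi_meth.empty:
        raise ValueError(f"no CGI has at least {min_probes} probes")
    cgi_meth.index.name = "cgi_id"
    return cgi_meth, n_probes


def combine_pvalues_fisher(pvalues: np.ndarray) -> float:
    """Fisher's combination: −2 Σ ln p ~ χ² with 2k df under the null."""
    p = np.clip(np.asarray(pvalues, dtype=float), _P_FLOOR, 1.0)
    stat = -2.0 * np.log(p).sum()
    return float(np.clip(stats.chi2.sf(stat, 2 * p.size), _P_FLOOR, 1.0))


def _combine_stouffer(pvalues: np.ndarray) -> float:
    p = np.clip(np.asarray(pvalues, dtype=float), _P_FLOOR, 1.0 - 1e-16)
    z = stats.norm.isf(p).sum() / np.sqrt(p.size)
    return float(np.clip(stats.norm.sf(z), _P_FLOOR, 1.0))


def _per_probe_welch_p(
    tum: np.ndarray, nor: np.ndarray
) -> np.ndarray:
    """Two-sided Welch t-test p per probe (rows), NaN-aware."""
    res = stats.ttest_ind(
        tum, nor, axis=1, equal_var=False, nan_policy="omit"
    )
    return np.asarray(res.pvalue, dtype=float)


def differential_cgi(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    sheet: pd.DataFrame,
    min_probes: int = 3,
    combine: str = "fisher",
    delta_thresh: float = DELTA_THRESH,
    p_thresh: float = P_THRESH,
) -> pd.DataFrame:
    """Island-level differential methylation records.

    Parameters
    ----------
    beta
        Probe × sample β matrix (QC-passed samples).
    annotation
        Probe table with ``cgi_id`` assignments.
    sheet
        Sample sheet indexed by sample id with a ``group`` column.
    combine
        ``fisher`` (default), ``stouffer`` or ``cgi-t`` (a single Welch
        t-test on island means instead of a probe-level combination).
    delta_thresh, p_thresh
        Only used to annotate the ``direction`` column
        (hyper / hypo / none).

    Returns
    -------
    pandas.DataFrame indexed by ``cgi_id`` with columns
    ``mean_beta_tumour``, ``mean_beta_normal``, ``delta_beta``,
    ``combined_p``, ``adjusted_p``, ``n_probes``, ``direction``.
    """
    if combine not in ("fisher", "stouffer", "cgi-t"):
        raise ValueError(f"unknown combination method {combine!r}")
    groups = sheet.loc[beta.columns, "group"]
    tum_ids = groups.index[groups == "tumour"]
    nor_ids = groups.index[groups == "normal"]
    if len(tum_ids) < 2 or len(nor_ids) < 2:
        raise ValueError("need at least two samples per group")

    cgi_meth, n_probes = aggregate_to_cgi(beta, annotation, min_probes)
    mean_t = cgi_meth[tum_ids].mean(axis=1)
    mean_n = cgi_meth[nor_ids].mean(axis=1)
    delta = mean_t - mean_n

    ann = annotation.loc[annotation["cgi_id"].notna()]
    common = beta.index.intersection(ann.index)
    probe_cgi = ann.loc[common, "cgi_id"]

    if combine == "cgi-t":
        res = stats.ttest_ind(
            cgi_meth[tum_ids], cgi_meth[nor_ids], axis=1, equal_var=False
        )
        combined = pd.Series(
            np.clip(res.pvalue, _P_FLOOR, 1.0), index=cgi_meth.index
        )
    else:
        probe_p = _per_probe_welch_p(
            beta.loc[common, tum_ids].to_numpy(),
            beta.loc[common, nor_ids].to_numpy(),
        )
        pseries = pd.Series(probe_p, index=common).dropna()
        if pseries.empty:
            raise ValueError("no testable probes in any CGI")
        fn = combine_pvalues_fisher if combine == "fisher" else _combine_stouffer
        combined_all = pseries.groupby(probe_cgi.loc[pseries.index]).apply(
            lambda s: fn(s.to_numpy())
        )
        combined = combined_all.reindex(cgi_meth.index)
        if combined.isna().any():
            missing = combined.index[combined.isna()][0]
            raise ValueError(f"CGI {missing!r} has zero testable probes")

    adjusted = pd.Series(
        multipletests(combined.to_numpy(), method="fdr_bh")[1],
        index=combined.index,
    )
    direction = pd.Series("none", index=cgi_meth.index, dtype=object)
    sig = combined < p_thresh
    direction[sig & (delta > delta_thresh)] = "hyper"
    direction[sig & (delta < -delta_thresh)] = "hypo"

    records = pd.DataFrame(
        {
            "mean_beta_tumour": mean_t,
            "mean_beta_normal": mean_n,
            "delta_beta": delta,
            "combined_p": combined,
            "adjusted_p": adjusted,
            "n_probes": n_probes,
            "direction": direction,
        }
    )
    records.index.name = "cgi_id"
    return records


def somatic_changes(
    cgi_meth: pd.DataFrame,
    sheet: pd.DataFrame,
    cgi_subset=None,
) -> pd.DataFrame:
    """Per-tumour somatic change matrix.

    Entry (tumour i, island j) = β_i(j) − mean over normal samples of
    β(j): each tumour's deviation from the average normal methylome.
    """
    groups = sheet.loc[cgi_meth.columns, "group"]
    tum_ids = groups.index[groups == "tumour"]
    nor_ids = groups.index[groups == "normal"]
    if len(nor_ids) == 0:
        raise ValueError("somatic changes need at least one normal sample")
    sub = cgi_meth if cgi_subset is None else cgi_meth.loc[list(cgi_subset)]
    normal_mean = sub[nor_ids].mean(axis=1)
    changes = sub[tum_ids].sub(normal_mean, axis=0)
    return changes.T  # tumour samples × CGIs
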