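"""Droplet digital PCR positivity calling and Poisson quantification.

A ddPCR reaction partitions the sample into ~15–20k droplets; target
molecules distribute over droplets approximately Poisson, so from the
positive-droplet fraction p the mean copies per droplet is

    λ = −ln(1 − p),

and the concentration is λ / droplet volume. A sample is callable only
if its multiplexed control channel shows amplifiable input
(``control_min_positive`` positive droplets); otherwise the assay is
invalid for that sample and the sample is excluded from performance
denominators. Positivity uses a threshold on target positive-droplet
counts — fixed (3 droplets by default) or derived from ROC analysis
with the Youden or best-accuracy criterion.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .selection import choose_threshold

__all__ = [
    "DROPLET_VOLUME_NL",
    "AssayCall",
    "poisson_quantify",
    "call_samples",
    "assay_metrics",
    "panel_call",
]

DROPLET_VOLUME_NL = 0.85     # QX200 droplet volume, configurable
DEFAULT_THRESHOLD = 3
DEFAULT_CONTROL_MIN = 1


@dataclass(frozen=True)
class AssayCall:
    sample_id: str
    lam: float
    copies_per_ul: float
    call: str                 # positive | negative | invalid
    threshold: float


def poisson_quantify(
    positive: int,
    accepted: int,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
) -> tuple[float, float]:
    """Poisson-corrected quantification from droplet counts.

    Returns (λ, copies/µL) with λ = −ln(1 − positive/accepted).
    Saturation (every droplet positive) is an error: λ is unbounded.
    """
    if accepted <= 0:
        raise ValueError("accepted droplets must be positive")
    if positive < 0 or positive > accepted:
        raise ValueError("positive droplets must lie in [0, accepted]")
    if positive == accepted:
        raise ValueError(
            "assay saturated (all droplets positive); λ is undefined"
        )
    p = positive / accepted
    lam = -np.log1p(-p)
    copies_per_ul = lam / droplet_volume_nl * 1000.0
    return float(lam), float(copies_per_ul)


def _pivot(counts: pd.DataFrame) -> pd.DataFrame:
    wide = counts.pivot(index="sample_id", columns="channel",
                        values=["positive_droplets", "accepted_droplets"])
    for ch in ("target", "control"):
        if ("positive_droplets", ch) not in wide.columns:
            raise ValueError(f"channel {ch!r} missing from droplet table")
    if wide.isna().any().any():
        sid = wide.index[wide.isna().any(axis=1)][0]
        raise ValueError(f"sample {sid!r} lacks a channel")
    return wide


def call_samples(
    counts: pd.DataFrame,
    control_min_positive: int = DEFAULT_CONTROL_MIN,
    threshold: float = DEFAULT_THRESHOLD,
    droplet_volume_nl: float = DROPLET_VOLUME_NL,
) -> pd.DataFrame:
    """Call methylation positivity per sample from a droplet-count table.

    A sample is ``invalid`` if its control channel shows fewer than
    ``control_min_positive`` positive droplets, ``positive`` if its
    target channel reaches ``threshold`` positive droplets, else
    ``negative``. λ and copies/µL are reported for the target channel
    (NaN when saturated).
    """
    wide = _pivot(counts)
    rows = []
    for sid in wide.index:
        tpos = int(wide.loc[sid, ("positive_droplets", "target")])
        tacc = int(wide.loc[sid, ("accepted_droplets", "target")])
        cpos = int(wide.loc[sid, ("positive_droplets", "control")])
        try:
            lam, conc = poisson_quantify(tpos, tacc, droplet_volume_nl)
        except ValueError:
            lam, conc = float("nan"), float("nan")
        if cpos < control_min_positive:
            call = "invalid"
        elif tpos >= threshold:
            call = "positive"
        else:
            call = "negative"
        rows.append((sid, tpos, tacc, lam, conc, call, float(threshold)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "target_positive", "target_accepted",
                 "lambda", "copies_per_ul", "call", "threshold"],
    ).set_index("sample_id")


def fit_threshold(
    counts: pd.DataFrame,
    truth: pd.Series,
    criterion: str = "youden",
    control_min_positive: int = DEFAULT_CONTROL_MIN,
) -> float:
    """Derive the positivity threshold from ROC on droplet counts."""
    calls = call_samples(counts, control_min_positive, threshold=0)
    valid = calls.index[calls["call"] != "invalid"]
    scores = calls.loc[valid, "target_positive"].to_numpy(dtype=float)
    y = truth.loc[valid].to_numpy()
    return choose_threshold(scores, y, criterion=criterion)


def assay_metrics(
    calls: pd.DataFrame, truth: pd.Series
) -> dict[str, float]:
    """Sensitivity, specificity, AUC and confusion counts of an assay.

    ``truth`` maps sample id → 1 (disease) / 0 (control); invalid
    samples are excluded from the denominators and counted separately.
    AUC uses target positive-droplet counts as the continuous score.
    Percentages are reported rounded to the nearest integer alongside
    the exact fractions.
    """
    merged = calls.join(truth.rename("truth"), how="inner")
    if merged["truth"].isna().any():
        raise ValueError("truth label missing for some samples")
    invalid = merged["call"] == "invalid"
    valid = merged.loc[~invalid]
    y = valid["truth"].astype(int).to_numpy()
    pred = (valid["call"] == "positive").to_numpy()
    tp = int((pred & (y == 1)).sum())
    fn = int((~pred & (y == 1)).sum())
    tn = int((~pred & (y == 0)).sum())
    fp = int((pred & (y == 0)).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("no valid samples in one of the classes")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    auc = float(
        roc_auc_score(y, valid["target_positive"].to_numpy(dtype=float))
    )
    return {
        "tp": tp, "fn": fn, "tn": tn, "fp": fp,
        "n_invalid": int(invalid.sum()),
        "sensitivity": sens,
        "specificity": spec,
        "sensitivity_pct": round(100.0 * sens),
        "specificity_pct": round(100.0 * spec),
        "auc": auc,
    }


def panel_call(per_assay_calls: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Combine assays with an OR rule.

    A sample is positive if ANY member assay calls it positive, invalid
    only if ALL member assays are invalid; an invalid member never
    vetoes a valid one. All assays must cover the same samples.
    """
    if not per_assay_calls:
        raise ValueError("no assays to combine")
    items = list(per_assay_calls.items())
    index = items[0][1].index
    for name, calls in items[1:]:
        if not index.equals(calls.index):
            raise ValueError(
                f"assay {name!r} covers a different sample set"
            )
    combined = []
    for sid in index:
        calls = [c.loc[sid, "call"] for _, c in items]
        if all(c == "invalid" for c in calls):
            call = "invalid"
        elif any(c == "positive" for c in calls):
            call = "positive"
        else:
            call = "negative"
        max_pos = max(
            int(c.loc[sid, "target_positive"]) for _, c in items
            if c.loc[sid, "call"] != "invalid"
        ) if call != "invalid" else 0
        combined.append((sid, max_pos, call))
    return pd.DataFrame(
        combined, columns=["sample_id", "target_positive", "call"]
    ).set_index("sample_id")
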