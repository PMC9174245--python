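"""Readers and writers for the pipeline's plain-text formats.

Formats
-------
* β matrix: tab-separated, probes as rows, header row of sample ids;
  missing values written as ``NA``.
* CpG islands: 4-column BED (chrom, start, end, name), 0-based half-open.
* Probe annotation: TSV with probe_id, chrom, pos (1-based).
* Sample sheet: CSV with sample_id, group, cohort, pair_id, location,
  stage, grade.
* ddPCR droplet counts: CSV with sample_id, channel, positive_droplets,
  accepted_droplets.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

__all__ = [
    "drop_sparse_probes",
    "read_beta_matrix",
    "write_beta_matrix",
    "read_bed",
    "write_bed",
    "read_probe_annotation",
    "write_probe_annotation",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_droplet_counts",
    "write_droplet_counts",
]

MISSING_TOKEN = "NA"

GROUPS = {"tumour", "normal"}
LOCATIONS = {"intrahepatic", "extrahepatic", "gallbladder"}
STAGES = {"I", "II", "III", "IV"}


def _validate_beta(beta: pd.DataFrame, path: str | os.PathLike) -> None:
    if beta.index.duplicated().any():
        dup = beta.index[beta.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate probe id {dup!r}")
    if beta.columns.duplicated().any():
        dup = beta.columns[beta.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    vals = beta.to_numpy(dtype=float)
    bad = (vals < 0) | (vals > 1)
    bad &= ~np.isnan(vals)
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ValueError(
            f"{path}: β-value {vals[i, j]} out of [0, 1] at probe "
            f"{beta.index[i]!r}, sample {beta.columns[j]!r}"
        )


def read_beta_matrix(
    path: str | os.PathLike, orientation: str = "probes_by_samples"
) -> pd.DataFrame:
    """Read a β-value matrix as probes × samples.

    ``orientation='samples_by_probes'`` transposes on input. Values are
    validated to lie in [0, 1]; ``NA`` marks missing.
    """
    if orientation not in ("probes_by_samples", "samples_by_probes"):
        raise ValueError(f"unknown orientation {orientation!r}")
    try:
        beta = pd.read_csv(
            path,
            sep="\t",
            index_col=0,
            na_values=[MISSING_TOKEN],
            keep_default_na=False,
        )
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if orientation == "samples_by_probes":
        beta = beta.T
    for col in beta.columns:
        nonnum = pd.to_numeric(beta[col], errors="coerce")
        bad = nonnum.isna() & beta[col].notna()
        if bad.any():
            row = beta.index[bad][0]
            raise ValueError(
                f"{path}: non-numeric cell {beta.loc[row, col]!r} at probe "
                f"{row!r}, sample {col!r}"
            )
        beta[col] = nonnum
    beta = beta.astype(float)
    _validate_beta(beta, path)
    beta.index.name = "probe_id"
    return beta


def write_beta_matrix(
    beta: pd.DataFrame, path: str | os.PathLike, precision: int = 6
) -> None:
    _validate_beta(beta, path)
    beta.to_csv(
        path,
        sep="\t",
        na_rep=MISSING_TOKEN,
        float_format=f"%.{precision}g",
        index_label="probe_id",
    )


def drop_sparse_probes(
    beta: pd.DataFrame, max_missing: float = 0.2
) -> pd.DataFrame:
    """Drop probes missing in more than ``max_missing`` of samples.

    The number of dropped probes is logged at INFO level.
    """
    frac = beta.isna().mean(axis=1)
    keep = frac <= max_missing
    n_drop = int((~keep).sum())
    if n_drop:
        import logging

        logging.getLogger(__name__).info(
            "dropping %d probes with >%.0f%% missing values",
            n_drop, 100 * max_missing,
        )
    return beta.loc[keep]


def read_bed(path: str | os.PathLike) -> pd.DataFrame:
    """Read 4-column BED of CpG islands (0-based half-open)."""
    bed = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chrom", "start", "end", "name"],
        dtype={"chrom": str, "start": int, "end": int, "name": str},
    )
    bad = bed["start"] >= bed["end"]
    if bad.any():
        row = bed[bad].iloc[0]
        raise ValueError(
            f"{path}: BED interval with start >= end: "
            f"{row['chrom']}:{row['start']}-{row['end']}"
        )
    if bed["name"].duplicated().any():
        dup = bed["name"][bed["name"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate CGI name {dup!r}")
    return bed


def write_bed(bed: pd.DataFrame, path: str | os.PathLike) -> None:
    bed[["chrom", "start", "end", "name"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_probe_annotation(path: str | os.PathLike) -> pd.DataFrame:
    ann = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str})
    ann = ann.set_index("probe_id")
    if ann.index.duplicated().any():
        raise ValueError(f"{path}: duplicate probe ids")
    ann["pos"] = ann["pos"].astype(int)
    return ann


def write_probe_annotation(ann: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in ("chrom", "pos", "cgi_id") if c in ann.columns]
    ann[cols].to_csv(path, sep="\t", index_label="probe_id")


def read_sample_sheet(path: str | os.PathLike) -> pd.DataFrame:
    """Read the sample sheet; validates groups and tumour/normal pairing."""
    sheet = pd.read_csv(path, dtype=str, keep_default_na=False)
    sheet = sheet.replace("", pd.NA)
    required = ["sample_id", "group", "cohort"]
    for col in required:
        if col not in sheet.columns:
            raise ValueError(f"{path}: sample sheet misses column {col!r}")
    for col in ("pair_id", "location", "stage", "grade"):
        if col not in sheet.columns:
            sheet[col] = pd.NA
    if sheet["sample_id"].duplicated().any():
        dup = sheet["sample_id"][sheet["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    bad_group = ~sheet["group"].isin(GROUPS)
    if bad_group.any():
        raise ValueError(
            f"{path}: unknown group {sheet['group'][bad_group].iloc[0]!r}"
        )
    for pid, sub in sheet.dropna(subset=["pair_id"]).groupby("pair_id"):
        groups = sorted(sub["group"])
        if groups != ["normal", "tumour"]:
            raise ValueError(
                f"{path}: pair {pid!r} must link exactly one tumour and one "
                f"normal (found {groups})"
            )
    return sheet.set_index("sample_id")


def write_sample_sheet(sheet: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = ["group", "cohort", "pair_id", "location", "stage", "grade"]
    sheet[cols].to_csv(path, index_label="sample_id")


def read_droplet_counts(path: str | os.PathLike) -> pd.DataFrame:
    counts = pd.read_csv(path, dtype={"sample_id": str, "channel": str})
    required = {"sample_id", "channel", "positive_droplets", "accepted_droplets"}
    missing = required - set(counts.columns)
    if missing:
        raise ValueError(f"{path}: droplet table misses {sorted(missing)}")
    counts["positive_droplets"] = counts["positive_droplets"].astype(int)
    counts["accepted_droplets"] = counts["accepted_droplets"].astype(int)
    if (counts["accepted_droplets"] <= 0).any():
        raise ValueError(f"{path}: accepted_droplets must be positive")
    bad = counts["positive_droplets"] > counts["accepted_droplets"]
    if bad.any():
        sid = counts["sample_id"][bad].iloc[0]
        raise ValueError(
            f"{path}: positive > accepted droplets for sample {sid!r}"
        )
    if (counts["positive_droplets"] < 0).any():
        raise ValueError(f"{path}: negative droplet count")
    return counts


def write_droplet_counts(counts: pd.DataFrame, path: str | os.PathLike) -> None:
    counts[
        ["sample_id", "channel", "positive_droplets", "accepted_droplets"]
    ].to_csv(path, index=False)
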