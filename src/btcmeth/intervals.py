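"""Genomic intervals and probe-to-CpG-island assignment.

Coordinates are 0-based half-open internally; user-facing labels are
rendered 1-based inclusive (UCSC style, ``chr2:176993479-176995557``),
matching how CpG islands are named on methylation arrays. Strand is
ignored: β-values are strand-symmetric at the CpG level.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GenomicInterval",
    "IntervalParseError",
    "parse_interval",
    "map_probes_to_cgis",
]

_LABEL_RE = re.compile(r"^([A-Za-z0-9_.]+):(\d+)-(\d+)$")


class IntervalParseError(ValueError):
    """Raised for malformed or inverted interval labels."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A genomic region, 0-based half-open.

    ``start < end`` always holds; a 1-based single-base label such as
    ``chrX:5-5`` maps to ``start=4, end=5`` (length 1).
    """

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.start >= self.end:
            raise IntervalParseError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )

    @property
    def id(self) -> str:
        """Label rendered 1-based inclusive."""
        return f"{self.chrom}:{self.start + 1}-{self.end}"

    def __len__(self) -> int:
        return self.end - self.start

    def contains_pos(self, pos_1based: int) -> bool:
        """Whether a 1-based genomic position falls inside the interval."""
        return self.start < pos_1based <= self.end


def parse_interval(label: str) -> GenomicInterval:
    """Parse a 1-based inclusive ``chrom:start-end`` label.

    Round-trips with :attr:`GenomicInterval.id`:
    ``parse_interval(iv.id) == iv``.
    """
    m = _LABEL_RE.match(label.strip())
    if m is None:
        raise IntervalParseError(f"malformed interval label: {label!r}")
    chrom, start, end = m.group(1), int(m.group(2)), int(m.group(3))
    if start < 1 or start > end:
        raise IntervalParseError(
            f"interval label {label!r} has start > end or start < 1"
        )
    return GenomicInterval(chrom, start - 1, end)


def _check_disjoint(cgis: pd.DataFrame) -> None:
    for chrom, sub in cgis.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        overlap = s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]
        if overlap.any():
            i = int(np.flatnonzero(overlap)[0])
            a, b = s.iloc[i], s.iloc[i + 1]
            raise ValueError(
                f"overlapping CpG islands on {chrom}: "
                f"{a['name']} and {b['name']}"
            )


def map_probes_to_cgis(
    probes: pd.DataFrame, cgis: pd.DataFrame
) -> pd.DataFrame:
    """Assign each probe to the unique CpG island covering its position.

    Parameters
    ----------
    probes
        Indexed by probe id, with columns ``chrom`` and ``pos``
        (1-based CpG position).
    cgis
        BED-style table with columns ``chrom``, ``start``, ``end``
        (0-based half-open) and ``name``. Islands must be disjoint
        within each chromosome; overlapping islands are an input error.

    Returns
    -------
    pandas.DataFrame
        Copy of ``probes`` with a ``cgi_id`` column; probes outside
        every island get ``NaN``.
    """
    required = {"chrom", "pos"}
    if not required.issubset(probes.columns):
        raise ValueError(f"probe table needs columns {sorted(required)}")
    _check_disjoint(cgis)

    out = probes.copy()
    out["cgi_id"] = pd.Series(pd.NA, index=out.index, dtype="object")
    for chrom, sub in cgis.groupby("chrom", sort=False):
        s = sub.sort_values("start")
        starts = s["start"].to_numpy()
        ends = s["end"].to_numpy()
        names = s["name"].to_numpy()
        mask = out["chrom"] == chrom
        if not mask.any():
            continue
        pos0 = out.loc[mask, "pos"].to_numpy() - 1  # 0-based probe position
        idx = np.searchsorted(starts, pos0, side="right") - 1
        hit = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        assigned = np.where(hit, names[np.clip(idx, 0, len(names) - 1)], None)
        out.loc[mask, "cgi_id"] = assigned
    return out
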