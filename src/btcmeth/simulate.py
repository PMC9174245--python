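"""Synthetic methylation cohorts and ddPCR droplet tables.

The generator emulates the statistical structure of an FFPE tumour /
normal methylation-array study at CpG-island (CGI) resolution:

* normals carry low β at candidate CGIs and a bimodal background
  elsewhere;
* planted hypermethylated CGIs gain a CGI-level effect ``delta`` in the
  tumour-cell fraction, diluted linearly by tumour purity
  (β is a fraction of methylated alleles, so a mixture of tumour and
  contaminating normal cells mixes β linearly);
* probe-level values are Beta-distributed around per-probe means with a
  common concentration ``kappa``; per-probe means are jittered on the
  logit scale once per CGI to mimic probe-to-probe variation;
* optionally, some samples are "FFPE-degraded": their β are shrunk
  toward 0.5 with added noise, reproducing the aberrant intermediate-β
  distributions that sample QC must catch.

All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .intervals import GenomicInterval

__all__ = [
    "CohortSpec",
    "PlantedTruth",
    "Cohort",
    "MultiDataset",
    "generate_cohort",
    "generate_on_universe",
    "degrade_ffpe",
    "generate_multidataset",
    "generate_droplets",
]

_LOGIT_JITTER_SD = 0.3
_FFPE_SEVERITY = 0.8


def _logit(p: np.ndarray) -> np.ndarray:
    return np.log(p) - np.log1p(-p)


def _expit(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic tumour/normal methylation cohort.

    Defaults mirror a discovery-style design: 50 tumours vs 10 matched
    normals, 200 CGIs of 4–10 probes with 20 hypermethylated and 2
    hypomethylated islands planted (roughly the hyper:hypo ratio seen in
    biliary tract tumours, at desk scale), a CGI-level effect of
    ``delta`` = 0.35 β units, probe concentration ``kappa`` = 50 and
    tumour purity between 0.6 and 1.
    """

    n_tumour: int = 50
    n_normal: int = 10
    n_cgis: int = 200
    probes_per_cgi: tuple[int, int] = (4, 10)
    n_hyper: int = 20
    n_hypo: int = 2
    delta: float = 0.35
    normal_mean_range: tuple[float, float] = (0.03, 0.15)
    background_mean_range: tuple[float, float] = (0.03, 0.97)
    kappa: float = 50.0
    purity_range: tuple[float, float] = (0.6, 1.0)
    n_ffpe_degraded: int = 0
    seed: int = 0

    def validate(self) -> None:
        if self.n_hyper + self.n_hypo > self.n_cgis:
            raise ValueError("n_hyper + n_hypo exceeds n_cgis")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must lie in (0, 1)")
        lo, hi = self.purity_range
        if not (0.0 < lo <= hi <= 1.0):
            raise ValueError("purity_range must lie in (0, 1]")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_tumour < 1 or self.n_normal < 1:
            raise ValueError("need at least one sample per group")
        if self.n_ffpe_degraded > self.n_tumour + self.n_normal:
            raise ValueError("more degraded samples than samples")
        lo, hi = self.probes_per_cgi
        if not (1 <= lo <= hi):
            raise ValueError("invalid probes_per_cgi range")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth planted by a generator."""

    cgi_labels: pd.Series       # cgi_id -> hyper | hypo | null
    degraded: tuple[str, ...]   # sample ids corrupted by FFPE model
    purity: pd.Series           # tumour sample id -> purity

    @property
    def hyper_cgis(self) -> tuple[str, ...]:
        return tuple(self.cgi_labels.index[self.cgi_labels == "hyper"])

    @property
    def hypo_cgis(self) -> tuple[str, ...]:
        return tuple(self.cgi_labels.index[self.cgi_labels == "hypo"])


@dataclass
class Cohort:
    """One generated cohort in the pipeline's native containers."""

    beta: pd.DataFrame        # probes x samples
    sheet: pd.DataFrame       # indexed by sample_id
    probes: pd.DataFrame      # probe_id -> chrom, pos, cgi_id
    cgis: pd.DataFrame        # BED-style: chrom, start, end, name
    truth: PlantedTruth


@dataclass
class MultiDataset:
    """A biliary-tract cohort plus other-cancer cohorts sharing its CGIs."""

    btc: Cohort
    others: dict[str, Cohort]
    btc_specific: tuple[str, ...]   # planted hyper CGIs unique to BTC
    shared: tuple[str, ...]         # planted hyper CGIs shared with others


def _make_layout(spec: CohortSpec, rng: np.random.Generator):
    """Place CGIs along chromosomes and probes inside them."""
    n_probes = rng.integers(
        spec.probes_per_cgi[0], spec.probes_per_cgi[1] + 1, size=spec.n_cgis
    )
    chroms, starts, ends, names = [], [], [], []
    cursor = {f"chr{i}": 10_000 for i in range(1, 23)}
    probe_rows = []
    for i in range(spec.n_cgis):
        chrom = f"chr{(i % 22) + 1}"
        start = cursor[chrom]
        length = int(500 + 100 * n_probes[i])
        end = start + length
        cursor[chrom] = end + 5_000
        name = GenomicInterval(chrom, start, end).id
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        names.append(name)
        pos = np.linspace(start + 1, end, n_probes[i]).astype(int)
        for k, p in enumerate(pos):
            probe_rows.append((f"cg{i:05d}_{k:02d}", chrom, int(p), name))
    cgis = pd.DataFrame(
        {"chrom": chroms, "start": starts, "end": ends, "name": names}
    )
    probes = pd.DataFrame(
        probe_rows, columns=["probe_id", "chrom", "pos", "cgi_id"]
    ).set_index("probe_id")
    return cgis, probes


def _plant_labels(spec: CohortSpec, rng: np.random.Generator,
                  cgi_names: list[str]) -> pd.Series:
    labels = np.array(
        ["hyper"] * spec.n_hyper
        + ["hypo"] * spec.n_hypo
        + ["null"] * (spec.n_cgis - spec.n_hyper - spec.n_hypo)
    )
    rng.shuffle(labels)
    return pd.Series(labels, index=pd.Index(cgi_names, name="cgi_id"))


def _cgi_normal_means(spec: CohortSpec, rng: np.random.Generator,
                      labels: pd.Series) -> np.ndarray:
    """Baseline (normal-tissue) mean β per CGI.

    Candidate (planted hyper) islands are low-methylated; hypomethylation
    candidates start high so there is room to lose ``delta``; the null
    background is U-shaped across ``background_mean_range``, as array β
    distributions are strongly bimodal.
    """
    lo, hi = spec.normal_mean_range
    blo, bhi = spec.background_mean_range
    means = np.empty(len(labels))
    lab = labels.to_numpy()
    n_hyper = int((lab == "hyper").sum())
    n_hypo = int((lab == "hypo").sum())
    n_null = len(lab) - n_hyper - n_hypo
    means[lab == "hyper"] = rng.uniform(lo, hi, size=n_hyper)
    hypo_lo = min(max(spec.delta + 0.05, 0.5), 0.85)
    means[lab == "hypo"] = rng.uniform(hypo_lo, 0.9, size=n_hypo)
    # sharply U-shaped: bisulfite arrays put ~85% of probes near 0 or 1
    means[lab == "null"] = blo + (bhi - blo) * rng.beta(0.2, 0.2, size=n_null)
    return means


def _simulate_betas(
    spec: CohortSpec,
    rng: np.random.Generator,
    probes: pd.DataFrame,
    labels: pd.Series,
    sample_ids: list[str],
    groups: np.ndarray,
    purity: np.ndarray,
) -> pd.DataFrame:
    cgi_means = _cgi_normal_means(spec, rng, labels)
    mean_by_cgi = dict(zip(labels.index, cgi_means))
    label_by_cgi = labels.to_dict()

    probe_cgi = probes["cgi_id"].to_numpy()
    base = np.array([mean_by_cgi[c] for c in probe_cgi])
    jitter = rng.normal(0.0, _LOGIT_JITTER_SD, size=len(base))
    probe_normal = np.clip(_expit(_logit(np.clip(base, 0.01, 0.99)) + jitter),
                           0.01, 0.99)
    shift = np.array(
        [
            spec.delta if label_by_cgi[c] == "hyper"
            else -spec.delta if label_by_cgi[c] == "hypo"
            else 0.0
            for c in probe_cgi
        ]
    )
    probe_tumour_cell = np.clip(probe_normal + shift, 0.01, 0.99)

    n_probe = len(probe_normal)
    n_sample = len(sample_ids)
    mu = np.empty((n_probe, n_sample))
    is_tumour = groups == "tumour"
    mu[:, ~is_tumour] = probe_normal[:, None]
    # observed tumour β = purity * tumour-cell β + (1 - purity) * normal β
    tum_purity = purity[is_tumour]
    mu[:, is_tumour] = (
        tum_purity[None, :] * probe_tumour_cell[:, None]
        + (1.0 - tum_purity[None, :]) * probe_normal[:, None]
    )
    beta = rng.beta(mu * spec.kappa, (1.0 - mu) * spec.kappa)
    return pd.DataFrame(beta, index=probes.index, columns=sample_ids)


def _make_sheet(spec: CohortSpec, rng: np.random.Generator,
                cohort: str) -> pd.DataFrame:
    tum_ids = [f"{cohort}_T{i + 1:02d}" for i in range(spec.n_tumour)]
    nor_ids = [f"{cohort}_N{i + 1:02d}" for i in range(spec.n_normal)]
    locations = ["intrahepatic", "gallbladder", "extrahepatic"]
    rows = []
    n_paired = min(spec.n_tumour, spec.n_normal)
    for i, sid in enumerate(tum_ids):
        rows.append(
            (
                sid,
                "tumour",
                cohort,
                f"{cohort}_P{i + 1:02d}" if i < n_paired else pd.NA,
                locations[i % 3],
                ["I", "II", "III", "IV"][int(rng.integers(0, 4))],
                int(rng.integers(2, 4)),
            )
        )
    for i, sid in enumerate(nor_ids):
        rows.append(
            (
                sid,
                "normal",
                cohort,
                f"{cohort}_P{i + 1:02d}" if i < n_paired else pd.NA,
                pd.NA,
                pd.NA,
                pd.NA,
            )
        )
    sheet = pd.DataFrame(
        rows,
        columns=[
            "sample_id", "group", "cohort", "pair_id",
            "location", "stage", "grade",
        ],
    ).set_index("sample_id")
    return sheet


def generate_cohort(spec: CohortSpec, cohort: str = "sim") -> Cohort:
    """Generate one tumour/normal cohort.

    Deterministic given ``spec.seed``; null CGIs share the same probe
    means between groups, planted CGIs shift the tumour-cell mean by
    ±``spec.delta`` before purity dilution.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cgis, probes = _make_layout(spec, rng)
    labels = _plant_labels(spec, rng, list(cgis["name"]))
    sheet = _make_sheet(spec, rng, cohort)
    groups = sheet["group"].to_numpy()
    purity_full = np.ones(len(sheet))
    is_tumour = groups == "tumour"
    purity_full[is_tumour] = rng.uniform(
        spec.purity_range[0], spec.purity_range[1], size=int(is_tumour.sum())
    )
    beta = _simulate_betas(
        spec, rng, probes, labels, list(sheet.index), groups, purity_full
    )
    degraded: tuple[str, ...] = ()
    if spec.n_ffpe_degraded > 0:
        degraded = _pick_degraded(rng, sheet, is_tumour,
                                  spec.n_ffpe_degraded)
        beta = degrade_ffpe(
            beta, degraded, severity=_FFPE_SEVERITY,
            seed=int(rng.integers(0, 2**31)),
        )
    truth = PlantedTruth(
        cgi_labels=labels,
        degraded=degraded,
        purity=pd.Series(
            purity_full[is_tumour], index=sheet.index[is_tumour], name="purity"
        ),
    )
    return Cohort(beta=beta, sheet=sheet, probes=probes, cgis=cgis, truth=truth)


def _pick_degraded(rng, sheet, is_tumour, n: int) -> tuple[str, ...]:
    """Corrupt tumours first (FFPE blocks), then normals if needed."""
    tumours = list(sheet.index[is_tumour])
    normals = list(sheet.index[~is_tumour])
    n_t = min(n, len(tumours))
    picked = [tumours[i] for i in
              rng.choice(len(tumours), size=n_t, replace=False)]
    if n > n_t:
        picked += [normals[i] for i in
                   rng.choice(len(normals), size=n - n_t, replace=False)]
    return tuple(sorted(picked))


def generate_on_universe(
    base: Cohort,
    labels: pd.Series,
    spec: CohortSpec,
    seed: int,
    cohort: str,
) -> Cohort:
    """Generate a cohort on an existing CGI/probe universe.

    ``labels`` assigns hyper/hypo/null per CGI of ``base``; used for
    replication cohorts (same planted alterations as the discovery
    cohort) and other-cancer cohorts (partially overlapping ones).
    """
    spec.validate()
    if not labels.index.equals(base.truth.cgi_labels.index):
        raise ValueError("labels do not match the base CGI universe")
    rng = np.random.default_rng(seed)
    sheet = _make_sheet(spec, rng, cohort)
    groups = sheet["group"].to_numpy()
    purity = np.ones(len(sheet))
    is_tum = groups == "tumour"
    purity[is_tum] = rng.uniform(
        spec.purity_range[0], spec.purity_range[1], size=int(is_tum.sum())
    )
    beta = _simulate_betas(
        spec, rng, base.probes, labels, list(sheet.index), groups, purity
    )
    degraded: tuple[str, ...] = ()
    if spec.n_ffpe_degraded > 0:
        degraded = _pick_degraded(rng, sheet, is_tum, spec.n_ffpe_degraded)
        beta = degrade_ffpe(
            beta, degraded, severity=_FFPE_SEVERITY,
            seed=int(rng.integers(0, 2**31)),
        )
    truth = PlantedTruth(
        cgi_labels=labels.copy(),
        degraded=degraded,
        purity=pd.Series(purity[is_tum], index=sheet.index[is_tum]),
    )
    return Cohort(
        beta=beta, sheet=sheet, probes=base.probes, cgis=base.cgis,
        truth=truth,
    )


def degrade_ffpe(
    beta: pd.DataFrame,
    sample_ids,
    severity: float,
    seed: int,
) -> pd.DataFrame:
    """Corrupt selected samples the way failed FFPE arrays look.

    β-values are shrunk toward 0.5 by ``severity`` and perturbed with
    Gaussian noise of sd ``0.08 * severity``; the fraction of
    intermediate β (0.3–0.7) grows monotonically with severity.
    Untouched samples are returned unchanged.
    """
    if not 0.0 < severity <= 1.0:
        raise ValueError(f"severity must lie in (0, 1], got {severity}")
    missing = [s for s in sample_ids if s not in beta.columns]
    if missing:
        raise KeyError(f"unknown sample id(s): {missing}")
    rng = np.random.default_rng(seed)
    out = beta.copy()
    for sid in sample_ids:
        v = out[sid].to_numpy(dtype=float)
        noise = rng.normal(0.0, 0.08 * severity, size=v.shape)
        out[sid] = np.clip(v + severity * (0.5 - v) + noise, 0.0, 1.0)
    return out


def generate_multidataset(
    shared_spec: CohortSpec,
    other_specs: dict[str, CohortSpec],
    overlap: float,
    seed: int,
) -> MultiDataset:
    """Generate a BTC cohort plus other-cancer cohorts on one CGI universe.

    A fraction ``overlap`` of the BTC-planted hyper CGIs is planted in
    every other-cancer cohort as well (the shared gastrointestinal
    alterations a specificity filter must remove); each other cancer
    additionally plants its own ``n_hyper`` private alterations among
    BTC-null CGIs. Truth records which planted CGIs are BTC-specific.
    """
    if not 0.0 <= overlap <= 1.0:
        raise ValueError("overlap must lie in [0, 1]")
    for name, ospec in other_specs.items():
        if ospec.n_cgis != shared_spec.n_cgis or (
            ospec.probes_per_cgi != shared_spec.probes_per_cgi
        ):
            raise ValueError(
                f"cohort {name!r} does not share the CGI universe "
                "(n_cgis / probes_per_cgi differ)"
            )
    rng = np.random.default_rng(seed)
    btc = generate_cohort(
        replace(shared_spec, seed=int(rng.integers(0, 2**31))), cohort="BTC"
    )
    btc_hyper = list(btc.truth.hyper_cgis)
    null_pool = [
        c for c in btc.truth.cgi_labels.index
        if btc.truth.cgi_labels[c] == "null"
    ]
    n_shared = int(round(overlap * len(btc_hyper)))
    shared = sorted(
        rng.choice(btc_hyper, size=n_shared, replace=False).tolist()
    ) if n_shared else []

    others: dict[str, Cohort] = {}
    for name in sorted(other_specs):
        ospec = other_specs[name]
        ospec.validate()
        pick_rng = np.random.default_rng(int(rng.integers(0, 2**31)))
        n_private = min(ospec.n_hyper, len(null_pool))
        private = sorted(
            pick_rng.choice(null_pool, size=n_private, replace=False).tolist()
        ) if n_private else []
        labels = pd.Series(
            "null", index=btc.truth.cgi_labels.index, name="label"
        )
        labels.loc[shared] = "hyper"
        labels.loc[private] = "hyper"
        others[name] = generate_on_universe(
            btc, labels, ospec, seed=int(rng.integers(0, 2**31)), cohort=name
        )
    other_hyper = set().union(*(o.truth.hyper_cgis for o in others.values())) \
        if others else set()
    btc_specific = tuple(sorted(set(btc_hyper) - other_hyper))
    return MultiDataset(
        btc=btc,
        others=others,
        btc_specific=btc_specific,
        shared=tuple(sorted(set(btc_hyper) & other_hyper)),
    )


def generate_droplets(
    n_positive: int,
    n_negative: int,
    accepted: int = 15_000,
    lam_positive: float = 0.05,
    lam_negative: float = 0.0,
    lam_control: float = 1.0,
    seed: int = 0,
    assay: str = "target",
) -> tuple[pd.DataFrame, pd.Series]:
    """Simulate a ddPCR droplet-count table for one assay.

    Positive-droplet counts are Binomial(accepted, 1 - exp(-λ)) with a
    class-specific mean copies-per-droplet λ; the multiplexed control
    channel is always positive-rich (λ = ``lam_control``). Returns the
    count table (sample_id, channel, positive_droplets,
    accepted_droplets) and the per-sample truth labels (1 = methylated
    target present).
    """
    if accepted <= 0:
        raise ValueError("accepted droplets must be positive")
    if min(lam_positive, lam_negative, lam_control) < 0:
        raise ValueError("copies per droplet (λ) cannot be negative")
    rng = np.random.default_rng(seed)
    sample_ids = [f"{assay}_P{i + 1:03d}" for i in range(n_positive)] + [
        f"{assay}_C{i + 1:03d}" for i in range(n_negative)
    ]
    lam = np.array([lam_positive] * n_positive + [lam_negative] * n_negative)
    p_pos = -np.expm1(-lam)
    target = rng.binomial(accepted, p_pos)
    control = rng.binomial(accepted, -np.expm1(-lam_control),
                           size=len(sample_ids))
    rows = []
    for sid, t, c in zip(sample_ids, target, control):
        rows.append((sid, "target", int(t), accepted))
        rows.append((sid, "control", int(c), accepted))
    counts = pd.DataFrame(
        rows,
        columns=["sample_id", "channel", "positive_droplets",
                 "accepted_droplets"],
    )
    truth = pd.Series(
        [1] * n_positive + [0] * n_negative,
        index=pd.Index(sample_ids, name="sample_id"),
        name="truth",
    )
    return counts, truth
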