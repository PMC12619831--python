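"""Synthetic urinary-metabolomics dataset generator.

Emulates the statistical structure of a targeted urinary metabolomics
case-control study of diabetic nephropathy: three groups (healthy controls
CTRL, type-2 diabetes DM2, diabetic nephropathy DN) of equal size, a few
hundred absolutely quantified metabolite concentrations (µM), left-censoring
at per-metabolite limits of detection (LOD), per-sample urinary creatinine
(mM), and clinical covariates (GFR, ACR, age, sex).

Generative model
----------------
Concentrations are log-normal: for metabolite ``j`` the natural-log
concentration of sample ``i`` is

    log X_ij = mu_j + sigma * (-a_j * r_i + sqrt(1 - a_j^2) * eps_ij) + ln(2) * d_jg

where ``r_i`` is the latent per-sample "renal function" factor — the
sample's GFR standardized against the whole cohort (GFR itself is drawn per
group around the group mean, so the factor carries both the within-group
variation and the DN depression), ``a_j`` is a loading that is nonzero only
for designated uremic-toxin-like metabolites, ``eps_ij`` is standard normal
noise, and ``d_jg`` is the planted log2 effect of metabolite ``j`` in group
``g`` (zero if not planted).

Toxin-like metabolites therefore correlate negatively with GFR across the
cohort at approximately the requested rho *and* accumulate in the DN group,
whose GFR is depressed — the mechanism by which uremic toxins mark declining
renal clearance. The LOD of each metabolite is the requested quantile
of its marginal log-normal distribution; values below it are recorded as
missing with the LOD retained, mirroring Type-I left-censoring of a
quantitative assay. A designated subset of metabolites receives a heavier
censoring quantile so the downstream missingness filter has work to do.

All draws flow from one ``numpy.random.default_rng(seed)`` stream; the same
seed yields bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

GROUPS = ("CTRL", "DM2", "DN")


class SyntheticSpecError(ValueError):
    """Raised when a SyntheticSpec field is invalid; names the field."""


@dataclass(frozen=True)
class PlantedEffect:
    """A group-discriminative metabolite: its concentration in ``group`` is
    multiplied by ``2**log2_effect`` relative to the shared baseline."""

    metabolite: int
    group: str
    log2_effect: float


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    Defaults reproduce the design the analysis assumes: 20 subjects per group,
    268 metabolites, 5% left-censoring (30% for a designated subset), and
    group GFR means of 112.5 / 107.8 / 71.2 mL/min/1.73m².
    """

    n_per_group: int = 20
    n_metabolites: int = 268
    planted: tuple[PlantedEffect, ...] = ()
    base_log_mean: float = 1.0
    base_log_sd: float = 1.0
    metabolite_log_mean_spread: float = 1.0
    censor_quantile: float = 0.05
    high_censor_indices: tuple[int, ...] = ()
    high_censor_quantile: float = 0.30
    creatinine_log_mean: float = math.log(10.0)
    creatinine_log_sd: float = 0.4
    gfr_means: tuple[float, float, float] = (112.5, 107.8, 71.2)
    gfr_sd: float = 15.0
    toxin_indices: tuple[int, ...] = ()
    toxin_gfr_rho: float = -0.5
    acr_means: tuple[float, float, float] = (16.65, 16.32, 380.1)
    acr_sds: tuple[float, float, float] = (6.5, 8.3, 272.0)
    age_means: tuple[float, float, float] = (46.0, 51.0, 57.0)
    age_sds: tuple[float, float, float] = (12.0, 5.8, 12.8)
    female_fraction: tuple[float, float, float] = (0.55, 0.55, 0.40)
    metabolite_names: tuple[str, ...] | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise SyntheticSpecError("n_per_group must be >= 2")
        if self.n_metabolites < 1:
            raise SyntheticSpecError("n_metabolites must be >= 1")
        if self.base_log_sd <= 0:
            raise SyntheticSpecError("base_log_sd must be > 0")
        if self.gfr_sd <= 0:
            raise SyntheticSpecError("gfr_sd must be > 0")
        if self.creatinine_log_sd <= 0:
            raise SyntheticSpecError("creatinine_log_sd must be > 0")
        if not 0.0 <= self.censor_quantile < 1.0:
            raise SyntheticSpecError("censor_quantile must be in [0, 1)")
        if not 0.0 <= self.high_censor_quantile < 1.0:
            raise SyntheticSpecError("high_censor_quantile must be in [0, 1)")
        if not -1.0 < self.toxin_gfr_rho < 1.0:
            raise SyntheticSpecError("toxin_gfr_rho must be in (-1, 1)")
        for eff in self.planted:
            if not 0 <= eff.metabolite < self.n_metabolites:
                raise SyntheticSpecError(
                    f"planted metabolite index {eff.metabolite} out of range"
                )
            if eff.group not in GROUPS:
                raise SyntheticSpecError(f"planted group {eff.group!r} unknown")
        for idx in self.high_censor_indices + self.toxin_indices:
            if not 0 <= idx < self.n_metabolites:
                raise SyntheticSpecError(f"metabolite index {idx} out of range")
        if self.metabolite_names is not None and len(self.metabolite_names) != self.n_metabolites:
            raise SyntheticSpecError("metabolite_names length must equal n_metabolites")


@dataclass
class SampleMetadata:
    """Clinical covariates and group labels, indexed by sample id."""

    table: pd.DataFrame  # columns: group, GFR, ACR, age, sex

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def sample_ids(self) -> pd.Index:
        return self.table.index

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.table.loc[list(sample_ids)].copy())


def generate_dataset(spec: SyntheticSpec):
    """Draw one synthetic study; returns ``(MetaboliteTable, SampleMetadata)``.

    Deterministic for a fixed ``spec.seed``.
    """
    from .preprocess import MetaboliteTable  # local import avoids a cycle

    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_per_group * len(GROUPS)
    p = spec.n_metabolites

    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    if spec.metabolite_names is not None:
        met_ids = list(spec.metabolite_names)
    else:
        met_ids = [f"M{j + 1:04d}" for j in range(p)]
    group_of = np.repeat(GROUPS, spec.n_per_group)

    # per-metabolite baseline log-means, spread around the global base
    mu = rng.normal(spec.base_log_mean, spec.metabolite_log_mean_spread, size=p)
    sigma = spec.base_log_sd

    # GFR per group; its cohort-standardized value is the latent renal
    # factor shared with the toxin-like metabolites
    eta = rng.standard_normal(n)
    eps = rng.standard_normal((n, p))
    gfr = np.empty(n)
    for g_idx, g in enumerate(GROUPS):
        mask = group_of == g
        gfr[mask] = spec.gfr_means[g_idx] + spec.gfr_sd * eta[mask]
    gfr = np.clip(gfr, 5.0, None)
    pooled_mean = float(np.mean(spec.gfr_means))
    pooled_sd = math.sqrt(
        float(np.var(spec.gfr_means)) + spec.gfr_sd**2
    )
    r = (gfr - pooled_mean) / pooled_sd

    loading = np.zeros(p)
    loading[list(spec.toxin_indices)] = abs(spec.toxin_gfr_rho)

    log_x = mu[None, :] + sigma * (
        -loading[None, :] * r[:, None]
        + np.sqrt(1.0 - loading[None, :] ** 2) * eps
    )
    for eff in spec.planted:
        mask = group_of == eff.group
        log_x[mask, eff.metabolite] += math.log(2.0) * eff.log2_effect

    values = np.exp(log_x)

    # Type-I left-censoring: LOD at the requested quantile of the marginal
    # (baseline) distribution of each metabolite.
    q = np.full(p, spec.censor_quantile)
    q[list(spec.high_censor_indices)] = spec.high_censor_quantile
    with np.errstate(divide="ignore"):
        lod = np.where(q > 0.0, np.exp(mu + sigma * norm.ppf(q)), 0.0)

    censored = values < lod[None, :]
    values = values.astype(float)
    values[censored] = np.nan

    creatinine = np.exp(
        rng.normal(spec.creatinine_log_mean, spec.creatinine_log_sd, size=n)
    )

    acr = np.empty(n)
    age = np.empty(n)
    sex = np.empty(n, dtype=object)
    for g_idx, g in enumerate(GROUPS):
        mask = group_of == g
        m = mask.sum()
        acr[mask] = np.clip(
            rng.normal(spec.acr_means[g_idx], spec.acr_sds[g_idx], size=m), 1.0, None
        )
        age[mask] = np.clip(
            rng.normal(spec.age_means[g_idx], spec.age_sds[g_idx], size=m), 18.0, None
        )
        sex[mask] = np.where(
            rng.random(m) < spec.female_fraction[g_idx], "F", "M"
        )

    table = MetaboliteTable(
        values=pd.DataFrame(values, index=sample_ids, columns=met_ids),
        lod=pd.Series(lod, index=met_ids, name="lod"),
        creatinine=pd.Series(creatinine, index=sample_ids, name="creatinine_mM"),
    )
    meta = SampleMetadata(
        pd.DataFrame(
            {"group": group_of, "GFR": gfr, "ACR": acr, "age": age, "sex": sex},
            index=pd.Index(sample_ids, name="sample_id"),
        )
    )
    return table, meta


# ---------------------------------------------------------------------------
# Study-condition factory


#: names given to the planted discriminative metabolites of ``study_spec``;
#: chosen after the metabolite classes the assay reports as DN-discriminant
#: (a beta-alanine-like depletion, an N-acetyl-amino-acid-like accumulation,
#: glycemia- and microbiome-linked markers, and uremic toxins tracking GFR).
STUDY_PANEL = {
    "beta_alanine": ("DN", -1.8),
    "kynurenine": ("DN", -1.6),
    "argininic_acid": ("DN", 1.6),
    "glucose": ("DN", 1.5),
    "hydroxybutyric_2": ("DN", 1.5),
    "shikimic_acid": ("DN", 1.4),
    "n_acetyl_asparagine": ("DN", 1.5),
    "cytidine": ("DN", 1.2),
}


def study_spec(seed: int = 0, n_metabolites: int = 268) -> SyntheticSpec:
    """The default synthetic study: a 20/20/20 design with a planted
    DN-discriminative panel, 86 toxin-like metabolites sharing the renal
    latent factor, and a 12-metabolite heavy-censoring subset."""
    names = [f"M{j + 1:04d}" for j in range(n_metabolites)]
    planted = []
    for k, (name, (group, eff)) in enumerate(STUDY_PANEL.items()):
        names[k] = name
        planted.append(PlantedEffect(k, group, eff))
    # the assay's toxin panel is the first 86 metabolites; roughly half of
    # them are renal-coupled (in real cohorts only a minority of catalogued
    # uremic toxins track GFR strongly)
    n_toxins = min(86, n_metabolites)
    toxin_indices = tuple(range(0, n_toxins, 2))
    # heavy-censoring subset: last 12 metabolites (may overlap the toxin
    # block on small panels; censoring and the renal loading are independent)
    n_high = min(12, max(0, n_metabolites - len(planted)))
    high = tuple(range(n_metabolites - n_high, n_metabolites))
    return SyntheticSpec(
        n_metabolites=n_metabolites,
        planted=tuple(planted),
        toxin_indices=toxin_indices,
        high_censor_indices=high,
        metabolite_names=tuple(names),
        seed=seed,
    )


def null_spec(seed: int = 0, n_per_group: int = 20, n_metabolites: int = 100) -> SyntheticSpec:
    """A no-effect study (no planted metabolites, no toxin loadings): every
    metabolite is exchangeable across groups. Used for calibration checks."""
    return SyntheticSpec(
        n_per_group=n_per_group,
        n_metabolites=n_metabolites,
        planted=(),
        toxin_indices=(),
        high_censor_indices=(),
        seed=seed,
    )


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    return replace(spec, seed=seed)
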