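"""Synthetic pediatric cohort generator.

Emulates the statistical structure of a longitudinal whole-blood
amino-acid/acylcarnitine panel study: ~2200 children aged 0.25-18 years with
repeated annual visits and sibling clusters, 30 metabolites whose age
profiles follow one of four canonical shapes, Tanner stage, BMI-SDS, and a
set of laboratory markers built to carry configurable correlations with the
metabolite SDS values.  Ground truth is expressed through the same LMS curve
objects the fitting machinery estimates, so parameter recovery is directly
checkable.

The four age-profile types:

1. elevated in infancy, falling to a minimum around 2-5 years, then stable
   or rising to age 18;
2. continuous increase from 0.25 to 18 years;
3. increase through mid-childhood, then a plateau;
4. no age trend.

Metabolite values are drawn by sampling a z-score (standard normal for
BCCG; Student t via a Gaussian copula for BCT, so the marginal is exactly
t with tau degrees of freedom) and inverting the Cole-Green transform.
Within-subject dependence enters on the z-scale through a subject-level
latent shift with configurable intraclass correlation, which keeps the
marginal percentiles correct in expectation.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .distributions import _boxcox_inv, _boxcox_z, t_to_normal_sds
from .reference import AGE_RANGE, LMSCurves, ParamCurve, SplineBasis

__all__ = [
    "MetaboliteSpec",
    "LabMarkerSpec",
    "CohortConfig",
    "TrueReference",
    "CohortData",
    "default_panel",
    "default_lab_markers",
    "make_true_curves",
    "make_true_reference",
    "simulate_cohort",
    "degrade_panel",
    "write_cohort",
    "read_cohort",
]

SEXES = ("F", "M")

# log-median shift applied to male curves; a mild sex difference
_MALE_LOG_SHIFT = 0.06

# puberty onset ages (years) for Tanner thresholds 1->2 ... 4->5; girls earlier
_TANNER_ONSETS = {"F": (9.2, 11.0, 12.4, 13.8), "M": (10.2, 12.0, 13.4, 14.8)}
_TANNER_SD = 1.2  # between-subject spread of pubertal timing
_TANNER_MISSING_BELOW = 8.0  # stage not assessed below this age


@dataclass(frozen=True)
class MetaboliteSpec:
    """Simulation spec for one metabolite."""

    name: str
    profile_type: int  # 1..4
    family: str  # "BCCG" | "BCT"
    base_level: float  # median scale, umol/L
    L: float = 0.4
    S: float = 0.15
    tau: float = 6.0  # used only for BCT

    def __post_init__(self):
        if self.profile_type not in (1, 2, 3, 4):
            raise ValueError(f"unknown profile_type {self.profile_type}")
        if self.family not in ("BCCG", "BCT"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.base_level <= 0:
            raise ValueError("base_level must be positive")


@dataclass(frozen=True)
class LabMarkerSpec:
    """A laboratory marker as a linear combination of metabolite SDS values.

    ``loadings`` maps metabolite name -> target correlation between the
    marker and that metabolite's SDS.  ``age_coef`` adds a standardized-age
    component (an age-confounded marker); residual noise tops the variance
    up to one, so marker z-scores are standard normal and the realized
    correlations match the targets in expectation.
    """

    name: str
    base: float
    scale: float
    loadings: dict = field(default_factory=dict)
    age_coef: float = 0.0

    def __post_init__(self):
        var = sum(v * v for v in self.loadings.values()) + self.age_coef**2
        if var > 1.0 + 1e-9:
            raise ValueError(
                f"marker {self.name!r}: loadings imply variance {var:.3f} > 1"
            )


def default_panel() -> list[MetaboliteSpec]:
    """The 30-metabolite whole-blood panel: 23 amino acids, 6 acylcarnitines
    and free carnitine, with field-plausible median concentrations (umol/L)
    and profile types; BCT (heavy-tailed) for Asp, Met and Tau."""
    type1 = [
        ("Ala", 330), ("Arg", 60), ("Glu", 250), ("LeuIle", 150), ("Orn", 80),
        ("Pro", 180), ("Ser", 130), ("Thr", 120), ("Tyr", 60), ("C0", 35),
        ("C2", 12), ("C16", 1.2), ("C18:1", 1.0),
    ]
    type2 = [
        ("Aba", 20), ("Asp", 60), ("Gly", 360), ("His", 75), ("OH-Prol", 12),
        ("MeHis", 8), ("PiPA", 1.5), ("Phe", 60), ("Trp", 50), ("Val", 180),
    ]
    type3 = [("Cit", 25), ("Sarc", 2.0)]
    type4 = [("Met", 20), ("Tau", 120), ("C3", 1.5), ("C18", 0.7), ("MMA", 0.25)]
    bct = {"Asp", "Met", "Tau"}
    specs = []
    for ptype, rows in ((1, type1), (2, type2), (3, type3), (4, type4)):
        for name, base in rows:
            specs.append(
                MetaboliteSpec(
                    name=name,
                    profile_type=ptype,
                    family="BCT" if name in bct else "BCCG",
                    base_level=float(base),
                )
            )
    return specs


def default_lab_markers() -> list[LabMarkerSpec]:
    """Thirteen markers of carbohydrate, lipid, liver, kidney and thyroid
    function.  Kidney markers carry broad positive loadings plus an age
    component (age-confounded); HbA1c loads negatively; cholesterol, liver
    and thyroid markers are essentially unrelated to the panel."""
    return [
        LabMarkerSpec("glucose", 85, 10, {"LeuIle": 0.20, "Val": 0.20, "Ala": 0.15}),
        LabMarkerSpec("hba1c", 5.3, 0.3, {"LeuIle": -0.20, "Val": -0.15, "Gly": -0.15}),
        LabMarkerSpec("triglycerides", 90, 35, {"Ala": 0.20, "LeuIle": 0.15, "Tyr": 0.15}),
        LabMarkerSpec("cholesterol_total", 170, 30),
        LabMarkerSpec("ldl_cholesterol", 100, 25),
        LabMarkerSpec("hdl_cholesterol", 55, 12),
        LabMarkerSpec("alt", 20, 8),
        LabMarkerSpec("ast", 25, 8),
        LabMarkerSpec(
            "cystatin_c", 0.85, 0.12,
            {m: 0.22 for m in ("Ala", "Arg", "LeuIle", "Pro", "Thr", "Tyr", "Val", "Gly")},
            age_coef=-0.30,
        ),
        LabMarkerSpec("creatinine", 0.55, 0.15, {"Arg": 0.20, "Gly": 0.15}, age_coef=0.60),
        LabMarkerSpec("tsh", 2.2, 0.9),
        LabMarkerSpec("ft3", 6.0, 1.0),
        LabMarkerSpec("ft4", 16.0, 2.0),
    ]


@dataclass
class CohortConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the emulated study: 2191 subjects contributing ~3989
    visits (mean 1.82 visits/subject), ages 0.25-18 years, balanced sexes,
    sibling clusters, z-scale intraclass correlation 0.4.

    ``bmi_slopes`` maps metabolite -> (female, male) z-scale shift per unit
    BMI-SDS; ``tanner_effects`` maps metabolite -> {"F2": shift, ...} z-scale
    shifts for (sex, stage) cells.  Both default empty (no injected effects).
    """

    n_subjects: int = 2191
    sibling_fraction: float = 0.2
    visits_mean: float = 3989 / 2191
    age_range: tuple = AGE_RANGE
    sex_ratio: float = 0.5  # fraction female
    metabolites: list = field(default_factory=default_panel)
    lab_markers: list = field(default_factory=default_lab_markers)
    lod_map: dict = field(default_factory=dict)
    outlier_rate: float = 0.0
    icc: float = 0.4
    seed: int = 0
    bmi_slopes: dict = field(default_factory=dict)
    tanner_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        lo, hi = self.age_range
        if not (AGE_RANGE[0] - 1e-9 <= lo < hi <= AGE_RANGE[1] + 1e-9):
            raise ValueError(f"age_range must lie within {AGE_RANGE}")
        for name, v in (
            ("sibling_fraction", self.sibling_fraction),
            ("sex_ratio", self.sex_ratio),
            ("outlier_rate", self.outlier_rate),
            ("icc", self.icc),
        ):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.visits_mean < 1:
            raise ValueError("visits_mean must be >= 1")

    def metabolite_names(self) -> list[str]:
        return [m.name for m in self.metabolites]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        return d


# ---------------------------------------------------------------------------
# ground-truth curves


def _log_median_shape(profile_type: int):
    """Relative log-median as a function of v in [0,1], v = normalized sqrt(age)."""
    if profile_type == 1:
        return lambda v: 0.8 * (v - 0.4) ** 2
    if profile_type == 2:
        return lambda v: 0.35 * v
    if profile_type == 3:
        def shape(v):
            w = np.minimum(np.asarray(v, dtype=float) / 0.7, 1.0)
            return 0.30 * (3 * w**2 - 2 * w**3)
        return shape
    if profile_type == 4:
        return lambda v: np.zeros_like(np.asarray(v, dtype=float))
    raise ValueError(f"unknown profile_type {profile_type!r}; expected 1, 2, 3 or 4")


def make_true_curves(
    profile_type: int,
    sex: str,
    base_level: float,
    family: str = "BCCG",
    L: float = 0.4,
    S: float = 0.15,
    tau: float = 6.0,
    age_range=AGE_RANGE,
) -> LMSCurves:
    """Ground-truth LMS curves for one profile type and sex.

    The log-median shape is projected onto the spline basis the fitting code
    uses (exact for types 1, 2 and 4, whose shapes are polynomial on the
    transformed age axis).  L and S are constant; male medians sit a fixed
    log-shift above female ones.
    """
    if sex not in SEXES:
        raise ValueError(f"sex must be one of {SEXES}, got {sex!r}")
    if base_level <= 0:
        raise ValueError("base_level must be positive")
    if not 0.05 <= S <= 0.5:
        raise ValueError("S must lie in [0.05, 0.5]")
    if not -2.0 <= L <= 2.0:
        raise ValueError("L must lie in [-2, 2]")
    shape = _log_median_shape(profile_type)
    df = 6 if profile_type == 3 else 4
    basis = SplineBasis(df, age_range)
    grid = np.linspace(age_range[0], age_range[1], 400)
    u = np.sqrt(grid)
    v = (u - basis.u0) / (basis.u1 - basis.u0)
    logM = np.log(base_level) + shape(v) + (_MALE_LOG_SHIFT if sex == "M" else 0.0)
    cM, *_ = np.linalg.lstsq(basis.design(grid), logM, rcond=None)
    const = SplineBasis(1, age_range)
    return LMSCurves(
        family=family,
        L=ParamCurve(const, np.array([L]), "identity"),
        M=ParamCurve(basis, cM, "log"),
        S=ParamCurve(const, np.array([np.log(S)]), "log"),
        tau=float(tau) if family == "BCT" else None,
    )


@dataclass
class TrueReference:
    """Simulation ground truth: LMS curves per metabolite and sex."""

    curves: dict  # (metabolite, sex) -> LMSCurves
    profile_types: dict  # metabolite -> 1..4

    def curve(self, metabolite: str, sex: str) -> LMSCurves:
        try:
            return self.curves[(metabolite, sex)]
        except KeyError:
            raise KeyError(f"no truth curves for {metabolite!r} / {sex!r}") from None

    def true_sds(self, metabolite, sex, age, value):
        """Normal-scale SDS of a value against the generating distribution."""
        c = self.curve(metabolite, sex)
        z = _boxcox_z(value, *c.params_at(age))
        if c.tau is not None:
            z = t_to_normal_sds(z, c.tau)
        return z

    def to_dict(self) -> dict:
        return {
            "curves": {f"{m}|{s}": c.to_dict() for (m, s), c in self.curves.items()},
            "profile_types": dict(self.profile_types),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TrueReference":
        curves = {}
        for key, cd in d["curves"].items():
            m, s = key.rsplit("|", 1)
            curves[(m, s)] = LMSCurves.from_dict(cd)
        return cls(curves=curves, profile_types=dict(d["profile_types"]))


def make_true_reference(config: CohortConfig) -> TrueReference:
    curves = {}
    types = {}
    for spec in config.metabolites:
        types[spec.name] = spec.profile_type
        for sex in SEXES:
            curves[(spec.name, sex)] = make_true_curves(
                spec.profile_type, sex, spec.base_level, spec.family,
                L=spec.L, S=spec.S, tau=spec.tau, age_range=config.age_range,
            )
    return TrueReference(curves=curves, profile_types=types)


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class CohortData:
    """A simulated cohort: visit table plus the truth that generated it."""

    table: pd.DataFrame
    truth: TrueReference
    config: CohortConfig


def _simulate_visits(config: CohortConfig, rng: np.random.Generator):
    lo, hi = config.age_range
    n = config.n_subjects
    # sibling pairs first (one triple if the sibling count is odd)
    n_sib = int(round(config.sibling_fraction * n))
    if n_sib == 1:
        n_sib = 2 if n >= 2 else 0
    family_of = np.empty(n, dtype=int)
    fam = 0
    i = 0
    while i < n_sib - 1:
        size = 3 if (n_sib - i) == 3 else 2
        family_of[i : i + size] = fam
        i += size
        fam += 1
    while i < n:
        family_of[i] = fam
        i += 1
        fam += 1
    sex = np.where(rng.random(n) < config.sex_ratio, "F", "M")
    n_visits = 1 + rng.poisson(max(config.visits_mean - 1.0, 0.0), size=n)
    rows = []
    for s in range(n):
        a0 = rng.uniform(lo, hi)
        ages = [a0]
        for _ in range(n_visits[s] - 1):
            nxt = ages[-1] + max(0.5, 1.0 + rng.normal(0.0, 0.1))
            if nxt > hi:
                break
            ages.append(nxt)
        for a in ages:
            rows.append((s, family_of[s], sex[s], a))
    df = pd.DataFrame(rows, columns=["_subj", "_fam", "sex", "age_years"])
    df["subject_id"] = "S" + df["_subj"].astype(str).str.zfill(5)
    df["family_id"] = "F" + df["_fam"].astype(str).str.zfill(5)
    return df, sex


def _simulate_tanner(df, rng):
    """Cumulative-ordinal pubertal stage: per-subject timing latent shifts the
    sex-specific onset ages; stage is non-decreasing within subject and
    missing (not assessed) below age 8."""
    subj = df["_subj"].to_numpy()
    n_subj = subj.max() + 1
    timing = rng.normal(0.0, _TANNER_SD, size=n_subj)
    age = df["age_years"].to_numpy()
    stage = np.ones(len(df), dtype=float)
    for sx in SEXES:
        m = (df["sex"] == sx).to_numpy()
        for onset in _TANNER_ONSETS[sx]:
            stage[m] += (age[m] > onset + timing[subj[m]]).astype(float)
    stage[age < 7.0] = 1.0
    out = pd.array(stage.astype(int), dtype="Int64")
    out[age < _TANNER_MISSING_BELOW] = pd.NA
    return out


def simulate_cohort(config: CohortConfig, truth: TrueReference | None = None) -> CohortData:
    """Draw a full synthetic cohort table; fully reproducible from the seed.

    Raises if ``truth`` does not cover every configured metabolite for both
    sexes.  Returns the visit table together with the truth curves so that
    downstream recovery checks can score against the generating distribution.
    """
    if truth is None:
        truth = make_true_reference(config)
    for spec in config.metabolites:
        for sx in SEXES:
            truth.curve(spec.name, sx)  # raises KeyError if missing

    rng = np.random.default_rng(config.seed)
    df, _ = _simulate_visits(config, rng)
    nrow = len(df)
    subj = df["_subj"].to_numpy()
    n_subj = subj.max() + 1
    age = df["age_years"].to_numpy()
    sexcol = df["sex"].to_numpy()

    df["tanner_stage"] = _simulate_tanner(df, rng)
    b_lat = rng.normal(size=n_subj)
    df["bmi_sds"] = np.sqrt(0.8) * b_lat[subj] + np.sqrt(0.2) * rng.normal(size=nrow)
    bmi = df["bmi_sds"].to_numpy()
    stage_num = df["tanner_stage"].to_numpy(dtype=float, na_value=np.nan)

    sds_store = {}
    for spec in config.metabolites:
        u_subj = rng.normal(size=n_subj)
        e = rng.normal(size=nrow)
        zg = np.sqrt(config.icc) * u_subj[subj] + np.sqrt(1.0 - config.icc) * e
        shift = np.zeros(nrow)
        if spec.name in config.bmi_slopes:
            sf, sm = config.bmi_slopes[spec.name]
            shift += np.where(sexcol == "F", sf, sm) * bmi
        for key, delta in config.tanner_effects.get(spec.name, {}).items():
            sx, st = key[0], int(key[1:])
            shift += np.where((sexcol == sx) & (stage_num == st), delta, 0.0)
        vals = np.empty(nrow)
        for sx in SEXES:
            m = sexcol == sx
            c = truth.curve(spec.name, sx)
            L, M, S = c.params_at(age[m])
            if c.tau is not None:
                z = stats.t.ppf(stats.norm.cdf(zg[m]), df=c.tau) + shift[m]
            else:
                z = zg[m] + shift[m]
            # keep z inside the Box-Cox support (mass beyond it is ~Phi(-1/(S|L|)))
            lowbound = np.where(L > 0, -1.0 / (L * S) * 0.999, -np.inf)
            upbound = np.where(L < 0, -1.0 / (L * S) * 0.999, np.inf)
            z = np.clip(z, lowbound, upbound)
            vals[m] = _boxcox_inv(z, L, M, S)
        df[spec.name] = vals
        if spec.family == "BCT":
            sds_store[spec.name] = np.where(
                sexcol == "F",
                t_to_normal_sds(
                    _boxcox_z(vals, *truth.curve(spec.name, "F").params_at(age)),
                    truth.curve(spec.name, "F").tau,
                ),
                t_to_normal_sds(
                    _boxcox_z(vals, *truth.curve(spec.name, "M").params_at(age)),
                    truth.curve(spec.name, "M").tau,
                ),
            )
        else:
            sds_store[spec.name] = zg + shift

    age_std = (age - age.mean()) / max(age.std(), 1e-12)
    for mk in config.lab_markers:
        z = np.zeros(nrow)
        var = 0.0
        for met, rho in mk.loadings.items():
            if met not in sds_store:
                raise ValueError(
                    f"marker {mk.name!r} loads on unknown metabolite {met!r}"
                )
            z += rho * sds_store[met]
            var += rho * rho
        z += mk.age_coef * age_std
        var += mk.age_coef**2
        z += np.sqrt(max(1.0 - var, 0.0)) * rng.normal(size=nrow)
        df[mk.name] = mk.base + mk.scale * z

    df = df.drop(columns=["_subj", "_fam"])
    cols = ["subject_id", "family_id", "sex", "age_years", "tanner_stage", "bmi_sds"]
    df = df[cols + [c for c in df.columns if c not in cols]]
    table = df.reset_index(drop=True)

    if config.outlier_rate > 0 or config.lod_map:
        table = degrade_panel(
            table,
            lod_map=config.lod_map,
            censor_rates={m: 0.0 for m in config.metabolite_names()},
            outlier_rate=config.outlier_rate,
            seed=config.seed + 1,
            metabolites=config.metabolite_names(),
        )
    return CohortData(table=table, truth=truth, config=config)


def degrade_panel(
    table: pd.DataFrame,
    lod_map: dict | None = None,
    censor_rates: dict | float = 0.0,
    outlier_rate: float = 0.0,
    seed: int = 0,
    metabolites: list[str] | None = None,
) -> pd.DataFrame:
    """Inject below-LOD censoring and extreme outliers into a cohort table.

    Values below a metabolite's detection limit (``lod_map``) are replaced by
    the below-LOD sentinel 0; additionally, approximately ``censor_rate`` of
    values are censored at random, and ``outlier_rate`` of the remaining
    values are multiplied by a factor >= e^6 (so they sit far beyond the
    5-SD log-scale cutoff).  Reproducible from the seed; all-zero rates with
    no detection limits return the table unchanged.
    """
    lod_map = lod_map or {}
    if metabolites is None:
        metabolites = list(lod_map) or [
            c for c in table.columns
            if c not in ("subject_id", "family_id", "sex", "age_years",
                         "tanner_stage", "bmi_sds")
        ]
    if not 0.0 <= outlier_rate <= 1.0:
        raise ValueError(f"outlier_rate must lie in [0, 1], got {outlier_rate}")
    rates = (
        {m: float(censor_rates) for m in metabolites}
        if np.isscalar(censor_rates)
        else dict(censor_rates)
    )
    for m, r in rates.items():
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"censor rate for {m!r} must lie in [0, 1], got {r}")
    rng = np.random.default_rng(seed)
    out = table.copy()
    for m in metabolites:
        vals = out[m].to_numpy(dtype=float).copy()
        n = vals.size
        censor = rng.random(n) < rates.get(m, 0.0)
        if m in lod_map:
            censor |= vals < lod_map[m]
        boost = rng.random(n) < outlier_rate
        factor = np.exp(6.0 + rng.exponential(0.5, size=n))
        vals = np.where(boost & ~censor, vals * factor, vals)
        vals = np.where(censor, 0.0, vals)
        out[m] = vals
    return out


# ---------------------------------------------------------------------------
# I/O


def write_cohort(data: CohortData, tsv_path, sidecar_path=None) -> None:
    """Write the visit table as TSV with a JSON sidecar holding the config
    and the ground-truth curves."""
    data.table.to_csv(tsv_path, sep="\t", index=False)
    if sidecar_path is not None:
        payload = {"config": data.config.to_dict(), "truth": data.truth.to_dict()}
        with open(sidecar_path, "w") as fh:
            json.dump(payload, fh, indent=1)


def read_cohort(tsv_path, sidecar_path=None):
    """Read a cohort TSV (and optionally its sidecar truth/config)."""
    table = pd.read_csv(tsv_path, sep="\t", dtype={"subject_id": str, "family_id": str})
    if "tanner_stage" in table:
        table["tanner_stage"] = table["tanner_stage"].astype("Int64")
    if sidecar_path is None:
        return table
    with open(sidecar_path) as fh:
        payload = json.load(fh)
    truth = TrueReference.from_dict(payload["truth"])
    return table, truth, payload["config"]
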