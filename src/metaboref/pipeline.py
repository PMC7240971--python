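"""Configuration-driven orchestration of the full analysis.

simulate/load -> QC -> reference fitting -> SDS scoring -> associations,
writing a complete, reproducible output bundle:

    qc_report.tsv            per-metabolite LOD fractions, retention, outliers
    references/<m>_<sex>.json  fitted LMS curves with fit metadata
    percentiles.tsv          2.5/10/50/90/97.5 percentile curves on an age grid
    sds_table.tsv            per-visit SDS values for retained metabolites
    associations_bmi.tsv     BMI-SDS slopes (pooled or per sex)
    associations_tanner.tsv  Tanner stage 2-5 vs 1 contrasts per sex
    interval_trends.tsv      per-age-interval SDS-on-age slopes
    correlations_absolute.tsv / correlations_sds.tsv   long-format matrices
    clusters.json            metabolite cluster labels + heatmap payload
    run_log.json             versions, seeds, settings, stage notes

Every random procedure receives an explicit seed; rerunning a config yields
a byte-identical bundle.  Configuration is validated (pydantic) before any
computation; the JSON Schema is available from :func:`config_schema`.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .associations import (
    DEFAULT_AGE_CUTS,
    bmi_association,
    cluster_correlation_profiles,
    interval_trends,
    lab_correlations,
    tanner_contrasts,
)
from dataclasses import replace

from .cohort import CohortConfig, default_lab_markers, default_panel, read_cohort, simulate_cohort
from .qc import qc_report
from .reference import (
    AGE_RANGE,
    FittedReference,
    fit_reference,
    fit_reference_resampled,
    percentile_table,
    sds,
)

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "config_schema"]

ID_COLUMNS = ("subject_id", "family_id", "sex", "age_years", "tanner_stage", "bmi_sds")


class PipelineError(RuntimeError):
    """A stage-attributed pipeline failure."""


class SynthSettings(BaseModel):
    n_subjects: int = Field(2191, ge=1)
    sibling_fraction: float = Field(0.2, ge=0.0, le=1.0)
    visits_mean: float = Field(3989 / 2191, ge=1.0)
    icc: float = Field(0.4, ge=0.0, le=1.0)
    outlier_rate: float = Field(0.0, ge=0.0, le=1.0)
    lod_map: dict[str, float] = {}
    seed: int = 0


class QcSettings(BaseModel):
    lod_threshold: float = Field(0.05, ge=0.0, le=1.0)
    outlier_sd: float = Field(5.0, gt=0.0)
    lod_map: dict[str, float] = {}


class ReferenceSettings(BaseModel):
    families: dict[str, str] = {}  # metabolite -> "BCCG"|"BCT"; default per panel
    df_grid: dict[str, list[int]] | None = None
    n_iter: int = Field(100, ge=1)
    seed: int = 0
    resample: bool = True
    age_grid_step: float = Field(0.25, gt=0.0)


class AssociationSettings(BaseModel):
    interval_cuts: list[float] = list(DEFAULT_AGE_CUTS)
    fdr_alpha: float = Field(0.05, gt=0.0, lt=1.0)
    cluster_k: int = Field(5, ge=1)


class PipelineConfig(BaseModel):
    """Validated pipeline configuration.

    Exactly one of ``input_tsv`` (a long-format visit table) or ``synth``
    (synthetic-cohort settings) must be given.  ``metabolites`` / ``markers``
    restrict the analysis to a subset of columns; by default the full
    30-metabolite panel and all marker columns found are used.
    ``lab_reference_tsv`` optionally supplies external LMS tables
    (columns marker, sex, age, L, M, S) for marker SDS conversion; without
    it marker references are fitted internally from the cohort.
    """

    input_tsv: str | None = None
    synth: SynthSettings | None = None
    metabolites: list[str] | None = None
    markers: list[str] | None = None
    lab_reference_tsv: str | None = None
    qc: QcSettings = QcSettings()
    reference: ReferenceSettings = ReferenceSettings()
    association: AssociationSettings = AssociationSettings()
    outdir: str = "metaboref_out"

    @model_validator(mode="after")
    def _one_source(self):
        if (self.input_tsv is None) == (self.synth is None):
            raise ValueError("exactly one of input_tsv or synth must be configured")
        return self


def config_schema() -> dict:
    """JSON Schema of the pipeline configuration."""
    return PipelineConfig.model_json_schema()


def _stage(name):
    def deco(fn):
        def wrapped(*a, **kw):
            try:
                return fn(*a, **kw)
            except PipelineError:
                raise
            except Exception as e:
                raise PipelineError(f"stage '{name}': {e}") from e
        return wrapped
    return deco


@_stage("input")
def _load_table(cfg: PipelineConfig):
    panel = {m.name: m for m in default_panel()}
    if cfg.synth is not None:
        specs = list(panel.values())
        if cfg.metabolites:
            unknown = set(cfg.metabolites) - set(panel)
            if unknown:
                raise ValueError(f"unknown panel metabolites: {sorted(unknown)}")
            specs = [panel[m] for m in cfg.metabolites]
        names = {m.name for m in specs}
        lab = [
            replace(mk, loadings={k: v for k, v in mk.loadings.items() if k in names})
            for mk in default_lab_markers()
        ]
        cc = CohortConfig(
            n_subjects=cfg.synth.n_subjects,
            sibling_fraction=cfg.synth.sibling_fraction,
            visits_mean=cfg.synth.visits_mean,
            icc=cfg.synth.icc,
            outlier_rate=cfg.synth.outlier_rate,
            lod_map=cfg.synth.lod_map,
            seed=cfg.synth.seed,
            metabolites=specs,
            lab_markers=lab,
        )
        data = simulate_cohort(cc)
        table = data.table
        mets = [m.name for m in specs]
        markers = [mk.name for mk in cc.lab_markers]
    else:
        table = read_cohort(cfg.input_tsv)
        missing = [c for c in ("subject_id", "family_id", "sex", "age_years") if c not in table]
        if missing:
            raise ValueError(f"input table lacks required columns {missing}")
        known = set(ID_COLUMNS)
        value_cols = [c for c in table.columns if c not in known]
        mets = cfg.metabolites or [c for c in value_cols if c in panel]
        markers = cfg.markers or [c for c in value_cols if c not in mets]
        absent = [c for c in mets if c not in table.columns]
        if absent:
            raise ValueError(f"configured metabolites absent from table: {absent}")
    if cfg.metabolites:
        mets = [m for m in mets if m in cfg.metabolites]
    if cfg.markers is not None:
        markers = [m for m in markers if m in cfg.markers]
    if table.empty:
        raise ValueError("input table is empty")
    family_map = {m.name: m.family for m in panel.values()}
    family_map.update(cfg.reference.families)
    return table, mets, markers, family_map


@_stage("qc")
def _run_qc(cfg, table, mets):
    filtered, report = qc_report(
        table, mets, lod_map=cfg.qc.lod_map, threshold=cfg.qc.lod_threshold,
        n_sd=cfg.qc.outlier_sd,
    )
    retained = report.loc[report.retained, "metabolite"].tolist()
    return filtered, report, retained


@_stage("references")
def _fit_references(cfg, table, retained, family_map, log):
    refs: dict[tuple[str, str], FittedReference] = {}
    grid = cfg.reference.df_grid
    if grid is not None:
        grid = {k: tuple(v) for k, v in grid.items()}
    for met in retained:
        fam = family_map.get(met, "BCCG")
        for sex in ("F", "M"):
            sub = table[(table["sex"] == sex)]
            ok = np.isfinite(sub[met].astype(float)) & (sub[met] > 0)
            sub = sub[ok]
            multi = sub.groupby("family_id").size().max() > 1
            if cfg.reference.resample and multi:
                ref = fit_reference_resampled(
                    sub, met, sex=sex, family=fam, df_grid=grid,
                    n_iter=cfg.reference.n_iter, seed=cfg.reference.seed,
                )
            else:
                ref = fit_reference(
                    sub["age_years"], sub[met], family=fam, df_grid=grid,
                    metabolite=met, sex=sex,
                )
            if not ref.converged:
                raise ValueError(f"reference fit failed to converge for {met}/{sex}")
            refs[(met, sex)] = ref
            log.setdefault("references", []).append(
                {"metabolite": met, "sex": sex, "family": fam,
                 "df": ref.df_per_parameter, "bic": ref.bic,
                 "resampled": bool(cfg.reference.resample and multi)}
            )
    return refs


def _score_sds(table, refs, mets):
    rows = []
    lo, hi = AGE_RANGE
    for met in mets:
        for sex in ("F", "M"):
            if (met, sex) not in refs:
                continue
            ref = refs[(met, sex)]
            rlo, rhi = ref.curves.age_range
            sub = table[table["sex"] == sex]
            ok = (
                np.isfinite(sub[met].astype(float))
                & (sub[met] > 0)
                & sub["age_years"].between(max(lo, rlo), min(hi, rhi))
            )
            sub = sub[ok]
            if sub.empty:
                continue
            z = sds(sub[met].to_numpy(float), sub["age_years"].to_numpy(float), ref)
            rows.append(
                pd.DataFrame(
                    {
                        "subject_id": sub["subject_id"],
                        "family_id": sub["family_id"],
                        "sex": sex,
                        "age_years": sub["age_years"],
                        "metabolite": met,
                        "value": sub[met].astype(float),
                        "sds": np.atleast_1d(z),
                        "row": sub.index,
                    }
                )
            )
    if not rows:
        raise ValueError("no scorable observations")
    return pd.concat(rows, ignore_index=True)


@_stage("marker_sds")
def _marker_sds(cfg, table, markers, log):
    """Marker SDS from external LMS tables when supplied, else fitted
    internally from the cohort with the same machinery (flagged in the log)."""
    out = {}
    external = {}
    if cfg.lab_reference_tsv:
        ext = pd.read_csv(cfg.lab_reference_tsv, sep="\t")
        need = {"marker", "sex", "age", "L", "M", "S"}
        if not need <= set(ext.columns):
            raise ValueError(f"lab reference table must have columns {sorted(need)}")
        for (mk, sex), g in ext.groupby(["marker", "sex"]):
            external[(mk, sex)] = g.sort_values("age")
    from .distributions import _boxcox_z

    for mk in markers:
        vals = pd.to_numeric(table[mk], errors="coerce")
        col = np.full(len(table), np.nan)
        for sex in ("F", "M"):
            m = (table["sex"] == sex).to_numpy() & np.isfinite(vals) & (vals > 0)
            if m.sum() < 50:
                continue
            age = table.loc[m, "age_years"].to_numpy(float)
            v = vals[m].to_numpy(float)
            if (mk, sex) in external:
                g = external[(mk, sex)]
                L = np.interp(age, g["age"], g["L"])
                M = np.interp(age, g["age"], g["M"])
                S = np.interp(age, g["age"], g["S"])
                col[m] = _boxcox_z(v, L, M, S)
                src = "external"
            else:
                ref = fit_reference(age, v, family="BCCG",
                                    df_grid={"L": (1,), "M": (2, 3), "S": (1,)},
                                    metabolite=mk, sex=sex)
                col[m] = sds(v, age, ref)
                src = "internal"
            log.setdefault("marker_references", []).append(
                {"marker": mk, "sex": sex, "source": src}
            )
        out[mk] = col
    return pd.DataFrame(out, index=table.index)


@_stage("associations")
def _associations(cfg, table, sds_long, marker_sds_df, retained, markers, outdir):
    alpha = cfg.association.fdr_alpha
    sds_wide = sds_long.pivot_table(index="row", columns="metabolite", values="sds")
    meta = table.loc[sds_wide.index]
    wide = pd.concat([meta[list(ID_COLUMNS)], sds_wide], axis=1)

    trends = interval_trends(
        wide, retained, cuts=cfg.association.interval_cuts, alpha=alpha
    )
    bmi = bmi_association(wide, retained, alpha=alpha)
    tanner = tanner_contrasts(wide, retained, alpha=alpha)

    groups = table["subject_id"].to_numpy()
    cors_abs = lab_correlations(
        table[retained].apply(pd.to_numeric, errors="coerce"),
        table[markers].apply(pd.to_numeric, errors="coerce"),
        groups, mode="absolute", alpha=alpha,
    )
    met_sds_full = sds_long.pivot_table(index="row", columns="metabolite", values="sds")
    met_sds_full = met_sds_full.reindex(table.index)
    cors_sds = lab_correlations(
        met_sds_full[retained], marker_sds_df, groups, mode="sds", alpha=alpha
    )
    labels = cluster_correlation_profiles(
        cors_sds, k=min(cfg.association.cluster_k, len(retained))
    )
    return trends, bmi, tanner, cors_abs, cors_sds, labels


def _matrix_long(cm) -> pd.DataFrame:
    est = cm.estimates.stack(future_stack=True).rename("estimate")
    padj = cm.p_adj.stack(future_stack=True).rename("p_adj")
    praw = cm.p_raw.stack(future_stack=True).rename("p_raw")
    out = pd.concat([est, praw, padj], axis=1).reset_index()
    out.columns = ["metabolite", "marker", "estimate", "p_raw", "p_adj"]
    out.insert(2, "mode", cm.mode)
    return out


def run_pipeline(config: PipelineConfig | dict) -> Path:
    """Run the full analysis and write the output bundle; returns outdir."""
    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.model_validate(config)
    log: dict = {
        "metaboref_version": __version__,
        "python": platform.python_version(),
        "seeds": {
            "synth": config.synth.seed if config.synth else None,
            "reference": config.reference.seed,
        },
        "config": json.loads(config.model_dump_json()),
    }
    table, mets, markers, family_map = _load_table(config)
    filtered, report, retained = _run_qc(config, table, mets)
    if not retained:
        raise PipelineError("stage 'qc': no metabolite passed the LOD filter")

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "references").mkdir(exist_ok=True)
    report.to_csv(outdir / "qc_report.tsv", sep="\t", index=False)

    refs = _fit_references(config, filtered, retained, family_map, log)
    ages = np.round(
        np.arange(AGE_RANGE[0], AGE_RANGE[1] + 1e-9, config.reference.age_grid_step), 6
    )
    pct = []
    for (met, sex), ref in sorted(refs.items()):
        safe = met.replace(":", "_").replace("/", "_")
        with open(outdir / "references" / f"{safe}_{sex}.json", "w") as fh:
            json.dump(ref.to_dict(), fh, indent=1)
        pct.append(percentile_table(ref, ages))
    pd.concat(pct, ignore_index=True).to_csv(
        outdir / "percentiles.tsv", sep="\t", index=False
    )

    sds_long = _score_sds(filtered, refs, retained)
    sds_long.drop(columns=["row"]).to_csv(outdir / "sds_table.tsv", sep="\t", index=False)

    marker_sds_df = _marker_sds(config, filtered, markers, log)
    trends, bmi, tanner, cors_abs, cors_sds, labels = _associations(
        config, filtered, sds_long, marker_sds_df, retained, markers, outdir
    )
    trends.to_csv(outdir / "interval_trends.tsv", sep="\t", index=False)
    bmi.to_csv(outdir / "associations_bmi.tsv", sep="\t", index=False)
    tanner.to_csv(outdir / "associations_tanner.tsv", sep="\t", index=False)
    _matrix_long(cors_abs).to_csv(outdir / "correlations_absolute.tsv", sep="\t", index=False)
    _matrix_long(cors_sds).to_csv(outdir / "correlations_sds.tsv", sep="\t", index=False)
    heat = {
        "rows": list(cors_sds.estimates.index),
        "cols": list(cors_sds.estimates.columns),
        "cluster_labels": {str(k): int(v) for k, v in labels.items()},
        "missing_markers": cors_sds.missing_markers,
    }
    with open(outdir / "clusters.json", "w") as fh:
        json.dump(heat, fh, indent=1)
    with open(outdir / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    return outdir
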