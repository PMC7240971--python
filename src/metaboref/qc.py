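"""Quality-control filters applied to a metabolite panel before modelling.

Two rules, applied per metabolite across the whole cohort:

* limit-of-detection filter — a metabolite is excluded when strictly more
  than 5% of its measurements fall below the detection limit (zeros encode
  non-detects and always count as below the limit);
* log-scale outlier removal — nonzero values further than 5 standard
  deviations from the mean of the logarithmized nonzero data are dropped.
  Zeros are never dropped by this rule; they are non-detects, not
  biological outliers, and are excluded from modelling separately.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["QcRow", "lod_filter", "outlier_mask", "qc_report", "LOD_FRACTION", "OUTLIER_SD"]

LOD_FRACTION = 0.05  # exclusion threshold: fraction below LOD must not exceed this
OUTLIER_SD = 5.0  # log-scale cutoff in standard deviations


@dataclass(frozen=True)
class QcRow:
    """Per-metabolite QC summary."""

    metabolite: str
    n_total: int
    n_below_lod: int
    fraction_below_lod: float
    retained: bool
    n_outliers_removed: int
    log_mean: float
    log_sd: float


def lod_filter(values, lod: float, threshold: float = LOD_FRACTION):
    """Decide retention of a metabolite from its below-LOD fraction.

    Returns ``(retained, n_below, fraction)``.  Retention fails only on the
    strict inequality ``fraction > threshold``: exactly 5% below the limit
    keeps the metabolite.  Zeros count as below the limit regardless of it.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("lod_filter requires a non-empty value list")
    if lod < 0:
        raise ValueError("detection limit must be non-negative")
    below = (values < lod) | (values == 0)
    n_below = int(below.sum())
    fraction = n_below / values.size
    return fraction <= threshold, n_below, fraction


def outlier_mask(values, n_sd: float = OUTLIER_SD):
    """Keep-mask for the +/- ``n_sd`` log-scale outlier rule.

    Mean and SD are computed on the natural log of the nonzero values only
    (the rule is invariant to the log base since both moments rescale
    together).  A nonzero value is dropped iff ``|ln v - mean| > n_sd * SD``;
    zeros always survive.  Returns ``(keep_mask, log_mean, log_sd)``.
    """
    values = np.asarray(values, dtype=float)
    nonzero = values > 0
    if int(nonzero.sum()) < 3:
        raise ValueError("outlier_mask requires at least 3 nonzero values")
    logs = np.log(values[nonzero])
    log_mean = float(np.mean(logs))
    log_sd = float(np.std(logs, ddof=1))
    keep = np.ones(values.size, dtype=bool)
    # strict >: with log_sd == 0 nothing can exceed the cutoff
    keep[nonzero] = np.abs(logs - log_mean) <= n_sd * log_sd
    return keep, log_mean, log_sd


def qc_report(
    table: pd.DataFrame,
    metabolites: list[str],
    lod_map: dict[str, float] | None = None,
    threshold: float = LOD_FRACTION,
    n_sd: float = OUTLIER_SD,
):
    """Run both QC rules over a cohort table.

    Returns ``(filtered_table, report)`` where the table has outlier cells of
    retained metabolites set to NaN (excluded metabolites are left untouched
    but flagged), and the report is one :class:`QcRow` per metabolite.
    The two rules are applied exactly once, LOD first.
    """
    lod_map = lod_map or {}
    out = table.copy()
    rows = []
    for met in metabolites:
        values = table[met].to_numpy(dtype=float)
        finite = np.isfinite(values)
        vals = values[finite]
        retained, n_below, fraction = lod_filter(vals, lod_map.get(met, 0.0), threshold)
        n_out = 0
        log_mean = np.nan
        log_sd = np.nan
        if retained:
            keep, log_mean, log_sd = outlier_mask(vals, n_sd)
            n_out = int((~keep).sum())
            if n_out:
                idx = out.index[finite][~keep]
                out.loc[idx, met] = np.nan
        rows.append(
            QcRow(
                metabolite=met,
                n_total=int(vals.size),
                n_below_lod=n_below,
                fraction_below_lod=fraction,
                retained=retained,
                n_outliers_removed=n_out,
                log_mean=log_mean,
                log_sd=log_sd,
            )
        )
    report = pd.DataFrame([r.__dict__ for r in rows])
    return out, report
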