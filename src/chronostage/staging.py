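"""Molecular staging: Predicted Age from developmental gene expression.

Toxicant exposure slows larval development, so samples harvested at the same
clock time can sit at different developmental ages -- a confound for any
expression comparison at fixed harvest time.  The staging procedure assigns
each sample a *Predicted Age* (PA):

1.  A developmental screen over the unexposed continuous arm keeps probes
    whose expression varies with harvest time (one-way ANOVA, BH FDR < 0.001)
    and changes at least 1.8-fold from time zero to some harvest.
2.  For each harvest, a staging panel is drawn from the screen: probes with
    at least a 2-fold change over the two preceding harvest intervals, a
    linear response (r^2 > 0.95 of harvest-mean expression on time), and no
    toxicant-dependent expression changes.
3.  Per panel probe, ordinary least squares of log2 expression on harvest
    time over the window (unexposed continuous samples only) gives a
    calibration line x = a + b t.
4.  A sample's apparent age under one probe is the inverse prediction
    (x - a)/b; the unweighted mean over the panel is its PA, the standard
    deviation of the apparent ages its dispersion.  The start of exposure is
    age zero.

The toxicant-dependent exclusion in step 2 is bootstrapped: the first pass
stages with no exclusions, a PA-adjusted lenient differential-expression
screen then flags exposure-responsive probes, and staging is repeated with
those excluded.  (A delay-unaware exposed-vs-control purge would evict every
sloped developmental probe -- a delayed developmental gene *does* differ from
control at matched harvest time -- and leave no panel.)
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datatypes import harvest_grid, indexed_metadata, select_samples
from .diffexpr import bh_fdr, lenient_significant


@dataclass(frozen=True)
class AgeModel:
    """Linear calibration x = intercept + slope * age for one probe."""

    probe_id: str
    intercept: float
    slope: float
    r2: float
    window: tuple[float, float]


@dataclass(frozen=True)
class PredictedAge:
    """Staging result for one sample."""

    sample_id: str
    pa_h: float
    sd_h: float
    n_probes: int
    extrapolated: bool


# ---------------------------------------------------------------------------
# developmental screen


def _control_samples_by_harvest(meta: pd.DataFrame) -> dict[float, list[str]]:
    out: dict[float, list[str]] = {}
    for h in harvest_grid(meta):
        ids = select_samples(meta, concentration=0.0, regime="continuous", harvest=h)
        if ids:
            out[h] = ids
    return out


def select_developmental_probes(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Screen for developmentally regulated probes in unexposed controls.

    One-way ANOVA over harvest time on the unexposed continuous samples, BH
    step-up across all tested probes, plus a fold filter: max over harvests of
    |mean log2(t) - mean log2(0)| >= log2(fc_dev).  Returns a DataFrame
    indexed by probe_id with columns ``p, q, max_abs_log2fc, selected``.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    groups = _control_samples_by_harvest(meta)
    if len(groups) < 3:
        raise ValueError("need >= 3 harvest times in the unexposed continuous arm")
    for h, ids in groups.items():
        if len(ids) < 2:
            raise ValueError(
                f"harvest {h} has {len(ids)} replicate(s); within-group variance undefined"
            )
    arrays = [matrix[ids].to_numpy(dtype=float) for ids in groups.values()]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant probes raise ConstantInputWarning
        f, p = stats.f_oneway(*arrays, axis=1)
    # a probe constant in every sample has no harvest signal: not selected
    p = np.where(np.isnan(p), 1.0, p)

    t0 = min(groups)
    base = matrix[groups[t0]].mean(axis=1)
    fold = pd.Series(0.0, index=matrix.index)
    for h, ids in groups.items():
        if h == t0:
            continue
        fold = np.maximum(fold, (matrix[ids].mean(axis=1) - base).abs())

    q = bh_fdr(p)
    out = pd.DataFrame(
        {
            "p": p,
            "q": q,
            "max_abs_log2fc": fold,
            "selected": (q < config.fdr_dev) & (fold >= config.log2_fc_dev),
        },
        index=matrix.index.rename("probe_id"),
    )
    return out


# ---------------------------------------------------------------------------
# per-harvest staging panel


def _staging_window(grid: list[float], harvest_t: float) -> list[float]:
    if harvest_t not in grid:
        raise ValueError(f"harvest {harvest_t} not in grid {grid}")
    i = grid.index(harvest_t)
    if i == 0:
        raise ValueError("the baseline harvest has no preceding interval")
    if i == 1:
        warnings.warn(
            f"harvest {harvest_t:g} h has a single preceding interval; "
            "staging window truncated",
            stacklevel=3,
        )
    return grid[max(0, i - 2) : i + 1]


def select_staging_subset(
    dev_probes,
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    harvest_t: float,
    de_probes_to_exclude=(),
    config: AnalysisConfig | None = None,
) -> list[str]:
    """Staging panel for one harvest.

    ``dev_probes`` may be the screen DataFrame of
    :func:`select_developmental_probes` or a plain list of probe ids.  Over
    the window of the two preceding harvest intervals a probe must change by
    at least ``fc_stage``-fold (the threshold is pro-rated for truncated early
    windows by window span relative to two nominal intervals), respond
    linearly (r^2 of harvest-mean expression on time > ``r2_stage``), and not
    appear in the exclusion list of toxicant-responsive probes.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    if isinstance(dev_probes, pd.DataFrame):
        candidates = list(dev_probes.index[dev_probes["selected"]])
    else:
        candidates = list(dev_probes)
    exclude = set(de_probes_to_exclude)
    candidates = [p for p in candidates if p not in exclude and p in matrix.index]

    groups = _control_samples_by_harvest(meta)
    grid = sorted(groups)
    window = _staging_window(grid, harvest_t)
    span = window[-1] - window[0]
    nominal = float(np.median(np.diff(grid))) if len(grid) > 1 else span
    fold_threshold = config.log2_fc_stage * span / (2.0 * nominal)

    sub = matrix.loc[candidates]
    means = np.column_stack([sub[groups[h]].mean(axis=1).to_numpy() for h in window])
    t = np.asarray(window, dtype=float)

    fold_ok = np.abs(means[:, -1] - means[:, 0]) >= fold_threshold
    if len(window) >= 3:
        tc = t - t.mean()
        mc = means - means.mean(axis=1, keepdims=True)
        denom = (mc**2).sum(axis=1) * (tc**2).sum()
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, (mc @ tc) ** 2 / np.where(denom > 0, denom, 1.0), 0.0)
        linear_ok = r2 > config.r2_stage
    else:
        linear_ok = np.ones(len(candidates), dtype=bool)  # two points: exactly linear
    return [p for p, ok in zip(candidates, fold_ok & linear_ok) if ok]


# ---------------------------------------------------------------------------
# age models


def fit_age_models(
    staging_panel,
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    window: tuple[float, float],
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """OLS calibration of log2 expression on harvest time per panel probe.

    Fit over the unexposed continuous samples with harvest inside ``window``
    (inclusive).  Probes with |slope| < ``slope_min`` are dropped: near-flat
    calibrations amplify noise unboundedly under inverse prediction.  Returns
    a DataFrame indexed by probe_id with columns ``intercept, slope, r2,
    window_lo, window_hi``.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    lo, hi = window
    groups = _control_samples_by_harvest(meta)
    samples: list[str] = []
    times: list[float] = []
    for h, ids in groups.items():
        if lo <= h <= hi:
            samples.extend(ids)
            times.extend([h] * len(ids))
    if len(samples) < 3:
        raise ValueError(f"only {len(samples)} calibration samples in window {window}")

    panel = [p for p in staging_panel if p in matrix.index]
    Y = matrix.loc[panel, samples].to_numpy(dtype=float)
    t = np.asarray(times, dtype=float)
    tc = t - t.mean()
    sxx = float((tc**2).sum())
    yc = Y - Y.mean(axis=1, keepdims=True)
    slope = (yc @ tc) / sxx
    intercept = Y.mean(axis=1) - slope * t.mean()
    ss_tot = (yc**2).sum(axis=1)
    ss_reg = slope**2 * sxx
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, ss_reg / np.where(ss_tot > 0, ss_tot, 1.0), 0.0)

    models = pd.DataFrame(
        {
            "intercept": intercept,
            "slope": slope,
            "r2": np.clip(r2, 0.0, 1.0),
            "window_lo": lo,
            "window_hi": hi,
        },
        index=pd.Index(panel, name="probe_id"),
    )
    return models[models["slope"].abs() >= config.slope_min]


def models_as_records(models: pd.DataFrame) -> list[AgeModel]:
    """Typed view of an age-model table."""
    return [
        AgeModel(
            probe_id=str(i),
            intercept=float(r.intercept),
            slope=float(r.slope),
            r2=float(r.r2),
            window=(float(r.window_lo), float(r.window_hi)),
        )
        for i, r in models.iterrows()
    ]


def predict_age(
    sample: pd.Series, models: pd.DataFrame, weighted: bool = False
) -> PredictedAge:
    """Invert every calibration line and average the apparent ages.

    ``sample`` is a log2 expression vector indexed by probe_id (extra probes
    are ignored); apparent age per probe is (x - intercept)/slope.  PA is the
    unweighted mean (the default), SD the standard deviation of the apparent
    ages.  With ``weighted=True`` a precision-weighted mean is used instead,
    weights proportional to slope^2 (the inverse variance of the inverted age
    under homoscedastic expression noise).  PAs outside the calibration
    window are permitted but flagged ``extrapolated``.
    """
    if len(models) == 0:
        raise ValueError("empty age-model list")
    x = sample.reindex(models.index)
    if x.isna().any():
        missing = list(x.index[x.isna()])[:5]
        raise ValueError(f"sample lacks panel probes {missing}")
    slopes = models["slope"].to_numpy()
    ages = (x.to_numpy(dtype=float) - models["intercept"].to_numpy()) / slopes
    if weighted:
        w = slopes**2
        pa = float(np.average(ages, weights=w))
    else:
        pa = float(ages.mean())
    sd = float(ages.std(ddof=1)) if len(ages) > 1 else 0.0
    lo = float(models["window_lo"].iloc[0])
    hi = float(models["window_hi"].iloc[0])
    return PredictedAge(
        sample_id=str(sample.name),
        pa_h=pa,
        sd_h=sd,
        n_probes=len(ages),
        extrapolated=not (lo <= pa <= hi),
    )


# ---------------------------------------------------------------------------
# whole-design staging


def stage_samples(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: AnalysisConfig | None = None,
    exclude=(),
    dev_screen: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict[float, pd.DataFrame]]:
    """Predicted Age for every sample, using per-harvest staging panels.

    Samples at harvest t are staged with the panel calibrated over the window
    ending at t; baseline (time-zero) samples reuse the earliest panel with a
    warning, since no preceding interval exists there.  Returns the PA table
    (indexed by sample_id: ``pa_h, sd_h, n_probes, extrapolated, harvest_h``)
    and the per-harvest age-model tables.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    if dev_screen is None:
        dev_screen = select_developmental_probes(matrix, meta, config)
    grid = harvest_grid(meta)

    panels: dict[float, pd.DataFrame] = {}
    for h in grid[1:]:
        panel = select_staging_subset(dev_screen, matrix, meta, h, exclude, config)
        window_times = _staging_window(grid, h)
        models = fit_age_models(
            panel, matrix, meta, (window_times[0], window_times[-1]), config
        )
        if len(models) == 0:
            raise ValueError(f"no staging probes survive for harvest {h:g} h")
        panels[h] = models

    rows = []
    for h in grid:
        models = panels[h] if h in panels else panels[grid[1]]
        if h not in panels:
            warnings.warn(
                f"harvest {h:g} h staged with the earliest calibration window",
                stacklevel=2,
            )
        sub = matrix.loc[
            models.index, select_samples(meta, harvest=h)
        ]
        a = models["intercept"].to_numpy()[:, None]
        b = models["slope"].to_numpy()[:, None]
        ages = (sub.to_numpy(dtype=float) - a) / b
        pa = ages.mean(axis=0)
        sd = ages.std(axis=0, ddof=1) if ages.shape[0] > 1 else np.zeros(ages.shape[1])
        lo = float(models["window_lo"].iloc[0])
        hi = float(models["window_hi"].iloc[0])
        for j, sid in enumerate(sub.columns):
            rows.append(
                (
                    sid,
                    float(pa[j]),
                    float(sd[j]),
                    len(models),
                    not (lo <= pa[j] <= hi),
                    h,
                )
            )
    pa_table = pd.DataFrame(
        rows, columns=["sample_id", "pa_h", "sd_h", "n_probes", "extrapolated", "harvest_h"]
    ).set_index("sample_id")
    return pa_table, panels


def stage_with_purge(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: AnalysisConfig | None = None,
    n_iter: int = 1,
) -> tuple[pd.DataFrame, dict[float, pd.DataFrame], list[str]]:
    """Stage, purge toxicant-responsive probes, and restage.

    The exclusion list after each pass is the set of probes passing the
    lenient PA-adjusted screen (p < 0.01, 1.5-fold) at any continuous-arm
    harvest; ``n_iter`` bootstrap iterations are performed (default 1).
    Returns the final PA table, panels, and the exclusion list.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    dev_screen = select_developmental_probes(matrix, meta, config)
    pa_table, panels = stage_samples(matrix, meta, config, (), dev_screen)
    exclusion: list[str] = []
    for _ in range(n_iter):
        exclusion = lenient_significant(matrix, meta, pa_table, config, arm="continuous")
        pa_table, panels = stage_samples(matrix, meta, config, exclusion, dev_screen)
    return pa_table, panels, exclusion


# ---------------------------------------------------------------------------
# delay estimation


def estimate_delay(
    pa_exposed: pd.DataFrame,
    pa_control: pd.DataFrame,
    harvest_t: float | None = None,
) -> float:
    """Developmental delay: mean control PA minus mean exposed PA (hours).

    Both tables must carry ``pa_h`` and ``harvest_h``; all rows must share the
    same harvest (checked against ``harvest_t`` when given).
    """
    if len(pa_exposed) == 0 or len(pa_control) == 0:
        raise ValueError("both PA sets must be non-empty")
    harvests = set(pa_exposed["harvest_h"]) | set(pa_control["harvest_h"])
    if len(harvests) != 1:
        raise ValueError(f"mismatched harvests in delay estimate: {sorted(harvests)}")
    if harvest_t is not None and harvests != {harvest_t}:
        raise ValueError(
            f"PA sets are from harvest {harvests.pop():g}, expected {harvest_t:g}"
        )
    return float(pa_control["pa_h"].mean() - pa_exposed["pa_h"].mean())


def delay_table(
    pa_table: pd.DataFrame,
    metadata: pd.DataFrame,
    arm: str = "continuous",
    high_concentration: float | None = None,
) -> pd.DataFrame:
    """Per-harvest delay estimates for one exposure arm."""
    meta = indexed_metadata(metadata)
    if high_concentration is None:
        high_concentration = float(meta["concentration_uM"].max())
    rows = []
    for h in harvest_grid(meta):
        exp_ids = select_samples(
            meta, concentration=high_concentration, regime=arm, harvest=h
        )
        ctl_regime = "continuous" if arm == "continuous" else "sham" + arm.removeprefix("washout")
        ctl_ids = select_samples(meta, concentration=0.0, regime=ctl_regime, harvest=h)
        if not ctl_ids:
            ctl_ids = select_samples(meta, concentration=0.0, regime="continuous", harvest=h)
        if not exp_ids or not ctl_ids:
            continue
        d = estimate_delay(pa_table.loc[exp_ids], pa_table.loc[ctl_ids], h)
        rows.append((h, arm, d, len(exp_ids), len(ctl_ids)))
    return pd.DataFrame(
        rows, columns=["harvest_h", "arm", "delay_h", "n_exposed", "n_control"]
    )
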