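"""Delay-adjusted differential expression and the downstream filter cascade.

The central model is a per-probe, per-harvest ANCOVA::

    log2 x = b0 + b1 * PA + b2 * I(exposed)

fit on the exposed samples of one harvest together with the control samples
of that harvest and the preceding one.  Predicted Age (PA) rather than
harvest time is the covariate, so expression differences that merely reflect
a toxicant-induced developmental delay are absorbed by b1 and the exposure
term b2 estimates the developmentally-independent effect (it doubles as the
adjusted log2 fold change).  b2 is tested with a two-sided t-test.

Strict significance requires three rules: p < 1e-4 on the exposure term, an
adjusted fold change of at least 1.8, and the *range guard* -- the mean
exposed expression (linear scale) must lie at least 1.2-fold outside the
min-max envelope of the included control samples, protecting the linear
model against non-linear time trends across a harvest interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import AnalysisConfig
from .datatypes import harvest_grid, indexed_metadata, select_samples

ARMS = ("continuous", "washout8")


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values.

    Monotone non-decreasing in the p-value rank and capped at 1.  Raises
    ``ValueError`` for p values outside [0, 1].
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p values")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# sample selection


def _control_regime(arm: str, metadata: pd.DataFrame, harvest: float) -> str:
    """Unexposed regime matched to an arm at one harvest (sham if available)."""
    if arm == "continuous":
        return "continuous"
    sham = "sham" + arm.removeprefix("washout")
    ids = select_samples(metadata, concentration=0.0, regime=sham, harvest=harvest)
    return sham if ids else "continuous"


def ancova_samples(
    metadata: pd.DataFrame,
    harvest_t: float,
    arm: str = "continuous",
    high_concentration: float | None = None,
) -> tuple[list[str], list[str]]:
    """(exposed, control) sample ids entering the ANCOVA at one harvest.

    Exposed: high-concentration samples of the arm at ``harvest_t``.
    Controls: unexposed samples (arm-matched regime where available) at
    ``harvest_t`` and at the preceding harvest of the full grid.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    if high_concentration is None:
        high_concentration = float(metadata["concentration_uM"].max())
    grid = harvest_grid(metadata)
    if harvest_t not in grid:
        raise ValueError(f"harvest {harvest_t} not in the design grid {grid}")
    i = grid.index(harvest_t)
    if i == 0:
        raise ValueError("no preceding harvest for the baseline time point")
    prev = grid[i - 1]

    exposed = select_samples(
        metadata, concentration=high_concentration, regime=arm, harvest=harvest_t
    )
    controls: list[str] = []
    for h in (prev, harvest_t):
        regime = _control_regime(arm, metadata, h)
        controls.extend(
            select_samples(metadata, concentration=0.0, regime=regime, harvest=h)
        )
    return exposed, controls


# ---------------------------------------------------------------------------
# ANCOVA


def ancova_de(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pa_table: pd.DataFrame,
    harvest_t: float,
    arm: str = "continuous",
    config: AnalysisConfig | None = None,
) -> pd.DataFrame:
    """Per-probe ANCOVA of exposure adjusted for Predicted Age at one harvest.

    ``pa_table`` must provide a ``pa_h`` column indexed by sample_id for every
    sample in the analysis set.  Returns a DataFrame indexed by probe_id with
    columns ``harvest_h, log2fc, se, t, p, q, n`` where ``log2fc`` is the b2
    contrast and ``q`` the BH adjustment across probes within the harvest.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    exposed, controls = ancova_samples(meta, harvest_t, arm)
    if not exposed or not controls:
        raise ValueError(f"no exposed or control samples at harvest {harvest_t} ({arm})")
    samples = controls + exposed

    missing = [s for s in samples if s not in pa_table.index]
    if missing:
        raise ValueError(f"samples without Predicted Age: {missing[:10]}")
    pa = pa_table.loc[samples, "pa_h"].to_numpy(dtype=float)
    is_exposed = np.array([0.0] * len(controls) + [1.0] * len(exposed))

    X = np.column_stack([np.ones(len(samples)), pa, is_exposed])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            f"rank-deficient ANCOVA design at harvest {harvest_t} "
            "(PA collinear with the exposure indicator)"
        )
    df_resid = len(samples) - X.shape[1]
    if df_resid < 2:
        raise ValueError(
            f"only {df_resid} residual degrees of freedom at harvest {harvest_t}"
        )

    Y = matrix[samples].to_numpy(dtype=float).T  # samples x probes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    sigma2 = (resid**2).sum(axis=0) / df_resid
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * xtx_inv[2, 2], 0.0))
    # zero residual variance: an exact fit gives an infinite t for any
    # nonzero contrast and t = 0 for a null one
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(
            se > 0,
            beta[2] / np.where(se > 0, se, 1.0),
            np.where(np.abs(beta[2]) > 1e-12, np.inf, 0.0),
        )
    p = 2.0 * stats.t.sf(np.abs(tstat), df_resid)
    return pd.DataFrame(
        {
            "harvest_h": harvest_t,
            "log2fc": beta[2],
            "se": se,
            "t": tstat,
            "p": p,
            "q": bh_fdr(p),
            "n": len(samples),
        },
        index=matrix.index.rename("probe_id"),
    )


def range_guard(
    matrix: pd.DataFrame,
    exposed_samples: list[str],
    control_samples: list[str],
    guard: float = 1.2,
) -> pd.Series:
    """Flag probes whose exposed mean lies outside the control envelope.

    Works on the linear scale: pass iff mean(2^x over exposed) is at least
    ``guard``-fold above the control maximum or below the control minimum.
    Boundary equality with the envelope fails (1.0-fold is not 1.2-fold).
    """
    linear = np.power(2.0, matrix[exposed_samples + control_samples].to_numpy(dtype=float))
    n_exp = len(exposed_samples)
    exp_mean = linear[:, :n_exp].mean(axis=1)
    ctrl = linear[:, n_exp:]
    cmin, cmax = ctrl.min(axis=1), ctrl.max(axis=1)
    ok = (exp_mean >= guard * cmax) | (exp_mean <= cmin / guard)
    return pd.Series(ok, index=matrix.index, name="range_pass")


# ---------------------------------------------------------------------------
# cascade


@dataclass
class DESetSummary:
    """Per-arm differential-expression summary.

    ``p_fold_significant`` holds the sets passing the p and fold rules only;
    ``significant`` additionally requires the range guard.  ``venn`` maps a
    '&'-joined harvest signature to the count of probes significant at
    exactly those harvests; its values sum to ``len(union)`` by construction.
    """

    arm: str
    harvests: list[float]
    results: dict[float, pd.DataFrame] = field(default_factory=dict)
    significant: dict[float, list[str]] = field(default_factory=dict)
    p_fold_significant: dict[float, list[str]] = field(default_factory=dict)
    union: list[str] = field(default_factory=list)
    venn: dict[str, int] = field(default_factory=dict)

    def counts(self) -> dict[float, int]:
        return {h: len(v) for h, v in self.significant.items()}


def _venn_partition(sets: dict[float, list[str]]) -> tuple[list[str], dict[str, int]]:
    membership: dict[str, tuple] = {}
    for h in sorted(sets):
        for probe in sets[h]:
            membership.setdefault(probe, ())
    for h in sorted(sets):
        members = set(sets[h])
        for probe in membership:
            if probe in members:
                membership[probe] += (h,)
    union = list(membership)
    venn: dict[str, int] = {}
    for sig in membership.values():
        key = "&".join(f"{h:g}" for h in sig)
        venn[key] = venn.get(key, 0) + 1
    return union, venn


def de_cascade(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pa_table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    arm: str = "continuous",
    harvests: list[float] | None = None,
) -> DESetSummary:
    """Run the strict cascade (ANCOVA p, fold change, range guard) per harvest."""
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    if harvests is None:
        grid = harvest_grid(meta)
        harvests = [
            h
            for h in grid[1:]
            if select_samples(
                meta, concentration=meta["concentration_uM"].max(), regime=arm, harvest=h
            )
        ]
    summary = DESetSummary(arm=arm, harvests=list(harvests))
    for h in harvests:
        res = ancova_de(matrix, meta, pa_table, h, arm, config)
        exposed, controls = ancova_samples(meta, h, arm)
        res["range_pass"] = range_guard(matrix, exposed, controls, config.range_guard)
        p_fold = (res["p"] < config.p_de) & (res["log2fc"].abs() >= config.log2_fc_de)
        res["significant"] = p_fold & res["range_pass"]
        summary.results[h] = res
        summary.p_fold_significant[h] = list(res.index[p_fold])
        summary.significant[h] = list(res.index[res["significant"]])
    summary.union, summary.venn = _venn_partition(summary.significant)
    return summary


# ---------------------------------------------------------------------------
# recovery and special gene lists


@dataclass
class RecoveryResult:
    """Washout-phase differential expression and recovery-specific probes."""

    strict: DESetSummary
    continuous_lenient: list[str]
    washout_unique: list[str]


def lenient_significant(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pa_table: pd.DataFrame,
    config: AnalysisConfig | None = None,
    arm: str = "continuous",
    harvests: list[float] | None = None,
) -> list[str]:
    """Probes passing the lenient screen (p < 0.01, 1.5-fold) at any harvest.

    Applied per harvest with no multiplicity correction and no range guard --
    this is a screen against false uniqueness, not a discovery rule.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    if harvests is None:
        grid = harvest_grid(meta)
        harvests = [
            h
            for h in grid[1:]
            if select_samples(
                meta, concentration=meta["concentration_uM"].max(), regime=arm, harvest=h
            )
        ]
    hits: set[str] = set()
    for h in harvests:
        res = ancova_de(matrix, meta, pa_table, h, arm, config)
        m = (res["p"] < config.p_lenient) & (
            res["log2fc"].abs() >= config.log2_fc_lenient
        )
        hits.update(res.index[m])
    return [p for p in matrix.index if p in hits]


def recovery_analysis(
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    pa_table: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> RecoveryResult:
    """Strict DE in the 8 h-washout arm and the washout-unique probe list.

    A probe is *washout-unique* when it is strict-significant at some washout
    harvest but does not even pass the lenient criteria at any harvest of the
    continuous arm.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    high = meta["concentration_uM"].max()
    if not select_samples(meta, concentration=high, regime="continuous"):
        raise ValueError("continuous-arm data are required for the uniqueness screen")
    strict = de_cascade(matrix, meta, pa_table, config, arm="washout8")
    lenient = set(
        lenient_significant(matrix, meta, pa_table, config, arm="continuous")
    )
    unique = [p for p in strict.union if p not in lenient]
    return RecoveryResult(
        strict=strict,
        continuous_lenient=sorted(lenient),
        washout_unique=unique,
    )


def delay_resistant_genes(
    dev_probes: list[str],
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    config: AnalysisConfig | None = None,
    step_window: tuple[float, float] = (8.0, 26.0),
) -> list[str]:
    """Developmental probes whose expression timing ignores the delay.

    Continuous-arm rules: (1) at every harvest the exposed/control difference
    is at most ``delay_resistant_max_fc`` (default 1.2-fold); (2) some pair of
    consecutive harvests inside ``step_window`` steps by at least
    ``delay_resistant_min_step`` (default 1.8-fold) in the control arm.
    """
    config = config or AnalysisConfig()
    meta = indexed_metadata(metadata, matrix)
    high = meta["concentration_uM"].max()
    grid = harvest_grid(meta)
    sub = matrix.loc[[p for p in dev_probes if p in matrix.index]]

    ctrl_means: dict[float, pd.Series] = {}
    ok = pd.Series(True, index=sub.index)
    rule1_tol = np.log2(config.delay_resistant_max_fc)
    for h in grid:
        exp_ids = select_samples(meta, concentration=high, regime="continuous", harvest=h)
        ctl_ids = select_samples(meta, concentration=0.0, regime="continuous", harvest=h)
        if ctl_ids:
            ctrl_means[h] = sub[ctl_ids].mean(axis=1)
        if exp_ids and ctl_ids:
            diff = (sub[exp_ids].mean(axis=1) - ctrl_means[h]).abs()
            ok &= diff <= rule1_tol

    step_tol = np.log2(config.delay_resistant_min_step)
    lo, hi = step_window
    window = [h for h in grid if lo <= h <= hi and h in ctrl_means]
    stepped = pd.Series(False, index=sub.index)
    for h0, h1 in zip(window, window[1:]):
        stepped |= (ctrl_means[h1] - ctrl_means[h0]).abs() >= step_tol
    return list(sub.index[ok & stepped])


def early_response(
    summary: DESetSummary,
    probe_gene_map: pd.DataFrame | dict | None = None,
    harvest: float = 2.0,
) -> list[str]:
    """Significant probes at the earliest harvest, optionally mapped to genes."""
    probes = summary.significant.get(harvest, [])
    if probe_gene_map is None:
        return list(probes)
    from .enrichment import map_probes_to_genes

    genes, n_dropped = map_probes_to_genes(probes, probe_gene_map)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} early-response probes dropped (multi/zero gene mapping)",
            stacklevel=2,
        )
    return genes
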