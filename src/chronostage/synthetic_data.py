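"""Synthetic dichlorvos-style exposure time course with known ground truth.

The generator emulates the design of an organophosphate exposure study in
synchronized *C. elegans* cultures: worms are exposed at the L3/L4 molt to a
high or low toxicant concentration (or none), either continuously or with the
toxicant washed out of the medium at 2 h or 8 h (sham washes for unexposed
cultures), and harvested at 0, 2, 8, 14, 20 and 26 h in four biological
replicates.  The full grid (minus pre-washout cells) yields 148 samples.

Probes fall into five classes:

``developmental``
    log2 x = c + s * a(t), where a(t) is the culture's true developmental
    age.  Exposure delays development: a(t) = t - d(t) with
    d(t) = delay_max * min(t, t_washout, accrual_window) / accrual_window,
    i.e. the delay accrues linearly during exposure over the first
    ``delay_accrual_window`` hours and then plateaus.  A configurable
    minority of developmental probes saturate (expression plateaus after a
    probe-specific age), and an optional minority is *delay-immune*, tracking
    harvest time rather than delayed age.
``toxicant``
    c plus an exposure effect m * ramp(t): the effect switches on at a
    probe-specific onset, rises linearly over ``effect_rise_h`` hours, and
    after washout decays exponentially with half-life
    ``washout_decay_halflife``.  A small fraction is *washout-triggered*:
    silent during exposure, induced only after the toxicant is removed
    (recovery-specific response).
``both``
    developmental trajectory plus a toxicant effect.
``null``
    constant baseline.
``absent``
    background level, Present call False in every sample.

Gaussian noise of SD ``noise_sd`` (log2 units) is added everywhere
(homoscedastic, consistent with RMA-normalized data).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .datatypes import META_COLUMNS, WASHOUT_TIME

PROBE_CLASSES = ("developmental", "toxicant", "both", "null", "absent")

_DEFAULT_FRACTIONS = {
    "developmental": 0.30,
    "toxicant": 0.15,
    "both": 0.05,
    "null": 0.45,
    "absent": 0.05,
}


@dataclass
class SimConfig:
    """Study-design and noise parameters of the simulator.

    Defaults reproduce the study conditions: 4 biological replicates,
    concentrations {0, 0.6, 15 uM}, continuous / 2 h-washout / 8 h-washout
    regimes with sham washes, harvests {0, 2, 8, 14, 20, 26 h}, a 6 h
    developmental delay accruing over the first 8 h of exposure, toxicant
    effects of ~1.5 log2 units that revert after washout with a 2 h
    half-life, and homoscedastic Gaussian log2 noise of SD 0.15.
    """

    n_probes: int = 2000
    class_fractions: Mapping[str, float] = field(
        default_factory=lambda: dict(_DEFAULT_FRACTIONS)
    )
    harvests: tuple[float, ...] = (0.0, 2.0, 8.0, 14.0, 20.0, 26.0)
    replicates: int = 4
    concentrations: tuple[float, ...] = (0.0, 0.6, 15.0)
    regimes: tuple[str, ...] = ("continuous", "washout2", "washout8")
    delay_max: float = 6.0
    delay_accrual_window: float = 8.0
    effect_scale: float = 1.5
    washout_decay_halflife: float = 2.0
    noise_sd: float = 0.15
    seed: int = 0
    # secondary knobs ------------------------------------------------------
    low_dose_potency: float = 0.0     # fraction of the high-dose effect at the low dose
    sham_delay: float = 0.0           # extra delay in sham washes ...
    sham_delay_from_h: float = 26.0   # ... applied at harvests >= this hour
    saturating_fraction: float = 0.10  # of developmental probes
    delay_immune_fraction: float = 0.0  # of developmental probes
    early_onset_fraction: float = 0.25  # of toxicant-responsive probes
    washout_triggered_fraction: float = 0.05  # of toxicant-responsive probes
    effect_rise_h: float = 2.0
    slope_range: tuple[float, float] = (0.06, 0.25)
    intercept_range: tuple[float, float] = (4.0, 10.0)
    background_level: float = 3.0

    def __post_init__(self) -> None:
        if self.n_probes <= 0:
            raise ValueError("n_probes must be positive")
        if len(self.harvests) == 0:
            raise ValueError("harvest list must not be empty")
        if self.replicates < 2:
            raise ValueError("need >= 2 replicates (within-condition variance undefined)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.delay_max < 0:
            raise ValueError("delay_max must be >= 0")
        if self.delay_accrual_window <= 0:
            raise ValueError("delay_accrual_window must be positive")
        unknown = set(self.class_fractions) - set(PROBE_CLASSES)
        if unknown:
            raise ValueError(f"unknown probe classes {sorted(unknown)}")
        total = float(sum(self.class_fractions.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_fractions must sum to 1, got {total}")
        for r in self.regimes:
            if r not in WASHOUT_TIME:
                raise ValueError(f"unknown regime {r!r}")

    @property
    def high_concentration(self) -> float:
        return max(self.concentrations)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a simulated data set.

    Attributes
    ----------
    probes
        Per-probe parameters, indexed by probe_id: ``class``, ``intercept``,
        ``slope``, ``t_sat`` (inf = linear), ``effect`` (signed log2
        magnitude), ``onset_h``, ``washout_triggered``, ``delay_immune``.
    conditions
        Per-condition truth, one row per (concentration, regime, harvest):
        ``delay_h`` and ``true_age_h``.
    sample_age
        True developmental age of every sample (hours).
    """

    probes: pd.DataFrame
    conditions: pd.DataFrame
    sample_age: pd.Series
    config: SimConfig

    def true_delay(self, concentration: float, regime: str, harvest_h: float) -> float:
        """Developmental delay t - a(t) for one condition (hours)."""
        m = (
            (self.conditions["concentration_uM"] == concentration)
            & (self.conditions["regime"] == regime)
            & (self.conditions["harvest_h"] == harvest_h)
        )
        if not m.any():
            raise KeyError(
                f"no condition ({concentration} uM, {regime}, {harvest_h} h) in truth"
            )
        return float(self.conditions.loc[m, "delay_h"].iloc[0])


def true_delay(truth: SyntheticTruth, condition: tuple[float, str], harvest_h: float) -> float:
    """Module-level accessor: condition is a (concentration, regime) pair."""
    conc, regime = condition
    return truth.true_delay(conc, regime, harvest_h)


# ---------------------------------------------------------------------------
# design grid


def design_cells(config: SimConfig) -> list[tuple[float, str, float]]:
    """(concentration, regime, harvest) cells of the experimental design.

    Washout regimes are only sampled from the first post-washout harvest
    onward (the shared early points belong to the continuous arm), and
    unexposed cultures in washout arms are labelled sham.  With the default
    configuration this yields 37 cells -> 148 samples at 4 replicates.
    """
    cells: list[tuple[float, str, float]] = [(0.0, "continuous", min(config.harvests))]
    t0 = min(config.harvests)
    for regime in config.regimes:
        wash = WASHOUT_TIME[regime]
        for conc in config.concentrations:
            label = regime
            if wash is not None and conc == 0.0:
                label = f"sham{int(wash)}"
            for h in config.harvests:
                if h <= t0:
                    continue  # time zero is the shared baseline
                if wash is not None and h <= wash:
                    continue  # covered by the continuous arm before washout
                cells.append((conc, label, float(h)))
    return cells


def _class_counts(fractions: Mapping[str, float], n: int) -> dict[str, int]:
    """Exact integer class counts by largest remainder."""
    names = list(fractions)
    raw = np.array([fractions[k] * n for k in names], dtype=float)
    base = np.floor(raw).astype(int)
    short = n - int(base.sum())
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return dict(zip(names, base.tolist()))


def _delay(config: SimConfig, conc: float, regime: str, t: float) -> float:
    """Developmental delay d(t) for one condition."""
    wash = WASHOUT_TIME[regime]
    if conc == 0.0:
        if regime.startswith("sham") and t >= config.sham_delay_from_h:
            return config.sham_delay
        return 0.0
    potency = 1.0 if conc == config.high_concentration else config.low_dose_potency
    t_end = t if wash is None else min(t, wash)
    accrued = min(t_end, config.delay_accrual_window)
    return config.delay_max * potency * accrued / config.delay_accrual_window


def _exposure_effect(
    config: SimConfig,
    effect: np.ndarray,
    onset: np.ndarray,
    washout_triggered: np.ndarray,
    conc: float,
    regime: str,
    t: float,
) -> np.ndarray:
    """Per-probe toxicant effect (log2 units) for one condition."""
    if conc == 0.0:
        return np.zeros_like(effect)
    potency = 1.0 if conc == config.high_concentration else config.low_dose_potency
    if potency == 0.0:
        return np.zeros_like(effect)
    wash = WASHOUT_TIME[regime]
    rise = max(config.effect_rise_h, 1e-9)
    t_end = t if wash is None else min(t, wash)
    ramp = np.clip((t_end - onset) / rise, 0.0, 1.0)
    e = effect * ramp
    if wash is not None and t > wash:
        e = e * 2.0 ** (-(t - wash) / config.washout_decay_halflife)
    # washout-triggered probes: silent during exposure, induced post-washout
    if wash is not None and t > wash:
        post = np.clip((t - wash) / rise, 0.0, 1.0)
        e = np.where(washout_triggered, effect * post, e)
    else:
        e = np.where(washout_triggered, 0.0, e)
    return potency * e


def generate(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Simulate one complete experiment.

    Returns
    -------
    (matrix, metadata, calls, truth)
        log2 expression (probes x samples), sample metadata, boolean
        presence calls on the same axes, and the ground truth.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_probes

    counts = _class_counts(config.class_fractions, n)
    classes = np.repeat(
        [c for c in PROBE_CLASSES if c in counts],
        [counts[c] for c in PROBE_CLASSES if c in counts],
    )
    classes = classes[rng.permutation(n)]
    probe_ids = [f"probe_{i:05d}" for i in range(n)]

    is_dev = np.isin(classes, ["developmental", "both"])
    is_tox = np.isin(classes, ["toxicant", "both"])
    is_absent = classes == "absent"

    lo_c, hi_c = config.intercept_range
    intercept = rng.uniform(lo_c, hi_c, n)
    lo_s, hi_s = config.slope_range
    slope = rng.uniform(lo_s, hi_s, n) * rng.choice([-1.0, 1.0], n)
    slope[~is_dev] = 0.0

    t_sat = np.full(n, np.inf)
    saturating = is_dev & (rng.random(n) < config.saturating_fraction)
    t_sat[saturating] = rng.uniform(8.0, 20.0, int(saturating.sum()))
    delay_immune = is_dev & (rng.random(n) < config.delay_immune_fraction)

    effect = rng.uniform(0.8, 1.2, n) * config.effect_scale
    effect *= rng.choice([-1.0, 1.0], n)
    effect[~is_tox] = 0.0
    onset = rng.choice([2.0, 8.0, 14.0], n, p=[0.4, 0.4, 0.2])
    onset[rng.random(n) < config.early_onset_fraction] = 0.0
    onset[~is_tox] = 0.0
    washout_triggered = is_tox & (rng.random(n) < config.washout_triggered_fraction)

    cells = design_cells(config)
    sample_ids: list[str] = []
    meta_rows: list[tuple] = []
    ages: list[float] = []
    cond_rows: list[tuple] = []
    blocks: list[np.ndarray] = []

    for conc, regime, t in cells:
        d = _delay(config, conc, regime, t)
        age = t - d
        cond_rows.append((conc, regime, t, d, age))
        dev_val = intercept + slope * np.minimum(np.where(delay_immune, t, age), t_sat)
        tox_val = _exposure_effect(config, effect, onset, washout_triggered, conc, regime, t)
        signal = np.where(is_absent, config.background_level, dev_val + tox_val)
        for rep in range(1, config.replicates + 1):
            sid = f"{regime}_c{conc:g}_t{int(t):02d}_r{rep}"
            sample_ids.append(sid)
            meta_rows.append((sid, conc, regime, t, rep))
            ages.append(age)
            blocks.append(signal)

    values = np.column_stack(blocks)
    if config.noise_sd > 0:
        values = values + rng.normal(0.0, config.noise_sd, values.shape)

    matrix = pd.DataFrame(values, index=probe_ids, columns=sample_ids)
    metadata = pd.DataFrame(meta_rows, columns=META_COLUMNS)
    calls = pd.DataFrame(
        np.broadcast_to(~is_absent[:, None], matrix.shape).copy(),
        index=probe_ids,
        columns=sample_ids,
    )

    probes = pd.DataFrame(
        {
            "class": classes,
            "intercept": intercept,
            "slope": slope,
            "t_sat": t_sat,
            "effect": effect,
            "onset_h": onset,
            "washout_triggered": washout_triggered,
            "delay_immune": delay_immune,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )
    conditions = pd.DataFrame(
        cond_rows,
        columns=["concentration_uM", "regime", "harvest_h", "delay_h", "true_age_h"],
    )
    truth = SyntheticTruth(
        probes=probes,
        conditions=conditions,
        sample_age=pd.Series(ages, index=sample_ids, name="true_age_h"),
        config=config,
    )
    return matrix, metadata, calls, truth


# ---------------------------------------------------------------------------
# serialization


def write_outputs(
    outdir: str | Path,
    matrix: pd.DataFrame,
    metadata: pd.DataFrame,
    calls: pd.DataFrame,
    truth: SyntheticTruth | None = None,
) -> None:
    """Write matrix/calls as TSV, metadata as CSV and truth as JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    matrix.to_csv(outdir / "expression.tsv", sep="\t", index_label="probe_id")
    calls.astype(int).to_csv(outdir / "presence.tsv", sep="\t", index_label="probe_id")
    metadata.to_csv(outdir / "metadata.csv", index=False)
    if truth is not None:
        payload = {
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(truth.config).items()
            },
            "probes": truth.probes.replace({np.inf: None}).reset_index().to_dict("records"),
            "conditions": truth.conditions.to_dict("records"),
            "sample_age": truth.sample_age.to_dict(),
        }
        (outdir / "truth.json").write_text(json.dumps(payload, indent=1))
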