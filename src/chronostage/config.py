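"""Analysis thresholds used throughout the pipeline.

All fold-change cutoffs are expressed on the linear scale (e.g. 1.8 means an
1.8-fold change, i.e. |log2 difference| >= log2(1.8)); the corresponding
log2 values are derived where needed.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass


@dataclass
class AnalysisConfig:
    """Cutoffs for staging, differential expression and enrichment.

    Parameters
    ----------
    fdr_dev, fc_dev
        Developmental screen: BH FDR and minimum fold change from time zero
        required for a probe to count as developmentally regulated.
    fc_stage, r2_stage
        Per-harvest staging panel: minimum fold change over the two preceding
        harvest intervals and minimum linearity (r^2 of expression on time).
    slope_min
        Minimum |slope| (log2 units / h) for an age model; guards the inverse
        prediction against near-flat calibration lines.
    p_de, fc_de, range_guard
        Strict differential-expression cascade: p cutoff on the exposure term
        of the PA-adjusted ANCOVA, fold-change cutoff on the adjusted
        contrast, and the factor by which exposed expression must sit outside
        the control min-max envelope (linear scale).
    p_lenient, fc_lenient
        Lenient screen used for washout-uniqueness and panel purging.
    fdr_enrich
        BH FDR cutoff for gene-set enrichment.
    r2_replicate
        Minimum pairwise R^2 for replicate quality control.
    delay_resistant_max_fc, delay_resistant_min_step
        Delay-resistant gene rules: maximum exposed/control fold difference at
        every harvest, and the minimum consecutive-harvest step in controls.
    """

    fdr_dev: float = 0.001
    fc_dev: float = 1.8
    fc_stage: float = 2.0
    r2_stage: float = 0.95
    slope_min: float = math.log2(1.2) / 26.0
    p_de: float = 1e-4
    fc_de: float = 1.8
    range_guard: float = 1.2
    p_lenient: float = 0.01
    fc_lenient: float = 1.5
    fdr_enrich: float = 0.01
    r2_replicate: float = 0.93
    delay_resistant_max_fc: float = 1.2
    delay_resistant_min_step: float = 1.8

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not v > 0:
                raise ValueError(f"{f.name} must be positive, got {v}")
        for name in (
            "fc_dev",
            "fc_stage",
            "fc_de",
            "range_guard",
            "fc_lenient",
            "delay_resistant_max_fc",
            "delay_resistant_min_step",
        ):
            if not getattr(self, name) > 1:
                raise ValueError(f"{name} is a fold change and must exceed 1")

    @property
    def log2_fc_dev(self) -> float:
        return math.log2(self.fc_dev)

    @property
    def log2_fc_stage(self) -> float:
        return math.log2(self.fc_stage)

    @property
    def log2_fc_de(self) -> float:
        return math.log2(self.fc_de)

    @property
    def log2_fc_lenient(self) -> float:
        return math.log2(self.fc_lenient)
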