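"""Internal z-score standardisation and SD <-> natural-unit conversion.

Cohort analyses of maternal and offspring BMI work on internally
standardised z-scores: maternal BMI within maternal-age strata (1-year
categories), offspring BMI/FMI within sex x age-in-months strata.
Effect estimates on the SD scale are converted back to kg/m^2 by
multiplying by a representative outcome SD (3.7 kg/m^2 for maternal
pre-pregnancy BMI, 2.0 kg/m^2 for offspring BMI).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .estimators import EffectEstimate


@dataclass
class StandardisationSpec:
    """Per-stratum mean and sample SD used for internal z-scores."""

    table: pd.DataFrame  # columns: stratum, n, mean, sd

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "StandardisationSpec":
        return cls(pd.read_csv(path, sep="\t"))


@dataclass(frozen=True)
class ConversionSpec:
    """Representative SDs (kg/m^2) for converting SD-scale estimates."""

    exposure_sd: float = 3.7
    outcome_sd: float = 2.0

    def __post_init__(self) -> None:
        if self.exposure_sd <= 0 or self.outcome_sd <= 0:
            raise ValueError("conversion SDs must be positive")


def internal_zscore(values, strata) -> tuple[np.ndarray, StandardisationSpec]:
    """Standardise ``values`` to mean 0, sample SD 1 within each stratum.

    Uses the sample SD (divisor n-1).  Strata with fewer than two
    records, or with identical values, cannot be standardised and raise
    an error naming the stratum.
    """
    v = np.asarray(values, dtype=float)
    s = pd.Series(strata)
    if len(v) != len(s):
        raise ValueError("values and strata labels must have equal length")
    out = np.full(len(v), np.nan)
    rows = []
    for key, idx in s.groupby(s).groups.items():
        idx = np.asarray(idx)
        x = v[idx]
        if len(x) < 2:
            raise ValueError(f"stratum {key!r} has a single record; cannot standardise")
        mu = float(np.mean(x))
        sd = float(np.std(x, ddof=1))
        if sd == 0.0:
            raise ValueError(f"stratum {key!r} has constant values; cannot standardise")
        out[idx] = (x - mu) / sd
        rows.append({"stratum": key, "n": len(x), "mean": mu, "sd": sd})
    spec = StandardisationSpec(pd.DataFrame(rows))
    return out, spec


def convert_sd_to_units(estimate: EffectEstimate, spec: ConversionSpec) -> EffectEstimate:
    """Convert an SD-scale estimate to kg/m^2 per SD of exposure.

    The point estimate, SE and CI bounds are each multiplied by the
    outcome SD; the per-SD-of-exposure framing is unchanged.  Linear,
    hence additive over estimates.
    """
    k = spec.outcome_sd
    return EffectEstimate(
        beta=estimate.beta * k,
        se=estimate.se * k if estimate.se is not None else None,
        ci_low=estimate.ci_low * k,
        ci_high=estimate.ci_high * k,
        n=estimate.n,
        df=estimate.df,
        label=(estimate.label + "_kgm2") if estimate.label else "kgm2",
    )
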