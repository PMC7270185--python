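"""Quantification math for the wet-lab validation experiments.

RIP-qPCR enrichment expressed as percent of (dilution-corrected) input via
the 2^(-ddCt) method, with the reverse-transcriptase-free control as a
DNA-background normalizer and Euclidean SEM propagation; GFP reporter
intensities in knock-out strains normalized to wild type with an ANOVA
significance contract across constructs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


@dataclass(frozen=True)
class QpcrMeasurement:
    target: str
    ct_ip: float
    ct_input: float
    input_fraction: float
    rt_condition: str = "plusRT"  # "plusRT" | "minusRT"

    def __post_init__(self) -> None:
        if not (math.isfinite(self.ct_ip) and self.ct_ip > 0):
            raise ValueError("ct_ip must be finite and positive")
        if not (math.isfinite(self.ct_input) and self.ct_input > 0):
            raise ValueError("ct_input must be finite and positive")
        if not 0 < self.input_fraction <= 1:
            raise ValueError("input_fraction must be in (0, 1]")


def percent_input(ct_ip: float, ct_input: float, input_fraction: float) -> float:
    """Percent of input recovered in the immunoprecipitate.

    The input aliquot is a fraction of the IP material, so its Ct is adjusted
    down by log2(1/input_fraction) cycles before the delta:
    %input = 100 * 2^(ct_input - log2(1/f) - ct_ip).
    """
    if input_fraction <= 0:
        raise ValueError("input_fraction must be positive")
    adjusted_input = ct_input - math.log2(1.0 / input_fraction)
    return 100.0 * 2.0 ** (adjusted_input - ct_ip)


def rt_normalize(plus_rt_percent: float, minus_rt_percent: float) -> float:
    """Normalize the +RT signal to the -RT (no reverse transcriptase) control.

    Ratios far above 1 indicate RNA-dependent (not DNA-background) signal.
    A zero -RT value is rejected; callers wanting a detection-limit floor
    must apply it explicitly before normalizing.
    """
    if minus_rt_percent <= 0:
        raise ValueError(
            "minus-RT percent input must be positive; configure a "
            "detection-limit floor for zero-background samples"
        )
    return plus_rt_percent / minus_rt_percent


def propagate_sem(sem1: float, sem2: float) -> float:
    """Combine two standard errors in quadrature: sqrt(sem1^2 + sem2^2)."""
    if sem1 < 0 or sem2 < 0:
        raise ValueError("standard errors must be non-negative")
    return math.hypot(sem1, sem2)


def gfp_normalize(
    ko_replicates: Sequence[float], wt_replicates: Sequence[float]
) -> dict[str, float]:
    """KO/WT reporter normalization for one construct.

    Each knock-out replicate is divided by the wild-type replicate mean;
    returns the mean and standard deviation (ddof=1) of those ratios.
    """
    ko = np.asarray(ko_replicates, dtype=float)
    wt = np.asarray(wt_replicates, dtype=float)
    if len(ko) < 2 or len(wt) < 2:
        raise ValueError("need at least 2 replicates per condition")
    wt_mean = wt.mean()
    if wt_mean == 0:
        raise ValueError("wild-type mean intensity is zero")
    ratios = ko / wt_mean
    return {
        "ratio_mean": float(ratios.mean()),
        "ratio_sd": float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        "n": int(len(ratios)),
    }


def gfp_screen_anova(
    construct_ratios: Mapping[str, Sequence[float]]
) -> dict[str, float]:
    """One-way ANOVA across constructs' per-replicate KO/WT ratios.

    The two-sided F-test asks whether any construct's normalized reporter
    level differs; per-construct follow-up against a flat ratio of 1 is a
    one-sample t-test (returned per construct as ``t_p_<name>``).
    """
    groups = [np.asarray(v, dtype=float) for v in construct_ratios.values()]
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least 2 constructs")
    f_stat, p = stats.f_oneway(*groups)
    out = {"f_statistic": float(f_stat), "anova_p": float(p)}
    for name, vals in construct_ratios.items():
        arr = np.asarray(vals, dtype=float)
        if len(arr) >= 2 and np.ptp(arr) > 0:
            _, tp = stats.ttest_1samp(arr, 1.0)
        else:
            tp = float("nan")
        out[f"t_p_{name}"] = float(tp)
    return out
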