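"""Named simulation scenarios used as the package's verification bench.

Each preset fixes the study conditions for one class of check; tests
and the reproduction script build on these rather than re-specifying
parameters ad hoc.  Problem sizes are chosen to give each check clear
statistical resolution on a single CPU.
"""

from __future__ import annotations

import numpy as np

from .synthetic import SyntheticScenario, betas_for_lag06_percent

__all__ = [
    "moments_scenario",
    "recovery_scenario",
    "null_scenario",
    "confounded_scenario",
    "lrt_scenario",
    "STUDY_START",
]

#: First analysable day in every preset: the first exposure month is
#: excluded so all case and referent days carry complete lag histories.
STUDY_START = "2004-02-01"


def moments_scenario(seed: int = 0, years: int = 9) -> SyntheticScenario:
    """Default-parameter scenario whose exposure surfaces target the
    polluted-megacity marginal moments (PM2.5 mean 24.6, SD 10.8 ug/m3;
    temperature mean 16.6 C, SD ~2.6 C)."""
    return SyntheticScenario(seed=seed, date_range=("2004-01-01", f"{2003 + years}-12-31"))


def recovery_scenario(seed: int, lag06_percent: float = 2.0,
                      baseline_rate: float = 0.4) -> SyntheticScenario:
    """Parameter-recovery bench: ~30,000 deaths over 36 localities and
    six years, with a persistent, high-variance exposure process so the
    cumulative lag06 effect is estimated with per-run SE well under 1
    percentage point."""
    return SyntheticScenario(
        n_urban_localities=16,
        n_rural_localities=20,
        grid_shape=(12, 12),
        date_range=("2004-01-01", "2009-12-31"),
        true_lag_betas_pm=betas_for_lag06_percent(lag06_percent),
        baseline_rate=baseline_rate,
        ar1_coef_pm=0.85,
        noise_sd_pm=12.0,
        seed=seed,
    )


def null_scenario(seed: int) -> SyntheticScenario:
    """Zero-truth replicate for calibration checks (~1,500 deaths,
    17 months, 12 localities): small enough for hundreds of replicates,
    large enough that Wald intervals are in their asymptotic regime."""
    return SyntheticScenario(
        seed=seed, baseline_rate=0.25, date_range=("2004-01-01", "2005-06-30")
    )


def confounded_scenario(seed: int) -> SyntheticScenario:
    """Zero PM truth with a strong monotone-nonlinear temperature effect
    and heavily shared PM-temperature innovations: the bench for showing
    the spline temperature adjustment removes confounding bias."""
    return SyntheticScenario(
        seed=seed,
        baseline_rate=0.5,
        date_range=("2004-01-01", "2006-12-31"),
        temp_effect={"type": "quadratic", "center": 8.0, "coef": 0.004},
        cross_corr=0.7,
    )


def lrt_scenario(seed: int, nonlinear: bool = False) -> SyntheticScenario:
    """Linearity-test bench: low death clustering (few deaths per
    locality-day) so likelihood-ratio p-values are close to nominal;
    ``nonlinear=True`` switches on a strong quadratic lag-0 PM term."""
    return SyntheticScenario(
        seed=seed,
        n_urban_localities=8,
        n_rural_localities=8,
        grid_shape=(8, 8),
        date_range=("2004-01-01", "2006-12-31"),
        true_lag_betas_pm=betas_for_lag06_percent(2.0),
        baseline_rate=0.3 if nonlinear else 0.08,
        pm_quad_coef=0.002 if nonlinear else 0.0,
    )
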