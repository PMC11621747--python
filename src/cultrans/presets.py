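"""Named desk-scale scenario presets.

The full-scale defaults (30 groups x 100 agents, 1,000 recorded years,
100,000 ABC simulations) are expensive; these presets encode the same
scenarios at desk scale for quick runs, demonstrations and validation:

* ``sweep-mini`` — the conformity x migration sweep at 10 groups x 50
  agents, 300 recorded years.
* ``panel-mini`` — the longitudinal-panel scenario: full-size population,
  age-dependent migration, a 500-person 30-year panel, and a shortened
  sampler.
* ``abc-mini`` — the ABC scenario at 10 x 50 with 2,000 simulations,
  keeping 20. Group size halves the full scale, so the innovation rate is
  doubled (mu = 0.02) to preserve the drift-innovation balance N*mu that
  sets within-group diversity; without this the reduced model's equilibria
  would not be comparable to the full-scale landscape.
"""

from __future__ import annotations

from dataclasses import replace

from .abc import ABCConfig
from .abm import ABMParams, AgeSchedule
from .longitudinal import SamplerConfig

__all__ = [
    "mini_sweep_params",
    "mini_panel_scenario",
    "mini_abc_config",
]


def mini_sweep_params(**overrides) -> ABMParams:
    """Reduced-scale simulator settings for sweep and contrast runs."""
    params = ABMParams(n_groups=10, group_size=50, burn_in_years=200, record_years=300)
    return replace(params, **overrides) if overrides else params


def mini_panel_scenario() -> dict:
    """Panel scenario: ABM params, cohort size, years, and sampler settings."""
    return {
        "abm_params": ABMParams(migration=AgeSchedule(), theta=1.7),
        "n_individuals": 500,
        "n_years": 30,
        "sampler": SamplerConfig(n_iter=1600, warmup=600, chains=1),
    }


def mini_abc_config(n_sims: int = 2000, n_keep: int = 20) -> ABCConfig:
    """Reduced-scale ABC configuration (drift-matched innovation rate)."""
    return ABCConfig(
        n_sims=n_sims,
        n_keep=n_keep,
        abm_params=ABMParams(
            n_groups=10, group_size=50, mu=0.02, burn_in_years=100, record_years=300
        ),
    )
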