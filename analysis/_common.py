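"""Shared configuration for the numbered analysis drivers.

The benchmark: one training cohort and one independent test cohort
drawn from the same planted module structure,
with two of six modules carrying a proportional-hazards effect.
"""

from pathlib import Path

from netscore.simulate import SimulationConfig

_ROOT = Path(__file__).resolve().parent.parent
RESULTS = _ROOT / "results" / "analysis"  # small derived tables
SCRATCH = _ROOT / "scratch" / "cohorts"  # bulky regenerable cohort data
SEED = 2026

CONFIG = SimulationConfig(seed=SEED)  # defaults: 6 modules, betas (1,1,0,0,0,0)


def cohort_paths(name: str):
    return SCRATCH / f"{name}_expression.tsv", SCRATCH / f"{name}_survival.tsv"
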