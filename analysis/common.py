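"""Shared setup for the numbered analysis drivers.

Every driver analyses the same reference synthetic study (seed 1) so the
numbers across steps refer to one dataset.  Big intermediate files live
under scratch/, small result tables under results/.
"""

from pathlib import Path

from ascoedit.pipeline import evaluate_recovery, run_simulated_study
from ascoedit.simulate import SimulationConfig

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"
SEED = 1

_cache = {}


def get_study():
    """Reference study + pipeline result, simulated once per process."""
    if "study" not in _cache:
        config = SimulationConfig()
        study, result = run_simulated_study(config, seed=SEED)
        _cache["study"] = (study, result, evaluate_recovery(study, result))
    return _cache["study"]


def outdirs():
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    return RESULTS, SCRATCH
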