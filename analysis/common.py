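"""Shared settings for the numbered analysis scripts.

One global seed drives every stage; all artifacts land under results/.
The cohorts mirror the study design: a 20-patient test cohort (14
responders / 6 non-responders) screened on a 91-gene universe, and an
independent 20-patient validation cohort (13 / 7) measured by qPCR.
"""

from pathlib import Path

from respanel import SimulationConfig

SEED = 11
RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA = RESULTS / "data"

COHORT_SHARED = dict(n_genes=91, n_informative=10, effect_size=2.0,
                     block_size=2, block_correlation=0.3, disease="CD")

TEST_COHORT = SimulationConfig(n_responders=14, n_nonresponders=6,
                               cohort="test", seed=SEED, **COHORT_SHARED)
VALIDATION_COHORT = SimulationConfig(n_responders=13, n_nonresponders=7,
                                     cohort="validation", seed=SEED + 1,
                                     **COHORT_SHARED)

N_RESTARTS = 100
CV_THRESHOLD = 80.0
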