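"""Shared paths and the study-scale simulation settings for the drivers."""

from pathlib import Path

from epichannel import SimulationConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
DATA_CSV = RESULTS / "synthetic_vital_records.csv"

STUDY_YEAR = 2020

#: 40 cities per stratum over 2009-2020: ten baseline years, a spare year,
#: and the study year — large enough for stable group fractions, small
#: enough to run in seconds.
STUDY_CONFIG = SimulationConfig(
    cities_per_group=(40, 40, 40, 40, 40, 40),
    year_start=2009,
    year_end=2020,
    seed=2024,
)
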