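"""Published summary statistics of the two reference CPI tasks.

The balanced bioactivity benchmark (ChEMBL-derived) and the imbalanced
Tox21 toxicity task are the full-scale datasets this framework targets;
their printed size characteristics are kept here both as documentation of
the data regimes the synthetic generator emulates and as inputs to simple
coverage/imbalance arithmetic.
"""

from __future__ import annotations

BENCHMARK_N_COMPOUNDS = 204_085
BENCHMARK_N_TARGETS = 1_227
BENCHMARK_N_OBSERVATIONS = 314_767
BENCHMARK_POSITIVE_RATE = 0.547

TOX21_N_MEASUREMENTS = 79_585
TOX21_N_POSITIVES = 5_957
TOX21_N_COMPOUNDS = 8_014
TOX21_N_TARGETS = 12

SMILES_LENGTH_P75 = 63.0
PROTEIN_LENGTH_P75 = 712.2
SMILES_FIXED_LENGTH = 100
PROTEIN_FIXED_LENGTH = 700


def possible_pairs(n_compounds: int = BENCHMARK_N_COMPOUNDS,
                   n_targets: int = BENCHMARK_N_TARGETS) -> int:
    """Size of the full bioactivity matrix."""
    return n_compounds * n_targets

def coverage_percent(n_observations: int = BENCHMARK_N_OBSERVATIONS,
                     n_compounds: int = BENCHMARK_N_COMPOUNDS,
                     n_targets: int = BENCHMARK_N_TARGETS) -> float:
    """Observed fraction of the bioactivity matrix, in percent."""
    return 100.0 * n_observations / possible_pairs(n_compounds, n_targets)

def imbalance_percent(n_positives: int = TOX21_N_POSITIVES,
                      n_measurements: int = TOX21_N_MEASUREMENTS) -> float:
    """Positive rate of the toxicity task, in percent."""
    return 100.0 * n_positives / n_measurements

def task_size_ratio(n_source: int = BENCHMARK_N_OBSERVATIONS,
                    n_target: int = TOX21_N_MEASUREMENTS) -> float:
    """How many times larger the pretraining task is than the target task."""
    return n_source / n_target
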