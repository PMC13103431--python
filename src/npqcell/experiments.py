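"""Canonical reference experiments used by benchmarks and validation.

Bundles the standard study conditions — four 300-cell reference
populations, a model trained with the default configuration, held-out
populations, WT mixtures and repeat pairs — behind a single master
seed, split deterministically per stage with ``numpy`` seed sequences.
"""

from __future__ import annotations

import numpy as np

from .npqspace import NpqModel, TrainConfig, train_pipeline
from .protocol import Protocol, build_reference_protocol
from .simulate import (LabeledTraceSet, default_population_spec,
                       simulate_population, simulate_repeat_pair)

TRAINING_POPS = ("Pop0", "PopQE", "PopQT", "PopQI")


def spawn_seeds(master: int, n: int) -> list[int]:
    """Deterministically split a master seed into ``n`` stage seeds."""
    return [int(s.generate_state(1)[0] % (2 ** 31))
            for s in np.random.SeedSequence(master).spawn(n)]


def reference_training_sets(seed: int, n_per_pop: int = 300,
                            noise_sigma: float = 0.02,
                            protocol: Protocol | None = None,
                            ) -> dict[str, LabeledTraceSet]:
    """The four single-component reference populations."""
    p = protocol or build_reference_protocol()
    seeds = spawn_seeds(seed, len(TRAINING_POPS))
    return {
        lab: simulate_population(
            default_population_spec(lab, n_per_pop, seed=s,
                                    noise_sigma=noise_sigma), p)
        for lab, s in zip(TRAINING_POPS, seeds)
    }


def train_reference_model(seed: int, n_per_pop: int = 300,
                          noise_sigma: float = 0.02,
                          protocol: Protocol | None = None,
                          ) -> tuple[NpqModel, dict[str, LabeledTraceSet]]:
    """Train the default model on freshly simulated reference populations.

    Stage seeds (population draws, training pipeline) are spawned from
    the single master seed.
    """
    data_seed, train_seed = spawn_seeds(seed, 2)
    sets = reference_training_sets(data_seed, n_per_pop=n_per_pop,
                                   noise_sigma=noise_sigma,
                                   protocol=protocol)
    model = train_pipeline(sets, TrainConfig(seed=train_seed))
    return model, sets


def heldout_populations(seed: int, n_per_pop: int = 200,
                        noise_sigma: float = 0.02,
                        protocol: Protocol | None = None,
                        ) -> dict[str, LabeledTraceSet]:
    """Held-out single-component populations for classification checks."""
    p = protocol or build_reference_protocol()
    seeds = spawn_seeds(seed, len(TRAINING_POPS))
    return {
        lab: simulate_population(
            default_population_spec(lab, n_per_pop, seed=s,
                                    noise_sigma=noise_sigma), p)
        for lab, s in zip(TRAINING_POPS, seeds)
    }


def wt_mixture(seed: int, n_cells: int = 300, noise_sigma: float = 0.02,
               protocol: Protocol | None = None) -> LabeledTraceSet:
    """A WT-like population co-expressing qE and qT."""
    p = protocol or build_reference_protocol()
    return simulate_population(
        default_population_spec("WT", n_cells, seed=seed,
                                noise_sigma=noise_sigma), p)


def repeat_pair(seed: int, population: str = "PopQT", n_cells: int = 150,
                noise_sigma: float = 0.02,
                protocol: Protocol | None = None,
                ) -> tuple[LabeledTraceSet, LabeledTraceSet]:
    """Two consecutive noisy acquisitions of the same cells."""
    p = protocol or build_reference_protocol()
    return simulate_repeat_pair(
        default_population_spec(population, n_cells, seed=seed,
                                noise_sigma=noise_sigma), p)
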