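"""Synthetic predation-trial generators.

Three generators mirror the three assay designs so every analysis stage can
be exercised without the original raw data:

* **functional response** — consumption at initial densities 1, 2, 4, 6, 8,
  10 (10 replicates each by default). Two modes: ``binomial`` draws
  ``consumed ~ Binomial(N0, Ne/N0)`` around the Rogers expectation (exactly
  the likelihood the fitter assumes, so parameter recovery is an
  unbiasedness test), while ``mechanistic`` simulates the sequential
  search/capture/handle renewal process prey by prey.
* **choice** — a competing-risks version of the mechanistic process with
  stage-specific attack rates and handling times, 5 + 5 prey offered.
* **no-choice** — per-replicate ``consumed ~ Binomial(offered, p)`` with a
  per-treatment consumption probability; the packaged default probabilities
  reproduce the reference study's treatment means (mean = 5 p).

Seeding: one master seed spawns independent per-trial streams in replicate
order (``numpy.random.SeedSequence``), so adding replicates never perturbs
earlier ones and identical config + seed is bit-stable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .functional_response import rogers_expected
from .io import Experiment, PredationTrial, TrialDataset

DEFAULT_DENSITIES = (1, 2, 4, 6, 8, 10)

#: per-prey 24 h consumption probabilities reproducing the reference
#: no-choice treatment means (mean consumed = offered * p, offered = 5)
DEFAULT_NOCHOICE_P = {
    ("A_limonicus", "I"): 0.62,
    ("A_limonicus", "II"): 0.12,
    ("Am_herbicolus", "I"): 0.02,
    ("Am_herbicolus", "II"): 0.0,
    ("Am_lentiginosus", "I"): 0.08,
    ("Am_lentiginosus", "II"): 0.0,
    ("N_cucumeris", "I"): 0.02,
    ("N_cucumeris", "II"): 0.0,
}


def _spawn_streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.Generator(np.random.PCG64(s))
            for s in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class FrGeneratorConfig:
    """Functional-response generator settings.

    ``a`` is the attack rate (day^-1), ``h`` the handling time (days),
    ``T`` the trial duration (days). ``mode`` selects the observation
    model (see module docstring).
    """

    a: float
    h: float
    T: float = 1.0
    densities: tuple = DEFAULT_DENSITIES
    reps: int = 10
    mode: str = "binomial"
    seed: int = 0
    species: str = "A_limonicus"
    stage: str = "I"

    def __post_init__(self) -> None:
        if self.a < 0 or self.h < 0 or not self.T > 0:
            raise ValueError("require a >= 0, h >= 0, T > 0")
        if any(d < 1 for d in self.densities):
            raise ValueError("densities must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.mode not in ("binomial", "mechanistic"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass(frozen=True)
class ChoiceGeneratorConfig:
    """Choice-trial generator settings (stage-specific rates, 5 + 5 offered)."""

    a_I: float
    a_II: float
    h_I: float = 0.0
    h_II: float = 0.0
    T: float = 1.0
    n_I0: int = 5
    n_II0: int = 5
    reps: int = 10
    seed: int = 0
    species: str = "A_limonicus"

    def __post_init__(self) -> None:
        if min(self.a_I, self.a_II, self.h_I, self.h_II) < 0 or not self.T > 0:
            raise ValueError("rates/times must be >= 0 and T > 0")
        if self.n_I0 < 1 or self.n_II0 < 1:
            raise ValueError("offered counts must be >= 1")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")


@dataclass(frozen=True)
class NoChoiceGeneratorConfig:
    """No-choice generator: per-treatment consumption probability map.

    ``p_map`` maps ``(species, stage)`` to the probability that one offered
    prey is consumed within the trial.
    """

    p_map: dict = field(default_factory=lambda: dict(DEFAULT_NOCHOICE_P))
    offered: int = 5
    reps: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for key, p in self.p_map.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"p out of [0, 1] for treatment {key}: {p}")
        if self.offered < 1 or self.reps < 1:
            raise ValueError("offered and reps must be >= 1")


def simulate_fr_trial(a: float, h: float, T: float, N0: int,
                      rng: np.random.Generator) -> int:
    """One mechanistic non-replacement trial; returns prey consumed in [0, N0].

    Sequential foraging: with ``n`` prey remaining, search time is
    exponential with rate ``a * n``; a capture occurring before ``T``
    removes one prey and is followed by a fixed handling interval ``h``
    during which no searching occurs. A capture counts if its instant is
    before ``T`` even when handling extends past ``T`` (the prey is gone
    either way).
    """
    if a < 0 or h < 0 or not T > 0 or N0 < 0:
        raise ValueError("invalid parameters")
    if a == 0 or N0 == 0:
        return 0
    t = 0.0
    n = int(N0)
    consumed = 0
    while n > 0:
        t += rng.exponential(1.0 / (a * n))
        if t >= T:
            break
        consumed += 1
        n -= 1
        t += h
    return consumed


def simulate_fr_dataset(config: FrGeneratorConfig) -> TrialDataset:
    """Functional-response dataset per the config; deterministic given seed."""
    n_trials = len(config.densities) * config.reps
    streams = _spawn_streams(config.seed, n_trials)
    trials = []
    idx = 0
    for density in config.densities:
        if config.mode == "binomial":
            p = rogers_expected(density, config.a, config.h, config.T) / density
        for _ in range(config.reps):
            rng = streams[idx]
            if config.mode == "binomial":
                consumed = int(rng.binomial(density, p))
            else:
                consumed = simulate_fr_trial(
                    config.a, config.h, config.T, density, rng
                )
            trials.append(
                PredationTrial(
                    experiment=Experiment.FUNCTIONAL_RESPONSE,
                    predator_species=config.species,
                    replicate_id=idx + 1,
                    offered={config.stage: int(density)},
                    consumed={config.stage: consumed},
                    duration_T=config.T,
                )
            )
            idx += 1
    return TrialDataset(
        trials=trials,
        metadata={
            "generator": "functional_response",
            "mode": config.mode,
            "a": config.a,
            "h": config.h,
            "T": config.T,
            "densities": list(config.densities),
            "reps": config.reps,
            "seed": config.seed,
        },
    )


def simulate_choice_trial(config: ChoiceGeneratorConfig,
                          rng: np.random.Generator) -> tuple[int, int]:
    """One competing-risks choice trial; returns (consumed_I, consumed_II).

    With ``n_I, n_II`` prey remaining the time to the next capture is
    exponential with rate ``a_I n_I + a_II n_II``; the captured stage is I
    with probability ``a_I n_I / (a_I n_I + a_II n_II)``; the stage's
    handling time follows each capture; foraging stops at ``T``.
    """
    t = 0.0
    n_I, n_II = config.n_I0, config.n_II0
    c_I = c_II = 0
    while n_I + n_II > 0:
        rate = config.a_I * n_I + config.a_II * n_II
        if rate == 0:
            break
        t += rng.exponential(1.0 / rate)
        if t >= config.T:
            break
        if rng.random() < config.a_I * n_I / rate:
            c_I += 1
            n_I -= 1
            t += config.h_I
        else:
            c_II += 1
            n_II -= 1
            t += config.h_II
    return c_I, c_II


def simulate_choice_dataset(config: ChoiceGeneratorConfig) -> TrialDataset:
    """Choice dataset with 5 + 5 offered by default; deterministic given seed."""
    streams = _spawn_streams(config.seed, config.reps)
    trials = []
    for rep, rng in enumerate(streams, start=1):
        c_I, c_II = simulate_choice_trial(config, rng)
        trials.append(
            PredationTrial(
                experiment=Experiment.CHOICE,
                predator_species=config.species,
                replicate_id=rep,
                offered={"I": config.n_I0, "II": config.n_II0},
                consumed={"I": c_I, "II": c_II},
                duration_T=config.T,
            )
        )
    return TrialDataset(
        trials=trials,
        metadata={
            "generator": "choice",
            "a_I": config.a_I,
            "a_II": config.a_II,
            "h_I": config.h_I,
            "h_II": config.h_II,
            "T": config.T,
            "offered": [config.n_I0, config.n_II0],
            "reps": config.reps,
            "seed": config.seed,
        },
    )


def simulate_nochoice_dataset(config: NoChoiceGeneratorConfig) -> TrialDataset:
    """No-choice factorial dataset; consumed ~ Binomial(offered, p_treatment)."""
    treatments = list(config.p_map.items())
    streams = _spawn_streams(config.seed, len(treatments) * config.reps)
    trials = []
    idx = 0
    for (species, stage), p in treatments:
        for rep in range(1, config.reps + 1):
            consumed = int(streams[idx].binomial(config.offered, p))
            trials.append(
                PredationTrial(
                    experiment=Experiment.NO_CHOICE,
                    predator_species=species,
                    replicate_id=rep,
                    offered={stage: config.offered},
                    consumed={stage: consumed},
                    duration_T=1.0,
                )
            )
            idx += 1
    return TrialDataset(
        trials=trials,
        metadata={
            "generator": "no_choice",
            "offered": config.offered,
            "reps": config.reps,
            "seed": config.seed,
        },
    )
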