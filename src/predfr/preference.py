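"""Manly's preference index for depleting two-prey choice trials.

Prey are not replaced during the exposure, so raw consumption ratios are
biased by depletion; the log-survival form of Manly's alpha corrects for
this. For stages I and II with offered counts ``n_s0``, consumed counts
``r_s`` and survival proportions ``p_s = (n_s0 - r_s) / n_s0``:

    alpha_I = ln(p_I) / (ln(p_I) + ln(p_II)),    alpha_II = 1 - alpha_I

alpha = 0.5 indicates no preference; 1 indicates complete preference for
the focal stage. Conventions for boundary outcomes: no predation at all is
undefined (the index conditions on at least one capture); exactly one stage
fully consumed takes the limiting value alpha = 1 for that stage; both
stages fully consumed is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io import Experiment, PredationTrial, TrialDataset

MANLY_VARIANT = "log-survival (depletion-corrected)"


@dataclass(frozen=True)
class ChoiceOutcome:
    """Offered/consumed counts for one two-stage choice replicate."""

    n_I0: int
    n_II0: int
    r_I: int
    r_II: int

    def __post_init__(self) -> None:
        if self.n_I0 < 1 or self.n_II0 < 1:
            raise ValueError("offered counts must be >= 1")
        if not (0 <= self.r_I <= self.n_I0):
            raise ValueError(f"require 0 <= r_I <= n_I0, got r_I={self.r_I}")
        if not (0 <= self.r_II <= self.n_II0):
            raise ValueError(f"require 0 <= r_II <= n_II0, got r_II={self.r_II}")

    @classmethod
    def from_trial(cls, trial: PredationTrial) -> "ChoiceOutcome":
        if trial.experiment is not Experiment.CHOICE:
            raise ValueError("not a choice trial")
        return cls(
            n_I0=trial.offered["I"],
            n_II0=trial.offered["II"],
            r_I=trial.consumed["I"],
            r_II=trial.consumed["II"],
        )

    def swapped(self) -> "ChoiceOutcome":
        """The same replicate with the stage labels exchanged."""
        return ChoiceOutcome(self.n_II0, self.n_I0, self.r_II, self.r_I)


@dataclass
class PreferenceResult:
    """Per-replicate Manly's alpha values and their summary.

    ``alphas`` holds one ``(alpha_I, alpha_II)`` pair per defined replicate.
    ``sem_alpha_I`` is the SEM over defined replicates; with a single
    defined replicate it is reported as 0.0 and ``single_replicate`` flags
    the degenerate sample size.
    """

    alphas: list[tuple[float, float]]
    mean_alpha_I: float
    sem_alpha_I: float
    n_defined: int
    n_undefined: int
    single_replicate: bool
    variant: str = MANLY_VARIANT

    @property
    def mean_alpha_II(self) -> float:
        return 1.0 - self.mean_alpha_I

    def summary(self) -> str:
        return (
            f"Manly's alpha ({self.variant}): "
            f"alpha_I = {self.mean_alpha_I:.4f} +/- {self.sem_alpha_I:.4f} SEM, "
            f"alpha_II = {self.mean_alpha_II:.4f} "
            f"({self.n_defined} defined, {self.n_undefined} undefined replicates)"
        )


def manly_alpha(outcome: ChoiceOutcome) -> tuple[float, float] | None:
    """Manly's alpha for one replicate, or ``None`` when undefined.

    Returns ``(alpha_I, alpha_II)`` with ``alpha_I + alpha_II = 1``.
    Undefined outcomes — no predation at all, or both stages completely
    consumed — are signalled as ``None``, never as numbers.
    """
    if outcome.r_I == 0 and outcome.r_II == 0:
        return None
    full_I = outcome.r_I == outcome.n_I0
    full_II = outcome.r_II == outcome.n_II0
    if full_I and full_II:
        return None
    if full_I:
        return (1.0, 0.0)
    if full_II:
        return (0.0, 1.0)
    p_I = (outcome.n_I0 - outcome.r_I) / outcome.n_I0
    p_II = (outcome.n_II0 - outcome.r_II) / outcome.n_II0
    log_I, log_II = math.log(p_I), math.log(p_II)
    alpha_I = log_I / (log_I + log_II)
    return (alpha_I, 1.0 - alpha_I)


def summarize_preference(outcomes) -> PreferenceResult:
    """Per-replicate alphas first, then mean and SEM over defined replicates.

    ``outcomes`` may be ChoiceOutcome records, choice PredationTrials, or a
    TrialDataset (its choice trials are used). Raises if every replicate is
    undefined.
    """
    if isinstance(outcomes, TrialDataset):
        outcomes = [t for t in outcomes if t.experiment is Experiment.CHOICE]
    records = [
        o if isinstance(o, ChoiceOutcome) else ChoiceOutcome.from_trial(o)
        for o in outcomes
    ]
    alphas = []
    n_undefined = 0
    for rec in records:
        pair = manly_alpha(rec)
        if pair is None:
            n_undefined += 1
        else:
            alphas.append(pair)
    if not alphas:
        raise ValueError("all replicates are undefined (no usable predation events)")
    values = [a for a, _ in alphas]
    n = len(values)
    mean = sum(values) / n
    if n > 1:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        sem = math.sqrt(var / n)
    else:
        sem = 0.0
    return PreferenceResult(
        alphas=alphas,
        mean_alpha_I=mean,
        sem_alpha_I=sem,
        n_defined=n,
        n_undefined=n_undefined,
        single_replicate=(n == 1),
    )
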