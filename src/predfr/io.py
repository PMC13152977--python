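"""Trial data model and CSV interchange.

One row per replicate, wide stage columns. The three experiment types share
a single schema: no-choice and functional-response trials use exactly one
prey-stage column pair, choice trials use both.

CSV schema (header required, comma-separated, UTF-8)::

    experiment,predator_species,replicate_id,duration_days,
    offered_I,consumed_I,offered_II,consumed_II

Stage columns not used by a trial are left empty.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Iterator, Mapping

import pandas as pd

STAGES = ("I", "II")

CSV_COLUMNS = [
    "experiment",
    "predator_species",
    "replicate_id",
    "duration_days",
    "offered_I",
    "consumed_I",
    "offered_II",
    "consumed_II",
]


class Experiment(str, Enum):
    """The three assay designs."""

    NO_CHOICE = "no_choice"
    CHOICE = "choice"
    FUNCTIONAL_RESPONSE = "functional_response"


class SchemaError(ValueError):
    """The CSV file does not conform to the trial schema."""


class ValidationError(ValueError):
    """A trial violates a data-model invariant."""


@dataclass(frozen=True)
class PredationTrial:
    """A single replicate: offered/consumed prey counts for one predator.

    Parameters
    ----------
    experiment
        Which assay design the replicate belongs to.
    predator_species
        Identifier for the predator (e.g. ``"A_limonicus"``).
    replicate_id
        Positive integer, unique within (experiment, species, stage set).
    offered, consumed
        Maps from prey-stage label (``"I"``, ``"II"``) to counts. Single-prey
        experiments carry exactly one stage key, choice trials exactly two.
    duration_T
        Trial duration in days (> 0); all assays in the reference design ran
        24 h, hence the default of 1.0.
    """

    experiment: Experiment
    predator_species: str
    replicate_id: int
    offered: Mapping[str, int]
    consumed: Mapping[str, int]
    duration_T: float = 1.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "experiment", Experiment(self.experiment))
        object.__setattr__(self, "offered", dict(self.offered))
        object.__setattr__(self, "consumed", dict(self.consumed))
        self._validate()

    def _validate(self) -> None:
        if not self.predator_species:
            raise ValidationError("predator_species must be a non-empty string")
        if int(self.replicate_id) != self.replicate_id or self.replicate_id < 1:
            raise ValidationError(
                f"replicate_id must be a positive integer, got {self.replicate_id!r}"
            )
        if not self.duration_T > 0:
            raise ValidationError(f"duration_T must be > 0, got {self.duration_T}")
        for label in self.offered:
            if label not in STAGES:
                raise ValidationError(
                    f"unknown prey stage {label!r}; allowed stages are {STAGES}"
                )
        if set(self.offered) != set(self.consumed):
            raise ValidationError(
                "offered and consumed must cover the same prey stages"
            )
        n_stages = len(self.offered)
        if self.experiment is Experiment.CHOICE:
            if n_stages != 2:
                raise ValidationError("choice trials require exactly two prey stages")
        elif n_stages != 1:
            raise ValidationError(
                f"{self.experiment.value} trials require exactly one prey stage"
            )
        for label in self.offered:
            off, con = self.offered[label], self.consumed[label]
            if off < 0 or con < 0:
                raise ValidationError(f"negative count for stage {label}")
            if con > off:
                raise ValidationError(
                    f"consumed_{label} = {con} exceeds offered_{label} = {off}"
                )

    @property
    def stages(self) -> tuple[str, ...]:
        return tuple(sorted(self.offered, key=STAGES.index))

    def key(self) -> tuple:
        """Uniqueness key within a dataset."""
        return (
            self.experiment.value,
            self.predator_species,
            self.stages,
            self.replicate_id,
        )


@dataclass
class TrialDataset:
    """An ordered collection of validated trials plus free-form metadata."""

    trials: list[PredationTrial] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for t in self.trials:
            k = t.key()
            if k in seen:
                raise ValidationError(f"duplicate trial key {k}")
            seen.add(k)

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self) -> Iterator[PredationTrial]:
        return iter(self.trials)

    def filter(self, experiment: Experiment | str) -> "TrialDataset":
        experiment = Experiment(experiment)
        return TrialDataset(
            trials=[t for t in self.trials if t.experiment is experiment],
            metadata=dict(self.metadata),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Wide per-replicate table in the CSV column order."""
        rows = []
        for t in self.trials:
            row: dict = {
                "experiment": t.experiment.value,
                "predator_species": t.predator_species,
                "replicate_id": t.replicate_id,
                "duration_days": t.duration_T,
            }
            for s in STAGES:
                row[f"offered_{s}"] = t.offered.get(s)
                row[f"consumed_{s}"] = t.consumed.get(s)
            rows.append(row)
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _parse_count(raw: str, column: str, line: int) -> int | None:
    if raw == "" or raw is None:
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise SchemaError(f"row {line}: {column} is not a number: {raw!r}") from exc
    if value != int(value):
        raise ValidationError(f"row {line}: {column} must be an integer, got {raw!r}")
    return int(value)


def read_trials(path, experiment_filter: Experiment | str | None = None) -> TrialDataset:
    """Read and validate a trial CSV.

    Rows violating the data-model invariants raise :class:`ValidationError`
    (naming the offending row); they are never silently dropped. A missing
    required column raises :class:`SchemaError` naming the column.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CSV_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    trials: list[PredationTrial] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # 1-based, after the header
        try:
            experiment = Experiment(row["experiment"])
        except ValueError as exc:
            raise ValidationError(
                f"row {line}: unknown experiment {row['experiment']!r}"
            ) from exc
        offered: dict[str, int] = {}
        consumed: dict[str, int] = {}
        for s in STAGES:
            off = _parse_count(row[f"offered_{s}"], f"offered_{s}", line)
            con = _parse_count(row[f"consumed_{s}"], f"consumed_{s}", line)
            if (off is None) != (con is None):
                raise ValidationError(
                    f"row {line}: offered_{s}/consumed_{s} must both be set or both empty"
                )
            if off is not None:
                offered[s] = off
                consumed[s] = con
        try:
            trial = PredationTrial(
                experiment=experiment,
                predator_species=row["predator_species"],
                replicate_id=int(float(row["replicate_id"])),
                duration_T=float(row["duration_days"]),
                offered=offered,
                consumed=consumed,
            )
        except ValidationError as exc:
            raise ValidationError(f"row {line}: {exc}") from exc
        trials.append(trial)

    dataset = TrialDataset(trials=trials, metadata={"source": str(path)})
    if experiment_filter is not None:
        dataset = dataset.filter(experiment_filter)
    return dataset


def write_trials(dataset: TrialDataset, path) -> None:
    """Write a dataset to CSV; ``read_trials`` round-trips it losslessly.

    Column order is fixed, counts are written as plain integers and unused
    stage cells as empty strings, so output is byte-stable for a given
    dataset.
    """
    frame = dataset.to_dataframe()
    for s in STAGES:
        for kind in ("offered", "consumed"):
            col = f"{kind}_{s}"
            frame[col] = frame[col].map(
                lambda v: "" if pd.isna(v) else str(int(v))
            )
    frame["duration_days"] = frame["duration_days"].map(_format_duration)
    frame.to_csv(path, index=False, lineterminator="\n")


def _format_duration(v: float) -> str:
    return str(int(v)) if float(v) == int(v) else repr(float(v))


def trials_from_counts(
    experiment: Experiment | str,
    species: str,
    stage_counts: Iterable[tuple[dict, dict]],
    duration_T: float = 1.0,
    start_replicate: int = 1,
) -> list[PredationTrial]:
    """Convenience builder: one trial per (offered, consumed) pair."""
    return [
        PredationTrial(
            experiment=Experiment(experiment),
            predator_species=species,
            replicate_id=start_replicate + i,
            offered=offered,
            consumed=consumed,
            duration_T=duration_T,
        )
        for i, (offered, consumed) in enumerate(stage_counts)
    ]
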