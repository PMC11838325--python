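"""Readers, writers and dataset validation for the tidy trial tables.

Trial tables are long/tidy CSV, one row per verification trial, with the
exact header ``person_id,session_id,item_id,rt,response``.  Censored
(no-response) trials carry ``response=none`` and an empty ``rt`` field.
Item tables carry ``item_id,operand_a,operand_b``; the sum and the
easy/hard class (sum <= 10 vs > 10) are derived.  Run configuration is a
flat YAML key-value file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError, DataValidationError, FormatError
from .params import PARAM_NAMES, PersonParams

TRIAL_COLUMNS = ["person_id", "session_id", "item_id", "rt", "response"]
RESPONSES = ("correct", "incorrect", "none")


@dataclass(frozen=True)
class TrialRecord:
    """One observed verification trial."""

    person_id: str
    session_id: str
    item_id: str
    rt: Optional[float]
    response: str

    def __post_init__(self):
        if self.response not in RESPONSES:
            raise DataValidationError(f"unknown response code: {self.response!r}")
        has_rt = self.rt is not None and not (
            isinstance(self.rt, float) and np.isnan(self.rt)
        )
        if (self.response == "none") == has_rt:
            raise DataValidationError(
                "rt must be present exactly when a response was given"
            )
        if has_rt and self.rt <= 0:
            raise DataValidationError(f"rt must be positive, got {self.rt}")


@dataclass(frozen=True)
class ItemSpec:
    """One addition-verification item; easy means sum <= 10."""

    item_id: str
    operand_a: int
    operand_b: int

    @property
    def sum(self) -> int:
        return self.operand_a + self.operand_b

    @property
    def difficulty_class(self) -> str:
        return "easy" if self.sum <= 10 else "hard"


@dataclass
class RunConfig:
    """Flat run configuration: task deadline, sampler settings, simulation
    dimensions, prior hyperparameters and numeric tolerances."""

    deadline: float = 5.0          # response deadline T_max, seconds
    chains: int = 2
    draws: int = 1500              # retained draws per chain
    warmup: int = 700              # adaptation sweeps, discarded
    thin: int = 1
    seed: int = 0
    accuracy_threshold: float = 0.5
    n_persons: int = 105
    n_sessions: int = 3
    n_items: int = 24
    trials_per_session: int = 60
    session_jitter: float = 0.1    # session scale as fraction of person scale
    loc_prior_sd: float = 2.0      # Normal hyperprior SD on group locations
    scale_prior_sd: float = 1.0    # half-Normal hyperprior scale on SDs
    extras_prior_sd: float = 2.0   # hyperprior scale on nu, lambda, Delta
    mass_tol: float = 1e-5         # outcome-mass closure tolerance
    init_jitter: float = 0.1       # initialization jitter, transformed scale

    def __post_init__(self):
        if not self.deadline > 0:
            raise ConfigError("deadline must be > 0")
        if self.chains < 2:
            raise ConfigError("chains must be >= 2")
        if self.draws < 1:
            raise ConfigError("draws must be >= 1")
        if self.warmup < 0 or self.thin < 1:
            raise ConfigError("warmup must be >= 0 and thin >= 1")
        if not 0 < self.accuracy_threshold < 1:
            raise ConfigError("accuracy_threshold must lie in (0, 1)")


def load_config(path) -> RunConfig:
    """Load a flat YAML key-value config; unspecified keys take defaults."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a flat key: value mapping")
    valid = {f.name: f.type for f in dc_fields(RunConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in valid:
            raise ConfigError(
                f"unknown config key {key!r}; valid keys: {sorted(valid)}"
            )
        if isinstance(value, bool) or not isinstance(value, (int, float)):
            raise ConfigError(f"config key {key!r} must be numeric, got {value!r}")
        kwargs[key] = value
    return RunConfig(**kwargs)


def read_trials(path) -> pd.DataFrame:
    """Read and validate a tidy trial table.

    Returns a DataFrame with columns person_id, session_id, item_id,
    rt (float, NaN for censored trials) and response.
    """
    try:
        df = pd.read_csv(path, dtype={c: str for c in TRIAL_COLUMNS[:3]})
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise FormatError(f"could not parse {path}: {exc}") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trial table missing column(s): {', '.join(missing)}")
    extra = [c for c in df.columns if c not in TRIAL_COLUMNS]
    if extra:
        raise FormatError(f"trial table has unexpected column(s): {', '.join(extra)}")
    df = df[TRIAL_COLUMNS].copy()
    try:
        df["rt"] = pd.to_numeric(df["rt"], errors="raise")
    except (ValueError, TypeError) as exc:
        raise FormatError(f"non-numeric rt value: {exc}") from exc
    df["rt"] = df["rt"].astype(float)
    return validate_trials(df)


def validate_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Validate trial-level invariants, with row numbers in messages."""
    bad_resp = ~df["response"].isin(RESPONSES)
    if bad_resp.any():
        row = int(np.flatnonzero(bad_resp)[0])
        raise DataValidationError(
            f"row {row}: unknown response code {df['response'].iloc[row]!r}"
        )
    has_rt = df["rt"].notna()
    mismatch = (df["response"] == "none") == has_rt
    if mismatch.any():
        row = int(np.flatnonzero(mismatch)[0])
        raise DataValidationError(
            f"row {row}: rt must be present exactly when response != none"
        )
    nonpos = has_rt & (df["rt"] <= 0)
    if nonpos.any():
        row = int(np.flatnonzero(nonpos)[0])
        raise DataValidationError(f"row {row}: rt must be positive")
    return df.reset_index(drop=True)


def write_trials(trials, path) -> None:
    """Write a trial table; round-trips through :func:`read_trials`."""
    if isinstance(trials, pd.DataFrame):
        df = trials[TRIAL_COLUMNS]
    else:
        df = pd.DataFrame(
            [
                {
                    "person_id": t.person_id,
                    "session_id": t.session_id,
                    "item_id": t.item_id,
                    "rt": np.nan if t.rt is None else t.rt,
                    "response": t.response,
                }
                for t in trials
            ],
            columns=TRIAL_COLUMNS,
        )
    df.to_csv(path, index=False)


def trials_to_records(df: pd.DataFrame) -> list[TrialRecord]:
    return [
        TrialRecord(
            r.person_id,
            r.session_id,
            r.item_id,
            None if pd.isna(r.rt) else float(r.rt),
            r.response,
        )
        for r in df.itertuples(index=False)
    ]


def read_items(path) -> pd.DataFrame:
    """Read an item table; derives sum, difficulty_class and keeps an
    optional difficulty column d."""
    df = pd.read_csv(path, dtype={"item_id": str})
    required = ["item_id", "operand_a", "operand_b"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"item table missing column(s): {', '.join(missing)}")
    df = df.copy()
    df["sum"] = df["operand_a"].astype(int) + df["operand_b"].astype(int)
    df["difficulty_class"] = np.where(df["sum"] <= 10, "easy", "hard")
    if df["item_id"].duplicated().any():
        raise DataValidationError("duplicate item_id in item table")
    return df


def write_items(items: pd.DataFrame, path) -> None:
    cols = [c for c in ["item_id", "operand_a", "operand_b", "d"] if c in items.columns]
    items[cols].to_csv(path, index=False)


def read_params(path) -> pd.DataFrame:
    """Read a person(-session) parameter table: identifier columns plus one
    column per parameter, natural scale."""
    df = pd.read_csv(path, dtype={"person_id": str, "session_id": str})
    missing = [c for c in PARAM_NAMES if c not in df.columns]
    if missing:
        raise FormatError(f"parameter table missing column(s): {', '.join(missing)}")
    for _, row in df.iterrows():
        PersonParams.from_array(row[list(PARAM_NAMES)].to_numpy(dtype=float))
    return df


def write_params(params: pd.DataFrame, path) -> None:
    params.to_csv(path, index=False)


@dataclass
class ValidationReport:
    """Dataset screening summary (warn, never drop)."""

    per_person: pd.DataFrame
    flagged_low_accuracy: list = field(default_factory=list)
    flagged_rt_at_deadline: list = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.flagged_low_accuracy and not self.flagged_rt_at_deadline


def validate_dataset(trials: pd.DataFrame, items: pd.DataFrame,
                     config: RunConfig) -> ValidationReport:
    """Screen a dataset: per-person counts, accuracy on answered trials,
    low-accuracy flags and deadline violations.  Pure: repeated calls on
    the same inputs give identical reports."""
    validate_trials(trials)
    unknown = set(trials["item_id"]) - set(items["item_id"])
    if unknown:
        raise DataValidationError(
            f"item_id(s) in trials absent from item table: {sorted(unknown)}"
        )
    answered = trials[trials["response"] != "none"]
    grp = trials.groupby("person_id", sort=True)
    per_person = pd.DataFrame(
        {
            "n_trials": grp.size(),
            "n_answered": answered.groupby("person_id").size().reindex(
                grp.size().index, fill_value=0
            ),
        }
    )
    acc = (
        answered.assign(correct=answered["response"] == "correct")
        .groupby("person_id")["correct"]
        .mean()
    )
    per_person["accuracy"] = acc.reindex(per_person.index)
    per_person["flagged"] = per_person["accuracy"] < config.accuracy_threshold
    flagged = per_person.index[per_person["flagged"].fillna(False)].tolist()
    at_deadline = trials["rt"].notna() & (trials["rt"] >= config.deadline)
    flagged_rt = trials.index[at_deadline].tolist()
    return ValidationReport(
        per_person=per_person.reset_index(),
        flagged_low_accuracy=flagged,
        flagged_rt_at_deadline=flagged_rt,
    )
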