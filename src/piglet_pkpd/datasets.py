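"""Synthetic study generation and the long-format dataset container.

A study dataset is a long-format table with one dosing record and a set of
observation records per subject, in the columns conventional for
pharmacometric software:

    ID    subject identifier (int)
    TIME  hours post-dose
    EVID  1 = dosing event, 0 = observation
    DVID  observation stream: 1 plasma drug, 2 ISF drug, 3 biomarker
    AMT   dose amount (mg/kg) on dosing records
    DV    observed value (ug/ml for drug streams, percent-of-control for
          the biomarker)
    BLQ   1 if the observation fell below the assay limit of quantification
          (DV then holds the LOQ value)

:func:`generate_study` emulates the study design that the analysis assumes:
8 piglets per group, a single intramuscular dose at t = 0, castration/tail
docking at t = 2 h (metadata only -- the turnover models carry no explicit
insult term), plasma/ISF/biomarker sampling over 0-48 h, lognormal
inter-individual variability, stream-appropriate residual noise, and LOQ
censoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .population import PopulationModel, apply_residual, sample_individuals
from .simulate import STREAM_IDS, simulate_individual

__all__ = [
    "StudyDesign",
    "StudyDataset",
    "generate_study",
    "percent_of_control",
    "read_dataset",
    "write_dataset",
]

FORMAT_HEADER = "# piglet-pkpd dataset v1"
_COLUMNS = ["ID", "TIME", "EVID", "DVID", "AMT", "DV", "BLQ"]
_ID_TO_STREAM = {v: k for k, v in STREAM_IDS.items()}


class DatasetFormatError(ValueError):
    """Malformed dataset file or frame."""


@dataclass(frozen=True)
class StudyDesign:
    """Study design: group size, dosing, sampling schedule, and assay LOQs."""

    n_per_group: int = 8
    dose: float = 0.0  # mg/kg, single IM dose at t = 0
    castration_time: float = 2.0  # h post-dose; recorded but not a model event
    schedule: Mapping[str, Sequence[float]] = field(default_factory=dict)
    loq: Mapping[str, float] = field(default_factory=dict)
    control_group: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 for fitting")
        for stream, times in self.schedule.items():
            if stream not in STREAM_IDS:
                raise ValueError(f"unknown stream {stream!r} in schedule")
            times = np.asarray(times, dtype=float)
            if times.size and (times.min() < 0 or times.max() > 48.0):
                raise ValueError(f"{stream} schedule outside [0, 48] h")


@dataclass(frozen=True)
class StudyDataset:
    """Long-format dosing + observation records (see module docstring)."""

    frame: pd.DataFrame
    meta: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        _validate_frame(self.frame)

    @property
    def subjects(self) -> list[int]:
        return sorted(self.frame["ID"].unique())

    def observations(self, stream: str, *, include_blq: bool = False) -> pd.DataFrame:
        dvid = STREAM_IDS[stream]
        obs = self.frame[(self.frame["EVID"] == 0) & (self.frame["DVID"] == dvid)]
        if not include_blq:
            obs = obs[obs["BLQ"] == 0]
        return obs

    def n_blq(self, stream: str | None = None) -> int:
        obs = self.frame[self.frame["EVID"] == 0]
        if stream is not None:
            obs = obs[obs["DVID"] == STREAM_IDS[stream]]
        return int(obs["BLQ"].sum())

    def dose_of(self, subject: int) -> float:
        rows = self.frame[(self.frame["ID"] == subject) & (self.frame["EVID"] == 1)]
        return float(rows["AMT"].iloc[0])


def _validate_frame(frame: pd.DataFrame) -> None:
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"dataset is missing columns {missing}")
    bad_evid = frame.index[~frame["EVID"].isin([0, 1])].tolist()
    if bad_evid:
        raise DatasetFormatError(f"invalid EVID values at rows {bad_evid[:10]}")
    obs = frame[frame["EVID"] == 0]
    bad_dvid = obs.index[~obs["DVID"].isin(_ID_TO_STREAM)].tolist()
    if bad_dvid:
        raise DatasetFormatError(f"unknown observation stream at rows {bad_dvid[:10]}")
    for subject, grp in frame.groupby("ID"):
        n_dose = int((grp["EVID"] == 1).sum())
        if n_dose != 1:
            raise DatasetFormatError(
                f"subject {subject} has {n_dose} dose records (expected exactly 1)"
            )
        if not grp["TIME"].is_monotonic_increasing:
            raise DatasetFormatError(f"times are not nondecreasing for subject {subject}")
        if not (grp["EVID"] == 0).any():
            warnings.warn(
                f"subject {subject} has no observations; retained for dosing records",
                stacklevel=3,
            )


def generate_study(
    design: StudyDesign, pop: PopulationModel, seed: int | np.random.Generator
) -> StudyDataset:
    """Simulate a complete synthetic study under the given design.

    Samples individual parameters, simulates each subject's trajectories at
    the scheduled times, applies the stream-appropriate residual-error model,
    and censors drug concentrations at the assay LOQ (``BLQ`` flagged, ``DV``
    set to the LOQ).  With all variances zero the dataset equals the
    typical-value predictions exactly.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pop = pop.with_dose(design.dose)
    individuals = sample_individuals(pop, design.n_per_group, rng)
    noise_rngs = rng.spawn(design.n_per_group)

    all_times = sorted({t for times in design.schedule.values() for t in times})
    rows = []
    for ind, noise_rng in zip(individuals, noise_rngs):
        rows.append((ind.subject, 0.0, 1, 0, design.dose, np.nan, 0))
        traj = simulate_individual(ind, times=all_times)
        lookup = {t: i for i, t in enumerate(traj.times)}
        for stream in sorted(design.schedule):
            times = np.asarray(design.schedule[stream], dtype=float)
            if times.size == 0:
                continue
            idx = [lookup[t] for t in times]
            pred = traj.stream(stream)[idx]
            spec = pop.error.get(stream)
            values = apply_residual(pred, spec, noise_rng) if spec is not None else pred
            loq = design.loq.get(stream)
            dvid = STREAM_IDS[stream]
            for t, value in zip(times, values):
                if loq is not None and value < loq:
                    rows.append((ind.subject, t, 0, dvid, np.nan, loq, 1))
                else:
                    rows.append((ind.subject, t, 0, dvid, np.nan, value, 0))

    frame = pd.DataFrame(rows, columns=_COLUMNS)
    frame = frame.sort_values(["ID", "TIME", "EVID", "DVID"], ascending=[True, True, False, True])
    frame = frame.reset_index(drop=True)
    meta = {
        "dose": design.dose,
        "model": pop.structural.name,
        "castration_time": design.castration_time,
        "control_group": design.control_group,
    }
    return StudyDataset(frame=frame, meta=meta)


def percent_of_control(
    treated: np.ndarray,
    control: np.ndarray,
    *,
    mode: str = "ratio",
) -> np.ndarray:
    """Express treated biomarker series relative to a control group.

    ``treated`` has shape (n_treated, n_times) (or (n_times,)), ``control``
    shape (n_control, n_times).  The control central tendency is the
    geometric mean across control subjects at each time.  ``mode="ratio"``
    returns ``100 * treated / central`` (so no drug effect maps to 100);
    ``mode="difference"`` returns ``100 * (treated - central) / central``.
    """
    treated = np.atleast_2d(np.asarray(treated, dtype=float))
    control = np.atleast_2d(np.asarray(control, dtype=float))
    if treated.shape[-1] != control.shape[-1]:
        raise ValueError("treated and control series must be time-aligned")
    if np.any(control <= 0):
        raise ValueError("control values must be positive for the geometric mean")
    central = np.exp(np.mean(np.log(control), axis=0))
    if mode == "ratio":
        out = 100.0 * treated / central
    elif mode == "difference":
        out = 100.0 * (treated - central) / central
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return out[0] if out.shape[0] == 1 else out


def write_dataset(ds: StudyDataset, path: str | Path) -> None:
    """Write the dataset as CSV with a one-line format declaration."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(FORMAT_HEADER + "\n")
        ds.frame.to_csv(fh, index=False)


def read_dataset(path: str | Path) -> StudyDataset:
    """Read a dataset written by :func:`write_dataset` (lossless round-trip)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != FORMAT_HEADER:
            raise DatasetFormatError(
                f"{path}:1: expected format declaration {FORMAT_HEADER!r}, got {header!r}"
            )
        try:
            frame = pd.read_csv(fh)
        except Exception as exc:
            raise DatasetFormatError(f"{path}: unparseable CSV body: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in frame.columns]
    if missing:
        raise DatasetFormatError(f"{path}:2: missing columns {missing}")
    frame = frame[_COLUMNS].astype(
        {"ID": int, "TIME": float, "EVID": int, "DVID": int, "AMT": float, "DV": float, "BLQ": int}
    )
    return StudyDataset(frame=frame)
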