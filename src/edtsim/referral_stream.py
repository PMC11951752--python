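"""Synthetic referral streams for a regional visual electrodiagnostics (EDT) service.

Emulates the referral cohort of a large tertiary EDT centre observed over a
13-week quarter.  Referrals fall into four groups:

* **A** — retinal symptoms or findings (e.g. nyctalopia, retinal pigmentation),
* **B** — retinal-disease risk for a non-ocular reason (systemic diagnosis,
  family history),
* **C** — retinal-disease risk due to non-retinal ophthalmic findings
  (e.g. unexplained high myopia or reduced vision),
* **D** — referred primarily for a visual evoked potential (VEP) and therefore
  not screenable with a hand-held ERG device.

Arrivals follow independent homogeneous Poisson processes per group.  Each
group A–C patient carries a latent gold-standard ERG status (abnormal with a
group-specific probability) drawn at referral; group D patients are modelled
purely as demand on the EDT laboratory and carry no ERG status.  The module
also builds the initial waiting-list backlog and round-trips patient-level
records through CSV.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "GROUPS",
    "WEEKS_PER_QUARTER",
    "WEEKS_PER_YEAR",
    "GroupParams",
    "PatientRecord",
    "default_group_params",
    "generate_referrals",
    "generate_backlog",
    "write_patients",
    "read_patients",
]

GROUPS = ("A", "B", "C", "D")

WEEKS_PER_QUARTER = 13.0
WEEKS_PER_YEAR = 52.0

# Referral counts and abnormal gold-standard ERG counts observed in one
# quarter (13 weeks) at the modelled service.
_QUARTER_COUNTS = {"A": 77, "B": 14, "C": 40, "D": 64}
_QUARTER_ABNORMAL = {"A": 23, "B": 4, "C": 5}

SeedLike = Union[int, Sequence[int], np.random.SeedSequence]


@dataclass(frozen=True)
class GroupParams:
    """Arrival rate and abnormality probability for one referral group.

    ``weekly_rate`` is the Poisson arrival rate in patients per week.
    ``p_abnormal`` is the probability that the gold-standard laboratory ERG
    would be abnormal; it is ``None`` for group D, whose referrals are
    primarily for VEP and carry no ERG-status draw.
    """

    group: str
    weekly_rate: float
    p_abnormal: Optional[float]
    screenable: bool = True

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.weekly_rate < 0:
            raise ValueError(f"weekly_rate must be >= 0, got {self.weekly_rate}")
        if self.p_abnormal is not None and not (0.0 <= self.p_abnormal <= 1.0):
            raise ValueError(
                f"p_abnormal must be in [0, 1] or None, got {self.p_abnormal}"
            )
        if self.group == "D" and self.screenable:
            raise ValueError(
                "group D is referred primarily for VEP and is not screenable "
                "with a hand-held ERG"
            )


def default_group_params() -> list[GroupParams]:
    """Group parameters reconstructed from the observed quarter.

    Weekly rates divide the quarterly referral counts by 13; abnormality
    probabilities divide abnormal gold-standard ERG counts by group size
    (A: 23/77, B: 4/14, C: 5/40).  The implied total of 15 referrals/week
    matches the service's expected 780 referrals per 52-week year.
    """
    out = []
    for g in GROUPS:
        n = _QUARTER_COUNTS[g]
        abn = _QUARTER_ABNORMAL.get(g)
        out.append(
            GroupParams(
                group=g,
                weekly_rate=n / WEEKS_PER_QUARTER,
                p_abnormal=None if abn is None else abn / n,
                screenable=g != "D",
            )
        )
    return out


@dataclass(slots=True)
class PatientRecord:
    """One referred patient flowing through the pathway.

    ``arrival_week`` is measured in continuous weeks from simulation start
    (0 for backlog patients already on the waiting list).  ``true_abnormal``
    is the latent gold-standard ERG status (``None`` for group D).
    ``screen_flagged`` is set only for patients who passed through the
    hand-held screening step.  ``edt_week``/``wait_weeks`` are filled when
    the patient receives their laboratory EDT appointment.
    """

    id: int
    source: str  # "backlog" or "referral"
    arrival_week: float
    group: str
    true_abnormal: Optional[bool] = None
    screen_flagged: Optional[bool] = None
    edt_week: Optional[float] = None
    wait_weeks: Optional[float] = None

    def __post_init__(self) -> None:
        if self.source not in ("backlog", "referral"):
            raise ValueError(f"source must be 'backlog' or 'referral', got {self.source!r}")
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.arrival_week < 0:
            raise ValueError(f"arrival_week must be >= 0, got {self.arrival_week}")
        if self.source == "backlog" and self.arrival_week != 0:
            raise ValueError("backlog records must have arrival_week = 0")


def generate_referrals(
    params: Sequence[GroupParams],
    horizon_weeks: float,
    demand_scale: float = 1.0,
    rng_seed: SeedLike = 0,
    id_start: int = 0,
) -> list[PatientRecord]:
    """Draw a referral stream over ``[0, horizon_weeks)``.

    Each group contributes an independent homogeneous Poisson process at
    ``weekly_rate * demand_scale``; arrival times are uniform over the
    horizon given the count.  Records are returned sorted by arrival time
    with ids assigned in arrival order starting at ``id_start``.
    Reproducible given ``rng_seed``.
    """
    if horizon_weeks <= 0:
        raise ValueError(f"horizon_weeks must be positive, got {horizon_weeks}")
    if demand_scale <= 0:
        raise ValueError(f"demand_scale must be positive, got {demand_scale}")
    rng = np.random.default_rng(rng_seed)
    events: list[tuple[float, str, Optional[bool]]] = []
    for gp in params:
        n = int(rng.poisson(gp.weekly_rate * demand_scale * horizon_weeks))
        times = rng.uniform(0.0, horizon_weeks, size=n)
        if gp.p_abnormal is None:
            statuses: Iterable[Optional[bool]] = (None,) * n
        else:
            statuses = (rng.random(n) < gp.p_abnormal).tolist()
        for t, abn in zip(times, statuses):
            events.append((float(t), gp.group, None if abn is None else bool(abn)))
    events.sort(key=lambda e: e[0])
    return [
        PatientRecord(
            id=id_start + k,
            source="referral",
            arrival_week=t,
            group=g,
            true_abnormal=abn,
        )
        for k, (t, g, abn) in enumerate(events)
    ]


def generate_backlog(
    n: int,
    params: Sequence[GroupParams],
    rng_seed: SeedLike = 0,
    id_start: int = 0,
) -> list[PatientRecord]:
    """Build the waiting-list backlog present at time zero.

    The group mix mirrors the arrival mix (bookkeeping only: backlog
    patients bypass screening and consume laboratory slots identically
    whatever their group).  Group A–C patients still receive a latent
    true-ERG-status draw.
    """
    if n < 0:
        raise ValueError(f"backlog size must be >= 0, got {n}")
    rng = np.random.default_rng(rng_seed)
    rates = np.array([gp.weekly_rate for gp in params], dtype=float)
    total = rates.sum()
    if n > 0 and total <= 0:
        raise ValueError("cannot draw a backlog group mix from all-zero rates")
    records = []
    for k in range(n):
        gp = params[int(rng.choice(len(params), p=rates / total))]
        abn = None if gp.p_abnormal is None else bool(rng.random() < gp.p_abnormal)
        records.append(
            PatientRecord(
                id=id_start + k,
                source="backlog",
                arrival_week=0.0,
                group=gp.group,
                true_abnormal=abn,
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV plumbing

CSV_HEADER = (
    "id",
    "source",
    "arrival_week",
    "group",
    "true_abnormal",
    "screen_flagged",
    "edt_week",
    "wait_weeks",
)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "True" if value else "False"
    if isinstance(value, float):
        return repr(value)
    return str(value)


def _parse_opt_bool(s: str, what: str):
    if s == "":
        return None
    if s == "True":
        return True
    if s == "False":
        return False
    raise ValueError(f"{what} must be 'True', 'False' or empty, got {s!r}")


def _parse_opt_float(s: str, what: str):
    if s == "":
        return None
    try:
        return float(s)
    except ValueError:
        raise ValueError(f"{what} must be a real number or empty, got {s!r}") from None


def write_patients(path, records: Sequence[PatientRecord]) -> None:
    """Write patient records to CSV with a fixed header (one row per patient)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_HEADER)
        for r in records:
            writer.writerow(
                [
                    r.id,
                    r.source,
                    _fmt(r.arrival_week),
                    r.group,
                    _fmt(r.true_abnormal),
                    _fmt(r.screen_flagged),
                    _fmt(r.edt_week),
                    _fmt(r.wait_weeks),
                ]
            )


def read_patients(path) -> list[PatientRecord]:
    """Read patient records written by :func:`write_patients`.

    Malformed rows are reported with their 1-based line number.
    """
    path = Path(path)
    records = []
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: line 1: missing header row") from None
        if tuple(header) != CSV_HEADER:
            raise ValueError(f"{path}: line 1: expected header {CSV_HEADER}, got {tuple(header)}")
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise ValueError(
                    f"{path}: line {lineno}: expected {len(CSV_HEADER)} fields, got {len(row)}"
                )
            try:
                rec = PatientRecord(
                    id=int(row[0]),
                    source=row[1],
                    arrival_week=float(row[2]),
                    group=row[3],
                    true_abnormal=_parse_opt_bool(row[4], "true_abnormal"),
                    screen_flagged=_parse_opt_bool(row[5], "screen_flagged"),
                    edt_week=_parse_opt_float(row[6], "edt_week"),
                    wait_weeks=_parse_opt_float(row[7], "wait_weeks"),
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from None
            records.append(rec)
    return records
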