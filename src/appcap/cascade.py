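"""In-scope population: practice registers and the prevalence cascade.

The in-scope population for brief psychological intervention is estimated
per primary care network (PCN) as

    adults (aged >= min_age)  x  mh_prevalence  x  severity_share

i.e. registered adults, of whom a fraction have a mental-health need, of
whom a fraction fall in the mild-to-moderate band. Values are carried as
reals through the cascade; rounding to whole persons happens only at
report time, so per-practice fractions never compound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import CascadeParams
from .errors import BoundaryMismatchError, SchemaError

REGISTER_COLUMNS = ["practice_id", "pcn_id", "age_band", "patients"]

_BAND_RE = re.compile(r"^\s*(\d+)\s*(?:-\s*(\d+)|\+)\s*$")


def parse_age_band(label: str) -> tuple[int, Optional[int]]:
    """Parse an age-band label like ``"0-14"`` or ``"15+"`` into (low, high).

    ``high`` is ``None`` for an open-ended band.
    """
    match = _BAND_RE.match(str(label))
    if not match:
        raise SchemaError(f"unparseable age band label {label!r}")
    low = int(match.group(1))
    high = int(match.group(2)) if match.group(2) is not None else None
    if high is not None and high < low:
        raise SchemaError(f"age band {label!r} has high < low")
    return low, high


@dataclass
class PracticeRecord:
    """One general practice: identifier, parent PCN and list sizes by band."""

    practice_id: str
    pcn_id: str
    list_size_by_age_band: dict[str, float]

    def __post_init__(self) -> None:
        for band, count in self.list_size_by_age_band.items():
            parse_age_band(band)
            if count < 0:
                raise ValueError(
                    f"practice {self.practice_id}: negative count in band {band}"
                )

    @property
    def total(self) -> float:
        return float(sum(self.list_size_by_age_band.values()))


@dataclass
class PCNRegister:
    """All practices belonging to one PCN."""

    pcn_id: str
    practices: list[PracticeRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.practices:
            raise ValueError(f"PCN {self.pcn_id}: register needs >= 1 practice")
        for practice in self.practices:
            if practice.pcn_id != self.pcn_id:
                raise ValueError(
                    f"practice {practice.practice_id} belongs to "
                    f"{practice.pcn_id}, not {self.pcn_id}"
                )

    @property
    def total_population(self) -> float:
        return float(sum(p.total for p in self.practices))


@dataclass
class CascadeResult:
    """Staged in-scope counts for one PCN (real-valued; round on report)."""

    total_population: float
    adult_population: float
    mh_population: float
    in_scope_population: float


def adult_population(register: PCNRegister, min_age: int) -> float:
    """Sum list sizes in bands at or above ``min_age`` across all practices.

    ``min_age`` must coincide with a band boundary; a cutoff strictly inside
    a band cannot be resolved from banded counts and raises
    :class:`BoundaryMismatchError`.
    """
    total = 0.0
    for practice in register.practices:
        for band, count in practice.list_size_by_age_band.items():
            low, high = parse_age_band(band)
            if low >= min_age:
                total += count
            elif high is None or high >= min_age:
                raise BoundaryMismatchError(
                    f"min_age {min_age} falls inside band {band!r} of practice "
                    f"{practice.practice_id}; it must align with a band boundary"
                )
    return float(total)


def compute_cascade(
    adult: float,
    params: CascadeParams,
    total_population: Optional[float] = None,
) -> CascadeResult:
    """Apply the prevalence-and-severity cascade to an adult population.

    ``total_population`` is carried through for reporting; when omitted the
    adult count stands in for it.
    """
    if adult < 0:
        raise ValueError(f"adult population must be >= 0, got {adult}")
    mh = adult * params.mh_prevalence
    in_scope = mh * params.severity_share
    return CascadeResult(
        total_population=float(total_population if total_population is not None else adult),
        adult_population=float(adult),
        mh_population=mh,
        in_scope_population=in_scope,
    )


def cascade_for_register(register: PCNRegister, params: CascadeParams) -> CascadeResult:
    """Cascade at PCN level: practices are pooled before the fractions apply."""
    adult = adult_population(register, params.min_age)
    return compute_cascade(adult, params, total_population=register.total_population)


def read_register(path: str | Path) -> list[PCNRegister]:
    """Read a long-format register CSV (practice_id, pcn_id, age_band, patients)."""
    frame = pd.read_csv(path, dtype={"practice_id": str, "pcn_id": str, "age_band": str})
    missing = set(REGISTER_COLUMNS) - set(frame.columns)
    if missing:
        raise SchemaError(f"register {path}: missing columns {sorted(missing)}")
    registers: list[PCNRegister] = []
    for pcn_id, pcn_rows in frame.groupby("pcn_id", sort=True):
        practices = [
            PracticeRecord(
                practice_id=str(practice_id),
                pcn_id=str(pcn_id),
                list_size_by_age_band=dict(
                    zip(rows["age_band"], rows["patients"].astype(float))
                ),
            )
            for practice_id, rows in pcn_rows.groupby("practice_id", sort=True)
        ]
        registers.append(PCNRegister(pcn_id=str(pcn_id), practices=practices))
    return registers


def registers_to_frame(registers: Iterable[PCNRegister]) -> pd.DataFrame:
    """Long-format table of one row per practice x age band."""
    rows = [
        {
            "practice_id": practice.practice_id,
            "pcn_id": register.pcn_id,
            "age_band": band,
            "patients": int(count),
        }
        for register in registers
        for practice in register.practices
        for band, count in practice.list_size_by_age_band.items()
    ]
    return pd.DataFrame(rows, columns=REGISTER_COLUMNS)


def write_register(registers: Iterable[PCNRegister], path: str | Path) -> Path:
    path = Path(path)
    registers_to_frame(registers).to_csv(path, index=False)
    return path
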