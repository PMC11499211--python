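"""Ethogram definition and observation data model.

Maternal behavior is scored by instantaneous (scan) sampling: during each
72-minute observation period the ongoing behavior is recorded every 3 minutes,
inclusive of the start, giving 25 samples per period.  Three periods are
observed per day -- two in the light phase (``AM`` at 9:00, ``PM`` at 14:00)
and one at the start of the dark phase (``DARK`` at 18:00) -- for 75 scans per
24-h cycle.

The scored repertoire has seven states:

======  =====================================================
HG      high crouch (arched-back) nursing posture
LW      low crouch ("blanket") nursing posture
SUP     supine/passive nursing posture
L       licking/grooming pups (alone, no nursing posture)
HG/L    high crouch nursing while licking pups
DN      dam in the nest, not nursing
OFF     dam off the nest
======  =====================================================

Six of these (all except ``L``) serve as nodes of the transition network;
``L`` alone is rare and is excluded from network construction (see
:mod:`maternet.transitions` for the two exclusion policies).

Non-pup-directed events (nest building, pup retrieval, self-grooming, pups
off nest) may co-occur with a scored state and are carried as per-slot
auxiliary annotations.  They never enter transition networks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

__all__ = [
    "CODES",
    "NETWORK_NODES",
    "AUX_EVENTS",
    "PERIODS",
    "GROUPS",
    "SLOTS_PER_PERIOD",
    "PERIODS_PER_DAY",
    "SCANS_PER_DAY",
    "PERIOD_MINUTES",
    "SCAN_INTERVAL_MINUTES",
    "PPD_MIN",
    "PPD_MAX",
    "EthogramError",
    "ObservationSession",
    "Dataset",
    "read_observations",
    "write_observations",
]

#: The seven scored behavior codes, in canonical order.
CODES: tuple[str, ...] = ("HG", "LW", "SUP", "L", "HG/L", "DN", "OFF")

#: The six codes used as transition-network nodes (L is excluded).
NETWORK_NODES: tuple[str, ...] = ("HG", "LW", "SUP", "HG/L", "DN", "OFF")

#: Auxiliary (non-pup-directed / litter) event annotations.
AUX_EVENTS: tuple[str, ...] = ("NEST_BUILD", "PUP_RETRIEVE", "SELF_GROOM", "PUP_OFF")

PERIODS: tuple[str, ...] = ("AM", "PM", "DARK")
GROUPS: tuple[str, ...] = ("CTRL", "LBN")

PERIOD_MINUTES = 72
SCAN_INTERVAL_MINUTES = 3
#: Scans per period: one at the start plus one every 3 min over 72 min.
SLOTS_PER_PERIOD = PERIOD_MINUTES // SCAN_INTERVAL_MINUTES + 1
PERIODS_PER_DAY = 3
SCANS_PER_DAY = SLOTS_PER_PERIOD * PERIODS_PER_DAY

#: Postpartum-day window of the housing manipulation and observations.
PPD_MIN, PPD_MAX = 2, 9

CSV_HEADER = ("dam_id", "group", "ppd", "period", "slot", "code", "aux")

_CODE_SET = frozenset(CODES)
_AUX_SET = frozenset(AUX_EVENTS)
_PERIOD_ORDER = {p: i for i, p in enumerate(PERIODS)}


class EthogramError(ValueError):
    """Raised for invalid observation data (unknown codes, missing slots, ...)."""


@dataclass(frozen=True)
class ObservationSession:
    """One dam's 25-slot scan-sample sequence for a single (PPD, period).

    Parameters
    ----------
    dam_id : str
        Subject identifier.
    group : str
        Housing condition, ``"CTRL"`` or ``"LBN"``.
    ppd : int
        Postpartum day, 2..9 (day of birth is PPD 0).
    period : str
        Observation period: ``"AM"``, ``"PM"`` (light phase) or ``"DARK"``.
    codes : tuple of str
        The 25 scored behavior codes, slot 0 first (3-min spacing).
    aux : tuple of frozenset of str
        Optional per-slot auxiliary event annotations (25 sets, may be empty).
    """

    dam_id: str
    group: str
    ppd: int
    period: str
    codes: tuple[str, ...]
    aux: tuple[frozenset[str], ...] = ()

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise EthogramError(f"unknown group {self.group!r} for dam {self.dam_id!r}")
        if self.period not in PERIODS:
            raise EthogramError(f"unknown period {self.period!r} for dam {self.dam_id!r}")
        if not isinstance(self.ppd, int) or not (PPD_MIN <= self.ppd <= PPD_MAX):
            raise EthogramError(
                f"ppd must be an integer in [{PPD_MIN}, {PPD_MAX}], got {self.ppd!r}"
            )
        if len(self.codes) != SLOTS_PER_PERIOD:
            raise EthogramError(
                f"session ({self.dam_id}, ppd {self.ppd}, {self.period}) has "
                f"{len(self.codes)} slots, expected {SLOTS_PER_PERIOD}"
            )
        bad = [c for c in self.codes if c not in _CODE_SET]
        if bad:
            raise EthogramError(
                f"unknown behavior code(s) {sorted(set(bad))} in session "
                f"({self.dam_id}, ppd {self.ppd}, {self.period})"
            )
        if self.aux:
            if len(self.aux) != SLOTS_PER_PERIOD:
                raise EthogramError(
                    f"aux annotations for ({self.dam_id}, ppd {self.ppd}, "
                    f"{self.period}) must cover all {SLOTS_PER_PERIOD} slots"
                )
            for slot, events in enumerate(self.aux):
                bad_aux = [e for e in events if e not in _AUX_SET]
                if bad_aux:
                    raise EthogramError(
                        f"unknown auxiliary event(s) {sorted(bad_aux)} at slot {slot} "
                        f"of ({self.dam_id}, ppd {self.ppd}, {self.period})"
                    )

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.dam_id, self.ppd, self.period)

    def aux_at(self, slot: int) -> frozenset[str]:
        return self.aux[slot] if self.aux else frozenset()


@dataclass
class Dataset:
    """A collection of observation sessions sharing one ethogram.

    Invariants enforced at construction: (dam_id, ppd, period) keys are
    unique, and every dam belongs to exactly one housing group.
    """

    sessions: list[ObservationSession]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[tuple[str, int, str], ObservationSession] = {}
        groups: dict[str, str] = {}
        for s in self.sessions:
            if s.key in seen:
                raise EthogramError(
                    f"duplicate session for dam {s.dam_id!r}, ppd {s.ppd}, "
                    f"period {s.period}"
                )
            seen[s.key] = s
            prev = groups.setdefault(s.dam_id, s.group)
            if prev != s.group:
                raise EthogramError(
                    f"dam {s.dam_id!r} appears under two groups ({prev} and {s.group})"
                )
        self._by_key = seen
        self._groups = groups

    def __len__(self) -> int:
        return len(self.sessions)

    def __iter__(self) -> Iterator[ObservationSession]:
        return iter(self.sessions)

    @property
    def dam_groups(self) -> Mapping[str, str]:
        """Mapping dam_id -> group."""
        return dict(self._groups)

    def dam_ids(self, group: str | None = None) -> list[str]:
        """Sorted dam identifiers, optionally restricted to one group."""
        return sorted(
            d for d, g in self._groups.items() if group is None or g == group
        )

    def ppds(self) -> list[int]:
        """Sorted postpartum days present in the dataset."""
        return sorted({s.ppd for s in self.sessions})

    def session(self, dam_id: str, ppd: int, period: str) -> ObservationSession:
        try:
            return self._by_key[(dam_id, ppd, period)]
        except KeyError:
            raise EthogramError(
                f"no session for dam {dam_id!r}, ppd {ppd}, period {period}"
            ) from None

    def has_session(self, dam_id: str, ppd: int, period: str) -> bool:
        return (dam_id, ppd, period) in self._by_key


def _canonical_order(sessions: Iterable[ObservationSession]):
    return sorted(
        sessions, key=lambda s: (s.group, s.dam_id, s.ppd, _PERIOD_ORDER[s.period])
    )


def read_observations(path: str | Path) -> Dataset:
    """Read a long-format observation CSV into a validated :class:`Dataset`.

    The file must carry the exact header ``dam_id,group,ppd,period,slot,code,aux``
    with one row per scan sample; ``aux`` is a semicolon-joined list of
    auxiliary events (may be empty).  Rows belonging to one
    (dam, ppd, period) must cover slots 0..24 exactly once.

    Raises
    ------
    EthogramError
        On a missing/duplicate slot, unknown symbol, or a dam appearing under
        two groups; the message names the offending (dam, ppd, period, slot).
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = tuple(next(reader))
        except StopIteration:
            raise EthogramError(f"{path}: empty file, expected header "
                                f"{','.join(CSV_HEADER)}") from None
        if header != CSV_HEADER:
            raise EthogramError(
                f"{path}: bad header {','.join(header)!r}, "
                f"expected {','.join(CSV_HEADER)!r}"
            )
        cells: dict[tuple[str, int, str], dict[int, tuple[str, frozenset[str]]]] = {}
        session_group: dict[tuple[str, int, str], str] = {}
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_HEADER):
                raise EthogramError(f"{path}:{lineno}: expected "
                                    f"{len(CSV_HEADER)} fields, got {len(row)}")
            dam_id, group, ppd_s, period, slot_s, code, aux_s = row
            try:
                ppd = int(ppd_s)
                slot = int(slot_s)
            except ValueError:
                raise EthogramError(
                    f"{path}:{lineno}: non-integer ppd/slot for dam {dam_id!r}"
                ) from None
            if not (0 <= slot < SLOTS_PER_PERIOD):
                raise EthogramError(
                    f"{path}:{lineno}: slot {slot} out of range 0..{SLOTS_PER_PERIOD - 1} "
                    f"for dam {dam_id!r}, ppd {ppd}, period {period}"
                )
            if code not in _CODE_SET:
                raise EthogramError(
                    f"{path}:{lineno}: unknown code {code!r} for dam {dam_id!r}, "
                    f"ppd {ppd}, period {period}, slot {slot}"
                )
            aux = frozenset(a for a in aux_s.split(";") if a)
            key = (dam_id, ppd, period)
            slots = cells.setdefault(key, {})
            if slot in slots:
                raise EthogramError(
                    f"{path}:{lineno}: duplicate slot {slot} for dam {dam_id!r}, "
                    f"ppd {ppd}, period {period}"
                )
            slots[slot] = (code, aux)
            session_group[key] = group

        sessions = []
        for key in cells:
            dam_id, ppd, period = key
            slots = cells[key]
            for want in range(SLOTS_PER_PERIOD):
                if want not in slots:
                    raise EthogramError(
                        f"{path}: missing slot {want} for dam {dam_id!r}, "
                        f"ppd {ppd}, period {period}"
                    )
            codes = tuple(slots[i][0] for i in range(SLOTS_PER_PERIOD))
            aux = tuple(slots[i][1] for i in range(SLOTS_PER_PERIOD))
            if not any(aux):
                aux = ()
            sessions.append(
                ObservationSession(
                    dam_id=dam_id,
                    group=session_group[key],
                    ppd=ppd,
                    period=period,
                    codes=codes,
                    aux=aux,
                )
            )
    return Dataset(sessions=_canonical_order(sessions), metadata={"source": str(path)})


def write_observations(dataset: Dataset, path: str | Path) -> None:
    """Write a :class:`Dataset` as a long CSV in canonical row order.

    Rows are sorted by (group, dam, ppd, period AM<PM<DARK, slot) so that
    writing the same dataset twice is byte-identical.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(CSV_HEADER)
        for s in _canonical_order(dataset.sessions):
            for slot, code in enumerate(s.codes):
                aux = ";".join(sorted(s.aux_at(slot)))
                writer.writerow([s.dam_id, s.group, s.ppd, s.period, slot, code, aux])
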