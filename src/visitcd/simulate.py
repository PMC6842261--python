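"""Synthetic EHR cohort generation with plantable visit-level signal.

Real pediatric-asthma EHR extracts are access-restricted, so experiments run
on synthetic cohorts that emulate their shape: ~10 visits per patient, ~2
codes per visit, a Zipf-like background code distribution, and a planted
class-discriminative visit pattern of controllable strength. A separate
injector adds the artificial validation visit (a single code outside the real
vocabulary) used to create a known ground-truth attribution target.

Synthetic codes are zero-padded integers ("000", "001", ...), which are fixed
points of code truncation at both granularities.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ehr import PatientRecord, Visit

__all__ = [
    "PlantedSignal",
    "CohortConfig",
    "ArtificialVisitConfig",
    "code_name",
    "generate_cohort",
    "inject_artificial_visit",
    "ARTIFICIAL_CODE",
]

#: Diagnosis code carried by the injected artificial visit; deliberately not a
#: zero-padded integer so it can never collide with the synthetic vocabulary.
ARTIFICIAL_CODE = "ART"


def code_name(i: int) -> str:
    return f"{i:03d}"


@dataclass(frozen=True)
class PlantedSignal:
    """A class-discriminative visit pattern planted into generated records.

    ``signal_codes`` (vocabulary indices) are written into ``n_signal_visits``
    consecutive visits at ``carrier_position``; cases receive the pattern with
    probability ``penetrance_case``, controls with ``penetrance_control``.
    """

    signal_codes: tuple[int, ...]
    carrier_position: str = "random"  # random | late | early
    penetrance_case: float = 1.0
    penetrance_control: float = 0.0
    n_signal_visits: int = 1

    def __post_init__(self) -> None:
        if not 0.0 <= self.penetrance_control <= self.penetrance_case <= 1.0:
            raise ValueError("require 0 <= penetrance_control <= penetrance_case <= 1")
        if self.carrier_position not in ("random", "late", "early"):
            raise ValueError(f"bad carrier_position {self.carrier_position!r}")
        if self.n_signal_visits < 1 or self.n_signal_visits > len(self.signal_codes):
            raise ValueError("need 1 <= n_signal_visits <= len(signal_codes)")


@dataclass(frozen=True)
class CohortConfig:
    n_patients: int = 2000
    vocab_size: int = 100
    visit_count_range: tuple[int, int] = (5, 12)
    codes_per_visit_range: tuple[int, int] = (1, 3)
    background_zipf: float = 1.0
    case_fraction: float = 0.5
    signal: PlantedSignal = field(
        default_factory=lambda: PlantedSignal(signal_codes=(97, 98, 99),
                                              penetrance_case=0.75,
                                              penetrance_control=0.25)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.visit_count_range, self.codes_per_visit_range):
            if lo > hi or lo < 1:
                raise ValueError("ranges must satisfy 1 <= min <= max")
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError("case_fraction must be in (0, 1)")
        if self.vocab_size < self.codes_per_visit_range[1]:
            raise ValueError("vocabulary smaller than max codes per visit")
        if self.signal.signal_codes and max(self.signal.signal_codes) >= self.vocab_size:
            raise ValueError("signal codes outside the vocabulary")


@dataclass(frozen=True)
class ArtificialVisitConfig:
    """Injection rule for the validation visit: cases receive it with
    probability ``p_art``, controls with ``1 - p_art``."""

    p_art: float = 1.0
    position: str = "random"  # random | append
    seed: int = 0
    code: str = ARTIFICIAL_CODE

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_art <= 1.0:
            raise ValueError("p_art must be in [0, 1]")
        if self.position not in ("random", "append"):
            raise ValueError(f"bad position {self.position!r}")


def _zipf_probs(vocab_size: int, exponent: float) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=np.float64)
    p = ranks ** (-exponent)
    return p / p.sum()


def _signal_visit_codes(signal: PlantedSignal) -> list[frozenset[str]]:
    # split the signal codes across the block's visits, in index order
    chunks = np.array_split(np.asarray(signal.signal_codes), signal.n_signal_visits)
    return [frozenset(code_name(int(i)) for i in chunk) for chunk in chunks]


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Sample a labeled cohort; deterministic given ``config.seed``.

    Each patient draws a visit count uniformly from ``visit_count_range``,
    strictly increasing ages, and per-visit background codes without
    within-visit repeats from a Zipf(``background_zipf``) distribution. A
    patient is a case with probability ``case_fraction``; signal carriers have
    the codes of ``n_signal_visits`` consecutive visits replaced by the
    planted signal codes.
    """
    rng = np.random.default_rng(config.seed)
    probs = _zipf_probs(config.vocab_size, config.background_zipf)
    vmin, vmax = config.visit_count_range
    cmin, cmax = config.codes_per_visit_range
    signal = config.signal
    block = _signal_visit_codes(signal)
    records: list[PatientRecord] = []
    for n in range(config.n_patients):
        is_case = rng.random() < config.case_fraction
        n_visits = int(rng.integers(vmin, vmax + 1))
        start = rng.uniform(0.0, 2.0)
        ages = start + np.cumsum(rng.uniform(0.2, 1.0, size=n_visits))
        visits_codes: list[frozenset[str]] = []
        for _ in range(n_visits):
            k = int(rng.integers(cmin, cmax + 1))
            chosen = rng.choice(config.vocab_size, size=k, replace=False, p=probs)
            visits_codes.append(frozenset(code_name(int(i)) for i in chosen))
        penetrance = signal.penetrance_case if is_case else signal.penetrance_control
        if signal.signal_codes and rng.random() < penetrance:
            nb = min(signal.n_signal_visits, n_visits)
            if signal.carrier_position == "early":
                pos = 0
            elif signal.carrier_position == "late":
                pos = n_visits - nb
            else:
                pos = int(rng.integers(0, n_visits - nb + 1))
            for off in range(nb):
                visits_codes[pos + off] = block[off]
        visits = [
            Visit(ordinal=t + 1, age_years=float(ages[t]), codes=visits_codes[t])
            for t in range(n_visits)
        ]
        records.append(
            PatientRecord(
                patient_id=f"S{n:06d}",
                visits=visits,
                label="case" if is_case else "control",
            )
        )
    return records


def inject_artificial_visit(
    records: Sequence[PatientRecord], cfg: ArtificialVisitConfig
) -> list[PatientRecord]:
    """Insert the artificial visit per the injection rule; existing visits are
    never altered, and each touched record is annotated with the insertion
    ordinal. Returns new records (inputs left untouched)."""
    rng = np.random.default_rng(cfg.seed)
    out: list[PatientRecord] = []
    for record in records:
        if record.label == "case":
            p_insert = cfg.p_art
        elif record.label == "control":
            p_insert = 1.0 - cfg.p_art
        else:
            raise ValueError(f"patient {record.patient_id} is unlabeled")
        if rng.random() >= p_insert:
            out.append(dataclasses.replace(record, artificial_ordinal=None))
            continue
        visits = list(record.visits)
        t = len(visits)
        if cfg.position == "append":
            k = t
        else:
            k = int(rng.integers(0, t + 1))
        if k == 0:
            age = max(0.0, visits[0].age_years - 0.25)
        elif k == t:
            age = visits[-1].age_years + 0.5
        else:
            age = 0.5 * (visits[k - 1].age_years + visits[k].age_years)
        new_visit = Visit(ordinal=k + 1, age_years=age, codes=frozenset({cfg.code}))
        rebuilt = (
            visits[:k]
            + [new_visit]
            + [Visit(ordinal=v.ordinal + 1, age_years=v.age_years, codes=v.codes)
               for v in visits[k:]]
        )
        out.append(
            dataclasses.replace(record, visits=rebuilt, artificial_ordinal=k + 1)
        )
    return out
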