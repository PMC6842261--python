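"""Domain model and I/O for longitudinal diagnosis-code records.

A patient record is an age-ordered list of visits, each carrying a set of
ICD-9-style diagnosis codes. Records are serialized as JSON Lines (one
patient per line) and encoded for modelling as multi-hot binary matrices,
one row per visit, over a fixed code vocabulary.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from enum import IntEnum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "CodeLevel",
    "truncate_code",
    "Visit",
    "PatientRecord",
    "CodeVocabulary",
    "EncodedSequence",
    "CohortSplit",
    "load_cohort",
    "save_cohort",
    "build_vocabulary",
    "encode_patient",
    "pad_batch",
    "label_asthma_outcome",
    "stratified_split",
]

LABELS = ("case", "control", "unlabeled")


class CodeLevel(IntEnum):
    """Granularity of ICD-9-style codes: 3-digit category or 4-digit subcategory."""

    THREE_DIGIT = 3
    FOUR_DIGIT = 4


def truncate_code(code: str, level: CodeLevel = CodeLevel.FOUR_DIGIT) -> str:
    """Truncate a diagnosis code to the requested granularity.

    3-digit keeps the first three characters of the category part before any
    dot suffix ("493.91" -> "493", "V20.2" -> "V20"); 4-digit keeps one
    character after the dot ("493.91" -> "493.9"). Idempotent at both levels.
    """
    head, dot, tail = code.partition(".")
    head = head[:3]
    if level == CodeLevel.THREE_DIGIT or not dot or not tail:
        return head
    return f"{head}.{tail[:1]}"


@dataclass(frozen=True)
class Visit:
    """One clinical encounter: ordinal position, patient age, and a code set."""

    ordinal: int
    age_years: float
    codes: frozenset[str]

    def __post_init__(self) -> None:
        if self.ordinal < 1:
            raise ValueError(f"visit ordinal must be >= 1, got {self.ordinal}")
        if self.age_years < 0:
            raise ValueError(f"age_years must be non-negative, got {self.age_years}")
        if not self.codes:
            raise ValueError("a visit must carry at least one diagnosis code")
        object.__setattr__(self, "codes", frozenset(self.codes))


@dataclass
class PatientRecord:
    """Age-ordered visit sequence with an outcome label.

    ``artificial_ordinal`` records where a synthetic validation visit was
    inserted (None when the record is untouched).
    """

    patient_id: str
    visits: list[Visit]
    label: str = "unlabeled"
    artificial_ordinal: int | None = None

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")
        if not self.visits:
            raise ValueError(f"patient {self.patient_id}: no visits")
        ages = [v.age_years for v in self.visits]
        if any(a > b for a, b in zip(ages, ages[1:])):
            raise ValueError(f"patient {self.patient_id}: ages not non-decreasing")
        ordinals = [v.ordinal for v in self.visits]
        if ordinals != list(range(1, len(self.visits) + 1)):
            raise ValueError(f"patient {self.patient_id}: ordinals not 1..T consecutive")

    @property
    def n_visits(self) -> int:
        return len(self.visits)


@dataclass(frozen=True)
class CodeVocabulary:
    """Bijection between diagnosis codes (at a fixed level) and 0-based indices."""

    codes: tuple[str, ...]
    level: CodeLevel = CodeLevel.FOUR_DIGIT
    index: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("vocabulary codes must be unique")
        object.__setattr__(self, "index", {c: i for i, c in enumerate(self.codes)})

    def __len__(self) -> int:
        return len(self.codes)

    def __contains__(self, code: str) -> bool:
        return truncate_code(code, self.level) in self.index

    def save(self, path: str) -> None:
        with open(path, "w") as fh:
            for code in self.codes:
                fh.write(code + "\n")

    @classmethod
    def load(cls, path: str, level: CodeLevel = CodeLevel.FOUR_DIGIT) -> "CodeVocabulary":
        with open(path) as fh:
            codes = tuple(line.strip() for line in fh if line.strip())
        return cls(codes=codes, level=level)


@dataclass
class EncodedSequence:
    """T x |D| multi-hot matrix for one patient; row t marks the codes of visit t."""

    matrix: np.ndarray
    true_length: int
    patient_id: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        if self.matrix.ndim != 2:
            raise ValueError("encoded matrix must be 2-D (visits x codes)")
        if not 1 <= self.true_length <= self.matrix.shape[0]:
            raise ValueError("true_length out of range")


@dataclass
class CohortSplit:
    """Disjoint train/validation/test partition of a labeled cohort."""

    train: list[PatientRecord]
    validation: list[PatientRecord]
    test: list[PatientRecord]
    seed: int

    def __iter__(self):
        yield from (self.train, self.validation, self.test)


# ---------------------------------------------------------------------------
# serialization

def _record_to_obj(record: PatientRecord) -> dict:
    obj = {
        "patient_id": record.patient_id,
        "label": record.label,
        "visits": [
            {"age_years": v.age_years, "codes": sorted(v.codes)} for v in record.visits
        ],
    }
    if record.artificial_ordinal is not None:
        obj["artificial_ordinal"] = record.artificial_ordinal
    return obj


def save_cohort(records: Iterable[PatientRecord], path: str) -> None:
    """Write a cohort as JSON Lines, one patient object per line, visits in time order."""
    with open(path, "w") as fh:
        for record in records:
            fh.write(json.dumps(_record_to_obj(record), sort_keys=True) + "\n")


def load_cohort(path: str) -> list[PatientRecord]:
    """Read a JSON Lines cohort file; inverse of :func:`save_cohort`.

    Visits are re-sorted by age if the file is out of order. Malformed lines
    raise ``ValueError`` naming the 1-based line number.
    """
    records: list[PatientRecord] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"line {lineno}: malformed JSON ({exc.msg})") from exc
            try:
                raw_visits = obj["visits"]
                visits_in = sorted(raw_visits, key=lambda v: v["age_years"])
                visits = [
                    Visit(ordinal=i + 1, age_years=float(v["age_years"]),
                          codes=frozenset(v["codes"]))
                    for i, v in enumerate(visits_in)
                ]
                records.append(
                    PatientRecord(
                        patient_id=str(obj["patient_id"]),
                        visits=visits,
                        label=obj.get("label", "unlabeled"),
                        artificial_ordinal=obj.get("artificial_ordinal"),
                    )
                )
            except (KeyError, TypeError, ValueError) as exc:
                raise ValueError(f"line {lineno}: invalid record ({exc})") from exc
    return records


# ---------------------------------------------------------------------------
# encoding

def build_vocabulary(
    records: Sequence[PatientRecord], level: CodeLevel = CodeLevel.FOUR_DIGIT
) -> CodeVocabulary:
    """Collect the distinct codes of a cohort at ``level``, sorted lexicographically."""
    if not any(r.visits for r in records):
        raise ValueError("cannot build a vocabulary from an empty cohort")
    codes = {truncate_code(c, level) for r in records for v in r.visits for c in v.codes}
    return CodeVocabulary(codes=tuple(sorted(codes)), level=level)


def encode_patient(record: PatientRecord, vocab: CodeVocabulary) -> EncodedSequence:
    """Multi-hot encode a record against ``vocab`` (codes truncated to the vocab level)."""
    matrix = np.zeros((record.n_visits, len(vocab)), dtype=np.float64)
    for t, visit in enumerate(record.visits):
        for code in visit.codes:
            key = truncate_code(code, vocab.level)
            if key not in vocab.index:
                raise KeyError(
                    f"patient {record.patient_id}, visit {visit.ordinal}: "
                    f"code {code!r} (as {key!r}) not in vocabulary"
                )
            matrix[t, vocab.index[key]] = 1.0
    return EncodedSequence(matrix=matrix, true_length=record.n_visits,
                           patient_id=record.patient_id)


def pad_batch(sequences: Sequence[EncodedSequence]) -> tuple[np.ndarray, np.ndarray]:
    """Stack sequences into an N x T_max x |D| array with zero rows appended
    after the real visits (post-padding); returns the batch and true lengths."""
    if not sequences:
        raise ValueError("empty batch")
    dims = {s.matrix.shape[1] for s in sequences}
    if len(dims) > 1:
        raise ValueError(f"sequences encoded against different vocabularies: {sorted(dims)}")
    d = dims.pop()
    lengths = np.array([s.true_length for s in sequences], dtype=np.int64)
    t_max = int(lengths.max())
    batch = np.zeros((len(sequences), t_max, d), dtype=np.float64)
    for n, s in enumerate(sequences):
        batch[n, : s.true_length] = s.matrix[: s.true_length]
    return batch, lengths


# ---------------------------------------------------------------------------
# cohort labeling and splitting

def _has(visit: Visit, prefix3: str, exclude4: str | None = None) -> bool:
    for code in visit.codes:
        if truncate_code(code, CodeLevel.THREE_DIGIT) == prefix3:
            if exclude4 is not None and truncate_code(code, CodeLevel.FOUR_DIGIT) == exclude4:
                continue
            return True
    return False


def label_asthma_outcome(record: PatientRecord) -> str:
    """Classify a record as school-age-asthma ``case``/``control``/``excluded``.

    Inclusion requires at least one respiratory-symptom visit (786*, excluding
    786.3 hemoptysis) before age 5 and more than two visits before age 5.
    A case additionally has an asthma code (493*) after age 6; a control has no
    493* code in the (6, 9) age window and is observed to at least age 9.
    Strict inequalities throughout; ages in real-valued years.
    """
    before5 = [v for v in record.visits if v.age_years < 5.0]
    has_symptom = any(_has(v, "786", exclude4="786.3") for v in before5)
    if not has_symptom or len(before5) <= 2:
        return "excluded"
    if any(v.age_years > 6.0 and _has(v, "493") for v in record.visits):
        return "case"
    no_asthma_window = not any(
        6.0 < v.age_years < 9.0 and _has(v, "493") for v in record.visits
    )
    observed_to_9 = record.visits[-1].age_years >= 9.0
    if no_asthma_window and observed_to_9:
        return "control"
    return "excluded"


def _allocate(n: int, fractions: Sequence[float]) -> tuple[int, int, int]:
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    n_train = min(n_train, n)
    n_val = min(n_val, n - n_train)
    return n_train, n_val, n - n_train - n_val


def stratified_split(
    records: Sequence[PatientRecord],
    fractions: tuple[float, float, float] = (0.55, 0.15, 0.30),
    seed: int = 0,
) -> CohortSplit:
    """Shuffle each class with ``seed`` and allocate per-class proportions,
    preserving the cohort's case/control mix in every part."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    bad = [r.patient_id for r in records if r.label not in ("case", "control")]
    if bad:
        raise ValueError(f"unlabeled records in split input: {bad[:5]}")
    rng = np.random.default_rng(seed)
    parts: tuple[list[PatientRecord], ...] = ([], [], [])
    for label in ("case", "control"):
        group = [r for r in records if r.label == label]
        order = rng.permutation(len(group))
        group = [group[i] for i in order]
        n_train, n_val, _ = _allocate(len(group), fractions)
        parts[0].extend(group[:n_train])
        parts[1].extend(group[n_train : n_train + n_val])
        parts[2].extend(group[n_train + n_val :])
    return CohortSplit(train=parts[0], validation=parts[1], test=parts[2], seed=seed)
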