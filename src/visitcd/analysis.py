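"""Experiment layer: subset-of-visits search, artificial-visit validation,
logistic-regression ground truth, CD/LR matching, and pattern mining.

These procedures turn raw CD scores into the quantities one actually reports:
which contiguous window of visits carries the prediction, whether CD finds a
visit that is known (by construction) to carry all the label information, how
often the top CD visit agrees with an odds-ratio-based importance ranking,
and which visit patterns most often carry a model's positive evidence.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cd import VisitSubset, decompose, visit_attributions
from .ehr import (
    CodeLevel,
    CodeVocabulary,
    PatientRecord,
    build_vocabulary,
    encode_patient,
    stratified_split,
    truncate_code,
)
from .model import BiLSTMModel, TrainConfig, predict_case_probability, train
from .simulate import ArtificialVisitConfig, CohortConfig, generate_cohort, inject_artificial_visit

__all__ = [
    "WindowSpec",
    "SubsetSearchResult",
    "CodeImportance",
    "GroundTruthTopVisits",
    "PatternTable",
    "SeparationError",
    "find_predictive_subset",
    "count_windows",
    "artificial_visit_experiment",
    "lr_code_importance",
    "ground_truth_top_visits",
    "cd_lr_matching_accuracy",
    "mine_top_patterns",
]


# ---------------------------------------------------------------------------
# most predictive subset of visits (exhaustive sliding-window search)

@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window grid: every width in ``window_sizes``, stride ``step``."""

    window_sizes: tuple[int, ...]
    step: int = 1

    def __post_init__(self) -> None:
        if not self.window_sizes or min(self.window_sizes) < 1 or self.step < 1:
            raise ValueError("window sizes and step must be >= 1")

    @classmethod
    def default(cls, true_length: int) -> "WindowSpec":
        return cls(window_sizes=tuple(range(1, min(5, true_length) + 1)), step=1)


@dataclass
class SubsetSearchResult:
    candidates: list[tuple[int, int, float]]  # (start ordinal, width, score)
    best: VisitSubset
    best_score: float
    best_start: int
    best_width: int


def count_windows(true_length: int, spec: WindowSpec) -> int:
    """Closed-form candidate count: sum over admissible w of floor((T-w)/s)+1."""
    return sum(
        (true_length - w) // spec.step + 1
        for w in spec.window_sizes
        if w <= true_length
    )


def find_predictive_subset(
    model: BiLSTMModel,
    seq,
    spec: WindowSpec | None = None,
    class_index: int = 1,
) -> SubsetSearchResult:
    """Exhaustively score every contiguous window and return the argmax.

    Windows of width w start at ordinals 1, 1+s, 1+2s, ... while they fit in
    the true sequence; each is scored by the CD relevant score of the window
    as the subset S. Ties break toward the smaller width, then earlier start.
    """
    t_len = seq.true_length
    if spec is None:
        spec = WindowSpec.default(t_len)
    if all(w > t_len for w in spec.window_sizes):
        raise ValueError(f"no window size in {spec.window_sizes} fits T={t_len}")
    candidates: list[tuple[int, int, float]] = []
    for w in spec.window_sizes:
        if w > t_len:
            continue
        for start in range(1, t_len - w + 2, spec.step):
            subset = VisitSubset.of(range(start, start + w))
            score = decompose(model, seq, subset, class_index).score_relevant
            candidates.append((start, w, score))
    best_start, best_width, best_score = min(
        candidates, key=lambda c: (-c[2], c[1], c[0])
    )
    return SubsetSearchResult(
        candidates=candidates,
        best=VisitSubset.of(range(best_start, best_start + best_width)),
        best_score=best_score,
        best_start=best_start,
        best_width=best_width,
    )


# ---------------------------------------------------------------------------
# artificial-visit validation experiment

def _cell_metrics(
    model: BiLSTMModel, test: Sequence[PatientRecord]
) -> tuple[float, float, int]:
    """Attribution and class-1 prediction accuracy over test cases bearing the
    artificial visit. A case counts as correctly attributed only if it is also
    predicted class 1, so attribution accuracy can never exceed the class-1
    prediction accuracy (the upper-bound curve)."""
    bearers = [r for r in test if r.label == "case" and r.artificial_ordinal is not None]
    if not bearers:
        raise ValueError("no test cases contain the artificial visit")
    probs = predict_case_probability(model, bearers)
    hits = 0
    predicted_1 = 0
    for record, p in zip(bearers, probs):
        if p <= 0.5:
            continue
        predicted_1 += 1
        seq = encode_patient(record, model.vocab)
        scores = visit_attributions(model, seq)
        if int(np.argmax(scores)) + 1 == record.artificial_ordinal:
            hits += 1
    return hits / len(bearers), predicted_1 / len(bearers), len(bearers)


def artificial_visit_experiment(
    p_art_grid: Sequence[float] = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5),
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    cohort_config: CohortConfig = CohortConfig(),
    model_kinds: Sequence[str] = ("lstm", "bilstm"),
    train_config: TrainConfig = TrainConfig(),
    position: str = "random",
) -> pd.DataFrame:
    """Run the train-then-decompose validation grid.

    For every (p_art, seed): generate a cohort, inject the artificial visit
    (into cases with probability p_art, controls with 1-p_art), split
    55/15/30 stratified, train each model kind, and measure attribution and
    class-1 prediction accuracy on the test cases bearing the artificial
    visit. Returns one row per (p_art, model, seed); aggregate over seeds
    with a groupby mean.
    """
    rows = []
    for p_art in p_art_grid:
        for seed in seeds:
            base = (seed * 10007 + int(round(p_art * 10)) * 101) % (2**31 - 1)
            cohort = generate_cohort(dataclasses.replace(cohort_config, seed=base))
            injected = inject_artificial_visit(
                cohort, ArtificialVisitConfig(p_art=p_art, position=position, seed=base + 1)
            )
            vocab = build_vocabulary(injected, CodeLevel.FOUR_DIGIT)
            split = stratified_split(injected, seed=base + 2)
            for kind in model_kinds:
                model = train(
                    split, vocab,
                    dataclasses.replace(train_config, seed=base + 3),
                    direction=kind,
                )
                attr_acc, pred_acc, n_eligible = _cell_metrics(model, split.test)
                rows.append(
                    {
                        "p_art": p_art,
                        "model": kind,
                        "seed": seed,
                        "attribution_accuracy": attr_acc,
                        "class1_prediction_accuracy": pred_acc,
                        "n_eligible": n_eligible,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# logistic-regression ground truth

class SeparationError(RuntimeError):
    """Raised when the logistic fit is non-identifiable (separated codes)."""

    def __init__(self, codes: list[str], message: str):
        super().__init__(f"{message}: {codes}")
        self.codes = codes


@dataclass(frozen=True)
class CodeImportance:
    code: str
    coefficient: float
    p_value: float
    odds_ratio: float
    group: int | None  # 1 (highest odds ratios) .. 4, None if filtered out
    score: int  # 4 .. 1, or 0 if filtered out


def lr_code_importance(
    records: Sequence[PatientRecord],
    vocab: CodeVocabulary | None = None,
    alpha: float = 0.05,
    aggregate: str = "presence",
) -> list[CodeImportance]:
    """Odds-ratio importance scores from a logistic fit on code aggregates.

    Fits outcome ~ per-patient code aggregates (binary presence by default,
    occurrence counts with ``aggregate="count"``), keeps codes with two-sided
    Wald p <= ``alpha`` and odds ratio > 1, sorts them by odds ratio
    descending, splits the sorted list into 4 contiguous groups (any
    remainder goes to the top groups), and assigns scores 4..1 from the
    highest-odds-ratio group down. All other codes score 0.
    """
    if aggregate not in ("presence", "count"):
        raise ValueError(f"aggregate must be 'presence' or 'count', got {aggregate!r}")
    if vocab is None:
        vocab = build_vocabulary(records, CodeLevel.FOUR_DIGIT)
    y = np.array([1 if r.label == "case" else 0 for r in records], dtype=np.float64)
    if len(np.unique(y)) < 2:
        raise ValueError("cohort contains a single class")
    x = np.zeros((len(records), len(vocab)))
    for n, r in enumerate(records):
        matrix = encode_patient(r, vocab).matrix
        x[n] = matrix.sum(axis=0) if aggregate == "count" else matrix.max(axis=0)
    cols = np.flatnonzero(x.std(axis=0) > 0)  # drop constant (degenerate) columns
    design = sm.add_constant(x[:, cols], has_constant="add")
    fit = sm.Logit(y, design).fit(method="lbfgs", maxiter=500, disp=0)
    coefs = fit.params[1:]
    pvals = fit.pvalues[1:]
    suspect = [
        vocab.codes[cols[k]]
        for k in range(len(cols))
        if abs(coefs[k]) > 15.0
        and len(np.unique(y[x[:, cols[k]] > 0])) == 1
    ]
    if suspect or not fit.mle_retvals.get("converged", True):
        if not suspect:
            suspect = [vocab.codes[cols[k]] for k in np.argsort(-np.abs(coefs))[:5]]
        raise SeparationError(suspect, "logistic fit not identifiable (separation)")
    stats = {
        vocab.codes[cols[k]]: (float(coefs[k]), float(pvals[k]), float(np.exp(coefs[k])))
        for k in range(len(cols))
    }
    kept = sorted(
        (c for c, (_, p, orat) in stats.items() if p <= alpha and orat > 1.0),
        key=lambda c: (-stats[c][2], c),
    )
    n_kept = len(kept)
    sizes = [n_kept // 4 + (1 if g < n_kept % 4 else 0) for g in range(4)]
    group_of: dict[str, int] = {}
    pos = 0
    for g, size in enumerate(sizes, start=1):
        for c in kept[pos : pos + size]:
            group_of[c] = g
        pos += size
    out = []
    for code in vocab.codes:
        coef, p, orat = stats.get(code, (0.0, 1.0, 1.0))
        g = group_of.get(code)
        out.append(
            CodeImportance(
                code=code, coefficient=coef, p_value=p, odds_ratio=orat,
                group=g, score=(5 - g) if g is not None else 0,
            )
        )
    return out


@dataclass
class GroundTruthTopVisits:
    patient_id: str
    entries: list[tuple[int, float]]  # (visit ordinal, visit score), descending
    complete: bool  # False when the record has fewer than 3 visits


def _visit_scores(record: PatientRecord, score_of: dict[str, int], level: CodeLevel) -> list[float]:
    return [
        float(sum(score_of.get(truncate_code(c, level), 0) for c in v.codes))
        for v in record.visits
    ]


def ground_truth_top_visits(
    record: PatientRecord,
    importances: Sequence[CodeImportance],
    level: CodeLevel = CodeLevel.FOUR_DIGIT,
) -> GroundTruthTopVisits:
    """Rank visits by the summed importance scores of their codes; the top
    three are the ground-truth attribution. Ties favor the later visit."""
    score_of = {imp.code: imp.score for imp in importances}
    scores = _visit_scores(record, score_of, level)
    order = sorted(range(len(scores)), key=lambda t: (-scores[t], -t))
    top = order[:3]
    return GroundTruthTopVisits(
        patient_id=record.patient_id,
        entries=[(t + 1, scores[t]) for t in top],
        complete=len(scores) >= 3,
    )


def cd_lr_matching_accuracy(
    model: BiLSTMModel,
    records: Sequence[PatientRecord],
    importances: Sequence[CodeImportance],
    class_index: int = 1,
) -> tuple[float, float, float]:
    """Fraction of patients whose top-CD visit lies among the top-k
    ground-truth visits, for k = 1, 2, 3 (non-decreasing in k)."""
    hits = np.zeros(3)
    for record in records:
        seq = encode_patient(record, model.vocab)
        top_cd = int(np.argmax(visit_attributions(model, seq, class_index))) + 1
        gt = [o for o, _ in ground_truth_top_visits(record, importances,
                                                    model.vocab.level).entries]
        for k in range(3):
            if top_cd in gt[: k + 1]:
                hits[k] += 1
    acc = hits / len(records)
    return float(acc[0]), float(acc[1]), float(acc[2])


# ---------------------------------------------------------------------------
# top scoring patterns

@dataclass
class PatternTable:
    """Top visit patterns (code sets, or pairs of code sets for length 2)
    carrying each correctly-predicted case's maximal positive CD score."""

    length: int
    rows: list[tuple[tuple, int, float]]  # (pattern, count, percent)
    n_contributing: int

    def to_frame(self) -> pd.DataFrame:
        def fmt(p):
            if self.length == 1:
                return ",".join(p)
            return " -> ".join("[" + ",".join(v) + "]" for v in p)

        return pd.DataFrame(
            [(fmt(p), c, pct) for p, c, pct in self.rows],
            columns=["pattern", "count", "percent"],
        )


def mine_top_patterns(
    model: BiLSTMModel,
    records: Sequence[PatientRecord],
    length: int = 1,
    class_index: int = 1,
    top: int = 10,
) -> PatternTable:
    """Tally the visit pattern with the highest positive CD score per patient.

    Only patients with true class 1 that the model predicts as class 1
    contribute. For length 1 the pattern is the sorted code set of the
    top-scoring visit; for length 2 it is the ordered pair of code sets of the
    top-scoring consecutive visit pair (window 2, step 1). Patients whose best
    score is not positive contribute nothing.
    """
    if length not in (1, 2):
        raise ValueError("pattern length must be 1 or 2")
    cases = [r for r in records if r.label == "case"]
    if not cases:
        return PatternTable(length=length, rows=[], n_contributing=0)
    probs = predict_case_probability(model, cases)
    counts: dict[tuple, int] = {}
    contributing = 0
    for record, p in zip(cases, probs):
        if p <= 0.5:
            continue
        seq = encode_patient(record, model.vocab)
        t_len = seq.true_length
        if length == 1:
            scores = visit_attributions(model, seq, class_index)
            best_t = int(np.argmax(scores))
            if scores[best_t] <= 0:
                continue
            pattern: tuple = tuple(sorted(record.visits[best_t].codes))
        else:
            if t_len < 2:
                continue
            pair_scores = [
                decompose(model, seq, VisitSubset.of({t, t + 1}), class_index).score_relevant
                for t in range(1, t_len)
            ]
            best_t = int(np.argmax(pair_scores))
            if pair_scores[best_t] <= 0:
                continue
            pattern = (
                tuple(sorted(record.visits[best_t].codes)),
                tuple(sorted(record.visits[best_t + 1].codes)),
            )
        contributing += 1
        counts[pattern] = counts.get(pattern, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))[:top]
    rows = [
        (pattern, count, 100.0 * count / contributing) for pattern, count in ranked
    ]
    return PatternTable(length=length, rows=rows, n_contributing=contributing)
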