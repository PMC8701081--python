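"""Synthetic literature streams with planted ground truth.

Emulates the statistical structure the metric suite assumes: a fixed
lemma vocabulary, ``k_true`` topic-word distributions drawn from a sharp
symmetric Dirichlet, documents written as bags of lemmas from exactly one
topic, and per-topic publication volumes per weekly window that encode
three temporal archetypes:

* **emergency** — heavy early volume decaying over the period, so the
  response rate RRR = mass / (B * E) peaks in the first window;
* **persistent** — volume peaking in the second window with a slow
  decline, so RRR peaks in window 2;
* **fluctuating** — alternating high/low volume, producing large RRR
  swings.

The archetype shapes below were designed from the identity
RRR(w) ~ n_w / (B_w * ln n_w) (with B_w growing linearly in w) so that
the planted peak/decay structure survives Poisson count noise; they are
the package's fixed study conditions, not free dials.  Tokens are
synthetic lemma strings ("w0001", ...) that pass unchanged through the
lemmatizer; dates are uniform within their window.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from .corpus_io import DocumentRecord, StudyPeriod
from .rpm import WindowPartition, mann_kendall

__all__ = [
    "SyntheticSpec",
    "GroundTruth",
    "WorkedExample",
    "default_period",
    "make_docs_per_window",
    "generate_corpus",
    "worked_example_fixture",
]

# Expected documents per window (10 weekly windows) for each archetype.
PROFILE_SHAPES: dict[str, tuple[float, ...]] = {
    "emergency": (110, 101, 93, 86, 80, 75, 71, 68, 65, 63),
    "persistent": (70, 130, 115, 105, 98, 92, 87, 83, 79, 76),
    "fluctuating": (130, 45, 130, 45, 130, 45, 130, 45, 130, 45),
}

_OUTBREAK = date(2019, 12, 12)
_STUDY_START = date(2020, 1, 24)  # 43 days after the outbreak anchor


def default_period(n_windows: int = 10, w_days: int = 7) -> StudyPeriod:
    """Study period of ``n_windows`` full windows starting 2020-01-24."""
    return StudyPeriod(
        start_date=_STUDY_START,
        end_date=_STUDY_START + timedelta(days=n_windows * w_days - 1),
        outbreak_start=_OUTBREAK,
    )


def make_docs_per_window(
    profiles: tuple[str, ...] | list[str],
    n_windows: int = 10,
    scale: float = 1.0,
) -> np.ndarray:
    """Expected-count matrix (k x n_windows) from archetype shapes.

    Shapes are defined on a 10-window grid and linearly interpolated to
    other window counts (the fluctuating archetype keeps strict
    alternation instead of interpolating).
    """
    rows = []
    for prof in profiles:
        if prof not in PROFILE_SHAPES:
            raise ValueError(f"unknown profile: {prof!r}")
        shape = np.asarray(PROFILE_SHAPES[prof], dtype=float)
        if n_windows == len(shape):
            row = shape
        elif prof == "fluctuating":
            row = np.where(np.arange(n_windows) % 2 == 0, shape[0], shape[1])
        else:
            row = np.interp(
                np.linspace(0, 1, n_windows), np.linspace(0, 1, len(shape)), shape
            )
        rows.append(row * scale)
    return np.vstack(rows)


@dataclass
class SyntheticSpec:
    """Study conditions for one synthetic corpus."""

    k_true: int = 6
    vocab_size: int = 200
    topic_sharpness: float = 0.04  # symmetric Dirichlet concentration
    doc_length: float = 40.0  # mean lemmas per abstract (Poisson, floor 5)
    profiles: tuple[str, ...] | None = ("emergency", "emergency", "persistent",
                                        "persistent", "fluctuating", "fluctuating")
    docs_per_window: np.ndarray | None = None  # k x n_windows expected counts
    n_windows: int = 10
    w_days: int = 7
    period: StudyPeriod | None = None
    seed: int = 0

    def resolve(self) -> tuple[np.ndarray, StudyPeriod]:
        if self.k_true < 2:
            raise ValueError("k_true must be >= 2")
        period = self.period or default_period(self.n_windows, self.w_days)
        if self.docs_per_window is not None:
            counts = np.asarray(self.docs_per_window, dtype=float)
        elif self.profiles is not None:
            if len(self.profiles) != self.k_true:
                raise ValueError("profiles length must equal k_true")
            counts = make_docs_per_window(self.profiles, self.n_windows)
        else:
            counts = np.full((self.k_true, self.n_windows), 10.0)
        if counts.shape != (self.k_true, self.n_windows):
            raise ValueError("docs_per_window must be k_true x n_windows")
        if (counts < 0).any():
            raise ValueError("docs_per_window must be non-negative")
        if (counts.sum(axis=1) <= 0).any():
            raise ValueError("every topic needs at least one expected document")
        return counts, period


@dataclass
class GroundTruth:
    """Planted structure of a generated corpus."""

    topic_of: dict[str, int]
    profiles: tuple[str, ...] | None
    expected_counts: np.ndarray
    rec_trends: tuple[str, ...]
    topic_word: np.ndarray
    period: StudyPeriod
    w_days: int
    n_windows: int

    def assignments(self) -> dict[int, set[str]]:
        k = self.expected_counts.shape[0]
        out: dict[int, set[str]] = {t: set() for t in range(k)}
        for d, t in self.topic_of.items():
            out[t].add(d)
        return out

    def uniform_probabilities(self) -> pd.DataFrame:
        """Ground-truth membership probabilities: uniform over each topic's docs."""
        assignments = self.assignments()
        docs = sorted(self.topic_of)
        k = self.expected_counts.shape[0]
        P = pd.DataFrame(0.0, index=docs, columns=range(k))
        for t, ds in assignments.items():
            if ds:
                P.loc[sorted(ds), t] = 1.0 / len(ds)
        return P

    def to_json(self, path: str | Path) -> None:
        obj = {
            "topic_of": self.topic_of,
            "profiles": list(self.profiles) if self.profiles else None,
            "rec_trends": list(self.rec_trends),
            "expected_counts": self.expected_counts.tolist(),
            "period": {
                "start_date": self.period.start_date.isoformat(),
                "end_date": self.period.end_date.isoformat(),
                "outbreak_start": self.period.outbreak_start.isoformat(),
            },
            "w_days": self.w_days,
            "n_windows": self.n_windows,
        }
        Path(path).write_text(json.dumps(obj, indent=2))


def _expected_rec_trends(counts: np.ndarray) -> tuple[str, ...]:
    """Planted REC trend label per topic from the *expected* share series."""
    totals = counts.sum(axis=0)
    labels = []
    for t in range(counts.shape[0]):
        share = np.divide(counts[t], totals, out=np.zeros_like(totals), where=totals > 0)
        mk = mann_kendall(share)
        if mk.significant and mk.direction == "decreasing":
            labels.append("decreasing")
        elif mk.significant and mk.direction == "increasing":
            labels.append("increasing")
        else:
            labels.append("stable")
    return tuple(labels)


def generate_corpus(spec: SyntheticSpec) -> tuple[list[DocumentRecord], GroundTruth]:
    """Draw a reproducible corpus from the spec.

    Counts per (topic, window) are Poisson around the expected matrix;
    each document samples its lemmas i.i.d. from its topic's word
    distribution and its date uniformly within its window.
    """
    counts, period = spec.resolve()
    rng = np.random.default_rng(spec.seed)
    k, n_windows = counts.shape
    topic_word = rng.dirichlet(
        np.full(spec.vocab_size, spec.topic_sharpness), size=k
    )
    # purely alphabetic synthetic lemmas ("wbace", ...) so they survive the
    # digit-stripping tokenizer and pass unchanged through the lemmatizer
    width = len(str(spec.vocab_size))
    vocab = np.array(
        [
            "w" + "".join(chr(ord("b") + int(c)) for c in str(j).zfill(width))
            for j in range(spec.vocab_size)
        ]
    )

    records: list[DocumentRecord] = []
    topic_of: dict[str, int] = {}
    serial = 0
    for w in range(n_windows):
        win_start = period.start_date + timedelta(days=w * spec.w_days)
        for t in range(k):
            n_docs = rng.poisson(counts[t, w])
            if n_docs == 0:
                continue
            day_offsets = rng.integers(0, spec.w_days, size=n_docs)
            lengths = np.maximum(rng.poisson(spec.doc_length, size=n_docs), 5)
            for j in range(n_docs):
                tokens = vocab[
                    rng.choice(spec.vocab_size, size=lengths[j], p=topic_word[t])
                ]
                doc_id = f"d{serial:06d}"
                serial += 1
                records.append(
                    DocumentRecord(
                        doc_id=doc_id,
                        abstract=" ".join(tokens),
                        pub_date=win_start + timedelta(days=int(day_offsets[j])),
                        language_tag="en",
                    )
                )
                topic_of[doc_id] = t
    truth = GroundTruth(
        topic_of=topic_of,
        profiles=spec.profiles if spec.docs_per_window is None else None,
        expected_counts=counts,
        rec_trends=_expected_rec_trends(counts),
        topic_word=topic_word,
        period=period,
        w_days=spec.w_days,
        n_windows=n_windows,
    )
    return records, truth


@dataclass
class WorkedExample:
    """Tiny fixed corpus with hand-computed metric tables."""

    records: list[DocumentRecord]
    assignments: dict[int, set[str]]
    probabilities: pd.DataFrame
    period: StudyPeriod
    partition: WindowPartition
    expected_rec: pd.DataFrame
    expected_b: pd.DataFrame
    expected_entropy: pd.DataFrame
    expected_rrr: pd.DataFrame


def worked_example_fixture() -> WorkedExample:
    """A 10-document, 2-topic, 2-window corpus with closed-form metrics.

    Topic 0 has three documents in window 0 (days 40-42 after the
    outbreak, global probabilities .5/.2/.1) and four documents in window
    1, all on day 50 with probability .05 each; topic 1 has one window-0
    document (day 42, p=.4) and two window-1 documents (days 48 and 52,
    p=.35/.25).  Every expected value below is the direct evaluation of
    the metric definitions on those numbers.
    """
    outbreak = date(2019, 12, 12)
    start = outbreak + timedelta(days=40)  # 2020-01-21
    period = StudyPeriod(start, start + timedelta(days=13), outbreak)
    partition = WindowPartition(start=start, w_days=7, n_windows=2)

    def day(n: int) -> date:
        return outbreak + timedelta(days=n)

    spec = [  # (doc_id, topic, day-after-outbreak, p(d|topic))
        ("a1", 0, 40, 0.50),
        ("a2", 0, 41, 0.20),
        ("a3", 0, 42, 0.10),
        ("a4", 0, 50, 0.05),
        ("a5", 0, 50, 0.05),
        ("a6", 0, 50, 0.05),
        ("a7", 0, 50, 0.05),
        ("b1", 1, 42, 0.40),
        ("b2", 1, 48, 0.35),
        ("b3", 1, 52, 0.25),
    ]
    records = [
        DocumentRecord(doc_id=d, abstract=f"synthetic abstract {d}", pub_date=day(b),
                       language_tag="en")
        for d, _, b, _ in spec
    ]
    assignments = {0: {d for d, t, _, _ in spec if t == 0},
                   1: {d for d, t, _, _ in spec if t == 1}}
    P = pd.DataFrame(0.0, index=[d for d, *_ in spec], columns=[0, 1])
    for d, t, _, p in spec:
        P.at[d, t] = p

    ln = math.log
    # hand-computed tables (topics x windows)
    rec = pd.DataFrame([[3 / 4, 4 / 6], [1 / 4, 2 / 6]], index=[0, 1], columns=[0, 1])
    b = pd.DataFrame([[41.0, 50.0], [42.0, 50.0]], index=[0, 1], columns=[0, 1])
    e_a0 = -(0.625 * ln(0.625) + 0.25 * ln(0.25) + 0.125 * ln(0.125))
    e_b1 = -(7 / 12 * ln(7 / 12) + 5 / 12 * ln(5 / 12))
    entropy = pd.DataFrame([[e_a0, ln(4)], [0.0, e_b1]], index=[0, 1], columns=[0, 1])
    rrr = pd.DataFrame(
        [[0.8 / (41 * e_a0), 0.2 / (50 * ln(4))], [math.nan, 0.6 / (50 * e_b1)]],
        index=[0, 1],
        columns=[0, 1],
    )
    return WorkedExample(
        records=records,
        assignments=assignments,
        probabilities=P,
        period=period,
        partition=partition,
        expected_rec=rec,
        expected_b=b,
        expected_entropy=entropy,
        expected_rrr=rrr,
    )
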