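"""The research-priority metric suite over time-windows.

Given a hard document-to-topic partition, day-level publication dates and
a partition of the study period into consecutive windows of ``w`` days,
this module computes, per topic t and window w:

* **REC(t, w)** — research effort coverage: the fraction of the window's
  publications that belong to topic t (windows with no publications give
  missing values);
* **B(t, w)** — research time distance: the mean number of days between
  the outbreak starting point and the publication dates of the topic's
  papers in the window;
* **E(t, w)** — topic information entropy: the Shannon entropy (nats) of
  the within-cell renormalized membership probabilities p(d|t), which
  damps cells whose membership is concentrated in few uncertainly
  assigned documents;
* **RRR(t, w)** — research response rate: the topic's probability mass
  falling in the window divided by B(t, w) * E(t, w); high early RRR
  marks urgent research fields.

Trends of REC series are assessed with the Mann-Kendall test (S statistic,
tie-corrected variance, continuity-corrected Z) at the 95% confidence
level.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .corpus_io import DocumentRecord, StudyPeriod

__all__ = [
    "WindowPartition",
    "TrendResult",
    "RpmTable",
    "partition_windows",
    "compute_rec",
    "mann_kendall",
    "time_distance",
    "topic_entropy",
    "compute_rrr",
    "build_rpm_table",
]


@dataclass(frozen=True)
class WindowPartition:
    """Contiguous half-open windows [start, start + w_days) in days."""

    start: date
    w_days: int
    n_windows: int
    last_short_days: int = 0  # >0 when an auto-fit last window was truncated

    @property
    def end(self) -> date:
        return self.start + timedelta(days=self.w_days * self.n_windows)

    def window_start(self, w: int) -> date:
        return self.start + timedelta(days=self.w_days * w)

    def index_of(self, d: date) -> int | None:
        """Window index containing date ``d``, or None if outside."""
        offset = (d - self.start).days
        if offset < 0:
            return None
        w = offset // self.w_days
        return w if w < self.n_windows else None


@dataclass(frozen=True)
class TrendResult:
    """Mann-Kendall monotone-trend test outcome for one series."""

    s_stat: int
    var_s: float
    z_mk: float
    direction: str  # "increasing" | "decreasing" | "none"
    significant: bool
    n_used: int
    flag: str = ""

    @property
    def symbol(self) -> str:
        sym = {"increasing": "+", "decreasing": "-", "none": "o"}[self.direction]
        return sym + ("**" if self.significant else "")


@dataclass
class RpmTable:
    """Per-topic, per-window metric tables (topics as rows, windows as columns)."""

    rec: pd.DataFrame
    b: pd.DataFrame
    entropy: pd.DataFrame
    rrr: pd.DataFrame
    partition: WindowPartition
    flags: dict[str, list] | None = None

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: one row per (topic, window) with all metrics."""
        rows = []
        for t in self.rec.index:
            for w in self.rec.columns:
                rows.append(
                    {
                        "topic_id": t,
                        "window_index": w,
                        "window_start": self.partition.window_start(w).isoformat(),
                        "rec": self.rec.at[t, w],
                        "b_days": self.b.at[t, w],
                        "entropy": self.entropy.at[t, w],
                        "rrr": self.rrr.at[t, w],
                    }
                )
        return pd.DataFrame(rows)


def partition_windows(
    period: StudyPeriod, w_days: int = 7, n_windows: int | None = None
) -> WindowPartition:
    """Partition the study period into consecutive ``w_days``-day windows.

    With ``n_windows=None`` ("auto") windows cover the whole period (the
    last may be short, recorded in ``last_short_days``).  With a fixed
    ``n_windows`` exactly that many full windows are produced even if they
    do not cover the period; documents beyond them are excluded later and
    reported.
    """
    if w_days < 1:
        raise ValueError("w_days must be >= 1")
    total_days = (period.end_date - period.start_date).days + 1
    if n_windows is None:
        n_windows = -(-total_days // w_days)  # ceil
        last_short = n_windows * w_days - total_days
        return WindowPartition(period.start_date, w_days, n_windows, last_short)
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if period.start_date + timedelta(days=0) > period.end_date:
        raise ValueError("empty period")
    return WindowPartition(period.start_date, w_days, n_windows, 0)


def _doc_dates(records: Sequence[DocumentRecord]) -> dict[str, date]:
    return {r.doc_id: r.pub_date for r in records}


def _cells(
    assignments_by_topic: Mapping[int, set],
    records: Sequence[DocumentRecord],
    partition: WindowPartition,
) -> dict[tuple[int, int], list[str]]:
    """Documents per (topic, window) cell, in deterministic doc-id order."""
    dates = _doc_dates(records)
    cells: dict[tuple[int, int], list[str]] = {}
    for t, docs in assignments_by_topic.items():
        for d in sorted(docs):
            if d not in dates:
                continue
            w = partition.index_of(dates[d])
            if w is None:
                continue
            cells.setdefault((t, w), []).append(d)
    return cells


def compute_rec(
    assignments_by_topic: Mapping[int, set],
    records: Sequence[DocumentRecord],
    partition: WindowPartition,
) -> pd.DataFrame:
    """Research effort coverage: topic share of each window's publications.

    The denominator counts every record dated in the window (assigned or
    not), so over topics the REC values sum to at most 1; the shortfall is
    the unassigned share.  Windows with zero publications give NaN.
    """
    topics = sorted(assignments_by_topic)
    windows = range(partition.n_windows)
    totals = np.zeros(partition.n_windows)
    for rec_ in records:
        w = partition.index_of(rec_.pub_date)
        if w is not None:
            totals[w] += 1
    cells = _cells(assignments_by_topic, records, partition)
    out = pd.DataFrame(np.nan, index=topics, columns=list(windows), dtype=float)
    for w in windows:
        if totals[w] == 0:
            continue
        for t in topics:
            out.at[t, w] = len(cells.get((t, w), ())) / totals[w]
    return out


def mann_kendall(series, alpha: float = 0.05) -> TrendResult:
    """Mann-Kendall monotone-trend test with tie-corrected variance.

    S = sum over pairs i<j of sgn(x_j - x_i); Var(S) uses the tie
    correction [n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5)] / 18; Z applies
    the +-1 continuity correction.  Missing values are dropped first; a
    series shorter than 4 gives a flagged null result.
    """
    x = np.asarray(pd.Series(series, dtype=float).dropna().to_numpy())
    n = len(x)
    if n < 4:
        return TrendResult(0, 0.0, 0.0, "none", False, n, flag="too_short")
    diff = np.sign(x[None, :] - x[:, None])
    s = int(np.triu(diff, 1).sum())
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var_s = (n * (n - 1) * (2 * n + 5) - np.sum(ties * (ties - 1) * (2 * ties + 5))) / 18.0
    if var_s <= 0:  # all values identical
        return TrendResult(s, 0.0, 0.0, "none", False, n, flag="constant")
    if s > 0:
        z = (s - 1) / np.sqrt(var_s)
    elif s < 0:
        z = (s + 1) / np.sqrt(var_s)
    else:
        z = 0.0
    z_crit = norm.ppf(1 - alpha / 2)
    significant = abs(z) > z_crit
    direction = "increasing" if z > 0 else ("decreasing" if z < 0 else "none")
    return TrendResult(s, float(var_s), float(z), direction, bool(significant), n)


def time_distance(
    assignments_by_topic: Mapping[int, set],
    records: Sequence[DocumentRecord],
    partition: WindowPartition,
    outbreak_start: date,
) -> pd.DataFrame:
    """Mean days from the outbreak start to each cell's publication dates.

    A publication dated before the outbreak start is a hard error; one
    dated exactly on it gets a one-day offset (b_i = 1) so that downstream
    response rates stay finite.  Empty cells give NaN.
    """
    dates = _doc_dates(records)
    for d, pub in dates.items():
        if (pub - outbreak_start).days < 0:
            raise ValueError(f"document {d} predates the outbreak start")
    topics = sorted(assignments_by_topic)
    cells = _cells(assignments_by_topic, records, partition)
    out = pd.DataFrame(
        np.nan, index=topics, columns=list(range(partition.n_windows)), dtype=float
    )
    for (t, w), docs in cells.items():
        b_vals = [max((dates[d] - outbreak_start).days, 1) for d in docs]
        out.at[t, w] = float(np.mean(b_vals))
    return out


def topic_entropy(
    probabilities: pd.DataFrame,
    assignments_by_topic: Mapping[int, set],
    records: Sequence[DocumentRecord],
    partition: WindowPartition,
) -> pd.DataFrame:
    """Shannon entropy (nats) of within-cell renormalized p(d|t).

    q(d) = p(d|t) / sum over the cell; E = -sum q ln q.  Cells with fewer
    than two documents (or zero mass) give E = 0.  Empty cells give NaN.
    """
    topics = sorted(assignments_by_topic)
    cells = _cells(assignments_by_topic, records, partition)
    out = pd.DataFrame(
        np.nan, index=topics, columns=list(range(partition.n_windows)), dtype=float
    )
    for (t, w), docs in cells.items():
        p = probabilities.loc[docs, t].to_numpy(dtype=float)
        mass = p.sum()
        if len(docs) < 2 or mass <= 0:
            out.at[t, w] = 0.0
            continue
        q = p / mass
        q = q[q > 0]
        out.at[t, w] = float(-(q * np.log(q)).sum())
    return out


def compute_rrr(
    b: pd.DataFrame,
    probabilities: pd.DataFrame,
    entropy: pd.DataFrame,
    assignments_by_topic: Mapping[int, set],
    records: Sequence[DocumentRecord],
    partition: WindowPartition,
) -> pd.DataFrame:
    """Research response rate: window mass / (B * E), NaN where undefined.

    The numerator sums the *global* per-topic membership probabilities of
    the cell's documents, i.e. the topic's probability mass published in
    the window.  Cells with E = 0 (fewer than two documents) or no
    documents are left missing rather than infinite.
    """
    topics = sorted(assignments_by_topic)
    cells = _cells(assignments_by_topic, records, partition)
    out = pd.DataFrame(
        np.nan, index=topics, columns=list(range(partition.n_windows)), dtype=float
    )
    for (t, w), docs in cells.items():
        e = entropy.at[t, w]
        bb = b.at[t, w]
        if not np.isfinite(e) or e <= 0 or not np.isfinite(bb):
            continue
        if bb == 0:
            raise ValueError(f"zero research time distance in cell ({t}, {w})")
        mass = float(probabilities.loc[docs, t].sum())
        out.at[t, w] = mass / (bb * e)
    return out


def build_rpm_table(
    assignments_by_topic: Mapping[int, set],
    probabilities: pd.DataFrame,
    records: Sequence[DocumentRecord],
    partition: WindowPartition,
    outbreak_start: date,
) -> RpmTable:
    """Compute the full REC/B/E/RRR table bundle for one corpus."""
    rec = compute_rec(assignments_by_topic, records, partition)
    b = time_distance(assignments_by_topic, records, partition, outbreak_start)
    ent = topic_entropy(probabilities, assignments_by_topic, records, partition)
    rrr = compute_rrr(b, probabilities, ent, assignments_by_topic, records, partition)
    return RpmTable(rec=rec, b=b, entropy=ent, rrr=rrr, partition=partition)
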