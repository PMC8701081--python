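"""Hotspot typing and priority-region assignment.

Each hotspot's RRR trajectory is typed as one of three temporal
archetypes:

* **emergency** — response peaks in the first window and declines overall;
* **persistent** — response peaks in the second window and declines
  slowly, i.e. the field lags the outbreak but stays active;
* **fluctuating** — large event-driven swings (many reversals or a high
  coefficient of variation).

The type letter (E/P/F) combined with the significance-gated Mann-Kendall
trend of the hotspot's REC series (1 = significantly decreasing,
2 = stable, 3 = significantly increasing) places each hotspot in a
priority region such as E-1 or P-3.  The typing rules are an explicit,
configurable operationalization of archetypes that are usually judged by
eye; thresholds can be adjusted to reproduce judgment-based labels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .rpm import RpmTable, TrendResult, mann_kendall
from .topics import Hotspot

__all__ = [
    "PriorityResult",
    "classify_type",
    "classify_region",
    "classify_all",
    "priority_report",
]

_TYPE_LETTER = {"emergency": "E", "persistent": "P", "fluctuating": "F", "unclassified": "U"}


@dataclass
class PriorityResult:
    """Per-topic temporal type, REC trend and priority region."""

    topic_id: int
    type_label: str  # emergency | persistent | fluctuating | unclassified
    rec_trend: TrendResult
    region: str
    evidence: dict = field(default_factory=dict)


def classify_type(
    rrr_series,
    theta_cv: float = 0.5,
    min_sign_changes: int = 3,
    theta_amp: float = 0.25,
    peak_tol: float = 0.1,
    alpha: float = 0.05,
) -> tuple[str, dict]:
    """Type one hotspot from its per-window RRR series (missing allowed).

    Rules applied in order:

    a. *fluctuating* if the first differences of the observed series
       reverse sign at least ``min_sign_changes`` times — counting only
       material moves, those with amplitude at least ``theta_amp`` times
       the series mean, so sampling jitter in a flat or slowly declining
       tail is not mistaken for event-driven swings (genuine swings are
       of the order of the mean level itself) — or if the coefficient of
       variation is at least ``theta_cv``;
    b. *emergency* if the series peaks in the first window, i.e. the first
       window's value is within a relative ``peak_tol`` of the series
       maximum (the tolerance absorbs sampling error in near-ties, which
       should resolve toward the faster-responding type);
    c. *persistent* if the maximum is attained in the second window;
    d. otherwise *persistent* when the Mann-Kendall trend of the RRR series
       is non-increasing, else *fluctuating*.

    Fewer than four observed values yield ``"unclassified"``.  Returns the
    label and an evidence dict (peak window, MK z, CV, sign changes).
    """
    s = pd.Series(rrr_series, dtype=float)
    obs = s.dropna()
    evidence: dict = {"n_obs": int(len(obs))}
    if len(obs) < 4:
        return "unclassified", evidence
    vals = obs.to_numpy()
    mean = vals.mean()
    cv = float(vals.std(ddof=0) / mean) if mean > 0 else np.inf
    diffs = np.diff(vals)
    material = diffs[np.abs(diffs) >= theta_amp * mean]
    signs = np.sign(material)
    sign_changes = int(np.sum(signs[1:] != signs[:-1])) if len(signs) > 1 else 0
    mk = mann_kendall(vals, alpha=alpha)
    peak_window = obs.index[int(np.argmax(vals))]
    evidence.update(
        rrr_peak_window=peak_window,
        rrr_mk_z=mk.z_mk,
        rrr_cv=cv,
        sign_changes=sign_changes,
    )
    if sign_changes >= min_sign_changes or cv >= theta_cv:
        return "fluctuating", evidence
    windows = list(s.index)
    first_val = s.get(windows[0], np.nan)
    if np.isfinite(first_val) and first_val >= (1 - peak_tol) * vals.max():
        return "emergency", evidence
    if len(windows) > 1 and peak_window == windows[1]:
        return "persistent", evidence
    return ("persistent" if mk.z_mk <= 0 else "fluctuating"), evidence


def classify_region(type_label: str, rec_trend: TrendResult) -> str:
    """Region string <E|P|F>-<1|2|3> from type and significance-gated trend.

    Digit 1 when the REC trend is significantly decreasing, 3 when
    significantly increasing, else 2 (stable).  Unclassified types map to
    ``U-x``.
    """
    letter = _TYPE_LETTER.get(type_label)
    if letter is None:
        raise ValueError(f"unknown type label: {type_label!r}")
    if letter == "U":
        return "U-x"
    if rec_trend.significant and rec_trend.direction == "decreasing":
        digit = "1"
    elif rec_trend.significant and rec_trend.direction == "increasing":
        digit = "3"
    else:
        digit = "2"
    return f"{letter}-{digit}"


def classify_all(
    table: RpmTable,
    theta_cv: float = 0.5,
    min_sign_changes: int = 3,
    theta_amp: float = 0.25,
    peak_tol: float = 0.1,
    alpha: float = 0.05,
) -> list[PriorityResult]:
    """Type every topic in an RPM table and assign its priority region."""
    results = []
    for t in table.rrr.index:
        label, evidence = classify_type(
            table.rrr.loc[t],
            theta_cv=theta_cv,
            min_sign_changes=min_sign_changes,
            theta_amp=theta_amp,
            peak_tol=peak_tol,
            alpha=alpha,
        )
        trend = mann_kendall(table.rec.loc[t], alpha=alpha)
        evidence["rec_mk_z"] = trend.z_mk
        results.append(
            PriorityResult(
                topic_id=int(t),
                type_label=label,
                rec_trend=trend,
                region=classify_region(label, trend),
                evidence=evidence,
            )
        )
    return results


def priority_report(
    results: Sequence[PriorityResult],
    hotspots: Sequence[Hotspot] | None = None,
) -> pd.DataFrame:
    """Deterministic summary table: one row per topic.

    Columns: topic_id, label, keywords (";"-joined top terms), type,
    rec_trend_symbol (+/-/o, ``**`` appended at 5% significance),
    significant, region.  Row order is by topic id.
    """
    kw: Mapping[int, str] = {}
    labels: Mapping[int, str] = {}
    if hotspots is not None:
        kw = {h.topic_id: ";".join(term for term, _ in h.top_terms) for h in hotspots}
        labels = {h.topic_id: h.label or "" for h in hotspots}
    rows = [
        {
            "topic_id": r.topic_id,
            "label": labels.get(r.topic_id, ""),
            "keywords": kw.get(r.topic_id, ""),
            "type": r.type_label,
            "rec_trend_symbol": r.rec_trend.symbol,
            "significant": r.rec_trend.significant,
            "region": r.region,
        }
        for r in sorted(results, key=lambda r: r.topic_id)
    ]
    return pd.DataFrame(rows)
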