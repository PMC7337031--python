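"""Binary-event forecast verification.

Everything downstream of a bleaching prediction reduces to a 2x2 contingency
table of predicted vs. observed events — hits (H), false alarms (FA), misses
(M) and correct negatives (CN) — from which the standard suite of weather
forecasting skill scores is computed.  The Equitable Threat Score (ETS),

    ETS = (H - H_random) / (H + FA + M - H_random),
    H_random = (H + FA) * (H + M) / n,

discounts hits expected by chance and is the threshold optimizer used
throughout the package.

Metrics whose denominator vanishes (e.g. the false-alarm ratio when nothing
was predicted) are reported as ``None`` — a typed "undefined" marker rather
than a silent NaN — and are excluded from optimizations by the callers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

import numpy as np
import pandas as pd

__all__ = ["ContingencyTable", "SkillReport", "build_contingency", "compute_skill"]


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of hits, false alarms, misses and correct negatives."""

    hits: int
    false_alarms: int
    misses: int
    correct_negatives: int

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if int(v) != v or v < 0:
                raise ValueError(f"{f.name} must be a nonnegative integer, got {v!r}")
            object.__setattr__(self, f.name, int(v))

    @property
    def n(self) -> int:
        return self.hits + self.false_alarms + self.misses + self.correct_negatives

    def scaled(self, k: int) -> "ContingencyTable":
        """Multiply every cell by a positive integer (skill scores are invariant)."""
        if k < 1:
            raise ValueError("scale factor must be a positive integer")
        return ContingencyTable(
            self.hits * k, self.false_alarms * k, self.misses * k, self.correct_negatives * k
        )


@dataclass(frozen=True)
class SkillReport:
    """The nine verification metrics; ``None`` marks an undefined value."""

    accuracy: Optional[float]
    bias: Optional[float]
    pd: Optional[float]
    pfd: Optional[float]
    far: Optional[float]
    ets: Optional[float]
    ts: Optional[float]
    orss: Optional[float]
    pss: Optional[float]
    h_random: float
    table: ContingencyTable = field(repr=False)

    METRIC_NAMES = ("accuracy", "bias", "pd", "pfd", "far", "ets", "ts", "orss", "pss")

    def to_dict(self) -> dict:
        d = {name: getattr(self, name) for name in self.METRIC_NAMES}
        d["h_random"] = self.h_random
        t = self.table
        d.update(H=t.hits, FA=t.false_alarms, M=t.misses, CN=t.correct_negatives, n=t.n)
        return d

    def to_series(self) -> "pd.Series":  # noqa: F821 - pandas Series
        return pd.Series(self.to_dict())


def _ratio(num: int, den: int) -> Optional[float]:
    """Exact-integer guarded ratio: None when the denominator is zero."""
    return None if den == 0 else num / den


def build_contingency(predicted: pd.Series, observed: pd.Series) -> ContingencyTable:
    """Cross-tabulate boolean predictions against boolean observations.

    Both series must be boolean and share exactly the same index (site-year
    keys); a mismatch raises with the offending keys listed.
    """
    pred_idx, obs_idx = predicted.index, observed.index
    if len(pred_idx) != len(obs_idx) or not pred_idx.sort_values().equals(
        obs_idx.sort_values()
    ):
        only_pred = pred_idx.difference(obs_idx)
        only_obs = obs_idx.difference(pred_idx)
        raise ValueError(
            "predicted and observed indices differ; "
            f"only in predicted: {list(only_pred[:10])}, "
            f"only in observed: {list(only_obs[:10])}"
        )
    obs = observed.reindex(pred_idx)
    p = np.asarray(predicted, dtype=bool)
    o = np.asarray(obs, dtype=bool)
    return ContingencyTable(
        hits=int(np.sum(p & o)),
        false_alarms=int(np.sum(p & ~o)),
        misses=int(np.sum(~p & o)),
        correct_negatives=int(np.sum(~p & ~o)),
    )


def compute_skill(table: ContingencyTable) -> SkillReport:
    """Evaluate all nine skill metrics on a contingency table.

    Ratios are formed from exact integer numerators/denominators so that the
    "denominator is zero" test is never subject to floating-point noise; in
    particular the ETS denominator ``H + FA + M - H_random`` is cleared of its
    division by n:  ETS = (H*n - (H+FA)(H+M)) / ((H+FA+M)*n - (H+FA)(H+M)).
    """
    h, fa, m, cn = table.hits, table.false_alarms, table.misses, table.correct_negatives
    n = table.n
    if n == 0:
        raise ValueError("contingency table is empty (n=0)")

    h_random = (h + fa) * (h + m) / n
    ets_num = h * n - (h + fa) * (h + m)
    ets_den = (h + fa + m) * n - (h + fa) * (h + m)

    pd_ = _ratio(h, h + m)
    pfd = _ratio(fa, cn + fa)
    return SkillReport(
        accuracy=_ratio(h + cn, n),
        bias=_ratio(h + fa, h + m),
        pd=pd_,
        pfd=pfd,
        far=_ratio(fa, h + fa),
        ets=_ratio(ets_num, ets_den),
        ts=_ratio(h, h + fa + m),
        orss=_ratio(h * cn - m * fa, h * cn + m * fa),
        pss=None if pd_ is None or pfd is None else pd_ - pfd,
        h_random=h_random,
        table=table,
    )
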