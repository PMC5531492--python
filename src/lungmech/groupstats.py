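"""Group-level comparison of per-pair hyper-expansion indices.

Each serial scan pair contributes one record (percent lung hyper-expanded
at the 50% threshold, tissue analogue, pair-level hyperinflation flags);
groups are compared against a reference group with Welch's unequal-variance
two-sample t test (Welch–Satterthwaite degrees of freedom, two-sided p from
the Student t distribution), significance at p < 0.05.  Pairs from the same
subject are treated as independent records by default, with an optional
per-subject averaging mode for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import scipy.stats

__all__ = [
    "PairRecord",
    "WelchResult",
    "welch_t",
    "group_table",
    "classify_pairs",
    "ALPHA",
]

ALPHA = 0.05


@dataclass
class PairRecord:
    """One serial scan pair's summary indices."""

    subject: str
    pair: str
    group: str
    pct_hyper_at_50: float
    pct_tissue_exp_at_50: float = np.nan
    interval: str = ""

    def __post_init__(self) -> None:
        for name in ("pct_hyper_at_50", "pct_tissue_exp_at_50"):
            v = getattr(self, name)
            if np.isfinite(v) and not (0.0 <= v <= 100.0):
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass
class WelchResult:
    """Welch two-sample t test result (two-sided)."""

    t: float
    df: float
    p: float
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    n_a: int
    n_b: int

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def welch_t(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Welch's unequal-variance two-sample t test.

    t = (mean_a - mean_b) / sqrt(s_a^2/n_a + s_b^2/n_b), with the
    Welch–Satterthwaite real-valued degrees of freedom and a two-sided p
    value.  Identical samples give t = 0, p = 1.  Requires at least two
    observations per group and nonzero variance in at least one group.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size < 2:
        raise ValueError(f"first sample has n={a.size} < 2")
    if b.size < 2:
        raise ValueError(f"second sample has n={b.size} < 2")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0,
                               float(a.mean()), float(b.mean()), 0.0, 0.0,
                               a.size, b.size)
        raise ValueError("both samples are degenerate (zero variance)")
    sa, sb = va / a.size, vb / b.size
    se = np.sqrt(sa + sb)
    t = (a.mean() - b.mean()) / se
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = 2.0 * scipy.stats.t.sf(abs(t), df)
    return WelchResult(
        t=float(t), df=float(df), p=float(min(p, 1.0)),
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)), sd_b=float(b.std(ddof=1)),
        n_a=int(a.size), n_b=int(b.size),
    )


def _records_frame(records: Sequence[PairRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject": [r.subject for r in records],
            "pair": [r.pair for r in records],
            "group": [r.group for r in records],
            "pct_hyper_at_50": [r.pct_hyper_at_50 for r in records],
            "pct_tissue_exp_at_50": [r.pct_tissue_exp_at_50 for r in records],
        }
    )


def group_table(
    records: Sequence[PairRecord],
    reference_group: str,
    per_subject: bool = False,
    indices: Sequence[str] = ("pct_hyper_at_50", "pct_tissue_exp_at_50"),
) -> pd.DataFrame:
    """Per-group mean (SD) of each index with Welch p vs the reference group.

    Groups with fewer than two records are excluded (with a console
    warning); `per_subject=True` averages a subject's pairs first.
    Returns a DataFrame indexed by group with columns
    `<index>_mean`, `<index>_sd`, `<index>_p`, `<index>_significant`, `n`.
    """
    df = _records_frame(records)
    if per_subject:
        df = df.groupby(["group", "subject"], as_index=False)[list(indices)].mean()
    if reference_group not in set(df["group"]):
        raise ValueError(f"reference group {reference_group!r} not present")

    sizes = df.groupby("group").size()
    small = sizes[sizes < 2].index.tolist()
    if small:
        import warnings

        warnings.warn(f"excluding single-record groups: {small}", stacklevel=2)
        df = df[~df["group"].isin(small)]
    if reference_group not in set(df["group"]):
        raise ValueError(f"reference group {reference_group!r} has < 2 records")

    ref = df[df["group"] == reference_group]
    rows = []
    for g, sub in df.groupby("group", sort=True):
        row: dict = {"group": g, "n": len(sub)}
        for idx in indices:
            x = sub[idx].dropna().to_numpy()
            row[f"{idx}_mean"] = x.mean() if x.size else np.nan
            row[f"{idx}_sd"] = x.std(ddof=1) if x.size > 1 else np.nan
            if g == reference_group:
                row[f"{idx}_p"] = np.nan
                row[f"{idx}_significant"] = False
            else:
                r = welch_t(sub[idx].dropna(), ref[idx].dropna())
                row[f"{idx}_p"] = r.p
                row[f"{idx}_significant"] = r.significant
        rows.append(row)
    return pd.DataFrame(rows).set_index("group")


def classify_pairs(
    records: Sequence[PairRecord], cutoff: float = 0.1
) -> tuple[pd.Series, pd.DataFrame]:
    """Flag each pair as hyperinflated when its index reaches the cutoff.

    The flag is pct_hyper_at_50 >= cutoff (cutoff in percent of lung
    volume).  Returns the per-pair boolean series (indexed subject/pair)
    and a contingency table of flags by group.
    """
    df = _records_frame(records)
    flags = (df["pct_hyper_at_50"] >= cutoff)
    flags.index = pd.MultiIndex.from_frame(df[["subject", "pair"]])
    flags.name = f"hyperinflated_at_{cutoff}pct"
    contingency = pd.crosstab(df["group"], flags.to_numpy())
    contingency.columns = [f"hyperinflated={c}" for c in contingency.columns]
    return flags, contingency
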