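"""Survival stratification by gene-level copy-number status and by ploidy class.

Kaplan–Meier curves and two-group log-rank tests (via lifelines) applied two
ways: per gene, samples with a copy-number loss versus copy-number-neutral
samples (gained samples are excluded, not pooled); and per cohort, samples
with tumour ploidy > 3 versus the rest.  Times are in months; event = 1
marks death/progression, 0 censoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .segments import CallMatrix, SampleProfile

__all__ = [
    "LogrankResult",
    "km_logrank",
    "gene_survival_screen",
    "ploidy_survival",
]

REQUIRED_COLUMNS = ("sample", "time", "event")


def _validate_survival(df: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"survival table missing columns: {sorted(missing)}")
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be > 0")
    if not df["event"].isin((0, 1)).all():
        raise ValueError("event must be 0 (censored) or 1 (event)")


@dataclass
class LogrankResult:
    """Two-group log-rank test with the per-group Kaplan–Meier curves."""

    statistic: float  # chi-square statistic, 1 df
    p: float
    curves: pd.DataFrame  # columns: group, time, survival, n_risk
    group_sizes: dict[str, int]


def km_logrank(records: pd.DataFrame, group_col: str = "group") -> LogrankResult:
    """Kaplan–Meier curves and log-rank test between exactly two groups.

    ``records`` must hold columns time, event and ``group_col`` with exactly
    two distinct labels.  Raises if a group is missing or no event occurred
    anywhere ("zero events").
    """
    df = records.copy()
    if group_col not in df.columns:
        raise ValueError(f"missing group column {group_col!r}")
    if "sample" not in df.columns:
        df["sample"] = [f"s{i}" for i in range(len(df))]
    _validate_survival(df)
    groups = sorted(df[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly two groups, got {groups}")
    if int(df["event"].sum()) == 0:
        raise ValueError("zero events: log-rank test undefined")

    a = df[df[group_col] == groups[0]]
    b = df[df[group_col] == groups[1]]
    res = logrank_test(
        a["time"], b["time"], event_observed_A=a["event"], event_observed_B=b["event"]
    )

    curve_rows = []
    for label, part in ((groups[0], a), (groups[1], b)):
        kmf = KaplanMeierFitter()
        kmf.fit(part["time"], event_observed=part["event"])
        sf = kmf.survival_function_.iloc[:, 0]
        at_risk = kmf.event_table["at_risk"]
        for t in sf.index:
            curve_rows.append(
                {
                    "group": label,
                    "time": float(t),
                    "survival": float(sf.loc[t]),
                    "n_risk": int(at_risk.loc[t]) if t in at_risk.index else 0,
                }
            )
    return LogrankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        curves=pd.DataFrame(curve_rows),
        group_sizes={str(groups[0]): len(a), str(groups[1]): len(b)},
    )


def gene_survival_screen(
    cm: CallMatrix,
    survival: pd.DataFrame,
    genes: set[str] | list[str],
    min_group: int = 3,
) -> pd.DataFrame:
    """Per-gene log-rank of copy-number-lost vs neutral samples.

    For each gene, samples with call −1 form the "lost" group and call 0 the
    "neutral" group; gained samples (call +1) are excluded.  Genes where
    either group has fewer than ``min_group`` samples are skipped with the
    reason recorded.  Returns a table (gene, n_lost, n_neutral, statistic, p,
    skipped).
    """
    _validate_survival(survival)
    surv = survival.set_index("sample")
    unknown = set(surv.index) - set(cm.samples)
    if unknown:
        raise ValueError(f"survival samples absent from call matrix: {sorted(unknown)[:5]}")

    rows = []
    for gene in sorted(genes):
        if gene not in cm.calls.index:
            rows.append(
                {"gene": gene, "n_lost": 0, "n_neutral": 0,
                 "statistic": np.nan, "p": np.nan, "skipped": "gene not in call matrix"}
            )
            continue
        calls = cm.calls.loc[gene, surv.index]
        lost = surv.index[calls == -1]
        neutral = surv.index[calls == 0]
        row = {"gene": gene, "n_lost": len(lost), "n_neutral": len(neutral)}
        if len(lost) < min_group or len(neutral) < min_group:
            reason = "empty group" if min(len(lost), len(neutral)) == 0 else (
                f"group smaller than {min_group}"
            )
            rows.append({**row, "statistic": np.nan, "p": np.nan, "skipped": reason})
            continue
        records = pd.concat(
            [
                surv.loc[lost].assign(group="lost"),
                surv.loc[neutral].assign(group="neutral"),
            ]
        ).reset_index()
        try:
            res = km_logrank(records)
        except ValueError as exc:
            rows.append({**row, "statistic": np.nan, "p": np.nan, "skipped": str(exc)})
            continue
        rows.append({**row, "statistic": res.statistic, "p": res.p, "skipped": ""})
    return pd.DataFrame(rows)


def ploidy_survival(
    profiles: list[SampleProfile],
    survival: pd.DataFrame,
    ploidy_cut: float = 3.0,
) -> LogrankResult:
    """Survival of high-ploidy (ploidy > cut) vs the remaining samples.

    The cut is strict: a sample at exactly the cut value falls in the
    low-ploidy group.  Raises when either side of the split is empty.
    """
    _validate_survival(survival)
    ploidy = {p.sample_id: p.ploidy for p in profiles}
    missing = set(survival["sample"]) - set(ploidy)
    if missing:
        raise ValueError(f"profiles missing for samples: {sorted(missing)[:5]}")
    records = survival.copy()
    records["group"] = [
        "high_ploidy" if ploidy[s] > ploidy_cut else "low_ploidy"
        for s in records["sample"]
    ]
    counts = records["group"].value_counts()
    if len(counts) < 2:
        raise ValueError(
            f"one-sided ploidy split at cut {ploidy_cut}: only {counts.index.tolist()} present"
        )
    return km_logrank(records)
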