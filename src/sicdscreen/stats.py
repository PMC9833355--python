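"""Two-group statistics and the per-patient unfavourable-segment table.

Implements the Welch two-sample t-test and the Mann–Whitney U test (exact
by enumeration for small tie-free samples, normal approximation with tie
and continuity corrections otherwise), plus the arithmetic that summarises
per-patient counts of 10-s segments with T:R > 1/3 into per-group,
per-vector means with 95% CIs.

The "±" convention for the published count table is the normal-approximation
95% CI half-width, 1.96·s/√n; with that convention the packaged per-patient
counts reproduce every printed group mean and ± value.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .containers import VECTOR_ORDER

N_SEGMENTS_24H = 8640
EXACT_MAX_N = 12


def welch_t(x, y) -> tuple:
    """Welch two-sample t: (t, Satterthwaite df, two-sided p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise ValueError("both groups have zero variance")
    sx2, sy2 = vx / x.size, vy / y.size
    t = (x.mean() - y.mean()) / math.sqrt(sx2 + sy2)
    df = (sx2 + sy2) ** 2 / (sx2**2 / (x.size - 1) + sy2**2 / (y.size - 1))
    p = 2.0 * sstats.t.sf(abs(t), df)
    return t, df, min(p, 1.0) if p > 0 else p


def _u_statistics(x, y) -> tuple:
    pooled = np.concatenate([x, y])
    ranks = sstats.rankdata(pooled)  # midranks for ties
    r1 = ranks[: len(x)].sum()
    u1 = r1 - len(x) * (len(x) + 1) / 2.0
    u2 = len(x) * len(y) - u1
    return u1, u2


def mann_whitney_u(x, y) -> tuple:
    """Mann–Whitney U (min of U1, U2) and two-sided p.

    Exact p by enumeration over all group labelings when the pooled sample
    has at most ``EXACT_MAX_N`` tie-free observations: p = P(min(U1, U2) <=
    observed) under the permutation null.  Larger or tied samples use the
    normal approximation with midrank tie correction and continuity
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    u1, u2 = _u_statistics(x, y)
    u = min(u1, u2)
    pooled = np.concatenate([x, y])
    tie_free = np.unique(pooled).size == pooled.size

    if tie_free and n1 + n2 <= EXACT_MAX_N:
        total = math.comb(n1 + n2, n1)
        hits = 0
        ranks = sstats.rankdata(pooled)
        for comb in combinations(range(n1 + n2), n1):
            r1 = sum(ranks[i] for i in comb)
            cu1 = r1 - n1 * (n1 + 1) / 2.0
            if min(cu1, n1 * n2 - cu1) <= u + 1e-12:
                hits += 1
        return u, hits / total

    # normal approximation with tie correction and continuity correction
    n = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (n * (n - 1))
    sigma2 = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    mu = n1 * n2 / 2.0
    z = (u - mu + 0.5) / math.sqrt(sigma2)
    p = 2.0 * sstats.norm.cdf(z)
    return u, float(min(p, 1.0))


def ci_halfwidth(x) -> float:
    """Normal-approximation 95% CI half-width, 1.96·s/√n."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    return 1.96 * x.std(ddof=1) / math.sqrt(x.size)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's per-vector counts of 10-s segments with T:R > 1/3."""

    patient_id: int
    group: str  # "HF" or "Normal"
    counts: dict  # vector -> count or None (NA)
    n_total: int = N_SEGMENTS_24H

    def __post_init__(self) -> None:
        if self.group not in ("HF", "Normal"):
            raise ValueError("group must be 'HF' or 'Normal'")
        for v, c in self.counts.items():
            if c is not None and not 0 <= c <= self.n_total:
                raise ValueError(f"count {c} for {v} outside [0, {self.n_total}]")


def load_patient_counts() -> list:
    """Packaged per-patient unfavourable-segment counts (21 patients)."""
    ref = importlib.resources.files("sicdscreen.data") / "table3_counts.csv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        counts = {}
        for vector in VECTOR_ORDER:
            val = row[vector]
            counts[vector] = None if pd.isna(val) else int(val)
        records.append(PatientRecord(int(row["patient_id"]), str(row["group"]), counts))
    return records


def summarize_table(records: list) -> pd.DataFrame:
    """Per-group, per-vector summary of the unfavourable-segment counts.

    Returns one row per (group, vector): non-NA n, mean count (exact and
    rounded to integer for display), SD, 95% CI half-width, and the mean
    percentage of the 24-h recording (mean count / 8640 · 100).  Groups with
    fewer than two non-NA values get a NaN CI (flagged via ``ci_defined``).
    """
    if not records:
        raise ValueError("no patient records")
    rows = []
    for group in ("Normal", "HF"):
        sub = [r for r in records if r.group == group]
        for vector in VECTOR_ORDER:
            vals = np.array(
                [r.counts[vector] for r in sub if r.counts.get(vector) is not None],
                dtype=float,
            )
            if vals.size == 0:
                continue
            mean = vals.mean()
            ci_ok = vals.size >= 2
            rows.append(
                {
                    "group": group,
                    "vector": vector,
                    "n": int(vals.size),
                    "mean_count": mean,
                    "mean_count_display": int(round(mean)),
                    "sd_count": vals.std(ddof=1) if ci_ok else float("nan"),
                    "ci_halfwidth": ci_halfwidth(vals) if ci_ok else float("nan"),
                    "ci_halfwidth_display": int(round(ci_halfwidth(vals))) if ci_ok else None,
                    "mean_percent": mean / N_SEGMENTS_24H * 100.0,
                    "ci_defined": ci_ok,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Two-group comparison of one per-patient quantity."""

    parameter: str
    mean_hf: float
    mean_normal: float
    ci_hf: float
    ci_normal: float
    welch_t: float
    welch_df: float
    welch_p: float
    mw_u: float
    mw_p: float

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def compare_groups(per_patient: pd.DataFrame) -> dict:
    """Mirror the headline group comparisons on per-patient summaries.

    ``per_patient`` needs columns ``group`` ("HF"/"Normal"), ``mean_tr`` and
    ``sd_tr``.  Returns a dict with one :class:`GroupComparison` per
    parameter (Welch t and Mann–Whitney U, both two-sided).
    """
    out = {}
    for param in ("mean_tr", "sd_tr"):
        hf = per_patient.loc[per_patient["group"] == "HF", param].to_numpy(dtype=float)
        nm = per_patient.loc[per_patient["group"] == "Normal", param].to_numpy(dtype=float)
        if hf.size < 2 or nm.size < 2:
            raise ValueError("need at least 2 patients per group")
        t, df, p = welch_t(hf, nm)
        u, up = mann_whitney_u(hf, nm)
        out[param] = GroupComparison(
            parameter=param,
            mean_hf=float(hf.mean()),
            mean_normal=float(nm.mean()),
            ci_hf=ci_halfwidth(hf),
            ci_normal=ci_halfwidth(nm),
            welch_t=t,
            welch_df=df,
            welch_p=p,
            mw_u=u,
            mw_p=up,
        )
    return out
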