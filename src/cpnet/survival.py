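"""Median-split Kaplan-Meier screening with logrank tests and hazard ratios.

For each candidate gene, patients are dichotomized at the cohort median of
that gene's expression (ties go to the high group), the two overall-survival
curves are compared with the standard two-group logrank test, and the
hazard ratio is estimated from the logrank observed/expected event totals,

    HR = (O_high / E_high) / (O_low / E_low),
    95% CI = exp(log HR +- 1.96 * sqrt(1/E_high + 1/E_low)).

No multiplicity correction is applied across screened genes by default
(each gene is judged at alpha individually); Benjamini-Hochberg is
available behind a switch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

from .errors import CpnetWarning, DegenerateError, InputError


@dataclass
class SurvivalTable:
    """Patient follow-up (months), event flag and per-gene expression."""

    data: pd.DataFrame  # index patient_id; columns: time, event, one per gene
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise InputError("survival table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise InputError("survival times must be positive")
        if not self.data["event"].isin([0, 1]).all():
            raise InputError("event flags must be 0 or 1")

    @property
    def genes(self) -> list:
        return [c for c in self.data.columns if c not in ("time", "event")]

    @classmethod
    def read_tsv(cls, path) -> "SurvivalTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def write_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", float_format="%.6f")


def median_split(table: SurvivalTable, gene: str) -> pd.Series:
    """Label patients 'high' (expression >= median) or 'low'."""
    if gene not in table.data.columns:
        raise InputError(f"gene {gene!r} absent from survival table")
    expr = table.data[gene]
    if expr.isna().any():
        raise InputError(f"gene {gene!r} has missing expression")
    if expr.nunique() == 1:
        raise DegenerateError(f"degenerate split: constant expression for {gene!r}")
    med = expr.median()
    return pd.Series(np.where(expr >= med, "high", "low"), index=expr.index, name=gene)


def km_curve(times, events):
    """Product-limit survival estimate; returns (event_times, S(t)) arrays.

    Censored subjects leave the risk set without stepping the curve.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise InputError("km_curve needs >= 1 subject")
    order = np.argsort(times, kind="mergesort")
    times, events = times[order], events[order]
    out_t, out_s = [], []
    s = 1.0
    n_at_risk = times.size
    i = 0
    while i < times.size:
        t = times[i]
        d = 0
        c = 0
        while i < times.size and times[i] == t:
            d += events[i]
            c += 1 - events[i]
            i += 1
        if d > 0:
            s *= 1.0 - d / n_at_risk
            out_t.append(t)
            out_s.append(s)
        n_at_risk -= d + c
    return np.asarray(out_t), np.asarray(out_s)


def _event_table(times_a, events_a, times_b, events_b):
    """Per distinct event time: risk sets, events, expectation and variance."""
    ta = np.asarray(times_a, float)
    ea = np.asarray(events_a, int)
    tb = np.asarray(times_b, float)
    eb = np.asarray(events_b, int)
    event_times = np.unique(np.concatenate([ta[ea == 1], tb[eb == 1]]))
    rows = []
    for t in event_times:
        n1 = int((ta >= t).sum())
        n2 = int((tb >= t).sum())
        d1 = int(((ta == t) & (ea == 1)).sum())
        d2 = int(((tb == t) & (eb == 1)).sum())
        n = n1 + n2
        d = d1 + d2
        if n == 0 or d == 0:
            continue
        e1 = d * n1 / n
        var = d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1) if n > 1 else 0.0
        rows.append((t, n1, n2, d1, d2, e1, var))
    return rows


def logrank(times_a, events_a, times_b, events_b):
    """Two-group logrank test: returns (chi2, p).

    U is the summed observed-minus-expected events in group A under
    hypergeometric sampling at each distinct event time, with the standard
    tie-corrected variance; chi2 = U^2 / Var(U), p from chi-square(1).
    """
    if len(times_a) == 0 or len(times_b) == 0:
        raise InputError("both groups must be nonempty")
    rows = _event_table(times_a, events_a, times_b, events_b)
    u = sum(d1 - e1 for _, _, _, d1, _, e1, _ in rows)
    var = sum(v for *_, v in rows)
    if var == 0:
        warnings.warn("logrank variance is zero (no comparable events)", CpnetWarning)
        return 0.0, 1.0
    chi2 = u * u / var
    p = float(chi2_dist.sf(chi2, df=1))
    return float(chi2), max(p, np.finfo(float).tiny)


def hazard_ratio(times_a, events_a, times_b, events_b):
    """O/E hazard ratio of group A vs group B with a 95% CI."""
    rows = _event_table(times_a, events_a, times_b, events_b)
    o1 = sum(d1 for _, _, _, d1, _, _, _ in rows)
    o2 = sum(d2 for _, _, _, _, d2, _, _ in rows)
    e1 = sum(e1 for *_, e1, _ in rows)
    d_tot = o1 + o2
    e2 = d_tot - e1
    if o1 == 0 or o2 == 0:
        raise InputError("need >= 1 event in each group")
    if e1 == 0 or e2 == 0:
        raise InputError("zero expected events in one group")
    hr = (o1 / e1) / (o2 / e2)
    half_width = 1.96 * np.sqrt(1.0 / e1 + 1.0 / e2)
    ci = (float(hr * np.exp(-half_width)), float(hr * np.exp(half_width)))
    return float(hr), ci


def km_screen(
    table: SurvivalTable, genes, alpha: float = 0.05, bh_correct: bool = False
) -> pd.DataFrame:
    """Median-split + logrank + hazard ratio per gene.

    A gene whose split or test fails is reported with an 'error' note
    rather than aborting the screen.
    """
    rows = []
    times = table.data["time"].to_numpy()
    events = table.data["event"].to_numpy()
    for gene in genes:
        try:
            labels = median_split(table, gene)
            hi = labels == "high"
            t_hi, e_hi = times[hi.to_numpy()], events[hi.to_numpy()]
            t_lo, e_lo = times[~hi.to_numpy()], events[~hi.to_numpy()]
            chi2, p = logrank(t_hi, e_hi, t_lo, e_lo)
            try:
                hr, ci = hazard_ratio(t_hi, e_hi, t_lo, e_lo)
            except InputError:
                hr, ci = float("nan"), (float("nan"), float("nan"))
            rows.append(
                {
                    "gene": gene,
                    "n_high": int(hi.sum()),
                    "n_low": int((~hi).sum()),
                    "logrank_chi2": chi2,
                    "p_value": p,
                    "hazard_ratio": hr,
                    "hr_ci_low": ci[0],
                    "hr_ci_high": ci[1],
                    "error": "",
                }
            )
        except (InputError, DegenerateError) as exc:
            rows.append(
                {
                    "gene": gene,
                    "n_high": 0,
                    "n_low": 0,
                    "logrank_chi2": float("nan"),
                    "p_value": float("nan"),
                    "hazard_ratio": float("nan"),
                    "hr_ci_low": float("nan"),
                    "hr_ci_high": float("nan"),
                    "error": str(exc),
                }
            )
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "n_high", "n_low", "logrank_chi2", "p_value",
            "hazard_ratio", "hr_ci_low", "hr_ci_high", "error",
        ],
    )
    if df.empty:
        df["significant"] = pd.Series(dtype=bool)
        return df
    if bh_correct:
        ok = df["p_value"].notna()
        adj = pd.Series(np.nan, index=df.index)
        if ok.any():
            from statsmodels.stats.multitest import multipletests

            adj[ok] = multipletests(df.loc[ok, "p_value"], method="fdr_bh")[1]
        df["p_adjusted"] = adj
        df["significant"] = df["p_adjusted"] < alpha
    else:
        df["significant"] = df["p_value"] < alpha
    df["significant"] = df["significant"].fillna(False)
    return df
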