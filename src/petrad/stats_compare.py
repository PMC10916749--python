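"""Paired comparison of two models' probability scores.

For each true group (control, dementia) the per-model score mean and
sample SD are summarized and the per-subject paired two-tailed Student's
t-test is run on the score difference: with d_i = a_i - b_i,

    t = mean(d) / (SD(d) / sqrt(n)),   df = n - 1,

and p from the two-tailed Student's t distribution.  The paired form is
the appropriate one here because the same held-out subjects are scored by
both models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["GroupComparison", "ComparisonResult", "column_summary", "paired_ttest",
           "compare_models", "load_reference_scores"]

ALPHA = 0.05


def column_summary(scores) -> tuple[float, float]:
    """Arithmetic mean and sample SD (n-1 denominator)."""
    x = np.asarray(scores, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 scores")
    return float(x.mean()), float(x.std(ddof=1))


def paired_ttest(a, b) -> tuple[float, int, float]:
    """Paired two-tailed Student's t-test on per-subject score pairs.

    Returns (t, df, two-tailed p); raises on zero-variance differences.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1D score lists")
    n = a.size
    if n < 2:
        raise ValueError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences; t undefined")
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return float(t), n - 1, float(p)


@dataclass
class GroupComparison:
    group: str
    n: int
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    mean_difference: float
    t: float | None
    df: int | None
    p: float | None
    significant: bool | None

    @property
    def verdict(self) -> str:
        if self.p is None:
            return "no difference"
        return f"P = {self.p:.4f}" if self.significant else "NS"


@dataclass
class ComparisonResult:
    model_a: str
    model_b: str
    groups: dict[str, GroupComparison]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.groups.values():
            rows.append(
                {
                    "group": g.group,
                    "n": g.n,
                    f"{self.model_a}_mean": round(g.mean_a, 2),
                    f"{self.model_a}_sd": round(g.sd_a, 2),
                    f"{self.model_b}_mean": round(g.mean_b, 2),
                    f"{self.model_b}_sd": round(g.sd_b, 2),
                    "mean_difference": round(g.mean_difference, 2),
                    "t": None if g.t is None else round(g.t, 3),
                    "df": g.df,
                    "p": None if g.p is None else round(g.p, 4),
                    "verdict": g.verdict,
                }
            )
        return pd.DataFrame(rows)


def compare_models(scores_a: pd.DataFrame, scores_b: pd.DataFrame) -> ComparisonResult:
    """Per-group summary and paired test of two ScoreTables.

    Tables must cover the same subjects; rows are aligned by subject_id.
    Identical score columns are reported as 'no difference' rather than an
    error.
    """
    a = scores_a.set_index("subject_id").sort_index()
    b = scores_b.set_index("subject_id").sort_index()
    if not a.index.equals(b.index):
        raise ValueError("the two score tables cover different subjects")
    if not (a["true_group"] == b["true_group"]).all():
        raise ValueError("true-group labels disagree between the tables")

    tag_a = str(scores_a["model"].iloc[0]) if "model" in scores_a else "model_a"
    tag_b = str(scores_b["model"].iloc[0]) if "model" in scores_b else "model_b"

    groups: dict[str, GroupComparison] = {}
    for group, sub_a in a.groupby("true_group"):
        sub_b = b.loc[sub_a.index]
        xa, xb = sub_a["score"].to_numpy(), sub_b["score"].to_numpy()
        mean_a, sd_a = column_summary(xa)
        mean_b, sd_b = column_summary(xb)
        try:
            t, df, p = paired_ttest(xa, xb)
            sig = p < ALPHA
        except ValueError:
            t = df = p = sig = None
        groups[str(group)] = GroupComparison(
            group=str(group), n=len(xa), mean_a=mean_a, sd_a=sd_a,
            mean_b=mean_b, sd_b=sd_b, mean_difference=float((xa - xb).mean()),
            t=t, df=df, p=p, significant=sig,
        )
    return ComparisonResult(model_a=tag_a, model_b=tag_b, groups=groups)


def load_reference_scores() -> pd.DataFrame:
    """The packaged reference held-out score table (20 subjects scored by
    both arms), used by worked examples and reproduction tests."""
    from importlib.resources import files

    path = files("petrad").joinpath("data/reference_scores.csv")
    with path.open() as fh:
        return pd.read_csv(fh)
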