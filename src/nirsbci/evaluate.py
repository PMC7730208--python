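"""Method comparison statistics, activation maps, and ground-truth metrics.

Per-subject accuracy vectors of two methods are compared with a two-tailed
paired Student's t-test; family-wise error over multiple comparisons is
controlled by Bonferroni correction of the significance threshold. For
simulated recordings with known active channels, selection quality is
summarised as sensitivity/specificity against the ground-truth mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .select import SelectionResult

__all__ = [
    "paired_ttest",
    "bonferroni_alpha",
    "t_critical",
    "activation_map",
    "plot_activation_map",
    "selection_metrics",
    "compare_methods",
    "EvalReport",
]


def paired_ttest(a, b) -> tuple[float, float]:
    """Two-tailed paired Student's t-test on matched accuracy vectors.

    ``t = mean(d) / (sd(d)/√n)`` with d = a − b and sample (n−1) standard
    deviation; p from the t-distribution with n−1 degrees of freedom.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("paired test needs two equal-length vectors, n >= 2")
    d = a - b
    if np.ptp(d) == 0:
        raise ValueError("all paired differences are equal; test degenerate")
    res = stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def bonferroni_alpha(family_alpha: float = 0.05, m: int = 3) -> float:
    """Bonferroni-adjusted per-comparison significance level, 4 decimals."""
    if not 0 < family_alpha < 1:
        raise ValueError("family_alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return round(family_alpha / m, 4)


def t_critical(alpha_one_tailed: float, df: int, precise: bool = False) -> float:
    """Upper one-tailed Student-t critical value.

    Reported rounded to 2 decimals by default (``precise=True`` returns full
    precision).
    """
    if not 0 < alpha_one_tailed < 1 or df < 1:
        raise ValueError("need 0 < alpha < 1 and df >= 1")
    val = float(stats.t.ppf(1.0 - alpha_one_tailed, df))
    return val if precise else round(val, 2)


def activation_map(result: SelectionResult, montage: np.ndarray | None = None) -> pd.DataFrame:
    """Per-channel table of raw and min-max-normalized method scores.

    Normalization maps the score vector to [0, 1]; constant scores map to
    all-zeros. Rows follow the result's channel order; montage coordinates
    are appended when given.
    """
    s = result.scores
    span = np.ptp(s)
    norm = (s - s.min()) / span if span > 0 else np.zeros_like(s)
    df = pd.DataFrame(
        {
            "channel": list(result.channel_ids),
            "score": s,
            "normalized_score": norm,
            "selected": result.selected,
        }
    )
    if montage is not None:
        montage = np.asarray(montage, dtype=float)
        if montage.shape != (len(result.channel_ids), 2):
            raise ValueError("montage must be (n_channels, 2)")
        df["x"] = montage[:, 0]
        df["y"] = montage[:, 1]
    return df


def plot_activation_map(result: SelectionResult, montage: np.ndarray, ax=None):
    """Scatter of channel positions colored by normalized score (optional)."""
    import matplotlib.pyplot as plt

    df = activation_map(result, montage)
    if ax is None:
        _, ax = plt.subplots()
    sc = ax.scatter(df["x"], df["y"], c=df["normalized_score"], cmap="hot", s=120,
                    edgecolors=np.where(df["selected"], "k", "none"))
    ax.set_title(f"{result.method} activation map")
    ax.set_aspect("equal")
    plt.colorbar(sc, ax=ax, label="normalized score")
    return ax


def selection_metrics(result: SelectionResult, truth) -> tuple[float, float]:
    """Sensitivity and specificity of a selection against ground truth.

    ``truth`` is a boolean mask or an object exposing ``.active``. With no
    truly active channels sensitivity is undefined and reported as NaN with
    a warning.
    """
    active = np.asarray(getattr(truth, "active", truth), dtype=bool)
    sel = result.selected
    if active.shape != sel.shape:
        raise ValueError("truth and selection channel counts differ")
    tp = int((sel & active).sum())
    fn = int((~sel & active).sum())
    tn = int((~sel & ~active).sum())
    fp = int((sel & ~active).sum())
    if tp + fn == 0:
        warnings.warn("no truly active channels; sensitivity undefined", UserWarning)
        sens = float("nan")
    else:
        sens = tp / (tp + fn)
    spec = tn / (tn + fp) if (tn + fp) else float("nan")
    return sens, spec


@dataclass(frozen=True)
class EvalReport:
    """Accuracy vectors per method/task plus paired-test comparison records."""

    accuracies: dict
    comparisons: list = field(default_factory=list)
    adjusted_alpha: float = 0.0167

    def to_report(self) -> dict:
        return {
            "accuracies": {k: list(np.asarray(v, dtype=float)) for k, v in self.accuracies.items()},
            "comparisons": list(self.comparisons),
            "adjusted_alpha": self.adjusted_alpha,
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame.from_records(self.comparisons)

    def summary(self) -> str:
        lines = [f"Method comparison (adjusted alpha = {self.adjusted_alpha})"]
        for c in self.comparisons:
            star = "*" if c["p"] < self.adjusted_alpha else " "
            lines.append(
                f"  {c['task']}: {c['method_a']} vs {c['method_b']}: "
                f"t = {c['t']:.3f}, p = {c['p']:.3g} {star}"
            )
        return "\n".join(lines)


def compare_methods(
    accuracy_table: pd.DataFrame,
    proposed: str,
    others: list[str],
    tasks: list[str],
    family_alpha: float = 0.05,
    m: int = 3,
) -> EvalReport:
    """Paired-test the proposed method against comparators per task.

    ``accuracy_table`` columns are named ``"<task>_<method>"`` with one row
    per subject.
    """
    alpha = bonferroni_alpha(family_alpha, m)
    accs = {}
    comps = []
    for task in tasks:
        a = accuracy_table[f"{task}_{proposed}"].to_numpy(dtype=float)
        accs[f"{task}_{proposed}"] = a
        for other in others:
            b = accuracy_table[f"{task}_{other}"].to_numpy(dtype=float)
            accs[f"{task}_{other}"] = b
            t, p = paired_ttest(a, b)
            comps.append(
                {
                    "task": task,
                    "method_a": proposed,
                    "method_b": other,
                    "t": t,
                    "p": p,
                    "significant": bool(p < alpha),
                }
            )
    return EvalReport(accuracies=accs, comparisons=comps, adjusted_alpha=alpha)
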