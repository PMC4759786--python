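"""Cohort-level statistics for classified QPS responses.

The biological replicate is the *culture*: response-class percentages
are computed per culture first, then averaged across cultures
(mean +/- SEM), mirroring how the assay is reported.  Group
comparisons use one-way ANOVA followed by Dunnett's many-to-one post
hoc test against the shared control (two-sided, multivariate-t
family-wise adjustment); pairwise checks use the unpaired pooled
two-sample t-test.  Viability concordance cross-tabulates response
class against propidium-iodide (PI) staining.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

THREE_CLASSES = ("BP", "RD", "ID")

#: Significance stars: *** p < 0.005, ** p < 0.01, * p < 0.05, else ns.
STAR_LEVELS = ((0.005, "***"), (0.01, "**"), (0.05, "*"))


def round_half_up(x: float) -> int:
    """Round to nearest integer with halves away from zero (report style)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def stars(p: float, alpha: float = 0.05) -> str:
    for cut, mark in STAR_LEVELS:
        if p < cut and cut <= alpha + 1e-12:
            return mark
    return "*" if p < alpha else "ns"


@dataclass(frozen=True)
class CultureSummary:
    """Response-class percentages for one culture.

    Percentages are over the BP/RD/ID classified cells only; NONE and
    UNCLASSIFIED cells are counted separately and excluded from the
    three-class denominator.
    """

    culture_id: str
    n_cells: int
    n_classified: int
    pct_BP: float
    pct_RD: float
    pct_ID: float
    n_none: int = 0
    n_unclassified: int = 0

    def pct(self, cls: str) -> float:
        return {"BP": self.pct_BP, "RD": self.pct_RD, "ID": self.pct_ID}[cls]


@dataclass(frozen=True)
class ConditionSummary:
    """Across-culture mean +/- SEM of class percentages for one condition."""

    condition_id: str
    n_cult: int
    n_cell: int
    mean_pct_BP: float
    sem_pct_BP: float
    mean_pct_RD: float
    sem_pct_RD: float
    mean_pct_ID: float
    sem_pct_ID: float
    per_culture_pct_ID: tuple[float, ...] = ()

    def mean(self, cls: str) -> float:
        return {"BP": self.mean_pct_BP, "RD": self.mean_pct_RD,
                "ID": self.mean_pct_ID}[cls]


@dataclass(frozen=True)
class DunnettResult:
    """One-way ANOVA + Dunnett many-to-one comparison vs a control."""

    f_statistic: float
    anova_p: float
    treatments: tuple[str, ...]
    adjusted_p: Mapping[str, float]
    statistics: Mapping[str, float]
    alpha: float = 0.05
    stars: Mapping[str, str] = field(default_factory=dict)

    def significant(self, name: str) -> bool:
        return self.adjusted_p[name] < self.alpha


@dataclass(frozen=True)
class ConcordanceTable:
    """PI-positivity cross-tabulated by response class."""

    counts: pd.DataFrame          # index: class; columns: pi_positive, pi_negative
    pct_pi_positive: Mapping[str, float]   # exact percentage per class (NaN if empty)

    def pct_rounded(self, cls: str) -> int:
        """Report-style nearest-integer (half-up) PI-positive percentage."""
        v = self.pct_pi_positive.get(cls, float("nan"))
        if not np.isfinite(v):
            raise ValueError(f"class {cls!r} has no cells; percentage undefined")
        return round_half_up(v)


def summarize_culture(labels: Iterable[str], culture_id: str = "") -> CultureSummary:
    """Per-culture BP/RD/ID percentages from per-cell labels."""
    labels = list(labels)
    if not labels:
        raise ValueError("cannot summarise an empty culture")
    counts = {cls: 0 for cls in THREE_CLASSES}
    n_none = n_uncl = 0
    for lab in labels:
        if lab in counts:
            counts[lab] += 1
        elif lab == "NONE":
            n_none += 1
        elif lab == "UNCLASSIFIED":
            n_uncl += 1
        else:
            raise ValueError(f"unknown label {lab!r}")
    n_classified = sum(counts.values())
    if n_classified == 0:
        raise ValueError("culture has no BP/RD/ID cells; percentages undefined")
    pct = {cls: 100.0 * counts[cls] / n_classified for cls in THREE_CLASSES}
    return CultureSummary(culture_id=culture_id, n_cells=len(labels),
                          n_classified=n_classified, pct_BP=pct["BP"],
                          pct_RD=pct["RD"], pct_ID=pct["ID"],
                          n_none=n_none, n_unclassified=n_uncl)


def summarize_condition(cultures: Sequence[CultureSummary],
                        condition_id: str = "") -> ConditionSummary:
    """Across-culture mean and SEM of class percentages.

    The culture is the statistical unit; SEM = SD / sqrt(n_cult) and is
    NaN for a single culture.
    """
    if not cultures:
        raise ValueError("cannot summarise an empty condition")
    n_cult = len(cultures)
    out: dict[str, float] = {}
    for cls in THREE_CLASSES:
        vals = np.array([c.pct(cls) for c in cultures])
        out[f"mean_pct_{cls}"] = float(vals.mean())
        out[f"sem_pct_{cls}"] = (float(vals.std(ddof=1) / math.sqrt(n_cult))
                                 if n_cult > 1 else float("nan"))
    return ConditionSummary(condition_id=condition_id, n_cult=n_cult,
                            n_cell=sum(c.n_cells for c in cultures),
                            per_culture_pct_ID=tuple(c.pct_ID for c in cultures),
                            **out)


def _check_group(name: str, values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError(f"group {name!r} needs >= 2 replicate cultures")
    return values


def dunnett_vs_control(control: Sequence[float],
                       treatments: Mapping[str, Sequence[float]],
                       alpha: float = 0.05,
                       rng: int | np.random.Generator | None = None) -> DunnettResult:
    """One-way ANOVA followed by Dunnett's test versus the control.

    ``control`` and each treatment are per-culture values (typically
    percentages of ID responses).  Adjusted p-values come from the
    two-sided multivariate-t family-wise distribution and handle
    unbalanced designs via the standard correlation structure.  ``rng``
    seeds the numerical evaluation of the multivariate-t CDF so results
    are reproducible.
    """
    if not treatments:
        raise ValueError("need at least one treatment group")
    control = _check_group("control", control)
    groups = {name: _check_group(name, vals) for name, vals in treatments.items()}
    all_groups = [control, *groups.values()]
    pooled_var = np.concatenate([g - g.mean() for g in all_groups]).var(ddof=0)
    if pooled_var == 0:
        raise ValueError("zero within-group variance; test undefined")

    f_stat, anova_p = stats.f_oneway(*all_groups)
    if rng is None or isinstance(rng, np.random.Generator):
        gen = rng
    else:
        gen = np.random.default_rng(rng)
    res = stats.dunnett(*groups.values(), control=control, alternative="two-sided",
                        rng=gen)
    names = tuple(groups)
    adj = {name: float(p) for name, p in zip(names, np.atleast_1d(res.pvalue))}
    stat = {name: float(s) for name, s in zip(names, np.atleast_1d(res.statistic))}
    return DunnettResult(f_statistic=float(f_stat), anova_p=float(anova_p),
                         treatments=names, adjusted_p=adj, statistics=stat,
                         alpha=alpha,
                         stars={name: stars(adj[name], alpha) for name in names})


def unpaired_t(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided unpaired (pooled-variance) Student's t-test p-value."""
    a = _check_group("a", group_a)
    b = _check_group("b", group_b)
    if np.concatenate([a - a.mean(), b - b.mean()]).var(ddof=0) == 0:
        raise ValueError("zero within-group variance; t-test undefined")
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def concordance(labels: Sequence[str], pi_positive: Sequence[bool],
                cell_ids: Sequence | None = None) -> ConcordanceTable:
    """Cross-tabulate response class against PI viability staining.

    Returns per-class counts and the percentage of PI-positive cells in
    each class (NaN for classes with no cells).  When ``cell_ids`` is
    given, labels and PI calls are matched on it and unmatched ids
    raise.
    """
    labels = list(labels)
    pi = list(pi_positive)
    if len(labels) != len(pi):
        raise ValueError("labels and PI calls must have equal length")
    if cell_ids is not None and len(set(cell_ids)) != len(labels):
        raise ValueError("cell ids must be unique and match the labels")
    df = pd.DataFrame({"label": labels, "pi": [bool(x) for x in pi]})
    classes = [c for c in ("BP", "RD", "ID", "NONE", "UNCLASSIFIED")
               if c in set(labels)]
    counts = pd.DataFrame(
        {"pi_positive": [int(((df.label == c) & df.pi).sum()) for c in classes],
         "pi_negative": [int(((df.label == c) & ~df.pi).sum()) for c in classes]},
        index=pd.Index(classes, name="label"))
    pct = {}
    for c in classes:
        total = counts.loc[c].sum()
        pct[c] = 100.0 * counts.loc[c, "pi_positive"] / total if total else float("nan")
    return ConcordanceTable(counts=counts, pct_pi_positive=pct)


@dataclass(frozen=True)
class DoseResponseResult:
    doses: tuple[float, ...]                 # non-control doses, ascending
    adjusted_p: Mapping[float, float]
    lowest_significant_dose: float | None
    monotone_decreasing: bool
    dunnett: DunnettResult


def dose_response(culture_pct_by_dose: Mapping[float, Sequence[float]],
                  control_dose: float = 0.0, alpha: float = 0.05,
                  rng: int | np.random.Generator | None = None) -> DoseResponseResult:
    """Dose-response analysis of per-culture ID percentages.

    Each dose (mM) maps to its per-culture values; the ``control_dose``
    group (0 mM) is the Dunnett control.  Reports the per-dose adjusted
    p-value, the lowest dose significant at ``alpha``, and whether the
    dose-group means are monotone non-increasing with dose.
    """
    if control_dose not in culture_pct_by_dose:
        raise ValueError(f"control dose {control_dose} mM missing from the design")
    doses = sorted(d for d in culture_pct_by_dose if d != control_dose)
    if len(doses) < 1:
        raise ValueError("need at least one non-control dose")
    res = dunnett_vs_control(
        culture_pct_by_dose[control_dose],
        {f"{d:g}": culture_pct_by_dose[d] for d in doses},
        alpha=alpha, rng=rng)
    adj = {d: res.adjusted_p[f"{d:g}"] for d in doses}
    sig = [d for d in doses if adj[d] < alpha]
    means = [float(np.mean(culture_pct_by_dose[d]))
             for d in [control_dose, *doses]]
    return DoseResponseResult(doses=tuple(doses), adjusted_p=adj,
                              lowest_significant_dose=min(sig) if sig else None,
                              monotone_decreasing=bool(np.all(np.diff(means) <= 0)),
                              dunnett=res)
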