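"""2^-dCt relative qPCR quantification and one-way ANOVA + Tukey HSD.

Each target gene's Ct is normalised within a (condition, replicate) pair
by subtracting the reference gene's Ct (e.g. the AtUBQ5 housekeeping
gene); relative expression is 2**-dCt, summarised per condition, and
optionally expressed as fold change over the control condition's mean.
Because dCt is a difference of two Ct values measured in the same
reaction plate, adding any constant to every Ct leaves the results
unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway, tukey_hsd

from .containers import ConfigError

__all__ = ["RelativeExpression", "relative_expression", "AnovaTukeyResult", "anova_tukey"]

CT_COLUMNS = ["condition", "gene", "replicate", "ct"]


def _validate_ct(ct: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in CT_COLUMNS if c not in ct.columns]
    if missing:
        raise ConfigError(f"Ct table is missing columns {missing}")
    vals = ct["ct"].to_numpy(dtype=float)
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise ConfigError("Ct values must be finite and > 0")
    return ct


@dataclass
class RelativeExpression:
    """Replicate-level 2^-dCt values with per-(condition, gene) summaries."""

    replicates: pd.DataFrame  # condition, gene, replicate, delta_ct, value
    summary: pd.DataFrame     # condition, gene, mean, sd, n [, fold_change]
    reference_gene: str
    control: str | None = None

    def values(self, condition: str, gene: str) -> np.ndarray:
        sub = self.replicates
        sel = (sub["condition"] == condition) & (sub["gene"] == gene)
        return sub.loc[sel, "value"].to_numpy()


def relative_expression(
    ct: pd.DataFrame, reference_gene: str, control: str | None = None
) -> RelativeExpression:
    """Per-replicate 2^-dCt against a reference gene.

    dCt = Ct(target) - Ct(reference) within the same (condition,
    replicate); every target measurement must have a matching reference
    measurement. When ``control`` is given, the summary also carries
    each (condition, gene)'s fold change over the control condition's
    mean value of the same gene.
    """
    ct = _validate_ct(ct)
    ref = ct[ct["gene"] == reference_gene]
    if ref.empty:
        raise ConfigError(f"reference gene {reference_gene!r} absent from the Ct table")
    ref_ct = ref.set_index(["condition", "replicate"])["ct"]
    if ref_ct.index.duplicated().any():
        ref_ct = ref_ct.groupby(level=[0, 1]).mean()

    targets = ct[ct["gene"] != reference_gene].copy()
    key = pd.MultiIndex.from_frame(targets[["condition", "replicate"]])
    missing = ~key.isin(ref_ct.index)
    if missing.any():
        cond, rep = key[int(np.argmax(missing))]
        raise ConfigError(
            f"no reference measurement for condition {cond!r}, replicate {rep}"
        )
    targets["delta_ct"] = targets["ct"].to_numpy() - ref_ct.loc[key].to_numpy()
    targets["value"] = np.exp2(-targets["delta_ct"])

    summary = (
        targets.groupby(["condition", "gene"], sort=False)["value"]
        .agg(mean="mean", sd="std", n="count")
        .reset_index()
    )
    summary["sd"] = summary["sd"].fillna(0.0)
    if control is not None:
        if control not in set(summary["condition"]):
            raise ConfigError(f"control condition {control!r} absent from the Ct table")
        ctrl_mean = summary[summary["condition"] == control].set_index("gene")["mean"]
        summary["fold_change"] = summary["mean"].to_numpy() / ctrl_mean.loc[
            summary["gene"]
        ].to_numpy()

    reps = targets[["condition", "gene", "replicate", "delta_ct", "value"]].reset_index(
        drop=True
    )
    return RelativeExpression(reps, summary, reference_gene, control)


@dataclass
class AnovaTukeyResult:
    """One-way ANOVA F/p plus Tukey-adjusted pairwise comparisons."""

    F: float
    p: float
    pairwise: dict = field(default_factory=dict)  # (a, b) -> (mean diff, adjusted p)
    degenerate: bool = False
    alpha: float = 0.05

    def significant_pairs(self) -> list:
        return [pair for pair, (_, padj) in self.pairwise.items() if padj < self.alpha]

    def summary(self) -> str:
        if self.degenerate:
            return "one-way ANOVA: degenerate (zero within-group variance), p undefined"
        lines = [f"one-way ANOVA: F = {self.F:.4g}, p = {self.p:.4g}"]
        for (a, b), (diff, padj) in self.pairwise.items():
            mark = "*" if padj < self.alpha else " "
            lines.append(f"  {a} vs {b}: diff = {diff:+.4g}, Tukey p = {padj:.4g} {mark}")
        return "\n".join(lines)


def anova_tukey(groups: dict, alpha: float = 0.05) -> AnovaTukeyResult:
    """Classical one-way ANOVA with Tukey HSD post-hoc comparisons.

    ``groups`` maps condition label -> replicate values. A design with
    zero within-group variance everywhere is returned flagged degenerate
    (F/p undefined) rather than raising or faking significance.
    """
    if len(groups) < 2:
        raise ConfigError("need at least two groups")
    # sort within groups so results are exactly invariant to replicate order
    arrays = {k: np.sort(np.asarray(v, dtype=float)) for k, v in groups.items()}
    for k, v in arrays.items():
        if v.size < 2:
            raise ConfigError(f"group {k!r} has fewer than two values")
    within_ss = sum(np.sum((v - v.mean()) ** 2) for v in arrays.values())
    if within_ss == 0:
        return AnovaTukeyResult(F=np.nan, p=np.nan, degenerate=True, alpha=alpha)

    names = list(arrays)
    values = [arrays[k] for k in names]
    F, p = f_oneway(*values)
    hsd = tukey_hsd(*values)
    pairwise = {}
    for i, j in combinations(range(len(names)), 2):
        diff = float(values[i].mean() - values[j].mean())
        pairwise[(names[i], names[j])] = (diff, float(hsd.pvalue[i, j]))
    return AnovaTukeyResult(F=float(F), p=float(p), pairwise=pairwise, alpha=alpha)
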