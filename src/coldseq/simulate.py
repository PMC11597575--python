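"""Synthetic data with known ground truth.

Emulates a cold-stress bulk RNA-seq design: a 22 degC control plus
low-temperature treatments, three biological replicates each, gene-level
negative-binomial counts with planted per-condition log2 fold changes,
annotation terms whose membership can be planted to correlate with the
effect sign, and long-format qPCR Ct tables.

Negative-binomial parameterisation throughout: variance = mu + phi*mu^2,
so phi = 0 is Poisson. This matches the dispersion convention of the
differential-expression module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ConfigError, CountMatrix, GOAnnotation, GOTerm, TruthTable

__all__ = ["SimConfig", "generate_counts", "generate_go_annotation", "generate_ct_table"]


@dataclass
class SimConfig:
    """Configuration of the count simulator.

    Parameters
    ----------
    n_genes
        Number of genes.
    conditions
        Ordered condition labels; the first is the control.
    reps_per_condition
        Biological replicates per condition (default 3).
    lib_size_mean
        Expected total counts per sample (default 5e6, a conventional
        bulk RNA-seq depth).
    lib_size_cv
        Coefficient of variation of library sizes; sizes are drawn
        log-normal (default 0.1, i.e. ~10% depth variation).
    baseline_log2_mean_range
        Interval of per-gene baseline log2 relative abundance b_g;
        abundances 2**b_g are normalised within each sample so the
        expected total equals the drawn library size.
    dispersion
        NB dispersion phi >= 0 (variance = mu + phi*mu^2).
    de_fraction_per_condition
        Fraction of genes with a planted nonzero effect in each
        treatment condition.
    logfc_mean, logfc_sd
        Mean and SD of the Gaussian from which planted signed log2
        fold changes are drawn.
    nested_effects
        If True, each later treatment's DE gene set is a random subset
        (80% retention) of the previous treatment's, so the coldest
        condition perturbs the most genes and milder conditions
        progressively fewer — the overlap structure of graded cold
        treatments. Default: independent draws per condition.
    seed
        Seed of the single generator all randomness flows through.
    """

    n_genes: int = 10_000
    conditions: tuple = ("22C", "0C", "4C", "10C")
    reps_per_condition: int = 3
    lib_size_mean: float = 5e6
    lib_size_cv: float = 0.1
    baseline_log2_mean_range: tuple = (0.0, 12.0)
    dispersion: float = 0.1
    de_fraction_per_condition: float = 0.1
    logfc_mean: float = 0.0
    logfc_sd: float = 2.0
    nested_effects: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.reps_per_condition <= 0:
            raise ConfigError("reps_per_condition must be positive")
        if len(self.conditions) < 2:
            raise ConfigError("need a control plus at least one treatment")
        if len(set(self.conditions)) != len(self.conditions):
            raise ConfigError("condition labels must be unique")
        if self.dispersion < 0:
            raise ConfigError("dispersion must be >= 0")
        if not 0 <= self.de_fraction_per_condition <= 1:
            raise ConfigError("de_fraction_per_condition must be in [0, 1]")
        lo, hi = self.baseline_log2_mean_range
        if hi < lo:
            raise ConfigError("baseline_log2_mean_range must be an interval")
        if self.lib_size_mean <= 0 or self.lib_size_cv < 0:
            raise ConfigError("library size parameters must be positive")


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float) -> np.ndarray:
    """NB(mean, phi) variates with variance mu + phi*mu^2, via gamma-Poisson."""
    if phi == 0:
        return rng.poisson(mean)
    shape = 1.0 / phi
    lam = rng.gamma(shape, mean * phi)
    return rng.poisson(lam)


def generate_counts(config: SimConfig) -> tuple[CountMatrix, TruthTable]:
    """Simulate a count matrix and its ground-truth effect table.

    Counts for gene g in sample j of condition c are drawn
    NB(mean = s_j * 2**(b_g + beta_gc), dispersion phi), where s_j
    scales the sample's expected total to its drawn library size and
    beta_gc is the planted log2 effect (0 in the control).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    lo, hi = config.baseline_log2_mean_range
    baseline = rng.uniform(lo, hi, size=config.n_genes)

    control, *treatments = config.conditions
    gene_ids = np.array([f"G{i:06d}" for i in range(config.n_genes)])

    beta = {control: np.zeros(config.n_genes)}
    n_de = int(round(config.de_fraction_per_condition * config.n_genes))
    prev_idx: np.ndarray | None = None
    for cond in treatments:
        b = np.zeros(config.n_genes)
        if n_de > 0:
            if config.nested_effects and prev_idx is not None:
                take = max(1, int(round(0.8 * prev_idx.size)))
                idx = rng.choice(prev_idx, size=take, replace=False)
            else:
                idx = rng.choice(config.n_genes, size=n_de, replace=False)
            effects = rng.normal(config.logfc_mean, config.logfc_sd, size=idx.size)
            effects[effects == 0] = config.logfc_sd or 1.0  # zero draw would unmark DE
            b[idx] = effects
            prev_idx = idx
        beta[cond] = b

    sample_ids, cond_of_sample, columns = [], {}, []
    sigma2 = np.log1p(config.lib_size_cv**2)
    for cond in config.conditions:
        rel = np.exp2(baseline + beta[cond])
        rel_sum = rel.sum()
        for r in range(1, config.reps_per_condition + 1):
            sid = f"{cond}_r{r}"
            lib = rng.lognormal(np.log(config.lib_size_mean) - sigma2 / 2, np.sqrt(sigma2))
            mu = rel * (lib / rel_sum)
            columns.append(_nb_draw(rng, mu, config.dispersion))
            sample_ids.append(sid)
            cond_of_sample[sid] = cond

    counts = pd.DataFrame(
        np.column_stack(columns), index=gene_ids, columns=sample_ids
    )
    effects = pd.DataFrame(
        [
            (g, cond, beta[cond][i], beta[cond][i] != 0)
            for cond in treatments
            for i, g in enumerate(gene_ids)
        ],
        columns=["gene_id", "condition", "true_log2fc", "is_de"],
    )
    return CountMatrix(counts, cond_of_sample), TruthTable(effects)


def generate_go_annotation(
    truth: TruthTable,
    n_terms: int,
    size_range: tuple = (5, 200),
    planted_fraction: float = 0.0,
    planted_strength: float = 1.0,
    seed: int = 0,
    condition: str | None = None,
    planted_direction: str = "alternate",
) -> tuple[GOAnnotation, TruthTable]:
    """Random annotation terms, optionally planted to track the true effects.

    A planted "up" term samples its members with weight proportional to
    exp(planted_strength * true_log2fc) of the chosen condition ("down"
    terms use the negated effect); non-planted terms sample uniformly.
    Planted terms are assigned the BP namespace so they surface in the
    biological-process rankings; non-planted terms get a random
    namespace. ``planted_direction`` is "alternate" (default: planted
    terms alternate up/down), "up", or "down". Returns the annotation
    and a TruthTable extended with the planted-term table.
    """
    if not 0 <= planted_fraction <= 1:
        raise ConfigError("planted_fraction must be in [0, 1]")
    if planted_direction not in {"alternate", "up", "down"}:
        raise ConfigError(f"unknown planted_direction {planted_direction!r}")
    if condition is None:
        condition = truth.effects["condition"].iloc[0]
    lfc = truth.true_log2fc(condition)
    genes = lfc.index.to_numpy()
    n_genes = genes.size
    lo, hi = int(size_range[0]), int(size_range[1])
    if not 1 <= lo <= hi <= n_genes:
        raise ConfigError("size_range must lie within [1, n_genes]")

    rng = np.random.default_rng(seed)
    n_planted = int(round(planted_fraction * n_terms))
    lfc_values = lfc.to_numpy()

    terms, planted_rows = [], []
    for k in range(n_terms):
        term_id = f"GO:{k:07d}"
        size = int(rng.integers(lo, hi + 1))
        if k < n_planted:
            if planted_direction == "alternate":
                direction = "up" if k % 2 == 0 else "down"
            else:
                direction = planted_direction
            signed = lfc_values if direction == "up" else -lfc_values
            w = np.exp(planted_strength * np.clip(signed, -30, 30))
            members = rng.choice(genes, size=size, replace=False, p=w / w.sum())
            namespace = "BP"
            planted_rows.append((term_id, direction, planted_strength))
        else:
            members = rng.choice(genes, size=size, replace=False)
            namespace = ("BP", "CC", "MF")[rng.integers(3)]
        terms.append(
            GOTerm(term_id, frozenset(members), name=f"synthetic term {k}", namespace=namespace)
        )

    planted = pd.DataFrame(planted_rows, columns=["term_id", "direction", "strength"])
    return GOAnnotation(terms), truth.with_terms(planted)


def generate_ct_table(
    n_targets: int,
    reference_label: str,
    delta_ct_effects: dict,
    noise_sd: float = 0.2,
    seed: int = 0,
    reps: int = 3,
    reference_base_ct: float = 20.0,
) -> pd.DataFrame:
    """Long-format qPCR Ct table with planted per-condition dCt shifts.

    Each target gene's Ct in a replicate equals that replicate's
    reference-gene Ct plus the condition's planted dCt effect plus
    Gaussian noise on the Ct scale, so with zero effects and zero noise
    every 2**-dCt value is exactly 1. The reference gene's Ct is
    independent of condition in expectation.
    """
    if not reference_label:
        raise ConfigError("reference_label is required")
    if noise_sd < 0:
        raise ConfigError("noise_sd must be >= 0")
    if n_targets <= 0:
        raise ConfigError("n_targets must be positive")
    rng = np.random.default_rng(seed)
    records = []
    targets = [f"T{i + 1}" for i in range(n_targets)]
    for cond, effect in delta_ct_effects.items():
        for r in range(1, reps + 1):
            sample = f"{cond}_r{r}"
            ref_ct = reference_base_ct + rng.normal(0, noise_sd)
            records.append((sample, cond, reference_label, r, ref_ct))
            for gene in targets:
                ct = ref_ct + effect + rng.normal(0, noise_sd)
                records.append((sample, cond, gene, r, ct))
    return pd.DataFrame(
        records, columns=["sample", "condition", "gene", "replicate", "ct"]
    )
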