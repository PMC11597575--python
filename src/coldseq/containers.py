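"""Core in-memory containers shared across the pipeline stages.

The central object is :class:`CountMatrix`, a validated genes x samples
integer count table with a condition label per sample, mirroring the
design of a cold-stress experiment: one control condition and one or more
treatment conditions, each with biological replicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CountMatrix",
    "GOTerm",
    "GOAnnotation",
    "TruthTable",
    "ConfigError",
]


class ConfigError(ValueError):
    """Invalid configuration or malformed input."""


class CountMatrix:
    """Genes x samples matrix of non-negative integer counts.

    Parameters
    ----------
    counts
        DataFrame indexed by gene ID with one column per sample ID.
        All entries must be non-negative integers.
    conditions
        Mapping (or Series) sample ID -> condition label. Every sample
        column must be covered.
    """

    def __init__(self, counts: pd.DataFrame, conditions) -> None:
        counts = pd.DataFrame(counts)
        if counts.index.duplicated().any():
            dups = counts.index[counts.index.duplicated()].unique().tolist()
            raise ConfigError(f"duplicate gene IDs: {dups[:5]}")
        if counts.columns.duplicated().any():
            dups = counts.columns[counts.columns.duplicated()].unique().tolist()
            raise ConfigError(f"duplicate sample IDs: {dups[:5]}")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ConfigError("counts must be numeric")
        if np.any(values < 0):
            g, s = np.argwhere(values < 0)[0]
            raise ConfigError(
                f"negative count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        if not np.allclose(values, np.round(values)):
            g, s = np.argwhere(~np.isclose(values, np.round(values)))[0]
            raise ConfigError(
                f"non-integer count at gene {counts.index[g]!r}, sample {counts.columns[s]!r}"
            )
        cond = pd.Series(conditions)
        missing = [s for s in counts.columns if s not in cond.index]
        if missing:
            raise ConfigError(f"samples without a condition label: {missing[:5]}")
        self.counts = counts.astype(np.int64)
        self.conditions = cond.reindex(counts.columns).rename(None)

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def library_sizes(self) -> pd.Series:
        """Total counts per sample."""
        return self.counts.sum(axis=0)

    def samples_of(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition]
        return list(sel.index)

    def subset_conditions(self, conditions) -> "CountMatrix":
        keep = [s for s in self.sample_ids if self.conditions[s] in set(conditions)]
        return CountMatrix(self.counts[keep], self.conditions[keep])

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        conds = ", ".join(f"{c}:{n}" for c, n in self.conditions.value_counts().items())
        return f"<CountMatrix {self.n_genes} genes x {self.n_samples} samples ({conds})>"


@dataclass
class GOTerm:
    """One annotation term with its member gene set."""

    term_id: str
    genes: frozenset
    name: str = ""
    namespace: str = "BP"

    def __post_init__(self) -> None:
        if not self.genes:
            raise ConfigError(f"term {self.term_id} has an empty gene set")
        if self.namespace not in {"BP", "CC", "MF"}:
            raise ConfigError(f"term {self.term_id}: unknown namespace {self.namespace!r}")


class GOAnnotation:
    """Collection of :class:`GOTerm` keyed by term ID."""

    def __init__(self, terms) -> None:
        self.terms: dict[str, GOTerm] = {}
        for t in terms:
            if t.term_id in self.terms:
                raise ConfigError(f"duplicate term ID {t.term_id}")
            self.terms[t.term_id] = t

    def __len__(self) -> int:
        return len(self.terms)

    def __iter__(self):
        return iter(self.terms.values())

    def __getitem__(self, term_id: str) -> GOTerm:
        return self.terms[term_id]

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def in_namespace(self, namespace: str) -> "GOAnnotation":
        return GOAnnotation(t for t in self if t.namespace == namespace)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (t.term_id, g, t.name, t.namespace)
            for t in self
            for g in sorted(t.genes)
        ]
        return pd.DataFrame(rows, columns=["term_id", "gene_id", "name", "namespace"])


@dataclass
class TruthTable:
    """Ground truth emitted by the simulator.

    ``effects`` holds one row per (gene, treatment condition) with the
    planted log2 fold change; ``terms`` holds one row per planted
    annotation term with its direction and association strength.
    """

    effects: pd.DataFrame
    terms: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            columns=["term_id", "direction", "strength"]
        )
    )

    def __post_init__(self) -> None:
        want = {"gene_id", "condition", "true_log2fc", "is_de"}
        if not want.issubset(self.effects.columns):
            raise ConfigError(f"effects table needs columns {sorted(want)}")
        bad = self.effects["is_de"] != (self.effects["true_log2fc"] != 0)
        if bad.any():
            raise ConfigError("is_de must hold exactly when true_log2fc != 0")

    def true_log2fc(self, condition: str) -> pd.Series:
        sub = self.effects[self.effects["condition"] == condition]
        return sub.set_index("gene_id")["true_log2fc"]

    def de_genes(self, condition: str) -> set:
        sub = self.effects[
            (self.effects["condition"] == condition) & self.effects["is_de"]
        ]
        return set(sub["gene_id"])

    def with_terms(self, terms: pd.DataFrame) -> "TruthTable":
        return TruthTable(self.effects, terms.reset_index(drop=True))
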