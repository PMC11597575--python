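"""Top-N induced-gene selection and exclusive Venn partitioning.

After per-contrast differential expression, the most strongly induced
genes of each treatment are selected by log2 fold change under strict
FDR and abundance thresholds, and the per-treatment top sets are
partitioned into exclusive Venn regions (genes in exactly a given
subset of the treatments).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import pandas as pd

from .containers import ConfigError
from .de import DEResults

__all__ = ["TopGeneSet", "VennPartition", "top_induced", "venn_partition", "shared_gene_table"]


@dataclass
class TopGeneSet:
    """Ordered top-induced genes of one condition.

    Ordering key (total, deterministic): logFC descending, then FDR
    ascending, then gene ID lexicographic.
    """

    condition: str
    gene_ids: list
    n_requested: int
    thresholds: dict = field(default_factory=lambda: {"fdr_max": 0.01, "logcpm_min": 4.0})

    def __len__(self) -> int:
        return len(self.gene_ids)


def top_induced(
    de: DEResults, n: int = 50, fdr_max: float = 0.01, logcpm_min: float = 4.0
) -> TopGeneSet:
    """Top-n induced genes: FDR < fdr_max, logCPM > logcpm_min, logFC > 0.

    Both thresholds are strict inequalities. If fewer than n genes
    qualify, all of them are returned without padding.
    """
    if n <= 0:
        raise ConfigError("n must be positive")
    f = de.frame
    ok = (f["FDR"] < fdr_max) & (f["logCPM"] > logcpm_min) & (f["logFC"] > 0)
    qual = f[ok].copy()
    qual["_gene"] = qual.index
    qual = qual.sort_values(
        ["logFC", "FDR", "_gene"], ascending=[False, True, True], kind="stable"
    )
    return TopGeneSet(
        condition=de.treatment,
        gene_ids=qual["_gene"].head(n).tolist(),
        n_requested=n,
        thresholds={"fdr_max": fdr_max, "logcpm_min": logcpm_min},
    )


class VennPartition:
    """Exclusive region -> gene set, over a family of named sets.

    Regions are indexed by frozensets of condition labels; region(S)
    holds the genes present in every set of S and in no other set, so
    regions are pairwise disjoint and their union is the union of the
    inputs.
    """

    def __init__(self, sets: dict) -> None:
        if len(sets) < 2:
            raise ConfigError("need at least two sets to partition")
        self.set_names = list(sets)
        universe: dict = {}
        for name, genes in sets.items():
            for g in genes:
                universe.setdefault(g, set()).add(name)
        self.regions: dict[frozenset, set] = {}
        for g, names in universe.items():
            self.regions.setdefault(frozenset(names), set()).add(g)

    def region(self, names) -> set:
        return set(self.regions.get(frozenset(names), set()))

    def counts(self) -> dict:
        return {self._label(k): len(v) for k, v in sorted(self.regions.items(), key=self._sort_key)}

    def _label(self, key: frozenset) -> str:
        return "&".join(n for n in self.set_names if n in key)

    def _sort_key(self, item):
        key = item[0]
        return (len(key), [self.set_names.index(n) for n in self.set_names if n in key])

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.counts(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def venn_partition(sets: dict) -> VennPartition:
    """Partition named gene sets into exclusive Venn regions."""
    return VennPartition(sets)


def shared_gene_table(
    partition: VennPartition,
    region,
    de_by_condition: dict,
    order_by: str,
) -> pd.DataFrame:
    """Per-region gene table with each condition's logFC, sorted.

    Rows are the members of the requested region; columns are the log2
    fold changes looked up from each relevant condition's DE results;
    rows are ordered by descending logFC of ``order_by``.
    """
    genes = sorted(partition.region(region))
    conds = [c for c in partition.set_names if c in set(region)]
    if order_by not in conds:
        raise ConfigError(f"order_by {order_by!r} not among region conditions {conds}")
    rows = {}
    for cond in conds:
        frame = de_by_condition[cond].frame
        missing = [g for g in genes if g not in frame.index]
        if missing:
            raise ConfigError(
                f"gene {missing[0]!r} missing from DE results of {cond!r}"
            )
        rows[f"logFC_{cond}"] = [frame.at[g, "logFC"] for g in genes]
    out = pd.DataFrame(rows, index=pd.Index(genes, name="gene_id"))
    return out.sort_values(f"logFC_{order_by}", ascending=False, kind="stable")
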