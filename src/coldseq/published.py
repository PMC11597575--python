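"""Published Arabidopsis cold-stress top-50 overlap table.

The bundled table transcribes the printed lists of top-50 cold-induced
genes shared between the 0, 4 and 10 degC treatments of the Arabidopsis
cold-stress study this toolkit re-implements: 31 genes common to all
three temperatures, 9 exclusive to 0&4 degC, 8 to 4&10 degC and 2 to
0&10 degC, with each gene's printed log2 fold changes. Only the shared
genes were published; reconstructing each temperature's full top-50 set
therefore pads the remainder with per-condition placeholder IDs, which
by construction fall in the exclusive single-condition Venn regions.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_top50_table", "reconstruct_top50_sets"]

CONDITIONS = ("0C", "4C", "10C")
TOP_N = 50


def load_top50_table() -> pd.DataFrame:
    """The transcribed shared-gene table (region, gene_id, symbol, logFCs)."""
    with resources.files("coldseq.data").joinpath("top50_regions.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def reconstruct_top50_sets(n: int = TOP_N) -> dict:
    """Per-temperature top-50 gene sets rebuilt from the published regions.

    Each condition's set is the union of the published shared-region
    genes it participates in, padded to ``n`` with unique placeholder
    IDs standing in for the unpublished condition-exclusive genes.
    """
    table = load_top50_table()
    sets: dict[str, set] = {c: set() for c in CONDITIONS}
    for _, row in table.iterrows():
        for cond in row["region"].split("&"):
            sets[cond].add(row["gene_id"])
    for cond in CONDITIONS:
        short = n - len(sets[cond])
        if short < 0:
            raise ValueError(f"condition {cond} has more than {n} published genes")
        sets[cond].update(f"{cond}_unique_{i:02d}" for i in range(short))
    return sets
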