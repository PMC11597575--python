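"""Readers and writers for the pipeline's on-disk formats.

Counts travel as TSV (first column = gene IDs, header = sample IDs) or
MatrixMarket (.mtx plus <stem>.rows.txt / <stem>.cols.txt sidecars);
sample-to-condition labels as a two-column TSV; annotations as a
two-to-four-column TSV (term_id, gene_id[, name[, namespace]]) or a GAF
2.x subset; Ct tables as long-format TSV; configuration as YAML.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

from .containers import ConfigError, CountMatrix, GOAnnotation, GOTerm, TruthTable

__all__ = [
    "read_counts", "write_counts", "read_sample_conditions", "write_sample_conditions",
    "read_annotation", "write_annotation", "read_gaf",
    "read_ct_table", "write_ct_table", "read_truth", "write_truth",
    "read_config_yaml", "write_config_yaml",
]


def read_sample_conditions(path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "condition"]:
        raise ConfigError(
            f"{path}: expected header 'sample_id<TAB>condition', got {list(df.columns)}"
        )
    return df.set_index("sample_id")["condition"]


def write_sample_conditions(conditions: pd.Series, path) -> None:
    out = conditions.rename("condition").rename_axis("sample_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


def _read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    values = df.to_numpy()
    bad = ~np.isfinite(values.astype(float)) if np.issubdtype(values.dtype, np.number) else None
    if bad is None:
        for j, col in enumerate(df.columns):
            coerced = pd.to_numeric(df[col], errors="coerce")
            nan_rows = np.flatnonzero(coerced.isna())
            if nan_rows.size:
                i = nan_rows[0]
                raise ConfigError(
                    f"{path}: malformed numeric cell at line {i + 2}, column {j + 2} "
                    f"(gene {df.index[i]!r}, sample {col!r})"
                )
    neg = np.argwhere(values.astype(float) < 0)
    if neg.size:
        i, j = neg[0]
        raise ConfigError(
            f"{path}: negative count at line {i + 2}, column {j + 2} "
            f"(gene {df.index[i]!r}, sample {df.columns[j]!r})"
        )
    nonint = np.argwhere(~np.isclose(values.astype(float), np.round(values.astype(float))))
    if nonint.size:
        i, j = nonint[0]
        raise ConfigError(
            f"{path}: non-integer count at line {i + 2}, column {j + 2} "
            f"(gene {df.index[i]!r}, sample {df.columns[j]!r})"
        )
    return df


def _sidecars(path: Path) -> tuple[Path, Path]:
    stem = path.with_suffix("")
    return stem.with_suffix(".rows.txt"), stem.with_suffix(".cols.txt")


def _read_counts_mtx(path: Path) -> pd.DataFrame:
    rows_path, cols_path = _sidecars(path)
    for p in (rows_path, cols_path):
        if not p.exists():
            raise ConfigError(f"missing MatrixMarket sidecar {p}")
    mat = scipy.io.mmread(path)
    genes = rows_path.read_text().split()
    samples = cols_path.read_text().split()
    dense = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat)
    if dense.shape != (len(genes), len(samples)):
        raise ConfigError(
            f"{path}: matrix shape {dense.shape} does not match sidecars "
            f"({len(genes)} genes, {len(samples)} samples)"
        )
    return pd.DataFrame(dense, index=genes, columns=samples)


def read_counts(path, conditions=None) -> CountMatrix:
    """Load a CountMatrix from TSV or MatrixMarket.

    ``conditions`` is a mapping/Series sample -> condition, or a path to
    a sample-conditions TSV. Malformed cells are rejected with their
    file location.
    """
    path = Path(path)
    df = _read_counts_mtx(path) if path.suffix == ".mtx" else _read_counts_tsv(path)
    df.index.name = None
    df.columns.name = None
    if conditions is None:
        raise ConfigError("sample conditions are required to build a CountMatrix")
    if isinstance(conditions, (str, Path)):
        conditions = read_sample_conditions(conditions)
    return CountMatrix(df, conditions)


def write_counts(cm: CountMatrix, path, fmt: str = "tsv") -> None:
    path = Path(path)
    if fmt == "tsv":
        out = cm.counts.copy()
        out.insert(0, "gene_id", out.index)
        out.to_csv(path, sep="\t", index=False)
    elif fmt == "mtx":
        rows_path, cols_path = _sidecars(path)
        scipy.io.mmwrite(path, scipy.sparse.coo_matrix(cm.counts.to_numpy()))
        rows_path.write_text("\n".join(cm.gene_ids) + "\n")
        cols_path.write_text("\n".join(cm.sample_ids) + "\n")
    else:
        raise ConfigError(f"unknown counts format {fmt!r}")


def read_annotation(path) -> GOAnnotation:
    """Two-to-four-column TSV: term_id, gene_id[, name[, namespace]]."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="!")
    if df.shape[1] < 2:
        raise ConfigError(f"{path}: need at least term_id and gene_id columns")
    df = df.rename(columns={0: "term_id", 1: "gene_id", 2: "name", 3: "namespace"})
    # tolerate a header row
    if df.iloc[0]["term_id"] == "term_id":
        df = df.iloc[1:]
    terms = []
    for term_id, sub in df.groupby("term_id", sort=True):
        name = sub["name"].iloc[0] if "name" in sub and pd.notna(sub["name"].iloc[0]) else ""
        ns = (
            sub["namespace"].iloc[0]
            if "namespace" in sub and pd.notna(sub["namespace"].iloc[0])
            else "BP"
        )
        terms.append(GOTerm(term_id, frozenset(sub["gene_id"]), name=name, namespace=ns))
    return GOAnnotation(terms)


def write_annotation(annotation: GOAnnotation, path) -> None:
    annotation.to_frame().to_csv(path, sep="\t", index=False, header=False)


_GAF_ASPECT = {"P": "BP", "C": "CC", "F": "MF"}


def read_gaf(path) -> GOAnnotation:
    """GAF 2.x subset: column 2 = gene, column 5 = term, column 9 = aspect."""
    members: dict[str, set] = {}
    aspects: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("!"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 5:
                raise ConfigError(f"{path}: GAF line with fewer than 5 columns")
            gene, term = fields[1], fields[4]
            members.setdefault(term, set()).add(gene)
            if len(fields) > 8 and fields[8] in _GAF_ASPECT:
                aspects[term] = _GAF_ASPECT[fields[8]]
    return GOAnnotation(
        GOTerm(t, frozenset(g), namespace=aspects.get(t, "BP"))
        for t, g in sorted(members.items())
    )


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"condition", "gene", "replicate", "ct"}
    if not need.issubset(df.columns):
        raise ConfigError(f"{path}: Ct table needs columns {sorted(need)}")
    return df


def write_ct_table(ct: pd.DataFrame, path) -> None:
    ct.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_truth(truth: TruthTable, effects_path, terms_path=None) -> None:
    truth.effects.to_csv(effects_path, sep="\t", index=False, float_format="%.10g")
    if terms_path is not None:
        truth.terms.to_csv(terms_path, sep="\t", index=False, float_format="%.10g")


def read_truth(effects_path, terms_path=None) -> TruthTable:
    effects = pd.read_csv(effects_path, sep="\t")
    terms = (
        pd.read_csv(terms_path, sep="\t")
        if terms_path is not None
        else pd.DataFrame(columns=["term_id", "direction", "strength"])
    )
    return TruthTable(effects, terms)


def read_config_yaml(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: YAML config must be a mapping")
    return cfg


def write_config_yaml(config: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config, fh, sort_keys=True)
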