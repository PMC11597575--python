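"""End-to-end pipeline: DE per contrast -> top-N/Venn -> enrichment -> heatmap.

`run_pipeline` chains the stages on file inputs, writes every stage
output under an output directory, and returns a manifest (versions,
seed, thresholds, SHA-256 checksums of every file written). Any stage
failure aborts with the stage name and the underlying cause.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .containers import ConfigError
from .de import NBExactTest
from .enrichment import LogisticEnrichment, enrichment_heatmap_matrix
from .io import read_annotation, read_counts, read_ct_table
from .qpcr import anova_tukey, relative_expression
from .ranking import top_induced, venn_partition

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    counts_path: str
    samples_path: str
    out_dir: str
    control: str
    treatments: list
    annotation_path: str | None = None
    ct_path: str | None = None
    ct_reference_gene: str | None = None
    fdr: float = 0.01
    logcpm: float = 4.0
    top_n: int = 50
    min_term_size: int = 5
    seed: int = 0
    thresholds: dict = field(init=False)

    def __post_init__(self) -> None:
        if self.fdr <= 0 or self.logcpm is None or self.top_n <= 0 or self.min_term_size <= 0:
            raise ConfigError("thresholds must be positive")
        if not self.treatments:
            raise ConfigError("at least one treatment contrast is required")
        self.thresholds = {
            "fdr": self.fdr, "logcpm": self.logcpm,
            "top_n": self.top_n, "min_term_size": self.min_term_size,
        }


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute DE -> ranking/Venn -> enrichment -> heatmap and write outputs."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    @_stage("load")
    def load():
        cm = read_counts(config.counts_path, config.samples_path)
        ann = read_annotation(config.annotation_path) if config.annotation_path else None
        return cm, ann

    cm, annotation = load()

    @_stage("de")
    def run_de():
        results = {}
        for treat in config.treatments:
            res = NBExactTest(cm, config.control, treat).fit()
            path = out / f"de_{treat}.tsv"
            res.to_tsv(path)
            written.append(path)
            results[treat] = res
        return results

    de_results = run_de()

    @_stage("ranking")
    def run_ranking():
        tops = {
            t: top_induced(r, n=config.top_n, fdr_max=config.fdr, logcpm_min=config.logcpm)
            for t, r in de_results.items()
        }
        for t, ts in tops.items():
            path = out / f"top_{t}.tsv"
            path.write_text("gene_id\n" + "".join(g + "\n" for g in ts.gene_ids))
            written.append(path)
        part = None
        if len(tops) >= 2:
            part = venn_partition({t: set(ts.gene_ids) for t, ts in tops.items()})
            path = out / "venn_counts.json"
            part.to_json(path)
            written.append(path)
            for key, genes in sorted(part.regions.items(), key=part._sort_key):
                label = part._label(key).replace("&", "_")
                rpath = out / f"venn_region_{label}.tsv"
                rpath.write_text("gene_id\n" + "".join(g + "\n" for g in sorted(genes)))
                written.append(rpath)
        return tops, part

    tops, partition = run_ranking()

    enrich_tables = {}
    if annotation is not None:
        @_stage("enrichment")
        def run_enrichment():
            tables = {}
            for treat, res in de_results.items():
                er = LogisticEnrichment(res, annotation, config.min_term_size).fit()
                path = out / f"enrichment_{treat}.tsv"
                er.to_tsv(path)
                written.append(path)
                tables[treat] = er
            mat = enrichment_heatmap_matrix(tables, namespace="BP")
            path = out / "heatmap_BP.tsv"
            mat.to_csv(path, sep="\t", float_format="%.10g")
            written.append(path)
            return tables

        enrich_tables = run_enrichment()

    if config.ct_path is not None:
        @_stage("qpcr")
        def run_qpcr():
            ct = read_ct_table(config.ct_path)
            ref = config.ct_reference_gene
            if ref is None:
                raise ConfigError("ct_reference_gene is required with a Ct table")
            rel = relative_expression(ct, ref, control=config.control)
            rows = [rel.summary]
            path = out / "qpcr_summary.tsv"
            stats_lines = []
            for gene in rel.summary["gene"].unique():
                groups = {
                    c: rel.values(c, gene)
                    for c in rel.summary.loc[rel.summary["gene"] == gene, "condition"]
                }
                groups = {c: v for c, v in groups.items() if v.size >= 2}
                if len(groups) >= 2:
                    res = anova_tukey(groups)
                    stats_lines.append(f"# {gene}\n{res.summary()}\n")
            rows[0].to_csv(path, sep="\t", index=False, float_format="%.10g")
            written.append(path)
            spath = out / "qpcr_anova.txt"
            spath.write_text("".join(stats_lines))
            written.append(spath)

        run_qpcr()

    manifest = {
        "coldseq_version": __version__,
        "python": sys.version.split()[0],
        "seed": config.seed,
        "control": config.control,
        "treatments": list(config.treatments),
        "thresholds": config.thresholds,
        "de_results": [f"de_{t}.tsv" for t in config.treatments],
        "enrichment_tables": [f"enrichment_{t}.tsv" for t in enrich_tables],
        "files": {p.name: _sha256(p) for p in written},
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
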