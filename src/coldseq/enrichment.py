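"""Gene-set enrichment by logistic regression on a signed significance score.

For one contrast, every gene in the universe receives the score

    x = sign(logFC) * -log10(FDR)

so strongly induced genes sit far right, strongly repressed genes far
left, and null genes near zero. For each annotation term, membership
(y = 1 inside the term, 0 outside) is regressed on x with a
binomial-logit model

    logit P(y = 1) = beta0 + beta1 * x

fitted over the FULL gene universe, never over significant genes only.
A positive slope means the term's members concentrate among induced
genes. The per-term enrichment score is

    score = sign(beta1) * -log10(p_enrich)

with p_enrich from the likelihood-ratio test of the slope against the
intercept-only model (the default; the two-sided Wald p is available
via ``p_method="wald"``, but is anti-conservative when a handful of
strongly significant genes give x a heavy tail). Terms whose membership is
perfectly separated along x have no finite maximum-likelihood slope;
those fits fall back to Firth's Jeffreys-prior penalised likelihood and
are flagged ``fit_method="firth"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import chi2, norm

from .containers import ConfigError, GOAnnotation
from .de import DEResults, bh_fdr

__all__ = [
    "signed_score",
    "EnrichmentRecord",
    "fit_logistic_enrichment",
    "LogisticEnrichment",
    "EnrichmentResults",
    "enrich_all",
    "enrichment_heatmap_matrix",
    "top_bp",
]

FDR_FLOOR = 1e-300  # keeps -log10(FDR) finite when BH underflows
_SEPARATION_SLOPE = 30.0
_MAX_ITER = 100
_DEV_TOL = 1e-10


def signed_score(logfc, fdr, fdr_floor: float = FDR_FLOOR):
    """sign(logFC) * -log10(max(FDR, floor)); sign(0) = 0.

    Accepts scalars or arrays; raises if any FDR falls outside [0, 1].
    """
    logfc = np.asarray(logfc, dtype=float)
    fdr_arr = np.asarray(fdr, dtype=float)
    if np.any(fdr_arr < 0) or np.any(fdr_arr > 1) or np.any(~np.isfinite(fdr_arr)):
        raise ConfigError("FDR values must lie in [0, 1]")
    x = np.sign(logfc) * (-np.log10(np.maximum(fdr_arr, fdr_floor)))
    if x.ndim == 0:
        return float(x)
    return x


@dataclass
class EnrichmentRecord:
    term_id: str
    beta0: float
    beta1: float
    se1: float
    p_enrich: float
    score: float
    n_in: int
    n_out: int
    fit_method: str
    converged: bool
    name: str = ""
    namespace: str = "BP"


# ---------------------------------------------------------------------------
# Fitting machinery
# ---------------------------------------------------------------------------

def _irls(X: np.ndarray, y: np.ndarray):
    """Binomial-logit fit by iteratively reweighted least squares.

    Returns (beta, cov, deviance, converged, separated). Separation is
    flagged on a runaway slope, collapsing weights, or non-convergence.
    """
    beta = np.zeros(X.shape[1])
    dev_old = np.inf
    converged = separated = False
    cov = np.full((X.shape[1], X.shape[1]), np.nan)
    for _ in range(_MAX_ITER):
        eta = np.clip(X @ beta, -500, 500)
        p = expit(eta)
        w = p * (1.0 - p)
        if np.max(w) < 1e-10:
            separated = True
            break
        w = np.maximum(w, 1e-12)
        zvec = eta + (y - p) / w
        XtW = X.T * w
        info = XtW @ X
        try:
            beta = np.linalg.solve(info, XtW @ zvec)
        except np.linalg.LinAlgError:
            separated = True
            break
        with np.errstate(divide="ignore"):
            dev = -2.0 * np.sum(y * np.log(np.maximum(p, 1e-320))
                                + (1 - y) * np.log(np.maximum(1 - p, 1e-320)))
        if abs(beta[-1]) > _SEPARATION_SLOPE:
            separated = True
            break
        if abs(dev - dev_old) < _DEV_TOL:
            converged = True
            break
        dev_old = dev
    eta = np.clip(X @ beta, -500, 500)
    p = expit(eta)
    w = np.maximum(p * (1.0 - p), 1e-320)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        separated = True
    if not converged and not separated:
        separated = True  # treat non-convergence like separation: refit penalised
    with np.errstate(divide="ignore"):
        dev = -2.0 * np.sum(y * np.log(np.maximum(p, 1e-320))
                            + (1 - y) * np.log(np.maximum(1 - p, 1e-320)))
    return beta, cov, dev, converged, separated


def _firth(X: np.ndarray, y: np.ndarray):
    """Firth-penalised logistic fit (Jeffreys prior), Newton with step-halving."""
    beta = np.zeros(X.shape[1])

    def penalised_ll(b):
        eta = np.clip(X @ b, -500, 500)
        p = expit(eta)
        w = np.maximum(p * (1 - p), 1e-320)
        info = (X.T * w) @ X
        sign, logdet = np.linalg.slogdet(info)
        if sign <= 0:
            return -np.inf
        with np.errstate(divide="ignore"):
            ll = np.sum(y * np.log(np.maximum(p, 1e-320))
                        + (1 - y) * np.log(np.maximum(1 - p, 1e-320)))
        return ll + 0.5 * logdet

    ll_old = penalised_ll(beta)
    converged = False
    for _ in range(_MAX_ITER):
        eta = np.clip(X @ beta, -500, 500)
        p = expit(eta)
        w = np.maximum(p * (1 - p), 1e-320)
        XtW = X.T * w
        info = XtW @ X
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of the weighted design
        h = np.einsum("ij,jk,ik->i", X, info_inv, X) * w
        score = X.T @ (y - p + h * (0.5 - p))
        step = info_inv @ score
        lam = 1.0
        for _ in range(30):
            cand = beta + lam * step
            ll_new = penalised_ll(cand)
            if ll_new >= ll_old - 1e-12:
                break
            lam *= 0.5
        beta = beta + lam * step
        if abs(ll_new - ll_old) < 1e-10 and np.linalg.norm(lam * step) < 1e-8:
            converged = True
            ll_old = ll_new
            break
        ll_old = ll_new
    eta = np.clip(X @ beta, -500, 500)
    p = expit(eta)
    w = np.maximum(p * (1 - p), 1e-320)
    info = (X.T * w) @ X
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(info)
    return beta, cov, converged


def fit_logistic_enrichment(
    x, members, gene_ids=None, term_id: str = "", p_method: str = "lrt",
    name: str = "", namespace: str = "BP",
) -> EnrichmentRecord:
    """Fit one term's membership-on-score logistic model.

    Parameters
    ----------
    x
        Signed scores; a pandas Series indexed by gene ID, or an array
        accompanied by ``gene_ids``.
    members
        Gene IDs belonging to the term; must be a strict non-empty
        subset of the universe.
    p_method
        "lrt" (default): likelihood-ratio test against the
        intercept-only model; "wald": two-sided Wald p on the slope.
    """
    if isinstance(x, pd.Series):
        gene_ids = x.index
        xv = x.to_numpy(dtype=float)
    else:
        xv = np.asarray(x, dtype=float)
        if gene_ids is None:
            raise ConfigError("gene_ids required when x is not a Series")
    members = set(members)
    y = np.fromiter((g in members for g in gene_ids), dtype=float, count=len(gene_ids))
    return _fit_term(xv, y, term_id=term_id, p_method=p_method,
                     name=name, namespace=namespace)


def _fit_term(xv: np.ndarray, y: np.ndarray, term_id: str, p_method: str,
              name: str = "", namespace: str = "BP") -> EnrichmentRecord:
    n_in = int(y.sum())
    n_out = int(y.size - n_in)
    if n_in == 0 or n_out == 0:
        raise ConfigError(
            f"degenerate term {term_id or '<anon>'}: {n_in} of {y.size} genes are members"
        )

    X = np.column_stack([np.ones_like(xv), xv])
    beta, cov, dev, converged, separated = _irls(X, y)
    fit_method = "irls"
    if separated:
        beta, cov, converged = _firth(X, y)
        fit_method = "firth"

    se1 = float(np.sqrt(max(cov[1, 1], 0.0)))
    if p_method == "wald":
        zstat = beta[1] / se1 if np.isfinite(se1) and se1 > 0 else 0.0
        p_enrich = float(2.0 * norm.sf(abs(zstat)))
    elif p_method == "lrt":
        if fit_method == "firth":
            # penalised null fit for a comparable deviance
            b0, _, _ = _firth(X[:, :1], y)
            eta0 = np.clip(X[:, :1] @ b0, -500, 500)
        else:
            p_bar = np.clip(y.mean(), 1e-320, 1 - 1e-16)
            eta0 = np.full_like(y, np.log(p_bar / (1 - p_bar)))
        p0 = expit(eta0)
        with np.errstate(divide="ignore"):
            dev0 = -2.0 * np.sum(y * np.log(np.maximum(p0, 1e-320))
                                 + (1 - y) * np.log(np.maximum(1 - p0, 1e-320)))
        eta1 = np.clip(X @ beta, -500, 500)
        p1 = expit(eta1)
        with np.errstate(divide="ignore"):
            dev1 = -2.0 * np.sum(y * np.log(np.maximum(p1, 1e-320))
                                 + (1 - y) * np.log(np.maximum(1 - p1, 1e-320)))
        p_enrich = float(chi2.sf(max(dev0 - dev1, 0.0), df=1))
    else:
        raise ConfigError(f"unknown p_method {p_method!r}")
    p_enrich = max(p_enrich, 5e-324)

    score = float(np.sign(beta[1]) * -np.log10(p_enrich))
    return EnrichmentRecord(
        term_id=term_id, beta0=float(beta[0]), beta1=float(beta[1]), se1=se1,
        p_enrich=p_enrich, score=score, n_in=n_in, n_out=n_out,
        fit_method=fit_method, converged=bool(converged),
        name=name, namespace=namespace,
    )


# ---------------------------------------------------------------------------
# Model / Results surface
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "term_id", "name", "namespace", "n_in", "beta0", "beta1", "se1",
    "p_enrich", "score", "fit_method",
]


class EnrichmentResults:
    """Per-term enrichment table for one contrast."""

    def __init__(self, frame: pd.DataFrame, condition: str, skipped: list) -> None:
        self.frame = frame
        self.condition = condition
        self.skipped = skipped  # (term_id, reason) pairs

    def summary(self, k: int = 5) -> str:
        f = self.frame
        lines = [
            f"Logistic enrichment: {self.condition} ({len(f)} terms fitted, "
            f"{len(self.skipped)} skipped)",
        ]
        top, _ = top_bp(f, k=k, direction="induced")
        for t in top:
            row = f.set_index("term_id").loc[t]
            lines.append(
                f"  {t}  score={row['score']:+.2f}  beta1={row['beta1']:+.3f}  {row['name']}"
            )
        return "\n".join(lines)

    def top_bp(self, k: int = 5, direction: str = "induced"):
        return top_bp(self.frame, k=k, direction=direction)

    def to_tsv(self, path) -> None:
        self.frame[RESULT_COLUMNS].to_csv(
            path, sep="\t", index=False, float_format="%.10g"
        )


class LogisticEnrichment:
    """Membership-on-signed-score logistic enrichment over an annotation.

    Parameters
    ----------
    de
        DE results of one contrast; defines the gene universe and, via
        logFC and FDR, the per-gene signed score.
    annotation
        GOAnnotation whose terms are tested one by one.
    min_term_size
        Terms with fewer in-universe members (or fewer non-members) are
        skipped with a recorded reason.
    """

    def __init__(self, de: DEResults, annotation: GOAnnotation,
                 min_term_size: int = 5, fdr_floor: float = FDR_FLOOR) -> None:
        self.de = de
        self.annotation = annotation
        self.min_term_size = min_term_size
        self.x = pd.Series(
            signed_score(de.frame["logFC"], de.frame["FDR"], fdr_floor),
            index=de.frame.index, name="x",
        )

    def fit(self, p_method: str = "lrt") -> EnrichmentResults:
        pos = {g: i for i, g in enumerate(self.x.index)}
        n_uni = len(pos)
        xv = self.x.to_numpy()
        records, skipped = [], []
        for term in self.annotation:
            idx = [pos[g] for g in term.genes if g in pos]
            if len(idx) < self.min_term_size:
                skipped.append((term.term_id, "too few in-universe members"))
                continue
            if len(idx) > n_uni - self.min_term_size:
                skipped.append((term.term_id, "covers nearly the whole universe"))
                continue
            y = np.zeros(n_uni)
            y[idx] = 1.0
            rec = _fit_term(
                xv, y, term_id=term.term_id, p_method=p_method,
                name=term.name, namespace=term.namespace,
            )
            records.append(rec)
        frame = pd.DataFrame([r.__dict__ for r in records])
        if not frame.empty:
            frame["fdr_enrich"] = bh_fdr(frame["p_enrich"])  # extra column, not used in ranking
        return EnrichmentResults(frame, self.de.treatment, skipped)


def enrich_all(
    de: DEResults, annotation: GOAnnotation, min_term_size: int = 5,
    fdr_floor: float = FDR_FLOOR, p_method: str = "lrt",
) -> EnrichmentResults:
    """Functional shorthand for ``LogisticEnrichment(...).fit()``."""
    return LogisticEnrichment(de, annotation, min_term_size, fdr_floor).fit(p_method)


def enrichment_heatmap_matrix(tables: dict, namespace: str = "BP") -> pd.DataFrame:
    """Terms x conditions matrix of enrichment scores in one namespace.

    Rows are the union of the namespace's terms over all conditions;
    a term absent from one condition's table contributes 0 there.
    """
    if not tables:
        raise ConfigError("need at least one condition table")
    cols = {}
    for cond, res in tables.items():
        frame = res.frame if isinstance(res, EnrichmentResults) else res
        if frame.empty:
            cols[cond] = pd.Series(dtype=float)
        else:
            sub = frame[frame["namespace"] == namespace]
            cols[cond] = sub.set_index("term_id")["score"]
    mat = pd.DataFrame(cols).fillna(0.0)
    mat.index.name = "term_id"
    return mat.sort_index()


def top_bp(table, k: int = 5, direction: str = "induced"):
    """Top-k biological-process terms by enrichment score.

    "induced" returns the k largest positive scores descending,
    "repressed" the k most negative ascending; ties break on term ID.
    Returns (term_ids, complete) where complete is False when fewer
    than k terms qualify.
    """
    frame = table.frame if isinstance(table, EnrichmentResults) else table
    if direction not in {"induced", "repressed"}:
        raise ConfigError(f"unknown direction {direction!r}")
    if frame.empty:
        return [], False
    sub = frame[frame["namespace"] == "BP"] if "namespace" in frame else frame
    if direction == "induced":
        qual = sub[sub["score"] > 0].sort_values(
            ["score", "term_id"], ascending=[False, True], kind="stable"
        )
    else:
        qual = sub[sub["score"] < 0].sort_values(
            ["score", "term_id"], ascending=[True, True], kind="stable"
        )
    ids = qual["term_id"].head(k).tolist()
    return ids, len(ids) == k
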