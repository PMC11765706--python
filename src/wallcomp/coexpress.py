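"""Transcriptomic rule set: normalization, thresholds, clustering, networks.

Expression is measured in total gene reads (TGR, the sum of reads mapped to
a gene's coding region).  The rules implemented here:

* **Normalization** — per-gene geometric means over samples form the
  reference profile; each sample's size factor is the median of its
  value/reference ratios (the median-of-ratios scheme); normalized values
  are counts divided by the size factor.  A literal variant that only
  rescales each gene by its geometric mean is available for sensitivity
  analysis (``method='gene_gm'``).
* **Expressed genes** — normalized TGR >= 16 in at least one sample
  (boundary inclusive).
* **DEG calls** — expressed in the contrast (max TGR >= 16), fold change
  >= 2 in either direction, and adjusted p <= 0.01.  The adjusted p-value
  is always an input column, never computed here.
* **Clustering** — k-means on correlation distance (1 - Pearson r between
  gene profiles); rows are standardized to zero mean and unit norm so that
  Euclidean Lloyd steps minimize correlation distance exactly.
* **Networks** — pairwise Pearson r with two-sided p-values from the
  t transform (df = n - 2), significance masked at alpha = 0.01;
  connectivity ranking raises |r| to a soft-threshold power (default 5)
  over each gene's significant partners.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .composition_io import ValidationError

EXPRESSED_TGR = 16.0
DEG_FOLD = 2.0
DEG_PADJ = 0.01
NETWORK_ALPHA = 0.01
SOFT_THRESHOLD = 5.0


@dataclass(frozen=True)
class ExpressionMatrix:
    """Gene x sample TGR values with per-sample group labels."""

    values: pd.DataFrame
    sample_groups: dict[str, str] = field(default_factory=dict)
    normalized: bool = False
    size_factors: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValidationError("TGR values must be non-negative")
        if self.size_factors is not None and (self.size_factors <= 0).any():
            raise ValidationError("size factors must be positive")
        unknown = set(self.sample_groups) - set(self.values.columns)
        if unknown:
            raise ValidationError(f"sample_groups for unknown samples: {unknown}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups.get(s) == group]


@dataclass(frozen=True)
class DEGCall:
    gene: str
    contrast: tuple[str, str]
    fold_change: float
    direction: str  # "up" means higher in contrast[1]
    max_tgr: float
    padj: float
    is_deg: bool


@dataclass(frozen=True)
class CoexpressionNetwork:
    """Pairwise Pearson r, p-values and the alpha-significance mask."""

    nodes: list[str]
    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    alpha: float
    n_samples: int


def normalize_tgr(
    m: ExpressionMatrix, *, method: str = "median_of_ratios"
) -> ExpressionMatrix:
    """Size-factor normalization of a TGR matrix.

    ``median_of_ratios``: reference = per-gene geometric mean across
    samples (genes with any zero excluded from the reference); size factor
    of a sample = median over reference genes of value/reference;
    normalized value = value / factor.  Idempotent and invariant to
    per-sample scaling.

    ``gene_gm``: literal per-gene rescaling by the gene's own geometric
    mean (no sample size factors); provided for sensitivity analysis only.
    """
    vals = m.values.astype(float)
    if vals.shape[1] < 2:
        raise ValidationError("need at least 2 samples to normalize")
    if method == "gene_gm":
        pos = (vals > 0).all(axis=1)
        gm = np.exp(np.log(vals[pos]).mean(axis=1))
        out = vals.copy()
        out.loc[pos] = vals[pos].div(gm, axis=0)
        return replace(m, values=out, normalized=True, size_factors=None)
    if method != "median_of_ratios":
        raise ValidationError(f"unknown normalization method {method!r}")

    pos = (vals > 0).all(axis=1)
    if not pos.any():
        raise ValidationError(
            "no gene has all-positive values; cannot form the geometric-mean "
            "reference (consider a pseudo-reference fallback flag)"
        )
    log_ref = np.log(vals[pos]).mean(axis=1)
    ratios = np.log(vals[pos]).sub(log_ref, axis=0)
    factors = np.exp(ratios.median(axis=0))
    # anchor the factors at geometric mean 1 so normalization is idempotent
    factors = factors / np.exp(np.log(factors).mean())
    out = vals.div(factors, axis=1)
    return replace(
        m,
        values=out,
        normalized=True,
        size_factors=pd.Series(factors, index=vals.columns),
    )


def filter_expressed(
    m: ExpressionMatrix, threshold: float = EXPRESSED_TGR
) -> list[str]:
    """Genes whose normalized TGR reaches ``threshold`` in >= 1 sample.

    The boundary is inclusive: a row maximum of exactly 16 is kept.
    """
    mx = m.values.max(axis=1)
    return list(m.values.index[mx >= threshold])


def call_degs(
    m: ExpressionMatrix,
    padj_table: pd.DataFrame,
    contrasts: list[tuple[str, str]],
    *,
    fold_threshold: float = DEG_FOLD,
    padj_threshold: float = DEG_PADJ,
    tgr_threshold: float = EXPRESSED_TGR,
    pseudocount: float = 0.0,
) -> list[DEGCall]:
    """Joint-threshold DEG calls on a (normalized) TGR matrix.

    A gene is a DEG for a contrast iff its maximum TGR over the contrast's
    samples is >= 16, the ratio of the larger to the smaller group mean is
    >= 2 (direction recorded), and the externally supplied adjusted p-value
    is <= 0.01.  All three boundaries are inclusive.  A zero group mean is
    an error unless a positive ``pseudocount`` is supplied (added to both
    means, with a warning).
    """
    calls: list[DEGCall] = []
    for a, b in contrasts:
        col = f"{a}_vs_{b}"
        if col not in padj_table.columns:
            raise ValidationError(f"padj table lacks contrast column {col!r}")
        sa = m.group_samples(a)
        sb = m.group_samples(b)
        if not sa or not sb:
            missing = a if not sa else b
            raise ValidationError(f"no samples for group {missing!r}")
        va = m.values[sa].astype(float)
        vb = m.values[sb].astype(float)
        mean_a = va.mean(axis=1)
        mean_b = vb.mean(axis=1)
        max_tgr = pd.concat([va, vb], axis=1).max(axis=1)
        for gene in m.values.index:
            if gene not in padj_table.index:
                raise ValidationError(f"padj missing for gene {gene!r}")
            ma, mb = float(mean_a[gene]), float(mean_b[gene])
            if min(ma, mb) == 0.0:
                if max(ma, mb) == 0.0:
                    fold = 1.0
                elif pseudocount > 0.0:
                    _warnings.warn(
                        f"gene {gene}: pseudocount {pseudocount} applied",
                        stacklevel=2,
                    )
                    fold = (max(ma, mb) + pseudocount) / pseudocount
                else:
                    raise ValidationError(
                        f"gene {gene!r}: zero group mean; set a pseudocount "
                        "to compute a finite fold change"
                    )
            else:
                fold = max(ma, mb) / min(ma, mb)
            padj = float(padj_table.loc[gene, col])
            is_deg = (
                float(max_tgr[gene]) >= tgr_threshold
                and fold >= fold_threshold
                and padj <= padj_threshold
            )
            calls.append(
                DEGCall(
                    gene=gene,
                    contrast=(a, b),
                    fold_change=fold,
                    direction="up" if mb >= ma else "down",
                    max_tgr=float(max_tgr[gene]),
                    padj=padj,
                    is_deg=is_deg,
                )
            )
    return calls


def _standardize_rows(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-norm rows: Euclidean distance == sqrt(2(1 - r))."""
    centered = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1, keepdims=True)
    return centered / norms


def kmeans_pearson(
    m: ExpressionMatrix,
    k: int,
    seed: int = 0,
    n_restarts: int = 10,
) -> dict[str, int]:
    """K-means on correlation distance between gene expression profiles.

    Rows are standardized (zero mean, unit norm) so that squared Euclidean
    distance equals 2(1 - Pearson r) and ordinary Lloyd iterations minimize
    within-cluster correlation distance.  Constant rows have no correlation
    profile and are excluded with a warning.  Best of ``n_restarts``
    initializations; reproducible under ``seed``.
    """
    if k < 2:
        raise ValidationError("k must be >= 2")
    vals = m.values.astype(float)
    variable = vals.std(axis=1) > 0
    dropped = list(vals.index[~variable])
    if dropped:
        _warnings.warn(
            f"{len(dropped)} constant gene(s) excluded from clustering",
            stacklevel=2,
        )
    vals = vals[variable]
    if len(vals) < k:
        raise ValidationError(f"only {len(vals)} variable genes for k={k}")

    from sklearn.cluster import KMeans

    x = _standardize_rows(vals.to_numpy())
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    labels = km.fit_predict(x)
    return dict(zip(vals.index, (int(c) for c in labels)))


def correlation_network(
    m: ExpressionMatrix,
    genes: list[str] | None = None,
    alpha: float = NETWORK_ALPHA,
) -> CoexpressionNetwork:
    """Pairwise Pearson coexpression with a significance mask at ``alpha``.

    Two-sided p-values come from the exact t transform
    ``t = r sqrt((n-2)/(1-r^2))`` with n - 2 degrees of freedom.  Pairs
    failing the mask correspond to the "X" (insignificant) labels of
    correlation plots.  Constant genes are excluded with a warning.
    """
    vals = m.values.astype(float)
    if genes is not None:
        missing = [g for g in genes if g not in vals.index]
        if missing:
            raise ValidationError(f"genes not in matrix: {missing}")
        vals = vals.loc[genes]
    n = vals.shape[1]
    if n < 3:
        raise ValidationError("need >= 3 samples for correlation p-values")
    variable = vals.std(axis=1) > 0
    if (~variable).any():
        _warnings.warn(
            f"{int((~variable).sum())} constant gene(s) excluded from the "
            "network",
            stacklevel=2,
        )
        vals = vals[variable]
    if len(vals) == 0:
        raise ValidationError("no variable genes left for the network")

    r = np.corrcoef(vals.to_numpy())
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    r = np.clip(r, -1.0, 1.0)
    df = n - 2
    with np.errstate(divide="ignore"):
        t = r * np.sqrt(df / np.clip(1.0 - r * r, 1e-300, None))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(p, 0.0)
    mask = p < alpha
    np.fill_diagonal(mask, False)
    return CoexpressionNetwork(
        nodes=list(vals.index),
        r=r,
        p=p,
        mask=mask,
        alpha=alpha,
        n_samples=n,
    )


def top_coexpressed(
    net: CoexpressionNetwork,
    n: int = 10,
    beta: float = SOFT_THRESHOLD,
) -> list[str]:
    """Rank genes by soft-threshold connectivity; return the top ``n``.

    Connectivity of gene i = sum over significant partners j of |r_ij|^beta.
    Ties break lexicographically by gene id.  Genes with no significant
    partner score 0 and are omitted; if ``n`` exceeds the number of scored
    genes, all of them are returned with a warning.
    """
    if len(net.nodes) == 0:
        raise ValidationError("empty network")
    score = (np.abs(net.r) ** beta * net.mask).sum(axis=1)
    scored = [(g, s) for g, s in zip(net.nodes, score) if s > 0]
    scored.sort(key=lambda gs: (-gs[1], gs[0]))
    if n > len(scored):
        _warnings.warn(
            f"requested top {n} but only {len(scored)} genes have "
            "significant partners",
            stacklevel=2,
        )
    return [g for g, _ in scored[:n]]


def network_to_edges(net: CoexpressionNetwork) -> pd.DataFrame:
    """Edge-list view (gene_a, gene_b, r, p, significant), i < j pairs."""
    rows = []
    for i, gi in enumerate(net.nodes):
        for j in range(i + 1, len(net.nodes)):
            rows.append(
                {
                    "gene_a": gi,
                    "gene_b": net.nodes[j],
                    "r": net.r[i, j],
                    "p": net.p[i, j],
                    "significant": bool(net.mask[i, j]),
                }
            )
    return pd.DataFrame(rows)


def read_expression_tsv(path, metadata: pd.DataFrame | None = None) -> ExpressionMatrix:
    """Genes-as-rows TSV (header = sample ids) into an ExpressionMatrix."""
    values = pd.read_csv(path, sep="\t", index_col=0)
    groups: dict[str, str] = {}
    if metadata is not None:
        for _, row in metadata.iterrows():
            groups[str(row["sample_id"])] = str(row["group"])
    return ExpressionMatrix(values=values, sample_groups=groups)


__all__ = [
    "EXPRESSED_TGR",
    "DEG_FOLD",
    "DEG_PADJ",
    "NETWORK_ALPHA",
    "SOFT_THRESHOLD",
    "ExpressionMatrix",
    "DEGCall",
    "CoexpressionNetwork",
    "normalize_tgr",
    "filter_expressed",
    "call_degs",
    "kmeans_pearson",
    "correlation_network",
    "top_coexpressed",
    "network_to_edges",
    "read_expression_tsv",
]
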