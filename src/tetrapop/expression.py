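"""Expression-count normalization, BGS expression classification, the
flowering-time correlation scan, and qPCR relative-expression arithmetic.

Counts are normalized for sequencing depth with median-of-ratios size
factors (each sample's median ratio to the per-gene geometric-mean
pseudo-reference, over genes with non-zero counts in every sample). The
focal population's expression state is classified per gene with a
post-hoc Tukey honest-significance test of a one-way ANOVA across the
three classes {BGS, MT, RW}:

* differentially expressed (DE): p(RW-MT) < 0.05;
* mountain-like in BGS:  DE and p(BGS-RW) < 0.05 and p(BGS-MT) > 0.5;
* railway-like in BGS:   DE and p(BGS-RW) > 0.5 and p(BGS-MT) < 0.05;
* otherwise intermediate/unclassified.

The p > 0.5 "similarity" criterion is a Tukey p-value threshold taken at
face value, not an equivalence test. Unbalanced classes use the
Tukey-Kramer adjustment (scipy's studentized-range implementation).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


def normalize_counts(counts: pd.DataFrame):
    """Median-of-ratios depth normalization.

    Returns ``(normalized, size_factors)``. Requires at least one gene
    with non-zero counts in every sample (the pseudo-reference genes).
    """
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        raise ValueError(
            "no gene has non-zero counts in every sample; cannot form the "
            "median-of-ratios pseudo-reference"
        )
    logref = np.log(mat[all_nonzero]).mean(axis=1)
    ratios = np.log(mat[all_nonzero]) - logref[:, None]
    size_factors = pd.Series(
        np.exp(np.median(ratios, axis=0)), index=counts.columns, name="size_factor"
    )
    normalized = counts / size_factors
    return normalized, size_factors


def top_variable_pca(normalized: pd.DataFrame, n_genes: int = 500):
    """PCA of the samples on the most variable genes.

    Returns ``(coordinates, variance_explained)``: sample coordinates on
    the principal components and the percentage of variance each explains.
    """
    if normalized.shape[1] < 3:
        raise ValueError("need at least three samples for a PCA")
    variances = normalized.var(axis=1)
    if n_genes > len(variances):
        logger.warning(
            "requested %d genes but only %d available; using all",
            n_genes,
            len(variances),
        )
        n_genes = len(variances)
    top = variances.nlargest(n_genes).index
    X = normalized.loc[top].to_numpy(dtype=float).T  # samples x genes
    X = X - X.mean(axis=0)
    u, s, _ = np.linalg.svd(X, full_matrices=False)
    coords = u * s
    var_exp = 100.0 * s**2 / (s**2).sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=normalized.columns, columns=cols), var_exp


@dataclass
class ClassCounts:
    n_de: int
    n_mountain_like: int
    n_railway_like: int


def _class_arrays(normalized, sample_classes, gene_row):
    groups = {"BGS": [], "MT": [], "RW": []}
    for sample, cls in sample_classes.items():
        groups[cls].append(gene_row[sample])
    return {k: np.asarray(v, dtype=float) for k, v in groups.items()}


def tukey_classify(
    normalized: pd.DataFrame,
    sample_classes: dict,
    de_alpha: float = 0.05,
    similar_p: float = 0.5,
):
    """Per-gene ANOVA + Tukey HSD classification of BGS expression state.

    *sample_classes* maps sample names to 'BGS', 'MT' or 'RW' (each class
    needs >= 2 replicates). Genes with zero within-class variance in every
    class are skipped with a log entry. Returns ``(table, counts)``.
    """
    classes = set(sample_classes.values())
    if classes != {"BGS", "MT", "RW"}:
        raise ValueError("sample classes must be exactly {BGS, MT, RW}")
    members = {c: [s for s, k in sample_classes.items() if k == c] for c in classes}
    for c, names in members.items():
        if len(names) < 2:
            raise ValueError(f"class {c} has fewer than 2 replicates")

    cols = {c: [normalized.columns.get_loc(s) for s in members[c]] for c in classes}
    mat = normalized.to_numpy(dtype=float)
    rows = []
    for i, gene in enumerate(normalized.index):
        bgs = mat[i, cols["BGS"]]
        mt = mat[i, cols["MT"]]
        rw = mat[i, cols["RW"]]
        if bgs.var() == 0 and mt.var() == 0 and rw.var() == 0:
            logger.info("gene %s skipped: zero within-class variance", gene)
            continue
        anova_p = float(stats.f_oneway(bgs, mt, rw).pvalue)
        hsd = stats.tukey_hsd(bgs, mt, rw)  # order: BGS, MT, RW
        p_bgs_mt = float(hsd.pvalue[0, 1])
        p_bgs_rw = float(hsd.pvalue[0, 2])
        p_rw_mt = float(hsd.pvalue[1, 2])
        de = p_rw_mt < de_alpha
        if de and p_bgs_rw < de_alpha and p_bgs_mt > similar_p:
            cls = "mountain_like"
        elif de and p_bgs_rw > similar_p and p_bgs_mt < de_alpha:
            cls = "railway_like"
        elif de:
            cls = "intermediate"
        else:
            cls = "not_de"
        rows.append(
            {
                "gene": gene,
                "anova_p": anova_p,
                "p_rw_mt": p_rw_mt,
                "p_bgs_rw": p_bgs_rw,
                "p_bgs_mt": p_bgs_mt,
                "de": de,
                "bgs_class": cls,
            }
        )
    table = pd.DataFrame(rows)
    counts = ClassCounts(
        n_de=int(table["de"].sum()) if len(table) else 0,
        n_mountain_like=int((table["bgs_class"] == "mountain_like").sum())
        if len(table)
        else 0,
        n_railway_like=int((table["bgs_class"] == "railway_like").sum())
        if len(table)
        else 0,
    )
    return table, counts


def flowering_correlation_scan(
    normalized: pd.DataFrame,
    sample_populations: dict,
    flowering_time: dict,
    classification: pd.DataFrame,
    exclude: str = "BGS",
    min_count: float = 10.0,
    de_alpha: float = 0.05,
    top_fraction: float = 0.01,
) -> pd.DataFrame:
    """Genes whose population-mean expression tracks flowering time.

    Genes are filtered to a normalized count above *min_count* in at least
    one sample and to railway-mountain differential expression
    (``p_rw_mt < de_alpha`` from *classification*); the Pearson
    correlation between per-population mean expression and the
    populations' mean flowering times is computed with the *exclude*
    population left out, and the top *top_fraction* of filtered genes by
    |r| is returned, ranked.
    """
    pops = [p for p in sorted(set(sample_populations.values())) if p != exclude]
    if len(pops) < 4:
        raise ValueError("need at least four populations after exclusion")
    missing_ft = [p for p in pops if p not in flowering_time]
    if missing_ft:
        raise KeyError(f"no flowering time for populations {missing_ft}")

    expressed = (normalized > min_count).any(axis=1)
    de_genes = set(classification.loc[classification["p_rw_mt"] < de_alpha, "gene"])
    genes = [g for g in normalized.index[expressed] if g in de_genes]
    if not genes:
        return pd.DataFrame(columns=["gene", "r"])

    pop_means = pd.DataFrame(
        {
            p: normalized[
                [s for s, q in sample_populations.items() if q == p]
            ].mean(axis=1)
            for p in pops
        }
    )
    ft = np.array([flowering_time[p] for p in pops], dtype=float)
    sub = pop_means.loc[genes].to_numpy(dtype=float)
    xc = sub - sub.mean(axis=1, keepdims=True)
    yc = ft - ft.mean()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / np.sqrt((xc**2).sum(axis=1) * (yc**2).sum())
    table = pd.DataFrame({"gene": genes, "r": r}).dropna()
    n_top = max(int(np.floor(len(table) * top_fraction)), 1)
    return (
        table.reindex(table["r"].abs().sort_values(ascending=False).index)
        .head(n_top)
        .reset_index(drop=True)
    )


def residual_outlier_p(
    x_included,
    y_included,
    x_excluded: float,
    y_excluded: float,
    residual: str = "orthogonal",
):
    """Two-tailed p for an excluded point's residual about a fitted trend.

    A line is fitted to the included points (total least squares for
    ``residual="orthogonal"``, i.e. residuals are orthogonal distances to
    the line; OLS for ``residual="vertical"``). The excluded point's
    residual is compared to a Normal(0, sigma) null with sigma the RMS of
    the included points' residuals about zero:
    ``p = 2 (1 - Phi(|d| / sigma))``.
    """
    x = np.asarray(x_included, dtype=float)
    y = np.asarray(y_included, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least three included points")
    if residual == "orthogonal":
        pts = np.column_stack([x, y])
        center = pts.mean(axis=0)
        _, _, vt = np.linalg.svd(pts - center)
        direction = vt[0]
        normal = np.array([-direction[1], direction[0]])
        d_in = (pts - center) @ normal
        d_ex = float((np.array([x_excluded, y_excluded]) - center) @ normal)
    elif residual == "vertical":
        slope, intercept = np.polyfit(x, y, 1)
        d_in = y - (slope * x + intercept)
        d_ex = float(y_excluded - (slope * x_excluded + intercept))
    else:
        raise ValueError("residual must be 'orthogonal' or 'vertical'")
    sigma = float(np.sqrt(np.mean(d_in**2)))
    if sigma < 1e-12:
        logger.warning("zero residual spread among included points")
        return 1.0 if abs(d_ex) < 1e-9 else 0.0
    return float(2.0 * stats.norm.sf(abs(d_ex) / sigma))


def qpcr_relative_expression(
    ct_target_sample,
    ct_target_calibrator,
    ct_ref_sample,
    ct_ref_calibrator,
    efficiency_target: float,
    efficiency_ref: float,
):
    """Efficiency-corrected relative expression with delta-method SD.

    Implements the 2^-ddCt idea with per-primer efficiencies E (fractions,
    e.g. 0.87): amplification per cycle is (1+E), so

        ratio = (1+E_t)^(-dCt_t) / (1+E_r)^(-dCt_r),

    with dCt the sample-minus-calibrator difference of mean Ct over
    technical replicates. The SD is first-order error propagation of the
    replicate Ct variances through log-ratio space. Returns
    ``(ratio, sd)``.
    """
    for e in (efficiency_target, efficiency_ref):
        if not 0.0 < e <= 1.5:
            raise ValueError(f"primer efficiency {e} outside (0, 1.5]")
    groups = [
        np.asarray(g, dtype=float)
        for g in (ct_target_sample, ct_target_calibrator, ct_ref_sample,
                  ct_ref_calibrator)
    ]
    if any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 technical replicates per well group")
    ts, tc, rs, rc = groups
    dct_t = ts.mean() - tc.mean()
    dct_r = rs.mean() - rc.mean()
    lt = np.log(1.0 + efficiency_target)
    lr = np.log(1.0 + efficiency_ref)
    ratio = float(np.exp(-dct_t * lt + dct_r * lr))
    var_dct_t = ts.var(ddof=1) / len(ts) + tc.var(ddof=1) / len(tc)
    var_dct_r = rs.var(ddof=1) / len(rs) + rc.var(ddof=1) / len(rc)
    var_log = lt**2 * var_dct_t + lr**2 * var_dct_r
    return ratio, float(ratio * np.sqrt(var_log))
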