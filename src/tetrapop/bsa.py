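"""Bulked-segregant / F2 single-marker QTL mapping.

Each marker is tested by ordinary least squares of the phenotype on a
genetic encoding of its tetraploid dosage — additive (the dosage itself),
dominant (any copy present) or recessive (all four copies) — and the model
with the highest LOD is kept. LOD is the classical OLS form

    LOD = (n/2) * log10(RSS_null / RSS_model) = -(n/2) * log10(1 - R^2),

with the F-test p-value of the regression reported alongside. Missing
genotypes drop only that marker's rows (pairwise deletion); censored
phenotypes enter at the censoring cutoff by default. Genome-wide
significance comes from phenotype permutations (both the maximum of
per-permutation maximum LOD and the conventional 95th percentile are
reported), and a forward-stepwise multiple-marker model yields retained
markers with semi-partial correlations and single-marker PVE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MODELS = ("additive", "dominant", "recessive")


@dataclass
class F2Panel:
    """Marker dosages (individuals x markers, NaN missing), phenotype and
    censoring flags, with per-marker metadata (marker, scaffold, position)."""

    dosage: np.ndarray
    phenotype: np.ndarray
    censored: np.ndarray
    markers: pd.DataFrame

    def __post_init__(self) -> None:
        n, m = self.dosage.shape
        if len(self.phenotype) != n or len(self.censored) != n:
            raise ValueError("phenotype/censoring length does not match dosage rows")
        if len(self.markers) != m:
            raise ValueError("marker table does not match dosage columns")

    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosage.shape[1]

    def marker_coverage(self) -> np.ndarray:
        return 1.0 - np.isnan(self.dosage).mean(axis=0)

    def filter_markers(self, min_coverage: float = 0.4) -> "F2Panel":
        """Drop markers genotyped in fewer than *min_coverage* of individuals."""
        keep = self.marker_coverage() >= min_coverage
        return F2Panel(
            dosage=self.dosage[:, keep],
            phenotype=self.phenotype,
            censored=self.censored,
            markers=self.markers.loc[keep].reset_index(drop=True),
        )

    def working_phenotype(self, drop_censored: bool = False):
        """Phenotype vector and row mask under the censoring policy."""
        rows = np.ones(self.n_individuals, dtype=bool)
        if drop_censored:
            rows = ~self.censored
        return self.phenotype, rows


def encode_model(dosage, model: str) -> np.ndarray:
    """Genetic encoding of tetraploid dosage for one marker model."""
    dosage = np.asarray(dosage, dtype=float)
    if model == "additive":
        return dosage.copy()
    if model == "dominant":
        out = (dosage > 0).astype(float)
    elif model == "recessive":
        out = (dosage == 4).astype(float)
    else:
        raise ValueError(f"unknown model {model!r}")
    out[np.isnan(dosage)] = np.nan
    return out


def _masked_regression(Y: np.ndarray, X: np.ndarray):
    """Per-(row of Y, marker) simple-regression R^2 with missing dosages.

    Y is (P, n) phenotype rows (observed + permutations), X is (n, m)
    encoded dosages with NaN for missing. Returns (r2, n_used, slope)
    arrays of shape (P, m); markers whose encoding is constant on their
    non-missing rows get r2 = NaN.
    """
    valid = ~np.isnan(X)
    X0 = np.where(valid, X, 0.0)
    V = valid.astype(float)
    n_used = V.sum(axis=0)  # (m,)
    sx = X0.sum(axis=0)
    sxx = (X0**2).sum(axis=0)
    sy = Y @ V  # (P, m)
    syy = (Y**2) @ V
    sxy = Y @ X0
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sy * sx / n_used
        varx = sxx - sx**2 / n_used
        vary = syy - sy**2 / n_used
        r2 = cov**2 / (varx * vary)
        slope = cov / varx
    r2 = np.where((varx > 1e-12) & (vary > 1e-12), r2, np.nan)
    r2 = np.clip(r2, 0.0, 1.0)
    return r2, np.broadcast_to(n_used, r2.shape), slope


def _lod_from_r2(r2, n):
    with np.errstate(invalid="ignore"):
        return -(n / 2.0) * np.log10(np.maximum(1.0 - r2, 1e-300))


def single_marker_scan(
    panel: F2Panel, drop_censored: bool = False, models=MODELS
) -> pd.DataFrame:
    """Per-marker best-model LOD scan.

    Returns one row per marker with the best model, its LOD, the F-test
    p-value and the effect estimate (slope of the encoded regressor);
    markers whose encodings are all constant come back with NaN LOD.
    Note the reported p-value belongs to the *selected* model: with the
    default three-way model selection it is anti-conservative relative to
    a single pre-specified encoding.
    """
    y, rows = panel.working_phenotype(drop_censored)
    y = y[rows].astype(float)
    Y = y[None, :]
    results = {}
    for model in models:
        X = np.column_stack(
            [encode_model(panel.dosage[rows, j], model) for j in range(panel.n_markers)]
        )
        r2, n_used, slope = _masked_regression(Y, X)
        lod = _lod_from_r2(r2, n_used)
        results[model] = (r2[0], n_used[0], slope[0], lod[0])

    out = panel.markers.copy()
    best_model, best_lod, best_p, best_eff = [], [], [], []
    for j in range(panel.n_markers):
        lods = {m: results[m][3][j] for m in models}
        finite = {m: v for m, v in lods.items() if np.isfinite(v)}
        if not finite:
            best_model.append("NA")
            best_lod.append(np.nan)
            best_p.append(np.nan)
            best_eff.append(np.nan)
            continue
        m = max(finite, key=finite.get)
        r2, n, slope = results[m][0][j], results[m][1][j], results[m][2][j]
        df2 = n - 2
        if df2 <= 0 or r2 >= 1.0:
            pval = np.nan
        else:
            fstat = r2 * df2 / (1.0 - r2)
            pval = float(stats.f.sf(fstat, 1, df2))
        best_model.append(m)
        best_lod.append(float(finite[m]))
        best_p.append(pval)
        best_eff.append(float(slope))
    out["model"] = best_model
    out["lod"] = best_lod
    out["p_value"] = best_p
    out["effect"] = best_eff
    return out


def permutation_threshold(
    panel: F2Panel, n_perm: int = 500, seed: int = 0, drop_censored: bool = False
) -> dict:
    """Genome-wide LOD thresholds from phenotype permutations.

    Phenotypes are permuted across individuals ``n_perm`` times and the
    maximum LOD over all markers and models recorded per permutation.
    Returns the maximum of those maxima (``max_of_max``), the conventional
    95th percentile (``q95``) and the per-permutation maxima.
    """
    import warnings

    if n_perm < 100:
        warnings.warn("fewer than 100 permutations gives unstable thresholds")
    y, rows = panel.working_phenotype(drop_censored)
    y = y[rows].astype(float)
    rng = np.random.default_rng(seed)
    n = len(y)
    Y = np.empty((n_perm, n))
    for p in range(n_perm):
        Y[p] = y[rng.permutation(n)]
    max_lod = np.full(n_perm, -np.inf)
    for model in MODELS:
        X = np.column_stack(
            [encode_model(panel.dosage[rows, j], model) for j in range(panel.n_markers)]
        )
        r2, n_used, _ = _masked_regression(Y, X)
        lod = _lod_from_r2(r2, n_used)
        max_lod = np.maximum(max_lod, np.nanmax(lod, axis=1))
    return {
        "max_of_max": float(np.max(max_lod)),
        "q95": float(np.quantile(max_lod, 0.95)),
        "per_perm_max": max_lod,
    }


def stepwise_mlm(
    panel: F2Panel,
    candidate_markers,
    alpha: float = 0.05,
    model: str = "additive",
    drop_censored: bool = False,
) -> pd.DataFrame:
    """Forward-stepwise multiple-marker regression over candidate markers.

    At each step the marker giving the largest reduction in the residual
    sum of squares is added if its partial F-test p-value is below
    *alpha*; collinear markers (no unique variance left) are skipped.
    Rows with a missing genotype at any candidate marker are dropped
    (complete-case within the candidate set). Returns the retained
    markers with their semi-partial correlation (square root of the R^2
    increment when added last to the final model) and the single-marker
    PVE (the marker's own R^2).
    """
    candidate_markers = list(candidate_markers)
    if not candidate_markers:
        return pd.DataFrame(
            columns=["marker", "step", "spc", "pve_single", "partial_f_p"]
        )
    y, rows = panel.working_phenotype(drop_censored)
    X = np.column_stack(
        [encode_model(panel.dosage[:, j], model) for j in candidate_markers]
    )
    keep_rows = rows & ~np.isnan(X).any(axis=1)
    y = y[keep_rows].astype(float)
    X = X[keep_rows]
    n = len(y)
    yc = y - y.mean()
    tss = float(yc @ yc)

    def rss_of(cols):
        if not cols:
            return tss
        A = np.column_stack([np.ones(n)] + [X[:, c] for c in cols])
        coef, res, rank, _ = np.linalg.lstsq(A, y, rcond=None)
        pred = A @ coef
        return float(((y - pred) ** 2).sum())

    selected: list = []
    steps = []
    remaining = list(range(len(candidate_markers)))
    current_rss = tss
    while remaining:
        best = None
        for c in remaining:
            cols = selected + [c]
            A = np.column_stack([np.ones(n)] + [X[:, cc] for cc in cols])
            if np.linalg.matrix_rank(A) < A.shape[1]:
                continue  # collinear with markers already in the model
            rss = rss_of(cols)
            if best is None or rss < best[1]:
                best = (c, rss)
        if best is None:
            break
        c, rss = best
        df2 = n - (len(selected) + 2)
        if df2 <= 0:
            break
        f = (current_rss - rss) / (rss / df2)
        pval = float(stats.f.sf(f, 1, df2))
        if pval >= alpha:
            break
        selected.append(c)
        steps.append((c, pval))
        remaining.remove(c)
        current_rss = rss

    rows_out = []
    full_rss = rss_of(selected)
    for step, (c, pval) in enumerate(steps, start=1):
        without = [s for s in selected if s != c]
        rss_without = rss_of(without)
        spc2 = (rss_without - full_rss) / tss
        pve = 1.0 - rss_of([c]) / tss
        rows_out.append(
            {
                "marker": panel.markers["marker"].iloc[candidate_markers[c]],
                "step": step,
                "spc": float(np.sqrt(max(spc2, 0.0))),
                "pve_single": float(pve),
                "partial_f_p": pval,
            }
        )
    return pd.DataFrame(rows_out)
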