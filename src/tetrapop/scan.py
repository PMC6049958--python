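"""Gene-wise aggregation, empirical outlier thresholds, and the
railway-specific selection-candidate intersection.

Window statistics are lifted to genes by taking the directed extreme of
all windows whose bp span (first to last SNP, inclusive) intersects the
gene interval: the maximum for differentiation (G_ST), the minimum for
the selection statistics (Fay & Wu's H, Tajima's D), whose
selection-relevant signals sit in the lower tail. When the same gene is
scored in several population comparisons, the *least extreme* value
across comparisons gives a conservative gene-level summary. Outlier
cutoffs are empirical genome-wide quantiles; outliers are strict
(value beyond, not at, the cutoff).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import FrequencyPanel, PROV_READCOUNT

#: directed extreme per statistic: which tail carries the signal
DIRECTIONS = {"gst": "max", "fwh": "min", "tajd": "min"}


def genewise_aggregate(
    window_stats: pd.DataFrame, genes, direction: str
) -> pd.DataFrame:
    """Directed extreme of overlapping windows per gene.

    *window_stats* needs columns ``scaffold, start_bp, end_bp, value``;
    *direction* is ``"max"`` or ``"min"``. Genes with no overlapping
    window are omitted.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    rows = []
    by_scaffold = dict(tuple(window_stats.groupby("scaffold")))
    for gene in genes:
        sub = by_scaffold.get(gene.scaffold)
        if sub is None:
            continue
        hit = sub[(sub["start_bp"] <= gene.end) & (sub["end_bp"] >= gene.start)]
        values = hit["value"].dropna()
        if values.empty:
            continue
        agg = values.max() if direction == "max" else values.min()
        rows.append(
            {"gene_id": gene.gene_id, "value": float(agg), "n_windows": len(values)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "value", "n_windows"])


def least_extreme_across(tables, direction: str) -> pd.DataFrame:
    """Conservative per-gene summary across comparisons.

    For a max-directed statistic the least extreme value is the minimum
    across comparisons (and vice versa); genes missing from any
    comparison are omitted.
    """
    if direction not in ("max", "min"):
        raise ValueError("direction must be 'max' or 'min'")
    tables = list(tables)
    merged = None
    for i, t in enumerate(tables):
        t = t[["gene_id", "value"]].rename(columns={"value": f"v{i}"})
        merged = t if merged is None else merged.merge(t, on="gene_id", how="inner")
    if merged is None or merged.empty:
        return pd.DataFrame(columns=["gene_id", "value"])
    vals = merged.drop(columns="gene_id").to_numpy()
    least = vals.min(axis=1) if direction == "max" else vals.max(axis=1)
    return pd.DataFrame({"gene_id": merged["gene_id"], "value": least})


def empirical_threshold(values, tail_quantile: float, side: str) -> float:
    """Empirical order-statistic cutoff on one tail.

    ``side="upper"`` with ``tail_quantile=0.05`` returns the value below
    which 95% of the data fall (the ceil(0.95 n)-th order statistic);
    ``side="lower"`` mirrors this on the left tail. Requires at least 100
    finite values.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if len(values) < 100:
        raise ValueError("need at least 100 finite values for an empirical cutoff")
    if not 0 < tail_quantile <= 0.5:
        raise ValueError("tail quantile must lie in (0, 0.5]")
    if side == "upper":
        return float(np.quantile(values, 1.0 - tail_quantile, method="inverted_cdf"))
    if side == "lower":
        return float(np.quantile(values, tail_quantile, method="inverted_cdf"))
    raise ValueError("side must be 'upper' or 'lower'")


def railway_selection_candidates(
    gst_genes: pd.DataFrame,
    fwh_by_pop: dict,
    tajd_by_pop: dict,
    railway_pops,
    mountain_pops,
    gst_quantile: float = 0.05,
    h_quantile: float = 0.05,
    tajd_quantile: float = 0.05,
) -> pd.DataFrame:
    """Genes with railway-specific selection marks.

    A candidate is in the top *gst_quantile* of gene-wise railway-mountain
    G_ST and is a lower-tail Fay & Wu's H outlier in **every** railway
    population and in **no** mountain population. Candidates additionally
    get a Tajima's D mark when D is below its lower-tail cutoff in all
    railway populations. Inputs are gene-level tables (``gene_id, value``)
    per population; thresholds are genome-wide per table.
    """
    for pop in list(railway_pops) + list(mountain_pops):
        if pop not in fwh_by_pop:
            raise KeyError(f"missing Fay & Wu's H table for population {pop!r}")
    for pop in railway_pops:
        if pop not in tajd_by_pop:
            raise KeyError(f"missing Tajima's D table for population {pop!r}")

    gst_cut = empirical_threshold(gst_genes["value"], gst_quantile, "upper")
    gst_out = set(gst_genes.loc[gst_genes["value"] > gst_cut, "gene_id"])

    def lower_outliers(table, q):
        cut = empirical_threshold(table["value"], q, "lower")
        return set(table.loc[table["value"] < cut, "gene_id"])

    h_out = {pop: lower_outliers(fwh_by_pop[pop], h_quantile) for pop in fwh_by_pop}
    d_out = {
        pop: lower_outliers(tajd_by_pop[pop], tajd_quantile) for pop in railway_pops
    }

    rows = []
    for gene_id in sorted(gst_out):
        in_all_railway = all(gene_id in h_out[p] for p in railway_pops)
        in_no_mountain = all(gene_id not in h_out[p] for p in mountain_pops)
        if not (in_all_railway and in_no_mountain):
            continue
        tajd_mark = all(gene_id in d_out[p] for p in railway_pops)
        rows.append(
            {
                "gene_id": gene_id,
                "gst_outlier": True,
                "h_railway_specific": True,
                "tajd_mark": tajd_mark,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "gst_outlier", "h_railway_specific", "tajd_mark"]
    )


def signature_frequencies(
    panel: FrequencyPanel, signature_sites, populations
) -> pd.DataFrame:
    """Mean derived frequency of a haplotype signature per population.

    *signature_sites* is a list of (scaffold, position) pairs defining the
    signature (e.g. the derived polymorphisms characteristic of a
    haplotype). Returns one row per population with the mean frequency,
    the number of sites found, and how many were filled by the read-count
    fallback; the mean is NA for a population with no scored site.
    """
    positions = list(signature_sites)
    if len(positions) != len(set(positions)):
        raise ValueError("signature positions must be unique")
    scaffolds = panel.sites["scaffold"].to_numpy()
    pos = panel.sites["position"].to_numpy()
    rows_idx = []
    for scaffold, position in positions:
        hit = np.flatnonzero((scaffolds == scaffold) & (pos == position))
        if len(hit):
            rows_idx.append(int(hit[0]))
    out = []
    for pop in populations:
        k = panel.pop_index(pop)
        p = panel.freq[rows_idx, k] if rows_idx else np.array([])
        prov = panel.provenance[rows_idx, k] if rows_idx else np.array([])
        scored = ~np.isnan(p)
        out.append(
            {
                "population": pop,
                "mean_frequency": float(np.mean(p[scored])) if scored.any() else np.nan,
                "n_sites": int(scored.sum()),
                "n_fallback": int((prov[scored] == PROV_READCOUNT).sum()),
            }
        )
    return pd.DataFrame(out)


def differentiated_variants(
    panel: FrequencyPanel, group_a, group_b, min_diff: float = 0.30
) -> pd.DataFrame:
    """Sites whose mean derived frequency differs by strictly more than
    *min_diff* between two population groups, annotated with the group
    carrying the derived state."""
    cols_a = [panel.pop_index(p) for p in group_a]
    cols_b = [panel.pop_index(p) for p in group_b]
    with np.errstate(invalid="ignore"):
        mean_a = np.nanmean(panel.freq[:, cols_a], axis=1)
        mean_b = np.nanmean(panel.freq[:, cols_b], axis=1)
        diff = mean_a - mean_b
    hit = np.abs(diff) > min_diff
    hit &= panel.polarizable
    hit &= ~np.isnan(diff)
    out = panel.sites.loc[hit, ["scaffold", "position"]].copy()
    out["freq_a"] = mean_a[hit]
    out["freq_b"] = mean_b[hit]
    out["derived_in"] = np.where(diff[hit] > 0, "A", "B")
    return out.reset_index(drop=True)
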