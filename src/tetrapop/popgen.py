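"""Allele-frequency estimation, windowing, and per-window statistics.

Frequencies are estimated from tetraploid dosages and polarized against an
outgroup consensus: the *derived* allele at a site is the allele not carried
(or minor) in the outgroup panel. Sites where the outgroup is missing or
polymorphic above ``max_outgroup_minor_freq`` are kept but flagged
unpolarizable, and are skipped by statistics that need ancestral/derived
states (Fay & Wu's H, ABBA-BABA patterns).

Three window statistics are provided, computed over fixed-size blocks of
consecutive usable SNPs (25 by default):

* ``gst`` — Nei's G_ST, aggregated ratio-of-sums across sites:
  ``sum(H_T - H_S) / sum(H_T)`` with H_S the unweighted mean
  within-population gene diversity 2p(1-p) and H_T the diversity of the
  unweighted mean frequency. Ratio-of-sums (rather than the mean of
  per-site ratios) keeps low-diversity sites from dominating.
* ``tajimas_d`` — Tajima's D with the standard a1..e2 constants evaluated
  at n = 4 x (median number of genotyped individuals across the window's
  sites); theta_pi uses the per-site unbiased correction n/(n-1).
* ``fay_wu_h`` — Fay & Wu's original H = theta_pi - theta_H (unnormalized),
  with theta_H = sum 2 p^2 n/(n-1) over polarized derived frequencies.

Tetraploid Hardy-Weinberg arithmetic (genotype-class probabilities from
the multinomial expansion of (sum p_i)^4) lives here as well.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .core import (
    MISSING,
    PROV_GENOTYPE,
    PROV_MISSING,
    PROV_READCOUNT,
    FrequencyPanel,
    GenotypeMatrix,
    Window,
)

__all__ = [
    "estimate_frequencies",
    "read_count_fallback",
    "make_windows",
    "gst",
    "tajimas_d",
    "fay_wu_h",
    "hwe_genotype_prob",
    "tajima_constants",
]


def estimate_frequencies(
    gm: GenotypeMatrix,
    populations=None,
    outgroup: str = "outgroup",
    min_individuals: int = 5,
    max_outgroup_minor_freq: float = 0.2,
) -> FrequencyPanel:
    """Population derived-allele frequencies polarized against an outgroup.

    Parameters
    ----------
    gm : GenotypeMatrix
        Dosage matrix; ``gm.populations`` (or *populations*) must map
        labels to sample names and include *outgroup*.
    min_individuals : int
        A population's frequency at a site is set missing when fewer
        individuals are genotyped there.
    max_outgroup_minor_freq : float
        Outgroup minor-allele frequency above which a site is flagged
        unpolarizable.
    """
    pops = dict(populations or gm.populations)
    if outgroup not in pops:
        raise KeyError(f"outgroup population {outgroup!r} not in sample map")
    focal = [p for p in pops.keys() if p != outgroup]

    lookup = {s: i for i, s in enumerate(gm.samples)}
    for label, names in pops.items():
        absent = [s for s in names if s not in lookup]
        if absent:
            raise KeyError(f"population {label!r}: samples {absent} not in matrix")

    def _pop_alt_freq(cols):
        d = gm.dosage[:, cols].astype(float)
        k = gm.ploidy[cols].astype(float)
        called = d != MISSING
        n_ind = called.sum(axis=1)
        n_chr = (called * k).sum(axis=1)
        alt = np.where(called, d, 0.0).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_chr > 0, alt / np.maximum(n_chr, 1), np.nan)
        return p, n_chr.astype(int), n_ind.astype(int)

    out_cols = np.array([lookup[s] for s in pops[outgroup]])
    p_out, nchr_out, _ = _pop_alt_freq(out_cols)

    # outgroup consensus: the major allele; unpolarizable when missing or
    # polymorphic beyond threshold
    with np.errstate(invalid="ignore"):
        minor = np.minimum(p_out, 1.0 - p_out)
    polarizable = (~np.isnan(p_out)) & (minor <= max_outgroup_minor_freq)
    derived_is_alt = np.where(np.isnan(p_out), True, p_out < 0.5)

    n_sites = gm.n_sites
    freq = np.full((n_sites, len(focal)), np.nan)
    n_chr = np.zeros((n_sites, len(focal)), dtype=int)
    prov = np.full((n_sites, len(focal)), PROV_MISSING, dtype="U1")

    for k, label in enumerate(focal):
        cols = np.array([lookup[s] for s in pops[label]])
        p_alt, nc, n_ind = _pop_alt_freq(cols)
        ok = (~np.isnan(p_alt)) & (n_ind >= min_individuals)
        p_derived = np.where(derived_is_alt, p_alt, 1.0 - p_alt)
        freq[ok, k] = p_derived[ok]
        n_chr[ok, k] = nc[ok]
        prov[ok, k] = PROV_GENOTYPE

    out_derived = np.where(derived_is_alt, p_out, 1.0 - p_out)

    sites = gm.sites.copy()
    sites["derived_is_alt"] = derived_is_alt
    sites["polarizable"] = polarizable
    return FrequencyPanel(
        sites=sites,
        populations=list(focal),
        freq=freq,
        n_chr=n_chr,
        provenance=prov,
        outgroup_freq=out_derived,
    )


def read_count_fallback(
    panel: FrequencyPanel, population: str, alt_reads, total_reads
) -> FrequencyPanel:
    """Fill missing entries of one population from pooled read counts.

    ``alt_reads`` / ``total_reads`` are per-site pooled counts of reads
    supporting the ALT allele and of all (quality-filtered) reads. Only
    entries currently missing are filled; filled entries are flagged
    ``PROV_READCOUNT`` and carry ``n_chr = 0`` (read counts carry no
    chromosome-count information). Sites with zero total reads stay
    missing. Returns the panel (modified in place) for chaining.
    """
    alt_reads = np.asarray(alt_reads, dtype=float)
    total_reads = np.asarray(total_reads, dtype=float)
    if alt_reads.shape != (panel.n_sites,) or total_reads.shape != (panel.n_sites,):
        raise ValueError("read-count arrays must have one entry per site")
    if (alt_reads > total_reads).any() or (alt_reads < 0).any():
        raise ValueError("alt_reads must lie in [0, total_reads]")
    k = panel.pop_index(population)
    derived_is_alt = panel.sites["derived_is_alt"].to_numpy(dtype=bool)
    fill = np.isnan(panel.freq[:, k]) & (total_reads > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_alt = alt_reads / np.maximum(total_reads, 1.0)
    p_derived = np.where(derived_is_alt, p_alt, 1.0 - p_alt)
    panel.freq[fill, k] = p_derived[fill]
    panel.provenance[fill, k] = PROV_READCOUNT
    return panel


def make_windows(
    sites: pd.DataFrame, window_size_snps: int = 25, usable=None, stride=None
) -> list:
    """Blocks of consecutive usable SNPs, never spanning scaffolds.

    *usable* is an optional boolean mask over site rows (e.g. "has a
    frequency in all populations of interest"); windows index the original
    rows. Trailing windows shorter than ``window_size_snps`` are emitted
    with ``full=False``. ``stride`` (in usable SNPs) defaults to the window
    size, i.e. disjoint windows; smaller strides give sliding windows.
    """
    if stride is None:
        stride = window_size_snps
    if window_size_snps <= 0 or stride <= 0:
        raise ValueError("window size and stride must be positive")
    usable = (
        np.ones(len(sites), dtype=bool) if usable is None
        else np.asarray(usable, dtype=bool)
    )
    positions = sites["position"].to_numpy()
    scaffolds = sites["scaffold"].to_numpy()
    windows = []
    for scaffold in pd.unique(scaffolds):
        rows = np.flatnonzero((scaffolds == scaffold) & usable)
        for lo in range(0, len(rows), stride):
            chunk = rows[lo : lo + window_size_snps]
            if len(chunk) == 0:
                break
            windows.append(
                Window(
                    scaffold=str(scaffold),
                    rows=chunk.copy(),
                    start_bp=int(positions[chunk[0]]),
                    end_bp=int(positions[chunk[-1]]),
                    full=len(chunk) == window_size_snps,
                )
            )
            if lo + window_size_snps >= len(rows):
                break
    return windows


def _window_rows(panel: FrequencyPanel, window) -> np.ndarray:
    if isinstance(window, Window):
        return window.rows
    return np.asarray(window, dtype=int)


def gst(panel: FrequencyPanel, window, populations) -> float:
    """Nei's G_ST over a window, ratio-of-sums across sites.

    Uses every site where at least two of *populations* have a frequency;
    returns NaN when the summed total diversity is zero (no site is
    polymorphic across the populations).
    """
    if len(populations) < 2:
        raise ValueError("G_ST needs at least two populations")
    rows = _window_rows(panel, window)
    cols = [panel.pop_index(p) for p in populations]
    p = panel.freq[np.ix_(rows, cols)]
    ok = (~np.isnan(p)).sum(axis=1) >= 2
    if not ok.any():
        return float("nan")
    p = p[ok]
    hs = np.nanmean(2.0 * p * (1.0 - p), axis=1)
    pbar = np.nanmean(p, axis=1)
    ht = 2.0 * pbar * (1.0 - pbar)
    denom = ht.sum()
    if denom <= 0:
        return float("nan")
    return float((ht - hs).sum() / denom)


def tajima_constants(n: int) -> dict:
    """Tajima's a1..e2 for a sample of *n* chromosomes."""
    if n < 2:
        raise ValueError("need at least two chromosomes")
    i = np.arange(1, n)
    a1 = float(np.sum(1.0 / i))
    a2 = float(np.sum(1.0 / i**2))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n**2 + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _window_freqs(panel, window, population, polarized_only):
    rows = _window_rows(panel, window)
    k = panel.pop_index(population)
    p = panel.freq[rows, k]
    n = panel.n_chr[rows, k].astype(float)
    ok = ~np.isnan(p)
    if polarized_only:
        ok &= panel.polarizable[rows]
    ok &= n >= 2
    return p[ok], n[ok]


def tajimas_d(panel: FrequencyPanel, window, population: str) -> float:
    """Tajima's D for one population over a window.

    Segregating sites are those with 0 < p < 1 in the population (on the
    observed chromosomes). The constants use n = 4 x median genotyped
    individuals, i.e. the median per-site chromosome count across the
    window; per-site theta_pi uses each site's own chromosome count for
    the n/(n-1) unbiasedness correction. Returns NaN when there is no
    segregating site or fewer than 4 chromosomes.
    """
    p, n = _window_freqs(panel, window, population, polarized_only=False)
    seg = (p > 0) & (p < 1)
    s = int(seg.sum())
    if s == 0 or len(n) == 0:
        return float("nan")
    n_window = int(np.median(n))
    if n_window < 4:
        return float("nan")
    const = tajima_constants(n_window)
    theta_pi = float(np.sum(2.0 * p[seg] * (1.0 - p[seg]) * n[seg] / (n[seg] - 1.0)))
    theta_w = s / const["a1"]
    var = const["e1"] * s + const["e2"] * s * (s - 1.0)
    if var <= 0:
        return float("nan")
    return (theta_pi - theta_w) / math.sqrt(var)


def fay_wu_h(panel: FrequencyPanel, window, population: str) -> float:
    """Fay & Wu's H = theta_pi - theta_H over polarizable sites.

    theta_H = sum 2 p^2 n/(n-1) with p the derived-allele frequency;
    strongly negative values flag an excess of high-frequency derived
    variants. Returns NaN when no polarizable segregating site is present.
    """
    p, n = _window_freqs(panel, window, population, polarized_only=True)
    seg = (p > 0) & (p < 1)
    if not seg.any():
        return float("nan")
    p, n = p[seg], n[seg]
    theta_pi = float(np.sum(2.0 * p * (1.0 - p) * n / (n - 1.0)))
    theta_h = float(np.sum(2.0 * p**2 * n / (n - 1.0)))
    return theta_pi - theta_h


def window_scan(panel, windows, statistic, **kwargs) -> pd.DataFrame:
    """Apply one window statistic over a window list; tidy output table."""
    fns = {"gst": gst, "tajd": tajimas_d, "fwh": fay_wu_h}
    if statistic not in fns:
        raise ValueError(f"unknown statistic {statistic!r}")
    fn = fns[statistic]
    rows = []
    for w in windows:
        rows.append(
            {
                "scaffold": w.scaffold,
                "start_bp": w.start_bp,
                "end_bp": w.end_bp,
                "n_snps": w.n_snps,
                "full": w.full,
                "statistic": statistic,
                "value": fn(panel, w, **kwargs),
            }
        )
    return pd.DataFrame(rows)


def hwe_genotype_prob(freqs: dict, query) -> float:
    """Tetraploid Hardy-Weinberg genotype-class probability.

    *freqs* maps allele names to frequencies summing to 1. *query* is one of

    * ``("homozygous", allele)`` — all four copies are *allele*: p^4
    * ``("exact", allele, k)`` — exactly k copies: C(4,k) p^k (1-p)^(4-k)
    * ``("zero_copies", {alleles})`` — no copy of any listed allele:
      (1 - sum p)^4
    """
    p = {a: float(v) for a, v in freqs.items()}
    total = sum(p.values())
    if abs(total - 1.0) > 1e-8:
        raise ValueError(f"allele frequencies sum to {total}, not 1")
    if any(v < 0 for v in p.values()):
        raise ValueError("allele frequencies must be non-negative")
    kind = query[0]
    if kind == "homozygous":
        return p[query[1]] ** 4
    if kind == "exact":
        allele, k = query[1], int(query[2])
        if not 0 <= k <= 4:
            raise ValueError("copy number must be 0..4")
        q = p[allele]
        return math.comb(4, k) * q**k * (1.0 - q) ** (4 - k)
    if kind == "zero_copies":
        alleles = query[1]
        s = sum(p[a] for a in alleles)
        return (1.0 - s) ** 4
    raise ValueError(f"unknown query kind {kind!r}")
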