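"""ABBA-BABA introgression statistics on frequency panels.

Site patterns are frequency-weighted over a (((P1, P2), P3), O) quartet:

    abba = (1 - p1) p2 p3 (1 - pO)        baba = p1 (1 - p2) p3 (1 - pO)

with p the derived-allele frequency in each population. Patterson's D is
sum(abba - baba) / sum(abba + baba) over informative sites. The admixture
fraction is estimated by comparing the observed numerator to the one
expected under complete replacement of P2 by the donor:

* ``f_hom`` substitutes P3 in the P2 slot of the denominator,
* ``f_d`` substitutes, per site, whichever of P2/P3 has the higher
  derived frequency (robust for small windows and genes); negative
  numerators are clamped to 0, as regions with D <= 0 carry no
  introgression signal.

Both denominators contain the product of two frequencies from the *same*
population, whose plug-in estimate p^2 is inflated by within-population
sampling (E[p^2] = p^2 + pq/n) — a ~10% downward bias on f at this
pipeline's sample sizes (6-8 tetraploid individuals). The duplicated slot
therefore uses the unbiased two-distinct-chromosome product
k(k-1)/(n(n-1)), the frequency-panel equivalent of drawing the donor pair
without replacement.

Uncertainty comes from a delete-one block jackknife over contiguous
blocks of informative sites. An *informative* site is biallelic,
polarizable, non-missing in all four populations, with abba + baba > 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import FrequencyPanel

logger = logging.getLogger(__name__)

OUTGROUP = "outgroup"  # sentinel: use the panel's polarization outgroup


@dataclass(frozen=True)
class QuartetConfig:
    """Labels for P1 (background), P2 (focal/admixed), P3 (donor) and the
    outgroup. ``o=OUTGROUP`` uses the panel's polarization outgroup."""

    p1: str
    p2: str
    p3: str
    o: str = OUTGROUP

    @property
    def name(self) -> str:
        return f"{self.p1},{self.p2},{self.p3},{self.o}"


@dataclass
class QuartetResult:
    quartet: QuartetConfig
    d: float
    d_sd: float
    f_hom: float
    f_hom_sd: float
    n_informative: int
    n_blocks: int


def site_patterns(p1, p2, p3, p_o):
    """Frequency-weighted (abba, baba) arrays for polarized frequencies."""
    p1, p2, p3, p_o = (np.asarray(x, dtype=float) for x in (p1, p2, p3, p_o))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p_o)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p_o)
    return abba, baba


def _unbiased_square(p, n):
    """Unbiased estimate of p^2 from a sample of n chromosomes:
    k(k-1)/(n(n-1)) with k = p n; falls back to p^2 when n < 2."""
    p = np.asarray(p, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        k = p * n
        ub = k * (k - 1.0) / (n * (n - 1.0))
    return np.where(n >= 2, np.maximum(ub, 0.0), p**2)


def _quartet_arrays(panel: FrequencyPanel, quartet: QuartetConfig):
    def pop(label):
        if label == OUTGROUP:
            if panel.outgroup_freq is None:
                raise ValueError("panel carries no outgroup frequencies")
            return panel.outgroup_freq, np.zeros(panel.n_sites)
        k = panel.pop_index(label)
        return panel.freq[:, k], panel.n_chr[:, k]

    p1, _ = pop(quartet.p1)
    p2, n2 = pop(quartet.p2)
    p3, n3 = pop(quartet.p3)
    p_o, _ = pop(quartet.o)
    ok = (
        panel.polarizable
        & ~np.isnan(p1)
        & ~np.isnan(p2)
        & ~np.isnan(p3)
        & ~np.isnan(p_o)
    )
    return p1, p2, p3, p_o, n2, n3, ok


def _informative(panel, quartet):
    p1, p2, p3, p_o, n2, n3, ok = _quartet_arrays(panel, quartet)
    abba, baba = site_patterns(p1, p2, p3, p_o)
    with np.errstate(invalid="ignore"):
        ok &= (abba + baba) > 0
    return p1, p2, p3, p_o, n2, n3, ok, abba, baba


def block_jackknife(num, den, block_size=1000, min_blocks: int = 10):
    """Delete-one-block jackknife SD of a ratio-of-sums statistic.

    *num*/*den* are per-informative-site contributions, in genome order;
    blocks are contiguous runs of about *block_size* sites.
    ``block_size=None`` targets ~50 blocks whatever the data size.
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    if block_size is None:
        block_size = max(len(num) // 50, 1)
    n_blocks = max(int(len(num) // block_size), 1)
    if n_blocks < min_blocks:
        raise ValueError(
            f"only {n_blocks} jackknife blocks at block size {block_size}; "
            "need at least 10 — use more data or smaller blocks"
        )
    num_b = np.array([b.sum() for b in np.array_split(num, n_blocks)])
    den_b = np.array([b.sum() for b in np.array_split(den, n_blocks)])
    loo = (num_b.sum() - num_b) / (den_b.sum() - den_b)
    b = n_blocks
    return float(np.sqrt((b - 1.0) / b * ((loo - loo.mean()) ** 2).sum())), n_blocks


def patterson_d(
    panel: FrequencyPanel, quartet: QuartetConfig, block_size=1000
) -> QuartetResult:
    """Patterson's D with jackknife SD; f fields are NaN."""
    *_, ok, abba, baba = _informative(panel, quartet)
    if not ok.any():
        return QuartetResult(quartet, np.nan, np.nan, np.nan, np.nan, 0, 0)
    num = (abba - baba)[ok]
    den = (abba + baba)[ok]
    d = float(num.sum() / den.sum())
    sd, n_blocks = block_jackknife(num, den, block_size)
    return QuartetResult(quartet, d, sd, np.nan, np.nan, int(ok.sum()), n_blocks)


def f_hom(
    panel: FrequencyPanel, quartet: QuartetConfig, block_size=1000
) -> QuartetResult:
    """Genome-wide admixture fraction f_hom = S(P1,P2,P3,O) / S(P1,P3,P3,O),
    with D filled in as well."""
    p1, p2, p3, p_o, n2, n3, ok, abba, baba = _informative(panel, quartet)
    if not ok.any():
        return QuartetResult(quartet, np.nan, np.nan, np.nan, np.nan, 0, 0)
    num = (abba - baba)[ok]
    d_den = (abba + baba)[ok]
    p3sq = _unbiased_square(p3, n3)
    den = ((1.0 - p_o) * (p3sq - p1 * p3))[ok]
    d = float(num.sum() / d_den.sum())
    d_sd, n_blocks = block_jackknife(num, d_den, block_size)
    if den.sum() <= 0:
        logger.warning("f_hom denominator <= 0 for quartet %s", quartet.name)
        return QuartetResult(quartet, d, d_sd, np.nan, np.nan, int(ok.sum()), n_blocks)
    f = float(num.sum() / den.sum())
    f_sd, _ = block_jackknife(num, den, block_size)
    return QuartetResult(quartet, d, d_sd, f, f_sd, int(ok.sum()), n_blocks)


def f_d(panel: FrequencyPanel, quartet: QuartetConfig, site_mask=None):
    """Dynamic-donor admixture fraction over a site subset (gene/window).

    Returns ``(f_d, n_informative)``; f_d is 0 where the numerator is
    negative and NaN where the denominator is not positive.
    """
    p1, p2, p3, p_o, n2, n3, ok, abba, baba = _informative(panel, quartet)
    if site_mask is not None:
        ok = ok & np.asarray(site_mask, dtype=bool)
    n_inf = int(ok.sum())
    if n_inf == 0:
        return float("nan"), 0
    num = (abba - baba)[ok]
    num_sum = num.sum()
    if num_sum <= 0:
        return 0.0, n_inf  # D <= 0 regions carry no introgression signal
    donor_is_p2 = p2 > p3
    pd_ = np.where(donor_is_p2, p2, p3)
    nd_ = np.where(donor_is_p2, n2, n3)
    pdsq = _unbiased_square(pd_, nd_)
    den = ((1.0 - p_o) * (pdsq - p1 * pd_))[ok]
    den_sum = den.sum()
    if den_sum <= 0:
        return float("nan"), n_inf
    return float(num_sum / den_sum), n_inf


def _gene_site_masks(sites: pd.DataFrame, genes):
    """Boolean site mask per gene (1-based closed gene intervals)."""
    scaffolds = sites["scaffold"].to_numpy()
    positions = sites["position"].to_numpy()
    masks = {}
    for gene in genes:
        m = (
            (scaffolds == gene.scaffold)
            & (positions >= gene.start)
            & (positions <= gene.end)
        )
        masks[gene.gene_id] = m
    return masks


def gene_fd_scan(
    panel: FrequencyPanel,
    genes,
    quartets,
    min_informative: int = 25,
) -> pd.DataFrame:
    """Per-gene f_d for each quartet, keeping genes with strictly more than
    *min_informative* informative SNPs (per quartet)."""
    masks = _gene_site_masks(panel.sites, genes)
    if not any(m.any() for m in masks.values()):
        logger.warning("no gene overlaps any panel site")
        return pd.DataFrame(columns=["gene_id", "quartet", "f_d", "n_informative"])
    # precompute informative arrays once per quartet
    rows = []
    for quartet in quartets:
        p1, p2, p3, p_o, n2, n3, ok, abba, baba = _informative(panel, quartet)
        num = abba - baba
        donor_is_p2 = p2 > p3
        pd_ = np.where(donor_is_p2, p2, p3)
        nd_ = np.where(donor_is_p2, n2, n3)
        with np.errstate(invalid="ignore"):
            den = (1.0 - p_o) * (_unbiased_square(pd_, nd_) - p1 * pd_)
        for gene_id, m in masks.items():
            sel = ok & m
            n_inf = int(sel.sum())
            if n_inf <= min_informative:
                continue
            den_sum = den[sel].sum()
            num_sum = num[sel].sum()
            if num_sum <= 0:
                fd = 0.0
            elif den_sum <= 0:
                fd = np.nan
            else:
                fd = float(num_sum / den_sum)
            rows.append(
                {
                    "gene_id": gene_id,
                    "quartet": quartet.name,
                    "f_d": fd,
                    "n_informative": n_inf,
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "quartet", "f_d", "n_informative"])


def call_candidates(
    gene_fd: pd.DataFrame, f_hom_by_quartet: dict, multiplier: float = 3.0
) -> pd.DataFrame:
    """Candidate introgressed genes: f_d > multiplier x the quartet's
    genome-wide f_hom, in every quartet of *f_hom_by_quartet*.

    Genes missing an estimate for any quartet cannot satisfy the rule and
    are excluded. Returns the called genes with their per-quartet f_d.
    """
    quartet_names = list(f_hom_by_quartet)
    wide = gene_fd.pivot_table(index="gene_id", columns="quartet", values="f_d")
    missing = [q for q in quartet_names if q not in wide.columns]
    if missing:
        wide = wide.reindex(columns=list(wide.columns) + missing)
    wide = wide[quartet_names]
    complete = wide.dropna()
    thresholds = np.array([multiplier * f_hom_by_quartet[q] for q in quartet_names])
    called = complete[(complete.to_numpy() > thresholds).all(axis=1)]
    return called.reset_index()
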