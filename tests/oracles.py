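"""Independent brute-force oracles used by the test suite.

Everything here is computed from explicit chromosome enumerations or
textbook count-based formulas, deliberately sharing no code with the
package: pairwise-difference sums for diversity, literal Tajima (1989)
constants, per-site heterozygosity sums for G_ST, and exhaustive
chromosome-quartet enumeration for the ABBA-BABA statistics (with the
donor pair drawn as two *distinct* chromosomes in duplicated-population
slots).
"""

import itertools
import math

import numpy as np


def theta_pi_counts(derived_counts, n):
    """Pairwise diversity from per-site derived counts: mean pairwise
    differences summed over sites, via explicit pair counting."""
    total = 0.0
    pairs = n * (n - 1) / 2.0
    for k in derived_counts:
        total += k * (n - k) / pairs
    return total


def tajimas_d_counts(derived_counts, n):
    """Textbook Tajima's D from segregating-site counts."""
    seg = [k for k in derived_counts if 0 < k < n]
    s = len(seg)
    if s == 0:
        return float("nan")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    theta_pi = theta_pi_counts(seg, n)
    theta_w = s / a1
    return (theta_pi - theta_w) / math.sqrt(e1 * s + e2 * s * (s - 1))


def fay_wu_h_counts(derived_counts, n):
    """H = theta_pi - theta_H from derived counts, count form."""
    seg = [k for k in derived_counts if 0 < k < n]
    if not seg:
        return float("nan")
    theta_pi = theta_pi_counts(seg, n)
    theta_h = sum(2.0 * k * k / (n * (n - 1)) for k in seg)
    return theta_pi - theta_h


def gst_sites(freqs):
    """G_ST over sites x populations frequencies, per-site brute force."""
    num = 0.0
    den = 0.0
    for row in np.asarray(freqs, dtype=float):
        hs = np.mean([2 * p * (1 - p) for p in row])
        pbar = np.mean(row)
        ht = 2 * pbar * (1 - pbar)
        num += ht - hs
        den += ht
    return num / den if den > 0 else float("nan")


def _site_pattern_enumeration(c1, c2, c3, co):
    """Mean ABBA/BABA over every chromosome quartet at one site."""
    c1, c2, c3, co = (list(map(int, c)) for c in (c1, c2, c3, co))
    abba = baba = 0
    n = 0
    for a, b, c, d in itertools.product(c1, c2, c3, co):
        abba += (1 - a) * b * c * (1 - d)
        baba += a * (1 - b) * c * (1 - d)
        n += 1
    return abba / n, baba / n


def _donor_pair_enumeration(c1, donor, co):
    """Numerator of the donor-substituted denominator: the duplicated slot
    is filled by two distinct donor chromosomes (ordered pairs)."""
    c1, donor, co = (list(map(int, c)) for c in (c1, donor, co))
    abba = baba = 0
    n = 0
    for a, d in itertools.product(c1, co):
        for i, j in itertools.permutations(range(len(donor)), 2):
            abba += (1 - a) * donor[i] * donor[j] * (1 - d)
            baba += a * (1 - donor[i]) * donor[j] * (1 - d)
            n += 1
    return abba / n, baba / n


def abba_baba_enumeration(h1, h2, h3, ho):
    """D, f_hom, and per-site f_d ingredients by chromosome enumeration.

    h* are (n_sites, n_chrom) 0/1 arrays. Returns (D, f_hom, f_d) over all
    sites; the f_d denominator picks, per site, whichever of P2/P3 has the
    higher sample frequency as the donor.
    """
    num = d_den = f_den = fd_den = 0.0
    for s in range(h1.shape[0]):
        c1, c2, c3, co = h1[s], h2[s], h3[s], ho[s]
        abba, baba = _site_pattern_enumeration(c1, c2, c3, co)
        if abba + baba == 0:
            continue  # not an informative site
        num += abba - baba
        d_den += abba + baba
        da, db = _donor_pair_enumeration(c1, c3, co)
        f_den += da - db
        donor = c2 if c2.mean() > c3.mean() else c3
        da, db = _donor_pair_enumeration(c1, donor, co)
        fd_den += da - db
    d = num / d_den if d_den > 0 else float("nan")
    f_hom = num / f_den if f_den > 0 else float("nan")
    if num <= 0:
        f_d = 0.0
    elif fd_den <= 0:
        f_d = float("nan")
    else:
        f_d = num / fd_den
    return d, f_hom, f_d


def ols_lod(y, x):
    """LOD from explicit OLS residual sums of squares."""
    y = np.asarray(y, dtype=float)
    x = np.asarray(x, dtype=float)
    n = len(y)
    rss0 = float(((y - y.mean()) ** 2).sum())
    A = np.column_stack([np.ones(n), x])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss1 = float(((y - A @ coef) ** 2).sum())
    return (n / 2.0) * math.log10(rss0 / rss1)
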