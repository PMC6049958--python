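"""Truth-tracked synthetic data generators.

Every downstream stage of the pipeline has a generator here that produces
data with the statistical structure it assumes, plus the ground truth
needed to score it:

* :func:`simulate_panel` — multi-population biallelic SNP panels for
  autotetraploids with an outgroup, under a Balding-Nichols drift model:
  per site an ancestral frequency is drawn, each population's frequency is
  drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) with its drift parameter F, and
  individual chromosomes are Bernoulli draws from the population track
  (dosage = sum over the individual's 4 chromosomes).
* :func:`apply_introgression` — contiguous donor tracts covering an
  expected fraction alpha of each recipient chromosome, resampled from the
  donor's frequency track, with a per-chromosome, per-site truth mask.
* :func:`introgress_sites` / :func:`apply_sweep` — locus-targeted variants:
  full replacement of a gene's sites from the donor track, and sweep-like
  distortion of the site-frequency spectrum (derived frequencies pushed
  toward fixation) in selected populations.
* :func:`simulate_f2` — tetraploid F2 crosses with bivalent meiosis
  (2 of 4 homologs transmitted, chosen uniformly without replacement; no
  double reduction), inter-marker recombination, planted QTL effects and
  right-censoring of the flowering phenotype at the experiment's end date.
* :func:`simulate_expression` — negative-binomial count matrices with
  group-structured means and planted BGS expression classes.

All generators are deterministic given (arguments, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsa import F2Panel
from .core import GenotypeMatrix


# ---------------------------------------------------------------------------
# population panels


@dataclass
class PopSpec:
    n_individuals: int
    F: float  # Balding-Nichols drift parameter, 0 <= F < 1
    ploidy: int = 4

    def __post_init__(self) -> None:
        if self.n_individuals <= 0:
            raise ValueError("n_individuals must be positive")
        if not 0.0 <= self.F < 1.0:
            raise ValueError("F must lie in [0, 1)")
        if self.ploidy not in (1, 2, 4):
            raise ValueError("ploidy must be 1, 2 or 4")


@dataclass
class LineageSpec:
    """A shared drift epoch: the lineage track is drawn from the ancestral
    frequency with drift *F*, and each member population then drifts from
    the lineage track with its own (within-lineage) F."""

    F: float
    members: tuple

    def __post_init__(self) -> None:
        if not 0.0 <= self.F < 1.0:
            raise ValueError("lineage F must lie in [0, 1)")


@dataclass
class PopModel:
    """Populations, drift parameters and panel dimensions.

    ``populations`` maps labels to :class:`PopSpec`; ``outgroup`` names the
    population used for polarization (different ploidy allowed). The
    ancestral frequency law is ``("uniform",)`` or ``("beta", a, b)``.
    ``lineages`` optionally groups populations into clades that share a
    drift epoch (two-level Balding-Nichols); populations not listed in any
    lineage drift directly from the ancestral frequency.
    """

    populations: dict
    n_sites: int
    outgroup: str = "outgroup"
    ancestral: tuple = ("uniform",)
    n_scaffolds: int = 8
    lineages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if not self.populations:
            raise ValueError("at least one population required")
        if self.outgroup not in self.populations:
            raise ValueError(f"outgroup {self.outgroup!r} missing from populations")
        seen = set()
        for label, lin in self.lineages.items():
            for pop in lin.members:
                if pop not in self.populations:
                    raise ValueError(f"lineage {label!r}: unknown population {pop!r}")
                if pop in seen:
                    raise ValueError(f"population {pop!r} in two lineages")
                seen.add(pop)

    def lineage_of(self, population: str):
        for label, lin in self.lineages.items():
            if population in lin.members:
                return label
        return None


def railway_mountain_model(n_sites: int = 50_000) -> PopModel:
    """The study-design default: a tight mountain clade (two mountain
    populations plus the focal admixed population), a strongly diverged
    lowland railway lineage (two sister populations), and a diploid
    outgroup panel. Sample sizes follow the resequencing design (6-8
    tetraploid individuals per population, 23 outgroup genomes); drift
    parameters mirror the observed structure: low differentiation within
    the mountain clade, deep shared divergence of the railway lineage, and
    an outgroup from a separate species that is near-fixed at most sites.
    """
    return PopModel(
        populations={
            "HO": PopSpec(7, 0.02),
            "KA": PopSpec(8, 0.02),
            "BGS": PopSpec(8, 0.02),
            "TBG": PopSpec(6, 0.02),
            "STE": PopSpec(8, 0.02),
            "outgroup": PopSpec(23, 0.9, ploidy=2),
        },
        n_sites=n_sites,
        lineages={
            "mountain": LineageSpec(0.1, ("HO", "KA", "BGS")),
            "railway": LineageSpec(0.3, ("TBG", "STE")),
        },
    )


@dataclass
class SimulatedPanel:
    """Chromosome-level panel plus the truth tracks that generated it."""

    model: PopModel
    sites: pd.DataFrame
    haplotypes: dict  # label -> (n_sites, n_ind * ploidy) int8
    truth_freq: dict  # label -> (n_sites,) population frequency track
    ancestral: np.ndarray

    def copy(self) -> "SimulatedPanel":
        return SimulatedPanel(
            model=self.model,
            sites=self.sites.copy(),
            haplotypes={k: v.copy() for k, v in self.haplotypes.items()},
            truth_freq={k: v.copy() for k, v in self.truth_freq.items()},
            ancestral=self.ancestral.copy(),
        )

    def genotype_matrix(self) -> GenotypeMatrix:
        dosages, samples, ploidy, populations = [], [], [], {}
        for label, spec in self.model.populations.items():
            hap = self.haplotypes[label]
            k = spec.ploidy
            d = hap.reshape(hap.shape[0], spec.n_individuals, k).sum(axis=2)
            dosages.append(d.astype(np.int16))
            names = [f"{label}_{i + 1}" for i in range(spec.n_individuals)]
            samples.extend(names)
            ploidy.extend([k] * spec.n_individuals)
            populations[label] = names
        return GenotypeMatrix(
            sites=self.sites.copy(),
            dosage=np.concatenate(dosages, axis=1),
            samples=samples,
            ploidy=np.array(ploidy, dtype=np.int16),
            populations=populations,
        )


def _draw_ancestral(law, n_sites, rng):
    if law[0] == "uniform":
        return rng.uniform(0.0, 1.0, size=n_sites)
    if law[0] == "beta":
        return rng.beta(law[1], law[2], size=n_sites)
    if law[0] == "fixed":
        return np.full(n_sites, float(law[1]))
    raise ValueError(f"unknown ancestral law {law[0]!r}")


def _balding_nichols(p, F, rng):
    if F < 1e-12:
        return p.copy()
    a = p * (1.0 - F) / F
    b = (1.0 - p) * (1.0 - F) / F
    # guard against exactly-fixed ancestral frequencies
    a = np.maximum(a, 1e-12)
    b = np.maximum(b, 1e-12)
    return rng.beta(a, b)


def simulate_panel(model: PopModel, seed: int) -> SimulatedPanel:
    """Draw a panel under the Balding-Nichols model; see module docstring."""
    rng = np.random.default_rng(seed)
    n = model.n_sites
    per_scaffold = int(np.ceil(n / model.n_scaffolds))
    scaffold_ids = np.repeat(
        [f"scaffold_{i + 1}" for i in range(model.n_scaffolds)], per_scaffold
    )[:n]
    steps = rng.integers(50, 500, size=n)
    positions = np.empty(n, dtype=np.int64)
    for scaffold in pd.unique(scaffold_ids):
        m = scaffold_ids == scaffold
        positions[m] = np.cumsum(steps[m])
    sites = pd.DataFrame(
        {
            "scaffold": scaffold_ids,
            "position": positions,
            "ref": "A",
            "alt": "T",
        }
    )
    ancestral = _draw_ancestral(model.ancestral, n, rng)
    haplotypes, truth = {}, {}
    lineage_tracks = {}
    for label, lin in model.lineages.items():
        lineage_tracks[label] = _balding_nichols(ancestral, lin.F, rng)
        truth[label] = lineage_tracks[label]
    for label, spec in model.populations.items():
        lineage = model.lineage_of(label)
        base = lineage_tracks[lineage] if lineage else ancestral
        track = _balding_nichols(base, spec.F, rng)
        n_chr = spec.n_individuals * spec.ploidy
        haplotypes[label] = (
            rng.random((n, n_chr)) < track[:, None]
        ).astype(np.int8)
        truth[label] = track
    return SimulatedPanel(
        model=model, sites=sites, haplotypes=haplotypes, truth_freq=truth,
        ancestral=ancestral,
    )


@dataclass
class IntrogressionPlan:
    alpha: float
    tract_length: int = 100  # sites per tract
    target: str = "BGS"
    donor: str = "TBG"

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.tract_length <= 0:
            raise ValueError("tract_length must be positive")


def apply_introgression(panel: SimulatedPanel, plan: IntrogressionPlan, seed: int):
    """Resample donor tracts onto recipient chromosomes.

    Each recipient chromosome is divided into contiguous blocks of
    ``tract_length`` sites (restarting at scaffold boundaries); each block
    is independently introgressed with probability alpha, in which case
    its sites are redrawn as Bernoulli draws from the donor's frequency
    track. Returns ``(new_panel, truth_mask)`` with the per-site,
    per-chromosome boolean replacement mask.
    """
    if plan.target not in panel.haplotypes:
        raise KeyError(f"target population {plan.target!r} not in panel")
    if plan.donor not in panel.truth_freq:
        raise KeyError(f"donor track {plan.donor!r} not in panel")
    rng = np.random.default_rng(seed)
    out = panel.copy()
    hap = out.haplotypes[plan.target]
    n_sites, n_chr = hap.shape
    scaffolds = panel.sites["scaffold"].to_numpy()
    block_of_site = np.empty(n_sites, dtype=np.int64)
    next_block = 0
    for scaffold in pd.unique(scaffolds):
        rows = np.flatnonzero(scaffolds == scaffold)
        local = np.arange(len(rows)) // plan.tract_length
        block_of_site[rows] = local + next_block
        next_block += int(local[-1]) + 1
    n_blocks = next_block
    chosen = rng.random((n_blocks, n_chr)) < plan.alpha
    mask = chosen[block_of_site, :]
    donor_track = panel.truth_freq[plan.donor]
    replacement = (rng.random(hap.shape) < donor_track[:, None]).astype(np.int8)
    hap[mask] = replacement[mask]
    alpha_track = chosen[block_of_site, :].mean(axis=1)
    out.truth_freq[plan.target] = (
        (1.0 - alpha_track) * panel.truth_freq[plan.target]
        + alpha_track * donor_track
    )
    return out, mask


def introgress_sites(
    panel: SimulatedPanel,
    site_mask,
    target: str,
    donor: str,
    seed: int,
    chromosome_fraction: float = 1.0,
):
    """Replace the masked sites of target chromosomes from the donor track.

    Used to plant fully-introgressed loci (e.g. whole genes) in an
    otherwise unadmixed background; with ``chromosome_fraction=1`` every
    recipient chromosome carries the donor tract.
    """
    site_mask = np.asarray(site_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    out = panel.copy()
    hap = out.haplotypes[target]
    n_chr = hap.shape[1]
    chroms = rng.random(n_chr) < chromosome_fraction
    donor_track = panel.truth_freq[donor]
    rows = np.flatnonzero(site_mask)
    repl = (rng.random((len(rows), n_chr)) < donor_track[rows, None]).astype(np.int8)
    hap[np.ix_(rows, np.flatnonzero(chroms))] = repl[:, chroms]
    track = out.truth_freq[target].copy()
    frac = chroms.mean()
    track[rows] = (1.0 - frac) * track[rows] + frac * donor_track[rows]
    out.truth_freq[target] = track
    mask = np.zeros(hap.shape, dtype=bool)
    mask[np.ix_(rows, np.flatnonzero(chroms))] = True
    return out, mask


def apply_sweep(
    panel: SimulatedPanel, populations, site_mask, seed: int, strength: float = 8.0
) -> SimulatedPanel:
    """Sweep-like SFS distortion: push derived frequencies toward fixation.

    For the masked sites of each listed population, the frequency track is
    raised to ``p**(1/strength)`` (segregating sites only) and chromosomes
    redrawn, mimicking hitchhiking: an excess of high-frequency derived
    variants (strongly negative Fay & Wu's H) and loss of intermediate
    diversity.
    """
    if strength <= 1:
        raise ValueError("strength must exceed 1")
    site_mask = np.asarray(site_mask, dtype=bool)
    rng = np.random.default_rng(seed)
    out = panel.copy()
    rows = np.flatnonzero(site_mask)
    for label in populations:
        track = out.truth_freq[label].copy()
        seg = track[rows] > 0
        boosted = track[rows].copy()
        boosted[seg] = boosted[seg] ** (1.0 / strength)
        track[rows] = boosted
        n_chr = out.haplotypes[label].shape[1]
        out.haplotypes[label][rows, :] = (
            rng.random((len(rows), n_chr)) < track[rows, None]
        ).astype(np.int8)
        out.truth_freq[label] = track
    return out


# ---------------------------------------------------------------------------
# tetraploid F2 crosses


@dataclass
class QtlPlan:
    """Planted QTL effects and the phenotype model.

    ``qtls`` holds (marker_index, effect, mode) with *effect* in phenotype
    units per dosage unit for the additive mode and per carrier class for
    dominant/recessive modes. Phenotypes above ``censor_threshold`` are
    recorded as the threshold with the censoring flag set (non-bolters are
    assigned the experiment end date).
    """

    qtls: list
    residual_sd: float = 10.0
    baseline: float = 60.0
    censor_threshold: float = 140.0

    def __post_init__(self) -> None:
        if self.censor_threshold <= 0:
            raise ValueError("censor_threshold must be positive")
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be non-negative")
        for _, effect, mode in self.qtls:
            if not np.isfinite(effect):
                raise ValueError("QTL effects must be finite")
            if mode not in ("additive", "dominant", "recessive"):
                raise ValueError(f"unknown QTL mode {mode!r}")


def _homologs_from_dosage(dosage: np.ndarray) -> np.ndarray:
    """Deterministic phasing: the first *d* homologs carry the allele."""
    m = len(dosage)
    hom = np.zeros((m, 4), dtype=np.int8)
    for j in range(4):
        hom[:, j] = dosage > j
    return hom


def _gamete(hom: np.ndarray, rec: np.ndarray, rng) -> np.ndarray:
    """One bivalent-pairing meiosis: returns an (m, 2) gamete.

    The four homologs are paired into two bivalents uniformly at random
    and each bivalent contributes one recombinant chromatid; together with
    the random pairing this transmits 2 of 4 homologs uniformly without
    replacement in the no-recombination limit. ``rec[i]`` is the
    recombination probability between markers i-1 and i (rec[0] ignored).
    """
    m = hom.shape[0]
    perm = rng.permutation(4)
    gam = np.empty((m, 2), dtype=np.int8)
    for b in range(2):
        pair = perm[2 * b : 2 * b + 2]
        switches = rng.random(m) < rec
        switches[0] = rng.random() < 0.5  # random starting homolog
        state = np.cumsum(switches) % 2
        gam[:, b] = hom[np.arange(m), pair[state]]
    return gam


def _encode(dosage: np.ndarray, mode: str) -> np.ndarray:
    if mode == "additive":
        return dosage.astype(float)
    if mode == "dominant":
        return (dosage > 0).astype(float)
    if mode == "recessive":
        return (dosage == 4).astype(float)
    raise ValueError(f"unknown model {mode!r}")


def simulate_f2(
    parent_a,
    parent_b,
    qtl: QtlPlan,
    n_f2: int,
    seed: int,
    marker_scaffolds=None,
    r_within: float = 0.01,
    n_f1: int = 2,
    missing_rate: float = 0.0,
    marker_meta: pd.DataFrame | None = None,
) -> F2Panel:
    """Tetraploid F2 population segregating the planted QTL.

    Parents are dosage vectors (0..4) over m markers; F1 siblings are
    produced by crossing the parents, F2 individuals by intercrossing
    random pairs of F1 siblings. Recombination between adjacent markers is
    ``r_within`` within a scaffold and free (0.5) across scaffolds.
    """
    if n_f2 < 2:
        raise ValueError("need at least two F2 individuals")
    parent_a = np.asarray(parent_a, dtype=np.int8)
    parent_b = np.asarray(parent_b, dtype=np.int8)
    m = len(parent_a)
    if len(parent_b) != m:
        raise ValueError("parents must share the marker set")
    rng = np.random.default_rng(seed)
    if marker_scaffolds is None:
        marker_scaffolds = np.array(["scaffold_1"] * m)
    marker_scaffolds = np.asarray(marker_scaffolds)
    rec = np.full(m, r_within)
    rec[0] = 0.5
    rec[1:][marker_scaffolds[1:] != marker_scaffolds[:-1]] = 0.5

    hom_a = _homologs_from_dosage(parent_a)
    hom_b = _homologs_from_dosage(parent_b)
    f1 = [
        np.concatenate([_gamete(hom_a, rec, rng), _gamete(hom_b, rec, rng)], axis=1)
        for _ in range(max(2, n_f1))
    ]
    dosage = np.empty((n_f2, m), dtype=float)
    for i in range(n_f2):
        pa, pb = rng.choice(len(f1), size=2, replace=False)
        ind = np.concatenate(
            [_gamete(f1[pa], rec, rng), _gamete(f1[pb], rec, rng)], axis=1
        )
        dosage[i] = ind.sum(axis=1)

    phenotype = np.full(n_f2, qtl.baseline, dtype=float)
    for marker, effect, mode in qtl.qtls:
        phenotype += effect * _encode(dosage[:, marker], mode)
    phenotype += rng.normal(0.0, qtl.residual_sd, size=n_f2)
    censored = phenotype > qtl.censor_threshold
    phenotype[censored] = qtl.censor_threshold

    if missing_rate > 0:
        dosage[rng.random(dosage.shape) < missing_rate] = np.nan

    if marker_meta is None:
        marker_meta = pd.DataFrame(
            {
                "marker": [f"m{j + 1}" for j in range(m)],
                "scaffold": marker_scaffolds,
                "position": np.arange(1, m + 1) * 1000,
            }
        )
    return F2Panel(
        dosage=dosage,
        phenotype=phenotype,
        censored=censored,
        markers=marker_meta,
    )


# ---------------------------------------------------------------------------
# expression counts


@dataclass
class DePlan:
    n_mountain_like: int = 30
    n_railway_like: int = 30
    n_other_de: int = 60
    fold: float = 10.0

    def __post_init__(self) -> None:
        if self.fold <= 1:
            raise ValueError("fold must exceed 1")


@dataclass
class FloweringPlan:
    """Planted flowering-time structure: per-population mean days to
    bolting, and how many genes get expression proportional to it."""

    times: dict
    n_correlated: int = 0


@dataclass
class ExpressionTruth:
    table: pd.DataFrame  # gene, base_mean, is_de, bgs_class, flowering_correlated
    size_factors: pd.Series


def simulate_expression(
    n_genes: int,
    populations: dict,
    de_plan: DePlan,
    seed: int,
    n_reps: int = 3,
    dispersion: float = 0.05,
    mean_range: tuple = (50.0, 1000.0),
    depth_sd: float = 0.2,
    flowering: FloweringPlan | None = None,
):
    """Negative-binomial count matrix with planted BGS expression classes.

    *populations* maps population names to classes ('RW', 'MT', 'BGS').
    Differentially expressed genes get a railway mean ``fold`` times higher
    or lower (random direction) than the mountain mean; planted
    mountain-like genes give BGS the mountain mean, railway-like genes the
    railway mean, remaining DE genes the geometric mean of the two.
    Per-sample sequencing-depth factors (log-normal, sd *depth_sd*) scale
    all counts and are recorded in the truth object.

    Returns ``(counts, sample_populations, truth)`` with *counts* a genes x
    samples DataFrame.
    """
    if dispersion <= 0:
        raise ValueError("dispersion must be positive")
    classes = set(populations.values())
    if not {"RW", "MT", "BGS"} <= classes:
        raise ValueError("populations must cover classes RW, MT and BGS")
    if n_reps < 2:
        raise ValueError("need at least two replicates per population")
    n_de = de_plan.n_mountain_like + de_plan.n_railway_like + de_plan.n_other_de
    if n_de > n_genes:
        raise ValueError("more DE genes planted than genes simulated")

    rng = np.random.default_rng(seed)
    genes = [f"gene{i + 1:05d}" for i in range(n_genes)]
    base = np.exp(
        rng.uniform(np.log(mean_range[0]), np.log(mean_range[1]), size=n_genes)
    )
    labels = np.array(["not_de"] * n_genes, dtype=object)
    de_rows = rng.choice(n_genes, size=n_de, replace=False)
    labels[de_rows[: de_plan.n_mountain_like]] = "mountain_like"
    labels[
        de_rows[de_plan.n_mountain_like : de_plan.n_mountain_like + de_plan.n_railway_like]
    ] = "railway_like"
    labels[de_rows[de_plan.n_mountain_like + de_plan.n_railway_like :]] = "intermediate"

    up_in_rw = rng.random(n_genes) < 0.5
    mt_mean = base.copy()
    rw_mean = np.where(
        labels == "not_de",
        base,
        np.where(up_in_rw, base * de_plan.fold, base / de_plan.fold),
    )
    bgs_mean = np.select(
        [labels == "mountain_like", labels == "railway_like", labels == "intermediate"],
        [mt_mean, rw_mean, np.sqrt(mt_mean * rw_mean)],
        default=base,
    )
    class_means = {"MT": mt_mean, "RW": rw_mean, "BGS": bgs_mean}

    pops = sorted(populations)
    flowering_rows = np.array([], dtype=int)
    if flowering is not None and flowering.n_correlated > 0:
        missing = [p for p in pops if p not in flowering.times]
        if missing:
            raise ValueError(f"no flowering time for populations {missing}")
        free = np.flatnonzero(labels == "not_de")
        if flowering.n_correlated > len(free):
            raise ValueError("not enough non-DE genes to plant correlations")
        flowering_rows = rng.choice(free, size=flowering.n_correlated,
                                    replace=False)
        ft_mean = float(np.mean([flowering.times[p] for p in pops]))

    columns, data, sample_pops = [], [], {}
    factors = {}
    for pop in pops:
        pop_mean = class_means[populations[pop]].copy()
        if len(flowering_rows):
            pop_mean[flowering_rows] = (
                base[flowering_rows] * flowering.times[pop] / ft_mean
            )
        for r in range(n_reps):
            name = f"{pop}_{r + 1}"
            sf = float(np.exp(rng.normal(0.0, depth_sd)))
            mu = pop_mean * sf
            r_nb = 1.0 / dispersion
            counts = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
            columns.append(name)
            data.append(counts)
            sample_pops[name] = pop
            factors[name] = sf
    counts = pd.DataFrame(np.column_stack(data), index=genes, columns=columns)
    correlated = np.zeros(n_genes, dtype=bool)
    correlated[flowering_rows] = True
    truth = ExpressionTruth(
        table=pd.DataFrame(
            {"gene": genes, "base_mean": base, "is_de": labels != "not_de",
             "bgs_class": labels, "flowering_correlated": correlated}
        ),
        size_factors=pd.Series(factors),
    )
    return counts, sample_pops, truth
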